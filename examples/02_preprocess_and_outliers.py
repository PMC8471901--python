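"""Absorbance, scan averaging, preprocessing and PCA outlier screening.

Converts raw intensities to absorbance A = -log10((R-D)/(S-D)), averages
the 5 consecutive scans, trims to the informative 720-955 nm region,
applies the Savitzky-Golay / SNV / detrend chain, and screens outliers
with the per-day boxplot rule on the first three PC scores.
"""

import aquamon as am

archive = am.simulate_preset("seedling_like", rng_seed=7)
# inject detector saturation and fiber-misalignment defects to screen out
archive, mis = am.inject_outliers(archive, 0.03, "misalignment", rng_seed=2)
archive, sat = am.inject_outliers(archive, 0.02, "saturation", rng_seed=1)

flags = am.screen_saturated(archive)
print(f"saturation screen : {flags.sum()} of {archive.n_sample_scans} scans"
      f" hit the detector ceiling ({len(sat)} injected)")

absorb = am.trim(am.absorbance_table(archive), 720, 955)
pca = am.fit_pca(absorb, 3)
print("explained variance:",
      [f"{f:.1%}" for f in pca.explained_variance_fraction],
      "(first three PCs of the per-scan absorbance)")

mask = am.boxplot_outliers(pca.scores, absorb.meta[["sample_type", "day"]])
recovered = mask[mis["row"].to_numpy()].mean()
print(f"boxplot screen    : {mask.sum()} scans flagged;"
      f" {recovered:.0%} of the injected misalignments recovered")

clean = am.remove_outliers(absorb.select_rows(~flags), mask[~flags])
avg = am.average_consecutive_scans(clean)
pp = am.preprocess(avg)
print(f"rows              : {archive.n_sample_scans} raw -> {clean.n_rows}"
      f" clean -> {avg.n_rows} scan-averaged")
print(f"provenance        : {' -> '.join(pp.provenance)}")
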