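"""Simulate a raw-scan archive and inspect its acquisition design.

The seedling-like preset emulates a 26-day germination monitoring study:
28 seeds scanned every other day from day 4, at 4 probe positions with 5
consecutive scans, on a 660-960 nm / 1 nm transmittance grid, with one
blank-air reference and one dark scan per day.
"""

import aquamon as am

archive = am.simulate_preset("seedling_like", rng_seed=42)
design = archive.truth.design

print(f"sample types      : {design.sample_types}")
print(f"seeds x pos x scan: {design.n_seeds_per_type} x {design.n_positions}"
      f" x {design.n_scans}")
print(f"monitored days    : {design.days}")
print(f"grid points       : {design.wavelengths.size}"
      f" ({design.wl_start:g}-{design.wl_end:g} nm)")
print(f"sample scans      : {archive.n_sample_scans}")
print(f"reference/dark    : {len(archive.references)} + {len(archive.darks)}"
      " (one of each per day)")

# The archive stores its generating truth: 3 latent seed clusters with
# different growth rates, and the planted water-pattern stage boundaries.
print(f"planted clusters  : {sorted(set(map(int, archive.truth.cluster_of_seed.ravel())))}")
print(f"stage boundaries  : {archive.truth.stage_boundaries}"
      " (days where the hydrogen-bonding state switches)")

# Round-trip through the CSV archive format:
am.write_archive(archive, "scratch/example_archive")
back = am.read_archive("scratch/example_archive")
print(f"CSV round-trip    : {back.n_sample_scans} scans re-read"
      " (samples/references/darks + truth.json)")
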