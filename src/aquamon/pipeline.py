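"""End-to-end orchestration of the monitoring workflow.

Stage order: simulate/ingest -> absorbance -> saturation screen -> scan
averaging -> trim (full range) -> preprocessing -> PCA boxplot outlier
removal -> per sample type: PLS day regression on the full and truncated
ranges, per-day Ward clustering with consensus assignment, and aquagram /
stage detection on the third-overtone range.  Sample types are processed
independently and written to disjoint subdirectories; a JSON manifest
records the configuration hash, the seed and the row counts before and
after every stage, so a run is reproducible from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aquagram as aq
from . import clustering as cl
from . import pca_outliers as po
from . import pls as plsmod
from . import spectra as sio
from . import synth
from .preprocess import PreprocessConfig, daily_average, preprocess

__all__ = ["RunConfig", "run_full", "report"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    preset: str | None = "seedling_like"
    input_dir: str | None = None
    out_dir: str = "aquamon_run"
    rng_seed: int = 0
    design_overrides: dict = field(default_factory=dict)
    full_range: tuple[float, float] = (720.0, 955.0)
    truncated_range: tuple[float, float] = (730.0, 870.0)
    aquagram_range: tuple[float, float] = (720.0, 780.0)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    outlier_components: tuple[int, ...] = (1, 2, 3)
    outlier_k: float = 1.5
    outlier_convention: str = "median"
    outlier_on: str = "preprocessed"   # or "absorbance"
    max_lv: int = 12
    n_clusters: int = 3
    average_before_removal: bool = False  # daily averages from pre-removal rows

    def __post_init__(self) -> None:
        if (self.preset is None) == (self.input_dir is None):
            raise ValueError("exactly one of preset / input_dir must be set")
        if self.preset is not None and self.preset not in synth.PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        for lo, hi in (self.full_range, self.truncated_range, self.aquagram_range):
            if lo >= hi:
                raise ValueError("range bounds must satisfy lo < hi")
        if self.outlier_convention not in ("median", "tukey"):
            raise ValueError("outlier_convention must be median or tukey")
        if self.outlier_on not in ("preprocessed", "absorbance"):
            raise ValueError("outlier_on must be preprocessed or absorbance")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["preprocess"] = self.preprocess.to_dict()
        for k in ("full_range", "truncated_range", "aquagram_range",
                  "outlier_components"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            pp = dict(d["preprocess"])
            if "order" in pp:
                pp["order"] = tuple(pp["order"])
            d["preprocess"] = PreprocessConfig(**pp)
        for k in ("full_range", "truncated_range", "aquagram_range",
                  "outlier_components"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        js = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(js.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _position_average(table: sio.SpectraTable) -> sio.SpectraTable:
    keys = ["sample_type", "seed_id", "day"]
    grouped = table.meta.groupby(keys, sort=True)
    rows, metas = [], []
    for key, idx in sorted(grouped.indices.items()):
        rows.append(table.values[idx].mean(axis=0))
        metas.append(dict(zip(keys, key)))
    return sio.SpectraTable(table.wavelengths, np.array(rows),
                            pd.DataFrame(metas),
                            table.provenance + ("position_average",))


def _analyze_type(absorb_clean: sio.SpectraTable, cfg: RunConfig,
                  out_dir: Path) -> dict:
    """Full-range + truncated-range analyses of one sample type's cleaned
    scan-averaged absorbance rows."""
    summary: dict = {}
    n_days = absorb_clean.meta["day"].nunique()
    n_seeds = absorb_clean.meta["seed_id"].nunique()

    for tag, rng in (("full", cfg.full_range), ("truncated", cfg.truncated_range)):
        table = preprocess(sio.trim(absorb_clean, *rng), cfg.preprocess)
        table.to_csv(out_dir / f"preprocessed_{tag}.csv")
        pca = po.fit_pca(table, n_components=min(3, table.n_rows - 1,
                                                 table.values.shape[1]))
        pd.DataFrame({"component": np.arange(1, pca.loadings.shape[0] + 1),
                      "explained_variance_fraction":
                          pca.explained_variance_fraction}
                     ).to_csv(out_dir / f"pca_explained_{tag}.csv", index=False)
        summary[f"pca_explained_{tag}"] = pca.explained_variance_fraction.tolist()

        if n_days >= 2 and n_seeds >= 2:
            cv = plsmod.one_seed_out_cv(table, y_key="day", max_lv=cfg.max_lv)
            cv.metrics.to_csv(out_dir / f"pls_metrics_{tag}.csv", index=False)
            cv.predictions.to_csv(out_dir / f"pls_predictions_{tag}.csv", index=False)
            model = plsmod.fit_pls1(table, np.asarray(table.meta["day"], float),
                                    cv.chosen_n_lv)
            pd.DataFrame({"wavelength_nm": table.wavelengths,
                          "coefficient": model.regression_vector}
                         ).to_csv(out_dir / f"regression_vector_{tag}.csv", index=False)
            summary[f"pls_{tag}"] = {
                "chosen_n_lv": cv.chosen_n_lv,
                "R2tr": cv.metric("R2tr"), "RMSEC": cv.metric("RMSEC"),
                "R2cv": cv.metric("R2cv"), "RMSECV": cv.metric("RMSECV"),
            }
        else:
            summary[f"pls_{tag}"] = None

        if tag == "truncated":
            daily_average(table).to_csv(out_dir / "daily_average_truncated.csv")
            # seed-level clustering on position-averaged spectra
            if n_seeds >= cfg.n_clusters and n_days >= 1:
                per_seed = _position_average(table)
                assignment = cl.cluster_seeds(per_seed, k=cfg.n_clusters)
                assignment.per_day_labels.to_csv(out_dir / "clusters_per_day.csv")
                cons = assignment.consensus.rename_axis("seed_id").reset_index()
                cons["tie"] = cons["seed_id"].isin(assignment.tie_flags)
                cons.to_csv(out_dir / "consensus_clusters.csv", index=False)
                profiles, d2 = cl.cluster_profiles(table, assignment)
                profiles.to_csv(out_dir / "cluster_profiles.csv")
                d2.to_csv(out_dir / "cluster_profiles_d2.csv")
                summary["cluster_sizes"] = assignment.consensus.value_counts() \
                    .sort_index().to_dict()
            else:
                assignment = None
                summary["cluster_sizes"] = None

    # aquagram on the third-overtone range, grouped by day; the WAMAC
    # channels are picked from the full-range preprocessed spectra so the
    # per-spectrum SNV/detrend corrections are not distorted by the narrow
    # window (a detrend fitted on 720-780 nm alone tilts the band pattern)
    aqua_table = sio.trim(preprocess(sio.trim(absorb_clean, *cfg.full_range),
                                     cfg.preprocess), *cfg.aquagram_range)
    wamacs = aq.default_wamacs()
    if n_days >= 2:
        result = aq.compute_aquagram(aqua_table, wamacs, group_key="day")
        result.values.to_csv(out_dir / "aquagram_by_day.csv")
        stages = aq.detect_stages(result, wamacs)
        summary["stages"] = [{"state": s.state, "start_day": s.start_day,
                              "end_day": s.end_day} for s in stages]
        if assignment is not None:
            cluster_col = aqua_table.meta["seed_id"].map(assignment.consensus)
            for c in sorted(assignment.consensus.unique()):
                sub = aqua_table.select_rows((cluster_col == c).to_numpy())
                if sub.meta["day"].nunique() < 2 or sub.n_rows < 2:
                    continue
                res_c = aq.compute_aquagram(sub, wamacs, group_key="day")
                res_c.values.to_csv(out_dir / f"aquagram_cluster_{c}.csv")
    else:
        result = aq.compute_aquagram(aqua_table, wamacs, group_key="sample_type") \
            if aqua_table.meta["sample_type"].nunique() >= 2 else None
        if result is not None:
            result.values.to_csv(out_dir / "aquagram_by_group.csv")
        summary["stages"] = None
    return summary


def run_full(config: RunConfig) -> dict:
    """Execute the whole workflow; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    if config.preset is not None:
        if config.preset == "water_temperature":
            design = None
        else:
            design_kw = {k: tuple(v) if isinstance(v, list) else v
                         for k, v in config.design_overrides.items()}
            types = {"seedling_like": ("seedling",), "callus_like": ("callus",)}
            design_kw.setdefault("sample_types", types[config.preset])
            design = synth.DesignSpec(**design_kw)
        truth = synth.make_preset(config.preset, design)
        archive = synth.generate_experiment(truth.design, truth, config.rng_seed)
    else:
        archive = sio.read_archive(config.input_dir)
    counts["raw_sample_scans"] = archive.n_sample_scans

    sat = sio.screen_saturated(archive)
    absorb = sio.absorbance_table(archive)
    invalid = sio.screen_saturated(absorb)  # non-positive transmittance rows
    keep = ~(sat | invalid)
    counts["saturation_flagged"] = int((~keep).sum())
    absorb = absorb.select_rows(keep, tag="saturation_screen")

    averaged = sio.average_consecutive_scans(absorb)
    counts["scan_averaged_rows"] = averaged.n_rows

    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "rng_seed": config.rng_seed,
        "counts": counts,
        "sample_types": {},
    }
    for stype in pd.unique(averaged.meta["sample_type"]):
        tdir = out / str(stype)
        tdir.mkdir(parents=True, exist_ok=True)
        sub = averaged.select_rows((averaged.meta["sample_type"] == stype).to_numpy())
        tcounts = {"rows_in": sub.n_rows}

        # outlier screen on the full analysis range
        trimmed = sio.trim(sub, *config.full_range)
        basis = preprocess(trimmed, config.preprocess) \
            if config.outlier_on == "preprocessed" else trimmed
        pca = po.fit_pca(basis, n_components=min(3, basis.n_rows - 1,
                                                 basis.values.shape[1]))
        mask = po.boxplot_outliers(
            pca.scores, basis.meta[["day"]], components=config.outlier_components,
            whisker_k=config.outlier_k, convention=config.outlier_convention)
        audit = basis.meta.copy()
        audit["outlier"] = mask
        audit.to_csv(tdir / "outlier_mask.csv", index=False)
        tcounts["outliers_removed"] = int(mask.sum())
        tcounts["removal_fraction"] = float(mask.mean())
        clean = po.remove_outliers(sub, mask)
        tcounts["rows_out"] = clean.n_rows
        log.info("%s: removed %.1f%% of rows as PCA outliers",
                 stype, 100 * tcounts["removal_fraction"])

        summary = _analyze_type(clean, config, tdir)
        summary["counts"] = tcounts
        manifest["sample_types"][str(stype)] = summary

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(manifest), fh, indent=1, sort_keys=True)
    return manifest


def report(manifest: dict | str | Path) -> dict[str, pd.DataFrame]:
    """Summary tables from a run manifest (idempotent; partial runs yield
    partial tables with missing-stage markers)."""
    if not isinstance(manifest, dict):
        with open(Path(manifest) if not isinstance(manifest, Path) else manifest,
                  encoding="utf-8") as fh:
            manifest = json.load(fh)
    pls_rows, ev_rows, cluster_rows, stage_rows = [], [], [], []
    for stype, s in manifest.get("sample_types", {}).items():
        for tag in ("full", "truncated"):
            m = s.get(f"pls_{tag}")
            if m is None:
                pls_rows.append({"sample_type": stype, "range": tag,
                                 "status": "missing"})
            else:
                pls_rows.append({"sample_type": stype, "range": tag,
                                 "status": "ok", **m})
            ev = s.get(f"pca_explained_{tag}")
            if ev is not None:
                for i, f in enumerate(ev, start=1):
                    ev_rows.append({"sample_type": stype, "range": tag,
                                    "component": i, "explained_fraction": f})
        cs = s.get("cluster_sizes")
        if cs:
            # JSON round-trips stringify the cluster keys
            items = sorted((int(c), n) for c, n in cs.items())
            for c, n in items:
                cluster_rows.append({"sample_type": stype, "cluster": c, "n_seeds": n})
        stages = s.get("stages")
        if stages is None:
            stage_rows.append({"sample_type": stype, "status": "missing"})
        else:
            for st in stages:
                stage_rows.append({"sample_type": stype, "status": "ok", **st})
    def frame(rows: list[dict], lead: list[str]) -> pd.DataFrame:
        df = pd.DataFrame(rows)
        cols = [c for c in lead if c in df.columns]
        cols += sorted(c for c in df.columns if c not in cols)
        return df[cols] if len(df) else df

    return {
        "pls_metrics": frame(pls_rows, ["sample_type", "range", "status",
                                        "chosen_n_lv"]),
        "pca_explained": frame(ev_rows, ["sample_type", "range", "component"]),
        "consensus_clusters": frame(cluster_rows, ["sample_type", "cluster"]),
        "stages": frame(stage_rows, ["sample_type", "status", "state",
                                     "start_day", "end_day"]),
        "counts": pd.DataFrame([manifest.get("counts", {})]),
    }
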