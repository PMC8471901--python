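"""Synthetic SWNIR transmittance archives with known ground truth.

The generator emulates a longitudinal transmittance monitoring study:
seeds (or callus masses) measured every other day on a 660-960 nm / 1 nm
grid, 4 probe positions x 5 consecutive scans per seed and day, with one
blank-air reference and one dark scan per day.

Forward model (Beer-Lambert with additive instrument effects):

    R(l) = D(l) + (S(l) - D(l)) * 10**(-A(l))
    A(l) = offset + slope*(l - l0)
           + path * sum_b amp_b * exp(-(l - c_b)^2 / (2 w_b^2))
           + tau * tempshape(l) + 0.5*tau + eps(l)

where ``offset``/``slope`` are per-(seed, day, position) baseline draws
(seed size/geometry), ``path`` a per-(seed, day) log-normal optical
path-length multiplier (growth), ``tau`` a per-scan temperature jitter
driving a correlated baseline shift shaped around the 835 nm and 794 nm
water bands, and ``eps`` white absorbance noise.  Band amplitudes carry
the biology: per sample type, per latent seed cluster and per day.

Three presets are provided:

``seedling_like``
    Stage-structured germination dynamics: weakly hydrogen-bonded water
    bands (731/736/745 nm) dominate early (days 4-14) and late (days
    22-26), strongly hydrogen-bonded bands (752-775 nm) dominate in
    between (days 16-20); monotone growth trend plus a declining 810 nm
    (oxidative metabolism) band makes the day of development learnable.
``callus_like``
    A band-amplitude random walk whose trend freezes after day 14
    (arrested proliferation); no stable water-pattern stages.
``water_temperature``
    A single-day design whose groups are water temperatures: weak-bond
    band amplitudes increase and strong-bond amplitudes decrease with
    temperature, the classical hot/cold water aquagram contrast.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectra import RawScanArchive, SpectraTable, SATURATION_CEILING

__all__ = [
    "DesignSpec",
    "Band",
    "GroundTruth",
    "make_preset",
    "generate_experiment",
    "inject_outliers",
    "simulate_preset",
    "PRESETS",
    "WEAK_BANDS",
    "STRONG_BANDS",
]

WEAK_BANDS = (731.0, 736.0, 745.0)
STRONG_BANDS = (752.0, 761.0, 768.0, 772.0, 775.0)

PRESETS = ("seedling_like", "callus_like", "water_temperature")


@dataclass(frozen=True)
class DesignSpec:
    """Acquisition design: who is scanned, how often, on which grid."""

    sample_types: tuple[str, ...] = ("seedling", "callus")
    n_seeds_per_type: int = 28
    n_positions: int = 4
    n_scans: int = 5
    days: tuple[int, ...] = tuple(range(4, 27, 2))
    wl_start: float = 660.0
    wl_end: float = 960.0
    wl_step: float = 1.0

    def __post_init__(self) -> None:
        if len(self.days) == 0:
            raise ValueError("days list must not be empty")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        if self.wl_step <= 0:
            raise ValueError("wavelength step must be positive")
        if min(self.n_seeds_per_type, self.n_positions, self.n_scans) < 1:
            raise ValueError("counts must be >= 1")
        if len(self.sample_types) < 1:
            raise ValueError("at least one sample type required")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.wl_end - self.wl_start) / self.wl_step)) + 1
        return self.wl_start + self.wl_step * np.arange(n)

    @property
    def n_sample_scans(self) -> int:
        return (len(self.sample_types) * self.n_seeds_per_type
                * self.n_positions * self.n_scans * len(self.days))


@dataclass(frozen=True)
class Band:
    center: float
    width: float
    label: str  # weak | strong | other

    def shape(self, wl: np.ndarray) -> np.ndarray:
        return np.exp(-((wl - self.center) ** 2) / (2.0 * self.width ** 2))


@dataclass
class GroundTruth:
    """Everything the generator knows and the analysis should recover."""

    preset: str
    design: DesignSpec
    bands: tuple[Band, ...]
    #: (n_types, n_clusters, n_days, n_bands), absorbance units, >= 0
    amplitudes: np.ndarray
    #: (n_types, n_seeds) latent cluster labels in 1..n_clusters
    cluster_of_seed: np.ndarray
    baseline_offset_mean: float = 0.30
    baseline_offset_sd: float = 0.05
    baseline_slope_sd: float = 5e-4
    path_sigma: float = 0.10
    temperature_jitter_sd: float = 0.010
    noise_sd: float = 0.010
    stage_boundaries: tuple[int, int] | None = None
    trend_halt_day: int | None = None
    temperatures: tuple[float, ...] | None = None
    outlier_spec: dict | None = None

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(self.amplitudes < 0):
            raise ValueError("band amplitudes must be non-negative")
        expect = (len(self.design.sample_types), self.n_clusters,
                  len(self.design.days), len(self.bands))
        if self.amplitudes.shape != expect:
            raise ValueError(f"amplitudes shape {self.amplitudes.shape} != {expect}")
        self.cluster_of_seed = np.asarray(self.cluster_of_seed, dtype=int)
        if self.cluster_of_seed.shape != (len(self.design.sample_types),
                                          self.design.n_seeds_per_type):
            raise ValueError("cluster_of_seed must be (n_types, n_seeds)")
        labels = np.unique(self.cluster_of_seed)
        if labels.min() < 1 or labels.max() > self.n_clusters or len(labels) > 3:
            raise ValueError("cluster labels must lie in 1..n_clusters (<= 3 groups)")

    @property
    def n_clusters(self) -> int:
        return self.amplitudes.shape[1]

    def band_index(self, center: float) -> int:
        for i, b in enumerate(self.bands):
            if b.center == center:
                return i
        raise KeyError(f"no band at {center} nm")

    def mean_amplitude(self, label: str, day: int, sample_type_idx: int = 0) -> float:
        """Mean true amplitude over bands with a label, averaged over clusters."""
        di = self.design.days.index(day)
        cols = [i for i, b in enumerate(self.bands) if b.label == label]
        return float(self.amplitudes[sample_type_idx, :, di, cols].mean())

    def to_json_dict(self) -> dict:
        d = {
            "preset": self.preset,
            "design": {
                "sample_types": list(self.design.sample_types),
                "n_seeds_per_type": self.design.n_seeds_per_type,
                "n_positions": self.design.n_positions,
                "n_scans": self.design.n_scans,
                "days": list(self.design.days),
                "wl_start": self.design.wl_start,
                "wl_end": self.design.wl_end,
                "wl_step": self.design.wl_step,
            },
            "bands": [{"center": b.center, "width": b.width, "label": b.label}
                      for b in self.bands],
            "amplitudes": self.amplitudes.tolist(),
            "cluster_of_seed": self.cluster_of_seed.tolist(),
            "baseline_offset_mean": self.baseline_offset_mean,
            "baseline_offset_sd": self.baseline_offset_sd,
            "baseline_slope_sd": self.baseline_slope_sd,
            "path_sigma": self.path_sigma,
            "temperature_jitter_sd": self.temperature_jitter_sd,
            "noise_sd": self.noise_sd,
            "stage_boundaries": list(self.stage_boundaries) if self.stage_boundaries else None,
            "trend_halt_day": self.trend_halt_day,
            "temperatures": list(self.temperatures) if self.temperatures else None,
            "outlier_spec": self.outlier_spec,
        }
        return d


# ---------------------------------------------------------------------------
# presets

def _common_bands() -> tuple[Band, ...]:
    weak = tuple(Band(c, 5.0, "weak") for c in WEAK_BANDS)
    strong = tuple(Band(c, 5.0, "strong") for c in STRONG_BANDS)
    other = (
        Band(794.0, 14.0, "other"),   # temperature-sensitive shoulder
        Band(810.0, 10.0, "other"),   # oxidative metabolism / proliferation
        Band(835.0, 20.0, "other"),   # bulk water / path length, temperature
        Band(890.0, 12.0, "other"),   # 3rd overtone of CH (medium sugars)
    )
    return weak + strong + other

_WEAK_BASE = {731.0: 0.24, 736.0: 0.22, 745.0: 0.20}
_STRONG_BASE = {752.0: 0.16, 761.0: 0.17, 768.0: 0.15, 772.0: 0.14, 775.0: 0.14}
_CLUSTER_RATE = (0.8, 1.0, 1.2)        # growth-rate multipliers of the 3 clusters
_CLUSTER_SIGNATURE = (0.85, 1.0, 1.15)  # cluster-specific weight of the 761 nm band


def _cycle_clusters(design: DesignSpec, k: int = 3) -> np.ndarray:
    seeds = np.arange(design.n_seeds_per_type)
    row = seeds % k + 1
    return np.tile(row, (len(design.sample_types), 1))


def _seedling_amplitudes(design: DesignSpec, bands: tuple[Band, ...]) -> np.ndarray:
    n_t, n_c = len(design.sample_types), 3
    amps = np.zeros((n_t, n_c, len(design.days), len(bands)))
    for ci, rate in enumerate(_CLUSTER_RATE):
        for di, day in enumerate(design.days):
            growth = 1.0 + 0.06 * rate * (day - design.days[0])
            weak_w = 1.0 if (day <= 14 or day >= 22) else 0.40
            strong_w = 1.0 if 16 <= day <= 20 else 0.40
            for bi, b in enumerate(bands):
                if b.label == "weak":
                    a = _WEAK_BASE[b.center] * weak_w * growth
                elif b.label == "strong":
                    a = _STRONG_BASE[b.center] * strong_w * growth
                    if b.center == 761.0:
                        a *= _CLUSTER_SIGNATURE[ci]
                elif b.center == 810.0:
                    a = 0.20 * (1.0 - 0.5 * (day - 4) / 22.0)
                elif b.center == 835.0:
                    a = 0.30
                elif b.center == 890.0:
                    a = 0.15 * (1.0 + 0.10 * rate * (day - 4))
                else:  # 794 shoulder
                    a = 0.10
                amps[:, ci, di, bi] = a
    return amps


def _callus_amplitudes(design: DesignSpec, bands: tuple[Band, ...],
                       halt_day: int = 14) -> np.ndarray:
    # Deterministic preset: the random walk uses a fixed internal stream.
    walk_rng = np.random.default_rng(90210)
    n_t, n_c = len(design.sample_types), 3
    amps = np.zeros((n_t, n_c, len(design.days), len(bands)))
    base = {**{c: 0.20 for c in WEAK_BANDS}, **{c: 0.18 for c in STRONG_BANDS}}
    # one shared walk per band (the biology, not the replicate noise)
    log_walk = np.zeros((len(design.days), len(bands)))
    for di in range(1, len(design.days)):
        day = design.days[di]
        step = walk_rng.normal(0.0, 0.25, size=len(bands))
        log_walk[di] = log_walk[di - 1] + (step if day <= halt_day else 0.0)
    for ci, rate in enumerate(_CLUSTER_RATE):
        for di, day in enumerate(design.days):
            eff_day = min(day, halt_day)
            growth = 1.0 + 0.05 * rate * (eff_day - design.days[0])
            for bi, b in enumerate(bands):
                if b.label in ("weak", "strong"):
                    a = base[b.center] * growth * float(np.exp(log_walk[di, bi]))
                    if b.center == 761.0:
                        a *= _CLUSTER_SIGNATURE[ci]
                elif b.center == 810.0:
                    a = 0.20 * (1.0 - 0.5 * (eff_day - 4) / 22.0)
                elif b.center == 835.0:
                    a = 0.30
                elif b.center == 890.0:
                    a = 0.15 * (1.0 + 0.10 * rate * (eff_day - 4))
                else:
                    a = 0.10
                amps[:, ci, di, bi] = a
    return amps


def _water_temperature_truth() -> GroundTruth:
    temps = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0)
    design = DesignSpec(
        sample_types=tuple(f"water_{int(t)}C" for t in temps),
        n_seeds_per_type=8, n_positions=1, n_scans=3, days=(1,),
    )
    bands = _common_bands()
    amps = np.zeros((len(temps), 1, 1, len(bands)))
    for ti, t in enumerate(temps):
        for bi, b in enumerate(bands):
            if b.label == "weak":
                a = 0.18 * (1.0 + 0.012 * (t - 35.0))
            elif b.label == "strong":
                a = 0.18 * (1.0 - 0.012 * (t - 35.0))
            elif b.center == 835.0:
                a = 0.30
            elif b.center == 890.0:
                a = 0.03
            else:
                a = 0.08
            amps[ti, 0, 0, bi] = a
    return GroundTruth(
        preset="water_temperature", design=design, bands=bands,
        amplitudes=amps, cluster_of_seed=np.ones((len(temps), 8), dtype=int),
        baseline_offset_sd=0.03, path_sigma=0.05, noise_sd=0.005,
        temperatures=temps,
    )


def make_preset(name: str, design: DesignSpec | None = None) -> GroundTruth:
    """Build the ground truth of a named study scenario.

    ``design`` overrides the preset's default acquisition design (the
    water_temperature preset fixes its own design).
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; valid presets: {', '.join(PRESETS)}")
    if name == "water_temperature":
        if design is not None:
            raise ValueError("water_temperature carries its own single-day design")
        return _water_temperature_truth()
    if design is None:
        types = ("seedling",) if name == "seedling_like" else ("callus",)
        design = DesignSpec(sample_types=types)
    bands = _common_bands()
    if name == "seedling_like":
        amps = _seedling_amplitudes(design, bands)
        return GroundTruth(preset=name, design=design, bands=bands,
                           amplitudes=amps,
                           cluster_of_seed=_cycle_clusters(design),
                           stage_boundaries=(16, 22))
    amps = _callus_amplitudes(design, bands)
    return GroundTruth(preset=name, design=design, bands=bands,
                       amplitudes=amps,
                       cluster_of_seed=_cycle_clusters(design),
                       trend_halt_day=14)


# ---------------------------------------------------------------------------
# forward simulation

def _reference_shape(wl: np.ndarray) -> np.ndarray:
    return 30000.0 + 18000.0 * np.exp(-((wl - 800.0) / 130.0) ** 2)


def generate_experiment(design: DesignSpec, truth: GroundTruth,
                        rng_seed: int) -> RawScanArchive:
    """Simulate a full raw-scan archive; bit-identical for a given seed."""
    if design.sample_types != truth.design.sample_types \
            or design.days != truth.design.days \
            or design.n_seeds_per_type != truth.design.n_seeds_per_type:
        raise ValueError("design and ground truth are inconsistent "
                         "(sample types / seeds / days differ)")
    wl = design.wavelengths
    if wl.size < 3:
        raise ValueError("wavelength grid must have at least 3 points")
    rng = np.random.default_rng(rng_seed)
    l0 = float(wl[wl.size // 2])

    n_t = len(design.sample_types)
    n_s, n_p, n_k = design.n_seeds_per_type, design.n_positions, design.n_scans
    days = design.days

    band_shapes = np.array([b.shape(wl) for b in truth.bands])  # (n_b, p)
    tempshape = (np.exp(-((wl - 835.0) ** 2) / (2 * 20.0 ** 2))
                 + 0.5 * np.exp(-((wl - 794.0) ** 2) / (2 * 14.0 ** 2)))

    s0 = _reference_shape(wl)
    references: dict[int, np.ndarray] = {}
    darks: dict[int, np.ndarray] = {}
    for day in days:
        references[int(day)] = s0 * (1.0 + 0.02 * rng.normal())
        darks[int(day)] = 500.0 + 3.0 * rng.normal(size=wl.size)

    meta_rows = []
    blocks_true = []
    blocks_inten = []
    cluster_idx = truth.cluster_of_seed - 1  # (n_t, n_s), 0-based
    for di, day in enumerate(days):
        nrow = n_t * n_s * n_p * n_k
        offset = rng.normal(truth.baseline_offset_mean, truth.baseline_offset_sd,
                            size=(n_t, n_s, n_p))
        slope = rng.normal(0.0, truth.baseline_slope_sd, size=(n_t, n_s, n_p))
        path = np.exp(rng.normal(0.0, truth.path_sigma, size=(n_t, n_s)))
        tau = rng.normal(0.0, truth.temperature_jitter_sd, size=(n_t, n_s, n_p, n_k))
        eps = rng.normal(0.0, truth.noise_sd, size=(nrow, wl.size)) \
            if truth.noise_sd > 0 else np.zeros((nrow, wl.size))

        # per-row expansion, row order: type, seed, position, scan
        off_r = np.repeat(offset.ravel(), n_k)
        slo_r = np.repeat(slope.ravel(), n_k)
        path_r = np.repeat(path.ravel(), n_p * n_k)
        tau_r = tau.ravel()
        amp_seed = truth.amplitudes[np.arange(n_t)[:, None], cluster_idx, di, :]
        amps_r = np.repeat(amp_seed.reshape(n_t * n_s, -1), n_p * n_k, axis=0)

        a_true = (off_r[:, None]
                  + slo_r[:, None] * (wl - l0)[None, :]
                  + path_r[:, None] * (amps_r @ band_shapes)
                  + tau_r[:, None] * tempshape[None, :]
                  + 0.5 * tau_r[:, None])
        a_obs = a_true + eps
        s, d = references[int(day)], darks[int(day)]
        inten = d[None, :] + (s - d)[None, :] * np.power(10.0, -a_obs)

        blocks_true.append(a_true)
        blocks_inten.append(inten)
        for t, seed, pos, scan in itertools.product(
                range(n_t), range(n_s), range(n_p), range(n_k)):
            meta_rows.append((design.sample_types[t], seed + 1, int(day),
                              pos + 1, scan + 1))

    meta = pd.DataFrame(meta_rows, columns=["sample_type", "seed_id", "day",
                                            "position", "scan_index"])
    samples = SpectraTable(wl, np.vstack(blocks_inten), meta)
    return RawScanArchive(wl, samples, references, darks, truth=truth,
                          true_absorbance=np.vstack(blocks_true))


def simulate_preset(name: str, rng_seed: int,
                    design: DesignSpec | None = None) -> RawScanArchive:
    """Convenience: ``generate_experiment(design, make_preset(name), seed)``."""
    truth = make_preset(name, design)
    return generate_experiment(truth.design, truth, rng_seed)


# ---------------------------------------------------------------------------
# defect injection

def inject_outliers(archive: RawScanArchive, fraction: float, mode: str,
                    rng_seed: int) -> tuple[RawScanArchive, pd.DataFrame]:
    """Corrupt a fraction of sample scans; returns (archive, defect labels).

    ``saturation`` boosts the scan until it clips at the detector ceiling;
    ``misalignment`` adds a large random absorbance offset (0.8-1.6 AU),
    as a badly coupled fiber would.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if mode not in ("saturation", "misalignment"):
        raise ValueError("mode must be 'saturation' or 'misalignment'")
    n = archive.n_sample_scans
    n_defects = int(np.floor(fraction * n + 0.5))
    rng = np.random.default_rng(rng_seed)
    values = archive.samples.values.copy()
    idx = np.sort(rng.choice(n, size=n_defects, replace=False)) if n_defects else \
        np.array([], dtype=int)
    days = np.asarray(archive.samples.meta["day"], dtype=int)
    for i in idx:
        row = values[i]
        if mode == "saturation":
            boost = 1.5 * SATURATION_CEILING / row.max()
            values[i] = np.minimum(row * boost, SATURATION_CEILING)
        else:
            d = archive.darks[int(days[i])]
            delta = rng.uniform(0.8, 1.6)
            values[i] = d + (row - d) * 10.0 ** (-delta)
    labels = pd.DataFrame({"row": idx, "mode": mode})
    samples = SpectraTable(archive.wavelengths, values,
                           archive.samples.meta.copy(),
                           archive.samples.provenance)
    out = RawScanArchive(archive.wavelengths, samples,
                         dict(archive.references), dict(archive.darks),
                         truth=archive.truth,
                         true_absorbance=archive.true_absorbance)
    return out, labels
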