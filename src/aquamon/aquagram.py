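"""Aquagrams: normalized water-band absorbance patterns and stage detection.

An aquagram summarizes a set of spectra at a small set of water matrix
coordinates (WAMACs) — wavelengths where distinct water molecular species
absorb.  For each WAMAC the per-spectrum absorbances are z-scored over
the whole analyzed set, then averaged per group (day, temperature,
cluster, ...), giving a dimensionless group x band matrix whose
group-size-weighted column means are exactly zero.

In the third overtone region (720-780 nm) the default WAMAC set splits
into weakly hydrogen-bonded species (731, 736, 745 nm; hot-water-like)
and strongly hydrogen-bonded species (752, 761, 768, 772, 775 nm;
cold-water/ice-like).  A day-by-day aquagram trajectory can therefore be
read as a hydrogen-bonding state sequence; merging consecutive days with
the same state yields developmental stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import SpectraTable

__all__ = ["WamacSet", "AquagramResult", "Stage", "default_wamacs",
           "compute_aquagram", "classify_hbond_state", "detect_stages"]


@dataclass(frozen=True)
class WamacSet:
    """Ordered water matrix coordinates with hydrogen-bonding class labels."""

    bands: tuple[tuple[float, str], ...]  # (wavelength nm, "weak"|"strong")

    def __post_init__(self) -> None:
        for wl, label in self.bands:
            if label not in ("weak", "strong"):
                raise ValueError(f"band label must be weak/strong, got {label!r}")

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(wl for wl, _ in self.bands)

    @property
    def weak(self) -> tuple[float, ...]:
        return tuple(wl for wl, l in self.bands if l == "weak")

    @property
    def strong(self) -> tuple[float, ...]:
        return tuple(wl for wl, l in self.bands if l == "strong")

    def swapped(self) -> "WamacSet":
        return WamacSet(tuple((wl, "strong" if l == "weak" else "weak")
                              for wl, l in self.bands))


def default_wamacs() -> WamacSet:
    """The 8 third-overtone water bands: 3 weakly and 5 strongly H-bonded."""
    return WamacSet((
        (731.0, "weak"), (736.0, "weak"), (745.0, "weak"),
        (752.0, "strong"), (761.0, "strong"), (768.0, "strong"),
        (772.0, "strong"), (775.0, "strong"),
    ))


@dataclass
class AquagramResult:
    groups: tuple
    values: pd.DataFrame              # groups x WAMAC wavelengths (z-units)
    normalization_stats: pd.DataFrame  # per band: mean, sd
    group_sizes: pd.Series
    group_key: str

    def row(self, group) -> np.ndarray:
        return self.values.loc[group].to_numpy()


def _band_values(table: SpectraTable, wamacs: WamacSet) -> np.ndarray:
    """Per-spectrum absorbance at each WAMAC (nearest grid point when the
    band sits on the grid, linear interpolation otherwise)."""
    wl = table.wavelengths
    step = table.step
    cols = []
    for band in wamacs.wavelengths:
        if band < wl[0] or band > wl[-1]:
            raise ValueError(f"WAMAC {band} nm outside the grid "
                             f"[{wl[0]:g}, {wl[-1]:g}]")
        j = int(round((band - wl[0]) / step))
        if abs(wl[j] - band) < 1e-9:
            cols.append(table.values[:, j])
        else:
            cols.append(np.array([np.interp(band, wl, row) for row in table.values]))
    return np.column_stack(cols)


def compute_aquagram(table: SpectraTable, wamacs: WamacSet | None = None,
                     group_key: str = "day") -> AquagramResult:
    """Z-score each WAMAC over all spectra, then average per group."""
    wamacs = wamacs or default_wamacs()
    if table.n_rows < 2:
        raise ValueError("aquagram needs at least 2 spectra")
    if group_key not in table.meta.columns:
        raise ValueError(f"rows carry no {group_key!r} metadata")
    vals = _band_values(table, wamacs)
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    for band, s in zip(wamacs.wavelengths, sd):
        if s == 0:
            raise ValueError(f"zero variance at WAMAC {band:g} nm")
    z = (vals - mu) / sd
    groups = table.meta[group_key]
    order = list(pd.unique(groups))
    try:
        order = sorted(order)
    except TypeError:
        pass
    rows = {g: z[(groups == g).to_numpy()].mean(axis=0) for g in order}
    values = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=list(wamacs.wavelengths))
    stats = pd.DataFrame({"mean": mu, "sd": sd}, index=list(wamacs.wavelengths))
    sizes = groups.value_counts().reindex(order)
    return AquagramResult(tuple(order), values, stats, sizes, group_key)


def classify_hbond_state(aquagram_row: np.ndarray | pd.Series, wamacs: WamacSet,
                         tau: float = 0.0) -> str:
    """weak / strong / mixed by the weak-minus-strong band mean contrast."""
    if isinstance(aquagram_row, pd.Series):
        row = aquagram_row
    else:
        row = pd.Series(np.asarray(aquagram_row, float),
                        index=list(wamacs.wavelengths))
    diff = row[list(wamacs.weak)].mean() - row[list(wamacs.strong)].mean()
    if diff > tau:
        return "weak"
    if diff < -tau:
        return "strong"
    return "mixed"


@dataclass(frozen=True)
class Stage:
    state: str
    start_day: int
    end_day: int


def detect_stages(aquagram_by_day: AquagramResult, wamacs: WamacSet | None = None,
                  tau: float = 0.0) -> list[Stage]:
    """Classify each day and merge consecutive equal states into stages.

    Stage boundaries are the start days of the second and later stages.
    Swapping the weak/strong band labels flips every state.
    """
    wamacs = wamacs or default_wamacs()
    days = sorted(int(g) for g in aquagram_by_day.groups)
    states = [classify_hbond_state(aquagram_by_day.values.loc[d], wamacs, tau)
              for d in days]
    stages: list[Stage] = []
    for day, state in zip(days, states):
        if stages and stages[-1].state == state:
            stages[-1] = Stage(state, stages[-1].start_day, day)
        else:
            stages.append(Stage(state, day, day))
    return stages


def stage_boundaries(stages: list[Stage]) -> list[int]:
    return [s.start_day for s in stages[1:]]
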