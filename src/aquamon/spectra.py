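"""Spectral containers, absorbance computation and archive I/O.

The instrument model is a short-wave NIR transmittance setup: for every
monitored day a *reference* scan (blank air, lamp on) and a *dark* scan
(lamp off) are taken once, and every sample scan of that day is converted
to absorbance against them,

    T(lambda) = (R - D) / (S - D),        A(lambda) = -log10 T(lambda)

with R the sample intensity, S the reference and D the dark.  The plain
dark-corrected transmittance ratio is also available (``mode="ratio"``)
because some instrument software reports that quantity directly.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawScan",
    "RawScanArchive",
    "SpectraTable",
    "compute_absorbance",
    "absorbance_table",
    "average_consecutive_scans",
    "trim",
    "screen_saturated",
    "read_archive",
    "write_archive",
    "SATURATION_CEILING",
]

#: Detector full-scale count used by the simulator and the saturation screen.
SATURATION_CEILING = 65535.0

META_COLUMNS = ["sample_type", "seed_id", "day", "position", "scan_index"]


def _check_grid(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size < 2:
        raise ValueError("wavelength grid needs at least 2 points")
    d = np.diff(wl)
    if np.any(d <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    if not np.allclose(d, d[0]):
        raise ValueError("wavelength grid must have a uniform step")
    return wl


@dataclass(frozen=True)
class RawScan:
    """One detector read-out: intensities on a uniform nm grid plus metadata.

    ``meta['kind']`` is one of ``sample``, ``reference``, ``dark``.
    Reference and dark scans carry a ``day`` but no seed/position.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    meta: dict

    def __post_init__(self) -> None:
        wl = _check_grid(self.wavelengths)
        inten = np.asarray(self.intensities, dtype=float)
        if inten.shape != wl.shape:
            raise ValueError("intensities and wavelengths differ in length")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", inten)


@dataclass
class SpectraTable:
    """A matrix of spectra (rows) on a shared wavelength grid (columns).

    ``meta`` holds one row of metadata per spectrum; ``provenance`` is an
    append-only tuple of tags recording every transformation applied, in
    order.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    meta: pd.DataFrame
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.wavelengths = _check_grid(self.wavelengths)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (rows x wavelengths)")
        if self.values.shape[1] != self.wavelengths.size:
            raise ValueError("values width must match the wavelength grid")
        if len(self.meta) != self.values.shape[0]:
            raise ValueError("meta must have one row per spectrum")
        self.meta = self.meta.reset_index(drop=True)
        self.provenance = tuple(self.provenance)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    def with_values(self, values: np.ndarray, tag: str) -> "SpectraTable":
        """Return a copy with new values and an appended provenance tag."""
        return SpectraTable(self.wavelengths, values, self.meta.copy(),
                            self.provenance + (tag,))

    def select_rows(self, mask: np.ndarray, tag: str | None = None) -> "SpectraTable":
        mask = np.asarray(mask, dtype=bool)
        prov = self.provenance + ((tag,) if tag else ())
        return SpectraTable(self.wavelengths, self.values[mask],
                            self.meta.loc[mask].copy(), prov)

    def to_csv(self, path: str | Path) -> None:
        wide = pd.DataFrame(self.values,
                            columns=[f"{wl:g}" for wl in self.wavelengths])
        df = pd.concat([self.meta.reset_index(drop=True), wide], axis=1)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# provenance: {' | '.join(self.provenance)}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraTable":
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
            provenance: tuple[str, ...] = ()
            if first.startswith("# provenance:"):
                tail = first.split(":", 1)[1].strip()
                provenance = tuple(t for t in (s.strip() for s in tail.split("|")) if t)
            else:
                fh.seek(0)
            df = pd.read_csv(fh)
        wl_cols = [c for c in df.columns if _is_number(c)]
        meta_cols = [c for c in df.columns if c not in wl_cols]
        wl = np.array([float(c) for c in wl_cols])
        return cls(wl, df[wl_cols].to_numpy(float), df[meta_cols], provenance)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


@dataclass
class RawScanArchive:
    """All raw scans of one monitoring experiment.

    ``samples`` holds every sample scan; ``references`` and ``darks`` map
    day -> intensity vector (one blank-air reference and one dark read-out
    per day).  When produced by the simulator, ``truth`` carries the
    generating parameters and ``true_absorbance`` the noise-free absorbance
    of every sample scan, for recovery tests.
    """

    wavelengths: np.ndarray
    samples: SpectraTable
    references: dict[int, np.ndarray]
    darks: dict[int, np.ndarray]
    truth: object | None = None
    true_absorbance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = _check_grid(self.wavelengths)
        for day in sorted(set(self.samples.meta["day"])):
            if int(day) not in self.references:
                raise ValueError(f"missing reference scan for day {int(day)}")
            if int(day) not in self.darks:
                raise ValueError(f"missing dark scan for day {int(day)}")

    @property
    def n_sample_scans(self) -> int:
        return self.samples.n_rows

    @property
    def days(self) -> list[int]:
        return sorted(int(d) for d in set(self.samples.meta["day"]))


# ---------------------------------------------------------------------------
# absorbance

def compute_absorbance(sample: RawScan, reference: RawScan, dark: RawScan,
                       mode: str = "neg_log10") -> np.ndarray:
    """Absorbance (default) or dark-corrected transmittance of one scan.

    Non-positive transmittance channels (detector artifacts) are returned
    as NaN in ``neg_log10`` mode so they can be flagged downstream.
    """
    if mode not in ("neg_log10", "ratio"):
        raise ValueError(f"unknown mode {mode!r}; use 'neg_log10' or 'ratio'")
    for other in (reference, dark):
        if not np.array_equal(sample.wavelengths, other.wavelengths):
            raise ValueError("sample/reference/dark wavelength grids differ")
    if "day" in sample.meta and "day" in reference.meta:
        if sample.meta["day"] != reference.meta["day"]:
            raise ValueError("reference scan is not from the sample's day")
    denom = reference.intensities - dark.intensities
    if np.any(denom == 0):
        raise ValueError("reference equals dark at some channel (S - D = 0)")
    t = (sample.intensities - dark.intensities) / denom
    if mode == "ratio":
        return t
    with np.errstate(divide="ignore", invalid="ignore"):
        a = -np.log10(np.where(t > 0, t, np.nan))
    return a


def absorbance_table(archive: RawScanArchive, mode: str = "neg_log10") -> SpectraTable:
    """Convert every sample scan of an archive using its day's reference/dark."""
    days = np.asarray(archive.samples.meta["day"], dtype=int)
    inten = archive.samples.values
    out = np.empty_like(inten)
    for day in archive.days:
        s = archive.references[day]
        d = archive.darks[day]
        denom = s - d
        if np.any(denom == 0):
            raise ValueError(f"reference equals dark at some channel on day {day}")
        rows = days == day
        t = (inten[rows] - d) / denom
        if mode == "ratio":
            out[rows] = t
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                out[rows] = -np.log10(np.where(t > 0, t, np.nan))
    return SpectraTable(archive.wavelengths, out, archive.samples.meta.copy(),
                        archive.samples.provenance + (f"absorbance[{mode}]",))


# ---------------------------------------------------------------------------
# table operations

def average_consecutive_scans(table: SpectraTable) -> SpectraTable:
    """Average the consecutive scans of each (type, seed, day, position).

    Groups with unequal scan counts are averaged over the scans present,
    with a warning (incomplete acquisition).
    """
    if "scan_index" not in table.meta.columns:
        raise ValueError("rows carry no scan_index; nothing to average")
    keys = ["sample_type", "seed_id", "day", "position"]
    grouped = table.meta.groupby(keys, sort=False)
    sizes = grouped.size()
    if sizes.nunique() > 1:
        warnings.warn("incomplete scan groups; averaging over available scans",
                      stacklevel=2)
    rows = []
    metas = []
    for key, idx in grouped.indices.items():
        rows.append(table.values[idx].mean(axis=0))
        metas.append(dict(zip(keys, key)))
    meta = pd.DataFrame(metas)
    return SpectraTable(table.wavelengths, np.array(rows), meta,
                        table.provenance + ("scan_average",))


def trim(table: SpectraTable, lo: float, hi: float) -> SpectraTable:
    """Keep columns with lo <= lambda <= hi (inclusive endpoints)."""
    if lo >= hi:
        raise ValueError("trim requires lo < hi")
    keep = (table.wavelengths >= lo) & (table.wavelengths <= hi)
    if not keep.any():
        raise ValueError(f"trim({lo}, {hi}) leaves no wavelengths on the grid")
    tag = f"trim[{lo:g},{hi:g}]"
    if table.provenance and table.provenance[-1] == tag:
        return dataclasses.replace(table)  # idempotent re-trim
    return SpectraTable(table.wavelengths[keep], table.values[:, keep],
                        table.meta.copy(), table.provenance + (tag,))


def screen_saturated(data: RawScanArchive | SpectraTable,
                     ceiling: float = SATURATION_CEILING) -> np.ndarray:
    """Flag scans that hit the detector ceiling or contain invalid channels.

    For a raw archive, a sample scan is flagged when its maximum intensity
    reaches ``ceiling``.  For an absorbance table, rows containing
    non-finite values (from non-positive transmittance) are flagged.
    Deterministic by construction.
    """
    if ceiling <= 0:
        raise ValueError("ceiling must be positive")
    if isinstance(data, RawScanArchive):
        return data.samples.values.max(axis=1) >= ceiling
    return ~np.isfinite(data.values).all(axis=1)


# ---------------------------------------------------------------------------
# archive I/O (wide CSV dialect: one file per scan kind)

def write_archive(archive: RawScanArchive, path: str | Path) -> None:
    """Write an archive as samples.csv / references.csv / darks.csv.

    Wide layout: metadata columns first, then one column per wavelength
    (nm).  A ground-truth sidecar (truth.json) is written when present.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    wl_cols = [f"{w:g}" for w in archive.wavelengths]

    df = pd.concat([archive.samples.meta.reset_index(drop=True),
                    pd.DataFrame(archive.samples.values, columns=wl_cols)],
                   axis=1)
    df.to_csv(path / "samples.csv", index=False)

    for name, scans in (("references.csv", archive.references),
                        ("darks.csv", archive.darks)):
        rows = pd.concat([pd.DataFrame({"day": sorted(scans)}),
                          pd.DataFrame(np.array([scans[d] for d in sorted(scans)]),
                                       columns=wl_cols)], axis=1)
        rows.to_csv(path / name, index=False)

    if archive.truth is not None and hasattr(archive.truth, "to_json_dict"):
        with open(path / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(archive.truth.to_json_dict(), fh, indent=1)


def _read_wide(path: Path, meta_cols: Sequence[str]) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # ragged rows
        raise ValueError(f"{path.name}: malformed CSV ({exc})") from exc
    wl_cols = [c for c in df.columns if c not in meta_cols]
    try:
        wl = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"{path.name}: non-numeric wavelength column") from exc
    if np.any(np.diff(wl) <= 0):
        raise ValueError(f"{path.name}: wavelengths not strictly increasing")
    return wl, df[list(meta_cols)], df[wl_cols].to_numpy(float)


def read_archive(path: str | Path) -> RawScanArchive:
    """Read an archive written by :func:`write_archive`.

    Raises descriptive errors for non-monotone grids, grid mismatches
    between files, and days missing a reference or dark scan.
    """
    path = Path(path)
    wl, meta, values = _read_wide(path / "samples.csv", META_COLUMNS)
    refs: dict[int, np.ndarray] = {}
    darks: dict[int, np.ndarray] = {}
    for name, store in (("references.csv", refs), ("darks.csv", darks)):
        wl2, days_df, vals = _read_wide(path / name, ["day"])
        if not np.array_equal(wl, wl2):
            raise ValueError(f"{name}: wavelength grid differs from samples.csv")
        for day, row in zip(days_df["day"].astype(int), vals):
            store[day] = row
    for day in sorted(set(meta["day"].astype(int))):
        if day not in refs:
            raise ValueError(f"references.csv: no reference scan for day {day}")
        if day not in darks:
            raise ValueError(f"darks.csv: no dark scan for day {day}")
    samples = SpectraTable(wl, values, meta)
    return RawScanArchive(wl, samples, refs, darks)
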