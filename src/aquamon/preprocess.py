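"""Row-wise spectral preprocessing chain.

The default chain is Savitzky-Golay smoothing (31 points, 2nd-order
polynomial), standard normal variate (SNV) and linear detrend, applied in
that order.  All operations act per spectrum (row-local), so they commute
with any row permutation or subsetting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .spectra import SpectraTable

__all__ = [
    "PreprocessConfig",
    "savgol_smooth",
    "snv",
    "detrend_linear",
    "second_derivative",
    "daily_average",
    "preprocess",
]

_STEPS = ("savgol", "snv", "detrend")


@dataclass(frozen=True)
class PreprocessConfig:
    sg_window: int = 31
    sg_polyorder: int = 2
    order: tuple[str, ...] = ("savgol", "snv", "detrend")
    derivative: str = "none"  # none | second
    derivative_sg_window: int = 31
    derivative_sg_polyorder: int = 2

    def __post_init__(self) -> None:
        for w, p in ((self.sg_window, self.sg_polyorder),
                     (self.derivative_sg_window, self.derivative_sg_polyorder)):
            if w % 2 == 0 or w <= p:
                raise ValueError("SG window must be odd and exceed the polyorder")
        unknown = set(self.order) - set(_STEPS)
        if unknown:
            raise ValueError(f"unknown preprocessing steps: {sorted(unknown)}")
        if self.derivative not in ("none", "second"):
            raise ValueError("derivative must be 'none' or 'second'")
        if self.derivative == "second" and self.derivative_sg_polyorder < 2:
            raise ValueError("second derivative needs polyorder >= 2")

    def to_dict(self) -> dict:
        return {
            "sg_window": self.sg_window, "sg_polyorder": self.sg_polyorder,
            "order": list(self.order), "derivative": self.derivative,
            "derivative_sg_window": self.derivative_sg_window,
            "derivative_sg_polyorder": self.derivative_sg_polyorder,
        }


def _check_window(window: int, polyorder: int, n_cols: int) -> None:
    if window % 2 == 0:
        raise ValueError("SG window must be odd")
    if window <= polyorder:
        raise ValueError("SG window must exceed the polynomial order")
    if window >= n_cols + 1:
        raise ValueError(f"SG window {window} too large for {n_cols} columns")


def savgol_smooth(table: SpectraTable, window: int = 31,
                  polyorder: int = 2) -> SpectraTable:
    """Savitzky-Golay least-squares smoothing.

    Edges are handled by a polynomial fit over the edge window (no
    reflection padding), so polynomials of degree <= polyorder pass
    through unchanged everywhere, including the first and last points.
    """
    _check_window(window, polyorder, table.values.shape[1])
    out = savgol_filter(table.values, window, polyorder, axis=1, mode="interp")
    return table.with_values(out, f"savgol({window},{polyorder})")


def snv(table: SpectraTable) -> SpectraTable:
    """Standard normal variate: centre each spectrum, scale to unit sd (n-1)."""
    v = table.values
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=1, keepdims=True)
    bad = np.where(sd.ravel() == 0)[0]
    if bad.size:
        raise ValueError(f"SNV undefined for constant spectrum at row(s) {bad.tolist()}")
    return table.with_values((v - mean) / sd, "snv")


def detrend_linear(table: SpectraTable) -> SpectraTable:
    """Subtract each spectrum's ordinary-least-squares line in wavelength."""
    if table.values.shape[1] < 3:
        raise ValueError("detrend needs at least 3 wavelengths")
    wl = table.wavelengths
    design = np.column_stack([np.ones_like(wl), wl])
    coef, *_ = np.linalg.lstsq(design, table.values.T, rcond=None)
    return table.with_values(table.values - (design @ coef).T, "detrend")


def second_derivative(table: SpectraTable, window: int = 31,
                      polyorder: int = 2) -> SpectraTable:
    """SG second derivative w.r.t. wavelength (per nm^2).

    Downward peaks of the result mark absorbance maxima.
    """
    if polyorder < 2:
        raise ValueError("second derivative needs polyorder >= 2")
    _check_window(window, polyorder, table.values.shape[1])
    out = savgol_filter(table.values, window, polyorder, deriv=2,
                        delta=table.step, axis=1, mode="interp")
    return table.with_values(out, f"d2({window},{polyorder})")


def daily_average(table: SpectraTable,
                  group_keys: tuple[str, ...] = ("sample_type", "day")) -> SpectraTable:
    """Arithmetic mean spectrum per (sample_type, day) group."""
    missing = [k for k in group_keys if k not in table.meta.columns]
    if missing:
        raise ValueError(f"rows carry no {missing} metadata")
    grouped = table.meta.groupby(list(group_keys), sort=True)
    if grouped.ngroups == 0:
        raise ValueError("no groups to average")
    rows, metas = [], []
    for key, idx in sorted(grouped.indices.items()):
        rows.append(table.values[idx].mean(axis=0))
        metas.append(dict(zip(group_keys, key if isinstance(key, tuple) else (key,))))
    return SpectraTable(table.wavelengths, np.array(rows), pd.DataFrame(metas),
                        table.provenance + ("daily_average",))


def preprocess(table: SpectraTable, config: PreprocessConfig | None = None) -> SpectraTable:
    """Apply the configured chain in order, then an optional 2nd derivative."""
    config = config or PreprocessConfig()
    out = table
    for step in config.order:
        if step == "savgol":
            out = savgol_smooth(out, config.sg_window, config.sg_polyorder)
        elif step == "snv":
            out = snv(out)
        elif step == "detrend":
            out = detrend_linear(out)
    if config.derivative == "second":
        out = second_derivative(out, config.derivative_sg_window,
                                config.derivative_sg_polyorder)
    return out
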