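"""Spectral pretreatment: absorbance, smoothing, SG derivatives, SNV, scaling.

The pretreatment registry enumerates the twelve pipelines used throughout the
analyses: a smoother (moving average, first- or second-order Savitzky-Golay
derivative, window 11) with or without a preceding standard normal variate
(SNV) transform, followed by mean-centering with or without unit-variance
scaling. Pipeline order is fixed: absorbance conversion (spectrometer data
only) -> SNV -> smoother/derivative -> centering (+/- scaling).

Row-wise transforms (SNV, smoothing, derivatives) depend only on the sample's
own spectrum; column statistics (centering/scaling) are fit on training rows
and applied to held-out rows, so cross-validation refits them per fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import savgol_coeffs

from .containers import SpectrumSet, WavelengthGrid

__all__ = [
    "PretreatmentSpec",
    "registry",
    "to_absorbance",
    "moving_average",
    "savgol_derivative",
    "snv",
    "center_scale",
    "ColumnStats",
    "pretreat_rows",
    "apply_rows",
]


@dataclass(frozen=True)
class PretreatmentSpec:
    """One named pretreatment pipeline.

    smoother: "moving_average" | "sg1" | "sg2"; window odd and >= 5;
    centering is always applied downstream, scaling is optional.
    """

    name: str
    smoother: str
    snv: bool
    scaling: bool
    window: int = 11
    polydeg: int = 2  # SG polynomial degree; must be >= derivative order

    def __post_init__(self) -> None:
        if self.smoother not in ("moving_average", "sg1", "sg2"):
            raise ValueError(f"unknown smoother {self.smoother!r}")
        if self.window % 2 == 0 or self.window < 5:
            raise ValueError("window must be odd and >= 5")
        order = {"moving_average": 0, "sg1": 1, "sg2": 2}[self.smoother]
        if self.smoother != "moving_average" and self.polydeg < order:
            raise ValueError("polydeg must be >= derivative order")


_SMOOTHER_LABEL = {"moving_average": "smoothing", "sg1": "SG1", "sg2": "SG2"}


def registry(window: int = 11, polydeg: int = 2) -> list[PretreatmentSpec]:
    """The twelve pretreatment pipelines, in their canonical order.

    smoothing, smoothing + scaling, SG1, SG1 + scaling, SG2, SG2 + scaling,
    then the same six with SNV applied first.
    """
    specs = []
    for use_snv in (False, True):
        for smoother in ("moving_average", "sg1", "sg2"):
            for scaling in (False, True):
                parts = []
                if use_snv:
                    parts.append("SNV")
                parts.append(_SMOOTHER_LABEL[smoother])
                if scaling:
                    parts.append("scaling")
                specs.append(
                    PretreatmentSpec(
                        name=" + ".join(parts),
                        smoother=smoother,
                        snv=use_snv,
                        scaling=scaling,
                        window=window,
                        polydeg=polydeg,
                    )
                )
    return specs


def spec_by_name(name: str, window: int = 11, polydeg: int = 2) -> PretreatmentSpec:
    for spec in registry(window=window, polydeg=polydeg):
        if spec.name == name:
            return spec
    raise KeyError(f"unknown pretreatment label {name!r}")


def to_absorbance(s: SpectrumSet) -> SpectrumSet:
    """Convert reflectance R to absorbance A = log10(1/R)."""
    if s.is_derivative or "absorbance" in s.stage:
        raise ValueError("absorbance conversion requires reflectance-stage data")
    bad = np.argwhere(s.values <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"nonpositive reflectance at sample {i}, band {s.grid.values[j]:g} nm"
        )
    return s.with_values(np.log10(1.0 / s.values), stage_append="absorbance")


def _moving_average_rows(X: np.ndarray, window: int) -> np.ndarray:
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > X.shape[1]:
        raise ValueError("window exceeds band count")
    return sliding_window_view(X, window, axis=1).mean(axis=2)


def moving_average(s: SpectrumSet, window: int = 11) -> SpectrumSet:
    """Unweighted centered moving average; output trimmed to the valid interior."""
    out = _moving_average_rows(s.values, window)
    half = (window - 1) // 2
    return s.with_values(out, grid=s.grid.trim(half), stage_append="smoothing")


def _savgol_rows(X: np.ndarray, order: int, window: int, polydeg: int) -> np.ndarray:
    if window <= polydeg:
        raise ValueError("window must exceed polynomial degree")
    if polydeg < order:
        raise ValueError("polydeg must be >= derivative order")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    # coefficients such that dot(window values in increasing order) gives the
    # derivative at the window center, per band-index step
    c = savgol_coeffs(window, polydeg, deriv=order, delta=1.0, use="dot")
    return sliding_window_view(X, window, axis=1) @ c


def savgol_derivative(
    s: SpectrumSet, order: int, window: int = 11, polydeg: int = 2
) -> SpectrumSet:
    """Savitzky-Golay derivative (order 0, 1 or 2) on the valid interior.

    Derivatives are reported per band-index step; on a uniform grid this is
    proportional to d/d(nm) by a factor 1/step_nm.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    out = _savgol_rows(s.values, order, window, polydeg)
    half = (window - 1) // 2
    return s.with_values(out, grid=s.grid.trim(half), stage_append=f"sg{order}")


def snv(s: SpectrumSet) -> SpectrumSet:
    """Standard normal variate: per-spectrum centering to mean 0, SD 1 (n-1)."""
    X = s.values
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        i = int(np.flatnonzero(sd.ravel() == 0)[0])
        raise ValueError(f"constant spectrum at sample {i}: SNV undefined")
    return s.with_values((X - mu) / sd, stage_append="snv")


@dataclass
class ColumnStats:
    """Training-set column statistics for centering/scaling held-out rows."""

    mean: np.ndarray
    sd: np.ndarray | None  # None when scaling is off
    kept: np.ndarray  # boolean mask of retained (non-constant) columns

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, self.kept]
        out = X - self.mean
        if self.sd is not None:
            out = out / self.sd
        return out


def center_scale(X: np.ndarray, scaling: bool) -> tuple[np.ndarray, ColumnStats]:
    """Mean-center columns; optionally divide by column SD (n-1 denominator).

    Zero-variance columns are dropped with a warning (they carry no
    information and would be undefined under scaling).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("center_scale needs at least 2 rows")
    sd_all = X.std(axis=0, ddof=1)
    kept = sd_all > 0
    if not kept.all():
        warnings.warn(
            f"dropping {int((~kept).sum())} zero-variance column(s)", stacklevel=2
        )
    mean = X[:, kept].mean(axis=0)
    sd = sd_all[kept] if scaling else None
    stats = ColumnStats(mean=mean, sd=sd, kept=kept)
    return stats.apply(X), stats


def apply_rows(X: np.ndarray, spec: PretreatmentSpec) -> np.ndarray:
    """Row-wise part of a pipeline (SNV then smoother) on a bare matrix.

    Each output row depends only on its own input row, so precomputing this
    before cross-validation is identical to refitting it per fold.
    """
    X = np.asarray(X, dtype=float)
    if spec.snv:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("constant spectrum: SNV undefined")
        X = (X - mu) / sd
    if spec.smoother == "moving_average":
        return _moving_average_rows(X, spec.window)
    order = int(spec.smoother[2])
    return _savgol_rows(X, order, spec.window, spec.polydeg)


def pretreat_rows(s: SpectrumSet, spec: PretreatmentSpec) -> SpectrumSet:
    """Apply the row-wise part of ``spec`` to a SpectrumSet (grid trimmed)."""
    out = s
    if spec.snv:
        out = snv(out)
    if spec.smoother == "moving_average":
        return moving_average(out, spec.window)
    order = int(spec.smoother[2])
    return savgol_derivative(out, order, spec.window, spec.polydeg)
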