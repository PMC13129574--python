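"""Hyperspectral image correction, ROI extraction and mean-spectrum summary.

Raw cubes Ir are converted to reflectance with a white reference cube Iw
(white calibration board) and a dark reference cube Id (capped lens):

    Ic = (Ir - Id) / (Iw - Id)

The leaf region of interest is segmented on a near-infrared score image —
the 780 nm band for VIS-NIR cubes, the mean of the 1260 and 1290 nm bands
for NIR cubes — where leaf tissue is bright and the light-exclusion sheet is
dark. The threshold defaults to Otsu's method on the score image, followed by
retaining the largest connected component; a fixed threshold can be supplied
instead. The sample's spectrum is the unweighted per-band mean over ROI
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label

from .containers import HyperCube, SpectrumSet

__all__ = ["ROIMask", "correct", "extract_roi", "mean_spectrum"]

#: score bands per segmentation mode (nm)
SCORE_BANDS = {"visnir": (780.0,), "nir": (1260.0, 1290.0)}


@dataclass
class ROIMask:
    mask: np.ndarray  # boolean rows x cols
    source_bands: tuple[float, ...]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def _broadcast_reference(ref: HyperCube | np.ndarray, like: HyperCube) -> np.ndarray:
    """Accept a full cube or a per-band (or rows x bands) profile reference."""
    if isinstance(ref, HyperCube):
        if ref.grid.values.tolist() != like.grid.values.tolist():
            raise ValueError("reference grid differs from scene grid")
        data = ref.data
    else:
        data = np.asarray(ref, dtype=float)
    return np.broadcast_to(data, like.data.shape)


def correct(ir: HyperCube, iw: HyperCube | np.ndarray, idark: HyperCube | np.ndarray) -> HyperCube:
    """White/dark calibration: Ic = (Ir - Id) / (Iw - Id), elementwise."""
    w = _broadcast_reference(iw, ir)
    d = _broadcast_reference(idark, ir)
    denom = w - d
    bad = np.argwhere(denom <= 0)
    if bad.size:
        r, c, b = bad[0]
        raise ValueError(
            f"white reference does not exceed dark at pixel ({r}, {c}), "
            f"band {ir.grid.values[b]:g} nm"
        )
    return HyperCube((ir.data - d) / denom, ir.grid, kind="corrected")


def _score_image(ic: HyperCube, mode: str) -> tuple[np.ndarray, tuple[float, ...]]:
    try:
        bands = SCORE_BANDS[mode]
    except KeyError:
        raise ValueError(f"mode must be one of {sorted(SCORE_BANDS)}") from None
    idx = [ic.grid.index_of(nm) for nm in bands]
    return ic.data[:, :, idx].mean(axis=2), bands


def extract_roi(
    ic: HyperCube, mode: str = "visnir", threshold: float | None = None
) -> ROIMask:
    """Segment the leaf by thresholding the mode's near-infrared score image.

    Otsu's threshold is used unless a fixed one is given; the mask is cleaned
    by keeping only the largest connected component (4-connectivity).
    """
    if ic.kind != "corrected":
        raise ValueError("extract_roi expects a corrected cube")
    score, bands = _score_image(ic, mode)
    if threshold is None:
        if np.ptp(score) == 0:
            raise ValueError("no foreground detected: flat score image")
        threshold = float(threshold_otsu(score))
    mask = score > threshold
    if not mask.any():
        raise ValueError("no foreground detected")
    labels = label(mask, connectivity=1)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    return ROIMask(mask=mask, source_bands=bands)


def mean_spectrum(ic: HyperCube, roi: ROIMask, sample_id: str = "roi") -> SpectrumSet:
    """Per-band unweighted mean reflectance over the ROI pixels."""
    if roi.mask.shape != ic.data.shape[:2]:
        raise ValueError("ROI mask dims differ from cube")
    spectrum = ic.data[roi.mask].mean(axis=0)
    meta = pd.DataFrame(
        [
            dict(
                sample_id=sample_id,
                cultivar="",
                subspecies="",
                field="",
                dat=-1,
                replicate=1,
                tissue="leaf",
                form="detached",
            )
        ]
    )
    return SpectrumSet(ic.grid, spectrum[None, :], meta, stage=("reflectance",))
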