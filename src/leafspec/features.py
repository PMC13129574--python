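"""Exhaustive two-band normalized difference spectral index (NDSI) features.

For reflectance values Ri, Rj at wavelengths i < j,

    NDSI(Ri, Rj) = (Rj - Ri) / (Rj + Ri)

which lies in (-1, 1) for positive reflectance and is invariant to
multiplying a spectrum by a positive constant — the property that makes it
robust to observation-condition (illumination) differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SpectrumSet

__all__ = ["NDSIFeatures", "ndsi"]


@dataclass
class NDSIFeatures:
    """Sample x band-pair NDSI matrix; pairs are (i_nm, j_nm) with j > i."""

    pairs: list[tuple[float, float]]
    values: np.ndarray  # samples x pairs
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.meta), len(self.pairs)):
            raise ValueError("values shape must be (samples, pairs)")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def frame(self) -> pd.DataFrame:
        cols = [f"ndsi_{i:g}_{j:g}" for i, j in self.pairs]
        return pd.concat(
            [self.meta.reset_index(drop=True), pd.DataFrame(self.values, columns=cols)],
            axis=1,
        )


def ndsi(s: SpectrumSet, max_bands: int = 256, force: bool = False) -> NDSIFeatures:
    """All-pairs NDSI of a reflectance SpectrumSet.

    Requires reflectance units (derivative-stage input is rejected) and
    strictly positive values. The pair list covers every unordered band pair
    (j > i), lexicographically ordered — n(n-1)/2 columns for n bands.
    Full pairwise growth is quadratic, so grids beyond ``max_bands`` bands
    are refused unless ``force`` is set (subsample or crop first).
    """
    if s.is_derivative:
        raise ValueError("NDSI requires reflectance, not derivative-stage data")
    if np.any(s.values <= 0):
        raise ValueError("NDSI requires strictly positive reflectance")
    n = s.grid.n_bands
    if n > max_bands and not force:
        raise ValueError(
            f"{n} bands would give {n * (n - 1) // 2} pairs; "
            f"crop/subsample the grid or pass force=True"
        )
    lam = s.grid.values
    X = s.values
    iu, ju = np.triu_indices(n, k=1)
    vals = (X[:, ju] - X[:, iu]) / (X[:, ju] + X[:, iu])
    pairs = list(zip(lam[iu].tolist(), lam[ju].tolist()))
    return NDSIFeatures(pairs=pairs, values=vals, meta=s.meta.reset_index(drop=True))
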