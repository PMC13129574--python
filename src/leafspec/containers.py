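"""Shared in-memory containers for the spectral / genetic analysis chain.

The central objects are

* :class:`WavelengthGrid` — a uniform wavelength axis in nanometres,
* :class:`SpectrumSet` — a sample x band matrix with per-sample metadata and a
  record of the transforms applied so far,
* :class:`HyperCube` — a rows x cols x bands image stack,
* :class:`GeneticMap` / :class:`RILPanel` — a marker map and a recombinant
  inbred line (RIL) panel of genotypes plus phenotypes.

Everything downstream (pretreatment, chemometrics, QTL mapping) operates on
these containers rather than on bare arrays, so provenance (grid, metadata,
pipeline stage) travels with the numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SpectrumSet",
    "HyperCube",
    "GeneticMap",
    "RILPanel",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniformly spaced wavelength axis.

    The channel count is ``round((stop - start) / step) + 1``; e.g. the
    400–2499.5 nm axis at 0.5 nm spacing has 4200 channels.
    """

    start_nm: float
    stop_nm: float
    step_nm: float

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")
        if self.stop_nm <= self.start_nm:
            raise ValueError("stop_nm must exceed start_nm")
        n = (self.stop_nm - self.start_nm) / self.step_nm
        if abs(n - round(n)) > 1e-6:
            raise ValueError(
                f"grid span {self.start_nm}-{self.stop_nm} is not a multiple of "
                f"step {self.step_nm}"
            )

    @staticmethod
    def spanning(start_nm: float, stop_nm: float, step_nm: float) -> "WavelengthGrid":
        """Grid from ``start_nm`` with the largest stop not exceeding ``stop_nm``."""
        n = int(np.floor((stop_nm - start_nm) / step_nm + 1e-9))
        return WavelengthGrid(start_nm, start_nm + n * step_nm, step_nm)

    @property
    def n_bands(self) -> int:
        return round((self.stop_nm - self.start_nm) / self.step_nm) + 1

    @property
    def values(self) -> np.ndarray:
        """Wavelengths in nm, strictly increasing, uniform spacing."""
        return self.start_nm + self.step_nm * np.arange(self.n_bands)

    def __len__(self) -> int:
        return self.n_bands

    def trim(self, k: int) -> "WavelengthGrid":
        """Drop ``k`` channels from each end (valid-interior trimming)."""
        if k < 0 or 2 * k >= self.n_bands:
            raise ValueError(f"cannot trim {k} channels from {self.n_bands}")
        return WavelengthGrid(
            self.start_nm + k * self.step_nm,
            self.stop_nm - k * self.step_nm,
            self.step_nm,
        )

    def index_of(self, nm: float) -> int:
        """Index of the band nearest ``nm``; must lie within half a step."""
        idx = int(round((nm - self.start_nm) / self.step_nm))
        if idx < 0 or idx >= self.n_bands:
            raise KeyError(f"{nm} nm outside grid {self.start_nm}-{self.stop_nm}")
        if abs(self.values[idx] - nm) > self.step_nm / 2 + 1e-9:
            raise KeyError(f"no band within half a step of {nm} nm")
        return idx

    def subset(self, start_nm: float, stop_nm: float) -> tuple["WavelengthGrid", slice]:
        """Crop to [start_nm, stop_nm]; returns the cropped grid and the slice."""
        vals = self.values
        lo = int(np.searchsorted(vals, start_nm - 1e-9))
        hi = int(np.searchsorted(vals, stop_nm + 1e-9))
        if hi - lo < 2:
            raise ValueError(f"region {start_nm}-{stop_nm} nm outside grid")
        return (
            WavelengthGrid(vals[lo], vals[hi - 1], self.step_nm),
            slice(lo, hi),
        )


# Metadata columns written ahead of the wavelength columns in the wide CSV format.
META_COLUMNS = ("sample_id", "cultivar", "subspecies", "field", "dat", "tissue", "form")


@dataclass
class SpectrumSet:
    """Sample x wavelength matrix with per-sample metadata.

    ``stage`` is an append-only record of applied transforms, e.g.
    ``("reflectance", "snv", "sg2")``. Derivative stages disqualify the data
    from transforms that require reflectance units (absorbance, NDSI).
    """

    grid: WavelengthGrid
    values: np.ndarray
    meta: pd.DataFrame
    stage: tuple[str, ...] = ("reflectance",)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D sample x band matrix")
        if self.values.shape[1] != self.grid.n_bands:
            raise ValueError(
                f"{self.values.shape[1]} columns but grid has {self.grid.n_bands} bands"
            )
        if len(self.meta) != self.values.shape[0]:
            raise ValueError("meta rows must match sample rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def is_derivative(self) -> bool:
        return any(s.startswith("sg") for s in self.stage)

    def with_values(
        self,
        values: np.ndarray,
        grid: WavelengthGrid | None = None,
        stage_append: str | None = None,
    ) -> "SpectrumSet":
        stage = self.stage + (stage_append,) if stage_append else self.stage
        return SpectrumSet(grid or self.grid, values, self.meta.reset_index(drop=True), stage)

    def select(self, mask: np.ndarray | pd.Series) -> "SpectrumSet":
        mask = np.asarray(mask, dtype=bool)
        return SpectrumSet(
            self.grid, self.values[mask], self.meta.loc[mask].reset_index(drop=True), self.stage
        )

    def subset_region(self, start_nm: float, stop_nm: float) -> "SpectrumSet":
        grid, sl = self.grid.subset(start_nm, stop_nm)
        return SpectrumSet(grid, self.values[:, sl], self.meta.reset_index(drop=True), self.stage)


@dataclass
class HyperCube:
    """Raw or corrected hyperspectral image stack (rows x cols x bands)."""

    data: np.ndarray
    grid: WavelengthGrid
    kind: str = "raw"  # "raw" | "corrected"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube must be rows x cols x bands")
        if self.data.shape[2] != self.grid.n_bands:
            raise ValueError(
                f"cube has {self.data.shape[2]} bands, grid {self.grid.n_bands}"
            )
        if self.kind == "corrected" and not np.all(np.isfinite(self.data)):
            raise ValueError("corrected cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class GeneticMap:
    """Ordered marker map: one table with marker, chrom, pos_cM (Kosambi cM)."""

    table: pd.DataFrame  # columns: marker, chrom, pos_cM

    def __post_init__(self) -> None:
        required = {"marker", "chrom", "pos_cM"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if self.table["marker"].duplicated().any():
            raise ValueError("marker names must be unique")
        for chrom, sub in self.table.groupby("chrom", sort=False):
            pos = sub["pos_cM"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions on {chrom} not nondecreasing")

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def markers_on(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom].reset_index(drop=True)

    @staticmethod
    def uniform(
        n_chrom: int = 12,
        markers_per_chrom: int | Sequence[int] = (15, 15, 15, 15, 15, 15, 15, 14, 14, 14, 14, 14),
        spacing_cM: float = 10.0,
    ) -> "GeneticMap":
        """Evenly spaced map; the default places 175 markers on 12 chromosomes."""
        if isinstance(markers_per_chrom, int):
            counts: Iterable[int] = [markers_per_chrom] * n_chrom
        else:
            counts = list(markers_per_chrom)
            if len(counts) != n_chrom:
                raise ValueError("markers_per_chrom length must equal n_chrom")
        rows = []
        for c, m in enumerate(counts, start=1):
            for k in range(m):
                rows.append((f"c{c}m{k + 1}", c, k * spacing_cM))
        return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "pos_cM"]))


@dataclass
class RILPanel:
    """Recombinant inbred line panel: genotypes, map, phenotypes.

    Genotypes are coded "A"/"B" (parental alleles; RILs are fixed, no
    heterozygotes) with NaN for missing. Phenotype columns carry trait names
    such as DH, PG, MW, BW, WB or spectral PC-score traits like B_A_PC1.
    """

    genotypes: pd.DataFrame  # lines x markers
    map: GeneticMap
    phenotypes: pd.DataFrame  # lines x traits

    def __post_init__(self) -> None:
        if list(self.genotypes.columns) != list(self.map.table["marker"]):
            raise ValueError("genotype columns must match map marker order")
        vals = self.genotypes.to_numpy(dtype=object)
        ok = pd.isna(vals) | np.isin(vals, ["A", "B"])
        if not ok.all():
            raise ValueError("genotypes must be 'A', 'B', or missing")
        if not self.genotypes.index.equals(self.phenotypes.index):
            raise ValueError("genotype and phenotype line indices must match")
        if self.phenotypes.columns.duplicated().any():
            raise ValueError("trait names must be unique")

    @property
    def n_lines(self) -> int:
        return len(self.genotypes)

    def genotype_codes(self, marker: str) -> np.ndarray:
        """Numeric coding: A -> +0.5, B -> -0.5, missing -> NaN."""
        g = self.genotypes[marker]
        return g.map({"A": 0.5, "B": -0.5}).to_numpy(dtype=float)

    def with_traits(self, extra: pd.DataFrame) -> "RILPanel":
        joined = self.phenotypes.join(extra, how="left")
        return RILPanel(self.genotypes, self.map, joined)
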