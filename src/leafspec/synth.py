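"""Synthetic-data generators with recorded ground truth.

The original field spectra, microarrays and RIL genotypes behind this kind of
study are not publicly deposited, so every analysis stage here runs on
generated data whose statistical structure mirrors the study designs:

* leaf reflectance spectra (400–2499.5 nm spectrometer grid, or the 450–950 /
  950–1650 nm imaging grids) driven by a latent growth variable with
  growth-stage, subspecies and field-soil effects planted in named wavelength
  windows;
* 54 transcript-cluster mean-expression trajectories tied to the same latent
  growth variable;
* hyperspectral image cubes with white/dark reference cubes and a known leaf
  mask;
* a recombinant inbred line (RIL) panel — genotypes from a Markov crossover
  model with the RIL-by-selfing recombination expansion, phenotypes from
  planted additive QTLs.

Every generator takes an integer seed, is bitwise reproducible, and returns a
:class:`GroundTruth` carrying the planted effects so downstream stages can be
tested for parameter recovery.

Spectral archetypes (Gaussian absorption features, a logistic red edge) are
stylised rather than radiative-transfer-based, but their wavelength windows —
pigment absorption 675–695 nm, red-edge shoulder 725–765 nm, subspecies
window 580–655 nm, soil-condition window 1600–1650 nm — are placed where the
corresponding biological effects are reported for rice leaves, so factor
loading and feature-window tests are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .containers import GeneticMap, RILPanel, SpectrumSet, WavelengthGrid
from .qtl import kosambi_inverse, ril_expansion

__all__ = [
    "LeafDesign",
    "GroundTruth",
    "ClusterExpression",
    "LeafScene",
    "QTLEffect",
    "spectrometer_grid",
    "visnir_imaging_grid",
    "nir_imaging_grid",
    "leaf_spectroscopy_design",
    "transcriptome_design",
    "gen_leaf_spectra",
    "gen_cluster_expression",
    "gen_image_cube",
    "gen_ril_panel",
    "gen_grain_spectra",
]


# ---------------------------------------------------------------------------
# designs and grids

def spectrometer_grid() -> WavelengthGrid:
    """400–2499.5 nm at 0.5 nm: the 4200-channel bench-spectrometer axis."""
    return WavelengthGrid(400.0, 2499.5, 0.5)


def visnir_imaging_grid() -> WavelengthGrid:
    """450–950 nm, 101 bands (5 nm): the VIS-NIR imaging axis."""
    return WavelengthGrid(450.0, 950.0, 5.0)


def nir_imaging_grid() -> WavelengthGrid:
    """950–1650 nm, 71 bands (10 nm): the NIR imaging axis."""
    return WavelengthGrid(950.0, 1650.0, 10.0)


@dataclass(frozen=True)
class LeafDesign:
    """Factorial sampling design: cultivars x fields x DATs x replicates."""

    cultivars: tuple[tuple[str, str], ...]  # (name, subspecies in {japonica, indica})
    fields: tuple[str, ...]  # subset of {alluvial, andosol}
    dats: tuple[int, ...]  # days after transplanting, strictly increasing
    replicates: int = 1

    def __post_init__(self) -> None:
        if not self.cultivars or not self.fields or not self.dats:
            raise ValueError("design factors must be nonempty")
        if any(s not in ("japonica", "indica") for _, s in self.cultivars):
            raise ValueError("subspecies must be japonica or indica")
        if any(b <= a for a, b in zip(self.dats, self.dats[1:])):
            raise ValueError("DATs must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def n_samples(self) -> int:
        return len(self.cultivars) * len(self.fields) * len(self.dats) * self.replicates

    def latent_growth(self, dat: float) -> float:
        """Latent growth in [0, 1]: linear rescaling of DAT over the design span."""
        lo, hi = min(self.dats), max(self.dats)
        return 0.0 if hi == lo else (dat - lo) / (hi - lo)

    def expand(self) -> pd.DataFrame:
        rows = []
        i = 0
        for cultivar, subspecies in self.cultivars:
            for fld in self.fields:
                for dat in self.dats:
                    for rep in range(self.replicates):
                        rows.append(
                            dict(
                                sample_id=f"S{i:04d}",
                                cultivar=cultivar,
                                subspecies=subspecies,
                                field=fld,
                                dat=dat,
                                replicate=rep + 1,
                            )
                        )
                        i += 1
        return pd.DataFrame(rows)


_DEFAULT_CULTIVARS = (
    ("Nipponbare", "japonica"),
    ("Koshihikari", "japonica"),
    ("Takanari", "indica"),
    ("IR64", "indica"),
)


def leaf_spectroscopy_design(replicates: int = 1) -> LeafDesign:
    """4 cultivars x 2 fields x 9 DATs (21–77, weekly): 72 cells per replicate."""
    return LeafDesign(
        cultivars=_DEFAULT_CULTIVARS,
        fields=("alluvial", "andosol"),
        dats=tuple(range(21, 78, 7)),
        replicates=replicates,
    )


def transcriptome_design() -> LeafDesign:
    """4 cultivars x 2 fields x 10 DATs (13, then 21–77 weekly): 80 samples."""
    return LeafDesign(
        cultivars=_DEFAULT_CULTIVARS,
        fields=("alluvial", "andosol"),
        dats=(13,) + tuple(range(21, 78, 7)),
        replicates=1,
    )


@dataclass
class GroundTruth:
    """Planted structure carried alongside every generated dataset."""

    latent_growth: np.ndarray | None = None  # per sample, in [0, 1]
    subspecies_effect: np.ndarray | None = None  # per wavelength (added to indica)
    field_effect: np.ndarray | None = None  # per wavelength at latent growth 0
    effect_windows: dict = field(default_factory=dict)  # name -> (lo_nm, hi_nm)
    cluster_truth: pd.DataFrame | None = None  # archetype, slope, offsets per cluster
    roi_mask_truth: np.ndarray | None = None  # boolean image
    qtl_truth: list = field(default_factory=list)  # list[QTLEffect]
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# leaf spectra

def _gauss(lam: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / width) ** 2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


#: effect windows planted in the leaf spectra (nm)
LEAF_WINDOWS = {
    "pigment": (675.0, 695.0),
    "red_edge": (725.0, 765.0),
    "subspecies": (580.0, 655.0),
    "field": (1600.0, 1650.0),
}


def _leaf_baseline(lam: np.ndarray) -> np.ndarray:
    """Smooth vegetation-like continuum: dark VIS, bright NIR, water dips."""
    base = 0.10 + 0.38 * _sigmoid((lam - 710.0) / 22.0)
    base -= 0.10 * _gauss(lam, 1450.0, 55.0)
    base -= 0.09 * _gauss(lam, 1940.0, 70.0)
    return base


def gen_leaf_spectra(
    design: LeafDesign,
    grid: WavelengthGrid,
    seed: int,
    *,
    noise_sd: float = 0.001,
    pigment_depth: float = 0.09,
    red_edge_amp: float = 0.05,
    subspecies_amp: float = 0.02,
    field_amp: float = 0.03,
    tissue: str = "leaf",
    form: str = "powder",
) -> tuple[SpectrumSet, GroundTruth]:
    """Leaf reflectance spectra with growth, subspecies and field effects.

    Per-sample model on wavelength ``lam`` with latent growth g in [0, 1]:

    * baseline continuum (dark VIS, red edge to a bright NIR, two water dips);
    * pigment absorption at 675 nm whose depth ``pigment_depth * (1 - g/2)``
      decreases with growth;
    * a red-edge shoulder bump (745 nm) with amplitude ``red_edge_amp * g``;
    * indica cultivars get ``+subspecies_amp`` x a 580–655 nm window bump;
    * alluvial fields get ``+field_amp * (1 - g)`` x a flat-topped 1600–1650 nm
      window (exactly ``field_amp`` at 1630 nm for the earliest DAT);
    * i.i.d. Gaussian noise of SD ``noise_sd``.

    All reflectance stays in (0, 1) for the default amplitudes.
    """
    if grid.step_nm > 25:
        raise ValueError(
            "grid step too coarse for the ~16-nm-wide planted features"
        )
    meta = design.expand()
    meta["tissue"] = tissue
    meta["form"] = form
    lam = grid.values
    rng = np.random.default_rng(seed)

    sub_effect = subspecies_amp * _gauss(lam, 617.0, 28.0)
    fld_effect = field_amp * np.exp(-(((lam - 1630.0) / 30.0) ** 4))
    base = _leaf_baseline(lam)

    g = np.array([design.latent_growth(d) for d in meta["dat"]])
    indica = (meta["subspecies"] == "indica").to_numpy()
    alluvial = (meta["field"] == "alluvial").to_numpy()

    X = np.empty((len(meta), grid.n_bands))
    for i in range(len(meta)):
        r = base.copy()
        r -= pigment_depth * (1.0 - 0.5 * g[i]) * _gauss(lam, 675.0, 16.0)
        r += red_edge_amp * g[i] * _gauss(lam, 745.0, 16.0)
        if indica[i]:
            r += sub_effect
        if alluvial[i]:
            r += (1.0 - g[i]) * fld_effect
        X[i] = r
    X += rng.normal(0.0, noise_sd, size=X.shape) if noise_sd > 0 else 0.0
    if np.any(X <= 0) or np.any(X >= 1):
        raise ValueError("generated reflectance left (0, 1); reduce amplitudes/noise")

    truth = GroundTruth(
        latent_growth=g,
        subspecies_effect=sub_effect,
        field_effect=fld_effect,
        effect_windows=dict(LEAF_WINDOWS),
        params=dict(
            noise_sd=noise_sd,
            pigment_depth=pigment_depth,
            red_edge_amp=red_edge_amp,
            subspecies_amp=subspecies_amp,
            field_amp=field_amp,
        ),
    )
    return SpectrumSet(grid, X, meta, stage=("reflectance",)), truth


# ---------------------------------------------------------------------------
# cluster expression

@dataclass
class ClusterExpression:
    """Per-sample mean expression of named transcript clusters."""

    values: np.ndarray  # samples x clusters
    clusters: tuple[str, ...]
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.meta), len(self.clusters)):
            raise ValueError("values shape must be (samples, clusters)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def frame(self) -> pd.DataFrame:
        return pd.concat(
            [
                self.meta.reset_index(drop=True),
                pd.DataFrame(self.values, columns=list(self.clusters)),
            ],
            axis=1,
        )

    def select(self, mask) -> "ClusterExpression":
        mask = np.asarray(mask, dtype=bool)
        return ClusterExpression(
            self.values[mask], self.clusters, self.meta.loc[mask].reset_index(drop=True)
        )


ARCHETYPES = ("monotone_down", "monotone_up", "flat_noisy")


def cluster_names(n: int) -> tuple[str, ...]:
    """Names in the Clus <group>_<letter> convention, three per group."""
    letters = "abc"
    return tuple(f"Clus {1 + i // 3}_{letters[i % 3]}" for i in range(n))


def gen_cluster_expression(
    design: LeafDesign,
    n_clusters: int = 54,
    seed: int = 0,
    *,
    noise_sd: float = 0.1,
    slope: float = 1.0,
    baseline: float = 8.0,
    subspecies_offset: float = 0.3,
    subspecies_every: int = 9,
) -> tuple[ClusterExpression, GroundTruth]:
    """Cluster mean-expression trajectories as affine functions of latent growth.

    Cluster i gets archetype ``ARCHETYPES[i % 3]``: slope -``slope``, +``slope``
    or 0 on the same latent growth variable used by :func:`gen_leaf_spectra`.
    Every ``subspecies_every``-th cluster additionally separates indica from
    japonica by ``subspecies_offset`` (the behaviour seen in clusters that
    track subspecies identity). Gaussian noise SD ``noise_sd`` throughout.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    meta = design.expand()
    rng = np.random.default_rng(seed)
    g = np.array([design.latent_growth(d) for d in meta["dat"]])
    indica = (meta["subspecies"] == "indica").to_numpy(dtype=float)

    names = cluster_names(n_clusters)
    rows = []
    X = np.empty((len(meta), n_clusters))
    for j in range(n_clusters):
        arch = ARCHETYPES[j % 3]
        s = {"monotone_down": -slope, "monotone_up": slope, "flat_noisy": 0.0}[arch]
        off = subspecies_offset if (subspecies_every and j % subspecies_every == 0) else 0.0
        X[:, j] = baseline + s * g + off * indica
        rows.append(dict(cluster=names[j], archetype=arch, slope=s, subspecies_offset=off))
    X += rng.normal(0.0, noise_sd, size=X.shape) if noise_sd > 0 else 0.0

    truth = GroundTruth(
        latent_growth=g,
        cluster_truth=pd.DataFrame(rows),
        params=dict(noise_sd=noise_sd, slope=slope, baseline=baseline),
    )
    return ClusterExpression(X, names, meta), truth


# ---------------------------------------------------------------------------
# image cubes

@dataclass(frozen=True)
class LeafScene:
    """Geometry and radiometry of a synthetic single-leaf imaging scene."""

    shape: tuple[int, int] = (48, 48)
    leaf_center: tuple[float, float] | None = None  # default: image centre
    leaf_axes: tuple[float, float] | None = None  # ellipse semi-axes (rows, cols)
    leaf_reflectance: float | np.ndarray = 0.6
    background_reflectance: float = 0.05
    gain: float = 2000.0
    dark_level: float = 100.0
    noise_sd: float = 0.0  # counts, on the raw scene image only


def gen_image_cube(
    scene: LeafScene, grid: WavelengthGrid, seed: int
) -> tuple["_RawCapture", GroundTruth]:
    """Raw capture Ir = Id + gain * reflectance (+ noise), with Iw and Id cubes.

    The background sits well below the leaf at every band (mimicking a light
    exclusion sheet), so thresholding any leaf-bright band separates the two.
    """
    from .containers import HyperCube  # local to avoid polluting module surface

    rows, cols = scene.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    center = scene.leaf_center if scene.leaf_center is not None else (rows / 2, cols / 2)
    ar, ac = scene.leaf_axes if scene.leaf_axes is not None else (rows / 3, cols / 5)
    mask = (((rr - center[0]) / ar) ** 2 + ((cc - center[1]) / ac) ** 2) <= 1.0
    if not mask.any():
        raise ValueError("leaf area is empty: scene geometry outside image")

    leaf_r = np.broadcast_to(
        np.asarray(scene.leaf_reflectance, dtype=float), (grid.n_bands,)
    )
    refl = np.where(
        mask[:, :, None], leaf_r[None, None, :], scene.background_reflectance
    )
    rng = np.random.default_rng(seed)
    ir = scene.dark_level + scene.gain * refl
    if scene.noise_sd > 0:
        ir = ir + rng.normal(0.0, scene.noise_sd, size=ir.shape)
    iw = np.full(refl.shape, scene.dark_level + scene.gain)
    idark = np.full(refl.shape, scene.dark_level)

    capture = _RawCapture(
        ir=HyperCube(ir, grid, "raw"),
        iw=HyperCube(iw, grid, "raw"),
        idark=HyperCube(idark, grid, "raw"),
    )
    truth = GroundTruth(roi_mask_truth=mask, params=dict(scene=scene))
    return capture, truth


@dataclass
class _RawCapture:
    """A raw scene cube with its white and dark reference cubes."""

    ir: "object"
    iw: "object"
    idark: "object"


# ---------------------------------------------------------------------------
# RIL panel

@dataclass(frozen=True)
class QTLEffect:
    """A planted additive QTL: trait, marker position, allele-mean difference.

    ``effect`` is the A-minus-B phenotype mean difference, i.e. the regression
    slope of phenotype on the +-0.5 genotype coding.
    """

    trait: str
    chrom: object
    pos_cM: float
    effect: float


DEFAULT_TRAITS = ("DH", "PG", "MW", "BW", "WB")
_TRAIT_BASE = {"DH": 90.0, "PG": 70.0, "MW": 10.0, "BW": 5.0, "WB": 5.0}


def gen_ril_panel(
    n_lines: int,
    gmap: GeneticMap,
    qtls: Sequence[QTLEffect] = (),
    seed: int = 0,
    *,
    noise_sd: float = 1.0,
    traits: Sequence[str] = DEFAULT_TRAITS,
    missing_rate: float = 0.0,
) -> tuple[RILPanel, GroundTruth]:
    """Simulate a RIL panel by gamete formation plus selfing to fixation.

    Per chromosome the genotype chain starts A or B with probability 1/2 and
    switches between adjacent markers with probability R = 2r / (1 + 2r),
    where r is the meiotic recombination fraction from the inverse Kosambi
    function of the interval length — the standard two-way RIL-by-selfing
    expansion. Lines are fully homozygous (entries A/B only).

    Phenotypes: trait value = trait baseline + sum of planted effects times
    the +-0.5 genotype coding + N(0, noise_sd).
    """
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    for q in qtls:
        sub = gmap.markers_on(q.chrom)
        if sub.empty or not np.any(np.abs(sub["pos_cM"] - q.pos_cM) < 1e-6):
            raise ValueError(f"QTL {q} does not reference an existing marker position")
        if q.trait not in traits:
            raise ValueError(f"QTL trait {q.trait!r} not among panel traits")

    rng = np.random.default_rng(seed)
    cols: list[np.ndarray] = []
    marker_order: list[str] = []
    for chrom in gmap.chromosomes:
        sub = gmap.markers_on(chrom)
        pos = sub["pos_cM"].to_numpy()
        m = len(pos)
        geno = np.empty((n_lines, m), dtype=np.int8)
        geno[:, 0] = rng.integers(0, 2, size=n_lines)
        for k in range(1, m):
            r = kosambi_inverse(pos[k] - pos[k - 1])
            big_r = ril_expansion(r)
            switch = rng.random(n_lines) < big_r
            geno[:, k] = np.where(switch, 1 - geno[:, k - 1], geno[:, k - 1])
        cols.append(geno)
        marker_order.extend(sub["marker"])
    G = np.concatenate(cols, axis=1)

    line_ids = [f"RIL{i + 1:03d}" for i in range(n_lines)]
    geno_df = pd.DataFrame(
        np.where(G == 0, "A", "B"), index=line_ids, columns=marker_order
    )

    x = np.where(G == 0, 0.5, -0.5)  # A -> +0.5, B -> -0.5
    marker_index = {m: i for i, m in enumerate(marker_order)}
    pheno = {}
    for trait in traits:
        y = np.full(n_lines, _TRAIT_BASE.get(trait, 0.0))
        for q in qtls:
            if q.trait != trait:
                continue
            sub = gmap.markers_on(q.chrom)
            mk = sub.loc[np.abs(sub["pos_cM"] - q.pos_cM) < 1e-6, "marker"].iloc[0]
            y = y + q.effect * x[:, marker_index[mk]]
        y = y + rng.normal(0.0, noise_sd, size=n_lines)
        pheno[trait] = y
    pheno_df = pd.DataFrame(pheno, index=line_ids)

    if missing_rate > 0:
        drop = rng.random(geno_df.shape) < missing_rate
        geno_df = geno_df.mask(drop)

    panel = RILPanel(geno_df, gmap, pheno_df)
    truth = GroundTruth(
        qtl_truth=list(qtls), params=dict(noise_sd=noise_sd, n_lines=n_lines)
    )
    return panel, truth


# ---------------------------------------------------------------------------
# grain spectra tied to the RIL panel

GRAIN_FORMS = ("powder", "brown_grain")


@dataclass(frozen=True)
class SpectralQTL:
    """A planted locus whose genotype shifts a grain spectral window."""

    chrom: object
    pos_cM: float
    center_nm: float
    width_nm: float
    amplitude: float  # reflectance difference (A minus B) at the window center


def _grain_baseline(lam: np.ndarray, form: str) -> np.ndarray:
    base = 0.35 + 0.25 * _sigmoid((lam - 550.0) / 60.0)
    base -= 0.12 * _gauss(lam, 1450.0, 60.0)
    base -= 0.15 * _gauss(lam, 1940.0, 80.0)
    base -= 0.05 * _gauss(lam, 2100.0, 60.0)
    if form == "powder":
        base = base + 0.05  # ground powder scatters more light than intact grain
    return base


def gen_grain_spectra(
    panel: RILPanel,
    grid: WavelengthGrid,
    seed: int,
    *,
    forms: Sequence[str] = GRAIN_FORMS,
    spectral_qtls: Sequence[SpectralQTL] = (),
    line_sd: float = 0.01,
    noise_sd: float = 0.001,
) -> tuple[SpectrumSet, GroundTruth]:
    """Grain reflectance spectra for every RIL line in each sample form.

    Each line's spectrum is a starch/protein-like grain continuum plus a
    smooth line-specific deviation (a low-order polynomial of amplitude
    ``line_sd``) plus, for every planted :class:`SpectralQTL`, a Gaussian
    window bump whose sign follows the line's genotype at the linked marker.
    The same genetic signal appears in both forms, so principal-component
    scores of either form can map back to the planted loci.
    """
    rng = np.random.default_rng(seed)
    lam = grid.values
    lam01 = (lam - lam[0]) / (lam[-1] - lam[0])
    for q in spectral_qtls:
        sub = panel.map.markers_on(q.chrom)
        if sub.empty or not np.any(np.abs(sub["pos_cM"] - q.pos_cM) < 1e-6):
            raise ValueError(f"spectral QTL {q} does not reference a marker position")

    bumps = []
    for q in spectral_qtls:
        sub = panel.map.markers_on(q.chrom)
        mk = sub.loc[np.abs(sub["pos_cM"] - q.pos_cM) < 1e-6, "marker"].iloc[0]
        x = panel.genotype_codes(mk)  # +-0.5, NaN treated as 0 contribution
        x = np.nan_to_num(x)
        bumps.append((x, q.amplitude * _gauss(lam, q.center_nm, q.width_nm)))

    rows = []
    spectra = []
    for form in forms:
        base = _grain_baseline(lam, form)
        for i, line in enumerate(panel.genotypes.index):
            dev_coef = rng.normal(0.0, line_sd, size=3)
            dev = dev_coef[0] + dev_coef[1] * (lam01 - 0.5) + dev_coef[2] * (
                (lam01 - 0.5) ** 2 - 1.0 / 12.0
            )
            r = base + dev
            for x, bump in bumps:
                r = r + x[i] * bump
            if noise_sd > 0:
                r = r + rng.normal(0.0, noise_sd, size=r.shape)
            spectra.append(r)
            rows.append(
                dict(
                    sample_id=f"{form[0].upper()}_{line}",
                    cultivar=line,
                    subspecies="",
                    field="alluvial",
                    dat=-1,
                    replicate=1,
                    tissue="grain",
                    form=form,
                )
            )
    X = np.vstack(spectra)
    if np.any(X <= 0) or np.any(X >= 1):
        raise ValueError("generated grain reflectance left (0, 1)")
    meta = pd.DataFrame(rows)
    truth = GroundTruth(
        qtl_truth=list(spectral_qtls),
        params=dict(line_sd=line_sd, noise_sd=noise_sd, forms=tuple(forms)),
    )
    return SpectrumSet(grid, X, meta, stage=("reflectance",)), truth
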