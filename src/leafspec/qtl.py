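"""QTL mapping for RIL panels: Kosambi map, EM interval mapping, permutations.

The scan model is simple interval mapping for a two-genotype-class RIL
population: at each position on a cM grid, the probability of each line
carrying the A allele is computed from its flanking markers (Markov two-point
model with RIL-expanded recombination fractions), and a two-component normal
mixture with those known per-line mixing probabilities is fit by EM (class
means and a common variance). Evidence is summarised as

    LOD = log10( L_mixture / L_single_normal ).

Genome-wide significance comes from phenotype permutations: the threshold is
the empirical (1 - alpha) quantile of the maximum LOD per permuted scan.

Map estimation converts observed RIL recombination frequencies R between
adjacent markers back to meiotic fractions via r = R / (2 - 2R) (the inverse
of the selfed-RIL expansion R = 2r / (1 + 2r)) and to centimorgans via the
Kosambi function d = 25 ln((1 + 2r) / (1 - 2r)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GeneticMap, RILPanel, SpectrumSet

__all__ = [
    "kosambi",
    "kosambi_inverse",
    "ril_expansion",
    "ril_shrink",
    "estimate_map",
    "QTLScan",
    "im_scan",
    "scan_phenotypes",
    "perm_threshold",
    "QTL",
    "extract_qtls",
    "colocalization",
    "pc_traits",
]

LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# map functions

def kosambi(r):
    """Kosambi map function: recombination fraction r -> distance in cM."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d):
    """Inverse Kosambi: distance in cM -> recombination fraction 0.5*tanh(d/50)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


def ril_expansion(r):
    """Meiotic r -> observed RIL (selfing to fixation) fraction R = 2r/(1+2r)."""
    r = np.asarray(r, dtype=float)
    R = 2.0 * r / (1.0 + 2.0 * r)
    return float(R) if R.ndim == 0 else R


def ril_shrink(R):
    """Observed RIL fraction R -> meiotic r = R/(2-2R), inverse of ril_expansion."""
    R = np.asarray(R, dtype=float)
    r = R / (2.0 - 2.0 * R)
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# map estimation

def estimate_map(panel: RILPanel) -> tuple[GeneticMap, pd.DataFrame]:
    """Re-estimate marker positions from observed recombination frequencies.

    Marker order is taken as given. For each adjacent pair the discordance
    frequency R among lines scored at both markers is shrunk to a meiotic r
    and mapped to cM with Kosambi; cumulative positions start at 0 per
    chromosome. Intervals whose R reaches 0.5 are flagged ``unlinked`` and
    their length is computed at an R capped just below 0.5.

    Returns the estimated map and a per-interval table
    (chrom, left, right, R_obs, n_scored, r, d_cM, unlinked).
    """
    rows = []
    map_rows = []
    cap = 0.49
    for chrom in panel.map.chromosomes:
        sub = panel.map.markers_on(chrom)
        markers = list(sub["marker"])
        pos = 0.0
        map_rows.append((markers[0], chrom, 0.0))
        g = panel.genotypes[markers].to_numpy(dtype=object)
        for k in range(len(markers) - 1):
            a, b = g[:, k], g[:, k + 1]
            scored = (~pd.isna(a)) & (~pd.isna(b))
            n_scored = int(scored.sum())
            if n_scored == 0:
                raise ValueError(f"no lines scored at {markers[k]}/{markers[k + 1]}")
            R_obs = float(np.mean(a[scored] != b[scored]))
            unlinked = R_obs >= 0.5
            R_eff = min(R_obs, cap)
            r = ril_shrink(R_eff)
            d = kosambi(r)
            rows.append(
                dict(
                    chrom=chrom,
                    left=markers[k],
                    right=markers[k + 1],
                    R_obs=R_obs,
                    n_scored=n_scored,
                    r=r,
                    d_cM=d,
                    unlinked=unlinked,
                )
            )
            pos += d
            map_rows.append((markers[k + 1], chrom, pos))
    est = GeneticMap(pd.DataFrame(map_rows, columns=["marker", "chrom", "pos_cM"]))
    return est, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genotype probabilities

def _transition_prob_a(g: np.ndarray, R: float) -> np.ndarray:
    """P(path consistent with QTL allele A) given flank genotype g (1=A, 0=B)."""
    return np.where(g == 1.0, 1.0 - R, R)


def genotype_prob_a(
    geno: np.ndarray, marker_pos: np.ndarray, pos: float
) -> np.ndarray:
    """Per-line probability of the A allele at ``pos`` from flanking markers.

    ``geno`` is lines x markers for one chromosome coded 1.0 (A), 0.0 (B),
    NaN (missing); ``marker_pos`` the marker cM positions. Lines with a
    missing flank use the nearest informative marker on that side; with no
    informative marker on either side the prior is 0.5.
    """
    n, m = geno.shape
    pa = np.full(n, 0.5)
    has_missing = np.isnan(geno).any()

    if not has_missing:
        left = int(np.searchsorted(marker_pos, pos, side="right") - 1)
        right = int(np.searchsorted(marker_pos, pos, side="left"))
        tl = tr = None
        if left >= 0:
            Rl = ril_expansion(kosambi_inverse(pos - marker_pos[left]))
            tl = (_transition_prob_a(geno[:, left], Rl),
                  _transition_prob_a(1.0 - geno[:, left], Rl))
        if right < m:
            Rr = ril_expansion(kosambi_inverse(marker_pos[right] - pos))
            tr = (_transition_prob_a(geno[:, right], Rr),
                  _transition_prob_a(1.0 - geno[:, right], Rr))
        if tl and tr:
            ua, ub = tl[0] * tr[0], tl[1] * tr[1]
        elif tl:
            ua, ub = tl
        elif tr:
            ua, ub = tr
        else:  # pragma: no cover - empty chromosome
            return pa
        return ua / (ua + ub)

    for i in range(n):
        obs = ~np.isnan(geno[i])
        idx = np.flatnonzero(obs)
        li = idx[marker_pos[idx] <= pos]
        ri = idx[marker_pos[idx] >= pos]
        ua = ub = 1.0
        informative = False
        if li.size:
            k = li[-1]
            R = ril_expansion(kosambi_inverse(pos - marker_pos[k]))
            ua *= (1.0 - R) if geno[i, k] == 1.0 else R
            ub *= R if geno[i, k] == 1.0 else (1.0 - R)
            informative = True
        if ri.size and (not li.size or ri[0] != li[-1]):
            k = ri[0]
            R = ril_expansion(kosambi_inverse(marker_pos[k] - pos))
            ua *= (1.0 - R) if geno[i, k] == 1.0 else R
            ub *= R if geno[i, k] == 1.0 else (1.0 - R)
            informative = True
        if informative:
            pa[i] = ua / (ua + ub)
    return pa


# ---------------------------------------------------------------------------
# EM mixture fit, vectorised over phenotype vectors

def _em_mixture(
    prior_a: np.ndarray,
    Y: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the two-class normal mixture at one position for many phenotypes.

    prior_a: (n,) per-line P(allele A); Y: (P, n) phenotype rows. Returns
    (lod, converged), both length P. LOD is clipped at 0 (the mixture nests
    the single normal). Constant phenotypes give LOD 0.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    P, n = Y.shape
    pa = np.clip(np.asarray(prior_a, dtype=float), 0.0, 1.0)[None, :]
    pb = 1.0 - pa

    var0 = Y.var(axis=1)
    lod = np.zeros(P)
    conv = np.ones(P, dtype=bool)
    act = var0 > 0
    if not act.any():
        return lod, conv
    Ya = Y[act]
    Pa = Ya.shape[0]

    # initialise at the prior-weighted class means
    w = np.broadcast_to(pa, (Pa, n)).copy()
    wa = np.maximum(w.sum(axis=1), 1e-12)
    wb = np.maximum(n - wa, 1e-12)
    muA = (w * Ya).sum(axis=1) / wa
    muB = ((1.0 - w) * Ya).sum(axis=1) / wb
    s2 = np.maximum(
        (w * (Ya - muA[:, None]) ** 2 + (1.0 - w) * (Ya - muB[:, None]) ** 2).sum(axis=1)
        / n,
        1e-300,
    )

    prev = np.full(Pa, -np.inf)
    converged = np.zeros(Pa, dtype=bool)
    ll = prev
    for _ in range(max_iter):
        da = (Ya - muA[:, None]) ** 2
        db = (Ya - muB[:, None]) ** 2
        la = -0.5 * da / s2[:, None]
        lb = -0.5 * db / s2[:, None]
        m = np.maximum(la, lb)
        fa = pa * np.exp(la - m)
        fb = pb * np.exp(lb - m)
        tot = np.maximum(fa + fb, 1e-300)
        ll = (np.log(tot) + m).sum(axis=1) - 0.5 * n * np.log(2.0 * np.pi * s2)
        converged = converged | (np.abs(ll - prev) < tol)
        prev = ll
        if converged.all():
            break
        w = fa / tot
        wa = w.sum(axis=1)
        wb = n - wa
        muA = np.where(wa > 1e-10, (w * Ya).sum(axis=1) / np.maximum(wa, 1e-10), muA)
        muB = np.where(
            wb > 1e-10, ((1.0 - w) * Ya).sum(axis=1) / np.maximum(wb, 1e-10), muB
        )
        s2 = np.maximum(
            (w * (Ya - muA[:, None]) ** 2 + (1.0 - w) * (Ya - muB[:, None]) ** 2).sum(
                axis=1
            )
            / n,
            1e-300,
        )

    logL0 = -0.5 * n * (np.log(2.0 * np.pi * var0[act]) + 1.0)
    lod[act] = np.maximum((ll - logL0) / LN10, 0.0)
    conv[act] = converged
    return lod, conv


# ---------------------------------------------------------------------------
# scans

@dataclass
class QTLScan:
    """LOD profile over a genome-wide cM grid, with per-trait thresholds."""

    grid: pd.DataFrame  # columns chrom, pos_cM
    lod: pd.DataFrame  # same rows, one column per trait
    thresholds: dict = field(default_factory=dict)  # trait -> genome-wide 5% LOD
    converged: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.lod):
            raise ValueError("grid and lod must align")
        if (self.lod.to_numpy() < 0).any():
            raise ValueError("LOD values must be nonnegative")


def _scan_grid(gmap: GeneticMap, step_cM: float) -> list[tuple[object, np.ndarray]]:
    out = []
    for chrom in gmap.chromosomes:
        pos = gmap.markers_on(chrom)["pos_cM"].to_numpy()
        grid = np.arange(pos[0], pos[-1] + 1e-9, step_cM)
        if grid[-1] < pos[-1] - 1e-9:
            grid = np.append(grid, pos[-1])
        out.append((chrom, grid))
    return out


def _chrom_geno_codes(panel: RILPanel, chrom) -> tuple[np.ndarray, np.ndarray]:
    sub = panel.map.markers_on(chrom)
    g = panel.genotypes[list(sub["marker"])]
    codes = g.map(lambda v: 1.0 if v == "A" else (0.0 if v == "B" else np.nan)).to_numpy(
        dtype=float
    )
    return codes, sub["pos_cM"].to_numpy()


def _position_priors(panel: RILPanel, step_cM: float):
    """Precompute (chrom, pos, prior_a) for every scan position."""
    out = []
    for chrom, grid in _scan_grid(panel.map, step_cM):
        codes, mpos = _chrom_geno_codes(panel, chrom)
        for pos in grid:
            out.append((chrom, float(pos), genotype_prob_a(codes, mpos, pos)))
    return out


def scan_phenotypes(
    panel: RILPanel,
    Y: np.ndarray,
    step_cM: float = 1.0,
    *,
    priors=None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Interval-mapping scan of many phenotype rows at once.

    Y is (P, n_lines). Returns (grid frame, lod (positions x P),
    converged (positions x P)). ``priors`` may carry precomputed position
    priors to amortise the genotype-probability work across permutations.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[1] != panel.n_lines:
        raise ValueError("phenotype columns must match panel lines")
    if priors is None:
        priors = _position_priors(panel, step_cM)
    lod = np.empty((len(priors), Y.shape[0]))
    conv = np.empty((len(priors), Y.shape[0]), dtype=bool)
    rows = []
    for i, (chrom, pos, pa) in enumerate(priors):
        lod[i], conv[i] = _em_mixture(pa, Y, tol=tol, max_iter=max_iter)
        rows.append((chrom, pos))
    grid = pd.DataFrame(rows, columns=["chrom", "pos_cM"])
    return grid, lod, conv


def im_scan(panel: RILPanel, trait: str, step_cM: float = 1.0) -> QTLScan:
    """Simple interval mapping with EM for one trait on a ``step_cM`` grid."""
    if trait not in panel.phenotypes.columns:
        raise KeyError(f"trait {trait!r} not in panel")
    y = panel.phenotypes[trait].to_numpy(dtype=float)
    informative = np.isfinite(y).sum()
    if informative < 20:
        raise ValueError("need >= 20 informative lines")
    grid, lod, conv = scan_phenotypes(panel, y[None, :], step_cM)
    return QTLScan(
        grid=grid,
        lod=pd.DataFrame({trait: lod[:, 0]}),
        converged=pd.DataFrame({trait: conv[:, 0]}),
    )


def perm_threshold(
    panel: RILPanel,
    trait: str,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    step_cM: float = 1.0,
    *,
    priors=None,
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    The phenotype vector is permuted against the genotype rows ``n_perm``
    times; each permuted vector is scanned and the maximum LOD retained. The
    threshold is the empirical (1 - alpha) quantile (type-7 linear
    interpolation) of that max-LOD distribution.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y = panel.phenotypes[trait].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    Y = np.stack([rng.permutation(y) for _ in range(n_perm)])
    if priors is None:
        priors = _position_priors(panel, step_cM)
    _, lod, _ = scan_phenotypes(panel, Y, step_cM, priors=priors)
    max_lod = lod.max(axis=0)
    return float(np.quantile(max_lod, 1.0 - alpha, method="linear"))


def threshold_type1_error(
    n_replicates: int = 200,
    n_perm: int = 500,
    alpha: float = 0.05,
    n_lines: int = 96,
    gmap: GeneticMap | None = None,
    step_cM: float = 10.0,
    seed: int = 0,
) -> float:
    """Empirical genome-wide type-I error of the permutation threshold.

    Each replicate simulates a fresh RIL panel whose phenotype is pure noise
    (no planted QTL), computes the genome-wide threshold by permuting that
    phenotype, and scans the phenotype itself; returned is the fraction of
    replicates whose maximum LOD exceeds their own threshold — the standard
    permutation-test guarantee, which should match ``alpha`` to Monte-Carlo
    accuracy under the exchangeable null.
    """
    from .synth import gen_ril_panel  # deferred: synth imports this module

    gmap = gmap if gmap is not None else GeneticMap.uniform()
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_replicates):
        panel, _ = gen_ril_panel(n_lines, gmap, seed=int(rng.integers(2**31)))
        priors = _position_priors(panel, step_cM)
        thr = perm_threshold(
            panel,
            "DH",
            n_perm=n_perm,
            alpha=alpha,
            seed=int(rng.integers(2**31)),
            step_cM=step_cM,
            priors=priors,
        )
        y = panel.phenotypes["DH"].to_numpy(dtype=float)
        _, lod, _ = scan_phenotypes(panel, y[None, :], step_cM, priors=priors)
        exceed += lod.max() > thr
    return exceed / n_replicates


# ---------------------------------------------------------------------------
# QTL extraction

@dataclass(frozen=True)
class QTL:
    trait: str
    chrom: object
    peak_cM: float
    peak_lod: float
    ci_lo_cM: float  # 1.5-LOD support interval
    ci_hi_cM: float


def extract_qtls(
    scan: QTLScan, thresholds: dict | None = None, lod_drop: float = 1.5
) -> list[QTL]:
    """Collapse contiguous supra-threshold regions to peaks with support intervals.

    The support interval extends from the peak in each direction until the
    LOD falls more than ``lod_drop`` below the peak (or the chromosome ends).
    """
    thresholds = thresholds if thresholds is not None else scan.thresholds
    out: list[QTL] = []
    for trait in scan.lod.columns:
        if trait not in thresholds:
            raise KeyError(f"no threshold for trait {trait!r}")
        thr = thresholds[trait]
        for chrom in scan.grid["chrom"].unique():
            sel = (scan.grid["chrom"] == chrom).to_numpy()
            pos = scan.grid.loc[sel, "pos_cM"].to_numpy()
            lod = scan.lod.loc[sel, trait].to_numpy()
            above = lod > thr
            if not above.any():
                continue
            # contiguous runs above threshold
            edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
            for start, stop in zip(edges[::2], edges[1::2]):
                k = start + int(np.argmax(lod[start:stop]))
                peak = lod[k]
                lo = k
                while lo > 0 and lod[lo - 1] > peak - lod_drop:
                    lo -= 1
                hi = k
                while hi < len(lod) - 1 and lod[hi + 1] > peak - lod_drop:
                    hi += 1
                out.append(
                    QTL(
                        trait=trait,
                        chrom=chrom,
                        peak_cM=float(pos[k]),
                        peak_lod=float(peak),
                        ci_lo_cM=float(pos[lo]),
                        ci_hi_cM=float(pos[hi]),
                    )
                )
    return out


def colocalization(qtls: list[QTL]) -> list[tuple[QTL, QTL]]:
    """Pairs of QTLs for different traits whose support intervals overlap."""
    pairs = []
    for i, a in enumerate(qtls):
        for b in qtls[i + 1 :]:
            if a.trait == b.trait or a.chrom != b.chrom:
                continue
            if a.ci_lo_cM <= b.ci_hi_cM and b.ci_lo_cM <= a.ci_hi_cM:
                pairs.append((a, b))
    return pairs


# ---------------------------------------------------------------------------
# spectral PC-score traits

REGIONS = {"A": (450.0, 2499.5), "V": (450.0, 750.0), "N": (750.0, 2499.5)}
FORM_CODES = {"powder": "P", "brown_grain": "B"}


def pc_traits(
    grain_spectra: SpectrumSet,
    spec=None,
    regions: dict | None = None,
    n_components: int = 10,
    line_col: str = "cultivar",
) -> pd.DataFrame:
    """Principal-component scores of grain spectra as phenotype columns.

    For each sample form (ground powder P, brown grain B) and each wavelength
    region (A = 450–2499.5 nm, V = 450–750 nm, N = 750–2499.5 nm), the
    spectra are pretreated (default SG2 + scaling), decomposed by PCA, and
    the first ``n_components`` scores become traits named
    ``<form>_<region>_PC<k>``, e.g. ``P_A_PC9`` or ``B_N_PC1``.
    """
    from .chemometrics import pca
    from .preprocess import apply_rows, center_scale, spec_by_name

    if spec is None:
        spec = spec_by_name("SG2 + scaling")
    regions = regions if regions is not None else REGIONS

    frames = []
    for form, code in FORM_CODES.items():
        sel = (grain_spectra.meta["form"] == form).to_numpy()
        if not sel.any():
            continue
        sub = grain_spectra.select(sel)
        lines = sub.meta[line_col].to_numpy()
        for rcode, (lo, hi) in regions.items():
            region = sub.subset_region(lo, hi)
            Xr = apply_rows(region.values, spec)
            Xc, _ = center_scale(Xr, scaling=spec.scaling)
            res = pca(Xc, scaling=False, pre_centered=True)
            k = min(n_components, res.scores.shape[1])
            cols = {f"{code}_{rcode}_PC{j + 1}": res.scores[:, j] for j in range(k)}
            frames.append(pd.DataFrame(cols, index=lines))
    if not frames:
        raise ValueError("no recognised sample forms in spectra metadata")
    return pd.concat(frames, axis=1)
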