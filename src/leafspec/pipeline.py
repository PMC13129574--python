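"""End-to-end study runners with config, seeding discipline and manifests.

Three studies are orchestrated:

* ``leaf_spectroscopy`` — bench-spectrometer leaf spectra over the growth
  season; pretreatment sweep, PCA, leave-one-out PLS prediction of the 54
  transcript-cluster means, and the held-out alluvial-DAT split prediction.
* ``leaf_imaging`` — hyperspectral leaf image cubes; white/dark correction,
  ROI extraction, mean spectra, {smoothing, SG1, SG2, NDSI} x PCA pooled and
  per-DAT.
* ``grain_qtl`` — RIL grain spectra (powder and brown grain); PC-score
  traits per wavelength region, merged with the measured grain traits, then
  genome scans with permutation thresholds and QTL extraction.

A single global seed is expanded into per-stage substreams by stable string
labels, so adding draws to one stage never perturbs another. Every run
writes a JSON manifest (config, seed, output hashes) sufficient to reproduce
outputs bitwise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemometrics, features, imaging, preprocess, qtl, synth
from .containers import GeneticMap
from .io import write_rqtl_csv, write_spectra_csv

__all__ = ["RunConfig", "stage_seed", "run_leaf_spectroscopy", "run_leaf_imaging", "run_grain_qtl", "run"]


def stage_seed(seed: int, label: str) -> int:
    """Derive a deterministic per-stage seed (< 2^31) from (seed, label)."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Serializable description of one study run."""

    study: str
    seed: int = 0
    outdir: str = "results"
    options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(study=self.study, seed=self.seed, outdir=str(self.outdir), options=self.options)

    @staticmethod
    def from_file(path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return RunConfig(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(cfg: RunConfig, outdir: Path, outputs: dict[str, Path], extra: dict) -> Path:
    manifest = dict(
        config=cfg.to_dict(),
        outputs={k: dict(path=str(p), sha256=_sha256(p)) for k, p in outputs.items()},
        **extra,
    )
    path = outdir / f"{cfg.study}_manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# study 1: leaf spectroscopy + expression prediction

#: held-out alluvial DATs predicted from the remaining design cells
SPLIT_TEST_DATS = (21, 35, 49, 63, 77)


def run_leaf_spectroscopy(cfg: RunConfig) -> dict:
    """Spectra + cluster expression -> pretreatment sweep -> PCA -> split prediction."""
    opt = cfg.options
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    n_clusters = opt.get("n_clusters", 54)
    step_nm = opt.get("wavelength_step_nm", 2.5)
    max_components = opt.get("max_components", 10)
    pred_spec_name = opt.get("prediction_pretreatment", "SG2 + scaling")
    grid = synth.spectrometer_grid() if step_nm == 0.5 else synth.WavelengthGrid.spanning(400.0, 2499.5, step_nm)

    design = synth.leaf_spectroscopy_design()
    spectra, spec_truth = synth.gen_leaf_spectra(
        design, grid, seed=stage_seed(cfg.seed, "leaf_spectra")
    )
    expr_design = synth.transcriptome_design()
    expr_all, expr_truth = synth.gen_cluster_expression(
        expr_design, n_clusters=n_clusters, seed=stage_seed(cfg.seed, "cluster_expression")
    )
    # the transcriptome series starts one sampling earlier; drop that first
    # DAT so expression aligns one-to-one with the spectroscopy design
    expr = expr_all.select(expr_all.meta["dat"] != min(expr_design.dats))
    keys = ["cultivar", "field", "dat"]
    if not expr.meta[keys].reset_index(drop=True).equals(spectra.meta[keys].reset_index(drop=True)):
        raise ValueError("expression design does not align with spectroscopy design")
    expr.meta["sample_id"] = spectra.meta["sample_id"].to_numpy()

    absorbance = preprocess.to_absorbance(spectra)
    registry = [
        s
        for s in preprocess.registry()
        if s.name in opt.get("pretreatments", [s.name for s in preprocess.registry()])
    ]
    cv_report = chemometrics.sweep(absorbance, expr, registry, max_components=max_components)

    pred_spec = preprocess.spec_by_name(pred_spec_name)
    pca_in = preprocess.apply_rows(absorbance.values, pred_spec)
    pca_mat, _ = preprocess.center_scale(pca_in, scaling=pred_spec.scaling)
    res = chemometrics.pca(pca_mat, scaling=False, pre_centered=True)
    scores = pd.concat(
        [
            spectra.meta.reset_index(drop=True),
            pd.DataFrame(res.scores[:, :4], columns=["PC1", "PC2", "PC3", "PC4"]),
        ],
        axis=1,
    )

    is_test = (
        (spectra.meta["field"] == "alluvial") & spectra.meta["dat"].isin(SPLIT_TEST_DATS)
    ).to_numpy()
    predictions = chemometrics.split_predict(
        absorbance.select(~is_test),
        expr.select(~is_test),
        absorbance.select(is_test),
        pred_spec,
        n_components=opt.get("n_pred_components", 5),
        test_expr=expr.select(is_test),
    )

    outputs = {
        "spectra": write_spectra_csv(spectra, outdir / "leaf_spectra.csv"),
        "expression": _write_csv(expr.frame(), outdir / "cluster_expression.csv"),
        "cv_report": _write_csv(cv_report, outdir / "loocv_sweep.csv"),
        "pca_scores": _write_csv(scores, outdir / "leaf_pca_scores.csv"),
        "predictions": _write_csv(predictions, outdir / "split_predictions.csv"),
    }
    manifest = _write_manifest(
        cfg,
        outdir,
        outputs,
        dict(
            n_pretreatments=len(registry),
            n_clusters=len(expr.clusters),
            n_train=int((~is_test).sum()),
            n_test=int(is_test.sum()),
        ),
    )
    return dict(
        cv_report=cv_report,
        predictions=predictions,
        pca=res,
        scores=scores,
        truth=(spec_truth, expr_truth),
        manifest=manifest,
        outputs=outputs,
    )


# ---------------------------------------------------------------------------
# study 2: leaf imaging PCA

def run_leaf_imaging(cfg: RunConfig) -> dict:
    """Cubes -> correction -> ROI -> mean spectra -> {smoothing, SG1, SG2, NDSI} -> PCA."""
    opt = cfg.options
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    replicates = opt.get("replicates", 3)
    design = synth.LeafDesign(
        cultivars=synth._DEFAULT_CULTIVARS,
        fields=("alluvial", "andosol"),
        dats=tuple(opt.get("dats", (26, 33, 40, 47, 54, 61, 68, 75, 83, 90))),
        replicates=replicates,
    )
    grid = synth.visnir_imaging_grid()
    subspecies_amp = opt.get("subspecies_amp", 0.02)

    # per-design-cell true leaf spectra (no measurement noise; pixel noise is
    # added inside each scene)
    leaf_true, truth = synth.gen_leaf_spectra(
        design,
        grid,
        seed=stage_seed(cfg.seed, "imaging_leaf_spectra"),
        noise_sd=0.0,
        subspecies_amp=subspecies_amp,
    )
    shape = tuple(opt.get("image_shape", (48, 48)))
    noise_sd = opt.get("pixel_noise_sd", 5.0)
    rows = []
    spectra_rows = []
    rng = np.random.default_rng(stage_seed(cfg.seed, "imaging_scenes"))
    for i in range(leaf_true.n_samples):
        scene = synth.LeafScene(
            shape=shape,
            leaf_center=(shape[0] / 2 + rng.uniform(-3, 3), shape[1] / 2 + rng.uniform(-3, 3)),
            leaf_axes=(shape[0] * 0.33, shape[1] * 0.2),
            leaf_reflectance=leaf_true.values[i],
            noise_sd=noise_sd,
        )
        capture, cube_truth = synth.gen_image_cube(
            scene, grid, seed=stage_seed(cfg.seed, f"cube_{i}")
        )
        ic = imaging.correct(capture.ir, capture.iw, capture.idark)
        roi = imaging.extract_roi(ic, mode="visnir")
        spectra_rows.append(imaging.mean_spectrum(ic, roi).values[0])
        rows.append(dict(roi_pixels=roi.n_pixels, roi_matches_truth=bool((roi.mask == cube_truth.roi_mask_truth).all())))
    mean_spectra = synth.SpectrumSet(grid, np.vstack(spectra_rows), leaf_true.meta, ("reflectance",))

    score_tables = {}
    for name in ("smoothing", "SG1", "SG2"):
        spec = preprocess.spec_by_name(name)
        X = preprocess.apply_rows(mean_spectra.values, spec)
        score_tables[name] = _pca_scores(X, mean_spectra.meta, scaling=False)
    smoothed = preprocess.moving_average(mean_spectra, window=5)
    nd = features.ndsi(smoothed)
    score_tables["NDSI"] = _pca_scores(nd.values, mean_spectra.meta, scaling=False)

    per_dat = {}
    for name, spec_name in (("SG1", "SG1"), ("NDSI", None)):
        tables = {}
        for dat in design.dats:
            sel = (mean_spectra.meta["dat"] == dat).to_numpy()
            if name == "NDSI":
                X = nd.values[sel]
            else:
                X = preprocess.apply_rows(mean_spectra.values[sel], preprocess.spec_by_name(spec_name))
            tables[dat] = _pca_scores(X, mean_spectra.meta.loc[sel], scaling=False)
        per_dat[name] = tables

    outputs = {"mean_spectra": write_spectra_csv(mean_spectra, outdir / "imaging_mean_spectra.csv")}
    for name, tab in score_tables.items():
        outputs[f"scores_{name}"] = _write_csv(tab, outdir / f"imaging_pca_{name}.csv")
    roi_report = pd.DataFrame(rows)
    outputs["roi_report"] = _write_csv(roi_report, outdir / "imaging_roi_report.csv")
    manifest = _write_manifest(
        cfg, outdir, outputs, dict(n_samples=mean_spectra.n_samples, per_dat_tables={k: len(v) for k, v in per_dat.items()})
    )
    return dict(
        mean_spectra=mean_spectra,
        scores=score_tables,
        per_dat=per_dat,
        roi_report=roi_report,
        truth=truth,
        manifest=manifest,
        outputs=outputs,
    )


def _pca_scores(X: np.ndarray, meta: pd.DataFrame, scaling: bool, k: int = 4) -> pd.DataFrame:
    Xc, _ = preprocess.center_scale(np.asarray(X, dtype=float), scaling=scaling)
    res = chemometrics.pca(Xc, scaling=False, pre_centered=True)
    k = min(k, res.scores.shape[1])
    return pd.concat(
        [
            meta.reset_index(drop=True),
            pd.DataFrame(res.scores[:, :k], columns=[f"PC{j + 1}" for j in range(k)]),
        ],
        axis=1,
    )


# ---------------------------------------------------------------------------
# study 3: grain spectra PC traits + QTL mapping

DEFAULT_GRAIN_QTLS = (
    synth.QTLEffect("PG", 3, 40.0, 1.5),
    synth.QTLEffect("MW", 3, 40.0, 1.2),
    synth.QTLEffect("PG", 8, 60.0, 1.2),
    synth.QTLEffect("MW", 8, 60.0, 1.0),
    synth.QTLEffect("DH", 8, 60.0, 1.5),
)

DEFAULT_SPECTRAL_QTLS = (
    synth.SpectralQTL(3, 40.0, 1200.0, 25.0, 0.02),
    synth.SpectralQTL(1, 130.0, 2100.0, 25.0, 0.015),
)


def run_grain_qtl(cfg: RunConfig) -> dict:
    """Grain spectra -> PC-score traits -> genome scans -> QTL table."""
    opt = cfg.options
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    n_lines = opt.get("n_lines", 96)
    gmap = opt.get("map") or GeneticMap.uniform()
    qtls = opt.get("qtls", DEFAULT_GRAIN_QTLS)
    spectral_qtls = opt.get("spectral_qtls", DEFAULT_SPECTRAL_QTLS)
    n_perm = opt.get("n_perm", 200)
    alpha = opt.get("alpha", 0.05)
    step_cM = opt.get("step_cM", 10.0)
    step_nm = opt.get("wavelength_step_nm", 2.5)
    grid = synth.WavelengthGrid.spanning(450.0, 2499.5, step_nm)

    panel, panel_truth = synth.gen_ril_panel(
        n_lines, gmap, qtls, seed=stage_seed(cfg.seed, "ril_panel")
    )
    grain, grain_truth = synth.gen_grain_spectra(
        panel, grid, seed=stage_seed(cfg.seed, "grain_spectra"), spectral_qtls=spectral_qtls
    )
    pcs = qtl.pc_traits(grain)
    panel = panel.with_traits(pcs)

    traits = list(panel.phenotypes.columns)
    priors = qtl._position_priors(panel, step_cM)
    Y = panel.phenotypes[traits].to_numpy(dtype=float).T
    grid_df, lod, _ = qtl.scan_phenotypes(panel, Y, step_cM, priors=priors)
    scan = qtl.QTLScan(grid=grid_df, lod=pd.DataFrame(lod, columns=traits))

    thresholds = {}
    if n_perm:
        for i, trait in enumerate(traits):
            thresholds[trait] = qtl.perm_threshold(
                panel,
                trait,
                n_perm=n_perm,
                alpha=alpha,
                seed=stage_seed(cfg.seed, f"perm_{trait}"),
                step_cM=step_cM,
                priors=priors,
            )
        scan.thresholds = thresholds
        found = qtl.extract_qtls(scan)
        pairs = qtl.colocalization(found)
    else:
        found, pairs = [], []

    qtl_table = pd.DataFrame(
        [
            dict(
                trait=q.trait,
                chrom=q.chrom,
                peak_cM=q.peak_cM,
                peak_lod=q.peak_lod,
                ci_lo_cM=q.ci_lo_cM,
                ci_hi_cM=q.ci_hi_cM,
                threshold=thresholds.get(q.trait, np.nan),
            )
            for q in found
        ]
    )
    coloc_table = pd.DataFrame(
        [
            dict(trait_a=a.trait, trait_b=b.trait, chrom=a.chrom, peak_a=a.peak_cM, peak_b=b.peak_cM)
            for a, b in pairs
        ]
    )
    scan_table = pd.concat([grid_df, pd.DataFrame(lod, columns=traits)], axis=1)

    outputs = {
        "cross": write_rqtl_csv(panel, outdir / "ril_cross.csv"),
        "scan": _write_csv(scan_table, outdir / "qtl_scan.csv"),
        "qtls": _write_csv(qtl_table, outdir / "qtl_table.csv"),
        "colocalization": _write_csv(coloc_table, outdir / "qtl_colocalization.csv"),
    }
    manifest = _write_manifest(
        cfg,
        outdir,
        outputs,
        dict(
            n_traits=len(traits),
            n_perm=n_perm,
            thresholds={k: float(v) for k, v in thresholds.items()},
        ),
    )
    return dict(
        panel=panel,
        scan=scan,
        qtls=found,
        colocalization=pairs,
        qtl_table=qtl_table,
        truth=(panel_truth, grain_truth),
        manifest=manifest,
        outputs=outputs,
    )


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


_RUNNERS = {
    "leaf_spectroscopy": run_leaf_spectroscopy,
    "leaf_imaging": run_leaf_imaging,
    "grain_qtl": run_grain_qtl,
}


def run(cfg: RunConfig) -> dict:
    try:
        runner = _RUNNERS[cfg.study]
    except KeyError:
        raise ValueError(f"unknown study {cfg.study!r}") from None
    return runner(cfg)
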