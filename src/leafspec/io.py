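"""Readers and writers for the on-disk interchange formats.

* SpectrumSet — wide CSV: metadata columns (sample_id, cultivar, subspecies,
  field, dat, replicate, tissue, form) followed by one column per wavelength
  named by its nm value.
* RILPanel — R/qtl-style cross CSV: row 1 phenotype + marker names, row 2
  chromosome (blank for phenotypes), row 3 cM position, then one row per
  line with genotypes coded A/B (blank = missing).
* HyperCube — band-sequential (BSQ) float32 binary with a JSON sidecar
  giving dims, dtype, interleave and the wavelength axis.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GeneticMap, HyperCube, RILPanel, SpectrumSet, WavelengthGrid

__all__ = [
    "write_spectra_csv",
    "read_spectra_csv",
    "write_rqtl_csv",
    "read_rqtl_csv",
    "write_cube",
    "read_cube",
]

_META = ["sample_id", "cultivar", "subspecies", "field", "dat", "replicate", "tissue", "form"]


def write_spectra_csv(s: SpectrumSet, path) -> Path:
    path = Path(path)
    meta = s.meta.copy()
    for col in _META:
        if col not in meta.columns:
            meta[col] = ""
    wide = pd.concat(
        [
            meta[_META].reset_index(drop=True),
            pd.DataFrame(s.values, columns=[f"{v:g}" for v in s.grid.values]),
        ],
        axis=1,
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    wide.to_csv(path, index=False)
    return path


def read_spectra_csv(path, stage: tuple[str, ...] = ("reflectance",)) -> SpectrumSet:
    df = pd.read_csv(path)
    meta_cols = [c for c in _META if c in df.columns]
    band_cols = [c for c in df.columns if c not in meta_cols]
    lam = np.array([float(c) for c in band_cols])
    steps = np.diff(lam)
    if not np.allclose(steps, steps[0]):
        raise ValueError("wavelength columns are not uniformly spaced")
    grid = WavelengthGrid(float(lam[0]), float(lam[-1]), float(round(steps[0], 9)))
    return SpectrumSet(grid, df[band_cols].to_numpy(dtype=float), df[meta_cols], stage)


def write_rqtl_csv(panel: RILPanel, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    phenos = list(panel.phenotypes.columns)
    markers = list(panel.map.table["marker"])
    chrom = {m: c for m, c in zip(panel.map.table["marker"], panel.map.table["chrom"])}
    pos = {m: p for m, p in zip(panel.map.table["marker"], panel.map.table["pos_cM"])}
    lines = []
    lines.append(",".join(["id"] + phenos + markers))
    lines.append(",".join([""] * (1 + len(phenos)) + [str(chrom[m]) for m in markers]))
    lines.append(",".join([""] * (1 + len(phenos)) + [f"{pos[m]:g}" for m in markers]))
    for line_id in panel.genotypes.index:
        ph = [f"{panel.phenotypes.at[line_id, t]:.10g}" for t in phenos]
        gt = [
            "" if pd.isna(v) else str(v)
            for v in panel.genotypes.loc[line_id, markers]
        ]
        lines.append(",".join([str(line_id)] + ph + gt))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_rqtl_csv(path) -> RILPanel:
    raw = pd.read_csv(path, header=None, dtype=str, keep_default_na=False)
    header = raw.iloc[0].tolist()
    chrom_row = raw.iloc[1].tolist()
    pos_row = raw.iloc[2].tolist()
    is_marker = [c != "" for c in chrom_row]
    is_marker[0] = False  # id column
    markers = [h for h, m in zip(header, is_marker) if m]
    phenos = [h for h, m in zip(header[1:], is_marker[1:]) if not m]
    map_df = pd.DataFrame(
        {
            "marker": markers,
            "chrom": [_maybe_int(c) for c, m in zip(chrom_row, is_marker) if m],
            "pos_cM": [float(p) for p, m in zip(pos_row, is_marker) if m],
        }
    )
    body = raw.iloc[3:].reset_index(drop=True)
    body.columns = header
    body = body.set_index("id")
    geno = body[markers].replace("", np.nan)
    pheno = body[phenos].astype(float)
    return RILPanel(geno, GeneticMap(map_df), pheno)


def _maybe_int(v: str):
    try:
        return int(v)
    except ValueError:
        return v


def write_ground_truth(truth, path) -> Path:
    """Serialise a GroundTruth record (arrays as lists, frames as records)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = {}
    for key, val in vars(truth).items():
        if val is None:
            continue
        if isinstance(val, np.ndarray):
            out[key] = val.tolist()
        elif isinstance(val, pd.DataFrame):
            out[key] = val.to_dict(orient="records")
        elif key in ("qtl_truth",):
            out[key] = [vars(q) if hasattr(q, "__dataclass_fields__") else q for q in val]
        elif key == "params":
            out[key] = {k: v for k, v in val.items() if isinstance(v, (int, float, str, bool, tuple, list))}
        else:
            out[key] = val
    path.write_text(json.dumps(out, default=str, indent=1))
    return path


def write_cube(cube: HyperCube, path) -> Path:
    """Write a BSQ float32 binary ``path`` with a ``path + '.json'`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows, cols, bands = cube.shape
    # BSQ: band-sequential, one full image plane per band
    np.ascontiguousarray(np.moveaxis(cube.data, 2, 0), dtype=np.float32).tofile(path)
    sidecar = dict(
        rows=rows,
        cols=cols,
        bands=bands,
        dtype="float32",
        interleave="BSQ",
        kind=cube.kind,
        wavelength_nm=dict(
            start=cube.grid.start_nm, stop=cube.grid.stop_nm, step=cube.grid.step_nm
        ),
    )
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_cube(path) -> HyperCube:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    if sidecar["interleave"] != "BSQ" or sidecar["dtype"] != "float32":
        raise ValueError("unsupported cube layout")
    w = sidecar["wavelength_nm"]
    grid = WavelengthGrid(w["start"], w["stop"], w["step"])
    data = np.fromfile(path, dtype=np.float32).reshape(
        sidecar["bands"], sidecar["rows"], sidecar["cols"]
    )
    return HyperCube(np.moveaxis(data, 0, 2).astype(float), grid, sidecar["kind"])
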