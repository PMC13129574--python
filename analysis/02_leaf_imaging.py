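"""Hyperspectral leaf imaging: correction, ROI, pretreatment x PCA.

Simulates the imaging campaign (4 cultivars x 2 soil conditions x 10
samplings at 26–90 DAT, 3 replicate leaves -> 240 cubes on the 450–950 nm /
101-band camera grid), runs white/dark correction, segments each leaf
against the dark background sheet, averages the ROI into one spectrum per
sample, and compares smoothing / SG1 / SG2 / NDSI as inputs to PCA — pooled
over the season and separately per sampling date.

Reported: ROI segmentation accuracy against the generator's planted masks,
and how cleanly NDSI-PCA separates the japonica and indica cultivars within
each sampling date (mean silhouette on PC1–PC2).

Tables land in results/leaf_imaging/.
"""

import numpy as np

from leafspec.pipeline import RunConfig, run_leaf_imaging


def _silhouette(X, labels):
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    vals = []
    for i in range(len(X)):
        same = labels == labels[i]
        same[i] = False
        if not same.any():
            continue
        a = d[i, same].mean()
        b = min(d[i, labels == o].mean() for o in set(labels) if o != labels[i])
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def main() -> None:
    cfg = RunConfig(study="leaf_imaging", seed=7, outdir="results/leaf_imaging")
    out = run_leaf_imaging(cfg)

    roi = out["roi_report"]
    print(f"Imaged {len(roi)} leaves; ROI exactly matches the planted mask in "
          f"{100 * roi.roi_matches_truth.mean():.1f}% of scenes "
          f"(median ROI size {int(roi.roi_pixels.median())} px).")

    print("\nPer-DAT subspecies separation (mean silhouette on PC1-PC2):")
    for name, tables in out["per_dat"].items():
        sils = [
            _silhouette(t[["PC1", "PC2"]].to_numpy(), t["subspecies"].to_numpy())
            for t in tables.values()
        ]
        print(f"  {name:10s} {np.mean(sils):.3f}")

    pooled = out["scores"]["SG1"]
    growth_corr = np.corrcoef(pooled["PC1"], pooled["dat"])[0, 1]
    print(f"\nPooled SG1-PCA: |corr(PC1, DAT)| = {abs(growth_corr):.3f} "
          "(PC1 tracks the growth stage)")
    print(f"Outputs written to {cfg.outdir} (manifest: {out['manifest'].name})")


if __name__ == "__main__":
    main()
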