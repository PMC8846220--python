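#!/usr/bin/env python
"""Optional validations that require externally downloaded datasets.

These reproduce the published observations that cannot be computed from
synthetic data alone:

* CHLA9 (Ewing sarcoma) scRNA-seq — zenodo record 5017357: trajectory
  reconstruction, turning-point extraction and the kinetic fit, expected to
  give an epoch-duration ratio T2s/T1s near 1.0 and a G2/M synthesis boost
  p near 2.5; the scree plot of cell-cycle genes carries ~83% of variance in
  two components with intrinsic dimensionality near 4.
* CCLE cell-line collection + Cellosaurus doubling times: the regression of
  doubling time on principal-circle length (Pearson r ~ 0.93 excluding the
  CHLA10/SCC25 outliers, ~ 0.67 including them; predicted doubling times
  ~64 h for CHLA10 and ~78 h for SCC25).

Nothing is downloaded here: point --counts / --scores-dir / --meta at local
copies of the public data.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np


def run_chla9(counts_path: Path, genes: Path, cells: Path, out: Path) -> None:
    from cct.io import default_gene_sets, read_counts_mtx
    from cct.kinetics import TurningPoints, fit_turning_points, identifiable_combinations
    from cct.pipeline import effective_rank, run_cct_pipeline

    counts = read_counts_mtx(counts_path, genes, cells)
    res = run_cct_pipeline(counts, gene_sets=default_gene_sets(), q=50, seed=0)

    # turning points: per-epoch medians of the two scores at the epoch borders
    q = res.curve.n_nodes
    bounds = np.concatenate([[0.0], res.segmentation.boundaries, [q]])
    pts = []
    for b in bounds:
        w = np.abs((res.pseudotime - b + q / 2) % q - q / 2) < 1.5
        pts.append([np.median(res.scores["S"][w]), np.median(res.scores["G2M"][w])])
    pts = np.array(pts)
    if pts.shape[0] > 5:  # merge the early-G1 sub-epochs as in the 2D reduction
        pts = np.vstack([pts[0], pts[-5:]])[:5] if pts.shape[0] == 6 else pts[:5]
    tp = TurningPoints(pts[:5])
    fit = fit_turning_points(tp)
    report = {
        "t2s_over_t1s": fit.params.t2s / fit.params.t1s,
        "p": fit.params.p,
        "combinations": identifiable_combinations(fit.params)["combinations"],
        "n_curvature_peaks": int(res.curvature.peaks.size),
    }

    # intrinsic dimensionality of the cell-cycle-gene subspace
    genes_cc = [g for gs in default_gene_sets().values() for g in gs]
    gene_index = {g: i for i, g in enumerate(res.normalization.lognorm.gene_ids)}
    rows = [gene_index[g] for g in genes_cc if g in gene_index]
    X = res.normalization.lognorm.dense()[rows].T
    Xc = X - X.mean(axis=0)
    sv = np.linalg.svd(Xc, compute_uv=False)
    var = sv**2 / (sv**2).sum()
    report["variance_pct_top2"] = float(100 * var[:2].sum())
    report["effective_rank_cc_subspace"] = effective_rank(Xc)
    out.write_text(json.dumps(report, indent=2, default=float))
    print(json.dumps({k: report[k] for k in ("t2s_over_t1s", "p", "variance_pct_top2")},
                     indent=2))


def run_doubling(scores_dir: Path, meta: Path, exclude: list[str], out: Path) -> None:
    import pandas as pd

    from cct.doubling import CircleLengthRecord, principal_circle_length, regress_doubling_time

    meta_df = pd.read_csv(meta).set_index("dataset_id")
    records = []
    for path in sorted(scores_dir.glob("*.csv")):
        df = pd.read_csv(path)
        lp, _ = principal_circle_length(df["S_score"], df["M_score"])
        dt = float(meta_df.loc[path.stem, "doubling_time_h"]) if path.stem in meta_df.index else None
        records.append(CircleLengthRecord(path.stem, lp, len(df), dt))
    rep_excl = regress_doubling_time(records, exclude)
    rep_incl = regress_doubling_time(records, [])
    report = {
        "pearson_r_excluding_outliers": rep_excl.pearson_r,
        "pearson_r_including_outliers": rep_incl.pearson_r,
        "p_value_excluding": rep_excl.p_value,
        "predictions": rep_excl.predictions.to_dict(orient="records"),
    }
    out.write_text(json.dumps(report, indent=2, default=float))
    print(f"r = {rep_excl.pearson_r:.3f} (outliers excluded), "
          f"{rep_incl.pearson_r:.3f} (included)")


def main():
    ap = argparse.ArgumentParser(description=__doc__,
                                 formatter_class=argparse.RawDescriptionHelpFormatter)
    sub = ap.add_subparsers(dest="cmd", required=True)
    c = sub.add_parser("chla9", help="fit the kinetic model to a CHLA9-style dataset")
    c.add_argument("--counts", type=Path, required=True)
    c.add_argument("--genes", type=Path, required=True)
    c.add_argument("--cells", type=Path, required=True)
    c.add_argument("--out", type=Path, required=True)
    d = sub.add_parser("doubling", help="doubling-time regression across cell lines")
    d.add_argument("--scores-dir", type=Path, required=True)
    d.add_argument("--meta", type=Path, required=True)
    d.add_argument("--exclude", default="CHLA10,SCC25")
    d.add_argument("--out", type=Path, required=True)
    args = ap.parse_args()
    if args.cmd == "chla9":
        run_chla9(args.counts, args.genes, args.cells, args.out)
    else:
        run_doubling(args.scores_dir, args.meta,
                     [e for e in args.exclude.split(",") if e], args.out)


if __name__ == "__main__":
    main()
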