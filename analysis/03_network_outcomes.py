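#!/usr/bin/env python
"""Connectivity matrices, spanning-tree backbones and the outcome table.

For every denoised subject: the Pearson correlation matrix over retained
volumes, its maximum spanning tree over positive correlations, and the
five outcome measures — global strength (mean tree edge weight), diameter,
leaf fraction, and the two regional PCC-DLPFC connections (synthetic
stand-in node sets at reduced region count).  Trees go to scratch/mst;
the cohort outcome table goes to results/outcomes.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from delnet import io
from delnet.connectivity import pearson_matrix, regional_connectivity
from delnet.mst import diameter, global_strength, kruskal_mst, leaf_fraction
from delnet.pipeline import _auto_region_sets

ROOT = Path(__file__).resolve().parents[1]


def main(argv=None):
    src = ROOT / "scratch" / "denoised"
    mst_dir = ROOT / "scratch" / "mst"
    results = ROOT / "results"
    mst_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for bold in sorted(src.glob("*_bold.tsv")):
        sid = bold.name[: -len("_bold.tsv")]
        series = io.read_series_tsv(bold)
        R = pearson_matrix(series)
        tree = kruskal_mst(R)
        io.write_edges_tsv(mst_dir / f"{sid}_edges.tsv", tree)
        row = {"id": sid, "strength": global_strength(tree),
               "diameter": float(diameter(tree)),
               "leaf_fraction": leaf_fraction(tree)}
        sets = _auto_region_sets(series.n_regions)
        if sets is not None:
            pcc, dl, dr = sets
            row["pcc_dlpfc_left"] = regional_connectivity(series, pcc, dl)
            row["pcc_dlpfc_right"] = regional_connectivity(series, pcc, dr)
        rows.append(row)
    outcomes = pd.DataFrame(rows)
    outcomes.to_csv(results / "outcomes.csv", index=False)
    print(f"outcomes for {len(outcomes)} subjects -> results/outcomes.csv")
    print(outcomes.drop(columns="id").describe().loc[["mean", "std"]]
          .round(3).to_string())


if __name__ == "__main__":
    sys.exit(main())
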