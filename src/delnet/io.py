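"""Plain-text readers/writers for the pipeline's on-disk formats.

Per-subject BOLD matrices are TSV (regions x volumes, row labels = region
index), motion tables are TSV (volumes x 6, one header line naming the
columns), covariates are CSV with the documented column names, connectivity
matrices are square TSV with a region-id header row/column, spanning trees
are 3-column edge lists, and run manifests are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .denoise import MOTION_COLUMNS, MotionRecord, RoiTimeSeriesMatrix
from .mst import SpanningTree

__all__ = [
    "write_series_tsv", "read_series_tsv",
    "write_motion_tsv", "read_motion_tsv",
    "write_covariates_csv", "read_covariates_csv",
    "write_connectivity_tsv", "read_connectivity_tsv",
    "write_edges_tsv", "read_edges_tsv",
    "write_manifest_json", "read_manifest_json",
]


def write_series_tsv(path, series: RoiTimeSeriesMatrix) -> None:
    df = pd.DataFrame(series.values,
                      index=pd.Index(series.region_ids, name="region"))
    with open(path, "w") as fh:
        fh.write(f"# tr_seconds={series.tr_seconds}\n")
        fh.write("# retained_mask=" +
                 "".join("1" if b else "0" for b in series.retained_mask) + "\n")
        df.to_csv(fh, sep="\t", header=False, float_format="%.10g")


def read_series_tsv(path) -> RoiTimeSeriesMatrix:
    tr, mask = None, None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "tr_seconds":
                tr = float(val)
            elif key.strip() == "retained_mask":
                mask = np.array([c == "1" for c in val.strip()])
    if tr is None:
        raise ValueError(f"{path}: missing tr_seconds header")
    df = pd.read_csv(path, sep="\t", comment="#", header=None, index_col=0)
    return RoiTimeSeriesMatrix(values=df.to_numpy(float), tr_seconds=tr,
                               retained_mask=mask,
                               region_ids=df.index.to_numpy(int))


def write_motion_tsv(path, motion: MotionRecord) -> None:
    df = pd.DataFrame(motion.params, columns=list(MOTION_COLUMNS))
    with open(path, "w") as fh:
        if motion.mean_rel_displacement is not None:
            fh.write(f"# mean_rel_displacement_mm={motion.mean_rel_displacement}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_motion_tsv(path) -> MotionRecord:
    mrd = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            mrd = float(first.partition("=")[2])
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns) != list(MOTION_COLUMNS):
        raise ValueError(f"{path}: unexpected motion columns {list(df.columns)}")
    return MotionRecord(df.to_numpy(float), mean_rel_displacement=mrd)


def write_covariates_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_covariates_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_connectivity_tsv(path, matrix: ConnectivityMatrix) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.region_ids,
                      columns=matrix.region_ids)
    df.to_csv(path, sep="\t", float_format="%.10g", index_label="region")


def read_connectivity_tsv(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(values=df.to_numpy(float),
                              region_ids=df.index.to_numpy(int))


def write_edges_tsv(path, tree: SpanningTree) -> None:
    ids = tree.region_ids if tree.region_ids is not None \
        else np.arange(1, tree.n_nodes + 1)
    df = pd.DataFrame({
        "region_i": ids[tree.edges[:, 0]],
        "region_j": ids[tree.edges[:, 1]],
        "weight": tree.weights,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_edges_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest_json(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest_json(path) -> dict:
    return json.loads(Path(path).read_text())
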