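"""Reading and writing the pipeline's standard artifacts.

Plain-text formats throughout: atlas metadata as TSV, ROI time series and
connectivity matrices as labeled CSV, Ca2+ traces as CSV with a header
comment carrying the sampling rate, motion parameters as whitespace
6-column text (realignment convention), node-metric tables as TSV, and
graph exports as GraphML/GEXF for force-based layout tools.  4-D image
series and label maps go through NIfTI via nibabel.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Union

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .graph_metrics import ThresholdedNetwork
from .preprocess import MotionParams, RoiTimeSeries
from .synthetic import Atlas, CaTrace, Region

PathLike = Union[str, Path]

__all__ = [
    "write_atlas_tsv", "read_atlas_tsv",
    "write_timeseries_csv", "read_timeseries_csv",
    "write_matrix_csv", "read_matrix_csv",
    "write_ca_trace_csv", "read_ca_trace_csv",
    "read_motion_params", "write_motion_params",
    "export_graph",
    "save_nifti", "load_nifti",
]


def write_atlas_tsv(atlas: Atlas, path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "abbreviation": [r.abbreviation for r in atlas.regions],
            "hemisphere": [r.hemisphere for r in atlas.regions],
            "functional_group": [r.functional_group for r in atlas.regions],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_atlas_tsv(path: PathLike) -> Atlas:
    df = pd.read_csv(path, sep="\t")
    regions = tuple(
        Region(str(row.abbreviation), str(row.hemisphere), str(row.functional_group))
        for row in df.itertuples()
    )
    return Atlas(regions)


def write_timeseries_csv(ts: RoiTimeSeries, path: PathLike) -> None:
    """T rows, R labeled columns; the sampling interval in a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# tr_seconds={ts.tr!r}\n")
        pd.DataFrame(ts.values, columns=list(ts.labels)).to_csv(fh, index=False)


def read_timeseries_csv(path: PathLike, tr: Optional[float] = None) -> RoiTimeSeries:
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# tr_seconds="):
            tr_file = float(first.split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            tr_file = None
            fh.seek(0)
            df = pd.read_csv(fh)
    tr_final = tr if tr is not None else tr_file
    if tr_final is None:
        raise ValueError("sampling interval not in file header; pass tr=")
    return RoiTimeSeries(values=df.to_numpy(float), tr=tr_final,
                         labels=tuple(df.columns))


def write_matrix_csv(matrix: ConnectivityMatrix, path: PathLike) -> None:
    pd.DataFrame(
        matrix.weights, index=list(matrix.labels), columns=list(matrix.labels)
    ).to_csv(path)


def read_matrix_csv(
    path: PathLike, domain: str = "r", n_timepoints: Optional[int] = None
) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(
        weights=df.to_numpy(float),
        labels=tuple(df.columns),
        domain=domain,
        n_timepoints=n_timepoints,
    )


def write_ca_trace_csv(trace: CaTrace, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={trace.sampling_rate!r}\n")
        if trace.burst_intervals:
            fh.write(f"# burst_intervals={json.dumps(list(trace.burst_intervals))}\n")
        fh.write("value\n")
        np.savetxt(fh, trace.samples, fmt="%.8g")


def read_ca_trace_csv(path: PathLike) -> CaTrace:
    sampling_rate = None
    intervals: tuple = ()
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "sampling_rate_hz":
                sampling_rate = float(val)
            elif key.strip() == "burst_intervals":
                intervals = tuple(tuple(x) for x in json.loads(val))
    if sampling_rate is None:
        raise ValueError("trace file lacks a '# sampling_rate_hz=' header")
    samples = pd.read_csv(path, comment="#")["value"].to_numpy(float)
    return CaTrace(samples=samples, sampling_rate=sampling_rate,
                   burst_intervals=intervals)


def read_motion_params(path: PathLike) -> MotionParams:
    """Whitespace 6-column text: 3 translations (mm), 3 rotations (deg)."""
    arr = np.loadtxt(path)
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 6:
        raise ValueError("expected 6 columns (3 translations, 3 rotations)")
    return MotionParams(translations=arr[:, :3], rotations=arr[:, 3:])


def write_motion_params(motion: MotionParams, path: PathLike) -> None:
    np.savetxt(path, np.hstack([motion.translations, motion.rotations]), fmt="%.6f")


def export_graph(
    net: ThresholdedNetwork,
    path: PathLike,
    atlas: Optional[Atlas] = None,
    partition=None,
    node_table: Optional[pd.DataFrame] = None,
    hub: Optional[pd.Series] = None,
    fmt: Optional[str] = None,
) -> None:
    """Write the network as GraphML or GEXF with node/edge attributes.

    Node attributes (where available): hemisphere, functional group,
    community id, strength, hub score; edge attribute: weight.  ``fmt``
    defaults from the file suffix (.graphml / .gexf).
    """
    g = net.to_networkx()
    if atlas is not None:
        meta = {r.abbreviation: r for r in atlas.regions}
        for node in g.nodes:
            if node in meta:
                g.nodes[node]["hemisphere"] = meta[node].hemisphere
                g.nodes[node]["functional_group"] = meta[node].functional_group
    if partition is not None:
        for node, cid in partition.membership.items():
            if node in g:
                g.nodes[node]["community"] = int(cid)
    if node_table is not None and "strength" in node_table:
        for node, val in node_table["strength"].items():
            if node in g:
                g.nodes[node]["strength"] = float(val)
    if hub is not None:
        for node, val in hub.items():
            if node in g:
                g.nodes[node]["hub_score"] = float(val)
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "gexf":
        nx.write_gexf(g, path)
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


def save_nifti(data: np.ndarray, path: PathLike, voxel_sizes=None) -> None:
    import nibabel as nib

    affine = np.eye(4)
    if voxel_sizes is not None:
        for i, v in enumerate(voxel_sizes[:3]):
            affine[i, i] = v
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_nifti(path: PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Returns (data array, affine)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine
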