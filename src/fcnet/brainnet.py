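"""Export subnetworks in BrainNet-Viewer plain-text formats.

``.node`` files carry one row per displayed node — ``x y z color size label``
(MNI mm coordinates) — and ``.edge`` files a full N x N symmetric weight
matrix; both are tab-separated plain text readable by the viewer.  Only the
file formats are produced here; rendering belongs to the external tool.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .nbs import Component

__all__ = ["export_brainnet", "read_edge_file"]


def export_brainnet(
    components: list[Component],
    coords: pd.DataFrame,
    region_labels: list[str],
    out_prefix: str | Path,
    edge_weights: dict[tuple[int, int], float] | None = None,
) -> tuple[Path, Path]:
    """Write ``<prefix>.node`` and ``<prefix>.edge`` for a component list.

    Parameters
    ----------
    coords : DataFrame with columns (label, x, y, z)
        MNI coordinates; every component node's region label must be present.
    edge_weights : optional mapping (i, j) -> weight
        Defaults to 1.0 for every component edge.  Off-component entries of
        the ``.edge`` matrix are zero.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    n = len(region_labels)
    coord_map = {str(r["label"]): (float(r["x"]), float(r["y"]), float(r["z"])) for _, r in coords.iterrows()}

    node_rows = []
    mat = np.zeros((n, n))
    for cid, comp in enumerate(components, start=1):
        degree = {v: 0 for v in comp.nodes}
        for i, j in comp.edges:
            degree[i] += 1
            degree[j] += 1
            w = 1.0 if edge_weights is None else float(edge_weights[(i, j)])
            mat[i, j] = mat[j, i] = w
        for v in comp.nodes:
            label = region_labels[v]
            if label not in coord_map:
                raise ValueError(f"no MNI coordinate for region {label!r}")
            x, y, z = coord_map[label]
            node_rows.append((x, y, z, cid, degree[v], label))

    node_path = out_prefix.with_suffix(".node")
    edge_path = out_prefix.with_suffix(".edge")
    with open(node_path, "w") as fh:
        for x, y, z, color, size, label in node_rows:
            fh.write(f"{x:g}\t{y:g}\t{z:g}\t{color}\t{size}\t{label}\n")
    np.savetxt(edge_path, mat, fmt="%.10g", delimiter="\t")
    return node_path, edge_path


def read_edge_file(path: str | Path) -> np.ndarray:
    """Read a ``.edge`` weight matrix back (write/read round-trip identity)."""
    return np.loadtxt(path, delimiter="\t", ndmin=2)
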