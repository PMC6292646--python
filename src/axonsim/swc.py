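"""SWC reading and writing (NeuroMorpho dialect).

Files are whitespace-delimited ``id type x y z radius parent`` with ``#``
comments, 1-based ids and parent -1 for roots.  Simulated trees use SWC
type 2 (axon) for main and type I nodes; type II protrusions are also
written as type 2 so files stay consumable by standard SWC tools, with the
branch class and order recorded in a sidecar CSV keyed by node id.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .population import AxonTree

__all__ = ["SwcParseError", "SwcMorphology", "write_swc", "read_swc",
           "tree_to_swc_frame"]

_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]


class SwcParseError(ValueError):
    """Malformed SWC content; the message names the offending line."""


@dataclass
class SwcMorphology:
    """A parsed SWC file: one row per node, topologically validated."""

    nodes: pd.DataFrame  # columns: id, type, x, y, z, radius, parent
    sidecar: pd.DataFrame | None = None  # node_id, branch_id, branch_type, order

    def root_id(self) -> int:
        roots = self.nodes.loc[self.nodes["parent"] == -1, "id"]
        return int(roots.iloc[0])

    def children(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for nid, parent in zip(self.nodes["id"], self.nodes["parent"]):
            if parent != -1:
                out.setdefault(int(parent), []).append(int(nid))
        return out

    def tip_paths(self) -> list[np.ndarray]:
        """Root-to-tip coordinate paths, one per leaf node."""
        xyz = {int(r.id): (r.x, r.y, r.z) for r in self.nodes.itertuples()}
        parent = {int(r.id): int(r.parent) for r in self.nodes.itertuples()}
        kids = self.children()
        leaves = [nid for nid in xyz if nid not in kids]
        paths = []
        for leaf in leaves:
            chain = []
            nid = leaf
            while nid != -1:
                chain.append(xyz[nid])
                nid = parent[nid]
            paths.append(np.array(chain[::-1]))
        return paths


def tree_to_swc_frame(tree: AxonTree,
                      diameter: float = 0.5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a simulated tree into SWC rows plus the branch sidecar.

    Node ids are assigned in branch order (main first, then branches in
    creation order); type II protrusions are written as a single chord.
    """
    rows = []
    side = []
    radius = 0.5 * diameter
    id_of_node: dict[tuple[int, int], int] = {}  # (branch_id, node index) -> swc id
    next_id = 1

    main = tree.branches[0]
    rows.append((next_id, 2, *main.origin_position, radius, -1))
    side.append((next_id, main.branch_id, "main", 0))
    id_of_node[(main.branch_id, -1)] = next_id
    next_id += 1

    for branch in tree.branches:
        label = "main" if branch.btype == "main" else "type_I"
        if branch.btype != "main":
            parent_swc = _origin_swc_id(tree, branch, id_of_node)
        else:
            parent_swc = id_of_node[(main.branch_id, -1)]
        prev = parent_swc if branch.btype != "main" else id_of_node[(main.branch_id, -1)]
        for i, p in enumerate(branch.nodes):
            rows.append((next_id, 2, *p, radius, prev))
            side.append((next_id, branch.branch_id, label, branch.order))
            id_of_node[(branch.branch_id, i)] = next_id
            prev = next_id
            next_id += 1

    for t2 in tree.type2:
        parent_swc = _nearest_node_swc_id(tree, t2.origin_position, id_of_node)
        rows.append((next_id, 2, *t2.tip_position, radius, parent_swc))
        side.append((next_id, -1, "type_II", -1))
        next_id += 1

    nodes = pd.DataFrame(rows, columns=_COLUMNS)
    sidecar = pd.DataFrame(side, columns=["node_id", "branch_id", "branch_type", "order"])
    return nodes, sidecar


def _origin_swc_id(tree: AxonTree, branch, id_of_node) -> int:
    parent = tree.branches[branch.parent_branch]
    pts = parent.nodes
    for i, p in enumerate(pts):
        if p == branch.origin_position:
            return id_of_node[(parent.branch_id, i)]
    if parent.origin_position == branch.origin_position:
        key = (parent.branch_id, -1) if parent.btype == "main" else None
        if key in id_of_node:
            return id_of_node[key]
        return _origin_swc_id(tree, parent, id_of_node)
    raise ValueError("branch origin not found on parent branch")


def _nearest_node_swc_id(tree: AxonTree, p, id_of_node) -> int:
    best, best_id = float("inf"), 1
    for branch in tree.branches:
        for i, q in enumerate(branch.nodes):
            dd = (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 + (p[2] - q[2]) ** 2
            if dd < best:
                best, best_id = dd, id_of_node[(branch.branch_id, i)]
    return best_id


def write_swc(tree: AxonTree, path: str | Path, diameter: float | None = None,
              sidecar: bool = True) -> None:
    """Write a simulated tree to ``path`` (and ``path + '.branches.csv'``)."""
    path = Path(path)
    nodes, side = tree_to_swc_frame(tree, diameter=diameter if diameter else 0.5)
    with open(path, "w") as fh:
        fh.write("# SWC export (axonsim)\n")
        fh.write("# id type x y z radius parent\n")
        for row in nodes.itertuples(index=False):
            fh.write(
                f"{row.id} {row.type} {row.x:.6f} {row.y:.6f} {row.z:.6f} "
                f"{row.radius:.4f} {row.parent}\n"
            )
    if sidecar:
        side.to_csv(path.with_suffix(path.suffix + ".branches.csv"), index=False)


def read_swc(path: str | Path) -> SwcMorphology:
    """Parse an SWC file, validating ids, parent references and acyclicity."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split()
            if len(parts) != 7:
                raise SwcParseError(f"{path}:{lineno}: expected 7 fields, got {len(parts)}")
            try:
                nid = int(parts[0])
                ntype = int(parts[1])
                x, y, z, radius = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SwcParseError(f"{path}:{lineno}: {exc}") from None
            rows.append((lineno, nid, ntype, x, y, z, radius, parent))
    if not rows:
        raise SwcParseError(f"{path}: no nodes found")

    seen: dict[int, int] = {}
    for lineno, nid, *_ in ((r[0], r[1]) for r in rows):
        if nid in seen:
            raise SwcParseError(
                f"{path}:{lineno}: duplicate node id {nid} (first seen line {seen[nid]})"
            )
        seen[nid] = lineno
    ids = set(seen)
    parent_of: dict[int, int] = {}
    for lineno, nid, _, _, _, _, _, parent in rows:
        if parent != -1 and parent not in ids:
            raise SwcParseError(f"{path}:{lineno}: unknown parent id {parent}")
        parent_of[nid] = parent
    # cycle check by walking to a root from every node
    for lineno, nid, *_ in ((r[0], r[1]) for r in rows):
        slow = nid
        visited = set()
        while slow != -1:
            if slow in visited:
                raise SwcParseError(f"{path}:{lineno}: cyclic parent chain at node {nid}")
            visited.add(slow)
            slow = parent_of[slow]

    nodes = pd.DataFrame(
        [(r[1], r[2], r[3], r[4], r[5], r[6], r[7]) for r in rows], columns=_COLUMNS
    )
    sidecar_path = path.with_suffix(path.suffix + ".branches.csv")
    sidecar = pd.read_csv(sidecar_path) if sidecar_path.exists() else None
    return SwcMorphology(nodes=nodes, sidecar=sidecar)
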