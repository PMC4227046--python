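"""Dendritic morphometry from SWC reconstructions.

Metrics follow the standard partial-slice reconstruction conventions: number
of primary dendrites (subtrees attached to the soma), number of branching
points (nodes with two or more children; higher-order nodes count once),
total dendritic length (sum of Euclidean inter-node distances), dendritic
paths (trajectory length from each terminal tip to the soma attachment) and
terminal-segment lengths. Reconstructions come from slices, so dendrites
that plunge deeper than 50 um below the slice surface are excluded before
any metric is computed; the coordinate convention puts the slice surface at
z = 0 with depth positive downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError

#: default slice-plane inclusion limit (um below the surface)
Z_LIMIT = 50.0


@dataclass
class Morphology:
    """Validated SWC node table with derived adjacency."""

    node_id: np.ndarray
    node_type: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    radius: np.ndarray
    parent: np.ndarray
    _children: dict[int, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        ids = set()
        for nid in self.node_id:
            if nid in ids:
                raise ValidationError(f"duplicate SWC node id {nid}")
            ids.add(int(nid))
        self._index = {int(n): i for i, n in enumerate(self.node_id)}
        self._children = {int(n): [] for n in self.node_id}
        roots = 0
        for nid, pid in zip(self.node_id, self.parent):
            if pid == -1:
                roots += 1
                continue
            if int(pid) not in self._index:
                raise ValidationError(f"node {int(nid)} references missing parent {int(pid)}")
            if self._index[int(pid)] >= self._index[int(nid)]:
                raise ValidationError(f"node {int(nid)}: parent {int(pid)} does not precede it")
            self._children[int(pid)].append(int(nid))
        if roots != 1:
            raise ValidationError(f"expected exactly one root node, found {roots}")

    @property
    def root(self) -> int:
        return int(self.node_id[np.flatnonzero(self.parent == -1)[0]])

    def children(self, nid: int) -> list[int]:
        return self._children[int(nid)]

    def position(self, nid: int) -> np.ndarray:
        i = self._index[int(nid)]
        return np.array([self.x[i], self.y[i], self.z[i]])

    def edge_length(self, nid: int) -> float:
        """Euclidean distance from a node to its parent (0 for the root)."""
        i = self._index[int(nid)]
        pid = int(self.parent[i])
        if pid == -1:
            return 0.0
        return float(np.linalg.norm(self.position(nid) - self.position(pid)))

    def subtree(self, nid: int) -> list[int]:
        out, stack = [], [int(nid)]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self._children[n])
        return out

    def node_table(self) -> np.ndarray:
        return np.column_stack([self.node_id, self.node_type, self.x, self.y,
                                self.z, self.radius, self.parent])


@dataclass
class MorphoMetrics:
    """The per-cell dendritic metric vector."""

    n_primary: int
    n_branch_points: int
    total_length: float               # mm
    dendritic_paths: list[float]      # um, one per terminal tip
    terminal_segment_lengths: list[float]  # um
    soma_area: float = np.nan         # um^2, external scalar (never from SWC)


def read_swc(path: str | Path) -> Morphology:
    """Parse a standard 7-column SWC file (um units)."""
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        if len(parts) != 7:
            raise ValidationError(f"{path}:{ln}: expected 7 SWC columns, got {len(parts)}")
        try:
            rows.append((int(parts[0]), int(parts[1]), float(parts[2]),
                         float(parts[3]), float(parts[4]), float(parts[5]),
                         int(parts[6])))
        except ValueError as exc:
            raise ValidationError(f"{path}:{ln}: malformed SWC row: {exc}") from exc
    if not rows:
        raise ValidationError(f"{path}: empty SWC file")
    arr = np.array(rows, dtype=object)
    return Morphology(
        node_id=np.array([r[0] for r in rows]),
        node_type=np.array([r[1] for r in rows]),
        x=np.array([r[2] for r in rows]),
        y=np.array([r[3] for r in rows]),
        z=np.array([r[4] for r in rows]),
        radius=np.array([r[5] for r in rows]),
        parent=np.array([r[6] for r in rows]),
    )


def write_swc(morph: Morphology, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in range(morph.node_id.size):
            fh.write(f"{int(morph.node_id[i])} {int(morph.node_type[i])} "
                     f"{morph.x[i]:.3f} {morph.y[i]:.3f} {morph.z[i]:.3f} "
                     f"{morph.radius[i]:.3f} {int(morph.parent[i])}\n")


def apply_slice_filter(morph: Morphology, z_limit: float = Z_LIMIT) -> Morphology:
    """Drop every radial dendrite plunging deeper than ``z_limit`` (um).

    Inclusion is decided per primary dendrite: if any node of the subtree
    hanging off a soma child exceeds the depth limit, the whole dendrite is
    excluded (only dendrites that stayed in the slice plane are analyzable).
    Never increases any metric.
    """
    root = morph.root
    keep: set[int] = {root}
    for child in morph.children(root):
        subtree = morph.subtree(child)
        depths = [morph.z[morph._index[n]] for n in subtree]
        if max(depths) <= z_limit:
            keep.update(subtree)
    mask = np.array([int(n) in keep for n in morph.node_id])
    return Morphology(
        node_id=morph.node_id[mask], node_type=morph.node_type[mask],
        x=morph.x[mask], y=morph.y[mask], z=morph.z[mask],
        radius=morph.radius[mask], parent=morph.parent[mask],
    )


def compute_metrics(morph: Morphology, soma_area: float = np.nan) -> MorphoMetrics:
    """Table-2 metrics of a (filtered) morphology."""
    root = morph.root
    primaries = morph.children(root)

    # distance from each node to the soma along the tree
    dist: dict[int, float] = {root: 0.0}
    order = [root]
    stack = [root]
    while stack:
        n = stack.pop()
        for c in morph.children(n):
            dist[c] = dist[n] + morph.edge_length(c)
            order.append(c)
            stack.append(c)

    total_um = sum(morph.edge_length(n) for n in order if n != root)
    branch_points = [n for n in order
                     if n != root and len(morph.children(n)) >= 2]
    tips = [n for n in order if n != root and not morph.children(n)]

    paths = [dist[t] for t in tips]
    terminal = []
    for t in tips:
        # walk up to the nearest branch point or the soma
        length = 0.0
        n = t
        while n != root:
            length += morph.edge_length(n)
            i = morph._index[n]
            p = int(morph.parent[i])
            if p == root or len(morph.children(p)) >= 2:
                break
            n = p
        terminal.append(length)

    return MorphoMetrics(
        n_primary=len(primaries),
        n_branch_points=len(branch_points),
        total_length=total_um / 1000.0,
        dendritic_paths=paths,
        terminal_segment_lengths=terminal,
        soma_area=soma_area,
    )
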