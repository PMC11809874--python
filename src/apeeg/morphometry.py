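"""Dendrite morphometry: SWC reading and the dendrite asymmetry index.

A dendritic arbour is reduced to truncated-cone segments, each carrying its
midpoint ``x_i`` (um, soma-relative) and volume ``V_i = pi/3 * L *
(r1^2 + r1 r2 + r2^2)`` (um^3).  The asymmetry index is the Euclidean norm of
the volume-weighted segment centroid sum divided element-wise by the
per-coordinate standard deviation of the midpoints about the soma::

    AI = || (sum_i V_i x_i)  (/)  sqrt( (1/(N-1)) sum_i x_i (*) x_i ) ||

where ``(/)`` and ``(*)`` are element-wise.  A coordinate with zero spread
necessarily has a zero weighted sum as well; that 0/0 is defined as 0.
Neurons whose weighted dendritic centroid sits far from the soma approximate
open-field dipole configurations and produce larger unitary scalp responses,
which is what makes this index predictive of apEEG strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Morphology", "load_morphology", "asymmetry_index"]

_SOMA, _AXON, _BASAL, _APICAL = 1, 2, 3, 4
_DENDRITE_TYPES = (_BASAL, _APICAL)


@dataclass
class Morphology:
    """Cone-segment representation of a dendritic arbour.

    midpoints : (N, 3) segment midpoints in um, relative to the soma origin
    volumes : (N,) truncated-cone volumes in um^3
    """

    midpoints: np.ndarray
    volumes: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.midpoints = np.atleast_2d(np.asarray(self.midpoints, dtype=float))
        self.volumes = np.atleast_1d(np.asarray(self.volumes, dtype=float))
        if self.midpoints.shape != (self.volumes.size, 3):
            raise ValueError("midpoints must be (N, 3) matching volumes (N,)")
        if np.any(self.volumes < 0):
            raise ValueError("segment volumes must be >= 0")

    @property
    def n_segments(self) -> int:
        return self.volumes.size


def cone_volume(r1: float, r2: float, length: float) -> float:
    """Volume of a truncated cone segment, um^3."""
    return np.pi / 3.0 * length * (r1 * r1 + r1 * r2 + r2 * r2)


def load_morphology(path: str | Path) -> Morphology:
    """Read an SWC file into soma-relative dendritic cone segments.

    Standard 7-column SWC (id, type, x, y, z, radius, parent) with ``#``
    comments.  Only dendritic nodes (types 3 and 4) form segments; each node
    with a parent contributes the truncated cone between itself and its
    parent.  The origin is the soma root node; multi-point somas use the
    centroid of their type-1 nodes.
    """
    path = Path(path)
    nodes: dict[int, tuple[int, np.ndarray, float, int]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"{path}:{lineno}: expected 7 SWC columns, got {len(parts)}")
        try:
            nid = int(parts[0])
            ntype = int(parts[1])
            xyz = np.array([float(v) for v in parts[2:5]])
            radius = float(parts[5])
            parent = int(parts[6])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed SWC line: {exc}") from None
        nodes[nid] = (ntype, xyz, radius, parent)

    soma_pts = [xyz for (ntype, xyz, _, _) in nodes.values() if ntype == _SOMA]
    if not soma_pts:
        raise ValueError(f"{path}: no soma node (type 1) found")
    origin = np.mean(soma_pts, axis=0)

    mids, vols = [], []
    for nid, (ntype, xyz, radius, parent) in sorted(nodes.items()):
        if ntype not in _DENDRITE_TYPES or parent == -1 or parent not in nodes:
            continue
        _, pxyz, pradius, _ = nodes[parent]
        length = float(np.linalg.norm(xyz - pxyz))
        if length == 0.0:
            continue
        mids.append((xyz + pxyz) / 2.0 - origin)
        vols.append(cone_volume(radius, pradius, length))
    if not mids:
        raise ValueError(f"{path}: no dendritic segments (SWC types 3/4)")
    return Morphology(np.array(mids), np.array(vols), label=path.stem)


def asymmetry_index(m: Morphology) -> float:
    """Dendrite asymmetry index; non-negative, 0 for point-symmetric arbours.

    Requires at least 2 segments (the 1/(N-1) spread factor is otherwise
    undefined).  Scale-covariant in um^3*um per um of spread; no further
    normalization is applied (any overall rescaling preserves the ranking).
    """
    n = m.n_segments
    if n < 2:
        raise ValueError(f"asymmetry index needs >= 2 segments, got {n}")
    weighted = (m.volumes[:, None] * m.midpoints).sum(axis=0)
    spread = np.sqrt((m.midpoints**2).sum(axis=0) / (n - 1))
    out = np.zeros(3)
    nz = spread > 0
    out[nz] = weighted[nz] / spread[nz]
    if np.any(np.abs(weighted[~nz]) > 0):  # cannot happen geometrically
        raise ValueError("zero spread with non-zero weighted sum")
    return float(np.linalg.norm(out))
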