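"""Source geometry: lead fields, cortical placement, pair-distance density.

Unit conventions (one conversion site, property-tested):
positions in mm, dipole moments in nA*um, potentials in uV.  The default
lead field is the infinite homogeneous medium

    nu_k(x) = 1e-3 * rhat_k / (4 pi sigma |r|^2)    [uV per nA*um]

with ``r`` the source-to-electrode displacement in mm and ``sigma`` the
tissue conductivity in S/m.  Realistic head-model lead fields (e.g. BEM
matrices sampled on a cortical mesh) load from HDF5 behind the same
interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "LeadField",
    "CortexGeometry",
    "PairDensity",
    "lead_field_infinite",
    "place_population",
    "pair_distance_density",
]

#: (nA*um / mm^2) / (S/m) -> uV
_LEADFIELD_SCALE = 1e-3
DEFAULT_CONDUCTIVITY = 0.33  # S/m, brain tissue


def lead_field_infinite(source_mm: np.ndarray, electrode_mm: np.ndarray,
                        conductivity: float = DEFAULT_CONDUCTIVITY) -> np.ndarray:
    """Lead-field vector nu (uV per nA*um) of an infinite homogeneous medium."""
    r = np.asarray(electrode_mm, float) - np.asarray(source_mm, float)
    dist = np.linalg.norm(r, axis=-1, keepdims=True)
    if np.any(dist == 0):
        raise ValueError("source coincides with the electrode")
    rhat = r / dist
    nu = _LEADFIELD_SCALE * rhat / (4.0 * np.pi * conductivity * dist**2)
    return nu


@dataclass
class LeadField:
    """Maps a source position (mm) to the 3-vector nu in uV per nA*um."""

    evaluator: "callable"
    provenance: str = "analytic-infinite-medium"

    def __call__(self, source_mm: np.ndarray) -> np.ndarray:
        return np.asarray(self.evaluator(np.asarray(source_mm, float)), float)

    @classmethod
    def infinite_medium(cls, electrode_mm: np.ndarray,
                        conductivity: float = DEFAULT_CONDUCTIVITY) -> "LeadField":
        electrode = np.asarray(electrode_mm, float)

        def ev(x: np.ndarray) -> np.ndarray:
            return lead_field_infinite(x, electrode, conductivity)

        return cls(ev, provenance="analytic-infinite-medium")

    @classmethod
    def from_file(cls, path: str | Path) -> "LeadField":
        """HDF5 lead field: datasets ``vertices`` (n, 3) mm and ``leadfield``
        (n, 3) uV per nA*um; evaluated by nearest-vertex lookup."""
        import h5py

        with h5py.File(path, "r") as fh:
            vertices = np.asarray(fh["vertices"])
            lf = np.asarray(fh["leadfield"])
        if vertices.shape[0] != lf.shape[0] or lf.shape[1] != 3:
            raise ValueError("leadfield file must have matching (n,3) datasets")

        def ev(x: np.ndarray) -> np.ndarray:
            d = np.linalg.norm(vertices - x, axis=1)
            return lf[int(np.argmin(d))]

        return cls(ev, provenance=f"file:{Path(path).name}")


@dataclass
class CortexGeometry:
    """Triangulated source surface with a uniform areal neuron density.

    ``mesh`` coordinates are mm; ``density`` is neurons per mm^2.
    """

    mesh: trimesh.Trimesh
    density: float = 1.0
    provenance: str = "mesh"

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("neuron density must be >= 0")

    @property
    def area_mm2(self) -> float:
        return float(self.mesh.area)

    @property
    def total_neurons(self) -> float:
        return self.density * self.area_mm2

    @classmethod
    def sphere(cls, radius_mm: float = 70.0, density: float = 1.0,
               subdivisions: int = 4) -> "CortexGeometry":
        mesh = trimesh.creation.icosphere(subdivisions=subdivisions,
                                          radius=radius_mm)
        return cls(mesh, density=density, provenance=f"sphere:{radius_mm}mm")

    @classmethod
    def plane_patch(cls, size_mm: float = 200.0, density: float = 1.0,
                    n_per_side: int = 40) -> "CortexGeometry":
        """Square z=0 patch centered at the origin (flat-geometry fixture)."""
        g = np.linspace(-size_mm / 2, size_mm / 2, n_per_side + 1)
        xx, yy = np.meshgrid(g, g)
        verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
        faces = []
        for i in range(n_per_side):
            for j in range(n_per_side):
                a = i * (n_per_side + 1) + j
                b, c, d = a + 1, a + n_per_side + 1, a + n_per_side + 2
                faces += [[a, b, d], [a, d, c]]
        mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
        return cls(mesh, density=density, provenance=f"plane:{size_mm}mm")

    @classmethod
    def from_ply(cls, path: str | Path, density: float = 1.0) -> "CortexGeometry":
        mesh = trimesh.load(str(path), force="mesh")
        return cls(mesh, density=density, provenance=f"file:{Path(path).name}")

    @classmethod
    def from_vertex_face_csv(cls, vertex_csv: str | Path, face_csv: str | Path,
                             density: float = 1.0) -> "CortexGeometry":
        verts = pd.read_csv(vertex_csv).to_numpy(dtype=float)[:, :3]
        faces = pd.read_csv(face_csv).to_numpy(dtype=int)[:, :3]
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        return cls(mesh, density=density, provenance="vertex-face-csv")

    def sample_surface(self, n: int, rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray]:
        """Area-uniform samples (positions, outward normals)."""
        areas = self.mesh.area_faces
        ok = areas > 0
        n_skipped = int(np.sum(~ok))
        if n_skipped:
            import warnings

            warnings.warn(f"skipped {n_skipped} degenerate faces")
        probs = areas[ok] / areas[ok].sum()
        face_idx = np.flatnonzero(ok)[rng.choice(probs.size, size=n, p=probs)]
        tri = self.mesh.triangles[face_idx]
        # uniform barycentric sampling
        r1 = np.sqrt(rng.random(n))[:, None]
        r2 = rng.random(n)[:, None]
        pts = (1 - r1) * tri[:, 0] + r1 * (1 - r2) * tri[:, 1] + r1 * r2 * tri[:, 2]
        normals = self.mesh.face_normals[face_idx]
        return pts, normals


@dataclass
class PairDensity:
    """dN(r): expected neuron pairs per mm of separation, per source neuron."""

    radii: np.ndarray
    dn: np.ndarray

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, float)
        self.dn = np.asarray(self.dn, float)
        if np.any(self.dn < -1e-9):
            raise ValueError("dN(r) must be >= 0")
        self.dn = np.maximum(self.dn, 0.0)

    def integral(self) -> float:
        return float(np.trapezoid(self.dn, self.radii))

    def gaussian_weighted_integral(self, sigma_x_mm: float) -> float:
        """integral exp(-r^2 / 2 sigma_x^2) dN(r) dr — the expected number of
        correlated partners per neuron under the spatial synchrony kernel."""
        w = np.exp(-self.radii**2 / (2.0 * sigma_x_mm**2))
        return float(np.trapezoid(w * self.dn, self.radii))

    def sample_r(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Displacement distances distributed proportionally to dN(r)."""
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (self.dn[1:] + self.dn[:-1]) * np.diff(self.radii))])
        cdf /= cdf[-1]
        u = rng.random(n)
        return np.interp(u, cdf, self.radii)


def _orthonormal_frames(normals: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Right-handed frames (columns x, y, z) with z = normal, random azimuth."""
    z = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    helper = np.tile([1.0, 0.0, 0.0], (len(z), 1))
    helper[np.abs(z[:, 0]) > 0.9] = [0.0, 1.0, 0.0]
    x = np.cross(helper, z)
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    y = np.cross(z, x)
    phi = rng.uniform(0, 2 * np.pi, len(z))
    c, s = np.cos(phi)[:, None], np.sin(phi)[:, None]
    xr = c * x + s * y
    yr = -s * x + c * y
    return np.stack([xr, yr, z], axis=-1)


def place_population(geometry: CortexGeometry, population: pd.DataFrame,
                     n_neurons: int, seed: int = 0) -> pd.DataFrame:
    """Place neurons on the cortex: class sampled by abundance, position
    area-uniform, apical axis (frame z-column) along the outward normal.

    Returns a DataFrame with columns ``name``, ``position`` (3,) mm and
    ``frame`` (3, 3) local-to-head rotation, one row per neuron.
    """
    if geometry.area_mm2 <= 0:
        raise ValueError("geometry has no surface area")
    rng = np.random.default_rng(seed)
    weights = population["abundance"].to_numpy(float)
    weights = weights / weights.sum()
    classes = rng.choice(population["name"].to_numpy(), size=n_neurons, p=weights)
    positions, normals = geometry.sample_surface(n_neurons, rng)
    frames = _orthonormal_frames(normals, rng)
    return pd.DataFrame({
        "name": classes,
        "position": list(positions),
        "frame": list(frames),
    })


def _surface_point_cloud(geometry: CortexGeometry, max_edge_mm: float
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Refine the mesh and return (centroids, areas) for area integration."""
    verts, faces = trimesh.remesh.subdivide_to_size(
        geometry.mesh.vertices, geometry.mesh.faces, max_edge=max_edge_mm)
    m = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    return m.triangles_center, m.area_faces


def pair_distance_density(geometry: CortexGeometry, radii_mm: np.ndarray,
                          n_centers: int = 100, seed: int = 0,
                          centers: np.ndarray | None = None,
                          max_edge_mm: float | None = None) -> PairDensity:
    """Estimate dN(r) by differentiating the Euclidean-ball surface count.

    For each center the cortical surface area inside a Euclidean ball of
    radius r is accumulated from a refined triangle point cloud; the neuron
    count is ``density * area`` and dN(r) is its central-difference
    derivative averaged over centers.  ``centers`` may be supplied explicitly
    (e.g. to stay clear of an open boundary on a flat patch fixture).
    """
    radii = np.asarray(radii_mm, float)
    if radii.size < 3 or np.any(np.diff(radii) <= 0) or radii[0] < 0:
        raise ValueError("radii must be an increasing grid starting at >= 0")
    rng = np.random.default_rng(seed)
    if centers is None:
        centers, _ = geometry.sample_surface(n_centers, rng)
    else:
        centers = np.atleast_2d(np.asarray(centers, float))
    if max_edge_mm is None:
        # element diameter well below the radii of interest; centroid binning
        # is unbiased to first order so ~1/10 of the max radius suffices
        max_edge_mm = float(np.clip(radii[-1] / 25.0, 0.25, 2.0))
    points, areas = _surface_point_cloud(geometry, max_edge_mm)
    counts = np.zeros((len(centers), radii.size))
    for i, c in enumerate(centers):
        d = np.linalg.norm(points - c, axis=1)
        order = np.argsort(d)
        cum_area = np.concatenate([[0.0], np.cumsum(areas[order])])
        idx = np.searchsorted(d[order], radii, side="right")
        counts[i] = geometry.density * cum_area[idx]
    mean_counts = counts.mean(axis=0)
    dn = np.gradient(mean_counts, radii)
    if radii[0] == 0:
        dn[0] = 0.0
    return PairDensity(radii, dn)
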