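"""Spherical head surrogate: shells, cortical mesh, parcellation, electrodes.

The head is modeled as concentric spherical shells with isotropic
conductivities.  The cortical source surface is a recursively
subdivided icosahedron with an optional smooth radial perturbation (so
triangle normals are not all exactly radial, as on a folded cortex),
carrying one current dipole per triangle at its barycenter, oriented
along the outward normal with moment proportional to triangle area.
Triangles are grouped into spatially contiguous macro-regions (66 by
default, 33 per hemisphere), each later driven by one neuronal
population.

Coordinate convention: right-handed, +z through the vertex (Cz),
+x toward the right ear, +y toward the nasion; all indices 0-based;
lengths in meters.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ShellModel",
    "CorticalMesh",
    "Parcellation",
    "ElectrodeLayout",
    "DipoleLayer",
    "InvalidGeometryError",
    "default_field_shells",
    "default_eeg_shells",
    "generate_cortical_mesh",
    "parcellate",
    "standard_electrode_positions",
    "dipole_layer",
]


class InvalidGeometryError(ValueError):
    """Raised for geometrically impossible inputs."""


# ---------------------------------------------------------------------------
# shells
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShellModel:
    """Concentric spherical shells.

    ``radii`` are outer radii in meters, innermost first and strictly
    increasing; ``conductivities`` are the isotropic conductivities
    (S/m) of the corresponding shells.
    """

    radii: tuple[float, ...]
    conductivities: tuple[float, ...]

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii)
        conds = tuple(float(c) for c in self.conductivities)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "conductivities", conds)
        if len(radii) != len(conds):
            raise InvalidGeometryError("radii and conductivities must have equal length")
        if len(radii) == 0:
            raise InvalidGeometryError("need at least one shell")
        if any(r <= 0 for r in radii) or any(b <= a for a, b in zip(radii, radii[1:])):
            raise InvalidGeometryError("radii must be positive and strictly increasing")
        if any(c <= 0 for c in conds):
            raise InvalidGeometryError("conductivities must be positive")

    @property
    def outer_radius(self) -> float:
        return self.radii[-1]

    def shell_index(self, r: float) -> int:
        """Index of the shell containing radius ``r`` (boundary points
        belong to the inner shell)."""
        for j, rj in enumerate(self.radii):
            if r <= rj:
                return j
        raise InvalidGeometryError(f"radius {r} outside the outermost shell {self.radii[-1]}")


def default_field_shells() -> ShellModel:
    """4-shell head for the stimulation-field solve.

    Brain (0.33 S/m) to 0.079 m, CSF (1.79 S/m) to 0.082 m, skull
    (0.008 S/m) to 0.087 m, scalp (0.33 S/m) to 0.092 m.
    """
    return ShellModel(radii=(0.079, 0.082, 0.087, 0.092),
                      conductivities=(0.33, 1.79, 0.008, 0.33))


def default_eeg_shells() -> ShellModel:
    """3-shell head for the EEG forward model: brain/skull/scalp at
    0.33, 0.008, 0.33 S/m with radii 0.082, 0.087, 0.092 m (no CSF
    layer, mirroring conventional 3-layer EEG head models)."""
    return ShellModel(radii=(0.082, 0.087, 0.092),
                      conductivities=(0.33, 0.008, 0.33))


# ---------------------------------------------------------------------------
# cortical mesh
# ---------------------------------------------------------------------------


@dataclass
class CorticalMesh:
    """Closed triangulated source surface.

    ``vertices`` (V, 3) and ``triangles`` (F, 3, int) define the
    surface; ``barycenters``, unit outward ``normals`` and ``areas``
    are per-triangle.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    barycenters: np.ndarray = field(init=False)
    normals: np.ndarray = field(init=False)
    areas: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        tri = self.vertices[self.triangles]
        self.barycenters = tri.mean(axis=1)
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(cross, axis=1)
        if np.any(norm == 0):
            raise InvalidGeometryError("degenerate (zero-area) triangle")
        self.normals = cross / norm[:, None]
        self.areas = 0.5 * norm

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def edge_counts(self) -> dict[tuple[int, int], int]:
        counts: dict[tuple[int, int], int] = {}
        for a, b, c in self.triangles:
            for e in ((a, b), (b, c), (c, a)):
                key = (min(e), max(e))
                counts[key] = counts.get(key, 0) + 1
        return counts

    def is_closed(self) -> bool:
        """Every edge shared by exactly two triangles."""
        return all(v == 2 for v in self.edge_counts().values())

    def euler_characteristic(self) -> int:
        n_e = len(self.edge_counts())
        return len(self.vertices) - n_e + len(self.triangles)

    def signed_volume(self) -> float:
        tri = self.vertices[self.triangles]
        return float(np.einsum("ij,ij->", np.cross(tri[:, 0], tri[:, 1]), tri[:, 2]) / 6.0)

    def triangle_adjacency(self) -> list[list[int]]:
        """Triangle indices sharing an edge with each triangle."""
        edge_faces: dict[tuple[int, int], list[int]] = {}
        for f, (a, b, c) in enumerate(self.triangles):
            for e in ((a, b), (b, c), (c, a)):
                edge_faces.setdefault((min(e), max(e)), []).append(f)
        adj: list[list[int]] = [[] for _ in range(self.n_triangles)]
        for faces in edge_faces.values():
            for f in faces:
                for g in faces:
                    if g != f:
                        adj[f].append(g)
        return adj

    # --- I/O -------------------------------------------------------------

    def write_off(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{len(self.vertices)} {len(self.triangles)} 0\n")
            for v in self.vertices:
                fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for t in self.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")

    def write_ply(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(self.vertices)}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write(f"element face {len(self.triangles)}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for v in self.vertices:
                fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for t in self.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")

    @classmethod
    def read_off(cls, path) -> "CorticalMesh":
        with open(path) as fh:
            tokens = fh.read().split()
        if tokens[0] != "OFF":
            raise InvalidGeometryError("not an OFF file")
        nv, nf = int(tokens[1]), int(tokens[2])
        pos = 4
        verts = np.array(tokens[pos:pos + 3 * nv], dtype=float).reshape(nv, 3)
        pos += 3 * nv
        faces = []
        for _ in range(nf):
            k = int(tokens[pos])
            if k != 3:
                raise InvalidGeometryError("only triangular faces supported")
            faces.append([int(t) for t in tokens[pos + 1:pos + 4]])
            pos += 1 + k
        return cls(vertices=verts, triangles=np.array(faces, dtype=int))


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=int)
    return verts, faces


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One 4-to-1 icosphere subdivision, reprojecting onto the unit sphere."""
    cache: dict[tuple[int, int], int] = {}
    verts = list(verts)

    def midpoint(a: int, b: int) -> int:
        key = (min(a, b), max(a, b))
        if key not in cache:
            m = verts[a] + verts[b]
            m = m / np.linalg.norm(m)
            cache[key] = len(verts)
            verts.append(m)
        return cache[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces.extend([[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]])
    return np.array(verts), np.array(new_faces, dtype=int)


def generate_cortical_mesh(subdivision_level: int, cortical_radius: float,
                           perturbation_amplitude: float = 0.0,
                           seed: int = 0, n_bumps: int = 12,
                           bump_width: float = 0.4) -> CorticalMesh:
    """Closed cortical source mesh: perturbed icosphere.

    A unit icosahedron is subdivided ``subdivision_level`` times
    (F = 20 * 4^level triangles) and scaled to ``cortical_radius``.  A
    smooth random radial perturbation — a seeded sum of ``n_bumps``
    Gaussian bumps of angular width ``bump_width`` (radians), peak
    amplitude ``perturbation_amplitude`` (m) — makes the surface gently
    non-spherical so that triangle normals deviate from the radial
    direction, a stand-in for cortical curvature.

    With ``perturbation_amplitude=0`` the mesh is an exact icosphere.
    """
    if cortical_radius <= 0:
        raise InvalidGeometryError("cortical_radius must be positive")
    if subdivision_level < 1:
        raise InvalidGeometryError("subdivision_level must be >= 1")
    if not (0 <= perturbation_amplitude < 0.2 * cortical_radius):
        raise InvalidGeometryError(
            "perturbation_amplitude must lie in [0, 0.2 * cortical_radius)")
    verts, faces = _icosahedron()
    for _ in range(subdivision_level):
        verts, faces = _subdivide(verts, faces)

    radius = np.full(len(verts), float(cortical_radius))
    if perturbation_amplitude > 0:
        rng = np.random.default_rng(seed)
        centers = rng.normal(size=(n_bumps, 3))
        centers /= np.linalg.norm(centers, axis=1)[:, None]
        amps = rng.normal(size=n_bumps)
        ang = np.arccos(np.clip(verts @ centers.T, -1.0, 1.0))  # (V, n_bumps)
        rho = (np.exp(-0.5 * (ang / bump_width) ** 2) * amps).sum(axis=1)
        rho /= max(np.abs(rho).max(), 1e-300)
        radius = cortical_radius + perturbation_amplitude * rho
    return CorticalMesh(vertices=verts * radius[:, None], triangles=faces)


# ---------------------------------------------------------------------------
# parcellation
# ---------------------------------------------------------------------------


@dataclass
class Parcellation:
    """Per-triangle macro-region labels in ``[0, n_regions)``."""

    labels: np.ndarray
    n_regions: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if present.min() < 0 or present.max() >= self.n_regions:
            raise InvalidGeometryError("labels outside [0, n_regions)")
        if len(present) != self.n_regions:
            missing = sorted(set(range(self.n_regions)) - set(present.tolist()))
            raise InvalidGeometryError(f"empty regions: {missing}")

    def members(self, region: int) -> np.ndarray:
        return np.flatnonzero(self.labels == region)

    def write_text(self, path) -> None:
        with open(path, "w") as fh:
            for i, lab in enumerate(self.labels):
                fh.write(f"{i}\t{lab}\n")

    @classmethod
    def read_text(cls, path, n_regions: int | None = None) -> "Parcellation":
        data = np.loadtxt(path, dtype=int, ndmin=2)
        order = np.argsort(data[:, 0])
        labels = data[order, 1]
        if not np.array_equal(data[order, 0], np.arange(len(labels))):
            raise InvalidGeometryError("triangle indices must be 0-based and contiguous")
        return cls(labels=labels, n_regions=n_regions or int(labels.max()) + 1)


def _kmeans_directions(points: np.ndarray, k: int, rng: np.random.Generator,
                       n_iter: int = 60) -> np.ndarray:
    """Seeded spherical k-means on unit vectors; returns labels."""
    # k-means++ style init on the sphere (cosine distance)
    centers = np.empty((k, 3))
    centers[0] = points[rng.integers(len(points))]
    d2 = 1.0 - points @ centers[0]
    for j in range(1, k):
        probs = np.maximum(d2, 1e-12)
        centers[j] = points[rng.choice(len(points), p=probs / probs.sum())]
        d2 = np.minimum(d2, 1.0 - points @ centers[j])
    labels = np.argmax(points @ centers.T, axis=1)
    for _ in range(n_iter):
        for j in range(k):
            sel = labels == j
            if not np.any(sel):
                # re-seed an empty cluster at the worst-assigned point
                worst = np.argmin(np.max(points @ centers.T, axis=1))
                centers[j] = points[worst]
            else:
                m = points[sel].sum(axis=0)
                centers[j] = m / np.linalg.norm(m)
        new = np.argmax(points @ centers.T, axis=1)
        if np.array_equal(new, labels):
            break
        labels = new
    return labels


def _repair_contiguity(labels: np.ndarray, adjacency: list[list[int]],
                       allowed: np.ndarray) -> np.ndarray:
    """Reassign minority connected components to neighboring regions.

    ``allowed`` restricts moves to triangles in the same pool (e.g. the
    same hemisphere): triangle i may only take labels from triangles j
    with allowed[i] == allowed[j].
    """
    labels = labels.copy()
    for _ in range(100):
        changed = False
        for region in np.unique(labels):
            members = np.flatnonzero(labels == region)
            comps = _components(members, adjacency, labels, region)
            if len(comps) <= 1:
                continue
            comps.sort(key=len, reverse=True)
            for comp in comps[1:]:
                frontier = list(comp)
                # peel: assign each stray triangle to an adjacent foreign label
                for _ in range(len(comp) * 4):
                    remaining = []
                    for f in frontier:
                        votes = [labels[g] for g in adjacency[f]
                                 if labels[g] != region and allowed[g] == allowed[f]]
                        if votes:
                            labels[f] = max(set(votes), key=votes.count)
                            changed = True
                        else:
                            remaining.append(f)
                    if not remaining:
                        break
                    frontier = remaining
        if not changed:
            return labels
    return labels


def _components(members: np.ndarray, adjacency: list[list[int]],
                labels: np.ndarray, region: int) -> list[list[int]]:
    member_set = set(members.tolist())
    seen: set[int] = set()
    comps = []
    for start in members:
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            f = stack.pop()
            comp.append(f)
            for g in adjacency[f]:
                if g in member_set and g not in seen:
                    seen.add(g)
                    stack.append(g)
        comps.append(comp)
    return comps


def parcellate(mesh: CorticalMesh, n_regions: int, seed: int = 0,
               hemisphere_symmetry: bool | None = None) -> Parcellation:
    """Group triangles into spatially contiguous macro-regions.

    Seeded spherical k-means on barycenter directions followed by a
    contiguity repair that merges stray connected components into
    adjacent regions.  With hemisphere symmetry (default whenever
    ``n_regions`` is even) the right hemisphere (barycenter x >= 0) is
    clustered into ``n_regions/2`` regions and the centroids mirrored
    to the left, yielding an equal split such as 33 + 33.
    Deterministic for a fixed seed.
    """
    if n_regions < 1:
        raise InvalidGeometryError("n_regions must be >= 1")
    if n_regions > mesh.n_triangles:
        raise InvalidGeometryError("more regions than triangles")
    if hemisphere_symmetry is None:
        hemisphere_symmetry = n_regions % 2 == 0 and n_regions > 1
    if hemisphere_symmetry and n_regions % 2 != 0:
        raise InvalidGeometryError("hemisphere symmetry requires an even n_regions")

    dirs = mesh.barycenters / np.linalg.norm(mesh.barycenters, axis=1)[:, None]
    rng = np.random.default_rng(seed)
    adjacency = mesh.triangle_adjacency()

    if not hemisphere_symmetry:
        labels = _kmeans_directions(dirs, n_regions, rng)
        labels = _repair_contiguity(labels, adjacency, np.zeros(len(labels), dtype=int))
        return Parcellation(labels=labels, n_regions=n_regions)

    half = n_regions // 2
    right = dirs[:, 0] >= 0.0
    labels = np.empty(mesh.n_triangles, dtype=int)
    right_labels = _kmeans_directions(dirs[right], half, rng)
    labels[right] = right_labels
    # mirror right-hemisphere centroids onto the left
    centers = np.empty((half, 3))
    for j in range(half):
        m = dirs[right][right_labels == j].sum(axis=0)
        centers[j] = m / np.linalg.norm(m)
    mirrored = centers * np.array([-1.0, 1.0, 1.0])
    labels[~right] = half + np.argmax(dirs[~right] @ mirrored.T, axis=1)
    hemi = right.astype(int)
    labels = _repair_contiguity(labels, adjacency, hemi)
    return Parcellation(labels=labels, n_regions=n_regions)


# ---------------------------------------------------------------------------
# electrodes
# ---------------------------------------------------------------------------


def _slerp(a: np.ndarray, b: np.ndarray, frac: float) -> np.ndarray:
    ang = math.acos(float(np.clip(np.dot(a, b), -1.0, 1.0)))
    if ang < 1e-12:
        return a
    return (math.sin((1 - frac) * ang) * a + math.sin(frac * ang) * b) / math.sin(ang)


def _ang(inclination_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector from inclination (from +z vertex) and azimuth
    (from +y nasion toward +x right ear)."""
    inc = math.radians(inclination_deg)
    az = math.radians(azimuth_deg)
    return np.array([math.sin(inc) * math.sin(az),
                     math.sin(inc) * math.cos(az),
                     math.cos(inc)])


def _build_unit_positions() -> dict[str, np.ndarray]:
    """Idealized 10-20 / 10-10 positions on the unit sphere.

    Nasion, inion and the preauricular points sit on the equator.  The
    outer 10% ring (Fp1..O2 through Fpz/Oz) lies at 72 deg inclination;
    midline electrodes follow the nasion-inion arc in 10% (18 deg)
    steps; intermediate electrodes (F3, C3, P3, PO3, ...) are great-
    circle midpoints, following the standard arc construction.
    """
    P: dict[str, np.ndarray] = {}
    P["Cz"] = _ang(0, 0)
    # midline, front (azimuth 0) and back (azimuth 180)
    P["Fpz"] = _ang(72, 0); P["AFz"] = _ang(54, 0); P["Fz"] = _ang(36, 0)
    P["FCz"] = _ang(18, 0); P["CPz"] = _ang(18, 180); P["Pz"] = _ang(36, 180)
    P["POz"] = _ang(54, 180); P["Oz"] = _ang(72, 180)
    # outer ring at 72 deg inclination, 18 deg azimuthal steps
    ring = {"Fp1": -18, "Fp2": 18, "AF7": -36, "AF8": 36, "F7": -54, "F8": 54,
            "FT7": -72, "FT8": 72, "T3": -90, "T4": 90, "TP7": -108, "TP8": 108,
            "T5": -126, "T6": 126, "PO7": -144, "PO8": 144, "O1": -162, "O2": 162}
    for name, az in ring.items():
        P[name] = _ang(72, az)
    # inferior 10-10 ring (equator): PO9/PO10 below PO7/PO8
    P["PO9"] = _ang(90, -144); P["PO10"] = _ang(90, 144)
    P["TP9"] = _ang(90, -108); P["TP10"] = _ang(90, 108)
    # intermediate positions: arc midpoints
    P["F3"] = _slerp(P["Fz"], P["F7"], 0.5); P["F4"] = _slerp(P["Fz"], P["F8"], 0.5)
    P["C3"] = _slerp(P["Cz"], P["T3"], 0.5); P["C4"] = _slerp(P["Cz"], P["T4"], 0.5)
    P["P3"] = _slerp(P["Pz"], P["T5"], 0.5); P["P4"] = _slerp(P["Pz"], P["T6"], 0.5)
    P["PO3"] = _slerp(P["POz"], P["PO7"], 0.5); P["PO4"] = _slerp(P["POz"], P["PO8"], 0.5)
    P["FC3"] = _slerp(P["FCz"], P["FT7"], 0.5); P["FC4"] = _slerp(P["FCz"], P["FT8"], 0.5)
    P["CP3"] = _slerp(P["CPz"], P["TP7"], 0.5); P["CP4"] = _slerp(P["CPz"], P["TP8"], 0.5)
    return P


_UNIT_POSITIONS = _build_unit_positions()

#: The classic 19-electrode 10-20 recording set.
MONTAGE_1020 = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
                "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2")

#: 10-10 extension used for stimulation targeting and posterior analysis.
MONTAGE_1010 = MONTAGE_1020 + ("Fpz", "AFz", "AF7", "AF8", "FT7", "FT8", "FCz",
                               "FC3", "FC4", "TP7", "TP8", "TP9", "TP10", "CPz",
                               "CP3", "CP4", "POz", "PO3", "PO4", "PO7", "PO8",
                               "PO9", "PO10", "Oz")


@dataclass
class ElectrodeLayout:
    """Named electrode positions on the scalp sphere."""

    names: tuple[str, ...]
    positions: np.ndarray  # (n, 3), meters

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.names) != len(self.positions):
            raise InvalidGeometryError("names/positions length mismatch")
        if len(set(self.names)) != len(self.names):
            raise InvalidGeometryError("duplicate electrode names")

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown electrode {name!r}") from None

    def position(self, name: str) -> np.ndarray:
        return self.positions[self.index(name)]

    def subset(self, names) -> "ElectrodeLayout":
        idx = [self.index(n) for n in names]
        return ElectrodeLayout(names=tuple(names), positions=self.positions[idx])

    def write_text(self, path) -> None:
        with open(path, "w") as fh:
            for name, p in zip(self.names, self.positions):
                fh.write(f"{name}\t{p[0]:.9g}\t{p[1]:.9g}\t{p[2]:.9g}\n")

    @classmethod
    def read_text(cls, path) -> "ElectrodeLayout":
        names, pos = [], []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                tok = line.split()
                names.append(tok[0])
                pos.append([float(x) for x in tok[1:4]])
        return cls(names=tuple(names), positions=np.array(pos))


def standard_electrode_positions(montage: str, scalp_radius: float) -> ElectrodeLayout:
    """Standard electrode layout mapped onto the scalp sphere.

    ``montage`` is ``"10-20"`` (the classic 19-electrode set) or
    ``"10-10"`` (a superset adding the midline and parieto-occipital
    positions, including PO9/PO10 used for pad placement).
    """
    if scalp_radius <= 0:
        raise InvalidGeometryError("scalp_radius must be positive")
    key = montage.replace("_", "-").lower()
    if key in ("10-20", "1020"):
        names = MONTAGE_1020
    elif key in ("10-10", "1010"):
        names = MONTAGE_1010
    else:
        raise ValueError(f"unknown montage {montage!r}; use '10-20' or '10-10'")
    positions = np.array([_UNIT_POSITIONS[n] for n in names]) * scalp_radius
    return ElectrodeLayout(names=names, positions=positions)


# ---------------------------------------------------------------------------
# dipole layer
# ---------------------------------------------------------------------------


@dataclass
class DipoleLayer:
    """One current dipole per mesh triangle.

    Dipoles sit at triangle barycenters, point along the outward
    normals, and have moments (A*m) proportional to triangle area.
    """

    positions: np.ndarray
    orientations: np.ndarray
    moments: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        self.moments = np.asarray(self.moments, dtype=float)
        if not (len(self.positions) == len(self.orientations) == len(self.moments)):
            raise InvalidGeometryError("dipole array length mismatch")
        if np.any(self.moments <= 0):
            raise InvalidGeometryError("dipole moments must be positive")

    def __len__(self) -> int:
        return len(self.moments)


def dipole_layer(mesh: CorticalMesh, moment_density: float) -> DipoleLayer:
    """Build the cortical dipole layer.

    ``moment_density`` is the dipole moment per unit area (A*m/m^2);
    each triangle carries ``moment_density * area``.
    """
    if moment_density <= 0:
        raise InvalidGeometryError("moment_density must be positive")
    return DipoleLayer(positions=mesh.barycenters.copy(),
                       orientations=mesh.normals.copy(),
                       moments=moment_density * mesh.areas)
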