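"""PCA shape space for "digital embryo" category stimuli.

A population of novel, naturalistic 3-D blob meshes with shared vertex
correspondence is summarised by principal components analysis of the flattened
vertex coordinates.  Each embryo is then a point of PC loadings; a stimulus
category is a 2-D Gaussian over two chosen PC axes (PCs 2 and 3 by default,
which carry subtler shape variation than PC 1).  Category difficulty is
controlled through the separation of the two category Gaussians, quantified
either as the between/within F-ratio or as the equal-covariance ideal-observer
d' (the Mahalanobis distance between the category means).

The module also renders trial screens: a centre query embryo flanked by one
labelled sample from each category, flat-shaded orthographic projections on a
neutral grey canvas, with each embryo's position jittered by up to a
configurable visual angle (0.8 deg by default) to discourage pixelwise
comparison strategies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from numpy.random import Generator, default_rng
from PIL import Image, ImageDraw
from scipy.spatial import ConvexHull


class ShapeError(ValueError):
    """Mesh populations with inconsistent vertex counts / correspondence."""


class LayoutError(ValueError):
    """An embryo projection does not fit on the configured canvas."""


class InfiniteSeparationError(ZeroDivisionError):
    """Between-category scatter is nonzero while within-category scatter is zero."""


# --------------------------------------------------------------------------- #
# meshes

@dataclass(frozen=True)
class EmbryoMesh:
    """Triangle mesh with fixed vertex correspondence across a population."""

    vertices: np.ndarray  # (V, 3) float
    faces: np.ndarray     # (F, 3) int, indices into vertices

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ShapeError(f"vertices must be (V, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ShapeError(f"faces must be (F, 3), got {f.shape}")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ShapeError("face index out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def flatten(self) -> np.ndarray:
        """Row vector of concatenated xyz coordinates (length 3*V)."""
        return self.vertices.reshape(-1)

    def is_connected(self) -> bool:
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        i = self.faces[:, [0, 1, 2]].reshape(-1)
        j = self.faces[:, [1, 2, 0]].reshape(-1)
        adj = coo_matrix((np.ones_like(i), (i, j)), shape=(self.n_vertices,) * 2)
        n_comp, _ = connected_components(adj, directed=False)
        return n_comp == 1

    def export_obj(self, path) -> None:
        """Write Wavefront OBJ preserving vertex order (correspondence matters)."""
        import trimesh

        mesh = trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)
        mesh.export(path, file_type="obj")


@lru_cache(maxsize=8)
def _sphere_topology(n_vertices: int) -> tuple[np.ndarray, np.ndarray]:
    """Fibonacci-sphere points (exactly n_vertices) with convex-hull triangulation.

    Every point of a Fibonacci sphere lies on the hull, so the triangulation
    uses all vertices and is a closed connected surface.  Faces are oriented
    outward.  Cached: the topology is shared by the whole population.
    """
    k = np.arange(n_vertices, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n_vertices
    theta = 2.0 * np.pi * k / golden
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    hull = ConvexHull(pts)
    faces = hull.simplices.copy()
    # orient all faces outward (hull centroid is the origin here)
    tri = pts[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    centroids = tri.mean(axis=1)
    flip = np.einsum("ij,ij->i", normals, centroids) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    pts.setflags(write=False)
    faces.setflags(write=False)
    return pts, faces


def generate_base_population(
    n_embryos: int,
    n_vertices: int,
    seed: int,
    n_bumps: int = 10,
) -> list[EmbryoMesh]:
    """Procedurally generate a random embryo population with shared topology.

    Each embryo is a unit sphere (Fibonacci point set triangulated by its
    convex hull, so the vertex count is hit exactly) radially perturbed by a
    seeded sum of ``n_bumps`` smooth Gaussian bumps with random centres, widths
    and amplitudes.  This yields naturalistic blob-like variation while keeping
    a fixed vertex correspondence across the population, which is what the
    downstream PCA requires.  Deterministic for a fixed seed.
    """
    if n_embryos < 1:
        raise ValueError(f"n_embryos must be >= 1, got {n_embryos}")
    if n_vertices < 12:
        raise ValueError(f"n_vertices must be >= 12, got {n_vertices}")
    base, faces = _sphere_topology(n_vertices)
    rng = default_rng(seed)
    population = []
    for _ in range(n_embryos):
        centers = rng.normal(size=(n_bumps, 3))
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        widths = rng.uniform(0.25, 0.8, size=n_bumps)       # radians
        amps = rng.normal(0.0, 0.06, size=n_bumps)          # radial units
        ang = np.arccos(np.clip(base @ centers.T, -1.0, 1.0))  # (V, n_bumps)
        radius = 1.0 + (amps * np.exp(-0.5 * (ang / widths) ** 2)).sum(axis=1)
        radius = np.maximum(radius, 0.2)
        population.append(EmbryoMesh(base * radius[:, None], faces))
    return population


# --------------------------------------------------------------------------- #
# PCA shape space

@dataclass(frozen=True)
class ShapeSpace:
    """Mean shape plus an ordered orthonormal PC basis over a mesh population.

    ``basis`` rows are unit-norm eigenvectors of the covariance of the
    flattened (n_embryos x 3V) coordinate matrix, ordered by non-increasing
    eigenvalue.  PC indices are 1-based throughout the package so that "PCs 2
    and 3" mean the components with the second and third largest eigenvalues.
    """

    mean_shape: np.ndarray   # (3V,)
    basis: np.ndarray        # (k, 3V), orthonormal rows
    eigenvalues: np.ndarray  # (k,), non-increasing, >= 0
    n_population: int
    faces: np.ndarray        # shared population topology

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_vertices(self) -> int:
        return len(self.mean_shape) // 3

    def loadings(self, mesh: EmbryoMesh) -> np.ndarray:
        """Project a mesh onto the basis; returns the full loading vector."""
        if mesh.n_vertices != self.n_vertices:
            raise ShapeError("mesh vertex count does not match the shape space")
        return self.basis @ (mesh.flatten() - self.mean_shape)


def build_shape_space(population: Sequence[EmbryoMesh]) -> ShapeSpace:
    """PCA of the flattened vertex coordinates of a corresponding population.

    Conventions: centred on the mean shape; components ordered by descending
    explained variance; at most min(n-1, 3V) components retained; each
    component's sign is fixed so that its largest-magnitude entry is positive
    (deterministic across platforms).
    """
    if len(population) < 2:
        raise ValueError("need at least 2 meshes to build a shape space")
    n_vertices = population[0].n_vertices
    for m in population:
        if m.n_vertices != n_vertices:
            raise ShapeError("all meshes must share a vertex count")
    x = np.stack([m.flatten() for m in population])  # (n, 3V)
    n = len(population)
    mean = x.mean(axis=0)
    xc = x - mean
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(n - 1, x.shape[1])
    basis = vt[:k].copy()
    eigenvalues = (s[:k] ** 2) / (n - 1)
    # deterministic sign: largest |entry| of each component is positive
    idx = np.argmax(np.abs(basis), axis=1)
    signs = np.sign(basis[np.arange(k), idx])
    signs[signs == 0] = 1.0
    basis *= signs[:, None]
    return ShapeSpace(
        mean_shape=mean,
        basis=basis,
        eigenvalues=eigenvalues,
        n_population=n,
        faces=population[0].faces,
    )


def reconstruct_mesh(space: ShapeSpace, pc_coords: Mapping[int, float]) -> EmbryoMesh:
    """Mean shape plus a sparse combination of basis vectors.

    ``pc_coords`` maps 1-based PC indices to loadings; unspecified loadings
    are zero.  Faces are copied from the population topology.
    """
    vec = space.mean_shape.copy()
    for index, loading in pc_coords.items():
        if not 1 <= index <= space.n_components:
            raise ValueError(
                f"PC index {index} out of range 1..{space.n_components}"
            )
        vec += loading * space.basis[index - 1]
    return EmbryoMesh(vec.reshape(-1, 3), space.faces)


# --------------------------------------------------------------------------- #
# Gaussian categories on a pair of PC axes

@dataclass(frozen=True)
class CategorySpec:
    """A 2-D Gaussian over two PC loadings defining one stimulus category."""

    label: str
    mean: np.ndarray                  # (2,)
    covariance: np.ndarray            # (2, 2) symmetric PSD
    axes: tuple[int, int] = (2, 3)    # 1-based PC indices

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float).reshape(2)
        cov = np.asarray(self.covariance, dtype=float).reshape(2, 2)
        if self.axes[0] == self.axes[1]:
            raise ValueError("category axes must be distinct")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ValueError("covariance must be positive semi-definite")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        object.__setattr__(self, "axes", tuple(int(a) for a in self.axes))


@dataclass(frozen=True)
class CategoryPair:
    """Two category Gaussians sharing axes, with their separation F-ratio."""

    spec_p: CategorySpec
    spec_q: CategorySpec
    f_ratio: float

    def __post_init__(self) -> None:
        if self.spec_p.axes != self.spec_q.axes:
            raise ValueError("both category specs must share the same PC axes")
        if self.spec_p.label == self.spec_q.label:
            raise ValueError("category labels must differ")

    @property
    def axes(self) -> tuple[int, int]:
        return self.spec_p.axes

    @property
    def labels(self) -> tuple[str, str]:
        return self.spec_p.label, self.spec_q.label

    def spec(self, label: str) -> CategorySpec:
        if label == self.spec_p.label:
            return self.spec_p
        if label == self.spec_q.label:
            return self.spec_q
        raise ValueError(f"unknown category label {label!r}")

    def to_manifest(self, seed: int | None = None) -> dict:
        """JSON-serialisable description sufficient to regenerate the pair."""
        out = {
            "axes": list(self.axes),
            "categories": {
                s.label: {
                    "mean": s.mean.tolist(),
                    "covariance": s.covariance.tolist(),
                }
                for s in (self.spec_p, self.spec_q)
            },
            "f_ratio": self.f_ratio,
        }
        if seed is not None:
            out["seed"] = seed
        return out


def sample_category(
    space: ShapeSpace, spec: CategorySpec, n: int, seed: int | Generator
) -> np.ndarray:
    """Draw n loading pairs from the category Gaussian; returns an (n, 2) array."""
    for axis in spec.axes:
        if not 1 <= axis <= space.n_components:
            raise ValueError(f"axis {axis} out of range 1..{space.n_components}")
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    return rng.multivariate_normal(spec.mean, spec.covariance, size=n, method="svd")


def compute_f_ratio(samples_p: np.ndarray, samples_q: np.ndarray) -> float:
    """Between-category over within-category variance (ratio of scatter traces).

    Between-scatter is the scatter of the two category means about their
    unweighted grand mean with K-1 divisor; within-scatter is the pooled
    unbiased covariance.  For identical categories the ratio tends to 0 as
    n grows; it increases monotonically with the separation of the means.
    """
    p = np.asarray(samples_p, dtype=float)
    q = np.asarray(samples_q, dtype=float)
    if len(p) < 2 or len(q) < 2:
        raise ValueError("need at least 2 points per category")
    mu_p, mu_q = p.mean(axis=0), q.mean(axis=0)
    grand = (mu_p + mu_q) / 2.0
    between = sum(
        np.outer(m - grand, m - grand) for m in (mu_p, mu_q)
    ) / (2 - 1)
    within = (
        (len(p) - 1) * np.cov(p, rowvar=False) + (len(q) - 1) * np.cov(q, rowvar=False)
    ) / (len(p) + len(q) - 2)
    tb, tw = float(np.trace(between)), float(np.trace(np.atleast_2d(within)))
    if tw <= 0.0:
        if tb > 0.0:
            raise InfiniteSeparationError(
                "within-category variance is zero with nonzero between-category "
                "separation (infinite F-ratio)"
            )
        return 0.0
    return tb / tw


def f_ratio_from_moments(pair_or_specs) -> float:
    """Population-level F-ratio from the category means and covariances."""
    if isinstance(pair_or_specs, CategoryPair):
        specs = (pair_or_specs.spec_p, pair_or_specs.spec_q)
    else:
        specs = tuple(pair_or_specs)
    mu_p, mu_q = specs[0].mean, specs[1].mean
    grand = (mu_p + mu_q) / 2.0
    tb = float(sum(np.sum((m - grand) ** 2) for m in (mu_p, mu_q)))
    tw = float(np.trace(specs[0].covariance + specs[1].covariance) / 2.0)
    if tw <= 0.0:
        if tb > 0.0:
            raise InfiniteSeparationError("zero within-variance with separated means")
        return 0.0
    return tb / tw


def mahalanobis_dprime(pair: CategoryPair) -> float:
    """Equal-covariance ideal-observer d': Mahalanobis distance between means."""
    sigma = (pair.spec_p.covariance + pair.spec_q.covariance) / 2.0
    delta = pair.spec_p.mean - pair.spec_q.mean
    return float(np.sqrt(delta @ np.linalg.solve(sigma, delta)))


def tune_category_pair(
    space: ShapeSpace,
    target_ideal_dprime: float,
    within_covariance: np.ndarray,
    seed: int,
    axes: tuple[int, int] = (2, 3),
    labels: tuple[str, str] = ("P", "Q"),
) -> CategoryPair:
    """Place two equal-covariance category Gaussians at a target ideal d'.

    The means are put symmetrically about the PC-space origin along a seeded
    random direction, at a Mahalanobis distance (under ``within_covariance``)
    equal to ``target_ideal_dprime``.  This is the difficulty dial: the task
    is near-chance for an untrained observer but learnable, with the target
    motivated by the training criterion d'.
    """
    if target_ideal_dprime < 0:
        raise ValueError("target_ideal_dprime must be >= 0")
    cov = np.asarray(within_covariance, dtype=float).reshape(2, 2)
    if not np.allclose(cov, cov.T, atol=1e-10) or np.linalg.eigvalsh(cov).min() <= 0:
        raise ValueError("within_covariance must be symmetric positive-definite")
    rng = default_rng(seed)
    u = rng.normal(size=2)
    u /= np.linalg.norm(u)
    cov_inv = np.linalg.inv(cov)
    if target_ideal_dprime == 0:
        delta = np.zeros(2)
    else:
        delta = u * (target_ideal_dprime / np.sqrt(u @ cov_inv @ u))
    spec_p = CategorySpec(labels[0], +delta / 2.0, cov, axes)
    spec_q = CategorySpec(labels[1], -delta / 2.0, cov, axes)
    return CategoryPair(spec_p, spec_q, f_ratio_from_moments((spec_p, spec_q)))


def mesh_from_loadings(
    space: ShapeSpace, axes: tuple[int, int], xy: np.ndarray
) -> EmbryoMesh:
    """Reconstruct the embryo at a 2-D category-space point."""
    return reconstruct_mesh(space, {axes[0]: float(xy[0]), axes[1]: float(xy[1])})


# --------------------------------------------------------------------------- #
# trial-screen rendering

@dataclass(frozen=True)
class ScreenLayout:
    """Canvas geometry in pixels plus the degrees-per-pixel conversion.

    Defaults follow the protocol constants: embryos subtend ~6 deg, anchored
    centre / left / right, at 40 px per degree of visual angle.
    """

    width_px: int = 832
    height_px: int = 352
    px_per_deg: float = 40.0
    embryo_deg: float = 6.0
    anchor_query: tuple[float, float] = (0.0, 0.0)
    anchor_left: tuple[float, float] = (-6.2, 0.0)
    anchor_right: tuple[float, float] = (6.2, 0.0)
    background: int = 128


def _disk_jitter(rng: Generator, jitter_max_deg: float) -> np.ndarray:
    """Uniform draw from the disk of radius jitter_max_deg (degrees)."""
    r = jitter_max_deg * np.sqrt(rng.random())
    theta = 2.0 * np.pi * rng.random()
    return np.array([r * np.cos(theta), r * np.sin(theta)])


def place_embryos(
    layout: ScreenLayout,
    side_of_p: str,
    jitter_max_deg: float,
    rng: Generator,
) -> list[dict]:
    """Jittered anchor placements for (query, sample_p, sample_q).

    Returns one manifest entry per embryo with its role, anchor, jitter offset
    (degrees) and offset magnitude; |offset| <= jitter_max_deg always.
    """
    if jitter_max_deg < 0:
        raise ValueError("jitter_max_deg must be >= 0")
    if side_of_p not in ("left", "right"):
        raise ValueError("side_of_p must be 'left' or 'right'")
    anchors = {
        "query": layout.anchor_query,
        "sample_p": layout.anchor_left if side_of_p == "left" else layout.anchor_right,
        "sample_q": layout.anchor_right if side_of_p == "left" else layout.anchor_left,
    }
    placements = []
    for role in ("query", "sample_p", "sample_q"):
        jitter = (
            np.zeros(2) if jitter_max_deg == 0 else _disk_jitter(rng, jitter_max_deg)
        )
        placements.append(
            {
                "role": role,
                "anchor_deg": list(anchors[role]),
                "jitter_deg": jitter.tolist(),
                "jitter_mag_deg": float(np.linalg.norm(jitter)),
            }
        )
    return placements


def _draw_mesh(
    draw: ImageDraw.ImageDraw,
    mesh: EmbryoMesh,
    center_px: tuple[float, float],
    size_px: float,
) -> tuple[float, float]:
    """Flat-shaded orthographic projection, painter's algorithm.

    Single directional light; returns the half-extent actually drawn (px) for
    canvas-bound checks.
    """
    v = mesh.vertices - mesh.vertices.mean(axis=0)
    extent = float(np.abs(v).max())
    scale = (size_px / 2.0) / extent
    xs = center_px[0] + v[:, 0] * scale
    ys = center_px[1] - v[:, 1] * scale
    zs = v[:, 2]
    tri = mesh.vertices[mesh.faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    normals /= norms
    light = np.array([0.35, 0.35, 0.87])
    light /= np.linalg.norm(light)
    intensity = 0.22 + 0.68 * np.clip(normals @ light, 0.0, 1.0)
    visible = normals[:, 2] > 0.0  # viewer along +z
    depth = zs[mesh.faces].mean(axis=1)
    order = np.argsort(depth)  # far faces first
    for f in order:
        if not visible[f]:
            continue
        a, b, c = mesh.faces[f]
        draw.polygon(
            [(xs[a], ys[a]), (xs[b], ys[b]), (xs[c], ys[c])],
            fill=int(255 * intensity[f]),
        )
    half_x = float(np.abs(v[:, 0]).max() * scale)
    half_y = float(np.abs(v[:, 1]).max() * scale)
    return half_x, half_y


def render_trial_screen(
    query: EmbryoMesh,
    sample_p: EmbryoMesh,
    sample_q: EmbryoMesh,
    layout: ScreenLayout = ScreenLayout(),
    side_of_p: str = "left",
    jitter_max_deg: float = 0.8,
    seed: int | Generator = 0,
) -> tuple[Image.Image, dict]:
    """Render a query-plus-two-samples screen; returns (image, placement manifest).

    The manifest records each embryo's jitter offset in degrees (bounded by
    ``jitter_max_deg``) and is sufficient to audit or reproduce the placement.
    Identical seeds give byte-identical images.
    """
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    placements = place_embryos(layout, side_of_p, jitter_max_deg, rng)
    img = Image.new("L", (layout.width_px, layout.height_px), layout.background)
    draw = ImageDraw.Draw(img)
    meshes = {"query": query, "sample_p": sample_p, "sample_q": sample_q}
    cx0 = layout.width_px / 2.0
    cy0 = layout.height_px / 2.0
    size_px = layout.embryo_deg * layout.px_per_deg
    for placement in placements:
        pos = np.asarray(placement["anchor_deg"]) + np.asarray(placement["jitter_deg"])
        center = (cx0 + pos[0] * layout.px_per_deg, cy0 - pos[1] * layout.px_per_deg)
        half = size_px / 2.0
        if (
            center[0] - half < 0
            or center[0] + half > layout.width_px
            or center[1] - half < 0
            or center[1] + half > layout.height_px
        ):
            raise LayoutError(
                f"embryo {placement['role']!r} at {pos} deg exceeds the canvas"
            )
        _draw_mesh(draw, meshes[placement["role"]], center, size_px)
    manifest = {
        "layout": {
            "width_px": layout.width_px,
            "height_px": layout.height_px,
            "px_per_deg": layout.px_per_deg,
            "embryo_deg": layout.embryo_deg,
        },
        "side_of_p": side_of_p,
        "jitter_max_deg": jitter_max_deg,
        "embryos": placements,
    }
    return img, manifest


def save_manifest(manifest: dict, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
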