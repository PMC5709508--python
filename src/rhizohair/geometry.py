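"""Labelled 3D soil volumes: generators, filtering, surfaces and distance maps.

All coordinates are physical and in micrometres (µm).  A point belongs to the
voxel whose centre is nearest, with round-half-up per axis; voxel indices are
0-based.  Volumes are stored as ``labels[ix, iy, iz]`` uint8 arrays with a
fixed label dialect (:data:`LABEL_NAMES`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from scipy import ndimage

# Fixed label dialect.
PORE = 0
TEXTURAL = 1
MINERAL = 2
ROOT = 3
OUTSIDE = 255

LABEL_NAMES = {"pore": PORE, "textural": TEXTURAL, "mineral": MINERAL,
               "root": ROOT, "outside": OUTSIDE}
VALID_LABELS = frozenset(LABEL_NAMES.values())

#: analytic packing densities of the supported lattices
BCC_DENSITY = np.pi * np.sqrt(3.0) / 8.0
HCP_DENSITY = np.pi / np.sqrt(18.0)


@dataclass
class PhaseVolume:
    """A labelled voxel grid with isotropic physical voxel size (µm)."""

    labels: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    geometry_kind: str = "cartesian"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float)
        bad = set(np.unique(self.labels)) - VALID_LABELS
        if bad:
            raise ValueError(f"unknown labels present: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def voxel_index(self, points: np.ndarray) -> np.ndarray:
        """Nearest-voxel-centre index (round-half-up per axis), 0-based."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return np.floor((points - self.origin) / self.voxel_size + 0.5).astype(np.int64)

    def label_at(self, points: np.ndarray) -> np.ndarray:
        """Label of the voxel containing each point; OUTSIDE beyond the grid."""
        idx = self.voxel_index(points)
        shape = np.array(self.shape)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        out = np.full(len(idx), OUTSIDE, dtype=np.uint8)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def voxel_centers_1d(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + self.voxel_size * np.arange(n)

    def phase_fractions(self) -> dict[str, float]:
        """Volume fractions over the interior (non-OUTSIDE) domain."""
        interior = self.labels[self.labels != OUTSIDE]
        n = interior.size
        if n == 0:
            raise ValueError("volume has no interior voxels")
        return {name: float(np.count_nonzero(interior == lab)) / n
                for name, lab in LABEL_NAMES.items() if lab != OUTSIDE}


@dataclass
class SurfaceModel:
    """Point-sampled initiating surface with inward unit normals.

    ``points`` lie on the surface (µm); ``normals`` point into the soil.
    ``patch_size`` is the linear size (µm) of the equal-area patch each point
    represents, used for uniform-by-area jittered sampling.
    """

    points: np.ndarray
    normals: np.ndarray
    area_mm2: float
    kind: str  # 'cartesian-face' | 'root-surface'
    patch_size: float
    plane_point: np.ndarray | None = None   # cartesian-face only
    plane_normal: np.ndarray | None = None  # cartesian-face only

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.normals = np.atleast_2d(np.asarray(self.normals, dtype=float))
        if len(self.points) and self.area_mm2 <= 0:
            raise ValueError("area must be positive for a non-empty surface")
        norms = np.linalg.norm(self.normals, axis=1)
        if len(norms) and not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("normals must be unit length")


@dataclass
class DistanceMap:
    """Euclidean distance (µm) from the initiating surface, per voxel."""

    distances: np.ndarray
    reference: str  # 'cartesian-face' | 'root-surface'
    voxel_size: float
    origin: np.ndarray
    plane_point: np.ndarray | None = None
    plane_normal: np.ndarray | None = None

    def at(self, points: np.ndarray) -> np.ndarray:
        """Distance evaluated at physical points.

        Planar references are evaluated analytically; volumetric references by
        linear interpolation of the distance grid.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.reference == "cartesian-face":
            return (points - self.plane_point) @ self.plane_normal
        coords = ((points - self.origin) / self.voxel_size).T
        return ndimage.map_coordinates(self.distances, coords, order=1,
                                       mode="nearest")


def _edge_to_dims(domain_edge, voxel_size: float) -> tuple[int, int, int]:
    edges = np.broadcast_to(np.asarray(domain_edge, dtype=float), (3,))
    dims = tuple(int(round(e / voxel_size)) for e in edges)
    if any(d < 1 for d in dims):
        raise ValueError("domain_edge smaller than one voxel")
    return dims


def _lattice_centers(packing: str, d: float, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Sphere centres of an infinite lattice intersecting the box [lo, hi].

    Lattices are axis-aligned; the HCP c-axis lies along axis 0 (normal to the
    canonical initiation face).
    """
    if packing == "BCC":
        a = 2.0 * d / np.sqrt(3.0)  # touching along the body diagonal
        basis = np.diag([a, a, a])
        offsets = np.array([[0.0, 0.0, 0.0], [0.5 * a, 0.5 * a, 0.5 * a]])
    elif packing == "HCP":
        c = d * np.sqrt(8.0 / 3.0)
        # triangular layers in (y, z), stacked ABAB along x
        basis = np.array([[c, 0.0, 0.0],
                          [0.0, d, 0.0],
                          [0.0, d / 2.0, d * np.sqrt(3.0) / 2.0]])
        offsets = np.array([[0.0, 0.0, 0.0],
                            [c / 2.0, d / 2.0, d / (2.0 * np.sqrt(3.0))]])
    else:
        raise ValueError(f"unknown packing {packing!r}; use 'BCC' or 'HCP'")

    # conservative integer ranges covering the box
    inv = np.linalg.inv(basis.T)
    corners = np.array(np.meshgrid(*zip(lo, hi), indexing="ij")).reshape(3, -1).T
    frac = corners @ inv.T
    imin = np.floor(frac.min(axis=0)).astype(int) - 2
    imax = np.ceil(frac.max(axis=0)).astype(int) + 2
    ranges = [np.arange(imin[k], imax[k] + 1) for k in range(3)]
    grid = np.array(np.meshgrid(*ranges, indexing="ij")).reshape(3, -1).T
    centers = grid @ basis
    centers = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    keep = np.all((centers >= lo) & (centers <= hi), axis=1)
    return centers[keep]


def generate_sphere_packing(packing: str, sphere_diameter: float,
                            domain_edge, voxel_size: float) -> PhaseVolume:
    """Voxelise a BCC or HCP array of touching spheres (MINERAL) in PORE.

    The lattice tiles all of space; spheres are clipped at the domain
    boundary so the realised mineral fraction converges to the analytic
    packing density as the voxel size shrinks.
    """
    if voxel_size > sphere_diameter / 10.0:
        raise ValueError(
            f"voxel_size {voxel_size} µm too coarse for spheres of "
            f"{sphere_diameter} µm; need voxel_size <= {sphere_diameter / 10.0} µm")
    dims = _edge_to_dims(domain_edge, voxel_size)
    labels = np.zeros(dims, dtype=np.uint8)
    r = sphere_diameter / 2.0
    lo = -r * np.ones(3)
    hi = np.array([dims[k] * voxel_size for k in range(3)]) + r
    centers = _lattice_centers(packing, sphere_diameter, lo, hi)

    axes = [np.arange(dims[k]) * voxel_size for k in range(3)]
    r2 = r * r
    for c in centers:
        sl = []
        local = []
        empty = False
        for k in range(3):
            i0 = max(0, int(np.ceil((c[k] - r) / voxel_size - 0.5)))
            i1 = min(dims[k] - 1, int(np.floor((c[k] + r) / voxel_size + 0.5)))
            if i0 > i1:
                empty = True
                break
            sl.append(slice(i0, i1 + 1))
            local.append(axes[k][i0:i1 + 1] - c[k])
        if empty:
            continue
        dx, dy, dz = local
        mask = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
                + dz[None, None, :] ** 2) <= r2
        labels[tuple(sl)][mask] = MINERAL
    return PhaseVolume(labels, voxel_size)


def _threshold_three_phase(fld: np.ndarray, fractions: Sequence[float]) -> np.ndarray:
    """Double-threshold a scalar field into PORE/TEXTURAL/MINERAL by quantile.

    The highest band becomes MINERAL and the middle band TEXTURAL, so the
    textural phase is automatically adjacent to mineral grains.
    """
    f_pore, f_text, f_min = fractions
    labels = np.full(fld.shape, PORE, dtype=np.uint8)
    flat = fld.ravel()
    order = np.argsort(flat, kind="stable")
    n = flat.size
    n_min = int(round(f_min * n))
    n_text = int(round(f_text * n))
    lab_flat = np.full(n, PORE, dtype=np.uint8)
    if n_min:
        lab_flat[order[n - n_min:]] = MINERAL
    if n_text:
        lab_flat[order[n - n_min - n_text:n - n_min]] = TEXTURAL
    labels = lab_flat.reshape(fld.shape)
    return labels


def generate_three_phase_soil(fractions: Sequence[float], domain_edge,
                              voxel_size: float, correlation_length: float = 100.0,
                              rng_seed: int | None = None) -> PhaseVolume:
    """Synthetic three-phase soil from a smoothed random field.

    ``fractions`` is (pore, textural, mineral) and must sum to 1; realised
    fractions match to within rounding of the voxel count.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    dims = _edge_to_dims(domain_edge, voxel_size)
    rng = np.random.default_rng(rng_seed)
    fld = rng.standard_normal(dims)
    sigma = max(correlation_length / voxel_size / 2.0, 0.5)
    fld = ndimage.gaussian_filter(fld, sigma=sigma)
    labels = _threshold_three_phase(fld, fractions)
    return PhaseVolume(labels, voxel_size)


def generate_cylindrical_domain(root_diameter: float = 600.0,
                                soil_extent: float = 600.0,
                                height: float = 600.0,
                                voxel_size: float = 6.0,
                                fractions: Sequence[float] = (0.35, 0.325, 0.325),
                                correlation_length: float = 100.0,
                                rng_seed: int | None = None) -> PhaseVolume:
    """Axis-aligned ROOT cylinder (axis 2) in an annulus of three-phase soil.

    Soil extends ``soil_extent`` µm from the root surface; voxels beyond are
    OUTSIDE.
    """
    if root_diameter <= 0 or soil_extent <= 0:
        raise ValueError("root_diameter and soil_extent must be positive")
    r_root = root_diameter / 2.0
    r_out = r_root + soil_extent
    side = 2.0 * r_out
    nxy = int(round(side / voxel_size))
    nz = max(1, int(round(height / voxel_size)))
    cx = (nxy - 1) * voxel_size / 2.0

    x = np.arange(nxy) * voxel_size - cx
    rho = np.hypot(x[:, None], x[None, :])  # radial distance per (x, y)

    rng = np.random.default_rng(rng_seed)
    fld = rng.standard_normal((nxy, nxy, nz))
    sigma = max(correlation_length / voxel_size / 2.0, 0.5)
    fld = ndimage.gaussian_filter(fld, sigma=sigma)

    labels = np.full((nxy, nxy, nz), OUTSIDE, dtype=np.uint8)
    root_mask = rho <= r_root
    soil_mask = (rho > r_root) & (rho <= r_out)
    labels[root_mask, :] = ROOT

    soil_vals = fld[soil_mask, :]
    soil_labels = _threshold_three_phase(soil_vals, fractions)
    labels[soil_mask, :] = soil_labels
    return PhaseVolume(labels, voxel_size, geometry_kind="cylindrical")


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def filter_small_grains(volume: PhaseVolume, min_equiv_diameter: float
                        ) -> tuple[PhaseVolume, int]:
    """Remove MINERAL grains with equivalent-sphere diameter below a threshold.

    Grains are 26-connected components; the equivalent diameter is
    ``(6 V / π)^(1/3)``.  Removed grains are relabelled to the majority phase
    among their face-adjacent non-mineral neighbours (tie -> TEXTURAL).
    Returns the filtered volume and the number of grains removed.
    """
    if min_equiv_diameter < volume.voxel_size:
        raise ValueError("min_equiv_diameter must be at least one voxel")
    mineral = volume.labels == MINERAL
    comp, n_comp = ndimage.label(mineral, structure=_STRUCT26)
    if n_comp == 0:
        return replace(volume, labels=volume.labels.copy()), 0
    counts = np.bincount(comp.ravel())
    vox_vol = volume.voxel_size ** 3
    equiv_d = np.zeros(n_comp + 1)
    equiv_d[1:] = (6.0 * counts[1:] * vox_vol / np.pi) ** (1.0 / 3.0)
    small = np.flatnonzero(equiv_d[1:] < min_equiv_diameter) + 1
    labels = volume.labels.copy()
    if small.size == 0:
        return replace(volume, labels=labels), 0

    objects = ndimage.find_objects(comp)
    for cid in small:
        sl = objects[cid - 1]
        # pad one voxel to see face neighbours
        sl_p = tuple(slice(max(0, s.start - 1), min(dim, s.stop + 1))
                     for s, dim in zip(sl, volume.shape))
        sub_comp = comp[sl_p]
        sub_lab = labels[sl_p]
        grain = sub_comp == cid
        dil = ndimage.binary_dilation(grain)  # face-adjacent shell
        shell = dil & ~grain
        neigh = sub_lab[shell]
        neigh = neigh[(neigh != MINERAL) & (neigh != OUTSIDE)]
        if neigh.size:
            vals, cnts = np.unique(neigh, return_counts=True)
            best = cnts.max()
            cands = set(vals[cnts == best].tolist())
            new_label = TEXTURAL if (len(cands) > 1 or not cands) else cands.pop()
        else:
            new_label = TEXTURAL
        sub_lab[grain] = new_label
    return replace(volume, labels=labels), int(small.size)


def cartesian_face(axis: int, side: str = "low") -> tuple[str, int, str]:
    """Face specifier for :func:`extract_surface`."""
    if axis not in (0, 1, 2) or side not in ("low", "high"):
        raise ValueError("axis must be 0/1/2 and side 'low' or 'high'")
    return ("face", axis, side)


def extract_surface(volume: PhaseVolume, which) -> SurfaceModel:
    """Extract an initiating surface with inward unit normals.

    ``which`` is either ``'root'`` or a :func:`cartesian_face` specifier.
    Face normals are exact; root normals come from the smoothed gradient of
    the signed root-phase distance transform (Gaussian sigma = 2 voxels).
    """
    if which == "root":
        return _extract_root_surface(volume)
    kind, axis, side = which
    if kind != "face":
        raise ValueError(f"unknown surface specifier {which!r}")
    vs = volume.voxel_size
    dims = volume.shape
    normal = np.zeros(3)
    if side == "low":
        plane = volume.origin[axis] - vs / 2.0
        normal[axis] = 1.0
        face_index = 0
    else:
        plane = volume.origin[axis] + (dims[axis] - 1) * vs + vs / 2.0
        normal[axis] = -1.0
        face_index = dims[axis] - 1
    other = [k for k in range(3) if k != axis]
    ga = volume.voxel_centers_1d(other[0])
    gb = volume.voxel_centers_1d(other[1])
    aa, bb = np.meshgrid(ga, gb, indexing="ij")
    pts = np.empty((aa.size, 3))
    pts[:, axis] = plane
    pts[:, other[0]] = aa.ravel()
    pts[:, other[1]] = bb.ravel()
    face = np.take(volume.labels, face_index, axis=axis)
    keep = (face.ravel() != OUTSIDE)
    pts = pts[keep]
    area = len(pts) * vs * vs / 1e6
    normals = np.broadcast_to(normal, (len(pts), 3)).copy()
    plane_point = np.zeros(3)
    plane_point[axis] = plane
    return SurfaceModel(pts, normals, area, "cartesian-face", vs,
                        plane_point=plane_point, plane_normal=normal)


def _extract_root_surface(volume: PhaseVolume) -> SurfaceModel:
    root = volume.labels == ROOT
    if not root.any():
        raise ValueError("volume contains no ROOT phase")
    soil = (volume.labels == PORE) | (volume.labels == TEXTURAL)
    # outermost ROOT voxels touching soil: distance to the surface is zero
    boundary = root & ndimage.binary_dilation(soil)
    idx = np.argwhere(boundary)
    pts = volume.origin + idx * volume.voxel_size

    d_out = ndimage.distance_transform_edt(~root)
    d_in = ndimage.distance_transform_edt(root)
    signed = ndimage.gaussian_filter(d_out - d_in, sigma=2.0)
    grads = np.gradient(signed)
    g = np.stack([g[idx[:, 0], idx[:, 1], idx[:, 2]] for g in grads], axis=1)
    norms = np.linalg.norm(g, axis=1)
    norms[norms == 0] = 1.0
    normals = g / norms[:, None]
    area = len(pts) * volume.voxel_size ** 2 / 1e6
    return SurfaceModel(pts, normals, area, "root-surface", volume.voxel_size)


def distance_from_surface(volume: PhaseVolume, surface: SurfaceModel) -> DistanceMap:
    """Euclidean distance map (µm) from the initiating surface."""
    if len(surface.points) == 0:
        raise ValueError("surface is empty")
    if surface.kind == "cartesian-face":
        coords = [volume.voxel_centers_1d(k) for k in range(3)]
        grids = np.meshgrid(*coords, indexing="ij")
        dist = sum((grids[k] - surface.plane_point[k]) * surface.plane_normal[k]
                   for k in range(3))
        return DistanceMap(np.asarray(dist, dtype=float), "cartesian-face",
                           volume.voxel_size, volume.origin.copy(),
                           plane_point=surface.plane_point.copy(),
                           plane_normal=surface.plane_normal.copy())
    root = volume.labels == ROOT
    dist = ndimage.distance_transform_edt(~root) * volume.voxel_size
    return DistanceMap(dist, "root-surface", volume.voxel_size,
                       volume.origin.copy())


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF (uint8) + sidecar JSON carrying the metadata

def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_volume(volume: PhaseVolume, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, volume.labels)
    meta = {
        "voxel_size_um": volume.voxel_size,
        "origin_um": list(volume.origin),
        "geometry_kind": volume.geometry_kind,
        "labels": LABEL_NAMES,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_volume(path) -> PhaseVolume:
    path = Path(path)
    labels = tifffile.imread(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "voxel_size_um" not in meta:
        raise ValueError(f"sidecar {sidecar} lacks required 'voxel_size_um'")
    bad = set(np.unique(labels)) - VALID_LABELS
    if bad:
        raise ValueError(f"file contains unknown labels: {sorted(int(b) for b in bad)}")
    return PhaseVolume(labels, float(meta["voxel_size_um"]),
                       origin=np.asarray(meta.get("origin_um", (0, 0, 0)), dtype=float),
                       geometry_kind=meta.get("geometry_kind", "cartesian"))


def write_surface_csv(surface: SurfaceModel, path) -> None:
    data = np.hstack([surface.points, surface.normals])
    header = "x,y,z,nx,ny,nz"
    np.savetxt(path, data, delimiter=",", header=header, comments="")


def uniform_volume(domain_edge, voxel_size: float, label: int = PORE) -> PhaseVolume:
    """A single-phase (default all-PORE) volume — the 'empty' control domain."""
    dims = _edge_to_dims(domain_edge, voxel_size)
    return PhaseVolume(np.full(dims, label, dtype=np.uint8), voxel_size)
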