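"""Stepwise, collision-avoiding tip growth through a labelled phase volume.

Each growth step places a fan of quasi-equally spaced test points on a sphere
around the current tip, classifies them by deviation angle from the reference
heading into equal-width angular bins, discards invalid candidates (outside
the domain, deviation >= pi/2, inside mineral or root, or violating fluid
confinement), and picks uniformly at random from the lowest-angle non-empty
bin.  Growth ceases when no candidate remains.

Two switches control the dynamics: the reference heading is either the
initial heading for the whole hair (A0) or the previous step's chosen vector
(A1); and hairs either cross fluid boundaries freely (F0) or, once inside
the hydrated textural phase, stay within it (F1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

from .geometry import MINERAL, OUTSIDE, ROOT, TEXTURAL, PhaseVolume
from .seeding import HairSeed, LengthAssignment

_EPS = 1e-9


@dataclass(frozen=True)
class GrowthConfig:
    """Parameters of the tip-extension algorithm."""

    step_length: float = 32.0   # r, µm
    fan_size: int = 100         # n test points per step
    bin_count: int = 4          # k angular bins of width (pi/2)/k
    condition_A: str = "A0"     # 'A0' fixed reference | 'A1' previous step
    condition_F: str = "F0"     # 'F0' free | 'F1' confined to textural phase
    rng_seed: int = 0
    max_steps: int = 100_000

    def __post_init__(self) -> None:
        if self.step_length <= 0:
            raise ValueError("step_length must be positive")
        if self.fan_size < 8:
            raise ValueError("fan_size must be at least 8")
        if self.bin_count < 1:
            raise ValueError("bin_count must be at least 1")
        if self.condition_A not in ("A0", "A1"):
            raise ValueError("condition_A must be 'A0' or 'A1'")
        if self.condition_F not in ("F0", "F1"):
            raise ValueError("condition_F must be 'F0' or 'F1'")

    @property
    def bin_width(self) -> float:
        return (np.pi / 2.0) / self.bin_count


@lru_cache(maxsize=16)
def _spiral_cached(n: int) -> np.ndarray:
    if n < 2:
        raise ValueError("need at least 2 points on the sphere")
    z = -1.0 + 2.0 * np.arange(n) / (n - 1)
    phi = np.zeros(n)
    for i in range(1, n - 1):
        phi[i] = phi[i - 1] + 3.6 / np.sqrt(n * (1.0 - z[i] ** 2))
    # poles keep azimuth 0
    s = np.sqrt(np.maximum(0.0, 1.0 - z ** 2))
    pts = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    pts[0] = (0.0, 0.0, -1.0)
    pts[-1] = (0.0, 0.0, 1.0)
    pts.setflags(write=False)
    return pts


def spiral_points(n: int) -> np.ndarray:
    """``n`` quasi-equally spaced unit vectors via the generalised spiral."""
    return _spiral_cached(n).copy()


def angle_between(h_ref: np.ndarray, h_test: np.ndarray) -> float:
    """Included angle in [0, pi], robust near 0 and pi.

    Computed as atan2(||h_ref x h_test||, h_ref . h_test), which is accurate
    where arccos of the normalised dot product loses precision.
    """
    a = np.asarray(h_ref, dtype=float)
    b = np.asarray(h_test, dtype=float)
    if np.linalg.norm(a) == 0 or np.linalg.norm(b) == 0:
        raise ValueError("vectors must be nonzero")
    cross = np.cross(a, b)
    return float(np.arctan2(np.linalg.norm(cross), np.dot(a, b)))


def _angles_vs(ref: np.ndarray, vecs: np.ndarray) -> np.ndarray:
    # ref unit, vecs rows unit
    dots = vecs @ ref
    crosses = np.cross(np.broadcast_to(ref, vecs.shape), vecs)
    return np.arctan2(np.linalg.norm(crosses, axis=1), dots)


def classify_bins(angles, k: int) -> np.ndarray:
    """Bin index 1..k for angles below pi/2 (half-open bins of width pi/2k);
    0 marks out-of-range angles."""
    if k < 1:
        raise ValueError("k must be at least 1")
    a = np.atleast_1d(np.asarray(angles, dtype=float))
    width = (np.pi / 2.0) / k
    idx = np.floor(a / width).astype(np.int64) + 1
    idx[a >= np.pi / 2.0] = 0
    return idx


@dataclass
class TestFan:
    """One step's candidate end-points with validity flags."""

    test_points: np.ndarray     # (n, 3) µm, on a sphere about the tip
    test_vectors: np.ndarray    # (n, 3) µm, length = step length
    angles: np.ndarray          # (n,) vs the reference heading
    bin_index: np.ndarray       # (n,) 1..k, 0 = out of range
    in_domain: np.ndarray = field(default=None)
    angle_ok: np.ndarray = field(default=None)
    not_mineral: np.ndarray = field(default=None)
    fluid_ok: np.ndarray = field(default=None)

    @property
    def selectable(self) -> np.ndarray:
        return self.in_domain & self.angle_ok & self.not_mineral & self.fluid_ok


def build_fan(tip: np.ndarray, reference_heading: np.ndarray,
              step_length: float, fan_size: int, bin_count: int) -> TestFan:
    dirs = _spiral_cached(fan_size)
    vecs = dirs * step_length
    pts = tip + vecs
    angles = _angles_vs(reference_heading, dirs)
    bins = classify_bins(angles, bin_count)
    return TestFan(pts, vecs, angles, bins)


def validity_tests(fan: TestFan, volume: PhaseVolume, config: GrowthConfig,
                   seed_in_fluid: bool) -> TestFan:
    """Flag each candidate: inside domain, angle in range, not mineral/root,
    and (under F1, when the tip sits in the textural phase) still textural."""
    labels = volume.label_at(fan.test_points)
    fan.in_domain = labels != OUTSIDE
    fan.angle_ok = fan.bin_index >= 1
    fan.not_mineral = (labels != MINERAL) & (labels != ROOT)
    if config.condition_F == "F1" and seed_in_fluid:
        fan.fluid_ok = labels == TEXTURAL
    else:
        fan.fluid_ok = np.ones(len(labels), dtype=bool)
    return fan


def grow_step(tip: np.ndarray, reference_heading: np.ndarray,
              volume: PhaseVolume, config: GrowthConfig,
              rng: np.random.Generator,
              step_length: float | None = None,
              seed_in_fluid: bool = False):
    """One tip extension; returns ``(new_tip, chosen_unit_heading)`` or
    ``None`` when every bin is empty (growth ceases)."""
    r = config.step_length if step_length is None else step_length
    fan = build_fan(tip, reference_heading, r, config.fan_size, config.bin_count)
    validity_tests(fan, volume, config, seed_in_fluid)
    ok = fan.selectable
    if not ok.any():
        return None
    bins = fan.bin_index[ok]
    j = bins.min()
    cand = np.flatnonzero(ok)[bins == j]
    choice = cand[rng.integers(len(cand))]
    new_tip = fan.test_points[choice]
    return new_tip, fan.test_vectors[choice] / r


@dataclass
class HairPath:
    hair_id: int
    vertices: np.ndarray          # (m+1, 3) µm; first vertex is T
    phases: np.ndarray            # label of each vertex's voxel
    headings: np.ndarray          # (m, 3) unit chosen growth vectors
    target_length: float          # l_v requested
    achieved_length: float
    terminated_early: bool
    termination_reason: str | None = None  # 'trapped' | 'max_steps'

    @property
    def chord(self) -> float:
        return float(np.linalg.norm(self.vertices[-1] - self.vertices[0]))


def _step_schedule(l_v: float, r: float) -> list[float]:
    m_full = int(np.floor(l_v / r + 1e-9))
    rem = l_v - m_full * r
    steps = [r] * m_full
    if rem > _EPS:
        steps.append(rem)
    return steps


def grow_hair(seed: HairSeed, l_v: float, volume: PhaseVolume,
              config: GrowthConfig, rng: np.random.Generator,
              hair_id: int = 0) -> HairPath:
    """Grow one hair for a remaining length ``l_v``.

    Full steps of the configured step length are taken, plus one shorter
    final step so the achieved length equals ``l_v`` exactly unless growth
    terminates early.
    """
    if l_v < 0:
        raise ValueError("l_v must be non-negative")
    tip = np.asarray(seed.transition_point, dtype=float)
    tip_label = int(volume.label_at(tip)[0])
    if tip_label == MINERAL:
        raise ValueError("seed transition point lies inside a mineral grain")

    vertices = [tip]
    phases = [tip_label]
    headings: list[np.ndarray] = []
    achieved = 0.0
    terminated = False
    reason = None

    ref = seed.heading
    steps = _step_schedule(l_v, config.step_length)
    for m, s in enumerate(steps):
        if m >= config.max_steps:
            terminated, reason = True, "max_steps"
            break
        in_fluid = phases[-1] == TEXTURAL
        res = grow_step(vertices[-1], ref, volume, config, rng,
                        step_length=s, seed_in_fluid=in_fluid)
        if res is None:
            terminated, reason = True, "trapped"
            break
        new_tip, h = res
        vertices.append(new_tip)
        phases.append(int(volume.label_at(new_tip)[0]))
        headings.append(h)
        achieved += s
        if config.condition_A == "A1":
            ref = h

    return HairPath(hair_id=hair_id,
                    vertices=np.array(vertices),
                    phases=np.array(phases, dtype=np.uint8),
                    headings=(np.array(headings) if headings
                              else np.zeros((0, 3))),
                    target_length=l_v,
                    achieved_length=achieved,
                    terminated_early=terminated,
                    termination_reason=reason)


def grow_population(seeds: Sequence[HairSeed], lengths: LengthAssignment,
                    volume: PhaseVolume, config: GrowthConfig) -> list[HairPath]:
    """Grow one computational replicate: one path per seed.

    Each hair uses an independent RNG substream derived from
    ``(config.rng_seed, hair_id)``, so replicates are reproducible and
    independent of execution order.
    """
    if len(seeds) != len(lengths.virtual_lengths):
        raise ValueError("seed and length lists differ in size")
    paths = []
    for hid, (seed, l_v) in enumerate(zip(seeds, lengths.virtual_lengths)):
        rng = np.random.default_rng([config.rng_seed, hid])
        paths.append(grow_hair(seed, float(l_v), volume, config, rng,
                               hair_id=hid))
    return paths


# ---------------------------------------------------------------------------
# exports

def write_paths_csv(paths: Sequence[HairPath], path) -> None:
    import pandas as pd
    rows = []
    for p in paths:
        for i, (v, ph) in enumerate(zip(p.vertices, p.phases)):
            rows.append({"hair_id": p.hair_id, "vertex_index": i,
                         "x_um": v[0], "y_um": v[1], "z_um": v[2],
                         "phase_label": int(ph),
                         "terminated_reason": p.termination_reason or ""})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_paths_vtk(paths: Sequence[HairPath], path) -> None:
    """Legacy ASCII VTK polydata: one polyline per hair."""
    n_pts = sum(len(p.vertices) for p in paths)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nhair paths\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {n_pts} float\n")
        for p in paths:
            for v in p.vertices:
                fh.write(f"{v[0]:.4f} {v[1]:.4f} {v[2]:.4f}\n")
        n_lines = len(paths)
        size = sum(len(p.vertices) + 1 for p in paths)
        fh.write(f"LINES {n_lines} {size}\n")
        offset = 0
        for p in paths:
            ids = " ".join(str(offset + i) for i in range(len(p.vertices)))
            fh.write(f"{len(p.vertices)} {ids}\n")
            offset += len(p.vertices)
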