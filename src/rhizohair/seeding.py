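"""Hair seeds, length models and the conditional (survival) length sampler.

A seed is a start point on the initiating surface plus an initial heading and
an already-visible length ``l_r`` (zero for fully synthetic hairs).  Total
lengths are either fixed or drawn from a Weibull model; partially grown hairs
receive the remaining ("future lifetime") length conditioned on having
already reached ``l_r``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .geometry import MINERAL, PhaseVolume, SurfaceModel


@dataclass
class HairSeed:
    transition_point: np.ndarray      # T: where synthetic growth begins (µm)
    heading: np.ndarray               # unit vector into the soil
    visible_length: float = 0.0       # l_r (µm)
    initiation_point: np.ndarray | None = None  # I, when known

    def __post_init__(self) -> None:
        self.transition_point = np.asarray(self.transition_point, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float)
        n = np.linalg.norm(self.heading)
        if not np.isfinite(n) or n == 0:
            raise ValueError("heading must be a nonzero vector")
        self.heading = self.heading / n
        if self.visible_length < 0:
            raise ValueError("visible_length must be non-negative")


@dataclass(frozen=True)
class WeibullModel:
    """Two-parameter Weibull length model: shape ``alpha``, scale ``beta`` (µm)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


@dataclass
class LengthAssignment:
    """Per-seed total and remaining growth lengths; l_v = l_tot - l_r."""

    total_lengths: np.ndarray     # l_tot per seed (µm)
    virtual_lengths: np.ndarray   # l_v per seed (µm)
    mode: str                     # 'fixed' | 'weibull_survival'


def sample_transition_points(surface: SurfaceModel, density: float,
                             rng: np.random.Generator,
                             volume: PhaseVolume | None = None,
                             max_resample: int = 100) -> list[HairSeed]:
    """Seed ``round(density × area)`` hairs uniformly by area on a surface.

    ``density`` is in hairs per mm².  Each surface point represents an
    equal-area patch; a seed picks a patch uniformly then jitters within it,
    which is exactly uniform on planar faces.  The heading is the inward
    surface normal.  Seeds landing in a MINERAL voxel are resampled (a hair
    cannot initiate inside an impenetrable grain).
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    count = int(np.floor(density * surface.area_mm2 + 0.5))
    if count == 0:
        return []
    if len(surface.points) == 0:
        raise ValueError("cannot seed a surface with no points")

    seeds: list[HairSeed] = []
    for _ in range(count):
        for _attempt in range(max_resample):
            i = rng.integers(len(surface.points))
            p = surface.points[i]
            n = surface.normals[i]
            # jitter within the patch, tangentially to the normal
            t1 = np.cross(n, [1.0, 0.0, 0.0])
            if np.linalg.norm(t1) < 1e-6:
                t1 = np.cross(n, [0.0, 1.0, 0.0])
            t1 /= np.linalg.norm(t1)
            t2 = np.cross(n, t1)
            u, v = rng.uniform(-0.5, 0.5, size=2) * surface.patch_size
            pt = p + u * t1 + v * t2
            if volume is None or volume.label_at(pt)[0] != MINERAL:
                break
        seeds.append(HairSeed(pt, n.copy(), visible_length=0.0))
    return seeds


def seeds_from_partial_hairs(pairs: Sequence[tuple]) -> list[HairSeed]:
    """Seeds from (initiation point I, transition point T) pairs.

    The heading is the unit vector from I to T and the visible length the
    distance between them.
    """
    seeds = []
    for I, T in pairs:
        I = np.asarray(I, dtype=float)
        T = np.asarray(T, dtype=float)
        d = T - I
        l_r = float(np.linalg.norm(d))
        if l_r == 0:
            raise ValueError(f"coincident initiation/transition points at {I}")
        seeds.append(HairSeed(T, d / l_r, visible_length=l_r,
                              initiation_point=I))
    return seeds


def fit_weibull(lengths: Sequence[float]) -> WeibullModel:
    """Maximum-likelihood two-parameter Weibull fit (location fixed at 0)."""
    x = np.asarray(lengths, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 lengths to fit")
    if np.any(x <= 0):
        raise ValueError("lengths must be positive")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all lengths identical")
    alpha, _loc, beta = stats.weibull_min.fit(x, floc=0)
    return WeibullModel(alpha=float(alpha), beta=float(beta))


def weibull_cdf(x, model: WeibullModel):
    """Weibull CDF ``1 - exp(-(x/beta)^alpha)``; x must be >= 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be non-negative")
    out = 1.0 - np.exp(-np.power(x / model.beta, model.alpha))
    return out if out.ndim else float(out)


def sample_future_length(l_r: float, model: WeibullModel,
                         rng: np.random.Generator, size: int | None = None):
    """Draw remaining length(s) l_v conditional on survival to ``l_r``.

    Inverse-CDF sampling of the future-lifetime law:
    ``l_v = beta * ((l_r/beta)^alpha - ln(1-u))^(1/alpha) - l_r``.
    """
    if l_r < 0:
        raise ValueError("l_r must be non-negative")
    u = rng.random(size)  # in [0, 1); avoids the infinite upper quantile
    a, b = model.alpha, model.beta
    l_v = b * np.power((l_r / b) ** a - np.log1p(-u), 1.0 / a) - l_r
    l_v = np.maximum(l_v, 0.0)  # guard fp round-off at u -> 0
    return l_v if size is not None else float(l_v)


class FixedLength:
    """Constant total length l_tot = c for every seed."""

    def __init__(self, c: float):
        if c <= 0:
            raise ValueError("fixed length must be positive")
        self.c = c


class WeibullSurvival:
    """Total lengths follow a Weibull model; seeds with l_r > 0 sample the
    conditional remainder so the l_tot distribution matches the model."""

    def __init__(self, model: WeibullModel):
        self.model = model


def assign_lengths(seeds: Sequence[HairSeed], mode,
                   rng: np.random.Generator | None = None) -> LengthAssignment:
    """Assign each seed a total length and the remaining growth length."""
    l_r = np.array([s.visible_length for s in seeds], dtype=float)
    if isinstance(mode, FixedLength):
        l_tot = np.full(len(seeds), float(mode.c))
        l_v = l_tot - l_r
        if np.any(l_v < 0):
            import warnings
            warnings.warn("some visible lengths exceed the fixed total; "
                          "their growth length is clamped to 0")
            l_v = np.maximum(l_v, 0.0)
            l_tot = l_r + l_v
        return LengthAssignment(l_tot, l_v, "fixed")
    if isinstance(mode, WeibullSurvival):
        if rng is None:
            raise ValueError("survival mode requires an rng")
        l_v = np.array([sample_future_length(lr, mode.model, rng) for lr in l_r])
        return LengthAssignment(l_r + l_v, l_v, "weibull_survival")
    raise TypeError(f"unknown length mode {mode!r}")


def write_seeds_csv(seeds: Sequence[HairSeed], path) -> None:
    import pandas as pd
    rows = []
    for i, s in enumerate(seeds):
        I = s.initiation_point if s.initiation_point is not None else (
            s.transition_point - s.visible_length * s.heading)
        rows.append({"hair_id": i,
                     "Ix": I[0], "Iy": I[1], "Iz": I[2],
                     "Tx": s.transition_point[0], "Ty": s.transition_point[1],
                     "Tz": s.transition_point[2],
                     "hx": s.heading[0], "hy": s.heading[1], "hz": s.heading[2],
                     "l_r_um": s.visible_length})
    pd.DataFrame(rows).to_csv(path, index=False)
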