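"""Shell-binned length profiles, bulk-control comparison and path statistics.

Hair length is accumulated into concentric distance shells (default width
50 µm) measured from the initiating surface.  Each path segment is split
into ~1 µm sub-segments and each sub-segment's length is attributed to the
shell containing its midpoint.  Profiles are plain length per shell (µm),
with no volume normalisation, so planar and cylindrical scenarios compare
directly.  The "wet" profile keeps only sub-segments whose midpoint voxel
lies in the hydrated textural phase; the bulk-control approximation instead
scales the total profile by the textural fraction j of the hair-accessible
domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import (MINERAL, OUTSIDE, PORE, ROOT, TEXTURAL, DistanceMap,
                       PhaseVolume)
from .growth import HairPath

SUBSEGMENT_UM = 1.0  # sub-segment resolution for shell/wet attribution


@dataclass
class LengthProfile:
    shell_edges: np.ndarray   # (n_shells + 1,) µm from initiating surface
    L_tot: np.ndarray         # µm of hair length per shell
    L_wet: np.ndarray | None = None  # fluid-coincident length, if computed

    @property
    def n_shells(self) -> int:
        return len(self.shell_edges) - 1

    @property
    def shell_width(self) -> float:
        return float(self.shell_edges[1] - self.shell_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.shell_edges[:-1] + self.shell_edges[1:])


@dataclass
class ReplicateSummary:
    """Total fluid-coincident length per replicate plus summary statistics."""

    wet_totals: np.ndarray
    mean: float
    sd: float


def _subsegment_samples(paths: Sequence[HairPath]):
    """Midpoints and lengths of ~1 µm sub-segments over all path segments."""
    mids = []
    lens = []
    for p in paths:
        v = p.vertices
        for a, b in zip(v[:-1], v[1:]):
            seg = b - a
            L = float(np.linalg.norm(seg))
            if L == 0:
                continue
            n_sub = max(1, int(math.ceil(L / SUBSEGMENT_UM)))
            t = (np.arange(n_sub) + 0.5) / n_sub
            mids.append(a + t[:, None] * seg)
            lens.append(np.full(n_sub, L / n_sub))
    if not mids:
        return np.zeros((0, 3)), np.zeros(0)
    return np.vstack(mids), np.concatenate(lens)


def length_profile(paths: Sequence[HairPath], dmap: DistanceMap,
                   volume: PhaseVolume, shell_width: float = 50.0,
                   n_shells: int | None = None,
                   wet: bool = True) -> LengthProfile:
    """Shell-binned total (and optionally fluid-coincident) hair length."""
    if shell_width <= 0:
        raise ValueError("shell_width must be positive")
    mids, lens = _subsegment_samples(paths)
    if len(mids) == 0:
        edges = np.arange((n_shells or 1) + 1) * shell_width
        z = np.zeros(len(edges) - 1)
        return LengthProfile(edges, z, z.copy() if wet else None)
    d = np.maximum(dmap.at(mids), 0.0)
    if n_shells is None:
        n_shells = int(math.floor(d.max() / shell_width)) + 1
    edges = np.arange(n_shells + 1) * shell_width
    idx = np.clip((d // shell_width).astype(np.int64), 0, n_shells - 1)
    L_tot = np.bincount(idx, weights=lens, minlength=n_shells)
    L_wet = None
    if wet:
        in_s = volume.label_at(mids) == TEXTURAL
        L_wet = np.bincount(idx[in_s], weights=lens[in_s], minlength=n_shells)
    return LengthProfile(edges, L_tot, L_wet)


def accessible_textural_fraction(volume: PhaseVolume) -> float:
    """j: fraction of the hair-accessible (non-mineral, non-root) domain
    occupied by the hydrated textural phase."""
    lab = volume.labels
    accessible = np.count_nonzero((lab == PORE) | (lab == TEXTURAL))
    if accessible == 0:
        raise ValueError("volume has no hair-accessible voxels")
    return float(np.count_nonzero(lab == TEXTURAL)) / accessible


def control_wet_approximation(profile_tot: LengthProfile,
                              volume: PhaseVolume) -> LengthProfile:
    """Bulk-control wet profile: L_wet = j * L_tot per shell."""
    j = accessible_textural_fraction(volume)
    return LengthProfile(profile_tot.shell_edges.copy(),
                         profile_tot.L_tot.copy(),
                         j * profile_tot.L_tot)


def elevation_percent(explicit_wet_total: float, control_wet_total: float) -> float:
    """Explicit-over-control wet length, in percent."""
    if control_wet_total <= 0:
        raise ValueError("control wet total must be positive")
    return 100.0 * explicit_wet_total / control_wet_total


def tortuosity(path: HairPath) -> float:
    """Path length over end-to-end chord (>= 1); NaN when undefined."""
    if len(path.vertices) < 2:
        return float("nan")
    chord = path.chord
    if chord == 0:
        return float("nan")
    return path.achieved_length / chord


def replicate_statistics(profiles: Sequence[LengthProfile]
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-shell mean and sample SD of L_tot over replicates."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 replicate profiles")
    edges = profiles[0].shell_edges
    for p in profiles[1:]:
        if len(p.shell_edges) != len(edges) or not np.allclose(p.shell_edges, edges):
            raise ValueError("replicate profiles have mismatched shells")
    stack = np.vstack([p.L_tot for p in profiles])
    return stack.mean(axis=0), stack.std(axis=0, ddof=1)


def summarize_replicates(wet_totals: Sequence[float]) -> ReplicateSummary:
    w = np.asarray(wet_totals, dtype=float)
    sd = float(w.std(ddof=1)) if len(w) > 1 else 0.0
    return ReplicateSummary(w, float(w.mean()), sd)


def profile_periodicity(profile: LengthProfile) -> float | None:
    """Dominant spatial period (µm) of the mean-subtracted total profile.

    Uses the first local maximum of the autocorrelation at non-zero lag;
    returns None for flat or aperiodic profiles.  The profile is linearly
    detrended first: finite hair length imposes a decaying trend that would
    otherwise swamp the oscillation.
    """
    y = np.asarray(profile.L_tot, dtype=float)
    if len(y) < 8:
        raise ValueError("need at least 8 shells")
    x = np.arange(len(y))
    y = y - np.polyval(np.polyfit(x, y, 1), x)
    if np.allclose(y, 0):
        return None
    acf = np.correlate(y, y, mode="full")[len(y) - 1:]
    acf = acf / acf[0]
    # first local maximum at lag >= 1
    for lag in range(1, len(acf) - 1):
        if acf[lag] >= acf[lag - 1] and acf[lag] > acf[lag + 1]:
            return lag * profile.shell_width
    return None


def write_profile_csv(profile: LengthProfile, path) -> None:
    import pandas as pd
    df = pd.DataFrame({
        "shell_lower_um": profile.shell_edges[:-1],
        "shell_upper_um": profile.shell_edges[1:],
        "L_tot_um": profile.L_tot,
        "L_wet_um": (profile.L_wet if profile.L_wet is not None
                     else np.full(profile.n_shells, np.nan)),
    })
    df.to_csv(path, index=False)
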