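"""End-to-end scenario runs: geometry -> seeds -> growth -> profiles.

A scenario grows one or more computational replicates of a hair population
in a (generated or loaded) phase volume, optionally alongside a matched
control population grown in an empty copy of the domain, and quantifies
both with shell-binned length profiles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry as geo
from . import morphometrics as morph
from .growth import GrowthConfig, HairPath, grow_population, write_paths_csv, write_paths_vtk
from .seeding import (FixedLength, WeibullModel, WeibullSurvival,
                      assign_lengths, sample_transition_points, write_seeds_csv)

log = logging.getLogger("rhizohair")


class ConfigError(ValueError):
    """Invalid scenario configuration (CLI exit code 2)."""


@dataclass
class ScenarioConfig:
    # geometry
    geometry: str = "three_phase"  # sphere_packing|three_phase|cylindrical|empty|file
    packing: str = "BCC"
    sphere_diameter: float = 90.0
    pore_fraction: float = 0.35
    textural_fraction: float = 0.325
    mineral_fraction: float = 0.325
    domain_edge: float = 1860.0
    voxel_size: float = 6.0
    correlation_length: float = 100.0
    volume_path: str | None = None
    root_diameter: float = 600.0
    soil_extent: float = 600.0
    height: float = 600.0
    filter_grains: bool = True
    # seeding / lengths
    surface: str = "face:0:low"  # 'root' or face:<axis>:<side>
    density: float = 121.0
    length_mode: str = "fixed"   # fixed | weibull
    fixed_length: float = 500.0
    weibull_alpha: float = 2.0
    weibull_beta: float = 150.0
    # growth
    step_length: float = 32.0
    fan_size: int = 100
    bin_count: int = 4
    condition_A: str = "A0"
    condition_F: str = "F0"
    # run
    replicates: int = 1
    rng_seed: int = 0
    run_control: bool = True
    shell_width: float = 50.0
    outdir: str = "scenario_out"

    def validate(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.geometry not in ("sphere_packing", "three_phase", "cylindrical",
                                 "empty", "file"):
            raise ConfigError(f"unknown geometry kind {self.geometry!r}")
        if self.geometry == "file":
            if not self.volume_path:
                raise ConfigError("geometry 'file' requires volume_path")
            if not Path(self.volume_path).exists():
                raise ConfigError(f"input volume not found: {self.volume_path}")
        if self.length_mode not in ("fixed", "weibull"):
            raise ConfigError(f"unknown length_mode {self.length_mode!r}")


_BOOLS = {"true": True, "false": False, "1": True, "0": False,
          "yes": True, "no": False}


def load_config(path) -> ScenarioConfig:
    """Parse a flat ``key = value`` config file (# comments allowed)."""
    cfg = ScenarioConfig()
    fields = {f.name: f for f in dataclasses.fields(ScenarioConfig)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in fields:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        ftype = fields[key].type
        try:
            if "bool" in str(ftype):
                value = _BOOLS[raw.lower()]
            elif "int" in str(ftype):
                value = int(raw)
            elif "float" in str(ftype):
                value = float(raw)
            else:
                value = raw
        except (KeyError, ValueError) as e:
            raise ConfigError(f"{path}:{lineno}: bad value for {key}: {raw!r}") from e
        setattr(cfg, key, value)
    return cfg


def build_volume(cfg: ScenarioConfig) -> geo.PhaseVolume:
    fr = (cfg.pore_fraction, cfg.textural_fraction, cfg.mineral_fraction)
    if cfg.geometry == "sphere_packing":
        vol = geo.generate_sphere_packing(cfg.packing, cfg.sphere_diameter,
                                          cfg.domain_edge, cfg.voxel_size)
    elif cfg.geometry == "three_phase":
        vol = geo.generate_three_phase_soil(fr, cfg.domain_edge, cfg.voxel_size,
                                            cfg.correlation_length, cfg.rng_seed)
    elif cfg.geometry == "cylindrical":
        vol = geo.generate_cylindrical_domain(cfg.root_diameter, cfg.soil_extent,
                                              cfg.height, cfg.voxel_size, fr,
                                              cfg.correlation_length, cfg.rng_seed)
    elif cfg.geometry == "empty":
        vol = geo.uniform_volume(cfg.domain_edge, cfg.voxel_size)
    else:
        vol = geo.read_volume(cfg.volume_path)
    if cfg.filter_grains and cfg.geometry != "empty":
        vol, removed = geo.filter_small_grains(vol, cfg.step_length)
        log.info("filtered %d grains below %.1f µm", removed, cfg.step_length)
    return vol


def parse_surface_spec(spec: str):
    if spec == "root":
        return "root"
    parts = spec.split(":")
    if len(parts) == 3 and parts[0] == "face":
        return geo.cartesian_face(int(parts[1]), parts[2])
    raise ConfigError(f"bad surface spec {spec!r}; use 'root' or 'face:<axis>:<side>'")


def _length_mode(cfg: ScenarioConfig):
    if cfg.length_mode == "fixed":
        return FixedLength(cfg.fixed_length)
    return WeibullSurvival(WeibullModel(cfg.weibull_alpha, cfg.weibull_beta))


def _empty_like(vol: geo.PhaseVolume) -> geo.PhaseVolume:
    """Control domain: same grid, all hair-accessible pore space."""
    labels = np.full(vol.shape, geo.PORE, dtype=np.uint8)
    keep = vol.labels == geo.OUTSIDE
    labels[keep] = geo.OUTSIDE
    root = vol.labels == geo.ROOT
    labels[root] = geo.ROOT
    return dataclasses.replace(vol, labels=labels)


@dataclass
class ScenarioResult:
    volume: geo.PhaseVolume
    explicit_paths: list[list[HairPath]]
    control_paths: list[list[HairPath]]
    explicit_profiles: list[morph.LengthProfile]
    control_profiles: list[morph.LengthProfile]
    provenance: dict = field(default_factory=dict)


def run_scenario(cfg: ScenarioConfig, write: bool = True) -> ScenarioResult:
    """Run a full scenario; optionally write all products under cfg.outdir."""
    cfg.validate()
    log.info("scenario rng_seed=%d replicates=%d", cfg.rng_seed, cfg.replicates)
    vol = build_volume(cfg)
    surface_spec = parse_surface_spec(cfg.surface)
    surface = geo.extract_surface(vol, surface_spec)
    dmap = geo.distance_from_surface(vol, surface)
    control_vol = _empty_like(vol)
    mode = _length_mode(cfg)

    n_shells = None
    explicit_paths, control_paths = [], []
    explicit_profiles, control_profiles = [], []
    for rep in range(cfg.replicates):
        rep_seed = cfg.rng_seed + 1000 * rep
        rng = np.random.default_rng([rep_seed, 17])
        log.info("replicate %d seed=%d", rep, rep_seed)
        seeds = sample_transition_points(surface, cfg.density, rng, volume=vol)
        lengths = assign_lengths(seeds, mode, rng)
        gcfg = GrowthConfig(step_length=cfg.step_length, fan_size=cfg.fan_size,
                            bin_count=cfg.bin_count, condition_A=cfg.condition_A,
                            condition_F=cfg.condition_F, rng_seed=rep_seed)
        paths = grow_population(seeds, lengths, vol, gcfg)
        explicit_paths.append(paths)
        if n_shells is None:
            # shells spanning the deepest possible hair extent
            max_d = max((float(lv) for lv in lengths.total_lengths), default=0.0)
            n_shells = int(np.ceil(max(max_d, cfg.shell_width) / cfg.shell_width))
        prof = morph.length_profile(paths, dmap, vol, cfg.shell_width,
                                    n_shells=n_shells)
        explicit_profiles.append(prof)
        if cfg.run_control:
            cpaths = grow_population(seeds, lengths, control_vol, gcfg)
            control_paths.append(cpaths)
            cprof_tot = morph.length_profile(cpaths, dmap, control_vol,
                                             cfg.shell_width, n_shells=n_shells,
                                             wet=False)
            control_profiles.append(
                morph.control_wet_approximation(cprof_tot, vol))

    prov = {"config": dataclasses.asdict(cfg),
            "replicate_seeds": [cfg.rng_seed + 1000 * r
                                for r in range(cfg.replicates)]}
    result = ScenarioResult(vol, explicit_paths, control_paths,
                            explicit_profiles, control_profiles, prov)
    if write:
        _write_outputs(cfg, result)
    return result


def _write_outputs(cfg: ScenarioConfig, res: ScenarioResult) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "provenance.json").write_text(json.dumps(res.provenance, indent=1))
    for rep, paths in enumerate(res.explicit_paths):
        write_paths_csv(paths, out / f"explicit_paths_rep{rep}.csv")
        write_paths_vtk(paths, out / f"explicit_paths_rep{rep}.vtk")
        morph.write_profile_csv(res.explicit_profiles[rep],
                                out / f"explicit_profile_rep{rep}.csv")
    for rep, paths in enumerate(res.control_paths):
        write_paths_csv(paths, out / f"control_paths_rep{rep}.csv")
        morph.write_profile_csv(res.control_profiles[rep],
                                out / f"control_profile_rep{rep}.csv")
    if len(res.explicit_profiles) > 1:
        mean, sd = morph.replicate_statistics(res.explicit_profiles)
        prof0 = res.explicit_profiles[0]
        pd.DataFrame({"shell_lower_um": prof0.shell_edges[:-1],
                      "shell_upper_um": prof0.shell_edges[1:],
                      "L_tot_mean_um": mean,
                      "L_tot_sd_um": sd}).to_csv(
            out / "explicit_profile_mean_sd.csv", index=False)


SWEEPABLE = ("step_length", "fan_size", "bin_count")


def sweep(parameter: str, values, base: ScenarioConfig) -> pd.DataFrame:
    """Re-run a scenario across values of one growth parameter.

    Returns a table of total length, wet length and mean tortuosity per value.
    """
    if parameter not in SWEEPABLE:
        raise ConfigError(f"unknown sweep parameter {parameter!r}; "
                          f"choose from {SWEEPABLE}")
    values = list(values)
    if not values:
        raise ConfigError("empty sweep value list")
    rows = []
    for v in values:
        cfg = dataclasses.replace(base, **{parameter: v})
        res = run_scenario(cfg, write=False)
        paths = [p for rep in res.explicit_paths for p in rep]
        total = sum(p.achieved_length for p in paths)
        wet = float(sum(prof.L_wet.sum() for prof in res.explicit_profiles))
        torts = [morph.tortuosity(p) for p in paths]
        torts = [t for t in torts if np.isfinite(t)]
        rows.append({parameter: v, "total_length_um": total,
                     "wet_length_um": wet,
                     "mean_tortuosity": float(np.mean(torts)) if torts else np.nan})
    return pd.DataFrame(rows)
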