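"""End-to-end pipeline: generate → hbonds → layers → contact-area →
decompose → crossover, with a provenance manifest.

:class:`RunConfig` gathers every tunable with its conventional default;
the full parameter set is serialised into the manifest and into each
output's metadata so no run depends on hidden defaults.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .composite import DEFAULT_MODEL_KINDS, CompositeKind, fit_composite
from .crossover import fit_two_segment
from .curves import WATER_MOLECULAR_VOLUME_NM3
from .hbonds import HBondCriteria, PairClass, detect_hbonds, hbond_density
from .io import write_configuration
from .layers import (
    assign_layers,
    fit_double_gaussian,
    layer_volume_fractions,
    polymer_water_distances,
    population_histogram,
)
from .sasa import contact_area
from .synthetic import (
    ShellMixtureParams,
    generate_fraction_schedule,
    generate_hydrated_configuration,
    generate_polymer_configuration,
    generate_property_curve,
)

log = logging.getLogger("hydropol")

STAGES = ("generate", "hbonds", "layers", "contact_area", "decompose", "crossover")

# the RunConfig field named "property" shadows the builtin inside the class body
_builtin_property = property


@dataclass
class RunConfig:
    """All pipeline parameters, each with its conventional default."""

    output_dir: str = "hydropol_out"
    seed: int = 0

    # synthetic system
    n_chains: int = 5
    beads_per_chain: int = 100
    target_density: float = 1.3  # g/cm^3
    bead_mass: float = 132.1  # g/mol
    m_levels: tuple = (0.1, 0.2, 0.3, 0.4)
    shell_mean1: float = 0.28  # nm
    shell_sd1: float = 0.05
    shell_mean2: float = 0.56
    shell_sd2: float = 0.15
    shell_weight1: float = 0.6

    # hydrogen bonds
    r_max: float = 0.35  # nm
    alpha_max: float = 30.0  # degrees

    # hydration layers
    bin_width: float = 0.01  # nm
    d_max: float = 2.0  # nm
    cutoff_12: float = 0.45  # nm
    cutoff_2end: float = 2.0  # nm
    water_molar_volume: float = WATER_MOLECULAR_VOLUME_NM3  # nm^3

    # surface area
    probe_radius: float = 0.1  # nm
    n_sphere_points: int = 960

    # composite decomposition / crossover
    property: str = "Q"
    property_units: str = "kJ/kg"
    model_kind: str = ""  # empty -> default map for the property
    X_p: float = 3340.0
    X_w1: float = 1110.0
    X_w2: float = 2660.0
    curve_m_min: float = 0.0
    curve_m_max: float = 0.6
    curve_n_points: int = 25
    m_sat: float = 0.3
    f_w1_max: float = 0.2
    noise_relative: float = 0.01  # noise sd as a fraction of curve range

    def __post_init__(self) -> None:
        if not 0 < self.cutoff_12 < self.cutoff_2end:
            raise ValueError("need 0 < cutoff_12 < cutoff_2end")
        if self.bin_width <= 0 or self.d_max <= 0:
            raise ValueError("bin_width and d_max must be positive")
        if self.r_max <= 0 or not 0 < self.alpha_max < 180:
            raise ValueError("invalid hydrogen-bond criteria")
        if self.probe_radius < 0 or self.n_sphere_points < 12:
            raise ValueError("invalid surface-area parameters")
        self.m_levels = tuple(float(m) for m in self.m_levels)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @_builtin_property
    def shells(self) -> ShellMixtureParams:
        return ShellMixtureParams(
            self.shell_mean1, self.shell_sd1,
            self.shell_mean2, self.shell_sd2, self.shell_weight1,
        )

    def resolved_model_kind(self) -> CompositeKind:
        if self.model_kind:
            return CompositeKind.coerce(self.model_kind)
        return DEFAULT_MODEL_KINDS[self.property.upper()]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; return the manifest dict.

    Writes CSV/JSON artifacts under ``config.output_dir`` plus
    ``manifest.json`` recording parameters, versions and completed stages.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    manifest: dict = {
        "package": "hydropol",
        "version": __version__,
        "numpy": np.__version__,
        "parameters": config.to_dict(),
        "stages": {},
        "outputs": [],
    }
    rng = np.random.default_rng(config.seed)
    # full parameter set in every output header; output_dir excluded so
    # identical runs into different directories stay byte-identical
    meta = {k: v for k, v in config.to_dict().items()
            if isinstance(v, (int, float, str)) and k != "output_dir"}

    def out(name: str) -> str:
        path = os.path.join(config.output_dir, name)
        manifest["outputs"].append(name)
        return path

    def done(stage: str, t0: float) -> None:
        manifest["stages"][stage] = {"status": "complete", "seconds": round(time.time() - t0, 3)}
        log.info("stage %-13s complete in %.2f s", stage, time.time() - t0)

    # -- generate ------------------------------------------------------
    t0 = time.time()
    polymer = generate_polymer_configuration(
        config.n_chains, config.beads_per_chain, config.target_density,
        config.bead_mass, seed=int(rng.integers(2**31)),
    )
    v0 = polymer.box.volume
    write_configuration(polymer, out("polymer_dry.gro"))
    hydrated = {}
    for m in config.m_levels:
        cfg = generate_hydrated_configuration(
            polymer, m, config.shells, seed=int(rng.integers(2**31))
        )
        hydrated[m] = cfg
        write_configuration(cfg, out(f"hydrated_m{m:.2f}.gro"))
    done("generate", t0)

    # -- hbonds --------------------------------------------------------
    t0 = time.time()
    rows = []
    criteria = HBondCriteria(config.r_max, config.alpha_max)
    for m, cfg in hydrated.items():
        bonds = detect_hbonds(cfg, criteria)
        for pc in PairClass:
            count = sum(1 for b in bonds if b.pair_class == pc)
            rows.append({
                "m": m, "frame": 0, "class": pc.value, "count": count,
                "density_per_nm3": hbond_density(bonds, pc, v0),
            })
    _write_csv(pd.DataFrame(rows), out("hbonds.csv"), meta)
    done("hbonds", t0)

    # -- layers --------------------------------------------------------
    t0 = time.time()
    part_rows, dgd = [], {}
    for m, cfg in hydrated.items():
        d = polymer_water_distances(cfg)
        hist = population_histogram(d, config.bin_width, config.d_max, m=m)
        _write_csv(
            pd.DataFrame({"bin_center_nm": hist.bin_centers,
                          "population": hist.population}),
            out(f"histogram_m{m:.2f}.csv"), meta,
        )
        try:
            dgd[f"{m:.2f}"] = fit_double_gaussian(hist).to_dict()
        except (ValueError, RuntimeError) as exc:
            dgd[f"{m:.2f}"] = {"error": str(exc)}
        part = assign_layers(d, config.cutoff_12, config.cutoff_2end)
        f_p, f_w1, f_w2 = layer_volume_fractions(
            part, cfg.box.volume, config.water_molar_volume
        )
        part_rows.append({
            "m": m, "n_w1": part.n_w1, "n_w2": part.n_w2,
            "n_beyond": part.n_beyond, "f_p": f_p, "f_w1": f_w1, "f_w2": f_w2,
        })
    _write_csv(pd.DataFrame(part_rows), out("layers.csv"), meta)
    _write_json({"parameters": meta, "fits": dgd}, out("dgd.json"))
    done("layers", t0)

    # -- contact area --------------------------------------------------
    t0 = time.time()
    area_rows = []
    for m, cfg in hydrated.items():
        areas = contact_area(cfg, config.probe_radius, config.n_sphere_points)
        area_rows.append({"m": m, **areas.to_dict()})
    _write_csv(pd.DataFrame(area_rows), out("contact_area.csv"), meta)
    done("contact_area", t0)

    # -- decompose -----------------------------------------------------
    t0 = time.time()
    m_grid = np.linspace(config.curve_m_min, config.curve_m_max, config.curve_n_points)
    schedule = generate_fraction_schedule(
        m_grid, config.m_sat, config.f_w1_max, config.water_molar_volume,
        polymer_density=config.target_density,
    )
    schedule.to_csv(out("fraction_schedule.csv"))
    kind = config.resolved_model_kind()
    exact = generate_property_curve(
        kind, config.X_p, config.X_w1, config.X_w2, schedule, noise_sd=0.0,
        property=config.property, units=config.property_units,
    )
    noise_sd = config.noise_relative * float(np.ptp(exact.values))
    curve = generate_property_curve(
        kind, config.X_p, config.X_w1, config.X_w2, schedule,
        noise_sd=noise_sd, seed=int(rng.integers(2**31)),
        property=config.property, units=config.property_units,
    )
    curve.to_csv(out("property_curve.csv"))
    fit = fit_composite(kind, curve)
    _write_json({"parameters": meta, **fit.to_dict()}, out("composite_fit.json"))
    done("decompose", t0)

    # -- crossover -----------------------------------------------------
    t0 = time.time()
    xfit = fit_two_segment(curve, seed=int(rng.integers(2**31)))
    _write_json({"parameters": meta, **xfit.to_dict()}, out("crossover_fit.json"))
    done("crossover", t0)

    _write_json(manifest, os.path.join(config.output_dir, "manifest.json"))
    return manifest


def _write_csv(df: pd.DataFrame, path: str, meta: dict) -> None:
    with open(path, "w", newline="") as fh:
        for k in sorted(meta):
            fh.write(f"# {k} = {meta[k]}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _write_json(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
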