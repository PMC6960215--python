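"""Synthetic polymer/water configurations and property curves.

This module supplies inputs with the statistical structure the analysis
stages assume, so the whole pipeline is testable without running
molecular dynamics:

* coarse-grained self-avoiding polymer bead chains packed to a target dry
  density (default study conditions: 5 chains of 100 monomer beads at
  1.3 g/cm³ in a ~4.4 nm cubic periodic box);
* water placed so that the nearest-polymer distance d_pw of each oxygen
  follows a prescribed two-Gaussian shell mixture (defaults: shells at
  0.28 nm and 0.56 nm), realised by rejection sampling against the actual
  polymer geometry, hence exact in distribution up to geometric
  truncation;
* layer volume-fraction schedules in which the first layer saturates at a
  chosen moisture content (default m_sat = 0.3);
* property-vs-moisture curves from the mixture/parallel/series composite
  laws plus Gaussian noise, and plain noisy linear series for the
  estimator suite.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .composite import CompositeKind, composite_predict
from .curves import (
    FractionSchedule,
    PropertyCurve,
    WATER_MOLECULAR_VOLUME_NM3,
)
from .geometry import Box, Configuration, Role, WATER_MOLAR_MASS

__all__ = [
    "ShellMixtureParams",
    "HydrationReport",
    "PackingError",
    "generate_polymer_configuration",
    "generate_hydrated_configuration",
    "generate_fraction_schedule",
    "generate_property_curve",
    "generate_linear_series",
    "DEFAULT_SHELLS",
]

AVOGADRO = 6.02214076e23
NM3_PER_CM3 = 1e21

#: Monomer bead parameters: mass of an average anhydro-pentose unit and a
#: bead excluded-volume radius sized so chains pack easily at 1.3 g/cm³.
DEFAULT_BEAD_MASS = 132.1
DEFAULT_BEAD_RADIUS = 0.25
BOND_LENGTH = 0.4
MIN_NONBONDED = 0.35

WATER_OH_BOND = 0.1
WATER_HOH_ANGLE_DEG = 104.5


class PackingError(RuntimeError):
    """Requested density is not reachable for the chosen bead geometry."""


@dataclass(frozen=True)
class ShellMixtureParams:
    """Two-Gaussian mixture of nearest-polymer distances (nm)."""

    mean1: float = 0.28
    sd1: float = 0.05
    mean2: float = 0.56
    sd2: float = 0.15
    weight1: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.mean1 < self.mean2:
            raise ValueError("need 0 < mean1 < mean2")
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("shell widths must be positive")
        if not 0 <= self.weight1 <= 1:
            raise ValueError("weight1 must lie in [0, 1]")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        first = rng.random(n) < self.weight1
        d = np.where(
            first,
            rng.normal(self.mean1, self.sd1, n),
            rng.normal(self.mean2, self.sd2, n),
        )
        return d

    def pdf(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        g1 = np.exp(-0.5 * ((d - self.mean1) / self.sd1) ** 2) / (
            self.sd1 * math.sqrt(2 * math.pi)
        )
        g2 = np.exp(-0.5 * ((d - self.mean2) / self.sd2) ** 2) / (
            self.sd2 * math.sqrt(2 * math.pi)
        )
        return self.weight1 * g1 + (1 - self.weight1) * g2


DEFAULT_SHELLS = ShellMixtureParams()


@dataclass
class HydrationReport:
    """Bookkeeping of the water-placement rejection sampler."""

    n_water: int = 0
    n_redrawn: int = 0  # target distances abandoned after the retry cap
    distance_tolerance: float = 0.005


# ---------------------------------------------------------------------------
# polymer generator


def generate_polymer_configuration(
    n_chains: int,
    beads_per_chain: int,
    target_density: float = 1.3,
    bead_mass: float = DEFAULT_BEAD_MASS,
    seed: int = 0,
    *,
    bead_radius: float = DEFAULT_BEAD_RADIUS,
) -> Configuration:
    """Self-avoiding random-walk bead chains at a target dry density.

    The cubic periodic box edge is fixed by mass conservation:
    V = n·M_bead/(N_A·ρ), so the realised density matches
    ``target_density`` (g/cm³) exactly.  Chains are grown step by step
    with bond length 0.4 nm and a 0.35 nm excluded-volume distance to all
    non-bonded beads; growth that stalls restarts the chain, and a global
    attempt cap turns an infeasible packing into :class:`PackingError`.
    """
    if n_chains < 1 or beads_per_chain < 1:
        raise ValueError("chain counts must be positive")
    if target_density <= 0 or bead_mass <= 0:
        raise ValueError("density and bead mass must be positive")
    n = n_chains * beads_per_chain
    volume_nm3 = n * bead_mass / (AVOGADRO * target_density) * NM3_PER_CM3
    edge = volume_nm3 ** (1.0 / 3.0)
    box = Box((edge, edge, edge))

    # hard-sphere feasibility: random sequential packing stalls well below
    # the close-packing limit
    occupied = n * (4.0 / 3.0) * math.pi * (MIN_NONBONDED / 2) ** 3
    if occupied / volume_nm3 > 0.45:
        raise PackingError(
            f"target density {target_density} g/cm³ needs bead volume fraction "
            f"{occupied / volume_nm3:.2f}, beyond the random-packing limit"
        )

    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    L = np.array([edge] * 3)

    def clashes(p: np.ndarray, skip_last: bool) -> bool:
        if not placed:
            return False
        arr = np.asarray(placed if not skip_last else placed[:-1])
        if len(arr) == 0:
            return False
        d = p - arr
        d -= L * np.round(d / L)
        return bool(np.any(np.einsum("ij,ij->i", d, d) < MIN_NONBONDED**2))

    mol_ids = np.empty(n, dtype=np.int64)
    for chain in range(n_chains):
        for attempt in range(200):
            start_len = len(placed)
            p = rng.random(3) * edge
            tries = 0
            while clashes(p, skip_last=False):
                p = rng.random(3) * edge
                tries += 1
                if tries > 1000:
                    raise PackingError("cannot place chain start; box too dense")
            placed.append(p)
            ok = True
            for _ in range(beads_per_chain - 1):
                for step_try in range(150):
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    q = np.mod(placed[-1] + BOND_LENGTH * u, edge)
                    if not clashes(q, skip_last=True):
                        placed.append(q)
                        break
                else:
                    ok = False
                    break
            if ok:
                mol_ids[start_len : start_len + beads_per_chain] = chain
                break
            del placed[start_len:]  # restart this chain
        else:
            raise PackingError(
                f"chain {chain} could not be grown after 200 restarts; "
                "density too high for self-avoiding growth"
            )

    positions = np.asarray(placed)
    return Configuration(
        positions=positions,
        roles=np.full(n, int(Role.POLYMER), dtype=np.int8),
        box=box,
        elements=["X"] * n,
        vdw_radii=np.full(n, bead_radius),
        masses=np.full(n, bead_mass),
        molecule_ids=mol_ids,
    )


# ---------------------------------------------------------------------------
# hydration generator


def generate_hydrated_configuration(
    polymer: Configuration,
    m: float,
    shells: ShellMixtureParams = DEFAULT_SHELLS,
    seed: int = 0,
    *,
    max_retries: int = 1000,
    distance_tolerance: float = 0.005,
    report: HydrationReport | None = None,
) -> Configuration:
    """Insert water so d_pw follows the requested two-Gaussian shell mixture.

    N_w = round(m · M_polymer / 18.015) molecules are added.  For each, a
    target distance d is drawn from the mixture and uniform box points are
    rejection-sampled until one realises a nearest-polymer distance within
    ±``distance_tolerance`` of d — unbiased in d whatever the polymer
    geometry.  Targets still unrealised after a bounded candidate budget
    (64·``max_retries`` shared candidate points) are redrawn from the
    mixture (counted in ``report.n_redrawn``), which truncates the
    mixture to distances the realised geometry can offer.  Hydrogens
    are attached at 0.1 nm with the rigid-water 104.5° angle in a random
    orientation.
    """
    if m < 0:
        raise ValueError("moisture content must be non-negative")
    if m == 0:
        return polymer
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(seed)
    n_w = int(round(m * polymer.polymer_mass / WATER_MOLAR_MASS))
    if report is None:
        report = HydrationReport()
    report.n_water = n_w
    report.distance_tolerance = distance_tolerance
    if n_w == 0:
        return polymer

    box = polymer.box
    L = box.lengths_array
    tree = cKDTree(np.mod(polymer.positions, L), boxsize=L)

    targets = shells.sample(rng, n_w)
    targets = np.abs(targets)  # negative tail of shell 1 reflects to contact
    oxygens = np.empty((n_w, 3))
    pending = list(range(n_w))
    tries = np.zeros(n_w, dtype=int)
    batch = max(2048, 4 * n_w)
    while pending:
        cand = rng.random((batch, 3)) * L
        d_real, _ = tree.query(cand, k=1)
        order = np.argsort(d_real)
        d_sorted = d_real[order]
        used = np.zeros(batch, dtype=bool)
        still: list[int] = []
        for idx in pending:
            t = targets[idx]
            lo = np.searchsorted(d_sorted, t - distance_tolerance, side="left")
            hi = np.searchsorted(d_sorted, t + distance_tolerance, side="right")
            # closest unused candidate to the target, so the realised
            # distance is symmetric about t (no half-window bias)
            hit = -1
            best = np.inf
            for k in range(lo, hi):
                if not used[k] and abs(d_sorted[k] - t) < best:
                    best = abs(d_sorted[k] - t)
                    hit = k
            if hit >= 0:
                used[hit] = True
                oxygens[idx] = cand[order[hit]]
            else:
                tries[idx] += batch
                if tries[idx] >= max_retries * 64:
                    # unreachable distance: redraw the target from the mixture
                    targets[idx] = abs(shells.sample(rng, 1)[0])
                    tries[idx] = 0
                    report.n_redrawn += 1
                still.append(idx)
        pending = still

    return _attach_water(polymer, oxygens, rng)


def _attach_water(
    polymer: Configuration, oxygens: np.ndarray, rng: np.random.Generator
) -> Configuration:
    n_w = len(oxygens)
    half = math.radians(WATER_HOH_ANGLE_DEG) / 2.0
    pos = [polymer.positions]
    for i in range(n_w):
        # random molecular frame
        a = rng.normal(size=3)
        a /= np.linalg.norm(a)
        b = rng.normal(size=3)
        b -= a * np.dot(a, b)
        b /= np.linalg.norm(b)
        h1 = oxygens[i] + WATER_OH_BOND * (math.cos(half) * a + math.sin(half) * b)
        h2 = oxygens[i] + WATER_OH_BOND * (math.cos(half) * a - math.sin(half) * b)
        pos.append(np.stack([oxygens[i], h1, h2]))
    positions = np.vstack(pos)

    np_poly = polymer.n_atoms
    roles = np.concatenate(
        [
            polymer.roles,
            np.tile([int(Role.WATER_O), int(Role.WATER_H), int(Role.WATER_H)], n_w),
        ]
    )
    elements = list(polymer.elements) + ["O", "H", "H"] * n_w
    vdw = np.concatenate(
        [polymer.vdw_radii, np.tile([0.152, 0.120, 0.120], n_w)]
    )
    masses = np.concatenate(
        [polymer.masses, np.tile([15.999, 1.008, 1.008], n_w)]
    )
    start = int(polymer.molecule_ids.max()) + 1 if np_poly else 0
    mol = np.concatenate(
        [polymer.molecule_ids, np.repeat(np.arange(start, start + n_w), 3)]
    )
    return Configuration(
        positions=positions,
        roles=roles,
        box=polymer.box,
        elements=elements,
        vdw_radii=vdw,
        masses=masses,
        molecule_ids=mol,
        frame_index=polymer.frame_index,
    )


# ---------------------------------------------------------------------------
# fraction schedules and property curves


def generate_fraction_schedule(
    m_grid,
    m_sat: float = 0.3,
    f_w1_max: float = 0.2,
    water_molar_volume: float = WATER_MOLECULAR_VOLUME_NM3,
    *,
    polymer_density: float = 1.3,
) -> FractionSchedule:
    """Layer volume-fraction schedule with first-layer saturation at m_sat.

    The total water volume fraction is the secant linearisation
    f_w(m) = v(m_sat)/m_sat · m of the additive-volume fraction
    v(m) = (m/ρ_w)/(1/ρ_p + m/ρ_w) (specific volumes 1/ρ_p for polymer,
    v_w per molecule for water).  The first layer grows linearly and
    fills exactly at m_sat, f_w1 = f_w1_max·min(m, m_sat)/m_sat, staying
    flat above; the second layer carries the rest — a small linear trickle
    before saturation, all new water after.  Every fraction is therefore
    piecewise linear in m with a single break at m_sat, which is the
    two-regime structure the schedule is meant to emulate: any property
    generated from it by an arithmetic-mean composite law is exactly two
    linear regimes meeting at m_sat.
    """
    m = np.asarray(m_grid, dtype=float)
    if np.any(m < 0) or np.any(np.diff(m) <= 0):
        raise ValueError("m_grid must be non-negative and strictly increasing")
    if not 0 < f_w1_max < 1:
        raise ValueError("f_w1_max must lie in (0, 1)")
    if m_sat <= 0:
        raise ValueError("m_sat must be positive")

    # additive-volume water fraction at saturation, with the water density
    # implied by the molecular volume; its secant sets the linear slope
    water_density = WATER_MOLAR_MASS / (AVOGADRO * water_molar_volume) * NM3_PER_CM3
    v_sat = (m_sat / water_density) / (1.0 / polymer_density + m_sat / water_density)
    if f_w1_max > v_sat:
        raise ValueError(
            f"f_w1_max={f_w1_max} exceeds the total water volume fraction "
            f"{v_sat:.4f} at m_sat={m_sat}; the first layer could not fill by m_sat"
        )
    f_w_total = (v_sat / m_sat) * m
    if np.any(f_w_total >= 1):
        raise ValueError("water volume fraction reaches 1 on the grid")
    f_w1 = f_w1_max * np.minimum(m, m_sat) / m_sat
    f_w2 = f_w_total - f_w1
    f_p = 1.0 - f_w1 - f_w2
    if np.any(f_w1 + f_w2 >= 1):
        raise ValueError("water fractions reach 1; schedule is unphysical")
    return FractionSchedule(
        m, f_p, f_w1, f_w2,
        metadata={
            "m_sat": m_sat,
            "f_w1_max": f_w1_max,
            "water_molar_volume_nm3": water_molar_volume,
            "polymer_density_g_cm3": polymer_density,
        },
    )


def generate_property_curve(
    model_kind,
    X_p: float,
    X_w1: float,
    X_w2: float,
    schedule: FractionSchedule,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    property: str = "",
    units: str = "",
) -> PropertyCurve:
    """Composite-model property curve over a fraction schedule plus noise.

    ``noise_sd`` (same units as the property) adds independent zero-mean
    Gaussian noise; zero gives the exact model values.
    """
    kind = CompositeKind.coerce(model_kind)
    values = np.asarray(
        composite_predict(
            kind, X_p, X_w1, X_w2, schedule.f_p, schedule.f_w1, schedule.f_w2
        )
    ).reshape(-1)
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, len(values))
    return PropertyCurve(
        schedule.m_grid,
        values,
        property=property,
        units=units,
        fractions=schedule,
        metadata={
            "model_kind": kind.value,
            "X_p": X_p, "X_w1": X_w1, "X_w2": X_w2,
            "noise_sd": noise_sd, "seed": seed,
        },
    )


def generate_linear_series(
    slope: float, intercept: float, x_grid, noise_sd: float = 0.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """y = slope·x + intercept (+ Gaussian noise); fixture for the estimators."""
    x = np.asarray(x_grid, dtype=float)
    if len(x) == 0:
        raise ValueError("x_grid must be non-empty")
    y = slope * x + intercept
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, len(x))
    return x, y
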