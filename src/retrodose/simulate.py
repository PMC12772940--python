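"""Monte Carlo conditional concentration distributions P(C | scenario).

For each scenario the simulator draws virtual patients from the population
model, evaluates the model concentration at the sampling time under the
scenario-edited dose history, and perturbs it with residual unexplained
variability (RUV):  C_obs = C_pred * (1 + eps_prop) + eps_add, negatives
truncated to zero. Defaults follow the idealized study conditions: 40,000
virtual patients per scenario and near-negligible RUV (additive 0.01 mg/L,
proportional 0.1%).

With common random numbers (the default) the identical eta and epsilon draws
are reused across scenarios, so paired per-patient differences reflect the
dosing scenario alone.

The conditional density is a Gaussian kernel estimate on log-transformed
positive samples (Silverman bandwidth, back-transformed), with an explicit
probability mass for samples below a near-zero floor — fully-missed scenarios
with tiny RUV concentrate there — and an exact point mass in the degenerate
no-variability case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .model import Patient, PopPKModelSpec
from .pk import DoseHistory, concentration_many, sample_individuals
from .scenarios import Scenario, ScenarioSet, scenario_history

__all__ = [
    "SimulationSettings",
    "ConditionalSamples",
    "DensityEstimate",
    "simulate_conditional",
    "simulate_scenarios",
    "estimate_density",
    "estimate_densities",
    "shared_grid",
]

#: default number of linearly spaced posterior-grid points
GRID_POINTS = 512


@dataclass(frozen=True)
class SimulationSettings:
    """Monte Carlo settings; defaults are the idealized study conditions."""

    n_virtual: int = 40_000
    seed: int = 0
    ruv_add: float = 0.01  # mg/L
    ruv_prop: float = 0.001  # fraction (0.1%)
    sampling_offset: float = 0.0  # h relative to the next scheduled dose
    common_random_numbers: bool = True
    grid_points: int = GRID_POINTS

    def __post_init__(self) -> None:
        if self.n_virtual < 1:
            raise ValueError("n_virtual must be >= 1")
        if self.ruv_add < 0 or self.ruv_prop < 0:
            raise ValueError("RUV magnitudes must be >= 0")

    @property
    def zero_floor(self) -> float:
        """Concentrations below this are pooled into the near-zero mass."""
        return max(2.0 * self.ruv_add, 1e-3)


@dataclass
class ConditionalSamples:
    """Monte Carlo concentration draws for one scenario (mg/L)."""

    bits: str
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")


def _streams(settings: SimulationSettings, scenario: Scenario):
    """Per-scenario RNGs derived from the root seed.

    With common random numbers every scenario sees the same eta/epsilon
    streams; otherwise streams are keyed by the scenario's canonical index so
    results do not depend on the order scenarios are simulated in.
    """
    key = 0 if settings.common_random_numbers else scenario.index + 1
    eta_rng = np.random.default_rng(np.random.SeedSequence((settings.seed, key, 0)))
    eps_rng = np.random.default_rng(np.random.SeedSequence((settings.seed, key, 1)))
    return eta_rng, eps_rng


def simulate_conditional(
    spec: PopPKModelSpec,
    patient: Patient,
    base: DoseHistory,
    scenario: Scenario,
    settings: SimulationSettings,
) -> ConditionalSamples:
    """Sample the observed-concentration distribution under one scenario."""
    t_sample = base.sampling_time + settings.sampling_offset
    if t_sample <= base.events[0].time:
        raise ValueError("sampling time falls before the first dose")
    eta_rng, eps_rng = _streams(settings, scenario)
    sample = sample_individuals(spec, patient, settings.n_virtual, eta_rng)
    history = scenario_history(base, scenario)
    c_pred = concentration_many(sample.arrays, history.events, t_sample, spec.structure)
    eps_prop = eps_rng.normal(0.0, settings.ruv_prop, size=settings.n_virtual)
    eps_add = eps_rng.normal(0.0, settings.ruv_add, size=settings.n_virtual)
    c_obs = np.maximum(c_pred * (1.0 + eps_prop) + eps_add, 0.0)
    return ConditionalSamples(scenario.bits, c_obs)


def simulate_scenarios(
    spec: PopPKModelSpec,
    patient: Patient,
    base: DoseHistory,
    sset: ScenarioSet,
    settings: SimulationSettings,
) -> list[ConditionalSamples]:
    """Simulate every scenario in the set (shared draws under CRN)."""
    return [simulate_conditional(spec, patient, base, s, settings) for s in sset]


# ---------------------------------------------------------------------------
# Density estimation
# ---------------------------------------------------------------------------


@dataclass
class DensityEstimate:
    """Estimated conditional density of the observed concentration.

    ``values`` is the continuous part on ``grid`` and integrates (trapezoid)
    to ``1 - zero_mass - sum(atoms)``. ``zero_mass`` is the probability of
    falling below ``zero_floor``, treated as uniform on ``[0, zero_floor)``
    when a density value is needed. ``atoms`` holds exact point masses from
    degenerate (no-variability) distributions.
    """

    bits: str
    grid: np.ndarray
    values: np.ndarray
    zero_mass: float = 0.0
    zero_floor: float = 1e-3
    atoms: dict[float, float] = field(default_factory=dict)
    degenerate: bool = False

    def continuous_at(self, c: float | np.ndarray) -> float | np.ndarray:
        """Continuous density at ``c``: KDE part plus the near-zero uniform."""
        v = np.interp(c, self.grid, self.values, left=0.0, right=0.0)
        if self.zero_mass > 0:
            v = v + np.where(np.asarray(c) < self.zero_floor, self.zero_mass / self.zero_floor, 0.0)
        return v

    def atom_at(self, c: float, rtol: float = 1e-9) -> float:
        """Exact point-mass probability matching ``c`` (0 when none)."""
        for value, prob in self.atoms.items():
            if abs(c - value) <= rtol * max(1.0, abs(value), abs(c)):
                return prob
        return 0.0

    def total_mass(self) -> float:
        return float(
            np.trapezoid(self.values, self.grid) + self.zero_mass + sum(self.atoms.values())
        )


def shared_grid(samples: Sequence[ConditionalSamples], settings: SimulationSettings) -> np.ndarray:
    """Linear grid from 0 to 1.1x the largest sample over all scenarios."""
    top = max(float(s.concentrations.max()) for s in samples)
    if top <= 0:
        top = settings.zero_floor
    return np.linspace(0.0, 1.1 * top, settings.grid_points)


def estimate_density(
    samples: ConditionalSamples,
    grid: np.ndarray,
    settings: SimulationSettings,
) -> DensityEstimate:
    """Kernel density estimate of one scenario's concentration distribution."""
    c = samples.concentrations
    if len(c) < 100:
        raise ValueError("density estimation needs at least 100 samples")
    floor = settings.zero_floor
    # Degenerate distribution (no BSV, no RUV): exact point mass.
    if float(c.max()) - float(c.min()) <= 1e-12 * max(1.0, float(c.max())):
        value = float(c[0])
        return DensityEstimate(
            samples.bits,
            grid,
            np.zeros_like(grid),
            zero_floor=floor,
            atoms={value: 1.0},
            degenerate=True,
        )
    positive = c[c >= floor]
    zero_mass = 1.0 - len(positive) / len(c)
    values = np.zeros_like(grid)
    if len(positive) >= 2 and float(positive.max()) > float(positive.min()):
        kde = gaussian_kde(np.log(positive), bw_method="silverman")
        pos = grid > 0
        with np.errstate(under="ignore"):
            values[pos] = kde(np.log(grid[pos])) / grid[pos] * (1.0 - zero_mass)
    elif len(positive):
        # all surviving samples identical: narrow atom above the floor
        return DensityEstimate(
            samples.bits,
            grid,
            values,
            zero_mass=zero_mass,
            zero_floor=floor,
            atoms={float(positive[0]): 1.0 - zero_mass},
            degenerate=True,
        )
    return DensityEstimate(samples.bits, grid, values, zero_mass=zero_mass, zero_floor=floor)


def estimate_densities(
    samples: Sequence[ConditionalSamples],
    settings: SimulationSettings,
    grid: Optional[np.ndarray] = None,
) -> list[DensityEstimate]:
    """Densities for all scenarios on one shared grid."""
    if grid is None:
        grid = shared_grid(samples, settings)
    return [estimate_density(s, grid, settings) for s in samples]
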