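"""Scenario posteriors, discrimination thresholds, and retrodiction labels.

The posterior over dosing scenarios at an observed concentration C is

    P(w_j | C) = P(w_j) * P(C | w_j) / P(C),     P(C) = sum_j P(w_j) P(C | w_j)

with the conditional densities estimated by Monte Carlo simulation. The
concentration at which two adjacent scenarios' posteriors are equal is the
discrimination threshold between them; the most-probable-scenario partition
of the concentration axis is the clinical readout (e.g. "below 3 mg/L the
most probable behaviour is missing both recent doses").

Retrodiction labels follow the 80% rule: *complete* when every scenario's
posterior curve peaks at or above the cutoff, *none* when at most one does,
*partial* otherwise.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import Patient, PopPKModelSpec, spec_hash
from .pk import DoseHistory, Regimen, steady_state_history
from .scenarios import ScenarioSet, assign_priors, enumerate_scenarios
from .simulate import (
    ConditionalSamples,
    DensityEstimate,
    SimulationSettings,
    estimate_densities,
    simulate_scenarios,
)

__all__ = [
    "PosteriorCurves",
    "ThresholdSet",
    "RetrodictionResult",
    "AdherenceAssessment",
    "posterior_at",
    "posterior_curves",
    "find_thresholds",
    "classify_retrodiction",
    "analyze",
    "assess",
    "AnalysisResult",
]

#: grid points whose marginal falls below this fraction of the peak marginal
#: are treated as data-unsupported (posteriors there are tail-noise artifacts);
#: 1e-6 keeps roughly the +-5-sigma span of each scenario cluster
MARGINAL_SUPPORT_FRAC = 1e-6

#: posterior cutoff defining the retrodiction taxonomy
RETRODICTION_CUTOFF = 0.8


class UndefinedPosteriorError(ValueError):
    """Marginal P(C) is zero at the observed concentration.

    The observation lies outside the support of every scenario's simulated
    distribution; raising the residual-error magnitudes widens the supports.
    """


def posterior_at(
    c: float,
    priors: Sequence[float],
    densities: Sequence[DensityEstimate],
) -> np.ndarray:
    """Posterior probability vector at a single concentration.

    Point masses are handled exactly: when any scenario carries an atom at
    ``c``, only atoms contribute (a continuous density has zero probability
    of producing the atom's exact value).

    Raises :class:`UndefinedPosteriorError` when every likelihood is zero.
    """
    priors = np.asarray(priors, dtype=float)
    atom_lik = np.array([d.atom_at(c) for d in densities])
    if np.any(atom_lik > 0):
        lik = atom_lik
    else:
        lik = np.array([float(d.continuous_at(c)) for d in densities])
    marginal = float(np.dot(priors, lik))
    if marginal <= 0.0:
        raise UndefinedPosteriorError(
            f"P(C) = 0 at C = {c:g} mg/L: the observation is outside every "
            "scenario's simulated support; consider increasing the RUV settings"
        )
    return priors * lik / marginal


@dataclass
class PosteriorCurves:
    """Posterior-vs-concentration curves for all scenarios on a shared grid."""

    grid: np.ndarray
    posteriors: np.ndarray  # (n_scenarios, n_grid)
    marginal: np.ndarray  # (n_grid,)
    bits: list[str]
    priors: np.ndarray
    defined: np.ndarray  # marginal > 0
    supported: np.ndarray  # marginal above the support floor

    def curve(self, bits: str) -> np.ndarray:
        return self.posteriors[self.bits.index(bits)]

    def max_posteriors(self, supported_only: bool = True) -> dict[str, float]:
        """Per-scenario maximum posterior over the (supported) grid."""
        mask = self.supported if supported_only else self.defined
        out = {}
        for i, b in enumerate(self.bits):
            vals = self.posteriors[i][mask]
            out[b] = float(vals.max()) if len(vals) else 0.0
        return out


def posterior_curves(sset: ScenarioSet, densities: Sequence[DensityEstimate]) -> PosteriorCurves:
    """Apply the posterior pointwise along the shared concentration grid.

    Atoms are folded onto their nearest grid point as ``prob / dgrid`` spikes
    so degenerate scenarios remain visible on the curves. Grid points where
    the marginal vanishes are masked (posterior NaN).
    """
    grids = [d.grid for d in densities]
    if any(len(g) != len(grids[0]) or not np.array_equal(g, grids[0]) for g in grids):
        raise ValueError("all densities must share one grid")
    if [d.bits for d in densities] != sset.bits:
        raise ValueError("densities must be ordered like the scenario set")
    grid = grids[0]
    dgrid = grid[1] - grid[0]
    priors = np.asarray(sset.priors())
    lik = np.zeros((len(densities), len(grid)))
    for i, d in enumerate(densities):
        lik[i] = d.continuous_at(grid)
        for value, prob in d.atoms.items():
            j = int(np.argmin(np.abs(grid - value)))
            lik[i, j] += prob / dgrid
    marginal = priors @ lik
    defined = marginal > 0.0
    supported = marginal >= MARGINAL_SUPPORT_FRAC * float(marginal.max())
    post = np.full_like(lik, np.nan)
    post[:, defined] = (priors[:, None] * lik)[:, defined] / marginal[defined]
    return PosteriorCurves(grid, post, marginal, list(sset.bits), priors, defined, supported)


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------


@dataclass
class ThresholdSet:
    """Crossings between adjacent most-probable scenarios and the partition.

    ``partition`` lists ``(bits, c_low, c_high)`` intervals in increasing
    concentration order; ``crossings`` holds ``((bits_low, bits_high), c*)``
    for each interior boundary. ``degenerate`` flags tie-dominated curves
    (indistinguishable scenarios).
    """

    crossings: list[tuple[tuple[str, str], float]]
    partition: list[tuple[str, float, float]]
    degenerate: bool = False
    absent: list[str] = field(default_factory=list)

    @property
    def lowest(self) -> Optional[float]:
        """The smallest crossing concentration (reference for sweeps)."""
        return min((c for _, c in self.crossings), default=None)


def _argmax_with_ties(post_col: np.ndarray) -> int:
    """Index of the most probable scenario; ties go to the lower bitstring.

    Scenario order is lexicographic, so the first maximal index *is* the
    lower bitstring (more missed doses) — conservative toward nonadherence.
    """
    return int(np.argmax(post_col))


def find_thresholds(curves: PosteriorCurves, tie_tol: float = 1e-9) -> ThresholdSet:
    """Derive discrimination thresholds from posterior curves.

    Works on the data-supported part of the grid: for each boundary between
    consecutive most-probable scenarios, the crossing concentration is found
    by linear interpolation of the posterior difference between the two
    bracketing grid points.
    """
    idx = np.where(curves.supported)[0]
    if len(idx) == 0:
        return ThresholdSet([], [], degenerate=True, absent=list(curves.bits))
    winners = np.array([_argmax_with_ties(curves.posteriors[:, j]) for j in idx])
    # tie detection: top-two posteriors equal within tolerance everywhere
    ties = 0
    for j in idx:
        col = np.sort(curves.posteriors[:, j])[::-1]
        if len(col) > 1 and col[0] - col[1] <= tie_tol:
            ties += 1
    degenerate = ties >= 0.9 * len(idx)

    partition: list[tuple[str, float, float]] = []
    crossings: list[tuple[tuple[str, str], float]] = []
    start = 0
    for k in range(1, len(idx) + 1):
        if k == len(idx) or winners[k] != winners[start]:
            bits = curves.bits[winners[start]]
            lo = float(curves.grid[idx[start]])
            hi = float(curves.grid[idx[k - 1]])
            partition.append((bits, lo, hi))
            if k < len(idx):
                a, b = winners[start], winners[k]
                j0, j1 = idx[k - 1], idx[k]
                d0 = curves.posteriors[a, j0] - curves.posteriors[b, j0]
                d1 = curves.posteriors[a, j1] - curves.posteriors[b, j1]
                if np.isfinite(d0) and np.isfinite(d1) and (d0 - d1) != 0:
                    frac = d0 / (d0 - d1)
                else:
                    frac = 0.5
                c_star = float(curves.grid[j0] + frac * (curves.grid[j1] - curves.grid[j0]))
                crossings.append(((curves.bits[a], curves.bits[b]), c_star))
            start = k
    present = {p[0] for p in partition}
    absent = [b for b in curves.bits if b not in present]
    return ThresholdSet(crossings, partition, degenerate=degenerate, absent=absent)


def curves_sup_distance(
    a: PosteriorCurves, b: PosteriorCurves, mass_frac: float = 0.95
) -> float:
    """Sup-norm distance between two sets of posterior curves.

    Curves are compared scenario-by-scenario over the central ``mass_frac``
    of ``a``'s marginal probability mass (``b`` linearly interpolated onto
    ``a``'s grid). Restricting to the data-supported core is essential: in
    the tails the marginal is driven by a handful of extreme Monte Carlo
    samples and no estimator is stable there; the central 95% of the mass is
    the region where kernel estimates at these sample sizes are reproducible.
    """
    if a.bits != b.bits:
        raise ValueError("curve sets describe different scenario sets")
    w = np.nan_to_num(a.marginal)
    cdf = np.cumsum(w)
    cdf = cdf / cdf[-1]
    tail = (1.0 - mass_frac) / 2.0
    lo, hi = np.searchsorted(cdf, [tail, 1.0 - tail])
    sel = slice(lo, min(hi + 1, len(a.grid)))
    ok_b = np.nan_to_num(b.marginal) > 0
    worst = 0.0
    for i in range(len(a.bits)):
        yb = np.interp(a.grid[sel], b.grid[ok_b], b.posteriors[i][ok_b])
        ya = a.posteriors[i][sel]
        good = np.isfinite(ya)
        if np.any(good):
            worst = max(worst, float(np.max(np.abs(ya[good] - yb[good]))))
    return worst


def pairwise_crossings(curves: PosteriorCurves) -> dict[tuple[str, str], list[float]]:
    """Diagnostic: every concentration where any two posterior curves cross."""
    out: dict[tuple[str, str], list[float]] = {}
    idx = np.where(curves.supported)[0]
    for a in range(len(curves.bits)):
        for b in range(a + 1, len(curves.bits)):
            diff = curves.posteriors[a, idx] - curves.posteriors[b, idx]
            sign = np.sign(diff)
            roots = []
            for k in np.where(np.diff(sign) != 0)[0]:
                j0, j1 = idx[k], idx[k + 1]
                d0, d1 = diff[k], diff[k + 1]
                frac = d0 / (d0 - d1) if d0 != d1 else 0.5
                roots.append(float(curves.grid[j0] + frac * (curves.grid[j1] - curves.grid[j0])))
            if roots:
                out[(curves.bits[a], curves.bits[b])] = roots
    return out


# ---------------------------------------------------------------------------
# Retrodiction classification
# ---------------------------------------------------------------------------


@dataclass
class RetrodictionResult:
    label: str  # complete | partial | none
    max_posterior: dict[str, float]
    cutoff: float


def classify_retrodiction(
    curves: PosteriorCurves, cutoff: float = RETRODICTION_CUTOFF
) -> RetrodictionResult:
    """Apply the cutoff rule to the per-scenario posterior maxima.

    complete: every scenario peaks at >= cutoff somewhere on the grid;
    none: at most one scenario does; partial: anything in between.
    """
    maxima = curves.max_posteriors()
    n_reached = sum(1 for v in maxima.values() if v >= cutoff)
    if n_reached == len(maxima):
        label = "complete"
    elif n_reached <= 1:
        label = "none"
    else:
        label = "partial"
    return RetrodictionResult(label, maxima, cutoff)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class AnalysisResult:
    """Everything one pipeline run produces."""

    sset: ScenarioSet
    base: DoseHistory
    samples: list[ConditionalSamples]
    densities: list[DensityEstimate]
    curves: PosteriorCurves
    thresholds: ThresholdSet
    retrodiction: RetrodictionResult
    settings: SimulationSettings


def analyze(
    spec: PopPKModelSpec,
    patient: Patient,
    regimen: Regimen,
    n: int,
    settings: Optional[SimulationSettings] = None,
    prior_mode: str = "equal",
    prior_p: Optional[float] = None,
    prior_table: Optional[dict[str, float]] = None,
) -> AnalysisResult:
    """Run the whole chain: scenarios -> simulation -> densities -> posterior."""
    settings = settings or SimulationSettings()
    sset = assign_priors(enumerate_scenarios(n), prior_mode, p=prior_p, table=prior_table)
    base = steady_state_history(spec, patient, regimen, n)
    samples = simulate_scenarios(spec, patient, base, sset, settings)
    densities = estimate_densities(samples, settings)
    curves = posterior_curves(sset, densities)
    return AnalysisResult(
        sset,
        base,
        samples,
        densities,
        curves,
        find_thresholds(curves),
        classify_retrodiction(curves),
        settings,
    )


@dataclass
class AdherenceAssessment:
    """Posterior over scenarios for one observed TDM concentration."""

    observed_c: float
    posterior: dict[str, float]
    most_likely: str
    ties: list[str]
    priors: dict[str, float]
    undefined: bool
    settings_hash: str
    analysis: Optional[AnalysisResult] = None


def assess(
    observed_c: float,
    spec: PopPKModelSpec,
    patient: Patient,
    regimen: Regimen,
    n: int,
    settings: Optional[SimulationSettings] = None,
    prior_mode: str = "equal",
    prior_p: Optional[float] = None,
    prior_table: Optional[dict[str, float]] = None,
    keep_analysis: bool = True,
) -> AdherenceAssessment:
    """Assess one observed trough concentration against all 2^n scenarios.

    When the observation falls outside every scenario's simulated support the
    assessment is returned flagged ``undefined`` (posterior all NaN) together
    with the advisory to raise the RUV settings.
    """
    if observed_c < 0:
        raise ValueError("observed concentration must be >= 0")
    settings = settings or SimulationSettings()
    result = analyze(
        spec, patient, regimen, n, settings, prior_mode, prior_p, prior_table
    )
    payload = (
        spec_hash(spec),
        patient.descriptor_hash(),
        regimen.dose,
        regimen.interval,
        n,
        prior_mode,
        prior_p,
        tuple(sorted((prior_table or {}).items())),
        settings,
    )
    shash = hashlib.sha256(repr(payload).encode()).hexdigest()[:12]
    priors = dict(zip(result.sset.bits, result.sset.priors()))
    try:
        post = posterior_at(observed_c, result.sset.priors(), result.densities)
    except UndefinedPosteriorError:
        return AdherenceAssessment(
            observed_c,
            {b: float("nan") for b in result.sset.bits},
            most_likely="undefined",
            ties=[],
            priors=priors,
            undefined=True,
            settings_hash=shash,
            analysis=result if keep_analysis else None,
        )
    top = float(post.max())
    tied = [b for b, v in zip(result.sset.bits, post) if top - v <= 1e-9]
    return AdherenceAssessment(
        observed_c,
        {b: float(v) for b, v in zip(result.sset.bits, post)},
        most_likely=tied[0],  # lower bitstring wins ties (conservative)
        ties=tied if len(tied) > 1 else [],
        priors=priors,
        undefined=False,
        settings_hash=shash,
        analysis=result if keep_analysis else None,
    )
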