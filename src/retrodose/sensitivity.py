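"""Critical-factor sweeps and the retrodiction summary table.

Each sweep re-runs the full pipeline per factor level with the same root
seed (common random numbers across levels), so level-to-level differences
isolate the factor from Monte Carlo noise. Threshold shifts are reported
against the lowest crossing (the boundary between the two most-nonadherent
scenarios) as ``(T_level - T_ref) / T_ref * 100``.

Supported factors mirror the clinically relevant perturbations: renal
function (eGFR), comedication tags (enzyme inducers/inhibitors), dosing
interval at constant daily dose (immediate- vs extended-release), sampling
time relative to the scheduled trough, per-dose prior adherence probability,
and proportional residual error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd

from .model import Patient, PopPKModelSpec
from .pk import Regimen
from .posterior import AnalysisResult, RetrodictionResult, ThresholdSet, analyze
from .simulate import SimulationSettings

__all__ = ["BaseConfig", "SweepResult", "sweep_factor", "retrodiction_table", "SWEEPABLE_FACTORS"]

SWEEPABLE_FACTORS = ("eGFR", "comedication", "interval", "sampling_offset", "prior_p", "ruv_prop")


@dataclass
class BaseConfig:
    """Reference configuration a sweep perturbs one factor of."""

    spec: PopPKModelSpec
    patient: Patient
    regimen: Regimen
    n: int = 2
    prior_mode: str = "equal"
    prior_p: Optional[float] = None
    settings: SimulationSettings = field(default_factory=SimulationSettings)

    def run(self) -> AnalysisResult:
        return analyze(
            self.spec,
            self.patient,
            self.regimen,
            self.n,
            self.settings,
            self.prior_mode,
            self.prior_p,
        )


@dataclass
class SweepResult:
    factor: str
    levels: list
    reference_level: object
    thresholds: list[ThresholdSet]
    retrodiction: list[RetrodictionResult]
    threshold_value: list[Optional[float]]  # lowest crossing per level
    relative_change_pct: list[Optional[float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "factor": self.factor,
                "level": [str(l) for l in self.levels],
                "threshold_mg_L": self.threshold_value,
                "relative_change_pct": self.relative_change_pct,
                "retrodiction": [r.label for r in self.retrodiction],
                "n_crossings": [len(t.crossings) for t in self.thresholds],
            }
        )


def _has_covariate(spec: PopPKModelSpec, name: str) -> bool:
    return any(rel.covariate == name for rel in spec.covariates)


def _config_at_level(base: BaseConfig, factor: str, level) -> BaseConfig:
    if factor == "eGFR":
        if not _has_covariate(base.spec, "eGFR"):
            raise ValueError(
                f"spec {base.spec.drug_name!r} declares no eGFR covariate relation; "
                "an eGFR sweep is not meaningful"
            )
        return replace(base, patient=base.patient.model_copy(update={"eGFR": float(level)}))
    if factor == "comedication":
        tag = None if level in (None, "none") else str(level)
        if tag is not None and not _has_covariate(base.spec, tag):
            raise ValueError(
                f"spec {base.spec.drug_name!r} declares no covariate relation for "
                f"comedication tag {tag!r}"
            )
        comeds = set() if tag is None else {tag}
        return replace(base, patient=base.patient.model_copy(update={"comedications": comeds}))
    if factor == "interval":
        # constant daily dose: dose scales with the interval (q12h -> q24h doubles it)
        interval = float(level)
        dose = base.regimen.dose * interval / base.regimen.interval
        return replace(base, regimen=Regimen(dose, interval))
    if factor == "sampling_offset":
        return replace(base, settings=replace(base.settings, sampling_offset=float(level)))
    if factor == "prior_p":
        p = float(level)
        return replace(base, prior_mode="per_dose", prior_p=p)
    if factor == "ruv_prop":
        return replace(base, settings=replace(base.settings, ruv_prop=float(level)))
    raise ValueError(f"unsupported sweep factor {factor!r}; choose from {SWEEPABLE_FACTORS}")


_DEFAULT_REFERENCE = {
    "eGFR": lambda b: b.patient.eGFR,
    "comedication": lambda b: None,
    "interval": lambda b: b.regimen.interval,
    "sampling_offset": lambda b: b.settings.sampling_offset,
    "prior_p": lambda b: 0.5,
    "ruv_prop": lambda b: b.settings.ruv_prop,
}


def sweep_factor(
    factor: str,
    levels: Sequence,
    base: BaseConfig,
    reference_level=None,
) -> SweepResult:
    """Re-run the pipeline per level and report threshold shifts and labels.

    The reference level defaults to the base configuration's own value of the
    factor; when that value is not among ``levels`` the first level is used.
    """
    if factor not in SWEEPABLE_FACTORS:
        raise ValueError(f"unsupported sweep factor {factor!r}; choose from {SWEEPABLE_FACTORS}")
    levels = list(levels)
    if reference_level is None:
        reference_level = _DEFAULT_REFERENCE[factor](base)
        if reference_level not in levels:
            reference_level = levels[0]
    elif reference_level not in levels:
        raise ValueError("reference_level must be one of the swept levels")

    results = {}
    for level in levels:
        results[level] = _config_at_level(base, factor, level).run()
    if reference_level not in results:
        results[reference_level] = _config_at_level(base, factor, reference_level).run()

    t_ref = results[reference_level].thresholds.lowest
    thresholds, retro, tvals, rel = [], [], [], []
    for level in levels:
        res = results[level]
        thresholds.append(res.thresholds)
        retro.append(res.retrodiction)
        t = res.thresholds.lowest
        tvals.append(t)
        if t is None or t_ref is None or t_ref == 0:
            rel.append(None)
        else:
            rel.append((t - t_ref) / t_ref * 100.0)
    return SweepResult(factor, levels, reference_level, thresholds, retro, tvals, rel)


def retrodiction_table(
    specs: Sequence[PopPKModelSpec],
    patients: dict[str, Patient],
    ns: Sequence[int],
    regimens: Regimen | dict[str, Regimen],
    settings: Optional[SimulationSettings] = None,
) -> pd.DataFrame:
    """Grid of retrodiction labels per (drug, population, scenario depth).

    ``regimens`` is either one regimen for every spec or a mapping keyed by
    ``drug_name``. Returns a tidy DataFrame with one row per combination,
    suitable for ``to_csv``.
    """
    settings = settings or SimulationSettings()
    rows = []
    for spec in specs:
        regimen = regimens[spec.drug_name] if isinstance(regimens, dict) else regimens
        for pop_name, patient in patients.items():
            for n in ns:
                res = analyze(spec, patient, regimen, int(n), settings)
                rows.append(
                    {
                        "drug": spec.drug_name,
                        "population": pop_name,
                        "n": int(n),
                        "retrodiction": res.retrodiction.label,
                    }
                )
    return pd.DataFrame(rows)
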