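"""Population-PK model specifications, patients, and synthetic fixtures.

A :class:`PopPKModelSpec` is a declarative description of one drug +
formulation: structural model, typical parameter values, between-subject
variability (lognormal, optionally correlated), covariate relations, and
residual-error magnitudes. Specs are read from and written to YAML; a JSON
Schema for the file format ships with the package (``schema/`` directory).

Internal units are fixed: time in hours, amounts in mg, volumes in L,
concentrations in mg/L.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "PopPKModelSpec",
    "CovariateRelation",
    "Patient",
    "parse_model_spec",
    "write_model_spec",
    "generate_fixture_spec",
    "spec_hash",
    "FIXTURE_PROFILES",
]

Formulation = Literal["IR_tablet", "ER_tablet", "solution", "suspension", "syrup"]
Structure = Literal["one_cpt_oral", "one_cpt_bolus", "two_cpt_oral"]
CovariateForm = Literal["power", "proportional", "linear", "exponential"]

#: parameters that must be present for each structural model
REQUIRED_PARAMS: dict[str, tuple[str, ...]] = {
    "one_cpt_oral": ("CL_F", "V_F", "Ka"),
    "one_cpt_bolus": ("CL_F", "V_F"),
    "two_cpt_oral": ("CL_F", "V_F", "Ka", "Q_F", "Vp_F"),
}

#: all parameter names a spec may declare
KNOWN_PARAMS = ("CL_F", "V_F", "Ka", "Q_F", "Vp_F", "F_rel", "tlag")

#: numeric patient descriptors resolvable by covariate relations
NUMERIC_COVARIATES = ("age", "weight", "height", "eGFR", "pregnancy_week")

# Flip-flop guard thresholds: relative |Ka - k| below REJECT is an error,
# below PERTURB the spec's Ka is nudged by 1e-6 relative (Bateman stability).
_FLIPFLOP_REJECT = 1e-6
_FLIPFLOP_PERTURB = 1e-4


class SpecValidationError(ValueError):
    """A model spec violates a structural or numeric invariant."""


class CovariateRelation(BaseModel):
    """One multiplicative covariate effect on a PK parameter.

    Forms (``x`` is the resolved covariate value, ``ref`` the reference):

    - ``power``:         ``(x / ref) ** theta``
    - ``proportional``:  ``1 + theta * x`` (for comedication/formulation tags
      ``x`` is 0/1, so present tag multiplies by ``1 + theta``)
    - ``linear``:        ``1 + theta * (x - ref)``
    - ``exponential``:   ``exp(theta * (x - ref))``
    """

    model_config = ConfigDict(extra="forbid")

    target_param: str
    covariate: str
    form: CovariateForm
    theta: float
    ref_value: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "CovariateRelation":
        if self.form == "power":
            if self.ref_value is None or self.ref_value <= 0:
                raise ValueError(
                    f"power relation on {self.target_param!r} requires ref_value > 0"
                )
        return self

    def is_flag(self) -> bool:
        """True when the covariate is a tag (comedication/sex/formulation)."""
        return self.covariate not in NUMERIC_COVARIATES


class PopPKModelSpec(BaseModel):
    """Declarative population-PK model for one drug and formulation."""

    model_config = ConfigDict(extra="forbid")

    drug_name: str
    formulation: Formulation = "IR_tablet"
    structure: Structure
    typical_params: dict[str, float]
    covariates: list[CovariateRelation] = Field(default_factory=list)
    omega: dict[str, float] = Field(default_factory=dict)
    omega_corr: Optional[list[list[float]]] = None
    sigma_add: float = 0.0
    sigma_prop: float = 0.0
    ref_covariates: dict[str, float] = Field(default_factory=dict)

    # -- validation ---------------------------------------------------------

    @field_validator("sigma_add", "sigma_prop")
    @classmethod
    def _nonneg_sigma(cls, v: float) -> float:
        if v < 0:
            raise ValueError("residual-error magnitudes must be >= 0")
        return v

    @model_validator(mode="after")
    def _check(self) -> "PopPKModelSpec":
        required = REQUIRED_PARAMS[self.structure]
        for name in required:
            if name not in self.typical_params:
                raise ValueError(
                    f"structure {self.structure!r} requires parameter {name!r}"
                )
        for name, value in self.typical_params.items():
            if name not in KNOWN_PARAMS:
                raise ValueError(f"unknown typical parameter {name!r}")
            if name == "tlag":
                if value < 0:
                    raise ValueError("tlag must be >= 0")
            elif value <= 0:
                raise ValueError(f"typical parameter {name!r} must be > 0")
        for name, sd in self.omega.items():
            if name not in self.typical_params:
                raise ValueError(f"omega given for undeclared parameter {name!r}")
            if sd < 0:
                raise ValueError(f"omega[{name!r}] must be >= 0")
        if self.omega_corr is not None:
            corr = np.asarray(self.omega_corr, dtype=float)
            k = len(self.omega)
            if corr.shape != (k, k):
                raise ValueError(
                    f"omega correlation must be {k}x{k} (one row per omega entry)"
                )
            if not np.allclose(corr, corr.T, atol=1e-12):
                raise ValueError("omega correlation matrix must be symmetric")
            if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
                raise ValueError("omega correlation must have unit diagonal")
            eigmin = float(np.linalg.eigvalsh(corr).min())
            if eigmin < -1e-10:
                raise ValueError(
                    f"omega correlation not positive semi-definite (min eig {eigmin:.3g})"
                )
        for rel in self.covariates:
            if rel.target_param not in self.typical_params:
                raise ValueError(
                    f"covariate relation targets undeclared parameter {rel.target_param!r}"
                )
            if rel.is_flag() and rel.form != "proportional":
                raise ValueError(
                    f"tag covariate {rel.covariate!r} only supports the proportional form"
                )
        self._guard_flipflop()
        return self

    def _guard_flipflop(self) -> None:
        """Reject or nudge Ka when it collides with the elimination constant."""
        if "Ka" not in self.typical_params:
            return
        ka = self.typical_params["Ka"]
        k = self.typical_params["CL_F"] / self.typical_params["V_F"]
        rel = abs(ka - k) / k
        if rel < _FLIPFLOP_REJECT:
            raise ValueError(
                f"Ka ({ka:.6g} 1/h) equals CL_F/V_F ({k:.6g} 1/h) within 1e-6 relative; "
                "the absorption and elimination constants are numerically degenerate"
            )
        if rel < _FLIPFLOP_PERTURB:
            sign = 1.0 if ka > k else -1.0
            self.typical_params["Ka"] = ka * (1.0 + sign * 1e-6)

    # -- helpers ------------------------------------------------------------

    @property
    def omega_names(self) -> list[str]:
        return list(self.omega.keys())

    def omega_cov(self) -> np.ndarray:
        """Covariance matrix of the log-scale random effects."""
        sd = np.array([self.omega[p] for p in self.omega_names], dtype=float)
        corr = (
            np.asarray(self.omega_corr, dtype=float)
            if self.omega_corr is not None
            else np.eye(len(sd))
        )
        return corr * np.outer(sd, sd)

    def to_dict(self) -> dict:
        d = self.model_dump(exclude_none=True)
        if not d.get("covariates"):
            d.pop("covariates", None)
        for key in ("omega", "ref_covariates"):
            if not d.get(key):
                d.pop(key, None)
        return d


class Patient(BaseModel):
    """Descriptor of one (virtual) patient."""

    model_config = ConfigDict(extra="forbid")

    age: float = Field(gt=0, description="years")
    weight: float = Field(gt=0, description="kg")
    height: float = Field(gt=0, description="cm")
    sex: Literal["male", "female"] = "male"
    eGFR: float = Field(default=90.0, gt=0, description="mL/min/1.73m^2")
    pregnancy_week: Optional[float] = Field(default=None, ge=0, le=42)
    comedications: set[str] = Field(default_factory=set)

    def descriptor_hash(self) -> str:
        payload = self.model_dump()
        payload["comedications"] = sorted(payload["comedications"])
        return hashlib.sha256(repr(sorted(payload.items())).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# YAML I/O
# ---------------------------------------------------------------------------


def parse_model_spec(path: str | Path) -> PopPKModelSpec:
    """Read and validate a model spec from a YAML file.

    Raises :class:`SpecValidationError` with the offending field named when
    the document violates the schema or a numeric invariant.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SpecValidationError(f"{path}: expected a YAML mapping at top level")
    try:
        return PopPKModelSpec.model_validate(raw)
    except Exception as exc:  # pydantic.ValidationError or ValueError
        raise SpecValidationError(f"{path}: {exc}") from exc


def write_model_spec(spec: PopPKModelSpec, path: str | Path) -> None:
    """Serialize a spec to YAML such that it round-trips through parsing."""
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


def spec_hash(spec: PopPKModelSpec) -> str:
    """Stable short hash of the spec contents (for report provenance)."""
    text = yaml.safe_dump(spec.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

# Base profiles are stylized but pharmacologically plausible oral regimens.
# fast_clearance: a rapidly eliminated drug (t1/2 ~ 2.3 h at q12h dosing) whose
#   concentration "signal" from doses more than one interval back falls below
#   the residual-error floor — the regime where retrodiction degrades fastest.
# slow_clearance: a phenobarbital-like accumulating drug (t1/2 ~ 99 h) with
#   modest variability, the regime where consecutive missed doses remain
#   resolvable the longest.
# with_covariates / two_cpt: mid-range elimination (t1/2 ~ 9 h) giving fully
#   distinct most-probable regions over the last two doses, plus allometric,
#   renal and comedication effects (inducer CL x3, inhibitor CL x0.55).
_PROFILE_BASES: dict[str, dict] = {
    "fast_clearance": dict(
        structure="one_cpt_oral",
        typical_params={"CL_F": 12.0, "V_F": 40.0, "Ka": 2.0},
        omega={"CL_F": 0.20, "V_F": 0.15, "Ka": 0.30},
        sigma_add=0.05,
        sigma_prop=0.10,
    ),
    "slow_clearance": dict(
        structure="one_cpt_oral",
        typical_params={"CL_F": 0.35, "V_F": 50.0, "Ka": 1.0},
        omega={"CL_F": 0.10, "V_F": 0.10, "Ka": 0.20},
        sigma_add=0.10,
        sigma_prop=0.08,
    ),
    "two_cpt": dict(
        structure="two_cpt_oral",
        typical_params={"CL_F": 3.5, "V_F": 35.0, "Ka": 1.2, "Q_F": 5.0, "Vp_F": 50.0},
        omega={"CL_F": 0.25, "V_F": 0.20, "Ka": 0.30},
        omega_corr=[[1.0, 0.3, 0.0], [0.3, 1.0, 0.0], [0.0, 0.0, 1.0]],
        sigma_add=0.05,
        sigma_prop=0.10,
    ),
    "with_covariates": dict(
        structure="one_cpt_oral",
        typical_params={"CL_F": 3.5, "V_F": 45.0, "Ka": 1.0},
        omega={"CL_F": 0.25, "V_F": 0.20, "Ka": 0.30},
        sigma_add=0.05,
        sigma_prop=0.10,
    ),
}

FIXTURE_PROFILES = tuple(_PROFILE_BASES)

_COVARIATE_SET = [
    dict(target_param="CL_F", covariate="weight", form="power", theta=0.75, ref_value=70.0),
    dict(target_param="V_F", covariate="weight", form="power", theta=1.0, ref_value=70.0),
    dict(target_param="CL_F", covariate="eGFR", form="power", theta=0.5, ref_value=90.0),
    # enzyme induction triples clearance; inhibition roughly halves it
    dict(target_param="CL_F", covariate="enzyme_inducer", form="proportional", theta=2.0),
    dict(target_param="CL_F", covariate="enzyme_inhibitor", form="proportional", theta=-0.4545),
]


def generate_fixture_spec(profile: str, seed: int) -> PopPKModelSpec:
    """Create a deterministic, validated synthetic model spec.

    The ``seed`` applies a small (3% CV) lognormal jitter to the typical
    parameter values so distinct seeds give distinct but same-regime models;
    the same ``(profile, seed)`` pair always returns an identical spec.
    """
    if profile not in _PROFILE_BASES:
        raise ValueError(
            f"unknown fixture profile {profile!r}; available: {', '.join(FIXTURE_PROFILES)}"
        )
    base = _PROFILE_BASES[profile]
    rng = np.random.default_rng(abs(int(seed)) % (2**31))
    params = {}
    for name, value in base["typical_params"].items():
        params[name] = round(float(value * np.exp(rng.normal(0.0, 0.03))), 6)
    kwargs = dict(
        drug_name=f"synthetic_{profile}",
        formulation="IR_tablet",
        structure=base["structure"],
        typical_params=params,
        omega=dict(base["omega"]),
        sigma_add=base["sigma_add"],
        sigma_prop=base["sigma_prop"],
    )
    if "omega_corr" in base:
        kwargs["omega_corr"] = [list(row) for row in base["omega_corr"]]
    if profile == "with_covariates":
        kwargs["covariates"] = [CovariateRelation(**c) for c in _COVARIATE_SET]
        kwargs["ref_covariates"] = {"weight": 70.0, "eGFR": 90.0}
    return PopPKModelSpec(**kwargs)


def export_json_schema(path: str | Path) -> None:
    """Write the JSON Schema of the YAML model-spec format."""
    import json

    schema = PopPKModelSpec.model_json_schema()
    schema["$schema"] = "https://json-schema.org/draft/2020-12/schema"
    with open(path, "w") as fh:
        json.dump(schema, fh, indent=2)
        fh.write("\n")
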