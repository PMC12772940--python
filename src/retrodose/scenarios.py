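"""Dosing-behaviour hypotheses over the last n scheduled doses.

A scenario is a bitstring of length n ordered most-recent-first: the first
digit describes the last dose before sampling (1 = taken, 0 = missed). With
trough sampling this convention makes the scenario concentrations ordered,
e.g. for n=2 at the sampling time: w00 < w01 < w10 < w11, because missing the
most recent dose removes the largest remaining contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional

from .pk import DoseEvent, DoseHistory

__all__ = ["Scenario", "ScenarioSet", "enumerate_scenarios", "assign_priors", "scenario_history"]

PRIOR_SUM_TOL = 1e-12


@dataclass(frozen=True)
class Scenario:
    bits: str
    prior: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.bits) < 1 or set(self.bits) - {"0", "1"}:
            raise ValueError(f"scenario bits must be a nonempty 0/1 string, got {self.bits!r}")
        if self.prior is not None and not (0.0 <= self.prior <= 1.0):
            raise ValueError("scenario prior must lie in [0, 1]")

    @property
    def n_taken(self) -> int:
        return self.bits.count("1")

    @property
    def n_missed(self) -> int:
        return self.bits.count("0")

    @property
    def label(self) -> str:
        return f"w{self.bits}"

    @property
    def index(self) -> int:
        """Canonical index: the bitstring read as a binary integer."""
        return int(self.bits, 2)


@dataclass
class ScenarioSet:
    """All 2^n scenarios over the last ``n`` dose slots."""

    n: int
    scenarios: list[Scenario]

    def __post_init__(self) -> None:
        bits = [s.bits for s in self.scenarios]
        if len(bits) != 2**self.n or len(set(bits)) != len(bits):
            raise ValueError(f"scenario set must hold exactly 2^{self.n} distinct bitstrings")
        priors = [s.prior for s in self.scenarios]
        if all(p is not None for p in priors):
            total = sum(priors)
            if abs(total - 1.0) > PRIOR_SUM_TOL:
                raise ValueError(f"scenario priors must sum to 1 (got {total!r})")

    def __iter__(self):
        return iter(self.scenarios)

    def __len__(self) -> int:
        return len(self.scenarios)

    @property
    def bits(self) -> list[str]:
        return [s.bits for s in self.scenarios]

    def priors(self) -> list[float]:
        if any(s.prior is None for s in self.scenarios):
            raise ValueError("priors are unset; call assign_priors first")
        return [s.prior for s in self.scenarios]


def enumerate_scenarios(n: int) -> ScenarioSet:
    """All 2^n scenarios in lexicographic bitstring order, priors unset."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > 10:
        raise ValueError("n above 10 is not supported (2^n scenarios become impractical)")
    bits = [format(i, f"0{n}b") for i in range(2**n)]
    return ScenarioSet(n, [Scenario(b) for b in bits])


def assign_priors(
    sset: ScenarioSet,
    mode: str = "equal",
    p: Optional[float] = None,
    table: Optional[Mapping[str, float]] = None,
) -> ScenarioSet:
    """Return a new ScenarioSet with priors set.

    - ``equal``: every scenario gets 2^-n (maximum-uncertainty default).
    - ``per_dose``: doses are independent Bernoulli trials with adherence
      probability ``p``: prior(w) = p^(#taken) * (1-p)^(#missed).
    - ``custom``: nonnegative weights per bitstring, normalized to sum 1.
    """
    n = sset.n
    if mode == "equal":
        priors = {b: 2.0**-n for b in sset.bits}
    elif mode == "per_dose":
        if p is None or not (0.0 < p < 1.0):
            raise ValueError("per_dose mode requires p in the open interval (0, 1)")
        priors = {}
        for s in sset:
            priors[s.bits] = p**s.n_taken * (1.0 - p) ** s.n_missed
    elif mode == "custom":
        if table is None:
            raise ValueError("custom mode requires a table of weights")
        missing = set(sset.bits) - set(table)
        if missing:
            raise ValueError(f"custom priors missing scenarios: {sorted(missing)}")
        if any(v < 0 for v in table.values()):
            raise ValueError("custom prior weights must be >= 0")
        total = sum(table[b] for b in sset.bits)
        if total <= 0:
            raise ValueError("custom prior weights must not all be zero")
        priors = {b: table[b] / total for b in sset.bits}
    else:
        raise ValueError(f"unknown prior mode {mode!r}")
    total = sum(priors.values())
    priors = {b: v / total for b, v in priors.items()}  # exact renormalization
    return ScenarioSet(n, [replace(s, prior=priors[s.bits]) for s in sset])


def scenario_history(base: DoseHistory, scenario: Scenario) -> DoseHistory:
    """Edit the terminal dose slots of ``base`` according to a scenario.

    Digit i (1-indexed from the left) addresses the i-th most recent dose:
    a 0 sets that slot's amount to 0, a 1 leaves it intact. Run-in doses are
    never touched; the all-ones scenario returns the base schedule unchanged.
    """
    n = len(scenario.bits)
    if n > base.n_editable:
        raise ValueError(
            f"scenario has {n} digits but the history exposes only "
            f"{base.n_editable} editable slots"
        )
    events = list(base.events)
    for i, bit in enumerate(scenario.bits):  # i=0 -> most recent = last event
        if bit == "0":
            slot = len(events) - 1 - i
            events[slot] = DoseEvent(events[slot].time, 0.0)
    return DoseHistory(events, base.n_editable, base.interval, base.sampling_time)
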