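# retrodose

Bayesian retrodiction of recent medication-taking behaviour from a single
therapeutic-drug-monitoring (TDM) concentration.

A trough concentration measured in a patient on chronic oral therapy (for
example an antiseizure medication dosed q12h) carries information about
whether the last few scheduled doses were actually taken. Population
reference ranges interpret such a measurement against an *average* adult,
ignoring age, weight, renal function, pregnancy, comedications and
formulation. `retrodose` instead treats each of the `2^n` hypotheses about
the last `n` doses — a bitstring ω, most-recent-first, `1` = taken, `0` =
missed — as a scenario, simulates the patient-specific concentration
distribution under every scenario with a population-pharmacokinetic model,
and inverts with Bayes' rule:

    P(ω_j | C) = P(ω_j) · P(C | ω_j) / P(C),      P(C) = Σ_j P(ω_j) · P(C | ω_j)

where `P(C | ω_j)` is estimated by Monte Carlo simulation (by default 40,000
virtual patients per scenario, lognormal between-subject variability on the
PK parameters, residual error minimized at 0.01 mg/L additive and 0.1%
proportional) and `P(ω_j)` is the prior over scenarios (equal by default, or
a per-dose Bernoulli adherence probability, or fully custom).

From the posterior-vs-concentration curves the package derives:

- **discrimination thresholds** — the concentrations at which two adjacent
  scenarios are equally probable, partitioning the concentration axis into
  most-probable-scenario windows;
- **retrodiction labels** — *complete* when every scenario's posterior curve
  peaks ≥ 80%, *none* when at most one does, *partial* otherwise;
- **single-observation assessments** — the posterior over all scenarios at a
  measured TDM value;
- **critical-factor sweeps** — how the thresholds and labels move with renal
  function, enzyme-inducing/inhibiting comedications, dosing interval,
  sampling time, prior probability and residual error.

It is aimed at pharmacometricians and TDM researchers; model parameters are
supplied as declarative YAML files (one drug + formulation per file, JSON
Schema in `src/retrodose/schema/`), so published population-PK models can be
transcribed without code changes. A synthetic fixture generator provides
realistic one- and two-compartment oral models so everything runs
self-contained.

## Worked example

```python
from retrodose import (Patient, Regimen, SimulationSettings, analyze,
                       generate_fixture_spec)

spec = generate_fixture_spec("with_covariates", seed=1)   # t1/2 ~ 9 h oral drug
adult = Patient(age=40, weight=70, height=180)
result = analyze(spec, adult, Regimen(dose=300, interval=12), n=2,
                 settings=SimulationSettings(n_virtual=40_000, seed=1))
for bits, lo, hi in result.thresholds.partition:
    print(f"w{bits}: {lo:6.2f} - {hi:6.2f} mg/L")
print(result.retrodiction.label)
```

prints

```
w00:   0.00 -   1.14 mg/L
w01:   1.18 -   2.43 mg/L
w10:   2.46 -   4.32 mg/L
w11:   4.35 -  18.22 mg/L
partial
```

i.e. a trough below 1.14 mg/L most likely means both recent doses were
missed (ω00), 1.18–2.43 mg/L means only the last dose was missed (ω01),
2.46–4.32 mg/L the second-to-last (ω10), and anything higher is most
consistent with full adherence (ω11). The label `partial` says that only
some scenarios (here ω00 and ω11) ever reach a posterior of 80%, so the last
two doses cannot be pinned down individually with certainty.

The `examples/` directory holds one short script per capability
(posterior curves, single-TDM assessment, factor sweeps, retrodiction
table); each prints its results with a comment on what they mean.

The same pipeline is available from the shell:

```bash
retrodose fixture --profile with_covariates --seed 1 --out model.yaml
retrodose curves --model model.yaml --dose 300 --interval 12 --n 2 \
    --age 40 --weight 70 --height 180 --out run/
retrodose assess --model model.yaml --dose 300 --interval 12 --n 2 \
    --age 75 --weight 70 --height 180 --egfr 40 --tdm 6.0 --out run/
retrodose sweep --model model.yaml --dose 300 --interval 12 --n 2 \
    --age 40 --weight 70 --height 180 --factor eGFR --levels 30,60,90 --out run/
```

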