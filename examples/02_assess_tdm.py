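"""Assess one observed trough concentration against all dosing scenarios.

A measured trough can sit inside the population reference range and still be
inconsistent with full adherence for this particular patient. The posterior
quantifies that directly.
"""

from retrodose import Patient, Regimen, SimulationSettings, assess, generate_fixture_spec

spec = generate_fixture_spec("with_covariates", seed=1)
patient = Patient(age=75, weight=70, height=180, eGFR=40)  # renally impaired
settings = SimulationSettings(n_virtual=40_000, seed=1)

for c_obs in (1.0, 6.0):
    out = assess(c_obs, spec, patient, Regimen(dose=300, interval=12), n=2, settings=settings)
    print(f"observed trough {c_obs:.1f} mg/L:")
    for bits, prob in out.posterior.items():
        print(f"  P(w{bits} | C) = {prob:.3f}")
    print(f"  most likely behaviour: w{out.most_likely}\n")
# w11 = took both recent doses ... w00 = missed both. A low trough shifts the
# posterior toward the missed-dose scenarios even before it leaves the
# population reference range.
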