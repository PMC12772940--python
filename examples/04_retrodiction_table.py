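"""How far back can dosing behaviour be read from a single trough?

Compares a rapidly eliminated drug (t1/2 ~ 2 h) with a slowly eliminated,
accumulating one (t1/2 ~ 100 h) for the last 1, 2 and 3 doses, in an adult
and a pediatric patient. Fast elimination erases the concentration signal of
earlier doses.
"""

from retrodose import Patient, Regimen, SimulationSettings, generate_fixture_spec, retrodiction_table

fast = generate_fixture_spec("fast_clearance", seed=1)
slow = generate_fixture_spec("slow_clearance", seed=1)
patients = {
    "adult": Patient(age=40, weight=70, height=180),
    "child": Patient(age=8, weight=25, height=127),
}
table = retrodiction_table(
    [fast, slow],
    patients,
    ns=[1, 2, 3],
    regimens={fast.drug_name: Regimen(300, 12), slow.drug_name: Regimen(100, 12)},
    settings=SimulationSettings(n_virtual=20_000, seed=1),
)
print(table.to_string(index=False))
# 'complete': every scenario's posterior curve peaks >= 80%; 'partial': some
# do (typically full adherence and full nonadherence); 'none': at most one.
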