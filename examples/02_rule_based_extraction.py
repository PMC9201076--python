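"""Rule-based patient-level stage extraction.

The rule engine parses compact TNM shorthand ("pT3aN0") and narrative
staging terms ("extracapsular extension" maps to T3 under AJCC 7th-edition
criteria), applies ConText-style negation/temporality scoping, and resolves
each patient's mentions to one dichotomized category per axis.
"""

from tnmstage import (
    SimulationConfig,
    assemble_patients,
    default_lexicon,
    extract_patient_stage,
    score,
    simulate_corpus,
)
from tnmstage.rules import extract_stage_table

notes, truth, _ = simulate_corpus(SimulationConfig(n_patients=150, seed=7))
records = assemble_patients(notes)
lexicon = default_lexicon()

stage = extract_patient_stage(records[0], lexicon)
print(f"patient {records[0].patient_id}:")
for task, field in stage.fields.items():
    print(f"  {task} = {field.category}  (from {len(field.provenance)} mention(s), "
          f"negation-derived={field.from_negation})")

predictions = extract_stage_table(records, lexicon)
report = score(predictions, truth.to_frame())
print("\nper-task F1 against the generator's gold labels:")
for task, entry in report.per_task.items():
    f1s = {cat: round(v["f1"], 3) if v["f1"] is not None else None
           for cat, v in entry["categories"].items()}
    print(f"  {task}: {f1s}  (kappa {entry['kappa']:.3f}, n={entry['n_scored']})")

# F1 near 1.0 per category is expected here: the synthetic corpus only
# injects noise the engine is designed to resolve (negation, history,
# hypothetical discussion, prefix ambiguity).
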