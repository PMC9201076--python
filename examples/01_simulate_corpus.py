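"""Generate a small synthetic prostate-cancer note corpus.

Every patient gets a true TNM stage per axis (clinical T/N/M, plus
pathological T/N for the ~third who undergo prostatectomy), a handful of
date-ordered notes rendering those stages as compact patterns, narrative
phrasings or prefix-less ambiguous mentions, and a registry row whose cells
are blanked independently — the missing fields are what imputation later
tries to recover.
"""

from tnmstage import SimulationConfig, simulate_corpus

config = SimulationConfig(n_patients=50, seed=42)
notes, truth, registry = simulate_corpus(config)

print(f"patients: {config.n_patients}, notes: {len(notes)}")
print(f"registry rows with missing clinical T: {registry['cT'].isna().sum()}")

pid = notes[0].patient_id
pt = truth.patients[pid]
print(f"\npatient {pid}: true stages {pt.raw}, documented {pt.documented}")
for note in notes:
    if note.patient_id == pid:
        print(f"  [{note.date} {note.note_type.value}] {note.text}")

# The printed stages are the generator's ground truth; the note text is what
# the extractors will see. Axes marked documented=False appear in no note and
# can only be recovered if the registry happens to hold them.
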