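"""Sentence-level mention detection and contextual flagging.

Shows what the rule engine extracts from individual sentences: axis, value,
clinical/pathological prefix, and the ConText flags (negated, historical,
hypothetical, other experiencer) that decide whether a mention counts as
evidence for the patient's stage.
"""

from tnmstage import default_lexicon
from tnmstage.rules import extract_sentence_mentions

lexicon = default_lexicon()

sentences = [
    "Final stage cT2aN0M0.",
    "Prostatectomy specimen shows extracapsular extension.",
    "No evidence of nodal metastasis.",
    "Will consider systemic therapy if distant metastasis develops.",
    "History of t2a disease.",
    "Father had metastatic prostate cancer.",
    "he has t3a prostate cancer",
]

for text in sentences:
    print(f"\n{text!r}")
    for m in extract_sentence_mentions(text, lexicon):
        flags = [f for f in ("negated", "historical", "hypothetical", "experiencer_other")
                 if getattr(m.context, f)]
        print(f"  {m.axis}{m.numeral}{m.subtype or ''} prefix={m.prefix} "
              f"source={m.source} ambiguous={m.ambiguous} flags={flags or 'none'}")

# Negated, hypothetical and other-experiencer mentions are discarded during
# patient-level resolution (a negated N1/M1 asserts N0/M0 instead);
# historical mentions are kept — a stage assigned in the past still holds.
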