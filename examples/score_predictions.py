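"""Scoring predictions against phenotype-array growth calls.

Each assay well offers one source per essential element plus fixed
supplements; a predicted minimal set matches a well when it equals the
well's composition or is a proper subset of it (a compound predicted to
source two elements makes a fixed supplement redundant).  Wells with growth
and a match are true positives; low-growth wells are excluded as
inconclusive.
"""

from minnut import PMRecord, matches, score

predicted = [
    frozenset({"glucose-1-phosphate", "ammonium", "sulfate"}),  # sources C and P
    frozenset({"glucose", "ammonium", "phosphate", "sulfate"}),
]

wells = [
    PMRecord("A01", frozenset({"glucose", "ammonium", "phosphate", "sulfate"}),
             "growth"),
    PMRecord("A02", frozenset({"glucose-1-phosphate", "ammonium", "phosphate",
                               "sulfate"}), "growth"),
    PMRecord("A03", frozenset({"citrate", "ammonium", "phosphate", "sulfate"}),
             "no-growth"),
    PMRecord("A04", frozenset({"acetamide", "ammonium", "phosphate", "sulfate"}),
             "low-growth"),
]

print("well A02 matched by subset rule:",
      matches(wells[1].nutrient_set, predicted))

report = score(wells, predicted)
print(f"TP={report.TP} TN={report.TN} FP={report.FP} FN={report.FN} "
      f"excluded={report.excluded_low_growth}")
print(f"accuracy: {report.accuracy} = {report.accuracy_percent:.1f}%")
print(
    "\nA02 scores as a true positive although phosphate is present in the\n"
    "well but absent from the prediction: glucose-1-phosphate already\n"
    "sources phosphorus, so the explicit supplement is redundant."
)
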