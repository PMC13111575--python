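"""Patient-level splitting of a 1000-case cohort with a leakage audit.

Generates a synthetic 60/40 benign/malignant cohort with CC and MLO views
per case, splits it 75/12/13 at the case level with label stratification,
and audits the assignment for leakage.
"""

from mammoprep import SplitPlan, audit_leakage, patient_level_split
from mammoprep.phantom import generate_cohort

cases = generate_cohort(1000, benign_fraction=0.60, seed=11)
plan = patient_level_split(cases, SplitPlan(seed=11))

labels = {c.case_id: c.label for c in cases}
for split in ("train", "val", "test"):
    ids = [cid for cid, s in plan.assignment.items() if s == split]
    n_b = sum(labels[c] == "benign" for c in ids)
    print(f"{split:5s}: {len(ids):4d} cases  ({n_b} benign, {len(ids) - n_b} malignant)")

report = audit_leakage(cases, plan)
print(f"leakage violations: {report.total()}")
print("Every case keeps both its views in a single split, so no")
print("near-duplicate image can appear in both training and testing.")
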