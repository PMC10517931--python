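"""Train the expert tree and classify one test patient end to end.

Tiles flow Root (tumor vs not-tumor) -> Node (super-group) -> Leaf
(subtype), with one refine pass after each stage; the patient's final
subtype is the majority vote over tumor-predicted tiles.
"""

from collections import Counter

from expertdt import CohortConfig, PruningPolicy, generate_cohort
from expertdt.pipeline import patient_grids, train_tree
from expertdt.tree import classify_patient

cohort = generate_cohort(CohortConfig(n_per_subtype=3, image_size=320, seed=7))
tree = train_tree(cohort, "expert", seed=1)

patient = cohort.test[0]
grids = patient_grids(patient, cohort)
result = classify_patient(tree, grids, PruningPolicy(), refine=True)

print(f"patient {patient.patient_id} (true subtype {patient.subtype})")
print(f"slides: {len(grids)}")
for i, sm in enumerate(result.maps):
    print(f"  slide {i}: stage1 {dict(sm.stage1.counts())}")
    print(f"           final  {dict(sm.stage3.counts())}")
votes = Counter(
    lab for sm in result.maps for lab in sm.stage3.labels.ravel()
    if lab not in ("BACKGROUND", "NT")
)
print(f"tumor-tile votes: {dict(votes)}")
print(f"node imbalance:   {result.diagnostics['node_imbalance']:.2f} "
      f"(pruning fired: {result.diagnostics['pruning_fired']})")
print(f"predicted subtype: {result.label}")

# The stage-1 counts show background exclusion and the tumor/not-tumor
# split; the final map counts show which subtype the leaves assigned.
# The predicted label is the plurality of the tumor-tile votes.
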