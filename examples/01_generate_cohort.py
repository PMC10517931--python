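"""Generate a small synthetic cohort and inspect its structure.

Each patient has 1-6 grayscale "slides" composed of a bright empty margin,
a not-tumor tissue region and a tumor region textured by the patient's
subtype. Training patients carry rectangular ROI annotations.
"""

from expertdt import CohortConfig, generate_cohort

config = CohortConfig(n_per_subtype=3, image_size=320, seed=7)
cohort = generate_cohort(config)

manifest = cohort.manifest()
print(manifest.head(8).to_string(index=False))
print(f"\npatients: {len(cohort.train)} train / {len(cohort.test)} test")
print(f"slides:   {len(manifest)} total, "
      f"{len(manifest) / manifest.patient_id.nunique():.2f} per patient")
n_ann = sum(len(p.annotations) for p in cohort.train)
print(f"training ROI annotations: {n_ann}")

# Each line above is one slide; the per-patient slide count follows a
# truncated geometric law with mean ~2.2, and only training patients get
# pathologist-style ROI annotations.
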