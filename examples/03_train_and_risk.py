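"""Train the risk model on a small synthetic cohort and stratify lesions.

Generates a labeled cohort, extracts the 69-entry feature vectors,
trains the polynomial-kernel SVM with its two operating points, and
prints the risk index for a few held-out lesions.
"""

import numpy as np

from lesionsf import (
    PipelineConfig,
    build_feature_vector,
    generate_cohort,
    predict_risk,
    train,
)

config = PipelineConfig()

cohort = generate_cohort(n_benign=15, n_malignant=15, seed=3)
print("extracting features for", len(cohort.images), "lesions ...")
vectors = np.array([build_feature_vector(img, config) for img in cohort.images])

# hold the last two lesions of each class out of training
held = [9, 10, 25, 29]
rest = [i for i in range(len(cohort.images)) if i not in held]
data = cohort.labeled_set(vectors).subset(rest)

model = train(data, config)
print(f"operating points: high-sens at {model.threshold_high_sens:.3f}, "
      f"high-spec at {model.threshold_high_spec:.3f}")

for i in held:
    rep = predict_risk(model, vectors[i], id=cohort.ids[i])
    # low risk = both operating points call naevus; high = both call
    # melanoma; middle = the two cutoffs disagree
    print(f"{rep.id}: decision={rep.decision_value:+.2f} risk={rep.risk}"
          f"  (true label: {cohort.labels[i]})")
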