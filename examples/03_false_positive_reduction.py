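"""Train the LCG naive-Bayes classifier and separate true from false nodules.

Draws the 20/20/20 synthetic training design (false positives, lung
true positives, wall true positives), fits one linear-combination-of-
Gaussians density per class and feature, and classifies fresh draws.
The posterior is the probability the candidate is a true nodule under
equal priors; wall candidates are judged on the two gray-level
features only.
"""

from nodtemplate import classify, make_feature_training_set, train_classifier

training = make_feature_training_set(n_per_class=20, seed=7)
print("training design:", training.class_sizes)
model = train_classifier(training, n_pos=2, n_neg=1, seed=7)

probes = [
    ("round, bright (nodule-like)", (1.0, 130.0, 70.0), False),
    ("elongated, dim (vessel-like)", (11.0, 75.0, 25.0), False),
    ("wall candidate, bright", (8.0, 128.0, 72.0), True),
]
print(f"\n{'candidate':30s} {'U':>5s} {'q_ave':>6s} {'q_10':>5s}  label  P(TPN)")
for name, (u, q_ave, q_10), wall in probes:
    label, posterior = classify((u, q_ave, q_10), model, wall_nodule=wall)
    print(f"{name:30s} {u:5.1f} {q_ave:6.1f} {q_10:5.1f}  {label:4s}  {posterior:.3f}")
# The wall probe has high U (the flat pleural edge distorts the border
# distances), yet is accepted because the wall path ignores U.
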