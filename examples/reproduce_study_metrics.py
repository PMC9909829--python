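"""Recompute the pilot study's headline metrics from the packaged tables.

The package ships the published per-tumor-type classification counts for
the 69-mass canine cohort; the confusion matrix and the five diagnostic
measures are a deterministic function of that table.
"""

from adtherm import compute_metrics, confusion_counts, fixture_predictions, load_study_fixture

fixture = load_study_fixture()
print(f"cohort: {fixture.benign_total} benign + {fixture.malignant_total} "
      f"malignant = {fixture.lesion_total} masses")

cm = confusion_counts(fixture_predictions(fixture))
print(f"confusion matrix: TP={cm.tp} TN={cm.tn} FP={cm.fp} FN={cm.fn}")

metrics = compute_metrics(cm)
for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
    print(f"  {name:12s} {metrics.percents[name]:3d}%  ({metrics.fractions[name]:.4f})")
# sensitivity counts detected malignancies; NPV is the fraction of
# "low-risk" calls that really are benign -- the number a clinician
# relies on when deciding against an aspirate.
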