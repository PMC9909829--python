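"""Confusion matrix, diagnostic metrics, and the packaged study tables.

The mass-level evaluation is a 2x2 confusion matrix (high-risk/low-risk
call vs. pathology label) and five derived measures:

    accuracy     = (TP + TN) / total
    sensitivity  = TP / (TP + FN)
    specificity  = TN / (TN + FP)
    PPV          = TP / (TP + FP)
    NPV          = TN / (TN + FN)

Percent values round half-up to integers.  Metrics with a zero denominator
are reported as undefined (``None``) and flagged, never silently zero.

The package ships a transcription of the published pilot-study tables:
per-tumor-type diagnosis-modality counts and per-tumor-type classifier
calls for the 69-mass canine cohort.  Their checksums are validated at
load time and the headline metrics (90/93/88/83/95%) are a deterministic
function of the classification table.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .model import MassPrediction

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "StudyFixture",
    "confusion_counts",
    "compute_metrics",
    "load_study_fixture",
    "fixture_predictions",
    "report",
    "read_report",
]

_FIXTURE_SHA256 = {
    "table1_diagnoses.csv": "a08094b688388f5afb04f616414ed00a7b9de48bd4eda98cc829b689c6d2b9e2",
    "table2_classification.csv": "68d30dfd27fe46e54e8ca4722f232d5ab0e2ad16b325a4f7e77da65b73e9427e",
}

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts; positive class is malignant/high-risk."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _round_half_up_percent(fraction: float) -> int:
    return int(fraction * 100 + 0.5)


@dataclass(frozen=True)
class MetricsReport:
    """The five diagnostic measures as exact fractions and integer percents.

    An undefined metric (zero denominator) is ``None`` in both mappings and
    listed in ``undefined``.
    """

    counts: ConfusionCounts
    fractions: dict
    percents: dict
    undefined: tuple

    def __getattr__(self, name):
        if name in METRIC_NAMES:
            return self.fractions[name]
        raise AttributeError(name)


def confusion_counts(predictions: list[MassPrediction]) -> ConfusionCounts:
    """Tally mass-level predictions into the 2x2 matrix."""
    if not predictions:
        raise ValueError("no predictions to tally")
    tp = tn = fp = fn = 0
    for p in predictions:
        if p.true_label not in ("benign", "malignant"):
            raise ValueError(f"unlabeled prediction for mass {p.mass_id}")
        high = p.predicted == "high-risk"
        if p.true_label == "malignant":
            tp += high
            fn += not high
        else:
            fp += high
            tn += not high
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def compute_metrics(cm: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity, specificity, PPV and NPV from the 2x2 counts."""
    ratios = {
        "accuracy": (cm.tp + cm.tn, cm.total),
        "sensitivity": (cm.tp, cm.tp + cm.fn),
        "specificity": (cm.tn, cm.tn + cm.fp),
        "ppv": (cm.tp, cm.tp + cm.fp),
        "npv": (cm.tn, cm.tn + cm.fn),
    }
    fractions: dict = {}
    percents: dict = {}
    undefined = []
    for name, (num, den) in ratios.items():
        if den == 0:
            fractions[name] = None
            percents[name] = None
            undefined.append(name)
        else:
            fractions[name] = num / den
            percents[name] = _round_half_up_percent(num / den)
    return MetricsReport(
        counts=cm, fractions=fractions, percents=percents, undefined=tuple(undefined)
    )


@dataclass(frozen=True)
class StudyFixture:
    """Packaged transcription of the pilot study's printed tables.

    ``diagnoses``: per tumor type, how many masses were diagnosed by
    cytology vs. histopathology.  ``classification``: per tumor type, how
    many masses the device called benign vs. malignant.
    """

    diagnoses: pd.DataFrame
    classification: pd.DataFrame

    @property
    def benign_total(self) -> int:
        d = self.diagnoses
        return int(d.loc[d["true_class"] == "benign", ["cytology", "histopathology"]].sum().sum())

    @property
    def malignant_total(self) -> int:
        d = self.diagnoses
        return int(d.loc[d["true_class"] == "malignant", ["cytology", "histopathology"]].sum().sum())

    @property
    def lesion_total(self) -> int:
        return self.benign_total + self.malignant_total


def _read_packaged_csv(name: str) -> pd.DataFrame:
    ref = resources.files("adtherm.data") / name
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise ValueError(f"packaged fixture {name} is corrupted (sha256 {digest})")
    from io import StringIO

    return pd.read_csv(StringIO(raw.decode("utf-8")))


def load_study_fixture() -> StudyFixture:
    """Load and checksum-validate the packaged study tables."""
    fixture = StudyFixture(
        diagnoses=_read_packaged_csv("table1_diagnoses.csv"),
        classification=_read_packaged_csv("table2_classification.csv"),
    )
    cls = fixture.classification
    cls_total = int(cls[["classified_benign", "classified_malignant"]].sum().sum())
    if cls_total != fixture.lesion_total:
        raise ValueError("fixture tables disagree on the lesion total")
    return fixture


def fixture_predictions(fixture: StudyFixture | None = None) -> list[MassPrediction]:
    """Expand the classification table into one MassPrediction per lesion.

    Pixel-level votes are not printed in the study tables, so each
    synthesized prediction carries a unanimous single vote consistent with
    the recorded call; only mass-level counts are meaningful downstream.
    """
    if fixture is None:
        fixture = load_study_fixture()
    preds: list[MassPrediction] = []
    i = 0
    for row in fixture.classification.itertuples(index=False):
        for call, count in (("low-risk", row.classified_benign),
                            ("high-risk", row.classified_malignant)):
            for _ in range(int(count)):
                preds.append(
                    MassPrediction(
                        mass_id=f"study_{i:03d}",
                        dog_id=f"study_{i:03d}",
                        true_label=row.true_class,
                        votes=1 if call == "high-risk" else 0,
                        n_pixels=1,
                        malignant_fraction=1.0 if call == "high-risk" else 0.0,
                        predicted=call,
                    )
                )
                i += 1
    return preds


def report(
    predictions: list[MassPrediction],
    out_dir: str | Path,
    tumor_types: dict | None = None,
    config_hash: str | None = None,
) -> MetricsReport:
    """Write metrics JSON, confusion CSV, per-mass predictions CSV.

    When ``tumor_types`` maps mass_id -> tumor type name, a per-type
    breakdown table (rows: type; columns: calls) is also written.
    Returns the computed MetricsReport.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm = confusion_counts(predictions)
    metrics = compute_metrics(cm)

    payload = {
        "counts": {"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn},
        "fractions": metrics.fractions,
        "percents": metrics.percents,
        "flags": list(metrics.undefined),
        "config_hash": config_hash,
    }
    with open(out / "metrics.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    with open(out / "confusion.csv", "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["", "predicted_benign", "predicted_malignant"])
        writer.writerow(["benign", cm.tn, cm.fp])
        writer.writerow(["malignant", cm.fn, cm.tp])

    rows = [
        {
            "mass_id": p.mass_id,
            "dog_id": p.dog_id,
            "true_label": p.true_label,
            "votes": p.votes,
            "fraction": p.malignant_fraction,
            "predicted": p.predicted,
        }
        for p in predictions
    ]
    pd.DataFrame(rows).to_csv(out / "predictions.csv", index=False, lineterminator="\n")

    if tumor_types:
        breakdown_rows = {}
        for p in predictions:
            ttype = tumor_types.get(p.mass_id, "")
            key = (p.true_label, ttype)
            cell = breakdown_rows.setdefault(
                key, {"true_class": p.true_label, "tumor_type": ttype,
                      "classified_benign": 0, "classified_malignant": 0}
            )
            cell["classified_benign" if p.predicted == "low-risk" else "classified_malignant"] += 1
        breakdown = pd.DataFrame(
            sorted(breakdown_rows.values(), key=lambda r: (r["true_class"], r["tumor_type"]))
        )
        breakdown.to_csv(out / "breakdown.csv", index=False, lineterminator="\n")

    return metrics


def read_report(out_dir: str | Path) -> MetricsReport:
    """Re-read a written metrics JSON into a MetricsReport."""
    with open(Path(out_dir) / "metrics.json", encoding="utf-8") as fh:
        payload = json.load(fh)
    cm = ConfusionCounts(**payload["counts"])
    return MetricsReport(
        counts=cm,
        fractions=payload["fractions"],
        percents=payload["percents"],
        undefined=tuple(payload["flags"]),
    )
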