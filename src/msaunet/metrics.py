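"""Overlap metrics between a ground-truth mask G and a prediction P.

DSC = 2|G∩P| / (|G|+|P|), IOU = |G∩P| / |G∪P|,
precision = |G∩P| / |P|, recall = |G∩P| / |G|.

Empty-denominator convention: when both masks are empty every metric is
1.0 (a correct prediction of "nothing"); when only the denominator mask
is empty the metric is 0.0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

__all__ = ["MetricsRecord", "MetricsReport", "segmentation_metrics"]

METRIC_NAMES = ("dsc", "iou", "precision", "recall")


@dataclass(frozen=True)
class MetricsRecord:
    case_id: str
    dsc: float
    iou: float
    precision: float
    recall: float

    def as_dict(self) -> dict:
        return asdict(self)


def _validate_mask(m, name: str) -> np.ndarray:
    m = np.asarray(m)
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary (entries in {{0, 1}})")
    return m.astype(bool)


def segmentation_metrics(gt, pred, case_id: str = "") -> MetricsRecord:
    """Compute DSC/IOU/precision/recall for one mask pair."""
    gt = _validate_mask(gt, "ground truth")
    pred = _validate_mask(pred, "prediction")
    if gt.shape != pred.shape:
        raise ValueError(
            f"mask shapes differ: {gt.shape} vs {pred.shape}"
        )
    inter = int(np.count_nonzero(gt & pred))
    n_g = int(np.count_nonzero(gt))
    n_p = int(np.count_nonzero(pred))
    union = n_g + n_p - inter

    def ratio(num: float, den: float) -> float:
        if den == 0:
            return 1.0 if (n_g == 0 and n_p == 0) else 0.0
        return num / den

    return MetricsRecord(
        case_id=case_id,
        dsc=ratio(2.0 * inter, n_g + n_p),
        iou=ratio(float(inter), float(union)),
        precision=ratio(float(inter), float(n_p)),
        recall=ratio(float(inter), float(n_g)),
    )


@dataclass
class MetricsReport:
    """Per-case metric rows with mean ± std aggregation."""

    records: list = field(default_factory=list)

    def add(self, record: MetricsRecord):
        self.records.append(record)

    @property
    def mean(self) -> dict:
        return {m: float(np.mean([getattr(r, m) for r in self.records]))
                for m in METRIC_NAMES}

    @property
    def std(self) -> dict:
        return {m: float(np.std([getattr(r, m) for r in self.records]))
                for m in METRIC_NAMES}

    def summary(self) -> dict:
        return {"n_cases": len(self.records), "mean": self.mean, "std": self.std}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_dict() for r in self.records])

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path):
        import json

        payload = {"cases": [r.as_dict() for r in self.records],
                   "aggregate": self.summary()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
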