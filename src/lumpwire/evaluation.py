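"""Area-overlap accuracy indices for segmentation masks.

Comparing the automatic mask S_A against the reference mask S_B:

    TP = |S_A ∩ S_B| / |S_B|        fraction of the lesion recovered
    FP = |S_A \\ S_B| / |S_B|        over-segmentation relative to the lesion
    FN = |S_B \\ S_A| / |S_B|        lesion area missed
    ME = |S_A Δ S_B| / |S_A ∪ S_B|  misclassification error, = 1 - Jaccard

TP + FN = 1 by construction; ME is symmetric in its arguments and zero
exactly when the masks coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_core import ValidationError


@dataclass(frozen=True)
class MetricReport:
    tp: float
    fp: float
    fn: float
    me: float
    area_sa: int
    area_sb: int

    def as_percent(self) -> dict[str, float]:
        return {
            "tp": 100.0 * self.tp,
            "fp": 100.0 * self.fp,
            "fn": 100.0 * self.fn,
            "me": 100.0 * self.me,
        }

    def to_dict(self) -> dict:
        d = {k: round(v, 4) for k, v in self.as_percent().items()}
        d["area_sa"] = self.area_sa
        d["area_sb"] = self.area_sb
        return d


def compute_metrics(sa: np.ndarray, sb: np.ndarray) -> MetricReport:
    """TP/FP/FN/ME of an automatic mask ``sa`` against a reference ``sb``."""
    sa = np.asarray(sa) > 0
    sb = np.asarray(sb) > 0
    if sa.shape != sb.shape:
        raise ValidationError(
            f"mask shapes differ: {sa.shape} vs {sb.shape}"
        )
    area_sb = int(sb.sum())
    if area_sb == 0:
        raise ValidationError("reference mask is empty")
    area_sa = int(sa.sum())
    inter = int((sa & sb).sum())
    union = int((sa | sb).sum())
    return MetricReport(
        tp=inter / area_sb,
        fp=(area_sa - inter) / area_sb,
        fn=(area_sb - inter) / area_sb,
        me=(union - inter) / union,
        area_sa=area_sa,
        area_sb=area_sb,
    )
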