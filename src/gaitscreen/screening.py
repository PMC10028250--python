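"""Individual-level screening verdicts from per-stride predictive inference.

A subject is flagged for *consistent underestimation* of a characteristic
(typically age, the developmental-delay signal) when more than 75% of all
pooled predictive samples fall below the actual value AND the majority of
the subject's strides are on average underestimated.  The per-subject
report mirrors the standard columns: number of strides, underestimation
count, underestimation ratio, mean and standard deviation of
Delta = predicted - actual (negative means underestimation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PredictiveInference

logger = logging.getLogger(__name__)

RATIO_THRESHOLD = 0.75


@dataclass
class SubjectVerdict:
    """Screening verdict for one subject, pooled over its strides."""

    subject_id: str
    outcome: str
    actual: float
    n_strides: int
    underestimation_count: int  # strides with mean Delta < 0
    underestimation_ratio: float  # pooled predictive samples below actual
    pred_mean_delta: float
    pred_sd: float
    consistent_underestimation: bool


def subject_verdict(
    inferences: list[PredictiveInference],
    ratio_threshold: float = RATIO_THRESHOLD,
) -> SubjectVerdict:
    """Pool one subject's stride inferences into a screening verdict.

    ``consistent_underestimation`` requires the pooled underestimation
    ratio to exceed ``ratio_threshold`` and more than half of the strides
    to have a negative mean Delta.  Invariant to stride ordering.
    """
    if not inferences:
        raise ValueError("need at least one stride inference")
    subject_ids = {inf.subject_id for inf in inferences}
    if len(subject_ids) > 1:
        raise ValueError(f"inferences span multiple subjects: {sorted(subject_ids)}")
    n = len(inferences)
    count = sum(1 for inf in inferences if inf.mean_delta < 0)
    pooled = np.concatenate([inf.samples for inf in inferences])
    actual = float(np.mean([inf.actual for inf in inferences]))
    ratio = float(np.mean([inf.fraction_below for inf in inferences]))
    deltas = np.concatenate([inf.delta for inf in inferences])
    return SubjectVerdict(
        subject_id=next(iter(subject_ids)),
        outcome=inferences[0].outcome,
        actual=actual,
        n_strides=n,
        underestimation_count=count,
        underestimation_ratio=ratio,
        pred_mean_delta=float(deltas.mean()),
        pred_sd=float(pooled.std(ddof=0)),
        consistent_underestimation=bool(ratio > ratio_threshold and count > n / 2),
    )


def verdict_table(
    inferences: list[PredictiveInference],
    ratio_threshold: float = RATIO_THRESHOLD,
) -> pd.DataFrame:
    """Per-subject verdict report (one row per subject)."""
    by_subject: dict[str, list[PredictiveInference]] = {}
    for inf in inferences:
        by_subject.setdefault(inf.subject_id, []).append(inf)
    rows = []
    for sid in sorted(by_subject):
        v = subject_verdict(by_subject[sid], ratio_threshold)
        rows.append(
            {
                "subject_id": v.subject_id,
                "actual": v.actual,
                "strides": v.n_strides,
                "underestimation_count": v.underestimation_count,
                "underestimation_ratio": round(v.underestimation_ratio, 4),
                "pred_mean_delta": v.pred_mean_delta,
                "pred_sd": v.pred_sd,
                "consistent_underestimation": v.consistent_underestimation,
            }
        )
    return pd.DataFrame(rows)


def delta_histograms(
    inferences: list[PredictiveInference],
    grouping: dict[str, list[str]] | pd.Series,
    bins: int = 41,
    value_range: tuple[float, float] | None = None,
) -> dict:
    """Per-group Delta distributions with per-category height normalization.

    ``grouping`` maps group name -> stride ids (or a Series of group label
    per stride id).  Returns a dict with a summary table (mean, sd, n per
    group) and normalized histogram arrays ready for plotting; groups with
    no matching inference are omitted with a log notice.
    """
    if isinstance(grouping, pd.Series):
        groups: dict[str, list[str]] = {}
        for sid, g in grouping.items():
            groups.setdefault(str(g), []).append(str(sid))
    else:
        groups = {k: [str(s) for s in v] for k, v in grouping.items()}

    by_stride = {inf.stride_id: inf for inf in inferences}
    deltas: dict[str, np.ndarray] = {}
    for name, stride_ids in groups.items():
        found = [by_stride[s].delta for s in stride_ids if s in by_stride]
        if not found:
            logger.info("group %r has no inferences; omitted", name)
            continue
        deltas[name] = np.concatenate(found)
    if not deltas:
        raise ValueError("no group has any inference")
    if value_range is None:
        allv = np.concatenate(list(deltas.values()))
        value_range = (float(allv.min()), float(allv.max()))
    edges = np.linspace(value_range[0], value_range[1], bins + 1)
    hist = {}
    for name, d in deltas.items():
        h, _ = np.histogram(d, bins=edges)
        hist[name] = h / h.max() if h.max() > 0 else h.astype(float)
    summary = pd.DataFrame(
        {
            "group": list(deltas),
            "n_samples": [len(d) for d in deltas.values()],
            "mean_delta": [float(d.mean()) for d in deltas.values()],
            "sd_delta": [float(d.std(ddof=0)) for d in deltas.values()],
        }
    ).set_index("group")
    return {"summary": summary, "bin_edges": edges, "histograms": hist}


def plot_delta_histograms(report: dict, ax=None):
    """Plot the normalized per-group Delta histograms (step style)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    edges = report["bin_edges"]
    centers = 0.5 * (edges[:-1] + edges[1:])
    for name, h in report["histograms"].items():
        ax.step(centers, h, where="mid", label=name)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("predicted - actual")
    ax.set_ylabel("normalized count")
    ax.legend()
    return ax
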