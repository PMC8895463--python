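"""Classifier evaluation: confusion-matrix metrics, ROC-AUC, and the
literature-consistency TP/FP ratio of a published hit list.

Metric definitions (N = TP + FP + TN + FN):

    SE  = TP / (TP + FN)                        sensitivity (recall on actives)
    SP  = TN / (TN + FP)                        specificity
    EF  = [TP / (TP + FP)] / [(TP + FN) / N]    enrichment: precision over prevalence
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A zero denominator flags the metric as undefined; MCC falls back to 0 by
convention (recorded in ``undefined``). ROC-AUC is the rank-based
Mann-Whitney statistic with midranks for ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .activity_model import DEFAULT_THRESHOLD

DEFAULT_POTENCY_CUTOFF_UM = 20.0


class EvalError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvalError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    se: Optional[float]
    sp: Optional[float]
    ef: Optional[float]
    mcc: float
    auc: Optional[float] = None
    undefined: Set[str] = field(default_factory=set)


def _as_bool_truth(truth: Sequence) -> np.ndarray:
    arr = []
    for t in truth:
        if isinstance(t, str):
            arr.append(t == "active")
        else:
            arr.append(bool(t))
    return np.asarray(arr, dtype=bool)


def confusion(
    truth: Sequence,
    indices: Sequence[float],
    threshold: float = DEFAULT_THRESHOLD,
) -> ConfusionCounts:
    """Count TP/FP/TN/FN under the inclusive >= threshold rule.

    ``truth`` entries may be the strings 'active'/'inactive' or booleans.
    """
    y = _as_bool_truth(truth)
    s = np.asarray(indices, dtype=float)
    if len(y) != len(s):
        raise EvalError("truth and indices have different lengths")
    if len(y) == 0:
        raise EvalError("empty evaluation set")
    pred = s >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & y)),
        fp=int(np.sum(pred & ~y)),
        tn=int(np.sum(~pred & ~y)),
        fn=int(np.sum(~pred & y)),
    )


def metrics(cc: ConfusionCounts, auc: Optional[float] = None) -> MetricReport:
    """SE/SP/EF/MCC from counts; optionally attach a precomputed AUC."""
    undefined: Set[str] = set()

    pos = cc.tp + cc.fn
    neg = cc.tn + cc.fp
    pred_pos = cc.tp + cc.fp

    se = cc.tp / pos if pos else None
    sp = cc.tn / neg if neg else None
    if pos == 0:
        undefined.add("se")
    if neg == 0:
        undefined.add("sp")

    if pred_pos == 0 or pos == 0 or cc.n == 0:
        ef = None
        undefined.add("ef")
    else:
        precision = cc.tp / pred_pos
        prevalence = pos / cc.n
        ef = precision / prevalence

    denom = (cc.tp + cc.fp) * (cc.tp + cc.fn) * (cc.tn + cc.fp) * (cc.tn + cc.fn)
    if denom == 0:
        mcc = 0.0
        undefined.add("mcc")
    else:
        mcc = (cc.tp * cc.tn - cc.fp * cc.fn) / math.sqrt(denom)

    return MetricReport(se=se, sp=sp, ef=ef, mcc=mcc, auc=auc, undefined=undefined)


def roc_auc(truth: Sequence, indices: Sequence[float]) -> float:
    """Rank-based AUC (Mann-Whitney with midranks for ties)."""
    y = _as_bool_truth(truth)
    s = np.asarray(indices, dtype=float)
    if len(y) != len(s):
        raise EvalError("truth and indices have different lengths")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvalError("both classes required for AUC")
    ranks = rankdata(s)  # midranks
    rank_sum_pos = ranks[y].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(truth: Sequence, indices: Sequence[float]) -> pd.DataFrame:
    """ROC curve points (FPR, TPR, threshold) at every distinct index."""
    y = _as_bool_truth(truth)
    s = np.asarray(indices, dtype=float)
    order = np.argsort(-s, kind="mergesort")
    y = y[order]
    s = s[order]
    n_pos = max(int(y.sum()), 1)
    n_neg = max(int((~y).sum()), 1)
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    distinct = np.r_[np.where(np.diff(s))[0], len(s) - 1]
    return pd.DataFrame(
        dict(threshold=s[distinct], fpr=fps[distinct] / n_neg, tpr=tps[distinct] / n_pos)
    )


@dataclass
class ConsistencyResult:
    tp: int
    fp: int
    n_new: int               # hits with no annotation at all
    ratio: Optional[float]   # None when undefined (no annotations or FP=0)
    infinite: bool = False


def literature_consistency(
    hit_table: pd.DataFrame,
    potency_cutoff: float = DEFAULT_POTENCY_CUTOFF_UM,
    assay_results: Mapping[str, float] = {},
    use_published_calls: bool = False,
) -> ConsistencyResult:
    """TP/FP ratio of a hit list against literature IC50 annotations.

    ``hit_table`` needs a ``name`` column plus a ``lit_ic50`` column holding
    numeric IC50 text that may carry '<'/'>' qualifiers (empty = no report).
    A hit counts as TP when its annotation is at or below ``potency_cutoff``
    (a '<x' bound with x <= cutoff confirms, '>x' with x >= cutoff refutes)
    and as FP when above it. ``assay_results`` maps compound names to
    measured IC50s from supplied in vitro work; those confirm or refute
    hits that have no literature annotation.

    With ``use_published_calls=True`` an explicit ``lit_class`` column
    ('potent'/'weak'/empty) takes precedence over the numeric route — this
    carries a source's own borderline binning.
    """
    tp = fp = n_new = 0
    for _, row in hit_table.iterrows():
        call = ""
        if use_published_calls and "lit_class" in hit_table.columns:
            v = row.get("lit_class")
            call = "" if v is None or (isinstance(v, float) and math.isnan(v)) else str(v)
        if not call:
            raw = row.get("lit_ic50")
            raw = "" if raw is None or (isinstance(raw, float) and math.isnan(raw)) else str(raw).strip()
            if raw:
                value = float(raw.lstrip("<>"))
                if raw.startswith(">"):
                    call = "weak" if value >= potency_cutoff else ""
                elif raw.startswith("<"):
                    call = "potent" if value <= potency_cutoff else ""
                else:
                    call = "potent" if value <= potency_cutoff else "weak"
        if not call:
            name = str(row.get("name", ""))
            if name in assay_results:
                call = "potent" if assay_results[name] <= potency_cutoff else "weak"
        if call == "potent":
            tp += 1
        elif call == "weak":
            fp += 1
        else:
            n_new += 1

    if tp == 0 and fp == 0:
        return ConsistencyResult(tp=0, fp=0, n_new=n_new, ratio=None)
    if fp == 0:
        return ConsistencyResult(tp=tp, fp=0, n_new=n_new, ratio=None, infinite=True)
    return ConsistencyResult(tp=tp, fp=fp, n_new=n_new, ratio=tp / fp)


def write_metrics_csv(report: MetricReport, cc: ConfusionCounts, path) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            dict(
                tp=cc.tp, fp=cc.fp, tn=cc.tn, fn=cc.fn,
                se=report.se, sp=report.sp, ef=report.ef, mcc=report.mcc,
                auc=report.auc,
                undefined=";".join(sorted(report.undefined)),
            )
        ]
    )
    df.to_csv(path, index=False)
    return df
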