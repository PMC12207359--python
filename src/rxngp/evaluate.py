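"""Scoring and aggregation for imbalanced binary prediction.

The headline metric is the area under the precision-recall curve
(AUPRC) in its average-precision form: walking the examples in order of
decreasing score, each positive contributes the precision at its rank.
Tied scores are handled as blocks — a block of equal scores contributes
all of its positives at the precision measured at the end of the block —
which makes a constant scorer score exactly the positive prevalence and
keeps the metric invariant under strictly monotone transforms of the
scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["auprc", "aggregate", "prevalence_baseline"]


def auprc(labels, scores) -> float:
    """Area under the precision-recall curve (average precision).

    Parameters
    ----------
    labels : array of 0/1 with at least one positive.
    scores : real-valued ranking scores, higher means more positive.
    """
    labels = np.asarray(labels).ravel().astype(int)
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("AUPRC undefined without positive examples")
    order = np.argsort(-scores, kind="mergesort")
    s, l = scores[order], labels[order]
    # block boundaries: last index of each tied-score run
    boundary = np.nonzero(np.diff(s))[0]
    ends = np.append(boundary, s.size - 1)
    cum_tp = np.cumsum(l)
    tp_at_end = cum_tp[ends]
    tp_in_block = np.diff(np.concatenate([[0], tp_at_end]))
    precision_at_end = tp_at_end / (ends + 1.0)
    return float(np.sum(tp_in_block * precision_at_end) / n_pos)


def prevalence_baseline(labels) -> float:
    """AUPRC of an uninformative (constant) scorer = positive prevalence."""
    labels = np.asarray(labels).ravel()
    return float(np.mean(labels))


def aggregate(per_repeat_scores, dispersion_kind: str = "sd") -> dict:
    """Mean and dispersion of per-repeat AUPRC scores.

    ``dispersion_kind`` is ``'sd'`` (sample standard deviation, ddof=1)
    or ``'se'`` (standard error, sd / sqrt(n)); a single repeat reports
    dispersion 0.
    """
    s = np.asarray(per_repeat_scores, dtype=float).ravel()
    if s.size == 0:
        raise ValueError("need at least one score")
    if dispersion_kind not in ("sd", "se"):
        raise ValueError("dispersion_kind must be 'sd' or 'se'")
    sd = float(np.std(s, ddof=1)) if s.size > 1 else 0.0
    disp = sd if dispersion_kind == "sd" else sd / np.sqrt(s.size)
    return {
        "mean_auprc": float(np.mean(s)),
        "dispersion": float(disp),
        "dispersion_kind": dispersion_kind,
        "n_repeats": int(s.size),
    }


def results_table(rows) -> pd.DataFrame:
    """Assemble per-repeat result rows into the canonical results frame."""
    df = pd.DataFrame(rows, columns=["method", "split_mode", "combination",
                                     "support_size", "repeat", "auprc"])
    return df


def aggregate_table(df: pd.DataFrame, dispersion_kind: str = "sd") -> pd.DataFrame:
    """Aggregate a per-repeat results frame over repeats."""
    rows = []
    keys = ["method", "split_mode", "combination", "support_size"]
    for key, grp in df.groupby(keys, sort=True):
        agg = aggregate(grp["auprc"].to_numpy(), dispersion_kind)
        rows.append(dict(zip(keys, key), **agg))
    return pd.DataFrame(rows)
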