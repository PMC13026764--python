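"""Virtual-screening evaluation: ROC/AUC, early enrichment, top-N hits.

Docking scores follow the docking convention that lower is better.  For
ensemble docking each ligand carries one score per receptor structure;
scores are aggregated to the per-ligand best (minimum) before ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

__all__ = [
    "ScreeningTable",
    "RocCurve",
    "ScreenMetrics",
    "read_screening_csv",
    "aggregate_scores",
    "roc_curve",
    "auc",
    "enrichment_at_fpr",
    "top_n_hits",
    "evaluate_screen",
]


@dataclass
class ScreeningTable:
    """Per-ligand active/decoy labels and per-structure docking scores."""

    ligand_ids: list[str]
    labels: np.ndarray               # boolean, True = active
    scores: np.ndarray               # (n_ligands, n_structures), NaN = missing
    structure_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if len(set(self.ligand_ids)) != len(self.ligand_ids):
            raise ValueError("ligand ids must be unique")
        if self.scores.shape != (len(self.ligand_ids), len(self.structure_ids)):
            raise ValueError("score matrix shape does not match ids")

    @property
    def n_active(self) -> int:
        return int(self.labels.sum())

    @property
    def n_decoy(self) -> int:
        return int((~self.labels).sum())


@dataclass
class RocCurve:
    """ROC vertices from (0, 0) to (1, 1), both axes non-decreasing."""

    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        if self.fpr[0] != 0 or self.tpr[0] != 0 or self.fpr[-1] != 1 or self.tpr[-1] != 1:
            raise ValueError("ROC curve must run from (0,0) to (1,1)")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC coordinates must be non-decreasing")


@dataclass
class ScreenMetrics:
    auc: float
    er1: float
    top50_hits: int
    n_active: int
    n_decoy: int


def read_screening_csv(path, higher_is_better: bool = False) -> ScreeningTable:
    """Read a CSV of ligand_id,label,score columns.

    ``label`` is 'active' or 'decoy'; every remaining column is a
    per-structure score.  With ``higher_is_better`` the scores are
    negated at ingestion so that lower-is-better holds internally.
    """
    df = pd.read_csv(path)
    if "ligand_id" not in df.columns or "label" not in df.columns:
        raise ValueError("screening CSV needs 'ligand_id' and 'label' columns")
    score_cols = [c for c in df.columns if c not in ("ligand_id", "label")]
    if not score_cols:
        raise ValueError("screening CSV has no score columns")
    bad = set(df["label"].unique()) - {"active", "decoy"}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    scores = df[score_cols].to_numpy(dtype=float)
    if higher_is_better:
        scores = -scores
    return ScreeningTable(
        df["ligand_id"].astype(str).tolist(),
        (df["label"] == "active").to_numpy(),
        scores,
        score_cols,
    )


def aggregate_scores(
    table: ScreeningTable, method: str = "best"
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Collapse per-structure scores to one score per ligand.

    'best' keeps the minimum (most favourable) finite score per ligand —
    the standard ensemble-docking convention; 'mean' and 'median' are
    available as alternatives.  Ligands with no finite score are dropped
    with a warning.  Returns (ligand_ids, labels, scores).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if method == "best":
            agg = np.nanmin(table.scores, axis=1)
        elif method == "mean":
            agg = np.nanmean(table.scores, axis=1)
        elif method == "median":
            agg = np.nanmedian(table.scores, axis=1)
        else:
            raise ValueError(f"unknown aggregation method {method!r}")
    keep = np.isfinite(agg)
    if not keep.all():
        dropped = [table.ligand_ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(
            f"ligands with no finite score excluded: {', '.join(dropped)}",
            stacklevel=2,
        )
    ids = [table.ligand_ids[i] for i in np.flatnonzero(keep)]
    return ids, table.labels[keep], agg[keep]


def roc_curve(labels: np.ndarray, scores: np.ndarray) -> RocCurve:
    """ROC of active-vs-decoy discrimination, lower score = predicted
    active; tied scores are grouped at one threshold."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("ROC needs both actives and decoys")
    fpr, tpr, _ = _skm.roc_curve(labels, -scores, drop_intermediate=False)
    return RocCurve(fpr, tpr)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC curve."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def enrichment_at_fpr(curve: RocCurve, fpr_level: float = 0.01) -> float:
    """ER at a false-positive-rate level: TPR(fpr_level) / fpr_level.

    TPR is linearly interpolated between ROC vertices; at a vertical
    segment the upper TPR is used.
    """
    if not 0 < fpr_level <= 1:
        raise ValueError("fpr_level must lie in (0, 1]")
    # collapse vertical segments: max TPR per unique FPR
    uniq, inverse = np.unique(curve.fpr, return_inverse=True)
    tpr_max = np.zeros_like(uniq)
    np.maximum.at(tpr_max, inverse, curve.tpr)
    tpr_at = float(np.interp(fpr_level, uniq, tpr_max))
    return tpr_at / fpr_level


def top_n_hits(
    ligand_ids: list[str], labels: np.ndarray, scores: np.ndarray, n: int = 50
) -> int:
    """Number of actives among the n best-scoring ligands.

    Ties at the boundary are broken by ligand id order (deterministic).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if len(ligand_ids) < n:
        warnings.warn(
            f"only {len(ligand_ids)} ligands for top-{n}; counting over all",
            stacklevel=2,
        )
        n = len(ligand_ids)
    order = sorted(range(len(ligand_ids)), key=lambda i: (scores[i], ligand_ids[i]))
    return int(sum(labels[i] for i in order[:n]))


def evaluate_screen(
    table: ScreeningTable,
    method: str = "best",
    top_n: int = 50,
    fpr_level: float = 0.01,
) -> ScreenMetrics:
    """Aggregate, rank, and compute AUC / ER / top-N in one pass."""
    ids, labels, scores = aggregate_scores(table, method)
    curve = roc_curve(labels, scores)
    return ScreenMetrics(
        auc=auc(curve),
        er1=enrichment_at_fpr(curve, fpr_level),
        top50_hits=top_n_hits(ids, labels, scores, top_n),
        n_active=int(labels.sum()),
        n_decoy=int((~labels).sum()),
    )
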