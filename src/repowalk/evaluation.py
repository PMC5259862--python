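"""Cross-validated ranking evaluation: ROC/AUC, top-rank hit counts, and the
two-pass versus single-pass comparison.

Known associations are split into k folds of near-equal size by association
(not by drug or disease). For each fold the association-derived similarities
and the transition matrix are rebuilt from the training edges only — held-out
edges contribute nothing to the model, they merely become candidates — and
every candidate pair of the training network is scored. Candidate pairs from
all folds are pooled for the headline ROC/AUC; per-fold AUCs and their mean
are reported alongside. Hit counts use per-disease rankings of candidate
drugs: a held-out association counts as recovered at threshold t if its drug
ranks in the top t candidates for its disease (rank <= t, inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .model import TwoPassRandomWalk
from .netio import AssociationNetwork, FeatureMatrix, WalkConfig

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (1, 10, 20, 50, 100)

Edge = tuple[str, str]


@dataclass
class CVResult:
    """Metrics of one cross-validated ranking experiment."""

    fold_assignments: dict[Edge, int]
    fold_aucs: list[float]
    pooled_auc: float
    roc_points: np.ndarray  # columns (fpr, tpr), pooled
    hits_at: dict[int, int]
    n_test_edges: int

    @property
    def mean_fold_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


class PassComparison(NamedTuple):
    two_pass: CVResult
    drug_centric: CVResult
    disease_centric: CVResult


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """Rank-based (Mann-Whitney) AUC with ties counted 1/2, plus ROC points.

    Equals the trapezoidal area under the (FPR, TPR) curve. Raises
    ``ValueError`` unless both classes are present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D of equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both positive and negative labels")
    ranks = rankdata(scores)  # midranks handle ties as 1/2
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(auc), np.column_stack([fpr, tpr])


def hits_at_thresholds(
    per_query_rankings: Mapping[str, Sequence[str]],
    test_edges: Sequence[Edge],
    thresholds: Sequence[int],
) -> dict[int, int]:
    """Count held-out associations recovered within each top-rank threshold.

    ``per_query_rankings`` maps a disease id to its candidate drugs ordered
    best-first; a test edge (drug, disease) is a hit at threshold t if the
    drug appears among the first t entries for that disease (inclusive).
    The counts are nondecreasing in t and saturate at ``len(test_edges)``.
    """
    ranks = []
    for drug, disease in test_edges:
        ranking = per_query_rankings.get(disease, ())
        try:
            ranks.append(list(ranking).index(drug) + 1)
        except ValueError:
            ranks.append(np.inf)  # not a candidate for this query
    ranks = np.asarray(ranks, dtype=float)
    return {int(t): int((ranks <= t).sum()) for t in thresholds}


def make_folds(
    net: AssociationNetwork, n_folds: int, seed: int
) -> dict[Edge, int]:
    """Randomly partition the known associations into folds 1..n_folds whose
    sizes differ by at most one. Deterministic given the seed."""
    edges = net.edges()
    if n_folds < 2:
        raise ValueError(f"n_folds must be >= 2, got {n_folds}")
    if n_folds > len(edges):
        raise ValueError(
            f"n_folds ({n_folds}) exceeds the number of associations ({len(edges)})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(edges))
    assignment: dict[Edge, int] = {}
    for fold, chunk in enumerate(np.array_split(order, n_folds), start=1):
        for idx in chunk:
            assignment[edges[idx]] = fold
    return assignment


def _per_disease_rankings(
    table: pd.DataFrame, score_column: str
) -> dict[str, list[str]]:
    ordered = table.sort_values(
        [score_column, "drug_id"], ascending=[False, True], kind="mergesort"
    )
    return {
        disease: list(group["drug_id"])
        for disease, group in ordered.groupby("disease_id", sort=False)
    }


def _run_folds(
    net: AssociationNetwork,
    fp: FeatureMatrix,
    cv_concepts: FeatureMatrix,
    cfg: WalkConfig,
    n_folds: int,
    seed: int,
    fold_assignments: Mapping[Edge, int] | None = None,
) -> tuple[dict[Edge, int], list[pd.DataFrame], list[list[Edge]]]:
    """Score every fold once; variant metrics are derived from the score
    columns afterwards, so the three-way pass comparison shares identical
    folds and walks."""
    if fold_assignments is None:
        assignment = make_folds(net, n_folds, seed)
    else:
        assignment = dict(fold_assignments)
        if set(assignment) != set(net.edges()):
            raise ValueError("fold_assignments must cover exactly the known edges")
        n_folds = max(assignment.values())
    tables: list[pd.DataFrame] = []
    fold_edges: list[list[Edge]] = []
    for fold in range(1, n_folds + 1):
        test = [e for e, f in assignment.items() if f == fold]
        train_net = net.without_edges(test)
        if not train_net.adjacency.any():
            raise ValueError(f"fold {fold} leaves an empty training network")
        est = TwoPassRandomWalk(
            lambda_jump=cfg.lambda_jump,
            alpha_restart=cfg.alpha_restart,
            eta_tradeoff=cfg.eta_tradeoff,
            epsilon=cfg.epsilon,
            max_iter=cfg.max_iter,
        ).fit(train_net, fp, cv_concepts)
        table = est.predict()
        test_set = set(test)
        table["label"] = [
            int((d, s) in test_set)
            for d, s in zip(table["drug_id"], table["disease_id"])
        ]
        tables.append(table)
        fold_edges.append(test)
    return assignment, tables, fold_edges


def _metrics(
    assignment: dict[Edge, int],
    tables: list[pd.DataFrame],
    fold_edges: list[list[Edge]],
    score_column: str,
    thresholds: Sequence[int],
) -> CVResult:
    fold_aucs = []
    hits = {int(t): 0 for t in thresholds}
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for table, test in zip(tables, fold_edges):
        auc, _ = roc_auc(table[score_column], table["label"])
        fold_aucs.append(auc)
        pooled_scores.append(table[score_column].to_numpy())
        pooled_labels.append(table["label"].to_numpy())
        fold_hits = hits_at_thresholds(
            _per_disease_rankings(table, score_column), test, thresholds
        )
        for t, c in fold_hits.items():
            hits[t] += c
    pooled_auc, roc_points = roc_auc(
        np.concatenate(pooled_scores), np.concatenate(pooled_labels)
    )
    return CVResult(
        fold_assignments=assignment,
        fold_aucs=fold_aucs,
        pooled_auc=pooled_auc,
        roc_points=roc_points,
        hits_at=hits,
        n_test_edges=len(assignment),
    )


def cross_validate(
    net: AssociationNetwork,
    fp: FeatureMatrix,
    cv_concepts: FeatureMatrix,
    cfg: WalkConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    score_column: str = "mean_prob",
    fold_assignments: Mapping[Edge, int] | None = None,
) -> CVResult:
    """k-fold cross-validation of the two-pass walk on one network.

    Association-derived similarities and the transition matrix are rebuilt per
    fold from training edges only. ``score_column`` selects the ranking score
    (``mean_prob`` for the two-pass method, ``drug_centric_prob`` or
    ``disease_centric_prob`` for a single pass). A precomputed edge-to-fold
    mapping may be supplied instead of the random split.
    """
    cfg = cfg or WalkConfig()
    assignment, tables, fold_edges = _run_folds(
        net, fp, cv_concepts, cfg, n_folds, seed, fold_assignments
    )
    return _metrics(assignment, tables, fold_edges, score_column, thresholds)


def compare_passes(
    net: AssociationNetwork,
    fp: FeatureMatrix,
    cv_concepts: FeatureMatrix,
    cfg: WalkConfig | None = None,
    seed: int = 0,
    n_folds: int = 10,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    fold_assignments: Mapping[Edge, int] | None = None,
) -> PassComparison:
    """Evaluate the two-pass score against each single pass on identical folds.

    All three variants share the same fold split and the same walks; they
    differ only in which score column ranks the candidates.
    """
    cfg = cfg or WalkConfig()
    assignment, tables, fold_edges = _run_folds(
        net, fp, cv_concepts, cfg, n_folds, seed, fold_assignments
    )
    return PassComparison(
        two_pass=_metrics(assignment, tables, fold_edges, "mean_prob", thresholds),
        drug_centric=_metrics(assignment, tables, fold_edges, "drug_centric_prob", thresholds),
        disease_centric=_metrics(
            assignment, tables, fold_edges, "disease_centric_prob", thresholds
        ),
    )
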