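"""Scikit-learn style estimator wrapping the two-pass restart walk.

``TwoPassRandomWalk`` is the package's front door: ``fit`` ingests a training
association network plus drug/disease features (or precomputed similarity
matrices), builds the fused similarity networks and the heterogeneous
transition matrix, and ``predict`` scores candidate pairs. The module-level
functions in :mod:`repowalk.similarity`, :mod:`repowalk.heterograph` and
:mod:`repowalk.walker` do the actual work and remain usable on their own.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd
from sklearn.base import BaseEstimator

from . import heterograph, similarity, walker
from .netio import AssociationNetwork, FeatureMatrix, SimilarityMatrix, WalkConfig


class TwoPassRandomWalk(BaseEstimator):
    """Two-pass random walk with restart on a drug-disease heterogeneous network.

    Parameters
    ----------
    lambda_jump : float, default 0.8
        Probability of crossing between the drug and disease networks along a
        known association edge.
    alpha_restart : float, default 0.3
        Restart probability back to the seed distribution at each step.
    eta_tradeoff : float, default 0.4
        Initial-mass split between the seed node and its cross-type
        associated nodes.
    epsilon : float, default 1e-10
        L1 convergence tolerance of the iteration.
    max_iter : int, default 10000
        Iteration cap; exceeded only on pathological inputs.
    zero_diagonal : bool, default True
        Drop similarity self-loops before transition normalisation.

    Attributes (after ``fit``)
    --------------------------
    network_ : AssociationNetwork
        The training association network.
    drug_similarity_, disease_similarity_ : SimilarityMatrix
        Fused intra-type similarity networks.
    transition_ : TransitionMatrix
        The assembled row-stochastic transition matrix.

    Examples
    --------
    >>> net, fp, cv = simulate_fixture(20, 15, 2, 0.6, 0.05, 64, 0.1, seed=0)
    >>> scores = TwoPassRandomWalk().fit(net, fp, cv).predict()
    """

    def __init__(
        self,
        lambda_jump: float = 0.8,
        alpha_restart: float = 0.3,
        eta_tradeoff: float = 0.4,
        epsilon: float = 1.0e-10,
        max_iter: int = 10_000,
        zero_diagonal: bool = True,
    ):
        self.lambda_jump = lambda_jump
        self.alpha_restart = alpha_restart
        self.eta_tradeoff = eta_tradeoff
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.zero_diagonal = zero_diagonal

    # ------------------------------------------------------------------
    def _walk_config(self) -> WalkConfig:
        return WalkConfig(
            lambda_jump=self.lambda_jump,
            alpha_restart=self.alpha_restart,
            eta_tradeoff=self.eta_tradeoff,
            epsilon=self.epsilon,
            max_iter=self.max_iter,
        )

    def fit(
        self,
        network: AssociationNetwork,
        drug_features: FeatureMatrix | None = None,
        disease_features: FeatureMatrix | None = None,
        *,
        drug_similarity: SimilarityMatrix | None = None,
        disease_similarity: SimilarityMatrix | None = None,
    ) -> "TwoPassRandomWalk":
        """Build the similarity networks and transition matrix.

        Per node type supply either a feature matrix (fingerprints for drugs,
        concept weights for diseases) or a precomputed feature-based
        similarity matrix; the association-derived bipartite-projection
        similarity is always computed from ``network`` and fused in with the
        probability disjunction.
        """
        self._walk_config()  # validates parameter ranges up front
        sim_c = self._side_similarity(
            network, drug_features, drug_similarity, "drug"
        )
        sim_d = self._side_similarity(
            network, disease_features, disease_similarity, "disease"
        )
        self.network_ = network
        self.drug_similarity_ = sim_c
        self.disease_similarity_ = sim_d
        self.transition_ = heterograph.build_transition(
            sim_c,
            sim_d,
            network,
            self.lambda_jump,
            zero_diagonal=self.zero_diagonal,
        )
        return self

    @staticmethod
    def _side_similarity(
        network: AssociationNetwork,
        features: FeatureMatrix | None,
        precomputed: SimilarityMatrix | None,
        side: str,
    ) -> SimilarityMatrix:
        ids = network.drug_ids if side == "drug" else network.disease_ids
        if (features is None) == (precomputed is None):
            raise ValueError(
                f"supply exactly one of {side} features or a precomputed "
                f"{side} similarity matrix"
            )
        if precomputed is not None:
            feature_sim = precomputed.reindex(ids)
        elif side == "drug":
            feature_sim = similarity.jaccard_similarity(features.reindex(ids))
        else:
            feature_sim = similarity.cosine_similarity(features.reindex(ids))
        return similarity.disjunctive_combine(
            feature_sim, similarity.bipartite_projection(network, side)
        )

    # ------------------------------------------------------------------
    def predict(
        self, candidates: Sequence[tuple[str, str]] | None = None
    ) -> pd.DataFrame:
        """Score candidate pairs; see :func:`repowalk.walker.score_all`."""
        self._check_fitted()
        return walker.score_all(
            self.network_, self.transition_, self._walk_config(), candidates
        )

    def predict_pair(self, drug_id: str, disease_id: str) -> tuple[float, float, float]:
        """(drug-centric, disease-centric, mean) score for one candidate pair."""
        self._check_fitted()
        return walker.score_pair(
            self.network_.drug_index(drug_id),
            self.network_.disease_index(disease_id),
            self.transition_,
            self.network_,
            self._walk_config(),
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "transition_"):
            raise RuntimeError("this TwoPassRandomWalk instance is not fitted yet")
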