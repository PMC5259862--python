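"""Assembly of the heterogeneous-network transition matrix.

The walk operates on the block matrix

    T = [[T_cc, T_cd],
         [T_dc, T_dd]]

over drugs-then-diseases. For a drug with at least one known association a
fraction ``lambda_jump`` of its transition mass crosses to its associated
diseases (split equally) and ``1 - lambda_jump`` stays inside the drug
network, spread proportionally to row-normalised drug-drug similarity; a drug
with no associations keeps all its mass inside the drug network. Disease rows
are defined dually. Every row of T therefore sums to 1, except documented
degenerate rows which sum to 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .netio import AssociationNetwork, SimilarityMatrix

logger = logging.getLogger(__name__)

#: above this node count the assembled matrix is stored sparse (CSR)
SPARSE_THRESHOLD = 3000


@dataclass(eq=False)
class TransitionMatrix:
    """Row-stochastic transition matrix of the drug-disease heterogeneous
    network, stored as one (n+m) x (n+m) array (dense or CSR)."""

    drug_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    matrix: object  # np.ndarray | scipy.sparse.csr_array
    lambda_jump: float

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def size(self) -> int:
        return self.n_drugs + self.n_diseases

    @property
    def node_ids(self) -> tuple[str, ...]:
        return self.drug_ids + self.disease_ids

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.matrix)

    def dense(self) -> np.ndarray:
        return self.matrix.toarray() if self.is_sparse else np.asarray(self.matrix)

    # block views (dense)
    @property
    def t_cc(self) -> np.ndarray:
        return self.dense()[: self.n_drugs, : self.n_drugs]

    @property
    def t_cd(self) -> np.ndarray:
        return self.dense()[: self.n_drugs, self.n_drugs :]

    @property
    def t_dc(self) -> np.ndarray:
        return self.dense()[self.n_drugs :, : self.n_drugs]

    @property
    def t_dd(self) -> np.ndarray:
        return self.dense()[self.n_drugs :, self.n_drugs :]


def _intra_cross(
    w: np.ndarray,
    assoc: np.ndarray,
    lambda_jump: float,
    zero_diagonal: bool,
    what: str,
) -> tuple[np.ndarray, np.ndarray]:
    """One side's intra-type and cross-type blocks.

    ``w``: similarity among the side's nodes; ``assoc``: that side's view of
    the association matrix (rows = this side).
    """
    w = w.astype(np.float64, copy=True)
    if zero_diagonal:
        np.fill_diagonal(w, 0.0)
    sim_mass = w.sum(axis=1)
    k = assoc.sum(axis=1)
    has_assoc = k > 0

    intra_weight = np.where(has_assoc, 1.0 - lambda_jump, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        intra = np.where(
            sim_mass[:, None] > 0, w / sim_mass[:, None] * intra_weight[:, None], 0.0
        )
        cross = np.where(
            has_assoc[:, None], lambda_jump * assoc / np.where(k, k, 1)[:, None], 0.0
        )

    # A node with associations but no similarity mass cannot place its
    # (1 - lambda) share anywhere intra-type; give the cross block its full
    # mass instead so the row still sums to 1. With lambda_jump = 0 crossing
    # is forbidden, so the row is left all-zero (absorbing leak, replenished
    # by the restart term).
    starved = has_assoc & (sim_mass == 0)
    if starved.any() and lambda_jump > 0:
        cross[starved] = assoc[starved] / k[starved, None]
        logger.warning(
            "%d %s node(s) have associations but zero similarity mass; "
            "their full transition mass was moved to the cross block",
            int(starved.sum()),
            what,
        )
    return intra, cross


def build_transition(
    sim_drug: SimilarityMatrix,
    sim_disease: SimilarityMatrix,
    net: AssociationNetwork,
    lambda_jump: float,
    *,
    zero_diagonal: bool = True,
    sparse: bool | None = None,
) -> TransitionMatrix:
    """Assemble the transition matrix from the two similarity networks and the
    association network.

    ``zero_diagonal`` removes similarity self-loops before row normalisation
    (the walk jumps between distinct nodes; self-loops would siphon mass).
    ``sparse`` forces the storage format; by default matrices above
    ``SPARSE_THRESHOLD`` nodes are stored CSR, with identical values either way.
    """
    if not 0.0 <= lambda_jump <= 1.0:
        raise ValueError(f"lambda_jump must be in [0, 1], got {lambda_jump}")
    if sim_drug.ids != net.drug_ids:
        raise ValueError("drug similarity ids do not match the network's drug ids")
    if sim_disease.ids != net.disease_ids:
        raise ValueError("disease similarity ids do not match the network's disease ids")

    a = net.adjacency.astype(np.float64)
    t_cc, t_cd = _intra_cross(sim_drug.values, a, lambda_jump, zero_diagonal, "drug")
    t_dd, t_dc = _intra_cross(sim_disease.values, a.T, lambda_jump, zero_diagonal, "disease")

    full = np.block([[t_cc, t_cd], [t_dc, t_dd]])
    n_nodes = full.shape[0]
    if sparse is None:
        sparse = n_nodes > SPARSE_THRESHOLD
    matrix = sp.csr_array(full) if sparse else full
    return TransitionMatrix(net.drug_ids, net.disease_ids, matrix, lambda_jump)


def assert_stochastic(T: TransitionMatrix, tol: float = 1e-10) -> list[str]:
    """Check that every row sums to 1 (connected node) or 0 (isolated node).

    Returns the ids of zero-row nodes; raises ``ValueError`` naming the worst
    offending row otherwise.
    """
    m = T.matrix
    sums = np.asarray(m.sum(axis=1)).ravel()
    dist = np.minimum(np.abs(sums - 1.0), np.abs(sums))
    worst = int(np.argmax(dist))
    if dist[worst] > tol:
        raise ValueError(
            f"transition matrix is not row-stochastic: row {worst} "
            f"({T.node_ids[worst]!r}) sums to {sums[worst]!r}"
        )
    return [T.node_ids[i] for i in np.nonzero(np.abs(sums) <= tol)[0]]
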