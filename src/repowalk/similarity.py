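"""Drug-drug and disease-disease similarity measures and their fusion.

Two measures exist per node type: a feature-based one (Jaccard on binary
chemical fingerprints for drugs, cosine on nonnegative concept-weight vectors
for diseases) and an association-based one (two-step resource-allocation
projection of the bipartite association network). The two are fused with the
probability-disjunction rule ``w = 1 - (1 - w1)(1 - w2)``.

Conventions for degenerate input, applied consistently:

* an all-zero feature vector has similarity 0 to everything, itself included
  (no evidence, rather than NaN);
* an isolated node (no associations) gets an all-zero projection row, matching
  the rule that nodes sharing no neighbour have similarity 0.
"""

from __future__ import annotations

import numpy as np

from .netio import AssociationNetwork, FeatureMatrix, SimilarityMatrix


def jaccard_similarity(fp: FeatureMatrix) -> SimilarityMatrix:
    """Pairwise Jaccard similarity of binary fingerprint rows.

    ``w[i, j] = |f_i AND f_j| / |f_i OR f_j|``; the diagonal is 1 for any
    nonzero row and 0 for an all-zero row.
    """
    if fp.kind != "fingerprint":
        raise ValueError(f"expected fingerprint features, got kind={fp.kind!r}")
    f = fp.values.astype(np.float64)
    inter = f @ f.T
    counts = f.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(union > 0, inter / union, 0.0)
    return SimilarityMatrix(fp.row_ids, w, symmetric=True)


def cosine_similarity(cv: FeatureMatrix) -> SimilarityMatrix:
    """Pairwise cosine similarity of nonnegative concept-weight rows.

    Values lie in [0, 1] because all entries are nonnegative. All-zero rows
    get similarity 0 everywhere, including the diagonal.
    """
    if cv.kind != "concept":
        raise ValueError(f"expected concept features, got kind={cv.kind!r}")
    t = cv.values.astype(np.float64)
    norms = np.linalg.norm(t, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = np.where(norms[:, None] > 0, t / norms[:, None], 0.0)
    w = np.clip(unit @ unit.T, 0.0, 1.0)
    return SimilarityMatrix(cv.row_ids, w, symmetric=True)


def bipartite_projection(net: AssociationNetwork, side: str) -> SimilarityMatrix:
    """Resource-allocation similarity from the bipartite association network.

    Each node of the chosen side distributes one unit of resource equally over
    its cross-type neighbours, which redistribute equally back; ``w[i, j]`` is
    the fraction node i's resource that lands on node j. On the drug side

        w[i, j] = (1 / k(c_i)) * sum_l  a_il * a_jl / k(d_l)

    and dually for diseases. The measure is NOT symmetric. A row of a
    connected node sums to exactly 1 (resource conservation); an isolated
    node's row is all zeros.
    """
    if side == "drug":
        a = net.adjacency.astype(np.float64)
    elif side == "disease":
        a = net.adjacency.T.astype(np.float64)
    else:
        raise ValueError(f"side must be 'drug' or 'disease', got {side!r}")
    k_row = a.sum(axis=1)  # degree of the projected side
    k_col = a.sum(axis=0)  # degree of the opposite side
    with np.errstate(divide="ignore", invalid="ignore"):
        src = np.where(k_row[:, None] > 0, a / k_row[:, None], 0.0)
        back = np.where(k_col[None, :] > 0, a / k_col[None, :], 0.0)
    w = src @ back.T
    ids = net.drug_ids if side == "drug" else net.disease_ids
    return SimilarityMatrix(ids, w, symmetric=False)


def disjunctive_combine(s1: SimilarityMatrix, s2: SimilarityMatrix) -> SimilarityMatrix:
    """Fuse two similarity matrices with the probability disjunction
    ``w = 1 - (1 - w1)(1 - w2)`` (evidence treated as independent).

    Commutative and monotone nondecreasing in each argument; 0 is neutral and
    1 absorbing. The result is flagged symmetric only if both inputs are.
    """
    if s1.ids != s2.ids:
        raise ValueError("cannot combine similarity matrices with different ids")
    w = 1.0 - (1.0 - s1.values) * (1.0 - s2.values)
    return SimilarityMatrix(s1.ids, w, symmetric=s1.symmetric and s2.symmetric)


def drug_similarity(net: AssociationNetwork, fp: FeatureMatrix) -> SimilarityMatrix:
    """Comprehensive drug-drug similarity: fingerprint Jaccard fused with the
    drug-side bipartite projection."""
    return disjunctive_combine(
        jaccard_similarity(fp.reindex(net.drug_ids)), bipartite_projection(net, "drug")
    )


def disease_similarity(net: AssociationNetwork, cv: FeatureMatrix) -> SimilarityMatrix:
    """Comprehensive disease-disease similarity: concept-vector cosine fused
    with the disease-side bipartite projection."""
    return disjunctive_combine(
        cosine_similarity(cv.reindex(net.disease_ids)),
        bipartite_projection(net, "disease"),
    )
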