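"""Restart-walk iteration, seed distributions, and two-pass scoring.

The walk iterates ``P(t+1) = (1 - alpha) T' P(t) + alpha P0`` where ``T'`` is
the transpose of the row-stochastic transition matrix (the column-action form:
probability mass flows along transitions) and ``alpha`` is the restart
probability. Convergence is declared when the L1 change between successive
iterates drops below ``epsilon``. For ``alpha > 0`` the fixed point is unique,
so the starting vector (we use ``P0`` itself) affects only the iteration
count.

A candidate pair (drug i, disease j) is scored by two passes: the drug-centric
walk seeded on drug i and its known diseases, read out at disease j, and the
disease-centric walk seeded on disease j and its known drugs, read out at drug
i. The mean of the two steady-state probabilities is the confidence score.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .heterograph import TransitionMatrix
from .netio import SCORE_COLUMNS, AssociationNetwork, WalkConfig


def mean_score(drug_centric_prob, disease_centric_prob):
    """Two-pass fusion: the confidence score of a candidate pair is the mean
    of its drug-centric and disease-centric steady-state probabilities.
    Accepts scalars or arrays; always lies between the two inputs."""
    return (np.asarray(drug_centric_prob) + np.asarray(disease_centric_prob)) / 2.0


def initial_drug_centric(
    drug_index: int, net: AssociationNetwork, eta: float
) -> np.ndarray:
    """Seed distribution for the drug-centric pass.

    Mass ``eta`` goes to the query drug; mass ``1 - eta`` is split equally
    over its known associated diseases. A drug with no known diseases gets the
    full unit mass itself (eta effectively 1), so new drugs remain scorable.
    """
    n, m = net.n_drugs, net.n_diseases
    if not 0 <= drug_index < n:
        raise IndexError(f"drug index {drug_index} out of range [0, {n})")
    p0 = np.zeros(n + m)
    row = net.adjacency[drug_index]
    k = int(row.sum())
    if k == 0:
        p0[drug_index] = 1.0
    else:
        p0[drug_index] = eta
        p0[n:] = (1.0 - eta) * row / k
    return p0


def initial_disease_centric(
    disease_index: int, net: AssociationNetwork, eta: float
) -> np.ndarray:
    """Seed distribution for the disease-centric pass (mirror image of
    :func:`initial_drug_centric`: eta on the disease, 1 - eta spread equally
    over its associated drugs)."""
    n, m = net.n_drugs, net.n_diseases
    if not 0 <= disease_index < m:
        raise IndexError(f"disease index {disease_index} out of range [0, {m})")
    p0 = np.zeros(n + m)
    col = net.adjacency[:, disease_index]
    k = int(col.sum())
    if k == 0:
        p0[n + disease_index] = 1.0
    else:
        p0[n + disease_index] = eta
        p0[:n] = (1.0 - eta) * col / k
    return p0


def _rwr_op(op, p0: np.ndarray, alpha: float, epsilon: float, max_iter: int):
    """Iterate to the fixed point given the column-action operator ``op``
    (i.e. ``op @ p`` computes ``T' p``)."""
    restart = alpha * p0
    p = p0.copy()
    for t in range(1, max_iter + 1):
        p_next = (1.0 - alpha) * (op @ p) + restart
        residual = np.abs(p_next - p).sum()
        p = p_next
        if residual < epsilon:
            return p, t
    raise RuntimeError(
        f"restart walk did not converge within {max_iter} iterations "
        f"(final L1 residual {residual:.3e} >= {epsilon:.3e})"
    )


def rwr(
    T: TransitionMatrix,
    p0: np.ndarray,
    alpha: float,
    epsilon: float = 1.0e-10,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, int]:
    """Run the restart iteration to its steady state.

    Returns the first iterate whose L1 change falls below ``epsilon`` together
    with the number of iterations taken. Raises ``RuntimeError`` with the
    final residual on non-convergence. With ``alpha = 1`` the result is ``P0``
    after a single step.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (T.size,):
        raise ValueError(f"p0 has shape {p0.shape}, expected ({T.size},)")
    return _rwr_op(T.matrix.T, p0, alpha, epsilon, max_iter)


def _steady_states(
    T: TransitionMatrix, net: AssociationNetwork, cfg: WalkConfig
) -> tuple[np.ndarray, np.ndarray, int]:
    """All drug-centric and disease-centric steady states.

    Exactly one walk per drug and one per disease is executed (n + m walks in
    total); each steady state serves every candidate pair that involves its
    seed. Returns (P_drug of shape (n, n+m), P_disease of shape (m, n+m),
    walk count).
    """
    n, m = net.n_drugs, net.n_diseases
    op = T.matrix.T
    p_drug = np.empty((n, n + m))
    p_disease = np.empty((m, n + m))
    for i in range(n):
        p_drug[i], _ = _rwr_op(
            op,
            initial_drug_centric(i, net, cfg.eta_tradeoff),
            cfg.alpha_restart,
            cfg.epsilon,
            cfg.max_iter,
        )
    for j in range(m):
        p_disease[j], _ = _rwr_op(
            op,
            initial_disease_centric(j, net, cfg.eta_tradeoff),
            cfg.alpha_restart,
            cfg.epsilon,
            cfg.max_iter,
        )
    return p_drug, p_disease, n + m


def score_pair(
    drug_index: int,
    disease_index: int,
    T: TransitionMatrix,
    net: AssociationNetwork,
    cfg: WalkConfig,
) -> tuple[float, float, float]:
    """Two-pass score of one candidate pair.

    Returns ``(drug_centric, disease_centric, mean)``: the drug-centric walk's
    steady-state probability at the disease node, the disease-centric walk's
    steady-state probability at the drug node, and their mean. The pair must
    not be a known association of ``net`` (known edges are not candidates).
    """
    if net.adjacency[drug_index, disease_index]:
        raise ValueError(
            f"({net.drug_ids[drug_index]}, {net.disease_ids[disease_index]}) "
            "is a known association, not a candidate"
        )
    op = T.matrix.T
    p_c, _ = _rwr_op(
        op,
        initial_drug_centric(drug_index, net, cfg.eta_tradeoff),
        cfg.alpha_restart,
        cfg.epsilon,
        cfg.max_iter,
    )
    p_d, _ = _rwr_op(
        op,
        initial_disease_centric(disease_index, net, cfg.eta_tradeoff),
        cfg.alpha_restart,
        cfg.epsilon,
        cfg.max_iter,
    )
    p_dc = float(p_c[net.n_drugs + disease_index])
    p_cc = float(p_d[drug_index])
    return p_dc, p_cc, float(mean_score(p_dc, p_cc))


def score_all(
    net: AssociationNetwork,
    T: TransitionMatrix,
    cfg: WalkConfig,
    candidates: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Score candidate drug-disease pairs with the two-pass walk.

    Runs one walk per drug and one per disease (never one per pair) and reads
    all candidate scores off the cached steady states. ``candidates`` defaults
    to every pair absent from the training network; known edges are excluded
    from the ranking either way. The returned table has columns
    ``drug_id, disease_id, drug_centric_prob, disease_centric_prob, mean_prob,
    rank``, ordered by descending mean probability with deterministic
    (drug_id, disease_id) tie-breaks; ``df.attrs['n_walks']`` records the
    number of walks executed.
    """
    n = net.n_drugs
    p_drug, p_disease, n_walks = _steady_states(T, net, cfg)
    if candidates is None:
        ii, jj = np.nonzero(net.adjacency == 0)
    else:
        ii = np.array([net.drug_index(d) for d, _ in candidates], dtype=int)
        jj = np.array([net.disease_index(s) for _, s in candidates], dtype=int)
        if net.adjacency[ii, jj].any():
            raise ValueError("candidate list contains known associations")
    p_dc = p_drug[ii, n + jj]
    p_cc = p_disease[jj, ii]
    table = pd.DataFrame(
        {
            "drug_id": [net.drug_ids[i] for i in ii],
            "disease_id": [net.disease_ids[j] for j in jj],
            "drug_centric_prob": p_dc,
            "disease_centric_prob": p_cc,
            "mean_prob": mean_score(p_dc, p_cc),
        }
    )
    table = table.sort_values(
        ["mean_prob", "drug_id", "disease_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table = table[SCORE_COLUMNS]
    table.attrs["n_walks"] = n_walks
    return table
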