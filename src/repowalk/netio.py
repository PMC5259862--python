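"""Domain types, tabular readers/writers, and the synthetic fixture generator.

All on-disk formats are plain tab-separated text:

* association edge lists: two columns ``drug_id<TAB>disease_id``, optional
  header line ``drug_id<TAB>disease_id``;
* labelled matrices: one header row of column labels with a corner cell,
  one label column;
* score tables: the columns written by :func:`write_scores`.

Identifier order is always first-appearance order in the file, so matrices
rebuilt from the same input are bit-for-bit reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCORE_COLUMNS = [
    "drug_id",
    "disease_id",
    "drug_centric_prob",
    "disease_centric_prob",
    "mean_prob",
    "rank",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass(eq=False)
class AssociationNetwork:
    """A bipartite drug-disease association network.

    Holds the ordered drug identifiers, the ordered disease identifiers and
    the binary n x m adjacency matrix A with ``A[i, l] = 1`` iff drug i has a
    known association with disease l.
    """

    drug_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = tuple(str(d) for d in self.drug_ids)
        self.disease_ids = tuple(str(d) for d in self.disease_ids)
        _check_unique(self.drug_ids, "drug ids")
        _check_unique(self.disease_ids, "disease ids")
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape != (len(self.drug_ids), len(self.disease_ids)):
            raise ValueError(
                f"adjacency shape {a.shape} does not match "
                f"({len(self.drug_ids)}, {len(self.disease_ids)})"
            )
        if a.shape[0] < 1 or a.shape[1] < 1:
            raise ValueError("need at least one drug and one disease")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def drug_degrees(self) -> np.ndarray:
        """k(c_i): number of associated diseases per drug."""
        return self.adjacency.sum(axis=1).astype(np.int64)

    @property
    def disease_degrees(self) -> np.ndarray:
        """k(d_l): number of associated drugs per disease."""
        return self.adjacency.sum(axis=0).astype(np.int64)

    def edges(self) -> list[tuple[str, str]]:
        """Known associations as (drug_id, disease_id) pairs, row-major order."""
        ii, jj = np.nonzero(self.adjacency)
        return [(self.drug_ids[i], self.disease_ids[j]) for i, j in zip(ii, jj)]

    def drug_index(self, drug_id: str) -> int:
        return self.drug_ids.index(drug_id)

    def disease_index(self, disease_id: str) -> int:
        return self.disease_ids.index(disease_id)

    def without_edges(self, edges: Iterable[tuple[str, str]]) -> "AssociationNetwork":
        """Copy of the network with the given associations removed.

        Node sets are preserved even if a node loses all its edges, which is
        exactly what a cross-validation fold needs.
        """
        a = self.adjacency.copy()
        for drug, disease in edges:
            a[self.drug_index(drug), self.disease_index(disease)] = 0
        return AssociationNetwork(self.drug_ids, self.disease_ids, a)


@dataclass(eq=False)
class FeatureMatrix:
    """Per-node feature vectors: binary chemical fingerprints for drugs or
    nonnegative concept weights (MeSH-style term weights) for diseases."""

    row_ids: tuple[str, ...]
    values: np.ndarray
    kind: str  # "fingerprint" | "concept"

    def __post_init__(self) -> None:
        self.row_ids = tuple(str(r) for r in self.row_ids)
        _check_unique(self.row_ids, "row ids")
        if self.kind not in ("fingerprint", "concept"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != len(self.row_ids):
            raise ValueError("values must be 2-D with one row per id")
        if self.kind == "fingerprint":
            if not np.isin(v, (0.0, 1.0)).all():
                raise ValueError("fingerprint entries must be 0 or 1")
        elif (v < 0).any():
            raise ValueError("concept weights must be nonnegative")
        self.values = v

    def reindex(self, ids: Sequence[str]) -> "FeatureMatrix":
        """Rows reordered (and subset) to ``ids``; every id must be present."""
        lookup = {r: i for i, r in enumerate(self.row_ids)}
        missing = [i for i in ids if i not in lookup]
        if missing:
            raise ValueError(f"feature matrix lacks rows for ids {missing[:5]}")
        sel = [lookup[i] for i in ids]
        return FeatureMatrix(tuple(ids), self.values[sel], self.kind)


@dataclass(eq=False)
class SimilarityMatrix:
    """Labelled square similarity matrix for one node type, entries in [0, 1].

    ``symmetric`` records whether the measure is symmetric; the bipartite
    projection similarity is not, and row-wise transition normalisation keeps
    asymmetric matrices well-defined downstream.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    symmetric: bool = True

    def __post_init__(self) -> None:
        self.ids = tuple(str(i) for i in self.ids)
        _check_unique(self.ids, "ids")
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"similarity matrix shape {v.shape} is not ({n}, {n})")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            bad = v[(v < -1e-12) | (v > 1 + 1e-12)]
            raise ValueError(f"similarity values outside [0, 1]: e.g. {bad.flat[0]}")
        if self.symmetric and not np.allclose(v, v.T, atol=1e-12, rtol=0):
            raise ValueError("matrix flagged symmetric but is not, within 1e-12")
        self.values = np.clip(v, 0.0, 1.0)

    def reindex(self, ids: Sequence[str]) -> "SimilarityMatrix":
        """Rows and columns reordered (and subset) to ``ids``."""
        lookup = {r: i for i, r in enumerate(self.ids)}
        missing = [i for i in ids if i not in lookup]
        if missing:
            raise ValueError(f"similarity matrix lacks ids {missing[:5]}")
        sel = np.array([lookup[i] for i in ids])
        return SimilarityMatrix(
            tuple(ids), self.values[np.ix_(sel, sel)], symmetric=self.symmetric
        )


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of the two-pass restart walk.

    lambda_jump
        probability of crossing between the drug and disease sub-networks
        along a known association edge.
    alpha_restart
        restart (teleport) probability back to the seed distribution.
    eta_tradeoff
        split of initial probability mass between the seed node and its
        cross-type associated nodes.
    epsilon
        L1 convergence tolerance of the iteration.
    """

    lambda_jump: float = 0.8
    alpha_restart: float = 0.3
    eta_tradeoff: float = 0.4
    epsilon: float = 1.0e-10
    max_iter: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_jump <= 1.0:
            raise ValueError(f"lambda_jump must be in [0, 1], got {self.lambda_jump}")
        if not 0.0 < self.alpha_restart <= 1.0:
            raise ValueError(
                f"alpha_restart must be in (0, 1], got {self.alpha_restart}"
            )
        if not 0.0 <= self.eta_tradeoff <= 1.0:
            raise ValueError(f"eta_tradeoff must be in [0, 1], got {self.eta_tradeoff}")
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if not self.max_iter >= 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_EDGE_HEADER = ("drug_id", "disease_id")


def read_associations(path, delimiter: str = "\t") -> AssociationNetwork:
    """Read a two-column (drug_id, disease_id) edge list.

    An optional header line ``drug_id<TAB>disease_id`` is skipped. Duplicate
    edges collapse to a single association (the adjacency is binary); the
    number collapsed is logged. Identifier order is first-appearance order.
    """
    path = Path(path)
    drugs: dict[str, int] = {}
    diseases: dict[str, int] = {}
    pairs: list[tuple[int, int]] = []
    n_dup = 0
    seen: set[tuple[int, int]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split(delimiter)
            if lineno == 1 and tuple(f.strip().lower() for f in fields) == _EDGE_HEADER:
                continue
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(
                    f"{path}: malformed association line {lineno}: {line!r} "
                    f"(expected two non-empty fields separated by {delimiter!r})"
                )
            drug, disease = fields[0].strip(), fields[1].strip()
            i = drugs.setdefault(drug, len(drugs))
            j = diseases.setdefault(disease, len(diseases))
            if (i, j) in seen:
                n_dup += 1
                continue
            seen.add((i, j))
            pairs.append((i, j))
    if not pairs:
        raise ValueError(f"{path}: no associations found")
    if n_dup:
        logger.warning("%s: collapsed %d duplicate association line(s)", path, n_dup)
    a = np.zeros((len(drugs), len(diseases)), dtype=np.int8)
    for i, j in pairs:
        a[i, j] = 1
    return AssociationNetwork(tuple(drugs), tuple(diseases), a)


def write_associations(net: AssociationNetwork, path, delimiter: str = "\t") -> None:
    """Write the network as a headered (drug_id, disease_id) edge list."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delimiter.join(_EDGE_HEADER) + "\n")
        for drug, disease in net.edges():
            fh.write(f"{drug}{delimiter}{disease}\n")


def _read_labelled(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    if "." in df.index or "." in df.columns:
        raise ValueError(f"{path}: '.' is not allowed as a row/column label")
    return df


def read_matrix(path, kind: str):
    """Read a labelled TSV matrix.

    ``kind`` is one of ``fingerprint``, ``concept`` (returning a
    :class:`FeatureMatrix`) or ``similarity`` (returning a
    :class:`SimilarityMatrix`; must be square with matching row/column labels).
    """
    df = _read_labelled(path)
    if kind in ("fingerprint", "concept"):
        return FeatureMatrix(tuple(df.index), df.to_numpy(dtype=float), kind)
    if kind == "similarity":
        if df.shape[0] != df.shape[1]:
            raise ValueError(
                f"{path}: similarity matrix must be square, got {df.shape}"
            )
        if list(df.index) != [str(c) for c in df.columns]:
            raise ValueError(f"{path}: row labels do not match column labels")
        v = df.to_numpy(dtype=float)
        return SimilarityMatrix(
            tuple(df.index), v, symmetric=bool(np.allclose(v, v.T, atol=1e-12, rtol=0))
        )
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(ids: Sequence[str], values: np.ndarray, path, corner: str = "id") -> None:
    """Write a labelled matrix TSV with a corner cell."""
    if corner == ".":
        raise ValueError("'.' is not allowed as the corner label")
    cols = ids if np.asarray(values).shape[1] == len(ids) else range(values.shape[1])
    df = pd.DataFrame(values, index=list(ids), columns=[str(c) for c in cols])
    df.index.name = corner
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_similarity(sim: SimilarityMatrix, path) -> None:
    write_matrix(sim.ids, sim.values, path)


def write_scores(table: pd.DataFrame, path) -> None:
    """Write a score table as TSV, sorted by mean probability descending.

    Ties break deterministically on (drug_id, disease_id). Probabilities are
    written with 10 significant digits and round-trip losslessly at that
    precision.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty score table")
    missing = [c for c in SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"score table is missing columns {missing}")
    out = table.sort_values(
        ["mean_prob", "drug_id", "disease_id"], ascending=[False, True, True]
    )
    out = out[SCORE_COLUMNS]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "disease_id": str})
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: score table is missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# synthetic fixture
# ---------------------------------------------------------------------------


def simulate_fixture(
    n_drugs: int,
    n_diseases: int,
    n_blocks: int,
    within_density: float,
    between_density: float,
    fp_bits: int,
    fp_flip_rate: float,
    seed: int,
    *,
    fingerprint_signal: bool = True,
    concept_signal: bool = True,
) -> tuple[AssociationNetwork, FeatureMatrix, FeatureMatrix]:
    """Generate a planted-block drug-disease fixture.

    Drugs and diseases are partitioned into ``n_blocks`` contiguous groups of
    near-equal size. An association edge between drug i and disease l is drawn
    with probability ``within_density`` if they belong to matching blocks and
    ``between_density`` otherwise, so block structure is the planted signal the
    walk should recover ("similar drugs treat similar diseases").

    Each drug block has a prototype fingerprint; members copy it with
    independent per-bit flip probability ``fp_flip_rate``. Each disease block
    has a prototype nonnegative concept vector; a member's vector is the convex
    mixture ``(1-r)*prototype + r*Uniform(0,1)`` with ``r = fp_flip_rate``.
    Setting ``fingerprint_signal=False`` (resp. ``concept_signal=False``)
    replaces that feature matrix by structureless noise, which is useful for
    experiments where only one side of the network carries information.

    The same ``seed`` yields bitwise-identical output. Each component draws
    from its own sub-stream keyed by a fixed offset, so changing one component
    never perturbs the draws of another.
    """
    if n_blocks < 1 or n_blocks > min(n_drugs, n_diseases):
        raise ValueError("need 1 <= n_blocks <= min(n_drugs, n_diseases)")
    for name, dens in (("within_density", within_density), ("between_density", between_density)):
        if not 0.0 <= dens <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {dens}")
    if within_density < between_density:
        raise ValueError("within_density must be >= between_density")
    if not 0.0 <= fp_flip_rate <= 1.0:
        raise ValueError(f"fp_flip_rate must be in [0, 1], got {fp_flip_rate}")
    if fp_bits < 1:
        raise ValueError("fp_bits must be >= 1")

    # fixed sub-stream offsets per component
    rng_edges = np.random.default_rng([int(seed), 0])
    rng_fp = np.random.default_rng([int(seed), 1])
    rng_cv = np.random.default_rng([int(seed), 2])

    drug_blocks = np.repeat(
        np.arange(n_blocks), np.diff(np.linspace(0, n_drugs, n_blocks + 1).astype(int))
    )
    disease_blocks = np.repeat(
        np.arange(n_blocks), np.diff(np.linspace(0, n_diseases, n_blocks + 1).astype(int))
    )

    prob = np.where(
        drug_blocks[:, None] == disease_blocks[None, :], within_density, between_density
    )
    a = (rng_edges.random((n_drugs, n_diseases)) < prob).astype(np.int8)

    if fingerprint_signal:
        proto = rng_fp.integers(0, 2, size=(n_blocks, fp_bits), dtype=np.int8)
        flips = rng_fp.random((n_drugs, fp_bits)) < fp_flip_rate
        fp = np.where(flips, 1 - proto[drug_blocks], proto[drug_blocks])
    else:
        fp = rng_fp.integers(0, 2, size=(n_drugs, fp_bits), dtype=np.int8)

    if concept_signal:
        cv_proto = rng_cv.random((n_blocks, fp_bits))
        noise = rng_cv.random((n_diseases, fp_bits))
        cv = (1.0 - fp_flip_rate) * cv_proto[disease_blocks] + fp_flip_rate * noise
    else:
        cv = rng_cv.random((n_diseases, fp_bits))

    drug_ids = tuple(f"drug{i:04d}" for i in range(n_drugs))
    disease_ids = tuple(f"disease{j:04d}" for j in range(n_diseases))
    net = AssociationNetwork(drug_ids, disease_ids, a)
    fingerprints = FeatureMatrix(drug_ids, fp.astype(float), "fingerprint")
    concepts = FeatureMatrix(disease_ids, cv, "concept")
    return net, fingerprints, concepts
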