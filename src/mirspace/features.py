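"""The five weighted feature blocks and their horizontal concatenation.

Every block is an m x * sparse nonnegative matrix over the same ordered list
of miRNAs:

* ``disease``  (m x d) -- 1 on known associations, otherwise the best Lin
  similarity between the column disease and any disease known for the miRNA;
* ``neighbor`` (m x m) -- genomic proximity through a decreasing sigmoid of
  base-pair distance;
* ``target``   (m x t) -- two-step resource-allocation diffusion of the
  binary miRNA-target matrix through the weighted one-mode target projection;
* ``word``     (m x w) -- TF-IDF over the per-miRNA abstract corpus,
  L2-normalized rows;
* ``family``   (m x f) -- raw 0/1 family membership.

The blocks concatenate, in that fixed order, into the combined matrix X.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from sklearn.feature_extraction.text import TfidfVectorizer

from .io import Dataset, tokenize
from .ontology import DiseaseOntology, lin_similarity

__all__ = [
    "BLOCK_ORDER",
    "FeatureMatrix",
    "NeighborParams",
    "CombinedMatrix",
    "sigmoid_weight",
    "genomic_distance",
    "disease_similarity_matrix",
    "build_disease_matrix",
    "build_neighbor_matrix",
    "project_targets",
    "build_target_matrix",
    "build_word_matrix",
    "build_family_matrix",
    "concatenate",
    "write_combined",
    "read_combined",
]

logger = logging.getLogger(__name__)

BLOCK_ORDER = ("disease", "neighbor", "target", "word", "family")

#: default sparsity floors; values strictly below are dropped
MD_FLOOR = 0.05
MN_FLOOR = 1e-3


@dataclass
class FeatureMatrix:
    """One sparse feature block with row (miRNA) and column labels."""

    rows: list[str]
    cols: list[str]
    block: str
    matrix: sp.csr_matrix

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.rows), len(self.cols)):
            raise ValueError(
                f"{self.block}: matrix shape {self.matrix.shape} does not match "
                f"labels ({len(self.rows)}, {len(self.cols)})"
            )


@dataclass
class NeighborParams:
    """Sigmoid parameters for the genomic-proximity weighting.

    ``dist0`` is the midpoint in bp (weight exactly 0.5 there) and
    ``steepness`` the slope in bp^-1. The default midpoint is 60 kb, matching
    the distance beyond which co-expression of neighboring miRNAs drops off.
    """

    dist0: float = 6.0e4
    steepness: float = 2.0e-4

    def __post_init__(self) -> None:
        if self.dist0 <= 0 or self.steepness <= 0:
            raise ValueError("dist0 and steepness must be positive")


@dataclass
class CombinedMatrix:
    """Horizontal concatenation of the feature blocks."""

    X: sp.csr_matrix
    row_labels: list[str]
    col_labels: list[str]
    #: list of (block name, start column, stop column); ranges partition [0, n)
    column_blocks: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def block_slice(self, block: str) -> slice:
        for name, start, stop in self.column_blocks:
            if name == block:
                return slice(start, stop)
        raise KeyError(f"no block {block!r}")

    def block_labels(self, block: str) -> list[str]:
        s = self.block_slice(block)
        return self.col_labels[s]

    def column_index(self, block: str, label: str) -> int:
        s = self.block_slice(block)
        try:
            return s.start + self.col_labels[s].index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in block {block!r}") from None


def sigmoid_weight(dist: float, params: NeighborParams) -> float:
    """Proximity weight 1 / (1 + exp(k * (dist - dist0))); 0.5 at dist0."""
    z = params.steepness * (dist - params.dist0)
    if z >= 0:  # overflow-safe for large distances
        e = np.exp(-z)
        return float(e / (1.0 + e))
    return float(1.0 / (1.0 + np.exp(z)))


def genomic_distance(locs_a, locs_b) -> float:
    """Minimum gap in bp between two location lists; inf across chromosomes.

    Coordinates are 1-based inclusive; overlapping or touching intervals have
    distance 0, otherwise the gap between the closest ends is used.
    """
    best = np.inf
    for chrom_a, _, start_a, end_a in locs_a:
        for chrom_b, _, start_b, end_b in locs_b:
            if chrom_a != chrom_b:
                continue
            gap = max(start_a - end_b, start_b - end_a, 0)
            best = min(best, gap)
    return best


def disease_similarity_matrix(diseases: list[str], ontology: DiseaseOntology) -> np.ndarray:
    """Dense symmetric matrix of pairwise Lin similarities."""
    d = len(diseases)
    S = np.eye(d)
    for i in range(d):
        for j in range(i + 1, d):
            S[i, j] = S[j, i] = lin_similarity(ontology, diseases[i], diseases[j])
    return S


def build_disease_matrix(
    dataset: Dataset,
    ontology: DiseaseOntology,
    floor: float = MD_FLOOR,
    agg: str = "max",
    similarity: np.ndarray | None = None,
    exclude: dict[str, set[str]] | None = None,
) -> FeatureMatrix:
    """Known associations at weight 1, Lin-propagated weights elsewhere.

    For miRNA i the entry at disease j is 1 when (i, j) is a known
    association and otherwise ``agg`` (max or mean) of the Lin similarity
    between j and each disease known for i. Entries below ``floor`` are
    dropped to preserve sparsity.

    ``exclude`` removes (mirna, disease) pairs before propagation and forces
    those entries to 0 afterwards — used by cross-validation so a held-out
    association leaks neither directly nor through the Lin propagation.
    """
    if agg not in ("max", "mean"):
        raise ValueError(f"agg must be 'max' or 'mean', got {agg!r}")
    diseases = dataset.diseases
    col_of = {d: j for j, d in enumerate(diseases)}
    S = similarity if similarity is not None else disease_similarity_matrix(diseases, ontology)
    exclude = exclude or {}

    rows_out = []
    for rec in dataset.mirnas:
        masked = exclude.get(rec.id, set())
        known = sorted(rec.diseases - masked)
        row = np.zeros(len(diseases))
        if known:
            idx = [col_of[d] for d in known]
            sims = S[:, idx]
            row = sims.max(axis=1) if agg == "max" else sims.mean(axis=1)
            row[idx] = 1.0
            row[row < floor] = 0.0
        for d in masked:
            if d in col_of:
                row[col_of[d]] = 0.0
        rows_out.append(sp.csr_matrix(row))
    matrix = sp.vstack(rows_out, format="csr") if rows_out else sp.csr_matrix((0, len(diseases)))
    return FeatureMatrix(rows=dataset.mirna_ids, cols=list(diseases), block="disease", matrix=matrix)


def build_neighbor_matrix(
    dataset: Dataset,
    params: NeighborParams | None = None,
    floor: float = MN_FLOOR,
) -> FeatureMatrix:
    """Symmetric genomic-proximity block; diagonal 1; weights < floor dropped."""
    params = params or NeighborParams()
    ids = dataset.mirna_ids
    m = len(ids)
    matrix = sp.lil_matrix((m, m))
    located = [bool(rec.locations) for rec in dataset.mirnas]
    for i, flag in enumerate(located):
        if not flag:
            logger.warning("miRNA %s has no genomic location; neighbor row is zero", ids[i])
    for i in range(m):
        if not located[i]:
            continue
        matrix[i, i] = 1.0
        for j in range(i + 1, m):
            if not located[j]:
                continue
            dist = genomic_distance(dataset.mirnas[i].locations, dataset.mirnas[j].locations)
            if not np.isfinite(dist):
                continue
            w = sigmoid_weight(dist, params)
            if w >= floor:
                matrix[i, j] = matrix[j, i] = w
    return FeatureMatrix(rows=ids, cols=list(ids), block="neighbor", matrix=matrix.tocsr())


def project_targets(M: sp.spmatrix | np.ndarray) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Two-step resource-allocation projection of a binary miRNA-target matrix.

    Returns ``(W, MT)``. Column l of the t x t matrix W gives the composition
    of target l's resource after one round trip through the bipartite graph:

        W[j, l] = (1 / deg(target j)) * sum_i M[i, j] * M[i, l] / deg(miRNA i)

    so each target's resource is fully redistributed (rows of W sum to 1
    whenever the target has at least one miRNA). ``MT = M @ W`` diffuses each
    miRNA's binary target vector, producing weights on existing edges and
    strictly positive weights on some implied, unreported edges. Zero-degree
    rows and columns contribute and receive nothing.
    """
    M = sp.csr_matrix(M, dtype=float)
    if M.nnz and not np.all(np.isin(M.data, (0.0, 1.0))):
        raise ValueError("target matrix must be binary")
    deg_mirna = np.asarray(M.sum(axis=1)).ravel()
    deg_target = np.asarray(M.sum(axis=0)).ravel()
    with np.errstate(divide="ignore"):
        inv_m = np.where(deg_mirna > 0, 1.0 / np.maximum(deg_mirna, 1), 0.0)
        inv_t = np.where(deg_target > 0, 1.0 / np.maximum(deg_target, 1), 0.0)
    Dm = sp.diags(inv_m)
    Dt = sp.diags(inv_t)
    W = (Dt @ M.T @ Dm @ M).tocsr()
    MT = (M @ W).tocsr()
    return W, MT


def build_target_matrix(dataset: Dataset) -> FeatureMatrix:
    genes = dataset.genes
    col_of = {g: j for j, g in enumerate(genes)}
    M = sp.lil_matrix((len(dataset.mirnas), len(genes)))
    for i, rec in enumerate(dataset.mirnas):
        for gene in rec.targets:
            M[i, col_of[gene]] = 1.0
    _, MT = project_targets(M.tocsr())
    return FeatureMatrix(rows=dataset.mirna_ids, cols=list(genes), block="target", matrix=MT)


def build_word_matrix(dataset: Dataset, zero_rows: set[str] | None = None) -> FeatureMatrix:
    """TF-IDF block: tf raw counts, idf = ln((1+m)/(1+df)) + 1, L2 rows.

    ``zero_rows`` blanks the listed miRNAs' documents before fitting, which
    both zeroes their rows and removes their contribution to the document
    frequencies (cross-validation removes all study-derived text for held-out
    miRNAs).
    """
    ids = dataset.mirna_ids
    zero_rows = zero_rows or set()
    if not dataset.vocabulary:
        matrix = sp.csr_matrix((len(ids), 0))
        return FeatureMatrix(rows=ids, cols=[], block="word", matrix=matrix)
    docs = [
        "" if rec.id in zero_rows else rec.abstract_text for rec in dataset.mirnas
    ]
    vectorizer = TfidfVectorizer(
        analyzer=tokenize, vocabulary=dataset.vocabulary, norm="l2", smooth_idf=True
    )
    matrix = sp.csr_matrix(vectorizer.fit_transform(docs))
    return FeatureMatrix(rows=ids, cols=list(dataset.vocabulary), block="word", matrix=matrix)


def build_family_matrix(dataset: Dataset) -> FeatureMatrix:
    families = dataset.families
    col_of = {f: j for j, f in enumerate(families)}
    matrix = sp.lil_matrix((len(dataset.mirnas), len(families)))
    for i, rec in enumerate(dataset.mirnas):
        if rec.family is not None:
            matrix[i, col_of[rec.family]] = 1.0
    return FeatureMatrix(
        rows=dataset.mirna_ids, cols=list(families), block="family", matrix=matrix.tocsr()
    )


def concatenate(blocks: list[FeatureMatrix]) -> CombinedMatrix:
    """Concatenate blocks horizontally in the fixed canonical order."""
    if not blocks:
        raise ValueError("no blocks to concatenate")
    names = [b.block for b in blocks]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate blocks: {names}")
    blocks = sorted(blocks, key=lambda b: BLOCK_ORDER.index(b.block))
    rows = blocks[0].rows
    for b in blocks[1:]:
        if b.rows != rows:
            diff = next(
                (i for i, (x, y) in enumerate(zip(b.rows, rows)) if x != y),
                min(len(b.rows), len(rows)),
            )
            raise ValueError(
                f"block {b.block!r} row labels differ from {blocks[0].block!r} "
                f"at position {diff}"
            )
    X = sp.hstack([b.matrix for b in blocks], format="csr")
    col_labels: list[str] = []
    column_blocks: list[tuple[str, int, int]] = []
    start = 0
    for b in blocks:
        col_labels.extend(b.cols)
        column_blocks.append((b.block, start, start + len(b.cols)))
        start += len(b.cols)
    return CombinedMatrix(X=X, row_labels=list(rows), col_labels=col_labels, column_blocks=column_blocks)


def write_combined(cm: CombinedMatrix, directory: str | Path) -> None:
    """Export as MatrixMarket plus row/column label sidecars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(str(directory / "combined.mtx"), cm.X)
    (directory / "rows.tsv").write_text(
        "".join(f"{r}\n" for r in cm.row_labels), encoding="utf-8"
    )
    block_of = {}
    for name, start, stop in cm.column_blocks:
        for j in range(start, stop):
            block_of[j] = name
    (directory / "cols.tsv").write_text(
        "".join(f"{c}\t{block_of[j]}\n" for j, c in enumerate(cm.col_labels)),
        encoding="utf-8",
    )


def read_combined(directory: str | Path) -> CombinedMatrix:
    directory = Path(directory)
    X = sp.csr_matrix(mmread(str(directory / "combined.mtx")))
    row_labels = (directory / "rows.tsv").read_text(encoding="utf-8").splitlines()
    col_labels: list[str] = []
    blocks: list[tuple[str, int, int]] = []
    for j, line in enumerate((directory / "cols.tsv").read_text(encoding="utf-8").splitlines()):
        label, block = line.split("\t")
        col_labels.append(label)
        if blocks and blocks[-1][0] == block:
            blocks[-1] = (block, blocks[-1][1], j + 1)
        else:
            blocks.append((block, j, j + 1))
    return CombinedMatrix(X=X, row_labels=row_labels, col_labels=col_labels, column_blocks=blocks)
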