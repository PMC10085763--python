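"""Covariance structures for genomic prediction and diversity analysis.

Builds every relationship/kernel matrix the prediction models consume:

* ``genomic_matrix`` — VanRaden-style G = MM'/p from column-centered,
  column-standardized dosages.
* ``pedigree_matrix`` — numerator relationship matrix A by the tabular
  method, with optional extra selfing generations per individual.
* ``gaussian_kernels`` — the kernel-averaging set exp(-h d^2) with
  bandwidths h = c/m, c in {1/5, 1, 5}, where m is the median off-diagonal
  squared Euclidean distance between lines.
* ``nei_distance`` — Nei's standard genetic distance D between
  allele-frequency profiles (a line's profile is dosage/2).
* ``pca_scores`` — principal-component scores of the centered dosages.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .genotypes import MarkerMatrix

__all__ = [
    "RelationshipMatrix",
    "DistanceSummary",
    "Pedigree",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "standardize_dosages",
    "genomic_matrix",
    "genomic_matrix_from_dosages",
    "distance_summary_from_dosages",
    "pedigree_matrix",
    "cop_matrix",
    "distance_summary",
    "gaussian_kernels",
    "nei_distance",
    "nei_distance_matrix",
    "pca_scores",
]

#: default kernel-averaging bandwidth multipliers c, giving h = c/m
DEFAULT_KERNEL_MULTIPLIERS = (1.0 / 5.0, 1.0, 5.0)


@dataclasses.dataclass
class RelationshipMatrix:
    """A named, symmetric covariance structure over a set of individuals."""

    ids: np.ndarray
    values: np.ndarray
    kind: str  # genomic | pedigree | kernel
    bandwidth: float | None = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def check_psd(self, rtol: float = 1e-8) -> None:
        """Raise if the smallest eigenvalue is below -rtol * largest."""
        w = np.linalg.eigvalsh(self.values)
        if w[0] < -rtol * max(w[-1], 1.0):
            raise ValueError(f"matrix is not PSD: min eigenvalue {w[0]:.3g}")

    def align(self, ids) -> "RelationshipMatrix":
        """Reorder/subset to the given id sequence."""
        lookup = {i: k for k, i in enumerate(self.ids)}
        idx = np.array([lookup[i] for i in ids])
        return RelationshipMatrix(
            np.asarray(ids, dtype=object),
            self.values[np.ix_(idx, idx)],
            self.kind,
            self.bandwidth,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path):
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str = "genomic") -> "RelationshipMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.index.to_numpy(dtype=object), df.to_numpy(), kind)


@dataclasses.dataclass
class DistanceSummary:
    """Pairwise squared Euclidean distances between lines plus their
    off-diagonal median m (each unordered pair counted once)."""

    ids: np.ndarray
    d2: np.ndarray
    m: float


# ---------------------------------------------------------------------------
# Genomic relationship matrix


def standardize_dosages(
    dosages: np.ndarray,
    means: np.ndarray | None = None,
    sds: np.ndarray | None = None,
) -> np.ndarray:
    """Center each marker column to mean 0 and scale to unit SD.

    External ``means``/``sds`` support standardizing selection candidates
    with training-population moments.
    """
    X = np.asarray(dosages, dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing dosages present; impute before standardizing")
    if means is None:
        means = X.mean(axis=0)
    if sds is None:
        sds = X.std(axis=0)
    if np.any(sds == 0):
        j = int(np.flatnonzero(sds == 0)[0])
        raise ValueError(
            f"marker column {j} has zero variance; run QC (monomorphic filter) first"
        )
    return (X - means) / sds


def genomic_matrix_from_dosages(
    ids,
    dosages: np.ndarray,
    means: np.ndarray | None = None,
    sds: np.ndarray | None = None,
) -> RelationshipMatrix:
    """Array-level G = MM'/p. Accepts real-valued dosages (e.g. bulk-DNA
    means of sibling plants) standardized with supplied moments."""
    X = np.asarray(dosages, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 individuals")
    M = standardize_dosages(X, means, sds)
    G = (M @ M.T) / X.shape[1]
    G = (G + G.T) / 2.0
    return RelationshipMatrix(np.asarray(ids, dtype=object), G, "genomic")


def genomic_matrix(
    mm: MarkerMatrix,
    means: np.ndarray | None = None,
    sds: np.ndarray | None = None,
) -> RelationshipMatrix:
    """G = MM'/p with M the centered, column-standardized dosage matrix and
    p the number of markers.  diag(G) averages ~1 in a large unstructured
    population."""
    return genomic_matrix_from_dosages(mm.individual_ids, mm.dosages, means, sds)


# ---------------------------------------------------------------------------
# Pedigree numerator relationship matrix


class PedigreeError(ValueError):
    pass


@dataclasses.dataclass
class PedigreeRecord:
    id: str
    parent1: str | None
    parent2: str | None
    selfing_generations: int = 0


class Pedigree:
    """Acyclic parent records; both parents known or both unknown per the
    usual crossing-record convention, with single known parents allowed.

    ``selfing_generations`` g on a record means the individual is derived
    from the cross of its parents by g additional generations of selfing
    (e.g. an F4 line recorded with its F2 plant's parents carries g=2).
    """

    def __init__(self, records: list[PedigreeRecord]):
        self.records = list(records)
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate ids in pedigree")
        self._index = {r.id: k for k, r in enumerate(self.records)}
        for r in self.records:
            for p in (r.parent1, r.parent2):
                if p is not None and p not in self._index:
                    raise PedigreeError(f"parent {p!r} of {r.id!r} is not in the pedigree")
            if r.selfing_generations < 0:
                raise PedigreeError("selfing_generations must be >= 0")
        self._order = self._toposort()

    @classmethod
    def from_tuples(cls, tuples) -> "Pedigree":
        """tuples of (id, parent1, parent2[, selfing_generations]); 0 or
        None marks an unknown parent."""
        recs = []
        for t in tuples:
            tid, p1, p2 = t[0], t[1], t[2]
            g = int(t[3]) if len(t) > 3 else 0
            p1 = None if p1 in (0, "0", None, "") else str(p1)
            p2 = None if p2 in (0, "0", None, "") else str(p2)
            recs.append(PedigreeRecord(str(tid), p1, p2, g))
        return cls(recs)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def _toposort(self) -> list[int]:
        # Kahn's algorithm; raises on cycles (an individual can never be
        # its own ancestor).
        n = len(self.records)
        children: dict[int, list[int]] = {k: [] for k in range(n)}
        indeg = [0] * n
        for k, r in enumerate(self.records):
            for p in (r.parent1, r.parent2):
                if p is not None:
                    children[self._index[p]].append(k)
                    indeg[k] += 1
        queue = sorted(k for k in range(n) if indeg[k] == 0)
        order = []
        while queue:
            k = queue.pop(0)
            order.append(k)
            for c in children[k]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != n:
            cyclic = [self.records[k].id for k in range(n) if indeg[k] > 0]
            raise PedigreeError(f"pedigree contains a cycle involving {cyclic[:5]}")
        return order

    def topological_records(self) -> list[PedigreeRecord]:
        return [self.records[k] for k in self._order]


def read_pedigree(path) -> Pedigree:
    """3- or 4-column whitespace/comma-delimited text: id parent1 parent2
    [selfing_generations]; 0 for unknown parents."""
    tuples = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) not in (3, 4):
                raise PedigreeError(f"line {ln}: expected 3 or 4 columns, got {len(parts)}")
            tuples.append(tuple(parts))
    return Pedigree.from_tuples(tuples)


def write_pedigree(ped: Pedigree, path):
    with open(path, "w") as fh:
        for r in ped.records:
            fh.write(
                f"{r.id}\t{r.parent1 or 0}\t{r.parent2 or 0}\t{r.selfing_generations}\n"
            )


def pedigree_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular method.

    Unknown parents are treated as unrelated and non-inbred.  For a record
    with both parents known, F = A(p1,p2)/2; g extra selfing generations
    accumulate inbreeding as F_g = 1 - (1 - F)/2^g.  Off-diagonals follow
    A(i,j) = (A(j,p1) + A(j,p2))/2 and are unaffected by selfing of i,
    matching expected identity-by-descent sharing.
    """
    order = ped.topological_records()
    ids = [r.id for r in order]
    pos = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for k, r in enumerate(order):
        p1 = pos[r.parent1] if r.parent1 is not None else None
        p2 = pos[r.parent2] if r.parent2 is not None else None
        if p1 is not None and p2 is not None:
            F0 = A[p1, p2] / 2.0
        else:
            F0 = 0.0
        F = 1.0 - (1.0 - F0) / (2.0 ** r.selfing_generations)
        A[k, k] = 1.0 + F
        row = np.zeros(n)
        if p1 is not None:
            row += A[:, p1]
        if p2 is not None:
            row += A[:, p2]
        row /= 2.0
        A[k, :k] = row[:k]
        A[:k, k] = row[:k]
    rel = RelationshipMatrix(np.array(ids, dtype=object), A, "pedigree")
    return rel.align(ped.ids)


def cop_matrix(A: RelationshipMatrix) -> RelationshipMatrix:
    """Coefficient-of-parentage (kinship) view of a numerator relationship
    matrix: COP = A/2."""
    return RelationshipMatrix(A.ids, A.values / 2.0, "pedigree")


# ---------------------------------------------------------------------------
# Gaussian kernels


def distance_summary_from_dosages(
    ids,
    dosages: np.ndarray,
    means: np.ndarray | None = None,
    sds: np.ndarray | None = None,
    m_subset=None,
) -> DistanceSummary:
    ids = np.asarray(ids, dtype=object)
    M = standardize_dosages(dosages, means, sds)
    d2 = squareform(pdist(M, metric="sqeuclidean"))
    if m_subset is not None:
        lookup = {i: k for k, i in enumerate(ids)}
        idx = np.array([lookup[i] for i in m_subset])
        sub = d2[np.ix_(idx, idx)]
        m = float(np.median(sub[np.triu_indices(len(idx), k=1)]))
    else:
        m = float(np.median(d2[np.triu_indices(len(ids), k=1)]))
    return DistanceSummary(ids.copy(), d2, m)


def distance_summary(
    mm: MarkerMatrix,
    means: np.ndarray | None = None,
    sds: np.ndarray | None = None,
    m_subset: np.ndarray | None = None,
) -> DistanceSummary:
    """Pairwise squared Euclidean distances on the same centered and
    standardized dosage matrix used for G; m is the median over strictly
    off-diagonal entries.  ``m_subset`` restricts the median to a subset
    of individuals (e.g. training lines) while distances cover everyone.
    """
    return distance_summary_from_dosages(
        mm.individual_ids, mm.dosages, means, sds, m_subset
    )


def gaussian_kernels(
    ds: DistanceSummary,
    multipliers=DEFAULT_KERNEL_MULTIPLIERS,
) -> list[RelationshipMatrix]:
    """Kernel-averaging set: for each multiplier c, bandwidth h = c/m and
    K(i,i') = exp(-h d2(i,i')).  Diagonals are exactly 1; larger c means a
    faster-decaying, more local kernel."""
    if not ds.m > 0:
        raise ValueError("median squared distance m must be > 0 (identical lines?)")
    kernels = []
    for c in multipliers:
        h = c / ds.m
        K = np.exp(-h * ds.d2)
        np.fill_diagonal(K, 1.0)
        kernels.append(RelationshipMatrix(ds.ids.copy(), K, "kernel", bandwidth=h))
    return kernels


# ---------------------------------------------------------------------------
# Nei's standard genetic distance


def _nei_identities(x: np.ndarray, y: np.ndarray):
    jx = float(np.mean(x * x + (1 - x) * (1 - x)))
    jy = float(np.mean(y * y + (1 - y) * (1 - y)))
    jxy = float(np.mean(x * y + (1 - x) * (1 - y)))
    return jx, jy, jxy


def nei_distance(freq_a: np.ndarray, freq_b: np.ndarray) -> float:
    """Nei's standard genetic distance D = -ln(Jxy / sqrt(Jx Jy)) over
    biallelic loci with allele frequencies in [0,1].

    Returns ``inf`` when the normalized identity Jxy is 0 (populations
    fixed for opposite alleles at every locus).  An individual inbred
    line enters as the frequency profile dosage/2.
    """
    x = np.asarray(freq_a, dtype=float)
    y = np.asarray(freq_b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("frequency vectors must cover the same markers")
    if ((x < 0) | (x > 1) | (y < 0) | (y > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    jx, jy, jxy = _nei_identities(x, y)
    if jxy == 0.0:
        return float("inf")
    return float(-np.log(jxy / np.sqrt(jx * jy)))


def nei_distance_matrix(freqs: np.ndarray, ids=None) -> pd.DataFrame:
    """All pairwise Nei distances between rows of a groups-x-markers (or
    lines-x-markers, frequencies = dosage/2) frequency table."""
    F = np.asarray(freqs, dtype=float)
    n = F.shape[0]
    if ids is None:
        ids = [str(k) for k in range(n)]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = nei_distance(F[i], F[j])
    return pd.DataFrame(D, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# PCA


def pca_scores(mm: MarkerMatrix, n_components: int = 2):
    """PC scores of the centered dosage matrix.

    Returns (scores DataFrame indexed by individual, explained-variance
    fractions).  Sign convention: the largest-magnitude loading of each
    component is positive.
    """
    X = np.asarray(mm.dosages, dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing dosages present; impute first")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(S))
    for c in range(k):
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    scores = U[:, :k] * S[:k]
    total = float((S ** 2).sum())
    explained = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    df = pd.DataFrame(
        scores, index=mm.individual_ids, columns=[f"PC{c+1}" for c in range(k)]
    )
    return df, explained
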