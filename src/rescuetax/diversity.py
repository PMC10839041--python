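"""Alpha and beta diversity, ordination, and group tests.

Alpha diversity: Shannon entropy (natural log) and bias-corrected Chao1
richness, with rarefied Chao1 over repeated subsampling without replacement.
Beta diversity: Bray-Curtis (abundance-based) and Jaccard (presence-based)
dissimilarities, classical-scaling PCoA, and one-way PERMANOVA with free
label permutations (optionally exhaustive on small designs).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import braycurtis as _sp_braycurtis
from scipy.spatial.distance import jaccard as _sp_jaccard
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import shannon as _skbio_shannon
from sklearn.base import BaseEstimator, TransformerMixin

from .io import AbundanceTable, StudyDesign

__all__ = [
    "shannon",
    "chao1",
    "alpha_diversity",
    "rarefied_chao",
    "bray_curtis",
    "jaccard_distance",
    "distance_matrix",
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "pcoa",
    "PCoA",
    "permanova",
    "PermanovaTest",
    "pairwise_permanova",
    "kruskal_wallis",
]


# ---------------------------------------------------------------- alpha

def shannon(abundances) -> float:
    """Shannon diversity H = -sum p_i ln p_i, in nats.

    The input is normalized to proportions first, so the index is invariant
    to rescaling by a positive constant (counts and proportions agree).
    """
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    return float(_skbio_shannon(x, base=np.e))


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1)).

    Defined for integer count vectors only; F1 and F2 are the numbers of
    singleton and doubleton taxa. The bias-corrected form keeps the
    estimator finite when no doubletons are observed.
    """
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    if not np.allclose(x, np.round(x)):
        raise ValueError("chao1 requires integer counts, not relative abundances")
    return float(_skbio_chao1(x.astype(int), bias_corrected=True))


def alpha_diversity(table: AbundanceTable, metric: str = "shannon") -> pd.Series:
    """Per-sample alpha diversity. ``chao1`` requires a counts-mode table."""
    if metric == "shannon":
        vals = [shannon(row) for row in table.values]
    elif metric == "chao1":
        if table.mode != "counts":
            raise ValueError("chao1 is undefined for relative-mode tables")
        vals = [chao1(row) for row in table.values]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.Series(vals, index=table.data.index, name=metric)


def rarefied_chao(table: AbundanceTable, depth: int, reps: int = 100,
                  seed: int | None = None) -> pd.Series:
    """Mean Chao1 over ``reps`` random subsamples at fixed ``depth``.

    Subsampling is without replacement (multivariate hypergeometric draw per
    replicate). Reproducible given ``seed``.
    """
    if table.mode != "counts":
        raise ValueError("rarefaction requires a counts-mode table")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    counts = np.round(table.values).astype(np.int64)
    totals = counts.sum(axis=1)
    if (depth > totals).any():
        sid = table.data.index[int(np.argmax(depth > totals))]
        raise ValueError(f"depth {depth} exceeds total count of sample {sid!r}")
    rng = np.random.default_rng(seed)
    out = np.empty(len(counts))
    for i, row in enumerate(counts):
        vals = [chao1(rng.multivariate_hypergeometric(row, depth)) for _ in range(reps)]
        out[i] = np.mean(vals)
    return pd.Series(out, index=table.data.index, name="rarefied_chao1")


# ----------------------------------------------------------------- beta

def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity: sum |x_i - y_i| / sum (x_i + y_i)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be nonnegative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_sp_braycurtis(x, y))


def jaccard_distance(x, y) -> float:
    """Jaccard dissimilarity on presence (value > 0): 1 - |shared| / |union|."""
    x = np.asarray(x, dtype=float) > 0
    y = np.asarray(y, dtype=float) > 0
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if not x.any() and not y.any():
        raise ValueError("Jaccard undefined for two empty supports")
    return float(_sp_jaccard(x, y))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative dissimilarity matrix with zero diagonal."""

    sample_ids: list
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("matrix shape does not match sample_ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("dissimilarities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def __len__(self) -> int:
        return len(self.sample_ids)


def distance_matrix(table: AbundanceTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """All pairwise dissimilarities between samples of a table."""
    fn = {"bray_curtis": bray_curtis, "jaccard": jaccard_distance}.get(metric)
    if fn is None:
        raise ValueError(f"unknown metric {metric!r}")
    x = table.values
    n = len(x)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(x[i], x[j])
    return DistanceMatrix(sample_ids=table.sample_ids, values=d, metric=metric)


# ----------------------------------------------------------- ordination

@dataclass(frozen=True)
class OrdinationResult:
    """Classical-scaling embedding of a dissimilarity matrix.

    ``eigenvalues`` holds the full descending spectrum of the Gower-centered
    matrix (negative values retained for diagnostics); ``coordinates`` and
    ``proportion_explained`` use positive eigenvalues only.
    """

    sample_ids: list
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinate analysis (Gower's classical scaling).

    Double-centers -D^2/2, eigendecomposes, and scales eigenvectors by the
    square root of their (positive) eigenvalues. Axes whose eigenvalue is
    not positive carry no coordinates and no explained variance.
    """
    n = len(dm)
    if n_axes is None:
        n_axes = n - 1
    if not 1 <= n_axes <= n - 1:
        raise ValueError(f"n_axes must be in [1, {n - 1}]")
    d2 = dm.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = np.clip(eigvals[:n_axes], 0, None)
    coords = eigvecs[:, :n_axes] * np.sqrt(pos)
    pos_all = eigvals[eigvals > 0]
    total = pos_all.sum() if len(pos_all) else 1.0
    proportions = np.clip(eigvals[:n_axes], 0, None) / total
    return OrdinationResult(
        sample_ids=dm.sample_ids,
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=proportions,
    )


class PCoA(TransformerMixin, BaseEstimator):
    """Transformer wrapper around classical scaling for pipeline use.

    Parameters
    ----------
    n_components : int
        Number of ordination axes to keep.

    Attributes
    ----------
    eigenvalues_ : ndarray
        Full descending spectrum of the centered matrix.
    proportion_explained_ : ndarray
        Variance fraction per retained axis (positive eigenvalues only).
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        dm = X if isinstance(X, DistanceMatrix) else DistanceMatrix(
            sample_ids=list(range(len(X))), values=np.asarray(X, dtype=float),
            metric="precomputed")
        result = pcoa(dm, n_axes=self.n_components)
        self.eigenvalues_ = result.eigenvalues
        self.proportion_explained_ = result.proportion_explained
        self.embedding_ = result.coordinates
        self.sample_ids_ = result.sample_ids
        return self

    def transform(self, X):
        return self.embedding_

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


# ------------------------------------------------------------ permanova

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None = None


def _permanova_ss(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray):
    """Total and within-group sums of squares from squared dissimilarities."""
    n = len(labels)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in groups:
        mask = labels == g
        n_g = int(mask.sum())
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(n_g, k=1)].sum() / n_g
    return ss_total, ss_within


def _pseudo_f_batch(d2: np.ndarray, label_codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Pseudo-F for a batch of label vectors (rows of ``label_codes``)."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = np.zeros(label_codes.shape[0])
    for g in range(n_groups):
        m = (label_codes == g).astype(float)
        n_g = m.sum(axis=1)
        ss_within += np.einsum("pi,ij,pj->p", m, d2, m) / (2 * n_g)
    ss_between = ss_total - ss_within
    a = n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        # a permutation with zero within-group scatter legitimately gives inf
        return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(dm: DistanceMatrix, grouping, n_permutations: int = 9999,
              seed: int | None = None, method: str = "monte_carlo") -> PermanovaResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    Partitions SS_total = sum_{i<j} d_ij^2 / N into within- and among-group
    components; R^2 = 1 - SS_within / SS_total and
    pseudo-F = (SS_between / (a-1)) / (SS_within / (N-a)). The p-value is the
    permutation tail probability of F under free relabeling of samples:
    ``(#{F_perm >= F_obs} + 1) / (n_permutations + 1)`` for Monte Carlo, or
    the exact fraction over all label orderings with ``method="exhaustive"``.

    ``grouping`` is a StudyDesign, a mapping, or a label sequence aligned
    with the matrix's samples.
    """
    labels = _resolve_labels(dm, grouping)
    groups, codes = np.unique(labels, return_inverse=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA requires at least two groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        small = groups[np.argmax(counts < 2)]
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    d2 = dm.values ** 2
    n = len(codes)
    a = len(groups)
    ss_total, ss_within = _permanova_ss(d2, codes, np.arange(a))
    ss_between = ss_total - ss_within
    r_squared = ss_between / ss_total if ss_total > 0 else 0.0
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a)) if ss_within > 0 else np.inf

    if method == "exhaustive":
        perms = np.array(list(_iter_permutations(range(n))))
        f_perm = _pseudo_f_batch(d2, codes[perms], a)
        p = float(np.mean(f_perm >= f_obs - 1e-12))
        n_perm_used = len(perms)
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)
        perms = rng.permuted(
            np.tile(np.arange(n), (n_permutations, 1)), axis=1)
        f_perm = _pseudo_f_batch(d2, codes[perms], a)
        p = float((np.sum(f_perm >= f_obs - 1e-12) + 1) / (n_permutations + 1))
        n_perm_used = n_permutations
    else:
        raise ValueError(f"unknown method {method!r}")
    return PermanovaResult(pseudo_f=float(f_obs), r_squared=float(r_squared),
                           p_value=p, n_permutations=n_perm_used, seed=seed)


def _resolve_labels(dm: DistanceMatrix, grouping) -> np.ndarray:
    if isinstance(grouping, StudyDesign):
        return grouping.groups_of(dm.sample_ids)
    if isinstance(grouping, (pd.Series, dict)):
        ser = pd.Series(grouping)
        return ser.loc[list(dm.sample_ids)].to_numpy()
    labels = np.asarray(grouping)
    if len(labels) != len(dm):
        raise ValueError("grouping length does not match distance matrix")
    return labels


class PermanovaTest(BaseEstimator):
    """Estimator-style one-way PERMANOVA.

    Parameters
    ----------
    n_permutations : int
        Monte-Carlo permutations (ignored for ``method="exhaustive"``).
    random_state : int or None
        Seed for the permutation stream.
    method : {"monte_carlo", "exhaustive"}

    Attributes (after :meth:`fit`)
    ------------------------------
    pseudo_f_, r_squared_, p_value_, n_permutations_
    """

    def __init__(self, n_permutations: int = 9999, random_state: int | None = None,
                 method: str = "monte_carlo"):
        self.n_permutations = n_permutations
        self.random_state = random_state
        self.method = method

    def fit(self, X, y):
        dm = X if isinstance(X, DistanceMatrix) else DistanceMatrix(
            sample_ids=list(range(len(X))), values=np.asarray(X, dtype=float),
            metric="precomputed")
        result = permanova(dm, y, n_permutations=self.n_permutations,
                           seed=self.random_state, method=self.method)
        self.pseudo_f_ = result.pseudo_f
        self.r_squared_ = result.r_squared
        self.p_value_ = result.p_value
        self.n_permutations_ = result.n_permutations
        return self


def pairwise_permanova(table: AbundanceTable, design: StudyDesign,
                       metric: str = "bray_curtis", n_permutations: int = 9999,
                       seed: int | None = None) -> pd.DataFrame:
    """PERMANOVA for each pair of study groups (raw p-values, no correction)."""
    from .io import subset_groups

    rows = []
    order = design.group_order
    pairs = [(order[0], order[1]), (order[0], order[2]), (order[1], order[2])]
    for g1, g2 in pairs:
        sub, labels = subset_groups(table, design, [g1, g2])
        dm = distance_matrix(sub, metric=metric)
        res = permanova(dm, labels, n_permutations=n_permutations, seed=seed)
        rows.append({"group_1": g1, "group_2": g2, "pseudo_f": res.pseudo_f,
                     "r_squared": res.r_squared, "p_value": res.p_value,
                     "n_permutations": res.n_permutations})
    return pd.DataFrame(rows)


# ------------------------------------------------------- group testing

def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p with k-1 df.

    All-tied input is a degenerate case where the statistic carries no
    information; it is reported as H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("Kruskal-Wallis requires at least two groups")
    samples = [values[groups == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*samples)
    return float(h), float(p)
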