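"""Expression-matrix preprocessing and gene-set overrepresentation.

The preprocessing pipeline for a genes × arrays signal matrix follows
standard single-channel microarray practice: each array is scaled so
its mean signal over all gene features equals a target value (default
240); signals below a floor (default 12) are raised to the floor;
genes whose across-array mean stays below a threshold (default 20) are
discarded as essentially unexpressed; per-gene profiles are displayed
after division by their own mean across conditions.

Overrepresentation of functional categories within a gene cluster is
tested with the hypergeometric upper tail (computed in log space) and
Bonferroni correction over the categories tested.

The growth-rate classifier is a deliberately simple, labelled stand-in
for the dedicated differential-expression and consensus-clustering
tools used in practice: per-gene rank correlation with specific growth
rate plus a seeded permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom, rankdata
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "HOUSEKEEPING_GENES",
    "EnrichmentResult",
    "scale_arrays",
    "floor_and_filter",
    "average_normalize",
    "housekeeping_cv",
    "hypergeometric_enrichment",
    "ExpressionPreprocessor",
    "GrowthCorrelationClassifier",
    "classify_growth_correlation",
    "venn_partition",
]

#: Stability-reference genes whose expression should not vary with growth rate.
HOUSEKEEPING_GENES = ("ACT1", "HHT2", "SHR3", "PDA1", "TPI", "TFC1")


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric overrepresentation of one category in one cluster."""

    category: str
    overlap: int          # k: genes in both cluster and category
    category_size: int    # K (after intersection with the background)
    cluster_size: int     # n
    background_size: int  # N
    p_value: float        # raw upper-tail P(X >= k)
    p_corrected: float    # Bonferroni over categories tested
    significant: bool     # p_corrected <= threshold

    def __post_init__(self) -> None:
        if not 0 <= self.overlap <= min(self.category_size, self.cluster_size):
            raise ValueError("overlap must satisfy 0 <= k <= min(K, n)")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must be in (0, 1]")


# ------------------------------------------------------------- preprocessing

def scale_arrays(matrix: pd.DataFrame, target: float = 240.0) -> pd.DataFrame:
    """Scale each array (column) so its mean over all genes equals *target*."""
    if (matrix < 0).any().any():
        raise ValueError("signals must be non-negative")
    means = matrix.mean(axis=0)
    if (means <= 0).any():
        bad = list(means.index[means <= 0])
        raise ValueError(f"arrays with non-positive mean signal: {bad}")
    return matrix * (target / means)


def floor_and_filter(
    matrix: pd.DataFrame, floor: float = 12.0, min_mean: float = 20.0
) -> tuple[pd.DataFrame, list[str]]:
    """Floor low signals, then drop genes whose across-array mean < *min_mean*.

    Returns the filtered matrix and the list of discarded gene IDs.
    """
    floored = matrix.clip(lower=floor)
    keep = floored.mean(axis=1) >= min_mean
    discarded = list(floored.index[~keep])
    return floored.loc[keep], discarded


def average_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each gene's profile by its own mean across conditions."""
    means = matrix.mean(axis=1)
    if (means <= 0).any():
        bad = list(means.index[means <= 0])
        raise ValueError(f"genes with non-positive mean expression: {bad}")
    return matrix.div(means, axis=0)


def housekeeping_cv(
    matrix: pd.DataFrame, genes: Sequence[str] = HOUSEKEEPING_GENES
) -> tuple[pd.Series, float, list[str]]:
    """Coefficient of variation across arrays for stability-reference genes.

    Returns per-gene CV (sd/mean), the set average, and any genes that
    were requested but absent from the matrix (reported, not fatal).
    """
    present = [g for g in genes if g in matrix.index]
    missing = [g for g in genes if g not in matrix.index]
    if not present:
        return pd.Series(dtype=float), float("nan"), missing
    sub = matrix.loc[present]
    cv = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
    return cv, float(cv.mean()), missing


class ExpressionPreprocessor(BaseEstimator, TransformerMixin):
    """Composed preprocessing transform: scale → floor → filter.

    Stateless between calls (each matrix is scaled to its own means);
    :meth:`transform` records ``discarded_genes_`` and ``n_kept_`` for
    the most recent input. The composition is idempotent: running it on
    its own output changes nothing (column means are already at target,
    no value is below the floor, no gene mean below the cut).
    """

    def __init__(
        self, target: float = 240.0, floor: float = 12.0, min_mean: float = 20.0
    ) -> None:
        self.target = target
        self.floor = floor
        self.min_mean = min_mean

    def fit(self, X: pd.DataFrame, y=None) -> "ExpressionPreprocessor":
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        scaled = scale_arrays(X, target=self.target)
        filtered, discarded = floor_and_filter(
            scaled, floor=self.floor, min_mean=self.min_mean
        )
        self.discarded_genes_ = discarded
        self.n_kept_ = int(filtered.shape[0])
        return filtered


# ------------------------------------------------------------- enrichment

def _log_hypergeom_sf(k: int, n_bg: int, n_cat: int, n_cluster: int) -> float:
    """log P(X >= k) for X ~ Hypergeom(N=n_bg, K=n_cat, n=n_cluster)."""
    if k <= 0:
        return 0.0
    upper = min(n_cat, n_cluster)
    ks = np.arange(k, upper + 1)
    return float(logsumexp(hypergeom.logpmf(ks, n_bg, n_cat, n_cluster)))


def hypergeometric_enrichment(
    cluster: Iterable[str],
    categories: Mapping[str, Iterable[str]],
    background: Iterable[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Overrepresentation of each category within *cluster*.

    Categories are intersected with the background before testing; the
    raw upper-tail p is Bonferroni-corrected across the categories
    tested. Results are sorted by corrected p.

    Raises
    ------
    ValueError
        If the background or cluster is empty, or the cluster is not a
        subset of the background.
    """
    bg = set(background)
    cl = set(cluster)
    if not bg:
        raise ValueError("background must be non-empty")
    if not cl:
        raise ValueError("cluster must be non-empty")
    if not cl <= bg:
        raise ValueError("cluster must be a subset of the background")
    n_tests = len(categories)
    if n_tests == 0:
        return []
    results = []
    for name, members in categories.items():
        cat = set(members) & bg
        k = len(cat & cl)
        log_p = _log_hypergeom_sf(k, len(bg), len(cat), len(cl))
        # clamp against float underflow for overwhelming overlaps
        p = min(1.0, max(float(np.exp(log_p)), 5e-324))
        p_corr = min(1.0, p * n_tests)
        results.append(
            EnrichmentResult(
                category=name,
                overlap=k,
                category_size=len(cat),
                cluster_size=len(cl),
                background_size=len(bg),
                p_value=p,
                p_corrected=p_corr,
                significant=p_corr <= alpha,
            )
        )
    return sorted(results, key=lambda r: (r.p_corrected, r.p_value, r.category))


# ------------------------------------------------------------- classification

class GrowthCorrelationClassifier(BaseEstimator):
    """Partition genes by rank correlation with specific growth rate.

    A simplified, clearly-labelled stand-in for dedicated
    differential-expression machinery: per-gene Spearman correlation of
    signal with the arrays' growth rates, a seeded permutation p-value
    on |ρ|, and a sign-based partition into positively correlated,
    negatively correlated, and non-responsive genes.

    Attributes (after :meth:`fit`)
    ------------------------------
    correlation_ : Series
        Spearman ρ per gene.
    p_values_ : Series
        Permutation p-values (add-one estimator).
    labels_ : Series
        +1 (up with growth rate), −1 (down), 0 (non-responsive).
    """

    def __init__(
        self,
        alpha: float = 0.01,
        n_permutations: int = 500,
        random_state: int | None = 0,
    ) -> None:
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y: Sequence[float]) -> "GrowthCorrelationClassifier":
        rates = np.asarray(y, dtype=float)
        if X.shape[1] != len(rates):
            raise ValueError("one growth rate per array is required")
        if len(np.unique(rates)) < 4:
            raise ValueError("need >= 4 arrays with distinct growth rates")
        rng = np.random.default_rng(self.random_state)

        # Spearman = Pearson on ranks; vectorized over genes.
        rx = np.apply_along_axis(rankdata, 1, X.to_numpy())
        rx = (rx - rx.mean(axis=1, keepdims=True))
        rx_norm = np.linalg.norm(rx, axis=1)
        rx_norm[rx_norm == 0.0] = np.inf  # constant gene: rho -> 0
        ry = rankdata(rates)
        ry = ry - ry.mean()
        ry_norm = np.linalg.norm(ry)
        rho = rx @ ry / (rx_norm * ry_norm)

        exceed = np.zeros(X.shape[0], dtype=int)
        for _ in range(self.n_permutations):
            perm = rng.permutation(ry)
            rho_p = rx @ perm / (rx_norm * ry_norm)
            exceed += np.abs(rho_p) >= np.abs(rho) - 1e-12
        p = (exceed + 1.0) / (self.n_permutations + 1.0)

        labels = np.zeros(X.shape[0], dtype=int)
        labels[(p <= self.alpha) & (rho > 0)] = 1
        labels[(p <= self.alpha) & (rho < 0)] = -1
        self.correlation_ = pd.Series(rho, index=X.index, name="spearman_rho")
        self.p_values_ = pd.Series(p, index=X.index, name="perm_p")
        self.labels_ = pd.Series(labels, index=X.index, name="label")
        return self

    def predict(self, X: pd.DataFrame | None = None) -> pd.Series:
        if not hasattr(self, "labels_"):
            raise RuntimeError("classifier is not fitted")
        return self.labels_

    @property
    def up_genes_(self) -> set:
        return set(self.labels_.index[self.labels_ == 1])

    @property
    def down_genes_(self) -> set:
        return set(self.labels_.index[self.labels_ == -1])


def classify_growth_correlation(
    matrix: pd.DataFrame,
    growth_rates: Sequence[float],
    alpha: float = 0.01,
    n_permutations: int = 500,
    random_state: int | None = 0,
) -> tuple[set, set, set, pd.DataFrame]:
    """Partition genes into up/down/non-responsive sets.

    Returns (up, down, non_responsive, per-gene table).
    """
    clf = GrowthCorrelationClassifier(
        alpha=alpha, n_permutations=n_permutations, random_state=random_state
    ).fit(matrix, growth_rates)
    table = pd.DataFrame(
        {
            "spearman_rho": clf.correlation_,
            "perm_p": clf.p_values_,
            "label": clf.labels_,
        }
    )
    non = set(clf.labels_.index[clf.labels_ == 0])
    return clf.up_genes_, clf.down_genes_, non, table


def venn_partition(set_a: Iterable, set_b: Iterable) -> dict:
    """Exact two-set Venn arithmetic: exclusive and shared members/counts."""
    a, b = set(set_a), set(set_b)
    return {
        "only_a": a - b,
        "only_b": b - a,
        "shared": a & b,
        "n_only_a": len(a - b),
        "n_only_b": len(b - a),
        "n_shared": len(a & b),
    }
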