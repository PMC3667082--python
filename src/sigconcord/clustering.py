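"""Consensus k-means clustering of expression samples with quality-factor
model selection.

Samples (columns) are clustered repeatedly on random subsamples; the
consensus matrix records, for every pair of samples, the fraction of
co-drawn resamples in which they landed in the same k-means cluster.  A
clean consensus matrix — entries near 0 or 1 — indicates a stable
partition.  Cleanness is summarized by the quality factor

    QF = mean over off-diagonal entries of 2*|m_ij - 0.5|,

which is 1 exactly when every entry is 0 or 1 and 0 when every entry is 0.5.
The number of clusters is chosen where the QF curve shows its largest drop:
adding one cluster beyond the true number forces an arbitrary split and the
consensus matrix degrades sharply.

Preprocessing helpers implement the standard recipe: drop genes whose median
absolute deviation (MAD) across samples is below a threshold, then
standardize each gene row to zero mean and unit variance.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .signatures import GeneSignature

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusResult",
    "KSelection",
    "ConfusionTable",
    "mad_filter",
    "zscore_rows",
    "consensus_kmeans",
    "quality_factor",
    "select_k",
    "confusion_match",
    "label_agreement",
]


def label_agreement(labels_a: Sequence | pd.Series, labels_b: Sequence | pd.Series) -> float:
    """Fraction of samples on which two clusterings agree under the best
    one-to-one relabeling (Hungarian assignment on the contingency table).

    Permutation-invariant: relabeling either clustering leaves it unchanged.
    """
    from scipy.optimize import linear_sum_assignment

    a = pd.Series(list(labels_a)) if not isinstance(labels_a, pd.Series) else labels_a
    b = pd.Series(list(labels_b)) if not isinstance(labels_b, pd.Series) else labels_b
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("label vectors must be nonempty and of equal length")
    table = pd.crosstab(a.to_numpy(), b.to_numpy()).to_numpy()
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum() / len(a))


def mad_filter(expr: pd.DataFrame, min_mad: float = 0.5) -> pd.DataFrame:
    """Keep genes with median absolute deviation >= ``min_mad`` across samples.

    MAD is the unscaled median(|x - median(x)|).  Raises if no gene survives.
    """
    if min_mad < 0:
        raise ValueError("min_mad must be >= 0")
    values = expr.to_numpy()
    med = np.median(values, axis=1, keepdims=True)
    mad = np.median(np.abs(values - med), axis=1)
    keep = mad >= min_mad
    if not keep.any():
        raise ValueError(f"MAD filter at {min_mad} removed every gene")
    logger.info("mad_filter: kept %d of %d genes at MAD >= %g", keep.sum(), len(keep), min_mad)
    return expr.loc[keep]


def zscore_rows(expr: pd.DataFrame, *, ddof: int = 0) -> pd.DataFrame:
    """Standardize each gene row to zero mean and unit (population) variance.

    Constant rows cannot be standardized and are an error — they should have
    been removed by the MAD filter.
    """
    values = expr.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        gene = expr.index[np.argmax(flat)]
        raise ValueError(f"constant row cannot be z-scored: gene {gene!r}")
    return pd.DataFrame((values - mean) / sd, index=expr.index, columns=expr.columns)


def quality_factor(consensus: pd.DataFrame | np.ndarray) -> float:
    """Cleanness of a consensus matrix: mean off-diagonal 2*|m - 0.5|.

    1.0 iff every entry is 0 or 1; 0.0 iff every entry is 0.5.
    """
    m = np.asarray(consensus, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("consensus matrix must be square")
    if (m < 0).any() or (m > 1).any():
        raise ValueError("consensus entries must lie in [0, 1]")
    n = m.shape[0]
    if n < 2:
        return 1.0
    off = ~np.eye(n, dtype=bool)
    return float(np.mean(2.0 * np.abs(m[off] - 0.5)))


@dataclass
class ConsensusResult:
    """Consensus matrix, extracted labels, and quality factor for one k."""

    k: int
    consensus: pd.DataFrame
    labels: pd.Series
    quality_factor: float
    run_params: dict = field(default_factory=dict)
    n_clusters_found: int = 0


def consensus_kmeans(
    expr: pd.DataFrame,
    k: int,
    *,
    n_resamples: int = 500,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    kmeans_restarts: int = 10,
) -> ConsensusResult:
    """Consensus clustering of samples (columns) with k-means.

    Each resample draws ``ceil(subsample_fraction * n)`` samples without
    replacement and partitions them with Euclidean k-means (best of
    ``kmeans_restarts`` random initializations).  The consensus entry
    ``m_ij`` is the number of resamples in which samples i and j were
    co-clustered divided by the number in which both were drawn; a pair
    never co-drawn is an error (increase ``n_resamples``).  Final labels
    come from average-linkage hierarchical clustering of the distances
    ``1 - m_ij`` cut at k.  Fully reproducible for a given seed.
    """
    n = expr.shape[1]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")

    rng = np.random.default_rng(seed)
    X = expr.to_numpy(dtype=float).T  # samples x genes
    m_sub = math.ceil(subsample_fraction * n)
    co_cluster = np.zeros((n, n))
    co_drawn = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=m_sub, replace=False))
        km_seed = int(rng.integers(0, 2**31 - 1))
        labels = KMeans(
            n_clusters=k, n_init=kmeans_restarts, random_state=km_seed
        ).fit_predict(X[idx])
        co_drawn[np.ix_(idx, idx)] += 1.0
        for c in range(k):
            members = idx[labels == c]
            co_cluster[np.ix_(members, members)] += 1.0
    if (co_drawn == 0).any():
        raise ValueError(
            "some sample pair was never co-drawn; increase n_resamples or "
            "subsample_fraction"
        )
    consensus = co_cluster / co_drawn
    consensus = pd.DataFrame(consensus, index=expr.columns, columns=expr.columns)

    if k == 1:
        labels = pd.Series(1, index=expr.columns, name="cluster")
    else:
        dist = 1.0 - consensus.to_numpy()
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2.0  # exact symmetry for squareform
        tree = linkage(squareform(dist, checks=False), method="average")
        labels = pd.Series(fcluster(tree, t=k, criterion="maxclust"),
                           index=expr.columns, name="cluster")
    found = labels.nunique()
    if found < k:
        logger.warning("consensus_kmeans: only %d of %d clusters are non-empty", found, k)
    return ConsensusResult(
        k=k,
        consensus=consensus,
        labels=labels,
        quality_factor=quality_factor(consensus),
        run_params={
            "n_resamples": n_resamples,
            "subsample_fraction": subsample_fraction,
            "seed": seed,
            "kmeans_restarts": kmeans_restarts,
        },
        n_clusters_found=found,
    )


@dataclass
class KSelection:
    """Quality-factor curve over a range of k with the selected k."""

    qf: dict[int, float]
    selected_k: int
    results: dict[int, ConsensusResult] = field(repr=False, default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"k": list(self.qf), "quality_factor": list(self.qf.values())})
        frame["selected"] = frame["k"] == self.selected_k
        return frame


def select_k(
    expr: pd.DataFrame,
    k_range: Sequence[int],
    *,
    n_resamples: int = 500,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    kmeans_restarts: int = 10,
) -> KSelection:
    """Run consensus clustering over ``k_range`` and pick k by the largest
    quality-factor drop.

    The selected k is the value preceding the largest decrease
    ``QF(k) - QF(k+1)`` over consecutive entries of the (ascending) range;
    ties go to the smaller k.  Each k uses an independent RNG stream derived
    from ``seed`` so that extending the range never perturbs earlier runs.
    """
    ks = list(k_range)
    if not ks or ks != sorted(ks) or len(set(ks)) != len(ks):
        raise ValueError("k_range must be nonempty, ascending, and without repeats")
    results: dict[int, ConsensusResult] = {}
    for k in ks:
        results[k] = consensus_kmeans(
            expr,
            k,
            n_resamples=n_resamples,
            subsample_fraction=subsample_fraction,
            seed=np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31),
            kmeans_restarts=kmeans_restarts,
        )
    qf = {k: results[k].quality_factor for k in ks}
    if len(ks) == 1:
        selected = ks[0]
    else:
        drops = {ks[i]: qf[ks[i]] - qf[ks[i + 1]] for i in range(len(ks) - 1)}
        selected = max(drops, key=lambda k: (drops[k], -k))
    return KSelection(qf=qf, selected_k=selected, results=results)


@dataclass
class ConfusionTable:
    """Cluster-vs-reference grid of up-gene overlap counts with a matching."""

    counts: pd.DataFrame  # clusters x references
    matching: dict[str, str]  # cluster name -> reference name
    informative: bool

    def to_frame(self) -> pd.DataFrame:
        return self.counts


def confusion_match(
    cluster_signatures: Sequence[GeneSignature],
    reference_signatures: Sequence[GeneSignature],
) -> ConfusionTable:
    """Match discovered cluster signatures to reference signatures by
    up-gene overlap counts.

    The grid entry is ``|cluster.up ∩ reference.up|``; matching is greedy on
    the maximum count with deterministic tie-breaking (lexicographic
    reference name, then cluster name).  Each cluster is matched to at most
    one reference.  An all-zero grid is flagged uninformative.
    """
    for sig in (*cluster_signatures, *reference_signatures):
        if not sig.up:
            raise ValueError(f"signature {sig.name!r} has an empty up set")
    counts = pd.DataFrame(
        [[len(c.up & r.up) for r in reference_signatures] for c in cluster_signatures],
        index=[c.name for c in cluster_signatures],
        columns=[r.name for r in reference_signatures],
    )
    informative = bool((counts.to_numpy() > 0).any())
    matching: dict[str, str] = {}
    remaining_rows = list(counts.index)
    remaining_cols = list(counts.columns)
    while remaining_rows and remaining_cols:
        # max() keeps the first of equal keys, so iterating references (then
        # clusters) in lexicographic order implements the tie-break
        _, col, row = max(
            ((counts.loc[r, c], c, r) for c in sorted(remaining_cols) for r in sorted(remaining_rows)),
            key=lambda t: t[0],
        )
        matching[row] = col
        remaining_rows.remove(row)
        remaining_cols.remove(col)
    if not informative:
        logger.warning("confusion_match: all overlap counts are zero; matching is uninformative")
    return ConfusionTable(counts=counts, matching=matching, informative=informative)
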