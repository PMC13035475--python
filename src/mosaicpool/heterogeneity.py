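"""Heterogeneity statistics for drug response within a line.

Two complementary views of subpopulation-restricted survival:

- **Gini concentration** — how unevenly a line's treated cells distribute
  across its expression clusters, relative to its vehicle cells, scored as a
  z against a permutation null that shuffles condition labels while keeping
  cluster sizes fixed.

- **Mutual-information enrichment** — an information-theoretic enrichment
  test: a continuous per-cell or per-gene statistic is quantized into
  equal-frequency bins, and the mutual information between the bin labels and
  a binary membership vector is compared with a shuffle null; per-bin
  hypergeometric tails localize over-/under-representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from mosaicpool.core import ValidationError

logger = logging.getLogger(__name__)


def gini(values: np.ndarray) -> float:
    """Gini coefficient G = Σ_i Σ_j |x_i − x_j| / (2 n² x̄) of a nonnegative vector."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 values")
    if (x < 0).any():
        raise ValidationError("values must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValidationError("all-zero vector has undefined Gini")
    xs = np.sort(x)
    n = x.size
    # sorted closed form of the mean-absolute-difference definition
    return float((2.0 * np.sum(np.arange(1, n + 1) * xs)) / (n * total) - (n + 1) / n)


@dataclass
class GiniResult:
    """Observed Gini of cluster occupancy with its permutation null."""

    observed: float
    null_mean: float
    null_sd: float
    z: float
    n_permutations: int
    seed: int
    relative_counts: pd.Series | None = None


def _cluster_relative_counts(
    treated_in_cluster: np.ndarray,
    cluster_sizes: np.ndarray,
    n_treated: int,
    n_total: int,
) -> np.ndarray:
    """Treated share per cluster normalized by the overall treated share."""
    overall = n_treated / n_total
    return (treated_in_cluster / cluster_sizes) / overall


def cluster_shift_z(
    cluster_labels: np.ndarray,
    treated: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> GiniResult:
    """Gini z-score of treated-cell concentration across clusters.

    For one line's cells, each cluster's relative count is the treated share
    within the cluster divided by the line's overall treated share; the Gini
    of these values measures how concentrated survival is.  The null permutes
    condition labels across cells (cluster sizes fixed), which makes the
    per-cluster treated counts multivariate hypergeometric.
    """
    clusters = pd.Categorical(np.asarray(cluster_labels))
    treated = np.asarray(treated, dtype=bool)
    if len(clusters.categories) < 2:
        raise ValidationError("need at least 2 clusters")
    if treated.all() or not treated.any():
        raise ValidationError("both conditions must be present")
    if n_permutations < 100:
        logger.warning("n_permutations < 100: null moments will be noisy")
    codes = clusters.codes
    n_clusters = len(clusters.categories)
    sizes = np.bincount(codes, minlength=n_clusters)
    obs_t = np.bincount(codes[treated], minlength=n_clusters)
    n_treated, n_total = int(treated.sum()), treated.size
    observed = gini(_cluster_relative_counts(obs_t, sizes, n_treated, n_total))

    rng = np.random.default_rng(seed)
    perm_t = rng.multivariate_hypergeometric(sizes, n_treated, size=n_permutations)
    rel = (perm_t / sizes) / (n_treated / n_total)
    null = np.array([gini(r) for r in rel])
    null_mean, null_sd = float(null.mean()), float(null.std(ddof=1))
    if null_sd == 0:
        raise ValidationError("degenerate permutation null (zero spread)")
    return GiniResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=(observed - null_mean) / null_sd,
        n_permutations=n_permutations,
        seed=seed,
        relative_counts=pd.Series(
            _cluster_relative_counts(obs_t, sizes, n_treated, n_total),
            index=list(clusters.categories),
        ),
    )


def quantize_equal_frequency(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin labels by rank (sizes differ by at most 1).

    Ties break by stable input order, so a constant vector splits
    deterministically into consecutive equal-size blocks.
    """
    x = np.asarray(values)
    if n_bins < 2:
        raise ValidationError("need at least 2 bins")
    if x.size < n_bins:
        raise ValidationError("more bins than values")
    order = np.argsort(x, kind="stable")
    labels = np.empty(x.size, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        labels[chunk] = b
    return labels


@dataclass
class MIEnrichment:
    """Mutual information of bins × membership with shuffle z and per-bin tails."""

    mi: float  # nats
    z: float
    null_mean: float
    null_sd: float
    per_bin: pd.DataFrame  # bin, observed, expected, p, sign
    n_bins: int
    n: int


def mutual_information(bin_labels: np.ndarray, membership: np.ndarray) -> float:
    """MI (nats) between discrete bin labels and a binary membership vector."""
    bins = np.asarray(bin_labels)
    mem = np.asarray(membership, dtype=bool)
    n = bins.size
    mi = 0.0
    for b in np.unique(bins):
        in_bin = bins == b
        for m in (True, False):
            joint = np.sum(in_bin & (mem == m)) / n
            if joint == 0:
                continue
            pb = in_bin.sum() / n
            pm = np.mean(mem == m)
            mi += joint * np.log(joint / (pb * pm))
    return float(max(mi, 0.0))


def mi_enrichment(
    bin_labels: np.ndarray,
    membership: np.ndarray,
    n_shuffle: int = 1000,
    seed: int = 0,
) -> MIEnrichment:
    """MI enrichment of a binary membership over quantized bins.

    z compares the observed MI with ``n_shuffle`` membership permutations.
    Per bin, a two-tailed hypergeometric tail p tests the overlap between the
    bin and the membership, signed + for over- and − for under-representation
    relative to expectation.
    """
    bins = np.asarray(bin_labels)
    mem = np.asarray(membership, dtype=bool)
    if bins.size != mem.size:
        raise ValidationError("bin labels and membership differ in length")
    if mem.sum() == 0:
        raise ValidationError("membership is empty")
    mi_obs = mutual_information(bins, mem)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffle)
    for i in range(n_shuffle):
        null[i] = mutual_information(bins, rng.permutation(mem))
    null_mean, null_sd = float(null.mean()), float(null.std(ddof=1))
    z = (mi_obs - null_mean) / null_sd if null_sd > 0 else 0.0

    n, K = bins.size, int(mem.sum())
    rows = []
    for b in np.unique(bins):
        in_bin = bins == b
        nb = int(in_bin.sum())
        k = int(np.sum(in_bin & mem))
        expected = nb * K / n
        rv = scipy.stats.hypergeom(n, K, nb)
        p_over = float(rv.sf(k - 1))
        p_under = float(rv.cdf(k))
        p = min(1.0, 2.0 * min(p_over, p_under))
        rows.append(
            {
                "bin": b,
                "observed": k,
                "expected": expected,
                "p": p,
                "sign": 1 if k > expected else (-1 if k < expected else 0),
            }
        )
    return MIEnrichment(
        mi=mi_obs,
        z=float(z),
        null_mean=null_mean,
        null_sd=null_sd,
        per_bin=pd.DataFrame(rows),
        n_bins=len(np.unique(bins)),
        n=n,
    )


def treated_enrichment_by_quantile(
    statistic: np.ndarray,
    treated: np.ndarray,
    n_bins: int = 10,
    n_shuffle: int = 1000,
    seed: int = 0,
) -> MIEnrichment:
    """MI enrichment of treated cells over quantile bins of a cell statistic.

    Convenience wrapper for the cell-level application: bins are deciles (by
    default) of e.g. mitochondrial expression, membership is "treated".
    """
    bins = quantize_equal_frequency(statistic, n_bins)
    return mi_enrichment(bins, treated, n_shuffle=n_shuffle, seed=seed)
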