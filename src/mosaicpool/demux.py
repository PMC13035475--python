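"""Sample and line-of-origin demultiplexing for pooled single-cell data.

Two independent channels identify each droplet:

- **Hashtag demultiplexing** — hashtag-oligo counts are centered-log-ratio
  transformed per cell; each channel gets an across-cell positivity threshold
  (one-dimensional Otsu split); exactly one positive channel calls the sample,
  two or more call a hash doublet, none leaves the cell unassigned.

- **Genotype demultiplexing** — per-cell SNP ref/alt reads are scored against
  each line's alt-allele dosages under a binomial read model with sequencing
  error ε, and against every unordered line pair under the fixed-α mixture
  (α = 0.5: a doublet is modeled as an equal mix of two cells).  The call is
  the maximum-posterior hypothesis with a configurable doublet prior; cells
  with too few informative reads are left ambiguous.

Expression clusters can additionally be mapped to lines by correlating the
cluster's pooled (pseudobulk) alt-allele fractions with reference dosages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from mosaicpool.core import CellAlleleCounts, GenotypeReference, ValidationError

logger = logging.getLogger(__name__)

AMBIGUOUS = "ambiguous"
DOUBLET = "doublet"
UNASSIGNED = "unassigned"


@dataclass
class DemuxCall:
    """Per-cell demultiplexing result."""

    barcode: str
    hash_call: str
    genotype_call: str  # line id, "lineA+lineB" for doublets, or "ambiguous"
    call_type: str  # singlet | doublet | ambiguous
    best_singlet: str
    best_singlet_ll: float
    best_doublet: str
    best_doublet_ll: float
    posterior_margin: float


# ---------------------------------------------------------------------------
# Hash demultiplexing


def clr_transform(counts: np.ndarray) -> np.ndarray:
    """Centered log-ratio per cell: log1p(count) minus the cell's mean log1p."""
    logc = np.log1p(np.asarray(counts, dtype=float))
    return logc - logc.mean(axis=1, keepdims=True)


def otsu_threshold(values: np.ndarray) -> float:
    """One-dimensional two-class Otsu split (maximal between-class variance)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 2 or v[0] == v[-1]:
        return v[-1] if n else 0.0
    csum = np.cumsum(v)
    total = csum[-1]
    k = np.arange(1, n)  # split after index k-1
    mean_lo = csum[:-1] / k
    mean_hi = (total - csum[:-1]) / (n - k)
    between = k * (n - k) * (mean_lo - mean_hi) ** 2
    split = int(np.argmax(between))
    return 0.5 * (v[split] + v[split + 1])


def assign_hash(
    hash_counts: pd.DataFrame, quantile_threshold: float | None = None
) -> pd.Series:
    """Call each cell's sample from hashtag counts.

    ``hash_counts`` is cells × channels.  Channels are CLR-transformed, then
    per-channel thresholds split positive from background cells — an Otsu
    split by default, or the given across-cell quantile.  Exactly one positive
    channel → that sample; two or more → ``doublet``; none → ``unassigned``.
    All-zero cells are unassigned.
    """
    if hash_counts.shape[1] < 1:
        raise ValidationError("need at least one hash channel")
    counts = hash_counts.to_numpy(dtype=float)
    clr = clr_transform(counts)
    nonzero = counts.sum(axis=1) > 0
    positive = np.zeros_like(clr, dtype=bool)
    for j in range(clr.shape[1]):
        if quantile_threshold is not None:
            thr = np.quantile(clr[:, j], quantile_threshold)
        else:
            thr = otsu_threshold(clr[:, j])
        positive[:, j] = clr[:, j] > thr
    positive[~nonzero] = False
    n_pos = positive.sum(axis=1)
    channels = np.asarray(hash_counts.columns, dtype=object)
    calls = np.where(
        n_pos == 1,
        channels[np.argmax(positive, axis=1)],
        np.where(n_pos >= 2, DOUBLET, UNASSIGNED),
    )
    return pd.Series(calls, index=hash_counts.index, name="hash_call")


# ---------------------------------------------------------------------------
# Genotype demultiplexing


def _mixture_p(dosage: np.ndarray, epsilon: float) -> np.ndarray:
    """Per-read alt probability given alt dosage d: (1−ε)·d + ε·(1−d)."""
    return (1.0 - epsilon) * dosage + epsilon * (1.0 - dosage)


def singlet_loglik(
    ref_reads: np.ndarray,
    alt_reads: np.ndarray,
    dosage: np.ndarray,
    epsilon: float = 0.01,
) -> float:
    """Binomial log-likelihood of a cell's allele reads under one line's dosages.

    Sums log Binomial(alt; ref+alt, p) over covered variants with
    p = (1−ε)·d + ε·(1−d); variants with missing dosage or zero coverage are
    skipped.  Empty evidence gives 0.0.
    """
    if not 0 < epsilon < 0.5:
        raise ValidationError("epsilon must be in (0, 0.5)")
    ref = np.asarray(ref_reads, dtype=float)
    alt = np.asarray(alt_reads, dtype=float)
    d = np.asarray(dosage, dtype=float)
    n = ref + alt
    use = (n > 0) & ~np.isnan(d)
    if not use.any():
        return 0.0
    ref, alt, n, d = ref[use], alt[use], n[use], d[use]
    p = _mixture_p(d, epsilon)
    coef = gammaln(n + 1) - gammaln(alt + 1) - gammaln(ref + 1)
    return float(np.sum(coef + alt * np.log(p) + ref * np.log(1.0 - p)))


def _hypothesis_dosages(
    reference: GenotypeReference, alpha: float
) -> tuple[np.ndarray, list[str], list[str]]:
    """Stack singlet dosages and α-mixture doublet dosages (hyp × variants)."""
    lines = reference.line_ids
    singlet_d = reference.dosage
    pair_labels = []
    pair_rows = []
    for a in range(len(lines)):
        for b in range(a + 1, len(lines)):
            pair_rows.append(
                alpha * singlet_d[a] + (1.0 - alpha) * singlet_d[b]
            )
            pair_labels.append(f"{lines[a]}+{lines[b]}")
    pair_d = np.array(pair_rows) if pair_rows else np.empty((0, reference.n_variants))
    return np.vstack([singlet_d, pair_d]), list(lines), pair_labels


def _loglik_matrix(
    alleles: CellAlleleCounts, dosages: np.ndarray, epsilon: float
) -> np.ndarray:
    """Cells × hypotheses log-likelihood, vectorized over sparse reads."""
    alt = alleles.alt.tocsr().astype(float)
    ref = alleles.ref.tocsr().astype(float)
    tot = alt + ref
    p = _mixture_p(dosages, epsilon)  # hyp × variants, NaN where missing
    known = ~np.isnan(p)
    logp = np.where(known, np.log(np.where(known, p, 0.5)), 0.0)
    log1mp = np.where(known, np.log(np.where(known, 1.0 - p, 0.5)), 0.0)
    ll = alt @ logp.T + ref @ log1mp.T
    # binomial coefficients, counted only at hypothesis-covered variants
    coef = tot.copy()
    coef.data = gammaln(tot.data + 1)
    coef_a = alt.copy()
    coef_a.data = gammaln(alt.data + 1)
    coef_r = ref.copy()
    coef_r.data = gammaln(ref.data + 1)
    const = coef - coef_a - coef_r
    ll += const @ known.T.astype(float)
    return np.asarray(ll)


def assign_genotype(
    alleles: CellAlleleCounts,
    reference: GenotypeReference,
    epsilon: float = 0.01,
    doublet_prior: float = 0.05,
    alpha: float = 0.5,
    min_informative_reads: int = 10,
    hash_calls: pd.Series | None = None,
) -> pd.DataFrame:
    """Genotype calls (singlet line, doublet pair or ambiguous) for every cell.

    The best singlet maximizes the binomial likelihood over lines; the best
    doublet maximizes it over unordered pairs under the α-weighted dosage
    mixture.  Posteriors spread (1 − doublet_prior) over singlets and
    doublet_prior over pairs; cells with fewer than ``min_informative_reads``
    covered reads are ambiguous.  Ties break by lexicographic line order.

    Returns one row per cell with call, type, best hypotheses,
    log-likelihoods and posterior margin (log-posterior gap to the runner-up).
    """
    if not 0 < epsilon < 0.5:
        raise ValidationError("epsilon must be in (0, 0.5)")
    if reference.n_lines < 2:
        raise ValidationError("reference must contain at least 2 lines")
    dosages, singlet_labels, pair_labels = _hypothesis_dosages(reference, alpha)
    ll = _loglik_matrix(alleles, dosages, epsilon)
    n_s, n_p = len(singlet_labels), len(pair_labels)
    log_prior = np.concatenate(
        [
            np.full(n_s, np.log((1 - doublet_prior) / n_s)),
            np.full(n_p, np.log(doublet_prior / n_p)) if n_p else np.empty(0),
        ]
    )
    log_post = ll + log_prior
    log_post -= logsumexp(log_post, axis=1, keepdims=True)

    informative = np.asarray((alleles.ref + alleles.alt).sum(axis=1)).ravel()
    best_s = np.argmax(ll[:, :n_s], axis=1)
    best_p = np.argmax(ll[:, n_s:], axis=1) if n_p else np.zeros(len(ll), dtype=int)
    order = np.argsort(log_post, axis=1)
    top = order[:, -1]
    margin = log_post[np.arange(len(ll)), top] - log_post[
        np.arange(len(ll)), order[:, -2]
    ]

    labels = np.array(singlet_labels + pair_labels, dtype=object)
    rows = []
    hash_arr = (
        hash_calls.reindex(alleles.barcodes).to_numpy()
        if hash_calls is not None
        else np.full(len(alleles.barcodes), UNASSIGNED, dtype=object)
    )
    for i, bc in enumerate(alleles.barcodes):
        if informative[i] < min_informative_reads:
            call, ctype = AMBIGUOUS, AMBIGUOUS
        else:
            call = labels[top[i]]
            ctype = "singlet" if top[i] < n_s else "doublet"
        rows.append(
            DemuxCall(
                barcode=bc,
                hash_call=hash_arr[i] if hash_arr[i] is not None else UNASSIGNED,
                genotype_call=call,
                call_type=ctype,
                best_singlet=singlet_labels[best_s[i]],
                best_singlet_ll=float(ll[i, best_s[i]]),
                best_doublet=pair_labels[best_p[i]] if n_p else "",
                best_doublet_ll=float(ll[i, n_s + best_p[i]]) if n_p else np.nan,
                posterior_margin=float(margin[i]),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def assign_clusters_by_pseudobulk(
    cluster_labels: pd.Series,
    alleles: CellAlleleCounts,
    reference: GenotypeReference,
) -> pd.DataFrame:
    """Map expression clusters to lines by pseudobulk allele correlation.

    Per cluster, alt-allele fractions are pooled over member cells and
    Pearson-correlated with each line's dosage vector over covered variants;
    the argmax line is assigned.  Ties break deterministically by line order
    with a warning; clusters with no covered variants are unassigned.
    """
    labels = pd.Series(cluster_labels)
    bc_index = pd.Index(alleles.barcodes)
    rows = []
    for cluster in pd.unique(labels):
        members = labels.index[labels == cluster]
        idx = bc_index.get_indexer(members)
        idx = idx[idx >= 0]
        if idx.size == 0:
            rows.append((cluster, UNASSIGNED, np.nan))
            continue
        alt = np.asarray(alleles.alt[idx].sum(axis=0)).ravel()
        tot = alt + np.asarray(alleles.ref[idx].sum(axis=0)).ravel()
        covered = tot > 0
        if not covered.any():
            rows.append((cluster, UNASSIGNED, np.nan))
            continue
        frac = alt[covered] / tot[covered]
        best_line, best_r = UNASSIGNED, -np.inf
        tie = False
        for li, line in enumerate(reference.line_ids):
            d = reference.dosage[li, covered]
            ok = ~np.isnan(d)
            if ok.sum() < 2 or np.std(d[ok]) == 0 or np.std(frac[ok]) == 0:
                continue
            r = float(np.corrcoef(frac[ok], d[ok])[0, 1])
            if r > best_r + 1e-12:
                best_line, best_r, tie = line, r, False
            elif abs(r - best_r) <= 1e-12:
                tie = True
        if tie:
            logger.warning(
                "cluster %s: correlation tie, keeping first line in order", cluster
            )
        rows.append((cluster, best_line, best_r if np.isfinite(best_r) else np.nan))
    return pd.DataFrame(rows, columns=["cluster", "line_id", "correlation"])
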