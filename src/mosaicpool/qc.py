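"""Apoptosis flagging, cell-cycle phase scoring and composition tests.

Apoptotic cells are flagged by fixed thresholds — fewer than 1,000 detected
genes, fewer than 2,000 total UMIs, or more than 15% of counts from
mitochondria-encoded genes.  Flags are stored, not filtered: shifts in the
apoptotic compartment across conditions are themselves a phenotype.

Cell-cycle phases are scored per cell as the mean log-normalized expression
of an S or G2M geneset minus the mean of an expression-matched random control
set; a cell is G1 when both scores are non-positive, otherwise the larger
score's phase wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from mosaicpool.core import PooledExperiment, QCThresholds, ValidationError


def flag_apoptotic(exp: PooledExperiment, thr: QCThresholds | None = None) -> np.ndarray:
    """Boolean apoptotic flag per cell.

    flag = (detected genes < min_genes) OR (mito fraction > max_mito_frac)
    OR (total counts < min_counts).  Cells are retained, not removed.
    """
    thr = thr or QCThresholds()
    counts = exp.counts
    n_genes = np.asarray((counts > 0).sum(axis=1)).ravel()
    n_counts = np.asarray(counts.sum(axis=1)).ravel()
    mito = np.asarray(exp.gene_meta["is_mito_encoded"], dtype=bool)
    mito_counts = np.asarray(counts[:, mito].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(n_counts > 0, mito_counts / np.maximum(n_counts, 1), 0.0)
    return (
        (n_genes < thr.min_genes)
        | (mito_frac > thr.max_mito_frac)
        | (n_counts < thr.min_counts)
    )


def log_normalize(counts: sp.spmatrix, target_sum: float = 1e4) -> np.ndarray:
    """Counts-per-10k then log1p (dense output)."""
    counts = sp.csr_matrix(counts, dtype=float)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    scale = target_sum / np.maximum(totals, 1.0)
    norm = counts.multiply(scale[:, None]).toarray()
    return np.log1p(norm)


@dataclass
class PhaseAssignment:
    """Per-cell S and G2M scores and the resulting phase call."""

    s_score: np.ndarray
    g2m_score: np.ndarray
    phase: np.ndarray  # "G1" | "S" | "G2M"

    def to_frame(self, barcodes=None) -> pd.DataFrame:
        return pd.DataFrame(
            {"s_score": self.s_score, "g2m_score": self.g2m_score, "phase": self.phase},
            index=barcodes,
        )


def _geneset_score(
    logX: np.ndarray,
    set_idx: np.ndarray,
    n_bins: int,
    ctrl_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean set expression minus mean of expression-bin-matched control genes."""
    mean_expr = logX.mean(axis=0)
    order = np.argsort(mean_expr, kind="stable")
    bins = np.empty(logX.shape[1], dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    ctrl: set[int] = set()
    for g in set_idx:
        pool = np.flatnonzero(bins == bins[g])
        take = min(ctrl_size, pool.size)
        ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    ctrl_idx = np.fromiter(ctrl, dtype=int)
    return logX[:, set_idx].mean(axis=1) - logX[:, ctrl_idx].mean(axis=1)


def score_cell_cycle(
    exp: PooledExperiment,
    s_genes: list[str],
    g2m_genes: list[str],
    n_ctrl_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> PhaseAssignment:
    """Score S and G2M programs per cell and call the phase.

    Scores use CP10k/log1p expression and subtract a seeded random control
    set matched on average expression (``n_ctrl_bins`` equal-frequency bins,
    ``ctrl_size`` controls per target gene).  Phase is G1 when both scores
    are ≤ 0, otherwise the larger score's phase.
    """
    for name, genes in (("s_genes", s_genes), ("g2m_genes", g2m_genes)):
        if not genes:
            raise ValidationError(f"{name} is empty")
    symbols = pd.Index(exp.gene_meta["symbol"])
    s_idx = symbols.get_indexer(s_genes)
    g2m_idx = symbols.get_indexer(g2m_genes)
    s_idx, g2m_idx = s_idx[s_idx >= 0], g2m_idx[g2m_idx >= 0]
    if s_idx.size == 0 or g2m_idx.size == 0:
        raise ValidationError("genesets share no genes with the matrix")
    logX = log_normalize(exp.counts)
    rng = np.random.default_rng(seed)
    s_score = _geneset_score(logX, s_idx, n_ctrl_bins, ctrl_size, rng)
    g2m_score = _geneset_score(logX, g2m_idx, n_ctrl_bins, ctrl_size, rng)
    phase = np.where(
        (s_score <= 0) & (g2m_score <= 0),
        "G1",
        np.where(s_score > g2m_score, "S", "G2M"),
    )
    return PhaseAssignment(s_score, g2m_score, phase)


def composition_chisq(table: pd.DataFrame) -> tuple[float, float]:
    """Two-sided Pearson χ² on a state × condition contingency table."""
    arr = np.asarray(table, dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("contingency table has an empty row or column")
    chi2, p, _, _ = scipy.stats.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


def g1_dose_trend(
    doses: np.ndarray,
    g1_fractions: np.ndarray,
    sided: str = "two-sided",
    vehicle_fraction: float | None = None,
) -> tuple[float, float, float]:
    """Trend of G1 fraction against log10 dose.

    OLS slope of G1 fraction on log10(dose) over nonzero doses, with the
    Pearson R and its t-distributed significance (``two-sided``, ``greater``
    or ``less``).  With ``vehicle_fraction`` given, fractions are first
    normalized to vehicle (DMSO-anchored variant).

    Returns (slope, R, p).
    """
    doses = np.asarray(doses, dtype=float)
    frac = np.asarray(g1_fractions, dtype=float)
    keep = doses > 0
    doses, frac = doses[keep], frac[keep]
    if doses.size < 3:
        raise ValidationError("need at least 3 nonzero dose points")
    x = np.log10(doses)
    if np.ptp(x) == 0:
        raise ValidationError("doses have zero variance")
    if vehicle_fraction is not None:
        frac = frac / vehicle_fraction
    slope, _ = np.polyfit(x, frac, 1)
    if np.std(frac) == 0:
        return float(slope), 0.0, 1.0
    res = scipy.stats.pearsonr(x, frac, alternative=sided)
    return float(slope), float(res.statistic), float(res.pvalue)
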