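"""Per-line differential expression and cross-model aggregation.

Each line contributes a per-gene log2 fold change (treated vs vehicle, on
CP10k-normalized means with pseudocount 1) and a rank-sum p.  Across lines,
fold changes are z-normalized within each line and averaged into a mean
difference z per gene, tested against a bootstrapped null and BH-corrected.
Group deltas (e.g. KRAS-G12C vs non-G12C lines) contrast mean fold changes
between line groups with Welch t-tests, and geneset shift tests ask whether
a geneset's statistics deviate from the background.  A model-downsampling
analysis tracks how geneset significance grows with the number of lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from mosaicpool.core import PooledExperiment, ValidationError
from mosaicpool.qc import log_normalize

logger = logging.getLogger(__name__)


def per_line_log2fc(
    exp: PooledExperiment,
    line: str,
    treated_condition: str,
    control_condition: str,
    min_cells: int = 20,
    compute_pvalues: bool = True,
) -> pd.DataFrame | None:
    """Per-gene log2 fold change (treated vs control) for one line.

    Uses CP10k-normalized mean expression with pseudocount 1 and a two-sided
    rank-sum p per gene.  Lines with fewer than ``min_cells`` cells in either
    arm are skipped (returns None with a warning).
    """
    meta = exp.cell_meta
    is_line = (meta["line_id"] == line).to_numpy()
    t_mask = is_line & (meta["condition"] == treated_condition).to_numpy()
    c_mask = is_line & (meta["condition"] == control_condition).to_numpy()
    if t_mask.sum() < min_cells or c_mask.sum() < min_cells:
        logger.warning(
            "line %s skipped: %d treated / %d control cells (< %d)",
            line,
            t_mask.sum(),
            c_mask.sum(),
            min_cells,
        )
        return None
    norm = log_normalize(exp.counts)
    # fold change on the normalized (not log) scale, pseudocount 1
    cp10k = np.expm1(norm)
    mean_t = cp10k[t_mask].mean(axis=0)
    mean_c = cp10k[c_mask].mean(axis=0)
    log2fc = np.log2(mean_t + 1.0) - np.log2(mean_c + 1.0)
    out = pd.DataFrame({"gene": exp.gene_meta["symbol"], "log2fc": log2fc})
    if compute_pvalues:
        res = scipy.stats.mannwhitneyu(
            norm[t_mask], norm[c_mask], axis=0, alternative="two-sided"
        )
        p = np.asarray(res.pvalue, dtype=float)
        # genes absent in both arms carry no evidence
        absent = (mean_t == 0) & (mean_c == 0)
        p[absent] = 1.0
        out["p"] = p
    return out


def zscore_within_line(log2fc: pd.DataFrame) -> pd.DataFrame:
    """z-normalize each line's log2FC column across genes (mean 0, SD 1)."""
    arr = log2fc.to_numpy(dtype=float)
    mu = arr.mean(axis=0, keepdims=True)
    sd = arr.std(axis=0, ddof=0, keepdims=True)
    if (sd == 0).any():
        raise ValidationError("a line has zero log2FC variance")
    return pd.DataFrame((arr - mu) / sd, index=log2fc.index, columns=log2fc.columns)


@dataclass
class CrossModelDE:
    """Cross-model aggregation of per-line fold changes."""

    z: pd.DataFrame  # genes × lines within-line z
    mean_z: pd.Series  # per-gene mean difference z
    p: pd.Series
    q: pd.Series


def cross_model_aggregate(
    log2fc: pd.DataFrame,
    n_boot: int = 10_000,
    resample: str = "independent",
    seed: int = 0,
) -> CrossModelDE:
    """Aggregate per-line log2FC into mean difference z scores with bootstrap p.

    ``log2fc`` is genes × lines.  Each line's fold changes are z-scored
    across genes and averaged per gene.  The bootstrap null for "no
    consistent cross-line shift" draws each line's z from an independently
    resampled gene (``resample='independent'``, the default): this breaks
    the gene linkage that carries a real shared signal while keeping each
    line's marginal z distribution.  ``resample='rows'`` instead resamples
    whole gene rows, which preserves inter-line noise correlation but folds
    any true signal into the null (conservative).  Two-tailed p compares
    each gene's |mean z| with the null; BH over genes.
    """
    if log2fc.shape[1] < 2:
        raise ValidationError("need at least 2 lines; use per-line results instead")
    z = zscore_within_line(log2fc)
    mean_z = z.mean(axis=1)
    rng = np.random.default_rng(seed)
    zv = z.to_numpy()
    if resample == "independent":
        idx = rng.integers(0, zv.shape[0], size=(n_boot, zv.shape[1]))
        null = zv[idx, np.arange(zv.shape[1])[None, :]].mean(axis=1)
    elif resample == "rows":
        idx = rng.integers(0, zv.shape[0], size=n_boot)
        null = zv[idx].mean(axis=1)
    else:
        raise ValidationError(f"unknown resample mode {resample!r}")
    abs_null = np.sort(np.abs(null))
    obs = np.abs(mean_z.to_numpy())
    exceed = len(abs_null) - np.searchsorted(abs_null, obs, side="left")
    p = (1.0 + exceed) / (n_boot + 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    return CrossModelDE(
        z=z,
        mean_z=mean_z,
        p=pd.Series(p, index=log2fc.index),
        q=pd.Series(q, index=log2fc.index),
    )


def group_delta(
    log2fc: pd.DataFrame, group1: list[str], group2: list[str]
) -> pd.DataFrame:
    """Per-gene mean log2FC difference between two line groups with Welch t p.

    delta = mean(log2FC | group1) − mean(log2FC | group2).  Groups of size
    < 2 keep the delta but report the p as missing.
    """
    if not group1 or not group2:
        raise ValidationError("both groups must be nonempty")
    a = log2fc[group1].to_numpy()
    b = log2fc[group2].to_numpy()
    delta = a.mean(axis=1) - b.mean(axis=1)
    if len(group1) >= 2 and len(group2) >= 2:
        res = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    else:
        p = np.full(len(delta), np.nan)
    return pd.DataFrame({"delta": delta, "p": p}, index=log2fc.index)


def geneset_shift_test(
    statistic: pd.Series,
    geneset: set[str],
    background: set[str] | None = None,
) -> dict[str, float]:
    """Does a geneset's statistic shift relative to the background?

    Runs both a two-sided Mann–Whitney U test and a two-sample t-test of the
    geneset's values against the background's (background defaults to all
    genes not in the set).  A set equal to its background has no contrast and
    returns p = 1 by convention.

    Returns dict with keys mw_p, t_p, direction (sign of the mean shift).
    """
    universe = set(statistic.index)
    members = sorted(geneset & universe)
    if not members:
        raise ValidationError("geneset does not intersect the statistic's genes")
    bg = sorted((background & universe) if background is not None else universe - set(members))
    if set(members) == set(bg) or not bg:
        return {"mw_p": 1.0, "t_p": 1.0, "direction": 0.0}
    x = statistic.loc[members].to_numpy()
    y = statistic.loc[bg].to_numpy()
    mw = scipy.stats.mannwhitneyu(x, y, alternative="two-sided")
    tt = scipy.stats.ttest_ind(x, y, equal_var=False)
    return {
        "mw_p": float(mw.pvalue),
        "t_p": float(tt.pvalue),
        "direction": float(np.sign(x.mean() - y.mean())),
    }


def downsample_models(
    log2fc: pd.DataFrame,
    ks: list[int],
    n_draws: int,
    genesets: dict[str, set[str]],
    n_random_sets: int = 10,
    random_set_size: int | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Geneset significance as a function of the number of lines used.

    For each k, draws ``n_draws`` k-line subsets (all subsets once when there
    are fewer than n_draws), reruns the cross-model aggregation and the
    geneset shift tests on the subset's mean z, and records the median p per
    geneset and per size-matched random set.

    Returns (summary, draws): the summary is a long table of k, set,
    set_type, median_p; draws holds every subset's p per set for trend tests
    that pool over draws.
    """
    lines = list(log2fc.columns)
    rng = np.random.default_rng(seed)
    if any(k < 2 or k > len(lines) for k in ks):
        raise ValidationError("each k must satisfy 2 <= k <= number of lines")
    sizes = {name: len(s) for name, s in genesets.items()}
    rsize = random_set_size or int(np.median(list(sizes.values())))
    universe = list(log2fc.index)
    random_sets = {
        f"random_{i + 1}": set(rng.choice(universe, size=rsize, replace=False))
        for i in range(n_random_sets)
    }
    rows, draw_rows = [], []
    for k in ks:
        all_subsets = list(combinations(lines, k))
        if len(all_subsets) <= n_draws:
            subsets = all_subsets
        else:
            picks = rng.choice(len(all_subsets), size=n_draws, replace=False)
            subsets = [all_subsets[i] for i in picks]
        pvals: dict[str, list[float]] = {
            name: [] for name in list(genesets) + list(random_sets)
        }
        for subset in subsets:
            agg = cross_model_aggregate(
                log2fc[list(subset)],
                n_boot=n_boot,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            for name, s in {**genesets, **random_sets}.items():
                res = geneset_shift_test(agg.mean_z, s)
                pvals[name].append(res["mw_p"])
        for name in pvals:
            set_type = "target" if name in genesets else "random"
            rows.append(
                {
                    "k": k,
                    "set": name,
                    "set_type": set_type,
                    "median_p": float(np.median(pvals[name])),
                }
            )
            draw_rows.extend(
                {"k": k, "set": name, "set_type": set_type, "p": p}
                for p in pvals[name]
            )
    return pd.DataFrame(rows), pd.DataFrame(draw_rows)
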