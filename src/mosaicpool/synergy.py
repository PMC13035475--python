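"""Bliss-independence synergy and gene-level synergy covariates.

The Bliss model predicts the combined effect of two independent drugs as
``eA + eB − eA·eB`` on the inhibition scale; deviation of the observed combo
effect from this expectation is synergy (+) or antagonism (−).  It is applied
to survival fractions, and to single-cell phenotypes such as the G1-arrest
fraction.

Gene-level synergy covariates contrast single-agent and dual-agent treatment
coefficients from log-linear count models fit on pseudobulk (summed) counts
per line × condition × replicate: s = (βA + βB) − βAB per gene per line,
averaged over lines and ranked by a t statistic against a bootstrapped null.
The count model uses median-of-ratios size-factor offsets, line + treatment
factors and a per-gene method-of-moments dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from mosaicpool.core import PooledExperiment, ValidationError


def bliss_expected(e_a: float, e_b: float) -> float:
    """Bliss independence expectation eA + eB − eA·eB for effects in [0, 1]."""
    e_a, e_b = float(e_a), float(e_b)
    if not (0 <= e_a <= 1 and 0 <= e_b <= 1):
        raise ValidationError("effects must lie in [0, 1]")
    return e_a + e_b - e_a * e_b


@dataclass
class BlissResult:
    """Observed vs Bliss-expected combination effect."""

    e_a: float
    e_b: float
    e_ab: float
    expected: float
    synergy: float  # observed − expected; + = synergy on the inhibition scale
    p: float = np.nan


def bliss_from_survival(
    control: float | np.ndarray,
    surv_a: float | np.ndarray,
    surv_b: float | np.ndarray,
    surv_ab: float | np.ndarray,
) -> BlissResult:
    """Bliss synergy from survival fractions (replicates → mean effect + t p).

    Effects are 1 − survival/control, clamped to [0, 1].  With ≥3 replicates
    per arm, a two-tailed one-sample t tests the per-replicate synergy values
    against 0 (the no-interaction null estimated from the replicate spread).
    """
    control = np.atleast_1d(np.asarray(control, dtype=float))
    if (control <= 0).any():
        raise ValidationError("control survival must be positive")
    arrs = [np.atleast_1d(np.asarray(a, dtype=float)) for a in (surv_a, surv_b, surv_ab)]
    ctrl_mean = control.mean()

    def effect(s):
        return np.clip(1.0 - s / ctrl_mean, 0.0, 1.0)

    eff = [effect(a) for a in arrs]
    e_a, e_b, e_ab = (float(e.mean()) for e in eff)
    expected = bliss_expected(e_a, e_b)
    synergy = e_ab - expected
    p = np.nan
    n_rep = min(len(a) for a in arrs)
    if n_rep >= 3:
        per_rep = [
            eff[2][i] - bliss_expected(float(eff[0][i]), float(eff[1][i]))
            for i in range(n_rep)
        ]
        if np.std(per_rep, ddof=1) > 0:
            p = float(scipy.stats.ttest_1samp(per_rep, 0.0).pvalue)
    return BlissResult(e_a, e_b, e_ab, expected, float(synergy), p)


def phenotype_bliss(
    g1_vehicle: float,
    g1_a: float,
    g1_b: float,
    g1_ab: float,
    normalized: bool = True,
) -> BlissResult:
    """Bliss synergy on G1-arrest fractions.

    The arrest effect of a condition is max(0, (G1 − G1_vehicle)/(1 −
    G1_vehicle)) — the fraction of the remaining non-G1 pool pushed into
    arrest.  ``normalized=False`` uses the raw difference max(0, G1 −
    G1_vehicle) instead.
    """
    if g1_vehicle >= 1.0:
        raise ValidationError("vehicle G1 fraction of 1 leaves no arrest headroom")

    def effect(g1):
        raw = g1 - g1_vehicle
        if normalized:
            raw = raw / (1.0 - g1_vehicle)
        return float(np.clip(raw, 0.0, 1.0))

    e_a, e_b, e_ab = effect(g1_a), effect(g1_b), effect(g1_ab)
    expected = bliss_expected(e_a, e_b)
    return BlissResult(e_a, e_b, e_ab, expected, e_ab - expected)


# ---------------------------------------------------------------------------
# Pseudobulk count model


def pseudobulk(
    exp: PooledExperiment, by: list[str] = ("line_id", "condition", "replicate")
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum cells to pseudobulk samples.

    Returns (counts genes × samples, sample metadata) with one pseudobulk
    sample per unique combination of ``by`` columns.
    """
    meta = exp.cell_meta
    groups = meta.groupby(list(by), observed=True, sort=True).indices
    cols, rows = [], []
    for key, idx in groups.items():
        key = key if isinstance(key, tuple) else (key,)
        cols.append(dict(zip(by, key)))
        rows.append(np.asarray(exp.counts[idx].sum(axis=0)).ravel())
    sample_meta = pd.DataFrame(cols)
    sample_meta["sample"] = [
        "_".join(str(v) for v in row) for row in sample_meta[list(by)].to_numpy()
    ]
    counts = pd.DataFrame(
        np.array(rows).T,
        index=exp.gene_meta["symbol"].to_numpy(),
        columns=sample_meta["sample"],
    )
    return counts, sample_meta


def median_of_ratios_size_factors(counts: np.ndarray) -> np.ndarray:
    """DESeq-style size factors: median ratio to the per-gene geometric mean."""
    counts = np.asarray(counts, dtype=float)
    log_counts = np.where(counts > 0, np.log(np.where(counts > 0, counts, 1.0)), np.nan)
    all_pos = ~np.isnan(log_counts).any(axis=1)
    if all_pos.sum() < 1:
        raise ValidationError("no gene is expressed in every sample")
    log_gm = log_counts[all_pos].mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_counts[all_pos] - log_gm, axis=0))
    return sf / np.exp(np.mean(np.log(sf)))


def _irls_loglinear(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, n_iter: int = 50, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Batched log-linear count fit: y (genes × samples), shared design X.

    Poisson IRLS first, then one NB reweighting round with per-gene
    method-of-moments dispersion (floor 1e-8).  Returns (beta genes × p,
    dispersion per gene).  Coefficients are on the natural-log scale.
    """
    G, S = y.shape
    p = X.shape[1]
    beta = np.zeros((G, p))
    # initialize intercept from mean normalized count
    mean_norm = np.maximum((y / np.exp(offset)).mean(axis=1), 1e-8)
    beta[:, 0] = np.log(mean_norm)

    def step(beta, weights_fn):
        for _ in range(n_iter):
            eta = beta @ X.T + offset  # G × S
            mu = np.exp(np.clip(eta, -30, 30))
            w = weights_fn(mu)
            z = eta - offset + (y - mu) / np.maximum(mu, 1e-12)
            XtWX = np.einsum("sp,gs,sq->gpq", X, w, X)
            XtWz = np.einsum("sp,gs,gs->gp", X, w, z)
            XtWX += 1e-10 * np.eye(p)[None]
            new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
            delta = np.max(np.abs(new - beta))
            beta = new
            if delta < tol:
                break
        return beta

    beta = step(beta, lambda mu: mu)  # Poisson weights
    eta = beta @ X.T + offset
    mu = np.exp(np.clip(eta, -30, 30))
    resid = (y - mu) ** 2 - mu
    denom = np.maximum(mu**2, 1e-12)
    df = max(S - p, 1)
    phi = np.maximum((resid / denom).sum(axis=1) / df, 1e-8)
    beta = step(beta, lambda mu: mu / (1.0 + phi[:, None] * mu))  # NB2 weights
    return beta, phi


def fit_treatment_model(
    counts: pd.DataFrame,
    sample_meta: pd.DataFrame,
    treatment_levels: list[str],
    reference_level: str,
    line_col: str = "line_id",
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Treatment coefficients per gene from a pseudobulk log-linear count model.

    ``counts`` is genes × samples (un-normalized); ``sample_meta`` has one
    row per sample with line and condition columns.  The model is
    log μ = log(size factor) + line effects + treatment effects with the
    given reference level; dispersion is per-gene method-of-moments with a
    1e-8 floor.  Returns a genes × treatment-level table of coefficients on
    the natural-log scale.
    """
    use = sample_meta[condition_col].isin([reference_level, *treatment_levels])
    meta = sample_meta.loc[use].reset_index(drop=True)
    y = counts.loc[:, meta["sample"]].to_numpy(dtype=float)
    conds = set(meta[condition_col])
    if reference_level not in conds:
        raise ValidationError(f"reference condition {reference_level!r} has no samples")
    for lvl in treatment_levels:
        if lvl not in conds:
            raise ValidationError(f"condition {lvl!r} has no samples")
    sf = median_of_ratios_size_factors(y)
    offset = np.log(sf)

    lines = sorted(meta[line_col].unique())
    cols = [np.ones(len(meta))]
    names = ["intercept"]
    for line in lines[1:]:
        cols.append((meta[line_col] == line).to_numpy(dtype=float))
        names.append(f"line_{line}")
    for lvl in treatment_levels:
        cols.append((meta[condition_col] == lvl).to_numpy(dtype=float))
        names.append(lvl)
    X = np.column_stack(cols)
    beta, _ = _irls_loglinear(y, X, offset[None, :])
    out = pd.DataFrame(beta, index=counts.index, columns=names)
    return out[treatment_levels]


@dataclass
class SynergyFit:
    """Per-gene synergy covariates s = (βA + βB) − βAB and their ranking."""

    s: pd.DataFrame  # genes × lines
    mean_s: pd.Series
    t: pd.Series
    z: pd.Series
    p: pd.Series
    rank: pd.Series  # 1 = most negative t (strongest synergy)


def synergy_covariates(
    beta_a: pd.DataFrame,
    beta_b: pd.DataFrame,
    beta_ab: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
) -> SynergyFit:
    """Combine single- and dual-agent coefficients into synergy covariates.

    All three inputs are genes × lines on the same gene universe.  Per gene
    and line, s = (βA + βB) − βAB; the per-gene mean over lines is compared
    with a bootstrapped null (gene-label resampling of mean s, B draws) via a
    t statistic, with a z of the coefficient difference and the resulting
    rank (ascending t: strong synergy first).
    """
    for other in (beta_b, beta_ab):
        if not beta_a.index.equals(other.index) or not beta_a.columns.equals(
            other.columns
        ):
            raise ValidationError("coefficient tables must share genes and lines")
    s = (beta_a + beta_b) - beta_ab
    mean_s = s.mean(axis=1)
    n_lines = s.shape[1]
    rng = np.random.default_rng(seed)
    null = mean_s.to_numpy()[rng.integers(0, len(mean_s), size=n_boot)]
    # robust null moments: a minority of genes with real interaction must not
    # shift the center that additive genes are scored against
    null_mean = float(np.median(null))
    null_sd = float(1.4826 * np.median(np.abs(null - null_mean)))
    if null_sd == 0:
        raise ValidationError("degenerate bootstrap null")
    z = (mean_s - null_mean) / null_sd
    if n_lines >= 2:
        se = s.std(axis=1, ddof=1) / np.sqrt(n_lines)
        t = (mean_s - null_mean) / se.replace(0, np.nan)
        p = pd.Series(
            2 * scipy.stats.t.sf(np.abs(t), df=n_lines - 1), index=s.index
        )
    else:
        t = z.copy()
        p = pd.Series(2 * scipy.stats.norm.sf(np.abs(z)), index=s.index)
    rank = t.rank(method="first")
    return SynergyFit(s=s, mean_s=mean_s, t=t, z=z, p=p, rank=rank)
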