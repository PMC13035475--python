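"""Drug-sensitivity phenotypes from pool representation.

A line's phenotype under drug is read from how its share of the pool changes
between treated and vehicle arms: pool fractions, relative representation
(treated/vehicle fraction ratio), relative survival (log2 of that ratio),
and a dose–response slope score (slope of log10 representation ratio on
log10 dose).  Growth-rate utilities support the inverse balancing used to
seed pools so that every line is well represented at harvest, and a lasso
associates mutations with the survival phenotype across lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.linear_model import LassoCV
from sklearn.model_selection import LeaveOneOut

from mosaicpool.core import MutationMatrix, ValidationError

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 0.5


def growth_rate(y0: float, yt: float, t: float) -> float:
    """Exponential growth rate r = ln(Yt / Y0) / t (per unit of t)."""
    if y0 <= 0 or yt <= 0 or t <= 0:
        raise ValidationError("growth_rate requires positive Y0, Yt, t")
    return float(np.log(yt / y0) / t)


def balance_seeding(
    rates: np.ndarray,
    total_cells: int,
    horizon: float | None = None,
    mode: str = "horizon",
) -> np.ndarray:
    """Per-line seed counts inversely balancing growth.

    ``horizon`` mode (default) seeds ∝ exp(−r·T) so expected representation
    is equal at time T; ``literal`` mode seeds ∝ 1/r (all rates must be
    positive).  Counts are rounded by largest remainder to sum exactly to
    ``total_cells``.
    """
    rates = np.asarray(rates, dtype=float)
    if total_cells <= 0:
        raise ValidationError("total_cells must be positive")
    if not np.isfinite(rates).all():
        raise ValidationError("rates must be finite")
    if mode == "horizon":
        if horizon is None:
            raise ValidationError("horizon mode requires a time horizon")
        w = np.exp(-rates * horizon)
    elif mode == "literal":
        if (rates <= 0).any():
            raise ValidationError("literal 1/r mode requires all rates > 0")
        w = 1.0 / rates
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    frac = w / w.sum()
    ideal = frac * total_cells
    base = np.floor(ideal).astype(int)
    remainder = total_cells - base.sum()
    order = np.argsort(-(ideal - base), kind="stable")
    base[order[:remainder]] += 1
    return base


@dataclass
class SensitivityTable:
    """Per-line sensitivity phenotypes for one drug contrast."""

    per_sample: pd.DataFrame  # line, sample, condition, dose, replicate, n_cells, pool_fraction
    per_line: pd.DataFrame  # line, ratio, relative_survival, display_value
    per_group: pd.DataFrame | None = None
    slopes: pd.DataFrame | None = None


def pool_fractions(counts: pd.DataFrame) -> pd.DataFrame:
    """Column-wise fractions of a lines × samples count table (sum to 1)."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValidationError("every sample needs > 0 cells")
    return counts / totals


def relative_representation(
    counts: pd.DataFrame,
    treated_samples: list[str],
    control_samples: list[str],
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Treated/vehicle representation ratio per line.

    ``counts`` is lines × samples.  Zero counts get a pseudocount before
    fractions; replicate fractions are averaged within each arm before the
    ratio.  Also reports the display value: counts normalized by the max
    per-line count within the treated condition.
    """
    for s in treated_samples + control_samples:
        if s not in counts.columns:
            raise ValidationError(f"sample {s!r} absent from counts")
    padded = counts.astype(float).mask(counts == 0, pseudocount)
    frac = pool_fractions(padded)
    f_treat = frac[treated_samples].mean(axis=1)
    f_ctrl = frac[control_samples].mean(axis=1)
    ratio = f_treat / f_ctrl
    display = counts[treated_samples].sum(axis=1)
    display = display / display.max()
    return pd.DataFrame(
        {
            "treated_fraction": f_treat,
            "control_fraction": f_ctrl,
            "ratio": ratio,
            "relative_survival": np.log2(ratio),
            "display_value": display,
        }
    )


def relative_survival(
    counts: pd.DataFrame,
    treated_samples: list[str],
    control_samples: list[str],
    mutation_groups: dict[str, list[str]] | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Per-line log2 survival score and optional mutation-group aggregates.

    The per-line score is log2(treated fraction / vehicle fraction) after
    pseudocounting; a group score is the mean over its member lines, with
    the replicate-wise mean ± SD reported alongside.
    """
    rep = relative_representation(counts, treated_samples, control_samples, pseudocount)
    scores = rep["relative_survival"]
    group_df = None
    if mutation_groups is not None:
        rows = []
        for name, members in mutation_groups.items():
            if not members:
                raise ValidationError(f"group {name!r} has no member lines")
            missing = set(members) - set(counts.index)
            if missing:
                raise ValidationError(f"group {name!r} members absent: {missing}")
            # replicate-level scores for mean ± SD
            rep_scores = []
            for t in treated_samples:
                for c in control_samples:
                    r = relative_representation(counts, [t], [c], pseudocount)
                    rep_scores.append(r.loc[members, "relative_survival"].mean())
            rows.append(
                {
                    "group": name,
                    "n_lines": len(members),
                    "score": scores.loc[members].mean(),
                    "replicate_mean": float(np.mean(rep_scores)),
                    "replicate_sd": float(np.std(rep_scores, ddof=1))
                    if len(rep_scores) > 1
                    else np.nan,
                }
            )
        group_df = pd.DataFrame(rows)
    return scores, group_df


def dose_slope(
    doses: np.ndarray,
    ratios: np.ndarray,
    sided: str = "less",
) -> tuple[float, float, float]:
    """Dose–response slope score from representation ratios.

    OLS slope of log10(representation ratio vs vehicle) on log10(dose) over
    nonzero doses (replicates are averaged per dose before calling this).
    The p-value is the one-sided Pearson-R significance in the direction of
    depletion by default (``sided='less'``).

    Returns (slope, R, p).
    """
    doses = np.asarray(doses, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    keep = doses > 0
    doses, ratios = doses[keep], ratios[keep]
    if doses.size < 3:
        raise ValidationError("need at least 3 nonzero doses")
    if (ratios <= 0).any():
        raise ValidationError("nonpositive representation ratio; check pseudocounts")
    x = np.log10(doses)
    y = np.log10(ratios)
    if np.ptp(x) == 0:
        raise ValidationError("doses have zero variance")
    slope, _ = np.polyfit(x, y, 1)
    if np.std(y) == 0:
        return float(slope), 0.0, 0.5 if sided != "two-sided" else 1.0
    res = scipy.stats.pearsonr(x, y, alternative=sided)
    return float(slope), float(res.statistic), float(res.pvalue)


def mutation_lasso(
    mm: MutationMatrix,
    scores: pd.Series,
    lambda_grid: np.ndarray | None = None,
    min_lines_per_mutation: int = 2,
    seed: int = 0,
) -> pd.Series:
    """Associate mutations with relative-survival scores by L1 regression.

    Covariates are mutation indicator columns present in at least
    ``min_lines_per_mutation`` lines; λ is chosen by leave-one-out
    cross-validation over the grid.  Returns the nonzero coefficients
    (negative = sensitizing).  A constant response yields an empty selection
    with a warning.
    """
    lines = [l for l in mm.line_ids if l in scores.index]
    if len(lines) < 5:
        raise ValidationError("need at least 5 lines with scores")
    X = mm.data.loc[lines]
    keep = X.sum(axis=0) >= min_lines_per_mutation
    X = X.loc[:, keep]
    y = scores.loc[lines].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValidationError("scores must be finite")
    if np.std(y) == 0 or X.shape[1] == 0:
        logger.warning("constant response or no usable covariates; empty selection")
        return pd.Series(dtype=float)
    alphas = lambda_grid if lambda_grid is not None else np.logspace(-3, 0.5, 30)
    model = LassoCV(
        alphas=alphas, cv=LeaveOneOut(), max_iter=50_000, random_state=seed
    )
    model.fit(X.to_numpy(dtype=float), y)
    coefs = pd.Series(model.coef_, index=X.columns)
    return coefs[coefs != 0]
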