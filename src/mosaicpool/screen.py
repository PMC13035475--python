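"""Pooled CRISPRi screen scoring.

Each guide's abundance shift between treated and vehicle arms is scored with
a binomial (logit) model weighted by total reads — equivalently a normalized
two-proportion z on guide count over library size.  Guide z scores are
rank-inverse-normal transformed, then combined per gene into a ρ score
(Stouffer: mean z · √k over k guides), with two-tailed normal p and BH q.
Protective/sensitizing annotation groups are tested with one-sample t
against 0, and whole screens compared by two-sample t on gene ρ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from mosaicpool.core import ValidationError

logger = logging.getLogger(__name__)


def guide_z(
    treated_counts: np.ndarray,
    vehicle_counts: np.ndarray,
    treated_libsize: float,
    vehicle_libsize: float,
) -> np.ndarray:
    """Per-guide enrichment z between treated and vehicle arms.

    Score test of the binomial logit model of per-read guide membership,
    weighted by total reads: the pooled two-proportion z on guide count over
    library size.  Sign + = enriched under treatment.
    """
    t = np.asarray(treated_counts, dtype=float)
    v = np.asarray(vehicle_counts, dtype=float)
    nt, nv = float(treated_libsize), float(vehicle_libsize)
    if nt <= 0 or nv <= 0:
        raise ValidationError("library sizes must be positive")
    p_t = t / nt
    p_v = v / nv
    pooled = (t + v) / (nt + nv)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / nt + 1.0 / nv))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (p_t - p_v) / se
    return np.where(se > 0, z, 0.0)


def guide_z_table(
    table: pd.DataFrame,
    treated_cols: list[str],
    vehicle_cols: list[str],
    lib_sizes: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Guide z for a count table (columns guide_id, gene, sample counts).

    Replicate counts are summed within each arm before scoring; library
    sizes default to column totals.  Guides absent everywhere are dropped
    with a warning.
    """
    lib = lib_sizes or {c: float(table[c].sum()) for c in treated_cols + vehicle_cols}
    t = table[treated_cols].sum(axis=1).to_numpy(dtype=float)
    v = table[vehicle_cols].sum(axis=1).to_numpy(dtype=float)
    present = (t + v) > 0
    if (~present).any():
        logger.warning("dropping %d guides with zero counts everywhere", (~present).sum())
    nt = sum(lib[c] for c in treated_cols)
    nv = sum(lib[c] for c in vehicle_cols)
    out = table.loc[present, ["guide_id", "gene"]].copy()
    out["z"] = guide_z(t[present], v[present], nt, nv)
    return out.reset_index(drop=True)


def normalize_z(z: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset), monotone in input.

    Deterministic stand-in for data-adaptive normalization: ties share the
    mean rank, and Φ⁻¹((r − 3/8)/(n + 1/4)) maps ranks to normal scores.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    if n < 10:
        raise ValidationError("need at least 10 guides to normalize")
    ranks = scipy.stats.rankdata(z, method="average")
    n_ties = n - len(np.unique(z))
    if n_ties > 0.5 * n:
        logger.warning("more than half of the z scores are tied")
    return scipy.stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))


@dataclass
class GeneRho:
    """Per-gene combined guide score and its significance."""

    table: pd.DataFrame  # gene, rho, p, q, n_guides, annotation


def gene_rho(
    guide_scores: pd.DataFrame,
    annotations: dict[str, str] | None = None,
    control_label: str = "control",
) -> GeneRho:
    """Combine normalized guide z into a per-gene ρ (Stouffer mean·√k).

    ``guide_scores`` needs columns gene and z (normalized).  ρ = mean(z)·√k
    over a gene's k guides; p is the two-tailed standard-normal tail; BH q
    across genes (non-targeting controls excluded from correction).
    Annotation maps gene → 'protective' / 'sensitizing'.
    """
    grouped = guide_scores.groupby("gene")["z"]
    rho = grouped.mean() * np.sqrt(grouped.size())
    p = 2.0 * scipy.stats.norm.sf(np.abs(rho))
    out = pd.DataFrame(
        {
            "gene": rho.index,
            "rho": rho.to_numpy(),
            "p": p,
            "n_guides": grouped.size().to_numpy(),
        }
    )
    genes = out["gene"] != control_label
    q = np.full(len(out), np.nan)
    q[genes.to_numpy()] = multipletests(out.loc[genes, "p"], method="fdr_bh")[1]
    out["q"] = q
    ann = annotations or {}
    out["annotation"] = [ann.get(g, "unannotated") for g in out["gene"]]
    return GeneRho(out.reset_index(drop=True))


def replicate_noise_scale(
    table: pd.DataFrame,
    treated_cols: list[str],
    vehicle_cols: list[str],
) -> float:
    """Null scale of the guide z estimated from replicate consistency.

    Per guide, z is recomputed on each matched (treated_i, vehicle_i)
    replicate pair; within-guide variance across pairs cancels the guide's
    true effect and measures technical noise only.  Because both the binomial
    term and the biological overdispersion scale as 1/m over m replicates,
    the per-pair z variance equals the null variance of the summed-arm z, so
    the mean within-guide variance across all guides estimates it without
    contamination from real effects.
    """
    m = min(len(treated_cols), len(vehicle_cols))
    if m < 2:
        raise ValidationError("need at least 2 replicate pairs")
    zs = []
    for t_col, v_col in zip(treated_cols[:m], vehicle_cols[:m]):
        zs.append(
            guide_z(
                table[t_col].to_numpy(),
                table[v_col].to_numpy(),
                float(table[t_col].sum()),
                float(table[v_col].sum()),
            )
        )
    zmat = np.column_stack(zs)
    var_within = zmat.var(axis=1, ddof=1)
    return float(np.sqrt(var_within.mean()))


def score_screen(
    table: pd.DataFrame,
    treated_cols: list[str],
    vehicle_cols: list[str],
    annotations: dict[str, str] | None = None,
    control_label: str = "control",
) -> GeneRho:
    """Full screen scoring: guide z → null-scale normalization → gene ρ → BH.

    Guide z scores are overdispersed relative to the binomial model, so they
    are standardized before aggregation.  With ≥2 replicate pairs the null
    scale comes from replicate consistency (:func:`replicate_noise_scale`),
    which is immune to contamination by true effects; otherwise scores are
    rank-inverse-normal transformed and re-scaled to the non-targeting
    controls' spread.
    """
    gz = guide_z_table(table, treated_cols, vehicle_cols)
    if min(len(treated_cols), len(vehicle_cols)) >= 2:
        scale = replicate_noise_scale(table, treated_cols, vehicle_cols)
        gz["z"] = gz["z"] / scale
    else:
        gz["z"] = normalize_z(gz["z"].to_numpy())
        ctrl = gz["gene"] == control_label
        if ctrl.sum() >= 10:
            mu = gz.loc[ctrl, "z"].mean()
            sd = gz.loc[ctrl, "z"].std(ddof=1)
            if sd > 0:
                gz["z"] = (gz["z"] - mu) / sd
    return gene_rho(gz, annotations=annotations, control_label=control_label)


def rho_group_test(
    result: GeneRho,
    groups: dict[str, list[str]],
    other: GeneRho | None = None,
) -> pd.DataFrame:
    """Annotation-group tests on gene ρ.

    Per group: two-tailed one-sample t of member ρ against 0.  With a second
    screen (``other``), also a two-sample t of the group's ρ between screens.
    Groups smaller than 3 report the mean but withhold the p.
    """
    tab = result.table.set_index("gene")
    rows = []
    for name, members in groups.items():
        members = [g for g in members if g in tab.index]
        if not members:
            raise ValidationError(f"group {name!r} has no scored genes")
        vals = tab.loc[members, "rho"].to_numpy()
        row = {"group": name, "n": len(vals), "mean_rho": float(vals.mean())}
        if len(vals) >= 3:
            row["p"] = float(scipy.stats.ttest_1samp(vals, 0.0).pvalue)
        else:
            row["p"] = np.nan
        if other is not None:
            other_tab = other.table.set_index("gene")
            shared = [g for g in members if g in other_tab.index]
            if len(shared) >= 3:
                res = scipy.stats.ttest_ind(
                    tab.loc[shared, "rho"], other_tab.loc[shared, "rho"]
                )
                row["cross_p"] = float(res.pvalue)
                row["cross_delta"] = float(
                    tab.loc[shared, "rho"].mean() - other_tab.loc[shared, "rho"].mean()
                )
        rows.append(row)
    return pd.DataFrame(rows)
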