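"""Synthetic pooled experiments with known ground truth.

Emulates the structure of a pooled multi-line drug-response study: several
cell lines mixed in one pool, split into hashed vehicle/drug samples at one
or more doses with replicates, profiled by scRNA-seq.  Line representation
per sample follows a multinomial whose weights combine the baseline pool
weight, exponential growth and a Hill-form survival fraction at the sample's
dose.  Gene counts are negative binomial around per-line expression profiles
with planted log2 expression programs in treated survivors; doublets sum two
cells' counts; apoptotic cells get depressed totals and inflated
mitochondrial share so they cross the QC thresholds.  Per-cell SNP allele
reads and dual-guide screen counts are generated from the same ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from mosaicpool.core import (
    CellAlleleCounts,
    GenotypeReference,
    PooledExperiment,
    ValidationError,
)


@dataclass
class LineSpec:
    """One cell line: growth rate (per hour), pool weight, dose response.

    Survival under dose d follows a Hill curve:
    ``1 − max_kill · d^h / (d^h + IC50^h)`` with IC50 = 10**log10_ic50.
    """

    line_id: str
    growth_rate: float = 0.02
    baseline_weight: float = 1.0
    max_kill: float = 0.0
    log10_ic50: float = 0.0
    hill: float = 1.0

    def survival_fraction(self, dose: float) -> float:
        if dose <= 0:
            return 1.0
        ic50 = 10.0 ** self.log10_ic50
        frac = dose**self.hill / (dose**self.hill + ic50**self.hill)
        return 1.0 - self.max_kill * frac


@dataclass
class ProgramSpec:
    """A planted expression program: log2 shift in treated survivors of given lines."""

    name: str
    genes: list[str]
    log2_shift: float
    lines: list[str] | None = None  # None = all lines


@dataclass
class ConditionSpec:
    label: str
    dose: float
    n_replicates: int = 1


@dataclass
class SimConfig:
    """Full description of a simulated pooled experiment."""

    lines: list[LineSpec]
    conditions: list[ConditionSpec]
    n_genes: int = 500
    n_mito_genes: int = 13
    pool_size: int = 1000
    programs: list[ProgramSpec] = field(default_factory=list)
    nb_dispersion: float = 0.3
    libsize_log_mean: float = np.log(4000.0)
    libsize_log_sd: float = 0.3
    doublet_rate: float = 0.0
    hash_error_rate: float = 0.0
    apoptotic_rate: float = 0.0
    apoptotic_count_multiplier: float = 0.25
    allele_depth_mean: float = 60.0
    allele_error: float = 0.01
    heterogeneity_fraction: float = 1.0
    growth_hours: float = 144.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lines:
            raise ValidationError("at least one line is required")
        for rate in (
            self.doublet_rate,
            self.hash_error_rate,
            self.apoptotic_rate,
        ):
            if not 0 <= rate < 1:
                raise ValidationError("rates must be in [0, 1)")
        if any(l.baseline_weight <= 0 for l in self.lines):
            raise ValidationError("pool weights must be positive")

    @property
    def line_ids(self) -> list[str]:
        return [l.line_id for l in self.lines]

    def gene_symbols(self) -> list[str]:
        mito = [f"MT-G{i + 1}" for i in range(self.n_mito_genes)]
        rest = [f"GENE{i + 1:05d}" for i in range(self.n_genes - self.n_mito_genes)]
        return mito + rest


@dataclass
class GroundTruth:
    """Per-cell and per-line truth behind a simulated experiment."""

    cell_line: np.ndarray  # true line per droplet
    cell_hash: np.ndarray  # true sample id per droplet
    doublet_partner: np.ndarray  # partner line id or "" for singlets
    cell_program: np.ndarray  # planted program name or "" per droplet
    apoptotic: np.ndarray  # bool per droplet
    survival: pd.DataFrame  # line × dose true survival fraction
    program_shifts: pd.DataFrame  # gene, program, log2_shift
    guide_effects: pd.DataFrame | None = None

    @property
    def is_doublet(self) -> np.ndarray:
        return self.doublet_partner != ""


def _expression_profiles(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-line relative expression profiles (lines × genes, rows sum to 1)."""
    n_lines = len(config.lines)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    # modest line-to-line variation around a shared baseline
    line_fac = rng.lognormal(mean=0.0, sigma=0.25, size=(n_lines, config.n_genes))
    prof = base[None, :] * line_fac
    return prof / prof.sum(axis=1, keepdims=True)


def simulate_pool(config: SimConfig) -> tuple[PooledExperiment, GroundTruth]:
    """Simulate one pooled experiment with ground truth.

    Per sample (condition × replicate), cell counts per line are multinomial
    with weights ∝ baseline_weight · exp(r · t_growth) · survival(dose).
    Identical seeds give identical output.
    """
    rng = np.random.default_rng(config.seed)
    symbols = config.gene_symbols()
    n_genes = config.n_genes
    mito_idx = np.arange(config.n_mito_genes)
    profiles = _expression_profiles(config, rng)
    line_ids = config.line_ids
    line_lookup = {lid: i for i, lid in enumerate(line_ids)}

    # program shift multipliers per (line, gene), applied in treated survivors
    prog_mult = np.ones((len(line_ids), n_genes))
    prog_of_line: dict[int, str] = {}
    shift_rows = []
    sym_index = pd.Index(symbols)
    for prog in config.programs:
        gidx = sym_index.get_indexer(prog.genes)
        if (gidx < 0).any():
            raise ValidationError(f"program {prog.name} references unknown genes")
        targets = prog.lines if prog.lines is not None else line_ids
        for lid in targets:
            prog_mult[line_lookup[lid], gidx] *= 2.0**prog.log2_shift
            prog_of_line[line_lookup[lid]] = prog.name
        for g in prog.genes:
            shift_rows.append(
                {"gene": g, "program": prog.name, "log2_shift": prog.log2_shift}
            )

    sample_ids = []
    all_line, all_hash, all_partner, all_prog, all_apop = [], [], [], [], []
    meta_rows = []
    blocks = []
    doses = sorted({c.dose for c in config.conditions})
    survival = pd.DataFrame(
        {d: [l.survival_fraction(d) for l in config.lines] for d in doses},
        index=line_ids,
    )

    weights_growth = np.array(
        [
            l.baseline_weight * np.exp(l.growth_rate * config.growth_hours)
            for l in config.lines
        ]
    )

    for cond in config.conditions:
        surv = np.array([l.survival_fraction(cond.dose) for l in config.lines])
        w = weights_growth * surv
        w = w / w.sum()
        for rep in range(cond.n_replicates):
            sample = f"{cond.label}_r{rep + 1}"
            sample_ids.append(sample)
            n_cells = config.pool_size
            per_line = rng.multinomial(n_cells, w)
            cell_line_idx = np.repeat(np.arange(len(line_ids)), per_line)
            rng.shuffle(cell_line_idx)

            treated = cond.dose > 0
            # which cells express their line's planted program
            has_prog = np.zeros(n_cells, dtype=bool)
            if treated:
                in_prog_line = np.array(
                    [i in prog_of_line for i in cell_line_idx]
                )
                has_prog = in_prog_line & (
                    rng.random(n_cells) < config.heterogeneity_fraction
                )

            mean_prof = profiles[cell_line_idx].copy()
            if has_prog.any():
                idx = np.flatnonzero(has_prog)
                mult = prog_mult[cell_line_idx[idx]]
                prog_mask = mult != 1.0
                # compositional correction: boost program genes so their fold
                # change in *normalized* expression equals the planted 2^shift
                # (profiles sum to 1, so an uncorrected multiplier is damped
                # by the program's expression share)
                share = np.where(prog_mask, mean_prof[idx], 0.0).sum(axis=1)
                share_f = np.where(prog_mask, mean_prof[idx] * mult, 0.0).sum(axis=1)
                k = np.where(share_f < 1.0, (1.0 - share) / (1.0 - share_f), 1.0)
                mean_prof[idx] *= np.where(prog_mask, mult * k[:, None], 1.0)
            mean_prof /= mean_prof.sum(axis=1, keepdims=True)

            libsize = rng.lognormal(
                config.libsize_log_mean, config.libsize_log_sd, size=n_cells
            )
            apop = rng.random(n_cells) < config.apoptotic_rate
            if apop.any():
                libsize[apop] *= config.apoptotic_count_multiplier
                # inflate mitochondrial share past the QC threshold
                mito_share = mean_prof[apop][:, mito_idx].sum(axis=1)
                boost = np.maximum(0.35 / np.maximum(mito_share, 1e-9), 1.0)
                mean_prof[np.ix_(np.flatnonzero(apop), mito_idx)] *= boost[:, None]
                mean_prof /= mean_prof.sum(axis=1, keepdims=True)

            mu = mean_prof * libsize[:, None]
            counts = _nb_sample(rng, mu, config.nb_dispersion)

            partner = np.array([""] * n_cells, dtype=object)
            if config.doublet_rate > 0:
                n_doub = rng.binomial(n_cells, config.doublet_rate)
                if n_doub:
                    hosts = rng.choice(n_cells, size=n_doub, replace=False)
                    # partner drawn from a different line: a same-line doublet
                    # is genotypically a singlet, not an α = 0.5 mixture
                    if len(line_ids) > 1:
                        partner_line = (
                            cell_line_idx[hosts]
                            + rng.integers(1, len(line_ids), size=n_doub)
                        ) % len(line_ids)
                    else:
                        partner_line = cell_line_idx[hosts]
                    p_prof = profiles[partner_line]
                    p_lib = rng.lognormal(
                        config.libsize_log_mean, config.libsize_log_sd, size=n_doub
                    )
                    p_counts = _nb_sample(
                        rng, p_prof * p_lib[:, None], config.nb_dispersion
                    )
                    counts[hosts] += p_counts
                    partner[hosts] = [line_ids[i] for i in partner_line]

            hash_true = np.array([sample] * n_cells, dtype=object)
            blocks.append(sp.csr_matrix(counts))
            all_line.append(np.array([line_ids[i] for i in cell_line_idx], dtype=object))
            all_hash.append(hash_true)
            all_partner.append(partner)
            prog_names = np.where(
                has_prog,
                [prog_of_line.get(i, "") for i in cell_line_idx],
                "",
            )
            all_prog.append(prog_names.astype(object))
            all_apop.append(apop)
            # meta carries the true labels; demux recovers them from evidence
            for i in range(n_cells):
                meta_rows.append(
                    {
                        "barcode": f"{sample}-BC{i + 1:06d}",
                        "line_id": line_ids[cell_line_idx[i]],
                        "condition": cond.label,
                        "dose": cond.dose,
                        "replicate": f"r{rep + 1}",
                        "hash_id": sample,
                        "doublet_flag": bool(partner[i]),
                        "apoptotic_flag": bool(apop[i]),
                    }
                )

    counts_all = sp.vstack(blocks).tocsr()
    cell_meta = pd.DataFrame(meta_rows)
    gene_meta = pd.DataFrame({"symbol": symbols})
    exp = PooledExperiment(counts_all, cell_meta, gene_meta)
    truth = GroundTruth(
        cell_line=np.concatenate(all_line),
        cell_hash=np.concatenate(all_hash),
        doublet_partner=np.concatenate(all_partner),
        cell_program=np.concatenate(all_prog),
        apoptotic=np.concatenate(all_apop),
        survival=survival,
        program_shifts=pd.DataFrame(
            shift_rows, columns=["gene", "program", "log2_shift"]
        ),
    )
    return exp, truth


def _nb_sample(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + dispersion·mu²."""
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    lam = rng.gamma(shape=r, scale=np.maximum(mu, 1e-12) / r)
    return rng.poisson(lam)


def simulate_hash_counts(
    exp: PooledExperiment,
    truth: GroundTruth,
    signal_mean: float = 200.0,
    background_mean: float = 2.0,
    doublet_second_hash: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Hashtag-count matrix (cells × samples) consistent with the truth.

    Each cell gets Poisson signal on its own sample channel and Poisson
    background elsewhere; doublets optionally carry a second channel's signal.
    """
    rng = np.random.default_rng(seed)
    samples = list(pd.unique(truth.cell_hash))
    n = exp.n_cells
    counts = rng.poisson(background_mean, size=(n, len(samples)))
    own = pd.Index(samples).get_indexer(truth.cell_hash)
    counts[np.arange(n), own] += rng.poisson(signal_mean, size=n)
    if doublet_second_hash:
        doub = np.flatnonzero(truth.is_doublet)
        if doub.size:
            other = rng.integers(0, len(samples), size=doub.size)
            counts[doub, other] += rng.poisson(signal_mean, size=doub.size)
    return pd.DataFrame(counts, index=exp.barcodes, columns=samples)


def random_genotype_reference(
    line_ids: list[str],
    n_variants: int,
    seed: int = 0,
    het_fraction: float = 0.3,
) -> GenotypeReference:
    """Random biallelic-SNP dosage reference for the given lines."""
    rng = np.random.default_rng(seed)
    p_hom = (1.0 - het_fraction) / 2.0
    dosage = rng.choice(
        [0.0, 0.5, 1.0],
        size=(len(line_ids), n_variants),
        p=[p_hom, het_fraction, p_hom],
    )
    variant_ids = [f"chr1:{1000 + 10 * i}:A:G" for i in range(n_variants)]
    return GenotypeReference(list(line_ids), variant_ids, dosage)


def simulate_allele_counts(
    exp: PooledExperiment,
    truth: GroundTruth,
    reference: GenotypeReference,
    depth: float = 60.0,
    epsilon: float = 0.01,
    seed: int = 0,
) -> CellAlleleCounts:
    """Per-cell SNP ref/alt read counts given true line identities.

    ``depth`` is the mean total allele-informative reads per cell, spread
    uniformly over variants; per covered variant, alt reads are binomial with
    success probability (1−ε)·d + ε·(1−d) where d is the line's alt dosage.
    Doublets draw from the equal (α = 0.5) mixture of both lines' dosages.
    """
    rng = np.random.default_rng(seed)
    missing = set(truth.cell_line) - set(reference.line_ids)
    missing |= set(truth.doublet_partner[truth.is_doublet]) - set(reference.line_ids)
    if missing:
        raise ValidationError(f"lines not in reference: {sorted(missing)}")
    n_cells = exp.n_cells
    n_var = reference.n_variants
    line_idx = pd.Index(reference.line_ids).get_indexer(truth.cell_line)
    d_eff = reference.dosage[line_idx].astype(float)
    doub = truth.is_doublet
    if doub.any():
        partner_idx = pd.Index(reference.line_ids).get_indexer(
            truth.doublet_partner[doub]
        )
        d_eff[doub] = 0.5 * (d_eff[doub] + reference.dosage[partner_idx])

    n_reads = rng.poisson(depth, size=n_cells)
    rows, cols, refs, alts = [], [], [], []
    for i in range(n_cells):
        if n_reads[i] == 0:
            continue
        var = rng.integers(0, n_var, size=n_reads[i])
        uniq, cnt = np.unique(var, return_counts=True)
        d = d_eff[i, uniq]
        covered = ~np.isnan(d)
        uniq, cnt, d = uniq[covered], cnt[covered], d[covered]
        if uniq.size == 0:
            continue
        p = (1 - epsilon) * d + epsilon * (1 - d)
        alt = rng.binomial(cnt, p)
        rows.append(np.full(uniq.size, i))
        cols.append(uniq)
        refs.append(cnt - alt)
        alts.append(alt)
    if rows:
        rows_a = np.concatenate(rows)
        cols_a = np.concatenate(cols)
        ref_m = sp.coo_matrix(
            (np.concatenate(refs), (rows_a, cols_a)), shape=(n_cells, n_var)
        )
        alt_m = sp.coo_matrix(
            (np.concatenate(alts), (rows_a, cols_a)), shape=(n_cells, n_var)
        )
    else:
        ref_m = sp.coo_matrix((n_cells, n_var))
        alt_m = sp.coo_matrix((n_cells, n_var))
    return CellAlleleCounts(
        list(exp.barcodes), list(reference.variant_ids), ref_m.tocsr(), alt_m.tocsr()
    )


def simulate_cluster_labels(
    n_cells: int,
    n_clusters: int,
    treated_fraction: float = 0.5,
    confined_cluster: int | None = None,
    confinement: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster and condition labels for heterogeneity-statistic tests.

    Under the null, cluster and condition are independent.  With
    ``confined_cluster`` set, a ``confinement`` fraction of treated cells is
    forced into that cluster, emulating subpopulation-restricted survival.
    """
    rng = np.random.default_rng(seed)
    clusters = rng.integers(0, n_clusters, size=n_cells)
    treated = rng.random(n_cells) < treated_fraction
    if confined_cluster is not None:
        move = treated & (rng.random(n_cells) < confinement)
        clusters[move] = confined_cluster
    return clusters, treated


def simulate_combo_pseudobulk(
    n_genes: int = 2000,
    n_lines: int = 4,
    n_replicates: int = 2,
    interaction_genes: int = 50,
    interaction_log2: float = -2.0,
    effect_sd: float = 0.3,
    depth: float = 2e5,
    dispersion: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pseudobulk counts for a two-drug combination design with planted interaction.

    Samples cover lines × {vehicle, drugA, drugB, combo} × replicates.  Every
    gene gets small random single-agent log2 effects (SD ``effect_sd``); the
    combo response is additive (log-scale) except for ``interaction_genes``
    genes whose combo term deviates by ``interaction_log2``.

    Returns (counts genes × samples, sample metadata, truth table with
    per-gene interaction sizes).
    """
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    base = rng.lognormal(0.0, 1.0, size=n_genes)
    base = base / base.sum()
    eff_a = rng.normal(0.0, effect_sd, size=n_genes)
    eff_b = rng.normal(0.0, effect_sd, size=n_genes)
    interaction = np.zeros(n_genes)
    planted = rng.choice(n_genes, size=interaction_genes, replace=False)
    interaction[planted] = interaction_log2
    line_fac = rng.lognormal(0.0, 0.2, size=(n_lines, n_genes))

    cols, meta_rows = [], []
    conditions = {
        "vehicle": (0.0, 0.0, 0.0),
        "drugA": (1.0, 0.0, 0.0),
        "drugB": (0.0, 1.0, 0.0),
        "combo": (1.0, 1.0, 1.0),
    }
    for li in range(n_lines):
        for cond, (a, b, ab) in conditions.items():
            for r in range(n_replicates):
                log2fc = a * eff_a + b * eff_b + ab * interaction
                prof = base * line_fac[li] * 2.0**log2fc
                prof = prof / prof.sum()
                lib = depth * rng.lognormal(0.0, 0.1)
                cols.append(_nb_sample(rng, prof * lib, dispersion))
                meta_rows.append(
                    {
                        "line_id": f"L{li + 1}",
                        "condition": cond,
                        "replicate": f"r{r + 1}",
                        "sample": f"L{li + 1}_{cond}_r{r + 1}",
                    }
                )
    sample_meta = pd.DataFrame(meta_rows)
    counts = pd.DataFrame(
        np.column_stack(cols), index=genes, columns=sample_meta["sample"]
    )
    truth = pd.DataFrame({"gene": genes, "interaction_log2": interaction})
    return counts, sample_meta, truth


def simulate_guide_screen(
    n_genes: int,
    guides_per_gene: int,
    planted_effects: dict[str, float] | None = None,
    n_treated_reps: int = 2,
    n_vehicle_reps: int = 2,
    lib_size: float = 1e6,
    n_controls: int = 50,
    dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a pooled guide screen count table with planted gene effects.

    Vehicle counts are negative binomial around library proportions; treated
    counts multiply the proportion by 2**effect for guides of affected genes.
    Non-targeting controls (gene label ``control``) have effect 0.

    Returns (guide table, truth table).  The guide table has columns
    guide_id, gene, treated_1..n, vehicle_1..n.
    """
    if guides_per_gene < 1:
        raise ValidationError("guides_per_gene must be >= 1")
    if lib_size <= 0:
        raise ValidationError("library size must be positive")
    rng = np.random.default_rng(seed)
    planted_effects = planted_effects or {}
    genes = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    guide_ids, guide_gene = [], []
    for g in genes:
        for j in range(guides_per_gene):
            guide_ids.append(f"{g}_g{j + 1}")
            guide_gene.append(g)
    for j in range(n_controls):
        guide_ids.append(f"NTC_g{j + 1}")
        guide_gene.append("control")
    n_guides = len(guide_ids)
    base = rng.lognormal(0.0, 0.5, size=n_guides)
    prop_v = base / base.sum()
    effect = np.array([planted_effects.get(g, 0.0) for g in guide_gene])
    prop_t = prop_v * 2.0**effect
    prop_t = prop_t / prop_t.sum()

    table = pd.DataFrame({"guide_id": guide_ids, "gene": guide_gene})
    for r in range(n_vehicle_reps):
        table[f"vehicle_{r + 1}"] = _nb_sample(
            rng, prop_v * lib_size, dispersion
        )
    for r in range(n_treated_reps):
        table[f"treated_{r + 1}"] = _nb_sample(
            rng, prop_t * lib_size, dispersion
        )
    truth = pd.DataFrame(
        {
            "gene": genes + ["control"],
            "log2_effect": [planted_effects.get(g, 0.0) for g in genes] + [0.0],
        }
    )
    return table, truth
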