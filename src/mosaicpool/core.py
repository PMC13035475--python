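"""Domain types and I/O for pooled single-cell drug-response experiments.

The central container is :class:`PooledExperiment` — a sparse cell × gene UMI
count matrix with per-cell labels (line of origin, treatment condition, dose,
replicate, hashtag, doublet/apoptotic flags, cell-cycle phase) and per-gene
annotation (mitochondrial flags, geneset memberships).  Genotype references
and per-cell allele evidence feed the demultiplexing stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

CELL_META_COLUMNS = [
    "barcode",
    "line_id",
    "condition",
    "dose",
    "replicate",
    "hash_id",
    "doublet_flag",
    "apoptotic_flag",
    "phase",
]

UNASSIGNED = "unassigned"


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class PooledExperiment:
    """Cell × gene UMI counts plus per-cell and per-gene annotation.

    Parameters
    ----------
    counts
        Sparse (CSR) nonnegative integer matrix, cells in rows.
    cell_meta
        One row per cell; must contain the columns in
        :data:`CELL_META_COLUMNS` (missing ones are filled with defaults).
        ``barcode`` values must be unique.
    gene_meta
        One row per gene with at least ``symbol``; ``is_mito_encoded`` /
        ``is_mito_resident`` are derived from the symbol prefix ``MT-``
        (case-insensitive) when absent.
    genesets
        Named gene-symbol sets (e.g. cell-cycle or pathway annotations).
        Every named set must be nonempty.
    """

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    genesets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts must be nonnegative")
        n_cells, n_genes = self.counts.shape
        if len(self.cell_meta) != n_cells:
            raise ValidationError(
                f"cell_meta has {len(self.cell_meta)} rows for {n_cells} cells"
            )
        if len(self.gene_meta) != n_genes:
            raise ValidationError(
                f"gene_meta has {len(self.gene_meta)} rows for {n_genes} genes"
            )
        self.cell_meta = self.cell_meta.reset_index(drop=True).copy()
        self.gene_meta = self.gene_meta.reset_index(drop=True).copy()
        defaults = {
            "line_id": UNASSIGNED,
            "condition": "",
            "dose": 0.0,
            "replicate": "",
            "hash_id": UNASSIGNED,
            "doublet_flag": False,
            "apoptotic_flag": False,
            "phase": "unset",
        }
        for col, default in defaults.items():
            if col not in self.cell_meta:
                self.cell_meta[col] = default
        if "barcode" not in self.cell_meta:
            raise ValidationError("cell_meta must contain a 'barcode' column")
        if self.cell_meta["barcode"].duplicated().any():
            raise ValidationError("cell barcodes must be unique")
        if "symbol" not in self.gene_meta:
            raise ValidationError("gene_meta must contain a 'symbol' column")
        if "is_mito_encoded" not in self.gene_meta:
            self.gene_meta["is_mito_encoded"] = mito_flags_from_symbols(
                self.gene_meta["symbol"]
            )
        if "is_mito_resident" not in self.gene_meta:
            self.gene_meta["is_mito_resident"] = self.gene_meta["is_mito_encoded"]
        for name, members in self.genesets.items():
            if not members:
                raise ValidationError(f"geneset {name!r} is empty")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def barcodes(self) -> np.ndarray:
        return self.cell_meta["barcode"].to_numpy()

    @property
    def symbols(self) -> np.ndarray:
        return self.gene_meta["symbol"].to_numpy()

    def gene_index(self, symbols) -> np.ndarray:
        """Positions of ``symbols`` in the gene universe (missing → error)."""
        lookup = pd.Index(self.gene_meta["symbol"])
        idx = lookup.get_indexer(list(symbols))
        if (idx < 0).any():
            missing = [s for s, i in zip(symbols, idx) if i < 0]
            raise ValidationError(f"symbols not in gene universe: {missing[:5]}")
        return idx

    def subset_cells(self, mask) -> "PooledExperiment":
        mask = np.asarray(mask)
        return PooledExperiment(
            counts=self.counts[mask],
            cell_meta=self.cell_meta.loc[mask].reset_index(drop=True),
            gene_meta=self.gene_meta,
            genesets=self.genesets,
        )

    def to_anndata(self):
        """View as an :class:`anndata.AnnData` (cells × genes)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=self.cell_meta.set_index("barcode"),
            var=self.gene_meta.set_index("symbol"),
        )
        return adata


def mito_flags_from_symbols(symbols) -> np.ndarray:
    """Mitochondria-encoded flag from the conventional ``MT-`` symbol prefix."""
    return np.array([str(s).upper().startswith("MT-") for s in symbols])


@dataclass
class GenotypeReference:
    """Per-line alt-allele dosage at biallelic SNPs.

    ``dosage`` is lines × variants with values in {0, 0.5, 1} and NaN for
    uncalled genotypes.
    """

    line_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if len(self.line_ids) < 2:
            raise ValidationError("need at least 2 lines")
        if len(self.variant_ids) < 1:
            raise ValidationError("need at least 1 variant")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValidationError("variant ids must be unique")
        if self.dosage.shape != (len(self.line_ids), len(self.variant_ids)):
            raise ValidationError("dosage shape mismatch")
        vals = self.dosage[~np.isnan(self.dosage)]
        if not np.isin(vals, [0.0, 0.5, 1.0]).all():
            raise ValidationError("dosage values must be in {0, 0.5, 1, NaN}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def line_index(self, line_id: str) -> int:
        return self.line_ids.index(line_id)


@dataclass
class CellAlleleCounts:
    """Per-cell ref/alt read counts at reference variants.

    Stored as two sparse cells × variants matrices aligned to a
    :class:`GenotypeReference` variant order.
    """

    barcodes: list[str]
    variant_ids: list[str]
    ref: sp.csr_matrix
    alt: sp.csr_matrix

    def __post_init__(self) -> None:
        self.ref = sp.csr_matrix(self.ref)
        self.alt = sp.csr_matrix(self.alt)
        shape = (len(self.barcodes), len(self.variant_ids))
        if self.ref.shape != shape or self.alt.shape != shape:
            raise ValidationError("ref/alt matrices must be cells × variants")
        for mat in (self.ref, self.alt):
            if mat.nnz and mat.data.min() < 0:
                raise ValidationError("allele counts must be nonnegative")

    @classmethod
    def from_long(
        cls, df: pd.DataFrame, reference: GenotypeReference
    ) -> "CellAlleleCounts":
        """Build from a long table with columns barcode, variant_id, ref_reads, alt_reads."""
        unknown = set(df["variant_id"]) - set(reference.variant_ids)
        if unknown:
            raise ValidationError(f"variants not in reference: {sorted(unknown)[:5]}")
        barcodes = list(pd.unique(df["barcode"]))
        bc_idx = pd.Index(barcodes).get_indexer(df["barcode"])
        var_idx = pd.Index(reference.variant_ids).get_indexer(df["variant_id"])
        shape = (len(barcodes), reference.n_variants)
        ref = sp.coo_matrix((df["ref_reads"], (bc_idx, var_idx)), shape=shape)
        alt = sp.coo_matrix((df["alt_reads"], (bc_idx, var_idx)), shape=shape)
        return cls(barcodes, list(reference.variant_ids), ref.tocsr(), alt.tocsr())

    def to_long(self) -> pd.DataFrame:
        tot = (self.ref + self.alt).tocoo()
        ref = np.asarray(self.ref.tocsr()[tot.row, tot.col]).ravel()
        alt = np.asarray(self.alt.tocsr()[tot.row, tot.col]).ravel()
        return pd.DataFrame(
            {
                "barcode": np.asarray(self.barcodes, dtype=object)[tot.row],
                "variant_id": np.asarray(self.variant_ids, dtype=object)[tot.col],
                "ref_reads": ref.astype(int),
                "alt_reads": alt.astype(int),
            }
        )


@dataclass
class QCThresholds:
    """Apoptotic-cell flagging thresholds.

    Defaults: fewer than 1,000 detected genes, fewer than 2,000 total UMIs,
    or mitochondria-encoded fraction above 0.15 flags the cell.
    """

    min_genes: int = 1000
    min_counts: int = 2000
    max_mito_frac: float = 0.15

    def __post_init__(self) -> None:
        if self.min_genes <= 0 or self.min_counts <= 0:
            raise ValidationError("thresholds must be positive")
        if not 0 < self.max_mito_frac < 1:
            raise ValidationError("max_mito_frac must be in (0, 1)")


@dataclass
class MutationMatrix:
    """Binary lines × mutations incidence matrix (e.g. KRAS_G12C, BRAF_V600E)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if not np.isin(vals, [0, 1]).all():
            raise ValidationError("mutation matrix must be binary")

    @property
    def line_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def mutations(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# Readers / writers


def read_genotype_reference(path: str | Path) -> GenotypeReference:
    """Read per-line genotypes from a VCF into alt-allele dosages.

    Genotypes 0/0, 0/1 and 1/1 map to dosages 0, 0.5 and 1; uncalled (./.)
    maps to missing (NaN).  Multiallelic records and indels are skipped with a
    warning — the downstream assignment model uses biallelic SNPs only.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValidationError("VCF contains no sample columns")
    variant_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        vid = f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        if vid in set(variant_ids):
            raise ValidationError(f"duplicate variant id {vid}")
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(rec.gt_types, dtype=float)
        dosage = np.select(
            [gt == 0, gt == 1, gt == 3], [0.0, 0.5, 1.0], default=np.nan
        )
        variant_ids.append(vid)
        rows.append(dosage)
    if n_skipped:
        logger.warning("skipped %d multiallelic/indel records", n_skipped)
    if not variant_ids:
        raise ValidationError("no usable biallelic SNPs in VCF")
    dosage = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    return GenotypeReference(samples, variant_ids, dosage)


def read_counts(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
    cell_meta_path: str | Path | None = None,
    cells_in_columns: bool = True,
    genesets: dict[str, set[str]] | None = None,
) -> PooledExperiment:
    """Read a MatrixMarket triplet count matrix with barcode/feature lists.

    By the common triplet convention the matrix stores cells in columns
    (genes × cells); set ``cells_in_columns=False`` if rows are cells.
    Mitochondrial flags are derived from the ``MT-`` symbol prefix unless the
    features file carries explicit ``is_mito_encoded`` / ``is_mito_resident``
    columns.
    """
    mat = scipy.io.mmread(str(matrix_path))
    if cells_in_columns:
        mat = mat.T
    mat = sp.csr_matrix(mat)
    if mat.nnz and mat.data.min() < 0:
        raise ValidationError("count matrix has negative entries")
    barcodes = pd.read_csv(barcodes_path, header=None, sep="\t")[0].astype(str)
    features = pd.read_csv(features_path, header=None, sep="\t")
    if len(barcodes) != mat.shape[0]:
        raise ValidationError(
            f"{len(barcodes)} barcodes for {mat.shape[0]} cells in matrix"
        )
    if len(features) != mat.shape[1]:
        raise ValidationError(
            f"{len(features)} features for {mat.shape[1]} genes in matrix"
        )
    gene_meta = pd.DataFrame({"symbol": features.iloc[:, -1].astype(str)})
    cell_meta = pd.DataFrame({"barcode": barcodes})
    if cell_meta_path is not None:
        extra = pd.read_csv(cell_meta_path)
        cell_meta = cell_meta.merge(extra, on="barcode", how="left")
    return PooledExperiment(mat, cell_meta, gene_meta, genesets=genesets or {})


def write_results_tables(
    tables: dict[str, pd.DataFrame], out_dir: str | Path
) -> list[Path]:
    """Write named result tables as TSV files with a header row.

    Deterministic: rewriting the same objects yields byte-identical files.
    Empty tables produce header-only files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
        written.append(path)
    return written
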