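"""Cohort input/output: expression, clinical and mutation tables.

The pipeline's native expression scale is log2-TPM (genes x samples). Raw
RNA-seq counts are supported through :func:`tpm_normalize` followed by
:func:`log2_transform`. Clinical tables carry RECIST response categories
(CR/PR/SD/PD), overall-survival follow-up, and the optional immunogenomic
covariates (PD-L1 level, immune phenotype, TMB) used by the composite score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD")
RESPONDER_CATEGORIES = ("CR", "PR")
PDL1_LEVELS = ("low", "high")
IMMUNE_PHENOTYPES = ("desert", "excluded", "inflamed")

OPTIONAL_CLINICAL_FIELDS = ("pdl1_level", "immune_phenotype", "tmb")


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values on the log2-TPM scale.

    Invariants checked at construction: unique gene/sample identifiers,
    finite values, shape consistency.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in expression matrix: {missing[:10]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(self.values[rows], list(genes), list(self.sample_ids))

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples not in expression matrix: {missing[:10]}")
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(self.values[:, cols], list(self.gene_ids), list(sample_ids))

    def sample_profile(self, gene: str) -> np.ndarray:
        """Expression of one gene across samples."""
        try:
            row = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in expression matrix") from None
        return self.values[row]

    def write_csv(self, path: str | Path, sep: str = ",") -> None:
        df = self.to_dataframe()
        df.index.name = "gene"
        # repr round-trips float64 exactly
        df.to_csv(path, sep=sep, float_format=None)


def read_expression(path: str | Path, sep: str | None = None, transpose: bool = False) -> ExpressionMatrix:
    """Read an expression matrix from CSV/TSV.

    Layout is genes as rows with a header of sample ids and gene symbols in
    the first column; ``transpose=True`` accepts the samples-as-rows layout.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if transpose:
        df = df.T
    if df.isna().any().any():
        raise ValueError(f"missing values in expression file {path}")
    return ExpressionMatrix.from_dataframe(df)


def read_expression_mtx(
    mtx_path: str | Path, genes_path: str | Path, samples_path: str | Path
) -> ExpressionMatrix:
    """Read a MatrixMarket triplet file with side files of gene/sample ids."""
    mat = np.asarray(mmread(str(mtx_path)).todense(), dtype=float)
    genes = [line.strip() for line in Path(genes_path).read_text().splitlines() if line.strip()]
    samples = [line.strip() for line in Path(samples_path).read_text().splitlines() if line.strip()]
    return ExpressionMatrix(mat, genes, samples)


def tpm_normalize(counts: np.ndarray, lengths: np.ndarray, sample_ids: list[str] | None = None) -> np.ndarray:
    """Length-adjusted TPM normalisation of a genes x samples count matrix.

    TPM_gi = (count_gi / length_g) / sum_h (count_hi / length_h) * 1e6,
    with gene lengths in bases. Every output column sums to 1e6.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D genes x samples matrix")
    if lengths.shape != (counts.shape[0],):
        raise ValueError("lengths must have one entry per gene")
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be strictly positive")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    rate = counts / lengths[:, None]
    colsum = rate.sum(axis=0)
    zero = np.flatnonzero(colsum == 0)
    if zero.size:
        names = [sample_ids[i] if sample_ids else str(i) for i in zero[:5]]
        raise ValueError(f"samples with zero total counts: {names}")
    return rate / colsum * 1e6


def log2_transform(tpm: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Elementwise log2(tpm + pseudocount); strictly monotone in the input."""
    tpm = np.asarray(tpm, dtype=float)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if np.any(tpm < 0):
        raise ValueError("TPM values must be non-negative")
    return np.log2(tpm + pseudocount)


def expression_from_counts(
    counts: np.ndarray,
    lengths: np.ndarray,
    gene_ids: list[str],
    sample_ids: list[str],
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Raw counts -> TPM -> log2 -> :class:`ExpressionMatrix`."""
    tpm = tpm_normalize(counts, lengths, sample_ids=sample_ids)
    return ExpressionMatrix(log2_transform(tpm, pseudocount), gene_ids, sample_ids)


def median_dichotomize(values, tie: str = "low") -> np.ndarray:
    """Split a numeric vector into {'low', 'high'} at the cohort median.

    'high' means strictly above the median; ties at the median go to the
    group named by ``tie`` ('low' by default, so 'high' is strict).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot dichotomize an empty vector")
    if values.size < 2:
        raise ValueError("need at least 2 values to dichotomize")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if tie not in ("low", "high"):
        raise ValueError("tie must be 'low' or 'high'")
    med = np.median(values)
    if tie == "low":
        high = values > med
    else:
        high = values >= med
    return np.where(high, "high", "low")


# ---------------------------------------------------------------------------
# Clinical


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations, indexed by sample id.

    Required: response (RECIST), responder (CR/PR=1), os_months, os_event.
    Optional: pdl1_level, immune_phenotype, tmb — tracked in
    ``optional_present``; operations needing one fail fast by name.
    """

    df: pd.DataFrame
    optional_present: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        df = self.df
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                df = df.copy()
                df.index.name = "sample_id"
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in clinical table: {dups[:5]}")
        for col in ("response", "os_months", "os_event"):
            if col not in df.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        bad = set(df["response"]) - set(RESPONSE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown response categories: {sorted(bad)}")
        derived = df["response"].isin(RESPONDER_CATEGORIES).astype(int)
        if "responder" in df.columns:
            if not (df["responder"].astype(int) == derived).all():
                raise ValueError("responder column inconsistent with RECIST response")
        df = df.assign(responder=derived)
        if (df["os_months"] < 0).any():
            raise ValueError("os_months must be non-negative")
        if not df["os_event"].isin([0, 1]).all():
            raise ValueError("os_event must be binary")
        if "pdl1_level" in df.columns:
            bad = set(df["pdl1_level"].dropna()) - set(PDL1_LEVELS)
            if bad:
                raise ValueError(f"unknown pdl1_level values: {sorted(bad)}")
        if "immune_phenotype" in df.columns:
            bad = set(df["immune_phenotype"].dropna()) - set(IMMUNE_PHENOTYPES)
            if bad:
                raise ValueError(f"unknown immune_phenotype values: {sorted(bad)}")
        if "tmb" in df.columns and (pd.to_numeric(df["tmb"]) < 0).any():
            raise ValueError("tmb must be non-negative")
        self.df = df
        self.optional_present = tuple(c for c in OPTIONAL_CLINICAL_FIELDS if c in df.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def require(self, field_name: str) -> pd.Series:
        """Return an optional column, or raise naming the missing field."""
        if field_name not in self.df.columns:
            raise KeyError(f"clinical table has no field {field_name!r}")
        col = self.df[field_name]
        if col.isna().any():
            raise ValueError(f"clinical field {field_name!r} has missing values")
        return col

    def aligned(self, sample_ids: list[str]) -> "ClinicalTable":
        missing = [s for s in sample_ids if s not in self.df.index]
        if missing:
            raise KeyError(f"samples missing from clinical table: {missing[:10]}")
        return ClinicalTable(self.df.loc[list(sample_ids)].copy())

    def write_csv(self, path: str | Path) -> None:
        self.df.to_csv(path)


def read_clinical(path: str | Path) -> ClinicalTable:
    return ClinicalTable(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Mutations


@dataclass
class MutationTable:
    """Long-format binary mutation calls: one row per (sample, gene)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        for col in ("sample_id", "gene", "mutated"):
            if col not in df.columns:
                raise ValueError(f"mutation table missing column {col!r}")
        df = df.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["gene"] = df["gene"].astype(str)
        if not df["mutated"].isin([0, 1]).all():
            raise ValueError("mutated must be 0/1")
        if df.duplicated(["sample_id", "gene"]).any():
            raise ValueError("duplicate (sample_id, gene) pairs in mutation table")
        self.df = df

    @property
    def genes(self) -> list[str]:
        return sorted(self.df["gene"].unique())

    def to_wide(self, sample_ids: list[str] | None = None, fill: int = 0) -> pd.DataFrame:
        wide = self.df.pivot(index="sample_id", columns="gene", values="mutated")
        if sample_ids is not None:
            wide = wide.reindex([str(s) for s in sample_ids])
        return wide.fillna(fill).astype(int)

    def mutated_vector(self, gene: str, sample_ids: list[str]) -> np.ndarray:
        wide = self.to_wide(sample_ids=sample_ids)
        if gene not in wide.columns:
            raise KeyError(f"gene {gene!r} not in mutation table")
        return wide[gene].to_numpy()

    def write_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def read_mutations(path: str | Path) -> MutationTable:
    """Read mutation calls from long CSV or a wide binary matrix."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"sample_id", "gene", "mutated"} <= cols:
        return MutationTable(df[["sample_id", "gene", "mutated"]])
    # wide layout: first column sample ids, remaining columns genes
    idcol = df.columns[0]
    long = df.melt(id_vars=idcol, var_name="gene", value_name="mutated")
    long = long.rename(columns={idcol: "sample_id"})
    return MutationTable(long)
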