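"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive throughout (VCF convention).  BED input is
converted on read.  Genotype dosages are alt-allele counts stored as floats
with ``numpy.nan`` marking missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: The 13 two-letter phenotype category codes.
CATEGORY_CODES = frozenset(
    ["AM", "CV", "DS", "EM", "HS", "LS", "ME", "MN", "MC", "OS", "PS", "RS", "TM"]
)


@dataclass(frozen=True)
class Variant:
    """A bi-allelic variant.

    Attributes
    ----------
    id : str
        Unique identifier within a :class:`GenotypeMatrix`.
    chromosome : str
    position : int
        1-based coordinate, ``>= 1``.
    ref_allele, alt_allele : str
        Must differ; dosages count copies of ``alt_allele``.
    maf : float, optional
        Minor-allele frequency in ``[0, 1]`` if known.
    """

    id: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    maf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"variant {self.id}: position must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"variant {self.id}: ref and alt alleles are identical")
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"variant {self.id}: maf outside [0, 1]")


class GenotypeMatrix:
    """Individuals x variants additive dosage matrix with variant metadata.

    Parameters
    ----------
    individuals : sequence of str
        Ordered, unique sample identifiers.
    variants : sequence of Variant
        Ordered variant metadata; ids must be unique.
    dosages : ndarray, shape (n_individuals, n_variants)
        Alt-allele counts in {0, 1, 2}; ``nan`` marks missing.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        variants: Sequence[Variant],
        dosages: np.ndarray,
    ) -> None:
        individuals = list(individuals)
        variants = list(variants)
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2 or dosages.shape != (len(individuals), len(variants)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(individuals)} individuals x {len(variants)} variants"
            )
        if len(set(individuals)) != len(individuals):
            raise ValueError("duplicate sample identifiers")
        ids = [v.id for v in variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant identifiers")
        valid = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2} or missing")
        self.individuals = individuals
        self.variants = variants
        self.dosages = dosages
        self._index = {v.id: j for j, v in enumerate(variants)}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list:
        return [v.id for v in self.variants]

    def column(self, variant_id: str) -> np.ndarray:
        """Dosage vector for one variant."""
        return self.dosages[:, self._index[variant_id]]

    def index_of(self, variant_id: str) -> int:
        return self._index[variant_id]

    def missingness(self) -> np.ndarray:
        """Per-variant fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)

    def allele_frequencies(self) -> np.ndarray:
        """Per-variant alt-allele frequency over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def mean_imputed(self) -> np.ndarray:
        """Dosage matrix with missing entries replaced by per-variant means."""
        out = self.dosages.copy()
        means = np.nanmean(np.where(np.isnan(out), np.nan, out), axis=0)
        means = np.where(np.isnan(means), 0.0, means)
        idx = np.where(np.isnan(out))
        out[idx] = means[idx[1]]
        return out

    def subset_individuals(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            [self.individuals[i] for i in keep],
            self.variants,
            self.dosages[keep, :],
        )

    def subset_variants(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        cols = [self._index[v] for v in variant_ids]
        return GenotypeMatrix(
            self.individuals,
            [self.variants[c] for c in cols],
            self.dosages[:, cols],
        )


@dataclass
class PhenotypeColumn:
    """Metadata for one phenotype column."""

    name: str
    kind: str  # "continuous" | "binary"
    category: str  # one of CATEGORY_CODES

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"{self.name}: kind must be continuous or binary")
        if self.category not in CATEGORY_CODES:
            raise ValueError(f"{self.name}: unknown category code {self.category!r}")


class PhenotypeTable:
    """Per-individual phenotype values plus age/sex covariates.

    Binary columns contain only {0, 1, nan}; continuous columns are floats.
    """

    COVARIATES = ("age", "sex")

    def __init__(
        self,
        individuals: Sequence[str],
        values: pd.DataFrame,
        columns: Sequence[PhenotypeColumn],
        covariates: pd.DataFrame,
    ) -> None:
        individuals = list(individuals)
        if len(set(individuals)) != len(individuals):
            raise ValueError("duplicate sample identifiers")
        columns = list(columns)
        names = [c.name for c in columns]
        if len(set(names)) != len(names):
            raise ValueError("duplicate phenotype names")
        if list(values.columns) != names:
            raise ValueError("value columns do not match phenotype metadata")
        if len(values) != len(individuals) or len(covariates) != len(individuals):
            raise ValueError("row counts do not match individual list")
        for cov in self.COVARIATES:
            if cov not in covariates.columns:
                raise ValueError(f"missing covariate column {cov!r}")
        for col in columns:
            if col.kind == "binary":
                vals = values[col.name].dropna().unique()
                bad = sorted(set(vals) - {0.0, 1.0})
                if bad:
                    raise ValueError(
                        f"binary phenotype {col.name!r} contains non-{{0,1}} "
                        f"values: {bad}"
                    )
        self.individuals = individuals
        self.values = values.reset_index(drop=True).astype(float)
        self.columns = columns
        self.covariates = covariates.reset_index(drop=True).astype(float)
        self._meta = {c.name: c for c in columns}

    @property
    def phenotype_names(self) -> list:
        return [c.name for c in self.columns]

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def kind(self, name: str) -> str:
        return self._meta[name].kind

    def category(self, name: str) -> str:
        return self._meta[name].category

    def phenotype(self, name: str) -> np.ndarray:
        return self.values[name].to_numpy(dtype=float)

    def covariate_matrix(self) -> np.ndarray:
        """Covariates as an (n, 2) array in (age, sex) order."""
        return self.covariates[list(self.COVARIATES)].to_numpy(dtype=float)

    def subset_individuals(self, keep: Sequence[int]) -> "PhenotypeTable":
        keep = list(keep)
        return PhenotypeTable(
            [self.individuals[i] for i in keep],
            self.values.iloc[keep].reset_index(drop=True),
            self.columns,
            self.covariates.iloc[keep].reset_index(drop=True),
        )


@dataclass(frozen=True)
class GeneInterval:
    """A gene locus; ``coding_subintervals`` are (start, end) pairs in the body."""

    gene_symbol: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    coding_subintervals: tuple = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_symbol}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_symbol}: strand must be + or -")
        for s, e in self.coding_subintervals:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(
                    f"{self.gene_symbol}: coding subinterval ({s},{e}) not "
                    f"nested within [{self.start},{self.end}]"
                )


@dataclass(frozen=True)
class AssociationRecord:
    """One (variant, phenotype) regression result."""

    variant_id: str
    phenotype_name: str
    effect: float
    standard_error: float
    p_value: float
    n_samples: int
    model: str  # "linear" | "logistic"

    def __post_init__(self) -> None:
        if self.standard_error <= 0:
            raise ValueError("standard_error must be positive")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must lie in (0, 1]")
        if self.model not in ("linear", "logistic"):
            raise ValueError("model must be linear or logistic")
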