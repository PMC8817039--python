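"""Trans-cohort locus overlap, fixed-effect meta-analysis, and the
PheWAS-driven vs EHR-driven phenotype-pair concordance.

Summary statistics from different cohorts are matched either on a shared
variant-id space or on (chromosome, position, allele set) with automatic
ref/alt flips; strand-ambiguous (A/T, C/G) variants are dropped by default
in positional mode.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .datatypes import AssociationRecord, PhenotypeTable, Variant
from .phewas import EXPLORATORY_P, GENOMEWIDE_P, fdr_adjust

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class OverlapSummary:
    phenotype: str
    n_only_cohort1: int
    n_shared: int
    n_only_cohort2: int

    @property
    def total(self) -> int:
        return self.n_only_cohort1 + self.n_shared + self.n_only_cohort2

    @property
    def ratios(self) -> Tuple[float, float, float]:
        """Percentages (only-1, shared, only-2) summing to 100."""
        t = self.total
        if t == 0:
            return (0.0, 0.0, 0.0)
        return (
            100.0 * self.n_only_cohort1 / t,
            100.0 * self.n_shared / t,
            100.0 * self.n_only_cohort2 / t,
        )


@dataclass
class MetaRecord:
    variant_id: str
    phenotype: str
    meta_effect: float
    meta_se: float
    meta_p: float
    cohort_effects: List[float]
    cohort_ses: List[float]
    cohort_ps: List[float]
    novelty: str  # significant-in-meta-only | significant-in-single | both | none


@dataclass
class PairConcordance:
    phenotype: str
    n_phewas_pairs: int
    n_shared_with_ehr: int
    category: Optional[str] = None

    @property
    def overlap_percent(self) -> Optional[float]:
        if self.n_phewas_pairs == 0:
            return None  # undefined, not zero
        return 100.0 * self.n_shared_with_ehr / self.n_phewas_pairs


# ---------------------------------------------------------------------------
# locus overlap


def _significant_loci(
    records: Iterable[AssociationRecord], phenotype: str, p_threshold: float
) -> Set[str]:
    return {
        r.variant_id
        for r in records
        if r.phenotype_name == phenotype and r.p_value < p_threshold
    }


def locus_overlap(
    stats1: Sequence[AssociationRecord],
    stats2: Sequence[AssociationRecord],
    matched_phenotypes: Sequence[str],
    p_threshold: float = EXPLORATORY_P,
) -> List[OverlapSummary]:
    """Per-phenotype exclusive/shared significant-locus counts.

    Variant ids must already be harmonized to a shared space.  Phenotypes
    with no significant locus in either cohort are reported with all-zero
    counts; phenotypes absent from a cohort's record set entirely are still
    processed (their significant set is simply empty) and logged.
    """
    phenos1 = {r.phenotype_name for r in stats1}
    phenos2 = {r.phenotype_name for r in stats2}
    out = []
    for pheno in matched_phenotypes:
        if pheno not in phenos1 or pheno not in phenos2:
            logger.info("phenotype %s absent from one cohort; skipped", pheno)
            continue
        s1 = _significant_loci(stats1, pheno, p_threshold)
        s2 = _significant_loci(stats2, pheno, p_threshold)
        out.append(
            OverlapSummary(
                phenotype=pheno,
                n_only_cohort1=len(s1 - s2),
                n_shared=len(s1 & s2),
                n_only_cohort2=len(s2 - s1),
            )
        )
    return out


# ---------------------------------------------------------------------------
# meta-analysis


def is_strand_ambiguous(ref: str, alt: str) -> bool:
    return _COMPLEMENT.get(ref.upper()) == alt.upper()


def harmonize_effect(
    v1: Variant, v2: Variant, effect2: float
) -> Optional[float]:
    """Orient cohort-2 effect onto cohort-1 alleles; None if unresolvable.

    Strand-ambiguous variants are dropped (returns None).
    """
    if v1.chromosome != v2.chromosome or v1.position != v2.position:
        return None
    if is_strand_ambiguous(v1.ref_allele, v1.alt_allele):
        return None
    a1 = (v1.ref_allele.upper(), v1.alt_allele.upper())
    a2 = (v2.ref_allele.upper(), v2.alt_allele.upper())
    if a1 == a2:
        return effect2
    if a1 == (a2[1], a2[0]):
        return -effect2
    flipped = tuple(
        "".join(_COMPLEMENT.get(b, "N") for b in allele) for allele in a2
    )
    if a1 == flipped:
        return effect2
    if a1 == (flipped[1], flipped[0]):
        return -effect2
    return None


def meta_analyze(
    stats_list: Sequence[Sequence[AssociationRecord]],
    variant_tables: Optional[Sequence[Dict[str, Variant]]] = None,
    genomewide_p: float = GENOMEWIDE_P,
) -> List[MetaRecord]:
    """Fixed-effect inverse-variance meta-analysis across cohorts.

    Only (variant, phenotype) keys present in every cohort are combined.
    With ``variant_tables`` supplied, cohort effects are re-oriented onto
    the first cohort's alleles; unresolvable or strand-ambiguous records
    are dropped with a logged count.
    """
    if len(stats_list) < 2:
        raise ValueError("need at least two cohorts")
    keyed = [
        {(r.variant_id, r.phenotype_name): r for r in stats} for stats in stats_list
    ]
    common = set(keyed[0])
    for k in keyed[1:]:
        common &= set(k)
    n_dropped = 0
    out = []
    for key in sorted(common):
        vid, pheno = key
        effects, ses, ps = [], [], []
        ok = True
        for c, k in enumerate(keyed):
            rec = k[key]
            eff = rec.effect
            if variant_tables is not None and c > 0:
                v1 = variant_tables[0].get(vid)
                v2 = variant_tables[c].get(vid)
                if v1 is None or v2 is None:
                    ok = False
                    break
                oriented = harmonize_effect(v1, v2, eff)
                if oriented is None:
                    ok = False
                    break
                eff = oriented
            elif variant_tables is not None:
                v1 = variant_tables[0].get(vid)
                if v1 is not None and is_strand_ambiguous(
                    v1.ref_allele, v1.alt_allele
                ):
                    ok = False
                    break
            effects.append(eff)
            ses.append(rec.standard_error)
            ps.append(rec.p_value)
        if not ok:
            n_dropped += 1
            continue
        w = 1.0 / np.asarray(ses) ** 2
        meta_effect = float(np.sum(w * np.asarray(effects)) / w.sum())
        meta_se = float(1.0 / np.sqrt(w.sum()))
        meta_p = float(2.0 * stats.norm.sf(abs(meta_effect / meta_se)))
        meta_p = max(meta_p, np.finfo(float).tiny)
        meta_sig = meta_p < genomewide_p
        single_sig = any(p < genomewide_p for p in ps)
        if meta_sig and single_sig:
            novelty = "both"
        elif meta_sig:
            novelty = "significant-in-meta-only"
        elif single_sig:
            novelty = "significant-in-single"
        else:
            novelty = "none"
        out.append(
            MetaRecord(
                variant_id=vid,
                phenotype=pheno,
                meta_effect=meta_effect,
                meta_se=meta_se,
                meta_p=meta_p,
                cohort_effects=effects,
                cohort_ses=ses,
                cohort_ps=ps,
                novelty=novelty,
            )
        )
    if n_dropped:
        logger.info("%d records dropped during allele harmonization", n_dropped)
    return out


# ---------------------------------------------------------------------------
# EHR-driven pair concordance


def ehr_pairs_from_table(
    table: PhenotypeTable,
    phenotypes: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    correction: str = "bh",
) -> Tuple[Set[FrozenSet[str]], Dict[FrozenSet[str], str]]:
    """Phenotype pairs significant under pairwise association testing.

    Continuous-continuous pairs use Pearson correlation; binary-binary a
    chi-squared test on the 2x2 table; mixed pairs a point-biserial
    correlation.  Multiple testing across all tested pairs uses BH-FDR
    (default) or Bonferroni at ``alpha``.
    """
    names = list(phenotypes) if phenotypes is not None else table.phenotype_names
    pairs: List[FrozenSet[str]] = []
    pvals: List[float] = []
    methods: Dict[FrozenSet[str], str] = {}
    for a, b in itertools.combinations(names, 2):
        xa, xb = table.phenotype(a), table.phenotype(b)
        mask = np.isfinite(xa) & np.isfinite(xb)
        if mask.sum() < 4:
            continue
        xa, xb = xa[mask], xb[mask]
        ka, kb = table.kind(a), table.kind(b)
        pair = frozenset((a, b))
        if ka == "binary" and kb == "binary":
            contingency = np.array(
                [
                    [np.sum((xa == i) & (xb == j)) for j in (0, 1)]
                    for i in (0, 1)
                ]
            )
            if (contingency.sum(axis=0) == 0).any() or (
                contingency.sum(axis=1) == 0
            ).any():
                continue
            _, p, _, _ = stats.chi2_contingency(contingency)
            methods[pair] = "chi-squared"
        else:
            if xa.std() == 0 or xb.std() == 0:
                continue
            _, p = stats.pearsonr(xa, xb)
            methods[pair] = (
                "pearson" if ka == kb == "continuous" else "point-biserial"
            )
        pairs.append(pair)
        pvals.append(max(float(p), np.finfo(float).tiny))
    if not pairs:
        return set(), {}
    if correction == "bh":
        adjusted = fdr_adjust(pvals)
    elif correction == "bonferroni":
        adjusted = np.minimum(np.asarray(pvals) * len(pvals), 1.0)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    significant = {pair for pair, q in zip(pairs, adjusted) if q < alpha}
    return significant, methods


def ehr_pair_concordance(
    phewas_pairs: Iterable[FrozenSet[str]],
    ehr_table: Optional[PhenotypeTable] = None,
    ehr_pairs: Optional[Set[FrozenSet[str]]] = None,
    shared_phenotypes: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    correction: str = "bh",
    categories: Optional[Dict[str, str]] = None,
) -> Tuple[List[PairConcordance], Dict[str, object]]:
    """Compare PheWAS-driven phenotype pairs with the EHR-driven pair set.

    The EHR set is either derived from ``ehr_table`` by pairwise
    correlation testing, or supplied precomputed via ``ehr_pairs`` (e.g.
    from an external cohort analysis).  When ``shared_phenotypes`` is given
    the PheWAS pair set is restricted to pairs fully inside it.

    Returns per-phenotype concordance records and an overall summary with
    the headline overlap percentage and per-category mean percentages.
    """
    if (ehr_table is None) == (ehr_pairs is None):
        raise ValueError("provide exactly one of ehr_table or ehr_pairs")
    if ehr_table is not None:
        ehr_pairs, _ = ehr_pairs_from_table(
            ehr_table,
            phenotypes=shared_phenotypes,
            alpha=alpha,
            correction=correction,
        )
    phewas_set = {frozenset(p) for p in phewas_pairs}
    if any(len(p) != 2 for p in phewas_set):
        raise ValueError("pairs must have exactly two distinct phenotypes")
    if shared_phenotypes is not None:
        allowed = set(shared_phenotypes)
        phewas_set = {p for p in phewas_set if p <= allowed}
    shared = phewas_set & set(ehr_pairs)

    pheno_names = sorted({p for pair in phewas_set for p in pair})
    per_pheno = []
    for pheno in pheno_names:
        mine = {p for p in phewas_set if pheno in p}
        per_pheno.append(
            PairConcordance(
                phenotype=pheno,
                n_phewas_pairs=len(mine),
                n_shared_with_ehr=len(mine & shared),
                category=(categories or {}).get(pheno),
            )
        )
    n_total = len(phewas_set)
    overall = 100.0 * len(shared) / n_total if n_total else None
    by_category: Dict[str, float] = {}
    if categories:
        cat_vals: Dict[str, List[float]] = {}
        for pc in per_pheno:
            if pc.category and pc.overlap_percent is not None:
                cat_vals.setdefault(pc.category, []).append(pc.overlap_percent)
        by_category = {c: float(np.mean(v)) for c, v in cat_vals.items()}
    summary = {
        "n_phewas_pairs": n_total,
        "n_ehr_pairs": len(ehr_pairs),
        "n_shared": len(shared),
        "overall_percent": overall,
        "by_category_percent": by_category,
    }
    return per_pheno, summary
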