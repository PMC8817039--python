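"""Coordinate-based variant-to-gene mapping with a 5 kb flank.

A variant is assigned to every gene whose body extended by the flank
contains its position (default policy), or to the single nearest such gene
behind a flag.  Variants inside a coding subinterval are classified coding
and collapsed to the "moderate-high" impact group; everything else is
"modifier-low".  Externally supplied impact labels can override the
two-level surrogate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .datatypes import GeneInterval, Variant

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 5000

IMPACT_MODIFIER_LOW = "modifier-low"
IMPACT_MODERATE_HIGH = "moderate-high"


@dataclass(frozen=True)
class VariantAnnotation:
    variant_id: str
    gene_symbols: Tuple[str, ...]
    region_class: str  # "coding" | "non-coding"
    impact_group: str  # "modifier-low" | "moderate-high"

    def __post_init__(self) -> None:
        if self.region_class == "coding" and not self.gene_symbols:
            raise ValueError(f"{self.variant_id}: coding variant without a gene")
        if self.region_class not in ("coding", "non-coding"):
            raise ValueError("region_class must be coding or non-coding")
        if self.impact_group not in (IMPACT_MODIFIER_LOW, IMPACT_MODERATE_HIGH):
            raise ValueError("unknown impact group")


class GeneIndex:
    """Per-chromosome sorted gene intervals for repeated lookups."""

    def __init__(self, genes: Sequence[GeneInterval]) -> None:
        self.by_chrom: Dict[str, List[GeneInterval]] = {}
        for g in genes:
            self.by_chrom.setdefault(g.chromosome, []).append(g)
        for lst in self.by_chrom.values():
            lst.sort(key=lambda g: (g.start, g.end, g.gene_symbol))


def map_variant_to_genes(
    variant: Variant,
    gene_index: GeneIndex,
    flank: int = DEFAULT_FLANK,
    policy: str = "all-overlapping",
    impact_override: Optional[str] = None,
) -> VariantAnnotation:
    """Annotate one variant against the gene index.

    ``policy`` is "all-overlapping" (every gene whose flanked interval
    contains the position) or "nearest" (single nearest gene within the
    flank; distance ties broken by smaller distance then symbol).  Strand is
    ignored: the flank applies to both sides of every gene.
    """
    if policy not in ("all-overlapping", "nearest"):
        raise ValueError(f"unknown mapping policy {policy!r}")
    genes = gene_index.by_chrom.get(variant.chromosome)
    if genes is None:
        logger.warning(
            "variant %s: unknown chromosome %s; left unassigned",
            variant.id,
            variant.chromosome,
        )
        return VariantAnnotation(
            variant.id, (), "non-coding", impact_override or IMPACT_MODIFIER_LOW
        )
    pos = variant.position
    hits: List[Tuple[int, str, GeneInterval]] = []  # (distance, symbol, gene)
    for g in genes:
        if g.start - flank <= pos <= g.end + flank:
            if g.start <= pos <= g.end:
                dist = 0
            else:
                dist = min(abs(pos - g.start), abs(pos - g.end))
            hits.append((dist, g.gene_symbol, g))
    if not hits:
        return VariantAnnotation(
            variant.id, (), "non-coding", impact_override or IMPACT_MODIFIER_LOW
        )
    hits.sort(key=lambda h: (h[0], h[1]))
    if policy == "nearest":
        hits = hits[:1]
    symbols = tuple(dict.fromkeys(h[1] for h in hits))
    coding = any(
        s <= pos <= e for _, _, g in hits for (s, e) in g.coding_subintervals
    )
    region = "coding" if coding else "non-coding"
    if impact_override is not None:
        impact = impact_override
    else:
        impact = IMPACT_MODERATE_HIGH if coding else IMPACT_MODIFIER_LOW
    return VariantAnnotation(variant.id, symbols, region, impact)


def annotate_variants(
    variants: Iterable[Variant],
    genes: Sequence[GeneInterval],
    flank: int = DEFAULT_FLANK,
    policy: str = "all-overlapping",
    impact_overrides: Optional[Dict[str, str]] = None,
) -> Dict[str, VariantAnnotation]:
    """Annotate a collection of variants; returns id -> annotation."""
    index = GeneIndex(genes)
    overrides = impact_overrides or {}
    return {
        v.id: map_variant_to_genes(
            v, index, flank=flank, policy=policy,
            impact_override=overrides.get(v.id),
        )
        for v in variants
    }


def coding_fraction(annotations: Iterable[VariantAnnotation]) -> float:
    """Fraction of annotated variants classified as coding."""
    anns = list(annotations)
    if not anns:
        raise ValueError("empty annotation set")
    return sum(1 for a in anns if a.region_class == "coding") / len(anns)


def write_annotations(
    annotations: Dict[str, VariantAnnotation], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write("variant\tgenes\tregion_class\timpact_group\n")
        for vid, a in annotations.items():
            fh.write(
                f"{vid}\t{','.join(a.gene_symbols) or '.'}\t"
                f"{a.region_class}\t{a.impact_group}\n"
            )
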