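"""Synthetic cohort generator with known pleiotropic and causal architecture.

Genotypes follow Hardy-Weinberg proportions with block-wise LD: each
haplotype is a first-order Markov chain of alleles whose adjacent-variant
correlation targets a configurable rho, so genotype (dosage) correlation
between neighbours is ~rho and decays geometrically within a block.  Traits
are additive-polygenic with optional phenotype-on-phenotype causal effects,
age/sex covariate effects and liability-threshold binary outcomes, and the
generator returns the ground truth needed to score downstream recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import (
    GenotypeMatrix,
    PhenotypeColumn,
    PhenotypeTable,
    Variant,
)


@dataclass
class PhenotypeSpec:
    """Architecture of one simulated trait.

    ``heritability`` is the target fraction of (genetic + noise) variance
    explained by the genetic score; parent-phenotype and covariate terms are
    added on top of that decomposition.
    """

    name: str
    kind: str = "continuous"  # "continuous" | "binary"
    category: str = "EM"
    heritability: float = 0.0
    causal_variant_ids: Tuple[str, ...] = ()
    effect_sizes: Tuple[float, ...] = ()
    prevalence: Optional[float] = None  # binary only
    parents: Dict[str, float] = field(default_factory=dict)  # name -> gamma

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"{self.name}: kind must be continuous or binary")
        if not (0.0 <= self.heritability < 1.0):
            raise ValueError(f"{self.name}: heritability must be in [0, 1)")
        if self.effect_sizes and len(self.effect_sizes) != len(
            self.causal_variant_ids
        ):
            raise ValueError(f"{self.name}: effect/causal-id length mismatch")
        if self.kind == "binary":
            if self.prevalence is None or not (0.0 < self.prevalence < 1.0):
                raise ValueError(f"{self.name}: prevalence must be in (0, 1)")


@dataclass
class SimulationConfig:
    n_individuals: int = 1000
    n_variants: int = 100
    n_ld_blocks: int = 10
    within_block_correlation: float = 0.0
    #: optional (low, high): each block draws its own correlation uniformly,
    #: overriding within_block_correlation; gives LD-score spread for
    #: heritability regression tests
    block_correlation_range: Optional[Tuple[float, float]] = None
    maf_range: Tuple[float, float] = (0.05, 0.5)
    phenotype_specs: List[PhenotypeSpec] = field(default_factory=list)
    age_effect: float = 0.0
    sex_effect: float = 0.0
    age_range: Tuple[int, int] = (30, 70)
    sex_fraction: float = 0.5
    # optional two-subpopulation allele-frequency shift to exercise PCs
    subpop_fraction: float = 0.0
    subpop_maf_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.within_block_correlation < 1.0):
            raise ValueError("within_block_correlation must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        names = [s.name for s in self.phenotype_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate phenotype names in specs")
        _check_acyclic(self.phenotype_specs)


def _check_acyclic(specs: Sequence[PhenotypeSpec]) -> List[str]:
    """Topologically order specs by parent relations; raise on cycles."""
    by_name = {s.name: s for s in specs}
    order: List[str] = []
    state: Dict[str, int] = {}  # 0 visiting, 1 done

    def visit(name: str) -> None:
        if state.get(name) == 1:
            return
        if state.get(name) == 0:
            raise ValueError(f"cyclic parent-phenotype graph at {name!r}")
        state[name] = 0
        for parent in by_name[name].parents:
            if parent not in by_name:
                raise ValueError(f"{name!r} references unknown parent {parent!r}")
            visit(parent)
        state[name] = 1
        order.append(name)

    for s in specs:
        visit(s.name)
    return order


@dataclass
class GroundTruth:
    """Oracle for recovery tests downstream of the simulator."""

    causal_variants: Dict[str, Dict[str, float]]  # phenotype -> {variant: beta}
    causal_edges: List[Tuple[str, str, float]]  # (parent, child, gamma)
    pleiotropic_map: Dict[str, Tuple[str, ...]]  # variant -> phenotypes

    def pleiotropy_pairs(self) -> set:
        """Unordered phenotype pairs induced by shared causal variants."""
        pairs = set()
        for phenos in self.pleiotropic_map.values():
            for i, a in enumerate(phenos):
                for b in phenos[i + 1 :]:
                    pairs.add(frozenset((a, b)))
        return pairs


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw HWE genotypes with block-wise AR(1)-style LD.

    Variants are evenly split into ``n_ld_blocks`` contiguous blocks (the
    last block absorbs any remainder); blocks are mutually independent and
    placed 1 Mb apart so distance windows can separate them.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_variants
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=m)

    block_sizes = _block_sizes(m, config.n_ld_blocks)
    if config.block_correlation_range is not None:
        blo, bhi = config.block_correlation_range
        if not (0.0 <= blo <= bhi < 1.0):
            raise ValueError("block_correlation_range must lie in [0, 1)")
        block_rho = rng.uniform(blo, bhi, size=len(block_sizes))
    else:
        block_rho = np.full(len(block_sizes), config.within_block_correlation)
    positions = np.empty(m, dtype=int)
    block_of = np.empty(m, dtype=int)
    j = 0
    for b, size in enumerate(block_sizes):
        for k in range(size):
            positions[j] = b * 1_000_000 + k * 1_000 + 1
            block_of[j] = b
            j += 1

    # subpopulation labels shift allele frequencies if requested
    subpop = np.zeros(n, dtype=bool)
    if config.subpop_fraction > 0:
        subpop = rng.random(n) < config.subpop_fraction

    haplotypes = np.empty((2, n, m), dtype=np.int8)
    for h in range(2):
        prev = None
        for j in range(m):
            p = np.full(n, mafs[j])
            if config.subpop_fraction > 0:
                p = np.where(
                    subpop,
                    np.clip(mafs[j] + config.subpop_maf_shift, 0.01, 0.99),
                    mafs[j],
                )
            new_block = j == 0 or block_of[j] != block_of[j - 1]
            rho = float(block_rho[block_of[j]])
            if new_block or rho == 0.0 or prev is None:
                allele = (rng.random(n) < p).astype(np.int8)
            else:
                # exact binary-pair conditional: preserves marginal p and
                # yields adjacent correlation min(rho, feasibility bound)
                p_prev = mafs[j - 1]
                s_prev = np.sqrt(p_prev * (1 - p_prev))
                s_cur = np.sqrt(p * (1 - p))
                bound1 = (1 - p) * s_prev / (s_cur * (1 - p_prev))
                bound2 = p * s_prev / (s_cur * p_prev)
                rho_eff = np.minimum(rho, np.minimum(bound1, bound2))
                cond = p + rho_eff * (s_cur / s_prev) * (prev - p_prev)
                cond = np.clip(cond, 0.0, 1.0)
                allele = (rng.random(n) < cond).astype(np.int8)
            haplotypes[h, :, j] = allele
            prev = allele

    dosages = haplotypes.sum(axis=0).astype(float)
    variants = [
        Variant(
            id=f"v{j}",
            chromosome="1",
            position=int(positions[j]),
            ref_allele="A",
            alt_allele="G",
            maf=float(mafs[j]),
        )
        for j in range(m)
    ]
    individuals = [f"ind{i}" for i in range(n)]
    gm = GenotypeMatrix(individuals, variants, dosages)
    gm.subpopulation = subpop  # carried for PC-structure tests
    return gm


def _block_sizes(m: int, n_blocks: int) -> List[int]:
    n_blocks = max(1, min(n_blocks, m))
    base = m // n_blocks
    sizes = [base] * n_blocks
    sizes[-1] += m - base * n_blocks
    return sizes


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> Tuple[PhenotypeTable, GroundTruth]:
    """Build traits over simulated genotypes and return their ground truth.

    Continuous trait: sum of beta * standardized dosage, plus gamma * parent
    values, covariate terms, and Gaussian noise scaled so the genetic
    fraction of (genetic + noise) variance hits the heritability target.
    Binary trait: liability thresholded at the empirical (1 - prevalence)
    quantile.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = genotypes.n_individuals
    order = _check_acyclic(config.phenotype_specs)
    by_name = {s.name: s for s in config.phenotype_specs}

    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    sex = (rng.random(n) < config.sex_fraction).astype(float)
    covariates = pd.DataFrame({"age": age.astype(float), "sex": sex})

    X = genotypes.mean_imputed()
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd

    values: Dict[str, np.ndarray] = {}
    causal: Dict[str, Dict[str, float]] = {}
    edges: List[Tuple[str, str, float]] = []
    pleio: Dict[str, List[str]] = {}

    for name in order:
        spec = by_name[name]
        ids = list(spec.causal_variant_ids)
        for vid in ids:
            if vid not in genotypes._index:
                raise ValueError(f"{name}: unknown causal variant {vid!r}")
        betas = (
            np.asarray(spec.effect_sizes, dtype=float)
            if spec.effect_sizes
            else rng.normal(0.0, 1.0, size=len(ids))
        )
        if spec.heritability == 0.0 and not spec.effect_sizes:
            betas = np.zeros(len(ids))
        g = np.zeros(n)
        if ids:
            cols = [genotypes.index_of(v) for v in ids]
            g = Z[:, cols] @ betas
        var_g = float(g.var())
        if spec.heritability > 0.0 and var_g > 0.0:
            var_e = var_g * (1.0 - spec.heritability) / spec.heritability
        else:
            var_e = 1.0
        noise = rng.normal(0.0, np.sqrt(var_e), size=n)
        liability = g + noise
        for parent, gamma in spec.parents.items():
            liability = liability + gamma * values[parent]
            edges.append((parent, name, gamma))
        liability = (
            liability + config.age_effect * (age - age.mean())
            + config.sex_effect * (sex - sex.mean())
        )
        if spec.kind == "binary":
            threshold = np.quantile(liability, 1.0 - spec.prevalence)
            values[name] = (liability > threshold).astype(float)
        else:
            values[name] = liability
        causal[name] = {v: float(b) for v, b in zip(ids, betas) if b != 0.0}
        for vid in causal[name]:
            pleio.setdefault(vid, []).append(name)

    columns = [
        PhenotypeColumn(name=s.name, kind=s.kind, category=s.category)
        for s in config.phenotype_specs
    ]
    table = PhenotypeTable(
        genotypes.individuals,
        pd.DataFrame({c.name: values[c.name] for c in columns}),
        columns,
        covariates,
    )
    truth = GroundTruth(
        causal_variants=causal,
        causal_edges=edges,
        pleiotropic_map={
            v: tuple(ps) for v, ps in pleio.items() if len(ps) >= 1
        },
    )
    return table, truth


def simulate_cohort(
    config: SimulationConfig,
) -> Tuple[GenotypeMatrix, PhenotypeTable, GroundTruth]:
    """Convenience wrapper: genotypes then phenotypes under one config."""
    gm = simulate_genotypes(config)
    table, truth = simulate_phenotypes(gm, config)
    return gm, table, truth
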