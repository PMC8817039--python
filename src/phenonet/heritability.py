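"""Single-component LD-score regression and the impact-vs-h2 correlation.

LD scores are computed in-sample from the analyzed genotypes (a reader for
externally supplied score tables is provided).  Heritability comes from a
weighted regression of per-variant association chi-square on LD score:
E[chi2_j] = 1 + N h2 l_j / M, so h2 = slope * M / N.  Standard errors use a
block jackknife over contiguous variant blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import IMPACT_MODERATE_HIGH, VariantAnnotation
from .datatypes import GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_KB = 1000
DEFAULT_JACKKNIFE_BLOCKS = 20


@dataclass
class LDScoreTable:
    variant_ids: List[str]
    scores: np.ndarray
    window_kb: float

    def __post_init__(self) -> None:
        if np.any(self.scores < 1.0 - 1e-9):
            raise ValueError("LD scores must be >= 1 (self r2 included)")

    def aligned(self, variant_ids: Sequence[str]) -> np.ndarray:
        index = {v: i for i, v in enumerate(self.variant_ids)}
        return self.scores[[index[v] for v in variant_ids]]


@dataclass
class HeritabilityEstimate:
    phenotype: str
    h2: float
    se: float
    intercept: float
    n_samples: int
    n_variants: int
    out_of_bounds: bool = False


def compute_ld_scores(
    genotypes: GenotypeMatrix, window_kb: float = DEFAULT_WINDOW_KB
) -> LDScoreTable:
    """l_j = 1 + sum of r2 with same-chromosome variants within the window."""
    X = genotypes.mean_imputed()
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    n, m = Z.shape
    chrom = np.array([v.chromosome for v in genotypes.variants])
    pos = np.array([v.position for v in genotypes.variants], dtype=float)
    order = np.lexsort((pos, chrom))
    scores = np.ones(m)
    win = window_kb * 1000.0
    # sliding window over position-sorted variants, one chromosome at a time
    lo = 0
    for idx, j in enumerate(order):
        while lo < idx and (
            chrom[order[lo]] != chrom[j] or pos[j] - pos[order[lo]] > win
        ):
            lo += 1
        neighbors = order[lo:idx]
        if len(neighbors):
            r = Z[:, neighbors].T @ Z[:, j] / n
            r2 = r * r
            scores[j] += float(r2.sum())
            scores[neighbors] += r2
    return LDScoreTable(
        variant_ids=genotypes.variant_ids, scores=scores, window_kb=window_kb
    )


def read_ld_scores(path: str) -> LDScoreTable:
    """Read an externally supplied two-column (variant, ldscore) table."""
    df = pd.read_csv(path, sep="\t")
    if "variant" not in df.columns or "ldscore" not in df.columns:
        raise ValueError(f"{path}: need 'variant' and 'ldscore' columns")
    return LDScoreTable(
        variant_ids=list(df["variant"].astype(str)),
        scores=df["ldscore"].to_numpy(dtype=float),
        window_kb=float("nan"),
    )


def write_ld_scores(table: LDScoreTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("variant\tldscore\n")
        for vid, sc in zip(table.variant_ids, table.scores):
            fh.write(f"{vid}\t{float(sc)!r}\n")


def ldsc_h2(
    chi2: np.ndarray,
    ld_scores: np.ndarray,
    n_samples: int,
    n_variants: Optional[int] = None,
    phenotype: str = "",
    n_blocks: int = DEFAULT_JACKKNIFE_BLOCKS,
) -> HeritabilityEstimate:
    """Heritability from the chi2-on-LD-score regression.

    Weights 1/(1 + N h2 l_j / M)^2 are iterated twice from an OLS start.
    Out-of-[0,1] estimates are reported and flagged, not clipped.
    """
    chi2 = np.asarray(chi2, dtype=float)
    ell = np.asarray(ld_scores, dtype=float)
    if chi2.shape != ell.shape:
        raise ValueError("chi2 and LD scores must align variant-by-variant")
    m = n_variants if n_variants is not None else len(chi2)
    n = n_samples
    if len(chi2) < 3:
        raise ValueError("need at least 3 variants")
    if n_blocks > len(chi2):
        logger.warning(
            "reducing jackknife blocks from %d to %d (few variants)",
            n_blocks,
            len(chi2),
        )
        n_blocks = len(chi2)

    x = ell * n / m

    def wls(mask: np.ndarray) -> Tuple[float, float]:
        w = np.ones(mask.sum())
        slope = intercept = 0.0
        for _ in range(3):  # OLS start + two reweighting passes
            D = np.column_stack([np.ones(mask.sum()), x[mask]])
            Wsq = np.sqrt(w)
            coef, _, _, _ = np.linalg.lstsq(
                D * Wsq[:, None], chi2[mask] * Wsq, rcond=None
            )
            intercept, slope = float(coef[0]), float(coef[1])
            h2_cur = np.clip(slope, 0.0, 1.0)
            w = 1.0 / (1.0 + h2_cur * x[mask]) ** 2
        return slope, intercept

    full = np.ones(len(chi2), dtype=bool)
    slope, intercept = wls(full)
    h2 = slope  # slope is d chi2 / d(N l/M) = h2 directly

    # delete-one-block jackknife over contiguous variant blocks
    bounds = np.linspace(0, len(chi2), n_blocks + 1).astype(int)
    pseudo = []
    for b in range(n_blocks):
        mask = full.copy()
        mask[bounds[b] : bounds[b + 1]] = False
        if mask.sum() < 3:
            continue
        s_b, _ = wls(mask)
        pseudo.append(n_blocks * h2 - (n_blocks - 1) * s_b)
    pseudo = np.asarray(pseudo)
    se = float(pseudo.std(ddof=1) / np.sqrt(len(pseudo))) if len(pseudo) > 1 else np.nan
    if not np.isfinite(se) or se <= 0:
        se = np.finfo(float).tiny ** 0.25
    return HeritabilityEstimate(
        phenotype=phenotype,
        h2=float(h2),
        se=se,
        intercept=float(intercept),
        n_samples=n,
        n_variants=m,
        out_of_bounds=not (0.0 <= h2 <= 1.0),
    )


def chi2_from_run(run, phenotype: str, variant_ids: Sequence[str]) -> np.ndarray:
    """Per-variant Wald chi-square (effect/se)^2 for one phenotype."""
    out = np.full(len(variant_ids), np.nan)
    for i, vid in enumerate(variant_ids):
        rec = run.record(vid, phenotype)
        if rec is not None:
            out[i] = (rec.effect / rec.standard_error) ** 2
    return out


def impact_heritability_correlation(
    annotations: Dict[str, VariantAnnotation],
    h2_by_phenotype: Dict[str, float],
    loci_by_phenotype: Dict[str, Sequence[str]],
) -> Dict[str, float]:
    """Correlate per-phenotype high-impact locus fraction with h2.

    For each phenotype the fraction of its sub-threshold loci in the
    moderate-high impact group is computed; the Pearson correlation of that
    fraction with h2 across phenotypes is returned with a Fisher-z CI.  A
    degenerate (zero-variance) input yields r = nan with a reason.
    """
    phenos = [p for p in h2_by_phenotype if loci_by_phenotype.get(p)]
    if len(phenos) < 3:
        raise ValueError("need at least 3 phenotypes with loci")
    fractions = []
    h2s = []
    for p in phenos:
        loci = loci_by_phenotype[p]
        n_high = sum(
            1
            for v in loci
            if v in annotations
            and annotations[v].impact_group == IMPACT_MODERATE_HIGH
        )
        fractions.append(n_high / len(loci))
        h2s.append(h2_by_phenotype[p])
    fractions = np.asarray(fractions)
    h2s = np.asarray(h2s)
    if fractions.std() == 0 or h2s.std() == 0:
        return {
            "r": float("nan"),
            "p": float("nan"),
            "ci_low": float("nan"),
            "ci_high": float("nan"),
            "n": len(phenos),
            "degenerate": True,
        }
    r, p = stats.pearsonr(fractions, h2s)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = 1.959963984540054 / np.sqrt(len(phenos) - 3)
    return {
        "r": float(r),
        "p": float(p),
        "ci_low": float(np.tanh(z - half)),
        "ci_high": float(np.tanh(z + half)),
        "n": len(phenos),
        "degenerate": False,
    }
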