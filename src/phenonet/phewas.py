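"""Multi-phenotype association scan with covariate adjustment.

Linear models are fit by exact least squares (vectorized across variants via
Frisch-Waugh residualization when a variant has no missing calls); logistic
models use maximum likelihood through statsmodels.  Both report Wald tests
for the dosage term.  Also provides PCA covariates, greedy LD pruning, the
LD-aware Bonferroni threshold and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .datatypes import AssociationRecord, GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

#: Defaults mirroring the published analysis set-up.
GENOMEWIDE_P = 4.92e-10
EXPLORATORY_P = 1e-4
PRUNE_R2 = 0.3


@dataclass
class PCScores:
    """Top-k principal-component scores over individuals."""

    individuals: List[str]
    scores: np.ndarray  # (n_individuals, k)

    @property
    def k(self) -> int:
        return self.scores.shape[1]


@dataclass
class PheWASRun:
    """Complete output of one association scan."""

    records: List[AssociationRecord]
    covariate_names: List[str]
    n_phenotypes: int
    n_variants: int
    thresholds: Dict[str, float] = field(
        default_factory=lambda: {
            "genomewide": GENOMEWIDE_P,
            "exploratory": EXPLORATORY_P,
        }
    )
    n_monomorphic_skipped: int = 0
    flagged: List[Tuple[str, str, str]] = field(default_factory=list)
    skipped_phenotypes: List[Tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (
            0 < self.thresholds["genomewide"] <= self.thresholds["exploratory"]
        ):
            raise ValueError("thresholds must be positive, genomewide <= exploratory")
        seen = set()
        for r in self.records:
            key = (r.variant_id, r.phenotype_name)
            if key in seen:
                raise ValueError(f"duplicate record for {key}")
            seen.add(key)
        self._by_key = {
            (r.variant_id, r.phenotype_name): r for r in self.records
        }

    def p_value(self, variant_id: str, phenotype: str) -> Optional[float]:
        rec = self._by_key.get((variant_id, phenotype))
        return rec.p_value if rec is not None else None

    def record(self, variant_id: str, phenotype: str) -> Optional[AssociationRecord]:
        return self._by_key.get((variant_id, phenotype))

    def significant(self, threshold: float) -> List[AssociationRecord]:
        return [r for r in self.records if r.p_value < threshold]


# ---------------------------------------------------------------------------
# principal components


def compute_pcs(genotypes: GenotypeMatrix, k: int = 3) -> PCScores:
    """Top-k PCs of the column-standardized, mean-imputed dosage matrix.

    Component signs are fixed so the largest-magnitude variant loading of
    each component is positive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if genotypes.n_individuals < k + 1:
        raise ValueError("need at least k+1 individuals")
    X = genotypes.mean_imputed()
    n_missing_all = int(np.isnan(genotypes.dosages).all(axis=0).sum())
    if n_missing_all:
        logger.warning("%d all-missing variants excluded from PCA", n_missing_all)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all variants have zero variance; PCA undefined")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    k = min(k, len(S))
    scores = U[:, :k] * S[:k]
    for c in range(k):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            scores[:, c] *= -1.0
    return PCScores(individuals=list(genotypes.individuals), scores=scores)


# ---------------------------------------------------------------------------
# regression primitives


def linear_assoc(
    y: np.ndarray, x: np.ndarray, covariates: Optional[np.ndarray] = None
) -> Tuple[float, float, float, int]:
    """Exact OLS of y on [1, x, covariates]; Wald t-test on the x term.

    Returns (beta, se, two-sided p, n).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    design = [np.ones(n), x]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        design.extend(C[:, j] for j in range(C.shape[1]))
    D = np.column_stack(design)
    p = D.shape[1]
    if n <= p:
        raise ValueError("not enough observations for the model")
    coef, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    if rank < p:
        raise ValueError("design matrix is rank deficient")
    resid = y - D @ coef
    sigma2 = float(resid @ resid) / (n - p)
    cov = sigma2 * np.linalg.inv(D.T @ D)
    beta = float(coef[1])
    se = float(np.sqrt(cov[1, 1]))
    tval = beta / se
    pval = float(2.0 * stats.t.sf(abs(tval), df=n - p))
    return beta, se, max(pval, np.finfo(float).tiny), n


def _vectorized_linear(
    Y: np.ndarray, X: np.ndarray, C: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of y on [C, x_j] for every column x_j at once (Frisch-Waugh).

    C must include the intercept column.  Returns (beta, se, p) arrays; NaN
    where a residualized variant has zero variance.
    """
    n, p_cov = C.shape
    proj = np.linalg.lstsq(C, np.column_stack([X, Y]), rcond=None)[0]
    R = X - C @ proj[:, :-1]
    ry = Y - C @ proj[:, -1]
    ss_x = (R * R).sum(axis=0)
    dof = n - p_cov - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (R * ry[:, None]).sum(axis=0) / ss_x
        rss = (ry @ ry) - beta**2 * ss_x
        rss = np.clip(rss, 0.0, None)
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / ss_x)
        tval = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tval), df=dof)
    pval = np.maximum(pval, np.finfo(float).tiny)
    bad = ~np.isfinite(se) | (se <= 0)
    beta[bad] = np.nan
    return beta, se, pval


def _logistic_assoc(
    y: np.ndarray, x: np.ndarray, C: np.ndarray
) -> Tuple[float, float, float, int, Optional[str]]:
    """Logistic ML fit; returns (beta, se, p, n, flag)."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    D = np.column_stack([C, x])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, D).fit(disp=0, maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        return np.nan, np.nan, np.nan, len(y), type(exc).__name__
    if not res.mle_retvals.get("converged", False):
        return np.nan, np.nan, np.nan, len(y), "non-convergence"
    beta = float(res.params[-1])
    se = float(res.bse[-1])
    if not np.isfinite(se) or se <= 0 or se > 100:
        return np.nan, np.nan, np.nan, len(y), "unstable-se"
    pval = float(2.0 * stats.norm.sf(abs(beta / se)))
    return beta, se, max(pval, np.finfo(float).tiny), len(y), None


# ---------------------------------------------------------------------------
# the scan


def run_phewas(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    pcs: Optional[PCScores] = None,
    model_map: Optional[Dict[str, str]] = None,
    thresholds: Optional[Dict[str, float]] = None,
) -> PheWASRun:
    """Fit outcome ~ dosage + age + sex (+ PCs) for every pair.

    Complete-case per (variant, phenotype): rows missing the phenotype, a
    covariate, or that variant's dosage are dropped from that single test.
    Monomorphic variants (after filtering) are skipped and counted; logistic
    fits hitting perfect separation or non-convergence are flagged with no
    fabricated p-value.
    """
    if genotypes.individuals != phenotypes.individuals:
        raise ValueError("genotype and phenotype sample lists differ")
    covariate_names = ["age", "sex"]
    cov_cols = [phenotypes.covariate_matrix()]
    if pcs is not None:
        if pcs.individuals != genotypes.individuals:
            raise ValueError("PC scores do not match the cohort samples")
        cov_cols.append(pcs.scores)
        covariate_names += [f"PC{i + 1}" for i in range(pcs.k)]
    covs = np.column_stack(cov_cols)
    n = genotypes.n_individuals
    X_all = genotypes.dosages

    records: List[AssociationRecord] = []
    flagged: List[Tuple[str, str, str]] = []
    skipped_phenotypes: List[Tuple[str, str]] = []
    n_monomorphic = 0
    variant_ids = genotypes.variant_ids

    for pheno in phenotypes.phenotype_names:
        y_full = phenotypes.phenotype(pheno)
        model = (model_map or {}).get(
            pheno, "logistic" if phenotypes.kind(pheno) == "binary" else "linear"
        )
        base_mask = np.isfinite(y_full) & np.isfinite(covs).all(axis=1)
        if model == "logistic":
            cases = np.nansum(y_full[base_mask])
            if cases == 0 or cases == base_mask.sum():
                skipped_phenotypes.append(
                    (pheno, "no cases or no controls after complete-case filter")
                )
                logger.info("phenotype %s skipped: degenerate case counts", pheno)
                continue
        if base_mask.sum() < covs.shape[1] + 3:
            skipped_phenotypes.append((pheno, "too few complete cases"))
            continue
        y = y_full[base_mask]
        C = np.column_stack([np.ones(base_mask.sum()), covs[base_mask]])
        X = X_all[base_mask, :]
        col_missing = np.isnan(X).any(axis=0)
        col_sd = np.nanstd(X, axis=0)
        mono = col_sd == 0
        n_monomorphic += int(mono.sum())

        if model == "linear":
            easy = ~col_missing & ~mono
            if easy.any():
                beta, se, pval = _vectorized_linear(y, X[:, easy], C)
                for pos, j in enumerate(np.flatnonzero(easy)):
                    if not np.isfinite(beta[pos]):
                        flagged.append((variant_ids[j], pheno, "degenerate-fit"))
                        continue
                    records.append(
                        AssociationRecord(
                            variant_id=variant_ids[j],
                            phenotype_name=pheno,
                            effect=float(beta[pos]),
                            standard_error=float(se[pos]),
                            p_value=float(pval[pos]),
                            n_samples=len(y),
                            model="linear",
                        )
                    )
            hard = np.flatnonzero(col_missing & ~mono)
        else:
            hard = np.flatnonzero(~mono)

        for j in hard:
            x = X[:, j]
            ok = np.isfinite(x)
            if ok.sum() < C.shape[1] + 2 or np.std(x[ok]) == 0:
                n_monomorphic += int(np.std(x[ok]) == 0) if ok.any() else 0
                continue
            if model == "linear":
                try:
                    b, s, p, nn = linear_assoc(y[ok], x[ok], C[ok, 1:])
                except ValueError as exc:
                    flagged.append((variant_ids[j], pheno, str(exc)))
                    continue
                flag = None
            else:
                b, s, p, nn, flag = _logistic_assoc(y[ok], x[ok], C[ok])
            if flag is not None or not np.isfinite(p):
                flagged.append((variant_ids[j], pheno, flag or "degenerate-fit"))
                continue
            records.append(
                AssociationRecord(
                    variant_id=variant_ids[j],
                    phenotype_name=pheno,
                    effect=b,
                    standard_error=s,
                    p_value=p,
                    n_samples=nn,
                    model=model,
                )
            )

    return PheWASRun(
        records=records,
        covariate_names=covariate_names,
        n_phenotypes=len(phenotypes.phenotype_names),
        n_variants=genotypes.n_variants,
        thresholds=thresholds
        or {"genomewide": GENOMEWIDE_P, "exploratory": EXPLORATORY_P},
        n_monomorphic_skipped=n_monomorphic,
        flagged=flagged,
        skipped_phenotypes=skipped_phenotypes,
    )


# ---------------------------------------------------------------------------
# LD pruning and thresholds


def ld_prune(
    genotypes: GenotypeMatrix,
    r2_threshold: float = PRUNE_R2,
    window: int = 500,
) -> List[str]:
    """Greedy position-order pruning to an approximately independent set.

    A variant is retained unless its squared correlation with any
    already-retained variant among the previous ``window`` retained-or-seen
    positions exceeds ``r2_threshold``.  Deterministic given input order.
    """
    if not (0.0 < r2_threshold < 1.0):
        raise ValueError("r2_threshold must be in (0, 1)")
    m = genotypes.n_variants
    if m == 0:
        return []
    order = sorted(
        range(m),
        key=lambda j: (genotypes.variants[j].chromosome, genotypes.variants[j].position),
    )
    X = genotypes.mean_imputed()
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    n = Z.shape[0]
    retained: List[Tuple[int, int]] = []  # (scan rank, column index)
    for rank, j in enumerate(order):
        chrom = genotypes.variants[j].chromosome
        keep = True
        for r_rank, i in reversed(retained):
            if rank - r_rank > window:
                break
            if genotypes.variants[i].chromosome != chrom:
                continue
            r = float(Z[:, i] @ Z[:, j]) / n
            if r * r > r2_threshold:
                keep = False
                break
        if keep:
            retained.append((rank, j))
    return [genotypes.variants[j].id for _, j in retained]


def ld_aware_threshold(
    n_independent: int, n_phenotypes: int, alpha: float = 0.05
) -> float:
    """Bonferroni alpha divided by (independent variants x phenotypes)."""
    if n_independent < 1 or n_phenotypes < 1:
        raise ValueError("counts must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / (n_independent * n_phenotypes)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
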