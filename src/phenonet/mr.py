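"""Split-sample, network-wide Mendelian randomization.

Instruments are discovered on the full-sample scan (exposure p below the
exploratory threshold, variants marginally associated with the outcome at
p < 0.01 removed, then strict LD clumping); effect estimates come from two
disjoint half-cohorts: exposure betas from split A, outcome betas from
split B.  IVW is the primary estimator (fixed-effect, with a multiplicative
random-effects variant behind a flag); MR-Egger and the weighted median act
as sensitivity analyses when at least three instruments survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy import stats

from .datatypes import GenotypeMatrix, PhenotypeTable
from .phewas import EXPLORATORY_P, PheWASRun, fdr_adjust

logger = logging.getLogger(__name__)

OUTCOME_SCREEN_P = 0.01
CLUMP_R2 = 0.001
CLUMP_KB = 10_000
MEDIAN_BOOTSTRAP = 1000


@dataclass
class InstrumentSet:
    """Per-variant exposure/outcome effects for one ordered phenotype pair."""

    exposure_name: str
    variant_ids: List[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.variant_ids)
        for arr in (
            self.beta_exposure,
            self.se_exposure,
            self.beta_outcome,
            self.se_outcome,
        ):
            if len(arr) != k:
                raise ValueError("instrument arrays must share one length")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def n_iv(self) -> int:
        return len(self.variant_ids)

    def drop_null_exposure(self) -> "InstrumentSet":
        """Remove instruments with exactly zero exposure beta (warned)."""
        keep = self.beta_exposure != 0.0
        if not keep.all():
            logger.warning(
                "%s: %d instruments with beta_X = 0 excluded",
                self.exposure_name,
                int((~keep).sum()),
            )
        return InstrumentSet(
            self.exposure_name,
            [v for v, k in zip(self.variant_ids, keep) if k],
            self.beta_exposure[keep],
            self.se_exposure[keep],
            self.beta_outcome[keep],
            self.se_outcome[keep],
        )

    def harmonized(self) -> "InstrumentSet":
        """Flip instruments so every exposure beta is positive."""
        sign = np.where(self.beta_exposure < 0, -1.0, 1.0)
        return InstrumentSet(
            self.exposure_name,
            list(self.variant_ids),
            self.beta_exposure * sign,
            self.se_exposure.copy(),
            self.beta_outcome * sign,
            self.se_outcome.copy(),
        )


@dataclass
class MRResult:
    exposure: str
    outcome: str
    ivw_estimate: float = np.nan
    ivw_se: float = np.nan
    ivw_p: float = np.nan
    egger_estimate: float = np.nan
    egger_intercept: float = np.nan
    egger_p: float = np.nan
    egger_intercept_p: float = np.nan
    median_estimate: float = np.nan
    median_se: float = np.nan
    median_p: float = np.nan
    n_iv: int = 0
    q_value: float = np.nan
    testable: bool = True


# ---------------------------------------------------------------------------
# cohort splitting and clumping


def split_sample(
    genotypes: GenotypeMatrix, phenotypes: PhenotypeTable, seed: int = 0
) -> Tuple[Tuple[GenotypeMatrix, PhenotypeTable], Tuple[GenotypeMatrix, PhenotypeTable]]:
    """Random disjoint halves (sizes differing by at most one)."""
    n = genotypes.n_individuals
    if n < 2:
        raise ValueError("need at least 2 individuals to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half = n // 2
    a, b = sorted(perm[:half]), sorted(perm[half:])
    return (
        (genotypes.subset_individuals(a), phenotypes.subset_individuals(a)),
        (genotypes.subset_individuals(b), phenotypes.subset_individuals(b)),
    )


def clump(
    genotypes: GenotypeMatrix,
    variant_ids: Sequence[str],
    p_values: Dict[str, float],
    r2: float = CLUMP_R2,
    kb: int = CLUMP_KB,
) -> List[str]:
    """Greedy p-value-ranked clumping to index variants.

    Retain the best remaining variant; discard every variant on the same
    chromosome within ``kb`` kilobases whose squared correlation with it
    exceeds ``r2``; repeat.
    """
    ids = [v for v in variant_ids if v in p_values]
    if not ids:
        return []
    X = genotypes.mean_imputed()
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    n = Z.shape[0]
    meta = {v.id: v for v in genotypes.variants}
    remaining = sorted(ids, key=lambda v: (p_values[v], v))
    retained: List[str] = []
    removed = set()
    for vid in remaining:
        if vid in removed:
            continue
        retained.append(vid)
        vi = meta[vid]
        ji = genotypes.index_of(vid)
        for other in remaining:
            if other == vid or other in removed:
                continue
            vo = meta[other]
            if vo.chromosome != vi.chromosome:
                continue
            if abs(vo.position - vi.position) > kb * 1000:
                continue
            r = float(Z[:, ji] @ Z[:, genotypes.index_of(other)]) / n
            if r * r > r2:
                removed.add(other)
    return retained


# ---------------------------------------------------------------------------
# estimators


def ivw(
    instruments: InstrumentSet, random_effects: bool = False
) -> Tuple[float, float, float]:
    """Fixed-effect inverse-variance-weighted estimate.

    Equivalent to a zero-intercept regression of beta_Y on beta_X with
    weights 1/se_Y^2.  ``random_effects`` inflates the se by the square root
    of the residual overdispersion when it exceeds one.
    """
    ins = instruments.drop_null_exposure()
    if ins.n_iv == 0:
        raise ValueError("no usable instruments (all exposure betas zero)")
    bx, by, sy = ins.beta_exposure, ins.beta_outcome, ins.se_outcome
    w = (bx / sy) ** 2
    ratios = by / bx
    estimate = float(np.sum(w * ratios) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    if random_effects and ins.n_iv > 1:
        resid = (by - estimate * bx) / sy
        phi = float(resid @ resid) / (ins.n_iv - 1)
        se *= max(1.0, np.sqrt(phi))
    p = float(2.0 * stats.norm.sf(abs(estimate / se)))
    return estimate, se, max(p, np.finfo(float).tiny)


def egger(
    instruments: InstrumentSet,
) -> Optional[Tuple[float, float, float, float]]:
    """MR-Egger: weighted regression with a free pleiotropy intercept.

    Returns (slope, intercept, p_slope, p_intercept), or None when fewer
    than 3 instruments make the fit not estimable.
    """
    ins = instruments.drop_null_exposure().harmonized()
    if ins.n_iv < 3:
        return None
    bx, by, sy = ins.beta_exposure, ins.beta_outcome, ins.se_outcome
    w = 1.0 / sy**2
    D = np.column_stack([np.ones(ins.n_iv), bx])
    Wsq = np.sqrt(w)
    coef, _, rank, _ = np.linalg.lstsq(D * Wsq[:, None], by * Wsq, rcond=None)
    if rank < 2:
        return None
    resid = (by - D @ coef) * Wsq
    dof = ins.n_iv - 2
    sigma2 = max(float(resid @ resid) / dof, 1.0)  # no underdispersion credit
    cov = sigma2 * np.linalg.inv((D * w[:, None]).T @ D)
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    p_slope = float(2.0 * stats.t.sf(abs(slope / se_slope), df=dof))
    p_int = float(2.0 * stats.t.sf(abs(intercept / se_int), df=dof))
    return slope, intercept, max(p_slope, np.finfo(float).tiny), max(
        p_int, np.finfo(float).tiny
    )


def egger_intercept_ci(
    instruments: InstrumentSet, level: float = 0.95
) -> Optional[Tuple[float, float]]:
    """Confidence interval for the Egger pleiotropy intercept."""
    ins = instruments.drop_null_exposure().harmonized()
    if ins.n_iv < 3:
        return None
    bx, by, sy = ins.beta_exposure, ins.beta_outcome, ins.se_outcome
    w = 1.0 / sy**2
    D = np.column_stack([np.ones(ins.n_iv), bx])
    Wsq = np.sqrt(w)
    coef, _, _, _ = np.linalg.lstsq(D * Wsq[:, None], by * Wsq, rcond=None)
    resid = (by - D @ coef) * Wsq
    dof = ins.n_iv - 2
    sigma2 = max(float(resid @ resid) / dof, 1.0)
    cov = sigma2 * np.linalg.inv((D * w[:, None]).T @ D)
    half = stats.t.ppf(0.5 + level / 2.0, df=dof) * np.sqrt(cov[0, 0])
    return float(coef[0] - half), float(coef[0] + half)


def weighted_median(
    instruments: InstrumentSet, n_bootstrap: int = MEDIAN_BOOTSTRAP, seed: int = 0
) -> Optional[Tuple[float, float, float]]:
    """Inverse-variance weighted median of per-instrument ratio estimates.

    The se comes from a seeded bootstrap over instruments.  Returns None
    below 3 instruments.
    """
    ins = instruments.drop_null_exposure()
    if ins.n_iv < 3:
        return None
    ratios = ins.beta_outcome / ins.beta_exposure
    weights = (ins.beta_exposure / ins.se_outcome) ** 2
    estimate = _weighted_median(ratios, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    idx_all = np.arange(ins.n_iv)
    for b in range(n_bootstrap):
        idx = rng.choice(idx_all, size=ins.n_iv, replace=True)
        boots[b] = _weighted_median(ratios[idx], weights[idx])
    se = float(boots.std(ddof=1))
    if se == 0:
        se = np.finfo(float).tiny ** 0.5
    p = float(2.0 * stats.norm.sf(abs(estimate / se)))
    return float(estimate), se, max(p, np.finfo(float).tiny)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return float(np.interp(0.5, cw, v))


# ---------------------------------------------------------------------------
# instrument assembly and the causal map


def select_instruments(
    exposure: str,
    outcome: str,
    run_full: PheWASRun,
    run_a: PheWASRun,
    run_b: PheWASRun,
    genotypes: GenotypeMatrix,
    iv_p: float = EXPLORATORY_P,
    outcome_p: float = OUTCOME_SCREEN_P,
    clump_r2: float = CLUMP_R2,
    clump_kb: int = CLUMP_KB,
) -> Optional[InstrumentSet]:
    """Build the instrument set for one ordered pair, or None if empty.

    Discovery: full-sample exposure p < ``iv_p``; screen: full-sample
    outcome p < ``outcome_p`` removes the variant; strict clumping by
    exposure p; estimates taken from split A (exposure) and split B
    (outcome).
    """
    candidates = {}
    for rec in run_full.records:
        if rec.phenotype_name == exposure and rec.p_value < iv_p:
            candidates[rec.variant_id] = rec.p_value
    for rec in run_full.records:
        if (
            rec.phenotype_name == outcome
            and rec.variant_id in candidates
            and rec.p_value < outcome_p
        ):
            del candidates[rec.variant_id]
    if not candidates:
        return None
    index = clump(genotypes, sorted(candidates), candidates, r2=clump_r2, kb=clump_kb)
    rows = []
    for vid in index:
        ra = run_a.record(vid, exposure)
        rb = run_b.record(vid, outcome)
        if ra is None or rb is None:
            continue
        rows.append((vid, ra.effect, ra.standard_error, rb.effect, rb.standard_error))
    if not rows:
        return None
    vids, bx, sx, by, sy = zip(*rows)
    return InstrumentSet(
        exposure_name=exposure,
        variant_ids=list(vids),
        beta_exposure=np.array(bx),
        se_exposure=np.array(sx),
        beta_outcome=np.array(by),
        se_outcome=np.array(sy),
    )


def causal_map(
    run_full: PheWASRun,
    run_a: PheWASRun,
    run_b: PheWASRun,
    network: nx.Graph,
    genotypes: GenotypeMatrix,
    fdr_cutoff: float = 0.05,
    iv_p: float = EXPLORATORY_P,
    outcome_p: float = OUTCOME_SCREEN_P,
    clump_r2: float = CLUMP_R2,
    clump_kb: int = CLUMP_KB,
    seed: int = 0,
) -> Tuple[List[MRResult], Dict[frozenset, str]]:
    """Test both orderings of every network edge; FDR-adjust globally.

    Returns the per-ordered-pair results and a direction call per unordered
    pair: forward / reverse (relative to the sorted pair ordering),
    bidirectional, or none.  Pairs with no surviving instruments are
    recorded as untestable.
    """
    results: List[MRResult] = []
    for a, b in sorted(map(lambda e: tuple(sorted(e)), network.edges())):
        for exposure, outcome in ((a, b), (b, a)):
            ins = select_instruments(
                exposure, outcome, run_full, run_a, run_b, genotypes,
                iv_p=iv_p, outcome_p=outcome_p,
                clump_r2=clump_r2, clump_kb=clump_kb,
            )
            res = MRResult(exposure=exposure, outcome=outcome)
            if ins is None or ins.drop_null_exposure().n_iv == 0:
                res.testable = False
                results.append(res)
                continue
            res.n_iv = ins.n_iv
            res.ivw_estimate, res.ivw_se, res.ivw_p = ivw(ins)
            eg = egger(ins)
            if eg is not None:
                (
                    res.egger_estimate,
                    res.egger_intercept,
                    res.egger_p,
                    res.egger_intercept_p,
                ) = eg
            med = weighted_median(ins, seed=seed)
            if med is not None:
                res.median_estimate, res.median_se, res.median_p = med
            results.append(res)

    tested = [r for r in results if r.testable]
    if tested:
        qs = fdr_adjust([r.ivw_p for r in tested])
        for r, q in zip(tested, qs):
            r.q_value = float(q)

    calls: Dict[frozenset, str] = {}
    by_pair: Dict[frozenset, List[MRResult]] = {}
    for r in results:
        by_pair.setdefault(frozenset((r.exposure, r.outcome)), []).append(r)
    for pair, rs in by_pair.items():
        a, b = sorted(pair)
        fwd = next((r for r in rs if r.exposure == a), None)
        rev = next((r for r in rs if r.exposure == b), None)
        sig_f = fwd is not None and fwd.testable and fwd.q_value < fdr_cutoff
        sig_r = rev is not None and rev.testable and rev.q_value < fdr_cutoff
        if sig_f and sig_r:
            calls[pair] = "bidirectional"
        elif sig_f:
            calls[pair] = "forward"
        elif sig_r:
            calls[pair] = "reverse"
        else:
            calls[pair] = "none"
    return results, calls


def write_causal_map(
    results: Sequence[MRResult], calls: Dict[frozenset, str], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "exposure\toutcome\tn_iv\tivw_estimate\tivw_se\tivw_p\t"
            "egger_estimate\tegger_intercept\tmedian_estimate\tq_value\t"
            "testable\tdirection_call\n"
        )
        for r in results:
            call = calls.get(frozenset((r.exposure, r.outcome)), "none")
            fh.write(
                f"{r.exposure}\t{r.outcome}\t{r.n_iv}\t{r.ivw_estimate}\t"
                f"{r.ivw_se}\t{r.ivw_p}\t{r.egger_estimate}\t"
                f"{r.egger_intercept}\t{r.median_estimate}\t{r.q_value}\t"
                f"{int(r.testable)}\t{call}\n"
            )
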