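"""SNP association under both phenotype definitions.

The sum-score arm regresses Likert sums on the additive genotype by OLS
(delegated to :mod:`phenofactor.sumscore`).  The latent arm extends the
measurement model to a MIMIC model: the SNP is regressed onto the latent
factors, entering the limited-information system through the implied
item-genotype correlations lambda_j * gamma_f / sd(y*_j), and loadings
and SNP paths are estimated simultaneously by DWLS.  With the genotype
standardised and each factor's total variance fixed at 1, the SNP
explains r2_percent = 100 * gamma^2 of the factor's variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .exceptions import DegeneratePredictorError, InvalidParameterError, InvalidSpecError
from .measurement import FitResult, MeasurementModelSpec, fit_dwls
from .polychoric import CorrelationStructure, assemble_correlation_structure, polyserial_corr, smooth_correlation_matrix
from .sumscore import compute_sum_scores, regress_sum_on_snp
from .synthetic import DIMENSIONS, GenotypeVector, ItemResponseMatrix

PHENOTYPES = ("global",) + DIMENSIONS


@dataclass
class AssociationResult:
    """One SNP x phenotype x method association."""

    snp_id: str
    phenotype: str       # global | somatic | social | anxiety | depression
    method: str          # sum_score | bifactor | first_order
    gamma: float
    se: float
    wald_z: float
    p: float
    r2_percent: float
    n: int


def qc_filter(genotypes: dict[str, GenotypeVector],
              call_rate_min: float = 0.90,
              maf_min: float = 0.05):
    """Drop SNPs failing the genotyping integrity thresholds.

    A SNP is dropped when its call rate is <= ``call_rate_min`` or its
    minor allele frequency is <= ``maf_min``.  Returns the retained
    table and a report naming each dropped SNP and the reason.
    """
    kept: dict[str, GenotypeVector] = {}
    rows = []
    for snp_id, g in genotypes.items():
        reasons = []
        if not (g.call_rate > call_rate_min):
            reasons.append("call rate")
        if not (g.maf > maf_min):
            reasons.append("MAF")
        if reasons:
            rows.append({"snp_id": snp_id, "reason": "; ".join(reasons),
                         "call_rate": g.call_rate, "maf": g.maf})
        else:
            kept[snp_id] = g
    report = pd.DataFrame(rows, columns=["snp_id", "reason", "call_rate", "maf"])
    return kept, report


def _attach_genotype(item_stats: CorrelationStructure,
                     items: ItemResponseMatrix,
                     g: GenotypeVector) -> CorrelationStructure:
    """Add item-genotype polyserials to a cached item-only structure.

    Valid only when the genotype is complete on the rows the cache was
    built from (the cache's complete-case set)."""
    mask = items.complete_mask()
    X = items.data.iloc[np.flatnonzero(mask)].to_numpy()
    gv = g.values[np.flatnonzero(mask)]
    p = len(item_stats.labels)
    g_rho = np.empty(p)
    g_avar = np.empty(p)
    for j in range(p):
        g_rho[j], g_avar[j] = polyserial_corr(X[:, j], gv)
    struct = CorrelationStructure(
        labels=list(item_stats.labels), rho=item_stats.rho.copy(),
        avar=item_stats.avar, n=item_stats.n,
        thresholds=item_stats.thresholds, g_rho=g_rho, g_avar=g_avar,
    )
    full, did = smooth_correlation_matrix(struct.full_matrix())
    if did:
        struct.rho = full[:p, :p]
        struct.g_rho = full[:p, p]
        struct.smoothed = True
    return struct


def fit_mimic(items: ItemResponseMatrix, g: GenotypeVector,
              spec: MeasurementModelSpec,
              item_stats: CorrelationStructure | None = None,
              options: dict | None = None):
    """Fit the MIMIC model and return (results, FitResult).

    ``results`` holds one :class:`AssociationResult` per factor.
    Complete cases only; a genotype that is constant after filtering
    raises :class:`DegeneratePredictorError`.  ``item_stats`` may carry a
    precomputed item-only correlation structure (the item polychorics do
    not depend on the SNP); it is reused only when the genotype is
    complete on the item-complete rows.
    """
    if spec.kind not in ("bifactor", "first_order"):
        raise InvalidSpecError("MIMIC fit requires a bifactor or first_order spec")
    mask = items.complete_mask() & g.complete_mask()
    gv = g.values[mask]
    if gv.size == 0 or np.ptp(gv) == 0:
        raise DegeneratePredictorError(
            f"genotype {g.snp_id!r} is constant after complete-case filtering"
        )
    reusable = item_stats is not None and bool(
        g.complete_mask()[items.complete_mask()].all()
    )
    if reusable:
        stats = _attach_genotype(item_stats, items, g)
    else:
        stats = assemble_correlation_structure(items, g, complete_case=True)
    fit = fit_dwls(stats, spec, options=options, include_genotype=True)
    results = []
    for f in spec.factors:
        gamma = fit.gammas[f]
        se = fit.se.get(f"gamma[{f}]", float("nan"))
        z = gamma / se if se and np.isfinite(se) and se > 0 else float("nan")
        p = float(2.0 * ndtr(-abs(z))) if np.isfinite(z) else float("nan")
        results.append(AssociationResult(
            snp_id=g.snp_id, phenotype="global" if f == "global" else f,
            method=spec.kind, gamma=float(gamma), se=float(se),
            wald_z=float(z), p=p,
            r2_percent=float(np.clip(100.0 * gamma * gamma, 0.0, 100.0)),
            n=fit.n,
        ))
    return results, fit


def sum_score_association(items: ItemResponseMatrix,
                          g: GenotypeVector) -> list[AssociationResult]:
    """OLS association of the global and subscale sums with one SNP."""
    scores = compute_sum_scores(items)
    gv = g.values[scores.complete_index]
    ok = ~np.isnan(gv)
    results = []
    for phen in PHENOTYPES:
        y = scores.score(phen)[ok]
        slope, r2, p = regress_sum_on_snp(y, gv[ok])
        n = int(ok.sum())
        # t statistic reported in the wald_z slot for symmetry with the
        # latent arm; p stays the exact t-based OLS p-value
        t = np.sign(slope) * np.sqrt(
            max(r2, 0.0) / 100.0 * (n - 2) / max(1.0 - r2 / 100.0, 1e-12)
        )
        results.append(AssociationResult(
            snp_id=g.snp_id, phenotype=phen, method="sum_score",
            gamma=slope, se=float("nan"), wald_z=float(t),
            p=p, r2_percent=r2, n=n,
        ))
    return results


def effect_size_density(values, grid_size: int = 512):
    """Gaussian kernel density of r2_percent values.

    Returns ``(grid, density)`` with trapezoid integral within 1e-3 of 1.
    Bandwidth is Silverman's rule with a small floor so that degenerate
    (all-equal) inputs yield a single narrow peak instead of failing.
    """
    v = np.asarray([r.r2_percent if isinstance(r, AssociationResult) else r
                    for r in values], dtype=float)
    if v.size < 2:
        raise InvalidParameterError("need at least 2 effect sizes for a density")
    sd = v.std(ddof=1)
    iqr = np.subtract(*np.percentile(v, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    bw = 0.9 * spread * v.size ** (-0.2) if spread > 0 else 0.0
    bw = max(bw, 1e-2 * max(np.abs(v).max(), 1.0) * 1e-1, 1e-3)
    grid = np.linspace(v.min() - 5 * bw, v.max() + 5 * bw, grid_size)
    z = (grid[:, None] - v[None, :]) / bw
    density = np.exp(-0.5 * z * z).sum(axis=1) / (v.size * bw * np.sqrt(2 * np.pi))
    return grid, density


def results_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Flat table: one row per SNP x phenotype x method."""
    return pd.DataFrame([{
        "snp_id": r.snp_id, "phenotype": r.phenotype, "method": r.method,
        "gamma": r.gamma, "se": r.se, "wald_z": r.wald_z, "p": r.p,
        "r2_percent": r.r2_percent, "n": r.n,
    } for r in results])


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; raw effect sizes are the default
    comparison for a-priori candidate SNPs)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        prev = min(prev, p[i] * m / (rank + 1))
        adj[i] = prev
    return adj
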