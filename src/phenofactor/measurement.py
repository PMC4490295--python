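"""Measurement-model specification and DWLS fitting on polychoric matrices.

Three rival structures for p ordinal indicators:

* ``bifactor`` — every indicator loads on one general factor and exactly
  one of four specific domain factors; all factor covariances fixed at 0.
* ``first_order`` — every indicator loads on exactly one of the four
  domain factors; the six factor correlations are free.
* ``baseline`` — the independence model (no loadings); supplies the
  reference chi-square for CFI/TLI.

Estimation is diagonally weighted least squares (a WLSMV-like limited-
information estimator): with s the vector of sample polychoric (and,
for MIMIC fits, item-genotype polyserial) correlations,

    F(theta) = sum_m w_m (s_m - sigma_m(theta))^2,

where sigma(theta) is the model-implied correlation under theta
parameterization (latent-response residual variances fixed at 1, the
implied covariance rescaled to the correlation metric) and w_m is the
inverse scaled asymptotic variance of s_m.  Minimisation is quasi-Newton
(L-BFGS-B) with the analytic gradient of sigma, deterministic start
values, gradient tolerance 1e-8 and at most 500 iterations.  The test
statistic is chi2 = (n-1) * F_hat; with diagonal weights matched to the
diagonal of the asymptotic covariance, the Satterthwaite mean-scaling
factor is identically 1, so no further scaling is applied.  Standard
errors are the sandwich form under the same diagonal approximation.

Fit-index conventions: RMSEA = sqrt(max(chi2-df,0)/(df*(n-1)));
CFI = 1 - max(chi2-df,0)/max(chi2_b-df_b, chi2-df, 0);
TLI = ((chi2_b/df_b)-(chi2/df)) / ((chi2_b/df_b)-1).  The usual cutpoint
annotations (CFI/TLI > 0.90 acceptable, > 0.95 excellent; RMSEA < 0.05
close, < 0.08 minimally acceptable) are reported as text only, never
applied as filters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import IdentificationError, InvalidSpecError
from .polychoric import CorrelationStructure
from .synthetic import DIMENSIONS

logger = logging.getLogger(__name__)

KINDS = ("bifactor", "first_order", "baseline")


@dataclass
class MeasurementModelSpec:
    """Loading pattern and factor-covariance constraints for one model."""

    kind: str
    dim_map: dict[str, str]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise InvalidSpecError(f"unknown model kind {self.kind!r}")
        for lab, dim in self.dim_map.items():
            if dim not in DIMENSIONS:
                raise InvalidSpecError(f"indicator {lab!r} maps to unknown "
                                       f"dimension {dim!r}")

    @property
    def indicators(self) -> list[str]:
        return list(self.dim_map)

    @property
    def p(self) -> int:
        return len(self.dim_map)

    @property
    def factors(self) -> list[str]:
        if self.kind == "bifactor":
            return ["global"] + list(DIMENSIONS)
        if self.kind == "first_order":
            return list(DIMENSIONS)
        return []

    def loading_pattern(self) -> list[tuple[str, str]]:
        """Free loadings as (indicator, factor) pairs."""
        if self.kind == "baseline":
            return []
        pat = []
        for lab in self.indicators:
            if self.kind == "bifactor":
                pat.append((lab, "global"))
            pat.append((lab, self.dim_map[lab]))
        return pat

    def free_factor_corrs(self) -> list[tuple[str, str]]:
        if self.kind != "first_order":
            return []
        f = self.factors
        return [(f[i], f[j]) for i in range(len(f)) for j in range(i + 1, len(f))]


def count_df(spec: MeasurementModelSpec, include_genotype: bool = False,
             n_gammas: int | None = None) -> int:
    """Degrees of freedom of the limited-information chi-square test.

    df = free sample correlations - (free loadings + free factor
    correlations [+ free SNP paths]).  Thresholds are excluded on both
    sides: they are saturated against the marginal proportions.
    """
    p = spec.p
    q = p * (p - 1) // 2
    t = len(spec.loading_pattern()) + len(spec.free_factor_corrs())
    if include_genotype:
        q += p
        t += len(spec.factors) if n_gammas is None else n_gammas
    df = q - t
    if df < 0:
        raise IdentificationError(f"negative degrees of freedom ({df})")
    return df


@dataclass
class FitResult:
    """Parameter estimates and global fit of one DWLS model fit."""

    kind: str
    loadings: pd.DataFrame            # p x m, zeros where fixed
    factor_corr: pd.DataFrame | None  # first_order only
    gammas: dict[str, float] | None   # MIMIC only
    thresholds: dict[str, np.ndarray]
    discrepancy: float
    chi_square: float
    df: int
    chi_square_baseline: float
    df_baseline: int
    rmsea: float
    cfi: float
    tli: float
    converged: bool
    n_iterations: int
    se: dict[str, float]
    n: int
    messages: list[str] = field(default_factory=list)

    def indices_annotation(self) -> str:
        notes = []
        notes.append("RMSEA %.3f (<0.05 close, <0.08 minimally acceptable)"
                     % self.rmsea)
        notes.append("CFI %.3f, TLI %.3f (>0.90 acceptable, >0.95 excellent)"
                     % (self.cfi, self.tli))
        return "; ".join(notes)


def fit_indices(chi_square: float, df: int, chi_square_baseline: float,
                df_baseline: int, n: int):
    """(RMSEA, CFI, TLI) from the target and baseline chi-squares."""
    if df <= 0 or df_baseline <= 0:
        raise InvalidSpecError("df and df_baseline must be positive")
    if n <= 1:
        raise InvalidSpecError("n must exceed 1")
    if df_baseline <= df and chi_square_baseline < chi_square:
        warnings.warn("baseline model fits better than target model",
                      stacklevel=2)
    excess = max(chi_square - df, 0.0)
    rmsea = float(np.sqrt(excess / (df * (n - 1))))
    denom = max(chi_square_baseline - df_baseline, chi_square - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - excess / denom
    ratio_b = chi_square_baseline / df_baseline
    ratio = chi_square / df
    tli = 1.0 if ratio_b == 1.0 else (ratio_b - ratio) / (ratio_b - 1.0)
    return rmsea, float(cfi), float(tli)


# --------------------------------------------------------------------------
# parameter layout and model-implied moments


class _ParamLayout:
    """Index bookkeeping for the free-parameter vector
    [loadings..., factor correlations..., gammas...]."""

    def __init__(self, spec: MeasurementModelSpec, with_genotype: bool,
                 fixed_gammas: set[str] | None = None):
        self.spec = spec
        self.factors = spec.factors
        self.findex = {f: i for i, f in enumerate(self.factors)}
        self.labels = spec.indicators
        self.lindex = {lab: i for i, lab in enumerate(self.labels)}
        self.loadings = spec.loading_pattern()
        self.corrs = spec.free_factor_corrs()
        self.fixed_gammas = set(fixed_gammas or ())
        self.with_genotype = with_genotype
        self.gammas = ([f for f in self.factors if f not in self.fixed_gammas]
                       if with_genotype else [])
        self.n_load = len(self.loadings)
        self.n_corr = len(self.corrs)
        self.n_gamma = len(self.gammas)
        self.size = self.n_load + self.n_corr + self.n_gamma
        self.names = (
            [f"lambda[{lab},{f}]" for lab, f in self.loadings]
            + [f"phi[{a},{b}]" for a, b in self.corrs]
            + [f"gamma[{f}]" for f in self.gammas]
        )

    def start(self, options: dict) -> np.ndarray:
        x = np.empty(self.size)
        sg = options.get("start_general", 0.5)
        ss = options.get("start_specific", 0.3)
        sc = options.get("start_corr", 0.3)
        for i, (lab, f) in enumerate(self.loadings):
            if self.spec.kind == "bifactor":
                x[i] = sg if f == "global" else ss
            else:
                x[i] = sg
        x[self.n_load:self.n_load + self.n_corr] = sc
        x[self.n_load + self.n_corr:] = 0.0
        return x

    def bounds(self):
        return ([(-15.0, 15.0)] * self.n_load
                + [(-0.99, 0.99)] * self.n_corr
                + [(-0.99, 0.99)] * self.n_gamma)

    def split(self, x: np.ndarray):
        """Returns (Lambda, free correlations, full m-vector of gammas
        with zeros at factors whose SNP path is fixed to 0)."""
        lam = np.zeros((len(self.labels), len(self.factors)))
        for i, (lab, f) in enumerate(self.loadings):
            lam[self.lindex[lab], self.findex[f]] = x[i]
        phi = x[self.n_load:self.n_load + self.n_corr]
        gam = np.zeros(len(self.factors))
        for i, f in enumerate(self.gammas):
            gam[self.findex[f]] = x[self.n_load + self.n_corr + i]
        return lam, phi, gam

    def factor_cov(self, phi: np.ndarray, gam: np.ndarray) -> np.ndarray:
        """Cov(eta): unit diagonal; off-diagonals are free correlations
        (first_order) or induced by the shared SNP, gamma_f * gamma_f'
        (bifactor MIMIC, disturbances orthogonal)."""
        m = len(self.factors)
        A = np.eye(m)
        if self.spec.kind == "first_order":
            for (a, b), v in zip(self.corrs, phi):
                i, j = self.findex[a], self.findex[b]
                A[i, j] = A[j, i] = v
        elif self.n_gamma:
            G = np.outer(gam, gam)
            A += G - np.diag(np.diag(G))
        return A


def _implied_and_jac(layout: _ParamLayout, x: np.ndarray, iu, want_jac: bool):
    lam, phi, gam = layout.split(x)
    A = layout.factor_cov(phi, gam)
    LA = lam @ A
    M = LA @ lam.T
    d = np.sqrt(np.diag(M) + 1.0)
    D = np.outer(d, d)
    sigma_items = (M / D)[iu]
    with_g = layout.with_genotype
    if with_g:
        c = lam @ gam
        sigma_g = c / d
        sigma = np.concatenate([sigma_items, sigma_g])
    else:
        sigma = sigma_items
    if not want_jac:
        return sigma, None

    p = len(layout.labels)
    q = sigma.size
    J = np.zeros((q, layout.size))
    Sjk = M / D

    def push(t, dM, dc):
        dd = np.diag(dM) / (2.0 * d)
        J[:len(iu[0]), t] = (dM / D)[iu] - Sjk[iu] * (
            dd[iu[0]] / d[iu[0]] + dd[iu[1]] / d[iu[1]]
        )
        if with_g:
            J[len(iu[0]):, t] = (dc / d) - sigma_g * dd / d

    for t, (lab, f) in enumerate(layout.loadings):
        r, cidx = layout.lindex[lab], layout.findex[f]
        v = LA[:, cidx]
        dM = np.zeros((p, p))
        dM[r, :] += v
        dM[:, r] += v
        dc = np.zeros(p)
        if with_g:
            dc[r] = gam[cidx]
        push(t, dM, dc)
    for i, (a, b) in enumerate(layout.corrs):
        fa, fb = layout.findex[a], layout.findex[b]
        dM = np.outer(lam[:, fa], lam[:, fb])
        dM = dM + dM.T
        push(layout.n_load + i, dM, np.zeros(p))
    for i, f in enumerate(layout.gammas):
        t = layout.n_load + layout.n_corr + i
        fi = layout.findex[f]
        dc = lam[:, fi]
        if layout.spec.kind == "first_order":
            dM = np.zeros((p, p))
        else:
            m = len(layout.factors)
            dA = np.zeros((m, m))
            dA[fi, :] += gam
            dA[:, fi] += gam
            dA[fi, fi] = 0.0
            dM = lam @ dA @ lam.T
        push(t, dM, dc)
    return sigma, J


def _sample_vector(stats: CorrelationStructure, with_genotype: bool, iu):
    s = stats.rho[iu]
    w = None
    if stats.avar is not None and np.isfinite(stats.avar[iu]).all():
        w = 1.0 / (stats.n * stats.avar[iu])
    if with_genotype:
        if stats.g_rho is None:
            raise InvalidSpecError("correlation structure carries no genotype column")
        s = np.concatenate([s, stats.g_rho])
        if w is not None:
            wg = 1.0 / (stats.n * stats.g_avar)
            w = np.concatenate([w, wg])
    if w is None or not np.isfinite(w).all():
        w = np.ones_like(s)
    return s, w


def _fix_signs(layout: _ParamLayout, x: np.ndarray) -> np.ndarray:
    """Resolve loading sign indeterminacy: make each factor's loading sum
    positive, flipping its SNP path and correlations to match."""
    lam, phi, gam = layout.split(x)
    flips = {f: (lam[:, i].sum() < 0) for f, i in layout.findex.items()}
    x = x.copy()
    for i, (lab, f) in enumerate(layout.loadings):
        if flips[f]:
            x[i] = -x[i]
    for i, (a, b) in enumerate(layout.corrs):
        if flips[a] != flips[b]:
            x[layout.n_load + i] = -x[layout.n_load + i]
    for i, f in enumerate(layout.gammas):
        if flips[f]:
            t = layout.n_load + layout.n_corr + i
            x[t] = -x[t]
    return x


def fit_dwls(stats: CorrelationStructure, spec: MeasurementModelSpec,
             options: dict | None = None,
             include_genotype: bool = False) -> FitResult:
    """Fit a measurement model (optionally a MIMIC extension) by DWLS.

    ``stats`` supplies the sample polychoric matrix, weights and n.
    Non-convergence returns a FitResult with ``converged=False`` and
    diagnostic messages rather than raising.
    """
    options = dict(options or {})
    labels = spec.indicators
    if list(stats.labels) != labels:
        if set(stats.labels) != set(labels):
            raise InvalidSpecError("correlation structure labels do not match spec")
        order = [stats.labels.index(lab) for lab in labels]
        stats = CorrelationStructure(
            labels=labels,
            rho=stats.rho[np.ix_(order, order)],
            avar=stats.avar[np.ix_(order, order)] if stats.avar is not None else None,
            n=stats.n,
            thresholds=stats.thresholds,
            g_rho=None if stats.g_rho is None else stats.g_rho[order],
            g_avar=None if stats.g_avar is None else stats.g_avar[order],
            smoothed=stats.smoothed,
        )
    p = spec.p
    iu = np.triu_indices(p, k=1)
    layout = _ParamLayout(spec, include_genotype,
                          fixed_gammas=options.get("fix_gamma_zero"))
    s, w = _sample_vector(stats, include_genotype, iu)
    n = stats.n
    df = count_df(spec, include_genotype, n_gammas=layout.n_gamma)
    messages: list[str] = []

    baseline_F = float(np.sum(w * s * s))
    chi2_baseline = (n - 1) * baseline_F
    df_baseline = s.size

    if spec.kind == "baseline":
        rmsea, cfi, tli = fit_indices(chi2_baseline, df_baseline,
                                      chi2_baseline, df_baseline, n)
        return FitResult(
            kind=spec.kind,
            loadings=pd.DataFrame(np.zeros((p, 0)), index=labels),
            factor_corr=None, gammas=None, thresholds=dict(stats.thresholds),
            discrepancy=baseline_F, chi_square=chi2_baseline, df=df_baseline,
            chi_square_baseline=chi2_baseline, df_baseline=df_baseline,
            rmsea=rmsea, cfi=cfi, tli=tli, converged=True, n_iterations=0,
            se={}, n=n,
        )

    def objective(x):
        sigma, J = _implied_and_jac(layout, x, iu, True)
        r = s - sigma
        F = float(np.sum(w * r * r))
        grad = -2.0 * (J.T @ (w * r))
        return F, grad

    gtol = options.get("gtol", 1e-8)
    maxiter = options.get("maxiter", 500)
    res = optimize.minimize(
        objective, layout.start(options), jac=True, method="L-BFGS-B",
        bounds=layout.bounds(),
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-14},
    )
    converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-6
    if not converged:
        messages.append(f"optimizer: {res.message} after {res.nit} iterations; "
                        f"max |gradient| {np.max(np.abs(res.jac)):.2e}")
        logger.warning("DWLS fit did not converge: %s", messages[-1])
    x = _fix_signs(layout, res.x)
    sigma, J = _implied_and_jac(layout, x, iu, True)
    F_hat = float(np.sum(w * (s - sigma) ** 2))
    if np.any(np.abs(sigma) > 1.0 + 1e-10):
        messages.append("Heywood pattern: implied correlation outside [-1, 1]")
        warnings.warn(messages[-1], stacklevel=2)

    chi2 = (n - 1) * F_hat
    rmsea, cfi, tli = fit_indices(chi2, df, chi2_baseline, df_baseline, n)

    JWJ = J.T @ (w[:, None] * J)
    try:
        acov = np.linalg.pinv(JWJ) / (n - 1)
        se_vec = np.sqrt(np.maximum(np.diag(acov), 0.0))
    except np.linalg.LinAlgError:
        se_vec = np.full(layout.size, np.nan)
    se = dict(zip(layout.names, se_vec))

    lam, phi, gam = layout.split(x)
    loadings = pd.DataFrame(lam, index=labels, columns=layout.factors)
    factor_corr = None
    if spec.kind == "first_order":
        A = layout.factor_cov(phi, gam)
        m = len(layout.factors)
        corr = np.eye(m)
        for (a, b), v in zip(layout.corrs, phi):
            i, j = layout.findex[a], layout.findex[b]
            corr[i, j] = corr[j, i] = v
        factor_corr = pd.DataFrame(corr, index=layout.factors,
                                   columns=layout.factors)
    gammas = ({f: float(gam[layout.findex[f]]) for f in layout.factors}
              if include_genotype else None)

    # thresholds on the theta (unit-residual) scale: marginal probit
    # thresholds rescaled by the implied latent-response SD
    M = (lam @ layout.factor_cov(phi, gam)) @ lam.T
    d = np.sqrt(np.diag(M) + 1.0)
    thresholds = {lab: np.asarray(stats.thresholds[lab]) * d[i]
                  for i, lab in enumerate(labels)}

    return FitResult(
        kind=spec.kind, loadings=loadings, factor_corr=factor_corr,
        gammas=gammas, thresholds=thresholds, discrepancy=F_hat,
        chi_square=chi2, df=df, chi_square_baseline=chi2_baseline,
        df_baseline=df_baseline, rmsea=rmsea, cfi=cfi, tli=tli,
        converged=converged, n_iterations=int(res.nit), se=se, n=n,
        messages=messages,
    )


def implied_polychoric_matrix(spec: MeasurementModelSpec,
                              loadings: pd.DataFrame,
                              factor_corr: pd.DataFrame | None = None) -> np.ndarray:
    """Noise-free model-implied polychoric matrix for given parameters.

    Used to build analytic fixtures: Sigma* = Lambda A Lambda' + I on the
    latent-response scale, rescaled to the correlation metric.
    """
    layout = _ParamLayout(spec, with_genotype=False)
    lam = loadings.loc[spec.indicators, layout.factors].to_numpy()
    m = len(layout.factors)
    A = np.eye(m)
    if spec.kind == "first_order" and factor_corr is not None:
        A = factor_corr.loc[layout.factors, layout.factors].to_numpy()
    M = lam @ A @ lam.T
    d = np.sqrt(np.diag(M) + 1.0)
    R = M / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R
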