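"""Thresholds, polychoric and polyserial correlations.

These are the sample statistics consumed by the limited-information
(DWLS) fitter.  Estimation is two-step maximum likelihood: thresholds
are fixed at their marginal probit estimates tau_k = Phi^{-1}(cumulative
proportion), then the latent correlation maximises the bivariate-normal
cell-probability likelihood (polychoric) or the ordinal-given-continuous
probit likelihood (polyserial).  Asymptotic variances come from the
observed information of the second-step likelihood and are used only as
DWLS weights, never for inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import ndtr, ndtri

from ._bvn import cell_probabilities
from .exceptions import (
    DataError,
    DegeneratePredictorError,
    EstimationError,
)
from .synthetic import GenotypeVector, ItemResponseMatrix

logger = logging.getLogger(__name__)

RHO_BOUND = 0.999
_PROB_FLOOR = 1e-12


def estimate_thresholds(x, n_categories: int | None = None) -> np.ndarray:
    """Probit thresholds from the marginal distribution of an ordinal vector.

    tau_k = Phi^{-1}(cumulative proportion through category k), one per
    gap between observed categories.  Categories with zero count collapse
    (their threshold pair merges); a warning is logged when a declared
    category is unobserved.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise DataError("no complete observations")
    cats, counts = np.unique(x, return_counts=True)
    if cats.size < 2:
        raise DataError("need at least 2 observed categories")
    if n_categories is not None and cats.size < n_categories:
        logger.warning(
            "only %d of %d declared categories observed; empty categories "
            "collapsed", cats.size, n_categories,
        )
    props = counts / counts.sum()
    return ndtri(np.cumsum(props)[:-1])


def _codes(x: np.ndarray):
    """Complete values mapped to consecutive 0..K-1 codes."""
    x = np.asarray(x, dtype=float)
    cats, codes = np.unique(x, return_inverse=True)
    return codes, cats.size


def _table(cx, kx, cy, ky) -> np.ndarray:
    return np.bincount(cx * ky + cy, minlength=kx * ky).reshape(kx, ky).astype(float)


def _poly_nll(table: np.ndarray, tau_x, tau_y):
    def nll(rho: float) -> float:
        P = cell_probabilities(tau_x, tau_y, rho)
        return -float(np.sum(table * np.log(np.maximum(P, _PROB_FLOOR))))
    return nll


def _avar_from_nll(nll, rho_hat: float, h: float = 1e-4) -> float:
    """Observed-information variance of the second-step estimate."""
    lo = max(rho_hat - h, -RHO_BOUND)
    hi = min(rho_hat + h, RHO_BOUND)
    d2 = (nll(hi) - 2.0 * nll(rho_hat) + nll(lo)) / ((0.5 * (hi - lo)) ** 2)
    if not np.isfinite(d2) or d2 <= 0:
        return float("inf")
    return 1.0 / d2


def _maximise_rho(nll, context: str):
    res = optimize.minimize_scalar(
        nll, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
        options={"xatol": 1e-10, "maxiter": 200},
    )
    if not res.success:
        raise EstimationError(
            f"{context}: correlation search failed after {res.nfev} evaluations: "
            f"{res.message}"
        )
    return float(res.x)


def polychoric_corr(x, y, min_pairs: int = 10):
    """Two-step ML polychoric correlation between two ordinal vectors.

    Returns ``(rho, avar)``; rho is confined to (-0.999, 0.999) and sits
    at the clip boundary for perfectly concordant tables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < min_pairs:
        raise DataError(f"need >= {min_pairs} complete pairs, got {x.size}")
    cx, kx = _codes(x)
    cy, ky = _codes(y)
    if kx < 2 or ky < 2:
        raise DataError("both variables need >= 2 observed categories")
    tau_x = estimate_thresholds(x)
    tau_y = estimate_thresholds(y)
    nll = _poly_nll(_table(cx, kx, cy, ky), tau_x, tau_y)
    rho = _maximise_rho(nll, "polychoric")
    return rho, _avar_from_nll(nll, rho)


def polyserial_corr(x, g, min_pairs: int = 10):
    """Two-step ML polyserial correlation: ordinal ``x`` vs numeric ``g``.

    ``g`` is standardised and treated as observed continuous; the
    genotype's three-point support is accepted as-is.
    """
    x = np.asarray(x, dtype=float)
    gv = g.values if isinstance(g, GenotypeVector) else np.asarray(g, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(gv))
    x, gv = x[ok], gv[ok]
    if x.size < min_pairs:
        raise DataError(f"need >= {min_pairs} complete pairs, got {x.size}")
    if np.ptp(gv) == 0:
        raise DegeneratePredictorError("continuous variable is constant")
    z = (gv - gv.mean()) / gv.std()
    cx, kx = _codes(x)
    if kx < 2:
        raise DataError("ordinal variable needs >= 2 observed categories")
    tau = estimate_thresholds(x)
    tau_pad = np.concatenate(([-np.inf], tau, [np.inf]))
    lo = tau_pad[cx]
    hi = tau_pad[cx + 1]

    def nll(rho: float) -> float:
        s = np.sqrt(max(1.0 - rho * rho, 1e-12))
        p = ndtr((hi - rho * z) / s) - ndtr((lo - rho * z) / s)
        return -float(np.sum(np.log(np.maximum(p, _PROB_FLOOR))))

    rho = _maximise_rho(nll, "polyserial")
    return rho, _avar_from_nll(nll, rho)


@dataclass
class CorrelationStructure:
    """Polychoric matrix (+ optional item-genotype polyserials) with
    per-entry asymptotic variances and the complete-case sample size."""

    labels: list[str]
    rho: np.ndarray                 # p x p polychoric matrix
    avar: np.ndarray                # p x p asymptotic variances (diag NaN)
    n: int
    thresholds: dict[str, np.ndarray]
    g_rho: np.ndarray | None = None     # p-vector, item-genotype
    g_avar: np.ndarray | None = None
    smoothed: bool = False

    @property
    def p(self) -> int:
        return len(self.labels)

    def full_matrix(self) -> np.ndarray:
        """Items (+ genotype as last row/column when present)."""
        if self.g_rho is None:
            return self.rho.copy()
        p = self.p
        out = np.empty((p + 1, p + 1))
        out[:p, :p] = self.rho
        out[:p, p] = out[p, :p] = self.g_rho
        out[p, p] = 1.0
        return out

    def to_tsv(self, path) -> None:
        labels = self.labels + (["_genotype_"] if self.g_rho is not None else [])
        M = self.full_matrix()
        with open(path, "w") as fh:
            fh.write("\t".join(labels) + "\n")
            for row in M:
                fh.write("\t".join(np.format_float_scientific(v, unique=True)
                                   for v in row) + "\n")

    @classmethod
    def matrix_from_tsv(cls, path):
        """Read back a matrix written by :meth:`to_tsv` (bit-exact)."""
        with open(path) as fh:
            labels = fh.readline().rstrip("\n").split("\t")
            M = np.array([[float(v) for v in line.rstrip("\n").split("\t")]
                          for line in fh])
        return labels, M


def smooth_correlation_matrix(R: np.ndarray, min_eig: float = 1e-6,
                              tol: float = -1e-8):
    """Eigenvalue-clip a symmetric correlation matrix to PSD.

    A no-op when the smallest eigenvalue is already above ``tol``.
    Returns (matrix, was_smoothed); logs pre/post eigenvalues on action.
    """
    w = np.linalg.eigvalsh(R)
    if w[0] >= tol:
        return R, False
    vals, vecs = np.linalg.eigh(R)
    clipped = np.maximum(vals, min_eig)
    S = vecs @ np.diag(clipped) @ vecs.T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    np.fill_diagonal(S, 1.0)
    logger.info("smoothed correlation matrix: min eigenvalue %.3e -> %.3e",
                w[0], np.linalg.eigvalsh(S)[0])
    return S, True


def assemble_correlation_structure(items: ItemResponseMatrix,
                                   g: GenotypeVector | None = None,
                                   complete_case: bool = True) -> CorrelationStructure:
    """Pairwise polychorics (and item-genotype polyserials) for an item matrix.

    With ``complete_case`` (the pipeline default) subjects missing any
    item — or the genotype, when supplied — are dropped before any
    estimation; otherwise estimation is pairwise-complete.  The assembled
    matrix is eigenvalue-smoothed if it is indefinite.
    """
    labels = items.labels
    df = items.data
    if complete_case:
        mask = items.complete_mask()
        if g is not None:
            mask = mask & g.complete_mask()
        df = df.iloc[np.flatnonzero(mask)]
        gv = GenotypeVector(g.values[np.flatnonzero(mask)], g.snp_id) if g is not None else None
    else:
        gv = g
    X = df.to_numpy()
    p = len(labels)
    rho = np.eye(p)
    avar = np.full((p, p), np.nan)
    thresholds = {lab: estimate_thresholds(X[:, j], items.n_categories.get(lab))
                  for j, lab in enumerate(labels)}
    for j in range(p):
        for k in range(j + 1, p):
            r, v = polychoric_corr(X[:, j], X[:, k])
            rho[j, k] = rho[k, j] = r
            avar[j, k] = avar[k, j] = v
    g_rho = g_avar = None
    if gv is not None:
        g_rho = np.empty(p)
        g_avar = np.empty(p)
        for j in range(p):
            g_rho[j], g_avar[j] = polyserial_corr(X[:, j], gv)
    n = len(df)

    struct = CorrelationStructure(
        labels=list(labels), rho=rho, avar=avar, n=n,
        thresholds=thresholds, g_rho=g_rho, g_avar=g_avar,
    )
    full = struct.full_matrix()
    smoothed_full, did = smooth_correlation_matrix(full)
    if did:
        struct.rho = smoothed_full[:p, :p]
        if g_rho is not None:
            struct.g_rho = smoothed_full[:p, p]
        struct.smoothed = True
    return struct
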