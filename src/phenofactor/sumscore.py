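"""Likert sum-score phenotypes and their SNP regression.

The traditional phenotype definition: unweighted sums of 0-based Likert
item codes, globally and per subscale.  Subjects with any missing item
are excluded (complete-case).  Association with an additive genotype is
ordinary least squares; the effect size is the regression R^2 expressed
as a percentage of phenotype variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, DegeneratePredictorError, InvalidParameterError
from .synthetic import DIMENSIONS, GenotypeVector, ItemResponseMatrix


@dataclass
class SumScoreSet:
    """Per-subject global and subscale sum scores over complete responders."""

    global_: np.ndarray
    somatic: np.ndarray
    social: np.ndarray
    anxiety: np.ndarray
    depression: np.ndarray
    n_complete: int
    n_excluded: int
    complete_index: np.ndarray  # row indices of complete responders

    def score(self, phenotype: str) -> np.ndarray:
        if phenotype == "global":
            return self.global_
        if phenotype in DIMENSIONS:
            return getattr(self, phenotype)
        raise InvalidParameterError(f"unknown phenotype {phenotype!r}")


def compute_sum_scores(items: ItemResponseMatrix,
                       dim_map: dict[str, str] | None = None) -> SumScoreSet:
    """Sum item codes per subject, globally and per subscale.

    Categories must lie in [0, n_categories-1] for each indicator; a
    violation raises :class:`DataError` naming the row and column.
    Composite 7-category indicators contribute their 0-6 code.
    """
    dim_map = dict(dim_map or items.dim_map)
    df = items.data
    for col in df.columns:
        upper = items.n_categories.get(col)
        vals = df[col].to_numpy()
        ok = np.isnan(vals) | (
            (vals >= 0) & (vals == np.floor(vals))
            & (vals <= (upper - 1 if upper else np.inf))
        )
        if not ok.all():
            row = int(np.flatnonzero(~ok)[0])
            raise DataError(
                f"category out of range at row {row}, column {col!r}: {vals[row]!r}"
            )
    complete = items.complete_mask()
    idx = np.flatnonzero(complete)
    sub = df.iloc[idx]
    per_dim = {}
    for dim in DIMENSIONS:
        cols = [c for c in df.columns if dim_map[c] == dim]
        per_dim[dim] = sub[cols].sum(axis=1).to_numpy(dtype=float)
    return SumScoreSet(
        global_=sub.sum(axis=1).to_numpy(dtype=float),
        somatic=per_dim["somatic"],
        social=per_dim["social"],
        anxiety=per_dim["anxiety"],
        depression=per_dim["depression"],
        n_complete=int(idx.size),
        n_excluded=int(len(df) - idx.size),
        complete_index=idx,
    )


def _skewness(x: np.ndarray) -> float:
    """Adjusted Fisher-Pearson standardised third moment; NaN if constant."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return float("nan")
    return float(stats.skew(x, bias=False))


def describe_scores(scores: SumScoreSet) -> pd.DataFrame:
    """One row per score with mean, min, max, skewness and n.

    Zero-variance scores report NaN skewness rather than raising.
    """
    if scores.n_complete < 2:
        raise InvalidParameterError("need at least 2 complete responders")
    rows = []
    for name in ("global",) + DIMENSIONS:
        x = scores.score(name)
        rows.append({
            "score": name,
            "mean": float(np.mean(x)),
            "min": float(np.min(x)),
            "max": float(np.max(x)),
            "skewness": _skewness(x),
            "n": int(x.size),
        })
    return pd.DataFrame(rows)


def regress_sum_on_snp(score: np.ndarray, g: GenotypeVector | np.ndarray):
    """OLS of a per-subject score on additive genotype.

    Returns ``(slope, r2_percent, p)`` where ``r2_percent`` is the
    percentage of score variance explained and ``p`` the two-sided
    p-value from the t distribution with n-2 degrees of freedom.
    """
    gv = g.values if isinstance(g, GenotypeVector) else np.asarray(g, float)
    score = np.asarray(score, dtype=float)
    ok = ~(np.isnan(score) | np.isnan(gv))
    x, y = gv[ok], score[ok]
    if x.size < 3:
        raise InvalidParameterError("need at least 3 complete (score, genotype) pairs")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("genotype is constant; regression undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(100.0 * res.rvalue ** 2), float(res.pvalue)
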