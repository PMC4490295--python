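"""Synthetic cohort generator: bi-factor graded-response item data with SNP effects.

The generator mirrors the data-generating process the downstream analysis
assumes.  Each of 26 GHQ-28-style ordinal indicators i measures one general
("global") factor and exactly one of four specific domains — somatic,
social, anxiety, depression — through a two-parameter normal-ogive
(graded-response) model under theta parameterization:

    y*_i = lambda_g[i] * eta_g + lambda_s[i] * eta_dim(i) + eps_i,
    eps_i ~ N(0, 1),  observed category = #{thresholds tau_i < y*_i}.

A biallelic SNP in Hardy-Weinberg equilibrium enters additively
(genotype coded 0/1/2 = minor-allele count).  For each factor f with a
target variance fraction R2_f, the centred genotype is given coefficient
gamma_f = sqrt(R2_f / var(g)) and the factor disturbance has variance
1 - R2_f, so every factor has unit marginal variance and the SNP explains
exactly R2_f of it by construction.

Two indicators ("headaches", "sleep problems") are composites of two
highly correlated raw items and carry 7 ordered categories; all other
indicators carry 4 (Likert 0-3).  Default loadings and thresholds are
synthetic: the source cohort's values are not publicly deposited, so the
defaults are chosen to give realistic right-skewed symptom marginals
(depression most skewed) rather than to reproduce any real estimate.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtri

from .exceptions import InvalidParameterError, InvalidSpecError

DIMENSIONS = ("somatic", "social", "anxiety", "depression")

#: indicator labels; "*_comp" marks the two 7-category composite indicators
DEFAULT_LABELS: dict[str, list[str]] = {
    "somatic": [
        "feeling_ill", "needing_tonic", "run_down", "hot_cold_spells",
        "headaches_comp", "pressure_in_head",
    ],
    "social": [
        "keeping_busy", "taking_longer", "doing_things_well",
        "satisfied_with_task", "playing_useful_part", "making_decisions",
        "enjoying_activities",
    ],
    "anxiety": [
        "sleep_problems_comp", "under_strain", "edgy_bad_tempered",
        "scared_panicky", "everything_on_top", "nervous_strung_up",
    ],
    "depression": [
        "worthless", "life_hopeless", "life_not_worth_living",
        "thought_of_doing_away", "nerves_too_bad", "wished_dead",
        "idea_taking_life",
    ],
}


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


@dataclass
class GenotypeVector:
    """Additively coded genotypes for one SNP; NaN marks a missing call."""

    values: np.ndarray
    snp_id: str = "snp"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        ok = self.values[~np.isnan(self.values)]
        if ok.size and not np.isin(ok, [0.0, 1.0, 2.0]).all():
            raise InvalidParameterError(
                f"genotypes for {self.snp_id!r} must be 0/1/2 or missing"
            )

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def call_rate(self) -> float:
        return float(np.mean(~np.isnan(self.values)))

    @property
    def maf(self) -> float:
        """Empirical minor-allele frequency (folded to <= 0.5)."""
        ok = self.values[~np.isnan(self.values)]
        if ok.size == 0:
            return float("nan")
        f = float(ok.mean() / 2.0)
        return min(f, 1.0 - f)

    def complete_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class ItemResponseMatrix:
    """n x p ordinal responses (0-based categories), plus simulation truth.

    ``data`` holds float entries so NaN can mark missing responses.
    ``factors`` (n x 5, columns global+dimensions) and ``latent`` (the
    continuous y* responses) are populated by the simulator and carried
    for oracle checks; they are never used by the estimators.
    """

    data: pd.DataFrame
    n_categories: dict[str, int]
    dim_map: dict[str, str]
    factors: pd.DataFrame | None = None
    latent: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def labels(self) -> list[str]:
        return list(self.data.columns)

    def complete_mask(self) -> np.ndarray:
        return ~self.data.isna().any(axis=1).to_numpy()

    def to_csv(self, path) -> None:
        out = self.data.copy()
        self_complete = out.notna()
        # integers where complete, blank where missing
        with open(path, "w") as fh:
            fh.write(",".join(out.columns) + "\n")
            arr = out.to_numpy()
            for row, okrow in zip(arr, self_complete.to_numpy()):
                cells = [str(int(v)) if ok else "" for v, ok in zip(row, okrow)]
                fh.write(",".join(cells) + "\n")

    @classmethod
    def from_csv(cls, path, dim_map: dict[str, str] | None = None,
                 n_categories: dict[str, int] | None = None) -> "ItemResponseMatrix":
        df = pd.read_csv(path, dtype=float)
        if n_categories is None:
            n_categories = {
                c: int(np.nanmax(df[c].to_numpy())) + 1 for c in df.columns
            }
        if dim_map is None:
            dim_map = infer_default_dim_map(list(df.columns))
        return cls(data=df, n_categories=n_categories, dim_map=dim_map)


def infer_default_dim_map(labels: list[str]) -> dict[str, str]:
    """Map labels to dimensions using the default label sets; fall back to
    a 6/7/6/7 split in order when labels are unrecognised."""
    lookup = {
        lab: dim for dim, labs in DEFAULT_LABELS.items() for lab in labs
    }
    if all(lab in lookup for lab in labels):
        return {lab: lookup[lab] for lab in labels}
    sizes = {"somatic": 6, "social": 7, "anxiety": 6, "depression": 7}
    out, i = {}, 0
    for dim in DIMENSIONS:
        for _ in range(sizes[dim]):
            if i < len(labels):
                out[labels[i]] = dim
                i += 1
    if i != len(labels):
        raise InvalidSpecError(
            f"cannot infer a 6/7/6/7 dimension map for {len(labels)} indicators"
        )
    return out


@dataclass
class PopulationSpec:
    """Parameter bundle of the generating bi-factor graded-response model."""

    indicator_labels: list[str]
    dim_map: dict[str, str]
    lambda_g: dict[str, float]
    lambda_s: dict[str, float]
    thresholds: dict[str, list[float]]
    snp_effects: dict[str, float] = field(default_factory=dict)
    maf: float = 0.3
    n: int = 1337

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise InvalidParameterError(f"maf must be in (0, 0.5], got {self.maf}")
        if self.n < 1:
            raise InvalidParameterError("n must be >= 1")
        labs = self.indicator_labels
        if set(labs) != set(self.dim_map):
            raise InvalidSpecError("dim_map must cover exactly the indicator labels")
        for lab in labs:
            if self.dim_map[lab] not in DIMENSIONS:
                raise InvalidSpecError(f"unknown dimension {self.dim_map[lab]!r}")
            tau = np.asarray(self.thresholds[lab], dtype=float)
            if tau.size < 1 or not np.all(np.diff(tau) > 0):
                raise InvalidSpecError(
                    f"thresholds for {lab!r} must be strictly increasing"
                )
        for f, r2 in self.snp_effects.items():
            if f not in ("global",) + DIMENSIONS:
                raise InvalidSpecError(f"unknown factor {f!r} in snp_effects")
            if not (0.0 <= r2 < 1.0):
                raise InvalidSpecError(
                    f"snp effect R2 for {f!r} must be in [0, 1), got {r2}"
                )

    @property
    def p(self) -> int:
        return len(self.indicator_labels)

    def n_categories(self) -> dict[str, int]:
        return {lab: len(self.thresholds[lab]) + 1 for lab in self.indicator_labels}

    # -- lossless round trip through YAML ---------------------------------
    def to_yaml(self, path=None) -> str | None:
        payload = {
            "indicator_labels": list(self.indicator_labels),
            "dim_map": dict(self.dim_map),
            "lambda_g": {k: float(v) for k, v in self.lambda_g.items()},
            "lambda_s": {k: float(v) for k, v in self.lambda_s.items()},
            "thresholds": {k: [float(t) for t in v] for k, v in self.thresholds.items()},
            "snp_effects": {k: float(v) for k, v in self.snp_effects.items()},
            "maf": float(self.maf),
            "n": int(self.n),
        }
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, source) -> "PopulationSpec":
        if hasattr(source, "read") or isinstance(source, io.IOBase):
            payload = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    payload = yaml.safe_load(fh)
            except (OSError, ValueError):
                payload = yaml.safe_load(source)
        return cls(**payload)


def simulate_genotypes(n: int, maf: float, seed) -> GenotypeVector:
    """Draw n independent Hardy-Weinberg genotypes: minor-allele count
    ~ Binomial(2, maf), i.e. P(2)=maf^2, P(1)=2*maf*(1-maf), P(0)=(1-maf)^2."""
    if not (0.0 < maf <= 0.5):
        raise InvalidParameterError(f"maf must be in (0, 0.5], got {maf}")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    g = _rng(seed).binomial(2, maf, size=int(n)).astype(float)
    return GenotypeVector(values=g)


def _draw_factors(spec: PopulationSpec, contributions, rng) -> pd.DataFrame:
    """Factor scores with unit marginal variance; ``contributions`` maps
    factor -> list of (standardised genotype, R2)."""
    n = spec.n
    factors = {}
    for f in ("global",) + DIMENSIONS:
        terms = contributions.get(f, [])
        total_r2 = sum(r2 for _, r2 in terms)
        resid_var = 1.0 - total_r2
        if resid_var < 0:
            raise InvalidSpecError(
                f"SNP effects on factor {f!r} sum to {total_r2:.3f} >= 1"
            )
        eta = rng.standard_normal(n) * np.sqrt(resid_var)
        for z, r2 in terms:
            eta = eta + np.sqrt(r2) * z
        factors[f] = eta
    return pd.DataFrame(factors)


def _standardise_genotype(g: GenotypeVector) -> np.ndarray:
    v = g.values
    if np.isnan(v).any():
        raise InvalidSpecError("generator requires complete genotypes")
    var = v.var()
    if var <= 0:
        raise InvalidSpecError("genotype is constant; cannot carry an effect")
    return (v - v.mean()) / np.sqrt(var)


def _emit_items(spec: PopulationSpec, factors: pd.DataFrame, rng,
                missing_rate: float, keep_latent: bool) -> ItemResponseMatrix:
    n = spec.n
    data = {}
    latent = {} if keep_latent else None
    eta_g = factors["global"].to_numpy()
    for lab in spec.indicator_labels:
        dim = spec.dim_map[lab]
        y = (
            spec.lambda_g[lab] * eta_g
            + spec.lambda_s[lab] * factors[dim].to_numpy()
            + rng.standard_normal(n)
        )
        tau = np.asarray(spec.thresholds[lab], dtype=float)
        data[lab] = np.searchsorted(tau, y).astype(float)
        if keep_latent:
            latent[lab] = y
    df = pd.DataFrame(data)
    if missing_rate > 0:
        mask = rng.random(df.shape) < missing_rate
        df = df.mask(mask)
    return ItemResponseMatrix(
        data=df,
        n_categories=spec.n_categories(),
        dim_map=dict(spec.dim_map),
        factors=factors,
        latent=pd.DataFrame(latent) if keep_latent else None,
    )


def simulate_item_responses(spec: PopulationSpec, g: GenotypeVector, seed,
                            missing_rate: float = 0.0,
                            keep_latent: bool = False) -> ItemResponseMatrix:
    """Simulate ordinal item responses given genotypes under ``spec``.

    The SNP acts additively on each factor named in ``spec.snp_effects``;
    the genotype is centred and scaled by its empirical standard deviation
    so the factor keeps unit variance and the SNP explains exactly the
    target R2 fraction of it.  ``missing_rate`` applies MCAR missingness
    to the emitted item matrix (the generator is complete by default).
    """
    if g.n != spec.n:
        raise InvalidSpecError(f"genotype length {g.n} != spec.n {spec.n}")
    if not (0.0 <= missing_rate < 1.0):
        raise InvalidParameterError("missing_rate must be in [0, 1)")
    rng = _rng(seed)
    contributions: dict[str, list] = {}
    if spec.snp_effects:
        z = _standardise_genotype(g)
        for f, r2 in spec.snp_effects.items():
            contributions[f] = [(z, r2)]
    factors = _draw_factors(spec, contributions, rng)
    return _emit_items(spec, factors, rng, missing_rate, keep_latent)


def simulate_cohort(spec: PopulationSpec, snps: list[dict], seed,
                    missing_rate: float = 0.0,
                    keep_latent: bool = False):
    """Simulate one item matrix influenced by several independent SNPs.

    ``snps`` is a list of dicts with keys ``snp_id``, ``maf`` and
    ``effects`` (factor -> R2).  Effects on a factor add; their sum must
    stay below 1.  Returns (ItemResponseMatrix, {snp_id: GenotypeVector}).
    """
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(snps) + 1)
    genotypes: dict[str, GenotypeVector] = {}
    contributions: dict[str, list] = {}
    for snp, cs in zip(snps, child[:-1]):
        g = simulate_genotypes(spec.n, snp["maf"], cs)
        g.snp_id = snp["snp_id"]
        genotypes[snp["snp_id"]] = g
        effects = snp.get("effects") or {}
        if effects:
            z = _standardise_genotype(g)
            for f, r2 in effects.items():
                if not (0.0 <= r2 < 1.0):
                    raise InvalidSpecError(f"R2 for {f!r} must be in [0, 1)")
                contributions.setdefault(f, []).append((z, r2))
    rng = _rng(child[-1])
    factors = _draw_factors(spec, contributions, rng)
    items = _emit_items(spec, factors, rng, missing_rate, keep_latent)
    return items, genotypes


def make_default_population(n: int = 1337, maf: float = 0.3,
                            snp_effects: dict[str, float] | None = None) -> PopulationSpec:
    """The default 26-indicator GHQ-28-like population (synthetic values).

    Dimension sizes 6/7/6/7; the two composite indicators carry 7 ordered
    categories (6 thresholds), all others 4 (3 thresholds).  Loadings are
    on the theta (unit-residual) scale and vary moderately across items;
    thresholds are placed so marginal category proportions are
    right-skewed, most strongly for depression items.
    """
    labels = [lab for dim in DIMENSIONS for lab in DEFAULT_LABELS[dim]]
    dim_map = {lab: dim for dim in DIMENSIONS for lab in DEFAULT_LABELS[dim]}

    # Loadings vary strongly across items, with the general/specific ratio
    # differing item to item, as item-level bi-factor fits of real symptom
    # scales show.  (If every item in a domain had the same general and
    # specific loading, the four specific columns of Lambda would sum to a
    # multiple of the general column and the five SNP paths of the MIMIC
    # extension would be unidentified; heterogeneous ratios are both the
    # realistic and the identified regime.)
    lam_g_pat = {
        "somatic": [1.2, 0.9, 0.7, 1.1, 0.5, 0.8],
        "social": [0.8, 1.3, 0.6, 1.0, 0.7, 1.2, 0.9],
        "anxiety": [1.3, 1.0, 0.7, 1.2, 0.5, 0.9],
        "depression": [1.1, 0.8, 1.3, 0.6, 1.0, 1.2, 0.9],
    }
    lam_s_pat = {
        "somatic": [0.3, 0.7, 0.9, 0.4, 1.0, 0.6],
        "social": [0.9, 0.3, 1.0, 0.5, 0.8, 0.4, 0.7],
        "anxiety": [0.3, 0.6, 1.0, 0.4, 1.1, 0.8],
        "depression": [0.5, 0.9, 0.3, 1.1, 0.6, 0.4, 0.8],
    }
    lambda_g, lambda_s = {}, {}
    for dim in DIMENSIONS:
        for i, lab in enumerate(DEFAULT_LABELS[dim]):
            lambda_g[lab] = lam_g_pat[dim][i]
            lambda_s[lab] = lam_s_pat[dim][i]

    # target cumulative marginal proportions (4-category items), per dimension
    cum4 = {
        "somatic": (0.60, 0.85, 0.96),
        "social": (0.45, 0.80, 0.95),
        "anxiety": (0.60, 0.85, 0.96),
        "depression": (0.85, 0.95, 0.99),
    }
    cum7 = {
        "headaches_comp": (0.50, 0.70, 0.85, 0.93, 0.97, 0.99),
        "sleep_problems_comp": (0.45, 0.65, 0.82, 0.92, 0.97, 0.99),
    }
    thresholds = {}
    for lab in labels:
        sd = float(np.sqrt(lambda_g[lab] ** 2 + lambda_s[lab] ** 2 + 1.0))
        cum = cum7.get(lab, cum4[dim_map[lab]])
        thresholds[lab] = [round(float(sd * ndtri(c)), 4) for c in cum]

    return PopulationSpec(
        indicator_labels=labels,
        dim_map=dim_map,
        lambda_g=lambda_g,
        lambda_s=lambda_s,
        thresholds=thresholds,
        snp_effects=dict(snp_effects or {}),
        maf=maf,
        n=n,
    )
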