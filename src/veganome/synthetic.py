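"""Synthetic two-group metabolomics cohorts with known ground truth.

The generator emulates the structure of a small cross-sectional plasma
metabolomics study comparing vegans with non-vegetarians: ~93 subjects,
~930 named metabolites organised in ~93 chemical subclasses, group
log-fold-change effects on a subset of metabolites, covariate effects,
latent batch-like factors (optionally confounded with diet group),
block-equicorrelated residual noise within subclasses, and per-metabolite
left-censoring at a detection limit.

The abundance model on the natural-log scale is

    log X_ij = mu_j + delta_j * vegan_i + sum_c gamma_jc z_ic
               + sum_f lambda_jf u_if + eps_ij

with eps block-correlated within each subclass at a single exchangeable
correlation.  Raw abundances are exp(log X); censoring then blanks the
lowest fraction of each metabolite's values, mimicking a detection
limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .containers import NONVEG, VEGAN, AbundanceMatrix, Annotation, CohortMetadata

MAJOR_CLASSES = (
    "Lipid",
    "Amino Acid",
    "Xenobiotics",
    "Carbohydrate",
    "Nucleotide",
    "Cofactors and Vitamins",
    "Peptide",
    "Energy",
    "Partially Characterized Molecules",
)


@dataclass
class EffectSpec:
    """Distribution of true log fold changes for non-null metabolites.

    |delta| is drawn as the absolute value of a normal with the given
    location/scale; the sign is negative (lower in vegans) with
    probability ``prob_negative``.  Defaults reflect a cohort where most
    differential metabolites are decreased in vegans and typical
    magnitudes are around 1.8-fold.
    """

    magnitude_mean: float = math.log(1.8)
    magnitude_sd: float = 0.3
    prob_negative: float = 0.72

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        mag = np.abs(rng.normal(self.magnitude_mean, self.magnitude_sd, size))
        sign = np.where(rng.random(size) < self.prob_negative, -1.0, 1.0)
        return sign * mag


@dataclass
class CovariateEffect:
    """Per-metabolite coefficient distribution for one covariate."""

    mean: float = 0.0
    sd: float = 0.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.sd == 0.0:
            return np.full(size, self.mean)
        return rng.normal(self.mean, self.sd, size)


def _default_covariate_effects() -> dict[str, CovariateEffect]:
    # BMI carries no direct effect by default: diet-driven BMI differences
    # are treated as a mediated part of the diet effect, and `delta`
    # records only the direct path.  Turn it on for mediator experiments.
    return {
        "age": CovariateEffect(0.0, 0.005),
        "sex": CovariateEffect(0.0, 0.05),
        "race": CovariateEffect(0.0, 0.05),
        "bmi": CovariateEffect(0.0, 0.0),
    }


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults mirror the two-group plasma study the pipeline targets:
    47 vegans vs 46 non-vegetarians, 930 metabolites in 93 subclasses.
    """

    n_vegan: int = 47
    n_nonveg: int = 46
    n_metabolites: int = 930
    subclass_sizes: Sequence[int] | None = None  # default: 93 subclasses of 10
    frac_nonnull: float = 0.63
    effect_log_fc: EffectSpec = field(default_factory=EffectSpec)
    n_latent: int = 3
    latent_sd: float = 0.3
    latent_diet_corr: float = 0.0
    within_subclass_rho: float = 0.3
    residual_sd: float = 0.5
    covariate_effects: Mapping[str, CovariateEffect] = field(
        default_factory=_default_covariate_effects
    )
    censor_quantile: float = 0.1
    seed: int = 0

    def resolved_subclass_sizes(self) -> np.ndarray:
        if self.subclass_sizes is not None:
            return np.asarray(self.subclass_sizes, dtype=int)
        n_sub = max(1, round(self.n_metabolites / 10))
        base = self.n_metabolites // n_sub
        sizes = np.full(n_sub, base, dtype=int)
        sizes[: self.n_metabolites - base * n_sub] += 1
        return sizes

    def validate(self) -> None:
        if self.n_vegan + self.n_nonveg < 4:
            raise ValueError("n_vegan + n_nonveg must be >= 4")
        if min(self.n_vegan, self.n_nonveg) < 1:
            raise ValueError("n_vegan and n_nonveg must be >= 1")
        if self.n_metabolites < 1:
            raise ValueError("n_metabolites must be >= 1")
        sizes = self.resolved_subclass_sizes()
        if sizes.sum() != self.n_metabolites:
            raise ValueError(
                f"subclass_sizes sums to {sizes.sum()}, expected n_metabolites="
                f"{self.n_metabolites}"
            )
        if (sizes < 1).any():
            raise ValueError("subclass_sizes entries must be >= 1")
        if not 0.0 <= self.frac_nonnull <= 1.0:
            raise ValueError("frac_nonnull must be in [0, 1]")
        if self.n_latent < 0:
            raise ValueError("n_latent must be >= 0")
        if self.latent_sd <= 0:
            raise ValueError("latent_sd must be positive")
        if not -1.0 < self.latent_diet_corr < 1.0:
            raise ValueError("latent_diet_corr must be in (-1, 1)")
        if not 0.0 <= self.within_subclass_rho < 1.0:
            raise ValueError("within_subclass_rho must be in [0, 1)")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if not 0.0 <= self.censor_quantile < 1.0:
            raise ValueError("censor_quantile must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort, for recovery tests."""

    nonnull_set: np.ndarray  # metabolite column indices with delta != 0
    delta: np.ndarray  # per-metabolite true log fold change (0 for nulls)
    latent_scores: np.ndarray  # n × n_latent
    latent_loadings: np.ndarray  # n_metabolites × n_latent


@dataclass
class SyntheticDataset:
    raw: AbundanceMatrix  # raw scale, censored entries missing
    metadata: CohortMetadata
    annotation: Annotation
    truth: SyntheticTruth
    config: SimulationConfig


def _simulate_metadata(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Covariates with the imbalance pattern of the target study design:
    BMI and energy intake shifted by group, sex/race balanced."""
    n = config.n_vegan + config.n_nonveg
    diet = np.array([VEGAN] * config.n_vegan + [NONVEG] * config.n_nonveg)
    vegan = diet == VEGAN
    age = rng.normal(63.0, 10.0, n)
    sex = rng.integers(0, 2, n).astype(float)
    race = rng.integers(0, 2, n).astype(float)
    bmi = np.where(vegan, rng.normal(24.7, 3.4, n), rng.normal(31.3, 7.0, n))
    kcal = np.where(vegan, rng.normal(1776.8, 744.7, n), rng.normal(2520.8, 902.8, n))
    kcal = np.clip(kcal, 500.0, 4500.0)
    ids = [f"S{i + 1:03d}" for i in range(n)]
    return pd.DataFrame(
        {"diet": diet, "age": age, "sex": sex, "race": race, "bmi": bmi,
         "energy_kcal": kcal},
        index=pd.Index(ids, name="sample_id"),
    )


def _block_noise(
    rng: np.random.Generator, n: int, sizes: np.ndarray, rho: float, sd: float
) -> np.ndarray:
    """Gaussian noise, exchangeably correlated at rho within each block."""
    p = int(sizes.sum())
    indiv = rng.normal(0.0, 1.0, (n, p))
    if rho == 0.0:
        return sd * indiv
    shared = rng.normal(0.0, 1.0, (n, len(sizes)))
    shared_full = np.repeat(shared, sizes, axis=1)
    return sd * (math.sqrt(rho) * shared_full + math.sqrt(1.0 - rho) * indiv)


def generate_cohort(config: SimulationConfig) -> SyntheticDataset:
    """Simulate one cohort. Identical config (incl. seed) gives identical data."""
    config.validate()
    n = config.n_vegan + config.n_nonveg
    p = config.n_metabolites
    sizes = config.resolved_subclass_sizes()

    meta = _simulate_metadata(config, substream(config.seed, "sim", "covariates"))
    vegan = (meta["diet"] == VEGAN).to_numpy(dtype=float)

    rng_eff = substream(config.seed, "sim", "effects")
    n_nonnull = int(math.floor(config.frac_nonnull * p))
    nonnull = np.sort(rng_eff.choice(p, size=n_nonnull, replace=False))
    delta = np.zeros(p)
    if n_nonnull:
        delta[nonnull] = config.effect_log_fc.sample(rng_eff, n_nonnull)

    mu = substream(config.seed, "sim", "baseline").normal(0.0, 1.0, p)

    # covariate effects, centered covariates so mu stays the baseline mean
    rng_cov = substream(config.seed, "sim", "coveffects")
    cov_term = np.zeros((n, p))
    for name, spec in config.covariate_effects.items():
        gamma = spec.sample(rng_cov, p)
        z = meta[name].to_numpy(dtype=float)
        cov_term += np.outer(z - z.mean(), gamma)

    rng_lat = substream(config.seed, "sim", "latent")
    if config.n_latent > 0:
        base = rng_lat.normal(0.0, 1.0, (n, config.n_latent))
        r = config.latent_diet_corr
        if r != 0.0:
            zdiet = (vegan - vegan.mean()) / vegan.std()
            base = r * zdiet[:, None] + math.sqrt(1.0 - r * r) * base
        scores = config.latent_sd * base
        loadings = rng_lat.normal(0.0, 1.0, (p, config.n_latent))
        latent_term = scores @ loadings.T
    else:
        scores = np.zeros((n, 0))
        loadings = np.zeros((p, 0))
        latent_term = 0.0

    eps = _block_noise(
        substream(config.seed, "sim", "noise"), n, sizes,
        config.within_subclass_rho, config.residual_sd,
    )

    log_x = mu[None, :] + np.outer(vegan, delta) + cov_term + latent_term + eps
    met_ids = [f"M{j + 1:04d}" for j in range(p)]
    raw = pd.DataFrame(np.exp(log_x), index=meta.index, columns=met_ids)

    matrix = AbundanceMatrix(raw, state="raw")
    if config.censor_quantile > 0:
        matrix = censor_below_detection(matrix, config.censor_quantile)

    sub_names = np.repeat(
        [f"Subclass {k + 1:02d}" for k in range(len(sizes))], sizes
    )
    major = np.repeat(
        [MAJOR_CLASSES[k % len(MAJOR_CLASSES)] for k in range(len(sizes))], sizes
    )
    annotation = Annotation(
        pd.DataFrame(
            {"subclass": sub_names, "major_class": major},
            index=pd.Index(met_ids, name="metabolite"),
        )
    )

    return SyntheticDataset(
        raw=matrix,
        metadata=CohortMetadata(meta),
        annotation=annotation,
        truth=SyntheticTruth(
            nonnull_set=nonnull, delta=delta,
            latent_scores=scores, latent_loadings=loadings,
        ),
        config=config,
    )


def censor_below_detection(
    matrix: AbundanceMatrix,
    censor_quantile: float | Sequence[float],
    seed: int | None = None,
) -> AbundanceMatrix:
    """Blank the lowest ``censor_quantile`` fraction of each metabolite.

    Censoring is deterministic by rank within each metabolite (the
    lowest values vanish), matching detection-limit physics; ``seed`` is
    accepted for interface uniformity but unused.  ``censor_quantile``
    may be a scalar or one fraction per metabolite.
    """
    matrix.require_state("raw")
    q = np.broadcast_to(
        np.asarray(censor_quantile, dtype=float), (matrix.n_metabolites,)
    )
    if (q < 0).any() or (q >= 1).any():
        raise ValueError("censor_quantile must be in [0, 1)")
    vals = matrix.values.copy()
    n = matrix.n_samples
    arr = vals.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    n_cens = np.floor(q * n).astype(int)
    for j in range(arr.shape[1]):
        if n_cens[j] > 0:
            arr[order[: n_cens[j], j], j] = np.nan
    return AbundanceMatrix(
        pd.DataFrame(arr, index=vals.index, columns=vals.columns), state="raw"
    )
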