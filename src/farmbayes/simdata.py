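"""Synthetic data with the statistical structure of smallholder dairy herds.

The generator emulates the features of a crossbred smallholder population that
drive the estimation problem: an admixed genotype background, a handful of
causal markers whose effects come from a four-component normal mixture (many
tiny effects, a few large ones), very small farms whose sizes follow a
zero-truncated Poisson distribution, farm (management) variance several times
the additive genetic variance, and repeated milk records summarized per cow
with heteroscedastic residuals.

Default parameter values reflect the study conditions this package targets:
mixture proportions (0.80, 0.15, 0.04, 0.01) over relative variances
(1e-4, 1e-3, 1e-2, 1e-1), farm-to-genetic variance ratio 3, average farm
sizes in {1, 2, 5, 20}, heritabilities in {0.10, 0.20, 0.50}, and an average
of 18 test-day records per cow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix
from .preadjust import garrick_weight

__all__ = [
    "AncestryConfig",
    "SimEffectMixture",
    "FarmStructure",
    "SimulatedDataset",
    "simulate_genotypes",
    "sample_qtl_effects",
    "assign_farms",
    "sample_record_counts",
    "simulate_phenotypes",
    "run_scenario_grid",
    "ztp_rate",
]


# ---------------------------------------------------------------------- #
# configuration / domain types
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class AncestryConfig:
    """Two-ancestry Balding–Nichols admixture model for genotype simulation.

    ``divergence`` is the Fst-like drift parameter between the ancestral
    populations; admixture proportions (share of the 'exotic' ancestry) are
    Beta(a, b) across animals, defaulting to mean 0.63 — echoing a crossbred
    population that is mostly exotic dairy with an indigenous remainder.
    ``discrete=True`` instead assigns each animal wholly to one ancestry
    (useful for checking between-group differentiation).
    """

    n_ancestries: int = 2
    divergence: float = 0.1
    admixture_beta: tuple[float, float] = (6.3, 3.7)
    maf_floor: float = 0.05
    discrete: bool = False

    def __post_init__(self):
        if self.n_ancestries < 1:
            raise ValueError("n_ancestries must be >= 1")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")
        if not 0.0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in [0, 0.5)")


@dataclass(frozen=True)
class SimEffectMixture:
    """Mixture of zero-mean normals for causal-marker effects."""

    proportions: tuple = (0.80, 0.15, 0.04, 0.01)
    variances: tuple = (1e-4, 1e-3, 1e-2, 1e-1)

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        v = np.asarray(self.variances, dtype=float)
        if len(p) != len(v):
            raise ValueError("proportions and variances must have equal length")
        if (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError("proportions must be nonnegative and sum to 1")
        if (v <= 0).any() or (np.diff(v) <= 0).any():
            raise ValueError("variances must be positive and strictly increasing")

    @property
    def mean_variance(self) -> float:
        """Per-causal-marker effect variance by the law of total variance."""
        return float(np.dot(self.proportions, self.variances))


@dataclass
class FarmStructure:
    """Partition of animals into farms; houses the farm design matrix V."""

    farm_of_animal: np.ndarray  # int index per animal
    n_farms: int

    def __post_init__(self):
        f = np.asarray(self.farm_of_animal)
        if f.min() < 0 or f.max() >= self.n_farms:
            raise ValueError("farm indices out of range")
        if len(np.unique(f)) != self.n_farms:
            raise ValueError("every farm must have at least one animal")

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.farm_of_animal, minlength=self.n_farms)


@dataclass
class SimulatedDataset:
    """Simulated phenotypes plus every piece of the generating truth."""

    y: np.ndarray
    true_breeding_value: np.ndarray
    true_farm_effect: np.ndarray
    farms: FarmStructure
    qtl_effects: np.ndarray          # dense over markers, zero off-causal
    qtl_component: np.ndarray        # 0 = non-causal, 1..K = mixture component
    record_counts: np.ndarray
    weights: np.ndarray
    h2: float
    farm_ratio: float
    mean_farm_size: float
    seed: int
    sigma_g2: float
    sigma_f2: float
    sigma_e2: float
    mean: float = 0.0


# ---------------------------------------------------------------------- #
# genotypes
# ---------------------------------------------------------------------- #
def simulate_genotypes(
    n_animals: int,
    n_markers: int,
    ancestry: AncestryConfig | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate admixed dosages under a Balding–Nichols two-ancestry model.

    Ancestral frequencies p0 are uniform on (maf_floor, 1 - maf_floor); each
    ancestry draws its own frequency from Beta(p0 (1-F)/F, (1-p0)(1-F)/F)
    where F is the divergence; each animal's marker frequency is its
    admixture-weighted average and dosages are Binomial(2, freq).
    Markers monomorphic in the realized sample are dropped.
    """
    if n_animals < 2 or n_markers < 1:
        raise ValueError("need n_animals >= 2 and n_markers >= 1")
    cfg = ancestry if ancestry is not None else AncestryConfig()
    rng = np.random.default_rng(seed)

    lo = max(cfg.maf_floor, 1e-3)
    p0 = rng.uniform(lo, 1.0 - lo, size=n_markers)
    F = cfg.divergence
    if F > 0.0:
        a = p0 * (1.0 - F) / F
        b = (1.0 - p0) * (1.0 - F) / F
        panc = rng.beta(a[:, None], b[:, None], size=(n_markers, cfg.n_ancestries))
    else:
        panc = np.repeat(p0[:, None], cfg.n_ancestries, axis=1)

    if cfg.n_ancestries == 1:
        q = np.ones(n_animals)
        freq = panc[:, 0][None, :].repeat(n_animals, axis=0)
    else:
        if cfg.discrete:
            mean_q = cfg.admixture_beta[0] / sum(cfg.admixture_beta)
            q = (rng.random(n_animals) < mean_q).astype(float)
        else:
            q = rng.beta(*cfg.admixture_beta, size=n_animals)
        # individual frequency: q * exotic + (1 - q) * indigenous
        freq = q[:, None] * panc[:, 0][None, :] + (1 - q[:, None]) * panc[:, 1][None, :]

    dosages = rng.binomial(2, freq).astype(np.int8)
    return GenotypeMatrix.from_dosages(dosages, ancestry=q)


# ---------------------------------------------------------------------- #
# QTL effects
# ---------------------------------------------------------------------- #
def sample_qtl_effects(
    n_markers: int,
    n_causal: int,
    mixture: SimEffectMixture | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sparse causal effects from the four-component normal mixture.

    Returns ``(effects, component)`` of length n_markers; ``component`` is 0
    for non-causal markers and 1..K for causal ones.
    """
    mixture = mixture if mixture is not None else SimEffectMixture()
    if n_causal > n_markers:
        raise ValueError("n_causal cannot exceed n_markers")
    rng = np.random.default_rng(seed)
    causal = rng.choice(n_markers, size=n_causal, replace=False)
    comp = rng.choice(len(mixture.proportions), size=n_causal, p=mixture.proportions)
    sd = np.sqrt(np.asarray(mixture.variances))[comp]
    effects = np.zeros(n_markers)
    effects[causal] = rng.standard_normal(n_causal) * sd
    component = np.zeros(n_markers, dtype=np.int64)
    component[causal] = comp + 1
    return effects, component


# ---------------------------------------------------------------------- #
# farms and record counts
# ---------------------------------------------------------------------- #
def ztp_rate(target_mean: float) -> float:
    """Rate lambda of a zero-truncated Poisson with the given truncated mean.

    Solves lambda / (1 - exp(-lambda)) = target_mean; the truncated mean is
    1 in the lambda -> 0 limit, so target_mean must be >= 1.
    """
    if target_mean < 1.0:
        raise ValueError("zero-truncated Poisson mean cannot be below 1")
    if target_mean == 1.0:
        return 0.0
    f = lambda lam: lam / (-np.expm1(-lam)) - target_mean
    return float(optimize.brentq(f, 1e-10, target_mean + 50.0))


def _sample_ztp(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Inverse-CDF sampling of a zero-truncated Poisson."""
    if lam == 0.0:
        return np.ones(size, dtype=np.int64)
    p0 = np.exp(-lam)
    u = p0 + rng.random(size) * (1.0 - p0)
    return stats.poisson.ppf(u, lam).astype(np.int64)


def assign_farms(n_animals: int, target_mean_size: float, seed: int = 0) -> FarmStructure:
    """Partition animals into farms with zero-truncated-Poisson sizes.

    Farm sizes are drawn until all animals are assigned; the last farm is
    truncated so that sizes sum exactly to ``n_animals``.
    """
    lam = ztp_rate(target_mean_size)
    rng = np.random.default_rng(seed)
    sizes: list[int] = []
    total = 0
    while total < n_animals:
        batch = _sample_ztp(rng, lam, max(16, int(n_animals / max(target_mean_size, 1.0))))
        for s in batch:
            s = int(min(s, n_animals - total))
            sizes.append(s)
            total += s
            if total >= n_animals:
                break
    farm_of_animal = np.repeat(np.arange(len(sizes)), sizes)
    return FarmStructure(farm_of_animal=farm_of_animal, n_farms=len(sizes))


def sample_record_counts(
    n_animals: int,
    mean_records: float = 18.0,
    dispersion: float = 0.15,
    seed: int = 0,
) -> np.ndarray:
    """Per-animal test-day record counts (zero-truncated negative binomial).

    ``dispersion`` is the negative-binomial alpha (var = mu + alpha mu^2) of
    the untruncated distribution; 0 gives deterministic counts round(mean).
    The untruncated mean mu is solved so the truncated mean hits the target.
    """
    if mean_records < 1.0:
        raise ValueError("mean_records must be >= 1")
    rng = np.random.default_rng(seed)
    if dispersion == 0.0:
        return np.full(n_animals, int(round(mean_records)), dtype=np.int64)

    alpha = dispersion

    def trunc_mean(mu):
        p0 = (1.0 + alpha * mu) ** (-1.0 / alpha)
        return mu / (1.0 - p0)

    mu = optimize.brentq(lambda m: trunc_mean(m) - mean_records, 1e-9, mean_records + 100.0)
    r = 1.0 / alpha
    p = 1.0 / (1.0 + alpha * mu)
    p0 = p**r
    u = p0 + rng.random(n_animals) * (1.0 - p0)
    return stats.nbinom.ppf(u, r, p).astype(np.int64)


# ---------------------------------------------------------------------- #
# phenotypes
# ---------------------------------------------------------------------- #
def simulate_phenotypes(
    G: GenotypeMatrix,
    qtl_effects: np.ndarray,
    farms: FarmStructure,
    h2: float,
    farm_ratio: float = 3.0,
    record_counts: np.ndarray | None = None,
    weight_h2: float = 0.19,
    weight_t: float = 0.60,
    heteroscedastic: bool = True,
    mean: float = 0.0,
    qtl_component: np.ndarray | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Phenotypes y = mean + Z a + farm + residual with the target structure.

    True breeding values are standardized-genotype x effect products; the
    additive variance sigma_g2 is their empirical variance.  Farm effects are
    N(0, farm_ratio * sigma_g2); the residual variance is set from
    sigma_e2 = sigma_g2 (1 - h2) / h2, so h2 = sigma_g2/(sigma_g2 + sigma_e2)
    excludes the farm variance (with farm_ratio 3, an h2 of 0.5 would be
    unreachable otherwise).  With ``heteroscedastic`` the residual of animal i
    has variance sigma_e2 / w_i with w_i the record-count weight.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be inside (0, 1)")
    if farm_ratio < 0.0:
        raise ValueError("farm_ratio must be nonnegative")
    if G.n_animals != len(farms.farm_of_animal):
        raise ValueError("genotypes and farm structure disagree on n_animals")
    rng = np.random.default_rng(seed)

    Z = G.standardized(order="C")
    a = np.asarray(qtl_effects, dtype=float)
    tbv = Z @ a
    sigma_g2 = float(tbv.var())
    if sigma_g2 <= 0.0:
        raise ValueError("all causal effects are zero; no genetic variance")

    farm_effect = rng.normal(0.0, np.sqrt(farm_ratio * sigma_g2), size=farms.n_farms)
    sigma_e2 = sigma_g2 * (1.0 - h2) / h2

    if record_counts is None:
        record_counts = np.ones(G.n_animals, dtype=np.int64)
    record_counts = np.asarray(record_counts)
    if (record_counts < 1).any():
        raise ValueError("record counts must be positive integers")
    w = garrick_weight(record_counts, weight_h2, weight_t)
    resid_sd = np.sqrt(sigma_e2 / w) if heteroscedastic else np.full(G.n_animals, np.sqrt(sigma_e2))
    e = rng.standard_normal(G.n_animals) * resid_sd

    y = mean + tbv + farm_effect[farms.farm_of_animal] + e
    return SimulatedDataset(
        y=y,
        true_breeding_value=tbv,
        true_farm_effect=farm_effect,
        farms=farms,
        qtl_effects=a,
        qtl_component=(
            np.asarray(qtl_component)
            if qtl_component is not None
            else (a != 0).astype(np.int64)
        ),
        record_counts=record_counts,
        weights=w,
        h2=h2,
        farm_ratio=farm_ratio,
        mean_farm_size=float(farms.sizes.mean()),
        seed=seed,
        sigma_g2=sigma_g2,
        sigma_f2=float(farm_ratio * sigma_g2),
        sigma_e2=sigma_e2,
        mean=mean,
    )


def simulate_dataset(
    n_animals: int,
    n_markers: int,
    n_causal: int,
    h2: float,
    mean_farm_size: float,
    farm_ratio: float = 3.0,
    mixture: SimEffectMixture | None = None,
    ancestry: AncestryConfig | None = None,
    mean_records: float = 18.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, SimulatedDataset]:
    """One full synthetic dataset (genotypes + phenotypes) from one seed."""
    ss = np.random.SeedSequence(seed)
    s_geno, s_qtl, s_farm, s_rec, s_phen = [int(s) for s in ss.generate_state(5) >> 1]
    G = simulate_genotypes(n_animals, n_markers, ancestry=ancestry, seed=s_geno)
    effects, comp = sample_qtl_effects(G.n_markers, min(n_causal, G.n_markers), mixture, seed=s_qtl)
    farms = assign_farms(n_animals, mean_farm_size, seed=s_farm)
    counts = sample_record_counts(n_animals, mean_records=mean_records, seed=s_rec)
    data = simulate_phenotypes(
        G, effects, farms, h2=h2, farm_ratio=farm_ratio,
        record_counts=counts, qtl_component=comp, seed=s_phen,
    )
    return G, data


# ---------------------------------------------------------------------- #
# scenario grid
# ---------------------------------------------------------------------- #
def run_scenario_grid(
    farm_size_means,
    h2_values,
    n_replicates: int,
    n_animals: int = 1000,
    n_markers: int = 2000,
    n_causal: int = 200,
    farm_ratio: float = 3.0,
    seed: int = 0,
    fit: bool = True,
    chain_config=None,
    model_spec=None,
    cv_folds: int = 0,
) -> pd.DataFrame:
    """Simulate-and-fit every (farm size, heritability) cell of a grid.

    One row per cell per replicate, with estimated additive variance and
    heritability (and optionally cross-validation accuracy/bias).  With
    ``fit=False`` only the scenario metadata is enumerated — useful to check
    the bookkeeping of a large grid without paying for the fits.  Replicate
    seeds derive deterministically from ``seed``, so two runs with the same
    base seed give identical tables.
    """
    farm_size_means = list(farm_size_means)
    h2_values = list(h2_values)
    if not farm_size_means or not h2_values or n_replicates < 1:
        raise ValueError("grid must be nonempty and n_replicates >= 1")

    from .sampler import ChainConfig, ModelSpec, run_chain, summarize

    if chain_config is None:
        chain_config = ChainConfig(n_iterations=5000, burn_in=2000, thinning=5)
    if model_spec is None:
        model_spec = ModelSpec()

    rows = []
    for ci, fs in enumerate(farm_size_means):
        for hi, h2 in enumerate(h2_values):
            for rep in range(n_replicates):
                rep_seed = int(
                    np.random.SeedSequence((seed, ci, hi, rep)).generate_state(1)[0] >> 1
                )
                row = {
                    "farm_size_mean": fs,
                    "h2_true": h2,
                    "replicate": rep,
                    "seed": rep_seed,
                    "sigma_g2_true": np.nan,
                    "sigma_g2_hat": np.nan,
                    "h2_hat": np.nan,
                    "accuracy": np.nan,
                    "bias": np.nan,
                    "status": "planned",
                }
                if fit:
                    try:
                        G, data = simulate_dataset(
                            n_animals, n_markers, n_causal, h2, fs,
                            farm_ratio=farm_ratio, seed=rep_seed,
                        )
                        samples = run_chain(
                            data.y, None, data.farms.farm_of_animal, G,
                            weights=data.weights, spec=model_spec,
                            config=replace(chain_config, seed=rep_seed),
                        )
                        summ = summarize(samples)
                        row["sigma_g2_true"] = data.sigma_g2
                        row["sigma_g2_hat"] = summ.sigma_g2_mean
                        row["h2_hat"] = summ.h2_mean
                        if cv_folds > 1:
                            from .evaluate import cross_validate, partition_groups

                            plan = partition_groups(
                                np.arange(n_animals), cv_folds, seed=rep_seed
                            )
                            cv = cross_validate(
                                G, data.y, np.arange(n_animals), plan,
                                farm_of_animal=data.farms.farm_of_animal,
                                weights=data.weights, spec=model_spec,
                                config=replace(chain_config, seed=rep_seed + 1),
                            )
                            row["accuracy"] = cv.mean_accuracy
                            row["bias"] = cv.mean_bias
                        row["status"] = "ok"
                    except Exception as exc:  # noqa: BLE001 - recorded, not raised
                        row["status"] = f"failed: {exc}"
                rows.append(row)
    return pd.DataFrame(rows)
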