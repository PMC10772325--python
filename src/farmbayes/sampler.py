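"""Gibbs sampler for y = 1 m + V f + Z g + e with a mixture prior on g.

The model is a whole-genome regression on standardized genotypes Z with an
overall mean (plus optional extra fixed effects), random farm effects
f ~ N(0, sigma_f2), and heteroscedastic residuals e ~ N(0, E sigma_e2) with
E = diag(1/w_i): averaged repeated-record phenotypes are less noisy for cows
with more records, and every full conditional uses w-weighted cross-products
while the residual-variance scale is sum(w_i e_i^2).

Three priors on SNP effects share one code path:

* ``bayesr`` — finite mixture with a point mass at zero and normal components
  whose variances are multipliers (default 0, 1e-4, 1e-3, 1e-2) of a common
  variance parameter, itself updated each iteration from the current nonzero
  effects; mixture proportions get a Dirichlet prior.
* ``bayesc`` — the exact two-component restriction (zero + one normal).
* ``rrblup`` — a single normal component with inclusion fixed at one, i.e.
  ridge regression / GBLUP estimated by the same Gibbs machinery.

Variance components carry scaled-inverse-chi-square priors (df 4, scales set
from a configurable prior partition of var(y)).  The reported additive
genetic variance per draw is the realized variance of the genetic values
var(Z g); heritability is h2 = sigma_g2 / (sigma_g2 + sigma_e2), farm
variance excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._gibbs import snp_sweep
from .genotypes import GenotypeMatrix

__all__ = [
    "ModelSpec",
    "ChainConfig",
    "McmcSamples",
    "PosteriorSummary",
    "snp_component_posterior",
    "run_chain",
    "summarize",
    "predict_gebv",
]

_DEFAULT_MULTIPLIERS = {
    "bayesr": (0.0, 1e-4, 1e-3, 1e-2),
    "bayesc": (0.0, 1.0),
    "rrblup": (1.0,),
}


# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class ModelSpec:
    """Prior family and model structure for one fit."""

    prior_kind: str = "bayesr"
    mixture_multipliers: tuple | None = None
    dirichlet_concentration: float = 1.0
    farm_effects: bool = True
    weights: bool = True
    update_sigma_g: bool = True
    fixed_variances: dict | None = None   # clamp sigma_g2/sigma_f2/sigma_e2
    prior_df: float = 4.0
    prior_genetic_fraction: float = 0.15
    prior_farm_fraction: float = 0.30

    def __post_init__(self):
        if self.prior_kind not in _DEFAULT_MULTIPLIERS:
            raise ValueError(f"unknown prior_kind {self.prior_kind!r}")
        mult = self.multipliers
        if self.prior_kind == "bayesr":
            if len(mult) < 2 or mult[0] != 0.0:
                raise ValueError("bayesr needs >=2 components with a zero first component")
        elif self.prior_kind == "bayesc":
            if len(mult) != 2 or mult[0] != 0.0 or mult[1] <= 0.0:
                raise ValueError("bayesc needs exactly (0, c) components")
        else:  # rrblup
            if len(mult) != 1 or mult[0] <= 0.0:
                raise ValueError("rrblup needs a single nonzero component")
        if any(b <= a for a, b in zip(mult, mult[1:])):
            raise ValueError("component multipliers must be strictly increasing")

    @property
    def multipliers(self) -> tuple:
        if self.mixture_multipliers is not None:
            return tuple(float(v) for v in self.mixture_multipliers)
        return _DEFAULT_MULTIPLIERS[self.prior_kind]

    @property
    def n_components(self) -> int:
        return len(self.multipliers)


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run lengths; retained draws = floor((n_iterations - burn_in)/thinning)."""

    n_iterations: int = 5000
    burn_in: int = 2000
    thinning: int = 5
    n_chains: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("need 0 <= burn_in < n_iterations")
        if self.thinning < 1 or self.n_chains < 1:
            raise ValueError("thinning and n_chains must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thinning


@dataclass
class McmcSamples:
    """Retained draws from one or more chains plus per-SNP accumulators."""

    spec: ModelSpec
    config: ChainConfig
    sigma_g2: np.ndarray        # (n_chains, n_retained) realized var(Z g)
    sigma_g2_hyper: np.ndarray
    sigma_f2: np.ndarray
    sigma_e2: np.ndarray
    h2: np.ndarray
    pi: np.ndarray              # (n_chains, n_retained, K)
    fixed: np.ndarray           # (n_chains, n_retained, n_fixed)
    fixed_names: list
    snp_effect_sum: np.ndarray  # (m,) summed over retained draws, all chains
    snp_comp_counts: np.ndarray  # (m, K)
    farm_effect_sum: np.ndarray | None
    marker_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    weights_used: np.ndarray
    final_states: list = field(default_factory=list)

    @property
    def n_retained_total(self) -> int:
        return self.sigma_g2.size


@dataclass
class PosteriorSummary:
    """Posterior means/SDs; houses the prediction equation (effects + constants)."""

    sigma_g2_mean: float
    sigma_g2_sd: float
    sigma_f2_mean: float
    sigma_f2_sd: float
    sigma_e2_mean: float
    sigma_e2_sd: float
    h2_mean: float
    h2_sd: float
    pi_mean: np.ndarray
    fixed_mean: np.ndarray
    fixed_sd: np.ndarray
    fixed_names: list
    snp_effect_mean: np.ndarray
    pip: np.ndarray
    comp_prob: np.ndarray
    farm_effect_mean: np.ndarray | None
    marker_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    center: np.ndarray
    scale: np.ndarray


# ---------------------------------------------------------------------- #
def snp_component_posterior(rhs, diag, sigma_e2, component_variances, pi):
    """Posterior probabilities that a marker occupies each mixture component.

    Log-space evaluation of pi_k times the marginal likelihood ratio of
    component k against the zero component; reference implementation of the
    arithmetic used inside the compiled sweep.
    """
    if sigma_e2 <= 0:
        raise ValueError("sigma_e2 must be positive")
    v = np.asarray(component_variances, dtype=float)
    pi = np.asarray(pi, dtype=float)
    logp = np.full(len(v), -np.inf)
    live = pi > 0
    if not live.any():
        raise ValueError("degenerate input: no component has positive prior mass")
    with np.errstate(divide="ignore"):
        base = np.log(pi, where=live, out=np.full(len(v), -np.inf))
    t = diag * v + sigma_e2
    ratio = np.where(v > 0, -0.5 * np.log(t / sigma_e2) + 0.5 * rhs**2 * v / (sigma_e2 * t), 0.0)
    logp = base + ratio
    logp -= logp[live].max()
    p = np.exp(logp)
    p[~live] = 0.0
    return p / p.sum()


# ---------------------------------------------------------------------- #
def _prepare_fixed(n: int, fixed_design) -> tuple[np.ndarray, list]:
    """Always prepend the overall-mean column."""
    if fixed_design is None:
        return np.ones((n, 1)), ["mean"]
    X = np.atleast_2d(np.asarray(fixed_design, dtype=float))
    if X.shape[0] != n:
        raise ValueError("fixed design rows do not match phenotype length")
    names = ["mean"] + [f"fixed{j}" for j in range(X.shape[1])]
    return np.column_stack([np.ones(n), X]), names


def run_chain(
    y,
    fixed_design,
    farm_of_animal,
    G: GenotypeMatrix,
    weights=None,
    spec: ModelSpec | None = None,
    config: ChainConfig | None = None,
) -> McmcSamples:
    """Run the Gibbs sampler; deterministic for a fixed ChainConfig.seed.

    ``fixed_design`` holds optional extra fixed-effect columns (the overall
    mean is always included); ``farm_of_animal`` is an integer farm index per
    animal or None to drop farm effects regardless of the spec flag.
    """
    spec = spec if spec is not None else ModelSpec()
    config = config if config is not None else ChainConfig()
    y = np.asarray(y, dtype=float)
    n = len(y)
    if G.n_animals != n:
        raise ValueError("genotypes and phenotypes disagree on n_animals")

    X, fixed_names = _prepare_fixed(n, fixed_design)
    use_farm = spec.farm_effects and farm_of_animal is not None
    if use_farm:
        farm_idx = np.asarray(farm_of_animal, dtype=np.int64)
        if len(farm_idx) != n:
            raise ValueError("farm index length does not match phenotypes")
        p_farms = int(farm_idx.max()) + 1
    else:
        farm_idx, p_farms = None, 0

    if spec.weights and weights is not None:
        w = np.asarray(weights, dtype=float)
        if len(w) != n or (w <= 0).any():
            raise ValueError("weights must be positive and match phenotype length")
    else:
        w = np.ones(n)

    Z = G.standardized(order="F")
    m = Z.shape[1]
    weighted = not np.all(w == 1.0)
    Zw = np.asfortranarray(Z * w[:, None]) if weighted else Z
    diag = np.einsum("i,ij,ij->j", w, Z, Z)

    mult = np.asarray(spec.multipliers)
    K = len(mult)
    vary = float(y.var())
    # prior scales: a coarse partition of the phenotypic variance
    s_gen = spec.prior_genetic_fraction * vary
    s_farm = spec.prior_farm_fraction * vary
    s_resid = max(vary - s_gen - s_farm, 0.05 * vary)
    if spec.prior_kind == "bayesr":
        scale_common = s_gen          # total-genetic-variance parameterization
    else:
        scale_common = s_gen / m      # per-marker-variance parameterization
    nu = spec.prior_df
    clamp = spec.fixed_variances or {}

    x_denoms = np.einsum("i,ij,ij->j", w, X, X)
    farm_w = np.bincount(farm_idx, weights=w, minlength=p_farms) if use_farm else None

    nr = config.n_retained
    shape2 = (config.n_chains, nr)
    out = McmcSamples(
        spec=spec,
        config=config,
        sigma_g2=np.zeros(shape2),
        sigma_g2_hyper=np.zeros(shape2),
        sigma_f2=np.full(shape2, np.nan),
        sigma_e2=np.zeros(shape2),
        h2=np.zeros(shape2),
        pi=np.zeros((*shape2, K)),
        fixed=np.zeros((*shape2, X.shape[1])),
        fixed_names=fixed_names,
        snp_effect_sum=np.zeros(m),
        snp_comp_counts=np.zeros((m, K), dtype=np.int64),
        farm_effect_sum=np.zeros(p_farms) if use_farm else None,
        marker_ids=G.marker_ids,
        chrom=G.chrom,
        pos=G.pos,
        center=G.center,
        scale=G.scale,
        weights_used=w,
    )

    for chain in range(config.n_chains):
        rng = np.random.default_rng(config.seed + 10007 * chain)
        b = np.zeros(X.shape[1])
        b[0] = float(np.average(y, weights=w))
        g = np.zeros(m)
        comp = np.zeros(m, dtype=np.int64)
        f = np.zeros(p_farms)
        e = y - X @ b

        sigma_common = float(clamp.get("sigma_g2", scale_common))
        sigma_f2 = float(clamp.get("sigma_f2", s_farm)) if use_farm else np.nan
        sigma_e2 = float(clamp.get("sigma_e2", s_resid))
        if K > 1:
            pi = np.full(K, 0.1 / (K - 1))
            pi[0] = 0.9
        else:
            pi = np.ones(1)

        kept = 0
        for it in range(config.n_iterations):
            # --- fixed effects (flat prior, scalar full conditionals) ---
            for c in range(X.shape[1]):
                xc = X[:, c]
                e += xc * b[c]
                rhs = float(np.dot(w * xc, e))
                b[c] = rhs / x_denoms[c] + rng.standard_normal() * np.sqrt(
                    sigma_e2 / x_denoms[c]
                )
                e -= xc * b[c]

            # --- SNP effects ---
            comp_var = mult * sigma_common
            counts, ssq_rel = snp_sweep(
                Z, Zw, e, g, comp, diag, comp_var, mult, pi, sigma_e2,
                rng.random(m), rng.standard_normal(m),
            )

            # --- farm effects (conditionally independent given e) ---
            if use_farm:
                e += f[farm_idx]
                sw = np.bincount(farm_idx, weights=w * e, minlength=p_farms)
                prec = farm_w / sigma_e2 + 1.0 / sigma_f2
                f = sw / sigma_e2 / prec + rng.standard_normal(p_farms) / np.sqrt(prec)
                e -= f[farm_idx]

            # --- variance components (scaled inverse chi-square) ---
            q = int(counts.sum() - (counts[0] if mult[0] == 0.0 else 0))
            if spec.update_sigma_g and "sigma_g2" not in clamp:
                sigma_common = (nu * scale_common + ssq_rel) / rng.chisquare(nu + q)
            if use_farm and "sigma_f2" not in clamp:
                sigma_f2 = (nu * s_farm + float(f @ f)) / rng.chisquare(nu + p_farms)
            if "sigma_e2" not in clamp:
                sigma_e2 = (nu * s_resid + float(w @ (e * e))) / rng.chisquare(nu + n)

            # --- mixture proportions ---
            if K > 1:
                pi = rng.dirichlet(spec.dirichlet_concentration + counts)

            # --- retention ---
            if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
                if kept < nr:
                    u_gen = y - X @ b - e - (f[farm_idx] if use_farm else 0.0)
                    sg2 = float(u_gen.var())
                    out.sigma_g2[chain, kept] = sg2
                    out.sigma_g2_hyper[chain, kept] = sigma_common
                    out.sigma_f2[chain, kept] = sigma_f2
                    out.sigma_e2[chain, kept] = sigma_e2
                    out.h2[chain, kept] = sg2 / (sg2 + sigma_e2)
                    out.pi[chain, kept] = pi
                    out.fixed[chain, kept] = b
                    out.snp_effect_sum += g
                    out.snp_comp_counts[np.arange(m), comp] += 1
                    if use_farm:
                        out.farm_effect_sum += f
                    kept += 1
        out.final_states.append(
            {"b": b.copy(), "g": g.copy(), "f": f.copy(), "e": e.copy(),
             "X": X, "farm_index": farm_idx, "y": y}
        )
    return out


# ---------------------------------------------------------------------- #
def summarize(samples: McmcSamples) -> PosteriorSummary:
    """Posterior means and SDs across all retained draws of all chains.

    h2 is computed per draw then averaged; the PIP of a marker is the
    fraction of retained draws in which it occupied a nonzero component.
    """
    if samples.n_retained_total == 0:
        raise ValueError("no retained draws to summarize")
    ndraws = samples.n_retained_total
    mult = np.asarray(samples.spec.multipliers)
    comp_prob = samples.snp_comp_counts / ndraws
    pip = comp_prob[:, mult > 0].sum(axis=1)
    use_farm = samples.farm_effect_sum is not None
    return PosteriorSummary(
        sigma_g2_mean=float(samples.sigma_g2.mean()),
        sigma_g2_sd=float(samples.sigma_g2.std()),
        sigma_f2_mean=float(samples.sigma_f2.mean()) if use_farm else float("nan"),
        sigma_f2_sd=float(samples.sigma_f2.std()) if use_farm else float("nan"),
        sigma_e2_mean=float(samples.sigma_e2.mean()),
        sigma_e2_sd=float(samples.sigma_e2.std()),
        h2_mean=float(samples.h2.mean()),
        h2_sd=float(samples.h2.std()),
        pi_mean=samples.pi.reshape(-1, samples.pi.shape[-1]).mean(axis=0),
        fixed_mean=samples.fixed.reshape(-1, samples.fixed.shape[-1]).mean(axis=0),
        fixed_sd=samples.fixed.reshape(-1, samples.fixed.shape[-1]).std(axis=0),
        fixed_names=samples.fixed_names,
        snp_effect_mean=samples.snp_effect_sum / ndraws,
        pip=pip,
        comp_prob=comp_prob,
        farm_effect_mean=(samples.farm_effect_sum / ndraws) if use_farm else None,
        marker_ids=samples.marker_ids,
        chrom=samples.chrom,
        pos=samples.pos,
        center=samples.center,
        scale=samples.scale,
    )


def predict_gebv(
    G_new: GenotypeMatrix,
    summary: PosteriorSummary,
    allow_partial: bool = False,
) -> np.ndarray:
    """GEBV for new animals: standardized dosages times posterior-mean effects.

    Standardization uses the TRAINING constants; markers are matched by id.
    Missing training markers are an error unless ``allow_partial``, in which
    case the overlapping subset is used (and at least one marker must match).
    """
    idx = G_new.marker_indexer(summary.marker_ids)
    present = idx >= 0
    if not present.all() and not allow_partial:
        raise ValueError(
            f"{int((~present).sum())} training markers absent from new genotypes; "
            "pass allow_partial=True to predict from the overlap"
        )
    if not present.any():
        raise ValueError("no overlapping markers between training and new genotypes")
    cols = idx[present]
    Z = (
        G_new.dosages[:, cols].astype(float) - summary.center[present]
    ) / summary.scale[present]
    return Z @ summary.snp_effect_mean[present]
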