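"""MCMC convergence diagnostics, trace export, and top-variant reporting.

Convergence across chains is assessed with the Brooks–Gelman multivariate
potential scale reduction factor (MPSRF),

    MPSRF = sqrt( (n-1)/n + (m+1)/m * lambda_max(W^{-1} B / n) ),

where W is the pooled within-chain covariance, B/n the between-chain
covariance of the means, m the number of chains and n the draws per chain.
Values near 1 indicate the chains have mixed; by convention a run is flagged
above 1.1.  By default the statistic is computed on the variance components
and fixed effects (not the SNP effects, whose dimension would swamp it).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import linalg

from .sampler import McmcSamples, PosteriorSummary

__all__ = ["gelman_rubin_mpsrf", "chain_matrix", "top_variants", "export_traces"]

logger = logging.getLogger(__name__)


def gelman_rubin_mpsrf(chains, threshold: float = 1.1) -> float:
    """Brooks–Gelman MPSRF over chains of parameter vectors.

    ``chains`` has shape (n_chains, n_draws, n_params) with >= 2 chains of
    equal length >= 10.  Logs a warning when the value exceeds ``threshold``.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
    m, n, d = chains.shape
    if m < 2:
        raise ValueError("need at least 2 chains")
    if n < 10:
        raise ValueError("need chains of length >= 10")

    means = chains.mean(axis=1)                      # (m, d)
    W = np.zeros((d, d))
    for j in range(m):
        dev = chains[j] - means[j]
        W += dev.T @ dev / (n - 1)
    W /= m
    grand = means.mean(axis=0)
    dm = means - grand
    B_over_n = dm.T @ dm / (m - 1)                   # = B / n

    try:
        lam = linalg.eigvals(linalg.solve(W, B_over_n)).real.max()
    except linalg.LinAlgError as exc:
        raise ValueError(
            "singular within-chain covariance; diagnose a parameter subset"
        ) from exc
    mpsrf = float(np.sqrt((n - 1) / n + (m + 1) / m * lam))
    if mpsrf > threshold:
        logger.warning("MPSRF %.3f exceeds threshold %.2f", mpsrf, threshold)
    return mpsrf


def chain_matrix(samples: McmcSamples, include_fixed: bool = True) -> np.ndarray:
    """Stack variance-component (and fixed-effect) draws as (chains, draws, params)."""
    parts = [samples.sigma_g2[..., None], samples.sigma_e2[..., None]]
    if samples.farm_effect_sum is not None:
        parts.insert(1, samples.sigma_f2[..., None])
    if include_fixed:
        parts.append(samples.fixed)
    return np.concatenate(parts, axis=2)


def top_variants(summary: PosteriorSummary, n_top: int = 10) -> pd.DataFrame:
    """Markers ranked by PIP (ties: |posterior mean effect|, then marker id)."""
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    m = len(summary.pip)
    if n_top > m:
        logger.warning("n_top=%d exceeds %d markers; truncating", n_top, m)
        n_top = m
    df = pd.DataFrame(
        {
            "marker_id": summary.marker_ids,
            "chrom": summary.chrom,
            "pos": summary.pos,
            "pip": summary.pip,
            "posterior_mean": summary.snp_effect_mean,
        }
    )
    df["abs_effect"] = df["posterior_mean"].abs()
    df = df.sort_values(
        ["pip", "abs_effect", "marker_id"],
        ascending=[False, False, True],
        kind="stable",
    ).drop(columns="abs_effect")
    return df.head(n_top).reset_index(drop=True)


def export_traces(samples: McmcSamples, path) -> pd.DataFrame:
    """Write retained draws as long-format CSV (chain, iteration, parameter, value)."""
    if samples.n_retained_total == 0:
        raise ValueError("no retained draws to export")
    records = []
    named = {
        "sigma_g2": samples.sigma_g2,
        "sigma_e2": samples.sigma_e2,
        "h2": samples.h2,
    }
    if samples.farm_effect_sum is not None:
        named["sigma_f2"] = samples.sigma_f2
    for k, name in enumerate(samples.fixed_names):
        named[name] = samples.fixed[:, :, k]
    for name, arr in named.items():
        nc, nd = arr.shape
        for c in range(nc):
            records.append(
                pd.DataFrame(
                    {"chain": c, "iteration": np.arange(nd), "parameter": name,
                     "value": arr[c]}
                )
            )
    df = pd.concat(records, ignore_index=True)
    df.to_csv(path, index=False)
    return df
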