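"""GBLUP comparator: GRM construction and a direct mixed-model-equation solver.

This module is the deterministic oracle against which the Gibbs sampler's
ridge (rrblup) restriction is checked: with fixed variance components the
posterior mean GEBV of the sampler must agree with the Henderson
mixed-model-equation solution using the relationship matrix G = Z Z' / m.
Dense direct solves only — clarity over speed at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .genotypes import GenotypeMatrix

__all__ = ["Grm", "MmeSolution", "build_grm", "solve_mme", "ridge_gebv"]

_JITTER = 1e-8


@dataclass
class Grm:
    """Genomic relationship matrix (VanRaden, standardized dosages)."""

    matrix: np.ndarray
    n_markers: int
    animal_ids: np.ndarray


@dataclass
class MmeSolution:
    fixed: np.ndarray
    gebv: np.ndarray
    farm: np.ndarray | None


def build_grm(G: GenotypeMatrix) -> Grm:
    """GRM = Z Z' / m from standardized dosages; symmetric, mean diagonal ~ 1."""
    if G.n_animals < 2:
        raise ValueError("need at least 2 animals")
    if G.n_markers < 1:
        raise ValueError("no polymorphic markers")
    Z = G.standardized(order="C")
    A = Z @ Z.T / G.n_markers
    return Grm(matrix=(A + A.T) / 2.0, n_markers=G.n_markers, animal_ids=G.animal_ids)


def solve_mme(
    y,
    fixed_design,
    farm_of_animal,
    grm: Grm,
    sigma_g2: float,
    sigma_e2: float,
    sigma_f2: float | None = None,
    weights=None,
) -> MmeSolution:
    """Direct solve of the weighted mixed-model equations.

    Breeding values u ~ N(0, G sigma_g2) with one record per animal; optional
    farm effects f ~ N(0, I sigma_f2); residual covariance diag(1/w) sigma_e2.
    The overall mean is always prepended to the fixed design.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if sigma_g2 <= 0 or sigma_e2 <= 0:
        raise ValueError("variance components must be positive")
    if fixed_design is None:
        X = np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), np.atleast_2d(np.asarray(fixed_design, float))])
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")

    # variance (GLS/BLUP) form: V = s_g2 A + s_f2 FF' + s_e2 diag(1/w).
    # Equivalent to Henderson's equations but needs no A^{-1} — important
    # because a GRM from sample-centered genotypes is singular (A 1 = 0).
    A = grm.matrix
    V = sigma_g2 * A + sigma_e2 * np.diag(1.0 / w)
    use_farm = farm_of_animal is not None
    if use_farm:
        if sigma_f2 is None or sigma_f2 <= 0:
            raise ValueError("farm effects requested but sigma_f2 not positive")
        farm_idx = np.asarray(farm_of_animal, dtype=np.int64)
        p = int(farm_idx.max()) + 1
        F = np.zeros((n, p))
        F[np.arange(n), farm_idx] = 1.0
        V += sigma_f2 * F @ F.T

    try:
        cho = linalg.cho_factor(V)
    except linalg.LinAlgError:
        cho = linalg.cho_factor(V + _JITTER * np.trace(V) / n * np.eye(n))
    Vi_y = linalg.cho_solve(cho, y)
    Vi_X = linalg.cho_solve(cho, X)
    try:
        fixed = linalg.solve(X.T @ Vi_X, X.T @ Vi_y, assume_a="sym")
    except linalg.LinAlgError as exc:
        raise ValueError("singular mixed-model coefficient matrix") from exc
    Vi_r = Vi_y - Vi_X @ fixed

    return MmeSolution(
        fixed=fixed,
        gebv=sigma_g2 * (A @ Vi_r),
        farm=sigma_f2 * (F.T @ Vi_r) if use_farm else None,
    )


def ridge_gebv(
    G: GenotypeMatrix, y, sigma_b2: float, sigma_e2: float, weights=None
) -> np.ndarray:
    """SNP-BLUP: ridge regression of y on standardized markers.

    Marker effects get variance sigma_b2; with sigma_b2 = sigma_g2 / m this
    reproduces the GRM-based MME GEBV (the classical RR-BLUP/GBLUP identity).
    An intercept with a flat prior is absorbed.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    Z = G.standardized(order="C")
    X = np.ones((n, 1))
    lam = sigma_e2 / sigma_b2
    # joint solve for [intercept, g] with penalty only on g
    Wm = np.column_stack([X, Z])
    C = Wm.T @ (w[:, None] * Wm)
    C[1:, 1:] += lam * np.eye(Z.shape[1])
    sol = linalg.solve(C, Wm.T @ (w * y), assume_a="sym")
    return Z @ sol[1:]
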