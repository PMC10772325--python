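"""Numba kernel for the single-site SNP sweep of the Gibbs sampler.

The sweep maintains the weighted residual vector incrementally: for marker j
with current effect g_j, the full-conditional right-hand side is

    r_j = z_j' W e + d_j g_j,      d_j = z_j' W z_j,

the marginal log-likelihood of mixture component k (variance v_k) relative to
the zero component is

    -0.5 log(1 + d_j v_k / s_e2) + 0.5 r_j^2 v_k / (s_e2 (d_j v_k + s_e2)),

and a sampled nonzero effect comes from N(r_j v_k / (d_j v_k + s_e2),
v_k s_e2 / (d_j v_k + s_e2)).  Randomness (one uniform and one standard
normal per marker) is pre-generated by the caller so a single NumPy Generator
governs the whole chain.
"""

import numpy as np
from numba import njit

__all__ = ["snp_sweep"]


@njit(cache=True, fastmath=True)
def snp_sweep(Z, Zw, e, g, comp, diag, comp_var, mult, pi, sigma_e2, u_comp, z_norm):
    """One Gibbs sweep over all markers; mutates e, g, comp in place.

    Returns (counts, ssq_rel): per-component occupancy and the sum of
    g_j^2 / mult_k over markers in nonzero components (the quantity entering
    the common-variance full conditional).
    """
    n, m = Z.shape
    K = comp_var.shape[0]
    counts = np.zeros(K, dtype=np.int64)
    ssq_rel = 0.0
    logp = np.empty(K)

    for j in range(m):
        gj = g[j]
        r = diag[j] * gj
        for i in range(n):
            r += Zw[i, j] * e[i]

        maxlog = -1e300
        for k in range(K):
            if pi[k] <= 0.0:
                logp[k] = -1e300
                continue
            v = comp_var[k]
            if v <= 0.0:
                lk = np.log(pi[k])
            else:
                t = diag[j] * v + sigma_e2
                lk = np.log(pi[k]) - 0.5 * np.log(t / sigma_e2) \
                    + 0.5 * r * r * v / (sigma_e2 * t)
            logp[k] = lk
            if lk > maxlog:
                maxlog = lk

        total = 0.0
        for k in range(K):
            logp[k] = np.exp(logp[k] - maxlog)
            total += logp[k]
        if total <= 0.0:
            raise ValueError("degenerate component posterior (all -inf)")

        u = u_comp[j] * total
        acc = 0.0
        k_new = K - 1
        for k in range(K):
            acc += logp[k]
            if u <= acc:
                k_new = k
                break

        v = comp_var[k_new]
        if v <= 0.0:
            g_new = 0.0
        else:
            t = diag[j] * v + sigma_e2
            g_new = r * v / t + np.sqrt(v * sigma_e2 / t) * z_norm[j]
            ssq_rel += g_new * g_new / mult[k_new]

        d = g_new - gj
        if d != 0.0:
            for i in range(n):
                e[i] -= Z[i, j] * d
        g[j] = g_new
        comp[j] = k_new
        counts[k_new] += 1

    return counts, ssq_rel
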