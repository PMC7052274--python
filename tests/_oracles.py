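"""Brute-force numerical oracles, independent of the closed-form code paths.

Everything here integrates the local Gaussian jump likelihood against the
conjugate prior on dense grids — no natural parameters, no closed forms —
and is used only to cross-check the analytic Bayes factors and posteriors on
small instances.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import simpson


def _z_prior_log(z: np.ndarray, d: int, n_pi: int, V_pi: float) -> np.ndarray:
    """Unnormalized log prior of z = b²Δt shared by H0 and H1 (Eq.-8 form)."""
    return -d * (n_pi - 1) / 2.0 * np.log(z) - n_pi * V_pi / (2.0 * z)


def _log_trapz(log_f: np.ndarray, x: np.ndarray, axis: int = -1) -> np.ndarray:
    m = np.max(log_f, axis=axis, keepdims=True)
    val = simpson(np.exp(log_f - m), x=x, axis=axis)
    return np.squeeze(m, axis=axis) + np.log(val)


def brute_force_log_bayes_factor(n: int, d: int, dr_mean, V: float, g_hat,
                                 dt: float, n_pi: int, V_pi: float,
                                 n_lambda: int = 201, n_z: int = 401,
                                 n_a: int = 401) -> float:
    """ln K^M by direct grid marginalization over (drift, b², λ).

    The likelihood of the bin's sufficient statistics is integrated against
    the normalized conditional drift prior aΔt ~ N(0, z/n_π) (per component)
    and the shared unnormalized z-prior; the drift integral factorizes over
    components, so each is a dense 1-d quadrature.
    """
    dr_mean = np.atleast_1d(np.asarray(dr_mean, dtype=float))
    g_dt = np.atleast_1d(np.asarray(g_hat, dtype=float)) * dt
    lam = np.linspace(0.0, 1.0, n_lambda)

    # z-grid covering the inverse-gamma posterior mass generously
    kappa = d * (n + n_pi - 1) / 2.0 - 1.0
    z_center = (n * V + n_pi * V_pi) / (2.0 * (kappa + 1.0))
    z = np.geomspace(z_center * 1e-3, z_center * 1e3, n_z)
    log_pz = _z_prior_log(z, d, n_pi, V_pi)

    # drift grid per component (aΔt), wide enough for every λ and z
    a_half = (np.max(np.abs(dr_mean)) + np.max(np.abs(g_dt)) + 1e-12
              + 12.0 * np.sqrt(z_center * 10.0 / min(n, n_pi)))
    a = np.linspace(-a_half, a_half, n_a)

    log_num = np.empty(n_lambda)
    log_den = np.empty(n_lambda)
    base = -n * d / 2.0 * np.log(2.0 * np.pi * z) - n * V / (2.0 * z)
    for i, lam_i in enumerate(lam):
        resid = dr_mean - lam_i * g_dt            # per-component residual
        # H0: drift pinned at the spurious value
        log_den[i] = _log_trapz(
            log_pz + base - n * np.sum(resid**2) / (2.0 * z), z)
        # H1: numeric drift integral per component
        log_comp = np.zeros_like(z)
        for k in range(d):
            integrand = (-n_pi * a[None, :] ** 2 / (2.0 * z[:, None])
                         - n * (resid[k] - a[None, :]) ** 2
                         / (2.0 * z[:, None]))
            log_comp += (_log_trapz(integrand, a, axis=1)
                         + 0.5 * (np.log(n_pi) - np.log(2.0 * np.pi * z)))
        log_num[i] = _log_trapz(log_pz + base + log_comp, z)
    return float(_log_trapz(log_num, lam) - _log_trapz(log_den, lam))


def brute_force_posterior_1d(n: int, dr_mean: float, V: float, g_hat: float,
                             dt: float, n_pi: int, V_pi: float,
                             a_dt_grid: np.ndarray, n_lambda: int = 201,
                             n_z: int = 1201) -> np.ndarray:
    """Unnormalized 1-d posterior of aΔt by grid marginalization over (b², λ)."""
    lam = np.linspace(0.0, 1.0, n_lambda)
    kappa = (n + n_pi - 1) / 2.0 - 1.0
    z_center = (n * V + n_pi * V_pi) / (2.0 * (kappa + 1.0))
    z = np.geomspace(z_center * 1e-3, z_center * 1e3, n_z)
    log_pz = _z_prior_log(z, 1, n_pi, V_pi)
    base = (-n / 2.0 * np.log(2.0 * np.pi * z) - n * V / (2.0 * z)
            - 0.5 * np.log(z))  # second term: drift-prior z-dependence
    out = np.empty(len(a_dt_grid))
    for j, a_dt in enumerate(a_dt_grid):
        logs = np.empty((n_lambda, n_z))
        for i, lam_i in enumerate(lam):
            resid = dr_mean - a_dt - lam_i * g_hat * dt
            logs[i] = (log_pz + base - n_pi * a_dt**2 / (2.0 * z)
                       - n * resid**2 / (2.0 * z))
        out[j] = _log_trapz(_log_trapz(logs, z, axis=1), lam)
    out -= out.max()
    return np.exp(out)
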