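"""Per-bin sufficient statistics, diffusivity/drift estimates, gradient map.

For the local Gaussian jump likelihood the displacements inside one bin enter
only through three numbers: the count n, the mean displacement Δr̄ and the
biased sample variance V = Σ|Δr_i − Δr̄|²/n (components summed).  This module
computes those statistics and the three per-bin point estimates built from
them:

* the MAP diffusivity with a 95% credible interval, from the inverse-gamma
  marginal posterior of the squared noise amplitude b²Δt (drift integrated
  out of the conjugate model);
* the total-drift estimate α̂ = Δr̄/Δt;
* the spurious-drift coefficient map ĝ = b̂∇b̂, obtained by a weighted
  least-squares plane fit of b̂ = √(2D̂) over each bin's spatial neighborhood.

ĝ is stored with the λ = 1 normalization (units µm/s), i.e. the full spurious
drift at convention λ is λ·ĝ.  For a smooth diffusivity field ĝ = ∇D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .bayes_core import PriorHyperparameters, effective_variance

__all__ = [
    "BinStatistics",
    "DiffusivityEstimate",
    "GradientEstimate",
    "bin_sufficient_stats",
    "estimate_diffusivity",
    "estimate_drift",
    "map_gradient",
]


@dataclass(frozen=True)
class BinStatistics:
    """Sufficient statistics of the displacements in one spatial bin."""

    n: int
    dr_mean: np.ndarray   # mean displacement vector [µm]
    V: float              # biased sample variance, components summed [µm²]
    dt: float             # frame interval [s]
    d: int
    centroid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("a bin must contain at least one displacement")
        if self.V < 0:
            raise ValueError("V must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class DiffusivityEstimate:
    """MAP diffusivity and 95% credible interval [µm²/s]."""

    D_map: float
    ci95: tuple
    degenerate: bool = False   # V = 0 with n > 1: prior-dominated posterior

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.D_map <= hi):
            raise ValueError("D_map must lie inside its credible interval")


@dataclass(frozen=True)
class GradientEstimate:
    """Spurious-drift coefficient ĝ = b∇b at a bin [µm/s]; None if undefined."""

    g_hat: np.ndarray | None

    @property
    def defined(self) -> bool:
        return self.g_hat is not None


def bin_sufficient_stats(deltas: np.ndarray, dt: float, d: int,
                         centroid=None) -> BinStatistics:
    """Compute (n, Δr̄, V) for the displacements assigned to one bin."""
    deltas = np.atleast_2d(np.asarray(deltas, dtype=float))
    if deltas.size == 0:
        raise ValueError("empty bin")
    if deltas.shape[1] != d:
        raise ValueError("displacement dimension mismatch")
    n = deltas.shape[0]
    dr_mean = deltas.mean(axis=0)
    if np.all(deltas == deltas[0]):
        V = 0.0   # identical displacements: exactly degenerate
    else:
        V = float(np.sum((deltas - dr_mean) ** 2) / n)
    return BinStatistics(n=n, dr_mean=dr_mean, V=V, dt=dt, d=d,
                         centroid=None if centroid is None
                         else np.asarray(centroid, dtype=float))


def estimate_diffusivity(stats: BinStatistics,
                         prior: PriorHyperparameters | None = None,
                         sigma_L: float | None = None) -> DiffusivityEstimate:
    """MAP and 95% CI of the diffusivity from the marginal b²-posterior.

    Integrating the drift out of likelihood × conjugate prior (prior centred
    on zero non-diffusive force, gradient term at its point estimate) leaves
    an inverse-gamma posterior for z = b²Δt with shape κ = d(n+n_π−1)/2 − 1
    and scale S/2, S = nV_eff(v + η²ζ_t²).  D = z/(2Δt); the MAP is
    S/(2(κ+1))/(2Δt) → V_eff/(2dΔt) as n → ∞, and the interval is the
    equal-tailed 95% posterior interval.
    """
    prior = prior or PriorHyperparameters()
    if sigma_L is None:
        sigma_L = prior.localization_sigma
    d, n = stats.d, stats.n
    n_pi = prior.resolve_n_pi(d)
    if n < n_pi:
        raise ValueError(f"n={n} < n_pi={n_pi}: no diffusivity estimate")
    V_eff, _ = effective_variance(stats.V, d, sigma_L)
    degenerate = stats.V == 0.0 and n > 1
    kappa = d * (n + n_pi - 1) / 2.0 - 1.0
    eta2 = n_pi / (n + n_pi)
    if V_eff > 0.0:
        zeta_t2 = float(stats.dr_mean @ stats.dr_mean) / V_eff
        v = 1.0 + n_pi * prior.u / n
        S = n * V_eff * (v + eta2 * zeta_t2)
    else:  # V = 0 exactly and no localization term: prior-dominated
        S = n_pi * prior.u * max(stats.V, 1e-30) + n * eta2 * float(
            stats.dr_mean @ stats.dr_mean)
        degenerate = True
    post = sps.invgamma(kappa, scale=S / 2.0)
    z_map = (S / 2.0) / (kappa + 1.0)
    lo, hi = post.ppf([0.025, 0.975])
    scale = 1.0 / (2.0 * stats.dt)
    return DiffusivityEstimate(D_map=z_map * scale,
                               ci95=(float(lo) * scale, float(hi) * scale),
                               degenerate=degenerate)


def estimate_drift(stats: BinStatistics) -> np.ndarray:
    """Total-drift point estimate α̂ = Δr̄/Δt [µm/s]."""
    return np.asarray(stats.dr_mean, dtype=float) / stats.dt


def _neighborhood_pitch(centroids: np.ndarray, i: int) -> float:
    """Distance from centroid i to its nearest other centroid."""
    diffs = centroids - centroids[i]
    dist = np.linalg.norm(diffs, axis=1)
    dist[i] = np.inf
    return float(dist.min())


def map_gradient(D_map: np.ndarray, tess, counts: np.ndarray,
                 pitch_factor: float = 1.5) -> list[GradientEstimate]:
    """Per-bin spurious-drift coefficient ĝ = b̂∇b̂ from a plane fit of b̂.

    For each bin with a diffusivity estimate, b̂ = √(2D̂) is fit by weighted
    least squares (weights = per-bin displacement counts) with an affine
    model over the bin and its neighbors — the non-empty bins whose
    centroids lie within ``pitch_factor`` × the local bin pitch (nearest
    centroid distance).  The fitted slope ∇b̂ at the centroid gives
    ĝ = b̂(x_i)·∇b̂.  Bins with fewer than d+2 usable neighbors (fit
    underdetermined) are returned undefined.
    """
    D_map = np.asarray(D_map, dtype=float)
    counts = np.asarray(counts)
    d = tess.d
    centroids = tess.centroids()
    usable = np.flatnonzero((counts > 0) & np.isfinite(D_map) & (D_map > 0))
    out: list[GradientEstimate] = [GradientEstimate(None)] * tess.n_bins
    if len(usable) < d + 1:
        return out
    cent_u = centroids[usable]
    b_u = np.sqrt(2.0 * D_map[usable])
    w_u = counts[usable].astype(float)
    for local_i, bin_i in enumerate(usable):
        pitch = _neighborhood_pitch(cent_u, local_i)
        if not np.isfinite(pitch):
            continue
        dist = np.linalg.norm(cent_u - cent_u[local_i], axis=1)
        sel = dist <= pitch_factor * pitch + 1e-12
        if np.sum(sel) < d + 2:
            continue
        X = np.hstack([np.ones((np.sum(sel), 1)),
                       cent_u[sel] - cent_u[local_i]])
        w = w_u[sel]
        # weighted normal equations for the affine fit b(x) = c0 + c·(x−x_i)
        A = X.T * w @ X
        rhs = X.T * w @ b_u[sel]
        try:
            coef = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            continue
        b0, slope = coef[0], coef[1:]
        out[bin_i] = GradientEstimate(g_hat=b0 * slope)
    return out
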