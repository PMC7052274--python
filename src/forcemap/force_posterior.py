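"""Marginalized and fixed-λ posteriors of the non-diffusive force.

Once the test favours a non-diffusive force, its magnitude is inferred from
the posterior of the dimensionless force signal-to-noise ζ_a = aΔt/√V_eff,

    p(ζ_a | T) ∝ ∫₀¹ dλ [ v + η²/(1−η²)·|ζ_a|² + |ζ_t − ζ_a − λζ_sp|² ]^{−κ−d/2},

in which the unknown convention λ is marginalized with its flat prior.  The
fixed-λ posteriors (Itô λ=0, Stratonovich 1/2, Hänggi 1) replace the integral
by a point evaluation; the marginalized posterior is their evidence-weighted
mixture, hence wider and, when ζ_sp ≠ 0, generally skewed — the honest price
of not knowing the convention.

For d = 2 all densities are evaluated in the frame aligned with ζ_sp (axes
"par" along the spurious drift and "perp" orthogonal to it); multiplying ζ_a
by scale = √V_eff/Δt converts to physical drift units (force per friction,
µm/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bayes_core import NaturalParameters, _log_trapezoid

__all__ = [
    "ForcePosterior",
    "GridSpec",
    "log_posterior_density",
    "posterior_density",
    "summarize_posterior",
    "fixed_lambda_posterior",
]


class GridTooSmallError(ValueError):
    """More than the allowed posterior mass sits on the grid boundary."""


@dataclass(frozen=True)
class GridSpec:
    """Evaluation grid for the force posterior, in the ζ_sp-aligned frame."""

    n_points: int = 201
    n_sigma: float = 6.0   # half-width in approximate posterior widths


@dataclass(frozen=True)
class ForcePosterior:
    """Normalized force posterior on a regular grid in ζ_a-space.

    ``axes`` holds the grid coordinates per dimension (par axis first);
    ``density`` the normalized values (shape = grid shape); ``map_point`` the
    grid argmax refined by a local quadratic fit; ``ci95_1d`` the equal-tailed
    95% interval of the 1-d marginal along the ĝ (par) direction.  ``scale``
    (√V_eff/Δt, µm/s) converts ζ_a to physical force-per-friction units, and
    ``frame`` gives the unit vectors of the aligned axes in data coordinates.
    """

    axes: tuple
    density: np.ndarray
    map_point: np.ndarray
    ci95_1d: tuple
    scale: float
    frame: np.ndarray
    lam: float | None = None   # None = marginalized

    def marginal_par(self) -> tuple[np.ndarray, np.ndarray]:
        """1-d marginal density along the ĝ direction."""
        x = self.axes[0]
        if self.density.ndim == 1:
            return x, self.density
        y = self.axes[1]
        marg = np.trapezoid(self.density, y, axis=1)
        return x, marg


def _lambda_nodes(np_: NaturalParameters, n_nodes: int = 257) -> np.ndarray:
    if float(np.linalg.norm(np_.zeta_sp)) == 0.0:
        return np.asarray([0.0])
    return np.linspace(0.0, 1.0, n_nodes)


def log_posterior_density(np_: NaturalParameters, zeta_a: np.ndarray,
                          lam: float | None = None,
                          n_lambda: int = 257) -> np.ndarray:
    """Log unnormalized posterior density at points ``zeta_a``.

    ``zeta_a`` has shape (..., d) in the ζ_sp-aligned frame (for d = 1 a
    trailing axis of length 1, or a bare array).  ``lam=None`` marginalizes λ
    by trapezoid quadrature in log-space; a float gives the fixed-λ density.
    """
    za = np.asarray(zeta_a, dtype=float)
    if za.ndim == 0 or za.shape[-1] != np_.d:
        za = za[..., None]
        if za.shape[-1] != np_.d:
            raise ValueError("zeta_a must have trailing dimension d")
    sp = float(np.linalg.norm(np_.zeta_sp))
    power = np_.kappa + np_.d / 2.0
    prior_w = np_.eta**2 / (1.0 - np_.eta**2)
    za2 = np.sum(za**2, axis=-1)
    # residual split in the aligned frame: par component carries λζ_sp
    res_par0 = np_.zeta_par - za[..., 0]
    res_perp2 = ((np_.zeta_perp - za[..., 1]) ** 2
                 if np_.d == 2 else np.zeros_like(za2))
    if lam is not None:
        q = (res_par0 - lam * sp) ** 2 + res_perp2
        return -power * np.log(np_.v + prior_w * za2 + q)
    nodes = _lambda_nodes(np_, n_lambda)
    if len(nodes) == 1:
        q = res_par0**2 + res_perp2
        return -power * np.log(np_.v + prior_w * za2 + q)
    logs = np.empty(nodes.shape + za2.shape)
    for i, lam_i in enumerate(nodes):
        q = (res_par0 - lam_i * sp) ** 2 + res_perp2
        logs[i] = -power * np.log(np_.v + prior_w * za2 + q)
    # trapezoid over λ in log space, vectorized over grid points
    m = logs.max(axis=0)
    w = np.exp(logs - m)
    w[0] *= 0.5
    w[-1] *= 0.5
    return m + np.log(w.sum(axis=0) / (len(nodes) - 1))


def posterior_density(np_: NaturalParameters, zeta_a: np.ndarray,
                      lam: float | None = None) -> np.ndarray:
    """Unnormalized posterior density (linear scale, max-shifted to 1)."""
    logp = log_posterior_density(np_, zeta_a, lam=lam)
    return np.exp(logp - np.max(logp))


def _approx_width(np_: NaturalParameters) -> float:
    """Gaussian-approximation posterior width of a fixed-λ posterior."""
    power = np_.kappa + np_.d / 2.0
    denom = 1.0 + np_.eta**2 / (1.0 - np_.eta**2)
    var = np_.v / max(2.0 * power - 3.0, 1.0) / denom
    return math.sqrt(var)


def _grid_axes(np_: NaturalParameters, spec: GridSpec) -> tuple:
    sp = float(np.linalg.norm(np_.zeta_sp))
    width = _approx_width(np_)
    half = spec.n_sigma * width + sp  # λ-mixture shifts the mass by up to ζ_sp
    x = np.linspace(np_.zeta_par - sp - half, np_.zeta_par + half,
                    spec.n_points)
    if np_.d == 1:
        return (x,)
    y = np.linspace(np_.zeta_perp - half, np_.zeta_perp + half, spec.n_points)
    return (x, y)


def _summaries(axes: tuple, density: np.ndarray) -> tuple:
    """Normalize in place; return (density, map_point, ci95_par)."""
    x = axes[0]
    if density.ndim == 1:
        norm = np.trapezoid(density, x)
        density = density / norm
        marg = density
    else:
        y = axes[1]
        norm = np.trapezoid(np.trapezoid(density, y, axis=1), x)
        density = density / norm
        marg = np.trapezoid(density, y, axis=1)
    # MAP: grid argmax refined by a local quadratic fit per axis
    flat = int(np.argmax(density))
    idx = np.unravel_index(flat, density.shape)
    map_pt = []
    for k, ax in enumerate(axes):
        i = idx[k]
        if 0 < i < len(ax) - 1:
            sl = list(idx)
            vals = []
            for j in (i - 1, i, i + 1):
                sl[k] = j
                vals.append(density[tuple(sl)])
            denom = vals[0] - 2 * vals[1] + vals[2]
            shift = 0.0 if denom == 0 else 0.5 * (vals[0] - vals[2]) / denom
            map_pt.append(ax[i] + shift * (ax[1] - ax[0]))
        else:
            map_pt.append(ax[i])
    # equal-tailed 95% interval of the par-axis marginal
    cdf = np.concatenate([[0.0], np.cumsum(
        0.5 * (marg[1:] + marg[:-1]) * np.diff(x))])
    cdf /= cdf[-1]
    lo = float(np.interp(0.025, cdf, x))
    hi = float(np.interp(0.975, cdf, x))
    return density, np.asarray(map_pt), (lo, hi)


def _edge_mass(axes: tuple, density: np.ndarray) -> float:
    if density.ndim == 1:
        edge = max(density[0], density[-1])
        peak = density.max()
    else:
        edge = max(density[0].max(), density[-1].max(),
                   density[:, 0].max(), density[:, -1].max())
        peak = density.max()
    return float(edge / peak)


def _frame(np_: NaturalParameters) -> np.ndarray:
    """Unit vectors of the (par, perp) axes in data coordinates."""
    sp = float(np.linalg.norm(np_.zeta_sp))
    if np_.d == 1:
        return np.asarray([[1.0]])
    if sp == 0.0:
        t = float(np.linalg.norm(np_.zeta_t))
        if t == 0.0:
            return np.eye(2)
        e_par = np_.zeta_t / t
    else:
        e_par = np_.zeta_sp / sp
    e_perp = np.asarray([-e_par[1], e_par[0]])
    return np.vstack([e_par, e_perp])


def _build(np_: NaturalParameters, lam: float | None,
           spec: GridSpec) -> ForcePosterior:
    spec_now = spec
    for attempt in range(4):
        axes = _grid_axes(np_, spec_now)
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        dens = posterior_density(np_, mesh, lam=lam)
        if _edge_mass(axes, dens) <= 1e-4:
            break
        spec_now = GridSpec(n_points=spec_now.n_points,
                            n_sigma=spec_now.n_sigma * 2.0)
    else:
        raise GridTooSmallError("posterior mass persists at the grid edge")
    dens, map_pt, ci = _summaries(axes, dens)
    return ForcePosterior(
        axes=axes, density=dens, map_point=map_pt, ci95_1d=ci,
        scale=math.sqrt(np_.V_eff) / np_.dt if math.isfinite(np_.V_eff)
        else float("nan"),
        frame=_frame(np_), lam=lam)


def summarize_posterior(np_: NaturalParameters,
                        spec: GridSpec | None = None) -> ForcePosterior:
    """Normalized marginalized force posterior with MAP and 95% CI."""
    return _build(np_, None, spec or GridSpec())


def fixed_lambda_posterior(np_: NaturalParameters, lam: float,
                           spec: GridSpec | None = None) -> ForcePosterior:
    """Force posterior at a fixed convention λ (Itô 0, Strat. 1/2, Hänggi 1)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return _build(np_, lam, spec or GridSpec())
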