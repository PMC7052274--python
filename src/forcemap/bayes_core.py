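"""Closed-form Bayes factors for non-diffusive forces under convention ambiguity.

The overdamped Langevin equation with heterogeneous diffusivity only defines a
random walk once a stochastic-integration convention λ ∈ [0, 1] is chosen
(λ = 0 Itô, 1/2 Stratonovich, 1 Hänggi–Klimontovich).  Each λ contributes a
"spurious" drift λ·b∇b proportional to the diffusivity gradient, so a recorded
mesoscopic drift is ambiguous: it may be a genuine non-diffusive force or a
convention artefact.  This module implements the statistical test that
discriminates the two nested hypotheses

    H0: only spurious forces (drift fully explained by some λ·b∇b),
    H1: a non-diffusive force a is present in addition,

via Bayes factors in which λ is marginalized with a flat prior.  With a
conjugate (normal–inverse-gamma) prior of effective strength ``n_pi`` on the
local drift and squared noise amplitude, both model evidences reduce to
one-dimensional λ-integrals, and the Bayes factor depends on the data only
through a handful of dimensionless natural parameters:

    ζ_t  = Δr̄ / √V_eff       signal-to-noise of the total drift per jump,
    ζ_sp = ĝΔt / √V_eff      signal-to-noise of the λ=1 spurious drift,
    η    = √(n_π/(n+n_π))     prior strength relative to the data,
    v    = 1 + n_π V_π/(n V_eff),
    κ    = d(n+n_π−1)/2 − 1   evidence exponent.

The fixed-λ Bayes factor is fully closed-form,

    K(λ) = η^d [ (v + η²|ζ_t − λζ_sp|²) / (v + |ζ_t − λζ_sp|²) ]^{−κ},

and the marginalized factor K^M = η^d ∫dλ[...]^{−κ} / ∫dλ[...]^{−κ} is the
ratio of two λ-integrals evaluated by adaptive trapezoid quadrature in
log-space.  All public functions work with log10 values; κ easily exceeds 500
for well-sampled bins, so nothing here ever exponentiates an un-shifted
integrand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PriorHyperparameters",
    "NaturalParameters",
    "BayesFactorResult",
    "effective_variance",
    "natural_parameters",
    "log_evidence",
    "bayes_factor_fixed",
    "bayes_factor_marginalized",
    "classify",
    "lambda_map_H0",
    "min_proper_n_pi",
    "compute_bayes_factors",
]

#: classification labels (Bayes-factor map colour code)
NONSPURIOUS = "nonspurious"
SPURIOUS_ONLY = "spurious_only"
INCONCLUSIVE = "inconclusive"

_CONVENTIONS = (0.0, 0.5, 1.0)  # Itô, Stratonovich, Hänggi–Klimontovich


def _min_n_pi(d: int) -> int:
    """Smallest integer prior strength giving a proper conjugate prior.

    Properness requires the inverse-gamma shape m(d) = d(n_π−1)/2 − 1 to be
    positive: n_π = 4 in 1D, 3 in 2D.
    """
    return next(n for n in range(1, 100) if d * (n - 1) / 2.0 - 1.0 > 0)


def min_proper_n_pi(d: int, numeric: bool = False) -> int:
    """Scan integer n_π for the smallest value with a normalizable prior.

    With ``numeric=True`` the properness of each candidate is established by
    numerically integrating the drift-marginalized prior density
    z^{−d(n_π−1)/2} exp(−c/(2z)) over the squared noise amplitude z = b²Δt
    with growing upper cutoffs, declaring convergence when the tail stops
    contributing; otherwise the closed-form positivity condition on the
    gamma-function argument m(d) is used.  Both agree.
    """
    if d not in (1, 2):
        raise ValueError("d must be 1 or 2")
    if not numeric:
        return _min_n_pi(d)
    for n_pi in range(1, 100):
        if _prior_normalization_is_finite(d, n_pi):
            return n_pi
    raise RuntimeError("scan exhausted")  # pragma: no cover


def _prior_normalization_is_finite(d: int, n_pi: int, c: float = 1.0) -> bool:
    """Numeric finiteness test of ∫ z^{−d(n_π−1)/2} e^{−c/(2z)} dz over z > 0.

    The integral over growing cutoffs converges iff the tail increments per
    decade shrink geometrically; at the divergence boundary (integrand
    ~ 1/z) they are constant, and for weaker decay they grow.
    """
    expo = -d * (n_pi - 1) / 2.0
    cutoffs = (1e2, 1e4, 1e6, 1e8)
    totals = []
    for upper in cutoffs:
        z = np.geomspace(1e-6, upper, 20001)
        totals.append(np.trapezoid(z**expo * np.exp(-c / (2 * z)), z))
    increments = np.diff(totals)
    ratios = increments[1:] / increments[:-1]
    return bool(np.all(ratios < 0.5))


@dataclass(frozen=True)
class PriorHyperparameters:
    """Hyperparameters of the conjugate prior on local drift and diffusivity.

    Parameters
    ----------
    n_pi : int or "auto"
        Effective number of prior observations.  ``"auto"`` resolves to the
        smallest proper value (4 in 1D, 3 in 2D), the least constraining
        choice.  The prior mean of the drift is internally centred on the
        spurious drift (zero non-diffusive force), so n_pi also sets how
        strongly H0 is favoured a priori.
    u : float
        Ratio V_π/V of the prior jump variance to the observed one.
    localization_sigma : float
        Static localization error σ_L in µm; inflates the apparent jump
        variance by 2dσ_L² which is subtracted before inference.
    """

    n_pi: int | str = "auto"
    u: float = 1.0
    localization_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.u <= 0:
            raise ValueError("u must be positive")
        if self.localization_sigma < 0:
            raise ValueError("localization_sigma must be non-negative")

    def resolve_n_pi(self, d: int) -> int:
        if self.n_pi == "auto":
            return _min_n_pi(d)
        n_pi = int(self.n_pi)
        if n_pi < _min_n_pi(d):
            raise ValueError(
                f"n_pi={n_pi} gives an improper prior in d={d}; "
                f"minimum is {_min_n_pi(d)}"
            )
        return n_pi


@dataclass(frozen=True)
class NaturalParameters:
    """Dimensionless sufficient inputs of every closed-form result."""

    zeta_t: np.ndarray      # Δr̄/√V_eff, d-vector
    zeta_sp: np.ndarray     # ĝΔt/√V_eff, d-vector
    zeta_par: float         # component of ζ_t along ζ_sp (signed)
    zeta_perp: float        # component of ζ_t orthogonal to ζ_sp (≥ 0)
    eta: float              # √(n_π/(n+n_π))
    v: float                # 1 + n_π V_π/(n V_eff)
    kappa: float            # d(n+n_π−1)/2 − 1
    m: float                # d(n_π−1)/2 − 1
    n: int
    d: int
    V_eff: float = float("nan")   # localization-corrected variance [µm²]
    dt: float = float("nan")      # frame interval [s]
    noise_dominated: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.eta < 1.0):
            raise ValueError("eta must lie in (0, 1)")
        if self.v < 1.0:
            raise ValueError("v must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


def effective_variance(V: float, d: int, sigma_L: float,
                       eps: float = 1e-6) -> tuple[float, bool]:
    """Localization-corrected jump variance V_eff = max(V − 2dσ_L², εV).

    Returns ``(V_eff, noise_dominated)``; the flag is set when the static
    localization error accounts for the whole observed variance, in which
    case the clamped value is returned but any inference from it is suspect.
    """
    corrected = V - 2.0 * d * sigma_L**2
    if corrected <= 0.0:
        return eps * V, True
    return max(corrected, eps * V), False


def natural_parameters(stats, grad=None,
                       prior: PriorHyperparameters | None = None) -> NaturalParameters:
    """Map per-bin sufficient statistics to the dimensionless parameters.

    Parameters
    ----------
    stats : BinStatistics
        Sufficient statistics (n, Δr̄, V, Δt, d) of the displacements in one
        spatial bin.
    grad : GradientEstimate or array-like, optional
        Spurious-drift coefficient ĝ = b∇b [µm/s] at the bin; ``None`` means
        no gradient (ζ_sp = 0).
    prior : PriorHyperparameters, optional
    """
    prior = prior or PriorHyperparameters()
    d = stats.d
    n = stats.n
    n_pi = prior.resolve_n_pi(d)
    if n < n_pi:
        raise ValueError(f"bin has n={n} < n_pi={n_pi}: excluded from testing")
    V_eff, noise_dom = effective_variance(stats.V, d, prior.localization_sigma)
    if V_eff <= 0.0:
        raise ValueError("non-positive effective variance")
    sqrtV = math.sqrt(V_eff)
    zeta_t = np.asarray(stats.dr_mean, dtype=float) / sqrtV
    g_hat = getattr(grad, "g_hat", grad)
    if g_hat is None:
        zeta_sp = np.zeros(d)
    else:
        zeta_sp = np.asarray(g_hat, dtype=float) * stats.dt / sqrtV
    sp_norm = float(np.linalg.norm(zeta_sp))
    t_norm2 = float(zeta_t @ zeta_t)
    if sp_norm > 0.0:
        zeta_par = float(zeta_t @ zeta_sp) / sp_norm
        zeta_perp = math.sqrt(max(t_norm2 - zeta_par**2, 0.0))
    else:
        # no spurious direction: align the frame with ζ_t itself
        zeta_par = math.sqrt(t_norm2)
        zeta_perp = 0.0
    return NaturalParameters(
        zeta_t=zeta_t,
        zeta_sp=zeta_sp,
        zeta_par=zeta_par,
        zeta_perp=zeta_perp,
        eta=math.sqrt(n_pi / (n + n_pi)),
        v=1.0 + n_pi * prior.u / n,
        kappa=d * (n + n_pi - 1) / 2.0 - 1.0,
        m=d * (n_pi - 1) / 2.0 - 1.0,
        n=n,
        d=d,
        V_eff=V_eff,
        dt=stats.dt,
        noise_dominated=noise_dom,
    )


# ---------------------------------------------------------------------------
# λ-quadrature in log-space
# ---------------------------------------------------------------------------

def _log_trapezoid(log_f: np.ndarray, h: float) -> float:
    """log ∫ f dλ on a uniform grid from log-integrand values (stable)."""
    m = float(np.max(log_f))
    w = np.exp(log_f - m)
    w[0] *= 0.5
    w[-1] *= 0.5
    return m + math.log(h * float(np.sum(w)))


def _shifted_norm_sq(np_: NaturalParameters, lam: np.ndarray) -> np.ndarray:
    """|ζ_t − λζ_sp|² for an array of λ values, via the (par, perp) split."""
    sp = float(np.linalg.norm(np_.zeta_sp))
    return (np_.zeta_par - lam * sp) ** 2 + np_.zeta_perp**2


def _log_lambda_integral(np_: NaturalParameters, scale: float,
                         rtol: float = 1e-9, max_doublings: int = 22) -> float:
    """log ∫₀¹ [v + scale·|ζ_t − λζ_sp|²]^{−κ} dλ, adaptive trapezoid.

    ``scale`` is η² for the H1 integral and 1 for H0.  The node count is
    doubled until the integral changes by less than ``rtol`` relative; the
    integrand is a smooth rational function of λ so convergence is fast, but
    κ ~ n can make it sharply peaked, hence the adaptive refinement.
    """
    if float(np.linalg.norm(np_.zeta_sp)) == 0.0:
        # integrand constant in λ: single-node value is exact
        q = np_.zeta_par**2 + np_.zeta_perp**2
        return -np_.kappa * math.log(np_.v + scale * q)
    n_nodes = 9
    prev = None
    for _ in range(max_doublings):
        lam = np.linspace(0.0, 1.0, n_nodes)
        log_f = -np_.kappa * np.log(np_.v + scale * _shifted_norm_sq(np_, lam))
        val = _log_trapezoid(log_f, 1.0 / (n_nodes - 1))
        if prev is not None and abs(val - prev) <= rtol * max(abs(val), 1.0):
            return val
        prev = val
        n_nodes = 2 * (n_nodes - 1) + 1
    return prev  # pragma: no cover - smooth integrands always converge


def log_evidence(np_: NaturalParameters, hypothesis: str) -> float:
    """Log model evidence up to a constant common to H0 and H1.

    The common factor (prior and likelihood normalizations, the (nV)^{−κ}
    data scale) cancels in every Bayes factor and is never computed; what is
    returned is the η-weighted λ-integral for H1 and the plain λ-integral
    for H0, so that log10 K^M = (logev_H1 − logev_H0)/ln 10 exactly.
    """
    if hypothesis in ("H1", "h1"):
        return np_.d * math.log(np_.eta) + _log_lambda_integral(np_, np_.eta**2)
    if hypothesis in ("H0", "h0"):
        return _log_lambda_integral(np_, 1.0)
    raise ValueError(f"unknown hypothesis {hypothesis!r}")


def bayes_factor_fixed(np_: NaturalParameters, lam: float) -> float:
    """log10 K(λ) for a fixed stochastic convention, exact closed form."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    q = float(_shifted_norm_sq(np_, np.asarray([lam]))[0])
    log_ratio = math.log(np_.v + np_.eta**2 * q) - math.log(np_.v + q)
    return (np_.d * math.log(np_.eta) - np_.kappa * log_ratio) / math.log(10.0)


def bayes_factor_marginalized(np_: NaturalParameters) -> float:
    """log10 K^M with λ marginalized over [0, 1] under a flat prior."""
    return (log_evidence(np_, "H1") - log_evidence(np_, "H0")) / math.log(10.0)


def classify(log10_K: float, threshold: float = 1.0) -> str:
    """Three-way evidence call used to colour Bayes-factor maps.

    log10 K ≥ threshold → non-spurious force; ≤ −threshold → spurious force
    only; otherwise the evidence is insufficient.  Boundary values are
    conclusive (the inequalities are non-strict).
    """
    if not math.isfinite(log10_K):
        raise ValueError("log10_K must be finite")
    if log10_K >= threshold:
        return NONSPURIOUS
    if log10_K <= -threshold:
        return SPURIOUS_ONLY
    return INCONCLUSIVE


def lambda_map_H0(np_: NaturalParameters) -> float | None:
    """Most efficient convention under H0: argmax_λ [v + |ζ_t − λζ_sp|²]^{−κ}.

    Closed form: the quadratic |ζ_t − λζ_sp|² is minimized at ζ_par/|ζ_sp|,
    clamped to [0, 1].  Undefined (None) when ζ_sp = 0, since then every λ
    describes the data equally well.
    """
    sp = float(np.linalg.norm(np_.zeta_sp))
    if sp == 0.0:
        return None
    return float(min(max(np_.zeta_par / sp, 0.0), 1.0))


@dataclass(frozen=True)
class BayesFactorResult:
    """Bayes factors and classification for one spatial bin."""

    log10_KM: float
    log10_K_at: dict = field(default_factory=dict)  # λ -> log10 K(λ)
    classification: str = INCONCLUSIVE
    lambda_map_H0: float | None = None


def compute_bayes_factors(np_: NaturalParameters,
                          threshold: float = 1.0) -> BayesFactorResult:
    """Marginalized + standard-convention Bayes factors for one bin."""
    log10_km = bayes_factor_marginalized(np_)
    at = {lam: bayes_factor_fixed(np_, lam) for lam in _CONVENTIONS}
    lam_star = lambda_map_H0(np_)
    # K^M is a weighted average of K(λ) over λ ∈ [0,1]; its envelope is
    # [K(λ*), max(K(0), K(1))] since K is monotone in |ζ_t − λζ_sp|².
    lo = min(at.values()) if lam_star is None else bayes_factor_fixed(np_, lam_star)
    hi = max(at.values())
    if not (lo - 1e-6 <= log10_km <= hi + 1e-6):
        raise RuntimeError("quadrature defect: log10 K^M outside its envelope")
    return BayesFactorResult(
        log10_KM=log10_km,
        log10_K_at=at,
        classification=classify(log10_km, threshold),
        lambda_map_H0=lam_star,
    )
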