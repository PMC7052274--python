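"""Synthetic trajectory generators for validating the force test.

Two settings are produced, mirroring the validation protocol of the method:

* ``simulate_ole`` — overdamped Langevin walkers in a periodic 2D box with a
  triangular diffusivity profile along x and either a uniform total drift α
  or a true non-diffusive drift a plus a convention λ_true.  The SDE is
  integrated in the Itô form with Euler–Maruyama substeps, so the spurious
  drift λ_true·b∇b = λ_true·∇D is injected explicitly — the simulator
  exhibits the Itô–Stratonovich dilemma by construction.
* ``simulate_crowding`` — free microscopic diffusion (no drift at all) among
  impenetrable immobile beads on a square lattice whose radii grow with x.
  Crowding lowers the *effective* mesoscopic diffusivity where beads are
  large, so recordings show a diffusivity gradient and a drift that is
  purely spurious: the ground truth for the H0 side of the test.

Default parameters follow the regimes of the validation figures: OLE box
1×1 µm² with D ∈ [0.05, 0.3] µm²/s and Δt = 0.04 s; crowding box 10×10 µm²,
lattice pitch 0.1 µm, bead radii 0 → 0.04 µm linear in x, D = 0.3 µm²/s,
1000 particles × 1000 recorded jumps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes_core import (NaturalParameters, PriorHyperparameters,
                         bayes_factor_marginalized)
from .trajectory_io import TrajectorySet

__all__ = [
    "TriangularProfile",
    "OLESimConfig",
    "CrowdingSimConfig",
    "triangular_D",
    "simulate_ole",
    "simulate_crowding",
    "expected_bayes_factor",
    "expected_natural_parameters",
]


@dataclass(frozen=True)
class TriangularProfile:
    """Continuous periodic triangular diffusivity profile along x [µm²/s]."""

    D_min: float = 0.05
    D_max: float = 0.3
    apex: float = 0.5     # position of the maximum [µm]
    period: float = 1.0   # box length along x [µm]

    def __post_init__(self) -> None:
        if not 0.0 < self.D_min <= self.D_max:
            raise ValueError("need 0 < D_min <= D_max")
        if not 0.0 < self.apex < self.period:
            raise ValueError("apex must lie inside the box")

    def D(self, x: np.ndarray) -> np.ndarray:
        """Diffusivity at (wrapped) position x: D_min at 0 and period, D_max at apex."""
        x = np.mod(np.asarray(x, dtype=float), self.period)
        rising = x <= self.apex
        up = self.D_min + (self.D_max - self.D_min) * x / self.apex
        down = self.D_max - (self.D_max - self.D_min) * (x - self.apex) / (
            self.period - self.apex)
        return np.where(rising, up, down)

    def dD_dx(self, x: np.ndarray) -> np.ndarray:
        """Slope of the profile; equals the λ=1 spurious drift b∇b [µm/s]."""
        x = np.mod(np.asarray(x, dtype=float), self.period)
        up = (self.D_max - self.D_min) / self.apex
        down = -(self.D_max - self.D_min) / (self.period - self.apex)
        return np.where(x <= self.apex, up, down)

    def mean_D(self, x_lo: float, x_hi: float) -> float:
        """Average diffusivity over the (un-wrapped) interval [x_lo, x_hi]."""
        x = np.linspace(x_lo, x_hi, 257)
        return float(np.trapezoid(self.D(x), x) / (x_hi - x_lo))

    def mean_dD_dx(self, x_lo: float, x_hi: float) -> float:
        """Average slope over [x_lo, x_hi] (exact for kink-free intervals)."""
        x = np.linspace(x_lo, x_hi, 257)
        return float(np.trapezoid(self.dD_dx(x), x) / (x_hi - x_lo))


def triangular_D(x: np.ndarray, cfg: "OLESimConfig | TriangularProfile") -> np.ndarray:
    """Triangular diffusivity profile evaluated at x (convenience wrapper)."""
    profile = cfg if isinstance(cfg, TriangularProfile) else cfg.profile
    return profile.D(x)


@dataclass(frozen=True)
class OLESimConfig:
    """Configuration of the heterogeneous-diffusivity Langevin simulation.

    Exactly one of ``total_drift`` (uniform total drift α [µm/s], the
    validation-figure setting) or the pair (``a``, ``lambda_true``) is the
    drift specification; with the latter the total drift is
    α(x) = a + λ_true·∇D(x).
    """

    box: tuple = (1.0, 1.0)
    profile: TriangularProfile = field(default_factory=TriangularProfile)
    total_drift: tuple | None = None
    a: tuple | None = None
    lambda_true: float = 0.0
    dt: float = 0.04
    n_particles: int = 50
    n_steps: int = 200
    substeps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.substeps < 1:
            raise ValueError("dt must be positive and substeps >= 1")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must lie in [0, 1]")
        if self.total_drift is not None and self.a is not None:
            raise ValueError("give either total_drift or a, not both")

    @property
    def d(self) -> int:
        return len(self.box)


def _to_trajectory_set(positions: np.ndarray, dt: float,
                       box: tuple | None = None) -> TrajectorySet:
    """Stack recorded positions (frames, particles, d) into a TrajectorySet."""
    n_frames, n_particles, d = positions.shape
    ids = np.repeat(np.arange(n_particles), n_frames)
    frames = np.tile(np.arange(n_frames), n_particles)
    coords = positions.transpose(1, 0, 2).reshape(-1, d)
    cols = {"traj_id": ids, "frame": frames, "x": coords[:, 0]}
    if d == 2:
        cols["y"] = coords[:, 1]
    return TrajectorySet(data=pd.DataFrame(cols), dt=dt, box=box)


def simulate_ole(cfg: OLESimConfig) -> TrajectorySet:
    """Euler–Maruyama integration of the heterogeneous OLE (Itô form).

    Per substep: X ← X + α(X)·dt_sub + b(X)·√dt_sub·ξ with b = √(2D) and
    α = a + λ_true·∇D (or the configured uniform α); positions wrapped
    periodically; every ``substeps``-th position recorded.  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    d = cfg.d
    box = np.asarray(cfg.box, dtype=float)
    dt_sub = cfg.dt / cfg.substeps
    b_max = math.sqrt(2.0 * cfg.profile.D_max)
    scale = min(cfg.profile.apex, cfg.profile.period - cfg.profile.apex)
    if b_max * math.sqrt(dt_sub) > 0.1 * scale:
        warnings.warn("substep noise exceeds 10% of the profile scale; "
                      "increase substeps", stacklevel=2)
    x = rng.uniform(0.0, 1.0, size=(cfg.n_particles, d)) * box
    recorded = np.empty((cfg.n_steps + 1, cfg.n_particles, d))
    recorded[0] = x
    uniform_alpha = (None if cfg.total_drift is None
                     else np.asarray(cfg.total_drift, dtype=float))
    a_vec = (np.zeros(d) if cfg.a is None else np.asarray(cfg.a, dtype=float))
    for step in range(cfg.n_steps):
        for _ in range(cfg.substeps):
            D = cfg.profile.D(x[:, 0])
            if uniform_alpha is not None:
                alpha = np.broadcast_to(uniform_alpha, x.shape).copy()
            else:
                alpha = np.tile(a_vec, (len(x), 1))
                alpha[:, 0] += cfg.lambda_true * cfg.profile.dD_dx(x[:, 0])
            noise = rng.standard_normal(x.shape)
            x = x + alpha * dt_sub + np.sqrt(2.0 * D * dt_sub)[:, None] * noise
            x = np.mod(x, box)
        recorded[step + 1] = x
    return _to_trajectory_set(recorded, cfg.dt, box=tuple(cfg.box))


@dataclass(frozen=True)
class CrowdingSimConfig:
    """Configuration of the immobile-bead crowding simulation."""

    box: tuple = (10.0, 10.0)
    pitch: float = 0.1                 # lattice spacing [µm]
    r_min: float = 0.0                 # bead radius at x = 0 [µm]
    r_max: float = 0.04                # bead radius at x = box_x [µm]
    D: float = 0.3                     # microscopic diffusivity [µm²/s]
    dt: float = 0.04
    substeps: int = 5
    n_particles: int = 1000
    n_steps: int = 1000
    drift: tuple | None = None         # optional uniform non-diffusive drift [µm/s]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pitch <= 0 or self.D <= 0 or self.dt <= 0:
            raise ValueError("pitch, D and dt must be positive")
        if not 0.0 <= self.r_min <= self.r_max:
            raise ValueError("radii must satisfy 0 <= r_min <= r_max")
        if self.r_max >= self.pitch / 2.0:
            raise ValueError("beads overlap: max radius must be < pitch/2")
        for L in self.box:
            if abs(L / self.pitch - round(L / self.pitch)) > 1e-9:
                raise ValueError("box must be a multiple of the lattice pitch "
                                 "for periodic consistency")

    def radius_at(self, x: np.ndarray) -> np.ndarray:
        """Bead radius at lattice-node x-coordinate (linear, monotone in x)."""
        frac = np.clip(np.asarray(x, dtype=float) / self.box[0], 0.0, 1.0)
        return self.r_min + (self.r_max - self.r_min) * frac


_NEIGHBOR_OFFSETS = np.array([(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)])
_SEGMENT_OFFSETS = np.array([(i, j) for i in range(-2, 3) for j in range(-2, 3)])


def _segment_hits_bead(p0: np.ndarray, p1: np.ndarray,
                       cfg: CrowdingSimConfig) -> np.ndarray:
    """True where the segment p0→p1 (unwrapped) enters any lattice bead.

    Candidate beads are the 5×5 lattice nodes around the segment midpoint,
    which covers every bead a segment of up to ~4 substep standard deviations
    can touch at the default pitch; the test is point-to-segment distance <
    bead radius, with the radius evaluated at the node's periodically wrapped
    x-coordinate.
    """
    mid = 0.5 * (p0 + p1)
    base = np.round(mid / cfg.pitch)
    nodes = (base[:, None, :] + _SEGMENT_OFFSETS[None, :, :]) * cfg.pitch
    node_x = np.mod(nodes[..., 0], cfg.box[0])
    radii = cfg.radius_at(node_x)
    seg = (p1 - p0)[:, None, :]
    rel = nodes - p0[:, None, :]
    seg_len2 = np.sum(seg**2, axis=-1)
    t = np.clip(np.sum(rel * seg, axis=-1) / np.maximum(seg_len2, 1e-300),
                0.0, 1.0)
    closest = p0[:, None, :] + t[..., None] * seg
    dist2 = np.sum((nodes - closest) ** 2, axis=-1)
    return np.any(dist2 < radii**2, axis=1)


def _point_in_bead(p: np.ndarray, cfg: CrowdingSimConfig) -> np.ndarray:
    base = np.round(p / cfg.pitch)
    nodes = (base[:, None, :] + _NEIGHBOR_OFFSETS[None, :, :]) * cfg.pitch
    node_x = np.mod(nodes[..., 0], cfg.box[0])
    radii = cfg.radius_at(node_x)
    dist2 = np.sum((nodes - p[:, None, :]) ** 2, axis=-1)
    return np.any(dist2 < radii**2, axis=1)


def simulate_crowding(cfg: CrowdingSimConfig) -> TrajectorySet:
    """Free diffusion among immobile beads, by rejection-sampled substeps.

    Each substep proposes a Gaussian step of per-component variance
    2D·dt_sub; proposals whose segment enters a bead are resampled (up to
    100 tries, then the particle stays put for the substep).  Rejection
    (rather than reflection) preserves the uniform equilibrium measure in
    the accessible region.  No recorded position ever lies inside a bead.
    """
    rng = np.random.default_rng(cfg.seed)
    box = np.asarray(cfg.box, dtype=float)
    dt_sub = cfg.dt / cfg.substeps
    sigma = math.sqrt(2.0 * cfg.D * dt_sub)
    drift = (np.zeros(2) if cfg.drift is None
             else np.asarray(cfg.drift, dtype=float)) * dt_sub

    # initial positions: uniform over the accessible region
    x = np.empty((0, 2))
    while len(x) < cfg.n_particles:
        cand = rng.uniform(0.0, 1.0, size=(2 * cfg.n_particles, 2)) * box
        cand = cand[~_point_in_bead(cand, cfg)]
        x = np.vstack([x, cand])[: cfg.n_particles]

    recorded = np.empty((cfg.n_steps + 1, cfg.n_particles, 2))
    recorded[0] = x
    for step in range(cfg.n_steps):
        for _ in range(cfg.substeps):
            active = np.arange(cfg.n_particles)
            proposal = x.copy()
            for _try in range(100):
                if len(active) == 0:
                    break
                cand = (x[active] + drift
                        + sigma * rng.standard_normal((len(active), 2)))
                bad = _segment_hits_bead(x[active], cand, cfg)
                proposal[active[~bad]] = cand[~bad]
                active = active[bad]
            # particles still active after 100 tries stay in place
            x = np.mod(proposal, box)
        recorded[step + 1] = x
    return _to_trajectory_set(recorded, cfg.dt, box=tuple(cfg.box))


def expected_natural_parameters(
        cfg: OLESimConfig, x_lo: float, x_hi: float, n: int,
        prior: PriorHyperparameters | None = None) -> NaturalParameters:
    """Population-level natural parameters for a bin spanning [x_lo, x_hi].

    Uses the true fields: bin-average jump variance V = 2dD̄Δt, total drift
    from the configuration, and spurious drift ĝ = ∇D averaged over the bin.
    """
    prior = prior or PriorHyperparameters()
    d = cfg.d
    n_pi = prior.resolve_n_pi(d)
    D_bar = cfg.profile.mean_D(x_lo, x_hi)
    V = 2.0 * d * D_bar * cfg.dt
    g = np.zeros(d)
    g[0] = cfg.profile.mean_dD_dx(x_lo, x_hi)
    if cfg.total_drift is not None:
        alpha = np.asarray(cfg.total_drift, dtype=float)
    else:
        alpha = (np.zeros(d) if cfg.a is None
                 else np.asarray(cfg.a, dtype=float)).copy()
        alpha[0] += cfg.lambda_true * g[0]
    sqrtV = math.sqrt(V)
    zeta_t = alpha * cfg.dt / sqrtV
    zeta_sp = g * cfg.dt / sqrtV
    sp = float(np.linalg.norm(zeta_sp))
    t2 = float(zeta_t @ zeta_t)
    if sp > 0:
        par = float(zeta_t @ zeta_sp) / sp
        perp = math.sqrt(max(t2 - par**2, 0.0))
    else:
        par, perp = 0.0, math.sqrt(t2)
    return NaturalParameters(
        zeta_t=zeta_t, zeta_sp=zeta_sp, zeta_par=par, zeta_perp=perp,
        eta=math.sqrt(n_pi / (n + n_pi)), v=1.0 + n_pi * prior.u / n,
        kappa=d * (n + n_pi - 1) / 2.0 - 1.0,
        m=d * (n_pi - 1) / 2.0 - 1.0, n=n, d=d, V_eff=V, dt=cfg.dt)


def expected_bayes_factor(cfg: OLESimConfig, x_lo: float, x_hi: float,
                          n: int,
                          prior: PriorHyperparameters | None = None) -> float:
    """Expected log10 K^M for a bin, from the true simulation fields."""
    np_ = expected_natural_parameters(cfg, x_lo, x_hi, n, prior)
    return bayes_factor_marginalized(np_)
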