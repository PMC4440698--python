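"""FPR stepping engine for a single reactant pair.

Particles move with the free-diffusion propagator (independent Gaussian
displacements plus joint rejection of overlapping moves).  Inside a reaction
zone of radius ``R_max = sigma + 3 sqrt(6 D dt)`` the association probability
of the exact irreversible Green's function is evaluated each step and
multiplied by the accumulated trajectory-reweighting ratio

    w_ratio = prod over zone steps of  p_irr(r_t, dt | r_{t-dt})
                                       / p_free*(r_t, dt | r_{t-dt}),

which corrects for sampling positions from the free instead of the exact
propagator.  The ratio is initialized to one on zone entry, reset to one on
exit (its ensemble mean at exit is one by construction), and the survival
stored for the next step's ``p_free*`` denominator is one minus the
*reweighted* association probability.

Two layers are provided: an explicit single-pair stepper (:func:`step_pair`,
cases A / B1 / B2 / C) that operates on full 3D positions, and vectorized
ensemble kernels (:func:`association_curve`, :func:`exit_ratios`) that
propagate the relative coordinate of many independent pairs at once.  The
relative coordinate of a pair undergoing joint-rejected free moves is itself
a free diffusion with ``D = D_a + D_b`` restricted to ``r >= sigma``, so the
two layers sample identical separation statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .greens import (
    PairParams,
    p_assoc,
    p_free,
    free_norm_constant,
    p_irr,
)

__all__ = [
    "ReactionZone",
    "PairState",
    "reaction_zone_radius",
    "sample_free_move",
    "reweight_increment",
    "attempt_dissociation",
    "place_complex",
    "place_dissociated",
    "step_pair",
    "association_curve",
    "exit_ratios",
    "AssociationCurve",
    "ExitRatioSample",
]

#: Floor applied to stored survival probabilities before they are used as the
#: denominator of p_free*; guards near-certain-association paths.
SURVIVAL_FLOOR = 1e-12

#: Cap on overlap-rejection redraw attempts before declaring the
#: configuration pathological.
MAX_OVERLAP_ATTEMPTS = 10**6


def reaction_zone_radius(sigma: float, D_tot: float, dt: float) -> float:
    """Reaction-zone radius ``sigma + 3 sqrt(6 D dt)``.

    Three times the rms relative displacement beyond contact: a good estimate
    of where the single-step association probability drops to zero.
    """
    if sigma < 0 or D_tot < 0 or dt < 0:
        raise ValueError("sigma, D_tot and dt must be non-negative")
    return sigma + 3.0 * math.sqrt(6.0 * D_tot * dt)


@dataclass(frozen=True)
class ReactionZone:
    """Reaction zone [sigma, R_max] with optional reduced reweighting radius.

    ``R_rewgt < R_max`` shortens the reweighted stretch of trajectories (the
    undersampling fix): between ``R_rewgt`` and ``R_max`` association is still
    attempted but with the ratio held at one.
    """

    R_max: float
    R_rewgt: float | None = None

    def __post_init__(self) -> None:
        rw = self.R_max if self.R_rewgt is None else self.R_rewgt
        if rw > self.R_max + 1e-12:
            raise ValueError("R_rewgt must not exceed R_max")
        object.__setattr__(self, "R_rewgt", rw)

    @classmethod
    def for_pair(cls, params: PairParams, dt: float, R_rewgt: float | None = None):
        return cls(reaction_zone_radius(params.sigma, params.D_tot, dt), R_rewgt)


@dataclass
class PairState:
    """Mutable state of one tracked pair.

    When ``bound`` is true, ``pos_a`` holds the complex position and the
    remaining bookkeeping fields are inert.
    """

    pos_a: np.ndarray
    pos_b: np.ndarray
    bound: bool = False
    r_prev: float = math.nan
    w_ratio: float = 1.0
    survival_prev: float = 1.0
    in_zone: bool = False

    @property
    def separation(self) -> float:
        return float(np.linalg.norm(np.asarray(self.pos_a) - np.asarray(self.pos_b)))


def sample_free_move(pos_a, pos_b, D_a, D_b, sigma, dt, rng,
                     max_attempts: int = MAX_OVERLAP_ATTEMPTS):
    """One free-propagator move of both particles with joint overlap rejection.

    Each coordinate is displaced by a Gaussian of variance ``2 D dt``.  If the
    trial separation falls below ``sigma`` BOTH moves are redrawn from the
    pre-move positions (the overlap depends on the combined ``D_a + D_b``, so
    rejecting a single particle's move would distort the pair statistics).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    pos_a = np.asarray(pos_a, dtype=float)
    pos_b = np.asarray(pos_b, dtype=float)
    sd_a = math.sqrt(2.0 * D_a * dt)
    sd_b = math.sqrt(2.0 * D_b * dt)
    for _ in range(max_attempts):
        new_a = pos_a + sd_a * rng.standard_normal(3)
        new_b = pos_b + sd_b * rng.standard_normal(3)
        if np.linalg.norm(new_a - new_b) >= sigma:
            return new_a, new_b
    raise RuntimeError(
        f"overlap rejection failed after {max_attempts} attempts for the pair at "
        f"{pos_a!r} / {pos_b!r}"
    )


def _p_free_star_vals(r, dt, r_prev, params: PairParams, survival_prev):
    """p_free* with the survival floor; array-friendly."""
    sv = np.maximum(survival_prev, SURVIVAL_FLOOR)
    denom = free_norm_constant(dt, r_prev, params.sigma, params.D_tot)
    return p_free(r, dt, r_prev, params.D_tot) / denom * sv


def reweight_increment(r_t, r_prev, params: PairParams, dt, survival_prev):
    """Single-step reweighting ratio ``p_irr / p_free*`` for r_prev -> r_t."""
    star = _p_free_star_vals(r_t, dt, r_prev, params, survival_prev)
    if np.any(np.asarray(star) <= 0.0):
        raise FloatingPointError(
            "p_free* vanished in the reweighting denominator; the free and "
            "exact propagators are inconsistent at these arguments"
        )
    return p_irr(r_t, dt, r_prev, params) / star


def attempt_dissociation(k_b: float, dt: float, rng) -> bool:
    """Poisson dissociation test: true with probability ``1 - exp(-k_b dt)``.

    ``k_b`` in 1/us (converted from s^-1 at config parse time).
    """
    if k_b < 0:
        raise ValueError("k_b must be non-negative")
    return bool(rng.random() < -math.expm1(-k_b * dt))


def place_complex(pos_a, pos_b, D_a, D_b):
    """Position of a newly formed complex, split by diffusion-constant fraction.

    ``pos_a + (D_a / (D_a + D_b)) (pos_b - pos_a)``; the more mobile particle
    moves farther.  Falls back to the midpoint (with a warning) if both
    particles are immobile.
    """
    pos_a = np.asarray(pos_a, dtype=float)
    pos_b = np.asarray(pos_b, dtype=float)
    D_tot = D_a + D_b
    if D_tot <= 0.0:
        import warnings

        warnings.warn("place_complex with D_a = D_b = 0; using the midpoint")
        return 0.5 * (pos_a + pos_b)
    return pos_a + (D_a / D_tot) * (pos_b - pos_a)


def place_dissociated(pos_c, sigma, D_a, D_b, rng):
    """Positions of a freshly dissociated pair at exact contact separation.

    A direction is drawn uniformly on the sphere; the two particles are
    displaced from the complex along it by their diffusion-constant fractions
    so that ``|pos_a - pos_b| = sigma`` and :func:`place_complex` is the exact
    inverse (detailed balance between association and dissociation placement).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pos_c = np.asarray(pos_c, dtype=float)
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    D_tot = D_a + D_b
    if D_tot <= 0.0:
        fa, fb = 0.5, 0.5
    else:
        fa, fb = D_a / D_tot, D_b / D_tot
    return pos_c - fa * sigma * u, pos_c + fb * sigma * u


def step_pair(state: PairState, params: PairParams, zone: ReactionZone, dt: float,
              rng) -> PairState:
    """Advance one pair by one time step (cases A / B1 / B2 / C).

    A: outside the zone -- free move only.  B1: first step inside the zone --
    ratio initialized to one, unreweighted association attempt.  B2:
    consecutive zone step -- ratio multiplied by the single-step increment,
    association probability scaled by it.  C: bound -- Poisson dissociation
    test, else the complex diffuses.  Association places the complex by
    diffusion-constant fraction; dissociation places the pair at contact and
    defers any re-association attempt to the next step.
    """
    if state.bound:  # Case C
        if attempt_dissociation(params.k_b, dt, rng):
            pos_a, pos_b = place_dissociated(state.pos_a, params.sigma,
                                             params.D_a, params.D_b, rng)
            return PairState(pos_a, pos_b, bound=False, in_zone=False)
        D_c = min(params.D_a, params.D_b)
        new_c = np.asarray(state.pos_a, float) + math.sqrt(2.0 * D_c * dt) * rng.standard_normal(3)
        return replace(state, pos_a=new_c, pos_b=new_c.copy())

    r = state.separation
    if r >= zone.R_max:  # Case A
        pos_a, pos_b = sample_free_move(state.pos_a, state.pos_b, params.D_a,
                                        params.D_b, params.sigma, dt, rng)
        return PairState(pos_a, pos_b, bound=False, in_zone=False)

    # Cases B1/B2: association attempt at the current separation.
    in_rewgt = r < zone.R_rewgt
    if state.in_zone and in_rewgt and not math.isnan(state.r_prev):
        w = state.w_ratio * float(
            reweight_increment(r, state.r_prev, params, dt, state.survival_prev)
        )
    else:
        w = 1.0
    p = float(p_assoc(dt, max(r, params.sigma), params))
    p_eff = w * p
    if p_eff > 1.0:
        import warnings

        warnings.warn(f"reweighted association probability {p_eff:.3g} > 1; clamped")
        p_eff = 1.0
    if p_eff > rng.random():
        pos_c = place_complex(state.pos_a, state.pos_b, params.D_a, params.D_b)
        return PairState(pos_c, pos_c.copy(), bound=True)
    pos_a, pos_b = sample_free_move(state.pos_a, state.pos_b, params.D_a,
                                    params.D_b, params.sigma, dt, rng)
    return PairState(pos_a, pos_b, bound=False, r_prev=r, w_ratio=w,
                     survival_prev=max(1.0 - p_eff, SURVIVAL_FLOOR),
                     in_zone=in_rewgt)


# ---------------------------------------------------------------------------
# Vectorized ensemble kernels (relative-coordinate propagation)
# ---------------------------------------------------------------------------


def _random_directions(n, rng):
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _free_relative_move(x, sigma, D_tot, dt, rng, max_rounds=10_000):
    """Vectorized joint-rejection free move of relative coordinates ``x``."""
    sd = math.sqrt(2.0 * D_tot * dt)
    new = x + sd * rng.standard_normal(x.shape)
    bad = np.einsum("ij,ij->i", new, new) < sigma * sigma
    rounds = 0
    while bad.any():
        rounds += 1
        if rounds > max_rounds:
            raise RuntimeError("overlap rejection failed to terminate")
        new[bad] = x[bad] + sd * rng.standard_normal((int(bad.sum()), 3))
        bad_idx = np.flatnonzero(bad)
        still = np.einsum("ij,ij->i", new[bad_idx], new[bad_idx]) < sigma * sigma
        bad[bad_idx] = still
    return new


@dataclass
class AssociationCurve:
    """Cumulative association fraction of an ensemble of pairs vs time."""

    times: np.ndarray
    cumulative: np.ndarray
    n_traj: int
    params: PairParams
    r0: float

    @property
    def stderr(self) -> np.ndarray:
        p = self.cumulative
        return np.sqrt(np.clip(p * (1.0 - p), 0.0, None) / self.n_traj)


def association_curve(params: PairParams, dt: float, r0: float, n_steps: int,
                      n_traj: int, rng, *, R_rewgt: float | None = None,
                      reweight: bool = True) -> AssociationCurve:
    """Cumulative association probability of ``n_traj`` independent pairs.

    All pairs start at separation ``r0``; the curve value at time
    ``(k+1) dt`` is the fraction that associated during steps ``0..k`` and is
    directly comparable to the closed-form ``p_assoc(t|r0)``.
    """
    zone = ReactionZone.for_pair(params, dt, R_rewgt)
    x = r0 * _random_directions(n_traj, rng)
    w = np.ones(n_traj)
    s_prev = np.ones(n_traj)
    r_prev = np.full(n_traj, r0)
    in_rw = np.zeros(n_traj, dtype=bool)
    assoc = np.zeros(n_steps, dtype=np.int64)

    for k in range(n_steps):
        m = x.shape[0]
        if m == 0:
            break
        r = np.linalg.norm(x, axis=1)
        np.maximum(r, params.sigma, out=r)
        inz = r < zone.R_max
        in_rw_now = r < zone.R_rewgt
        entering = in_rw_now & ~in_rw
        staying = in_rw_now & in_rw
        w[entering] = 1.0
        w[~in_rw_now] = 1.0
        if reweight and staying.any():
            idx = np.flatnonzero(staying)
            w[idx] *= reweight_increment(r[idx], r_prev[idx], params, dt, s_prev[idx])
        p_eff = np.zeros(m)
        if inz.any():
            idx = np.flatnonzero(inz)
            p_eff[idx] = np.clip(w[idx] * p_assoc(dt, r[idx], params), 0.0, 1.0)
        react = p_eff > rng.random(m)
        assoc[k] = int(react.sum())
        keep = ~react
        x = x[keep]
        w = w[keep]
        r = r[keep]
        s_prev = np.maximum(1.0 - p_eff[keep], SURVIVAL_FLOOR)
        r_prev = r
        in_rw = in_rw_now[keep]
        x = _free_relative_move(x, params.sigma, params.D_tot, dt, rng)

    times = dt * np.arange(1, n_steps + 1)
    cum = np.cumsum(assoc) / n_traj
    return AssociationCurve(times, cum, n_traj, params, r0)


@dataclass
class ExitRatioSample:
    """Accumulated reweighting ratios recorded at first reaction-zone exit."""

    weights: np.ndarray
    r0: np.ndarray
    n_started: int
    n_associated: int
    n_truncated: int

    @property
    def mean(self) -> float:
        return float(self.weights.mean())

    @property
    def stderr(self) -> float:
        return float(self.weights.std(ddof=1) / math.sqrt(self.weights.size))


def exit_ratios(params: PairParams, dt: float, r0, n_traj: int, rng, *,
                max_steps: int = 200_000) -> ExitRatioSample:
    """Accumulated reweighting ratio of pairs at their first zone exit.

    Trajectories start inside the zone at separations ``r0`` (scalar or
    array, cycled to ``n_traj`` starts) and are propagated until they either
    associate or first cross ``R_max``; the ratio recorded at exit includes
    the increment of the boundary-crossing step.  In well-sampled regimes the
    mean is one; a mean below one diagnoses trajectory undersampling.
    """
    zone = ReactionZone.for_pair(params, dt)
    r0 = np.atleast_1d(np.asarray(r0, dtype=float))
    if np.any(r0 < params.sigma) or np.any(r0 >= zone.R_max):
        raise ValueError("exit-ratio starts must lie inside [sigma, R_max)")
    starts = np.resize(r0, n_traj)
    x = starts[:, None] * _random_directions(n_traj, rng)
    w = np.ones(n_traj)
    s_prev = np.ones(n_traj)
    r_prev = starts.copy()
    start_of = starts.copy()
    in_zone = np.zeros(n_traj, dtype=bool)

    exit_w: list[np.ndarray] = []
    exit_r0: list[np.ndarray] = []
    n_assoc = 0
    for _ in range(max_steps):
        m = x.shape[0]
        if m == 0:
            break
        r = np.linalg.norm(x, axis=1)
        np.maximum(r, params.sigma, out=r)
        out_now = r >= zone.R_max
        exiting = out_now & in_zone
        if exiting.any():
            idx = np.flatnonzero(exiting)
            inc = reweight_increment(r[idx], r_prev[idx], params, dt, s_prev[idx])
            exit_w.append(w[idx] * np.asarray(inc))
            exit_r0.append(start_of[idx])
        inz = ~out_now
        staying = inz & in_zone
        p_eff = np.zeros(m)
        if staying.any():
            idx = np.flatnonzero(staying)
            w[idx] *= reweight_increment(r[idx], r_prev[idx], params, dt, s_prev[idx])
        if inz.any():
            idx = np.flatnonzero(inz)
            p_eff[idx] = np.clip(w[idx] * p_assoc(dt, r[idx], params), 0.0, 1.0)
        react = p_eff > rng.random(m)
        n_assoc += int(react.sum())
        keep = inz & ~react
        x = x[keep]
        w = w[keep]
        s_prev = np.maximum(1.0 - p_eff[keep], SURVIVAL_FLOOR)
        r_prev = r[keep]
        start_of = start_of[keep]
        in_zone = np.ones(x.shape[0], dtype=bool)
        x = _free_relative_move(x, params.sigma, params.D_tot, dt, rng)

    n_trunc = x.shape[0]
    weights = np.concatenate(exit_w) if exit_w else np.empty(0)
    origins = np.concatenate(exit_r0) if exit_r0 else np.empty(0)
    return ExitRatioSample(weights, origins, n_traj, n_assoc, n_trunc)
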