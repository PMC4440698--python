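"""Pair interaction potentials and numerically tabulated Green's functions.

A radially symmetric potential (here Coulomb, ``beta V(r) = r_c / r`` with
``r_c > 0`` repulsive and ``r_c < 0`` attractive; the inverse temperature is
absorbed into ``r_c``) adds a drift ``D beta F`` to the free-propagator
moves.  The pair Green's function under the potential has no closed form, so
survival probabilities and propagator densities are tabulated by fine-step
Brownian dynamics with a thin reactive shell at contact (the method of Zhou)
and smoothed by fitting to the analytic functional forms with free
parameters.

For many-body systems with a long-range potential two strategies are
provided: summing all pairwise forces into each particle's drift
(:func:`longrange_force_sum`), or ignoring forces outside the reaction zone
and correcting the entry density with an initial reweighting ratio
``exp(-beta V(R_max))`` (:func:`longrange_entry_weight`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .greens import PairParams, p_free, p_irr, free_norm_constant, p_assoc as p_assoc_analytic
from .pair_fpr import SURVIVAL_FLOOR, reaction_zone_radius, AssociationCurve

__all__ = [
    "PotentialSpec",
    "coulomb",
    "drift_move",
    "p_free_drift",
    "drift_norm_constant",
    "kon_coulomb",
    "longrange_force_sum",
    "longrange_entry_weight",
    "GFTable",
    "tabulate_numerical_gf",
    "fit_gf_tables",
    "association_curve_potential",
    "association_curve_exactgf",
    "check_drift_timestep",
]


@dataclass(frozen=True)
class PotentialSpec:
    """Coulomb pair potential ``beta V(r) = r_c / r`` (r_c in nm)."""

    r_c: float

    def beta_v(self, r):
        return self.r_c / np.asarray(r, dtype=float)

    def beta_f(self, r):
        """Radial force ``-d(beta V)/dr = r_c / r^2`` (positive = repulsive)."""
        r = np.asarray(r, dtype=float)
        return self.r_c / r**2


def coulomb(r, spec: PotentialSpec):
    """``(beta V, beta F)`` of the Coulomb potential at separation ``r``."""
    if np.any(np.asarray(r) <= 0):
        raise ValueError("separation must be positive")
    return spec.beta_v(r), spec.beta_f(r)


def drift_move(pos, D, beta_force, dt, rng):
    """One drifted free-propagator move: ``pos + D beta F dt + N(0, 2 D dt)``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    pos = np.asarray(pos, dtype=float)
    bf = np.asarray(beta_force, dtype=float)
    return pos + D * bf * dt + math.sqrt(2.0 * D * dt) * rng.standard_normal(pos.shape)


def p_free_drift(r, dt, r0, D, spec: PotentialSpec):
    """Single-step radial density of the drifted free propagator.

    The free propagator with the initial position shifted by the drift
    ``D dt beta F(r0)``; accurate for one step when the force is roughly
    constant over the displacement.
    """
    r0d = np.asarray(r0, dtype=float) + D * dt * spec.beta_f(r0)
    if np.any(r0d <= 0):
        raise ValueError("drift-shifted origin is non-positive; reduce dt")
    return p_free(r, dt, r0d, D)


def drift_norm_constant(dt, r0, sigma, D, spec: PotentialSpec):
    """Mass of the drifted free propagator on ``[sigma, inf)`` (closed form)."""
    r0d = np.asarray(r0, dtype=float) + D * dt * spec.beta_f(r0)
    return free_norm_constant(dt, r0d, sigma, D)


def kon_coulomb(r_c: float, sigma: float, k_a: float, D_tot: float) -> float:
    """Steady-state association rate under a Coulomb interaction (nm^3/us).

    ``k_on = 4 pi D r_c [ (1 + 4 pi D r_c / k_a) exp(r_c/sigma) - 1 ]^-1``;
    the continuous ``r_c -> 0`` limit is ``((1/k_a) + (1/k_D))^-1``.
    """
    if D_tot <= 0 or sigma <= 0:
        raise ValueError("require D_tot > 0 and sigma > 0")
    k_D = 4.0 * math.pi * sigma * D_tot
    if r_c == 0.0:
        if math.isinf(k_a):
            return k_D
        return 1.0 / (1.0 / k_a + 1.0 / k_D)
    four_pi_D_rc = 4.0 * math.pi * D_tot * r_c
    if math.isinf(k_a):
        denom = math.exp(r_c / sigma) - 1.0
    else:
        denom = (1.0 + four_pi_D_rc / k_a) * math.exp(r_c / sigma) - 1.0
    return four_pi_D_rc / denom


def longrange_entry_weight(spec: PotentialSpec, R_max: float) -> float:
    """Initial reweighting ratio ``exp(-beta V(R_max))`` on zone entry.

    Corrects the density of particles entering the reaction zone when
    long-range forces are ignored outside of it (strategy B).
    """
    if R_max <= 0:
        raise ValueError("R_max must be positive")
    return float(np.exp(-spec.beta_v(R_max)))


def longrange_force_sum(pos: np.ndarray, spec: PotentialSpec,
                        box: float | None = None) -> np.ndarray:
    """Total pairwise Coulomb drift force on every particle (strategy A).

    Minimum-image convention when ``box`` is given; no lattice sums.
    Returns ``beta F`` vectors, shape ``(N, 3)``; exactly antisymmetric
    pairwise (Newton's third law).
    """
    pos = np.asarray(pos, dtype=float)
    n = pos.shape[0]
    out = np.zeros_like(pos)
    if n < 2 or spec.r_c == 0.0:
        return out
    d = pos[:, None, :] - pos[None, :, :]
    if box is not None:
        d -= box * np.round(d / box)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    np.fill_diagonal(r2, np.inf)
    # beta F_ij = r_c * rhat / r^2 acting on i from j
    coef = spec.r_c / (r2 * np.sqrt(r2))
    out = np.einsum("ij,ijk->ik", coef, d)
    return out


def check_drift_timestep(params: PairParams, spec: PotentialSpec, dt: float,
                         R_max: float | None = None) -> bool:
    """Warn when the drift displacement is not small against diffusion.

    Flags ``|D beta F dt| > 0.1 sqrt(6 D dt)`` anywhere in the zone (the
    single-step propagator requires the force to be nearly constant over a
    displacement).
    """
    D = params.D_tot
    if R_max is None:
        R_max = reaction_zone_radius(params.sigma, D, dt)
    r = np.linspace(params.sigma, R_max, 200)
    drift = np.abs(D * spec.beta_f(r) * dt)
    ok = drift.max() <= 0.1 * math.sqrt(6.0 * D * dt)
    if not ok:
        warnings.warn(
            "drift displacement exceeds 10% of the rms diffusive displacement "
            "inside the reaction zone; consider a smaller dt")
    return ok


# ---------------------------------------------------------------------------
# Numerical Green's function tabulation (method of Zhou)
# ---------------------------------------------------------------------------


@dataclass
class GFTable:
    """Tabulated survival and propagator densities under a potential.

    Built by fine-step radial Brownian dynamics with a reactive shell of
    width ``eps = f D 4 pi sigma^2 / k_a`` at contact and inner step
    ``delta_t = f eps^2 / (2 D)``; each walker runs until it reacts or
    reaches the FPR step ``dt``.  ``fit()`` smooths the raw data:
    the survival-vs-r0 curve is fitted to the closed-form radiation-boundary
    expression with the rate and diffusion constant free, and each endpoint
    density to a scaled analytic template with separate fits over its inner
    and outer halves.
    """

    params: PairParams
    spec: PotentialSpec
    dt: float
    f: float
    r0_grid: np.ndarray
    survival_raw: np.ndarray         # (n_r0,)
    n_reps: np.ndarray               # (n_r0,)
    hist_edges: np.ndarray           # (n_bins+1,)
    hist_counts: np.ndarray          # (n_r0, n_bins) surviving endpoints
    fit_params: dict = field(default_factory=dict)

    # ------------------------------------------------------------------ fits
    def fit(self) -> "GFTable":
        return fit_gf_tables(self)

    @property
    def fitted(self) -> bool:
        return bool(self.fit_params)

    def survival_at(self, r0):
        """Smoothed survival probability S(dt | r0); 1 beyond the zone."""
        r0 = np.asarray(r0, dtype=float)
        if self.fitted and self.fit_params.get("survival") is not None:
            ka_f, D_f = self.fit_params["survival"]
            pf = PairParams(self.params.sigma, D_f / 2.0, D_f / 2.0, ka_f)
            out = 1.0 - p_assoc_analytic(self.dt, np.maximum(r0, self.params.sigma), pf)
        else:
            out = np.interp(r0, self.r0_grid, self.survival_raw,
                            left=self.survival_raw[0], right=1.0)
        return np.clip(out, 0.0, 1.0)

    def p_assoc_at(self, r0):
        return 1.0 - self.survival_at(r0)

    # -------------------------------------------------------------- densities
    def _density_node(self, i: int, r: np.ndarray,
                      source: str = "fit") -> np.ndarray:
        """Fitted (or raw-histogram) radial density at grid node i.

        The density carries the 4 pi r^2 Jacobian convention of the package
        and integrates to the raw survival at the node.  ``source="raw"``
        forces the empirical histogram even on a fitted table — the smooth
        templates cannot represent the Boltzmann pileup of an attractive
        potential at contact, and a biased reweighting numerator shifts
        association rates, whereas histogram noise only adds variance.
        """
        entry = self.fit_params.get("density", [None] * self.r0_grid.size)[i] \
            if (self.fitted and source == "fit") else None
        if entry is not None:
            (a_lo, ka_lo, D_lo, kind_lo), (a_hi, ka_hi, D_hi, kind_hi), r_mid = entry
            r0 = self.r0_grid[i]
            lo = a_lo * self._template(r, r0, ka_lo, D_lo, kind_lo)
            hi = a_hi * self._template(r, r0, ka_hi, D_hi, kind_hi)
            return np.where(r < r_mid, lo, hi)
        # raw histogram as a step density
        widths = np.diff(self.hist_edges)
        dens = self.hist_counts[i] / (self.n_reps[i] * widths)
        idx = np.clip(np.searchsorted(self.hist_edges, r) - 1, 0, len(widths) - 1)
        out = dens[idx] / (4.0 * math.pi * r**2)
        out[(r < self.hist_edges[0]) | (r > self.hist_edges[-1])] = 0.0
        return out

    def _template(self, r, r0, ka, D, kind: str = "irr"):
        """Analytic fit templates.

        ``"irr"``: the closed-form radiation-boundary propagator with free
        rate and diffusion constant (captures contact-boundary structure);
        ``"drift"``: the drift-shifted free propagator (captures the bulk
        displacement under the force).  Both are scaled by a free amplitude
        in the fits.
        """
        if kind == "irr":
            pf = PairParams(self.params.sigma, D / 2.0, D / 2.0, max(ka, 0.0))
            return p_irr(r, self.dt, r0, pf)
        r0d = max(r0 + D * self.dt * self.spec.beta_f(r0), 1e-6)
        return p_free(r, self.dt, r0d, D)

    def density(self, r, r0: float) -> np.ndarray:
        """Propagator density p(r, dt | r0), linear blend between r0 nodes."""
        r = np.asarray(r, dtype=float)
        g = self.r0_grid
        if r0 <= g[0]:
            return self._density_node(0, r)
        if r0 >= g[-1]:
            return self._density_node(len(g) - 1, r)
        i = int(np.searchsorted(g, r0) - 1)
        t = (r0 - g[i]) / (g[i + 1] - g[i])
        return (1 - t) * self._density_node(i, r) + t * self._density_node(i + 1, r)

    def build_sampler(self, n_quantiles: int = 800, n_r: int = 600,
                      source: str = "raw"):
        """Inverse-CDF tables of the survival-conditioned density per node.

        ``source="raw"`` inverts the empirical endpoint histograms directly
        (most faithful for propagation; the histogram bins are much finer
        than the single-step displacement scale); ``source="fit"`` inverts
        the fitted smooth densities.
        """
        from .reference_theory import _quantile_grid

        sig = self.params.sigma
        q = _quantile_grid(n_quantiles)
        tables = np.empty((self.r0_grid.size, q.size))
        if source == "raw":
            from .reference_theory import _trim_flat_cdf

            edges = self.hist_edges
            for i in range(self.r0_grid.size):
                counts = self.hist_counts[i].astype(float)
                if counts.sum() <= 0:
                    raise FloatingPointError(
                        f"no surviving endpoints at r0={self.r0_grid[i]}")
                cdf = np.concatenate(([0.0], np.cumsum(counts)))
                cdf /= cdf[-1]
                cdf = np.maximum.accumulate(cdf)
                tables[i] = np.interp(q, *_trim_flat_cdf(cdf, edges))
        else:
            span = self.hist_edges[-1] - sig
            step_span = 8.0 * math.sqrt(4.0 * self.params.D_tot * self.dt)
            for i, r0 in enumerate(self.r0_grid):
                r = np.linspace(max(sig + 1e-9, r0 - step_span),
                                min(sig + span, r0 + step_span), n_r)
                dens = 4.0 * math.pi * r**2 * self._density_node(i, r)
                cdf = np.concatenate(([0.0],
                                      np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(r))))
                if cdf[-1] <= 0:
                    raise FloatingPointError(f"empty density at r0={r0}")
                cdf /= cdf[-1]
                cdf = np.maximum.accumulate(cdf)
                from .reference_theory import _trim_flat_cdf

                tables[i] = np.interp(q, *_trim_flat_cdf(cdf, r))
        self._sampler_tables = tables
        self._sampler_q = q
        return tables

    def sample_conditional(self, r0: np.ndarray, rng) -> np.ndarray:
        """Draw surviving end separations from the tabulated density."""
        if not hasattr(self, "_sampler_tables"):
            self.build_sampler()
        g = self.r0_grid
        t = self._sampler_tables
        nq = self._sampler_q.size
        r0 = np.asarray(r0, dtype=float)
        fi = np.clip(np.interp(r0, g, np.arange(g.size)), 0, g.size - 1 - 1e-9)
        i0 = fi.astype(int)
        wi = fi - i0
        u = rng.random(r0.shape)
        fj = np.clip(np.interp(u, self._sampler_q, np.arange(nq)), 0, nq - 1 - 1e-9)
        j0 = fj.astype(int)
        wj = fj - j0
        return ((1 - wi) * ((1 - wj) * t[i0, j0] + wj * t[i0, j0 + 1])
                + wi * ((1 - wj) * t[i0 + 1, j0] + wj * t[i0 + 1, j0 + 1]))


def tabulate_numerical_gf(params: PairParams, spec: PotentialSpec, dt_target: float,
                          f: float, n_reps: int, rng, *, dr0: float = 0.05,
                          r0_max: float | None = None,
                          compress_every: int = 400) -> GFTable:
    """Numerical pair Green's function by fine-step radial Brownian dynamics.

    For every initial separation on the ``r0`` grid, ``n_reps`` walkers run
    the radial Ito dynamics ``dr = (2D/r + D beta F) dt' + sqrt(2D) dW``
    with specular reflection at contact; walkers inside the reactive shell
    ``[sigma, sigma + eps)`` react with probability
    ``k_a delta_t / (4 pi sigma^2 eps)`` per inner step.  Records the
    survival fraction at ``dt_target`` and the histogram of surviving
    endpoints.  The shell factor ``f`` controls accuracy (error -> 0 with f);
    all walkers across the grid are propagated in one vectorized batch.
    """
    if math.isinf(params.k_a):
        raise ValueError(
            "the shell tabulator requires finite k_a (the shell width divides "
            "by k_a); for V = 0 use the analytic absorbing branch instead")
    D = params.D_tot
    sig = params.sigma
    if D <= 0:
        raise ValueError("D_tot must be positive")
    if params.k_a > 0:
        eps = f * D * 4.0 * math.pi * sig**2 / params.k_a
        delta_t = f * eps**2 / (2.0 * D)
        # reaction probability per inner step for a walker inside the shell:
        # k_a delta_t divided by the exact shell volume (using 4 pi sigma^2 eps
        # instead over-reacts by the O(eps/sigma) Jacobian of the shell)
        v_shell = 4.0 * math.pi * (sig**2 * eps + sig * eps**2 + eps**3 / 3.0)
        p_shell = params.k_a * delta_t / v_shell
    else:
        eps = 0.0
        delta_t = f * sig**2 / (2.0 * D)
        p_shell = 0.0
    n_inner = max(int(math.ceil(dt_target / delta_t)), 1)
    if r0_max is None:
        r0_max = reaction_zone_radius(sig, D, dt_target)
    r0_grid = np.arange(sig, r0_max + 0.5 * dr0, dr0)
    r0_grid[0] = max(r0_grid[0], sig + 1e-9)
    n_r0 = r0_grid.size

    r = np.repeat(r0_grid, n_reps)
    origin = np.repeat(np.arange(n_r0), n_reps)
    alive_counts = np.full(n_r0, n_reps, dtype=np.int64)
    sd = math.sqrt(2.0 * D * delta_t)
    span = 8.0 * math.sqrt(4.0 * D * dt_target)
    edges = np.linspace(sig, sig + span, 321)
    use_force = spec.r_c != 0.0

    for step in range(n_inner):
        drift = (2.0 * D / r) * delta_t
        if use_force:
            drift += D * spec.beta_f(r) * delta_t
        r += drift + sd * rng.standard_normal(r.size)
        below = r < sig
        if below.any():
            r[below] = 2.0 * sig - r[below]
        if p_shell > 0.0:
            shell = r < sig + eps
            if shell.any():
                idx = np.flatnonzero(shell)
                dead = idx[rng.random(idx.size) < p_shell]
                if dead.size:
                    np.subtract.at(alive_counts, origin[dead], 1)
                    keep = np.ones(r.size, dtype=bool)
                    keep[dead] = False
                    r = r[keep]
                    origin = origin[keep]
    hist = np.zeros((n_r0, edges.size - 1), dtype=np.int64)
    bin_idx = np.clip(np.searchsorted(edges, r) - 1, 0, edges.size - 2)
    np.add.at(hist, (origin, bin_idx), 1)
    surv = alive_counts / n_reps
    return GFTable(params, spec, dt_target, f, r0_grid, surv,
                   np.full(n_r0, n_reps, dtype=np.int64), edges, hist)


def fit_gf_tables(table: GFTable) -> GFTable:
    """Smooth a raw GF table by fitting analytic templates.

    Survival across the r0 grid is fitted to the closed-form
    radiation-boundary association probability with ``k_a`` and ``D`` free;
    each endpoint density is fitted to a scaled analytic template (three
    parameters) separately over the inner and outer halves of its support.
    Non-convergent fits fall back to the raw data with a warning.
    """
    par = table.params
    sig = par.sigma

    def surv_model(r0, ka, D):
        pf = PairParams(sig, D / 2.0, D / 2.0, abs(ka))
        return 1.0 - p_assoc_analytic(table.dt, r0, pf)

    def surv_model_ka(r0, ka):
        return surv_model(r0, ka, par.D_tot)

    fit = {}
    # weight nodes by their binomial errors and drop nodes inside the
    # reactive shell, where the discrete reaction rule distorts the start
    # condition at finite f
    if par.k_a > 0:
        eps = table.f * par.D_tot * 4.0 * math.pi * sig**2 / par.k_a
    else:
        eps = 0.0
    mask = table.r0_grid >= sig + eps
    if mask.sum() < 4:
        mask = np.ones_like(mask)
    s_raw = table.survival_raw[mask]
    # add-one smoothing keeps the error realistic at nodes with zero
    # observed reactions (a plain binomial estimate would give them
    # near-infinite weight)
    n_m = table.n_reps[mask]
    s_err = np.sqrt((s_raw * (1.0 - s_raw) + 1.0 / n_m) / n_m)
    try:
        ka0 = max(par.k_a, 1e-3)
        # one-parameter fit: the Brownian dynamics uses the exact drift and
        # diffusion constant, so only the effective absorption strength needs
        # calibrating; freeing D as well is hopelessly degenerate at reduced
        # repetition counts
        popt, _ = curve_fit(surv_model_ka, table.r0_grid[mask], s_raw,
                            sigma=s_err, absolute_sigma=True, p0=[ka0],
                            bounds=(ka0 / 10.0, ka0 * 10.0), maxfev=20000)
        fit["survival"] = (abs(popt[0]), par.D_tot)
    except Exception as err:  # pragma: no cover - diagnostic path
        warnings.warn(f"survival fit failed ({err}); keeping raw interpolation")
        fit["survival"] = None

    centers = 0.5 * (table.hist_edges[1:] + table.hist_edges[:-1])
    widths = np.diff(table.hist_edges)
    density_fits = []
    for i, r0 in enumerate(table.r0_grid):
        dens = table.hist_counts[i] / (table.n_reps[i] * widths)
        dens = dens / (4.0 * math.pi * centers**2)
        support = np.flatnonzero(table.hist_counts[i] > 0)
        if support.size < 8:
            density_fits.append(None)
            continue
        lo_edge, hi_edge = centers[support[0]], centers[support[-1]]
        r_mid = 0.5 * (lo_edge + hi_edge)

        halves = []
        ok = True
        for sel in (centers <= r_mid, centers >= r_mid):
            m = sel & (dens > 0)
            if m.sum() < 4:
                ok = False
                break
            best = None
            for kind in ("irr", "drift"):

                def model(r, a, ka, D, _r0=r0, _kind=kind):
                    return a * table._template(r, _r0, abs(ka), abs(D), _kind)

                try:
                    popt, _ = curve_fit(model, centers[m], dens[m],
                                        p0=[1.0, max(par.k_a, 1e-3), par.D_tot],
                                        maxfev=20000)
                    resid = float(np.sum(
                        (model(centers[m], *popt) - dens[m]) ** 2))
                    cand = (resid, (popt[0], abs(popt[1]), abs(popt[2]), kind))
                    if best is None or cand[0] < best[0]:
                        best = cand
                except Exception:
                    continue
            if best is None:
                ok = False
                break
            halves.append(best[1])
        density_fits.append((halves[0], halves[1], r_mid) if ok else None)
    if any(d is None for d in density_fits):
        warnings.warn("some density fits failed; those nodes keep raw histograms")
    fit["density"] = density_fits
    out = GFTable(table.params, table.spec, table.dt, table.f, table.r0_grid,
                  table.survival_raw, table.n_reps, table.hist_edges,
                  table.hist_counts, fit)
    return out


# ---------------------------------------------------------------------------
# Pair-level engines under a potential
# ---------------------------------------------------------------------------


def _drifted_relative_move(x, r, sigma, D, dt, spec: PotentialSpec, rng,
                           max_rounds=10_000):
    """Vectorized drifted move of relative coordinates with contact rejection."""
    sd = math.sqrt(2.0 * D * dt)
    drift = (D * dt * spec.beta_f(r) / r)[:, None] * x
    new = x + drift + sd * rng.standard_normal(x.shape)
    bad = np.einsum("ij,ij->i", new, new) < sigma * sigma
    rounds = 0
    while bad.any():
        rounds += 1
        if rounds > max_rounds:
            raise RuntimeError("overlap rejection failed to terminate")
        idx = np.flatnonzero(bad)
        new[idx] = (x[idx] + drift[idx]
                    + sd * rng.standard_normal((idx.size, 3)))
        bad[idx] = np.einsum("ij,ij->i", new[idx], new[idx]) < sigma * sigma
    return new


def association_curve_potential(table: GFTable, dt: float, r0: float,
                                n_steps: int, n_traj: int, rng) -> AssociationCurve:
    """Cumulative association of pairs interacting through a potential.

    FPR propagation: drifted free moves everywhere, association probability
    and reweighting increments from the numerically tabulated Green's
    function, with the drifted renormalized free propagator in the
    denominator.
    """
    params = table.params
    spec = table.spec
    sig, D = params.sigma, params.D_tot
    R_max = reaction_zone_radius(sig, D, dt)
    dirs = rng.standard_normal((n_traj, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    x = r0 * dirs
    w = np.ones(n_traj)
    s_prev = np.ones(n_traj)
    r_prev = np.full(n_traj, r0)
    in_zone = np.zeros(n_traj, dtype=bool)
    assoc = np.zeros(n_steps, dtype=np.int64)

    for k in range(n_steps):
        m = x.shape[0]
        if m == 0:
            break
        r = np.linalg.norm(x, axis=1)
        np.maximum(r, sig, out=r)
        inz = r < R_max
        entering = inz & ~in_zone
        staying = inz & in_zone
        w[entering] = 1.0
        w[~inz] = 1.0
        if staying.any():
            idx = np.flatnonzero(staying)
            num = _table_density_pairwise(table, r[idx], r_prev[idx])
            denom = (p_free_drift(r[idx], dt, r_prev[idx], D, spec)
                     / drift_norm_constant(dt, r_prev[idx], sig, D, spec)
                     * np.maximum(s_prev[idx], SURVIVAL_FLOOR))
            w[idx] *= num / denom
        p_eff = np.zeros(m)
        if inz.any():
            idx = np.flatnonzero(inz)
            p_eff[idx] = np.clip(w[idx] * table.p_assoc_at(r[idx]), 0.0, 1.0)
        react = p_eff > rng.random(m)
        assoc[k] = int(react.sum())
        keep = ~react
        x = x[keep]
        w = w[keep]
        r = r[keep]
        s_prev = np.maximum(1.0 - p_eff[keep], SURVIVAL_FLOOR)
        r_prev = r
        in_zone = inz[keep]
        x = _drifted_relative_move(x, r, sig, D, dt, spec, rng)

    times = dt * np.arange(1, n_steps + 1)
    return AssociationCurve(times, np.cumsum(assoc) / n_traj, n_traj,
                            params, r0)


def _table_density_pairwise(table: GFTable, r: np.ndarray, r0: np.ndarray,
                            source: str = "raw") -> np.ndarray:
    """Tabulated density evaluated elementwise for (r_i, r0_i) pairs."""
    g = table.r0_grid
    fi = np.clip(np.interp(r0, g, np.arange(g.size)), 0, g.size - 1 - 1e-9)
    i0 = fi.astype(int)
    wi = fi - i0
    out = np.zeros(r.size)
    for node in np.unique(np.concatenate([i0, i0 + 1])):
        sel_lo = i0 == node
        sel_hi = (i0 + 1) == node
        if sel_lo.any():
            out[sel_lo] += (1.0 - wi[sel_lo]) * table._density_node(
                int(node), r[sel_lo], source)
        if sel_hi.any():
            out[sel_hi] += wi[sel_hi] * table._density_node(
                int(node), r[sel_hi], source)
    return out


def association_curve_exactgf(table: GFTable, dt: float, r0: float,
                              n_steps: int, n_traj: int, rng) -> AssociationCurve:
    """Cumulative association with separations propagated by the exact GF.

    Radial-only propagation: association is decided by the tabulated
    survival and surviving separations are drawn from the tabulated density
    conditioned on survival (inverse CDF).  Beyond the tabulated r0 range
    the association probability is zero and separations advance by the
    drifted free propagator (to which the GF converges away from contact).
    """
    params = table.params
    spec = table.spec
    sig, D = params.sigma, params.D_tot
    table.build_sampler()
    r = np.full(n_traj, float(r0))
    assoc = np.zeros(n_steps, dtype=np.int64)
    r_table_max = table.r0_grid[-1]
    sd = math.sqrt(2.0 * D * dt)
    for k in range(n_steps):
        m = r.size
        if m == 0:
            break
        p = np.where(r <= r_table_max, table.p_assoc_at(r), 0.0)
        hit = p > rng.random(m)
        assoc[k] = int(hit.sum())
        r = r[~hit]
        near = r <= r_table_max
        if near.any():
            r[near] = table.sample_conditional(r[near], rng)
        farm = ~near
        if farm.any():
            rf = r[farm]
            # exact radial update of the drifted free propagator (with the
            # same contact rejection as the position-space engines)
            shift = rf + D * dt * spec.beta_f(rf)
            new = np.abs(np.stack([shift, np.zeros_like(rf), np.zeros_like(rf)],
                                  axis=1) + sd * rng.standard_normal((rf.size, 3)))
            nr = np.linalg.norm(new, axis=1)
            bad = nr < sig
            while bad.any():
                idx = np.flatnonzero(bad)
                trial = (np.stack([shift[idx], np.zeros_like(shift[idx]),
                                   np.zeros_like(shift[idx])], axis=1)
                         + sd * rng.standard_normal((idx.size, 3)))
                nr[idx] = np.linalg.norm(trial, axis=1)
                bad[idx] = nr[idx] < sig
            r[farm] = nr
    times = dt * np.arange(1, n_steps + 1)
    return AssociationCurve(times, np.cumsum(assoc) / n_traj, n_traj, params, r0)


def save_gf_table(table: GFTable, path) -> None:
    """Write a GF table (with metadata) to a portable JSON file."""
    import json

    payload = {
        "sigma": table.params.sigma, "D_a": table.params.D_a,
        "D_b": table.params.D_b, "k_a": table.params.k_a,
        "k_b": table.params.k_b, "r_c": table.spec.r_c,
        "dt": table.dt, "f": table.f,
        "r0_grid": table.r0_grid.tolist(),
        "survival_raw": table.survival_raw.tolist(),
        "n_reps": table.n_reps.tolist(),
        "hist_edges": table.hist_edges.tolist(),
        "hist_counts": table.hist_counts.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_gf_table(path) -> GFTable:
    import json

    with open(path) as fh:
        d = json.load(fh)
    par = PairParams(d["sigma"], d["D_a"], d["D_b"], d["k_a"], d["k_b"])
    return GFTable(par, PotentialSpec(d["r_c"]), d["dt"], d["f"],
                   np.asarray(d["r0_grid"]), np.asarray(d["survival_raw"]),
                   np.asarray(d["n_reps"], dtype=np.int64),
                   np.asarray(d["hist_edges"]),
                   np.asarray(d["hist_counts"], dtype=np.int64))
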