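"""Fixed-time-step many-particle FPR engine.

Each step runs four phases in order: (1) Poisson dissociation tests for all
bound complexes; (2) measurement of reactive-pair separations (cKDTree
neighbor search, minimum image when periodic) and evaluation of reweighted
association probabilities for pairs inside their reaction zone; (3)
association attempts with multi-partner resolution (individual pair
probabilities are summed per particle, one uniform random number selects the
partner interval) followed by free/drift moves of everything that did not
react; (4) sequential overlap resolution in which a particle that has
settled at a non-overlapping position is never moved again within the step.
Each particle undergoes at most one reactive event and exactly one accepted
displacement per step.

The module also houses the target-problem engines (one central particle in
a bath of mutually non-interacting partners): a plain survival simulator and
an accelerated equilibrium estimator that collapses bound intervals and
fast-forwards out-of-zone free diffusion with exact aggregated Gaussian
steps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .greens import PairParams, p_assoc
from .pair_fpr import (
    SURVIVAL_FLOOR,
    place_complex,
    place_dissociated,
    reaction_zone_radius,
    reweight_increment,
)
from .reference_theory import TimeSeries

__all__ = [
    "Species",
    "Reaction",
    "SimConfig",
    "SystemState",
    "initialize_system",
    "find_reactive_pairs",
    "resolve_association",
    "resolve_overlaps",
    "step_system",
    "run_simulation",
    "suggest_timestep",
    "simulate_target_fpr_survival",
    "TargetEquilibriumEstimator",
]


@dataclass(frozen=True)
class Species:
    name: str
    D: float  # nm^2/us


@dataclass(frozen=True)
class Reaction:
    """One bimolecular channel: A + B -> C (reversible) or A + A -> 0.

    ``product`` of None marks annihilation (both reactants removed).
    ``D_product`` defaults to ``min(D_a, D_b)`` — a conservative choice for
    the complex's diffusion constant, configurable per reaction.
    """

    a: str
    b: str
    sigma: float
    k_a: float  # nm^3/us, may be inf
    k_b: float = 0.0  # 1/us
    product: str | None = None
    D_product: float | None = None
    r_c: float = 0.0  # Coulomb parameter of beta*V = r_c / r (nm)

    def pair_params(self, species: dict[str, Species]) -> PairParams:
        return PairParams(self.sigma, species[self.a].D, species[self.b].D,
                          self.k_a, self.k_b)


@dataclass
class SimConfig:
    species: list[Species]
    reactions: list[Reaction]
    counts: dict[str, int]
    box: float  # cubic edge length, nm
    dt: float
    T_max: float
    boundary: str = "periodic"  # or "none"
    seed: int | None = None
    target_center: str | None = None  # species fixed at the box center
    products_avoid_reactants: bool = False
    longrange_strategy: str | None = None  # None | "sum" | "entry_weight"
    R_rewgt: dict[tuple[str, str], float] | None = None
    allow_large_dt: bool = False

    def __post_init__(self) -> None:
        if self.boundary not in ("periodic", "none"):
            raise ValueError(f"unknown boundary mode {self.boundary!r}")
        names = {s.name for s in self.species}
        for r in self.reactions:
            if r.a not in names or r.b not in names:
                raise ValueError(f"reaction references unknown species: {r}")
            if r.product is not None and r.product not in names:
                raise ValueError(f"unknown product species {r.product!r}")

    def species_map(self) -> dict[str, Species]:
        return {s.name: s for s in self.species}


class SystemState:
    """Positions, species indices and pair bookkeeping of the whole system.

    Particles carry persistent integer ids so that per-pair reweighting
    records survive the removal of other particles.
    """

    def __init__(self, pos: np.ndarray, species_idx: np.ndarray, config: SimConfig):
        self.pos = np.asarray(pos, dtype=float)
        self.species_idx = np.asarray(species_idx, dtype=np.int64)
        self.config = config
        n = self.pos.shape[0]
        self.ids = np.arange(n, dtype=np.int64)
        self._next_id = n
        self.time = 0.0
        # (id_lo, id_hi) -> [r_prev, w_ratio, survival_prev]
        self.pair_records: dict[tuple[int, int], list[float]] = {}
        # complexes: id -> reaction index (to recover constituents)
        self.complex_reaction: dict[int, int] = {}
        self._names = [s.name for s in config.species]
        self._name_to_idx = {s.name: i for i, s in enumerate(config.species)}
        self._D = np.array([s.D for s in config.species])

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    def counts(self) -> dict[str, int]:
        out = {}
        for i, name in enumerate(self._names):
            out[name] = int(np.sum(self.species_idx == i))
        return out

    def new_ids(self, k: int) -> np.ndarray:
        ids = np.arange(self._next_id, self._next_id + k, dtype=np.int64)
        self._next_id += k
        return ids

    def remove_and_add(self, remove_mask: np.ndarray, new_pos, new_species, new_ids):
        keep = ~remove_mask
        self.pos = np.concatenate([self.pos[keep], np.asarray(new_pos, float).reshape(-1, 3)])
        self.species_idx = np.concatenate(
            [self.species_idx[keep], np.asarray(new_species, np.int64)])
        self.ids = np.concatenate([self.ids[keep], np.asarray(new_ids, np.int64)])


def _min_image(d: np.ndarray, box: float | None) -> np.ndarray:
    if box is not None:
        d = d - box * np.round(d / box)
    return d


def suggest_timestep(reactions: list[Reaction], species: list[Species],
                     densities: dict[str, float]) -> float:
    """Upper bound on dt such that particles rarely see multiple partners.

    ``dt < min_A (sum_B 12 pi sigma_AB^2 sqrt(6 D_AB) rho_B)^-2`` — derived
    from requiring fewer than one reactive partner in the shell swept during
    one step.  Returns ``inf`` when every partner density is zero.
    """
    smap = {s.name: s for s in species}
    per_species_sum: dict[str, float] = {}
    for r in reactions:
        D_ab = smap[r.a].D + smap[r.b].D
        coef = 12.0 * math.pi * r.sigma**2 * math.sqrt(6.0 * D_ab)
        per_species_sum[r.a] = per_species_sum.get(r.a, 0.0) + coef * densities.get(r.b, 0.0)
        if r.a != r.b:
            per_species_sum[r.b] = per_species_sum.get(r.b, 0.0) + coef * densities.get(r.a, 0.0)
    vals = [s for s in per_species_sum.values() if s > 0]
    if not vals:
        return math.inf
    return min(s**-2 for s in vals)


def initialize_system(config: SimConfig, rng) -> SystemState:
    """Uniform non-overlapping placement (reactive pairs at >= sigma).

    With ``target_center`` set, one particle of that species sits at the box
    center and the remaining particles are placed uniformly outside its
    contact volume.
    """
    if config.dt <= 0:
        raise ValueError("dt must be positive")
    smap = config.species_map()
    name_idx = {s.name: i for i, s in enumerate(config.species)}
    # dt sanity against the single-partner bound
    vol = config.box**3
    dens = {k: v / vol for k, v in config.counts.items()}
    bound = suggest_timestep(config.reactions, config.species, dens)
    if config.dt > bound and not config.allow_large_dt:
        raise ValueError(
            f"dt = {config.dt} exceeds the single-partner bound {bound:.4g} us; "
            "set allow_large_dt to override")
    max_zone = 0.0
    for r in config.reactions:
        D_ab = smap[r.a].D + smap[r.b].D
        max_zone = max(max_zone, reaction_zone_radius(r.sigma, D_ab, config.dt))
    if config.boundary == "periodic" and config.box <= 2.0 * max_zone:
        raise ValueError("periodic box edge must exceed twice the largest R_max")

    pos_list, sp_list = [], []
    if config.target_center is not None:
        pos_list.append(np.full((1, 3), config.box / 2.0))
        sp_list.append([name_idx[config.target_center]])
    for name, cnt in config.counts.items():
        k = cnt - (1 if name == config.target_center else 0)
        if k < 0:
            raise ValueError("target species count must be at least one")
        if k:
            pos_list.append(rng.random((k, 3)) * config.box)
            sp_list.append([name_idx[name]] * k)
    if not pos_list:
        state = SystemState(np.empty((0, 3)), np.empty(0, np.int64), config)
        return state
    pos = np.concatenate(pos_list)
    spi = np.concatenate([np.asarray(s, np.int64) for s in sp_list])
    state = SystemState(pos, spi, config)

    sigma_of = _sigma_matrix(config)
    box = config.box if config.boundary == "periodic" else None
    for _ in range(200):
        bad = _overlapping_particles(state, sigma_of, box)
        if not bad.size:
            break
        if config.target_center is not None:
            bad = bad[bad != 0]  # never move the central target
            if not bad.size:
                break
        state.pos[bad] = rng.random((bad.size, 3)) * config.box
    else:
        raise ValueError("could not place particles without reactive overlap "
                         "(system too dense)")
    return state


def _sigma_matrix(config: SimConfig) -> dict[tuple[int, int], float]:
    idx = {s.name: i for i, s in enumerate(config.species)}
    out = {}
    for r in config.reactions:
        i, j = sorted((idx[r.a], idx[r.b]))
        out[(i, j)] = r.sigma
    return out


def _overlapping_particles(state: SystemState, sigma_of, box) -> np.ndarray:
    if state.n < 2:
        return np.empty(0, np.int64)
    max_sig = max(sigma_of.values(), default=0.0)
    if max_sig == 0.0:
        return np.empty(0, np.int64)
    tree = cKDTree(state.pos, boxsize=box)
    pairs = tree.query_pairs(max_sig, output_type="ndarray")
    bad = []
    for i, j in pairs:
        key = tuple(sorted((int(state.species_idx[i]), int(state.species_idx[j]))))
        sig = sigma_of.get(key)
        if sig is None:
            continue
        d = np.linalg.norm(_min_image(state.pos[i] - state.pos[j], box))
        if d < sig:
            bad.append(j)
    return np.unique(np.asarray(bad, np.int64))


@dataclass
class _Channel:
    reaction_index: int
    a_idx: int
    b_idx: int
    params: PairParams
    R_max: float
    R_rewgt: float
    product_idx: int | None
    D_product: float
    spec: object | None = None       # PotentialSpec for Coulomb channels
    gf: object | None = None         # GFTable for Coulomb channels
    entry_w: float = 1.0             # initial w_ratio on zone entry


def _channels(config: SimConfig, gf_tables: dict | None = None) -> list[_Channel]:
    smap = config.species_map()
    name_idx = {s.name: i for i, s in enumerate(config.species)}
    out = []
    for k, r in enumerate(config.reactions):
        params = r.pair_params(smap)
        R_max = reaction_zone_radius(r.sigma, params.D_tot, config.dt)
        rw = R_max
        if config.R_rewgt:
            rw = config.R_rewgt.get((r.a, r.b), config.R_rewgt.get((r.b, r.a), R_max))
        Dp = r.D_product if r.D_product is not None else min(smap[r.a].D, smap[r.b].D)
        spec = gf = None
        entry_w = 1.0
        if r.r_c != 0.0:
            from .potentials import PotentialSpec, longrange_entry_weight

            spec = PotentialSpec(r.r_c)
            gf = (gf_tables or {}).get(k)
            if gf is None:
                raise ValueError(
                    f"reaction {k} has a Coulomb potential; supply its GFTable "
                    "through gf_tables")
            if config.longrange_strategy == "entry_weight":
                entry_w = longrange_entry_weight(spec, R_max)
        out.append(_Channel(k, name_idx[r.a], name_idx[r.b], params, R_max, rw,
                            name_idx[r.product] if r.product else None, Dp,
                            spec, gf, entry_w))
    return out


def find_reactive_pairs(state: SystemState, channels: list[_Channel] | None = None):
    """All unbound reactive-species pairs with separation below their R_max.

    Returns ``(i, j, channel_index, separation)`` arrays; equivalent to the
    brute-force O(N^2) enumeration (tested against it).
    """
    config = state.config
    if channels is None:
        channels = _channels(config)
    if state.n < 2 or not channels:
        z = np.empty(0, np.int64)
        return z, z, z, np.empty(0)
    box = config.box if config.boundary == "periodic" else None
    r_query = max(c.R_max for c in channels)
    if box is not None and r_query >= config.box / 2.0:
        raise ValueError("reaction zone exceeds half the periodic box edge")
    tree = cKDTree(np.mod(state.pos, box) if box is not None else state.pos,
                   boxsize=box)
    pairs = tree.query_pairs(r_query, output_type="ndarray")
    if not pairs.size:
        z = np.empty(0, np.int64)
        return z, z, z, np.empty(0)
    chan_of = {}
    for k, c in enumerate(channels):
        chan_of[(c.a_idx, c.b_idx)] = k
        chan_of[(c.b_idx, c.a_idx)] = k
    ii, jj, cc, rr = [], [], [], []
    si = state.species_idx
    d = _min_image(state.pos[pairs[:, 0]] - state.pos[pairs[:, 1]], box)
    dist = np.linalg.norm(d, axis=1)
    for (i, j), r in zip(pairs, dist):
        k = chan_of.get((int(si[i]), int(si[j])))
        if k is None or r >= channels[k].R_max:
            continue
        ii.append(i)
        jj.append(j)
        cc.append(k)
        rr.append(r)
    return (np.asarray(ii, np.int64), np.asarray(jj, np.int64),
            np.asarray(cc, np.int64), np.asarray(rr))


def _pair_increment(channel: _Channel, r_t: float, r_prev: float, dt: float,
                    survival_prev: float) -> float:
    """Single-step reweighting ratio for one channel (analytic or tabulated)."""
    if channel.gf is None:
        return float(reweight_increment(r_t, r_prev, channel.params, dt,
                                        survival_prev))
    from .potentials import _table_density_pairwise, drift_norm_constant, p_free_drift

    num = _table_density_pairwise(channel.gf, np.atleast_1d(float(r_t)),
                                  np.atleast_1d(float(r_prev)))[0]
    par = channel.params
    denom = (float(p_free_drift(r_t, dt, r_prev, par.D_tot, channel.spec))
             / float(drift_norm_constant(dt, r_prev, par.sigma, par.D_tot,
                                         channel.spec))
             * max(survival_prev, SURVIVAL_FLOOR))
    if denom <= 0:
        raise FloatingPointError("drifted free propagator vanished in reweighting")
    return num / denom


def resolve_association(partner_probs, rng):
    """Multi-partner association: pick a partner index or None.

    The individual probabilities are summed (clamped at one with a warning);
    a single URN decides both whether association happens and, through the
    cumulative probability interval it falls into, with whom.
    """
    p = np.asarray(partner_probs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("partner probabilities must lie in [0, 1]")
    total = p.sum()
    if total > 1.0:
        warnings.warn(f"summed association probability {total:.3g} > 1; clamped")
    u = rng.random() * max(total, 1.0) if total > 1.0 else rng.random()
    if u >= total:
        return None
    return int(np.searchsorted(np.cumsum(p), u, side="right"))


def resolve_overlaps(state: SystemState, proposals: np.ndarray,
                     overlap_pairs, settled: np.ndarray, rng,
                     max_attempts: int = 10**6) -> np.ndarray:
    """Sequential overlap resolution of proposed moves (single-move rule).

    ``overlap_pairs`` is a list of ``(i, j, sigma)`` index pairs to keep
    separated.  Particles are visited in random order; on overlap both
    members are redrawn from their pre-move positions unless one has already
    settled, in which case only the unsettled one moves.  Once a particle's
    turn ends it never moves again this step.
    """
    config = state.config
    box = config.box if config.boundary == "periodic" else None
    dt = config.dt
    D = state._D[state.species_idx]
    partners: dict[int, list[tuple[int, float]]] = {}
    for i, j, sig in overlap_pairs:
        partners.setdefault(int(i), []).append((int(j), sig))
        partners.setdefault(int(j), []).append((int(i), sig))
    new_pos = proposals
    done = settled.copy()
    movable = [i for i in partners if not done[i]]
    order = rng.permutation(np.asarray(movable, dtype=np.int64)) if movable else []
    for i in order:
        attempts = 0
        while True:
            bad_j = None
            for j, sig in partners[i]:
                d = np.linalg.norm(_min_image(new_pos[i] - new_pos[j], box))
                if d < sig:
                    bad_j = j
                    break
            if bad_j is None:
                break
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(f"overlap resolution failed for particle index {i}")
            sd_i = math.sqrt(2.0 * D[i] * dt)
            new_pos[i] = state.pos[i] + sd_i * rng.standard_normal(3)
            if not done[bad_j]:
                sd_j = math.sqrt(2.0 * D[bad_j] * dt)
                new_pos[bad_j] = state.pos[bad_j] + sd_j * rng.standard_normal(3)
        done[i] = True
    return new_pos


def step_system(state: SystemState, rng, channels: list[_Channel] | None = None,
                forces=None) -> SystemState:
    """Advance the whole system by one time step (phases 1-4).

    ``forces`` optionally supplies a per-particle drift force field
    (beta F, 1/nm) for the long-range summation strategy.
    """
    config = state.config
    dt = config.dt
    box = config.box if config.boundary == "periodic" else None
    if channels is None:
        channels = _channels(config)
    smap = config.species_map()

    # ---- phase 1: dissociation of bound complexes -------------------------
    no_react: set[int] = set()
    if state.complex_reaction:
        remove = np.zeros(state.n, dtype=bool)
        new_pos, new_sp, new_ids = [], [], []
        id_to_row = {int(pid): k for k, pid in enumerate(state.ids)}
        for cid, ridx in list(state.complex_reaction.items()):
            reac = config.reactions[ridx]
            p_diss = -math.expm1(-reac.k_b * dt)
            if rng.random() >= p_diss:
                continue
            row = id_to_row[cid]
            D_a = smap[reac.a].D
            D_b = smap[reac.b].D
            pa, pb = place_dissociated(state.pos[row], reac.sigma, D_a, D_b, rng)
            if box is not None:
                pa, pb = np.mod(pa, box), np.mod(pb, box)
            ids = state.new_ids(2)
            remove[row] = True
            new_pos.extend([pa, pb])
            name_idx = state._name_to_idx
            new_sp.extend([name_idx[reac.a], name_idx[reac.b]])
            new_ids.extend(ids)
            no_react.update(int(x) for x in ids)
            del state.complex_reaction[cid]
        if new_ids:
            state.remove_and_add(remove, np.asarray(new_pos), new_sp, new_ids)

    # ---- phase 2: pair detection and reweighted probabilities -------------
    ii, jj, cc, rr = find_reactive_pairs(state, channels)
    probs = np.zeros(ii.size)
    new_records: dict[tuple[int, int], list[float]] = {}
    fresh = np.array([
        (int(state.ids[i]) in no_react) or (int(state.ids[j]) in no_react)
        for i, j in zip(ii, jj)], dtype=bool) if ii.size else np.empty(0, bool)
    for m in range(ii.size):
        c = channels[cc[m]]
        r = rr[m]
        key = (min(int(state.ids[ii[m]]), int(state.ids[jj[m]])),
               max(int(state.ids[ii[m]]), int(state.ids[jj[m]])))
        rec = state.pair_records.get(key)
        w = c.entry_w
        if rec is not None and r < c.R_rewgt and rec[0] < c.R_rewgt:
            w = rec[1] * float(_pair_increment(c, r, rec[0], dt, rec[2]))
        if fresh.size and fresh[m]:
            # freshly dissociated pairs skip association this step and carry
            # no record: their next attempt is an unreweighted zone entry
            probs[m] = 0.0
            continue
        rcl = max(r, c.params.sigma)
        if c.gf is not None:
            p = float(c.gf.p_assoc_at(rcl))
        else:
            p = float(p_assoc(dt, rcl, c.params))
        p_eff = w * p
        if p_eff > 1.0:
            warnings.warn("reweighted association probability > 1; clamped")
            p_eff = 1.0
        probs[m] = p_eff
        new_records[key] = [r, w, max(1.0 - p_eff, SURVIVAL_FLOOR)]

    # ---- phase 3: association attempts + moves ----------------------------
    by_particle: dict[int, list[int]] = {}
    for m in range(ii.size):
        by_particle.setdefault(int(ii[m]), []).append(m)
        by_particle.setdefault(int(jj[m]), []).append(m)
    reacted = np.zeros(state.n, dtype=bool)
    decided = np.zeros(ii.size, dtype=bool)  # each pair is tested at most once
    events: list[tuple[int, int, int]] = []  # (pair-row, i, j)
    order = rng.permutation(np.fromiter(by_particle.keys(), np.int64,
                                        count=len(by_particle)))
    for i in order:
        if reacted[i]:
            continue
        rows = [m for m in by_particle[i]
                if not decided[m] and not reacted[ii[m]] and not reacted[jj[m]]]
        if not rows:
            continue
        decided[rows] = True
        pick = resolve_association([probs[m] for m in rows], rng)
        if pick is None:
            continue
        m = rows[pick]
        reacted[ii[m]] = reacted[jj[m]] = True
        events.append((m, int(ii[m]), int(jj[m])))

    # proposed moves for everything that did not react
    D_eff = state._D[state.species_idx].astype(float)
    if state.complex_reaction:
        id_to_row = {int(pid): k for k, pid in enumerate(state.ids)}
        for cid, ridx in state.complex_reaction.items():
            c = channels[ridx]
            D_eff[id_to_row[cid]] = c.D_product
    disp = np.sqrt(2.0 * D_eff * dt)[:, None] * rng.standard_normal((state.n, 3))
    if forces is not None:
        disp += (D_eff * dt)[:, None] * forces
    elif config.longrange_strategy == "entry_weight":
        # drift only from partners inside the reaction zone
        zone_forces = np.zeros((state.n, 3))
        for m in range(ii.size):
            c = channels[cc[m]]
            if c.spec is None:
                continue
            d = _min_image(state.pos[ii[m]] - state.pos[jj[m]], box)
            rm = max(rr[m], 1e-9)
            fvec = c.spec.beta_f(rm) * d / rm
            zone_forces[ii[m]] += fvec
            zone_forces[jj[m]] -= fvec
        disp += (D_eff * dt)[:, None] * zone_forces
    proposals = state.pos + disp
    settled = np.zeros(state.n, dtype=bool)
    frozen = np.zeros(state.n, dtype=bool)
    if config.target_center is not None:
        # the central target never moves
        centre = np.flatnonzero((state.species_idx ==
                                 state._name_to_idx[config.target_center]))
        if centre.size:
            c0 = centre[0]
            proposals[c0] = state.pos[c0]
            settled[c0] = True
            frozen[c0] = True
    if no_react:
        idmask = np.isin(state.ids, np.fromiter(no_react, np.int64, len(no_react)))
        proposals[idmask] = state.pos[idmask]  # dissociation placement IS the move
        settled[idmask] = True

    # ---- phase 4: overlap resolution --------------------------------------
    overlap_pairs = []
    for m in range(ii.size):
        if reacted[ii[m]] or reacted[jj[m]]:
            continue
        overlap_pairs.append((int(ii[m]), int(jj[m]), channels[cc[m]].params.sigma))
    if overlap_pairs:
        proposals = resolve_overlaps(state, proposals, overlap_pairs, settled, rng)
        if frozen.any():
            proposals[frozen] = state.pos[frozen]
    if box is not None:
        proposals = np.mod(proposals, box)
    state.pos = proposals

    # apply association events: remove pairs, add products
    if events:
        remove = np.zeros(state.n, dtype=bool)
        new_pos, new_sp, new_ids = [], [], []
        for m, i, j in events:
            c = channels[cc[m]]
            remove[i] = remove[j] = True
            if c.product_idx is None:
                continue
            pj = state.pos[i] + _min_image(state.pos[j] - state.pos[i], box)
            Da = smap[config.reactions[c.reaction_index].a].D
            Db = smap[config.reactions[c.reaction_index].b].D
            # orient masses correctly: particle i may be either reactant
            if state.species_idx[i] != c.a_idx:
                Da, Db = Db, Da
            pc = place_complex(state.pos[i], pj, Da, Db)
            if box is not None:
                pc = np.mod(pc, box)
            nid = int(state.new_ids(1)[0])
            new_pos.append(pc)
            new_sp.append(c.product_idx)
            new_ids.append(nid)
            state.complex_reaction[nid] = c.reaction_index
        state.remove_and_add(remove, np.asarray(new_pos).reshape(-1, 3),
                             new_sp, new_ids)

    # retain records only for pairs that are both alive and still in a zone
    alive_ids = set(int(x) for x in state.ids)
    state.pair_records = {
        k: v for k, v in new_records.items()
        if k[0] in alive_ids and k[1] in alive_ids
    }
    state.time += dt
    return state


def run_simulation(config: SimConfig, rng=None, record_every: int = 1,
                   forces_fn=None, gf_tables: dict | None = None) -> TimeSeries:
    """Run a full simulation and record species counts versus time.

    ``gf_tables`` maps reaction indices to :class:`~fprsim.potentials.GFTable`
    objects for Coulomb channels.  With ``longrange_strategy="sum"`` the
    drift of every particle sums all pairwise forces (minimum image); with
    ``"entry_weight"`` only in-zone forces act and the zone-entry ratio is
    ``exp(-beta V(R_max))``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = initialize_system(config, rng)
    channels = _channels(config, gf_tables)
    if forces_fn is None and config.longrange_strategy == "sum":
        specs = [c.spec for c in channels if c.spec is not None]
        if specs:
            from .potentials import longrange_force_sum

            spec0 = specs[0]
            box_ = config.box if config.boundary == "periodic" else None

            def forces_fn(st, _spec=spec0, _box=box_):
                return longrange_force_sum(st.pos, _spec, _box)
    n_steps = int(round(config.T_max / config.dt))
    names = [s.name for s in config.species]
    rec_t = [0.0]
    rec = {n: [c] for n, c in zip(names, [state.counts()[n] for n in names])}
    for k in range(n_steps):
        forces = forces_fn(state) if forces_fn is not None else None
        state = step_system(state, rng, channels, forces=forces)
        if (k + 1) % record_every == 0:
            cts = state.counts()
            rec_t.append(state.time)
            for n in names:
                rec[n].append(cts[n])
    meta = {"seed": config.seed, "dt": config.dt, "box": config.box,
            "boundary": config.boundary}
    return TimeSeries(np.asarray(rec_t), {k: np.asarray(v, float) for k, v in rec.items()},
                      meta)


# ---------------------------------------------------------------------------
# Target-problem engines (one central particle, non-interacting partners)
# ---------------------------------------------------------------------------


def _reflecting_moves(x, sigma, sd, rng, max_rounds=10_000):
    """Gaussian moves of bath particles, redrawn while overlapping the target.

    ``sd`` may be a scalar or any array broadcastable to ``x.shape``.
    """
    sd_arr = np.broadcast_to(np.asarray(sd, dtype=float), x.shape)
    flat_x = x.reshape(-1, 3)
    flat_sd = sd_arr.reshape(-1, 3)
    flat_new = flat_x + flat_sd * rng.standard_normal(flat_x.shape)
    bad = np.einsum("ij,ij->i", flat_new, flat_new) < sigma * sigma
    rounds = 0
    while bad.any():
        rounds += 1
        if rounds > max_rounds:
            raise RuntimeError("target overlap rejection failed to terminate")
        idx = np.flatnonzero(bad)
        flat_new[idx] = flat_x[idx] + flat_sd[idx] * rng.standard_normal((idx.size, 3))
        bad[idx] = np.einsum("ij,ij->i", flat_new[idx], flat_new[idx]) < sigma * sigma
    return flat_new.reshape(x.shape)


def simulate_target_fpr_survival(params: PairParams, dt: float, n_B: int,
                                 R_out: float, n_steps: int, n_replicas: int,
                                 rng) -> np.ndarray:
    """Irreversible target survival by FPR in an open domain.

    Matches the geometry of
    :func:`fprsim.reference_theory.simulate_target_exact`: partners start
    uniformly in the shell ``[sigma, R_out]`` around a static absorberless
    target and diffuse freely (no outer boundary).  Returns the unbound
    fraction of targets after each step.
    """
    sig = params.sigma
    R_max = reaction_zone_radius(sig, params.D_tot, dt)
    u = rng.random((n_replicas, n_B))
    radii = (sig**3 + u * (R_out**3 - sig**3)) ** (1.0 / 3.0)
    dirs = rng.standard_normal((n_replicas, n_B, 3))
    dirs /= np.linalg.norm(dirs, axis=2, keepdims=True)
    x = radii[..., None] * dirs
    w = np.ones((n_replicas, n_B))
    s_prev = np.ones((n_replicas, n_B))
    r_prev = radii.copy()
    in_zone = np.zeros((n_replicas, n_B), dtype=bool)
    alive = np.ones(n_replicas, dtype=bool)
    sd = math.sqrt(2.0 * params.D_tot * dt)
    surv = np.empty(n_steps)
    for k in range(n_steps):
        idx = np.flatnonzero(alive)
        if idx.size:
            r = np.linalg.norm(x[idx], axis=2)
            np.maximum(r, sig, out=r)
            inz = r < R_max
            entering = inz & ~in_zone[idx]
            staying = inz & in_zone[idx]
            wv = w[idx]
            wv[entering] = 1.0
            wv[~inz] = 1.0
            if staying.any():
                rows = np.where(staying)
                wv[rows] *= reweight_increment(r[rows], r_prev[idx][rows],
                                               params, dt, s_prev[idx][rows])
            p_eff = np.zeros_like(r)
            if inz.any():
                rows = np.where(inz)
                p_eff[rows] = np.clip(wv[rows] * p_assoc(dt, r[rows], params), 0, 1)
            hit = (p_eff > rng.random(r.shape)).any(axis=1)
            w[idx] = wv
            s_prev[idx] = np.maximum(1.0 - p_eff, SURVIVAL_FLOOR)
            r_prev[idx] = r
            in_zone[idx] = inz
            alive[idx[hit]] = False
            live = idx[~hit]
            x[live] = _reflecting_moves(x[live], sig, sd, rng)
        surv[k] = alive.mean()
    return surv


@dataclass
class TargetEquilibriumResult:
    p_bound: float
    stderr: float
    n_cycles: int
    p_theory: float
    bound_time: float
    unbound_time: float


class TargetEquilibriumEstimator:
    """Equilibrium bound fraction of a reversible target by renewal sampling.

    One static target (D_A = 0) sits at the center of a periodic box of
    volume ``V`` with ``n_B`` non-interacting partners (concentration
    ``B0 = n_B / V``).  The unbound dynamics is plain FPR.  Two exact
    accelerations make the slow-dissociation parameter regimes reachable:

    * bound intervals are collapsed: the per-step Bernoulli dissociation test
      is equivalent to a geometric step count, which is sampled directly;
      the untouched bath partners are then redrawn from their uniform
      stationary distribution (valid when the bound interval greatly exceeds
      the box mixing time ``L^2/6D`` — violations are counted and warned
      about), while the released partner is placed at contact;
    * while every partner is farther than ``R_max`` from the target, free
      diffusion is fast-forwarded with a single aggregated Gaussian step
      whose horizon keeps the zone-crossing probability below ~1e-11
      (4 rms displacements short of the zone).

    The bound fraction is the renewal (ratio) estimator over completed
    cycles, where a cycle is one sampled bound interval followed by the
    unbound period ending at the next association.  Each replica contributes
    a fixed number of completed cycles — a count-based stopping rule, so long
    unbound searches are never truncated by a time window (a fixed-time
    window would under-sample them and bias the bound fraction upward).  The
    stretch before each replica's first association is discarded; because
    the bath is resampled during every bound interval, the cycles that
    follow are already stationary.  Standard errors come from a jackknife
    over replicas.
    """

    def __init__(self, params: PairParams, dt: float, n_B: int, box: float,
                 *, accelerate: bool = True):
        if params.k_b <= 0:
            raise ValueError("equilibrium estimation requires k_b > 0")
        self.params = params
        self.dt = float(dt)
        self.n_B = int(n_B)
        self.box = float(box)
        self.accelerate = accelerate
        self.R_max = reaction_zone_radius(params.sigma, params.D_tot, dt)
        if box <= 2.0 * self.R_max:
            raise ValueError("box edge must exceed twice R_max")
        self.mixing_time = box**2 / (6.0 * params.D_tot)
        self.short_bound_intervals = 0

    def run(self, n_cycles: int, n_replicas: int, rng,
            max_steps: int = 5_000_000) -> TargetEquilibriumResult:
        par = self.params
        sig, dt, L = par.sigma, self.dt, self.box
        half = L / 2.0
        p_diss = -math.expm1(-par.k_b * dt)
        skip_unit = 4.0 * math.sqrt(6.0 * par.D_tot * dt)
        R = n_replicas
        NB = self.n_B
        x = rng.random((R, NB, 3)) * L - half  # target at origin, centered box
        r = np.linalg.norm(x, axis=2)
        redo = r < sig
        while redo.any():
            k = int(redo.sum())
            x[redo] = rng.random((k, 3)) * L - half
            r[redo] = np.linalg.norm(x[redo], axis=1)
            redo = r < sig
        w = np.ones((R, NB))
        s_prev = np.ones((R, NB))
        r_prev = np.full((R, NB), np.inf)
        in_zone = np.zeros((R, NB), dtype=bool)
        bound_t = np.zeros(R)
        unbound_committed = np.zeros(R)
        pending_unbound = np.zeros(R)
        pending_bound = np.zeros(R)  # sampled bound interval awaiting its cycle
        cycles = np.zeros(R, dtype=np.int64)
        had_first = np.zeros(R, dtype=bool)
        done = np.zeros(R, dtype=bool)

        for _ in range(max_steps):
            if done.all():
                break
            # minimum image & radii
            x -= L * np.round(x / L)
            r = np.linalg.norm(x, axis=2)
            np.maximum(r, sig, out=r)
            r[done] = np.inf  # finished replicas are inert
            d_min = r.min(axis=1)
            far = d_min > self.R_max + skip_unit
            m_steps = np.ones(R)
            if self.accelerate and far.any():
                m_steps[far] = np.floor(((d_min[far] - self.R_max) / skip_unit) ** 2)
                np.maximum(m_steps, 1.0, out=m_steps)
            m_steps[done] = 1.0
            pending_unbound += np.where(done, 0.0, m_steps * dt)

            inz = r < self.R_max
            assoc_row = np.full(R, -1, dtype=np.int64)
            act = np.flatnonzero(inz.any(axis=1))
            if act.size:
                entering = inz & ~in_zone
                staying = inz & in_zone
                w[entering] = 1.0
                w[~inz] = 1.0
                rows = np.where(staying)
                if rows[0].size:
                    w[rows] *= reweight_increment(r[rows], r_prev[rows], par,
                                                  dt, s_prev[rows])
                p_eff = np.zeros((R, NB))
                zr = np.where(inz)
                p_eff[zr] = np.clip(w[zr] * p_assoc(dt, r[zr], par), 0.0, 1.0)
                tot = p_eff.sum(axis=1)
                over = tot > 1.0
                if over.any():
                    warnings.warn("summed target association probability > 1; clamped")
                u = rng.random(R) * np.maximum(tot, 1.0)
                hit = u < tot
                if hit.any():
                    cum = np.cumsum(p_eff[hit], axis=1)
                    assoc_row[hit] = np.argmax(cum > u[hit, None], axis=1)
                s_prev = np.maximum(1.0 - p_eff, SURVIVAL_FLOOR)
            else:
                s_prev.fill(1.0)
            r_prev = r
            in_zone = inz

            hitmask = assoc_row >= 0
            if hitmask.any():
                idx = np.flatnonzero(hitmask)
                # a completed cycle = previous bound interval + the unbound
                # period that just ended
                for i in idx:
                    if had_first[i]:
                        unbound_committed[i] += pending_unbound[i]
                        bound_t[i] += pending_bound[i]
                        cycles[i] += 1
                        if cycles[i] >= n_cycles:
                            done[i] = True
                    had_first[i] = True
                    pending_unbound[i] = 0.0
                # bound interval: geometric step count
                g = rng.geometric(p_diss, size=idx.size).astype(float)
                tb = g * dt
                pending_bound[idx] = tb
                short = tb < 5.0 * self.mixing_time
                self.short_bound_intervals += int(short.sum())
                # bath resampled from its stationary distribution
                x[idx] = rng.random((idx.size, NB, 3)) * L - half
                rr = np.linalg.norm(x[idx], axis=2)
                bad = rr < sig
                while bad.any():
                    rows = np.where(bad)
                    x[idx[rows[0]], rows[1]] = rng.random((rows[0].size, 3)) * L - half
                    rr2 = np.linalg.norm(x[idx[rows[0]], rows[1]], axis=1)
                    bad[rows] = rr2 < sig
                # released partner at contact
                dirs = rng.standard_normal((idx.size, 3))
                dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
                x[idx, assoc_row[idx]] = sig * dirs
                w[idx] = 1.0
                s_prev[idx] = 1.0
                in_zone[idx] = False
                r_prev[idx] = np.inf

            # --- moves -------------------------------------------------------
            sd = np.sqrt(2.0 * par.D_tot * dt * m_steps)  # per replica
            live = ~hitmask & ~done
            if live.any():
                li = np.flatnonzero(live)
                x[li] = _reflecting_moves(x[li], sig, sd[li][:, None, None], rng)

        if not done.all():
            warnings.warn(
                f"{int((~done).sum())} of {R} replicas did not complete "
                f"{n_cycles} cycles within max_steps; their finished cycles "
                "still contribute")
        tot_b = bound_t.sum()
        tot_u = unbound_committed.sum()
        n_cyc = int(cycles.sum())
        if tot_b + tot_u <= 0 or n_cyc == 0:
            raise RuntimeError("no completed binding cycles; increase max_steps")
        p_hat = tot_b / (tot_b + tot_u)
        # jackknife over replicas
        jk = []
        for i in range(R):
            b = tot_b - bound_t[i]
            uu = tot_u - unbound_committed[i]
            if b + uu > 0:
                jk.append(b / (b + uu))
        jk = np.asarray(jk)
        se = math.sqrt(max(len(jk) - 1, 1) / max(len(jk), 1)) * math.sqrt(
            np.sum((jk - jk.mean()) ** 2))
        from .reference_theory import RateSet, equilibrium_pbound

        rs = RateSet.from_pair(par)
        p_th = equilibrium_pbound(rs.K_eq, NB / L**3)
        return TargetEquilibriumResult(p_hat, se, n_cyc, p_th, tot_b, tot_u)
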