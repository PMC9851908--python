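"""1D loop-extrusion dynamics with CTCF capture/release on a monomer lattice.

Loop-extruding factors (LEFs) occupy pairs of monomers (1 monomer = 1 kb).
Each 1D step every free upstream leg moves i -> i-1 with probability 1/2
and every free downstream leg j -> j+1 with probability 1/2, unless the
target monomer is occupied by another leg or lies in a blocked region.
A leg arriving at a CTCF site with blocking orientation is captured with
probability min((fc - 1)/fc_med, 1) and is immobile until released
(probability 0.006 per step). Each LEF unloads with probability 1/100 per
step and immediately reloads at a uniformly random unoccupied position,
so the LEF count stays at floor(n_monomers / mean_separation).

Orientation semantics (convergent rule): a '+' site captures upstream
(leftward-moving) legs, a '-' site captures downstream (rightward-moving)
legs; an orientation-agnostic mode captures both.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BinTable, ContactMatrix

__all__ = ["Lattice", "SimParams", "Trajectory", "simulate",
           "contact_map_from_trajectory", "barrier_traversal_assay",
           "mean_loop_size"]

MONOMER_BP = 1000


@dataclass
class Lattice:
    """1D lattice with oriented CTCF sites and optional blocked regions."""

    n_monomers: int
    ctcf_pos: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    ctcf_strand: np.ndarray = field(default_factory=lambda: np.array([], dtype="U1"))
    ctcf_capture: np.ndarray = field(default_factory=lambda: np.array([]))
    blocked_regions: list = field(default_factory=list)   # [(start, end)) half-open

    def __post_init__(self):
        self.ctcf_pos = np.asarray(self.ctcf_pos, dtype=int)
        self.ctcf_capture = np.asarray(self.ctcf_capture, dtype=float)
        if len(self.ctcf_capture) and (np.any(self.ctcf_capture < 0)
                                       or np.any(self.ctcf_capture > 1)):
            raise ValueError("capture probabilities must lie in [0, 1]")
        if len(self.ctcf_pos) and (self.ctcf_pos.min() < 0
                                   or self.ctcf_pos.max() >= self.n_monomers):
            raise ValueError("CTCF positions outside lattice")

    @classmethod
    def from_fold_changes(cls, n_monomers, positions, strands, fold_changes,
                          blocked_regions=None) -> "Lattice":
        """Capture probability per site: min((fc - 1)/fc_med, 1)."""
        fc = np.asarray(fold_changes, dtype=float)
        if np.any(fc <= 0):
            raise ValueError("fold changes must be positive")
        fc_med = np.median(fc)
        p = np.minimum((fc - 1.0) / fc_med, 1.0)
        p = np.clip(p, 0.0, 1.0)
        return cls(n_monomers, np.asarray(positions, dtype=int),
                   np.asarray(strands, dtype="U1"), p,
                   blocked_regions=list(blocked_regions or []))

    def blocked_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_monomers, dtype=bool)
        for s, e in self.blocked_regions:
            mask[s:e] = True
        return mask


@dataclass
class SimParams:
    """1D dynamics parameters (probabilities per 1D step)."""

    step_prob: float = 0.5
    release_prob: float = 0.006
    unload_prob: float = 0.01
    mean_separation: int = 600
    n_steps: int = 100_000
    orientation_agnostic: bool = False
    md_steps_per_1d: int = 400      # metadata only; no 3D layer here

    def __post_init__(self):
        for p in (self.step_prob, self.release_prob, self.unload_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class Trajectory:
    """Sampled LEF system states plus capture-episode statistics."""

    lattice: Lattice
    params: SimParams
    sample_steps: np.ndarray        # (S,)
    positions: np.ndarray           # (S, N, 2) legs [upstream, downstream]
    captured: np.ndarray            # (S, N, 2) bool
    load_positions: np.ndarray      # (S, N) loading site of the current LEF
    dwell_times: np.ndarray         # completed (release-ended) capture dwells
    n_dwell_censored: int           # capture episodes ended by unload/run end

    @property
    def n_samples(self) -> int:
        return len(self.sample_steps)


def _place_lef(rng, occupied, blocked, n):
    for _ in range(10000):
        p = int(rng.integers(0, n - 1))
        if not (occupied[p] or occupied[p + 1] or blocked[p] or blocked[p + 1]):
            return p
    raise RuntimeError("lattice too small to place LEFs")


def simulate(lattice: Lattice, params: SimParams, seed: int = 0,
             sample_every: int = 100) -> Trajectory:
    """Run the 1D LEF dynamics and sample the system state periodically."""
    rng = np.random.default_rng(seed)
    n = lattice.n_monomers
    n_lefs = n // params.mean_separation
    if n_lefs < 1:
        raise ValueError("lattice too small for one LEF at this mean separation")
    blocked = lattice.blocked_mask()
    # per-monomer CTCF capture probability by leg direction
    cap_up = np.zeros(n)      # captures upstream (left-moving) legs
    cap_down = np.zeros(n)
    for pos, strand, p in zip(lattice.ctcf_pos, lattice.ctcf_strand,
                              lattice.ctcf_capture):
        if params.orientation_agnostic or strand == "+":
            cap_up[pos] = max(cap_up[pos], p)
        if params.orientation_agnostic or strand == "-":
            cap_down[pos] = max(cap_down[pos], p)

    occupied = np.zeros(n, dtype=bool)
    pos = np.zeros((n_lefs, 2), dtype=np.int64)
    cap = np.zeros((n_lefs, 2), dtype=bool)
    load_pos = np.zeros(n_lefs, dtype=np.int64)
    cap_start = np.full((n_lefs, 2), -1, dtype=np.int64)
    for l in range(n_lefs):
        p = _place_lef(rng, occupied, blocked, n)
        pos[l] = (p, p + 1)
        occupied[p] = occupied[p + 1] = True
        load_pos[l] = p

    dwells = []
    censored = 0
    samples_pos, samples_cap, samples_load, sample_steps = [], [], [], []
    deltas = np.array([-1, 1])
    for step in range(params.n_steps):
        # release captured legs
        if cap.any():
            rel = cap & (rng.random((n_lefs, 2)) < params.release_prob)
            if rel.any():
                for l, s in zip(*np.nonzero(rel)):
                    dwells.append(step - cap_start[l, s])
                    cap_start[l, s] = -1
                cap[rel] = False
        # propose moves for free legs
        want = (~cap) & (rng.random((n_lefs, 2)) < params.step_prob)
        if want.any():
            wl, ws = np.nonzero(want)
            order = rng.permutation(len(wl))
            for idx in order:
                l, s = wl[idx], ws[idx]
                t = pos[l, s] + deltas[s]
                if t < 0 or t >= n or occupied[t] or blocked[t]:
                    continue
                occupied[pos[l, s]] = False
                pos[l, s] = t
                occupied[t] = True
                p_cap = cap_up[t] if s == 0 else cap_down[t]
                if p_cap > 0 and rng.random() < p_cap:
                    cap[l, s] = True
                    cap_start[l, s] = step
        # unload and immediately reload
        unload = rng.random(n_lefs) < params.unload_prob
        for l in np.nonzero(unload)[0]:
            for s in (0, 1):
                if cap[l, s]:
                    censored += 1
                    cap_start[l, s] = -1
            occupied[pos[l, 0]] = occupied[pos[l, 1]] = False
            cap[l] = False
            p = _place_lef(rng, occupied, blocked, n)
            pos[l] = (p, p + 1)
            occupied[p] = occupied[p + 1] = True
            load_pos[l] = p
        if (step + 1) % sample_every == 0:
            sample_steps.append(step + 1)
            samples_pos.append(pos.copy())
            samples_cap.append(cap.copy())
            samples_load.append(load_pos.copy())
    censored += int((cap_start >= 0).sum())
    return Trajectory(lattice, params, np.array(sample_steps),
                      np.array(samples_pos), np.array(samples_cap),
                      np.array(samples_load),
                      np.array(dwells, dtype=float), censored)


def mean_loop_size(traj: Trajectory, burn_in: int = 0) -> float:
    """Time-averaged loop size j - i over samples after ``burn_in`` steps."""
    keep = traj.sample_steps > burn_in
    sizes = traj.positions[keep, :, 1] - traj.positions[keep, :, 0]
    return float(sizes.mean())


def contact_map_from_trajectory(traj: Trajectory, resolution: int = 10,
                                background_weight: float = 1.0,
                                decay_exponent: float = 1.0) -> ContactMatrix:
    """Loop-base contact counts on a power-law background, binned.

    Each sampled LEF adds one contact at its (i, j) leg pair; a smooth
    s^(-decay_exponent) background carrying ``background_weight`` times the
    loop contact mass stands in for the out-of-scope 3D polymer readout.
    """
    if traj.n_samples and traj.n_samples < 100:
        raise ValueError("need >= 100 sampled states (or an empty trajectory)")
    n = traj.lattice.n_monomers
    nb = int(np.ceil(n / resolution))
    bins = BinTable.from_chromsizes({"sim": n * MONOMER_BP},
                                    resolution * MONOMER_BP)
    counts = np.zeros((nb, nb))
    if traj.n_samples:
        bi = traj.positions[:, :, 0].ravel() // resolution
        bj = traj.positions[:, :, 1].ravel() // resolution
        np.add.at(counts, (bi, bj), 1.0)
        np.add.at(counts, (bj, bi), 1.0)
    sep = np.abs(np.arange(nb)[:, None] - np.arange(nb)[None, :])
    background = 1.0 / (sep + 1.0) ** decay_exponent
    np.fill_diagonal(background, 0.0)
    loop_mass = counts.sum()
    if loop_mass > 0:
        background *= background_weight * loop_mass / background.sum()
    values = counts + background
    np.fill_diagonal(values, 0.0)
    return ContactMatrix(bins, values)


@dataclass
class TraversalStats:
    """Outcome of the heterochromatin-interval traversal assay."""

    traversal_fraction: float        # LEF loads outside whose leg entered
    n_loads_outside: int
    boundary_spanning_fraction: float  # sampled loops with one leg inside


def barrier_traversal_assay(n_monomers: int, interval: tuple[int, int],
                            params: SimParams, seed: int = 0,
                            blocked: bool = False,
                            ctcf_sites: tuple = (), sample_every: int = 50):
    """Fraction of outside-loaded LEF legs that cross a heterochromatic
    interval, for an open or LEF-impermeable (blocked) variant.

    Returns (TraversalStats, Trajectory).
    """
    lo, hi = interval
    positions = [p for p, _, _ in ctcf_sites]
    strands = [s for _, s, _ in ctcf_sites]
    fcs = [f for _, _, f in ctcf_sites]
    if positions:
        lattice = Lattice.from_fold_changes(
            n_monomers, positions, strands, fcs,
            blocked_regions=[interval] if blocked else None)
    else:
        lattice = Lattice(n_monomers,
                          blocked_regions=[interval] if blocked else [])
    traj = simulate(lattice, params, seed=seed, sample_every=sample_every)
    inside = (traj.positions >= lo) & (traj.positions < hi)        # (S, N, 2)
    load_outside = (traj.load_positions < lo) | (traj.load_positions >= hi)
    entered = inside.any(axis=2) & load_outside                     # (S, N)
    # loading episodes = maximal sample runs with an unchanged load position
    n_out = 0
    n_entered = 0
    S, N = traj.load_positions.shape
    for l in range(N):
        lp = traj.load_positions[:, l]
        starts = np.flatnonzero(np.r_[True, lp[1:] != lp[:-1]])
        ends = np.r_[starts[1:], S]
        for a, b in zip(starts, ends):
            if load_outside[a, l]:
                n_out += 1
                if entered[a:b, l].any():
                    n_entered += 1
    spanning = (inside.sum(axis=2) == 1).mean() if traj.n_samples else 0.0
    frac = n_entered / n_out if n_out else float("nan")
    return TraversalStats(frac, n_out, float(spanning)), traj
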