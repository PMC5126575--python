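"""On-the-fly coarse-grained Brownian dynamics of field-driven chain formation.

Particles and the chains they merge into are both represented by a single
kind of coarse-grained (CG) object: a rigid segment of ``s`` particles
pinned to the field (z) axis, diffusing with slender-body anisotropic
diffusion coefficients. At every step each object takes an independent
Gaussian displacement (variance 2·D·Δt per axis, D_par along z and D_perp
laterally for chains); afterwards every pair of objects is checked against
the polar attraction zones of radius r_a(s) — any pair whose nearest tips
approach closer than the zone radius of the longer partner aggregates
instantly into one object whose length is the sum of the two and whose
position is the length-weighted centre of mass. The object count therefore
shrinks as aggregation proceeds ("on the fly" coarse-graining), and the
mean chain length ⟨s⟩ = N / (number of objects) only ever grows.

Zero-field runs, and weak-coupling particles with Γ ≤ 1, never merge:
they reduce to hard-core Brownian motion of singletons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.constants import Boltzmann as K_B

from .errors import ConfigError
from .magnetics import (
    EnvironmentSpec,
    ParticleSpec,
    attraction_radius,
    coupling_parameter,
)

__all__ = [
    "CoarseObject",
    "SimulationConfig",
    "SimulationState",
    "ChainStatistics",
    "Snapshot",
    "Trajectory",
    "RunResult",
    "diffusion_coefficients",
    "effective_time_step",
    "init_configuration",
    "brownian_step",
    "detect_and_merge",
    "run_simulation",
    "concentration_to_count",
    "compute_statistics",
    "write_xyz",
]

# Slender-body end-correction constants for a rigid rod of aspect ratio s
# (axial and transverse); their difference fixes D_par/D_perp -> 2 as s -> inf.
GAMMA_PAR = -0.207
GAMMA_PERP = 0.839

# Fraction of a diameter the RMS singleton step may not exceed (zone resolution).
MAX_RMS_STEP_D0 = 0.1

_OVERLAP_TOL = 1.0 - 1e-9


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoarseObject:
    """A diffusing simulation entity: a single particle or a chain of ``s``.

    The chain axis is pinned to the field (z) axis; the physical extent
    along z is ``s·d0`` and the tip-particle centres sit at
    ``z ± (s−1)·d0/2``.
    """

    length: int
    position_m: tuple[float, float, float]
    object_id: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ConfigError("chain length must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Box geometry, particle count and stepping parameters.

    ``box_d0_units`` is the cubic box side in particle diameters (the
    standard setup is 80·d0). ``dt_s = None`` lets the simulator pick the
    largest stable step; an explicit dt is clamped so the RMS singleton
    step stays below 0.1·d0 (no tunnelling through attraction zones).
    """

    n_particles: int = 380
    box_d0_units: float = 80.0
    total_time_s: float = 5e-3
    dt_s: float | None = None
    snapshot_interval_s: float | None = None
    field_on: bool = True
    boundary: str = "periodic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ConfigError("n_particles must be >= 1")
        if self.box_d0_units <= 0:
            raise ConfigError("box side must be positive")
        if self.total_time_s < 0:
            raise ConfigError("total_time_s must be nonnegative")
        if self.dt_s is not None and self.dt_s <= 0:
            raise ConfigError("dt_s must be positive")
        if self.boundary not in ("periodic", "reflecting"):
            raise ConfigError("boundary must be 'periodic' or 'reflecting'")

    def box_m(self, p: ParticleSpec) -> float:
        return self.box_d0_units * p.diameter_m


@dataclass
class SimulationState:
    """Mutable state of a run: object arrays, elapsed time, RNG, merge count.

    Arrays are kept in stable-id order (insertion order); merged objects
    receive fresh ids appended at the end, so the order in which random
    draws are consumed is deterministic.
    """

    t_s: float
    lengths: np.ndarray          # (M,) int
    positions_m: np.ndarray      # (M, 3) float, wrapped into the box
    unwrapped_m: np.ndarray      # (M, 3) float, cumulative true displacement
    ids: np.ndarray              # (M,) int
    rng: np.random.Generator
    box_m: float
    n_merges: int = 0
    next_id: int = 0

    @property
    def n_objects(self) -> int:
        return len(self.lengths)

    @property
    def total_particles(self) -> int:
        return int(self.lengths.sum())

    @property
    def mean_length(self) -> float:
        return self.total_particles / self.n_objects

    def objects(self) -> Iterator[CoarseObject]:
        for s, pos, oid in zip(self.lengths, self.positions_m, self.ids):
            yield CoarseObject(int(s), tuple(pos), int(oid))


@dataclass(frozen=True)
class Snapshot:
    """Frozen view of the object list at one instant."""

    t_s: float
    lengths: np.ndarray
    positions_m: np.ndarray
    ids: np.ndarray


@dataclass(frozen=True)
class Trajectory:
    """Sequence of snapshots plus the geometry needed to interpret them."""

    snapshots: tuple[Snapshot, ...]
    box_m: float
    diameter_m: float
    boundary: str = "periodic"

    def __len__(self) -> int:
        return len(self.snapshots)


@dataclass(frozen=True)
class ChainStatistics:
    """Per-snapshot chain statistics and the final length distribution.

    ``mean_spacing_m`` is the mean nearest-neighbour lateral (x–y)
    distance between chains (objects with s ≥ 2); NaN where fewer than
    two chains exist. ``order_parameter`` is ⟨cos²θ⟩ of inter-particle
    bonds against the field axis (identically 1 in this axis-pinned
    model whenever chains exist, NaN for all-singleton snapshots).
    """

    time_s: np.ndarray
    mean_length: np.ndarray
    n_objects: np.ndarray
    mean_spacing_m: np.ndarray
    order_parameter: np.ndarray
    final_length_counts: np.ndarray   # index i = count of chains of length i+1
    n_total: int

    @property
    def final_mean_length(self) -> float:
        return float(self.mean_length[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_s": self.time_s,
                "mean_length": self.mean_length,
                "n_objects": self.n_objects,
                "order_parameter": self.order_parameter,
                "mean_spacing_m": self.mean_spacing_m,
            }
        )


@dataclass(frozen=True)
class RunResult:
    final_state: SimulationState
    statistics: ChainStatistics
    trajectory: Trajectory


# ---------------------------------------------------------------------------
# Diffusion
# ---------------------------------------------------------------------------

def diffusion_coefficients(
    s: int, p: ParticleSpec, env: EnvironmentSpec
) -> tuple[float, float]:
    """Axial and transverse diffusion coefficients of a chain of ``s`` particles.

    A singleton obeys Stokes–Einstein, D = kB·T/(3π η d0), isotropically.
    A chain of s ≥ 2 is a rigid rod of length s·d0 and width d0 with
    slender-body coefficients

        D_par  = kB·T (ln s − 0.207) / (2π η s d0),
        D_perp = kB·T (ln s + 0.839) / (4π η s d0),

    whose ratio tends to the free-draining rod limit D_par/D_perp → 2.

    Returns
    -------
    (D_par, D_perp) : tuple of float, m²/s
    """
    if s < 1:
        raise ValueError("chain length must be >= 1")
    kt = K_B * env.temperature_K
    eta, d0 = env.viscosity_PaS, p.diameter_m
    if s == 1:
        d = kt / (3.0 * np.pi * eta * d0)
        return d, d
    d_par = kt * (np.log(s) + GAMMA_PAR) / (2.0 * np.pi * eta * s * d0)
    d_perp = kt * (np.log(s) + GAMMA_PERP) / (4.0 * np.pi * eta * s * d0)
    return d_par, d_perp


def effective_time_step(cfg: SimulationConfig, p: ParticleSpec, env: EnvironmentSpec) -> float:
    """Time step after the RMS-step clamp √(2 D₁ Δt) ≤ 0.1·d0."""
    d1, _ = diffusion_coefficients(1, p, env)
    dt_max = (MAX_RMS_STEP_D0 * p.diameter_m) ** 2 / (2.0 * d1)
    if cfg.dt_s is None:
        return dt_max
    return min(cfg.dt_s, dt_max)


def _step_sigmas(lengths: np.ndarray, p: ParticleSpec, env: EnvironmentSpec, dt: float) -> np.ndarray:
    """Per-object, per-axis Gaussian step widths √(2 D Δt), shape (M, 3)."""
    sig = np.empty((len(lengths), 3))
    for s in np.unique(lengths):
        d_par, d_perp = diffusion_coefficients(int(s), p, env)
        mask = lengths == s
        sig[mask, 0] = sig[mask, 1] = np.sqrt(2.0 * d_perp * dt)
        sig[mask, 2] = np.sqrt(2.0 * d_par * dt)
    return sig


# ---------------------------------------------------------------------------
# Geometry helpers (vectorized over all pairs)
# ---------------------------------------------------------------------------

def _deltas(pos: np.ndarray, box: float, periodic: bool) -> np.ndarray:
    d = pos[np.newaxis, :, :] - pos[:, np.newaxis, :]
    if periodic:
        d -= box * np.round(d / box)
    return d


def _core_distance(pos, lengths, d0, box, periodic):
    """Closest particle-centre distance between segment pairs (M, M)."""
    d = _deltas(pos, box, periodic)
    dxy = np.hypot(d[..., 0], d[..., 1])
    half = (lengths - 1) * d0 / 2.0
    gap_z = np.abs(d[..., 2]) - (half[:, np.newaxis] + half[np.newaxis, :])
    np.maximum(gap_z, 0.0, out=gap_z)
    return np.hypot(dxy, gap_z)


def _tip_distance(pos, lengths, d0, box, periodic):
    """Nearest tip-to-tip distance between segment pairs (M, M)."""
    d = _deltas(pos, box, periodic)
    dxy = np.hypot(d[..., 0], d[..., 1])
    half = (lengths - 1) * d0 / 2.0
    hi = half[:, np.newaxis]
    hj = half[np.newaxis, :]
    dz = d[..., 2]
    best = np.abs(dz + hj - hi)
    for combo in (dz + hj + hi, dz - hj - hi, dz - hj + hi):
        np.minimum(best, np.abs(combo), out=best)
    return np.hypot(dxy, best)


def _zone_radii(lengths: np.ndarray, p: ParticleSpec, env: EnvironmentSpec) -> np.ndarray:
    """r_a(max(s_i, s_j)) for every pair, shape (M, M)."""
    smax = int(lengths.max())
    table = np.array([attraction_radius(s, p, env) for s in range(1, smax + 1)])
    return table[np.maximum.outer(lengths, lengths) - 1]


def _apply_boundary(pos: np.ndarray, box: float, boundary: str) -> np.ndarray:
    if boundary == "periodic":
        return np.mod(pos, box)
    # reflecting: fold into [0, box]
    folded = np.mod(pos, 2.0 * box)
    return box - np.abs(folded - box)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def concentration_to_count(
    concentration_kgm3: float, cfg: SimulationConfig, p: ParticleSpec
) -> int:
    """Particle count implied by a mass concentration in the configured box.

    N = round(c L³ / (ρ_p V0)). Reproduction runs typically override N
    directly with the published 380/760/1520 counts instead.
    """
    if concentration_kgm3 <= 0:
        raise ValueError("concentration must be positive")
    box = cfg.box_m(p)
    return int(round(concentration_kgm3 * box**3 / (p.mass_density_kgm3 * p.volume_m3)))


def init_configuration(
    cfg: SimulationConfig,
    p: ParticleSpec,
    env: EnvironmentSpec,
    rng: np.random.Generator | None = None,
) -> SimulationState:
    """Place N non-overlapping singletons uniformly at random in the box.

    Deterministic under a fixed seed (random sequential addition with a
    minimum pairwise distance of one diameter). Refuses packing
    fractions above 0.3, where sequential addition stalls and the
    dilute-regime model is invalid anyway.
    """
    n, d0 = cfg.n_particles, p.diameter_m
    box = cfg.box_m(p)
    packing = n * p.volume_m3 / box**3
    if packing > 0.3:
        raise ConfigError(
            f"packing fraction {packing:.3f} > 0.3: dense regime unsupported"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    periodic = cfg.boundary == "periodic"
    pos = np.empty((n, 3))
    placed = 0
    max_attempts = 2000 * n + 10000
    for _ in range(max_attempts):
        if placed == n:
            break
        cand = rng.uniform(0.0, box, size=3)
        if placed:
            d = pos[:placed] - cand
            if periodic:
                d -= box * np.round(d / box)
            if np.min(np.einsum("ij,ij->i", d, d)) < d0**2:
                continue
        pos[placed] = cand
        placed += 1
    if placed < n:
        raise ConfigError("could not place particles without overlap")
    return SimulationState(
        t_s=0.0,
        lengths=np.ones(n, dtype=np.int64),
        positions_m=pos,
        unwrapped_m=pos.copy(),
        ids=np.arange(n, dtype=np.int64),
        rng=rng,
        box_m=box,
        n_merges=0,
        next_id=n,
    )


def brownian_step(
    state: SimulationState,
    cfg: SimulationConfig,
    p: ParticleSpec,
    env: EnvironmentSpec,
    dt_s: float | None = None,
) -> SimulationState:
    """Advance every object by one Gaussian diffusive step (in place).

    Each object draws independent per-axis increments of variance
    2·D·Δt, anisotropically for chains (D_par along z). A move that
    would create a hard-core overlap between a pair of objects that do
    NOT satisfy the attraction-zone test is rejected for the later-id
    member of the pair this step; zone-satisfying contacts are left to
    :func:`detect_and_merge`. The boundary rule (periodic wrap or
    reflection) is applied afterwards.
    """
    dt = effective_time_step(cfg, p, env) if dt_s is None else dt_s
    if dt == 0.0 or state.n_objects == 0:
        state.t_s += dt
        return state
    d0 = p.diameter_m
    box = state.box_m
    periodic = cfg.boundary == "periodic"
    mergeable = cfg.field_on and coupling_parameter(p, env) > 1.0

    sig = _step_sigmas(state.lengths, p, env, dt)
    disp = state.rng.standard_normal((state.n_objects, 3)) * sig
    prop = state.positions_m + disp
    movable = np.ones(state.n_objects, dtype=bool)

    # Reject moves that create non-mergeable overlaps; iterate because a
    # revert can expose a new contact. Each pass reverts >= 1 object, so
    # the loop terminates.
    for _ in range(state.n_objects):
        core = _core_distance(prop, state.lengths, d0, box, periodic)
        overlap = core < d0 * _OVERLAP_TOL
        np.fill_diagonal(overlap, False)
        if mergeable:
            tips = _tip_distance(prop, state.lengths, d0, box, periodic)
            overlap &= ~(tips < _zone_radii(state.lengths, p, env))
        ii, jj = np.nonzero(np.triu(overlap, k=1))
        if len(ii) == 0:
            break
        to_revert = set()
        for a, b in zip(ii, jj):
            if movable[b]:
                to_revert.add(int(b))
            elif movable[a]:
                to_revert.add(int(a))
        if not to_revert:
            break  # residual contact between two already-reverted objects
        idx = np.fromiter(to_revert, dtype=int)
        prop[idx] = state.positions_m[idx]
        movable[idx] = False

    actual = prop - state.positions_m
    state.unwrapped_m += actual
    state.positions_m = _apply_boundary(prop, box, cfg.boundary)
    state.t_s += dt
    return state


def detect_and_merge(
    state: SimulationState,
    cfg: SimulationConfig,
    p: ParticleSpec,
    env: EnvironmentSpec,
) -> SimulationState:
    """Aggregate every pair of objects whose polar attraction zones are met.

    The zone test: the nearest tip-to-tip distance of the pair is below
    r_a of the longer partner. Qualifying pairs merge in ascending
    tip-distance order, one at a time with a re-scan after each merge,
    into an object of length s1 + s2 at the length-weighted centre of
    mass (minimum-image) with a fresh id. No-op when the field is off or
    in the weak-coupling regime Γ ≤ 1.
    """
    if not cfg.field_on or coupling_parameter(p, env) <= 1.0:
        return state
    if state.n_objects < 2:
        return state
    d0 = p.diameter_m
    box = state.box_m
    periodic = cfg.boundary == "periodic"

    # Work on a dense pair matrix of "tip distance minus zone radius",
    # updated incrementally: a merge cascade then costs O(M) per merge
    # instead of a full O(M^2) rebuild.
    lengths = state.lengths.copy()
    pos = state.positions_m.copy()
    unw = state.unwrapped_m.copy()
    ids = state.ids.copy()
    tips = _tip_distance(pos, lengths, d0, box, periodic)
    np.fill_diagonal(tips, np.inf)
    margin = tips - _zone_radii(lengths, p, env)
    np.fill_diagonal(margin, np.inf)
    alive = np.ones(len(lengths), dtype=bool)

    def _pair_row(k: int) -> tuple[np.ndarray, np.ndarray]:
        """Tip distances and zone margins of object k against all objects."""
        d = pos - pos[k]
        if periodic:
            d = d - box * np.round(d / box)
        dxy = np.hypot(d[:, 0], d[:, 1])
        half = (lengths - 1) * d0 / 2.0
        hk = half[k]
        dz = d[:, 2]
        best = np.abs(dz + half - hk)
        for combo in (dz + half + hk, dz - half - hk, dz - half + hk):
            np.minimum(best, np.abs(combo), out=best)
        t = np.hypot(dxy, best)
        smax = int(lengths.max())
        table = np.array([attraction_radius(s, p, env) for s in range(1, smax + 1)])
        r = table[np.maximum(lengths, lengths[k]) - 1]
        return t, t - r

    while alive.sum() > 1:
        # candidates: pairs inside the zone; process closest tips first
        ii, jj = np.nonzero(margin < 0)
        if len(ii) == 0:
            break
        k = np.argmin(tips[ii, jj])
        a, b = int(min(ii[k], jj[k])), int(max(ii[k], jj[k]))

        sa, sb = int(lengths[a]), int(lengths[b])
        delta = pos[b] - pos[a]
        if periodic:
            delta = delta - box * np.round(delta / box)
        w = sb / (sa + sb)
        # reuse slot a for the merged object; retire slot b
        pos[a] = _apply_boundary(pos[a] + w * delta, box, cfg.boundary)
        unw[a] = unw[a] + w * (unw[b] - unw[a])
        lengths[a] = sa + sb
        ids[a] = state.next_id
        state.next_id += 1
        state.n_merges += 1
        alive[b] = False
        margin[b, :] = np.inf
        margin[:, b] = np.inf
        tips[b, :] = np.inf
        tips[:, b] = np.inf
        t_row, m_row = _pair_row(a)
        t_row[~alive] = np.inf
        m_row[~alive] = np.inf
        t_row[a] = np.inf
        m_row[a] = np.inf
        tips[a, :] = t_row
        tips[:, a] = t_row
        margin[a, :] = m_row
        margin[:, a] = m_row
        # a longer chain has a larger zone radius: refresh margins of pairs
        # whose governing radius may have changed (rows where the new chain
        # is now the longer partner are exactly the refreshed row/col above;
        # other pairs are unaffected by this merge).

    state.lengths = lengths[alive]
    state.positions_m = pos[alive]
    state.unwrapped_m = unw[alive]
    state.ids = ids[alive]
    order = np.argsort(state.ids)
    state.lengths = state.lengths[order]
    state.positions_m = state.positions_m[order]
    state.unwrapped_m = state.unwrapped_m[order]
    state.ids = state.ids[order]
    return state


def run_simulation(
    cfg: SimulationConfig, p: ParticleSpec, env: EnvironmentSpec
) -> RunResult:
    """Run the full chain-formation simulation.

    Alternates :func:`brownian_step` and :func:`detect_and_merge` for
    ``total_time_s`` of simulated time, recording snapshots at
    ``snapshot_interval_s`` (default: 50 snapshots per run), and returns
    the final state, per-snapshot statistics and the trajectory.
    Bit-identical under a fixed (config, seed) pair.
    """
    dt = effective_time_step(cfg, p, env)
    n_steps = int(np.ceil(cfg.total_time_s / dt)) if cfg.total_time_s > 0 else 0
    interval = cfg.snapshot_interval_s
    if interval is None:
        snap_every = max(1, n_steps // 50)
    else:
        snap_every = max(1, int(round(interval / dt)))

    state = init_configuration(cfg, p, env)
    snapshots = [_take_snapshot(state)]
    for step in range(1, n_steps + 1):
        brownian_step(state, cfg, p, env, dt_s=dt)
        detect_and_merge(state, cfg, p, env)
        if step % snap_every == 0 or step == n_steps:
            snapshots.append(_take_snapshot(state))
    traj = Trajectory(
        snapshots=tuple(snapshots),
        box_m=state.box_m,
        diameter_m=p.diameter_m,
        boundary=cfg.boundary,
    )
    return RunResult(final_state=state, statistics=compute_statistics(traj), trajectory=traj)


def _take_snapshot(state: SimulationState) -> Snapshot:
    return Snapshot(
        t_s=state.t_s,
        lengths=state.lengths.copy(),
        positions_m=state.positions_m.copy(),
        ids=state.ids.copy(),
    )


# ---------------------------------------------------------------------------
# Statistics and output
# ---------------------------------------------------------------------------

def _lateral_nn_spacing(snap: Snapshot, box: float, periodic: bool) -> float:
    """Mean nearest-neighbour x–y distance between chains (s >= 2)."""
    chains = snap.positions_m[snap.lengths >= 2]
    if len(chains) < 2:
        return np.nan
    d = chains[np.newaxis, :, :2] - chains[:, np.newaxis, :2]
    if periodic:
        d -= box * np.round(d / box)
    r = np.hypot(d[..., 0], d[..., 1])
    np.fill_diagonal(r, np.inf)
    return float(np.mean(r.min(axis=1)))


def compute_statistics(trajectory: Trajectory) -> ChainStatistics:
    """Chain statistics over a trajectory.

    Raises on an empty trajectory. See :class:`ChainStatistics` for the
    quantities computed.
    """
    if len(trajectory) == 0:
        raise ValueError("trajectory has no snapshots")
    periodic = trajectory.boundary == "periodic"
    snaps = trajectory.snapshots
    n_total = int(snaps[0].lengths.sum())
    times = np.array([s.t_s for s in snaps])
    n_obj = np.array([len(s.lengths) for s in snaps])
    mean_len = n_total / n_obj
    spacing = np.array(
        [_lateral_nn_spacing(s, trajectory.box_m, periodic) for s in snaps]
    )
    order = np.array(
        [1.0 if np.any(s.lengths >= 2) else np.nan for s in snaps]
    )
    final = snaps[-1].lengths
    counts = np.bincount(final, minlength=int(final.max()) + 1)[1:]
    return ChainStatistics(
        time_s=times,
        mean_length=mean_len,
        n_objects=n_obj,
        mean_spacing_m=spacing,
        order_parameter=order,
        final_length_counts=counts,
        n_total=n_total,
    )


def _element_for_length(s: int) -> str:
    """Element tag encoding the chain-length bucket in XYZ output."""
    if s == 1:
        return "H"
    if s <= 4:
        return "C"
    if s <= 9:
        return "N"
    return "O"


def write_xyz(trajectory: Trajectory, path) -> None:
    """Write the trajectory in XYZ format, one pseudo-atom per CG object.

    Coordinates are in nanometres; the element tag encodes the chain
    length bucket (H singleton, C 2–4, N 5–9, O ≥ 10).
    """
    with open(path, "w") as fh:
        for snap in trajectory.snapshots:
            fh.write(f"{len(snap.lengths)}\n")
            fh.write(f"t_s={snap.t_s:.9g} box_nm={trajectory.box_m * 1e9:.6g}\n")
            for s, pos in zip(snap.lengths, snap.positions_m):
                x, y, z = pos * 1e9
                fh.write(f"{_element_for_length(int(s))} {x:.4f} {y:.4f} {z:.4f}\n")


def trajectory_frame(trajectory: Trajectory):
    """CSV-ready long-format table: t_s, object_id, s, x_m, y_m, z_m."""
    import pandas as pd

    rows = []
    for snap in trajectory.snapshots:
        for oid, s, pos in zip(snap.ids, snap.lengths, snap.positions_m):
            rows.append(
                {
                    "t_s": snap.t_s,
                    "object_id": int(oid),
                    "s": int(s),
                    "x_m": pos[0],
                    "y_m": pos[1],
                    "z_m": pos[2],
                }
            )
    return pd.DataFrame(rows)
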