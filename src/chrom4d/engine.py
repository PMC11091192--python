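"""Langevin MD engine for the chromatin polymer plus diffusing binders.

The integrator is BAOAB splitting of the Langevin equation (half kick,
half drift, exact Ornstein-Uhlenbeck velocity update, half drift, half
kick): with friction zeta = 0 and the thermostat off it reduces exactly to
velocity Verlet, and at zeta = 0.5, dt = 0.01 its kinetic temperature
matches the target to within the sampling error, which the equipartition
test checks.  All runs are deterministic given the replica seed: the SAW
initial state, binder placement, thermostat noise and extrusion randomness
all flow from one ``numpy.random.Generator`` per replica.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .builders import PolymerModel
from .config import SimulationConfig
from .extrusion import ExtruderSystem
from .forcefield import R_MIN, affinity_to_epsilon
from .state import Conformation, Ensemble, Trajectory

__all__ = [
    "init_saw_conformation",
    "Simulator",
    "run_replicas",
    "kinetic_temperature",
]

_LATTICE_STEPS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=int
)


def _saw_sites(n_beads: int, half_extent: int, rng: np.random.Generator,
               max_restarts: int = 200) -> np.ndarray:
    """Self-avoiding walk on the unit cubic lattice inside a cube of
    half-edge ``half_extent``, grown with backtracking."""
    for _ in range(max_restarts):
        path = [np.zeros(3, dtype=int)]
        visited = {(0, 0, 0)}
        choices: list[list[int]] = [list(rng.permutation(6))]
        budget = 60 * n_beads
        while len(path) < n_beads and budget > 0:
            budget -= 1
            opts = choices[-1]
            if not opts:
                if len(path) == 1:
                    break  # restart
                dead = path.pop()
                visited.discard(tuple(dead))
                choices.pop()
                continue
            step = _LATTICE_STEPS[opts.pop()]
            cand = path[-1] + step
            key = (int(cand[0]), int(cand[1]), int(cand[2]))
            if key in visited or np.abs(cand).max() > half_extent:
                continue
            path.append(cand)
            visited.add(key)
            choices.append(list(rng.permutation(6)))
        if len(path) == n_beads:
            return np.array(path, dtype=float)
    raise RuntimeError(
        f"could not grow a {n_beads}-bead self-avoiding walk inside a box of "
        f"half-extent {half_extent} after {max_restarts} restarts (box too small?)"
    )


def init_saw_conformation(n_beads: int, box_L: float, seed: int | None = None,
                          rng: np.random.Generator | None = None) -> Conformation:
    """Initial polymer state: a self-avoiding walk with unit bonds.

    Consecutive beads are exactly 1 sigma apart and no two beads are closer
    than 1 sigma (lattice construction).  The walk is recentred on the box
    centre.  Reproducible given ``seed``.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    centre = np.full(3, box_L / 2.0)
    if n_beads == 1:
        return Conformation(beads=centre[None, :].copy(), box_L=box_L)
    half_extent = int(box_L / 2.0) - 1
    if half_extent < 1:
        raise ValueError(f"box_L={box_L} too small to contain a SAW")
    sites = _saw_sites(n_beads, half_extent, rng)
    sites = sites - sites.mean(axis=0)
    # re-clip into the box after recentring (lattice coords are integers)
    beads = sites + centre
    return Conformation(beads=beads, box_L=box_L)


def _place_binders(n: int, existing: np.ndarray, box_L: float,
                   rng: np.random.Generator, min_dist: float = 0.9) -> np.ndarray:
    """Uniform random binder positions at least ``min_dist`` from every
    already-placed particle (avoids force blow-ups at step one)."""
    if n == 0:
        return np.empty((0, 3))
    placed: list[np.ndarray] = []
    pool = existing.copy()
    for _ in range(n):
        for attempt in range(500):
            cand = rng.random(3) * box_L
            tree = cKDTree(np.vstack([pool] + placed) % box_L, boxsize=box_L)
            d, _ = tree.query(cand % box_L, k=1)
            if d >= min_dist:
                placed.append(cand)
                break
        else:
            raise RuntimeError("could not place binders without overlap (box too dense)")
    return np.array(placed)


def kinetic_temperature(ke: float | np.ndarray, n_particles: int) -> float | np.ndarray:
    """Instantaneous kinetic temperature 2<KE> / (3 N) in kBT units."""
    return 2.0 * np.asarray(ke) / (3.0 * n_particles)


class Simulator:
    """MD driver binding a :class:`PolymerModel` to a :class:`SimulationConfig`.

    Owns the flat particle arrays (beads first, binders after), the Verlet
    neighbour list, and the optional extrusion layer, and produces
    :class:`Trajectory` objects of unwrapped polymer coordinates.
    """

    #: Verlet-list skin distance (sigma)
    SKIN = 0.4

    def __init__(self, model: PolymerModel, config: SimulationConfig) -> None:
        if model.affinity_matrix.shape[1] <= (model.bead_types.max(initial=0)):
            raise ValueError("model bead types not covered by affinity matrix")
        self.model = model
        self.config = config
        counts = dict(config.binder_counts) or model.default_binder_counts()
        self.binder_counts = counts
        binder_types = np.concatenate(
            [np.full(counts.get(t, 0), t, dtype=int) for t in range(model.n_binder_types)]
        ) if model.n_binder_types else np.empty(0, dtype=int)
        self.n_beads = model.n_beads
        self.n_binders = len(binder_types)
        n_total = self.n_beads + self.n_binders
        self.type_id = np.concatenate([model.bead_types, binder_types]).astype(np.int64)
        self.is_binder = np.zeros(n_total, dtype=np.bool_)
        self.is_binder[self.n_beads:] = True
        # affinity (well depth, kBT) -> bare LJ epsilon for the kernel
        unit = -_min_shifted_lj(model.r_int)
        if unit <= 0 and np.any(model.affinity_matrix > 0):
            raise ValueError(f"r_int={model.r_int} leaves the attractive well empty")
        self.eps_lj = np.ascontiguousarray(
            model.affinity_matrix / unit if unit > 0 else model.affinity_matrix * 0.0
        )
        self.R0 = 1.6
        self.K_fene = 30.0
        self._rc_nb = max(R_MIN, model.r_int if np.any(self.eps_lj > 0) else R_MIN)

    # ------------------------------------------------------------------
    def _init_arrays(self, rng: np.random.Generator):
        conf = init_saw_conformation(self.n_beads, self.config.box_L, rng=rng)
        binders = _place_binders(self.n_binders, conf.beads, self.config.box_L, rng)
        x = np.vstack([conf.beads, binders]) if self.n_binders else conf.beads.copy()
        v = rng.standard_normal(x.shape) * math.sqrt(self.config.T)
        return np.ascontiguousarray(x), np.ascontiguousarray(v)

    def _nlist_capacity(self) -> int:
        n = self.n_beads + self.n_binders
        rc = self._rc_nb + self.SKIN
        # generous bound: local density of a dense melt within the cutoff
        per = int(8.0 * rc**3) + 16
        return max(n * per, 4096)

    def run_replica(
        self,
        seed: int,
        replica_id: int = 0,
        n_equil_steps: int | None = None,
        n_production_steps: int | None = None,
        sample_interval: int | None = None,
        loop_log: list | None = None,
        ke_log: list | None = None,
    ) -> Trajectory:
        """Equilibrate then sample one replica.  Deterministic given seed."""
        cfg = self.config
        n_equil = cfg.n_equil_steps if n_equil_steps is None else n_equil_steps
        n_prod = cfg.n_production_steps if n_production_steps is None else n_production_steps
        interval = cfg.sample_interval if sample_interval is None else sample_interval

        rng = np.random.default_rng(seed)
        x, v = self._init_arrays(rng)
        img = np.zeros_like(x, dtype=np.int64)
        f = np.zeros_like(x)
        n = x.shape[0]

        ext_sys = None
        spring_i = np.empty(0, dtype=np.int64)
        spring_j = np.empty(0, dtype=np.int64)
        K_spring, r_eq, ext_interval = 0.0, 1.1, 0
        if self.model.extrusion is not None:
            ext_sys = ExtruderSystem(
                self.model.extrusion, self.n_beads, self.model.anchors,
                self.model.g_bp, rng,
            )
            spring_i, spring_j = ext_sys.spring_arrays()
            K_spring = self.model.extrusion.K_spring
            r_eq = self.model.extrusion.r_eq
            ext_interval = self.model.extrusion.step_interval

        cap = self._nlist_capacity()
        pairs_i = np.zeros(cap, dtype=np.int64)
        pairs_j = np.zeros(cap, dtype=np.int64)
        nlist_state = np.zeros(1, dtype=np.int64)
        x_build = x.copy()
        rc2 = (self._rc_nb + self.SKIN) ** 2
        cnt = _kernels._build_pairs(x, cfg.box_L, rc2, pairs_i, pairs_j)
        if cnt < 0:
            raise RuntimeError("neighbour-list capacity exceeded at initialisation")
        nlist_state[0] = cnt
        status = _kernels._forces(
            x, f, cfg.box_L, self.is_binder, self.type_id, self.n_beads,
            self.eps_lj, self.model.r_int, self.R0, self.K_fene,
            spring_i, spring_j, K_spring, r_eq, pairs_i, pairs_j, nlist_state[0],
        )
        self._raise_on(status, 0)

        frames: list[Conformation] = []
        t = 0
        total = n_equil + n_prod
        next_sample = n_equil + interval
        next_ext = ext_interval if ext_sys is not None else total + 1
        max_chunk = min(2048, ext_interval or 2048, interval, max(total, 1))
        noise_buf = np.empty((max_chunk, n, 3))

        while t < total:
            stop = min(total, next_ext if ext_sys is not None else total, next_sample)
            chunk = min(stop - t, max_chunk)
            if chunk > 0:
                noise = noise_buf[:chunk]
                rng.standard_normal(out=noise)
                ke_trace = np.empty(chunk)
                status = _kernels._run_chunk(
                    x, img, v, f, noise, cfg.dt, cfg.zeta, cfg.T, 1.0, cfg.box_L,
                    self.is_binder, self.type_id, self.n_beads,
                    self.eps_lj, self.model.r_int, self.R0, self.K_fene,
                    spring_i, spring_j, K_spring, r_eq,
                    pairs_i, pairs_j, nlist_state, x_build, self.SKIN,
                    self._rc_nb, ke_trace,
                )
                self._raise_on(status, t)
                t += chunk
                if ke_log is not None:
                    ke_log.append((t - chunk, ke_trace.copy()))
                if t < stop:
                    continue
            if ext_sys is not None and t == next_ext:
                if loop_log is not None:
                    ext_sys.extrusion_step()
                    loop_log.extend(ext_sys.detach_rebind())
                    spring_i, spring_j = ext_sys.spring_arrays()
                else:
                    spring_i, spring_j = ext_sys.update()
                next_ext += ext_interval
            if t == next_sample and t > n_equil:
                xu = x + img * cfg.box_L  # unwrapped coordinates
                frames.append(
                    Conformation(
                        beads=xu[: self.n_beads],
                        binders=xu[self.n_beads:] if cfg.store_binders else None,
                        box_L=cfg.box_L,
                        time=t,
                    )
                )
                next_sample += interval

        if not frames:  # always keep at least the final state
            xu = x + img * cfg.box_L
            frames.append(Conformation(beads=xu[: self.n_beads],
                                       box_L=cfg.box_L, time=max(t, 1)))
        return Trajectory(frames=frames, replica_id=replica_id,
                          sample_interval=interval, seed=seed)

    @staticmethod
    def _raise_on(status: int, t: int) -> None:
        if status == _kernels.OK:
            return
        if status == _kernels.FENE_BROKEN:
            raise RuntimeError(f"FENE bond exceeded R0 at step {t}: dt too large or overlap")
        if status == _kernels.NOT_FINITE:
            raise RuntimeError(f"non-finite force/energy at step {t}: dt too large")
        if status == _kernels.NLIST_OVERFLOW:
            raise RuntimeError("neighbour-list capacity exceeded mid-run")
        raise RuntimeError(f"unknown engine status {status}")

    # ------------------------------------------------------------------
    def potential_energy(self, x: np.ndarray,
                         spring_i=None, spring_j=None,
                         K_spring: float = 0.0, r_eq: float = 1.1) -> float:
        """All-pairs potential energy (bookkeeping oracle for NVE tests)."""
        si = np.empty(0, dtype=np.int64) if spring_i is None else np.asarray(spring_i, dtype=np.int64)
        sj = np.empty(0, dtype=np.int64) if spring_j is None else np.asarray(spring_j, dtype=np.int64)
        return float(
            _kernels._potential_energy(
                np.ascontiguousarray(x % self.config.box_L), self.config.box_L, self.is_binder,
                self.type_id, self.n_beads, self.eps_lj, self.model.r_int,
                self.R0, self.K_fene, si, sj, K_spring, r_eq,
            )
        )

    def forces(self, x: np.ndarray, all_pairs: bool = False) -> np.ndarray:
        """Forces at positions ``x``; with ``all_pairs`` the neighbour list
        is replaced by every pair (reference for the Verlet-list contract)."""
        x = np.ascontiguousarray(np.asarray(x, dtype=float) % self.config.box_L)
        n = x.shape[0]
        f = np.zeros_like(x)
        if all_pairs:
            npairs = n * (n - 1) // 2
            pi = np.empty(npairs, dtype=np.int64)
            pj = np.empty(npairs, dtype=np.int64)
            k = 0
            for i in range(n - 1):
                m = n - 1 - i
                pi[k:k + m] = i
                pj[k:k + m] = np.arange(i + 1, n)
                k += m
            cnt = npairs
        else:
            cap = self._nlist_capacity()
            pi = np.zeros(cap, dtype=np.int64)
            pj = np.zeros(cap, dtype=np.int64)
            cnt = _kernels._build_pairs(x, self.config.box_L,
                                        (self._rc_nb + self.SKIN) ** 2, pi, pj)
            if cnt < 0:
                raise RuntimeError("neighbour-list capacity exceeded")
        status = _kernels._forces(
            x, f, self.config.box_L, self.is_binder, self.type_id, self.n_beads,
            self.eps_lj, self.model.r_int, self.R0, self.K_fene,
            np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), 0.0, 1.1,
            pi, pj, cnt,
        )
        self._raise_on(status, 0)
        return f


def _min_shifted_lj(r_int: float) -> float:
    """Minimum of the truncated-shifted LJ with eps = 1 (negative number)."""
    if r_int <= R_MIN:
        return 0.0
    shift = (1.0 / r_int) ** 12 - (1.0 / r_int) ** 6
    return 4.0 * (0.25 - 0.5 - shift)  # value at r = 2^(1/6)


def run_replicas(model: PolymerModel, config: SimulationConfig,
                 progress: bool = False) -> Ensemble:
    """Run ``config.n_replicas`` independent trajectories with distinct seeds.

    A replica that fails (e.g. a broken bond from an unstable timestep) is
    isolated and reported on the returned :class:`Ensemble`, which warns
    that it is partial rather than silently truncating.
    """
    sim = Simulator(model, config)
    trajectories: list[Trajectory] = []
    failures: list[tuple[int, str]] = []
    for rid, seed in enumerate(config.replica_seeds()):
        try:
            trajectories.append(sim.run_replica(seed=seed, replica_id=rid))
        except RuntimeError as exc:  # isolate per-replica failures
            failures.append((rid, str(exc)))
        if progress:
            print(f"replica {rid}: done ({len(trajectories)} ok, {len(failures)} failed)")
    if not trajectories:
        raise RuntimeError(f"all {config.n_replicas} replicas failed: {failures}")
    return Ensemble(trajectories=trajectories, failed_replicas=failures)
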