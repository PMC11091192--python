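"""Numba kernels for the Langevin bead-spring engine.

Layout: one flat particle array holding the polymer beads first, then the
binders.  ``type_id`` holds the bead type for beads and the binder type
for binders; ``is_binder`` separates the two.  Positions are kept wrapped
into the periodic box; integer image counters accumulate boundary
crossings so unwrapped polymer coordinates (needed by every shape and
distance analysis) are reconstructed exactly as ``x + img * box_L``.
Because wrapped coordinates differ by less than one box length, the
minimum-image convention reduces to a single correction per component.

Nonbonded interactions come from a Verlet neighbour list (cell-assisted
build, cutoff + skin) rebuilt whenever any particle has moved more than
half the skin since the last build; forces are identical (to round-off)
to an all-pairs evaluation, which the tests check.

Pair rules:

* bead-bead and binder-binder: WCA repulsive core (eps = 1, cut 2^(1/6)),
* binder-bead with cognate eps > 0: truncated-shifted LJ with cutoff
  ``r_int`` (the r^-12 term of the well is the repulsive core),
* binder-bead with eps = 0: WCA,
* consecutive beads additionally: FENE bond,
* extruder legs additionally: harmonic spring (K_spring, r_eq).
"""

from __future__ import annotations

import numpy as np
from numba import njit

R_MIN2 = 2.0 ** (1.0 / 3.0)  # (2^(1/6))^2

# status codes
OK = 0
FENE_BROKEN = 1
NOT_FINITE = 2
NLIST_OVERFLOW = 3


@njit(cache=True, fastmath=True)
def _build_pairs_allpairs(x, box_L, rc2, pairs_i, pairs_j):
    """O(N^2) reference pair build on wrapped coordinates; returns count
    (-1 on overflow)."""
    n = x.shape[0]
    cap = pairs_i.shape[0]
    half_L = 0.5 * box_L
    cnt = 0
    for i in range(n - 1):
        xi0 = x[i, 0]
        xi1 = x[i, 1]
        xi2 = x[i, 2]
        for j in range(i + 1, n):
            d0 = xi0 - x[j, 0]
            d1 = xi1 - x[j, 1]
            d2 = xi2 - x[j, 2]
            if d0 > half_L:
                d0 -= box_L
            elif d0 < -half_L:
                d0 += box_L
            if d1 > half_L:
                d1 -= box_L
            elif d1 < -half_L:
                d1 += box_L
            if d2 > half_L:
                d2 -= box_L
            elif d2 < -half_L:
                d2 += box_L
            r2 = d0 * d0 + d1 * d1 + d2 * d2
            if r2 < rc2:
                if cnt >= cap:
                    return -1
                pairs_i[cnt] = i
                pairs_j[cnt] = j
                cnt += 1
    return cnt


@njit(cache=True, fastmath=True)
def _build_pairs(x, box_L, rc2, pairs_i, pairs_j):
    """Cell-assisted pair build: bin wrapped particles into cells of edge
    >= cutoff and scan the 27 neighbouring cells (periodic).  Identical
    output set (order aside) to the all-pairs reference; returns the pair
    count (-1 on overflow)."""
    n = x.shape[0]
    rc = np.sqrt(rc2)
    ncell = int(box_L / rc)
    if ncell < 3:
        return _build_pairs_allpairs(x, box_L, rc2, pairs_i, pairs_j)
    cell_sz = box_L / ncell
    ncell3 = ncell * ncell * ncell

    head = np.full(ncell3, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cx = np.empty(n, dtype=np.int64)
    cy = np.empty(n, dtype=np.int64)
    cz = np.empty(n, dtype=np.int64)
    for i in range(n):
        a = int(x[i, 0] / cell_sz)
        b = int(x[i, 1] / cell_sz)
        c = int(x[i, 2] / cell_sz)
        if a >= ncell:
            a = ncell - 1
        if b >= ncell:
            b = ncell - 1
        if c >= ncell:
            c = ncell - 1
        cx[i] = a
        cy[i] = b
        cz[i] = c
        idx = (a * ncell + b) * ncell + c
        nxt[i] = head[idx]
        head[idx] = i

    cap = pairs_i.shape[0]
    cnt = 0
    for i in range(n):
        for da in range(-1, 2):
            a = cx[i] + da
            s0 = 0.0
            if a < 0:
                a += ncell
                s0 = box_L
            elif a >= ncell:
                a -= ncell
                s0 = -box_L
            for db in range(-1, 2):
                b = cy[i] + db
                s1 = 0.0
                if b < 0:
                    b += ncell
                    s1 = box_L
                elif b >= ncell:
                    b -= ncell
                    s1 = -box_L
                for dc in range(-1, 2):
                    c = cz[i] + dc
                    s2 = 0.0
                    if c < 0:
                        c += ncell
                        s2 = box_L
                    elif c >= ncell:
                        c -= ncell
                        s2 = -box_L
                    # shift applied to the neighbour cell's particles
                    xi0 = x[i, 0] + s0
                    xi1 = x[i, 1] + s1
                    xi2 = x[i, 2] + s2
                    j = head[(a * ncell + b) * ncell + c]
                    while j >= 0:
                        if j > i:
                            d0 = xi0 - x[j, 0]
                            d1 = xi1 - x[j, 1]
                            d2 = xi2 - x[j, 2]
                            r2 = d0 * d0 + d1 * d1 + d2 * d2
                            if r2 < rc2:
                                if cnt >= cap:
                                    return -1
                                pairs_i[cnt] = i
                                pairs_j[cnt] = j
                                cnt += 1
                        j = nxt[j]
    return cnt


@njit(cache=True, fastmath=True)
def _forces(
    x,
    f,
    box_L,
    is_binder,
    type_id,
    n_beads,
    eps_mat,
    r_int,
    R0,
    K_fene,
    spring_i,
    spring_j,
    K_spring,
    r_eq,
    pairs_i,
    pairs_j,
    n_pairs,
):
    """Accumulate forces into ``f`` (zeroed here) on wrapped coordinates.
    Returns a status code."""
    n = x.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0

    rint2 = r_int * r_int
    half_L = 0.5 * box_L

    # nonbonded pairs from the Verlet list
    for p in range(n_pairs):
        i = pairs_i[p]
        j = pairs_j[p]
        d0 = x[i, 0] - x[j, 0]
        d1 = x[i, 1] - x[j, 1]
        d2 = x[i, 2] - x[j, 2]
        if d0 > half_L:
            d0 -= box_L
        elif d0 < -half_L:
            d0 += box_L
        if d1 > half_L:
            d1 -= box_L
        elif d1 < -half_L:
            d1 += box_L
        if d2 > half_L:
            d2 -= box_L
        elif d2 < -half_L:
            d2 += box_L
        r2 = d0 * d0 + d1 * d1 + d2 * d2
        if r2 <= 1e-12:
            return NOT_FINITE

        eps = 0.0
        if is_binder[i] != is_binder[j]:
            if is_binder[i]:
                eps = eps_mat[type_id[i], type_id[j]]
            else:
                eps = eps_mat[type_id[j], type_id[i]]

        if eps > 0.0:
            cut2 = rint2
        else:
            eps = 1.0
            cut2 = R_MIN2
        if r2 < cut2:
            inv2 = 1.0 / r2
            inv6 = inv2 * inv2 * inv2
            fscal = 24.0 * eps * inv6 * (2.0 * inv6 - 1.0) * inv2
            f[i, 0] += fscal * d0
            f[i, 1] += fscal * d1
            f[i, 2] += fscal * d2
            f[j, 0] -= fscal * d0
            f[j, 1] -= fscal * d1
            f[j, 2] -= fscal * d2

    # FENE bonds between consecutive beads (minimum image; R0 << box)
    R02 = R0 * R0
    for i in range(n_beads - 1):
        j = i + 1
        d0 = x[i, 0] - x[j, 0]
        d1 = x[i, 1] - x[j, 1]
        d2 = x[i, 2] - x[j, 2]
        if d0 > half_L:
            d0 -= box_L
        elif d0 < -half_L:
            d0 += box_L
        if d1 > half_L:
            d1 -= box_L
        elif d1 < -half_L:
            d1 += box_L
        if d2 > half_L:
            d2 -= box_L
        elif d2 < -half_L:
            d2 += box_L
        r2 = d0 * d0 + d1 * d1 + d2 * d2
        if r2 >= R02:
            return FENE_BROKEN
        fscal = -K_fene / (1.0 - r2 / R02)
        f[i, 0] += fscal * d0
        f[i, 1] += fscal * d1
        f[i, 2] += fscal * d2
        f[j, 0] -= fscal * d0
        f[j, 1] -= fscal * d1
        f[j, 2] -= fscal * d2

    # extruder springs (minimum image; spring extension << box)
    for s in range(spring_i.shape[0]):
        i = spring_i[s]
        j = spring_j[s]
        d0 = x[i, 0] - x[j, 0]
        d1 = x[i, 1] - x[j, 1]
        d2 = x[i, 2] - x[j, 2]
        if d0 > half_L:
            d0 -= box_L
        elif d0 < -half_L:
            d0 += box_L
        if d1 > half_L:
            d1 -= box_L
        elif d1 < -half_L:
            d1 += box_L
        if d2 > half_L:
            d2 -= box_L
        elif d2 < -half_L:
            d2 += box_L
        r2 = d0 * d0 + d1 * d1 + d2 * d2
        r = np.sqrt(r2)
        if r < 1e-9:
            continue
        fscal = -K_spring * (r - r_eq) / r
        f[i, 0] += fscal * d0
        f[i, 1] += fscal * d1
        f[i, 2] += fscal * d2
        f[j, 0] -= fscal * d0
        f[j, 1] -= fscal * d1
        f[j, 2] -= fscal * d2

    return OK


@njit(cache=True)
def _potential_energy(
    x,
    box_L,
    is_binder,
    type_id,
    n_beads,
    eps_mat,
    r_int,
    R0,
    K_fene,
    spring_i,
    spring_j,
    K_spring,
    r_eq,
):
    """Total potential energy by all-pairs evaluation on wrapped
    coordinates (bookkeeping oracle for NVE-drift tests)."""
    n = x.shape[0]
    rint2 = r_int * r_int
    half_L = 0.5 * box_L
    shift_wca = 1.0  # -4*(-0.25): WCA shift with eps = 1
    e = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            d0 = x[i, 0] - x[j, 0]
            d1 = x[i, 1] - x[j, 1]
            d2 = x[i, 2] - x[j, 2]
            if d0 > half_L:
                d0 -= box_L
            elif d0 < -half_L:
                d0 += box_L
            if d1 > half_L:
                d1 -= box_L
            elif d1 < -half_L:
                d1 += box_L
            if d2 > half_L:
                d2 -= box_L
            elif d2 < -half_L:
                d2 += box_L
            r2 = d0 * d0 + d1 * d1 + d2 * d2
            eps = 0.0
            if is_binder[i] != is_binder[j]:
                if is_binder[i]:
                    eps = eps_mat[type_id[i], type_id[j]]
                else:
                    eps = eps_mat[type_id[j], type_id[i]]
            if eps > 0.0:
                if r2 < rint2:
                    inv6 = 1.0 / (r2 * r2 * r2)
                    shift6 = (1.0 / rint2) ** 3
                    e += 4.0 * eps * (inv6 * inv6 - inv6 - shift6 * shift6 + shift6)
            else:
                if r2 < R_MIN2:
                    inv6 = 1.0 / (r2 * r2 * r2)
                    e += 4.0 * (inv6 * inv6 - inv6) + shift_wca
    R02 = R0 * R0
    for i in range(n_beads - 1):
        d0 = x[i, 0] - x[i + 1, 0]
        d1 = x[i, 1] - x[i + 1, 1]
        d2 = x[i, 2] - x[i + 1, 2]
        if d0 > half_L:
            d0 -= box_L
        elif d0 < -half_L:
            d0 += box_L
        if d1 > half_L:
            d1 -= box_L
        elif d1 < -half_L:
            d1 += box_L
        if d2 > half_L:
            d2 -= box_L
        elif d2 < -half_L:
            d2 += box_L
        r2 = d0 * d0 + d1 * d1 + d2 * d2
        # the WCA core of bonded pairs is already counted in the all-pairs loop
        e += -0.5 * K_fene * R02 * np.log(1.0 - r2 / R02)
    for s in range(spring_i.shape[0]):
        i = spring_i[s]
        j = spring_j[s]
        d0 = x[i, 0] - x[j, 0]
        d1 = x[i, 1] - x[j, 1]
        d2 = x[i, 2] - x[j, 2]
        if d0 > half_L:
            d0 -= box_L
        elif d0 < -half_L:
            d0 += box_L
        if d1 > half_L:
            d1 -= box_L
        elif d1 < -half_L:
            d1 += box_L
        if d2 > half_L:
            d2 -= box_L
        elif d2 < -half_L:
            d2 += box_L
        r = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
        e += 0.5 * K_spring * (r - r_eq) ** 2
    return e


@njit(cache=True, fastmath=True)
def _run_chunk(
    x,
    img,
    v,
    f,
    noise,
    dt,
    zeta,
    T,
    mass,
    box_L,
    is_binder,
    type_id,
    n_beads,
    eps_mat,
    r_int,
    R0,
    K_fene,
    spring_i,
    spring_j,
    K_spring,
    r_eq,
    pairs_i,
    pairs_j,
    nlist_state,
    x_build,
    skin,
    rc_nb,
    ke_trace,
):
    """Advance ``noise.shape[0]`` BAOAB Langevin steps in place.

    ``x`` stays wrapped in [0, box_L); ``img`` accumulates the boundary
    crossings of every particle.  ``nlist_state[0]`` carries the current
    pair count across calls; ``x_build`` the wrapped positions at the last
    neighbour-list build.  Returns a status code; on success the kinetic
    energy after each step is written to ``ke_trace``.
    """
    n_steps = noise.shape[0]
    n = x.shape[0]
    c1 = np.exp(-zeta * dt / mass)
    c2 = np.sqrt((1.0 - c1 * c1) * T / mass)
    half = 0.5 * dt
    inv_m = 1.0 / mass
    rc2 = (rc_nb + skin) ** 2
    half_skin2 = (0.5 * skin) ** 2
    half_L = 0.5 * box_L

    for step in range(n_steps):
        # B: half kick
        for i in range(n):
            v[i, 0] += half * f[i, 0] * inv_m
            v[i, 1] += half * f[i, 1] * inv_m
            v[i, 2] += half * f[i, 2] * inv_m
        # A: half drift
        for i in range(n):
            x[i, 0] += half * v[i, 0]
            x[i, 1] += half * v[i, 1]
            x[i, 2] += half * v[i, 2]
        # O: exact Ornstein-Uhlenbeck update of velocities
        if zeta > 0.0:
            for i in range(n):
                v[i, 0] = c1 * v[i, 0] + c2 * noise[step, i, 0]
                v[i, 1] = c1 * v[i, 1] + c2 * noise[step, i, 1]
                v[i, 2] = c1 * v[i, 2] + c2 * noise[step, i, 2]
        # A: half drift, then wrap (per-half-step motion << box)
        for i in range(n):
            x[i, 0] += half * v[i, 0]
            x[i, 1] += half * v[i, 1]
            x[i, 2] += half * v[i, 2]
            if x[i, 0] >= box_L:
                x[i, 0] -= box_L
                img[i, 0] += 1
            elif x[i, 0] < 0.0:
                x[i, 0] += box_L
                img[i, 0] -= 1
            if x[i, 1] >= box_L:
                x[i, 1] -= box_L
                img[i, 1] += 1
            elif x[i, 1] < 0.0:
                x[i, 1] += box_L
                img[i, 1] -= 1
            if x[i, 2] >= box_L:
                x[i, 2] -= box_L
                img[i, 2] += 1
            elif x[i, 2] < 0.0:
                x[i, 2] += box_L
                img[i, 2] -= 1

        # neighbour list validity: rebuild if any displacement > skin/2
        need = False
        for i in range(n):
            d0 = x[i, 0] - x_build[i, 0]
            d1 = x[i, 1] - x_build[i, 1]
            d2 = x[i, 2] - x_build[i, 2]
            if d0 > half_L:
                d0 -= box_L
            elif d0 < -half_L:
                d0 += box_L
            if d1 > half_L:
                d1 -= box_L
            elif d1 < -half_L:
                d1 += box_L
            if d2 > half_L:
                d2 -= box_L
            elif d2 < -half_L:
                d2 += box_L
            if d0 * d0 + d1 * d1 + d2 * d2 > half_skin2:
                need = True
                break
        if need:
            cnt = _build_pairs(x, box_L, rc2, pairs_i, pairs_j)
            if cnt < 0:
                return NLIST_OVERFLOW
            nlist_state[0] = cnt
            for i in range(n):
                x_build[i, 0] = x[i, 0]
                x_build[i, 1] = x[i, 1]
                x_build[i, 2] = x[i, 2]

        # B: force + half kick
        status = _forces(
            x, f, box_L, is_binder, type_id, n_beads, eps_mat, r_int,
            R0, K_fene, spring_i, spring_j, K_spring, r_eq,
            pairs_i, pairs_j, nlist_state[0],
        )
        if status != OK:
            return status
        ke = 0.0
        for i in range(n):
            v[i, 0] += half * f[i, 0] * inv_m
            v[i, 1] += half * f[i, 1] * inv_m
            v[i, 2] += half * f[i, 2] * inv_m
            ke += v[i, 0] * v[i, 0] + v[i, 1] * v[i, 1] + v[i, 2] * v[i, 2]
        ke *= 0.5 * mass
        if not np.isfinite(ke):
            return NOT_FINITE
        ke_trace[step] = ke

    return OK
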