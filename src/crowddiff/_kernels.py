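"""Numba kernels for the lattice and hard-disk stepping loops.

The step logic lives in small njit'ed functions that take pre-drawn random
variates, so the same code path serves both the single-step Python API
(tests drive it with chosen variates) and the long-run kernels (which draw
the variates internally from the numba legacy RNG seeded per run).

Direction codes: 0 = left (col-1), 1 = right (col+1), 2 = up (row-1),
3 = down (row+1); a uniform variate u maps to int(4*u), i.e. quartiles of
[0, 1).  A direction of -1 marks a tracer that does not attempt a move this
step (bound, failed its escape draw).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# site_kind codes, kept in sync with world.py
EMPTY = 0
CRO = 1
PRO = 2

_DR = np.array([0, 0, -1, 1], dtype=np.int64)
_DC = np.array([-1, 1, 0, 0], dtype=np.int64)


@njit(cache=True)
def draw_moves(bound, p_escape, literal_escape, dirs, uref):
    """Draw per-tracer participation, direction and reflection variates.

    Bound tracers first draw an escape variate; only on success do they
    draw a direction (dirs[i] = -1 otherwise).  With the conventional
    inequality a tracer escapes when u < P_escape; ``literal_escape``
    flips it to u >= P_escape.
    """
    for i in range(bound.size):
        if bound[i]:
            u = np.random.random()
            escaped = (u >= p_escape) if literal_escape else (u < p_escape)
            if not escaped:
                dirs[i] = -1
                uref[i] = 0.0
                continue
        dirs[i] = np.int64(np.random.random() * 4.0)
        uref[i] = np.random.random()


@njit(cache=True)
def step_exclusion(site, occ, rows, cols, drow, dcol, bound,
                   dirs, uref1, uref2, p_reflect, recursive, moved, blocked):
    """One time step with tracer-tracer steric exclusion.

    Pass one: sequential hops in index order; a destination holding a
    tracer (including a bound tracer sitting on a PRO, which then acts as
    a complete reflector) blocks the hop and labels the tracer
    "blocked by another DT".  Pass two (``recursive``): the labelled set is
    re-examined against the same destinations; those now free of tracers
    hop (a vacated PRO re-applies partial reflection with a fresh variate),
    the rest stay blocked.  This removes false self-blocking caused by the
    sequential update order.
    """
    n = site.shape[0]
    n_tr = rows.size
    for i in range(n_tr):
        d = dirs[i]
        if d < 0:
            continue
        nr = rows[i] + _DR[d]
        nc = cols[i] + _DC[d]
        if nr < 0:
            nr += n
        elif nr >= n:
            nr -= n
        if nc < 0:
            nc += n
        elif nc >= n:
            nc -= n
        k = site[nr, nc]
        if k == CRO:
            continue
        if occ[nr, nc] == 1:
            blocked[i] = True
            continue
        if k == PRO and uref1[i] < p_reflect:
            continue
        occ[rows[i], cols[i]] = 0
        occ[nr, nc] = 1
        drow[i] += _DR[d]
        dcol[i] += _DC[d]
        rows[i] = nr
        cols[i] = nc
        moved[i] = True
        bound[i] = k == PRO
    if recursive:
        for i in range(n_tr):
            if not blocked[i]:
                continue
            d = dirs[i]
            nr = rows[i] + _DR[d]
            nc = cols[i] + _DC[d]
            if nr < 0:
                nr += n
            elif nr >= n:
                nr -= n
            if nc < 0:
                nc += n
            elif nc >= n:
                nc -= n
            if occ[nr, nc] == 1:
                continue  # still genuinely blocked by a tracer
            k = site[nr, nc]
            blocked[i] = False
            if k == PRO and uref2[i] < p_reflect:
                continue  # freed PRO reflected the retry
            occ[rows[i], cols[i]] = 0
            occ[nr, nc] = 1
            drow[i] += _DR[d]
            dcol[i] += _DC[d]
            rows[i] = nr
            cols[i] = nc
            moved[i] = True
            bound[i] = k == PRO
    # a tracer that attempted but failed to move re-binds if it sits on a PRO
    for i in range(n_tr):
        if dirs[i] >= 0 and not moved[i]:
            bound[i] = site[rows[i], cols[i]] == PRO


@njit(cache=True)
def step_independent(site, rows, cols, drow, dcol, bound,
                     dirs, uref1, p_reflect, moved):
    """One time step without tracer-tracer exclusion.

    Tracers are independent: any number may share a site and bind the same
    PRO.  Obstacle rules (CRO reflection, PRO partial reflection and
    binding) are unchanged.
    """
    n = site.shape[0]
    for i in range(rows.size):
        d = dirs[i]
        if d < 0:
            continue
        nr = rows[i] + _DR[d]
        nc = cols[i] + _DC[d]
        if nr < 0:
            nr += n
        elif nr >= n:
            nr -= n
        if nc < 0:
            nc += n
        elif nc >= n:
            nc -= n
        k = site[nr, nc]
        if k == CRO or (k == PRO and uref1[i] < p_reflect):
            bound[i] = site[rows[i], cols[i]] == PRO
            continue
        drow[i] += _DR[d]
        dcol[i] += _DC[d]
        rows[i] = nr
        cols[i] = nc
        moved[i] = True
        bound[i] = k == PRO


@njit(cache=True)
def run_lattice(site, rows0, cols0, bound0, exclusion, recursive, literal_escape,
                p_reflect, p_escape, n_anneal, n_measure, record_every,
                seed, record_traj):
    """Anneal then measure a lattice population; single-seed deterministic.

    Returns per-frame (sum over tracers of squared unwrapped displacement,
    bound fraction), an optional full displacement trajectory, the bound
    fraction sampled during annealing, and the final tracer state.
    """
    np.random.seed(seed)
    n_tr = rows0.size
    rows = rows0.copy()
    cols = cols0.copy()
    bound = bound0.copy()
    n = site.shape[0]
    occ = np.zeros((n, n), dtype=np.uint8)
    if exclusion:
        for i in range(n_tr):
            occ[rows[i], cols[i]] = 1
    drow = np.zeros(n_tr, dtype=np.int64)
    dcol = np.zeros(n_tr, dtype=np.int64)
    dirs = np.empty(n_tr, dtype=np.int64)
    uref1 = np.empty(n_tr, dtype=np.float64)
    uref2 = np.empty(n_tr, dtype=np.float64)
    moved = np.zeros(n_tr, dtype=np.bool_)
    blocked = np.zeros(n_tr, dtype=np.bool_)

    n_arec = n_anneal // record_every if record_every > 0 else 0
    anneal_bound = np.zeros(n_arec, dtype=np.float64)
    for t in range(1, n_anneal + 1):
        draw_moves(bound, p_escape, literal_escape, dirs, uref1)
        for i in range(n_tr):
            moved[i] = False
            blocked[i] = False
        if exclusion:
            for i in range(n_tr):
                uref2[i] = np.random.random()
            step_exclusion(site, occ, rows, cols, drow, dcol, bound,
                           dirs, uref1, uref2, p_reflect, recursive, moved, blocked)
        else:
            step_independent(site, rows, cols, drow, dcol, bound,
                             dirs, uref1, p_reflect, moved)
        if record_every > 0 and t % record_every == 0:
            f = t // record_every - 1
            nb = 0
            for i in range(n_tr):
                if bound[i]:
                    nb += 1
            anneal_bound[f] = nb / max(n_tr, 1)

    # measurement clock starts here: zero the displacement accumulators
    for i in range(n_tr):
        drow[i] = 0
        dcol[i] = 0
    n_frames = n_measure // record_every if record_every > 0 else 0
    msd_sum = np.zeros(n_frames, dtype=np.float64)
    bound_frac = np.zeros(n_frames, dtype=np.float64)
    nf_traj = n_frames if record_traj else 0
    traj = np.zeros((nf_traj, n_tr, 2), dtype=np.int64)
    for t in range(1, n_measure + 1):
        draw_moves(bound, p_escape, literal_escape, dirs, uref1)
        for i in range(n_tr):
            moved[i] = False
            blocked[i] = False
        if exclusion:
            for i in range(n_tr):
                uref2[i] = np.random.random()
            step_exclusion(site, occ, rows, cols, drow, dcol, bound,
                           dirs, uref1, uref2, p_reflect, recursive, moved, blocked)
        else:
            step_independent(site, rows, cols, drow, dcol, bound,
                             dirs, uref1, p_reflect, moved)
        if record_every > 0 and t % record_every == 0:
            f = t // record_every - 1
            s = 0.0
            nb = 0
            for i in range(n_tr):
                s += drow[i] * drow[i] + dcol[i] * dcol[i]
                if bound[i]:
                    nb += 1
            msd_sum[f] = s
            bound_frac[f] = nb / max(n_tr, 1)
            if record_traj:
                for i in range(n_tr):
                    traj[f, i, 0] = drow[i]
                    traj[f, i, 1] = dcol[i]
    return msd_sum, bound_frac, traj, anneal_bound, rows, cols, drow, dcol, bound


@njit(cache=True)
def _wrap(v, box):
    if v >= box:
        return v - box
    if v < 0.0:
        return v + box
    return v


@njit(cache=True)
def _overlaps_allpairs(x, y, nx, ny, i, box, d2min):
    half = 0.5 * box
    for j in range(x.size):
        if j == i:
            continue
        ddx = x[j] - nx
        if ddx > half:
            ddx -= box
        elif ddx < -half:
            ddx += box
        ddy = y[j] - ny
        if ddy > half:
            ddy -= box
        elif ddy < -half:
            ddy += box
        if ddx * ddx + ddy * ddy < d2min:
            return True
    return False


@njit(cache=True)
def _overlaps_cells(x, y, nx, ny, i, box, d2min, ncell, head, nxt):
    half = 0.5 * box
    ci = int(nx / box * ncell)
    cj = int(ny / box * ncell)
    if ci >= ncell:
        ci = ncell - 1
    if cj >= ncell:
        cj = ncell - 1
    # 5x5 neighbourhood: the cell list is rebuilt once per sweep, so a disk
    # that moved earlier in the sweep may sit one cell away from its listed
    # cell; one-step displacements are far smaller than a cell width.
    for a in range(ci - 2, ci + 3):
        ca = a % ncell
        for b in range(cj - 2, cj + 3):
            cb = b % ncell
            j = head[ca * ncell + cb]
            while j >= 0:
                if j != i:
                    ddx = x[j] - nx
                    if ddx > half:
                        ddx -= box
                    elif ddx < -half:
                        ddx += box
                    ddy = y[j] - ny
                    if ddy > half:
                        ddy -= box
                    elif ddy < -half:
                        ddy += box
                    if ddx * ddx + ddy * ddy < d2min:
                        return True
                j = nxt[j]
    return False


@njit(cache=True)
def sweep_disks(x, y, ux, uy, px, py, box, d2min, use_exclusion,
                ncell, head, nxt):
    """One sequential Metropolis-style sweep over all disks.

    px/py are the pre-drawn Gaussian displacement proposals.  A proposal
    bringing any pair of centres closer than 2*radius (minimum image) is
    rejected and the disk keeps its position; accepted moves update the
    unwrapped accumulators.  Returns the number of accepted moves.
    """
    n_disks = x.size
    use_cells = ncell >= 5 and use_exclusion
    if use_cells:
        for c in range(ncell * ncell):
            head[c] = -1
        for i in range(n_disks):
            ci = int(x[i] / box * ncell)
            cj = int(y[i] / box * ncell)
            if ci >= ncell:
                ci = ncell - 1
            if cj >= ncell:
                cj = ncell - 1
            c = ci * ncell + cj
            nxt[i] = head[c]
            head[c] = i
    accepted = 0
    for i in range(n_disks):
        nx = _wrap(x[i] + px[i], box)
        ny = _wrap(y[i] + py[i], box)
        if use_exclusion and n_disks > 1:
            if use_cells:
                if _overlaps_cells(x, y, nx, ny, i, box, d2min, ncell, head, nxt):
                    continue
            else:
                if _overlaps_allpairs(x, y, nx, ny, i, box, d2min):
                    continue
        x[i] = nx
        y[i] = ny
        ux[i] += px[i]
        uy[i] += py[i]
        accepted += 1
    return accepted


@njit(cache=True)
def run_disks(x0, y0, box, radius, sigma, use_exclusion,
              n_anneal, n_steps, record_every, seed, record_traj):
    """Anneal then measure a hard-disk system; single-seed deterministic.

    Returns per-frame summed squared unwrapped displacement (um^2), an
    optional full trajectory, final positions, and the overall move
    acceptance fraction during measurement.
    """
    np.random.seed(seed)
    n_disks = x0.size
    x = x0.copy()
    y = y0.copy()
    ux = np.zeros(n_disks, dtype=np.float64)
    uy = np.zeros(n_disks, dtype=np.float64)
    px = np.empty(n_disks, dtype=np.float64)
    py = np.empty(n_disks, dtype=np.float64)
    d2min = 4.0 * radius * radius
    ncell = int(box / (2.0 * radius)) if radius > 0 else 0
    if ncell < 5 or n_disks <= 16:
        ncell = 0
    head = np.full(max(ncell * ncell, 1), -1, dtype=np.int64)
    nxt = np.full(max(n_disks, 1), -1, dtype=np.int64)

    for _ in range(n_anneal):
        for i in range(n_disks):
            px[i] = sigma * np.random.standard_normal()
            py[i] = sigma * np.random.standard_normal()
        sweep_disks(x, y, ux, uy, px, py, box, d2min, use_exclusion, ncell, head, nxt)
    for i in range(n_disks):
        ux[i] = 0.0
        uy[i] = 0.0

    n_frames = n_steps // record_every if record_every > 0 else 0
    msd_sum = np.zeros(n_frames, dtype=np.float64)
    nf_traj = n_frames if record_traj else 0
    traj = np.zeros((nf_traj, n_disks, 2), dtype=np.float64)
    accepted = 0
    proposed = 0
    for t in range(1, n_steps + 1):
        for i in range(n_disks):
            px[i] = sigma * np.random.standard_normal()
            py[i] = sigma * np.random.standard_normal()
        accepted += sweep_disks(x, y, ux, uy, px, py, box, d2min,
                                use_exclusion, ncell, head, nxt)
        proposed += n_disks
        if record_every > 0 and t % record_every == 0:
            f = t // record_every - 1
            s = 0.0
            for i in range(n_disks):
                s += ux[i] * ux[i] + uy[i] * uy[i]
            msd_sum[f] = s
            if record_traj:
                for i in range(n_disks):
                    traj[f, i, 0] = ux[i]
                    traj[f, i, 1] = uy[i]
    acc_rate = accepted / proposed if proposed > 0 else 1.0
    return msd_sum, traj, x, y, acc_rate
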