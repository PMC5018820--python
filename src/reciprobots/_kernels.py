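"""Compiled simulation kernels (numba) shared by the arena, assay and
evolution layers.

All randomness flows through a tiny splitmix64 stream whose 1-element
uint64 state array is passed explicitly, so the step-level API and the
full-evaluation kernel share one generator and one documented draw order:
per step, first any food-respawn draws (two uniforms per item eaten, robots
in index order), then exactly one stuck/release uniform per robot in index
order.

Geometry: continuous coordinates in [0, side) metres on a torus, origin
bottom-left, angles counter-clockwise from +x.  Wheel velocities are in
cm/s; positions in metres; dt in seconds.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# indices into the params array (see ArenaConfig.params_array)
P_SIDE = 0
P_ROBOT_R = 1
P_FOOD_R = 2
P_DT = 3
P_VMAX = 4
P_PSELF = 5
P_HELPMULT = 6
P_HELPGAP = 7
P_PROXRANGE = 8
N_PARAMS = 9

CONE_HALF = math.pi / 6.0  # 60 degree camera cone
SECTOR = math.pi / 9.0  # three 20 degree sectors

STATUS_OK = 0
STATUS_PLACEMENT_FAILED = 1

_INV_2_53 = 1.0 / 9007199254740992.0


@njit(cache=True)
def _next_u64(rs):
    rs[0] = rs[0] + np.uint64(0x9E3779B97F4A7C15)
    z = rs[0]
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True)
def _uniform(rs):
    return float(_next_u64(rs) >> np.uint64(11)) * _INV_2_53


@njit(cache=True)
def _wrap(x, side):
    x = x % side
    if x < 0.0:
        x += side
    return x


@njit(cache=True)
def _sdelta(a, b, side):
    """Shortest signed displacement from a to b on a circle of length side."""
    d = b - a
    d -= side * math.floor(d / side + 0.5)
    return d


@njit(cache=True)
def _angdiff(a):
    """Wrap an angle to [-pi, pi)."""
    two_pi = 2.0 * math.pi
    return a - two_pi * math.floor((a + math.pi) / two_pi)


@njit(cache=True)
def _torus_dist(ax, ay, bx, by, side):
    dx = _sdelta(ax, bx, side)
    dy = _sdelta(ay, by, side)
    return math.sqrt(dx * dx + dy * dy)


@njit(cache=True)
def sense_proximity(px, py, heading, qx, qy, see, params, out):
    """Eight proximity activations; sensor k faces heading + k*45 degrees.

    Only the partner robot is a solid detectable body.  Activation falls
    linearly from 1 at contact to 0 at the sensor range (edge-to-edge).
    """
    for k in range(8):
        out[k] = 0.0
    if see == 0:
        return
    side = params[P_SIDE]
    diam = 2.0 * params[P_ROBOT_R]
    prange = params[P_PROXRANGE]
    dx = _sdelta(px, qx, side)
    dy = _sdelta(py, qy, side)
    dist = math.sqrt(dx * dx + dy * dy)
    gap = dist - diam
    if gap >= prange:
        return
    a = 1.0 if gap <= 0.0 else 1.0 - gap / prange
    bearing = _angdiff(math.atan2(dy, dx) - heading)
    k = int(math.floor(bearing / (math.pi / 4.0) + 0.5)) % 8
    out[k] = a


@njit(cache=True)
def sense_camera(px, py, heading, qx, qy, q_stuck, see, food, params, out):
    """Nine camera activations: colors red/green/blue x three 20deg sectors.

    ``out[color*3 + sector]`` is the fraction of the sector's angular width
    covered by the nearest visible object of that color.  Food items render
    red; the partner renders green when mobile and blue when stuck.
    Sectors are ordered from relative bearing -30deg to +30deg.
    """
    for k in range(9):
        out[k] = 0.0
    side = params[P_SIDE]
    robot_r = params[P_ROBOT_R]
    food_r = params[P_FOOD_R]

    lo = np.empty(4)
    hi = np.empty(4)
    dep = np.empty(4)
    col = np.empty(4, np.int64)
    nobj = 0

    nfood = food.shape[0]
    for i in range(nfood + 1):
        if i < nfood:
            ox, oy, orad = food[i, 0], food[i, 1], food_r
            c = 0  # red
        else:
            if see == 0:
                continue
            ox, oy, orad = qx, qy, robot_r
            c = 2 if q_stuck else 1  # blue when stuck, green otherwise
        dx = _sdelta(px, ox, side)
        dy = _sdelta(py, oy, side)
        dist = math.sqrt(dx * dx + dy * dy)
        if dist < 1e-12:
            continue
        ratio = orad / dist
        half = math.pi / 2.0 if ratio >= 1.0 else math.asin(ratio)
        rel = _angdiff(math.atan2(dy, dx) - heading)
        a = rel - half
        b = rel + half
        if b < -CONE_HALF or a > CONE_HALF:
            continue
        lo[nobj] = max(a, -CONE_HALF)
        hi[nobj] = min(b, CONE_HALF)
        dep[nobj] = dist
        col[nobj] = c
        nobj += 1

    if nobj == 0:
        return

    # breakpoints: sector edges plus clamped interval endpoints
    bp = np.empty(4 + 2 * 4)
    bp[0] = -CONE_HALF
    bp[1] = -CONE_HALF + SECTOR
    bp[2] = CONE_HALF - SECTOR
    bp[3] = CONE_HALF
    nb = 4
    for j in range(nobj):
        bp[nb] = lo[j]
        bp[nb + 1] = hi[j]
        nb += 2
    # insertion sort of the small breakpoint list
    for i in range(1, nb):
        v = bp[i]
        j = i - 1
        while j >= 0 and bp[j] > v:
            bp[j + 1] = bp[j]
            j -= 1
        bp[j + 1] = v

    for i in range(nb - 1):
        x0 = bp[i]
        x1 = bp[i + 1]
        w = x1 - x0
        if w <= 1e-15:
            continue
        m = 0.5 * (x0 + x1)
        best = -1
        bestd = 1e300
        for j in range(nobj):
            if lo[j] <= m <= hi[j] and dep[j] < bestd:
                best = j
                bestd = dep[j]
        if best >= 0:
            sec = int((m + CONE_HALF) / SECTOR)
            if sec < 0:
                sec = 0
            elif sec > 2:
                sec = 2
            out[col[best] * 3 + sec] += w / SECTOR


@njit(cache=True)
def forward(w_in, w_out, x, vmax, vel_out):
    """Logistic network forward pass; writes wheel velocities in cm/s."""
    nh = w_in.shape[0]
    nin = w_in.shape[1]
    h = np.empty(nh + 1)
    for i in range(nh):
        s = 0.0
        for j in range(nin):
            s += w_in[i, j] * x[j]
        h[i] = 1.0 / (1.0 + math.exp(-s))
    h[nh] = 1.0
    for o in range(w_out.shape[0]):
        s = 0.0
        for j in range(nh + 1):
            s += w_out[o, j] * h[j]
        vel_out[o] = -vmax + 2.0 * vmax / (1.0 + math.exp(-s))


@njit(cache=True)
def step_core(
    pos,
    heading,
    stuck,
    food,
    food_counts,
    mem_opp,
    mem_help,
    helping_given,
    vel,
    params,
    pstuck,
    can_self,
    rs,
    ev,
):
    """Advance the world by one step.

    ``vel`` holds per-robot (left, right) wheel velocities in cm/s; stuck
    robots do not move regardless of it.  ``ev`` (2, 3) reports per-robot
    events this step: [stuck onset, released, release was helped].
    """
    side = params[P_SIDE]
    robot_r = params[P_ROBOT_R]
    diam = 2.0 * robot_r
    dt = params[P_DT]
    axle = diam  # metres

    # differential-drive motion (Euler: translate along old heading, then turn)
    for r in range(2):
        ev[r, 0] = 0
        ev[r, 1] = 0
        ev[r, 2] = 0
        if stuck[r]:
            continue
        vl = vel[r, 0]
        vr = vel[r, 1]
        v = 0.5 * (vl + vr) * 0.01  # m/s
        omega = (vr - vl) * 0.01 / axle  # rad/s
        pos[r, 0] = _wrap(pos[r, 0] + v * dt * math.cos(heading[r]), side)
        pos[r, 1] = _wrap(pos[r, 1] + v * dt * math.sin(heading[r]), side)
        heading[r] = _angdiff(heading[r] + omega * dt)

    # hard-disc collision: project so the discs end in contact, never overlapping
    dx = _sdelta(pos[0, 0], pos[1, 0], side)
    dy = _sdelta(pos[0, 1], pos[1, 1], side)
    dist = math.sqrt(dx * dx + dy * dy)
    if dist < diam:
        if dist < 1e-12:
            nx = math.cos(heading[0])
            ny = math.sin(heading[0])
        else:
            nx = dx / dist
            ny = dy / dist
        overlap = diam - dist
        m0 = stuck[0] == 0
        m1 = stuck[1] == 0
        if m0 and m1:
            s0 = 0.5 * overlap
            s1 = 0.5 * overlap
        elif m0:
            s0 = overlap
            s1 = 0.0
        elif m1:
            s0 = 0.0
            s1 = overlap
        else:
            s0 = 0.0
            s1 = 0.0
        pos[0, 0] = _wrap(pos[0, 0] - nx * s0, side)
        pos[0, 1] = _wrap(pos[0, 1] - ny * s0, side)
        pos[1, 0] = _wrap(pos[1, 0] + nx * s1, side)
        pos[1, 1] = _wrap(pos[1, 1] + ny * s1, side)

    # eating: moving over a food item consumes it; it respawns uniformly
    # (stuck robots cannot move, hence cannot eat)
    eat_r = robot_r + params[P_FOOD_R]
    for r in range(2):
        if stuck[r]:
            continue
        for f in range(food.shape[0]):
            if _torus_dist(pos[r, 0], pos[r, 1], food[f, 0], food[f, 1], side) < eat_r:
                food_counts[r] += 1
                food[f, 0] = _uniform(rs) * side
                food[f, 1] = _uniform(rs) * side

    # stochastic sticking and release (one uniform per robot, fixed order)
    pself = params[P_PSELF]
    helpmult = params[P_HELPMULT]
    helpgap = params[P_HELPGAP]
    for r in range(2):
        u = _uniform(rs)
        o = 1 - r
        if stuck[r] == 0:
            if u < pstuck[r]:
                stuck[r] = 1
                ev[r, 0] = 1
        else:
            gap = (
                _torus_dist(pos[r, 0], pos[r, 1], pos[o, 0], pos[o, 1], side) - diam
            )
            helped_now = gap < helpgap
            if helped_now:
                hazard = helpmult * pself
            elif can_self[r]:
                hazard = pself
            else:
                hazard = 0.0
            if u < hazard:
                stuck[r] = 0
                mem_opp[r] += 1
                ev[r, 1] = 1
                if helped_now:
                    mem_help[r] += 1
                    helping_given[o] += 1
                    ev[r, 2] = 1


@njit(cache=True)
def place_robots(rs, params, min_gap, pos, heading):
    """Uniform random non-overlapping placement; returns a status code."""
    side = params[P_SIDE]
    diam = 2.0 * params[P_ROBOT_R]
    pos[0, 0] = _uniform(rs) * side
    pos[0, 1] = _uniform(rs) * side
    heading[0] = _angdiff(_uniform(rs) * 2.0 * math.pi)
    heading[1] = _angdiff(_uniform(rs) * 2.0 * math.pi)
    for _ in range(1000):
        pos[1, 0] = _uniform(rs) * side
        pos[1, 1] = _uniform(rs) * side
        d = _torus_dist(pos[0, 0], pos[0, 1], pos[1, 0], pos[1, 1], side)
        if d - diam >= min_gap:
            return STATUS_OK
    return STATUS_PLACEMENT_FAILED


@njit(cache=True)
def run_eval(
    w_in0,
    w_out0,
    w_in1,
    w_out1,
    has_memory,
    clamp,
    see,
    params,
    pstuck,
    can_self,
    n_steps,
    n_food,
    init_stuck,
    min_gap,
    end_on_release_of,
    seed,
    record,
    traj,
):
    """One full evaluation of a robot pair.

    Sense -> network -> world step, for ``n_steps`` steps (or until robot
    ``end_on_release_of`` is released, if >= 0).  Stuck robots skip sensing
    and the network (their motors are ignored anyway).

    Returns (status, steps_done, food_counts, helping_given, mem_opp,
    mem_help, n_ep, ep_start, ep_end, ep_helped).  Episodes with
    ``helped == -1`` were still ongoing at the end (censored); robots stuck
    from initialization have episode start -1 so that duration is always
    ``end - start``.
    """
    rs = np.empty(1, np.uint64)
    rs[0] = seed

    pos = np.empty((2, 2))
    heading = np.empty(2)
    status = place_robots(rs, params, min_gap, pos, heading)
    food = np.empty((n_food, 2))
    for f in range(n_food):
        food[f, 0] = _uniform(rs) * params[P_SIDE]
        food[f, 1] = _uniform(rs) * params[P_SIDE]

    stuck = np.empty(2, np.uint8)
    cur_start = np.empty(2, np.int64)
    for r in range(2):
        stuck[r] = init_stuck[r]
        cur_start[r] = -1  # robots stuck at t=0 count from before step 0

    food_counts = np.zeros(2, np.int64)
    mem_opp = np.zeros(2, np.int64)
    mem_help = np.zeros(2, np.int64)
    helping_given = np.zeros(2, np.int64)
    ev = np.zeros((2, 3), np.int64)

    cap = n_steps // 2 + 2
    ep_start = np.empty((2, cap), np.int64)
    ep_end = np.empty((2, cap), np.int64)
    ep_helped = np.empty((2, cap), np.int64)
    n_ep = np.zeros(2, np.int64)

    if status != STATUS_OK:
        return (
            status,
            0,
            food_counts,
            helping_given,
            mem_opp,
            mem_help,
            n_ep,
            ep_start,
            ep_end,
            ep_helped,
        )

    nin = w_in0.shape[1]  # 1 + sensor count
    x = np.empty(nin)
    vel = np.zeros((2, 2))
    vmax = params[P_VMAX]
    steps_done = n_steps

    for t in range(n_steps):
        for r in range(2):
            if stuck[r]:
                vel[r, 0] = 0.0
                vel[r, 1] = 0.0
                continue
            o = 1 - r
            x[0] = 1.0
            sense_proximity(
                pos[r, 0],
                pos[r, 1],
                heading[r],
                pos[o, 0],
                pos[o, 1],
                see[r],
                params,
                x[1:9],
            )
            sense_camera(
                pos[r, 0],
                pos[r, 1],
                heading[r],
                pos[o, 0],
                pos[o, 1],
                stuck[o],
                see[r],
                food,
                params,
                x[9:18],
            )
            if has_memory:
                if clamp[r] >= 0:
                    x[18] = float(clamp[r])
                elif mem_opp[r] == 0:
                    x[18] = 1.0
                else:
                    x[18] = mem_help[r] / mem_opp[r]
            if r == 0:
                forward(w_in0, w_out0, x, vmax, vel[0])
            else:
                forward(w_in1, w_out1, x, vmax, vel[1])

        step_core(
            pos,
            heading,
            stuck,
            food,
            food_counts,
            mem_opp,
            mem_help,
            helping_given,
            vel,
            params,
            pstuck,
            can_self,
            rs,
            ev,
        )

        for r in range(2):
            if ev[r, 0]:
                cur_start[r] = t
            if ev[r, 1] and n_ep[r] < cap:
                k = n_ep[r]
                ep_start[r, k] = cur_start[r]
                ep_end[r, k] = t
                ep_helped[r, k] = ev[r, 2]
                n_ep[r] = k + 1

        if record:
            traj[t, 0] = pos[0, 0]
            traj[t, 1] = pos[0, 1]
            traj[t, 2] = heading[0]
            traj[t, 3] = float(stuck[0])
            traj[t, 4] = pos[1, 0]
            traj[t, 5] = pos[1, 1]
            traj[t, 6] = heading[1]
            traj[t, 7] = float(stuck[1])
            traj[t, 8] = float(food_counts[0])
            traj[t, 9] = float(food_counts[1])
            traj[t, 10] = 1.0 if mem_opp[0] == 0 else mem_help[0] / mem_opp[0]
            traj[t, 11] = 1.0 if mem_opp[1] == 0 else mem_help[1] / mem_opp[1]

        if end_on_release_of >= 0 and ev[end_on_release_of, 1]:
            steps_done = t + 1
            break

    # censored episodes: still stuck when the evaluation ended
    for r in range(2):
        if stuck[r] and n_ep[r] < cap:
            k = n_ep[r]
            ep_start[r, k] = cur_start[r]
            ep_end[r, k] = steps_done - 1
            ep_helped[r, k] = -1
            n_ep[r] = k + 1

    return (
        STATUS_OK,
        steps_done,
        food_counts,
        helping_given,
        mem_opp,
        mem_help,
        n_ep,
        ep_start,
        ep_end,
        ep_helped,
    )


@njit(cache=True)
def stuck_episode_durations(n_episodes, partner_gap, params, can_self_flag, seed):
    """Durations (in steps) of repeated stuck episodes of a motionless robot.

    The partner sits at a fixed edge-to-edge gap ``partner_gap`` and never
    moves, so the release hazard is constant throughout each episode; the
    sampling runs through the same step/release code as full evaluations.
    """
    rs = np.empty(1, np.uint64)
    rs[0] = seed
    side = params[P_SIDE]
    diam = 2.0 * params[P_ROBOT_R]

    pos = np.empty((2, 2))
    pos[0, 0] = 0.2
    pos[0, 1] = 0.2
    pos[1, 0] = _wrap(0.2 + diam + partner_gap, side)
    pos[1, 1] = 0.2
    heading = np.zeros(2)
    food = np.empty((2, 2))
    food[0, 0] = 0.7
    food[0, 1] = 0.7
    food[1, 0] = 0.7
    food[1, 1] = 0.5
    stuck = np.empty(2, np.uint8)
    stuck[1] = 0
    food_counts = np.zeros(2, np.int64)
    mem_opp = np.zeros(2, np.int64)
    mem_help = np.zeros(2, np.int64)
    helping_given = np.zeros(2, np.int64)
    vel = np.zeros((2, 2))
    pstuck = np.zeros(2)
    can_self = np.empty(2, np.uint8)
    can_self[0] = can_self_flag
    can_self[1] = 1
    ev = np.zeros((2, 3), np.int64)

    durations = np.empty(n_episodes, np.int64)
    for i in range(n_episodes):
        stuck[0] = 1
        t = 0
        while True:
            t += 1
            step_core(
                pos,
                heading,
                stuck,
                food,
                food_counts,
                mem_opp,
                mem_help,
                helping_given,
                vel,
                params,
                pstuck,
                can_self,
                rs,
                ev,
            )
            if ev[0, 1]:
                durations[i] = t
                break
    return durations
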