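"""Numba kernels for the lattice simulator and lineage walks.

All kernels operate on flat (row-major) lattice indices ``i = y*W + x``.
The event loop keeps, per growth-rate class, a swap-removal active list of
eligible sites (occupied, positive rate, >=1 colonizable empty 4-neighbor),
so mother selection is O(1) per event: there are at most four distinct
rates on the lattice — 1, 1+s, k and k*(1+s).
"""

import numpy as np
from numba import njit

# termination codes
REACHED_N = 0
PINNED = 1
MAX_EVENTS = 2
EDGE = 3

# fixed neighbor scan order: +x, -x, +y, -y
_DX = np.array([1, -1, 0, 0], dtype=np.int64)
_DY = np.array([0, 0, 1, -1], dtype=np.int64)


@njit(cache=True, inline="always")
def _neighbor(i, j, W, H, linear):
    """j-th 4-neighbor of flat site i, or -1 if outside the lattice.

    Linear geometry is periodic in x and open in y."""
    x = i % W
    y = i // W
    nx = x + _DX[j]
    ny = y + _DY[j]
    if linear:
        if nx < 0:
            nx += W
        elif nx >= W:
            nx -= W
        if ny < 0 or ny >= H:
            return -1
    else:
        if nx < 0 or nx >= W or ny < 0 or ny >= H:
            return -1
    return ny * W + nx


@njit(cache=True, inline="always")
def _colonizable(i, occ, dis, k):
    """Empty site that a daughter may occupy; at k=0 obstacles are impassable."""
    if occ[i] != 0:
        return False
    if k == 0.0 and dis[i] != 0:
        return False
    return True


@njit(cache=True, inline="always")
def _has_open_neighbor(i, occ, dis, k, W, H, linear):
    for j in range(4):
        n = _neighbor(i, j, W, H, linear)
        if n >= 0 and _colonizable(n, occ, dis, k):
            return True
    return False


@njit(cache=True, inline="always")
def _site_class(i, geno, dis, k):
    # at k == 1 the disorder label is dynamically inert; collapsing the class
    # keeps trajectories bit-identical to rho=0 for the same seed
    if k == 1.0:
        return np.int64(geno[i])
    return np.int64(dis[i]) * 2 + np.int64(geno[i])


@njit(cache=True)
def run_kernel(
    occ,
    geno,
    clone,
    dis,
    W,
    H,
    linear,
    k,
    s,
    mu,
    n_target,
    h_target,
    max_events,
    edge_margin,
    seed,
    colh,
    log_mother,
    log_daughter,
    log_time,
    log_geno,
    log_clone,
    log_mut,
):
    """Run the generalized Eden model until a stopping condition.

    Returns (n_events, termination_code, t_final, n_occupied, next_clone_id).
    ``colh`` (length W) is the running per-column max height, used for the
    mean-front-height stop in linear geometry; pass a zero array for radial.
    """
    np.random.seed(seed)
    n_sites = W * H

    rate = np.empty(4, dtype=np.float64)
    rate[0] = 1.0
    rate[1] = 1.0 + s
    rate[2] = k
    rate[3] = k * (1.0 + s)

    act = np.empty((4, n_sites), dtype=np.int32)
    n_act = np.zeros(4, dtype=np.int64)
    pos = np.full(n_sites, -1, dtype=np.int32)
    cls_of = np.zeros(n_sites, dtype=np.int8)

    n_occ = 0
    hsum = np.int64(0)
    for i in range(n_sites):
        if occ[i] != 0:
            n_occ += 1
            c = _site_class(i, geno, dis, k)
            cls_of[i] = c
            if rate[c] > 0.0 and _has_open_neighbor(i, occ, dis, k, W, H, linear):
                pos[i] = n_act[c]
                act[c, n_act[c]] = i
                n_act[c] += 1
    if linear:
        for x in range(W):
            colh[x] = 0

    next_clone = 1
    t = 0.0
    n_events = 0
    code = MAX_EVENTS

    while n_events < max_events:
        total = 0.0
        for c in range(4):
            if rate[c] > 0.0:
                total += rate[c] * n_act[c]
        if total <= 0.0:
            code = PINNED
            break

        # one draw selects both the rate class and the member within it
        u = np.random.random() * total
        m = -1
        acc = 0.0
        for c in range(4):
            if rate[c] <= 0.0 or n_act[c] == 0:
                continue
            w = rate[c] * n_act[c]
            if u < acc + w:
                member = int((u - acc) / rate[c])
                if member >= n_act[c]:
                    member = n_act[c] - 1
                m = act[c, member]
                break
            acc += w
        if m < 0:  # numerical fallthrough
            for c in range(3, -1, -1):
                if rate[c] > 0.0 and n_act[c] > 0:
                    m = act[c, n_act[c] - 1]
                    break

        # daughter site: uniform among colonizable empty neighbors
        nnb = 0
        nbuf = np.empty(4, dtype=np.int64)
        for j in range(4):
            n = _neighbor(m, j, W, H, linear)
            if n >= 0 and _colonizable(n, occ, dis, k):
                nbuf[nnb] = n
                nnb += 1
        j = int(np.random.random() * nnb)
        if j >= nnb:
            j = nnb - 1
        d = nbuf[j]

        # inheritance and mutation (daughter mutates; mutants never revert)
        g = geno[m]
        cl = clone[m]
        mut = 0
        if g == 0 and mu > 0.0:
            if np.random.random() < mu:
                g = 1
                cl = next_clone
                next_clone += 1
                mut = 1

        occ[d] = 1
        geno[d] = g
        clone[d] = cl
        t += 1.0 / total
        n_occ += 1

        log_mother[n_events] = m
        log_daughter[n_events] = d
        log_time[n_events] = t
        log_geno[n_events] = g
        log_clone[n_events] = cl
        log_mut[n_events] = mut
        n_events += 1

        # activate daughter if eligible
        c = _site_class(d, geno, dis, k)
        cls_of[d] = c
        if rate[c] > 0.0 and _has_open_neighbor(d, occ, dis, k, W, H, linear):
            pos[d] = n_act[c]
            act[c, n_act[c]] = d
            n_act[c] += 1
        # neighbors of d (incl. mother) may have lost their last open site
        for j in range(4):
            n = _neighbor(d, j, W, H, linear)
            if n >= 0 and occ[n] != 0 and pos[n] >= 0:
                if not _has_open_neighbor(n, occ, dis, k, W, H, linear):
                    c2 = cls_of[n]
                    p = pos[n]
                    last = act[c2, n_act[c2] - 1]
                    act[c2, p] = last
                    pos[last] = p
                    n_act[c2] -= 1
                    pos[n] = -1

        if linear:
            y = d // W
            x = d % W
            if y > colh[x]:
                hsum += y - colh[x]
                colh[x] = y
            if ny_mean_reached(hsum, W, h_target):
                code = REACHED_N
                break
            if y >= H - 1:
                code = EDGE
                break
        else:
            x = d % W
            y = d // W
            if n_occ >= n_target:
                code = REACHED_N
                break
            if (
                x < edge_margin
                or x >= W - edge_margin
                or y < edge_margin
                or y >= H - edge_margin
            ):
                code = EDGE
                break

    return n_events, code, t, n_occ, next_clone


@njit(cache=True, inline="always")
def ny_mean_reached(hsum, W, h_target):
    return hsum >= h_target * W


@njit(cache=True)
def replay_widths(daughters, W, thresholds):
    """Global interface width W_G at mean-front-height snapshots.

    Replays the division log (daughter flat indices, in order) keeping the
    per-column max height; whenever the mean height crosses the next
    threshold, records rms height fluctuation. Returns (h_mean, W_G, n_done).
    """
    colh = np.zeros(W, dtype=np.float64)
    hsum = 0.0
    n_thr = thresholds.shape[0]
    out_h = np.zeros(n_thr, dtype=np.float64)
    out_w = np.zeros(n_thr, dtype=np.float64)
    out_e = np.zeros(n_thr, dtype=np.int64)
    nxt = 0
    for e in range(daughters.shape[0]):
        d = daughters[e]
        y = d // W
        x = d % W
        if y > colh[x]:
            hsum += y - colh[x]
            colh[x] = y
        while nxt < n_thr and hsum / W >= thresholds[nxt]:
            mean = hsum / W
            var = 0.0
            for i in range(W):
                var += (colh[i] - mean) ** 2
            out_h[nxt] = mean
            out_w[nxt] = np.sqrt(var / W)
            out_e[nxt] = e
            nxt += 1
        if nxt >= n_thr:
            break
    return out_h, out_w, out_e, nxt


@njit(cache=True)
def mrca_pairs(parent, birth_order, leaves_a, leaves_b):
    """MRCA (flat site) for each leaf pair, by walking the younger branch up.

    ``birth_order`` is the birth event index per site (-1 for the founder),
    which strictly orders every ancestor chain."""
    n = leaves_a.shape[0]
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        a = leaves_a[i]
        b = leaves_b[i]
        while a != b:
            if birth_order[a] > birth_order[b]:
                a = parent[a]
            else:
                b = parent[b]
        out[i] = a
    return out


@njit(cache=True)
def walk_paths(parent, leaves):
    """Concatenated root-ward paths for each leaf.

    Returns (flat site sequence, start offsets of length n_leaves+1)."""
    n = leaves.shape[0]
    # first pass: lengths
    total = 0
    for i in range(n):
        a = leaves[i]
        length = 1
        while parent[a] >= 0:
            a = parent[a]
            length += 1
        total += length
    sites = np.empty(total, dtype=np.int64)
    offs = np.empty(n + 1, dtype=np.int64)
    p = 0
    for i in range(n):
        offs[i] = p
        a = leaves[i]
        sites[p] = a
        p += 1
        while parent[a] >= 0:
            a = parent[a]
            sites[p] = a
            p += 1
    offs[n] = p
    return sites, offs
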