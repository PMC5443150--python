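"""Numba kernels: closed-itemset enumeration and stability subset sampling.

The miner is an LCM-style depth-first enumeration of closed itemsets using
prefix-preserving closure extension, operating on the CSR transaction
encoding of a formal context.  Each closed set is visited exactly once; no
candidate generation or duplicate check is needed.  The Python-facing
wrappers live in :mod:`spade_stp.mining`.

The stability kernels count, over sampled (or exhaustively enumerated)
bit-masks representing subsets, how many subsets avoid being contained in any
of a family of "spoiler" masks; both intensional and extensional stability
reduce to this primitive (see :mod:`spade_stp.stability`).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["lcm_mine", "count_successes", "count_successes_exact"]


@njit(cache=True)
def _bsearch_contains(arr, lo, hi, x):
    """Is x present in sorted arr[lo:hi]?"""
    while lo < hi:
        mid = (lo + hi) // 2
        v = arr[mid]
        if v == x:
            return True
        if v < x:
            lo = mid + 1
        else:
            hi = mid
    return False


@njit(cache=True)
def _intersect_rows(indptr, indices, T, scratch):
    """Sorted intersection of the item rows of transactions T (the closure).

    Writes into ``scratch`` and returns the number of common items.
    """
    t0 = T[0]
    t1 = T[1]
    j, hj = indptr[t0], indptr[t0 + 1]
    k, hk = indptr[t1], indptr[t1 + 1]
    n = 0
    while j < hj and k < hk:
        x = indices[j]
        y = indices[k]
        if x == y:
            scratch[n] = x
            n += 1
            j += 1
            k += 1
        elif x < y:
            j += 1
        else:
            k += 1
    for ii in range(2, T.shape[0]):
        if n == 0:
            break
        t = T[ii]
        k, hk = indptr[t], indptr[t + 1]
        j = 0
        w = 0
        while j < n and k < hk:
            x = scratch[j]
            y = indices[k]
            if x == y:
                scratch[w] = x
                w += 1
                j += 1
                k += 1
            elif x < y:
                j += 1
            else:
                k += 1
        n = w
    return n


@njit(cache=True)
def _emit(closure, T, out_int, out_int_ptr, out_ext, out_ext_ptr, counters):
    ncl = closure.shape[0]
    nT = T.shape[0]
    p = counters[0]
    ip = counters[1]
    ep = counters[2]
    if (ip + ncl > out_int.shape[0] or ep + nT > out_ext.shape[0]
            or p + 1 >= out_int_ptr.shape[0]):
        counters[3] = 1
        return
    for k in range(ncl):
        out_int[ip + k] = closure[k]
    for k in range(nT):
        out_ext[ep + k] = T[k]
    counters[0] = p + 1
    counters[1] = ip + ncl
    counters[2] = ep + nT
    out_int_ptr[p + 1] = ip + ncl
    out_ext_ptr[p + 1] = ep + nT


@njit(cache=True)
def _grow64(arr, used, extra):
    if used + extra <= arr.shape[0]:
        return arr
    newcap = arr.shape[0] * 2
    while newcap < used + extra:
        newcap *= 2
    out = np.empty(newcap, dtype=arr.dtype)
    out[:used] = arr[:used]
    return out


@njit(cache=True)
def lcm_mine(indptr, indices, colptr, colidx, n_objects, n_attributes,
             min_support, min_size, n_roots,
             out_int, out_int_ptr, out_ext, out_ext_ptr):
    """Enumerate all closed itemsets with support >= min_support.

    Iterative LCM with prefix-preserving closure extension over an explicit
    DFS stack.  Results with fewer than ``min_size`` items are traversed
    (they may extend into larger closed sets) but not emitted.  Returns the
    counters array; counters[3] == 1 signals output-buffer overflow (the
    caller retries with bigger buffers).

    ``n_roots`` restricts the search to subtrees rooted at items
    ``< n_roots``.  Because (with an empty root closure) the generating path
    of every closed set starts at its minimum item, this enumerates exactly
    the closed sets whose minimum item is below ``n_roots`` — the hook used
    to mine only canonical shift-class representatives when items are
    permuted so that offset-0 attributes come first.
    """
    counters = np.zeros(4, dtype=np.int64)
    out_int_ptr[0] = 0
    out_ext_ptr[0] = 0
    if n_objects < min_support or n_objects == 0:
        return counters

    cnt = np.zeros(n_attributes, dtype=np.int64)
    visited = np.empty(indices.shape[0] + 1, dtype=np.int32)

    # root: closure over all objects (items of full support)
    root_n = 0
    for a in range(n_attributes):
        if colptr[a + 1] - colptr[a] == n_objects:
            root_n += 1
    clo_pool = np.empty(max(1024, 4 * root_n), dtype=np.int32)
    j = 0
    for a in range(n_attributes):
        if colptr[a + 1] - colptr[a] == n_objects:
            clo_pool[j] = a
            j += 1
    clo_used = root_n
    if root_n >= min_size:
        T_all = np.arange(n_objects).astype(np.int64)
        _emit(clo_pool[:root_n], T_all, out_int, out_int_ptr, out_ext,
              out_ext_ptr, counters)

    # DFS stack: frames reference slices of ext_pool (tidsets) and clo_pool
    # (parent closures); pools are append-only for the run
    cap_fr = 1024
    fr_ts = np.empty(cap_fr, dtype=np.int64)   # tidset start in ext_pool
    fr_tl = np.empty(cap_fr, dtype=np.int64)   # tidset length
    fr_core = np.empty(cap_fr, dtype=np.int64)
    fr_ps = np.empty(cap_fr, dtype=np.int64)   # parent closure start
    fr_pl = np.empty(cap_fr, dtype=np.int64)   # parent closure length
    ext_pool = np.empty(max(4096, indices.shape[0]), dtype=np.int64)
    ext_used = 0
    sp = 0

    # push root children (reverse order => ascending item pop order)
    for a in range(n_roots - 1, -1, -1):
        sup = colptr[a + 1] - colptr[a]
        if sup < min_support or sup == n_objects:
            continue
        ext_pool = _grow64(ext_pool, ext_used, sup)
        for k in range(sup):
            ext_pool[ext_used + k] = colidx[colptr[a] + k]
        if sp >= fr_ts.shape[0]:
            fr_ts = _grow64(fr_ts, sp, 1)
            fr_tl = _grow64(fr_tl, sp, 1)
            fr_core = _grow64(fr_core, sp, 1)
            fr_ps = _grow64(fr_ps, sp, 1)
            fr_pl = _grow64(fr_pl, sp, 1)
        fr_ts[sp] = ext_used
        fr_tl[sp] = sup
        fr_core[sp] = a
        fr_ps[sp] = 0
        fr_pl[sp] = root_n
        sp += 1
        ext_used += sup

    while sp > 0:
        if counters[3] == 1:
            return counters
        sp -= 1
        ts = fr_ts[sp]
        nT = fr_tl[sp]
        core = fr_core[sp]
        ps = fr_ps[sp]
        npc = fr_pl[sp]
        T = ext_pool[ts:ts + nT]

        if nT == min_support and nT >= 2:
            # no extension can stay frequent without being in the closure,
            # so this node is a leaf: straight row intersection into scratch
            ncl = _intersect_rows(indptr, indices, T, visited)
            ok = True
            for k in range(ncl):
                a = visited[k]
                if a >= core:
                    break
                if not _bsearch_contains(clo_pool, ps, ps + npc, a):
                    ok = False
                    break
            if ok and ncl >= min_size:
                _emit(visited[:ncl], T, out_int, out_int_ptr, out_ext,
                      out_ext_ptr, counters)
            continue

        nv = 0
        for ii in range(nT):
            t = T[ii]
            for k in range(indptr[t], indptr[t + 1]):
                a = indices[k]
                if cnt[a] == 0:
                    visited[nv] = a
                    nv += 1
                cnt[a] += 1

        # closure = items in every transaction; candidates = frequent others
        ncl = 0
        ncand = 0
        for k in range(nv):
            a = visited[k]
            c = cnt[a]
            if c == nT:
                ncl += 1
            elif c >= min_support and a > core:
                ncand += 1
        closure = np.empty(ncl, dtype=np.int32)
        cands = np.empty(ncand, dtype=np.int32)
        sup_c = np.empty(ncand, dtype=np.int64)
        j = 0
        jc = 0
        for k in range(nv):
            a = visited[k]
            c = cnt[a]
            if c == nT:
                closure[j] = a
                j += 1
            elif c >= min_support and a > core:
                cands[jc] = a
                jc += 1
        closure.sort()
        cands.sort()
        for k in range(ncand):
            sup_c[k] = cnt[cands[k]]
        for k in range(nv):
            cnt[visited[k]] = 0

        # prefix-preserving check: no closure item below the core that the
        # parent closure lacks (else this set is reached from another branch)
        ok = True
        for k in range(ncl):
            a = closure[k]
            if a >= core:
                break
            if not _bsearch_contains(clo_pool, ps, ps + npc, a):
                ok = False
                break
        if not ok:
            continue

        if ncl >= min_size:
            _emit(closure, T, out_int, out_int_ptr, out_ext, out_ext_ptr, counters)
        if ncand == 0:
            continue

        # store this closure; push children in reverse candidate order
        clo_pool = _grow64(clo_pool, clo_used, ncl)
        cs = clo_used
        for k in range(ncl):
            clo_pool[cs + k] = closure[k]
        clo_used += ncl

        for k in range(ncand - 1, -1, -1):
            a = cands[k]
            m = sup_c[k]
            ext_pool = _grow64(ext_pool, ext_used, m)
            j = 0
            for ii in range(nT):
                t = T[ii]
                if _bsearch_contains(indices, indptr[t], indptr[t + 1], a):
                    ext_pool[ext_used + j] = t
                    j += 1
            if sp >= fr_ts.shape[0]:
                fr_ts = _grow64(fr_ts, sp, 1)
                fr_tl = _grow64(fr_tl, sp, 1)
                fr_core = _grow64(fr_core, sp, 1)
                fr_ps = _grow64(fr_ps, sp, 1)
                fr_pl = _grow64(fr_pl, sp, 1)
            fr_ts[sp] = ext_used
            fr_tl[sp] = m
            fr_core[sp] = a
            fr_ps[sp] = cs
            fr_pl[sp] = ncl
            sp += 1
            ext_used += m
    return counters


@njit(cache=True)
def count_successes(draws, spoilers, has_outside):
    """Count sampled subset masks contained in no spoiler mask.

    draws: (Z, W) uint64 subset masks; spoilers: (n_S, W) uint64.
    The empty subset always derives to the full dual set, so it succeeds only
    when nothing lies outside the concept (has_outside == False).
    """
    Z, W = draws.shape
    nS = spoilers.shape[0]
    cnt = 0
    for i in range(Z):
        nonzero = False
        for w in range(W):
            if draws[i, w] != np.uint64(0):
                nonzero = True
                break
        if not nonzero:
            if not has_outside:
                cnt += 1
            continue
        ok = True
        for s in range(nS):
            covered = True
            for w in range(W):
                if draws[i, w] & ~spoilers[s, w]:
                    covered = False
                    break
            if covered:
                ok = False
                break
        if ok:
            cnt += 1
    return cnt


@njit(cache=True)
def count_successes_exact(width, spoilers, has_outside):
    """Exhaustive version over all 2**width single-word subset masks."""
    nS = spoilers.shape[0]
    total = np.int64(1) << width
    cnt = 0
    for x in range(total):
        m = np.uint64(x)
        if x == 0:
            if not has_outside:
                cnt += 1
            continue
        ok = True
        for s in range(nS):
            if m & ~spoilers[s, 0] == np.uint64(0):
                ok = False
                break
        if ok:
            cnt += 1
    return cnt
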