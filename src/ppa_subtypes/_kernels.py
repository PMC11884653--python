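"""Numba kernels for the hot inner loops of sequence optimization.

The greedy fit relocates one event at a time and must score all N target
positions against all subjects and stages; doing that in pure numpy spends
most of its time building candidate trajectories.  These kernels fuse
candidate construction, trajectory evaluation and the stage-marginal
log-likelihood into compiled loops (BLAS via ``np.dot`` for the subject x
stage cross terms).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["reloc_objectives", "build_trajectory"]


@njit(cache=True)
def _fill_trajectory(E, b, pos, thr, m, zmax, N):
    """Piecewise-linear trajectory of one biomarker into column b of E.

    Anchors: (0, 0), (pos[a], thr[a]) for a < m, and (N, zmax) unless the
    last threshold event already sits at stage N.
    """
    E[0, b] = 0.0
    last_x = 0.0
    last_y = 0.0
    for a in range(m):
        x = pos[a]
        y = thr[a]
        for k in range(int(last_x) + 1, int(x) + 1):
            E[k, b] = last_y + (y - last_y) * (k - last_x) / (x - last_x)
        last_x = x
        last_y = y
    if last_x < N:
        for k in range(int(last_x) + 1, N + 1):
            E[k, b] = last_y + (zmax - last_y) * (k - last_x) / (N - last_x)


@njit(cache=True)
def build_trajectory(order, ev_bio, bio_thr, bio_nev, zmax, B):
    """Expected-value matrix (N+1, B) for one canonical sequence."""
    N = order.shape[0]
    E = np.zeros((N + 1, B))
    pos = np.empty((B, bio_thr.shape[1]))
    cnt = np.zeros(B, dtype=np.int64)
    for j in range(N):
        b = ev_bio[order[j]]
        pos[b, cnt[b]] = j + 1.0
        cnt[b] += 1
    for b in range(B):
        _fill_trajectory(E, b, pos[b], bio_thr[b], bio_nev[b], zmax[b], N)
    return E


@njit(cache=True)
def reloc_objectives(rest, event, ev_bio, bio_thr, bio_nev, zmax, Ws, ss, weights, L_const, sigma):
    """Objective of relocating ``event`` to each of the N target positions.

    ``rest`` is the current sequence with ``event`` removed (length N-1).
    Candidate q inserts the event at position q (stage q+1) and re-sorts that
    biomarker's thresholds into ascending order, which here amounts to
    assigning the biomarker's ascending thresholds to its ascending anchor
    stages.  Returns the responsibility-weighted stage-marginal log-likelihood
    for every candidate.  Subjects with exactly zero weight are skipped, and
    all candidates' cross terms go through one matrix product.
    """
    N = rest.shape[0] + 1
    B = Ws.shape[1]
    maxR = bio_thr.shape[1]
    obj = np.empty(N)
    pos = np.empty((B, maxR))
    cnt = np.empty(B, dtype=np.int64)
    be = ev_bio[event]

    # trajectories of every candidate, sigma-scaled, flattened over stages
    Es_all = np.zeros((N, N + 1, B))
    for q in range(N):
        for b in range(B):
            cnt[b] = 0
        for j in range(N - 1):
            b = ev_bio[rest[j]]
            stage = j + 1.0 if j < q else j + 2.0
            pos[b, cnt[b]] = stage
            cnt[b] += 1
        # merge the moved event's stage q+1 into its biomarker's sorted stages
        m = cnt[be]
        ins = m
        for a in range(m):
            if pos[be, a] > q + 1.0:
                ins = a
                break
        for a in range(m, ins, -1):
            pos[be, a] = pos[be, a - 1]
        pos[be, ins] = q + 1.0
        cnt[be] = m + 1
        for b in range(B):
            _fill_trajectory(Es_all[q], b, pos[b], bio_thr[b], bio_nev[b], zmax[b], N)
    flat = Es_all.reshape(N * (N + 1), B)
    for r in range(flat.shape[0]):
        for b in range(B):
            flat[r, b] /= sigma[b]

    active = np.flatnonzero(weights != 0.0)
    flatT = flat.T.copy()
    cross = np.dot(Ws[active], flatT).reshape(active.shape[0], N, N + 1)
    buf = np.empty(N + 1)
    for q in range(N):
        EE = np.zeros(N + 1)
        for k in range(N + 1):
            for b in range(B):
                EE[k] += flat[q * (N + 1) + k, b] ** 2
        total = 0.0
        for a in range(active.shape[0]):
            i = active[a]
            dmin = np.inf
            for k in range(N + 1):
                d = ss[i] - 2.0 * cross[a, q, k] + EE[k]
                buf[k] = d
                if d < dmin:
                    dmin = d
            s = 0.0
            for k in range(N + 1):
                dd = buf[k] - dmin
                if dd < 40.0:  # exp(-20) ~ 2e-9: below every tolerance in use
                    s += np.exp(-0.5 * dd)
            total += weights[i] * (L_const - 0.5 * dmin + np.log(s) - np.log(N + 1.0))
        obj[q] = total
    return obj
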