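"""Numba kernels for the alignment-heavy inner loops.

Three kernels live here: an affine-gap local aligner (Gotoh) used by the
seed-and-extend search engine, the profile scorer used by the
sequence+structure model, and a Nussinov base-pair maximiser used to derive
consensus secondary structures.  All scores in the local aligner are
integers, so traceback decisions compare exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int64(-(10**9))


@njit(cache=True)
def gotoh_local(q, s, match, mismatch, gap_open, gap_extend):
    """Smith-Waterman with affine gaps (Gotoh).

    A gap of length g costs ``gap_open + (g - 1) * gap_extend`` (the opening
    position is charged ``gap_open``).  Returns
    ``(score, qstart, qend, sstart, send, n_match, aln_len)`` for the best
    local alignment; all coordinates are 0-based half-open.  The ``N`` code
    (4) never counts as a match.
    """
    nq, ns = q.shape[0], s.shape[0]
    H = np.zeros((nq + 1, ns + 1), dtype=np.int64)
    E = np.full((nq + 1, ns + 1), NEG, dtype=np.int64)
    F = np.full((nq + 1, ns + 1), NEG, dtype=np.int64)
    best = np.int64(0)
    bi = 0
    bj = 0
    for i in range(1, nq + 1):
        for j in range(1, ns + 1):
            e = H[i, j - 1] - gap_open
            if E[i, j - 1] - gap_extend > e:
                e = E[i, j - 1] - gap_extend
            E[i, j] = e
            f = H[i - 1, j] - gap_open
            if F[i - 1, j] - gap_extend > f:
                f = F[i - 1, j] - gap_extend
            F[i, j] = f
            if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                sub = match
            else:
                sub = mismatch
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            # tie-break: earlier subject end, then earlier query end
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0
    # traceback
    i, j = bi, bj
    state = 0  # 0=H, 1=E (gap consuming subject), 2=F (gap consuming query)
    n_match = 0
    aln_len = 0
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                sub = match
            else:
                sub = mismatch
            if H[i, j] == H[i - 1, j - 1] + sub:
                if sub == match:
                    n_match += 1
                aln_len += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            aln_len += 1
            if E[i, j] == H[i, j - 1] - gap_open:
                state = 0
            j -= 1
        else:
            aln_len += 1
            if F[i, j] == H[i - 1, j] - gap_open:
                state = 0
            i -= 1
    return int(best), i, bi, j, bj, n_match, aln_len


@njit(cache=True)
def profile_score(E, gamma, pairs_i, pairs_j, G, seq):
    """Score a sequence against a sequence+structure profile.

    Stage 1 aligns the sequence globally to the L profile columns maximising
    the sum of single-column emissions with a linear penalty ``gamma`` per gap
    symbol.  The canonical optimal alignment (prefer match, then column
    deletion, then insertion; leftmost first) is traced, and stage 2 adds the
    pair emission for every paired column whose both partners matched.
    Returns ``(total_bits, matched)`` where ``matched[j]`` is the nucleotide
    code matched to column j, or -1.
    """
    n = seq.shape[0]
    L = E.shape[0]
    S = np.empty((n + 1, L + 1), dtype=np.float64)
    S[n, L] = 0.0
    for j in range(L - 1, -1, -1):
        S[n, j] = -gamma * (L - j)
    for i in range(n - 1, -1, -1):
        S[i, L] = -gamma * (n - i)
    for i in range(n - 1, -1, -1):
        for j in range(L - 1, -1, -1):
            m = E[j, seq[i]] + S[i + 1, j + 1]
            d = -gamma + S[i, j + 1]
            ins = -gamma + S[i + 1, j]
            if d > m:
                m = d
            if ins > m:
                m = ins
            S[i, j] = m
    matched = np.full(L, -1, dtype=np.int8)
    i = 0
    j = 0
    while i < n or j < L:
        if i < n and j < L and E[j, seq[i]] + S[i + 1, j + 1] == S[i, j]:
            matched[j] = seq[i]
            i += 1
            j += 1
        elif j < L and -gamma + S[i, j + 1] == S[i, j]:
            j += 1
        else:
            i += 1
    total = S[0, 0]
    for p in range(pairs_i.shape[0]):
        a = matched[pairs_i[p]]
        b = matched[pairs_j[p]]
        if a >= 0 and b >= 0:
            total += G[p, a, b]
    return total, matched


@njit(cache=True)
def profile_score_batch(E, gamma, pairs_i, pairs_j, G, genome, starts, wlen):
    """Exact profile scores of fixed-length windows at the given starts."""
    out = np.empty(starts.shape[0], dtype=np.float64)
    for k in range(starts.shape[0]):
        seq = genome[starts[k] : starts[k] + wlen]
        total, _ = profile_score(E, gamma, pairs_i, pairs_j, G, seq)
        out[k] = total
    return out


@njit(cache=True)
def nussinov_pairs(seq, min_loop):
    """Maximum Watson-Crick + GU base pairing (Nussinov) on a code array.

    ``min_loop`` is the minimum number of unpaired nucleotides enclosed by a
    pair.  Returns an (P, 2) array of paired positions i < j, sorted by i.
    The traceback is deterministic (leave-i-unpaired preferred, then
    leave-j, then pair, then leftmost bifurcation).
    """
    n = seq.shape[0]
    can = np.zeros((5, 5), dtype=np.uint8)
    can[0, 3] = 1
    can[3, 0] = 1
    can[1, 2] = 1
    can[2, 1] = 1
    can[2, 3] = 1
    can[3, 2] = 1
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j]
            if dp[i, j - 1] > best:
                best = dp[i, j - 1]
            if j - i - 1 >= min_loop and can[seq[i], seq[j]] == 1:
                # lower triangle of dp is 0, so dp[i+1, j-1] is safe even
                # when the enclosed region is empty
                v = dp[i + 1, j - 1] + 1
                if v > best:
                    best = v
            for k in range(i + 1, j):
                v = dp[i, k] + dp[k + 1, j]
                if v > best:
                    best = v
            dp[i, j] = best
    # traceback with an explicit stack
    out_i = np.empty(n // 2 + 1, dtype=np.int64)
    out_j = np.empty(n // 2 + 1, dtype=np.int64)
    n_out = 0
    stack_i = np.empty(2 * n + 2, dtype=np.int64)
    stack_j = np.empty(2 * n + 2, dtype=np.int64)
    top = 0
    if n > 1:
        stack_i[0] = 0
        stack_j[0] = n - 1
        top = 1
    while top > 0:
        top -= 1
        i = stack_i[top]
        j = stack_j[top]
        if i >= j or dp[i, j] == 0:
            continue
        if dp[i, j] == dp[i + 1, j]:
            stack_i[top] = i + 1
            stack_j[top] = j
            top += 1
        elif dp[i, j] == dp[i, j - 1]:
            stack_i[top] = i
            stack_j[top] = j - 1
            top += 1
        else:
            paired = False
            if j - i - 1 >= min_loop and can[seq[i], seq[j]] == 1:
                inner = dp[i + 1, j - 1]
                if dp[i, j] == inner + 1:
                    out_i[n_out] = i
                    out_j[n_out] = j
                    n_out += 1
                    if i + 1 < j - 1:
                        stack_i[top] = i + 1
                        stack_j[top] = j - 1
                        top += 1
                    paired = True
            if not paired:
                for k in range(i + 1, j):
                    if dp[i, j] == dp[i, k] + dp[k + 1, j]:
                        stack_i[top] = i
                        stack_j[top] = k
                        top += 1
                        stack_i[top] = k + 1
                        stack_j[top] = j
                        top += 1
                        break
    pairs = np.empty((n_out, 2), dtype=np.int64)
    for p in range(n_out):
        pairs[p, 0] = out_i[p]
        pairs[p, 1] = out_j[p]
    # sort by i (insertion sort; P is small)
    for a in range(1, n_out):
        vi = pairs[a, 0]
        vj = pairs[a, 1]
        b = a - 1
        while b >= 0 and pairs[b, 0] > vi:
            pairs[b + 1, 0] = pairs[b, 0]
            pairs[b + 1, 1] = pairs[b, 1]
            b -= 1
        pairs[b + 1, 0] = vi
        pairs[b + 1, 1] = vj
    return pairs


@njit(cache=True)
def gapfree_sweep(E, used_cols, used_pos, pair_idx, pi_pos, pj_pos, G, codes, wlen):
    """Gap-free profile score at every window offset (prefilter stage).

    Columns are gathered at their position within the ungapped reference
    (``used_pos``); columns where the reference row is gapped are skipped —
    the exact DP rescoring stage accounts for them.
    """
    n_off = codes.shape[0] - wlen + 1
    out = np.empty(max(n_off, 0), dtype=np.float64)
    for k in range(n_off):
        s = 0.0
        for t in range(used_cols.shape[0]):
            s += E[used_cols[t], codes[k + used_pos[t]]]
        for t in range(pair_idx.shape[0]):
            s += G[pair_idx[t], codes[k + pi_pos[t]], codes[k + pj_pos[t]]]
        out[k] = s
    return out
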