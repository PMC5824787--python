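"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: alignment identity
by exhaustive enumeration of global alignments (tiny strings) or an
independently written affine-gap dynamic program, tree likelihoods and
posteriors by exhaustive summation over internal states with
scipy.linalg.expm, and Michaelis-Menten optima by grid search.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm
from Bio.Align import substitution_matrices

GAP_OPEN = 11.0
GAP_EXTEND = 1.0

_BLOSUM = substitution_matrices.load("BLOSUM62")


def _pair_score(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_BLOSUM[a, b])


def _score_alignment(cols) -> float:
    """Affine-gap score: a gap run of length k costs open + (k-1)*extend."""
    score, gap_a, gap_b = 0.0, False, False
    for x, y in cols:
        if x == "-":
            score -= GAP_EXTEND if gap_a else GAP_OPEN
            gap_a, gap_b = True, False
        elif y == "-":
            score -= GAP_EXTEND if gap_b else GAP_OPEN
            gap_a, gap_b = False, True
        else:
            score += _pair_score(x, y)
            gap_a = gap_b = False
    return score


def enumerate_alignments(a: str, b: str):
    """All global alignments of two tiny strings as lists of column pairs."""
    if not a and not b:
        yield []
        return
    if a:
        for rest in enumerate_alignments(a[1:], b):
            yield [(a[0], "-")] + rest
    if b:
        for rest in enumerate_alignments(a, b[1:]):
            yield [("-", b[0])] + rest
    if a and b:
        for rest in enumerate_alignments(a[1:], b[1:]):
            yield [(a[0], b[0])] + rest


def optimal_identities(a: str, b: str) -> set:
    """Identities (matches / non-terminal-gap columns) of all optimal
    global alignments of two tiny strings."""
    best, idents = -np.inf, set()
    for cols in enumerate_alignments(a, b):
        s = _score_alignment(cols)
        if s < best - 1e-9:
            continue
        start = 0
        while start < len(cols) and "-" in cols[start]:
            start += 1
        end = len(cols)
        while end > start and "-" in cols[end - 1]:
            end -= 1
        trimmed = cols[start:end]
        ident = (sum(1 for x, y in trimmed if x == y and x != "-")
                 / len(trimmed)) if trimmed else 0.0
        if s > best + 1e-9:
            best, idents = s, {round(ident, 12)}
        else:
            idents.add(round(ident, 12))
    return idents


def gotoh_identity(a: str, b: str) -> float:
    """Affine-gap Needleman-Wunsch (Gotoh) with traceback preferring
    match, then gap in b, then gap in a; identity excludes terminal gaps."""
    n, m = len(a), len(b)
    neg = -1e18
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(GAP_OPEN + (i - 1) * GAP_EXTEND)
    for j in range(1, m + 1):
        Y[0, j] = -(GAP_OPEN + (j - 1) * GAP_EXTEND)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _pair_score(a[i - 1], b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                          Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - GAP_OPEN, X[i - 1, j] - GAP_EXTEND,
                          Y[i - 1, j] - GAP_OPEN)
            Y[i, j] = max(M[i, j - 1] - GAP_OPEN, Y[i, j - 1] - GAP_EXTEND,
                          X[i, j - 1] - GAP_OPEN)
    # traceback
    i, j = n, m
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    cols = []
    while i > 0 or j > 0:
        if i == 0:
            cols.append(("-", b[j - 1])); j -= 1; continue
        if j == 0:
            cols.append((a[i - 1], "-")); i -= 1; continue
        if state == 0:
            cols.append((a[i - 1], b[j - 1]))
            prev = np.array([M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]])
            prev += _pair_score(a[i - 1], b[j - 1])
            state = int(np.argmax(np.isclose(prev, M[i, j])))
            i, j = i - 1, j - 1
        elif state == 1:
            cols.append((a[i - 1], "-"))
            opts = np.array([M[i - 1, j] - GAP_OPEN, X[i - 1, j] - GAP_EXTEND,
                             Y[i - 1, j] - GAP_OPEN])
            state = int(np.argmax(np.isclose(opts, X[i, j])))
            i -= 1
        else:
            cols.append(("-", b[j - 1]))
            opts = np.array([M[i, j - 1] - GAP_OPEN, Y[i, j - 1] - GAP_EXTEND,
                             X[i, j - 1] - GAP_OPEN])
            state = int(np.argmax(np.isclose(opts, Y[i, j])))
            j -= 1
    cols.reverse()
    start = 0
    while start < len(cols) and "-" in cols[start]:
        start += 1
    end = len(cols)
    while end > start and "-" in cols[end - 1]:
        end -= 1
    trimmed = cols[start:end]
    if not trimmed:
        return 0.0
    return sum(1 for x, y in trimmed if x == y and x != "-") / len(trimmed)


# ---------------------------------------------------------------------------
# Tree likelihood / posterior enumeration

def _pmat(model, t):
    return expm(model.rate_matrix * t)


def star3_loglik(model, branch_lengths, leaf_states) -> float:
    """Exhaustive log-likelihood of a 3-leaf star tree, one column.

    leaf_states: list of state indices (None = missing).
    """
    pi = model.frequencies
    ps = [_pmat(model, t) for t in branch_lengths]
    total = 0.0
    for r in range(20):
        term = pi[r]
        for p, s in zip(ps, leaf_states):
            term *= 1.0 if s is None else p[r, s]
        total += term
    return float(np.log(total))


def star3_root_posterior(model, branch_lengths, leaf_states) -> np.ndarray:
    pi = model.frequencies
    ps = [_pmat(model, t) for t in branch_lengths]
    post = np.zeros(20)
    for r in range(20):
        term = pi[r]
        for p, s in zip(ps, leaf_states):
            term *= 1.0 if s is None else p[r, s]
        post[r] = term
    return post / post.sum()


def quartet_loglik(model, tb_root_u, tb_root_v, tb_leaves, leaf_states
                   ) -> float:
    """Exhaustive log-likelihood of ((A,B)u,(C,D)v) rooted between u and v.

    tb_leaves: (tA, tB, tC, tD); leaf_states: 4 state indices.
    """
    pi = model.frequencies
    pu = _pmat(model, tb_root_u)
    pv = _pmat(model, tb_root_v)
    pl = [_pmat(model, t) for t in tb_leaves]
    a, b, c, d = leaf_states
    total = 0.0
    for r in range(20):
        for u in range(20):
            for v in range(20):
                total += (pi[r] * pu[r, u] * pv[r, v]
                          * pl[0][u, a] * pl[1][u, b]
                          * pl[2][v, c] * pl[3][v, d])
    return float(np.log(total))


# ---------------------------------------------------------------------------
# Michaelis-Menten grid search

def mm_grid_search(s, v, vmax_range, km_range, n: int = 200) -> tuple:
    """(Vmax, KM) minimizing SSE on an n x n grid."""
    s = np.asarray(s, float)
    v = np.asarray(v, float)
    vmaxs = np.linspace(*vmax_range, n)
    kms = np.linspace(*km_range, n)
    best = (None, None, np.inf)
    for vm in vmaxs:
        pred = vm * s[None, :] / (kms[:, None] + s[None, :])
        sse = ((pred - v[None, :]) ** 2).sum(axis=1)
        k = int(np.argmin(sse))
        if sse[k] < best[2]:
            best = (vm, kms[k], sse[k])
    return best[0], best[1]
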