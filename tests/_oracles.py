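"""Independent brute-force oracles used to pin down expected values.

Everything here is deliberately naive (pair enumeration, exhaustive
search, resampling) and shares no code with the implementation paths it
checks.
"""

from __future__ import annotations

import numpy as np


def auroc_pair_count(scores, labels) -> float:
    """O(n^2) Mann-Whitney pair enumeration; ties count one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos, neg = s[y], s[~y]
    total = wins = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                wins += 1
            elif p == q:
                wins += 0.5
    return wins / total


def obuchowski_exhaustive(scores, stages, penalty=0.25) -> float:
    """Weighted mean pair score over all unordered pairs of unlike stages."""
    s = np.asarray(scores, dtype=float)
    k = np.asarray(stages, dtype=int)
    num = den = 0.0
    n = len(s)
    for i in range(n):
        for j in range(i + 1, n):
            if k[i] == k[j]:
                continue
            w = penalty * abs(int(k[i]) - int(k[j]))
            if s[i] == s[j]:
                c = 0.5
            else:
                c = 1.0 if (s[i] > s[j]) == (k[i] > k[j]) else 0.0
            num += w * c
            den += w
    return num / den


def exhaustive_cutoffs(scores, labels, se_target=0.85, sp_target=0.95):
    """Search every midpoint candidate directly; return achieved (se, sp) triples."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    u = np.unique(s)
    cands = [-np.inf] + [(a + b) / 2 for a, b in zip(u[:-1], u[1:])] + [np.inf]

    def perf(c):
        pred = s >= c
        se = (pred & y).sum() / y.sum()
        sp = (~pred & ~y).sum() / (~y).sum()
        return se, sp

    best = max(cands, key=lambda c: (perf(c)[0] + perf(c)[1] - 1, -c if np.isfinite(c) else 0))
    # resolve ties toward the lower cutoff explicitly
    best_y = None
    for c in cands:
        se, sp = perf(c)
        j = se + sp - 1
        if best_y is None or j > best_y + 1e-12:
            best, best_y = c, j
    feas_out = [c for c in cands if perf(c)[0] >= se_target]
    rule_out = max(
        (c for c in feas_out), key=lambda c: (perf(c)[1], -np.inf if not np.isfinite(c) else -c)
    ) if feas_out else None
    # ties toward lower cutoff: pick the first candidate attaining max sp
    if feas_out:
        sps = [perf(c)[1] for c in feas_out]
        m = max(sps)
        rule_out = feas_out[sps.index(m)]
    feas_in = [c for c in cands if perf(c)[1] >= sp_target]
    if feas_in:
        ses = [perf(c)[0] for c in feas_in]
        m = max(ses)
        rule_in = feas_in[ses.index(m)]
    else:
        rule_in = None
    return {"best_single": (best, perf(best)),
            "rule_out": (rule_out, perf(rule_out) if rule_out is not None else None),
            "rule_in": (rule_in, perf(rule_in) if rule_in is not None else None)}


def mcnemar_binomial_two_sided(b: int, c: int) -> float:
    """Exact two-sided McNemar p by direct binomial tail summation."""
    from math import comb

    n = b + c
    if n == 0:
        return 1.0
    k = min(b, c)
    tail = sum(comb(n, i) for i in range(0, k + 1)) / 2 ** n
    return min(1.0, 2 * tail)


def delong_permutation_p(scores_a, scores_b, labels, n_perm=10000, seed=0) -> float:
    """Permutation reference for the paired AUROC difference.

    Per permutation each subject's pair of scores is swapped with
    probability 1/2 (label-preserving exchange under H0: the two markers
    are interchangeable).
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)

    def auc(s):
        pos, neg = s[y], s[~y]
        cmp = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
        return cmp.mean()

    obs = abs(auc(a) - auc(b))
    hits = 0
    for _ in range(n_perm):
        swap = rng.random(len(a)) < 0.5
        aa = np.where(swap, b, a)
        bb = np.where(swap, a, b)
        if abs(auc(aa) - auc(bb)) >= obs - 1e-12:
            hits += 1
    return hits / n_perm


def bootstrap_pv_difference_p(test_a, test_b, labels, which="ppv",
                              n_boot=10000, seed=0) -> float:
    """Subject-bootstrap two-sided p for a paired predictive-value difference.

    p is twice the smaller tail of the bootstrap difference distribution
    around zero (percentile-symmetry convention).
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(test_a, dtype=bool)
    b = np.asarray(test_b, dtype=bool)
    d = np.asarray(labels, dtype=bool)
    n = len(a)

    def diff(idx):
        aa, bb, dd = a[idx], b[idx], d[idx]
        if which == "ppv":
            if aa.sum() == 0 or bb.sum() == 0:
                return None
            return dd[aa].mean() - dd[bb].mean()
        if (~aa).sum() == 0 or (~bb).sum() == 0:
            return None
        return (1 - dd[~aa].mean()) - (1 - dd[~bb].mean())

    diffs = []
    while len(diffs) < n_boot:
        v = diff(rng.integers(0, n, n))
        if v is not None:
            diffs.append(v)
    diffs = np.asarray(diffs)
    lower = (diffs <= 0).mean()
    upper = (diffs >= 0).mean()
    return min(1.0, 2 * min(lower, upper))
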