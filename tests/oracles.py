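"""Independent brute-force oracles used by the test suite.

Deliberately naive reimplementations (loops, full enumeration) kept
separate from the package so tests compare two independent routes.
"""

import itertools

import numpy as np
from scipy import stats


def brute_force_clusters(t_map, threshold, adj_matrix):
    """Naive BFS clustering of same-sign suprathreshold samples."""
    n_ch, n_t = t_map.shape
    visited = set()
    clusters = []
    for c in range(n_ch):
        for t in range(n_t):
            if (c, t) in visited or abs(t_map[c, t]) <= threshold:
                continue
            sign = np.sign(t_map[c, t])
            stack, members = [(c, t)], []
            visited.add((c, t))
            while stack:
                ci, ti = stack.pop()
                members.append((ci, ti))
                neighbors = [(ci, ti - 1), (ci, ti + 1)] + [
                    (cj, ti) for cj in range(n_ch) if adj_matrix[ci, cj]
                ]
                for cj, tj in neighbors:
                    if (
                        0 <= tj < n_t
                        and (cj, tj) not in visited
                        and abs(t_map[cj, tj]) > threshold
                        and np.sign(t_map[cj, tj]) == sign
                    ):
                        visited.add((cj, tj))
                        stack.append((cj, tj))
            clusters.append(
                (frozenset(members), float(sum(t_map[m] for m in members)))
            )
    return clusters


def brute_force_paired_p(diffs, threshold, adj_matrix):
    """Exact cluster p-values by enumerating every sign flip."""
    n = diffs.shape[0]
    observed_t = stats.ttest_1samp(diffs, 0.0, axis=0).statistic
    observed = brute_force_clusters(observed_t, threshold, adj_matrix)
    null_pos, null_neg = [], []
    for signs in itertools.product([1.0, -1.0], repeat=n):
        flipped = diffs * np.asarray(signs)[:, None, None]
        t_map = stats.ttest_1samp(flipped, 0.0, axis=0).statistic
        clusters = brute_force_clusters(t_map, threshold, adj_matrix)
        masses = [m for _, m in clusters]
        null_pos.append(max([m for m in masses if m > 0], default=0.0))
        null_neg.append(min([m for m in masses if m < 0], default=0.0))
    results = []
    for members, mass in observed:
        tol = 1e-9 * (1.0 + abs(mass))
        if mass > 0:
            count = sum(1 for v in null_pos if v >= mass - tol)
        else:
            count = sum(1 for v in null_neg if v <= mass + tol)
        results.append((members, mass, count / 2**n))
    return results


def oracle_signed_rank_p(pre, post):
    """Exact two-sided signed-rank p by enumerating sign assignments."""
    diffs = pre - post
    diffs = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    ge = le = 0
    n = len(diffs)
    for signs in itertools.product([0, 1], repeat=n):
        w = float(np.dot(signs, ranks))
        if w >= w_obs - 1e-12:
            ge += 1
        if w <= w_obs + 1e-12:
            le += 1
    return min(1.0, 2 * min(ge, le) / 2**n)


def oracle_u_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)

    def u_of(idx_a):
        idx_a = list(idx_a)
        ranks = stats.rankdata(pooled)
        return ranks[idx_a].sum() - n_a * (n_a + 1) / 2

    u_obs = u_of(range(n_a))
    ge = le = total = 0
    for combo in itertools.combinations(range(n), n_a):
        u = u_of(combo)
        total += 1
        if u >= u_obs - 1e-12:
            ge += 1
        if u <= u_obs + 1e-12:
            le += 1
    return min(1.0, 2 * min(ge, le) / total)


def brute_force_epoch_flags(eeg, ecg_peaks, epoch_peaks, fs, limit=75.0):
    """Naive per-epoch rejection bookkeeping (amplitude + extra beat)."""
    lo, hi = int(-0.1 * fs), int(0.7 * fs)
    flags = []
    n_samples = eeg.shape[1]
    for p in epoch_peaks:
        if p + lo < 0 or p + hi + 1 > n_samples:
            flags.append("boundary")
            continue
        segment = eeg[:, p + lo:p + hi + 1]
        over = bool((np.abs(segment) > limit).any())
        extra = any(
            0 < (q - p) * 1000.0 / fs <= 700.0 for q in ecg_peaks if q != p
        )
        if over:
            flags.append("amplitude")
        elif extra:
            flags.append("multi_rpeak")
        else:
            flags.append("kept")
    return flags
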