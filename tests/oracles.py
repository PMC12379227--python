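"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately naive (enumeration, BFS, run-length scan) and
shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
from scipy.stats import hypergeom


def rle_bouts(labels, epoch_length_s, start_time_s=0.0):
    """Run-length-encoded bouts via itertools.groupby."""
    out = []
    t = start_time_s
    for state, grp in itertools.groupby(labels):
        n = sum(1 for _ in grp)
        out.append((state, t, t + n * epoch_length_s))
        t += n * epoch_length_s
    return out


def architecture_from_rle(labels, epoch_length_s, states=("WAKE", "NREM", "REM")):
    """Architecture statistics computed from the RLE oracle."""
    labels = list(labels)
    bouts = rle_bouts(labels, epoch_length_s)
    stats = {}
    for s in states:
        runs = [(a, b) for st, a, b in bouts if st == s]
        stats[s] = {
            "percent_time": labels.count(s) * 100.0 / len(labels),
            "bout_count": len(runs),
            "mean_bout_duration_s": (
                float(np.mean([b - a for a, b in runs])) if runs else float("nan")
            ),
            "latency_s": runs[0][0] if runs else float("nan"),
        }
    return stats


def greedy_suppression_bruteforce(times, heights, min_interval_s):
    """All valid subsets (pairwise spacing >= interval); pick the one the
    tallest-first greedy would pick, as the lexicographic maximum under the
    (height desc, time asc) member ordering."""
    n = len(times)
    assert n <= 14, "brute force only for small candidate sets"

    def valid(subset):
        return all(
            abs(times[i] - times[j]) >= min_interval_s
            for i, j in itertools.combinations(subset, 2)
        )

    def key(subset):
        members = sorted(subset, key=lambda i: (-heights[i], times[i]))
        return tuple((heights[i], -times[i]) for i in members)

    best = max(
        (s for r in range(n + 1) for s in itertools.combinations(range(n), r)
         if valid(s)),
        key=key,
    )
    return sorted(best, key=lambda i: times[i])


def flood_fill_areas(image, connectivity=8):
    """Connected-component pixel counts by BFS flood fill."""
    img = np.asarray(image, dtype=bool)
    seen = np.zeros_like(img, dtype=bool)
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    areas = []
    rows, cols = img.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if img[r0, c0] and not seen[r0, c0]:
                count = 0
                q = deque([(r0, c0)])
                seen[r0, c0] = True
                while q:
                    r, c = q.popleft()
                    count += 1
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < rows and 0 <= cc < cols
                                and img[rr, cc] and not seen[rr, cc]):
                            seen[rr, cc] = True
                            q.append((rr, cc))
                areas.append(count)
    return sorted(areas)


def fisher_two_sided_p(a, b, c, d):
    """Two-sided Fisher p by hypergeometric point-probability enumeration."""
    N = a + b + c + d
    K = a + c  # members of the set
    n = a + b  # hits
    rv = hypergeom(N, K, n)
    p_obs = rv.pmf(a)
    ks = np.arange(max(0, n + K - N), min(K, n) + 1)
    pm = rv.pmf(ks)
    return float(pm[pm <= p_obs * (1 + 1e-9)].sum())


def t_s0_oracle(x1, x2, s0):
    """Pooled-variance s0 t-statistic, written independently."""
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    n1, n2 = len(x1), len(x2)
    sp2 = ((n1 - 1) * np.var(x1, ddof=1) + (n2 - 1) * np.var(x2, ddof=1)) / (
        n1 + n2 - 2
    )
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return (np.mean(x1) - np.mean(x2)) / (se + s0)
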