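"""Independent reference implementations and instance generators for testing.

These deliberately avoid the algorithms used by the production code: the
matching oracle enumerates matchings exhaustively rather than using
nearest-neighbor queries.
"""

from __future__ import annotations

import numpy as np

__all__ = ["brute_force_max_matching", "separated_instance"]


def brute_force_max_matching(a: np.ndarray, b: np.ndarray, threshold: float) -> int:
    """Maximum matching size between two small point sets, by exhaustive search.

    Considers every admissible assignment of A-points to distinct B-points
    with pairwise distance at most ``threshold``. Exponential; intended for
    at most ~12 points per side.
    """
    a = np.asarray(a, float).reshape(-1, 2)
    b = np.asarray(b, float).reshape(-1, 2)
    edges = [
        [j for j in range(len(b)) if np.hypot(*(a[i] - b[j])) <= threshold]
        for i in range(len(a))
    ]

    def rec(i: int, used: int) -> int:
        if i == len(a):
            return 0
        best = rec(i + 1, used)
        for j in edges[i]:
            if not used & (1 << j):
                best = max(best, 1 + rec(i + 1, used | (1 << j)))
        return best

    return rec(0, 0)


def separated_instance(
    rng: np.random.Generator, threshold: float = 1.5
) -> tuple[np.ndarray, np.ndarray]:
    """Random two-channel matching instance with resolvable spot sites.

    Sites are separated by more than twice the matching threshold; each
    site may host a point in either or both channels, jittered within
    ±0.4×threshold. Within-site distances therefore stay below the
    threshold and cross-site distances above it — the regime of resolvable
    single molecules, where the optimal matching is site-by-site.
    """
    n_sites = rng.integers(1, 13)
    sites: list[np.ndarray] = []
    while len(sites) < n_sites:
        p = rng.uniform(0, 60, size=2)
        if all(np.hypot(*(p - q)) > 2.2 * threshold for q in sites):
            sites.append(p)
    a, b = [], []
    for site in sites:
        in_a = rng.random() < 0.7
        in_b = rng.random() < 0.7
        if in_a and len(a) < 12:
            a.append(site + rng.uniform(-0.4, 0.4, 2) * threshold)
        if in_b and len(b) < 12:
            b.append(site + rng.uniform(-0.4, 0.4, 2) * threshold)
    return np.array(a).reshape(-1, 2), np.array(b).reshape(-1, 2)
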