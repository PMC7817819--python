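"""Independent oracles shared by the test suite (brute force, enumeration)."""

import itertools


def enumeration_ranksum_p(x, y):
    """Exact two-sided rank-sum p by full enumeration of group assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(group1, group2):
        return sum(a > b for a in group1 for b in group2)

    u_obs = u_stat(x, y)
    m = min(u_obs, n1 * (len(pooled) - n1) - u_obs)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(g1, g2)
        if min(u, n1 * len(g2) - u) <= m:
            hits += 1
        total += 1
    return hits / total
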