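"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately avoid the package's own algorithmic shortcuts: the
discovery oracle enumerates every subset of the sequence universe, and the
clustering oracle re-derives every inter-cluster distance from scratch at
each agglomeration step.
"""

from itertools import chain, combinations


def oracle_discover(footprints, min_support):
    """Exhaustive-enumeration oracle for greedy largest-first set discovery.

    Same preference key as the engine (set size, supporter count, summed
    collection-relative abundance, lexicographically smaller UID list) and
    the same peeling of chosen members from supporter footprints, but the
    candidate pool is every subset of the universe.
    """
    current = {f.source: set(f.members) for f in footprints}
    rel = {f.source: f.rel for f in footprints}
    universe = sorted(set().union(*[f.members for f in footprints]))

    def pick(member_sets):
        best = None
        for members in member_sets:
            if not members:
                continue
            sup = sorted(s for s in current if set(members) <= current[s])
            if len(sup) < min_support:
                continue
            summed = sum(rel[s][u] for s in sup for u in members)
            key = (len(members), len(sup), summed,
                   [-u for u in sorted(members)])
            if best is None or key > best[0]:
                best = (key, set(members), sup)
        return best

    out = []
    while True:
        # whole footprints take precedence; arbitrary subsets are the
        # collapse path when no whole footprint is supported
        best = pick([frozenset(m) for m in current.values()])
        if best is None:
            best = pick(chain.from_iterable(
                combinations(universe, k)
                for k in range(1, len(universe) + 1)))
        if best is None:
            return out
        _, members, sup = best
        out.append((frozenset(members), tuple(sup)))
        for s in sup:
            current[s] -= members


def oracle_cluster(dm, counts, cutoff):
    """Brute-force count-weighted average-linkage agglomeration."""
    labels = list(dm.ids)
    idx = {lab: i for i, lab in enumerate(labels)}
    clusters = [[lab] for lab in labels]

    def dist(a, b):
        num = den = 0.0
        for x in a:
            for y in b:
                w = counts[x] * counts[y]
                num += w * dm[idx[x], idx[y]]
                den += w
        return num / den

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = dist(clusters[i], clusters[j])
                if best is None or d < best[0] - 1e-15:
                    best = (d, i, j)
        d, i, j = best
        if d > cutoff:
            break
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(tuple(sorted(c)) for c in clusters)
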