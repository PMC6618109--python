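"""The 97%-similarity OTU clustering baseline.

Fixed-threshold clustering is the approach the profile engine is contrasted
against: sequences are agglomerated by count-weighted average linkage on
uncorrected p-distances until the smallest inter-cluster distance exceeds
the dissimilarity cutoff (3% by default).  Because intragenomic ITS2
variants typically differ by only a few bases, this collapses distinct taxa
into a single OTU - the resolution loss the DIV approach avoids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .distance import align_sequences, pairwise_distances

__all__ = [
    "OTUCluster",
    "cluster_average_neighbour",
    "otu_representatives",
    "run_otu_pipeline",
]


@dataclass
class OTUCluster:
    """One OTU: member sequences with counts and its formation height."""

    members: dict[str, int] = field(default_factory=dict)
    merge_height: float = 0.0

    @property
    def total(self) -> int:
        return sum(self.members.values())

    @property
    def representative(self) -> str:
        """Most abundant member; count ties go lexicographically."""
        return min(self.members, key=lambda s: (-self.members[s], s))


def cluster_average_neighbour(dm, counts: Mapping[str, int],
                              cutoff: float = 0.03) -> list[OTUCluster]:
    """Count-weighted average-linkage clustering up to a distance cutoff.

    ``dm`` is a distance matrix whose ids key into ``counts``.  Every
    redundant read contributes to the linkage average: the distance
    between clusters is the count-weighted mean of the pairwise sequence
    distances.  Merging proceeds while the minimum inter-cluster distance
    is <= ``cutoff``; equal distances are broken by label order.  Each
    cluster records the height at which its last merge happened.
    """
    labels = list(dm.ids)
    for lab in labels:
        if lab not in counts:
            raise KeyError(f"no count for label {lab!r}")
    clusters: dict[int, OTUCluster] = {
        i: OTUCluster(members={lab: counts[lab]})
        for i, lab in enumerate(labels)}
    idx = {lab: i for i, lab in enumerate(labels)}
    base = np.asarray(dm.data, dtype=float)

    def linkage_dist(a: OTUCluster, b: OTUCluster) -> float:
        num = den = 0.0
        for sa, na in a.members.items():
            for sb, nb in b.members.items():
                w = na * nb
                num += w * base[idx[sa], idx[sb]]
                den += w
        return num / den

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, ka in enumerate(keys):
            for kb in keys[i + 1:]:
                d = linkage_dist(clusters[ka], clusters[kb])
                if best is None or d < best[0] - 1e-15:
                    best = (d, ka, kb)
        d, ka, kb = best
        if d > cutoff:
            break
        merged = OTUCluster(members={**clusters[ka].members},
                            merge_height=d)
        for s, n in clusters[kb].members.items():
            merged.members[s] = merged.members.get(s, 0) + n
        del clusters[kb]
        clusters[ka] = merged
    return [clusters[k] for k in sorted(clusters)]


def otu_representatives(clusters: Sequence[OTUCluster]) -> dict[int, str]:
    """Map cluster index -> representative (most abundant) sequence."""
    if not clusters:
        raise ValueError("no clusters")
    return {i: c.representative for i, c in enumerate(clusters)}


def run_otu_pipeline(sample_counts: Mapping[str, Mapping[str, int]],
                     mode: str = "across", cutoff: float = 0.03):
    """OTU count table for post-QC sequences of one clade.

    ``sample_counts`` maps sample id -> (sequence -> count).  In
    ``across`` mode all samples' reads are pooled before a single
    clustering, so OTU labels are shared; in ``within`` mode each sample
    is clustered independently.  Returns a ``pandas.DataFrame`` with OTU
    representatives as rows, samples as columns, plus the merge height of
    each OTU's final cluster; counts are conserved per sample.
    """
    import pandas as pd
    samples = sorted(sample_counts)
    if mode not in ("across", "within"):
        raise ValueError(f"unknown mode {mode!r}")

    def cluster(counts: Mapping[str, int]) -> list[OTUCluster]:
        seqs = sorted(counts)
        if len(seqs) == 1:
            return [OTUCluster(members=dict(counts))]
        aln = align_sequences(seqs)
        dm = pairwise_distances(aln, labels=seqs, ignore_terminal_gaps=True)
        return cluster_average_neighbour(dm, counts, cutoff)

    rows: dict[str, dict] = {}

    def add(rep: str, height: float, per_sample: Mapping[str, int]) -> None:
        row = rows.setdefault(rep, {"merge_height": 0.0,
                                    **{s: 0 for s in samples}})
        row["merge_height"] = max(row["merge_height"], height)
        for s, n in per_sample.items():
            row[s] += n

    if mode == "across":
        pooled: dict[str, int] = {}
        for counts in sample_counts.values():
            for s, n in counts.items():
                pooled[s] = pooled.get(s, 0) + n
        for c in cluster(pooled):
            add(c.representative, c.merge_height,
                {sample: sum(n for s, n in sample_counts[sample].items()
                             if s in c.members)
                 for sample in samples})
    else:
        for sample in samples:
            counts = sample_counts[sample]
            if not counts:
                continue
            for c in cluster(counts):
                add(c.representative, c.merge_height, {sample: c.total})
    df = pd.DataFrame(
        [{"representative": rep, **row} for rep, row in sorted(rows.items())])
    return df.set_index("representative")
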