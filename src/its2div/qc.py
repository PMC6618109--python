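"""Paired-read quality control down to per-sample, per-clade collections.

The chain mirrors the standard mothur-style ITS2 workflow: overlap-merge
read pairs into contigs, screen for ambiguous bases and homopolymer runs,
assign each sequence to a Symbiodiniaceae clade (A-I) against the bundled
anchor references, drop low-abundance uniques, trim the amplification
primers, screen by length, and finally collapse residual error variants
with an entropy-guided decomposition.  The output is one
:class:`~its2div.core.CladeCollection` per (sample, clade), the searchable
unit of the profile engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import edlib
import numpy as np

from .core import CladeCollection, Config, SequenceRegistry

# Symbiodiniaceae-specific ITS2 primer pair used throughout as defaults
# (given 5'->3'; the reverse primer anneals to the 3' end of the amplicon).
FWD_PRIMER = "GAATTGCAGAACTCCGTGAACC"
REV_PRIMER = "CGGGTTCWCTTGTYTGACTTCATGC"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ReadPair:
    """A demultiplexed forward/reverse read pair with qualities."""

    read_id: str
    fwd: str
    fwd_qual: str
    rev: str
    rev_qual: str

    def __post_init__(self) -> None:
        if not self.fwd or not self.rev:
            raise ValueError(f"{self.read_id}: empty read")
        if len(self.fwd) != len(self.fwd_qual) or len(self.rev) != len(self.rev_qual):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


# Stage order of the per-sample QC report; values are absolute read counts
# except the two entries explicitly labelled "unique".
QC_STAGES = (
    "reads_in",
    "contigs",
    "quality_screened",
    "clade_assigned",
    "abundance_filtered",
    "primer_trimmed",
    "length_screened",
    "post_decomposition",
    "unique_post_qc",
    "unique_nodes",
)


@dataclass
class QCReport:
    """Survivor counts at each QC stage for one sample."""

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def as_row(self) -> list[int]:
        return [self.counts.get(stage, 0) for stage in QC_STAGES]


# ---------------------------------------------------------------------------
# Individual QC operations
# ---------------------------------------------------------------------------

def merge_read_pair(pair: ReadPair, min_overlap: int = 30,
                    min_overlap_identity: float = 0.9) -> str | None:
    """Overlap-merge a read pair into a contig, or ``None`` to reject.

    The reverse read is reverse-complemented and slid against the forward
    read; the highest-scoring ungapped overlap of length >= ``min_overlap``
    (match +1, mismatch -1; ties broken toward the longer overlap) is used.
    Overlap mismatches are resolved toward the base with the higher quality
    score (forward base on quality ties).  Pairs whose best overlap is
    shorter than ``min_overlap`` or less than ``min_overlap_identity``
    identical are rejected - a counted, normal outcome.
    """
    f, fq = pair.fwd, pair.fwd_qual
    r = revcomp(pair.rev)
    rq = pair.rev_qual[::-1]
    max_l = min(len(f), len(r))
    fa = np.frombuffer(f.encode(), dtype=np.uint8)
    ra = np.frombuffer(r.encode(), dtype=np.uint8)
    best_score, best_l = None, None
    for L in range(max_l, min_overlap - 1, -1):
        matches = int((fa[len(f) - L:] == ra[:L]).sum())
        score = 2 * matches - L  # (+1 per match, -1 per mismatch)
        if best_score is None or score > best_score:
            best_score, best_l = score, L
    if best_l is None:
        return None
    L = best_l
    matches = (best_score + L) // 2
    if matches / L < min_overlap_identity:
        return None
    merged = []
    for i in range(L):
        bf, br = f[len(f) - L + i], r[i]
        if bf == br:
            merged.append(bf)
        else:
            qf, qr = fq[len(f) - L + i], rq[i]
            merged.append(bf if qf >= qr else br)
    return f[:len(f) - L] + "".join(merged) + r[L:]


def screen_quality(contig: str, maxambig: int = 0, maxhomop: int = 5) -> bool:
    """Keep a contig iff ambiguous bases <= maxambig and runs <= maxhomop."""
    ambig = sum(1 for c in contig if c not in "ACGT")
    if ambig > maxambig:
        return False
    run = longest = 1
    for a, b in zip(contig, contig[1:]):
        run = run + 1 if a == b else 1
        longest = max(longest, run)
    return longest <= maxhomop


def dereplicate(contigs: Iterable[str]) -> dict[str, int]:
    """Collapse redundant sequences into a sequence -> count map."""
    counts: dict[str, int] = {}
    for seq in contigs:
        counts[seq] = counts.get(seq, 0) + 1
    return counts


def assign_clade(sequence: str, clade_refs: Mapping[str, str],
                 max_edit_frac: float = 0.2) -> str | None:
    """Closest-clade screen against the nine anchor references.

    The anchor must align within the sequence (infix edit-distance
    alignment, both orientations tried) with at most ``max_edit_frac`` of
    its length in edits, i.e. >= 80% identity at the default.  Returns the
    best clade or ``None`` if no anchor comes close enough.
    """
    clade, _ = _assign_clade_oriented(sequence, clade_refs, max_edit_frac)
    return clade


def _assign_clade_oriented(sequence: str, clade_refs: Mapping[str, str],
                           max_edit_frac: float = 0.2
                           ) -> tuple[str | None, str]:
    best = None  # (distance, clade, oriented_seq)
    for orient_seq in (sequence, revcomp(sequence)):
        for clade, ref in sorted(clade_refs.items()):
            d = edlib.align(ref, orient_seq, mode="HW", task="distance",
                            k=int(len(ref) * max_edit_frac))["editDistance"]
            if d == -1:
                continue
            if best is None or d < best[0]:
                best = (d, clade, orient_seq)
    if best is None:
        return None, sequence
    return best[1], best[2]


def filter_low_abundance(counts: Mapping[str, int], cutoff: int = 2
                         ) -> dict[str, int]:
    """Retain exactly the sequences found at abundance strictly > cutoff."""
    return {seq: n for seq, n in counts.items() if n > cutoff}


def _primer_mismatches(window: str, primer: str) -> int:
    return sum(1 for b, p in zip(window, primer) if b not in IUPAC.get(p, ""))


def trim_primers(sequence: str, fwd_primer: str = FWD_PRIMER,
                 rev_primer: str = REV_PRIMER, pdiffs: int = 2,
                 rdiffs: int = 2, jitter: int = 3) -> str | None:
    """Trim the primer regions off an amplicon, or ``None`` to discard.

    The forward primer is located within ``pdiffs`` mismatches at the 5'
    end and the reverse complement of the reverse primer within ``rdiffs``
    at the 3' end, each allowing the start position to shift by up to
    ``jitter`` bases from the sequence end.  IUPAC degeneracies in the
    primers match their base sets.  Mismatch counting is indel-free.
    """
    rc_rev = revcomp(rev_primer)
    lf, lr = len(fwd_primer), len(rc_rev)
    if len(sequence) < lf + lr:
        return None
    f_hit = None
    for off in range(0, jitter + 1):
        mm = _primer_mismatches(sequence[off:off + lf], fwd_primer)
        if mm <= pdiffs and (f_hit is None or mm < f_hit[1]):
            f_hit = (off, mm)
    if f_hit is None:
        return None
    r_hit = None
    for off in range(0, jitter + 1):
        start = len(sequence) - lr - off
        mm = _primer_mismatches(sequence[start:start + lr], rc_rev)
        if mm <= rdiffs and (r_hit is None or mm < r_hit[1]):
            r_hit = (start, mm)
    if r_hit is None:
        return None
    interior = sequence[f_hit[0] + lf:r_hit[0]]
    return interior if interior else None


def screen_length(sequence: str, minlength: int = 184,
                  maxlength: int = 310) -> bool:
    """Keep iff minlength <= len <= maxlength (strict removal outside)."""
    return minlength <= len(sequence) <= maxlength


# ---------------------------------------------------------------------------
# Entropy-guided decomposition (simplified MED-style denoiser)
# ---------------------------------------------------------------------------

def _column_entropy(rows: list[str], counts: list[int], col: int) -> float:
    freq: dict[str, float] = {}
    total = 0
    for row, n in zip(rows, counts):
        c = row[col]
        if c in "ACGT":
            freq[c] = freq.get(c, 0) + n
            total += n
    if total == 0 or len(freq) < 2:
        return 0.0
    p = np.array(list(freq.values()), dtype=float) / total
    return float(-(p * np.log2(p)).sum())


def _pad_align(seqs: list[str]) -> list[str]:
    """Columns for entropy: direct when equal-length, else aligned."""
    if len({len(s) for s in seqs}) == 1:
        return list(seqs)
    from .distance import align_sequences
    return align_sequences(seqs)


def entropy_decompose(counts: Mapping[str, int],
                      entropy_threshold: float = 0.10,
                      min_node_reads: int = 10,
                      min_node_frac: float = 0.01) -> dict[str, int]:
    """Partition unique sequences into nodes by entropy-guided splitting.

    While the highest-entropy alignment column (Shannon entropy of the
    count-weighted base frequencies over non-gap characters) exceeds
    ``entropy_threshold``, sequences are split by their base at that
    column.  Children totalling fewer than max(``min_node_reads``,
    ``min_node_frac`` x parent) reads are merged back into the nearest
    sibling by edit distance between representatives.  Each final node is
    reported by its most abundant member sequence (ties to the
    lexicographically smaller); counts are conserved exactly.
    """
    if not counts:
        return {}
    seqs = sorted(counts)
    rows = _pad_align(seqs)
    aligned = dict(zip(seqs, rows))

    def representative(group: list[str]) -> str:
        return min(group, key=lambda s: (-counts[s], s))

    def decompose(group: list[str], blocked: frozenset[int]) -> list[list[str]]:
        if len(group) == 1:
            return [group]
        grows = [aligned[s] for s in group]
        gcounts = [counts[s] for s in group]
        ncol = len(grows[0])
        entropies = [(-1.0 if c in blocked else
                      _column_entropy(grows, gcounts, c)) for c in range(ncol)]
        col = int(np.argmax(entropies))
        if entropies[col] <= entropy_threshold:
            return [group]
        parent_total = sum(gcounts)
        children: dict[str, list[str]] = {}
        for s in group:
            children.setdefault(aligned[s][col], []).append(s)
        min_abund = max(min_node_reads, min_node_frac * parent_total)
        big = {c: g for c, g in children.items()
               if sum(counts[s] for s in g) >= min_abund}
        if len(big) < 2:
            # splitting would only shave off sub-threshold noise nodes
            if not big:
                return [group]
            main_char = next(iter(big))
            merged = children[main_char]
            for c, g in children.items():
                if c != main_char:
                    merged.extend(g)
            return decompose(sorted(merged), blocked | {col})
        small = {c: g for c, g in children.items() if c not in big}
        big_reps = {c: representative(g) for c, g in big.items()}
        for c, g in sorted(small.items()):
            rep = representative(g)
            nearest = min(
                sorted(big),
                key=lambda bc: edlib.align(rep, big_reps[bc],
                                           task="distance")["editDistance"])
            big[nearest].extend(g)
        out: list[list[str]] = []
        for c in sorted(big):
            out.extend(decompose(sorted(big[c]), blocked | {col}))
        return out

    nodes = decompose(seqs, frozenset())
    result: dict[str, int] = {}
    for group in nodes:
        rep = representative(group)
        result[rep] = result.get(rep, 0) + sum(counts[s] for s in group)
    return result


# ---------------------------------------------------------------------------
# Whole-sample pipeline
# ---------------------------------------------------------------------------

def build_clade_collections(sample_id: str,
                            clade_node_counts: Mapping[str, Mapping[str, int]],
                            registry: SequenceRegistry) -> list[CladeCollection]:
    """One collection per (sample, clade); sequences enter the registry."""
    out = []
    for clade in sorted(clade_node_counts):
        node_counts = clade_node_counts[clade]
        if not node_counts:
            continue
        abundances: dict[int, int] = {}
        for seq, n in sorted(node_counts.items()):
            uid = registry.register(seq, clade)
            abundances[uid] = abundances.get(uid, 0) + n
        out.append(CladeCollection(sample_id=sample_id, clade=clade,
                                   abundances=abundances))
    return out


def run_sample_qc(sample_id: str, pairs: Iterable[ReadPair], config: Config,
                  clade_refs: Mapping[str, str], registry: SequenceRegistry,
                  fwd_primer: str = FWD_PRIMER, rev_primer: str = REV_PRIMER
                  ) -> tuple[list[CladeCollection], QCReport]:
    """Run the full QC chain on one sample's read pairs.

    Returns the per-clade collections (empty clades omitted) and the
    stage-by-stage survivor report.  The pipeline is deterministic:
    identical reads and configuration give identical collections.
    """
    report = QCReport(sample_id=sample_id)
    pairs = list(pairs)
    report.counts["reads_in"] = len(pairs)

    contigs = []
    merge_cache: dict[tuple[str, str, str, str], str | None] = {}
    for pair in pairs:
        key = (pair.fwd, pair.fwd_qual, pair.rev, pair.rev_qual)
        if key in merge_cache:
            contig = merge_cache[key]
        else:
            contig = merge_read_pair(pair)
            merge_cache[key] = contig
        if contig is not None:
            contigs.append(contig)
    report.counts["contigs"] = len(contigs)

    screened = [c for c in contigs
                if screen_quality(c, config.maxambig, config.maxhomop)]
    report.counts["quality_screened"] = len(screened)

    unique = dereplicate(screened)
    by_clade: dict[str, dict[str, int]] = {}
    for seq in sorted(unique):
        clade, oriented = _assign_clade_oriented(seq, clade_refs)
        if clade is None:
            continue
        cmap = by_clade.setdefault(clade, {})
        cmap[oriented] = cmap.get(oriented, 0) + unique[seq]
    report.counts["clade_assigned"] = sum(
        n for cmap in by_clade.values() for n in cmap.values())

    for clade in list(by_clade):
        by_clade[clade] = filter_low_abundance(by_clade[clade],
                                               config.abund_cutoff)
    report.counts["abundance_filtered"] = sum(
        n for cmap in by_clade.values() for n in cmap.values())

    for clade in list(by_clade):
        trimmed: dict[str, int] = {}
        for seq, n in sorted(by_clade[clade].items()):
            t = trim_primers(seq, fwd_primer, rev_primer,
                             config.pdiffs, config.rdiffs)
            if t is not None:
                trimmed[t] = trimmed.get(t, 0) + n
        by_clade[clade] = trimmed
    report.counts["primer_trimmed"] = sum(
        n for cmap in by_clade.values() for n in cmap.values())

    for clade in list(by_clade):
        by_clade[clade] = {
            seq: n for seq, n in by_clade[clade].items()
            if screen_length(seq, config.minlength, config.maxlength)}
    report.counts["length_screened"] = sum(
        n for cmap in by_clade.values() for n in cmap.values())
    report.counts["unique_post_qc"] = sum(
        len(cmap) for cmap in by_clade.values())

    for clade in list(by_clade):
        by_clade[clade] = entropy_decompose(
            by_clade[clade], entropy_threshold=config.entropy_threshold)
    by_clade = {c: m for c, m in by_clade.items() if m}
    report.counts["post_decomposition"] = sum(
        n for cmap in by_clade.values() for n in cmap.values())
    report.counts["unique_nodes"] = sum(
        len(cmap) for cmap in by_clade.values())

    collections = build_clade_collections(sample_id, by_clade, registry)
    return collections, report
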