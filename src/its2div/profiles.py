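"""The profile-discovery engine: from clade collections to ITS2 type profiles.

The engine separates intragenomic from intergenomic ITS2 variation by
searching, clade by clade, for the largest sets of sequences that re-occur
across samples.  Sequences in a sufficiently supported re-occurring set are
defining intragenomic variants (DIVs); the set plus the characteristic
relative-abundance range of each DIV is an ITS2 type profile.  Collections
in which no re-occurring set can be matched conservatively receive a
fallback profile made of their single most abundant sequence.

Abundance conventions.  Footprint membership is judged against the whole
clade collection (a sequence enters the footprint at >= 1% of the
collection by default).  DIV abundances used to characterize and match
profiles are normalized within the profile's own DIV set, so that a taxon
keeps its intragenomic signature when it shares a sample with another taxon
of the same clade; collection-level DIV sums are used when competing
overlapping profiles are resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from .core import (CladeCollection, Config, ProfileAssignment,
                   SequenceRegistry, TypeProfile)

__all__ = [
    "Footprint",
    "CandidateProfile",
    "extract_footprint",
    "discover_candidate_profiles",
    "split_multimodal",
    "characterize_profile",
    "assign_profiles",
    "resolve_overlaps",
    "fallback_assign",
    "name_profile",
    "parse_profile_name",
    "merge_genus_outputs",
    "flag_super_types",
    "run_analysis",
    "AnalysisResult",
]


@dataclass(frozen=True)
class Footprint:
    """The above-cutoff sequence set of one searchable clade collection."""

    clade: str
    members: frozenset[int]
    source: str                      # CladeCollection id
    rel_abundances: tuple[tuple[int, float], ...]  # collection-relative

    @property
    def rel(self) -> dict[int, float]:
        return dict(self.rel_abundances)


@dataclass
class CandidateProfile:
    """A supported re-occurring sequence set, before characterization.

    ``abundances`` holds, per supporting collection, each member's relative
    abundance normalized within the member set.
    """

    clade: str
    members: frozenset[int]
    supporting: list[str]
    abundances: dict[str, dict[int, float]] = field(default_factory=dict)


def extract_footprint(cc: CladeCollection, footprint_rel_cutoff: float = 0.01,
                      min_collection_size: int = 200) -> Footprint:
    """Sequences at or above the relative-abundance cutoff in a collection.

    Only searchable collections (> ``min_collection_size`` reads) may be
    footprinted.  If every sequence falls below the cutoff the most
    abundant one still forms a singleton footprint.
    """
    if not cc.searchable(min_collection_size):
        raise ValueError(f"collection {cc.id} is not searchable "
                         f"(total {cc.total} <= {min_collection_size})")
    rel = cc.relative_abundances()
    members = {u for u, x in rel.items() if x >= footprint_rel_cutoff}
    if not members:
        top = min(cc.abundances, key=lambda u: (-cc.abundances[u], u))
        members = {top}
    return Footprint(clade=cc.clade, members=frozenset(members),
                     source=cc.id,
                     rel_abundances=tuple(sorted(
                         (u, rel[u]) for u in members)))


def _intersection_closure(sets: Iterable[frozenset[int]]) -> set[frozenset[int]]:
    """All non-empty intersections of any combination of the input sets."""
    pool = {s for s in sets if s}
    frontier = set(pool)
    while frontier:
        new = set()
        for f in frontier:
            for s in pool:
                inter = f & s
                if inter and inter not in pool and inter not in new:
                    new.add(inter)
        pool |= new
        frontier = new
    return pool


def discover_candidate_profiles(footprints: Sequence[Footprint],
                                min_support: int = 3
                                ) -> list[CandidateProfile]:
    """Greedy largest-first search for re-occurring sequence sets.

    Repeatedly selects the largest member set contained in at least
    ``min_support`` of the footprints' still-unexplained portions,
    preferring larger sets, then more supporters, then higher summed
    collection-relative abundance, then the lexicographically smaller UID
    list.  A chosen set's members are peeled off its supporters'
    footprints, so a footprint holding the variants of two co-occurring
    genotypes supports the second genotype's set with its residue, while a
    footprint wholly explained by a larger set never re-supports that
    set's subsets.  Deterministic for fixed input.
    """
    clades = {f.clade for f in footprints}
    if len(clades) > 1:
        raise ValueError(f"footprints span multiple clades: {sorted(clades)}")
    by_source = {f.source: f for f in footprints}
    if len(by_source) != len(footprints):
        raise ValueError("duplicate footprint sources")
    current: dict[str, frozenset[int]] = {s: f.members
                                          for s, f in by_source.items()}
    out: list[CandidateProfile] = []

    def pick(candidates, active):
        best = None
        for members in candidates:
            sup = [s for s in active if members <= current[s]]
            if len(sup) < min_support:
                continue
            summed = sum(by_source[s].rel[u] for s in sup for u in members)
            key = (len(members), len(sup), summed,
                   [-u for u in sorted(members)])
            if best is None or key > best[0]:
                best = (key, members, sup)
        return best

    while True:
        active = sorted(s for s in current if current[s])
        # whole footprints first: a supported footprint is a set some
        # sample actually carries, whereas an intersection of footprints
        # from different mixtures may correspond to no genotype at all;
        # intersections are the collapse path for unsupported footprints
        best = pick({current[s] for s in active}, active)
        if best is None:
            best = pick(_intersection_closure(current[s] for s in active),
                        active)
        if best is None:
            break
        _, members, sup = best
        # multi-member sets are normalized within the member set (mixture-
        # invariant); singletons keep collection-relative abundance, which
        # is the only meaningful scale for a one-sequence profile
        abunds = {}
        for s in sup:
            rel = by_source[s].rel
            if len(members) == 1:
                abunds[s] = {u: rel[u] for u in members}
            else:
                tot = sum(rel[u] for u in members)
                abunds[s] = {u: rel[u] / tot for u in members}
        out.append(CandidateProfile(clade=footprints[0].clade,
                                    members=members, supporting=sorted(sup),
                                    abundances=abunds))
        for s in sup:
            current[s] = current[s] - members
    return out


# ---------------------------------------------------------------------------
# Multimodality
# ---------------------------------------------------------------------------

def _find_modes(values: np.ndarray, valley_ratio: float = 0.85
                ) -> list[float]:
    """Mode locations of a kernel density estimate of the values.

    Gaussian kernel with Silverman bandwidth; neighbouring maxima are
    merged unless the deepest intervening valley drops below
    ``valley_ratio`` of the lower of the two peaks.
    """
    from scipy.stats import gaussian_kde
    if values.std() < 1e-9:
        return [float(values.mean())]
    kde = gaussian_kde(values, bw_method="silverman")
    lo = values.min() - 3 * kde.factor * values.std()
    hi = values.max() + 3 * kde.factor * values.std()
    grid = np.linspace(lo, hi, 512)
    dens = kde(grid)
    peaks = [i for i in range(1, len(grid) - 1)
             if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]]
    if not peaks:
        return [float(grid[int(np.argmax(dens))])]
    # merge insignificant neighbouring peaks, keeping the higher one
    merged = [peaks[0]]
    for p in peaks[1:]:
        prev = merged[-1]
        valley = dens[prev:p + 1].min()
        if valley >= valley_ratio * min(dens[prev], dens[p]):
            if dens[p] > dens[prev]:
                merged[-1] = p
        else:
            merged.append(p)
    return [float(grid[p]) for p in merged]


def split_multimodal(candidate: CandidateProfile, min_support: int = 3
                     ) -> list[CandidateProfile]:
    """Split a candidate whose members show multimodal abundances.

    Each member's relative abundance across the supporting collections is
    tested for multiple modes; if found, supporters are partitioned by
    nearest mode and each part re-tested recursively, so two profiles may
    end up with the same DIV set at different abundances.  Partitions that
    would leave any part below ``min_support`` supporters are dissolved.
    """
    if len(candidate.supporting) < 2 * min_support:
        return [candidate]
    for member in sorted(candidate.members):
        values = np.array([candidate.abundances[s][member]
                           for s in candidate.supporting])
        modes = _find_modes(values)
        if len(modes) < 2:
            continue
        groups: dict[int, list[str]] = {i: [] for i in range(len(modes))}
        for s, v in zip(candidate.supporting, values):
            nearest = int(np.argmin([abs(v - m) for m in modes]))
            groups[nearest].append(s)
        if any(len(g) < min_support for g in groups.values()):
            continue
        out = []
        for i in sorted(groups):
            sub = CandidateProfile(
                clade=candidate.clade, members=candidate.members,
                supporting=sorted(groups[i]),
                abundances={s: candidate.abundances[s] for s in groups[i]})
            out.extend(split_multimodal(sub, min_support))
        return out
    return [candidate]


# ---------------------------------------------------------------------------
# Characterization and naming
# ---------------------------------------------------------------------------

def characterize_profile(candidate: CandidateProfile, uid: int,
                         range_tolerance: float = 0.0) -> TypeProfile:
    """Turn a supported, unimodal candidate into a named type profile.

    DIVs are ordered by decreasing mean relative abundance (ties to the
    lower UID); each DIV's [min, max] abundance across supporters is
    optionally widened by ``range_tolerance`` (fractional); the majority
    set collects every DIV observed as some supporter's top DIV.
    """
    members = sorted(candidate.members)
    means = {u: float(np.mean([candidate.abundances[s][u]
                               for s in candidate.supporting]))
             for u in members}
    divs = sorted(members, key=lambda u: (-means[u], u))
    ranges = {}
    for u in members:
        vals = [candidate.abundances[s][u] for s in candidate.supporting]
        lo, hi = min(vals), max(vals)
        lo = max(0.0, lo * (1.0 - range_tolerance))
        hi = min(1.0, hi * (1.0 + range_tolerance))
        ranges[u] = (lo, hi)
    majority = set()
    for s in candidate.supporting:
        ab = candidate.abundances[s]
        majority.add(min(ab, key=lambda u: (-ab[u], u)))
    profile = TypeProfile(uid=uid, clade=candidate.clade, divs=divs,
                          ranges=ranges, majority_set=majority,
                          support=list(candidate.supporting))
    profile.validate()
    return profile


def name_profile(profile: TypeProfile, registry: SequenceRegistry) -> str:
    """Profile name: majority DIVs joined by '/', the rest by '-'.

    Both groups are in decreasing mean-abundance order (the order of
    ``profile.divs``); DIVs without a canonical name appear as their UID.
    """
    maj = [u for u in profile.divs if u in profile.majority_set]
    rest = [u for u in profile.divs if u not in profile.majority_set]
    name = "/".join(registry.label(u) for u in maj)
    if rest:
        name += "-" + "-".join(registry.label(u) for u in rest)
    return name


def parse_profile_name(name: str) -> tuple[list[str], list[str]]:
    """Inverse of :func:`name_profile` on labels.

    Returns (ordered DIV labels, majority labels).
    """
    parts = name.split("-")
    majority = parts[0].split("/")
    return majority + parts[1:], majority


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

_MATCH_EPS = 1e-9  # guards float-path differences at exact range endpoints


def _profile_matches(cc: CladeCollection, profile: TypeProfile) -> bool:
    if profile.clade != cc.clade:
        return False
    if not set(profile.divs) <= set(cc.abundances):
        return False
    if profile.fallback:
        # a fallback profile is defined by being the sample's most
        # abundant sequence; it matches only where that still holds
        top = min(cc.abundances, key=lambda u: (-cc.abundances[u], u))
        return top == profile.divs[0]
    if len(profile.divs) == 1:
        u = profile.divs[0]
        lo, hi = profile.ranges[u]
        x = cc.abundances[u] / cc.total
        return lo - _MATCH_EPS <= x <= hi + _MATCH_EPS
    tot = sum(cc.abundances[u] for u in profile.divs)
    for u in profile.divs:
        lo, hi = profile.ranges[u]
        x = cc.abundances[u] / tot
        if not (lo - _MATCH_EPS <= x <= hi + _MATCH_EPS):
            return False
    return True


def _div_sum(cc: CladeCollection, profile: TypeProfile) -> float:
    return sum(cc.abundances.get(u, 0) for u in profile.divs) / cc.total


def resolve_overlaps(profiles: Sequence[TypeProfile], cc: CladeCollection
                     ) -> TypeProfile:
    """Pick one of several matching profiles that share DIVs.

    The winner holds the greatest summed DIV relative abundance in the
    collection; ties go to the profile with more DIVs, then the lower UID.
    """
    return min(profiles,
               key=lambda p: (-_div_sum(cc, p), -len(p.divs), p.uid))


def assign_profiles(cc: CladeCollection, profiles: Sequence[TypeProfile],
                    standalone_uids: set[int] | None = None
                    ) -> list[tuple[TypeProfile, float]]:
    """Profiles assigned to one clade collection, with within-clade shares.

    A profile matches when every DIV is present and each DIV's relative
    abundance (within the profile's DIV set) lies inside its characterized
    range.  A matching profile whose DIV set is covered by two or more
    disjoint matching profiles, each previously found as the sole profile
    of some sample (``standalone_uids``), is treated as an intergenomic
    composite and set aside in favour of the combination.  Remaining
    matches are assigned greedily: the best-covering profile always, then
    further standalone-validated profiles with DIV sets disjoint from all
    profiles already assigned.  Within-clade shares are the assigned
    profiles' collection DIV sums normalized to 1.
    """
    standalone_uids = standalone_uids or set()
    matches = [p for p in profiles if _profile_matches(cc, p)]
    if not matches:
        return []
    standalone = [p for p in matches if p.uid in standalone_uids]

    def decomposable(p: TypeProfile) -> bool:
        parts = [q for q in standalone if q.uid != p.uid
                 and set(q.divs) <= set(p.divs)]
        covered: set[int] = set()
        used = 0
        for q in sorted(parts, key=lambda q: (-len(q.divs), q.uid)):
            if covered & set(q.divs):
                continue
            covered |= set(q.divs)
            used += 1
        return used >= 2 and covered == set(p.divs)

    pool = [p for p in matches if not decomposable(p)]
    if not pool:
        pool = matches
    pool = sorted(pool, key=lambda p: (-_div_sum(cc, p), -len(p.divs), p.uid))
    assigned = [pool[0]]
    taken = set(pool[0].divs)
    for p in pool[1:]:
        if p.uid in standalone_uids and not (set(p.divs) & taken):
            assigned.append(p)
            taken |= set(p.divs)
    sums = {p.uid: _div_sum(cc, p) for p in assigned}
    total = sum(sums.values())
    return [(p, sums[p.uid] / total) for p in assigned]


def fallback_assign(cc: CladeCollection, registry: SequenceRegistry,
                    existing: Sequence[TypeProfile], next_uid: int
                    ) -> TypeProfile:
    """The single-DIV profile of a collection's most abundant sequence.

    Reuses an existing single-DIV profile for the same sequence when one
    exists, otherwise creates a new profile flagged as a fallback.
    """
    top = min(cc.abundances, key=lambda u: (-cc.abundances[u], u))
    for p in existing:
        if p.divs == [top]:
            if cc.id not in p.support:
                p.support.append(cc.id)
            return p
    profile = TypeProfile(uid=next_uid, clade=cc.clade, divs=[top],
                          ranges={top: (0.0, 1.0)}, majority_set={top},
                          support=[cc.id], fallback=True)
    profile.name = name_profile(profile, registry)
    return profile


def merge_genus_outputs(sample_id: str,
                        per_clade: Mapping[str, Sequence[tuple[int, float]]],
                        clade_totals: Mapping[str, int],
                        sample_total: int) -> list[ProfileAssignment]:
    """Re-merge clade-separated assignments into whole-sample abundances.

    Each within-clade share is multiplied by the clade's fraction of the
    sample's post-QC reads, so per-sample abundances sum to at most 1
    (exactly 1 when every clade collection received an assignment).
    """
    if sum(clade_totals.values()) > sample_total:
        raise ValueError(f"{sample_id}: clade totals exceed sample total")
    out = []
    for clade in sorted(per_clade):
        scale = clade_totals[clade] / sample_total
        for uid, within in per_clade[clade]:
            out.append(ProfileAssignment(sample_id=sample_id,
                                         profile_uid=uid,
                                         rel_abundance=within * scale))
    return out


def flag_super_types(profile: TypeProfile, registry: SequenceRegistry,
                     max_edits: int = 3) -> bool:
    """Warn when a profile's DIVs form two or more sequence radiations.

    DIVs are joined by edges when their sequences are within ``max_edits``
    nucleotide edits; two or more connected components suggest the profile
    conflates sequences of co-occurring taxa (an intergenomic "super
    type").  The profile is flagged, never split automatically.
    """
    if len(profile.divs) < 2:
        return False
    uids = sorted(profile.divs)
    parent = {u: u for u in uids}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for i, u in enumerate(uids):
        su = registry.get(u).sequence
        for v in uids[i + 1:]:
            d = edlib.align(su, registry.get(v).sequence,
                            task="distance")["editDistance"]
            if d <= max_edits:
                ru, rv = find(u), find(v)
                if ru != rv:
                    parent[ru] = rv
    return len({find(u) for u in uids}) >= 2


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisResult:
    """Everything one analysis produces."""

    profiles: list[TypeProfile]
    per_collection: dict[str, list[tuple[int, float]]]  # cc id -> assignments
    assignments: list[ProfileAssignment]                # merged, whole-sample
    super_type_flags: list[int] = field(default_factory=list)


def run_analysis(collections: Sequence[CladeCollection],
                 registry: SequenceRegistry, config: Config,
                 existing_profiles: Sequence[TypeProfile] = ()
                 ) -> AnalysisResult:
    """Discover, characterize and assign ITS2 type profiles.

    Orchestrates the clade-separated chain: footprint extraction over the
    searchable collections, greedy re-occurring-set discovery, multimodal
    splitting, characterization and naming, profile assignment with
    fallbacks, and cross-clade re-merging of abundances.  Profiles handed
    in from earlier analyses keep their UIDs and are re-supported; newly
    discovered duplicates of an existing DIV set merge into the existing
    profile.  Discovered profiles that end up assigned to no collection
    are pruned.  The procedure is deterministic for fixed inputs.
    """
    profiles: list[TypeProfile] = [p for p in existing_profiles]
    existing_uids = {p.uid for p in existing_profiles}
    existing_fallback = {p.uid for p in existing_profiles if p.fallback}
    next_uid = max((p.uid for p in profiles), default=0) + 1
    searchable = [cc for cc in collections
                  if cc.searchable(config.min_collection_size)]
    by_clade: dict[str, list[CladeCollection]] = {}
    for cc in searchable:
        by_clade.setdefault(cc.clade, []).append(cc)

    for clade in sorted(by_clade):
        footprints = [extract_footprint(cc, config.footprint_rel_cutoff,
                                        config.min_collection_size)
                      for cc in sorted(by_clade[clade],
                                       key=lambda c: c.id)]
        candidates = discover_candidate_profiles(footprints,
                                                 config.min_support)
        final: list[CandidateProfile] = []
        for cand in candidates:
            final.extend(split_multimodal(cand, config.min_support))
        for cand in final:
            prof = characterize_profile(cand, next_uid,
                                        config.range_tolerance)
            match = next(
                (p for p in profiles if p.clade == prof.clade
                 and p.divs == prof.divs
                 and p.majority_set == prof.majority_set), None)
            if match is not None:
                # re-supported from an earlier analysis: widen ranges
                for u in match.divs:
                    lo, hi = match.ranges[u]
                    nlo, nhi = prof.ranges[u]
                    match.ranges[u] = (min(lo, nlo), max(hi, nhi))
                match.support = sorted(set(match.support) | set(prof.support))
            else:
                profiles.append(prof)
                next_uid += 1

    for p in profiles:
        if not p.name:
            p.name = name_profile(p, registry)

    # first matching pass establishes which profiles stand alone somewhere
    prelim = {cc.id: [p for p in profiles if _profile_matches(cc, p)]
              for cc in searchable}
    standalone_uids = {ms[0].uid for ms in prelim.values() if len(ms) == 1}
    standalone_uids |= existing_uids - existing_fallback

    per_collection: dict[str, list[tuple[int, float]]] = {}
    for cc in sorted(searchable, key=lambda c: c.id):
        assigned = assign_profiles(cc, profiles, standalone_uids)
        if not assigned:
            fb = fallback_assign(cc, registry, profiles, next_uid)
            if fb.uid == next_uid:
                profiles.append(fb)
                next_uid += 1
            assigned = [(fb, 1.0)]
        per_collection[cc.id] = [(p.uid, x) for p, x in assigned]

    used = {uid for pairs in per_collection.values() for uid, _ in pairs}
    keep_uids = used | existing_uids
    profiles = [p for p in profiles if p.uid in keep_uids]

    by_sample: dict[str, list[CladeCollection]] = {}
    for cc in collections:
        by_sample.setdefault(cc.sample_id, []).append(cc)
    assignments: list[ProfileAssignment] = []
    for sample_id in sorted(by_sample):
        ccs = by_sample[sample_id]
        clade_totals = {cc.clade: cc.total for cc in ccs}
        per_clade = {cc.clade: per_collection.get(cc.id, [])
                     for cc in ccs}
        assignments.extend(
            merge_genus_outputs(sample_id, per_clade, clade_totals,
                                sum(clade_totals.values())))

    flags = [p.uid for p in profiles
             if not p.fallback and flag_super_types(p, registry)]
    return AnalysisResult(profiles=profiles, per_collection=per_collection,
                          assignments=assignments, super_type_flags=flags)
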