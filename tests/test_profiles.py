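"""Profile engine: footprints, discovery, splitting, naming, assignment."""

import numpy as np
import pytest

from its2div.core import (CladeCollection, Config, SequenceRegistry,
                          TypeProfile, catalogue_by_name)
from its2div.profiles import (CandidateProfile, Footprint, assign_profiles,
                              characterize_profile,
                              discover_candidate_profiles, extract_footprint,
                              fallback_assign, flag_super_types,
                              merge_genus_outputs, name_profile,
                              parse_profile_name, resolve_overlaps,
                              run_analysis, split_multimodal)


def _cc(sample, counts, clade="C"):
    return CladeCollection(sample_id=sample, clade=clade, abundances=counts)


def _fp(source, rel, clade="C"):
    """Footprint from a member -> collection-relative abundance map."""
    return Footprint(clade=clade, members=frozenset(rel), source=source,
                     rel_abundances=tuple(sorted(rel.items())))


class TestExtractFootprint:
    def test_members_at_or_above_cutoff(self):
        cc = _cc("s1", {1: 600, 2: 300, 3: 50, 4: 5})
        fp = extract_footprint(cc, footprint_rel_cutoff=0.01)
        assert fp.members == {1, 2, 3}

    def test_cutoff_zero_keeps_everything(self):
        cc = _cc("s1", {1: 600, 2: 300, 3: 50, 4: 5})
        assert extract_footprint(cc, 0.0).members == {1, 2, 3, 4}

    def test_all_below_cutoff_yields_singleton_majority(self):
        counts = {i: 2 for i in range(150)}
        counts[0] = 3
        cc = _cc("s1", counts)
        assert extract_footprint(cc, 0.05).members == {0}

    def test_unsearchable_collection_rejected(self):
        with pytest.raises(ValueError):
            extract_footprint(_cc("s1", {1: 100}), 0.01)


from _oracles import oracle_discover as _oracle_discover  # noqa: E402


class TestDiscovery:
    def test_recurring_pair_found_with_all_supporters(self):
        fps = [_fp(f"s{i}", {1: 0.7, 2: 0.3}) for i in range(3)]
        cands = discover_candidate_profiles(fps, min_support=2)
        assert len(cands) == 1
        assert cands[0].members == {1, 2}
        assert len(cands[0].supporting) == 3

    def test_nested_sets_resolved_largest_first(self):
        """Supporters of the larger set do not re-support its subset."""
        fps = [_fp(f"a{i}", {1: 0.5, 2: 0.3, 3: 0.2}) for i in range(4)]
        fps += [_fp(f"b{i}", {1: 0.6, 2: 0.4}) for i in range(3)]
        cands = discover_candidate_profiles(fps, min_support=3)
        assert [(c.members, len(c.supporting)) for c in cands] == \
            [(frozenset({1, 2, 3}), 4), (frozenset({1, 2}), 3)]

    def test_single_sample_yields_no_candidate(self):
        fps = [_fp("s1", {1: 0.9, 2: 0.1})]
        assert discover_candidate_profiles(fps, min_support=3) == []

    def test_mixed_footprint_supports_both_constituent_sets(self):
        """A two-genotype footprint is peeled into both genotype sets."""
        fps = [_fp(f"a{i}", {1: 0.6, 2: 0.4}) for i in range(3)]
        fps += [_fp(f"b{i}", {3: 0.7, 4: 0.3}) for i in range(3)]
        fps += [_fp("mix", {1: 0.3, 2: 0.2, 3: 0.35, 4: 0.15})]
        cands = discover_candidate_profiles(fps, min_support=3)
        sets = {c.members: set(c.supporting) for c in cands}
        assert sets[frozenset({1, 2})] >= {"a0", "a1", "a2", "mix"}
        assert sets[frozenset({3, 4})] >= {"b0", "b1", "b2", "mix"}

    def test_cross_clade_footprints_rejected(self):
        with pytest.raises(ValueError):
            discover_candidate_profiles(
                [_fp("s1", {1: 1.0}, "C"), _fp("s2", {2: 1.0}, "D")], 2)

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_on_random_instances(self, seed):
        """Greedy output equals exhaustive subset enumeration."""
        rng = np.random.default_rng(seed)
        n_seqs = int(rng.integers(3, 9))
        n_colls = int(rng.integers(3, 11))
        fps = []
        for i in range(n_colls):
            k = int(rng.integers(1, n_seqs + 1))
            members = sorted(rng.choice(n_seqs, size=k, replace=False) + 1)
            weights = rng.dirichlet(np.ones(k))
            fps.append(_fp(f"s{i:02d}",
                           {int(u): float(w)
                            for u, w in zip(members, weights)}))
        min_support = int(rng.integers(2, 4))
        got = [(c.members, tuple(c.supporting))
               for c in discover_candidate_profiles(fps, min_support)]
        assert got == _oracle_discover(fps, min_support)


def _candidate(members, per_sample):
    """CandidateProfile from {sample: {uid: abundance}}."""
    return CandidateProfile(clade="C", members=frozenset(members),
                            supporting=sorted(per_sample),
                            abundances={s: dict(v)
                                        for s, v in per_sample.items()})


class TestSplitMultimodal:
    def test_unimodal_candidate_untouched(self):
        rng = np.random.default_rng(0)
        per = {f"s{i}": {1: 0.3 + rng.normal(0, 0.01)} for i in range(8)}
        cand = _candidate({1}, per)
        assert split_multimodal(cand, min_support=3) == [cand]

    def test_two_well_separated_modes_split_supporters(self):
        per = {}
        for i in range(6):
            per[f"lo{i}"] = {1: 0.05 + 0.003 * i, 2: 0.95 - 0.003 * i}
        for i in range(6):
            per[f"hi{i}"] = {1: 0.40 + 0.003 * i, 2: 0.60 - 0.003 * i}
        out = split_multimodal(_candidate({1, 2}, per), min_support=3)
        assert len(out) == 2
        supporter_sets = sorted(tuple(c.supporting) for c in out)
        assert all(s.startswith("hi") for s in supporter_sets[0])
        assert all(s.startswith("lo") for s in supporter_sets[1])
        assert all(c.members == frozenset({1, 2}) for c in out)

    def test_minor_mode_below_support_not_split(self):
        per = {f"lo{i}": {1: 0.05} for i in range(2)}
        per |= {f"hi{i}": {1: 0.40 + 0.001 * i} for i in range(7)}
        out = split_multimodal(_candidate({1}, per), min_support=3)
        assert len(out) == 1


class TestCharacterize:
    def test_ranges_are_observed_min_max(self):
        per = {"s1": {1: 0.5, 2: 0.5}, "s2": {1: 0.6, 2: 0.4},
               "s3": {1: 0.55, 2: 0.45}}
        p = characterize_profile(_candidate({1, 2}, per), uid=7)
        assert p.ranges[1] == (0.5, 0.6)
        assert p.ranges[2] == (0.4, 0.5)
        assert p.divs == [1, 2]
        assert p.majority_set == {1}

    def test_range_tolerance_widens_fractionally(self):
        per = {"s1": {1: 0.5}, "s2": {1: 0.6}, "s3": {1: 0.55}}
        p = characterize_profile(_candidate({1}, per), uid=1,
                                 range_tolerance=0.1)
        assert p.ranges[1] == (pytest.approx(0.45), pytest.approx(0.66))

    def test_comajority_recorded(self):
        per = {"s1": {1: 0.6, 2: 0.4}, "s2": {1: 0.4, 2: 0.6},
               "s3": {1: 0.55, 2: 0.45}}
        p = characterize_profile(_candidate({1, 2}, per), uid=1)
        assert p.majority_set == {1, 2}


class TestNaming:
    def _registry_with(self, names):
        reg = SequenceRegistry.with_bundled_catalogue()
        cat = catalogue_by_name()
        return reg, [reg.register(cat[n][1], cat[n][0]) for n in names]

    def test_single_majority_name_joined_by_dashes(self):
        reg, uids = self._registry_with(["C3", "C3gulf", "C3c", "C3aq"])
        p = TypeProfile(uid=1, clade="C", divs=uids,
                        ranges={u: (0, 1) for u in uids},
                        majority_set={uids[0]})
        assert name_profile(p, reg) == "C3-C3gulf-C3c-C3aq"

    def test_comajority_denoted_by_slash(self):
        reg, uids = self._registry_with(["C3", "C3c", "C3gulf"])
        p = TypeProfile(uid=1, clade="C", divs=uids,
                        ranges={u: (0, 1) for u in uids},
                        majority_set={uids[0], uids[1]})
        assert name_profile(p, reg) == "C3/C3c-C3gulf"

    def test_single_div_profile_is_bare_name(self):
        reg, uids = self._registry_with(["C3"])
        p = TypeProfile(uid=1, clade="C", divs=uids,
                        ranges={uids[0]: (0, 1)}, majority_set={uids[0]})
        assert name_profile(p, reg) == "C3"

    def test_unnamed_divs_rendered_as_uid(self):
        reg = SequenceRegistry()
        u = reg.register("ACGT" * 50, "C")
        p = TypeProfile(uid=1, clade="C", divs=[u], ranges={u: (0, 1)},
                        majority_set={u})
        assert name_profile(p, reg) == str(u)

    @pytest.mark.parametrize("names,n_major", [
        (["C3", "C3gulf", "C3c", "C3aq"], 1),
        (["C3", "C3c", "C3gulf"], 2),
        (["C15", "C15x"], 1),
        (["D1"], 1),
    ])
    def test_name_round_trip(self, names, n_major):
        """parse(name(p)) recovers the ordered DIV names and majority set."""
        reg, uids = self._registry_with(names)
        p = TypeProfile(uid=1, clade=names[0][0], divs=uids,
                        ranges={u: (0, 1) for u in uids},
                        majority_set=set(uids[:n_major]))
        ordered, majority = parse_profile_name(name_profile(p, reg))
        assert ordered == names
        assert majority == names[:n_major]


def _profile(uid, ranges, majority=None, clade="C", fallback=False):
    divs = sorted(ranges, key=lambda u: -sum(ranges[u]) / 2)
    return TypeProfile(uid=uid, clade=clade, divs=divs,
                       ranges={u: tuple(r) for u, r in ranges.items()},
                       majority_set=majority or {divs[0]}, fallback=fallback)


class TestAssignment:
    def test_profile_assigned_when_divs_within_ranges(self):
        p = _profile(1, {1: (0.55, 0.65), 2: (0.35, 0.45)})
        cc = _cc("s1", {1: 600, 2: 400, 3: 10})
        out = assign_profiles(cc, [p])
        assert [(q.uid, pytest.approx(x)) for q, x in out] == [(1, 1.0)]

    def test_div_below_range_minimum_blocks_assignment(self):
        p = _profile(1, {1: (0.5, 0.6), 2: (0.4, 0.5)})
        cc = _cc("s1", {1: 950, 2: 50})  # DIV 2 at 0.05, below 0.4
        assert assign_profiles(cc, [p]) == []

    def test_missing_div_blocks_assignment(self):
        p = _profile(1, {1: (0.0, 1.0), 2: (0.0, 1.0)})
        assert assign_profiles(_cc("s1", {1: 1000}), [p]) == []

    def test_two_disjoint_standalone_profiles_both_assigned(self):
        pa = _profile(1, {1: (0.5, 0.7), 2: (0.3, 0.5)})
        pb = _profile(2, {3: (0.6, 0.8), 4: (0.2, 0.4)})
        cc = _cc("s1", {1: 360, 2: 240, 3: 280, 4: 120})
        out = assign_profiles(cc, [pa, pb], standalone_uids={1, 2})
        assert [q.uid for q, _ in out] == [1, 2]
        assert sum(x for _, x in out) == pytest.approx(1.0)

    def test_non_standalone_second_profile_not_added(self):
        pa = _profile(1, {1: (0.5, 0.7), 2: (0.3, 0.5)})
        pb = _profile(2, {3: (0.6, 0.8), 4: (0.2, 0.4)})
        cc = _cc("s1", {1: 360, 2: 240, 3: 280, 4: 120})
        out = assign_profiles(cc, [pa, pb], standalone_uids={1})
        assert [q.uid for q, _ in out] == [1]

    def test_composite_profile_set_aside_for_standalone_pair(self):
        """A union profile loses to its two standalone constituents."""
        pa = _profile(1, {1: (0.5, 0.7), 2: (0.3, 0.5)})
        pb = _profile(2, {3: (0.6, 0.8), 4: (0.2, 0.4)})
        punion = _profile(3, {1: (0.3, 0.4), 2: (0.2, 0.3),
                              3: (0.25, 0.35), 4: (0.1, 0.2)})
        cc = _cc("s1", {1: 360, 2: 240, 3: 280, 4: 120})
        out = assign_profiles(cc, [pa, pb, punion],
                              standalone_uids={1, 2})
        assert sorted(q.uid for q, _ in out) == [1, 2]

    def test_fallback_profile_requires_majority_sequence(self):
        fb = _profile(1, {1: (0.0, 1.0)}, fallback=True)
        assert assign_profiles(_cc("s1", {1: 600, 2: 400}), [fb])
        assert assign_profiles(_cc("s1", {1: 400, 2: 600}), [fb]) == []


class TestResolveOverlaps:
    def test_greatest_div_abundance_wins(self):
        p1 = _profile(1, {1: (0, 1), 2: (0, 1)})
        p2 = _profile(2, {1: (0, 1), 3: (0, 1)})
        cc = _cc("s1", {1: 500, 2: 320, 3: 50})
        assert resolve_overlaps([p1, p2], cc).uid == 1

    def test_equal_sums_more_divs_wins(self):
        p1 = _profile(1, {1: (0, 1), 2: (0, 1), 3: (0, 1), 4: (0, 1)})
        p2 = _profile(2, {1: (0, 1), 2: (0, 1), 5: (0, 1)})
        cc = _cc("s1", {1: 300, 2: 300, 3: 100, 4: 100, 5: 200})
        assert resolve_overlaps([p1, p2], cc).uid == 1

    def test_full_tie_breaks_to_lower_uid(self):
        p1 = _profile(4, {1: (0, 1), 2: (0, 1)})
        p2 = _profile(2, {1: (0, 1), 3: (0, 1)})
        cc = _cc("s1", {1: 400, 2: 300, 3: 300})
        assert resolve_overlaps([p1, p2], cc).uid == 2


class TestFallback:
    def test_most_abundant_sequence_defines_fallback(self, registry):
        cat = catalogue_by_name()
        u3 = registry.register(cat["C3"][1], "C")
        ug = registry.register(cat["C3gulf"][1], "C")
        cc = _cc("s1", {u3: 700, ug: 300})
        fb = fallback_assign(cc, registry, [], next_uid=10)
        assert fb.divs == [u3] and fb.fallback and fb.name == "C3"

    def test_tie_goes_to_lower_uid(self, registry):
        u1 = registry.register("ACGT" * 50, "C")
        u2 = registry.register("TGCA" * 50, "C")
        cc = _cc("s1", {u2: 500, u1: 500})
        assert fallback_assign(cc, registry, [], 10).divs == [min(u1, u2)]

    def test_existing_single_div_profile_reused(self, registry):
        u1 = registry.register("ACGT" * 50, "C")
        existing = TypeProfile(uid=3, clade="C", divs=[u1],
                               ranges={u1: (0, 1)}, majority_set={u1},
                               support=["s0|C"], fallback=True)
        fb = fallback_assign(_cc("s1", {u1: 100}), registry, [existing], 10)
        assert fb.uid == 3
        assert fb.support == ["s0|C", "s1|C"]


class TestMergeGenusOutputs:
    def test_abundances_scaled_by_clade_share(self):
        out = merge_genus_outputs("s1", {"C": [(1, 1.0)], "A": [(2, 1.0)]},
                                  {"C": 150, "A": 50}, 200)
        shares = {a.profile_uid: a.rel_abundance for a in out}
        assert shares == {1: pytest.approx(0.75), 2: pytest.approx(0.25)}

    def test_single_clade_unchanged(self):
        out = merge_genus_outputs("s1", {"C": [(1, 0.8), (2, 0.2)]},
                                  {"C": 400}, 400)
        assert [a.rel_abundance for a in out] == [
            pytest.approx(0.8), pytest.approx(0.2)]

    def test_partial_clade_share_scales(self):
        out = merge_genus_outputs("s1", {"C": [(1, 0.8)]}, {"C": 100}, 200)
        assert out[0].rel_abundance == pytest.approx(0.40)

    def test_clade_totals_exceeding_sample_total_raise(self):
        with pytest.raises(ValueError):
            merge_genus_outputs("s1", {"C": [(1, 1.0)]}, {"C": 300}, 200)


class TestSuperTypeFlag:
    def test_single_radiation_passes(self, registry):
        cat = catalogue_by_name()
        uids = [registry.register(cat[n][1], "C")
                for n in ["C3", "C3gulf", "C3c", "C3aq"]]
        p = TypeProfile(uid=1, clade="C", divs=uids,
                        ranges={u: (0, 1) for u in uids},
                        majority_set={uids[0]})
        assert flag_super_types(p, registry) is False

    def test_two_distant_radiations_flagged(self, registry):
        cat = catalogue_by_name()
        uids = [registry.register(cat[n][1], "C")
                for n in ["C3", "C3gulf", "C15", "C15x"]]
        p = TypeProfile(uid=1, clade="C", divs=uids,
                        ranges={u: (0, 1) for u in uids},
                        majority_set={uids[0]})
        assert flag_super_types(p, registry) is True

    def test_single_div_profile_passes(self, registry):
        u = registry.register("ACGT" * 50, "C")
        p = TypeProfile(uid=1, clade="C", divs=[u], ranges={u: (0, 1)},
                        majority_set={u})
        assert flag_super_types(p, registry) is False


class TestRunAnalysis:
    def _toy_collections(self, registry):
        cat = catalogue_by_name()
        u = {n: registry.register(cat[n][1], cat[n][0])
             for n in ["C3", "C3gulf", "C15", "C15x", "D1", "D4"]}
        colls = []
        rng = np.random.default_rng(3)
        for i in range(4):
            n3 = 600 + int(rng.integers(-20, 20))
            colls.append(_cc(f"a{i}", {u["C3"]: n3, u["C3gulf"]: 1000 - n3}))
        for i in range(4):
            n15 = 700 + int(rng.integers(-20, 20))
            colls.append(_cc(f"b{i}", {u["C15"]: n15,
                                       u["C15x"]: 1000 - n15}))
        return colls, u

    def test_rerun_on_identical_data_is_identical(self, registry):
        colls, _ = self._toy_collections(registry)
        r1 = run_analysis(colls, registry, Config())
        r2 = run_analysis(colls, registry, Config())
        assert [(p.uid, p.name, p.divs) for p in r1.profiles] == \
            [(p.uid, p.name, p.divs) for p in r2.profiles]
        assert r1.per_collection == r2.per_collection
        assert r1.assignments == r2.assignments

    def test_existing_profiles_retained_and_resupported(self, registry):
        colls, _ = self._toy_collections(registry)
        r1 = run_analysis(colls, registry, Config())
        r2 = run_analysis(colls, registry, Config(),
                          existing_profiles=r1.profiles)
        assert {p.uid for p in r1.profiles} <= {p.uid for p in r2.profiles}
        # unchanged samples keep their assignments
        assert r2.per_collection == r1.per_collection

    def test_every_searchable_collection_receives_a_profile(self, registry):
        colls, _ = self._toy_collections(registry)
        result = run_analysis(colls, registry, Config())
        for cc in colls:
            if cc.searchable(200):
                assert result.per_collection[cc.id]

    def test_assignment_only_references_present_sequences(self, small_study_qc):
        colls, _, registry, _ = small_study_qc
        result = run_analysis(colls, registry, Config())
        by_uid = {p.uid: p for p in result.profiles}
        cc_by_id = {cc.id: cc for cc in colls}
        for cc_id, pairs in result.per_collection.items():
            for uid, _ in pairs:
                assert set(by_uid[uid].divs) <= set(cc_by_id[cc_id].abundances)

    def test_merged_abundances_sum_to_one(self, small_study_qc):
        colls, _, registry, _ = small_study_qc
        result = run_analysis(colls, registry, Config())
        sums: dict[str, float] = {}
        for a in result.assignments:
            sums[a.sample_id] = sums.get(a.sample_id, 0.0) + a.rel_abundance
        for total in sums.values():
            assert total == pytest.approx(1.0, abs=1e-9)
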