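"""Marker filtering, map merging, linkage-group resolution and splitting."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anchorkit.io_formats import AlignmentHit, GeneticMapRecord
from anchorkit.marker_anchor import (
    PlacedMarker,
    ScaffoldPlacement,
    SplitDecision,
    UnplacedScaffold,
    apply_splits,
    filter_hits,
    merge_map_positions,
    place_markers,
    reassign_markers,
    resolve_scaffold_lg,
)


def _hit(qid="m1", tid="s1", identity=0.95, coverage=0.95, start=0, end=100, strand="+"):
    return AlignmentHit(qid, tid, identity, coverage, start, end, strand)


class TestFilterHits:
    def test_strict_90_90_boundary(self):
        kept = _hit(identity=0.95, coverage=0.92)
        at_boundary = _hit(identity=0.90, coverage=0.95)
        assert filter_hits([kept, at_boundary]) == [kept]

    @given(
        st.lists(
            st.tuples(st.floats(0.8, 1.0), st.floats(0.8, 1.0)),
            max_size=100,
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_matches_independent_predicate_scan(self, pairs):
        hits = [_hit(qid=f"m{i}", identity=i_, coverage=c) for i, (i_, c) in enumerate(pairs)]
        expected = [h for h in hits if h.identity > 0.9 and h.coverage > 0.9]
        assert filter_hits(hits) == expected


class TestMergeMapPositions:
    @pytest.mark.parametrize(
        "pub,new,expected",
        [
            (10.0, 50.0, 10.0),   # >30 cM apart: published wins
            (10.0, 20.0, 15.0),   # within 30 cM: mean
            (10.0, None, 10.0),   # single source
            (None, 7.5, 7.5),
            (10.0, 40.0, 25.0),   # exactly 30 cM is not "more than"
        ],
    )
    def test_merge_rules(self, pub, new, expected):
        assert merge_map_positions(pub, new) == pytest.approx(expected)

    def test_both_absent_is_an_error(self):
        with pytest.raises(ValueError):
            merge_map_positions(None, None)


class TestPlaceMarkers:
    MAP_PUB = [GeneticMapRecord("m1", "LG1", 10.0, "published"),
               GeneticMapRecord("m3", "LG2", 5.0, "published")]
    MAP_NEW = [GeneticMapRecord("m1", "LG1", 20.0, "new"),
               GeneticMapRecord("m3", "LG1", 6.0, "new")]

    def test_single_hit_published_only_marker(self):
        res = place_markers([_hit("m1", "s1")], self.MAP_PUB, [])
        (m,) = res.placed
        assert not m.ambiguous and m.cm_resolved == 10.0 and m.linkage_group == "LG1"

    def test_multi_position_marker_tagged_and_retained(self):
        res = place_markers(
            [_hit("m1", "s1"), _hit("m1", "s2", start=500, end=600)],
            self.MAP_PUB, self.MAP_NEW,
        )
        assert len(res.placed) == 2
        assert all(m.ambiguous for m in res.placed)
        # both maps agree on LG1: positions averaged
        assert all(m.cm_resolved == 15.0 for m in res.placed)

    def test_marker_absent_from_both_maps_dropped(self):
        res = place_markers([_hit("mX", "s1")], self.MAP_PUB, self.MAP_NEW)
        assert res.placed == [] and res.dropped_unmapped == ["mX"]

    def test_cross_map_linkage_group_conflict_removed(self):
        res = place_markers([_hit("m3", "s1")], self.MAP_PUB, self.MAP_NEW)
        (m,) = res.placed
        assert m.removed and m.removed_reason == "discordant_unresolvable"
        assert m.cm_resolved is None


def _pm(mid, sid, pos, lg, cm, ambiguous=False):
    return PlacedMarker(
        marker_id=mid, scaffold_id=sid, scaffold_pos=pos,
        linkage_group=lg, cm_resolved=cm, ambiguous=ambiguous,
    )


class TestResolveScaffoldLg:
    def test_unanimous_markers_mean_cm(self):
        ms = [_pm("a", "s", 10, "LG1", 5.0), _pm("b", "s", 20, "LG1", 10.0),
              _pm("c", "s", 30, "LG1", 15.0)]
        out = resolve_scaffold_lg(ms)
        assert isinstance(out, ScaffoldPlacement)
        assert out.linkage_group == "LG1" and out.cm_key == pytest.approx(10.0)
        assert out.n_support_markers == 3

    def test_single_dissenter_removed_majority_placed(self):
        ms = [_pm("a", "s", 10, "LG1", 5.0), _pm("b", "s", 20, "LG1", 6.0),
              _pm("c", "s", 30, "LG2", 40.0)]
        out = resolve_scaffold_lg(ms)
        assert isinstance(out, ScaffoldPlacement) and out.linkage_group == "LG1"
        dissenter = next(m for m in ms if m.marker_id == "c")
        assert dissenter.removed and dissenter.removed_reason == "dissenter"

    def test_two_coordinate_separated_groups_split_at_midpoint(self):
        ms = [_pm("a", "s", 10_000, "LG1", 5.0), _pm("b", "s", 20_000, "LG1", 6.0),
              _pm("c", "s", 80_000, "LG2", 40.0), _pm("d", "s", 90_000, "LG2", 41.0)]
        out = resolve_scaffold_lg(ms)
        assert isinstance(out, SplitDecision)
        assert out.split_pos == 50_000
        assert (out.left_lg, out.right_lg) == ("LG1", "LG2")

    def test_fully_interleaved_groups_unplaceable(self):
        ms = [_pm("a", "s", 10, "LG1", 5.0), _pm("b", "s", 20, "LG2", 40.0),
              _pm("c", "s", 30, "LG1", 6.0), _pm("d", "s", 40, "LG2", 41.0)]
        out = resolve_scaffold_lg(ms)
        assert isinstance(out, UnplacedScaffold) and out.interleaved

    def test_one_vs_one_is_unplaceable(self):
        ms = [_pm("a", "s", 10, "LG1", 5.0), _pm("b", "s", 20, "LG2", 40.0)]
        assert isinstance(resolve_scaffold_lg(ms), UnplacedScaffold)

    def test_empty_and_ambiguous_only_rules(self):
        assert isinstance(resolve_scaffold_lg([]), UnplacedScaffold)
        # one multi-position marker cannot place a scaffold alone
        lone = [_pm("a", "s", 10, "LG1", 5.0, ambiguous=True)]
        assert isinstance(resolve_scaffold_lg(lone), UnplacedScaffold)
        # two agreeing multi-position markers can
        pair = [_pm("a", "s", 10, "LG1", 5.0, ambiguous=True),
                _pm("b", "s", 20, "LG1", 6.0, ambiguous=True)]
        out = resolve_scaffold_lg(pair)
        assert isinstance(out, ScaffoldPlacement) and out.linkage_group == "LG1"

    def test_ambiguous_markers_do_not_outvote_unambiguous(self):
        ms = [_pm("a", "s", 10, "LG1", 5.0),
              _pm("x", "s", 20, "LG2", 40.0, ambiguous=True),
              _pm("y", "s", 30, "LG2", 41.0, ambiguous=True)]
        out = resolve_scaffold_lg(ms)
        assert isinstance(out, ScaffoldPlacement) and out.linkage_group == "LG1"

    def test_single_stray_inside_other_group_removed_and_split(self):
        # a lone wrong-linkage-group marker stranded in the other group's
        # coordinate range must not block an otherwise clean split
        ms = [_pm("a", "s", 10_000, "LG1", 5.0), _pm("b", "s", 20_000, "LG1", 6.0),
              _pm("c", "s", 30_000, "LG1", 7.0),
              _pm("x", "s", 50_000, "LG1", 35.0),  # stray: in the LG2 block, far off-map for LG1
              _pm("d", "s", 45_000, "LG2", 40.0), _pm("e", "s", 60_000, "LG2", 41.0),
              _pm("f", "s", 70_000, "LG2", 42.0)]
        out = resolve_scaffold_lg(ms)
        assert isinstance(out, SplitDecision)
        assert (out.left_lg, out.right_lg) == ("LG1", "LG2")
        assert out.split_pos == 37_500  # midpoint of 30k and 45k once the stray is gone
        stray = next(m for m in ms if m.marker_id == "x")
        assert stray.removed and stray.removed_reason == "dissenter"

    @given(st.permutations(range(6)))
    @settings(derandomize=True, max_examples=30)
    def test_resolution_is_permutation_invariant(self, order):
        base = [
            _pm("a", "s", 10_000, "LG1", 5.0), _pm("b", "s", 20_000, "LG1", 6.0),
            _pm("c", "s", 35_000, "LG1", 7.0),
            _pm("d", "s", 70_000, "LG2", 40.0), _pm("e", "s", 80_000, "LG2", 41.0),
            _pm("f", "s", 95_000, "LG2", 42.0),
        ]
        reference = resolve_scaffold_lg([_copy(m) for m in base])
        permuted = resolve_scaffold_lg([_copy(base[i]) for i in order])
        assert type(reference) is type(permuted)
        assert permuted.split_pos == reference.split_pos
        assert (permuted.left_lg, permuted.right_lg) == (reference.left_lg, reference.right_lg)


def _copy(m: PlacedMarker) -> PlacedMarker:
    return PlacedMarker(**vars(m))


class TestSplitsApplication:
    def test_sequences_partitioned_and_markers_shifted(self):
        seqs = {"s": "A" * 100_000}
        sd = SplitDecision("s", split_pos=50_000, left_lg="LG1", right_lg="LG2")
        out = apply_splits(seqs, [sd])
        assert len(out["s_1"]) == 50_000 and len(out["s_2"]) == 50_000
        assert "s" not in out
        ms = [_pm("a", "s", 10_000, "LG1", 5.0), _pm("b", "s", 80_000, "LG2", 40.0)]
        moved = reassign_markers(ms, [sd])
        assert (moved[0].scaffold_id, moved[0].scaffold_pos) == ("s_1", 10_000)
        assert (moved[1].scaffold_id, moved[1].scaffold_pos) == ("s_2", 30_000)

    def test_split_at_boundary_rejected(self):
        sd = SplitDecision("s", split_pos=0, left_lg="LG1", right_lg="LG2")
        with pytest.raises(ValueError):
            apply_splits({"s": "ACGT"}, [sd])


class TestStateReconciliation:
    def test_every_marker_ends_in_exactly_one_state(self):
        """placed / removed-with-reason / dropped-unmapped counts reconcile."""
        map_pub = [GeneticMapRecord(f"m{i}", "LG1", float(i), "published") for i in range(4)]
        map_new = [GeneticMapRecord("m3", "LG2", 3.0, "new")]  # conflicts with published LG1
        hits = [_hit(f"m{i}", "s1", start=i * 10, end=i * 10 + 100) for i in range(4)]
        hits.append(_hit("mZ", "s1", start=900, end=1000))  # in neither map
        res = place_markers(hits, map_pub, map_new)
        n_ok = sum(1 for m in res.placed if not m.removed)
        n_removed = sum(1 for m in res.placed if m.removed)
        assert n_ok + n_removed + len(res.dropped_unmapped) == len(hits)
        assert n_removed == 1 and res.dropped_unmapped == ["mZ"]
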