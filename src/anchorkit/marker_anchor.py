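"""Marker-based scaffold anchoring.

Resolves each scaffold's linkage group and map position from marker
alignments against two genetic maps (a previously published map and a new
map), using the following rules:

* alignments kept only when identity and coverage both exceed 90% (strict);
* markers aligning to more than one position are tagged ambiguous but
  retained; they never decide a linkage group on their own;
* a marker placed by both maps keeps the published position when the two
  maps disagree by more than 30 cM, otherwise the mean of the two;
* a single marker dissenting from the linkage group of the other markers
  on its scaffold is removed;
* a scaffold with two well-supported (>=2 markers each) linkage groups is
  split in two when the marker groups are coordinate-separable (chimeric
  scaffold), at the midpoint between the innermost markers of the groups.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .io_formats import AlignmentHit, GeneticMapRecord

log = logging.getLogger(__name__)

REASON_NONE = "none"
REASON_DISSENTER = "dissenter"
REASON_DISCORDANT = "discordant_unresolvable"


@dataclass
class PlacedMarker:
    """A marker resolved onto a scaffold position with map evidence."""

    marker_id: str
    scaffold_id: str
    scaffold_pos: int  # 0-based
    linkage_group: str | None
    cm_published: float | None = None
    cm_new: float | None = None
    cm_resolved: float | None = None
    ambiguous: bool = False
    removed: bool = False
    removed_reason: str = REASON_NONE


@dataclass
class ScaffoldPlacement:
    scaffold_id: str
    linkage_group: str
    cm_key: float
    orientation: str = "?"
    evidence: str = "marker"  # 'marker' or 'bac_link'
    split_of: str | None = None
    n_support_markers: int = 0
    insert_rank: int = 0  # 0 for marker placements; >=1 for bac_link inserts
    anchored_to: str | None = None  # anchor scaffold for bac_link placements


@dataclass
class SplitDecision:
    scaffold_id: str
    split_pos: int
    left_lg: str
    right_lg: str
    interleaved: bool = False


@dataclass
class UnplacedScaffold:
    scaffold_id: str
    reason: str  # no_markers | tie | interleaved | multi_lg | ambiguous_only
    interleaved: bool = False


@dataclass
class MarkerPlacementResult:
    placed: list[PlacedMarker]
    dropped_unmapped: list[str]  # marker ids present in neither map


# ---------------------------------------------------------------------------


def filter_hits(
    hits: Iterable[AlignmentHit],
    min_identity: float = 0.90,
    min_coverage: float = 0.90,
) -> list[AlignmentHit]:
    """Keep hits with identity AND coverage strictly above the thresholds."""
    return [h for h in hits if h.identity > min_identity and h.coverage > min_coverage]


def merge_map_positions(
    cm_published: float | None,
    cm_new: float | None,
    max_discord_cm: float = 30.0,
) -> float:
    """Combine the two maps' positions for one marker.

    Both present and differing by more than ``max_discord_cm``: the published
    value wins; within the tolerance: arithmetic mean; one present: that one.
    """
    if cm_published is None and cm_new is None:
        raise ValueError("marker has no position in either map")
    if cm_published is None:
        return cm_new
    if cm_new is None:
        return cm_published
    if abs(cm_published - cm_new) > max_discord_cm:
        return cm_published
    return (cm_published + cm_new) / 2.0


def place_markers(
    filtered_hits: Sequence[AlignmentHit],
    map_published: Sequence[GeneticMapRecord],
    map_new: Sequence[GeneticMapRecord],
    max_discord_cm: float = 30.0,
) -> MarkerPlacementResult:
    """Turn retained marker alignments into PlacedMarkers.

    One PlacedMarker per (marker, scaffold, position) alignment; markers
    found in neither map are dropped (ids reported); a marker whose two maps
    disagree on the linkage group is kept but flagged removed with reason
    ``discordant_unresolvable``.
    """
    pub = {r.marker_id: r for r in map_published}
    new = {r.marker_id: r for r in map_new}
    n_hits_per_marker = Counter(h.query_id for h in filtered_hits)

    placed: list[PlacedMarker] = []
    dropped: list[str] = []
    for hit in filtered_hits:
        mid = hit.query_id
        rec_pub, rec_new = pub.get(mid), new.get(mid)
        if rec_pub is None and rec_new is None:
            if mid not in dropped:
                dropped.append(mid)
            continue
        removed, reason = False, REASON_NONE
        if rec_pub is not None and rec_new is not None and rec_pub.linkage_group != rec_new.linkage_group:
            removed, reason = True, REASON_DISCORDANT
            lg = None
        else:
            lg = rec_pub.linkage_group if rec_pub is not None else rec_new.linkage_group
        cm_pub = rec_pub.cm if rec_pub is not None else None
        cm_new = rec_new.cm if rec_new is not None else None
        marker = PlacedMarker(
            marker_id=mid,
            scaffold_id=hit.target_id,
            scaffold_pos=hit.target_start,
            linkage_group=lg,
            cm_published=cm_pub,
            cm_new=cm_new,
            ambiguous=n_hits_per_marker[mid] > 1,
            removed=removed,
            removed_reason=reason,
        )
        if not removed:
            marker.cm_resolved = merge_map_positions(cm_pub, cm_new, max_discord_cm)
        placed.append(marker)
    log.info(
        "place_markers: %d placements from %d hits; %d markers in neither map; "
        "%d discordant between maps",
        len(placed), len(filtered_hits), len(dropped),
        sum(1 for m in placed if m.removed_reason == REASON_DISCORDANT),
    )
    return MarkerPlacementResult(placed=placed, dropped_unmapped=dropped)


# ---------------------------------------------------------------------------


def resolve_scaffold_lg(
    markers: Sequence[PlacedMarker],
) -> ScaffoldPlacement | SplitDecision | UnplacedScaffold:
    """Vote over linkage groups for one scaffold's markers.

    Unambiguous markers vote; ambiguous (multi-position) markers are used
    only when no unambiguous marker exists, and then at least two of them
    must agree. Count-1 dissenting voters against a >=2 majority are marked
    removed. Two >=2 groups that are coordinate-separable yield a
    SplitDecision at the midpoint between the innermost markers.

    Markers already flagged removed may be mutated (dissenter marking);
    the decision is invariant under permutation of the marker list.
    """
    active = [m for m in markers if not m.removed and m.cm_resolved is not None]
    sid = markers[0].scaffold_id if markers else ""
    if not active:
        return UnplacedScaffold(sid, "no_markers")
    sid = active[0].scaffold_id

    unambiguous = [m for m in active if not m.ambiguous]
    if unambiguous:
        voters = unambiguous
    else:
        counts = Counter(m.linkage_group for m in active)
        if max(counts.values()) < 2:
            return UnplacedScaffold(sid, "ambiguous_only")
        voters = active

    counts = Counter(m.linkage_group for m in voters)
    # deterministic count-descending order, ties by name
    ranked = sorted(counts, key=lambda lg: (-counts[lg], lg))
    majors = [lg for lg in ranked if counts[lg] >= 2]
    singles = sorted(lg for lg in ranked if counts[lg] == 1)

    if len(counts) == 1:
        return _placement(sid, next(iter(counts)), active)

    if majors and singles:
        # count-1 dissenters against an established majority: remove them
        for m in voters:
            if m.linkage_group in singles and not m.ambiguous:
                m.removed = True
                m.removed_reason = REASON_DISSENTER
        active = [m for m in active if not m.removed]

    if len(majors) == 1:
        return _placement(sid, majors[0], active)
    if len(majors) >= 2:
        top_a, top_b = majors[0], majors[1]
        extra = majors[2:]
        # the method only ever splits a scaffold in two, so a third group
        # strictly outvoted by both main groups is dissenting noise; a group
        # as large as the weaker major is unresolvable
        if any(counts[lg] >= counts[top_b] for lg in extra):
            return UnplacedScaffold(sid, "multi_lg")
        for m in voters:
            if m.linkage_group in extra and not m.ambiguous:
                m.removed = True
                m.removed_reason = REASON_DISSENTER
        active = [m for m in active if not m.removed]
        return _split_or_interleaved(sid, (top_a, top_b), active)
    return UnplacedScaffold(sid, "tie")


def _placement(sid: str, lg: str, active: Sequence[PlacedMarker]) -> ScaffoldPlacement:
    support = [m for m in active if m.linkage_group == lg]
    cm_key = sum(m.cm_resolved for m in support) / len(support)
    return ScaffoldPlacement(
        scaffold_id=sid, linkage_group=lg, cm_key=cm_key,
        n_support_markers=len(support),
    )


def _split_or_interleaved(
    sid: str, majors: Sequence[str], active: Sequence[PlacedMarker]
) -> SplitDecision | UnplacedScaffold:
    """Split the scaffold between two well-supported linkage groups.

    All cuts (both left/right assignments) are scanned. Markers a cut
    strands on the wrong side ("strays") are capped at two per linkage
    group, each group's strays must be outnumbered 2:1 by its correctly
    sided markers, and both sides must keep at least two markers. Cuts are
    ranked by number of strays, then by the strays' cM incoherence with
    their claimed group (distance of the resolved position from the
    group's retained median): a corrupted label sits far from its group's
    map neighbourhood, a genuine member does not, so among equal-sized
    stray sets the least coherent markers are the ones removed. Strays are
    removed as dissenters; no feasible cut leaves the scaffold
    unplaceable.
    """
    lg_a, lg_b = majors
    voters = sorted(
        (m for m in active if not m.ambiguous and m.linkage_group in (lg_a, lg_b)),
        key=lambda m: (m.scaffold_pos, m.marker_id),
    )
    n = len(voters)
    is_a = [m.linkage_group == lg_a for m in voters]
    n_a = sum(is_a)
    n_b = n - n_a

    def median(values: list[float]) -> float:
        vs = sorted(values)
        k = len(vs)
        return (vs[(k - 1) // 2] + vs[k // 2]) / 2.0

    best = None  # (n_strays, -incoherence, direction, cut) + payload
    for direction in (0, 1):
        left_lg, right_lg = (lg_a, lg_b) if direction == 0 else (lg_b, lg_a)
        for cut in range(n + 1):
            strays = [
                m for i, m in enumerate(voters)
                if (m.linkage_group != left_lg) == (i < cut)
            ]
            stray_ids = {id(m) for m in strays}
            retained = [m for m in voters if id(m) not in stray_ids]
            stray_counts = Counter(m.linkage_group for m in strays)
            retained_counts = Counter(m.linkage_group for m in retained)
            left_ok = sum(1 for m in retained if m.linkage_group == left_lg)
            right_ok = len(retained) - left_ok
            if (
                any(
                    c > 2 or 2 * c > retained_counts.get(lg, 0)
                    for lg, c in stray_counts.items()
                )
                or left_ok < 2
                or right_ok < 2
            ):
                continue
            incoherence = 0.0
            for m in strays:
                group_cm = [
                    r.cm_resolved for r in retained if r.linkage_group == m.linkage_group
                ]
                if group_cm:
                    incoherence += abs(m.cm_resolved - median(group_cm))
            cand = (
                len(strays), -incoherence, direction, cut,
                strays, retained, left_lg, right_lg,
            )
            if best is None or cand[:4] < best[:4]:
                best = cand
    if best is None:
        return UnplacedScaffold(sid, "interleaved", interleaved=True)
    _, _, _, _, strays, retained, left_lg, right_lg = best
    for m in strays:
        m.removed = True
        m.removed_reason = REASON_DISSENTER
    left_max = max(m.scaffold_pos for m in retained if m.linkage_group == left_lg)
    right_min = min(m.scaffold_pos for m in retained if m.linkage_group == right_lg)
    split = (left_max + right_min) // 2
    return SplitDecision(sid, split_pos=split, left_lg=left_lg, right_lg=right_lg)


# ---------------------------------------------------------------------------


def apply_splits(
    sequences: Mapping[str, str],
    split_decisions: Sequence[SplitDecision],
) -> dict[str, str]:
    """Replace each split scaffold's sequence with '<id>_1' and '<id>_2'."""
    out = dict(sequences)
    for sd in split_decisions:
        if sd.scaffold_id not in out:
            raise KeyError(f"no sequence for split scaffold {sd.scaffold_id}")
        seq = out.pop(sd.scaffold_id)
        if not (0 < sd.split_pos < len(seq)):
            raise ValueError(
                f"split position {sd.split_pos} outside (0, {len(seq)}) "
                f"for {sd.scaffold_id}"
            )
        out[f"{sd.scaffold_id}_1"] = seq[: sd.split_pos]
        out[f"{sd.scaffold_id}_2"] = seq[sd.split_pos :]
    return out


def reassign_markers(
    markers: Sequence[PlacedMarker],
    split_decisions: Sequence[SplitDecision],
) -> list[PlacedMarker]:
    """Move markers of split scaffolds onto the child scaffolds, shifting
    coordinates for the right child."""
    splits = {sd.scaffold_id: sd for sd in split_decisions}
    out: list[PlacedMarker] = []
    for m in markers:
        sd = splits.get(m.scaffold_id)
        if sd is None:
            out.append(m)
        elif m.scaffold_pos < sd.split_pos:
            out.append(replace(m, scaffold_id=f"{m.scaffold_id}_1"))
        else:
            out.append(
                replace(
                    m,
                    scaffold_id=f"{m.scaffold_id}_2",
                    scaffold_pos=m.scaffold_pos - sd.split_pos,
                )
            )
    return out


@dataclass
class AnchoringResult:
    placements: list[ScaffoldPlacement]
    splits: list[SplitDecision]
    unplaced: list[UnplacedScaffold]
    markers: list[PlacedMarker]  # post-split marker set (reassigned to children)


def resolve_placements(markers: Sequence[PlacedMarker]) -> AnchoringResult:
    """Run linkage-group resolution over all scaffolds, apply split
    decisions to the marker set, and re-resolve the split children."""
    by_scaffold: dict[str, list[PlacedMarker]] = {}
    for m in markers:
        by_scaffold.setdefault(m.scaffold_id, []).append(m)

    placements: list[ScaffoldPlacement] = []
    splits: list[SplitDecision] = []
    unplaced: list[UnplacedScaffold] = []
    for sid in sorted(by_scaffold):
        outcome = resolve_scaffold_lg(by_scaffold[sid])
        if isinstance(outcome, ScaffoldPlacement):
            placements.append(outcome)
        elif isinstance(outcome, SplitDecision):
            splits.append(outcome)
        else:
            unplaced.append(outcome)

    final_markers = reassign_markers(list(markers), splits)
    if splits:
        child_ids = {f"{sd.scaffold_id}_{i}": sd.scaffold_id for sd in splits for i in (1, 2)}
        by_child: dict[str, list[PlacedMarker]] = {}
        for m in final_markers:
            if m.scaffold_id in child_ids:
                by_child.setdefault(m.scaffold_id, []).append(m)
        for cid in sorted(by_child):
            outcome = resolve_scaffold_lg(by_child[cid])
            if isinstance(outcome, ScaffoldPlacement):
                outcome.split_of = child_ids[cid]
                placements.append(outcome)
            elif isinstance(outcome, UnplacedScaffold):
                unplaced.append(outcome)
            # a second-level split of a child is not attempted
    log.info(
        "resolve_placements: %d placed, %d split, %d unplaceable scaffolds",
        len(placements), len(splits), len(unplaced),
    )
    return AnchoringResult(
        placements=placements, splits=splits, unplaced=unplaced, markers=final_markers
    )
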