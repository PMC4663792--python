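"""BAC-end / physical-map linking of scaffolds.

BAC-end alignments plus BAC -> physical-contig membership give each
scaffold a profile of alignment counts per contig. A scaffold-contig link
is accepted when

* all alignments point to one contig (**unique**, given a minimum total),
* more than half point to one contig with enough total support
  (**dominant**), or
* the top contig clearly outnumbers the runner-up (**strong**).

Spurious "sink" contigs — repeat-derived contigs linking indiscriminately
across the genome — are removed first, either by explicit id or by a
leave-one-out degree outlier test. Accepted links let unplaced scaffolds
inherit the position of a placed scaffold sharing the same contig.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import AlignmentHit, PhysicalMembership
from .marker_anchor import ScaffoldPlacement

log = logging.getLogger(__name__)

ACCEPTED_CATEGORIES = ("unique", "dominant", "strong")


@dataclass
class LinkCall:
    scaffold_id: str
    contig_id: str | None  # argmax contig; None when the top count is tied
    n_total: int
    n_to_contig: int
    category: str  # unique | dominant | strong | rejected


@dataclass
class SinkFilterResult:
    hits: list[AlignmentHit]
    removed_contigs: list[str]
    n_unresolved_hits: int


def membership_index(memberships: Iterable[PhysicalMembership]) -> dict[str, str]:
    """bac_id -> contig_id for BACs that belong to a contig."""
    return {m.bac_id: m.contig_id for m in memberships if m.contig_id is not None}


def _bac_of(query_id: str) -> str:
    """BAC id from an end-read id ('<bac>.f' / '<bac>.r'; else the id itself)."""
    if query_id.endswith((".f", ".r")):
        return query_id[:-2]
    return query_id


def filter_sink_contigs(
    bac_hits: Sequence[AlignmentHit],
    memberships: Iterable[PhysicalMembership] | Mapping[str, str],
    explicit_ids: Iterable[str] = (),
    auto: bool = True,
) -> SinkFilterResult:
    """Drop hits whose BAC belongs to a sink contig.

    ``explicit_ids`` names known sinks. With ``auto``, a contig is
    additionally removed when its scaffold degree (number of distinct
    scaffolds its BACs hit) both (a) exceeds mean + 3*SD of the other
    contigs' degrees — computed leave-one-out so an extreme sink cannot
    mask itself by inflating the spread — and (b) is at least 3.5 times
    the other contigs' 90th-percentile degree, so the heavy but genuine
    tail of large physical contigs is not mistaken for a sink.
    """
    bac2ctg = memberships if isinstance(memberships, Mapping) else membership_index(memberships)
    explicit = set(explicit_ids)

    resolved: list[tuple[AlignmentHit, str]] = []
    n_unresolved = 0
    for h in bac_hits:
        ctg = bac2ctg.get(_bac_of(h.query_id))
        if ctg is None:
            n_unresolved += 1
        else:
            resolved.append((h, ctg))
    if n_unresolved:
        log.info("filter_sink_contigs: dropped %d hits with no contig membership", n_unresolved)

    removed = sorted(explicit & {ctg for _, ctg in resolved})
    kept = [(h, ctg) for h, ctg in resolved if ctg not in explicit]

    if auto:
        degree: dict[str, set[str]] = {}
        for h, ctg in kept:
            degree.setdefault(ctg, set()).add(h.target_id)
        contigs = sorted(degree)
        degs = np.array([len(degree[c]) for c in contigs], dtype=float)
        if len(contigs) >= 3:
            auto_removed = []
            for i, c in enumerate(contigs):
                others = np.delete(degs, i)
                if degs[i] > others.mean() + 3.0 * others.std() and degs[
                    i
                ] >= 3.5 * np.percentile(others, 90):
                    auto_removed.append(c)
            if auto_removed:
                log.info("filter_sink_contigs: auto-detected sink contig(s): %s", auto_removed)
                removed = sorted(set(removed) | set(auto_removed))
                kept = [(h, ctg) for h, ctg in kept if ctg not in set(auto_removed)]

    return SinkFilterResult(
        hits=[h for h, _ in kept],
        removed_contigs=removed,
        n_unresolved_hits=n_unresolved,
    )


def classify_links(
    bac_hits: Sequence[AlignmentHit],
    memberships: Iterable[PhysicalMembership] | Mapping[str, str],
    min_total_unique: int = 2,
    min_total_dominant: int = 4,
    strong_ratio: float = 2.0,
    strong_min: int = 3,
) -> list[LinkCall]:
    """Classify each scaffold's best contig link as unique/dominant/strong.

    Per scaffold, alignments are counted per contig and the rules are
    evaluated in order: unique (all alignments to one contig, total >=
    ``min_total_unique``), dominant (top fraction > 0.5, total >=
    ``min_total_dominant``), strong (top >= ``strong_ratio`` x runner-up and
    top >= ``strong_min``); anything else, including a tied top, is
    rejected. Output is independent of hit order.
    """
    bac2ctg = memberships if isinstance(memberships, Mapping) else membership_index(memberships)
    per_scaffold: dict[str, Counter] = {}
    for h in bac_hits:
        ctg = bac2ctg.get(_bac_of(h.query_id))
        if ctg is None:
            continue
        per_scaffold.setdefault(h.target_id, Counter())[ctg] += 1

    calls: list[LinkCall] = []
    for sid in sorted(per_scaffold):
        counts = per_scaffold[sid]
        n_total = sum(counts.values())
        top_count = max(counts.values())
        top_contigs = sorted(c for c, n in counts.items() if n == top_count)
        if len(top_contigs) > 1:
            calls.append(LinkCall(sid, None, n_total, top_count, "rejected"))
            continue
        top = top_contigs[0]
        second = max((n for c, n in counts.items() if c != top), default=0)
        if len(counts) == 1 and n_total >= min_total_unique:
            category = "unique"
        elif top_count / n_total > 0.5 and n_total >= min_total_dominant:
            category = "dominant"
        elif top_count >= strong_ratio * second and top_count >= strong_min:
            category = "strong"
        else:
            category = "rejected"
        calls.append(LinkCall(sid, top if category != "rejected" else top, n_total, top_count, category))
    return calls


def resolve_anchor_lg(
    anchors: Sequence[tuple[ScaffoldPlacement, LinkCall]],
) -> tuple[str, list[tuple[ScaffoldPlacement, LinkCall]]] | None:
    """Linkage group a contig's placed neighbours agree on, or None.

    A lone dissenting neighbour against a clear majority (more anchoring
    scaffolds, or equal scaffolds but more supporting markers) is outvoted;
    two or more neighbours on a second linkage group, or an unbreakable
    tie, is a genuine conflict (None).
    """
    lgs = {p.linkage_group for p, _ in anchors}
    if len(lgs) == 1:
        return next(iter(lgs)), list(anchors)
    by_lg: dict[str, list[tuple[ScaffoldPlacement, LinkCall]]] = {}
    for p, c in anchors:
        by_lg.setdefault(p.linkage_group, []).append((p, c))
    ranked = sorted(
        by_lg,
        key=lambda lg: (
            -len(by_lg[lg]),
            -sum(p.n_support_markers for p, _ in by_lg[lg]),
            lg,
        ),
    )
    top, runner = ranked[0], ranked[1]
    tie = len(by_lg[top]) == len(by_lg[runner]) and sum(
        p.n_support_markers for p, _ in by_lg[top]
    ) == sum(p.n_support_markers for p, _ in by_lg[runner])
    substantive = any(len(by_lg[lg]) >= 2 for lg in ranked[1:])
    if tie or substantive:
        return None
    return top, by_lg[top]


def propagate_placement(
    link_calls: Sequence[LinkCall],
    marker_placements: Sequence[ScaffoldPlacement],
    exclude_scaffolds: Iterable[str] = (),
) -> tuple[list[ScaffoldPlacement], list[str]]:
    """Place unplaced scaffolds next to placed scaffolds sharing a contig.

    An unplaced scaffold with an accepted link to contig C, where at least
    one placed scaffold also holds an accepted link to C, is inserted
    immediately after the placed neighbour with the most alignments to C
    (ties broken by scaffold id), on that neighbour's linkage group, with
    unknown orientation. Placed scaffolds are never moved.

    When the placed neighbours disagree on the linkage group, the same
    single-dissenter principle used in marker anchoring applies: a lone
    dissenting neighbour against a clear majority (more anchoring
    scaffolds, or equal scaffolds but more supporting markers) is ignored;
    a substantive disagreement (two or more neighbours on a second linkage
    group, or an unbreakable tie) makes the contig abstain (conflict
    reported).

    ``exclude_scaffolds`` lists ids that must not be propagated (e.g. split
    chimera parents whose sequence now lives in the children).
    """
    placed_by_id = {p.scaffold_id: p for p in marker_placements}
    excluded = set(exclude_scaffolds)
    accepted = [c for c in link_calls if c.category in ACCEPTED_CATEGORIES]

    anchors_by_contig: dict[str, list[tuple[ScaffoldPlacement, LinkCall]]] = {}
    for call in accepted:
        p = placed_by_id.get(call.scaffold_id)
        if p is not None:
            anchors_by_contig.setdefault(call.contig_id, []).append((p, call))

    new_placements: list[ScaffoldPlacement] = []
    conflicts: list[str] = []
    next_rank: Counter = Counter()
    newly_placed: set[str] = set()
    for call in sorted(accepted, key=lambda c: c.scaffold_id):
        sid = call.scaffold_id
        if sid in placed_by_id or sid in excluded or sid in newly_placed:
            continue
        anchors = anchors_by_contig.get(call.contig_id, [])
        if not anchors:
            continue
        resolved = resolve_anchor_lg(anchors)
        if resolved is None:
            conflicts.append(sid)
            log.warning(
                "propagate_placement: %s links contig %s whose placed scaffolds "
                "disagree on linkage group (%s); abstaining",
                sid, call.contig_id, sorted({p.linkage_group for p, _ in anchors}),
            )
            continue
        _, anchors = resolved
        anchor, _ = min(anchors, key=lambda pc: (-pc[1].n_to_contig, pc[0].scaffold_id))
        newly_placed.add(sid)
        next_rank[anchor.scaffold_id] += 1
        new_placements.append(
            ScaffoldPlacement(
                scaffold_id=sid,
                linkage_group=anchor.linkage_group,
                cm_key=anchor.cm_key,
                orientation="?",
                evidence="bac_link",
                insert_rank=anchor.insert_rank + next_rank[anchor.scaffold_id],
                anchored_to=anchor.scaffold_id,
            )
        )
    log.info(
        "propagate_placement: %d scaffolds linked in, %d linkage-group conflicts",
        len(new_placements), len(conflicts),
    )
    return new_placements, conflicts
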