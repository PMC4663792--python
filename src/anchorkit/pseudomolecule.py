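"""Ordering, orienting and emitting gap-padded pseudomolecules.

Scaffolds are ordered within each linkage group by their map key (mean
resolved cM of supporting markers), oriented by the sign of the rank
correlation between marker base positions and cM positions, and
concatenated with fixed-length N gaps (default 10 kb) between joins.
Output is FASTA plus AGP v2.1.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .io_formats import AgpRow
from .marker_anchor import PlacedMarker, ScaffoldPlacement

log = logging.getLogger(__name__)

DEFAULT_GAP_LENGTH = 10_000
GAP_TYPE = "scaffold"
GAP_LINKAGE = "yes"
GAP_EVIDENCE = "map"


@dataclass
class Component:
    kind: str  # 'W' (scaffold segment) or 'N' (gap)
    length: int
    scaffold_id: str | None = None
    orientation: str | None = None  # '+', '-', '?'


@dataclass
class Pseudomolecule:
    name: str
    components: list[Component] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.components)

    def agp_rows(self) -> list[AgpRow]:
        rows: list[AgpRow] = []
        pos = 1
        for i, c in enumerate(self.components, start=1):
            end = pos + c.length - 1
            if c.kind == "W":
                rows.append(
                    AgpRow(
                        object_id=self.name, object_start=pos, object_end=end,
                        part_number=i, component_type="W",
                        component_id=c.scaffold_id, component_start=1,
                        component_end=c.length, orientation=c.orientation,
                    )
                )
            else:
                rows.append(
                    AgpRow(
                        object_id=self.name, object_start=pos, object_end=end,
                        part_number=i, component_type="N",
                        gap_length=c.length, gap_type=GAP_TYPE,
                        linkage=GAP_LINKAGE, evidence=GAP_EVIDENCE,
                    )
                )
            pos = end + 1
        return rows


# ---------------------------------------------------------------------------


def orient_scaffold(markers_on_scaffold: Sequence[PlacedMarker]) -> str:
    """Orientation from concordance of marker base position with cM.

    Sign of the Kendall-type concordant-minus-discordant pair count between
    ``scaffold_pos`` and ``cm_resolved``: positive -> '+', negative -> '-',
    zero or fewer than two usable markers -> '?'.
    """
    usable = [
        (m.scaffold_pos, m.cm_resolved)
        for m in markers_on_scaffold
        if not m.removed and m.cm_resolved is not None
    ]
    if len(usable) < 2:
        return "?"
    score = 0
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            dp = usable[j][0] - usable[i][0]
            dc = usable[j][1] - usable[i][1]
            if dp * dc > 0:
                score += 1
            elif dp * dc < 0:
                score -= 1
    if score > 0:
        return "+"
    if score < 0:
        return "-"
    return "?"


def _lg_sort_key(lg: str) -> tuple:
    m = re.search(r"(\d+)$", lg)
    return (int(m.group(1)), lg) if m else (float("inf"), lg)


def order_scaffolds(
    placements: Sequence[ScaffoldPlacement],
) -> dict[str, list[ScaffoldPlacement]]:
    """Deterministic per-linkage-group ordering.

    Sort key: (cm_key, insertion rank, scaffold id); insertion rank is 0 for
    marker placements and >=1 for scaffolds inserted after a BAC-link
    anchor, so inserted scaffolds follow their anchor.
    """
    by_lg: dict[str, list[ScaffoldPlacement]] = {}
    for p in placements:
        by_lg.setdefault(p.linkage_group, []).append(p)
    return {
        lg: sorted(by_lg[lg], key=lambda p: (p.cm_key, p.insert_rank, p.scaffold_id))
        for lg in sorted(by_lg, key=_lg_sort_key)
    }


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def build_pseudomolecules(
    ordered: Mapping[str, Sequence[ScaffoldPlacement]],
    sequences: Mapping[str, str],
    gap_length: int = DEFAULT_GAP_LENGTH,
    name_map: Mapping[str, str] | None = None,
) -> tuple[list[Pseudomolecule], dict[str, str]]:
    """Concatenate ordered, oriented scaffolds into pseudomolecules.

    '-' components are reverse-complemented; '?' is emitted as forward
    sequence but written as '?' in the AGP. k scaffolds get k-1 gaps of
    ``gap_length`` N's. Returns the pseudomolecules and their sequences.
    """
    if gap_length <= 0:
        raise ValueError("gap_length must be positive")
    pms: list[Pseudomolecule] = []
    seqs: dict[str, str] = {}
    for lg, placements in ordered.items():
        name = name_map.get(lg, lg) if name_map else lg
        pm = Pseudomolecule(name=name)
        parts: list[str] = []
        for k, p in enumerate(placements):
            if p.scaffold_id not in sequences:
                raise KeyError(f"no sequence for placed scaffold {p.scaffold_id}")
            if k > 0:
                pm.components.append(Component(kind="N", length=gap_length))
                parts.append("N" * gap_length)
            seq = sequences[p.scaffold_id]
            emitted = reverse_complement(seq) if p.orientation == "-" else seq
            pm.components.append(
                Component(
                    kind="W", length=len(seq),
                    scaffold_id=p.scaffold_id, orientation=p.orientation,
                )
            )
            parts.append(emitted)
        pms.append(pm)
        seqs[name] = "".join(parts)
        log.info("pseudomolecule %s: %d scaffolds, %d bp", name, len(placements), pm.total_length)
    return pms, seqs


# ---------------------------------------------------------------------------
# coordinate lifting (scaffold <-> pseudomolecule)
# ---------------------------------------------------------------------------


def lift_to_object(pm: Pseudomolecule, scaffold_id: str, pos: int) -> int:
    """0-based scaffold position -> 0-based pseudomolecule position.

    '?' components are treated as '+' (matching sequence emission).
    """
    offset = 0
    for c in pm.components:
        if c.kind == "W" and c.scaffold_id == scaffold_id:
            if not (0 <= pos < c.length):
                raise ValueError(f"position {pos} outside {scaffold_id}")
            if c.orientation == "-":
                return offset + (c.length - 1 - pos)
            return offset + pos
        offset += c.length
    raise KeyError(f"{scaffold_id} not in pseudomolecule {pm.name}")


def lift_from_object(pm: Pseudomolecule, obj_pos: int) -> tuple[str, int] | None:
    """0-based pseudomolecule position -> (scaffold_id, scaffold position);
    None inside a gap."""
    offset = 0
    for c in pm.components:
        if offset <= obj_pos < offset + c.length:
            if c.kind == "N":
                return None
            local = obj_pos - offset
            if c.orientation == "-":
                local = c.length - 1 - local
            return c.scaffold_id, local
        offset += c.length
    raise ValueError(f"position {obj_pos} outside pseudomolecule {pm.name}")
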