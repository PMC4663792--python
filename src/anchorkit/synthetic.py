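"""Seeded generator of a ground-truthed benchmark genome.

Emulates the evidence the anchoring pipeline consumes: a multi-chromosome
genome fragmented into (possibly chimeric) scaffolds, two noisy genetic
maps with injectable corruption (>30 cM discordance between maps,
multi-mapping markers, wrong-linkage-group markers), a BAC tiling grouped
into physical contigs including repeat-derived "sink" contigs, and a
random-mating population with distance-decaying LD sequenced at GBS-like
depth. Every generator is a pure function of its parameters and a seed.

Ground truth is carried in plain DataFrames so recovery metrics
(chromosome assignment, ordering, orientation, split placement) can be
computed by :func:`evaluate_anchoring`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AlignmentHit, GeneticMapRecord, PhysicalMembership
from .ld import GenotypeMatrix
from .marker_anchor import PlacedMarker, ScaffoldPlacement, SplitDecision
from .physical_link import LinkCall
from .pseudomolecule import order_scaffolds, reverse_complement

log = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))


def lg_name(chrom: str) -> str:
    """chr7 -> LG7 (chromosome/linkage-group naming convention)."""
    return "LG" + "".join(ch for ch in chrom if ch.isdigit())


def chrom_of_lg(lg: str) -> str:
    return "chr" + "".join(ch for ch in lg if ch.isdigit())


# ---------------------------------------------------------------------------
# genome and scaffolds
# ---------------------------------------------------------------------------


def simulate_genome(
    chrom_lengths: Mapping[str, int],
    gc: float = 0.36,
    seed: int = 0,
) -> dict[str, str]:
    """I.i.d. bases at the given GC fraction; deterministic for a seed."""
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        chrom: "".join(rng.choice(BASES, size=length, p=p))
        for chrom, length in chrom_lengths.items()
    }


@dataclass
class FragmentResult:
    scaffolds: dict[str, str]
    # one row per scaffold part: scaffold_id, part_index, chrom, chrom_start,
    # chrom_end, scaffold_start, scaffold_end, orientation
    parts: pd.DataFrame
    # one row per chimera: scaffold_id, breakpoint, left_chrom, right_chrom
    chimeras: pd.DataFrame

    def scaffold_lengths(self) -> dict[str, int]:
        return {sid: len(s) for sid, s in self.scaffolds.items()}

    def true_chrom(self, scaffold_id: str) -> str:
        """Dominant (longest-part) chromosome of a scaffold."""
        rows = self.parts[self.parts.scaffold_id == scaffold_id]
        if rows.empty:
            raise KeyError(scaffold_id)
        spans = rows.chrom_end - rows.chrom_start
        return rows.chrom.iloc[int(np.argmax(spans.to_numpy()))]


def fragment_genome(
    genome: Mapping[str, str],
    mean_length: int = 40_000,
    sigma: float = 0.7,
    min_length: int = 5_000,
    n_chimeric: int = 0,
    min_chimera_part: int = 80_000,
    seed: int = 0,
) -> FragmentResult:
    """Partition each chromosome into lognormal-length scaffolds.

    Half the scaffolds (at random) are stored reverse-complemented with
    truth orientation '-'. ``n_chimeric`` pairs of large scaffolds from
    different chromosomes are concatenated into chimeric scaffolds whose
    breakpoints are recorded.
    """
    rng = np.random.default_rng(seed)
    mu = math.log(mean_length) - sigma**2 / 2.0

    pieces: list[tuple[str, int, int]] = []  # (chrom, start, end)
    for chrom in genome:
        length = len(genome[chrom])
        pos = 0
        while pos < length:
            size = int(rng.lognormal(mu, sigma))
            size = max(size, min_length)
            if length - (pos + size) < min_length:
                size = length - pos
            pieces.append((chrom, pos, pos + size))
            pos += size

    order = rng.permutation(len(pieces))
    width = max(4, len(str(len(pieces))))
    scaffolds: dict[str, str] = {}
    part_rows: list[dict] = []
    assembled: dict[str, list[tuple[str, int, int, str]]] = {}
    for rank, piece_idx in enumerate(order):
        chrom, start, end = pieces[piece_idx]
        sid = f"scf{rank + 1:0{width}d}"
        orient = "+" if rng.random() < 0.5 else "-"
        seq = genome[chrom][start:end]
        scaffolds[sid] = seq if orient == "+" else reverse_complement(seq)
        assembled[sid] = [(chrom, start, end, orient)]

    chimera_rows: list[dict] = []
    if n_chimeric:
        # smallest eligible scaffolds first: keeps chimeras near the minimum
        # detectable size instead of fusing the largest scaffolds
        eligible = sorted(
            (
                sid for sid, parts in assembled.items()
                if parts[0][2] - parts[0][1] >= min_chimera_part
            ),
            key=lambda sid: (assembled[sid][0][2] - assembled[sid][0][1], sid),
        )
        made = 0
        while made < n_chimeric and len(eligible) >= 2:
            a = eligible.pop(0)
            partner = next(
                (s for s in eligible if assembled[s][0][0] != assembled[a][0][0]),
                None,
            )
            if partner is None:
                continue
            eligible.remove(partner)
            cid = f"{a}c"
            seq = scaffolds.pop(a) + scaffolds.pop(partner)
            scaffolds[cid] = seq
            left = assembled.pop(a)[0]
            right = assembled.pop(partner)[0]
            assembled[cid] = [left, right]
            chimera_rows.append(
                {
                    "scaffold_id": cid,
                    "breakpoint": left[2] - left[1],
                    "left_chrom": left[0],
                    "right_chrom": right[0],
                }
            )
            made += 1
        if made < n_chimeric:
            log.warning("fragment_genome: only %d/%d chimeras injected", made, n_chimeric)

    for sid in assembled:
        offset = 0
        for i, (chrom, start, end, orient) in enumerate(assembled[sid]):
            part_rows.append(
                {
                    "scaffold_id": sid,
                    "part_index": i,
                    "chrom": chrom,
                    "chrom_start": start,
                    "chrom_end": end,
                    "scaffold_start": offset,
                    "scaffold_end": offset + (end - start),
                    "orientation": orient,
                }
            )
            offset += end - start

    parts = pd.DataFrame(part_rows).sort_values(["chrom", "chrom_start"]).reset_index(drop=True)
    chimeras = pd.DataFrame(
        chimera_rows, columns=["scaffold_id", "breakpoint", "left_chrom", "right_chrom"]
    )
    return FragmentResult(scaffolds=scaffolds, parts=parts, chimeras=chimeras)


def map_genome_interval(
    parts: pd.DataFrame, chrom: str, g0: int, g1: int
) -> tuple[str, int, int, str] | None:
    """Map a genome interval [g0, g1) to (scaffold_id, s0, s1, strand), or
    None when it is not fully inside a single scaffold part."""
    rows = parts[(parts.chrom == chrom) & (parts.chrom_start <= g0) & (parts.chrom_end >= g1)]
    if rows.empty:
        return None
    r = rows.iloc[0]
    if r.orientation == "+":
        s0 = r.scaffold_start + (g0 - r.chrom_start)
        s1 = r.scaffold_start + (g1 - r.chrom_start)
        return r.scaffold_id, int(s0), int(s1), "+"
    s0 = r.scaffold_start + (r.chrom_end - g1)
    s1 = r.scaffold_start + (r.chrom_end - g0)
    return r.scaffold_id, int(s0), int(s1), "-"


# ---------------------------------------------------------------------------
# genetic maps and marker alignments
# ---------------------------------------------------------------------------

CORRUPTION_NONE = "none"
CORRUPTION_MULTI = "multi_map"
CORRUPTION_WRONG_LG = "wrong_lg"
CORRUPTION_DISCORDANT = "discordant_cm"


@dataclass
class MapSim:
    map_published: list[GeneticMapRecord]
    map_new: list[GeneticMapRecord]
    psl_rows: list[dict]  # rows for io_formats.write_psl
    # marker_id, chrom, genome_pos, true_cm, scaffold_id, scaffold_pos, corruption
    markers: pd.DataFrame


def simulate_maps(
    genome: Mapping[str, str],
    fragments: FragmentResult,
    n_markers: int = 470,
    marker_length: int = 120,
    cm_per_mb: float = 35.0,
    noise_cm_sd: float = 0.5,
    p_published: float = 0.85,
    p_new: float = 0.85,
    frac_discordant: float = 0.0,
    frac_wrong_lg: float = 0.0,
    frac_multimap: float = 0.0,
    chimera_flank_markers: int = 3,
    seed: int = 0,
) -> MapSim:
    """Simulate two genetic maps and the markers' scaffold alignments.

    True cM is a linear (hence monotone) function of the chromosome base
    position at ``cm_per_mb``; each map observes it with independent
    Gaussian noise. Corruption fractions are realised exactly (rounded)
    on disjoint marker subsets and recorded in the truth table:

    * ``discordant_cm`` — the new map's position is shifted >30 cM away
      from the published one;
    * ``wrong_lg`` — both maps consistently assign the wrong linkage group;
    * ``multi_map`` — the marker gets a second alignment on another
      scaffold.

    Every chimeric scaffold is guaranteed ``chimera_flank_markers`` markers
    on each side of its junction: junction detection needs flanking
    markers, so the benchmark covers them by design.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    positions: list[tuple[str, int]] = []  # (chrom, genome_pos)
    mapped: list[tuple[str, int, int, str]] = []  # scaffold mapping

    def try_add(chrom: str, gpos: int) -> bool:
        m = map_genome_interval(fragments.parts, chrom, gpos, gpos + marker_length)
        if m is None:
            return False
        positions.append((chrom, gpos))
        mapped.append(m)
        return True

    # guaranteed junction-flank markers on chimeras
    for ch in fragments.chimeras.itertuples(index=False):
        parts = fragments.parts[fragments.parts.scaffold_id == ch.scaffold_id]
        for part in parts.itertuples(index=False):
            placed = 0
            attempts = 0
            span = part.chrom_end - part.chrom_start - marker_length
            while placed < chimera_flank_markers and attempts < 200:
                attempts += 1
                gpos = int(part.chrom_start + rng.integers(0, max(span, 1)))
                if try_add(part.chrom, gpos):
                    placed += 1

    while len(positions) < n_markers:
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        gpos = int(rng.integers(0, len(genome[chrom]) - marker_length))
        try_add(chrom, gpos)

    n = len(positions)
    marker_ids = [f"mk{i + 1:05d}" for i in range(n)]
    true_cm = np.array([gpos * cm_per_mb / 1e6 for _, gpos in positions])

    corruption = np.array([CORRUPTION_NONE] * n, dtype=object)
    pool = rng.permutation(n)
    n_disc = round(frac_discordant * n)
    n_wrong = round(frac_wrong_lg * n)
    n_multi = round(frac_multimap * n)
    disc_idx = pool[:n_disc]
    wrong_idx = pool[n_disc : n_disc + n_wrong]
    multi_idx = pool[n_disc + n_wrong : n_disc + n_wrong + n_multi]
    corruption[disc_idx] = CORRUPTION_DISCORDANT
    corruption[wrong_idx] = CORRUPTION_WRONG_LG
    corruption[multi_idx] = CORRUPTION_MULTI

    in_pub = rng.random(n) < p_published
    in_new = rng.random(n) < p_new
    in_pub[disc_idx] = True  # discordance needs both maps
    in_new[disc_idx] = True

    map_pub: list[GeneticMapRecord] = []
    map_new: list[GeneticMapRecord] = []
    marker_rows: list[dict] = []
    psl_rows: list[dict] = []
    scaffold_ids = sorted(fragments.scaffolds)
    lengths_by_sid = fragments.scaffold_lengths()

    for i in range(n):
        chrom, gpos = positions[i]
        sid, s0, s1, strand = mapped[i]
        lg = lg_name(chrom)
        cm_pub = max(0.0, true_cm[i] + rng.normal(0.0, noise_cm_sd))
        cm_new = max(0.0, true_cm[i] + rng.normal(0.0, noise_cm_sd))
        if corruption[i] == CORRUPTION_WRONG_LG:
            others = [c for c in chroms if c != chrom]
            wrong_chrom = others[int(rng.integers(0, len(others)))]
            lg = lg_name(wrong_chrom)
            base = rng.uniform(0.0, len(genome[wrong_chrom]) * cm_per_mb / 1e6)
            cm_pub = base + rng.normal(0.0, noise_cm_sd)
            cm_new = base + rng.normal(0.0, noise_cm_sd)
        if corruption[i] == CORRUPTION_DISCORDANT:
            shift = rng.uniform(35.0, 60.0)
            cm_new = cm_pub + shift  # strictly >30 cM from the published value
        if in_pub[i]:
            map_pub.append(GeneticMapRecord(marker_ids[i], lg, max(cm_pub, 0.0), "published"))
        if in_new[i]:
            map_new.append(GeneticMapRecord(marker_ids[i], lg, max(cm_new, 0.0), "new"))

        psl_rows.append(
            {
                "matches": marker_length - 2,
                "mismatches": 2,
                "strand": strand,
                "qname": marker_ids[i],
                "qsize": marker_length,
                "qstart": 0,
                "qend": marker_length,
                "tname": sid,
                "tsize": lengths_by_sid[sid],
                "tstart": s0,
                "tend": s1,
            }
        )
        if corruption[i] == CORRUPTION_MULTI:
            other_sids = [s for s in scaffold_ids if s != sid]
            osid = other_sids[int(rng.integers(0, len(other_sids)))]
            opos = int(rng.integers(0, max(lengths_by_sid[osid] - marker_length, 1)))
            psl_rows.append(
                {
                    "matches": marker_length - 3,
                    "mismatches": 3,
                    "strand": "+",
                    "qname": marker_ids[i],
                    "qsize": marker_length,
                    "qstart": 0,
                    "qend": marker_length,
                    "tname": osid,
                    "tsize": lengths_by_sid[osid],
                    "tstart": opos,
                    "tend": opos + marker_length,
                }
            )
        marker_rows.append(
            {
                "marker_id": marker_ids[i],
                "chrom": chrom,
                "genome_pos": gpos,
                "true_cm": true_cm[i],
                "scaffold_id": sid,
                "scaffold_pos": s0,
                "corruption": corruption[i],
                "in_published": bool(in_pub[i]),
                "in_new": bool(in_new[i]),
            }
        )

    return MapSim(
        map_published=map_pub,
        map_new=map_new,
        psl_rows=psl_rows,
        markers=pd.DataFrame(marker_rows),
    )


# ---------------------------------------------------------------------------
# BACs and physical contigs
# ---------------------------------------------------------------------------


@dataclass
class BacSim:
    blast6_rows: list[dict]  # rows for io_formats.write_blast6
    query_lengths: dict[str, int]
    memberships: list[PhysicalMembership]
    # contig_id, chrom, start, end, sink
    contigs: pd.DataFrame
    sink_ids: list[str]


def simulate_bacs(
    genome: Mapping[str, str],
    fragments: FragmentResult,
    n_bacs: int = 600,
    bac_length_mean: int = 30_000,
    bac_length_sd: int = 5_000,
    end_length: int = 500,
    min_overlap: int | None = None,
    n_sink_contigs: int = 0,
    sink_n_bacs: int = 30,
    seed: int = 0,
) -> BacSim:
    """BACs tile the chromosomes; overlapping BACs form physical contigs.

    Two BACs join a contig only when they overlap by at least
    ``min_overlap`` (default a third of the mean BAC length) — fingerprint
    assembly needs substantial shared content, and requiring it keeps
    contig sizes realistic rather than chaining marginal overlaps.

    Each BAC contributes two end reads aligned back to the scaffolds
    (BLAST-tabular rows; ends crossing a scaffold boundary are lost, as in
    real end mapping). BACs that overlap no neighbour are singletons
    (no contig membership). Sink contigs aggregate repeat-derived clones:
    their end reads scatter uniformly over scaffolds genome-wide.
    """
    rng = np.random.default_rng(seed)
    if min_overlap is None:
        min_overlap = bac_length_mean // 3
    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    bacs: list[tuple[str, str, int, int]] = []  # (bac_id, chrom, start, end)
    for i in range(n_bacs):
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        size = max(int(rng.normal(bac_length_mean, bac_length_sd)), 3 * end_length)
        start = int(rng.integers(0, max(len(genome[chrom]) - size, 1)))
        bacs.append((f"bac{i + 1:05d}", chrom, start, start + size))

    # merge overlapping BAC intervals per chromosome into contigs
    memberships: list[PhysicalMembership] = []
    contig_rows: list[dict] = []
    contig_counter = 0
    bac_contig: dict[str, str | None] = {}
    for chrom in chroms:
        chrom_bacs = sorted((b for b in bacs if b[1] == chrom), key=lambda b: b[2])
        group: list[tuple[str, str, int, int]] = []
        group_end = -1

        def flush(group):
            nonlocal contig_counter
            if not group:
                return
            if len(group) == 1:
                bac_contig[group[0][0]] = None
                return
            contig_counter += 1
            cid = f"ctg{contig_counter:04d}"
            for b in group:
                bac_contig[b[0]] = cid
            contig_rows.append(
                {
                    "contig_id": cid,
                    "chrom": chrom,
                    "start": min(b[2] for b in group),
                    "end": max(b[3] for b in group),
                    "sink": False,
                }
            )

        for b in chrom_bacs:
            if group and group_end - b[2] >= min_overlap:
                group.append(b)
                group_end = max(group_end, b[3])
            else:
                flush(group)
                group = [b]
                group_end = b[3]
        flush(group)

    blast6_rows: list[dict] = []
    qlens: dict[str, int] = {}

    def end_hit(qid: str, chrom: str, g0: int) -> None:
        m = map_genome_interval(fragments.parts, chrom, g0, g0 + end_length)
        if m is None:
            return
        sid, s0, s1, strand = m
        if strand == "+":
            sstart, send = s0 + 1, s1
        else:
            sstart, send = s1, s0 + 1
        blast6_rows.append(
            {
                "qseqid": qid,
                "sseqid": sid,
                "pident": float(rng.uniform(95.0, 99.8)),
                "length": end_length,
                "qstart": 1,
                "qend": end_length,
                "sstart": sstart,
                "send": send,
            }
        )
        qlens[qid] = end_length

    for bac_id, chrom, start, end in bacs:
        membership_contig = bac_contig[bac_id]
        memberships.append(
            PhysicalMembership(
                bac_id=bac_id,
                contig_id=membership_contig,
                singleton=membership_contig is None,
            )
        )
        end_hit(f"{bac_id}.f", chrom, start)
        end_hit(f"{bac_id}.r", chrom, end - end_length)

    sink_ids: list[str] = []
    scaffold_ids = sorted(fragments.scaffolds)
    slen = fragments.scaffold_lengths()
    for j in range(n_sink_contigs):
        cid = f"sink{j + 1:02d}"
        sink_ids.append(cid)
        contig_rows.append({"contig_id": cid, "chrom": "", "start": -1, "end": -1, "sink": True})
        for k in range(sink_n_bacs):
            bac_id = f"rep{j + 1:02d}_{k + 1:03d}"
            memberships.append(PhysicalMembership(bac_id=bac_id, contig_id=cid, singleton=False))
            for suffix in (".f", ".r"):
                sid = scaffold_ids[int(rng.integers(0, len(scaffold_ids)))]
                if slen[sid] <= end_length:
                    continue
                pos = int(rng.integers(0, slen[sid] - end_length))
                qid = f"{bac_id}{suffix}"
                blast6_rows.append(
                    {
                        "qseqid": qid,
                        "sseqid": sid,
                        "pident": float(rng.uniform(95.0, 99.8)),
                        "length": end_length,
                        "qstart": 1,
                        "qend": end_length,
                        "sstart": pos + 1,
                        "send": pos + end_length,
                    }
                )
                qlens[qid] = end_length

    contigs = pd.DataFrame(contig_rows, columns=["contig_id", "chrom", "start", "end", "sink"])
    return BacSim(
        blast6_rows=blast6_rows,
        query_lengths=qlens,
        memberships=memberships,
        contigs=contigs,
        sink_ids=sink_ids,
    )


# ---------------------------------------------------------------------------
# GBS population
# ---------------------------------------------------------------------------


@dataclass
class PopulationSim:
    matrix: GenotypeMatrix  # depths only (genotypes uncalled)
    true_dosage: np.ndarray  # (n_sites, n_individuals)


def simulate_population(
    chrom_lengths: Mapping[str, int],
    n_founders: int = 10,
    n_generations: int = 10,
    n_individuals: int = 60,
    n_sites: int = 500,
    mean_depth: float = 15.0,
    error_rate: float = 0.01,
    cm_per_mb: float = 50.0,
    seed: int = 0,
) -> PopulationSim:
    """Random-mating population descended from a finite founder pool.

    Founder haplotypes draw alleles from per-site frequencies; each
    generation recombines parental haplotypes with a Poisson number of
    crossovers per chromosome (mean = genetic length in Morgans at
    ``cm_per_mb``). Sequencing draws per-site depths from
    Poisson(``mean_depth``) and reads from the true genotype with a
    per-read error rate, yielding GBS-like allele-depth data. Fewer
    founders means higher baseline LD.
    """
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    sites_per_chrom = np.maximum(np.round(n_sites * lens / lens.sum()).astype(int), 2)

    site_chrom: list[str] = []
    site_pos: list[int] = []
    for c, k in zip(chroms, sites_per_chrom):
        pos = np.sort(rng.choice(chrom_lengths[c], size=k, replace=False))
        site_chrom.extend([c] * k)
        site_pos.extend(int(p) + 1 for p in pos)  # 1-based
    n_sites_actual = len(site_pos)

    freqs = rng.uniform(0.2, 0.8, size=n_sites_actual)
    founder_haps = (rng.random((2 * n_founders, n_sites_actual)) < freqs).astype(np.int8)

    chrom_slices: list[tuple[int, int, float]] = []  # (lo, hi, morgans)
    lo = 0
    for c, k in zip(chroms, sites_per_chrom):
        morgans = chrom_lengths[c] * cm_per_mb / 1e6 / 100.0
        chrom_slices.append((lo, lo + k, morgans))
        lo += k

    def gamete(h0: np.ndarray, h1: np.ndarray) -> np.ndarray:
        out = np.empty(n_sites_actual, dtype=np.int8)
        for (a, b, morgans) in chrom_slices:
            k = a
            pos = np.asarray(site_pos[a:b])
            n_cross = rng.poisson(morgans)
            cuts = np.sort(rng.uniform(pos[0], pos[-1], size=n_cross)) if n_cross else np.array([])
            phase = int(rng.integers(0, 2))
            src = (h0, h1)
            seg_start = a
            boundaries = list(np.searchsorted(pos, cuts) + a) + [b]
            for boundary in boundaries:
                out[seg_start:boundary] = src[phase][seg_start:boundary]
                seg_start = boundary
                phase ^= 1
        return out

    # generation 0: individuals draw two founder haplotypes
    pop = [
        (
            founder_haps[rng.integers(0, 2 * n_founders)].copy(),
            founder_haps[rng.integers(0, 2 * n_founders)].copy(),
        )
        for _ in range(n_individuals)
    ]
    for _ in range(n_generations):
        nxt = []
        for _ in range(n_individuals):
            p1, p2 = rng.integers(0, n_individuals, size=2)
            nxt.append((gamete(*pop[p1]), gamete(*pop[p2])))
        pop = nxt

    dosage = np.stack([h0 + h1 for h0, h1 in pop], axis=1).astype(np.int16)  # (S, N)

    total = rng.poisson(mean_depth, size=dosage.shape)
    p_alt_read = dosage / 2.0 * (1.0 - error_rate) + (1.0 - dosage / 2.0) * error_rate
    alt = rng.binomial(total, p_alt_read)
    ref = total - alt

    sites_df = pd.DataFrame(
        {"chrom": site_chrom, "pos": site_pos, "ref": "A", "alt": "G"}
    )
    individuals = [f"ind{i + 1:03d}" for i in range(n_individuals)]
    matrix = GenotypeMatrix(
        sites=sites_df,
        individuals=individuals,
        ref_depth=ref.astype(np.int64),
        alt_depth=alt.astype(np.int64),
    )
    return PopulationSim(matrix=matrix, true_dosage=dosage)


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------


def _true_chrom_for_placement(
    p: ScaffoldPlacement,
    fragments: FragmentResult,
    splits: Sequence[SplitDecision],
) -> str | None:
    """Dominant true chromosome of a placement's sequence (split children
    map to the corresponding interval of the parent)."""
    sid = p.scaffold_id
    if p.split_of is not None:
        parent = p.split_of
        sd = next((s for s in splits if s.scaffold_id == parent), None)
        if sd is None:
            return None
        side = sid.rsplit("_", 1)[-1]
        parts = fragments.parts[fragments.parts.scaffold_id == parent]
        lo, hi = (0, sd.split_pos) if side == "1" else (sd.split_pos, int(parts.scaffold_end.max()))
        best_chrom, best_overlap = None, 0
        for r in parts.itertuples(index=False):
            ov = min(hi, r.scaffold_end) - max(lo, r.scaffold_start)
            if ov > best_overlap:
                best_chrom, best_overlap = r.chrom, ov
        return best_chrom
    try:
        return fragments.true_chrom(sid)
    except KeyError:
        return None


def _true_start_for_placement(
    p: ScaffoldPlacement,
    chrom: str,
    fragments: FragmentResult,
) -> int | None:
    """True chromosome start coordinate of the placement's dominant part."""
    sid = p.scaffold_id if p.split_of is None else p.split_of
    parts = fragments.parts[
        (fragments.parts.scaffold_id == sid) & (fragments.parts.chrom == chrom)
    ]
    if parts.empty:
        return None
    spans = (parts.chrom_end - parts.chrom_start).to_numpy()
    return int(parts.chrom_start.iloc[int(np.argmax(spans))])


def evaluate_anchoring(
    placements: Sequence[ScaffoldPlacement],
    fragments: FragmentResult,
    splits: Sequence[SplitDecision] = (),
    markers: Sequence[PlacedMarker] = (),
    marker_truth: pd.DataFrame | None = None,
) -> dict:
    """Recovery metrics against the generator's ground truth.

    * ``placed_fraction`` — placed scaffolds (split children count once via
      their parent) over all scaffolds.
    * ``chrom_accuracy`` — fraction of placements whose linkage group
      matches the dominant true chromosome of their sequence.
    * ``order_rank_correlation`` — per-chromosome Spearman correlation
      between recovered order and true start, over marker-evidence
      placements (BAC-inserted scaffolds carry no intra-contig order
      signal); the mean and the per-chromosome values are both reported,
      plus an all-placements variant.
    * ``orientation_accuracy`` — over placements with recovered
      orientation != '?' (truth from the dominant part).
    * ``split_recall`` — fraction of injected chimeras receiving a split
      with both sides on the correct linkage group and the split position
      on the correct side of the true breakpoint neighbourhood: the window
      between the innermost junction-flanking markers whose map evidence is
      uncorrupted (``marker_truth``, when given, identifies those; a
      wrong-linkage-group or multi-mapping marker at the junction makes its
      own flank unknowable to any method).
    """
    n_scaffolds = fragments.parts.scaffold_id.nunique()
    placed_parents = {p.split_of or p.scaffold_id for p in placements}
    metrics: dict = {
        "placed_fraction": len(placed_parents) / n_scaffolds if n_scaffolds else float("nan"),
        "n_placed": len(placements),
    }

    # chromosome accuracy
    n_ok = n_tot = 0
    truth_chrom: dict[str, str | None] = {}
    for p in placements:
        tc = _true_chrom_for_placement(p, fragments, splits)
        truth_chrom[p.scaffold_id] = tc
        if tc is None:
            continue
        n_tot += 1
        if chrom_of_lg(p.linkage_group) == tc:
            n_ok += 1
    metrics["chrom_accuracy"] = n_ok / n_tot if n_tot else float("nan")

    # ordering (marker placements; BAC-inserted scaffolds have no order signal)
    def order_corr(pls: Sequence[ScaffoldPlacement]) -> dict[str, float]:
        per_chrom: dict[str, float] = {}
        ordered = order_scaffolds(list(pls))
        for lg, ordered_pls in ordered.items():
            chrom = chrom_of_lg(lg)
            recovered, truth = [], []
            for rank, p in enumerate(ordered_pls):
                if truth_chrom.get(p.scaffold_id) != chrom:
                    continue
                start = _true_start_for_placement(p, chrom, fragments)
                if start is None:
                    continue
                recovered.append(rank)
                truth.append(start)
            if len(recovered) >= 2:
                rho = stats.spearmanr(recovered, truth).statistic
                per_chrom[chrom] = float(rho)
        return per_chrom

    marker_pls = [p for p in placements if p.evidence == "marker"]
    per_chrom = order_corr(marker_pls)
    metrics["order_rank_correlation_per_chrom"] = per_chrom
    metrics["order_rank_correlation"] = (
        float(np.mean(list(per_chrom.values()))) if per_chrom else float("nan")
    )
    all_corr = order_corr(placements)
    metrics["order_rank_correlation_all"] = (
        float(np.mean(list(all_corr.values()))) if all_corr else float("nan")
    )

    # orientation
    n_ok = n_tot = 0
    for p in placements:
        if p.orientation == "?":
            continue
        sid = p.scaffold_id if p.split_of is None else p.split_of
        chrom = truth_chrom.get(p.scaffold_id)
        parts = fragments.parts[
            (fragments.parts.scaffold_id == sid) & (fragments.parts.chrom == chrom)
        ]
        if parts.empty:
            continue
        spans = (parts.chrom_end - parts.chrom_start).to_numpy()
        true_orient = parts.orientation.iloc[int(np.argmax(spans))]
        n_tot += 1
        if p.orientation == true_orient:
            n_ok += 1
    metrics["orientation_accuracy"] = n_ok / n_tot if n_tot else float("nan")

    # chimera split recall
    if len(fragments.chimeras):
        split_by_sid = {s.scaffold_id: s for s in splits}
        n_ok = 0
        for ch in fragments.chimeras.itertuples(index=False):
            sd = split_by_sid.get(ch.scaffold_id)
            if sd is None:
                continue
            if (
                chrom_of_lg(sd.left_lg) != ch.left_chrom
                or chrom_of_lg(sd.right_lg) != ch.right_chrom
            ):
                continue
            # the split must fall in the marker-free window around the
            # junction; markers may already carry child ids after the split
            ms: list[int] = []
            if marker_truth is not None:
                visible = marker_truth.in_published | marker_truth.in_new
                trusted = marker_truth[
                    (marker_truth.scaffold_id == ch.scaffold_id)
                    & marker_truth.corruption.isin([CORRUPTION_NONE, CORRUPTION_DISCORDANT])
                    & visible
                ]
                ms = [int(p) for p in trusted.scaffold_pos]
            else:
                for m in markers:
                    if m.scaffold_id == ch.scaffold_id or m.scaffold_id == f"{ch.scaffold_id}_1":
                        ms.append(m.scaffold_pos)
                    elif m.scaffold_id == f"{ch.scaffold_id}_2":
                        ms.append(m.scaffold_pos + sd.split_pos)
            left = [pos for pos in ms if pos < ch.breakpoint]
            right = [pos for pos in ms if pos >= ch.breakpoint]
            lo = max(left) if left else 0
            hi = min(right) if right else int(ch.breakpoint)
            if lo <= sd.split_pos <= hi:
                n_ok += 1
        metrics["split_recall"] = n_ok / len(fragments.chimeras)
    else:
        metrics["split_recall"] = float("nan")
    return metrics


def evaluate_propagation(
    link_calls: Sequence[LinkCall],
    marker_placements: Sequence[ScaffoldPlacement],
    propagated: Sequence[ScaffoldPlacement],
    fragments: FragmentResult,
    sink_ids: Sequence[str] = (),
    exclude_scaffolds: Sequence[str] = (),
) -> dict:
    """Accuracy of BAC-link propagation against truth.

    A scaffold is *recoverable* when it is unplaced, holds an accepted link
    to a non-sink contig, at least one marker-placed scaffold holds an
    accepted link to the same contig, and the contig's placed neighbours
    carry a resolvable linkage-group signal (a contig whose anchors are
    tied or substantively conflicted provides zero placement information,
    so no method could recover from it). Reported: fraction of recoverable
    scaffolds propagated onto their true chromosome, and accuracy among
    those actually propagated.
    """
    from .physical_link import ACCEPTED_CATEGORIES, resolve_anchor_lg

    placed_by_id = {p.scaffold_id: p for p in marker_placements}
    placed_ids = set(placed_by_id)
    excluded = set(exclude_scaffolds)
    accepted = [c for c in link_calls if c.category in ACCEPTED_CATEGORIES]
    anchors_by_contig: dict[str, list] = {}
    for c in accepted:
        if c.scaffold_id in placed_ids:
            anchors_by_contig.setdefault(c.contig_id, []).append(
                (placed_by_id[c.scaffold_id], c)
            )
    informative_contigs = {
        ctg for ctg, anchors in anchors_by_contig.items()
        if resolve_anchor_lg(anchors) is not None
    }
    recoverable = [
        c.scaffold_id
        for c in accepted
        if c.scaffold_id not in placed_ids
        and c.scaffold_id not in excluded
        and c.contig_id not in set(sink_ids)
        and c.contig_id in informative_contigs
    ]
    prop_by_id = {p.scaffold_id: p for p in propagated}
    n_ok = 0
    for sid in recoverable:
        p = prop_by_id.get(sid)
        if p is None:
            continue
        try:
            tc = fragments.true_chrom(sid)
        except KeyError:
            continue
        if chrom_of_lg(p.linkage_group) == tc:
            n_ok += 1
    n_prop_ok = 0
    for sid, p in prop_by_id.items():
        try:
            tc = fragments.true_chrom(sid)
        except KeyError:
            continue
        if chrom_of_lg(p.linkage_group) == tc:
            n_prop_ok += 1
    return {
        "n_recoverable": len(recoverable),
        "recoverable_placed_true": n_ok / len(recoverable) if recoverable else float("nan"),
        "n_propagated": len(propagated),
        "propagated_accuracy": n_prop_ok / len(propagated) if propagated else float("nan"),
    }


# ---------------------------------------------------------------------------
# truth persistence (so `evaluate` can run from files)
# ---------------------------------------------------------------------------


def write_truth(fragments: FragmentResult, markers: pd.DataFrame | None, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fragments.parts.to_csv(out / "scaffold_parts.tsv", sep="\t", index=False)
    fragments.chimeras.to_csv(out / "chimeras.tsv", sep="\t", index=False)
    if markers is not None:
        markers.to_csv(out / "markers.tsv", sep="\t", index=False)


def read_truth(truth_dir) -> FragmentResult:
    """Reload ground truth written by :func:`write_truth` (sequences are
    not stored; metrics only need the coordinate tables)."""
    from pathlib import Path

    d = Path(truth_dir)
    parts = pd.read_csv(d / "scaffold_parts.tsv", sep="\t")
    chim_path = d / "chimeras.tsv"
    chimeras = (
        pd.read_csv(chim_path, sep="\t")
        if chim_path.exists()
        else pd.DataFrame(columns=["scaffold_id", "breakpoint", "left_chrom", "right_chrom"])
    )
    return FragmentResult(scaffolds={}, parts=parts, chimeras=chimeras)


# ---------------------------------------------------------------------------
# divergence / synteny generators for the comparative module
# ---------------------------------------------------------------------------


def simulate_divergent_pair(
    length: int, p_transition: float, p_transversion: float, seed: int = 0
) -> tuple[str, str]:
    """A random sequence and a copy with i.i.d. per-site transitions and
    transversions at the given probabilities (observed proportions, not
    rates, so small values map directly onto K2P's P and Q)."""
    rng = np.random.default_rng(seed)
    a = rng.choice(BASES, size=length)
    b = a.copy()
    u = rng.random(length)
    ts_map = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv_map = {"A": "C", "G": "T", "C": "A", "T": "G"}
    for i in range(length):
        if u[i] < p_transition:
            b[i] = ts_map[a[i]]
        elif u[i] < p_transition + p_transversion:
            b[i] = tv_map[a[i]]
    return "".join(a), "".join(b)


def simulate_synteny_anchors(
    n_blocks: int = 4,
    block_size: int = 40,
    n_noise: int = 30,
    inverted_every: int = 2,
    seed: int = 0,
):
    """Gene-anchor pairs containing known collinear blocks plus scattered
    noise anchors; returns (anchors, truth block descriptions)."""
    from .compgen import SyntenyAnchor

    rng = np.random.default_rng(seed)
    anchors: list[SyntenyAnchor] = []
    truth: list[dict] = []
    next_a = 0
    next_b = 0
    gene = 0
    for blk in range(n_blocks):
        direction = "inverted" if inverted_every and (blk + 1) % inverted_every == 0 else "forward"
        ia = next_a
        ib_range = list(range(next_b, next_b + block_size))
        if direction == "inverted":
            ib_range = ib_range[::-1]
        for k in range(block_size):
            anchors.append(
                SyntenyAnchor(
                    gene_a=f"ga{gene}", index_a=ia + k,
                    gene_b=f"gb{gene}", index_b=ib_range[k],
                    chrom_a="A1", chrom_b="B1",
                )
            )
            gene += 1
        truth.append({"direction": direction, "size": block_size, "start_a": ia})
        next_a = ia + block_size + 20
        next_b += block_size + 20
    for _ in range(n_noise):
        anchors.append(
            SyntenyAnchor(
                gene_a=f"ga{gene}", index_a=int(rng.integers(0, next_a + 200)),
                gene_b=f"gb{gene}", index_b=int(rng.integers(2000, 4000)),
                chrom_a="A1", chrom_b="B1",
            )
        )
        gene += 1
    order = rng.permutation(len(anchors))
    return [anchors[i] for i in order], truth
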