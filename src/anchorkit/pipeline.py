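"""End-to-end anchoring pipeline and its configuration.

Stage order: filter alignments -> place markers -> resolve linkage groups /
split chimeras -> classify BAC links -> propagate placements -> orient and
order -> build pseudomolecules -> evaluate against truth when available.
Reruns with the same configuration and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import io_formats, marker_anchor, physical_link, pseudomolecule, synthetic
from .io_formats import AlignmentHit, GeneticMapRecord, PhysicalMembership
from .marker_anchor import ScaffoldPlacement

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline thresholds with their defaults."""

    min_identity: float = 0.90
    min_coverage: float = 0.90
    max_discord_cm: float = 30.0
    min_total_unique: int = 2
    min_total_dominant: int = 4
    strong_ratio: float = 2.0
    strong_min: int = 3
    gap_length: int = 10_000
    min_pairs: int = 30        # synteny block threshold
    max_rank_gap: int = 5
    bin_width: int = 5_000     # LD decay bin width (bp)
    max_dist: int = 500_000
    min_total_depth: int = 10
    min_minor_depth: int = 2
    max_missing: float = 0.20
    min_maf: float = 0.05
    sink_ids: tuple[str, ...] = ()
    auto_sink: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("max_missing", "min_maf"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "max_discord_cm", "strong_ratio", "gap_length", "min_pairs",
            "bin_width", "max_dist", "min_total_unique", "min_total_dominant",
            "strong_min", "min_total_depth", "min_minor_depth", "max_rank_gap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "sink_ids" in raw:
            raw["sink_ids"] = tuple(str(s) for s in raw["sink_ids"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    placements: list[ScaffoldPlacement]          # all placements, marker + bac_link
    splits: list[marker_anchor.SplitDecision]
    unplaced: list[marker_anchor.UnplacedScaffold]
    markers: list[marker_anchor.PlacedMarker]    # post-split marker set
    link_calls: list[physical_link.LinkCall]
    propagation_conflicts: list[str]
    sink_removed: list[str]
    pseudomolecules: list[pseudomolecule.Pseudomolecule]
    pm_sequences: dict[str, str]
    unplaced_sequences: dict[str, str]
    metrics: dict = field(default_factory=dict)


def anchor_genome(
    sequences: Mapping[str, str],
    marker_hits: Sequence[AlignmentHit],
    map_published: Sequence[GeneticMapRecord],
    map_new: Sequence[GeneticMapRecord],
    bac_hits: Sequence[AlignmentHit] | None = None,
    memberships: Sequence[PhysicalMembership] | None = None,
    config: RunConfig | None = None,
    fragments: "synthetic.FragmentResult | None" = None,
    true_sink_ids: Sequence[str] = (),
    marker_truth=None,
) -> PipelineResult:
    """Run the full anchoring pipeline in memory.

    ``fragments`` (generator ground truth) is optional; when given,
    recovery metrics are attached to the result.
    """
    cfg = config or RunConfig()
    cfg.validate()

    # markers
    kept = marker_anchor.filter_hits(marker_hits, cfg.min_identity, cfg.min_coverage)
    log.info("filter_hits: %d / %d marker alignments retained", len(kept), len(marker_hits))
    placement_res = marker_anchor.place_markers(kept, map_published, map_new, cfg.max_discord_cm)
    anchoring = marker_anchor.resolve_placements(placement_res.placed)
    sequences = marker_anchor.apply_splits(sequences, anchoring.splits)
    split_parents = [sd.scaffold_id for sd in anchoring.splits]

    # BAC links
    link_calls: list[physical_link.LinkCall] = []
    propagated: list[ScaffoldPlacement] = []
    conflicts: list[str] = []
    sink_removed: list[str] = []
    if bac_hits is not None and memberships is not None:
        bac_kept = marker_anchor.filter_hits(bac_hits, cfg.min_identity, cfg.min_coverage)
        log.info("BAC-end hits retained: %d / %d", len(bac_kept), len(bac_hits))
        sink_res = physical_link.filter_sink_contigs(
            bac_kept, memberships, cfg.sink_ids, auto=cfg.auto_sink
        )
        sink_removed = sink_res.removed_contigs
        link_calls = physical_link.classify_links(
            sink_res.hits, memberships,
            min_total_unique=cfg.min_total_unique,
            min_total_dominant=cfg.min_total_dominant,
            strong_ratio=cfg.strong_ratio,
            strong_min=cfg.strong_min,
        )
        propagated, conflicts = physical_link.propagate_placement(
            link_calls, anchoring.placements, exclude_scaffolds=split_parents
        )

    # orient marker placements from their supporting markers
    markers_by_scaffold: dict[str, list] = {}
    for m in anchoring.markers:
        markers_by_scaffold.setdefault(m.scaffold_id, []).append(m)
    for p in anchoring.placements:
        support = [
            m for m in markers_by_scaffold.get(p.scaffold_id, [])
            if m.linkage_group == p.linkage_group
        ]
        p.orientation = pseudomolecule.orient_scaffold(support)

    all_placements = anchoring.placements + propagated
    ordered = pseudomolecule.order_scaffolds(all_placements)
    pms, pm_seqs = pseudomolecule.build_pseudomolecules(
        ordered, sequences, gap_length=cfg.gap_length,
        name_map={lg: synthetic.chrom_of_lg(lg) for lg in ordered},
    )
    placed_ids = {p.scaffold_id for p in all_placements}
    unplaced_seqs = {sid: sequences[sid] for sid in sorted(sequences) if sid not in placed_ids}

    result = PipelineResult(
        placements=all_placements,
        splits=anchoring.splits,
        unplaced=anchoring.unplaced,
        markers=anchoring.markers,
        link_calls=link_calls,
        propagation_conflicts=conflicts,
        sink_removed=sink_removed,
        pseudomolecules=pms,
        pm_sequences=pm_seqs,
        unplaced_sequences=unplaced_seqs,
    )

    if fragments is not None:
        result.metrics = synthetic.evaluate_anchoring(
            all_placements, fragments, splits=anchoring.splits,
            markers=anchoring.markers, marker_truth=marker_truth,
        )
        if link_calls:
            # "recoverable" is judged on links classified with only the TRUE
            # sinks removed, so false-positive/missed sink detection is
            # penalised rather than hidden
            oracle_res = physical_link.filter_sink_contigs(
                bac_kept, memberships, true_sink_ids, auto=False
            )
            oracle_calls = physical_link.classify_links(
                oracle_res.hits, memberships,
                min_total_unique=cfg.min_total_unique,
                min_total_dominant=cfg.min_total_dominant,
                strong_ratio=cfg.strong_ratio,
                strong_min=cfg.strong_min,
            )
            result.metrics["propagation"] = synthetic.evaluate_propagation(
                oracle_calls, anchoring.placements, propagated, fragments,
                sink_ids=true_sink_ids, exclude_scaffolds=split_parents,
            )
            result.metrics["sink_removed"] = sink_removed
            result.metrics["true_sinks_detected"] = sorted(
                set(true_sink_ids) & set(sink_removed)
            )
    return result


# ---------------------------------------------------------------------------
# output writing
# ---------------------------------------------------------------------------


def _placements_table(placements: Sequence[ScaffoldPlacement]) -> str:
    cols = [
        "scaffold_id", "linkage_group", "cm_key", "insert_rank", "orientation",
        "evidence", "split_of", "n_support_markers", "anchored_to",
    ]
    lines = ["\t".join(cols)]
    for p in sorted(placements, key=lambda p: (p.linkage_group, p.cm_key, p.insert_rank, p.scaffold_id)):
        lines.append(
            "\t".join(
                [
                    p.scaffold_id, p.linkage_group, f"{p.cm_key:.6f}",
                    str(p.insert_rank), p.orientation, p.evidence,
                    p.split_of or "-", str(p.n_support_markers), p.anchored_to or "-",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the pipeline artifacts; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["placements"] = out / "placements.tsv"
    paths["placements"].write_text(_placements_table(result.placements))

    lines = ["scaffold_id\tsplit_pos\tleft_lg\tright_lg"]
    for sd in sorted(result.splits, key=lambda s: s.scaffold_id):
        lines.append(f"{sd.scaffold_id}\t{sd.split_pos}\t{sd.left_lg}\t{sd.right_lg}")
    paths["splits"] = out / "splits.tsv"
    paths["splits"].write_text("\n".join(lines) + "\n")

    lines = ["scaffold_id\tcontig_id\tn_total\tn_to_contig\tcategory"]
    for c in sorted(result.link_calls, key=lambda c: c.scaffold_id):
        lines.append(
            f"{c.scaffold_id}\t{c.contig_id or '-'}\t{c.n_total}\t{c.n_to_contig}\t{c.category}"
        )
    paths["links"] = out / "links.tsv"
    paths["links"].write_text("\n".join(lines) + "\n")

    paths["fasta"] = out / "genome.fa"
    io_formats.write_fasta(result.pm_sequences, paths["fasta"])
    paths["agp"] = out / "genome.agp"
    io_formats.write_agp(result.pseudomolecules, paths["agp"])
    if result.unplaced_sequences:
        paths["unplaced"] = out / "genome.unplaced.fa"
        io_formats.write_fasta(result.unplaced_sequences, paths["unplaced"])
    if result.metrics:
        paths["metrics"] = out / "metrics.json"
        paths["metrics"].write_text(json.dumps(result.metrics, indent=2, sort_keys=True) + "\n")
    return paths


def output_digests(out_dir: str | Path) -> dict[str, str]:
    """SHA-256 of every file under an output directory (determinism checks)."""
    out = Path(out_dir)
    return {
        str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.rglob("*"))
        if p.is_file()
    }


# ---------------------------------------------------------------------------
# synthetic scenarios
# ---------------------------------------------------------------------------

#: Desk-scale study conditions: 3 chromosomes x 2 Mb, ~150 scaffolds,
#: ~470 markers shared across two maps, 600 BACs, one GBS population.
CHROM_LENGTHS = {"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 2_000_000}

CLEAN_SCENARIO = dict(
    n_markers=470, noise_cm_sd=0.0,
    frac_discordant=0.0, frac_wrong_lg=0.0, frac_multimap=0.0,
    n_chimeric=0, n_sink_contigs=0,
)

CORRUPTED_SCENARIO = dict(
    n_markers=470, noise_cm_sd=0.5,
    frac_discordant=0.10, frac_wrong_lg=0.05, frac_multimap=0.05,
    n_chimeric=6, n_sink_contigs=1,
)


@dataclass
class SimBundle:
    genome: dict[str, str]
    fragments: synthetic.FragmentResult
    maps: synthetic.MapSim
    bacs: synthetic.BacSim


def simulate_scenario(
    seed: int,
    scenario: Mapping[str, object] = CLEAN_SCENARIO,
    chrom_lengths: Mapping[str, int] = CHROM_LENGTHS,
) -> SimBundle:
    """Generate one full synthetic study (genome, maps, BACs)."""
    sc = dict(scenario)
    genome = synthetic.simulate_genome(chrom_lengths, seed=seed)
    fragments = synthetic.fragment_genome(
        genome, n_chimeric=int(sc.pop("n_chimeric", 0)), seed=seed + 1
    )
    n_sink = int(sc.pop("n_sink_contigs", 0))
    maps = synthetic.simulate_maps(genome, fragments, seed=seed + 2, **sc)
    bacs = synthetic.simulate_bacs(
        genome, fragments, n_sink_contigs=n_sink, seed=seed + 3
    )
    return SimBundle(genome=genome, fragments=fragments, maps=maps, bacs=bacs)


def write_scenario(bundle: SimBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated study in the exact formats the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "scaffolds": out / "scaffolds.fa",
        "marker_hits": out / "marker_hits.psl",
        "map_published": out / "map_published.tsv",
        "map_new": out / "map_new.tsv",
        "bac_hits": out / "bac_hits.tsv",
        "bac_lengths": out / "bac_lengths.tsv",
        "physical_map": out / "physical_map.tsv",
    }
    io_formats.write_fasta(bundle.fragments.scaffolds, paths["scaffolds"])
    io_formats.write_psl(bundle.maps.psl_rows, paths["marker_hits"])
    io_formats.write_genetic_map(bundle.maps.map_published, paths["map_published"])
    io_formats.write_genetic_map(bundle.maps.map_new, paths["map_new"])
    io_formats.write_blast6(bundle.bacs.blast6_rows, paths["bac_hits"])
    io_formats.write_query_lengths(bundle.bacs.query_lengths, paths["bac_lengths"])
    io_formats.write_physical_map(bundle.bacs.memberships, paths["physical_map"])
    synthetic.write_truth(bundle.fragments, bundle.maps.markers, out / "truth")
    paths["truth"] = out / "truth"
    return paths


def run_synthetic(
    seed: int,
    scenario: Mapping[str, object] = CLEAN_SCENARIO,
    out_dir: str | Path | None = None,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Simulate a scenario, anchor it, and (optionally) write artifacts."""
    bundle = simulate_scenario(seed, scenario)
    result = anchor_genome(
        bundle.fragments.scaffolds,
        _hits_from_psl_rows(bundle.maps.psl_rows),
        bundle.maps.map_published,
        bundle.maps.map_new,
        bac_hits=_hits_from_blast6_rows(bundle.bacs.blast6_rows, bundle.bacs.query_lengths),
        memberships=bundle.bacs.memberships,
        config=config,
        fragments=bundle.fragments,
        true_sink_ids=bundle.bacs.sink_ids,
        marker_truth=bundle.maps.markers,
    )
    if out_dir is not None:
        write_scenario(bundle, Path(out_dir) / "inputs")
        write_outputs(result, Path(out_dir) / "anchored")
    return result


def _hits_from_psl_rows(rows: Sequence[Mapping[str, object]]) -> list[AlignmentHit]:
    hits = []
    for r in rows:
        matches, mismatches = int(r["matches"]), int(r["mismatches"])
        hits.append(
            AlignmentHit(
                query_id=str(r["qname"]),
                target_id=str(r["tname"]),
                identity=matches / (matches + mismatches),
                coverage=(int(r["qend"]) - int(r["qstart"])) / int(r["qsize"]),
                target_start=int(r["tstart"]),
                target_end=int(r["tend"]),
                strand=str(r["strand"]),
            )
        )
    return hits


def _hits_from_blast6_rows(
    rows: Sequence[Mapping[str, object]], qlens: Mapping[str, int]
) -> list[AlignmentHit]:
    hits = []
    for r in rows:
        sstart, send = int(r["sstart"]), int(r["send"])
        if sstart <= send:
            strand, t0, t1 = "+", sstart - 1, send
        else:
            strand, t0, t1 = "-", send - 1, sstart
        hits.append(
            AlignmentHit(
                query_id=str(r["qseqid"]),
                target_id=str(r["sseqid"]),
                identity=float(r["pident"]) / 100.0,
                coverage=int(r["length"]) / qlens[str(r["qseqid"])],
                target_start=t0,
                target_end=t1,
                strand=strand,
            )
        )
    return hits
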