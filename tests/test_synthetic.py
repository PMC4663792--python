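"""Generator determinism, ground-truth bookkeeping, and recovery metrics."""

import numpy as np
import pytest

from anchorkit import io_formats as io
from anchorkit import pipeline
from anchorkit.marker_anchor import ScaffoldPlacement
from anchorkit.pseudomolecule import reverse_complement
from anchorkit.synthetic import (
    evaluate_anchoring,
    fragment_genome,
    lg_name,
    simulate_bacs,
    simulate_genome,
    simulate_maps,
    simulate_population,
)

LENGTHS = {"chr1": 300_000, "chr2": 300_000}


class TestGenome:
    def test_deterministic_and_lengths_honoured(self):
        g1 = simulate_genome(LENGTHS, seed=9)
        g2 = simulate_genome(LENGTHS, seed=9)
        assert g1 == g2
        assert {c: len(s) for c, s in g1.items()} == LENGTHS
        assert simulate_genome(LENGTHS, seed=10) != g1

    def test_gc_extremes(self):
        g = simulate_genome({"chr1": 2_000}, gc=1.0, seed=0)
        assert set(g["chr1"]) <= {"G", "C"}


class TestFragmentation:
    def test_truth_ordered_oriented_scaffolds_reconstruct_chromosomes(self):
        genome = simulate_genome(LENGTHS, seed=2)
        frag = fragment_genome(genome, seed=3)
        for chrom, seq in genome.items():
            parts = frag.parts[frag.parts.chrom == chrom].sort_values("chrom_start")
            rebuilt = []
            for r in parts.itertuples(index=False):
                piece = frag.scaffolds[r.scaffold_id][r.scaffold_start:r.scaffold_end]
                rebuilt.append(piece if r.orientation == "+" else reverse_complement(piece))
            assert "".join(rebuilt) == seq

    def test_min_length_respected_and_reproducible(self):
        genome = simulate_genome(LENGTHS, seed=2)
        a = fragment_genome(genome, min_length=5_000, seed=3)
        b = fragment_genome(genome, min_length=5_000, seed=3)
        assert a.scaffolds == b.scaffolds
        assert min(len(s) for s in a.scaffolds.values()) >= 5_000

    def test_chimeras_recorded_with_breakpoints(self):
        genome = simulate_genome({"chr1": 600_000, "chr2": 600_000}, seed=4)
        frag = fragment_genome(genome, n_chimeric=2, min_chimera_part=40_000, seed=5)
        assert len(frag.chimeras) == 2
        for ch in frag.chimeras.itertuples(index=False):
            parts = frag.parts[frag.parts.scaffold_id == ch.scaffold_id]
            assert len(parts) == 2
            assert ch.left_chrom != ch.right_chrom
            assert 0 < ch.breakpoint < len(frag.scaffolds[ch.scaffold_id])


class TestMaps:
    def _sim(self, **kw):
        genome = simulate_genome(LENGTHS, seed=2)
        frag = fragment_genome(genome, seed=3)
        defaults = dict(n_markers=120, seed=6)
        defaults.update(kw)
        return genome, frag, simulate_maps(genome, frag, **defaults)

    def test_zero_noise_maps_identical_and_monotone(self):
        _, _, sim = self._sim(noise_cm_sd=0.0, p_published=1.0, p_new=1.0)
        pub = {r.marker_id: r for r in sim.map_published}
        new = {r.marker_id: r for r in sim.map_new}
        assert set(pub) == set(new)
        assert all(pub[m].cm == new[m].cm and pub[m].linkage_group == new[m].linkage_group for m in pub)
        truth = sim.markers.sort_values("genome_pos")
        for chrom, grp in truth.groupby("chrom"):
            assert grp.true_cm.is_monotonic_increasing

    def test_corruption_counts_realised_exactly(self):
        _, _, sim = self._sim(frac_wrong_lg=0.05, frac_multimap=0.05, frac_discordant=0.10)
        n = len(sim.markers)
        counts = sim.markers.corruption.value_counts()
        assert counts.get("wrong_lg", 0) == round(0.05 * n)
        assert counts.get("multi_map", 0) == round(0.05 * n)
        assert counts.get("discordant_cm", 0) == round(0.10 * n)

    def test_discordant_markers_differ_by_more_than_30cm(self):
        _, _, sim = self._sim(frac_discordant=0.10)
        pub = {r.marker_id: r.cm for r in sim.map_published}
        new = {r.marker_id: r.cm for r in sim.map_new}
        disc = sim.markers[sim.markers.corruption == "discordant_cm"]
        assert len(disc) > 0
        for m in disc.marker_id:
            assert abs(pub[m] - new[m]) > 30.0

    def test_hits_pass_default_filters_and_psl_round_trip(self, tmp_path):
        from anchorkit.marker_anchor import filter_hits

        _, _, sim = self._sim(frac_multimap=0.05)
        p = tmp_path / "hits.psl"
        io.write_psl(sim.psl_rows, p)
        hits = io.read_psl(p)
        assert len(filter_hits(hits)) == len(hits)
        multimap = set(sim.markers[sim.markers.corruption == "multi_map"].marker_id)
        from collections import Counter

        per_marker = Counter(h.query_id for h in hits)
        assert all(per_marker[m] == 2 for m in multimap)


class TestBacs:
    def test_sink_contig_dominates_scaffold_degree(self):
        genome = simulate_genome(LENGTHS, seed=2)
        frag = fragment_genome(genome, seed=3)
        sim = simulate_bacs(genome, frag, n_bacs=120, n_sink_contigs=1, seed=8)
        assert sim.sink_ids == ["sink01"]
        bac2ctg = {m.bac_id: m.contig_id for m in sim.memberships if m.contig_id}
        deg: dict[str, set] = {}
        for row in sim.blast6_rows:
            ctg = bac2ctg.get(row["qseqid"][:-2])
            if ctg:
                deg.setdefault(ctg, set()).add(row["sseqid"])
        sink_deg = len(deg["sink01"])
        assert sink_deg > max(len(v) for c, v in deg.items() if c != "sink01")

    def test_non_sink_end_reads_hit_scaffolds_of_their_chromosome(self):
        genome = simulate_genome(LENGTHS, seed=2)
        frag = fragment_genome(genome, seed=3)
        sim = simulate_bacs(genome, frag, n_bacs=80, seed=8)
        chrom_of = {}
        for r in frag.parts.itertuples(index=False):
            chrom_of.setdefault(r.scaffold_id, set()).add(r.chrom)
        bac_chrom = {}
        for row in sim.blast6_rows:
            bac = row["qseqid"][:-2]
            bac_chrom.setdefault(bac, set()).update(chrom_of[row["sseqid"]])
        assert all(len(cs) == 1 for cs in bac_chrom.values())

    def test_zero_coverage_empty_outputs(self):
        genome = simulate_genome(LENGTHS, seed=2)
        frag = fragment_genome(genome, seed=3)
        sim = simulate_bacs(genome, frag, n_bacs=0, seed=8)
        assert sim.blast6_rows == [] and sim.memberships == []


class TestPopulation:
    def test_no_noise_limit_recovers_truth(self):
        from anchorkit.ld import call_genotypes

        pop = simulate_population(
            LENGTHS, n_founders=6, n_generations=0, n_individuals=20,
            n_sites=60, mean_depth=60.0, error_rate=0.0, seed=13,
        )
        called = call_genotypes(pop.matrix)
        assert np.array_equal(called.genotypes, pop.true_dosage.astype(float))

    def test_fixed_seed_reproducible(self):
        a = simulate_population(LENGTHS, n_sites=40, n_individuals=10, seed=21)
        b = simulate_population(LENGTHS, n_sites=40, n_individuals=10, seed=21)
        assert np.array_equal(a.matrix.ref_depth, b.matrix.ref_depth)
        assert np.array_equal(a.matrix.alt_depth, b.matrix.alt_depth)


class TestEvaluation:
    def test_truth_fed_back_scores_perfectly(self):
        genome = simulate_genome(LENGTHS, seed=2)
        frag = fragment_genome(genome, seed=3)
        placements = []
        for sid in frag.scaffolds:
            r = frag.parts[frag.parts.scaffold_id == sid].iloc[0]
            placements.append(
                ScaffoldPlacement(
                    scaffold_id=sid, linkage_group=lg_name(r.chrom),
                    cm_key=float(r.chrom_start), orientation=r.orientation,
                )
            )
        m = evaluate_anchoring(placements, frag)
        assert m["placed_fraction"] == 1.0
        assert m["chrom_accuracy"] == 1.0
        assert m["orientation_accuracy"] == 1.0
        assert all(v == pytest.approx(1.0) for v in m["order_rank_correlation_per_chrom"].values())

    def test_random_permutation_order_has_low_correlation(self):
        genome = simulate_genome({"chr1": 900_000}, seed=2)
        frag = fragment_genome(genome, seed=3)
        sids = sorted(frag.scaffolds)[:20]
        rng = np.random.default_rng(17)
        keys = rng.permutation(len(sids)).astype(float)
        placements = [
            ScaffoldPlacement(scaffold_id=s, linkage_group="LG1", cm_key=float(k))
            for s, k in zip(sids, keys)
        ]
        m = evaluate_anchoring(placements, frag)
        assert abs(m["order_rank_correlation"]) < 0.5

    def test_empty_placements(self):
        genome = simulate_genome(LENGTHS, seed=2)
        frag = fragment_genome(genome, seed=3)
        m = evaluate_anchoring([], frag)
        assert m["placed_fraction"] == 0.0
        assert np.isnan(m["chrom_accuracy"])


class TestScenarioFiles:
    def test_generated_files_accepted_by_readers(self, tmp_path, corrupted_bundle):
        paths = pipeline.write_scenario(corrupted_bundle, tmp_path)
        seqs = io.read_fasta(paths["scaffolds"])
        assert seqs == corrupted_bundle.fragments.scaffolds
        hits = io.read_psl(paths["marker_hits"])
        assert len(hits) == len(corrupted_bundle.maps.psl_rows)
        maps = io.read_genetic_map(paths["map_published"])
        assert maps == corrupted_bundle.maps.map_published
        qlens = io.read_query_lengths(paths["bac_lengths"])
        bac_hits = io.read_blast6(paths["bac_hits"], qlens)
        assert len(bac_hits) == len(corrupted_bundle.bacs.blast6_rows)
        phys = io.read_physical_map(paths["physical_map"])
        assert phys == corrupted_bundle.bacs.memberships
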