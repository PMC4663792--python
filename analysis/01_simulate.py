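#!/usr/bin/env python
"""Generate the two synthetic studies the downstream analyses consume.

Writes, under results/sim/{clean,corrupted}/, a fragmented three-chromosome
genome (scaffold FASTA), two noisy genetic maps plus marker alignments
(PSL), BAC-end alignments with the physical-map membership table, and the
ground-truth tables. The clean study has no corruption; the corrupted one
injects 10% >30 cM inter-map discordances, 5% wrong-linkage-group markers,
5% multi-mapping markers, six chimeric scaffolds and one repeat-derived
sink contig.
"""

from pathlib import Path

from anchorkit import pipeline

SEED = 1
ROOT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    for name, scenario in (("clean", pipeline.CLEAN_SCENARIO),
                           ("corrupted", pipeline.CORRUPTED_SCENARIO)):
        bundle = pipeline.simulate_scenario(SEED, scenario)
        out = ROOT / name
        pipeline.write_scenario(bundle, out)
        n_markers = len(bundle.maps.markers)
        n_chim = len(bundle.fragments.chimeras)
        print(
            f"{name}: {len(bundle.fragments.scaffolds)} scaffolds, "
            f"{n_markers} markers ({len(bundle.maps.map_published)} published / "
            f"{len(bundle.maps.map_new)} new map entries), "
            f"{len(bundle.bacs.memberships)} BACs, {n_chim} chimeras, "
            f"sinks {bundle.bacs.sink_ids or 'none'} -> {out}"
        )


if __name__ == "__main__":
    main()
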