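# Methods

`anchorkit` re-implements, as a tested library, the marker- and
physical-map-based anchoring workflow used to lift a fragmented draft
assembly of a diploid plant genome (seven chromosomes, ~300 Mb scale in
the real setting) to chromosome-scale pseudomolecules, together with the
comparative (Kimura-2P divergence, LTR dating, collinearity blocks) and
population (GBS genotype calling, LD decay) computations that accompany
such a project. All computations run at desk scale on a seeded synthetic
genome whose ground truth makes recovery quantifiable.

## Marker anchoring

Markers from two genetic maps — a previously published map and a newer
one — are aligned to the scaffolds (BLAT-style PSL input). Alignments are
retained only when base-pair identity **and** query coverage are strictly
above 90%. PSL identity is defined as `matches / (matches + misMatches)`
(repeat matches and Ns ignored) and coverage as `(qEnd − qStart)/qSize`;
both are explicit dialect decisions since PSL does not carry them.

Markers aligning to more than one position are tagged *ambiguous* and
retained, but never decide a linkage group on their own: linkage-group
votes use unambiguous markers when any exist, and a scaffold supported
only by ambiguous markers needs at least two in agreement.

Per marker, the two maps are merged before any scaffold-level decision:
if both maps position the marker and disagree by **more than 30 cM**, the
published position is kept; within 30 cM the arithmetic mean is used; a
single source stands as is. A marker whose two maps disagree on the
linkage group itself is removed as unresolvable.

### Linkage-group resolution and chimera splitting

For each scaffold, the retained markers vote:

* unanimous → placed, with map key `cm_key` = mean resolved cM of the
  supporting markers (the ordering statistic; the source protocol names no
  statistic, and the mean is stable for the 1–10 marker supports seen
  here);
* a count-1 dissenter against a ≥2 majority → the dissenter is removed
  and the majority wins (the "any single marker linking to a different
  linkage group … was removed" rule, implemented literally as
  count 1 vs count ≥ 2);
* two groups of ≥2 markers each → chimera candidate (below);
* anything else (1 vs 1, several large groups) → unplaceable.

A chimeric scaffold joins material from two chromosomes, so its two
marker groups should be coordinate-separable. The split point is found by
scanning every cut of the position-sorted markers, in both left/right
assignments, and ranking cuts by (i) the number of markers stranded on
the wrong side ("strays"), then (ii) the strays' cM incoherence with
their claimed group (distance of the resolved position from the group's
retained median) — a corrupted label sits at a random place on another
chromosome's map, a genuine member does not. A positional-isolation
criterion was evaluated for this ranking and rejected: marker spacing is
approximately exponential, so ~25% of genuine junction-flanking markers
look "isolated" and the criterion removes the wrong marker more often
than it helps. Strays are capped at two per linkage group, must be
outnumbered 2:1 by their group's correctly sided markers, and are removed
as dissenters; each side must keep ≥2 markers. A third linkage-group
cluster strictly outvoted by both main groups is treated the same way
(the method only ever splits a scaffold in two). If no feasible cut
exists the groups are genuinely interleaved and the scaffold is left
unplaced. The split position is the midpoint between the innermost
retained markers of the two sides; children are named `<id>_1`/`<id>_2`,
markers are re-assigned with shifted coordinates, and each child is
re-resolved.

## Physical-map (BAC-end) linking

BAC-end reads aligned to the scaffolds (MegaBLAST-style tabular input,
same strict >90%/>90% filter) plus the BAC→physical-contig membership
table give each scaffold a count profile over contigs. **Sink contigs** —
repeat-derived contigs linking indiscriminately across the genome — are
removed first: explicitly by id, and automatically when a contig's
scaffold degree both exceeds mean + 3·SD of the *other* contigs' degrees
(leave-one-out, so one extreme sink cannot mask itself by inflating the
spread) and is at least 3.5× their 90th-percentile degree (without this
second condition the genuinely heavy tail of large physical contigs is
flagged; with it, sweeps over 100 generator seeds show no false
positives while a true sink, ~4–6× the largest genuine degree, is always
caught).

A scaffold–contig link is then accepted as

* **unique** — every alignment points to one contig (total ≥ 2);
* **dominant** — the top contig has >50% of alignments and total ≥ 4;
* **strong** — the top contig has ≥2× the runner-up and ≥3 alignments;

otherwise (including a tied top) it is rejected. The source protocol
leaves "a minimum number of total alignments" and "significantly higher"
unquantified; the defaults above are explicit and configurable.

Unplaced scaffolds inherit positions through shared contigs: an unplaced
scaffold with an accepted link to contig C, where placed scaffolds also
link C, is inserted immediately after the placed neighbour with the most
alignments to C, on its linkage group, orientation unknown. When the
placed neighbours disagree on the linkage group, a lone dissenting
neighbour against a clear majority (more anchoring scaffolds, or equal
scaffolds but more supporting markers) is outvoted — the same
single-dissenter principle as in marker anchoring; two or more
neighbours on a second linkage group, or an unbreakable tie, makes the
contig abstain. Placed scaffolds are never moved and nothing is placed
twice.

## Pseudomolecule construction

Within each linkage group scaffolds are ordered by
(`cm_key`, insertion rank, scaffold id); insertion rank is 0 for marker
placements and ≥1 for BAC-inserted scaffolds so they follow their anchor.
Orientation is the sign of the concordant-minus-discordant pair count
between marker base position and resolved cM (`+`, `−`, or `?` with fewer
than two usable markers or a tie); monotonicity of the genetic map along
the chromosome is the only usable signal. Sequences are concatenated with
one 10,000-bp `N` gap per join (`scaffold`/`yes`/`map` in AGP v2.1
terms); `−` components are reverse-complemented, `?` components are
emitted forward but written as `?` in the AGP. Internal coordinates are
0-based half-open; AGP output is 1-based inclusive; lifting a scaffold
coordinate into the pseudomolecule and back is the identity for all
orientations.

## Comparative computations

* **Kimura-2-parameter divergence** over gap-free, unambiguous aligned
  sites: with transition proportion `P` and transversion proportion `Q`,
  `K = −½·ln((1−2P−Q)·√(1−2Q))`; transitions are A↔G and C↔T. `P+Q`
  approximates `K` to within 5% when `P+Q ≤ 0.05`; saturation
  (non-positive log arguments) raises an error rather than returning a
  number.
* **LTR insertion age** `T = K/(2r)` with the legume substitution rate
  `r = 1.3×10⁻⁸` per site per year by default.
* **Collinearity blocks**: gene-anchor pairs are chained per chromosome
  pair into maximal runs strictly monotone in both genomes' gene ranks
  (forward and inverted), with consecutive rank gaps ≤5 by default
  ("consecutive" is interpreted in rank space with a small tolerance,
  since a zero-gap reading would shatter blocks on any unannotated gene).
  Chains are extracted longest-first by an exact quadratic dynamic
  program (ties: forward, then smaller start rank) without anchor reuse;
  a block needs ≥30 pairs.
* **Divergence histograms** use half-open bins `[i·w, (i+1)·w)` with an
  edge-robust bin-index computation; modal ties go to the smaller bin.

## GBS genotypes and LD

Genotypes are called per individual-site from allele depths: fewer than
10 reads → missing; both alleles with ≥2 reads → heterozygous; otherwise
homozygous for the major allele. A site-individual with exactly one
minor read is called homozygous-major — the single read is treated as
sequencing error — with `single_minor="missing"` exposing the
conservative alternative. Sites are removed when missingness exceeds
0.20 or the dosage-based minor allele frequency (over called genotypes)
falls below 0.05; both boundaries are inclusive-keep. LD is the squared
Pearson correlation of unphased dosages ("composite" r², the appropriate
estimator without phase), undefined with fewer than two jointly-called
individuals or a monomorphic site, and summarised as pair-count-weighted
means in 5-kb distance bins up to 500 kb.

## The synthetic study and what it shows

The generator builds, from one seed, a deterministic ground-truthed
study at desk scale: 3 chromosomes × 2 Mb, i.i.d. bases at GC 0.36,
fragmented into ~150 lognormal scaffolds (mean 40 kb, minimum 5 kb), half
stored reverse-complemented. Genetic maps use a linear 35 cM/Mb
position–cM relation (≈70 cM per chromosome, the per-chromosome genetic
length of a typical plant linkage map) observed with 0.5 cM per-map
noise; ~470 markers are each present in either map with probability
0.85. BACs (600, ~30 kb — BAC length scaled to the 1/40-scale genome)
tile the chromosomes; BACs overlapping by at least a third of a BAC
length form a physical contig (fingerprint assembly needs substantial
shared content; merging on any overlap produces unrealistic
chromosome-spanning contigs), and singletons stay contig-less.

The corrupted scenario adds exactly (rounded): 10% of markers with a
>30 cM discordance injected into the new map, 5% consistently
wrong-linkage-group markers, 5% multi-mappers with a second alignment on
a random scaffold, six chimeric scaffolds, and one sink contig whose 30
clones scatter their end reads uniformly over the genome. Chimeras pair
the smallest fragments above 80 kb from different chromosomes, and the
map generator guarantees ≥3 markers on each junction flank: detectability
of a junction requires flanking markers, so the benchmark measures the
splitting algorithm rather than marker-sampling luck.

The GBS population descends from a founder pool (default 10 founders, 4
and 32 in the contrast scenarios) through 10 generations of random
mating — synthetic polycross varieties are few generations removed from
their founders — with Poisson crossovers at 50 cM/Mb (genetic length
compressed with the physical scale so recombination is visible within
500 kb), ~500 sites, depth ~Poisson(15), per-read error 1%.

Recovery is scored against truth: chromosome-assignment accuracy,
per-chromosome Spearman correlation of recovered order with true
position, orientation accuracy over decided (non-`?`) scaffolds, chimera
split recall, and propagation accuracy. Two metric definitions follow an
"achievable information" principle: the split-recall window around a
junction is bounded by the innermost *uncorrupted, in-map* markers (a
wrong-LG or multi-map marker at the junction makes its own flank
unknowable to any method), and the propagation denominator excludes
contigs whose placed neighbours are tied or substantively conflicted
(zero decision information). Contigs whose anchor signal is unanimous
but *wrong* remain counted, so the cost of following bad anchors is not
hidden. Order correlation is reported over marker-evidence placements:
BAC-inserted scaffolds are placed "immediately after" their anchor by
construction and carry no intra-contig order signal (an all-placements
figure is reported alongside).

What passing these tests does *not* show: the generator has i.i.d. base
composition and no repeat structure, alignment hits are given (not
recomputed from sequence), map noise is Gaussian and corruption rates
are exact, BAC coverage is uniform, and the population model is a
fixed-size Wright–Fisher-style polycross without selection or structure.
Real data add alignment ambiguity in repeats, map-order errors beyond
single markers, and uneven coverage that these tests do not exercise.

## Numerical and degenerate-input conventions

Threshold boundaries follow the stated rules exactly: identity/coverage
strictly `>`, the 30 cM rule strictly `>`, missingness removal strictly
`>` 0.20, MAF removal strictly `<` 0.05. Ties are deterministic
everywhere (lexicographic scaffold ids, smaller bins, forward chains,
smaller cuts); reruns with one seed are byte-identical, which the suite
checks by hashing every artifact. Empty inputs return empty results
where a vacuous answer exists (no hits, no markers on a scaffold) and
raise where a statistic is undefined (empty histogram, zero comparable
sites, both map positions absent).

## Problem sizes

Default end-to-end runs use the desk-scale scenario above (~150
scaffolds, ~470 markers, 600 BACs, 60 × 500 GBS matrix); every analysis
script and the full test suite complete in well under five minutes on
one CPU, and single-module tests in seconds.
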