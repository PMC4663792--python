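"""Comparative-genomics computations.

* Kimura two-parameter nucleotide divergence
  K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)), with P the transition and Q
  the transversion proportion over compared (gap-free, unambiguous) sites.
* LTR retrotransposon insertion age T = K / (2r) for a substitution rate r
  per site per year (default 1.3e-8, the legume figure used for such
  dating).
* Collinearity (synteny) block calling over gene-anchor pairs: maximal
  chains of anchors strictly monotone in both genomes' gene ranks, with a
  bounded rank gap between consecutive anchors and a minimum chain length
  (default 30 gene pairs).
* Divergence-rate histograms with half-open bins and a modal bin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_ACGT = set("ACGT")


class SaturationError(ValueError):
    """Divergence too high for the K2P distance to be defined."""


@dataclass(frozen=True)
class K2PResult:
    P: float  # transition proportion
    Q: float  # transversion proportion
    K: float  # substitutions per site
    n_sites: int


def kimura2p(seq_a: str, seq_b: str) -> K2PResult:
    """Kimura-2-parameter distance between two aligned sequences.

    Sites where either sequence has a gap or non-ACGT symbol are excluded
    from the comparison.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}")
    n_sites = transitions = transversions = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a not in _ACGT or b not in _ACGT:
            continue
        n_sites += 1
        if a == b:
            continue
        if (a, b) in TRANSITIONS:
            transitions += 1
        else:
            transversions += 1
    if n_sites == 0:
        raise ValueError("no comparable sites")
    P = transitions / n_sites
    Q = transversions / n_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated divergence (P={P:.3f}, Q={Q:.3f})")
    K = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PResult(P=P, Q=Q, K=K, n_sites=n_sites)


def ltr_insertion_time(K: float, rate: float = 1.3e-8) -> float:
    """Insertion age in years, T = K / (2 * rate)."""
    if rate <= 0:
        raise ValueError(f"substitution rate must be positive, got {rate}")
    if K < 0:
        raise ValueError(f"negative divergence {K}")
    return K / (2.0 * rate)


# ---------------------------------------------------------------------------
# synteny blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntenyAnchor:
    gene_a: str
    index_a: int  # gene rank on the genome-A chromosome
    gene_b: str
    index_b: int
    chrom_a: str
    chrom_b: str
    start_a: int | None = None
    start_b: int | None = None


@dataclass
class SyntenyBlock:
    anchors: list[SyntenyAnchor]
    direction: str  # 'forward' or 'inverted'
    chrom_a: str
    chrom_b: str

    @property
    def n_pairs(self) -> int:
        return len(self.anchors)

    @property
    def span_a(self) -> tuple[int, int]:
        idx = [a.index_a for a in self.anchors]
        return min(idx), max(idx)

    @property
    def span_b(self) -> tuple[int, int]:
        idx = [a.index_b for a in self.anchors]
        return min(idx), max(idx)


def _best_chain(
    anchors: Sequence[SyntenyAnchor], sign: int, max_rank_gap: int
) -> list[int]:
    """Longest chain (as indices into ``anchors``, which must be sorted by
    (index_a, index_b)) strictly increasing in index_a and strictly
    monotone (per ``sign``) in index_b, with consecutive rank gaps at most
    ``max_rank_gap`` on both genomes. Deterministic tie-break: the chain
    with the smaller starting index_a, then smaller indices throughout."""
    n = len(anchors)
    dp = [1] * n
    parent = [-1] * n
    for i in range(n):
        ai = anchors[i]
        for j in range(i):
            aj = anchors[j]
            da = ai.index_a - aj.index_a
            db = (ai.index_b - aj.index_b) * sign
            if 0 < da <= max_rank_gap and 0 < db <= max_rank_gap:
                if dp[j] + 1 > dp[i]:
                    dp[i] = dp[j] + 1
                    parent[i] = j
    if not n:
        return []
    best_len = max(dp)
    # among maximal chains, prefer the one whose start anchor is earliest
    candidates = [i for i in range(n) if dp[i] == best_len]

    def chain_of(end: int) -> list[int]:
        chain = []
        k = end
        while k != -1:
            chain.append(k)
            k = parent[k]
        return chain[::-1]

    best = min(
        (chain_of(i) for i in candidates),
        key=lambda ch: (anchors[ch[0]].index_a, ch),
    )
    return best


def call_synteny_blocks(
    anchors: Iterable[SyntenyAnchor],
    min_pairs: int = 30,
    max_rank_gap: int = 5,
) -> list[SyntenyBlock]:
    """Chain gene-anchor pairs into synteny blocks per chromosome pair.

    Within each (chrom_a, chrom_b) pair, maximal forward and inverted
    chains are extracted iteratively (longest first; on equal length the
    forward chain, then the chain starting at the smaller index_a, wins);
    anchors already used are not reused, so overlapping chains resolve to
    the longer one. Duplicate (gene_a, gene_b) anchors are dropped with a
    logged count. Blocks need at least ``min_pairs`` anchors.
    """
    seen: set[tuple[str, str]] = set()
    unique: list[SyntenyAnchor] = []
    n_dup = 0
    for a in anchors:
        key = (a.gene_a, a.gene_b)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        unique.append(a)
    if n_dup:
        log.info("call_synteny_blocks: dropped %d duplicate anchor(s)", n_dup)

    groups: dict[tuple[str, str], list[SyntenyAnchor]] = {}
    for a in unique:
        groups.setdefault((a.chrom_a, a.chrom_b), []).append(a)

    blocks: list[SyntenyBlock] = []
    for (ca, cb) in sorted(groups):
        pool = sorted(groups[(ca, cb)], key=lambda a: (a.index_a, a.index_b))
        while True:
            fwd = _best_chain(pool, +1, max_rank_gap)
            inv = _best_chain(pool, -1, max_rank_gap)
            cand = []
            if fwd:
                cand.append((len(fwd), 0, pool[fwd[0]].index_a, "forward", fwd))
            if inv:
                cand.append((len(inv), 1, pool[inv[0]].index_a, "inverted", inv))
            if not cand:
                break
            cand.sort(key=lambda t: (-t[0], t[2], t[1]))
            length, _, _, direction, chain = cand[0]
            if length < min_pairs:
                break
            blocks.append(
                SyntenyBlock(
                    anchors=[pool[i] for i in chain],
                    direction=direction,
                    chrom_a=ca,
                    chrom_b=cb,
                )
            )
            used = set(chain)
            pool = [a for i, a in enumerate(pool) if i not in used]
    return blocks


# ---------------------------------------------------------------------------
# divergence histogram
# ---------------------------------------------------------------------------


@dataclass
class HistogramBin:
    lo: float
    hi: float
    count: int


@dataclass
class Histogram:
    bins: list[HistogramBin]
    modal_bin: tuple[float, float]


def _bin_index(value: float, width: float) -> int:
    """Index i such that value lies in [i*width, (i+1)*width), robust to
    floating-point division artefacts at bin edges."""
    i = int(math.floor(value / width))
    while value >= (i + 1) * width:
        i += 1
    while value < i * width:
        i -= 1
    return i


def divergence_histogram(values: Sequence[float], bin_width: float = 0.01) -> Histogram:
    """Bin divergence values into half-open bins [i*w, (i+1)*w).

    The modal bin is the highest-count bin; ties go to the smaller bin.
    """
    if len(values) == 0:
        raise ValueError("no values to bin")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    counts: dict[int, int] = {}
    for v in values:
        counts[_bin_index(v, bin_width)] = counts.get(_bin_index(v, bin_width), 0) + 1
    lo_i, hi_i = min(counts), max(counts)
    bins = [
        HistogramBin(lo=i * bin_width, hi=(i + 1) * bin_width, count=counts.get(i, 0))
        for i in range(lo_i, hi_i + 1)
    ]
    modal_i = min(counts, key=lambda i: (-counts[i], i))
    return Histogram(bins=bins, modal_bin=(modal_i * bin_width, (modal_i + 1) * bin_width))
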