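"""GBS genotype calling, SNP filtering, and linkage-disequilibrium decay.

Genotypes are called from per-individual allele depths: at least 10 reads
total, and for a heterozygote at least 2 reads of the minor allele. Sites
are filtered on missingness (> 0.20 removed) and minor allele frequency
(< 0.05 removed). LD is the squared Pearson correlation of unphased
alt-allele dosages (composite r^2), summarised in distance bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Individuals x sites allele-depth data with optionally called genotypes.

    ``genotypes`` holds alt-allele dosage (0, 1, 2) with NaN for missing,
    shaped (n_sites, n_individuals) like the depth arrays.
    """

    sites: pd.DataFrame  # columns chrom, pos (1-based), ref, alt
    individuals: list[str]
    ref_depth: np.ndarray
    alt_depth: np.ndarray
    genotypes: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)


def call_genotypes(
    matrix: GenotypeMatrix,
    min_total: int = 10,
    min_minor: int = 2,
    single_minor: str = "hom",
) -> GenotypeMatrix:
    """Call dosages from allele depths.

    total < ``min_total``: missing. Both alleles >= ``min_minor``:
    heterozygous. Otherwise homozygous for the major allele — unless
    ``single_minor='missing'``, in which case a site-individual with 1..
    ``min_minor``-1 minor reads is set missing instead of treating those
    reads as sequencing error.
    """
    if single_minor not in ("hom", "missing"):
        raise ValueError(f"single_minor must be 'hom' or 'missing', got {single_minor!r}")
    ref = matrix.ref_depth
    alt = matrix.alt_depth
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("negative allele depth")
    total = ref + alt
    minor = np.minimum(ref, alt)
    geno = np.full(ref.shape, np.nan)
    callable_ = total >= min_total
    het = callable_ & (minor >= min_minor)
    hom = callable_ & (minor < min_minor)
    if single_minor == "missing":
        hom &= minor == 0
    geno[het] = 1.0
    geno[hom & (alt > ref)] = 2.0
    geno[hom & (alt <= ref)] = 0.0
    return replace(matrix, genotypes=geno)


def filter_sites(
    matrix: GenotypeMatrix,
    max_missing: float = 0.20,
    min_maf: float = 0.05,
) -> GenotypeMatrix:
    """Keep sites with missingness <= ``max_missing`` and MAF >= ``min_maf``.

    MAF is dosage-based over called genotypes only.
    """
    if matrix.genotypes is None:
        raise ValueError("call_genotypes first")
    g = matrix.genotypes
    missing_frac = np.isnan(g).mean(axis=1)
    with np.errstate(invalid="ignore"):
        p_alt = np.nanmean(g, axis=1) / 2.0
    maf = np.minimum(p_alt, 1.0 - p_alt)
    keep = (missing_frac <= max_missing) & (maf >= min_maf) & ~np.isnan(maf)
    log.info(
        "filter_sites: kept %d / %d sites (missingness <= %.2f, MAF >= %.2f)",
        int(keep.sum()), matrix.n_sites, max_missing, min_maf,
    )
    return GenotypeMatrix(
        sites=matrix.sites.loc[keep].reset_index(drop=True),
        individuals=list(matrix.individuals),
        ref_depth=matrix.ref_depth[keep],
        alt_depth=matrix.alt_depth[keep],
        genotypes=g[keep],
    )


def pairwise_r2(site_i: np.ndarray, site_j: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over individuals called at
    both sites; NaN when fewer than two informative individuals or either
    site has zero variance."""
    mask = ~np.isnan(site_i) & ~np.isnan(site_j)
    n = int(mask.sum())
    if n < 2:
        return float("nan")
    x = site_i[mask]
    y = site_j[mask]
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


@dataclass
class LDBin:
    distance_lo: int
    distance_hi: int  # half-open
    n_pairs: int
    mean_r2: float  # NaN for empty bins
    chrom: str | None = None  # None for genome-pooled bins


def ld_decay(
    matrix: GenotypeMatrix,
    bin_width: int = 5000,
    max_dist: int = 500_000,
    per_chromosome: bool = False,
) -> list[LDBin]:
    """Distance-binned mean r^2 over intra-chromosomal site pairs.

    Pairs with distance < ``max_dist`` enter bin
    [k*bin_width, (k+1)*bin_width). Empty bins are reported with
    n_pairs = 0 and NaN mean. With ``per_chromosome``, bins are computed
    separately for each chromosome; otherwise pooled across chromosomes.
    """
    if matrix.genotypes is None:
        raise ValueError("call_genotypes first")
    n_bins = int(np.ceil(max_dist / bin_width))
    chroms = list(dict.fromkeys(matrix.sites["chrom"]))

    def _accumulate(chrom_set):
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins, dtype=int)
        for chrom in chrom_set:
            idx = np.flatnonzero((matrix.sites["chrom"] == chrom).to_numpy())
            pos = matrix.sites["pos"].to_numpy()[idx]
            order = np.argsort(pos, kind="stable")
            idx, pos = idx[order], pos[order]
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    d = int(pos[b] - pos[a])
                    if d >= max_dist:
                        break
                    r2 = pairwise_r2(matrix.genotypes[idx[a]], matrix.genotypes[idx[b]])
                    if np.isnan(r2):
                        continue
                    k = d // bin_width
                    sums[k] += r2
                    counts[k] += 1
        return sums, counts

    def _bins(sums, counts, chrom=None):
        out = []
        for k in range(n_bins):
            mean = sums[k] / counts[k] if counts[k] else float("nan")
            out.append(
                LDBin(
                    distance_lo=k * bin_width,
                    distance_hi=(k + 1) * bin_width,
                    n_pairs=int(counts[k]),
                    mean_r2=mean,
                    chrom=chrom,
                )
            )
        return out

    if per_chromosome:
        bins: list[LDBin] = []
        for chrom in chroms:
            sums, counts = _accumulate([chrom])
            bins.extend(_bins(sums, counts, chrom=chrom))
        return bins
    sums, counts = _accumulate(chroms)
    return _bins(sums, counts)


def mean_r2_near(bins: Sequence[LDBin], distance: int, window: int = 25_000) -> float:
    """Pair-weighted mean r^2 over bins overlapping
    [distance - window, distance + window]."""
    lo, hi = distance - window, distance + window
    tot = n = 0.0
    for b in bins:
        if b.n_pairs and b.distance_hi > lo and b.distance_lo < hi:
            tot += b.mean_r2 * b.n_pairs
            n += b.n_pairs
    return tot / n if n else float("nan")


def summarize_heterozygosity(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-site observed heterozygote fraction and Hardy-Weinberg expected
    heterozygosity 2pq from called genotypes."""
    if matrix.genotypes is None:
        raise ValueError("call_genotypes first")
    g = matrix.genotypes
    called = ~np.isnan(g)
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore"):
        obs = np.where(n_called > 0, np.nansum(g == 1.0, axis=1) / np.maximum(n_called, 1), np.nan)
        p = np.nanmean(g, axis=1) / 2.0
    exp = 2.0 * p * (1.0 - p)
    df = matrix.sites.copy()
    df["obs_het"] = obs
    df["exp_het"] = exp
    return df
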