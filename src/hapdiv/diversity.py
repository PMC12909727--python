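"""Sequence diversity statistics and the 2pq sliding-window diversity scan.

Alignment-based statistics (S, Watterson's theta, mean-pairwise pi, Tajima's
D) use complete deletion: every column containing a gap or missing base is
dropped before anything is counted.  Window-based pi deliberately uses the
uncorrected sum of 2pq per SNP divided by window length — the estimator the
VCFtools --freq workflow yields — with the n/(n-1) small-sample correction
available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .haplotypes import AMBIGUOUS, HaplotypeAlignment
from .variant_io import GenomicInterval, VariantRecord, allele_frequency

#: sentinel for Tajima's D when the variance term vanishes with S > 0
UNDEFINED = float("nan")

DeletionPolicy = Literal["complete", "pairwise"]


@dataclass(frozen=True)
class DiversityStats:
    """Per-group diversity summary: one row of a Table-2-style report.

    tajima_d is 0 when S = 0 (the convention used for invariant groups) and
    NaN when genuinely indeterminate (variance denominator 0 with S > 0).
    """

    group: str
    n: int
    L: int
    S: int
    theta_w_site: float
    pi_site: float
    tajima_d: float

    def summary(self) -> str:
        d = "undefined" if math.isnan(self.tajima_d) else f"{self.tajima_d:.5f}"
        return (
            f"{self.group}: n={self.n}, L={self.L}, S={self.S}, "
            f"theta/site={self.theta_w_site:.5f}, pi/site={self.pi_site:.5f}, "
            f"Tajima's D={d}"
        )


@dataclass
class WindowTrack:
    """Ordered non-overlapping windows with per-bp diversity values.

    Windows are reported as 1-based closed intervals tiling ``interval``.
    """

    windows: list[tuple[int, int, float]]
    window_size: int
    interval: GenomicInterval

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.windows, columns=["start", "end", "pi"]).assign(
            chrom=self.interval.chrom
        )[["chrom", "start", "end", "pi"]]

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def write_bedgraph(self, path: str | Path) -> None:
        # BedGraph is 0-based half-open
        with open(path, "w") as fh:
            for start, end, pi in self.windows:
                fh.write(f"{self.interval.chrom}\t{start - 1}\t{end}\t{pi:.8g}\n")


def _comparable_columns(alignment: HaplotypeAlignment) -> list[int]:
    """Columns free of gap/missing symbols (complete-deletion policy)."""
    return [
        j
        for j in range(alignment.length)
        if all(seq[j] not in AMBIGUOUS for seq in alignment.sequences)
    ]


def harmonic_a1(n: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i, the Watterson normaliser."""
    return sum(1.0 / i for i in range(1, n))


def segregating_sites(alignment: HaplotypeAlignment) -> tuple[int, int]:
    """(S, L): segregating and comparable site counts under complete deletion."""
    if alignment.n_samples < 2:
        raise ValueError("need >= 2 sequences")
    cols = _comparable_columns(alignment)
    S = sum(
        1 for j in cols if len({seq[j] for seq in alignment.sequences}) >= 2
    )
    return S, len(cols)


def watterson_theta(S: int, n: int, L: int) -> float:
    """Watterson's theta per site: S / (a1 * L)."""
    if n < 2:
        raise ValueError("need n >= 2")
    if L < 1:
        raise ValueError("need L >= 1")
    return S / (harmonic_a1(n) * L)


def mean_pairwise_differences(alignment: HaplotypeAlignment) -> float:
    """pi_total: mean number of differences over all unordered sequence pairs,
    counted over comparable columns only."""
    cols = _comparable_columns(alignment)
    seqs = alignment.sequences
    total = 0
    npairs = 0
    for s1, s2 in combinations(seqs, 2):
        total += sum(1 for j in cols if s1[j] != s2[j])
        npairs += 1
    return total / npairs if npairs else 0.0


def nucleotide_diversity(alignment: HaplotypeAlignment) -> float:
    """pi per site: mean pairwise differences divided by comparable length."""
    if alignment.n_samples < 2:
        raise ValueError("need >= 2 sequences")
    _, L = segregating_sites(alignment)
    if L == 0:
        return 0.0
    return mean_pairwise_differences(alignment) / L


def tajima_constants(n: int) -> dict[str, float]:
    """The classical normalising constants of Tajima's D for sample size n."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d(alignment: HaplotypeAlignment) -> float:
    """Tajima's D = (pi_total - S/a1) / sqrt(e1*S + e2*S*(S-1)).

    Returns 0 when S = 0 (invariant-group convention) and NaN when the
    variance term vanishes with S > 0 (e.g. n = 2, where e1 = 0 and the
    statistic is 0/0).
    """
    n = alignment.n_samples
    if n < 2:
        raise ValueError("need n >= 2")
    S, _ = segregating_sites(alignment)
    if S == 0:
        return 0.0
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return UNDEFINED
    pi_total = mean_pairwise_differences(alignment)
    return (pi_total - S / k["a1"]) / math.sqrt(var)


def diversity_stats(alignment: HaplotypeAlignment, group: str = "") -> DiversityStats:
    """All four statistics for one sample group (one Table-2-style row)."""
    S, L = segregating_sites(alignment)
    n = alignment.n_samples
    if S == 0:
        return DiversityStats(group=group, n=n, L=L, S=0,
                              theta_w_site=0.0, pi_site=0.0, tajima_d=0.0)
    return DiversityStats(
        group=group,
        n=n,
        L=L,
        S=S,
        theta_w_site=watterson_theta(S, n, L),
        pi_site=nucleotide_diversity(alignment),
        tajima_d=tajimas_d(alignment),
    )


def diversity_table(stats: Iterable[DiversityStats]) -> pd.DataFrame:
    rows = [
        {"group": s.group, "n": s.n, "S": s.S, "theta_site": s.theta_w_site,
         "pi_site": s.pi_site, "tajima_d": s.tajima_d}
        for s in stats
    ]
    return pd.DataFrame(rows, columns=["group", "n", "S", "theta_site", "pi_site",
                                       "tajima_d"])


def window_pi(
    freqs: Sequence[tuple[int, float, float]] | pd.DataFrame,
    interval: GenomicInterval,
    window_size: int = 10_000,
    sample_size: int | None = None,
) -> WindowTrack:
    """Windowed diversity: pi_w = sum over SNPs in w of 2pq / window_size.

    ``freqs`` is (pos, p, q) triples or a DataFrame with pos/p/q columns,
    normally from MAF-filtered biallelic SNPs.  When ``sample_size`` is given
    the n/(n-1) correction is applied (off by default — the plain 2pq sum is
    the estimator used here).  Windows tile the interval from its start; a
    trailing partial window is truncated at interval.end (logged).
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if isinstance(freqs, pd.DataFrame):
        triples = list(zip(freqs["pos"], freqs["p"], freqs["q"]))
    else:
        triples = list(freqs)
    if interval.length % window_size != 0:
        import logging

        logging.getLogger(__name__).info(
            "interval length %d not a multiple of %d; last window truncated",
            interval.length, window_size,
        )
    correction = sample_size / (sample_size - 1) if sample_size else 1.0
    windows: list[tuple[int, int, float]] = []
    start = interval.start
    while start <= interval.end:
        end = min(start + window_size - 1, interval.end)
        het = sum(2.0 * p * q for pos, p, q in triples if start <= pos <= end)
        windows.append((start, end, correction * het / window_size))
        start = end + 1
    return WindowTrack(windows=windows, window_size=window_size, interval=interval)


def flank_scan(
    vcf_records: Sequence[VariantRecord],
    gene_interval: GenomicInterval,
    flank: int = 400_000,
    window_size: int = 10_000,
    sample_indices: Sequence[int] | None = None,
) -> WindowTrack:
    """2pq diversity track over the gene plus ``flank`` bp on each side.

    ``sample_indices`` restricts the frequency calculation to a sample subset
    (per-group tracks: phenol-positive vs -negative, species vs species).
    Records are assumed already hard-filtered and MAF-screened.
    """
    scan = GenomicInterval(
        chrom=gene_interval.chrom,
        start=max(1, gene_interval.start - flank),
        end=gene_interval.end + flank,
    )
    triples = []
    for rec in vcf_records:
        if (rec.chrom, rec.pos) not in scan:
            continue
        if sample_indices is not None:
            rec = VariantRecord(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alts=rec.alts,
                qual=rec.qual, depth=rec.depth, mapping_quality=rec.mapping_quality,
                genotypes=tuple(rec.genotypes[i] for i in sample_indices),
            )
        af = allele_frequency(rec)
        if af.n_called > 0:
            triples.append((rec.pos, af.p, af.q))
    return window_pi(triples, scan, window_size=window_size)
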