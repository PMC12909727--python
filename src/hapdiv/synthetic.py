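"""Synthetic inputs for every pipeline stage: coalescent alignments, VCFs with
known allele frequencies, F2 populations, and star-like haplotype fixtures.

All generators are pure functions of their seeds.  A single master seed fans
out to per-component streams via ``numpy.random.SeedSequence.spawn`` — the
documented splitting rule is ``SeedSequence(seed).spawn(k)`` in the order the
components are drawn, so reruns are bitwise identical.

Genotypes are haploid-equivalent by default (inbred rice lines are
effectively homozygous, so a diploid sample carries two copies of one
allele); ``diploid=True`` draws the two alleles independently for
heterozygote-policy testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeAlignment
from .segregation import phenotype_from_genotype
from .variant_io import MISSING, VariantRecord

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CoalescentParams:
    """Standard neutral coalescent with infinite-sites mutation.

    theta is the per-locus scaled mutation rate (2 N mu L in haploid scaling):
    E[S] = theta * a1 and E[pi_total] = theta under neutrality.
    """

    n: int
    theta: float
    L: int
    seed: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 samples")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        if self.L < 1:
            raise ValueError("L must be >= 1")


@dataclass(frozen=True)
class F2Params:
    """An F2 population segregating 1:2:1 at one locus.

    With ``dominance`` set, carriers of the functional allele (AA, Aa) show
    the positive phenotype — the single-gene dominant model of the phenol
    reaction.
    """

    n_plants: int
    seed: int
    dominance: bool = True

    def __post_init__(self) -> None:
        if self.n_plants < 1:
            raise ValueError("need n_plants >= 1")


def simulate_coalescent_alignment(params: CoalescentParams) -> HaplotypeAlignment:
    """Simulate one locus under the standard coalescent with infinite sites.

    The genealogy is drawn by merging random lineage pairs at exponential
    intervals with rate k(k-1)/2 (time in units of 2N generations); mutations
    fall on branches as a Poisson process with mean theta/2 per unit branch
    length, each creating a new segregating column at a distinct position in
    [0, L).  Raises ValueError if more mutations arise than L columns can
    hold (no silent truncation).
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    n, L = params.n, params.L

    # genealogy: children[internal] = (left, right); branch_len[node]
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=int)
    node_time = np.zeros(n_nodes)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    root = active[0]

    branch_len = np.array([
        node_time[parent[v]] - node_time[v] if parent[v] != -1 else 0.0
        for v in range(n_nodes)
    ])
    total_len = branch_len.sum()
    n_mut = rng.poisson(params.theta / 2.0 * total_len) if total_len > 0 else 0
    if n_mut > L:
        raise ValueError(
            f"{n_mut} mutations exceed sequence length L={L}; increase L or lower theta"
        )

    ancestral = rng.choice(BASES, size=L)
    seqs = np.tile(ancestral, (n, 1))
    if n_mut > 0:
        cols = rng.choice(L, size=n_mut, replace=False)
        probs = branch_len / total_len
        mut_nodes = rng.choice(n_nodes, size=n_mut, p=probs)
        # leaf sets below each node
        below: list[set[int]] = [set() for _ in range(n_nodes)]
        for leaf in range(n):
            v = leaf
            while v != -1:
                below[v].add(leaf)
                v = parent[v]
        for col, node in zip(cols, mut_nodes):
            choices = [b for b in "ACGT" if b != ancestral[col]]
            derived = rng.choice(choices)
            for leaf in below[node]:
                seqs[leaf, col] = derived
    sequences = ["".join(row) for row in seqs]
    return HaplotypeAlignment(
        sample_ids=[f"sim{i:03d}" for i in range(n)],
        sequences=sequences,
    )


def simulate_vcf(
    n_samples: int,
    snp_freqs: Sequence[tuple[int, float]],
    missing_rate: float = 0.0,
    qual_range: tuple[float, float] = (40.0, 60.0),
    seed: int = 0,
    chrom: str = "chr04",
    diploid: bool = False,
    inject_violations: bool = False,
) -> list[VariantRecord]:
    """VariantRecords with specified per-site alternate-allele frequencies.

    Genotypes are haploid-equivalent by default (hom-ref or hom-alt drawn
    Bernoulli(freq) per sample); ``diploid`` draws each allele independently.
    DP and MQ are set comfortably above the standard hard-filter thresholds.
    With ``inject_violations``, five extra records are appended, each failing
    exactly one hard-filter criterion (low QUAL, low DP, low MQ, triallelic,
    1-bp indel), for filter testing.
    """
    positions = [p for p, _ in snp_freqs]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("positions must be strictly increasing")
    if any(not 0.0 <= f <= 1.0 for _, f in snp_freqs):
        raise ValueError("frequencies must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    qual_lo, qual_hi = qual_range
    records = []
    for pos, freq in snp_freqs:
        ref, alt = rng.choice(BASES, size=2, replace=False)
        if diploid:
            alleles = rng.random((n_samples, 2)) < freq
        else:
            hom = rng.random(n_samples) < freq
            alleles = np.stack([hom, hom], axis=1)
        gts = []
        for a, b in alleles.astype(int):
            if missing_rate and rng.random() < missing_rate:
                gts.append((MISSING, MISSING))
            else:
                gts.append((int(a), int(b)))
        records.append(
            VariantRecord(
                chrom=chrom, pos=int(pos), ref=str(ref), alts=(str(alt),),
                qual=float(rng.uniform(qual_lo, qual_hi)),
                depth=float(rng.integers(15, 60)),
                mapping_quality=float(rng.uniform(45, 60)),
                genotypes=tuple(gts),
            )
        )
    if inject_violations:
        base = positions[-1] if positions else 1000
        gt = tuple((0, 0) for _ in range(n_samples))
        mk = dict(chrom=chrom, genotypes=gt)
        records += [
            VariantRecord(pos=base + 10, ref="A", alts=("G",), qual=29.0,
                          depth=30.0, mapping_quality=50.0, ids="low_qual", **mk),
            VariantRecord(pos=base + 20, ref="A", alts=("G",), qual=50.0,
                          depth=9.0, mapping_quality=50.0, ids="low_dp", **mk),
            VariantRecord(pos=base + 30, ref="A", alts=("G",), qual=50.0,
                          depth=30.0, mapping_quality=39.0, ids="low_mq", **mk),
            VariantRecord(pos=base + 40, ref="A", alts=("G", "T"), qual=50.0,
                          depth=30.0, mapping_quality=50.0, ids="triallelic", **mk),
            VariantRecord(pos=base + 50, ref="AT", alts=("A",), qual=50.0,
                          depth=30.0, mapping_quality=50.0, ids="indel", **mk),
        ]
    return records


def simulate_f2(params: F2Params) -> pd.DataFrame:
    """F2 genotype/phenotype table: multinomial(1/4, 1/2, 1/4) genotypes.

    Columns: plant_id, genotype in {AA, Aa, aa}, phenotype in
    {positive, negative}.  Under dominance the negative count equals the aa
    count exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    draws = rng.choice(["AA", "Aa", "aa"], size=params.n_plants,
                       p=[0.25, 0.5, 0.25])
    rows = [
        {
            "plant_id": f"F2_{i + 1:03d}",
            "genotype": g,
            "phenotype": phenotype_from_genotype(g, dominant=params.dominance),
        }
        for i, g in enumerate(draws)
    ]
    return pd.DataFrame(rows)


def simulate_f2_counts(n_plants: int, n_reps: int, seed: int = 0) -> np.ndarray:
    """Vectorised genotype counts for many F2 populations: (n_reps, 3) array
    of (AA, Aa, aa) counts drawn multinomial(n_plants; 1/4, 1/2, 1/4)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return rng.multinomial(n_plants, [0.25, 0.5, 0.25], size=n_reps)


def make_haplotype_fixture(
    counts: Sequence[int],
    steps_from_core: Sequence[int],
    L: int = 60,
    seed: int = 0,
) -> HaplotypeAlignment:
    """Star-like haplotype alignment: a core haplotype plus satellites at
    given mutational distances, each replicated to the given counts.

    ``counts[0]`` is the core; ``counts[i]`` (i >= 1) carries
    ``steps_from_core[i-1]`` differences from the core, at columns disjoint
    across satellites so pairwise distances are exactly additive.  Emulates
    the skewed spectra seen at domestication loci, where one haplotype
    carries about half the samples and satellites sit one step away.
    """
    counts = list(counts)
    steps = list(steps_from_core)
    if len(counts) != len(steps) + 1:
        raise ValueError("need |counts| = |steps_from_core| + 1 (first is the core)")
    if any(c < 1 for c in counts) or any(s < 1 for s in steps):
        raise ValueError("counts and steps must be positive")
    if sum(steps) > L:
        raise ValueError(f"total steps {sum(steps)} exceed L={L}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    core = rng.choice(BASES, size=L)
    cols = rng.choice(L, size=sum(steps), replace=False)
    seqs = [core.copy()]
    used = 0
    for s in steps:
        sat = core.copy()
        for col in cols[used:used + s]:
            sat[col] = rng.choice([b for b in "ACGT" if b != core[col]])
        used += s
        seqs.append(sat)
    sample_ids, sequences = [], []
    for h, (seq, c) in enumerate(zip(seqs, counts), start=1):
        s = "".join(seq)
        for rep in range(c):
            sample_ids.append(f"hap{h}_s{rep:03d}")
            sequences.append(s)
    return HaplotypeAlignment(sample_ids=sample_ids, sequences=sequences)
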