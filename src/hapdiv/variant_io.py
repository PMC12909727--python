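"""Multi-sample VCF handling: hard filters, region extraction, allele frequencies.

The hard-filter semantics mirror the GATK-style post-calling cleanup commonly
applied to short-read rice resequencing data: drop sites with low call quality
(QUAL), low total depth (INFO/DP) or low mapping quality (INFO/MQ), drop
indels, and keep exactly-biallelic sites.  All thresholds are **inclusive**:
"below 30" is excluded, so QUAL == 30 survives.

Coordinates are 1-based and fully closed throughout, matching VCF convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: allele-index value marking a missing call (``.`` in VCF)
MISSING = -1

_ALLELE_RE = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class VariantRecord:
    """One variant site with per-sample genotypes.

    genotypes holds one ``(a, b)`` pair of allele indices per sample;
    ``MISSING`` (-1) marks an uncalled allele.  ``depth`` (DP) and
    ``mapping_quality`` (MQ) come from the INFO field and may be None
    when the annotation is absent.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    depth: float | None
    mapping_quality: float | None
    genotypes: tuple[tuple[int, int], ...]
    ids: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for allele in (self.ref, *self.alts):
            if not allele or not _ALLELE_RE.match(allele):
                raise ValueError(f"invalid allele {allele!r} at {self.chrom}:{self.pos}")
        n_alleles = 1 + len(self.alts)
        for gt in self.genotypes:
            for a in gt:
                if a != MISSING and not (0 <= a < n_alleles):
                    raise ValueError(
                        f"allele index {a} out of range at {self.chrom}:{self.pos}"
                    )

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref, *self.alts)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def is_snp(self) -> bool:
        return all(len(a) == 1 for a in self.alleles)


@dataclass(frozen=True)
class FilterCriteria:
    """Hard-filter thresholds; all inclusive (records AT a threshold pass).

    ``missing_annotation_passes`` controls sites lacking DP or MQ INFO
    annotations: by default they fail the respective filter (conservative).
    """

    min_qual: float = 30.0
    min_depth: float = 10.0
    min_mq: float = 40.0
    biallelic_only: bool = True
    snps_only: bool = True
    missing_annotation_passes: bool = False

    def __post_init__(self) -> None:
        if self.min_qual < 0 or self.min_depth < 0 or self.min_mq < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass(frozen=True)
class GenomicInterval:
    """1-based, fully-closed genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("coordinates are 1-based; start must be >= 1")

    def __contains__(self, item: tuple[str, int]) -> bool:
        chrom, pos = item
        return chrom == self.chrom and self.start <= pos <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def from_string(cls, spec: str) -> "GenomicInterval":
        """Parse ``chrom:start-end`` (commas in numbers tolerated)."""
        m = re.match(r"^(.+):([\d,]+)-([\d,]+)$", spec)
        if m is None:
            raise ValueError(f"cannot parse interval {spec!r}")
        return cls(m.group(1), int(m.group(2).replace(",", "")), int(m.group(3).replace(",", "")))


@dataclass(frozen=True)
class AlleleFrequency:
    """Reference/alternate allele frequencies over non-missing calls.

    When no allele is called, ``p = q = 0`` and ``n_called = 0`` flag the
    degenerate case; otherwise p + q = 1 exactly (computed rationally).
    """

    p: float
    q: float
    n_called: int

    @property
    def maf(self) -> float:
        return min(self.p, self.q)


def _parse_gt_pair(gts: Sequence[int]) -> tuple[int, int]:
    # cyvcf2 genotype rows are [a0, a1, phased]; haploid rows are [a0, phased]
    alleles = [int(a) for a in gts[:-1]]
    if len(alleles) == 1:
        alleles = alleles * 2
    return (alleles[0] if alleles[0] >= 0 else MISSING,
            alleles[1] if alleles[1] >= 0 else MISSING)


def read_vcf(path: str | Path, samples: Sequence[str] | None = None) -> list[VariantRecord]:
    """Read a VCF (plain or bgzipped) into :class:`VariantRecord` objects.

    Records are returned sorted by (chrom, pos); a warning is logged if the
    file was out of order.  ``samples`` restricts the genotype columns to the
    named subset, preserving the given order.

    Raises
    ------
    FileNotFoundError
        if ``path`` does not exist.
    KeyError
        if a requested sample is absent from the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    vcf = VCF(str(path))
    header_samples = list(vcf.samples)
    if samples is not None:
        missing = [s for s in samples if s not in header_samples]
        if missing:
            raise KeyError(f"samples not in VCF header: {missing}")
        vcf.set_samples(list(samples))
    records: list[VariantRecord] = []
    for var in vcf:
        qual = None if var.QUAL is None else float(var.QUAL)
        dp = var.INFO.get("DP")
        mq = var.INFO.get("MQ")
        gts = tuple(_parse_gt_pair(row) for row in var.genotypes) if var.genotypes is not None else ()
        records.append(
            VariantRecord(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF.upper(),
                alts=tuple(a.upper() for a in var.ALT),
                qual=qual,
                depth=None if dp is None else float(dp),
                mapping_quality=None if mq is None else float(mq),
                genotypes=gts,
                ids=var.ID or ".",
            )
        )
    vcf.close()
    keyed = [(r.chrom, r.pos) for r in records]
    if keyed != sorted(keyed):
        logger.warning("VCF %s not coordinate-sorted; re-sorting records", path)
        records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def write_vcf(records: Iterable[VariantRecord], path: str | Path,
              sample_ids: Sequence[str]) -> None:
    """Write records as a minimal VCF 4.2 text file."""
    path = Path(path)
    records = list(records)
    contigs = sorted({r.chrom for r in records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT", *sample_ids]
        fh.write("\t".join(cols) + "\n")
        for r in records:
            info_parts = []
            if r.depth is not None:
                info_parts.append(f"DP={int(r.depth)}")
            if r.mapping_quality is not None:
                info_parts.append(f"MQ={r.mapping_quality:g}")
            info = ";".join(info_parts) or "."
            qual = "." if r.qual is None else f"{r.qual:g}"
            gt_strs = [
                "/".join("." if a == MISSING else str(a) for a in gt) for gt in r.genotypes
            ]
            fh.write(
                "\t".join(
                    [r.chrom, str(r.pos), r.ids, r.ref, ",".join(r.alts) or ".",
                     qual, "PASS", info, "GT", *gt_strs]
                )
                + "\n"
            )


def _passes(record: VariantRecord, c: FilterCriteria) -> tuple[bool, str | None]:
    if record.qual is None or record.qual < c.min_qual:
        if not (record.qual is None and c.missing_annotation_passes):
            return False, "qual"
    if record.depth is None:
        if not c.missing_annotation_passes:
            return False, "depth"
    elif record.depth < c.min_depth:
        return False, "depth"
    if record.mapping_quality is None:
        if not c.missing_annotation_passes:
            return False, "mq"
    elif record.mapping_quality < c.min_mq:
        return False, "mq"
    if c.biallelic_only and not record.is_biallelic:
        return False, "multiallelic"
    if c.snps_only and not record.is_snp:
        return False, "indel"
    return True, None


def apply_filters(records: Iterable[VariantRecord],
                  criteria: FilterCriteria | None = None) -> list[VariantRecord]:
    """Apply hard filters, preserving input order.

    Survivors satisfy QUAL >= min_qual, DP >= min_depth, MQ >= min_mq (all
    inclusive), are biallelic (if ``biallelic_only``) and pure single-base
    substitutions (if ``snps_only``).  Per-criterion rejection counts are
    logged at INFO level.  Multiallelic records are dropped whole, never split.
    """
    criteria = criteria or FilterCriteria()
    survivors: list[VariantRecord] = []
    rejected: dict[str, int] = {}
    for rec in records:
        ok, reason = _passes(rec, criteria)
        if ok:
            survivors.append(rec)
        else:
            rejected[reason] = rejected.get(reason, 0) + 1
    if rejected:
        logger.info(
            "apply_filters rejected %d records: %s",
            sum(rejected.values()),
            ", ".join(f"{k}={v}" for k, v in sorted(rejected.items())),
        )
    return survivors


def extract_region(records: Iterable[VariantRecord],
                   interval: GenomicInterval) -> list[VariantRecord]:
    """Records with matching chrom and interval.start <= pos <= interval.end."""
    return [r for r in records if (r.chrom, r.pos) in interval]


def allele_frequency(record: VariantRecord) -> AlleleFrequency:
    """Reference (p) and alternate (q) frequencies over non-missing calls.

    Only defined for biallelic records.  p + q = 1 exactly: counts are tallied
    as integers and divided rationally before conversion to float.
    """
    if not record.is_biallelic:
        raise ValueError(f"allele_frequency requires a biallelic record, got {record.alleles}")
    n_ref = n_alt = 0
    for a, b in record.genotypes:
        for allele in (a, b):
            if allele == MISSING:
                continue
            if allele == 0:
                n_ref += 1
            else:
                n_alt += 1
    n_called = n_ref + n_alt
    if n_called == 0:
        return AlleleFrequency(p=0.0, q=0.0, n_called=0)
    p = Fraction(n_ref, n_called)
    return AlleleFrequency(p=float(p), q=float(1 - p), n_called=n_called)


def maf_filter(records: Iterable[VariantRecord], min_maf: float = 0.05) -> list[VariantRecord]:
    """Keep biallelic records whose minor allele frequency is >= min_maf (inclusive)."""
    out = []
    for rec in records:
        af = allele_frequency(rec)
        if af.n_called > 0 and af.maf >= min_maf:
            out.append(rec)
    return out


def write_frequency_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    """TSV of chrom, pos, p, q, n_called per biallelic record."""
    import pandas as pd

    rows = []
    for rec in records:
        af = allele_frequency(rec)
        rows.append({"chrom": rec.chrom, "pos": rec.pos, "p": af.p, "q": af.q,
                     "n_called": af.n_called})
    pd.DataFrame(rows, columns=["chrom", "pos", "p", "q", "n_called"]).to_csv(
        path, sep="\t", index=False
    )
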