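"""Haplotype construction: genotype matrix -> aligned sequences -> collapsed haplotypes.

A haplotype here is the concatenation of a sample's alleles at the retained
variant sites, not the full genomic sequence; ``site_positions`` keep the
genomic context of each column.  Samples from inbred rice lines are
effectively homozygous, so a diploid genotype normally contributes one
unambiguous base per site; heterozygous and missing calls are handled by
explicit policies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .variant_io import MISSING, VariantRecord

AMBIGUOUS = {"N", "-"}

HetPolicy = Literal["missing", "ref", "alt", "iupac"]
MissingPolicy = Literal["exclude", "pairwise"]

_IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


@dataclass
class HaplotypeAlignment:
    """Equal-length sequences over the retained variant columns.

    ``group_labels`` maps sample_id -> annotation dict (e.g. species,
    phenotype, country) and is carried through collapsing.
    """

    sample_ids: list[str]
    sequences: list[str]
    site_positions: list[int] | None = None
    group_labels: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise ValueError("sample_ids and sequences must have equal length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        if self.site_positions is not None:
            if self.sequences and len(self.site_positions) != self.length:
                raise ValueError("site_positions length must equal alignment length")
            if any(b <= a for a, b in zip(self.site_positions, self.site_positions[1:])):
                raise ValueError("site_positions must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def sequence_of(self, sample_id: str) -> str:
        return self.sequences[self.sample_ids.index(sample_id)]

    def subset(self, sample_ids: Sequence[str]) -> "HaplotypeAlignment":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        return HaplotypeAlignment(
            sample_ids=list(sample_ids),
            sequences=[self.sequences[idx[s]] for s in sample_ids],
            site_positions=self.site_positions,
            group_labels={s: self.group_labels[s] for s in sample_ids if s in self.group_labels},
        )


@dataclass
class Haplotype:
    """A distinct sequence with its carriers.

    hap_id follows the field convention H1, H2, ... assigned by descending
    carrier count (ties broken by first sample occurrence in the alignment).
    """

    hap_id: str
    sequence: str
    members: list[str]
    group_summary: dict[str, Counter] = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.members)


def genotypes_to_alignment(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    het_policy: HetPolicy = "missing",
    group_labels: Mapping[str, Mapping[str, str]] | None = None,
) -> HaplotypeAlignment:
    """Build one sequence per sample from biallelic genotypes.

    Column j of sample i holds the base the sample carries at site j:
    homozygous calls give the allele base, missing calls give 'N', and
    heterozygous calls follow ``het_policy`` ('missing' -> 'N' by default,
    'ref'/'alt' -> the respective allele, 'iupac' -> ambiguity code).
    """
    if het_policy not in ("missing", "ref", "alt", "iupac"):
        raise ValueError(f"unknown het_policy {het_policy!r}")
    n_expected = len(records[0].genotypes) if records else None
    for rec in records:
        if not rec.is_biallelic:
            raise ValueError(f"non-biallelic record at {rec.chrom}:{rec.pos}")
        if len(rec.genotypes) != n_expected:
            raise ValueError("inconsistent sample sets across records")
    if records and n_expected != len(samples):
        raise ValueError(
            f"{len(samples)} sample names for {n_expected} genotype columns"
        )
    columns = []
    for rec in records:
        col = []
        for a, b in rec.genotypes:
            if a == MISSING or b == MISSING:
                col.append("N")
            elif a == b:
                col.append(rec.alleles[a])
            else:  # heterozygous
                if het_policy == "missing":
                    col.append("N")
                elif het_policy == "ref":
                    col.append(rec.ref)
                elif het_policy == "alt":
                    col.append(rec.alts[0])
                else:
                    pair = frozenset(rec.alleles[i] for i in (a, b))
                    col.append(_IUPAC.get(pair, "N"))
        columns.append(col)
    sequences = ["".join(col[i] for col in columns) for i in range(len(samples))]
    return HaplotypeAlignment(
        sample_ids=list(samples),
        sequences=sequences,
        site_positions=[r.pos for r in records] or None,
        group_labels={k: dict(v) for k, v in (group_labels or {}).items()},
    )


def collapse_haplotypes(
    alignment: HaplotypeAlignment,
    missing_policy: MissingPolicy = "exclude",
) -> tuple[list[Haplotype], list[str]]:
    """Partition samples into haplotypes by exact sequence identity.

    Under the default policy samples whose sequence contains 'N' or '-' are
    excluded from collapsing and returned separately; under 'pairwise' every
    sample joins the first haplotype whose sequence matches at all mutually
    unambiguous columns.  Haplotypes are numbered H1, H2, ... by descending
    count, ties broken by first occurrence.

    Returns (haplotypes, excluded_sample_ids).
    """
    if alignment.n_samples == 0:
        raise ValueError("empty alignment")
    excluded: list[str] = []
    groups: list[tuple[str, list[str]]] = []  # (representative sequence, members)
    index: dict[str, int] = {}
    for sid, seq in zip(alignment.sample_ids, alignment.sequences):
        ambiguous = any(c in AMBIGUOUS for c in seq)
        if missing_policy == "exclude" and ambiguous:
            excluded.append(sid)
            continue
        if missing_policy == "pairwise":
            placed = False
            for rep, members in groups:
                if all(
                    a == b or a in AMBIGUOUS or b in AMBIGUOUS
                    for a, b in zip(rep, seq)
                ):
                    members.append(sid)
                    placed = True
                    break
            if not placed:
                groups.append((seq, [sid]))
            continue
        if seq in index:
            groups[index[seq]][1].append(sid)
        else:
            index[seq] = len(groups)
            groups.append((seq, [sid]))
    if not groups:
        raise ValueError("all samples excluded by missing_policy")
    # stable sort: descending count, then first occurrence (input order of groups)
    order = sorted(range(len(groups)), key=lambda i: (-len(groups[i][1]), i))
    haps = []
    for rank, i in enumerate(order, start=1):
        seq, members = groups[i]
        summary: dict[str, Counter] = {}
        for sid in members:
            for key, val in alignment.group_labels.get(sid, {}).items():
                summary.setdefault(key, Counter())[val] += 1
        haps.append(Haplotype(hap_id=f"H{rank}", sequence=seq, members=members,
                              group_summary=summary))
    return haps, excluded


def match_identical(
    haps_a: Sequence[Haplotype], haps_b: Sequence[Haplotype]
) -> list[tuple[str, str]]:
    """Pairs (hap_id_a, hap_id_b) whose sequences are exactly equal.

    Haplotype lists collapse distinct sequences, so each haplotype appears in
    at most one pair.  Used to link identical haplotypes across species, the
    way shared Phr1 haplotypes tie O. glaberrima to its wild relative.
    """
    by_seq = {h.sequence: h.hap_id for h in haps_b}
    return [(h.hap_id, by_seq[h.sequence]) for h in haps_a if h.sequence in by_seq]


# ---------------------------------------------------------------------------
# io

def write_fasta(alignment: HaplotypeAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(alignment.sample_ids, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> HaplotypeAlignment:
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return HaplotypeAlignment(sample_ids=ids, sequences=seqs)


def read_metadata(path: str | Path) -> dict[str, dict[str, str]]:
    """Sample metadata TSV with a sample_id column; remaining columns become labels.

    Phenotype labels and Sanger-typed deletion genotypes travel here — they
    are annotations attached to samples, never inferred from sequence.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError("metadata TSV must have a sample_id column")
    out: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        out[row["sample_id"]] = {
            k: row[k] for k in df.columns if k != "sample_id" and pd.notna(row[k])
        }
    return out


def haplotype_table(haps: Sequence[Haplotype],
                    tally_fields: Sequence[str] = ()) -> pd.DataFrame:
    """Summary table: hap_id, count, members, plus one tally column per field."""
    rows = []
    for h in haps:
        row: dict[str, object] = {
            "hap_id": h.hap_id,
            "count": h.count,
            "members": ",".join(h.members),
        }
        for f in tally_fields:
            tally = h.group_summary.get(f, Counter())
            row[f] = ";".join(f"{k}={v}" for k, v in sorted(tally.items()))
        rows.append(row)
    return pd.DataFrame(rows, columns=["hap_id", "count", "members", *tally_fields])
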