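"""End-to-end orchestration: filter -> haplotypes -> network -> diversity -> scan.

Every report is a plain TSV; a JSON manifest records parameters, seeds and
input checksums so that each reported number can be reproduced by calling
the owning module directly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .variant_io import (FilterCriteria, GenomicInterval, apply_filters,
                         extract_region, maf_filter, read_vcf, write_frequency_table,
                         write_vcf)
from .haplotypes import (collapse_haplotypes, genotypes_to_alignment,
                         haplotype_table, match_identical, read_metadata,
                         write_fasta)
from .network import (build_network, connection_limit, pairwise_steps,
                      write_edge_list, write_graphml)
from .diversity import diversity_stats, diversity_table, flank_scan
from .segregation import chi_square_gof

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str
    metadata: str | None = None
    out_dir: str = "hapdiv_out"
    filters: FilterCriteria = field(default_factory=FilterCriteria)
    gene_interval: str = "chr04:31749155-31751459"
    flank: int = 400_000
    window_size: int = 10_000
    min_maf: float = 0.05
    network_limit: int | None = None  # None -> max observed distance
    network_confidence: float | None = None  # set to use the parsimony estimator
    group_field: str | None = None  # metadata column defining diversity groups
    het_policy: str = "missing"
    f2_observed: Sequence[int] | None = None
    f2_ratio: Sequence[float] | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "filters" in raw:
            raw["filters"] = FilterCriteria(**raw["filters"])
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def group_frequency_table(
    metadata: Mapping[str, Mapping[str, str]] | pd.DataFrame,
    group_by: Sequence[str],
) -> pd.DataFrame:
    """Counts per combination of the given metadata fields (e.g. country x
    phenotype x species); the count column totals the sample count."""
    if isinstance(metadata, pd.DataFrame):
        df = metadata
    else:
        df = pd.DataFrame(
            [{"sample_id": sid, **dict(labels)} for sid, labels in metadata.items()]
        )
    if df.empty:
        logger.warning("empty metadata; frequency table is empty")
        return pd.DataFrame(columns=[*group_by, "count"])
    missing = [f for f in group_by if f not in df.columns]
    if missing:
        raise KeyError(f"metadata fields not present: {missing}")
    out = (
        df.groupby(list(group_by), dropna=False).size().reset_index(name="count")
    )
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all reports under config.out_dir.

    Returns the manifest dict.  Any stage failure raises RuntimeError naming
    the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "hapdiv_version": __version__,
        "config": {k: (asdict(v) if isinstance(v, FilterCriteria) else v)
                   for k, v in asdict(config).items()},
        "inputs": {},
        "stages": {},
    }
    meta = {}
    if config.metadata:
        manifest["inputs"]["metadata_sha256"] = _sha256(config.metadata)
        meta = read_metadata(config.metadata)
    manifest["inputs"]["vcf_sha256"] = _sha256(config.vcf)
    gene = GenomicInterval.from_string(config.gene_interval)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    def _filter():
        records = read_vcf(config.vcf)
        kept = apply_filters(records, config.filters)
        samples = _vcf_samples(config.vcf)
        write_vcf(kept, out / "filtered.vcf", samples)
        write_frequency_table([r for r in kept if r.is_biallelic],
                              out / "frequencies.tsv")
        manifest["stages"]["filter"] = {"n_in": len(records), "n_out": len(kept)}
        return kept, samples

    kept, samples = stage("filter", _filter)

    def _haplotypes():
        region = extract_region(kept, gene)
        aln = genotypes_to_alignment(region, samples,
                                     het_policy=config.het_policy,
                                     group_labels=meta)
        haps, excluded = collapse_haplotypes(aln)
        write_fasta(aln, out / "gene_alignment.fasta")
        tally_fields = sorted({k for labels in meta.values() for k in labels})
        haplotype_table(haps, tally_fields).to_csv(out / "haplotypes.tsv",
                                                   sep="\t", index=False)
        manifest["stages"]["haplotypes"] = {
            "n_sites": len(region), "n_haplotypes": len(haps),
            "n_excluded_samples": len(excluded),
        }
        return aln, haps

    aln, haps = stage("haplotypes", _haplotypes)

    def _network():
        if config.network_confidence is not None:
            limit = connection_limit(aln.length, config.network_confidence)
        elif config.network_limit is not None:
            limit = config.network_limit
        else:
            limit = max(
                (pairwise_steps(a, b) for i, a in enumerate(haps)
                 for b in haps[i + 1:]),
                default=1,
            ) or 1
        net = build_network(haps, limit)
        write_graphml(net, out / "network.graphml")
        write_edge_list(net, out / "network_edges.tsv")
        manifest["stages"]["network"] = {
            "limit": limit, "n_edges": len(net.edges),
            "n_components": len(net.components),
        }

    stage("network", _network)

    def _diversity():
        stats = [diversity_stats(aln, group="all")]
        if config.group_field:
            values = sorted({labels.get(config.group_field)
                             for labels in meta.values()
                             if labels.get(config.group_field)})
            for val in values:
                ids = [s for s in aln.sample_ids
                       if meta.get(s, {}).get(config.group_field) == val]
                if len(ids) >= 2:
                    stats.append(diversity_stats(aln.subset(ids), group=str(val)))
        diversity_table(stats).to_csv(out / "diversity.tsv", sep="\t", index=False)
        manifest["stages"]["diversity"] = {"n_groups": len(stats)}

    stage("diversity", _diversity)

    def _scan():
        screened = maf_filter([r for r in kept if r.is_biallelic], config.min_maf)
        track = flank_scan(screened, gene, flank=config.flank,
                           window_size=config.window_size)
        track.write_tsv(out / "window_pi.tsv")
        track.write_bedgraph(out / "window_pi.bedgraph")
        manifest["stages"]["scan"] = {
            "n_snps": len(screened), "n_windows": len(track.windows),
        }

    stage("scan", _scan)

    if config.f2_observed and config.f2_ratio:
        def _segregation():
            res = chi_square_gof(config.f2_observed, config.f2_ratio)
            pd.DataFrame([res.to_row()]).to_csv(out / "segregation.tsv",
                                                sep="\t", index=False)
            manifest["stages"]["segregation"] = {"chi2": res.chi2, "df": res.df,
                                                 "p": res.p_value}

        stage("segregation", _segregation)

    if meta:
        fields = [f for f in ("country", "phenotype", "species")
                  if any(f in labels for labels in meta.values())]
        if fields:
            group_frequency_table(meta, fields).to_csv(
                out / "group_frequencies.tsv", sep="\t", index=False)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _vcf_samples(path: str | Path) -> list[str]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    vcf.close()
    return samples
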