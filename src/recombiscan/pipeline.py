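"""End-to-end orchestration: SNP calling, phasing, filtering, summary.

``run_full`` takes aligned reads for a heterokaryon and its two parental
homokaryons and produces per-sample heterozygous-SNP sets, haplotype
windows, four summary rows (each homokaryon, the heterokaryon, and the
heterokaryon after both cross-sample filters), an optional genomic-region
fold-enrichment table, and a machine-readable JSON report.

Filter chain for the "filtered heterokaryon" column:

1. heterokaryon SNPs detected in either homokaryon are removed
   (position-level; likely strain-versus-reference differences);
2. haplotype windows are rebuilt on the reduced SNP set;
3. recombinant strings also present — as recombinants — in a homokaryon
   window over the same five positions are excluded.  For step 3 the
   homokaryon reads are phased at the heterokaryon's filtered SNP
   positions, so window keys are comparable across samples; each
   homokaryon's own summary column still uses its own SNP set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from recombiscan import haplotypes as hap
from recombiscan import snps as snpmod
from recombiscan.enrichment import enrichment, partition_genome

logger = logging.getLogger("recombiscan")

SAMPLE_ORDER = ("homokaryon1", "homokaryon2", "heterokaryon",
                "filtered_heterokaryon")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs and thresholds of a full run."""

    het_alignments: str
    hom1_alignments: str
    hom2_alignments: str
    outdir: str
    annotation: str | None = None
    reference: str | None = None
    mapq_min: int = 10
    min_depth: int = 10
    major_frac: float = 0.90
    max_diff: float = 0.20
    k: int = 5
    window_policy: str = "leading"
    apply_snp_filter: bool = True
    snp_filter_match_alleles: bool = False
    strict_sites: bool = False
    seed: int | None = None  # recorded for provenance of simulated inputs

    def __post_init__(self) -> None:
        if not 0.0 <= self.major_frac <= 1.0:
            raise ValueError(f"major_frac must be in [0, 1]: {self.major_frac}")
        if not 0.0 <= self.max_diff <= 1.0:
            raise ValueError(f"max_diff must be in [0, 1]: {self.max_diff}")
        if self.min_depth < 1:
            raise ValueError(f"min_depth must be >= 1: {self.min_depth}")
        if self.mapq_min < 0:
            raise ValueError(f"mapq_min must be >= 0: {self.mapq_min}")
        if self.k < 2:
            raise ValueError(f"k must be >= 2: {self.k}")
        if self.window_policy not in ("leading", "sliding"):
            raise ValueError(f"unknown window_policy: {self.window_policy!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**data)


def _md5(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as e:  # noqa: BLE001 - rewrapped with stage name
            raise PipelineError(name, e) from e
    return wrap


def make_table2(summaries: dict[str, hap.SampleSummary],
                order: tuple[str, ...] = SAMPLE_ORDER) -> pd.DataFrame:
    """Summary table: one column pair (reads, pct) per sample, rows for
    non-recombinants, recombinants and the total."""
    for name in order:
        if name not in summaries or summaries[name] is None:
            raise ValueError(f"missing summary for sample {name!r}")
    data: dict[str, list] = {"row": ["non_recombinants", "recombinants",
                                     "total"]}
    for name in order:
        s = summaries[name]
        if s.total_reads == 0:
            raise ValueError(
                f"sample {name!r} has no phased reads; cannot build table")
        data[f"{name}_reads"] = [s.nonrecombinant_reads,
                                 s.recombinant_reads, s.total_reads]
        data[f"{name}_pct"] = [s.nonrecombinant_pct, s.recombinant_pct,
                               100.0]
    return pd.DataFrame(data)


def run_full(config: RunConfig) -> dict:
    """Run every stage and return the JSON-serializable report.

    All tabular outputs (SNPs, windows, per-read assignments, summaries,
    region table) and ``report.json`` are written under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {"het": config.het_alignments, "hom1": config.hom1_alignments,
              "hom2": config.hom2_alignments}
    if config.annotation:
        inputs["annotation"] = config.annotation
    checksums = {name: _md5(path) for name, path in inputs.items()}

    # --- SNP calling ------------------------------------------------------
    called: dict[str, list[snpmod.HetSNP]] = {}
    for name in ("hom1", "hom2", "het"):
        path = inputs[name]
        pileup = _stage(f"pileup:{name}")(
            snpmod.build_pileup, path, mapq_min=config.mapq_min)
        called[name] = _stage(f"callsnps:{name}")(
            snpmod.call_het_snps, pileup, min_depth=config.min_depth,
            major_frac=config.major_frac, max_diff=config.max_diff)
        logger.info("%s: %d heterozygous SNPs", name, len(called[name]))
        snpmod.write_snps_tsv(called[name], outdir / f"{name}.snps.tsv")
        snpmod.write_vcf(called[name], outdir / f"{name}.snps.vcf")

    if config.apply_snp_filter:
        het_filtered_snps = _stage("filter_shared_snps")(
            snpmod.filter_shared_snps, called["het"], called["hom1"],
            called["hom2"], match_alleles=config.snp_filter_match_alleles)
    else:
        het_filtered_snps = called["het"]
    logger.info("heterokaryon SNPs: %d raw, %d after shared-SNP filter",
                len(called["het"]), len(het_filtered_snps))
    snpmod.write_snps_tsv(het_filtered_snps, outdir / "het.snps.filtered.tsv")

    # --- phasing & windows ------------------------------------------------
    def phase(name: str, snp_set) -> hap.PhasedSample:
        vectors = _stage(f"extract:{name}")(
            hap.extract_sample_alleles, inputs[name], snp_set,
            mapq_min=config.mapq_min, strict=config.strict_sites)
        return _stage(f"windows:{name}")(
            hap.build_windows, vectors, k=config.k,
            policy=config.window_policy)

    phased = {
        "hom1": phase("hom1", called["hom1"]),
        "hom2": phase("hom2", called["hom2"]),
        "het": phase("het", called["het"]),
    }
    het_on_filtered = phase("het", het_filtered_snps)
    hom1_at_het = phase("hom1", het_filtered_snps)
    hom2_at_het = phase("hom2", het_filtered_snps)

    filtered, excluded = _stage("filter_shared_recombinants")(
        hap.filter_shared_recombinants, het_on_filtered, hom1_at_het,
        hom2_at_het)
    logger.info("excluded %d shared recombinant haplotype(s)", len(excluded))

    summaries = {
        "homokaryon1": hap.summarize_sample(phased["hom1"], "homokaryon1"),
        "homokaryon2": hap.summarize_sample(phased["hom2"], "homokaryon2"),
        "heterokaryon": hap.summarize_sample(phased["het"], "heterokaryon"),
        "filtered_heterokaryon": hap.summarize_sample(
            filtered, "filtered_heterokaryon"),
    }
    for sample, ps in [("hom1", phased["hom1"]), ("hom2", phased["hom2"]),
                       ("het", phased["het"]),
                       ("het.filtered", filtered)]:
        hap.windows_to_frame(ps).to_csv(
            outdir / f"{sample}.windows.tsv", sep="\t", index=False)
        hap.reads_to_frame(ps).to_csv(
            outdir / f"{sample}.reads.tsv", sep="\t", index=False)
    summary_frames = pd.concat(
        [hap.summary_to_frame(s) for s in summaries.values()],
        ignore_index=True)
    summary_frames.to_csv(outdir / "summaries.tsv", sep="\t", index=False)
    table2 = _stage("make_table2")(make_table2, summaries)
    table2.to_csv(outdir / "table2.tsv", sep="\t", index=False)

    # --- enrichment -------------------------------------------------------
    region_table = None
    if config.annotation:
        import pysam

        with pysam.AlignmentFile(inputs["het"]) as af:
            lengths = dict(zip(af.references, af.lengths))
        partition = _stage("partition_genome")(
            partition_genome, config.annotation, lengths)
        rec_reads = [(sc, start, end) for _, sc, start, end
                     in filtered.recombinant_reads()]
        region_table = _stage("enrichment")(enrichment, rec_reads, partition)
        region_table.to_csv(outdir / "region_enrichment.tsv", sep="\t",
                            index=False)

    # --- report -----------------------------------------------------------
    from recombiscan import __version__

    report = {
        "tool": "recombiscan",
        "version": __version__,
        "inputs": inputs,
        "input_md5": checksums,
        "thresholds": {
            "mapq_min": config.mapq_min, "min_depth": config.min_depth,
            "major_frac": config.major_frac, "max_diff": config.max_diff,
            "k": config.k, "window_policy": config.window_policy,
            "apply_snp_filter": config.apply_snp_filter,
            "snp_filter_match_alleles": config.snp_filter_match_alleles,
            "strict_sites": config.strict_sites,
        },
        "seed": config.seed,
        "snp_counts": {
            "hom1": len(called["hom1"]), "hom2": len(called["hom2"]),
            "het_raw": len(called["het"]),
            "het_filtered": len(het_filtered_snps),
        },
        "excluded_shared_haplotypes": [
            {"window": "{}:{}".format(
                key[0], "-".join(str(p) for p in key[1:])),
             "haplotype": string}
            for key, string in excluded],
        "n_excluded_shared_haplotypes": len(excluded),
        "summaries": {
            name: {
                "nonrecombinant_reads": s.nonrecombinant_reads,
                "recombinant_reads": s.recombinant_reads,
                "total_reads": s.total_reads,
                "nonrecombinant_pct": s.nonrecombinant_pct,
                "recombinant_pct": s.recombinant_pct,
            } for name, s in summaries.items()},
    }
    if region_table is not None:
        report["region_enrichment"] = region_table.to_dict(orient="records")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
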