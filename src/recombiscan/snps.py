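"""MAPQ-filtered pileups and heterozygous SNP calling.

A biallelic heterozygous SNP is called at a pileup column when, counting
only alignments with MAPQ >= 10, (i) depth >= 10 reads, (ii) the two major
alleles account for >= 90% of the reads, and (iii) the difference between
them is <= 20% of the depth.  All three boundaries are inclusive.
Heterokaryon SNPs detected in either parental homokaryon are filtered out
as likely strain-versus-reference differences rather than true
parental-allele heterozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam

_ACGT = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PileupColumn:
    """Base counts at one reference position from MAPQ-passing reads.

    Only A/C/G/T calls are counted; N and deleted/clipped bases contribute
    nothing.  ``position`` is 1-based.
    """

    scaffold: str
    position: int
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def top_two(self) -> list[tuple[str, int]]:
        """The two largest (base, count) pairs; ties broken A<C<G<T."""
        ranked = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return ranked[:2]


@dataclass(frozen=True, order=True)
class HetSNP:
    scaffold: str
    position: int
    major_allele: str
    second_allele: str
    major_count: int
    second_count: int
    depth: int

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.major_allele, self.second_allele)

    @property
    def key(self) -> tuple[str, int]:
        return (self.scaffold, self.position)


def _open_alignments(path: str | Path) -> pysam.AlignmentFile:
    af = pysam.AlignmentFile(str(path))
    so = (af.header.to_dict().get("HD") or {}).get("SO")
    if so != "coordinate" and not af.has_index():
        raise ValueError(
            f"{path}: alignments are not coordinate-sorted and no index is "
            "present; sort them first (e.g. `samtools sort`)")
    return af


def build_pileup(
    alignments: str | Path | pysam.AlignmentFile,
    mapq_min: int = 10,
) -> list[PileupColumn]:
    """Pileup columns over all covered positions, skipping MAPQ < mapq_min.

    Accepts a coordinate-sorted SAM/BAM path or an open AlignmentFile.
    Uses htslib's pileup engine with base-quality filtering disabled (the
    calling rule uses read counts only).
    """
    own = not isinstance(alignments, pysam.AlignmentFile)
    af = _open_alignments(alignments) if own else alignments
    try:
        columns: list[PileupColumn] = []
        for col in af.pileup(min_mapping_quality=mapq_min, min_base_quality=0,
                             max_depth=1_000_000):
            counts: dict[str, int] = {}
            for base in col.get_query_sequences():
                b = base.upper()
                if b in _ACGT:
                    counts[b] = counts.get(b, 0) + 1
            if counts:
                columns.append(PileupColumn(
                    scaffold=col.reference_name,
                    position=col.reference_pos + 1,
                    counts=counts))
        return columns
    finally:
        if own:
            af.close()


def call_het_snps(
    pileup: list[PileupColumn],
    min_depth: int = 10,
    major_frac: float = 0.90,
    max_diff: float = 0.20,
) -> list[HetSNP]:
    """Call biallelic heterozygous SNPs from pileup columns.

    A column with top-two counts c1 >= c2 (c2 >= 1) and depth d qualifies
    iff ``d >= min_depth``, ``(c1 + c2) / d >= major_frac`` and
    ``(c1 - c2) / d <= max_diff``; all comparisons inclusive.
    Non-qualifying columns are silently skipped.
    """
    out: list[HetSNP] = []
    for col in pileup:
        d = col.depth
        if d < min_depth:
            continue
        top = col.top_two()
        if len(top) < 2:
            continue
        (b1, c1), (b2, c2) = top
        if c2 < 1:
            continue
        if (c1 + c2) / d < major_frac:
            continue
        if (c1 - c2) / d > max_diff:
            continue
        out.append(HetSNP(scaffold=col.scaffold, position=col.position,
                          major_allele=b1, second_allele=b2,
                          major_count=c1, second_count=c2, depth=d))
    return out


def filter_shared_snps(
    het_snps: list[HetSNP],
    hom1_snps: list[HetSNP],
    hom2_snps: list[HetSNP],
    match_alleles: bool = False,
) -> list[HetSNP]:
    """Drop heterokaryon SNPs also detected in either homokaryon.

    By default a SNP is shared when its (scaffold, position) occurs in a
    homokaryon call set regardless of alleles; ``match_alleles=True``
    additionally requires the same unordered allele pair.
    """
    if match_alleles:
        def key(s: HetSNP):
            return (s.scaffold, s.position, frozenset(s.alleles))
    else:
        def key(s: HetSNP):
            return (s.scaffold, s.position)
    shared = {key(s) for s in hom1_snps} | {key(s) for s in hom2_snps}
    return [s for s in het_snps if key(s) not in shared]


# ---------------------------------------------------------------------------
# serialization


def snps_to_frame(snps: list[HetSNP]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"scaffold": s.scaffold, "pos": s.position,
          "major_allele": s.major_allele, "second_allele": s.second_allele,
          "major_count": s.major_count, "second_count": s.second_count,
          "depth": s.depth} for s in snps],
        columns=["scaffold", "pos", "major_allele", "second_allele",
                 "major_count", "second_count", "depth"])


def write_snps_tsv(snps: list[HetSNP], path: str | Path) -> None:
    snps_to_frame(snps).to_csv(path, sep="\t", index=False)


def read_snps_tsv(path: str | Path) -> list[HetSNP]:
    df = pd.read_csv(path, sep="\t")
    return [HetSNP(scaffold=str(r.scaffold), position=int(r.pos),
                   major_allele=str(r.major_allele),
                   second_allele=str(r.second_allele),
                   major_count=int(r.major_count),
                   second_count=int(r.second_count), depth=int(r.depth))
            for r in df.itertuples()]


def write_vcf(snps: list[HetSNP], path: str | Path,
              source: str = "recombiscan") -> None:
    """Minimal VCF: REF = major allele, ALT = second allele, INFO DP/AD."""
    scaffolds = sorted({s.scaffold for s in snps})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,'
                 'Description="MAPQ-passing depth">\n')
        fh.write('##INFO=<ID=AD,Number=2,Type=Integer,'
                 'Description="Major,second allele read counts">\n')
        for sc in scaffolds:
            fh.write(f"##contig=<ID={sc}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(snps):
            fh.write(f"{s.scaffold}\t{s.position}\t.\t{s.major_allele}\t"
                     f"{s.second_allele}\t.\tPASS\t"
                     f"DP={s.depth};AD={s.major_count},{s.second_count}\n")
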