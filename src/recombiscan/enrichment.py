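"""Fold enrichment of recombinant reads over genomic regions.

Every genomic base pair carries exactly one region label (genic where any
gene interval covers it, intergenic elsewhere; exon/intron sub-labels when
the annotation provides exon features).  A recombinant read is assigned to
the label at its alignment midpoint, and a region's fold enrichment is its
share of recombinant reads divided by its share of the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GENIC = "genic"
INTERGENIC = "intergenic"
EXON = "exon"
INTRON = "intron"


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based closed intervals."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


@dataclass
class GenomePartition:
    """A labeled partition of the genome into genic/intergenic bp.

    ``genic`` (and optionally ``exon``) hold per-scaffold merged 1-based
    closed intervals; intronic bp are genic minus exon, intergenic bp the
    complement of genic.
    """

    scaffold_lengths: dict[str, int]
    genic: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    exon: dict[str, list[tuple[int, int]]] | None = None

    @property
    def has_subfeatures(self) -> bool:
        return self.exon is not None

    @property
    def labels(self) -> list[str]:
        return ([EXON, INTRON, INTERGENIC] if self.has_subfeatures
                else [GENIC, INTERGENIC])

    def genome_bp(self) -> dict[str, int]:
        total = sum(self.scaffold_lengths.values())
        genic = sum(e - s + 1 for ivs in self.genic.values()
                    for s, e in ivs)
        if not self.has_subfeatures:
            return {GENIC: genic, INTERGENIC: total - genic}
        exon = sum(e - s + 1 for ivs in (self.exon or {}).values()
                   for s, e in ivs)
        return {EXON: exon, INTRON: genic - exon, INTERGENIC: total - genic}

    def label_at(self, scaffold: str, position: int) -> str:
        if scaffold not in self.scaffold_lengths:
            raise ValueError(f"unknown scaffold: {scaffold!r}")
        if not 1 <= position <= self.scaffold_lengths[scaffold]:
            raise ValueError(
                f"position {position} outside {scaffold} "
                f"(length {self.scaffold_lengths[scaffold]})")
        if self.has_subfeatures and _covered(
                self.exon.get(scaffold, []), position):
            return EXON
        if _covered(self.genic.get(scaffold, []), position):
            return INTRON if self.has_subfeatures else GENIC
        return INTERGENIC


def _covered(intervals: list[tuple[int, int]], position: int) -> bool:
    if not intervals:
        return False
    starts = np.array([s for s, _ in intervals])
    i = int(np.searchsorted(starts, position, side="right")) - 1
    return i >= 0 and intervals[i][1] >= position


def partition_genome(
    annotation: list[tuple[str, int, int, str]] | str | Path,
    scaffold_lengths: dict[str, int],
) -> GenomePartition:
    """Build the labeled partition from gene (and exon) intervals.

    ``annotation`` is either a list of (scaffold, start, end, feature_type)
    with 1-based closed coordinates, or a GFF3 path.  Overlapping gene
    intervals are unioned.  Exon/intron sub-labels are produced only when
    exon features are present.
    """
    if isinstance(annotation, (str, Path)):
        annotation = read_gff3(annotation)
    genes: dict[str, list[tuple[int, int]]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    for scaffold, start, end, ftype in annotation:
        if scaffold not in scaffold_lengths:
            raise ValueError(
                f"annotation interval on unknown scaffold {scaffold!r}: "
                f"{scaffold}:{start}-{end}")
        if start < 1 or end > scaffold_lengths[scaffold] or start > end:
            raise ValueError(
                f"annotation interval out of bounds: {scaffold}:{start}-{end}"
                f" (scaffold length {scaffold_lengths[scaffold]})")
        if ftype in ("gene", "mRNA"):
            genes.setdefault(scaffold, []).append((start, end))
        elif ftype == "exon":
            exons.setdefault(scaffold, []).append((start, end))
    genic = {sc: _merge(ivs) for sc, ivs in genes.items()}
    if exons:
        # exons count as genic even without an enclosing gene record
        for sc, ivs in exons.items():
            genic[sc] = _merge(genic.get(sc, []) + ivs)
        exon_merged = {sc: _merge(ivs) for sc, ivs in exons.items()}
        return GenomePartition(scaffold_lengths, genic, exon_merged)
    return GenomePartition(scaffold_lengths, genic)


def read_gff3(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Gene/mRNA/exon intervals from a GFF3 file (via gffutils)."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True,
                            merge_strategy="create_unique")
    out = []
    for ftype in ("gene", "mRNA", "exon"):
        for feat in db.features_of_type(ftype):
            out.append((feat.seqid, feat.start, feat.end, ftype))
    return out


def enrichment(
    recombinant_reads: list[tuple[str, int, int]] | pd.DataFrame,
    partition: GenomePartition,
) -> pd.DataFrame:
    """The region table: genome share, recombinant share and fold per label.

    ``recombinant_reads`` holds (scaffold, start, end) alignment spans of
    recombinant-classified reads (1-based inclusive); each read counts at
    the label of its alignment midpoint.  fold_enrichment =
    recombinant_pct / genome_pct.
    """
    if isinstance(recombinant_reads, pd.DataFrame):
        spans = list(recombinant_reads[["scaffold", "start", "end"]]
                     .itertuples(index=False, name=None))
    else:
        spans = [(sc, int(s), int(e)) for sc, s, e in recombinant_reads]
    counts = dict.fromkeys(partition.labels, 0)
    for scaffold, start, end in spans:
        mid = (start + end) // 2
        counts[partition.label_at(scaffold, mid)] += 1
    genome_bp = partition.genome_bp()
    total_bp = sum(genome_bp.values())
    total_reads = sum(counts.values())
    rows = []
    for label in partition.labels:
        g_pct = 100.0 * genome_bp[label] / total_bp
        r_pct = (100.0 * counts[label] / total_reads
                 if total_reads else float("nan"))
        fold = r_pct / g_pct if g_pct > 0 else float("nan")
        rows.append({"region": label, "genome_bp": genome_bp[label],
                     "genome_pct": g_pct, "recombinant_count": counts[label],
                     "recombinant_pct": r_pct, "fold_enrichment": fold})
    return pd.DataFrame(rows)
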