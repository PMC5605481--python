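"""Read-backed haplotype windows and parental/recombinant classification.

Each aligned read is reduced to the alleles it carries at called
heterozygous SNPs.  Reads phased by at least five heterozygous SNPs
contribute a 5-character allele string to a haplotype window keyed by
those five SNP positions.  Within a window the universe of strings is
2^5 = 32; the two most frequent are designated parental and the up to 30
others recombinant.  A recombinant string observed in the heterokaryon is
discarded when the same window in either parental homokaryon contains the
identical string as a recombinant there — such strings reflect
duplication or mapping artifacts rather than meiotic-like exchange.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from recombiscan.snps import HetSNP

WindowKey = tuple  # (scaffold, pos1, ..., posk)

PARENTAL = "parental"
RECOMBINANT = "recombinant"


class SnpIndex:
    """Per-scaffold sorted lookup over a sample's called heterozygous SNPs."""

    def __init__(self, snps: list[HetSNP]):
        by_scaffold: dict[str, list[HetSNP]] = {}
        for s in snps:
            by_scaffold.setdefault(s.scaffold, []).append(s)
        self.positions: dict[str, np.ndarray] = {}
        self.alleles: dict[str, list[tuple[str, str]]] = {}
        for scaffold, group in by_scaffold.items():
            group.sort(key=lambda s: s.position)
            self.positions[scaffold] = np.array(
                [s.position for s in group], dtype=int)
            self.alleles[scaffold] = [s.alleles for s in group]

    @property
    def scaffolds(self) -> set[str]:
        return set(self.positions)


@dataclass(frozen=True)
class ReadAlleleVector:
    """The ordered alleles one read carries at heterozygous SNPs.

    ``sites`` holds (snp_index within the scaffold's sorted SNP list,
    1-based position, observed base); indices are strictly increasing.
    """

    read_id: str
    scaffold: str
    sites: tuple[tuple[int, int, str], ...]
    ref_start: int = 0  # 1-based alignment span, for region assignment
    ref_end: int = 0

    @property
    def n_phased(self) -> int:
        return len(self.sites)


@dataclass
class HaplotypeWindow:
    """Observed allele-string spectrum over k consecutive het SNPs."""

    scaffold: str
    positions: tuple[int, ...]
    spectrum: Counter = field(default_factory=Counter)

    @property
    def key(self) -> WindowKey:
        return (self.scaffold, *self.positions)


@dataclass(frozen=True)
class WindowClassification:
    parental: tuple[str, ...]
    recombinant: tuple[str, ...]


@dataclass(frozen=True)
class ReadWindowRecord:
    read_id: str
    key: WindowKey
    string: str


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample phased-read bookkeeping (one row pair of the summary
    table: counts and 2-decimal percentages of non-recombinant vs
    recombinant reads)."""

    label: str
    nonrecombinant_reads: int
    recombinant_reads: int

    @property
    def total_reads(self) -> int:
        return self.nonrecombinant_reads + self.recombinant_reads

    @property
    def nonrecombinant_pct(self) -> float | None:
        return _pct(self.nonrecombinant_reads, self.total_reads)

    @property
    def recombinant_pct(self) -> float | None:
        return _pct(self.recombinant_reads, self.total_reads)


def _pct(count: int, total: int) -> float | None:
    """Percentage rounded half-up to 2 decimals; None on an empty sample."""
    if total == 0:
        return None
    q = (Decimal(count) * 100 / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(q)


# ---------------------------------------------------------------------------
# per-read allele extraction


def extract_read_alleles(
    read: pysam.AlignedSegment,
    index: SnpIndex,
    strict: bool = False,
) -> ReadAlleleVector | None:
    """Record the base a read carries at every het SNP it overlaps.

    Positions under clips or deletions are omitted, as are N calls.  A base
    matching neither of a site's two called alleles drops that site from
    the vector (sequencing-error tolerance); with ``strict=True`` the whole
    read is discarded (returns None).
    """
    scaffold = read.reference_name
    positions = index.positions.get(scaffold)
    if positions is None or len(positions) == 0:
        return ReadAlleleVector(read.query_name, scaffold, (),
                                read.reference_start + 1, read.reference_end)
    lo = np.searchsorted(positions, read.reference_start + 1, side="left")
    hi = np.searchsorted(positions, read.reference_end, side="right")
    if hi <= lo:
        return ReadAlleleVector(read.query_name, scaffold, (),
                                read.reference_start + 1, read.reference_end)
    ref_to_query = {rpos: qpos for qpos, rpos
                    in read.get_aligned_pairs(matches_only=True)}
    seq = read.query_sequence
    alleles = index.alleles[scaffold]
    sites: list[tuple[int, int, str]] = []
    for i in range(lo, hi):
        pos = int(positions[i])
        qpos = ref_to_query.get(pos - 1)
        if qpos is None:
            continue
        base = seq[qpos].upper()
        if base not in "ACGT":
            continue
        if base not in alleles[i]:
            if strict:
                return None
            continue
        sites.append((i, pos, base))
    return ReadAlleleVector(read.query_name, scaffold, tuple(sites),
                            read.reference_start + 1, read.reference_end)


def extract_sample_alleles(
    alignments: str | Path | pysam.AlignmentFile,
    het_snps: list[HetSNP],
    mapq_min: int = 10,
    strict: bool = False,
) -> list[ReadAlleleVector]:
    """Allele vectors for every primary MAPQ-passing read of a sample."""
    own = not isinstance(alignments, pysam.AlignmentFile)
    af = pysam.AlignmentFile(str(alignments)) if own else alignments
    try:
        sam_refs = set(af.references)
        snp_refs = {s.scaffold for s in het_snps}
        unknown = snp_refs - sam_refs
        if unknown:
            raise ValueError(
                "SNP scaffolds absent from the alignment header "
                f"(coordinate-system mismatch): {sorted(unknown)[:5]}")
        index = SnpIndex(het_snps)
        vectors: list[ReadAlleleVector] = []
        for read in af.fetch(until_eof=True):
            if (read.is_unmapped or read.is_secondary
                    or read.is_supplementary or read.is_duplicate):
                continue
            if read.mapping_quality < mapq_min:
                continue
            vec = extract_read_alleles(read, index, strict=strict)
            if vec is not None:
                vectors.append(vec)
        return vectors
    finally:
        if own:
            af.close()


# ---------------------------------------------------------------------------
# windows


@dataclass
class PhasedSample:
    """All haplotype windows of one sample plus per-read contributions."""

    k: int
    policy: str
    windows: dict[WindowKey, HaplotypeWindow] = field(default_factory=dict)
    records: list[ReadWindowRecord] = field(default_factory=list)
    read_spans: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def classify(self) -> dict[WindowKey, WindowClassification]:
        return {key: classify_window(w) for key, w in self.windows.items()}

    def read_labels(self) -> dict[str, str]:
        """Per-read class: recombinant if any of its window strings is
        recombinant (relevant under the sliding policy; under leading each
        read has exactly one window)."""
        classes = self.classify()
        labels: dict[str, str] = {}
        for rec in self.records:
            cls = classes[rec.key]
            lab = (RECOMBINANT if rec.string in cls.recombinant
                   else PARENTAL)
            if labels.get(rec.read_id) != RECOMBINANT:
                labels[rec.read_id] = lab
        return labels

    def recombinant_reads(self) -> list[tuple[str, str, int, int]]:
        """(read_id, scaffold, start, end) of recombinant-classified reads."""
        return [(rid, *self.read_spans[rid])
                for rid, lab in self.read_labels().items()
                if lab == RECOMBINANT]


def build_windows(
    vectors: list[ReadAlleleVector],
    k: int = 5,
    policy: str = "leading",
) -> PhasedSample:
    """Aggregate reads phased by >= k het SNPs into haplotype windows.

    ``leading`` (default): each qualifying read contributes one string
    over its first k phased sites, keeping read counts additive.
    ``sliding``: each read contributes every run of k consecutive phased
    sites; per-read classification is then "recombinant if any window says
    so" and each read still counts once in summaries.
    """
    if k < 2:
        raise ValueError(f"window size k must be >= 2, got {k}")
    if policy not in ("leading", "sliding"):
        raise ValueError(f"unknown window policy: {policy!r}")
    phased = PhasedSample(k=k, policy=policy)
    for vec in vectors:
        if vec.n_phased < k:
            continue
        runs = ([vec.sites[:k]] if policy == "leading"
                else [vec.sites[i:i + k]
                      for i in range(vec.n_phased - k + 1)])
        phased.read_spans[vec.read_id] = (
            vec.scaffold, vec.ref_start, vec.ref_end)
        for run in runs:
            positions = tuple(pos for _, pos, _ in run)
            string = "".join(base for _, _, base in run)
            key = (vec.scaffold, *positions)
            window = phased.windows.get(key)
            if window is None:
                window = HaplotypeWindow(vec.scaffold, positions)
                phased.windows[key] = window
            window.spectrum[string] += 1
            phased.records.append(ReadWindowRecord(vec.read_id, key, string))
    return phased


def classify_window(window: HaplotypeWindow) -> WindowClassification:
    """Designate the two most frequent strings parental, the rest
    recombinant.  Ties at the parental cut break lexicographically; a
    window with a single observed string has one parental and no
    recombinants."""
    ranked = sorted(window.spectrum.items(), key=lambda kv: (-kv[1], kv[0]))
    parental = tuple(s for s, _ in ranked[:2])
    recombinant = tuple(s for s, _ in ranked[2:])
    return WindowClassification(parental=parental, recombinant=recombinant)


# ---------------------------------------------------------------------------
# cross-sample haplotype filter


def filter_shared_recombinants(
    het: PhasedSample,
    hom1: PhasedSample,
    hom2: PhasedSample,
) -> tuple[PhasedSample, list[tuple[WindowKey, str]]]:
    """Drop heterokaryon recombinant strings shared with a homokaryon.

    A heterokaryon recombinant string is excluded iff a window with the
    identical scaffold and identical k SNP positions exists in either
    homokaryon and contains the identical string classified recombinant
    there.  Excluded strings' reads are removed entirely (from recombinant
    and total counts alike); parental strings are never removed.
    Heterokaryon windows with no same-positioned homokaryon window are
    retained unfiltered.

    Returns the filtered sample and the list of excluded (window key,
    string) pairs.
    """
    for other in (hom1, hom2):
        if other.k != het.k:
            raise ValueError(
                f"window size mismatch: heterokaryon k={het.k}, "
                f"homokaryon k={other.k}")
    shared: set[tuple[WindowKey, str]] = set()
    for hom in (hom1, hom2):
        for key, cls in hom.classify().items():
            for s in cls.recombinant:
                shared.add((key, s))
    het_classes = het.classify()
    excluded: list[tuple[WindowKey, str]] = []
    for key, cls in het_classes.items():
        for s in cls.recombinant:
            if (key, s) in shared:
                excluded.append((key, s))
    excluded_set = set(excluded)
    dropped_reads = {rec.read_id for rec in het.records
                     if (rec.key, rec.string) in excluded_set}
    kept_records = [rec for rec in het.records
                    if rec.read_id not in dropped_reads]
    filtered = PhasedSample(k=het.k, policy=het.policy)
    for rec in kept_records:
        window = filtered.windows.get(rec.key)
        if window is None:
            src = het.windows[rec.key]
            window = HaplotypeWindow(src.scaffold, src.positions)
            filtered.windows[rec.key] = window
        window.spectrum[rec.string] += 1
        filtered.records.append(rec)
    filtered.read_spans = {rid: span for rid, span in het.read_spans.items()
                           if rid not in dropped_reads}
    return filtered, excluded


# ---------------------------------------------------------------------------
# summaries


def summarize_counts(nonrecombinant_reads: int, recombinant_reads: int,
                     label: str = "sample") -> SampleSummary:
    """Summary-row arithmetic from already-aggregated read counts."""
    if nonrecombinant_reads < 0 or recombinant_reads < 0:
        raise ValueError("read counts must be non-negative")
    return SampleSummary(label=label,
                         nonrecombinant_reads=nonrecombinant_reads,
                         recombinant_reads=recombinant_reads)


def summarize_sample(phased: PhasedSample,
                     label: str = "sample") -> SampleSummary:
    """Aggregate per-read classifications into the summary-table row pair."""
    labels = phased.read_labels()
    rec = sum(1 for v in labels.values() if v == RECOMBINANT)
    return summarize_counts(len(labels) - rec, rec, label=label)


# ---------------------------------------------------------------------------
# serialization


def windows_to_frame(phased: PhasedSample) -> pd.DataFrame:
    classes = phased.classify()
    rows = []
    for key, window in sorted(phased.windows.items()):
        cls = classes[key]
        for string, count in sorted(window.spectrum.items()):
            rows.append({
                "scaffold": window.scaffold,
                **{f"pos{i + 1}": p for i, p in enumerate(window.positions)},
                "haplotype": string, "reads": count,
                "class": (PARENTAL if string in cls.parental
                          else RECOMBINANT)})
    cols = (["scaffold"] + [f"pos{i + 1}" for i in range(phased.k)]
            + ["haplotype", "reads", "class"])
    return pd.DataFrame(rows, columns=cols)


def reads_to_frame(phased: PhasedSample) -> pd.DataFrame:
    classes = phased.classify()
    rows = []
    for rec in phased.records:
        cls = classes[rec.key]
        rows.append({
            "read_id": rec.read_id,
            "window": "{}:{}".format(rec.key[0],
                                     "-".join(str(p) for p in rec.key[1:])),
            "haplotype": rec.string,
            "class": (PARENTAL if rec.string in cls.parental
                      else RECOMBINANT)})
    return pd.DataFrame(rows, columns=["read_id", "window", "haplotype",
                                       "class"])


def read_windows_tsv(path: str | Path) -> PhasedSample:
    """Rebuild a sample's windows (spectra only, no per-read records) from
    a windows TSV, e.g. to filter another sample against it."""
    df = pd.read_csv(path, sep="\t")
    pos_cols = [c for c in df.columns
                if c.startswith("pos") and c[3:].isdigit()]
    phased = PhasedSample(k=len(pos_cols), policy="leading")
    for row in df.itertuples():
        positions = tuple(int(getattr(row, c)) for c in pos_cols)
        key = (row.scaffold, *positions)
        window = phased.windows.get(key)
        if window is None:
            window = HaplotypeWindow(str(row.scaffold), positions)
            phased.windows[key] = window
        window.spectrum[str(row.haplotype)] += int(row.reads)
    return phased


def summary_to_frame(summary: SampleSummary) -> pd.DataFrame:
    return pd.DataFrame([
        {"sample": summary.label, "class": "non_recombinant",
         "reads": summary.nonrecombinant_reads,
         "pct": summary.nonrecombinant_pct},
        {"sample": summary.label, "class": "recombinant",
         "reads": summary.recombinant_reads, "pct": summary.recombinant_pct},
        {"sample": summary.label, "class": "total",
         "reads": summary.total_reads,
         "pct": None if summary.total_reads == 0 else 100.0},
    ])
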