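"""Synthetic heterokaryon sequencing data with full ground truth.

The generator emulates the statistical structure the recombination pipeline
assumes: a draft-genome reference split into scaffolds, two parental nuclear
haplotypes differing at clustered heterozygous SNPs (~1 per kb overall, but
locally dense — real fungal heterozygosity comes in tight clusters, which is
what makes 5-SNP read-backed windows observable at 250 bp read length),
a pool of source molecules of which a configurable fraction are
single-crossover recombinants, and error-bearing aligned reads at ~30-43x
depth with a stated fraction of low-MAPQ alignments.

Every stage records ground truth (SNP table, per-molecule breakpoints,
per-read source labels) so downstream calls can be checked read-by-read.
All outputs are deterministic functions of :class:`SimConfig`, including
its ``seed``.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)

PARENTAL1 = "parental1"
PARENTAL2 = "parental2"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated sample.

    Defaults mirror the sequencing design the pipeline targets: 250 bp
    reads at ~35x depth over a genome with ~1 heterozygous SNP per kb and
    a 5% recombinant molecule fraction.
    """

    n_scaffolds: int = 1
    scaffold_length: int = 100_000
    snp_rate: float = 1e-3
    recomb_fraction: float = 0.05
    read_length: int = 250
    mean_depth: float = 35.0
    error_rate: float = 0.001
    seed: int = 0
    genic_fraction: float = 0.4
    mapq_low_fraction: float = 0.05
    snp_cluster_size: int = 6
    n_molecules: int = 200

    def __post_init__(self) -> None:
        for name in ("snp_rate", "recomb_fraction", "error_rate",
                     "genic_fraction", "mapq_low_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_scaffolds < 1:
            raise ValueError(f"n_scaffolds must be >= 1, got {self.n_scaffolds}")
        if self.scaffold_length < 1:
            raise ValueError(
                f"scaffold_length must be >= 1, got {self.scaffold_length}")
        if self.read_length < 1:
            raise ValueError(f"read_length must be >= 1, got {self.read_length}")
        if self.scaffold_length < self.read_length:
            raise ValueError(
                f"scaffold_length ({self.scaffold_length}) must be >= "
                f"read_length ({self.read_length})")
        if self.mean_depth <= 0:
            raise ValueError(f"mean_depth must be > 0, got {self.mean_depth}")
        if self.snp_cluster_size < 1:
            raise ValueError(
                f"snp_cluster_size must be >= 1, got {self.snp_cluster_size}")
        if self.n_molecules < 1:
            raise ValueError(f"n_molecules must be >= 1, got {self.n_molecules}")
        if 0 < self.snp_rate * self.scaffold_length < 5:
            warnings.warn(
                "expected SNP count per scaffold is below 5; "
                "5-SNP haplotype windows will be impossible", stacklevel=2)


@dataclass(frozen=True)
class Molecule:
    """A source molecule reads are drawn from.

    A molecule is a (possibly segment-restricted) copy of one parental
    haplotype, or a single-crossover mosaic of the two.  ``breakpoint`` is
    the 1-based position of the last base taken from ``orientation[0]``;
    the crossover junction therefore lies strictly between ``breakpoint``
    and ``breakpoint + 1``, i.e. strictly between two adjacent SNPs when
    drawn by :func:`simulate_recombinant_pool`.
    """

    molecule_id: str
    scaffold: str
    label: str  # "parental1" | "parental2" | "recombinant-<k>"
    breakpoint: int | None = None
    orientation: tuple[str, str] = (PARENTAL1, PARENTAL2)
    start: int = 1          # 1-based inclusive extent on the scaffold
    end: int | None = None  # None = scaffold end

    @property
    def is_recombinant(self) -> bool:
        return self.breakpoint is not None


@dataclass(frozen=True)
class SimRead:
    read_id: str
    scaffold: str
    start: int  # 1-based leftmost aligned position
    sequence: str
    mapq: int
    molecule_id: str
    label: str
    breakpoint: int | None


@dataclass
class TruthSet:
    """Ground truth for one simulated sample."""

    config: SimConfig
    sample_name: str
    references: dict[str, str]
    annotation: list[tuple[str, int, int, str]]  # (scaffold, start, end, label)
    haplotypes: dict[str, tuple[str, str]]       # scaffold -> (parental1, parental2)
    snp_table: pd.DataFrame                      # scaffold, pos, allele1, allele2
    molecules: list[Molecule] = field(default_factory=list)
    reads: list[SimRead] = field(default_factory=list)

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.references.items()}

    def snp_positions(self, scaffold: str) -> np.ndarray:
        sub = self.snp_table[self.snp_table["scaffold"] == scaffold]
        return sub["pos"].to_numpy()

    def molecule_by_id(self, molecule_id: str) -> Molecule:
        return {m.molecule_id: m for m in self.molecules}[molecule_id]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA / GFF3 / SAM / FASTQ / truth TSVs; return the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        name = self.sample_name
        paths = {
            "fasta": outdir / "reference.fa",
            "gff3": outdir / "annotation.gff3",
            "sam": outdir / f"{name}.sam",
            "fastq": outdir / f"{name}.fastq",
            "snps": outdir / "truth_snps.tsv",
            "reads": outdir / f"{name}.truth_reads.tsv",
            "molecules": outdir / f"{name}.truth_molecules.tsv",
        }
        write_fasta(self.references, paths["fasta"])
        write_gff3(self.annotation, self.scaffold_lengths, paths["gff3"])
        write_sam(self.reads, self.scaffold_lengths, paths["sam"])
        write_fastq(self.reads, paths["fastq"])
        self.snp_table.to_csv(paths["snps"], sep="\t", index=False)
        pd.DataFrame(
            [{"read_id": r.read_id, "scaffold": r.scaffold, "start": r.start,
              "mapq": r.mapq, "molecule_id": r.molecule_id, "label": r.label,
              "breakpoint": "" if r.breakpoint is None else r.breakpoint}
             for r in self.reads]
        ).to_csv(paths["reads"], sep="\t", index=False)
        pd.DataFrame(
            [{"molecule_id": m.molecule_id, "scaffold": m.scaffold,
              "label": m.label,
              "breakpoint": "" if m.breakpoint is None else m.breakpoint,
              "hap_a": m.orientation[0], "hap_b": m.orientation[1],
              "start": m.start, "end": m.end if m.end is not None else ""}
             for m in self.molecules]
        ).to_csv(paths["molecules"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# stage 1: reference + annotation


def _tile_intervals(length: int, fraction: float,
                    block: int) -> list[tuple[int, int]]:
    """Deterministic 1-based closed intervals covering ~fraction of length.

    Blocks of size ``block`` are placed at the head of periods of size
    ``block / fraction``, so the covered share equals ``fraction`` up to one
    block's granularity.
    """
    if fraction <= 0 or length <= 0:
        return []
    if fraction >= 1:
        return [(1, length)]
    block = min(block, length)
    period = max(int(round(block / fraction)), block)
    out = []
    start = 1
    while start <= length:
        end = min(start + block - 1, length)
        out.append((start, end))
        start += period
    return out


def simulate_reference(
    config: SimConfig, rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], list[tuple[str, int, int, str]]]:
    """Random uppercase A/C/G/T scaffolds plus a genic/intergenic partition.

    The annotation tiles each scaffold with fixed-size gene blocks so that
    the genic share matches ``config.genic_fraction`` up to one block.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    references: dict[str, str] = {}
    annotation: list[tuple[str, int, int, str]] = []
    gene_block = min(2000, config.scaffold_length)
    for i in range(config.n_scaffolds):
        name = f"scaffold_{i + 1}"
        seq = _BASE_ARR[rng.integers(0, 4, size=config.scaffold_length)]
        references[name] = seq.tobytes().decode()
        for start, end in _tile_intervals(
                config.scaffold_length, config.genic_fraction, gene_block):
            annotation.append((name, start, end, "gene"))
    return references, annotation


# ---------------------------------------------------------------------------
# stage 2: parental haplotypes


def _place_clustered_snps(length: int, n: int, cluster_size: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Place n SNP positions (1-based) in clusters with 2-12 bp gaps."""
    chosen: set[int] = set()
    while len(chosen) < n:
        m = min(cluster_size, n - len(chosen))
        gaps = rng.integers(2, 13, size=m - 1) if m > 1 else np.array([], int)
        span = int(gaps.sum())
        if span >= length:
            m, gaps, span = 1, np.array([], int), 0
        start = int(rng.integers(1, length - span + 1))
        pos = start + np.concatenate(([0], np.cumsum(gaps)))
        chosen.update(int(p) for p in pos)
    out = np.array(sorted(chosen), dtype=int)
    return out[:n] if len(out) > n else out


def simulate_haplotypes(
    references: dict[str, str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[str, str]]]:
    """Derive the two parental haplotypes and the ground-truth SNP table.

    Parental 1 is the reference itself; parental 2 differs at SNP positions
    only.  The SNP count per scaffold is Binomial(length, snp_rate);
    positions are placed in clusters of ``snp_cluster_size`` because
    observed fungal heterozygosity is locally dense, which is what makes
    5-SNP windows coverable by a single read.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows = []
    haplotypes: dict[str, tuple[str, str]] = {}
    for name, ref in references.items():
        n = int(rng.binomial(len(ref), config.snp_rate))
        positions = _place_clustered_snps(
            len(ref), n, config.snp_cluster_size, rng)
        hap2 = bytearray(ref, "ascii")
        for pos in positions:
            ref_base = ref[pos - 1]
            alts = [b for b in BASES if b != ref_base]
            alt = alts[int(rng.integers(0, 3))]
            hap2[pos - 1] = ord(alt)
            rows.append({"scaffold": name, "pos": int(pos),
                         "allele1": ref_base, "allele2": alt})
        haplotypes[name] = (ref, hap2.decode())
    snp_table = pd.DataFrame(
        rows, columns=["scaffold", "pos", "allele1", "allele2"])
    snp_table = snp_table.sort_values(["scaffold", "pos"]).reset_index(drop=True)
    return snp_table, haplotypes


# ---------------------------------------------------------------------------
# stage 3: molecule pool


def draw_breakpoint(snp_positions: np.ndarray,
                    rng: np.random.Generator) -> int:
    """A crossover cut uniform over inter-SNP intervals.

    Picks one of the n-1 intervals between adjacent SNPs uniformly, then a
    cut position uniformly within it.  The returned value is the 1-based
    last position taken from the left haplotype; it satisfies
    ``pos[i] <= cut < pos[i+1]`` so the junction falls strictly between
    the two SNP positions.
    """
    if len(snp_positions) < 2:
        raise ValueError("need at least 2 SNPs on a scaffold for a crossover")
    i = int(rng.integers(0, len(snp_positions) - 1))
    lo, hi = int(snp_positions[i]), int(snp_positions[i + 1])
    return int(rng.integers(lo, hi))


def make_recombinant(truth: TruthSet, scaffold: str, interval_index: int,
                     molecule_id: str = "inject",
                     orientation: tuple[str, str] = (PARENTAL1, PARENTAL2),
                     start: int = 1, end: int | None = None) -> Molecule:
    """A recombinant molecule with its cut midway between SNPs
    ``interval_index`` and ``interval_index + 1`` (deterministic helper for
    constructing shared/unique recombinants across samples)."""
    pos = truth.snp_positions(scaffold)
    lo, hi = int(pos[interval_index]), int(pos[interval_index + 1])
    cut = (lo + hi) // 2
    return Molecule(molecule_id=molecule_id, scaffold=scaffold,
                    label=f"recombinant-{molecule_id}", breakpoint=cut,
                    orientation=orientation, start=start, end=end)


def simulate_recombinant_pool(
    truth: TruthSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    inject: list[Molecule] | None = None,
    recomb_fraction: float | None = None,
) -> list[Molecule]:
    """Build the per-scaffold molecule pool.

    Each of ``n_molecules`` molecules per scaffold is an independent
    Bernoulli(``recomb_fraction``) recombinant — a single-crossover mosaic
    with its cut uniform over inter-SNP intervals and random orientation —
    while the remainder alternates evenly between the two parentals.
    ``inject`` appends externally constructed molecules (e.g. recombinant
    haplotypes shared with another sample) to the pool.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    frac = config.recomb_fraction if recomb_fraction is None else recomb_fraction
    if not 0.0 <= frac <= 1.0:
        raise ValueError(f"recomb_fraction must be in [0, 1], got {frac}")
    pool: list[Molecule] = []
    k = 0
    for scaffold in truth.references:
        positions = truth.snp_positions(scaffold)
        parity = 0
        for j in range(config.n_molecules):
            mid = f"{scaffold}:mol{j + 1}"
            if frac > 0 and len(positions) >= 2 and rng.random() < frac:
                k += 1
                cut = draw_breakpoint(positions, rng)
                orient = ((PARENTAL1, PARENTAL2) if rng.random() < 0.5
                          else (PARENTAL2, PARENTAL1))
                pool.append(Molecule(mid, scaffold, f"recombinant-{k}",
                                     breakpoint=cut, orientation=orient))
            else:
                label = PARENTAL1 if parity == 0 else PARENTAL2
                parity ^= 1
                pool.append(Molecule(mid, scaffold, label,
                                     orientation=(label, label)))
    if inject:
        for i, mol in enumerate(inject):
            pool.append(dataclasses.replace(
                mol, molecule_id=f"{mol.scaffold}:inject{i + 1}"))
    return pool


def molecule_base_range(molecule: Molecule, haplotypes: dict[str, tuple[str, str]],
                        start0: int, length: int) -> str:
    """Sequence of ``molecule`` over [start0, start0+length) (0-based)."""
    hap1, hap2 = haplotypes[molecule.scaffold]
    by_name = {PARENTAL1: hap1, PARENTAL2: hap2}
    hap_a = by_name[molecule.orientation[0]]
    hap_b = by_name[molecule.orientation[1]]
    if molecule.breakpoint is None:
        return hap_a[start0:start0 + length]
    cut = molecule.breakpoint  # 1-based last base from hap_a == 0-based slice point
    if start0 + length <= cut:
        return hap_a[start0:start0 + length]
    if start0 >= cut:
        return hap_b[start0:start0 + length]
    return hap_a[start0:cut] + hap_b[cut:start0 + length]


# ---------------------------------------------------------------------------
# stage 4: reads


def simulate_reads(
    molecules: list[Molecule],
    truth: TruthSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    sample_name: str = "sample",
) -> list[SimRead]:
    """Draw error-bearing aligned reads from the molecule pool.

    Per scaffold, ``round(mean_depth * L / read_length)`` reads are drawn;
    a molecule is chosen with probability proportional to its eligible
    extent and the read start uniformly within it, so segment molecules
    (duplicated-region copies) add localized coverage the way real
    duplications do.  Substitution errors occur per base at ``error_rate``;
    a fraction ``mapq_low_fraction`` of reads gets MAPQ drawn uniformly
    from 0-9 (exercising the MAPQ<10 filter), the rest MAPQ 60.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rl = config.read_length
    reads: list[SimRead] = []
    by_scaffold: dict[str, list[Molecule]] = {}
    for m in molecules:
        by_scaffold.setdefault(m.scaffold, []).append(m)
    for scaffold, ref in truth.references.items():
        pool = by_scaffold.get(scaffold, [])
        if not pool:
            continue
        L = len(ref)
        if L < rl:
            raise ValueError(
                f"read_length {rl} exceeds scaffold {scaffold} length {L}")
        # eligible start range per molecule (0-based starts)
        lo = np.array([m.start - 1 for m in pool])
        hi = np.array([(m.end if m.end is not None else L) - rl for m in pool])
        weights = np.maximum(hi - lo + 1, 0).astype(float)
        if weights.sum() == 0:
            raise ValueError(
                f"no molecule on {scaffold} is long enough for {rl} bp reads")
        n_reads = int(round(config.mean_depth * L / rl))
        picks = rng.choice(len(pool), size=n_reads, p=weights / weights.sum())
        offsets = rng.random(n_reads)
        mapq_low = rng.random(n_reads) < config.mapq_low_fraction
        low_vals = rng.integers(0, 10, size=n_reads)
        for i in range(n_reads):
            m = pool[picks[i]]
            start0 = int(lo[picks[i]] + offsets[i] * (hi[picks[i]] - lo[picks[i]] + 1))
            seq = molecule_base_range(m, truth.haplotypes, start0, rl)
            if config.error_rate > 0:
                err = np.flatnonzero(rng.random(rl) < config.error_rate)
                if len(err):
                    b = bytearray(seq, "ascii")
                    for p in err:
                        cur = BASES.index(chr(b[p]))
                        b[p] = ord(BASES[(cur + int(rng.integers(1, 4))) % 4])
                    seq = b.decode()
            mapq = int(low_vals[i]) if mapq_low[i] else 60
            reads.append(SimRead(
                read_id=f"{sample_name}:{scaffold}:{i + 1}",
                scaffold=scaffold, start=start0 + 1, sequence=seq,
                mapq=mapq, molecule_id=m.molecule_id, label=m.label,
                breakpoint=m.breakpoint))
    return reads


# ---------------------------------------------------------------------------
# convenience drivers


def simulate_sample(
    config: SimConfig,
    inject: list[Molecule] | None = None,
    sample_name: str = "sample",
    outdir: str | Path | None = None,
) -> TruthSet:
    """Run all generator stages for one (heterokaryon-like) sample."""
    rng = np.random.default_rng(config.seed)
    references, annotation = simulate_reference(config, rng)
    snp_table, haplotypes = simulate_haplotypes(references, config, rng)
    truth = TruthSet(config=config, sample_name=sample_name,
                     references=references, annotation=annotation,
                     haplotypes=haplotypes, snp_table=snp_table)
    truth.molecules = simulate_recombinant_pool(truth, config, rng, inject)
    truth.reads = simulate_reads(truth.molecules, truth, config, rng,
                                 sample_name)
    if outdir is not None:
        truth.write(outdir)
    return truth


def _homokaryon_pool(truth: TruthSet, config: SimConfig, own: str,
                     blocks: dict[str, list[tuple[int, int]]],
                     minor_fraction: float,
                     inject: list[Molecule] | None) -> list[Molecule]:
    """Pool for a homokaryon-like sample: pure own-parental molecules plus,
    inside 'duplicated' blocks, segment molecules of the other parental at a
    coverage share of ``minor_fraction`` (emulating the duplication-driven
    apparent heterozygosity of real homokaryon samples)."""
    other = PARENTAL2 if own == PARENTAL1 else PARENTAL1
    pool: list[Molecule] = []
    for scaffold in truth.references:
        for j in range(config.n_molecules):
            pool.append(Molecule(f"{scaffold}:mol{j + 1}", scaffold, own,
                                 orientation=(own, own)))
        n_seg = int(round(config.n_molecules * minor_fraction
                          / max(1.0 - minor_fraction, 1e-9)))
        for bi, (bs, be) in enumerate(blocks.get(scaffold, [])):
            if be - bs + 1 < config.read_length:
                continue
            for j in range(n_seg):
                pool.append(Molecule(
                    f"{scaffold}:dup{bi + 1}.{j + 1}", scaffold, other,
                    orientation=(other, other), start=bs, end=be))
    if inject:
        for i, mol in enumerate(inject):
            pool.append(dataclasses.replace(
                mol, molecule_id=f"{mol.scaffold}:inject{i + 1}"))
    return pool


@dataclass
class TrioResult:
    het: TruthSet
    hom1: TruthSet
    hom2: TruthSet
    blocks: dict[str, list[tuple[int, int]]]

    def __getitem__(self, name: str) -> TruthSet:
        return {"het": self.het, "hom1": self.hom1, "hom2": self.hom2}[name]


def simulate_trio(
    config: SimConfig,
    hom_het_fraction: float = 0.3,
    hom_block: int = 5000,
    hom_minor_fraction: float = 0.5,
    inject_het: list[Molecule] | None = None,
    inject_hom1: list[Molecule] | None = None,
    inject_hom2: list[Molecule] | None = None,
    inject_builder=None,
    outdir: str | Path | None = None,
) -> TrioResult:
    """Simulate a heterokaryon and its two parental homokaryons.

    All three samples share the reference, haplotypes and SNP ground truth.
    The heterokaryon draws from a balanced two-parental pool with
    ``config.recomb_fraction`` recombinant molecules.  Each homokaryon is
    pure own-parental except inside deterministic 'duplicated' blocks
    covering ``hom_het_fraction`` of each scaffold, where other-parental
    segment molecules are mixed in at coverage share ``hom_minor_fraction``
    (0.5 makes those positions pass the het-SNP balance rule, emulating the
    duplication-driven apparent heterozygosity of real homokaryons).

    ``inject_*`` append recombinant molecules to a sample's pool, e.g. a
    haplotype shared between the heterokaryon and a homokaryon.  When the
    molecules must be chosen relative to the generated SNP table,
    ``inject_builder(truth, blocks)`` is called after haplotype generation
    and must return three lists (het, hom1, hom2) that are appended to any
    directly passed ones.
    """
    ss = np.random.SeedSequence(config.seed)
    child = [np.random.default_rng(s) for s in ss.spawn(4)]
    references, annotation = simulate_reference(config, child[0])
    snp_table, haplotypes = simulate_haplotypes(references, config, child[0])
    blocks = homokaryon_blocks(config, hom_het_fraction, hom_block,
                               references)
    base = TruthSet(config=config, sample_name="truth",
                    references=references, annotation=annotation,
                    haplotypes=haplotypes, snp_table=snp_table)
    injections = {"het": list(inject_het or []),
                  "hom1": list(inject_hom1 or []),
                  "hom2": list(inject_hom2 or [])}
    if inject_builder is not None:
        extra_het, extra_hom1, extra_hom2 = inject_builder(base, blocks)
        injections["het"] += extra_het
        injections["hom1"] += extra_hom1
        injections["hom2"] += extra_hom2
    out: dict[str, TruthSet] = {}
    specs = [
        ("het", None, child[1]),
        ("hom1", PARENTAL1, child[2]),
        ("hom2", PARENTAL2, child[3]),
    ]
    for name, own, rng in specs:
        truth = TruthSet(config=config, sample_name=name,
                         references=references, annotation=annotation,
                         haplotypes=haplotypes, snp_table=snp_table)
        inject = injections[name]
        if own is None:
            truth.molecules = simulate_recombinant_pool(
                truth, config, rng, inject)
        else:
            truth.molecules = _homokaryon_pool(
                truth, config, own, blocks, hom_minor_fraction, inject)
        truth.reads = simulate_reads(truth.molecules, truth, config, rng, name)
        if outdir is not None:
            truth.write(Path(outdir) / name)
        out[name] = truth
    return TrioResult(het=out["het"], hom1=out["hom1"], hom2=out["hom2"],
                      blocks=blocks)


def homokaryon_blocks(
    config: SimConfig, hom_het_fraction: float, hom_block: int,
    references: dict[str, str] | None = None,
) -> dict[str, list[tuple[int, int]]]:
    """Deterministic 'duplicated' blocks used by :func:`simulate_trio`."""
    names = (list(references) if references is not None
             else [f"scaffold_{i + 1}" for i in range(config.n_scaffolds)])
    return {name: _tile_intervals(config.scaffold_length, hom_het_fraction,
                                  hom_block)
            for name in names}


def molecule_string_at(molecule: Molecule,
                       haplotypes: dict[str, tuple[str, str]],
                       positions: tuple[int, ...]) -> str:
    """The allele string a molecule carries over the given positions."""
    return "".join(
        molecule_base_range(molecule, haplotypes, p - 1, 1)
        for p in positions)


def _snp_clusters(positions: np.ndarray, max_gap: int = 50,
                  min_size: int = 5) -> list[np.ndarray]:
    """Indices of runs of SNPs separated by at most max_gap bp."""
    if len(positions) == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) > max_gap) + 1
    runs = np.split(np.arange(len(positions)), breaks)
    return [run for run in runs if len(run) >= min_size]


def shared_recombinant_scenario(
    config: SimConfig,
    hom_het_fraction: float = 0.3,
    hom_block: int = 5000,
    weight: int = 30,
    margin: int = 260,
    outdir: str | Path | None = None,
) -> tuple[TrioResult, dict[str, list[Molecule]]]:
    """A trio with one recombination event shared by the heterokaryon and
    homokaryon 1, and one unique to the heterokaryon.

    Each event is injected as a reciprocal crossover pair — ``weight``
    segment-molecule copies split between the two orientation mosaics at
    the same cut — spanning the event's SNP cluster plus ``margin`` bp.
    Reciprocity keeps allele counts balanced at the flanking het SNPs, so
    the injection never perturbs the SNP-calling balance rule, exactly as
    a true crossover would not.  The shared event's cluster lies inside a
    homokaryon 'duplicated' block (so homokaryon 1 observes both parental
    strings there and classifies the injected strings as recombinants);
    the unique event's cluster lies outside every block.  Returns the trio
    and ``{"shared": [mosaic, reciprocal], "unique": [...]}``.
    """
    chosen: dict[str, list[Molecule]] = {}

    def builder(truth: TruthSet, blocks):
        scaffold = next(iter(truth.references))
        positions = truth.snp_positions(scaffold)
        clusters = _snp_clusters(positions)
        scaffold_blocks = blocks.get(scaffold, [])

        def in_block(p1, p5):
            return any(bs + margin <= p1 and p5 <= be - 10
                       for bs, be in scaffold_blocks)

        def outside_blocks(p1, p5):
            return all(be < p1 - margin or bs > p5 + margin
                       for bs, be in scaffold_blocks)

        shared_cluster = unique_cluster = None
        for run in clusters:
            p1, p5 = int(positions[run[0]]), int(positions[run[4]])
            if shared_cluster is None and in_block(p1, p5):
                shared_cluster = run
            elif unique_cluster is None and outside_blocks(p1, p5):
                unique_cluster = run
        if shared_cluster is None or unique_cluster is None:
            raise RuntimeError(
                "no qualifying SNP cluster inside/outside homokaryon blocks "
                "for this seed; use another seed or a longer scaffold")

        def molecules(run, name):
            p1, p5 = int(positions[run[0]]), int(positions[run[4]])
            start = max(1, p1 - margin)
            end = min(len(truth.references[scaffold]), p5 + margin)
            mol = make_recombinant(truth, scaffold,
                                   interval_index=int(run[1]),
                                   molecule_id=name, start=start, end=end)
            rec = dataclasses.replace(
                mol, molecule_id=f"{name}_reciprocal",
                orientation=(PARENTAL2, PARENTAL1))
            chosen[name] = [mol, rec]
            return [mol] * (weight // 2) + [rec] * (weight - weight // 2)

        shared = molecules(shared_cluster, "shared")
        unique = molecules(unique_cluster, "unique")
        return shared + unique, list(shared), []

    trio = simulate_trio(config, hom_het_fraction=hom_het_fraction,
                         hom_block=hom_block, inject_builder=builder,
                         outdir=outdir)
    return trio, chosen


def expected_recombinant(truth: TruthSet, read_id: str,
                         window_positions: tuple[int, ...]) -> bool:
    """Whether a phased read is expected recombinant given ground truth.

    A read carries a recombinant window string iff its source molecule has
    a crossover cut c with at least one window SNP on each side:
    ``positions[0] <= c < positions[-1]``.
    """
    read = next(r for r in truth.reads if r.read_id == read_id)
    if read.breakpoint is None:
        return False
    return window_positions[0] <= read.breakpoint < window_positions[-1]


# ---------------------------------------------------------------------------
# writers


def write_fasta(references: dict[str, str], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in references.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(annotation: list[tuple[str, int, int, str]],
               scaffold_lengths: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in scaffold_lengths.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for i, (scaffold, start, end, label) in enumerate(annotation):
            fh.write("\t".join([
                scaffold, "recombiscan_sim", label, str(start), str(end),
                ".", "+", ".", f"ID={label}{i + 1}"]) + "\n")


def _sam_header(scaffold_lengths: dict[str, int]) -> dict:
    return {"HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": ln} for n, ln in scaffold_lengths.items()]}


def write_sam(reads: list[SimRead], scaffold_lengths: dict[str, int],
              path: str | Path) -> None:
    """Coordinate-sorted SAM with full-match CIGARs and constant base
    qualities (the pipeline never uses base quality)."""
    order = {n: i for i, n in enumerate(scaffold_lengths)}
    reads = sorted(reads, key=lambda r: (order[r.scaffold], r.start, r.read_id))
    header = _sam_header(scaffold_lengths)
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for r in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.read_id
            a.flag = 0
            a.reference_id = order[r.scaffold]
            a.reference_start = r.start - 1
            a.mapping_quality = r.mapq
            a.cigarstring = f"{len(r.sequence)}M"
            a.query_sequence = r.sequence
            a.query_qualities = pysam.qualitystring_to_array(
                "I" * len(r.sequence))
            fh.write(a)


def write_fastq(reads: list[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
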