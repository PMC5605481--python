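import numpy as np
import pysam
import pytest
from hypothesis import settings

from recombiscan.simulate import SimConfig, simulate_sample

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sam_writer():
    """Write a coordinate-sorted SAM from (name, scaffold, start1, seq, mapq)
    tuples with full-match CIGARs."""

    def write(path, scaffold_lengths, reads):
        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": n, "LN": ln}
                         for n, ln in scaffold_lengths.items()]}
        order = {n: i for i, n in enumerate(scaffold_lengths)}
        reads = sorted(reads, key=lambda r: (order[r[1]], r[2]))
        with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
            for name, scaffold, start1, seq, mapq in reads:
                a = pysam.AlignedSegment(fh.header)
                a.query_name = name
                a.flag = 0
                a.reference_id = order[scaffold]
                a.reference_start = start1 - 1
                a.mapping_quality = mapq
                a.cigarstring = f"{len(seq)}M"
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(seq))
                fh.write(a)
        return path

    return write


@pytest.fixture(scope="session")
def clean_sample(tmp_path_factory):
    """Error-free 50 kb heterokaryon-like sample (no low-MAPQ reads):
    every read is an exact slice of a parental or recombinant molecule."""
    cfg = SimConfig(scaffold_length=50_000, seed=101, recomb_fraction=0.05,
                    error_rate=0.0, mapq_low_fraction=0.0)
    outdir = tmp_path_factory.mktemp("clean_sample")
    truth = simulate_sample(cfg, outdir=outdir, sample_name="het")
    return {"truth": truth, "sam": outdir / "het.sam", "outdir": outdir}


@pytest.fixture(scope="session")
def noisy_sample(tmp_path_factory):
    """50 kb sample with sequencing errors and low-MAPQ reads."""
    cfg = SimConfig(scaffold_length=50_000, seed=202, recomb_fraction=0.05,
                    error_rate=0.001, mapq_low_fraction=0.1)
    outdir = tmp_path_factory.mktemp("noisy_sample")
    truth = simulate_sample(cfg, outdir=outdir, sample_name="het")
    return {"truth": truth, "sam": outdir / "het.sam", "outdir": outdir}


@pytest.fixture(scope="session")
def scenario(tmp_path_factory):
    """Trio with a reciprocal crossover shared between heterokaryon and
    homokaryon 1, plus one unique to the heterokaryon; phased at the
    heterokaryon's called SNPs so window keys are comparable."""
    from recombiscan.haplotypes import build_windows, extract_sample_alleles
    from recombiscan.simulate import shared_recombinant_scenario
    from recombiscan.snps import build_pileup, call_het_snps

    cfg = SimConfig(scaffold_length=100_000, seed=404,
                    recomb_fraction=0.0, error_rate=0.0,
                    mapq_low_fraction=0.0, mean_depth=80)
    outdir = tmp_path_factory.mktemp("scenario")
    trio, injected = shared_recombinant_scenario(cfg, outdir=outdir)
    het_snps = call_het_snps(build_pileup(outdir / "het" / "het.sam"))
    phased = {
        name: build_windows(
            extract_sample_alleles(outdir / name / f"{name}.sam", het_snps),
            k=5)
        for name in ("het", "hom1", "hom2")}
    return {"trio": trio, "injected": injected, "phased": phased,
            "outdir": outdir}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
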