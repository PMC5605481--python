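"""Read phasing, window classification, cross-sample haplotype filter."""

from collections import Counter

import pytest
from hypothesis import given
from hypothesis import strategies as st

from recombiscan.haplotypes import (
    HaplotypeWindow,
    build_windows,
    classify_window,
    extract_sample_alleles,
    filter_shared_recombinants,
    summarize_counts,
    summarize_sample,
)
from recombiscan.simulate import (
    PARENTAL2,
    SimConfig,
    molecule_string_at,
    shared_recombinant_scenario,
    simulate_sample,
)
from recombiscan.snps import HetSNP, build_pileup, call_het_snps


def _snps(positions, a1="A", a2="C", scaffold="s1"):
    return [HetSNP(scaffold, p, a1, a2, 6, 4, 10) for p in positions]


def _vectors(sam_writer, tmp_path, reads, snps, **kwargs):
    lengths = {"s1": 10_000}
    sam = sam_writer(tmp_path / "reads.sam", lengths, reads)
    return extract_sample_alleles(sam, snps, **kwargs)


class TestExtraction:
    def test_read_spanning_six_snps_phases_six(self, tmp_path, sam_writer):
        snps = _snps([110, 120, 130, 140, 150, 160])
        (vec,) = _vectors(sam_writer, tmp_path,
                          [("r1", "s1", 101, "A" * 100, 60)], snps)
        assert vec.n_phased == 6
        assert [p for _, p, _ in vec.sites] == [110, 120, 130, 140, 150, 160]
        assert all(b == "A" for _, _, b in vec.sites)

    def test_read_spanning_four_snps_is_excluded_from_windows(
            self, tmp_path, sam_writer):
        snps = _snps([110, 120, 130, 140])
        vectors = _vectors(sam_writer, tmp_path,
                           [("r1", "s1", 101, "C" * 100, 60)], snps)
        assert vectors[0].n_phased == 4
        assert build_windows(vectors, k=5).windows == {}

    def test_third_allele_site_dropped_vs_strict_discard(
            self, tmp_path, sam_writer):
        snps = _snps([110, 120, 130, 140, 150, 160])
        seq = "A" * 9 + "G" + "A" * 90  # G at position 110: neither allele
        reads = [("r1", "s1", 101, seq, 60)]
        (vec,) = _vectors(sam_writer, tmp_path, reads, snps)
        assert vec.n_phased == 5
        assert [p for _, p, _ in vec.sites] == [120, 130, 140, 150, 160]
        assert _vectors(sam_writer, tmp_path, reads, snps, strict=True) == []

    def test_low_mapq_reads_are_not_phased(self, tmp_path, sam_writer):
        snps = _snps([110, 120, 130, 140, 150])
        vectors = _vectors(sam_writer, tmp_path,
                           [("r1", "s1", 101, "A" * 100, 9)], snps)
        assert vectors == []

    def test_coordinate_system_mismatch_raises(self, tmp_path, sam_writer):
        snps = _snps([110], scaffold="other_ref")
        with pytest.raises(ValueError, match="coordinate-system"):
            _vectors(sam_writer, tmp_path,
                     [("r1", "s1", 101, "A" * 50, 60)], snps)

    def test_error_free_parental2_reads_carry_parental2_alleles(
            self, clean_sample):
        truth = clean_sample["truth"]
        snps = call_het_snps(build_pileup(clean_sample["sam"]))
        vectors = extract_sample_alleles(clean_sample["sam"], snps)
        labels = {r.read_id: r.label for r in truth.reads}
        hap2 = {sc: h2 for sc, (_, h2) in truth.haplotypes.items()}
        checked = 0
        for vec in vectors:
            if labels[vec.read_id] != PARENTAL2 or not vec.sites:
                continue
            for _, pos, base in vec.sites:
                assert base == hap2[vec.scaffold][pos - 1]
            checked += 1
        assert checked > 0


class TestWindows:
    def test_leading_policy_one_window_per_read(self, tmp_path, sam_writer):
        snps = _snps([110, 120, 130, 140, 150, 160, 170])
        vectors = _vectors(sam_writer, tmp_path,
                           [("r1", "s1", 101, "A" * 100, 60)], snps)
        phased = build_windows(vectors, k=5, policy="leading")
        assert list(phased.windows) == [("s1", 110, 120, 130, 140, 150)]
        assert len(phased.records) == 1

    def test_sliding_policy_every_run_of_k(self, tmp_path, sam_writer):
        snps = _snps([110, 120, 130, 140, 150, 160, 170])
        vectors = _vectors(sam_writer, tmp_path,
                           [("r1", "s1", 101, "A" * 100, 60)], snps)
        phased = build_windows(vectors, k=5, policy="sliding")
        assert sorted(phased.windows) == [
            ("s1", 110, 120, 130, 140, 150),
            ("s1", 120, 130, 140, 150, 160),
            ("s1", 130, 140, 150, 160, 170)]
        assert len(phased.records) == 3
        assert summarize_sample(phased).total_reads == 1

    def test_window_size_below_two_rejected(self):
        with pytest.raises(ValueError, match="k"):
            build_windows([], k=1)

    def test_leading_string_count_equals_qualifying_reads(self, clean_sample):
        snps = call_het_snps(build_pileup(clean_sample["sam"]))
        vectors = extract_sample_alleles(clean_sample["sam"], snps)
        phased = build_windows(vectors, k=5, policy="leading")
        qualifying = sum(1 for v in vectors if v.n_phased >= 5)
        assert len(phased.records) == qualifying
        assert sum(w.spectrum.total() for w in phased.windows.values()) \
            == qualifying


class TestClassification:
    def test_two_most_frequent_are_parental(self):
        window = HaplotypeWindow("s1", (1, 2, 3, 4, 5), Counter(
            {"AAAAA": 14, "CCCCC": 14, "AACCC": 1, "CCAAA": 1}))
        cls = classify_window(window)
        assert set(cls.parental) == {"AAAAA", "CCCCC"}
        assert set(cls.recombinant) == {"AACCC", "CCAAA"}

    def test_single_observed_string_is_parental(self):
        window = HaplotypeWindow("s1", (1, 2, 3, 4, 5),
                                 Counter({"AAAAA": 30}))
        cls = classify_window(window)
        assert cls.parental == ("AAAAA",)
        assert cls.recombinant == ()

    def test_tie_at_parental_cut_breaks_lexicographically(self):
        window = HaplotypeWindow("s1", (1, 2, 3, 4, 5), Counter(
            {"CCCCC": 5, "AAAAA": 5, "AACCC": 5}))
        cls = classify_window(window)
        assert cls.parental == ("AAAAA", "AACCC")
        assert cls.recombinant == ("CCCCC",)

    @given(st.dictionaries(
        st.text(alphabet="AC", min_size=5, max_size=5),
        st.integers(1, 50), min_size=1, max_size=12))
    def test_matches_sort_by_count_oracle(self, spectrum):
        window = HaplotypeWindow("s1", (1, 2, 3, 4, 5), Counter(spectrum))
        cls = classify_window(window)
        oracle = sorted(spectrum, key=lambda s: (-spectrum[s], s))
        assert list(cls.parental) == oracle[:2]
        assert list(cls.recombinant) == oracle[2:]
        assert len(cls.parental) <= 2
        assert len(cls.recombinant) <= 2 ** 5 - 2


class TestSummaries:
    def test_printed_count_arithmetic(self):
        s = summarize_counts(401_623, 21_336, "filtered")
        assert s.total_reads == 422_959
        assert s.recombinant_pct == 5.04
        assert s.nonrecombinant_pct == 94.96
        s2 = summarize_counts(1_832_757, 450_166, "hom1-like")
        assert s2.recombinant_pct == 19.72

    def test_empty_sample_has_undefined_percentages(self):
        s = summarize_counts(0, 0)
        assert s.total_reads == 0
        assert s.recombinant_pct is None and s.nonrecombinant_pct is None

    @given(st.integers(0, 10**7), st.integers(0, 10**7))
    def test_percentages_sum_to_100(self, a, b):
        s = summarize_counts(a, b)
        if s.total_reads:
            assert abs(s.nonrecombinant_pct + s.recombinant_pct - 100.0) \
                <= 0.01


def _phase_at(sam, snps):
    return build_windows(extract_sample_alleles(sam, snps), k=5)


class TestSharedRecombinantFilter:
    def _manual(self, het_spectra, hom_spectra):
        def sample(spectra):
            from recombiscan.haplotypes import PhasedSample, ReadWindowRecord
            ps = PhasedSample(k=5, policy="leading")
            for key, spectrum in spectra.items():
                ps.windows[key] = HaplotypeWindow(key[0], key[1:],
                                                  Counter(spectrum))
                i = 0
                for s, n in spectrum.items():
                    for _ in range(n):
                        rid = f"{key[0]}-{i}"
                        i += 1
                        ps.records.append(ReadWindowRecord(rid, key, s))
                        ps.read_spans[rid] = (key[0], 1, 100)
            return ps
        empty = sample({})
        return filter_shared_recombinants(sample(het_spectra),
                                          sample(hom_spectra), empty)

    def test_identical_recombinant_string_at_same_window_excluded(self):
        key = ("s1", 1, 2, 3, 4, 5)
        filtered, excluded = self._manual(
            {key: {"AAAAA": 10, "CCCCC": 9, "AACCC": 2}},
            {key: {"AAAAA": 8, "CCCCC": 8, "AACCC": 1}})
        assert excluded == [(key, "AACCC")]
        assert "AACCC" not in filtered.windows[key].spectrum
        s = summarize_sample(filtered)
        assert (s.total_reads, s.recombinant_reads) == (19, 0)

    def test_no_same_positioned_window_nothing_excluded(self):
        filtered, excluded = self._manual(
            {("s1", 1, 2, 3, 4, 5): {"AAAAA": 10, "CCCCC": 9, "AACCC": 2}},
            {("s1", 6, 7, 8, 9, 10): {"AAAAA": 8, "AACCC": 7, "CCCCC": 1}})
        assert excluded == []
        assert summarize_sample(filtered).recombinant_reads == 2

    def test_parental_strings_never_removed(self):
        key = ("s1", 1, 2, 3, 4, 5)
        # the heterokaryon's parental string is a recombinant in the
        # homokaryon; it must survive
        filtered, excluded = self._manual(
            {key: {"AAAAA": 10, "CCCCC": 9}},
            {key: {"ACACA": 8, "CACAC": 8, "AAAAA": 1}})
        assert excluded == []
        assert filtered.windows[key].spectrum == Counter(
            {"AAAAA": 10, "CCCCC": 9})

    def test_filter_monotonicity(self):
        key = ("s1", 1, 2, 3, 4, 5)
        het = {key: {"AAAAA": 10, "CCCCC": 9, "AACCC": 2, "CCAAA": 1}}
        filtered, _ = self._manual(het, {key: {"AAAAA": 8, "CCCCC": 8,
                                               "AACCC": 1, "ACCCC": 1}})
        unfiltered, _ = self._manual(het, {})
        sf, su = summarize_sample(filtered), summarize_sample(unfiltered)
        assert sf.recombinant_reads <= su.recombinant_reads
        assert sf.total_reads <= su.total_reads

    def test_window_size_mismatch_raises(self):
        from recombiscan.haplotypes import PhasedSample
        with pytest.raises(ValueError, match="mismatch"):
            filter_shared_recombinants(PhasedSample(k=5, policy="leading"),
                                       PhasedSample(k=4, policy="leading"),
                                       PhasedSample(k=5, policy="leading"))


class TestSharedRecombinantScenario:
    """One recombination event unique to the heterokaryon, one injected
    into homokaryon 1 as well: the filter must exclude exactly the shared
    one and retain the unique one."""

    def test_exactly_the_shared_haplotype_is_excluded(self, scenario):
        trio = scenario["trio"]
        haps = trio.het.haplotypes
        shared = scenario["injected"]["shared"]
        unique = scenario["injected"]["unique"]
        filtered, excluded = filter_shared_recombinants(
            scenario["phased"]["het"], scenario["phased"]["hom1"],
            scenario["phased"]["hom2"])
        assert excluded, "the shared recombinant haplotype was not excluded"
        for key, string in excluded:
            expect = {molecule_string_at(m, haps, key[1:]) for m in shared}
            assert string in expect
        # the unique haplotypes survive and stay classified recombinant
        unique_hits = [
            (key, s) for key, cls in filtered.classify().items()
            for s in cls.recombinant
            if s in {molecule_string_at(m, haps, key[1:]) for m in unique}]
        assert unique_hits

    def test_unfiltered_heterokaryon_sees_both_recombinants(self, scenario):
        trio = scenario["trio"]
        het = scenario["phased"]["het"]
        hits = {name: 0 for name in ("shared", "unique")}
        for key, cls in het.classify().items():
            for name, mols in scenario["injected"].items():
                expect = {molecule_string_at(m, trio.het.haplotypes, key[1:])
                          for m in mols}
                hits[name] += sum(1 for s in cls.recombinant if s in expect)
        assert hits["shared"] >= 1 and hits["unique"] >= 1


class TestErrorSensitivity:
    def test_sequencing_errors_inflate_recombinant_estimate(self):
        ests = {}
        for err in (0.0, 0.01):
            cfg = SimConfig(scaffold_length=60_000, seed=77,
                            recomb_fraction=0.05, error_rate=err)
            truth = simulate_sample(cfg)
            import tempfile
            from pathlib import Path
            with tempfile.TemporaryDirectory() as tmp:
                truth.write(tmp)
                sam = Path(tmp) / "sample.sam"
                snps = call_het_snps(build_pileup(sam))
                s = summarize_sample(_phase_at(sam, snps))
            ests[err] = (s.recombinant_reads, s.total_reads)
        rate = {e: r / t for e, (r, t) in ests.items()}
        assert rate[0.01] >= rate[0.0]
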