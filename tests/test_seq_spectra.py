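"""Spectra, backgrounds and the binomial enrichment test."""

from collections import Counter

import numpy as np
import pytest

from fusionkit.breakpoint_windows import JunctionWindow
from fusionkit.io_formats import NUCLEOTIDE, SequenceRecord
from fusionkit.seq_spectra import (
    KmerSpectrum,
    all_kmers,
    background_spectrum,
    enrichment_test,
    junction_spectrum,
    position_labels,
    positional_frequencies,
)


def window(up, down):
    return JunctionWindow("g", up, down)


def random_windows(rng, n, k=5):
    return [
        window(
            "".join(rng.choice(list("ACGT"), size=k)),
            "".join(rng.choice(list("ACGT"), size=k)),
        )
        for _ in range(n)
    ]


class TestPositionalFrequencies:
    def test_single_window_one_hot(self):
        table = positional_frequencies([window("ACGTA", "CGTAC")])
        f = table.freq
        assert f.at["P-5", "A"] == 1.0
        assert f.at["P-1", "A"] == 1.0
        assert f.at["P+1", "C"] == 1.0
        assert f.at["P-5", "C"] == 0.0

    def test_two_windows_same_pm1(self):
        table = positional_frequencies(
            [window("ACGTG", "CGTAC"), window("TTTTG", "AGTAC")]
        )
        assert table.freq.at["P-1", "G"] == 1.0

    def test_windows_with_n_are_excluded(self):
        table = positional_frequencies(
            [window("ACGTA", "CGTAC"), window("ACGNA", "CGTAC")]
        )
        assert table.n_windows == 1

    def test_empty_collection_errors(self):
        with pytest.raises(ValueError):
            positional_frequencies([])

    def test_uniform_sampling_within_binomial_bound(self, rng):
        windows = random_windows(rng, 10_000)
        freq = positional_frequencies(windows).freq
        se = np.sqrt(0.25 * 0.75 / 10_000)
        assert (np.abs(freq.to_numpy() - 0.25) <= 5 * se).all()


class TestJunctionSpectrum:
    def test_direct_count(self):
        windows = [
            window("AAAAG", "GAAAA"),
            window("AAAAG", "GAAAA"),
            window("AAAAG", "AAAAA"),
            window("AAAAT", "CAAAA"),
        ]
        spec = junction_spectrum(windows, k=2)
        assert spec.freq == {"GG": 0.5, "GA": 0.25, "TC": 0.25}

    def test_point_mass(self):
        spec = junction_spectrum([window("GGGGG", "GGGGG")] * 7, k=3)
        assert spec.freq == {"GGG": 1.0}

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            junction_spectrum([window("AAAAA", "AAAAA")], k=4)

    def test_matches_bruteforce_dictionary_count(self, rng):
        windows = random_windows(rng, 100)
        oracle_di = Counter(w.upstream[-1] + w.downstream[0] for w in windows)
        oracle_tri = Counter(w.upstream[-3:] for w in windows)
        assert junction_spectrum(windows, k=2).counts == dict(oracle_di)
        assert junction_spectrum(windows, k=3).counts == dict(oracle_tri)

    def test_pm1_marginal_consistency(self, rng):
        windows = random_windows(rng, 500)
        table = positional_frequencies(windows).freq
        di = junction_spectrum(windows, k=2)
        for nt in "ACGT":
            marginal = sum(
                f for kmer, f in di.freq.items() if kmer[0] == nt
            )
            assert marginal == pytest.approx(table.at["P-1", nt], abs=1e-12)


class TestBackgroundSpectrum:
    def test_homopolymer(self):
        spec = background_spectrum(
            [SequenceRecord("g", NUCLEOTIDE, "AAAA")], k=2
        )
        assert spec.counts == {"AA": 3} and spec.freq == {"AA": 1.0}

    def test_overlapping_thirds(self):
        spec = background_spectrum([SequenceRecord("g", NUCLEOTIDE, "ACGT")], k=2)
        assert spec.freq == {
            "AC": pytest.approx(1 / 3),
            "CG": pytest.approx(1 / 3),
            "GT": pytest.approx(1 / 3),
        }

    def test_n_kmers_skipped(self):
        spec = background_spectrum([SequenceRecord("g", NUCLEOTIDE, "ANAA")], k=2)
        assert spec.counts == {"AA": 1}

    def test_empty_corpus_errors(self):
        with pytest.raises(ValueError):
            background_spectrum([SequenceRecord("g", NUCLEOTIDE, "N")], k=2)

    def test_uniform_corpus_within_binomial_bound(self, rng):
        residues = "".join(rng.choice(list("ACGT"), size=1_000_000))
        spec = background_spectrum([SequenceRecord("g", NUCLEOTIDE, residues)], k=2)
        se = np.sqrt((1 / 16) * (15 / 16) / spec.n)
        for kmer in all_kmers(2):
            assert abs(spec.frequency(kmer) - 1 / 16) <= 5 * se


class TestEnrichmentTest:
    def uniform_background(self, per_kmer=1000):
        return KmerSpectrum(
            k=2, counts={k: per_kmer for k in all_kmers(2)}, n=per_kmer * 16
        )

    def test_null_case_ratios_one(self):
        observed = KmerSpectrum(k=2, counts={k: 10 for k in all_kmers(2)}, n=160)
        results = enrichment_test(observed, self.uniform_background())
        assert all(r.ratio == pytest.approx(1.0) for r in results)
        assert all(r.p_value >= 0.99 for r in results)

    def test_planted_gg_dominates(self):
        counts = {k: 75 for k in all_kmers(2)}
        counts["GG"] = 875
        observed = KmerSpectrum(k=2, counts=counts, n=2000)
        results = enrichment_test(observed, self.uniform_background())
        assert results[0].kmer == "GG"
        assert results[0].q_value < 1e-6

    def test_single_observation_has_no_power(self):
        observed = KmerSpectrum(k=2, counts={"GG": 1}, n=1)
        results = enrichment_test(observed, self.uniform_background())
        assert all(r.q_value >= 0.05 for r in results)

    def test_q_dominates_p(self, rng):
        counts = dict(
            zip(all_kmers(2), rng.multinomial(300, [1 / 16] * 16))
        )
        results = enrichment_test(
            KmerSpectrum(k=2, counts=counts, n=300), self.uniform_background()
        )
        assert all(r.q_value >= r.p_value for r in results)

    def test_k_mismatch_and_empty_errors(self):
        with pytest.raises(ValueError):
            enrichment_test(
                KmerSpectrum(k=3, counts={"AAA": 1}, n=1), self.uniform_background()
            )
        with pytest.raises(ValueError):
            enrichment_test(
                KmerSpectrum(k=2, counts={}, n=0), self.uniform_background()
            )


def test_position_labels_have_no_zero():
    labels = position_labels(5)
    assert labels == [
        "P-5", "P-4", "P-3", "P-2", "P-1", "P+1", "P+2", "P+3", "P+4", "P+5",
    ]
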