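"""Positional nucleotide frequencies and k-mer spectra around junctions.

Three statistics characterize the sequence context of breakpoints:

* per-position nucleotide frequencies over the ten window positions
  P-5 ... P+5;
* the junction dinucleotide spectrum over the pair (P-1, P+1);
* the pre-break trinucleotide spectrum over (P-3, P-2, P-1).

Each spectrum can be contrasted against a background k-mer distribution
counted over a reference sequence corpus (all overlapping k-mers, step 1).
Enrichment per k-mer is assessed with a two-sided exact binomial test of
the observed count against the background frequency, with Benjamini-
Hochberg correction across the 4^k k-mers.  Windows containing ambiguous
characters (N) are excluded from all counts.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .breakpoint_windows import (
    JunctionWindow,
    is_unambiguous,
    junction_dinucleotide,
    pre_break_trinucleotide,
)
from .io_formats import SequenceRecord

NUCLEOTIDES = "ACGT"


def position_labels(k: int) -> list[str]:
    """Window position labels P-k ... P-1, P+1 ... P+k (no position 0)."""
    return [f"P-{i}" for i in range(k, 0, -1)] + [f"P+{i}" for i in range(1, k + 1)]


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=k)]


@dataclass
class PositionalFrequencyTable:
    """Per-position nucleotide counts over a set of junction windows."""

    counts: pd.DataFrame  # index: position labels; columns: A,C,G,T
    n_windows: int

    @property
    def freq(self) -> pd.DataFrame:
        return self.counts / self.n_windows

    def to_dataframe(self) -> pd.DataFrame:
        df = self.freq.reset_index(names="position")
        return df


@dataclass
class KmerSpectrum:
    """Exact k-mer counts and the frequencies they induce."""

    k: int
    counts: dict[str, int]
    n: int

    @property
    def freq(self) -> dict[str, float]:
        return {kmer: c / self.n for kmer, c in self.counts.items()}

    def frequency(self, kmer: str) -> float:
        return self.counts.get(kmer, 0) / self.n

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"kmer": kmer, "count": self.counts.get(kmer, 0),
             "freq": self.counts.get(kmer, 0) / self.n}
            for kmer in all_kmers(self.k)
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class EnrichmentResult:
    """Binomial enrichment of one k-mer against the background."""

    kmer: str
    observed_count: int
    observed_freq: float
    background_freq: float
    ratio: float
    p_value: float
    q_value: float


def _usable(windows: Iterable[JunctionWindow]) -> list[JunctionWindow]:
    return [w for w in windows if is_unambiguous(w)]


def positional_frequencies(
    windows: Iterable[JunctionWindow],
) -> PositionalFrequencyTable:
    """Exact per-position nucleotide count ratios over the windows.

    All windows must share the same k; windows containing ambiguous
    characters are excluded before counting.
    """
    usable = _usable(windows)
    if not usable:
        raise ValueError("no unambiguous windows to count")
    ks = {w.k for w in usable}
    if len(ks) > 1:
        raise ValueError(f"windows have mixed k: {sorted(ks)}")
    k = ks.pop()
    labels = position_labels(k)
    counts = pd.DataFrame(0, index=labels, columns=list(NUCLEOTIDES))
    for w in usable:
        for label, ch in zip(labels, w.upstream + w.downstream):
            counts.at[label, ch] += 1
    return PositionalFrequencyTable(counts=counts, n_windows=len(usable))


def junction_spectrum(windows: Iterable[JunctionWindow], k: int) -> KmerSpectrum:
    """Junction k-mer spectrum: k=2 uses (P-1, P+1); k=3 uses (P-3, P-2, P-1)."""
    if k == 2:
        extractor = junction_dinucleotide
    elif k == 3:
        extractor = pre_break_trinucleotide
    else:
        raise ValueError(f"junction spectra are defined for k in {{2, 3}}, got {k}")
    usable = _usable(windows)
    if not usable:
        raise ValueError("no unambiguous windows to count")
    counts = Counter(extractor(w) for w in usable)
    return KmerSpectrum(k=k, counts=dict(counts), n=len(usable))


def background_spectrum(
    sequences: Iterable[SequenceRecord], k: int
) -> KmerSpectrum:
    """Count all overlapping k-mers (step 1) in the corpus, skipping any
    k-mer that contains a character outside A/C/G/T."""
    if k not in (2, 3):
        raise ValueError(f"background spectra are defined for k in {{2, 3}}, got {k}")
    counts: Counter[str] = Counter()
    for seq in sequences:
        s = seq.residues
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if all(ch in NUCLEOTIDES for ch in kmer):
                counts[kmer] += 1
    n = sum(counts.values())
    if n == 0:
        raise ValueError("background corpus contains no usable k-mers")
    return KmerSpectrum(k=k, counts=dict(counts), n=n)


def enrichment_test(
    observed: KmerSpectrum, background: KmerSpectrum
) -> list[EnrichmentResult]:
    """Per-k-mer exact binomial test of the observed spectrum vs background.

    The background receives a +1 pseudocount on every k-mer so its
    frequencies are strictly positive; p-values are two-sided exact
    binomial tail probabilities and q-values are Benjamini-Hochberg over
    the 4^k tests.  Results are sorted by descending observed/background
    ratio.
    """
    if observed.k != background.k:
        raise ValueError(
            f"k mismatch: observed k={observed.k}, background k={background.k}"
        )
    if observed.n == 0:
        raise ValueError("observed spectrum has n=0")
    kmers = all_kmers(observed.k)
    bg_total = background.n + len(kmers)
    bg_freq = {
        kmer: (background.counts.get(kmer, 0) + 1) / bg_total for kmer in kmers
    }
    pvals = []
    for kmer in kmers:
        c = observed.counts.get(kmer, 0)
        pvals.append(
            stats.binomtest(c, observed.n, bg_freq[kmer], alternative="two-sided").pvalue
        )
    qvals = stats.false_discovery_control(np.asarray(pvals), method="bh")
    results = []
    for kmer, p, q in zip(kmers, pvals, qvals):
        c = observed.counts.get(kmer, 0)
        obs_f = c / observed.n
        results.append(
            EnrichmentResult(
                kmer=kmer,
                observed_count=c,
                observed_freq=obs_f,
                background_freq=bg_freq[kmer],
                ratio=obs_f / bg_freq[kmer],
                p_value=float(p),
                q_value=float(q),
            )
        )
    results.sort(key=lambda r: (-r.ratio, r.kmer))
    return results


def enrichment_to_dataframe(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "kmer": r.kmer,
                "observed_count": r.observed_count,
                "observed_freq": r.observed_freq,
                "background_freq": r.background_freq,
                "ratio": r.ratio,
                "p_value": r.p_value,
                "q_value": r.q_value,
            }
            for r in results
        ]
    )
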