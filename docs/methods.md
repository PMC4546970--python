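# Methods

## Coordinates and the junction window

A breakpoint is stored as the number of residues retained 5′/N-terminal of
the junction (`offset`), 1-based, so the junction lies between positions
`offset` and `offset + 1` and there is no position 0. The junction window
covers P−k … P−1, P+1 … P+k with k = 5 by default (ten positions). Windows
that would cross a sequence end are skipped rather than padded: padding
with any fill symbol would bias the per-position frequencies, and skipping
loses only breakpoints within k of an end. Windows containing an ambiguous
base (N) are excluded from all spectra for the same reason — counting them
would require either a fifth symbol or an imputation rule. All sequences
are assumed to be supplied in coding orientation; the package never
reverse-complements silently.

## Spectra and the enrichment test

Positional frequencies are exact count ratios per window position. The
dinucleotide spectrum is counted at (P−1, P+1) and the trinucleotide
spectrum at (P−3, P−2, P−1). The background is the distribution of all
overlapping k-mers (step 1) over whatever reference corpus the user
supplies; the statistic is background-relative by design, since "all human
genes" is not something a desk-sized package can ship.

Enrichment per k-mer uses a two-sided exact binomial test of the observed
count among n junctions against the background frequency, with
Benjamini–Hochberg correction over the 4^k tests. The exact test was
chosen because junction counts are often small (hundreds); a χ² or G-test
adds nothing at these sizes and misbehaves for rare k-mers. The background
receives a +1 pseudocount on every k-mer so ratios are always defined;
with realistic backgrounds (≥10⁴ k-mers) the pseudocount shifts
frequencies by < 0.2%.

## Fusion construction and junction mapping

`build_fusion` concatenates a[1..bp_a] with b[bp_b+1..end]; length
conservation (len = bp_a + len(b) − bp_b) is asserted by tests, and
`bp_b = 0` keeps all of partner B. Translation uses the standard genetic
code (Biopython), drops the partial trailing codon, and by default
truncates at the first stop codon — out-of-frame fusions produce early
stops and the truncated product is what a ribosome would make. A
`keep_through_stops` policy retains `*` characters for QC.

The junction maps to the protein through d = bp_a − frame_offset coding
nucleotides from partner A. When 3 | d the junction is codon-aligned and
residue d/3 is the last residue encoded entirely by partner A; otherwise
the junction splits a codon and the chimeric residue ⌈d/3⌉ is reported
with a `split` flag. The ceil rule assigns the breakpoint to the
biologically ambiguous residue rather than to either clean neighbour, and
the flag preserves the distinction; the bound 3r − 2 ≤ d ≤ 3r holds for
every valid input and is tested exhaustively. `frame_offset` defaults to 0
(inputs assumed CDS-trimmed); frame detection is out of scope.

## Disorder scoring and region calling

External per-residue disorder predictions are ingested as long-format TSV
tracks and never recomputed. For offline use the package bundles a
deterministic scorer based on the classic charge–hydropathy unfoldability
index: over a sliding window of 21 residues (truncated to the available
residues at the termini),

    u = 2.785·⟨H⟩ − |⟨q⟩| − 1.151,

where ⟨H⟩ is the window-mean Kyte–Doolittle hydropathy rescaled to [0, 1]
by (h + 4.5)/9 and ⟨q⟩ the window-mean net charge (K, R = +1; D, E = −1).
The disorder score is clip(0.5 − u/2, 0, 1), so the u = 0 folding boundary
maps exactly onto the 0.5 decision threshold used throughout. Closed
forms: poly-E scores 1.0, poly-I scores 0.0. Unknown residues (X) take the
mean hydropathy of the 20 amino acids (−0.49) and zero charge. The window
width (21) is the conventional mid-range choice for windowed
charge-hydropathy scoring: long enough to suppress single-residue noise,
short enough to resolve ~40-residue segments.

Regions are maximal runs of residues with score **strictly** greater than
0.5 — a residue at exactly 0.5 is ordered. `min_length` (default 1) can
drop short runs. A breakpoint is "in disorder" iff its junction residue
falls inside a called interval. Proteins shorter than 100 residues are
flagged and excluded by the CLI's disorder stage (windowed prediction is
unreliable there) but the library never drops them silently.

Consensus over predictors is the exact Venn partition of per-breakpoint
boolean calls over all 2^k predictor subsets (the empty subset counts
breakpoints no predictor calls disordered), from which at-least-k counts
are derived; the partition summing to n and at_least_k being nonincreasing
are asserted on every run. Partner-protein statistics use the same
operations on partner inputs — there is no separate code path.

## PTM enrichment

Site tables from external predictors are ingested as TSV (with an
optional score cutoff, default ≥ 0.5 at the CLI, matching the usual
default threshold of neural-network phosphosite predictors); the bundled
motif predictor (proline-directed and basophilic S/T, acidic-context Y,
RG/GR-context R, KK-context K) exists so the pipeline is testable
offline, and is deliberately simple and deterministic.

The "ratio of occurrence" supports two denominators:

* `region` (default): sites per residue of the region — 0.079 means 7.9%
  of disordered residues are predicted phospho-serines; this makes the
  disordered and structured rows directly comparable;
* `residue_type`: sites per eligible residue of the class — the fraction
  of disordered serines that are phosphorylated. This is the estimator
  that recovers a per-eligible-residue planting density, so the
  recovery tests use it.

Pooling across proteins sums numerators and denominators; averaging
per-protein ratios would weight a 100-residue protein like a
1000-residue one and is never done. The ±50-residue junction window is
clipped at sequence ends rather than skipped (the window definition gives
a range but no edge rule; clipping retains data). The
disordered/structured contrast per residue class is a two-sided Fisher
exact test on sites/non-sites × region kind, BH-corrected over the five
classes; rows with an empty denominator are flagged untested.

## The synthetic generator

The generator emulates the statistical structure of curated fusion
datasets without their data: junction motif biases, disordered segments
around breakpoints, and PTM densities that differ by region.

**Partner genes.** I.i.d. sequences from a configurable base composition
(default uniform, length 500, 427 breakpoints — one per sequence, uniform
in [k, len−k] so every window is constructible). With probability equal
to the trinucleotide bias mass a 3-mer is planted at (P−3, P−2, P−1);
independently, with probability equal to the dinucleotide bias mass a
2-mer is planted at (P−1, P+1), overwriting P−1 if both fire. Defaults:
GG at 0.3, and 0.3 total on the four ?AG trinucleotides (an AG preference
at (P−2, P−1)). `expected_junction_dinucleotide_freq` and
`expected_pre_break_suffix_freq` give the exact closed-form expectations
under this scheme, including the overwrite interaction, and the recovery
tests compare estimates against them.

**Fusion proteins.** Each protein is an ordered–disordered–ordered
sandwich. Tract lengths are uniform on [60, 120] (ordered) and [40, 80]
(disordered). Ordered tracts are drawn from a composition dominated by
hydrophobic residues (I/L/V/F/A/M at 13% each) with S/T/Y/R/K at 2–5%;
disordered tracts from the eight disorder-promoting residues
E/K/R/S/P/Q/G/D at 11.5% each plus T/Y at 4%. The minority residues exist
so region-specific PTM densities are estimable in both region kinds; the
compositions keep the bundled scorer's expected scores ≈ 0.09 (ordered)
vs ≈ 0.78 (disordered), more than 5 SD apart for a 21-residue window, so
region recovery is limited only by boundary blur (≈ 2–3 residues per
boundary, giving mean Jaccard ≈ 0.9 at these tract lengths). With
probability `p_breakpoint_in_disorder` (default 0.68) the junction residue
is placed in the disordered tract, else in an ordered tract, always
keeping a 12-residue margin (half the scorer window plus two) from tract
boundaries so windowed scoring at the junction never straddles a boundary
— the generator is calibrated to the bundled scorer, making the planted
fraction recoverable as a clean binomial.

**PTM sites.** Every eligible residue becomes a site independently with
the class- and region-specific density; defaults place serine at
0.08 (disordered) vs 0.03 (structured) with the minor classes at
occurrence-table magnitudes (T 0.024/0.011, Y 0.011/0.012, R 0.009/0.003,
K 0.007/0.004) — enrichment for S/T/R, none for Y/K.

Everything is a pure function of the config: per-stage RNGs are derived
from (seed, stage) via `numpy.random.SeedSequence`, and regeneration is
bit-identical. What the generator does **not** emulate: real human base
composition and isochore structure, exon/intron architecture, Alu
elements, correlated predictor errors, and motif-dependent PTM placement.
Passing recovery tests therefore demonstrates that the pipeline's
estimators and tests are correct and calibrated — not that real fusion
datasets will show any particular effect size.

## Problem sizes and numerical choices

Recovery tests use 2000 breakpoints for motif recovery, 500 proteins for
the disorder fraction, and 200 proteins for PTM densities — sizes at
which 3 binomial SE is a few percent, comparable to curated-dataset
scales. Null calibration uses 500 replicates (spectra) and 200 replicates
(PTM contrast) at a ≤ 7% empirical q < 0.05 call rate against the nominal
5%. Determinism is asserted at the byte level on full CLI runs: stage
manifests record inputs, parameters, seed and package version, but never
timestamps. Spectra ties in the enrichment ranking break
lexicographically by k-mer.

## Known limitations

* The bundled disorder scorer is a windowed charge–hydropathy index, far
  coarser than pairwise-energy or neural-network predictors; it exists to
  make the pipeline testable offline, not to substitute for them on real
  proteins — ingest real predictor tracks for real analyses.
* Breakpoint offsets are sequence-relative; genomic↔transcript liftover,
  strand resolution, and splice isoforms are the caller's responsibility.
* The bundled PTM predictor's motif rules are intentionally minimal and
  should not be used for biological site prediction.
* Enrichment p-values assume junctions are independent draws; recurrent
  breakpoints from related samples violate this and inflate significance.
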