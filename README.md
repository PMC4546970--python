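# fusionkit

Sequence and structure features of tumor fusion-gene breakpoints.

Chromosomal translocations in cancer join the 5′ prefix of one partner gene
to the 3′ suffix of another, producing fusion genes whose protein products
(EML4-ALK, BCR-ABL, ...) are frequently oncogenic. The breakpoints are not
random: specific nucleotide combinations are over-represented at and just
before the junction, the junction residue of the fusion protein tends to
fall in intrinsically disordered regions, and phosphorylation/methylation
sites are enriched in those disordered regions. `fusionkit` implements this
analysis as a tested pipeline for anyone working with breakpoint-annotated
fusion sequences:

* **junction windows & spectra** — extract the ten positions
  P−5 … P−1, P+1 … P+5 around each breakpoint (no position 0; the junction
  lies between P−1 and P+1), compute per-position nucleotide frequencies,
  the dinucleotide spectrum at (P−1, P+1) and the trinucleotide spectrum at
  (P−3, P−2, P−1), and test each k-mer against a background corpus with a
  two-sided exact binomial test, Benjamini–Hochberg corrected over the 4^k
  k-mers;
* **fusion construction** — build the fused transcript
  a[1..bp_a] + b[bp_b+1..], translate it with the standard code, and map
  the nucleotide junction onto the protein: with d = bp_a − frame_offset,
  a codon-aligned junction (3 | d) maps to residue d/3, otherwise the
  chimeric codon's residue ⌈d/3⌉ is flagged `split`;
* **disorder regions** — per-residue disorder scores (ingested from
  external predictors as TSV tracks, or from the bundled hydropathy/charge
  scorer), regions called as maximal runs of score > 0.5, breakpoints
  classified disordered/structured, and an exact Venn/at-least-k consensus
  across predictors;
* **PTM enrichment** — occurrence ratios of phospho-S/T/Y and methyl-R/K
  sites in disordered vs structured regions and in the ±50-residue window
  around the junction, with per-class Fisher exact contrasts;
* **synthetic corpora** — a generator that plants junction motif biases,
  disordered segments and region-dependent PTM densities with known
  parameters, so every stage has a parameter-recovery test with no
  external downloads.

## Worked example

Library use — build a fusion and locate its junction on the protein:

```python
from fusionkit import SequenceRecord, build_fusion, translate

a = SequenceRecord("EML4ish", "nucleotide", "ATGGACGGATTCGCCGGAAGTCTGGAT")
b = SequenceRecord("ALKish",  "nucleotide", "GGTTACCGCATCATGACTCCTAACTAA")
fc = translate(build_fusion(a, 15, b, 6))
print(len(fc.fused_nt), fc.protein, fc.junction_residue, fc.junction_in_codon)
```

prints `36 MDGFARIMTPN 5 aligned`: 15 nt of partner A plus 21 nt of partner
B give a 36-nt transcript whose first stop truncates the product to 11
residues, and the junction sits exactly after codon 5 (15/3), so residue 5
is the last one encoded wholly by partner A.

CLI use — a full run on a synthetic corpus sized like a typical curated
fusion dataset (427 breakpoints, 108 fusion proteins):

```sh
fusionkit simulate --outdir demo --seed 7 --n-partners 427 --n-fusions 108
fusionkit spectra  --outdir demo
fusionkit disorder --outdir demo
fusionkit ptm      --outdir demo
fusionkit report   --outdir demo
```

The top of `demo/dinucleotide_enrichment.tsv`:

```
kmer  observed_freq  background_freq    ratio      q_value
  GG       0.384075         0.064724 5.934030 5.435294e-80
  GC       0.098361         0.062575 1.571889 9.654035e-03
```

GG flanks 38% of junctions against a 6.5% background — the generator's
planted GG bias (0.3) plus the background's chance contribution — and is
the only strongly significant dinucleotide. `demo/disorder_summary.tsv`
reports a breakpoint-in-disorder fraction of 0.639 (planted: 0.68, n=108),
and `demo/ptm_enrichment.tsv` shows serine phosphosites about 7× denser in
disordered than structured regions (0.0088 vs 0.0012 sites per region
residue). `demo/summary.tsv` collates all stages into one long-format
table. External predictor output drops into the same seams: pass
IUPred/PONDR-style per-residue tracks with `fusionkit disorder --tracks`,
and NetPhos/MeMo-style site tables with `fusionkit ptm --sites`.

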