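"""Synthetic fusion events with known ground truth for every pipeline stage.

Real fusion-gene datasets (COSMIC/TICdb-style breakpoint tables plus
Ensembl/GenBank sequences) cannot be bundled, so this module generates
corpora that carry the same statistical signals with knowable parameters:

* partner genes: i.i.d. nucleotide sequences with a junction dinucleotide
  bias planted at (P-1, P+1) and a pre-break trinucleotide bias planted at
  (P-3, P-2, P-1);
* fusion proteins: ordered-disordered-ordered "sandwich" sequences whose
  tract compositions are chosen so the bundled hydropathy/charge scorer
  separates them decisively, with the junction residue planted inside the
  disordered tract with configurable probability;
* PTM sites: each eligible residue becomes a site independently, with a
  per-class density that differs between disordered and structured tracts.

Everything is a pure function of the config (seed included): the same
config regenerates a bit-identical corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .disorder_regions import RegionSet
from .io_formats import (
    NUCLEOTIDE,
    PROTEIN,
    BreakpointRecord,
    PTMSite,
    SequenceRecord,
)

# Tract compositions.  Ordered tracts are dominated by hydrophobic residues
# and disordered tracts by charged/polar disorder-promoting residues, which
# puts their bundled-scorer scores >5 SD apart; each tract also carries the
# modifiable residues (S/T/Y, R/K) at low frequency so that region-specific
# PTM densities are estimable in both region kinds.
ORDERED_COMPOSITION: Mapping[str, float] = {
    "I": 0.13, "L": 0.13, "V": 0.13, "F": 0.13, "A": 0.13, "M": 0.13,
    "W": 0.02, "S": 0.05, "T": 0.05, "Y": 0.04, "R": 0.03, "K": 0.03,
}
DISORDERED_COMPOSITION: Mapping[str, float] = {
    "E": 0.115, "K": 0.115, "R": 0.115, "S": 0.115,
    "P": 0.115, "Q": 0.115, "G": 0.115, "D": 0.115,
    "T": 0.04, "Y": 0.04,
}

_NT = np.array(list("ACGT"))


def _default_di_bias() -> dict[str, float]:
    return {"GG": 0.3}


def _default_tri_bias() -> dict[str, float]:
    # AG preference at (P-2, P-1): total mass 0.3 split over the four
    # trinucleotides ending in AG
    return {"AAG": 0.075, "CAG": 0.075, "GAG": 0.075, "TAG": 0.075}


def _default_ptm_disorder() -> dict[str, float]:
    return {"S": 0.08, "T": 0.024, "Y": 0.011, "R": 0.009, "K": 0.007}


def _default_ptm_structural() -> dict[str, float]:
    return {"S": 0.03, "T": 0.011, "Y": 0.012, "R": 0.003, "K": 0.004}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a synthetic fusion corpus.

    Defaults mirror the qualitative structure of real tumor fusion data:
    a GG bias of 0.3 at the junction, an AG preference of 0.3 just before
    the break, 68% of junctions inside disordered tracts, and serine
    phosphorylation densities of 0.08 (disordered) vs 0.03 (structured),
    with the minor classes at occurrence-ratio-table magnitudes.
    """

    seed: int = 0
    n_partners: int = 427
    gene_length: int = 500
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    junction_dinucleotide_bias: Mapping[str, float] = field(
        default_factory=_default_di_bias
    )
    pre_break_trinucleotide_bias: Mapping[str, float] = field(
        default_factory=_default_tri_bias
    )
    p_breakpoint_in_disorder: float = 0.68
    disorder_segment_length: tuple[int, int] = (40, 80)
    ordered_segment_length: tuple[int, int] = (60, 120)
    #: residues kept between a planted junction and its tract boundary, so
    #: windowed scoring never straddles the boundary at the junction itself
    junction_margin: int = 12
    ptm_density_disorder: Mapping[str, float] = field(
        default_factory=_default_ptm_disorder
    )
    ptm_density_structural: Mapping[str, float] = field(
        default_factory=_default_ptm_structural
    )
    n_fusions: int = 108
    window_k: int = 5

    def validate(self) -> None:
        if self.n_partners < 1 or self.n_fusions < 1:
            raise ValueError("n_partners and n_fusions must be >= 1")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if any(p < 0 for p in self.base_composition):
            raise ValueError("base_composition must be non-negative")
        for name, bias, k in (
            ("junction_dinucleotide_bias", self.junction_dinucleotide_bias, 2),
            ("pre_break_trinucleotide_bias", self.pre_break_trinucleotide_bias, 3),
        ):
            total = sum(bias.values())
            if total > 1.0 + 1e-9 or any(v < 0 for v in bias.values()):
                raise ValueError(f"{name} probabilities must be in [0,1], sum <= 1")
            for kmer in bias:
                if len(kmer) != k or any(c not in "ACGT" for c in kmer):
                    raise ValueError(f"{name}: bad k-mer {kmer!r}")
        if not 0.0 <= self.p_breakpoint_in_disorder <= 1.0:
            raise ValueError("p_breakpoint_in_disorder must be in [0,1]")
        if self.gene_length < 2 * self.window_k + 1:
            raise ValueError(
                f"gene_length {self.gene_length} cannot host a +/-{self.window_k} "
                f"window"
            )
        d_lo, d_hi = self.disorder_segment_length
        o_lo, o_hi = self.ordered_segment_length
        if not (1 <= d_lo <= d_hi and 1 <= o_lo <= o_hi):
            raise ValueError("segment length ranges must satisfy 1 <= lo <= hi")
        if d_lo < 2 * self.junction_margin + 1 or o_lo < 2 * self.junction_margin + 1:
            raise ValueError(
                "segment minimum lengths must exceed twice the junction margin"
            )
        for dens in (self.ptm_density_disorder, self.ptm_density_structural):
            for residue, p in dens.items():
                if residue not in "STYRK" or not 0.0 <= p <= 1.0:
                    raise ValueError(f"bad PTM density {residue!r}={p}")


def _rng(cfg: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stage]))


def _choice_map(bias: Mapping[str, float]) -> tuple[list[str], np.ndarray, float]:
    kmers = sorted(bias)
    probs = np.array([bias[k] for k in kmers])
    return kmers, probs, float(probs.sum())


def gen_partner_genes(
    cfg: SyntheticConfig,
) -> tuple[list[SequenceRecord], list[BreakpointRecord]]:
    """Breakpoint-bearing partner-gene sequences with planted junction biases.

    One breakpoint per sequence, uniform in [k, length-k] so every window
    is constructible.  The trinucleotide plant (if drawn) overwrites
    (P-3, P-2, P-1) first; the dinucleotide plant (if drawn) then
    overwrites (P-1, P+1).
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    tri_kmers, tri_probs, tri_total = _choice_map(cfg.pre_break_trinucleotide_bias)
    di_kmers, di_probs, di_total = _choice_map(cfg.junction_dinucleotide_bias)
    width = len(str(cfg.n_partners))
    sequences, breakpoints = [], []
    for i in range(cfg.n_partners):
        seq = rng.choice(_NT, size=cfg.gene_length, p=list(cfg.base_composition))
        offset = int(
            rng.integers(cfg.window_k, cfg.gene_length - cfg.window_k + 1)
        )
        if tri_total > 0 and rng.random() < tri_total:
            kmer = tri_kmers[rng.choice(len(tri_kmers), p=tri_probs / tri_total)]
            seq[offset - 3 : offset] = list(kmer)
        if di_total > 0 and rng.random() < di_total:
            kmer = di_kmers[rng.choice(len(di_kmers), p=di_probs / di_total)]
            seq[offset - 1] = kmer[0]
            seq[offset] = kmer[1]
        seq_id = f"partner_{i + 1:0{width}d}"
        sequences.append(
            SequenceRecord(id=seq_id, alphabet=NUCLEOTIDE, residues="".join(seq))
        )
        breakpoints.append(
            BreakpointRecord(
                sequence_id=seq_id, offset=offset, role="partner",
                molecule=NUCLEOTIDE,
            )
        )
    return sequences, breakpoints


def expected_junction_dinucleotide_freq(cfg: SyntheticConfig, dinuc: str) -> float:
    """Exact probability of observing ``dinuc`` at (P-1, P+1) under the
    generator's planting scheme (trinucleotide plant first, dinucleotide
    plant second and overwriting)."""
    base = dict(zip("ACGT", cfg.base_composition))
    di_total = sum(cfg.junction_dinucleotide_bias.values())
    tri_total = sum(cfg.pre_break_trinucleotide_bias.values())
    # P-1 distribution before the dinucleotide plant
    p_m1 = {nt: (1 - tri_total) * base[nt] for nt in "ACGT"}
    for kmer, p in cfg.pre_break_trinucleotide_bias.items():
        p_m1[kmer[2]] += p
    p_no_plant = p_m1[dinuc[0]] * base[dinuc[1]]
    return (
        cfg.junction_dinucleotide_bias.get(dinuc, 0.0)
        + (1 - di_total) * p_no_plant
    )


def expected_pre_break_suffix_freq(cfg: SyntheticConfig, suffix: str) -> float:
    """Exact probability that (P-2, P-1) equals the 2-mer ``suffix``."""
    base = dict(zip("ACGT", cfg.base_composition))
    di_total = sum(cfg.junction_dinucleotide_bias.values())
    tri_total = sum(cfg.pre_break_trinucleotide_bias.values())
    # joint (P-2, P-1) before the dinucleotide plant
    p_tri = sum(
        p
        for kmer, p in cfg.pre_break_trinucleotide_bias.items()
        if kmer[1:] == suffix
    )
    p_pair = p_tri + (1 - tri_total) * base[suffix[0]] * base[suffix[1]]
    # the dinucleotide plant rewrites P-1 only
    p_m2_tri = sum(
        p for kmer, p in cfg.pre_break_trinucleotide_bias.items() if kmer[1] == suffix[0]
    )
    p_m2 = p_m2_tri + (1 - tri_total) * base[suffix[0]]
    p_di_first = sum(
        p
        for kmer, p in cfg.junction_dinucleotide_bias.items()
        if kmer[0] == suffix[1]
    )
    return (1 - di_total) * p_pair + p_m2 * p_di_first


def _sample_tract(
    rng: np.random.Generator, length: int, composition: Mapping[str, float]
) -> str:
    residues = np.array(sorted(composition))
    probs = np.array([composition[r] for r in sorted(composition)])
    probs = probs / probs.sum()
    return "".join(rng.choice(residues, size=length, p=probs))


def gen_fusion_proteins(
    cfg: SyntheticConfig,
) -> tuple[list[SequenceRecord], list[BreakpointRecord], dict[str, RegionSet]]:
    """Sandwich proteins (ordered-disordered-ordered) with planted junctions.

    With probability ``p_breakpoint_in_disorder`` the junction residue is
    placed inside the disordered tract, otherwise inside one of the two
    ordered tracts; placements keep ``junction_margin`` residues between
    the junction and the nearest tract boundary.  Ground-truth disordered
    intervals are returned alongside the sequences.
    """
    cfg.validate()
    rng = _rng(cfg, 2)
    d_lo, d_hi = cfg.disorder_segment_length
    o_lo, o_hi = cfg.ordered_segment_length
    m = cfg.junction_margin
    width = len(str(cfg.n_fusions))
    proteins, breakpoints = [], []
    truth: dict[str, RegionSet] = {}
    for i in range(cfg.n_fusions):
        len1 = int(rng.integers(o_lo, o_hi + 1))
        len_d = int(rng.integers(d_lo, d_hi + 1))
        len2 = int(rng.integers(o_lo, o_hi + 1))
        residues = (
            _sample_tract(rng, len1, ORDERED_COMPOSITION)
            + _sample_tract(rng, len_d, DISORDERED_COMPOSITION)
            + _sample_tract(rng, len2, ORDERED_COMPOSITION)
        )
        if rng.random() < cfg.p_breakpoint_in_disorder:
            junction = int(rng.integers(len1 + m + 1, len1 + len_d - m + 1))
        elif rng.random() < 0.5:
            junction = int(rng.integers(m + 1, len1 - m + 1))
        else:
            junction = int(
                rng.integers(len1 + len_d + m + 1, len1 + len_d + len2 - m + 1)
            )
        seq_id = f"fusion_{i + 1:0{width}d}"
        proteins.append(
            SequenceRecord(id=seq_id, alphabet=PROTEIN, residues=residues)
        )
        breakpoints.append(
            BreakpointRecord(
                sequence_id=seq_id, offset=junction, role="fusion", molecule=PROTEIN
            )
        )
        truth[seq_id] = RegionSet(
            sequence_id=seq_id,
            disordered=((len1 + 1, len1 + len_d),),
            length=len(residues),
        )
    return proteins, breakpoints, truth


def gen_ptm_sites(
    proteins: list[SequenceRecord],
    truth: Mapping[str, RegionSet],
    cfg: SyntheticConfig,
) -> list[PTMSite]:
    """Bernoulli-plant PTM sites with region-dependent per-class densities."""
    cfg.validate()
    rng = _rng(cfg, 3)
    modification = {"S": "phosphorylation", "T": "phosphorylation",
                    "Y": "phosphorylation", "R": "methylation", "K": "methylation"}
    sites: list[PTMSite] = []
    for protein in proteins:
        mask = truth[protein.id].mask()
        draws = rng.random(len(protein))
        for pos0, ch in enumerate(protein.residues):
            if ch not in modification:
                continue
            dens = (
                cfg.ptm_density_disorder if mask[pos0] else cfg.ptm_density_structural
            )
            if draws[pos0] < dens.get(ch, 0.0):
                sites.append(
                    PTMSite(
                        sequence_id=protein.id,
                        position=pos0 + 1,
                        residue=ch,
                        modification=modification[ch],
                        score=1.0,
                    )
                )
    return sites


# ---------------------------------------------------------------------------
# flat key=value config files


def save_config(cfg: SyntheticConfig, path: str | Path) -> None:
    """Write the config as a flat, diff-able key=value file."""
    lines = ["# fusionkit synthetic corpus configuration"]
    lines.append(f"seed={cfg.seed}")
    lines.append(f"n_partners={cfg.n_partners}")
    lines.append(f"gene_length={cfg.gene_length}")
    lines.append(
        "base_composition=" + ",".join(f"{p:g}" for p in cfg.base_composition)
    )
    for name, bias in (
        ("junction_dinucleotide_bias", cfg.junction_dinucleotide_bias),
        ("pre_break_trinucleotide_bias", cfg.pre_break_trinucleotide_bias),
    ):
        lines.append(
            f"{name}=" + ",".join(f"{k}:{v:g}" for k, v in sorted(bias.items()))
        )
    lines.append(f"p_breakpoint_in_disorder={cfg.p_breakpoint_in_disorder:g}")
    lines.append(
        "disorder_segment_length="
        + ",".join(str(v) for v in cfg.disorder_segment_length)
    )
    lines.append(
        "ordered_segment_length="
        + ",".join(str(v) for v in cfg.ordered_segment_length)
    )
    lines.append(f"junction_margin={cfg.junction_margin}")
    for name, dens in (
        ("ptm_density_disorder", cfg.ptm_density_disorder),
        ("ptm_density_structural", cfg.ptm_density_structural),
    ):
        lines.append(
            f"{name}=" + ",".join(f"{k}:{v:g}" for k, v in sorted(dens.items()))
        )
    lines.append(f"n_fusions={cfg.n_fusions}")
    lines.append(f"window_k={cfg.window_k}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> SyntheticConfig:
    """Read a flat key=value config written by :func:`save_config`."""
    kwargs: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        if key in ("seed", "n_partners", "gene_length", "junction_margin",
                   "n_fusions", "window_k"):
            kwargs[key] = int(value)
        elif key == "p_breakpoint_in_disorder":
            kwargs[key] = float(value)
        elif key == "base_composition":
            kwargs[key] = tuple(float(v) for v in value.split(","))
        elif key in ("disorder_segment_length", "ordered_segment_length"):
            kwargs[key] = tuple(int(v) for v in value.split(","))
        elif key in ("junction_dinucleotide_bias", "pre_break_trinucleotide_bias",
                     "ptm_density_disorder", "ptm_density_structural"):
            mapping = {}
            if value:
                for item in value.split(","):
                    k, _, v = item.partition(":")
                    mapping[k] = float(v)
            kwargs[key] = mapping
        else:
            raise ValueError(f"{path}: unknown config key {key!r}")
    return SyntheticConfig(**kwargs)
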