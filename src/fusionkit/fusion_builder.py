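"""Construction and translation of fusion genes, with junction coordinate maps.

A fusion joins the 5' prefix of partner A (its first ``bp_a`` nucleotides)
to the 3' suffix of partner B (everything after ``bp_b``), exactly as a
reciprocal translocation would.  The fused transcript is translated with
the standard genetic code and the nucleotide junction is mapped onto the
protein:

    d = bp_a - frame_offset          (coding nucleotides from partner A)
    d % 3 == 0  ->  junction "aligned" at residue d/3
                    (the last residue encoded wholly by partner A)
    otherwise   ->  junction "split"  at residue ceil(d/3)
                    (the residue whose codon straddles the junction)

so that 3r - 2 <= d <= 3r always holds for the mapped residue r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from Bio.Seq import Seq

from .io_formats import NUCLEOTIDE, SequenceRecord, ValidationError

TRUNCATE_AT_FIRST_STOP = "truncate_at_first_stop"
KEEP_THROUGH_STOPS = "keep_through_stops"
STOP_POLICIES = frozenset({TRUNCATE_AT_FIRST_STOP, KEEP_THROUGH_STOPS})

ALIGNED = "aligned"
SPLIT = "split"


@dataclass(frozen=True)
class FusionConstruct:
    """A fused nucleotide sequence and, once translated, its protein product.

    ``protein`` may contain ``*`` only under the ``keep_through_stops``
    policy (a QC view of out-of-frame products); the default policy
    truncates before the first stop.
    """

    partner_a_id: str
    partner_b_id: str
    bp_a: int
    bp_b: int
    fused_nt: str
    frame_offset: int = 0
    protein: str | None = None
    junction_residue: int | None = None
    junction_in_codon: str | None = None


def build_fusion(
    a: SequenceRecord, bp_a: int, b: SequenceRecord, bp_b: int
) -> FusionConstruct:
    """Concatenate a[1..bp_a] with b[bp_b+1..end] (1-based, inclusive).

    The junction offset in fused coordinates equals ``bp_a``.
    """
    for seq in (a, b):
        if seq.alphabet != NUCLEOTIDE:
            raise ValidationError(
                f"fusion partners must be nucleotide sequences; {seq.id!r} is "
                f"{seq.alphabet}"
            )
    if not 1 <= bp_a < len(a):
        raise ValidationError(
            f"bp_a={bp_a} out of range for {a.id!r} (length {len(a)})"
        )
    if not 0 <= bp_b < len(b):
        raise ValidationError(
            f"bp_b={bp_b} out of range for {b.id!r} (length {len(b)})"
        )
    return FusionConstruct(
        partner_a_id=a.id,
        partner_b_id=b.id,
        bp_a=bp_a,
        bp_b=bp_b,
        fused_nt=a.residues[:bp_a] + b.residues[bp_b:],
    )


def translate(
    fc: FusionConstruct,
    frame_offset: int = 0,
    stop_policy: str = TRUNCATE_AT_FIRST_STOP,
) -> FusionConstruct:
    """Translate the fused transcript and map the junction onto the protein.

    The partial trailing codon is dropped.  Under the default policy the
    protein ends just before the first stop codon; ``keep_through_stops``
    retains ``*`` characters for QC of out-of-frame fusions.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    if stop_policy not in STOP_POLICIES:
        raise ValueError(f"unknown stop policy {stop_policy!r}")
    coding = fc.fused_nt[frame_offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    if not coding:
        raise ValidationError(
            "fused sequence shorter than one codon in the requested frame"
        )
    aa = str(Seq(coding).translate())
    if stop_policy == TRUNCATE_AT_FIRST_STOP:
        aa = aa.split("*", 1)[0]
    fc = replace(fc, frame_offset=frame_offset, protein=aa)
    residue, in_codon = map_breakpoint_to_residue(fc)
    return replace(fc, junction_residue=residue, junction_in_codon=in_codon)


def map_breakpoint_to_residue(fc: FusionConstruct) -> tuple[int, str]:
    """Map the nucleotide junction to a protein residue.

    Returns ``(junction_residue, "aligned"|"split")``.  With
    ``d = bp_a - frame_offset`` coding nucleotides contributed by partner
    A: a codon-aligned junction (d divisible by 3) maps to residue d/3,
    the last residue fully from partner A; otherwise the junction falls
    inside codon ceil(d/3) and that chimeric residue is flagged split.
    """
    d = fc.bp_a - fc.frame_offset
    if d <= 0:
        raise ValidationError(
            f"junction at bp_a={fc.bp_a} lies upstream of the coding start "
            f"(frame offset {fc.frame_offset})"
        )
    if d % 3 == 0:
        return d // 3, ALIGNED
    return math.ceil(d / 3), SPLIT


def fused_record(fc: FusionConstruct, fused_id: str | None = None) -> SequenceRecord:
    """The fused transcript as a nucleotide :class:`SequenceRecord`."""
    return SequenceRecord(
        id=fused_id or f"{fc.partner_a_id}--{fc.partner_b_id}",
        alphabet=NUCLEOTIDE,
        residues=fc.fused_nt,
    )
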