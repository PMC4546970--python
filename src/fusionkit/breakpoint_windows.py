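"""Extraction of the +/-5-position junction windows around breakpoints.

A junction window covers the ten positions P-5 ... P-1, P+1 ... P+5 around
a breakpoint (there is no position 0: the junction falls between P-1 and
P+1).  Windows that would run past either end of the sequence are skipped,
not padded, so positional frequencies downstream are never distorted by
fill characters.  All sequences are assumed to be supplied in coding
orientation; no reverse-complementing is performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .io_formats import BreakpointRecord, SequenceRecord, ValidationError

logger = logging.getLogger(__name__)

#: nucleotides allowed in spectrum computations (windows with anything else,
#: e.g. N, are excluded downstream)
UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class JunctionWindow:
    """The k positions on each side of one junction.

    ``upstream`` holds P-k ... P-1 left to right (its last character is the
    residue immediately 5' of the junction); ``downstream`` holds
    P+1 ... P+k (its first character is immediately 3').
    """

    sequence_id: str
    upstream: str
    downstream: str
    role: str = "partner"

    def __post_init__(self) -> None:
        if len(self.upstream) != len(self.downstream) or not self.upstream:
            raise ValidationError(
                f"window on {self.sequence_id!r}: upstream/downstream must be "
                f"non-empty and equal length"
            )

    @property
    def k(self) -> int:
        return len(self.upstream)


def extract_window(
    seq: SequenceRecord, bp: BreakpointRecord, k: int = 5
) -> JunctionWindow | None:
    """Extract the window of ``k`` positions on each side of ``bp``.

    Returns ``None`` (with a logged skip) when the breakpoint sits closer
    than ``k`` to either sequence end.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if bp.sequence_id != seq.id:
        raise ValidationError(
            f"breakpoint references {bp.sequence_id!r}, sequence is {seq.id!r}"
        )
    offset = bp.offset
    if offset < k or offset + k > len(seq):
        logger.debug(
            "skipping breakpoint %s@%d: window of +/-%d does not fit in "
            "length %d", seq.id, offset, k, len(seq),
        )
        return None
    return JunctionWindow(
        sequence_id=seq.id,
        upstream=seq.residues[offset - k : offset],
        downstream=seq.residues[offset : offset + k],
        role=bp.role,
    )


def extract_windows(
    sequences: Mapping[str, SequenceRecord] | Iterable[SequenceRecord],
    breakpoints: Iterable[BreakpointRecord],
    k: int = 5,
) -> list[JunctionWindow]:
    """Extract all constructible windows; out-of-range breakpoints are skipped."""
    if not isinstance(sequences, Mapping):
        sequences = {s.id: s for s in sequences}
    windows = []
    n_skipped = 0
    for bp in breakpoints:
        if bp.sequence_id not in sequences:
            raise ValidationError(
                f"breakpoint references unknown sequence {bp.sequence_id!r}"
            )
        w = extract_window(sequences[bp.sequence_id], bp, k=k)
        if w is None:
            n_skipped += 1
        else:
            windows.append(w)
    if n_skipped:
        logger.info("skipped %d breakpoint(s) too close to a sequence end", n_skipped)
    return windows


def junction_dinucleotide(window: JunctionWindow) -> str:
    """The 2-mer at (P-1, P+1) flanking the junction."""
    return window.upstream[-1] + window.downstream[0]


def pre_break_trinucleotide(window: JunctionWindow) -> str:
    """The 3-mer at (P-3, P-2, P-1) immediately upstream of the junction."""
    if window.k < 3:
        raise ValueError(
            f"window k={window.k} too small for a pre-break trinucleotide"
        )
    return window.upstream[-3:]


def is_unambiguous(window: JunctionWindow) -> bool:
    """True when every window character is a plain A/C/G/T."""
    return all(ch in UNAMBIGUOUS for ch in window.upstream + window.downstream)
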