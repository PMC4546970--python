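"""Readers, writers and validated record types for the pipeline's file formats.

Formats
-------
* FASTA — nucleotide or protein sequences (Biopython-backed).
* breakpoints TSV — columns ``sequence_id, offset, role, molecule``.
* score-track TSV — columns ``sequence_id, predictor, position, score``;
  long format, one row per residue; the ingestion point for external
  per-residue disorder predictors.
* PTM-site TSV — columns ``sequence_id, position, residue, modification,
  score`` (score may be empty); the ingestion point for external
  phosphorylation/methylation predictors.
* generic results TSV — tab-separated, ``#`` comments, mandatory header.

Coordinate convention
---------------------
All positions in files are 1-based inclusive.  A breakpoint ``offset`` is
the number of residues retained 5'/N-terminal of the junction: the junction
lies between positions ``offset`` and ``offset + 1`` (there is no position
0), so the junction dinucleotide is ``(seq[offset], seq[offset + 1])`` in
1-based coordinates.  Conversion to Python slicing happens inside the
package and nowhere at the file boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file does not conform to the expected syntax."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"
ALPHABETS = frozenset({NUCLEOTIDE, PROTEIN})

NUCLEOTIDE_CHARS = frozenset("ACGTN")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_CHARS = frozenset(AMINO_ACIDS + "X")

ROLES = frozenset({"partner", "fusion"})

PHOSPHO_RESIDUES = frozenset("STY")
METHYL_RESIDUES = frozenset("RK")
MODIFICATION_RESIDUES = {
    "phosphorylation": PHOSPHO_RESIDUES,
    "methylation": METHYL_RESIDUES,
}


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or protein sequence.

    ``residues`` is upper-case and restricted to the declared alphabet
    (ACGTN for nucleotide; the 20 amino acids plus X for protein).
    """

    id: str
    alphabet: str
    residues: str

    def __post_init__(self) -> None:
        if self.alphabet not in ALPHABETS:
            raise ValidationError(f"unknown alphabet {self.alphabet!r}")
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} is empty")
        allowed = NUCLEOTIDE_CHARS if self.alphabet == NUCLEOTIDE else PROTEIN_CHARS
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in allowed:
                raise ValidationError(
                    f"sequence {self.id!r}: illegal {self.alphabet} character "
                    f"{ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class BreakpointRecord:
    """One breakpoint on one sequence.

    ``offset`` counts the residues retained before the junction, so the
    junction lies between 1-based positions ``offset`` and ``offset + 1``.
    """

    sequence_id: str
    offset: int
    role: str
    molecule: str

    def __post_init__(self) -> None:
        if self.offset < 1:
            raise ValidationError(
                f"breakpoint on {self.sequence_id!r}: offset must be >= 1, "
                f"got {self.offset}"
            )
        if self.role not in ROLES:
            raise ValidationError(
                f"breakpoint on {self.sequence_id!r}: unknown role {self.role!r}"
            )
        if self.molecule not in ALPHABETS:
            raise ValidationError(
                f"breakpoint on {self.sequence_id!r}: unknown molecule "
                f"{self.molecule!r}"
            )

    def validate_against(self, seq: SequenceRecord) -> None:
        """Check the junction fits inside ``seq`` (needs a P+1 residue)."""
        if seq.id != self.sequence_id:
            raise ValidationError(
                f"breakpoint references {self.sequence_id!r} but sequence is "
                f"{seq.id!r}"
            )
        if not 1 <= self.offset < len(seq):
            raise ValidationError(
                f"breakpoint on {self.sequence_id!r}: offset {self.offset} out "
                f"of range for length {len(seq)} (need 1 <= offset < length)"
            )


@dataclass(frozen=True)
class ScoreTrack:
    """Per-residue scores from one predictor for one sequence."""

    sequence_id: str
    predictor_name: str
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValidationError(
                f"score track for {self.sequence_id!r} is empty"
            )
        for pos, s in enumerate(self.scores, start=1):
            if not math.isfinite(s):
                raise ValidationError(
                    f"score track for {self.sequence_id!r} "
                    f"({self.predictor_name}): non-finite score at position {pos}"
                )

    def validate_against(self, seq: SequenceRecord) -> None:
        if len(self.scores) != len(seq):
            raise ValidationError(
                f"score track for {self.sequence_id!r} "
                f"({self.predictor_name}) has {len(self.scores)} scores but the "
                f"sequence has {len(seq)} residues"
            )


@dataclass(frozen=True)
class PTMSite:
    """A predicted post-translational modification site (1-based position)."""

    sequence_id: str
    position: int
    residue: str
    modification: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"PTM site on {self.sequence_id!r}: position must be >= 1"
            )
        if self.modification not in MODIFICATION_RESIDUES:
            raise ValidationError(
                f"PTM site on {self.sequence_id!r}: unknown modification "
                f"{self.modification!r}"
            )
        allowed = MODIFICATION_RESIDUES[self.modification]
        if self.residue not in allowed:
            raise ValidationError(
                f"PTM site on {self.sequence_id!r} at {self.position}: "
                f"{self.modification} not allowed on residue {self.residue!r}"
            )

    def validate_against(self, seq: SequenceRecord) -> None:
        if self.position > len(seq):
            raise ValidationError(
                f"PTM site on {self.sequence_id!r}: position {self.position} "
                f"beyond sequence length {len(seq)}"
            )
        actual = seq.residues[self.position - 1]
        if actual != self.residue:
            raise ValidationError(
                f"PTM site on {self.sequence_id!r}: residue at position "
                f"{self.position} is {actual!r}, site claims {self.residue!r}"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: str) -> list[SequenceRecord]:
    """Read a FASTA file into validated, upper-cased :class:`SequenceRecord`s.

    Raises :class:`FormatError` for syntactic problems (naming the line) and
    :class:`ValidationError` for illegal characters or duplicate ids.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: expected a '>' header before "
                    f"sequence data"
                )
            break
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA entry with empty header")
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(id=rec.id, alphabet=alphabet, residues=str(rec.seq).upper())
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def as_mapping(records: Iterable[SequenceRecord]) -> dict[str, SequenceRecord]:
    out: dict[str, SequenceRecord] = {}
    for r in records:
        if r.id in out:
            raise ValidationError(f"duplicate sequence id {r.id!r}")
        out[r.id] = r
    return out


# ---------------------------------------------------------------------------
# TSV helpers

_TSV_KWARGS = dict(sep="\t", comment="#")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a results/input TSV (tab-separated, '#' comments, header row)."""
    try:
        return pd.read_csv(path, **_TSV_KWARGS)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty table") from exc


def write_table(rows: pd.DataFrame | Iterable[Mapping], path: str | Path) -> None:
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# Breakpoints


def read_breakpoints(
    path: str | Path,
    sequences: Mapping[str, SequenceRecord] | None = None,
) -> list[BreakpointRecord]:
    """Read a breakpoint TSV; offsets are checked against ``sequences`` when given."""
    df = read_table(path)
    _require_columns(df, ["sequence_id", "offset", "role", "molecule"], path)
    records = []
    for row in df.itertuples(index=False):
        bp = BreakpointRecord(
            sequence_id=str(row.sequence_id),
            offset=int(row.offset),
            role=str(row.role),
            molecule=str(row.molecule),
        )
        if sequences is not None:
            if bp.sequence_id not in sequences:
                raise ValidationError(
                    f"{path}: breakpoint references unknown sequence "
                    f"{bp.sequence_id!r}"
                )
            bp.validate_against(sequences[bp.sequence_id])
        records.append(bp)
    return records


def write_breakpoints(breakpoints: Iterable[BreakpointRecord], path: str | Path) -> None:
    write_table(
        pd.DataFrame(
            [
                {
                    "sequence_id": b.sequence_id,
                    "offset": b.offset,
                    "role": b.role,
                    "molecule": b.molecule,
                }
                for b in breakpoints
            ],
            columns=["sequence_id", "offset", "role", "molecule"],
        ),
        path,
    )


# ---------------------------------------------------------------------------
# Score tracks


def read_score_tracks(
    path: str | Path,
    sequences: Mapping[str, SequenceRecord] | None = None,
) -> list[ScoreTrack]:
    """Read long-format per-residue score tracks.

    Each (sequence_id, predictor) group must cover positions 1..L contiguously;
    when ``sequences`` is given, L must equal the sequence length.
    """
    df = read_table(path)
    _require_columns(df, ["sequence_id", "predictor", "position", "score"], path)
    tracks = []
    for (seq_id, predictor), grp in df.groupby(["sequence_id", "predictor"], sort=True):
        grp = grp.sort_values("position")
        positions = grp["position"].to_numpy()
        if positions[0] != 1 or (positions != range(1, len(positions) + 1)).any():
            raise FormatError(
                f"{path}: track {seq_id!r}/{predictor!r} does not cover "
                f"positions 1..n contiguously"
            )
        track = ScoreTrack(
            sequence_id=str(seq_id),
            predictor_name=str(predictor),
            scores=tuple(float(s) for s in grp["score"]),
        )
        if sequences is not None:
            if track.sequence_id not in sequences:
                raise ValidationError(
                    f"{path}: score track references unknown sequence {seq_id!r}"
                )
            track.validate_against(sequences[track.sequence_id])
        tracks.append(track)
    return tracks


def write_score_tracks(tracks: Iterable[ScoreTrack], path: str | Path) -> None:
    rows = []
    for t in tracks:
        for pos, score in enumerate(t.scores, start=1):
            rows.append(
                {
                    "sequence_id": t.sequence_id,
                    "predictor": t.predictor_name,
                    "position": pos,
                    "score": score,
                }
            )
    write_table(
        pd.DataFrame(rows, columns=["sequence_id", "predictor", "position", "score"]),
        path,
    )


# ---------------------------------------------------------------------------
# PTM sites


def read_ptm_sites(
    path: str | Path,
    sequences: Mapping[str, SequenceRecord] | None = None,
    min_score: float | None = None,
) -> list[PTMSite]:
    """Read a PTM-site TSV.

    ``min_score`` drops sites whose score is present and below the cutoff
    (sites without a score always pass); ``None`` keeps everything so that
    write/read round-trips are lossless.
    """
    df = read_table(path)
    _require_columns(df, ["sequence_id", "position", "residue", "modification"], path)
    sites = []
    for row in df.itertuples(index=False):
        score = getattr(row, "score", None)
        if score is not None and (isinstance(score, float) and math.isnan(score)):
            score = None
        if score is not None:
            score = float(score)
            if min_score is not None and score < min_score:
                continue
        site = PTMSite(
            sequence_id=str(row.sequence_id),
            position=int(row.position),
            residue=str(row.residue),
            modification=str(row.modification),
            score=score,
        )
        if sequences is not None:
            if site.sequence_id not in sequences:
                raise ValidationError(
                    f"{path}: PTM site references unknown sequence "
                    f"{site.sequence_id!r}"
                )
            site.validate_against(sequences[site.sequence_id])
        sites.append(site)
    return sites


def write_ptm_sites(sites: Iterable[PTMSite], path: str | Path) -> None:
    write_table(
        pd.DataFrame(
            [
                {
                    "sequence_id": s.sequence_id,
                    "position": s.position,
                    "residue": s.residue,
                    "modification": s.modification,
                    "score": s.score,
                }
                for s in sites
            ],
            columns=["sequence_id", "position", "residue", "modification", "score"],
        ),
        path,
    )
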