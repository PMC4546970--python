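"""Per-residue disorder scoring, region calling and multi-predictor consensus.

A residue is *disordered* when its per-residue disorder score is strictly
greater than 0.5; maximal runs of such residues form the disordered
regions and everything else is the structured ("structural") part of the
protein.  External predictor output (IUPred-, PONDR- or PreDisorder-style
per-residue tracks) is ingested as :class:`~fusionkit.io_formats.ScoreTrack`
TSVs; the predictors themselves are never executed here.

For offline, fully deterministic operation the package bundles a
hydropathy/charge scorer built on the classic charge-hydropathy
unfoldability index: over a sliding window (default 21 residues, truncated
at the sequence ends)

    u = 2.785 * <H> - |<q>| - 1.151

with ``<H>`` the window mean Kyte-Doolittle hydropathy rescaled to [0, 1]
via (h + 4.5) / 9 and ``<q>`` the window mean net charge (K, R = +1;
D, E = -1).  Folded sequences give u > 0, unfolded u < 0, so the disorder
score is ``clip(0.5 - u / 2, 0, 1)``: the u = 0 folding boundary maps to
the 0.5 decision threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import PROTEIN, ScoreTrack, SequenceRecord, ValidationError

BUNDLED_PREDICTOR = "bundled"
DEFAULT_THRESHOLD = 0.5
DEFAULT_WINDOW = 21
#: minimum protein length used for structural statistics; shorter proteins
#: are flagged because window-based disorder prediction is unreliable there
MIN_PROTEIN_LENGTH = 100

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    # unknown residue: mean hydropathy of the 20 amino acids, charge 0
    "X": -0.49,
}

CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue disorder scores in [0, 1] for one protein."""

    sequence_id: str
    predictor_name: str
    scores: tuple[float, ...]
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        for pos, s in enumerate(self.scores, start=1):
            if not 0.0 <= s <= 1.0:
                raise ValidationError(
                    f"disorder profile {self.sequence_id!r} "
                    f"({self.predictor_name}): score {s} at position {pos} "
                    f"outside [0, 1]"
                )


@dataclass(frozen=True)
class RegionSet:
    """Disordered intervals (1-based, inclusive, sorted, disjoint, maximal)."""

    sequence_id: str
    disordered: tuple[tuple[int, int], ...]
    length: int

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.disordered:
            if start <= prev_end or end < start or end > self.length:
                raise ValidationError(
                    f"regions for {self.sequence_id!r} are not sorted, "
                    f"disjoint 1-based intervals within length {self.length}"
                )
            prev_end = end

    @property
    def n_disordered(self) -> int:
        return sum(end - start + 1 for start, end in self.disordered)

    def mask(self) -> np.ndarray:
        """Boolean per-residue indicator (index 0 = residue 1)."""
        m = np.zeros(self.length, dtype=bool)
        for start, end in self.disordered:
            m[start - 1 : end] = True
        return m


@dataclass(frozen=True)
class ConsensusSummary:
    """Venn partition of breakpoint disorder calls across predictors."""

    n_breakpoints: int
    predictors: tuple[str, ...]
    per_predictor_disordered: Mapping[str, int]
    venn_counts: Mapping[tuple[str, ...], int]
    at_least_k: Mapping[int, int]


def bundled_disorder_score(
    protein: SequenceRecord, window: int = DEFAULT_WINDOW
) -> DisorderProfile:
    """Deterministic hydropathy/charge disorder scores for ``protein``.

    Window means are truncated at the sequence ends (mean over the residues
    actually available), so terminal residues are scored from one-sided
    windows rather than padded.
    """
    if protein.alphabet != PROTEIN:
        raise ValidationError(
            f"disorder scoring requires a protein sequence; {protein.id!r} is "
            f"{protein.alphabet}"
        )
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    h = np.array([(KYTE_DOOLITTLE[ch] + 4.5) / 9.0 for ch in protein.residues])
    q = np.array([CHARGE.get(ch, 0.0) for ch in protein.residues])
    mean_h = (
        pd.Series(h).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    mean_q = (
        pd.Series(q).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    u = 2.785 * mean_h - np.abs(mean_q) - 1.151
    scores = np.clip(0.5 - u / 2.0, 0.0, 1.0)
    return DisorderProfile(
        sequence_id=protein.id,
        predictor_name=BUNDLED_PREDICTOR,
        scores=tuple(float(s) for s in scores),
    )


def track_to_profile(
    track: ScoreTrack, threshold: float = DEFAULT_THRESHOLD
) -> DisorderProfile:
    """Adapt an ingested external score track to a disorder profile."""
    return DisorderProfile(
        sequence_id=track.sequence_id,
        predictor_name=track.predictor_name,
        scores=track.scores,
        threshold=threshold,
    )


def call_regions(profile: DisorderProfile, min_length: int = 1) -> RegionSet:
    """Maximal runs of residues with score strictly above the threshold.

    Ties at exactly the threshold count as ordered.  Runs shorter than
    ``min_length`` are dropped.
    """
    intervals: list[tuple[int, int]] = []
    start = None
    for pos, score in enumerate(profile.scores, start=1):
        if score > profile.threshold:
            if start is None:
                start = pos
        elif start is not None:
            intervals.append((start, pos - 1))
            start = None
    if start is not None:
        intervals.append((start, len(profile.scores)))
    intervals = [iv for iv in intervals if iv[1] - iv[0] + 1 >= min_length]
    return RegionSet(
        sequence_id=profile.sequence_id,
        disordered=tuple(intervals),
        length=len(profile.scores),
    )


def breakpoint_in_disorder(regions: RegionSet, junction_residue: int) -> bool:
    """True iff the junction residue lies inside a disordered interval."""
    if not 1 <= junction_residue <= regions.length:
        raise ValidationError(
            f"residue {junction_residue} out of range 1..{regions.length} for "
            f"{regions.sequence_id!r}"
        )
    return any(start <= junction_residue <= end for start, end in regions.disordered)


def consensus(calls: Mapping[str, Mapping[str, bool]]) -> ConsensusSummary:
    """Exact Venn partition of per-breakpoint calls over the predictors.

    ``calls`` maps predictor -> breakpoint id -> disordered?.  Every
    predictor must cover exactly the same breakpoints.  The Venn partition
    is over all 2^k predictor subsets (including the empty subset:
    breakpoints no predictor calls disordered), and ``at_least_k`` counts
    breakpoints called disordered by at least k predictors.
    """
    predictors = tuple(sorted(calls))
    if not predictors:
        raise ValueError("no predictors supplied")
    keysets = [set(calls[p]) for p in predictors]
    if any(ks != keysets[0] for ks in keysets[1:]):
        raise ValidationError("predictors do not cover the same breakpoints")
    breakpoints = sorted(keysets[0])
    venn: dict[tuple[str, ...], int] = {}
    for bp in breakpoints:
        subset = tuple(p for p in predictors if calls[p][bp])
        venn[subset] = venn.get(subset, 0) + 1
    at_least = {
        k: sum(count for subset, count in venn.items() if len(subset) >= k)
        for k in range(1, len(predictors) + 1)
    }
    per_pred = {
        p: sum(1 for bp in breakpoints if calls[p][bp]) for p in predictors
    }
    assert sum(venn.values()) == len(breakpoints)
    assert all(
        at_least[k] >= at_least[k + 1] for k in range(1, len(predictors))
    )
    return ConsensusSummary(
        n_breakpoints=len(breakpoints),
        predictors=predictors,
        per_predictor_disordered=per_pred,
        venn_counts=venn,
        at_least_k=at_least,
    )


def disorder_fraction(calls: Mapping[str, bool] | Iterable[bool]) -> float:
    """Fraction of breakpoints called disordered (one predictor)."""
    values = list(calls.values()) if isinstance(calls, Mapping) else list(calls)
    if not values:
        raise ValueError("no calls supplied")
    return sum(bool(v) for v in values) / len(values)


def filter_by_length(
    proteins: Iterable[SequenceRecord], min_length: int = MIN_PROTEIN_LENGTH
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split proteins into (kept, flagged-short); nothing is silently dropped."""
    kept, flagged = [], []
    for p in proteins:
        (kept if len(p) >= min_length else flagged).append(p)
    return kept, flagged


def regions_to_dataframe(
    region_sets: Sequence[RegionSet], predictor: str
) -> pd.DataFrame:
    rows = [
        {"sequence_id": rs.sequence_id, "predictor": predictor,
         "start": start, "end": end}
        for rs in region_sets
        for start, end in rs.disordered
    ]
    return pd.DataFrame(rows, columns=["sequence_id", "predictor", "start", "end"])


def consensus_to_dataframe(summary: ConsensusSummary) -> pd.DataFrame:
    """One row per Venn subset (2^k rows), counts summing to n_breakpoints."""
    rows = []
    from itertools import combinations

    for r in range(len(summary.predictors) + 1):
        for subset in combinations(summary.predictors, r):
            rows.append(
                {
                    "predictors": "+".join(subset) if subset else "none",
                    "n_predictors": len(subset),
                    "count": summary.venn_counts.get(subset, 0),
                }
            )
    return pd.DataFrame(rows, columns=["predictors", "n_predictors", "count"])
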