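"""PTM occurrence ratios in disordered vs structured regions of fusion proteins.

Phosphorylation (S/T/Y) and methylation (R/K) sites — ingested from
external predictor output or produced by the bundled motif predictor —
are partitioned by the disorder regions of the protein, and per-residue-
class occurrence ratios are tabulated for the disordered part, the
structured part, and optionally the [-50, +50]-residue window around the
junction.

Two denominator conventions are supported for the "ratio of occurrence":

* ``region`` (default): sites per residue of the region, e.g. the fraction
  of all disordered residues that are predicted phospho-serines;
* ``residue_type``: sites per eligible residue of that class in the
  region, e.g. the fraction of disordered serines that are predicted
  phosphorylated.

Pooling across proteins always sums numerators and denominators —
never averages per-protein ratios.  Disorder/structure contrast per
residue class uses a two-sided Fisher exact test on the 2x2 table of
sites/non-sites x disordered/structured, Benjamini-Hochberg corrected
over the five residue classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .disorder_regions import RegionSet
from .io_formats import (
    PROTEIN,
    PTMSite,
    SequenceRecord,
    ValidationError,
)

RESIDUE_CLASSES = (
    ("S", "phosphorylation"),
    ("T", "phosphorylation"),
    ("Y", "phosphorylation"),
    ("R", "methylation"),
    ("K", "methylation"),
)

DENOM_REGION = "region"
DENOM_RESIDUE_TYPE = "residue_type"
DENOMINATORS = frozenset({DENOM_REGION, DENOM_RESIDUE_TYPE})

#: half-width of the junction window, in residues
JUNCTION_HALF_WINDOW = 50


def bundled_ptm_predict(protein: SequenceRecord) -> list[PTMSite]:
    """Deterministic motif-rule PTM predictor (offline stand-in for
    neural-network/SVM site predictors).

    Rules, applied per residue:

    * phospho-S/T: the S/T is followed by P (proline-directed kinase
      motif), or preceded within 3 residues by R or K (basophilic motif);
    * phospho-Y: the Y is preceded within 2 residues by D or E (acidic
      kinase motif);
    * methyl-R: R in an RG or GR dinucleotide context (RGG/GAR-like);
    * methyl-K: K adjacent to another K.
    """
    if protein.alphabet != PROTEIN:
        raise ValidationError(
            f"PTM prediction requires a protein sequence; {protein.id!r} is "
            f"{protein.alphabet}"
        )
    s = protein.residues
    sites: list[PTMSite] = []
    for i, ch in enumerate(s):  # i is 0-based; positions reported 1-based
        pos = i + 1
        if ch in "ST":
            followed_by_p = i + 1 < len(s) and s[i + 1] == "P"
            basic_upstream = any(c in "RK" for c in s[max(0, i - 3) : i])
            if followed_by_p or basic_upstream:
                sites.append(
                    PTMSite(protein.id, pos, ch, "phosphorylation", score=1.0)
                )
        elif ch == "Y":
            if any(c in "DE" for c in s[max(0, i - 2) : i]):
                sites.append(
                    PTMSite(protein.id, pos, ch, "phosphorylation", score=1.0)
                )
        elif ch == "R":
            if (i > 0 and s[i - 1] == "G") or (i + 1 < len(s) and s[i + 1] == "G"):
                sites.append(PTMSite(protein.id, pos, ch, "methylation", score=1.0))
        elif ch == "K":
            if (i > 0 and s[i - 1] == "K") or (i + 1 < len(s) and s[i + 1] == "K"):
                sites.append(PTMSite(protein.id, pos, ch, "methylation", score=1.0))
    return sites


@dataclass
class ClassCounts:
    """Site and residue counts for one residue class, split by region kind."""

    n_sites_disorder: int = 0
    n_sites_structural: int = 0
    n_residues_disorder: int = 0
    n_residues_structural: int = 0

    def __iadd__(self, other: "ClassCounts") -> "ClassCounts":
        self.n_sites_disorder += other.n_sites_disorder
        self.n_sites_structural += other.n_sites_structural
        self.n_residues_disorder += other.n_residues_disorder
        self.n_residues_structural += other.n_residues_structural
        return self

    @property
    def ratio_disorder(self) -> float:
        return (
            self.n_sites_disorder / self.n_residues_disorder
            if self.n_residues_disorder
            else 0.0
        )

    @property
    def ratio_structural(self) -> float:
        return (
            self.n_sites_structural / self.n_residues_structural
            if self.n_residues_structural
            else 0.0
        )

    @property
    def disorder_defined(self) -> bool:
        return self.n_residues_disorder > 0

    @property
    def structural_defined(self) -> bool:
        return self.n_residues_structural > 0


@dataclass
class PTMEnrichmentTable:
    """Occurrence-ratio table over the five residue classes.

    ``rows`` covers the whole protein(s); ``window_rows`` (when junctions
    were supplied) covers only residues within the +/-50 junction window.
    """

    rows: dict[str, ClassCounts]
    window_rows: dict[str, ClassCounts] | None = None
    denominator: str = DENOM_REGION
    n_proteins: int = 1

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        scopes = [("all", self.rows)]
        if self.window_rows is not None:
            scopes.append(("breakpoint_window", self.window_rows))
        for scope, rows in scopes:
            for residue, modification in RESIDUE_CLASSES:
                cc = rows[residue]
                records.append(
                    {
                        "scope": scope,
                        "residue": residue,
                        "modification": modification,
                        "n_sites_disorder": cc.n_sites_disorder,
                        "n_sites_structural": cc.n_sites_structural,
                        "n_residues_disorder": cc.n_residues_disorder,
                        "n_residues_structural": cc.n_residues_structural,
                        "ratio_disorder": cc.ratio_disorder,
                        "ratio_structural": cc.ratio_structural,
                        "disorder_defined": cc.disorder_defined,
                        "structural_defined": cc.structural_defined,
                    }
                )
        return pd.DataFrame(records)


def _empty_rows() -> dict[str, ClassCounts]:
    return {residue: ClassCounts() for residue, _ in RESIDUE_CLASSES}


def _count_into(
    rows: dict[str, ClassCounts],
    protein: SequenceRecord,
    disorder_mask: np.ndarray,
    site_positions: dict[str, set[int]],
    positions: Iterable[int],
    denominator: str,
) -> None:
    for pos in positions:  # 1-based
        ch = protein.residues[pos - 1]
        in_dis = bool(disorder_mask[pos - 1])
        if denominator == DENOM_REGION:
            # every residue of the region counts in every class denominator
            for residue, _ in RESIDUE_CLASSES:
                cc = rows[residue]
                if in_dis:
                    cc.n_residues_disorder += 1
                else:
                    cc.n_residues_structural += 1
        elif ch in rows:
            cc = rows[ch]
            if in_dis:
                cc.n_residues_disorder += 1
            else:
                cc.n_residues_structural += 1
        if ch in rows and pos in site_positions.get(ch, ()):
            cc = rows[ch]
            if in_dis:
                cc.n_sites_disorder += 1
            else:
                cc.n_sites_structural += 1


def enrichment_table(
    sites: Iterable[PTMSite],
    regions: RegionSet,
    protein: SequenceRecord,
    junction: int | None = None,
    denominator: str = DENOM_REGION,
) -> PTMEnrichmentTable:
    """Tabulate site occurrence ratios for one protein.

    Every residue is classified disordered/structural from ``regions``;
    sites must reference ``protein`` and sit on a matching residue.  When
    ``junction`` is given, a second row set is computed over the window
    [junction - 50, junction + 50] clipped to the sequence bounds.
    """
    if denominator not in DENOMINATORS:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    if regions.sequence_id != protein.id:
        raise ValidationError(
            f"regions are for {regions.sequence_id!r}, protein is {protein.id!r}"
        )
    if regions.length != len(protein):
        raise ValidationError(
            f"regions length {regions.length} != protein length {len(protein)} "
            f"for {protein.id!r}"
        )
    mask = regions.mask()
    site_positions: dict[str, set[int]] = {}
    for site in sites:
        if site.sequence_id != protein.id:
            raise ValidationError(
                f"site references {site.sequence_id!r}, protein is {protein.id!r}"
            )
        site.validate_against(protein)
        site_positions.setdefault(site.residue, set()).add(site.position)

    rows = _empty_rows()
    _count_into(
        rows, protein, mask, site_positions, range(1, len(protein) + 1), denominator
    )
    if denominator == DENOM_REGION:
        cc = rows[RESIDUE_CLASSES[0][0]]
        assert (
            cc.n_residues_disorder + cc.n_residues_structural == len(protein)
        ), "region residue split must conserve protein length"

    window_rows = None
    if junction is not None:
        if not 1 <= junction <= len(protein):
            raise ValidationError(
                f"junction residue {junction} out of range for {protein.id!r}"
            )
        lo = max(1, junction - JUNCTION_HALF_WINDOW)
        hi = min(len(protein), junction + JUNCTION_HALF_WINDOW)
        window_rows = _empty_rows()
        _count_into(
            window_rows, protein, mask, site_positions, range(lo, hi + 1), denominator
        )
    return PTMEnrichmentTable(
        rows=rows, window_rows=window_rows, denominator=denominator
    )


def pool_tables(tables: Sequence[PTMEnrichmentTable]) -> PTMEnrichmentTable:
    """Pool per-protein tables by summing numerators and denominators."""
    if not tables:
        raise ValueError("no tables to pool")
    denoms = {t.denominator for t in tables}
    if len(denoms) > 1:
        raise ValueError(f"cannot pool mixed denominator conventions {denoms}")
    pooled = PTMEnrichmentTable(
        rows=_empty_rows(),
        window_rows=_empty_rows() if any(t.window_rows for t in tables) else None,
        denominator=denoms.pop(),
        n_proteins=len(tables),
    )
    for t in tables:
        for residue, _ in RESIDUE_CLASSES:
            pooled.rows[residue] += t.rows[residue]
            if pooled.window_rows is not None and t.window_rows is not None:
                pooled.window_rows[residue] += t.window_rows[residue]
    return pooled


def compare_classes(table: PTMEnrichmentTable) -> pd.DataFrame:
    """Disorder-vs-structure Fisher exact test per residue class.

    Rows with an empty disordered or structural denominator are flagged
    untested; q-values are Benjamini-Hochberg over the tested rows.
    """
    records = []
    pvals = []
    for residue, modification in RESIDUE_CLASSES:
        cc = table.rows[residue]
        tested = cc.disorder_defined and cc.structural_defined
        rec = {
            "residue": residue,
            "modification": modification,
            "ratio_disorder": cc.ratio_disorder,
            "ratio_structural": cc.ratio_structural,
            "tested": tested,
            "odds_ratio": np.nan,
            "p_value": np.nan,
            "q_value": np.nan,
        }
        if tested:
            table22 = [
                [cc.n_sites_disorder, cc.n_residues_disorder - cc.n_sites_disorder],
                [
                    cc.n_sites_structural,
                    cc.n_residues_structural - cc.n_sites_structural,
                ],
            ]
            odds, p = stats.fisher_exact(table22, alternative="two-sided")
            rec["odds_ratio"] = odds
            rec["p_value"] = p
            pvals.append((len(records), p))
        records.append(rec)
    if pvals:
        idx, ps = zip(*pvals)
        qs = stats.false_discovery_control(np.asarray(ps), method="bh")
        for i, q in zip(idx, qs):
            records[i]["q_value"] = float(q)
    return pd.DataFrame(records)
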