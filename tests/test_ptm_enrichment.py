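"""Bundled PTM prediction, occurrence-ratio tables and the class contrast."""

import numpy as np
import pytest
from scipy import stats

from fusionkit.disorder_regions import RegionSet
from fusionkit.io_formats import PROTEIN, PTMSite, SequenceRecord, ValidationError
from fusionkit.ptm_enrichment import (
    DENOM_REGION,
    DENOM_RESIDUE_TYPE,
    ClassCounts,
    PTMEnrichmentTable,
    bundled_ptm_predict,
    compare_classes,
    enrichment_table,
    pool_tables,
)


def protein(seq_id, residues):
    return SequenceRecord(seq_id, PROTEIN, residues)


class TestBundledPredictor:
    @pytest.mark.parametrize(
        "residues,expected",
        [
            ("ASPG", [(2, "S", "phosphorylation")]),  # S followed by P
            ("ARGA", [(2, "R", "methylation")]),  # RG context
            ("AAAA", []),
            ("RAAS", [(4, "S", "phosphorylation")]),  # basic residue within 3
            ("ADYA", [(3, "Y", "phosphorylation")]),  # acidic residue within 2
            ("AKKA", [(2, "K", "methylation"), (3, "K", "methylation")]),
            ("AGRA", [(3, "R", "methylation")]),  # GR context
            ("AAYA", []),  # Y without an acidic neighbour
        ],
    )
    def test_motif_rules(self, residues, expected):
        sites = bundled_ptm_predict(protein("p", residues))
        assert [(s.position, s.residue, s.modification) for s in sites] == expected

    def test_sites_satisfy_invariants(self):
        prot = protein("p", "MSPKKYRGSDEYTTPRK" * 5)
        for site in bundled_ptm_predict(prot):
            site.validate_against(prot)  # residue identity at stated position


class TestEnrichmentTable:
    def build_protein(self):
        # 100 residues, disordered [1, 50]; serines at fixed positions
        residues = list("A" * 100)
        for pos in (5, 15, 25, 35, 60):
            residues[pos - 1] = "S"
        return protein("p", "".join(residues))

    def sites(self):
        return [
            PTMSite("p", pos, "S", "phosphorylation") for pos in (5, 15, 25, 35, 60)
        ]

    def test_region_denominator_ratios(self):
        prot = self.build_protein()
        # 4 phospho-S in the disordered half, 1 in the structured half:
        # the serine occurrence ratio is higher in disorder, the same
        # direction as the published disorder/structure contrast
        rs = RegionSet("p", ((1, 50),), length=100)
        table = enrichment_table(self.sites()[:4], rs, prot)
        table2 = enrichment_table(self.sites(), rs, prot)
        cc = table2.rows["S"]
        assert cc.n_sites_disorder == 4 and cc.n_sites_structural == 1
        assert cc.ratio_disorder == pytest.approx(4 / 50)
        assert cc.ratio_structural == pytest.approx(1 / 50)
        assert cc.ratio_disorder > cc.ratio_structural
        assert table.rows["S"].n_residues_disorder == 50

    def test_residue_type_denominator(self):
        prot = self.build_protein()
        rs = RegionSet("p", ((1, 50),), length=100)
        cc = enrichment_table(
            self.sites(), rs, prot, denominator=DENOM_RESIDUE_TYPE
        ).rows["S"]
        assert cc.n_residues_disorder == 4 and cc.n_residues_structural == 1
        assert cc.ratio_disorder == 1.0 and cc.ratio_structural == 1.0

    def test_no_disordered_regions_is_flagged(self):
        prot = self.build_protein()
        rs = RegionSet("p", (), length=100)
        table = enrichment_table(self.sites(), rs, prot)
        assert not table.rows["S"].disorder_defined
        assert table.rows["S"].ratio_disorder == 0.0

    def test_junction_window_is_clipped(self):
        prot = self.build_protein()
        rs = RegionSet("p", ((1, 50),), length=100)
        table = enrichment_table(self.sites(), rs, prot, junction=10)
        cc = table.window_rows["S"]
        # window [1, 60] -> 50 disordered + 10 structured residues
        assert cc.n_residues_disorder == 50
        assert cc.n_residues_structural == 10
        assert cc.n_sites_disorder == 4 and cc.n_sites_structural == 1

    def test_site_residue_mismatch_errors(self):
        prot = self.build_protein()
        rs = RegionSet("p", ((1, 50),), length=100)
        with pytest.raises(ValidationError):
            enrichment_table(
                [PTMSite("p", 2, "S", "phosphorylation")], rs, prot
            )

    def test_residue_conservation_on_random_proteins(self, rng):
        for _ in range(20):
            n = int(rng.integers(50, 200))
            residues = "".join(rng.choice(list("ASTYRKLIVE"), size=n))
            prot = protein("p", residues)
            start = int(rng.integers(1, n))
            end = int(rng.integers(start, n + 1))
            rs = RegionSet("p", ((start, end),), length=n)
            cc = enrichment_table([], rs, prot).rows["S"]
            assert cc.n_residues_disorder + cc.n_residues_structural == n


class TestPooling:
    def test_pooling_sums_counts_never_averages_ratios(self, rng):
        tables = []
        raw = []
        for _ in range(10):
            cc = ClassCounts(
                n_sites_disorder=int(rng.integers(0, 10)),
                n_sites_structural=int(rng.integers(0, 10)),
                n_residues_disorder=int(rng.integers(10, 100)),
                n_residues_structural=int(rng.integers(10, 100)),
            )
            raw.append(cc)
            rows = {r: ClassCounts() for r in "STYRK"}
            rows["S"] = cc
            tables.append(PTMEnrichmentTable(rows=rows))
        pooled = pool_tables(tables).rows["S"]
        assert pooled.n_sites_disorder == sum(c.n_sites_disorder for c in raw)
        assert pooled.n_residues_disorder == sum(c.n_residues_disorder for c in raw)
        expected = sum(c.n_sites_disorder for c in raw) / sum(
            c.n_residues_disorder for c in raw
        )
        assert pooled.ratio_disorder == pytest.approx(expected)

    def test_mixed_denominators_rejected(self):
        rows = {r: ClassCounts() for r in "STYRK"}
        with pytest.raises(ValueError):
            pool_tables(
                [
                    PTMEnrichmentTable(rows=dict(rows), denominator=DENOM_REGION),
                    PTMEnrichmentTable(
                        rows=dict(rows), denominator=DENOM_RESIDUE_TYPE
                    ),
                ]
            )


class TestCompareClasses:
    def table_with(self, s_counts):
        rows = {r: ClassCounts() for r in "STYRK"}
        rows["S"] = s_counts
        return PTMEnrichmentTable(rows=rows)

    def test_equal_ratios_are_null(self):
        table = self.table_with(ClassCounts(20, 20, 500, 500))
        row = compare_classes(table).set_index("residue").loc["S"]
        assert row["p_value"] > 0.9

    def test_fisher_detects_contrast(self):
        # hand-checkable 2x2: 40/500 vs 15/500
        table = self.table_with(ClassCounts(40, 15, 500, 500))
        row = compare_classes(table).set_index("residue").loc["S"]
        expected = stats.fisher_exact([[40, 460], [15, 485]]).pvalue
        assert row["p_value"] == pytest.approx(expected)
        assert row["p_value"] < 0.01

    def test_empty_class_is_flagged_untested(self):
        table = self.table_with(ClassCounts(0, 5, 0, 500))
        row = compare_classes(table).set_index("residue").loc["S"]
        assert not row["tested"] and np.isnan(row["p_value"])
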