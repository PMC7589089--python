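"""Codon-usage tables, the virus/host ratio, and favorability classification."""

import numpy as np
import pandas as pd
import pytest

from chlorotrna.cub import (
    CubError,
    FavorabilityParams,
    classify_favorability,
    codon_frequencies,
    cub_ratio,
    gc_content,
    preferred_codons,
    round_half_up,
    tils_benefit,
)
from chlorotrna.genetic import SENSE_CODONS_DNA, rna
from chlorotrna.trna import TrnaGene, TrnaIdentity


def _gene(aa, codon, n=1):
    from chlorotrna.genetic import revcomp_rna

    return [
        TrnaGene(identity=TrnaIdentity(aa, codon), anticodon=revcomp_rna(codon),
                 start=100 * i + 1, end=100 * i + 73, strand="+")
        for i in range(n)
    ]


class TestCodonFrequencies:
    def test_terminal_stop_excluded_and_percentages(self):
        t = codon_frequencies(["ATGAAAAAATAA"])
        assert t.total_codons == 3
        assert t["AUG"] == pytest.approx(100 / 3)
        assert t["AAA"] == pytest.approx(200 / 3)

    def test_uniform_over_all_61_sense_codons(self):
        seq = "".join(SENSE_CODONS_DNA) + "TAA"
        t = codon_frequencies([seq])
        assert all(t[rna(c)] == pytest.approx(100 / 61) for c in SENSE_CODONS_DNA)

    def test_internal_stops_counted_in_qc_channel_only(self):
        t = codon_frequencies(["ATGTAAAAATAA"])
        assert t.internal_stops == 1
        assert t.total_codons == 2  # ATG + AAA

    def test_ambiguous_codons_skipped(self):
        t = codon_frequencies(["ATGNNNAAA"])
        assert t.total_codons == 2

    def test_empty_input_rejected(self):
        with pytest.raises(CubError):
            codon_frequencies([])

    def test_computed_tables_sum_to_100(self, host_sim):
        record, _ = host_sim
        cds = [record.feature_sequence(f) for f in record.features if f.kind == "CDS"]
        t = codon_frequencies(cds)
        assert t.sum == pytest.approx(100.0, abs=1e-9)

    def test_scale_invariance(self):
        base = ["ATGAAATTTGGGCCC" * 3 + "TAA"]
        t1 = codon_frequencies(base)
        t2 = codon_frequencies(base * 7)
        pd.testing.assert_series_equal(t1.frequencies, t2.frequencies)

    def test_monte_carlo_recovery_of_host_column(self, cu_tables):
        """100k codons sampled from the host table recover each frequency
        within 3 sigma of its binomial sampling error."""
        _, _, host, _ = cu_tables
        rng = np.random.default_rng(2024)
        probs = host.frequencies / host.frequencies.sum()
        n = 100_000
        draw = rng.choice(probs.index.to_numpy(), size=n, p=probs.to_numpy())
        seq = "".join(c.replace("U", "T") for c in draw) + "TAA"
        t = codon_frequencies([seq])
        for codon, p in probs.items():
            sigma_pp = 100 * np.sqrt(p * (1 - p) / n)
            assert abs(t[codon] - 100 * p) <= 3 * sigma_pp + 1e-9, codon


class TestGcContent:
    def test_pure_gc_and_pure_at(self):
        assert gc_content("GGCC") == 100.0
        assert gc_content("ATAT") == 0.0

    def test_ambiguous_bases_excluded(self):
        assert gc_content("GCNN") == 100.0
        with pytest.raises(CubError):
            gc_content("NNNN")

    def test_simulated_virus_hits_its_gc_target(self, nc64a_sim):
        record, _ = nc64a_sim
        assert abs(gc_content(record) - 40.0) <= 1.5


class TestCubRatio:
    def test_identity_tables_give_unit_ratio(self, cu_tables):
        _, _, host, _ = cu_tables
        r = cub_ratio([host, host], host)
        defined = r.table["ratio"].dropna()
        assert np.allclose(defined, 1.0)

    def test_printed_aua_ratio_reproduced(self, ratio_table):
        assert round_half_up(ratio_table.ratio("AUA")) == 12.70

    def test_gau_follows_the_formula_not_the_misprint(self, ratio_table):
        # (3.02 + 1.91)/2 / 1.06 = 2.33; the printed 4.56 is a documented erratum
        assert round_half_up(ratio_table.ratio("GAU")) == 2.33

    def test_host_zero_frequency_is_flagged_undefined(self, cu_tables):
        pbcv1, _, host, _ = cu_tables
        zeroed = host.frequencies.copy()
        zeroed["AUA"] = 0.0
        from chlorotrna.cub import CodonUsageTable

        r = cub_ratio([pbcv1], CodonUsageTable(frequencies=zeroed, total_codons=0))
        assert "AUA" in r.undefined
        with pytest.raises(CubError):
            r.ratio("AUA")

    def test_single_virus_table_degrades_gracefully(self, cu_tables):
        pbcv1, _, host, _ = cu_tables
        r = cub_ratio(pbcv1, host)
        assert r.ratio("AUA") == pytest.approx(2.44 / 0.20)


class TestPreferredCodons:
    def test_host_prefers_gc_rich_gly_codon(self, cu_tables):
        _, _, host, _ = cu_tables
        assert preferred_codons(host)["G"] == {"GGC"}

    def test_virus_prefers_at_rich_glu_codon(self, cu_tables):
        pbcv1, _, _, _ = cu_tables
        assert preferred_codons(pbcv1)["E"] == {"GAA"}

    def test_uniform_table_reports_ties(self):
        from chlorotrna.cub import CodonUsageTable

        uniform = CodonUsageTable(
            frequencies=pd.Series(100 / 61, index=[rna(c) for c in SENSE_CODONS_DNA]),
            total_codons=61,
        )
        best = preferred_codons(uniform)
        assert all(len(v) > 1 for aa, v in best.items() if aa not in ("M", "W"))


class TestFavorability:
    def test_pbcv1_seven_of_eight_codons_assist(self, cohort, ratio_table):
        inventories, _ = cohort
        report = classify_favorability(inventories["PBCV-1"], ratio_table)
        assert set(report.recognized_codons) == {
            "UUG", "AUA", "AAC", "UUA", "AGA", "AAG", "AAA", "UAC"
        }
        assert report.assisting_count == 7
        assert report.neutral == ["AAG"]  # R = 0.87 favors the host

    def test_all_ratios_above_one_makes_every_codon_assist(self, cu_tables):
        pbcv1, _, host, _ = cu_tables
        doubled = pbcv1.frequencies * 0 + host.frequencies * 2
        from chlorotrna.cub import CodonUsageTable

        r = cub_ratio([CodonUsageTable(frequencies=doubled, total_codons=0)], host)
        genes = _gene("Asn", "AAC") + _gene("Tyr", "UAC")
        report = classify_favorability(genes, r)
        assert len(report.assisting) == len(report.recognized_codons)

    def test_per_gene_counting_counts_copies(self, ratio_table):
        genes = _gene("Asn", "AAC", n=3)
        distinct = classify_favorability(genes, ratio_table)
        per_gene = classify_favorability(
            genes, ratio_table, FavorabilityParams(counting="per_gene")
        )
        assert distinct.assisting_count == 1
        assert per_gene.assisting_count == 3

    def test_pseudogenes_excluded_with_warning(self, ratio_table):
        from dataclasses import replace

        genes = _gene("Asn", "AAC") + [replace(_gene("Tyr", "UAC")[0], pseudogene=True)]
        with pytest.warns(UserWarning, match="excluded"):
            report = classify_favorability(genes, ratio_table)
        assert report.gene_count == 1
        assert report.excluded_genes == 1

    def test_wobble_expands_the_recognized_set(self, cohort, ratio_table):
        inventories, _ = cohort
        strict = classify_favorability(inventories["PBCV-1"], ratio_table)
        wob = classify_favorability(
            inventories["PBCV-1"], ratio_table, FavorabilityParams(use_wobble=True)
        )
        assert set(wob.recognized_codons) > set(strict.recognized_codons)
        assert "UAU" in wob.recognized_codons  # G34 tRNA-Tyr reads UAU too


class TestTilsBenefit:
    def test_aua_ratio_is_assisting(self, ratio_table):
        codon, ratio, label = tils_benefit(ratio_table)
        assert codon == "AUA"
        assert round_half_up(ratio) == 12.70
        assert label == "assisting"

    def test_identical_tables_sit_on_the_boundary(self, cu_tables):
        _, _, host, _ = cu_tables
        r = cub_ratio([host], host)
        assert tils_benefit(r)[2] == "boundary"

    def test_zero_host_aua_is_an_error(self, cu_tables):
        pbcv1, _, host, _ = cu_tables
        zeroed = host.frequencies.copy()
        zeroed["AUA"] = 0.0
        from chlorotrna.cub import CodonUsageTable

        r = cub_ratio([pbcv1], CodonUsageTable(frequencies=zeroed, total_codons=0))
        with pytest.raises(CubError):
            tils_benefit(r)
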