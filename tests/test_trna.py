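"""Anticodon/codon semantics, wobble, TilS, introns, promoter boxes,
inventory construction."""

import itertools

import numpy as np
import pytest

from chlorotrna.annotations import GenomeRecord, GenomicFeature
from chlorotrna.simulate import generate_trna_gene_sequence
from chlorotrna.trna import (
    BoxMotifConfig,
    TrnaError,
    TrnaGene,
    TrnaIdentity,
    WobbleRules,
    anticodon_to_codon,
    apply_tils,
    build_inventory,
    detect_cca_end,
    find_polIII_boxes,
    intron_geometry,
    wobble_recognition_set,
)

ALL_TRIPLETS = ["".join(t) for t in itertools.product("ACGU", repeat=3)]


class TestAnticodonCodon:
    def test_met_anticodon_cau_reads_aug(self):
        # 5'-CAU-3' anticodon is 3'-UAC-5' against the mRNA: codon AUG
        assert anticodon_to_codon("CAU") == "AUG"

    def test_tyr_anticodon_gua_reads_uac(self):
        assert anticodon_to_codon("GUA") == "UAC"

    def test_involution_on_all_64_triplets(self):
        for t in ALL_TRIPLETS:
            assert anticodon_to_codon(anticodon_to_codon(t)) == t

    def test_non_rna_characters_rejected(self):
        with pytest.raises(TrnaError):
            anticodon_to_codon("CXU")


class TestWobble:
    def test_g34_tyr_reads_both_tyrosine_codons(self):
        assert wobble_recognition_set("GUA") == {"UAC", "UAU"}

    def test_c34_met_does_not_wobble(self):
        assert wobble_recognition_set("CAU") == {"AUG"}

    def test_disabled_wobble_gives_watson_crick_singleton(self):
        rules = WobbleRules(enabled=False)
        for t in ALL_TRIPLETS:
            assert wobble_recognition_set(t, rules) == {anticodon_to_codon(t)}

    def test_wobble_set_is_superset_of_strict_set(self):
        strict = WobbleRules(enabled=False)
        for t in ALL_TRIPLETS:
            assert wobble_recognition_set(t) >= wobble_recognition_set(t, strict)

    def test_pairings_must_include_watson_crick_partner(self):
        with pytest.raises(TrnaError):
            WobbleRules(pairings={"G": frozenset({"U"})})


class TestTils:
    def _met(self):
        return TrnaGene(
            identity=TrnaIdentity("Met", "AUG"), anticodon="CAU",
            start=100, end=172, strand="+",
        )

    def test_recoded_met_reads_ile_codon_aua_only(self):
        recoded = apply_tils(self._met())
        assert recoded.identity == TrnaIdentity("Ile", "AUA")
        assert recoded.recognition_set() == {"AUA"}
        assert recoded.recognition_set(WobbleRules()) == {"AUA"}

    def test_original_gene_unmodified(self):
        gene = self._met()
        apply_tils(gene)
        assert gene.identity.amino_acid == "Met"
        assert gene.recognition_set() == {"AUG"}

    def test_non_met_substrate_rejected(self):
        tyr = TrnaGene(identity=TrnaIdentity("Tyr", "UAC"), anticodon="GUA",
                       start=1, end=73, strand="+")
        with pytest.raises(TrnaError):
            apply_tils(tyr)

    def test_double_application_rejected(self):
        with pytest.raises(TrnaError):
            apply_tils(apply_tils(self._met()))


class TestIntronGeometry:
    @pytest.mark.parametrize("length", [10, 11, 13, 14])
    def test_recovers_offset_and_length_exactly(self, length):
        seq, exons = generate_trna_gene_sequence(
            "Tyr", "GUA", intron=(1, length), rng=np.random.default_rng(length)
        )
        gene = TrnaGene(identity=TrnaIdentity("Tyr", "UAC"), anticodon="GUA",
                        start=1, end=len(seq), strand="+", sequence=seq,
                        exons_local=exons)
        assert intron_geometry(gene) == (1, length)

    def test_single_exon_gene_has_no_intron(self):
        seq, exons = generate_trna_gene_sequence("Tyr", "GUA")
        gene = TrnaGene(identity=TrnaIdentity("Tyr", "UAC"), anticodon="GUA",
                        start=1, end=len(seq), strand="+", sequence=seq)
        assert intron_geometry(gene) is None

    def test_unlocatable_anticodon_is_an_error(self):
        gene = TrnaGene(identity=TrnaIdentity("Tyr", "UAC"), anticodon="GUA",
                        start=1, end=20, strand="+", sequence="A" * 30,
                        exons_local=[(1, 10), (21, 30)])
        with pytest.raises(TrnaError):
            intron_geometry(gene)


class TestPromoterBoxes:
    def test_embedded_consensus_found_verbatim_a_before_b(self):
        seq, _ = generate_trna_gene_sequence("Gly", "UCC")
        hits = find_polIII_boxes(seq, BoxMotifConfig(max_mismatches=0))
        assert hits == [("A", 7, 0), ("B", 52, 0)]

    def test_boxless_random_sequence_yields_no_hits(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("AC"), size=200))  # cannot match either box
        assert find_polIII_boxes(seq, BoxMotifConfig(max_mismatches=0)) == []

    def test_sequence_shorter_than_window_yields_no_hits(self):
        assert find_polIII_boxes("ACGTACGTAC") == []


class TestCcaEnd:
    def test_generated_genes_lack_cca(self):
        seq, _ = generate_trna_gene_sequence("Gly", "UCC")
        gene = TrnaGene(identity=TrnaIdentity("Gly", "GGA"), anticodon="UCC",
                        start=1, end=len(seq), strand="+", sequence=seq)
        assert detect_cca_end(gene) is False

    def test_cca_terminated_sequence_detected(self):
        gene = TrnaGene(identity=None, anticodon=None, start=1, end=9,
                        strand="+", sequence="GGTCCA")
        assert detect_cca_end(gene) is True

    def test_strand_symmetry(self, nc64a_sim):
        record, _ = nc64a_sim
        inv = build_inventory(record)
        plus = inv[0]
        flipped = GenomeRecord(
            id="flip", clade="x", sequence=record.sequence,
            features=[
                GenomicFeature("f", "tRNA", plus.start, plus.end, "-",
                               qualifiers={"product": "tRNA-Leu",
                                           "anticodon": "caa"})
            ],
        )
        minus = build_inventory(flipped)[0]
        # the minus-strand twin reads the reverse complement region; its CCA
        # status is judged on its own coding strand
        assert detect_cca_end(minus) == detect_cca_end(
            TrnaGene(identity=None, anticodon=None, start=1, end=plus.length,
                     strand="+", sequence=flipped.feature_sequence(flipped.features[0]))
        )


class TestBuildInventory:
    def test_recovers_generator_truth_completely(self, nc64a_sim):
        record, truth = nc64a_sim
        inv = build_inventory(record)
        assert [g.label for g in inv] == [g.label for g in truth.genes]
        assert [g.anticodon for g in inv] == [g.anticodon for g in truth.genes]
        assert [g.pseudogene for g in inv] == [g.pseudogene for g in truth.genes]
        for got, want in zip(inv, truth.genes):
            geom = intron_geometry(got) if got.exons_local else None
            assert geom == (
                (want.intron_offset, want.intron_length)
                if want.intron_length
                else None
            )

    def test_genome_without_trnas_gives_empty_inventory(self, host_sim):
        record, _ = host_sim
        assert build_inventory(record) == []

    def test_pseudogene_flag_propagates(self):
        seq, _ = generate_trna_gene_sequence("Asn", "GUU", pseudogene=True)
        rec = GenomeRecord(
            id="p", clade="x", sequence="T" * 50 + seq + "T" * 50,
            features=[GenomicFeature("f", "tRNA", 51, 50 + len(seq), "+",
                                     qualifiers={"product": "tRNA-Asn",
                                                 "anticodon": "gtt",
                                                 "pseudo": ""})],
        )
        inv = build_inventory(rec)
        assert len(inv) == 1 and inv[0].pseudogene
        assert inv[0].recognition_set() == frozenset()

    def test_identity_from_product_string_when_anticodon_missing(self):
        rec = GenomeRecord(
            id="q", clade="x", sequence="A" * 200,
            features=[GenomicFeature("f", "tRNA", 10, 82, "+",
                                     qualifiers={"product": "tRNA-Tyr (GTA)"})],
        )
        inv = build_inventory(rec)
        assert inv[0].identity == TrnaIdentity("Tyr", "UAC")
        assert inv[0].anticodon == "GUA"

    def test_unresolvable_identity_warns_and_is_kept(self):
        rec = GenomeRecord(
            id="u", clade="x", sequence="A" * 200,
            features=[GenomicFeature("f", "tRNA", 10, 82, "+",
                                     qualifiers={"product": "mystery RNA"})],
        )
        with pytest.warns(UserWarning, match="identity-unknown"):
            inv = build_inventory(rec)
        assert len(inv) == 1 and inv[0].identity is None

    def test_inventory_is_order_stable_under_feature_permutation(self, nc64a_sim):
        record, _ = nc64a_sim
        shuffled = GenomeRecord(
            id=record.id, clade=record.clade, sequence=record.sequence,
            features=list(reversed(record.features)),
        )
        assert [g.start for g in build_inventory(shuffled)] == [
            g.start for g in build_inventory(record)
        ]
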