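"""Gene naming, fixtures, and file round-trips."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitorder import mtio
from mitorder.gene_order import GeneOrder
from mitorder.mtio import (
    VOCABULARY,
    GeneAnnotation,
    MitoGenome,
    UnknownGeneError,
    canonical_name,
    fixture_order,
    read_orders,
    write_orders,
)
from mitorder.synthetic_data import SimulationConfig, simulate_genome


class TestCanonicalName:
    @pytest.mark.parametrize(
        "raw,anticodon,expected",
        [
            ("COI", None, "cox1"),
            ("cox1", None, "cox1"),
            ("ND4L", None, "nad4L"),
            ("CYTB", None, "cob"),
            ("ATPase 6", None, "atp6"),
            ("16S ribosomal RNA", None, "rrnL"),
            ("12S rRNA", None, "rrnS"),
            ("D-loop", None, "CR"),
            ("control region", None, "CR"),
            ("tRNA-Ala", None, "trnA"),
            ("tRNA-Leu", "UAG", "trnL1"),  # UAG anticodon decodes CUN codons
            ("tRNA-Leu", "UAA", "trnL2"),
            ("tRNA-Leu(CUN)", None, "trnL1"),
            ("tRNA-Leu(UUR)", None, "trnL2"),
            ("tRNA-Ser(AGN)", None, "trnS1"),
            ("tRNA-Ser", "UGA", "trnS2"),
            ("L1", None, "trnL1"),
            ("S2", None, "trnS2"),
        ],
    )
    def test_synonym_mapping(self, raw, anticodon, expected):
        assert canonical_name(raw, anticodon) == expected

    @pytest.mark.parametrize("token", sorted(VOCABULARY))
    def test_idempotent_on_canonical_tokens(self, token):
        assert canonical_name(token) == token

    @pytest.mark.parametrize(
        "raw,anticodon",
        [("tRNA-Xle", None), ("tRNA-Leu", None), ("tRNA-Ser", None),
         ("tRNA", None), ("frobnicase", None), ("tRNA-Leu", "GGG")],
    )
    def test_rejects_unmappable_and_ambiguous(self, raw, anticodon):
        with pytest.raises(UnknownGeneError):
            canonical_name(raw, anticodon)


class TestFixtures:
    def test_vocabulary_has_38_tokens(self):
        assert len(VOCABULARY) == 38

    @pytest.mark.parametrize("key", ["ground_pattern", "thalassina", "gebiidea", "axiidea"])
    def test_each_fixture_covers_vocabulary_once(self, key):
        order = fixture_order(key)
        names = [g for g, _ in order.elements]
        assert sorted(names) == sorted(VOCABULARY)

    def test_thalassina_retains_ground_pattern(self, gp):
        assert fixture_order("thalassina") == gp

    def test_rrna_separation_differs_between_infraorders(self, gebiidea, axiidea):
        # Gebiidea keeps trnV between the rRNAs; in Axiidea they are adjacent
        def neighbors(order, gene):
            names = [g for g, _ in order.elements]
            i = names.index(gene)
            return {names[i - 1], names[(i + 1) % len(names)]}

        assert "trnV" in neighbors(gebiidea, "rrnL") | neighbors(gebiidea, "rrnS")
        assert "rrnS" in neighbors(axiidea, "rrnL")

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError):
            fixture_order("upogebia")


class TestGenBankRoundTrip:
    def test_synthetic_record_round_trips(self, truth_seed1, tmp_path):
        path = tmp_path / "genome.gb"
        mtio.write_genbank(truth_seed1.genome, path)
        back = mtio.read_genbank(path)
        assert back.sequence == truth_seed1.genome.sequence
        original = sorted(truth_seed1.genome.annotations, key=lambda a: a.start)
        assert [(a.name, a.start, a.end, a.strand) for a in back.annotations] == [
            (a.name, a.start, a.end, a.strand) for a in original
        ]

    def test_origin_spanning_feature_round_trips(self, tmp_path):
        truth = simulate_genome(SimulationConfig(seed=3, origin_offset=40))
        first = truth.genome.annotations[-1]
        assert any(a.end > len(truth.genome) for a in truth.genome.annotations)
        path = tmp_path / "wrapped.gb"
        mtio.write_genbank(truth.genome, path)
        back = mtio.read_genbank(path)
        wrapped = [a for a in back.annotations if a.end > len(back)]
        assert wrapped, "wrap across the origin was lost"
        assert back.sequence == truth.genome.sequence

    def test_unmapped_features_are_reported_not_dropped(self, truth_seed1, tmp_path):
        path = tmp_path / "extra.gb"
        mtio.write_genbank(truth_seed1.genome, path)
        text = path.read_text()
        extra = (
            '     misc_feature    1..10\n'
            '                     /note="mystery ORF"\n'
        )
        marker = "ORIGIN"
        text = text.replace(marker, extra + marker, 1)
        path.write_text(text)
        with pytest.warns(UserWarning, match="unmappable"):
            back = mtio.read_genbank(path)
        assert ("misc_feature", "mystery ORF") in back.unmapped


class TestOrderTextFormat:
    def test_round_trip_with_comments(self, gp, gebiidea, tmp_path):
        path = tmp_path / "orders.txt"
        write_orders({"GP": gp, "GEB": gebiidea}, path)
        text = "# derived orders\n" + path.read_text()
        path.write_text(text)
        back = read_orders(path)
        assert back["GP"] == gp and back["GEB"] == gebiidea


class TestMitoGenomeValidation:
    def test_duplicate_annotation_rejected(self):
        genome = MitoGenome(
            "x",
            "ACGT" * 30,
            [GeneAnnotation("cox1", 0, 10, "+"), GeneAnnotation("cox1", 20, 30, "+")],
        )
        with pytest.raises(ValueError, match="duplicate"):
            genome.validate(complete=False)

    def test_incomplete_genome_needs_relax(self):
        genome = MitoGenome("x", "ACGT" * 30, [GeneAnnotation("cox1", 0, 10, "+")])
        with pytest.raises(ValueError, match="lacks"):
            genome.validate(complete=True)
        genome.validate(complete=False)

    @given(st.integers(min_value=0, max_value=119))
    @settings(max_examples=25, deadline=None)
    def test_rotation_preserves_feature_sequences(self, offset):
        genome = MitoGenome(
            "x",
            "ACGTTGCA" * 15,
            [GeneAnnotation("cox1", 5, 40, "+"), GeneAnnotation("nad5", 60, 100, "-")],
        )
        rotated = mtio.rotate_genome(genome, offset)
        assert rotated.feature_sequence("cox1") == genome.feature_sequence("cox1")
        assert rotated.feature_sequence("nad5") == genome.feature_sequence("nad5")
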