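"""Built-in assay definitions, variant application, and catalog I/O."""

import numpy as np
import pytest

from pyrocall import (
    Assay,
    CatalogValidationError,
    DispensationOrder,
    InvalidInputError,
    MutationVariant,
    Substitution,
    UnknownAssayError,
    apply_variant,
    builtin_assays,
    expected_pattern,
    get_assay,
    load_catalog,
    mixture_pattern,
    reference_position_map,
    reference_positions,
    save_catalog,
    unexpected_positions,
)
from pyrocall.catalog import derive_unexpected_positions

# Targeted sequences and dispensation orders as printed in the assay design.
PRINTED_DESIGN = {
    "EGFR_ex18_719": ("DSCTCCGGTGC", "CATGTCACTCGTG"),
    "EGFR_ex19_del": ("TATCAA[GGAATTAAGAGAAGC]AACATCTCCGAAAGCCA", "CTATCACTGTCAGCTCGATCGTCATCGTCACGC"),
    "EGFR_ex20_768": ("CAGCGTGGACAACCCCCACG", "GCAGTACGTGTCGTGTACGTGACCACACTG"),
    "EGFR_ex20_T790": ("ATCAYG", "GATTCATCTG"),
    "EGFR_ex21": ("CKGGCCAAACDGCTGGGT", "ACGTGTCACATGTC"),
    "KRAS_12_13": ("NNTGRCGTAGGC", "ACTGTACGTGATCGTAGCAAGAG"),
    "KRAS_61": ("CTCDTGACCTG", "GCTCGATACGACCT"),
    "BRAF_600": ("CWCTGTAG", "TCGTATCTGTAG"),
}


class TestBuiltinCatalog:
    def test_eight_assays(self):
        assert len(builtin_assays()) == 8

    def test_targets_and_orders_match_printed_design(self, assays):
        assert set(assays) == set(PRINTED_DESIGN)
        for name, (target, order) in PRINTED_DESIGN.items():
            assert assays[name].target == target
            assert assays[name].order.bases == order

    @pytest.mark.parametrize(
        "name,wildtype",
        [
            ("EGFR_ex21", "CTGGCCAAACTGCTGGGT"),
            ("BRAF_600", "CACTGTAG"),
            ("KRAS_12_13", "GGTGGCGTAGGC"),
            ("EGFR_ex20_T790", "ATCACG"),
        ],
    )
    def test_wildtype_reads(self, assays, name, wildtype):
        assert assays[name].wildtype_read == wildtype

    def test_unknown_assay_lookup(self):
        with pytest.raises(UnknownAssayError):
            get_assay("HRAS_61")

    def test_exon19_ships_ten_deletion_variants(self, assays):
        assert len(assays["EGFR_ex19_del"].variants) == 10


class TestApplyVariant:
    @pytest.mark.parametrize(
        "name,vid,mutant",
        [
            ("EGFR_ex21", "L858R", "CGGGCCAAACTGCTGGGT"),
            ("BRAF_600", "V600E", "CTCTGTAG"),
            ("BRAF_600", "V600K", "CTTTGTAG"),
            ("EGFR_ex19_del", "E746_A750del", "TATCAA" + "AACATCTCCGAAAGCCA"),
        ],
    )
    def test_catalog_edits(self, assays, name, vid, mutant):
        assay = assays[name]
        assert apply_variant(assay, assay.variant_by_id(vid)).sequence == mutant

    def test_foreign_variant_rejected(self, assays):
        stray = MutationVariant(id="X999Y", edit=Substitution(position=1, new="T"))
        with pytest.raises(InvalidInputError):
            apply_variant(assays["BRAF_600"], stray)

    def test_out_of_range_edit_rejected(self):
        assay = Assay(
            name="toy",
            target="ACGT",
            order=DispensationOrder("ACGT"),
            variants=(MutationVariant(id="bad", edit=Substitution(position=9, new="A")),),
        )
        with pytest.raises(InvalidInputError, match="out of range"):
            apply_variant(assay, assay.variants[0])

    def test_every_builtin_variant_differs_from_wildtype_only_at_its_edit(self, assays):
        """Pairwise-distinct reads and patterns across each assay's catalog."""
        for assay in assays.values():
            reads = {None: assay.wildtype_read}
            for v in assay.variants:
                reads[v.id] = apply_variant(assay, v).sequence
            assert len(set(reads.values())) == len(reads)
            patterns = {k: tuple(expected_pattern(assay, k)) for k in reads}
            assert len(set(patterns.values())) == len(patterns)


class TestReferenceAndUnexpectedPositions:
    def test_braf_unexpected_is_1_3_6_both_explicit_and_derived(self, assays):
        braf = assays["BRAF_600"]
        assert unexpected_positions(braf) == {1, 3, 6}
        assert derive_unexpected_positions(braf) == {1, 3, 6}

    def test_exon21_unexpected_derivation(self, assays):
        assert unexpected_positions(assays["EGFR_ex21"]) == {1, 6, 13}

    def test_all_builtin_unexpected_sets_nonempty(self, assays):
        for assay in assays.values():
            assert unexpected_positions(assay)

    def test_fully_consumed_assay_has_no_unexpected_positions(self):
        assay = Assay(name="toy", target="ACGT", order=DispensationOrder("ACGT"))
        assert unexpected_positions(assay) == frozenset()

    def test_reference_positions_are_single_copy_under_every_hypothesis(self, assays):
        """B calibrates on peaks of expected height exactly 1, whatever the
        specimen's true mutation and mutant fraction."""
        for assay in assays.values():
            ref_map = reference_position_map(assay)
            for key, positions in ref_map.items():
                assert positions, f"{assay.name}/{key} has no reference positions"
                vid = None if key == "wildtype" else key
                for p in positions:
                    assert expected_pattern(assay)[p - 1] == 1
                    if vid is not None:
                        assert expected_pattern(assay, vid)[p - 1] == 1
                        mid = mixture_pattern(assay, vid, 0.37)
                        assert mid[p - 1] == pytest.approx(1.0, abs=1e-12)

    def test_exon21_reference_positions_follow_the_published_set(self, assays):
        assert assays["EGFR_ex21"].reference_positions == {2, 9, 11, 12, 14}
        # position 11 is altered by L861Q, so the fitting set drops it
        assert reference_positions(assays["EGFR_ex21"], "L861Q") == {2, 9, 12, 14}


class TestCatalogIO:
    def test_round_trip_identity(self, assays, tmp_path):
        path = tmp_path / "catalog.json"
        save_catalog(builtin_assays(), path)
        assert load_catalog(path) == builtin_assays()

    def test_reference_position_of_height_two_rejected(self, tmp_path):
        import json

        bad = [
            {
                "name": "toy",
                "target": "AACGT",
                "dispensation_order": "ACGT",
                "reference_positions": [1],  # AA run: expected height 2
                "variants": [],
            }
        ]
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(bad))
        with pytest.raises(CatalogValidationError, match="must be exactly 1"):
            load_catalog(path)

    def test_missing_order_and_bad_edit_reported_together(self, tmp_path):
        import json

        bad = [
            {"name": "a", "target": "ACGT", "variants": []},
            {
                "name": "b",
                "target": "ACGT",
                "dispensation_order": "ACGT",
                "variants": [{"id": "v1", "edit": {"type": "frameshift"}}],
            },
        ]
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(bad))
        with pytest.raises(CatalogValidationError) as err:
            load_catalog(path)
        failures = "\n".join(err.value.failures)
        assert "dispensation_order" in failures and "edit type" in failures
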