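"""Quantification formula, least-squares fitting, ranking, and the final call."""

import numpy as np
import pytest

from pyrocall import (
    Assay,
    DegenerateSignalError,
    DispensationOrder,
    InvalidInputError,
    MutationVariant,
    Pyrogram,
    QuantPeaks,
    Substitution,
    UndefinedFractionError,
    call_specimen,
    exon21_quant_peaks,
    fit_candidate,
    mixture_pattern,
    quant_l858r,
    rank_candidates,
    v600k_discriminator,
)
from pyrocall.caller import MUTATION_DETECTED, WILDTYPE, INDETERMINATE
from pyrocall.preprocess import ReferenceStats

# The printed 23-dispensation KRAS codon-12/13 pyrogram carrying 47% G12C.
KRAS_47_HEIGHTS = [0, 0, 40.89, 133.11, 87, 0, 0, 174, 0, 0, 0, 0,
                   87, 87, 87, 87, 174, 87, 0, 0, 0, 0, 0]


class TestQuantL858R:
    @pytest.mark.parametrize(
        "peaks,expected",
        [
            (dict(A=0, B=1, C=1, D=2, E=2), 0.0),  # pure wildtype pattern
            (dict(A=3, B=1, C=0, D=0, E=2), 100.0),  # pure mutant pattern
            (dict(A=330, B=200, C=90, D=180, E=400), 55.0),  # worked example
        ],
    )
    def test_formula(self, peaks, expected):
        assert quant_l858r(QuantPeaks(**peaks)) == pytest.approx(expected)

    def test_zero_reference_peaks_rejected(self):
        with pytest.raises(InvalidInputError):
            QuantPeaks(A=1, B=0, C=1, D=1, E=1)
        with pytest.raises(InvalidInputError):
            QuantPeaks(A=1, B=1, C=1, D=1, E=0)


class TestFitCandidate:
    def test_braf_half_mixture(self, assays):
        h = np.array([0, 1, 0, 0.5, 0.5, 0, 1, 1, 1, 1, 1, 1], dtype=float)
        fit = fit_candidate(h, assays["BRAF_600"], "V600E")
        assert fit.fraction == pytest.approx(0.5, abs=1e-12)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_kras_printed_pyrogram(self, assays):
        h = np.asarray(KRAS_47_HEIGHTS) / 87.0
        fit = fit_candidate(h, assays["KRAS_12_13"], "G12C")
        assert fit.fraction == pytest.approx(0.47, abs=1e-9)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_pure_wildtype_fits_any_variant_at_zero(self, assays):
        for assay in assays.values():
            h = mixture_pattern(assay, assay.variants[0].id, 0.0)
            for v in assay.variants:
                assert fit_candidate(h, assay, v).fraction == 0.0

    def test_identical_patterns_are_unfittable(self):
        # the edit lies beyond the dispensation order's reach
        assay = Assay(
            name="toy",
            target="ACT",
            order=DispensationOrder("AC"),
            variants=(MutationVariant(id="t3g", edit=Substitution(position=3, new="G")),),
        )
        with pytest.raises(UndefinedFractionError):
            fit_candidate(np.array([1.0, 1.0]), assay, "t3g")

    def test_estimate_outside_unit_interval_is_clipped_and_flagged(self, assays):
        assay = assays["BRAF_600"]
        h = mixture_pattern(assay, "V600E", 1.0) * 1.5 - 0.5 * mixture_pattern(assay, "V600E", 0.0)
        fit = fit_candidate(h, assay, "V600E")
        assert fit.fraction == 1.0 and fit.clipped

    def test_agrees_with_grid_search_oracle_on_noisy_data(self, assays):
        """Closed-form minimizer vs brute-force grid (step 1e-4)."""
        rng = np.random.default_rng(11)
        grid = np.arange(0.0, 1.0 + 1e-12, 1e-4)
        cases = [(a, v.id) for a in assays.values() for v in a.variants]
        for assay, vid in cases[::3]:
            f_true = rng.uniform(0, 1)
            h = mixture_pattern(assay, vid, f_true) + rng.normal(0, 0.05, len(assay.order))
            w = mixture_pattern(assay, vid, 0.0)
            m = mixture_pattern(assay, vid, 1.0)
            sse = ((h[None, :] - (np.outer(1 - grid, w) + np.outer(grid, m))) ** 2).sum(axis=1)
            f_grid = grid[np.argmin(sse)]
            f_closed = fit_candidate(h, assay, vid).fraction
            assert abs(f_closed - f_grid) <= 1e-4 + 1e-12


class TestRankCandidates:
    def test_l858r_mixture_ranks_first(self, assays):
        h = mixture_pattern(assays["EGFR_ex21"], "L858R", 0.30)
        fits = rank_candidates(h, assays["EGFR_ex21"])
        assert fits[0].variant_id == "L858R"
        assert fits[0].fraction == pytest.approx(0.30, abs=1e-12)

    def test_v600k_mixture_beats_v600e(self, assays):
        h = mixture_pattern(assays["BRAF_600"], "V600K", 0.20)
        fits = rank_candidates(h, assays["BRAF_600"])
        assert fits[0].variant_id == "V600K"
        assert fits[0].fraction == pytest.approx(0.20, abs=1e-12)

    def test_pure_wildtype_ties_are_ambiguous(self, assays):
        assay = assays["KRAS_12_13"]
        h = mixture_pattern(assay, "G12C", 0.0)
        fits = rank_candidates(h, assay)
        assert all(f.fraction == 0.0 for f in fits)
        assert fits[0].ambiguous
        # lexicographic tie-break on equal residuals
        assert fits[0].variant_id == sorted(v.id for v in assay.variants)[0]


class TestV600KDiscriminator:
    def stats(self, mean=1.0, sd=0.0):
        return ReferenceStats(mean=mean, sd=sd, positions=frozenset({9, 10, 12}))

    def test_fires_on_v600k_mixture_with_noisy_references(self, assays):
        h = mixture_pattern(assays["BRAF_600"], "V600K", 0.30)  # disp 7,8 at 0.70
        assert v600k_discriminator(h, assays["BRAF_600"], self.stats(sd=0.02)) is True

    def test_silent_on_pure_v600e(self, assays):
        for f in (0.2, 0.6, 1.0):
            h = mixture_pattern(assays["BRAF_600"], "V600E", f)  # disp 7,8 stay at 1
            assert v600k_discriminator(h, assays["BRAF_600"], self.stats(sd=0.02)) is False

    def test_silent_on_wildtype(self, assays):
        h = mixture_pattern(assays["BRAF_600"], "V600E", 0.0)
        assert v600k_discriminator(h, assays["BRAF_600"], self.stats()) is False


class TestCallSpecimen:
    def test_six_percent_l858r_is_detected(self, assays, noiseless):
        res = call_specimen(noiseless("EGFR_ex21", "L858R", 0.06), assays["EGFR_ex21"])
        assert res.call == MUTATION_DETECTED and res.variant_id == "L858R"

    def test_four_percent_l858r_is_not_called(self, assays, noiseless):
        res = call_specimen(noiseless("EGFR_ex21", "L858R", 0.04), assays["EGFR_ex21"])
        assert res.call == WILDTYPE
        assert res.best_fit.fraction == pytest.approx(0.04, abs=1e-9)

    def test_threshold_comparison_is_strict(self, assays, noiseless):
        # f = 0.25 is exact in binary floating point, so the estimated
        # percentage equals the threshold exactly and must not be called
        res = call_specimen(
            noiseless("EGFR_ex21", "L858R", 0.25),
            assays["EGFR_ex21"],
            threshold_percent=25.0,
        )
        assert res.mutant_percent == 25.0 and res.call == WILDTYPE

    def test_kras_printed_pyrogram_calls_g12c_47(self, assays):
        assay = assays["KRAS_12_13"]
        pyro = Pyrogram(bases=assay.order.bases, heights=np.asarray(KRAS_47_HEIGHTS, float))
        res = call_specimen(pyro, assay)
        assert res.call == MUTATION_DETECTED and res.variant_id == "G12C"
        assert res.mutant_percent == pytest.approx(47.0, abs=0.1)

    def test_pure_wildtype_calls_wildtype(self, assays, noiseless):
        for name in assays:
            res = call_specimen(noiseless(name), assays[name])
            assert res.call == WILDTYPE and res.mutant_percent == pytest.approx(0.0, abs=1e-9)

    def test_garbage_signal_is_indeterminate(self, assays):
        assay = assays["BRAF_600"]
        heights = np.array([50, 10, 40, 5, 5, 60, 10, 10, 200, 10, 150, 10], dtype=float)
        res = call_specimen(Pyrogram(bases=assay.order.bases, heights=heights), assay)
        assert res.call == INDETERMINATE

    def test_flat_zero_pyrogram_is_unanalyzable(self, assays):
        assay = assays["BRAF_600"]
        pyro = Pyrogram(bases=assay.order.bases, heights=np.zeros(12))
        with pytest.raises(DegenerateSignalError):
            call_specimen(pyro, assay)

    def test_order_mismatch_rejected(self, assays):
        pyro = Pyrogram(bases="ACGT", heights=np.ones(4))
        with pytest.raises(InvalidInputError):
            call_specimen(pyro, assays["BRAF_600"])

    @pytest.mark.parametrize("scale", [1.0, 3.7, 250.0])
    def test_call_is_scale_invariant(self, assays, noiseless, scale):
        base = noiseless("KRAS_61", "Q61R", 0.33, scale=1.0)
        scaled = Pyrogram(bases=base.bases, heights=base.heights * scale)
        r1 = call_specimen(base, assays["KRAS_61"])
        r2 = call_specimen(scaled, assays["KRAS_61"])
        assert (r1.call, r1.variant_id) == (r2.call, r2.variant_id)
        assert r1.mutant_percent == pytest.approx(r2.mutant_percent, abs=1e-9)

    def test_formula_and_least_squares_agree_on_ideal_exon21_data(self, assays, noiseless):
        """On noiseless mixtures both estimators return exactly 100 f."""
        for f in np.arange(0.0, 1.0001, 0.1):
            pyro = noiseless("EGFR_ex21", "L858R", float(f), scale=200.0)
            formula = quant_l858r(exon21_quant_peaks(pyro))
            fit = fit_candidate(
                pyro.heights / 200.0, assays["EGFR_ex21"], "L858R"
            )
            assert formula == pytest.approx(100.0 * f, abs=1e-9)
            assert fit.fraction * 100.0 == pytest.approx(formula, abs=1e-9)
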