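"""Pattern recognition, mutant-fraction estimation, and the final call.

The caller treats a normalized pyrogram ``h`` (per-copy units) as a convex
combination of the wildtype expected pattern ``w`` and one candidate mutant
pattern ``m``:

    h_i  =  (1 - f) * w_i  +  f * m_i  +  noise,     f in [0, 1]

For each catalog variant the mutant fraction ``f`` has a closed-form
one-dimensional least-squares solution (clipped to [0, 1]); candidates are
ranked by root-mean-square residual.  The published exon-21 L858R
quantification formula

    [ (1/3) * A/B + (1 - C/B) + (1 - D/E) ] / 3 * 100

is implemented verbatim as well; on ideal exon-21 data it coincides with the
least-squares estimate (both equal 100 f).

The call rule: a specimen is reported mutant only when the estimated mutant
percentage strictly exceeds the calling threshold (default 5%, the assay's
validated sensitivity); otherwise wildtype.  A specimen whose best fit is
poor (residual above three times the wildtype tolerance) is indeterminate.

BRAF V600K carries a dedicated discriminator mirroring manual review: apart
from the mutant T peak at dispensation 4, V600K lowers the peaks at
dispensations 7 and 8, and "lower" is judged against the reference-peak mean
minus two sample standard deviations (reference dispensations 9, 10, 12).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import catalog as cat
from . import preprocess as pre
from .catalog import Assay, MutationVariant
from .errors import InvalidInputError, UndefinedFractionError
from .preprocess import NoiseStats, Pyrogram, ReferenceStats

#: Calls
WILDTYPE = "wildtype"
MUTATION_DETECTED = "mutation-detected"
INDETERMINATE = "indeterminate"

#: Default calling threshold: validated assay sensitivity, in percent.
DEFAULT_THRESHOLD_PERCENT = 5.0

#: Default wildtype-fit tolerance (rms residual, per-copy units).
DEFAULT_WILDTYPE_TOL = 0.15

#: Two best residuals within this relative difference flag an ambiguous call.
AMBIGUITY_REL_TOL = 0.10

# Exon-21 formula peak positions (dispensations): A at 3, C at 4, D at 5,
# E at 7; B averages the single-copy reference dispensations.
EXON21_A, EXON21_C, EXON21_D, EXON21_E = 3, 4, 5, 7
EXON21_REFERENCE = frozenset({2, 9, 11, 12, 14})

# BRAF V600K discriminator dispensations.
BRAF_MUT_T = 4
BRAF_LOWERED = (7, 8)


@dataclass(frozen=True)
class QuantPeaks:
    """Peak heights feeding the exon-21 L858R quantification formula."""

    A: float  # mutant-signature G peak (dispensation 3)
    B: float  # mean single-copy reference height
    C: float  # dispensation 4 (T)
    D: float  # dispensation 5 (G)
    E: float  # dispensation 7 (C)

    def __post_init__(self) -> None:
        if min(self.A, self.B, self.C, self.D, self.E) < 0:
            raise InvalidInputError("quantification peaks must be non-negative")
        if self.B <= 0 or self.E <= 0:
            raise InvalidInputError("reference peaks B and E must be positive")


@dataclass
class CandidateFit:
    """One variant hypothesis fitted to a normalized pyrogram."""

    variant_id: str | None
    fraction: float  # f, clipped to [0, 1]
    scale: float  # instrument units per copy (B used for this fit)
    rms_residual: float
    fitted: np.ndarray  # per-dispensation fitted heights, per-copy units
    observed: np.ndarray  # the normalized vector the fit was computed on
    clipped: bool = False  # raw estimate fell outside [0, 1]
    ambiguous: bool = False  # runner-up fit nearly as good

    @property
    def mutant_percent(self) -> float:
        return 100.0 * self.fraction


@dataclass
class CallResult:
    """Final call for one specimen."""

    assay_name: str
    call: str  # wildtype | mutation-detected | indeterminate
    variant_id: str | None
    mutant_percent: float
    threshold_percent: float
    noise: NoiseStats
    reference: ReferenceStats
    fits: list[CandidateFit] = field(default_factory=list)
    ambiguous: bool = False
    clipped: bool = False
    wildtype_rms: float = float("nan")

    @property
    def best_fit(self) -> CandidateFit | None:
        return self.fits[0] if self.fits else None


def quant_l858r(p: QuantPeaks) -> float:
    """Exon-21 L858R mutant percentage from the published three-term formula.

    The three terms are averaged with equal weight exactly as printed; the
    1/3 factor on A/B compensates the three-G mutant run at dispensation 3.
    The result is clipped to [0, 100].
    """
    value = ((p.A / p.B) / 3.0 + (1.0 - p.C / p.B) + (1.0 - p.D / p.E)) / 3.0 * 100.0
    return float(min(100.0, max(0.0, value)))


def exon21_quant_peaks(pyro: Pyrogram) -> QuantPeaks:
    """Read the formula's A-E peaks off an exon-21 pyrogram (instrument units)."""
    h = pyro.heights
    if len(h) < max(EXON21_REFERENCE):
        raise InvalidInputError("pyrogram too short for the exon-21 assay")
    return QuantPeaks(
        A=float(h[EXON21_A - 1]),
        B=float(np.mean([h[p - 1] for p in sorted(EXON21_REFERENCE)])),
        C=float(h[EXON21_C - 1]),
        D=float(h[EXON21_D - 1]),
        E=float(h[EXON21_E - 1]),
    )


def fit_candidate(
    norm_heights: np.ndarray,
    assay: Assay,
    variant: MutationVariant | str,
    scale: float = 1.0,
) -> CandidateFit:
    """Closed-form least-squares mutant fraction for one variant hypothesis.

    Minimizes ``sum_i (h_i - [(1-f) w_i + f m_i])^2`` over f in [0, 1]:
    with d = m - w, the unconstrained optimum is ``d . (h - w) / d . d``,
    then clipped.  Raises when the two patterns coincide (f unidentifiable).
    """
    variant_id = variant if isinstance(variant, str) else variant.id
    h = np.asarray(norm_heights, dtype=float)
    w = cat.expected_pattern(assay)
    m = cat.expected_pattern(assay, variant_id)
    if h.shape != w.shape:
        raise InvalidInputError(
            f"normalized heights have {h.size} entries, assay order has {w.size}"
        )
    d = m - w
    denom = float(d @ d)
    if denom == 0.0:
        raise UndefinedFractionError(
            f"variant {variant_id!r} has the same expected pattern as wildtype"
        )
    f_raw = float(d @ (h - w)) / denom
    f = min(1.0, max(0.0, f_raw))
    fitted = w + f * d
    rms = float(np.sqrt(np.mean((h - fitted) ** 2)))
    return CandidateFit(
        variant_id=variant_id,
        fraction=f,
        scale=scale,
        rms_residual=rms,
        fitted=fitted,
        observed=h,
        clipped=(f != f_raw),
    )


def rank_candidates(
    norm_heights: np.ndarray,
    assay: Assay,
    *,
    pyro: Pyrogram | None = None,
    noise: NoiseStats | None = None,
    scale: float = 1.0,
) -> list[CandidateFit]:
    """Fit every catalog variant and sort ascending by rms residual.

    When the raw ``pyro`` is supplied, each candidate is normalized with its
    own per-copy unit B, estimated from the reference dispensations that stay
    single-copy under that hypothesis (this matters for deletions, which
    remove some wildtype reference peaks).  Otherwise the supplied normalized
    vector is used for every candidate.

    Ties are broken by variant id; the best fit is flagged ambiguous when the
    two lowest residuals differ by less than 10% relatively.
    """
    if not assay.variants:
        raise InvalidInputError(f"assay {assay.name!r} has no catalog variants")
    fits: list[CandidateFit] = []
    for v in assay.variants:
        if pyro is not None:
            refs = cat.reference_positions(assay, v.id)
            stats_v = pre.reference_stats(pyro, refs)
            if stats_v.mean <= 0:
                continue  # uncalibratable hypothesis: no reference signal
            h_v = pre.normalize(pyro, stats_v, noise)
            fits.append(fit_candidate(h_v, assay, v, scale=stats_v.mean))
        else:
            fits.append(fit_candidate(norm_heights, assay, v, scale=scale))
    fits.sort(key=lambda fit: (fit.rms_residual, fit.variant_id))
    if len(fits) >= 2:
        r1, r2 = fits[0].rms_residual, fits[1].rms_residual
        if r2 == 0.0 or (r2 - r1) / r2 < AMBIGUITY_REL_TOL:
            fits[0].ambiguous = True
    return fits


def v600k_discriminator(
    norm_heights: np.ndarray, assay: Assay, stats: ReferenceStats
) -> bool:
    """BRAF V600K two-SD rule.

    True iff the peaks at dispensations 7 and 8 are both below the reference
    mean minus two sample standard deviations (instrument units) *and* a
    mutant T signal survives the artifact cutoff at dispensation 4 (the
    normalized vector has flagged peaks zeroed, so any positive value there
    is above the cutoff).
    """
    h = np.asarray(norm_heights, dtype=float)
    if h.size < max(BRAF_LOWERED + (BRAF_MUT_T,)):
        raise InvalidInputError("pyrogram too short for the BRAF assay")
    if stats.mean <= 0:
        return False
    limit = stats.mean - 2.0 * stats.sd  # instrument units
    lowered = all(h[p - 1] * stats.mean < limit for p in BRAF_LOWERED)
    mutant_t = h[BRAF_MUT_T - 1] > 0
    return bool(lowered and mutant_t)


def call_specimen(
    pyro: Pyrogram,
    assay: Assay,
    threshold_percent: float = DEFAULT_THRESHOLD_PERCENT,
    wildtype_residual_tol: float = DEFAULT_WILDTYPE_TOL,
    noise_multiplier: float = pre.DEFAULT_NOISE_MULTIPLIER,
) -> CallResult:
    """Full analysis pipeline for one pyrogram.

    artifact cutoff -> reference stats -> normalization -> wildtype check ->
    candidate ranking -> (BRAF: V600K discriminator) -> threshold rule.

    The wildtype check short-circuits only when the pyrogram both fits the
    wildtype pattern within tolerance *and* no candidate fits strictly
    better, so a low-fraction mutant is still quantified and judged against
    the calling threshold.
    """
    pyro.check_order(assay.order)
    unexpected = cat.unexpected_positions(assay)
    noise = pre.artifact_cutoff(pyro, unexpected, noise_multiplier)
    refs = cat.reference_positions(assay)
    stats = pre.reference_stats(pyro, refs)
    norm = pre.normalize(pyro, stats, noise)  # raises DegenerateSignalError if B = 0

    wt_pattern = cat.expected_pattern(assay)
    wt_rms = float(np.sqrt(np.mean((norm - wt_pattern) ** 2)))

    fits = (
        rank_candidates(norm, assay, pyro=pyro, noise=noise, scale=stats.mean)
        if assay.variants
        else []
    )

    result = CallResult(
        assay_name=assay.name,
        call=WILDTYPE,
        variant_id=None,
        mutant_percent=0.0,
        threshold_percent=threshold_percent,
        noise=noise,
        reference=stats,
        fits=fits,
        wildtype_rms=wt_rms,
    )

    if not fits:
        if wt_rms > 3.0 * wildtype_residual_tol:
            result.call = INDETERMINATE
        return result

    # BRAF fine-tuning: the two-SD rule confirms or vetoes the V600E/V600K
    # choice, but only between fits that are actually confusable (runner-up
    # residual within the ambiguity margin) — it resolves subtle-peak cases,
    # it does not override a clear least-squares verdict.
    best = fits[0]
    ids = {fit.variant_id for fit in fits}
    if {"V600E", "V600K"} <= ids and best.variant_id in ("V600E", "V600K"):
        fired = v600k_discriminator(norm, assay, stats)
        other_id = "V600K" if best.variant_id == "V600E" else "V600E"
        other = next(fit for fit in fits if fit.variant_id == other_id)
        confusable = (
            other.rms_residual == 0.0
            or (other.rms_residual - best.rms_residual) / other.rms_residual
            < AMBIGUITY_REL_TOL
        )
        preferred = "V600K" if fired else "V600E"
        if confusable and best.variant_id != preferred:
            fits.remove(other)
            fits.insert(0, other)
            best = other
            best.ambiguous = True

    result.ambiguous = best.ambiguous
    result.clipped = best.clipped
    result.mutant_percent = best.mutant_percent

    eps = 1e-12
    if wt_rms <= wildtype_residual_tol and wt_rms <= best.rms_residual + eps:
        # Fits wildtype and no mutant hypothesis does better.
        result.call = WILDTYPE
        result.mutant_percent = best.mutant_percent
        return result
    if best.rms_residual > 3.0 * wildtype_residual_tol:
        result.call = INDETERMINATE
        result.variant_id = best.variant_id
        return result
    if best.mutant_percent > threshold_percent:
        result.call = MUTATION_DETECTED
        result.variant_id = best.variant_id
    else:
        result.call = WILDTYPE
    return result
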