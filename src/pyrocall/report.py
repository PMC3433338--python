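"""Per-peak wildtype/mutant attribution and report rendering.

For a fitted specimen every dispensation's signal splits additively into a
wildtype share ``(1 - f) * w_i * s`` and a mutant share ``f * m_i * s``
(instrument units, s = per-copy scale), which is the per-peak annotation a
reviewer uses to see which peak — or which portion of a peak — comes from
the wildtype or the mutant allele.  A small 2x2 chi-square utility supports
concordance comparisons between two call sets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats as sstats

from . import catalog as cat
from .caller import CallResult, CandidateFit
from .catalog import Assay
from .errors import InvalidInputError
from .preprocess import NoiseStats, ReferenceStats

#: Attribution labels.
LABEL_WT = "WT"
LABEL_MUT = "Mut"
LABEL_MIXED = "Mixed"
LABEL_NOISE = "Noise"
LABEL_ABSENT = "Absent"

REPORT_FORMATS = ("json", "tsv", "text")

_TSV_COLUMNS = ("disp", "base", "observed", "wildtype", "mutant", "label")


@dataclass(frozen=True)
class PeakAttribution:
    disp: int
    base: str
    observed: float  # instrument units
    wildtype: float  # fitted wildtype contribution, instrument units
    mutant: float  # fitted mutant contribution, instrument units
    label: str


def attribute_peaks(
    fit: CandidateFit,
    assay: Assay,
    stats: ReferenceStats,
    noise: NoiseStats | None = None,
) -> list[PeakAttribution]:
    """Split each fitted peak into wildtype and mutant contributions.

    Labels: ``WT``/``Mut`` when only one allele contributes, ``Mixed`` when
    both do, ``Noise`` for artifact-flagged peaks, ``Absent`` when neither
    allele is expected to produce signal.
    """
    w = cat.expected_pattern(assay)
    m = cat.expected_pattern(assay, fit.variant_id) if fit.variant_id else w
    f = fit.fraction if fit.variant_id else 0.0
    s = stats.mean
    flagged = noise.flagged if noise is not None else frozenset()
    out: list[PeakAttribution] = []
    for i, base in enumerate(assay.order):
        disp = i + 1
        wt_c = (1.0 - f) * w[i] * s
        mut_c = f * m[i] * s
        observed = float(fit.observed[i] * fit.scale)
        if wt_c == 0 and mut_c == 0:
            label = LABEL_NOISE if disp in flagged else LABEL_ABSENT
        elif disp in flagged:
            label = LABEL_NOISE
        elif mut_c == 0:
            label = LABEL_WT
        elif wt_c == 0:
            label = LABEL_MUT
        else:
            label = LABEL_MIXED
        out.append(
            PeakAttribution(
                disp=disp,
                base=base,
                observed=observed,
                wildtype=float(wt_c),
                mutant=float(mut_c),
                label=label,
            )
        )
    return out


def _report_dict(result: CallResult, attributions: list[PeakAttribution]) -> dict:
    return {
        "assay": result.assay_name,
        "call": result.call,
        "variant": result.variant_id,
        "mutant_percent": result.mutant_percent,
        "threshold_percent": result.threshold_percent,
        "ambiguous": result.ambiguous,
        "qc": {
            "B": result.reference.mean,
            "SD": result.reference.sd,
            "noise_cutoff": result.noise.cutoff,
            "unexpected_mean": result.noise.unexpected_mean,
            "flagged": sorted(result.noise.flagged),
            "wildtype_rms": result.wildtype_rms,
        },
        "attributions": [asdict(a) for a in attributions],
    }


def render_report(
    result: CallResult,
    attributions: list[PeakAttribution],
    format: str = "text",
) -> str:
    """Serialize a call result; deterministic for identical inputs.

    ``json`` round-trips losslessly; ``tsv`` is the attribution table with a
    fixed column order; ``text`` is a human-readable summary.
    """
    if format not in REPORT_FORMATS:
        raise InvalidInputError(
            f"unknown report format {format!r}; choose from {', '.join(REPORT_FORMATS)}"
        )
    if format == "json":
        return json.dumps(_report_dict(result, attributions), indent=2, sort_keys=True)
    if format == "tsv":
        lines = ["\t".join(_TSV_COLUMNS)]
        for a in attributions:
            lines.append(
                f"{a.disp}\t{a.base}\t{a.observed:.4f}\t{a.wildtype:.4f}"
                f"\t{a.mutant:.4f}\t{a.label}"
            )
        return "\n".join(lines) + "\n"

    if result.call == "mutation-detected":
        mutation_line = f"mutation: {result.variant_id} (detected)"
    elif result.call == "indeterminate":
        mutation_line = "mutation: indeterminate"
    else:
        mutation_line = "mutation: not detected"
    lines = [
        f"assay: {result.assay_name}",
        f"call: {result.call}",
        mutation_line,
        f"mutant percent: {result.mutant_percent:.1f}"
        f" (threshold {result.threshold_percent:.1f})",
        "QC:",
        f"  reference B: {result.reference.mean:.4g}",
        f"  reference SD: {result.reference.sd:.4g}",
        f"  noise cutoff: {result.noise.cutoff:.4g}",
        f"  wildtype rms: {result.wildtype_rms:.4g}",
        "",
        "\t".join(_TSV_COLUMNS),
    ]
    for a in attributions:
        lines.append(
            f"{a.disp}\t{a.base}\t{a.observed:.2f}\t{a.wildtype:.2f}"
            f"\t{a.mutant:.2f}\t{a.label}"
        )
    return "\n".join(lines) + "\n"


def concordance_chisq(table) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table.

    Returns the statistic and its two-tailed p-value.  This is the standard
    computation for comparing two detection rates; no Yates correction is
    applied.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise InvalidInputError("concordance table must be 2x2")
    if np.any(arr < 0) or not np.all(arr == np.floor(arr)):
        raise InvalidInputError("counts must be non-negative integers")
    arr = arr.astype(float)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise InvalidInputError("every row and column margin must be positive")
    chi2, p, _, _ = sstats.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)
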