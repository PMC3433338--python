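"""Noise filtering and normalization of a measured pyrogram.

Two calibrations are estimated from the pyrogram itself before calling:

* the *artifact cutoff* — twice the mean peak height at the assay's
  unexpected dispensations (positions with zero expected signal under
  wildtype and every catalog variant); peaks strictly below the cutoff are
  treated as non-specific and zeroed;
* the *per-copy unit* B — the mean height of the reference peaks, each of
  which arises from a single nucleotide incorporation, together with its
  sample standard deviation (used by the BRAF V600K two-SD rule).

Both are per-pyrogram, so the downstream pipeline is invariant to any
positive rescaling of the instrument signal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .chemistry import DispensationOrder
from .errors import DegenerateSignalError, InvalidInputError

logger = logging.getLogger("pyrocall")

#: Default artifact-cutoff multiplier (cutoff = multiplier x mean unexpected height).
DEFAULT_NOISE_MULTIPLIER = 2.0


@dataclass(eq=False)
class Pyrogram:
    """Ordered per-dispensation peak heights (instrument units).

    ``bases`` is the dispensed-base sequence (one character per dispensation,
    i.e. the dispensation order actually run); dispensation indices are
    1-based and consecutive.
    """

    bases: str
    heights: np.ndarray
    assay_name: str | None = None

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 1 or len(self.bases) != self.heights.size:
            raise InvalidInputError(
                "pyrogram needs one height per dispensed base "
                f"({len(self.bases)} bases, {self.heights.size} heights)"
            )
        DispensationOrder(self.bases)  # validates non-empty ACGT
        if np.any(self.heights < 0):
            raise InvalidInputError("peak heights must be non-negative")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def records(self) -> list[tuple[int, str, float]]:
        """(dispensation index, base, height) triples, 1-based."""
        return [
            (i + 1, b, float(h))
            for i, (b, h) in enumerate(zip(self.bases, self.heights))
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pyrogram):
            return NotImplemented
        return (
            self.bases == other.bases
            and self.assay_name == other.assay_name
            and np.array_equal(self.heights, other.heights)
        )

    def check_order(self, order: DispensationOrder | str) -> None:
        expected = order.bases if isinstance(order, DispensationOrder) else order
        if self.bases != expected:
            raise InvalidInputError(
                f"pyrogram dispensed bases {self.bases!r} do not match the assay "
                f"dispensation order {expected!r}"
            )


@dataclass(frozen=True)
class NoiseStats:
    """Artifact cutoff derived from unexpected-position peaks."""

    unexpected_mean: float
    multiplier: float
    cutoff: float
    flagged: frozenset[int]  # dispensation indices zeroed as artifact
    positions: frozenset[int] = field(default_factory=frozenset)


@dataclass(frozen=True)
class ReferenceStats:
    """Per-copy calibration from single-incorporation reference peaks."""

    mean: float  # B, instrument units per copy
    sd: float  # sample (n-1) standard deviation
    positions: frozenset[int]

    # The field is conventionally called B in the quantification formulas.
    @property
    def B(self) -> float:
        return self.mean


def artifact_cutoff(
    pyro: Pyrogram,
    unexpected: frozenset[int] | set[int],
    multiplier: float = DEFAULT_NOISE_MULTIPLIER,
) -> NoiseStats:
    """Estimate the non-specific peak cutoff and flag artifact peaks.

    The cutoff is ``multiplier`` times the arithmetic mean of the heights at
    the unexpected dispensations (0 if the set is empty, with a warning).
    Every *observed* peak (height > 0) strictly below the cutoff is flagged;
    peaks equal to the cutoff are kept.
    """
    n = len(pyro)
    positions = frozenset(int(p) for p in unexpected)
    if any(not 1 <= p <= n for p in positions):
        raise InvalidInputError("unexpected positions must lie within the pyrogram")
    if positions:
        mean = float(np.mean([pyro.heights[p - 1] for p in sorted(positions)]))
    else:
        warnings.warn(
            "no unexpected positions available; artifact cutoff set to 0",
            stacklevel=2,
        )
        mean = 0.0
    cutoff = multiplier * mean
    flagged = frozenset(
        i + 1 for i, h in enumerate(pyro.heights) if 0 < h < cutoff
    )
    return NoiseStats(
        unexpected_mean=mean,
        multiplier=multiplier,
        cutoff=cutoff,
        flagged=flagged,
        positions=positions,
    )


def reference_stats(
    pyro: Pyrogram, positions: frozenset[int] | set[int]
) -> ReferenceStats:
    """Mean (B) and sample SD of the reference peaks at the given dispensations."""
    if not positions:
        raise InvalidInputError("reference position set must be non-empty")
    n = len(pyro)
    pos = sorted(int(p) for p in positions)
    if any(not 1 <= p <= n for p in pos):
        raise InvalidInputError("reference positions must lie within the pyrogram")
    values = np.array([pyro.heights[p - 1] for p in pos], dtype=float)
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return ReferenceStats(mean=float(values.mean()), sd=sd, positions=frozenset(pos))


def normalize(
    pyro: Pyrogram, stats: ReferenceStats, noise: NoiseStats | None = None
) -> np.ndarray:
    """Heights in per-copy units: divide by B and zero artifact-flagged peaks."""
    if stats.mean <= 0:
        raise DegenerateSignalError(
            "reference mean B is zero; the pyrogram carries no usable signal"
        )
    out = pyro.heights / stats.mean
    if noise is not None:
        for p in noise.flagged:
            out[p - 1] = 0.0
    return out
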