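"""Deterministic model of pyrosequencing signal generation.

In pyrosequencing the four dNTPs are dispensed one at a time in a fixed,
assay-specific *dispensation order*.  When the dispensed base is
complementary to the template at the current synthesis position it is
incorporated, pyrophosphate is released, and the light emitted is
proportional to the number of bases incorporated in that dispensation.
A homopolymer run of length *k* matching the dispensed base therefore
produces a peak of height *k* (in per-copy units where a single
incorporation is 1.0); a non-matching dispensation produces no peak.

All sequences in this package live in *read space*: the sequence of bases
incorporated into the synthesized strand (the analyzed sequence), not the
template strand.  Assays sequenced with a reverse primer store the
reverse-complemented context directly.

A specimen is modelled as an additive mixture of template reads (e.g.
wildtype plus one mutant at mutant fraction *f*); expected peak heights are
exactly linear in the mixture fractions.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from itertools import groupby

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .errors import InvalidInputError

#: Concrete nucleotide alphabet.
NUCLEOTIDES = "ACGT"

#: IUPAC code -> set of concrete bases it stands for (e.g. ``K`` -> {G, T}).
IUPAC_CODES: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code != "X"  # X is a biopython extension, not an IUPAC nucleotide code
}

#: Fractions of a mixture must sum to one within this tolerance.
FRACTION_SUM_TOL = 1e-12


def _check_acgt(seq: str, what: str) -> None:
    for i, ch in enumerate(seq, start=1):
        if ch not in NUCLEOTIDES:
            raise InvalidInputError(
                f"{what} contains non-ACGT character {ch!r} at position {i}"
            )


@dataclass(frozen=True)
class DispensationOrder:
    """The fixed sequence in which nucleotides are dispensed (1-based positions)."""

    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise InvalidInputError("dispensation order must be non-empty")
        _check_acgt(self.bases, "dispensation order")

    def __len__(self) -> int:
        return len(self.bases)

    def __iter__(self):
        return iter(self.bases)

    def base_at(self, dispensation: int) -> str:
        """Base dispensed at a 1-based dispensation index."""
        return self.bases[dispensation - 1]


@dataclass(frozen=True)
class TemplateRead:
    """A concrete analyzed sequence (read space), with an optional label."""

    sequence: str
    label: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidInputError("template read must be non-empty")
        _check_acgt(self.sequence, f"read {self.label or self.sequence!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TemplateMixture:
    """An additive mixture of template reads with fractions summing to one."""

    components: tuple[tuple[TemplateRead, float], ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise InvalidInputError("mixture must contain at least one component")
        fractions = [f for _, f in self.components]
        if any(f < 0 for f in fractions):
            raise InvalidInputError("mixture fractions must be non-negative")
        if abs(sum(fractions) - 1.0) > FRACTION_SUM_TOL:
            raise InvalidInputError(
                f"mixture fractions must sum to 1 (got {sum(fractions)!r})"
            )

    @classmethod
    def two_component(
        cls, wildtype: TemplateRead | str, mutant: TemplateRead | str, mutant_fraction: float
    ) -> "TemplateMixture":
        """Wildtype/mutant mixture at a given mutant fraction."""
        if not 0.0 <= mutant_fraction <= 1.0:
            raise InvalidInputError("mutant fraction must lie in [0, 1]")
        return cls(
            (
                (_as_read(wildtype), 1.0 - mutant_fraction),
                (_as_read(mutant), mutant_fraction),
            )
        )


@dataclass(frozen=True)
class ExpectedPattern:
    """Expected per-dispensation peak heights in per-copy units."""

    heights: tuple[float, ...]
    order: DispensationOrder = field(compare=False)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.heights, dtype=float)


def _as_read(read: TemplateRead | str) -> TemplateRead:
    return read if isinstance(read, TemplateRead) else TemplateRead(read)


def _as_order(order: DispensationOrder | str) -> DispensationOrder:
    return order if isinstance(order, DispensationOrder) else DispensationOrder(order)


def incorporation_walk(
    read: TemplateRead | str, order: DispensationOrder | str
) -> np.ndarray:
    """Per-dispensation run lengths incorporated from a single template read.

    Walks the read with a cursor starting at position 1.  Each dispensation of
    base ``X`` consumes the maximal run of ``X`` at the cursor (possibly
    empty) and reports its length; the cursor never retreats.  Read bases left
    after the final dispensation contribute nothing.

    Returns an integer vector with one entry per dispensation.
    """
    read = _as_read(read)
    order = _as_order(order)
    # Run-length encode the read once; the cursor can only ever sit at a run
    # boundary because consumption is maximal.
    runs = [(base, len(list(grp))) for base, grp in groupby(read.sequence)]
    out = np.zeros(len(order), dtype=int)
    run_idx = 0
    for i, dispensed in enumerate(order):
        if run_idx < len(runs) and runs[run_idx][0] == dispensed:
            out[i] = runs[run_idx][1]
            run_idx += 1
    return out


def simulate_pyrogram(
    mix: TemplateMixture, order: DispensationOrder | str
) -> ExpectedPattern:
    """Expected noiseless pyrogram of a template mixture.

    The height at each dispensation is the fraction-weighted sum of the
    per-component incorporation run lengths — exactly linear in fractions.
    """
    order = _as_order(order)
    heights = np.zeros(len(order), dtype=float)
    for read, fraction in mix.components:
        heights += fraction * incorporation_walk(read, order)
    return ExpectedPattern(heights=tuple(heights.tolist()), order=order)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-degenerate) nucleotide string.

    Degenerate codes map to their complements (e.g. ``K`` -> ``M``).
    """
    for i, ch in enumerate(seq, start=1):
        if ch not in IUPAC_CODES:
            raise InvalidInputError(
                f"non-IUPAC nucleotide character {ch!r} at position {i}"
            )
    return str(Seq(seq).reverse_complement())


def expand_iupac(seq: str, assignment: Mapping[int, str]) -> TemplateRead:
    """Resolve a degenerate sequence to a concrete read.

    ``assignment`` maps 1-based positions of degenerate codes to the chosen
    concrete base; the choice must be allowed by the code at that position.
    Non-degenerate positions need no assignment and pass through unchanged
    (an assignment equal to the existing base is tolerated).
    """
    out: list[str] = []
    for pos, ch in enumerate(seq, start=1):
        if ch not in IUPAC_CODES:
            raise InvalidInputError(
                f"non-IUPAC nucleotide character {ch!r} at position {pos}"
            )
        allowed = IUPAC_CODES[ch]
        chosen = assignment.get(pos)
        if chosen is not None:
            if chosen not in allowed:
                raise InvalidInputError(
                    f"assignment {chosen!r} at position {pos} is outside the "
                    f"IUPAC code {ch!r} = {{{','.join(sorted(allowed))}}}"
                )
            out.append(chosen)
        elif ch in NUCLEOTIDES:
            out.append(ch)
        else:
            raise InvalidInputError(
                f"degenerate position {pos} ({ch!r}) has no assignment"
            )
    return TemplateRead("".join(out))


def total_incorporated(read: TemplateRead | str, order: DispensationOrder | str) -> int:
    """Number of read bases consumed before the dispensation order is exhausted."""
    return int(incorporation_walk(read, order).sum())
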