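"""Assay definitions and mutation catalogs.

An :class:`Assay` bundles everything needed to analyze one targeted
pyrosequencing test: the analyzed (read-space) wildtype sequence — stored as
the printed, possibly IUPAC-degenerate target plus the wildtype resolution of
its degenerate positions — the dispensation order, the catalog of hotspot
variants as read-space edits, and the reference / unexpected dispensation
positions used for calibration and noise estimation.

Eight assays covering the EGFR (codons 719, 746-753, 768, 790, 858), KRAS
(codons 12/13 and 61) and BRAF (codon 600) hotspots ship as a JSON catalog;
user catalogs in the same schema can be loaded and validated.

Coordinate conventions: variant edits are 1-based positions in the wildtype
read (read space); reverse-sequencing assays (KRAS codon 61, BRAF) store the
already reverse-complemented context, so their edits are read-space too.
The exon-19 target keeps the printed square brackets marking the commonly
deleted block; brackets are stripped when deriving the wildtype read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np

from . import chemistry
from .errors import (
    CatalogValidationError,
    InvalidInputError,
    UnknownAssayError,
    UnknownVariantError,
)

# --------------------------------------------------------------------------
# Edits and variants
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Substitution:
    """Replace ``len(new)`` bases starting at ``position`` with ``new``."""

    position: int
    new: str


@dataclass(frozen=True)
class Deletion:
    start: int
    length: int


@dataclass(frozen=True)
class Insertion:
    """Insert ``bases`` after read position ``after`` (0 = before the read)."""

    after: int
    bases: str


@dataclass(frozen=True)
class Delins:
    """Delete ``length`` bases starting at ``start`` and insert ``replacement``."""

    start: int
    length: int
    replacement: str


Edit = Union[Substitution, Deletion, Insertion, Delins]


@dataclass(frozen=True)
class MutationVariant:
    id: str
    edit: Edit
    notes: str = ""


def apply_edit(read: str, edit: Edit) -> str:
    """Apply one edit to a read-space sequence; coordinates are 1-based."""
    n = len(read)
    if isinstance(edit, Substitution):
        if not (1 <= edit.position and edit.position + len(edit.new) - 1 <= n):
            raise InvalidInputError(
                f"substitution at {edit.position} (x{len(edit.new)}) is out of range "
                f"for a {n}-base read"
            )
        return read[: edit.position - 1] + edit.new + read[edit.position - 1 + len(edit.new):]
    if isinstance(edit, Deletion):
        if not (1 <= edit.start and edit.start + edit.length - 1 <= n and edit.length >= 1):
            raise InvalidInputError(
                f"deletion {edit.start}+{edit.length} is out of range for a {n}-base read"
            )
        return read[: edit.start - 1] + read[edit.start - 1 + edit.length:]
    if isinstance(edit, Insertion):
        if not (0 <= edit.after <= n) or not edit.bases:
            raise InvalidInputError(
                f"insertion after {edit.after} is out of range for a {n}-base read"
            )
        return read[: edit.after] + edit.bases + read[edit.after:]
    if isinstance(edit, Delins):
        if not (1 <= edit.start and edit.start + edit.length - 1 <= n and edit.length >= 1):
            raise InvalidInputError(
                f"delins {edit.start}+{edit.length} is out of range for a {n}-base read"
            )
        return read[: edit.start - 1] + edit.replacement + read[edit.start - 1 + edit.length:]
    raise InvalidInputError(f"unknown edit type {type(edit).__name__}")


# --------------------------------------------------------------------------
# Assay
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Assay:
    """One targeted pyrosequencing test and its mutation catalog."""

    name: str
    target: str  # as printed, possibly IUPAC-degenerate, may contain [] markers
    order: chemistry.DispensationOrder
    orientation: str = "forward"  # forward | reverse (primer strand)
    variants: tuple[MutationVariant, ...] = ()
    description: str = ""
    #: wildtype resolution of degenerate target positions (1-based, bracket-stripped)
    wildtype_assignment: tuple[tuple[int, str], ...] = ()
    #: explicit single-copy calibration dispensations; None = auto-derive
    reference_positions: frozenset[int] | None = None
    #: explicit zero-signal dispensations; None = auto-derive
    unexpected_positions: frozenset[int] | None = None

    @property
    def degenerate_read(self) -> str:
        """The target with deletion-block brackets stripped (still degenerate)."""
        return self.target.replace("[", "").replace("]", "")

    @property
    def wildtype_read(self) -> str:
        return chemistry.expand_iupac(
            self.degenerate_read, dict(self.wildtype_assignment)
        ).sequence

    def variant_by_id(self, variant_id: str) -> MutationVariant:
        for v in self.variants:
            if v.id == variant_id:
                return v
        raise UnknownVariantError(
            f"assay {self.name!r} has no variant {variant_id!r}"
        )


def apply_variant(assay: Assay, variant: MutationVariant) -> chemistry.TemplateRead:
    """Mutant read produced by applying a catalog variant to the wildtype read."""
    if variant not in assay.variants:
        # allow lookup by id so callers can pass reconstructed variants
        try:
            variant = assay.variant_by_id(variant.id)
        except UnknownVariantError:
            raise InvalidInputError(
                f"variant {variant.id!r} does not belong to assay {assay.name!r}"
            ) from None
    mutant = apply_edit(assay.wildtype_read, variant.edit)
    return chemistry.TemplateRead(mutant, label=variant.id)


# -- expected patterns -----------------------------------------------------


@lru_cache(maxsize=512)
def _pattern_cached(assay: Assay, variant_id: str | None) -> tuple[int, ...]:
    if variant_id is None:
        read = assay.wildtype_read
    else:
        read = apply_variant(assay, assay.variant_by_id(variant_id)).sequence
    return tuple(chemistry.incorporation_walk(read, assay.order).tolist())


def expected_pattern(assay: Assay, variant_id: str | None = None) -> np.ndarray:
    """Per-copy expected heights for wildtype (``variant_id=None``) or a variant."""
    return np.asarray(_pattern_cached(assay, variant_id), dtype=float)


def mixture_pattern(assay: Assay, variant_id: str, fraction: float) -> np.ndarray:
    """Expected heights of a wildtype/mutant mixture at the given mutant fraction."""
    mix = chemistry.TemplateMixture.two_component(
        assay.wildtype_read,
        apply_variant(assay, assay.variant_by_id(variant_id)),
        fraction,
    )
    return chemistry.simulate_pyrogram(mix, assay.order).as_array()


def unexpected_positions(assay: Assay) -> frozenset[int]:
    """Dispensations with zero expected signal under wildtype and all variants.

    Peaks observed there can only be non-specific background; the preprocess
    module averages them to set the artifact cutoff.  An explicit set on the
    assay takes precedence over derivation.
    """
    if assay.unexpected_positions is not None:
        return assay.unexpected_positions
    return derive_unexpected_positions(assay)


def derive_unexpected_positions(assay: Assay) -> frozenset[int]:
    """Always derive (ignoring any explicit set): intersection of zero-height
    dispensations over wildtype and every catalog variant."""
    zero = expected_pattern(assay) == 0
    for v in assay.variants:
        zero &= expected_pattern(assay, v.id) == 0
    return frozenset(int(i) + 1 for i in np.nonzero(zero)[0])


def reference_positions(assay: Assay, variant_id: str | None = None) -> frozenset[int]:
    """Single-copy calibration dispensations for a given hypothesis.

    The base set is the assay's explicit set, or auto-derived as the
    dispensations with expected height exactly 1 under wildtype.  Whenever a
    subset of it stays single-copy under *every* catalog variant, that shared
    subset is used for all hypotheses: such positions have height exactly 1
    no matter which mutation the specimen carries, so the per-copy unit B is
    unbiased by the (unknown) true variant.  Only when no position survives
    every variant (possible for rich deletion catalogs) does the set become
    hypothesis-specific: positions single-copy under wildtype and the named
    candidate.
    """
    wt = expected_pattern(assay)
    base = assay.reference_positions
    if base is None:
        base = frozenset(int(i) + 1 for i in np.nonzero(wt == 1)[0])
    base = frozenset(p for p in base if wt[p - 1] == 1)
    shared = frozenset(
        p
        for p in base
        if all(expected_pattern(assay, v.id)[p - 1] == 1 for v in assay.variants)
    )
    if shared:
        return shared
    if variant_id is None:
        return base
    pat = expected_pattern(assay, variant_id)
    kept = frozenset(p for p in base if pat[p - 1] == 1)
    if kept:
        return kept
    # Degenerate catalog entry: no position is single-copy under both
    # templates; fall back to positions single-copy under the mutant alone.
    fallback = frozenset(int(i) + 1 for i in np.nonzero(pat == 1)[0])
    if fallback:
        return fallback
    raise InvalidInputError(
        f"no single-copy reference position exists for {assay.name}/{variant_id}"
    )


def reference_position_map(assay: Assay) -> dict[str, frozenset[int]]:
    """Mapping hypothesis -> reference positions (``"wildtype"`` plus one key per variant)."""
    out = {"wildtype": reference_positions(assay)}
    for v in assay.variants:
        out[v.id] = reference_positions(assay, v.id)
    return out


# --------------------------------------------------------------------------
# Built-in catalog and JSON I/O
# --------------------------------------------------------------------------

_EDIT_TYPES = {"substitution", "deletion", "insertion", "delins"}


def _edit_from_json(obj: dict, where: str, failures: list[str]) -> Edit | None:
    etype = obj.get("type")
    try:
        if etype == "substitution":
            return Substitution(position=int(obj["position"]), new=str(obj["new"]))
        if etype == "deletion":
            return Deletion(start=int(obj["start"]), length=int(obj["length"]))
        if etype == "insertion":
            return Insertion(after=int(obj["after"]), bases=str(obj["bases"]))
        if etype == "delins":
            return Delins(
                start=int(obj["start"]),
                length=int(obj["length"]),
                replacement=str(obj["replacement"]),
            )
    except (KeyError, TypeError, ValueError) as exc:
        failures.append(f"{where}: malformed edit fields ({exc})")
        return None
    failures.append(f"{where}: edit type must be one of {sorted(_EDIT_TYPES)}, got {etype!r}")
    return None


def _edit_to_json(edit: Edit) -> dict:
    if isinstance(edit, Substitution):
        return {"type": "substitution", "position": edit.position, "new": edit.new}
    if isinstance(edit, Deletion):
        return {"type": "deletion", "start": edit.start, "length": edit.length}
    if isinstance(edit, Insertion):
        return {"type": "insertion", "after": edit.after, "bases": edit.bases}
    return {
        "type": "delins",
        "start": edit.start,
        "length": edit.length,
        "replacement": edit.replacement,
    }


def _assay_from_json(obj: dict, failures: list[str]) -> Assay | None:
    name = obj.get("name")
    where = f"assay {name!r}" if name else "assay <unnamed>"
    local: list[str] = []
    if not name or not isinstance(name, str):
        local.append("assay entry is missing a 'name' string")
    target = obj.get("target")
    if not target or not isinstance(target, str):
        local.append(f"{where}: missing 'target' sequence")
    order = obj.get("dispensation_order")
    if not order or not isinstance(order, str):
        local.append(f"{where}: missing 'dispensation_order'")
    orientation = obj.get("orientation", "forward")
    if orientation not in ("forward", "reverse"):
        local.append(f"{where}: orientation must be 'forward' or 'reverse'")
    assignment_raw = obj.get("wildtype_assignment", {})
    try:
        assignment = tuple(
            sorted((int(k), str(v)) for k, v in dict(assignment_raw).items())
        )
    except (TypeError, ValueError):
        local.append(f"{where}: wildtype_assignment must map positions to bases")
        assignment = ()
    variants: list[MutationVariant] = []
    for vobj in obj.get("variants", []):
        vid = vobj.get("id")
        if not vid:
            local.append(f"{where}: variant entry missing 'id'")
            continue
        edit = _edit_from_json(vobj.get("edit", {}), f"{where} variant {vid!r}", local)
        if edit is not None:
            variants.append(MutationVariant(id=vid, edit=edit, notes=vobj.get("notes", "")))
    refs = obj.get("reference_positions")
    unexpected = obj.get("unexpected_positions")
    if local:
        failures.extend(local)
        return None
    try:
        return Assay(
            name=name,
            target=target,
            order=chemistry.DispensationOrder(order),
            orientation=orientation,
            variants=tuple(variants),
            description=obj.get("description", ""),
            wildtype_assignment=assignment,
            reference_positions=frozenset(int(p) for p in refs) if refs is not None else None,
            unexpected_positions=(
                frozenset(int(p) for p in unexpected) if unexpected is not None else None
            ),
        )
    except InvalidInputError as exc:
        failures.append(f"{where}: {exc}")
        return None


def _assay_to_json(assay: Assay) -> dict:
    obj: dict = {
        "name": assay.name,
        "description": assay.description,
        "target": assay.target,
        "wildtype_assignment": {str(p): b for p, b in assay.wildtype_assignment},
        "dispensation_order": assay.order.bases,
        "orientation": assay.orientation,
        "variants": [
            {"id": v.id, "edit": _edit_to_json(v.edit), "notes": v.notes}
            for v in assay.variants
        ],
    }
    if assay.reference_positions is not None:
        obj["reference_positions"] = sorted(assay.reference_positions)
    if assay.unexpected_positions is not None:
        obj["unexpected_positions"] = sorted(assay.unexpected_positions)
    return obj


def validate_assay(assay: Assay, failures: list[str]) -> None:
    """Semantic checks; appends human-readable failure messages."""
    where = f"assay {assay.name!r}"
    try:
        wt = assay.wildtype_read
    except InvalidInputError as exc:
        failures.append(f"{where}: wildtype read invalid: {exc}")
        return
    seen: set[str] = set()
    for v in assay.variants:
        if v.id in seen:
            failures.append(f"{where}: duplicate variant id {v.id!r}")
        seen.add(v.id)
        try:
            mutant = apply_edit(wt, v.edit)
            chemistry.TemplateRead(mutant, label=v.id)
        except InvalidInputError as exc:
            failures.append(f"{where} variant {v.id!r}: {exc}")
            continue
        if mutant == wt:
            failures.append(f"{where} variant {v.id!r}: edit leaves the read unchanged")
    if assay.reference_positions is not None:
        wt_pat = expected_pattern(assay)
        for p in sorted(assay.reference_positions):
            if not (1 <= p <= len(assay.order)):
                failures.append(f"{where}: reference position {p} outside dispensation range")
            elif wt_pat[p - 1] != 1:
                failures.append(
                    f"{where}: reference position {p} has expected wildtype height "
                    f"{wt_pat[p - 1]:g}, must be exactly 1"
                )
    if assay.unexpected_positions is not None:
        derived = derive_unexpected_positions(assay)
        for p in sorted(assay.unexpected_positions):
            if not (1 <= p <= len(assay.order)):
                failures.append(f"{where}: unexpected position {p} outside dispensation range")
            elif p not in derived:
                failures.append(
                    f"{where}: unexpected position {p} carries expected signal under "
                    "wildtype or a catalog variant"
                )


def load_catalog(path: str | Path) -> list[Assay]:
    """Load and validate a JSON assay catalog; raises with *all* failures listed."""
    failures: list[str] = []
    try:
        data = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise CatalogValidationError([f"cannot read catalog: {exc}"]) from exc
    if not isinstance(data, list):
        raise CatalogValidationError(["catalog top level must be a list of assay objects"])
    assays: list[Assay] = []
    for obj in data:
        assay = _assay_from_json(obj, failures)
        if assay is not None:
            validate_assay(assay, failures)
            assays.append(assay)
    names = [a.name for a in assays]
    for dup in {n for n in names if names.count(n) > 1}:
        failures.append(f"duplicate assay name {dup!r}")
    if failures:
        raise CatalogValidationError(failures)
    return assays


def save_catalog(assays: list[Assay], path: str | Path) -> None:
    Path(path).write_text(json.dumps([_assay_to_json(a) for a in assays], indent=2) + "\n")


@lru_cache(maxsize=1)
def _builtin() -> tuple[Assay, ...]:
    with resources.files("pyrocall.data").joinpath("default_catalog.json").open() as fh:
        data = json.load(fh)
    failures: list[str] = []
    assays = []
    for obj in data:
        assay = _assay_from_json(obj, failures)
        if assay is not None:
            validate_assay(assay, failures)
            assays.append(assay)
    if failures:  # pragma: no cover - shipped catalog is validated by tests
        raise CatalogValidationError(failures)
    return tuple(assays)


def builtin_assays() -> list[Assay]:
    """The eight built-in EGFR/KRAS/BRAF assays."""
    return list(_builtin())


def get_assay(name: str) -> Assay:
    for assay in _builtin():
        if assay.name == name:
            return assay
    raise UnknownAssayError(
        f"unknown assay {name!r}; available: {', '.join(a.name for a in _builtin())}"
    )
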