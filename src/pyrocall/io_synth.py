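"""Pyrogram TSV I/O, the synthetic-pyrogram generator, and the command line.

The interchange format is a three-column TSV with header ``disp\\tbase\\theight``
(1-based consecutive dispensation indices, dispensed base, non-negative peak
height with dot decimal).  No public standard exists for pyrogram peak
exports, so this dialect is the package's own; heights are written with
Python's shortest float repr so a write/read round trip is lossless.

The generator emulates a measured pyrogram: per-copy expected heights of a
wildtype/mutant mixture, multiplied by the instrument scale, plus i.i.d.
Gaussian peak noise truncated at zero, plus small uniform non-specific peaks
at the assay's unexpected dispensations.  All randomness flows from the
config's seed; there is no global RNG state.
"""

from __future__ import annotations

import argparse
import csv
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import catalog as cat
from . import caller as call_mod
from . import preprocess as pre
from . import report as rep
from .errors import (
    DegenerateSignalError,
    InvalidInputError,
    ParseError,
    PyrocallError,
    UnknownAssayError,
    UnknownVariantError,
)
from .preprocess import Pyrogram

logger = logging.getLogger("pyrocall")

TSV_HEADER = ("disp", "base", "height")

#: Exit codes for the command line.
EXIT_OK = 0
EXIT_USAGE = 1
EXIT_UNANALYZABLE = 2


# --------------------------------------------------------------------------
# TSV I/O
# --------------------------------------------------------------------------


def write_pyrogram_tsv(pyro: Pyrogram, path) -> None:
    lines = ["\t".join(TSV_HEADER)]
    for disp, base, height in pyro.records:
        lines.append(f"{disp}\t{base}\t{height!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pyrogram_tsv(path, assay: cat.Assay | None = None) -> Pyrogram:
    """Parse a pyrogram TSV; validates indices, bases and (optionally) the
    assay's dispensation order.  Errors carry the offending 1-based line."""
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    rows = list(csv.reader(text.splitlines(), delimiter="\t"))
    if not rows:
        raise ParseError("empty pyrogram file", line=1)
    header = tuple(h.strip() for h in rows[0])
    if header != TSV_HEADER:
        raise ParseError(
            f"expected header {'/'.join(TSV_HEADER)}, got {'/'.join(header)}", line=1
        )
    bases: list[str] = []
    heights: list[float] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue  # tolerate trailing blank lines
        if len(row) != 3:
            raise ParseError(f"expected 3 columns, got {len(row)}", line=lineno)
        disp_s, base, height_s = (c.strip() for c in row)
        try:
            disp = int(disp_s)
        except ValueError:
            raise ParseError(f"bad dispensation index {disp_s!r}", line=lineno) from None
        if disp != len(bases) + 1:
            raise ParseError(
                f"dispensation indices must be consecutive from 1; got {disp}",
                line=lineno,
            )
        if base not in "ACGT" or len(base) != 1:
            raise ParseError(f"bad base {base!r} (must be A/C/G/T)", line=lineno)
        try:
            height = float(height_s)
        except ValueError:
            raise ParseError(f"bad height {height_s!r}", line=lineno) from None
        if not np.isfinite(height) or height < 0:
            raise ParseError(
                f"height must be finite and non-negative, got {height_s}", line=lineno
            )
        bases.append(base)
        heights.append(height)
    if not bases:
        raise ParseError("pyrogram file has no data rows", line=2)
    pyro = Pyrogram(
        bases="".join(bases),
        heights=np.array(heights),
        assay_name=assay.name if assay else None,
    )
    if assay is not None:
        try:
            pyro.check_order(assay.order)
        except InvalidInputError as exc:
            raise ParseError(str(exc)) from exc
    return pyro


# --------------------------------------------------------------------------
# Synthetic pyrograms
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic pyrogram.

    ``noise_sd`` and the non-specific amplitude range are fractions of the
    instrument scale; defaults emulate a clean clinical run (peak noise a few
    percent of a single-copy peak, small background blips at positions where
    no signal is expected).
    """

    assay: str
    variant: str | None = None  # None = pure wildtype
    fraction: float = 0.0  # mutant fraction f
    scale: float = 100.0  # instrument units per copy
    noise_sd: float = 0.03
    nonspecific_range: tuple[float, float] = (0.01, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise InvalidInputError("fraction must lie in [0, 1]")
        if self.scale <= 0:
            raise InvalidInputError("scale must be positive")
        if self.noise_sd < 0:
            raise InvalidInputError("noise sd must be non-negative")
        lo, hi = self.nonspecific_range
        if lo < 0 or hi < lo:
            raise InvalidInputError("nonspecific range must satisfy 0 <= lo <= hi")


def synth_pyrogram(cfg: SynthConfig) -> Pyrogram:
    """Simulate a measured pyrogram under the configured conditions.

    heights = scale x expected mixture pattern
              + Gaussian(0, noise_sd x scale) per peak
              + Uniform(nonspecific range) x scale at unexpected positions,
    truncated at zero.  Identical configs (including seed) yield identical
    pyrograms.
    """
    assay = cat.get_assay(cfg.assay)
    if cfg.variant is None:
        expected = cat.expected_pattern(assay)
        if cfg.fraction != 0.0:
            raise InvalidInputError("fraction must be 0 for a wildtype pyrogram")
    else:
        assay.variant_by_id(cfg.variant)  # raises UnknownVariantError
        expected = cat.mixture_pattern(assay, cfg.variant, cfg.fraction)
    rng = np.random.default_rng(cfg.seed)
    heights = cfg.scale * expected
    if cfg.noise_sd > 0:
        heights = heights + rng.normal(0.0, cfg.noise_sd * cfg.scale, heights.size)
    lo, hi = cfg.nonspecific_range
    if hi > 0:
        for p in sorted(cat.unexpected_positions(assay)):
            heights[p - 1] += cfg.scale * rng.uniform(lo, hi)
    heights = np.maximum(heights, 0.0)
    return Pyrogram(bases=assay.order.bases, heights=heights, assay_name=assay.name)


# --------------------------------------------------------------------------
# Command line
# --------------------------------------------------------------------------


class _UsageError(Exception):
    pass


class _Parser(argparse.ArgumentParser):
    def error(self, message):  # argparse default exits with code 2
        raise _UsageError(message)


def _build_parser() -> _Parser:
    parser = _Parser(prog="pyrocall", description="Pyrosequencing pyrogram analysis")
    sub = parser.add_subparsers(dest="command")

    p_an = sub.add_parser("analyze", help="call a measured pyrogram")
    p_an.add_argument("--assay", required=True)
    p_an.add_argument("--input", required=True, help="pyrogram TSV")
    p_an.add_argument("--out", default="-", help="output path ('-' = stdout)")
    p_an.add_argument("--format", default="text", choices=rep.REPORT_FORMATS)
    p_an.add_argument("--min-call-percent", type=float, default=call_mod.DEFAULT_THRESHOLD_PERCENT)
    p_an.add_argument("--noise-multiplier", type=float, default=pre.DEFAULT_NOISE_MULTIPLIER)
    p_an.add_argument("--wildtype-tol", type=float, default=call_mod.DEFAULT_WILDTYPE_TOL)

    for cmd in ("simulate", "synth"):
        p_sy = sub.add_parser(cmd, help="generate a synthetic pyrogram")
        p_sy.add_argument("--assay", required=True)
        p_sy.add_argument("--variant", default=None)
        p_sy.add_argument("--fraction", type=float, default=0.0)
        p_sy.add_argument("--scale", type=float, default=100.0)
        p_sy.add_argument("--noise-sd", type=float, default=0.0)
        p_sy.add_argument("--nonspecific", type=float, nargs=2, default=(0.0, 0.0),
                          metavar=("LO", "HI"))
        p_sy.add_argument("--seed", type=int, default=0)
        p_sy.add_argument("--out", default="-")

    p_cat = sub.add_parser("catalog", help="inspect or validate assay catalogs")
    p_cat.add_argument("action", choices=("list", "show", "validate"))
    p_cat.add_argument("name_or_path", nargs="?")
    return parser


def _write_out(text: str, out: str) -> None:
    if out == "-":
        sys.stdout.write(text if text.endswith("\n") else text + "\n")
    else:
        Path(out).write_text(text if text.endswith("\n") else text + "\n")


def _cmd_analyze(args) -> int:
    assay = cat.get_assay(args.assay)
    pyro = read_pyrogram_tsv(args.input, assay)
    result = call_mod.call_specimen(
        pyro,
        assay,
        threshold_percent=args.min_call_percent,
        wildtype_residual_tol=args.wildtype_tol,
        noise_multiplier=args.noise_multiplier,
    )
    logger.info(
        "analyze assay=%s threshold=%.3g%% noise-multiplier=%.3g "
        "B=%.4g SD=%.4g cutoff=%.4g call=%s percent=%.2f",
        assay.name, args.min_call_percent, args.noise_multiplier,
        result.reference.mean, result.reference.sd, result.noise.cutoff,
        result.call, result.mutant_percent,
    )
    fit = result.best_fit
    if fit is None or result.call == call_mod.WILDTYPE:
        fit = call_mod.CandidateFit(
            variant_id=None, fraction=0.0, scale=result.reference.mean,
            rms_residual=result.wildtype_rms,
            fitted=cat.expected_pattern(assay),
            observed=pre.normalize(pyro, result.reference, result.noise),
        )
    attributions = rep.attribute_peaks(fit, assay, result.reference, result.noise)
    _write_out(rep.render_report(result, attributions, args.format), args.out)
    return EXIT_OK


def _cmd_synth(args) -> int:
    cfg = SynthConfig(
        assay=args.assay,
        variant=args.variant,
        fraction=args.fraction,
        scale=args.scale,
        noise_sd=args.noise_sd,
        nonspecific_range=tuple(args.nonspecific),
        seed=args.seed,
    )
    pyro = synth_pyrogram(cfg)
    logger.info("synth assay=%s variant=%s fraction=%.3g seed=%d",
                cfg.assay, cfg.variant, cfg.fraction, cfg.seed)
    if args.out == "-":
        lines = ["\t".join(TSV_HEADER)]
        lines += [f"{d}\t{b}\t{h!r}" for d, b, h in pyro.records]
        sys.stdout.write("\n".join(lines) + "\n")
    else:
        write_pyrogram_tsv(pyro, args.out)
    return EXIT_OK


def _cmd_catalog(args) -> int:
    if args.action == "list":
        for assay in cat.builtin_assays():
            print(f"{assay.name}\t{assay.description}\t{len(assay.variants)} variants")
        return EXIT_OK
    if args.name_or_path is None:
        raise _UsageError(f"catalog {args.action} requires a name or path")
    if args.action == "show":
        assay = cat.get_assay(args.name_or_path)
        print(json.dumps(cat._assay_to_json(assay), indent=2))
        return EXIT_OK
    cat.load_catalog(args.name_or_path)
    print(f"{args.name_or_path}: OK")
    return EXIT_OK


def cli(argv: list[str] | None = None) -> int:
    """Entry point; returns an exit code (0 ok, 1 usage, 2 unanalyzable)."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    parser = _build_parser()
    try:
        args = parser.parse_args(argv)
        if args.command is None:
            parser.print_usage(sys.stderr)
            return EXIT_USAGE
        if args.command == "analyze":
            return _cmd_analyze(args)
        if args.command in ("simulate", "synth"):
            return _cmd_synth(args)
        return _cmd_catalog(args)
    except _UsageError as exc:
        print(f"usage error: {exc}", file=sys.stderr)
        return EXIT_USAGE
    except (UnknownAssayError, UnknownVariantError) as exc:
        print(f"usage error: {exc.args[0]}", file=sys.stderr)
        return EXIT_USAGE
    except DegenerateSignalError as exc:
        print(f"unanalyzable input: {exc}", file=sys.stderr)
        return EXIT_UNANALYZABLE
    except (ParseError, InvalidInputError, PyrocallError) as exc:
        print(f"error: {exc}", file=sys.stderr)
        return EXIT_USAGE


def main() -> None:  # console-script entry point
    sys.exit(cli())
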