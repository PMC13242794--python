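"""Core data model: sequencing reads, quality encodings, and step specifiers.

A :class:`Read` is one FASTQ record with its quality string already decoded to
integer PHRED scores.  PHRED score ``q`` corresponds to a base-call error
probability of ``10**(-q/10)`` and is stored on disk as the ASCII character
``chr(q + offset)`` with ``offset`` either 33 (modern Illumina, Sanger) or 64
(legacy Illumina 1.3-1.7).  Using the wrong offset silently corrupts every
quality-based decision downstream, which is why the offset is auto-detected
(:func:`detect_encoding`) unless the user pins it explicitly.

Coordinates everywhere in this package are 0-based, half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import islice
from typing import Iterable, Sequence

PHRED33 = 33
PHRED64 = 64
#: Highest PHRED score representable in ASCII FASTQ with offset 33 (chr 126).
MAX_PHRED = 93


class FastqFormatError(ValueError):
    """Malformed FASTQ input (truncated record, length mismatch, bad offset)."""


class StepParseError(ValueError):
    """A step token could not be parsed (unknown name, arity, bad number)."""


class AmbiguousEncodingError(ValueError):
    """Observed quality characters are compatible with both PHRED offsets."""


class PairingError(ValueError):
    """Paired-end input files are out of sync or of unequal length."""


@dataclass(frozen=True, slots=True)
class QualityEncoding:
    """PHRED score encoding; ``offset`` is 33 or 64."""

    offset: int

    def __post_init__(self) -> None:
        if self.offset not in (PHRED33, PHRED64):
            raise ValueError(f"unsupported PHRED offset {self.offset}")


@dataclass(slots=True)
class Read:
    """One sequencing record.

    Parameters
    ----------
    name
        FASTQ header without the leading ``@``.
    bases
        Nucleotide string over ``{A, C, G, T, N}`` (case preserved).
    quals
        Decoded integer PHRED scores, one per base, stored as ``bytes``
        (each element is an ``int`` in ``[0, 93]``).
    """

    name: str
    bases: str
    quals: bytes

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise FastqFormatError(
                f"record {self.name!r}: sequence length {len(self.bases)} != "
                f"quality length {len(self.quals)}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def window(self, start: int, end: int) -> "Read":
        """Contiguous sub-read ``[start, end)``, bases and quals in lockstep."""
        return Read(self.name, self.bases[start:end], self.quals[start:end])


@dataclass(slots=True)
class ReadPair:
    """Synchronized forward/reverse mates; either may be dropped downstream."""

    fwd: Read | None
    rev: Read | None


_DECODE_TABLES: dict[int, bytes] = {}


def _decode_table(offset: int) -> bytes:
    table = _DECODE_TABLES.get(offset)
    if table is None:
        table = bytes(max(0, i - offset) for i in range(256))
        _DECODE_TABLES[offset] = table
    return table


def decode_quality(
    qual_text: str, encoding: QualityEncoding, record_name: str = ""
) -> bytes:
    """Decode an ASCII quality string to integer PHRED scores.

    Raises :class:`FastqFormatError` if any character code is below the
    encoding offset (which would imply a negative score) or above the
    printable-ASCII ceiling.
    """
    raw = qual_text.encode("ascii")
    if raw:
        lo, hi = min(raw), max(raw)
        if lo < encoding.offset or hi > encoding.offset + MAX_PHRED:
            bad = chr(lo if lo < encoding.offset else hi)
            where = f" in record {record_name!r}" if record_name else ""
            raise FastqFormatError(
                f"quality character {bad!r}{where} is outside the valid range "
                f"for PHRED+{encoding.offset}"
            )
    return raw.translate(_decode_table(encoding.offset))


def encode_quality(quals: Sequence[int], encoding: QualityEncoding) -> str:
    """Inverse of :func:`decode_quality`."""
    return bytes(q + encoding.offset for q in quals).decode("ascii")


def detect_encoding(
    quality_lines: Iterable[str], sample_limit: int = 10_000
) -> QualityEncoding:
    """Infer the PHRED offset from observed quality characters.

    Scans up to ``sample_limit`` quality lines and applies the character-code
    range rule: any code below 64 forces offset 33 (offset-64 scores would be
    negative); otherwise a code above 74 forces offset 64 (offset-33 scores
    above Q41 do not occur in Illumina data).  If every observed code lies in
    64..74 both offsets remain plausible and an
    :class:`AmbiguousEncodingError` is raised — a silent guess is exactly the
    hard-to-diagnose failure mode this detector exists to prevent.
    """
    lo, hi = 256, -1
    for line in islice(quality_lines, sample_limit):
        if not line:
            continue
        raw = line.encode("ascii")
        lo = min(lo, min(raw))
        hi = max(hi, max(raw))
    if hi < 0:
        raise FastqFormatError("cannot detect PHRED encoding: no quality data")
    if lo < PHRED64:
        return QualityEncoding(PHRED33)
    if hi > 74:
        return QualityEncoding(PHRED64)
    raise AmbiguousEncodingError(
        "quality characters all fall in the ambiguous range 64..74; "
        "pass -phred33 or -phred64 explicitly"
    )


# ---------------------------------------------------------------------------
# Step specifiers
# ---------------------------------------------------------------------------


def _parse_int(minimum: int):
    def parse(tok: str) -> int:
        try:
            value = int(tok)
        except ValueError:
            raise StepParseError(f"expected an integer, got {tok!r}") from None
        if value < minimum:
            raise StepParseError(f"expected an integer >= {minimum}, got {value}")
        return value

    return parse


def _parse_strictness(tok: str) -> float:
    try:
        value = float(tok)
    except ValueError:
        raise StepParseError(f"expected a number, got {tok!r}") from None
    if not 0.0 < value < 1.0:
        raise StepParseError(f"strictness must lie in (0, 1), got {value}")
    return value


def _parse_bool(tok: str) -> bool:
    low = tok.lower()
    if low == "true":
        return True
    if low == "false":
        return False
    raise StepParseError(f"expected 'true' or 'false', got {tok!r}")


def _parse_path(tok: str) -> str:
    if not tok:
        raise StepParseError("empty file path")
    return tok


# name -> (ordered parameter parsers, number of required parameters)
STEP_SCHEMAS: dict[str, tuple[tuple, int]] = {
    "ILLUMINACLIP": (
        (_parse_path, _parse_int(0), _parse_int(0), _parse_int(0),
         _parse_int(1), _parse_bool),
        4,
    ),
    "SLIDINGWINDOW": ((_parse_int(1), _parse_int(0)), 2),
    "MAXINFO": ((_parse_int(1), _parse_strictness), 2),
    "LEADING": ((_parse_int(0),), 1),
    "TRAILING": ((_parse_int(0),), 1),
    "CROP": ((_parse_int(1),), 1),
    "HEADCROP": ((_parse_int(0),), 1),
    "TAILCROP": ((_parse_int(0),), 1),
    "MINLEN": ((_parse_int(0),), 1),
    "AVGQUAL": ((_parse_int(0),), 1),
    "BASECOUNT": ((_parse_int(0),), 1),
}

#: Step names recognized on the command line.
KNOWN_STEPS = frozenset(STEP_SCHEMAS)


@dataclass(frozen=True, slots=True)
class StepSpec:
    """A parsed ``NAME:p1:p2:...`` step token."""

    step_name: str
    params: tuple

    def render(self) -> str:
        """Re-serialize to the colon-delimited token dialect."""
        fields = [self.step_name]
        for p in self.params:
            if isinstance(p, bool):
                fields.append("true" if p else "false")
            else:
                fields.append(str(p))
        return ":".join(fields)


def parse_step_spec(token: str) -> StepSpec:
    """Parse one colon-delimited step token, validating arity and ranges.

    All validation happens here, before any read data is touched, so a typo
    aborts the run up front rather than after hours of processing.
    """
    if not token:
        raise StepParseError("empty step token")
    fields = token.split(":")
    name = fields[0]
    schema = STEP_SCHEMAS.get(name)
    if schema is None:
        raise StepParseError(f"unknown step {name!r}")
    parsers, n_required = schema
    raw_params = fields[1:]
    if not n_required <= len(raw_params) <= len(parsers):
        want = (
            str(n_required)
            if n_required == len(parsers)
            else f"{n_required}..{len(parsers)}"
        )
        raise StepParseError(
            f"{name}: expected {want} parameters, got {len(raw_params)}"
        )
    params = []
    for parser, tok in zip(parsers, raw_params):
        try:
            params.append(parser(tok))
        except StepParseError as exc:
            raise StepParseError(f"{name}: {exc}") from None
    return StepSpec(name, tuple(params))
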