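"""FASTQ reading/writing with transparent compression and pairing utilities.

Compression is selected by file suffix: ``.gz`` (GZIP), ``.bz2`` (BZIP2),
anything else plain text.  Output qualities are always written PHRED+33.

Parallel compressed output is a *multi-member* GZIP stream: records are
grouped into fixed-size blocks, each block compressed independently (the
deflate dictionary resets with every member) on a worker pool, and the
finished members written strictly in input order.  Standard decompressors
read concatenated members as a single stream, so the decompressed bytes are
identical to the serial writer's output by construction; the only cost is a
small per-member header and the lost cross-block dictionary context.
"""

from __future__ import annotations

import bz2
import gzip
import os
from collections import deque
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from itertools import islice, zip_longest
from typing import IO, Iterable, Iterator

from .core_model import (
    PHRED33,
    FastqFormatError,
    PairingError,
    QualityEncoding,
    Read,
    decode_quality,
    detect_encoding,
)

#: Records per independently compressed block in parallel GZIP mode.
DEFAULT_BLOCK_RECORDS = 10_000


def _open_text_reader(path: str) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    if str(path).endswith(".bz2"):
        return bz2.open(path, "rt")
    return open(path, "rt")


def _open_bytes_writer(path: str) -> IO[bytes]:
    if str(path).endswith(".gz"):
        # fixed mtime keeps compressed bytes reproducible run-to-run; the
        # compression level matches the parallel block writer so serial and
        # parallel outputs differ only by per-member framing
        return gzip.GzipFile(path, "wb", compresslevel=6, mtime=0)
    if str(path).endswith(".bz2"):
        return bz2.open(path, "wb")
    return open(path, "wb")


_ENCODE33 = bytes(min(255, i + PHRED33) for i in range(256))


def format_record(read: Read) -> bytes:
    """Serialize one read as a 4-line FASTQ record (PHRED+33, bare '+')."""
    return b"".join(
        (
            b"@", read.name.encode("ascii"), b"\n",
            read.bases.encode("ascii"), b"\n+\n",
            read.quals.translate(_ENCODE33), b"\n",
        )
    )


def _raw_records(path: str) -> Iterator[tuple[int, list[str]]]:
    """Yield (ordinal, [header, bases, plus, quals]) with structural checks."""
    with _open_text_reader(path) as fh:
        it = iter(fh)
        ordinal = 0
        while True:
            header = next(it, None)
            if header is None:
                return
            header = header.rstrip("\n")
            if header == "":
                # tolerate trailing blank line(s) at EOF only
                if next(it, None) is None:
                    return
                raise FastqFormatError(
                    f"{path}: blank line at record {ordinal}"
                )
            lines = [header]
            for _ in range(3):
                line = next(it, None)
                if line is None:
                    raise FastqFormatError(
                        f"{path}: truncated record {ordinal} (unexpected EOF)"
                    )
                lines.append(line.rstrip("\n"))
            if not lines[0].startswith("@"):
                raise FastqFormatError(
                    f"{path}: record {ordinal} header does not start with '@'"
                )
            if not lines[2].startswith("+"):
                raise FastqFormatError(
                    f"{path}: record {ordinal} separator does not start with '+'"
                )
            yield ordinal, lines
            ordinal += 1


def read_quality_lines(path: str) -> Iterator[str]:
    """Stream raw (undecoded) quality lines — input to encoding detection."""
    for _, lines in _raw_records(path):
        yield lines[3]


def read_names(path: str) -> Iterator[str]:
    """Stream record names (headers without '@') — input to pair validation."""
    for _, lines in _raw_records(path):
        yield lines[0][1:]


def detect_file_encoding(path: str, sample_limit: int = 10_000) -> QualityEncoding:
    """Auto-detect the PHRED offset from the first ``sample_limit`` records."""
    return detect_encoding(islice(read_quality_lines(path), sample_limit),
                           sample_limit)


def open_reader(path: str, encoding: QualityEncoding | None = None) -> Iterator[Read]:
    """Yield decoded reads from a (possibly compressed) FASTQ file.

    ``encoding=None`` auto-detects the PHRED offset with a bounded pre-scan.
    """
    if encoding is None:
        encoding = detect_file_encoding(path)
    for ordinal, lines in _raw_records(path):
        name, bases, _, qual = lines
        name = name[1:]
        if len(bases) != len(qual):
            raise FastqFormatError(
                f"{path}: record {ordinal} ({name!r}): sequence length "
                f"{len(bases)} != quality length {len(qual)}"
            )
        yield Read(name, bases, decode_quality(qual, encoding, name))


class SerialFastqWriter:
    """Streams records through a single (optionally compressed) writer."""

    def __init__(self, path: str):
        self.path = path
        self._fh = _open_bytes_writer(path)

    def write(self, read: Read) -> None:
        self._fh.write(format_record(read))

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class ParallelGzipFastqWriter:
    """Order-preserving block-parallel GZIP writer (multi-member stream)."""

    def __init__(self, path: str, workers: int,
                 block_records: int = DEFAULT_BLOCK_RECORDS,
                 compresslevel: int = 6):
        if not str(path).endswith(".gz"):
            raise ValueError("parallel block output requires a .gz path")
        self.path = path
        self._block_records = block_records
        self._level = compresslevel
        self._buffer: list[bytes] = []
        self._pending: deque = deque()
        self._pool = ThreadPoolExecutor(max_workers=max(1, workers))
        self._max_pending = 2 * max(1, workers)
        self._fh = open(path, "wb")
        self._blocks_written = 0

    def write(self, read: Read) -> None:
        self._buffer.append(format_record(read))
        if len(self._buffer) >= self._block_records:
            self._submit_block()

    def _submit_block(self) -> None:
        data = b"".join(self._buffer)
        self._buffer = []
        # each gzip.compress call is a complete member: fresh dictionary
        self._pending.append(
            self._pool.submit(gzip.compress, data, self._level, mtime=0)
        )
        while len(self._pending) > self._max_pending:
            self._fh.write(self._pending.popleft().result())
            self._blocks_written += 1

    def close(self) -> None:
        if self._buffer or (self._blocks_written == 0 and not self._pending):
            # flush the tail; an empty stream still gets one valid empty member
            self._submit_block()
        while self._pending:
            self._fh.write(self._pending.popleft().result())
            self._blocks_written += 1
        self._pool.shutdown()
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def open_writer(path: str, workers: int = 1,
                block_records: int = DEFAULT_BLOCK_RECORDS):
    """Writer factory: block-parallel GZIP when ``workers > 1`` and the path
    is ``.gz``, otherwise serial (plain, GZIP or BZIP2 by suffix)."""
    if workers > 1 and str(path).endswith(".gz"):
        return ParallelGzipFastqWriter(path, workers, block_records)
    return SerialFastqWriter(path)


def write_fastq(reads: Iterable[Read], path: str, workers: int = 1,
                block_records: int = DEFAULT_BLOCK_RECORDS) -> None:
    """Write a read stream to ``path`` (see :func:`open_writer`)."""
    with open_writer(path, workers, block_records) as out:
        for read in reads:
            out.write(read)


# ---------------------------------------------------------------------------
# Template-based file naming
# ---------------------------------------------------------------------------

_COMPRESSION_EXTS = (".gz", ".bz2")
_FASTQ_EXTS = (".fastq", ".fq", ".txt")


@dataclass(frozen=True, slots=True)
class OutputNameSet:
    """The four paired-end output paths derived from one template."""

    fwd_paired: str
    fwd_unpaired: str
    rev_paired: str
    rev_unpaired: str

    def __iter__(self):
        return iter(
            (self.fwd_paired, self.fwd_unpaired,
             self.rev_paired, self.rev_unpaired)
        )


def _split_extension_chain(path: str) -> tuple[str, str]:
    base = path
    chain = ""
    for exts in (_COMPRESSION_EXTS, _FASTQ_EXTS):
        for ext in exts:
            if base.endswith(ext):
                base = base[: -len(ext)]
                chain = ext + chain
                break
    return base, chain


def derive_output_names(baseout_template: str) -> OutputNameSet:
    """Expand ``out.fq.gz`` into ``out_1P.fq.gz`` / ``_1U`` / ``_2P`` / ``_2U``."""
    base, chain = _split_extension_chain(baseout_template)
    return OutputNameSet(
        f"{base}_1P{chain}", f"{base}_1U{chain}",
        f"{base}_2P{chain}", f"{base}_2U{chain}",
    )


_MATE_PATTERNS = (("_1", "_2"), ("_R1", "_R2"), (".1.", ".2."))


def find_mate_path(basein: str) -> str:
    """Given the forward file of a pair, locate the reverse file.

    Replaces the last occurrence of ``_1``/``_R1``/``.1.`` with its mate
    form; the first pattern that names an existing file wins.
    """
    for pat, repl in _MATE_PATTERNS:
        idx = basein.rfind(pat)
        if idx < 0:
            continue
        candidate = basein[:idx] + repl + basein[idx + len(pat):]
        if os.path.exists(candidate):
            return candidate
    raise PairingError(
        f"cannot infer the mate file for {basein!r}; "
        "pass both input files explicitly"
    )


# ---------------------------------------------------------------------------
# Pairing validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class PairingReport:
    """Outcome of validating two name streams for pair synchrony."""

    ok: bool
    mismatch_ordinal: int | None = None
    fwd_name: str | None = None
    rev_name: str | None = None
    n_fwd: int = 0
    n_rev: int = 0

    @property
    def length_mismatch(self) -> bool:
        return self.n_fwd != self.n_rev

    def message(self) -> str:
        if self.ok:
            return "paired files are synchronized"
        if self.mismatch_ordinal is not None:
            return (
                f"pair mismatch at record {self.mismatch_ordinal}: "
                f"{self.fwd_name!r} vs {self.rev_name!r}"
            )
        return (
            f"paired files have unequal record counts "
            f"({self.n_fwd} vs {self.n_rev})"
        )


def canonical_name(name: str) -> str:
    """First whitespace token with a trailing ``/1`` or ``/2`` stripped."""
    token = name.split()[0] if name.split() else ""
    if token.endswith(("/1", "/2")):
        token = token[:-2]
    return token


def validate_pairing(names_fwd: Iterable[str],
                     names_rev: Iterable[str]) -> PairingReport:
    """Check two name streams record-by-record for pair synchrony.

    Returns the first mismatching ordinal (0-based) with both offending
    names, or flags unequal stream lengths, or reports ok.
    """
    n_fwd = n_rev = 0
    first_mismatch: tuple[int, str, str] | None = None
    for i, (a, b) in enumerate(zip_longest(names_fwd, names_rev)):
        if a is not None:
            n_fwd += 1
        if b is not None:
            n_rev += 1
        if first_mismatch is None and a is not None and b is not None:
            if canonical_name(a) != canonical_name(b):
                first_mismatch = (i, a, b)
    if first_mismatch is not None:
        i, a, b = first_mismatch
        return PairingReport(False, i, a, b, n_fwd, n_rev)
    if n_fwd != n_rev:
        return PairingReport(False, None, None, None, n_fwd, n_rev)
    return PairingReport(True, None, None, None, n_fwd, n_rev)


def validate_pairing_files(path_fwd: str, path_rev: str) -> PairingReport:
    """:func:`validate_pairing` over the record names of two FASTQ files."""
    return validate_pairing(read_names(path_fwd), read_names(path_rev))
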