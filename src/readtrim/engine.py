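"""Pipeline engine: compile step tokens, apply them to read streams, and run
whole files with paired fate bookkeeping and order-preserving concurrency.

Reads are consumed in file order, grouped into fixed-size batches, processed
(possibly by a worker pool) and written strictly in input order.  Because
every step is a pure function of its input read(s), the outputs are
bit-identical for every worker count — concurrency is an implementation
freedom constrained only by that contract.
"""

from __future__ import annotations

from collections import deque
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from itertools import zip_longest
from typing import Iterable, Iterator, Sequence

from . import adapter_clip, trim_steps
from .adapter_clip import AdapterSet, ClipParams
from .core_model import (
    PairingError,
    QualityEncoding,
    Read,
    ReadPair,
    StepSpec,
    parse_step_spec,
)
from .fastq_io import (
    DEFAULT_BLOCK_RECORDS,
    _open_bytes_writer,
    open_reader,
    open_writer,
    validate_pairing_files,
)
from .reporting import PAIRED, SINGLE, RunStats, render_summary
from .trim_steps import MaxInfoParams, StepOutcome

DEFAULT_BATCH_SIZE = 5_000

BOTH_SURVIVING = "both_surviving"
FWD_ONLY = "fwd_only"
REV_ONLY = "rev_only"
DROPPED = "dropped"


class PerReadStep:
    """A step applied independently to each read."""

    pair_aware = False

    def __init__(self, name: str, fn):
        self.name = name
        self._fn = fn

    def __call__(self, read: Read) -> StepOutcome:
        return self._fn(read)


class IlluminaClipStep:
    """ILLUMINACLIP: palindrome mode across the pair, then simple mode per
    mate.  In single-end mode only simple adapters apply."""

    pair_aware = True
    name = "ILLUMINACLIP"

    def __init__(self, adapters: AdapterSet, params: ClipParams):
        self.adapters = adapters
        self.params = params

    def __call__(self, read: Read) -> StepOutcome:
        cur = read
        cut_end = 0
        for _, seq in self.adapters.simple_adapters:
            out = adapter_clip.simple_clip(cur, seq, self.params)
            cut_end += out.cut_from_end
            if out.dropped:
                return StepOutcome(None, 0, len(read))
            cur = out.read
        return StepOutcome(cur, 0, cut_end)

    def process_pair(self, fwd: Read, rev: Read) -> tuple[StepOutcome, StepOutcome]:
        n1, n2 = len(fwd), len(rev)
        cur_f: Read | None = fwd
        cur_r: Read | None = rev
        for _, fwd_prefix, rev_prefix in self.adapters.palindrome_pairs:
            out_f, out_r = adapter_clip.palindrome_clip(
                cur_f, cur_r, fwd_prefix, rev_prefix, self.params
            )
            cur_f, cur_r = out_f.read, out_r.read
            if (out_f.cut_from_end or out_r.dropped or out_r.cut_from_end):
                break  # a pair triggered; further palindrome pairs are moot
            if cur_f is None or cur_r is None:
                break
        res_f = self(cur_f) if cur_f is not None else StepOutcome(None, 0, n1)
        res_r = self(cur_r) if cur_r is not None else StepOutcome(None, 0, n2)
        out_f = (
            StepOutcome(None, 0, n1)
            if res_f.dropped
            else StepOutcome(res_f.read, 0, n1 - len(res_f.read))
        )
        out_r = (
            StepOutcome(None, 0, n2)
            if res_r.dropped
            else StepOutcome(res_r.read, 0, n2 - len(res_r.read))
        )
        return out_f, out_r


def compile_step(spec: StepSpec):
    """Turn a parsed :class:`StepSpec` into an executable step object."""
    name, p = spec.step_name, spec.params
    if name == "ILLUMINACLIP":
        adapters = adapter_clip.load_adapters(p[0])
        params = ClipParams(
            seed_mismatches=p[1],
            palindrome_threshold=float(p[2]),
            simple_threshold=float(p[3]),
            min_adapter_length=p[4] if len(p) > 4 else 8,
            keep_both_reads=p[5] if len(p) > 5 else False,
        )
        return IlluminaClipStep(adapters, params)
    if name == "SLIDINGWINDOW":
        return PerReadStep(name, lambda r: trim_steps.sliding_window(r, p[0], p[1]))
    if name == "MAXINFO":
        mp = MaxInfoParams(p[0], p[1])
        return PerReadStep(name, lambda r: trim_steps.maxinfo(r, mp))
    if name == "LEADING":
        return PerReadStep(name, lambda r: trim_steps.leading(r, p[0]))
    if name == "TRAILING":
        return PerReadStep(name, lambda r: trim_steps.trailing(r, p[0]))
    if name == "CROP":
        return PerReadStep(name, lambda r: trim_steps.crop(r, p[0]))
    if name == "HEADCROP":
        return PerReadStep(name, lambda r: trim_steps.headcrop(r, p[0]))
    if name == "TAILCROP":
        return PerReadStep(name, lambda r: trim_steps.tailcrop(r, p[0]))
    if name in ("MINLEN", "BASECOUNT"):
        return PerReadStep(name, lambda r: trim_steps.min_length(r, p[0]))
    if name == "AVGQUAL":
        return PerReadStep(name, lambda r: trim_steps.avgqual(r, p[0]))
    raise ValueError(f"unknown step {name!r}")


def compile_steps(specs: Iterable[StepSpec | str]) -> list:
    """Compile a step list; plain strings are parsed first."""
    compiled = []
    for spec in specs:
        if isinstance(spec, str):
            spec = parse_step_spec(spec)
        compiled.append(compile_step(spec))
    return compiled


@dataclass(slots=True)
class _ReadResult:
    """Per-read pipeline result, sufficient for output and the trim log."""

    name: str
    original_length: int
    outcome: StepOutcome
    drop_step: str | None = None


def _apply_to_read(read: Read, steps: Sequence) -> _ReadResult:
    cur = read
    cut_start = 0
    cut_end = 0
    for step in steps:
        out = step(cur)
        if out.dropped:
            return _ReadResult(
                read.name, len(read), StepOutcome(None, 0, 0), step.name
            )
        cut_start += out.cut_from_start
        cut_end += out.cut_from_end
        cur = out.read
    return _ReadResult(read.name, len(read), StepOutcome(cur, cut_start, cut_end))


def apply_steps_single(read: Read, steps: Sequence) -> StepOutcome:
    """Apply steps left to right to one read; a drop short-circuits."""
    return _apply_to_read(read, steps).outcome


@dataclass(slots=True)
class _PairResult:
    fwd: _ReadResult
    rev: _ReadResult
    fate: str


def _apply_to_pair(pair: ReadPair, steps: Sequence) -> _PairResult:
    fwd, rev = pair.fwd, pair.rev
    n1, n2 = len(fwd), len(rev)
    name1, name2 = fwd.name, rev.name
    cur_f: Read | None = fwd
    cur_r: Read | None = rev
    cs = [0, 0]
    ce = [0, 0]
    drop_step: list[str | None] = [None, None]

    for step in steps:
        if cur_f is None and cur_r is None:
            break
        if step.pair_aware and cur_f is not None and cur_r is not None:
            out_f, out_r = step.process_pair(cur_f, cur_r)
            outs = (out_f, out_r)
        else:
            outs = tuple(
                step(c) if c is not None else None for c in (cur_f, cur_r)
            )
        for i, out in enumerate(outs):
            if out is None:
                continue
            if out.dropped:
                drop_step[i] = step.name
                if i == 0:
                    cur_f = None
                else:
                    cur_r = None
            else:
                cs[i] += out.cut_from_start
                ce[i] += out.cut_from_end
                if i == 0:
                    cur_f = out.read
                else:
                    cur_r = out.read

    res_f = _ReadResult(
        name1, n1,
        StepOutcome(cur_f, cs[0], ce[0]) if cur_f is not None
        else StepOutcome(None, 0, 0),
        drop_step[0],
    )
    res_r = _ReadResult(
        name2, n2,
        StepOutcome(cur_r, cs[1], ce[1]) if cur_r is not None
        else StepOutcome(None, 0, 0),
        drop_step[1],
    )
    if cur_f is not None and cur_r is not None:
        fate = BOTH_SURVIVING
    elif cur_f is not None:
        fate = FWD_ONLY
    elif cur_r is not None:
        fate = REV_ONLY
    else:
        fate = DROPPED
    return _PairResult(res_f, res_r, fate)


def apply_steps_pair(
    pair: ReadPair, steps: Sequence
) -> tuple[StepOutcome, StepOutcome, str]:
    """Apply steps to a pair; pair-aware steps see both mates at once."""
    res = _apply_to_pair(pair, steps)
    return res.fwd.outcome, res.rev.outcome, res.fate


def _batched(items: Iterator, size: int) -> Iterator[list]:
    batch: list = []
    for item in items:
        batch.append(item)
        if len(batch) >= size:
            yield batch
            batch = []
    if batch:
        yield batch


def _zip_pairs(fwd_reads: Iterator[Read], rev_reads: Iterator[Read],
               fwd_path: str, rev_path: str) -> Iterator[ReadPair]:
    for i, (f, r) in enumerate(zip_longest(fwd_reads, rev_reads)):
        if f is None or r is None:
            short = fwd_path if f is None else rev_path
            raise PairingError(
                f"{short}: ran out of records at pair {i}; "
                "paired inputs have unequal length"
            )
        yield ReadPair(f, r)


def run(
    fwd_in: str,
    rev_in: str | None = None,
    steps: Sequence[StepSpec | str] = (),
    *,
    out_single: str | None = None,
    out_fwd_paired: str | None = None,
    out_fwd_unpaired: str | None = None,
    out_rev_paired: str | None = None,
    out_rev_unpaired: str | None = None,
    threads: int = 1,
    encoding: QualityEncoding | None = None,
    batch_size: int = DEFAULT_BATCH_SIZE,
    block_records: int = DEFAULT_BLOCK_RECORDS,
    trimlog: str | None = None,
    summary: str | None = None,
    validate_pairs: bool = False,
) -> RunStats:
    """Run the full pipeline over one file (SE) or a file pair (PE).

    Validation (step parsing, adapter loading, optional pairing check,
    encoding detection) completes before any output file is created.  For
    fixed inputs and steps, all outputs are byte-identical (after
    decompression) for every ``threads`` value.
    """
    compiled = compile_steps(steps)
    paired = rev_in is not None
    if paired and validate_pairs:
        report = validate_pairing_files(fwd_in, rev_in)
        if not report.ok:
            raise PairingError(report.message())

    if encoding is None:
        from .fastq_io import detect_file_encoding

        encoding = detect_file_encoding(fwd_in)

    stats = RunStats(mode=PAIRED if paired else SINGLE)
    log_fh = _open_bytes_writer(trimlog) if trimlog else None

    try:
        if paired:
            _run_paired(
                fwd_in, rev_in, compiled, encoding, stats,
                (out_fwd_paired, out_fwd_unpaired,
                 out_rev_paired, out_rev_unpaired),
                threads, batch_size, block_records, log_fh,
            )
        else:
            _run_single(
                fwd_in, compiled, encoding, stats, out_single,
                threads, batch_size, block_records, log_fh,
            )
    finally:
        if log_fh is not None:
            log_fh.close()

    stats.check_partition()
    if summary:
        with _open_bytes_writer(summary) as fh:
            fh.write(render_summary(stats).encode("ascii"))
    return stats


def _map_batches(process, batches: Iterator[list], threads: int):
    """Ordered map over batches with a bounded in-flight window."""
    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            pending: deque = deque()
            for batch in batches:
                pending.append(pool.submit(process, batch))
                if len(pending) > 2 * threads:
                    yield pending.popleft().result()
            while pending:
                yield pending.popleft().result()
    else:
        for batch in batches:
            yield process(batch)


def _write_log(log_fh, results: Iterable[_ReadResult]) -> None:
    from .reporting import render_trimlog_line

    for res in results:
        line = render_trimlog_line(res.name, res.outcome, res.original_length)
        log_fh.write(line.encode("ascii") + b"\n")


def _run_paired(fwd_in, rev_in, compiled, encoding, stats, out_paths,
                threads, batch_size, block_records, log_fh) -> None:
    pairs = _zip_pairs(
        open_reader(fwd_in, encoding), open_reader(rev_in, encoding),
        fwd_in, rev_in,
    )

    def process(batch: list[ReadPair]) -> list[_PairResult]:
        return [_apply_to_pair(p, compiled) for p in batch]

    writers = [
        open_writer(p, threads, block_records) if p else None
        for p in out_paths
    ]
    w_1p, w_1u, w_2p, w_2u = writers
    try:
        for results in _map_batches(process, _batched(pairs, batch_size), threads):
            for res in results:
                stats.input_count += 1
                fate = res.fate
                if fate == BOTH_SURVIVING:
                    stats.both_surviving += 1
                    if w_1p:
                        w_1p.write(res.fwd.outcome.read)
                    if w_2p:
                        w_2p.write(res.rev.outcome.read)
                elif fate == FWD_ONLY:
                    stats.fwd_only += 1
                    if w_1u:
                        w_1u.write(res.fwd.outcome.read)
                elif fate == REV_ONLY:
                    stats.rev_only += 1
                    if w_2u:
                        w_2u.write(res.rev.outcome.read)
                else:
                    stats.dropped += 1
                for rr in (res.fwd, res.rev):
                    if rr.drop_step:
                        stats.count_drop(rr.drop_step)
                if log_fh is not None:
                    _write_log(log_fh, (res.fwd, res.rev))
    finally:
        for w in writers:
            if w is not None:
                w.close()


def _run_single(path_in, compiled, encoding, stats, out_single,
                threads, batch_size, block_records, log_fh) -> None:
    reads = open_reader(path_in, encoding)

    def process(batch: list[Read]) -> list[_ReadResult]:
        return [_apply_to_read(r, compiled) for r in batch]

    writer = open_writer(out_single, threads, block_records) if out_single else None
    try:
        for results in _map_batches(process, _batched(reads, batch_size), threads):
            for res in results:
                stats.input_count += 1
                if res.outcome.dropped:
                    stats.dropped += 1
                    if res.drop_step:
                        stats.count_drop(res.drop_step)
                else:
                    stats.surviving += 1
                    if writer:
                        writer.write(res.outcome.read)
                if log_fh is not None:
                    _write_log(log_fh, (res,))
    finally:
        if writer is not None:
            writer.close()
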