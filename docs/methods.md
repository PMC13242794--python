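# Methods

## Scope and model

`readtrim` preprocesses Illumina-style short reads: it removes adapter
sequence and low-quality regions from single-end or paired-end FASTQ data
before alignment or assembly. The unit of processing is the read (or the
read pair); a pipeline is an ordered list of steps, each a pure function
mapping a read to a contiguous sub-window of itself or to *dropped*. Steps
compose left to right; a drop short-circuits the rest of the list. In
paired mode the two mates pass through the same step list; pair-aware steps
(palindrome adapter clipping) see both mates at once, and the pair's fate —
both surviving, forward only, reverse only, dropped — decides which of the
four output files each surviving mate is written to, preserving mate
synchrony for downstream pair-aware tools.

All coordinates are 0-based, half-open. Quality thresholds are uniformly
strict ("fails when `< q`"), and window means are compared in exact integer
arithmetic (`sum(quals) < q*w`), so boundary cases are well defined and the
same on every platform.

## Quality model and encoding detection

A PHRED score `q` encodes base-call error probability `10^(-q/10)` and is
stored as ASCII `chr(q + offset)` with offset 33 or 64. The detector scans
up to 10,000 records (bounded startup cost, ample signal) and applies the
character-code range rule: any code below 64 forces offset 33; otherwise a
code above 74 forces offset 64; codes confined to 64..74 are compatible
with both, and the detector refuses to guess — a wrong offset silently
corrupts every quality decision, so ambiguity is an error that tells the
user to pass `-phred33`/`-phred64` explicitly.

## Trimming steps

* **HEADCROP / TAILCROP / CROP** — fixed-length truncation (UMI/barcode
  removal, cycle trimming). A crop that consumes the whole read drops it
  (CROP, which *keeps* a prefix, never drops).
* **LEADING / TRAILING** — strip end bases individually below `q`.
* **SLIDINGWINDOW:w:q** — scan windows of width `w` from the 5' end; at the
  first window with mean quality `< q`, truncate to that window's start
  offset, then strip any remaining 3' bases individually below `q` (without
  the cleanup, a bad tail shorter than the window could survive). A read
  shorter than `w` is one window. No failing window leaves the read
  untouched.
* **MAXINFO:T:s** — keep the prefix length `L*` maximizing
  `-ln(1+e^(T-1-L)) + (1-s)·ln L + s·Σ_{i<L} ln(1-10^(-q_i/10))`:
  a logistic ramp that discounts prefixes short of the target length `T`, a
  coverage reward for extra bases, and a correctness penalty accumulating
  the log-probability that every kept base is right (`q=0` treated as
  `q=1` to stay finite). Strictness `s ∈ (0,1)` tilts the balance toward
  error avoidance. Ties break toward the longer prefix; the exhaustive
  arg-max over all prefixes *is* the definition, and the vectorized
  implementation is tested against a brute-force transcription of it.
* **AVGQUAL:q** — drop the read when its mean quality is below `q`
  (global filter for systemically failed reads; empty reads drop).
* **MINLEN:n / BASECOUNT:n** — drop reads shorter than `n`; BASECOUNT is a
  second token name for the same post-trimming length threshold.

## Adapter clipping (ILLUMINACLIP)

Scoring: a match earns `log10 4 ≈ 0.602` (the information content of one
certain base, in bans), a mismatch costs `q/10` with `q` the read base's
quality; `N` never matches. The conventional thresholds then mean what
practitioners expect: a simple threshold of 10 requires ≈17 perfect
matches, a palindrome threshold of 30 requires ≈50. A 16-base seed with a
small mismatch budget (`seed_mismatches`) prunes candidates before full
scoring.

*Simple mode* slides the adapter along the read (earliest qualifying offset
wins, including partial 3' overlaps; offsets whose maximum possible score
cannot reach the threshold are skipped) and truncates the read before the
alignment start.

*Palindrome mode* detects read-through directly from pair structure: when
the fragment is shorter than the read, the forward read equals the reverse
complement of the reverse read across the whole fragment, and each read
runs on into the reverse complement of the *other* mate's 5' adapter.
Prepending each mate's adapter prefix extends the palindromic overlap into
the adapters, so even one-base read-through yields a long, specific
overlap. Fragment lengths are scanned ascending; the best-scoring
qualifying length wins (ties to the shortest); both mates are trimmed to
that length. The trimmed reverse mate duplicates the forward mate's
information, so it is dropped unless `keepBothReads` is set.

Adapter FASTA records named `stem/1` + `stem/2` form palindrome prefix
pairs; all other records are simple adapters; a lone `/1` or `/2` record
falls back to simple mode with a warning.

## Engine, concurrency, and compression

Reads are consumed in order, grouped into batches (default 5,000 pairs —
large enough to amortize coordination, small enough to bound memory at
roughly batch × read length), processed by a worker pool, and written
strictly in input order with a bounded in-flight window. Because steps are
pure and stateless, the outputs are byte-identical for every worker count;
that invariance is the tested contract, and the worker count is free to be
a pure performance knob.

Parallel GZIP output groups records into blocks (default 10,000), each
compressed as a complete, independent GZIP member — the deflate dictionary
resets at each member boundary, which is what makes blocks independently
compressible. Standard decompressors concatenate members, so `gunzip`
yields bytes identical to the serial writer's output by construction; the
cost is the per-member framing plus the lost cross-block dictionary,
measured by the acceptance script at roughly 2% for 200-record blocks on
simulated reads (it shrinks as blocks grow). Serial and parallel writers
use the same compression level (6) and a fixed member mtime so compressed
bytes are reproducible run to run. BZIP2 is supported for reading and
serial writing only; parallel BZIP2 writing is out of scope.

## Reporting

The summary file is a frozen `key: value` format (PE: input pairs, both
surviving, forward only, reverse only, dropped, each with a percentage to
two decimals; SE: input, surviving, dropped) so downstream parsers can rely
on it. The optional trim log writes one space-separated line per input
read: name, surviving length, first kept offset, last kept offset
(exclusive), bases trimmed from the end; a dropped read logs
`name 0 0 0 L`.

## Synthetic data

The generator emulates a short-insert Illumina library: fragment lengths
from a normal distribution truncated below (default 60 ± 10, minimum 20),
2 × 100 bp reads, per-cycle mean quality decaying linearly Q38 → Q20
(per-base jitter sd 3, clipped to 2..41), and substitution errors at an
overall rate (default 0.1%/base) distributed across positions in proportion
to each base's nominal error probability `10^(-q/10)`, so low-quality
cycles err more often. When the insert is shorter than the read, each mate
reads through into the reverse complement of the other mate's adapter
prefix, then into random padding; the truth table records the insert length
and adapter start offset per pair, making clipping accuracy exactly
scorable. The adapter sequences are fixed synthetic inventions with the
structure (not the sequence) of a TruSeq-style kit. Corruption modes
(shuffle, drop-one, rename) produce pairing-validator fixtures with a known
first divergence, and a re-encoder shifts quality characters by +31 to
produce PHRED+64 fixtures.

Deliberately not modeled: indels, optical duplicates, platform-specific
error motifs, quality-by-sequence context, and UMI semantics. Passing
tests therefore demonstrate correctness of the trimming logic under a
clean substitution-error model, not robustness to every artifact of real
instruments.

## Problem sizes and numerical choices

The test suite exercises 10,000-pair scenarios for the oracle-equivalence,
worker-invariance, and adapter-recovery checks and 50 small randomized
configurations for fate conservation; the acceptance script uses 5,000
pairs, chosen as comfortably large enough for stable percentages while
keeping a full run in seconds. Scores in MAXINFO use `logaddexp` for the
logistic term, so large targets cannot overflow. The palindrome search
prunes fragment lengths whose overlap cannot reach the threshold; the
pruning is score-conservative and cannot change results.

## Known limitations

Simple-mode clipping keeps only the sequence before the *earliest*
qualifying alignment; adapter dimers with internal repeats can in principle
truncate one base early if the repeat offers an equally scoring earlier
offset. The encoding detector inspects only character-code ranges, not
score distributions, so pathological files (e.g. uniformly Q31..Q41 data
in PHRED+33) are reported ambiguous rather than guessed. Threads share the
Python interpreter, so CPU-bound scaling is modest; the parallel paths
exist to honor (and test) the order/byte-identity contracts and to
parallelize compression, which releases the interpreter lock.
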