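"""Adapter detection and removal (the ILLUMINACLIP step).

Two complementary detection modes are implemented:

* **Simple mode** aligns an adapter sequence against a single read at every
  offset and truncates the read where a sufficiently good alignment starts.
  It works on any read but short 3' adapter remnants are hard to distinguish
  from chance matches.
* **Palindrome mode** exploits paired-end structure.  When the sequenced
  fragment is shorter than the read length, both mates read through the
  insert into the adapter on the far side; the forward read then equals the
  reverse complement of the reverse read over the whole fragment.  Prepending
  each mate's 5' adapter prefix extends that palindromic overlap into the
  adapters themselves, allowing even a one-base read-through to be scored
  against a long, highly specific overlap.  A qualifying overlap at fragment
  length ``f`` trims both mates to ``f`` bases.

Alignment scoring gives each match ``+log10(4)`` (~0.602 bits in decibans —
the information content of one certain base) and each mismatch ``-q/10``
where ``q`` is the read base's quality, so the conventional thresholds have a
direct interpretation: a simple threshold of 10 needs ~17 perfect matches, a
palindrome threshold of 30 needs ~50.  ``N`` never counts as a match.  A
16-base seed with a small mismatch budget prunes the search.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from Bio import SeqIO

from .core_model import Read
from .trim_steps import StepOutcome

#: Per-match score increment: log10 of the 4-letter alphabet size.
MATCH_BONUS = math.log10(4.0)
#: Length of the exact-ish seed used to prune candidate alignments.
SEED_LENGTH = 16
#: Nominal quality assumed for (quality-less) adapter prefix positions.
_ADAPTER_QUAL = 40

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet, case-preserving."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class ClipParams:
    """ILLUMINACLIP parameters (``file:seed:palindrome:simple[:minlen[:keep]]``)."""

    seed_mismatches: int
    palindrome_threshold: float
    simple_threshold: float
    min_adapter_length: int = 8
    keep_both_reads: bool = False


@dataclass(slots=True)
class AdapterSet:
    """Adapter sequences partitioned into palindrome prefix pairs and
    simple adapters.

    FASTA records named ``<stem>/1`` and ``<stem>/2`` form a palindrome pair;
    everything else is used in simple mode.
    """

    palindrome_pairs: list[tuple[str, str, str]]  # (stem, fwd prefix, rev prefix)
    simple_adapters: list[tuple[str, str]]  # (name, sequence)


def load_adapters(path: str) -> AdapterSet:
    """Load an adapter FASTA, pairing ``/1``-``/2`` records for palindrome mode.

    A ``/1`` record without its ``/2`` partner (or vice versa) falls back to
    simple mode with a warning.  An empty file is an error.
    """
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(path, "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"adapter file {path!r} contains no sequences")

    by_name = dict(records)
    if len(by_name) != len(records):
        raise ValueError(f"adapter file {path!r} has duplicate record names")

    pairs: list[tuple[str, str, str]] = []
    simple: list[tuple[str, str]] = []
    paired_names: set[str] = set()
    for name, seq in records:
        if name.endswith("/1"):
            stem = name[:-2]
            mate = stem + "/2"
            if mate in by_name:
                pairs.append((stem, seq, by_name[mate]))
                paired_names.update((name, mate))
    for name, seq in records:
        if name in paired_names:
            continue
        if name.endswith(("/1", "/2")):
            warnings.warn(
                f"adapter record {name!r} has no palindrome partner; "
                "using it in simple mode"
            )
        simple.append((name, seq))
    return AdapterSet(pairs, simple)


def alignment_score(read_bases: str, read_quals: bytes, adapter_bases: str) -> float:
    """Score an equal-length read window against an adapter window.

    Case-insensitive match: ``+log10(4)``.  Mismatch (including any position
    where either base is ``N``): ``-q/10`` with ``q`` the read base quality.
    """
    if len(read_bases) != len(adapter_bases):
        raise ValueError("alignment windows must have equal length")
    score = 0.0
    rb = read_bases.upper()
    ab = adapter_bases.upper()
    for i in range(len(rb)):
        b = rb[i]
        if b == ab[i] and b != "N":
            score += MATCH_BONUS
        else:
            score -= read_quals[i] / 10.0
    return score


def _seed_ok(rb: str, quals: bytes, ab: str, offset: int, overlap: int,
             budget: int) -> bool:
    mism = 0
    for i in range(min(SEED_LENGTH, overlap)):
        b = rb[offset + i]
        if b != ab[i] or b == "N":
            mism += 1
            if mism > budget:
                return False
    return True


def simple_clip(read: Read, adapter: str, p: ClipParams) -> StepOutcome:
    """Truncate ``read`` before the earliest qualifying adapter alignment.

    Every start offset of the adapter within the read is considered,
    including partial 3' overlaps, skipping only offsets whose overlap is too
    short to ever reach ``simple_threshold``.  A candidate must first pass
    the seed test (at most ``seed_mismatches`` mismatches within the first
    ``min(16, overlap)`` adapter bases), then score at least
    ``simple_threshold`` over the full overlap.  An alignment starting at
    offset 0 drops the read.
    """
    n = len(read)
    ab = adapter.upper()
    alen = len(ab)
    rb = read.bases.upper()
    quals = read.quals
    for offset in range(n):
        overlap = min(alen, n - offset)
        if overlap * MATCH_BONUS < p.simple_threshold:
            continue
        if not _seed_ok(rb, quals, ab, offset, overlap, p.seed_mismatches):
            continue
        score = alignment_score(
            rb[offset:offset + overlap], quals[offset:offset + overlap],
            ab[:overlap],
        )
        if score >= p.simple_threshold:
            if offset == 0:
                return StepOutcome(None, 0, n)
            return StepOutcome(read.window(0, offset), 0, n - offset)
    return StepOutcome(read, 0, 0)


def palindrome_clip(
    fwd: Read, rev: Read, fwd_prefix: str, rev_prefix: str, p: ClipParams
) -> tuple[StepOutcome, StepOutcome]:
    """Detect read-through via the palindromic mate overlap and trim both
    mates to the implied fragment length.

    Conceptually the forward prefix adapter is prepended to the forward read
    and the reverse prefix adapter to the reverse read; the extended forward
    read is then aligned against the reverse complement of the extended
    reverse read at every candidate fragment length below the read length,
    scanned ascending.  Each candidate must pass the 16-base seed test before
    the full overlap is scored; the best-scoring qualifying fragment length
    wins (ties go to the shorter fragment).  If the best score reaches
    ``palindrome_threshold`` both mates are trimmed to the fragment length;
    unless ``keep_both_reads`` is set the reverse mate is then dropped as
    fully redundant with the forward one.
    """
    a1 = fwd_prefix.upper()
    a2 = rev_prefix.upper()
    la1, la2 = len(a1), len(a2)
    n1, n2 = len(fwd), len(rev)

    ext1 = a1 + fwd.bases.upper()
    # reverse complement of (rev prefix + reverse read)
    rc2 = revcomp(a2 + rev.bases.upper())  # == revcomp(rev bases) + revcomp(a2)
    ext1_quals = bytes([_ADAPTER_QUAL]) * la1 + fwd.quals
    rc2_quals = rev.quals[::-1] + bytes([_ADAPTER_QUAL]) * la2

    len1 = la1 + n1
    len2 = la2 + n2

    best_score = -math.inf
    best_frag = -1
    for frag in range(1, max(n1, n2)):
        shift = la1 - n2 + frag  # ext1[k] pairs with rc2[k - shift]
        start = max(0, shift)
        stop = min(len1, shift + len2)
        overlap = stop - start
        if overlap <= 0 or overlap * MATCH_BONUS < p.palindrome_threshold:
            continue
        # seed: first min(16, overlap) positions of the overlap
        mism = 0
        ok = True
        for k in range(start, start + min(SEED_LENGTH, overlap)):
            b = ext1[k]
            if b != rc2[k - shift] or b == "N":
                mism += 1
                if mism > p.seed_mismatches:
                    ok = False
                    break
        if not ok:
            continue
        score = 0.0
        for k in range(start, stop):
            b = ext1[k]
            if b == rc2[k - shift] and b != "N":
                score += MATCH_BONUS
            else:
                # penalize by the real read base's quality where one exists
                q = ext1_quals[k] if k >= la1 else rc2_quals[k - shift]
                score -= q / 10.0
        if score > best_score:
            best_score = score
            best_frag = frag

    if best_frag < 0 or best_score < p.palindrome_threshold:
        return StepOutcome(fwd, 0, 0), StepOutcome(rev, 0, 0)

    keep1 = min(best_frag, n1)
    out_fwd = (
        StepOutcome(fwd, 0, 0)
        if keep1 == n1
        else StepOutcome(fwd.window(0, keep1), 0, n1 - keep1)
    )
    if not p.keep_both_reads:
        out_rev = StepOutcome(None, 0, n2)
    else:
        keep2 = min(best_frag, n2)
        out_rev = (
            StepOutcome(rev, 0, 0)
            if keep2 == n2
            else StepOutcome(rev.window(0, keep2), 0, n2 - keep2)
        )
    return out_fwd, out_rev
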