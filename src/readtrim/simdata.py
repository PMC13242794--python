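"""Seeded synthetic paired-end read generator.

Emulates a short-insert Illumina library at desk scale: fragments drawn from
a truncated normal insert-size distribution, 2 x ``read_length`` sequencing,
adapter read-through whenever the insert is shorter than the read, per-cycle
quality decay, and quality-consistent substitution errors.  Every pair comes
with a truth row (true insert length, adapter start offset per mate) so
adapter-removal accuracy can be scored exactly without external data.

The default configuration — 2 x 100 bp, insert 60 +/- 10 (min 20), 0.1%
errors, quality decaying from Q38 to Q20 — is a NovaSeq-like short-insert
scenario in which most pairs read through into adapter, the hard case for
adapter clipping.  What the generator does *not* emulate: indels, optical
duplicates, platform-specific error motifs, or UMI semantics.

The adapter sequences are synthetic inventions with the structure of a
TruSeq-style kit (a /1,/2 palindrome prefix pair whose reverse complements
appear at the 3' ends of the mates); they match no real vendor sequence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .adapter_clip import revcomp
from .core_model import Read, ReadPair
from .fastq_io import SerialFastqWriter, _open_bytes_writer, _raw_records

#: Synthetic palindrome prefix adapters (fixed inventions, no real kit).
ADAPTER_FWD_PREFIX = "ACGTTGTATACGACGGCGGCGCAGGGGATTTCG"
ADAPTER_REV_PREFIX = "CTTCTGCCCTAAAAACTCTGGTAACCTCATCCC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {c: i for i, c in enumerate("ACGT")}


def _to_codes(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.int64)


@dataclass(frozen=True, slots=True)
class SimConfig:
    """Generator configuration; same seed and config give identical output."""

    n_pairs: int = 1000
    read_length: int = 100
    insert_mean: float = 60.0
    insert_sd: float = 10.0
    insert_min: int = 20
    adapter_fwd: str = ADAPTER_FWD_PREFIX
    adapter_rev: str = ADAPTER_REV_PREFIX
    error_rate: float = 0.001
    qual_start: float = 38.0
    qual_end: float = 20.0
    qual_sd: float = 3.0
    seed: int = 1


@dataclass(slots=True)
class TruthRow:
    """Ground truth for one simulated pair.

    ``adapter_start`` is the 0-based offset at which adapter sequence begins
    in each mate (equal to the insert length), or -1 when the insert is at
    least as long as the read (no read-through).
    """

    name: str
    insert_length: int
    adapter_start_fwd: int
    adapter_start_rev: int


def _qualities(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    means = np.linspace(cfg.qual_start, cfg.qual_end, cfg.read_length)
    q = rng.normal(means, cfg.qual_sd)
    return np.clip(np.rint(q), 2, 41).astype(np.uint8)


def _apply_errors(rng: np.random.Generator, codes: np.ndarray,
                  quals: np.ndarray, error_rate: float) -> np.ndarray:
    """Substitution errors at overall rate ``error_rate``, distributed across
    positions proportionally to each base's nominal error probability
    ``10**(-q/10)`` (low-quality cycles err more often)."""
    if error_rate <= 0.0:
        return codes
    e = np.power(10.0, -quals.astype(np.float64) / 10.0)
    p = np.minimum(1.0, error_rate * e / e.mean())
    hits = rng.random(codes.size) < p
    if hits.any():
        codes = codes.copy()
        codes[hits] = (codes[hits] + rng.integers(1, 4, int(hits.sum()))) % 4
    return codes


def _mate_codes(fragment: np.ndarray, adapter_codes: np.ndarray,
                read_length: int, rng: np.random.Generator) -> np.ndarray:
    """Insert, then adapter read-through, then random padding."""
    parts = [fragment[:read_length]]
    have = parts[0].size
    if have < read_length:
        parts.append(adapter_codes[: read_length - have])
        have += parts[1].size
    if have < read_length:
        parts.append(rng.integers(0, 4, read_length - have))
    return np.concatenate(parts) if len(parts) > 1 else parts[0]


def generate_read_pairs(cfg: SimConfig) -> tuple[list[ReadPair], list[TruthRow]]:
    """Generate ``cfg.n_pairs`` read pairs plus their truth table."""
    rng = np.random.default_rng(cfg.seed)
    rl = cfg.read_length
    rc_a2 = _to_codes(revcomp(cfg.adapter_rev))  # read 1 reads into this
    rc_a1 = _to_codes(revcomp(cfg.adapter_fwd))  # read 2 reads into this

    inserts = np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, cfg.n_pairs))
    inserts = np.maximum(inserts, cfg.insert_min).astype(np.int64)

    pairs: list[ReadPair] = []
    truth: list[TruthRow] = []
    for i in range(cfg.n_pairs):
        ins = int(inserts[i])
        fragment = rng.integers(0, 4, ins)
        codes1 = _mate_codes(fragment, rc_a2, rl, rng)
        # reverse read sequences the fragment from the other end
        rc_fragment = 3 - fragment[::-1]
        codes2 = _mate_codes(rc_fragment, rc_a1, rl, rng)

        q1 = _qualities(rng, cfg)
        q2 = _qualities(rng, cfg)
        codes1 = _apply_errors(rng, codes1, q1, cfg.error_rate)
        codes2 = _apply_errors(rng, codes2, q2, cfg.error_rate)

        stem = f"sim_{i:06d}"
        fwd = Read(f"{stem}/1", _BASES[codes1].tobytes().decode("ascii"),
                   q1.tobytes())
        rev = Read(f"{stem}/2", _BASES[codes2].tobytes().decode("ascii"),
                   q2.tobytes())
        pairs.append(ReadPair(fwd, rev))
        adapter_start = ins if ins < rl else -1
        truth.append(TruthRow(stem, ins, adapter_start, adapter_start))
    return pairs, truth


def write_pairs(cfg: SimConfig, prefix: str,
                compress: bool = False) -> tuple[str, str, str]:
    """Write the generated pairs as two FASTQ files plus a truth TSV.

    Returns ``(fwd_path, rev_path, truth_path)``.
    """
    ext = ".fq.gz" if compress else ".fq"
    path1 = f"{prefix}_1{ext}"
    path2 = f"{prefix}_2{ext}"
    truth_path = f"{prefix}_truth.tsv"
    pairs, truth = generate_read_pairs(cfg)
    with SerialFastqWriter(path1) as w1, SerialFastqWriter(path2) as w2:
        for pair in pairs:
            w1.write(pair.fwd)
            w2.write(pair.rev)
    with open(truth_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["name", "insert_length", "adapter_start_fwd", "adapter_start_rev"]
        )
        for row in truth:
            writer.writerow(
                [row.name, row.insert_length,
                 row.adapter_start_fwd, row.adapter_start_rev]
            )
    return path1, path2, truth_path


def write_adapter_fasta(path: str, cfg: SimConfig | None = None,
                        include_simple: bool = True) -> str:
    """Write the paired-end adapter FASTA matching the generator's adapters.

    Contains the palindrome prefix pair plus (optionally) the two simple
    records for the adapter sequence as it actually appears at the 3' end of
    each mate (the reverse complement of the other mate's prefix).
    """
    cfg = cfg or SimConfig()
    records = [
        ("synthPE/1", cfg.adapter_fwd),
        ("synthPE/2", cfg.adapter_rev),
    ]
    if include_simple:
        records += [
            ("synth_read1_3prime", revcomp(cfg.adapter_rev)),
            ("synth_read2_3prime", revcomp(cfg.adapter_fwd)),
        ]
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path


def write_se_adapter_fasta(path: str, cfg: SimConfig | None = None) -> str:
    """Single-adapter FASTA for single-end simple-mode clipping."""
    cfg = cfg or SimConfig()
    with open(path, "w") as fh:
        fh.write(f">synthSE\n{revcomp(cfg.adapter_rev)}\n")
    return path


# ---------------------------------------------------------------------------
# Deliberate corruption (fixtures for the pairing validator)
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class CorruptionTruth:
    """What the pairing validator is expected to report."""

    mode: str
    expected_mismatch_ordinal: int | None
    expect_length_mismatch: bool


def _load_raw(path: str) -> list[list[str]]:
    return [lines for _, lines in _raw_records(path)]


def _dump_raw(records: list[list[str]], path: str) -> None:
    with _open_bytes_writer(path) as fh:
        for lines in records:
            fh.write(("\n".join(lines) + "\n").encode("ascii"))


def corrupt_pairing(path_fwd: str, path_rev: str, out_fwd: str, out_rev: str,
                    mode: str, seed: int = 0) -> CorruptionTruth:
    """Produce a corrupted copy of a file pair that must fail validation.

    Modes: ``shuffle`` permutes the reverse file, ``drop_one`` deletes one
    reverse record (shifting everything after it), ``rename`` rewrites one
    reverse record's name.  The returned truth gives the first divergence
    the validator must report.
    """
    from .fastq_io import canonical_name

    rng = np.random.default_rng(seed)
    fwd = _load_raw(path_fwd)
    rev = _load_raw(path_rev)
    n = len(rev)
    if n < 2:
        raise ValueError("need at least 2 records to corrupt")

    if mode == "shuffle":
        perm = rng.permutation(n)
        if (perm == np.arange(n)).all():
            perm[0], perm[1] = perm[1], perm[0]
        rev = [rev[i] for i in perm]
        ordinal = None
        for i in range(min(len(fwd), n)):
            if canonical_name(fwd[i][0][1:]) != canonical_name(rev[i][0][1:]):
                ordinal = i
                break
        truth = CorruptionTruth(mode, ordinal, False)
    elif mode == "drop_one":
        k = int(rng.integers(0, n))
        del rev[k]
        ordinal = k if k < n - 1 else None
        truth = CorruptionTruth(mode, ordinal, True)
    elif mode == "rename":
        k = int(rng.integers(0, n))
        rev[k] = list(rev[k])
        rev[k][0] = rev[k][0] + "_renamed"
        truth = CorruptionTruth(mode, k, False)
    else:
        raise ValueError(f"unknown corruption mode {mode!r}")

    _dump_raw(fwd, out_fwd)
    _dump_raw(rev, out_rev)
    return truth


def reencode_phred64(in_path: str, out_path: str) -> str:
    """Rewrite a PHRED+33 FASTQ as PHRED+64 (every quality char shifted +31)."""
    records = _load_raw(in_path)
    for lines in records:
        lines[3] = "".join(chr(ord(c) + 31) for c in lines[3])
    _dump_raw(records, out_path)
    return out_path
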