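import gzip
import os

import pytest

from readtrim.core_model import PairingError, Read, ReadPair
from readtrim.engine import (
    BOTH_SURVIVING,
    DROPPED,
    FWD_ONLY,
    apply_steps_pair,
    apply_steps_single,
    compile_steps,
    run,
)
from readtrim.fastq_io import open_reader
from readtrim.core_model import PHRED33, QualityEncoding
from readtrim.simdata import (
    SimConfig,
    corrupt_pairing,
    write_adapter_fasta,
    write_pairs,
)

ENC33 = QualityEncoding(PHRED33)


def mk(quals, name="r") -> Read:
    return Read(name, "A" * len(quals), bytes(quals))


class TestApplySingle:
    def test_empty_step_list_is_identity(self):
        r = mk([30] * 50)
        out = apply_steps_single(r, compile_steps([]))
        assert out.read.quals == r.quals and out.cut_from_start == 0

    def test_long_read_passes_minlen(self):
        out = apply_steps_single(mk([30] * 100), compile_steps(["MINLEN:36"]))
        assert not out.dropped

    def test_drop_short_circuits_later_steps(self):
        # SLIDINGWINDOW truncates to 20 bases, then MINLEN:36 drops
        quals = [30] * 20 + [17, 17, 17] + [0] * 77
        steps = compile_steps(["SLIDINGWINDOW:4:20", "MINLEN:36"])
        first = apply_steps_single(mk(quals), compile_steps(["SLIDINGWINDOW:4:20"]))
        assert len(first.read) == 20
        assert apply_steps_single(mk(quals), steps).dropped

    def test_cut_accounting_accumulates_across_steps(self):
        out = apply_steps_single(
            mk(list(range(2, 52))), compile_steps(["HEADCROP:5", "TAILCROP:7"])
        )
        assert (out.cut_from_start, out.cut_from_end) == (5, 7)
        assert len(out.read) == 38

    def test_steps_apply_left_to_right(self):
        r = mk([30] * 20)
        a = apply_steps_single(r, compile_steps(["CROP:10", "HEADCROP:5"]))
        b = apply_steps_single(r, compile_steps(["HEADCROP:5", "CROP:10"]))
        assert len(a.read) == 5 and len(b.read) == 10


class TestApplyPair:
    def test_fates_follow_mate_survival(self):
        good, bad = mk([40] * 50, "g"), mk([2] * 50, "b")
        steps = compile_steps(["AVGQUAL:20"])
        assert apply_steps_pair(ReadPair(good, good), steps)[2] == BOTH_SURVIVING
        assert apply_steps_pair(ReadPair(good, bad), steps)[2] == FWD_ONLY
        assert apply_steps_pair(ReadPair(bad, bad), steps)[2] == DROPPED

    def test_per_read_steps_treat_mates_independently(self):
        fwd, rev = mk([40] * 60, "f"), mk([40] * 30, "r")
        out_f, out_r, fate = apply_steps_pair(
            ReadPair(fwd, rev), compile_steps(["MINLEN:40"])
        )
        assert fate == FWD_ONLY
        assert not out_f.dropped and out_r.dropped


@pytest.fixture(scope="module")
def sim_files(tmp_path_factory):
    d = tmp_path_factory.mktemp("engine")
    cfg = SimConfig(n_pairs=400, seed=21)
    p1, p2, truth = write_pairs(cfg, str(d / "sim"))
    fa = write_adapter_fasta(str(d / "ad.fa"), cfg)
    return d, p1, p2, fa


def _outputs(base, tag, suffix=".fq"):
    return {
        "out_fwd_paired": str(base / f"{tag}_1P{suffix}"),
        "out_fwd_unpaired": str(base / f"{tag}_1U{suffix}"),
        "out_rev_paired": str(base / f"{tag}_2P{suffix}"),
        "out_rev_unpaired": str(base / f"{tag}_2U{suffix}"),
    }


class TestRun:
    def test_identity_pipeline_preserves_records(self, sim_files):
        d, p1, p2, _ = sim_files
        outs = _outputs(d, "ident")
        stats = run(p1, p2, [], **outs)
        assert stats.both_surviving == stats.input_count == 400
        orig = [(r.name, r.bases, r.quals) for r in open_reader(p1, ENC33)]
        back = [(r.name, r.bases, r.quals)
                for r in open_reader(outs["out_fwd_paired"], ENC33)]
        assert back == orig

    def test_fates_partition_input(self, sim_files):
        d, p1, p2, fa = sim_files
        stats = run(p1, p2, [f"ILLUMINACLIP:{fa}:2:30:10", "SLIDINGWINDOW:4:20",
                             "MINLEN:36"], **_outputs(d, "part"))
        total = (stats.both_surviving + stats.fwd_only + stats.rev_only
                 + stats.dropped)
        assert total == stats.input_count == 400

    def test_worker_count_invariance_on_compressed_outputs(self, sim_files):
        d, p1, p2, fa = sim_files
        steps = [f"ILLUMINACLIP:{fa}:2:30:10", "SLIDINGWINDOW:4:20", "MINLEN:36"]
        payloads = {}
        for threads in (1, 4):
            outs = _outputs(d, f"w{threads}", ".fq.gz")
            summary = str(d / f"w{threads}_summary.txt")
            run(p1, p2, steps, threads=threads, summary=summary,
                block_records=100, **outs)
            payloads[threads] = [
                gzip.open(p, "rb").read() for p in outs.values()
            ] + [open(summary, "rb").read()]
        assert payloads[1] == payloads[4]

    def test_single_end_mode_uses_surviving_dropped_stats(self, sim_files):
        d, p1, _, _ = sim_files
        out = str(d / "se.fq")
        stats = run(p1, None, ["AVGQUAL:25", "MINLEN:36"], out_single=out)
        assert stats.mode == "SE"
        assert stats.surviving + stats.dropped == stats.input_count == 400
        assert sum(1 for _ in open_reader(out, ENC33)) == stats.surviving

    def test_validation_failure_aborts_before_output(self, sim_files, tmp_path):
        d, p1, p2, _ = sim_files
        c1, c2 = str(tmp_path / "c1.fq"), str(tmp_path / "c2.fq")
        corrupt_pairing(p1, p2, c1, c2, "rename", seed=4)
        outs = _outputs(tmp_path, "bad")
        with pytest.raises(PairingError):
            run(c1, c2, [], validate_pairs=True, **outs)
        assert not os.path.exists(outs["out_fwd_paired"])

    def test_unequal_input_lengths_raise_mid_run(self, sim_files, tmp_path):
        d, p1, p2, _ = sim_files
        c1, c2 = str(tmp_path / "d1.fq"), str(tmp_path / "d2.fq")
        corrupt_pairing(p1, p2, c1, c2, "drop_one", seed=0)
        with pytest.raises(PairingError):
            run(c1, c2, [], **_outputs(tmp_path, "short"))

    def test_trimlog_has_one_line_per_input_read(self, sim_files):
        d, p1, p2, fa = sim_files
        log = str(d / "trim.log")
        run(p1, p2, ["SLIDINGWINDOW:4:20", "MINLEN:36"], trimlog=log,
            **_outputs(d, "log"))
        lines = open(log).read().splitlines()
        assert len(lines) == 2 * 400
        name, surv, first, last, tail = lines[0].split()
        assert int(last) - int(first) == int(surv)

    def test_rerun_is_deterministic(self, sim_files):
        d, p1, p2, fa = sim_files
        steps = ["SLIDINGWINDOW:4:20", "MINLEN:36"]
        s1 = run(p1, p2, steps, **_outputs(d, "det_a"))
        s2 = run(p1, p2, steps, **_outputs(d, "det_b"))
        assert (s1.both_surviving, s1.fwd_only, s1.rev_only, s1.dropped) == \
            (s2.both_surviving, s2.fwd_only, s2.rev_only, s2.dropped)
        assert open(str(d / "det_a_1P.fq"), "rb").read() == \
            open(str(d / "det_b_1P.fq"), "rb").read()
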