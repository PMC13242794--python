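"""Run statistics, the summary file, and the per-read trim log."""

from __future__ import annotations

from dataclasses import dataclass, field

from .trim_steps import StepOutcome

PAIRED = "PE"
SINGLE = "SE"


@dataclass(slots=True)
class RunStats:
    """Counters of read/pair fates plus per-step drop tallies.

    In paired mode the four fate counters partition ``input_count`` exactly;
    in single-end mode ``surviving + dropped == input_count``.
    """

    mode: str = PAIRED
    input_count: int = 0
    both_surviving: int = 0
    fwd_only: int = 0
    rev_only: int = 0
    dropped: int = 0
    surviving: int = 0  # SE mode only
    step_drops: dict[str, int] = field(default_factory=dict)

    def count_drop(self, step_name: str, n: int = 1) -> None:
        self.step_drops[step_name] = self.step_drops.get(step_name, 0) + n

    def check_partition(self) -> None:
        if self.mode == PAIRED:
            total = self.both_surviving + self.fwd_only + self.rev_only + self.dropped
        else:
            total = self.surviving + self.dropped
        if total != self.input_count:
            raise RuntimeError(
                f"fate counters ({total}) do not partition input "
                f"({self.input_count})"
            )


def _pct(x: int, n: int) -> str:
    return f"{(100.0 * x / n if n else 0.0):.2f}%"


def render_summary(stats: RunStats) -> str:
    """Render the summary statistics file (one datum per line)."""
    stats.check_partition()
    n = stats.input_count
    if stats.mode == PAIRED:
        lines = [
            f"Input Read Pairs: {n}",
            f"Both Surviving: {stats.both_surviving} ({_pct(stats.both_surviving, n)})",
            f"Forward Only Surviving: {stats.fwd_only} ({_pct(stats.fwd_only, n)})",
            f"Reverse Only Surviving: {stats.rev_only} ({_pct(stats.rev_only, n)})",
            f"Dropped: {stats.dropped} ({_pct(stats.dropped, n)})",
        ]
    else:
        lines = [
            f"Input Reads: {n}",
            f"Surviving: {stats.surviving} ({_pct(stats.surviving, n)})",
            f"Dropped: {stats.dropped} ({_pct(stats.dropped, n)})",
        ]
    return "\n".join(lines) + "\n"


def render_trimlog_line(read_name: str, outcome: StepOutcome,
                        original_length: int) -> str:
    """One trim-log line: name, surviving length, first kept offset
    (0-based), last kept position (exclusive), amount trimmed from the end.

    A dropped read is logged as ``name 0 0 0 L`` with ``L`` the original
    length.
    """
    if outcome.dropped:
        return f"{read_name} 0 0 0 {original_length}"
    first = outcome.cut_from_start
    last = original_length - outcome.cut_from_end
    return (
        f"{read_name} {last - first} {first} {last} {outcome.cut_from_end}"
    )
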