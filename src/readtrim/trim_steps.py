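"""Per-read trimming and filtering operators.

Every operator maps a :class:`~readtrim.core_model.Read` to a
:class:`StepOutcome`: either a surviving read that is a contiguous sub-window
of the input (bases and qualities trimmed in lockstep) or ``dropped``.
Operators are pure functions — they never mutate their input and carry no
state across reads — which is what allows the engine to process batches
concurrently while guaranteeing bit-identical output.

Threshold comparisons are uniformly strict: a read *fails* when the measured
quantity is ``< threshold``, so a value exactly at the threshold survives.
Window means are compared in exact integer arithmetic
(``sum(quals) < q * w``), avoiding floating-point drift at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import Read


@dataclass(slots=True)
class StepOutcome:
    """Result of applying one step to one read.

    ``cut_from_start + len(result) + cut_from_end`` equals the input length
    whenever the read survives.
    """

    read: Read | None
    cut_from_start: int = 0
    cut_from_end: int = 0

    @property
    def dropped(self) -> bool:
        return self.read is None


@dataclass(frozen=True, slots=True)
class MaxInfoParams:
    """Parameters of the information-maximizing trimmer.

    ``target_length`` is the read length needed for confident unique mapping;
    ``strictness`` in (0, 1) weighs error avoidance against the coverage
    benefit of longer reads.
    """

    target_length: int
    strictness: float


def _keep(read: Read, start: int, end: int) -> StepOutcome:
    n = len(read)
    if end <= start:
        return StepOutcome(None, 0, n)
    if start == 0 and end == n:
        return StepOutcome(read, 0, 0)
    return StepOutcome(read.window(start, end), start, n - end)


def headcrop(read: Read, n: int) -> StepOutcome:
    """Remove a fixed number of 5' bases (UMI / barcode removal)."""
    length = len(read)
    if length <= n:
        return StepOutcome(None, length, 0)
    return _keep(read, n, length)


def tailcrop(read: Read, n: int) -> StepOutcome:
    """Remove a fixed number of 3' bases."""
    length = len(read)
    if length <= n:
        return StepOutcome(None, 0, length)
    return _keep(read, 0, length - n)


def crop(read: Read, n: int) -> StepOutcome:
    """Keep at most the first ``n`` bases; never drops."""
    length = len(read)
    if length <= n:
        return StepOutcome(read, 0, 0)
    return StepOutcome(read.window(0, n), 0, length - n)


def leading(read: Read, q: int) -> StepOutcome:
    """Strip 5' bases while their quality is below ``q``."""
    start = 0
    quals = read.quals
    length = len(read)
    while start < length and quals[start] < q:
        start += 1
    return _keep(read, start, length)


def trailing(read: Read, q: int) -> StepOutcome:
    """Strip 3' bases while their quality is below ``q``."""
    quals = read.quals
    end = len(read)
    while end > 0 and quals[end - 1] < q:
        end -= 1
    return _keep(read, 0, end)


def sliding_window(read: Read, w: int, q: int) -> StepOutcome:
    """Truncate at the first length-``w`` window whose mean quality drops
    below ``q``.

    A read shorter than ``w`` is treated as a single window.  After
    truncation, any remaining 3' bases individually below ``q`` are removed
    as well, so a low-quality tail shorter than the window cannot survive.
    """
    length = len(read)
    if length == 0:
        return StepOutcome(None, 0, 0)
    quals = read.quals
    if length < w:
        end = 0 if sum(quals) < q * length else length
        if end == length:
            return StepOutcome(read, 0, 0)
    else:
        qa = np.frombuffer(quals, dtype=np.uint8).astype(np.int64)
        csum = np.concatenate(([0], np.cumsum(qa)))
        window_sums = csum[w:] - csum[:-w]  # offsets 0 .. length - w
        failing = window_sums < q * w
        if not failing.any():
            return StepOutcome(read, 0, 0)
        end = int(np.argmax(failing))  # first failing window's start offset
    while end > 0 and quals[end - 1] < q:
        end -= 1
    return _keep(read, 0, end)


def maxinfo(read: Read, params: MaxInfoParams) -> StepOutcome:
    """Keep the prefix that maximizes an information score.

    For every prefix length ``L`` the score is the sum of three terms::

        length   : ln(1 / (1 + e^(T - 1 - L)))          (logistic ramp at T)
        coverage : (1 - s) * ln(L)                       (more bases help)
        error    : s * sum_{i<L} ln(1 - 10^(-q_i / 10))  (errors hurt)

    with ``T = target_length`` and ``s = strictness``; a quality of 0 is
    treated as 1 so the error term stays finite.  The prefix of the arg-max
    length is kept, ties broken toward the longer prefix; an empty read is
    dropped (the only case where L* = 0).
    """
    n = len(read)
    if n == 0:
        return StepOutcome(None, 0, 0)
    t = float(params.target_length)
    s = params.strictness
    q = np.frombuffer(read.quals, dtype=np.uint8).astype(np.float64)
    q[q == 0.0] = 1.0
    lengths = np.arange(1, n + 1, dtype=np.float64)
    f_len = -np.logaddexp(0.0, (t - 1.0) - lengths)
    f_cov = (1.0 - s) * np.log(lengths)
    f_err = s * np.cumsum(np.log1p(-np.power(10.0, -q / 10.0)))
    score = f_len + f_cov + f_err
    # argmax with ties toward the larger prefix
    best_len = n - int(np.argmax(score[::-1]))
    return _keep(read, 0, best_len)


def avgqual(read: Read, q: int) -> StepOutcome:
    """Drop the whole read when its mean quality is below ``q``."""
    length = len(read)
    if length == 0 or sum(read.quals) < q * length:
        return StepOutcome(None, 0, length)
    return StepOutcome(read, 0, 0)


def min_length(read: Read, n: int) -> StepOutcome:
    """Drop reads shorter than ``n`` bases (MINLEN and BASECOUNT tokens)."""
    length = len(read)
    if length < n:
        return StepOutcome(None, 0, length)
    return StepOutcome(read, 0, 0)
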