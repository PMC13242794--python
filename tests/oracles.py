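"""Independent brute-force oracles for the adaptive trimmers.

Deliberately written as direct, unoptimized transcriptions of the step
definitions (explicit window scan, explicit prefix-score maximization) so
they share no code with the implementations they check.
"""

import math


def oracle_sliding_window(quals, w: int, q: int) -> int:
    """Surviving prefix length under the sliding-window rule."""
    n = len(quals)
    if n == 0:
        return 0
    windows = [(0, n)] if n < w else [(i, i + w) for i in range(n - w + 1)]
    end = None
    for s, e in windows:
        if sum(quals[s:e]) < q * (e - s):
            end = s
            break
    if end is None:  # no failing window: read unchanged, no tail cleanup
        return n
    while end > 0 and quals[end - 1] < q:
        end -= 1
    return end


def oracle_maxinfo(quals, target_length: int, strictness: float) -> int:
    """Arg-max prefix length of the three-factor information score."""
    n = len(quals)
    best_score = -math.inf
    best_len = 0
    err_sum = 0.0
    for length in range(1, n + 1):
        q = quals[length - 1] or 1
        err_sum += math.log(1.0 - 10.0 ** (-q / 10.0))
        x = (target_length - 1) - length
        f_len = -x if x > 700 else -math.log(1.0 + math.exp(x))
        score = (
            f_len
            + (1.0 - strictness) * math.log(length)
            + strictness * err_sum
        )
        if score >= best_score:  # ties toward the longer prefix
            best_score = score
            best_len = length
    return best_len
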