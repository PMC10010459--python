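"""Y-maze spontaneous alternation scoring from arm-entry sequences.

An alternation is a sliding triad of three consecutive entries into three
distinct arms; the percent alternation is the triad count divided by
(entries - 2), times 100.  Consecutive re-entries into the same arm are
retained as entries.
"""

from __future__ import annotations

from typing import Sequence


def count_alternations(entries: Sequence[str]) -> int:
    """Number of consecutive triplets whose three labels are pairwise
    distinct (overlapping sliding window)."""
    entries = list(entries)
    return sum(
        len({entries[i], entries[i + 1], entries[i + 2]}) == 3
        for i in range(len(entries) - 2)
    )


def percent_alternation(entries: Sequence[str]) -> float:
    """% Alternation = alternations / (total entries - 2) x 100.

    Undefined (raises) for fewer than 3 entries.
    """
    entries = list(entries)
    if len(entries) < 3:
        raise ValueError("percent alternation undefined for < 3 arm entries")
    return 100.0 * count_alternations(entries) / (len(entries) - 2)
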