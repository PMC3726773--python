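"""Simple tandem-repeat detection shared by the repeat filter and the simulator.

A "simple repeat" here is a contiguous tandem run of a short unit (1-4 bp by
default, covering homopolymers and short STRs).  The quantity of interest is
the maximum number of full unit copies in any run overlapping a position.
"""

from __future__ import annotations


def max_tandem_copies(seq: str, pos0: int, max_unit: int = 4, flank: int = 25) -> int:
    """Maximum copy count of any 1..max_unit bp tandem run overlapping ``pos0``.

    ``pos0`` is 0-based.  The scan is confined to ``pos0 +/- flank``; at
    contig edges the available span is scanned.  Only full unit copies count.
    """
    lo = max(0, pos0 - flank)
    hi = min(len(seq), pos0 + flank + 1)
    window = seq[lo:hi]
    p = pos0 - lo
    n = len(window)
    best = 0
    for unit_len in range(1, max_unit + 1):
        start = 0
        while start + unit_len <= n:
            unit = window[start : start + unit_len]
            copies = 1
            while window[start + copies * unit_len : start + (copies + 1) * unit_len] == unit:
                copies += 1
            run_end = start + copies * unit_len  # exclusive
            if copies > best and start <= p < run_end:
                best = copies
            start += 1
    return best


def overlaps_repeat(seq: str, pos0: int, min_copies: int = 6, max_unit: int = 4, flank: int = 25) -> bool:
    """True iff ``pos0`` lies inside a tandem run of at least ``min_copies`` copies."""
    return max_tandem_copies(seq, pos0, max_unit=max_unit, flank=flank) >= min_copies
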