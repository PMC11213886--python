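"""Sliding-window bookkeeping shared by diversity and scan statistics.

Windows are 0-based half-open ``[k*step, k*step + size)`` tiled per contig
from coordinate 0; trailing partial windows are kept.  Variant positions are
1-based, so a variant at ``pos`` falls in windows containing ``pos - 1``.
"""

from __future__ import annotations

import numpy as np


def window_starts(span_bp: int, size: int, step: int) -> np.ndarray:
    """Start coordinates of all windows whose span intersects [0, span_bp)."""
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    if span_bp <= 0:
        return np.array([], dtype=np.int64)
    last = ((span_bp - 1) // step) * step
    return np.arange(0, last + 1, step, dtype=np.int64)


def window_slices(pos: np.ndarray, span_bp: int, size: int, step: int):
    """Yield (start, end, lo, hi): window bounds and the index range of the
    1-based sorted positions ``pos`` falling inside."""
    z = pos - 1  # to 0-based
    for start in window_starts(span_bp, size, step):
        end = start + size
        lo = np.searchsorted(z, start, side="left")
        hi = np.searchsorted(z, end, side="left")
        yield int(start), int(end), int(lo), int(hi)
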