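"""Small shared numeric helpers."""

from __future__ import annotations

import math

import numpy as np


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with halves going away from zero (17.45 -> 17.5, -0.95 -> -1.0).

    Python's built-in round is banker's rounding, which does not match the
    reporting convention used for the area-change and percentage tables.
    """
    if not math.isfinite(x):
        return x
    factor = 10.0 ** ndigits
    scaled = x * factor
    # nudge by a few ulps so that values printed as exact halves round away
    nudged = scaled + math.copysign(1e-9, scaled) * max(1.0, abs(scaled))
    return math.copysign(math.floor(abs(nudged) + 0.5), scaled) / factor


def round_half_away_arr(x: np.ndarray, ndigits: int = 0) -> np.ndarray:
    return np.vectorize(lambda v: round_half_away(float(v), ndigits))(x)
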