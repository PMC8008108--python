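"""Fixed-bin-width gray-level discretization.

CT intensities are calibrated (HU-like), so a fixed bin width (default
25 units) is used rather than a fixed bin count.  The minimum intensity in
the region maps to level 1::

    level(v) = floor((v - min) / bin_width) + 1

An intensity lying exactly on the upper edge (max - min an exact multiple of
the bin width) opens its own top bin, so the number of levels is
``floor((max - min)/bin_width) + 1``.
"""

from __future__ import annotations

import numpy as np

DEFAULT_BIN_WIDTH = 25.0


def discretize(values: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH) -> np.ndarray:
    """Map intensities to integer gray levels >= 1.

    Parameters
    ----------
    values : array of intensities (any shape).
    bin_width : positive bin width in intensity units.

    Returns
    -------
    Integer array of the same shape with levels in ``1..Ng``.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot discretize an empty array")
    return np.floor((v - v.min()) / bin_width).astype(np.int64) + 1
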