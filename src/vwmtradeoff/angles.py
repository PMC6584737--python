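"""Angular conventions for the 360-point colour circle.

All colour values live on a plain circle of 360 degrees; analyses use
either the absolute circular offset in [0, 180] (feedback / scoring) or
the signed recall error in (-180, 180] (mixture modelling). 180 maps to
+180 so the signed wrap is single-valued.
"""

from __future__ import annotations

import numpy as np

__all__ = ["circular_offset", "signed_error", "wrap_degrees"]


def _check_finite(*values) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError("angles must be finite, got non-finite input")


def wrap_degrees(angle):
    """Wrap an angle (degrees) into [0, 360)."""
    _check_finite(angle)
    return np.asarray(angle, dtype=float) % 360.0


def circular_offset(a, b):
    """Absolute circular difference between two angles in degrees.

    Returns the minimal absolute angular difference, in [0, 180].
    Symmetric in its arguments; accepts scalars or arrays.
    """
    _check_finite(a, b)
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    out = np.minimum(d, 360.0 - d)
    if np.isscalar(a) and np.isscalar(b):
        return float(out)
    return out

def signed_error(response, target):
    """Signed recall error response - target, wrapped to (-180, 180].

    The magnitude equals :func:`circular_offset`; an exact half-turn is
    reported as +180.
    """
    _check_finite(response, target)
    d = (np.asarray(response, dtype=float) - np.asarray(target, dtype=float)) % 360.0
    out = np.where(d > 180.0, d - 360.0, d)
    if np.isscalar(response) and np.isscalar(target):
        return float(out)
    return out
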