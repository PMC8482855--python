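"""Angular conventions shared by every module.

All angles are in degrees, counterclockwise, reduced to [0, 360).  Signed
differences live on (-180, 180]; the tie at +/-180 deg maps to +180 so that
the difference is single-valued.
"""

from __future__ import annotations

import numpy as np


def wrap_angle(a):
    """Reduce an angle (scalar or array, degrees) to [0, 360)."""
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    out = np.mod(a, 360.0)
    # guard float roundoff: mod of a tiny negative can return exactly 360.0
    out = np.where(out >= 360.0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def signed_angle_diff(a, b):
    """Signed angular difference a - b in degrees, wrapped to (-180, 180].

    Antisymmetric except at the 180 deg tie, which always returns +180.
    Invariant under adding any multiple of 360 to either argument.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("angles must be finite")
    d = np.mod(a - b, 360.0)
    out = np.where(d > 180.0, d - 360.0, d)
    return float(out) if out.ndim == 0 else out
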