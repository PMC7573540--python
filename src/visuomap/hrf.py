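"""Canonical hemodynamic response function.

The double-gamma form used throughout: a positive gamma density peaking
at 6 s minus a scaled undershoot gamma peaking at 16 s (peak-to-undershoot
ratio 6), the shape popularised by SPM's canonical HRF.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["double_gamma_hrf"]


def double_gamma_hrf(
    dt: float,
    duration: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    p_u_ratio: float = 6.0,
) -> np.ndarray:
    """Sample the canonical double-gamma HRF.

    Parameters
    ----------
    dt : float
        Sampling interval in seconds.
    duration : float
        Length of the sampled kernel in seconds.

    Returns
    -------
    ndarray
        Kernel sampled at ``t = 0, dt, 2*dt, ...``, normalized to a
        peak value of 1.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, duration, dt)
    peak = stats.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = stats.gamma.pdf(t, undershoot_delay / undershoot_disp,
                            scale=undershoot_disp)
    h = peak - under / p_u_ratio
    return h / h.max()
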