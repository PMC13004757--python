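"""Closed-form update of the release-fraction depression variable.

Between presynaptic spikes the releasable fraction ``D`` recovers toward
1 exponentially with time constant ``tau_d``; at each spike it is
decremented multiplicatively by ``pv * D``.  The same event-driven
closed form is used inside the simulation engine; this module exposes it
as a standalone, easily testable function.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .params import DepressionParams, ParameterError

__all__ = ["update_depression"]


def update_depression(
    d0: float,
    params: DepressionParams,
    spike_times: Sequence[float],
    t_eval: float,
    t0: float = 0.0,
) -> float:
    """Evolve the depression variable from ``t0`` to ``t_eval``.

    Parameters
    ----------
    d0
        Depression state at ``t0``; must lie in (0, 1].
    params
        ``pv`` and ``tau_d``.
    spike_times
        Sorted presynaptic spike times, all within ``[t0, t_eval]``.
    t_eval
        Time at which the state is returned.  A spike exactly at
        ``t_eval`` is applied before the state is returned.

    Returns
    -------
    float
        ``D(t_eval)``, guaranteed to lie in (0, 1].
    """
    if not (0.0 < d0 <= 1.0):
        raise ParameterError(f"d0 must lie in (0, 1], got {d0}")
    times = np.asarray(spike_times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ParameterError("spike_times must be sorted")
    if times.size and (times[0] < t0 or times[-1] > t_eval):
        raise ParameterError("spike_times must lie within [t0, t_eval]")

    d = float(d0)
    t_last = t0
    for ts in times:
        d = 1.0 - (1.0 - d) * np.exp(-(ts - t_last) / params.tau_d)
        d *= 1.0 - params.pv
        t_last = ts
    d = 1.0 - (1.0 - d) * np.exp(-(t_eval - t_last) / params.tau_d)
    return float(min(max(d, np.finfo(float).tiny), 1.0))
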