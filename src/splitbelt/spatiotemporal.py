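"""Step lengths and step-length asymmetry (SLA).

Step length is the anterior-posterior distance between the two ankle markers at
the ipsilateral foot strike, positive when the striking foot is anterior.  SLA
normalizes the difference of fast- and slow-leg step lengths to stride length:

    SLA = (L_fast - L_slow) / (L_fast + L_slow)

Negative SLA means the slow-belt leg is taking the longer step; zero means
equal steps.  Within a stride the fast-leg step is paired with the subsequent
slow-leg step, indexed by the fast-strike time.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .preprocess import EventTable

__all__ = ["step_lengths", "sla", "sla_series", "assign_fast_leg"]


def _ap_at(t_query: np.ndarray, t: np.ndarray, x: np.ndarray) -> np.ndarray:
    if np.any(t_query < t[0]) or np.any(t_query > t[-1]):
        raise ValueError("strike time outside marker time range")
    return np.interp(t_query, t, x)


def step_lengths(t: np.ndarray, ankle_ap_fast: np.ndarray, ankle_ap_slow: np.ndarray,
                 events: EventTable) -> pd.DataFrame:
    """Per-step lengths at every foot strike of both legs.

    Returns a table with one row per strike: leg, strike_time and step length
    L = AP(striking ankle) - AP(contralateral ankle).  Negative lengths
    (crossover steps) are kept but warned about.
    """
    rows = []
    for leg, strikes in (("fast", events.fast_strikes), ("slow", events.slow_strikes)):
        ipsi = ankle_ap_fast if leg == "fast" else ankle_ap_slow
        contra = ankle_ap_slow if leg == "fast" else ankle_ap_fast
        ls = _ap_at(strikes, t, ipsi) - _ap_at(strikes, t, contra)
        rows.append(pd.DataFrame({"leg": leg, "strike_time": strikes, "length": ls}))
    out = pd.concat(rows, ignore_index=True).sort_values("strike_time", ignore_index=True)
    if (out["length"] < 0).any():
        warnings.warn("negative step length(s): crossover step or mislabelled legs")
    return out


def sla(l_fast, l_slow):
    """Step-length asymmetry (L_fast - L_slow) / (L_fast + L_slow)."""
    l_fast = np.asarray(l_fast, float)
    l_slow = np.asarray(l_slow, float)
    denom = l_fast + l_slow
    if np.any(denom == 0):
        raise ZeroDivisionError("stride length (L_fast + L_slow) is zero")
    return (l_fast - l_slow) / denom


def sla_series(steps: pd.DataFrame) -> pd.DataFrame:
    """Per-stride SLA from the step table.

    Each fast-leg step is paired with the next slow-leg step; the pair is
    timestamped by the fast strike.  Trailing unpaired steps are dropped.
    """
    fast = steps[steps["leg"] == "fast"].reset_index(drop=True)
    slow = steps[steps["leg"] == "slow"].reset_index(drop=True)
    rows = []
    j = 0
    for _, f in fast.iterrows():
        while j < len(slow) and slow.loc[j, "strike_time"] <= f["strike_time"]:
            j += 1
        if j >= len(slow):
            break
        s = slow.loc[j]
        rows.append({
            "t": f["strike_time"],
            "step_length_fast": f["length"],
            "step_length_slow": s["length"],
            "sla": sla(f["length"], s["length"]),
            "stride_length": f["length"] + s["length"],
        })
    return pd.DataFrame(rows)


def assign_fast_leg(baseline_steps: pd.DataFrame, n_last: int = 5) -> str:
    """Which physical leg goes on the fast belt.

    The leg taking the shorter mean step over the last ``n_last`` strides of
    tied-belt baseline is assigned to the fast belt.  ``baseline_steps`` must
    have columns leg in {'left','right'} and length.
    """
    means = {}
    for leg, grp in baseline_steps.groupby("leg"):
        means[leg] = grp["length"].tail(n_last).mean()
    if set(means) != {"left", "right"}:
        raise ValueError("baseline step table must contain both 'left' and 'right' legs")
    return min(means, key=means.get)
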