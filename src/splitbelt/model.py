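"""Core domain types: adaptation-curve parameters, subjects, cohort configuration.

The central object is the dual-rate exponential learning curve

    y(t) = c + a_f * exp(-t / r_f) + a_s * exp(-t / r_s)

with a plateau ``c`` approached as t -> inf, a fast component (amplitude
``a_f``, time constant ``r_f``) and a slow component (``a_s``, ``r_s``).
Amplitudes are signed: measures that rise toward their plateau carry negative
amplitudes.  At one time constant an exponential component has completed
1 - e^-1 = 63.2% of its total change.  A single-timescale curve drops the
slow component.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AdaptationParams",
    "SubjectParams",
    "CohortConfig",
    "dual_rate_curve",
    "DEFAULT_TRUTH",
]


@dataclass(frozen=True)
class AdaptationParams:
    """Parameters of a single- or dual-rate exponential adaptation curve.

    Units of ``c``, ``a_f``, ``a_s`` are the measure's units; time constants
    are in seconds.  ``n_components`` is 1 (fast only) or 2 (fast + slow),
    and for a dual-rate curve ``r_s > r_f`` is required.
    """

    c: float
    a_f: float
    r_f: float
    a_s: float = 0.0
    r_s: float = np.inf
    n_components: int = 2

    def __post_init__(self) -> None:
        if self.n_components not in (1, 2):
            raise ValueError(f"n_components must be 1 or 2, got {self.n_components}")
        if not (self.r_f > 0):
            raise ValueError(f"fast time constant r_f must be positive, got {self.r_f}")
        if self.n_components == 2:
            if not (self.r_s > 0):
                raise ValueError(f"slow time constant r_s must be positive, got {self.r_s}")
            if not (self.r_s > self.r_f):
                raise ValueError(
                    f"slow time constant r_s={self.r_s} must exceed fast r_f={self.r_f}"
                )
        for name in ("c", "a_f", "a_s"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"amplitude/plateau field {name!r} must be finite")

    def curve(self, t: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the adaptation curve at times ``t`` (seconds)."""
        return dual_rate_curve(t, self)

    def with_plateau_offset(self, delta: float) -> "AdaptationParams":
        """Return a copy whose plateau is shifted by ``delta`` (subject random effect)."""
        return replace(self, c=self.c + delta)


def dual_rate_curve(t, params: AdaptationParams):
    """Evaluate c + a_f*exp(-t/r_f) [+ a_s*exp(-t/r_s)]."""
    t = np.asarray(t, dtype=float)
    y = params.c + params.a_f * np.exp(-t / params.r_f)
    if params.n_components == 2:
        y = y + params.a_s * np.exp(-t / params.r_s)
    return y


@dataclass(frozen=True)
class SubjectParams:
    """Anthropometrics and fitness for one participant.

    plateau_offset is the subject's random deviation of the plateau ``c``,
    shared across all of that subject's measures (in each measure's units it
    is scaled by the cohort's per-measure plateau SD).
    """

    id: str
    mass: float = 72.0  # kg
    height: float = 1.72  # m
    leg_length: float = 0.90  # m (greater trochanter height)
    vo2peak: float = 40.0  # ml kg^-1 min^-1
    gender: str = "woman"
    plateau_offset: float = 0.0  # standard-normal draw, scaled per measure

    def __post_init__(self) -> None:
        for name in ("mass", "height", "leg_length", "vo2peak"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level simulation settings.

    Defaults mirror the study conditions: 17 participants, 20 min of split-belt
    adaptation at 1.5 / 0.5 m s^-1, ~1.1 s stride period, breaths every ~4 s,
    and a metabolic response lagging gait mechanics by ~2 min.
    """

    n_subjects: int = 17
    duration: float = 1200.0  # s
    seed: int = 0
    stride_period: float = 1.1  # s
    breath_period: float = 4.0  # s
    belt_speeds: tuple[float, float] = (1.5, 0.5)  # (fast, slow) m s^-1
    metabolic_lag: float = 120.0  # s, onset delay of the metabolic response
    metabolic_onset_tau: float = 30.0  # s, mono-exponential on-transient
    noise_sd: dict[str, float] = field(default_factory=dict)
    plateau_sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if not (self.duration > 0):
            raise ValueError("duration must be positive")
        if not (self.stride_period > 0 and self.breath_period > 0):
            raise ValueError("stride_period and breath_period must be positive")
        if any(v <= 0 for v in self.belt_speeds):
            raise ValueError("belt speeds must be positive")
        for d in (self.noise_sd, self.plateau_sd):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"negative SD for measure {k!r}")

    def noise_for(self, measure: str) -> float:
        return self.noise_sd.get(measure, _DEFAULT_NOISE_SD[measure])

    def plateau_sd_for(self, measure: str) -> float:
        return self.plateau_sd.get(measure, _DEFAULT_PLATEAU_SD[measure])


# ---------------------------------------------------------------------------
# Calibration defaults for the eleven adaptation measures.  Time constants are
# the study's fitted values; amplitudes/plateaus are calibration defaults on
# physiologically sensible scales (SLA dimensionless, step lengths m, MoS cm,
# work and metabolic rates W kg^-1) since the fitted amplitudes are not
# tabulated numerically.  Time-constant recovery is insensitive to the
# amplitude scale at adequate signal-to-noise.

DEFAULT_TRUTH: dict[str, AdaptationParams] = {
    "sla": AdaptationParams(c=0.05, a_f=-0.20, r_f=23.0, a_s=-0.10, r_s=321.0),
    "step_length_fast": AdaptationParams(c=0.62, a_f=-0.10, r_f=25.0, a_s=-0.08, r_s=210.0),
    "step_length_slow": AdaptationParams(c=0.48, a_f=0.04, r_f=4.0, a_s=0.03, r_s=46.0),
    "mos_fast": AdaptationParams(c=3.0, a_f=-2.0, r_f=40.0, n_components=1),
    "mos_slow": AdaptationParams(c=2.5, a_f=1.5, r_f=51.0, n_components=1),
    "metabolic_rate": AdaptationParams(c=2.5, a_f=0.8, r_f=60.0, a_s=1.2, r_s=353.0),
    "work_net": AdaptationParams(c=-0.05, a_f=0.15, r_f=30.0, a_s=0.25, r_s=357.0),
    "work_pos_fast": AdaptationParams(c=0.30, a_f=0.12, r_f=25.0, a_s=0.15, r_s=300.0),
    "work_neg_fast": AdaptationParams(c=-0.35, a_f=-0.10, r_f=25.0, a_s=-0.12, r_s=300.0),
    "work_pos_slow": AdaptationParams(c=0.15, a_f=0.05, r_f=30.0, a_s=0.06, r_s=250.0),
    "work_neg_slow": AdaptationParams(c=-0.15, a_f=0.08, r_f=30.0, a_s=0.06, r_s=250.0),
}

_DEFAULT_NOISE_SD: dict[str, float] = {
    "sla": 0.02,
    "step_length_fast": 0.015,
    "step_length_slow": 0.015,
    "mos_fast": 0.8,
    "mos_slow": 0.8,
    "metabolic_rate": 0.25,
    "work_net": 0.10,
    "work_pos_fast": 0.06,
    "work_neg_fast": 0.06,
    "work_pos_slow": 0.05,
    "work_neg_slow": 0.05,
}

_DEFAULT_PLATEAU_SD: dict[str, float] = {
    "sla": 0.02,
    "step_length_fast": 0.02,
    "step_length_slow": 0.02,
    "mos_fast": 0.1,
    "mos_slow": 0.1,
    "metabolic_rate": 0.3,
    "work_net": 0.05,
    "work_pos_fast": 0.04,
    "work_neg_fast": 0.04,
    "work_pos_slow": 0.03,
    "work_neg_slow": 0.03,
}

#: Measures modelled with a single timescale (mediolateral margins of stability).
SINGLE_TIMESCALE_MEASURES = ("mos_fast", "mos_slow")

#: Stride-cadence measures; everything else in DEFAULT_TRUTH except
#: metabolic_rate is also stride-cadence.
BREATH_CADENCE_MEASURES = ("metabolic_rate",)
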