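"""Population-averaged arterial input function (AIF).

The kinetic model is driven by the plasma gadolinium concentration
Cp(t).  Individual AIF measurement in a knee coil is impractical, so a
population-averaged whole-blood AIF is used: a mixture of two Gaussian
bolus terms plus an exponentially decaying sigmoid washout,

    Cb(t) = sum_{n=1,2} A_n / (sigma_n sqrt(2 pi)) exp(-(t-T_n)^2 / (2 sigma_n^2))
            + alpha exp(-beta t) / (1 + exp(-s (t - tau)))

evaluated relative to bolus arrival, and converted to plasma
concentration with the subject's haematocrit: Cp = Cb / (1 - Hct).

The ten population constants default to the standard high-temporal-
resolution population fit but are plain configuration values, so an
alternative AIF can be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["AIFParameters", "population_aif_blood", "haematocrit_correct",
           "plasma_aif", "DEFAULT_HAEMATOCRIT"]

#: Population-mean haematocrit used when no individual value is supplied.
DEFAULT_HAEMATOCRIT = 0.42


@dataclass(frozen=True)
class AIFParameters:
    """Constants of the population AIF (times in minutes).

    a1, a2 : Gaussian areas, mmol·min
    t1, t2 : Gaussian centres, min
    sigma1, sigma2 : Gaussian widths, min
    alpha : sigmoid amplitude, mmol
    beta : washout decay, min⁻¹
    s : sigmoid slope, min⁻¹
    tau : sigmoid centre, min
    bolus_arrival_offset : shift of the whole curve, min (t < offset ⇒ 0)
    """

    a1: float = 0.809
    a2: float = 0.330
    t1: float = 0.17046
    t2: float = 0.365
    sigma1: float = 0.0563
    sigma2: float = 0.132
    alpha: float = 1.050
    beta: float = 0.1685
    s: float = 38.078
    tau: float = 0.483
    bolus_arrival_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("Gaussian widths must be > 0")
        if self.a1 < 0 or self.a2 < 0 or self.alpha < 0:
            raise ValueError("amplitudes must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AIFParameters":
        return cls(**d)


def population_aif_blood(t, params: AIFParameters | None = None) -> np.ndarray:
    """Whole-blood concentration Cb(t) in mmol/L on the minute grid ``t``.

    ``t`` must be non-decreasing with t=0 the injection-aligned start;
    the curve is zero before ``bolus_arrival_offset``.
    """
    t = np.asarray(t, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    if np.any(np.diff(t) < 0):
        raise ValueError("time grid must be non-decreasing")
    if params is None:
        params = AIFParameters()
    ts = t - params.bolus_arrival_offset
    cb = np.zeros_like(ts)
    pos = ts > 0
    u = ts[pos]
    for a, mu, sig in ((params.a1, params.t1, params.sigma1),
                       (params.a2, params.t2, params.sigma2)):
        cb[pos] += a / (sig * np.sqrt(2 * np.pi)) * np.exp(-((u - mu) ** 2) / (2 * sig**2))
    cb[pos] += params.alpha * np.exp(-params.beta * u) / (1 + np.exp(-params.s * (u - params.tau)))
    return cb


def haematocrit_correct(cb: np.ndarray, hct: float) -> np.ndarray:
    """Blood → plasma concentration: Cp(t) = Cb(t) / (1 - Hct)."""
    if not 0 <= hct < 1:
        raise ValueError(f"haematocrit must be in [0, 1), got {hct}")
    return np.asarray(cb, dtype=float) / (1.0 - hct)


def plasma_aif(t, hct: float = DEFAULT_HAEMATOCRIT,
               params: AIFParameters | None = None) -> np.ndarray:
    """Haematocrit-corrected plasma AIF Cp(t) on the minute grid ``t``."""
    return haematocrit_correct(population_aif_blood(t, params), hct)
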