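"""Synthetic in-vivo cohorts, tumor growth inhibition, and the
dose-outcome correlation.

The cohort generator emulates a five-group design (one control plus
irradiation at 40/80/120/160 kVp, five mice per group, 3 Gy surface
dose): tumors start at 70-125 mm^3, grow exponentially, and treatment
suppresses the growth rate in proportion to the normalized tumor
average absorbed dose (AAD).  Measured volumes carry multiplicative
lognormal noise.  The cohort is a synthetic stand-in for an animal
experiment with known ground truth; it exists to exercise the
dose-outcome correlation pipeline, not to reproduce any particular
animal study's numbers.

Tumor volume uses T = 0.5 L W exactly as the caliper formula is usually
printed in this design (L, W in mm); note this is dimensionally an
area, and the conventional variant 0.5 L W^2 is available via
``formula="lww"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TumorMeasurement", "GroupOutcome", "CohortDesign", "tumor_volume",
           "tgi", "simulate_cohort", "pearson", "correlate_aad_tgi",
           "recover_effect_slope"]

DEFAULT_GROUPS = ("control", 40, 80, 120, 160)


@dataclass(frozen=True)
class TumorMeasurement:
    """One caliper measurement: length >= width, mm."""

    L: float
    W: float
    day: int = 0

    def __post_init__(self) -> None:
        if not (self.L >= self.W > 0):
            raise ValueError("need length >= width > 0")


def tumor_volume(m: TumorMeasurement, formula: str = "printed") -> float:
    """Caliper tumor volume, mm^3.

    ``printed``: T = 0.5 L W;  ``lww``: T = 0.5 L W^2 (conventional).
    """
    if formula == "printed":
        return 0.5 * m.L * m.W
    if formula == "lww":
        return 0.5 * m.L * m.W**2
    raise ValueError("formula must be 'printed' or 'lww'")


def tgi(v_ts: float, v_te: float, v_ns: float, v_ne: float) -> float:
    """Tumor growth inhibition, percent.

    TGI = (1 - (V_TE - V_TS) / (V_NE - V_NS)) * 100 with T = treated,
    N = control, S/E = start/end.  May exceed 100 (tumor regression) or
    go negative (faster-than-control growth).
    """
    if v_ne == v_ns:
        raise ZeroDivisionError("control group did not grow; TGI undefined")
    return (1.0 - (v_te - v_ts) / (v_ne - v_ns)) * 100.0


@dataclass(frozen=True)
class GroupOutcome:
    """Group-level endpoint of one synthetic cohort."""

    label: object  # "control" or the kVp value
    v_start: float  # group mean initial volume, mm^3
    v_end: float  # group mean final volume, mm^3
    tgi: float | None  # percent; None for the control group

    def __post_init__(self) -> None:
        if self.v_start <= 0 or self.v_end <= 0:
            raise ValueError("volumes must be positive")


@dataclass(frozen=True)
class CohortDesign:
    """Study design and generative parameters of the synthetic cohort."""

    groups: tuple = DEFAULT_GROUPS
    n_per_group: int = 5
    start_volume_range: tuple = (70.0, 125.0)  # mm^3
    days: int = 14
    control_growth_rate: float = 0.20  # per day (4T1-like doubling ~3.5 d)
    dose_effect_slope: float = 0.8  # growth-rate suppression per unit normalized AAD
    noise_cv: float = 0.15  # lognormal measurement CV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("need at least one mouse per group")
        if self.control_growth_rate < 0 or self.noise_cv < 0 or self.dose_effect_slope < 0:
            raise ValueError("rates, slope and noise must be non-negative")
        if "control" not in self.groups:
            raise ValueError("design must contain a control group")


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_cohort(design: CohortDesign, aad_by_group: dict,
                    per_mouse_tgi: bool = False):
    """Simulate one cohort; returns (outcomes, per-mouse DataFrame).

    ``aad_by_group`` maps each non-control group label to its normalized
    AAD in [0, 1].  Treated growth rate is
    g (1 - s * AAD_norm), clipped at zero; measured volumes carry
    lognormal noise with the design CV; group mean volumes, normalized
    to their baseline so that start-volume randomization does not bias
    the endpoint, feed the TGI formula (``per_mouse_tgi`` computes
    per-mouse TGI against the control means and averages afterwards).
    Deterministic for a fixed design seed.
    """
    missing = [g for g in design.groups if g != "control" and g not in aad_by_group]
    if missing:
        raise ValueError(f"normalized AAD missing for group(s) {missing}")
    for g, a in aad_by_group.items():
        if not 0.0 <= a <= 1.0:
            raise ValueError(f"normalized AAD for group {g!r} outside [0, 1]: {a}")

    rng = np.random.default_rng(design.seed)
    lo, hi = design.start_volume_range
    rows = []
    true_by_group = {}
    for g in design.groups:
        v0 = rng.uniform(lo, hi, design.n_per_group)
        rate = design.control_growth_rate
        if g != "control":
            rate = max(rate * (1.0 - design.dose_effect_slope * aad_by_group[g]), 0.0)
        v_end = v0 * np.exp(rate * design.days)
        v0_meas = v0 * _lognormal_factor(rng, design.noise_cv, design.n_per_group)
        v_end_meas = v_end * _lognormal_factor(rng, design.noise_cv, design.n_per_group)
        true_by_group[g] = (v0_meas, v_end_meas)
        for i in range(design.n_per_group):
            rows.append({"group": str(g), "mouse_id": i, "day_start": 0,
                         "day_end": design.days,
                         "v_start_mm3": v0_meas[i], "v_end_mm3": v_end_meas[i]})
    mice = pd.DataFrame(rows)

    c0, c1 = (v.mean() for v in true_by_group["control"])
    outcomes = []
    for g in design.groups:
        v0m, v1m = true_by_group[g]
        if g == "control":
            outcomes.append(GroupOutcome(g, float(c0), float(c1), None))
            continue
        if per_mouse_tgi:
            vals = [tgi(1.0, b / a, 1.0, c1 / c0) for a, b in zip(v0m, v1m)]
            t = float(np.mean(vals))
        else:
            t = tgi(1.0, float(v1m.mean() / v0m.mean()), 1.0, float(c1 / c0))
        outcomes.append(GroupOutcome(g, float(v0m.mean()), float(v1m.mean()), t))
    return outcomes, mice


def pearson(x, y) -> float:
    """Product-moment correlation coefficient in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-D vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    return float(stats.pearsonr(x, y)[0])


def correlate_aad_tgi(aad_by_kvp: dict, outcomes) -> float:
    """Pearson correlation between group TGI and the model AAD.

    ``aad_by_kvp`` maps simulated tube potentials to tumor AAD (any
    common scale); values at the experimental potentials are linearly
    interpolated from the simulated grid where needed.
    """
    kvps = np.array(sorted(float(k) for k in aad_by_kvp))
    aads = np.array([aad_by_kvp[k] if k in aad_by_kvp else aad_by_kvp[int(k)]
                     for k in kvps])
    xs, ys = [], []
    for o in outcomes:
        if o.tgi is None:
            continue
        k = float(o.label)
        if k < kvps[0] or k > kvps[-1]:
            raise ValueError(f"group {o.label!r} outside the simulated kVp range")
        xs.append(float(np.interp(k, kvps, aads)))
        ys.append(o.tgi)
    if len(xs) < 3:
        raise ValueError("need at least 3 matched (AAD, TGI) points")
    return pearson(xs, ys)


def recover_effect_slope(outcomes, aad_by_group: dict, design: CohortDesign) -> float:
    """Invert the growth model to recover the dose-effect slope.

    With baseline-normalized volumes the measured TGI gives the treated
    growth rate g_T = ln(1 + (1 - TGI/100)(e^{g d} - 1)) / d, and
    (1 - g_T/g) regressed on AAD_norm through the origin recovers the
    slope exactly in the zero-noise limit.
    """
    g, d = design.control_growth_rate, design.days
    num = den = 0.0
    for o in outcomes:
        if o.tgi is None:
            continue
        growth = (1.0 - o.tgi / 100.0) * (np.exp(g * d) - 1.0)
        g_t = np.log1p(growth) / d
        a = aad_by_group[o.label]
        num += (1.0 - g_t / g) * a
        den += a * a
    if den == 0:
        raise ValueError("all normalized AADs are zero; slope unidentifiable")
    return num / den
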