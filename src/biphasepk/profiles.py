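"""Biphasic-dissolution partitioning profiles and their absorption-input reading.

A biphasic dissolution run follows the fraction of an oral dose that has
transferred from an aqueous donor phase (a staged gastric-to-intestinal pH
program) into an organic acceptor phase acting as an absorption sink.  The
cumulative organic-phase profile is interpreted here like a controlled-release
dissolution curve: its shape sets the rate of intestinal absorption and its
plateau the extent (the plateau is identified with the fraction absorbed, Fa).

Conventions
-----------
* Profile times are **minutes**; the PK engine works in hours and converts
  through :class:`AbsorptionInput`.
* Fractions are of dose, dimensionless.  Up to 5% analytical overshoot is
  tolerated on input and clamped to 1.0 when building an absorption input.
* Synthetic profiles carry a 30-minute gastric lag during which the organic
  phase holds no drug (the acceptor phase is only exposed after the gastric
  stage of the assay).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProfileError",
    "PartitioningProfile",
    "ProfileDialect",
    "ShapeSpec",
    "AbsorptionInput",
    "PlateauEstimate",
    "read_profile",
    "write_profile",
    "parametric_profile",
    "estimate_plateau",
    "release_function",
    "SHAPES",
    "GASTRIC_LAG_MIN",
    "ASSAY_DURATION_MIN",
    "OVERSHOOT_TOLERANCE",
]

#: minutes of gastric stage before the organic sink is exposed
GASTRIC_LAG_MIN = 30.0
#: default total assay duration, minutes (4.5 h)
ASSAY_DURATION_MIN = 270.0
#: fractions up to this value are accepted on input (analytical overshoot)
OVERSHOOT_TOLERANCE = 1.05

SHAPES = ("zero_order", "first_order", "square_root", "sigmoidal")


class ProfileError(ValueError):
    """Raised for malformed or inconsistent partitioning-profile data."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ProfileError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class PartitioningProfile:
    """Timestamped aqueous/organic fraction-of-dose series from a biphasic run.

    Parameters
    ----------
    times
        Minutes since dose, strictly increasing, non-negative.
    organic_fraction
        Fraction of dose in the organic (absorption sink) phase at each time.
    aqueous_fraction, ph
        Optional dissolved-fraction and pH traces on the same grid.
    label
        Free-text identifier (drug product, run id, ...).
    duration
        Nominal run duration in minutes (defaults to the assay's 4.5 h).
    """

    times: np.ndarray
    organic_fraction: np.ndarray
    aqueous_fraction: Optional[np.ndarray] = None
    ph: Optional[np.ndarray] = None
    label: str = ""
    duration: float = ASSAY_DURATION_MIN

    def __post_init__(self) -> None:
        times = _as_float_array(self.times, "times")
        org = _as_float_array(self.organic_fraction, "organic_fraction")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "organic_fraction", org)
        if times.size != org.size:
            raise ProfileError("times and organic_fraction differ in length")
        if times.size < 2:
            raise ProfileError("a profile needs at least two time points")
        if times[0] < 0:
            raise ProfileError("times must be non-negative")
        if np.any(np.diff(times) <= 0):
            bad = int(np.argmax(np.diff(times) <= 0)) + 1
            raise ProfileError(f"times must be strictly increasing (row {bad})")
        for name in ("organic_fraction",):
            vals = getattr(self, name)
            if np.any(vals < -1e-9) or np.any(vals > OVERSHOOT_TOLERANCE + 1e-12):
                raise ProfileError(
                    f"{name} must lie in [0, {OVERSHOOT_TOLERANCE}] (fraction of dose)"
                )
        if self.aqueous_fraction is not None:
            aq = _as_float_array(self.aqueous_fraction, "aqueous_fraction")
            if aq.size != times.size:
                raise ProfileError("aqueous_fraction length mismatch")
            if np.any(aq < -1e-9) or np.any(aq > OVERSHOOT_TOLERANCE + 1e-12):
                raise ProfileError("aqueous_fraction out of [0, 1.05]")
            object.__setattr__(self, "aqueous_fraction", aq)
        if self.ph is not None:
            object.__setattr__(self, "ph", _as_float_array(self.ph, "ph"))
            if self.ph.size != times.size:
                raise ProfileError("ph length mismatch")

    @property
    def n_points(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class ProfileDialect:
    """Column/unit mapping for reading profile CSV files.

    The canonical dialect is ``time_min,aqueous_pct,organic_pct,ph`` with
    percent amounts; alternative column names or units (hours, fractions)
    are declared here.
    """

    time_col: str = "time_min"
    organic_col: str = "organic_pct"
    aqueous_col: str = "aqueous_pct"
    ph_col: str = "ph"
    time_unit: str = "min"  # "min" or "h"
    amount_unit: str = "percent"  # "percent" or "fraction"

    def __post_init__(self) -> None:
        if self.time_unit not in ("min", "h"):
            raise ProfileError("time_unit must be 'min' or 'h'")
        if self.amount_unit not in ("percent", "fraction"):
            raise ProfileError("amount_unit must be 'percent' or 'fraction'")


def read_profile(path, dialect: Optional[ProfileDialect] = None,
                 label: str = "") -> PartitioningProfile:
    """Read a partitioning profile from CSV and validate it.

    Lines starting with ``#`` are comments.  Percent columns are divided by
    100; hour time columns are converted to minutes.  Fractions above 1.05
    after conversion, duplicate or non-monotone times, and missing required
    columns raise :class:`ProfileError`.
    """
    dialect = dialect or ProfileDialect()
    path = Path(path)
    if not path.exists():
        raise ProfileError(f"no such profile file: {path}")
    df = pd.read_csv(path, comment="#")
    for col in (dialect.time_col, dialect.organic_col):
        if col not in df.columns:
            raise ProfileError(f"{path}: missing required column '{col}'")
    times = df[dialect.time_col].to_numpy(dtype=float)
    if np.any(pd.isna(times)):
        raise ProfileError(f"{path}: missing time value")
    dup = pd.Series(times).duplicated()
    if dup.any():
        raise ProfileError(
            f"{path}: duplicate time point at row {int(dup.idxmax()) + 2}"
        )
    if dialect.time_unit == "h":
        times = times * 60.0
    scale = 0.01 if dialect.amount_unit == "percent" else 1.0
    org = df[dialect.organic_col].to_numpy(dtype=float) * scale
    if np.any(org > OVERSHOOT_TOLERANCE + 1e-12):
        row = int(np.argmax(org > OVERSHOOT_TOLERANCE + 1e-12)) + 2
        raise ProfileError(
            f"{path}: organic fraction exceeds {OVERSHOOT_TOLERANCE} at row {row} "
            "(check units)"
        )
    aq = None
    if dialect.aqueous_col in df.columns:
        aq = df[dialect.aqueous_col].to_numpy(dtype=float) * scale
    ph = df[dialect.ph_col].to_numpy(dtype=float) if dialect.ph_col in df.columns else None
    order = np.argsort(times, kind="stable")
    if np.any(np.diff(times) <= 0):
        # strictly increasing required; duplicates were caught above, so this
        # is an out-of-order file -- report rather than silently sorting
        raise ProfileError(f"{path}: time column is not strictly increasing")
    del order
    return PartitioningProfile(
        times=times, organic_fraction=org, aqueous_fraction=aq, ph=ph,
        label=label or path.stem, duration=float(times[-1]),
    )


def write_profile(profile: PartitioningProfile, path) -> None:
    """Write a profile in the canonical CSV dialect (minutes, percent)."""
    path = Path(path)
    cols = {"time_min": profile.times,
            "organic_pct": profile.organic_fraction * 100.0}
    if profile.aqueous_fraction is not None:
        cols["aqueous_pct"] = profile.aqueous_fraction * 100.0
    if profile.ph is not None:
        cols["ph"] = profile.ph
    df = pd.DataFrame(cols)
    # canonical column order
    order = [c for c in ("time_min", "aqueous_pct", "organic_pct", "ph") if c in df]
    df[order].to_csv(path, index=False, float_format="%.6g")


@dataclass(frozen=True)
class ShapeSpec:
    """Parametric description of one of the four observed partitioning shapes.

    ``zero_order`` is a linear ramp ending at ``t_ramp_end``; ``first_order``
    approaches the plateau with rate constant ``k`` (1/min); ``square_root``
    follows a Higuchi-type sqrt law with coefficient ``coeff`` (1/sqrt(min));
    ``sigmoidal`` is a Hill curve with midpoint ``t_mid`` minutes after the
    lag and steepness ``hill``.  All shapes are zero during the gastric lag
    ``t_lag`` and capped at the plateau fraction ``f_inf``.
    """

    shape: str
    f_inf: float
    t_lag: float = GASTRIC_LAG_MIN
    t_ramp_end: float = ASSAY_DURATION_MIN  # zero_order only
    k: float = 0.025                        # first_order only, 1/min
    coeff: float = 0.08                     # square_root only, 1/sqrt(min)
    t_mid: float = 120.0                    # sigmoidal only, min after lag
    hill: float = 10.0                      # sigmoidal only

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ProfileError(f"unknown shape {self.shape!r}; one of {SHAPES}")
        if not 0.0 <= self.f_inf <= 1.0:
            raise ProfileError("f_inf must lie in [0, 1]")
        if self.t_lag < 0:
            raise ProfileError("t_lag must be >= 0")
        for name in ("k", "coeff", "t_mid", "hill"):
            if getattr(self, name) <= 0:
                raise ProfileError(f"{name} must be > 0")
        if self.shape == "zero_order" and self.t_ramp_end <= self.t_lag:
            raise ProfileError("zero_order ramp must end after t_lag")


def parametric_profile(spec: ShapeSpec,
                       grid: Optional[Sequence[float]] = None,
                       duration: float = ASSAY_DURATION_MIN) -> PartitioningProfile:
    """Construct a noiseless partitioning profile of the requested shape.

    The grid defaults to 5-minute sampling over ``[0, duration]``.  The
    result is zero on ``[0, t_lag]`` and capped at ``spec.f_inf``.
    """
    if grid is None:
        grid = np.arange(0.0, duration + 1e-9, 5.0)
        if grid[-1] < duration:
            grid = np.append(grid, duration)
    grid = _as_float_array(grid, "grid")
    if grid.size < 2 or grid[-1] < spec.t_lag:
        raise ProfileError("grid must extend beyond the gastric lag")
    tau = np.maximum(grid - spec.t_lag, 0.0)
    f = spec.f_inf
    if spec.shape == "zero_order":
        frac = f * np.clip(tau / (spec.t_ramp_end - spec.t_lag), 0.0, 1.0)
    elif spec.shape == "first_order":
        frac = f * (1.0 - np.exp(-spec.k * tau))
    elif spec.shape == "square_root":
        frac = f * np.minimum(1.0, spec.coeff * np.sqrt(tau))
    else:  # sigmoidal
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(
                tau > 0,
                f * tau ** spec.hill / (spec.t_mid ** spec.hill + tau ** spec.hill),
                0.0,
            )
    frac = np.minimum(frac, f)
    return PartitioningProfile(
        times=grid, organic_fraction=frac,
        label=f"synthetic:{spec.shape}", duration=float(grid[-1]),
    )


@dataclass(frozen=True)
class PlateauEstimate:
    value: float
    stable: bool


def estimate_plateau(profile: PartitioningProfile,
                     window: float = 60.0) -> PlateauEstimate:
    """Mean organic fraction over the final ``window`` minutes, clamped to [0, 1].

    The stability flag is true iff the range (max - min) inside the window is
    at most 0.02 absolute, i.e. the profile has genuinely levelled off.
    """
    t_end = profile.times[-1]
    if t_end - profile.times[0] < window:
        raise ProfileError("profile shorter than the plateau window")
    sel = profile.times >= t_end - window
    vals = profile.organic_fraction[sel]
    value = float(np.clip(vals.mean(), 0.0, 1.0))
    stable = bool(vals.max() - vals.min() <= 0.02)
    return PlateauEstimate(value=value, stable=stable)


@dataclass(frozen=True)
class AbsorptionInput:
    """Right-continuous, non-decreasing cumulative release function of time.

    ``times_min`` / ``release`` are the knots (minutes, fraction of dose); the
    function interpolates linearly between knots, is 0 at t=0 and holds the
    plateau ``f_inf`` beyond the last knot.  ``time_scale`` maps in vitro
    minutes to in vivo minutes (default 1:1).
    """

    times_min: np.ndarray
    release: np.ndarray
    time_scale: float = 1.0

    def __post_init__(self) -> None:
        t = _as_float_array(self.times_min, "times_min")
        r = _as_float_array(self.release, "release")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "release", r)
        if t.size != r.size or t.size < 2:
            raise ProfileError("release knots malformed")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ProfileError("knot times must be strictly increasing, >= 0")
        if np.any(np.diff(r) < -1e-12):
            raise ProfileError("release must be non-decreasing")
        if r[0] != 0.0 and t[0] == 0.0:
            raise ProfileError("release(0) must be 0")
        if np.any(r < 0) or r[-1] > 1.0 + 1e-12:
            raise ProfileError("release must lie in [0, 1]")
        if self.time_scale <= 0:
            raise ProfileError("time_scale must be > 0")

    @property
    def f_inf(self) -> float:
        """Plateau fraction of dose ultimately releasable."""
        return float(self.release[-1])

    @property
    def is_zero(self) -> bool:
        return self.f_inf == 0.0

    def __call__(self, t_min):
        """Cumulative released fraction at in vivo time ``t_min`` (minutes)."""
        t = np.asarray(t_min, dtype=float) / self.time_scale
        out = np.interp(t, self.times_min, self.release,
                        left=0.0, right=self.f_inf)
        out = np.where(t < self.times_min[0], 0.0, out)
        return out if out.ndim else float(out)

    def knots_hours(self) -> np.ndarray:
        """Knot positions on the in vivo clock, in hours."""
        return self.times_min * self.time_scale / 60.0

    def segment_rates_per_hour(self) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-constant release rate (fraction of dose per hour).

        Returns the knot times in hours and the rate on each inter-knot
        segment (one fewer entry than knots); the rate is 0 after the last
        knot.
        """
        kh = self.knots_hours()
        rates = np.diff(self.release) / np.diff(kh)
        return kh, rates


def release_function(profile: PartitioningProfile,
                     normalize: str = "none",
                     time_scale: float = 1.0) -> AbsorptionInput:
    """Convert a partitioning profile into a cumulative absorption input.

    A running-maximum envelope removes analytical non-monotonicity (release
    into the organic sink is physically cumulative), values are clamped to
    [0, 1], and the plateau is held constant beyond the last knot.  With
    ``normalize="to_plateau"`` the envelope is rescaled so the plateau is 1
    (for use when the extent of absorption is handled separately); by default
    the plateau equals the in vitro partitioned extent, which is what encodes
    the fraction absorbed.
    """
    if normalize not in ("none", "to_plateau"):
        raise ProfileError("normalize must be 'none' or 'to_plateau'")
    org = profile.organic_fraction
    if np.any(org < -1e-9):
        raise ProfileError("negative organic fractions")
    env = np.maximum.accumulate(np.clip(org, 0.0, 1.0))
    times = profile.times
    if times[0] > 0.0:
        times = np.concatenate([[0.0], times])
        env = np.concatenate([[0.0], env])
    else:
        env = env.copy()
        env[0] = 0.0 if org[0] <= 0 else env[0]
    if env[-1] > 0 and normalize == "to_plateau":
        env = env / env[-1]
    return AbsorptionInput(times_min=times, release=env, time_scale=time_scale)
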