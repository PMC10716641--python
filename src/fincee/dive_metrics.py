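"""Dive segmentation and per-dive behavioural metrics.

A dive is a maximal run of depth samples strictly deeper than a surface
threshold (3 m by default).  For each dive three metric categories are
computed: dive-behaviour metrics (times, depth, lunges, breaths), angular
metrics (circular summaries of pitch/roll/heading over descent and
ascent), and horizontal metrics (speeds, turning rate, distance to the
sound source).  A companion step attaches per-dive exposure covariates
(max/avg/min received level, cumulative SEL, phase) from a ping schedule,
yielding the five-variable-plus-covariates records the HMM consumes.

Conventions (configurable, stated here because the field has no single
standard): the bottom phase is the set of samples deeper than 85% of the
dive's maximum depth; descent runs from the dive start to the first
bottom-phase sample and ascent from the last bottom-phase sample to the
dive end; angular channels are summarized with circular means; lunges and
breaths are consumed as annotated event-time streams, not detected here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import circmean

from .synthetic import PingSchedule, ReceivedExposure, exposure_covariates

__all__ = [
    "DiveInterval",
    "ResamplingRequiredError",
    "MissingChannelError",
    "segment_dives",
    "compute_metrics",
    "metrics_table",
    "attach_exposure",
    "DIVE_THRESHOLD_M",
    "BOTTOM_FRACTION",
]

DIVE_THRESHOLD_M = 3.0
BOTTOM_FRACTION = 0.85


class ResamplingRequiredError(ValueError):
    """Raised when the depth series is not uniformly sampled."""


class MissingChannelError(KeyError):
    """Raised when a required tag channel is absent for a metric category."""


@dataclass(frozen=True)
class DiveInterval:
    """One segmented dive: sample index span, times and maximum depth."""

    start_s: float
    end_s: float
    max_depth_m: float
    i0: int  # first in-dive sample index
    i1: int  # last in-dive sample index (inclusive)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _sample_interval(series: pd.DataFrame) -> float:
    t = series["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ResamplingRequiredError("series too short to establish a sample rate")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ResamplingRequiredError("depth series must be uniformly sampled")
    return float(dt[0])


def segment_dives(series: pd.DataFrame, threshold_m: float = DIVE_THRESHOLD_M) -> list[DiveInterval]:
    """Find maximal runs of depth strictly greater than ``threshold_m``.

    Runs shorter than two samples are discarded; adjacent dives are by
    construction separated by at least one at-surface sample.  A sample at
    exactly the threshold counts as surface.
    """
    if threshold_m <= 0:
        raise ValueError("threshold_m must be positive")
    dt = _sample_interval(series)
    depth = series["depth_m"].to_numpy(dtype=float)
    t = series["time_s"].to_numpy(dtype=float)
    wet = depth > threshold_m
    edges = np.diff(np.concatenate(([0], wet.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1  # inclusive
    out = []
    for i0, i1 in zip(starts, ends):
        if i1 - i0 + 1 < 2:
            continue
        out.append(DiveInterval(
            start_s=float(t[i0]), end_s=float(t[i1] + dt),
            max_depth_m=float(depth[i0:i1 + 1].max()), i0=int(i0), i1=int(i1),
        ))
    return out


def _circ(x: np.ndarray) -> float:
    return float(circmean(x, high=np.pi, low=-np.pi))


def _wrap(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into (-pi, pi]."""
    return -((-np.asarray(a) + np.pi) % (2 * np.pi) - np.pi)


def _phases(series: pd.DataFrame, dive: DiveInterval,
            bottom_fraction: float = BOTTOM_FRACTION) -> tuple[slice, slice, slice]:
    """Descent / bottom / ascent index slices within the dive."""
    depth = series["depth_m"].to_numpy(dtype=float)[dive.i0:dive.i1 + 1]
    bottom = depth > bottom_fraction * depth.max()
    first_b = int(np.flatnonzero(bottom)[0])
    last_b = int(np.flatnonzero(bottom)[-1])
    base = dive.i0
    return (slice(base, base + first_b + 1),
            slice(base + first_b, base + last_b + 1),
            slice(base + last_b, dive.i1 + 1))


def compute_metrics(
    series: pd.DataFrame,
    dive: DiveInterval,
    category: str,
    source_track: pd.DataFrame | None = None,
    whale_track: pd.DataFrame | None = None,
    lunge_times: np.ndarray | None = None,
    breath_times: np.ndarray | None = None,
    next_dive_start_s: float | None = None,
    bottom_fraction: float = BOTTOM_FRACTION,
) -> dict[str, float]:
    """Metrics of one dive for one category (``dive``/``angular``/``horizontal``).

    Dive-behaviour metrics use the descent/bottom/ascent convention in the
    module docstring; angular metrics are circular means (and wrapped
    first-to-last changes) of pitch, roll and heading over descent and
    ascent; horizontal metrics summarize the speed channel, the wrapped
    heading increments per unit time, and (when whale and source tracks are
    supplied) ranges to the source at the dive's start and end.
    """
    dt = _sample_interval(series)
    t = series["time_s"].to_numpy(dtype=float)
    desc, bot, asc = _phases(series, dive, bottom_fraction)

    if category == "dive":
        bottom_n = bot.stop - bot.start
        res = {
            "dive_time_s": dive.duration_s,
            "max_depth_m": dive.max_depth_m,
            "descent_time_s": (desc.stop - desc.start - 1) * dt,
            "ascent_time_s": (asc.stop - asc.start - 1) * dt,
            "bottom_time_s": max(bottom_n - 1, 0) * dt,
            "post_surface_s": (next_dive_start_s - dive.end_s)
                              if next_dive_start_s is not None else np.nan,
        }
        res["lunges"] = int(np.sum((lunge_times >= dive.start_s) & (lunge_times < dive.end_s))) \
            if lunge_times is not None else 0
        if breath_times is not None and next_dive_start_s is not None:
            res["breaths"] = int(np.sum((breath_times >= dive.end_s)
                                        & (breath_times < next_dive_start_s)))
        else:
            res["breaths"] = 0
        return res

    if category == "angular":
        for ch in ("pitch_rad", "roll_rad", "heading_rad"):
            if ch not in series.columns:
                raise MissingChannelError(ch)
        res = {}
        for phase, sl in (("descent", desc), ("ascent", asc)):
            for ch, name in (("pitch_rad", "pitch"), ("roll_rad", "roll"),
                             ("heading_rad", "heading")):
                v = series[ch].to_numpy(dtype=float)[sl]
                res[f"{phase}_{name}"] = _circ(v)
                res[f"d_{phase}_{name}"] = float(_wrap(v[-1] - v[0]))
        return res

    if category == "horizontal":
        if "speed_ms" not in series.columns:
            raise MissingChannelError("speed_ms")
        spd = series["speed_ms"].to_numpy(dtype=float)
        hdg = series["heading_rad"].to_numpy(dtype=float)
        in_dive = slice(dive.i0, dive.i1 + 1)
        dh = _wrap(np.diff(hdg[in_dive]))
        res = {
            "horizontal_speed_ms": float(spd[in_dive].mean()),
            "turning_rate_rad_s": float(np.mean(np.abs(dh)) / dt) if np.size(dh) else 0.0,
            "turn_angle_rad": float(_wrap(hdg[dive.i1] - hdg[dive.i0])),
        }
        if next_dive_start_s is not None:
            surf = (t >= dive.end_s) & (t < next_dive_start_s)
            res["surface_speed_ms"] = float(spd[surf].mean()) if surf.any() else np.nan
        else:
            res["surface_speed_ms"] = np.nan
        if source_track is not None and whale_track is not None:
            def _range_at(ts: float) -> float:
                wi = np.searchsorted(whale_track["time_s"].to_numpy(), ts)
                si = np.searchsorted(source_track["time_s"].to_numpy(), ts)
                wi = min(wi, len(whale_track) - 1)
                si = min(si, len(source_track) - 1)
                w = whale_track.iloc[wi]
                s = source_track.iloc[si]
                return float(np.hypot(w["x"] - s["x"], w["y"] - s["y"]))
            res["dist_start_m"] = _range_at(dive.start_s)
            res["dist_end_m"] = _range_at(dive.end_s)
            res["d_dist_m"] = res["dist_end_m"] - res["dist_start_m"]
        else:
            res["dist_start_m"] = res["dist_end_m"] = res["d_dist_m"] = np.nan
        return res

    raise ValueError(f"unknown category {category!r}")


def metrics_table(
    series: pd.DataFrame,
    dives: list[DiveInterval] | None = None,
    threshold_m: float = DIVE_THRESHOLD_M,
    **kwargs,
) -> pd.DataFrame:
    """All-category per-dive metric table with ``c1_``/``c2_``/``c3_`` prefixes."""
    if dives is None:
        dives = segment_dives(series, threshold_m)
    rows = []
    for j, dv in enumerate(dives):
        nxt = dives[j + 1].start_s if j + 1 < len(dives) else None
        row = {"start_s": dv.start_s, "end_s": dv.end_s}
        row.update({f"c1_{k}": v for k, v in compute_metrics(
            series, dv, "dive", next_dive_start_s=nxt, **{
                k: v for k, v in kwargs.items()
                if k in ("lunge_times", "breath_times", "bottom_fraction")}).items()})
        row.update({f"c2_{k}": v for k, v in compute_metrics(
            series, dv, "angular", **{
                k: v for k, v in kwargs.items() if k in ("bottom_fraction",)}).items()})
        row.update({f"c3_{k}": v for k, v in compute_metrics(
            series, dv, "horizontal", next_dive_start_s=nxt, **{
                k: v for k, v in kwargs.items()
                if k in ("source_track", "whale_track", "bottom_fraction")}).items()})
        rows.append(row)
    return pd.DataFrame(rows)


def attach_exposure(
    dives: pd.DataFrame,
    exposure: ReceivedExposure | None,
    schedule: PingSchedule,
) -> pd.DataFrame:
    """Attach per-dive exposure covariates to a metric table.

    ``dives`` must carry ``start_s``/``end_s`` (CEE clock).  The output
    keeps the HMM's five observation variables (dive time, max depth,
    lunges, speed over ground, turning angle) when their source columns are
    present and appends ``max_rl``, ``avg_rl``, ``min_rl``,
    ``cumulative_sel`` (all 0 outside exposure), the 0/1 ``exposure`` flag
    and the CEE ``phase`` of the dive start.
    """
    cov = exposure_covariates(dives["start_s"].to_numpy(), dives["end_s"].to_numpy(),
                              schedule, exposure)
    out = dives.reset_index(drop=True).copy()
    rename = {"c1_dive_time_s": "dive_time_s", "c1_max_depth_m": "max_depth_m",
              "c1_lunges": "lunges", "c3_horizontal_speed_ms": "speed_ms",
              "c3_turn_angle_rad": "turn_angle_rad"}
    for src, dst in rename.items():
        if src in out.columns and dst not in out.columns:
            out[dst] = out[src]
    return pd.concat([out, cov], axis=1)
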