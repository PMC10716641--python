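"""Synthetic controlled-exposure-experiment (CEE) data generation.

A CEE presents a tagged whale with a structured acoustic treatment: a
30-min pre-exposure baseline, a 30-min exposure phase in which a
mid-frequency signal (MFAS or pseudorandom noise, PRN) is projected once
every 25 s and ramped up in 3 dB source-level increments, and a 30-min
post-exposure phase.  Control CEEs follow the same timeline with no
transmissions.

This module builds ping schedules honouring that design, propagates them
to a whale position to obtain per-ping received levels (RL) and cumulative
sound exposure level (cSEL), simulates per-dive behaviour from the
context hidden-Markov model used throughout the package, renders sampled
depth/orientation tag series from simulated dives, and loads the packaged
transcriptions of the study's CEE-metadata and expert-severity tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PingSchedule",
    "ReceivedExposure",
    "SimTruth",
    "FixtureTables",
    "InvalidConfigError",
    "PropagationDomainError",
    "FixtureCorruptionError",
    "make_cee_schedule",
    "received_levels",
    "exposure_covariates",
    "simulate_dives",
    "render_depth_series",
    "simulate_response_design",
    "load_study_tables",
    "DEFAULT_PING_INTERVAL_S",
    "DEFAULT_SL_INITIAL_DB",
    "DEFAULT_SL_MAX_MFAS_DB",
    "DEFAULT_SL_MAX_PRN_DB",
    "DEFAULT_RAMP_STEP_DB",
    "DEFAULT_PHASE_MINUTES",
]

# CEE design constants (study protocol defaults).
DEFAULT_PING_INTERVAL_S = 25.0
DEFAULT_SL_INITIAL_DB = 160.0
DEFAULT_SL_MAX_MFAS_DB = 210.0
DEFAULT_SL_MAX_PRN_DB = 206.0
DEFAULT_RAMP_STEP_DB = 3.0
DEFAULT_PHASE_MINUTES = 30.0
#: default ping duration used to convert RL to single-ping SEL (dB offset
#: 10*log10(duration)); the protocol does not pin this down, so it is a
#: configurable package convention.
DEFAULT_PING_DURATION_S = 1.0


class InvalidConfigError(ValueError):
    """Raised when a CEE or simulation configuration is self-contradictory."""


class PropagationDomainError(ValueError):
    """Raised when the spreading-loss model is evaluated outside its domain."""


class FixtureCorruptionError(RuntimeError):
    """Raised when a packaged fixture fails its schema or count checks."""


@dataclass(frozen=True)
class PingSchedule:
    """Transmission times and source levels for one CEE.

    ``ping_times`` are seconds from the start of the *exposure phase* and
    strictly increasing with constant spacing.  Source levels ramp from the
    initial level in fixed increments and are then held at the maximum; a
    final partial increment is permitted so the maximum is reached exactly.
    CONTROL schedules contain no pings.
    """

    ping_times: np.ndarray
    source_levels: np.ndarray
    signal_type: str
    phase_bounds: tuple[float, float, float]  # start of pre / exposure / post, s

    def __post_init__(self):
        t = np.asarray(self.ping_times, dtype=float)
        sl = np.asarray(self.source_levels, dtype=float)
        if t.shape != sl.shape:
            raise InvalidConfigError("ping_times and source_levels differ in length")
        if self.signal_type == "CONTROL" and t.size:
            raise InvalidConfigError("CONTROL schedules must contain zero pings")
        if t.size > 1:
            dt = np.diff(t)
            if not (np.all(dt > 0) and np.allclose(dt, dt[0])):
                raise InvalidConfigError("ping times must increase with constant spacing")
            if np.any(np.diff(sl) < -1e-9):
                raise InvalidConfigError("source levels must be non-decreasing")
        object.__setattr__(self, "ping_times", t)
        object.__setattr__(self, "source_levels", sl)

    @property
    def n_pings(self) -> int:
        return int(self.ping_times.size)

    def absolute_ping_times(self) -> np.ndarray:
        """Ping times on the CEE clock (seconds from pre-exposure start)."""
        return self.ping_times + self.phase_bounds[1]


@dataclass(frozen=True)
class ReceivedExposure:
    """Per-ping received levels at a whale and the running energy sum.

    RL is an RMS level in dB re 1 uPa (one-third-octave-band sense); a
    single ping's SEL is RL + 10*log10(ping duration); the cumulative SEL
    is the running energy sum of per-ping SELs, dB re 1 uPa^2 s.
    """

    per_ping_rl: np.ndarray
    per_ping_sel: np.ndarray
    cumulative_sel: np.ndarray
    range_m: np.ndarray

    def __post_init__(self):
        cs = np.asarray(self.cumulative_sel, dtype=float)
        if cs.size and np.any(np.diff(cs) < -1e-9):
            raise InvalidConfigError("cumulative SEL must be non-decreasing")


@dataclass(frozen=True)
class SimTruth:
    """Generating truth of a simulated dataset.

    One context (state-switching regime) per whale, one hidden state per
    dive, plus the generating parameters and seed.
    """

    contexts: np.ndarray            # (n_whales,), 1-based
    states: list[np.ndarray]        # per whale, 1-based state path
    params: dict
    seed: int


@dataclass(frozen=True)
class FixtureTables:
    """Validated transcriptions of the study's printed tables."""

    cee_table: pd.DataFrame
    severity_table: pd.DataFrame


def make_cee_schedule(
    signal_type: str,
    phase_minutes: float = DEFAULT_PHASE_MINUTES,
    ping_interval_s: float = DEFAULT_PING_INTERVAL_S,
    sl_initial_db: float | None = None,
    sl_max_db: float | None = None,
    ramp_step_db: float = DEFAULT_RAMP_STEP_DB,
    first_ping_s: float = 0.0,
) -> PingSchedule:
    """Build the transmission schedule for one CEE.

    Pings occur every ``ping_interval_s`` seconds starting ``first_ping_s``
    into the exposure phase, strictly inside the phase.  The source level of
    ping ``i`` is ``min(sl_initial + i*ramp_step, sl_max)``: the ramp runs
    in fixed increments with a final partial step onto the maximum when the
    remaining gap is smaller than one increment.

    ``phase_minutes`` sets the common length of the pre, exposure and post
    phases.  CONTROL schedules carry no pings (and must not be given a
    nonzero source level).
    """
    signal_type = signal_type.upper()
    if signal_type not in {"MFAS", "PRN", "CONTROL"}:
        raise InvalidConfigError(f"unknown signal type {signal_type!r}")
    if phase_minutes <= 0:
        raise InvalidConfigError("phase_minutes must be positive")
    if ramp_step_db <= 0:
        raise InvalidConfigError("ramp_step_db must be positive")

    phase_s = phase_minutes * 60.0
    bounds = (0.0, phase_s, 2 * phase_s)

    if signal_type == "CONTROL":
        # a deliberately configured nonzero source level on a control is a
        # contradiction (defaults of None mean "protocol value")
        if (sl_initial_db not in (None, 0.0)) or (sl_max_db not in (None, 0.0)):
            raise InvalidConfigError("CONTROL CEEs transmit no signal")
        return PingSchedule(np.empty(0), np.empty(0), "CONTROL", bounds)

    if sl_initial_db is None:
        sl_initial_db = DEFAULT_SL_INITIAL_DB
    if sl_max_db is None:
        sl_max_db = DEFAULT_SL_MAX_MFAS_DB if signal_type == "MFAS" else DEFAULT_SL_MAX_PRN_DB
    if sl_max_db < sl_initial_db:
        raise InvalidConfigError("sl_max_db must be >= sl_initial_db")

    times = np.arange(first_ping_s, phase_s, ping_interval_s, dtype=float)
    levels = np.minimum(sl_initial_db + ramp_step_db * np.arange(times.size), sl_max_db)
    return PingSchedule(times, levels, signal_type, bounds)


def received_levels(
    schedule: PingSchedule,
    whale_positions: np.ndarray | None = None,
    source_positions: np.ndarray | None = None,
    tl_coeff: float = 20.0,
    ping_duration_s: float = DEFAULT_PING_DURATION_S,
    ranges_m: np.ndarray | float | None = None,
) -> ReceivedExposure:
    """Propagate a ping schedule to a whale.

    Spreading loss only: ``RL_i = SL_i - tl_coeff * log10(range_i)`` (dB),
    with ``tl_coeff = 20`` the spherical-spreading default; absorption is
    neglected at these band/range scales.  Positions (shape ``(n_pings, 2)``
    metres) may be given for whale and source, or per-ping ranges directly
    via ``ranges_m``.  Ranges below 1 m are outside the model's domain.
    """
    n = schedule.n_pings
    if ranges_m is not None:
        r = np.broadcast_to(np.asarray(ranges_m, dtype=float), (n,)).copy()
    else:
        if whale_positions is None or source_positions is None:
            raise InvalidConfigError("provide positions or ranges_m")
        wp = np.asarray(whale_positions, dtype=float).reshape(n, -1)
        sp = np.asarray(source_positions, dtype=float).reshape(n, -1)
        r = np.linalg.norm(wp - sp, axis=1)
    if n and np.any(r < 1.0):
        raise PropagationDomainError("source-whale range < 1 m invalidates the model")

    rl = schedule.source_levels - tl_coeff * np.log10(np.maximum(r, 1.0))
    sel = rl + 10.0 * np.log10(ping_duration_s)
    if n:
        csel = 10.0 * np.log10(np.cumsum(10.0 ** (sel / 10.0)))
    else:
        csel = np.empty(0)
    return ReceivedExposure(rl, sel, csel, r)


def exposure_covariates(
    dive_starts: np.ndarray,
    dive_ends: np.ndarray,
    schedule: PingSchedule,
    exposure: ReceivedExposure | None,
) -> pd.DataFrame:
    """Per-dive exposure covariates from a ping schedule.

    For each dive interval (on the CEE clock) the maximum, arithmetic-mean
    and minimum received level over the pings whose transmission time falls
    inside the dive, the cumulative SEL at the end of the dive, a 0/1
    exposure flag, and the CEE phase of the dive start.  All level
    covariates are exactly 0 when no ping overlaps the dive.
    """
    dive_starts = np.asarray(dive_starts, dtype=float)
    dive_ends = np.asarray(dive_ends, dtype=float)
    n = dive_starts.size
    out = {
        "max_rl": np.zeros(n), "avg_rl": np.zeros(n), "min_rl": np.zeros(n),
        "cumulative_sel": np.zeros(n), "exposure": np.zeros(n, dtype=int),
    }
    pre_s, exp_s, post_s = schedule.phase_bounds
    phase = np.where(dive_starts < exp_s, "before",
                     np.where(dive_starts < post_s, "during", "after"))
    if schedule.n_pings and exposure is not None:
        t = schedule.absolute_ping_times()
        for i in range(n):
            sel_mask = (t >= dive_starts[i]) & (t < dive_ends[i])
            if sel_mask.any():
                rl = exposure.per_ping_rl[sel_mask]
                out["max_rl"][i] = rl.max()
                out["avg_rl"][i] = rl.mean()
                out["min_rl"][i] = rl.min()
                out["exposure"][i] = 1
            n_done = int(np.searchsorted(t, dive_ends[i], side="left"))
            if n_done > 0:
                out["cumulative_sel"][i] = exposure.cumulative_sel[n_done - 1]
    out["phase"] = phase
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Generative context-HMM
# ---------------------------------------------------------------------------

def _validate_gen_params(params: dict) -> None:
    for key in ("time_shape", "time_rate", "depth_shape", "depth_rate",
                "lunge_rate", "speed_shape", "speed_rate", "kappa"):
        if np.any(np.asarray(params[key], dtype=float) <= 0) and key != "kappa":
            raise InvalidConfigError(f"{key} must be strictly positive")
        if key == "kappa" and np.any(np.asarray(params[key], dtype=float) < 0):
            raise InvalidConfigError("kappa must be non-negative")


def _row_tpm(eta: np.ndarray, beta: np.ndarray, x: float) -> np.ndarray:
    """Transition matrix from off-diagonal logits at covariate value x.

    Multinomial-logit link with the diagonal (staying put) as reference:
    ``gamma_ij propto exp(eta_ij + beta_ij * x)`` for j != i, ``gamma_ii
    propto 1``.
    """
    n = eta.shape[0]
    logits = eta + beta * x
    logits[np.arange(n), np.arange(n)] = 0.0
    z = np.exp(logits - logits.max(axis=1, keepdims=True))
    return z / z.sum(axis=1, keepdims=True)


def simulate_dives(
    hmm_params: dict,
    covariate_series: np.ndarray | Sequence[np.ndarray] | None,
    n_whales: int,
    dives_per_whale: int,
    seed: int,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate per-dive observation sequences from the context HMM.

    ``hmm_params`` holds, per state, the emission parameters of the five
    observation streams — gamma(shape, rate) for dive time, max depth and
    speed over ground; Poisson(rate) for lunges; von Mises(mu, kappa) for
    turning angle — and, per context, off-diagonal transition intercepts
    ``eta`` (K, N, N), covariate coefficients ``beta`` (K, N, N), initial
    state distributions ``delta`` (K, N) and mixing probabilities ``pi``
    (K,).  Emission parameters are shared across contexts.

    ``covariate_series`` gives the transition covariate per dive, already on
    the model (link) scale: either one array of length ``dives_per_whale``
    shared by every whale, a per-whale sequence of arrays, or ``None`` for
    an all-zero covariate.  The covariate at dive ``t`` acts on the
    transition into dive ``t``.

    Returns a tidy frame (one row per dive, ``whale_id`` column) and the
    generating truth.  The same seed reproduces the output bit for bit.
    """
    _validate_gen_params(hmm_params)
    rng = np.random.default_rng(seed)
    pi = np.asarray(hmm_params["pi"], dtype=float)
    eta = np.asarray(hmm_params["eta"], dtype=float)
    beta = np.asarray(hmm_params.get("beta", np.zeros_like(eta)), dtype=float)
    delta = np.asarray(hmm_params["delta"], dtype=float)
    K, N = delta.shape

    if covariate_series is None:
        xs = [np.zeros(dives_per_whale)] * n_whales
    elif isinstance(covariate_series, np.ndarray) and covariate_series.ndim == 1:
        if covariate_series.size != dives_per_whale:
            raise InvalidConfigError("covariate_series length must equal dives_per_whale")
        xs = [np.asarray(covariate_series, dtype=float)] * n_whales
    else:
        xs = [np.asarray(x, dtype=float) for x in covariate_series]
        if len(xs) != n_whales:
            raise InvalidConfigError("need one covariate series per whale")

    shp = {k: np.asarray(hmm_params[k], dtype=float) for k in
           ("time_shape", "time_rate", "depth_shape", "depth_rate",
            "lunge_rate", "speed_shape", "speed_rate", "mu", "kappa")}

    rows, states_out = [], []
    contexts = rng.choice(K, size=n_whales, p=pi) + 1
    for w in range(n_whales):
        k = contexts[w] - 1
        x = xs[w]
        T = x.size
        s = np.empty(T, dtype=int)
        s[0] = rng.choice(N, p=delta[k])
        for t in range(1, T):
            tpm = _row_tpm(eta[k].copy(), beta[k], x[t])
            s[t] = rng.choice(N, p=tpm[s[t - 1]])
        dive_time = rng.gamma(shp["time_shape"][s], 1.0 / shp["time_rate"][s])
        depth = rng.gamma(shp["depth_shape"][s], 1.0 / shp["depth_rate"][s])
        lunges = rng.poisson(shp["lunge_rate"][s])
        speed = rng.gamma(shp["speed_shape"][s], 1.0 / shp["speed_rate"][s])
        angle = rng.vonmises(shp["mu"][s], shp["kappa"][s])
        rows.append(pd.DataFrame({
            "whale_id": f"sim{w:03d}",
            "dive_time_s": dive_time,
            "max_depth_m": depth,
            "lunges": lunges,
            "speed_ms": speed,
            "turn_angle_rad": angle,
            "covariate": x,
        }))
        states_out.append(s + 1)

    data = pd.concat(rows, ignore_index=True)
    truth = SimTruth(contexts=contexts, states=states_out,
                     params={k: np.asarray(v).tolist() for k, v in hmm_params.items()},
                     seed=seed)
    return data, truth


# ---------------------------------------------------------------------------
# Tag-series rendering
# ---------------------------------------------------------------------------

class ResolutionError(ValueError):
    """Raised when a dive is too short to be represented at the sample rate."""


def render_depth_series(
    dive_sequence: pd.DataFrame,
    sampling_hz: float = 1.0,
    surface_gap_s: float = 60.0,
    dive_shape: str = "U",
    edge_depth_m: float = 3.5,
) -> pd.DataFrame:
    """Render simulated dives into a sampled tag series.

    Each dive becomes a piecewise-linear U- (or V-) shaped depth excursion
    of its stated duration whose sampled maximum matches the stated maximum
    depth; dives are separated by ``surface_gap_s`` of near-zero depth.
    Pitch is negative on descent and positive on ascent, roll is zero, the
    heading channel turns by the dive's turning angle across the dive, and
    the speed channel is flat at the dive's speed over ground.

    Returns a frame with columns ``time_s, depth_m, pitch_rad, roll_rad,
    heading_rad, speed_ms`` sampled at ``sampling_hz``.
    """
    if sampling_hz <= 0:
        raise InvalidConfigError("sampling_hz must be positive")
    dt = 1.0 / sampling_hz
    t_cursor = surface_gap_s
    segs = []  # (start_s, duration_s, max_depth, turn, speed)
    for _, row in dive_sequence.iterrows():
        d = float(row["dive_time_s"])
        if d < 2 * dt:
            raise ResolutionError(f"dive of {d:.2f}s needs >= 2 samples at {sampling_hz} Hz")
        segs.append((t_cursor, d, float(row["max_depth_m"]),
                     float(row.get("turn_angle_rad", 0.0)), float(row.get("speed_ms", 0.0))))
        t_cursor += d + surface_gap_s

    n = int(np.ceil(t_cursor * sampling_hz)) + 1
    time = np.arange(n) * dt
    depth = np.zeros(n)
    pitch = np.zeros(n)
    heading = np.zeros(n)
    speed = np.zeros(n)

    frac_bottom = 0.5 if dive_shape == "U" else 0.0
    for start, dur, mx, turn, spd in segs:
        # sample indices strictly inside (start, start+dur)
        i0 = int(np.floor(start * sampling_hz)) + 1
        i1 = int(np.ceil((start + dur) * sampling_hz)) - 1
        if i1 < i0 + 1:
            i1 = i0 + 1
        tt = (time[i0:i1 + 1] - start) / dur  # in (0, 1)
        ramp = (1 - frac_bottom) / 2
        prof = np.minimum(np.minimum(tt, 1 - tt) / ramp, 1.0)
        z = edge_depth_m + (mx - edge_depth_m) * prof
        # pin the sample nearest the profile peak to the exact max depth
        z[np.argmax(prof)] = mx
        depth[i0:i1 + 1] = z
        mid = i0 + (i1 - i0) // 2
        pitch[i0:mid] = -np.pi / 4
        pitch[mid:i1 + 1] = np.pi / 4
        heading[i0:i1 + 1] = np.linspace(0.0, turn, i1 - i0 + 1)
        speed[i0:i1 + 1] = spd

    return pd.DataFrame({
        "time_s": time, "depth_m": depth, "pitch_rad": pitch,
        "roll_rad": np.zeros(n), "heading_rad": heading, "speed_ms": speed,
    })


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

_CEE_COLS = ["behavioural_state", "cee_type", "subject_id", "cee_date",
             "cee_number", "pre_start", "exposure_start", "exposure_min",
             "post_start", "prey_mapping"]
_SEV_COLS = ["behavioural_state", "cee_type", "subject_id", "cee_date",
             "prey_pre", "prey_post", "csel_db", "change", "confidence",
             "severity_score", "description"]


def load_study_tables() -> FixtureTables:
    """Load and validate the packaged study tables.

    The CEE-metadata table (21 tagged whales, CEE types and phase timings)
    and the expert-severity table (per-CEE change flag, severity score and
    cSEL at the change point or at the exposure maximum).  Validation
    enforces the schema and the published totals; any mismatch raises
    :class:`FixtureCorruptionError`.
    """
    pkg = resources.files("fincee.fixtures")
    cee = pd.read_csv(pkg / "table1_cee.csv", dtype={"pre_start": str,
                                                     "exposure_start": str,
                                                     "post_start": str})
    sev = pd.read_csv(pkg / "table3_severity.csv")

    if list(cee.columns) != _CEE_COLS or list(sev.columns) != _SEV_COLS:
        raise FixtureCorruptionError("fixture schema mismatch")
    if cee["subject_id"].duplicated().any() or sev["subject_id"].duplicated().any():
        raise FixtureCorruptionError("duplicate subject id in fixture")
    if len(cee) != 21 or len(sev) != 21:
        raise FixtureCorruptionError("fixture row counts do not match the study")
    type_counts = cee["cee_type"].value_counts()
    if (type_counts.get("MFAS", 0), type_counts.get("PRN", 0),
            type_counts.get("CONTROL", 0)) != (11, 4, 6):
        raise FixtureCorruptionError("CEE type counts do not match the study")
    responders = sev[sev["change"] == "yes"]
    if len(responders) != 5 or (responders["cee_type"] == "CONTROL").any():
        raise FixtureCorruptionError("responder rows do not match the study")
    return FixtureTables(cee_table=cee, severity_table=sev)


def simulate_response_design(
    n_whales: int = 21,
    dives_per_whale: int = 100,
    effect_per_db: float = 0.0,
    seed: int = 0,
    noise_sd: float = 1.0,
    whale_sd: float = 0.4,
    rl_threshold_db: float = 110.0,
) -> pd.DataFrame:
    """Per-dive design table for the group-level response models.

    Whales cycle through MFAS / PRN / CONTROL treatments.  Each exposed
    whale receives the protocol ping schedule propagated over a slowly
    drifting source range (a lognormal random walk around 1 km), and dives
    are laid out on a regular cycle so each carries max/avg/min received
    level and cumulative SEL covariates.  The response column ``y`` is
    ``effect_per_db * max(maxRL - rl_threshold_db, 0)`` plus whale-level
    and dive-level Gaussian noise — an RL-driven behavioural shift with no
    treatment-type dependence, the qualitative group-level pattern under
    study.  ``effect_per_db = 0`` gives pure noise for null calibration.
    """
    rng = np.random.default_rng(seed)
    states = ("deep-feeding", "shallow-feeding", "non-feeding")
    n_before = int(0.4 * dives_per_whale)
    slot_s = (DEFAULT_PHASE_MINUTES * 60.0) / (0.25 * dives_per_whale)
    rows = []
    for w in range(n_whales):
        ctype = ("MFAS", "PRN", "CONTROL")[w % 3]
        schedule = make_cee_schedule(ctype)
        starts = np.arange(dives_per_whale) * slot_s - n_before * slot_s \
            + schedule.phase_bounds[1]
        if ctype == "CONTROL":
            exposure = None
        else:
            ranges = 1000.0 * np.exp(np.cumsum(
                rng.normal(0.0, 0.05, schedule.n_pings)))
            exposure = received_levels(schedule, ranges_m=ranges)
        cov = exposure_covariates(starts, starts + slot_s, schedule, exposure)
        y = (effect_per_db * np.maximum(cov["max_rl"] - rl_threshold_db, 0.0)
             + rng.normal(0.0, noise_sd, dives_per_whale)
             + rng.normal(0.0, whale_sd))
        rows.append(pd.DataFrame({
            "y": y, "phase": cov["phase"], "cee_type": ctype,
            "behavioural_state": states[w % 3], "whale_id": f"w{w:03d}",
            "max_rl": cov["max_rl"], "avg_rl": cov["avg_rl"],
            "min_rl": cov["min_rl"], "cumulative_sel": cov["cumulative_sel"]}))
    return pd.concat(rows, ignore_index=True)


def truth_to_json(truth: SimTruth) -> str:
    """Serialize simulation truth for a sidecar file."""
    return json.dumps({
        "contexts": truth.contexts.tolist(),
        "states": [s.tolist() for s in truth.states],
        "params": truth.params,
        "seed": truth.seed,
    }, indent=1)
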