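"""Run orchestration: configuration, validation and the demo pipeline.

Ties the stages into one reproducible run: simulate CEE exposure and dive
behaviour, extract per-dive metrics, select a context HMM by AIC, fit the
PCA + additive response models, and fit the severity survival models to
the packaged expert-scoring table.  Every stochastic stage receives a
sub-seed derived deterministically from the master seed, so a config
reproduces its report bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dive_metrics, hmm, pca_gamm, severity, synthetic

__all__ = ["RunConfig", "RunReport", "validate_tables", "run_pipeline"]

logger = logging.getLogger("fincee")


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    seed: int = 1
    output_dir: str = "fincee_out"
    # CEE design
    ping_interval_s: float = synthetic.DEFAULT_PING_INTERVAL_S
    sl_initial_db: float = synthetic.DEFAULT_SL_INITIAL_DB
    sl_max_db: float = synthetic.DEFAULT_SL_MAX_MFAS_DB
    ramp_step_db: float = synthetic.DEFAULT_RAMP_STEP_DB
    phase_minutes: float = synthetic.DEFAULT_PHASE_MINUTES
    range_m: float = 1000.0
    # simulation scale
    n_whales: int = 12
    dives_per_whale: int = 80
    # HMM candidate grid
    n_states: int = 3
    context_grid: tuple[int, ...] = (1, 2)
    covariate: str = "custom"
    n_starts: int = 3
    # survival options
    moderate_implies_low: bool = True
    include_unscored_moderate: bool = True

    def sub_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31 - 1)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["context_grid"] = list(self.context_grid)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if "context_grid" in raw:
            raw["context_grid"] = tuple(raw["context_grid"])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage status and headline outputs of one run."""

    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def report_hash(self) -> str:
        return hashlib.sha256(json.dumps(
            {"config": self.config_hash, "stages": self.stages,
             "outputs": self.outputs}, sort_keys=True, default=str
        ).encode()).hexdigest()[:16]

    def to_json(self) -> str:
        return json.dumps({
            "config_hash": self.config_hash, "version": self.version,
            "stages": self.stages, "outputs": self.outputs,
            "report_hash": self.report_hash()}, indent=1, default=str)


def validate_tables(cee_table: pd.DataFrame, severity_table: pd.DataFrame) -> dict:
    """Schema, uniqueness, cross-table and count checks on the study tables.

    Returns a report dict with a ``passed`` flag and the list of failures;
    an empty table is a hard error.
    """
    if len(cee_table) == 0 or len(severity_table) == 0:
        raise ValueError("empty table")
    failures = []
    for col in ("subject_id", "cee_type", "behavioural_state"):
        for name, tab in (("cee", cee_table), ("severity", severity_table)):
            if col not in tab.columns:
                failures.append(f"{name} table missing column {col}")
    if not failures:
        for name, tab in (("cee", cee_table), ("severity", severity_table)):
            dup = tab["subject_id"][tab["subject_id"].duplicated()]
            if len(dup):
                failures.append(f"{name} table: duplicate subject ids {sorted(set(dup))}")
        if set(cee_table["subject_id"]) != set(severity_table["subject_id"]):
            failures.append("subject ids differ between tables")
        bad_types = set(cee_table["cee_type"]) - {"MFAS", "PRN", "CONTROL"}
        if bad_types:
            failures.append(f"unknown CEE types {bad_types}")
    state_counts = cee_table["behavioural_state"].value_counts().to_dict()
    type_counts = cee_table["cee_type"].value_counts().to_dict()
    return {
        "passed": not failures,
        "failures": failures,
        "n_subjects": int(cee_table["subject_id"].nunique()),
        "state_counts": state_counts,
        "type_counts": type_counts,
        "n_responders": int((severity_table["change"] == "yes").sum())
        if "change" in severity_table else None,
    }


def _simulate_stage(cfg: RunConfig):
    """CEE schedule, received exposure and simulated dive sequences."""
    schedule = synthetic.make_cee_schedule(
        "MFAS", phase_minutes=cfg.phase_minutes, ping_interval_s=cfg.ping_interval_s,
        sl_initial_db=cfg.sl_initial_db, sl_max_db=cfg.sl_max_db,
        ramp_step_db=cfg.ramp_step_db)
    exposure = synthetic.received_levels(schedule, ranges_m=cfg.range_m)

    # lay out nominal per-dive windows (mean dive + surface gap) to derive a
    # per-dive exposure covariate on the model scale
    slot_s = 240.0
    starts = np.arange(cfg.dives_per_whale) * slot_s
    cov = synthetic.exposure_covariates(starts, starts + slot_s, schedule, exposure)
    x = cov["max_rl"].to_numpy()
    exposed = x > 0
    x_std = np.zeros_like(x)
    if exposed.any() and x[exposed].std() > 0:
        x_std[exposed] = (x[exposed] - x[exposed].mean()) / x[exposed].std()
        x_std[exposed] += 1.0  # exposure itself shifts the logits

    params = default_generator_params(cfg.n_states)
    data, truth = synthetic.simulate_dives(
        params, x_std, cfg.n_whales, cfg.dives_per_whale, seed=cfg.sub_seed("simulate"))
    data["max_rl"] = np.tile(x, cfg.n_whales)
    data["phase"] = np.tile(cov["phase"].to_numpy(), cfg.n_whales)
    data["exposure"] = np.tile(cov["exposure"].to_numpy(), cfg.n_whales)
    return schedule, exposure, data, truth


def default_generator_params(n_states: int = 3, k_contexts: int = 2,
                             beta_21: float = 0.0) -> dict:
    """Generator parameters for a three-state diving repertoire.

    State 1 deep feeding (long, deep, many lunges), state 2 non-feeding
    (short shallow dives, no lunges, fast travel), state 3 shallow feeding.
    ``beta_21`` puts an exposure effect on the non-feeding-to-deep-feeding
    transition, the qualitative response pattern of interest.
    """
    if n_states != 3:
        raise ValueError("the default repertoire is three-state")
    eta = np.full((k_contexts, 3, 3), -2.0)
    if k_contexts > 1:
        eta[1] = -1.0
    beta = np.zeros((k_contexts, 3, 3))
    beta[:, 1, 0] = beta_21
    return {
        "time_shape": np.array([20.0, 8.0, 10.0]),
        "time_rate": np.array([20.0 / 420, 8.0 / 120, 10.0 / 240]),
        "depth_shape": np.array([25.0, 6.0, 12.0]),
        "depth_rate": np.array([25.0 / 180, 6.0 / 15, 12.0 / 50]),
        "lunge_rate": np.array([5.0, 0.1, 2.0]),
        "speed_shape": np.array([9.0, 16.0, 9.0]),
        "speed_rate": np.array([9.0 / 1.5, 16.0 / 2.5, 9.0 / 1.8]),
        "mu": np.array([0.0, 0.0, 0.0]),
        "kappa": np.array([0.5, 4.0, 1.0]),
        "eta": eta,
        "beta": beta,
        "delta": np.tile(np.ones(3) / 3, (k_contexts, 1)),
        "pi": np.ones(k_contexts) / k_contexts,
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute simulate -> metrics -> HMM selection -> PCA models -> survival.

    Stage failures are recorded in the report and downstream stages that
    depend on them are skipped; artifacts are written under
    ``config.output_dir``.
    """
    from importlib.metadata import version as _v
    try:
        ver = _v("fincee")
    except Exception:
        ver = "unknown"
    report = RunReport(config_hash=config.config_hash(), version=ver)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("run %s -> %s", report.config_hash, outdir)

    data = None
    try:
        schedule, exposure, data, truth = _simulate_stage(config)
        data.to_csv(outdir / "dives.csv", index=False)
        (outdir / "sim_truth.json").write_text(synthetic.truth_to_json(truth))
        report.stages["simulate"] = "ok"
        report.outputs["n_dives"] = int(len(data))
        report.outputs["n_pings"] = schedule.n_pings
        report.outputs["final_csel_db"] = round(float(exposure.cumulative_sel[-1]), 3)
    except Exception as exc:  # pragma: no cover - defensive
        logger.exception("simulate failed")
        report.stages["simulate"] = f"failed: {exc}"

    if data is not None:
        try:
            one = data[data["whale_id"] == data["whale_id"].iloc[0]]
            series = synthetic.render_depth_series(one.head(20))
            dives = dive_metrics.segment_dives(series)
            mt = dive_metrics.metrics_table(series, dives)
            rec = dive_metrics.attach_exposure(mt, exposure, schedule)
            rec.to_csv(outdir / "dive_metrics.csv", index=False)
            report.stages["metrics"] = "ok"
            report.outputs["n_segmented_dives"] = len(dives)
        except Exception as exc:
            logger.exception("metrics failed")
            report.stages["metrics"] = f"failed: {exc}"

        try:
            specs = [hmm.HMMSpec(n_states=config.n_states, n_contexts=k,
                                 covariate=config.covariate)
                     for k in config.context_grid]
            fits = hmm.select_model(data, specs, n_starts=config.n_starts,
                                    seed=config.sub_seed("hmm"))
            best = fits[0]
            (outdir / "hmm_fit.json").write_text(hmm.fit_to_json(best))
            dec = hmm.local_decode(best, data)
            pd.concat([data.reset_index(drop=True), dec.state_posterior,
                       dec.states], axis=1).to_csv(outdir / "dives_decoded.csv",
                                                   index=False)
            report.stages["hmm"] = "ok"
            report.outputs["selected_K"] = best.spec.n_contexts
            report.outputs["hmm_aic"] = round(best.aic, 3)
            report.outputs["aic_by_K"] = {f.spec.n_contexts: round(f.aic, 3)
                                          for f in fits}
        except Exception as exc:
            logger.exception("hmm failed")
            report.stages["hmm"] = f"failed: {exc}"

        try:
            mtab = data.rename(columns={
                "dive_time_s": "c1_dive_time_s", "max_depth_m": "c1_max_depth_m",
                "lunges": "c1_lunges", "speed_ms": "c1_speed_ms"})
            pca = pca_gamm.run_pca(mtab, category="dive")
            axes = pca_gamm.select_components(pca)
            design = pd.DataFrame({
                "phase": data["phase"], "cee_type": "MFAS",
                "behavioural_state": "deep-feeding", "whale_id": data["whale_id"],
                "max_rl": data["max_rl"], "avg_rl": data["max_rl"],
                "cumulative_sel": data["max_rl"].cummax()})
            fitr = pca_gamm.fit_response_model(
                pca.scores[axes[0]].to_numpy(), design.loc[pca.scores.index],
                "phase_model", axis=axes[0])
            pca.loadings.to_csv(outdir / "pca_loadings.csv")
            report.stages["pca_gamm"] = "ok"
            report.outputs["retained_axes"] = axes
            report.outputs["variance_fractions"] = [round(float(v), 4)
                                                    for v in pca.variance_fraction]
            report.outputs["rl_smooth_p"] = round(fitr.smooth_pvalues["max_rl"], 5)
        except Exception as exc:
            logger.exception("pca_gamm failed")
            report.stages["pca_gamm"] = f"failed: {exc}"

    try:
        tables = synthetic.load_study_tables()
        val = validate_tables(tables.cee_table, tables.severity_table)
        events = severity.build_event_table(
            tables.severity_table,
            moderate_implies_low=config.moderate_implies_low,
            include_unscored_moderate=config.include_unscored_moderate)
        events.to_csv(outdir / "severity_events.csv", index=False)
        null_fit = severity.fit_hazards(events, None)
        sig_fit = severity.fit_hazards(events, ["signal_type"])
        pht = severity.ph_test(sig_fit)
        curves = severity.response_function(
            sig_fit, events, pd.DataFrame({"signal_type": ["MFAS", "PRN"]}))
        for key, cur in curves.items():
            name = "curve_" + "_".join(str(k) for k in key) + ".csv"
            cur.to_csv(outdir / name, index=False)
        report.stages["severity"] = "ok"
        report.outputs["tables_valid"] = val["passed"]
        report.outputs["n_event_rows"] = int(len(events))
        report.outputs["n_events"] = int(events["event"].sum())
        report.outputs["aic_null"] = round(null_fit.aic, 4)
        report.outputs["aic_signal"] = round(sig_fit.aic, 4)
        report.outputs["delta_aic"] = round(abs(null_fit.aic - sig_fit.aic), 4)
        report.outputs["ph_global_p"] = round(pht.global_p, 4)
    except Exception as exc:
        logger.exception("severity failed")
        report.stages["severity"] = f"failed: {exc}"

    (outdir / "report.json").write_text(report.to_json())
    return report
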