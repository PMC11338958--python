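"""End-to-end orchestration: simulation -> behavior -> model fits -> report.

The group analysis mirrors the staged procedure the library modules
implement:

1. grand-average rating probabilities (per-participant probability vectors
   averaged) determine (mu_signal, sigma_signal);
2. five decision criteria are fitted per participant;
3. raw predicted amplitude profiles (truncated-distribution means) are
   averaged across participants, then shifted so the noise-class rating-1
   amplitude maps to 0 and scaled by the post-shift signal-class rating-1
   amplitude (A_H1);
4. measured per-rating amplitudes are aggregated and normalized the same
   way, and R^2 quantifies the agreement;
5. the bimodal (bifurcation) and threshold competitor models re-use the same
   machinery.

``run_pipeline`` drives all stages off one config dict and writes every
artifact plus a checksummed manifest; results are a pure function of the
config (including its seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavioral, model_variants, pupil, sdt_core, simulate, waveforms

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": True,
    "trials_path": None,
    "out_dir": "results/pipeline",
    "simulation": {},
    "dichotomization_cut": 3,
    "threshold_rating": 3,
    "n_permutations": 1000,
    "pupil_participants": 2,
    "pupil_trials_per_participant": 40,
}


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def load_config(overrides: dict | None = None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for key, value in (overrides or {}).items():
        if key not in cfg:
            raise PipelineError("config", f"unknown config key {key!r}")
        if isinstance(cfg[key], dict) and isinstance(value, dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    sim_keys = {f.name for f in fields(simulate.SimulationConfig)}
    unknown = set(cfg["simulation"]) - sim_keys
    if unknown:
        raise PipelineError("config", f"unknown simulation keys {sorted(unknown)}")
    return cfg


# ---------------------------------------------------------------------------
# analysis building blocks
# ---------------------------------------------------------------------------

def grand_probabilities(trials: pd.DataFrame
                        ) -> tuple[sdt_core.RatingProbabilities,
                                   sdt_core.RatingProbabilities]:
    """Grand-average rating probabilities (per-participant vectors averaged)."""
    counts = behavioral.rating_counts(trials)
    out = {}
    for cls in ("signal", "noise"):
        sub = counts[counts["class"] == cls]
        if sub.empty:
            raise ValueError(f"no {cls}-class trials")
        mat = sub[[f"n_r{r}" for r in range(1, 7)]].to_numpy(dtype=float)
        probs = (mat / mat.sum(axis=1, keepdims=True)).mean(axis=0)
        out[cls] = sdt_core.RatingProbabilities(cls, probs / probs.sum(),
                                                n_trials=int(mat.sum()))
    return out["signal"], out["noise"]


def measured_group_profiles(trials: pd.DataFrame
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Group-mean measured amplitude per rating for (noise, signal) classes.

    Per participant the mean amplitude of each rating x class cell is taken;
    cells are then averaged across participants (ignoring participants
    without trials in a cell).  Returns (noise 6-vector, signal 6-vector);
    empty cells are NaN.
    """
    if "amplitude" not in trials.columns:
        raise ValueError("trials lack an 'amplitude' column")
    cell = (trials.groupby(["participant_id", "condition", "rating"])["amplitude"]
            .mean().reset_index())
    out = {}
    for cond, cls in (("absent", "noise"), ("signal", "signal")):
        sub = cell[cell["condition"] == cond]
        vec = np.full(6, np.nan)
        for r in range(1, 7):
            vals = sub.loc[sub["rating"] == r, "amplitude"]
            if len(vals):
                vec[r - 1] = float(vals.mean())
        out[cls] = vec
    return out["noise"], out["signal"]


def _normalize_group(noise_vals: np.ndarray, signal_vals: np.ndarray,
                     divisor: float | None = None
                     ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Shift by the noise rating-1 value, scale by post-shift signal rating 1.

    An explicit ``divisor`` (in post-shift units) overrides the A_H1 anchor;
    competitor models are scaled by the primary fit's divisor because their
    own rating-1 anchor can sit arbitrarily close to the noise level.
    """
    shift = float(noise_vals[0])
    if divisor is None:
        divisor = float(signal_vals[0] - shift)
    if not np.isfinite(divisor) or divisor <= 0:
        raise sdt_core.NormalizationError(
            f"group normalization divisor {divisor} must be positive")
    return ((noise_vals - shift) / divisor, (signal_vals - shift) / divisor,
            shift, divisor)


def analyze_rating_experiment(trials: pd.DataFrame) -> sdt_core.FitReport:
    """Full unequal-variance analysis of a rating experiment with amplitudes."""
    grand_signal, grand_noise = grand_probabilities(trials)
    model = sdt_core.fit_signal_distribution(grand_signal, grand_noise)
    counts = behavioral.rating_counts(trials)
    pred_noise, pred_signal, criteria = [], [], {}
    for pid in sorted(trials["participant_id"].unique()):
        sub = counts[counts["participant_id"] == pid]
        probs = {}
        for cls in ("signal", "noise"):
            row = sub[sub["class"] == cls]
            if row.empty:
                continue
            probs[cls] = sdt_core.RatingProbabilities.from_counts(
                cls, row[[f"n_r{r}" for r in range(1, 7)]].to_numpy()[0])
        if len(probs) < 2:
            continue
        cs = sdt_core.fit_participant_criteria(probs["signal"], probs["noise"],
                                               model)
        criteria[int(pid)] = cs
        pred_noise.append(sdt_core.predicted_amplitudes(model, cs, "noise").values)
        pred_signal.append(sdt_core.predicted_amplitudes(model, cs, "signal").values)
    pn = np.vstack(pred_noise).mean(axis=0)
    ps = np.vstack(pred_signal).mean(axis=0)
    pn_n, ps_n, p_shift, p_div = _normalize_group(pn, ps)
    meas_noise, meas_signal = measured_group_profiles(trials)
    mn_n, ms_n, m_shift, m_div = _normalize_group(meas_noise, meas_signal)
    pred_cat = np.concatenate([pn_n, ps_n])
    meas_cat = np.concatenate([mn_n, ms_n])
    usable = np.isfinite(meas_cat)
    r2 = sdt_core.goodness_of_fit(pred_cat[usable], meas_cat[usable])
    return sdt_core.FitReport(
        model_name="unequal_variance_sdt",
        parameters={"mu_signal": model.mu_signal,
                    "sigma_signal": model.sigma_signal,
                    "mu_noise": model.mu_noise, "sigma_noise": model.sigma_noise,
                    "delta_mu_over_delta_sigma": model.delta_ratio,
                    "shift": p_shift, "scale": p_div},
        criteria=criteria,
        predicted={"noise": pn_n, "signal": ps_n},
        measured={"noise": mn_n, "signal": ms_n,
                  "shift": m_shift, "scale": m_div},
        r_squared=float(r2))


def analyze_bimodal(trials: pd.DataFrame, cut: int = 3,
                    scale: float | None = None) -> sdt_core.FitReport:
    """Bifurcation-model analysis: beta from the dichotomized hit rate.

    ``scale`` (post-shift evidence units) normalizes the predicted profiles;
    by default the model's own post-shift signal rating-1 amplitude is used,
    but when comparing against the unimodal fit the caller should pass that
    fit's divisor so both predictions share a scale.
    """
    grand_signal, grand_noise = grand_probabilities(trials)
    per = behavioral.summaries_by_participant(trials, cut=cut)
    beta = model_variants.beta_from_hit_rate(float(per["hit_rate"].mean()))
    bimodal = model_variants.fit_bimodal_model(grand_signal, grand_noise, beta)
    # the mixture shares the noise component N(0, 1)
    base = sdt_core.GaussianSdtModel(mu_signal=max(bimodal.mu_high, 1e-6),
                                     sigma_signal=1.0)
    counts = behavioral.rating_counts(trials)
    pred_noise, pred_signal, criteria = [], [], {}
    for pid in sorted(trials["participant_id"].unique()):
        sub = counts[counts["participant_id"] == pid]
        probs = {}
        for cls in ("signal", "noise"):
            row = sub[sub["class"] == cls]
            if row.empty:
                continue
            probs[cls] = sdt_core.RatingProbabilities.from_counts(
                cls, row[[f"n_r{r}" for r in range(1, 7)]].to_numpy()[0])
        if len(probs) < 2:
            continue
        cs = sdt_core.fit_participant_criteria(probs["signal"], probs["noise"],
                                               base, signal_sf=bimodal.sf)
        criteria[int(pid)] = cs
        pred_noise.append(sdt_core.predicted_amplitudes(base, cs, "noise").values)
        pred_signal.append(
            model_variants.bimodal_predicted_amplitudes(bimodal, cs).values)
    pn = np.vstack(pred_noise).mean(axis=0)
    ps = np.vstack(pred_signal).mean(axis=0)
    pn_n, ps_n, p_shift, p_div = _normalize_group(pn, ps, divisor=scale)
    meas_noise, meas_signal = measured_group_profiles(trials)
    mn_n, ms_n, _, _ = _normalize_group(meas_noise, meas_signal)
    pred_cat = np.concatenate([pn_n, ps_n])
    meas_cat = np.concatenate([mn_n, ms_n])
    usable = np.isfinite(meas_cat)
    r2 = sdt_core.goodness_of_fit(pred_cat[usable], meas_cat[usable])
    return sdt_core.FitReport(
        model_name="bimodal_bifurcation",
        parameters={"beta": beta, "mu_high": bimodal.mu_high,
                    "mu_low": bimodal.mu_low,
                    "sigma_common": bimodal.sigma_common,
                    "shift": p_shift, "scale": p_div},
        criteria=criteria,
        predicted={"noise": pn_n, "signal": ps_n},
        measured={"noise": mn_n, "signal": ms_n},
        r_squared=float(r2))


def analyze_threshold(sdt_report: sdt_core.FitReport,
                      threshold_rating: int = 3) -> sdt_core.FitReport:
    """Threshold-model analysis derived from the fitted unequal-variance model."""
    params = sdt_report.parameters
    model = sdt_core.GaussianSdtModel(params["mu_signal"], params["sigma_signal"])
    tm = model_variants.ThresholdModel(base=model,
                                       threshold_rating=threshold_rating)
    profile = sdt_core.AmplitudeProfile(
        class_label="signal", values=np.asarray(sdt_report.predicted["signal"]),
        state="shifted_and_scaled")
    zeroed = model_variants.threshold_amplitudes(profile, tm)
    pred_cat = np.concatenate([np.asarray(sdt_report.predicted["noise"]),
                               zeroed.values])
    meas_cat = np.concatenate([np.asarray(sdt_report.measured["noise"]),
                               np.asarray(sdt_report.measured["signal"])])
    usable = np.isfinite(meas_cat)
    r2 = sdt_core.goodness_of_fit(pred_cat[usable], meas_cat[usable])
    return sdt_core.FitReport(
        model_name="threshold",
        parameters={**{k: params[k] for k in
                       ("mu_signal", "sigma_signal", "mu_noise", "sigma_noise")},
                    "threshold_rating": threshold_rating},
        criteria={},
        predicted={"noise": np.asarray(sdt_report.predicted["noise"]),
                   "signal": zeroed.values},
        measured=sdt_report.measured,
        r_squared=float(r2))


def compare_models(trials: pd.DataFrame, cut: int = 3,
                   threshold_rating: int = 3) -> dict:
    """Fit all three models and quantify signal-distribution similarity."""
    sdt_report = analyze_rating_experiment(trials)
    bi_report = analyze_bimodal(trials, cut=cut,
                                scale=sdt_report.parameters["scale"])
    th_report = analyze_threshold(sdt_report, threshold_rating)
    model = sdt_core.GaussianSdtModel(sdt_report.parameters["mu_signal"],
                                      sdt_report.parameters["sigma_signal"])
    bimodal = model_variants.BimodalSignalModel(
        beta=bi_report.parameters["beta"],
        mu_high=bi_report.parameters["mu_high"])
    grid = np.linspace(-4.0, model.mu_signal + 4 * model.sigma_signal, 400)
    similarity = model_variants.distribution_similarity(
        lambda x: model.density(x, "signal"), bimodal, grid)
    return {"sdt": sdt_report, "bimodal": bi_report, "threshold": th_report,
            "signal_distribution_similarity_r": float(similarity)}


# ---------------------------------------------------------------------------
# pipeline stages and orchestration
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, sdt_core.CriterionSet):
            return o.criteria.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=_default, allow_nan=True) + "\n")


def run_pipeline(config: dict | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Run every stage and return the artifact manifest."""
    cfg = load_config(config)
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    written: list[Path] = []
    manifest = {"seed": seed, "config": {k: v for k, v in cfg.items()},
                "files": {}}

    def emit(name: str):
        p = out / name
        written.append(p)
        return p

    # --- simulate / load ---------------------------------------------------
    try:
        sim_cfg = simulate.SimulationConfig(**cfg["simulation"])
        if cfg["simulate"]:
            trials, truth = simulate.simulate_rating_experiment(sim_cfg, seed)
            trials = simulate.simulate_trial_amplitudes(
                trials, sim_cfg.amplitude_noise_sd, seed)
            trials.to_csv(emit("trials.csv"), index=False)
            _write_json({"mu_signal": sim_cfg.mu_signal,
                         "sigma_signal": sim_cfg.sigma_signal,
                         "group_criteria": list(sim_cfg.criteria),
                         "seed": seed}, emit("ground_truth.json"))
        else:
            if not cfg["trials_path"] or not Path(cfg["trials_path"]).exists():
                raise PipelineError("simulate",
                                    "simulate=false but trials_path is missing")
            trials = pd.read_csv(cfg["trials_path"])
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", str(exc)) from exc

    cut = int(cfg["dichotomization_cut"])

    # --- behavior ----------------------------------------------------------
    try:
        summaries = behavioral.summaries_by_participant(trials, cut=cut)
        summaries.to_csv(emit("behavior_summaries.csv"), index=False)
        pv = behavioral.predictive_values(trials)
        pv.to_csv(emit("predictive_values.csv"), index=False)
        quintiles, qtable = behavioral.pupil_quintile_rates(trials, cut=cut)
        qtable.to_csv(emit("pupil_quintiles.csv"), index=False)
        split, stable = behavioral.chronological_split_rates(trials, cut=cut)
        stable.to_csv(emit("chronological_split.csv"), index=False)
        qmat = qtable.pivot(index="participant_id", columns="bin",
                            values="rate").to_numpy()
        qcontrast = waveforms.polynomial_contrast_test(qmat)
        _write_json({
            "group": {"hit_rate": float(summaries["hit_rate"].mean()),
                      "fa_rate": float(summaries["fa_rate"].mean()),
                      "criterion_c": float(summaries["criterion_c"].mean()),
                      "d_prime": float(summaries["d_prime"].mean())},
            "quintile_rates": quintiles,
            "quintile_contrast": {"linear_f": qcontrast.linear_f,
                                  "linear_p": qcontrast.linear_p,
                                  "quadratic_f": qcontrast.quadratic_f,
                                  "quadratic_p": qcontrast.quadratic_p},
            "chronological_rates": split}, emit("behavior_group.json"))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("behavior", str(exc)) from exc

    # --- model fits --------------------------------------------------------
    try:
        comparison = compare_models(trials, cut=cut,
                                    threshold_rating=int(cfg["threshold_rating"]))
        _write_json(comparison["sdt"].to_dict(), emit("fit_sdt.json"))
        _write_json({name: comparison[name].to_dict()
                     for name in ("sdt", "bimodal", "threshold")}
                    | {"signal_distribution_similarity_r":
                       comparison["signal_distribution_similarity_r"]},
                    emit("model_comparison.json"))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fit", str(exc)) from exc

    # --- pupil -------------------------------------------------------------
    try:
        k = int(cfg["pupil_participants"])
        n_tr = int(cfg["pupil_trials_per_participant"])
        subset = trials[trials["trial_index"] < n_tr]
        keep = sorted(trials["participant_id"].unique())[:k]
        traces = simulate.simulate_pupil_traces(
            subset[subset["participant_id"].isin(keep)], sim_cfg, seed,
            participants=set(keep))
        rows = []
        for pid, trace in traces.items():
            clean, mask = pupil.interpolate_blinks(trace)
            epochs = pupil.preprocess_and_epoch(clean, mask)
            sub = subset[subset["participant_id"] == pid].sort_values("trial_index")
            for ep, (_, trial) in zip(epochs, sub.iterrows()):
                if ep.rejected:
                    continue
                deriv = pupil.pdr_derivative(ep, subtract_baseline=True)
                win = (deriv.times_ms >= 500) & (deriv.times_ms <= 1000)
                rows.append({"participant_id": pid,
                             "rating": int(trial["rating"]),
                             "condition": trial["condition"],
                             "pdr_deriv_mean": float(deriv.samples[win].mean())})
        pdr = pd.DataFrame(rows)
        pdr.to_csv(emit("pupil_pdr_window_means.csv"), index=False)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("pupil", str(exc)) from exc

    # --- waveform statistics ----------------------------------------------
    try:
        wsets = simulate.simulate_group_waveforms(trials, sim_cfg, seed)
        nperm = int(cfg["n_permutations"])
        stats_out, amps = {}, []
        for name, ws in sorted(wsets.items()):
            res = waveforms.cluster_permutation_test(
                ws, None, window_ms=waveforms.WINDOWS_MS["AC"],
                n_permutations=nperm, seed=seed)
            stats_out[name] = {"clusters": res.clusters,
                               "n_permutations": res.n_permutations}
            amps.append(waveforms.window_mean(ws, waveforms.WINDOWS_MS["AC"]))
        amp_matrix = np.column_stack(amps)
        contrast = waveforms.polynomial_contrast_test(amp_matrix)
        anova = waveforms.rm_anova_oneway(amp_matrix)
        _write_json({"cluster_tests": stats_out,
                     "window_mean_by_rating": amp_matrix.mean(axis=0),
                     "contrast": {"linear_f": contrast.linear_f,
                                  "linear_p": contrast.linear_p,
                                  "quadratic_f": contrast.quadratic_f,
                                  "quadratic_p": contrast.quadratic_p},
                     "rm_anova": anova}, emit("waveform_stats.json"))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("waveforms", str(exc)) from exc

    # --- report ------------------------------------------------------------
    try:
        report = write_report(comparison, json.loads((out / "behavior_group.json")
                                                     .read_text()))
        emit("report.md").write_text(report)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("report", str(exc)) from exc

    for p in written:
        manifest["files"][p.name] = _sha256(p)
    _write_json(manifest, out / "manifest.json")
    return manifest


def write_report(comparison: dict, behavior_group: dict) -> str:
    """Human-readable markdown summary of the fits and behavioral results."""
    lines = ["# Graded-perception analysis report", ""]
    warnings_count = 0
    g = behavior_group.get("group", {})
    if g:
        lines += ["## Behavior",
                  f"- dichotomized hit rate: {g['hit_rate']:.3f}",
                  f"- false-alarm rate: {g['fa_rate']:.3f}",
                  f"- criterion c: {g['criterion_c']:.3f}",
                  f"- d': {g['d_prime']:.3f}", ""]
    else:
        lines += ["## Behavior", "- WARNING: behavioral table empty", ""]
        warnings_count += 1
    lines.append("## Model comparison")
    for name in ("sdt", "bimodal", "threshold"):
        rep = comparison.get(name)
        if rep is None:
            lines.append(f"- {name}: WARNING missing fit")
            warnings_count += 1
            continue
        pars = ", ".join(f"{k}={v:.3f}" for k, v in rep.parameters.items()
                         if isinstance(v, (int, float)) and np.isfinite(v))
        lines.append(f"- {rep.model_name}: R^2 = {rep.r_squared:.3f} ({pars})")
    sim = comparison.get("signal_distribution_similarity_r")
    if sim is not None:
        lines.append(f"- signal-distribution similarity (SDT vs bimodal): "
                     f"Pearson r = {sim:.3f}")
    qc = behavior_group.get("quintile_contrast")
    if qc:
        lines += ["", "## Baseline-pupil quintile contrast",
                  f"- linear F = {qc['linear_f']:.2f} (p = {qc['linear_p']:.3g})",
                  f"- quadratic F = {qc['quadratic_f']:.2f} "
                  f"(p = {qc['quadratic_p']:.3g})"]
    lines += ["", f"warnings: {warnings_count}", ""]
    return "\n".join(lines)
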