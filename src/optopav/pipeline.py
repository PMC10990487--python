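"""End-to-end pipeline: simulate a cohort, preprocess, analyze, test.

``run_pipeline`` composes the full workflow for a synthetic cohort:

1. *Learning*: each subject runs 10 training sessions; per-trial cue AUCs
   (0–1.5 s) feed a subject x session x cue learning curve and a two-way
   repeated-measures ANOVA (session, cue, interaction).
2. *Omission*: each subject runs an omission session (20 laser / 10 omission
   / 30 non-laser); the mean omission-window AUC per subject feeds a
   one-sample t test against 0.
3. *Kinetics*: stimulation-trial mean traces from two region presets are
   differentiated; zero-crossing point A is compared between regions with an
   unpaired t test.
4. *Terminal stimulation*: stimulation-only sessions under drug conditions
   (vehicle / D1 antagonist / D2 antagonist) give per-subject AUCs (0–5 s)
   for a one-way RM ANOVA with Tukey post-hoc, plus a freely-moving vs
   anesthetized paired t test on 0–20 s AUCs.

All randomness descends from a single integer seed; outputs embed the seed
and a hash of the configuration so every analyzed value can be traced back
to the generator manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as opio
from . import kinetics as kin
from . import perievent as pe
from . import stats as st
from .errors import ConfigError, OptoPavError
from .preprocess import preprocess
from .simulate import (REGION_PRESETS, GroundTruth, KernelParams,
                       simulate_traces)
from .task import (LASER_PAIRED, NON_LASER, OMISSION, TaskConfig,
                   generate_schedule)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the synthetic cohort and its analysis.

    ``region`` selects the kernel preset for the learning/omission phases;
    ``kinetics_regions`` the two presets compared by zero-crossing analysis;
    ``terminal_region`` the preset (slow calcium indicator by default) for
    the terminal-stimulation pharmacology phase.  Windows are seconds
    relative to the alignment event.
    """

    seed: int = 0
    n_subjects: int = 4
    n_sessions: int = 10
    fs: float = 50.0
    region: str = "NAc_dopamine"
    lowpass_hz: Optional[float] = 12.0
    subject_scale_sd: float = 0.1
    task: TaskConfig = field(default_factory=TaskConfig)
    truth: GroundTruth = field(default_factory=GroundTruth)
    align_window_s: tuple[float, float] = (-5.0, 10.0)
    baseline_window_s: tuple[float, float] = (-2.0, 0.0)
    cue_auc_window_s: tuple[float, float] = (0.0, 1.5)
    omission_window_s: tuple[float, float] = (0.0, 2.0)
    smoothing_window_s: float = 0.5
    kinetics_regions: tuple[str, str] = ("LH_dopamine", "NAc_dopamine")
    terminal_region: str = "LH_orexin"
    conditions: tuple[str, ...] = ("vehicle", "SCH23390", "raclopride")
    n_terminal_trials: int = 10
    n_subjects_anesthesia: int = 3
    terminal_auc_window_s: tuple[float, float] = (0.0, 5.0)
    terminal_long_window_s: tuple[float, float] = (0.0, 20.0)

    def __post_init__(self) -> None:
        for name in ("align_window_s", "cue_auc_window_s", "omission_window_s",
                     "terminal_auc_window_s", "terminal_long_window_s"):
            lo, hi = getattr(self, name)
            if hi <= lo:
                raise ConfigError(f"{name}: require lo < hi, got ({lo}, {hi})")
        if self.smoothing_window_s <= 0:
            raise ConfigError("smoothing_window_s must be > 0")
        for r in (self.region, self.terminal_region, *self.kinetics_regions):
            if r not in REGION_PRESETS:
                raise ConfigError(f"unknown region preset {r!r}; "
                                  f"known: {sorted(REGION_PRESETS)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["truth"] = self.truth.to_dict()
        return _jsonable(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "task" in d and isinstance(d["task"], dict):
            d["task"] = TaskConfig(**d["task"])
        if "truth" in d and isinstance(d["truth"], dict):
            t = dict(d["truth"])
            if "motion_band_hz" in t:
                t["motion_band_hz"] = tuple(t["motion_band_hz"])
            d["truth"] = GroundTruth(**t)
        for key, val in d.items():
            if isinstance(val, list):
                d[key] = tuple(val)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(opio.read_yaml(path))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def _subject_truths(config: PipelineConfig,
                    n_subjects: Optional[int] = None) -> list[GroundTruth]:
    """Per-subject ground truths with lognormal response-amplitude variability."""
    n = n_subjects if n_subjects is not None else config.n_subjects
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 901]))
    sd = config.subject_scale_sd
    scales = (np.exp(rng.normal(0.0, sd, size=n)) if sd > 0 else np.ones(n))
    return [config.truth.scaled(float(s)) for s in scales]


def _session_seed(config: PipelineConfig, *tags: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([config.seed, *tags])


def _simulate_session(config: PipelineConfig, task: TaskConfig,
                      kernel: KernelParams, truth: GroundTruth,
                      session_index: int, tags: Sequence[int],
                      condition: str = "vehicle"):
    ss = _session_seed(config, *tags)
    sched_seed, trace_seed = (int(s) for s in ss.generate_state(2) >> np.uint32(1))
    schedule = generate_schedule(task, seed=sched_seed, session_index=session_index)
    trace, manifest = simulate_traces(schedule, kernel, truth, fs=config.fs,
                                      seed=trace_seed, condition=condition)
    dff = preprocess(trace, lowpass_hz=config.lowpass_hz)
    return schedule, dff, manifest


# --------------------------------------------------------------------------
# Phases (each usable on its own; run_pipeline composes them)


def learning_phase(config: PipelineConfig,
                   truths: Optional[list[GroundTruth]] = None,
                   collect_manifests: Optional[list] = None) -> dict:
    """Training sessions -> per-trial AUC table, learning curve, two-way RM ANOVA."""
    truths = truths if truths is not None else _subject_truths(config)
    kernel = REGION_PRESETS[config.region]
    task = config.task.with_(omission_mode=False)
    rows = []
    for subj, truth in enumerate(truths, start=1):
        for session in range(1, config.n_sessions + 1):
            schedule, dff, manifest = _simulate_session(
                config, task, kernel, truth, session, tags=(1, subj, session))
            if collect_manifests is not None:
                collect_manifests.append(manifest)
            for ttype in (LASER_PAIRED, NON_LASER):
                tensor = pe.align(dff, schedule, pe.CUE_ONSET,
                                  window_s=config.align_window_s,
                                  baseline_window_s=config.baseline_window_s,
                                  trial_types=[ttype])
                rows.append(pe.make_auc_table(tensor, config.cue_auc_window_s,
                                              subject=f"m{subj}", session=session,
                                              trial_type=ttype))
    auc_table = pd.concat(rows, ignore_index=True)
    curve = pe.session_curve(auc_table)
    anova = st.two_way_rm_anova(curve, factor_a="session", factor_b="trial_type")
    return {"auc_table": auc_table, "learning_curve": curve, "anova": anova}


def omission_phase(config: PipelineConfig,
                   truths: Optional[list[GroundTruth]] = None,
                   collect_manifests: Optional[list] = None) -> dict:
    """Omission session per subject -> subject AUCs and a one-sample t test."""
    truths = truths if truths is not None else _subject_truths(config)
    kernel = REGION_PRESETS[config.region]
    task = config.task.with_(omission_mode=True)
    session_index = config.n_sessions + 1
    subject_aucs = {}
    tensors = {}
    for subj, truth in enumerate(truths, start=1):
        schedule, dff, manifest = _simulate_session(
            config, task, kernel, truth, session_index, tags=(2, subj))
        if collect_manifests is not None:
            collect_manifests.append(manifest)
        tensor = pe.align(dff, schedule, pe.OMISSION_EXPECTED_LASER,
                          window_s=config.align_window_s,
                          baseline_window_s=config.baseline_window_s)
        tensors[f"m{subj}"] = tensor
        subject_aucs[f"m{subj}"] = pe.omission_auc(tensor, config.omission_window_s)
    ttest = st.one_sample_t(list(subject_aucs.values()), mu0=0.0)
    return {"subject_aucs": subject_aucs, "ttest": ttest, "tensors": tensors}


def kinetics_phase(config: PipelineConfig,
                   truths: Optional[list[GroundTruth]] = None) -> dict:
    """Stimulation-trial kinetics in two region presets -> zero-crossing table + t test."""
    truths = truths if truths is not None else _subject_truths(config)
    task = config.task.with_(omission_mode=True)
    session_index = config.n_sessions + 1
    rows = []
    crossings: dict[str, list[kin.ZeroCrossingResult]] = {}
    for rtag, region in enumerate(config.kinetics_regions):
        kernel = REGION_PRESETS[region]
        crossings[region] = []
        for subj, truth in enumerate(truths, start=1):
            schedule, dff, _ = _simulate_session(
                config, task, kernel, truth, session_index, tags=(3, rtag, subj))
            tensor = pe.align(dff, schedule, pe.LASER_ONSET,
                              window_s=config.align_window_s,
                              baseline_window_s=config.baseline_window_s)
            deriv = kin.derivative(tensor.mean_trace(), fs=config.fs,
                                   smoothing_window_s=config.smoothing_window_s)
            res = kin.find_zero_crossings(deriv, tensor.rel_t, t_ref=0.0,
                                          reference_label=pe.LASER_ONSET,
                                          smoothing_window_s=config.smoothing_window_s)
            crossings[region].append(res)
            rows.append({"subject": f"m{subj}", "region": region,
                         "alignment": pe.LASER_ONSET,
                         "point_a_s": res.point_a_s, "point_b_s": res.point_b_s})
    table = pd.DataFrame(rows)
    r1, r2 = config.kinetics_regions
    ttest = kin.compare_regions(crossings[r1], crossings[r2], point="point_a_s")
    return {"table": table, "crossings": crossings, "ttest": ttest}


def terminal_phase(config: PipelineConfig,
                   truths: Optional[list[GroundTruth]] = None) -> dict:
    """Terminal-stimulation pharmacology: condition AUCs, RM ANOVA + Tukey, paired t."""
    truths = truths if truths is not None else _subject_truths(config)
    kernel = REGION_PRESETS[config.terminal_region]
    # Stimulation-only sessions: the laser train (5 s at 20 Hz under the
    # default task timing) is delivered without any predictive cue learning.
    stim_task = config.task.with_(
        omission_mode=False, n_laser_trials=config.n_terminal_trials,
        n_nonlaser_trials=0)
    no_cue = dataclasses.replace

    def stim_truth(truth: GroundTruth) -> GroundTruth:
        return no_cue(truth, a_max=0.0, nonlaser_amplitude=0.0)

    def subject_auc(subj: int, truth: GroundTruth, condition: str, tag: int,
                    window: tuple[float, float]) -> float:
        schedule, dff, _ = _simulate_session(
            config, stim_task, kernel, stim_truth(truth), 1,
            tags=(4, tag, subj), condition=condition)
        tensor = pe.align(dff, schedule, pe.LASER_ONSET,
                          window_s=(config.align_window_s[0],
                                    max(config.align_window_s[1], window[1] + 1)),
                          baseline_window_s=config.baseline_window_s)
        return float(pe.trial_auc(tensor, window).mean())

    rows = []
    for ctag, condition in enumerate(config.conditions):
        for subj, truth in enumerate(truths, start=1):
            rows.append({"subject": f"m{subj}", "condition": condition,
                         "auc": subject_auc(subj, truth, condition, ctag,
                                            config.terminal_auc_window_s)})
    cond_table = pd.DataFrame(rows)
    anova = st.one_way_rm_anova_with_tukey(cond_table)

    n_an = min(config.n_subjects_anesthesia, len(truths))
    moving, anesth = [], []
    for subj, truth in enumerate(truths[:n_an], start=1):
        moving.append(subject_auc(subj, truth, "freely_moving", 90,
                                  config.terminal_long_window_s))
        anesth.append(subject_auc(subj, truth, "anesthetized", 91,
                                  config.terminal_long_window_s))
    paired = st.paired_t(moving, anesth)
    return {"condition_table": cond_table, "anova": anova,
            "anesthesia": {"freely_moving": moving, "anesthetized": anesth},
            "paired_t": paired}


# --------------------------------------------------------------------------
# Driver


def _write_csv(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all four phases and write the result bundle to ``outdir``.

    Writes ``auc_table.csv``, ``learning_curve.csv``, ``kinetics.csv``,
    ``stats.json``, ``manifests.json`` and ``provenance.json``; every file
    embeds the seed and config hash.  Deterministic given the config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    meta = [f"seed: {config.seed}", f"config_hash: {chash}"]
    manifests: list = []
    truths = _subject_truths(config)
    results: dict = {}
    t_start = time.perf_counter()
    for name, phase in [("learning", learning_phase), ("omission", omission_phase),
                        ("kinetics", kinetics_phase), ("terminal", terminal_phase)]:
        t0 = time.perf_counter()
        try:
            if name in ("learning", "omission"):
                results[name] = phase(config, truths, collect_manifests=manifests)
            else:
                results[name] = phase(config, truths)
        except OptoPavError as exc:
            raise OptoPavError(f"pipeline stage {name!r} failed: {exc}") from exc
        logger.info("stage %s finished in %.1f s", name, time.perf_counter() - t0)

    _write_csv(results["learning"]["auc_table"], outdir / "auc_table.csv", meta)
    _write_csv(results["learning"]["learning_curve"],
               outdir / "learning_curve.csv", meta)
    _write_csv(results["kinetics"]["table"], outdir / "kinetics.csv", meta)

    stats_out = {
        "seed": config.seed,
        "config_hash": chash,
        "learning_anova": results["learning"]["anova"].to_dict(),
        "omission_t": results["omission"]["ttest"].to_dict(),
        "omission_subject_aucs": results["omission"]["subject_aucs"],
        "kinetics_t": results["kinetics"]["ttest"].to_dict(),
        "terminal_anova": results["terminal"]["anova"].to_dict(),
        "anesthesia_paired_t": results["terminal"]["paired_t"].to_dict(),
    }
    (outdir / "stats.json").write_text(
        json.dumps(_jsonable(stats_out), indent=2, default=float) + "\n")
    (outdir / "manifests.json").write_text(
        json.dumps(_jsonable(manifests), default=float) + "\n")
    provenance = {"seed": config.seed, "config_hash": chash,
                  "config": config.to_dict(),
                  "runtime_s": round(time.perf_counter() - t_start, 2),
                  "outputs": ["auc_table.csv", "learning_curve.csv", "kinetics.csv",
                              "stats.json", "manifests.json"]}
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, default=float) + "\n")
    results["outdir"] = outdir
    results["stats"] = stats_out
    return results
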