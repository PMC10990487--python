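"""Monte-Carlo recovery studies over the synthetic cohort.

Each study repeats a complete simulate -> preprocess -> align -> test chain
over many seeds and reports how often the known ground-truth structure is
recovered: the region ordering of derivative zero-crossings, the omission
dip (and its absence under a null generator), the session x cue learning
interaction, and the type-I error calibration of the statistical layer.

Studies run at 20 Hz sampling with the low-pass stage disabled — the
coarsest grid that resolves the fastest kernel — so that hundreds of
full-session simulations stay cheap; single-recording analyses elsewhere
default to 50 Hz.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from . import perievent as pe
from . import kinetics as kin
from . import stats as st
from .preprocess import preprocess
from .simulate import REGION_PRESETS, GroundTruth, simulate_traces
from .task import TaskConfig, generate_schedule

STUDY_FS = 20.0


def _subject_scales(rng: np.random.Generator, n: int, sd: float = 0.1) -> np.ndarray:
    return np.exp(rng.normal(0.0, sd, size=n))


def _seed_pair(ss: np.random.SeedSequence) -> tuple[int, int]:
    a, b = ss.generate_state(2) >> np.uint32(1)
    return int(a), int(b)


def region_ordering_study(n_seeds: int = 100, base_seed: int = 0,
                          n_subjects: int = 4,
                          regions: tuple[str, str] = ("LH_dopamine",
                                                      "NAc_dopamine"),
                          n_stim_trials: int = 20,
                          smoothing_window_s: float = 0.5) -> dict:
    """How often the fast region's point A precedes the slow region's.

    Per seed, each region contributes ``n_subjects`` synthetic subjects
    (default noise), each running a stimulation session of ``n_stim_trials``
    laser deliveries; point A is detected on the subject-mean laser-aligned
    trace and compared between regions as group means.
    """
    truth = GroundTruth()
    task = TaskConfig(n_laser_trials=n_stim_trials, n_nonlaser_trials=0)
    successes = 0
    for k in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([base_seed, 41, k]))
        scales = _subject_scales(rng, n_subjects)
        means = {}
        for r, region in enumerate(regions):
            kernel = REGION_PRESETS[region]
            points = []
            for subj in range(n_subjects):
                s_seed, t_seed = _seed_pair(
                    np.random.SeedSequence([base_seed, 42, k, r, subj]))
                sched = generate_schedule(task, seed=s_seed, session_index=11)
                trace, _ = simulate_traces(sched, kernel,
                                           truth.scaled(scales[subj]),
                                           fs=STUDY_FS, seed=t_seed)
                dff = preprocess(trace)
                tensor = pe.align(dff, sched, pe.LASER_ONSET)
                deriv = kin.derivative(tensor.mean_trace(), fs=STUDY_FS,
                                       smoothing_window_s=smoothing_window_s)
                res = kin.find_zero_crossings(deriv, tensor.rel_t, t_ref=0.0)
                if res.point_a_s is not None:
                    points.append(res.point_a_s)
            means[region] = float(np.mean(points)) if points else np.inf
        if means[regions[0]] < means[regions[1]]:
            successes += 1
    return {"n_seeds": n_seeds, "n_success": successes,
            "success_rate": successes / n_seeds}


def omission_dip_study(n_seeds: int = 100, base_seed: int = 0,
                       n_subjects: int = 4,
                       dip_amplitude: Optional[float] = None,
                       region: str = "NAc_dopamine",
                       window_s: tuple[float, float] = (0.0, 2.0)) -> dict:
    """Recovery of the omission dip sign across seeds (or its null absence).

    Per seed, each subject runs one omission session (20 laser / 10 omission /
    30 non-laser trials, default noise); subject mean omission-window AUCs
    feed a one-sample t test against 0.  Returns counts of seeds with all
    AUCs negative and with a significant t.  Pass ``dip_amplitude=0.0`` for
    the null generator.
    """
    truth = GroundTruth()
    if dip_amplitude is not None:
        truth = dataclasses.replace(truth, dip_amplitude=dip_amplitude)
    kernel = REGION_PRESETS[region]
    task = TaskConfig.omission()
    n_all_negative = 0
    n_significant = 0
    for k in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([base_seed, 51, k]))
        scales = _subject_scales(rng, n_subjects)
        aucs = []
        for subj in range(n_subjects):
            s_seed, t_seed = _seed_pair(
                np.random.SeedSequence([base_seed, 52, k, subj]))
            sched = generate_schedule(task, seed=s_seed, session_index=11)
            trace, _ = simulate_traces(sched, kernel, truth.scaled(scales[subj]),
                                       fs=STUDY_FS, seed=t_seed)
            dff = preprocess(trace)
            tensor = pe.align(dff, sched, pe.OMISSION_EXPECTED_LASER)
            aucs.append(pe.omission_auc(tensor, window_s))
        if all(a < 0 for a in aucs):
            n_all_negative += 1
        if st.one_sample_t(aucs).significant:
            n_significant += 1
    return {"n_seeds": n_seeds, "n_all_negative": n_all_negative,
            "n_significant": n_significant,
            "significant_rate": n_significant / n_seeds}


def learning_curve_study(n_seeds: int = 100, base_seed: int = 0,
                         n_subjects: int = 4, n_sessions: int = 10,
                         a_max: Optional[float] = None,
                         region: str = "NAc_dopamine") -> dict:
    """Detection rate of the session x cue interaction over seeds.

    Per seed: ``n_subjects`` subjects x ``n_sessions`` training sessions;
    per-trial cue AUCs (0-1.5 s) are averaged per subject/session/cue and a
    two-way repeated-measures ANOVA tests the interaction at alpha = 0.05.
    Also verifies the interaction df structure.
    """
    truth = GroundTruth()
    if a_max is not None:
        truth = dataclasses.replace(truth, a_max=a_max)
    kernel = REGION_PRESETS[region]
    task = TaskConfig()
    n_significant = 0
    df_expected = (float(n_sessions - 1), float((n_sessions - 1) * (n_subjects - 1)))
    df_ok = True
    for k in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([base_seed, 61, k]))
        scales = _subject_scales(rng, n_subjects)
        tables = []
        for subj in range(n_subjects):
            for session in range(1, n_sessions + 1):
                s_seed, t_seed = _seed_pair(
                    np.random.SeedSequence([base_seed, 62, k, subj, session]))
                sched = generate_schedule(task, seed=s_seed,
                                          session_index=session)
                trace, _ = simulate_traces(sched, kernel,
                                           truth.scaled(scales[subj]),
                                           fs=STUDY_FS, seed=t_seed)
                dff = preprocess(trace)
                for ttype in ("laser_paired", "non_laser"):
                    tensor = pe.align(dff, sched, pe.CUE_ONSET,
                                      trial_types=[ttype])
                    tables.append(pe.make_auc_table(
                        tensor, (0.0, 1.5), subject=f"m{subj}",
                        session=session, trial_type=ttype))
        import pandas as pd
        curve = pe.session_curve(pd.concat(tables, ignore_index=True))
        res = st.two_way_rm_anova(curve, factor_a="session",
                                  factor_b="trial_type")
        df_ok = df_ok and res.df == df_expected
        if res.significant:
            n_significant += 1
    return {"n_seeds": n_seeds, "n_significant": n_significant,
            "significant_rate": n_significant / n_seeds,
            "interaction_df": df_expected, "df_structure_ok": df_ok}


def type_one_error_study(n_reps: int = 2000, base_seed: int = 0) -> dict:
    """Empirical type-I error of every implemented test under a normal null.

    Each replicate draws iid standard-normal data shaped like the study's
    designs (n = 4 subjects; 4 x 3 condition tables; 4 x 10 x 2 session
    tables) and records rejections at alpha = 0.05.
    """
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, 71]))
    rejections = {name: 0 for name in
                  ("one_sample_t", "paired_t", "unpaired_t", "one_way_rm_anova",
                   "two_way_rm_session", "two_way_rm_cue",
                   "two_way_rm_interaction")}
    for _ in range(n_reps):
        if st.one_sample_t(rng.normal(size=4)).significant:
            rejections["one_sample_t"] += 1
        if st.paired_t(rng.normal(size=4), rng.normal(size=4)).significant:
            rejections["paired_t"] += 1
        if st.unpaired_t(rng.normal(size=4), rng.normal(size=4)).significant:
            rejections["unpaired_t"] += 1
        if st.one_way_rm_anova(rng.normal(size=(4, 3))).significant:
            rejections["one_way_rm_anova"] += 1
        eff = st.two_way_rm_anova(rng.normal(size=(4, 10, 2))).effects
        p = eff.set_index("effect")["p"]
        if p["session"] < st.ALPHA:
            rejections["two_way_rm_session"] += 1
        if p["trial_type"] < st.ALPHA:
            rejections["two_way_rm_cue"] += 1
        if p["interaction"] < st.ALPHA:
            rejections["two_way_rm_interaction"] += 1
    rates = {name: count / n_reps for name, count in rejections.items()}
    return {"n_reps": n_reps, "rejections": rejections, "rates": rates}


def binomial_bounds(p: float = 0.05, n: int = 2000,
                    confidence: float = 0.99) -> tuple[float, float]:
    """Normal-approximation binomial bounds for an empirical rate."""
    from scipy import stats as sst
    z = sst.norm.ppf(0.5 + confidence / 2.0)
    half = z * np.sqrt(p * (1.0 - p) / n)
    return p - half, p + half
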