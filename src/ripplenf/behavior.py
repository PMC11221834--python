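"""SWR-rate, dwell, speed and task-performance metrics, plus the statistics
layer: within-subject rank-sum comparisons with Benjamini-Hochberg
correction, groupwise mixed-effects models, sign tests, and pre/post
correlations.

Conventions shared by all metrics:

* Events are assigned to trial periods by their **peak time**; the pre-reward
  period is center-poke → reward, the post-reward period reward → port exit.
* The NF **trigger** SWR is excluded from rate metrics by default — the task
  guarantees exactly one suprathreshold event immediately before reward on
  every completed neurofeedback trial, which would otherwise dominate
  reward-aligned rates.
* The **suprathreshold** exclusion drops every event matching a logged online
  suprathreshold detection (on both neurofeedback *and* delay trials): the
  size comparison between trial types is biased without it, because NF trials
  end at their first suprathreshold event while delay trials do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.ndimage import gaussian_filter1d

from .signals import SwrEvent
from .task import Trial

SPEED_SMOOTH_SD = 0.25  # s, Gaussian smoothing of head speed
SPEED_FS = 30.0  # Hz, head-tracking rate of the synthetic speed traces
TRIGGER_MATCH_TOL = 0.075  # s, matching offline events to online triggers


# ---------------------------------------------------------------------------
# event ↔ trial assignment helpers


def _event_peaks(events: list[SwrEvent]) -> np.ndarray:
    return np.array([e.t_peak for e in events], dtype=float)


def _excluded_mask(
    peaks: np.ndarray,
    trial: Trial,
    exclude_trigger: bool,
    exclude_suprathreshold: bool,
) -> np.ndarray:
    """True for events that the active exclusion rules drop."""
    drop = np.zeros(peaks.size, dtype=bool)
    if exclude_trigger and trial.trigger_event is not None:
        drop |= np.abs(peaks - trial.trigger_event.t_peak) <= TRIGGER_MATCH_TOL
    if exclude_suprathreshold:
        for t in trial.online_suprathreshold_times:
            drop |= np.abs(peaks - t) <= TRIGGER_MATCH_TOL
    return drop


def smoothed_mean_speed(trace: np.ndarray | None, fs: float = SPEED_FS) -> float:
    if trace is None or len(trace) == 0:
        return np.nan
    return float(gaussian_filter1d(np.asarray(trace, float), SPEED_SMOOTH_SD * fs).mean())


# ---------------------------------------------------------------------------
# timewise (reward-aligned) rates


def timewise_rate(
    trials: list[Trial],
    events: list[SwrEvent],
    bin_width: float = 0.5,
    min_trials: int = 100,
    exclude_trigger: bool = True,
) -> pd.DataFrame:
    """Reward-aligned SWR rate curve in fixed-width bins.

    For each trial, events between center poke and port exit are counted in
    bins indexed relative to reward delivery (bin ``k`` covers
    ``[reward + k*w, reward + (k+1)*w)``; negative ``k`` is pre-reward). A
    trial contributes to a bin only when its port interval covers the whole
    bin; bins with fewer than ``min_trials`` contributing trials are omitted.
    Returns a DataFrame indexed by bin start offset with columns
    ``rate`` (ev/s, mean across trials), ``sem`` and ``n_trials``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    peaks = _event_peaks(events)
    per_bin: dict[int, list[float]] = {}
    for trial in trials:
        if not (
            np.isfinite(trial.t_center_poke)
            and np.isfinite(trial.t_reward)
            and np.isfinite(trial.t_center_exit)
        ):
            continue
        drop = _excluded_mask(peaks, trial, exclude_trigger, False)
        k_lo = int(np.ceil((trial.t_center_poke - trial.t_reward) / bin_width))
        k_hi = int(np.floor((trial.t_center_exit - trial.t_reward) / bin_width))
        for k in range(k_lo, k_hi):
            lo = trial.t_reward + k * bin_width
            sel = (peaks >= lo) & (peaks < lo + bin_width) & ~drop
            per_bin.setdefault(k, []).append(sel.sum() / bin_width)
    rows = []
    for k in sorted(per_bin):
        vals = np.asarray(per_bin[k])
        if vals.size < min_trials:
            continue
        rows.append(
            {
                "bin_start": k * bin_width,
                "rate": vals.mean(),
                "sem": vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan,
                "n_trials": vals.size,
            }
        )
    return pd.DataFrame(rows).set_index("bin_start") if rows else pd.DataFrame(
        columns=["rate", "sem", "n_trials"]
    )


# ---------------------------------------------------------------------------
# per-trial period metrics


def period_metrics(
    trials: list[Trial],
    events: list[SwrEvent],
    exclude_trigger: bool = True,
    exclude_suprathreshold: bool = False,
) -> pd.DataFrame:
    """Per-trial pre/post/total SWR counts, rates, dwell, speed and size.

    Timeout/aborted trials (missing period boundaries) are returned with
    ``skipped=True`` and NaN metrics. ``conservation``: with both exclusions
    off, ``pre_count + post_count`` equals the number of events whose peak
    falls in the port interval.
    """
    peaks = _event_peaks(events)
    sizes = np.array([e.size for e in events], dtype=float)
    rows = []
    for trial in trials:
        base = {
            "trial": trial.index,
            "type": trial.type,
            "trigger_excluded": exclude_trigger,
            "suprathreshold_excluded": exclude_suprathreshold,
        }
        if not (
            np.isfinite(trial.t_center_poke)
            and np.isfinite(trial.t_reward)
            and np.isfinite(trial.t_center_exit)
        ):
            rows.append({**base, "skipped": True})
            continue
        if trial.t_reward < trial.t_center_poke or trial.t_center_exit < trial.t_reward:
            raise ValueError(f"trial {trial.index} has negative period durations")
        drop = _excluded_mask(peaks, trial, exclude_trigger, exclude_suprathreshold)
        pre = (peaks >= trial.t_center_poke) & (peaks < trial.t_reward) & ~drop
        post = (peaks >= trial.t_reward) & (peaks < trial.t_center_exit) & ~drop
        pre_dur = trial.t_reward - trial.t_center_poke
        post_dur = trial.t_center_exit - trial.t_reward
        rows.append(
            {
                **base,
                "skipped": False,
                "pre_count": int(pre.sum()),
                "post_count": int(post.sum()),
                "pre_dur": pre_dur,
                "post_dur": post_dur,
                "pre_rate": pre.sum() / pre_dur if pre_dur > 0 else np.nan,
                "post_rate": post.sum() / post_dur if post_dur > 0 else np.nan,
                "total_rate": (pre.sum() + post.sum()) / (pre_dur + post_dur)
                if pre_dur + post_dur > 0
                else np.nan,
                "post_dwell": post_dur,
                "pre_mean_size": float(sizes[pre].mean()) if pre.any() else np.nan,
                "post_mean_size": float(sizes[post].mean()) if post.any() else np.nan,
                "pre_speed": smoothed_mean_speed(trial.pre_speed),
                "post_speed": smoothed_mean_speed(trial.post_speed),
            }
        )
    return pd.DataFrame(rows)


def speed_quartile_analysis(metrics: pd.DataFrame, min_trials: int = 4) -> dict:
    """Speed-matched subset comparison.

    Selects the top-speed quartile of neurofeedback trials and the
    bottom-speed quartiles of delay and control trials (ties broken by trial
    index), then compares pre-reward SWR rates between the NF subset and
    each other subset with two-sided rank-sum tests. Returns the subsets and
    the comparisons; groups with fewer than ``min_trials`` usable trials are
    flagged and skipped.
    """
    out = {"subsets": {}, "comparisons": {}, "flags": []}
    usable = metrics[~metrics.get("skipped", False)].dropna(subset=["pre_speed"])
    subsets = {}
    for ttype, take_top in (("neurofeedback", True), ("delay", False), ("control", False)):
        grp = usable[usable["type"] == ttype]
        if len(grp) < min_trials:
            out["flags"].append(f"too few {ttype} trials")
            continue
        q = max(len(grp) // 4, 1)
        order = grp.sort_values(
            ["pre_speed", "trial"], ascending=[not take_top, True], kind="stable"
        )
        subsets[ttype] = order.iloc[:q]
    out["subsets"] = subsets
    if "neurofeedback" in subsets:
        for other in ("delay", "control"):
            if other in subsets:
                stat = sstats.ranksums(
                    subsets["neurofeedback"]["pre_rate"].dropna(),
                    subsets[other]["pre_rate"].dropna(),
                )
                out["comparisons"][f"nf_vs_{other}"] = {
                    "statistic": float(stat.statistic),
                    "p_value": float(stat.pvalue),
                }
    return out


# ---------------------------------------------------------------------------
# task performance


def performance_metrics(trials: list[Trial]) -> dict:
    """Search/repeat performance and the NF share of suboptimal trials.

    ``search_efficiency``: fraction of search trials choosing a not-yet-
    sampled arm (sampling history resets at every goal switch).
    ``redundant_nf_fraction``: of search trials revisiting a sampled arm, the
    fraction that are neurofeedback trials. ``correct_repeat_fraction``: goal
    visits / repeat trials. ``error_nf_fraction``: of repeat trials missing
    the goal, the NF fraction. Undefined metrics are NaN with a flag.
    """
    search_total = search_novel = 0
    redundant_nf = redundant_total = 0
    repeat_total = repeat_correct = 0
    error_nf = error_total = 0
    sampled: set[int] = set()
    current_block = None
    for trial in trials:
        if trial.timeout or trial.aborted or trial.arm_choice == 0:
            continue
        if trial.goal_block != current_block:
            current_block = trial.goal_block
            sampled = set()
        if trial.phase == "search":
            search_total += 1
            if trial.arm_choice in sampled:
                redundant_total += 1
                if trial.type == "neurofeedback":
                    redundant_nf += 1
            else:
                search_novel += 1
            sampled.add(trial.arm_choice)
        else:
            repeat_total += 1
            if trial.arm_choice == trial.goal_arm:
                repeat_correct += 1
            else:
                error_total += 1
                if trial.type == "neurofeedback":
                    error_nf += 1
    flags = []
    if search_total == 0:
        flags.append("no search trials")
    if repeat_total == 0:
        flags.append("no repeat trials")
    return {
        "search_efficiency": search_novel / search_total if search_total else np.nan,
        "redundant_nf_fraction": redundant_nf / redundant_total
        if redundant_total
        else np.nan,
        "correct_repeat_fraction": repeat_correct / repeat_total
        if repeat_total
        else np.nan,
        "error_nf_fraction": error_nf / error_total if error_total else np.nan,
        "n_search": search_total,
        "n_redundant": redundant_total,
        "n_repeat": repeat_total,
        "n_error": error_total,
        "flags": flags,
    }


# ---------------------------------------------------------------------------
# statistics layer


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (via statsmodels)."""
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def within_subject_compare(
    samples_a: list[np.ndarray],
    samples_b: list[np.ndarray],
) -> pd.DataFrame:
    """Per-subject two-sided rank-sum tests with BH correction.

    ``samples_a[i]``/``samples_b[i]`` are the two trial-type samples of
    subject ``i``; the BH family is the set of per-subject comparisons.
    Subjects with an empty side are flagged and excluded from the family.
    """
    rows = []
    for i, (a, b) in enumerate(zip(samples_a, samples_b)):
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if a.size == 0 or b.size == 0:
            rows.append({"subject": i, "p_raw": np.nan, "skipped": True})
            continue
        rows.append(
            {
                "subject": i,
                "p_raw": float(sstats.ranksums(a, b).pvalue),
                "skipped": False,
            }
        )
    df = pd.DataFrame(rows)
    ok = ~df["skipped"]
    adj = np.full(len(df), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = benjamini_hochberg(df.loc[ok, "p_raw"].to_numpy())
    df["p_adjusted"] = adj
    return df


@dataclass
class GroupComparison:
    """Groupwise mixed-model contrasts against the control cohort."""

    family: str
    coefficients: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def groupwise_model(
    data: pd.DataFrame, family: str = "linear", value_col: str = "value"
) -> GroupComparison:
    """Mixed model of a per-trial measure on cohort-group labels.

    ``data`` needs columns ``subject``, ``group`` (levels ``control``,
    ``manip-NF``, ``manip-delay``) and the value. Fixed group effects
    (control as reference) with a subject random intercept; ``linear`` fits
    a Gaussian mixed model (rate, dwell, amplitude, proportion measures),
    ``poisson`` a Poisson mixed model for counts (variational Bayes, with
    normal-approximation p-values from the posterior). Estimation is
    delegated to statsmodels; this function owns design construction, family
    selection and contrast extraction.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if family not in ("linear", "poisson"):
        raise ValueError("family must be 'linear' or 'poisson'")
    df = data.dropna(subset=[value_col]).copy()
    df["group"] = pd.Categorical(
        df["group"], categories=["control", "manip-NF", "manip-delay"]
    )
    counts = df.groupby("group", observed=True)["subject"].nunique()
    comp = GroupComparison(family=family)
    manip_subjects = df.loc[df["group"] != "control", "subject"].nunique()
    if counts.get("control", 0) < 2 or manip_subjects < 2:
        comp.flags.append("fewer than 2 subjects in a cohort; model refused")
        return comp
    if family == "poisson" and not np.allclose(df[value_col] % 1, 0):
        raise ValueError("poisson family requires integer count outcomes")
    if family == "linear" and df[value_col].dtype.kind in "iu" and (
        df[value_col].max() > 1
    ):
        comp.flags.append("integer outcome with linear family; check family choice")
    contrast_names = {
        "group[T.manip-NF]": "nf_vs_control",
        "group[T.manip-delay]": "delay_vs_control",
    }
    if family == "linear":
        fit = None
        for method in (None, "powell", "nm"):
            try:
                model = smf.mixedlm(f"{value_col} ~ group", df, groups=df["subject"])
                fit = model.fit(reml=True) if method is None else model.fit(
                    reml=True, method=method
                )
                if fit.converged:
                    break
                fit = None
            except (np.linalg.LinAlgError, ValueError):
                continue
        if fit is not None and any(
            not np.isfinite(fit.pvalues.get(t, np.nan)) for t in contrast_names
        ):
            fit = None
        if fit is None:
            # near-zero between-subject variance can defeat the mixed-model
            # optimizer; fall back to OLS with subject-clustered errors
            fit = smf.ols(f"{value_col} ~ group", df).fit(
                cov_type="cluster", cov_kwds={"groups": df["subject"]}
            )
            comp.flags.append("mixed model singular; cluster-robust OLS fallback")
        for term, name in contrast_names.items():
            if term in fit.params.index:
                comp.coefficients[name] = float(fit.params[term])
                comp.p_values[name] = float(fit.pvalues[term])
    else:
        model = sm.PoissonBayesMixedGLM.from_formula(
            f"{value_col} ~ group", {"subject": "0 + C(subject)"}, df
        )
        fit = model.fit_vb()
        names = list(fit.model.exog_names)
        for term, name in contrast_names.items():
            if term in names:
                j = names.index(term)
                mean, sd = fit.fe_mean[j], fit.fe_sd[j]
                comp.coefficients[name] = float(mean)
                comp.p_values[name] = float(2 * sstats.norm.sf(abs(mean) / sd))
    return comp


def sign_test_fraction(successes: int, n: int) -> float:
    """Exact two-sided binomial sign test against 0.5."""
    if n == 0:
        return np.nan
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    return float(sstats.binomtest(successes, n, 0.5, alternative="two-sided").pvalue)


def prepost_correlation(metrics: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (with t-based p) between pre and post measures per subject.

    ``metrics`` needs a ``subject`` column plus the pre/post pairs; one row
    per (subject, measure) with r, p and a flag for degenerate inputs.
    """
    pairs = [
        ("count", "pre_count", "post_count"),
        ("rate", "pre_rate", "post_rate"),
        ("dwell", "pre_dur", "post_dwell"),
    ]
    rows = []
    for subject, grp in metrics.groupby("subject"):
        for name, a, b in pairs:
            if a not in grp or b not in grp:
                continue
            x = grp[a].to_numpy(float)
            y = grp[b].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            if x.size < 3 or x.std() == 0 or y.std() == 0:
                rows.append(
                    {"subject": subject, "measure": name, "r": np.nan,
                     "p_value": np.nan, "flagged": True}
                )
                continue
            r, p = sstats.pearsonr(x, y)
            rows.append(
                {"subject": subject, "measure": name, "r": float(r),
                 "p_value": float(p), "flagged": False}
            )
    return pd.DataFrame(rows)
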