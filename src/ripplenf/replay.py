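"""Replay content classification and the arm-category Poisson GLM.

Each SWR's decoded posterior is classified as *interpretable* spatial content
if the time-averaged probability of the continuous movement state exceeds 0.8
and at least 30% of the (time-averaged) posterior density falls in a single
maze segment. Interpretable events are *local* when the dominant segment is
the one the animal currently occupies, *remote* otherwise; everything else
("fragmented") is excluded from replay analyses.

The behavioral relevance of replayed arms is quantified with a Poisson GLM:
for every trial (search and repeat trials from the second goal block on, so
a previous goal exists), each of the eight arms contributes one row with
binary predictors *previous arm* (visited on the immediately preceding
trial), *future arm* (chosen on this trial), and *previous goal arm* (goal
of the preceding block); the response is the number of replays of that arm
during the trial's analysis period. Coefficients exponentiate to fold
changes, with Wald confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .decoding import PosteriorGrid
from .signals import SwrEvent
from .task import N_ARMS, Trial

P_CONTINUOUS_THRESHOLD = 0.8  # strict: "exceeds"
SEGMENT_DENSITY_THRESHOLD = 0.30  # inclusive: "at least 30%"


@dataclass
class ReplayLabel:
    """Classification of one SWR's decoded content."""

    event_id: int
    interpretable: bool
    kind: str  # local | remote | none
    dominant_segment: int | None
    p_continuous: float
    segment_density: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind != "none" and not self.interpretable:
            raise ValueError("only interpretable events carry a replay kind")


def classify_event(
    posterior: PosteriorGrid,
    animal_segment: int,
    event_id: int = 0,
    p_threshold: float = P_CONTINUOUS_THRESHOLD,
    density_threshold: float = SEGMENT_DENSITY_THRESHOLD,
    pointwise: bool = False,
) -> ReplayLabel:
    """Apply the interpretability rule to a decoded event.

    ``p_continuous`` is the time-averaged marginal probability of the
    continuous state (with ``pointwise=True``, the minimum over time bins —
    the stricter alternative reading of "during the event").
    """
    if posterior.n_time == 0:
        raise ValueError("empty posterior")
    pc_series = posterior.p_continuous()
    p_continuous = float(pc_series.min() if pointwise else pc_series.mean())
    density = posterior.segment_density()
    dominant = max(density, key=density.get)
    interpretable = (p_continuous > p_threshold) and (
        density[dominant] >= density_threshold
    )
    if not interpretable:
        return ReplayLabel(
            event_id, False, "none", None, p_continuous, density
        )
    kind = "local" if dominant == animal_segment else "remote"
    return ReplayLabel(event_id, True, kind, int(dominant), p_continuous, density)


# ---------------------------------------------------------------------------
# rate metrics


def _period_window(trial: Trial, period: str) -> tuple[float, float]:
    if period == "pre":
        return trial.t_center_poke, trial.t_reward
    if period == "post":
        return trial.t_reward, trial.t_center_exit
    if period == "total":
        return trial.t_center_poke, trial.t_center_exit
    raise ValueError("period must be pre | post | total")


def replay_rates(
    labels: list[ReplayLabel],
    events: list[SwrEvent],
    trials: list[Trial],
    period: str = "pre",
    exclude_trigger: bool = True,
) -> pd.DataFrame:
    """Per-trial remote-replay rate and the epoch interpretable fraction.

    Events are assigned to a trial's period by peak time. NF trigger events
    are excluded from rate metrics by default, consistent with the timewise
    quantification rules. Returns one row per usable trial with columns
    ``remote_rate``, ``local_rate``, ``n_remote``, ``duration``; the epoch
    interpretable fraction is attached as ``df.attrs['interpretable_fraction']``.
    """
    if len(labels) != len(events):
        raise ValueError("one label per event required")
    peaks = np.array([e.t_peak for e in events])
    rows = []
    for trial in trials:
        t0, t1 = _period_window(trial, period)
        if not np.isfinite(t0) or not np.isfinite(t1):
            continue
        if t1 <= t0:
            continue
        sel = (peaks >= t0) & (peaks < t1)
        if exclude_trigger and trial.trigger_event is not None:
            sel &= np.abs(peaks - trial.trigger_event.t_peak) > 0.05
        chosen = [labels[i] for i in np.flatnonzero(sel)]
        n_remote = sum(lb.kind == "remote" for lb in chosen)
        n_local = sum(lb.kind == "local" for lb in chosen)
        rows.append(
            {
                "trial": trial.index,
                "type": trial.type,
                "period": period,
                "duration": t1 - t0,
                "n_remote": n_remote,
                "n_local": n_local,
                "remote_rate": n_remote / (t1 - t0),
                "local_rate": n_local / (t1 - t0),
            }
        )
    df = pd.DataFrame(rows)
    n_classified = len(labels)
    df.attrs["interpretable_fraction"] = (
        sum(lb.interpretable for lb in labels) / n_classified if n_classified else np.nan
    )
    return df


# ---------------------------------------------------------------------------
# arm-category GLM


def build_arm_design(
    trials: list[Trial],
    replay_arm_counts: dict[int, dict[int, int]],
    min_goal_block: int = 2,
) -> pd.DataFrame:
    """(trial × arm) design table for the category GLM.

    ``replay_arm_counts`` maps trial index → {arm: replay count}. Only search
    and repeat trials from ``min_goal_block`` onwards contribute (so every
    row has a valid previous-goal option); each contributing trial adds
    exactly eight rows.
    """
    rows = []
    for trial in trials:
        if trial.timeout or trial.aborted or trial.goal_block < min_goal_block:
            continue
        counts = replay_arm_counts.get(trial.index, {})
        for arm in range(1, N_ARMS + 1):
            rows.append(
                {
                    "trial": trial.index,
                    "arm": arm,
                    "previous_arm": int(arm == trial.prev_arm),
                    "future_arm": int(arm == trial.arm_choice),
                    "previous_goal_arm": int(arm == trial.prev_goal_arm),
                    "count": int(counts.get(arm, 0)),
                }
            )
    return pd.DataFrame(rows)


PREDICTORS = ["previous_arm", "future_arm", "previous_goal_arm"]


class ArmCategoryGLM(BaseEstimator):
    """Poisson GLM of replay counts on behavioral arm categories.

    Fits ``count ~ previous_arm + future_arm + previous_goal_arm`` by maximum
    likelihood; coefficients are reported as fold changes (exponentiated)
    with exponentiated Wald confidence intervals. Categories overlap
    additively: an arm that is both the previous arm and the previous goal
    carries both indicators.

    Attributes
    ----------
    result_ : pandas.DataFrame indexed by predictor, with columns
        ``coef, fold_change, ci_low, ci_high, p_value, estimable``.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, design: pd.DataFrame, y=None) -> "ArmCategoryGLM":
        required = set(PREDICTORS + ["count"])
        if not required.issubset(design.columns):
            raise ValueError(f"design must have columns {sorted(required)}")
        estimable = {
            p: design[p].nunique() > 1 for p in PREDICTORS
        }
        usable = [p for p in PREDICTORS if estimable[p]]
        X = sm.add_constant(design[usable].astype(float), has_constant="add")
        model = sm.GLM(design["count"].to_numpy(), X, family=sm.families.Poisson())
        fit = model.fit()
        ci = fit.conf_int(alpha=self.alpha)
        rows = []
        for p in PREDICTORS:
            if not estimable[p]:
                rows.append(
                    {
                        "predictor": p,
                        "coef": np.nan,
                        "fold_change": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p_value": np.nan,
                        "estimable": False,
                    }
                )
                continue
            rows.append(
                {
                    "predictor": p,
                    "coef": float(fit.params[p]),
                    "fold_change": float(np.exp(fit.params[p])),
                    "ci_low": float(np.exp(ci.loc[p, 0])),
                    "ci_high": float(np.exp(ci.loc[p, 1])),
                    "p_value": float(fit.pvalues[p]),
                    "estimable": True,
                }
            )
        self.result_ = pd.DataFrame(rows).set_index("predictor")
        self.fit_ = fit
        return self

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(
            design[[p for p in PREDICTORS if p in self.fit_.params.index]].astype(float),
            has_constant="add",
        )
        return np.asarray(self.fit_.predict(X))


def fit_replay_glm(design: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Functional wrapper around :class:`ArmCategoryGLM`."""
    return ArmCategoryGLM(alpha=alpha).fit(design).result_
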