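"""Behavioral score standardization and change curves.

Raw task scores (proportion correct for accuracy domains, reaction time
for the speed domain) are z-transformed with the mean and SD computed
from baseline data only, applied to both timepoints, so follow-up scores
are expressed on the baseline scale. Speed-domain z-scores are sign
inverted so that higher always means better. Per participant, available
tasks within a domain are averaged into a single domain score per
timepoint; participants need at least one available task per domain.

Domain change curves are then built both ways: cross-sectionally by
differencing the kernel-weighted baseline score series at a 5-year lag,
and longitudinally by kernel-weighting each participant's follow-up minus
baseline score by baseline age (weighted mean, dividing by the weight
sum, so the two curves share a scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .change import ChangeCurve, cross_sectional_change
from .kernel import KernelSpec, weighted_scalar_series

__all__ = [
    "ZScoreParams",
    "fit_zscore_params",
    "apply_zscore",
    "domain_scores",
    "behavioral_change_curves",
]

RT_DOMAINS = frozenset({"SPEED"})


@dataclass(frozen=True)
class ZScoreParams:
    """Per-task baseline mean and sample SD (the standardization anchor)."""

    means: dict
    sds: dict

    def tasks(self):
        return set(self.means)


def fit_zscore_params(table: pd.DataFrame) -> ZScoreParams:
    """Fit per-task standardization parameters from baseline rows only.

    Uses available baseline scores; sample SD (ddof=1). A task whose
    baseline scores are constant (or fewer than 2) cannot be standardized
    and is reported by name.
    """
    base = table[(table["timepoint"] == "baseline") & table["available"]]
    means, sds = {}, {}
    for task_id, grp in base.groupby("task_id"):
        scores = grp["score"].dropna().to_numpy(dtype=float)
        if scores.size < 2:
            raise ValueError(f"task {task_id!r} has fewer than 2 baseline scores")
        sd = float(np.std(scores, ddof=1))
        if sd == 0:
            raise ValueError(f"task {task_id!r} has zero baseline SD; cannot z-transform")
        means[task_id] = float(np.mean(scores))
        sds[task_id] = sd
    return ZScoreParams(means=means, sds=sds)


def apply_zscore(table: pd.DataFrame, params: ZScoreParams, rt_domains=RT_DOMAINS) -> pd.DataFrame:
    """Standardize both timepoints against the baseline anchor.

    z = (raw - baseline_mean) / baseline_SD; speed-domain (reaction time)
    z-scores are multiplied by -1 so a faster-than-average response is a
    positive score.
    """
    unknown = set(table["task_id"].unique()) - params.tasks()
    if unknown:
        raise KeyError(f"no z-score parameters for tasks {sorted(unknown)}")
    out = table.copy()
    mu = out["task_id"].map(params.means)
    sd = out["task_id"].map(params.sds)
    z = (out["score"] - mu) / sd
    invert = out["domain"].isin(rt_domains)
    out["z"] = np.where(invert, -z, z)
    return out


def domain_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Average available task z-scores into one score per participant,
    domain and timepoint; cells with no available task are dropped."""
    if "z" not in table.columns:
        raise ValueError("table must be standardized first (apply_zscore)")
    avail = table[table["available"] & table["z"].notna()]
    return (
        avail.groupby(["participant_id", "domain", "timepoint"], as_index=False)["z"]
        .mean()
        .rename(columns={"z": "score"})
    )


def behavioral_change_curves(
    scores: pd.DataFrame,
    ages: pd.Series | dict,
    spec: KernelSpec = KernelSpec(),
    lag: int = 5,
) -> tuple:
    """Cross-sectional and longitudinal 5-year change curves for one domain.

    Parameters
    ----------
    scores : DataFrame
        Columns participant_id, timepoint, score for a single domain.
    ages : mapping participant_id -> baseline age.

    Returns
    -------
    (cross_sectional, longitudinal) : ChangeCurve pair over baseline ages
        20..75 under the default kernel spec.
    """
    ages = dict(ages)
    wide = scores.pivot_table(index="participant_id", columns="timepoint", values="score")
    if "baseline" not in wide.columns:
        raise ValueError("no baseline scores supplied")

    base = wide["baseline"].dropna()
    base_ages = np.array([ages[p] for p in base.index], dtype=float)
    series = weighted_scalar_series(base.to_numpy(dtype=float), base_ages, spec)
    cross = cross_sectional_change(series, lag=lag)
    cross_curve = ChangeCurve(baseline_ages=cross.baseline_ages, values=cross.maps[:, 0])

    if "followup" not in wide.columns:
        raise ValueError("no follow-up scores supplied for the longitudinal curve")
    both = wide.dropna(subset=["baseline", "followup"])
    deltas = (both["followup"] - both["baseline"]).to_numpy(dtype=float)
    delta_ages = np.array([ages[p] for p in both.index], dtype=float)
    targets = spec.ages_array
    keep = targets + lag <= targets.max()
    sub = KernelSpec(sigma=spec.sigma, target_ages=tuple(int(a) for a in targets[keep]))
    long_series = weighted_scalar_series(deltas, delta_ages, sub)
    long_curve = ChangeCurve(baseline_ages=long_series.target_ages, values=long_series.values)
    return cross_curve, long_curve
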