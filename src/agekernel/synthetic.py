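"""Synthetic two-timepoint cohorts with known ground truth.

Emulates the study design every downstream stage expects: baseline ages
drawn uniformly over 20-80 years, a follow-up exactly 5 years later,
per-voxel smooth age trajectories f_v(age), an optional birth-cohort
offset (the confounder that biases cross-sectional but not longitudinal
change), four behavioral domains of three tasks each (accuracy-type
scores in [0, 1], reaction times in ms for the speed domain), per-cell
missingness repaired so every participant keeps at least one task per
domain, and Gaussian measurement noise.

The generative model for an activation value of participant i at voxel v,
timepoint shift s (0 at baseline, 5 at follow-up) is

    beta_{i,v} = f_v(a_i + s) + c_v * birth_offset_i + eps_{i,v}

with eps ~ N(0, noise_sd^2) and birth_offset_i = a_i - mean(a) (years
born earlier than the sample-average birth date). The cohort term is
identical at both timepoints, so within-participant differences cancel it
while cross-sectional age gradients absorb it -- exactly the divergence
the analysis is built to expose.

All randomness flows from ``SyntheticConfig.seed`` through
``numpy.random.default_rng``; identical config and seed reproduce
bit-identical cohorts, activations and behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .change import GrayMatterMask
from .kernel import ActivationMatrix

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "CohortTable",
    "DOMAIN_NAMES",
    "generate_cohort",
    "generate_activation",
    "generate_behavior",
]

DOMAIN_NAMES = ("MEM", "FLUID", "SPEED", "VOCAB")
FOLLOWUP_YEARS = 5

# default raw-score trajectories per domain: accuracy domains decline or
# (vocabulary) improve gently; the speed domain is a reaction time in ms
# that slows with age
_DEFAULT_BEHAVIOR = {
    "MEM": lambda a: 0.88 - 0.0030 * (np.asarray(a, dtype=float) - 20.0),
    "FLUID": lambda a: 0.85 - 0.0035 * (np.asarray(a, dtype=float) - 20.0),
    "SPEED": lambda a: 850.0 + 7.0 * (np.asarray(a, dtype=float) - 20.0),
    "VOCAB": lambda a: 0.68 + 0.0020 * (np.asarray(a, dtype=float) - 20.0),
}
RT_DOMAINS = frozenset({"SPEED"})
_RT_NOISE_SCALE = 1000.0  # behavioral noise SD multiplier for RT tasks (ms per unit)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of a simulated cohort.

    Defaults reproduce the reference design: 200 participants aged 20-80
    at baseline, follow-up 5 years later, a 12x14x12 grid of 3-mm voxels
    (~2,000 mask voxels), four domains x three tasks, 10% missing task
    cells, activation noise SD 0.5 beta-units, no cohort effect and no
    practice effect unless planted.
    """

    n_participants: int = 200
    age_range: tuple = (20, 80)
    grid_shape: tuple = (12, 14, 12)
    voxel_size_mm: float = 3.0
    mask_fill: float = 1.0
    n_domains: int = 4
    tasks_per_domain: int = 3
    trajectory_basis: np.ndarray | None = None  # (n_domains, V, 3) poly coeffs
    cohort_effect: object = 0.0  # scalar or (V,) beta-units per birth-year
    noise_sd: float = 0.5
    behavior_noise_sd: float = 0.03
    practice_effect: float = 0.0
    missing_rate: float = 0.1
    age_sampling: str = "random"  # 'random' (uniform draws) | 'uniform_grid'
    seed: int = 0

    def __post_init__(self):
        if self.age_sampling not in ("random", "uniform_grid"):
            raise ValueError("age_sampling must be 'random' or 'uniform_grid'")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy min < max")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be positive")
        if not 0 < self.mask_fill <= 1:
            raise ValueError("mask_fill must lie in (0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_sd < 0 or self.behavior_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.n_participants < 0:
            raise ValueError("n_participants must be nonnegative")

    @property
    def domains(self) -> tuple:
        if self.n_domains <= len(DOMAIN_NAMES):
            return DOMAIN_NAMES[: self.n_domains]
        extra = tuple(f"DOM{i + 1}" for i in range(len(DOMAIN_NAMES), self.n_domains))
        return DOMAIN_NAMES + extra


@dataclass
class CohortTable:
    """Participant roster plus task availability.

    ``table`` columns: participant_id, baseline_age (integer years), sex,
    birth_offset (years born before the sample-average birth date =
    baseline_age - mean baseline_age). ``availability`` is a boolean
    (n_participants, n_domains, tasks_per_domain) array; after repair
    every participant has >= 1 available task in every domain.
    """

    table: pd.DataFrame
    availability: np.ndarray
    domains: tuple

    @property
    def n_participants(self) -> int:
        return len(self.table)

    @property
    def baseline_ages(self) -> np.ndarray:
        return self.table["baseline_age"].to_numpy()

    @property
    def participant_ids(self) -> np.ndarray:
        return self.table["participant_id"].to_numpy()

    @property
    def birth_offsets(self) -> np.ndarray:
        return self.table["birth_offset"].to_numpy()


@dataclass
class GroundTruth:
    """Planted generative functions, for parameter-recovery oracles.

    ``poly`` holds per-domain, per-voxel quadratic coefficients of the
    trajectory in the centered variable u = (age - 50)/30, so
    f_v(age) = p0 + p1*u + p2*u^2. ``cohort`` is c_v in beta-units per
    year-earlier-born.
    """

    mask: GrayMatterMask
    poly: np.ndarray  # (n_domains, V, 3)
    cohort: np.ndarray  # (V,)
    domains: tuple
    behavior_trajectories: dict
    config: SyntheticConfig

    def _domain_index(self, domain: str) -> int:
        try:
            return self.domains.index(domain)
        except ValueError:
            raise KeyError(f"unknown domain {domain!r}; expected one of {self.domains}") from None

    def f(self, domain: str, ages) -> np.ndarray:
        """Noise-free trajectory values, shape (len(ages), V)."""
        d = self._domain_index(domain)
        u = (np.asarray(ages, dtype=float) - 50.0) / 30.0
        p = self.poly[d]  # (V, 3)
        return p[:, 0][None, :] + np.outer(u, p[:, 1]) + np.outer(u**2, p[:, 2])

    def true_longitudinal_delta(self, domain: str, ages) -> np.ndarray:
        """f_v(age+5) - f_v(age), shape (len(ages), V); exact, noise-free."""
        ages = np.asarray(ages, dtype=float)
        return self.f(domain, ages + FOLLOWUP_YEARS) - self.f(domain, ages)


def _empty_cohort(config: SyntheticConfig) -> CohortTable:
    table = pd.DataFrame(
        {
            "participant_id": pd.Series(dtype=str),
            "baseline_age": pd.Series(dtype=int),
            "sex": pd.Series(dtype=str),
            "birth_offset": pd.Series(dtype=float),
        }
    )
    avail = np.zeros((0, config.n_domains, config.tasks_per_domain), dtype=bool)
    return CohortTable(table=table, availability=avail, domains=config.domains)


def _make_mask(config: SyntheticConfig, rng: np.random.Generator) -> GrayMatterMask:
    n_grid = int(np.prod(config.grid_shape))
    n_keep = max(1, int(round(config.mask_fill * n_grid)))
    included = np.zeros(n_grid, dtype=bool)
    if n_keep >= n_grid:
        included[:] = True
    else:
        included[rng.choice(n_grid, size=n_keep, replace=False)] = True
    return GrayMatterMask(
        grid_shape=config.grid_shape,
        voxel_size_mm=config.voxel_size_mm,
        included=included.reshape(config.grid_shape, order="F"),
    )


def generate_cohort(config: SyntheticConfig) -> tuple:
    """Draw a cohort roster and its planted ground truth.

    Ages are integer years uniform over ``age_range``; task availability
    is sampled at ``missing_rate`` and then repaired so the at-least-one-
    task-per-domain inclusion rule holds. With a single task per domain a
    nonzero missing rate cannot be repaired without contradicting it, so
    that combination is rejected outright.
    """
    if config.missing_rate > 0 and config.tasks_per_domain == 1:
        raise ValueError(
            "missing_rate > 0 with tasks_per_domain = 1 cannot satisfy the "
            "at-least-one-task-per-domain inclusion constraint"
        )
    rng = np.random.default_rng(config.seed)
    mask = _make_mask(config, rng)
    v = mask.n_voxels

    if config.trajectory_basis is not None:
        poly = np.asarray(config.trajectory_basis, dtype=float)
        if poly.shape != (config.n_domains, v, 3):
            raise ValueError(
                f"trajectory_basis must have shape {(config.n_domains, v, 3)}, got {poly.shape}"
            )
    else:
        # smooth random quadratics in u = (age-50)/30
        poly = rng.normal(0.0, 1.0, size=(config.n_domains, v, 3)) * np.array([1.0, 0.6, 0.4])

    cohort_effect = np.asarray(config.cohort_effect, dtype=float)
    cohort = np.broadcast_to(cohort_effect, (v,)).copy() if cohort_effect.ndim == 0 else cohort_effect
    if cohort.shape != (v,):
        raise ValueError(f"cohort_effect must be scalar or shape ({v},)")

    behavior = {d: _DEFAULT_BEHAVIOR.get(d, _DEFAULT_BEHAVIOR["MEM"]) for d in config.domains}
    truth = GroundTruth(
        mask=mask, poly=poly, cohort=cohort, domains=config.domains,
        behavior_trajectories=behavior, config=config,
    )

    n = config.n_participants
    if n == 0:
        return _empty_cohort(config), truth

    lo, hi = config.age_range
    if config.age_sampling == "uniform_grid":
        # stratified coverage: every year in range appears floor(n/span)
        # times, leftovers spread evenly; used for bias-free recovery
        # designs where random age draws would dominate the estimate
        span = hi - lo + 1
        ages = np.tile(np.arange(lo, hi + 1), n // span)
        rem = n - ages.size
        if rem:
            ages = np.concatenate([ages, np.linspace(lo, hi, rem).round().astype(int)])
        ages = rng.permutation(ages)
    else:
        ages = rng.integers(lo, hi + 1, size=n)
    sexes = rng.choice(["F", "M"], size=n)
    avail = rng.random((n, config.n_domains, config.tasks_per_domain)) >= config.missing_rate
    # repair: any participant x domain with no available task gets one back
    empty = ~avail.any(axis=2)
    for i, d in zip(*np.nonzero(empty)):
        avail[i, d, rng.integers(config.tasks_per_domain)] = True

    table = pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "baseline_age": ages.astype(int),
            "sex": sexes,
            "birth_offset": ages - ages.mean(),
        }
    )
    return CohortTable(table=table, availability=avail, domains=config.domains), truth


def generate_activation(
    cohort: CohortTable,
    truth: GroundTruth,
    domain: str,
    timepoint: str,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> ActivationMatrix:
    """Per-participant beta maps for one domain and timepoint.

    Implements the generative formula directly; the birth-cohort term uses
    the baseline birth offset at both timepoints so that longitudinal
    differences cancel it.
    """
    if timepoint not in ("baseline", "followup"):
        raise ValueError(f"unknown timepoint {timepoint!r}; use 'baseline' or 'followup'")
    d = truth._domain_index(domain)
    shift = 0 if timepoint == "baseline" else FOLLOWUP_YEARS
    noise_sd = truth.config.noise_sd if noise_sd is None else float(noise_sd)
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")

    ages = cohort.baseline_ages
    values = truth.f(domain, ages + shift)  # (n, V)
    values = values + np.outer(cohort.birth_offsets, truth.cohort)
    if noise_sd > 0:
        base_seed = truth.config.seed if seed is None else seed
        # distinct stream per domain/timepoint so noise is independent
        rng = np.random.default_rng([int(base_seed) % (2**31), d, shift])
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return ActivationMatrix(
        values=values,
        participant_ids=cohort.participant_ids,
        voxel_index=truth.mask.linear_indices,
    )


def generate_behavior(cohort: CohortTable, truth: GroundTruth, seed: int | None = None) -> pd.DataFrame:
    """Long-format task score table for both timepoints.

    Columns: participant_id, task_id, domain, timepoint, score, available.
    Accuracy-type scores are clipped to [0, 1]; reaction times stay
    positive; ``practice_effect`` is added to raw follow-up scores (use a
    negative value to model an RT speed-up). Only available cells carry a
    score; unavailable cells are emitted with NaN and ``available=False``.
    """
    cfg = truth.config
    base_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng([int(base_seed) % (2**31), 9173])
    ages = cohort.baseline_ages
    rows = []
    for d, domain in enumerate(cohort.domains):
        traj = truth.behavior_trajectories[domain]
        is_rt = domain in RT_DOMAINS
        noise_sd = cfg.behavior_noise_sd * (_RT_NOISE_SCALE if is_rt else 1.0)
        for t in range(cfg.tasks_per_domain):
            task_id = f"{domain}_task{t + 1}"
            avail = cohort.availability[:, d, t]
            for timepoint, shift in (("baseline", 0), ("followup", FOLLOWUP_YEARS)):
                score = traj(ages + shift).astype(float)
                if timepoint == "followup":
                    score = score + cfg.practice_effect
                if noise_sd > 0:
                    score = score + rng.normal(0.0, noise_sd, size=score.shape)
                score = np.maximum(score, 1.0) if is_rt else np.clip(score, 0.0, 1.0)
                score = np.where(avail, score, np.nan)
                rows.append(
                    pd.DataFrame(
                        {
                            "participant_id": cohort.participant_ids,
                            "task_id": task_id,
                            "domain": domain,
                            "timepoint": timepoint,
                            "score": score,
                            "available": avail,
                        }
                    )
                )
    if not rows:
        return pd.DataFrame(
            columns=["participant_id", "task_id", "domain", "timepoint", "score", "available"]
        )
    return pd.concat(rows, ignore_index=True)
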