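"""End-to-end orchestration: simulate or load -> kernel -> change ->
metrics -> report, with deterministic outputs and a run manifest.

A run produces, per domain: the 61-point kernel-weighted baseline series,
both 56-point change-map series (cross-sectional and longitudinal), their
global change curves, ROI curve matrices for both measurements,
per-bracket MAE maps with percentile tails, sign-split integral maps with
tails, peak maps, per-bracket fluctuation maps, plus the cross-domain
stability maps and behavioral change curves. The manifest echoes the
configuration and seed, records per-stage counts and the SHA-256 checksum
of every output file; a rerun with the same config and seed reproduces
identical checksums.
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

from . import behavior as beh
from . import io as akio
from . import metrics as met
from .change import (
    DEFAULT_LAG,
    DEFAULT_RADIUS_MM,
    build_roi_table,
    cross_sectional_change,
    global_curve,
    longitudinal_change,
    roi_change_curves,
)
from .kernel import KernelSpec, weighted_series
from .metrics import AgeBracketSpec
from .synthetic import SyntheticConfig, generate_activation, generate_behavior, generate_cohort

__all__ = ["RunConfig", "RunManifest", "PipelineError", "run_pipeline", "write_report"]

log = logging.getLogger("agekernel")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and entity."""


@dataclass
class InputPaths:
    cohort_tsv: str
    behavior_tsv: str
    activation_pattern: str  # format string with {participant},{domain},{timepoint}
    mask_nifti: str


@dataclass
class RunConfig:
    """Analysis configuration; exactly one of ``simulate``/``inputs``.

    Defaults follow the reference analysis: sigma 4, target ages 20-80,
    12-mm sphere radius, brackets 20-40/41-60/61-75, tail alpha 0.025,
    lag 5 years, top-3 report rows per bracket and domain.
    """

    simulate: SyntheticConfig | None = None
    inputs: InputPaths | None = None
    sigma: float = 4.0
    target_ages: tuple = tuple(range(20, 81))
    radius_mm: float = DEFAULT_RADIUS_MM
    brackets: AgeBracketSpec = field(default_factory=AgeBracketSpec)
    alpha: float = 0.025
    lag: int = DEFAULT_LAG
    top_k: int = 3
    seed: int = 0
    make_plots: bool = False

    def __post_init__(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulate' or 'inputs' must be given")

    @property
    def kernel_spec(self) -> KernelSpec:
        return KernelSpec(sigma=self.sigma, target_ages=self.target_ages)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "simulate" in raw and isinstance(raw["simulate"], dict):
            sim = dict(raw["simulate"])
            for key in ("age_range", "grid_shape"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["simulate"] = SyntheticConfig(**sim)
        if "inputs" in raw and isinstance(raw["inputs"], dict):
            raw["inputs"] = InputPaths(**raw["inputs"])
        if "brackets" in raw and isinstance(raw["brackets"], dict):
            raw["brackets"] = AgeBracketSpec(**{k: tuple(v) for k, v in raw["brackets"].items()})
        if "target_ages" in raw:
            raw["target_ages"] = tuple(raw["target_ages"])
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    versions: dict
    seed: int
    counts: dict
    checksums: dict

    def to_json(self, path) -> Path:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True, default=str)
        return Path(path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _config_echo(config: RunConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        return obj

    return clean(config)


def _load_inputs(config: RunConfig):
    """Materialize cohort, mask, per-domain matrices and behavior table."""
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        cohort, truth = generate_cohort(sim)
        mask = truth.mask
        domains = cohort.domains
        matrices = {
            d: {
                tp: generate_activation(cohort, truth, d, tp)
                for tp in ("baseline", "followup")
            }
            for d in domains
        }
        behavior_table = generate_behavior(cohort, truth)
        cohort_df = cohort.table
    else:
        paths = config.inputs
        mask = akio.read_mask(paths.mask_nifti)
        cohort_df = akio.read_cohort_tsv(paths.cohort_tsv)
        behavior_table = pd.read_csv(paths.behavior_tsv, sep="\t")
        domains = tuple(behavior_table["domain"].unique())
        pids = cohort_df["participant_id"].tolist()
        matrices = {}
        for d in domains:
            matrices[d] = {}
            for tp in ("baseline", "followup"):
                files = [
                    paths.activation_pattern.format(participant=p, domain=d, timepoint=tp)
                    for p in pids
                ]
                matrices[d][tp] = akio.read_activation_volumes(files, mask, participant_ids=pids)
    return cohort_df, mask, domains, matrices, behavior_table


def _stage(name: str, entity: str = ""):
    """Context for pipeline stages: re-raise with stage and entity names."""
    import contextlib

    @contextlib.contextmanager
    def ctx():
        try:
            yield
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - deliberate stage wrapping
            where = f"stage '{name}'" + (f" ({entity})" if entity else "")
            raise PipelineError(f"{where} failed: {exc}") from exc

    return ctx()


def run_pipeline(config: RunConfig, out_dir) -> RunManifest:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.kernel_spec
    brackets = config.brackets
    counts: dict = {}
    outputs: list[Path] = []

    with _stage("load"):
        cohort_df, mask, domains, matrices, behavior_table = _load_inputs(config)
    ages = cohort_df["baseline_age"].to_numpy(dtype=float)
    counts["participants"] = int(len(cohort_df))
    counts["mask_voxels"] = int(mask.n_voxels)
    counts["domains"] = list(domains)
    outputs.append(akio.write_mask(mask, out / "mask.nii"))
    cohort_path = out / "cohort.tsv"
    cohort_df.to_csv(cohort_path, sep="\t", index=False)
    outputs.append(cohort_path)
    behavior_path = out / "behavior.tsv"
    behavior_table.to_csv(behavior_path, sep="\t", index=False)
    outputs.append(behavior_path)

    with _stage("roi_table"):
        rois = build_roi_table(mask, radius_mm=config.radius_mm)
    counts["rois"] = int(rois.n_rois)
    counts["roi_size_median"] = float(np.median(rois.sizes))

    roi_long_by_domain = {}
    change_ages = None
    for domain in domains:
        n_dom = matrices[domain]["baseline"].n_participants
        log.info("domain %s: %d participants", domain, n_dom)
        with _stage("weighted_series", domain):
            series = weighted_series(matrices[domain]["baseline"], ages, spec)
            counts.setdefault("target_ages", int(series.n_ages))
            outputs.append(akio.write_series_nifti(series, mask, out / f"{domain}_weighted_baseline.nii"))
        with _stage("cross_sectional_change", domain):
            cross = cross_sectional_change(series, lag=config.lag)
        with _stage("longitudinal_change", domain):
            longi = longitudinal_change(
                matrices[domain]["baseline"], matrices[domain]["followup"], ages, spec, lag=config.lag
            )
        change_ages = cross.baseline_ages
        counts.setdefault("change_ages", int(len(change_ages)))
        for cms, tag in ((cross, "cross_sectional"), (longi, "longitudinal")):
            outputs.append(akio.write_series_nifti(cms, mask, out / f"{domain}_change_{tag}.nii"))
            curve = global_curve(cms)
            outputs.append(
                akio.write_curve_tsv(curve.values, curve.baseline_ages, out / f"{domain}_global_{tag}.tsv")
            )
        with _stage("roi_curves", domain):
            roi_cross = roi_change_curves(cross, rois)
            roi_long = roi_change_curves(longi, rois)
            roi_long_by_domain[domain] = roi_long
            outputs.append(akio.write_curve_tsv(roi_cross, change_ages, out / f"{domain}_roi_cross_sectional.tsv"))
            outputs.append(akio.write_curve_tsv(roi_long, change_ages, out / f"{domain}_roi_longitudinal.tsv"))

        with _stage("metrics", domain):
            mae_df = met.mae_table(roi_cross, roi_long, change_ages, brackets)
            mae_df = _attach_tails(mae_df, "mae", config.alpha)
            mae_df.to_csv(out / f"{domain}_mae.tsv", sep="\t", index=False)
            outputs.append(out / f"{domain}_mae.tsv")

            integ = met.signed_integral_table(roi_long, change_ages, brackets)
            integ = _attach_tails(integ, "positive_integral", config.alpha, upper_only=True)
            integ = _attach_tails(integ, "negative_integral", config.alpha, lower_only=True)
            integ.to_csv(out / f"{domain}_integrals.tsv", sep="\t", index=False)
            outputs.append(out / f"{domain}_integrals.tsv")

            peaks = met.peak_table(roi_long, change_ages, brackets)
            peaks.to_csv(out / f"{domain}_peaks.tsv", sep="\t", index=False)
            outputs.append(out / f"{domain}_peaks.tsv")

    with _stage("stability"):
        fluct = {
            d: met.fluctuation_table(roi_long_by_domain[d], change_ages, brackets)
            for d in domains
        }
        stab_rows = []
        for name in brackets.names:
            per_domain = {
                d: fluct[d].loc[fluct[d]["bracket"] == name, "fluctuates"].to_numpy()
                for d in domains
            }
            stable = met.cross_domain_stability(per_domain, n_domains=len(domains))
            stab_rows.append(
                pd.DataFrame({"roi": np.arange(rois.n_rois), "bracket": name, "fluctuates_in_all_domains": stable})
            )
        stability = pd.concat(stab_rows, ignore_index=True)
        stability.to_csv(out / "stability.tsv", sep="\t", index=False)
        outputs.append(out / "stability.tsv")

    with _stage("behavior"):
        params = beh.fit_zscore_params(behavior_table)
        standardized = beh.apply_zscore(behavior_table, params)
        dscores = beh.domain_scores(standardized)
        age_map = dict(zip(cohort_df["participant_id"], cohort_df["baseline_age"]))
        for domain in domains:
            dom = dscores[dscores["domain"] == domain]
            if dom.empty:
                continue
            cross_c, long_c = beh.behavioral_change_curves(dom, age_map, spec, lag=config.lag)
            outputs.append(
                akio.write_curve_tsv(
                    np.vstack([cross_c.values, long_c.values]),
                    cross_c.baseline_ages,
                    out / f"{domain}_behavior_change.tsv",
                    index_name="measurement",
                )
            )

    with _stage("report"):
        outputs.extend(write_report(out, domains, brackets, rois, top_k=config.top_k))
        if config.make_plots:
            outputs.extend(_plot_curves(out, domains, change_ages))

    manifest = RunManifest(
        config=_config_echo(config),
        versions=_versions(),
        seed=config.seed,
        counts=counts,
        checksums={p.name: _sha256(p) for p in sorted(set(outputs))},
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def _attach_tails(df: pd.DataFrame, column: str, alpha: float, upper_only=False, lower_only=False) -> pd.DataFrame:
    """Flag per-bracket lower/upper percentile-tail membership."""
    df = df.copy()
    lo_col, hi_col = f"{column}_lower_tail", f"{column}_upper_tail"
    if not upper_only:
        df[lo_col] = False
    if not lower_only:
        df[hi_col] = False
    for name, grp in df.groupby("bracket"):
        lower, upper = met.tail_select(grp[column].to_numpy(), alpha)
        idx = grp.index.to_numpy()
        if not upper_only:
            df.loc[idx[lower], lo_col] = True
        if not lower_only:
            df.loc[idx[upper], hi_col] = True
    return df


def write_report(out_dir, domains, brackets: AgeBracketSpec, rois, top_k: int = 3, label_volume=None) -> list:
    """Ranked top-k tables per analysis, bracket and domain.

    Coordinates are the ROI-center voxel in mm world space. Without a
    user-supplied anatomical label volume the region column reads
    'unlabeled'.
    """
    out = Path(out_dir)
    coords = rois.mask.coordinates_mm
    written = []
    for domain in domains:
        mae_df = pd.read_csv(out / f"{domain}_mae.tsv", sep="\t")
        integ = pd.read_csv(out / f"{domain}_integrals.tsv", sep="\t")
        rows = []
        for name in brackets.names:
            grp = mae_df[mae_df["bracket"] == name]
            k = min(top_k, len(grp))
            if k < top_k:
                log.warning("top-%d requested but only %d ROIs available", top_k, len(grp))
            for label, sub in (
                ("greatest_difference", grp.nlargest(k, "mae")),
                ("greatest_similarity", grp.nsmallest(k, "mae")),
            ):
                for _, r in sub.iterrows():
                    x, y, z = coords[int(r["roi"])]
                    rows.append((label, name, x, y, z, r["mae"], "unlabeled"))
            gi = integ[integ["bracket"] == name]
            for label, sub, col in (
                ("greatest_positive_integral", gi.nlargest(k, "positive_integral"), "positive_integral"),
                ("greatest_negative_integral", gi.nsmallest(k, "negative_integral"), "negative_integral"),
            ):
                for _, r in sub.iterrows():
                    x, y, z = coords[int(r["roi"])]
                    rows.append((label, name, x, y, z, r[col], "unlabeled"))
        rep = pd.DataFrame(rows, columns=["analysis", "bracket", "x_mm", "y_mm", "z_mm", "value", "region"])
        path = out / f"{domain}_report.tsv"
        rep.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def _plot_curves(out_dir, domains, change_ages) -> list:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    written = []
    fig, axes = plt.subplots(2, len(domains), figsize=(4 * len(domains), 7), squeeze=False)
    for j, domain in enumerate(domains):
        for i, kind in enumerate(("global", "behavior_change")):
            path = out / f"{domain}_{kind}_cross_sectional.tsv" if kind == "global" else out / f"{domain}_behavior_change.tsv"
            ax = axes[i][j]
            if kind == "global":
                _, cross = akio.read_curve_tsv(out / f"{domain}_global_cross_sectional.tsv")
                _, longi = akio.read_curve_tsv(out / f"{domain}_global_longitudinal.tsv")
                ax.plot(change_ages, cross[0], label="cross-sectional")
                ax.plot(change_ages, longi[0], label="longitudinal")
                ax.set_ylabel("delta activation / 5 y")
            elif path.exists():
                _, curves = akio.read_curve_tsv(path)
                ax.plot(change_ages, curves[0], label="cross-sectional")
                ax.plot(change_ages, curves[1], label="longitudinal")
                ax.set_ylabel("delta performance (z) / 5 y")
            ax.set_title(domain)
            ax.set_xlabel("baseline age (y)")
            ax.legend(fontsize=7)
    fig.tight_layout()
    path = out / "change_curves.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    written.append(path)
    return written


def _versions() -> dict:
    import nibabel
    import scipy

    from . import __version__

    return {
        "agekernel": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "nibabel": nibabel.__version__,
    }
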