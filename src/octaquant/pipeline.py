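"""Reproducible end-to-end workflow: simulate -> metrics -> stats.

Three stages mirror the separation between imaging and statistics: simulate
writes a fixture directory (angiograms, FAZ outlines, truth, cohort table,
manifest), metrics turns a directory of angiograms into a per-eye metric
table, and stats runs the full cohort analysis.  Each stage is deterministic
under the configured seed and stamps its outputs with a hash of the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as qio
from . import regions, stats, synthetic

__all__ = ["PipelineConfig", "run_simulate", "run_metrics", "run_stats"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Knobs of the whole pipeline, loadable from a YAML/JSON file."""

    n_participants: int = 24
    seed: int = 0
    # region geometry (mm)
    inner_radius_mm: float = 0.5
    outer_radius_mm: float = 1.25
    # binarization
    binarize_window_px: int = 11
    binarize_offset: float = 0.08
    # fractal ladder
    min_box_px: int = 2
    max_box_divisor: int = 4
    # metric options
    capillary_only_vd: bool = False
    # statistics
    covariates: list[str] = field(default_factory=lambda: list(stats.DEFAULT_COVARIATES))
    alpha: float = 0.05
    outcome_family_size: int = 2
    specificity: float = 0.415
    quality_threshold: float = 7.0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not 0 < self.inner_radius_mm < self.outer_radius_mm:
            raise ValueError("need 0 < inner_radius_mm < outer_radius_mm")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.outcome_family_size < 1:
            raise ValueError("outcome_family_size must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_simulate(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Write a fixture directory: per-participant SCP/DCP scenes plus cohort.

    Layout: ``<id>_scp.png`` / ``<id>_dcp.png`` with JSON sidecars,
    ``<id>_<plexus>_faz.csv`` outlines, ``<id>_truth.json`` scalars,
    ``cohort.csv`` and ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    cohort_params = synthetic.CohortParams(
        n_per_group=_split_groups(config.n_participants), seed=int(rng.integers(2**31))
    )
    cohort, truth_effects = synthetic.generate_cohort(cohort_params)
    pids = []
    for i in range(config.n_participants):
        pid = f"S{i + 1:04d}"
        pids.append(pid)
        scene_seed = int(rng.integers(2**31))
        scp, dcp = synthetic.generate_scene_pair(scene_seed)
        for label, truth in (("scp", scp), ("dcp", dcp)):
            truth.image.participant_id = pid
            truth.image.eye = "OD"
            img_path = out / f"{pid}_{label}.png"
            qio.write_angiogram(truth.image, img_path)
            qio.write_faz_polygon(truth.faz_polygon, out / f"{pid}_{label}_faz.csv")
        with open(out / f"{pid}_truth.json", "w") as fh:
            json.dump(
                {
                    "scp_skeleton_length_mm": scp.skeleton_length_mm,
                    "dcp_skeleton_length_mm": dcp.skeleton_length_mm,
                    "scp_faz_area_mm2": scp.faz_polygon.area_mm2,
                    "dcp_faz_area_mm2": dcp.faz_polygon.area_mm2,
                    "scene_seed": scene_seed,
                },
                fh,
                indent=1,
            )
    cohort = cohort.iloc[: config.n_participants].copy()
    cohort["participant_id"] = pids
    # the cohort table carries membership and covariates; outcome metrics
    # enter the statistics stage from the metrics CSV measured off the images
    cohort = cohort.drop(columns=[c for c in synthetic.METRIC_NAMES if c in cohort.columns])
    cohort.to_csv(out / "cohort.csv", index=False)
    manifest = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "n_participants": config.n_participants,
        "participants": pids,
        "true_effects": truth_effects,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def _split_groups(n: int) -> dict[str, int]:
    """Split n participants across AD/MCI/control in roughly 24:37:29."""
    weights = {"AD": 24, "MCI": 37, "control": 29}
    total = sum(weights.values())
    out = {g: max(1, round(n * w / total)) for g, w in weights.items()}
    # fix rounding drift on the largest group
    drift = n - sum(out.values())
    out["MCI"] = max(1, out["MCI"] + drift)
    return out


def run_metrics(
    config: PipelineConfig, fixture_dir: str | Path, out_csv: str | Path
) -> tuple[Path, int]:
    """Compute a MetricRecord per participant from a fixture directory.

    Per-image failures are logged and skipped; the function returns the
    output path and the number of failures (callers may map failures > 0 to
    a 'partial' exit status).
    """
    fixture_dir = Path(fixture_dir)
    records = []
    failures = 0
    scp_images = sorted(fixture_dir.glob("*_scp.png")) + sorted(fixture_dir.glob("*_scp.tif"))
    for scp_path in scp_images:
        pid = scp_path.name.rsplit("_scp", 1)[0]
        try:
            scp = qio.read_angiogram(scp_path, scp_path.with_suffix(".json"))
            scp_faz = qio.read_faz_polygon(fixture_dir / f"{pid}_scp_faz.csv")
            dcp_path = scp_path.with_name(scp_path.name.replace("_scp", "_dcp"))
            dcp = dcp_faz = None
            if dcp_path.exists():
                dcp = qio.read_angiogram(dcp_path, dcp_path.with_suffix(".json"))
                dcp_faz = qio.read_faz_polygon(fixture_dir / f"{pid}_dcp_faz.csv")
            rec = regions.compute_metric_record(
                scp,
                dcp,
                scp_faz,
                dcp_faz,
                inner_radius_mm=config.inner_radius_mm,
                outer_radius_mm=config.outer_radius_mm,
                capillary_only_vd=config.capillary_only_vd,
                binarize_kwargs={
                    "window_px": config.binarize_window_px,
                    "offset": config.binarize_offset,
                },
            )
            records.append(rec)
            logger.info("metrics: %s ok (vd_scp=%.3f)", pid, rec.vd_scp or float("nan"))
        except Exception:
            failures += 1
            logger.exception("metrics: failed on participant %s; skipping", pid)
    qio.write_metrics(records, out_csv)
    return Path(out_csv), failures


def run_stats(
    config: PipelineConfig,
    metrics_csv: str | Path,
    cohort_csv: str | Path,
    out_dir: str | Path,
) -> dict:
    """Join metrics onto the cohort table and run the full statistics stage.

    Produces the baseline comparison table, a covariate-adjusted model per
    metric (publication-style CSV), ROC results for discriminating cases from
    controls, paired AUC comparisons among the top markers, a post hoc power
    report, and (when exclusion flags are present) the eligibility tally.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics = pd.read_csv(metrics_csv)
    cohort = pd.read_csv(cohort_csv)

    drop = [c for c in metrics.columns if c in cohort.columns and c != "participant_id"]
    merged = cohort.drop(columns=drop).merge(metrics, on="participant_id", how="inner")
    orphans_m = sorted(set(metrics["participant_id"]) - set(cohort["participant_id"]))
    orphans_c = sorted(set(cohort["participant_id"]) - set(metrics["participant_id"]))
    if orphans_m or orphans_c:
        raise ValueError(
            f"participant id mismatch between tables; metrics-only={orphans_m}, cohort-only={orphans_c}"
        )
    covariates = [c for c in config.covariates if c in merged.columns]
    missing_cov = [c for c in config.covariates if c not in merged.columns]
    if missing_cov:
        raise ValueError(f"cohort table is missing covariate column(s): {missing_cov}")

    results: dict = {"config_hash": config.hash(), "n": len(merged)}

    # eligibility tally (optional; only when enrollment flags are present)
    if {"fatigue", "eye_disease", "signal_strength_od", "signal_strength_os"} <= set(cohort.columns):
        included, tally = stats.apply_eligibility_filters(cohort, config.quality_threshold)
        results["eligibility"] = {"included": len(included), "excluded": tally}

    # baseline characteristics
    baseline_rows = []
    for var, kind in [
        ("age", "continuous"),
        ("female", "categorical"),
        ("chinese", "categorical"),
        ("diabetes", "categorical"),
        ("sbp", "continuous"),
        ("dbp", "continuous"),
        ("signal_strength", "continuous"),
    ]:
        if var in merged.columns:
            stat, p = stats.baseline_comparison(merged, var, kind=kind)
            baseline_rows.append({"variable": var, "statistic": stat, "p_value": p})
    baseline = pd.DataFrame(baseline_rows)
    baseline.to_csv(out / "baseline.csv", index=False)
    results["baseline"] = baseline.to_dict(orient="records")

    # adjusted models, Bonferroni within outcome families
    threshold = stats.bonferroni_threshold(config.alpha, config.outcome_family_size)
    results["bonferroni_threshold"] = threshold
    metric_cols = [m for m in synthetic.METRIC_NAMES if m in merged.columns]
    model_rows = []
    results["adjusted_models"] = {}
    for m in metric_cols:
        fit = stats.fit_adjusted_model(merged, m, covariates=covariates, alpha=config.alpha)
        frame = fit.to_row_frame()
        frame["significant"] = frame["p_value"] < threshold
        model_rows.append(frame)
        results["adjusted_models"][m] = {
            "beta": fit.beta,
            "ci": {g: list(v) for g, v in fit.ci.items()},
            "p_value": fit.p_value,
            "adjusted_mean": fit.adjusted_mean,
            "n": fit.n,
        }
    if model_rows:
        pd.concat(model_rows, ignore_index=True).to_csv(out / "adjusted_models.csv", index=False)

    # ROC: cases (AD or MCI) vs controls; markers oriented so impairment scores high
    labels = (merged["group"] != "control").astype(int).to_numpy()
    roc_markers = [m for m in ("fd_scp", "vd_scp", "vd_dcp") if m in merged.columns]
    results["roc"] = {}
    if labels.min() != labels.max():
        for m in roc_markers:
            scores = -merged[m].to_numpy(dtype=float)  # lower metric -> more impaired
            r = stats.roc_auc(scores, labels)
            sens = stats.sensitivity_at_specificity(scores, labels, config.specificity)
            results["roc"][m] = {
                "auc": r.auc,
                "sensitivity_at_specificity": {str(config.specificity): sens},
            }
        pairs = {}
        for i in range(len(roc_markers)):
            for j in range(i + 1, len(roc_markers)):
                a, b = roc_markers[i], roc_markers[j]
                delta, p = stats.compare_auc_paired(
                    -merged[a].to_numpy(float), -merged[b].to_numpy(float), labels
                )
                pairs[f"{a} vs {b}"] = {"delta_auc": delta, "p_value": p}
        results["roc"]["paired_comparisons"] = pairs

    # post hoc power, AD vs control per metric, from raw means and SDs
    power = {}
    ad = merged[merged["group"] == "AD"]
    ctrl = merged[merged["group"] == "control"]
    if len(ad) >= 2 and len(ctrl) >= 2:
        for m in metric_cols:
            power[m] = stats.posthoc_power(
                stats.PowerInputs(
                    mean1=float(ad[m].mean()),
                    sd1=float(ad[m].std(ddof=1)),
                    n1=len(ad),
                    mean2=float(ctrl[m].mean()),
                    sd2=float(ctrl[m].std(ddof=1)),
                    n2=len(ctrl),
                    alpha=config.alpha,
                )
            )
    results["posthoc_power"] = power

    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True, default=float)
    return results
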