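"""End-to-end orchestration: synthetic cohort -> features -> screening ->
thermal safety sweep, with reproducible artifacts.

Every stochastic stage receives an explicit seed from the run configuration;
a manifest (config hash, package versions, seeds) makes any artifact
reproducible bit-for-bit.  Plots are advisory; the CSV/JSON tables are the
tested surface.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic, thermal
from .features import FeatureVector, extract_features
from .images import depth_profile, save_image_png, save_mask_png
from .screening import abs_mean_difference_ranking, screen_features
from .thermal import (PROTOCOL_GRID, SonicationProtocol, TissueStack,
                      TransducerSpec, default_abdominal_stack, safety_report,
                      simulate_protocol, thermal_dose)


@dataclass
class RunConfig:
    out_dir: str = "echopanc_run"
    seed: int = 0
    n_dm: int = 11
    n_non_dm: int = 11
    images_per_patient: int = 2
    alpha: float = 0.05
    n_boot: int = 2000
    exclude_from_ranking: tuple = ("area",)
    run_synth: bool = True
    run_features: bool = True
    run_screening: bool = True
    run_simulation: bool = True
    make_plots: bool = True
    sweep_intensities: tuple = PROTOCOL_GRID["intensities_w_cm2"]
    sweep_duties: tuple = PROTOCOL_GRID["duty_factors"]
    sweep_durations: tuple = PROTOCOL_GRID["durations_min"]
    sim_dr_mm: float = 0.5
    sim_dz_mm: float = 0.5

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("exclude_from_ranking", "sweep_intensities",
                    "sweep_duties", "sweep_durations"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def digest(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def cohort_feature_table(entries) -> pd.DataFrame:
    """One row of features + metadata per (image, mask, label) entry."""
    rows = []
    for k, (image, mask, label) in enumerate(entries):
        fv = extract_features(image, mask)
        row = dict(patient_id=image.patient_id, image_index=k, label=label,
                   region=mask.region_label)
        row.update(fv.as_dict())
        row["degenerate_flags"] = ";".join(fv.degenerate_flags)
        rows.append(row)
    return pd.DataFrame(rows)


def protocol_sweep(stack: TissueStack | None = None,
                   transducer: TransducerSpec | None = None,
                   intensities=PROTOCOL_GRID["intensities_w_cm2"],
                   duties=PROTOCOL_GRID["duty_factors"],
                   durations=PROTOCOL_GRID["durations_min"],
                   dr_mm: float = 0.5, dz_mm: float = 0.5) -> pd.DataFrame:
    """Safety matrix over the protocol grid: one bioheat simulation per
    (intensity, duty factor, duration) cell.

    Per-cell failures are recorded in the ``error`` column and the sweep
    continues."""
    stack = stack or default_abdominal_stack()
    transducer = transducer or TransducerSpec()
    rows = []
    for inten in intensities:
        for duty in duties:
            for dur in durations:
                proto = SonicationProtocol(surface_intensity_w_cm2=inten,
                                           duty_factor=duty, duration_min=dur)
                row = dict(intensity_w_cm2=inten, duty_factor=duty,
                           duration_min=dur, error="")
                try:
                    fld = simulate_protocol(stack, transducer, proto,
                                            dr_mm=dr_mm, dz_mm=dz_mm)
                    dose = thermal_dose(fld)
                    rep = safety_report(dose, fld, stack, protocol=proto)
                    row.update(
                        peak_temp_c=fld.peak_temperature,
                        peak_pancreas_temp_c=fld.peak_in_tissue("pancreas"),
                        max_pancreas_cem43=dose.max_in_tissue("pancreas"),
                        max_cem43=float(dose.cem43_min.max()),
                        verdict=rep["overall"],
                        high_duty_avoid_flag=rep["high_duty_avoid_flag"])
                except Exception as exc:  # pragma: no cover - defensive
                    row["error"] = f"{type(exc).__name__}: {exc}"
                    row["verdict"] = "error"
                rows.append(row)
    return pd.DataFrame(rows)


def _plot_outputs(out: Path, features: pd.DataFrame, screening: pd.DataFrame,
                  ranking: pd.DataFrame, fields: dict) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    made = []
    retained = screening[screening.retained].sort_values("p_value")
    top = retained.head(8)["feature"].tolist()
    if top:
        fig, axes = plt.subplots(2, 4, figsize=(14, 6))
        for ax, f in zip(axes.ravel(), top):
            groups = [features.loc[features.label == lab, f]
                      for lab in ("DM", "non-DM")]
            ax.boxplot(groups, tick_labels=["DM", "non-DM"])
            ax.set_title(f, fontsize=8)
        for ax in axes.ravel()[len(top):]:
            ax.axis("off")
        fig.tight_layout()
        fig.savefig(out / "feature_boxplots.png", dpi=120)
        plt.close(fig)
        made.append("feature_boxplots.png")

    fig, axes = plt.subplots(1, 3, figsize=(15, 5))
    for ax, col, title in zip(
            axes, ["spearman_rho", "neglog10_p", "mi_score"],
            ["Spearman rho vs DM", "-log10(p)", "Mutual information (nats)"]):
        s = screening.sort_values(col)
        ax.barh(s.feature, s[col])
        ax.set_title(title)
        ax.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(out / "screening_rankings.png", dpi=120)
    plt.close(fig)
    made.append("screening_rankings.png")

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.barh(ranking.feature, ranking.range_adjusted_abs_mean_diff)
    ax.set_title("Range-adjusted |mean difference|")
    ax.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(out / "abs_mean_difference.png", dpi=120)
    plt.close(fig)
    made.append("abs_mean_difference.png")

    if "auc" in screening.columns:
        from .screening import roc_curve_points
        top5 = screening.reindex(
            screening.auc.sub(0.5).abs().sort_values(ascending=False).index
        ).head(5)
        fig, ax = plt.subplots(figsize=(5, 5))
        y = (features.label == "DM").astype(int)
        for f in top5.feature:
            pts = roc_curve_points(features[f], y)
            ax.plot(pts.fpr, pts.tpr, label=f, lw=1)
        ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.set_xlabel("FPR")
        ax.set_ylabel("TPR")
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(out / "roc_overlay.png", dpi=120)
        plt.close(fig)
        made.append("roc_overlay.png")

    if fields:
        fig, ax = plt.subplots(figsize=(6, 4))
        for name, fld in fields.items():
            ax.plot(fld.times_s / 60.0, fld.on_axis.max(axis=1), label=name)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("peak on-axis T (degC)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out / "heating_curves.png", dpi=120)
        plt.close(fig)
        made.append("heating_curves.png")
    return made


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the artifact manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = dict(config=dataclasses.asdict(config),
                          config_hash=config.digest(), stages={}, outputs=[])

    entries = features = screening = None
    if config.run_synth:
        cohort = synthetic.CohortSpec(
            n_dm=config.n_dm, n_non_dm=config.n_non_dm,
            images_per_patient=config.images_per_patient,
            master_seed=config.seed)
        entries, meta = synthetic.generate_cohort(cohort)
        meta.to_csv(out / "cohort_metadata.csv", index=False)
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for k, (image, mask, _label) in enumerate(entries):
            save_image_png(image, img_dir / f"{image.patient_id}_{k:03d}.png")
            save_mask_png(mask, img_dir / f"{image.patient_id}_{k:03d}_mask.png")
        summary, frac = depth_profile((im, mk) for im, mk, _ in entries)
        summary.assign(depths=summary.depths.map(
            lambda d: ";".join(f"{x:.4f}" for x in d))).to_csv(
                out / "depth_profile.csv", index=False)
        frac.to_csv(out / "region_visualization.csv", index=False)
        manifest["stages"]["synth"] = dict(n_images=len(entries))
        manifest["outputs"] += ["cohort_metadata.csv", "depth_profile.csv",
                                "region_visualization.csv"]
    else:
        manifest["stages"]["synth"] = "skipped"

    if config.run_features and entries is not None:
        features = cohort_feature_table(entries)
        features.to_csv(out / "features.csv", index=False)
        manifest["stages"]["features"] = dict(n_rows=len(features))
        manifest["outputs"].append("features.csv")
    else:
        manifest["stages"]["features"] = "skipped"

    ranking = None
    if config.run_screening and features is not None:
        screening = screen_features(
            features[list(FeatureVector.FEATURE_NAMES) + ["label"]],
            alpha=config.alpha, n_boot=config.n_boot, seed=config.seed)
        screening.to_csv(out / "screening.csv", index=False)
        ranking = abs_mean_difference_ranking(
            features[list(FeatureVector.FEATURE_NAMES) + ["label"]],
            exclude=tuple(config.exclude_from_ranking))
        ranking.to_csv(out / "abs_mean_difference.csv", index=False)
        with open(out / "screening_summary.json", "w") as fh:
            json.dump(dict(
                alpha=config.alpha,
                n_retained=int(screening.retained.sum()),
                retained=screening.loc[screening.retained, "feature"].tolist(),
                top_auc=screening.sort_values("auc", ascending=False)
                .head(5)[["feature", "auc", "auc_ci_low", "auc_ci_high"]]
                .to_dict("records")), fh, indent=2)
        manifest["stages"]["screening"] = dict(
            n_retained=int(screening.retained.sum()))
        manifest["outputs"] += ["screening.csv", "abs_mean_difference.csv",
                                "screening_summary.json"]
    else:
        manifest["stages"]["screening"] = "skipped"

    fields = {}
    if config.run_simulation:
        stack = default_abdominal_stack()
        sweep = protocol_sweep(stack, TransducerSpec(),
                               intensities=config.sweep_intensities,
                               duties=config.sweep_duties,
                               durations=config.sweep_durations,
                               dr_mm=config.sim_dr_mm, dz_mm=config.sim_dz_mm)
        sweep.to_csv(out / "protocol_sweep.csv", index=False)
        demo_proto = SonicationProtocol(5.0, 0.5, 3.0)
        fld = simulate_protocol(stack, TransducerSpec(), demo_proto,
                                dr_mm=config.sim_dr_mm, dz_mm=config.sim_dz_mm)
        fields["focused 5 W/cm2, 50% duty"] = fld
        dose = thermal_dose(fld)
        with open(out / "safety_report.json", "w") as fh:
            json.dump(safety_report(dose, fld, stack, protocol=demo_proto),
                      fh, indent=2)
        pd.DataFrame(fld.on_axis, columns=[f"z_{z:.2f}cm" for z in fld.z_cm]) \
            .assign(time_s=fld.times_s).to_csv(out / "on_axis_temperature.csv",
                                               index=False)
        manifest["stages"]["simulation"] = dict(n_sweep_cells=len(sweep))
        manifest["outputs"] += ["protocol_sweep.csv", "safety_report.json",
                                "on_axis_temperature.csv"]
    else:
        manifest["stages"]["simulation"] = "skipped"

    if config.make_plots and features is not None and screening is not None:
        manifest["outputs"] += _plot_outputs(out, features, screening,
                                             ranking, fields)

    import skimage
    import sklearn

    import echopanc
    manifest["versions"] = dict(
        echopanc=echopanc.__version__, numpy=np.__version__,
        pandas=pd.__version__, scikit_image=skimage.__version__,
        scikit_learn=sklearn.__version__)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
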