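"""End-to-end orchestration: QC → group ICA → post-processing → sFC → dFC → stats.

``run_pipeline`` executes the full analysis on a synthetic cohort from one
:class:`RunConfig`, writing every stage's outputs plus a JSON manifest that
records seeds, per-subject graphical-lasso penalties, the selected number of
states and the QC exclusions — enough to reproduce the run exactly.

A single master seed is expanded into per-stage seeds with
``numpy.random.SeedSequence(master).spawn(...)`` in a fixed stage order
(simulate, ICASSO, autoencoder, k-means), so individual stochastic stages can
be isolated and re-run deterministically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gica, groupstats, qc as qc_mod, states as states_mod, staticfc
from .autoencoder import Autoencoder, AutoencoderSpec, standardize_features
from .simulate import Cohort, SubjectTimeSeries, SyntheticConfig, generate_cohort
from .timecourse import process_timecourse
from .windows import WindowSpec, WindowedFC, select_lambda, sliding_window_fc

__all__ = ["RunConfig", "discard_initial_volumes", "run_pipeline", "run_dfc"]

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "icasso", "autoencoder", "kmeans")


@dataclass
class RunConfig:
    """One configuration object for the whole pipeline."""

    outdir: str = "dynconn_out"
    master_seed: int = 0
    discard_volumes: int = 5
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    autoencoder: AutoencoderSpec = field(default_factory=AutoencoderSpec)
    fd_threshold: float = qc_mod.DEFAULT_FD_THRESHOLD_MM
    max_disp_threshold: float = qc_mod.DEFAULT_MAX_DISP_THRESHOLD_MM
    n_subject_pcs: int = 30
    n_group_pcs: int = 12
    n_ica_components: int = 10
    n_ica_runs: int = 10
    iq_threshold: float = 0.8
    k_range: tuple[int, int] = (2, 9)   # inclusive candidate range for the state count
    fixed_k: int | None = None          # skip elbow selection when set
    postprocess_timecourses: bool = True
    lambda_grid: tuple[float, ...] | None = None  # None → module default
    use_ground_truth_sources: bool = False  # dFC on generator source courses (skips GICA)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub_cls in (
            ("synthetic", SyntheticConfig), ("window", WindowSpec),
            ("autoencoder", AutoencoderSpec),
        ):
            if key in raw and isinstance(raw[key], dict):
                if "encoder_units" in raw.get(key, {}):
                    raw[key]["encoder_units"] = tuple(raw[key]["encoder_units"])
                raw[key] = sub_cls(**raw[key])
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        if "lambda_grid" in raw and raw["lambda_grid"] is not None:
            raw["lambda_grid"] = tuple(raw["lambda_grid"])
        return cls(**raw)


def discard_initial_volumes(ts: SubjectTimeSeries, n: int = 5) -> SubjectTimeSeries:
    """Drop the first ``n`` volumes (steady-state magnetization rule); order preserved."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= ts.n_timepoints:
        raise ValueError(f"cannot discard {n} of {ts.n_timepoints} volumes")
    return SubjectTimeSeries(
        data=ts.data[:, n:], tr_seconds=ts.tr_seconds, subject_id=ts.subject_id
    )


def _stage_seeds(master_seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


def run_dfc(
    timecourses: dict[str, np.ndarray],
    window: WindowSpec,
    ae_spec: AutoencoderSpec,
    k_range: tuple[int, int] = (2, 9),
    fixed_k: int | None = None,
    kmeans_seed: int = 0,
    lambda_grid: tuple[float, ...] | None = None,
) -> dict:
    """Sliding-window + deep-clustering dynamic FC on a set of subject time courses.

    Per subject: cross-validated graphical-lasso penalty, tapered windowed FC.
    Pooled across subjects: per-edge standardization, autoencoder encoding,
    exemplar selection, elbow choice of k (unless ``fixed_k``), two-stage
    k-means, and per-subject state temporal metrics.
    """
    lambdas: dict[str, float] = {}
    wfc: dict[str, WindowedFC] = {}
    for sid, tc in timecourses.items():
        kwargs = {} if lambda_grid is None else {"lambda_grid": lambda_grid}
        lam = select_lambda(tc, window, **kwargs)
        lambdas[sid] = lam
        wfc[sid] = sliding_window_fc(tc, window, lambda_l1=lam)

    sids = list(wfc)
    stacked = np.vstack([wfc[s].windows for s in sids])
    std, mu, sd = standardize_features(stacked)
    ae = Autoencoder(std.shape[1], ae_spec).fit(std)
    encoded_all = ae.encode(std)

    exemplar_rows = []
    offset = 0
    fallbacks = 0
    for sid in sids:
        idx, fell_back = states_mod.select_exemplars(wfc[sid].windows)
        fallbacks += int(fell_back)
        exemplar_rows.append(encoded_all[offset + idx])
        offset += wfc[sid].n_windows
    encoded_exemplars = np.vstack(exemplar_rows)

    if fixed_k is None:
        k, ratios, models, confident = states_mod.elbow_select_k(
            encoded_all, encoded_exemplars,
            k_range=range(k_range[0], k_range[1] + 1), seed=kmeans_seed,
        )
        model = models[k]
    else:
        k = fixed_k
        model = states_mod.cluster_states(
            encoded_all, encoded_exemplars, k, seed=kmeans_seed
        )
        ratios, confident = {}, True

    assignments: dict[str, np.ndarray] = {}
    offset = 0
    for sid in sids:
        n_w = wfc[sid].n_windows
        assignments[sid] = model.assignments[offset:offset + n_w]
        offset += n_w
    metrics = states_mod.state_metrics(assignments, window, k, windowed=wfc)
    return {
        "windowed": wfc,
        "lambdas": lambdas,
        "autoencoder": ae,
        "encoded": encoded_all,
        "state_model": model,
        "k": k,
        "ratio_curve": ratios,
        "elbow_confident": confident,
        "assignments": assignments,
        "metrics": metrics,
        "exemplar_fallbacks": fallbacks,
        "feature_mean": mu,
        "feature_sd": sd,
    }


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> dict:
    """Run the full analysis and write all stage outputs under ``config.outdir``.

    Stage order: simulate (unless a cohort is passed) → motion QC and
    exclusions → group ICA (ICASSO + back-reconstruction) → time-course
    post-processing → static FC → windowed FC + deep clustering → group
    statistics. Each stage consumes only prior-stage outputs; any failure
    surfaces as an exception naming the stage. Re-running with the same
    config reproduces the deterministic outputs byte-identically.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.master_seed)
    manifest: dict = {"master_seed": config.master_seed, "stage_seeds": seeds}

    def _stage(name: str):
        logger.info("pipeline stage: %s", name)

    # --- simulate ---------------------------------------------------------
    _stage("simulate")
    if cohort is None:
        syn = dataclasses.replace(config.synthetic, seed=seeds["simulate"])
        cohort = generate_cohort(syn)
        manifest["synthetic"] = dataclasses.asdict(syn)

    # --- quality control --------------------------------------------------
    _stage("qc")
    qcs = [
        qc_mod.framewise_displacement(
            qc_mod.MotionTrace(
                translations=cohort.truth.motion_traces[s.subject_id][3:],
                rotations=cohort.truth.motion_traces[s.subject_id][:3],
                tr_seconds=s.tr_seconds, subject_id=s.subject_id,
            )
        )
        for s in cohort.subjects
    ]
    kept_qc, excl_qc = qc_mod.apply_exclusions(
        qcs, fd_threshold=config.fd_threshold,
        max_disp_threshold=config.max_disp_threshold,
    )
    qc_mod.qc_table(qcs).to_csv(outdir / "qc.tsv", sep="\t", index=False)
    kept_ids = {q.subject_id for q in kept_qc}
    subjects = [s for s in cohort.subjects if s.subject_id in kept_ids]
    if not subjects:
        raise RuntimeError("qc stage excluded every subject; nothing to analyse")
    manifest["qc"] = {
        "excluded": {q.subject_id: q.reason for q in excl_qc},
        "n_kept": len(subjects),
    }
    table = cohort.table[cohort.table["subject_id"].isin(kept_ids)].reset_index(drop=True)

    # --- component time courses ------------------------------------------
    if config.use_ground_truth_sources:
        _stage("sources")
        courses = {
            s.subject_id: cohort.truth.source_timecourses[s.subject_id]
            for s in subjects
        }
        manifest["gica"] = {"skipped": True}
    else:
        _stage("gica")
        spcas = [gica.subject_pca(s, config.n_subject_pcs) for s in subjects]
        gpca = gica.group_pca_concat(spcas, config.n_group_pcs, seed=seeds["icasso"])
        result = gica.icasso_stability(
            gpca, config.n_ica_components, n_runs=config.n_ica_runs,
            seed=seeds["icasso"], iq_threshold=config.iq_threshold,
            n_subject_pcs=config.n_subject_pcs,
        )
        gica.back_reconstruct(result, gpca, spcas, subjects)
        np.savetxt(outdir / "group_maps.tsv", result.group_maps, delimiter="\t")
        keep = np.flatnonzero(result.retained)
        if keep.size == 0:
            logger.warning(
                "no component exceeded the stability threshold I_q > %.2f; "
                "keeping all %d components", result.iq_threshold,
                result.group_maps.shape[0],
            )
            keep = np.arange(result.group_maps.shape[0])
        report = pd.DataFrame({
            "component": np.arange(1, result.group_maps.shape[0] + 1),
            "stability_iq": result.stability_iq,
            "retained": result.retained,
        })
        metrics_rows = []
        courses = {}
        for s in subjects:
            tc_all = result.subject_timecourses[s.subject_id]  # (T, C)
            courses[s.subject_id] = tc_all[:, keep].T
        # spectral screening on the first subject's retained courses (cohort-level report)
        for c in keep:
            mets = [
                gica.spectral_icn_metrics(
                    result.subject_timecourses[s.subject_id][:, c], s.tr_seconds
                )
                for s in subjects
            ]
            metrics_rows.append({
                "component": int(c + 1),
                "power_ratio": float(np.median([m.power_ratio for m in mets])),
                "dynamic_range": float(np.median([m.dynamic_range for m in mets])),
                "is_icn": bool(np.median([m.is_icn for m in mets]) > 0.5),
            })
        metrics_df = pd.DataFrame(
            metrics_rows,
            columns=["component", "power_ratio", "dynamic_range", "is_icn"],
        )
        report.merge(metrics_df, on="component", how="left").to_csv(
            outdir / "component_report.tsv", sep="\t", index=False
        )
        manifest["gica"] = {
            "n_subject_pcs": config.n_subject_pcs,
            "n_group_pcs": config.n_group_pcs,
            "n_components": config.n_ica_components,
            "n_runs_converged": result.n_ica_runs,
            "stability_iq": [float(v) for v in result.stability_iq],
            "n_retained": int(result.retained.sum()),
        }

    # --- post-processing --------------------------------------------------
    if config.postprocess_timecourses:
        _stage("postproc")
        spikes = {}
        for sid, tc in courses.items():
            rows = []
            n_spikes = 0
            for row in tc:
                proc = process_timecourse(row, cohort.config.tr_seconds)
                rows.append(proc.values)
                n_spikes += len(proc.spike_indices)
            courses[sid] = np.vstack(rows)
            spikes[sid] = n_spikes
        manifest["postproc"] = {"spikes_replaced": spikes}

    # --- static FC --------------------------------------------------------
    _stage("sfc")
    sfc = {sid: staticfc.static_fc(tc) for sid, tc in courses.items()}
    sfc_dir = outdir / "sfc"
    sfc_dir.mkdir(exist_ok=True)
    for sid, fc in sfc.items():
        staticfc.write_fc(fc, sfc_dir / f"{sid}_sfc.tsv")
    sfc_edges = pd.DataFrame(
        {sid: staticfc.edge_vector(fc.z_values) for sid, fc in sfc.items()}
    ).T
    sfc_edges.columns = [f"e{i}" for i in range(sfc_edges.shape[1])]

    # --- dynamic FC -------------------------------------------------------
    _stage("dfc")
    window = dataclasses.replace(config.window, tr_seconds=cohort.config.tr_seconds)
    ae_spec = dataclasses.replace(config.autoencoder, seed=seeds["autoencoder"])
    dfc = run_dfc(
        courses, window, ae_spec, k_range=config.k_range, fixed_k=config.fixed_k,
        kmeans_seed=seeds["kmeans"], lambda_grid=config.lambda_grid,
    )
    manifest["dfc"] = {
        "lambda_l1": {sid: float(l) for sid, l in dfc["lambdas"].items()},
        "n_windows": {sid: int(w.n_windows) for sid, w in dfc["windowed"].items()},
        "k": int(dfc["k"]),
        "elbow_confident": bool(dfc["elbow_confident"]),
        "ratio_curve": {str(k): float(v) for k, v in dfc["ratio_curve"].items()},
        "autoencoder_final_mse": float(dfc["autoencoder"].final_mse),
    }
    metrics = dfc["metrics"]
    metrics.dwell_time.to_csv(outdir / "dwell_time_seconds.tsv", sep="\t")
    metrics.fractional_occupancy.to_csv(outdir / "fractional_occupancy.tsv", sep="\t")
    pd.DataFrame(dfc["assignments"]).to_csv(
        outdir / "state_assignments.tsv", sep="\t", index=False
    )

    # --- group statistics -------------------------------------------------
    _stage("stats")
    sfc_tests = groupstats.residual_ttest(sfc_edges, table)
    sfc_tests.to_csv(outdir / "sfc_group_tests.tsv", sep="\t", index=False)
    metric_rows = []
    for s in range(1, dfc["k"] + 1):
        col = f"state_{s}"
        for name, frame in (
            ("dwell_time", metrics.dwell_time),
            ("fractional_occupancy", metrics.fractional_occupancy),
        ):
            try:
                t, p = groupstats.ancova_group_effect(frame[col], table)
            except ValueError as err:
                logger.warning("stats: state %d %s skipped (%s)", s, name, err)
                t, p = np.nan, np.nan
            metric_rows.append({"state": s, "metric": name, "t": t, "p": p})
    pd.DataFrame(metric_rows).to_csv(
        outdir / "temporal_metric_tests.tsv", sep="\t", index=False
    )
    manifest["stats"] = {
        "n_sfc_edges": int(len(sfc_tests)),
        "n_sfc_significant_fdr": int(sfc_tests["significant_fdr"].sum()),
    }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {
        "cohort": cohort, "table": table, "qc": qcs, "sfc": sfc,
        "sfc_tests": sfc_tests, "dfc": dfc, "manifest": manifest,
    }
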