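"""End-to-end composition: simulate -> preprocess -> connect -> significance ->
cohort statistics, with a JSON manifest per stage.

Reruns with the same config are bit-identical: every stochastic step draws
from a generator seeded deterministically from ``config.seed``.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import io
from .config import PipelineConfig
from .connectivity import SpectralGrid, average_hemispheres, tpdc
from .cohort import run_mediation_battery, run_pca
from .preprocess import ROI_LABELS, default_roi_map, preprocess_recording
from .significance import (
    BootstrapConfig,
    make_stationary_statistic,
    significance_test,
    summarize_connections,
)
from .synthetic import (
    ArtifactSpec,
    CohortSpec,
    generate_cohort,
    generate_network,
    simulate_roi_timeseries,
    synthesize_raw_recording,
)

__all__ = ["run_pipeline"]


def run_pipeline(config: PipelineConfig, output_dir=None) -> dict:
    """Run the full synthetic-study pipeline and write all outputs.

    Stage 1 simulates a ground-truth network and per-subject recordings;
    stage 2 preprocesses them to ROI series; stage 3 estimates TPDC; stage 4
    applies bootstrap + TRT significance; stage 5 generates the cohort tables
    and runs PCA + the mediation battery.  Returns a results bundle dict.
    """
    config.validate()
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    n_samples = int(round(config.duration_s * config.fs))
    roi_map = default_roi_map()
    grid = SpectralGrid(fs=config.fs, n_freq=config.n_freq, band=config.band)

    # --- stage 1: simulate -------------------------------------------------
    network = generate_network(
        n_rois=len(ROI_LABELS), edge_density=config.edge_density, seed=seed
    )
    (out / "network.json").write_text(json.dumps(network.to_dict(), indent=2) + "\n")
    recordings = {}
    for subj in range(config.n_nirs_subjects):
        latent, _ = simulate_roi_timeseries(
            network, n_samples=n_samples, fs=config.fs, seed=seed + 1000 + subj
        )
        rec = synthesize_raw_recording(
            latent,
            roi_map=roi_map,
            fs=config.fs,
            artifact_spec=ArtifactSpec(),
            seed=seed + 2000 + subj,
        )
        path = out / f"subject{subj:02d}.snirf"
        io.write_snirf(rec, path)
        recordings[subj] = rec
    io.write_manifest(
        out / "simulate.manifest.json",
        "simulate",
        {
            "seed": seed,
            "n_subjects": config.n_nirs_subjects,
            "fs": config.fs,
            "n_samples": n_samples,
            "edge_density": config.edge_density,
        },
    )

    # --- stages 2-4: preprocess, connect, significance ---------------------
    subject_results = []
    boot_cfg = BootstrapConfig(
        n_iterations=config.bootstrap.n_iterations,
        n_windows=config.bootstrap.n_windows,
        percentile=config.bootstrap.percentile,
        trt_percentile=config.bootstrap.trt_percentile,
        seed=seed + 3000,
    )
    dekf_params = {
        "state_noise": config.dekf.state_noise,
        "weight_noise": config.dekf.weight_noise,
        "obs_noise": config.dekf.obs_noise,
        "init_scale": config.dekf.init_scale,
        "burn_in": config.dekf.burn_in,
    }
    for subj, rec in recordings.items():
        rois = preprocess_recording(
            rec,
            roi_map=roi_map,
            chromophore=config.chromophore,
            motion_params={"wavelet_alpha": config.wavelet_alpha},
        )
        per_hemi = {}
        for hemi, series in rois.items():
            per_hemi[hemi] = tpdc(
                series.series,
                fs=config.fs,
                order=config.order,
                grid=grid,
                dekf_params=dekf_params,
                order_range=config.order_range,
                keep_tensor=False,
                roi_labels=ROI_LABELS,
            )
        if config.hemisphere_policy == "average" and len(per_hemi) == 2:
            result = average_hemispheres(per_hemi["left"], per_hemi["right"])
            sig_series = rois["left"].series  # significance on one probe's series
        else:
            hemi = (
                config.hemisphere_policy
                if config.hemisphere_policy in per_hemi
                else next(iter(per_hemi))
            )
            result = per_hemi[hemi]
            sig_series = rois[hemi].series
        io.write_connectivity_tsv(
            result.band_time_average, ROI_LABELS, out / f"subject{subj:02d}_tpdc.tsv"
        )
        order = config.order or result_order_guess(result, sig_series, config)
        statistic = make_stationary_statistic(order, grid)
        sig = significance_test(
            sig_series,
            statistic,
            config=boot_cfg,
            roi_labels=ROI_LABELS,
            observed=result.band_time_average,
        )
        sig.to_frame().to_csv(
            out / f"subject{subj:02d}_significance.tsv", sep="\t", index=False
        )
        subject_results.append(sig)
    summary = summarize_connections(subject_results)
    summary.to_csv(out / "connection_summary.tsv", sep="\t", index=False)
    io.write_manifest(
        out / "connectivity.manifest.json",
        "connectivity+significance",
        {
            "band": config.band,
            "n_freq": config.n_freq,
            "bootstrap": config.bootstrap.__dict__,
            "dekf": {k: v for k, v in dekf_params.items()},
            "hemisphere_policy": config.hemisphere_policy,
            "seed": seed,
        },
    )

    # --- stage 5: cohort statistics ---------------------------------------
    cohort = generate_cohort(CohortSpec(n_ci=config.cohort.n_ci, n_th=config.cohort.n_th, seed=seed))
    cohort["clinical"].to_csv(out / "clinical.csv")
    cohort["reading"].to_csv(out / "reading.csv")
    cohort["connectivity"].to_csv(out / "cohort_connectivity.csv")
    pca = run_pca(cohort["clinical"])
    pca.loadings.to_csv(out / "pca_pattern_matrix.tsv", sep="\t")
    ci_mask = cohort["clinical"]["group"] == "CI"
    battery = run_mediation_battery(
        pca.scores,
        cohort["connectivity"].loc[ci_mask],
        cohort["reading"].loc[ci_mask],
        n_boot=config.cohort.n_boot,
        seed=seed + 4000,
    )
    battery.to_csv(out / "mediation_battery.tsv", sep="\t", index=False)
    io.write_manifest(
        out / "cohort.manifest.json",
        "cohort_stats",
        {
            "n_ci": config.cohort.n_ci,
            "n_th": config.cohort.n_th,
            "n_boot": config.cohort.n_boot,
            "seed": seed,
            "n_components": pca.n_retained,
        },
    )
    return {
        "network": network,
        "subject_results": subject_results,
        "summary": summary,
        "pca": pca,
        "mediation": battery,
        "output_dir": out,
    }


def result_order_guess(result, series, config) -> int:
    """Model order for the significance statistic when none is configured."""
    from .connectivity import select_model_order

    return select_model_order(series, *config.order_range)
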