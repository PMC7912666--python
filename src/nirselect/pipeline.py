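"""End-to-end study orchestration.

One :class:`StudyConfig` drives the whole experiment: simulate a population,
hold out a random external-validation third, remove spectral outliers from
the full calibration (FC) set, build every selection set (NH thresholds with
center and sqrt-n picks, Ward-dendrogram cuts with one and sqrt-n picks, and
count-targeted NH/HC sets at one third and half of the FC size), fit an MPLS
calibration per reference parameter on each set, predict the validation set
and compare every reduced model's SEP against the FC model with a Fisher
test.

Reproducibility: every stage draws from its own named sub-seed, derived from
the master seed through ``numpy.random.SeedSequence(master, spawn_key)``, so
rerunning the same config is bit-identical and changing one stage's stream
does not disturb the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import evaluation, mpls, selection, spectral_space, synthetic
from .preprocessing import parse_pretreatment
from .synthetic import SimulationConfig, SpectralDataset, round_half_up

#: Pretreatment found most effective per reference parameter.
DEFAULT_PRETREATMENTS = {
    "TA": "MSC 0,0,1,1",
    "TSS": "MSC 1,5,5,1",
    "TSP": "SNV 2,5,5,1",
    "pH": "MSC 2,5,5,1",
}

_STAGES = ("simulate", "split", "picks", "cv", "count_targets")


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Named sub-seed derived from the master seed (below 2**31)."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(master_seed, spawn_key=(_STAGES.index(stage), index))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class StudyConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    validation_fraction: float = 1.0 / 3.0
    pca_target_explained: float | None = 0.99
    pca_fixed_k: int | None = None
    outlier_threshold: float = 3.0
    nh_thresholds: tuple = (0.6, 0.9)
    hc_cut_percents: tuple = (1.0, 0.5)
    pick_modes: tuple = ("one", "sqrt_n")
    count_target_fractions: tuple = (1.0 / 3.0, 1.0 / 2.0)
    pretreatments: dict = field(default_factory=lambda: dict(DEFAULT_PRETREATMENTS))
    alpha: float = 0.05
    n_cv_segments: int = 4
    master_seed: int = 0


@dataclass
class StudyResult:
    config: StudyConfig
    population: SpectralDataset
    calibration: SpectralDataset  # FC set after spectral-outlier removal
    validation: SpectralDataset
    removed_outliers: list
    selections: dict  # set name -> SelectionResult
    runs: list        # per (set, parameter) dicts for build_report
    report: "object"  # pandas DataFrame


def _nh_label(threshold: float) -> str:
    return f"{int(round(threshold * 10)):02d}"  # 0.6 -> "06", 0.9 -> "09"


def build_selection_sets(
    fc: SpectralDataset,
    scores: spectral_space.ScoreMatrix,
    config: StudyConfig,
) -> dict:
    """All reduced calibration sets defined by the study design."""
    nh = spectral_space.nh_matrix(scores)
    dend = selection.ward_dendrogram(scores)
    sets: dict[str, selection.SelectionResult] = {}

    pick_seed = stage_seed(config.master_seed, "picks")
    for ti, thr in enumerate(config.nh_thresholds):
        grouping = selection.group_by_nh(nh, thr, fc.sample_ids)
        label = _nh_label(thr)
        for mode in config.pick_modes:
            if mode == "one":
                sets[f"NH-{label}-1"] = selection.pick_center(grouping)
            else:
                sets[f"NH-{label}-sqrtn"] = selection.pick_sqrt_n(
                    grouping, nh, seed=pick_seed + ti
                )

    for ci, pct in enumerate(config.hc_cut_percents):
        labels = selection.cut_dendrogram(dend, pct)
        plabel = format(pct, "g").replace("0.", "0").replace(".", "")  # 1 -> "1", 0.5 -> "05"
        for mi, mode in enumerate(config.pick_modes):
            name = f"HC-{plabel}-{'1' if mode == 'one' else 'sqrtn'}"
            sets[name] = selection.hc_pick(
                dend, labels, mode, seed=pick_seed + 100 + 10 * ci + mi
            )

    n = fc.n_samples
    for fi, frac in enumerate(config.count_target_fractions):
        target = round_half_up(frac * n)
        try:
            sets[f"NH-{target}"] = selection.select_by_count(
                "NH", target, nh=nh, sample_ids=fc.sample_ids
            )
        except ValueError:
            # threshold ties can make an exact NH group count unattainable;
            # fall back to the nearest achievable count below the target
            sets[f"NH-{target}"] = _nearest_nh_by_count(nh, target, fc.sample_ids)
        sets[f"HC-{target}"] = selection.select_by_count(
            "HC", target, scores=scores, dend=dend
        )
    return sets


def _nearest_nh_by_count(nh, target, sample_ids):
    for delta in range(1, nh.shape[0]):
        for t in (target - delta, target + delta):
            if 1 <= t <= nh.shape[0]:
                try:
                    res = selection.select_by_count("NH", t, nh=nh, sample_ids=sample_ids)
                    res.params["requested_target"] = target
                    return res
                except ValueError:
                    continue
    raise ValueError("no achievable NH group count")  # pragma: no cover


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyResult:
    """Execute the full study; optionally write all artifacts under out_dir."""
    population = synthetic.generate_population(config.simulation)
    fc_raw, validation = synthetic.split_calibration_validation(
        population, config.validation_fraction, stage_seed(config.master_seed, "split")
    )

    fc_abs = fc_raw.to_absorbance()
    pca = spectral_space.fit_pca(
        fc_abs.spectra,
        target_explained=config.pca_target_explained,
        fixed_k=config.pca_fixed_k,
    )
    fc, removed = spectral_space.remove_spectral_outliers(
        fc_abs, pca, config.outlier_threshold
    )
    scores = pca.transform(fc.spectra, fc.sample_ids)

    selections = build_selection_sets(fc, scores, config)

    runs: list[dict] = []
    fc_val_stats: dict[str, evaluation.ValidationStats] = {}
    cv_seed = stage_seed(config.master_seed, "cv")
    set_order = ["FC"] + list(selections)
    for set_name in set_order:
        subset = fc if set_name == "FC" else fc.subset_by_ids(selections[set_name].selected_ids)
        for pi, param in enumerate(synthetic.REFERENCE_PARAMETERS):
            spec = parse_pretreatment(config.pretreatments[param])
            model, cal_stats = mpls.fit_calibration(
                subset,
                param,
                spec,
                n_segments=config.n_cv_segments,
                seed=cv_seed + pi,
            )
            y_pred = model.predict_dataset(validation)
            y_true = validation.references[param].to_numpy(dtype=float)
            val_stats = evaluation.validation_stats(
                y_true, y_pred, (cal_stats.min_estimate, cal_stats.max_estimate)
            )
            fisher = None
            if set_name == "FC":
                fc_val_stats[param] = val_stats
            else:
                fisher = evaluation.fisher_compare(
                    val_stats, fc_val_stats[param], config.alpha
                )
            runs.append(
                {
                    "set": set_name,
                    "parameter": param,
                    "pretreatment": config.pretreatments[param],
                    "calibration_stats": cal_stats,
                    "validation_stats": val_stats,
                    "fisher": fisher,
                }
            )

    report = evaluation.build_report(runs)
    result = StudyResult(
        config=config,
        population=population,
        calibration=fc,
        validation=validation,
        removed_outliers=removed,
        selections=selections,
        runs=runs,
        report=report,
    )
    if out_dir is not None:
        write_artifacts(result, Path(out_dir))
    return result


def write_artifacts(result: StudyResult, out_dir: Path) -> None:
    """data/, selections/, report/ directory layout with a manifest."""
    out_dir = Path(out_dir)
    for sub in ("data", "selections", "report"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    synthetic.write_dataset_csv(
        result.population, out_dir / "data" / "spectra.csv", out_dir / "data" / "references.csv"
    )
    (out_dir / "data" / "validation_ids.txt").write_text(
        "\n".join(map(str, result.validation.sample_ids)) + "\n"
    )
    for name, sel in result.selections.items():
        sel.to_frame().to_csv(out_dir / "selections" / f"{name}.csv", index=False)
        (out_dir / "selections" / f"{name}.json").write_text(
            json.dumps({"method": sel.method, "params": sel.params,
                        "n_selected": sel.n_selected}, default=str)
        )
    result.report.to_csv(out_dir / "report" / "report.csv", index=False)
    (out_dir / "report" / "report.txt").write_text(
        evaluation.render_report(result.report) + "\n"
    )
    manifest = {
        "master_seed": result.config.master_seed,
        "n_population": result.population.n_samples,
        "n_validation": result.validation.n_samples,
        "n_fc": result.calibration.n_samples,
        "removed_spectral_outliers": list(map(str, result.removed_outliers)),
        "selection_sizes": {k: v.n_selected for k, v in result.selections.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


__all__ = [
    "StudyConfig",
    "StudyResult",
    "DEFAULT_PRETREATMENTS",
    "stage_seed",
    "build_selection_sets",
    "run_study",
    "write_artifacts",
]
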