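"""Build every calibration selection set from the full-calibration spectra.

Reads the population written by 01_simulate.py, rebuilds the validation
split, fits the PCA score space on the FC set, removes H > 3 spectral
outliers, and constructs the NH-threshold sets (0.6/0.9, center and sqrt-n
picks), the Ward dendrogram cut sets (D_link/D_max 1.0%/0.5%, one and
sqrt-n picks) and the count-targeted sets at a third and a half of the FC
size.  Writes one CSV per selection plus a sizes table.
"""

from pathlib import Path

import pandas as pd

from nirselect import pipeline, spectral_space, synthetic

MASTER_SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data_dir = RESULTS / "data"
    population = synthetic.read_dataset_csv(
        data_dir / "spectra.csv", data_dir / "references.csv"
    )
    val_ids = set((data_dir / "validation_ids.txt").read_text().split())
    cal_idx = [i for i, s in enumerate(population.sample_ids) if s not in val_ids]
    fc_raw = population.subset(cal_idx).to_absorbance()

    cfg = pipeline.StudyConfig(master_seed=MASTER_SEED)
    pca = spectral_space.fit_pca(fc_raw.spectra, target_explained=cfg.pca_target_explained)
    fc, removed = spectral_space.remove_spectral_outliers(fc_raw, pca, cfg.outlier_threshold)
    scores = pca.transform(fc.spectra, fc.sample_ids)
    print(f"PCA: k={pca.k} components explain {pca.explained_fraction:.1%} of FC variance")
    print(f"spectral outliers removed (H > {cfg.outlier_threshold:g}): {removed or 'none'}")
    print(f"selectable FC population: {fc.n_samples} samples")

    selections = pipeline.build_selection_sets(fc, scores, cfg)
    sel_dir = RESULTS / "selections"
    sel_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, sel in selections.items():
        sel.to_frame().to_csv(sel_dir / f"{name}.csv", index=False)
        rows.append(
            {
                "set": name,
                "n_selected": sel.n_selected,
                "percent_of_FC": round(100 * sel.n_selected / fc.n_samples, 1),
                "n_groups": int(sel.group_labels.max()) + 1,
            }
        )
    sizes = pd.DataFrame(rows)
    sizes.to_csv(sel_dir / "sizes.csv", index=False)
    print(sizes.to_string(index=False))
    print(f"wrote per-set CSVs and sizes.csv under {sel_dir}")


if __name__ == "__main__":
    main()
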