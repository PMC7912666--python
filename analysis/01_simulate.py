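"""Generate the synthetic grape population and the external-validation split.

A 213-sample population (3 cultivars, 8 weekly sampling dates, NIR
reflectance over 900-1700 nm with scatter artifacts, and four linked
reference parameters) is drawn, and a random third is reserved for external
validation.  Writes data/ CSVs under results/ for the later stages.
"""

from pathlib import Path

from nirselect import pipeline, synthetic

MASTER_SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = pipeline.StudyConfig(master_seed=MASTER_SEED)
    population = synthetic.generate_population(cfg.simulation)
    cal, val = synthetic.split_calibration_validation(
        population, cfg.validation_fraction, pipeline.stage_seed(MASTER_SEED, "split")
    )

    data_dir = RESULTS / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    synthetic.write_dataset_csv(
        population, data_dir / "spectra.csv", data_dir / "references.csv"
    )
    (data_dir / "validation_ids.txt").write_text(
        "\n".join(val.sample_ids) + "\n"
    )

    print(f"population: {population.n_samples} samples x {len(population.wavelengths)} bands")
    print(f"validation: {val.n_samples} samples, full calibration (FC): {cal.n_samples}")
    for p in synthetic.REFERENCE_PARAMETERS:
        col = population.references[p]
        print(f"  {p}: {col.min():.2f} .. {col.max():.2f}")
    print(f"wrote {data_dir}/spectra.csv, references.csv, validation_ids.txt")


if __name__ == "__main__":
    main()
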