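"""Seeded synthetic grape populations: NIR reflectance spectra with linked
reference chemistry.

The generator emulates a harvest-season sampling campaign: several cultivars,
weekly sampling dates from pre-bloom to vintage, and four routine quality
parameters (total acidity, total soluble solids, total skin phenols, pH)
measured on every sample.  Each sample carries a small latent "chemistry"
vector (water, sugar, acid, phenol loadings); the spectrum is a mixture of
Gaussian pure-component absorption bands pushed through Beer-Lambert to
reflectance, with per-sample multiplicative/additive scatter and detector
noise on top.  Reference values are documented affine functions of the
latents plus measurement noise, so spectra and chemistry share exactly the
structure a calibration model is supposed to exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REFERENCE_PARAMETERS = ("TA", "TSS", "TSP", "pH")

#: Affine link from the latent vector (water, sugar, acid, phenol) to each
#: reference parameter: value = intercept + coeffs . latents (+ noise).
#: TA falls and TSS/pH rise along ripening, TSP tracks the phenol latent
#: (markedly lower in the white cultivar).
DEFAULT_REFERENCE_COEFFICIENTS: dict[str, tuple[float, tuple[float, float, float, float]]] = {
    "TA": (-8.0, (0.0, 0.0, 40.0, 0.0)),       # g/L tartaric acid equivalents
    "TSS": (-14.0, (0.0, 36.0, 0.0, 0.0)),     # degrees Brix
    "TSP": (-0.5, (0.0, 0.0, 0.0, 14.5)),      # mg/g skin, gallic acid eq.
    "pH": (4.55, (0.0, 0.35, -1.85, 0.0)),     # unitless
}

#: Measurement noise for the emulated wet-chemistry reference methods, in
#: reference units (chosen to sit at the error level routine oenological
#: assays achieve).
DEFAULT_REFERENCE_NOISE_SD = {"TA": 2.0, "TSS": 0.9, "TSP": 1.3, "pH": 0.10}

# Gaussian absorption bands per pure component: (center nm, width nm, amplitude).
# Loosely placed at O-H / C-H overtone and combination regions inside
# 900-1700 nm; amplitudes give absorbances of order 1 for latents of order 1.
DEFAULT_PURE_COMPONENTS: tuple[tuple[tuple[float, float, float], ...], ...] = (
    ((970.0, 40.0, 0.20), (1190.0, 45.0, 0.30), (1450.0, 55.0, 1.00)),   # water
    ((1200.0, 50.0, 0.40), (1360.0, 40.0, 0.30), (1580.0, 60.0, 0.50)),  # sugar
    ((1150.0, 60.0, 0.50), (1690.0, 50.0, 0.40)),                        # organic acid
    ((1415.0, 35.0, 0.60), (1660.0, 45.0, 0.50)),                        # phenolics
)

# Cultivar baseline latents (water, sugar, acid, phenol): two red-like
# profiles and one white-like profile with low skin phenols.
_CULTIVAR_BASE = np.array(
    [
        [1.00, 0.50, 1.20, 0.90],
        [1.05, 0.45, 1.25, 0.80],
        [0.95, 0.55, 1.15, 0.30],
    ]
)
# Ripening trend added as r * trend with r in [0, 1] over the season.
_RIPENING_TREND = np.array([-0.10, 0.80, -0.80, 0.25])

N_DATES = 8  # weekly sampling dates per cultivar


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic population.

    All standard deviations are >= 0; the same seed always yields a
    bit-identical dataset.
    """

    n_samples: int = 213
    n_cultivars: int = 3
    wavelength_start: float = 900.0
    wavelength_end: float = 1700.0
    n_bands: int = 256
    n_latent_components: int = 4
    pure_components: tuple = DEFAULT_PURE_COMPONENTS
    latent_noise_sd: float = 0.05
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.01
    noise_sd: float = 0.002
    reference_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_COEFFICIENTS)
    )
    reference_noise_sd: dict = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_NOISE_SD)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_cultivars <= 0:
            raise ValueError("n_samples and n_cultivars must be positive")
        if self.n_bands < 2:
            raise ValueError("n_bands must be at least 2")
        if not self.wavelength_end > self.wavelength_start:
            raise ValueError("degenerate wavelength grid")
        for sd in (
            self.latent_noise_sd,
            self.scatter_slope_sd,
            self.scatter_offset_sd,
            self.noise_sd,
        ):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        if any(v < 0 for v in self.reference_noise_sd.values()):
            raise ValueError("reference noise sds must be non-negative")


@dataclass
class SpectralDataset:
    """Sample spectra plus reference chemistry and sampling metadata.

    ``spectra`` rows align with ``sample_ids`` and with the rows of
    ``references`` (columns TA, TSS, TSP, pH) and ``metadata`` (columns
    cultivar, date_index).  ``is_absorbance`` flags whether ``spectra`` holds
    log10(1/R) (True) or reflectance (False).
    """

    sample_ids: list
    wavelengths: np.ndarray
    spectra: np.ndarray
    references: pd.DataFrame
    metadata: pd.DataFrame
    is_absorbance: bool = False
    latents: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.spectra.shape != (n, len(self.wavelengths)):
            raise ValueError("spectra shape inconsistent with ids/wavelengths")
        if len(self.references) != n or len(self.metadata) != n:
            raise ValueError("references/metadata row count mismatch")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.references[list(REFERENCE_PARAMETERS)].isna().any().any():
            raise ValueError("missing reference values")
        ph = self.references["pH"].to_numpy()
        if np.any((ph <= 0) | (ph >= 14)):
            raise ValueError("pH out of (0, 14)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, indices) -> "SpectralDataset":
        indices = np.asarray(indices)
        return SpectralDataset(
            sample_ids=[self.sample_ids[i] for i in indices],
            wavelengths=self.wavelengths,
            spectra=self.spectra[indices],
            references=self.references.iloc[indices].reset_index(drop=True),
            metadata=self.metadata.iloc[indices].reset_index(drop=True),
            is_absorbance=self.is_absorbance,
            latents=None if self.latents is None else self.latents[indices],
        )

    def subset_by_ids(self, ids) -> "SpectralDataset":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return self.subset([pos[s] for s in ids])

    def to_absorbance(self, floor: float = 1e-6) -> "SpectralDataset":
        """Return a copy in log10(1/R); reflectance is floored at ``floor``
        before the log so scatter/noise excursions below zero stay finite."""
        if self.is_absorbance:
            return self
        refl = np.clip(self.spectra, floor, None)
        out = SpectralDataset(
            sample_ids=list(self.sample_ids),
            wavelengths=self.wavelengths,
            spectra=-np.log10(refl),
            references=self.references.copy(),
            metadata=self.metadata.copy(),
            is_absorbance=True,
            latents=self.latents,
        )
        return out


def _cultivar_means(n_cultivars: int) -> np.ndarray:
    base = _CULTIVAR_BASE
    if n_cultivars <= base.shape[0]:
        return base[:n_cultivars]
    # deterministic extension for configs with more cultivars than presets
    reps = [base[i % base.shape[0]] + 0.02 * (i // base.shape[0]) for i in range(n_cultivars)]
    return np.array(reps)


def pure_component_matrix(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Wavelength grid and the (components x bands) pure absorbance matrix."""
    wl = np.linspace(config.wavelength_start, config.wavelength_end, config.n_bands)
    comps = config.pure_components[: config.n_latent_components]
    if len(comps) < config.n_latent_components:
        raise ValueError("not enough pure-component band definitions")
    K = np.zeros((config.n_latent_components, config.n_bands))
    for i, bands in enumerate(comps):
        for center, width, amp in bands:
            K[i] += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return wl, K


def references_from_latents(
    latents: np.ndarray, coefficients: dict | None = None
) -> pd.DataFrame:
    """Noise-free reference values implied by a latent matrix (rows = samples)."""
    coefficients = coefficients or DEFAULT_REFERENCE_COEFFICIENTS
    out = {}
    for param in REFERENCE_PARAMETERS:
        intercept, coefs = coefficients[param]
        out[param] = intercept + latents @ np.asarray(coefs)
    return pd.DataFrame(out)


def generate_population(config: SimulationConfig) -> SpectralDataset:
    """Draw a full synthetic population from the configured study design.

    Latents = cultivar baseline + ripening trend * (date / last date) + noise;
    spectra = 10**(-absorbance) with per-sample scatter (slope/offset) and
    i.i.d. detector noise; references = affine(latents) + assay noise.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    wl, K = pure_component_matrix(config)

    cultivar = np.arange(n) % config.n_cultivars
    date_index = (np.arange(n) // config.n_cultivars) % N_DATES
    r = date_index / (N_DATES - 1)

    means = _cultivar_means(config.n_cultivars)
    latents = (
        means[cultivar]
        + r[:, None] * _RIPENING_TREND[None, :]
        + rng.normal(0.0, config.latent_noise_sd, size=(n, config.n_latent_components))
    )
    latents = np.clip(latents, 0.05, None)  # concentrations stay positive

    absorbance = latents @ K
    reflectance = 10.0 ** (-absorbance)  # in (0, 1] since absorbance >= 0

    slope = rng.normal(0.0, config.scatter_slope_sd, size=n)
    offset = rng.normal(0.0, config.scatter_offset_sd, size=n)
    spectra = (1.0 + slope)[:, None] * reflectance + offset[:, None]
    spectra = spectra + rng.normal(0.0, config.noise_sd, size=spectra.shape)

    refs = references_from_latents(latents, config.reference_coefficients)
    for param in REFERENCE_PARAMETERS:
        sd = config.reference_noise_sd.get(param, 0.0)
        if sd > 0:
            refs[param] = refs[param] + rng.normal(0.0, sd, size=n)
    refs["TA"] = refs["TA"].clip(lower=0.1)
    refs["TSS"] = refs["TSS"].clip(lower=0.1)
    refs["TSP"] = refs["TSP"].clip(lower=0.05)
    refs["pH"] = refs["pH"].clip(lower=0.01, upper=13.99)

    ids = [f"S{i:04d}" for i in range(n)]
    meta = pd.DataFrame({"cultivar": cultivar, "date_index": date_index})
    return SpectralDataset(
        sample_ids=ids,
        wavelengths=wl,
        spectra=spectra,
        references=refs,
        metadata=meta,
        is_absorbance=False,
        latents=latents,
    )


def round_half_up(x: float) -> int:
    """Round to the nearest whole number, halves away from zero upward."""
    return int(math.floor(x + 0.5))


def split_calibration_validation(
    dataset: SpectralDataset, fraction: float, seed: int
) -> tuple[SpectralDataset, SpectralDataset]:
    """Random external-validation split; returns (calibration, validation).

    Validation size is round-half-up(fraction * n), so a one-third split of
    213 samples reserves exactly 71 for validation.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    n = dataset.n_samples
    n_val = round_half_up(fraction * n)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    val_idx = np.sort(perm[:n_val])
    cal_idx = np.sort(perm[n_val:])
    return dataset.subset(cal_idx), dataset.subset(val_idx)


# ---------------------------------------------------------------------------
# wide-CSV round trip

def write_dataset_csv(dataset: SpectralDataset, spectra_path, references_path) -> None:
    """Write wide spectra (id + one numeric column per wavelength) and the
    reference table (id, TA, TSS, TSP, pH, cultivar, date_index)."""
    spec = pd.DataFrame(dataset.spectra, columns=[f"{w:.6g}" for w in dataset.wavelengths])
    spec.insert(0, "id", dataset.sample_ids)
    spec.to_csv(spectra_path, index=False)
    refs = dataset.references.copy()
    refs.insert(0, "id", dataset.sample_ids)
    refs["cultivar"] = dataset.metadata["cultivar"].to_numpy()
    refs["date_index"] = dataset.metadata["date_index"].to_numpy()
    refs.to_csv(references_path, index=False)


def read_dataset_csv(spectra_path, references_path, is_absorbance: bool = False) -> SpectralDataset:
    spec = pd.read_csv(spectra_path)
    refs = pd.read_csv(references_path)
    ids = spec["id"].astype(str).tolist()
    if refs["id"].astype(str).tolist() != ids:
        raise ValueError("spectra and reference files list different samples")
    wavelengths = np.array([float(c) for c in spec.columns[1:]])
    return SpectralDataset(
        sample_ids=ids,
        wavelengths=wavelengths,
        spectra=spec.iloc[:, 1:].to_numpy(dtype=float),
        references=refs[list(REFERENCE_PARAMETERS)].copy(),
        metadata=refs[["cultivar", "date_index"]].copy(),
        is_absorbance=is_absorbance,
    )


__all__ = [
    "REFERENCE_PARAMETERS",
    "SimulationConfig",
    "SpectralDataset",
    "generate_population",
    "references_from_latents",
    "pure_component_matrix",
    "split_calibration_validation",
    "round_half_up",
    "write_dataset_csv",
    "read_dataset_csv",
]
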