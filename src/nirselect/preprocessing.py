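"""Spectral pretreatments in the WinISI idiom.

Scatter corrections (SNV, MSC, SNV+detrend) and gap-segment derivatives
encoded as ``d,g,s1,s2`` (derivative order, gap, first and second smoothing
segment, all in bands).  A pretreatment is fitted on the calibration set
(MSC keeps its reference spectrum) and then applied, frozen, to validation
spectra.  Composition order is scatter correction first, then derivative;
edge bands without a full derivative window are dropped and the surviving
band indices are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_SCATTER_MODES = ("none", "snv", "msc", "snv_detrend")


@dataclass(frozen=True)
class PretreatmentSpec:
    """One pretreatment recipe: a scatter mode plus a derivative code."""

    scatter: str = "none"
    derivative: int = 0
    gap: int = 0
    smooth1: int = 1
    smooth2: int = 1

    def __post_init__(self) -> None:
        if self.scatter not in _SCATTER_MODES:
            raise ValueError(f"unknown scatter mode {self.scatter!r}")
        if self.derivative < 0 or self.gap < 0:
            raise ValueError("derivative order and gap must be >= 0")
        if self.smooth1 < 1 or self.smooth2 < 1:
            raise ValueError("smoothing segments must be >= 1")
        if self.derivative > 0 and self.gap < 1:
            raise ValueError("derivative requires gap >= 1")

    @property
    def code(self) -> str:
        return f"{self.derivative},{self.gap},{self.smooth1},{self.smooth2}"

    def __str__(self) -> str:  # round-trips through parse_pretreatment
        label = {"none": "none", "snv": "SNV", "msc": "MSC", "snv_detrend": "SNV+detrend"}
        return f"{label[self.scatter]} {self.code}"


def parse_pretreatment(text: str) -> PretreatmentSpec:
    """Parse codes like ``"MSC 1,5,5,1"`` or ``"none 0,0,1,1"``."""
    parts = text.split()
    if len(parts) != 2:
        raise ValueError(f"cannot parse pretreatment {text!r}")
    scatter = parts[0].lower().replace("+", "_")
    nums = parts[1].split(",")
    if len(nums) != 4:
        raise ValueError(f"derivative code must have 4 fields: {text!r}")
    d, g, s1, s2 = (int(v) for v in nums)
    return PretreatmentSpec(scatter=scatter, derivative=d, gap=g, smooth1=s1, smooth2=s2)


@dataclass
class PretreatmentState:
    """Fitted state carried from the calibration set to new spectra."""

    msc_reference: np.ndarray | None = None


# ---------------------------------------------------------------------------
# scatter corrections

def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: each row centered and scaled to unit
    population (1/n) standard deviation."""
    X = np.asarray(spectra, dtype=float)
    if X.shape[-1] < 2:
        raise ValueError("SNV needs at least 2 bands per row")
    mean = X.mean(axis=-1, keepdims=True)
    sd = X.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("SNV undefined for a constant row")
    return (X - mean) / sd


def msc(
    spectra: np.ndarray, reference: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative scatter correction against ``reference`` (default: the
    column-mean spectrum of ``spectra``).

    Each row x becomes (x - a) / b with a, b the least-squares intercept and
    slope of x regressed on the reference.  Returns (corrected, reference) so
    the calibration reference can be reused on validation spectra.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom <= 0:
        raise ValueError("MSC reference has zero variance")
    slope = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(slope == 0):
        raise ValueError("MSC slope of zero; row uncorrelated with reference")
    intercept = X.mean(axis=1) - slope * ref.mean()
    corrected = (X - intercept[:, None]) / slope[:, None]
    return corrected, ref


def detrend(
    spectra: np.ndarray, wavelengths: np.ndarray | None = None, degree: int = 2
) -> np.ndarray:
    """Subtract a per-row polynomial (in wavelength) of the given degree.

    Degree 2 is the Barnes SNV-detrend convention; degree 0 mean-centers.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    p = X.shape[1]
    if degree >= p:
        raise ValueError("polynomial degree must be below the band count")
    x = np.arange(p, dtype=float) if wavelengths is None else np.asarray(wavelengths, float)
    # orthonormal polynomial basis for numerical stability
    basis = np.polynomial.polynomial.polyvander((x - x.mean()) / (x.std() or 1.0), degree)
    q, _ = np.linalg.qr(basis)
    return X - (X @ q) @ q.T


# ---------------------------------------------------------------------------
# gap-segment derivative

def _moving_average(X: np.ndarray, segment: int) -> np.ndarray:
    if segment == 1:
        return X
    if segment % 2 == 0:
        raise ValueError("smoothing segment must be odd")
    if segment > X.shape[1]:
        raise ValueError("smoothing segment exceeds row length")
    kernel = np.ones(segment) / segment
    out = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, X)
    return out


def gap_segment_derivative(
    spectra: np.ndarray, d: int, g: int, s1: int = 1, s2: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Gap-segment derivative ``d,g,s1,s2``.

    Applies a moving average of segment s1, then d successive gap differences
    y'(i) = y(i+g) - y(i-g), then a moving average of segment s2.  Edge bands
    without a full window are dropped: returns (matrix, kept band indices
    into the input grid).  The code 0,0,1,1 is the identity.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    n_bands = X.shape[1]
    if d == 0:
        g = 0  # gap ignored without a derivative
    shrink = (s1 - 1) // 2 + d * g + (s2 - 1) // 2
    if 2 * shrink >= n_bands and shrink > 0:
        raise ValueError("derivative windows exceed row length")
    Y = _moving_average(X, s1)
    for _ in range(d):
        if 2 * g >= Y.shape[1]:
            raise ValueError("gap difference window exceeds remaining bands")
        Y = Y[:, 2 * g :] - Y[:, : Y.shape[1] - 2 * g]
    Y = _moving_average(Y, s2)
    kept = np.arange(shrink, n_bands - shrink)
    return Y, kept


# ---------------------------------------------------------------------------
# composition

def apply_pretreatment(
    spec: PretreatmentSpec,
    spectra: np.ndarray,
    wavelengths: np.ndarray | None = None,
    state: PretreatmentState | None = None,
) -> tuple[np.ndarray, np.ndarray | None, PretreatmentState]:
    """Apply a full pretreatment: scatter correction, then derivative.

    When ``state`` is None the pretreatment is fitted (MSC stores its
    calibration reference); pass the returned state to transform validation
    spectra against the calibration fit.  Returns
    (pretreated matrix, output wavelength grid or None, state).
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    fitting = state is None
    state = state or PretreatmentState()

    if spec.scatter == "snv":
        X = snv(X)
    elif spec.scatter == "msc":
        if fitting:
            X, ref = msc(X)
            state.msc_reference = ref
        else:
            if state.msc_reference is None:
                raise ValueError("MSC state missing its reference spectrum")
            X, _ = msc(X, reference=state.msc_reference)
    elif spec.scatter == "snv_detrend":
        X = detrend(snv(X), wavelengths=wavelengths, degree=2)

    if spec.derivative > 0 or spec.smooth1 > 1 or spec.smooth2 > 1:
        X, kept = gap_segment_derivative(
            X, spec.derivative, spec.gap, spec.smooth1, spec.smooth2
        )
    else:
        kept = np.arange(X.shape[1])

    wl_out = None if wavelengths is None else np.asarray(wavelengths)[kept]
    return X, wl_out, state


__all__ = [
    "PretreatmentSpec",
    "PretreatmentState",
    "parse_pretreatment",
    "snv",
    "msc",
    "detrend",
    "gap_segment_derivative",
    "apply_pretreatment",
]
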