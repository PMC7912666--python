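"""Modified partial least squares (MPLS) calibration.

MPLS is PLS1 (NIPALS) with one modification: after each extracted factor the
X residuals at every wavelength, and the y residual, are divided by their
current standard deviations before the next factor is computed, so late
factors are not dominated by the few wavelengths with large early residuals.
With the re-standardisation disabled the algorithm reduces exactly to
standard PLS1.

The calibration pipeline is: pretreat the spectra, choose the number of
factors by segmented cross-validation (lowest SECV wins), remove chemical
outliers whose cross-validated residual exceeds 2.5 x SECV (at most two
elimination passes), and refit on the retained samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .preprocessing import PretreatmentSpec, PretreatmentState, apply_pretreatment
from .synthetic import SpectralDataset

T_CRITICAL = 2.5


@dataclass
class MPLSCore:
    """Fitted MPLS factors for one pretreated X block and one response.

    The per-factor scaling vectors (``x_scales`` rows, ``y_scales``) are the
    residual standard deviations used before each extraction; storing them
    makes prediction exactly reproduce the training recursion.  ``coef`` and
    ``intercept`` give the equivalent single linear form in pretreated space.
    """

    n_factors: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray    # factors x bands
    loadings: np.ndarray   # factors x bands
    q: np.ndarray          # factors
    x_scales: np.ndarray   # factors x bands
    y_scales: np.ndarray   # factors
    scale_residuals: bool
    coef: np.ndarray = field(default=None)  # type: ignore[assignment]
    intercept: float = 0.0

    def predict_all_factors(self, X: np.ndarray) -> np.ndarray:
        """Predictions using 1..n_factors factors; shape (n, n_factors)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        x_res = X - self.x_mean
        out = np.empty((X.shape[0], self.n_factors))
        acc = np.zeros(X.shape[0])
        y_scale_prod = 1.0
        for f in range(self.n_factors):
            x_res = x_res / self.x_scales[f]
            y_scale_prod *= self.y_scales[f]
            t = x_res @ self.weights[f]
            acc = acc + self.q[f] * t * y_scale_prod
            out[:, f] = self.y_mean + acc
            x_res = x_res - np.outer(t, self.loadings[f])
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_all_factors(X)[:, -1]


def fit_mpls_core(
    X: np.ndarray, y: np.ndarray, n_factors: int, scale_residuals: bool = True
) -> MPLSCore:
    """Extract ``n_factors`` MPLS factors from a pretreated matrix.

    Raises if the requested factor count exceeds the effective rank of the
    residual sequence; :func:`cross_validate` uses the tolerant variant that
    stops early instead.
    """
    return _fit_core(X, y, n_factors, scale_residuals, strict=True)


def _fit_core(
    X: np.ndarray, y: np.ndarray, n_factors: int, scale_residuals: bool, strict: bool
) -> MPLSCore:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y disagree on the sample count")
    if n < n_factors + 1:
        raise ValueError("need at least n_factors + 1 samples")
    if np.std(y) == 0:
        raise ValueError("y has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    x_res = X - x_mean
    y_res = y - y_mean

    W = np.empty((n_factors, p))
    P = np.empty((n_factors, p))
    q = np.empty(n_factors)
    DX = np.empty((n_factors, p))
    dy = np.empty(n_factors)

    for f in range(n_factors):
        if scale_residuals:
            d = x_res.std(axis=0)
            d[d < 1e-12] = 1.0
            e = float(y_res.std())
            if e < 1e-12:
                e = 1.0
        else:
            d = np.ones(p)
            e = 1.0
        x_res = x_res / d
        y_res = y_res / e
        DX[f], dy[f] = d, e

        w = x_res.T @ y_res
        wn = np.linalg.norm(w)
        degenerate = wn < 1e-12
        if not degenerate:
            w = w / wn
            t = x_res @ w
            tt = float(t @ t)
            degenerate = tt < 1e-12
        if degenerate:
            if strict or f == 0:
                raise ValueError(f"rank exhausted at factor {f + 1}")
            n_factors = f  # stop early; later factors would contribute nothing
            W, P, q, DX, dy = W[:f], P[:f], q[:f], DX[:f], dy[:f]
            break
        P[f] = x_res.T @ t / tt
        q[f] = float(y_res @ t / tt)
        W[f] = w
        x_res = x_res - np.outer(t, P[f])
        y_res = y_res - q[f] * t

    core = MPLSCore(
        n_factors=n_factors,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        q=q,
        x_scales=DX,
        y_scales=dy,
        scale_residuals=scale_residuals,
    )
    # the fitted map is affine in x; recover its single linear form
    base = core.predict(np.zeros((1, p)))[0]
    core.coef = core.predict(np.eye(p)) - base
    core.intercept = float(base)
    return core


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    max_factors: int,
    n_segments: int = 4,
    seed: int = 0,
    scale_residuals: bool = True,
) -> tuple[np.ndarray, int, np.ndarray]:
    """Segmented cross-validation over 1..max_factors factors.

    Segments are contiguous blocks of a seeded shuffle.  Returns
    (secv_by_factor, chosen_factors, cv_predictions at the chosen count);
    SECV(f) = sqrt(mean squared cross-validated residual) and the factor
    count with the lowest SECV is chosen.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n_segments < 2:
        raise ValueError("need at least 2 cross-validation segments")
    if n < n_segments:
        raise ValueError("fewer samples than segments")
    max_factors = min(max_factors, n - int(np.ceil(n / n_segments)) - 1)
    if max_factors < 1:
        raise ValueError("not enough samples for even one factor")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    segments = np.array_split(order, n_segments)

    preds = np.empty((n, max_factors))
    for seg in segments:
        mask = np.ones(n, dtype=bool)
        mask[seg] = False
        core = _fit_core(X[mask], y[mask], max_factors, scale_residuals, strict=False)
        block = core.predict_all_factors(X[seg])
        if core.n_factors < max_factors:  # rank exhausted: later factors add nothing
            pad = np.repeat(block[:, -1:], max_factors - core.n_factors, axis=1)
            block = np.hstack([block, pad])
        preds[seg] = block

    secv = np.sqrt(((y[:, None] - preds) ** 2).mean(axis=0))
    chosen = int(np.argmin(secv)) + 1
    return secv, chosen, preds[:, chosen - 1]


def eliminate_t_outliers(
    X: np.ndarray,
    y: np.ndarray,
    max_factors: int,
    n_segments: int = 4,
    seed: int = 0,
    scale_residuals: bool = True,
    t_critical: float = T_CRITICAL,
    max_passes: int = 2,
) -> tuple[np.ndarray, int, np.ndarray, int, np.ndarray]:
    """Remove chemical outliers with T = |y - y_cv| / SECV >= t_critical.

    At most ``max_passes`` elimination passes, re-cross-validating after each.
    Returns (retained indices, n_removed, secv_by_factor, chosen_factors,
    cv_predictions on the retained samples).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    retained = np.arange(len(y))
    removed = 0
    passes_left = max_passes
    while True:
        secv, chosen, cv_pred = cross_validate(
            X[retained], y[retained], max_factors, n_segments, seed, scale_residuals
        )
        resid = np.abs(y[retained] - cv_pred)
        s = secv[chosen - 1]
        # SECV at numerical zero means a perfect fit; T is then meaningless
        floor = 1e-8 * max(1.0, float(np.std(y[retained])))
        t_vals = resid / s if s > floor else np.zeros_like(resid)
        out = t_vals >= t_critical
        if not out.any() or passes_left == 0:
            break
        if len(retained) - int(out.sum()) < chosen + 2:
            raise ValueError("outlier removal would leave too few samples")
        retained = retained[~out]
        removed += int(out.sum())
        passes_left -= 1
    return retained, removed, secv, chosen, cv_pred


@dataclass
class CalibrationStats:
    """Summary statistics of one fitted calibration."""

    n: int
    n_t_outliers: int
    min_estimate: float
    max_estimate: float
    rsq: float
    secv: float

    def __post_init__(self) -> None:
        if self.secv < 0:
            raise ValueError("SECV must be non-negative")


@dataclass
class MPLSModel:
    """A pretreatment plus a fitted MPLS core, operating on raw spectra."""

    pretreatment: PretreatmentSpec
    pretreatment_state: PretreatmentState
    wavelengths: np.ndarray
    core: MPLSCore

    def predict_dataset(self, dataset: SpectralDataset) -> np.ndarray:
        ds = dataset.to_absorbance()
        if len(ds.wavelengths) != len(self.wavelengths) or not np.allclose(
            ds.wavelengths, self.wavelengths
        ):
            raise ValueError("wavelength grid differs from the training grid")
        Xp, _, _ = apply_pretreatment(
            self.pretreatment, ds.spectra, ds.wavelengths, self.pretreatment_state
        )
        return self.core.predict(Xp)

    # -- JSON round trip ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "pretreatment": str(self.pretreatment),
            "msc_reference": _arr(self.pretreatment_state.msc_reference),
            "wavelengths": _arr(self.wavelengths),
            "core": {
                "n_factors": self.core.n_factors,
                "x_mean": _arr(self.core.x_mean),
                "y_mean": self.core.y_mean,
                "weights": _arr(self.core.weights),
                "loadings": _arr(self.core.loadings),
                "q": _arr(self.core.q),
                "x_scales": _arr(self.core.x_scales),
                "y_scales": _arr(self.core.y_scales),
                "scale_residuals": self.core.scale_residuals,
                "coef": _arr(self.core.coef),
                "intercept": self.core.intercept,
            },
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "MPLSModel":
        from .preprocessing import parse_pretreatment

        doc = json.loads(text)
        c = doc["core"]
        core = MPLSCore(
            n_factors=c["n_factors"],
            x_mean=np.array(c["x_mean"]),
            y_mean=c["y_mean"],
            weights=np.array(c["weights"]),
            loadings=np.array(c["loadings"]),
            q=np.array(c["q"]),
            x_scales=np.array(c["x_scales"]),
            y_scales=np.array(c["y_scales"]),
            scale_residuals=c["scale_residuals"],
            coef=np.array(c["coef"]),
            intercept=c["intercept"],
        )
        state = PretreatmentState(
            msc_reference=None
            if doc["msc_reference"] is None
            else np.array(doc["msc_reference"])
        )
        return cls(
            pretreatment=parse_pretreatment(doc["pretreatment"]),
            pretreatment_state=state,
            wavelengths=np.array(doc["wavelengths"]),
            core=core,
        )


def _arr(a):
    return None if a is None else np.asarray(a).tolist()


def default_max_factors(n: int) -> int:
    """Cap on PLS factors: min(15, n // 3), at least 1."""
    return max(1, min(15, n // 3))


def fit_calibration(
    dataset: SpectralDataset,
    parameter: str,
    spec: PretreatmentSpec,
    max_factors: int | None = None,
    n_segments: int = 4,
    seed: int = 0,
    scale_residuals: bool = True,
    t_critical: float = T_CRITICAL,
    max_outlier_passes: int = 2,
) -> tuple[MPLSModel, CalibrationStats]:
    """Full calibration pipeline for one reference parameter.

    Pretreat, cross-validate the factor count, strip T-outliers, refit; the
    Min/Max estimate range is the span of the calibration predictions with
    negative estimates floored at zero.  RSQ is the cross-validated
    coefficient of determination (clamped to [0, 1]).
    """
    if parameter not in dataset.references.columns:
        raise ValueError(f"dataset lacks parameter {parameter!r}")
    ds = dataset.to_absorbance()
    y = ds.references[parameter].to_numpy(dtype=float)
    Xp, _, state = apply_pretreatment(spec, ds.spectra, ds.wavelengths, None)
    if max_factors is None:
        max_factors = default_max_factors(len(y))

    retained, removed, secv_vec, chosen, cv_pred = eliminate_t_outliers(
        Xp, y, max_factors, n_segments, seed, scale_residuals,
        t_critical, max_outlier_passes,
    )
    core = _fit_core(Xp[retained], y[retained], chosen, scale_residuals, strict=False)
    cal_pred = core.predict(Xp[retained])

    y_ret = y[retained]
    ss_res = float(((y_ret - cv_pred) ** 2).sum())
    ss_tot = float(((y_ret - y_ret.mean()) ** 2).sum())
    rsq = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    stats = CalibrationStats(
        n=len(retained),
        n_t_outliers=removed,
        min_estimate=max(0.0, float(cal_pred.min())),
        max_estimate=max(0.0, float(cal_pred.max())),
        rsq=float(np.clip(rsq, 0.0, 1.0)),
        secv=float(secv_vec[chosen - 1]),
    )
    model = MPLSModel(
        pretreatment=spec,
        pretreatment_state=state,
        wavelengths=ds.wavelengths,
        core=core,
    )
    return model, stats


def predict(model: MPLSModel, dataset: SpectralDataset) -> np.ndarray:
    """Predict a dataset with a fitted calibration (pretreatment included)."""
    return model.predict_dataset(dataset)


__all__ = [
    "MPLSCore",
    "MPLSModel",
    "CalibrationStats",
    "fit_mpls_core",
    "cross_validate",
    "eliminate_t_outliers",
    "fit_calibration",
    "predict",
    "default_max_factors",
]
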