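"""Absolute abundance calibration: from intensities to molecules and molar.

Two calibration routes:

* smFISH copy number — nurse-cell spot intensities are fitted with a 1D
  Gaussian mixture (EM); the mean of the component carrying the largest
  weight is the *unit intensity*, the signal of a single mRNA molecule
  (nurse-cell particles are predominantly 1-copy, so the dominant mode is
  the single-molecule peak). Granule intensities divided by the unit give
  copy numbers, and copies over granule volume give molar concentration.

* fluorophore-tagged protein — a dilution ladder of recombinant
  fluorophore imaged under identical settings yields a linear
  intensity-vs-concentration calibration curve; granule mean intensities
  are inverted through it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from ._rng import child_rng

__all__ = [
    "AVOGADRO",
    "MixtureModel",
    "CalibrationCurve",
    "AbundanceResult",
    "fit_gaussian_mixture",
    "unit_intensity",
    "copy_number",
    "molar_concentration",
    "fit_calibration_curve",
    "protein_concentration",
]

AVOGADRO = 6.02214076e23

_EM_TOL = 1e-8
_EM_MAX_ITER = 1000
_EM_MAX_RESTARTS = 10


@dataclass
class MixtureModel:
    """1D Gaussian mixture (means, SDs, weights on the simplex)."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float = float("nan")
    bic: float = float("nan")

    @property
    def K(self) -> int:
        return len(self.means)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("sds must be > 0")
        if not np.all(np.isfinite(self.means)):
            raise ValueError("means must be finite")


@dataclass
class CalibrationCurve:
    """Linear intensity-vs-molar-concentration calibration."""

    slope: float  # intensity per molar
    intercept: float
    r_squared: float
    concentration_range: tuple[float, float]


@dataclass
class AbundanceResult:
    """Per-granule copy numbers and molar concentrations."""

    unit_intensity: float
    copies_raw: np.ndarray
    copies_rounded: np.ndarray
    volumes_L: np.ndarray
    concentrations_M: np.ndarray
    volume_source: str = "per-granule"


# ---------------------------------------------------------------------------
# Gaussian mixture EM
# ---------------------------------------------------------------------------


def _em_once(
    x: np.ndarray, means0: np.ndarray, sd0: float, seed_rng: np.random.Generator | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    n = len(x)
    K = len(means0)
    means = means0.copy()
    sds = np.full(K, sd0)
    weights = np.full(K, 1.0 / K)
    scale = max(float(np.std(x)), 1e-12)
    min_sd = 1e-6 * scale

    ll_prev = -np.inf
    for _ in range(_EM_MAX_ITER):
        # E-step in log space
        log_pdf = (
            -0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
            - np.log(sds[None, :])
            - 0.5 * np.log(2 * np.pi)
        )
        log_w = np.log(np.clip(weights, 1e-300, None))
        log_joint = log_pdf + log_w[None, :]
        log_norm = logsumexp(log_joint, axis=1)
        ll = float(log_norm.sum())
        if ll < ll_prev - 1e-9 * max(1.0, abs(ll_prev)):
            raise AssertionError("EM log-likelihood decreased")
        resp = np.exp(log_joint - log_norm[:, None])
        # M-step
        nk = resp.sum(axis=0)
        if np.any(nk <= 0):
            raise _DegenerateComponent
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(var)
        if np.any(sds < min_sd):
            raise _DegenerateComponent
        weights = nk / n
        if abs(ll - ll_prev) < _EM_TOL * max(1.0, abs(ll)):
            ll_prev = ll
            break
        ll_prev = ll
    return means, sds, weights, ll_prev


class _DegenerateComponent(RuntimeError):
    pass


def fit_gaussian_mixture(
    intensities: np.ndarray,
    K: int | None = None,
    K_range: tuple[int, int] | None = None,
    seed: int = 0,
) -> MixtureModel:
    """EM fit of a 1D Gaussian mixture to an intensity population.

    With ``K`` fixed the mixture of that order is fitted; with ``K_range``
    (inclusive; default (1, 4) when neither is given) the order is chosen
    by BIC. Initialization is quantile-spaced means with pooled SD and
    uniform weights; degenerate components trigger restarts with means
    jittered by ±10% from a seed-derived stream, with an error after 10
    failed restarts. Convergence: relative log-likelihood change < 1e-8 or
    1000 iterations; the log-likelihood is asserted non-decreasing.

    Requires ``n >= 10 K``.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if K is not None and K_range is not None:
        raise ValueError("give K or K_range, not both")
    if K is not None:
        ks = [int(K)]
    else:
        lo, hi = K_range if K_range is not None else (1, 4)
        ks = list(range(int(lo), int(hi) + 1))

    rng = child_rng(seed, "gmm")
    best: MixtureModel | None = None
    for k in ks:
        if len(x) < 10 * k:
            if best is None and k == ks[0]:
                raise ValueError(f"need at least {10 * k} samples for K={k}")
            continue
        q = (np.arange(k) + 0.5) / k
        means0 = np.quantile(x, q)
        sd0 = max(float(np.std(x)), 1e-12)
        fitted = None
        for restart in range(_EM_MAX_RESTARTS + 1):
            m0 = means0 if restart == 0 else means0 * (
                1.0 + rng.uniform(-0.1, 0.1, size=k)
            )
            try:
                fitted = _em_once(x, m0, sd0, rng)
                break
            except _DegenerateComponent:
                continue
        if fitted is None:
            raise RuntimeError(
                f"EM degenerate for K={k} after {_EM_MAX_RESTARTS} restarts"
            )
        means, sds, weights, ll = fitted
        order = np.argsort(means)
        n_params = 3 * k - 1
        bic = -2.0 * ll + n_params * np.log(len(x))
        model = MixtureModel(
            means=means[order],
            sds=sds[order],
            weights=weights[order],
            log_likelihood=ll,
            bic=float(bic),
        )
        if best is None or model.bic < best.bic:
            best = model
    assert best is not None
    return best


def unit_intensity(model: MixtureModel) -> float:
    """Signal intensity of one molecule: the mean of the mixture component
    with the largest weight, ties broken toward the smaller mean (the
    single-molecule peak dominates nurse-cell populations)."""
    w = model.weights
    best = np.flatnonzero(np.isclose(w, w.max()))
    return float(min(model.means[i] for i in best))


def copy_number(
    granule_intensity: np.ndarray | float, unit: float
) -> tuple[np.ndarray | float, np.ndarray | int]:
    """Copies per granule: intensity / unit, raw and rounded (floor 0)."""
    if unit <= 0:
        raise ValueError("unit intensity must be > 0")
    raw = np.asarray(granule_intensity, dtype=float) / unit
    rounded = np.maximum(np.rint(raw), 0).astype(int)
    if np.isscalar(granule_intensity):
        return float(raw), int(rounded)
    return raw, rounded


def molar_concentration(
    copies: np.ndarray | float, volume_liters: np.ndarray | float
) -> np.ndarray | float:
    """Molar concentration ``copies / (N_A * volume)``."""
    vol = np.asarray(volume_liters, dtype=float)
    if np.any(vol <= 0):
        raise ValueError("volume must be > 0")
    conc = np.asarray(copies, dtype=float) / (AVOGADRO * vol)
    if np.isscalar(copies) and np.isscalar(volume_liters):
        return float(conc)
    return conc


# ---------------------------------------------------------------------------
# protein calibration curve
# ---------------------------------------------------------------------------


def fit_calibration_curve(
    concentrations_M: np.ndarray, mean_intensities: np.ndarray
) -> CalibrationCurve:
    """Ordinary least squares of intensity on molar concentration."""
    c = np.asarray(concentrations_M, dtype=float)
    y = np.asarray(mean_intensities, dtype=float)
    if len(c) != len(y):
        raise ValueError("concentrations and intensities must share length")
    if len(np.unique(c)) < 2:
        raise ValueError("need at least 2 distinct concentrations")
    fit = stats.linregress(c, y)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        concentration_range=(float(c.min()), float(c.max())),
    )


def protein_concentration(
    granule_mean_intensity: np.ndarray | float, curve: CalibrationCurve
) -> np.ndarray | float:
    """Invert the calibration curve: ``(intensity - intercept) / slope``.

    Values outside the fitted concentration range are flagged with a
    warning (extrapolation beyond the validated linear regime).
    """
    if curve.slope <= 0:
        raise ValueError("calibration slope must be > 0")
    conc = (np.asarray(granule_mean_intensity, dtype=float) - curve.intercept) / curve.slope
    lo, hi = curve.concentration_range
    if np.any(conc < lo - 1e-15) or np.any(conc > hi + 1e-15):
        warnings.warn(
            "concentration outside the fitted calibration range (extrapolated)",
            stacklevel=2,
        )
    if np.isscalar(granule_mean_intensity):
        return float(conc)
    return conc
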