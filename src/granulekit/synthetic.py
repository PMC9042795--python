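"""Synthetic fluorescence-microscopy generator with exact ground truth.

Every downstream stage of granulekit (segmentation, morphometrics, FRAP
kinetics, abundance calibration, colocalization, polarity) is validated
against fields produced here, so no raw imaging data is required.

The generator emulates the statistical structure of RNP-granule imaging
data: granules are hard ellipsoids with Gaussian-distributed diameters
(the in-vivo population is well described by a normal size distribution,
e.g. mean 400 nm / SD 129 nm), filled at uniform density so that the
integrated signal of a granule equals ``copies x unit_intensity``, then
optionally blurred with a Gaussian PSF and degraded with Poisson shot
noise and additive Gaussian read noise — in that order, matching photon
physics. Nurse-cell-like intensity populations are dominated by 1–2 mRNA
copies; FRAP traces follow the single-exponential recovery model
``I0 + I1 * (1 - exp(-(t - t_bleach)/tau))``.

Determinism contract: identical parameters + seed => bit-identical images,
traces and ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from ._rng import child_rng
from .frap import FrapFit, FrapTrace, half_time, immobile_fraction
from .image import ImageStack

__all__ = [
    "GranuleFieldParams",
    "GranuleTruth",
    "GroundTruth",
    "FrapSimParams",
    "FieldTooCrowdedError",
    "generate_granule_image",
    "generate_two_channel_field",
    "generate_frap_trace",
    "generate_intensity_population",
    "generate_polarity_field",
    "generate_calibration_ladder",
]

_MAX_DIAMETER_RESAMPLES = 10_000
_PLACEMENT_ATTEMPTS_PER_GRANULE = 1_000


class FieldTooCrowdedError(RuntimeError):
    """Raised when ``n_granules`` cannot be placed at ``min_separation``."""


# ---------------------------------------------------------------------------
# parameter and ground-truth containers
# ---------------------------------------------------------------------------


@dataclass
class GranuleFieldParams:
    """Parameters of a simulated granule field.

    ``copies_distribution`` may be an integer (every granule carries that
    many molecules), a ``{copies: weight}`` mapping, ``("poisson", lam)``
    (zero-truncated), or ``("constant_concentration", c_per_um3)`` where the
    copy count scales with granule volume (constant internal concentration,
    the regime observed in vivo where RNA content grows with granule volume
    at unchanged concentration). ``noise_model`` is one of ``none |
    gaussian | poisson | poisson+gaussian``; ``noise_sd`` applies to the
    Gaussian part.
    """

    field_shape: tuple[int, ...] = (32, 128, 128)
    voxel_size_nm: tuple[float, ...] = (100.0, 50.0, 50.0)
    n_granules: int = 50
    diameter_mean_nm: float = 400.0
    diameter_sd_nm: float = 129.0
    axis_ratio: float = 1.0
    unit_intensity: float = 1000.0
    copies_distribution: object = 1
    psf_sigma_nm: tuple[float, ...] | float = 0.0
    background_level: float = 0.0
    noise_model: str = "none"
    noise_sd: float = 0.0
    min_separation_nm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.field_shape = tuple(int(s) for s in self.field_shape)
        self.voxel_size_nm = tuple(float(v) for v in self.voxel_size_nm)
        if len(self.voxel_size_nm) != len(self.field_shape):
            raise ValueError("voxel_size_nm must match field_shape dimensionality")
        if self.diameter_mean_nm <= 0:
            raise ValueError("diameter_mean_nm must be > 0")
        if self.diameter_sd_nm < 0:
            raise ValueError("diameter_sd_nm must be >= 0")
        if self.min_separation_nm < 0:
            raise ValueError("min_separation_nm must be >= 0")
        if self.axis_ratio < 1.0:
            raise ValueError("axis_ratio must be >= 1 (1.0 = spheres)")
        if self.n_granules < 0:
            raise ValueError("n_granules must be >= 0")
        if self.noise_model not in {"none", "gaussian", "poisson", "poisson+gaussian"}:
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if np.isscalar(self.psf_sigma_nm):
            self.psf_sigma_nm = (float(self.psf_sigma_nm),) * len(self.field_shape)
        else:
            self.psf_sigma_nm = tuple(float(s) for s in self.psf_sigma_nm)


@dataclass
class GranuleTruth:
    """Ground truth for one simulated granule (all lengths in nm)."""

    id: int
    centroid_nm: list[float]
    diameter_nm: float
    axes_nm: list[float]
    copies: int
    channel: str = "ref"
    partner_id: int | None = None


@dataclass
class GroundTruth:
    """Exact generative record serialized losslessly alongside the image."""

    granules: list[GranuleTruth] = field(default_factory=list)
    field_shape: list[int] = field(default_factory=list)
    voxel_size_nm: list[float] = field(default_factory=list)
    true_com_displacement: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        granules = [GranuleTruth(**g) for g in d.pop("granules")]
        return cls(granules=granules, **d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_json(fh.read())

    def centroids_nm(self, channel: str | None = None) -> np.ndarray:
        gs = [g for g in self.granules if channel is None or g.channel == channel]
        if not gs:
            return np.empty((0, len(self.field_shape)))
        return np.array([g.centroid_nm for g in gs], dtype=float)


@dataclass
class FrapSimParams:
    """Generative parameters of a synthetic FRAP experiment.

    ``I0`` is the normalized intensity just after bleach, ``I1`` the dynamic
    range of recovery and ``tau`` the recovery time constant in seconds; the
    immobile fraction of the simulated species is ``(1-I0-I1)/(1-I0)``.
    ``acquisition_bleach_rate`` is the per-frame multiplicative intensity
    loss applied to the reference ROI (and, physically, to the whole field).
    """

    I0: float = 0.2
    I1: float = 0.5
    tau_s: float = 10.0
    n_prebleach: int = 3
    n_postbleach: int = 157
    frame_interval_s: float = 0.35
    acquisition_bleach_rate: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.I0 < 0 or self.I1 < 0:
            raise ValueError("I0 and I1 must be non-negative")
        if self.I0 + self.I1 > 1 + 1e-12:
            raise ValueError("I0 + I1 must not exceed 1")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be > 0")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach frame")
        if not (0 <= self.acquisition_bleach_rate < 1):
            raise ValueError("acquisition_bleach_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# granule rendering
# ---------------------------------------------------------------------------


def _sample_diameters(
    n: int, mean: float, sd: float, min_diameter: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian diameters, rejection-truncated at ``min_diameter`` (nm)."""
    out = np.empty(n)
    filled = 0
    for _ in range(_MAX_DIAMETER_RESAMPLES):
        if filled == n:
            break
        draw = rng.normal(mean, sd, size=n - filled)
        keep = draw[draw > min_diameter]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    else:
        raise RuntimeError(
            "could not sample diameters above the 2-voxel floor after "
            f"{_MAX_DIAMETER_RESAMPLES} rounds"
        )
    return out


def _sample_copies(spec: object, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec, (int, np.integer)):
        return np.full(n, int(spec))
    if isinstance(spec, dict):
        ks = np.array(sorted(spec), dtype=int)
        w = np.array([spec[int(k)] for k in ks], dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("copy weights must be non-negative and sum to 1")
        return rng.choice(ks, size=n, p=w / w.sum())
    if isinstance(spec, (tuple, list)) and len(spec) == 2 and spec[0] == "poisson":
        lam = float(spec[1])
        draws = rng.poisson(lam, size=n)
        # zero-truncate: an invisible granule is not a granule
        while np.any(draws == 0):
            zero = draws == 0
            draws[zero] = rng.poisson(lam, size=int(zero.sum()))
        return draws
    raise ValueError(f"unsupported copies_distribution {spec!r}")


def _place_centers(
    n: int,
    lo_nm: np.ndarray,
    hi_nm: np.ndarray,
    min_separation_nm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform rejection placement with a hard-core separation constraint."""
    if np.any(hi_nm <= lo_nm):
        raise FieldTooCrowdedError(
            "field too crowded: granules do not fit inside the field margins"
        )
    centers: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(_PLACEMENT_ATTEMPTS_PER_GRANULE):
            cand = rng.uniform(lo_nm, hi_nm)
            if min_separation_nm > 0 and centers:
                d2 = np.sum((np.array(centers) - cand) ** 2, axis=1)
                if d2.min() < min_separation_nm**2:
                    continue
            centers.append(cand)
            break
        else:
            raise FieldTooCrowdedError(
                f"field too crowded: placed {len(centers)}/{n} granules at "
                f"min_separation {min_separation_nm} nm"
            )
    return np.array(centers).reshape(n, len(lo_nm))


def _render_ellipsoid(
    field: np.ndarray,
    center_nm: np.ndarray,
    semi_axes_nm: np.ndarray,
    total_signal: float,
    voxel_size_nm: np.ndarray,
    oversample: int = 3,
) -> None:
    """Add a uniform-density hard ellipsoid to ``field`` in place.

    Per-voxel fill fractions come from ``oversample**ndim`` sub-voxel sample
    points and are renormalized so the added signal sums to ``total_signal``
    exactly (photon conservation before PSF and noise).
    """
    ndim = field.ndim
    lo = np.maximum(np.floor((center_nm - semi_axes_nm) / voxel_size_nm).astype(int) - 1, 0)
    hi = np.minimum(
        np.ceil((center_nm + semi_axes_nm) / voxel_size_nm).astype(int) + 2,
        np.array(field.shape),
    )
    if np.any(hi <= lo):
        return
    # sub-voxel sample offsets in [0, 1)
    sub = (np.arange(oversample) + 0.5) / oversample
    axis_terms = []
    for ax in range(ndim):
        idx = np.arange(lo[ax], hi[ax])
        pts = np.add.outer(idx, sub).ravel() * voxel_size_nm[ax]
        axis_terms.append(((pts - center_nm[ax]) / semi_axes_nm[ax]) ** 2)
    r2 = axis_terms[0]
    for term in axis_terms[1:]:
        r2 = r2[..., np.newaxis] + term
    inside = (r2 <= 1.0).astype(float)
    # average the oversampled indicator back to voxel resolution
    shape = []
    for ax in range(ndim):
        shape.extend([hi[ax] - lo[ax], oversample])
    frac = inside.reshape(shape).mean(axis=tuple(range(1, 2 * ndim, 2)))
    s = frac.sum()
    if s <= 0:
        return
    frac = frac * (total_signal / s)
    sel = tuple(slice(lo[ax], hi[ax]) for ax in range(ndim))
    field[sel] += frac


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def generate_granule_image(
    params: GranuleFieldParams,
) -> tuple[ImageStack, GroundTruth]:
    """Render a seeded field of blurred ellipsoidal granules.

    Returns the image stack and the exact per-granule ground truth. With
    ``psf_sigma_nm = 0`` and ``noise_model = "none"`` the integrated
    above-background signal of each granule equals ``copies x
    unit_intensity`` to within ~1% voxelization tolerance.
    """
    rng = child_rng(params.seed, "granule-field")
    voxel = np.array(params.voxel_size_nm)
    shape = np.array(params.field_shape)
    field = np.zeros(params.field_shape, dtype=float)

    truth = GroundTruth(
        field_shape=list(params.field_shape),
        voxel_size_nm=list(params.voxel_size_nm),
    )
    if params.n_granules > 0:
        min_d = 2.0 * float(voxel.max())
        diameters = _sample_diameters(
            params.n_granules, params.diameter_mean_nm, params.diameter_sd_nm, min_d, rng
        )
        spec = params.copies_distribution
        if isinstance(spec, (tuple, list)) and len(spec) == 2 and spec[0] == "constant_concentration":
            vol_um3 = (np.pi / 6.0) * (diameters / 1e3) ** 3 * params.axis_ratio
            copies = np.maximum(1, np.rint(float(spec[1]) * vol_um3)).astype(int)
        else:
            copies = _sample_copies(spec, params.n_granules, rng)
        # keep the whole blurred granule inside the field
        semi_major = (diameters.max() / 2.0) * params.axis_ratio
        margin = semi_major + 3.0 * max(params.psf_sigma_nm)
        lo = np.full(len(shape), margin)
        hi = shape * voxel - margin
        centers = _place_centers(
            params.n_granules, lo, hi, params.min_separation_nm, rng
        )
        for i in range(params.n_granules):
            semi = np.full(len(shape), diameters[i] / 2.0)
            semi[-1] *= params.axis_ratio  # major axis along x
            _render_ellipsoid(
                field,
                centers[i],
                semi,
                float(copies[i]) * params.unit_intensity,
                voxel,
            )
            truth.granules.append(
                GranuleTruth(
                    id=i,
                    centroid_nm=[float(c) for c in centers[i]],
                    diameter_nm=float(diameters[i]),
                    axes_nm=[float(2 * s) for s in semi],
                    copies=int(copies[i]),
                )
            )

    if max(params.psf_sigma_nm) > 0:
        field = gaussian_filter(field, sigma=np.array(params.psf_sigma_nm) / voxel)
    field = field + params.background_level
    if params.noise_model in {"poisson", "poisson+gaussian"}:
        field = rng.poisson(np.clip(field, 0, None)).astype(float)
    if params.noise_model in {"gaussian", "poisson+gaussian"}:
        field = field + rng.normal(0.0, params.noise_sd, size=field.shape)

    stack = ImageStack(field[np.newaxis], ["granules"], params.voxel_size_nm)
    return stack, truth


def generate_two_channel_field(
    params: GranuleFieldParams,
    n_ref: int,
    n_target: int,
    true_coloc_fraction: float,
    jitter_sd_nm: float = 0.0,
) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Two-channel field with a controlled true colocalization fraction.

    Exactly ``round(true_coloc_fraction * n_ref)`` reference granules get a
    target partner displaced by isotropic Gaussian jitter; the remaining
    targets are placed uniformly. Ground truth labels partner pairs.
    """
    if not (0.0 <= true_coloc_fraction <= 1.0):
        raise ValueError("true_coloc_fraction must be in [0, 1]")
    n_partnered = int(round(true_coloc_fraction * n_ref))
    if n_target < n_partnered:
        raise ValueError("n_target smaller than the partnered count")

    rng = child_rng(params.seed, "two-channel")
    voxel = np.array(params.voxel_size_nm)
    shape = np.array(params.field_shape)
    min_d = 2.0 * float(voxel.max())
    diam_ref = _sample_diameters(
        n_ref, params.diameter_mean_nm, params.diameter_sd_nm, min_d, rng
    ) if n_ref else np.empty(0)
    diam_tgt = _sample_diameters(
        n_target, params.diameter_mean_nm, params.diameter_sd_nm, min_d, rng
    ) if n_target else np.empty(0)

    all_d = np.concatenate([diam_ref, diam_tgt]) if n_ref + n_target else np.array([min_d])
    margin = all_d.max() / 2.0 * params.axis_ratio + 3.0 * max(params.psf_sigma_nm)
    lo = np.full(len(shape), margin)
    hi = shape * voxel - margin

    ref_centers = _place_centers(n_ref, lo, hi, params.min_separation_nm, rng)
    partner_ids = rng.choice(n_ref, size=n_partnered, replace=False) if n_partnered else np.empty(0, int)
    tgt_centers = np.empty((n_target, len(shape)))
    for j, rid in enumerate(partner_ids):
        c = ref_centers[rid] + rng.normal(0.0, jitter_sd_nm, size=len(shape))
        tgt_centers[j] = np.clip(c, lo, hi)
    if n_target > n_partnered:
        tgt_centers[n_partnered:] = _place_centers(
            n_target - n_partnered, lo, hi, params.min_separation_nm, rng
        )

    truth = GroundTruth(
        field_shape=list(params.field_shape),
        voxel_size_nm=list(params.voxel_size_nm),
    )
    fields = {
        "ref": np.zeros(params.field_shape, dtype=float),
        "target": np.zeros(params.field_shape, dtype=float),
    }
    gid = 0
    for ch, centers, diams in (
        ("ref", ref_centers, diam_ref),
        ("target", tgt_centers, diam_tgt),
    ):
        for i in range(len(centers)):
            semi = np.full(len(shape), diams[i] / 2.0)
            semi[-1] *= params.axis_ratio
            _render_ellipsoid(fields[ch], centers[i], semi, params.unit_intensity, voxel)
            partner = None
            if ch == "target" and i < n_partnered:
                partner = int(partner_ids[i])
            truth.granules.append(
                GranuleTruth(
                    id=gid,
                    centroid_nm=[float(c) for c in centers[i]],
                    diameter_nm=float(diams[i]),
                    axes_nm=[float(2 * s) for s in semi],
                    copies=1,
                    channel=ch,
                    partner_id=partner,
                )
            )
            gid += 1

    stacks = []
    for ch in ("ref", "target"):
        img = fields[ch]
        if max(params.psf_sigma_nm) > 0:
            img = gaussian_filter(img, sigma=np.array(params.psf_sigma_nm) / voxel)
        img = img + params.background_level
        if params.noise_model in {"poisson", "poisson+gaussian"}:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if params.noise_model in {"gaussian", "poisson+gaussian"}:
            img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
        stacks.append(ImageStack(img[np.newaxis], [ch], params.voxel_size_nm))
    return stacks[0], stacks[1], truth


def generate_frap_trace(params: FrapSimParams) -> tuple[FrapTrace, FrapFit]:
    """Simulate a FRAP recording following single-exponential recovery.

    Pre-bleach ROI frames equal the reference; post-bleach frames follow
    ``I0 + I1 * (1 - exp(-(t - t_bleach)/tau))`` modulated by per-frame
    acquisition bleaching of the whole field; additive Gaussian noise is
    applied to the ROI. Returns the raw trace and the generating parameters
    packaged as a :class:`~granulekit.frap.FrapFit`.
    """
    n = params.n_prebleach + params.n_postbleach
    t = np.arange(n) * params.frame_interval_s
    t_bleach = t[params.n_prebleach]
    decay = (1.0 - params.acquisition_bleach_rate) ** np.arange(n)

    model = np.ones(n)
    post = t[params.n_prebleach :] - t_bleach
    model[params.n_prebleach :] = params.I0 + params.I1 * (1.0 - np.exp(-post / params.tau_s))

    roi = model * decay
    if params.noise_sd > 0:
        rng = child_rng(params.seed, "frap")
        roi = roi + rng.normal(0.0, params.noise_sd, size=n)
    trace = FrapTrace(
        time_s=t,
        roi=roi,
        reference=decay.copy(),
        background=None,
        bleach_index=params.n_prebleach,
    )
    true_fit = FrapFit(
        I0=params.I0,
        I1=params.I1,
        tau_s=params.tau_s,
        immobile_fraction=immobile_fraction(params.I0, params.I1),
        t_half_s=half_time(params.tau_s),
        residual_rms=0.0,
    )
    return trace, true_fit


def generate_intensity_population(
    unit_intensity: float,
    copy_weights: dict[int, float],
    n: int,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Spot intensities ``k * unit * (1 + eps)``, ``eps ~ N(0, noise_cv)``.

    Emulates a nurse-cell smFISH intensity population dominated by 1–2 copy
    particles. Returns ``(intensities, true_copies)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    w = np.array([copy_weights[k] for k in sorted(copy_weights)], dtype=float)
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("copy weights must be non-negative and sum to 1")
    ks = np.array(sorted(copy_weights), dtype=int)
    rng = child_rng(seed, "population")
    copies = rng.choice(ks, size=n, p=w / w.sum())
    eps = rng.normal(0.0, noise_cv, size=n) if noise_cv > 0 else np.zeros(n)
    return copies * unit_intensity * (1.0 + eps), copies


def generate_polarity_field(
    mask_shape: Sequence[int],
    ap_axis: int,
    posterior_weight: float,
    n_granules: int,
    seed: int = 0,
    voxel_size_nm: Sequence[float] | None = None,
    spot_intensity: float = 1000.0,
) -> tuple[ImageStack, np.ndarray, float]:
    """Posterior-biased point-granule field inside a rectangular cell mask.

    Each granule falls in the posterior half (increasing coordinate along
    ``ap_axis``) with probability ``posterior_weight``, uniformly within the
    chosen half. Returns the image, the boolean mask and the analytic
    normalized centre-of-mass displacement of the placements
    (``(mean AP position - centre) / AP extent``, posterior positive).
    """
    if not (0.0 <= posterior_weight <= 1.0):
        raise ValueError("posterior_weight must be in [0, 1]")
    shape = tuple(int(s) for s in mask_shape)
    if voxel_size_nm is None:
        voxel_size_nm = (100.0,) * len(shape)
    voxel = np.array(voxel_size_nm, dtype=float)
    rng = child_rng(seed, "polarity")

    extent = np.array(shape) * voxel
    img = np.zeros(shape, dtype=float)
    ap_positions = []
    for _ in range(n_granules):
        pos = rng.uniform(0.0, extent)
        half = extent[ap_axis] / 2.0
        if rng.uniform() < posterior_weight:
            pos[ap_axis] = rng.uniform(half, extent[ap_axis])
        else:
            pos[ap_axis] = rng.uniform(0.0, half)
        idx = np.minimum((pos / voxel).astype(int), np.array(shape) - 1)
        img[tuple(idx)] += spot_intensity
        # analytic truth uses the voxel-centre position actually deposited
        ap_positions.append((idx[ap_axis] + 0.5) * voxel[ap_axis])

    mask = np.ones(shape, dtype=bool)
    if ap_positions:
        com = float(np.mean(ap_positions))
        true_disp = (com - extent[ap_axis] / 2.0) / extent[ap_axis]
    else:
        true_disp = 0.0
    stack = ImageStack(img[np.newaxis], ["signal"], tuple(voxel))
    return stack, mask, float(true_disp)


def generate_calibration_ladder(
    concentrations_M: Sequence[float],
    response_slope: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    frame_shape: tuple[int, int] = (64, 64),
) -> list[tuple[float, np.ndarray]]:
    """Uniform calibration frames: mean intensity = slope x concentration.

    Emulates imaging a dilution series of recombinant fluorophore under
    identical optical settings. Per-pixel Gaussian noise of SD ``noise_sd``
    is added. Requires at least two distinct concentrations.
    """
    concs = [float(c) for c in concentrations_M]
    if len(set(concs)) < 2:
        raise ValueError("need at least 2 distinct concentrations")
    rng = child_rng(seed, "ladder")
    out = []
    for c in concs:
        frame = np.full(frame_shape, response_slope * c, dtype=float)
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame_shape)
        out.append((c, frame))
    return out
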