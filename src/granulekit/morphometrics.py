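"""Shape and intensity statistics of segmented granules.

Covers the quantities reported for RNP-granule populations: the aspect
ratio from line profiles along the principal axes (axis length defined as
the full width at half maximum of the background-subtracted profile), the
Gaussian fit of the diameter distribution, the volume–intensity
(concentration) relation, the condensate partition coefficient, and
polygon-ROI integrated density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .image import ImageStack
from .segmentation import GranuleRecord

__all__ = [
    "UnboundedProfileError",
    "SizeDistributionFit",
    "PartitionCoefficient",
    "VolumeIntensityRelation",
    "aspect_ratio",
    "fit_size_distribution",
    "volume_intensity_relation",
    "partition_coefficient",
    "integrated_density",
]


class UnboundedProfileError(RuntimeError):
    """Line profile never drops below half maximum within the field."""


@dataclass
class SizeDistributionFit:
    """Maximum-likelihood Gaussian fit of a diameter population (nm)."""

    mean_diameter_nm: float
    sd_diameter_nm: float
    n: int


@dataclass
class PartitionCoefficient:
    """Mean intensity inside condensates over the dilute phase."""

    value: float
    mean_inside: float
    mean_dilute: float
    n_objects: int
    exclusion_halo_voxels: int = 0


@dataclass
class VolumeIntensityRelation:
    """Per-granule concentration proxy and its trend with volume.

    ``proxy`` is integrated intensity / volume per granule; ``slope`` (with
    standard error) is the least-squares trend of proxy against volume, so
    "concentration does not increase with volume" is testable as
    slope within ~2 SE of 0.
    """

    proxy: np.ndarray
    volumes: np.ndarray
    slope: float
    slope_se: float
    intercept: float


# ---------------------------------------------------------------------------
# aspect ratio from line profiles
# ---------------------------------------------------------------------------


def _profile_fwhm(
    img: np.ndarray,
    centroid_nm: np.ndarray,
    direction: np.ndarray,
    voxel_nm: np.ndarray,
    step_nm: float,
    max_steps: int,
    background: float,
) -> float:
    """FWHM in nm of the background-subtracted line profile through
    ``centroid_nm`` along the physical unit vector ``direction``."""
    s = np.arange(-max_steps, max_steps + 1) * step_nm
    pos_nm = centroid_nm[:, None] + direction[:, None] * s[None, :]
    coords = pos_nm / voxel_nm[:, None] - 0.5
    inside = np.all(
        (coords >= -0.5) & (coords <= np.array(img.shape)[:, None] - 0.5), axis=0
    )
    prof = ndimage.map_coordinates(
        img.astype(float), coords, order=1, mode="nearest"
    )
    prof = prof - background
    center = len(s) // 2
    peak = prof[inside].max() if inside.any() else prof[center]
    half = peak / 2.0
    if peak <= 0:
        raise UnboundedProfileError("profile peak does not rise above background")

    def cross(idxs: np.ndarray) -> float:
        # walk from the centre outward to the first drop below half-max
        prev = center
        for i in idxs:
            if not inside[i]:
                raise UnboundedProfileError(
                    "profile never drops below half maximum within the field"
                )
            if prof[i] < half:
                # linear interpolation between the straddling samples
                f = (prof[prev] - half) / (prof[prev] - prof[i])
                return abs(s[prev] + f * (s[i] - s[prev]))
            prev = i
        raise UnboundedProfileError(
            "profile never drops below half maximum within the field"
        )

    left = cross(np.arange(center - 1, -1, -1))
    right = cross(np.arange(center + 1, len(s)))
    return left + right


def aspect_ratio(
    stack: ImageStack,
    record: GranuleRecord,
    channel: str | int | None = None,
    step_fraction: float = 0.25,
) -> tuple[float, float, float]:
    """Granule axis lengths and aspect ratio from centroid line profiles.

    Principal directions come from the intensity-weighted second-moment
    tensor stored on the record; each axis length is the FWHM of the
    background-subtracted line profile through the centroid along that
    direction (linear interpolation between voxels). Background is the
    median intensity of the voxels bordering the object's bounding box.

    Returns ``(major_nm, minor_nm, ratio)`` with ratio = major/minor >= 1.
    """
    if record.n_voxels < 3 or record.principal_axes is None or record.bbox is None:
        raise ValueError("degenerate object: need >= 3 voxels and principal axes")
    img = stack.channel(channel)
    voxel = np.array(stack.voxel_size_nm)

    # background = median of the 1-voxel shell around the bounding box
    grow = tuple(
        slice(max(b[0] - 1, 0), min(b[1] + 1, img.shape[ax]))
        for ax, b in enumerate(record.bbox)
    )
    shell = np.ones(tuple(g.stop - g.start for g in grow), dtype=bool)
    inner = tuple(
        slice(record.bbox[ax][0] - grow[ax].start, record.bbox[ax][1] - grow[ax].start)
        for ax in range(img.ndim)
    )
    shell[inner] = False
    background = float(np.median(img[grow][shell])) if shell.any() else 0.0

    centroid_nm = np.array(record.centroid_nm)
    step_nm = step_fraction * float(voxel.min())
    diag_nm = float(np.linalg.norm(np.array(img.shape) * voxel))
    max_steps = int(diag_nm / step_nm) + 2
    lengths_nm = []
    for direction in record.principal_axes:
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        lengths_nm.append(
            _profile_fwhm(img, centroid_nm, d, voxel, step_nm, max_steps, background)
        )

    major = max(lengths_nm)
    minor = min(lengths_nm)
    return major, minor, major / minor


# ---------------------------------------------------------------------------
# population statistics
# ---------------------------------------------------------------------------


def fit_size_distribution(diameters_nm: np.ndarray) -> SizeDistributionFit:
    """Gaussian ML fit of a diameter population: sample mean and SD
    (n-1 denominator). Requires n >= 2."""
    d = np.asarray(diameters_nm, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 diameters")
    return SizeDistributionFit(
        mean_diameter_nm=float(d.mean()),
        sd_diameter_nm=float(d.std(ddof=1)),
        n=int(d.size),
    )


def volume_intensity_relation(
    records: list[GranuleRecord], channel: str
) -> VolumeIntensityRelation:
    """Concentration proxy (integrated intensity / volume) vs volume.

    A flat relation (slope consistent with 0) means granule composition is
    volume-independent, i.e. larger granules hold proportionally more RNA
    at unchanged concentration.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 granules")
    vols = np.array([r.volume for r in records], dtype=float)
    if np.any(vols <= 0):
        raise ValueError("zero or negative granule volume")
    integ = np.array([r.integrated_intensity[channel] for r in records], dtype=float)
    proxy = integ / vols
    fit = stats.linregress(vols, proxy)
    return VolumeIntensityRelation(
        proxy=proxy,
        volumes=vols,
        slope=float(fit.slope),
        slope_se=float(fit.stderr),
        intercept=float(fit.intercept),
    )


def partition_coefficient(
    stack: ImageStack,
    channel: str | int | None,
    condensate_mask: np.ndarray,
    exclusion_halo_voxels: int = 1,
) -> PartitionCoefficient:
    """Partition coefficient: mean intensity inside condensates over the
    dilute phase.

    The dilute phase is the complement of the mask dilated by
    ``exclusion_halo_voxels`` (a buffer against blurred condensate edges
    contaminating the dilute estimate; halo size is reported in the
    result).
    """
    mask = np.asarray(condensate_mask, dtype=bool)
    img = stack.channel(channel)
    if mask.shape != img.shape:
        raise ValueError("mask and image must share shape")
    if not mask.any():
        raise ValueError("condensate mask is empty")
    if mask.all():
        raise ValueError("condensate mask covers the whole image")
    if exclusion_halo_voxels > 0:
        dilute = ~ndimage.binary_dilation(mask, iterations=exclusion_halo_voxels)
    else:
        dilute = ~mask
    if not dilute.any():
        raise ValueError("dilute region empty after halo exclusion")
    mean_in = float(img[mask].mean())
    mean_out = float(img[dilute].mean())
    if mean_out <= 0:
        raise ValueError("dilute-phase mean must be > 0")
    from .segmentation import label_objects  # local import avoids cycle at import time

    n_obj = label_objects(mask).n_objects
    return PartitionCoefficient(
        value=mean_in / mean_out,
        mean_inside=mean_in,
        mean_dilute=mean_out,
        n_objects=n_obj,
        exclusion_halo_voxels=exclusion_halo_voxels,
    )


# ---------------------------------------------------------------------------
# polygon ROI
# ---------------------------------------------------------------------------


def _points_in_polygon(points_yx: np.ndarray, polygon_yx: np.ndarray) -> np.ndarray:
    """Even-odd (ray casting) point-in-polygon test, vectorized over points."""
    y = points_yx[:, 0]
    x = points_yx[:, 1]
    inside = np.zeros(len(points_yx), dtype=bool)
    n = len(polygon_yx)
    for i in range(n):
        y1, x1 = polygon_yx[i]
        y2, x2 = polygon_yx[(i + 1) % n]
        straddles = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_cross = (x2 - x1) * (y - y1) / (y2 - y1) + x1
        inside ^= straddles & (x < x_cross)
    return inside


def integrated_density(
    stack: ImageStack,
    channel: str | int | None,
    polygon_nm: np.ndarray,
) -> float:
    """Sum of intensities of voxels whose centres fall inside a polygon ROI.

    ``polygon_nm`` lists (y, x) vertices in nm matching the stack's last
    two axes; membership uses the even-odd rule. For 3D stacks the same
    polygon is applied on every slice and the sums accumulated.
    """
    poly = np.asarray(polygon_nm, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise ValueError("polygon needs >= 3 (y, x) vertices")
    img = stack.channel(channel)
    vy, vx = stack.voxel_size_nm[-2], stack.voxel_size_nm[-1]
    ny, nx = img.shape[-2], img.shape[-1]
    if (
        poly[:, 0].min() < 0
        or poly[:, 1].min() < 0
        or poly[:, 0].max() > ny * vy
        or poly[:, 1].max() > nx * vx
    ):
        raise ValueError("polygon vertices must lie inside the field")
    yy, xx = np.meshgrid(
        (np.arange(ny) + 0.5) * vy, (np.arange(nx) + 0.5) * vx, indexing="ij"
    )
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1)
    inside = _points_in_polygon(pts, poly).reshape(ny, nx)
    if img.ndim == 2:
        return float(img[inside].sum())
    return float(img[..., inside].sum())
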