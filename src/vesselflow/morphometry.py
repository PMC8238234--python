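"""Binary vessel-mask ingestion and 2D morphometric indices.

Implements the three standard retinal-plexus metrics: vascular density
(percent area covered by lumen), vessel length density (percent area covered
by the skeletonized centerline) and branching index (skeleton branch points
per millimetre of centerline length).

Conventions
-----------
* masks are 2D uint8/bool arrays, 1 = lumen, 0 = tissue;
* ``pixel_size`` is isotropic, in micrometres per pixel;
* skeleton topology uses 8-connectivity; a branch point is a skeleton pixel
  with three or more skeleton neighbours;
* centerline length sums unique adjacent skeleton-pixel pairs: an orthogonal
  pair contributes ``pixel_size`` and a diagonal pair ``sqrt(2)*pixel_size``,
  except diagonal pairs already bridged by a shared orthogonal neighbour
  (corner shortcuts), which are skipped.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

__all__ = [
    "VesselMask2D",
    "SkeletonMask2D",
    "MorphometryReport",
    "load_mask",
    "vascular_density",
    "skeletonize_mask",
    "vessel_length_density",
    "branching_index",
    "morphometry_report",
]

SQRT2 = float(np.sqrt(2.0))


@dataclass
class VesselMask2D:
    """Binary lumen raster with physical pixel size.

    Parameters
    ----------
    pixels : ndarray of {0, 1}
        1 = vessel lumen, 0 = surrounding tissue.
    pixel_size : float
        Micrometres per pixel (isotropic).
    roi : ndarray of {0, 1}, optional
        Analyzed tissue region (e.g. the artery-vein wedge). When present the
        lumen must be contained in it and area densities use it as the
        denominator.
    """

    pixels: np.ndarray
    pixel_size: float
    roi: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {self.pixels.shape}")
        uniq = np.unique(self.pixels)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("mask pixels must be binary (0/1)")
        self.pixels = self.pixels.astype(np.uint8)
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.roi is not None:
            self.roi = np.asarray(self.roi).astype(np.uint8)
            if self.roi.shape != self.pixels.shape:
                raise ValueError("roi shape must match mask shape")
            if np.any(self.pixels & ~self.roi.astype(bool)):
                raise ValueError("lumen pixels must lie inside the roi")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    @property
    def lumen_area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def analysis_area_px(self) -> int:
        if self.roi is not None:
            return int(self.roi.sum())
        return int(self.pixels.size)


@dataclass
class SkeletonMask2D:
    """One-pixel-wide centerline raster derived from a :class:`VesselMask2D`."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(np.uint8)
        if self.pixels.ndim != 2:
            raise ValueError("skeleton must be 2D")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class MorphometryReport:
    """Bundle of the three morphometric indices for one sample."""

    vascular_density: float        # percent of analysis area
    vessel_length_density: float   # percent of analysis area
    branching_index: float         # branch points per mm of centerline
    n_branch_points: int
    total_length_mm: float
    degenerate_length: bool = field(default=False)  # True if length was zero

    def to_row(self, sample_id: str = "") -> dict:
        return {
            "sample_id": sample_id,
            "vascular_density": self.vascular_density,
            "vessel_length_density": self.vessel_length_density,
            "branching_index": self.branching_index,
            "n_branch_points": self.n_branch_points,
            "total_length_mm": self.total_length_mm,
        }


def _to_grayscale(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        return img.astype(np.float64)
    if img.ndim == 3 and img.shape[-1] in (2, 3, 4):
        # mean over channels; alpha (if any) treated as a channel on purpose
        # to keep the rule simple and stated.
        return img[..., : min(img.shape[-1], 3)].astype(np.float64).mean(axis=-1)
    raise ValueError(f"cannot reduce image of shape {img.shape} to 2D grayscale")


def load_mask(
    image_path: str | os.PathLike,
    pixel_size: float,
    threshold: float = 0.5,
    otsu: bool = False,
) -> VesselMask2D:
    """Read a raster image and binarize it into a vessel mask.

    Multi-channel images are reduced to grayscale by the channel mean, then
    thresholded at ``threshold`` times the dynamic range of the image dtype
    (integer images) or at ``threshold`` directly for float images assumed in
    [0, 1]. With ``otsu=True`` the threshold is chosen automatically instead.
    """
    import imageio.v3 as iio

    try:
        img = iio.imread(os.fspath(image_path))
    except Exception as exc:  # pragma: no cover - message path
        raise IOError(f"could not read image {image_path!r}: {exc}") from exc
    gray = _to_grayscale(np.asarray(img))
    if otsu:
        from skimage.filters import threshold_otsu

        cut = float(threshold_otsu(gray))
    else:
        if not 0.0 < threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if np.issubdtype(np.asarray(img).dtype, np.integer):
            lo, hi = 0.0, float(np.iinfo(np.asarray(img).dtype).max)
        else:
            lo, hi = 0.0, 1.0
        cut = lo + threshold * (hi - lo)
    return VesselMask2D(pixels=(gray > cut).astype(np.uint8), pixel_size=pixel_size)


def vascular_density(mask: VesselMask2D) -> float:
    """Percent of the analysis area occupied by lumen pixels."""
    denom = mask.analysis_area_px
    if denom == 0:
        raise ValueError("analysis area is empty")
    return 100.0 * mask.lumen_area_px / denom


def skeletonize_mask(mask: VesselMask2D) -> SkeletonMask2D:
    """Topology-preserving thinning of the lumen down to a 1-px centerline."""
    skel = _sk_skeletonize(mask.pixels.astype(bool), method="lee")
    return SkeletonMask2D(pixels=skel.astype(np.uint8), pixel_size=mask.pixel_size)


def vessel_length_density(skeleton: SkeletonMask2D, mask: VesselMask2D) -> float:
    """Percent of the analysis area occupied by skeleton pixels."""
    denom = mask.analysis_area_px
    if denom == 0:
        raise ValueError("analysis area is empty")
    return 100.0 * float(skeleton.pixels.sum()) / denom


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(
        skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant", cval=0
    )


def skeleton_length_um(skeleton: SkeletonMask2D) -> float:
    """Centerline length in micrometres (see module docstring for the rule)."""
    s = skeleton.pixels.astype(bool)
    ps = skeleton.pixel_size
    # orthogonal pairs
    n_h = np.count_nonzero(s[:, :-1] & s[:, 1:])
    n_v = np.count_nonzero(s[:-1, :] & s[1:, :])
    # diagonal pairs, skipping corner shortcuts bridged orthogonally
    dr = s[:-1, :-1] & s[1:, 1:] & ~(s[:-1, 1:] | s[1:, :-1])
    dl = s[:-1, 1:] & s[1:, :-1] & ~(s[:-1, :-1] | s[1:, 1:])
    n_d = np.count_nonzero(dr) + np.count_nonzero(dl)
    return (n_h + n_v) * ps + n_d * SQRT2 * ps


def branching_index(skeleton: SkeletonMask2D) -> MorphometryReport:
    """Branch points per millimetre of centerline; densities left at 0.

    Returns a partially filled :class:`MorphometryReport` carrying
    ``n_branch_points``, ``total_length_mm`` and ``branching_index``; the
    area densities are computed by :func:`morphometry_report`.
    """
    s = skeleton.pixels.astype(bool)
    counts = _neighbor_counts(s)
    n_branch = int(np.count_nonzero(s & (counts >= 3)))
    length_mm = skeleton_length_um(skeleton) / 1000.0
    degenerate = length_mm == 0.0
    index = 0.0 if degenerate else n_branch / length_mm
    return MorphometryReport(
        vascular_density=0.0,
        vessel_length_density=0.0,
        branching_index=index,
        n_branch_points=n_branch,
        total_length_mm=length_mm,
        degenerate_length=degenerate,
    )


def morphometry_report(mask: VesselMask2D) -> MorphometryReport:
    """Full morphometric report for one mask (skeletonizes internally)."""
    skel = skeletonize_mask(mask)
    rep = branching_index(skel)
    rep.vascular_density = vascular_density(mask)
    rep.vessel_length_density = vessel_length_density(skel, mask)
    return rep
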