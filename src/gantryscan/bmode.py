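"""B-mode slice synthesis: oblique resampling of the phantom plus a
first-order display model (depth attenuation, Rayleigh speckle, log
compression).

The model is deliberately minimal — it produces images whose lesion content
is geometrically exact (masks come straight from the phantom labels) while
looking qualitatively like B-mode ultrasound.  No wave propagation,
shadowing or refraction is simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import map_coordinates

from ._util import ValidationError
from .geometry import GantryGeometry, ProbePose, pose_to_plane
from .phantom import Phantom

__all__ = ["BModeImage", "extract_slice", "render_bmode", "save_image"]


@dataclass
class BModeImage:
    """A synthesized slice.

    ``pixels`` is the displayed 8-bit image (rows = depth, columns =
    lateral); ``mask`` the per-pixel lesion ground truth; ``labels`` the
    per-pixel lesion index (0 background); ``out_of_volume`` flags pixels
    sampled outside the phantom, which carry background echogenicity and no
    label.  ``pose`` records provenance.
    """

    pixels: np.ndarray
    mask: np.ndarray
    labels: np.ndarray
    out_of_volume: np.ndarray
    pixel_spacing: float
    pose: ProbePose | None = None
    noise_seed: int | None = None

    def __post_init__(self):
        shapes = {self.pixels.shape, self.mask.shape,
                  self.labels.shape, self.out_of_volume.shape}
        if len(shapes) != 1:
            raise ValidationError("pixels, mask, labels, out_of_volume must share a shape")
        if np.any(self.mask & self.out_of_volume):
            raise ValidationError("mask must be 0 wherever out_of_volume is 1")


def _plane_samples(plane, geometry: GantryGeometry, pixel_spacing: float):
    """World coordinates of the image sample grid, shape (n_v, n_u, 3).

    Samples run from the rectangle's left edge in steps of ``pixel_spacing``:
    lateral offsets ``-W/2 + k*ps`` and depths ``j*ps`` along the beam, so a
    grid with ``ps`` equal to the voxel spacing lands exactly on voxel
    centers for an untilted pose at a lattice-aligned station.
    """
    n_u = int(round(geometry.image_width / pixel_spacing))
    n_v = int(round(geometry.image_depth / pixel_spacing))
    if n_u < 1 or n_v < 1:
        raise ValidationError("image dimensions yield an empty pixel grid")
    su = -geometry.image_width / 2.0 + np.arange(n_u) * pixel_spacing
    sv = np.arange(n_v) * pixel_spacing
    return (
        plane.origin[None, None, :]
        + sv[:, None, None] * plane.v[None, None, :]
        + su[None, :, None] * plane.u[None, None, :]
    )


def extract_slice(
    phantom: Phantom,
    pose: ProbePose,
    geometry: GantryGeometry,
    pixel_spacing: float = 0.5,
):
    """Resample the phantom on the pose's imaging plane.

    Echogenicity is sampled by trilinear interpolation, lesion labels by
    nearest neighbor.  Samples outside the phantom's voxel-center hull get
    the background echogenicity and label 0, flagged in the returned
    out-of-volume plane.

    Returns ``(echogenicity, labels, out_of_volume)`` as 2-D arrays of shape
    (depth rows, lateral columns).
    """
    if pixel_spacing <= 0:
        raise ValidationError("pixel_spacing must be positive")
    plane = pose_to_plane(pose, geometry)
    pts = _plane_samples(plane, geometry, pixel_spacing)
    # voxel index coordinates
    idx = (pts - phantom.origin[None, None, :]) / phantom.spacing[None, None, :]
    shape = np.array(phantom.shape, dtype=float)
    inside = np.all((idx >= 0.0) & (idx <= shape - 1.0), axis=-1)
    coords = np.moveaxis(idx, -1, 0)
    ech = map_coordinates(phantom.grid, coords, order=1, mode="nearest")
    lab = map_coordinates(phantom.labels, coords, order=0, mode="nearest")
    ech[~inside] = phantom.background
    lab[~inside] = 0
    return ech, lab.astype(np.int16), ~inside


def render_bmode(
    echogenicity: np.ndarray,
    labels: np.ndarray,
    out_of_volume: np.ndarray,
    pixel_spacing: float,
    attenuation_coeff: float = 0.01,
    noise_seed: int = 0,
    speckle: bool = True,
    gain: float = 50.0,
    pose: ProbePose | None = None,
) -> BModeImage:
    """Turn a resampled echogenicity plane into a display image.

    The pixel model is ``I = echogenicity * exp(-mu * depth) * s`` with
    ``mu = attenuation_coeff`` (per mm) and ``s`` unit-mean Rayleigh speckle
    (multiplicative, seeded), followed by log compression
    ``log1p(gain * I) / log1p(gain)`` and scaling to 8 bits.  With
    attenuation 0 and speckle disabled the image is a monotone rescaling of
    echogenicity.
    """
    if attenuation_coeff < 0:
        raise ValidationError("attenuation_coeff must be >= 0")
    ech = np.asarray(echogenicity, dtype=float)
    depth = (np.arange(ech.shape[0]) * pixel_spacing)[:, None]
    intensity = ech * np.exp(-attenuation_coeff * depth)
    if speckle:
        rng = np.random.default_rng(int(noise_seed))
        # Rayleigh(scale=sqrt(2/pi)) has mean exactly 1
        intensity = intensity * rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=ech.shape)
    compressed = np.log1p(gain * np.clip(intensity, 0.0, None)) / np.log1p(gain)
    pixels = np.clip(np.rint(np.clip(compressed, 0.0, 1.0) * 255.0), 0, 255).astype(np.uint8)
    labels = np.asarray(labels)
    oov = np.asarray(out_of_volume, dtype=bool)
    return BModeImage(
        pixels=pixels,
        mask=(labels > 0) & ~oov,
        labels=labels,
        out_of_volume=oov,
        pixel_spacing=float(pixel_spacing),
        pose=pose,
        noise_seed=int(noise_seed),
    )


def acquire(
    phantom: Phantom,
    pose: ProbePose,
    geometry: GantryGeometry,
    pixel_spacing: float = 0.5,
    attenuation_coeff: float = 0.01,
    noise_seed: int = 0,
    speckle: bool = True,
    gain: float = 50.0,
) -> BModeImage:
    """Extract and render a slice in one call (the per-pose "image capture")."""
    ech, lab, oov = extract_slice(phantom, pose, geometry, pixel_spacing)
    return render_bmode(
        ech, lab, oov, pixel_spacing,
        attenuation_coeff=attenuation_coeff,
        noise_seed=noise_seed, speckle=speckle, gain=gain, pose=pose,
    )


def occlude(image: BModeImage, rows: slice, cols: slice, fill: float) -> BModeImage:
    """Copy of the image with a rectangular region replaced by a background
    intensity and stripped of lesion content (used by occlusion saliency)."""
    pixels = image.pixels.copy()
    mask = image.mask.copy()
    labels = image.labels.copy()
    pixels[rows, cols] = np.uint8(np.clip(round(fill), 0, 255))
    mask[rows, cols] = False
    labels[rows, cols] = 0
    return replace(image, pixels=pixels, mask=mask, labels=labels)


def save_image(image: BModeImage, png_path, mask_path=None, sidecar_path=None) -> None:
    """Write the image (8-bit grayscale PNG), optionally the mask (0/255 PNG)
    and a JSON sidecar with pose, seed and spacing."""
    iio.imwrite(str(png_path), image.pixels)
    if mask_path is not None:
        iio.imwrite(str(mask_path), (image.mask.astype(np.uint8)) * 255)
    if sidecar_path is not None:
        pose = image.pose
        meta = {
            "pixel_spacing_mm": image.pixel_spacing,
            "noise_seed": image.noise_seed,
            "pose": None if pose is None else
                {"x_mm": pose.x, "pitch_deg": pose.pitch, "roll_deg": pose.roll},
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")
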