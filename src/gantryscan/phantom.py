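"""Digital tissue phantoms with embedded ellipsoidal lesions.

A phantom is a 3-D voxel grid of echogenicity (relative scatterer strength in
[0, 1]) plus an integer label grid marking which voxels belong to which
lesion.  It stands in for the tissue-mimicking breast phantoms used to
validate motorized ultrasound gantries: a roughly 16 x 12 cm block with
embedded tumors 1.2-1.8 cm in diameter.

Coordinate convention (fixed throughout the package):

* ``x`` — travel axis of the linear rail, mm
* ``y`` — lateral axis, mm
* ``z`` — depth, mm, increasing downward from the phantom surface (z = 0)

Voxel centers sit at ``origin + index * spacing`` (node-centered grid);
indices are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

from ._util import ValidationError

__all__ = [
    "LesionSpec",
    "Phantom",
    "build_phantom",
    "two_tumor_layout",
    "save_phantom",
    "load_phantom",
]

#: Lesion diameter range (mm) reported for commercial breast phantoms.
LESION_DIAMETER_RANGE = (12.0, 18.0)


@dataclass(frozen=True)
class LesionSpec:
    """An ellipsoidal lesion: center and semi-axes in mm, plus an
    echogenicity contrast in [-1, 1] relative to the background level
    (negative = hypoechoic, the usual appearance of solid tumors)."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    echogenicity: float = -0.25

    def __post_init__(self):
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        r = tuple(float(v) for v in self.radii)
        object.__setattr__(self, "radii", r)
        if len(self.center) != 3 or len(r) != 3:
            raise ValidationError("lesion center and radii must be 3-vectors")
        if any(v <= 0 for v in r):
            raise ValidationError(f"lesion radii must be positive, got {r}")
        if not -1.0 <= self.echogenicity <= 1.0:
            raise ValidationError(
                f"lesion echogenicity contrast must lie in [-1, 1], "
                f"got {self.echogenicity}"
            )

    @classmethod
    def sphere(cls, center, diameter: float, echogenicity: float = -0.25) -> "LesionSpec":
        r = diameter / 2.0
        return cls(tuple(center), (r, r, r), echogenicity)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Ellipsoid inclusion test for an (..., 3) array of world points."""
        d = (np.asarray(points, dtype=float) - np.array(self.center)) / np.array(self.radii)
        return np.sum(d * d, axis=-1) <= 1.0

    def volume(self) -> float:
        """Analytic ellipsoid volume, mm^3."""
        a, b, c = self.radii
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass
class Phantom:
    """Voxelized tissue block.

    ``grid`` holds echogenicity in [0, 1]; ``labels`` holds 0 for background
    and ``k`` for voxels whose centers fall inside lesion ``k`` (1-based,
    matching the order of ``lesions``).
    """

    grid: np.ndarray
    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    background: float
    lesions: list[LesionSpec] = field(default_factory=list)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.labels = np.asarray(self.labels)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.grid.shape != self.labels.shape:
            raise ValidationError("grid and labels must have identical shape")
        if np.any(self.spacing <= 0):
            raise ValidationError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def extent(self) -> np.ndarray:
        """Nominal physical extent (mm) along each axis."""
        return np.array(self.shape) * self.spacing

    def voxel_centers(self, stride: int = 1) -> np.ndarray:
        """World coordinates of (optionally strided) voxel centers,
        shape (n, 3)."""
        axes = [
            self.origin[a] + np.arange(0, self.shape[a], stride) * self.spacing[a]
            for a in range(3)
        ]
        grid = np.meshgrid(*axes, indexing="ij")
        return np.stack([g.ravel() for g in grid], axis=-1)


def _validate_lesions(lesions, extent):
    extent = np.asarray(extent, dtype=float)
    for idx, les in enumerate(lesions):
        c = np.array(les.center)
        r = np.array(les.radii)
        if np.any(c - r < 0) or np.any(c + r > extent):
            raise ValidationError(
                f"lesion {idx} (center {les.center}, radii {les.radii}) "
                f"extends outside the phantom extent {tuple(extent)}"
            )


def build_phantom(
    extent=(160.0, 120.0, 60.0),
    spacing=(1.0, 1.0, 1.0),
    background_echogenicity: float = 0.35,
    lesions: list[LesionSpec] | None = None,
    texture_seed: int = 0,
    texture_amplitude: float = 0.05,
    texture_smoothing: float = 1.5,
) -> Phantom:
    """Build a phantom with the given lesions and a seeded background texture.

    Parameters
    ----------
    extent
        Physical size (mm) along (x, y, z).  The default footprint matches a
        16 x 12 cm breast phantom; depth 60 mm is a package default.
    spacing
        Voxel size (mm); the grid has ``round(extent / spacing)`` voxels per
        axis (at least 2).
    background_echogenicity
        Baseline echogenicity of tissue outside any lesion.
    lesions
        Lesion specifications; each must lie fully inside the extent.  Where
        lesions overlap, the later one wins the label.
    texture_seed
        Seed for the background texture (zero-mean Gaussian noise, smoothed,
        rescaled to ``texture_amplitude`` standard deviation).  The texture
        keeps slices from being piecewise constant; it makes no claim of
        acoustic realism.
    """
    extent = np.asarray(extent, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    if extent.shape != (3,) or spacing.shape != (3,):
        raise ValidationError("extent and spacing must be 3-vectors")
    if np.any(spacing <= 0):
        raise ValidationError("spacing must be positive")
    shape = tuple(int(round(e / s)) for e, s in zip(extent, spacing))
    if any(n < 2 for n in shape):
        raise ValidationError(
            f"extent/spacing must yield at least 2 voxels per axis, got {shape}"
        )
    lesions = list(lesions or [])
    _validate_lesions(lesions, extent)
    if not 0.0 <= background_echogenicity <= 1.0:
        raise ValidationError("background echogenicity must lie in [0, 1]")

    origin = np.zeros(3)
    axes = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    base = np.full(shape, background_echogenicity, dtype=float)
    labels = np.zeros(shape, dtype=np.int16)

    for k, les in enumerate(lesions, start=1):
        # restrict the inclusion test to the lesion's bounding box
        lo = [int(np.floor((les.center[a] - les.radii[a] - origin[a]) / spacing[a])) for a in range(3)]
        hi = [int(np.ceil((les.center[a] + les.radii[a] - origin[a]) / spacing[a])) + 1 for a in range(3)]
        lo = [max(0, v) for v in lo]
        hi = [min(shape[a], hi[a]) for a in range(3)]
        sub = np.meshgrid(*[axes[a][lo[a]:hi[a]] for a in range(3)], indexing="ij")
        pts = np.stack(sub, axis=-1)
        inside = les.contains(pts)
        region = tuple(slice(lo[a], hi[a]) for a in range(3))
        labels[region][inside] = k
        base[region][inside] = np.clip(
            background_echogenicity + les.echogenicity, 0.0, 1.0
        )

    if texture_amplitude > 0:
        rng = np.random.default_rng(int(texture_seed))
        noise = gaussian_filter(rng.standard_normal(shape), texture_smoothing)
        sd = noise.std()
        if sd > 0:
            noise *= texture_amplitude / sd
        base = np.clip(base + noise, 0.0, 1.0)

    return Phantom(
        grid=base,
        labels=labels,
        spacing=spacing,
        origin=origin,
        background=background_echogenicity,
        lesions=lesions,
    )


def two_tumor_layout(
    on_axis_diameter: float = 14.0,
    off_axis_diameter: float = 18.0,
    off_axis_offset: float = 42.0,
    extent=(160.0, 120.0, 60.0),
    on_axis_x: float = 60.0,
    off_axis_x: float = 100.0,
    on_axis_depth: float = 30.0,
    off_axis_depth: float = 40.0,
) -> list[LesionSpec]:
    """Two-lesion validation layout: tumor 1 centered on the central scan
    line, tumor 2 displaced laterally by ``off_axis_offset`` mm.

    This mirrors the standard gantry-validation phantom in which one tumor
    lies on the scanning line (seen by a purely linear scan) and the second
    sits off to one side, outside the zero-angle imaging slab, so only an
    angular (gimbal) scan can reach it.
    """
    lo, hi = LESION_DIAMETER_RANGE
    for name, d in (("on_axis", on_axis_diameter), ("off_axis", off_axis_diameter)):
        if not lo <= d <= hi:
            raise ValidationError(
                f"{name} diameter {d} mm outside the phantom lesion range "
                f"[{lo}, {hi}] mm"
            )
    extent = np.asarray(extent, dtype=float)
    y_center = extent[1] / 2.0
    specs = [
        LesionSpec.sphere((on_axis_x, y_center, on_axis_depth), on_axis_diameter, -0.25),
        LesionSpec.sphere(
            (off_axis_x, y_center + off_axis_offset, off_axis_depth),
            off_axis_diameter,
            -0.25,
        ),
    ]
    _validate_lesions(specs, extent)
    return specs


def _affine(phantom_spacing, origin):
    aff = np.eye(4)
    aff[:3, :3] = np.diag(phantom_spacing)
    aff[:3, 3] = origin
    return aff


def save_phantom(phantom: Phantom, grid_path, labels_path, meta_path=None) -> None:
    """Write the phantom as a pair of NIfTI volumes (echogenicity float32,
    labels int16); spacing and origin go into the affine.  An optional JSON
    sidecar records the background level and lesion specs."""
    aff = _affine(phantom.spacing, phantom.origin)
    nib.save(nib.Nifti1Image(phantom.grid.astype(np.float32), aff), str(grid_path))
    nib.save(nib.Nifti1Image(phantom.labels.astype(np.int16), aff), str(labels_path))
    if meta_path is not None:
        meta = {
            "background": phantom.background,
            "lesions": [
                {"center": list(l.center), "radii": list(l.radii),
                 "echogenicity": l.echogenicity}
                for l in phantom.lesions
            ],
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


def load_phantom(grid_path, labels_path, meta_path=None) -> Phantom:
    """Load a phantom previously written by :func:`save_phantom`."""
    gimg = nib.load(str(grid_path))
    limg = nib.load(str(labels_path))
    grid = np.asarray(gimg.dataobj, dtype=float)
    labels = np.asarray(limg.dataobj, dtype=np.int16)
    aff = gimg.affine
    spacing = np.diag(aff)[:3].copy()
    origin = aff[:3, 3].copy()
    background = float(np.median(grid))
    lesions: list[LesionSpec] = []
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = json.load(fh)
        background = float(meta["background"])
        lesions = [
            LesionSpec(tuple(l["center"]), tuple(l["radii"]), l["echogenicity"])
            for l in meta["lesions"]
        ]
    return Phantom(
        grid=grid, labels=labels, spacing=spacing, origin=origin,
        background=background, lesions=lesions,
    )
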