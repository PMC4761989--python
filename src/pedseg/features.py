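"""Per-region feature extraction for candidate PED regions.

Features are extracted B-scan by B-scan from the 8-connected 2D components
of the initial segmentation mask, 62 values per region:

* f1-f17   shape/intensity: area, perimeter, major/minor axis length,
           their ratio, perimeter/area, eccentricity, orientation, Euler
           number, bright-pixel count (above the B-scan's Otsu threshold),
           equivalent diameter, solidity, extent, convex-hull area, and
           max/min/mean intensity;
* f18-f21  signed axial distance (voxels) from the region centroid to the
           ILM, EZ roof, RPE floor and BM on the centroid's column;
* f22-f28  centroid x, z and intensity, plus the axis-aligned bounding
           rectangle (min x, min z, width, height);
* f29-f52  the extremum pixel in each of 8 compass directions, as
           (x, z, intensity) triples;
* f53-f62  regional means of the two Hessian eigenvalues (ordered by
           magnitude) at Gaussian scales 1, 3, 6, 9 and 14.

Ellipse features follow the normalized-second-central-moment convention
(the de-facto regionprops definition). Coordinate features are in voxel
units, deliberately not micrometres: within one acquisition protocol the
spacing is constant, and the classifier only compares regions to regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label
from skimage.measure import regionprops

from .io import ContractError, Surface

__all__ = [
    "CandidateRegion",
    "FEATURE_NAMES",
    "HESSIAN_SCALES",
    "components_2d",
    "extract_features",
    "hessian_features",
    "extract_all_features",
]

HESSIAN_SCALES = (1.0, 3.0, 6.0, 9.0, 14.0)

#: Eight compass directions in the (x, z) plane, z increasing downward.
_DIRECTIONS = (
    (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1),
)

FEATURE_NAMES: tuple[str, ...] = (
    "area", "perimeter", "major_axis", "minor_axis", "axis_ratio",
    "perimeter_over_area", "eccentricity", "orientation", "euler_number",
    "n_bright_pixels", "equivalent_diameter", "solidity", "extent",
    "convex_area", "max_intensity", "min_intensity", "mean_intensity",
    "dist_centroid_ilm", "dist_centroid_ez", "dist_centroid_rpe",
    "dist_centroid_bm",
    "centroid_x", "centroid_z", "centroid_intensity",
    "bbox_min_x", "bbox_min_z", "bbox_width", "bbox_height",
) + tuple(
    f"ext_{d}_{c}"
    for d in ("e", "ne", "n", "nw", "w", "sw", "s", "se")
    for c in ("x", "z", "intensity")
) + tuple(
    f"hessian_l{i}_s{int(s)}" for s in HESSIAN_SCALES for i in (1, 2)
)

assert len(FEATURE_NAMES) == 62


@dataclass
class CandidateRegion:
    """One 8-connected 2D component of the initial mask on one B-scan."""

    bscan: int
    pixels: np.ndarray  # (n, 2) array of (x, z) coordinates
    label: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.int64)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2 or not len(self.pixels):
            raise ContractError("region pixels must be a non-empty (n, 2) array")

    @property
    def size(self) -> int:
        return len(self.pixels)


def components_2d(mask_slice: np.ndarray, bscan: int = 0) -> list[CandidateRegion]:
    """8-connected components of a binary (nx, nz) slice, in raster order."""
    mask_slice = np.asarray(mask_slice).astype(bool)
    labels = _cc_label(mask_slice.T, connectivity=2).T  # raster order over (z, x)
    out = []
    for lab in range(1, labels.max() + 1):
        xs, zs = np.nonzero(labels == lab)
        out.append(CandidateRegion(bscan, np.column_stack([xs, zs]), lab))
    return out


def _hessian_eigen_images(image_zx: np.ndarray, sigma: float):
    """Magnitude-ordered Hessian eigenvalue images at Gaussian scale sigma."""
    hzz = gaussian_filter(image_zx, sigma, order=(2, 0), mode="nearest")
    hxx = gaussian_filter(image_zx, sigma, order=(0, 2), mode="nearest")
    hzx = gaussian_filter(image_zx, sigma, order=(1, 1), mode="nearest")
    tr_half = (hxx + hzz) / 2.0
    disc = np.sqrt(((hxx - hzz) / 2.0) ** 2 + hzx**2)
    lam_a = tr_half + disc
    lam_b = tr_half - disc
    swap = np.abs(lam_a) > np.abs(lam_b)
    lam1 = np.where(swap, lam_b, lam_a)   # |lam1| <= |lam2|
    lam2 = np.where(swap, lam_a, lam_b)
    return lam1, lam2


def hessian_features(region: CandidateRegion, image: np.ndarray,
                     scales=HESSIAN_SCALES) -> np.ndarray:
    """Regional means of both Hessian eigenvalues at each scale (2 per scale)."""
    image_zx = np.asarray(image, dtype=np.float64).T  # (nz, nx)
    xs, zs = region.pixels[:, 0], region.pixels[:, 1]
    vals = []
    for sigma in scales:
        lam1, lam2 = _hessian_eigen_images(image_zx, sigma)
        vals.append(lam1[zs, xs].mean())
        vals.append(lam2[zs, xs].mean())
    return np.asarray(vals)


def extract_features(region: CandidateRegion, image: np.ndarray,
                     surfaces: dict[str, Surface]) -> np.ndarray:
    """The 62-value feature vector of one candidate region.

    ``image`` is the (nx, nz) B-scan the region lives on; ``surfaces``
    must contain ILM, EZ_ROOF, RPE_FLOOR and BM height maps. Deterministic;
    directional-extremum ties break in raster order.
    """
    image = np.asarray(image, dtype=np.float64)
    nx, nz = image.shape
    xs, zs = region.pixels[:, 0], region.pixels[:, 1]
    if xs.min() < 0 or zs.min() < 0 or xs.max() >= nx or zs.max() >= nz:
        raise ContractError("region pixels outside the image bounds")

    mask = np.zeros((nz, nx), dtype=np.uint8)
    mask[zs, xs] = 1
    props = regionprops(mask, intensity_image=image.T)[0]

    area = float(props.area)
    perimeter = float(props.perimeter)
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    axis_ratio = major / minor if minor > 0 else 0.0
    intens = image[xs, zs]

    otsu = threshold_otsu(image) if image.min() < image.max() else image.max()
    n_bright = float(np.count_nonzero(intens > otsu))

    cz, cx = props.centroid  # row=z, col=x
    ci = float(image[int(round(cx)), int(round(cz))])

    col = int(np.clip(round(cx), 0, surfaces["ILM"].heights.shape[0] - 1))
    b = min(region.bscan, surfaces["ILM"].heights.shape[1] - 1)
    dists = [
        cz - float(surfaces[name].heights[col, b])
        for name in ("ILM", "EZ_ROOF", "RPE_FLOOR", "BM")
    ]

    min_z, min_x, max_z, max_x = props.bbox  # half-open

    f = [
        area, perimeter, major, minor, axis_ratio, perimeter / area,
        float(props.eccentricity), float(props.orientation),
        float(props.euler_number), n_bright,
        float(props.equivalent_diameter_area), float(props.solidity),
        float(props.extent), float(props.area_convex),
        float(intens.max()), float(intens.min()), float(intens.mean()),
        *dists,
        cx, cz, ci,
        float(min_x), float(min_z), float(max_x - min_x), float(max_z - min_z),
    ]

    order = np.lexsort((xs, zs))  # raster order: z, then x
    xo, zo = xs[order], zs[order]
    for dx, dz in _DIRECTIONS:
        proj = dx * xo + dz * zo
        i = int(np.argmax(proj))  # first (raster-order) maximum wins
        f.extend([float(xo[i]), float(zo[i]), float(image[xo[i], zo[i]])])

    f.extend(hessian_features(region, image))
    vec = np.asarray(f, dtype=np.float64)
    assert vec.shape == (62,) and np.all(np.isfinite(vec))
    return vec


def extract_all_features(volume_data: np.ndarray, mask: np.ndarray,
                         surfaces: dict[str, Surface]
                         ) -> tuple[list[CandidateRegion], np.ndarray]:
    """All candidate regions of a 3D mask with their feature matrix.

    Iterates B-scans, collects 8-connected 2D components and stacks their
    feature vectors into an (n_regions, 62) matrix.
    """
    regions: list[CandidateRegion] = []
    rows = []
    for b in range(volume_data.shape[1]):
        slice_mask = mask[:, b, :]
        if not slice_mask.any():
            continue
        image = volume_data[:, b, :]
        for region in components_2d(slice_mask, bscan=b):
            regions.append(region)
            rows.append(extract_features(region, image, surfaces))
    feats = np.asarray(rows) if rows else np.empty((0, 62))
    return regions, feats
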