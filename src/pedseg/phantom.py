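"""Seeded synthetic SD-OCT phantoms with known surfaces and PED masks.

A phantom paints noise-free intensity bands between four smooth surfaces
(ILM, EZ roof, RPE floor, BM; z increases with depth):

* background above the ILM and below BM,
* a bright inner band (NFL level) from the ILM down,
* a dark outer-nuclear band (ONL level) down to the EZ roof,
* the bright EZ/RPE complex from the EZ roof to the RPE floor,
* where a serous PED lifts the RPE floor off the near-planar BM baseline,
  a hypo-reflective arch-shaped lumen in the half-open slab (RPE, BM].

PEDs are half-ellipsoid lifts of the RPE floor; optional confounding fluid
pockets are dark half-ellipsoid notches carved into the EZ/RPE band just
above the RPE floor (emulating subretinal fluid), which mislead a
bright-to-dark boundary search and so exercise the false-positive removal
stages. Speckle is multiplicative unit-mean gamma noise.

The generator is a pure function of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .io import INTENSITY_RANGE, OctVolume, RegionMask, Surface

__all__ = [
    "CapSpec",
    "PhantomParams",
    "PhantomTruth",
    "PhantomParamError",
    "generate_phantom",
    "add_speckle",
]


class PhantomParamError(ValueError):
    """Invalid phantom parameters."""


@dataclass(frozen=True)
class CapSpec:
    """One half-ellipsoid cap: a PED dome or a fluid-pocket notch.

    ``center_x``/``center_b`` locate the apex column; ``half_width`` and
    ``half_depth`` are the semi-axes along x and B (voxels); ``apex`` is
    the lift height at the center (voxels).
    """

    center_x: float
    center_b: float
    half_width: float
    half_depth: float
    apex: float

    def lift(self, nx: int, nB: int) -> np.ndarray:
        """Half-ellipsoid height field h(x, B) >= 0 on the grid."""
        x = np.arange(nx)[:, None]
        b = np.arange(nB)[None, :]
        q = ((x - self.center_x) / self.half_width) ** 2 + (
            (b - self.center_b) / self.half_depth
        ) ** 2
        h = np.where(q < 1.0, self.apex * np.sqrt(np.clip(1.0 - q, 0.0, 1.0)), 0.0)
        return h


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, intensity and noise parameters of a synthetic volume.

    Defaults give a desk-scale 128 x 16 x 160 phantom whose layer
    thicknesses and contrasts mimic (in voxels and grey levels) the macular
    anatomy the segmentation stages assume. Band levels live inside the
    0..255 raster range with the PED lumen darker than the RPE band.
    """

    nx: int = 128
    nB: int = 16
    nz: int = 160

    # band grey levels
    level_background: float = 10.0
    level_nfl: float = 130.0
    level_onl: float = 45.0
    level_ez: float = 140.0
    level_rpe: float = 170.0
    level_lumen: float = 30.0

    # geometry (voxels)
    ilm_depth: float = 40.0
    nfl_thickness: int = 10
    onl_to_ez: int = 30          # ILM -> EZ roof offset
    ez_to_rpe: int = 12          # EZ roof -> RPE floor offset
    bm_depth: float = 95.0       # BM baseline depth
    bm_tilt: float = 0.02        # BM slope along x (voxel per voxel)

    # smooth low-frequency undulation of the ILM
    undulation_amplitude: float = 2.5
    undulation_length: float = 40.0

    peds: tuple[CapSpec, ...] = (CapSpec(64.0, 8.0, 20.0, 5.5, 16.0),)
    confounders: tuple[CapSpec, ...] = ()

    speckle_scale: float = 0.0   # gamma-speckle std; 0 = noise free
    seed: int = 0

    def validate(self) -> None:
        if min(self.nx, self.nB, self.nz) < 8:
            raise PhantomParamError("all voxel counts must be >= 8")
        lo, hi = INTENSITY_RANGE
        for name in (
            "level_background",
            "level_nfl",
            "level_onl",
            "level_ez",
            "level_rpe",
            "level_lumen",
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise PhantomParamError(f"{name}={v} outside raster range {INTENSITY_RANGE}")
        if self.level_lumen >= self.level_rpe:
            raise PhantomParamError("PED lumen must be darker than the RPE band")
        for cap in self.peds + self.confounders:
            if cap.apex < 1:
                raise PhantomParamError("every cap apex height must be >= 1 voxel")
            if cap.half_width <= 0 or cap.half_depth <= 0:
                raise PhantomParamError("cap semi-axes must be positive")
        if self.speckle_scale < 0:
            raise PhantomParamError("speckle scale must be >= 0")


@dataclass
class PhantomTruth:
    """Ground-truth surfaces and masks of a generated phantom."""

    surfaces: dict[str, Surface]
    ped_mask: RegionMask
    retina_mask: RegionMask


def _smooth_field(rng: np.random.Generator, nx: int, nB: int, amplitude: float,
                  length: float) -> np.ndarray:
    """Low-frequency random undulation via Gaussian-smoothed white noise."""
    if amplitude == 0:
        return np.zeros((nx, nB))
    from scipy.ndimage import gaussian_filter

    noise = rng.standard_normal((nx, nB))
    sig_x = max(length / 4.0, 1.0)
    sig_b = max(length / 16.0, 1.0)
    smooth = gaussian_filter(noise, sigma=(sig_x, sig_b), mode="reflect")
    peak = np.abs(smooth).max()
    return amplitude * smooth / peak if peak > 0 else smooth


def _caps_overlap(caps) -> bool:
    for i in range(len(caps)):
        for j in range(i + 1, len(caps)):
            a, b = caps[i], caps[j]
            dx = (a.center_x - b.center_x) / (a.half_width + b.half_width)
            db = (a.center_b - b.center_b) / (a.half_depth + b.half_depth)
            if dx * dx + db * db < 1.0:
                return True
    return False


def generate_phantom(params: PhantomParams) -> tuple[OctVolume, PhantomTruth]:
    """Generate a noise-free phantom volume and its ground truth.

    Raises
    ------
    PhantomParamError
        If parameters are invalid, caps overlap, or the implied surfaces
        would cross or leave the grid.
    """
    params.validate()
    if _caps_overlap(params.peds + params.confounders):
        raise PhantomParamError("overlapping caps would force surface crossing")

    rng = np.random.default_rng(params.seed)
    nx, nB, nz = params.nx, params.nB, params.nz

    ilm = params.ilm_depth + _smooth_field(
        rng, nx, nB, params.undulation_amplitude, params.undulation_length
    )
    bm = params.bm_depth + params.bm_tilt * (np.arange(nx)[:, None] - nx / 2.0)
    bm = np.broadcast_to(bm, (nx, nB)).copy()

    ped_lift = np.zeros((nx, nB))
    for cap in params.peds:
        ped_lift += cap.lift(nx, nB)
    rpe = bm - ped_lift
    ez = rpe - params.ez_to_rpe
    inner = ilm + params.nfl_thickness

    ilm_i = np.round(ilm).astype(np.int64)
    bm_i = np.round(bm).astype(np.int64)
    rpe_i = np.round(rpe).astype(np.int64)
    ez_i = np.round(ez).astype(np.int64)
    inner_i = np.round(inner).astype(np.int64)

    if np.any(ilm_i < 1) or np.any(bm_i >= nz - 1):
        raise PhantomParamError("surfaces leave the axial extent of the grid")
    if not (np.all(ilm_i <= ez_i) and np.all(ez_i <= rpe_i) and np.all(rpe_i <= bm_i)
            and np.all(inner_i <= ez_i)):
        raise PhantomParamError("parameters force surface crossing")

    z = np.arange(nz)[None, None, :]
    vol = np.full((nx, nB, nz), params.level_background, dtype=np.float32)
    vol[(z >= ilm_i[:, :, None]) & (z < inner_i[:, :, None])] = params.level_nfl
    vol[(z >= inner_i[:, :, None]) & (z < ez_i[:, :, None])] = params.level_onl
    mid = (ez_i + rpe_i) // 2
    vol[(z >= ez_i[:, :, None]) & (z < mid[:, :, None])] = params.level_ez
    vol[(z >= mid[:, :, None]) & (z <= rpe_i[:, :, None])] = params.level_rpe

    # PED lumen: half-open slab (rpe, bm], dark
    ped = (z > rpe_i[:, :, None]) & (z <= bm_i[:, :, None])
    vol[ped] = params.level_lumen

    # confounding fluid pockets: dark notches with their floor on the RPE floor
    for cap in params.confounders:
        lift = np.round(cap.lift(nx, nB)).astype(np.int64)
        notch = (z > (rpe_i - lift)[:, :, None]) & (z <= rpe_i[:, :, None]) & (
            lift[:, :, None] > 0
        )
        vol[notch] = params.level_lumen

    retina = (z >= ilm_i[:, :, None]) & (z <= bm_i[:, :, None])

    surfaces = {
        "ILM": Surface("ILM", ilm_i),
        "EZ_ROOF": Surface("EZ_ROOF", ez_i),
        "RPE_FLOOR": Surface("RPE_FLOOR", rpe_i),
        "BM": Surface("BM", bm_i),
    }
    truth = PhantomTruth(
        surfaces=surfaces,
        ped_mask=RegionMask(ped),
        retina_mask=RegionMask(retina),
    )
    volume = OctVolume(vol, spacing=(11.72, 93.75, 3.50))
    if params.speckle_scale > 0:
        volume = add_speckle(volume, params.speckle_scale, params.seed + 1)
    return volume, truth


def random_phantom_params(seed: int, with_confounder: bool = True,
                          speckle_scale: float = 0.25) -> PhantomParams:
    """Randomized study-condition phantom: one serous PED, optionally one
    confounding subretinal-fluid pocket, moderate speckle.

    The PED cap is drawn wide enough (half-width 14-22 voxels, apex 10-18)
    to exercise the large-smoothness surface search; the confounder is a
    smaller notch (half-width 7-11, apex 6-9) placed laterally clear of the
    PED so the two stay separate candidate regions.
    """
    r = np.random.default_rng(seed)
    ped = CapSpec(
        center_x=float(r.uniform(45, 85)),
        center_b=float(r.uniform(6, 10)),
        half_width=float(r.uniform(14, 22)),
        half_depth=float(r.uniform(4.5, 6.5)),
        apex=float(r.uniform(10, 18)),
    )
    confounders: tuple[CapSpec, ...] = ()
    if with_confounder:
        cx = ped.center_x - ped.half_width - r.uniform(14, 20)
        if cx < 12:
            cx = ped.center_x + ped.half_width + r.uniform(14, 20)
        confounders = (CapSpec(
            center_x=float(cx),
            center_b=float(r.uniform(5, 11)),
            half_width=float(r.uniform(7, 11)),
            half_depth=float(r.uniform(2.5, 4)),
            apex=float(r.uniform(6, 9)),
        ),)
    return PhantomParams(seed=int(seed), speckle_scale=speckle_scale,
                         peds=(ped,), confounders=confounders)


def add_speckle(volume: OctVolume, scale: float, seed: int) -> OctVolume:
    """Apply multiplicative unit-mean gamma speckle of standard deviation ``scale``.

    A gamma multiplier with shape ``k = 1/scale**2`` and mean 1 is drawn per
    voxel; the result is clipped to the raster range. ``scale == 0`` returns
    the input unchanged.
    """
    if scale < 0:
        raise PhantomParamError("speckle scale must be >= 0")
    if scale == 0:
        return OctVolume(volume.data.copy(), volume.spacing)
    rng = np.random.default_rng(seed)
    k = 1.0 / (scale * scale)
    mult = rng.gamma(shape=k, scale=1.0 / k, size=volume.data.shape)
    noisy = np.clip(volume.data * mult, *INTENSITY_RANGE).astype(np.float32)
    return OctVolume(noisy, volume.spacing)
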