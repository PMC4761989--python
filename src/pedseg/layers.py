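"""Retinal layer segmentation by multi-scale optimal-surface graph search.

Three boundaries are segmented in order — the ILM (the most prominent
dark-to-bright edge), the photoreceptor ellipsoid-zone roof (dark-to-bright)
and the RPE floor (bright-to-dark) — each as the globally optimal single
surface of a 3D cost raster under hard smoothness constraints (maximum
axial jump between adjacent columns along x and along B). The optimum is
found with the closed-set reduction of Li et al.'s optimal-surface method,
solved as a min s-t cut; ties are broken toward the pointwise-smallest z.

Each surface is searched at three scales: the volume is down-sampled twice
by factor 2 along z, the coarse solution constrains a band around the next
finer search. Bruch's membrane, not directly visible, is estimated per
B-scan as the lower boundary (max-z chain) of the convex hull of the RPE
floor trace; the slab between the RPE floor and BM is the initial serous
PED segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._graph import min_st_cut
from .io import ContractError, OctVolume, RegionMask, Surface, slab_mask

__all__ = [
    "SurfaceSearchSpec",
    "LayerParams",
    "InfeasibleBandError",
    "surface_cost",
    "single_surface_search",
    "multiscale_search",
    "segment_layers",
    "estimate_bm",
    "initial_ped_mask",
]

DARK_TO_BRIGHT = "dark-to-bright"
BRIGHT_TO_DARK = "bright-to-dark"


class InfeasibleBandError(ValueError):
    """No surface satisfying the smoothness constraints fits the bands."""


@dataclass
class SurfaceSearchSpec:
    """Constraints for one surface search.

    ``delta_x``/``delta_b`` bound the axial jump between 4-adjacent columns
    along x and B. ``band_lo``/``band_hi`` are per-column inclusive feasible
    z ranges (scalars broadcast). ``scales`` is the number of factor-2
    axial down-samplings for the multi-scale search; ``margin`` the +/- band
    half-width around the up-sampled coarser surface.
    """

    polarity: str = DARK_TO_BRIGHT
    delta_x: int = 1
    delta_b: int = 1
    band_lo: np.ndarray | int = 0
    band_hi: np.ndarray | int | None = None
    scales: int = 2
    margin: int = 8

    def bands(self, nx: int, nB: int, nz: int) -> tuple[np.ndarray, np.ndarray]:
        lo = np.broadcast_to(np.asarray(self.band_lo, dtype=np.int64), (nx, nB)).copy()
        hi_val = nz - 1 if self.band_hi is None else self.band_hi
        hi = np.broadcast_to(np.asarray(hi_val, dtype=np.int64), (nx, nB)).copy()
        np.clip(lo, 0, nz - 1, out=lo)
        np.clip(hi, 0, nz - 1, out=hi)
        return lo, hi


def surface_cost(volume: OctVolume, polarity: str) -> np.ndarray:
    """Per-voxel boundary cost from the signed axial derivative.

    The boundary voxel is taken to lie on the bright side of its edge:
    dark-to-bright surfaces respond to the backward difference
    ``I[z] - I[z-1]`` (first bright voxel), bright-to-dark surfaces to the
    forward difference ``I[z] - I[z+1]`` (last bright voxel). Cost is the
    negated matching response, so it is low where the edge polarity matches.
    """
    data = volume.data.astype(np.float64)
    if polarity == DARK_TO_BRIGHT:
        g = np.diff(data, axis=2, prepend=data[:, :, :1])
    elif polarity == BRIGHT_TO_DARK:
        g = -np.diff(data, axis=2, append=data[:, :, -1:])
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    return -g


def _propagate_bands(lo, hi, delta_x, delta_b):
    """Tighten bands to mutual consistency; raise if any column empties."""
    lo = lo.copy()
    hi = hi.copy()
    for _ in range(lo.size + 1):
        changed = False
        for axis, d in ((0, delta_x), (1, delta_b)):
            for shift in (1, -1):
                nlo = np.roll(lo, shift, axis=axis)
                nhi = np.roll(hi, shift, axis=axis)
                # roll wraps around; neutralize the wrapped border
                sl = [slice(None), slice(None)]
                sl[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
                nlo[tuple(sl)] = 0
                nhi[tuple(sl)] = hi.max()
                new_lo = np.maximum(lo, nlo - d)
                new_hi = np.minimum(hi, nhi + d)
                if np.any(new_lo != lo) or np.any(new_hi != hi):
                    changed = True
                lo, hi = new_lo, new_hi
        if np.any(lo > hi):
            raise InfeasibleBandError(
                "no surface satisfies the smoothness constraints within the bands"
            )
        if not changed:
            return lo, hi
    return lo, hi


def _dp_search_2d(cost2d: np.ndarray, delta: int, lo: np.ndarray,
                  hi: np.ndarray) -> np.ndarray:
    """Exact DP for the single-B-scan subproblem (float arithmetic).

    Returns the lexicographically smallest (by column, then z) optimal
    height vector.
    """
    from scipy.ndimage import minimum_filter1d

    nx, nz = cost2d.shape
    INF = np.inf
    banded = np.full((nx, nz), INF)
    for i in range(nx):
        banded[i, lo[i]: hi[i] + 1] = cost2d[i, lo[i]: hi[i] + 1]

    suffix = np.empty_like(banded)
    suffix[-1] = banded[-1]
    size = 2 * delta + 1
    for i in range(nx - 2, -1, -1):
        if delta >= nz:
            reach = np.full(nz, suffix[i + 1].min())
        else:
            reach = minimum_filter1d(suffix[i + 1], size=size,
                                     mode="constant", cval=INF)
        suffix[i] = banded[i] + reach

    heights = np.empty(nx, dtype=np.int64)
    best = suffix[0].min()
    if not np.isfinite(best):
        raise InfeasibleBandError("no feasible surface in the bands")
    heights[0] = int(np.flatnonzero(suffix[0] == best)[0])
    for i in range(1, nx):
        zlo = max(heights[i - 1] - delta, 0)
        zhi = min(heights[i - 1] + delta, nz - 1)
        window = suffix[i, zlo: zhi + 1]
        heights[i] = zlo + int(np.flatnonzero(window == window.min())[0])
    return heights


def single_surface_search(cost: np.ndarray, spec: SurfaceSearchSpec,
                          name: str = "surface") -> Surface:
    """Globally optimal surface through a 3D cost raster.

    Minimizes the total cost over all height maps ``S(x, B)`` inside the
    bands with ``|S(x+1,B)-S(x,B)| <= delta_x`` and
    ``|S(x,B+1)-S(x,B)| <= delta_b``, via the minimum-closed-set min-cut
    reduction. Among equal-cost optima the pointwise-smallest surface is
    returned.
    """
    cost = np.asarray(cost, dtype=np.float64)
    nx, nB, nz = cost.shape
    lo, hi = spec.bands(nx, nB, nz)
    if np.any(lo > hi):
        raise InfeasibleBandError("empty feasible band")
    lo, hi = _propagate_bands(lo, hi, spec.delta_x, spec.delta_b)

    if nB == 1:  # exact float DP for the 2D subproblem
        heights = _dp_search_2d(cost[:, 0, :], spec.delta_x, lo[:, 0], hi[:, 0])
        return Surface(name, heights[:, None])

    counts = (hi - lo + 1).ravel()
    offsets = np.concatenate([[0], np.cumsum(counts)])
    n_nodes = int(offsets[-1])
    col_of = np.repeat(np.arange(nx * nB), counts)
    k_of = np.arange(n_nodes) - offsets[col_of] + lo.ravel()[col_of]

    cflat = cost.reshape(nx * nB, nz)
    node_cost = cflat[col_of, k_of]
    is_base = k_of == lo.ravel()[col_of]
    prev_cost = np.where(is_base, 0.0, cflat[col_of, np.maximum(k_of - 1, 0)])
    # base nodes are forced into the closed set by an infinite source link,
    # so their own cost is a constant offset and their weight is 0
    w = np.where(is_base, 0.0, node_cost - prev_cost)

    tails = [np.flatnonzero(~is_base)]
    heads = [tails[0] - 1]                      # in-column closure edges
    INF_placeholder = None

    # smoothness edges: node (col, k) -> (neighbor col, k - delta)
    grid = np.arange(nx * nB).reshape(nx, nB)
    lo_flat = lo.ravel()
    for axis, d in ((0, spec.delta_x), (1, spec.delta_b)):
        for shift in (-1, 1):
            nb = np.roll(grid, shift, axis=axis)
            sl = [slice(None), slice(None)]
            sl[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
            nb = nb.copy()
            nb[tuple(sl)] = -1                  # no neighbor across the border
            nb_of_node = nb.ravel()[col_of]
            tgt_k = k_of - d
            ok = (nb_of_node >= 0) & (tgt_k > lo_flat[np.maximum(nb_of_node, 0)])
            src = np.flatnonzero(ok)
            nbc = nb_of_node[src]
            tails.append(src)
            heads.append(offsets[nbc] + (tgt_k[src] - lo_flat[nbc]))

    e_tails = np.concatenate(tails)
    e_heads = np.concatenate(heads)

    s, t = n_nodes, n_nodes + 1
    neg = np.flatnonzero(w < 0)
    pos = np.flatnonzero(w > 0)
    base = np.flatnonzero(is_base)
    st_tails = np.concatenate([np.full(neg.size, s), pos])
    st_heads = np.concatenate([neg, np.full(pos.size, t)])
    st_caps = np.concatenate([-w[neg], w[pos]])
    INF = st_caps.sum() + 1.0

    tails_all = np.concatenate([e_tails, st_tails, np.full(base.size, s)])
    heads_all = np.concatenate([e_heads, st_heads, base])
    caps_all = np.concatenate(
        [np.full(e_tails.size, INF), st_caps, np.full(base.size, INF)]
    )

    side = min_st_cut(n_nodes + 2, tails_all, heads_all, caps_all, s, t, inf=INF)
    included = side[:n_nodes]
    # closed set: per column a prefix [lo .. S]; base nodes always included
    n_in = np.bincount(col_of, weights=included, minlength=nx * nB).astype(np.int64)
    heights = (lo_flat + n_in - 1).reshape(nx, nB)
    return Surface(name, heights)


def _downsample_z(data: np.ndarray) -> np.ndarray:
    """Factor-2 mean pooling along z (trailing odd plane dropped)."""
    nz2 = data.shape[2] // 2
    d = data[:, :, : nz2 * 2]
    return d.reshape(d.shape[0], d.shape[1], nz2, 2).mean(axis=3)


def multiscale_search(volume: OctVolume, spec: SurfaceSearchSpec,
                      name: str = "surface") -> Surface:
    """Coarse-to-fine optimal surface search over ``spec.scales + 1`` scales.

    The coarse surface, up-sampled by 2, restricts the next finer search to
    a band of +/- ``spec.margin`` voxels (intersected with the caller's
    band; if the caller's band excludes it entirely, the search clamps to
    the nearest feasible range). ``scales == 0`` is a plain single-scale
    search.
    """
    nx, nB, nz = volume.shape
    if nz < 4 * 2 ** spec.scales:
        raise ValueError(
            f"volume depth {nz} too shallow for {spec.scales} down-samplings"
        )
    lo0, hi0 = spec.bands(nx, nB, nz)

    pyramid = [volume.data]
    for _ in range(spec.scales):
        pyramid.append(_downsample_z(pyramid[-1]))

    heights = None
    for level in range(spec.scales, -1, -1):
        data = pyramid[level]
        nzl = data.shape[2]
        f = 2 ** level
        lo = np.minimum(-(-lo0 // f), nzl - 1)   # ceil: keep excluded voxels out
        hi = np.minimum(hi0 // f, nzl - 1)
        hi = np.maximum(hi, lo)
        if heights is not None:
            up = heights * 2
            lo = np.maximum(lo, up - spec.margin)
            hi = np.minimum(hi, up + spec.margin)
            bad = lo > hi          # caller band excludes the refined band
            lo[bad] = np.minimum(lo[bad], hi[bad])
            np.clip(lo, 0, nzl - 1, out=lo)
            np.clip(hi, lo, nzl - 1, out=hi)
        level_spec = replace(spec, band_lo=lo, band_hi=hi)
        cost = surface_cost(OctVolume(data, volume.spacing), spec.polarity)
        heights = single_surface_search(cost, level_spec, name).heights
    return Surface(name, heights)


@dataclass(frozen=True)
class LayerParams:
    """Search settings for the three-surface segmentation.

    The ILM is a smooth prominent edge (small jump bound); the EZ roof and
    RPE floor deform abruptly under a PED, so they get a larger smoothness
    allowance. ``min_gap`` keeps consecutive surfaces at least that many
    voxels apart.
    """

    delta_ilm: int = 1
    delta_rpe: int = 4
    min_gap: int = 2
    scales: int = 2
    margin: int = 8


def segment_layers(volume: OctVolume, params: LayerParams | None = None
                   ) -> dict[str, Surface]:
    """Segment ILM, EZ roof and RPE floor in order, each constraining the next."""
    params = params or LayerParams()
    nx, nB, nz = volume.shape

    def run(polarity, delta, lo, hi, name):
        spec = SurfaceSearchSpec(
            polarity=polarity, delta_x=delta, delta_b=delta,
            band_lo=lo, band_hi=hi, scales=params.scales, margin=params.margin,
        )
        try:
            return multiscale_search(volume, spec, name)
        except InfeasibleBandError as exc:
            raise InfeasibleBandError(f"{name}: {exc}") from exc

    ilm = run(DARK_TO_BRIGHT, params.delta_ilm, 0, nz - 1, "ILM")
    ez = run(DARK_TO_BRIGHT, params.delta_rpe,
             ilm.heights + params.min_gap, nz - 1, "EZ_ROOF")
    rpe = run(BRIGHT_TO_DARK, params.delta_rpe,
              ez.heights + params.min_gap, nz - 1, "RPE_FLOOR")
    return {"ILM": ilm, "EZ_ROOF": ez, "RPE_FLOOR": rpe}


def _concave_majorant(z: np.ndarray) -> np.ndarray:
    """Upper (max-z) convex-hull chain of the trace, as floats.

    Monotone-chain over points (x, z); the returned envelope is the
    pointwise-smallest concave function >= z (z increases downward, so on
    screen this is the convex lower boundary of the hull).
    """
    n = z.size
    hull: list[int] = []
    for i in range(n):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            # keep the chain concave: drop i1 if it lies at or below chord i0->i
            if (z[i1] - z[i0]) * (i - i0) <= (z[i] - z[i0]) * (i1 - i0):
                hull.pop()
            else:
                break
        hull.append(i)
    xs = np.asarray(hull, dtype=float)
    return np.interp(np.arange(n, dtype=float), xs, z[np.asarray(hull)])


def estimate_bm(rpe_floor: Surface) -> Surface:
    """Estimate Bruch's membrane as the lower hull boundary of the RPE floor.

    Computed per B-scan in 2D: the max-z chain of the convex hull of the
    points ``(x, z_RPE(x))``. The envelope is >= the RPE floor everywhere
    and touches it at both end columns; a serous arch that lifts the RPE
    floor is bridged by the chord of its shoulders.
    """
    heights = rpe_floor.heights
    bm = np.empty_like(heights)
    for b in range(heights.shape[1]):
        env = _concave_majorant(heights[:, b].astype(float))
        # floor: the discrete envelope never overshoots the chord, which
        # keeps one-voxel slivers from bridging separate arches
        bm[:, b] = np.maximum(np.floor(env + 1e-9).astype(np.int64), heights[:, b])
    return Surface("BM", bm)


def initial_ped_mask(rpe_floor: Surface, bm: Surface, nz: int) -> RegionMask:
    """Initial PED segmentation: half-open slab ``(z_RPE, z_BM]`` per column."""
    if np.any(bm.heights < rpe_floor.heights):
        raise ContractError("BM must lie at or below the RPE floor everywhere")
    return RegionMask(slab_mask(rpe_floor, bm, nz))
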