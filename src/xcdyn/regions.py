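"""Region definitions, shifted-control generation and trajectory assignment.

The flux analysis compares the XC (the RNA-coated compartment) against
randomized control regions obtained by shifting and rotating the XC
mask inside the nucleus. A proposed control is accepted only when it
(1) lies entirely inside the nucleus, (2) sits at a comparable mean
distance from the nuclear periphery (within ±50% of the original's),
(3) overlaps nucleoli by at most 1% of its own area, and (4) overlaps
the original XC and every previously accepted control by at most 10%
of the respective areas. Proposals repeat until the requested number
of controls is found or the iteration budget is exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import (
    RegionMaskSet,
    TrajectoryTable,
    ValidationError,
    positions_to_pixels,
)


@dataclass
class ControlRegionParams:
    """Acceptance rules for shifted control regions."""

    max_regions: int = 10
    max_iterations: int = 500_000
    max_frac_outside_nucleus: float = 0.0
    periphery_distance_frac_bounds: tuple[float, float] = (-0.5, 0.5)
    max_overlap_nucleoli: float = 0.01
    max_overlap_masks: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.periphery_distance_frac_bounds
        if lo > hi:
            raise ValidationError("periphery distance bounds must be ordered")
        for f in (self.max_frac_outside_nucleus, self.max_overlap_nucleoli, self.max_overlap_masks):
            if not 0.0 <= f <= 1.0:
                raise ValidationError("overlap fractions must be in [0, 1]")


# ---------------------------------------------------------------------------
# Combining raw segmentations
# ---------------------------------------------------------------------------


def combine_segmentations(
    nucleus: np.ndarray,
    xist_territory: np.ndarray,
    nucleoli_raw: np.ndarray,
    nucleoplasm_raw: np.ndarray,
    pixel_size: float,
    voxel_depth: float | None = None,
    tag: str = "",
) -> RegionMaskSet:
    """Resolve raw per-class segmentations into the final region set.

    XC = nucleus ∧ territory; nucleoli = nucleus ∧ nucleoli ∧ ¬XC;
    nucleoplasm = nucleus ∧ nucleoplasm ∧ ¬XC. A pixel carrying both the
    territory and nucleolus labels is therefore assigned to the XC.
    """
    nucleus = np.asarray(nucleus, dtype=bool)
    shapes = {np.asarray(m).shape for m in (nucleus, xist_territory, nucleoli_raw, nucleoplasm_raw)}
    if len(shapes) != 1:
        raise ValidationError(f"segmentation shapes differ: {shapes}")
    xc = nucleus & np.asarray(xist_territory, dtype=bool)
    nucleoli = nucleus & np.asarray(nucleoli_raw, dtype=bool) & ~xc
    nucleoplasm = nucleus & np.asarray(nucleoplasm_raw, dtype=bool) & ~xc
    return RegionMaskSet(
        nucleus=nucleus,
        xc=xc,
        nucleoli=nucleoli,
        nucleoplasm=nucleoplasm,
        pixel_size=pixel_size,
        voxel_depth=voxel_depth,
        tag=tag,
    )


# ---------------------------------------------------------------------------
# Mask interpolation (pre/post acquisition masks)
# ---------------------------------------------------------------------------


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Negative inside the mask, positive outside, in pixels."""
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return outside - inside


def interpolate_mask_pair(
    mask_before: np.ndarray, mask_after: np.ndarray, t_frac: float
) -> np.ndarray:
    """Interpolate between two masks by blending signed distances.

    At ``t_frac`` 0/1 the endpoint masks are returned exactly;
    intermediate masks are the zero sublevel set of the linear blend of
    the two signed Euclidean distance transforms, which moves and
    morphs shapes continuously.
    """
    mask_before = np.asarray(mask_before, dtype=bool)
    mask_after = np.asarray(mask_after, dtype=bool)
    if mask_before.shape != mask_after.shape:
        raise ValidationError("masks must share one shape")
    if not 0.0 <= t_frac <= 1.0:
        raise ValidationError("t_frac must be in [0, 1]")
    if t_frac == 0.0:
        return mask_before.copy()
    if t_frac == 1.0:
        return mask_after.copy()
    blend = (1.0 - t_frac) * _signed_distance(mask_before) + t_frac * _signed_distance(mask_after)
    return blend < 0


# ---------------------------------------------------------------------------
# Shifted control regions
# ---------------------------------------------------------------------------


def _mean_periphery_distance(mask_pixels_rc: tuple[np.ndarray, np.ndarray], edt: np.ndarray) -> float:
    return float(edt[mask_pixels_rc].mean())


def check_control_rules(
    control: np.ndarray,
    maskset: RegionMaskSet,
    accepted: list[np.ndarray],
    params: ControlRegionParams,
    nucleus_edt: np.ndarray | None = None,
    reference_distance: float | None = None,
) -> bool:
    """Re-check the four acceptance rules for a candidate control mask."""
    area = int(control.sum())
    if area == 0:
        return False
    if nucleus_edt is None:
        nucleus_edt = ndimage.distance_transform_edt(maskset.nucleus)
    if reference_distance is None:
        reference_distance = float(nucleus_edt[maskset.xc].mean())
    # rule 1: inside the nucleus
    frac_outside = float((control & ~maskset.nucleus).sum()) / area
    if frac_outside > params.max_frac_outside_nucleus:
        return False
    # rule 2: comparable distance to the nuclear periphery
    rel = float(nucleus_edt[control].mean()) / reference_distance - 1.0
    lo, hi = params.periphery_distance_frac_bounds
    if not lo <= rel <= hi:
        return False
    # rule 3: nucleoli overlap
    if float((control & maskset.nucleoli).sum()) / area > params.max_overlap_nucleoli:
        return False
    # rule 4: overlap with the XC and previously accepted controls
    for other in [maskset.xc, *accepted]:
        other_area = int(other.sum())
        olap = int((control & other).sum())
        if olap > params.max_overlap_masks * area or olap > params.max_overlap_masks * other_area:
            return False
    return True


def _inverse_rasterize(
    source: np.ndarray, cr: float, cc: float, theta: float, tr: float, tc: float
) -> tuple[np.ndarray, int]:
    """Nearest-neighbor re-rasterization of ``source`` rotated by theta
    about its centroid (cr, cc) and moved to (tr, tc).

    Target pixels map back into the source frame, which keeps the copy
    hole-free (forward-mapping pixel clouds lose pixels to rounding
    collisions and acquire ragged boundaries). Returns the mask and the
    number of mask pixels falling off the image.
    """
    h, w = source.shape
    rows, cols = np.nonzero(source)
    radius = int(np.ceil(np.hypot(rows - cr, cols - cc).max())) + 2
    gr = np.arange(-radius, radius + 1)
    gg_r, gg_c = np.meshgrid(gr, gr, indexing="ij")
    t_rows = np.rint(tr).astype(int) + gg_r
    t_cols = np.rint(tc).astype(int) + gg_c
    # back-rotate target offsets into the source frame
    off_r = t_rows - tr
    off_c = t_cols - tc
    ct, st = np.cos(theta), np.sin(theta)
    sr = np.rint(off_r * ct + off_c * st + cr).astype(int)
    sc = np.rint(-off_r * st + off_c * ct + cc).astype(int)
    valid_src = (sr >= 0) & (sr < h) & (sc >= 0) & (sc < w)
    member = np.zeros_like(valid_src)
    member[valid_src] = source[sr[valid_src], sc[valid_src]]
    on_img = (t_rows >= 0) & (t_rows < h) & (t_cols >= 0) & (t_cols < w)
    n_off = int((member & ~on_img).sum())
    keep = member & on_img
    out = np.zeros((h, w), dtype=bool)
    out[t_rows[keep], t_cols[keep]] = True
    return out, n_off


def generate_shifted_controls(
    maskset: RegionMaskSet,
    params: ControlRegionParams | None = None,
    seed: int | None = None,
    return_provenance: bool = False,
):
    """Generate randomized shifted/rotated copies of the XC mask.

    Proposals draw a rotation uniform in [0°, 360°) about the XC
    centroid and a translation of the centroid uniform over the nuclear
    bounding box, re-rasterized by nearest neighbor. Each accepted mask
    satisfies the four rules in the module docstring. Returns the list
    of accepted masks (possibly empty); with ``return_provenance`` a
    DataFrame of (shift, rotation, metrics) per accepted mask is
    returned as well.
    """
    params = params or ControlRegionParams()
    rng = np.random.default_rng(seed)
    if maskset.xc.ndim != 2:
        raise ValidationError("control generation operates on 2D masks")
    rows, cols = np.nonzero(maskset.xc)
    if rows.size == 0:
        return ([], pd.DataFrame()) if return_provenance else []
    h, w = maskset.shape
    cr, cc = rows.mean(), cols.mean()
    dr = rows - cr
    dc = cols - cc
    nucleus_edt = ndimage.distance_transform_edt(maskset.nucleus)
    ref_dist = float(nucleus_edt[maskset.xc].mean())
    nrows, ncols = np.nonzero(maskset.nucleus)
    rmin, rmax = nrows.min(), nrows.max()
    cmin, cmax = ncols.min(), ncols.max()

    lo, hi = params.periphery_distance_frac_bounds
    accepted: list[np.ndarray] = []
    prov = []
    remaining = params.max_iterations
    batch = 256
    done = False
    while remaining > 0 and not done:
        nb = min(batch, remaining)
        remaining -= nb
        theta = rng.uniform(0.0, 2 * np.pi, size=nb)
        tr = rng.uniform(rmin, rmax, size=nb)
        tc = rng.uniform(cmin, cmax, size=nb)
        ct, st = np.cos(theta)[:, None], np.sin(theta)[:, None]
        pr = np.rint(dr[None, :] * ct - dc[None, :] * st + tr[:, None]).astype(int)
        pc = np.rint(dr[None, :] * st + dc[None, :] * ct + tc[:, None]).astype(int)
        # cheap duplicate-tolerant screen of rules 1-3, exact re-check below
        inside_img = (pr >= 0) & (pr < h) & (pc >= 0) & (pc < w)
        prc = np.clip(pr, 0, h - 1)
        pcc = np.clip(pc, 0, w - 1)
        in_nuc = maskset.nucleus[prc, pcc] & inside_img
        n_px = pr.shape[1]
        frac_out = 1.0 - in_nuc.sum(axis=1) / n_px
        cand = frac_out <= params.max_frac_outside_nucleus + 1e-12
        if cand.any():
            mean_dist = np.where(
                inside_img, nucleus_edt[prc, pcc], 0.0
            ).sum(axis=1) / np.maximum(inside_img.sum(axis=1), 1)
            rel = mean_dist / ref_dist - 1.0
            cand &= (rel >= lo - 0.05) & (rel <= hi + 0.05)
            olap_nucleoli = (maskset.nucleoli[prc, pcc] & inside_img).sum(axis=1) / n_px
            cand &= olap_nucleoli <= params.max_overlap_nucleoli + 0.005
        for i in np.nonzero(cand)[0]:
            candidate, n_off_img = _inverse_rasterize(
                maskset.xc, cr, cc, theta[i], tr[i], tc[i]
            )
            if n_off_img and params.max_frac_outside_nucleus == 0.0:
                continue
            if not check_control_rules(
                candidate, maskset, accepted, params, nucleus_edt, ref_dist
            ):
                continue
            accepted.append(candidate)
            prov.append(
                {
                    "row_shift": float(tr[i] - cr),
                    "col_shift": float(tc[i] - cc),
                    "rotation_deg": float(np.degrees(theta[i])),
                    "area_px": int(candidate.sum()),
                    "frac_outside_nucleus": float(
                        (candidate & ~maskset.nucleus).sum() / candidate.sum()
                    ),
                    "periphery_distance_rel": float(nucleus_edt[candidate].mean() / ref_dist - 1.0),
                }
            )
            if len(accepted) >= params.max_regions:
                done = True
                break
    if return_provenance:
        return accepted, pd.DataFrame(prov)
    return accepted


# ---------------------------------------------------------------------------
# Trajectory → region assignment
# ---------------------------------------------------------------------------


def assign_trajectories(
    trajs: TrajectoryTable,
    region: np.ndarray | RegionMaskSet,
    rule: str = "any",
) -> pd.Series:
    """Label each trajectory as inside/outside a region raster.

    Rule ``any``: a trajectory is in-region iff at least one of its
    localizations falls inside the region. Rule ``none``: a trajectory
    is labelled True (out-region) iff none of its localizations fall
    inside. Pixel membership of the localization's pixel decides;
    out-of-bounds localizations are clipped with a warning.
    """
    if rule not in ("any", "none"):
        raise ValueError("rule must be 'any' or 'none'")
    mask = region.xc if isinstance(region, RegionMaskSet) else np.asarray(region, dtype=bool)
    if mask.ndim != 2:
        raise ValidationError("assignment needs a 2D raster")
    df = trajs.records
    row, col = positions_to_pixels(
        df["x"].to_numpy(), df["y"].to_numpy(), trajs.pixel_size, mask.shape
    )
    inside = pd.Series(mask[row, col], index=df.index)
    per_traj = inside.groupby(df["trajectory_id"]).any()
    if rule == "any":
        return per_traj
    return ~per_traj


def assign_trajectories_interpolated(
    trajs: TrajectoryTable,
    mask_before: np.ndarray,
    mask_after: np.ndarray,
    total_frames: int,
    rule: str = "any",
    n_steps: int = 21,
) -> pd.Series:
    """Assign trajectories against a region that moves during acquisition.

    The region mask is known before and after the movie; each trajectory
    is scored against the mask interpolated at its mid-acquisition time
    (mid-frame / ``total_frames``), quantized to ``n_steps`` levels so
    at most that many interpolated masks are rasterized.
    """
    df = trajs.records
    mid = df.groupby("trajectory_id")["frame"].mean()
    t_frac = np.clip(mid / max(total_frames - 1, 1), 0.0, 1.0)
    levels = np.round(t_frac * (n_steps - 1)).astype(int)
    out = pd.Series(index=mid.index, dtype=bool)
    for level in np.unique(levels):
        mask = interpolate_mask_pair(mask_before, mask_after, level / (n_steps - 1))
        ids = levels.index[levels == level]
        keep = df["trajectory_id"].isin(ids)
        sub = TrajectoryTable(
            df[keep].reset_index(drop=True),
            frame_interval=trajs.frame_interval,
            pixel_size=trajs.pixel_size,
        )
        out[ids] = assign_trajectories(sub, mask, rule=rule)
    return out
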