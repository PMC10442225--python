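"""Ground-truth simulators for every pipeline stage.

The generator emulates sparse photoactivation SPT in a nucleus with an
RNA-coated subcompartment (XC) and nucleoli, FCS autocorrelation curves,
FCS-calibration image stacks, and FRAP traces, so that every estimator
in the package can be scored against known truth without external data.

Trajectory model
----------------
Molecules perform 3D Brownian motion inside the nucleus (an elliptical
cylinder: elliptical cross-section in xy, a reflecting slab of total
depth ``slab_depth`` in z). Each molecule is bound (slow, D_bound) or
free (fast, D_free), with optional first-order switching. Only
molecules within the axial detection window |z| < dz/2 are localized;
an out-of-focus frame ends the current trajectory (no gap closing), and
observed positions carry isotropic Gaussian localization error σ. A
configurable permeability makes the XC boundary a partial barrier to
free molecules: each step that crosses the boundary is rejected with
probability 1 − permeability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    DEFAULT_FRAME_INTERVAL,
    DEFAULT_PIXEL_SIZE,
    FcsCurve,
    FrapTraceSet,
    RegionMaskSet,
    TrajectoryTable,
    ValidationError,
)
from .fcs import FcsModelParams, autocorrelation_model

REGION_CODES = {0: "nucleoplasm", 1: "xc", 2: "nucleoli"}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimGeometry:
    """Nuclear geometry in μm; rasterized on a ``shape`` pixel grid."""

    shape: tuple[int, int] = (128, 128)
    pixel_size: float = DEFAULT_PIXEL_SIZE
    nucleus_center: tuple[float, float] | None = None  # (x, y) μm; image center if None
    nucleus_semiaxes: tuple[float, float] = (4.0, 3.0)  # (x, y) μm
    xc_center: tuple[float, float] | None = None  # nucleus center if None
    xc_radius: float = 1.5
    nucleoli: tuple[tuple[float, float, float], ...] = ()  # (cx, cy, r) μm
    dz: float = 0.7  # axial detection window (total depth), μm
    slab_depth: float = 3.0  # reflecting z slab (total depth), μm

    def __post_init__(self) -> None:
        if self.nucleus_center is None:
            h, w = self.shape
            self.nucleus_center = (w * self.pixel_size / 2, h * self.pixel_size / 2)
        if self.xc_center is None:
            self.xc_center = self.nucleus_center
        if self.dz <= 0 or self.slab_depth < self.dz:
            raise ValidationError("need 0 < dz <= slab_depth")
        a, b = self.nucleus_semiaxes
        for cx, cy, r in ((*self.xc_center, self.xc_radius),) + tuple(self.nucleoli):
            if r >= min(a, b):
                raise ValidationError("disc radius exceeds nucleus semi-minor axis")
            u = (cx - self.nucleus_center[0]) / (a - r)
            v = (cy - self.nucleus_center[1]) / (b - r)
            if u * u + v * v > 1.0:
                raise ValidationError("disc does not fit inside the nucleus")


@dataclass
class SimKinetics:
    """Two-state kinetics and the XC boundary barrier."""

    d_free: float = 3.8  # μm² s⁻¹
    d_bound: float = 0.005  # μm² s⁻¹
    f_bound_nucleoplasm: float = 0.40
    f_bound_xc: float = 0.33
    k_bind: float = 0.0  # s⁻¹; 0 = static states
    k_unbind: float = 0.0  # s⁻¹
    boundary_permeability: float = 1.0  # 1 = no barrier

    def __post_init__(self) -> None:
        if not self.d_free > self.d_bound >= 0:
            raise ValidationError("need d_free > d_bound >= 0")
        for f in (self.f_bound_nucleoplasm, self.f_bound_xc, self.boundary_permeability):
            if not 0.0 <= f <= 1.0:
                raise ValidationError("fractions/probabilities must be in [0, 1]")
        if self.k_bind < 0 or self.k_unbind < 0:
            raise ValidationError("rates must be >= 0")


@dataclass
class SimCamera:
    """Acquisition parameters of the SPT movie."""

    frame_interval: float = DEFAULT_FRAME_INTERVAL  # s
    localization_error: float = 0.028  # μm, per coordinate
    # per-frame photobleaching; mean observed track ~3 localizations,
    # typical of sparse PALM at full-power 1 ms excitation
    bleach_probability: float = 0.35
    activation_rate: float = 5.0  # new molecules per frame
    n_frames: int = 3000

    def __post_init__(self) -> None:
        if self.localization_error < 0:
            raise ValidationError("localization error must be >= 0")
        if not 0.0 <= self.bleach_probability <= 1.0:
            raise ValidationError("bleach probability must be in [0, 1]")
        if self.frame_interval <= 0 or self.n_frames < 1 or self.activation_rate < 0:
            raise ValidationError("invalid camera configuration")


@dataclass
class GroundTruth:
    """Per-localization and per-trajectory truth for scoring estimators."""

    localizations: pd.DataFrame  # trajectory_id, frame, molecule, bound, region
    trajectories: pd.DataFrame  # trajectory_id, n_locs, bound_fraction, region
    geometry: SimGeometry
    kinetics: SimKinetics
    camera: SimCamera
    seed: int | None = None


# ---------------------------------------------------------------------------
# Geometry rasterization
# ---------------------------------------------------------------------------


def _pixel_centers(shape: tuple[int, int], pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    y = (np.arange(h) + 0.5) * pixel_size
    x = (np.arange(w) + 0.5) * pixel_size
    return np.meshgrid(x, y)  # X, Y


def build_geometry(geometry: SimGeometry) -> RegionMaskSet:
    """Rasterize the configured geometry into a region mask set.

    A pixel belongs to a region when its center does. The XC wins over
    nucleoli where they would overlap, and the nucleoplasm is the rest
    of the nucleus.
    """
    X, Y = _pixel_centers(geometry.shape, geometry.pixel_size)
    cx, cy = geometry.nucleus_center
    a, b = geometry.nucleus_semiaxes
    nucleus = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0
    dx, dy = geometry.xc_center
    xc = ((X - dx) ** 2 + (Y - dy) ** 2 <= geometry.xc_radius**2) & nucleus
    nucleoli = np.zeros_like(nucleus)
    for ncx, ncy, r in geometry.nucleoli:
        nucleoli |= (X - ncx) ** 2 + (Y - ncy) ** 2 <= r**2
    nucleoli &= nucleus & ~xc
    nucleoplasm = nucleus & ~xc & ~nucleoli
    return RegionMaskSet(
        nucleus=nucleus,
        xc=xc,
        nucleoli=nucleoli,
        nucleoplasm=nucleoplasm,
        pixel_size=geometry.pixel_size,
        tag="simulated",
    )


def _region_codes(
    x: np.ndarray, y: np.ndarray, masks: RegionMaskSet
) -> np.ndarray:
    h, w = masks.shape
    col = np.clip((x / masks.pixel_size).astype(int), 0, w - 1)
    row = np.clip((y / masks.pixel_size).astype(int), 0, h - 1)
    codes = np.zeros(x.shape, dtype=np.int8)
    codes[masks.xc[row, col]] = 1
    codes[masks.nucleoli[row, col]] = 2
    return codes


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------


def _sample_in_nucleus(rng: np.random.Generator, geometry: SimGeometry, n: int):
    cx, cy = geometry.nucleus_center
    a, b = geometry.nucleus_semiaxes
    r = np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0, 2 * np.pi, size=n)
    return cx + a * r * np.cos(th), cy + b * r * np.sin(th)


def _reflect_ellipse(x, y, cx, cy, a, b):
    """Radial fold back into the ellipse (reflection in scaled coords)."""
    u = (x - cx) / a
    v = (y - cy) / b
    rho = np.hypot(u, v)
    out = rho > 1.0
    if out.any():
        rho_new = np.clip(2.0 - rho[out], 1e-6, 1.0)
        scale = rho_new / rho[out]
        x = x.copy()
        y = y.copy()
        x[out] = cx + (x[out] - cx) * scale
        y[out] = cy + (y[out] - cy) * scale
    return x, y


def _reflect_slab(z: np.ndarray, half: float) -> np.ndarray:
    period = 4.0 * half
    zz = np.mod(z + half, period)
    return np.where(zz <= 2 * half, zz, period - zz) - half


def simulate_trajectories(
    geometry: SimGeometry,
    kinetics: SimKinetics,
    camera: SimCamera,
    seed: int | None = None,
    masks: RegionMaskSet | None = None,
    n_molecules: int | None = None,
) -> tuple[TrajectoryTable, GroundTruth]:
    """Simulate an SPT movie and return observed trajectories plus truth.

    Molecules appear at Poisson-distributed activation times (or exactly
    ``n_molecules`` at uniform start frames when given), photobleach
    geometrically, and are emitted as trajectories over maximal runs of
    consecutive in-focus frames; runs shorter than two localizations are
    dropped, as a tracker links nothing from a single detection.
    """
    rng = np.random.default_rng(seed)
    if masks is None:
        masks = build_geometry(geometry)
    dt = camera.frame_interval
    n_frames = camera.n_frames

    if n_molecules is None:
        n_mol = int(rng.poisson(camera.activation_rate * n_frames))
    else:
        n_mol = int(n_molecules)
    if n_mol == 0:
        empty = pd.DataFrame(
            {
                "trajectory_id": pd.Series(dtype=int),
                "frame": pd.Series(dtype=int),
                "x": pd.Series(dtype=float),
                "y": pd.Series(dtype=float),
            }
        )
        truth = GroundTruth(
            localizations=pd.DataFrame(),
            trajectories=pd.DataFrame(),
            geometry=geometry,
            kinetics=kinetics,
            camera=camera,
            seed=seed,
        )
        return (
            TrajectoryTable(empty, frame_interval=dt, pixel_size=geometry.pixel_size),
            truth,
        )

    start = rng.integers(0, n_frames, size=n_mol)
    if camera.bleach_probability > 0:
        life = rng.geometric(camera.bleach_probability, size=n_mol)
    else:
        life = np.full(n_mol, n_frames)
    life = np.minimum(life, n_frames - start)
    l_max = int(life.max())

    x, y = _sample_in_nucleus(rng, geometry, n_mol)
    half_slab = geometry.slab_depth / 2.0
    z = rng.uniform(-half_slab, half_slab, size=n_mol)

    in_xc = _region_codes(x, y, masks) == 1
    f_bound = np.where(in_xc, kinetics.f_bound_xc, kinetics.f_bound_nucleoplasm)
    bound = rng.uniform(size=n_mol) < f_bound

    cx, cy = geometry.nucleus_center
    a, b = geometry.nucleus_semiaxes
    p_bind = 1.0 - np.exp(-kinetics.k_bind * dt) if kinetics.k_bind > 0 else 0.0
    p_unbind = 1.0 - np.exp(-kinetics.k_unbind * dt) if kinetics.k_unbind > 0 else 0.0
    sigma = camera.localization_error
    half_dz = geometry.dz / 2.0
    perm = kinetics.boundary_permeability

    rec_mol, rec_frame, rec_x, rec_y, rec_bound, rec_region = [], [], [], [], [], []

    def record(t: int, active: np.ndarray) -> None:
        det = active & (np.abs(z) < half_dz)
        if not det.any():
            return
        idx = np.nonzero(det)[0]
        xo = x[idx] + rng.normal(0.0, sigma, size=idx.size) if sigma > 0 else x[idx]
        yo = y[idx] + rng.normal(0.0, sigma, size=idx.size) if sigma > 0 else y[idx]
        rec_mol.append(idx)
        rec_frame.append(start[idx] + t)
        rec_x.append(np.maximum(xo, 0.0))
        rec_y.append(np.maximum(yo, 0.0))
        rec_bound.append(bound[idx].copy())
        rec_region.append(_region_codes(x[idx], y[idx], masks))

    record(0, np.ones(n_mol, dtype=bool))
    for t in range(1, l_max):
        active = life > t
        if not active.any():
            break
        if p_bind or p_unbind:
            u = rng.uniform(size=n_mol)
            switch_on = (~bound) & (u < p_bind)
            switch_off = bound & (u < p_unbind)
            bound = bound ^ switch_on ^ switch_off
        d = np.where(bound, kinetics.d_bound, kinetics.d_free)
        step_sd = np.sqrt(2.0 * d * dt)
        steps = rng.normal(size=(3, n_mol)) * step_sd
        nx, ny = _reflect_ellipse(x + steps[0], y + steps[1], cx, cy, a, b)
        nz = _reflect_slab(z + steps[2], half_slab)
        if perm < 1.0:
            crossed = (
                (~bound)
                & ((_region_codes(nx, ny, masks) == 1) != (_region_codes(x, y, masks) == 1))
            )
            reject = crossed & (rng.uniform(size=n_mol) >= perm)
            nx = np.where(reject, x, nx)
            ny = np.where(reject, y, ny)
            nz = np.where(reject, z, nz)
        x = np.where(active, nx, x)
        y = np.where(active, ny, y)
        z = np.where(active, nz, z)
        record(t, active)

    loc = pd.DataFrame(
        {
            "molecule": np.concatenate(rec_mol),
            "frame": np.concatenate(rec_frame),
            "x": np.concatenate(rec_x),
            "y": np.concatenate(rec_y),
            "bound": np.concatenate(rec_bound),
            "region": np.concatenate(rec_region),
        }
    ).sort_values(["molecule", "frame"], kind="stable", ignore_index=True)

    # split per molecule into runs of consecutive frames → trajectories
    mol = loc["molecule"].to_numpy()
    frame = loc["frame"].to_numpy()
    new_seg = np.ones(len(loc), dtype=bool)
    if len(loc) > 1:
        new_seg[1:] = (mol[1:] != mol[:-1]) | (np.diff(frame) != 1)
    seg_id = np.cumsum(new_seg) - 1
    loc["trajectory_id"] = seg_id
    sizes = loc.groupby("trajectory_id")["frame"].transform("size")
    loc = loc[sizes >= 2].copy()
    # renumber trajectories consecutively
    loc["trajectory_id"] = pd.factorize(loc["trajectory_id"])[0]

    table = TrajectoryTable(
        records=loc[["trajectory_id", "frame", "x", "y"]].reset_index(drop=True),
        frame_interval=dt,
        pixel_size=geometry.pixel_size,
        source_id=f"sim-seed-{seed}",
    )
    per_traj = (
        loc.groupby("trajectory_id")
        .agg(
            n_locs=("frame", "size"),
            bound_fraction=("bound", "mean"),
            region=("region", "first"),  # region at the first localization
            molecule=("molecule", "first"),
        )
        .reset_index()
    )
    truth = GroundTruth(
        localizations=loc.reset_index(drop=True),
        trajectories=per_traj,
        geometry=geometry,
        kinetics=kinetics,
        camera=camera,
        seed=seed,
    )
    return table, truth


# ---------------------------------------------------------------------------
# FCS curve simulation
# ---------------------------------------------------------------------------


def simulate_fcs_curve(
    params: FcsModelParams,
    noise_sd: float = 0.0,
    n_lags: int = 120,
    lag_min: float = 1e-6,
    lag_max: float = 1.0,
    seed: int | None = None,
    label: str = "protein",
) -> FcsCurve:
    """Evaluate the autocorrelation model on log-spaced lags plus noise."""
    if lag_min <= 0 or lag_max <= lag_min:
        raise ValidationError("need 0 < lag_min < lag_max")
    lag = np.geomspace(lag_min, lag_max, n_lags)
    G = autocorrelation_model(lag, params)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        G = G + rng.normal(0.0, noise_sd, size=n_lags)
    return FcsCurve(lag=lag, G=G, label=label)


# ---------------------------------------------------------------------------
# Calibration stack simulation
# ---------------------------------------------------------------------------


def simulate_calibration_stack(
    true_concentration_field: np.ndarray,
    a: float,
    b: float,
    background: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    n_points: int = 50,
    n_negative: int = 20,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Generate an intensity stack from a concentration field.

    The forward model inverts the linear calibration: intensity =
    background + (C − b)/a per voxel, plus Gaussian noise. The returned
    point list pairs sampled voxel intensities with their true
    concentrations (label ``control``) and adds background-only
    negative-control points (label ``negative``).
    """
    if a <= 0:
        raise ValidationError("calibration slope a must be > 0")
    C = np.asarray(true_concentration_field, dtype=float)
    rng = np.random.default_rng(seed)
    stack = background + (C - b) / a
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd, size=C.shape)
    flat_idx = rng.choice(C.size, size=min(n_points, C.size), replace=False)
    records = [
        {
            "point_id": i,
            "intensity": float(stack.flat[j]),
            "concentration": float(C.flat[j]),
            "label": "control",
        }
        for i, j in enumerate(flat_idx)
    ]
    neg = background + (
        rng.normal(0.0, noise_sd, size=n_negative) if noise_sd > 0 else np.zeros(n_negative)
    )
    records += [
        {
            "point_id": len(records) + i,
            "intensity": float(v),
            "concentration": np.nan,
            "label": "negative",
        }
        for i, v in enumerate(neg)
    ]
    return stack, pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# FRAP simulation
# ---------------------------------------------------------------------------


def simulate_frap_experiment(
    mobile_fraction: float,
    recovery_rate: float,
    bleach_depth: float = 0.8,
    acquisition_bleach_rate: float = 0.0,
    n_frames: int = 400,
    bleach_frame: int = 80,
    noise_sd: float = 0.0,
    seed: int | None = None,
    frame_interval: float = 0.03195,
    roi_level: float = 100.0,
    control_level: float = 100.0,
    background_level: float = 20.0,
) -> FrapTraceSet:
    """Simulate a FRAP experiment at the trace level.

    The bleached-ROI signal follows a plateau recovery model — constant
    before the pulse, then ``(1 − depth) + depth·mobile·(1 − e^(−k·t))``
    — multiplied by global exponential acquisition bleaching. The
    control trace carries the acquisition bleaching only. All three
    traces sit on a common additive background so that the double
    normalization has something real to remove.
    """
    for f in (mobile_fraction, bleach_depth):
        if not 0.0 <= f <= 1.0:
            raise ValidationError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * frame_interval
    model = np.ones(n_frames)
    post = np.arange(n_frames) >= bleach_frame
    tb = t - t[bleach_frame]
    model[post] = (1.0 - bleach_depth) + bleach_depth * mobile_fraction * (
        1.0 - np.exp(-recovery_rate * tb[post])
    )
    acq = np.exp(-acquisition_bleach_rate * t)

    def noisy(base: np.ndarray) -> np.ndarray:
        return base + rng.normal(0.0, noise_sd, size=n_frames) if noise_sd > 0 else base

    return FrapTraceSet(
        time=t,
        roi=noisy(background_level + roi_level * model * acq),
        control=noisy(background_level + control_level * acq),
        background=noisy(np.full(n_frames, background_level)),
        bleach_frame=bleach_frame,
    )
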