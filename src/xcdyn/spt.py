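"""Single-particle-tracking statistics.

Jump extraction, MSD and velocity autocorrelation, per-trajectory
mobility classification, jump-angle anisotropy, entering-event flux
against control regions, the two-state (bound/free) jump-length fit
with axial defocalization correction, a fixed-grid diffusion-coefficient
spectrum, and delta-method scaling of concentrations by fractions.

Two-state model
---------------
Single-frame displacements of a molecule diffusing with coefficient D,
observed with localization error σ, have the 2D Rayleigh-type density

    k(r; D, dt) = r / (2 s) · exp(−r² / (4 s)),   s = D·dt·Δt + σ²

The observed population mixes a bound state (D_bound ≈ 0) with a free
state (D_free), but fast molecules leave the axial detection window
|z| < dz/2 between frames, so the free component is down-weighted at
lag dt by the slab escape factor Z(dt; D_free, dz). The mixture CDF is
fitted to the empirical jump-length CDFs at dt = 1…max_dt jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core_io import TrajectoryTable, ValidationError, positions_to_pixels

DEFAULT_LOCALIZATION_ERROR = 0.028  # μm
DEFAULT_DZ = 0.7  # μm
DEFAULT_BOUND_RANGE = (0.0, 0.02)  # μm² s⁻¹
DEFAULT_FREE_RANGE = (0.1, 20.0)  # μm² s⁻¹


# ---------------------------------------------------------------------------
# Jumps
# ---------------------------------------------------------------------------


@dataclass
class JumpTable:
    """Displacements between frames n and n+dt within trajectories."""

    records: pd.DataFrame  # trajectory_id, dt, length, frame0, x0, y0, x1, y1
    frame_interval: float

    def at_dt(self, dt: int) -> pd.DataFrame:
        return self.records[self.records["dt"] == dt]

    @property
    def dts(self) -> np.ndarray:
        return np.sort(self.records["dt"].unique())


def _run_ids(trajs: TrajectoryTable) -> np.ndarray:
    """Segment localizations into runs of consecutive frames.

    A missing frame ends a jump chain: displacements are only taken
    within runs, never across gaps.
    """
    df = trajs.records
    tid = df["trajectory_id"].to_numpy()
    frame = df["frame"].to_numpy()
    new = np.ones(len(df), dtype=bool)
    if len(df) > 1:
        new[1:] = (tid[1:] != tid[:-1]) | (np.diff(frame) != 1)
    return np.cumsum(new) - 1


def compute_jumps(
    trajs: TrajectoryTable,
    max_dt: int = 6,
    max_jumps_per_traj: int | None = 3,
    max_jump_length: float | None = 2.0,
) -> JumpTable:
    """Extract jump lengths for dt = 1…max_dt.

    At most ``max_jumps_per_traj`` jumps per trajectory per dt are kept
    (the earliest ones), and jumps longer than ``max_jump_length`` μm
    are discarded.
    """
    df = trajs.records
    run = _run_ids(trajs)
    tid = df["trajectory_id"].to_numpy()
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    frame = df["frame"].to_numpy()
    pieces = []
    for dt in range(1, max_dt + 1):
        if len(df) <= dt:
            break
        ok = run[dt:] == run[:-dt]
        i0 = np.nonzero(ok)[0]
        i1 = i0 + dt
        if i0.size == 0:
            continue
        pieces.append(
            pd.DataFrame(
                {
                    "trajectory_id": tid[i0],
                    "dt": dt,
                    "frame0": frame[i0],
                    "x0": x[i0],
                    "y0": y[i0],
                    "x1": x[i1],
                    "y1": y[i1],
                    "length": np.hypot(x[i1] - x[i0], y[i1] - y[i0]),
                }
            )
        )
    if not pieces:
        records = pd.DataFrame(
            columns=["trajectory_id", "dt", "frame0", "x0", "y0", "x1", "y1", "length"]
        )
        return JumpTable(records, trajs.frame_interval)
    records = pd.concat(pieces, ignore_index=True)
    if max_jumps_per_traj is not None:
        rank = records.groupby(["trajectory_id", "dt"]).cumcount()
        records = records[rank < max_jumps_per_traj]
    if max_jump_length is not None:
        records = records[records["length"] <= max_jump_length]
    return JumpTable(records.reset_index(drop=True), trajs.frame_interval)


def classify_msrd(
    trajs: TrajectoryTable,
    free_threshold: float = 0.2,
    bound_threshold: float = 0.1,
) -> pd.Series:
    """Classify trajectories by mean single-frame jump length (MSRD).

    MSRD > ``free_threshold`` (μm) → "free"; MSRD < ``bound_threshold``
    → "bound"; in between, or no single-frame jump available,
    → "unclassified".
    """
    jumps = compute_jumps(trajs, max_dt=1, max_jumps_per_traj=None, max_jump_length=None)
    msrd = jumps.records.groupby("trajectory_id")["length"].mean()
    all_ids = trajs.records["trajectory_id"].unique()
    out = pd.Series("unclassified", index=pd.Index(all_ids, name="trajectory_id"))
    out[msrd.index[msrd > free_threshold]] = "free"
    out[msrd.index[msrd < bound_threshold]] = "bound"
    return out


# ---------------------------------------------------------------------------
# MSD and VAC
# ---------------------------------------------------------------------------


@dataclass
class MsdCurve:
    """Mean squared displacement per lag with bootstrap errors."""

    lags: np.ndarray  # frames
    msd: np.ndarray  # μm²
    boot_sd: np.ndarray
    n_pairs: np.ndarray
    frame_interval: float
    label: str = "all"


def compute_msd(
    trajs: TrajectoryTable,
    max_lag: int = 6,
    n_boot: int = 50,
    boot_size: int = 3000,
    seed: int | None = None,
    label: str = "all",
) -> MsdCurve:
    """MSD(dt) over all (trajectory, start-frame) pairs at each lag.

    Errors come from bootstrapping trajectories: ``n_boot`` resamples of
    ``boot_size`` trajectories with replacement.
    """
    df = trajs.records
    run = _run_ids(trajs)
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    tids, tid_idx = np.unique(df["trajectory_id"].to_numpy(), return_inverse=True)
    n_traj = tids.size
    if n_traj == 0:
        raise ValidationError("no trajectories")
    if n_traj < boot_size:
        warnings.warn(
            f"only {n_traj} trajectories for bootstrap size {boot_size}; "
            "sampling with replacement anyway",
            stacklevel=2,
        )
    lags = np.arange(1, max_lag + 1)
    sums = np.zeros((max_lag, n_traj))
    counts = np.zeros((max_lag, n_traj))
    for k, lag in enumerate(lags):
        if len(df) <= lag:
            break
        ok = run[lag:] == run[:-lag]
        i0 = np.nonzero(ok)[0]
        sq = (x[i0 + lag] - x[i0]) ** 2 + (y[i0 + lag] - y[i0]) ** 2
        np.add.at(sums[k], tid_idx[i0], sq)
        np.add.at(counts[k], tid_idx[i0], 1.0)
    total_counts = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        msd = sums.sum(axis=1) / total_counts
    rng = np.random.default_rng(seed)
    boots = np.full((n_boot, max_lag), np.nan)
    for bi in range(n_boot):
        pick = rng.integers(0, n_traj, size=boot_size)
        s = sums[:, pick].sum(axis=1)
        c = counts[:, pick].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            boots[bi] = s / c
    return MsdCurve(
        lags=lags,
        msd=msd,
        boot_sd=np.nanstd(boots, axis=0, ddof=1),
        n_pairs=total_counts,
        frame_interval=trajs.frame_interval,
        label=label,
    )


def compute_vac(trajs: TrajectoryTable, max_lag: int = 5) -> np.ndarray:
    """Normalized velocity autocorrelation VAC(k) for k = 0…max_lag.

    v_n is the displacement vector between consecutive frames; VAC(k) =
    ⟨v_n·v_{n+k}⟩ / ⟨|v|²⟩ pooled over trajectories.
    """
    df = trajs.records
    run = _run_ids(trajs)
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    ok = run[1:] == run[:-1]
    i0 = np.nonzero(ok)[0]
    vx = x[i0 + 1] - x[i0]
    vy = y[i0 + 1] - y[i0]
    vrun = run[i0]
    vstart = i0  # index of the jump's first localization
    denom = np.mean(vx**2 + vy**2)
    out = np.full(max_lag + 1, np.nan)
    out[0] = 1.0
    for k in range(1, max_lag + 1):
        if vx.size <= k:
            break
        pair = (vrun[k:] == vrun[:-k]) & (vstart[k:] == vstart[:-k] + k)
        j = np.nonzero(pair)[0]
        if j.size == 0:
            continue
        out[k] = np.mean(vx[j] * vx[j + k] + vy[j] * vy[j + k]) / denom
    return out


# ---------------------------------------------------------------------------
# Jump angles
# ---------------------------------------------------------------------------


@dataclass
class AngleDistribution:
    """Angles between consecutive jump pairs, folded to [0°, 180°]."""

    angles: np.ndarray  # degrees
    bin_edges: np.ndarray
    counts: np.ndarray
    context: str = "all"
    region: str = ""

    @property
    def n(self) -> int:
        return self.angles.size


def _fold_angle(ux, uy, vx, vy) -> np.ndarray:
    dot = ux * vx + uy * vy
    norm = np.hypot(ux, uy) * np.hypot(vx, vy)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.clip(dot / norm, -1.0, 1.0)
    return np.degrees(np.arccos(c))


def angle_distribution(
    trajs: TrajectoryTable,
    min_jump: float = 0.2,
    max_jump: float = 3.0,
    dt: int = 1,
    bin_width: float = 10.0,
    max_jumps_per_traj: int | None = 100,
    context: str = "all",
    region: str = "",
) -> AngleDistribution:
    """Histogram of angles between consecutive dt-frame jump pairs.

    Only pairs with both jump lengths within [min_jump, max_jump] μm
    contribute; at most ``max_jumps_per_traj`` pairs per trajectory.
    """
    df = trajs.records
    run = _run_ids(trajs)
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    n = len(df)
    angles = np.empty(0)
    if n > 2 * dt:
        ok = (run[2 * dt:] == run[:-2 * dt])
        i0 = np.nonzero(ok)[0]
        i1 = i0 + dt
        i2 = i0 + 2 * dt
        ux, uy = x[i1] - x[i0], y[i1] - y[i0]
        vx, vy = x[i2] - x[i1], y[i2] - y[i1]
        lu = np.hypot(ux, uy)
        lv = np.hypot(vx, vy)
        keep = (lu >= min_jump) & (lu <= max_jump) & (lv >= min_jump) & (lv <= max_jump)
        if max_jumps_per_traj is not None:
            tid = df["trajectory_id"].to_numpy()[i0]
            rank = pd.Series(np.arange(i0.size)).groupby(tid).cumcount().to_numpy()
            keep &= rank < max_jumps_per_traj
        angles = _fold_angle(ux[keep], uy[keep], vx[keep], vy[keep])
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    counts, _ = np.histogram(angles, bins=edges)
    return AngleDistribution(
        angles=angles, bin_edges=edges, counts=counts, context=context, region=region
    )


@dataclass
class AngleRatio:
    """Forward/backward jump-angle ratio with bootstrap error."""

    ratio: float
    boot_sd: float
    n_forward: int
    n_backward: int
    n_total: int
    defined: bool = True


def forward_backward_ratio(
    dist: AngleDistribution,
    fwd: tuple[float, float] = (0.0, 30.0),
    bwd: tuple[float, float] = (160.0, 180.0),
    n_boot: int = 50,
    boot_size: int | None = None,
    seed: int | None = None,
) -> AngleRatio:
    """Ratio of forward (0–30°) to backward (160–180°) angle densities.

    Counts in each window are divided by the window width before taking
    the ratio, so an isotropic walk has expectation 1.0 regardless of
    the (possibly unequal) window widths; for equal widths this is the
    plain count ratio. The bootstrap resamples the underlying angle
    pairs (``boot_size`` defaults to all of them) and reports the
    standard deviation of the ratio across resamples. With zero
    backward angles the ratio is undefined and flagged.
    """
    a = dist.angles
    width_f = fwd[1] - fwd[0]
    width_b = bwd[1] - bwd[0]
    if width_f <= 0 or width_b <= 0:
        raise ValueError("angle windows must have positive width")

    def density_ratio(sample: np.ndarray) -> float | None:
        nf = ((sample >= fwd[0]) & (sample <= fwd[1])).sum()
        nb = ((sample >= bwd[0]) & (sample <= bwd[1])).sum()
        if nb == 0:
            return None
        return (nf / width_f) / (nb / width_b)

    n_f = int(((a >= fwd[0]) & (a <= fwd[1])).sum())
    n_b = int(((a >= bwd[0]) & (a <= bwd[1])).sum())
    if n_b == 0:
        return AngleRatio(np.nan, np.nan, n_f, 0, a.size, defined=False)
    ratio = density_ratio(a)
    boot_size = boot_size or a.size
    rng = np.random.default_rng(seed)
    rs = []
    for _ in range(n_boot):
        r = density_ratio(a[rng.integers(0, a.size, size=boot_size)])
        if r is not None:
            rs.append(r)
    sd = float(np.std(rs, ddof=1)) if len(rs) > 1 else np.nan
    return AngleRatio(float(ratio), sd, n_f, n_b, a.size)


# ---------------------------------------------------------------------------
# Entering events and flux comparison
# ---------------------------------------------------------------------------


def detect_entering(
    trajs: TrajectoryTable,
    region: np.ndarray,
    free_only: bool = True,
    msrd_threshold: float = 0.2,
) -> pd.DataFrame:
    """Find trajectories entering a region from outside.

    A trajectory enters when some localization lies outside the region
    and a later one inside; the entering jump is the first
    outside→inside transition between consecutive localizations, and
    each trajectory is counted at most once. With ``free_only`` only
    freely diffusing trajectories (MSRD > ``msrd_threshold`` μm) are
    considered. Returns one row per entering event with the entering
    jump and the angle to the following jump (NaN if the trajectory
    ends there).
    """
    region = np.asarray(region, dtype=bool)
    df = trajs.records
    if free_only:
        cls = classify_msrd(trajs, free_threshold=msrd_threshold)
        free_ids = set(cls.index[cls == "free"])
        df = df[df["trajectory_id"].isin(free_ids)]
    if df.empty:
        return pd.DataFrame(
            columns=["trajectory_id", "frame", "x0", "y0", "x1", "y1", "angle_to_next"]
        )
    row, col = positions_to_pixels(
        df["x"].to_numpy(), df["y"].to_numpy(), trajs.pixel_size, region.shape
    )
    inside = region[row, col]
    tid = df["trajectory_id"].to_numpy()
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    frame = df["frame"].to_numpy()
    events = []
    same = tid[1:] == tid[:-1]
    trans = same & ~inside[:-1] & inside[1:]
    cand = np.nonzero(trans)[0]
    seen: set = set()
    for i in cand:
        t = tid[i]
        if t in seen:
            continue
        seen.add(t)
        angle = np.nan
        if i + 2 < len(tid) and tid[i + 2] == t:
            angle = float(
                _fold_angle(
                    x[i + 1] - x[i], y[i + 1] - y[i], x[i + 2] - x[i + 1], y[i + 2] - y[i + 1]
                )
            )
        events.append(
            {
                "trajectory_id": int(t),
                "frame": int(frame[i]),
                "x0": x[i],
                "y0": y[i],
                "x1": x[i + 1],
                "y1": y[i + 1],
                "angle_to_next": angle,
            }
        )
    return pd.DataFrame(events)


def entering_counts(
    trajs: TrajectoryTable,
    regions: list[np.ndarray],
    free_only: bool = True,
    msrd_threshold: float = 0.2,
) -> list[int]:
    """Number of entering trajectories for each region raster.

    Same definition as :func:`detect_entering`, but the localization →
    pixel mapping and the mobility filter are computed once and shared
    across regions, which matters when scoring many control regions.
    """
    df = trajs.records
    if free_only:
        cls = classify_msrd(trajs, free_threshold=msrd_threshold)
        free_ids = set(cls.index[cls == "free"])
        df = df[df["trajectory_id"].isin(free_ids)]
    if df.empty:
        return [0] * len(regions)
    shape = np.asarray(regions[0]).shape
    row, col = positions_to_pixels(
        df["x"].to_numpy(), df["y"].to_numpy(), trajs.pixel_size, shape
    )
    tid = df["trajectory_id"].to_numpy()
    same = tid[1:] == tid[:-1]
    out = []
    for region in regions:
        inside = np.asarray(region, dtype=bool)[row, col]
        trans = same & ~inside[:-1] & inside[1:]
        out.append(int(np.unique(tid[:-1][trans]).size))
    return out


@dataclass
class FluxComparison:
    """KS comparison of per-cell entering counts, XC vs pooled controls."""

    statistic: float
    pvalue: float
    per_cell: pd.DataFrame  # cell, xc_count, mean_control_count


def compare_flux(
    xc_counts: np.ndarray, control_counts: list[np.ndarray]
) -> FluxComparison:
    """Two-sample two-sided KS test on per-cell entering-event counts.

    ``xc_counts`` has one entry per cell; ``control_counts`` one array
    per cell holding that cell's per-control counts. Controls are pooled
    across cells for the test.
    """
    xc = np.asarray(xc_counts, dtype=float)
    ctrl_arrays = [np.asarray(c, dtype=float) for c in control_counts]
    pooled = np.concatenate([c for c in ctrl_arrays if c.size]) if ctrl_arrays else np.empty(0)
    if xc.size < 2 or pooled.size < 2:
        raise ValidationError("need counts from at least 2 cells on both sides")
    res = stats.ks_2samp(xc, pooled, alternative="two-sided", method="auto")
    per_cell = pd.DataFrame(
        {
            "cell": np.arange(xc.size),
            "xc_count": xc,
            "mean_control_count": [
                float(np.mean(c)) if c.size else np.nan for c in ctrl_arrays
            ],
        }
    )
    return FluxComparison(float(res.statistic), float(res.pvalue), per_cell)


# ---------------------------------------------------------------------------
# Axial defocalization
# ---------------------------------------------------------------------------


def axial_escape_fraction(D: float, dt: float, dz: float = DEFAULT_DZ, tol: float = 1e-8) -> float:
    """Fraction of molecules still inside the detection slab after dt.

    Solves 1D diffusion in a slab of depth ``dz`` with absorbing walls,
    starting from a uniform distribution, by the image/eigenfunction
    series; terms below ``tol`` truncate the sum. Monotone
    non-increasing in D·dt, equal to 1 at D = 0.
    """
    if dz <= 0:
        raise ValidationError("dz must be > 0")
    if D < 0:
        raise ValidationError("D must be >= 0")
    if D == 0 or dt == 0:
        return 1.0
    beta = np.pi**2 * D * dt / dz**2
    total = 0.0
    n = 1
    while True:
        term = 8.0 / (n**2 * np.pi**2) * np.exp(-(n**2) * beta)
        total += term
        if term < tol or n > 10_001:
            break
        n += 2
    return float(min(total, 1.0))


def detection_survival(
    D: float,
    max_lag: int,
    frame_interval: float,
    dz: float = DEFAULT_DZ,
    slab_depth: float = 3.0,
) -> np.ndarray:
    """Probability of staying detectable over 1…max_lag frame lags.

    Unlike :func:`axial_escape_fraction`, which absorbs molecules the
    instant they cross the window edge, this propagates the axial
    density frame by frame — Gaussian diffusion step (with reflection
    at the outer slab of depth ``slab_depth``), then truncation to the
    detection window — so molecules that dip out of focus *between*
    frames and return are kept. This matches how a tracker actually
    loses molecules: detection is only checked at frame times.
    Returns the survival for lags 1…max_lag, starting from a uniform
    in-window distribution.
    """
    if dz <= 0 or slab_depth < dz:
        raise ValidationError("need 0 < dz <= slab_depth")
    if D < 0:
        raise ValidationError("D must be >= 0")
    if D == 0:
        return np.ones(max_lag)
    a = slab_depth / 2.0
    s = np.sqrt(2.0 * D * frame_interval)
    h = max(min(dz, s) / 12.0, dz / 150.0)
    x = np.arange(-a + h / 2.0, a, h)
    f = (np.abs(x) < dz / 2.0).astype(float)
    f /= f.sum()
    # transition kernel with mirror images for the reflecting outer slab
    diff = x[None, :] - x[:, None]
    kernel = (
        np.exp(-(diff**2) / (2 * s**2))
        + np.exp(-((2 * a - x[:, None] - x[None, :]) ** 2) / (2 * s**2))
        + np.exp(-((-2 * a - x[:, None] - x[None, :]) ** 2) / (2 * s**2))
    )
    kernel /= kernel.sum(axis=0, keepdims=True)
    window = np.abs(x) < dz / 2.0
    out = np.empty(max_lag)
    for k in range(max_lag):
        f = kernel @ f
        f[~window] = 0.0
        out[k] = f.sum()
    return out


# ---------------------------------------------------------------------------
# Two-state fitting
# ---------------------------------------------------------------------------


@dataclass
class TwoStateFit:
    """Bound fraction and diffusion coefficients from the jump-length fit."""

    f_bound: float
    d_bound: float
    d_free: float
    sigma: float
    dz: float
    converged: bool
    f_bound_sd: float = np.nan
    d_bound_sd: float = np.nan
    d_free_sd: float = np.nan
    mode: str = "CDF"


class _SurvivalInterpolator:
    """Per-lag detection survival as a smooth function of D_free.

    Precomputed on a log-spaced D grid so the optimizer can evaluate it
    cheaply; linear interpolation in log D.
    """

    def __init__(
        self,
        dts: list[int],
        frame_interval: float,
        dz: float,
        free_range: tuple[float, float],
        slab_depth: float,
        mode: str,
        n_grid: int = 40,
    ) -> None:
        self.dts = list(dts)
        self.log_d = np.log(np.geomspace(free_range[0], free_range[1], n_grid))
        max_lag = max(dts)
        table = np.empty((n_grid, len(dts)))
        for i, ld in enumerate(self.log_d):
            d = float(np.exp(ld))
            if mode == "frames":
                surv = detection_survival(d, max_lag, frame_interval, dz, slab_depth)
                table[i] = surv[[dt - 1 for dt in dts]]
            else:
                table[i] = [
                    axial_escape_fraction(d, dt * frame_interval, dz) for dt in dts
                ]
        self.table = table

    def __call__(self, d_free: float) -> np.ndarray:
        ld = np.log(np.clip(d_free, np.exp(self.log_d[0]), np.exp(self.log_d[-1])))
        out = np.empty(len(self.dts))
        for j in range(len(self.dts)):
            out[j] = np.interp(ld, self.log_d, self.table[:, j])
        return out


def _two_state_cdf(
    r: np.ndarray,
    dt_frames: int,
    f_bound: float,
    d_bound: float,
    d_free: float,
    sigma: float,
    z: float,
    frame_interval: float,
) -> np.ndarray:
    t = dt_frames * frame_interval
    sb = 4.0 * (d_bound * t + sigma**2)
    sf = 4.0 * (d_free * t + sigma**2)
    kb = 1.0 - np.exp(-(r**2) / sb)
    kf = 1.0 - np.exp(-(r**2) / sf)
    wb = f_bound
    wf = (1.0 - f_bound) * z
    return (wb * kb + wf * kf) / (wb + wf)


def _fit_two_state_curves(
    lengths_by_dt: dict[int, np.ndarray],
    r_grid: np.ndarray,
    sigma: float,
    frame_interval: float,
    bound_range: tuple[float, float],
    free_range: tuple[float, float],
    survival: _SurvivalInterpolator,
    p_init: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    dts = sorted(lengths_by_dt)
    emp = {dt: np.searchsorted(np.sort(v), r_grid, side="right") / v.size
           for dt, v in lengths_by_dt.items()}
    dt_pos = {dt: survival.dts.index(dt) for dt in dts}

    def residual(p: np.ndarray) -> np.ndarray:
        f, db, df_ = p
        z = survival(df_)
        out = [
            _two_state_cdf(r_grid, dt, f, db, df_, sigma, z[dt_pos[dt]], frame_interval)
            - emp[dt]
            for dt in dts
        ]
        return np.concatenate(out)

    lo = [0.0, bound_range[0], free_range[0]]
    hi = [1.0, bound_range[1], free_range[1]]
    if p_init is not None:
        starts = [np.clip(p_init, lo, hi)]
    else:
        starts = [
            [f0, min(max(0.005, lo[1]), hi[1]), min(max(df0, lo[2]), hi[2])]
            for f0 in (0.3, 0.6)
            for df0 in (1.0, 5.0)
        ]
    best = None
    for p0 in starts:
        try:
            res = optimize.least_squares(residual, p0, bounds=(lo, hi), xtol=1e-10)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return np.array([np.nan] * 3), False
    return best.x, bool(best.success)


def fit_two_state(
    jumps: JumpTable,
    sigma: float = DEFAULT_LOCALIZATION_ERROR,
    dz: float = DEFAULT_DZ,
    bound_range: tuple[float, float] = DEFAULT_BOUND_RANGE,
    free_range: tuple[float, float] = DEFAULT_FREE_RANGE,
    weight_by_dt: bool = True,
    n_boot: int = 50,
    boot_size: int = 3000,
    seed: int | None = None,
    n_grid: int = 100,
    slab_depth: float = 3.0,
    z_correction: str = "frames",
) -> TwoStateFit:
    """Fit the two-state jump-length mixture on stacked per-dt CDFs.

    The localization error σ is fixed, the free component is corrected
    for defocalization, and parameters are bounded (D_bound in
    ``bound_range``, D_free in ``free_range``). Errors come from
    ``n_boot`` bootstrap resamples of ``boot_size`` trajectories. With
    ``weight_by_dt`` each dt-curve contributes equally (a shared
    evaluation grid makes this automatic in CDF mode).

    ``z_correction`` selects the defocalization model for the free
    component: ``"frames"`` (default) uses the discrete-frame detection
    survival of :func:`detection_survival`, which keeps molecules that
    leave the detection window and return between frames;
    ``"absorbing"`` uses the continuous absorbing-slab factor of
    :func:`axial_escape_fraction`, which systematically over-corrects
    and is kept for comparison.
    """
    if z_correction not in ("frames", "absorbing"):
        raise ValueError("z_correction must be 'frames' or 'absorbing'")
    df = jumps.records
    if df.empty:
        raise ValidationError("no jumps to fit")
    dts = sorted(df["dt"].unique())
    if len(dts) == 1:
        warnings.warn("all jumps at a single dt; fit is poorly constrained", stacklevel=2)
    r_max = float(df["length"].max())
    r_grid = np.linspace(0.0, r_max, n_grid + 1)[1:]
    lengths_by_dt = {dt: df.loc[df["dt"] == dt, "length"].to_numpy() for dt in dts}
    survival = _SurvivalInterpolator(
        dts, jumps.frame_interval, dz, free_range, slab_depth, z_correction
    )
    p, converged = _fit_two_state_curves(
        lengths_by_dt, r_grid, sigma, jumps.frame_interval, bound_range, free_range, survival
    )
    fit = TwoStateFit(
        f_bound=float(p[0]),
        d_bound=float(p[1]),
        d_free=float(p[2]),
        sigma=sigma,
        dz=dz,
        converged=converged,
    )
    if n_boot and n_boot > 1:
        rng = np.random.default_rng(seed)
        tids = df["trajectory_id"].unique()
        grouped = {t: g for t, g in df.groupby("trajectory_id")}
        boots = []
        for _ in range(n_boot):
            pick = rng.choice(tids, size=min(boot_size, tids.size), replace=True)
            sample = pd.concat([grouped[t] for t in pick], ignore_index=True)
            by_dt = {
                dt: sample.loc[sample["dt"] == dt, "length"].to_numpy()
                for dt in sorted(sample["dt"].unique())
                if (sample["dt"] == dt).any()
            }
            pb, okb = _fit_two_state_curves(
                by_dt,
                r_grid,
                sigma,
                jumps.frame_interval,
                bound_range,
                free_range,
                survival,
                p_init=p,
            )
            if okb:
                boots.append(pb)
        if len(boots) > 1:
            arr = np.asarray(boots)
            fit.f_bound_sd = float(arr[:, 0].std(ddof=1))
            fit.d_bound_sd = float(arr[:, 1].std(ddof=1))
            fit.d_free_sd = float(arr[:, 2].std(ddof=1))
    return fit


# ---------------------------------------------------------------------------
# Diffusion-coefficient spectrum
# ---------------------------------------------------------------------------


@dataclass
class DiffusionSpectrum:
    """Occupation weights over a fixed log-spaced diffusion grid."""

    d_grid: np.ndarray
    weights: np.ndarray  # defocalization-corrected
    weights_raw: np.ndarray
    n_trajectories: int
    n_iter: int


def diffusion_spectrum(
    jumps: JumpTable,
    d_grid: np.ndarray | None = None,
    sigma: float = DEFAULT_LOCALIZATION_ERROR,
    dz: float = DEFAULT_DZ,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> DiffusionSpectrum:
    """Fixed-grid mixture spectrum of apparent diffusion coefficients.

    Per trajectory, the sum of squared single-frame 2D jumps is gamma
    distributed with shape = number of jumps and scale 4(D·Δt + σ²);
    EM over a fixed log-spaced D grid maximizes the mixture likelihood
    until the largest weight change drops below ``tol``. Free-component
    weights are then divided by the axial escape factor to undo the
    defocalization bias and renormalized.

    This is a deliberately simplified fixed-grid estimator of the
    diffusion-coefficient distribution, not a posterior state-array
    inference.
    """
    if d_grid is None:
        d_grid = np.geomspace(1e-3, 30.0, 40)
    d_grid = np.asarray(d_grid, dtype=float)
    if d_grid.size == 0:
        raise ValidationError("empty diffusion grid")
    df = jumps.records[jumps.records["dt"] == 1]
    if df.empty:
        raise ValidationError("spectrum needs dt=1 jumps")
    g = df.groupby("trajectory_id")["length"]
    s = g.apply(lambda v: float((v**2).sum())).to_numpy()
    n = g.size().to_numpy().astype(float)
    scale = 4.0 * (d_grid[None, :] * jumps.frame_interval + sigma**2)
    loglik = (
        (n[:, None] - 1.0) * np.log(s[:, None])
        - s[:, None] / scale
        - n[:, None] * np.log(scale)
        - special.gammaln(n[:, None])
    )
    w = np.full(d_grid.size, 1.0 / d_grid.size)
    it = 0
    for it in range(1, max_iter + 1):
        logr = loglik + np.log(np.maximum(w, 1e-300))[None, :]
        logr -= logr.max(axis=1, keepdims=True)
        r = np.exp(logr)
        r /= r.sum(axis=1, keepdims=True)
        w_new = r.mean(axis=0)
        if np.abs(w_new - w).max() < tol:
            w = w_new
            break
        w = w_new
    z = np.array([axial_escape_fraction(d, jumps.frame_interval, dz) for d in d_grid])
    corrected = w / z
    corrected /= corrected.sum()
    return DiffusionSpectrum(
        d_grid=d_grid, weights=corrected, weights_raw=w, n_trajectories=s.size, n_iter=it
    )


# ---------------------------------------------------------------------------
# Delta-method scaling
# ---------------------------------------------------------------------------


@dataclass
class ScaledConcentration:
    """Concentration × fraction with delta-method error propagation."""

    value: float  # nM
    sd: float
    ci95: float  # half-width = 1.96·sd


def scale_concentration_by_fraction(
    conc_mean: float, conc_sd: float, frac_mean: float, frac_sd: float
) -> ScaledConcentration:
    """Product C·f with variance f²·var(C) + C²·var(f) (delta method)."""
    if conc_sd < 0 or frac_sd < 0:
        raise ValidationError("standard deviations must be >= 0")
    var = frac_mean**2 * conc_sd**2 + conc_mean**2 * frac_sd**2
    sd = float(np.sqrt(var))
    return ScaledConcentration(value=float(conc_mean * frac_mean), sd=sd, ci95=1.96 * sd)
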