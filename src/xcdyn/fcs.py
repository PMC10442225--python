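"""FCS fitting and calibrated concentration imaging.

Fluorescence correlation spectroscopy (FCS) measures the autocorrelation
G(τ) of intensity fluctuations at a confocal point. Fitting G(τ) yields
the mean occupancy N of the confocal volume and per-component diffusion
times. A pure-dye measurement with known diffusion coefficient anchors
the confocal volume, which converts occupancy into absolute
concentration; a linear regression of FCS concentrations against image
intensities then calibrates whole images into nM per voxel
("FCS-calibrated imaging").

Model
-----
The autocorrelation model is a two-component anomalous-diffusion form
with a triplet-like blinking term::

    G(τ) = (1 + T/(1−T) · exp(−τ/τ_T)) · (1/N) ·
           Σ_i f_i · (1 + (τ/τ_i)^α_i)^−1 · (1 + (τ/τ_i)^α_i / κ²)^−1/2

with f₁ + f₂ = 1, diffusion times τ_i, anomaly exponents α_i, axial to
lateral aspect ratio κ and triplet fraction T. One-component mode fixes
f₁ = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import lmfit
import numpy as np
from scipy import stats

from .core_io import FcsCurve, RegionMaskSet, ValidationError

AVOGADRO = 6.02214e23

D_DYE_AF568 = 521.46
"""Diffusion coefficient of the AF568 calibration dye in solution at
37 °C, μm² s⁻¹."""

DYE_LAG_MAX = 10239e-6
"""Maximum lag (s) used when fitting pure-dye curves, to avoid
overfitting the flat tail of the autocorrelation."""


@dataclass
class FcsModelParams:
    """Parameters of the autocorrelation model (also drives simulation)."""

    N: float = 5.0
    f1: float = 1.0
    tau1: float = 25e-6
    alpha1: float = 1.0
    tau2: float = 5e-3
    alpha2: float = 1.0
    kappa: float = 5.0
    triplet_fraction: float = 0.0
    triplet_tau: float = 5e-6

    def validate(self) -> None:
        if self.N <= 0:
            raise ValidationError("N must be > 0")
        if not 0.0 <= self.f1 <= 1.0:
            raise ValidationError("f1 must be in [0, 1]")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValidationError("diffusion times must be > 0")
        if self.kappa <= 0:
            raise ValidationError("kappa must be > 0")
        if not 0.0 <= self.triplet_fraction < 1.0:
            raise ValidationError("triplet fraction must be in [0, 1)")


def autocorrelation_model(lag: np.ndarray, p: FcsModelParams) -> np.ndarray:
    """Evaluate G(τ) for the two-component anomalous-diffusion model."""
    lag = np.asarray(lag, dtype=float)
    p.validate()

    def component(tau_d: float, alpha: float) -> np.ndarray:
        u = (lag / tau_d) ** alpha
        return 1.0 / (1.0 + u) / np.sqrt(1.0 + u / p.kappa**2)

    diff = p.f1 * component(p.tau1, p.alpha1)
    if p.f1 < 1.0:
        diff = diff + (1.0 - p.f1) * component(p.tau2, p.alpha2)
    trip = 1.0
    if p.triplet_fraction > 0:
        T = p.triplet_fraction
        trip = 1.0 + T / (1.0 - T) * np.exp(-lag / p.triplet_tau)
    return trip * diff / p.N


@dataclass
class FcsFit:
    """Result of fitting the autocorrelation model to one curve."""

    params: FcsModelParams
    residual_rms: float
    n_points: int
    converged: bool
    fixed: tuple[str, ...] = ()
    label: str = "protein"

    @property
    def N(self) -> float:
        return self.params.N

    @property
    def tau_components(self) -> tuple[float, ...]:
        """Diffusion times ordered fastest (largest D) first."""
        if self.params.f1 >= 1.0:
            return (self.params.tau1,)
        return tuple(sorted((self.params.tau1, self.params.tau2)))


@dataclass
class ConfocalVolume:
    """Effective confocal detection volume from dye measurements."""

    w0: float  # lateral 1/e² radius, μm
    kappa: float  # axial / lateral aspect ratio
    d_dye: float  # dye diffusion coefficient used, μm² s⁻¹

    @property
    def volume(self) -> float:
        """V = π^{3/2} κ w0³ in μm³ (≡ fL)."""
        return np.pi**1.5 * self.kappa * self.w0**3


@dataclass
class CalibrationFit:
    """Linear intensity → concentration calibration."""

    slope: float  # a, nM per background-corrected intensity unit
    intercept: float  # b, nM
    background: float  # mean negative-control intensity
    r_squared: float
    n_points: int


@dataclass
class ConcentrationVolume:
    """Voxel grid of absolute concentrations (nM)."""

    concentrations: np.ndarray
    pixel_size: float
    voxel_depth: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.voxel_depth <= 0:
            raise ValidationError("voxel dimensions must be > 0")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        return self.pixel_size**2 * self.voxel_depth


# ---------------------------------------------------------------------------
# Curve fitting
# ---------------------------------------------------------------------------

_PARAM_NAMES = (
    "N",
    "f1",
    "tau1",
    "alpha1",
    "tau2",
    "alpha2",
    "kappa",
    "triplet_fraction",
    "triplet_tau",
)


def _make_lmfit_params(
    init: FcsModelParams, n_components: int, fix: Sequence[str]
) -> lmfit.Parameters:
    pars = lmfit.Parameters()
    pars.add("N", value=init.N, min=1e-6)
    pars.add("f1", value=init.f1, min=0.0, max=1.0)
    pars.add("tau1", value=init.tau1, min=1e-8, max=10.0)
    pars.add("alpha1", value=init.alpha1, min=0.2, max=2.0)
    pars.add("tau2", value=init.tau2, min=1e-8, max=10.0)
    pars.add("alpha2", value=init.alpha2, min=0.2, max=2.0)
    pars.add("kappa", value=init.kappa, min=0.5, max=20.0)
    pars.add("triplet_fraction", value=init.triplet_fraction, min=0.0, max=0.999)
    pars.add("triplet_tau", value=init.triplet_tau, min=1e-8, max=1e-3)
    if n_components == 1:
        pars["f1"].set(value=1.0, vary=False)
        pars["tau2"].set(vary=False)
        pars["alpha2"].set(vary=False)
    for name in fix:
        pars[name].set(vary=False)
    return pars


def _params_from_lmfit(pars: lmfit.Parameters) -> FcsModelParams:
    return FcsModelParams(**{k: float(pars[k].value) for k in _PARAM_NAMES})


def _initial_guess(lag: np.ndarray, G: np.ndarray, base: FcsModelParams | None) -> FcsModelParams:
    if base is not None:
        return base
    amp = max(float(G[0]), 1e-6)
    # half-amplitude lag as a diffusion-time scale
    below = np.nonzero(G <= amp / 2)[0]
    tau_half = float(lag[below[0]]) if below.size else float(lag[len(lag) // 2])
    return FcsModelParams(
        N=1.0 / amp, f1=0.7, tau1=tau_half / 2, tau2=tau_half * 20, kappa=5.0
    )


def fit_fcs_autocorrelation(
    curve: FcsCurve,
    n_components: int = 2,
    lag_max: float | None = None,
    weights: np.ndarray | None = None,
    fix: Sequence[str] = (),
    init: FcsModelParams | None = None,
    seed: int = 0,
) -> FcsFit:
    """Fit the autocorrelation model to one curve.

    One-component mode (``n_components=1``) fixes f₁ = 1, as used for
    the pure dye and the freely diffusing control. Dye-labelled curves
    are truncated at 10 239 μs unless ``lag_max`` overrides it.
    Parameters named in ``fix`` are held at their initial values. The
    optimizer runs twice, the second time from perturbed initial values,
    and keeps the better solution.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if lag_max is None and curve.label == "dye":
        lag_max = DYE_LAG_MAX
    lag, G = curve.lag, curve.G
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != lag.shape:
            raise ValidationError("weights must match the curve length")
    if lag_max is not None:
        keep = lag <= lag_max
        lag, G = lag[keep], G[keep]
        weights = weights[keep] if weights is not None else None
    if len(lag) < 10:
        raise ValidationError("curve has fewer than 10 usable lags")

    guess = _initial_guess(lag, G, init)

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        r = autocorrelation_model(lag, _params_from_lmfit(pars)) - G
        return r * weights if weights is not None else r

    rng = np.random.default_rng(seed)
    best = None
    for run in range(2):
        start = guess
        if run == 1:
            start = replace(
                guess,
                N=guess.N * float(rng.uniform(0.5, 2.0)),
                tau1=guess.tau1 * float(rng.uniform(0.3, 3.0)),
                tau2=guess.tau2 * float(rng.uniform(0.3, 3.0)),
            )
        pars = _make_lmfit_params(start, n_components, fix)
        try:
            out = lmfit.minimize(residual, pars, method="least_squares")
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        return FcsFit(
            params=guess,
            residual_rms=float(np.sqrt(np.mean(residual(_make_lmfit_params(guess, n_components, fix)) ** 2))),
            n_points=len(lag),
            converged=False,
            fixed=tuple(fix),
            label=curve.label,
        )
    fitted = _params_from_lmfit(best.params)
    rms = float(np.sqrt(best.chisqr / len(lag)))
    return FcsFit(
        params=fitted,
        residual_rms=rms,
        n_points=len(lag),
        converged=bool(best.success),
        fixed=tuple(fix),
        label=curve.label,
    )


# ---------------------------------------------------------------------------
# Confocal volume and diffusion coefficients
# ---------------------------------------------------------------------------


def estimate_confocal_volume(
    dye_fits: Sequence[FcsFit], d_dye: float = D_DYE_AF568
) -> ConfocalVolume:
    """Average confocal volume from one-component dye fits.

    Per fit, w0 = 2·√(D_dye·τ_dye); the returned volume averages w0 and
    κ over all dye measurements of the experiment.
    """
    if not dye_fits:
        raise ValidationError("need at least one dye fit")
    w0s, kappas = [], []
    for f in dye_fits:
        tau = f.params.tau1
        if tau <= 0:
            raise ValidationError("dye diffusion time must be > 0")
        w0s.append(2.0 * np.sqrt(d_dye * tau))
        kappas.append(f.params.kappa)
    return ConfocalVolume(w0=float(np.mean(w0s)), kappa=float(np.mean(kappas)), d_dye=d_dye)


def diffusion_from_tau(volume: ConfocalVolume, tau_protein: float) -> float:
    """Diffusion coefficient D = (w0/2)² / τ for one fitted component.

    For two-component fits pass each τ separately; the component with
    the smallest τ is the fastest (free) one.
    """
    if tau_protein <= 0:
        raise ValidationError("tau_protein must be > 0")
    return (volume.w0 / 2.0) ** 2 / tau_protein


def free_diffusion_coefficient(volume: ConfocalVolume, fit: FcsFit) -> float:
    """D of the free (fastest) component of a fit."""
    return diffusion_from_tau(volume, min(fit.tau_components))


def concentration_from_occupancy(volume: ConfocalVolume, N: float) -> float:
    """Convert mean occupancy N of the confocal volume into nM."""
    # N molecules in V μm³ = V·1e-15 L → mol/L → nM
    return N / (AVOGADRO * volume.volume * 1e-15) * 1e9


# ---------------------------------------------------------------------------
# Intensity calibration
# ---------------------------------------------------------------------------


def fit_intensity_calibration(
    intensities: np.ndarray,
    concentrations: np.ndarray,
    negative_control_intensities: np.ndarray,
) -> CalibrationFit:
    """Least-squares line C = a·(I − I_background) + b.

    The regression is meant to be established on freely diffusing
    control measurements only; the caller selects those points. The
    background is the mean intensity over negative-control (untagged)
    measurements.
    """
    I = np.asarray(intensities, dtype=float)
    C = np.asarray(concentrations, dtype=float)
    neg = np.asarray(negative_control_intensities, dtype=float)
    if I.shape != C.shape or I.ndim != 1:
        raise ValidationError("intensities and concentrations must be 1D and equal length")
    if len(I) < 2:
        raise ValidationError("need at least 2 calibration points")
    if neg.size == 0:
        raise ValidationError("need negative-control intensities")
    background = float(np.mean(neg))
    x = I - background
    if np.ptp(x) == 0:
        if np.ptp(C) == 0:
            # degenerate but well defined: flat response
            return CalibrationFit(0.0, float(C[0]), background, 1.0, len(I))
        raise ValidationError("zero intensity variance among calibration points")
    if np.ptp(C) == 0:
        return CalibrationFit(0.0, float(C[0]), background, 1.0, len(I))
    res = stats.linregress(x, C)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        background=background,
        r_squared=float(res.rvalue**2),
        n_points=len(I),
    )


def calibrate_stack(
    stack: np.ndarray, calib: CalibrationFit, pixel_size: float, voxel_depth: float
) -> ConcentrationVolume:
    """Convert an intensity stack to concentrations, C = a·(I − bkg) + b."""
    stack = np.asarray(stack, dtype=float)
    conc = calib.slope * (stack - calib.background) + calib.intercept
    return ConcentrationVolume(conc, pixel_size=pixel_size, voxel_depth=voxel_depth)


# ---------------------------------------------------------------------------
# Region summaries
# ---------------------------------------------------------------------------


@dataclass
class RegionConcentration:
    """Mean concentration, volume and molecule count of one region."""

    region: str
    mean_nM: float
    ci95_nM: float  # half-width; NaN when undefined
    volume_um3: float
    n_molecules: float
    n_voxels: int


def molecule_count(mean_nM: float, volume_um3: float) -> float:
    """Number of molecules in a region: C·10⁻⁹ · N_A · V·10⁻¹⁵ L."""
    return mean_nM * 1e-9 * AVOGADRO * volume_um3 * 1e-15


def summarize_region_concentration(
    conc: ConcentrationVolume, maskset: RegionMaskSet
) -> dict[str, RegionConcentration]:
    """Per-region mean concentration, 95% CI across voxels, volume and
    molecule count for xc, nucleoplasm and nucleoli.

    The CI is a normal approximation over voxels and ignores their
    spatial correlation. Empty regions return NaN entries; single-voxel
    regions have an undefined CI.
    """
    out = {}
    for region in ("xc", "nucleoplasm", "nucleoli"):
        mask = maskset.region(region)
        if mask.shape != conc.concentrations.shape:
            raise ValidationError(
                f"mask shape {mask.shape} does not match stack {conc.concentrations.shape}"
            )
        values = conc.concentrations[mask]
        n = values.size
        volume = n * conc.voxel_volume
        if n == 0:
            out[region] = RegionConcentration(region, np.nan, np.nan, 0.0, np.nan, 0)
            continue
        mean = float(values.mean())
        ci = float(1.96 * values.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        out[region] = RegionConcentration(
            region=region,
            mean_nM=mean,
            ci95_nM=ci,
            volume_um3=volume,
            n_molecules=molecule_count(mean, volume),
            n_voxels=n,
        )
    return out
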