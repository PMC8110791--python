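"""Seeded synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here with a
prescribed ground truth, so each stage is testable by round trip:

* pulsatile WSS vector series with exact target TAWSS and OSI,
* cyclic area series with a prescribed cycle-averaged wall strain
  (defaults emulate the ~1% strains with ~2% extremes seen at the venous
  anastomosis),
* shear-thinning rheology curves on the rheometer's 10–1500 s⁻¹ grid
  (6 points per decade), calibrated so η(200 s⁻¹) matches the 4·10⁻³ Pa·s
  blood-viscosity reference,
* group-structured qPCR Ct tables with technical replicates and injected
  quality-control violations,
* fibrous images with von-Mises-distributed orientations (doubled-angle
  convention for axial data),
* truncated-Fourier pulsatile inlet flow waveforms.

All generators are deterministic given a seed (bit-identical output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .metrics import AreaSeries, WssSeries

__all__ = [
    "InletWaveform",
    "gen_wss_series",
    "gen_area_series",
    "gen_rheology",
    "gen_ct_table",
    "gen_fiber_image",
    "gen_inlet_waveform",
    "FeasibilityError",
]


class FeasibilityError(ValueError):
    """Requested ground truth is not attainable by the waveform family."""


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# WSS series


def _offset_sine_osi(a: float, t: np.ndarray, T: float) -> float:
    f = a + np.sin(2.0 * np.pi * t / T)
    num = abs(np.trapezoid(f, t))
    den = np.trapezoid(np.abs(f), t)
    return 0.5 * (1.0 - num / den)


def gen_wss_series(
    target_tawss: float,
    target_osi: float,
    period: float = 1.0,
    n_samples: int = 200,
    n_elements: int = 1,
    noise_sd: float = 0.0,
    seed=0,
) -> WssSeries:
    """Axial offset-sinusoid WSS series with exact target TAWSS and OSI.

    Per element, ``τ(t) = s·(a + b·sin(2πt/T))·x̂`` with ``(a, b)`` solved
    numerically on the output grid so that the noise-free series has
    exactly the requested metrics under trapezoidal quadrature.  The
    family attains any OSI in [0, 0.5]: OSI 0 is the constant (b = 0)
    limit, OSI 0.5 the zero-offset (a = 0) limit.  ``noise_sd`` applies
    multiplicative lognormal element-level jitter to the amplitude scale
    (it perturbs TAWSS across elements but leaves each element's OSI
    exact).
    """
    if target_tawss <= 0:
        raise FeasibilityError("target TAWSS must be positive")
    if not 0.0 <= target_osi <= 0.5:
        raise FeasibilityError("target OSI must lie in [0, 0.5]")
    rng = _rng(seed)
    t = np.linspace(0.0, period, n_samples)
    if target_osi == 0.0:
        f = np.ones_like(t)
    else:
        # offset a in [0, 1) for b = 1: OSI decreases monotonically from 0.5
        a = 0.0 if target_osi == 0.5 else brentq(
            lambda a_: _offset_sine_osi(a_, t, period) - target_osi,
            0.0,
            1.0,
            xtol=1e-15,
        )
        f = a + np.sin(2.0 * np.pi * t / period)
    tawss_unit = np.trapezoid(np.abs(f), t) / period
    scale = target_tawss / tawss_unit
    jitter = np.exp(noise_sd * rng.standard_normal(n_elements)) if noise_sd > 0 else np.ones(n_elements)
    vecs = np.zeros((n_samples, n_elements, 3))
    vecs[:, :, 0] = scale * f[:, None] * jitter[None, :]
    ids = np.array([f"e{i}" for i in range(n_elements)])
    return WssSeries(ids, t, vecs, period=period)


def gen_area_series(
    target_strain: float = 0.01,
    period: float = 1.0,
    n_samples: int = 200,
    n_elements: int = 1,
    seed=0,
) -> AreaSeries:
    """Cyclic area series whose cycle-averaged wall strain is exact.

    The instantaneous strain is a raised sine,
    ``ε(t) = ε̄·(1 − cos(2πt/T))`` (cycle mean ε̄, peak 2ε̄ — defaults give
    ~1% average with 2% extremes), and areas follow ``A_n = A_0·(1+ε²)``
    so the square-root strain metric recovers ε(t) exactly.  Reference
    areas vary across elements (lognormal around 1 mm²); the metric is
    scale invariant so this does not affect the recovered strain.
    """
    if target_strain < 0:
        raise ValueError("strain must be >= 0")
    rng = _rng(seed)
    t = np.linspace(0.0, period, n_samples)
    eps_t = target_strain * (1.0 - np.cos(2.0 * np.pi * t / period))
    A0 = np.exp(0.1 * rng.standard_normal(n_elements))  # mm^2
    An = A0[None, :] * (1.0 + eps_t[:, None] ** 2)
    ids = np.array([f"e{i}" for i in range(n_elements)])
    return AreaSeries(ids, t, A0, An, period=period)


# ---------------------------------------------------------------------------
# Rheology

#: Carreau parameters of a blood-like shear-thinning fluid
#: (η0, η∞ in Pa·s; λ in s; a, n dimensionless).
CARREAU_BLOODLIKE = {"eta0": 0.056, "eta_inf": 0.00345, "lam": 3.313, "a": 2.0, "n": 0.3568}


def carreau_viscosity(shear_rate, eta0, eta_inf, lam, a, n):
    g = np.asarray(shear_rate, dtype=float)
    return eta_inf + (eta0 - eta_inf) * (1.0 + (lam * g) ** a) ** ((n - 1.0) / a)


def power_law_viscosity(shear_rate, K, n):
    g = np.asarray(shear_rate, dtype=float)
    return K * g ** (n - 1.0)


def rheometer_grid(span=(10.0, 1500.0), n_per_decade: int = 6) -> np.ndarray:
    """Log-spaced shear-rate grid, ``n_per_decade`` points per decade."""
    lo, hi = span
    n_steps = int(np.floor(n_per_decade * np.log10(hi / lo)))
    return lo * 10.0 ** (np.arange(n_steps + 1) / n_per_decade)


def gen_rheology(
    model: str = "carreau",
    model_params: dict | None = None,
    n_per_decade: int = 6,
    span=(10.0, 1500.0),
    noise_cv: float = 0.0,
    n_samples: int = 3,
    calibration: tuple[float, float] | None = (200.0, 4.0e-3),
    seed=0,
) -> pd.DataFrame:
    """Synthetic rheometry table: sample_id, replicate, shear_rate, viscosity.

    Viscosities follow a Carreau or power-law model, optionally rescaled
    so the model passes exactly through the calibration point (default:
    the blood-viscosity reference η(200 s⁻¹) = 4·10⁻³ Pa·s), with
    multiplicative lognormal noise of coefficient of variation
    ``noise_cv``.  One technical replicate per sample, matching cone-plate
    practice.
    """
    rng = _rng(seed)
    grid = rheometer_grid(span, n_per_decade)
    if model == "carreau":
        params = dict(CARREAU_BLOODLIKE, **(model_params or {}))
        eta = carreau_viscosity(grid, **params)
        eta_at = lambda g: carreau_viscosity(g, **params)  # noqa: E731
    elif model == "power_law":
        params = dict({"K": 0.02, "n": 0.7}, **(model_params or {}))
        if params["K"] <= 0:
            raise ValueError("power-law K must be positive")
        eta = power_law_viscosity(grid, **params)
        eta_at = lambda g: power_law_viscosity(g, **params)  # noqa: E731
    elif model == "newtonian":
        params = dict({"eta": 1.0e-3}, **(model_params or {}))
        eta = np.full_like(grid, params["eta"])
        eta_at = lambda g: params["eta"]  # noqa: E731
    else:
        raise ValueError(f"unknown rheology model {model!r}")
    if np.any(eta <= 0):
        raise ValueError("model produced non-positive viscosities")
    if calibration is not None:
        # rescale so the piecewise-linear interpolant of the noise-free
        # grid passes exactly through the calibration point
        g_cal, eta_cal = calibration
        if not grid[0] <= g_cal <= grid[-1]:
            raise ValueError("calibration shear rate outside the measured span")
        eta = eta * (eta_cal / np.interp(g_cal, grid, eta))
    rows = []
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    for s in range(n_samples):
        noise = np.exp(sigma * rng.standard_normal(grid.size) - 0.5 * sigma**2) if sigma else 1.0
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": f"s{s}",
                    "replicate": 1,
                    "shear_rate_1_per_s": grid,
                    "viscosity_pa_s": eta * noise,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# qPCR Ct tables


def gen_ct_table(
    genes=("ACTA2", "COL1A1", "COL3A1", "ELN", "MMP1"),
    groups=("HSS", "OSS", "LSS"),
    fold_matrix: dict | None = None,
    replicate_sd: float = 0.0,
    n_samples_per_group: int = 5,
    contamination_rate: float = 0.0,
    housekeeping: str = "GAPDH",
    control_group: str = "LSS",
    seed=0,
) -> pd.DataFrame:
    """Synthetic Ct table with two technical replicates per reaction.

    ``fold_matrix[(group, gene)]`` is the planted fold change relative to
    the control group (default 1 everywhere).  Gene Ct values are built
    as ``Ct_housekeeping + ΔCt_control − log2(fold)`` so the ΔΔCt
    pipeline recovers the planted folds exactly when ``replicate_sd = 0``.
    ``contamination_rate`` injects quality-control violations (wide
    replicate spread, failed melt curve, or a blanco too close to the
    signal) for exclusion-filter testing.
    """
    rng = _rng(seed)
    fold_matrix = fold_matrix or {}
    # fixed per-gene abundance offsets relative to the housekeeping gene
    dct_control = {g: 4.0 + 0.7 * i for i, g in enumerate(genes)}
    rows = []
    for group in groups:
        for k in range(n_samples_per_group):
            sample = f"{group}_{k + 1}"
            hk_ct = 18.0 + (0.3 * rng.standard_normal() if replicate_sd > 0 else 0.0)
            for gene in (housekeeping, *genes):
                if gene == housekeeping:
                    ct = hk_ct
                else:
                    fold = fold_matrix.get((group, gene), 1.0)
                    if fold <= 0:
                        raise ValueError("planted folds must be positive")
                    ct = hk_ct + dct_control[gene] - np.log2(fold)
                r1 = ct + replicate_sd * rng.standard_normal()
                r2 = ct + replicate_sd * rng.standard_normal()
                melt_ok = True
                blanco = 35.0
                if contamination_rate > 0 and rng.random() < contamination_rate:
                    kind = rng.integers(3)
                    if kind == 0:
                        r2 = r1 + 0.8  # replicate spread beyond the 0.5 Ct rule
                    elif kind == 1:
                        melt_ok = False
                    else:
                        blanco = ct + 1.0  # blanco within the exclusion margin
                rows.append(
                    {
                        "sample_id": sample,
                        "group": group,
                        "gene": gene,
                        "ct_rep1": r1,
                        "ct_rep2": r2,
                        "melt_curve_ok": melt_ok,
                        "blanco_ct": blanco,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fiber images


def gen_fiber_image(
    n_fibers: int = 200,
    mu_deg: float = 90.0,
    kappa: float = 8.0,
    length_px: int = 60,
    width_px: int = 1,
    image_size: int = 256,
    blur_sigma: float = 1.0,
    noise_sd: float = 0.02,
    seed=0,
) -> np.ndarray:
    """Synthetic fibrous image with von-Mises-distributed orientations.

    Axial (undirected) orientations are sampled with the doubled-angle
    convention: ``θ = (φ/2) mod 180°`` with ``φ ~ vonMises(2μ, κ)``, so
    κ → ∞ concentrates all fibers at μ and κ → 0 gives an isotropic
    texture.  Angles follow the mathematical convention (0° along the
    image x-axis, counterclockwise positive).  Returns a float image in
    [0, 1].
    """
    from skimage.draw import line_aa

    rng = _rng(seed)
    img = np.zeros((image_size, image_size))
    if kappa > 0:
        phi = rng.vonmises(np.deg2rad(2.0 * mu_deg), kappa, n_fibers)
        theta = np.mod(phi / 2.0, np.pi)
    else:
        theta = rng.uniform(0.0, np.pi, n_fibers)
    cx = rng.uniform(0, image_size, n_fibers)
    cy = rng.uniform(0, image_size, n_fibers)
    half = length_px / 2.0
    for i in range(n_fibers):
        dx = half * np.cos(theta[i])
        dy = -half * np.sin(theta[i])  # rows grow downward
        for off in range(width_px):
            r0 = int(np.clip(round(cy[i] - dy + off), 0, image_size - 1))
            c0 = int(np.clip(round(cx[i] - dx), 0, image_size - 1))
            r1 = int(np.clip(round(cy[i] + dy + off), 0, image_size - 1))
            c1 = int(np.clip(round(cx[i] + dx), 0, image_size - 1))
            rr, cc, val = line_aa(r0, c0, r1, c1)
            img[rr, cc] = np.maximum(img[rr, cc], val)
    if blur_sigma > 0:
        img = gaussian_filter(img, blur_sigma)
    if noise_sd > 0:
        img = img + noise_sd * rng.standard_normal(img.shape)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Inlet waveform


@dataclass(frozen=True)
class InletWaveform:
    """Truncated-Fourier pulsatile flow waveform, strictly positive.

    ``Q(t) = Q̄·(1 + Σ_k c_k·cos(2πkt/T − φ_k))``; the fluctuation shape is
    fixed and scaled to the requested pulsatility index (max−min)/mean.
    """

    mean_flow: float  # m^3/s
    period: float  # s
    amplitudes: np.ndarray  # relative harmonic amplitudes c_k
    phases: np.ndarray

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.ones_like(t)
        w = 2.0 * np.pi / self.period
        for k, (c, p) in enumerate(zip(self.amplitudes, self.phases), start=1):
            out = out + c * np.cos(k * w * t - p)
        return self.mean_flow * out

    def sample(self, n: int = 401) -> tuple[np.ndarray, np.ndarray]:
        t = np.linspace(0.0, self.period, n)
        return t, self(t)

    @property
    def pulsatility(self) -> float:
        _, q = self.sample(4001)
        return float((q.max() - q.min()) / self.mean_flow)


def gen_inlet_waveform(
    mean_flow: float = 2.5e-5,
    pulsatility: float = 0.8,
    harmonics: int = 3,
    period: float = 1.0,
) -> InletWaveform:
    """Build a positive pulsatile flow waveform with exact mean flow.

    ``mean_flow`` in m³/s, ``pulsatility`` = (max−min)/mean.  Harmonic
    amplitudes decay as 1/k with fixed phases, giving a systolic-pulse-like
    shape; ``harmonics = 0`` or ``pulsatility = 0`` yields constant flow.
    The requested pulsatility must keep the waveform positive.
    """
    if mean_flow <= 0 or period <= 0:
        raise ValueError("mean flow and period must be positive")
    if pulsatility < 0:
        raise ValueError("pulsatility must be >= 0")
    if harmonics == 0 or pulsatility == 0.0:
        return InletWaveform(mean_flow, period, np.zeros(0), np.zeros(0))
    k = np.arange(1, harmonics + 1)
    amp = 1.0 / k
    phases = k * np.pi / 4.0
    base = InletWaveform(1.0, period, amp, phases)
    _, q = base.sample(4001)
    scale = pulsatility / (q.max() - q.min())
    wf = InletWaveform(mean_flow, period, amp * scale, phases)
    _, q2 = wf.sample(4001)
    if q2.min() <= 0:
        raise ValueError("requested pulsatility makes the flow non-positive")
    return wf
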