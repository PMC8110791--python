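"""Hemodynamic wall metrics: TAWSS, OSI, and cyclic wall strain.

The three metrics summarize one cardiac cycle of wall data per surface
element:

* TAWSS — time-averaged magnitude of the wall shear stress (WSS) vector,
  ``(1/T) ∫ ||τ(t)|| dt`` (Pa).
* OSI — oscillatory shear index, ``0.5 * (1 - ||∫ τ dt|| / ∫ ||τ|| dt)``,
  ranging from 0 (unidirectional WSS) to 0.5 (purely oscillatory WSS).
* ε — cyclic wall strain from element areas, ``sqrt((A_n - A_0)/A_0)``
  evaluated per instant and then time-averaged over the cycle.

All time integrals use composite trapezoidal quadrature on the supplied
grid; no interpolation or resampling is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WssSeries",
    "AreaSeries",
    "MetricField",
    "PercentileSummary",
    "compute_tawss",
    "compute_osi",
    "compute_strain",
    "summarize",
    "in_percentile_window",
    "read_wss_csv",
    "read_areas_csv",
]


class InvalidInputError(ValueError):
    """Raised when a series violates its structural contract."""


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 3:
        raise InvalidInputError("need at least 3 time samples over one cycle")
    if not np.all(np.isfinite(times)):
        raise InvalidInputError("non-finite time values")
    if np.any(np.diff(times) <= 0):
        raise InvalidInputError("times must be strictly increasing")
    return times


@dataclass(frozen=True)
class WssSeries:
    """Per-element WSS vector time series over one cardiac cycle.

    Parameters
    ----------
    element_ids : (n_elements,) array of identifiers
    times : (n_times,) seconds, strictly increasing, within [0, T]
    vectors : (n_times, n_elements, 3) WSS vectors in Pa
    period : cycle duration T in seconds; defaults to ``times[-1]``
    """

    element_ids: np.ndarray
    times: np.ndarray
    vectors: np.ndarray
    period: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "element_ids", np.asarray(self.element_ids))
        object.__setattr__(self, "times", _check_times(self.times))
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 3 or v.shape[2] != 3:
            raise InvalidInputError("vectors must have shape (n_times, n_elements, 3)")
        if v.shape[0] != self.times.size or v.shape[1] != self.element_ids.size:
            raise InvalidInputError("vectors shape inconsistent with times/element_ids")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("non-finite WSS vector components")
        object.__setattr__(self, "vectors", v)
        T = float(self.times[-1]) if self.period is None else float(self.period)
        if self.times[-1] > T + 1e-12 or self.times[0] < -1e-12:
            raise InvalidInputError("times must lie within [0, T]")
        object.__setattr__(self, "period", T)

    @property
    def n_elements(self) -> int:
        return int(self.element_ids.size)


@dataclass(frozen=True)
class AreaSeries:
    """Per-element surface-area time series over one cardiac cycle.

    ``A0`` is the reference (initial) area per element (mm²); ``An`` the
    instantaneous areas, shape (n_times, n_elements).
    """

    element_ids: np.ndarray
    times: np.ndarray
    A0: np.ndarray
    An: np.ndarray
    period: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "element_ids", np.asarray(self.element_ids))
        object.__setattr__(self, "times", _check_times(self.times))
        A0 = np.asarray(self.A0, dtype=float)
        An = np.asarray(self.An, dtype=float)
        if A0.shape != (self.element_ids.size,):
            raise InvalidInputError("A0 must be one reference area per element")
        if An.shape != (self.times.size, self.element_ids.size):
            raise InvalidInputError("An must have shape (n_times, n_elements)")
        if np.any(A0 <= 0) or np.any(An <= 0):
            raise InvalidInputError("areas must be positive")
        object.__setattr__(self, "A0", A0)
        object.__setattr__(self, "An", An)
        T = float(self.times[-1]) if self.period is None else float(self.period)
        object.__setattr__(self, "period", T)


@dataclass(frozen=True)
class MetricField:
    """Per-element TAWSS (Pa), OSI (dimensionless) and ε (dimensionless)."""

    element_ids: np.ndarray
    tawss: np.ndarray | None = None
    osi: np.ndarray | None = None
    epsilon: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"element_id": self.element_ids})
        if self.tawss is not None:
            df["tawss_pa"] = self.tawss
        if self.osi is not None:
            df["osi"] = self.osi
        if self.epsilon is not None:
            df["epsilon"] = self.epsilon
        return df


@dataclass(frozen=True)
class PercentileSummary:
    """Empirical percentiles plus a histogram of a per-element metric."""

    probe_percentiles: np.ndarray
    values: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray

    def percentile_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"percentile": self.probe_percentiles, "value": self.values}
        )

    def histogram_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def _cycle_integrals(wss: WssSeries) -> tuple[np.ndarray, np.ndarray, float]:
    """Return (∫||τ||dt, ||∫τ dt||) per element and the period T."""
    t = wss.times
    mag = np.linalg.norm(wss.vectors, axis=2)  # (nt, ne)
    int_mag = np.trapezoid(mag, t, axis=0)
    int_vec = np.trapezoid(wss.vectors, t, axis=0)  # (ne, 3)
    return int_mag, np.linalg.norm(int_vec, axis=1), float(wss.period)


def compute_tawss(wss: WssSeries) -> np.ndarray:
    """Time-averaged WSS magnitude per element (Pa).

    Integrates ``||τ(t)||`` by the composite trapezoid rule on the series'
    own grid and divides by the cycle period T.
    """
    int_mag, _, T = _cycle_integrals(wss)
    span = float(wss.times[-1] - wss.times[0])
    # normalize by the covered span so partial grids average correctly;
    # a full-cycle grid has span == T
    return int_mag / (span if span > 0 else T)


def compute_osi(wss: WssSeries) -> np.ndarray:
    """Oscillatory shear index per element, in [0, 0.5].

    Elements whose cycle integral of ``||τ||`` is zero (identically zero
    WSS) have an undefined OSI and are returned as NaN rather than 0.
    """
    int_mag, norm_int_vec, _ = _cycle_integrals(wss)
    osi = np.full(int_mag.shape, np.nan)
    ok = int_mag > 0
    osi[ok] = 0.5 * (1.0 - norm_int_vec[ok] / int_mag[ok])
    # absorb floating-point excursions only
    tiny = 1e-9
    osi[ok] = np.clip(osi[ok], -tiny, 0.5 + tiny)
    osi[ok] = np.clip(osi[ok], 0.0, 0.5)
    return osi


def compute_strain(
    areas: AreaSeries, *, negative_policy: str = "clamp"
) -> np.ndarray:
    """Cycle-averaged wall strain ``ε = sqrt((A_n - A_0)/A_0)`` per element.

    The square root is evaluated per time instant, then averaged over the
    cycle with the trapezoid rule.  Instants with ``A_n < A_0`` have no
    real strain under this metric; by default the area deficit is clamped
    to zero with a warning (``negative_policy="clamp"``), while
    ``negative_policy="strict"`` raises.
    """
    if negative_policy not in ("clamp", "strict"):
        raise ValueError("negative_policy must be 'clamp' or 'strict'")
    rel = (areas.An - areas.A0[np.newaxis, :]) / areas.A0[np.newaxis, :]
    n_neg = int(np.count_nonzero(rel < 0))
    if n_neg:
        if negative_policy == "strict":
            raise InvalidInputError(
                f"{n_neg} instants with A_n < A_0 (compressive); strain undefined"
            )
        warnings.warn(
            f"clamped {n_neg} instants with A_n < A_0 to zero strain",
            RuntimeWarning,
            stacklevel=2,
        )
        rel = np.clip(rel, 0.0, None)
    eps_t = np.sqrt(rel)
    t = areas.times
    span = float(t[-1] - t[0])
    return np.trapezoid(eps_t, t, axis=0) / span


def summarize(
    values: np.ndarray,
    *,
    probe_percentiles: np.ndarray | None = None,
    bins: int = 50,
) -> PercentileSummary:
    """Percentile curve and histogram of a per-element metric.

    Percentiles use the linear-interpolation empirical quantile; NaN
    entries (e.g. undefined OSI) are dropped first.
    """
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise InvalidInputError("no finite values to summarize")
    if probe_percentiles is None:
        probe_percentiles = np.arange(0.0, 101.0, 1.0)
    probe_percentiles = np.asarray(probe_percentiles, dtype=float)
    quant = np.percentile(values, probe_percentiles)
    counts, edges = np.histogram(values, bins=bins)
    return PercentileSummary(probe_percentiles, quant, edges, counts)


def in_percentile_window(
    candidate: float, dataset: np.ndarray, lo: float, hi: float
) -> tuple[bool, float, float]:
    """Whether ``candidate`` lies inside the [lo, hi] percentile window.

    Mirrors the boundary-condition selection rule used to pick bioreactor
    loads from computed strain/WSS distributions: a candidate load is
    acceptable when it falls between the window's empirical quantiles.
    Returns ``(inside, lower_bound, upper_bound)``.
    """
    if not (0 <= lo < hi <= 100):
        raise ValueError("need 0 <= lo < hi <= 100")
    dataset = np.asarray(dataset, dtype=float).ravel()
    dataset = dataset[np.isfinite(dataset)]
    if dataset.size == 0:
        raise InvalidInputError("empty dataset")
    lo_v, hi_v = np.percentile(dataset, [lo, hi])
    return bool(lo_v <= candidate <= hi_v), float(lo_v), float(hi_v)


# ---------------------------------------------------------------------------
# CSV interfaces (long format)

def read_wss_csv(path) -> WssSeries:
    """Read a long-format WSS table: element_id, time_s, tau_x, tau_y, tau_z."""
    df = pd.read_csv(path)
    need = {"element_id", "time_s", "tau_x", "tau_y", "tau_z"}
    if not need.issubset(df.columns):
        raise InvalidInputError(f"WSS CSV must have columns {sorted(need)}")
    times = np.sort(df["time_s"].unique())
    elements = df["element_id"].unique()
    wide = df.set_index(["time_s", "element_id"]).sort_index()
    vecs = np.empty((times.size, elements.size, 3))
    for j, e in enumerate(elements):
        sub = wide.xs(e, level="element_id")
        sub = sub.reindex(times)
        vecs[:, j, :] = sub[["tau_x", "tau_y", "tau_z"]].to_numpy()
    return WssSeries(elements, times, vecs)


def read_areas_csv(path) -> AreaSeries:
    """Read a long-format area table: element_id, time_s, A0_mm2, An_mm2."""
    df = pd.read_csv(path)
    need = {"element_id", "time_s", "A0_mm2", "An_mm2"}
    if not need.issubset(df.columns):
        raise InvalidInputError(f"area CSV must have columns {sorted(need)}")
    times = np.sort(df["time_s"].unique())
    elements = df["element_id"].unique()
    wide = df.set_index(["time_s", "element_id"]).sort_index()
    A0 = np.empty(elements.size)
    An = np.empty((times.size, elements.size))
    for j, e in enumerate(elements):
        sub = wide.xs(e, level="element_id").reindex(times)
        A0[j] = sub["A0_mm2"].iloc[0]
        An[:, j] = sub["An_mm2"].to_numpy()
    return AreaSeries(elements, times, A0, An)
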