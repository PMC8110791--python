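"""Fiber-orientation analysis of grayscale images via the structure tensor.

Local orientation is the direction of the eigenvector of the smoothed
gradient structure tensor belonging to its *smaller* eigenvalue (image
intensity varies least along a fiber).  Orientations are axial data on
[0°, 180°) in the mathematical convention (0° along the image x-axis,
counterclockwise positive) — in the bioreactor frame, applied stretch is
at 0° and applied shear/flow at 90°.  The angular histogram is weighted
by tensor coherence times tensor energy so that flat background and
isotropic noise contribute little, and dispersion is summarized by the
circular standard deviation of the doubled angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import structure_tensor

__all__ = ["OrientationHistogram", "orientation_histogram", "read_image"]


@dataclass(frozen=True)
class OrientationHistogram:
    """Angular density of fiber orientations over [0°, 180°)."""

    bin_centers: np.ndarray  # degrees
    density: np.ndarray  # sums to 1
    peak_angle: float  # degrees, center of the modal bin
    circular_dispersion: float  # degrees, circular SD of doubled angles

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"angle_deg": self.bin_centers, "density": self.density})


def orientation_histogram(
    image: np.ndarray,
    sigma_gradient: float = 1.0,
    sigma_window: float = 4.0,
    n_bins: int = 36,
) -> OrientationHistogram:
    """Weighted fiber-orientation histogram of a 2D grayscale image.

    ``sigma_gradient`` smooths the image before differentiation (px);
    ``sigma_window`` is the tensor-averaging window (px); ``n_bins``
    angular bins cover [0°, 180°) (36 bins of 5° by default).  Raises on
    a constant image, where orientation is undefined.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    if np.ptp(img) == 0:
        raise ValueError("constant image: orientation undefined")
    if sigma_gradient > 0:
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(img, sigma_gradient)
    Arr, Arc, Acc = structure_tensor(img, sigma=sigma_window, mode="mirror", order="rc")
    # math convention: x = columns, y = -rows
    Jxx, Jyy, Jxy = Acc, Arr, -Arc
    # dominant-eigenvector (gradient) angle; fiber is perpendicular
    theta_grad = 0.5 * np.arctan2(2.0 * Jxy, Jxx - Jyy)
    theta = np.mod(theta_grad + 0.5 * np.pi, np.pi)
    energy = Jxx + Jyy
    lam_diff = np.sqrt((Jxx - Jyy) ** 2 + 4.0 * Jxy**2)
    coherence = np.where(energy > 0, lam_diff / (energy + 1e-30), 0.0)
    weight = (coherence * energy).ravel()
    counts, edges = np.histogram(
        np.degrees(theta).ravel(), bins=n_bins, range=(0.0, 180.0), weights=weight
    )
    total = counts.sum()
    if total <= 0:
        raise ValueError("no oriented structure detected")
    density = counts / total
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = float(centers[np.argmax(density)])
    # circular SD of doubled angles, weighted
    z = np.exp(2j * theta.ravel())
    R = np.abs(np.sum(weight * z)) / weight.sum()
    dispersion = float(np.degrees(np.sqrt(max(-2.0 * np.log(max(R, 1e-300)), 0.0))))
    return OrientationHistogram(centers, density, peak, dispersion)


def read_image(path) -> np.ndarray:
    """Load an 8/16-bit grayscale TIFF or PNG as a float image in [0, 1]."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    vmax = img.max()
    return img / vmax if vmax > 0 else img
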