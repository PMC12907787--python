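"""Fan-to-parallel rebinning and filtered backprojection.

A full 360-degree fan-beam sinogram is resampled onto a uniform
(parallel angle, radial offset) grid using the identities

    theta = beta + gamma + 3*pi/2  (mod 2*pi),   r = R_source * sin(gamma)

by bilinear interpolation, then reconstructed with the classical ramp-
filtered backprojection (band-limited discrete ramp kernel, optional cosine
apodization emulating a moderately smooth quantitative kernel). Pixel values
come out in the units of the input sinogram per cm: attenuation sinograms
give mu in 1/cm, material-length sinograms (cm) give dimensionless relative
density.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .projector import Sinogram

log = logging.getLogger(__name__)


@dataclass
class Image:
    """Square-pixel reconstruction grid.

    ``grid_offset`` shifts the grid center (mm, isocenter coordinates, y up),
    which compensates an off-centered phantom exactly.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0  # mm
    grid_offset: tuple[float, float] = (0.0, 0.0)
    units: str = "mu"  # "mu" | "relative density" | "HU"
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.pixels.shape[0]

    def coords(self):
        """Pixel-center coordinates (x, y) in mm, y increasing upward."""
        n = self.n
        c = (np.arange(n) - (n - 1) / 2.0) * self.pixel_size
        x = c[None, :] + self.grid_offset[0]
        y = c[:, None] + self.grid_offset[1]
        return x, y

    def copy_with(self, pixels, **kw) -> "Image":
        out = replace(self, pixels=pixels)
        for k, v in kw.items():
            setattr(out, k, v)
        return out


@dataclass
class ParallelSinogram:
    values: np.ndarray  # (n_angles, n_radial)
    angles: np.ndarray  # radians, in [0, pi)
    radii: np.ndarray  # mm, uniform
    label: str = ""
    meta: dict = field(default_factory=dict)


def rebin_fan_to_parallel(sinogram: Sinogram, n_angles: int | None = None,
                          n_radial: int | None = None,
                          radial_span_mm: float | None = None
                          ) -> ParallelSinogram:
    """Resample a 360-degree fan-beam sinogram to parallel geometry."""
    geo = sinogram.geometry
    if n_angles is None:
        n_angles = geo.n_projections // 2
    if n_radial is None:
        # oversample radially: detector sampling at the isocenter is about
        # source_radius * channel_width, finer than one sample per channel
        # over the full span
        n_radial = 2 * geo.n_channels + 1
    if radial_span_mm is None:
        radial_span_mm = 2.0 * geo.scan_radius
    if n_angles < 64:
        log.warning("only %d parallel angles; expect angular aliasing",
                    n_angles)
    angles = np.pi * np.arange(n_angles) / n_angles
    radii = np.linspace(-radial_span_mm / 2.0, radial_span_mm / 2.0, n_radial)
    gamma = np.arcsin(np.clip(radii / geo.source_radius, -1.0, 1.0))
    dg = math.radians(geo.channel_width_deg)
    ch_idx = gamma / dg + (geo.n_channels - 1) / 2.0  # fractional channel
    ch0 = np.clip(np.floor(ch_idx).astype(int), 0, geo.n_channels - 2)
    wc = np.clip(ch_idx - ch0, 0.0, 1.0)
    dbeta = 2.0 * np.pi / geo.n_projections
    out = np.empty((n_angles, n_radial))
    vals = sinogram.values
    for j, theta in enumerate(angles):
        beta = np.mod(theta - gamma - 1.5 * np.pi, 2.0 * np.pi)
        b_idx = beta / dbeta
        b0 = np.floor(b_idx).astype(int) % geo.n_projections
        b1 = (b0 + 1) % geo.n_projections
        wb = b_idx - np.floor(b_idx)
        row = ((1 - wb) * ((1 - wc) * vals[b0, ch0] + wc * vals[b0, ch0 + 1])
               + wb * ((1 - wc) * vals[b1, ch0] + wc * vals[b1, ch0 + 1]))
        out[j] = row
    return ParallelSinogram(values=out, angles=angles, radii=radii,
                            label=sinogram.label, meta=dict(sinogram.meta))


def _ramp_kernel(n: int, dr_cm: float) -> np.ndarray:
    """Band-limited discrete ramp filter kernel (spatial domain)."""
    k = np.arange(-n, n + 1)
    h = np.zeros(k.size)
    h[n] = 1.0 / (4.0 * dr_cm**2)
    odd = k % 2 != 0
    h[odd] = -1.0 / (np.pi * k[odd] * dr_cm) ** 2
    return h


def filter_projections(psino: ParallelSinogram,
                       apodization: float = 1.0) -> np.ndarray:
    """Ramp-filter every projection row (FFT convolution).

    ``apodization`` is the exponent of a cosine roll-off window
    cos(pi*f/(2*f_N))**apodization applied on top of the ramp; 0 disables it
    (sharp kernel), larger values emulate smoother quantitative kernels.
    """
    n_r = psino.values.shape[1]
    dr_cm = float(psino.radii[1] - psino.radii[0]) / 10.0
    nfft = int(2 ** np.ceil(np.log2(4 * n_r)))
    h = _ramp_kernel(n_r, dr_cm)
    hf = np.fft.rfft(h, nfft)
    if apodization > 0:
        f = np.fft.rfftfreq(nfft)
        window = np.cos(np.pi * f / (2 * f.max())) ** apodization
        hf = hf * window
    pf = np.fft.rfft(psino.values, nfft, axis=1)
    q = np.fft.irfft(pf * hf[None, :], nfft, axis=1)
    # kernel is centered at sample n_r; same-length slice
    return dr_cm * q[:, n_r:n_r + n_r]


def fbp_reconstruct(psino: ParallelSinogram, n_pixels: int = 256,
                    pixel_size: float = 1.0,
                    grid_offset: tuple[float, float] = (0.0, 0.0),
                    apodization: float = 1.0, units: str = "mu") -> Image:
    """Filtered backprojection onto a centered or shifted pixel grid."""
    q = filter_projections(psino, apodization=apodization)
    img = Image(pixels=np.zeros((n_pixels, n_pixels)), pixel_size=pixel_size,
                grid_offset=grid_offset, units=units,
                meta={"apodization": apodization, "label": psino.label})
    x, y = img.coords()
    r0 = float(psino.radii[0])
    dr = float(psino.radii[1] - psino.radii[0])
    acc = img.pixels
    for j, theta in enumerate(psino.angles):
        t = x * math.cos(theta) + y * math.sin(theta)
        idx = (t - r0) / dr
        acc += np.interp(idx, np.arange(q.shape[1]), q[j], left=0.0, right=0.0)
    acc *= np.pi / len(psino.angles)
    return img


def reconstruct(sinogram: Sinogram, n_pixels: int = 256, pixel_size: float = 1.0,
                grid_offset: tuple[float, float] = (0.0, 0.0),
                apodization: float = 1.0, units: str = "mu",
                n_angles: int | None = None,
                n_radial: int | None = None) -> Image:
    """Convenience: rebin + FBP in one call."""
    psino = rebin_fan_to_parallel(sinogram, n_angles=n_angles,
                                  n_radial=n_radial)
    return fbp_reconstruct(psino, n_pixels=n_pixels, pixel_size=pixel_size,
                           grid_offset=grid_offset, apodization=apodization,
                           units=units)
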