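"""Fan-beam geometry, analytic path lengths, polychromatic forward model.

Geometry convention: the source travels counter-clockwise on a circle of
radius ``source_radius`` (mm); at projection ``p`` the source sits at angle
``beta_p = 2*pi*p/n_projections``. Channel ``i`` looks along the central ray
(direction from source through the isocenter) rotated by the fan angle
``gamma_i = (i - (C-1)/2) * channel_width``. Rays are source-to-channel-
center lines; distances in geometry are mm, material path lengths are cm,
attenuation is 1/cm.

The polychromatic measurement model for a ray is

    g = -log( sum_E W(E) * exp(-sum_mat mu_mat(E) * L_mat)  +  s )

with ``W`` the per-channel normalized energy response and ``s`` an optional
additive scatter intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .phantoms import GeometryError, Phantom
from .physics import EnergyResponse, Material, material_mu

# Table-1 full-scale values; the scaled-down default preserves the total fan
# angle by widening the channels.
FULL_N_PROJECTIONS = 2304
FULL_N_CHANNELS = 736
FULL_CHANNEL_WIDTH_DEG = 0.067864


@dataclass(frozen=True)
class FanBeamGeometry:
    n_projections: int = 720
    n_channels: int = 368
    source_to_detector: float = 1085.6  # mm
    source_radius: float = 595.0  # mm
    channel_width_deg: float = FULL_CHANNEL_WIDTH_DEG * FULL_N_CHANNELS / 368
    fov_diameter: float = 250.0  # mm, reconstruction field of view

    def __post_init__(self):
        if self.source_radius >= self.source_to_detector:
            raise GeometryError("source radius must be below the detector distance")
        if self.scan_radius <= 0:
            raise GeometryError("empty fan")

    @classmethod
    def scaled(cls, n_projections: int = 720, n_channels: int = 368,
               **kw) -> "FanBeamGeometry":
        """Scaled-down geometry preserving the Table-1 total fan angle."""
        width = FULL_CHANNEL_WIDTH_DEG * FULL_N_CHANNELS / n_channels
        return cls(n_projections=n_projections, n_channels=n_channels,
                   channel_width_deg=width, **kw)

    @classmethod
    def full_scale(cls, **kw) -> "FanBeamGeometry":
        return cls(n_projections=FULL_N_PROJECTIONS, n_channels=FULL_N_CHANNELS,
                   channel_width_deg=FULL_CHANNEL_WIDTH_DEG, **kw)

    @property
    def fan_angles(self) -> np.ndarray:
        """Fan angle of each channel center (radians)."""
        i = np.arange(self.n_channels)
        dg = math.radians(self.channel_width_deg)
        return (i - (self.n_channels - 1) / 2.0) * dg

    @property
    def source_angles(self) -> np.ndarray:
        """Source position angle of each projection (radians)."""
        return 2.0 * np.pi * np.arange(self.n_projections) / self.n_projections

    @property
    def scan_radius(self) -> float:
        """Radius (mm) of the region covered by every projection."""
        gmax = math.radians(self.channel_width_deg) * (self.n_channels - 1) / 2.0
        return self.source_radius * math.sin(gmax)

    def rays(self):
        """Ray origins and unit directions, each shaped (P, C)."""
        beta = self.source_angles[:, None]
        gamma = self.fan_angles[None, :]
        ox = self.source_radius * np.cos(beta) + 0.0 * gamma
        oy = self.source_radius * np.sin(beta) + 0.0 * gamma
        phi = beta + np.pi + gamma
        return ox, oy, np.cos(phi), np.sin(phi)


@dataclass
class MaterialLengths:
    """Per-material intersection lengths (cm), each array (P, C)."""

    lengths: dict[str, np.ndarray]
    materials: dict[str, Material]
    geometry: FanBeamGeometry

    def __getitem__(self, name: str) -> np.ndarray:
        return self.lengths[name]

    def names(self):
        return list(self.lengths)


@dataclass
class Sinogram:
    """Line-integral-domain measurements g, shaped (P, C)."""

    values: np.ndarray
    label: str
    geometry: FanBeamGeometry
    meta: dict = field(default_factory=dict)

    def copy_with(self, values: np.ndarray, **meta) -> "Sinogram":
        m = dict(self.meta)
        m.update(meta)
        return Sinogram(values=values, label=self.label,
                        geometry=self.geometry, meta=m)


# ---------------------------------------------------------------------------
# Path lengths
# ---------------------------------------------------------------------------

def _nesting_parents(shapes) -> list[int]:
    """Index of the smallest shape directly containing each shape (-1 = none)."""
    parents = []
    for i, s in enumerate(shapes):
        best, best_ext = -1, np.inf
        for j, o in enumerate(shapes):
            if j != i and o.contains_shape(s) and o.extent < best_ext:
                best, best_ext = j, o.extent
        parents.append(best)
    return parents


def path_lengths(phantom: Phantom, geometry: FanBeamGeometry) -> MaterialLengths:
    """Analytic per-material chord lengths for every ray (cm).

    Nested shapes follow the replacement rule: a container's length is its
    own chord minus the chords of the shapes directly inside it.
    """
    if phantom.extent > geometry.scan_radius:
        raise GeometryError(
            f"phantom extent {phantom.extent:.1f} mm exceeds the scanned "
            f"region radius {geometry.scan_radius:.1f} mm")
    shapes = phantom.shapes()
    parents = _nesting_parents(shapes)
    ox, oy, ux, uy = geometry.rays()
    chords = [s.chord_lengths(ox, oy, ux, uy) for s in shapes]
    eff = [c.copy() for c in chords]
    for i, parent in enumerate(parents):
        if parent >= 0:
            eff[parent] -= chords[i]
    out: dict[str, np.ndarray] = {}
    for s, e in zip(shapes, eff):
        name = s.material.name
        out[name] = out.get(name, 0.0) + e
    # mm -> cm at the module boundary
    out = {k: v / 10.0 for k, v in out.items()}
    return MaterialLengths(lengths=out, materials=phantom.materials(),
                           geometry=geometry)


# ---------------------------------------------------------------------------
# Polychromatic forward model
# ---------------------------------------------------------------------------

def forward_intensity(lengths: MaterialLengths, response: EnergyResponse,
                      chunk: int = 64) -> np.ndarray:
    """Transmitted primary fraction T = sum_E W(E) exp(-sum_mat mu*L), (P, C)."""
    if response.n_channels != lengths.geometry.n_channels:
        raise ValueError("response channel count does not match the geometry")
    e = response.grid.energies
    mus = {name: material_mu(lengths.materials[name], e)
           for name in lengths.names()}
    p, c = next(iter(lengths.lengths.values())).shape
    t = np.empty((p, c))
    for lo in range(0, p, chunk):
        hi = min(lo + chunk, p)
        expo = np.zeros((hi - lo, c, e.size))
        for name, arr in lengths.lengths.items():
            expo += arr[lo:hi, :, None] * mus[name][None, None, :]
        t[lo:hi] = np.einsum("pce,ce->pc", np.exp(-expo), response.weights)
    return t


def polychromatic_forward(lengths: MaterialLengths, response: EnergyResponse,
                          scatter: np.ndarray | float = 0.0) -> Sinogram:
    """Line-integral measurements g = -log(T + s)."""
    t = forward_intensity(lengths, response)
    total = t + scatter
    if np.any(total <= 0):
        raise ValueError("non-positive detected intensity (T + s <= 0)")
    return Sinogram(values=-np.log(total), label=response.label,
                    geometry=lengths.geometry)


def add_poisson_noise(sinogram: Sinogram, photons_per_ray: float,
                      seed: int, n_repeats: int = 1) -> Sinogram:
    """Poisson noise in the intensity domain, then back to line integrals.

    Emulates the repeat-and-average protocol when ``n_repeats`` > 1: counts
    from the repeats are averaged before the log. Zero total counts are
    clipped to 0.5 counts.
    """
    if photons_per_ray <= 0:
        raise ValueError("photons_per_ray must be positive")
    rng = np.random.default_rng(seed)
    i0 = photons_per_ray * np.exp(-sinogram.values)
    counts = rng.poisson(i0 * n_repeats) / n_repeats
    counts = np.maximum(counts, 0.5)
    g = -np.log(counts / photons_per_ray)
    return sinogram.copy_with(g, noise_seed=seed,
                              photons_per_ray=photons_per_ray,
                              n_repeats=n_repeats)
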