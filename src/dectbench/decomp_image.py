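"""Image-domain material decomposition and virtual mono-energetic synthesis.

The image-based comparator mirrors common vendor practice: reconstructed LE
and HE images are interpreted as approximately mono-energetic at effective
energies identified from a two-configuration calibration phantom, then each
pixel's (mu_LE, mu_HE) pair is inverted through a 2x2 basis-material matrix
to relative densities (f_w, f_c). Virtual mono-energetic images (VMIs) at
any energy follow by recombining the densities with the basis attenuation
coefficients; the same synthesis step serves the data-based path, which
supplies density images reconstructed from decomposed length sinograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantoms import GeometryError
from .physics import Material, hu_from_mu, material_mu
from .recon import Image


@dataclass(frozen=True)
class RatioCurve:
    """Tabulated ground-truth basis attenuation ratio mu_c(E)/mu_w(E)."""

    energies: np.ndarray
    ratio: np.ndarray

    @classmethod
    def from_materials(cls, water: Material, calcium: Material,
                       e_min: float = 30.0, e_max: float = 140.0,
                       step: float = 0.1) -> "RatioCurve":
        e = np.arange(e_min, e_max + step / 2, step)
        r = material_mu(calcium, e) / material_mu(water, e)
        return cls(energies=e, ratio=r)

    def __call__(self, e: float) -> float:
        return float(np.interp(e, self.energies, self.ratio))


@dataclass(frozen=True)
class DecompositionMatrix:
    """2x2 basis matrix D = [[mu_w(eps_LE), mu_c(eps_LE)],
    [mu_w(eps_HE), mu_c(eps_HE)]]."""

    eps_le: float
    eps_he: float
    matrix: np.ndarray

    @classmethod
    def from_energies(cls, eps_le: float, eps_he: float, water: Material,
                      calcium: Material) -> "DecompositionMatrix":
        if not eps_le < eps_he:
            raise ValueError("effective LE energy must be below the HE one")
        d = np.array([
            [material_mu(water, eps_le), material_mu(calcium, eps_le)],
            [material_mu(water, eps_he), material_mu(calcium, eps_he)],
        ])
        det = abs(float(np.linalg.det(d)))
        if det < 1e-6 * np.linalg.norm(d) ** 2:
            raise np.linalg.LinAlgError(
                "near-singular decomposition matrix (effective energies too "
                "close)")
        return cls(eps_le=eps_le, eps_he=eps_he, matrix=d)


def compute_insert_ratio(image_water_cfg: Image, image_calcium_cfg: Image,
                         roi, mu_water_ref: float):
    """ROI means of the two calibration configurations as relative densities.

    Both images must be reconstructions of same-kV scans in attenuation
    units referenced to the energy-independent water value ``mu_water_ref``.
    Returns (rho_w, rho_c, ratio) with ratio = rho_c / rho_w.
    """
    from .evaluation import roi_stats  # local import to avoid a cycle

    rho_w = roi_stats(image_water_cfg, roi)[0] / mu_water_ref
    rho_c = roi_stats(image_calcium_cfg, roi)[0] / mu_water_ref
    return rho_w, rho_c, ratio_from_densities(rho_w, rho_c)


def ratio_from_densities(rho_w: float, rho_c: float) -> float:
    """Calibration ratio of the central-insert relative densities."""
    return rho_c / rho_w


def find_effective_energy(ratio: float, curve: RatioCurve) -> float:
    """Energy at which the ground-truth ratio curve equals ``ratio``.

    The curve is strictly monotone (decreasing for water/calcium) over its
    tabulated range; inversion is by linear interpolation at the curve's
    resolution.
    """
    r = curve.ratio
    lo, hi = min(r[0], r[-1]), max(r[0], r[-1])
    if not (lo <= ratio <= hi):
        raise ValueError(
            f"ratio {ratio:.4f} outside the curve range [{lo:.4f}, {hi:.4f}]")
    if r[0] > r[-1]:  # decreasing: flip for np.interp
        return float(np.interp(ratio, r[::-1], curve.energies[::-1]))
    return float(np.interp(ratio, r, curve.energies))


def decompose_pixelwise(img_le: Image, img_he: Image,
                        dm: DecompositionMatrix) -> tuple[Image, Image]:
    """Per-pixel inversion (f_w, f_c) = D^-1 (mu_LE, mu_HE)."""
    if img_le.pixels.shape != img_he.pixels.shape:
        raise GeometryError("LE and HE images are not on the same grid")
    inv = np.linalg.inv(dm.matrix)
    f_w = inv[0, 0] * img_le.pixels + inv[0, 1] * img_he.pixels
    f_c = inv[1, 0] * img_le.pixels + inv[1, 1] * img_he.pixels
    meta = {"eps_le": dm.eps_le, "eps_he": dm.eps_he}
    return (img_le.copy_with(f_w, units="relative density", meta=meta),
            img_le.copy_with(f_c, units="relative density", meta=meta))


def synthesize_vmi(f_w: Image, f_c: Image, e_kev: float, water: Material,
                   calcium: Material, units: str = "HU") -> Image:
    """Virtual mono-energetic image mu = f_w mu_w(E) + f_c mu_c(E).

    Returned in HU against mu_w(E) by default, or raw mu with units="mu".
    """
    mu_w = material_mu(water, e_kev)
    mu_c = material_mu(calcium, e_kev)
    mu = f_w.pixels * mu_w + f_c.pixels * mu_c
    if units == "HU":
        out = hu_from_mu(mu, mu_w)
    elif units == "mu":
        out = mu
    else:
        raise ValueError(f"unknown VMI units {units!r}")
    return f_w.copy_with(out, units=units, meta={"energy_kev": e_kev})
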