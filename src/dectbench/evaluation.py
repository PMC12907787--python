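"""ROI statistics, ring beam-hardening error, ground truth, energy curves."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantoms import GeometryError
from .physics import Material, hu_from_mu, material_mu
from .recon import Image

# Evaluation defaults: insert ROIs are 20 mm diameter circles; the bone ring
# has inner radius 17.64 mm and thickness 4.9 mm.
INSERT_ROI_RADIUS = 10.0
RING_INNER_RADIUS = 17.64
RING_THICKNESS = 4.9
ENERGY_RANGE = np.arange(30.0, 141.0, 5.0)


@dataclass(frozen=True)
class ROISpec:
    kind: str  # "circle" | "ring"
    center: tuple[float, float]  # mm, isocenter coordinates
    radius: float = INSERT_ROI_RADIUS  # circle radius
    inner_radius: float = RING_INNER_RADIUS
    thickness: float = RING_THICKNESS

    def __post_init__(self):
        if self.kind not in ("circle", "ring"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "circle" and self.radius <= 0:
            raise GeometryError("circle ROI radius must be positive")
        if self.kind == "ring" and (self.inner_radius <= 0 or self.thickness <= 0):
            raise GeometryError("ring ROI dimensions must be positive")

    def mask(self, image: Image) -> np.ndarray:
        """Pixels whose centers fall inside the ROI."""
        x, y = image.coords()
        d = np.hypot(x - self.center[0], y - self.center[1])
        if self.kind == "circle":
            m = d <= self.radius
        else:
            m = (d >= self.inner_radius) & (d <= self.inner_radius
                                            + self.thickness)
        if not m.any():
            raise GeometryError("ROI contains no pixel centers")
        return m


def roi_stats(image: Image, roi: ROISpec):
    """(mean, std, n_pixels) over the ROI."""
    vals = image.pixels[roi.mask(image)]
    return float(vals.mean()), float(vals.std()), int(vals.size)


def ring_mae(image: Image, gt_value: float, ring: ROISpec) -> float:
    """Mean absolute pixel deviation from the ground truth over a ring ROI
    (absolute values avoid cancellation of over- and undershoots)."""
    vals = image.pixels[ring.mask(image)]
    return float(np.mean(np.abs(vals - gt_value)))


def gt_hu(material: Material, e_kev: float, water: Material) -> float:
    """Ground-truth HU of a material at energy e."""
    return float(hu_from_mu(material_mu(material, e_kev),
                            material_mu(water, e_kev)))


def noise_energy_curve(vmi_stack, energies, roi: ROISpec):
    """Std inside the ROI per energy and the arg-min energy.

    Ties resolve to the lowest energy (leftmost), which also covers the
    noise-free degenerate case.
    """
    stds = np.array([roi_stats(img, roi)[1] for img in vmi_stack])
    energies = np.asarray(energies, dtype=float)
    return stds, float(energies[int(np.argmin(stds))])


def accuracy_table(f_w: Image, f_c: Image, water: Material, calcium: Material,
                   rois: dict[str, tuple[ROISpec, Material]],
                   energies=ENERGY_RANGE, method: str = "",
                   position: str = "") -> pd.DataFrame:
    """Mean/GT/error per ROI and energy from a decomposed density pair.

    For every energy the VMI is the linear recombination of the density
    images, so the stack costs one decomposition. Relative error for the
    water insert is computed on mu values (GT HU is zero there).
    """
    from .decomp_image import synthesize_vmi

    rows = []
    for e in energies:
        vmi_mu = synthesize_vmi(f_w, f_c, e, water, calcium, units="mu")
        mu_w = material_mu(water, e)
        for name, (roi, mat) in rois.items():
            mean_mu, std_mu, n = roi_stats(vmi_mu, roi)
            gt_mu = material_mu(mat, e)
            mean_hu = float(hu_from_mu(mean_mu, mu_w))
            gt = gt_hu(mat, e, water)
            rel = 100.0 * (mean_mu - gt_mu) / gt_mu
            rows.append({"method": method, "position": position,
                         "energy_kev": e, "roi": name, "n_pixels": n,
                         "mean_mu": mean_mu, "gt_mu": gt_mu,
                         "mean_hu": mean_hu, "gt_hu": gt,
                         "std_hu": 1000.0 * std_mu / mu_w,
                         "rel_err_pct": rel})
    return pd.DataFrame(rows)
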