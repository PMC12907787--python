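"""Projection-domain material decomposition.

The proposed method tabulates the inverse of the noise-free polychromatic
forward map with two bivariate polynomials: for every pair of basis-material
lengths (L_w, L_c) on a training grid (negative lengths included), the
scatter-free measurements (g_HE, g_LE) are simulated from the analytical
energy response, and L_w and L_c are then least-squares fitted as bivariate
polynomials (total degree <= 5 by default) in the normalized measurements.
Because the energy response varies across detector channels (bowtie filter),
polynomials are fitted per channel group by default; a central-only mode
reproduces the simplified single-spectrum variant.

The conventional comparator fits its polynomials to calibration scans of a
standard two-configuration phantom (scatter included, no subtraction),
pooled over channels, in the standard cubic or constrained-quartic forms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .physics import EnergyResponse, Material, material_mu
from .projector import MaterialLengths, Sinogram

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LengthGrid:
    """Uniform water/calcium length grids (cm); the cartesian product is the
    polynomial training set."""

    water: np.ndarray
    calcium: np.ndarray

    @property
    def pairs(self) -> np.ndarray:
        """(N, 2) row-major cartesian product [L_w, L_c]."""
        lw, lc = np.meshgrid(self.water, self.calcium, indexing="ij")
        return np.column_stack([lw.ravel(), lc.ravel()])


def build_length_grid(w_range=(-2.0, 28.0), c_range=(-4.0, 5.0),
                      step: float = 0.1) -> LengthGrid:
    """Inclusive uniform grids; defaults follow the reference study conditions."""
    if step <= 0:
        raise ValueError("step must be positive")

    def grid(lo, hi):
        if hi <= lo:
            raise ValueError("degenerate range")
        n = int(round((hi - lo) / step)) + 1
        return np.linspace(lo, hi, n)

    return LengthGrid(water=grid(*w_range), calcium=grid(*c_range))


# ---------------------------------------------------------------------------
# Proposed: analytical-response polynomial decomposition
# ---------------------------------------------------------------------------

def _poly_terms(degree: int):
    """Exponent pairs (k, l) with 0 <= k + l <= degree, constant included."""
    return [(k, l) for k in range(degree + 1) for l in range(degree + 1 - k)]


def _design_matrix(x, y, terms):
    return np.column_stack([x**k * y**l for k, l in terms])


def group_channels_by_bowtie(bowtie_mm: np.ndarray, n_groups: int = 16):
    """Group channels whose bowtie thickness agrees within a tolerance.

    Channels are binned on thickness into at most ``n_groups`` equal-width
    bins; each bin shares one polynomial pair. Returns (group_of_channel,
    list of channel-index arrays).
    """
    t = np.asarray(bowtie_mm, dtype=float)
    lo, hi = t.min(), t.max()
    if hi - lo < 1e-9 or n_groups <= 1:
        return np.zeros(t.size, dtype=int), [np.arange(t.size)]
    edges = np.linspace(lo, hi, n_groups + 1)
    idx = np.clip(np.digitize(t, edges[1:-1]), 0, n_groups - 1)
    used = np.unique(idx)
    remap = {g: i for i, g in enumerate(used)}
    group_of = np.array([remap[g] for g in idx])
    members = [np.where(group_of == i)[0] for i in range(len(used))]
    return group_of, members


@dataclass
class DecompPolynomials:
    """Bivariate polynomial pairs mapping (g_HE, g_LE) -> (L_w, L_c)."""

    degree: int
    terms: list
    # per group: coefficient arrays and fitted (g_HE, g_LE) domain boxes
    coeffs_w: np.ndarray  # (G, n_terms)
    coeffs_c: np.ndarray
    domain_lo: np.ndarray  # (G, 2)
    domain_hi: np.ndarray
    group_of_channel: np.ndarray
    residual_rms: np.ndarray  # (G, 2) cm, training RMS per material
    channel_binding: str = "per-channel-group"

    def _eval_group(self, g, ghe, gle):
        lo, hi = self.domain_lo[g], self.domain_hi[g]
        span = np.maximum(hi - lo, 1e-12)
        x = (ghe - lo[0]) / span[0]
        y = (gle - lo[1]) / span[1]
        a = _design_matrix(x, y, self.terms)
        return a @ self.coeffs_w[g], a @ self.coeffs_c[g]

    def evaluate(self, ghe: np.ndarray, gle: np.ndarray):
        """Elementwise evaluation on (P, C) arrays; returns (L_w, L_c) in cm
        and the count of rays outside the fitted domain box."""
        lw = np.empty_like(ghe)
        lc = np.empty_like(ghe)
        n_extrap = 0
        for g in range(self.coeffs_w.shape[0]):
            cols = np.where(self.group_of_channel == g)[0]
            xh, xl = ghe[:, cols], gle[:, cols]
            lo, hi = self.domain_lo[g], self.domain_hi[g]
            n_extrap += int(np.sum((xh < lo[0]) | (xh > hi[0])
                                   | (xl < lo[1]) | (xl > hi[1])))
            w, c = self._eval_group(g, xh.ravel(), xl.ravel())
            lw[:, cols] = w.reshape(xh.shape)
            lc[:, cols] = c.reshape(xh.shape)
        return lw, lc, n_extrap


def _simulate_training_g(grid: LengthGrid, weights_row: np.ndarray,
                         energies: np.ndarray, mu_w: np.ndarray,
                         mu_c: np.ndarray) -> np.ndarray:
    """Noise-free g for every (L_w, L_c) pair under one response row.

    The transmitted fraction factorizes over the two materials, so the
    (W x C) table is a product of two small matrices summed over energy.
    """
    aw = np.exp(-np.outer(grid.water, mu_w))  # (W, E)
    ac = np.exp(-np.outer(grid.calcium, mu_c))  # (C, E)
    t = np.einsum("we,ce,e->wc", aw, ac, weights_row)
    return -np.log(t).ravel()  # row-major, matches grid.pairs


def fit_decomposition_polynomials(
        grid: LengthGrid, response_le: EnergyResponse,
        response_he: EnergyResponse, water: Material, calcium: Material,
        degree: int = 5, channel_binding: str = "per-channel-group",
        bowtie_mm: np.ndarray | None = None,
        n_groups: int = 16) -> DecompPolynomials:
    """Least-squares fit of the length maps on the training grid.

    ``channel_binding``:
      * "per-channel-group" (default) -- channels sharing bowtie thickness
        (within the binning tolerance) share one polynomial pair fitted to
        the group-mean response row; requires ``bowtie_mm``.
      * "central-only" -- one pair for all channels, fitted to the central
        channel's response.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    n_ch = response_le.n_channels
    if channel_binding == "central-only":
        group_of = np.zeros(n_ch, dtype=int)
        members = [np.array([n_ch // 2])]
    elif channel_binding == "per-channel-group":
        if bowtie_mm is None:
            raise ValueError("per-channel-group binding needs the bowtie profile")
        group_of, members = group_channels_by_bowtie(bowtie_mm, n_groups)
    else:
        raise ValueError(f"unknown channel binding {channel_binding!r}")

    terms = _poly_terms(degree)
    mu_w_le = material_mu(water, response_le.grid.energies)
    mu_c_le = material_mu(calcium, response_le.grid.energies)
    mu_w_he = material_mu(water, response_he.grid.energies)
    mu_c_he = material_mu(calcium, response_he.grid.energies)
    pairs = grid.pairs
    n_g = len(members)
    coeffs_w = np.empty((n_g, len(terms)))
    coeffs_c = np.empty((n_g, len(terms)))
    dom_lo = np.empty((n_g, 2))
    dom_hi = np.empty((n_g, 2))
    rms = np.empty((n_g, 2))
    for g, chans in enumerate(members):
        w_le = response_le.weights[chans].mean(axis=0)
        w_he = response_he.weights[chans].mean(axis=0)
        gle = _simulate_training_g(grid, w_le, response_le.grid.energies,
                                   mu_w_le, mu_c_le)
        ghe = _simulate_training_g(grid, w_he, response_he.grid.energies,
                                   mu_w_he, mu_c_he)
        lo = np.array([ghe.min(), gle.min()])
        hi = np.array([ghe.max(), gle.max()])
        span = np.maximum(hi - lo, 1e-12)
        a = _design_matrix((ghe - lo[0]) / span[0], (gle - lo[1]) / span[1],
                           terms)
        sol, _, rank, _ = np.linalg.lstsq(a, pairs, rcond=None)
        if rank < len(terms):
            raise np.linalg.LinAlgError(
                "rank-deficient polynomial fit; check measurement "
                "normalization and grid coverage")
        resid = a @ sol - pairs
        coeffs_w[g], coeffs_c[g] = sol[:, 0], sol[:, 1]
        dom_lo[g], dom_hi[g] = lo, hi
        rms[g] = np.sqrt(np.mean(resid**2, axis=0))
    return DecompPolynomials(degree=degree, terms=terms, coeffs_w=coeffs_w,
                             coeffs_c=coeffs_c, domain_lo=dom_lo,
                             domain_hi=dom_hi, group_of_channel=group_of,
                             residual_rms=rms, channel_binding=channel_binding)


def apply_decomposition(le: Sinogram, he: Sinogram,
                        polys: DecompPolynomials) -> tuple[Sinogram, Sinogram]:
    """Map scatter-subtracted (g_HE, g_LE) to material-length sinograms (cm)."""
    if le.values.shape != he.values.shape:
        raise ValueError("LE and HE sinograms are not aligned")
    lw, lc, n_extrap = polys.evaluate(he.values, le.values)
    if n_extrap:
        log.warning("decomposition evaluated %d rays outside the fitted "
                    "domain box", n_extrap)
    meta = {"decomposition": "proposed", "degree": polys.degree,
            "extrapolated_rays": n_extrap}
    return (Sinogram(lw, label="L_water", geometry=le.geometry, meta=meta),
            Sinogram(lc, label="L_calcium", geometry=le.geometry, meta=meta))


# ---------------------------------------------------------------------------
# Conventional calibration-based decomposition
# ---------------------------------------------------------------------------

CUBIC_TERMS = [(k, l) for k in range(4) for l in range(4 - k)
               if 1 <= k + l <= 3]  # 9 terms, no constant


@dataclass
class ConventionalPolynomials:
    """Calibration-fitted polynomial pair, cubic or constrained quartic."""

    variant: str  # "cubic" | "constrained-quartic"
    coeffs_w: np.ndarray
    coeffs_c: np.ndarray
    residual_rms: tuple[float, float] = (np.nan, np.nan)

    def _design(self, ghe, gle):
        if self.variant == "cubic":
            a_w = np.column_stack([ghe**k * gle**l for k, l in CUBIC_TERMS])
            return a_w, a_w
        d = ghe - gle
        a_w = np.column_stack([ghe + gle, d**2, d**3, d**4])
        a_c = np.column_stack([d, d**2, d**3, d**4])
        return a_w, a_c

    def evaluate(self, ghe: np.ndarray, gle: np.ndarray):
        shape = np.asarray(ghe).shape
        a_w, a_c = self._design(np.ravel(ghe), np.ravel(gle))
        return ((a_w @ self.coeffs_w).reshape(shape),
                (a_c @ self.coeffs_c).reshape(shape))

    def apply(self, le: Sinogram, he: Sinogram):
        lw, lc = self.evaluate(he.values, le.values)
        meta = {"decomposition": f"conventional-{self.variant}"}
        return (Sinogram(lw, label="L_water", geometry=le.geometry, meta=meta),
                Sinogram(lc, label="L_calcium", geometry=le.geometry, meta=meta))


def fit_conventional_polynomials(calib_le, calib_he, known_lengths,
                                 variant: str = "cubic",
                                 min_coverage_cm: float = 0.5
                                 ) -> ConventionalPolynomials:
    """Fit the conventional decomposition from calibration scans.

    ``calib_le``/``calib_he`` are sinograms (or sequences of sinograms) of
    the calibration phantom configurations, acquired with scatter included
    and no subtraction; ``known_lengths`` are the matching MaterialLengths.
    The fit pools all channels (one polynomial pair for the whole detector).
    """
    if variant not in ("cubic", "constrained-quartic"):
        raise ValueError(f"unknown variant {variant!r}")
    les = [calib_le] if isinstance(calib_le, Sinogram) else list(calib_le)
    hes = [calib_he] if isinstance(calib_he, Sinogram) else list(calib_he)
    kls = ([known_lengths] if isinstance(known_lengths, MaterialLengths)
           else list(known_lengths))
    gle = np.concatenate([s.values.ravel() for s in les])
    ghe = np.concatenate([s.values.ravel() for s in hes])
    lw = np.concatenate([k["water"].ravel() for k in kls])
    lc = np.concatenate([k.lengths.get("calcium",
                                       k.lengths.get("bone", 0 * k["water"])
                                       ).ravel() for k in kls])
    if np.ptp(lc) < min_coverage_cm:
        log.warning("calcium lengths cover only %.2f cm; conventional fit "
                    "may be ill-conditioned", float(np.ptp(lc)))
    model = ConventionalPolynomials(variant=variant,
                                    coeffs_w=np.zeros(1), coeffs_c=np.zeros(1))
    a_w, a_c = model._design(ghe, gle)
    cw, res_w, *_ = np.linalg.lstsq(a_w, lw, rcond=None)
    cc, res_c, *_ = np.linalg.lstsq(a_c, lc, rcond=None)
    model.coeffs_w, model.coeffs_c = cw, cc
    model.residual_rms = (
        float(np.sqrt(np.mean((a_w @ cw - lw) ** 2))),
        float(np.sqrt(np.mean((a_c @ cc - lc) ** 2))),
    )
    return model
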