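"""X-ray physics: energy grids, materials, Hounsfield units, energy response.

Attenuation is modeled with the two-basis (Alvarez-Macovski) parameterization

    mu(E) = pe_coeff * E**-3  +  kn_coeff * f_KN(E)

where ``f_KN`` is the total Klein-Nishina cross-section shape normalized to
1 at 100 keV. Per-material coefficients are calibrated from a two-point
reference attenuation table shipped with the package. In this two-basis
world every material is an exact linear combination of any two independent
basis materials, which makes the two-material decomposition problem
well-posed by construction and gives the testbench a self-consistent ground
truth.

The per-channel energy response W(E) is the normalized product of a
simplified bremsstrahlung tube spectrum, aluminum bowtie/inherent filtration,
and an energy-integrating detector weighting d(E) = E.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

# Valid energy range for the material model (keV).
MIN_ENERGY = 10.0
MAX_ENERGY = 150.0

# Default lower bound of the spectral integration grid (keV). Below this,
# realistically filtered clinical spectra carry negligible weight, while the
# photoelectric E^-3 term makes negative-length training measurements
# numerically explosive; the simplified bremsstrahlung model is therefore
# truncated here.
SPECTRUM_MIN_ENERGY = 30.0

# Energy-independent water reference used for "relative density" scaling.
WATER_REF_ENERGY = 70.0

_ELECTRON_REST_KEV = 510.99895


class DegenerateSpectrumError(ValueError):
    """A response row integrated to zero after filtration."""


# ---------------------------------------------------------------------------
# Klein-Nishina shape
# ---------------------------------------------------------------------------

def kn_total_cross_section(e_kev):
    """Total Klein-Nishina cross-section (arbitrary units) at energy ``e_kev``."""
    k = np.asarray(e_kev, dtype=float) / _ELECTRON_REST_KEV
    t = 1.0 + 2.0 * k
    return (
        (1.0 + k) / k**2 * (2.0 * (1.0 + k) / t - np.log(t) / k)
        + np.log(t) / (2.0 * k)
        - (1.0 + 3.0 * k) / t**2
    )


_KN_AT_100 = float(kn_total_cross_section(100.0))


def f_kn(e_kev):
    """Klein-Nishina shape normalized so that f_KN(100 keV) = 1."""
    return kn_total_cross_section(e_kev) / _KN_AT_100


# ---------------------------------------------------------------------------
# Energy grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyGrid:
    """Strictly increasing, uniform energy grid in keV."""

    energies: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 1 or e.size < 2:
            raise ValueError("energy grid must be a 1-D array with >= 2 points")
        steps = np.diff(e)
        if not np.all(steps > 0):
            raise ValueError("energies must be strictly increasing")
        if not np.allclose(steps, steps[0]):
            raise ValueError("energy grid must have a uniform step")
        if e[0] < MIN_ENERGY:
            raise ValueError(f"grid minimum {e[0]} keV below {MIN_ENERGY} keV")
        object.__setattr__(self, "energies", e)

    @classmethod
    def from_range(cls, e_min: float = MIN_ENERGY, e_max: float = 120.0,
                   step: float = 1.0) -> "EnergyGrid":
        n = int(round((e_max - e_min) / step)) + 1
        return cls(np.linspace(e_min, e_max, n))

    @property
    def e_min(self) -> float:
        return float(self.energies[0])

    @property
    def e_max(self) -> float:
        return float(self.energies[-1])

    @property
    def step(self) -> float:
        return float(self.energies[1] - self.energies[0])

    def __len__(self) -> int:
        return self.energies.size


# ---------------------------------------------------------------------------
# Materials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Material:
    """Two-basis material: photoelectric weight + Compton (KN) weight."""

    name: str
    density: float  # g/cm^3, informational
    pe_coeff: float  # mu contribution = pe_coeff * E^-3
    kn_coeff: float  # mu contribution = kn_coeff * f_KN(E)

    def mu(self, e_kev):
        return material_mu(self, e_kev)


def material_mu(material: Material, e_kev):
    """Linear attenuation coefficient (1/cm) of ``material`` at ``e_kev``."""
    e = np.asarray(e_kev, dtype=float)
    if np.any(e < MIN_ENERGY) or np.any(e > MAX_ENERGY):
        raise ValueError(
            f"energy outside the supported range "
            f"[{MIN_ENERGY}, {MAX_ENERGY}] keV"
        )
    mu = material.pe_coeff * e**-3 + material.kn_coeff * f_kn(e)
    return mu if mu.ndim else float(mu)


def hu_from_mu(mu, mu_water_ref: float):
    """Hounsfield units: 1000 * (mu - mu_water) / mu_water."""
    if mu_water_ref <= 0:
        raise ValueError("water reference attenuation must be positive")
    return 1000.0 * (np.asarray(mu, dtype=float) - mu_water_ref) / mu_water_ref


def fit_material(name: str, density: float, e1: float, mu1: float,
                 e2: float, mu2: float) -> Material:
    """Solve the 2x2 system for (pe_coeff, kn_coeff) from two reference points."""
    a = np.array([[e1**-3, float(f_kn(e1))],
                  [e2**-3, float(f_kn(e2))]])
    pe, kn = np.linalg.solve(a, np.array([mu1, mu2]))
    return Material(name=name, density=density, pe_coeff=float(pe),
                    kn_coeff=float(kn))


def load_materials(csv_path=None) -> dict[str, Material]:
    """Load and calibrate the fixture materials from the two-point CSV table.

    Returns a dict keyed by material name. The ``calcium`` key is an alias of
    the bone-equivalent material, which serves as the second decomposition
    basis.
    """
    if csv_path is None:
        ref = resources.files("dectbench").joinpath(
            "data/attenuation_two_point.csv")
        text = ref.read_text()
    else:
        with open(csv_path) as fh:
            text = fh.read()
    rows = [r for r in text.splitlines() if r.strip() and not r.startswith("#")]
    mats: dict[str, Material] = {}
    for rec in csv.DictReader(rows):
        mats[rec["material"]] = fit_material(
            rec["material"], float(rec["density_g_cm3"]),
            float(rec["e1_kev"]), float(rec["mu1_cm1"]),
            float(rec["e2_kev"]), float(rec["mu2_cm1"]),
        )
    if "bone" in mats:
        mats["calcium"] = mats["bone"]
    return mats


def load_reference_checks(csv_path=None) -> dict[str, tuple[float, float]]:
    """Independent (energy, mu) check points from the fixture table."""
    if csv_path is None:
        ref = resources.files("dectbench").joinpath(
            "data/attenuation_two_point.csv")
        text = ref.read_text()
    else:
        with open(csv_path) as fh:
            text = fh.read()
    rows = [r for r in text.splitlines() if r.strip() and not r.startswith("#")]
    return {rec["material"]: (float(rec["e_check_kev"]), float(rec["mu_check_cm1"]))
            for rec in csv.DictReader(rows)}


# ---------------------------------------------------------------------------
# Tube spectrum and energy response
# ---------------------------------------------------------------------------

def tube_spectrum(grid: EnergyGrid, tube_kv: float) -> np.ndarray:
    """Simplified bremsstrahlung fluence shape S(E) ~ (kV - E) * E, E <= kV."""
    e = grid.energies
    if grid.e_max > tube_kv:
        raise ValueError("energy grid extends beyond the tube voltage")
    return np.clip(tube_kv - e, 0.0, None) * e


def bowtie_profile(fan_angles_rad: np.ndarray, t0_mm: float = 2.0,
                   edge_factor: float = 3.0) -> np.ndarray:
    """Quadratic aluminum-equivalent bowtie thickness per channel (mm).

    t_i = t0 + t2 * gamma_i^2, with t2 set so the edge channel receives
    ``edge_factor`` times the central filtration.
    """
    g = np.asarray(fan_angles_rad, dtype=float)
    gmax = np.max(np.abs(g))
    t2 = (edge_factor - 1.0) * t0_mm / gmax**2 if gmax > 0 else 0.0
    return t0_mm + t2 * g**2


@dataclass(frozen=True)
class EnergyResponse:
    """Normalized per-channel spectral weighting W[channel, energy]."""

    label: str  # "LE" | "HE"
    weights: np.ndarray  # (n_channels, n_energies), rows sum to 1
    grid: EnergyGrid
    tube_kv: float = 0.0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != len(self.grid):
            raise ValueError("weights must be (channels, energies)")
        if np.any(w < 0):
            raise ValueError("response weights must be non-negative")
        object.__setattr__(self, "weights", w)

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]

    def mean_energies(self) -> np.ndarray:
        """Per-channel mean energy of the response (keV)."""
        return self.weights @ self.grid.energies

    def row(self, channel: int) -> np.ndarray:
        return self.weights[channel]


def build_energy_response(tube_kv: float, bowtie_mm: np.ndarray,
                          grid: EnergyGrid | None = None,
                          label: str | None = None,
                          inherent_filtration_mm_al: float = 6.0,
                          filter_material: Material | None = None,
                          energy_step: float = 1.0) -> EnergyResponse:
    """Build the normalized analytical energy response model.

    Each row is S(E; kV) * exp(-mu_Al(E) * t_i) * E, normalized to sum 1.
    The channel dependence comes from the bowtie profile ``bowtie_mm``
    (aluminum-equivalent thickness per channel, mm).
    """
    if grid is None:
        grid = EnergyGrid.from_range(SPECTRUM_MIN_ENERGY, tube_kv, energy_step)
    if filter_material is None:
        filter_material = load_materials()["aluminum"]
    t = np.asarray(bowtie_mm, dtype=float)
    if t.ndim != 1:
        raise ValueError("bowtie profile must be one thickness per channel")
    s = tube_spectrum(grid, tube_kv)
    mu_al = material_mu(filter_material, grid.energies)  # 1/cm
    total_mm = t[:, None] + inherent_filtration_mm_al
    w = s[None, :] * np.exp(-mu_al[None, :] * total_mm / 10.0) * grid.energies[None, :]
    sums = w.sum(axis=1)
    if np.any(sums <= 0) or not np.all(np.isfinite(sums)):
        raise DegenerateSpectrumError("a response row integrated to zero")
    w /= sums[:, None]
    if label is None:
        label = "LE" if tube_kv <= 100 else "HE"
    return EnergyResponse(label=label, weights=w, grid=grid, tube_kv=tube_kv)
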