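"""Acoustic and optical material properties for ionoacoustic simulations.

A :class:`Material` bundles everything the forward model needs to know about a
medium: the acoustic triplet (density, speed of sound, Grüneisen parameter)
that converts absorbed dose to pressure and governs wave propagation, the
optical absorption spectrum over the luminescence band (300-700 nm), the
luminescence light yield, and the water-equivalent ratio used to shift proton
ranges through upstream degraders.

The built-in registry holds the media of the two experimental arrangements:
the 22 MeV water-tank setup (titanium vacuum window, air gap, polyimide foils,
water, diluted India ink) and the clinical liver scenario (liver tissue with
an embedded hepatic tumor carrying ink-like optical absorption).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Material",
    "material_grueneisen",
    "get_material",
    "register_material",
    "MATERIALS",
    "WAVELENGTH_RANGE_NM",
]

# Luminescence band over which optical photons are generated and transported.
WAVELENGTH_RANGE_NM = (300.0, 700.0)

# Pure-water absorption coefficient, literature magnitudes (Pope & Fry scale),
# tabulated in m^-1 on the luminescence band and converted to mm^-1 below.
_WATER_MU_A_NM = np.array([300.0, 350.0, 400.0, 450.0, 500.0, 550.0, 600.0, 650.0, 700.0])
_WATER_MU_A_PER_M = np.array([0.0382, 0.0204, 0.0058, 0.0092, 0.0257, 0.0565, 0.2224, 0.340, 0.624])


def material_grueneisen(beta: float, c: float, cp: float) -> float:
    """Grüneisen parameter Γ = β c² / Cp.

    Parameters
    ----------
    beta : volumetric thermal-expansion coefficient of the medium [K⁻¹].
    c : speed of sound [m s⁻¹].
    cp : isobaric specific heat capacity [J kg⁻¹ K⁻¹].
    """
    if c <= 0 or cp <= 0 or beta < 0:
        raise ValueError("material_grueneisen requires beta >= 0, c > 0, cp > 0")
    return beta * c * c / cp


@dataclass(frozen=True)
class Material:
    """A medium with acoustic, optical and range-shifting properties.

    ``mu_a`` is a tabulated absorption spectrum ``(wavelength_nm, mu_a_mm)``;
    values are linearly interpolated and clamped at the table edges.  ``None``
    means optically transparent.
    """

    name: str
    density: float  # kg m^-3
    speed_of_sound: float  # m s^-1
    grueneisen: float  # dimensionless
    mu_a: tuple | None = None  # (wavelengths_nm, mu_a_mm) arrays
    light_yield: float = 0.0  # photons / MeV (per-material override; 0 = use run default)
    water_equivalent_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be > 0")
        if self.speed_of_sound <= 0:
            raise ValueError(f"{self.name}: speed_of_sound must be > 0")
        if self.grueneisen < 0:
            raise ValueError(f"{self.name}: grueneisen must be >= 0")
        if self.light_yield < 0:
            raise ValueError(f"{self.name}: light_yield must be >= 0")
        if self.water_equivalent_ratio < 0:
            raise ValueError(f"{self.name}: water_equivalent_ratio must be >= 0")
        if self.mu_a is not None:
            wl, mu = (np.asarray(a, dtype=float) for a in self.mu_a)
            if wl.shape != mu.shape or wl.ndim != 1:
                raise ValueError(f"{self.name}: mu_a table must be two 1-d arrays of equal length")
            if np.any(mu < 0):
                raise ValueError(f"{self.name}: mu_a must be >= 0 everywhere")
            object.__setattr__(self, "mu_a", (wl, mu))

    def mu_a_at(self, wavelength_nm) -> np.ndarray:
        """Absorption coefficient [mm⁻¹] at the given wavelength(s) [nm]."""
        if self.mu_a is None:
            return np.zeros_like(np.asarray(wavelength_nm, dtype=float))
        wl, mu = self.mu_a
        return np.interp(wavelength_nm, wl, mu)

    def with_overrides(self, **kwargs) -> "Material":
        return replace(self, **kwargs)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "density_kg_m3": self.density,
            "speed_of_sound_m_s": self.speed_of_sound,
            "grueneisen": self.grueneisen,
            "light_yield_photons_per_mev": self.light_yield,
            "water_equivalent_ratio": self.water_equivalent_ratio,
        }
        if self.mu_a is not None:
            d["mu_a_wavelength_nm"] = [float(v) for v in self.mu_a[0]]
            d["mu_a_per_mm"] = [float(v) for v in self.mu_a[1]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Material":
        mu_a = None
        if "mu_a_wavelength_nm" in d:
            mu_a = (np.asarray(d["mu_a_wavelength_nm"]), np.asarray(d["mu_a_per_mm"]))
        return cls(
            name=d["name"],
            density=d["density_kg_m3"],
            speed_of_sound=d["speed_of_sound_m_s"],
            grueneisen=d["grueneisen"],
            mu_a=mu_a,
            light_yield=d.get("light_yield_photons_per_mev", 0.0),
            water_equivalent_ratio=d.get("water_equivalent_ratio", 1.0),
        )


_WATER_MU_A = (_WATER_MU_A_NM, _WATER_MU_A_PER_M / 1e3)  # -> mm^-1

# 1% diluted India ink: the printed value at 632.8 nm, applied flat over the
# band (no spectral slope is printed; the mean free path is sub-micrometre at
# any plausible slope, so deposition geometry is insensitive to it).
_INK_MU_A = (np.array([300.0, 700.0]), np.array([3.7e3, 3.7e3]))

# Water acoustic state at 20.5 degC: Γ=0.11 with rho=998, c=1484.1.
WATER = Material(
    name="water",
    density=998.0,
    speed_of_sound=1484.1,
    grueneisen=0.11,
    mu_a=_WATER_MU_A,
)

# Thin degraders upstream of the water tank.  Only c=2400 m/s of polyimide is
# fixed by the printed c_ref; rho and Γ are literature-typical defaults.
POLYIMIDE = Material(
    name="polyimide",
    density=1420.0,
    speed_of_sound=2400.0,
    grueneisen=0.9,
    mu_a=_WATER_MU_A,  # optical properties taken equal to water
    water_equivalent_ratio=1.40,
)

TITANIUM = Material(
    name="titanium",
    density=4506.0,
    speed_of_sound=6070.0,
    grueneisen=1.1,
    water_equivalent_ratio=3.0,
)

AIR = Material(
    name="air",
    density=1.204,
    speed_of_sound=343.0,
    grueneisen=0.4,
    water_equivalent_ratio=1.07e-3,
)

# Contrast-agent phantom content: India ink diluted in water takes water
# acoustic properties, only the optical absorption differs.
INDIA_INK_1PCT = Material(
    name="india_ink_1pct",
    density=998.0,
    speed_of_sound=1484.1,
    grueneisen=0.11,
    mu_a=_INK_MU_A,
)

# Clinical liver scenario.  The tumor speed of sound 1556.9 m/s is printed;
# remaining acoustic values are liver-typical defaults (the HU conversion
# table is out of scope).  The tumor carries ink-like optical absorption,
# liver absorbs like water.
LIVER = Material(
    name="liver",
    density=1060.0,
    speed_of_sound=1578.0,
    grueneisen=0.20,
    mu_a=_WATER_MU_A,
)

HEPATIC_TUMOR = Material(
    name="hepatic_tumor",
    density=1041.0,
    speed_of_sound=1556.9,
    grueneisen=0.20,
    mu_a=_INK_MU_A,
)

MATERIALS: dict[str, Material] = {
    m.name: m
    for m in (WATER, POLYIMIDE, TITANIUM, AIR, INDIA_INK_1PCT, LIVER, HEPATIC_TUMOR)
}


def get_material(name: str) -> Material:
    try:
        return MATERIALS[name]
    except KeyError:
        raise KeyError(f"unknown material {name!r}; known: {sorted(MATERIALS)}") from None


def register_material(material: Material) -> None:
    MATERIALS[material.name] = material
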