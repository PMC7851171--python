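"""Monte Carlo energy deposition of proton-induced luminescence photons.

Protons stopping in water make the medium luminesce; the emitted optical
photons follow the dose distribution, carry a λ⁻² wavelength spectrum on
300-700 nm, and are re-absorbed with a medium- and wavelength-dependent
absorption coefficient.  In near-transparent water they travel far and mostly
escape; in an India-ink-loaded region the mean free path is sub-micrometre,
so their energy re-deposits locally and, for photons arriving from upstream
water, in a razor-thin layer at the ink interface.  That interface layer is
the photoacoustic source this package studies.

Transport is absorption-only (no scattering, refraction or re-emission):
the effect is dominated by the orders-of-magnitude absorption contrast, and
scattering parameters are not part of the model.  Emission is isotropic.
Photons are tracked with full 3D direction vectors through the axially
layered media; deposits are binned on the dose grid (on-axis slab for 1D
maps, central slice with an effective Gaussian slab thickness for 2D maps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfcx

from .dose import DoseMap
from .geometry import Scenario
from .materials import WAVELENGTH_RANGE_NM

__all__ = ["OpticalDoseMap", "optical_energy_deposition", "sample_wavelengths", "mean_wavelength"]

_H_C = 6.62607015e-34 * 2.99792458e8  # J m
_PATH_CAP = 1e3  # m; a photon exceeding this path length counts as escaped


def sample_wavelengths(n: int, rng: np.random.Generator,
                       band_nm: tuple = WAVELENGTH_RANGE_NM) -> np.ndarray:
    """Draw wavelengths [nm] from the λ⁻² luminescence spectrum (inverse CDF)."""
    lo, hi = band_nm
    u = rng.random(n)
    return 1.0 / (1.0 / lo - u * (1.0 / lo - 1.0 / hi))


def mean_wavelength(band_nm: tuple = WAVELENGTH_RANGE_NM) -> float:
    """Mean of the λ⁻² spectrum: ln(hi/lo) / (1/lo - 1/hi)  [nm]."""
    lo, hi = band_nm
    return np.log(hi / lo) / (1.0 / lo - 1.0 / hi)


@dataclass
class OpticalDoseMap:
    """Gy per voxel deposited by absorbed luminescence photons."""

    x: np.ndarray
    values: np.ndarray
    light_yield: float  # photons/MeV driving the emission
    n_photons_sampled: int
    seed: int
    y: np.ndarray | None = None
    wavelength_range_nm: tuple = WAVELENGTH_RANGE_NM
    spectrum_exponent: float = -2.0
    accounting: dict = field(default_factory=dict)  # emitted/absorbed/escaped [J]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("optical dose must be non-negative")

    @property
    def on_axis(self) -> np.ndarray:
        if self.values.ndim == 1:
            return self.values
        j = int(np.argmin(np.abs(self.y)))
        return self.values[:, j]


def _transport_layers(scenario: Scenario):
    """Layer table clipped to the grid extent (photons leaving it escape)."""
    x0, x1 = scenario.grid.extent
    starts, ends, mats = [], [], []
    for l in scenario.layers:
        a, b = max(l.x_start, x0), min(l.x_end, x1)
        if b > a:
            starts.append(a)
            ends.append(b)
            mats.append(l.material)
    return np.array(starts), np.array(ends), mats


def optical_energy_deposition(
    dose: DoseMap,
    scenario: Scenario,
    light_yield: float,
    n_photons: int = 200_000,
    seed: int = 0,
) -> OpticalDoseMap:
    """Sample luminescence photons off a dose map and deposit their energy.

    Emission density is proportional to the local deposited energy times the
    light yield Y [photons/MeV]; each sampled photon carries the physical
    weight (Y x total deposited energy in MeV) / n_photons and the energy
    hc/λ of its sampled wavelength.  A photon deposits its full energy where
    its exponential free path ends; photons leaving the gridded domain (or
    exceeding a path cap in near-transparent media) are tallied as escaped.
    """
    if light_yield < 0:
        raise ValueError("light yield must be >= 0")
    if n_photons < 0:
        raise ValueError("n_photons must be >= 0")
    if dose.x.shape != scenario.grid.x.shape or not np.allclose(dose.x, scenario.grid.x):
        raise ValueError("dose grid does not match scenario grid")

    grid = scenario.grid
    two_d = dose.values.ndim == 2
    rho = scenario.density_map
    dx = grid.axial_spacing
    sigma_beam = dose.beam.lateral_sigma
    if two_d:
        dy = grid.lateral_spacing
        dz_eff = np.sqrt(2.0 * np.pi) * sigma_beam
        voxel_mass = rho[:, None] * dx * dy * dz_eff * np.ones_like(dose.values)
    else:
        area_eff = 2.0 * np.pi * sigma_beam**2
        voxel_mass = rho * dx * area_eff

    energy_per_voxel = dose.values * voxel_mass  # J
    total_energy_j = float(energy_per_voxel.sum())
    shape = dose.values.shape
    out = np.zeros(shape)
    zero = OpticalDoseMap(dose.x, out, light_yield, n_photons, seed, y=dose.y,
                          accounting={"emitted_j": 0.0, "absorbed_j": 0.0, "escaped_j": 0.0})
    if light_yield == 0.0 or n_photons == 0 or total_energy_j == 0.0:
        return zero

    rng = np.random.default_rng(seed)
    n_physical = light_yield * total_energy_j / 1.602176634e-13  # photons
    weight = n_physical / n_photons

    # emission sites ~ deposited energy; uniform jitter inside the voxel
    pvox = energy_per_voxel.ravel() / total_energy_j
    vox = rng.choice(pvox.size, size=n_photons, p=pvox)
    if two_d:
        ix, iy = np.unravel_index(vox, shape)
        y = dose.y[iy] + (rng.random(n_photons) - 0.5) * grid.lateral_spacing
    else:
        ix = vox
        y = np.zeros(n_photons)
    x = dose.x[ix] + (rng.random(n_photons) - 0.5) * dx
    x_emit = x.copy()

    lam = sample_wavelengths(n_photons, rng)
    e_photon = weight * _H_C / (lam * 1e-9)  # physical J represented per sample
    emitted_j = float(e_photon.sum())

    # isotropic 3D directions; the layered media vary only along x, but the
    # transverse components set the lateral dilution of the deposits
    mu_x = 1.0 - 2.0 * rng.random(n_photons)
    phi = 2.0 * np.pi * rng.random(n_photons)
    mu_perp = np.sqrt(np.clip(1.0 - mu_x**2, 0.0, None))
    mu_y = mu_perp * np.cos(phi)
    mu_z = mu_perp * np.sin(phi)
    z = rng.normal(0.0, sigma_beam, n_photons) if two_d else None

    starts, ends, mats = _transport_layers(scenario)
    mu_a = np.stack([m.mu_a_at(lam) * 1e3 for m in mats])  # m^-1, (L, N)

    tau = rng.exponential(1.0, n_photons)
    path = np.zeros(n_photons)
    active = np.ones(n_photons, dtype=bool)
    dep_x = np.empty(n_photons)
    dep_y = np.empty(n_photons)
    dep_z = np.empty(n_photons) if two_d else None
    absorbed = np.zeros(n_photons, dtype=bool)
    x0, x1 = grid.extent
    y_lo, y_hi = (grid.lateral_extent if two_d else (-np.inf, np.inf))
    edge = 1e-12

    while active.any():
        idx = np.nonzero(active)[0]
        xi, yi = x[idx], y[idx]
        li = np.clip(np.searchsorted(starts, xi, side="right") - 1, 0, len(mats) - 1)
        mu = mu_a[li, idx]
        mx, my = mu_x[idx], mu_y[idx]

        with np.errstate(divide="ignore", invalid="ignore"):
            bx = np.where(mx > 0, ends[li], starts[li])
            dist_x = np.where(mx != 0, (bx - xi) / mx, np.inf)
            by = np.where(my > 0, y_hi, y_lo)
            dist_y = np.where(my != 0, (by - yi) / my, np.inf)
            dist_abs = np.where(mu > 0, tau[idx] / mu, np.inf)
        dist_b = np.minimum(np.minimum(dist_x, dist_y), _PATH_CAP - path[idx])

        absorb_here = dist_abs <= dist_b
        ia = idx[absorb_here]
        s = dist_abs[absorb_here]
        dep_x[ia] = x[ia] + mu_x[ia] * s
        dep_y[ia] = y[ia] + mu_y[ia] * s
        if two_d:
            dep_z[ia] = z[ia] + mu_z[ia] * s
        absorbed[ia] = True
        active[ia] = False

        im = idx[~absorb_here]
        s = dist_b[~absorb_here] + edge
        x[im] += mu_x[im] * s
        y[im] += mu_y[im] * s
        if two_d:
            z[im] += mu_z[im] * s
        tau[im] -= mu_a[li[~absorb_here], im] * s
        path[im] += s
        gone = (x[im] <= x0) | (x[im] >= x1) | (y[im] <= y_lo) | (y[im] >= y_hi) | (path[im] >= _PATH_CAP)
        active[im[gone]] = False

    # bin deposits on the dose grid
    ia = np.nonzero(absorbed)[0]
    bx = np.clip(((dep_x[ia] - x0) / dx).astype(int), 0, shape[0] - 1)
    if two_d:
        byi = np.clip(((dep_y[ia] - y_lo) / grid.lateral_spacing).astype(int), 0, shape[1] - 1)
        # central-slice density estimate in the collapsed z direction: a
        # Gaussian kernel of width sigma_beam on the tracked z deposit
        # position, normalized so deposits that stay within the beam
        # (z ~ N(0, sigma)) keep unit weight while photons that have spread
        # far in z are diluted away (true slice value, not a slab average)
        w_slice = np.sqrt(2.0) * np.exp(-0.5 * (dep_z[ia] / sigma_beam) ** 2)
        np.add.at(out, (bx, byi), e_photon[ia] * w_slice)
    else:
        # On-axis density estimate: a photon absorbed an axial distance L from
        # its emitter has spread laterally; the on-axis fluence of an isotropic
        # emitter column of Gaussian width sigma at distance L is diluted by
        # w(L) = 1 - x sqrt(pi) exp(x^2) erfc(x), x = L / (sqrt(2) sigma),
        # relative to the laterally-infinite slab tally (w(0)=1, w ~ sigma^2/L^2
        # far away).  The energy accounting below stays unweighted.
        xarg = np.abs(dep_x[ia] - x_emit[ia]) / (np.sqrt(2.0) * sigma_beam)
        w_axis = 1.0 - xarg * np.sqrt(np.pi) * erfcx(xarg)
        np.add.at(out, bx, e_photon[ia] * w_axis)
    absorbed_j = float(e_photon[ia].sum())

    out /= voxel_mass
    return OpticalDoseMap(
        dose.x, out, light_yield, n_photons, seed, y=dose.y,
        accounting={
            "emitted_j": emitted_j,
            "absorbed_j": absorbed_j,
            "escaped_j": emitted_j - absorbed_j,
        },
    )
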