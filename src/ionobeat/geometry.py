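"""Layered phantom geometries, simulation grids, sensors and scenario presets.

Coordinate convention: the axial coordinate x is 0 at the outer (upstream)
face of the water-tank entrance foil and increases along the beam direction.
Upstream beamline elements (vacuum window, air gap) sit at negative x.  All
printed distances (1.6 mm phantom entrance, 31/36 mm sensor distances,
11.4 cm clinical Bragg position) live in this frame, which makes
time-of-flight checks unambiguous.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import yaml

from .materials import MATERIALS, Material, get_material

__all__ = ["GridSpec", "SensorSpec", "Layer", "Scenario", "build_scenario", "PRESETS"]

SCHEMA_VERSION = 1

# Geometry constants of the tandem 22 MeV beamline (metres).
TI_WINDOW_THICKNESS = 11.4e-6
AIR_GAP = 6e-2
FOIL_THICKNESS = 50e-6
PHANTOM_ENTRANCE = 1.6e-3  # downstream face of the CA phantom entrance foil
PHANTOM_LENGTH = 20e-3
TANDEM_SENSOR_POSITION = 36e-3  # on axis, from the tank entrance window

# Clinical preset anchors (metres).
CLINICAL_BRAGG_DEPTH = 0.114  # Bragg maximum along the beam axis
CLINICAL_TUMOR_LENGTH = 0.02
CLINICAL_BRAGG_TO_EDGE = 14.49e-3
CLINICAL_SENSOR_POSITION = 0.27
CLINICAL_DOMAIN_LENGTH = 0.288


@dataclass(frozen=True)
class GridSpec:
    """Cartesian simulation grid: axial (beam) axis plus optional lateral axis.

    The time step follows the CFL condition dt = cfl * axial_spacing / c_ref,
    with c_ref the maximum speed of sound inside the simulated extent.
    """

    extent: tuple  # (x0, x1) m, axial
    axial_spacing: float = 25e-6
    lateral_extent: tuple | None = None  # (y0, y1) m; None -> 1D on-axis
    lateral_spacing: float = 50e-6
    cfl: float = 0.3
    pml_points: int = 20

    def __post_init__(self):
        if self.axial_spacing <= 0 or self.lateral_spacing <= 0:
            raise ValueError("grid spacings must be > 0")
        if not 0 < self.cfl <= 0.3:
            raise ValueError("CFL must be in (0, 0.3]")
        if self.extent[1] <= self.extent[0]:
            raise ValueError("axial extent must be increasing")

    @property
    def nx(self) -> int:
        return int(round((self.extent[1] - self.extent[0]) / self.axial_spacing))

    @property
    def ny(self) -> int:
        if self.lateral_extent is None:
            return 1
        return int(round((self.lateral_extent[1] - self.lateral_extent[0]) / self.lateral_spacing))

    @property
    def x(self) -> np.ndarray:
        """Axial cell centres."""
        return self.extent[0] + (np.arange(self.nx) + 0.5) * self.axial_spacing

    @property
    def y(self) -> np.ndarray | None:
        if self.lateral_extent is None:
            return None
        return self.lateral_extent[0] + (np.arange(self.ny) + 0.5) * self.lateral_spacing

    def time_step(self, c_ref: float) -> float:
        return self.cfl * self.axial_spacing / c_ref

    def to_dict(self) -> dict:
        return {
            "extent_m": [float(v) for v in self.extent],
            "axial_spacing_m": self.axial_spacing,
            "lateral_extent_m": None if self.lateral_extent is None else [float(v) for v in self.lateral_extent],
            "lateral_spacing_m": self.lateral_spacing,
            "cfl": self.cfl,
            "pml_points": self.pml_points,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        lat = d.get("lateral_extent_m")
        return cls(
            extent=tuple(d["extent_m"]),
            axial_spacing=d["axial_spacing_m"],
            lateral_extent=None if lat is None else tuple(lat),
            lateral_spacing=d.get("lateral_spacing_m", 50e-6),
            cfl=d.get("cfl", 0.3),
            pml_points=d.get("pml_points", 20),
        )


@dataclass(frozen=True)
class SensorSpec:
    """An on-axis pressure sensor: ideal point or finite disk aperture."""

    position: float  # m, axial
    geometry: str = "point"  # "point" | "disk"
    diameter: float = 3.5e-3

    def __post_init__(self):
        if self.geometry not in ("point", "disk"):
            raise ValueError("sensor geometry must be 'point' or 'disk'")
        if self.geometry == "disk" and self.diameter <= 0:
            raise ValueError("disk diameter must be > 0")

    def to_dict(self) -> dict:
        return {"position_m": self.position, "geometry": self.geometry, "diameter_m": self.diameter}

    @classmethod
    def from_dict(cls, d: dict) -> "SensorSpec":
        return cls(d["position_m"], d.get("geometry", "point"), d.get("diameter_m", 3.5e-3))


@dataclass(frozen=True)
class Layer:
    material: Material
    x_start: float
    x_end: float

    def __post_init__(self):
        if self.x_end <= self.x_start:
            raise ValueError(f"layer {self.material.name}: empty or inverted interval")

    @property
    def thickness(self) -> float:
        return self.x_end - self.x_start


@dataclass(frozen=True)
class Scenario:
    """A layered 1D/2D medium with a beam axis, a sensor and a grid."""

    name: str
    layers: tuple
    sensor: SensorSpec
    grid: GridSpec
    temperature: float = 20.5  # degC, recorded; material values already reflect it

    def __post_init__(self):
        layers = tuple(sorted(self.layers, key=lambda l: l.x_start))
        object.__setattr__(self, "layers", layers)
        for a, b in zip(layers, layers[1:]):
            if abs(a.x_end - b.x_start) > 1e-12:
                raise ValueError(
                    f"layers must tile the axis: gap/overlap between "
                    f"{a.material.name} and {b.material.name} at x={a.x_end}"
                )
        x0, x1 = self.grid.extent
        if not (layers[0].x_start - 1e-12 <= x0 and x1 <= layers[-1].x_end + 1e-12):
            raise ValueError("grid extent must lie inside the layered region")
        if not (x0 <= self.sensor.position <= x1):
            raise ValueError("sensor position lies outside the simulated domain")

    # -- material fields on the grid ------------------------------------
    def layer_index_at(self, x) -> np.ndarray:
        """Index of the layer containing each axial position."""
        edges = np.array([l.x_start for l in self.layers[1:]])
        return np.searchsorted(edges, np.asarray(x, dtype=float), side="right")

    def material_at(self, x):
        idx = np.atleast_1d(self.layer_index_at(x))
        return [self.layers[i].material for i in idx]

    def _field(self, attr: str) -> np.ndarray:
        vals = np.array([getattr(l.material, attr) for l in self.layers])
        return vals[self.layer_index_at(self.grid.x)]

    @property
    def density_map(self) -> np.ndarray:
        return self._field("density")

    @property
    def sound_speed_map(self) -> np.ndarray:
        return self._field("speed_of_sound")

    @property
    def grueneisen_map(self) -> np.ndarray:
        return self._field("grueneisen")

    @property
    def c_ref(self) -> float:
        """Maximum speed of sound over materials inside the grid extent."""
        x0, x1 = self.grid.extent
        cs = [l.material.speed_of_sound for l in self.layers if l.x_end > x0 + 1e-12 and l.x_start < x1 - 1e-12]
        return float(max(cs))

    @property
    def time_step(self) -> float:
        return self.grid.time_step(self.c_ref)

    # -- water-equivalent depth -----------------------------------------
    def water_equivalent_depth(self, x) -> np.ndarray:
        """WE path length from the upstream end of the first layer to x."""
        knots = [self.layers[0].x_start]
        we = [0.0]
        for l in self.layers:
            knots.append(l.x_end)
            we.append(we[-1] + l.thickness * l.material.water_equivalent_ratio)
        return np.interp(np.asarray(x, dtype=float), np.array(knots), np.array(we))

    def geometric_depth(self, we) -> np.ndarray:
        """Inverse of :meth:`water_equivalent_depth` (both monotone)."""
        knots = [self.layers[0].x_start]
        wek = [0.0]
        for l in self.layers:
            knots.append(l.x_end)
            wek.append(wek[-1] + l.thickness * l.material.water_equivalent_ratio)
        return np.interp(np.asarray(we, dtype=float), np.array(wek), np.array(knots))

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "units": {"length": "m", "temperature": "degC", "density": "kg m^-3", "speed": "m s^-1"},
            "temperature_degC": self.temperature,
            "sensor": self.sensor.to_dict(),
            "grid": self.grid.to_dict(),
            "layers": [
                {"material": l.material.to_dict(), "x_start_m": float(l.x_start), "x_end_m": float(l.x_end)}
                for l in self.layers
            ],
        }

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        if d.get("schema_version", 1) != SCHEMA_VERSION:
            raise ValueError(f"unsupported scenario schema version {d.get('schema_version')}")
        layers = tuple(
            Layer(Material.from_dict(ld["material"]), ld["x_start_m"], ld["x_end_m"]) for ld in d["layers"]
        )
        return cls(
            name=d["name"],
            layers=layers,
            sensor=SensorSpec.from_dict(d["sensor"]),
            grid=GridSpec.from_dict(d["grid"]),
            temperature=d.get("temperature_degC", 20.5),
        )

    @classmethod
    def from_yaml(cls, source) -> "Scenario":
        if hasattr(source, "read"):
            d = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh)
            except (OSError, ValueError):
                d = yaml.safe_load(io.StringIO(source))
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

_TANDEM_OVERRIDE_KEYS = {
    "phantom_fill",
    "sensor_position",
    "sensor_geometry",
    "temperature",
    "lateral_extent",
    "mode",
    "include_rear_foil",
}
_CLINICAL_OVERRIDE_KEYS = {
    "tumor_start",
    "bragg_to_edge",
    "sensor_position",
    "temperature",
    "mode",
}


def _tandem_scenario(name: str, overrides: dict) -> Scenario:
    unknown = set(overrides) - _TANDEM_OVERRIDE_KEYS
    if unknown:
        raise KeyError(f"unknown overrides for {name}: {sorted(unknown)}")
    fill = overrides.get("phantom_fill", "water")
    fill_mat = fill if isinstance(fill, Material) else get_material(fill)
    mode = overrides.get("mode", "2d")
    include_rear = overrides.get("include_rear_foil", True)

    water, poly, ti, air = (get_material(n) for n in ("water", "polyimide", "titanium", "air"))
    x_air0 = -AIR_GAP
    x_ti0 = x_air0 - TI_WINDOW_THICKNESS
    pe = PHANTOM_ENTRANCE
    layers = [
        Layer(ti, x_ti0, x_air0),
        Layer(air, x_air0, 0.0),
        Layer(poly, 0.0, FOIL_THICKNESS),
        Layer(water, FOIL_THICKNESS, pe - FOIL_THICKNESS),
        Layer(poly, pe - FOIL_THICKNESS, pe),
        Layer(fill_mat, pe, pe + PHANTOM_LENGTH),
    ]
    tail_start = pe + PHANTOM_LENGTH
    if include_rear:
        layers.append(Layer(poly, tail_start, tail_start + FOIL_THICKNESS))
        tail_start += FOIL_THICKNESS
    layers.append(Layer(water, tail_start, 60e-3))

    lateral = overrides.get("lateral_extent", (-4.8e-3, 4.8e-3)) if mode == "2d" else None
    grid = GridSpec(
        extent=(-2.5e-3, 45.5e-3),
        axial_spacing=25e-6,
        lateral_extent=lateral,
        lateral_spacing=50e-6,
    )
    sensor = SensorSpec(
        position=overrides.get("sensor_position", TANDEM_SENSOR_POSITION),
        geometry=overrides.get("sensor_geometry", "disk" if mode == "2d" else "point"),
    )
    return Scenario(
        name=name,
        layers=tuple(layers),
        sensor=sensor,
        grid=grid,
        temperature=overrides.get("temperature", 20.5),
    )


def _clinical_scenario(overrides: dict) -> Scenario:
    unknown = set(overrides) - _CLINICAL_OVERRIDE_KEYS
    if unknown:
        raise KeyError(f"unknown overrides for clinical_liver: {sorted(unknown)}")
    if "tumor_start" in overrides and "bragg_to_edge" in overrides:
        raise ValueError("give either tumor_start or bragg_to_edge, not both")
    if "tumor_start" in overrides:
        ts = overrides["tumor_start"]
    else:
        ts = CLINICAL_BRAGG_DEPTH - overrides.get("bragg_to_edge", CLINICAL_BRAGG_TO_EDGE)
    liver, tumor = get_material("liver"), get_material("hepatic_tumor")
    L = CLINICAL_DOMAIN_LENGTH + 0.012
    layers = (
        Layer(liver, 0.0, ts),
        Layer(tumor, ts, ts + CLINICAL_TUMOR_LENGTH),
        Layer(liver, ts + CLINICAL_TUMOR_LENGTH, L),
    )
    mode = overrides.get("mode", "2d")
    if mode == "2d":
        # coarsened clinical grid: the analysed band (< 0.5 MHz, wavelengths
        # > 3 mm) tolerates 100 µm axial / 400 µm lateral spacing, which keeps
        # the 29 cm domain tractable on one CPU
        grid = GridSpec(
            extent=(0.0, CLINICAL_DOMAIN_LENGTH),
            axial_spacing=100e-6,
            lateral_extent=(-19.2e-3, 19.2e-3),
            lateral_spacing=400e-6,
        )
    else:
        grid = GridSpec(extent=(0.0, CLINICAL_DOMAIN_LENGTH), axial_spacing=50e-6)
    sensor = SensorSpec(position=overrides.get("sensor_position", CLINICAL_SENSOR_POSITION), geometry="point")
    return Scenario(
        name="clinical_liver",
        layers=layers,
        sensor=sensor,
        grid=grid,
        temperature=overrides.get("temperature", 37.0),
    )


PRESETS = ("tandem22", "tandem22_ripple", "clinical_liver")


def build_scenario(preset: str, overrides: dict | None = None) -> Scenario:
    """Build one of the three study scenarios.

    ``tandem22`` / ``tandem22_ripple``: 22 MeV water-tank setup -- titanium
    vacuum window, 6 cm air gap, 50 µm polyimide tank-entrance foil, water,
    contrast-agent phantom starting 1.6 mm past the tank entrance, disk
    sensor 36 mm from the entrance window on the beam axis.  The ripple
    variant shares the geometry; the spread-out beam is produced by the dose
    model's range-shift mixture.

    ``clinical_liver``: liver with an embedded 2 cm hepatic tumor whose
    proximal edge defaults to 14.49 mm upstream of the 130 MeV Bragg maximum,
    point sensor 27 cm from the phantom entrance, 1D on-axis grid.
    """
    overrides = dict(overrides or {})
    if preset in ("tandem22", "tandem22_ripple"):
        return _tandem_scenario(preset, overrides)
    if preset == "clinical_liver":
        return _clinical_scenario(overrides)
    raise KeyError(f"unknown preset {preset!r}; known: {PRESETS}")
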