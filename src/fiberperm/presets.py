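"""Packaged bundle presets: the simulated-bundle matrix.

Names encode configuration (O = orthogonal, A = angled 20 deg), fiber outer
diameter, wall thickness and pitch in micrometres.  The two reference
bundles (O_380_50_500, A_380_50_500) share a porosity of 0.40; the pitch
variants change porosity at fixed fiber size, and the small-fiber variants
keep porosity 0.40 at smaller diameters.
"""

from __future__ import annotations

from .geometry import BundleLayout, FiberSpec, UnitCell, build_unit_cell

__all__ = ["PRESETS", "PRESET_DIRECTIONS", "build_preset", "preset_names"]

PRESETS: dict = {
    "O_380_50_500": (FiberSpec(380, 50), BundleLayout("orthogonal", 500)),
    "A_380_50_500": (FiberSpec(380, 50), BundleLayout("angled", 500, 20.0)),
    "O_380_50_450": (FiberSpec(380, 50), BundleLayout("orthogonal", 450)),
    "O_380_50_550": (FiberSpec(380, 50), BundleLayout("orthogonal", 550)),
    "O_200_25_263": (FiberSpec(200, 25), BundleLayout("orthogonal", 263)),
    "O_300_25_395": (FiberSpec(300, 25), BundleLayout("orthogonal", 395)),
}

#: Flow directions of interest per preset: the reference bundles get the
#: full anisotropy set, the parameter-variation bundles the main (Z)
#: direction only.
PRESET_DIRECTIONS: dict = {
    "O_380_50_500": ("z", "x"),
    "A_380_50_500": ("x", "y", "z"),
    "O_380_50_450": ("z",),
    "O_380_50_550": ("z",),
    "O_200_25_263": ("z",),
    "O_300_25_395": ("z",),
}


def preset_names() -> list:
    return list(PRESETS)


def build_preset(name: str) -> UnitCell:
    """Undeformed unit cell of a named preset."""
    try:
        spec, layout = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESETS)}"
        ) from None
    return build_unit_cell(spec, layout)
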