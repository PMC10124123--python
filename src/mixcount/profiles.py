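"""Optics, chamber, staining, and counting-parameter configuration.

This module holds the small, validated data model everything else is built
on: the camera/chamber geometry that converts a per-field object count into
a volume (and hence a concentration), the staining plan that records how far
the original sample was diluted before it reached the chamber, and the
per-channel counting parameter sets (diameter gate, roundness gate,
fluorescent threshold, decluster factor).

Built-in parameter sets are provided for the four instrument configurations
used by the validated counting method (yeast AO/PI monoculture channels 1
and 2, SYTO BC bacteria monoculture, and mixed-mode yeast/bacteria size
gates), plus the two disposable counting chambers (SD100, SD025).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "OpticsConfig",
    "ChamberSpec",
    "StainingPlan",
    "CountingProfile",
    "UnknownProfileError",
    "UnknownChamberError",
    "UnknownStainingError",
    "builtin_profile",
    "builtin_chamber",
    "builtin_staining",
    "BUILTIN_PROFILES",
    "BUILTIN_CHAMBERS",
    "BUILTIN_STAINING",
    "dump_config",
    "load_config",
    "DEFAULT_OPTICS",
]

#: Valid meanings a channel can carry in a staining plan.
CHANNEL_ROLES = ("total", "dead", "yeast", "bacteria")


class UnknownProfileError(ValueError):
    """Raised when a counting-profile name is not a known built-in."""


class UnknownChamberError(ValueError):
    """Raised when a chamber name is not a known built-in."""


class UnknownStainingError(ValueError):
    """Raised when a staining-plan name is not a known built-in."""


@dataclass(frozen=True)
class OpticsConfig:
    """Imaging geometry of the instrument.

    Attributes
    ----------
    pixel_area : float
        Sample-plane area imaged by one pixel, in square micrometers.
        The 10X configuration images roughly 0.5 um^2 per pixel.
    bit_depth : int
        Intensity bit depth of the acquired grayscale images.
    fields_per_sample : int
        Number of distinct chamber areas imaged per loaded sample.
    """

    pixel_area: float = 0.5
    bit_depth: int = 16
    fields_per_sample: int = 4

    def __post_init__(self) -> None:
        if not self.pixel_area > 0:
            raise ValueError(f"pixel_area must be > 0, got {self.pixel_area}")
        if self.bit_depth < 1:
            raise ValueError(f"bit_depth must be >= 1, got {self.bit_depth}")
        if self.fields_per_sample < 1:
            raise ValueError(
                f"fields_per_sample must be >= 1, got {self.fields_per_sample}"
            )

    @property
    def pixel_side_um(self) -> float:
        """Side length of one (square) pixel in micrometers."""
        return math.sqrt(self.pixel_area)

    @property
    def full_scale(self) -> int:
        """Maximum representable intensity value."""
        return 2**self.bit_depth - 1


DEFAULT_OPTICS = OpticsConfig()


@dataclass(frozen=True)
class ChamberSpec:
    """A fixed-depth disposable counting chamber.

    ``field_area_um2 * depth_um`` is the analysis volume per imaged field in
    cubic micrometers; division by 1e12 converts to milliliters.  All
    concentration arithmetic reads the geometry from here — nothing is
    hard-coded downstream.
    """

    name: str
    depth_um: float
    field_area_um2: float = 1.0e6

    def __post_init__(self) -> None:
        if not self.depth_um > 0:
            raise ValueError(f"depth_um must be > 0, got {self.depth_um}")
        if not self.field_area_um2 > 0:
            raise ValueError(
                f"field_area_um2 must be > 0, got {self.field_area_um2}"
            )

    @property
    def volume_per_field_ml(self) -> float:
        """Analysis volume of one imaged field, in mL."""
        return self.field_area_um2 * self.depth_um * 1e-12

    def with_field_area(self, field_area_um2: float) -> "ChamberSpec":
        return replace(self, field_area_um2=field_area_um2)


@dataclass(frozen=True)
class StainingPlan:
    """How a sample was diluted and which channel sees which population.

    ``overall_dilution_factor`` is the fold-dilution of the *original*
    sample by the time it sits in the chamber (dilution buffer plus dye
    additions, composed multiplicatively).  ``channel_roles`` maps a channel
    label (e.g. ``"FL1"``) to what that channel's image contains: ``total``
    (all cells), ``dead`` (membrane-compromised cells only), or one of the
    size-separated populations ``yeast`` / ``bacteria``.
    """

    name: str
    overall_dilution_factor: float
    channel_roles: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.overall_dilution_factor >= 1:
            raise ValueError(
                "overall_dilution_factor must be >= 1, got "
                f"{self.overall_dilution_factor}"
            )
        if not self.channel_roles:
            raise ValueError("channel_roles must be non-empty")
        roles = set(self.channel_roles.values())
        unknown = roles - set(CHANNEL_ROLES)
        if unknown:
            raise ValueError(
                f"unknown channel roles {sorted(unknown)}; "
                f"valid roles are {CHANNEL_ROLES}"
            )
        if "dead" in roles and "total" not in roles:
            raise ValueError(
                "a 'dead' channel is only meaningful alongside a 'total' channel"
            )
        # freeze the mapping so the dataclass stays hashable-by-value
        object.__setattr__(self, "channel_roles", dict(self.channel_roles))

    @property
    def roles(self) -> set[str]:
        return set(self.channel_roles.values())


@dataclass(frozen=True)
class CountingProfile:
    """One channel's detection and filtering parameter set.

    The diameter gate is applied to the equivalent diameter (the diameter of
    the circle with the object's area), the roundness gate to the
    isoperimetric ratio 4*pi*A/P^2, the fluorescent threshold to the
    background-subtracted dynamic range (percent), and the decluster factor
    to the splitting of touching-cell blobs (1.0 splits maximally, values
    near 0 never split).
    """

    diameter_min_um: float
    diameter_max_um: float
    roundness_min: float
    fluorescent_threshold: float
    decluster_factor: float

    def __post_init__(self) -> None:
        if not 0 < self.diameter_min_um < self.diameter_max_um:
            raise ValueError(
                "need 0 < diameter_min < diameter_max, got "
                f"({self.diameter_min_um}, {self.diameter_max_um})"
            )
        if not 0 <= self.roundness_min <= 1:
            raise ValueError(f"roundness_min must be in [0, 1], got {self.roundness_min}")
        if not self.fluorescent_threshold > 0:
            raise ValueError(
                f"fluorescent_threshold must be > 0, got {self.fluorescent_threshold}"
            )
        if not 0 < self.decluster_factor <= 1:
            raise ValueError(
                f"decluster_factor must be in (0, 1], got {self.decluster_factor}"
            )


# Built-in counting parameter sets, exactly as used by the validated method.
BUILTIN_PROFILES: dict[str, CountingProfile] = {
    # AO/PI yeast monoculture, channel 1 (total) and channel 2 (dead)
    "yeast_aopi_fl1": CountingProfile(2.0, 30.0, 0.00, 25.0, 0.90),
    "yeast_aopi_fl2": CountingProfile(2.0, 30.0, 0.00, 20.0, 0.90),
    # SYTO BC bacteria monoculture
    "bacteria_sytobc": CountingProfile(0.7, 40.0, 0.00, 10.0, 0.90),
    # mixed culture, size-exclusion gates on the shared green channel
    "mixed_yeast": CountingProfile(6.0, 50.0, 0.00, 8.0, 0.90),
    "mixed_bacteria": CountingProfile(0.5, 5.0, 0.00, 10.0, 0.90),
}

# Chamber depths are configurable; defaults follow the product naming
# (SD100 -> 100 um deep, SD025 -> 25 um deep).  The default field area is an
# internal convention — concentration math only needs count/volume
# consistency, which round-trip simulation tests pin down.
BUILTIN_CHAMBERS: dict[str, ChamberSpec] = {
    "SD100": ChamberSpec("SD100", depth_um=100.0),
    "SD025": ChamberSpec("SD025", depth_um=25.0),
}

BUILTIN_STAINING: dict[str, StainingPlan] = {
    # sample 1:1 into dilution buffer, then 1:1 into AO/PI -> 4x
    "yeast_aopi": StainingPlan(
        "yeast_aopi", 4.0, {"FL1": "total", "FL2": "dead"}
    ),
    # sample 1:1 into SYTO BC working stock -> 2x
    "bacteria_sytobc": StainingPlan("bacteria_sytobc", 2.0, {"FL1": "total"}),
    # sample 1:1 into the AO + SYTO BC mix -> 2x; both channels image the
    # same green band, so the simulator renders a single 'total' frame and
    # population assignment is purely by size downstream.
    "mixed_ao_sytobc": StainingPlan("mixed_ao_sytobc", 2.0, {"FL1": "total"}),
}


def builtin_profile(name: str) -> CountingProfile:
    """Return a built-in counting profile by name.

    Raises
    ------
    UnknownProfileError
        If ``name`` is not one of the built-in profile names.
    """
    try:
        return BUILTIN_PROFILES[name]
    except KeyError:
        raise UnknownProfileError(
            f"unknown counting profile {name!r}; "
            f"valid names: {sorted(BUILTIN_PROFILES)}"
        ) from None


def builtin_chamber(name: str) -> ChamberSpec:
    """Return a built-in chamber spec by name (``SD100`` or ``SD025``)."""
    try:
        return BUILTIN_CHAMBERS[name]
    except KeyError:
        raise UnknownChamberError(
            f"unknown chamber {name!r}; valid names: {sorted(BUILTIN_CHAMBERS)}"
        ) from None


def builtin_staining(name: str) -> StainingPlan:
    """Return a built-in staining plan by name."""
    try:
        return BUILTIN_STAINING[name]
    except KeyError:
        raise UnknownStainingError(
            f"unknown staining plan {name!r}; "
            f"valid names: {sorted(BUILTIN_STAINING)}"
        ) from None


# ---------------------------------------------------------------------------
# plain-text (YAML) serialization

_TYPE_TAGS = {
    "optics": OpticsConfig,
    "chamber": ChamberSpec,
    "staining": StainingPlan,
    "profile": CountingProfile,
}


def _to_plain(obj) -> dict:
    for tag, cls in _TYPE_TAGS.items():
        if isinstance(obj, cls):
            d = asdict(obj)
            d["kind"] = tag
            return d
    raise TypeError(f"cannot serialize object of type {type(obj).__name__}")


def _from_plain(d: Mapping) -> object:
    d = dict(d)
    kind = d.pop("kind")
    cls = _TYPE_TAGS[kind]
    return cls(**d)


def dump_config(objects: Mapping[str, object], path: str | Path) -> None:
    """Write a named collection of config objects to one YAML document."""
    doc = {name: _to_plain(obj) for name, obj in objects.items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_config(path: str | Path) -> dict[str, object]:
    """Read a YAML config document written by :func:`dump_config`."""
    doc = yaml.safe_load(Path(path).read_text())
    return {name: _from_plain(d) for name, d in doc.items()}
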