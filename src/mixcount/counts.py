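"""Population counts, concentrations, and viability.

Converts detected objects into per-population results: pooled raw counts
across the imaged fields, concentration of the *original* (undiluted)
sample via the chamber volume and dilution bookkeeping, the size-exclusion
dual count for mixed cultures, and AO/PI-style viability.

Counts are pooled over fields before conversion (identical expectation to
per-field averaging, lower variance).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

from .detect import (
    ConfigurationError,
    DetectedObject,
    ImageFrame,
    detect_frame,
    filter_objects,
)
from .profiles import ChamberSpec, CountingProfile, StainingPlan

log = logging.getLogger(__name__)

__all__ = [
    "CountResult",
    "counts_to_concentration",
    "count_population",
    "dual_count",
    "viability",
]


@dataclass
class CountResult:
    """Count and concentration of one population across a sample's fields."""

    population: str
    raw_count: int
    fields_used: int
    concentration: float  # cells/mL of the original undiluted sample
    chamber_concentration: float = 0.0  # cells/mL as loaded in the chamber
    viability: float | None = None
    spillover_count: int | None = None  # objects falling between the gates

    def __post_init__(self) -> None:
        if self.raw_count < 0 or self.concentration < 0:
            raise ValueError("raw_count and concentration must be >= 0")


def counts_to_concentration(
    raw_count: int,
    fields_used: int,
    chamber: ChamberSpec,
    staining: StainingPlan,
    extra_dilution: float = 1.0,
) -> float:
    """Concentration (cells/mL of the original sample) from a pooled count.

    ``raw_count / (fields_used * field_area * depth * 1e-12)`` gives the
    chamber-level concentration; multiplying by the staining plan's overall
    dilution factor and any extra upstream dilution undoes the dilutions.
    """
    if fields_used < 1:
        raise ValueError(f"fields_used must be >= 1, got {fields_used}")
    if extra_dilution < 1:
        raise ValueError(f"extra_dilution must be >= 1, got {extra_dilution}")
    if raw_count < 0:
        raise ValueError(f"raw_count must be >= 0, got {raw_count}")
    chamber_conc = raw_count / (fields_used * chamber.volume_per_field_ml)
    return chamber_conc * staining.overall_dilution_factor * extra_dilution


def _check_geometry(frames: Sequence[ImageFrame]) -> None:
    if not frames:
        return
    areas = {f.pixel_area for f in frames}
    if len(areas) > 1:
        raise ConfigurationError(
            f"frames mix pixel geometries: pixel areas {sorted(areas)}"
        )


def count_population(
    frames: Sequence[ImageFrame], profile: CountingProfile
) -> tuple[int, list[DetectedObject]]:
    """Run the full detection pipeline over a sample's frames.

    Returns the pooled raw count and the retained objects.  All frames must
    share the same pixel geometry.
    """
    _check_geometry(frames)
    objects: list[DetectedObject] = []
    for frame in frames:
        objects.extend(detect_frame(frame, profile))
    return len(objects), objects


def dual_count(
    frames: Sequence[ImageFrame],
    yeast_profile: CountingProfile,
    bacteria_profile: CountingProfile,
    chamber: ChamberSpec,
    staining: StainingPlan,
    extra_dilution: float = 1.0,
) -> tuple[CountResult, CountResult]:
    """Size-exclusion dual count of the same frames with two profiles.

    The frames are analyzed twice — once per parameter set — and objects
    are assigned to a population purely by the diameter gates, mirroring
    the two-channel single-band trick of the validated method.  Objects
    falling in the gap between the gates are reported in the spill-over
    diagnostic, counted by neither population.
    """
    if yeast_profile.diameter_min_um < bacteria_profile.diameter_max_um:
        warnings.warn(
            "diameter gates overlap: yeast gate starts at "
            f"{yeast_profile.diameter_min_um} um but bacteria gate extends to "
            f"{bacteria_profile.diameter_max_um} um; objects in the overlap "
            "will be counted twice",
            stacklevel=2,
        )
    _check_geometry(frames)
    n_fields = len(frames)
    yeast_raw, _ = count_population(frames, yeast_profile)
    # bacteria pass: keep the unfiltered objects so the spill-over diagnostic
    # (objects between the gates, counted by neither population) is free
    bacteria_raw = 0
    spill = 0
    lo = bacteria_profile.diameter_max_um
    hi = yeast_profile.diameter_min_um
    for frame in frames:
        unfiltered = detect_frame(frame, bacteria_profile, filtered=False)
        bacteria_raw += len(filter_objects(unfiltered, bacteria_profile))
        if hi > lo:
            spill += sum(
                1 for o in unfiltered if lo < o.equivalent_diameter_um < hi
            )
    if spill:
        log.info("%d object(s) fell between the size gates (%g-%g um)", spill, lo, hi)
    results = []
    for population, raw in (("yeast", yeast_raw), ("bacteria", bacteria_raw)):
        conc = counts_to_concentration(
            raw, n_fields, chamber, staining, extra_dilution
        )
        chamber_conc = raw / (n_fields * chamber.volume_per_field_ml)
        results.append(
            CountResult(
                population=population,
                raw_count=raw,
                fields_used=n_fields,
                concentration=conc,
                chamber_concentration=chamber_conc,
                spillover_count=spill,
            )
        )
    return results[0], results[1]


def viability(total: CountResult, dead: CountResult) -> float | None:
    """Viable fraction ``(total - dead) / total``.

    A dead count exceeding the total is clamped (with a warning); a zero
    total has no defined viability and is reported as absent.
    """
    if total.raw_count == 0:
        warnings.warn("zero total count: viability undefined", stacklevel=2)
        return None
    d = dead.raw_count
    if d > total.raw_count:
        warnings.warn(
            f"dead count {d} exceeds total {total.raw_count}; clamping",
            stacklevel=2,
        )
        d = total.raw_count
    return (total.raw_count - d) / total.raw_count
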