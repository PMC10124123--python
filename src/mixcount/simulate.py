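"""Synthetic counting-chamber micrographs with known ground truth.

Every experimental design the counting method was validated on can be
emulated here: monoculture titrations, constant-plus-titration mixtures,
ratio mixtures, chamber comparisons, and mixed-culture fermentation time
courses, each with paired simulated plate counts.

Per-field object counts follow a Poisson law whose mean is the
chamber-level concentration (original concentration divided by the staining
plan's overall dilution) times the analysis volume of one field.  Yeast are
rendered as filled disks, bacteria as capsule-shaped rods, both with 4x
supersampled anti-aliased edges so sub-pixel-wide rods survive at the
~0.71 um pixel pitch.  All randomness flows from explicit seeds; identical
arguments give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .detect import ImageFrame
from .profiles import ChamberSpec, OpticsConfig, StainingPlan, DEFAULT_OPTICS
from .stats import PlateCount

__all__ = [
    "SizeModel",
    "TruthObject",
    "FieldTruth",
    "GrowthScenario",
    "PeakedGrowth",
    "LogisticGrowth",
    "ConstantGrowth",
    "SimulatedSample",
    "sample_field_truth",
    "render_field",
    "simulate_experiment",
    "simulate_fermentation",
    "simulate_plate_counts",
    "DEFAULT_SIZES",
]

_SUPERSAMPLE = 4


@dataclass(frozen=True)
class SizeModel:
    """Size and brightness distributions for the two populations.

    Yeast diameters and bacterial rod dimensions are truncated normals
    within the stated bounds; peak intensities (fraction of full scale) are
    uniform.  Defaults keep the two size distributions well separated so
    the diameter gates discriminate cleanly.
    """

    yeast_diameter_mean_um: float = 7.5
    yeast_diameter_sd_um: float = 0.6
    yeast_diameter_bounds_um: tuple[float, float] = (4.0, 10.0)
    bacteria_width_mean_um: float = 1.0
    bacteria_width_sd_um: float = 0.12
    bacteria_width_bounds_um: tuple[float, float] = (0.7, 1.5)
    bacteria_length_mean_um: float = 2.4
    bacteria_length_sd_um: float = 0.4
    bacteria_length_bounds_um: tuple[float, float] = (1.5, 4.0)
    peak_intensity_range: tuple[float, float] = (0.6, 0.95)


DEFAULT_SIZES = SizeModel()


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    """Rejection-sampled truncated normal; exact and seed-stable."""
    if n == 0:
        return np.empty(0)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 8))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


@dataclass(frozen=True)
class TruthObject:
    """Ground truth for one simulated cell."""

    cls: Literal["yeast", "bacteria"]
    viability: Literal["live", "dead"]
    x_um: float
    y_um: float
    peak_intensity: float
    diameter_um: float | None = None  # yeast
    length_um: float | None = None  # bacteria
    width_um: float | None = None  # bacteria
    orientation_rad: float | None = None  # bacteria


@dataclass
class FieldTruth:
    """Ground-truth object list for one simulated chamber field."""

    objects: list[TruthObject]
    field_area_um2: float
    chamber: ChamberSpec
    staining: StainingPlan

    @property
    def side_um(self) -> float:
        return math.sqrt(self.field_area_um2)

    def count(self, cls: str | None = None, viability: str | None = None) -> int:
        return sum(
            1
            for o in self.objects
            if (cls is None or o.cls == cls)
            and (viability is None or o.viability == viability)
        )


def sample_field_truth(
    conc_yeast: float,
    conc_bacteria: float,
    chamber: ChamberSpec,
    staining: StainingPlan,
    dead_fraction: float = 0.0,
    seed: int | np.random.SeedSequence | None = None,
    *,
    rng: np.random.Generator | None = None,
    sizes: SizeModel = DEFAULT_SIZES,
    cluster_fraction: float = 0.0,
) -> FieldTruth:
    """Draw the ground truth of one field at given original concentrations.

    Object counts per class are Poisson with mean
    ``(concentration / overall_dilution_factor) * field_area * depth * 1e-12``;
    positions are uniform over the field; each object is independently
    labeled dead with probability ``dead_fraction``.  A nonzero
    ``cluster_fraction`` places that fraction of objects touching a
    previously placed object of the same class, to exercise declustering.
    """
    if conc_yeast < 0 or conc_bacteria < 0:
        raise ValueError("concentrations must be >= 0")
    if not 0 <= dead_fraction <= 1:
        raise ValueError(f"dead_fraction must be in [0, 1], got {dead_fraction}")
    if not 0 <= cluster_fraction <= 1:
        raise ValueError(f"cluster_fraction must be in [0, 1], got {cluster_fraction}")
    if rng is None:
        rng = np.random.default_rng(seed)
    vol_ml = chamber.volume_per_field_ml
    side = math.sqrt(chamber.field_area_um2)
    objects: list[TruthObject] = []
    for cls, conc in (("yeast", conc_yeast), ("bacteria", conc_bacteria)):
        mean = conc / staining.overall_dilution_factor * vol_ml
        n = int(rng.poisson(mean))
        if n == 0:
            continue
        xs = rng.uniform(0, side, n)
        ys = rng.uniform(0, side, n)
        dead = rng.uniform(size=n) < dead_fraction
        peaks = rng.uniform(*sizes.peak_intensity_range, n)
        if cls == "yeast":
            diam = _truncated_normal(
                rng,
                sizes.yeast_diameter_mean_um,
                sizes.yeast_diameter_sd_um,
                *sizes.yeast_diameter_bounds_um,
                n,
            )
        else:
            width = _truncated_normal(
                rng,
                sizes.bacteria_width_mean_um,
                sizes.bacteria_width_sd_um,
                *sizes.bacteria_width_bounds_um,
                n,
            )
            length = _truncated_normal(
                rng,
                sizes.bacteria_length_mean_um,
                sizes.bacteria_length_sd_um,
                *sizes.bacteria_length_bounds_um,
                n,
            )
            length = np.maximum(length, width)
            theta = rng.uniform(0, math.pi, n)
        cluster = rng.uniform(size=n) < cluster_fraction
        placed: list[TruthObject] = []
        for i in range(n):
            x, y = float(xs[i]), float(ys[i])
            if cluster[i] and placed:
                anchor = placed[int(rng.integers(len(placed)))]
                if cls == "yeast":
                    gap = 0.95 * (anchor.diameter_um + diam[i]) / 2.0
                else:
                    gap = 0.95 * (anchor.width_um + width[i]) / 2.0
                phi = float(rng.uniform(0, 2 * math.pi))
                x = min(max(anchor.x_um + gap * math.cos(phi), 0.0), side)
                y = min(max(anchor.y_um + gap * math.sin(phi), 0.0), side)
            common = dict(
                cls=cls,
                viability="dead" if dead[i] else "live",
                x_um=x,
                y_um=y,
                peak_intensity=float(peaks[i]),
            )
            if cls == "yeast":
                obj = TruthObject(**common, diameter_um=float(diam[i]))
            else:
                obj = TruthObject(
                    **common,
                    length_um=float(length[i]),
                    width_um=float(width[i]),
                    orientation_rad=float(theta[i]),
                )
            placed.append(obj)
        objects.extend(placed)
    return FieldTruth(objects, chamber.field_area_um2, chamber, staining)


# ---------------------------------------------------------------------------
# rendering


def _paint_object(canvas: np.ndarray, obj: TruthObject, side_px_um: float) -> None:
    """Render one object into the canvas (max-composited), anti-aliased.

    The object footprint is rasterized on a local 4x supersampled grid and
    box-downsampled, so edge pixels carry fractional coverage.
    """
    s = side_px_um
    h, w = canvas.shape
    xc, yc = obj.x_um / s, obj.y_um / s  # pixel coordinates (col, row)
    if obj.cls == "yeast":
        r_px = obj.diameter_um / 2.0 / s
        reach = r_px
    else:
        reach = (obj.length_um / 2.0) / s
    r0 = max(int(math.floor(yc - reach - 1)), 0)
    r1 = min(int(math.ceil(yc + reach + 2)), h)
    c0 = max(int(math.floor(xc - reach - 1)), 0)
    c1 = min(int(math.ceil(xc + reach + 2)), w)
    if r0 >= r1 or c0 >= c1:
        return
    ss = _SUPERSAMPLE
    sub = (np.arange((r1 - r0) * ss) + 0.5) / ss + r0
    rows = sub[:, None]
    sub = (np.arange((c1 - c0) * ss) + 0.5) / ss + c0
    cols = sub[None, :]
    if obj.cls == "yeast":
        inside = (rows - yc) ** 2 + (cols - xc) ** 2 <= r_px**2
    else:
        half_w = obj.width_um / 2.0 / s
        seg = max(obj.length_um - obj.width_um, 0.0) / 2.0 / s
        ux, uy = math.cos(obj.orientation_rad), math.sin(obj.orientation_rad)
        dx, dy = cols - xc, rows - yc
        t = np.clip(dx * ux + dy * uy, -seg, seg)
        inside = (dx - t * ux) ** 2 + (dy - t * uy) ** 2 <= half_w**2
    cov = inside.reshape(r1 - r0, ss, c1 - c0, ss).mean(axis=(1, 3))
    patch = canvas[r0:r1, c0:c1]
    np.maximum(patch, obj.peak_intensity * cov, out=patch)


_ROLE_FILTERS = {
    "total": lambda o: True,
    "dead": lambda o: o.viability == "dead",
    "yeast": lambda o: o.cls == "yeast",
    "bacteria": lambda o: o.cls == "bacteria",
}


def render_field(
    truth: FieldTruth,
    optics: OpticsConfig,
    channel_role: str,
    noise_sd: float = 0.01,
    background_level: float = 0.05,
    seed: int | np.random.SeedSequence | None = None,
    *,
    rng: np.random.Generator | None = None,
    frame_id: str = "",
) -> ImageFrame:
    """Render one channel of a field to a 16-bit grayscale frame.

    Only objects visible in ``channel_role`` are drawn: ``total`` renders
    everything, ``dead`` only dead cells, ``yeast``/``bacteria`` one class
    (both populations fluoresce in the same band; separation downstream is
    purely by size).  ``noise_sd`` and ``background_level`` are fractions
    of full scale.  Deterministic for a fixed seed.
    """
    if channel_role not in _ROLE_FILTERS:
        raise ValueError(f"unknown channel role {channel_role!r}")
    if channel_role not in truth.staining.roles:
        raise ValueError(
            f"role {channel_role!r} not in staining plan "
            f"{truth.staining.name!r} (roles: {sorted(truth.staining.roles)})"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    side_um = truth.side_um
    n_px = max(int(round(side_um / optics.pixel_side_um)), 1)
    canvas = np.zeros((n_px, n_px), dtype=np.float64)
    visible = _ROLE_FILTERS[channel_role]
    for obj in truth.objects:
        if visible(obj):
            _paint_object(canvas, obj, optics.pixel_side_um)
    img = canvas + background_level
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    full = optics.full_scale
    pixels = np.rint(img * full).astype(np.uint16 if optics.bit_depth <= 16 else np.uint32)
    return ImageFrame(
        pixels=pixels,
        pixel_area=optics.pixel_area,
        channel_role=channel_role,
        frame_id=frame_id,
        bit_depth=optics.bit_depth,
    )


# ---------------------------------------------------------------------------
# experiment designs


@dataclass
class SimulatedSample:
    """One sample of a simulated experiment: descriptor, frames, truths."""

    sample_id: str
    descriptor: dict
    frames: dict[str, list[ImageFrame]]  # role -> one frame per field
    truths: list[FieldTruth]


def _simulate_sample(
    sample_id: str,
    descriptor: dict,
    conc_yeast: float,
    conc_bacteria: float,
    chamber: ChamberSpec,
    staining: StainingPlan,
    optics: OpticsConfig,
    seed_seq: np.random.SeedSequence,
    *,
    dead_fraction: float,
    noise_sd: float,
    background_level: float,
    sizes: SizeModel,
    cluster_fraction: float,
    render_roles: Sequence[str],
) -> SimulatedSample:
    truths: list[FieldTruth] = []
    frames: dict[str, list[ImageFrame]] = {role: [] for role in render_roles}
    children = seed_seq.spawn(optics.fields_per_sample)
    for f, child in enumerate(children):
        sub = child.spawn(1 + len(render_roles))
        truth = sample_field_truth(
            conc_yeast,
            conc_bacteria,
            chamber,
            staining,
            dead_fraction=dead_fraction,
            rng=np.random.default_rng(sub[0]),
            sizes=sizes,
            cluster_fraction=cluster_fraction,
        )
        truths.append(truth)
        for r, role in enumerate(render_roles):
            frames[role].append(
                render_field(
                    truth,
                    optics,
                    role,
                    noise_sd=noise_sd,
                    background_level=background_level,
                    rng=np.random.default_rng(sub[1 + r]),
                    frame_id=f"{sample_id}_f{f}_{role}",
                )
            )
    return SimulatedSample(sample_id, descriptor, frames, truths)


def simulate_experiment(
    design: str,
    params: dict,
    chamber: ChamberSpec,
    staining: StainingPlan,
    optics: OpticsConfig = DEFAULT_OPTICS,
    replicates: int = 1,
    seed: int = 0,
    *,
    dead_fraction: float = 0.0,
    noise_sd: float = 0.005,
    background_level: float = 0.05,
    sizes: SizeModel = DEFAULT_SIZES,
    cluster_fraction: float = 0.0,
    render_roles: Sequence[str] | None = None,
) -> list[SimulatedSample]:
    """Simulate a full counting experiment with ground truth.

    Designs and their ``params``:

    - ``titration``: ``organism`` ("yeast"|"bacteria"), ``stock_conc``
      (cells/mL), ``fractions`` (dilution fractions).
    - ``constant_plus_titration``: ``titrated`` organism with
      ``stock_conc`` and ``fractions``, plus ``constant`` organism at
      ``constant_conc``.
    - ``ratio_mix``: ``yeast_stock``, ``bacteria_stock``, and
      ``percentages`` of yeast (bacteria take the complement).
    - ``chamber_comparison``: yeast ``stock_conc``, ``fractions``, and
      ``chambers`` (list of ChamberSpec) — the positional ``chamber``
      argument is ignored for this design.

    Every sample gets ``optics.fields_per_sample`` fields, each rendered in
    the requested roles (default: the unique roles of the staining plan).
    Descriptors carry the nominal dilution fraction and the true original
    concentrations for downstream regression against ground truth.
    """
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    specs: list[tuple[dict, float, float, ChamberSpec]] = []
    if design == "titration":
        fractions = list(params["fractions"])
        if not fractions:
            raise ValueError("empty dilution fraction list")
        organism = params["organism"]
        if organism not in ("yeast", "bacteria"):
            raise ValueError(f"unknown organism {organism!r}")
        stock = float(params["stock_conc"])
        for frac in fractions:
            cy = stock * frac if organism == "yeast" else 0.0
            cb = stock * frac if organism == "bacteria" else 0.0
            specs.append(
                ({"design": design, "organism": organism, "fraction": frac}, cy, cb, chamber)
            )
    elif design == "constant_plus_titration":
        fractions = list(params["fractions"])
        if not fractions:
            raise ValueError("empty dilution fraction list")
        titrated = params["titrated"]
        if titrated not in ("yeast", "bacteria"):
            raise ValueError(f"unknown organism {titrated!r}")
        stock = float(params["stock_conc"])
        const_conc = float(params["constant_conc"])
        for frac in fractions:
            if titrated == "bacteria":
                cy, cb = const_conc, stock * frac
            else:
                cy, cb = stock * frac, const_conc
            specs.append(
                ({"design": design, "titrated": titrated, "fraction": frac}, cy, cb, chamber)
            )
    elif design == "ratio_mix":
        percentages = list(params["percentages"])
        if not percentages:
            raise ValueError("empty percentage list")
        ys = float(params["yeast_stock"])
        bs = float(params["bacteria_stock"])
        for pct in percentages:
            if not 0 <= pct <= 100:
                raise ValueError(f"percentage must be in [0, 100], got {pct}")
            cy = ys * pct / 100.0
            cb = bs * (100.0 - pct) / 100.0
            specs.append(
                ({"design": design, "yeast_percent": pct}, cy, cb, chamber)
            )
    elif design == "chamber_comparison":
        fractions = list(params["fractions"])
        if not fractions:
            raise ValueError("empty dilution fraction list")
        stock = float(params["stock_conc"])
        for cham in params["chambers"]:
            for frac in fractions:
                specs.append(
                    (
                        {"design": design, "chamber": cham.name, "fraction": frac},
                        stock * frac,
                        0.0,
                        cham,
                    )
                )
    else:
        raise ValueError(f"unknown design {design!r}")

    if render_roles is None:
        render_roles = sorted(staining.roles)
    root = np.random.SeedSequence(seed)
    sample_seeds = root.spawn(len(specs) * replicates)
    out: list[SimulatedSample] = []
    i = 0
    for desc, cy, cb, cham in specs:
        for rep in range(replicates):
            descriptor = dict(desc)
            descriptor.update(
                rep=rep,
                conc_yeast=cy,
                conc_bacteria=cb,
                chamber=cham.name,
                staining=staining.name,
            )
            tag = "_".join(
                f"{k}{v}" for k, v in desc.items() if k != "design"
            ).replace(" ", "")
            sample_id = f"{design}_{tag}_r{rep}"
            out.append(
                _simulate_sample(
                    sample_id,
                    descriptor,
                    cy,
                    cb,
                    cham,
                    staining,
                    optics,
                    sample_seeds[i],
                    dead_fraction=dead_fraction,
                    noise_sd=noise_sd,
                    background_level=background_level,
                    sizes=sizes,
                    cluster_fraction=cluster_fraction,
                    render_roles=render_roles,
                )
            )
            i += 1
    return out


# ---------------------------------------------------------------------------
# growth trajectories and fermentation


@dataclass(frozen=True)
class PeakedGrowth:
    """Exponential rise to a peak followed by exponential decline."""

    c0: float
    peak: float
    t_peak_hr: float
    decline_rate_per_hr: float

    def concentration(self, t_hr: float) -> float:
        if t_hr <= self.t_peak_hr:
            if self.t_peak_hr == 0 or self.c0 == self.peak:
                return self.peak if t_hr >= self.t_peak_hr else self.c0
            return self.c0 * (self.peak / self.c0) ** (t_hr / self.t_peak_hr)
        return self.peak * math.exp(-self.decline_rate_per_hr * (t_hr - self.t_peak_hr))


@dataclass(frozen=True)
class LogisticGrowth:
    """Logistic rise from ``c0`` to a ``plateau`` carrying capacity."""

    c0: float
    plateau: float
    rate_per_hr: float

    def concentration(self, t_hr: float) -> float:
        e = math.exp(self.rate_per_hr * t_hr)
        return self.plateau * self.c0 * e / (self.plateau + self.c0 * (e - 1.0))


@dataclass(frozen=True)
class ConstantGrowth:
    c0: float

    def concentration(self, t_hr: float) -> float:
        return self.c0


@dataclass(frozen=True)
class GrowthScenario:
    """Per-organism concentration trajectories plus the sampling schedule."""

    yeast: PeakedGrowth | LogisticGrowth | ConstantGrowth
    bacteria: PeakedGrowth | LogisticGrowth | ConstantGrowth
    times_hr: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 12.0, 24.0, 48.0)

    def __post_init__(self) -> None:
        for t in self.times_hr:
            if not self.yeast.concentration(t) > 0:
                raise ValueError(f"yeast concentration not positive at t={t}")
            if not self.bacteria.concentration(t) > 0:
                raise ValueError(f"bacteria concentration not positive at t={t}")


def default_fermentation_scenario() -> GrowthScenario:
    """A sour-beer-style mixed fermentation: yeast peak at 9 hr, bacteria
    logistic plateau after ~12 hr."""
    yeast = PeakedGrowth(
        c0=2.0e6,
        peak=1.82e7,
        t_peak_hr=9.0,
        decline_rate_per_hr=math.log(1.82e7 / 3.0e6) / 39.0,
    )
    bacteria = LogisticGrowth(c0=1.48e8, plateau=3.55e8, rate_per_hr=0.4)
    return GrowthScenario(yeast=yeast, bacteria=bacteria)


def simulate_fermentation(
    scenario: GrowthScenario,
    chamber: ChamberSpec,
    staining: StainingPlan,
    seed: int = 0,
    optics: OpticsConfig = DEFAULT_OPTICS,
    *,
    replicates: int = 4,
    extra_dilution: float = 10.0,
    trials: int = 1,
    noise_sd: float = 0.005,
    background_level: float = 0.05,
    sizes: SizeModel = DEFAULT_SIZES,
    render_roles: Sequence[str] | None = None,
) -> list[SimulatedSample]:
    """Simulate the time-course sampling of a mixed-culture fermentation.

    At every sampling time the culture is diluted ``extra_dilution``-fold
    (the at-sampling dilution, on top of the staining dilution) and imaged
    with ``replicates`` independent chamber loads per trial.  Descriptors
    carry trial, time, and the true concentrations.
    """
    if render_roles is None:
        render_roles = sorted(staining.roles)
    root = np.random.SeedSequence(seed)
    seeds = root.spawn(trials * len(scenario.times_hr) * replicates)
    out: list[SimulatedSample] = []
    i = 0
    for trial in range(1, trials + 1):
        for t in scenario.times_hr:
            cy = scenario.yeast.concentration(t) / extra_dilution
            cb = scenario.bacteria.concentration(t) / extra_dilution
            for rep in range(replicates):
                sample_id = f"ferm_T{trial}_t{t:g}_r{rep}"
                descriptor = {
                    "design": "fermentation",
                    "trial": trial,
                    "time_hr": t,
                    "rep": rep,
                    # concentrations of the diluted (as-imaged) sample;
                    # extra_dilution is undone downstream
                    "conc_yeast": cy,
                    "conc_bacteria": cb,
                    "true_yeast": scenario.yeast.concentration(t),
                    "true_bacteria": scenario.bacteria.concentration(t),
                    "extra_dilution": extra_dilution,
                    "chamber": chamber.name,
                    "staining": staining.name,
                }
                out.append(
                    _simulate_sample(
                        sample_id,
                        descriptor,
                        cy,
                        cb,
                        chamber,
                        staining,
                        optics,
                        seeds[i],
                        dead_fraction=0.0,
                        noise_sd=noise_sd,
                        background_level=background_level,
                        sizes=sizes,
                        cluster_fraction=0.0,
                        render_roles=render_roles,
                    )
                )
                i += 1
    return out


# ---------------------------------------------------------------------------
# simulated plating


def simulate_plate_counts(
    true_conc: float,
    dilution_exponents: Sequence[int],
    plated_volume_ml: float,
    plates_per_dilution: int,
    seed: int | np.random.SeedSequence | None = None,
    *,
    rng: np.random.Generator | None = None,
    sample_id: str = "sim",
    medium: str = "",
) -> list[PlateCount]:
    """Simulate a serial-dilution plating of a sample.

    Colony counts are Poisson with mean
    ``true_conc * 10^exponent * plated_volume`` per plate.
    """
    if true_conc < 0:
        raise ValueError(f"true_conc must be >= 0, got {true_conc}")
    if not plated_volume_ml > 0:
        raise ValueError(f"plated_volume_ml must be > 0, got {plated_volume_ml}")
    if plates_per_dilution < 1:
        raise ValueError("plates_per_dilution must be >= 1")
    for e in dilution_exponents:
        if e > 0:
            raise ValueError(
                f"dilution exponents must be <= 0 (dilutions only), got {e}"
            )
    if rng is None:
        rng = np.random.default_rng(seed)
    out: list[PlateCount] = []
    for e in dilution_exponents:
        mean = true_conc * 10.0**e * plated_volume_ml
        for p in range(plates_per_dilution):
            out.append(
                PlateCount(
                    sample_id=sample_id,
                    dilution_exponent=int(e),
                    plated_volume_ml=plated_volume_ml,
                    colonies=int(rng.poisson(mean)),
                    medium=medium,
                )
            )
    return out
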