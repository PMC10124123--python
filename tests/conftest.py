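import numpy as np
import pytest

from mixcount.detect import ImageFrame
from mixcount.profiles import (
    OpticsConfig,
    StainingPlan,
    builtin_chamber,
    builtin_profile,
    builtin_staining,
)
from mixcount.simulate import (
    DEFAULT_SIZES,
    FieldTruth,
    SizeModel,
    TruthObject,
    render_field,
)


@pytest.fixture(scope="session")
def optics():
    return OpticsConfig()


@pytest.fixture(scope="session")
def sd025():
    return builtin_chamber("SD025")


@pytest.fixture(scope="session")
def sd025_small():
    """SD025 with a small 0.01 mm^2 field: fast to render and detect."""
    return builtin_chamber("SD025").with_field_area(1e4)


@pytest.fixture(scope="session")
def mixed_plan():
    return builtin_staining("mixed_ao_sytobc")


@pytest.fixture(scope="session")
def aopi_plan():
    return builtin_staining("yeast_aopi")


@pytest.fixture(scope="session")
def sytobc_plan():
    return builtin_staining("bacteria_sytobc")


@pytest.fixture(scope="session")
def yeast_profile():
    return builtin_profile("mixed_yeast")


@pytest.fixture(scope="session")
def bacteria_profile():
    return builtin_profile("mixed_bacteria")


def make_disk(x, y, diameter=7.5, peak=0.8):
    return TruthObject(
        cls="yeast", viability="live", x_um=x, y_um=y,
        peak_intensity=peak, diameter_um=diameter,
    )


def make_rod(x, y, theta=0.0, length=2.4, width=1.0, peak=0.8):
    return TruthObject(
        cls="bacteria", viability="live", x_um=x, y_um=y,
        peak_intensity=peak, length_um=length, width_um=width,
        orientation_rad=theta,
    )


@pytest.fixture(scope="session")
def make_frame(optics, sd025_small, mixed_plan):
    """Render a list of truth objects into a single frame."""

    def _make(objects, *, noise_sd=0.0, background=0.05, seed=7,
              chamber=None, role="total"):
        chamber = chamber or sd025_small
        truth = FieldTruth(list(objects), chamber.field_area_um2, chamber, mixed_plan)
        return render_field(
            truth, optics, role, noise_sd=noise_sd,
            background_level=background, seed=seed,
        )

    return _make


def uniform_frame(value, shape=(32, 32), pixel_area=0.5):
    return ImageFrame(
        pixels=np.full(shape, value, dtype=np.uint16), pixel_area=pixel_area
    )
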