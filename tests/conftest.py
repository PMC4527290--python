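"""Shared fixtures: small rendered scenes reused across test modules."""

import warnings

import pytest

from patchdyn import (
    CellGeometry,
    EventSet,
    ImagingModel,
    PatchEvent,
    make_genotype_preset,
    render_movie,
    simulate_events,
)

warnings.filterwarnings("ignore", category=FutureWarning)


def manual_patch(x_px, y_px, birth=0.0, assembly=8.0, disassembly=8.0,
                 molecules=900.0, internalizes=False, query_amplitude=0.0,
                 pixel_size=0.16):
    """A hand-placed patch event at pixel coordinates (unit inward normal +y)."""
    return PatchEvent(
        birth_time=birth, assembly_time=assembly, disassembly_time=disassembly,
        peak_molecules=molecules,
        cortex_position=(x_px * pixel_size, y_px * pixel_size),
        inward_normal=(0.0, 1.0), internalizes=internalizes,
        query_amplitude=query_amplitude,
    )


def manual_events(patches, cell=None, eisosomes=(), puncta=()):
    return EventSet(cell=cell or CellGeometry(), patches=list(patches),
                    eisosomes=list(eisosomes), puncta=list(puncta), seed=0)


@pytest.fixture(scope="session")
def imaging():
    return ImagingModel()


@pytest.fixture(scope="session")
def imaging_long():
    return ImagingModel(n_frames=61)


@pytest.fixture(scope="session")
def wt_scene(imaging_long):
    """One WT cell: (events, movie) with default noise."""
    preset = make_genotype_preset("WT")
    events = simulate_events(preset, imaging=imaging_long, seed=310)
    movie = render_movie(events, imaging_long, seed=311)
    return events, movie
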