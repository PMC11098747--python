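import numpy as np
import pytest

from histoshell import (
    CellRecord,
    SectionOutline,
    SimulationSpec,
    SpecimenMap,
    simulate_specimen,
)


def square_section(section_id="s0", side=100.0, z_l=-10.0, z_u=10.0,
                   origin=(0.0, 0.0)):
    x0, y0 = origin
    return SectionOutline(
        section_id,
        [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)],
        z_l, z_u)


def star_polygon(rng, n_vertices=10, scale=100.0, center=(0.0, 0.0),
                 irregularity=0.6):
    """Random star-shaped (hence simple) polygon, possibly non-convex."""
    base = (np.arange(n_vertices) + rng.uniform(0.05, 0.95, n_vertices))
    theta = 2 * np.pi * base / n_vertices  # strictly increasing angles
    radii = scale * rng.uniform(1 - irregularity, 1 + irregularity, n_vertices)
    x = center[0] + radii * np.cos(theta)
    y = center[1] + radii * np.sin(theta)
    return list(zip(x.tolist(), y.tolist()))


@pytest.fixture
def square_specimen():
    """One 100×100 µm square section, thickness 20, a handful of cells."""
    sec = square_section()
    cells = [
        CellRecord("s0", 50.0, 50.0, "WT", {"Ki67": True}),
        CellRecord("s0", 10.0, 10.0, "WT"),
        CellRecord("s0", 90.0, 90.0, "HD", {"TUNEL": True}),
    ]
    return SpecimenMap("sq", [sec], cells, injection_site=(50.0, 50.0, 0.0),
                       thickness=20.0, spacing=160.0)


@pytest.fixture(scope="session")
def default_chimera():
    """One full-size synthetic chimera at generator defaults (shared)."""
    spec = SimulationSpec(seed=7)
    s, truth = simulate_specimen(spec)
    return spec, s, truth


@pytest.fixture(scope="session")
def small_chimera():
    """Cheap specimen for I/O and CLI tests (fewer sections, sparse)."""
    spec = SimulationSpec(seed=11, n_sections=5, lambda_resident=2e-6,
                          lambda_invader=2e-6, R_front=400.0)
    s, truth = simulate_specimen(spec)
    return spec, s, truth
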