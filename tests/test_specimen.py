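"""Specimen model, validation, and on-disk round-tripping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histoshell import (
    CellRecord,
    SectionOutline,
    SpecimenIOError,
    SpecimenMap,
    SpecimenParseError,
    SpecimenValidationError,
    parse_section_filter,
    read_specimen,
    validate_specimen,
    write_specimen,
)
from conftest import square_section, star_polygon


def test_write_read_round_trip(square_specimen, tmp_path):
    write_specimen(square_specimen, tmp_path / "sq")
    back = read_specimen(tmp_path / "sq")
    assert back == square_specimen


def test_write_is_byte_deterministic(square_specimen, tmp_path):
    p1 = write_specimen(square_specimen, tmp_path / "a")
    p2 = write_specimen(square_specimen, tmp_path / "b")
    for name in ("specimen.json", "sections.csv", "markers.csv"):
        assert (p1 / name).read_bytes() == (p2 / name).read_bytes()


def test_zero_cell_specimen_round_trips(tmp_path):
    s = SpecimenMap("empty", [square_section()], [], thickness=20.0)
    write_specimen(s, tmp_path / "e")
    back = read_specimen(tmp_path / "e")
    assert back.cells == [] and back == s


def test_outline_orientation_normalized_ccw():
    cw = SectionOutline("s", [(0, 0), (0, 100), (100, 100), (100, 0)], 0, 20)
    ccw = SectionOutline("s", [(0, 0), (100, 0), (100, 100), (0, 100)], 0, 20)

    def signed_area(v):
        return sum(x1 * y2 - x2 * y1
                   for (x1, y1), (x2, y2) in zip(v, v[1:] + v[:1])) / 2

    assert signed_area(cw.vertices) > 0 and signed_area(ccw.vertices) > 0
    # same cycle up to the starting vertex
    i = cw.vertices.index(ccw.vertices[0])
    assert cw.vertices[i:] + cw.vertices[:i] == ccw.vertices
    assert cw.area == pytest.approx(10000.0)


@pytest.mark.parametrize("mutate, code", [
    (lambda s: s.sections[0].vertices.__setitem__(
        slice(None), [(0.0, 0.0), (1.0, 1.0)]), "POLYGON_TOO_FEW_VERTICES"),
    (lambda s: s.cells.append(CellRecord("s99", 1, 1, "WT")), "UNKNOWN_SECTION"),
    (lambda s: setattr(s, "spacing", 10.0), "SECTIONS_OVERLAP"),
    (lambda s: setattr(s.sections[0], "z_u", s.sections[0].z_l), "BAD_SLAB"),
    (lambda s: setattr(s.sections[0], "z_u", s.sections[0].z_u + 1), "THICKNESS_MISMATCH"),
    (lambda s: s.sections[0].vertices.__setitem__(
        slice(None), [(0, 0), (100, 100), (100, 0), (0, 100)]), "POLYGON_NOT_SIMPLE"),
], ids=["few-vertices", "unknown-section", "overlapping-slabs", "flat-slab",
        "thickness-mismatch", "self-intersecting"])
def test_validation_errors(square_specimen, mutate, code):
    mutate(square_specimen)
    rep = validate_specimen(square_specimen)
    assert code in rep.error_codes()
    assert not rep.ok


def test_clean_specimen_has_no_findings(square_specimen):
    rep = validate_specimen(square_specimen)
    assert rep.ok and not rep.warnings


def test_marker_outside_outline_is_warning_not_error(square_specimen):
    square_specimen.cells.append(CellRecord("s0", 105.0, 50.0, "WT"))
    rep = validate_specimen(square_specimen)
    assert rep.ok
    assert "MARKER_OUTSIDE_OUTLINE" in rep.warning_codes()


def test_spacing_mismatch_detected():
    secs = [square_section("s0", z_l=0, z_u=20),
            square_section("s1", z_l=150, z_u=170)]
    s = SpecimenMap("m", secs, [], thickness=20.0, spacing=160.0)
    rep = validate_specimen(s)
    assert "SPACING_MISMATCH" in rep.error_codes()


def test_read_missing_file_names_it(tmp_path):
    with pytest.raises(SpecimenIOError, match="specimen.json"):
        read_specimen(tmp_path / "nowhere")


def test_read_bad_number_reports_row(square_specimen, tmp_path):
    root = write_specimen(square_specimen, tmp_path / "sq")
    text = (root / "markers.csv").read_text().splitlines()
    text[2] = text[2].replace("10.0", "ten", 1)
    (root / "markers.csv").write_text("\n".join(text) + "\n")
    with pytest.raises(SpecimenParseError) as err:
        read_specimen(root)
    assert err.value.row == 3


def test_read_invalid_specimen_raises_with_codes(square_specimen, tmp_path):
    root = write_specimen(square_specimen, tmp_path / "sq")
    lines = (root / "markers.csv").read_text().splitlines()
    lines.append("s99,WT,1.0,1.0,0,0,0,0,0")
    (root / "markers.csv").write_text("\n".join(lines) + "\n")
    with pytest.raises(SpecimenValidationError) as err:
        read_specimen(root)
    assert "UNKNOWN_SECTION" in {c for c, _, _ in err.value.report.errors}


def test_injection_site_on_section_uses_slab_midpoint(square_specimen, tmp_path):
    root = write_specimen(square_specimen, tmp_path / "sq")
    meta = (root / "specimen.json").read_text()
    meta = meta.replace('"injection_site": {',
                        '"injection_site": {"section_id": "s0", ', 1)
    import json
    data = json.loads(meta)
    del data["injection_site"]["z"]
    (root / "specimen.json").write_text(json.dumps(data))
    back = read_specimen(root)
    assert back.injection_site == (50.0, 50.0, 0.0)  # slab [-10, 10] midpoint


def test_section_transform_applied_at_load(square_specimen, tmp_path):
    square_specimen.metadata["section_transforms"] = {"s0": {"dx": 10.0, "dy": -5.0}}
    root = write_specimen(square_specimen, tmp_path / "sq")
    back = read_specimen(root)
    assert back.sections[0].vertices[0] == (10.0, -5.0)
    assert back.cells[0].x == 60.0 and back.cells[0].y == 45.0


def test_parse_section_filter_cadence():
    secs = [square_section(f"s{i}", z_l=i * 160.0, z_u=i * 160.0 + 20.0)
            for i in range(15)]
    keep = parse_section_filter("every:3", secs)
    assert keep == {"s0", "s3", "s6", "s9", "s12"}
    assert parse_section_filter("s1,s2", secs) == {"s1", "s2"}
    assert parse_section_filter(None, secs) == {f"s{i}" for i in range(15)}


@st.composite
def valid_specimens(draw):
    rng = np.random.default_rng(draw(st.integers(0, 2**31 - 1)))
    n_sections = draw(st.integers(1, 4))
    thickness, spacing = 20.0, 160.0
    sections = []
    for i in range(n_sections):
        poly = star_polygon(rng, n_vertices=draw(st.integers(4, 12)),
                            scale=200.0, irregularity=0.5)
        z_l = i * spacing
        sections.append(SectionOutline(f"s{i}", poly, z_l, z_l + thickness))
    cells = []
    for _ in range(draw(st.integers(0, 10))):
        sec = sections[int(rng.integers(n_sections))]
        cells.append(CellRecord(
            sec.section_id, float(rng.uniform(-300, 300)),
            float(rng.uniform(-300, 300)),
            draw(st.sampled_from(["WT", "HD"])),
            {"Ki67": bool(rng.integers(2))}))
    return SpecimenMap("prop", sections, cells,
                       injection_site=(0.0, 0.0, 10.0),
                       thickness=thickness, spacing=spacing)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(valid_specimens())
def test_round_trip_is_identity_on_valid_specimens(tmp_path_factory, s):
    """write ∘ read is the identity on any valid specimen."""
    root = tmp_path_factory.mktemp("rt")
    write_specimen(s, root)
    assert read_specimen(root) == s
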