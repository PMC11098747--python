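"""Domain model and on-disk layout for mapped serial-section specimens.

A *specimen* is the coordinate-level export of a 3D-reconstructed series of
sagittal sections: per-section striatal outline polygons (µm), per-section
cell markers with a population label and phenotype flags, an optional
injection-site reference point, and the acquisition geometry (section
thickness and spacing).  Section ``i`` occupies the axial slab
``[z_l, z_u] = [i * spacing, i * spacing + thickness]`` with the first
collected section at ``z_l = 0``; only relative spacing matters downstream,
so any affine shift of z is immaterial.

On-disk layout (one directory per specimen)::

    specimen.json   specimen_id, thickness_um, spacing_um,
                    injection_site {x,y,z} | null, metadata
    sections.csv    section_id,vertex_index,x_um,y_um,z_l_um,z_u_um
    markers.csv     section_id,population,x_um,y_um,ki67,tunel,olig2,gfap,hn

All files are UTF-8, comma-delimited, ``.`` decimal point, with mandatory
header rows.  Floats are written with ``repr`` (shortest round-trip form), so
write → read is the identity and byte output is deterministic.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import shapely
from shapely.geometry import Polygon

__all__ = [
    "FLAG_NAMES",
    "SectionOutline",
    "CellRecord",
    "SpecimenMap",
    "ValidationReport",
    "HistoshellError",
    "SpecimenIOError",
    "SpecimenParseError",
    "SpecimenValidationError",
    "read_specimen",
    "write_specimen",
    "validate_specimen",
]

#: Canonical phenotype flag labels, in marker-table column order.
FLAG_NAMES = ("Ki67", "TUNEL", "Olig2", "GFAP", "hN")
_FLAG_COLUMNS = ("ki67", "tunel", "olig2", "gfap", "hn")

_THICKNESS_TOL = 1e-9  # µm, per-section slab vs declared thickness
_SPACING_TOL = 1e-6  # µm, consecutive z_l differences vs declared spacing


class HistoshellError(Exception):
    """Base class for all package errors; carries a short machine code."""

    def __init__(self, code: str, message: str):
        super().__init__(f"{code}: {message}")
        self.code = code
        self.message = message


class SpecimenIOError(HistoshellError):
    pass


class SpecimenParseError(HistoshellError):
    def __init__(self, code: str, message: str, row: Optional[int] = None):
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(code, message)
        self.row = row


class SpecimenValidationError(HistoshellError):
    def __init__(self, report: "ValidationReport"):
        codes = sorted({c for c, _, _ in report.errors})
        super().__init__(
            "SPECIMEN_INVALID",
            f"specimen failed validation: {', '.join(codes)}",
        )
        self.report = report


def _signed_area(vertices) -> float:
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class SectionOutline:
    """One section's tissue outline plus its axial slab.

    The outline is a simple polygon (µm, in-plane); orientation is
    normalized counter-clockwise on construction.
    """

    section_id: str
    vertices: list  # ordered (x, y) tuples, µm
    z_l: float
    z_u: float

    def __post_init__(self) -> None:
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]
        if len(self.vertices) >= 3 and _signed_area(self.vertices) < 0:
            self.vertices = self.vertices[::-1]
        self.z_l = float(self.z_l)
        self.z_u = float(self.z_u)

    @property
    def thickness(self) -> float:
        return self.z_u - self.z_l

    @property
    def area(self) -> float:
        """Polygon area in µm² (shoelace)."""
        return abs(_signed_area(self.vertices))

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class CellRecord:
    """One mapped cell: in-plane position, population, phenotype flags.

    Depth within the slab is unknown by construction — the marker carries
    only (x, y) plus its section — which is exactly the information loss the
    uniform point-probability counting model handles.
    """

    section_id: str
    x: float
    y: float
    population: str
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = float(self.x)
        self.y = float(self.y)
        unknown = set(self.flags) - set(FLAG_NAMES)
        if unknown:
            raise SpecimenParseError(
                "UNKNOWN_FLAG", f"unknown phenotype flags {sorted(unknown)}"
            )
        self.flags = {name: bool(self.flags.get(name, False)) for name in FLAG_NAMES}


@dataclass
class SpecimenMap:
    """A whole reconstructed specimen."""

    specimen_id: str
    sections: list  # SectionOutline, strictly increasing z_l
    cells: list  # CellRecord
    injection_site: Optional[tuple] = None  # (x, y, z) µm
    thickness: float = 20.0
    spacing: float = 160.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.injection_site is not None:
            self.injection_site = tuple(float(c) for c in self.injection_site)
        self.thickness = float(self.thickness)
        self.spacing = float(self.spacing)

    def section_by_id(self, section_id: str) -> SectionOutline:
        for s in self.sections:
            if s.section_id == section_id:
                return s
        raise KeyError(section_id)

    def populations(self) -> list:
        seen: dict = {}
        for c in self.cells:
            seen.setdefault(c.population, None)
        return list(seen)


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)  # (code, message, locus)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def error_codes(self) -> set:
        return {c for c, _, _ in self.errors}

    def warning_codes(self) -> set:
        return {c for c, _, _ in self.warnings}


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_specimen(s: SpecimenMap) -> ValidationReport:
    """Check every structural invariant of a specimen.

    Returns a report; never raises.  Cells lying outside their section's
    outline are *warnings*, not errors: outlines alone define tissue volume,
    but stray markers usually indicate a mapping slip worth surfacing rather
    than silently deleting.
    """
    rep = ValidationReport()
    err = rep.errors.append
    warn = rep.warnings.append

    if not s.sections:
        err(("NO_SECTIONS", "specimen has no sections", s.specimen_id))

    ids = [sec.section_id for sec in s.sections]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        err(("DUPLICATE_SECTION_ID", f"duplicate section ids {dupes}", s.specimen_id))

    polys = {}
    for sec in s.sections:
        loc = sec.section_id
        if len(sec.vertices) < 3:
            err(("POLYGON_TOO_FEW_VERTICES",
                 f"outline has {len(sec.vertices)} vertices (need ≥3)", loc))
            continue
        if sec.z_u <= sec.z_l:
            err(("BAD_SLAB", f"z_u={sec.z_u} ≤ z_l={sec.z_l}", loc))
        elif abs(sec.thickness - s.thickness) > _THICKNESS_TOL:
            err(("THICKNESS_MISMATCH",
                 f"slab thickness {sec.thickness} != declared {s.thickness}", loc))
        poly = Polygon(sec.vertices)
        if not poly.is_valid:
            err(("POLYGON_NOT_SIMPLE", "outline polygon self-intersects", loc))
            continue
        if poly.area <= 0.0:
            err(("POLYGON_ZERO_AREA", "outline polygon has zero area", loc))
            continue
        polys[sec.section_id] = poly

    z_ls = [sec.z_l for sec in s.sections]
    if any(b <= a for a, b in zip(z_ls, z_ls[1:])):
        err(("SECTIONS_NOT_SORTED", "sections not in strictly increasing z_l order",
             s.specimen_id))
    else:
        for i, (a, b) in enumerate(zip(z_ls, z_ls[1:])):
            if abs((b - a) - s.spacing) > _SPACING_TOL:
                err(("SPACING_MISMATCH",
                     f"z_l step {b - a} != declared spacing {s.spacing}",
                     s.sections[i + 1].section_id))
        if s.spacing < s.thickness - _THICKNESS_TOL:
            err(("SECTIONS_OVERLAP",
                 f"spacing {s.spacing} < thickness {s.thickness}: slabs overlap",
                 s.specimen_id))

    # Markers: referential integrity, then vectorized containment per section.
    by_section: dict = {}
    for i, c in enumerate(s.cells):
        if c.section_id not in {sec.section_id for sec in s.sections}:
            err(("UNKNOWN_SECTION",
                 f"marker references unknown section {c.section_id!r}", f"marker[{i}]"))
        else:
            by_section.setdefault(c.section_id, []).append((i, c))
    for sid, items in by_section.items():
        poly = polys.get(sid)
        if poly is None:
            continue
        xs = np.array([c.x for _, c in items])
        ys = np.array([c.y for _, c in items])
        inside = shapely.contains_xy(poly, xs, ys) | shapely.contains_xy(
            poly.exterior.buffer(1e-6), xs, ys
        )
        for (i, c), ok in zip(items, inside):
            if not ok:
                warn(("MARKER_OUTSIDE_OUTLINE",
                      f"marker at ({c.x}, {c.y}) lies outside outline of {sid}",
                      f"marker[{i}]"))
    return rep


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    """Shortest exact decimal form; round-trips through float()."""
    return repr(float(x))


def _apply_transform(xy: tuple, tf: dict) -> tuple:
    """Optional per-section rigid in-plane transform (rotation about the
    origin by theta_deg, then translation by dx/dy), applied at load time.
    Registration itself (landmark alignment) is out of scope — it was done
    upstream; this only honours exported alignment corrections."""
    theta = math.radians(float(tf.get("theta_deg", 0.0)))
    dx = float(tf.get("dx", 0.0))
    dy = float(tf.get("dy", 0.0))
    x, y = xy
    if theta:
        x, y = x * math.cos(theta) - y * math.sin(theta), x * math.sin(theta) + y * math.cos(theta)
    return (x + dx, y + dy)


def write_specimen(s: SpecimenMap, root_path) -> Path:
    """Write a specimen directory; byte-deterministic for equal input."""
    rep = validate_specimen(s)
    if not rep.ok:
        raise SpecimenValidationError(rep)
    root = Path(root_path)
    try:
        root.mkdir(parents=True, exist_ok=True)
    except OSError as e:  # pragma: no cover - filesystem dependent
        raise SpecimenIOError("UNWRITABLE_PATH", f"cannot create {root}: {e}")

    meta = {
        "specimen_id": s.specimen_id,
        "thickness_um": s.thickness,
        "spacing_um": s.spacing,
        "injection_site": (
            None if s.injection_site is None
            else {"x": s.injection_site[0], "y": s.injection_site[1],
                  "z": s.injection_site[2]}
        ),
        "metadata": s.metadata,
    }
    (root / "specimen.json").write_text(
        json.dumps(meta, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )

    with open(root / "sections.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["section_id", "vertex_index", "x_um", "y_um", "z_l_um", "z_u_um"])
        for sec in s.sections:
            for j, (x, y) in enumerate(sec.vertices):
                w.writerow([sec.section_id, j, _fmt(x), _fmt(y),
                            _fmt(sec.z_l), _fmt(sec.z_u)])

    with open(root / "markers.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["section_id", "population", "x_um", "y_um", *(c for c in _FLAG_COLUMNS)])
        for c in s.cells:
            w.writerow([c.section_id, c.population, _fmt(c.x), _fmt(c.y),
                        *(int(c.flags[name]) for name in FLAG_NAMES)])
    return root


def _require_columns(header, required, path):
    missing = [c for c in required if c not in header]
    if missing:
        raise SpecimenParseError(
            "MISSING_COLUMN", f"{path}: missing columns {missing}", row=1
        )


def _read_csv_rows(path: Path):
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SpecimenParseError("EMPTY_FILE", f"{path} has no header", row=1)
        yield reader.fieldnames
        for i, row in enumerate(reader, start=2):
            yield i, row


def _parse_float(value, path, row, column) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SpecimenParseError(
            "BAD_NUMBER", f"{path}: cannot parse {column}={value!r}", row=row
        )


def read_specimen(root_path) -> SpecimenMap:
    """Load and validate a specimen directory.

    Raises :class:`SpecimenIOError` on missing files,
    :class:`SpecimenParseError` (with row number) on schema violations, and
    :class:`SpecimenValidationError` listing codes if invariants fail.
    """
    root = Path(root_path)
    for name in ("specimen.json", "sections.csv", "markers.csv"):
        if not (root / name).exists():
            raise SpecimenIOError("MISSING_FILE", f"{root / name} does not exist")

    try:
        meta = json.loads((root / "specimen.json").read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise SpecimenParseError("BAD_JSON", f"specimen.json: {e}")
    for key in ("specimen_id", "thickness_um", "spacing_um"):
        if key not in meta:
            raise SpecimenParseError("MISSING_KEY", f"specimen.json: missing {key!r}")

    transforms = (meta.get("metadata") or {}).get("section_transforms", {})

    # sections.csv → outlines, grouping consecutive rows by section_id and
    # ordering vertices by vertex_index.
    spath = root / "sections.csv"
    rows_by_section: dict = {}
    it = _read_csv_rows(spath)
    header = next(it)
    _require_columns(header, ["section_id", "vertex_index", "x_um", "y_um",
                              "z_l_um", "z_u_um"], spath)
    for rowno, row in it:
        sid = row["section_id"]
        entry = rows_by_section.setdefault(sid, {"verts": [], "z": None})
        vi = int(_parse_float(row["vertex_index"], spath, rowno, "vertex_index"))
        xy = (_parse_float(row["x_um"], spath, rowno, "x_um"),
              _parse_float(row["y_um"], spath, rowno, "y_um"))
        if sid in transforms:
            xy = _apply_transform(xy, transforms[sid])
        entry["verts"].append((vi, xy))
        z = (_parse_float(row["z_l_um"], spath, rowno, "z_l_um"),
             _parse_float(row["z_u_um"], spath, rowno, "z_u_um"))
        if entry["z"] is None:
            entry["z"] = z
        elif entry["z"] != z:
            raise SpecimenParseError(
                "INCONSISTENT_SLAB", f"{spath}: section {sid} has varying z bounds",
                row=rowno)

    sections = []
    for sid, entry in rows_by_section.items():
        verts = [xy for _, xy in sorted(entry["verts"], key=lambda t: t[0])]
        sections.append(SectionOutline(sid, verts, entry["z"][0], entry["z"][1]))
    sections.sort(key=lambda sec: sec.z_l)

    mpath = root / "markers.csv"
    cells = []
    it = _read_csv_rows(mpath)
    header = next(it)
    _require_columns(header, ["section_id", "population", "x_um", "y_um",
                              *_FLAG_COLUMNS], mpath)
    for rowno, row in it:
        xy = (_parse_float(row["x_um"], mpath, rowno, "x_um"),
              _parse_float(row["y_um"], mpath, rowno, "y_um"))
        if row["section_id"] in transforms:
            xy = _apply_transform(xy, transforms[row["section_id"]])
        flags = {}
        for name, col in zip(FLAG_NAMES, _FLAG_COLUMNS):
            raw = row[col]
            if raw not in ("0", "1"):
                raise SpecimenParseError(
                    "BAD_FLAG", f"{mpath}: {col}={raw!r} (must be 0 or 1)", row=rowno)
            flags[name] = raw == "1"
        cells.append(CellRecord(row["section_id"], xy[0], xy[1],
                                row["population"], flags))

    site = meta.get("injection_site")
    injection_site = None
    if site is not None:
        if "section_id" in site:
            # Site recorded on a section: z is the slab midpoint.
            sec = next((s for s in sections if s.section_id == site["section_id"]), None)
            if sec is None:
                raise SpecimenParseError(
                    "UNKNOWN_SECTION",
                    f"injection_site references unknown section {site['section_id']!r}")
            injection_site = (float(site["x"]), float(site["y"]),
                              0.5 * (sec.z_l + sec.z_u))
        else:
            injection_site = (float(site["x"]), float(site["y"]), float(site["z"]))

    s = SpecimenMap(
        specimen_id=str(meta["specimen_id"]),
        sections=sections,
        cells=cells,
        injection_site=injection_site,
        thickness=float(meta["thickness_um"]),
        spacing=float(meta["spacing_um"]),
        metadata=meta.get("metadata") or {},
    )
    rep = validate_specimen(s)
    if not rep.ok:
        raise SpecimenValidationError(rep)
    return s


def parse_section_filter(spec: Optional[str], sections: Iterable[SectionOutline]):
    """Translate a section-filter spec into a set of section ids.

    ``None`` keeps everything; ``"every:k"`` or ``"every:k:offset"`` keeps
    every k-th section (by z order) starting at ``offset`` — e.g. ``every:3``
    mirrors a 480 µm mapping cadence on 160 µm-spaced sections; a comma list
    of ids keeps exactly those.
    """
    sections = list(sections)
    if spec is None:
        return {s.section_id for s in sections}
    if spec.startswith("every:"):
        parts = spec.split(":")
        k = int(parts[1])
        offset = int(parts[2]) if len(parts) > 2 else 0
        if k < 1 or not (0 <= offset < k):
            raise HistoshellError("BAD_SECTION_FILTER", f"invalid filter {spec!r}")
        ordered = sorted(sections, key=lambda s: s.z_l)
        return {s.section_id for i, s in enumerate(ordered) if i % k == offset}
    wanted = {t.strip() for t in spec.split(",") if t.strip()}
    known = {s.section_id for s in sections}
    unknown = wanted - known
    if unknown:
        raise HistoshellError(
            "BAD_SECTION_FILTER", f"unknown section ids {sorted(unknown)}")
    return wanted
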