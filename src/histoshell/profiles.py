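"""Radial cell-density profiles around an injection site.

The central quantity is the per-shell density of each population,

    ρ_{a,b} = N_{a,b} / V_{a,b}

where N_{a,b} is the sum over cells of the fraction of each cell's uniform
depth-probability segment falling inside the spherical shell [a, b), and
V_{a,b} is the combined exact section volume inside the shell.  Shells are
taken in fixed radial increments (default 125 µm) out to a maximum analysis
radius (default 2 mm); shells containing no tissue are reported as
*undefined*, never as zero density, because a zero there would fabricate
signal at the profile's edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry
from .specimen import HistoshellError, SpecimenMap

__all__ = [
    "RadialProfile",
    "radial_counts",
    "radial_volumes",
    "radial_density_profile",
    "per_section_density",
    "control_reference_center",
    "crossover_radius",
    "write_profile_csv",
    "write_profile_json",
]

DEFAULT_DR = 125.0  # µm, shell increment
DEFAULT_R_MAX = 2000.0  # µm, analysis radius cap


@dataclass
class RadialProfile:
    """Per-shell fractional counts, volumes and densities per population.

    ``counts[pop][k]`` is N over shell [edges[k], edges[k+1]);
    ``outside[pop]`` accumulates each cell's probability mass beyond the
    outermost edge so count conservation stays checkable.  ``densities`` are
    NaN where ``defined`` is False (no tissue volume in the shell).
    """

    shell_edges: np.ndarray  # increasing radii, starts at 0
    counts: dict  # population -> array of N_{a,b}
    volumes: np.ndarray  # V_{a,b}, µm³
    densities: dict  # population -> array, NaN where undefined
    defined: np.ndarray  # bool per shell: tissue volume > 0
    outside: dict  # population -> probability mass beyond the last edge
    totals: dict  # population -> total cell count in the specimen
    center: tuple  # (x, y, z) µm
    r_max: float  # µm
    volume_err: np.ndarray = field(default=None)  # quadrature bounds per shell

    @property
    def n_shells(self) -> int:
        return len(self.shell_edges) - 1

    def shell_midpoints(self) -> np.ndarray:
        e = self.shell_edges
        return 0.5 * (e[:-1] + e[1:])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        e = self.shell_edges
        for pop in self.counts:
            for k in range(self.n_shells):
                rows.append({
                    "shell_a_um": e[k],
                    "shell_b_um": e[k + 1],
                    "population": pop,
                    "count": self.counts[pop][k],
                    "volume_um3": self.volumes[k],
                    "density_per_um3": self.densities[pop][k],
                    "defined": bool(self.defined[k]),
                })
        return pd.DataFrame(rows)


def _check_edges(shell_edges) -> np.ndarray:
    e = np.asarray(shell_edges, dtype=float)
    if e.ndim != 1 or len(e) < 2 or e[0] < 0.0 or np.any(np.diff(e) <= 0):
        raise HistoshellError(
            "BAD_SHELL_EDGES",
            "shell edges must be non-negative and strictly increasing")
    return e


def _population_cells(s: SpecimenMap, population: str):
    cells = [c for c in s.cells if c.population == population]
    if not cells and population not in s.populations():
        raise HistoshellError("UNKNOWN_POPULATION",
                              f"population {population!r} not in specimen")
    return cells


def radial_counts(s: SpecimenMap, population: str, center, shell_edges,
                  section_ids=None):
    """Fractional cell counts N_{a,b} of one population per shell.

    Each cell contributes the integral of its uniform depth probability over
    the shell; a cell straddling a shell boundary is split fractionally.
    Returns ``(counts, outside)`` where ``outside`` is the mass beyond the
    last edge.
    """
    edges = _check_edges(shell_edges)
    cells = _population_cells(s, population)
    counts = np.zeros(len(edges) - 1)
    outside = 0.0
    for sec in s.sections:
        if section_ids is not None and sec.section_id not in section_ids:
            continue
        here = [c for c in cells if c.section_id == sec.section_id]
        if not here:
            continue
        x = np.array([c.x for c in here])
        y = np.array([c.y for c in here])
        # cumulative fraction inside a sphere of each edge radius
        cum = np.stack([
            geometry.axial_overlap_fractions(x, y, sec.z_l, sec.z_u, center, r)
            for r in edges
        ])
        counts += np.clip(np.diff(cum, axis=0), 0.0, None).sum(axis=1)
        outside += float(np.sum(1.0 - cum[-1]))
    return counts, outside


def radial_volumes(s: SpecimenMap, center, shell_edges,
                   rel_tol: float = geometry.DEFAULT_REL_TOL,
                   section_ids=None):
    """Combined exact section volume V_{a,b} per shell (µm³).

    Evaluates each section's prism ∩ sphere volume once per edge radius and
    differences consecutive edges, so a full partition telescopes exactly to
    the total tissue volume.  Returns ``(volumes, err_bounds)``.
    """
    edges = _check_edges(shell_edges)
    volumes = np.zeros(len(edges) - 1)
    errs = np.zeros(len(edges) - 1)
    for sec in s.sections:
        if section_ids is not None and sec.section_id not in section_ids:
            continue
        vals = np.empty(len(edges))
        ebnd = np.empty(len(edges))
        for i, r in enumerate(edges):
            est = geometry.prism_sphere_volume(sec, geometry.Sphere(center, r),
                                               rel_tol)
            vals[i] = est.value
            ebnd[i] = est.abs_err_bound
        volumes += np.clip(np.diff(vals), 0.0, None)
        errs += ebnd[1:] + ebnd[:-1]
    return volumes, errs


def radial_density_profile(s: SpecimenMap, populations=None,
                           dr: float = DEFAULT_DR,
                           r_max: float = DEFAULT_R_MAX,
                           center=None,
                           rel_tol: float = geometry.DEFAULT_REL_TOL,
                           section_ids=None) -> RadialProfile:
    """Full radial density profile ρ_{a,b} = N_{a,b} / V_{a,b}.

    Shell edges are {0, dr, 2·dr, …, r_max} (the outer edge never exceeds
    r_max).  ``center`` defaults to the specimen's mapped injection site;
    ``section_ids`` restricts counting *and* volumes to a section subset
    (e.g. the every-third-section cadence used for proliferation mapping).
    """
    if center is None:
        if s.injection_site is None:
            raise HistoshellError(
                "NO_REFERENCE_CENTER",
                "specimen has no injection site and no center was given")
        center = s.injection_site
    center = tuple(float(c) for c in center)
    if populations is None:
        populations = s.populations()
    n_shells = int(np.floor(r_max / dr + 1e-9))
    edges = np.arange(n_shells + 1, dtype=float) * dr

    volumes, errs = radial_volumes(s, center, edges, rel_tol, section_ids)
    defined = volumes > 0.0
    counts = {}
    outside = {}
    totals = {}
    densities = {}
    for pop in populations:
        c, out = radial_counts(s, pop, center, edges, section_ids)
        counts[pop] = c
        outside[pop] = out
        totals[pop] = sum(
            1 for cell in s.cells
            if cell.population == pop
            and (section_ids is None or cell.section_id in section_ids))
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(defined, c / np.where(defined, volumes, 1.0), np.nan)
        densities[pop] = d
    return RadialProfile(
        shell_edges=edges, counts=counts, volumes=volumes,
        densities=densities, defined=defined, outside=outside, totals=totals,
        center=center, r_max=float(r_max), volume_err=errs)


def per_section_density(s: SpecimenMap, population: str) -> pd.DataFrame:
    """Per-section density: cell count / (thickness × outline area).

    This is the per-section normalization used for graft-expansion series
    where no single reference point applies.
    """
    cells = _population_cells(s, population)
    rows = []
    for sec in s.sections:
        area = sec.area
        if area <= 0:
            raise HistoshellError("POLYGON_ZERO_AREA",
                                  f"section {sec.section_id} has zero area")
        n = sum(1 for c in cells if c.section_id == sec.section_id)
        vol = sec.thickness * area
        rows.append({"section_id": sec.section_id, "z_l_um": sec.z_l,
                     "count": n, "volume_um3": vol,
                     "density_per_um3": n / vol})
    return pd.DataFrame(rows)


def control_reference_center(specimens) -> tuple:
    """Surrogate reference point for specimens without their own injection
    site: the arithmetic mean of donor specimens' mapped delivery sites."""
    specimens = list(specimens)
    if not specimens:
        raise HistoshellError("EMPTY_SPECIMEN_LIST",
                              "need at least one specimen with an injection site")
    sites = []
    for sp in specimens:
        if sp.injection_site is None:
            raise HistoshellError(
                "NO_REFERENCE_CENTER",
                f"specimen {sp.specimen_id!r} has no injection site")
        sites.append(sp.injection_site)
    return tuple(float(v) for v in np.mean(np.asarray(sites, dtype=float), axis=0))


def crossover_radius(profile: RadialProfile, pop_a: str, pop_b: str):
    """Radius where the two populations' densities cross — a proxy for the
    position of the replacement front.

    Scans shells outward and returns the midpoint radius of the first shell
    whose sign of (ρ_a − ρ_b) differs from the previous defined shell's;
    ``None`` if the sign never changes.  Undefined shells are skipped.
    """
    for pop in (pop_a, pop_b):
        if pop not in profile.densities:
            raise HistoshellError("UNKNOWN_POPULATION",
                                  f"population {pop!r} not in profile")
    mid = profile.shell_midpoints()
    diff = profile.densities[pop_a] - profile.densities[pop_b]
    prev_sign = 0
    for k in range(profile.n_shells):
        if not profile.defined[k] or not np.isfinite(diff[k]):
            continue
        sign = int(np.sign(diff[k]))
        if sign != 0 and prev_sign != 0 and sign != prev_sign:
            return float(mid[k])
        if sign != 0:
            prev_sign = sign
    return None


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_profile_csv(profile: RadialProfile, path) -> Path:
    path = Path(path)
    df = profile.to_frame()
    lines = ["shell_a_um,shell_b_um,population,count,volume_um3,density_per_um3,defined"]
    for _, row in df.iterrows():
        lines.append(
            f"{row.shell_a_um!r},{row.shell_b_um!r},{row.population},"
            f"{row['count']!r},{row.volume_um3!r},"
            f"{'' if not row.defined else repr(row.density_per_um3)},"
            f"{int(row.defined)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_profile_json(profile: RadialProfile, path) -> Path:
    path = Path(path)
    payload = {
        "center": list(profile.center),
        "r_max_um": profile.r_max,
        "shell_edges_um": [float(v) for v in profile.shell_edges],
        "totals": {p: int(t) for p, t in profile.totals.items()},
        "outside": {p: float(v) for p, v in profile.outside.items()},
        "counted": {p: float(np.sum(c)) for p, c in profile.counts.items()},
        "total_volume_um3": float(np.sum(profile.volumes)),
    }
    path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n",
                    encoding="utf-8")
    return path
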