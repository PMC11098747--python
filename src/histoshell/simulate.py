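"""Synthetic chimeric-striatum generator with ground truth.

Emulates the statistical structure the radial analysis assumes: two glial
populations competing around an injection site, with

* an *invader* population whose intensity falls off radially as
  λ_inv · σ(−(r − R_front)/w)  (σ the logistic function, r the 3D distance
  to the injection site) — dense behind the advancing front, sparse beyond;
* a *resident* population with the mirrored intensity λ_res · σ(+(r − R)/w);
* a higher mitotic (Ki67⁺) fraction in the invader;
* apoptosis (TUNEL⁺) enrichment of the resident population within a band
  around the front, where the two populations are in contact.

Cells are drawn as an inhomogeneous Poisson process in each section slab
restricted to the outline (thinning of a homogeneous process).  The sampled
z coordinate is *discarded* — markers keep only their section id and (x, y)
— reproducing exactly the information loss that the uniform-depth
probabilistic counting is designed to handle.

This generator is a verification harness: it matches the acquisition
geometry of the mapped datasets (15 sagittal sections of 20 µm cut every
160 µm) and the qualitative biology (discrete front, mutual exclusivity,
proliferation/apoptosis asymmetry), not any fitted biological model.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Polygon

from .specimen import (
    CellRecord,
    HistoshellError,
    SectionOutline,
    SpecimenMap,
)

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "make_striatum_template",
    "simulate_specimen",
    "expected_shell_counts",
    "write_ground_truth",
]

#: Default population labels (opaque strings throughout the pipeline).
INVADER = "WT_mCherry"
RESIDENT = "HD_EGFP"


@dataclass
class SimulationSpec:
    """Parameters of one synthetic specimen.

    Geometry defaults mirror the mapped acquisition series (15 sections,
    20 µm thick, 160 µm apart).  Densities are in cells·µm⁻³; 2×10⁻⁵ µm⁻³
    (20 000 cells·mm⁻³) per population gives a few ×10⁴ mapped cells per
    specimen, the scale of a densely engrafted striatum.  The front width w
    (logistic length scale, default 100 µm) sets how sharp the replacement
    boundary is; the front band (default 250 µm) is the contact zone where
    resident apoptosis is elevated.
    """

    n_sections: int = 15
    thickness: float = 20.0  # µm
    spacing: float = 160.0  # µm
    injection_site: tuple = None  # default: mid-specimen, set in __post_init__
    lambda_resident: float = 2e-5  # cells/µm³
    lambda_invader: float = 2e-5  # cells/µm³
    R_front: float = 750.0  # µm
    front_width: float = 100.0  # µm (w)
    p_ki67_invader: float = 0.15
    p_ki67_resident: float = 0.05
    p_tunel_base: float = 0.02
    p_tunel_front: float = 0.10
    front_band: float = 250.0  # µm
    seed: int = 0
    # outline template: in-plane semi-axes of the body at its widest section
    semi_axis_x: float = 1600.0  # µm
    semi_axis_y: float = 1100.0  # µm
    n_vertices: int = 48
    invader_pop: str = INVADER
    resident_pop: str = RESIDENT

    def __post_init__(self):
        if self.n_sections < 1:
            raise HistoshellError("BAD_SIMULATION_SPEC", "n_sections < 1")
        if self.thickness <= 0 or self.spacing < self.thickness:
            raise HistoshellError("BAD_SIMULATION_SPEC",
                                  "need 0 < thickness ≤ spacing")
        for name in ("p_ki67_invader", "p_ki67_resident", "p_tunel_base",
                     "p_tunel_front"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise HistoshellError("BAD_SIMULATION_SPEC",
                                      f"{name}={v} outside [0, 1]")
        if self.lambda_resident < 0 or self.lambda_invader < 0:
            raise HistoshellError("BAD_SIMULATION_SPEC", "negative density")
        if self.R_front < 0 or self.front_width <= 0 or self.front_band < 0:
            raise HistoshellError("BAD_SIMULATION_SPEC", "bad front geometry")
        if self.n_vertices < 24:
            raise HistoshellError("BAD_SIMULATION_SPEC", "n_vertices < 24")
        if self.injection_site is None:
            # centre of the middle section's slab, on the in-plane centroid
            mid = (self.n_sections - 1) // 2
            self.injection_site = (0.0, 0.0,
                                   mid * self.spacing + 0.5 * self.thickness)
        self.injection_site = tuple(float(v) for v in self.injection_site)


@dataclass
class GroundTruth:
    """Realized generator truth for recovery tests."""

    spec: SimulationSpec
    totals: dict  # population -> realized cell count
    section_totals: dict  # population -> {section_id: count}
    expected_shell_counts: dict = field(default_factory=dict)


def _logistic(u):
    return 1.0 / (1.0 + np.exp(-np.clip(u, -500, 500)))


def invader_intensity(spec: SimulationSpec, r):
    """λ_inv · σ(−(r − R_front)/w) at 3D radius r from the injection site."""
    return spec.lambda_invader * _logistic(-(np.asarray(r, float) - spec.R_front)
                                           / spec.front_width)


def resident_intensity(spec: SimulationSpec, r):
    """λ_res · σ(+(r − R_front)/w)."""
    return spec.lambda_resident * _logistic((np.asarray(r, float) - spec.R_front)
                                            / spec.front_width)


def make_striatum_template(spec: SimulationSpec):
    """Deterministic per-seed striatum-like outlines for each section.

    Sections carry an elliptical body whose scale follows a lens profile
    across the series (largest mid-series, tapering laterally, as a convex
    3D body cut into parallel sections would), with small smooth low-order
    harmonic irregularities so outlines are realistic non-convex simple
    polygons.  Star-shaped by construction, hence always simple.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x5747]))
    n = spec.n_sections
    amp = rng.uniform(0.02, 0.06, size=4)
    pha = rng.uniform(0.0, 2.0 * math.pi, size=4)
    theta = np.linspace(0.0, 2.0 * math.pi, spec.n_vertices, endpoint=False)
    wobble = 1.0 + sum(a * np.cos((k + 2) * theta + p)
                       for k, (a, p) in enumerate(zip(amp, pha)))
    sections = []
    for i in range(n):
        u = (i - (n - 1) / 2.0) / ((n + 1) / 2.0)
        scale = math.sqrt(max(1.0 - u * u, 0.05))
        x = spec.semi_axis_x * scale * wobble * np.cos(theta)
        y = spec.semi_axis_y * scale * wobble * np.sin(theta)
        z_l = i * spec.spacing
        sections.append(SectionOutline(
            f"s{i:02d}", list(zip(x.tolist(), y.tolist())),
            z_l, z_l + spec.thickness))
    return sections


def _sample_population(rng, spec, sections, population, lam, radial_profile_fn):
    """Thinned homogeneous Poisson sampling of one population.

    Candidate points are homogeneous at rate ``lam`` in each section's
    bounding slab, restricted to the outline, then thinned by the radial
    profile evaluated at the point's true 3D radius.  z is used only for the
    thinning and then dropped.
    """
    cx, cy, cz = spec.injection_site
    cells = []
    section_totals = {}
    for sec, sub in zip(sections, rng):
        poly = Polygon(sec.vertices)
        xmin, ymin, xmax, ymax = poly.bounds
        bbox_vol = (xmax - xmin) * (ymax - ymin) * sec.thickness
        n = sub.poisson(lam * bbox_vol) if lam > 0 else 0
        count = 0
        if n:
            x = sub.uniform(xmin, xmax, n)
            y = sub.uniform(ymin, ymax, n)
            z = sub.uniform(sec.z_l, sec.z_u, n)
            keep = shapely.contains_xy(poly, x, y)
            x, y, z = x[keep], y[keep], z[keep]
            r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
            accept = sub.uniform(size=len(x)) < radial_profile_fn(r) / lam
            x, y, r = x[accept], y[accept], r[accept]
            count = len(x)
            for xi, yi, ri in zip(x, y, r):
                cells.append((sec.section_id, float(xi), float(yi), float(ri)))
        section_totals[sec.section_id] = count
    return cells, section_totals


def simulate_specimen(spec: SimulationSpec):
    """Draw one synthetic specimen; returns ``(SpecimenMap, GroundTruth)``.

    One root RNG stream per specimen, with deterministic per-section and
    per-population substreams, so output is reproducible per seed and stable
    under changes to other populations' parameters.
    """
    sections = make_striatum_template(spec)
    root = np.random.SeedSequence([int(spec.seed), 0xC417])
    streams = root.spawn(2 * spec.n_sections + 1)
    rng_flags = np.random.default_rng(streams[-1])
    inv_rngs = [np.random.default_rng(s) for s in streams[:spec.n_sections]]
    res_rngs = [np.random.default_rng(s) for s in streams[spec.n_sections:2 * spec.n_sections]]

    inv_pts, inv_totals = _sample_population(
        inv_rngs, spec, sections, spec.invader_pop, spec.lambda_invader,
        lambda r: invader_intensity(spec, r))
    res_pts, res_totals = _sample_population(
        res_rngs, spec, sections, spec.resident_pop, spec.lambda_resident,
        lambda r: resident_intensity(spec, r))

    cells = []
    for sid, x, y, r in inv_pts:
        flags = {"Ki67": bool(rng_flags.uniform() < spec.p_ki67_invader),
                 "TUNEL": bool(rng_flags.uniform() < spec.p_tunel_base),
                 "hN": True}
        cells.append(CellRecord(sid, x, y, spec.invader_pop, flags))
    for sid, x, y, r in res_pts:
        p_tunel = (spec.p_tunel_front
                   if abs(r - spec.R_front) < spec.front_band
                   else spec.p_tunel_base)
        flags = {"Ki67": bool(rng_flags.uniform() < spec.p_ki67_resident),
                 "TUNEL": bool(rng_flags.uniform() < p_tunel),
                 "hN": True}
        cells.append(CellRecord(sid, x, y, spec.resident_pop, flags))

    s = SpecimenMap(
        specimen_id=f"synthetic-chimera-seed{spec.seed}",
        sections=sections,
        cells=cells,
        injection_site=spec.injection_site,
        thickness=spec.thickness,
        spacing=spec.spacing,
        metadata={"generator": "histoshell.simulate", "seed": spec.seed},
    )
    truth = GroundTruth(
        spec=spec,
        totals={spec.invader_pop: len(inv_pts), spec.resident_pop: len(res_pts)},
        section_totals={spec.invader_pop: inv_totals,
                        spec.resident_pop: res_totals},
    )
    return s, truth


def expected_shell_counts(spec: SimulationSpec, shell_edges,
                          n_samples_per_section: int = 100_000,
                          seed: int = 12345):
    """Monte-Carlo expectations of per-shell counts under the generator.

    Integrates each population's intensity over shell ∩ tissue by uniform
    sampling in each section's bounding slab (fixed seed, standard error
    reported).  Because the probabilistic counting integrates P(z) exactly,
    these are also the expectations of the fractional shell counts.
    Returns ``(expectations, standard_errors)`` as population → array.
    """
    edges = np.asarray(shell_edges, dtype=float)
    sections = make_striatum_template(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE5]))
    cx, cy, cz = spec.injection_site
    pops = {
        spec.invader_pop: lambda r: invader_intensity(spec, r),
        spec.resident_pop: lambda r: resident_intensity(spec, r),
    }
    sums = {p: np.zeros(len(edges) - 1) for p in pops}
    sq_sums = {p: np.zeros(len(edges) - 1) for p in pops}
    for sec in sections:
        poly = Polygon(sec.vertices)
        xmin, ymin, xmax, ymax = poly.bounds
        bbox_vol = (xmax - xmin) * (ymax - ymin) * sec.thickness
        m = n_samples_per_section
        x = rng.uniform(xmin, xmax, m)
        y = rng.uniform(ymin, ymax, m)
        z = rng.uniform(sec.z_l, sec.z_u, m)
        inside = shapely.contains_xy(poly, x, y)
        r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
        which = np.digitize(r, edges) - 1  # shell index; -1/len-1 out of range
        for p, fn in pops.items():
            w = np.where(inside, fn(r), 0.0) * bbox_vol
            for k in range(len(edges) - 1):
                sel = which == k
                if sel.any():
                    sums[p][k] += w[sel].sum() / m
                    sq_sums[p][k] += (w[sel] ** 2).sum() / m
    ses = {}
    for p in pops:
        # per-section MC variance of the mean, summed over sections
        var = (sq_sums[p] - 0.0) / n_samples_per_section
        ses[p] = np.sqrt(np.clip(var, 0.0, None))
    return sums, ses


def write_ground_truth(truth: GroundTruth, path) -> Path:
    path = Path(path)
    payload = {
        "spec": asdict(truth.spec),
        "totals": truth.totals,
        "section_totals": truth.section_totals,
    }
    path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n",
                    encoding="utf-8")
    return path
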