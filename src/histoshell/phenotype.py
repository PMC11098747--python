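"""Phenotype-fraction statistics and optical-fractionator estimation.

Phenotype fractions (proliferating Ki67⁺, apoptotic TUNEL⁺, lineage markers)
are exact integer ratios per population, optionally over a section subset —
proliferation is typically mapped at a sparser cadence (every third section,
i.e. every 480 µm for 160 µm-spaced series) than the full reconstruction.

Absolute population size is estimated with the optical fractionator,

    N̂ = ΣQ / (ssf · asf · hsf)

where ΣQ is the number of cells counted in systematically sampled counting
frames, ssf/asf/hsf the section/area/height sampling fractions.  Counting
the entire section height without guard zones gives hsf = 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .specimen import FLAG_NAMES, HistoshellError, SpecimenMap, parse_section_filter

__all__ = [
    "FractionResult",
    "FractionatorParams",
    "marker_fraction",
    "fractionator_estimate",
    "simulate_fractionator_sampling",
    "write_fraction_csv",
]


@dataclass
class FractionResult:
    population: str
    flag: str
    positive: int
    total: int

    @property
    def fraction(self) -> Optional[float]:
        """positive/total, or None when the population is absent."""
        if self.total == 0:
            return None
        return self.positive / self.total


@dataclass
class FractionatorParams:
    """Sampling fractions of one fractionator run plus the raw count ΣQ.

    ``ssf`` is thickness-free: the fraction of sections sampled.  When the
    estimate should refer to the specimen's own mapped sections it is
    1/period; referring to continuous tissue it is thickness/spacing-derived
    (e.g. 20 µm sections every 480 µm → 1/24).
    """

    ssf: float
    asf: float
    hsf: float
    sum_Q: int

    def __post_init__(self):
        for name in ("ssf", "asf", "hsf"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise HistoshellError("BAD_SAMPLING_FRACTION",
                                      f"{name}={v} must lie in (0, 1]")
        if self.sum_Q < 0:
            raise HistoshellError("BAD_COUNT", f"sum_Q={self.sum_Q} < 0")


def marker_fraction(s: SpecimenMap, population: str, flag: str,
                    section_filter: Optional[str] = None) -> FractionResult:
    """Fraction of one population carrying a phenotype flag.

    ``section_filter`` accepts ``"every:k[:offset]"`` or a comma list of
    section ids (see :func:`histoshell.specimen.parse_section_filter`).
    Counts are exact integers; an absent population yields total 0 and an
    undefined fraction.
    """
    if flag not in FLAG_NAMES:
        raise HistoshellError("UNKNOWN_FLAG",
                              f"flag {flag!r} not in {list(FLAG_NAMES)}")
    keep = parse_section_filter(section_filter, s.sections)
    total = 0
    positive = 0
    for c in s.cells:
        if c.population != population or c.section_id not in keep:
            continue
        total += 1
        positive += int(c.flags[flag])
    return FractionResult(population, flag, positive, total)


def fractionator_estimate(p: FractionatorParams) -> float:
    """Optical-fractionator population estimate N̂ = ΣQ/(ssf·asf·hsf)."""
    return p.sum_Q / (p.ssf * p.asf * p.hsf)


def simulate_fractionator_sampling(s: SpecimenMap, population: str,
                                   frame=(200.0, 200.0), grid=(400.0, 400.0),
                                   section_period: int = 3,
                                   seed: int = 0) -> FractionatorParams:
    """Emulate a fractionator counting session on mapped coordinates.

    Counting frames of size ``frame`` are placed one per ``grid`` cell at a
    single uniform random lattice offset (systematic uniform random
    sampling), so every point has inclusion probability exactly
    asf = frame_area/grid_area.  Sections are sampled every
    ``section_period``-th by z order with a uniform random phase.  Cells are
    counted with the unbiased-frame rule: inside the frame or on its
    left/bottom inclusion edges.  Whole slabs are counted (hsf = 1).
    """
    fw, fh = (float(v) for v in frame)
    gx, gy = (float(v) for v in grid)
    if not (0 < fw <= gx and 0 < fh <= gy):
        raise HistoshellError("BAD_FRAME_DIMS",
                              f"frame {frame} must fit in grid {grid}")
    if section_period < 1 or section_period > max(len(s.sections), 1):
        raise HistoshellError("BAD_SECTION_PERIOD",
                              f"section_period={section_period}")
    if population not in s.populations() and any(s.cells):
        raise HistoshellError("UNKNOWN_POPULATION",
                              f"population {population!r} not in specimen")

    rng = np.random.default_rng(seed)
    phase = int(rng.integers(section_period))
    x0 = float(rng.uniform(0.0, gx))
    y0 = float(rng.uniform(0.0, gy))
    ordered = sorted(s.sections, key=lambda sec: sec.z_l)
    sampled = {sec.section_id for i, sec in enumerate(ordered)
               if i % section_period == phase}

    xs = np.array([c.x for c in s.cells
                   if c.population == population and c.section_id in sampled])
    ys = np.array([c.y for c in s.cells
                   if c.population == population and c.section_id in sampled])
    if len(xs):
        # A point lies in some frame of the offset lattice iff its position
        # modulo the grid pitch falls in [0, frame); the half-open interval
        # is the left/bottom-inclusive counting rule.
        in_x = np.mod(xs - x0, gx) < fw
        in_y = np.mod(ys - y0, gy) < fh
        sum_q = int(np.count_nonzero(in_x & in_y))
    else:
        sum_q = 0
    return FractionatorParams(ssf=1.0 / section_period,
                              asf=(fw * fh) / (gx * gy),
                              hsf=1.0, sum_Q=sum_q)


def write_fraction_csv(results, path) -> Path:
    """Write fraction results as `population,flag,positive,total,fraction`."""
    path = Path(path)
    lines = ["population,flag,positive,total,fraction"]
    for r in results:
        frac = "" if r.fraction is None else repr(r.fraction)
        lines.append(f"{r.population},{r.flag},{r.positive},{r.total},{frac}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_fraction_json(results, path) -> Path:
    path = Path(path)
    payload = [
        {"population": r.population, "flag": r.flag, "positive": r.positive,
         "total": r.total, "fraction": r.fraction}
        for r in results
    ]
    path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n",
                    encoding="utf-8")
    return path
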