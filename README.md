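# histoshell

Quantitative analysis of 3D-reconstructed serial-section cell maps, built for
studies of competing engrafted glial populations in rodent striatum (and any
comparable setting where labelled cells are mapped section by section around
a stereotactic injection site).

After serial sagittal sections are outlined and every labelled cell is mapped,
the exported data are per-section outline polygons, per-cell coordinates with
population and phenotype labels, and an injection-site reference point.
`histoshell` turns these into:

- **Radial density profiles.** Each mapped cell's depth within its section is
  unknown, so the cell is represented by a uniform point-probability function
  P(z) = 1/(z_u − z_l) across its slab [z_l, z_u]. Counting in concentric
  spherical shells about the injection site is then fractional: a cell counts
  1 if its representative segment lies fully inside the shell, 0 if fully
  outside, and partially if it crosses a shell boundary. The density of
  population *p* in the shell with radii a < b is

      ρ_{a,b} = N_{a,b} / V_{a,b}

  with N_{a,b} the summed segment fractions and V_{a,b} the **exact** tissue
  volume inside the shell — each section's extruded outline ∩ sphere volume,
  computed from the exact polygon–disk intersection area (Green's-theorem
  circular-segment decomposition) integrated across the slab by adaptive
  quadrature with a certified error bound. Defaults: 125 µm shell increments
  out to a 2 mm radius.
- **Front summaries.** `crossover_radius` reports where the invading and
  resident populations' density profiles cross — a proxy for the position of
  the advancing replacement front.
- **Phenotype fractions.** Ki67⁺ (proliferating) and TUNEL⁺ (apoptotic)
  fractions per population, with section filters for sparser mapping cadences
  (e.g. `every:3` = every 480 µm on a 160 µm-spaced series).
- **Optical fractionator.** The standard stereological estimate
  N̂ = ΣQ/(ssf·asf·hsf), plus a simulator of systematic-uniform-random frame
  sampling (200×200 µm frames in a 400×400 µm grid by default) for
  verifying unbiasedness on synthetic ground truth.
- **A synthetic chimera generator.** Two populations drawn as inhomogeneous
  Poisson processes with a logistic replacement front, higher invader
  proliferation and resident apoptosis enriched at the contact zone, with the
  true parameters recorded for recovery tests. The sampled z coordinate is
  discarded, reproducing the exact information loss the probabilistic
  counting handles.

## Worked example

```sh
histoshell simulate --seed 1 --out demo/specimen
histoshell profile demo/specimen --out demo/profile
histoshell phenotype demo/specimen --sections every:3 --out demo/phenotype
histoshell fractionator demo/specimen --population HD_EGFP --seed 2 --out demo/frac
```

The simulation writes a 15-section specimen (20 µm sections, 160 µm apart)
with 5 075 invading (`WT_mCherry`) and 18 016 resident (`HD_EGFP`) cells and
its ground truth. The profile logs its conservation checks —

```
INFO histoshell: conservation WT_mCherry: counted 5075.000000 of 5075 mapped cells (residual 0.00e+00)
INFO histoshell: conservation HD_EGFP: counted 18016.000000 of 18016 mapped cells (residual 0.00e+00)
INFO histoshell: total tissue volume in shells: 1.176e+09 µm³
```

— and `profile.csv` holds the per-shell counts, exact volumes and densities:

```
shell_a_um,shell_b_um,population,count,volume_um3,density_per_um3,defined
0.0,125.0,WT_mCherry,17.0,979653.3091444173,1.735307770750756e-05,1
125.0,250.0,WT_mCherry,141.26582162102136,7578045.079234179,1.8641459656676704e-05,1
...
```

The invader density stays near its plateau value 2×10⁻⁵ cells·µm⁻³ inside the
front (true front radius 750 µm) and collapses beyond it; the two profiles
cross in the 750–875 µm shell. The Ki67 cadence run reports the invader
fraction 0.146 vs the resident 0.052 (generator truth 0.15 vs 0.05):

```
population,flag,positive,total,fraction
WT_mCherry,Ki67,239,1637,0.14599877825290164
HD_EGFP,Ki67,311,5943,0.052330472825172475
```

The fractionator samples every 3rd section with quarter-area frames
(ssf = 1/3, asf = 1/4, hsf = 1), counts ΣQ = 1510 cells and estimates
N̂ = 1510/(1/3 · 1/4) = 18 120 — within 0.6 % of the true 18 016.

Every command writes a `manifest.json` (parameters, package version, input
hashes, no timestamps), so identical configs and seeds reproduce outputs byte
for byte.

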