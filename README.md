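# phytogeom

Geometric analysis of bacteriophytochrome photosensory-module structures and
their UV–vis difference spectra.

Bacteriophytochromes (BphPs) are red/far-red photoreceptors built from PAS,
GAF and PHY domains around a biliverdin chromophore. Photoconversion between
the red-absorbing Pr state (λmax ≈ 700 nm) and the far-red-absorbing Pfr
state (λmax ≈ 750 nm) isomerizes the chromophore, refolds the PHY-domain
"sensory tongue" and repositions the PHY domains relative to a nearly rigid
PAS–GAF core. `phytogeom` quantifies that rearrangement from Cα coordinates
and processes the accompanying absorption spectra. It is aimed at structural
biologists comparing parallel two-subunit photosensory-module (PCM) models —
dark/illuminated states, point mutants, cryo vs room-temperature structures —
with a small set of reproducible descriptors.

## Descriptors

For a dimer with subunits A and B (Cα coordinates, Å, angles in degrees):

- **Interface offset angle φ** — each subunit's two interface helices are
  fitted with axes (oriented N→C); the subunit bundle axis is the normalized
  mean of the two; φ is the angle between the two bundle axes, folded into
  [0°, 90°], with bundles more than 135° apart flagged antiparallel (AP).
- **d-centroids** — distance between the PHY-domain Cα centroids of the two
  subunits.
- **Opening angle Ω** — angle ∠(centroid_A, V, centroid_B) at a vertex V
  placed midway between the C-terminal Cα of interface helix 3 (subunit A)
  and helix 6 (subunit B).
- **PHY rotation / translation** — residues of two structures are paired by
  Smith–Waterman local alignment of their sequences; the PAS–GAF cores are
  superposed by an iterative Kabsch fit in which pairs deviating by more
  than 5 Å are rejected until the rejected set is stable; the residual rigid
  motion of the PHY domain after that core alignment gives the rotation
  angle (from the rotation matrix trace) and the centroid shift.
- **r.m.s.d.** — over retained core Cα pairs after the outlier-rejected fit.
- **B-factor displacement** — √(3B/8π²), the isotropic rms displacement
  corresponding to a crystallographic B factor (≈ 1.95 Å at B = 100 Å²).
- **Spectra** — two-column UV–vis series (240–800 nm) are normalized to unit
  maximum in the 550–800 nm band, subtracted (illuminated − dark) after
  linear interpolation onto a common grid, and summarized by λmax (5-point
  median smoothing, reported at grid resolution) and difference extrema.

A synthetic-data generator builds two-subunit Cα models whose φ, d-centroids,
Ω and PHY rotation/translation are set exactly by construction (plus optional
Gaussian coordinate noise), and absorption spectra as Gaussian Pr/Pfr band
mixtures — so every stage of the pipeline is testable against known ground
truth without any downloads.

## Worked example

```python
from phytogeom.synthetic import DimerSpec, make_synthetic_dimer
from phytogeom.dimer_geometry import measure_dimer, domain_rotation

spec = DimerSpec(phi=45, d_centroids=35, omega=66,
                 phy_rotation=8, phy_translation=3, seed=1)
model, truth = make_synthetic_dimer(spec)

g = measure_dimer(model, truth.scheme)
print(f"phi = {g.phi:.1f} deg, d_centroids = {g.d_centroids:.1f} A, "
      f"omega = {g.omega:.1f} deg")

motion = domain_rotation(truth.reference, model, truth.scheme)
print(f"PHY rotation = {motion.rotation:.1f} deg, "
      f"translation = {motion.translation:.1f} A, "
      f"core rmsd = {motion.core_fit.rmsd:.2f} A")
```

prints

```
phi = 45.0 deg, d_centroids = 35.0 A, omega = 66.0 deg
PHY rotation = 8.0 deg, translation = 3.0 A, core rmsd = 0.00 A
```

The first line re-measures the dimer geometry the generator was asked for: a
45° crossing of the interface helix bundles and PHY centroids 35 Å apart
subtending 66° at the interface vertex — the scale of a Pr-state dimer. The
second line recovers the 8° PHY rotation and 3 Å shift that were applied
relative to the companion reference model, with a PAS–GAF core r.m.s.d. of
0.00 Å because the cores are identical.

## Command line

```bash
phytogeom simulate --out fixtures --seed 3 --phi 32 --d-centroids 35 --omega 66
phytogeom compare  --config run.yaml --out results
phytogeom spectra  --config run.yaml --out results
phytogeom table    results/geometry.tsv more/geometry.tsv --out merged.tsv
```

`compare` writes `geometry.tsv` with one row per structure (φ or AP,
d-centroids, Ω, PHY rotation/translation, core r.m.s.d., retained pair
count, flags); `spectra` writes normalized and difference spectra plus a
summary TSV per dark/illuminated job. The YAML config supplies the domain
scheme (residue ranges for PAS, GAF, PHY and the interface helices),
alignment parameters, the rejection cutoff, and optionally a crystallographic
symmetry operator (12 numbers) to build a dimer from a monomeric asymmetric
unit. Per-row failures are flagged; remaining rows still compute.

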