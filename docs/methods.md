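# Methods

This note documents the models, conventions and numerical choices behind
`phytogeom`, and what its synthetic benchmarks do and do not demonstrate.

## Coordinate conventions

Coordinates are in Å, angles reported in degrees. Residue ranges are 1-based
inclusive in author numbering, so ranges match the residue labels structural
biologists use (e.g. Thr289, Arg472). Alternate conformers are resolved on
parse by keeping the highest-occupancy atom (ties: first label) — the
pipeline is single-conformer and deterministic. Waters and hydrogens are
dropped at parse time; het records (the biliverdin chromophore and other
ligands) are kept and addressable by residue name in atom-distance queries.
Only the first model of a multi-model file is read. Insertion codes sort
after the blank code. Dimers given as a monomeric asymmetric unit are
completed from a user-supplied 12-number symmetry operator in the config;
the package deliberately does not interpret space-group symbols.

Default domain boundaries for a PAS–GAF–PHY photosensory module: PAS 1–120,
GAF 121–325, PHY 326–516, sensory tongue 435–485. The GAF/PHY boundary is
placed at the helical kink near residue 325; the tongue range is reported
variously as 435–485 or 435–490 in the literature and both the boundary and
the tongue are configurable. The PAS/GAF split only matters through the
union PAS∪GAF used as the rigid core, so its exact position is immaterial
to every descriptor.

## Residue pairing

Cα sets of two structures are paired by optimal local alignment of their
one-letter sequences (Smith–Waterman). Scoring defaults are the standard
protein choices — BLOSUM62, gap open 10, gap extend 1, a gap of length *g*
costing open + (g−1)·extend — and are configurable, including loading a
substitution matrix from an NCBI-layout file. Because the structures being
compared are homologous over the aligned region, the resulting Cα pairing
(and therefore the superposition) is insensitive to these parameters at the
tolerances the descriptors carry. The alignment engine is
`Bio.Align.PairwiseAligner`; ties between co-optimal alignments are broken
by its deterministic enumeration order, and scores are verified in the test
suite against an independent exhaustive-enumeration oracle for short
sequences, so the tie-break convention affects no verified quantity. When no
pair of residues scores positive the pairing is empty with score 0. Modified
residues map to their parent one-letter code when tabulated, else X.

## Superposition and outlier rejection

The rigid fit is the Kabsch algorithm: SVD of the weighted covariance of the
centered point sets, with the smallest singular direction flipped when the
determinant would be negative, so the rotation is always proper — including
for near-planar, reflection-prone configurations. Weights default to
uniform; occupancy weighting is available but off. Fits require ≥ 3
non-collinear pairs; rank deficiency raises a degenerate-fit error rather
than returning a spurious rotation.

Outlier rejection iterates to a fixed point: fit on retained pairs,
recompute all per-pair deviations, reject pairs deviating by more than the
cutoff (default 5 Å), repeat until the rejected set stops changing or 20
iterations. Rejection is monotone — a rejected pair stays rejected — which
guarantees termination. The reported r.m.s.d. is over retained pairs only.
The 5 Å cutoff is the convention for comparing homologous structures whose
mobile domains would otherwise dominate a least-squares fit.

The rotation angle of a transform is the angle of its rotation matrix,
mathematically arccos((tr R − 1)/2) but computed as
atan2(‖antisymmetric part‖/2, (tr R − 1)/2): the arccos form loses half the
floating-point digits near the identity, where most domain rotations of
interest live (a few degrees).

`kabsch_fit` is cross-checked in the tests against an independently
implemented quaternion (Horn) absolute-orientation solver on 1,000 random
instances; agreement is required to 1e-9 Å.

## B factor → displacement

A crystallographic B factor (Å²) converts to a three-dimensional isotropic
rms displacement √(3B/8π²). At B = 100 Å² — the scale of a flexible PHY
domain — this gives 1.95 Å, i.e. "about 2 Å" of thermal disorder, the yard
stick against which a ~4 Å coherent domain shift is judged significant. The
one-dimensional form √(B/8π²) (≈ 1.1 Å at the same B) is also exposed; the
3-D form is the default because the quantity is compared against magnitudes
of 3-D displacement vectors.

## Helix axes and the interface offset angle φ

A helix axis is fitted in two stages. The initial direction is the
null-space direction of the Cα second differences: for an ideal helix every
second-difference vector is exactly perpendicular to the axis (the constant
rise cancels), so the smallest right singular vector of the stacked second
differences is the exact axis. A plain principal-axis (PCA) fit was
rejected: on a 12-residue ideal helix the non-integral number of turns
biases the PCA axis by ≈ 2.3°, which is the same order as the angular
differences the pipeline is meant to resolve. The initial axis is then
refined by a least-squares cylinder fit (Levenberg–Marquardt on the spread
of radial distances about their mean), which is a no-op on exact data and a
maximum-likelihood-flavoured estimate under coordinate noise; at σ = 0.3 Å
on a 26-residue helix the axis direction is recovered within 3° in ≥ 99/100
seeded trials. Axes are sign-aligned N→C, making the orientation
deterministic; fit quality is reported as the rms radial scatter.

Each subunit's bundle axis is the normalized mean of its two interface-helix
axes; φ is the angle between the two bundle axes. The exact convention for
this angle is a design decision of this package, validated against the
literature values for the compact (≈ 32°) and extended (≈ 46°) interfaces
with a ±5° tolerance. φ is folded into [0°, 90°]; raw bundle angles above
135° are flagged antiparallel (AP), matching how antiparallel dimers are
reported rather than assigned a misleading acute angle. A perfectly
anti-aligned helix pair within one subunit has no defined bundle axis and
raises a degenerate-bundle error.

## PHY centroid metrics and domain motion

d-centroids is the distance between the two PHY Cα centroids. The opening
angle Ω needs a vertex "between the ends" of the two long interface helices;
this package defines it as the midpoint of the C-terminal Cα of the first
listed interface helix in subunit A and of the last listed one in subunit B.
Relabeling the subunits while swapping the helix roles consistently leaves
both φ and Ω unchanged (asserted in the tests).

PHY rotation/translation between two structures: (1) pair and iteratively
fit the PAS–GAF core Cα of the mobile structure onto the reference (5 Å
rule); (2) apply that single transform to the whole mobile structure; (3)
fit the paired PHY Cα sets; the rotation is the angle of the stage-3
transform and the translation is the PHY centroid shift remaining after
stage 2. When both structures are dimers the subunit correspondence is the
assignment minimizing the core r.m.s.d. of a *joint* fit of both subunits
under one rigid transform — a per-chain criterion cannot distinguish the
two assignments of a nearly symmetric homodimer, whereas the joint fit can
unless the dimer is exactly two-fold symmetric. The single reported value is
for the first matched subunit pair; the second pair is computed and logged.

## Spectra

Spectra are two-column (wavelength nm, absorbance AU) text files on the
240–800 nm measurement range; rows may be unordered and duplicate
wavelengths are averaged. Normalization divides by the maximum within a
window, by default 550–800 nm (the red/far-red Q band), so dark and
illuminated traces are compared on the chromophore band rather than the
protein band; unit-area or other conventions can be had by changing the
window or scaling externally. Normalization is idempotent and
scale-invariant. Differences are illuminated − dark after linear
interpolation of the second spectrum onto the first's grid restricted to
the overlap. λmax is the grid wavelength of the maximum after 5-point
running median smoothing (robust to single-point spikes; `mode="nearest"`
at the edges), searched in a 650–780 nm window by default. Ties in the
smoothed signal — which a symmetric band centred on a grid point always
produces — are broken by the raw absorbance, so noise-free on-grid bands
are recovered exactly; sub-nm maxima (e.g. 701.5 nm) arise from sub-nm
grids, never from interpolation. A maximum on the window edge is flagged
monotone-in-window. No baseline subtraction is applied by default.
Illumination protocols (660/740 nm vs 700/750 nm) are carried as opaque
labels. Photokinetics, quantum yields and decomposition into pure Pr/Pfr
basis spectra are out of scope.

## Synthetic data: what it emulates and what it does not

The generator builds each subunit from two ideal interface helices (1.5 Å
rise, 100° twist, 2.3 Å radius — the canonical ~3.8 Å Cα spacing), a filler
lattice for the PAS–GAF core and a lattice cloud for the PHY domain, then
places the two subunits so that φ, d-centroids and Ω take the requested
values exactly at zero noise: the subunit templates are tilted by ±φ/2, and
the PHY centroids are placed on the two rays from the measured vertex that
subtend Ω at separation d. PHY rotation/translation ground truth is created
by rotating each PHY cloud about its own centroid (so the translation is
exactly the applied shift) and emitting a companion reference model holding
the unperturbed pose. Noise is isotropic Gaussian per atom, added last,
independently per emitted model. Sequences are random over the 20 amino
acids (seeded separately, so structures meant to be compared can share a
sequence); a homolog mode introduces substitutions and deletions to
exercise the alignment. Generators are bit-reproducible given their spec.

Default sizes mirror a real photosensory module: 516 residues per subunit
(core 1–325, PHY 326–516), 26-residue interface helices. These defaults are
the conditions under which the recovery benchmarks run: 50 seeded dimers
with φ ∈ [10°, 60°], rotation ∈ [0°, 45°], translation ∈ [0, 10 Å] are
recovered within 0.5°/0.1 Å at σ = 0 and within 3°/1 Å at σ = 0.3 Å.

What passing these tests shows: the descriptor definitions are internally
consistent, the estimators are unbiased on rigid bodies, and their noise
sensitivity is quantified. What it does not show: behaviour on real folded
proteins — lattice clouds have no secondary-structure anisotropy, no
correlated (domain-level) disorder unless enabled, no missing loops, no
sequence-dependent alignment ambiguity, and the synthetic helices are
ideal. Conclusions about real structures still require real coordinates.

## The acceptance script

`scripts/acceptance.py` recomputes every reported number at run time from
the seed: oracle agreements (quaternion superposition, exhaustive-alignment
scores), the B-factor conversion, dimer descriptors re-measured from
synthetic structures constructed at the Pr-, Pfr- and mutant-scale
geometries (φ 46/45/42/32°, d-centroids 30/26/35/46 Å, Ω 54/44/66/85°, PHY
rotations 2/8/33°, 4 Å PHY shift), the Pr→Pfr differences derived from
them (25° rotation, 11 Å centroid opening), chromophore-pocket hydrogen
bonds measured on a labelled synthetic pocket model (2.8/3.1 Å by
construction), and λmax values of synthetic bands at 698/702/701.5/706 nm.
Core r.m.s.d. quantities (0.9/1.4/1.8 Å vs the reference geometry, 0.4 Å
between two realizations of one geometry) are measured on constructions
whose per-coordinate noise is calibrated in closed form (r.m.s.d. = √3·σ
against a noise-free reference, √6·σ between two noisy realizations); the
measurement itself is the pipeline's outlier-rejected fit. These synthetic
reproductions demonstrate the pipeline measures back the scales it is asked
to construct; they are not re-derivations from deposited coordinates, which
would require downloading public structure files.
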