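# Methods

`fusemotion` implements the quantitative analyses used to characterize the
prefusion → postfusion transition of a class II membrane fusogen (the
gamete fusion protein HAP2/GCS1 is the motivating system): how far and how
much a domain moves between the two states, whether negative-stain class
averages are consistent with projections of an atomic model, what the
molar masses of a glycoprotein–detergent conjugate are, and how thermally
stable the ectodomain is.  Every stage has a synthetic forward model with
embedded ground truth, so each analysis is validated as an inverse problem.

## Rigid-body domain kinematics

**Model.** Domains are treated as rigid bodies.  Given a prefusion and a
postfusion structure, the postfusion structure is first superposed onto the
prefusion one by least squares over the Cα atoms of a reference domain
(D1 by convention), putting both states in the reference domain's frame.
The least-squares proper rigid transform (R, t) carrying the prefusion
mobile-domain Cα set onto the reference-aligned postfusion set is then
decomposed as

- rotation angle θ = arccos((tr R − 1)/2), reported unsigned in [0°, 180°];
- rotation axis = the unit rotation vector of R, sign fixed so the
  largest-magnitude component is positive (an unsigned angle cannot
  distinguish ±axis; the convention stabilizes reports near 180°, where the
  foldback of D3 lives);
- center-of-mass displacement = |⟨x⟩_post − ⟨x⟩_pre| over the paired Cα
  centroids, with the axis anchored at the postfusion centroid.

Superpositions use the Kabsch algorithm with reflections forbidden
(`scipy.spatial.transform.Rotation.align_vectors`); at least three
non-collinear paired Cα atoms are required.  Centers of mass are unweighted
Cα centroids, matching the superposition atom set; an all-atom mode exists
but the default keeps the two computations self-consistent.

**Assumptions and limits.** The decomposition is exact only if the domain
really moves rigidly; internal deformation is absorbed into the reported
fit RMSD, which should be inspected.  No screw-axis pitch or hinge location
is computed — the readout is deliberately the angle + displacement pair.
Residue correspondences between different proteins come from a global
sequence alignment (match +1, mismatch −1, gap −2, configurable, via
Biopython) or a user-supplied table; for same-protein comparisons the
author-numbering identity map is used.  All residue addressing is author
numbering; the package never renumbers.

`max_extent` reports the maximum pairwise Cα–Cα distance (convex-hull
accelerated), the convention used for quoting a ~155 Å extended-ectodomain
length; glycans and other heteroatoms are excluded by the Cα filter.

## Negative-stain projection matching

**Density synthesis.** Each non-hydrogen atom contributes an isotropic
Gaussian with integrated weight equal to its atomic number and
σ = resolution/(π√2), the width at which the Gaussian's Fourier falloff
reaches the nominal resolution; the grid is then low-pass filtered with a
cosine-edged Fourier mask that is fully attenuating beyond 1/resolution
(edge starting at 75% of the cutoff).  At the 25 Å resolutions relevant to
negative stain, element-specific scattering factors are irrelevant and the
Gaussian-atom model is adequate.  The grid is cubic, padded ≥ 2σ around the
model; voxel size must be ≤ resolution/3 (default resolution/4).

**Projection.** The volume is resampled with cubic-spline interpolation
under the rotation taking the viewing axis to z (orientation = polar and
azimuthal angles of the view plus an in-plane angle, ZYZ convention) and
summed along z.  Pixel sums match voxel sums to ≲0.5%.

**Template bank.** Orientations form latitude rings at multiples of the
angular step from pole to equator, with ⌈360·sinθ/step⌉ azimuthal samples
per ring — a deterministic quasi-uniform hemisphere grid (projections of a
real density obey Friedel symmetry, so the opposite hemisphere is
redundant).  In-plane rotation is searched at match time, not banked.

**Matching.** Class averages are scored by Pearson correlation under a
circular mask (default 96% of the inscribed circle; zero-mean/unit-variance
normalization under the mask) against each template over all in-plane
rotations at the bank's step and all integer-pixel translations within a
quarter image (FFT search; the reported score is the exact masked Pearson
at the best shift, so |cc| ≤ 1 holds by construction).  Sub-pixel
refinement is not attempted: class averages are pre-centered upstream.

`particle_length` binarizes at a fraction of the image maximum (default
0.2), keeps the largest 8-connected component and returns its maximal
pairwise pixel distance in Å.  At 25 Å the blur extends a sharp edge by
roughly ±σ, so lengths read ~5% long at the default threshold.

A caution on identifiability: a strictly axially symmetric rod gives
projections that depend only on the polar angle, leaving the azimuth
unconstrained.  The orientation-recovery tests therefore use a rod with an
off-axis lobe, which is also the realistic shape regime (elongated
particles with lateral domain bumps).

## SEC-MALS protein-conjugate analysis

Per elution slice, three detectors constrain a two-component mixture of an
absorbing conjugate (glycoprotein) and a non-absorbing modifier (glycan or
detergent micelle):

    UV  = k_UV · ε_conj · c_conj
    RI  = k_RI · (dn/dc_conj · c_conj + dn/dc_mod · c_mod)
    LS  = k_LS · M_total · (dn/dc)_w² · c_total

with (dn/dc)_w the concentration-weighted refractive-index increment.  The
zero-angle (form factor = 1) light-scattering form is used: particles of
~15 nm are far below λ/20.  The solver reads c_conj from UV, c_mod from
the RI residual, and M_total from LS; component masses follow the solved
concentration weight fractions, M_conj = M_total·c_conj/c_total (stated
explicitly; commercial software does not document its convention).
Negative solved concentrations within 1e−6 g/L are clamped to zero; a more
negative RI residual raises an inconsistent-signals error, as does
scattering with strictly zero solute.  Peak masses are
concentration-weighted averages over a user-selected elution window.

The conjugate's own optical constants come from weight-fraction mixing,
ε_glycoprot = ε_prot·f_prot + ε_glycan·f_glycan (glycan and detergent
ε₂₈₀ = 0 by default) and likewise for dn/dc.  With the standard constants
(ε_prot = 1.411 mL·mg⁻¹·cm⁻¹, dn/dc 0.185/0.145 mL/g, f = 0.877/0.123)
these give 1.237 mL·mg⁻¹·cm⁻¹ and 0.1801 ≈ 0.181 mL/g.

The chromatogram generator co-elutes the two components in fixed mass
ratio under a Gaussian peak (defaults: 186,300 Da glycoprotein trimer +
75,770 Da micelle, 0.5 g/L apex, σ = 0.35 mL, 101 slices over 10–14 mL,
unit calibrations) with optional per-channel Gaussian noise as a fraction
of each channel's apex signal.  Noisy recovery tests integrate a ±1σ
window around the apex: tail slices at clamp-level concentration have
unbounded relative noise and would dominate a weight-averaged mass, which
is also why practitioners set peak windows.  No band broadening or
inter-detector volume offsets are modelled — real data need those
corrections upstream, so noise-free closure here validates the algebra,
not an instrument chain.

## Thermal unfolding (nanoDSF)

The fluorescence intensity ratio FIR = F350/F330 of tryptophan emission
rises as buried tryptophans become exposed.  The melt derivative is a
Savitzky–Golay (local quadratic) first derivative on the uniform ramp
grid; Tm is the global positive derivative peak, refined to sub-grid
precision by parabolic interpolation through the three points around the
maximum, and the onset is the lowest temperature where the derivative
first exceeds 10% of the peak height on the way up.  Additional peaks with
prominence ≥ 50% of the global peak are reported and flagged as
multi-transition.  A sign flag handles probes whose signal falls on
unfolding.  Half a smoothing window at each end of the ramp is excluded
from the peak search, because the smoother's boundary polynomial fits are
noise-inflated.

The API default window is 2.5 °C; for 0.5 °C-step ramps with ~1% FIR
noise the recovery tests use 5 °C, the matched-filter choice — the
derivative peak of a two-state transition with logistic width w ≈ 1.5 °C
has FWHM ≈ 3.5 w ≈ 5 °C, so a window of that size maximizes peak SNR
without biasing a symmetric peak.  Replicates combine as mean ±
half-range, the convention used when duplicate capillaries are reported.

The generator produces a van 't Hoff two-state curve with linear folded
and unfolded baselines on a 20–95 °C ramp at 0.5 °C steps; the stated
noise fraction applies to the FIR signal, with the two channels derived
consistently from the noisy ratio.  Aggregation, scattering artifacts and
baseline drifts of real capillaries are not modelled.

## Synthetic data and what passing tests mean

All generators are pure functions of (seed, parameters): same spec, same
bytes.  Each generator/analyzer pair closes the loop exactly in the
noise-free limit, and under the stated noise the estimators meet the
recovery bounds asserted in the test suite (angle to 1e−3° noise-free and
median error < 1° at 0.5 Å Cα noise; conjugate masses within 2% at 1%
signal noise; orientation within the angular step at SNR 3; Tm bias
< 0.2 °C and SD < 0.5 °C at 1% noise).  These results validate the
estimators against their own forward models; they do not certify
performance on real micrographs, chromatograms or melts, whose noise is
neither Gaussian nor white.  Structure-based end-to-end checks run on
synthetic stand-ins constructed at the literature magnitudes (a 155 Å
four-domain rod; a 168°/76 Å foldback of its distal domain; a 3.4 Å
perturbed "predicted model"); analysing deposited coordinate files uses
exactly the same code paths via the CLI.

## Numerical choices

- Rotation matrices are validated to orthogonality and det = +1 at 1e−6.
- Degenerate superpositions (< 3 pairs, collinear sets) raise rather than
  return ill-conditioned fits.
- Recovery assertions for constructed transforms use 1e−3 tolerances
  (float64 SVD noise is orders below that).
- Alternate locations resolve to the highest-occupancy conformer; waters
  and hydrogens are dropped on read by default.
- PDB coordinates round-trip at the format's 0.001 Å precision.
- Domain intervals are inclusive on both ends, in author numbering.  The
  default domain table places D3 at 458–564 (inferred from the 28–457
  two-domain construct); the D1/D2 and D2.1/D2.2 splits are placeholders
  that real analyses should override from a YAML config.

## Known limitations

- No flexible fitting, hinge detection or normal modes; strictly rigid
  two-state decomposition.
- No CTF or stain physics; the projection matcher assumes pre-centered,
  pre-normalized class averages.
- No band-broadening correction or angular (Zimm/Berry) extrapolation in
  MALS; single-angle, zero-angle form only.
- No ΔH/ΔG fitting for melts; Tm and onset are derivative-based readouts.
- Sequence-alignment correspondences are a fallback; for distant homologs
  a structure-alignment-derived user table is more faithful.
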