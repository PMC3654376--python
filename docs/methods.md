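# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `corticoh`.

## Patch tessellation and oriented equivalent dipoles

The cortical mesh (vertices in mm, triangles with consistent winding) is
partitioned into contiguous patches of a target area (1 cm² by
convention) by greedy region growing on the triangle adjacency graph:
seed triangles are placed by farthest-point sampling (hop distance,
deterministic given the configurable seed, default 0), patches grow one
triangle at a time always extending the currently smallest patch, and a
balancing pass then moves boundary triangles between adjacent patches —
preserving donor connectivity — until areas are equalized. Resulting
areas stay within [0.5, 2.0]x the target; the patch count is
`round(total area / target)`.

Each patch's dipole orientation is the normalized sum of its triangles'
cross products. The un-normalized cross product already carries the
triangle area, so the sum is area-weighted; normalizing to unit length
makes the patch amplitude in `J` carry all source strength. A patch
whose normals cancel (norm below 1e-6 of the patch area) is flagged
degenerate, given a +z axis, and logged. Both the weighting and the
unit-norm convention are package choices; a plain unweighted vector sum
differs negligibly on near-uniform meshes.

Patches are neighbors iff they share a mesh edge (not merely a vertex);
on hexagonal-like tessellations this yields the familiar ~6 neighbors.
By default adjacency does not cross the hemisphere boundary, so the
smoothness penalty never ties the hemispheres together; a flag relaxes
this. The Laplacian `W` has `w_ii = −1`, `w_ij = 1/N_i` for neighbors,
zero elsewhere; rows of connected patches sum to zero, so `W`
annihilates spatially constant sources. An isolated patch keeps a bare
−1 diagonal (its amplitude is penalized directly) with a logged warning.
`W` is not symmetric when neighbor counts differ; nothing downstream
assumes it is.

## Inverse estimation

`Ĵ = (KᵀK + α WᵀW + ridge·I)⁻¹ Kᵀ Φ` minimizes
`‖Φ − KJ‖² + α‖WJ‖²`. Because `WᵀW` annihilates constants it is
singular, so a ridge of `1e-10 · tr(KᵀK + αWᵀW)/n_patches` guarantees
invertibility; it perturbs solutions at the 1e-10 relative level. With
`α = 0` the plain least-squares solution is returned and a
rank-deficient lead field is an error.

When sensors < patches the solver switches to the representer form
`Ĵ = M⁻¹Kᵀ(K M⁻¹Kᵀ + I)⁻¹Φ` with `M = αWᵀW + ridge·I`, which only
factorizes a sensors x sensors matrix. `M` is ill-conditioned
(condition ~ 1/ridge), so two iterative-refinement steps on the normal
equations, each applying `(KᵀK + M)⁻¹` through the Woodbury identity,
restore agreement with the dense normal-equation solve to better than
1e-8.

Scalp data and lead-field columns are average-referenced before solving
(the standard dense-array convention); the low-level solver leaves
referencing to the caller, the pipeline applies it.

α is chosen by generalized cross-validation on a log grid
`10⁻⁶…10² × tr(KᵀK)/tr(WᵀW)`:
`GCV(α) = n‖Φ−KĴ_α‖² / tr(I−H_α)²`. Two tie rules matter. Scores within
1e-12 relative of the minimum resolve to the larger α (prefer
smoothing). For overdetermined systems only, residuals at the round-off
floor count as perfect fits and the smallest such α wins — when the
data are exactly consistent the least-regularized solution is correct.
The floor rule must not apply to underdetermined systems, which
reproduce any data at small α; GCV there compares genuine effective
degrees of freedom.

The minimum-norm variant is unweighted (`W = I`); depth weighting would
be a natural extension but is not implemented.

## Spike-locked epoching

Spike peak times are taken as given (detection is out of scope). Each
spike yields a [t−1.5 s, t+1.5 s) segment; spikes too close to an edge
are dropped with a warning. The central 3 s are carved into pre-spike
[t−1.5, t−0.5), spike [t−0.5, t+0.5), and post-spike [t+0.5, t+1.5)
epochs. All boundaries are `round(fs·t)` sample indices with half-open
intervals, so the three epochs tile the segment exactly; the spike
window is centered on the nearest sample to the peak. One-second epochs
make the spectral grid exactly 1 Hz. A non-integer `fs·1 s` floors the
epoch length with a warning, and the resulting bin spacing deviation is
reported rather than hidden.

For localization timing, `half_peak_time` returns the moment the rising
phase crosses 50% of the spike peak (linearly interpolated between
samples), which is less contaminated by propagated activity than the
peak itself. Polarity is auto-detected as the largest absolute extremum
unless forced.

## Coherence

Within each parcel the signed patch waveforms are averaged. Signed
averaging can cancel opposing dipoles within a parcel — a real hazard of
anatomical grouping on folded cortex, kept deliberately and covered by a
test.

Per epoch the parcel waveforms are demeaned and transformed with a
rectangular window (which preserves the exact 1 Hz resolution; a Hann
taper is available). Cross-spectra are averaged across spike epochs —
with one 1-s window per epoch this is the only averaging unit available
— and coherence is `|⟨X conj(Y)⟩| / sqrt(S_XX S_YY)` on integer-Hz bins
1–70. The magnitude of the complex mean cross-spectrum is a convention
of this package: it is required for a real value bounded in [0, 1]. A
single epoch makes the estimate identically 1; the package computes it
but logs a prominent warning. Bins with vanishing power are NaN and
excluded from band averages. The alternative estimator — coherence per
spike, then averaged — is not implemented; with one window per epoch it
degenerates to 1.

Band averages are unweighted means over delta {1–3}, theta {4–7}, alpha
{8–12}, beta {13–29}, gamma {30–70} Hz: boundary frequencies belong to
the upper band, delta starts at 1 Hz because the analysis range is
1–70 Hz, and gamma keeps its closed 70 Hz top.

Matrices order parcels right hemisphere first (each sorted by label), so
right-intra pairs fill the upper-left quadrant. Top-K edge extraction
(default K = 100) is per band with a pooled option; ties break by band
order then parcel indices, deterministically.

## Synthetic scenes

The generator emulates a patient recording with every input synthesized:

- **Mesh** — an icosphere (20·4^s triangles) deformed by ~24 random
  radial Gaussian bumps (±12% of the radius, width 0.35 rad,
  deterministic per seed). The bumps play the role of gyrification:
  a perfectly smooth sphere with purely radial dipoles is a degenerate
  geometry whose lead-field columns are maximally correlated, making
  the inverse problem look worse than anatomy warrants. Hemisphere
  labels split at x = 0.
- **Lead field** — infinite-homogeneous-medium dipole potentials
  `V = p·(r−r₀)/(4πσ|r−r₀|³)` (σ = 0.33 S/m) from patch centroids to 64
  Fibonacci-lattice sensors on a shell 15% outside the outermost vertex,
  average-referenced per column and globally rescaled to median column
  norm 1, fixing the amplitude units (one moment unit ≈ 1 µV at the
  sensors). No skull or scalp physics is modeled.
- **Sources** — per-patch 1/f Gaussian background (unit sd); a planted
  pair of patches near the ±x poles sharing a band-limited alpha
  component (coupling c = asymptotic in-band coherence: each focus gets
  `sqrt(c)·shared + sqrt(1−c)·independent`, amplitude 2.0); and a 70 ms
  biphasic (derivative-of-Gaussian) spike transient, amplitude 8, on
  the patch nearest the +z pole at ≥3 s spacings.
- **Parcels** — a coarser tessellation of the same mesh groups the 200
  patches into 20 parcels (~10 patches each). This matches the spatial
  extent of the inverse point spread (~80% of a source's reconstructed
  energy falls within the source patch and its first ring) and is the
  closest desk-scale analog of grouping ~2400 patches into ~80 Brodmann
  areas.

Everything derives from one seed; identical configs give byte-identical
ground-truth records.

What the simulation does not emulate: realistic skull/scalp conduction,
electrode caps, non-stationary background, artifacts, spike morphology
variability, or spatially correlated background sources. Passing tests
demonstrate the estimator chain is correct, not that clinical recordings
behave this way.

## Resolution limits of coherence mapping (measured)

Two regimes must be distinguished.

**Well-posed regime** (sensors ≥ patches, low noise): with 256 sensors
and 100 patches at zero sensor noise, sources are recovered essentially
exactly (per-patch correlation > 0.999 at α→0), and the planted
alpha-coupled pair ranks first among all parcel pairs in every seed
tested — uncoupled pairs sit near 0.3 while the planted pair reaches
~0.8 (dilution by parcel averaging accounts for the gap to the 0.9
ground truth).

**Underdetermined regime** (64 sensors, 200 patches): every parcel
waveform is a linear functional of the same ≤63-dimensional
average-referenced sensor signal, so uncoupled parcel pairs share
reconstructed background and exhibit a deterministic coherence floor —
the asymptotic parcel-pair coherence under the background covariance has
median ~0.8 at every regularization level, and the tenth-largest
alpha-band edge among 190 pairs is typically 0.87–0.93 even with no
planted coupling at all. A pair whose true coupling is 0.9 (hence whose
estimated coherence is below 0.9 by construction) cannot consistently
rank in the top 10 against that floor: across 100 seeded runs at the
default desk scale the planted pair lands in the alpha top-10 edges in
roughly a fifth of runs. This is the classic source-leakage limitation
of magnitude coherence on an underdetermined inverse; leakage-robust
variants (imaginary coherence, orthogonalization) are deliberately out
of scope here. Practical readings of the networks in this regime should
treat high-coherence edges as candidates shaped jointly by coupling and
leakage — which is also the appropriate caution for the clinical
setting this package addresses.

## Numerical conventions

- Coherence values above 1 by more than 1e-12 raise; values within that
  tolerance are clipped to 1. Matrices are symmetrized exactly and the
  diagonal forced to 1.
- EDF is written by a built-in 16-bit writer (1-s records, physical
  ranges quantized against their 8-character stored form) and read via
  MNE; round-trip error is bounded by one quantization step.
- Pipeline configuration is validated field by field with errors naming
  the offending field; CLI exit codes are 0 (success), 2 (validation),
  1 (runtime).
- Tests and the acceptance script use desk-scale problem sizes (icosphere
  level 3, 200 patches, 20 spikes, 30–100 replicates), chosen so the
  full study runs in minutes on one CPU while keeping every estimator in
  its intended regime.
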