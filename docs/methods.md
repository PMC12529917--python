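# Methods

This note records the models implemented in `phonorank`, the conventions
and defaults chosen where several were defensible, and what the synthetic
test data does and does not establish.

## Data model and conventions

A `ModeSet` is the universal input: one polymorph, one method, one
lattice-dynamics run. Frequencies are wavenumbers (cm⁻¹); **imaginary
modes are encoded as negative wavenumbers**, the convention of the common
phonon codes. Eigenvectors are stored **mass-weighted, real-valued and
unit-normalized** (Γ and commensurate q-points only; complex eigenvectors
are rejected at load). Mass weighting makes the eigenvector overlap a
proper inner product under which degenerate subspaces are orthonormal, and
it is the natural output basis of a diagonalized dynamical matrix. The
comparison of eigenvectors across codes is only meaningful with a fixed
normalization; this one is a package decision, documented here, not a
universal standard.

Atom ordering is part of the file contract: two sets are comparable only
if their atom count and a SHA-256 checksum over symbols + masses agree.
A mismatch raises, never warns — silently comparing re-ordered atoms
produces meaningless overlaps that look like physics.

Energies are kJ/mol **per cell** internally; all reported quantities
divide by the formula-unit count `z_formula`. Acoustic identification at
Γ requires both |ν| < 0.1 cm⁻¹ *and* an eigenvector within 10⁻³ of the
rigid-translation subspace; frequency alone misclassifies soft librations,
eigenvector alone misclassifies numerically contaminated acoustics.

Serialization is JSON with sorted keys and `repr`-exact floats: saves are
byte-stable and frequencies round-trip at full precision, so fixtures can
be diffed and checksummed.

## Raman synthesis

The measurable intensity of mode *m* under a laser of angular frequency
ω₀ at temperature T is

    I_m = (ω₀ − ω_m)⁴ / (c⁴ ħ ω_m) · [ 1/(e^{ħω_m/k_BT} − 1) + 1 ] · I'_m

with I'_m the orientation-averaged activity of the polarizability
derivative. Both ω₀ and ω_m are treated as angular frequencies —
consistent with the 532 nm default laser being quoted as
ω₀ = 2πc/λ = 3540.70 THz. All frequency/energy conversions route through
`phonorank.units` so the constants (CODATA via `scipy.constants`) are
auditable in one place.

Orientational averaging is the standard unpolarized powder combination
45ā² + 7γ² of the two rotational invariants. Only proportionality of I'_m
to the squared tensor is physically fixed; the 45/7 convention
(backscattering, unpolarized detection) is a package decision. It is
irrelevant to peak *positions* and only mildly reweights intensities;
after max-peak normalization (the standard presentation for polymorph
fingerprinting) the absolute scale cancels entirely, which is also why the
1/c⁴ prefactor convention question is moot.

Numerics: the Bose bracket at T = 0 is exactly 1 (no expm1 evaluation);
for ħω/k_BT > 700 the occupation underflows double precision and the
bracket saturates at 1 — monotonicity in T is strict only where the
increment is representable. The bracket diverges as ω → 0⁺, which is the
physical reason translational (and imaginary) modes are excluded from
synthesis; they are skipped with a logged count rather than raised,
matching the practice of plotting only real optical modes. Broadening uses
unit-area Lorentzians (FWHM default 10 cm⁻¹, mimicking instrumental
resolution); the default window 0–250 cm⁻¹ at 0.5 cm⁻¹ step covers the
lattice-mode region where polymorphs differ.

## Mode matching

Equivalent modes between two calculations are found by maximizing
Σ|e_i·e_j| over bijections — a linear sum assignment solved with SciPy's
Hungarian implementation. Decisions:

- **Absolute value of the dot product.** Eigenvector sign/phase is
  arbitrary between codes; equivalence means |overlap| = 1.
- **Symmetry blocking.** With irrep labels on both sets the problem is
  solved per label: modes of different irreps cannot mix, and blocks are
  smaller. If either set lacks labels the matcher falls back to one global
  block with a warning — blocking is an optimization plus a physical
  constraint, not a silent requirement.
- **Tie-breaking** is lexicographic via infinitesimal cost penalties: the
  overlap objective dominates (ε = 10⁻⁹ on a normalized frequency-gap
  penalty, 10⁻¹² on an index penalty); among equal-overlap optima the
  frequency-nearest pairing wins, then the lowest index. The index penalty
  couples row and column (a separable i+j term is permutation-invariant
  and would break no ties).
- **Degeneracy.** Individual overlaps within an exactly degenerate
  multiplet are basis-dependent; a 45° internal rotation halves them
  without any physical disagreement. The matcher therefore also reports a
  subspace-level overlap per pair (the norm of the overlap row over the
  partners matched to the multiplet), which stays 1 for a pure rotation.
  How any specific published assignment resolved degeneracies is not
  reconstructable; the subspace report is a mitigation.

The matched-frequency RMSD is computed over pairs whose *reference* (first
argument) frequency lies in a window, default 0–250 cm⁻¹ — the
intermolecular region that controls polymorph stability. Matched overlaps
below 0.4 are counted as "poor" in the histogram summary.

## Harmonic thermodynamics

    F(T, p) = E_DFT + Σ_{i,q} w_q [ ħω_iq/2 + k_B T ln(1 − e^{−ħω_iq/k_BT}) ] + pV

- The q-weights must sum to 1 (tolerance 10⁻¹⁰); the package consumes
  pre-interpolated q-point mode lists and does no Fourier interpolation of
  its own.
- **Frequency scaling** multiplies frequencies strictly above a threshold
  (default 250 cm⁻¹) by an empirical factor and is applied **before** all
  thermodynamic evaluation, so zero-point and thermal terms both see
  scaled frequencies. Published factors for the common Hamiltonian/basis
  combinations ship as a registry (`SCALING_FACTOR_REGISTRY`); the
  plane-wave GGA entry is 1.0 and the pob-TZVP/GGA entry reuses the
  def2-TZVP/GGA value, the closest benchmarked combination. Lattice modes
  are never scaled: the factors are benchmarked against molecular
  (intramolecular) references only.
- **pV** uses the fixed athermal optimized volume (constant-volume
  harmonic approximation; geometries are relaxed without vibrational
  contributions, thermal expansion neglected). One audited constant
  converts MPa·Å³ → kJ/mol. The quasi-harmonic extension is out of scope.
- Mode sets with imaginary nontranslational modes are refused with the
  offending indices; near-zero modes that pass the rigid-translation test
  are classified acoustic and excluded.

The polymorph difference ΔF is partitioned by spectral band: a static term
ΔF_DFT (electronic difference with the pΔV work folded in — at p = 0 the
fold is zero, so the choice of where to report pΔV is invisible in
zero-pressure partitions), then lattice [0, 250), fingerprint [250, 1750),
an explicit **gap band [1750, 2500)** and stretches [2500, ∞) cm⁻¹. The
gap band exists so the bands exactly partition [0, ∞) and the components
sum to the total to 10⁻⁹; it is expected empty for acetaminophen-like
spectra and warns if populated. Band membership is decided on the *scaled*
frequency — the one that enters the mode sum — so conservation is exact.
Note the partition's band edges (stretches from 2500) intentionally differ
from the generator's stretch band (above 2800): the empty 2500–2800 window
makes the two coincide in practice.

## Phase diagrams

At fixed volumes ΔF(T, p) = ΔF(T, 0) + p·ΔV·conv is exactly affine in p,
so the coexistence pressure p*(T) is a closed-form root — no tolerance
games. A bisection fallback (Brent) exists for future volume-dependent
models and is cross-checked against the closed form in the tests.
Columns where ΔF ≡ 0 (identical inputs) yield no isolated boundary point.
Nodes with |ΔF| ≤ 0.1 kJ/mol per formula are masked "uncertain" — a
typical scale both for harmonic-DFT ranking errors and for the error bars
drawn on published diagrams; the threshold is a named, configurable
constant. Default window 0–400 K × 0–1000 MPa at 5 K / 10 MPa steps,
endpoints inclusive; the grid spacing is a package choice (fine enough
that boundary interpolation error is invisible at plot scale), not a
reconstruction of any published figure.

The experimental topological form I/II boundary is encoded as
p(MPa) = −0.3182·T(K) + 394.25 and extrapolates linearly outside the
fitted range; callers clip to the physical window.

`volume_percent_error` is the signed 100·(V − V_exp)/V_exp bookkeeping
used in geometry-benchmark tables; its tests verify that experimental
volumes back-derived from any row of such a table reproduce every other
row's printed percentage within rounding (±0.02 points).

## Synthetic data: what it emulates, what it does not

The generator produces mode sets with the statistical *shape* of a
lattice-dynamics run on an acetaminophen-like crystal:

- three spectral regions — lattice 20–250 cm⁻¹ (~15% of modes),
  fingerprint 250–1750 cm⁻¹ (~70%), X–H stretches 2800–3600 cm⁻¹ (~15%) —
  with 1750–2800 cm⁻¹ empty, as observed for this class of crystal;
  frequencies are uniform within each band;
- exactly orthonormal eigenvectors (QR of a seeded Gaussian matrix,
  completed around the exact mass-weighted rigid translations at Γ), with
  a sign convention (first nonzero component positive) making output
  bit-reproducible across platforms;
- random symmetric Raman tensors whose magnitude decays with band
  (lattice 1.0, fingerprint 0.5, stretch 0.3 — chosen so the low-frequency
  window dominates the powder spectrum, as in the real material);
- default formula counts (4, 8) and experimental-scale volumes
  (741.2, 1441.2 Å³) mirroring the monoclinic/orthorhombic cells; default
  electronic-energy offset 1 kJ/mol per formula, the order of magnitude of
  real polymorph gaps. Note both generated sets share `n_atoms` per cell,
  so with unequal z the per-formula vibrational terms differ by
  construction; pair studies meant to emulate a physical ranking (as in
  the README example) should use equal z or interpret per-cell quantities.
- atoms cycle through the C₈H₉NO₂ composition so masses are realistic.

The **method-change perturbation** stands in for a basis-set/Hamiltonian
switch: frequencies gain a multiplicative bias and relative Gaussian noise
(defaults in tests: 2% noise, matching the observed cross-method scatter
of lattice modes), eigenvectors of modes closer than a 5 cm⁻¹ gap are
mixed pairwise by a fixed rotation angle, modes are shuffled within each
(q, irrep) block, and the electronic energy shifts. The rotation angle is
applied exactly (not sampled) so overlap geometry is deterministic:
a 90° rotation of a degenerate pair yields overlap 0 against the origin
and 1 against the partner. The true permutation is returned for recovery
scoring.

What passing tests on this data shows: the pipeline's algebra, conventions
and solvers are correct, and assignment recovery is exact under
cross-method distortions of the magnitude actually observed for lattice
modes. What it does not show: that any particular electronic-structure
method reproduces real spectra or stability orderings — real eigenvectors
have molecular structure (rigid-body vs internal character), real
frequency errors are systematic not uniform, and real Raman tensors are
far from random. Claims of that kind need real DFT output, which this
package consumes but does not produce.

## Problem sizes

The shipped tests and the acceptance script run on cells of 6–20 atoms
with 1–2 q-points and matching blocks of ≤ 63 modes — sizes at which
brute-force enumeration (≤ 6!) and 100-trial recovery sweeps are
instantaneous while exercising every code path; all quantities checked
(limits, invariances, conservation, exactness of roots) are
size-independent properties.

## Known limitations

- Harmonic, constant-volume only: no quasi-harmonic volume relaxation, no
  anharmonic corrections. Boundary positions at high T or p inherit the
  constant-volume bias.
- Γ-only Raman; no resonance effects, no polarization-resolved spectra.
- Matching operates within one q-point (Γ) and never re-diagonalizes
  dynamical matrices; modes are matched, not re-derived.
- The mode-set reader accepts only real eigenvectors; band-structure
  output at incommensurate q requires pre-processing elsewhere.
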