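# Methods

This note records the models and numerical choices behind each pipeline
stage, the assumptions they rest on, and what the synthetic study
conditions do and do not establish about real data.

## IRMPD–VUV cross-section model

The extraction formula assumes an idealized kinetics: during the IR
macropulse every ground-state molecule is excited with rate Φσ(ν), so
the surviving fraction after exposure τ is exp(−Φστ); once excited, the
molecule dissociates with certainty.  The VUV probe ionizes parents and
fragments with equal summed probability, detection efficiency is
mass-independent, and an unknown but IR-frequency-independent fraction
of ionized parents fragments after ionization.  Under these assumptions

σ(ν) = (1/Φτ)·[ln P_off/(P_off+F_off) − ln P_on/(P_on+F_on)],

and the IR-off reference cancels the post-ionization term exactly — in
expectation the estimate is invariant to the fragmentation fraction,
which the acceptance suite verifies against a generative twin of the
same model.  The photon measure Φτ is taken proportional to pulse
energy divided by photon energy (∝ E/ν); only relative σ values are
meaningful, so the proportionality constant defaults to 1.  Negative σ
values (noise below baseline) are flagged, never clamped, to keep the
noise statistics unbiased.  Saturation and multi-photon kinetics beyond
the single-rate model are out of scope; if depletion is total
(P_on = 0) the estimate is undefined and an error is raised rather than
a clipped value returned.

## Harmonic spectra

Band frequencies are multiplied by 0.98, the empirical scaling specific
to B3LYP harmonic analyses, *before* broadening; the Gaussian width
σ = 0.01·ν is evaluated at the scaled frequency because the width
models the spectrometer line width at the observed position.  Each band
(ν, I) becomes a Gaussian of mean ν integrating to I; on the default
grid (0.5 cm⁻¹ spacing over 300–1900 cm⁻¹, covering the 340–1820 cm⁻¹
measurement window with margin) the trapezoid integral of every band is
conserved to well within 0.1%, and a coverage error is raised if a band
± 5σ leaves the grid rather than silently truncating intensity.
Composites are abundance-weighted pointwise sums.  The similarity score
(cosine of mean-subtracted spectra) is a convenience for ranking
predicted-versus-measured agreement; no normalization convention of
plotted intensities is asserted.

## Dynamics-based spectra

Via the Fermi golden rule and the Wiener–Khintchine theorem the
absorbance of a classical dipole trajectory reduces to the power
spectral density of μ(t).  Per Cartesian component the mean is removed,
a Hann window applied (spectral-leakage control), the series zero-padded
(default ×4) and transformed; squared magnitudes are summed over
components and normalized by the sample count, which makes total PSD
power equal the time-domain energy (Parseval) when window and padding
are disabled.  Three absorbance prefactors are provided — none (raw
PSD), ν² (default; the classical golden-rule prefactor for a
dipole-power spectrum), and the harmonic quantum correction
ν·(1 − e^{−hcν/k_BT}) — because conventions differ between
dipole-autocorrelation formulations; all three share peak positions,
which is what the downstream analysis consumes.

Spectra are averaged over independent runs (the protocol uses 30) and
frequency-scaled by the same 0.98 factor.  The finite trajectory length
τ already implies a line width σ_τ = κ/(c·τ); the make-up broadening
convolves each output point ν with a Gaussian of variance
(0.01·ν)² − σ_τ², skipped where the difference is non-positive, so the
final width matches the instrument model without double-broadening.
κ defaults to 0.5 and is configurable — only the variance-composition
contract matters to the pipeline, not κ's particular value.  The
convolution kernel is evaluated locally at each output frequency
(O(N·K) rather than FFT) to remain faithful to the ν-dependent width.

The MD protocol itself is reproduced on analytic model potentials
(site/bond harmonic springs, Morse pairs, point charges for the dipole):
initial Maxwell–Boltzmann velocities with temperature parameter 2T so
each mode carries k_B·T after equipartition, removal of linear and
angular momenta by projection (pseudo-inverse of the inertia tensor, so
collinear systems lose only their well-defined rotation axes), and
velocity-Verlet integration in amu/Å/fs units.  Model potentials keep
every downstream stage testable at desk scale; they do not reproduce the
anharmonic mode coupling of a real peptide on an electronic-structure
surface, so passing tests validate the *processing chain*, not any
specific molecule's spectrum.  Velocity-Verlet total energy oscillates
boundedly with relative amplitude ≈ (ωΔt)²/8 and shows no secular
drift; the test suite asserts exactly that (an instantaneous-energy
conservation much tighter than (ωΔt)²/8 is not a property this
integrator has).

## Time-step blue shift

On a harmonic mode velocity Verlet oscillates at exactly
ν_D = (2/Δt)·asin(ωΔt/2)/(2πc), a blue shift of leading order
ν·(ωΔt)²/24.  In the dimensionless frequency x = ν·c·Δt (non-angular
convention, the only one consistent with the shipped calibration triple)
the shift obeys Δx = a·x^b independent of mass and force constant.  Two
named profiles ship: `admp-b3lyp-n07d` (a = 2.95, b = 3.25, the
published calibration of the ADMP propagator — evaluating it at
1900 cm⁻¹ and 0.5 fs gives 1.87 cm⁻¹, under the 2 cm⁻¹ negligibility
bound) and `velocity-verlet` (a = (2π)²/24 ≈ 1.645, b = 3, the analytic
leading order).  Fitting is least squares of log Δx on log x;
zero-or-negative shifts carry no log-space information and are excluded
with a warning.  The inverse correction solves ν_H + Δν(ν_H) = ν_D by
Newton iteration to 1e-8 cm⁻¹; forward and inverse are mutual inverses
to 1e-6 cm⁻¹ across the calibrated range.  Note the pure power law is a
leading-order model: at ωΔt ≈ 0.9 (e.g. 1600 cm⁻¹ at 3 fs) the next
asin term contributes ~9%, so a log–log fit over such a wide step range
recovers the exponent well but biases the fitted constant high; the
constant is recovered to better than 2% only in the small-step regime
(Δt ≤ 1 fs for the frequencies tested).

The classical-versus-quantum width argument is implemented as
k_B·T = h·c·ν (1439 K at 1000 cm⁻¹, "around 1500 K"); equating
classical and quantum ground-state position variances instead would
give roughly half that, and the choice is documented rather than
asserted as unique.

## Conformer analysis

Torsions use the IUPAC sign convention.  The informative set for an
n-residue peptide is 2n angles ordered from the N-terminus: φ_N
(backbone extended to the centroid of the amine hydrogens), the
interior φ/ψ pairs, and ψ_C (extended to the carboxyl hydroxyl oxygen).
ω torsions are retained as metadata only — the peptide bond's π
character locks them trans — and χ angles are not classified.
Classification uses symmetric 60°-wide sectors by absolute value:
cis |θ| < 30°, gauche to 90°, anticlinal to 150°, trans beyond; the
ten-position name replaces the torsions whose central bonds lie on a
detected turn's covalent ring path with a bracketed token ([C5]: φ_i,
ψ_i; [γ]: φ_{i+1}, ψ_{i+1}; [β]: φ/ψ of i+1 and i+2), keeping the
string unambiguous.  Torsion signs (G+ vs G−) are not distinguished in
names.

H-bonds from a density grid follow the NCI triplet: a corridor point
between the hydrogen and the acceptor must have ρ ≥ 18 nm⁻³ (15–18 for
a weak interaction), reduced density gradient
s = |∇ρ|/(2(3π²)^{1/3}ρ^{4/3}) ≤ 0.5, and second Hessian eigenvalue
λ₂ ≤ 0.  s is dimensionless for any consistent length unit, so densities
canonically in nm⁻³ (the unit of the thresholds; cube files in atomic
units are converted by 6748.33 nm⁻³/a.u.) need no rescaling.
Derivatives are central finite differences at one grid spacing;
gradient *components* are interpolated and the norm taken afterwards,
because the magnitude has a conical minimum at the bond critical point
and interpolating it directly overestimates s exactly where the
criterion bites.  Corridor points within 0.5 Å of any nucleus are
excluded — the criteria characterize interstitial density bridges, not
nuclear/covalent regions.  The geometric fallback (H···A ≤ 2.5 Å,
D–H···A ≥ 120°, common literature cutoffs) is used when no grid is
available and reports no strength.  Ring order is 1 plus the atom count
of the shortest covalent path from the donor heavy atom to the
acceptor: 5 for the intra-unit NH···O contact, 7 for a γ-turn (i, i+2),
10 for a β-turn (i, i+3).

The conformer distance is the minimal root-sum-square of atom
displacements (MRSSAD = RMSD·√N) over proper rigid motions and atom
reindexings.  Reindexing is restricted to orbits of the covalent-graph
symmetry refined by element (iterative neighborhood-signature
refinement) — the full permutation group is both chemically wrong and
intractable — and reflections are excluded so enantiomers of a chiral
peptide do not collapse to zero distance.  All atoms carry equal
weight.  The minimum is found by alternating Kabsch superposition with
optimal within-orbit assignment (Hungarian), restarted from the
identity correspondence plus random initial orientations (default 10
starts, seed 0); on small instances this matches exhaustive enumeration
exactly, and the triangle inequality holds on sampled triples.  The
conformer graph draws an edge below 10 Å and marks the Kruskal minimal
spanning forest, ties broken by lexicographic node order.

Abundances are Boltzmann weights of Gibbs energies at a common
temperature (default 400 K, the laser-desorption estimate), computed
with the minimum energy subtracted for numerical stability; ranks and
"A*n*" short names follow ascending energy.

## Synthetic study conditions

The generators fix the conditions under which the pipeline is
validated.  Dipole signals are sums of cosines (default 0.5 fs
sampling, 2.5 ps duration — the BOMD protocol's step and length) with
optional white noise.  Toy peptides are ideal-geometry polyalanines
built by internal-coordinate chaining; requested backbone torsions are
realized essentially exactly (well under 1°), and turn motifs use
canonical torsion values (type-I β, inverse γ, extended C5).  Density
grids are sums of atom-centered Gaussians plus a bridge Gaussian at the
H···acceptor midpoint whose amplitude is solved so the total midpoint
density equals the requested peak — giving a genuine (3,−1)-like bridge
feature with vanishing reduced gradient and λ₂ < 0.  Ion counts are
binomial draws from the same survival/fragmentation model the estimator
assumes (default 1e5 molecules per frequency, 10% post-ionization
fragmentation).  Everything is seed-deterministic.

What these conditions do not probe: real electron densities (the
analytic grids have no shell structure), anharmonic couplings and
temperature-dependent line shapes of real molecules, saturation effects
in the ion source, and conformer geometries of any particular peptide —
those require electronic-structure inputs that are deliberately outside
this package's scope.

## Problem sizes

Default test-suite scales, chosen as the smallest that expose each
property cleanly: integrator-law recovery uses five frequencies
(400–1600 cm⁻¹) × three steps with 2.5 ps runs (10 ps in the small-step
companion check, where sub-0.01 cm⁻¹ shifts must be resolved); metric
axioms use 200 sampled triples of 4-atom systems and exhaustive-oracle
comparisons on 8-atom systems; estimator recovery uses 20 frequencies at
1e5 counts each.
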