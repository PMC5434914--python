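# Methods

## Model

`amideir` treats the Amide I band of a protein as a system of coupled local
carbonyl-stretch oscillators.  For each structure snapshot it builds an
N×N one-quantum exciton Hamiltonian H (N = number of backbone amide
linkages), diagonalizes it, lifts it to the N(N+1)/2-dimensional symmetric
two-quantum space, and evaluates 1D absorption and absorptive 2D-IR spectra
from the eigenstates.  Snapshot spectra are averaged with uniform weights;
all inhomogeneous broadening therefore comes from structural disorder
across snapshots, and homogeneous broadening is modeled by fixed convolution
kernels.

### Chromophores

One site per backbone amide linkage: the C=O of residue k with the N–H of
residue k+1.  Terminal ammonium/carboxylate groups and Gln/Asn side-chain
amides are not chromophores (their atoms still contribute point charges).
A C(k)–N(k+1) distance above 2.0 Å is a chain break: no site, a warning is
logged.  If the amide hydrogen is absent from the input (common in crystal
structures) it is constructed in the O=C–N plane with N–H = 1.02 Å,
antiparallel to C=O, and the construction is logged.  Each site stores
φ of its following residue and ψ of its preceding residue — the two
main-chain dihedrals that always exist for an interior linkage — so the
(φ, ψ) of the residue shared by two adjacent sites is available for the
coupling-map lookup.

### Site energies (electrostatic frequency map)

ω_k = ω₀ + Σ_j l_j φ_{k,j}, with the Coulomb potential φ evaluated at the
four amide atoms (C, O, N, H) of site k over all point charges in the
system except those four atoms themselves.  Parameters:

| parameter | default | unit | role |
|---|---|---|---|
| ω₀ | 1680 | cm⁻¹ | central frequency of an unperturbed site |
| l_C, l_O, l_N, l_H | 0.00160, −0.00554, 0.00479, −0.00086 | e | linear response of the mode frequency to the potential |
| proline frequency | 1653 | cm⁻¹ | fixed diagonal for X–Pro linkages (no amide H) |
| isotope shift | 65 | cm⁻¹ | ¹³C¹⁸O red shift applied to labeled diagonals |
| potential unit scale | a₀[Å] × E_h[cm⁻¹] ≈ 1.1614×10⁵ | — | converts Σ q/r (e/Å) into cm⁻¹ per e |

The potential-unit choice deserves a note: the map's l coefficients are in
units of e, so e·φ must be an energy in cm⁻¹.  We evaluate φ in atomic
units (distance Å → Bohr) and convert Hartree → cm⁻¹; the combined constant
is exposed as `SiteEnergyParams.potential_unit_scale` and recorded in
output metadata.  Under this convention a hydrogen-bonded first-shell water
shifts a site by −10 to −40 cm⁻¹, and a thin solvation shell shifts the
band maximum of a helix fixture red by ~5–15 cm⁻¹ — the physically expected
magnitude regime (full solvation shifts the band several tens of cm⁻¹).

Charges come from a user-suppliable two-column table (`ATOM` or
`RES:ATOM` keys).  The built-in default carries the standard backbone amide
charges (C +0.51, O −0.51, N −0.47, H +0.31 e) plus an effective Cα charge
of +0.16 e that absorbs Hα and the alanine side chain so that a
backbone-only fixture residue is neutral.  Waters are fixed TIP3P
(O −0.834, H +0.417 e); monoatomic ions carry formal charges.  Backbone
amide charges carry the owning site's index so the self-exclusion rule is
exact; every other protein atom is categorised "sidechain" so that
solvent-only or protein-only potentials can be formed by category
filtering.

### Couplings

Sequence-adjacent sites within a chain use a nearest-neighbor coupling map:
a periodic 13×13 grid over (φ, ψ) ∈ [−180°, 180°] in 30° steps, bilinearly
interpolated on the torus (exact at nodes, wrap-around across ±180°),
queried at the shared residue's dihedrals.  All other pairs — including
across chain breaks and between chains — use transition dipole coupling
with the dipole placed 0.868 Å from the carbonyl carbon along C=O, tilted
20° toward N in the OCN plane, magnitude 3.7 D Å⁻¹ amu⁻¹ᐟ².  The printed
TDC prefactor 0.1/ε with these units does not fix an absolute cm⁻¹ scale
by itself, so the implementation keeps it verbatim ("internal units",
ε = 1 by default, solvent is explicit) and exposes a `tdc_scale`
multiplier for physical calibration; the value used is written into every
output header.  Proline sites couple normally — only their diagonal is
fixed.

### Two-quantum space

Pair states |mn⟩ with m ≤ n.  Diagonal: overtones 2H_mm − Δ, combinations
H_mm + H_nn, with Δ = 16 cm⁻¹ by default.  Off-diagonal:
overtone↔combination sharing a site is √2·H, combinations sharing exactly
one site couple by the corresponding one-quantum element, disjoint pairs do
not couple.  The √2 is the bosonic matrix element ⟨2|a†|1⟩ = √2; the same
factor appears in the two-quantum transition dipoles
μ_{n→(m,n)} = √2 μ_n δ_{mn} + μ_m(1−δ_{mn}).  The construction is verified
in the test suite against an explicit two-boson product-basis oracle, and —
the decisive end-to-end check — with Δ = 0 the total 2D signal cancels to
machine precision for arbitrary Hamiltonians, couplings and dipoles.  Only
the √2 convention has this property.

### 2D response

The spectra are static: each snapshot is frozen, t₂ = 0, and the absorptive
signal is the sum of the six standard rephasing + nonrephasing double-sided
pathways evaluated in the eigenbasis:

* ground-state bleach (two diagrams): +2·O(μ_a, μ_a, μ_b, μ_b) at (E_a, E_b)
* stimulated emission, rephasing: +O(μ_a, μ_b, μ_a, μ_b) at (E_a, E_b)
* stimulated emission, nonrephasing: +O(μ_a, μ_b, μ_b, μ_a) at (E_a, E_a)
* excited-state absorption, rephasing: −O(μ_a, μ_b, μ_{b→c}, μ_{a→c}) at (E_a, F_c − E_a)
* excited-state absorption, nonrephasing: −O(μ_a, μ_b, μ_{a→c}, μ_{b→c}) at (E_a, F_c − E_b)

with a, b one-exciton and c two-exciton eigenstates, μ_{a→c} the eigenbasis
two-quantum dipoles, and O the isotropic four-point orientational factor:
⟨ZZZZ⟩ = (1/15)(cosθ_αβcosθ_γδ + cosθ_αγcosθ_βδ + cosθ_αδcosθ_βγ),
⟨ZXXZ⟩ = −(1/30)(cosθ_αβcosθ_γδ − 4cosθ_αγcosθ_βδ + cosθ_αδcosθ_βγ),
enhanced = ⟨ZZZZ⟩ − 3⟨ZXXZ⟩.  Dipole magnitudes are folded into O by using
unnormalised vectors.  A useful identity that the tests exploit: under the
enhanced combination the net positive (bleach + rephasing-SE) weight at
every stick position cancels exactly, so enhanced spectra are carried by
the anharmonically shifted excited-state absorption — which is why the
scheme suppresses diagonal peaks and sharpens cross-peaks.

Line shapes: 1D sticks are convolved with a unit-area Gaussian of FWHM
4 cm⁻¹; 2D sticks with a separable 2D Lorentzian of FWHM 10 cm⁻¹ per axis.
The "bandwidth" of the 2D kernel is read as FWHM (configurable); the choice
is recorded in metadata.  Default grids: 1500–1800 cm⁻¹ step 0.5 (1D) and
1520–1780 cm⁻¹ step 1.0 (2D), wide enough to hold 65 cm⁻¹ isotope shifts.

### Analyses

* **Delocalization** — squared eigenvector coefficients per site; sites
  above a threshold (default 0.25) are flagged dominant; the inverse
  participation ratio is reported.
* **Hydrogen-bond statistics** — for every (site, snapshot), the
  solvent-only frequency shift (potential restricted to water charges)
  binned by the number of water hydrogens donating to the carbonyl oxygen
  (H···O ≤ 2.6 Å and O_w–H···O ≥ 130°, both configurable; counts of 2+
  share a bin).  Proline sites are excluded (their frequency is not map-
  derived).
* **Isotope-label selection** — sites are labeled when their carbonyl
  (preceding) residue carries the targeted secondary-structure label:
  helix = {H, G} (the 3₁₀ inclusion is a toggle), sheet = {E}.  The
  carbonyl residue decides because ¹³C¹⁸O substitution sits on that
  residue's C=O group.
* **Per-residue dipole strength** — |μ|⁴/residue is the sum over the
  positive diagonal bleach contributions of |μ_a|⁴ (orientational factor
  divided out), divided by the residue count; |μ|²/residue is its square
  root.  Positive (bleach) diagonal sticks are used; this choice is the
  one that makes the two columns consistent by construction.

## Synthetic data

The fixtures module emulates the inputs a solvated-MD workflow would
provide:

* **Ideal backbones** built by internal-coordinate chaining with fixed
  bond lengths/angles (N–Cα 1.458, Cα–C 1.525, C–N 1.329, C=O 1.231,
  N–H 1.02 Å; ω = 180°): helices at (−57°, −47°), antiparallel sheets at
  (−139°, +135°) with ~4.8 Å strand spacing and alternating strand
  direction, dipeptides at arbitrary (φ, ψ).
* **Solvation shells** — rigid TIP3P waters rejection-sampled into a
  3–6 Å shell (configurable) with a 2.2 Å overlap cutoff.  A water whose
  oxygen is within 5 Å of a protein oxygen is oriented to donate one O–H
  toward the nearest such acceptor (random azimuth); others are oriented
  uniformly at random.  The hydrogen-bonding orientation preference is the
  salient feature of first-shell water around carbonyls and the physical
  origin of the solvent red shift; a fully random-orientation shell has a
  zero-mean electrostatic effect and would make the red-shift property a
  coin flip.
* **Perturbed ensembles** — independent Gaussian displacement per atom
  coordinate (model 0 unperturbed).  Spectral ensembles use 0.02 Å: large
  enough to produce measurable inhomogeneous broadening, small enough that
  bond lengths stay within the chromophore validity windows
  (C–N ∈ [1.2, 1.5] Å is only ~4.6σ away at this amplitude).
* **Resampled-shell ensembles** — snapshots sharing the solute but with
  independently drawn solvation shells, emulating the fact that solvent
  rearranges much faster than backbone.  Solvent-effect statistics (band
  shift, H-bond histograms) are computed on these.
* **Coupling map** — a low-order random Fourier series on the torus,
  scaled into ±10 cm⁻¹: smooth, periodic edges exactly equal,
  byte-reproducible under a seed.

What the generator does **not** emulate: real conformational basins
(jitter is isotropic Gaussian, not a force field), water structure beyond
the first-shell orientation bias (no H-bond network, no density
correlations), side chains (poly-alanine backbone only) and capped termini.
Passing tests therefore demonstrate the correctness of the spectroscopic
machinery and the qualitative solvent/disorder physics, not quantitative
agreement with any particular protein's measured band positions.

## Numerical choices

* Symmetric eigenproblems via LAPACK (`eigh`); eigenvector phase fixed by
  making the largest-magnitude component positive, so delocalization
  reports are reproducible under degeneracy.
* Bilinear torus interpolation uses the 12 independent grid nodes; the
  +180° row/column is validated against the −180° one on load.
* The ESA pathway sums are vectorised with einsum over (a, b, c); cost is
  O(N²·P) with P = N(N+1)/2, comfortably fast to N ≈ 50 per snapshot.
* Stick weights below absolute 0 are kept (cancellation tests aggregate by
  position); the 2D convolution drops exactly-zero weights and chunks the
  kernel evaluation to bound memory.
* Study-condition sizes (chosen once, used by tests and the acceptance
  script): 12-residue helices, 2×6 sheets, 90-water shells, 16–24 solvent
  resamples, 100-model jitter ensembles.  All end-to-end checks run in
  seconds on one CPU.

## Design decisions on open points

* The one/two-quantum "2" vs √2 prefactor ambiguity is resolved to √2 (see
  above); only √2 reproduces the boson-ladder oracle and the harmonic-limit
  cancellation.
* The two-quantum space is N(N+1)/2-dimensional (symmetric pair states),
  not N².
* Absolute unit conventions of the TDC prefactor and the electrostatic
  potential are explicit, configurable constants recorded in output
  metadata rather than hard-wired claims.
* Snapshot similarity (most/least similar to the ensemble mean) is plain
  Euclidean distance on the common grid, unnormalised — absolute intensity
  differences are informative.
* The ensemble-broadening check compares the mean band's second moment with
  the unperturbed reference structure's convolved spectrum.  The stronger
  statement "broader than every individual snapshot" is not attainable
  under independent per-atom disorder: the mean's second moment is the
  average of the single-snapshot moments plus the (small) centroid
  variance, so the widest single snapshot always exceeds it.
* Config files are flat `key = value` text; CLI flags override file values;
  every output embeds the resolved configuration.

## Limitations

* Static snapshots: no waiting-time dynamics, spectral diffusion or
  motional narrowing (line widths from frozen snapshots can be
  overestimates); no non-Condon effects.
* Dipole approximation for through-space couplings (no transition-charge
  or multipole corrections); NNC map accuracy is bounded by the supplied
  grid.
* The electrostatic map is linear in the potential; strong fields and
  charge transfer are outside its validity.
* PDB is the only structure format; trajectories must be converted to
  multi-model PDB upstream.
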