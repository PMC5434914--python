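# amideir

Vibrational-exciton simulation of protein **Amide I** infrared spectra:
ensemble-averaged 1D absorption and static absorptive **2D-IR** spectra
computed from structure snapshots.

The Amide I band (≈1600–1700 cm⁻¹, dominated by the backbone C=O stretch) is
the workhorse probe of protein secondary structure and conformational
dynamics.  `amideir` is for spectroscopists and computational chemists who
want to connect structural ensembles (multi-model PDB files, e.g. MD
snapshots) to measured 1D and 2D-IR line shapes: which residues a band comes
from, how delocalized its underlying modes are, what solvent exposure does to
it, and where an isotope-labeled segment will appear.

## The model

Each backbone amide linkage is one local mode ("site").  The one-quantum
exciton Hamiltonian is built per snapshot:

* **Diagonal** — electrostatic frequency map:
  `ω_k = ω₀ + Σ_j l_j φ_j`, where φ_j is the Coulomb potential of all
  atom-centered partial charges (protein, solvent, ions; the site's own four
  amide atoms excluded) evaluated at the site's C, O, N, H atoms, and l_j are
  linear expansion coefficients in e.  Defaults: ω₀ = 1680 cm⁻¹,
  l = (0.00160, −0.00554, 0.00479, −0.00086) e for (C, O, N, H).  Proline
  sites are fixed at 1653 cm⁻¹; ¹³C¹⁸O isotope-labeled sites are red-shifted
  by 65 cm⁻¹.
* **Nearest-neighbor coupling** — sequence-adjacent sites couple through
  bonds; the coupling is looked up by bilinear interpolation on a periodic
  13×13 map over the shared residue's (φ, ψ) dihedrals (30° grid).
* **All other couplings** — transition dipole coupling (TDC):
  `f_ij = (0.1/ε) κ_ij m_i m_j / r_ij³`, with each site dipole
  (|μ| = 3.7 D Å⁻¹ amu⁻¹ᐟ²) placed 0.868 Å from the carbonyl carbon along
  C=O and tilted 20° toward the amide nitrogen in the OCN plane.

The two-quantum Hamiltonian is the symmetric two-boson lift of H (dimension
N(N+1)/2) with overtone anharmonicity Δ = 16 cm⁻¹, and two-quantum
transition dipoles `μ_{n→(m,n)} = √2 μ_n δ_{mn} + μ_m (1−δ_{mn})`.  The
absorptive 2D signal is the static (t₂ = 0) frequency-domain sum over the
standard rephasing + nonrephasing third-order pathways: positive
ground-state bleach / stimulated emission, negative excited-state
absorption, each weighted by the isotropic orientational factor of the
⟨ZZZZ⟩ or ⟨ZXXZ⟩ polarization scheme; the cross-peak-enhanced signal is
⟨ZZZZ⟩ − 3⟨ZXXZ⟩.  Sticks are broadened with a 4 cm⁻¹ FWHM Gaussian (1D) or
a separable 10 cm⁻¹ FWHM 2D Lorentzian, and snapshot spectra are averaged
uniformly.

A fixtures module generates every input synthetically — ideal helices and
antiparallel sheets at exact (φ, ψ), dipeptides, hydrogen-bond-oriented
TIP3P solvation shells, Gaussian-perturbed ensembles, and a smooth periodic
coupling map — so the whole pipeline runs and is tested without any
external data.

## Worked example

Generate a solvated, thermally disordered 12-residue helix ensemble and
compute its spectra:

```bash
amideir fixtures helix --n-res 12 --models 24 --waters 60 --jitter 0.02 \
        --seed 7 -o helix.pdb
amideir fixtures nnc-map --seed 3 -o nnc.map

amideir spectra 1d helix.pdb --nnc-map nnc.map --solvent on  -o helix_1d.tsv
amideir spectra 1d helix.pdb --nnc-map nnc.map --solvent off -o helix_1d_vac.tsv
amideir spectra 2d helix.pdb --nnc-map nnc.map --scheme zzzz --snapshots 8 \
        -o helix_2d.tsv
amideir analyze hbonds helix.pdb -o hb.tsv
```

which prints

```
wrote 1D spectrum to helix_1d.tsv; band maximum at 1678.0 cm-1
wrote 1D spectrum to helix_1d_vac.tsv; band maximum at 1690.0 cm-1
wrote 2D zzzz spectrum (8 snapshot(s)) to helix_2d.tsv
wrote H-bond histogram (264 observations) to hb.tsv
```

Including the solvent point charges moves the band maximum from 1690.0 to
1678.0 cm⁻¹ — the solvent-induced red shift, here 12 cm⁻¹ for a thin
60-water shell.  The hydrogen-bond histogram (`hb.tsv`) shows why:

```
# n_hbonds	n_observations	mean_shift_cm-1
0	151	-7.380
1	113	-10.514
```

sites whose carbonyl accepts a water hydrogen bond are red-shifted ~3 cm⁻¹
further on average than sites without one.  The 2D spectrum file holds the
signed (ω₁, ω₃) amplitude map: positive bleach/stimulated-emission peaks on
the diagonal and negative excited-state-absorption peaks displaced along ω₃
by the anharmonicity.  (A single 1680 cm⁻¹ oscillator gives exactly one
positive peak at (1680, 1680) and one negative peak at (1680, 1664).)

The same pipeline is available as a library — `build_one_exciton`,
`build_two_exciton`, `spectrum_2d_sticks`, `ensemble_spectrum_1d`, … — see
the module docstrings and `docs/methods.md`.

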