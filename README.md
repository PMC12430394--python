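# itacorr

Information-theoretic electron-density descriptors for predicting
*post*-Hartree–Fock electron correlation energies, with Hirshfeld stockholder
partitioning, multicenter numerical integration, and generalized energy-based
fragmentation (GEBF) for large molecular clusters.

## Who this is for

Quantum chemists who want correlation-energy estimates at Hartree–Fock (or
promolecular) cost for homologous families — polymers of increasing repeat
count, molecular clusters of increasing size — and developers of
density-functional / information-theoretic descriptors who need a clean,
tested implementation of the descriptor integrals and the stockholder
partition.

## The model

The electron density ρ(**r**), treated as a (unnormalized) probability
distribution, is summarized by eleven descriptors, all in atomic units:

- Shannon entropy  S_S = −∫ ρ ln ρ d**r**  (global delocalization)
- Fisher information  I_F = ∫ |∇ρ|²/ρ d**r**  (local sharpness)
- Ghosh–Berkowitz–Parr entropy
  S_GBP = ∫ (3/2) k ρ [c + ln(t/t_TF)] d**r**, with the noninteracting
  kinetic-energy density t from the occupied orbitals, t_TF = c_K ρ^{5/3},
  c_K = (3/10)(3π²)^{2/3}, c = 5/3 + ln(4π c_K/3), k = 1 a.u.
- Onicescu information energies  E_n = 1/(n−1) ∫ ρⁿ d**r**  (n = 2, 3)
- relative Rényi integrals  Ω_n = ∫ ρⁿ/(ρ⁰)^{n−1} d**r**  (n = 2, 3), the
  quantity reported as R2r/R3r; the literal entropy form
  (1/(1−n)) log₁₀ Ω_n is also available
- information gain (Kullback–Leibler divergence)  I_G = ∫ ρ ln(ρ/ρ⁰) d**r**
- relative Fisher measures G₁, G₂, G₃ summed over Hirshfeld atoms A, with
  ρ_A = ω_A ρ, ω_A = ρ⁰_A / Σ_B ρ⁰_B (stockholder weights against free-atom
  reference densities ρ⁰_A):
  G₁ = Σ_A ∫ ∇²ρ_A ln(ρ_A/ρ⁰_A), G₂ = Σ_A ∫ ρ_A[∇²ρ_A/ρ_A − ∇²ρ⁰_A/ρ⁰_A],
  G₃ = Σ_A ∫ ρ_A |∇ ln(ρ_A/ρ⁰_A)|².

All descriptors are extensive: for non-interacting copies they add. Across a
homologous series they are therefore linear in system size, and so is the
correlation energy ϵ_corr = E(post-HF) − E(HF). The LR(ITA) protocol exploits
this: fit ϵ_corr = a·D + b against a single descriptor D on small members of
a family, then predict ϵ_corr for larger members from their descriptor value
alone.

For clusters too large to treat whole, GEBF assembles the total energy from
embedded subsystems: E_tot = Σ_m C_m Ẽ_m − (Σ_m C_m − 1) Σ_{A<B} Q_A Q_B/R_AB,
with primitive subsystems (each fragment plus neighbors within a distance
threshold ζ, at most γ_max fragments, C_m = +1) and derivative subsystems
whose integer coefficients come from the principle of inclusion and
exclusion, so each fragment is counted exactly once.

Descriptors are integrated on multicenter grids: per-atom Gauss–Chebyshev
radial × Gauss–Legendre/uniform angular product grids blended with Becke
partition-of-unity weights. Densities come either from packaged promolecular
(free-atom superposition) models or from single-determinant wavefunctions in
Molden format (spherical s/p/d Gaussian basis sets).

## Worked example

Fit one linear model per descriptor on the packaged benzene-cluster table
(HF/6-311++G(d,p) descriptors vs MP2/6-311++G(d,p) correlation energies for
(C₆H₆)₄ … (C₆H₆)₁₄), then predict the n = 14 cluster from its G₃ value:

```sh
$ ita fit --table table11_benzene --out models.json
               slope  intercept   R2  RMSD_mH
descriptor
SS         -0.019073   0.127353  1.0     10.7
IF         -0.576383   0.088048  1.0      7.6
SGBP       -3.042672   0.090776  1.0      7.6
E2         -0.004546   0.084698  1.0      7.1
E3         -0.128290   0.086104  1.0      6.9
R2r        -0.019951   0.084550  1.0      7.3
R3r        -0.018848   0.084577  1.0      7.3
G1          0.039689   0.091213  1.0      7.5
G3         -0.015173  -0.016440  1.0      2.8

$ ita predict --model models.json --descriptor G3 --x 789.848
-12.000855
```

Each row is one single-descriptor model ϵ_corr = slope·D + intercept
(hartree); R² is the squared correlation over the 11 training clusters and
RMSD = sqrt(SSR/n) in millihartree. G₃ is the best single descriptor here
(2.8 mH ≈ chemical accuracy); its prediction for the largest cluster,
−12.000855 hartree, sits 1.2 mH from the reference value −12.0021 hartree.

Other entry points: `ita compute` evaluates the eleven descriptors for an XYZ
geometry (promolecular density) or a Molden wavefunction; `ita gebf-plan` /
`ita gebf-energy` build fragmentation plans and assemble cluster energies;
`ita report` runs a TOML-configured task end to end. The same functionality
is available as a library (`itacorr.compute_all`, `itacorr.fit_all`,
`itacorr.build_plan`, …).

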