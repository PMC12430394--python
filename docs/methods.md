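# Methods

This note records the models, numerical choices and limitations behind
itacorr, at the level of detail a user needs to judge what computed numbers
mean.

## Densities

Two density backends satisfy the same field contract (ρ, ∇ρ, ∇²ρ at
arbitrary points, plus the electron count):

**Promolecular fields.** The promolecule is the superposition of spherically
averaged neutral free-atom densities at the molecular geometry. The packaged
reference atoms (H–Ar) are s-Gaussian expansions, ρ⁰(r) = Σ_k c_k (α_k/π)^{3/2}
e^{−α_k r²}, fitted by non-negative least squares to a Slater-orbital atomic
model (Slater screening rules, shell-by-shell). Coefficients are non-negative,
so ρ⁰ > 0 everywhere, and are renormalized on load so Σ_k c_k equals the
integer electron count exactly. The exponent ladder is capped at 60 Z² bohr⁻²:
steeper Gaussians act as cusp mimics that production grids cannot integrate
and contribute nothing chemically. These synthetic reference atoms are
internally consistent but are *not* the ROHF/6-311++G(d,p) atoms used in the
published tables, so absolute values of the reference-dependent descriptors
(I_G, Ω_n, G₁–G₃) differ from Multiwfn's; their structure (positivity,
extensivity, vanishing at ρ = ρ⁰) is what the tests pin down.

**Wavefunction fields.** Single-determinant wavefunctions are read from
Molden files ([Atoms] AU/Angs, [GTO], [MO], [5D]/[7F] flags). Basis functions
are real spherical-harmonic Gaussians with l ≤ 2; each primitive is expanded
into Cartesian monomials × Gaussian, so orbital values, gradients and
Laplacians are analytic. Cartesian d sets and f/g shells are rejected
explicitly rather than silently mis-normalized. The kinetic-energy density is
t = Σ_i (1/8)|∇ρ_i|²/ρ_i − (1/8)∇²ρ over occupied orbital densities
ρ_i = occ_i|φ_i|², which integrates to the kinetic energy T_S (verified
against closed forms in the tests).

## Quadrature

Descriptor integrals use per-atom product grids glued by Becke
partition-of-unity weights (three iterations of the smoothing polynomial, no
atomic-radius adjustment in the cell functions; the radial map is element
scaled instead):

- radial: Gauss–Chebyshev (second kind) under the map r = R_m(1+x)/(1−x),
  with R_m the element's Bragg–Slater radius; default 75 points;
- angular: Gauss–Legendre in cos θ × uniform in φ with n_φ = 2 n_θ. Supported
  point counts are 2k²; the default 392 (k = 14) integrates spherical
  harmonics exactly through degree 27. A product rule was chosen over Lebedev
  grids because it is generated in three lines from `leggauss` — no node
  tables to transcribe — at a modest (~30 %) point-count premium for
  comparable accuracy.

Point ordering is deterministic (atom-major, radial-major), making integral
sums bit-stable run to run on one platform. On the closed-form suite the
default grid is accurate to ~1e−9 relative; electron counts on molecular
promolecules are reproduced to better than 1e−6 relative. Two integrands are
known to converge more slowly: ∫∇²ρ (exact value 0) for heavy atoms, where
the integrand magnitude is 10²–10³ and the default grid leaves ~1e−6 of it
uncancelled in absolute terms, and Becke-cell interfaces at intermediate
(6–12 bohr) separations of very diffuse synthetic atoms, where the interface
falls in a sparsely sampled radial region. Neither regime affects bonded
molecules or well-separated fragments, the two regimes the package's
analyses use.

Density floor: points with ρ < 1e−12 are excluded from logarithmic
integrands (ln ρ, ln ρ/ρ⁰); their contribution is below grid accuracy. Where
the promolecule itself underflows the floor (far tails with zero integral
weight) Hirshfeld weights fall back to a uniform share so the partition of
unity holds pointwise.

## Descriptor conventions

- S_GBP carries the positive overall sign of the Ghosh–Berkowitz–Parr
  convention, with k = 1 (atomic units); that is the only sign consistent
  with positive tabulated values. Points where t ≤ 0 (numerically possible
  near nuclei and in tails) are skipped and counted in the log.
- The tabulated R2r/R3r quantities are the integrals Ω_n = ∫ρⁿ/(ρ⁰)^{n−1}
  (they collapse to N at ρ = ρ⁰, matching the printed magnitudes ≈ N); the
  literal entropy form (1/(1−n)) log₁₀ Ω_n is exposed separately.
- G₁ uses the logarithmic integrand ∫∇²ρ_A ln(ρ_A/ρ⁰_A); the non-logarithmic
  variant is dimensionally inconsistent with the tabulated magnitudes and
  with the relative-Fisher origin of the G family.
- Because Hirshfeld weights give ρ_A/ρ⁰_A = ρ/ρ⁰ identically, the atomic sums
  for G₁–G₃ collapse to closed forms in the total and promolecular densities;
  the implementation evaluates those collapsed forms, which need no
  derivatives of the stockholder weights. E₂/E₃ carry the 1/(n−1) prefactor
  (so E₃ = ½∫ρ³).

## Regression

Each model is ordinary least squares with intercept of ϵ_corr (hartree)
against one descriptor column, via `scipy.stats.linregress` behind the module
surface. R² = 1 − SSR/SST; RMSD = sqrt(SSR/n) over the n fitted points —
the root mean squared deviation convention of the source tables, validated by
reproducing their printed RMSD rows — reported in millihartree. Training-set
statistics (`fit_lr`/`fit_all`) and extrapolation metrics (`evaluate`) are
deliberately distinct verbs: the former describe the fit inside the training
data, the latter apply a frozen model to held-out systems.

The packaged tables are verbatim transcriptions of the published
descriptor/energy tables for polyyne, polyene, all-trans-polymethineimine,
acene, (CO₂)_n and (C₆H₆)_n, with provenance headers recording units and the
printed scale factors (fits are scale-invariant, so columns are stored
exactly as printed). Two typographical defects are flagged in the CO₂ table's
header (a duplicated E2/E3 pair and one out-of-sequence E2/E3 row); those two
columns are excluded from quality assertions. Reproducing a printed RMSD from
rounded table values is limited by quantization of the descriptor column:
a column printed to 3 decimals contributes |slope|·step/(2√3) of RMS noise,
which dominates for steeply sloped /10³ columns (~1 mH) and is negligible
(~0.01 mH) elsewhere; tests allow exactly this much.

## GEBF

Fragments are connected components of the covalent bond graph (bond when
distance < 1.2 × sum of covalent radii; deterministic numbering by lowest
atom index) or user-assigned labels. Primitive subsystems take each fragment
plus all fragments whose *minimal interatomic distance* lies within ζ
(default 4.0 Å), truncated to the γ_max nearest (default 6; ties broken by
lower fragment index, with a warning on truncation); primitives contained in
another primitive are dropped. Derivative coefficients are computed on the
intersection closure of the primitive family by the recursion
C_S = 1 − Σ_{T⊋S} C_T in decreasing size order, which guarantees the
single-counting identity Σ_{m: f∈S_m} C_m = 1 for every fragment (every
closure member containing f contains the minimal intersection of primitives
containing f). A brute-force inclusion–exclusion oracle cross-checks the
coefficients in the tests.

The point-charge double-counting correction applies to *total-energy*
assembly only. The correlation-energy combination is Σ_m C_m ϵ_m: the
classical charge term carries no correlation component, so including it
there would contaminate the prediction. Charges Q_A are user-supplied (the
charge model is the energy backend's concern); the default is zero.

## Synthetic fixtures

The generator families stand in for the homologous series of the study:
`gaussian` systems are chains of identical pseudo-atoms whose density is one
normalized s-Gaussian (every descriptor has a closed form for one center;
30-bohr separations make multimers non-interacting to ~1e−8), `chain` and
`ring_cluster` series grow linearly in size for trend and fragmentation
tests, with all randomness drawn from recorded seeds. What these fixtures
establish is the *mathematics* of the pipeline — integral accuracy,
extensivity, single counting, telescoping of the linear model over GEBF
coefficients. They do not emulate real electronic structure: no shell
structure, no density deformation on bonding, no correlation physics. The
published-table fits are the empirical anchor; the synthetic results say
nothing about how well a single descriptor tracks correlation energy in a
new chemical family.

## Problem sizes

Default analyses are sized for a single CPU: descriptor grids of ~3 × 10⁴
points per atom, synthetic chains to n = 30 pseudo-atoms, 200 random cluster
geometries (≤ 8 fragments) for the fragmentation property checks, and the
train-on-4–14 / extrapolate-to-30 workflow on the chain family. All are the
package's own defaults, chosen so the full check suite completes in minutes.

## Known limitations

- No SCF: densities come from promolecular models or external wavefunctions.
- Spherical s/p/d basis sets only; no ECPs, no periodic systems, no
  spin-resolved densities (total density only).
- Rényi orders are restricted to n ∈ {2, 3}, matching the tabulated
  descriptors.
- Absolute reference-dependent descriptor values depend on the packaged
  reference atoms (see above) and will not match Multiwfn bit for bit.
- The large-cluster extrapolation comparison of the source study requires
  MP2-level reference energies that are not printed; the workflow is
  exercised on synthetic families instead.
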