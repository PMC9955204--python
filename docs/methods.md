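# Methods

This note documents the models, estimators and numerical choices behind
`casdyn`, and what the synthetic-data tests do and do not demonstrate.

## Featurization

Backbone torsions are the configuration variables: φ(i) =
C(i−1)–N(i)–CA(i)–C(i) and ψ(i) = N(i)–CA(i)–C(i)–N(i+1), each expanded to
(sin, cos) columns so the circular topology does not create artificial
discontinuities. Terminal residues contribute only their defined angle;
residues with missing backbone atoms are skipped and logged, never
imputed. A χ1 column set can be enabled through the torsion-quadruple
helper, but backbone-only is the default because backbone atoms are common
to wild-type and mutant topologies. Feature labels carry
(residue, torsion, sin|cos) provenance end to end, which is what makes
residue-level contribution thresholding possible after tICA.

## tICA

With mean-free features, `C₀ = ⟨x xᵀ⟩` (averaged over both ends of the lag
pairs) and `C_τ = ⟨x(t) x(t+τ)ᵀ⟩`, symmetrized as `(C_τ + C_τᵀ)/2` before
solving `C_τ v = λ C₀ v`. Symmetrization assumes reversible dynamics; it is
the standard estimator choice and guarantees a real spectrum.
Eigenvectors are C₀-orthonormal, so projected coordinates are kinetically
whitened (unit instantaneous variance on training data). A ridge
`reg·I` (default 1e-8) stabilizes C₀; exactly collinear features with
`reg = 0` raise a dedicated singular-covariance error rather than
returning garbage. Eigenvalues are clipped to |λ| ≤ 1 + 1e-6; anything
beyond that tolerance indicates an estimation problem and fails loudly.

**Contributions.** The residue-selection rule scales each kept component
to unit maximum absolute loading, scores each feature by its maximum
|normalized loading| over components, merges sin/cos partners by taking
the residue-level maximum, and keeps residues scoring ≥ 0.195 by default.
"Contribution" is not a uniquely defined quantity; the max-abs normalized
loading is one defensible reading, chosen because it is scale-free per
component and reduces to the intuitive answer on one-hot eigenvectors.

**VAMP2.** The score is the sum of squared top singular values of
`C₀₀^{-1/2} C₀τ C_ττ^{-1/2}` built on raw features augmented with a
constant column, so the stationary process contributes exactly 1 and the
score is ≥ 1. On one-hot features of a two-state chain the score
approaches 1 + λ₂², the spectral identity used in tests.

## MSM estimation

Counts are sliding-window at integer lag, never crossing trajectory
boundaries. Estimation is restricted to the largest strongly connected
component of the count graph (dropped states logged, original indices kept
in `active_set`). The reversible maximum-likelihood estimator iterates the
standard fixed point

    x_ij ← (c_ij + c_ji) / (c_i/x_i + c_j/x_j)

to 1e-10 in log-likelihood (the unnormalized flux `x` yields
`T = x / rowsum`, `π = rowsum / total`). Reversibility is the default
because PCCA++ requires a real spectrum. Eigenvalues are computed on the
symmetrized similarity transform `D^{1/2} T D^{-1/2}` (D = diag π), which
is numerically exactly symmetric for a detailed-balance matrix.

Implied timescales are `t_i = −τ·stride / ln|λ_{i+1}|`, reported +∞ for
|λ| ≥ 1 and NaN (missing, not fabricated) for non-positive eigenvalues.

**Bayesian uncertainty.** Rows of T are sampled from independent Dirichlet
posteriors over the *observed* transitions of each row (concentration =
counts, optional additive prior, default 0). Restricting to observed
transitions matters: a uniform prior over all k states adds k
pseudo-counts per row and swamps sparse count matrices, which destroys the
calibration of the credible bands. This is the conjugate non-reversible
sampler — simpler and exact, a documented deviation from reversible
samplers; its λ₂ credible intervals empirically cover the truth at the
nominal rate in the seeded coverage test.

**Chapman–Kolmogorov.** For each factor k the model propagated k steps,
`T(τ)^k`, is compared with a model re-estimated at lag kτ on macrostate
occupation curves (started π-distributed inside each macrostate). The
Bayesian ensemble supplies the 95% band; the test passes when ≥ 95% of
(factor × macrostate) points fall inside. The discriminating power is
verified constructively: a hidden 4-state cycle observed through a
2-symbol projection has period-4 memory that a lag-1 MSM cannot represent,
and the test rejects it.

**PCCA++.** The top-m right eigenvectors (first column fixed to the
constant vector) are searched for the m states spanning the largest
simplex (inner-simplex vertex algorithm); memberships are the linear map
of all states onto that simplex basis, clipped to [0, 1] and row-
renormalized to absorb the small negative round-off the linear map can
produce. Crisp assignments are row argmax. On spectrally gapped block
chains the recovery is exact, which is the property the tests pin.

**MFPT.** Mean first-passage times solve the first-step system
`h = 1 + T h` with `h = 0` on the target set; the source average is
π-weighted over the source set. The linear solve is checked against value
iteration on random chains up to 6 states. Times convert to ns via
lag × frame stride; unreachable targets give +∞, never a clipped number.

**Free-energy surface.** Frames are reweighted by
`π(microstate)/count(frames in microstate)` and binned in the first two
tICA coordinates; `F(bin) = −kT ln Σ w`, shifted so the minimum is 0.
Empty bins are NaN — flagged, not zero — because an unvisited bin has no
estimate, not a free energy of 0.

## Macrostate–structure association

Jarvis–Patrick clustering joins two frames iff each is in the other's K
nearest neighbors (ties with the K-th distance included, so equidistant
frames are treated alike) and they share ≥ k_min common neighbors;
clusters are connected components of the join graph. K = 10 and k_min = 3
by default — common trajectory-clustering values, config-exposed because
no principled universal choice exists. Average structures use iterative
Kabsch alignment to the running mean (convergence 1e-6 Å). Each
macrostate is represented by the frame with the highest PCCA++ membership
and matched to the minimum-backbone-RMSD cluster average; ties break
toward the larger cluster weight, then the lower cluster id. An optional
maximum-RMSD acceptance cutoff (off by default) lets a run report "no
matching structure".

## Allostery

Couplings are scalar dot-product correlations of 3-D Cα displacement
vectors, `C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)`, after rigid-body
alignment of every frame to the iterative mean structure (alignment can be
disabled for controlled fixtures). This deterministic estimator replaces a
trained neural relational inference model: only the correlation/pathway
outputs are consumed downstream, the estimator is pluggable, and a
deterministic surrogate makes the pathway reproducible bit-for-bit.
Zero-variance residues are flagged undefined and excluded from graphs.
Edges require mean Cα–Cα distance ≤ 12 Å (1.2 nm converted at the module
boundary) and non-zero coupling; weights are `−ln|C_ij|` so perfect
coupling costs 0 and the minimum-weight path is the dominant
communication route. The shortest-path search is Dijkstra with heap
entries ordered by (distance, path), which yields a deterministic
lexicographic tie-break among equal-weight paths — the reason it is not a
plain `networkx.dijkstra_path` call. Alternating-residue coarse-graining
(offsets 0/1, union-merged) mirrors the half-resolution node scheme used
for large regions: 767–984 splits into 109 + 109 nodes.

## Markers

Protein anchors default to Cα; Arg976 uses its terminal side-chain carbon
(CZ) as the stated exception; nucleic anchors named as base steps resolve
to the midpoint of the named P atoms (the anchor point is otherwise
under-determined — midpoint is the symmetric choice). Histograms use
Freedman–Diaconis bins unless configured. Single-Gaussian fits are the
closed-form sample moments; mixtures use EM (seeded, best of 5 restarts by
likelihood). Mixture order is fixed by config, not selected automatically.
Unresolvable selectors (mutant topologies) skip the marker with a log
entry rather than failing the set.

## Nucleic-acid geometry

Delta is the C5′–C4′–C3′–O3′ torsion, reported in [0, 360) for plotting
parity ("O" in loose writings of the definition is taken as O3′, the
standard delta). Pseudorotation inverts
`ν_j = τ_m cos(P + 144°(j−2))` via
`tan P = ((ν₄+ν₁) − (ν₃+ν₀)) / (2ν₂(sin 36° + sin 72°))`, implemented as
`P = atan2(τ_m sin P, ν₂)` with amplitude `hypot` of the two — identical
in exact arithmetic to ν₂/cos P but well-defined at P = 90°/270°. A flat
ring (both arguments ≈ 0) raises an undefined-pucker error. Regime
classification keys on phase alone with precedence R-loop (> 270°) >
B-form (≥ 100°) > A-form, resolving the overlap of the >100° and >270°
windows.

## Synthetic data: what it emulates and what it does not

The generators supply the *statistical structure* each stage assumes, with
parameters chosen once as study-realistic defaults:

- **Markov chains**: inverse-CDF sampling; block matrices (2×2 blocks,
  intra-block hop 0.1, inter-block 1e-3 for estimator tests; 0.08/0.02 for
  the end-to-end demo so all four states are visited in 400 frames).
  Recovery tests use 1e5 steps, where the binomial standard error per
  transition-matrix row (~3e-3) is well below the tested tolerances.
- **Langevin**: Euler–Maruyama on a quartic double well whose barrier is
  exactly the requested height for two wells (≥ the requested height for
  three or more, product form); stationary density ∝ exp(−V/noise²).
  Occupancy tests use batch-mean standard errors because the samples are
  strongly autocorrelated.
- **Toy Cα chains**: extended chain at 3.8 Å spacing; each Cartesian
  component of the residue displacements drawn independently from the
  specified residue-residue covariance (eigendecomposition square root,
  robust to PSD matrices with zero eigenvalues).
- **Peptide trajectories**: an internal-coordinate (NeRF) backbone builder
  places N/CA/C/O with ideal bond geometry and requested φ/ψ; chain states
  map to well-separated Ramachandran basins with 5° torsion noise.
- **Sugar rings**: torsion sets from the pseudorotation formula directly
  (exact round-trip), and 3-D deoxyribose fragments built on a pentagon
  with out-of-plane displacements calibrated by a short fixed-point loop
  so measured (P, τ_m) matches the request to <1e-6°, with delta set
  exactly by NeRF placement of O3′.
- **Distance series**: i.i.d. Gaussian mixtures from one seeded stream per
  call (per-component streams were rejected to keep reproducibility
  trivial).

Passing these tests shows the estimators are correct on data satisfying
their own assumptions (Markovianity, Gaussian displacements, ideal
geometry, i.i.d. mixtures). It does not show robustness to force-field
artifacts, aligned-frame correlations, solvent effects, or the
non-Markovian memory real torsion dynamics can carry at short lags — the
CK test exists precisely to detect the latter on real input.

## Problem sizes and determinism

Default test/demo sizes — 400-frame demo trajectories, 1e5-step chains,
1e4-sample fits, ≤ 8-node exhaustive graph oracles — were chosen so the
statistical tolerances above are comfortably resolvable while the whole
suite stays interactive. Every stochastic routine takes an explicit seed
(`numpy.random.default_rng`), the pipeline consumes named seeds from the
config, and TSV output uses fixed float formatting, so identical
config + seed reproduces outputs byte-for-byte.

## Known limitations

- The Bayesian sampler is non-reversible; its samples need not satisfy
  detailed balance even though the point estimate does.
- PCCA++ membership feasibility is handled by clip-and-renormalize rather
  than the full constrained optimization of the memberships; for strongly
  overlapping macrostates the fuzzy memberships are approximate (crisp
  assignments are unaffected in the gapped regimes tested).
- The kinetics of the real S1–S4 Cas9 macrostates (transition times,
  cluster weights, association RMSDs) require the original microsecond
  trajectories, which are not distributable; the package reproduces the
  method, and its trajectory-independent printed quantities, not those
  trajectory-dependent numbers.
- No mmCIF input; binary trajectory support is XTC/DCD via the mdtraj
  adapter.
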