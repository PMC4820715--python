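# Methods

This note documents the models, conventions and numerical choices behind
`quadmsm`, and what the synthetic test systems do and do not establish about
real simulation data.

## The analysis pipeline

The package implements the standard Markov-state-model (MSM) workflow for
unfolding ensembles of a small nucleic acid, with the thrombin-binding aptamer
(TBA, 5′-GGTTGGTGTGGTTGG-3′, a two-tetrad chair-type G-quadruplex) as the
motivating system:

1. **Discretization.** All frames of an ensemble of short trajectories are
   pooled (file order, then frame order — this ordering fixes center identity)
   and clustered with greedy farthest-point *k-centers* under a pairwise
   metric, by default backbone Kabsch RMSD. In cutoff mode the algorithm
   guarantees every frame lies within the cutoff of its assigned center; in
   k mode it stops at a fixed number of centers. The first center is frame 0
   of the pooled ensemble, and all ties resolve to the lowest index, so the
   procedure is deterministic.
2. **Counting and estimation.** Transitions s(t) = i → s(t+τ) = j are counted
   with a sliding window (every frame is a window start; trajectories are
   never concatenated). The transition matrix is estimated by symmetrizing
   the counts, C′ = (C + Cᵀ)/2, and row-normalizing. This yields a
   row-stochastic T that satisfies detailed balance exactly, with stationary
   distribution π proportional to the row sums of C′. Counting before
   estimation restricts to the largest strongly connected component of the
   directed count graph (ergodic trimming), so all downstream linear systems
   are solvable.
3. **Validation.** Markovianity is checked two ways: implied timescales
   t_k(τ) = −τ / ln μ_k(τ) should be flat in τ for a Markovian process, and
   the model-propagated probability of remaining in a macrostate over a
   horizon h, π_Mᵀ T^h 1_M / Σπ_M, should match the directly counted
   residence fraction.
4. **Lumping.** PCCA+ (robust Perron cluster cluster analysis) assigns each
   microstate fuzzy memberships in n metastable macrostates from the geometry
   of the top n right eigenvectors. We implement the inner-simplex algorithm:
   the eigenvector rows lie near a simplex whose vertices are the metastable
   sets; vertices are located by greedy farthest-point selection in
   eigenvector space, memberships follow from the affine transform mapping
   vertices to unit coordinates, and small infeasibilities are clipped and
   rows renormalized. The crispness trace(S)/n of
   S = diag(πχ)⁻¹ χᵀ diag(π) χ is reported (1 for a perfectly crisp
   partition). n is a required user input; the package emits a spectral-gap
   report to guide the choice rather than auto-selecting.
5. **Kinetics.** Transition path theory between a source set A (native) and a
   target set B (unfolded): the forward committor solves the harmonic system
   q⁺_i = Σ_j T_ij q⁺_j on intermediates with q⁺ = 0 on A, 1 on B; the
   backward committor solves the same system on the time-reversed matrix
   T̃_ij = π_j T_ji / π_i. Reactive gross fluxes are
   f_ij = π_i q⁻_i T_ij q⁺_j (zero diagonal), net fluxes
   f⁺_ij = max(f_ij − f_ji, 0) remove back-and-forth loops, and the total
   reactive flux F is the net flux out of A (equal to the flux into B, an
   identity asserted at run time). Pathways are extracted by iterative
   bottleneck (widest-path) decomposition of the **net** flux network — find
   the A→B path whose minimum-capacity edge is maximal, subtract its
   bottleneck flux, repeat — with deterministic lexicographic tie-breaking.
   Mean first passage times solve MFPT_i = t + Σ_j T_ij MFPT_j with MFPT = 0
   on the target, where t is the physical lag time, so MFPTs scale exactly
   linearly in t.
6. **Reporting.** Each macrostate is characterized over a fixed-seed uniform
   subsample of member frames (default 100 per state): population, mean ± sd
   superposition RMSD for the backbone and for configured loop selections,
   mean ± sd residue-center distances, hydrogen-bond occupancies, and a
   representative conformation — the member with the lowest RMSD to the
   average structure after superposing all members onto the first. The
   macrostate network (node populations and RMSD, coarse transition weights
   above a floor) is exported as GraphML and GEXF for external layout tools.

### Pathway times

The "unfolding time" attached to a pathway is the MFPT from its initial to
its final macrostate on the coarse-grained macrostate matrix
W_MN = Σ_{i∈M, j∈N} π_i T_ij / P_M. Per-edge times along a pathway are
pairwise MFPTs between consecutive macrostates, computed by default on the
full matrix; a path-restricted variant (matrix confined to the pathway's
states and renormalized) is offered and labelled, since both conventions are
defensible and give different numbers.

## Structural conventions

* **Residue labels** combine the one-letter base code with the 1-based
  sequence position (G1 … G15 for TBA).
* **Backbone** means the sugar–phosphate atoms P, O5′, C5′, C4′, C3′, O3′.
  The same selection is used for fitting and for the deviation in every RMSD.
* **Residue–residue and residue–molecule distances** are between heavy-atom
  *geometric* centers; "C" denotes the heavy-atom geometric center of the
  whole molecule. Mass-weighted centers are available as an option. Published
  per-residue distance tables rarely state their atom convention, so small
  (sub-Å) discrepancies against other conventions are expected.
* **Hydrogen bonds** use donor–acceptor distance ≤ 3.5 Å and, when the
  structures contain hydrogens, a donor–H–acceptor angle ≥ 135° for at least
  one hydrogen covalently bonded to the donor (same residue, ≤ 1.25 Å);
  without hydrogens the distance criterion alone applies. Occupancy is the
  percentage of supplied structures satisfying the criterion, computed over
  the given structure set only; intra-residue contacts are excluded and
  records below a report floor (default 50%) are dropped. Records use the
  ``N7@G14…N2@G2`` donor–acceptor notation.
* Superposition uses the Kabsch algorithm (via SVD, proper rotations
  enforced); trajectory-against-reference series use a batched vectorized
  implementation verified in tests against frame-by-frame superposition and
  against a brute-force rotation search.

## Synthetic ground truth

Real unfolding studies of this kind rest on microseconds of all-atom MD that
cannot be redistributed or regenerated cheaply, so the package ships two
generators whose answers are known exactly.

**Planted chains.** `build_metastable_chain` constructs a symmetric weight
matrix with entry `intra_p` for every within-block pair (including the
diagonal) and `inter_p` for pairs across adjacent blocks, optionally with
symmetric multiplicative jitter, then row-normalizes. Row-normalizing a
symmetric matrix gives a reversible chain with π proportional to row sums, so
the ground-truth T, π and block labels are all exact. `intra_p ≫ inter_p`
produces the metastable spectrum (block-count − 1 eigenvalues near 1) the
estimator and PCCA+ are expected to recover. Sampled trajectories start from
the stationary distribution; one seed fixes the whole stream.

**Toy unfolding simulator.** Overdamped Euler–Maruyama walkers move on a
1-D reaction coordinate r with potential

    V(r) = h · [r (r − 0.5) (r − 1)]²  +  lift · kT · exp(−(r − 0.5)² / 2σ²)

with minima at r = 0 (folded), 0.5 (connector) and 1 (unfolded), h = 12.
Each saved position is rendered as a 15-bead structure by linear
interpolation between a compact helical template and a fully extended strand
(end-to-end 44.8 Å, the scale of an unfolded 15-mer), plus Gaussian bead
jitter (0.35 Å). Choices that matter:

* The bare triple well has a polynomial barrier of ≈ 0.0023·h energy units;
  the thermal energy default kT = 0.005 therefore puts the barriers at
  ≈ 5.6 kT — high enough for clear metastability, low enough that an
  ensemble of 31 × 2×10⁵ steps shows dozens of well transitions. This is the
  package's calibration of "rare but observable" at workstation scale.
* The bare triple well's minima are equally deep and the middle well is the
  broadest, which would make the connector the *most* populated state. The
  Gaussian lift (default 2.5 kT, σ = 0.12) raises the middle well so the
  connector is a genuinely low-population gateway (≈ 8% occupancy at the
  defaults) between two ≈ 45% basins — the topology of a folding-region /
  connector / unfolding-region network.
* Walkers start evenly spread over r ∈ [0, 1] by default, standing in for
  unfolding seeds scattered over conformation space; a fixed start is
  available for basin-escape experiments.
* Euler–Maruyama is stable only if dt resolves the stiffest curvature; the
  constructor enforces dt ≤ 1/max|V″| (max taken numerically over
  r ∈ [−0.3, 1.3]) and the integrator aborts with a diagnostic if a
  trajectory ever diverges. Walkers reflect at r = −0.25 and 1.25.

**What the synthetic systems do not show.** The toy landscape has a single
1-D order parameter, isotropic Gaussian "thermal" noise on beads, no solvent,
ions, force field or barrier anisotropy, and by construction exactly
Markovian coarse dynamics. Passing tests therefore certify the *analysis
machinery* — counting, estimation, spectral lumping, committors, fluxes,
passage times, bookkeeping — not the fidelity of any MD force field or the
transferability of a chosen lag time to real aptamer dynamics. In particular
implied-timescale flatness on synthetic data validates the test itself, not
Markovianity of any real system.

## Numerical choices

* Eigenproblems of reversible T are solved on the symmetric conjugate
  D^{1/2} T D^{−1/2} (D = diag π) with a symmetric eigensolver; right
  eigenvectors are recovered as D^{−1/2} v. Non-reversible matrices fall back
  to a dense nonsymmetric solver.
* Implied timescales report NaN for non-positive (or complex) eigenvalues
  and +inf for eigenvalues within 1e−12 of 1.
* Committor and MFPT systems are solved densely (`numpy.linalg.solve`);
  MFPT first verifies reachability of the target on the directed transition
  graph and names unreachable states.
* PCCA+ raises on non-reversible input, on a degenerate eigenvalue gap at
  the cut, and on empty crisp macrostates, rather than returning a silently
  arbitrary partition.
* Assignment and decomposition tie-breaks (nearest center, argmax
  membership, widest path) all resolve toward the lowest index, making every
  stage reproducible bit-for-bit from one seed.
* The estimator's sliding-window counting maximizes data use at the cost of
  correlated counts; this biases error bars, not means, and none of the
  package's statistics depend on count independence.

## Parameters that matter

| Parameter | Default | Meaning |
|---|---|---|
| cluster cutoff / k | k = 40 (toy) | microstate resolution; cutoff mode guarantees max frame–center distance |
| lag τ | 2 frames (toy) | MSM time step; choose on the implied-timescale plateau |
| n_macro | 3 (toy) | macrostate count; guided by the spectral-gap report |
| n_samples | 100 | frames per state for structural summaries |
| H-bond cutoffs | 3.5 Å / 135° | geometric hydrogen-bond criterion |
| barrier_height h | 12 | toy potential prefactor (see calibration above) |
| kT | 0.005 | thermal energy of the toy walker |
| connector_lift | 2.5 kT | raise of the middle well (low-population connector) |

## Known limitations

* Only multi-model PDB trajectory I/O is supported; no DCD/XTC readers.
* The transition-matrix estimator is the symmetrize-and-normalize maximum
  of the reversible likelihood's fixed-count approximation, not the full
  iterative reversible MLE; no Bayesian error bars are provided.
* PCCA+ uses the inner-simplex construction without the subsequent
  constrained optimization of the crispness objective; for well-separated
  metastable spectra (the regime the pipeline targets) the two coincide in
  the crisp assignment.
* Pathway decomposition operates on net fluxes; gross-flux ranking is not
  offered.
* The analysis assumes the supplied ensemble samples all relevant basins;
  no attempt is made to detect missing states.
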