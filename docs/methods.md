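# Methods

`spider2d` identifies governing partial differential equations for a
two-dimensional active nematic — a film of extensile, apolar filament bundles
described by a unit director field **n**(x, y, t) (with the nematic symmetry
**n** ≡ −**n**), an interfacial velocity **u**(x, y, t), and an intensity /
packing-fraction proxy φ used only to mask unreliable regions.  The pipeline
has four stages: field preprocessing, symmetry-constrained term-library
generation, weak-form evaluation, and sparse regression.  This note records
the model assumptions, the tunable parameters, and the design decisions made
where the method leaves genuine freedom.

## Field preprocessing

All fields live on a regular (t, y, x) grid.  The index convention is fixed
once and used everywhere, including the synthetic generators:
`gradu[..., i, j] = ∂_i u_j`, strain rate A = (∇u + ∇uᵀ)/2, rotation rate
Ω = (∇u − ∇uᵀ)/2, scalar vorticity ω = −2Ω_xy.  Because discovery only asks
which *combinations* of terms vanish, any self-consistent convention yields
the same relations; what matters is that generation and analysis share it.

- **Smoothing** is a moving-least-squares fit (3-D Savitzky–Golay): each point
  is replaced by the value of a local total-degree-2 polynomial fit over a
  5×5×5 spatiotemporal window (clipped at boundaries).  Degree 2 with window 5
  preserves exactly the quadratics that the second-order centered differences
  used downstream differentiate exactly.
- **Differentiation** uses second-order centered stencils, one-sided
  second-order at boundaries (`numpy.gradient`, `edge_order=2`).  Boundary
  accuracy is nearly irrelevant because the weak-form envelope vanishes there.
- **Director sign handling.**  The stored director sign is arbitrary per
  point.  Every derivative of **n** is taken on a smoothly gauged copy
  produced by sweep alignment (propagate signs along x, then y, then t; fix
  the overall sign by requiring n_x ≥ 0 at the grid origin).  The result is
  exactly invariant under sign flips of any subset of stored directors.  With
  topological defects a smooth global gauge does not exist; the weak-form
  assembler detects seams and falls back to independent per-subdomain gauges
  (defect cores themselves are excluded by the mask).
- **Masking.**  ψ₀ = 1 where φ ≥ 0.15·max φ *and* ‖∇n‖ ≤ 2 × median ‖∇n‖,
  else 0; ψ is ψ₀ after 10 passes of a 5-point box filter per axis, clipped to
  [0, 1].  The thresholds are configuration options; the defaults are chosen
  to excise defect cores and dim regions while leaving ≥ 95 % of a clean frame
  untouched.
- **Nondimensionalization** rescales length and time so the mask-weighted
  mean speed and mean |ω| are both exactly 1 (the two conditions fix both
  scales: T = 1/⟨|ω|⟩, Λ = ⟨|u|⟩/⟨|ω|⟩).  Discovered coefficients are
  reported in these units; fixture comparisons transform back with the stored
  scales.

## Term libraries

A library term is a product of factors u, n (each with optional time and
spatial derivatives) and optionally the 2-D Levi-Civita symbol, with all
tensor indices either contracted in pairs or left free.  Libraries group
terms by rank (0, 1, 2), nematic parity (power of n mod 2) and, for rank 2,
symmetry class (symmetric-traceless or antisymmetric; projections are applied
at evaluation time).  Every admissible relation Σ c_r F^r = 0 then respects
rotation and nematic symmetry by construction.

Grammar bounds (defaults): total spatial derivatives ≤ 2, time derivatives
≤ 1, and per-class limits on field factors / total complexity
(fields + derivative order): scalar 3/5, vector 4/5, symmetric-traceless 5/6,
antisymmetric 3/5.  These are the smallest budgets that contain every term of
the target relations — the alignment term n_i(n_a n_b ∂_a u_b) needs four
field factors, and the tensor stress balance (n_a n_b ∂_a u_b) n_i n_j needs
five.  The projector P⊥ = δ − nn and the Q-tensor are deliberately *not*
primitives: regression discovers their groupings as coefficient patterns.
Mirror-breaking (ε-bearing) terms are excluded by default; the discovered
relations are achiral.

Symbolic cleanup applies n·n = 1 and n·(∂n) = 0 (single derivative), then a
numeric *fingerprint deduplication*: every term is evaluated on several
independent band-limited random field sets and removed if its sample vector
is (to 1e−7 relative) in the span of retained earlier terms or numerically
zero.  This catches identities the rewriter does not encode — e.g.
n·Δn = −∇n:∇n follows from differentiating n·n = 1 twice.  Removals are
logged on the library.  Probe fields keep the *director* spectrum far below
the grid Nyquist mode (angle rms 0.35, cutoff mode 3, Gaussian decay) so
Fourier differentiation resolves identities to ~1e−9 — rougher probes alias
and blur the identity/physical separation.

## Weak form

Each term is integrated against weight functions on rectangular subdomains
mapped to [−1,1]³.  A weight is envelope × modulation × mask: the envelope
(1−x²)^τ(1−y²)^τ(1−t²)^τ with τ = 4 vanishes with τ−1 derivatives on the
boundary, so integration by parts transfers derivatives onto the weight with
no boundary terms; the modulation is one of {1, cos(πx−θ_x), cos(πy−θ_y),
cos(πt−θ_t)} with independent random phases (four weights per subdomain).
Only derivatives attached to a term consisting of a *single* field factor are
transferred (one sign flip each); derivatives locked inside products stay on
the data — transferring them would require product-rule splittings that
change the library.  Integrals use the trapezoidal rule in physical
coordinates.

Subdomain extents default to 54×54×65 grid points and are clamped (with a
warning) to 42 % of any smaller grid axis, never below 9 points; centers are
uniform over admissible positions.  The number of subdomains is set so the
row count (subdomains × weights × tensor components) is at least 10× the
column count.  Rows for rank-2 symmetric-traceless terms use components
(1,1) and (1,2); antisymmetric uses (1,2).

Per-column single-term scales Ξ_r are Frobenius norms over rows of the weak
integrals of each term's fully uncontracted tensor (for ∇·u this is ‖∇u‖ —
the scale against which a single-term relation's residual is meaningful).
They are estimated on a fixed subsample of subdomains (default 4, giving
hundreds of entries per term); Ξ is a normalization scale, not a fitted
quantity, and the subsample changes it by well under a percent.

When the director field admits a seam-free global gauge, terms are evaluated
once on the full mesh (proper centered stencils throughout) and sliced per
subdomain; otherwise each subdomain re-gauges independently.

## Sparse regression

The relation coefficients solve min ‖Gc‖₂ over ‖c‖₂ = 1 — the right singular
vector of the smallest singular value.  Sequentially thresholded regression
(STR) repeatedly discards the term with the smallest magnitude ‖c_r G^r‖₂
and stops when the residual jumps by more than a factor γ or one term
remains.  Residuals are η = ‖Gc‖₂/Ξ with Ξ = max_r ‖c_r G^r‖₂ for multi-term
relations and the single-term scale above otherwise.

Numerical hardening around the skeleton (all observable in the reports):

- The jump rule and the full-library stopping residual use the *effective*
  residual min(multi-term η, best single-term η among active columns):
  an exact one-term relation makes the multi-term normalization saturate
  near 1 and would otherwise fire the jump rule on numerical noise.
- Columns whose single-term scale Ξ vanishes are identically zero on the
  data (e.g. any time derivative of a steady field); they are emitted
  directly as trivially exact relations instead of letting their quadrature
  dust distort the magnitude ordering.
- If one member column of a selected multi-term model already achieves the
  model's residual by itself, the single-term model is preferred (parsimony
  refinement).
- Ties in the drop rule remove the column later in canonical order.

Multiple relations are extracted by iterated STR: after each accepted
relation (η ≤ 0.1) its largest-magnitude term is removed from the library
and the search restarts, until the full-library residual exceeds 0.4.
Rejected candidates also prune their largest term so the loop terminates.
γ defaults to 1.15 at the algorithm level; the pipeline uses 1.3 — the top
of the method's robust range — because on short, noisy datasets the residual
creeps upward so slowly that γ = 1.15 halts while tens of noise-fitting
terms are still active.

Relations are labelled *identity* when re-evaluated on random smooth probe
fields with residual below 1e−6 (identities of vector calculus and the unit
director hold on any smooth data; physical relations do not), and *physical*
otherwise.  STR selections are validated by exhaustive combinatorial search
when C(N, K) permits (budget 10⁶).  Coefficient uncertainties come from 100
half-row subsamples with the support held fixed: the mean and standard
deviation over re-fits (signs aligned to the full solution) give the value
and its error.

## Synthetic data

The generators plant known relations so every stage is testable without
experimental data:

- **eq3 / eq4** — a solenoidal, *time-dependent* two-mode traveling
  stream-function flow (ψ = Σ_m (a_m/k_m) sin(k_m x − w_m t + p_m)
  sin(k_m y + q_m), amplitudes 0.7/0.35, wavenumbers 1/2, frequencies
  2.1/3.3) advects a director whose angle obeys
  ∂_t θ = −c₁ u·∇θ + c₂ Ω_xy + c₃(Ā_xx sin 2θ − Ā_xy cos 2θ)
  — the angle form of the planted director equation — integrated with RK4
  (4 substeps per frame) and Fourier spatial derivatives on the periodic
  box.  A *steady single-mode* cell flow was rejected: it satisfies
  Δu = −2k²u and has vanishing time derivatives, planting spurious exact
  relations in the libraries that no experimental dataset would contain.
  Generating the *angle* (a smooth scalar) keeps the generation path free
  of sign ambiguity, so the analysis path is what exercises alignment.
- Default grids are 64×64×64 (2π box, dt set by an advective CFL number of
  0.2).  The eq4 fixture uses 192 frames: coefficient identification needs
  data spanning several correlation times (the experimental dataset covers
  ~17 nondimensional time units; 64 frames cover well under one), and the
  initial angle field (rms 0.5, modes ≤ 2) is chosen so advective
  filamentation keeps neighbor rotations resolved over the run.
- **eq9/eq5** — steady extensional flow u = (Ex + g′(y), −Ey − f′(x)) with
  cubic mean-flow profiles (which add vorticity — needed for
  nondimensionalization — without changing the strain along the director),
  n = x̂, planted rate E = 0.56.  Both the scalar and the tensor stress
  balance hold exactly with c₅ = c₅′ = −E.
- **defect-mask** — an isolated ±1/2 defect (θ_n = m·atan2 + θ₀) with an
  intensity hole, for mask construction tests.
- **Noise**: per-component Gaussian velocity noise with SD = level × RMS,
  Gaussian angle noise with SD = level radians (renormalized).  The default
  test level is 20 % (the experimental level is not quantified; the weak
  form is reported to tolerate up to 100 %).

What the fixtures do *not* emulate: defect creation/annihilation, density
evolution, genuinely turbulent spectra, and measurement artifacts of PIV or
orientation extraction.  Passing tests therefore demonstrate the pipeline's
correctness and noise robustness on resolved, statistically stationary data
— not performance on raw microscopy.

## Known limitations

- Recovery of the director equation at 20 % noise depends on the pruning
  order of the iterated STR loop; with the pipeline defaults it succeeded on
  every seed tried, but the combinatorial search on reduced libraries is the
  robust validator.
- The structure-tensor orientation extractor is a lightweight stand-in for
  coherence-enhancing diffusion filtering; it is accurate away from defects
  but degrades faster near cores.
- Fingerprint deduplication is numeric, not a symbolic ideal-membership
  test; removals are logged so a run is auditable.
- The antisymmetric rank-2 library is generated and tested for symmetry
  correctness but no fixture plants a relation in it.
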