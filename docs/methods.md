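# Methods

This note records the models implemented in metacal, the parameter choices
that matter, and what the synthetic test bed does and does not demonstrate.

## Contact maps and path collective variables

A conformation is the vector of switching values `s(r) = (1−x⁶)/(1−x¹⁰)`,
`x = r/r0`, over a fixed contact selection (`r0` = 4.5 Å for polar contacts,
6.5 Å for side-chain contacts by convention).  The function is evaluated
through the exact factored form `(Σ_{j<6} x^j)/(Σ_{j<10} x^j)` — algebraically
identical, monotone, and free of the removable singularity at `x = 1` (where
`s = 3/5`); for `x > 1` the equivalent inverse-power form avoids overflow.
Contacts are deemed activation-relevant when the active/inactive switching
values differ by more than 0.65 **in absolute value**: a contact broken on
activation is as informative as one formed, so the one-sided convention is
not used.  Distance between conformations is the Euclidean norm of the
selected-contact vector.

### Path selection

The transition path is an ordered subset of N trajectory frames (default
N = 10) with endpoints pinned to the mutually furthest frame pair (ties broken
lexicographically).  Interior nodes minimize

    W = (k/2) · Σ_i (d_i − d̄)² · Σ_i d_i / Σ_j ρ_j ,

where `d_i` are edge lengths and `ρ_j` neighbour counts within a radius of
3× the median nearest-neighbour distance (self excluded).  The three factors
encode the three design goals — similar edges, short total length, nodes in
densely sampled (low-free-energy) regions — and the ratio form makes the
objective invariant to the absolute scale of the density counts.  A
weighted-sum variant (`form="composite"`) is retained; with raw neighbour
counts its density term dominates the geometry terms by 2–3 orders of
magnitude and it selects paths with strongly uneven edges, which is why it is
not the default.

Optimization is Metropolis simulated annealing: moves are {replace a random
interior node with an unused frame, swap adjacent interior nodes}; one sweep
is N−2 attempted moves; the schedule is geometric (factor 0.95, 40 levels,
200 sweeps per level).  Since k is a global factor of the ratio objective,
moves are scored at the final k and the schedule instead scales the Metropolis
temperature, calibrated to 0.1× the magnitude of the initial objective so
cooling happens at the problem's own energy scale.  The best state visited
(under the final-k objective) is returned, making results directly comparable
with exhaustive search; on instances small enough to enumerate (≤ 13 frames,
N ≤ 5) the annealer attains the exhaustive optimum in ≥ 95% of seeded runs.

Path CVs use `λ = 2.0` by default (an `auto` heuristic `λ = 2.3/⟨edge⟩` is
available) and a shifted log-sum-exp, so S ∈ [1, N] and Z are exact for any
`λ‖R − R_k‖`.

## Well-tempered MetaD reweighting

Bias, tempered heights and the free-energy limit follow the standard
well-tempered relations with bias factor `γ = (T+ΔT)/T` (default 12) and
free-energy prefactor `γ/(γ−1)`.  The correction `c(t)` is evaluated on a
per-CV grid (200 points spanning the hill centers ± 3× the largest σ) at each
deposition time as

    c(t) = kB·T · [ ln Σ_s e^{ γ/(γ−1) βV(s,t) } − ln Σ_s e^{ βV(s,t)/(γ−1) } ],

linearly interpolated between depositions, with c(0) = 0.  This is zero for
zero bias and equals V(t) for a spatially constant bias, so weights
`e^{(V_t−c_t)/kB T}` are invariant under any global shift of the bias after
normalization.  Energies default to kJ/mol with kB = 0.0083144621; the toy
stack uses reduced units (kB = 1, T = 1).

Dynamical averages `R(q) = ⟨|r_t(q) − r_{t+δt′}(q)|⟩` are reweighted with the
start-frame weight, numerator and denominator over the identical valid-pair
set; the prefactor is read as "mean over valid pairs" (the alternative
total-time normalization rescales all constraints uniformly and is absorbed
by the MaxCal lag convention).  The biased lag δt′ maps to an unbiased lag via
`δt = Δt Σ_s e^{(V_s−c_s)/kB T}`, summarized over the trajectory by the
median window sum (robust to transient bias spikes).

**Validity domain.**  The weight factor corrects the *ensemble* of visited
configurations exactly — on the 8 kT double well the reweighted profile
matches the analytic one to < 0.1 kT RMS — but it is only a short-lag
approximation for *dynamics*: once the lag is long enough for bias-driven
barrier recrossings to contribute, the reweighted displacement average
exceeds the unbiased one (the instantaneous weight does not encode the
barrier-top boost, which is the same reason infrequent-metadynamics needs
hills kept away from transition states).  Dynamical constraints are therefore
estimated at the shortest resolved lag, where the displacement statistics are
noise-dominated and the test against a long unbiased run agrees to < 10%.
This limitation is intrinsic to the estimator, not to the implementation.

## Information theory

All entropies are plug-in estimates on weighted histograms with *shared* bin
edges: every joint distribution is accumulated sparsely from digitized bin
indices (`np.unique` over occupied cells), so the up-to-7-dimensional joints
of the `MI(X∪Y, Z)` route never allocate a dense array, and the two CI routes
(`MI(X,Y) − MI(X,Y|Z)` vs `MI(X,Z)+MI(Y,Z)−MI(X∪Y,Z)`) agree to float
round-off by construction.  Natural log internally; bits via flag.  Default
binning is 12 bins per dimension with edges from the global min/max of each
coordinate class; the per-residue scan pools all residues' coordinates per
axis so every residue is binned identically — reusing edges across residues
is required for the ranking to be meaningful.  Raw CI values are always
reported; a normalized column divides by the maximum |CI| across residues.

Plug-in CI estimates of continuous noise variables carry a negative
O(K/n) bias from the high-dimensional joint.  An optional Miller–Madow
correction (`miller_madow=True`, off by default) adds `(K_occ − 1)/(2 n_eff)`
per entropy with the Kish effective sample size, which cancels the bias in
the CI combination to leading order; the ranking itself is insensitive to the
common bias, which is why the correction is optional.

Weighted PCA of pocket coordinates uses the weighted covariance
eigendecomposition, components ordered by variance and signs fixed so each
component's largest-magnitude loading is positive.

## Maximum Caliber models

Maximizing the path entropy `S = −Σ_ij π_i p_ij ln p_ij` under the mean jump
rate and displacement constraints gives transition weights
`W_ij = e^{−a} e^{−Σ_q b_q R_ij(q)}`; imposing detailed balance fixes the
π-ratio exponent to one half:

    κ_ij = μ √(π_j/π_i) e^{−Σ_q b_q R_ij(q)},  i ≠ j,  κ_ii = −Σ_{j≠i} κ_ij,

the only form for which `π_i κ_ij = π_j κ_ji` holds with a symmetric kernel.
`R_ij(q) = |q̄_i − q̄_j|` uses absolute state-mean CV differences, keeping R
symmetric as detailed balance requires.  `p = e^{δt κ}` is computed by
eigendecomposition of the symmetrized generator `D^{1/2} κ D^{−1/2}`
(guaranteed real spectrum under detailed balance).

**Solver.**  The mean jump rate is linear in μ at fixed b:
`⟨N⟩ = μ Σ_{i≠j} √(π_i π_j) e^{−b·R_ij}`, so μ is eliminated in closed form
and only the b_q (one per constraint, typically two) are solved by a hybrid
Powell root find on the relative residuals of `Σ_ij π_i p_ij R_ij(q) =
R0(q)·δt`; convergence demands residuals ≤ 10⁻⁸, and a failed solve probes
the monotone extremes of b to distinguish infeasible targets from
non-convergence.  Constraints generated from a model of this family are
recovered entrywise to 10⁻⁶ relative (round-trip test).

**Microstates and empirical constraints.**  Microstates are weighted k-means
clusters (seeded k-means++, default 20 states); π_i is the normalized member
weight and q̄_i the weighted member mean.  N0 is the fraction of (t, t+δt)
pairs whose state changed, per unit time; R0(q) is the mean |q̄ difference|
over the same pairs — state-mean-based, so the empirical targets live on
exactly the scale of the model quantity.  For MetaD input the pairs are
weighted by the start-frame unbiasing weight and δt is the median rescaled
lag.

**Lag choice.**  The model lag must sit above the intra-basin relaxation time
(otherwise the displacement constraints only see intra-basin diffusion and
the maximum-entropy model, which cannot know barrier heights, overestimates
hopping rates) and below the passage times of interest.  On the bundled
four-well system (intra-basin relaxation ≈ 0.1 time units, passage times
40–90) the default lag is 5 time units; region MFPTs then agree with a direct
count-matrix MSM of the same trajectory to a geometric-mean fold error of
about 1.6.

MFPTs solve `Σ_j κ_ij m_j = −1` outside the target with m = 0 on it;
region-level values are the π-weighted source average with π renormalized
within the source region.  Regions are axis-aligned boxes over CV space
(quadrants for the four-well system); overlapping boxes are rejected.

## Synthetic dynamics

Overdamped (Brownian) Euler–Maruyama integration,
`x ← x − ∇U dt/γ_f + √(2 kT dt/γ_f) η`, in reduced units (kB = 1, friction 1,
kT = 1, dt = 0.005–0.01); overdamped rather than full Langevin because the
MetaD-dynamics results the reweighting relies on are formulated for
reversible diffusions, and it has two fewer parameters.  Everything is seeded
and bit-reproducible.

* **Double well** `U = h(x²−1)²`, default barrier h = 8 kT — high enough that
  unbiased crossings are rare on test timescales, matching the regime
  enhanced sampling is for.
* **Four-well 2-D landscape** `U = −ln Σ_m w_m N(x; μ_m, σ²I)` with minima at
  (±1, ±1), σ = 0.3 and weights (0.35, 0.30, 0.20, 0.15): at kT = 1 the
  Boltzmann density *is* the mixture, so basin populations equal the weights
  up to overlap and every downstream quantity has a quadrature/count
  ground truth.  Saddle heights are ≈ 5 kT, giving a few hundred transitions
  per basin pair in a 2·10⁶-step run — enough for a stable reference MSM.
* **ABMD ratchet**: elastic bias `½k(d − d_min)²` on the distance to a target,
  active only when d exceeds its running minimum; stepwise-increasing k
  (0.1 → 15 by default) mirrors staged ratchet protocols.
* **Well-tempered MetaD**: on-the-fly hills (default height 1.2 kT, σ = 0.15,
  every 500 steps, γ = 12 — the deposition cadence playing the role of the
  τ = 5 ps interval of production MetaD setups) with the instantaneous bias
  logged per frame and the hills round-trippable through the HILLS writer.
* **Planted information fields**: pocket PCs and activation CVs driven by a
  common latent; "redundant" residues follow the latent with Gaussian noise,
  "synergistic" residues mix the latent sign with an independent binary
  through a parity construction, "noise" residues are independent.

What the synthetic bed does **not** emulate: real contact-map dimensionality
(hundreds of contacts), inertial/multiscale dynamics, anisotropic diffusion,
CV-measurement noise, and the approximate Markovianity questions of real MD.
Passing tests therefore demonstrates correctness of the estimators and
solvers under the stated model assumptions, not accuracy on any particular
receptor.

## Numerical conventions

Degenerate inputs raise typed errors (`metacal.errors`) rather than warnings:
non-positive r0 or radii, overlapping variable blocks, unnormalized
histograms, overlapping region boxes, unreachable MFPT targets, infeasible
constraint targets.  Text tables are written with 10 significant digits in
the C locale and round-trip bit-identically through the COLVAR/HILLS
readers.  Ties (endpoint pairs, PCA signs) are broken deterministically.
Out-of-range histogram samples are dropped with a warning by default.
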