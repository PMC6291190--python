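# metacal

Post-processing toolkit for estimating the **thermodynamics and kinetics of
slow conformational transitions** — the motivating case being G protein-coupled
receptor (GPCR) activation, e.g. the μ-opioid receptor — from well-tempered
metadynamics (MetaD) simulations run with path collective variables, without
any further sampling.

It combines four analysis stages, each usable on its own:

1. **Contact-map paths** (`metacal.contacts_paths`) — conformations are
   contact-map vectors `R_i = s(r_i)` with the rational switching function
   `s(r) = (1 − (r/r0)^6) / (1 − (r/r0)^10)`; an N-node transition path is
   selected from trajectory frames by simulated annealing of
   `W = (k/2) Σ_i (d_i − d̄)² · Σ_i d_i / Σ_j ρ_j`
   (equal edges, short path, densely sampled nodes), defining the smooth path
   CVs `S(R) = Σ_k k e^{−λ‖R−R_k‖} / Σ_k e^{−λ‖R−R_k‖}` and
   `Z(R) = −λ⁻¹ ln Σ_k e^{−λ‖R−R_k‖}`.
2. **Reweighting** (`metacal.metad_reweight`) — well-tempered bias
   `V(s,t) = Σ_{t′≤t} w_{t′} Π_i exp(−(s_i−s_i(t′))²/2σ_i²)` with tempered
   heights `w_{t′} = w e^{−V/k_B ΔT}`; free energies from
   `F = −(γ/(γ−1)) V` and unbiased static/dynamical averages via
   Tiwary–Parrinello weights `e^{(V_t − c_t)/k_B T}` with the running
   correction `c(t)`, plus the rescaled lag
   `δt = Δt Σ_s e^{(V_s − c_s)/k_B T}`.
3. **n-body information theory** (`metacal.nbit`) — weighted-histogram
   entropies, mutual information and the three-body co-information
   `CI(X,Y,Z) = MI(X,Y) − MI(X,Y|Z)`, scanned per residue to rank allosteric
   conduits between the ligand pocket and the activation CVs (negative CI =
   synergy = information transmission).
4. **Maximum Caliber models** (`metacal.maxcal_msm`) — the maximum-path-entropy
   Markov model consistent with a stationary distribution π, a mean jump rate
   ⟨N⟩ and CV-displacement averages ⟨R_q⟩, with detailed-balanced rates
   `κ_ij = μ √(π_j/π_i) e^{−Σ_q b_q R_ij(q)}`, transition matrix
   `p = e^{δt κ}`, and mean first passage times from the first-step linear
   system.

A synthetic-dynamics module (`metacal.synthetic`) provides seeded Brownian
dynamics on analytic potentials (double well, four-well Gaussian-mixture
landscape), ABMD-style ratchet runs, on-the-fly well-tempered MetaD, a
count-matrix reference MSM, and feature fields with planted
redundant/synergistic information structure — so every stage is verifiable
against ground truth on a laptop.

## Worked example

```python
import numpy as np
from metacal import synthetic as syn, contacts_paths as cp, metad_reweight as mr

# 1. select a 10-node activation path through a noisy contact-map transition
frames = syn.curved_contact_trajectory(n_frames=200, seed=0)
path = cp.anneal_path(frames, cp.AnnealConfig(n_nodes=10, seed=0))
print("endpoints:", path.endpoint_indices)
print("edge-length variance: %.2e" % path.edge_lengths.var())
S, Z = cp.path_cvs(frames[100], path)
print("frame 100: S = %.3f, Z = %.3f" % (S, Z))

# 2. reweight a well-tempered MetaD run on an 8 kT double well (gamma = 12)
traj, hills = syn.metad_run(
    syn.DoubleWell1D(barrier=8.0),
    syn.SimConfig(dt=0.005, n_steps=600_000, seed=0, stride=1),
    height=1.2, sigma=0.15, deposit_stride=500, bias_factor=12.0,
)
wt = mr.reweight_trajectory(traj, hills, ["x"], bias_col="bias")
x, w = traj["x"].to_numpy(), wt.weights
print("hills deposited:", len(hills))
print("reweighted well populations: left %.3f / right %.3f"
      % (w[x < 0].sum() / w.sum(), w[x > 0].sum() / w.sum()))
```

prints

```
endpoints: (39, 119)
edge-length variance: 1.59e-04
frame 100: S = 3.778, Z = -0.520
hills deposited: 1200
reweighted well populations: left 0.485 / right 0.515
```

The path's nine edges are equal to within variance 1.6·10⁻⁴ (the annealing
objective converges well below the 0.05 quality threshold); frame 100 sits
between path nodes 3 and 4 and slightly off-path (Z < 0 means inside the
softmin envelope of the nodes).  The reweighted populations of the two
symmetric wells are equal to within sampling error, and the reweighted
free-energy profile reproduces the analytic 8 kT barrier (the same run gives
a barrier estimate of 7.9 kT).

## Command line

Each stage is exposed as a subcommand of `metacal` — `simulate`, `path-find`,
`cv-eval`, `reweight`, `fes`, `nbit`, `maxcal`, `mfpt` — and
`metacal pipeline --config run.yaml` chains them on one run directory with a
manifest so unchanged stages are skipped on re-run.  All subcommands take
`--seed`, `--log-level` and `--out`.

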