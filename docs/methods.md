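# Methods

## Model and assumptions

The cell is modeled in the regime where both RNA polymerases and
ribosomes are limiting, so transcription of gene *i* is proportional to
its polymerase allocation fraction φ_i(c) = g_i(c)/Σ_j g_j(c) and
translation to the mRNA fraction c_mi/c_mT. Cell volume is proportional
to total protein (unit density, equal protein masses), which makes the
protein concentrations sum to one identically and turns the simplex
into the natural state space. Regulation acts multiplicatively on
effective gene copy numbers through Hill functions of regulator
concentrations; independent regulators stack as factors
(1 + γ_ij f_ij). The ribosome gene (index N−1) never regulates; the
RNA polymerase gene is index N−2. All internal indexing is 0-based.

Two dynamical layers are implemented: the full coupled mRNA/protein
concentration system (2N equations) and its fast-mRNA reduction
dc/dt = k_p c_r (φ(c) − c). Molecule-number dynamics appear only as a
test oracle for the growth-rate identity μ = k_p φ_r − 1/τ_p; other
cellular regimes (gene-copy-limited transcription, mRNA-limited
translation) and stochastic expression noise are out of scope.

## Parameters

| symbol | meaning | default | rationale |
| --- | --- | --- | --- |
| Ω_max | upper bound of per-edge fold-change, Ω_ij ~ U(1, Ω_max) | per experiment | 1.5–2 for scaling studies; 1000 for empirical-composition studies (TFs change targets 100–1000 fold) |
| h | Hill coefficient (global) | 1 | 1 for scaling/bipartite studies, 2 for composition studies |
| K_ij | activation threshold | κ/N, κ = 1 | TF binding thresholds are comparable to TF concentrations, which scale as 1/N |
| g_i0 | unregulated copy number | U(0.5, 1.5) | unit-mean range bounded away from 0, avoiding degenerate allocations; only ratios matter |
| k_m, k_p | transcription/translation rates | 1 | time measured in units of 1/k_p |
| τ_m, τ_p | mRNA/protein lifetimes | 0.1, 10⁶ | fast-mRNA growing regime for N up to a few thousand; only ω = (1/τ_m − 1/τ_p)/β0 affects the 2N spectrum, and nothing dynamical depends on the lifetimes beyond it |
| P_neg | inhibitory edge fraction | 0.5 | equal up/down unless an empirical census dictates otherwise |

Sign assignment is exact (round(P_neg·u) repressing edges placed by a
seeded shuffle) rather than per-edge Bernoulli, so requested fractions
reproduce exactly. All generators take explicit integer seeds; every
ensemble replicate records the derived sub-seed that regenerates it
bit-for-bit.

## Synthetic networks

`gen_random` samples edges uniformly from the (N−1)² ordered pairs with
the ribosome excluded as regulator and self-loops excluded. A pool of
exactly N(N−1) pairs cannot simultaneously exclude both; self-loops are
excluded by default so that the random-versus-acyclic comparison
isolates cycle structure, and a flag restores the N(N−1) pool with
self-loops for sensitivity checks (an O(1/N) difference). `gen_dag`
rejects any proposal that closes a directed cycle and flags a shortfall
if the proposal budget is exhausted. `gen_bipartite` allows edges only
from the first q indices (TFs) to the rest. Two scrambling null models
randomize an empirical composition: `scramble_fixed_q` (keeps N, q, u
and the activation count) and `scramble_composition` (additionally
keeps the self / TF→otherTF / TF→nonTF category counts and their
per-category activation counts). `ecoli_like_fixture` applies the
latter to the census of the curated *E. coli* network; the three
category counts (134 + 373 + 5148 = 5655) are taken as authoritative
for the total. What these networks do **not** emulate: scale-free
out-degree distributions, motif enrichment (feed-forward loops, single
input modules) beyond what the category census implies, and
gene-specific parameter heterogeneity — conclusions about those
features of real networks are outside what passing tests establish.

## Fixed-point solver

Steady states solve c = φ(c). The solver runs a damped iteration
c ← (1−α)c + αφ(c) (α = 0.5, max-norm tolerance 10⁻¹⁰, up to 10⁵
iterations, 3 restarts from independent uniform simplex points drawn
by exponential normalization). The iterate remains on the simplex, so
divergence cannot occur; non-convergence manifests as a stalling
residual, detected over 1000-iteration windows. On a stall a damped
Newton polish on F(c) = φ(c) − c is attempted from the best iterate:
this recovers fixed points whose interaction spectrum has large
imaginary parts (the damped map can spiral even when the dynamical
fixed point is stable). "No findable fixed point" — all restarts
exhausted — is reported, not raised; it is the instability observable
for strongly interacting networks. A final undamped step makes the
no-regulation case exact to machine precision. Multistability, if two
restarts converged to different points, would surface through the
restart-agreement test; it has not been observed at the tested
densities.

## Spectra

The nonzero spectrum of M is computed from the q×q TF block Q
(dense LAPACK eigensolver); since columns of M outside the TF set
vanish, eig(M) = eig(Q) ∪ {0}^(N−q) and λ_M,rmax = max(max Re eig(Q), 0)
whenever q < N. The stability verdict uses a margin of 10⁻⁸ below the
λ = 1 boundary, and the boundary itself counts as unstable. The 2N×2N
Jacobian is assembled analytically (all state dependences included:
allocation fractions, polymerase/ribosome concentrations, total mRNA
pool); finite differences exist only as test oracles.

A caution for anyone re-deriving the eigenvalue mapping numerically:
the structural zero eigenvalues of M (genes that regulate nothing)
form defective clusters whose images lie at λ̃ = −1 and −(1+ω). Double
precision cannot resolve those clusters to better than ~10⁻²
regardless of implementation, so the test suite verifies the mapping
through the characteristic-polynomial identity
det(J̃ − zI) = (1+ω)^N det(w(z)I − M) with
w(z) = (z+1)(z+1+ω)/(1+ω) at random probe points (agreement ~10⁻¹²)
and matches individual eigenvalues at 10⁻⁶ only away from the
defective images.

## Dynamics classification

Long-run behavior is labeled from the reduced system by a two-stage
protocol: settle onto the attractor, then analyze a window starting
there, with a twin trajectory perturbed by 10⁻⁸ (relative,
re-normalized to the simplex) at the window start. Labels, in order:
`fixed_point` if the per-gene relative fluctuation stays below 10⁻⁶;
`oscillatory` if a dominant spectral peak and its harmonics hold at
least half the fluctuation power, the implied period fits at least
three times into the window, and the twins do not diverge; `chaotic`
if the log twin separation grows at a positive fitted rate (middle
third of the growth segment, guarded by twice the regression standard
error and by at least two decades of total growth); otherwise
`undetermined`.

By default the classifier integrates the orbit-equivalent
intrinsic-time system dc/ds = φ(c) − c, where ds = k_p c_r dt. The
reparameterization preserves fixed points, periodic orbits and the
signs of divergence rates, and removes a degeneracy of the wall-clock
formulation: strongly repressed states drive c_r (and with it every
rate in the system) down by many orders of magnitude — values around
10⁻⁹ were measured at Ω_max = 200 — so wall-clock trajectories freeze
on any feasible horizon while the orbit itself is far from an
attractor. Intrinsic-time horizons of a few thousand units
(transient 2000, window 4000, 8192 samples) resolve the attractors;
wall-clock integration remains available with `clock="wall"`.

At the strong-coupling benchmark (N = 200, ρ = 0.2, h = 1) the
ensemble straddles the stability threshold: across ten networks at
Ω_max = 20 the labels split 4 chaotic / 4 fixed-point / 2 oscillatory,
and at Ω_max = 200, 6 chaotic / 3 fixed-point / 1 oscillatory.
Oscillation as the *typical* ensemble outcome at Ω_max = 20 does not
reproduce under these conditions — individual networks pass through an
oscillatory window at network-specific coupling strengths instead —
and the corresponding acceptance test records that disagreement rather
than papering over it.

## Ensemble experiments

All sweeps return tidy per-replicate records plus median/IQR summaries
(the statistic used throughout), with failed fixed points counted and
excluded from medians. P(stable) uses the nested "sets of replicates"
design (default 15 sets × 10 networks; the desk-scale acceptance runs
use 5 × 5 at N = 500 with the empirical composition scaled
proportionally, q = 47). The √N-scaling sweep fits the log-log slope
of median λ_M,rmax against N over N ∈ {100, 200, 400, 800} at
ρ = 0.01 (10 replicates); on this grid the fitted slope is 0.63–0.69
across master seeds because the N = 100 point (only ~100 edges) is
pre-asymptotic — over {200, 400, 800} the same data give 0.51–0.55,
consistent with the √N law. The bipartite sweep locates the critical
inhibitory fraction as the smallest grid value whose median λ_M,rmax
exceeds 10⁻¹² (exact zeros below threshold are a structural property
of λ_M,b = max(λ_Q,b, 0)); on the 0.05 grid at N = 1000, q = 100 it
lands at 0.65.

## Known limitations

* The oscillation/chaos criterion is a heuristic (spectral
  concentration plus twin divergence), not a Lyapunov-spectrum
  computation; borderline attractors can land in `undetermined`.
* The solver's "no findable fixed point" conflates nonexistence with
  failure of all restarts; no homotopy continuation across Ω_max is
  attempted, and multiple coexisting fixed points are not enumerated.
* Dense eigendecompositions cap practical sizes near N ≈ 2500 (the
  TF-block shortcut keeps empirical-scale networks cheap).
* Only the polymerase- and ribosome-limited regime is implemented;
  post-transcriptional regulation and division-time stochasticity are
  not modeled.
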