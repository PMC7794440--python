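# grnstab

Stability analysis of transcriptional regulatory networks in growing
cells.

Protein concentrations inside a cell must be stable against
fluctuations, yet gene expression is regulated by proteins
(transcription factors, TFs), so the full proteome is a large system of
interacting components that can, in principle, go unstable the way
large random ecosystems do. `grnstab` implements a growing-cell model
of coupled mRNA/protein dynamics under transcriptional regulation and
asks when the steady state survives: how stability scales with the
number of genes *N*, how network topology (random, acyclic, bipartite,
or scrambled empirical networks) changes the answer, and why mRNA and
protein degradation rates do not change it at all. It is aimed at
systems biologists and quantitative modelers studying regulatory
network architecture; everything runs on synthetic networks, including
a generator that emulates the interaction composition of the curated
*E. coli* transcriptional regulatory network (2274 genes, 211 TFs,
5655 signed interactions).

## Model

Each gene *i* carries an effective copy number modulated
multiplicatively by its regulators,

```
g_i(c) = g_i0 · Π_j (1 + γ_ij f_ij(c_j)),     f_ij(c) = c^h / (K_ij^h + c^h),
```

with γ_ij = Ω_ij − 1 for activation and 1/Ω_ij − 1 for repression
(Ω_ij ~ U(1, Ω_max) is the saturated fold-change). When RNA
polymerases and ribosomes are both limiting, transcription of gene *i*
is proportional to its allocation fraction φ_i = g_i / Σ_j g_j and the
concentration dynamics are

```
dc_mi/dt = k_m φ_i(c) c_n − c_mi (k_p c_r + 1/τ),    1/τ = 1/τ_m − 1/τ_p,
dc_i/dt  = k_p c_r (c_mi / c_mT − c_i),
```

where c_n, c_r are the RNA polymerase and ribosome concentrations and
c_mT = Σ c_mi. In the fast-mRNA limit this reduces to
dc_i/dt = k_p c_r (φ_i(c) − c_i), whose fixed point satisfies
c^ss = φ(c^ss). Stability is decided by the interaction matrix

```
M_ij = ∂φ_i/∂c_j |_ss = c_i^ss (M1_ij − M2_ij),
```

where M1 holds the direct regulatory derivatives ∂log g_i/∂c_j and M2
(rank 1) the indirect competition for shared machinery: the fixed point
is stable iff the maximal real part λ_M,rmax of M's eigenvalues is
below 1. Because regulators are TFs, the nonzero spectrum of M lives
in the q×q TF block Q; for strictly bipartite networks Q is rank 1
with the closed-form eigenvalue λ_Q,b = −Σ_{i∈TF} c_i ∂log g_T/∂c_i
and λ_M,b = max(λ_Q,b, 0). For the full 2N×2N Jacobian J, the scaled
eigenvalues λ̃ of J/β0 (β0 = k_p c_r^ss) obey

```
λ̃ = ½(−ω ± sqrt(ω² + 4 λ_M (1 + ω))) − 1,     ω = 1/(τ β0) ≥ −1,
```

which crosses Re λ̃ = 0 exactly at λ_M = 1 for every admissible ω:
degradation rates tune relaxation speed, never stability.

## Worked example

Compare a synthetic network carrying the *E. coli* interaction
composition with a fully random network of the same density at strong
regulation (Ω_max = 1000, h = 2):

```python
import grnstab as g

es = g.ecoli_like_fixture(seed=1)
comp = g.census(es)
# u = 5655  q = 211  rho = 0.0011  rho_q = 0.00842

net = g.assign_parameters(es, omega_max=1000.0, h=2.0, seed=2)
report = g.analyze(net, params=g.CellParams(tau_m=0.1, tau_p=1e8), seed=3)
# converged=True stable=True lambda_max=0.1619
# beta0=6.083e-07  omega=1.644e+07  mu=5.983e-07

es_rand = g.gen_random(2274, comp.density,
                       1 - comp.n_activating / comp.n_edges, seed=1)
net_rand = g.assign_parameters(es_rand, omega_max=1000.0, h=2.0, seed=2)
g.analyze(net_rand, seed=3)
# converged=False stable=False lambda_max=nan
```

The composition-preserving network sits deep in the stable regime
(λ_M,rmax = 0.16 « 1) and grows exponentially at rate μ ≈ 6·10⁻⁷ k_p;
the random network of identical density and activation fraction has no
findable fixed point at all — the interaction composition, not just
the density, is what stabilizes the system. Ensemble versions of this
comparison (and the √N-scaling, bipartite-threshold and TF–TF-density
sweeps) live in `grnstab.experiments`, or from the shell:

```
grnstab generate --topology ecoli-like --seed 1 --out net.tsv
grnstab census net.tsv
grnstab sweep --config sweep.yaml --outdir results/
```

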