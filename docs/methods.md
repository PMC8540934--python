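# Methods

## The model

The package follows 17 interacting quantities in a breast-tumor
microenvironment: naive/helper/cytotoxic/regulatory T cells (TN, Th, Tc,
Tr), naive/activated dendritic cells (DN, D), naive/activated macrophages
(MN, M), cancer cells (C), necrotic cells (N), cancer-associated
adipocytes (A), and six molecules — HMGB1 (H), IL-12, IL-10, estrogen
(E), IFN-γ (Iγ) and IL-6.  Cells are in absolute counts, molecules in
relative expression units, time in days.

All interactions are mass-action, with three logistic self-renewal
terms.  Naive pools lose exactly the activation flux that the activated
pools gain (plus constant sources A_TN, A_DN, A_M and linear death),
which bounds activation without additional nonlinearities.  Cancer
proliferates logistically with capacity C0, stimulated by IL-6 and
adipocytes, and is killed by cytotoxic cells, IFN-γ and natural death:

    dC/dt = (λ_C + λ_CIL6·IL6 + λ_CA·A)(1 − C/C0)·C
            − (δ_CTc·Tc + δ_CIγ·Iγ + δ_C)·C.

A fraction α_NC of dying cancer cells becomes necrotic debris, cleared at
rate δ_N.  Adipocytes and estrogen carry their own logistic terms
(capacities A0, E0).  Decay/inhibition groups always multiply the cell
variable as a grouped factor, e.g. the Th losses read
(δ_ThTr·Tr + δ_ThIL10·IL10 + δ_Th)·Th.

The system has exactly 75 named parameters (44 production/activation
rates, 24 death/inhibition rates, 3 sources, 3 capacities, α_NC); the
right-hand side, both analytic Jacobians and the estimation rows are all
generated from a single term table (`tme.ode.TERMS`), so they cannot
drift apart.

## Cohort processing and clustering

Deconvolution tables (LM22 dialect: 22 cell-type fractions plus
P-value/Correlation/RMSE) are collapsed onto the model pools
(e.g. Tc = CD8 + activated NK; MN = M0 + monocytes; M = M1 + M2), and
molecules onto their encoding genes (IL12 = IL12A + IL12B,
E = ESR1 + ESR2, ...).  Patients with deconvolution p ≥ 0.05 (strict
inequality) or missing source-required clinical fields are excluded;
zero fractions are replaced by 10% of the smallest positive fraction of
the table.  Absolute numbers derive from tumor bulk with density scale
α = 4.5×10⁴ cells per unit and the immune:cancer:necrotic composition
0.3:0.6:0.1: for size+necrosis sources N = TCN·Np, C = ⅔·TCN·(1−Np),
TIC = 0.5·C; for weight-only sources TIC comes from the deconvolution
immune content and C = 6/7·(TCN − TIC), N = C/6.  If the two independent
formulas give TIC > TCN for a patient, TIC is clipped with a warning.
Adipocytes are set to twice the total immune count.

Clustering is K-means (25 restarts, fixed seed) on the unstandardized
fractions; K is chosen at the maximum-curvature point of WCSS versus K,
measured as the second difference of log WCSS.  (On a clustered dataset
WCSS decays roughly geometrically up to the true K and then flattens;
the raw second difference peaks at K = 2 for about half of the synthetic
seeds, the log-scale version recovers the planted K reliably.)  Cluster
profiles take initial conditions from members at or below the 10th
percentile of total cell number, steady states from those at or above
the 90th, and scale maxima as per-variable cluster maxima; the
percentile cutoffs are configurable and logged.

## Parameter estimation

Thirteen death rates come from measured half-lives
(`src/tme/data/known_rates.yaml`): naive T cells ~1 year, effector CD8/NK
~41 h, CD4 ~3 d, Treg ~2 d, activated DC ~2.5 d, macrophages ~1 month,
adipocytes ~6 months (the remodelling scale of tumor-associated
adipocytes; it also places the slowest system mode well inside the
3000-day simulation horizon), HMGB1 and estradiol ~2 h, IL-6 ~1 h, IL-10
~3 h, IL-12 ~8 h, IFN-γ ~4 h.  Five quantities are configured rather
than estimated: the capacities C0, A0, E0 (headroom 1.2 × the scale
maxima — they enter nonlinearly and are not identifiable from one steady
state), the necrotic fraction α_NC = 0.5, and the necrotic clearance
δ_N = 0.2/day (t½ ≈ 3.5 d).

The remaining 57 rates are determined by requiring F(X∞, θ) = 0 at the
cluster steady state.  Each of the 17 equations is linear in θ once X∞
is fixed, and 40 linear assumption relations
(`src/tme/data/assumptions.yaml`) complete a square system, solved
exactly (LAPACK) with a nonnegative-least-squares fallback for modified
or inconsistent configurations.  Negative estimates are an error, never
clipped.  The relations state that competing channels of one equation
are comparably effective once each rate is weighted by the scale maximum
of its interacting variable, e.g.

    scale × δ_CTc·[Tc_max] = 6·δ_CIγ·[Iγ_max]        (kill_split_tc_vs_ifng)
    scale × δ_C            = 6·δ_CIγ·[Iγ_max]        (death_split_natural_vs_ifng)
    scale × 2·λ_CA·[A_max] = λ_CIL6·[IL6_max]        (growth_split_adipocyte_vs_il6)

plus the macrophage-activation splits (`m_act_*`) and analogous relations
for the remaining blocks.  The cancer death side is anchored through the
necrotic balance α_NC·(δ_CTc·Tc∞ + δ_CIγ·Iγ∞ + δ_C)·C∞ = δ_N·N∞, i.e.
the observed necrotic load fixes the total cancer loss rate; the cancer
steady-state equation then fixes the growth scale.  Down-scaling the
kill split raises δ_CTc and lowers δ_C; down-scaling the natural-death
split lowers δ_CTc and raises δ_C — the qualitative response pattern the
scaling experiments probe.
Assumption configs are YAML and fully user-replaceable; `max:` factors
can be switched globally to steady-state (`ss:`) context.

The five reference cluster profiles shipped in
`src/tme/data/study_clusters.json` carry the reference per-cluster
initial and steady states of a TCGA+METABRIC-derived breast-cancer
cohort.  Patient-level cohort maxima are not recoverable for most
variables and are set to 1.5 × the across-cluster maximum of the summary
values — a synthetic stand-in — except [Tc_max] = 2.495×10⁴ and
[Iγ_max] = 8.78, which are implied (to <0.3% consistency across all five
clusters) by the reference death-rate estimates themselves.

## Nondimensionalization

Variables are divided by their scale maxima; time stays in days.  A rate
in a term p·(∏ states) feeding equation i rescales by (∏ state scales)/
(scale of i); activation rates shared with naive-pool equations scale by
their activated pool's equation, and the rescaled system accounts for
the pool ratio internally, so rescaled trajectories reproduce
dimensional ones exactly (tested to 1e-6) and round-trip to 1e-12.
Sensitivity analysis runs on the nondimensional system for conditioning.

## Simulation

`scipy.integrate.solve_ivp` with LSODA (stiffness-switching) and the
analytic Jacobian, rtol 1e-8 / atol 1e-10: the state spans ~10⁰–10⁵
across variables and molecule clearance is fast against cellular
turnover.  Steady state is declared at ‖F(x)‖/‖x‖ < 1e-8; when a
converged result is requested the horizon (default 3000 d) doubles up to
4 times.  Negative excursions are clipped to zero in reported
trajectories only, never inside the solver state.

## Sensitivity analysis

Local: s = dX*/dθ = −(∂F/∂X)⁻¹(∂F/∂θ) with analytic Jacobians, verified
against central finite differences of the re-solved steady state (1e-4
relative).  Outputs of interest are the cancer steady state and total
cells = Th + Tc + Tr + DN + D + 0.2·MN + M + C + N + A (naive T cells
circulate and are excluded; 20% of naive macrophages count as
tumor-resident).

Global: each assumption relation k is rescaled over [0.01, 100]
(Gauss–Legendre nodes on log10 scale; 33 nodes by default, convergence
tested by node halving), the parameters are re-estimated at every node
(the steady state stays pinned to the cluster data) and

    S_ik = ∫ s_i dθ

is integrated as a line integral along the induced nondimensional
parameter path (arc-length weighting; plain log10-scale measure
selectable).  Neighborhood weights decay with the mean relative distance
of the re-estimated sets from the base set, w̃_k = exp(−d_k), normalized
to sum to one, and S_i = Σ_k w_ik·S_ik.  In every reference cluster the
adipocyte parameters λ_A (positive) and δ_A (negative) rank among the
top global cancer sensitivities, reflecting the direct adipocyte drive
of cancer proliferation.

## Bifurcation analysis

With IL-6, A, Tc and Iγ frozen at cluster steady states the cancer
equation is scalar logistic with growth Λ and loss Δ; equilibria are 0
and C* = C0(1 − Δ/Λ) (present iff Λ > Δ, always < C0), exchanging
stability transcritically at Λ = Δ.  Stability is the sign of the scalar
derivative; thresholds are linear solves in the swept parameter.  In all
five reference clusters the tumor is cleared for λ_C below its
transcritical value.

## The synthetic cohort generator

Emulates the deconvolution + expression + clinical inputs: five
Dirichlet components around synthetic centroids (tightness 60 on the
centroid component plus a symmetric concentration, default 1, acting as
the separation control — raising it blurs the planted structure
monotonically), log-normal tumor sizes (median 2.5, σ_log 0.4) and
weights (median 60, σ_log 0.5), Beta(2, 18) necrosis (mean 0.1, matching
the assumed necrotic share), log-normal molecule expressions with mild
per-cluster tilts, and a deconvolution p-value column with ~10% planted
failures.  It does not attempt realistic transcriptome marginals, batch
effects, or empirical LM22 correlation structure — passing pipeline
tests on it demonstrates the machinery (clustering recovery, estimation,
convergence), not fidelity to any real cohort.

## Numerical and design choices

* Estimation solve: exact for the square consistent default; NNLS with
  residual reporting otherwise; rank computed on a column-equilibrated
  matrix (columns span ~10 orders of magnitude).
* Saturation time: first time the cancer trajectory enters and remains
  within 5% of its terminal value.
* Perturbation envelopes: 200 draws by default, each sensitive parameter
  independently scaled by U[1−f, 1+f].
* Default problem sizes used by the test suite and the reproduction
  script: 33 (or fewer) quadrature nodes per neighborhood, 500-patient
  synthetic cohorts, 3000-day horizon with at most 4 doublings.

## Known limitations

* The assumption set beyond the six reference relations is this
  package's own completion; with it, the base cluster-1 cancer death
  rate δ_C reproduces the reference value to ~2%, but the reference
  *rescaled* estimates (and with them per-cluster contrasts such as the
  special λ_CA-sensitivity of the lowest-adipocyte cluster) depend on
  additional coupling between growth- and death-side relations that the
  reference summary tables do not determine; the rescaled δ_C here responds
  in the right direction but with smaller magnitude.
* Macrophages form a single pool (no M1/M2 split); no spatial dynamics;
  no treatment terms; survival fields are consumed, not modelled.
* Capacities are configured, not identified; conclusions that hinge on
  the distance of a steady state from its capacity inherit the headroom
  choice (1.2).
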