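# Methods

`idopnet` reconstructs individualized, signed, weighted, directed genetic
networks from longitudinal mapping data in four stages: functional mapping
of per-SNP genotypic trajectories, functional clustering of those
trajectories into modules, mixed-ODE decomposition of each trajectory into
self-driven and regulator-driven parts with group-LASSO regulator
selection, and assembly of epistatic/pleiotropic edge lists.  A built-in
five-SNP simulator defines the conditions under which edge-recovery power
is evaluated.

## Functional mapping

At each SNP the population splits into genotype classes (two for a
testcross marker, three for an intercross).  Each class has its own
logistic mean curve per trait, `a / (1 + b e^{-r t})`; all classes share a
first-order structured antedependence, SAD(1), residual covariance:
`z_j = phi z_{j-1} + eps_j`, `eps_j ~ N(0, nu2)` with zero pre-sample
state.  This nonstationary convention gives a variance profile that grows
to its stationary level, the standard choice in functional mapping, and
yields closed forms: the inverse covariance is tridiagonal (`L'L / nu2`
with `L` the unit lower-bidiagonal innovation operator) and the
log-determinant is `T log nu2`.

For two traits fitted jointly the per-trait SAD(1) processes share an
innovation correlation `rho` at equal times.  The innovation covariance
(per-trait `nu2`, and `rho` in the bivariate case) is profiled out
analytically, so Nelder–Mead searches only the log-scale logistic
parameters and the antedependence coefficients, started from moment
estimates with three perturbed restarts.

The QTL statistic is `LR = 2(l_full - l_null)` against a pooled
single-curve-per-trait null fitted once per dataset (refitted on the
usable subset when a SNP has missing genotypes, so the nested-model
inequality holds exactly).  The genome-wide threshold is the `1 - alpha`
quantile of the per-permutation maximum LR, permuting whole phenotype
vectors against genotypes; individuals are canonically ordered first so
the threshold does not depend on input row order.  Missing phenotypes
exclude an individual from the affected fit (complete-case per trait
set); missing genotypes exclude it from that SNP only.

Each individual then inherits, per trait, the fitted curve of the
genotype class it carries — its time-varying genotypic values.

## Functional clustering

Genotypic-value curves are clustered by a finite mixture whose component
means are logistic curves (per trait; two-trait clustering concatenates
the curves and shares one SAD(1)+`rho` covariance).  The E-step computes
posteriors in closed form; the M-step updates priors exactly and the
mean/covariance parameters by Nelder–Mead on the expected complete-data
log-likelihood with the innovation covariance profiled, started at the
current parameters — a generalized EM step, so the observed-data
log-likelihood never decreases.  Initialization is seeded k-means on raw
curve vectors (or random hard labels); emptied clusters are reseeded from
the curve farthest from all others.  Model size minimizes BIC
(`-2 l + p log n_curves`; AIC available), ties to the smaller K.  Modules
larger than `unit_size` are re-clustered recursively; a unit is accepted
when model selection prefers one cluster or a split fails to shrink it,
which guarantees termination.

## Mixed-ODE decomposition and regulator selection

Each node's trajectory is modelled as
`dy/dt = Q_self(y) + sum_j Q_j(y_j)`: a self-driven rate plus one term
per candidate regulator.  Integrating once turns this into a linear
regression of the anchored trajectory `z(t) = y(t) - y(t_1)` on
cumulative integrals:

* self block (unpenalized), default `independent_form="logistic"`: the
  logistic rate `r y - (r/a) y^2` is linear in `(r, r/a)`, giving the two
  columns `[int y, int y^2]`.  The nonparametric alternative
  (`"lop"`) uses a linear-in-time column plus integrals of each Legendre
  polynomial times the focal curve.  The parametric form is the default
  because a fully flexible self term can absorb nearly any smooth
  trajectory and destroys regulator identifiability.
* one penalized block per candidate: integrals of Legendre polynomials
  (order `lop_order_dependent`, default 0, i.e. constant coupling
  coefficients — the minimal correctly-specified order for couplings
  linear in the regulator) times the candidate's curve.

All integrals run on a 20x spline-refined grid in scaled time and are
subsampled back to the observation grid; quadrature error on the coarse
grid is itself smooth and would otherwise be soaked up by spurious
regulator blocks.  When curves come from noisy observations, each series
is first denoised by Legendre least squares with BIC-chosen degree (2 to
min(8, T-3)), which also yields a noise-variance estimate; the raw series
remains the regression response, anchored at the smoothed curve's first
value (anchoring at a noisy observation would inject a constant offset
the intercept-free design cannot absorb).

Regulators are selected by a group LASSO,
`0.5 ||z - Xb||^2 + lambda sum_g sqrt(p_g) ||b_g||_2`, solved by block
coordinate descent with exact per-block updates (SVD plus a scalar
secular-equation root-find; a plain soft threshold for single-column
blocks), finished by damped-Newton steps on the active support when
blocks are strongly correlated, with an accelerated proximal-gradient
fallback; every returned solution satisfies the KKT conditions to
`1e-5` of the gradient scale.  `lambda` runs over a grid of fractions of
the data-dependent `lambda_max` (default `geomspace(1e-2, 1, 10)`),
traversed sparse-to-dense with warm starts and truncated after four
successive non-improving supports.

Each support visited is scored by its unpenalized OLS refit (relaxed
group LASSO; scoring the shrunken fits would bias selection dense):
`BIC = T log((RSS + delta)/T) + df log T` with
`delta = max(1e-5 ||z||^2, 3.5 T sigma2_hat)`.  The floor `delta` encodes
that fit improvements below the curve-reconstruction error scale
(spline/quadrature error on noise-free data, smoothing error otherwise)
carry no evidence and must not buy extra regulators; it is what makes
selection exact on noise-free data and controls false discoveries on
noisy data.  The selected support is then refined by greedy single-block
drops/additions under the same criterion, because a penalized path can
visit supersets (a weak block entering before a strong one) or skip a
regulator entirely.  Final component estimates come from the OLS refit on
the selected support, so the decomposition identity
`overall = independent + sum(dependent)` holds to machine precision at
every grid point.

Edges: regulator block active => directed edge regulator -> focal;
epistatic within a trait layer, pleiotropic between the two trajectories
of the same SNP across layers.  The sign is that of the time integral of
the dependent component (ties, within a small numerical tolerance, to the
larger-magnitude half, positive on an exact tie); the weight is the
time-averaged absolute dependent component.  Module-level (upper-layer)
networks run the same machinery on module mean curves; the two-trait
"entanglement" analysis adds, per focal node, the same SNP's curve in the
other trait layer as one extra penalized block.  The two-node systems
mapping special case keeps both blocks unpenalized.

## Simulator and power evaluation

The generator integrates a ten-node system (five SNPs by two trait
layers) with logistic self-dynamics and couplings linear in the
regulator's value: within layer one, activating edges 1<-3, 2<-3, 4<-1
and repressing edges 3<-1, 5<-1; layer two is purely self-driven and
feeds back through one activating (2<-2*) and one repressing (4<-4*)
pleiotropic coupling.  Observations are the exact trajectories at T
equally spaced times over [0, 28] plus i.i.d. Gaussian noise (variance
`sigma2` per node per time); scenarios combine T in {7, 11, 15} with
`sigma2` in {0.5, 1.0, 1.5}.

Default parameters are the study conditions and were fixed once, by an
identifiability analysis rather than by aesthetics:

* asymptotes 40–75 trait units (centimetre-scale growth), rates
  0.3–0.6 per time unit;
* shape parameters set through inflection times spread across the
  window.  This is essential: near-parallel S-curves make regulators
  mutually indistinguishable — with homogeneous shapes a false regulator
  explains a trajectory as well as the true one even on noise-free data,
  and no selection rule can recover the wiring;
* coupling strengths `kappa a_target / a_source` with `kappa = +0.2`
  (activation) and `-0.09` (repression).  Repression is bounded by the
  target's self-restoring capacity `r a / 4`; the negatively regulated
  nodes therefore start early and carry the largest intrinsic rates, and
  repression is weaker than activation by design, not by preference.

Edge recovery is scored per replicate over all ordered candidate pairs
(in-layer ordered pairs for epistasis; same-SNP cross-layer pairs for
pleiotropy): TPR = recovered true edges / 7, FPR = false edges / 36
non-true candidates, averaged over replicates (edge-level averaging).

What the generator does not emulate: a finite mapping population (the
genotypic values carry observation noise directly rather than
FunMap estimation error), genotyping error, linkage between SNPs,
non-Gaussian residuals, or couplings that vary in time.  Passing power
tests therefore demonstrate the selection machinery under the stated
noise model, not performance on raw field data.

### Observed operating characteristics

At these conditions the pipeline recovers the wiring exactly on
noise-free data (TPR 1.0, FPR 0.0 at T = 15).  Under noise the recovery
rates increase with T and decrease with `sigma2`, and the false-positive
rate at T in {11, 15} is far smaller than the proportion of candidates;
at `sigma2 = 0.5`, T = 15 the mean TPR is about 0.87–0.91.  Repression
edges and pleiotropic couplings are the hardest to recover, because their
strengths are stability-bounded.  The test suite runs the nine scenarios
at 20 replicates each and the acceptance script runs the headline
scenario at 100 replicates; the clustering and mapping checks use 100
seeded runs at (n = 30 curves, T = 11) and (n = 40 individuals, 20 SNPs,
T = 11) respectively.

## Numerical choices

* Times are stored in original units; all basis computations rescale to
  [-1, 1] internally (endpoints map exactly).
* Antiderivatives and design columns use cumulative trapezoid quadrature
  in scaled time, anchored to zero at the first observation; design
  columns are computed on the spline-refined grid as described above.
* Degenerate inputs: constant time grids, non-positive variances,
  penalties or orders are rejected with explicit errors; monomorphic
  SNPs are dropped at load with a warning; genotype classes smaller than
  three individuals skip the SNP (or merge, configurably).
* Posterior/assignment ties break to the lowest cluster index; BIC ties
  break to the smaller model (clustering) or the sparser penalty
  (regulator selection).
* The group-LASSO `lambda_grid` is interpreted as fractions of
  `lambda_max` so one grid serves all response scales.

## Known limitations

* Identifiability of sigmoid trajectory systems is intrinsically weak;
  the decomposition attributes variation within the span of the chosen
  basis, and regulators whose curves occupy similar shape niches can be
  confused under noise.  Reported edge signs/weights inherit this
  ambiguity.
* The direction of a pleiotropic coupling between two saturating curves
  is only weakly identified; reversed pleiotropic edges are the dominant
  false-positive class under noise.
* The bivariate covariance (per-trait SAD(1) plus one innovation
  cross-correlation) is a deliberate simplification; richer cross-trait
  dependence is not modelled.
* Phase of intercross markers is not resolved; heterozygotes form one
  class.
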