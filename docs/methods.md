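# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the known limitations of `alaamnet`.

## The autologistic actor-attribute model

The ALAAM is the social-influence counterpart of the exponential random
graph model: the network is treated as fixed and the binary node attribute
$y \in \{0,1\}^n$ is modeled jointly,

$$P(Y=y \mid \theta) = \exp\big(\theta^\top z(y)\big) / \kappa(\theta),
\qquad \kappa(\theta) = \sum_{y' \in \{0,1\}^n} \exp\big(\theta^\top z(y')\big).$$

The statistic vector $z(y)$ can combine attribute density (an intercept on
the prevalence scale), out- and in-degree activity, covariate activity,
direct contagion, and the higher-order contagion terms (reciprocal,
indirect, closed-indirect, transitive); exact formulas are in the README
and in the `alaamnet.model` docstrings. Degree-activity terms absorb the
tendency of well-connected people to hold the attribute, so that the
contagion terms measure attribute *co-occurrence across ties* beyond what
degree and covariates explain. On an undirected layer the in-degree term is
disallowed (it would duplicate out-degree and act as a proxy for household
size), and each undirected edge contributes once to direct contagion.

**A structural fact the implementation leans on.** Every statistic above is
at most quadratic in $y$ with a weight matrix that does not depend on $y$:
the middle node of a two-path or triangle contributes no attribute value.
Writing $z_t(y) = \tfrac12 y^\top U_t y$ with symmetric, zero-diagonal
integer $U_t$:

| term | $U_t$ (from binary adjacency $A$) |
|---|---|
| direct (directed) | $A + A^\top$ |
| direct (undirected) | $A$ (symmetric) |
| reciprocal | $A \circ A^\top$ |
| indirect | $T + T^\top$, $T = A A$ with zeroed diagonal |
| closed-indirect | $C + C^\top$, $C = A \circ (A A)$ |
| transitive | $P + P^\top$, $P = A \circ (A A^\top)$ |

Consequently the change statistic of node $i$ is the sparse product
$(U_t\,y)_i$, full statistics are quadratic forms, and the Gibbs kernel
reduces to weighted neighbor sums (compiled with numba). The change
statistics are verified against full-recompute differences and against
naive triple-loop enumeration in the test suite; on integer-valued
statistics the identity holds exactly.

## Inference

The posterior is doubly intractable ($\kappa(\theta)$ appears in the
likelihood), so `Alaam.fit` uses the exchange algorithm:

1. propose $\theta' \sim \mathcal N(\theta, \Sigma_{\rm prop})$ (diagonal);
2. simulate an auxiliary attribute vector $y'$ from the model at $\theta'$
   by sequential-scan Gibbs over the exact full conditionals
   $P(y_i = 1 \mid y_{-i}) = \operatorname{logit}^{-1}(\theta'^\top \delta_i)$;
3. accept with probability
   $\min\{1,\ \exp((\theta'-\theta)^\top(z(y_{\rm obs}) - z(y')))\,
   \pi(\theta')/\pi(\theta)\}$,

which cancels $\kappa$ exactly when $y'$ is a perfect draw. Key settings,
with defaults and rationale:

* **Priors** — independent $\mathcal N(0, 10^2)$ per parameter: proper (the
  exchange ratio needs a proper prior) and wide enough to be dominated by
  the data on study-scale networks. Configurable per model.
* **Auxiliary draws** — 30 full Gibbs sweeps initialized at the observed
  vector (`aux_sweeps`). On the sparse networks in scope, single-site Gibbs
  mixes quickly; doubling the sweeps did not measurably move posterior
  summaries in the null-calibration study.
* **Initialization** — the maximum pseudolikelihood estimate (logistic
  regression of $y_i$ on the change statistics $\delta_i(y_{\rm obs})$),
  with a ridge-stabilized Newton solver; it also supplies per-parameter
  proposal scales via the inverse pseudo-Fisher information. Falls back to
  zeros when separated.
* **Adaptation** — during burn-in a global proposal factor is adjusted
  every 25 iterations toward ~25% acceptance, then frozen, preserving
  detailed balance for the retained draws.
* **Seeds** — mandatory everywhere; all child seeds derive from one
  generator, so fits, suites, and the pipeline are bit-for-bit reproducible.
* **Diagnostics** — summaries report mean, sd, central 95% interval, % of
  posterior mass above zero, and bulk effective sample size (via arviz).
  Exchange chains are sticky (typical ESS is a few percent of the draw
  count); `draws` should be increased when tail quantiles matter.

For networks with $n \le 20$ the likelihood is also available exactly by
enumerating all $2^n$ states (`exact_loglik`, `exact_state_probs`); this is
a test oracle, not an estimation path. The test suite checks (i) that
long-run Gibbs state frequencies match the enumerated distribution in total
variation (< 0.02 at $10^6$ sweeps; observed ≈ 0.001), and (ii) that
exchange posterior means agree with an exact-likelihood Metropolis sampler
within three Monte-Carlo standard errors on a 10-node fixture.

## Model suite conventions

* Tie-subset models (same-/mixed-gender, kin/nonkin) filter **ties, not
  nodes**: the node universe and covariate adjustment set stay fixed, while
  degree-activity terms are recomputed on the filtered network. The
  same-/mixed-gender filters partition gender-known ties; kin/nonkin
  partition the directed layers.
* The edge-directionality contrast refits the model on the transposed tie
  matrix, restricted to ties among network reporters (non-reporters cannot
  have outgoing ties, which would otherwise bias the contrast). Because the
  direct-contagion statistic itself is transpose-invariant, any difference
  between outgoing and incoming fits is carried by the degree-activity
  adjustments; the comparison reports the mean paired-draw difference, the
  share of paired draws in a consistent direction, and the overlap of the
  two 95% intervals. Undirected layers are refused.
* Higher-order variants add one extra contagion term at a time to the base
  specification; fitting all four jointly on sparse data is underpowered
  and not attempted.
* Covariate encoding: woman indicator; education indicators with "none" as
  reference; village indicators with the first village as reference; wealth
  rank (1 = richest decile) as an integer score. Nodes with a missing
  outcome are dropped complete-case with a logged count; isolates are
  retained (they inform density and covariate terms).

## The synthetic-data generator

`alaamnet.synthetic` emulates the *statistical structure* the analysis
assumes so every stage can be tested without external data: ~9 villages of
households (household size $1 + \mathrm{Poisson}(\lambda)$, truncated;
$\lambda = 3$ by default, $\lambda = 1.6$ in the `table1_like` preset where
it reproduces a mean household-layer degree near 2.2); ~50.2% women; ~49.3%
network reporters; each reporter nominating a Poisson number of alters per
layer (capped at 10) with configurable same-gender, kin, and cross-village
odds; and attitudes drawn from the ALAAM at known parameters by long-run
Gibbs (400 sweeps from a random start). Density intercepts in the presets
put equilibrium prevalence in the ~10% regime, higher among women.

Gendered contagion is generated by splitting the direct-contagion term into
same-gender and mixed-gender tie subsets with separate coefficients
(+1.0 / −1.0 in the `same_gender_contagion` preset) — the minimal
generative structure able to produce opposing-sign contagion by gender
pairing.

What the generator deliberately does **not** reproduce: reciprocity and
transitivity of real nomination networks (nominations are conditionally
independent, so both are near zero rather than ~0.18/0.20), kin flags
correlated with household structure, realistic perception–attitude joint
distributions (perceptions are generated independently), or homophily on
the outcome itself (ties never depend on attitudes, so recovered contagion
is influence by construction). Passing tests therefore demonstrate that the
estimator recovers contagion **when the model is true**; they cannot speak
to confounding by social selection in real data, which is a design problem,
not an estimation problem.

## Study sizes used in the checks

Chosen as the package's standard verification settings: parameter recovery
runs 20 replicates of the `same_gender_contagion` preset (~1,000 people,
~1,400 chatting ties) fitted with the generative-family model (1,500 draws,
500 burn-in); null calibration runs 20 replicates of the `null` preset
(1,200 draws). In the recovery study the 90% credible intervals cover the
generative parameters in ≥ 80% of replicate × parameter cases and the
same-gender term shows > 90% posterior mass above zero in ≥ 18/20
replicates; under the null the mean posterior positivity sits within
50 ± 10. `scripts/acceptance.py` re-runs scaled versions of these studies
(10 and 12 replicates) plus the structural margins of the ~5,000-person
`table1_like` scenario.

## Alter matching

Free-text alters are matched to census entries by the mean of per-field
normalized Levenshtein similarities $1 - d/\max(|a|,|b|)$ over the given,
father's, and paternal-grandfather's names (fields absent on the alter side
are skipped), computed with edlib. Gender is a hard constraint when known
on both sides; the acceptance threshold defaults to 0.80; ties break on
given-name similarity, then smallest person id, making the mapping
deterministic. Matching the census against itself returns the identity.
These defaults are explicit and configurable rather than canonical — real
deployments should calibrate the threshold against a hand-validated sample.

## Known limitations

* Cross-sectional contagion estimates conflate influence with selection and
  shared exposure; the directionality and higher-order checks are
  descriptive, not causal.
* Partial reporting (~50% name generators) biases reciprocity, transitivity
  and centrality downward; values are computed raw and should be compared
  between groups, not interpreted absolutely.
* Exchange chains mix slowly relative to their draw count; report effective
  sample sizes alongside summaries.
* The weakly identified mixed-gender contagion term (few mixed ties × low
  prevalence leaves the accept–accept count near zero) can drift toward
  strongly negative values with wide intervals; pooled interval coverage in
  the recovery study is dominated by this term.
* Exact enumeration is limited to $n \le 20$ nodes ($n \le 16$ for state
  recording).
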