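# Methods

This note documents the models behind `fungalcomp`, the choices made where
the design was genuinely open, and what the synthetic-data generator does
and does not emulate.

## The experimental design being modelled

The pipeline targets a factorial plate assay: *S* fungal species grown on
agar at *P* pH levels in three treatments — a single central plug
(`single`), two plugs of the same strain (`SvS`, self-versus-self), and
two plugs of different strains (`competition`) — with *R* replicate plates
per treatment. At the defaults (S = 5, P = 2, R = 10) that is
(5 single + 5 SvS + 10 pairs) × 2 pH × 10 = 400 plates. Single plates
yield one plug-level record, SvS and competition plates two. Plates lost
to contamination, dislodged plugs or dormancy are flagged as excluded and
propagate as absent observations; nothing is imputed.

## Growth-rate estimation

Colony area is assumed exponential during early growth,
A(t) = A₀·exp(r·t), so ln A is linear in t and *r* is the OLS slope of
ln A on day. The fit is restricted to a day window, by default [0, 4],
chosen to capture the exponential phase before colonies approach plate
edges or each other; the window is a configuration knob and is shared
across plates rather than selected per plate (per-plate windows would
couple the response to the noise realisation). Three in-window points are
required; fewer is an error that names the plate rather than silently
dropping it. Duplicate measurement days are rejected as data errors, not
averaged. The slope is invariant to rescaling all areas by a positive
constant, and points after the window (e.g. a saturating colony) never
influence it — both properties are tested.

Maximum colony area over the full series is carried alongside the rate as
an alternate response: rate proxies exploitation competition (fast
substrate capture), final size proxies interference competition (the
long-run outcome of the physical interaction).

Because the two plugs of an SvS plate are interchangeable, one is chosen
uniformly at random per plate (seeded, reproducible) as the plate's
baseline measurement.

## EoC, distances, IoA

EoC for a competition plug is its response divided by the **mean** of the
same-species, same-pH SvS baselines. A matched-replicate pairing would be
arbitrary after random plug selection; the stratum mean is the only
well-defined denominator. EoC is stored as the raw ratio; the log is taken
at model time, so the ratio and log-ratio views derive from one stored
value.

Growth distance is |difference of stratum-mean SvS responses| per pH — a
one-dimensional trait distance, hence automatically a metric. Patristic
distance uses tree branch lengths exactly as given (no ultrametric
transformation); zero-length branches are allowed, negative ones rejected.

IoA scoring assigns integer points per plug from a contact-zone category.
The default table (intermingling 2/2, deadlock at a distance 1/1, deadlock
with contact 2/2, partial overgrowth 4 vs 1, complete overgrowth 5 vs 0)
is a Wicklow–Hirschfield-style scheme; published variants can be dropped
in as a YAML mapping, and the scoring functions only ever consult the
table.

## The mixed models

Both models predict log EoC with crossed random intercepts for focal
species and plate (a plate hosts two focal species; a species appears on
many plates — the factors are crossed, not nested):

    log(EoC) ~ d_growth + pH + (1 | focal) + (1 | plate)
    log(EoC) ~ d_phylo * pH + (1 | focal) + (1 | plate)

pH enters as a two-level factor with the lower (acidic) level as
reference. The growth-distance model excludes the distance:pH interaction
because that distance is already computed per pH; the patristic distance
is pH-constant, so its model retains the interaction. Random intercepts
only — no random slopes.

Implementation: `statsmodels` MixedLM with the two factors as variance
components over a single trivial group. The optimizer runs L-BFGS-B and
then polishes with BFGS from that solution; without the polish, variance
components sitting near their zero boundary stop at optimizer-dependent
points and log-likelihoods are not reproducible to the tolerance the tests
demand. A component estimated at (numerically) zero sets a `boundary`
flag on the result; results are still returned.

Estimation defaults to REML for reported coefficients. AIC is
−2·logLik + 2k with k counting fixed effects, the two variance components
and the residual variance; BIC uses k·log n. Note that REML
log-likelihoods shift under affine rescaling of a fixed-effect column
(through the log|XᵀV⁻¹X| term) and are only comparable across models with
the same fixed-effect structure; for cross-model likelihood comparisons
the ML option should be used, and the comparison report records which
estimation produced it. The comparison itself leads with ΔAIC — the
defensible summary for non-nested models — and also reports a
likelihood-ratio-style chi-square on the parameter-count difference,
floored at zero (yielding the degenerate "chi-square = 0, p = 1" when the
second model has no likelihood advantage).

Fixed-effect p-values use a t reference with n − p residual degrees of
freedom. This is a pragmatic stand-in for a Satterthwaite denominator; at
the design's n ≈ 360 with p ≤ 4 the difference from the z or Satterthwaite
references is negligible, but p-values near the threshold should not be
over-read at much smaller n.

### Pseudo-R²

Variance partitioning over the fitted components: with var_f the sample
variance (ddof = 1) of the fixed-effect linear predictor and s_u, s_w, s_e
the species, plate and residual variances,

    marginal    = var_f / (var_f + s_u + s_w + s_e)
    conditional = (var_f + s_u + s_w) / (var_f + s_u + s_w + s_e)

so 0 ≤ marginal ≤ conditional ≤ 1 always.

### Predictor-independence check

The check regresses patristic on growth distance with a pH random
intercept and reports that slope and SE. Its p-value, however, comes from
a pair-permutation test (patristic values shuffled across species pairs,
999 permutations, seeded): each pair contributes its single patristic
value at every pH, so observations are duplicated within pair and a naive
t reference is anti-conservative. The permutation preserves the
duplication structure exactly and is calibrated by construction (verified
by simulation in the tests).

### Factorial interaction model

`EoC ~ focal * opponent * pH` by OLS. The full factorial crossing contains
self-pairings that never occur, so the design is necessarily rank
deficient; aliased columns are identified by pivoted QR and reported by
name, estimation proceeds via the pseudoinverse, and degrees of freedom
come from the design rank (39 numerator df for 5 species × 2 pH).

## Networks

All networks are complete directed graphs built per pH; node size is the
sum of outgoing edge widths. Control networks: width(i→j) = mean rate of
i / mean rate of j, so opposing widths multiply to 1. EoC-wins networks
compare the two plugs of each competition plate head to head (cross-plate
pairings would compare plugs that never interacted; a pooled cross-plate
mode exists as an option) and report the percentage of plates won, exact
ties counting half — opposing widths therefore sum to 100 exactly. Ties
have measure zero on real data but arise in noiseless synthetic runs, and
the tie rule keeps those deterministic. IoA networks average each
species' score against each opponent.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the rest of the package is validated under.

* **Phylogeny**: a pure-birth (Yule) tree over the species, built by
  explicit lineage splitting with exponential waiting times from a
  dedicated, seeded generator, so the tree stream is independent of the
  noise stream and the phylogeny can be held fixed across noise
  replicates. Patristic distances are validated against an independent
  path-sum oracle in the tests.
* **Intrinsic rates** μ(species, pH): plausible plate-culture values
  (0.12–0.40 day⁻¹) with most species slower on acidic medium, one
  strongly pH-sensitive species and one insensitive one.
* **Competition effects**: per competition plug,
  log EoC = β₀ + β_d·d_phylo(i, j) + β_pH·1[pH = 7] + u_i + w_plate + ε
  with defaults β₀ = −0.02, β_d = −0.05, β_pH = −0.10, species intercept
  SD 0.10, plate intercept SD 0.05, residual SD 0.10. The realised rate is
  μ·EoC, and the per-plug true EoC is recorded in the ground truth.
* **Measurement**: areas follow A₀·exp(r·t) with lognormal observation
  noise (SD 0.05) at days 0–10 (unit spacing; a measurement schedule is
  rarely published, so this is a package default, not a reproduced value),
  A₀ = 24.6 mm² (a 5.6 mm plug). An optional saturation day flattens the
  trajectory afterwards, existing to exercise window selection.
* **Attrition**: plates are excluded uniformly at random (default 8%)
  with a free-text reason; real exclusions are cause-specific, but no
  per-cause rates are available, and downstream stages only consume the
  flag.

What the generator does **not** emulate: spatially explicit mycelial
interaction (contact timing, overgrowth geometry), non-exponential growth
forms, pH drift of the medium, or correlated attrition (e.g. batches of
contaminated plates). Passing recovery tests therefore demonstrate that
the estimators are correct for the generative model stated above — not
that the model captures every feature of real plate data.

## Validation strategy and problem sizes

The test suite validates each stage against independent oracles (hand
path sums and an independent tree library for distances, closed-form
slopes for growth fits, the generative linear predictor for EoC) and the
statistical layer by simulation: 2·SE coverage of the distance slope
across 200 study-scale replicates, AIC preference for the true predictor
over an independent noise predictor across the same replicates,
chi-square calibration of nested likelihood ratios, family-wise error
calibration of Tukey HSD on 2000 null draws, and exact network
invariants. The acceptance script reruns the pipeline at full study scale
and a 40-replicate recovery study; replicate counts were chosen so the
whole validation remains a coffee-break computation on one CPU.

## Known limitations

* Satterthwaite/Kenward–Roger denominator df are not implemented; see
  above for when that matters.
* The chi-square model comparison is reported for completeness but is not
  meaningful for non-nested models; rely on ΔAIC.
* With only two pH levels, the pH random intercept of the
  predictor-independence model is weakly identified; the code falls back
  to pooled OLS for slope/SE when the mixed fit is singular (the
  permutation p-value is unaffected).
* `read_newick` accepts trees without a root-edge length (standard in
  practice) but requires lengths on all other edges.
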