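# Methods

## Interaction-strength model

The per-capita effect of a consumer on a resource is
`IS = α · xR · mR / mC`.  The literature sometimes prints this relation
without the fraction bar; the ratio form is used here because the
per-capita effect of a search-rate-limited consumer scales with the
resource biomass encountered (`xR · mR`) per unit consumer biomass
(`mC`).  Search rate and resource density follow mass power laws with
dimensionality-specific coefficients:

| law          | dim | intercept   | exponent | SE   |
|--------------|-----|-------------|----------|------|
| search rate  | 2D  | 10^−3.08    | 0.68     | 0.12 |
| search rate  | 3D  | 10^−1.77    | 1.05     | 0.08 |
| density      | 2D  | 10^−2.67    | −0.79    | 0.09 |
| density      | 3D  | 10^−2.48    | −0.86    | 0.06 |

These are the published Pawar–Dell–Savage cross-ecosystem regressions;
they ship as `data/scaling_coefficients.yaml` and are config, not code —
swap the file to use system-specific regressions.  Masses are in grams;
intercepts are on the natural scale of each power law, so the absolute
IS units are arbitrary-but-consistent; every downstream analysis uses
only relative magnitudes (medians, ranks, log-slopes).

**Dimensionality rule.**  The resource's movement space decides the
interaction dimensionality: benthic prey are hunted on the plane even
by pelagic predators (2D), pelagic prey are hunted in the volume even
by benthic predators (3D).

**Mass-independent resources.**  For macroalgae, sponges, necromass and
detritus, `mR = xR = 1`, reducing IS to `α(mC)/mC`.  Whether the
consumer's mass should also collapse to 1 is ambiguous in the source
material ("a value of 1 was assigned to mR and mC" versus the strength
being "solely dependent on consumer biomass"); the default keeps the
consumer's real mass — otherwise every detritus link in the web would
share one constant strength, carrying no information — and a
`unit_consumer_mass` switch exposes the alternative reading.

**Monte-Carlo propagation.**  1000 replicates (default); each replicate
draws the four regression exponents from Normal(point, SE) and applies
them to *all* links, because the uncertainty lives in the globally
estimated regressions, not in individual links.  Intercepts stay at
their point estimates (only exponent uncertainty is reported for the
source regressions).  Empirical densities, being observations rather
than regression predictions, are never perturbed.  The per-link median
(linear-interpolated 50th percentile) summarizes the right-skewed
sample.  One seeded NumPy generator drives the whole pass; with all SEs
zero the samples equal the closed-form point estimates bit-for-bit
(the scalar path deliberately uses `np.power` so both routes share one
libm).

## Distribution fitting

Pooled per-link medians are fitted by ML to exponential, gamma,
log-normal, normal, power-law and uniform families and ranked by
AIC = 2k − 2·loglik.  Gamma uses scipy's ML optimizer with the location
pinned at zero; exponential, log-normal, normal and uniform use their
closed forms; the power law is a continuous Pareto with `xmin` fixed at
the sample minimum and the closed-form ML exponent (no xmin search —
nothing in the method calls for one).  The normal is fitted on the raw
positive values even though its support includes negatives, to keep the
candidate list faithful.  AIC ties (<1e−9) break toward fewer
parameters, then lexicographic name.  Zero-variance inputs flag the
two-parameter continuous fits as degenerate and exclude them from
selection instead of producing ±∞ log-likelihoods.

## Species metrics

Standard literature definitions, each isolated behind one function so a
formula swap is a one-function change:

- **Trophic level**: prey-averaged, solved exactly as the linear system
  `(I − D)·TL = 1`; consumers with no feeding path to a basal species
  raise an error naming the offending set.  Self-links are excluded
  here and in all other metrics.
- **Degree**: prey + predators.
- **Omnivory**: population SD (ddof = 0) of the prey's trophic levels;
  0 for basal and single-prey species.  (SD, not variance, keeps the
  index on the trophic-level scale.)
- **Trophic similarity**: Jaccard overlap of the combined prey∪predator
  sets per ordered pair; the species value is the mean over all
  partners; a pair of isolated species scores 0.
- **Modules**: Louvain modularity maximization on the undirected
  projection, best of 20 seeded restarts (first winner on AIC-style
  ties), module ids renumbered by smallest member for determinism.
- **Intermodule connectivity**: Guimerà–Amaral participation
  coefficient `1 − Σ_m (k_im/k_i)²` on undirected links; 0 for
  linkless species.

## Quantile regressions

`ln(total IS)` (natural log; only relative slopes matter) against each
of trophic level, degree, omnivory and trophic similarity at
τ ∈ {0.25, 0.5, 0.75}, fitted with statsmodels' QuantReg (IRLS,
deterministic).  Species with zero total IS are excluded with a
warning.  Slope inference is a case-resampling pairs bootstrap (1000
resamples by default; the resample count is a package choice — the
source method prescribes "the bootstrap" without a count): percentile
95% CI and two-sided p = 2·min(P(b ≤ 0), P(b ≥ 0)).  Degenerate
resamples with constant x are redrawn, capped at 10× the requested
count.

## Stability and extinctions

**QSS.**  Each replicate builds a community matrix with the web's sign
pattern — `A[i,j] = −u₁·IS_ij`, `A[j,i] = +u₂·IS_ij` for resource i,
consumer j — with u₁, u₂ independent Uniform(0, 1] (the
minimal-assumption reading of "magnitudes randomized below the
estimated strength"; a `magnitude="fixed"` policy pins them at 1).  The
diagonal is identically zero: self-regulation data are absent, so
maximum eigenvalues are generally ≥ 0 and measure the self-regulation
the web would need to be stable.  Eigenvalues come from the dense
non-symmetric LAPACK solver; both the mean and the median of the
maximum real parts are computed, with the median (plus IQR) as the
headline statistic.  In the rare event of a mutual-predation pair, the
later link in sorted order sets the shared entries; such 2-cycles are
not part of the sign-pattern guarantee.

**Extinctions.**  Species are ranked once on the intact web (static
order; results phrased as "the n-th species with higher strength"
imply a fixed ranking — re-ranking after each removal is available but
off by default), ties broken by id, and the top 50 are removed one at a
time under six criteria: total IS, trophic level, degree, omnivory,
trophic similarity, intermodule connectivity.  After each removal the
remnant's QSS (reusing the per-link medians, not redrawn Monte-Carlo
samples) and its number of connected components (undirected projection;
isolated species are singletons) are recorded.  No secondary
extinctions: orphaned consumers stay in the web.  Fragmentation events
are the removals whose step raised the component count (the first step
compares against 1).  QSS seeds derive deterministically from
(master seed, criterion, step), so trajectories are bit-reproducible
and insensitive to which criteria are run together.

## Synthetic data

The generator emulates the statistical shape of a well-resolved coastal
Antarctic web; it targets the shape, not any particular empirical
degree sequence or module structure.  Topology: the classic niche model
(niche value ~U(0,1), range `n·Beta(1, 1/(2C) − 1)`, centre
`U(r/2, n)`), with the smallest-niche species forced basal and
regeneration until the web is connected and every consumer is grounded.
Defaults: S = 110, C = 0.054 (≈ 649/110² links), ~half the basal layer
flagged mass-independent (the macroalgae/detritus analogue), log-normal
masses with log-mean −2 (≈ 0.14 g) at the base rising 2.5 natural-log
units per trophic level (so a TL-3.5 fish sits near 10² g), log-sd 1,
and 25% pelagic species (a benthic-dominated fjord).  Real webs differ
in ways the generator ignores — taxonomic block structure, empirical
density data, body-mass measurement error — so green tests certify the
machinery and its statistical behaviour, not field accuracy for any
particular system.

A hard-coded 6-species fixture (2 basal, 2 herbivores, 1 intermediate
consumer, 1 top predator; round masses 1–1000 g) makes every metric
hand-computable; its hand-derived table lives in the
`fixture_web` docstring and is asserted verbatim in the test suite.

## Problem sizes and determinism

Default analysis sizes are 1000 Monte-Carlo IS samples, 1000 QSS
replicates, 50 removals and 1000 bootstrap resamples.  The acceptance
script runs the full 110-species pipeline at 200 QSS replicates and 200
bootstrap resamples — with ~5400 links-worth of dense 110×110
eigenproblems per extinction criterion, 200 replicates already puts the
Monte-Carlo error of the median eigenvalue well below the step-to-step
changes being read off.  All randomness flows from one master seed
through named `SeedSequence` child streams; identical config + seed
gives byte-identical result tables (the manifest's wall-clock timings
are the only run-to-run difference).

## Known limitations

- IS magnitudes are relative: no temperature correction, no per-link
  calibration against measured fluxes.
- Mutual-predation 2-cycles break the strict sign-pattern guarantee
  (see above); the niche model occasionally produces them.
- The stability metric ignores dynamics beyond the linearization, and
  extinction simulations hold interaction strengths fixed as the web
  shrinks, although real biomasses would redistribute.
- Weighted (flux-based) trophic levels and weighted modularity are out
  of scope.
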