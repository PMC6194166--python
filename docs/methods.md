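# Methods

This note documents the models implemented by `embryoscope`, their
assumptions and tunable parameters, the design choices made where the
behavioural protocol leaves the computational model open, and what the
simulations can and cannot say about real observers.

## Stimulus model

### Procedural embryo populations

Real "digital embryo" stimuli are grown by an iterative simulated-embryogeny
procedure. `generate_base_population` is a deliberately simpler procedural
generator that preserves the only properties downstream analysis relies on:
a fixed vertex count with exact vertex correspondence across the population,
a closed connected surface, and smooth, naturalistic, blob-like shape
variation. Each embryo is a unit Fibonacci sphere — which realises *any*
requested vertex count exactly, unlike icosphere subdivision — triangulated
by its convex hull (shared topology, 2V − 4 faces), then radially perturbed
by a seeded sum of 10 Gaussian bumps with random centres on the sphere,
widths uniform in [0.25, 0.8] rad, and amplitudes ~ N(0, 0.06) of the unit
radius. Amplitudes are small enough that the radial field stays positive
(clipped at 0.2 as a safety net) and the surface remains star-shaped and
smooth. Defaults: 400 embryos × 1474 vertices.

### Shape space

PCA is taken over the flattened `n × 3V` coordinate matrix (the `n × V`
phrasing of per-vertex data is treated as shorthand; running PCA per
coordinate plane is the unimplemented alternative). Conventions: centred on
the mean shape; components ordered by descending eigenvalue with at most
min(n − 1, 3V) retained; unit-norm rows; sign fixed so each component's
largest-magnitude entry is positive, making the basis reproducible across
BLAS implementations. PC indices are 1-based so that "PCs 2 and 3" name the
second- and third-largest eigenvalue directions; those are the default
category axes because the first component is dominated by overall
size/elongation.

### Categories and difficulty

A category is a 2-D Gaussian over the two axis loadings; covariances default
to diagonal but any SPD matrix is accepted. `tune_category_pair` places the
two means symmetrically about the origin along a seeded random direction at
a Mahalanobis distance (under the shared within-category covariance) equal
to the target ideal-observer d′. The package default target is 2.5: high
enough above the 1.68 training criterion that a noisy prototype learner can
actually reach three consecutive criterion blocks, low enough that the task
is far from trivial and unaided naive clients sit at chance.

The F-ratio (between-category variance / within-category variance) is the
trace of the scatter of the two category means about their unweighted grand
mean (divisor K − 1) over the trace of the pooled unbiased within-category
covariance. The mean-scatter is *not* multiplied by the per-category n, so
the statistic estimates a population separation (→ 0 for identical
categories as n grows) rather than the classical ANOVA mean-square ratio
(→ 1 under the null); this matches the moment-level definition stored with
each tuned pair. Degenerate zero-within/nonzero-between input raises an
explicit infinite-separation error instead of dividing by zero.

### Rendering

Trial screens are 8-bit grayscale flat-shaded orthographic projections with
a single directional light and painter's-algorithm face ordering —
shading/shadow cues are what the explanation texts reference, so shading
matters and photorealism does not. Geometry is configured in degrees of
visual angle with a px-per-degree constant (default 40 px/deg; embryos 6°;
anchors at 0° and ±6.2°). Positional jitter is uniform over the disk of
radius `jitter_max_deg` (default 0.8°), drawn independently per embryo; the
placement manifest records every offset, and offsets can never exceed the
bound by construction. BMP output is available beside PNG; OBJ export
preserves vertex order because correspondence is meaningful.

## Observer models

No computational model of the human subjects exists; all agents are
explicit stand-ins whose parameters were chosen once so the simulated
protocol reproduces the qualitative pattern of findings, not fitted to any
unavailable raw data.

* **Ideal observer** — adds isotropic Gaussian noise (sd in loading units)
  to the query, then picks the higher-likelihood category. Its noiseless
  Monte-Carlo d′ equals the Mahalanobis separation; used for difficulty
  calibration.
* **Exemplar observer** — adds independent noise to the query and both
  on-screen samples and picks the nearer sample; mirrors the actual trial
  format. It is strictly worse than the ideal observer in expectation.
* **Prototype learner** — category-centre beliefs start at the origin
  (decisions at chance via tie-breaking and noise) and move toward each
  feedback example by `learning_rate` (default 0.08; perceptual noise sd
  0.3 loading units, against a within-category sd of 1 per axis). Constant-
  rate delta updates converge to a stationary distribution around the true
  means with per-axis sd ≈ σ√(rate/(2 − rate)); the learner therefore
  *hovers near* rather than converges to the category means, which is the
  intended stand-in for an imperfect human expert (asymptotic accuracy
  ≈ 0.88 at the default difficulty). All ties anywhere are broken uniformly
  at random from the operation's own seeded stream.

### Explanations

Explanation content is reduced to two observables: a locality class
(local/global, drawn Bernoulli(`locality_mix`, default 0.5)) and a latent
scalar *cue validity* — the probability that following the explanation
alone yields the correct category — fixed per class at 0.85 (local) and
0.55 (global). The asymmetry encodes the finding that spatially localized
explanations transfer much better than global ones. Surface text is
rendered from a plain-text template bank (editable without code changes)
and carries no additional information. SER_S, the server's self-rating, is
a truncated Gaussian on [0, 100] (mean 85, sd 12) whose mean is independent
of cue validity: servers rate their explanations well regardless of their
actual efficacy, so SER_S is uncorrelated with usefulness by construction.

### Clients

`client_decide` implements a hierarchical fall-through: copy a provided
decision with probability `compliance_weight` (default 0.6), else follow a
provided explanation cue with probability `explanation_weight` (default
0.8), else decide unaided (exemplar comparison with `own_noise_sd`, default
25 — large enough that an untrained client is at chance; expert clients
instead carry their trained prototype state). Both server channels are used
only when the source is believed expert; perceived-naive server data are
ignored outright. Whether humans combine decision and explanation
hierarchically or multiplicatively is unresolved; the fall-through policy
is one defensible reading, and it reproduces the observed ordering
(decisions ≥ explanations > chance, no further gain from adding
explanations to decisions being approximated rather than exact here).

`client_rate` produces OUR (base 70 — the text is understandable whether or
not it is useful) and OER (base 40 for naive clients, independent of cue
validity; for expert clients a linear function of validity, 10 + 160(v −
0.5), housing the training-dependent OER improvement), each plus
`conformity_bias` (default 15 points) when the source is labelled expert,
plus N(0, 10) noise, clipped to [0, 100]. Means are reported on the clipped
scale. With these mid-scale bases the injected bias is recoverable from the
expert-minus-naive rating difference to ±1 at n = 5000, and naive OUR and
OER are uncorrelated by construction.

## Protocol engine

Blocks are 40 trials; query category and P-sample side are fair coin flips
per trial; feedback exists only during training. The training criterion is
three consecutive blocks at d′ ≥ 1.68 (boundary inclusive), detected as the
first qualifying run; training stops at the block completing the run
(stop-at-criterion is the reproducible choice; a `continue_blocks` option
trains past it). Non-convergence within `max_blocks` is an explicit flag on
the log, not an exception. Per-trial RNG streams derive from (master seed,
CRC32 of subject id, trial id), so any subject's log is bit-reproducible
regardless of roster order.

Scrambling: 4A permutes the server's decisions uniformly across trials,
leaving explanations and stimuli untouched; 4B additionally swaps the two
sample-stimulus labels on an independent fair coin flip per trial, which
inverts the explanation cue on flipped trials and drives its effective
validity to 1/2. (An alternative reading — shuffling the query labels
across trials — is available as `variant="query_labels"`; it likewise
flips about half the trials.) Both preserve the decision and explanation
multisets exactly and are deterministic per seed. Practice/warm-up trials
are represented only as an option to discard a leading block; self-pacing,
viewing time and response times have no simulator counterpart.

## Statistics

d′ = z(H) − z(F) via the inverse normal CDF, hits/false alarms designated
on category P (the designation is arbitrary; swapping it leaves
equal-variance d′ unchanged, exactly). The behavioural protocol never
states an extreme-rate correction; the package default for block-level d′
is the log-linear +0.5-per-cell correction because simulated experts
produce perfect 40-trial blocks that must stay finite, and `none` (which
raises on extreme rates rather than silently returning ±∞) is available.
Block chance thresholds come exact from the Binomial(n, ½) tail (k = 26 at
n = 40, α = 0.05) or from the Gaussian approximation (the dashed-line
convention in learning-curve figures). Cross-subject learning summaries
report mean/median/SEM/range of blocks-to-criterion, SEM with unbiased sd
and a documented SEM = 0 convention at n = 1; non-converged subjects are
listed separately and excluded from moments. Condition reports use seeded
percentile-bootstrap CIs (2000 resamples by default). Omnibus
ANCOVA/Tukey-HSD machinery is out of scope; the report's group means and
CIs support the same contrasts, and thin paired-t / one-way ANOVA /
Pearson wrappers cover the remaining tests.

## Problem sizes and determinism

The demo pipeline and the test suite run on reduced problem sizes chosen as
the package's own defaults for quick, fully seeded reproduction: shape
spaces from 25–60 embryos of 40–150 vertices (the PCA, category and
rendering machinery is resolution-independent), 1000 server trials per
client condition (enough power that the 4A above-chance-but-degraded
contrast is significant at the 0.05 level), 500–2000 bootstrap resamples.
The full-scale 400 × 1474 population takes a few seconds and is exercised
by the population-contract test. `scripts/acceptance.py` renders 1000
screens at 150-vertex resolution through the real rasteriser.

## Limitations

* All agent parameters are stand-ins; passing tests show the *protocol and
  analysis machinery* behave correctly and that the chosen parameterisation
  reproduces the qualitative phenomena — they are not evidence about human
  mechanism, effect sizes, or learning durations (the simulated learner
  reaches criterion in far fewer blocks than human subjects).
* Explanation semantics are compressed to (locality, cue validity);
  nothing is modelled about language, and OUR/OER bases are constants, not
  functions of text.
* The generator's shape statistics are not those of grown embryos; only
  correspondence, smoothness and PCA-compressibility are emulated.
* Rendering is untextured orthographic grayscale; no perspective, colour,
  or animation.
* The fine structure of a session (self-pacing, fatigue, multi-day
  spacing) is outside the model; timestamps are optional metadata only.
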