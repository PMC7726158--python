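# Methods

`norfevo` implements the comparative-genomics stages used to ask whether
novel open reading frame (nORF) regions of a genome evolve non-neutrally,
and how long ago a pair of species diverged at those regions. This note
documents the models, the numerical choices, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Substitution models

Nucleotide substitution is modelled as a stationary, time-reversible
continuous-time Markov chain over (A, C, G, T). Two parameterisations are
provided:

- **REV/GTR** — six symmetric exchangeabilities `r_ij` and stationary
  frequencies `pi`, with `Q_ij = r_ij pi_j` off-diagonal. Used as the
  neutral model for conservation/acceleration scoring.
- **HKY85** — one transition/transversion ratio `kappa` and arbitrary
  `pi`. Used for divergence-time estimation, with empirical base
  frequencies and no site-rate heterogeneity.

`Q` is normalised so that one unit of branch length equals one expected
substitution per site (`-sum_i pi_i Q_ii = 1`), the PHAST convention, so
fitted branch lengths read directly as substitutions/site. Transition
probabilities `P(t) = exp(Qt)` are computed by eigendecomposition of the
symmetrised matrix `diag(sqrt(pi)) Q diag(1/sqrt(pi))`; reversibility
guarantees a real spectrum, which is both exact and numerically stable.
The implementation is verified against the Jukes–Cantor and HKY analytic
closed forms and the Chapman–Kolmogorov identity to 1e-8 or better.

## Phylogenetic likelihood

Column likelihoods are computed by Felsenstein pruning on a rooted tree
stored as flat arrays, vectorised across unique site patterns. Gaps and
`N` are treated as missing data and marginalised (partial vector of
ones) — they are "insufficient data", never a fifth state. Per-node
renormalisation with accumulated log factors prevents underflow on long
trees. A rate-scale argument multiplies every branch length, with
`scale = 0` handled as the exact no-substitution limit so optimisers can
reach the boundary for perfectly conserved sites.

## Neutral model from four-fold-degenerate sites

The neutral null is fitted to third codon positions of the eight
four-fold codon families (CTN, GTN, TCN, CCN, ACN, GCN, CGN, GGN),
derived programmatically from the standard genetic code. Degeneracy is
judged from the **reference species codon only** (the convention of the
standard alignment-extraction tools); other species need not share the
first two positions. Minus-strand CDS are read as reverse complements for
degeneracy, but the emitted column keeps the forward-strand states as
stored in the alignment — under a reversible fit with empirical
frequencies this is equivalent and avoids mixed-strand bookkeeping.
Codons whose three reference positions are not consecutive, non-gap and
inside a single alignment block are dropped; stitching codons across
block boundaries would add cross-block gap reconciliation for a
negligible gain in sites at genome scale.

Fitting maximises the pruning likelihood jointly over branch lengths and
five free exchangeabilities (GT fixed at 1) with L-BFGS-B on
log-transformed parameters, three starts, relative tolerance 1e-6, branch
lengths floored at 1e-8. Base frequencies are set empirically from the 4D
column counts, reducing the optimisation dimension. Because root
placement is unidentifiable under a reversible model (only the sum of the
two root-adjacent branch lengths matters), the topology's root is
collapsed to a trifurcation before fitting; recovery claims are therefore
statements about the unrooted parameterisation. On 10,000 simulated
neutral columns all seven branch lengths of the five-taxon test tree are
recovered within 10% relative error.

## Conservation–acceleration (CONACC) scoring

For every reference-anchored alignment column, a single rate multiplier
`rho` scaling **all** branches of the neutral tree is fitted by bounded
1-D optimisation (Brent, `rho` in [0, 20], tolerance 1e-6), and compared
with the neutral model (`rho = 1`) by a likelihood-ratio test:
`LRT = 2 (logL(rho_hat) - logL(1))`, `p` from the upper tail of
chi-square with 1 df. The signed score is `-log10(p)` when `rho_hat < 1`
(conservation, positive) and `+log10(p)` when `rho_hat > 1`
(acceleration, negative), capped at |20| so WIG output stays finite when
`p` underflows.

Choices that matter:

- The chi-square(1) reference is used **without** the 50:50
  boundary-mixture correction, matching the behaviour of the widely used
  LRT scoring tool rather than the statistically purer mixture. Together
  with the discreteness of a single 5-taxon column, this makes per-site
  p-values conservative: in a 10,000-column null simulation the fraction
  of sites with p < 0.05 is about 0.03–0.04, and the calibration test
  asserts a band of [0.005, 0.05 + 3 binomial SE] rather than a
  symmetric band around 0.05.
- Sites need at least 2 non-missing taxa to be scored (`min_present`,
  configurable); columns where the reference has a gap are never scored
  and are simply absent from the track — no placeholder values.
- Identical site patterns share one optimisation (pattern caching),
  which is what makes genome-scale scoring tractable: a 5-taxon
  alignment has at most 5^5 distinct patterns.

## Feature mapping and the length-matched resampling test

Scores are mapped onto feature classes (CDS, 5'UTR, 3'UTR, intron,
intergenic, ancestral repeats, novel regions) by half-open interval
overlap; a site may belong to several classes. A region's score is the
**mean of its per-site scores**; intervals with no scored site are
reported as unmapped and excluded. Class distributions are compared by
ECDF and Welch's unequal-variance t-test (Welch–Satterthwaite df).
The Welch tests compare pooled per-site scores rather than per-region
means: with only 9 novel regions a test on region means would be far too
weak to produce the reported majority-significant resampling outcomes,
and the distributions being compared are distributions of site scores.

Because novel regions are few relative to ancestral repeats, significance
is assessed by resampling: each iteration draws one length-matched AR per
target (uniformly among ARs within `max(20 bp, 10%)` of the target
length, nearest-length fallback with a logged warning), pools the drawn
ARs' site scores, and Welch-tests them against the pooled target scores;
the result is the count of significant iterations out of `n_iter`
(10,000 at alpha = 0.05 at full scale, no multiple-testing correction —
the raw count is the summary). Iteration `i` uses the seeded substream
`(seed, i)`, so results are bit-reproducible and independent of
iteration order.

Two statistical properties of this procedure are worth knowing:

- Repeating iterations against one **fixed** target set estimates the
  rejection rate *conditional on that target set*, which varies widely
  between target sets (sd ~ 0.07 in our simulations). Only the marginal
  rate over target redraws is near alpha; the calibration test therefore
  uses many independent replicate genomes with one iteration each.
- Sampling ARs with replacement across targets means one AR can enter
  the pooled sample twice; with very small AR pools this correlates the
  sample and inflates the type-I rate. With study-like pools (tens to
  hundreds of ARs per length class) the effect is negligible and the
  marginal rate matches alpha.

## Strict-clock divergence-time estimation

Node ages of a fixed topology are sampled by Metropolis–Hastings:

- **Likelihood** — pruning likelihood with branch lengths
  `clock_rate x (parent age - child age) x rate_multiplier`. The clock
  rate (substitutions/site/MY) is a required constant with no default,
  forcing callers to state units; `rate_multiplier` (default 1) lets a
  locus deviate from the neutral rate. A zero-column alignment has
  constant likelihood — the prior-only mode.
- **Tree prior** — Yule (pure birth):
  `log p = (n-1) log(lambda) - lambda x sum(internal node ages)`, with
  the birth rate `lambda` Gibbs-sampled under a broad exponential
  hyperprior (mean 10 /MY) by default, or fixable by config. The exact
  Yule normalisation is irrelevant to MCMC over ages.
- **Calibration** — a lognormal density on the age of one designated
  MRCA, parameterised by its real-space mean and sd:
  `sigma^2 = ln(1 + (sd/mean)^2)`, `mu = ln(mean) - sigma^2/2`, so the
  real-space mean of the prior equals the stated mean exactly. The
  calibrated taxon set must be monophyletic in the topology.
- **Proposals** — uniform slide of a single internal node age within
  (oldest child, parent); log-scale moves for the root age and for all
  internal ages jointly (Hastings-corrected); step sizes auto-tuned
  toward ~30% acceptance during burn-in only, so the post-burn-in chain
  is a valid fixed-kernel sampler. Burn-in defaults to 10%; thinning
  retains ~10,000 samples.

Topology search is deliberately absent: the use case is comparing node
ages across loci on a known 5-taxon tree. In prior-only mode the
calibrated node's posterior reproduces the lognormal's real-space
moments (45.5 / 0.5 MY recovered to within Monte-Carlo error); with
simulated strict-clock data, the 95% credible interval for a 30 MY focal
split covers the truth in >= 18/20 replicates with posterior means a few
percent from the truth.

## Synthetic-data generator

The simulator evolves an ancestral sequence (drawn from the model's
stationary frequencies) down the tree by sampling child states from
`P(branch x rho)` site by site — exact marginally, with no within-branch
event history. The default scenario emulates a five-way cichlid-like
alignment: 5 taxa on the topology (((PN,MZ),AB),NB),ON; codon-structured
CDS at rho = 0.3 whose four-fold third positions evolve at rho = 1 (so 4D
extraction finds genuinely neutral sites, with stop codons excluded from
the ancestor by per-codon rejection); UTRs at 0.7; introns at 0.9;
intergenic background and >= 220 ancestral-repeat-like regions at 1.0
with a right-skewed length distribution; 9 novel-intergenic regions at
rho = 2 and 27 novel-intronic regions at rho = 0.5, echoing the mapped
novel-region counts of the motivating study design. The genome (~200 kb)
is emitted as MAF blocks of <= 10 kb to exercise block-boundary handling.

The scenario tree totals ~1 substitution/site. Real cichlid genomes are
far less diverged; at desk scale a near-zero-length tree would leave
per-site tests with no signal, so the scenario trades realism of scale
for informative per-site statistics. Consequences of the design that
passing tests do **not** establish for real data: there are no alignment
gaps or missing species (gaps enter only via masking, never an indel
process), no alignment error, no assembly/liftover attrition, no
selection heterogeneity within a region, and the neutral model fitted to
4D sites is exactly the generating model family. Region counts and rate
multipliers are study conditions, not tuning knobs.

## Numerical and degenerate-input conventions

- Base order fixed as (A, C, G, T) everywhere.
- BED semantics (0-based half-open) throughout the API; WIG is 1-based
  at the file boundary only; minus-strand MAF reference rows are mapped
  to forward-strand coordinates for anchoring.
- Overlapping intervals are merged before complementation ("not
  annotated" means not covered by the union).
- MAF block sorting is lexicographic by reference chrom, then numeric
  start, stable for ties; any total order works downstream because
  score mapping is coordinate-keyed.
- Welch's test refuses two zero-variance samples; the ECDF of an empty
  sample is an error, not an empty list.
- All randomness flows from explicit integer seeds; per-iteration and
  per-stage substreams are derived by counter so no result depends on
  execution order.

## Problem sizes used by the shipped checks

Desk-scale sizes, chosen so the whole suite runs on one CPU in minutes:
neutral-fit recovery at 10,000 columns; null calibration of site scoring
at 10,000 columns; resampling calibration over 300 independent replicate
genomes (one iteration each) and power at 1,000 iterations; clock-dating
recovery over 20 replicates of 1,500 bp loci at chain length 1e5;
prior-only calibration recovery at chain length 2.5e5 (~10,000 retained
samples). The library defaults remain the full-scale settings (10,000
resampling iterations, 1e6 MCMC steps).

## Known limitations

- No rate heterogeneity across sites (by design), no codon models, no
  non-reversible models.
- No indel process; scoring treats gaps as missing data only.
- The per-site LRT p-values are conservative near the `rho = 0`
  boundary (chi-square(1) convention); region-level conclusions rest on
  comparisons between classes, which are unaffected.
- The strict clock is an assumption, not an inference; violations bias
  node ages in ways the sampler cannot detect.
- bigWig/bigBed, assembly liftover and PHAST `.mod` parsing are out of
  scope; models are serialised as a small key-value text format.
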