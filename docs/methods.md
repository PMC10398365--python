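# Methods

## Scope and model

`cessalex` implements a word-count ("dictionary") approach to emotion
profiling of forum text.  The unit of analysis is a forum (corpus of
posts), not a user or a post: category match counts are pooled over a
forum's posts and normalised once by the pooled total, so each forum is
summarised by a K-vector of occurrence-frequency percentages.  The
approach deliberately ignores context — no stemming, negation handling,
valence weighting or embeddings — trading sensitivity for transparency
and auditability.  Every downstream statistic (outlier flags, cosine
similarities, abstinence contrasts) is a function of these percentage
vectors or of the underlying counts.

## Preprocessing

Markup tags (`<...>`) are removed first, then every Unicode punctuation
or symbol character is replaced by a space, letters are lowercased, and
tokens are maximal runs of non-whitespace.  Replacing punctuation with a
space (rather than deleting it) splits contractions ("don't" → `don`,
`t`), which keeps tokenisation monotone: no new token can be created by
joining fragments.  Numerals are retained by default; `strip_numerals`
and `min_token_len` flags exist because the effect of either choice on a
word-bank analysis is nil (banks contain no numerals) but users may want
cleaner token streams.  Lexicon entries are passed through the same
function at load time, so matching can never disagree with tokenisation
about case or punctuation; multi-word entries are rejected because
n-gram matching would silently change the normalisation denominator.

## Word banks

The shipped emotion bank has 21 categories: Plutchik's eight primary
emotions, the eight secondary dyads, the intensity variant terror, and
the social/self-conscious emotions anxiety, pride, gratitude and
serenity.  The 15-category time bank (morning, evening, week, year, ...)
serves as a non-emotional control vocabulary of comparable structure.
Word lists are this package's own compact curation — surface forms only,
pairwise disjoint within a bank so percentages sum to exactly 100.
Category overlap in user-supplied banks is permitted (each shared word
increments every containing category) but triggers a warning, since it
breaks the sum-to-100 reading.  All analyses accept any user lexicon in
`category,word` CSV or JSON form; no result in this package depends on
the specific curation beyond the category names.

## Corpus filters

"Body text" means at least one token after preprocessing, so
whitespace- or punctuation-only bodies count as image-only posts.  The
inclusion rule (≥ 3000 text posts of a 5025-post window) is defined on
the extraction window, and the code refuses to evaluate it on a corpus
with a different window size rather than silently rescaling.  Truncation
to the most recent 3003 text posts breaks timestamp ties by input-file
order, which makes reruns byte-identical.  The median split retains
forums whose emotion score is strictly greater than the sample median:
with n distinct scores this keeps ⌊n/2⌋, the only reading consistent
with keeping exactly half of an even-sized sample.  The emotion score is
the raw pooled match count by default; a per-token rate is available
(`emotion_score(..., per_token=True)`) for corpora with very different
post lengths.

## Outliers and similarity

Percentile thresholds use linear interpolation between order statistics
(`numpy.percentile` default); the method is a parameter because no
single convention is canonical, and with ~50 control forums the choice
moves the threshold by less than the spacing of adjacent order
statistics.  The outlier flag is strict (`frequency > threshold`).
Fewer than 20 control profiles triggers a warning — the 95th percentile
of a handful of values is mostly noise.  Cosine similarity is computed
on the percentage vectors; since cosine is scale-invariant this equals
the raw-count result, and values lie in [0, 1] because profiles are
nonnegative.  Top-k neighbour ties are broken lexicographically for
reproducibility across snapshots.

## Abstinence analysis

Durations are binned into 15 bins over [0, 1000] days: a day-0 bin
[0, 1) ("within the first 24 hours"), 8 logarithmic bins on [1, 100),
and 6 logarithmic bins on [100, 1000], the last closed at 1000.  The
edge set is a package choice (posting-volume histograms of duration data
are conventionally log-scaled, and log-uniform tails put comparable mass
in each log-spaced bin); it is fully configurable and echoed in every
report.  Posts beyond 1000 days are excluded.

The two-way ANOVA treats the per-bin percentage of each emotion as the
response, with factors emotion (K levels) and abstinence level (short =
9 bins below 100 days, long = 6 bins above) and bins as replicates
within level: df = K−1, 1, K−1 with K·15 − 2K residual df (20/1/20/273
for K = 21).  Sums of squares are sequential with emotion entered first;
because every bin's percentages sum to 100, both level means equal 100/K
and the abstinence main effect is exactly zero for *any* per-bin
normalised table — an identity the test suite asserts to 1e-8, and the
reason only the interaction and the per-emotion contrasts carry
information.  A table with no variation at all short-circuits to all-zero
F statistics rather than evaluating the indeterminate 0/0 ratio.

Post-hoc contrasts are two-sided independent-samples t tests on the 9
short vs 6 long bin percentages per emotion, pooled variance by default
(df = 13), Welch available via `method="welch"`; both are exposed
because the two reasonable df conventions (13 pooled, data-dependent
Welch) genuinely differ at this sample size.  Bonferroni adjustment
divides α by the number of emotions tested.  Degenerate zero-variance
groups with equal means return t = 0, p = 1.

## Synthetic corpus generator

The generator emulates the features the pipeline is sensitive to:

* **Composition** — each forum has a true simplex composition over the
  lexicon's categories; emotion tokens are multinomial draws from it at
  a per-token `emotion_rate`, all other tokens come from a filler
  vocabulary with a reserved `zz` prefix that can never collide with a
  word bank.  Recounting generated text through the pipeline reproduces
  the truth record exactly, which the tests use as an end-to-end
  integrity check.
* **Post structure** — lengths are negative binomial (default mean 30
  tokens, shape 5, matching short, highly dispersed forum posts); a
  fraction of posts (default 10%) are image-only; a fraction of tokens
  carry punctuation suffixes and a fraction of posts HTML wrappers, all
  constructed so preprocessing removes them without touching token
  boundaries.
* **Abstinence** — tagged forums place a point mass (default 7%) of
  posts in the first 24 hours and draw the remainder log-uniformly on
  [1, 10,000] days, mirroring a heavy right tail over roughly four
  decades; beyond day 100 the composition can shift (default: anxiety
  −0.10 of composition, renormalised), which is the effect the
  short-vs-long contrast is powered to detect.
* **Study preset** — `generate_study` draws control compositions from a
  symmetric Dirichlet (α = 3, giving marginal category shares of
  4.8% ± 2.7%) and control emotion rates from U(0.02, 0.14) so a median
  split separates emotion-rich from emotion-poor forums; target forums
  elevate designated categories to 0.18, far above the Dirichlet
  marginal's 95th percentile, and carry abstinence metadata.

What the generator does **not** emulate: natural language (word order,
syntax, topic structure), author-level longitudinal behaviour, bursty
posting dynamics, category co-occurrence induced by shared context, and
vocabulary outside the banks plus filler.  Passing tests therefore
demonstrate that the pipeline's statistics behave correctly under its
own model assumptions — unbiased composition recovery, calibrated null
rejection rates, correctly forced identities — not that the word banks
capture real emotional expression.

## Statistical calibration choices

Parameter-recovery tests compare recovered percentages to the generating
composition in units of the binomial standard error
100·√(p(1−p)/N).  A per-cell 3-SE band has a ~0.27% two-sided
exceedance probability, so when a test sweeps many forum × category
cells at once the band is carried to the family level by a Šidák
adjustment (per-cell threshold ≈ 4.7 SE for ~1100 cells); otherwise a
correct generator would fail the sweep almost surely.  For forums whose
composition shifts after day 100, the recoverable truth is the marginal
mixture over posting times (`effective_probs`), weighting the shifted
composition by the probability that a post falls beyond 100 days.
Null-calibration tests check the Bonferroni-corrected post-hoc
rejection rate against its nominal value within two Monte-Carlo
standard errors over 2000 replicates.

Test-suite and acceptance-script problem sizes (e.g. 108 forums × 3003
posts at a mean length of 15 tokens; 200 power replicates of a
1400-post tagged forum) are chosen so every check completes in seconds
to a few minutes on one CPU while keeping per-forum match totals in the
thousands, where the normal approximation to the binomial is accurate.

## Known limitations

* Word-count scoring cannot see negation ("not proud" counts as pride),
  sarcasm, or context; the shipped banks are small curations, not
  validated psychometric instruments.
* The median split and percentile thresholds are rank-based and stable,
  but with few control forums the 95th percentile is dominated by the
  top one or two order statistics.
* The abstinence analysis treats bins as independent replicates; serial
  correlation across adjacent duration bins (the same users posting
  repeatedly) would inflate the nominal t-test precision on real data.
* Self-reported abstinence durations are unverified; the generator makes
  no attempt to model misreporting.
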