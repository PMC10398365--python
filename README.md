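# cessalex

Lexicon-based emotion profiling of text posts from web support forums,
built for studying the subjective experience of substance cessation.
People trying to quit alcohol, nicotine or cannabis post in dedicated
forums, often tagging posts with the number of days since their last
use.  `cessalex` quantifies the emotional composition of such forums,
compares them against a large control sample of general-interest forums,
and tracks how emotion expression changes with abstinence duration.

The package is aimed at computational researchers in digital phenotyping
and health social-media text mining.  Because forum dumps cannot be
redistributed, it ships a synthetic-corpus generator that reproduces the
statistical structure the analysis assumes (multinomial emotion-word
composition, image-only posts, markup noise, heavy-tailed abstinence
durations) with known ground truth, so the whole pipeline is testable
end to end.

## The method

1. **Preprocessing** — post text is lowercased; HTML tags, punctuation
   and extra whitespace are stripped; tokens are surface forms.
2. **Word banks** — a 21-category emotion lexicon (built around
   Plutchik's primary/secondary emotions plus anxiety, pride, gratitude,
   serenity) and a 15-category time lexicon used as a non-emotional
   control vocabulary.  Users can substitute their own CSV/JSON banks.
3. **Corpus filters** — a forum enters the sample when at least 3000 of
   its 5025-post extraction window carry body text; retained forums are
   truncated to their 3003 most recent text posts.  Forums whose total
   emotion-word match count (*emotion score*) does not exceed the sample
   median are excluded as emotion-poor; with distinct scores this keeps
   exactly half (54 of 108; 47 of 95 in a replication snapshot).
4. **Profiles** — for forum *s* with pooled category counts
   *n<sub>s,c</sub>* and total *N<sub>s</sub> = Σ<sub>c</sub>
   n<sub>s,c</sub>*, the occurrence frequency is
   *f<sub>s,c</sub> = 100 · n<sub>s,c</sub> / N<sub>s</sub>*, a
   K-vector of percentages summing to 100.
5. **Outliers** — forum *s* is an outlier on category *c* when
   *f<sub>s,c</sub>* exceeds the 95th percentile (linear interpolation)
   of the control forums' frequencies on *c*.
6. **Similarity** — cos(θ) = **f**<sub>s</sub>·**f**<sub>t</sub> /
   (‖**f**<sub>s</sub>‖ ‖**f**<sub>t</sub>‖) between profile vectors;
   top-5 neighbour lists per forum, ties broken lexicographically.
7. **Abstinence dynamics** — tagged posts are binned into 15 duration
   bins up to 1000 days (a day-0 bin, then logarithmic edges with 9 bins
   below 100 days and 6 above).  A two-way fixed-effects ANOVA (emotion
   × short/long level, bins as replicates) tests for an interaction;
   per-emotion short-vs-long pooled-variance t tests follow, Bonferroni
   corrected.  Per-bin normalisation pins each bin's percentages at a
   sum of 100, so the abstinence *main* effect is analytically zero —
   only the interaction is informative.

## Worked example

```python
import cessalex as cx

bundle = cx.generate_study(n_control=40, n_target=3, n_posts=1000,
                           seed=7, post_length_mean=20)
cfg = cx.PipelineConfig(window=1000, min_text=700, truncate=700,
                        targets=tuple(bundle.target_outliers),
                        abstinence_forums=("target_alcohol",))
report = cx.run_pipeline(cfg, bundle.corpora)

print(f"retained {len(report.retained)} of {len(report.scores)} forums")
for forum, rep in report.outliers.items():
    print(f"{forum}: outlier emotions {rep.outliers}")
ar = report.abstinence["target_alcohol"]
print(f"first-day posting share: {ar.first_day_pct:.1f}% "
      f"(uniform chance {ar.uniform_chance_pct}%)")
print(f"ANOVA: emotion F={ar.anova.emotion.F:.1f}, "
      f"abstinence F={ar.anova.abstinence.F:.2e}, "
      f"interaction F={ar.anova.interaction.F:.2f}")
for tt in ar.ttests:
    print(f"  {tt.emotion}: t({tt.df:.0f})={tt.t:.2f}, p={tt.p:.4f}, "
          f"significant={tt.significant}")
```

Output:

```
retained 21 of 43 forums
target_alcohol: outlier emotions ('pride', 'gratitude')
target_nicotine: outlier emotions ('disgust',)
target_cannabis: outlier emotions ('anxiety', 'disgust')
first-day posting share: 6.9% (uniform chance 0.01%)
ANOVA: emotion F=80.5, abstinence F=4.04e-28, interaction F=2.29
  anxiety: t(13)=5.38, p=0.0001, significant=True
  disgust: t(13)=-0.60, p=0.5581, significant=False
  gratitude: t(13)=0.03, p=0.9771, significant=False
  pride: t(13)=-1.50, p=0.1569, significant=False
```

The median split keeps 21 of 43 forums (the emotion-rich half).  Each
target forum is flagged as an outlier on exactly the categories its
generating composition elevated.  Tagged posts cluster in the first 24
hours of abstinence (6.9% of posts, against a 0.01% uniform-chance
expectation over a 10,000-day range).  The abstinence main-effect F is
zero to machine precision, as per-bin normalisation forces; the
generator's built-in post-100-day anxiety decrease shows up as a
significant positive short-vs-long anxiety contrast, while the other
focal emotions stay null.

A command-line interface wraps the same functions:

```sh
cessalex simulate --preset small --seed 7 --out study/
cessalex run --config study.yaml --out run_a/
cessalex compare run_a/ run_b/
```

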