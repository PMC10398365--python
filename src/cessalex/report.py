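"""Pipeline orchestration and result tables.

``run_pipeline`` executes the full analysis on a set of per-forum corpora
(or a JSONL dump): text-post filtering, window inclusion, truncation to a
common post count, the median-split emotion-density filter, per-forum
occurrence-frequency profiles, percentile outlier detection for the
designated target forums, pairwise cosine similarity with top-k neighbour
lists, and (when configured) the abstinence-duration analysis.  Every
filter logs counts before and after.

``compare_runs`` summarises the agreement between two snapshots run
through the identical pipeline — outlier-category overlap, Jaccard
similarity of top-k neighbour sets, and per-category frequency deltas —
the replication surface of the analysis.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

from . import abstinence as ab
from .corpus_io import Corpus, group_by_forum, read_posts_jsonl, \
    filter_text_posts, passes_inclusion, truncate_recent
from .lexicons import Lexicon, default_emotion_lexicon, default_time_lexicon, \
    load_lexicon
from .scoring import CorpusProfile, OutlierReport, corpus_profile, \
    emotion_score, median_split_retain, percentile_outliers
from .similarity import SimilarityMatrix, similarity_matrix, top_k_similar

__all__ = ["PipelineConfig", "RunReport", "AbstinenceReport",
           "run_pipeline", "compare_runs", "write_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to regenerate a run."""

    posts_path: Optional[str] = None      # JSONL dump (or pass corpora)
    lexicon: str = "emotion"              # "emotion", "time", or a file path
    field_choice: str = "body"            # or "title+body"
    window: int = 5025
    min_text: int = 3000
    truncate: int = 3003
    percentile_q: float = 95.0
    top_k: int = 5
    targets: Tuple[str, ...] = ()
    abstinence_forums: Tuple[str, ...] = ()
    abstinence_n_keep: int = 1205
    posthoc_emotions: Tuple[str, ...] = ()
    alpha: float = 0.05

    def resolve_lexicon(self) -> Lexicon:
        if self.lexicon == "emotion":
            return default_emotion_lexicon()
        if self.lexicon == "time":
            return default_time_lexicon()
        return load_lexicon(self.lexicon)


@dataclass(frozen=True)
class AbstinenceReport:
    forum: str
    n_tagged: int
    first_day_pct: float
    uniform_chance_pct: float
    first_day_top: Tuple[Tuple[str, float], ...]
    anova: ab.AnovaResult
    ttests: Tuple[ab.TTestResult, ...]
    bin_edges: Tuple[float, ...]


@dataclass(frozen=True)
class RunReport:
    config: PipelineConfig
    scores: Dict[str, float]
    retained: Tuple[str, ...]
    profiles: Dict[str, CorpusProfile]
    outliers: Dict[str, OutlierReport]
    neighbours: Dict[str, Tuple[Tuple[str, float], ...]]
    similarity: Optional[SimilarityMatrix]
    abstinence: Dict[str, AbstinenceReport]
    exclusion_log: Tuple[str, ...]


def run_pipeline(config: PipelineConfig,
                 corpora: Optional[Mapping[str, Corpus]] = None) -> RunReport:
    """Run the full profiling pipeline and assemble a report."""
    lexicon = config.resolve_lexicon()
    log: List[str] = [f"lexicon={lexicon.name} K={lexicon.K} "
                      f"field={config.field_choice}"]
    if corpora is None:
        if config.posts_path is None:
            raise ValueError("config needs posts_path when no corpora given")
        posts = read_posts_jsonl(config.posts_path)
        corpora = group_by_forum(posts, window_size=config.window)
        log.append(f"ingest: {len(posts)} posts, {len(corpora)} forums")

    # window inclusion + truncation to a common number of text posts
    text_corpora: Dict[str, Corpus] = {}
    for forum, corpus in corpora.items():
        textful = filter_text_posts(corpus)
        log.append(f"filter_text_posts[{forum}]: {len(corpus)} -> "
                   f"{len(textful)}")
        if not passes_inclusion(corpus, config.min_text, config.window):
            log.append(f"exclude[{forum}]: < {config.min_text} text posts "
                       f"in window of {config.window}")
            continue
        text_corpora[forum] = truncate_recent(textful, config.truncate)
        log.append(f"truncate_recent[{forum}]: -> {config.truncate}")

    if len(text_corpora) < 2:
        raise ValueError("fewer than 2 forums pass the inclusion filter")

    scores = {f: emotion_score(c, lexicon, config.field_choice)
              for f, c in text_corpora.items()}
    retained_set = median_split_retain(scores)
    log.append(f"median_split: retained {len(retained_set)} of "
               f"{len(scores)} forums")
    retained = tuple(sorted(retained_set))

    profiles = {f: corpus_profile(text_corpora[f], lexicon,
                                  config.field_choice)
                for f in retained}

    targets = tuple(t for t in config.targets if t in profiles)
    for t in config.targets:
        if t not in profiles:
            log.append(f"target[{t}]: not retained, no outlier analysis")
    control_profiles = [profiles[f] for f in retained if f not in targets]
    outliers = {t: percentile_outliers(profiles[t], control_profiles,
                                       config.percentile_q)
                for t in targets}

    sim = None
    neighbours: Dict[str, Tuple[Tuple[str, float], ...]] = {}
    if len(retained) >= 2:
        sim = similarity_matrix([profiles[f] for f in retained])
        k = min(config.top_k, len(retained) - 1)
        for t in (targets or retained):
            neighbours[t] = tuple(top_k_similar(sim, t, k))

    abstinence_reports: Dict[str, AbstinenceReport] = {}
    bins = ab.default_bins()
    for forum in config.abstinence_forums:
        if forum not in corpora:
            log.append(f"abstinence[{forum}]: forum missing, skipped")
            continue
        tagged = ab.filter_abstinence_tagged(corpora[forum].posts,
                                             config.abstinence_n_keep)
        if not tagged:
            log.append(f"abstinence[{forum}]: no tagged posts, skipped")
            continue
        _, top = ab.first_day_profile(tagged, lexicon)
        table = ab.bin_posts(tagged, lexicon, bins, forum=forum)
        anova = ab.two_way_anova(table, bins)
        emotions = config.posthoc_emotions or tuple(
            sorted({c for rep in outliers.values() for c in rep.outliers}))
        tts = (ab.posthoc_ttests(table, bins, emotions, config.alpha)
               if emotions else [])
        abstinence_reports[forum] = AbstinenceReport(
            forum=forum, n_tagged=len(tagged),
            first_day_pct=ab.first_day_fraction(tagged),
            uniform_chance_pct=ab.uniform_chance_first_day(),
            first_day_top=tuple(top), anova=anova, ttests=tuple(tts),
            bin_edges=bins.edges)
        log.append(f"abstinence[{forum}]: {len(tagged)} tagged posts, "
                   f"bin edges logged")

    return RunReport(config=config, scores=scores, retained=retained,
                     profiles=profiles, outliers=outliers,
                     neighbours=neighbours, similarity=sim,
                     abstinence=abstinence_reports,
                     exclusion_log=tuple(log))


def compare_runs(a: RunReport, b: RunReport) -> Dict[str, dict]:
    """Replication summary between two snapshots of the same design."""
    lex_a = a.config.lexicon
    if lex_a != b.config.lexicon:
        raise ValueError("runs used different lexicons")
    summary: Dict[str, dict] = {}
    for target in a.outliers:
        if target not in b.outliers:
            continue
        oa = set(a.outliers[target].outliers)
        ob = set(b.outliers[target].outliers)
        na = {f for f, _ in a.neighbours.get(target, ())}
        nb = {f for f, _ in b.neighbours.get(target, ())}
        union = na | nb
        jaccard = len(na & nb) / len(union) if union else 1.0
        deltas = {
            c: b.profiles[target].frequencies[c]
            - a.profiles[target].frequencies[c]
            for c in a.profiles[target].frequencies
        } if target in b.profiles else {}
        summary[target] = {
            "outliers_a": tuple(sorted(oa)),
            "outliers_b": tuple(sorted(ob)),
            "outlier_overlap": tuple(sorted(oa & ob)),
            "neighbour_jaccard": jaccard,
            "frequency_deltas": deltas,
        }
    return summary


def write_report(report: RunReport, out_dir: str | Path) -> None:
    """Materialise a run as CSV tables (profiles, outliers, similarity...)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if report.profiles:
        cats = list(next(iter(report.profiles.values())).frequencies)
        with open(out / "profiles.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["forum"] + cats)
            for forum in sorted(report.profiles):
                prof = report.profiles[forum]
                w.writerow([forum] + [f"{prof.frequencies[c]:.6f}"
                                      for c in cats])

    with open(out / "scores.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["forum", "emotion_score", "retained"])
        for forum in sorted(report.scores):
            w.writerow([forum, report.scores[forum],
                        int(forum in report.retained)])

    if report.outliers:
        with open(out / "outliers.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["forum", "category", "frequency", "threshold",
                        "is_outlier"])
            for forum in sorted(report.outliers):
                rep = report.outliers[forum]
                for c in rep.frequencies:
                    w.writerow([forum, c, f"{rep.frequencies[c]:.6f}",
                                f"{rep.thresholds[c]:.6f}",
                                int(rep.is_outlier(c))])

    if report.similarity is not None:
        sim = report.similarity
        with open(out / "similarity.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["forum"] + list(sim.forums))
            for i, f in enumerate(sim.forums):
                w.writerow([f] + [f"{v:.6f}" for v in sim.values[i]])

    if report.neighbours:
        with open(out / "neighbours.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["forum", "rank", "neighbour", "cosine"])
            for forum in sorted(report.neighbours):
                for rank, (nb, val) in enumerate(report.neighbours[forum], 1):
                    w.writerow([forum, rank, nb, f"{val:.6f}"])

    if report.abstinence:
        with open(out / "abstinence.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["forum", "n_tagged", "first_day_pct",
                        "uniform_chance_pct", "anova_emotion_F",
                        "anova_abstinence_F", "anova_interaction_F"])
            for forum in sorted(report.abstinence):
                r = report.abstinence[forum]
                w.writerow([forum, r.n_tagged, f"{r.first_day_pct:.4f}",
                            f"{r.uniform_chance_pct:.4f}",
                            f"{r.anova.emotion.F:.4f}",
                            f"{r.anova.abstinence.F:.2e}",
                            f"{r.anova.interaction.F:.4f}"])
        with open(out / "ttests.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["forum", "emotion", "t", "df", "p",
                        "alpha_adjusted", "significant", "method"])
            for forum in sorted(report.abstinence):
                for tt in report.abstinence[forum].ttests:
                    w.writerow([forum, tt.emotion, f"{tt.t:.4f}", tt.df,
                                f"{tt.p:.6g}", tt.alpha_adjusted,
                                int(tt.significant), tt.method])

    with open(out / "log.txt", "w") as fh:
        fh.write("\n".join(report.exclusion_log) + "\n")
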