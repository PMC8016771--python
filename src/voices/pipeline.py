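"""End-to-end pipeline: ingest → clean → stats → prep → topics → phrases.

Each stage writes its outputs to the run directory before the next starts,
so any stage can be re-run or inspected on its own. A run ends with a
manifest listing every output file with its SHA-256 hash: two runs with
identical config and inputs produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from voices import corpus, phrases, stats, survey, synthetic, topics
from voices.errors import ConfigurationError, StageError

log = logging.getLogger("voices")

SIGNIFICANCE = 0.05


@dataclass
class RunConfig:
    out_dir: str
    seed: int
    simulate: dict | None = None          # {"n_respondents": .., "k_true": ..}
    input_table: str | None = None
    input_documents: str | None = None
    schema: dict | None = None
    background_path: str | None = None
    background_tokens: int = 50_000
    exclusions: list = field(default_factory=list)
    combine_questions: list = field(default_factory=lambda: ["night", "research"])
    k_range: tuple = (2, 6)
    gamma: float = phrases.DEFAULT_GAMMA
    group_by: list = field(default_factory=lambda: ["mtg"])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed must be explicit")
        if self.simulate is None and self.input_table is None:
            raise ConfigurationError("either simulate or input_table required")
        for attr in ("input_table", "input_documents", "background_path"):
            value = getattr(self, attr)
            if value is not None and not Path(value).exists():
                raise ConfigurationError(f"{attr} does not exist: {value}")
        if not (0.0 <= self.gamma <= 1.0):
            raise ConfigurationError("gamma must be in [0, 1]")


@dataclass
class ReportBundle:
    out_dir: Path
    demographics: pd.DataFrame
    summaries: pd.DataFrame
    tests: pd.DataFrame
    model_selection: pd.DataFrame
    topic_report: pd.DataFrame
    phrase_report: pd.DataFrame
    audit: dict
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, lineterminator="\n")


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
        return inner
    return wrap


@_stage("ingest")
def _ingest(config: RunConfig):
    if config.simulate is not None:
        n = int(config.simulate.get("n_respondents", 300))
        k_true = int(config.simulate.get("k_true", 3))
        cohort_spec = synthetic.CohortSpec(n_respondents=n, seed=config.seed)
        cohort = synthetic.generate_cohort(cohort_spec)
        text_spec = synthetic.default_text_spec(k_true=k_true, seed=config.seed)
        document_set = synthetic.generate_open_text(text_spec, cohort)
        records = survey.records_from_table(cohort, document_set)
        report = survey.ValidationReport()
    else:
        records, report = survey.load_responses(config.input_table, config.schema)
        if config.input_documents:
            document_set = corpus.read_jsonl(config.input_documents)
        else:
            document_set = corpus.DocumentSet([])
    log.info("ingest: %d records, %d documents, %d validation issues",
             len(records), len(document_set), len(report))
    return records, document_set, report


@_stage("clean")
def _clean(config: RunConfig, records, document_set):
    rules = [survey.ExclusionRule(**r) if isinstance(r, dict) else r
             for r in config.exclusions]
    kept, audit = survey.apply_exclusions(records, rules)
    kept_ids = {r.respondent_id for r in kept}
    docs = [d for d in document_set.documents if d.respondent_id in kept_ids]
    log.info("clean: kept %d / %d records", len(kept), len(records))
    return kept, corpus.DocumentSet(docs, document_set.provenance), audit


@_stage("stats")
def _stats(config: RunConfig, records):
    summaries = [stats.summarise_ratings(records, t) for t in synthetic.TOPICS]
    order, tie = stats.rank_topics(summaries)
    sum_frame = pd.DataFrame([
        {"topic": s.topic, "n": s.n, "mean": s.mean, "sd": s.sd,
         "priority_rank": order.index(s.topic) + 1}
        for s in summaries
    ]).sort_values("priority_rank", kind="stable").reset_index(drop=True)

    rows = []

    def add(res: stats.StatTestResult):
        df = res.df if not isinstance(res.df, tuple) else f"{res.df[0]:g},{res.df[1]:g}"
        rows.append({
            "kind": res.kind, "comparison": " vs ".join(res.comparison),
            "statistic": res.statistic, "df": df, "p_raw": res.p_raw,
            "p_adjusted": res.p_adjusted, "m": res.m,
            "degenerate": res.degenerate,
        })

    pair_family = list(itertools.combinations(synthetic.TOPICS, 2))
    for a, b in pair_family:
        res = stats.paired_t(records, a, b)
        res.m = len(pair_family)
        res.p_adjusted = stats.bonferroni(res.p_raw, res.m)
        add(res)

    groupers = {"mtg": lambda r: r.mtg, "gender": lambda r: r.gender,
                "region": lambda r: survey.map_region(r.country)}
    for var in config.group_by:
        group_of = groupers[var]
        for topic in synthetic.TOPICS:
            groups = stats.ratings_by_group(records, topic, group_of)
            if var == "gender":
                # contrasts are female vs male; undisclosed is descriptive only
                groups = {g: v for g, v in groups.items()
                          if g in ("female", "male")}
            groups = {g: v for g, v in groups.items() if len(v) >= 2}
            if len(groups) < 2:
                continue
            res = stats.one_way_anova(groups)
            res.comparison = (var, topic)
            add(res)
            for post in stats.posthoc_pairwise(groups):
                post.comparison = (topic,) + post.comparison
                add(post)

    tests = pd.DataFrame(rows)
    return sum_frame, tests, tie


@_stage("prep")
def _prep(config: RunConfig, document_set):
    document_set, _failures = corpus.translate(document_set)
    prepared = corpus.prepare(document_set)
    available = {d.question_id for d in prepared.documents}
    wanted = [q for q in config.combine_questions if q in available]
    if wanted:
        prepared = corpus.combine_questions(prepared, wanted)
    return prepared


@_stage("topics")
def _topics(config: RunConfig, prepared):
    matrix = topics.build_tfidf(prepared)
    embeddings = topics.embeddings_for(prepared, seed=config.seed)
    kmin, kmax = config.k_range
    selection = topics.select_k(matrix, range(int(kmin), int(kmax) + 1),
                                embeddings, seed=config.seed)
    model_rows = [
        {"k": k, "mean_coherence": r.mean_coherence,
         "reconstruction_error": r.reconstruction_error,
         "selected": k == selection.k_star, "tie": selection.tie}
        for k, r in sorted(selection.results.items())
    ]
    best = selection.results[selection.k_star]
    topic_rows = [
        {"topic": idx, "rank": rank + 1, "term": term, "weight": weight,
         "coherence": best.coherence_per_topic[idx]}
        for idx, words in enumerate(best.top_words)
        for rank, (term, weight) in enumerate(words)
    ]
    log.info("topics: selected k=%d (mean coherence %.4f)",
             selection.k_star, best.mean_coherence)
    return pd.DataFrame(model_rows), pd.DataFrame(topic_rows), selection


@_stage("phrases")
def _phrases(config: RunConfig, prepared):
    if config.background_path:
        background = phrases.BackgroundCorpus.from_file(config.background_path)
    else:
        text_spec = synthetic.default_text_spec(seed=config.seed)
        background = synthetic.generate_background_corpus(
            text_spec, config.background_tokens)
    rankings = phrases.rank_by_group(prepared, background, config.gamma)
    rows = [
        {"mtg": mtg, "rank": i + 1, "phrase": s.text, "length": len(s.phrase),
         "fg_count": s.fg_count, "phraseness": s.phraseness,
         "informativeness": s.informativeness, "klip": s.klip}
        for mtg, ranked in rankings.items()
        for i, s in enumerate(ranked[:25])
    ]
    return pd.DataFrame(rows), rankings


def run(config: RunConfig) -> ReportBundle:
    """Execute the full pipeline; see module docstring.

    Any stage failure aborts with a :class:`StageError` naming the stage;
    outputs written so far stay on disk next to a ``FAILED`` marker.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(frame: pd.DataFrame, name: str):
        path = out / name
        _write_csv(frame, path)
        written.append(path)

    try:
        records, document_set, validation = _ingest(config)
        records, document_set, audit = _clean(config, records, document_set)

        demo = survey.demographics_frame(survey.demographic_summary(records))
        emit(demo, "demographics.csv")
        audit_path = out / "audit.json"
        audit_payload = {
            "excluded": audit,
            "validation_issues": [dataclasses.asdict(i) for i in validation.issues],
            "significance_threshold": SIGNIFICANCE,
        }
        audit_path.write_text(json.dumps(audit_payload, indent=2, sort_keys=True))
        written.append(audit_path)

        sum_frame, tests, tie = _stats(config, records)
        emit(sum_frame, "rating_summaries.csv")
        emit(tests, "rating_tests.csv")

        prepared = _prep(config, document_set)
        if len(prepared) >= 2:
            model_frame, topic_frame, _sel = _topics(config, prepared)
            emit(model_frame, "model_selection.csv")
            emit(topic_frame, "topics.csv")
            phrase_frame, _rankings = _phrases(config, prepared)
            emit(phrase_frame, "phrases.csv")
        else:
            model_frame = topic_frame = phrase_frame = pd.DataFrame()
    except StageError:
        (out / "FAILED").write_text("pipeline aborted; see logs\n")
        raise

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return ReportBundle(
        out_dir=out, demographics=demo, summaries=sum_frame, tests=tests,
        model_selection=model_frame, topic_report=topic_frame,
        phrase_report=phrase_frame, audit=audit_payload, manifest=manifest,
    )
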