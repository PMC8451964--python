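"""Config-driven orchestration of the multistage retrieval pipeline.

Seven builtin run recipes compose the primitives (first-stage search,
reciprocal rank fusion, second-stage reranking, logistic score fusion):

=====  ====================  ==================================================
run    label                 definition
=====  ====================  ==================================================
M1     bm25                  BM25 against the metadata index
M2     bow+rrf               RRF of {BM25, DFR, LMD} x {metadata, fulltext}
M3     mlm+rrf               RRF of the registered rerankers applied to the
                             top-k of M2
M4     bow+mlm+rrf           RRF of M2 and M3
M5     bow+mlm+lm            pairwise learning-to-rank over M2/M3 scores —
                             requires a registered pairwise plug-in
M6     bow+mlm+lr            logistic fusion over the constituent scores of
                             M2 and M3
M7     bow+mlm+lr+rrf        RRF of M2, M3 and M6
=====  ====================  ==================================================

Custom recipes are declared in the config as small DAGs over the same
primitives; references are resolved and checked for cycles before any
computation starts.  Identical config + inputs produce byte-identical
run files.
"""

from __future__ import annotations

import datetime
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .corpus_io import (DocumentRecord, JudgmentSet, RankedList, TopicRecord,
                        write_run)
from .evaluation import MetricsReport, evaluate_run
from .fixtures import corpus_by_id
from .fusion_rerank import (PAIRWISE_REGISTRY, RRFParams, SCORER_REGISTRY,
                            assemble_features, fit_logistic, rerank_topk,
                            rrf_fuse, score_logistic)
from .index_core import (ConfigurationError, IndexConfig, build_index,
                         make_query_plan, search)
from .text_pipeline import SynonymTable, default_synonyms, load_synonyms
from .weighting import MODEL_HANDLES, default_params

__all__ = ["PipelineConfig", "load_config", "run_pipeline",
            "BUILTIN_RECIPES", "validate_recipe"]

log = logging.getLogger("pubrank.pipeline")

BUILTIN_RECIPES = ("M1", "M2", "M3", "M4", "M5", "M6", "M7")
DEFAULT_RECIPES = ("M1", "M2", "M3", "M4", "M6", "M7")

_BOW_MODELS = ("bm25", "dfr", "lmd")
_INDEX_KINDS = ("metadata", "fulltext")


@dataclass
class PipelineConfig:
    """Everything a pipeline execution depends on."""

    model_params: dict = dc_field(default_factory=dict)
    rrf_k: float = 60.0
    rerank_depth: int = 5000
    run_depth: int = 1000
    top_k: int = 1000
    cutoff: datetime.date | None = None
    keep_undated: bool = True
    scorers: tuple[str, ...] = ("overlap-query", "overlap-question",
                                "overlap-narrative")
    pairwise_model: str | None = None
    recipes: tuple[str, ...] = DEFAULT_RECIPES
    custom_recipes: dict = dc_field(default_factory=dict)
    synonyms: SynonymTable | None = None
    logistic_l2: float = 1.0

    def params_for(self, model: str):
        if model in self.model_params:
            return self.model_params[model]
        return default_params(model)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a declarative YAML pipeline config."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    cfg = PipelineConfig()
    if "models" in raw:
        for name, kwargs in raw["models"].items():
            if name not in MODEL_HANDLES:
                raise ConfigurationError(f"unknown weighting model {name!r}")
            cfg.model_params[name] = MODEL_HANDLES[name](**(kwargs or {}))
    for key in ("rrf_k", "rerank_depth", "run_depth", "top_k",
                "keep_undated", "logistic_l2"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if raw.get("cutoff"):
        cfg.cutoff = datetime.date.fromisoformat(str(raw["cutoff"]))
    if "scorers" in raw:
        cfg.scorers = tuple(raw["scorers"])
    if "pairwise_model" in raw:
        cfg.pairwise_model = raw["pairwise_model"]
    if "recipes" in raw:
        cfg.recipes = tuple(raw["recipes"])
    if "custom_recipes" in raw:
        cfg.custom_recipes = dict(raw["custom_recipes"])
    if "synonyms" in raw:
        cfg.synonyms = (default_synonyms() if raw["synonyms"] == "default"
                        else load_synonyms(raw["synonyms"]))
    return cfg


def validate_recipe(name: str, nodes: Sequence[Mapping]) -> list[Mapping]:
    """Check a custom recipe DAG: unique names, resolvable references,
    registered scorers, acyclic.  Returns nodes in topological order."""
    by_name: dict[str, Mapping] = {}
    for node in nodes:
        node_name = node.get("name")
        if not node_name or node_name in by_name:
            raise ConfigurationError(
                f"recipe {name!r}: nodes need unique names (got {node_name!r})")
        by_name[node_name] = node
    for node in nodes:
        for ref in node.get("inputs", []):
            if ref not in by_name and ref not in BUILTIN_RECIPES:
                raise ConfigurationError(
                    f"recipe {name!r}: node {node['name']!r} references "
                    f"unknown input {ref!r}")
        if node.get("op") == "rerank" and node.get("scorer") not in SCORER_REGISTRY:
            raise ConfigurationError(
                f"recipe {name!r}: unregistered scorer {node.get('scorer')!r}")
    # Kahn topological sort; leftovers mean a cycle
    pending = {n["name"]: set(r for r in n.get("inputs", []) if r in by_name)
               for n in nodes}
    order: list[Mapping] = []
    while pending:
        ready = sorted(n for n, deps in pending.items() if not deps)
        if not ready:
            raise ConfigurationError(f"recipe {name!r}: cyclic dependency")
        for n in ready:
            order.append(by_name[n])
            del pending[n]
        for deps in pending.values():
            deps.difference_update(ready)
    return order


class _Pipeline:
    def __init__(self, config: PipelineConfig, corpus: Sequence[DocumentRecord],
                 topics: Sequence[TopicRecord], qrels: JudgmentSet | None):
        self.cfg = config
        self.corpus = list(corpus)
        self.lookup = corpus_by_id(corpus)
        self.topics = sorted(topics, key=lambda t: t.number)
        self.qrels = qrels
        self.rrf = RRFParams(k=config.rrf_k)
        self._cache: dict[str, list[RankedList]] = {}

        t0 = time.perf_counter()
        self.indices = {kind: build_index(corpus, IndexConfig(kind=kind))
                        for kind in _INDEX_KINDS}
        self.plans = {
            kind: {t.number: make_query_plan(t, kind, config.synonyms)
                   for t in self.topics}
            for kind in _INDEX_KINDS
        }
        log.info("indexed %d docs (both flavours) in %.2fs",
                 len(self.corpus), time.perf_counter() - t0)

    # -- primitives -------------------------------------------------------

    def bow_run(self, model: str, kind: str) -> list[RankedList]:
        key = f"bow:{model}:{kind}"
        if key not in self._cache:
            cfg = self.cfg
            self._cache[key] = [
                search(self.indices[kind], self.plans[kind][t.number], model,
                       cfg.params_for(model), top_k=cfg.top_k,
                       cutoff=cfg.cutoff, keep_undated=cfg.keep_undated,
                       tag=f"{model}-{kind}")
                for t in self.topics
            ]
        return self._cache[key]

    def _fuse(self, run_lists: Sequence[list[RankedList]], tag: str
              ) -> list[RankedList]:
        by_topic: dict[int, list[RankedList]] = {}
        for run in run_lists:
            for lst in run:
                by_topic.setdefault(lst.topic, []).append(lst)
        return [rrf_fuse(by_topic[t], self.rrf, tag=tag,
                         top_k=self.cfg.run_depth)
                for t in sorted(by_topic)]

    def rerank_run(self, base: list[RankedList], scorer_name: str
                   ) -> list[RankedList]:
        scorer = SCORER_REGISTRY[scorer_name]
        topic_by_number = {t.number: t for t in self.topics}
        depth = min(self.cfg.rerank_depth, len(self.corpus))
        return [rerank_topk(lst, scorer, topic_by_number[lst.topic],
                            self.lookup, k=depth, tag=scorer_name)
                for lst in base]

    def feature_runs(self) -> dict[str, list[RankedList]]:
        """The constituent runs of M2 and M3: six bag-of-words lists plus
        one list per registered reranker."""
        runs = {f"{m}-{kind}": self.bow_run(m, kind)
                for m in _BOW_MODELS for kind in _INDEX_KINDS}
        base = self.recipe("M2")
        for name in self.cfg.scorers:
            runs[name] = self.rerank_run(base, name)
        return runs

    # -- builtin recipes --------------------------------------------------

    def recipe(self, name: str) -> list[RankedList]:
        if name in self._cache:
            return self._cache[name]
        t0 = time.perf_counter()
        if name == "M1":
            run = [l.truncated(self.cfg.run_depth)
                   for l in self.bow_run("bm25", "metadata")]
            run = [RankedList(l.topic, l.entries, "M1") for l in run]
        elif name == "M2":
            run = self._fuse([self.bow_run(m, k) for m in _BOW_MODELS
                              for k in _INDEX_KINDS], "M2")
        elif name == "M3":
            if not self.cfg.scorers:
                raise ConfigurationError("M3 requires at least one reranker")
            base = self.recipe("M2")
            run = self._fuse([self.rerank_run(base, s) for s in self.cfg.scorers],
                             "M3")
        elif name == "M4":
            run = self._fuse([self.recipe("M2"), self.recipe("M3")], "M4")
        elif name == "M5":
            model = self.cfg.pairwise_model
            plugin = PAIRWISE_REGISTRY.get(model or "")
            if plugin is None:
                raise ConfigurationError(
                    "M5 requires a registered pairwise plug-in "
                    f"(got {model!r})")
            run = plugin(self.feature_runs(), self.qrels)
        elif name == "M6":
            if self.qrels is None:
                raise ConfigurationError("M6 needs training judgments")
            table = assemble_features(self.feature_runs(), self.qrels)
            model = fit_logistic(table, l2=self.cfg.logistic_l2)
            run = score_logistic(model, table, tag="M6",
                                 top_k=self.cfg.run_depth)
        elif name == "M7":
            run = self._fuse([self.recipe("M2"), self.recipe("M3"),
                              self.recipe("M6")], "M7")
        else:
            raise ConfigurationError(f"unknown recipe {name!r}")
        log.info("recipe %s: %d topics in %.2fs", name, len(run),
                 time.perf_counter() - t0)
        self._cache[name] = run
        return run

    # -- custom DAG recipes -----------------------------------------------

    def custom_recipe(self, name: str, nodes: Sequence[Mapping]
                      ) -> list[RankedList]:
        order = validate_recipe(name, nodes)
        results: dict[str, list[RankedList]] = {}

        def resolve(ref: str) -> list[RankedList]:
            if ref in results:
                return results[ref]
            return self.recipe(ref)  # builtin reference

        last = None
        for node in order:
            op = node.get("op")
            if op == "search":
                out = self.bow_run(node["model"], node.get("index", "metadata"))
                out = [l.truncated(self.cfg.run_depth) for l in out]
            elif op == "rrf":
                out = self._fuse([resolve(r) for r in node["inputs"]],
                                 node["name"])
            elif op == "rerank":
                (ref,) = node["inputs"]
                out = self.rerank_run(resolve(ref), node["scorer"])
            elif op == "logistic":
                if self.qrels is None:
                    raise ConfigurationError(
                        f"recipe {name!r}: logistic node needs judgments")
                table = assemble_features(
                    {r: resolve(r) for r in node["inputs"]}, self.qrels)
                model = fit_logistic(table, l2=self.cfg.logistic_l2)
                out = score_logistic(model, table, tag=node["name"],
                                     top_k=self.cfg.run_depth)
            else:
                raise ConfigurationError(
                    f"recipe {name!r}: unknown op {op!r}")
            results[node["name"]] = out
            last = out
        assert last is not None
        return [RankedList(l.topic, l.entries, name) for l in last]


def run_pipeline(config: PipelineConfig, corpus: Sequence[DocumentRecord],
                 topics: Sequence[TopicRecord],
                 qrels: JudgmentSet | None = None,
                 out_dir: str | Path | None = None
                 ) -> tuple[dict[str, list[RankedList]],
                            dict[str, MetricsReport]]:
    """Execute the configured recipes end to end.

    Returns (runs, reports): one list-of-RankedList per recipe and, when
    judgments are supplied, one MetricsReport per recipe.  With
    ``out_dir`` set, one TREC run file per recipe is written there.
    """
    # fail fast on configuration problems before any computation
    for scorer in config.scorers:
        if scorer not in SCORER_REGISTRY:
            raise ConfigurationError(f"unregistered scorer {scorer!r}")
    for rname, nodes in config.custom_recipes.items():
        validate_recipe(rname, nodes)
    for rname in config.recipes:
        if rname not in BUILTIN_RECIPES and rname not in config.custom_recipes:
            raise ConfigurationError(f"unknown recipe {rname!r}")

    pipe = _Pipeline(config, corpus, topics, qrels)
    runs: dict[str, list[RankedList]] = {}
    for rname in config.recipes:
        if rname in BUILTIN_RECIPES:
            runs[rname] = pipe.recipe(rname)
        else:
            runs[rname] = pipe.custom_recipe(rname,
                                             config.custom_recipes[rname])
    reports: dict[str, MetricsReport] = {}
    if qrels is not None:
        for rname, run in runs.items():
            reports[rname] = evaluate_run(run, qrels)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rname, run in runs.items():
            write_run(run, out_dir / f"{rname}.run", depth=config.run_depth)
    return runs, reports
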