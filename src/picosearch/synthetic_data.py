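"""Seeded simulator of gold standards and per-strategy ranked search outputs.

Real evaluations of search strategies need a systematic review per
question (the gold standard) and the live search outputs of every
strategy — neither of which is available offline. The simulator
generates both with the statistical structure such data exhibit, so the
whole evaluation pipeline can be exercised and tested end to end.

Per question:

- the number of included studies is a rounded log-normal draw, floored
  at 4 (reviews with fewer than 4 trials are too thin to serve as a
  gold standard), calibrated so the median review holds about 12
  PubMed-indexed trials;
- each included study is independently PubMed-indexed with probability
  ``indexing_prob`` (default 0.85);
- for each strategy, each indexed gold article enters the output with
  probability ``query_retention * filter_retention`` — the chance the
  base Boolean query matches it times the chance the methodological
  filter keeps it (broad filters retain ~0.99 of trials, narrow ~0.93);
- the count of nonrelevant articles is a rounded log-normal draw
  (unfiltered searches yield a median of ~173 hits, narrow-filtered
  ~33);
- relevant articles are placed at ranks drawn without replacement with
  weight proportional to ``exp(-lambda * u)``, where ``u`` in [0, 1] is
  the fractional position and ``lambda = rank_concentration``; lambda 0
  scatters them uniformly, larger lambda pulls them toward the first
  pages, which is the behaviour that makes narrow-filtered searches
  effective within a 40-item screening budget.

Randomness comes from a single root seed that spawns one child stream
per question, so adding questions never perturbs earlier ones. Realized
per-question retention draws are kept in a truth record for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from picosearch.errors import ConfigError
from picosearch.retrieval_metrics import GoldStandard, RankedOutput

__all__ = [
    "OutputModel",
    "SimulationConfig",
    "SimulatedQuestion",
    "SimulatedStudy",
    "simulate_question",
    "simulate_study",
    "default_config",
]


@dataclass(frozen=True)
class OutputModel:
    """Generative model of one strategy's ranked output.

    ``nonrelevant_size_log_mean``/``_sd`` parameterize the log-normal
    count of nonrelevant hits (natural-log scale; the median count is
    ``exp(log_mean)``). ``rank_concentration`` >= 0 controls how
    strongly relevant items are pulled toward early ranks.
    """

    strategy_id: str
    query_retention: float = 0.85
    filter_retention: float = 1.0
    nonrelevant_size_log_mean: float = float(np.log(173))
    nonrelevant_size_log_sd: float = 1.0
    rank_concentration: float = 0.0

    def __post_init__(self) -> None:
        for name in ("query_retention", "filter_retention"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p!r}")
        if self.rank_concentration < 0:
            raise ConfigError("rank_concentration must be >= 0")
        if self.nonrelevant_size_log_sd < 0:
            raise ConfigError("nonrelevant_size_log_sd must be >= 0")

    @property
    def retention(self) -> float:
        """Probability an indexed gold article appears in the output."""
        return self.query_retention * self.filter_retention


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level parameters: question count, gold sizes, output models."""

    n_questions: int = 30
    gold_size_log_mean: float = float(np.log(12))
    gold_size_log_sd: float = 0.70
    gold_size_min: int = 4
    indexing_prob: float = 0.85
    output_models: tuple[OutputModel, ...] = ()
    seed: int = 20120612

    def __post_init__(self) -> None:
        if self.n_questions < 1:
            raise ConfigError("n_questions must be >= 1")
        if not 0.0 < self.indexing_prob <= 1.0:
            raise ConfigError("indexing_prob must be in (0, 1]")
        if self.gold_size_min < 1:
            raise ConfigError("gold_size_min must be >= 1")
        object.__setattr__(self, "output_models", tuple(self.output_models))


@dataclass(frozen=True)
class SimulatedQuestion:
    """One simulated question: gold standard, outputs, realized truth."""

    gold: GoldStandard
    outputs: tuple[RankedOutput, ...]
    truth: dict


@dataclass(frozen=True)
class SimulatedStudy:
    """A full simulated study; ``questions`` are mutually independent."""

    config: SimulationConfig
    questions: tuple[SimulatedQuestion, ...]

    @property
    def golds(self) -> list[GoldStandard]:
        return [q.gold for q in self.questions]

    def outputs_for(self, strategy_id: str) -> list[RankedOutput]:
        return [o for q in self.questions for o in q.outputs
                if o.strategy_id == strategy_id]


def default_config() -> SimulationConfig:
    """The documented calibration of the simulator.

    30 questions with a median of ~12 indexed gold trials each, 85%
    indexing, and four output models spanning the behaviours of the
    strategy grid: an unfiltered query (large diffuse output), a broad
    therapy filter (slightly smaller, retention 0.99), a narrow therapy
    filter (small output, retention 0.93, relevant items concentrated
    early), and a related-articles search (very large output, moderate
    concentration, lower retention).
    """
    return SimulationConfig(
        n_questions=30,
        gold_size_log_mean=float(np.log(12)),
        gold_size_log_sd=0.70,
        indexing_prob=0.85,
        output_models=(
            OutputModel("unfiltered", query_retention=0.85,
                        filter_retention=1.0,
                        nonrelevant_size_log_mean=float(np.log(173)),
                        nonrelevant_size_log_sd=1.0,
                        rank_concentration=0.0),
            OutputModel("broad", query_retention=0.85,
                        filter_retention=0.99,
                        nonrelevant_size_log_mean=float(np.log(126)),
                        nonrelevant_size_log_sd=1.0,
                        rank_concentration=0.5),
            OutputModel("narrow", query_retention=0.85,
                        filter_retention=0.93,
                        nonrelevant_size_log_mean=float(np.log(33)),
                        nonrelevant_size_log_sd=1.0,
                        rank_concentration=2.0),
            OutputModel("related", query_retention=0.60,
                        filter_retention=1.0,
                        nonrelevant_size_log_mean=float(np.log(330)),
                        nonrelevant_size_log_sd=0.8,
                        rank_concentration=1.0),
        ),
        seed=20120612,
    )


def _place_relevant(n_total: int, n_relevant: int, lam: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw 0-based positions for relevant items, weight exp(-lam * u)."""
    if n_relevant == 0:
        return np.empty(0, dtype=np.int64)
    positions = np.arange(n_total)
    u = positions / max(n_total - 1, 1)
    w = np.exp(-lam * u)
    w /= w.sum()
    return rng.choice(positions, size=n_relevant, replace=False, p=w)


def _simulate_question_stream(
    config: SimulationConfig, question_index: int,
    rng: np.random.Generator,
) -> SimulatedQuestion:
    qid = f"Q{question_index + 1:03d}"
    n_included = max(
        config.gold_size_min,
        int(np.rint(rng.lognormal(config.gold_size_log_mean,
                                  config.gold_size_log_sd))),
    )
    included = [f"{qid}-G{j + 1:03d}" for j in range(n_included)]
    indexed_mask = rng.random(n_included) < config.indexing_prob
    if not indexed_mask.any():
        # a review whose trials are all outside PubMed cannot be evaluated;
        # keep one retrievable trial so the question stays scorable
        indexed_mask[int(rng.integers(n_included))] = True
    indexed = [a for a, m in zip(included, indexed_mask) if m]

    outputs: list[RankedOutput] = []
    truth: dict = {
        "question_id": qid,
        "n_included": n_included,
        "n_indexed": len(indexed),
        "strategies": {},
    }
    for model in config.output_models:
        retained_mask = rng.random(len(indexed)) < model.retention
        retained = [a for a, m in zip(indexed, retained_mask) if m]
        rng.shuffle(retained)
        n_nonrel = int(np.rint(rng.lognormal(model.nonrelevant_size_log_mean,
                                             model.nonrelevant_size_log_sd)))
        n_total = n_nonrel + len(retained)
        ranked = [f"{qid}-{model.strategy_id}-N{j + 1:05d}"
                  for j in range(n_total)]
        pos = _place_relevant(n_total, len(retained), model.rank_concentration,
                              rng)
        for p, article in zip(sorted(pos), retained):
            ranked[p] = article
        outputs.append(RankedOutput(qid, model.strategy_id, tuple(ranked)))
        truth["strategies"][model.strategy_id] = {
            "n_retained": len(retained),
            "n_nonrelevant": n_nonrel,
            "retention": model.retention,
        }
    gold = GoldStandard(qid, frozenset(included), frozenset(indexed))
    return SimulatedQuestion(gold=gold, outputs=tuple(outputs), truth=truth)


def simulate_question(config: SimulationConfig, question_index: int,
                      seed: int | None = None) -> SimulatedQuestion:
    """Simulate one question on its own child stream.

    The stream is derived from ``(seed or config.seed, question_index)``,
    so the same question index always yields the same data regardless
    of how many questions a study contains.
    """
    root = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(root).spawn(
        question_index + 1)[question_index])
    return _simulate_question_stream(config, question_index, rng)


def simulate_study(config: SimulationConfig | None = None,
                   seed: int | None = None) -> SimulatedStudy:
    """Simulate ``config.n_questions`` independent questions.

    ``seed`` overrides ``config.seed`` without mutating the config it
    was given (the echoed config records the seed actually used).
    """
    if config is None:
        config = default_config()
    if seed is not None:
        config = replace(config, seed=seed)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_questions)
    questions = tuple(
        _simulate_question_stream(config, i, np.random.default_rng(s))
        for i, s in enumerate(streams)
    )
    return SimulatedStudy(config=config, questions=questions)
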