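"""File formats, the packaged benchmark fixture, and the pipeline driver.

CSV schemas (UTF-8, comma-separated, header row required):

- gold standards: ``question_id, article_id, in_pubmed`` with
  ``in_pubmed`` in {0, 1}; one row per included study;
- ranked outputs: ``question_id, strategy_id, rank, article_id`` with
  1-based, gap-free ranks per (question, strategy);
- metric rows: ``question_id, strategy_id, cutoff, gold_size,
  n_screened, n_relevant_retrieved, sensitivity_pct, ppv_pct, nnr``.

The packaged fixture is a transcription of a published per-question
benchmark: 30 therapy questions from Cochrane systematic reviews with
the sensitivity and PPV of an unfiltered PIC search (S1) and a
narrow-filtered PIC search (S4), on the full output and on a 2-page
(40-item) output. Percentages are stored exactly as printed (one
decimal); integer retrieval counts are derived at load time and checked
for consistency with the printed percentages. The file is checksummed
against an embedded digest.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from picosearch.aggregation_stats import (
    ComparisonReport,
    StrategySummary,
    compare_strategies,
    median_cumulative_curve,
    summarize_strategy,
)
from picosearch.errors import (
    CorruptedFixtureError,
    IntegrityError,
    SchemaError,
)
from picosearch.retrieval_metrics import (
    GoldStandard,
    MetricResult,
    RankedOutput,
    evaluate,
    round_half_away,
)
from picosearch.synthetic_data import SimulatedStudy

__all__ = [
    "StudyDataset",
    "Table1Row",
    "Table1Fixture",
    "read_gold_csv",
    "write_gold_csv",
    "read_outputs_csv",
    "write_outputs_csv",
    "write_metrics_csv",
    "load_table1_fixture",
    "fixture_metric_results",
    "run_pipeline",
]

logger = logging.getLogger("picosearch")

_TABLE1_SHA256 = (
    "71426fcaf56e0bc797b10646bc2341f0a7e70ab9e8b8a859e8c9417c921fd221"
)


@dataclass(frozen=True)
class StudyDataset:
    """Gold standards plus per-question, per-strategy ranked outputs."""

    golds: tuple[GoldStandard, ...]
    outputs: tuple[RankedOutput, ...]
    provenance: str = "files"

    def __post_init__(self) -> None:
        gold_qids = {g.question_id for g in self.golds}
        if len(gold_qids) != len(self.golds):
            raise IntegrityError("duplicate question_id among gold standards")
        seen: set[tuple[str, str]] = set()
        for o in self.outputs:
            if o.question_id not in gold_qids:
                raise IntegrityError(
                    f"output for question {o.question_id!r} has no gold standard"
                )
            key = (o.question_id, o.strategy_id)
            if key in seen:
                raise IntegrityError(f"duplicate output for {key!r}")
            seen.add(key)

    @property
    def strategy_ids(self) -> list[str]:
        return sorted({o.strategy_id for o in self.outputs})

    def gold_for(self, question_id: str) -> GoldStandard:
        for g in self.golds:
            if g.question_id == question_id:
                return g
        raise KeyError(question_id)

    def outputs_for(self, strategy_id: str) -> list[RankedOutput]:
        return [o for o in self.outputs if o.strategy_id == strategy_id]

    @classmethod
    def from_simulation(cls, study: SimulatedStudy) -> "StudyDataset":
        return cls(
            golds=tuple(study.golds),
            outputs=tuple(o for q in study.questions for o in q.outputs),
            provenance="simulation",
        )


# ---------------------------------------------------------------------------
# CSV readers / writers

def read_gold_csv(path: str | Path) -> list[GoldStandard]:
    """Read gold standards; rejects bad in_pubmem flags and duplicate ids."""
    df = pd.read_csv(path, dtype=str)
    required = ["question_id", "article_id", "in_pubmed"]
    if list(df.columns) != required:
        raise SchemaError(
            f"{path}: expected columns {required}, found {list(df.columns)}"
        )
    golds: list[GoldStandard] = []
    for qid, grp in df.groupby("question_id", sort=True):
        included: set[str] = set()
        indexed: set[str] = set()
        for row in grp.itertuples():
            flag = str(row.in_pubmed).strip()
            if flag not in ("0", "1"):
                raise SchemaError(
                    f"{path}: row {row.Index + 2}, column in_pubmed: "
                    f"expected 0 or 1, found {row.in_pubmed!r}"
                )
            article = str(row.article_id).strip()
            if article in included:
                raise IntegrityError(
                    f"{path}: duplicate article {article!r} for question {qid!r}"
                )
            included.add(article)
            if flag == "1":
                indexed.add(article)
        golds.append(GoldStandard(str(qid), frozenset(included),
                                  frozenset(indexed)))
    return golds


def write_gold_csv(golds: Iterable[GoldStandard], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["question_id", "article_id", "in_pubmed"])
        for g in golds:
            for article in sorted(g.included_ids):
                writer.writerow(
                    [g.question_id, article, int(article in g.indexed_ids)]
                )


def read_outputs_csv(path: str | Path) -> list[RankedOutput]:
    """Read ranked outputs; ranks must be 1-based and gap-free per search."""
    df = pd.read_csv(path, dtype={"question_id": str, "strategy_id": str,
                                  "article_id": str, "rank": "Int64"})
    required = ["question_id", "strategy_id", "rank", "article_id"]
    if list(df.columns) != required:
        raise SchemaError(
            f"{path}: expected columns {required}, found {list(df.columns)}"
        )
    outputs: list[RankedOutput] = []
    for (qid, sid), grp in df.groupby(["question_id", "strategy_id"],
                                      sort=True):
        ranks = grp["rank"].to_list()
        if sorted(ranks) != list(range(1, len(ranks) + 1)):
            raise IntegrityError(
                f"{path}: ranks for ({qid!r}, {sid!r}) are not 1-based and "
                "gap-free"
            )
        ordered = grp.sort_values("rank")["article_id"].str.strip().to_list()
        if len(set(ordered)) != len(ordered):
            raise IntegrityError(
                f"{path}: duplicate article ids for ({qid!r}, {sid!r})"
            )
        outputs.append(RankedOutput(str(qid), str(sid), tuple(ordered)))
    return outputs


def write_outputs_csv(outputs: Iterable[RankedOutput],
                      path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["question_id", "strategy_id", "rank", "article_id"])
        for o in outputs:
            for rank, article in enumerate(o.ranked_ids, start=1):
                writer.writerow([o.question_id, o.strategy_id, rank, article])


def write_metrics_csv(metrics: Iterable[MetricResult],
                      path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["question_id", "strategy_id", "cutoff", "gold_size", "n_screened",
             "n_relevant_retrieved", "sensitivity_pct", "ppv_pct", "nnr"]
        )
        for m in metrics:
            writer.writerow(
                [m.question_id, m.strategy_id, m.cutoff, m.gold_size,
                 m.n_screened, m.n_relevant_retrieved, m.sensitivity_pct,
                 m.ppv_pct, m.nnr if m.nnr is not None else ""]
            )


# ---------------------------------------------------------------------------
# Packaged benchmark fixture

@dataclass(frozen=True)
class Table1Row:
    """One benchmark question with the printed S1/S4 performance figures."""

    review_id: int
    title: str
    n_included: int
    n_retrievable: int
    s1_full_sens: float
    s4_full_sens: float
    s1_full_ppv: float
    s4_full_ppv: float
    s1_2p_sens: float
    s4_2p_sens: float
    s1_2p_ppv: float
    s4_2p_ppv: float

    def n_retrieved(self, strategy: Literal["S1", "S4"],
                    cutoff: Literal["full", "2p"]) -> int:
        """Integer retrieval count derived from the printed sensitivity."""
        pct = getattr(self, f"{strategy.lower()}_{cutoff}_sens")
        return int(round_half_away(pct * self.n_retrievable / 100.0))


@dataclass(frozen=True)
class Table1Fixture:
    rows: tuple[Table1Row, ...]

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, review_id: int) -> Table1Row:
        for r in self.rows:
            if r.review_id == review_id:
                return r
        raise KeyError(review_id)

    def column(self, name: str) -> list[float]:
        return [getattr(r, name) for r in self.rows]

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rows])


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged 30-question benchmark transcription.

    The raw bytes are checked against an embedded SHA-256 digest, and
    each derived retrieval count is checked to reproduce the printed
    percentage after rounding; either failure raises
    :class:`CorruptedFixtureError`.
    """
    data = (resources.files("picosearch") / "data" / "table1.csv").read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _TABLE1_SHA256:
        raise CorruptedFixtureError(
            f"table1.csv digest mismatch: {digest} != {_TABLE1_SHA256}"
        )
    rows: list[Table1Row] = []
    for rec in csv.DictReader(data.decode("utf-8").splitlines()):
        row = Table1Row(
            review_id=int(rec["review_id"]),
            title=rec["title"],
            n_included=int(rec["n_included"]),
            n_retrievable=int(rec["n_retrievable"]),
            **{k: float(rec[k]) for k in (
                "s1_full_sens", "s4_full_sens", "s1_full_ppv", "s4_full_ppv",
                "s1_2p_sens", "s4_2p_sens", "s1_2p_ppv", "s4_2p_ppv")},
        )
        if not (0 < row.n_retrievable <= row.n_included):
            raise CorruptedFixtureError(
                f"review {row.review_id}: impossible study counts"
            )
        for strategy in ("S1", "S4"):
            for cutoff in ("full", "2p"):
                n = row.n_retrieved(strategy, cutoff)  # type: ignore[arg-type]
                back = round_half_away(100.0 * n / row.n_retrievable, 1)
                printed = getattr(row, f"{strategy.lower()}_{cutoff}_sens")
                if back != printed:
                    raise CorruptedFixtureError(
                        f"review {row.review_id}: derived count {n} does not "
                        f"reproduce printed {strategy} {cutoff} sensitivity "
                        f"{printed}"
                    )
        rows.append(row)
    if len(rows) != 30:
        raise CorruptedFixtureError(f"expected 30 rows, found {len(rows)}")
    return Table1Fixture(tuple(rows))


def fixture_metric_results(
    fixture: Table1Fixture,
    strategy: Literal["S1", "S4"],
    cutoff: Literal["full", "2p"] = "2p",
) -> list[MetricResult]:
    """Per-question MetricResults reconstructed from the printed figures.

    Sensitivity and PPV are taken exactly as printed; the relevant
    count is derived from sensitivity, and the screened count from
    PPV where PPV > 0 (it is unknowable from the printed figures for
    zero-PPV searches and is left at the cutoff bound there).
    """
    out: list[MetricResult] = []
    cut: int | Literal["full"] = "full" if cutoff == "full" else 40
    for row in fixture.rows:
        sens = getattr(row, f"{strategy.lower()}_{cutoff}_sens")
        ppv = getattr(row, f"{strategy.lower()}_{cutoff}_ppv")
        n_rel = row.n_retrieved(strategy, cutoff)
        if ppv > 0 and n_rel > 0:
            n_screened = int(round_half_away(100.0 * n_rel / ppv))
        else:
            n_screened = 40 if cut == 40 else 0
        out.append(MetricResult(
            question_id=str(row.review_id),
            strategy_id=strategy,
            cutoff=cut,
            gold_size=row.n_retrievable,
            n_screened=n_screened,
            n_relevant_retrieved=n_rel,
            sensitivity_pct=sens,
            ppv_pct=ppv,
        ))
    return out


# ---------------------------------------------------------------------------
# Pipeline driver

def run_pipeline(
    dataset: StudyDataset,
    cutoffs: Sequence[int | Literal["full"]] = (40, "full"),
    comparisons: Sequence[tuple[str, str]] = (),
    out_dir: str | Path | None = None,
    curve_max_rank: int | None = 100,
    comparison_cutoff: int = 40,
) -> dict:
    """Run the whole evaluation: metrics, summaries, comparisons, curves.

    Returns a bundle with per-search :class:`MetricResult` rows, one
    :class:`StrategySummary` per strategy and cutoff, one
    :class:`ComparisonReport` per requested strategy pair (on the
    ``comparison_cutoff``), and per-strategy median cumulative
    sensitivity curves. When ``out_dir`` is given the bundle is also
    written there as CSV/JSON files.
    """
    metrics: dict[tuple[str, int | str], list[MetricResult]] = {}
    summaries: list[dict] = []
    for sid in dataset.strategy_ids:
        outputs = dataset.outputs_for(sid)
        sizes = [len(o) for o in outputs]
        for cutoff in cutoffs:
            ms = [evaluate(o, dataset.gold_for(o.question_id), cutoff)
                  for o in outputs]
            metrics[(sid, cutoff)] = ms
            summaries.append(
                {"cutoff": cutoff,
                 "summary": summarize_strategy(sid, ms, output_sizes=sizes)}
            )
            logger.info("strategy %s cutoff %s: %d searches evaluated",
                        sid, cutoff, len(ms))
    reports: list[ComparisonReport] = []
    for a, b in comparisons:
        if (a, comparison_cutoff) not in metrics:
            raise ValueError(
                f"comparison cutoff {comparison_cutoff} must be one of the "
                f"evaluated cutoffs {tuple(cutoffs)}"
            )
        reports.append(compare_strategies(metrics[(a, comparison_cutoff)],
                                          metrics[(b, comparison_cutoff)]))
        logger.info("compared %s vs %s", a, b)
    curves: dict[str, list[float]] = {}
    if curve_max_rank:
        golds = list(dataset.golds)
        for sid in dataset.strategy_ids:
            curves[sid] = median_cumulative_curve(
                dataset.outputs_for(sid), golds, curve_max_rank
            )
    bundle = {
        "metrics": [m for ms in metrics.values() for m in ms],
        "summaries": summaries,
        "comparisons": reports,
        "curves": curves,
    }
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_metrics_csv(bundle["metrics"], out_dir / "metrics.csv")
    pd.DataFrame(
        [{"cutoff": s["cutoff"], **asdict(s["summary"])}
         for s in bundle["summaries"]]
    ).to_csv(out_dir / "strategy_summaries.csv", index=False)
    with open(out_dir / "comparisons.json", "w", encoding="utf-8") as fh:
        json.dump([asdict(r) for r in bundle["comparisons"]], fh, indent=2)
    curve_rows = [
        {"strategy_id": sid, "rank": k + 1, "median_sensitivity_pct": v}
        for sid, curve in bundle["curves"].items()
        for k, v in enumerate(curve)
    ]
    if curve_rows:
        pd.DataFrame(curve_rows).to_csv(out_dir / "median_curves.csv",
                                        index=False)
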