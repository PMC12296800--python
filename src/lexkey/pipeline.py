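"""End-to-end orchestration: ingest -> filter -> preprocess -> keyness -> report.

`run_pipeline` wires the stages together with per-stage logging and error
attribution; `render_report` turns a scored run into the ranked top-k tables
and a plot-data file for a two-panel ranked bar chart.  Given identical
inputs and configuration the results files are byte-identical across runs
(wall-clock time appears nowhere in them).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import corpus_io, keyness, preprocess
from .errors import PipelineStageError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    narratives_path: Path
    tokens_path: Path
    reference_freq_path: Path
    stopwords_path: Path
    out_dir: Path
    alpha: float = 0.01
    tail_convention: str = "one-sided"
    top_k: int = 50
    #: apply the stopword lemma list to the reference frequency list as well
    filter_reference_stopwords: bool = True
    near_duplicate_threshold: float | None = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.top_k < 1:
            raise ValueError(f"top_k must be >= 1, got {self.top_k}")
        for name in ("narratives_path", "tokens_path", "reference_freq_path",
                     "stopwords_path", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))


@dataclass
class PipelineResult:
    run: keyness.KeynessRun
    target_keys: list[keyness.KeynessResult]
    reference_keys: list[keyness.KeynessResult]
    stage_log: dict[str, dict]
    artifacts: dict[str, Path]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full keyness analysis; any stage error aborts, named.

    Stages: ingest both corpus formats; apply the sample trimming rules and
    drop tokens of excluded narratives; remove stopwords and count lemmas;
    read (and optionally stopword-filter) the reference frequency list;
    merge; score; threshold (Bonferroni over the number of merged lemmas);
    select and write reports.
    """
    stage_log: dict[str, dict] = {}
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    # -- ingest ------------------------------------------------------------
    try:
        quarantine: list = []
        pairs = corpus_io.read_narrative_table(
            config.narratives_path, quarantine=quarantine
        )
        counters: dict[str, int] = {}
        tokens = list(corpus_io.read_token_table(config.tokens_path, counters))
    except Exception as exc:
        raise PipelineStageError("ingest", exc) from exc
    stage_log["ingest"] = {
        "narratives_read": len(pairs),
        "rows_quarantined": len(quarantine),
        "tokens_read": len(tokens),
        **counters,
    }
    logger.info("ingest: %s", stage_log["ingest"])

    # -- filter ------------------------------------------------------------
    try:
        retained, exclusions = corpus_io.filter_participants(
            pairs, near_duplicate_threshold=config.near_duplicate_threshold
        )
        kept_ids = {record.doc_id for record, _ in retained}
        tokens = [t for t in tokens if t.doc_id in kept_ids]
        corpus_io.write_exclusion_log(exclusions, out / "exclusions.jsonl")
    except Exception as exc:
        raise PipelineStageError("filter", exc) from exc
    stage_log["filter"] = {
        "retained": len(retained),
        "excluded": len(exclusions),
        "tokens_after_filter": len(tokens),
    }
    logger.info("filter: %s", stage_log["filter"])

    # -- preprocess --------------------------------------------------------
    try:
        stopwords = preprocess.load_stopwords(config.stopwords_path)
        content_tokens = preprocess.remove_stopwords(tokens, stopwords)
        target_table = preprocess.count_lemmas(content_tokens, "target")
        reference_table = preprocess.read_frequency_list(
            config.reference_freq_path, "reference"
        )
        if config.filter_reference_stopwords:
            reference_table = preprocess.filter_frequency_table(
                reference_table, stopwords
            )
    except Exception as exc:
        raise PipelineStageError("preprocess", exc) from exc
    stage_log["preprocess"] = {
        "stopword_lemmas": len(stopwords),
        "tokens_after_stopwords": len(content_tokens),
        "target_lemmas": target_table.n_lemmas,
        "target_tokens": target_table.total_tokens,
        "reference_lemmas": reference_table.n_lemmas,
        "reference_tokens": reference_table.total_tokens,
    }
    logger.info("preprocess: %s", stage_log["preprocess"])

    # -- merge -------------------------------------------------------------
    try:
        combined = preprocess.merge_tables(target_table, reference_table)
    except Exception as exc:
        raise PipelineStageError("merge", exc) from exc
    stage_log["merge"] = {"combined_lemmas": combined.n_rows}
    logger.info("merge: %s", stage_log["merge"])

    # -- keyness -----------------------------------------------------------
    try:
        results = keyness.compute_keyness(combined)
        threshold = keyness.bonferroni_threshold(
            config.alpha, combined.n_rows, config.tail_convention
        )
        target_keys, reference_keys = keyness.select_keys(results, threshold)
        run = keyness.KeynessRun(
            results=results,
            threshold_z=threshold,
            alpha=config.alpha,
            m=combined.n_rows,
            tail_convention=config.tail_convention,
        )
    except Exception as exc:
        raise PipelineStageError("keyness", exc) from exc
    stage_log["keyness"] = {
        "threshold_z": threshold,
        "target_keys": len(target_keys),
        "reference_keys": len(reference_keys),
    }
    logger.info("keyness: %s", stage_log["keyness"])

    # -- report ------------------------------------------------------------
    try:
        artifacts = run.save(out)
        report_text, plot_data = render_report(
            run, config.top_k, target_keys, reference_keys
        )
        (out / "report.txt").write_text(report_text, encoding="utf-8")
        plot_data.to_csv(out / "plot_data.tsv", sep="\t", index=False)
        (out / "stage_log.json").write_text(
            json.dumps(stage_log, indent=2, default=str) + "\n",
            encoding="utf-8",
        )
        (out / "run_config.json").write_text(
            json.dumps(
                {k: str(v) if isinstance(v, Path) else v
                 for k, v in dataclasses.asdict(config).items()},
                indent=2,
            ) + "\n",
            encoding="utf-8",
        )
        artifacts.update({
            "report": out / "report.txt",
            "plot_data": out / "plot_data.tsv",
            "stage_log": out / "stage_log.json",
            "exclusions": out / "exclusions.jsonl",
        })
    except Exception as exc:
        raise PipelineStageError("report", exc) from exc

    return PipelineResult(
        run=run,
        target_keys=target_keys,
        reference_keys=reference_keys,
        stage_log=stage_log,
        artifacts=artifacts,
    )


def render_report(
    run: keyness.KeynessRun,
    k: int,
    target_keys: list[keyness.KeynessResult] | None = None,
    reference_keys: list[keyness.KeynessResult] | None = None,
    gloss_map: dict[str, str] | None = None,
) -> tuple[str, pd.DataFrame]:
    """Human-readable top-k report plus plot data (panel, rank, lemma, |z|)."""
    if target_keys is None or reference_keys is None:
        target_keys, reference_keys = keyness.select_keys(
            run.results, run.threshold_z
        )
    lines = [
        "Keyness report",
        f"  tests (m): {run.m}",
        f"  family-wise alpha: {run.alpha} ({run.tail_convention})",
        f"  |z| threshold: {run.threshold_z:.4f}",
        f"  target-diagnostic keys: {len(target_keys)}",
        f"  reference-diagnostic keys: {len(reference_keys)}",
        "",
    ]
    frames = []
    for panel, keys in (("target", target_keys),
                        ("reference", reference_keys)):
        lines.append(f"Top {min(k, len(keys))} {panel}-diagnostic lemmas:")
        if not keys:
            lines.append("  (panel empty: no significant keys)")
        table = keyness.top_k_table(keys, k, gloss_map) if keys else None
        if table is not None:
            for row in table.itertuples(index=False):
                gloss = f" ({row.gloss})" if row.gloss else ""
                lines.append(
                    f"  {row.rank:>3d}. {row.lemma}{gloss}  |z|={row.abs_z:.2f}"
                )
            table = table.assign(panel=panel)
            frames.append(table)
        lines.append("")
    plot_data = (
        pd.concat(frames, ignore_index=True)[
            ["panel", "rank", "lemma", "abs_z"]
        ]
        if frames
        else pd.DataFrame(columns=["panel", "rank", "lemma", "abs_z"])
    )
    return "\n".join(lines), plot_data
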