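"""Reproducible end-to-end pipeline with file artifacts and a manifest.

Ties the stages together for shell use: simulate (optional) -> score ->
diary summaries -> concordance table.  Every run writes plain CSV/YAML
artifacts plus a manifest recording the package version, seed and all
parameter values, so the manifest alone reproduces any output.  No stage
mutates its inputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .concordance import MEASURES, compare_sources
from .diary import diary_to_summary, write_diary_csv
from .errors import ValidationError
from .scoring import (
    DEFAULT_MIN_AWAKENING_MIN,
    DEFAULT_SUSTAINED_EPOCHS,
    ClassifierWeights,
    classify_series,
)
from .synthdata import (
    CohortConfig,
    DiaryNoiseModel,
    MovementModel,
    generate_truth,
    render_activity,
    render_diary,
    score_cohort,
)
from .timeutil import minutes_to_clock

log = logging.getLogger("actisleep")


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    output_dir: Path
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    movement: MovementModel = field(default_factory=MovementModel)
    diary_noise: DiaryNoiseModel = field(default_factory=DiaryNoiseModel)
    weights: ClassifierWeights = field(default_factory=ClassifierWeights)
    sustained_epochs: int = DEFAULT_SUSTAINED_EPOCHS
    min_awakening_min: int = DEFAULT_MIN_AWAKENING_MIN
    stratum: str = "all"
    correlation_pooling: str = "nights"

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.sustained_epochs < 1 or self.min_awakening_min < 2:
            raise ValidationError("scoring thresholds out of range")
        if self.stratum not in ("all", "weekday", "weekend"):
            raise ValidationError(f"unknown stratum {self.stratum!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, sub_cls in (
            ("cohort", CohortConfig),
            ("movement", MovementModel),
            ("diary_noise", DiaryNoiseModel),
            ("weights", ClassifierWeights),
        ):
            if key in raw:
                sub = dict(raw.pop(key))
                if key == "cohort" and "start_date" in sub:
                    sub["start_date"] = date.fromisoformat(str(sub["start_date"]))
                kwargs[key] = sub_cls(**sub)
        kwargs.update(raw)
        return cls(**kwargs)

    def manifest(self) -> dict:
        def plain(obj):
            d = dataclasses.asdict(obj)
            return {k: (v.isoformat() if isinstance(v, date) else v) for k, v in d.items()}

        return {
            "actisleep_version": __version__,
            "seed": self.seed,
            "cohort": plain(self.cohort),
            "movement": plain(self.movement),
            "diary_noise": plain(self.diary_noise),
            "weights": plain(self.weights),
            "sustained_epochs": self.sustained_epochs,
            "min_awakening_min": self.min_awakening_min,
            "stratum": self.stratum,
            "correlation_pooling": self.correlation_pooling,
        }


def summaries_to_frame(summaries) -> pd.DataFrame:
    rows = [
        {
            "child_id": s.child_id,
            "night_date": s.night_date.isoformat(),
            "source": s.source,
            "month": s.month,
            "bedtime": s.bedtime.isoformat(),
            "wake_up": s.wake_up.isoformat(),
            "nighttime_sleep_min": s.nighttime_sleep,
            "awakenings": s.awakenings,
            "is_weekend": s.is_weekend,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


def concordance_table(results) -> pd.DataFrame:
    """Shape the concordance results like a published comparison table."""
    rows = []
    for (measure, month), r in sorted(results.items()):
        clock = measure in ("bedtime", "wake_up")
        fmt = (lambda v: minutes_to_clock(v)) if clock else (lambda v: f"{v:.2f}")
        rows.append(
            {
                "measure": measure,
                "month": month,
                "n_participants": r.n,
                "actigraphy_mean": fmt(r.mean_actigraphy),
                "entered_mean": fmt(r.mean_diary),
                "t_statistic": round(r.t_statistic, 2),
                "df": r.df,
                "p_value": round(r.p_value, 4),
                "pearson_r": round(r.pearson_r, 3),
                "r_squared": round(r.r_squared, 3),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Simulate, score, summarize and compare; return the artifact paths.

    Deterministic given config + seed; artifacts are per-epoch scores,
    per-night summaries from both sources, the concordance table, and a
    YAML manifest.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    log.info("simulating cohort (seed=%d)", seed)
    truths = generate_truth(config.cohort, seed)
    series = render_activity(truths, config.movement, seed)
    records = render_diary(truths, config.diary_noise, seed)

    log.info("scoring %d child-nights", len(series))
    epoch_frames = []
    for s in series:
        sw = classify_series(s, config.weights)
        epoch_frames.append(
            pd.DataFrame(
                {
                    "child_id": s.child_id,
                    "epoch_start": [t.isoformat() for t in s.epoch_starts()],
                    "intensity": s.intensities,
                    "z": sw.z_scores.round(6),
                    "label": [
                        {0: "sleep", 1: "wake", -1: "undefined"}[int(v)]
                        for v in sw.labels
                    ],
                }
            )
        )
    act_summaries, n_failed = score_cohort(
        truths,
        series,
        weights=config.weights,
        sustained_epochs=config.sustained_epochs,
        min_awakening_min=config.min_awakening_min,
    )
    if n_failed:
        log.warning("%d night(s) had no detectable sleep and were skipped", n_failed)

    month_of = {(t.child_id, t.night_date): t.month for t in truths}
    diary_summaries = [
        diary_to_summary(r, month=month_of[(r.child_id, r.night_date)])
        for r in records
    ]
    all_summaries = act_summaries + diary_summaries
    months = sorted({s.month for s in all_summaries})
    results = {
        (measure, month): compare_sources(
            all_summaries,
            measure,
            month=month,
            stratum=config.stratum,
            correlation_pooling=config.correlation_pooling,
        )
        for measure in MEASURES
        for month in months
    }

    paths = {
        "epochs": out / "epochs.csv",
        "summaries": out / "night_summaries.csv",
        "diary": out / "diary.csv",
        "comparison": out / "comparison.csv",
        "manifest": out / "manifest.yaml",
    }
    pd.concat(epoch_frames, ignore_index=True).to_csv(paths["epochs"], index=False)
    summaries_to_frame(all_summaries).to_csv(paths["summaries"], index=False)
    write_diary_csv(records, paths["diary"])
    concordance_table(results).to_csv(paths["comparison"], index=False)
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(config.manifest(), fh, sort_keys=False)
    log.info("wrote %d artifacts to %s", len(paths), out)
    return paths
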