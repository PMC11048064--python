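"""End-to-end pipeline: trials in, features + statistics + manifest out.

A trial is segmented according to its metadata's test (TUG, STS or 10MWT)
and reduced to its feature set; all trials' features are stacked into a
long-format table; each feature is analysed with the mixed ANOVA and the
stroke-vs-control percent contrasts. Trials whose automatic segmentation
fails are excluded from the statistics but always recorded in the run
manifest for manual review — mirroring the visual-confirmation step of the
reference protocol.
"""

from __future__ import annotations

import datetime as _dt
import logging
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import __version__
from .config import PipelineConfig, config_hash
from .errors import MobisegError, PipelineError
from .gait import detect_gait_events, extract_gait_features
from .io import (
    RunManifest,
    read_recording,
    write_feature_table,
)
from .preprocess import KinematicRecording, lowpass_filter
from .stats import anova_by_feature, cell_means, group_contrast_percent
from .sts import detect_sts_cycles, extract_sts_features
from .synth import default_cohort_spec, draw_cohort_params, trial_from_row
from .tug import detect_tug_events, extract_tug_features

__all__ = ["extract_trial_features", "run_pipeline"]

logger = logging.getLogger("mobiseg")


def extract_trial_features(
    rec: KinematicRecording, config: PipelineConfig
) -> dict[str, float]:
    """Segment one trial and return its feature dict (name -> value)."""
    test = rec.meta.test
    spec = config.filter_spec()
    if test == "TUG":
        events = detect_tug_events(rec, config.tug_config())
        feats = extract_tug_features(rec, events, config.tug_config())
        logger.info(
            "TUG %s/%s: events %s", rec.meta.subject_id, rec.meta.condition,
            [round(t, 2) for t in events.as_tuple()],
        )
        return feats.as_dict()
    if test == "STS":
        cfg = config.sts_config()
        thigh_l = lowpass_filter(rec.gyr_magnitude("thigh_L"), spec, rec.fs)
        thigh_r = lowpass_filter(rec.gyr_magnitude("thigh_R"), spec, rec.fs)
        cycles = detect_sts_cycles(thigh_l, thigh_r, rec.fs, cfg)
        feats = extract_sts_features(rec, cycles, cfg)
        return feats.as_dict()
    if test == "10MWT":
        cfg = config.gait_config()
        shank_l = lowpass_filter(rec.acc_magnitude("shank_L"), spec, rec.fs)
        shank_r = lowpass_filter(rec.acc_magnitude("shank_R"), spec, rec.fs)
        events = detect_gait_events(shank_l, shank_r, rec.fs, cfg)
        walk_time = events.last - events.first
        feats = extract_gait_features(events, walk_time, config.distance_m)
        return feats.as_dict()
    raise PipelineError(f"unknown test {test!r}")


def _iter_input_trials(
    input_dir: Path,
) -> Iterable[tuple[str, "KinematicRecording | Exception"]]:
    paths = sorted(input_dir.glob("*.csv"))
    for path in paths:
        if path.name.endswith(".meta.csv") or path.name == "ground_truth.csv":
            continue
        try:
            yield path.stem, read_recording(path)
        except MobisegError as exc:
            yield path.stem, exc


def run_pipeline(
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, RunManifest]:
    """Run the full pipeline described by ``config``.

    Trials come either from ``config.input_dir`` (recording CSVs with YAML
    sidecars) or, when ``config.cohort`` is set, from the built-in simulated
    cohort. Returns ``(feature_table, anova_table, manifest)`` and — when
    ``config.out_dir`` is set — writes ``features.csv``, ``anova.csv``,
    ``contrasts.csv`` and ``manifest.json`` there. Output data files are
    byte-identical across runs with identical config, inputs and seed.
    """
    manifest = RunManifest(
        config_hash=config_hash(config),
        version=__version__,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
    )

    rows: list[dict] = []

    def _process(trial_id: str, rec_or_exc) -> None:
        if isinstance(rec_or_exc, Exception):
            manifest.add(trial_id, "error", str(rec_or_exc))
            logger.warning("%s: unreadable (%s)", trial_id, rec_or_exc)
            return
        rec = rec_or_exc
        try:
            feats = extract_trial_features(rec, config)
        except MobisegError as exc:
            manifest.add(trial_id, "segmentation-failed", str(exc))
            logger.warning("%s: segmentation failed (%s)", trial_id, exc)
            return
        manifest.add(trial_id, "ok")
        for name, value in feats.items():
            rows.append(
                {
                    "subject_id": rec.meta.subject_id,
                    "group": rec.meta.group,
                    "condition": rec.meta.condition,
                    "test": rec.meta.test,
                    "feature": f"{rec.meta.test}:{name}",
                    "value": value,
                }
            )

    if config.input_dir is not None:
        for trial_id, item in _iter_input_trials(Path(config.input_dir)):
            _process(trial_id, item)
    elif config.cohort is not None:
        spec = default_cohort_spec(
            n_control=config.cohort.n_control,
            n_stroke=config.cohort.n_stroke,
            seed=config.seed,
            tests=tuple(config.cohort.tests),
            rms_scale=config.cohort.rms_scale,
        )
        table = draw_cohort_params(spec)
        for _, row in table.iterrows():
            trial_id = f"{row.subject_id}_{row.condition}_{row.test}"
            try:
                rec, _truth = trial_from_row(row)
            except MobisegError as exc:
                _process(trial_id, exc)
                continue
            _process(trial_id, rec)
    else:
        raise PipelineError("config must set either input_dir or cohort")

    if not rows:
        raise PipelineError("all trials failed; nothing to analyse")

    features = pd.DataFrame(rows).sort_values(
        ["test", "feature", "group", "subject_id", "condition"], kind="stable"
    ).reset_index(drop=True)

    # Drop subjects with incomplete condition pairs per feature (kept in the
    # feature table, excluded from the ANOVA) by letting the per-feature
    # model validate; anova_by_feature records per-feature errors instead of
    # raising.
    complete = _complete_pairs(features)
    anova = anova_by_feature(complete)

    contrasts = _contrast_table(complete)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_feature_table(features, out / "features.csv")
        anova.to_csv(out / "anova.csv", index=False, float_format="%.6g")
        contrasts.to_csv(out / "contrasts.csv", index=False, float_format="%.6g")
        manifest.write(out / "manifest.json")

    return features, anova, manifest


def _complete_pairs(features: pd.DataFrame) -> pd.DataFrame:
    """Keep only subject x feature blocks that have both conditions."""
    counts = features.groupby(["feature", "subject_id"])["condition"].transform("nunique")
    return features[counts == 2]


def _contrast_table(features: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for feature in sorted(features["feature"].unique()):
        means = cell_means(features, feature)
        for averaging in ("pooled_over_CL", "ST_only", "DT_only"):
            try:
                c = group_contrast_percent(means, averaging, feature_name=feature)
            except MobisegError:
                continue
            rows.append(
                {
                    "feature": feature,
                    "averaging": averaging,
                    "percent_difference": c.percent_difference,
                    "direction": c.direction,
                }
            )
    return pd.DataFrame(rows)
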