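"""End-to-end orchestration: simulate -> preprocess -> features -> effects ->
classify -> bootstrap -> report.

All randomness flows from one master seed through named substreams
(simulation / hold-out / bootstrap) so stages can be re-run independently
and a rerun with the same configuration reproduces every number.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .classify import CLASSIFIER_ROSTER, EvalSummary, evaluate_holdout, evaluate_loo
from .effects import effect_table
from .mg import extract_mg_features
from .pattern import BootstrapPatternResult, bootstrap_pattern_test
from .preprocess import preprocess_mg_trial
from .records import CohortDataset, FEATURE_NAMES, ParticipantRecord
from .synthetic import SyntheticConfig, generate_cohort_dataset, study_config
from .tmt import extract_tmt_features

logger = logging.getLogger(__name__)

META_COLUMNS = ("id", "cohort", "caarms")


@dataclass
class PipelineConfig:
    """Settings for a full run."""

    synthetic: SyntheticConfig = field(default_factory=study_config)
    output_dir: Optional[Path] = None
    holdout_folds: int = 1000
    per_class_holdout: int = 8
    bootstrap_splits: int = 10_000
    include_first_session: bool = False
    classifiers: tuple[str, ...] = tuple(CLASSIFIER_ROSTER)
    seed: int = 0

    def substream(self, name: str) -> int:
        """Named integer substream of the master seed (stays below 2**31)."""
        import hashlib

        tag = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
        ss = np.random.SeedSequence([self.seed, tag])
        return int(ss.generate_state(1)[0] % (2**31))


def participant_features(
    record: ParticipantRecord, include_first_session: bool = False
) -> dict[str, float]:
    """The 18 named features for one participant (NaN where unavailable)."""
    prepared = [preprocess_mg_trial(t) for t in record.mg_trials]
    feats = extract_tmt_features(record.tmt_logs)
    feats.update(extract_mg_features(prepared, include_first_session=include_first_session))
    return feats


def cohort_features(
    dataset: CohortDataset, include_first_session: bool = False
) -> pd.DataFrame:
    """Feature matrix: one row per participant, id/cohort/caarms + 18 columns."""
    rows = []
    for p in dataset.participants:
        feats = participant_features(p, include_first_session=include_first_session)
        rows.append({"id": p.id, "cohort": p.cohort, "caarms": p.caarms, **feats})
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + list(FEATURE_NAMES))


def complete_rows(features: pd.DataFrame) -> pd.DataFrame:
    """Drop participants with any missing feature, logging who and why."""
    bad = features[list(FEATURE_NAMES)].isna().any(axis=1)
    for pid in features.loc[bad, "id"]:
        logger.warning("excluding participant %s: incomplete feature vector", pid)
    return features.loc[~bad].reset_index(drop=True)


@dataclass
class RunReport:
    """All result tables of one pipeline run."""

    features: pd.DataFrame
    effect_tables: dict[str, pd.DataFrame]
    classification: pd.DataFrame
    evaluations: dict[tuple[str, str, str], EvalSummary]
    bootstrap: BootstrapPatternResult
    metadata: dict


def _summary_row(name: str, protocol: str, labelling: str, s: EvalSummary) -> dict:
    row = {"classifier": name, "protocol": protocol, "labels": labelling}
    if s.protocol == "holdout":
        for m, v in s.medians.items():
            row[m] = v
            row[f"{m}_lo"] = s.centiles_low[m]
            row[f"{m}_hi"] = s.centiles_high[m]
    else:
        cm = s.pooled_confusion
        row.update({"TN": cm.tn, "FP": cm.fp, "TP": cm.tp, "FN": cm.fn})
        row.update(s.pooled_metrics)
    return row


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and assemble the report tables."""
    logger.info("stage: simulate (seed %d)", config.synthetic.seed)
    dataset = generate_cohort_dataset(config.synthetic)
    logger.info("stage: preprocess + features (%d participants)", len(dataset.participants))
    features = complete_rows(
        cohort_features(dataset, include_first_session=config.include_first_session))

    cc = features[features["cohort"] == "CC"]
    su = features[features["cohort"] == "SU"]
    su0 = su[su["caarms"] == 0]
    su_pos = su[su["caarms"] > 0]

    logger.info("stage: effect tables")
    table_c0 = effect_table(cc, su0)
    tables = {
        "CC_vs_SU": effect_table(cc, su),
        "CC_vs_SU_caarms0": table_c0,
        "CC_vs_SU_caarms_pos": effect_table(cc, su_pos, reference_contrast=table_c0),
    }

    logger.info("stage: classification (%d variants)", len(config.classifiers))
    evaluations: dict[tuple[str, str, str], EvalSummary] = {}
    rows = []
    y_cohort = (features["cohort"] == "SU").astype(int).to_numpy()
    ho_seed = config.substream("holdout")
    for name in config.classifiers:
        spec = CLASSIFIER_ROSTER[name]
        ho = evaluate_holdout(features, y_cohort, spec,
                              n_folds=config.holdout_folds,
                              per_class_holdout=config.per_class_holdout,
                              seed=ho_seed)
        evaluations[(name, "holdout", "cohort")] = ho
        rows.append(_summary_row(name, "holdout", "cohort", ho))
        loo = evaluate_loo(features, y_cohort, spec)
        evaluations[(name, "loo", "cohort")] = loo
        rows.append(_summary_row(name, "loo", "cohort", loo))
        y_caarms = (su["caarms"] > 0).astype(int).to_numpy()
        loo_c = evaluate_loo(su.reset_index(drop=True), y_caarms, spec)
        evaluations[(name, "loo", "caarms")] = loo_c
        rows.append(_summary_row(name, "loo", "caarms", loo_c))
    classification = pd.DataFrame(rows)

    logger.info("stage: bootstrap pattern test (%d splits)", config.bootstrap_splits)
    bootstrap = bootstrap_pattern_test(
        cc, su, (su["caarms"] > 0).to_numpy(),
        n=config.bootstrap_splits, seed=config.substream("bootstrap"))

    metadata = {
        "seed": config.seed,
        "synthetic_config_hash": config.synthetic.hash(),
        "holdout_folds": config.holdout_folds,
        "bootstrap_splits": config.bootstrap_splits,
    }
    report = RunReport(features=features, effect_tables=tables,
                       classification=classification, evaluations=evaluations,
                       bootstrap=bootstrap, metadata=metadata)
    if config.output_dir is not None:
        write_report(report, config.output_dir)
    return report


def write_report(report: RunReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.features.to_csv(out / "features.csv", index=False)
    for name, table in report.effect_tables.items():
        table.to_csv(out / f"effects_{name}.csv", index=False)
    report.classification.to_csv(out / "classification.csv", index=False)
    obs = report.bootstrap.observed
    (out / "bootstrap.json").write_text(json.dumps({
        "p_value": report.bootstrap.p_value,
        "n_splits": report.bootstrap.n_splits,
        "observed_statistic": obs.statistic,
        "observed_pattern": {"tmt_low": obs.tmt_low, "solo_high": obs.solo_high,
                             "lf_high": obs.lf_high},
        "median_changes": {"TMT": obs.median_tmt, "Solo": obs.median_solo,
                           "LF": obs.median_lf, "overall": obs.overall_median},
    }, indent=1))
    (out / "run_metadata.json").write_text(json.dumps(report.metadata, indent=1))
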