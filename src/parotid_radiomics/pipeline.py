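"""One-command pipeline: simulate -> extract -> select -> score -> evaluate.

Stage order is fixed: cohort generation (or manifest loading),
preprocessing + filtering + extraction, ICC stability gate (on the
re-segmented subset, before splitting), stratified train/test split,
univariate screen and Spearman pruning on the training rows only,
LASSO-CV score fit, and the ROC readout on both splits. Every artifact
carries the configuration hash, and a run is fully reconstructible from
its log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort import CohortSpec, EffectProfile, generate_cohort
from .evaluation import diagnostic_metrics, optimal_cutoff, stratified_split
from .features import ExtractionConfig, FEATURES_PER_SEQUENCE, extract_table
from .filters import FilterBankConfig
from .io import load_cohort_lesions, write_cohort, write_json
from .preprocess import PreprocessConfig
from .selection import SelectionConfig, run_selection_cascade, score_table

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("parotid_radiomics")


def _dataclass_from_dict(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) under {path}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class PipelineConfig:
    simulate: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    filters: FilterBankConfig = field(default_factory=FilterBankConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    seed: int = 0
    manifest: str | None = None  # load an existing cohort instead of simulating
    save_cohort: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key, sub_cls in (
            ("simulate", CohortSpec),
            ("preprocess", PreprocessConfig),
            ("filters", FilterBankConfig),
            ("selection", SelectionConfig),
        ):
            if key in data and isinstance(data[key], dict):
                sub = dict(data[key])
                if key == "simulate" and isinstance(sub.get("effect_profile"), dict):
                    sub["effect_profile"] = _dataclass_from_dict(
                        EffectProfile, sub["effect_profile"], "simulate.effect_profile"
                    )
                data[key] = _dataclass_from_dict(sub_cls, sub, key)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline and write all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    t0 = time.time()
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("config hash %s; seed %d", cfg_hash, config.seed)
        (out / "config.yaml").write_text(
            yaml.safe_dump(config.to_dict(), sort_keys=True)
        )

        if config.manifest:
            lesions = load_cohort_lesions(config.manifest)
            log.info("loaded %d lesions from %s", len(lesions), config.manifest)
        else:
            spec = dataclasses.replace(config.simulate, seed=config.simulate.seed or config.seed)
            lesions = generate_cohort(spec)
            log.info("simulated %d lesions (seed %d)", len(lesions), spec.seed)
            if config.save_cohort:
                write_cohort(lesions, out / "cohort")

        ext_cfg = ExtractionConfig(preprocess=config.preprocess, filters=config.filters)
        features = extract_table(lesions, ext_cfg)
        n_per_seq = sum(c.startswith("T2|") for c in features.columns)
        log.info("extracted %d features per sequence (%d lesions)", n_per_seq, len(features))
        assert n_per_seq == FEATURES_PER_SEQUENCE
        features.to_csv(out / "features.csv")

        reseg = [l for l in lesions if l.mask_reseg is not None]
        seg1 = seg2 = None
        if reseg:
            seg1 = features.loc[[l.lesion_id for l in reseg]]
            seg2 = extract_table(reseg, ext_cfg, use_reseg_mask=True)
            seg2.to_csv(out / "features_reseg.csv")
            log.info("ICC subset: %d lesions", len(reseg))

        sel_cfg = dataclasses.replace(config.selection, seed=config.selection.seed or config.seed)
        labels = features["label"].to_numpy()
        train_idx, test_idx = stratified_split(labels, seed=config.seed)
        train = features.iloc[train_idx]
        test = features.iloc[test_idx]
        log.info(
            "split: train %d (%s), test %d",
            len(train), train["label"].value_counts().to_dict(), len(test),
        )

        report = run_selection_cascade(train, seg1, seg2, sel_cfg)
        model = report["model"]
        sel_json = {
            "config_hash": cfg_hash,
            "n_input": report["n_input"],
            "stage_counts": {
                s: len(report[f"stage_{s}"]) for s in ("icc", "screen", "spearman", "lasso")
            },
            "stages": {s: report[f"stage_{s}"] for s in ("screen", "spearman", "lasso")},
            "eliminations": report["eliminations"],
            "lambda_path": report["lambda_path"].to_dict(orient="list"),
            "model": model.to_dict(),
        }
        if "icc" in report:
            sel_json["icc"] = report["icc"].to_dict()
        write_json(sel_json, out / "selection_report.json")
        write_json({"config_hash": cfg_hash} | model.to_dict(), out / "score_model.json")

        train_scores = score_table(model, train)
        test_scores = score_table(model, test)
        cutoff, direction = optimal_cutoff(train_scores, train["label"])
        results = {"config_hash": cfg_hash, "features_per_sequence": n_per_seq}
        for name, scores, tbl in (
            ("training", train_scores, train),
            ("testing", test_scores, test),
        ):
            rep = diagnostic_metrics(scores, tbl["label"], cutoff, direction)
            results[name] = rep.to_dict()
            log.info("%s AUC %.3f (cutoff %.3f)", name, rep.auc, cutoff)
        write_json(results, out / "diagnostic_report.json")
        pd.DataFrame(
            {
                "lesion_id": list(train.index) + list(test.index),
                "split": ["train"] * len(train) + ["test"] * len(test),
                "label": list(train["label"]) + list(test["label"]),
                "score": list(train_scores) + list(test_scores),
            }
        ).to_csv(out / "scores.csv", index=False)
        log.info("done in %.1f s", time.time() - t0)
        return results
    finally:
        log.removeHandler(handler)
        handler.close()
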