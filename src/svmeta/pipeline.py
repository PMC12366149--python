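"""End-to-end orchestration: filter -> merge -> features -> score -> report.

These functions are the library behind the command-line interface: they
take parsed calls or VCF paths, run the type-specific pipelines (DEL and
INS are merged, featurized and scored independently), and produce the
probability-ranked consensus VCF, model artifacts and benchmark reports.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .bench import (MatchParams, compute_metrics, decile_report,
                    match_to_truth, roc_auc)
from .dialects import DEL_CALLERS, INS_CALLERS, DialectRegistry, default_registry
from .features import (FeatureMatrix, basic_feature_matrix,
                       build_feature_matrix, correlation_select,
                       default_feature_registry)
from .filtering import filter_sv_calls
from .merge import MergeParams, merge_calls
from .model import (TrainedMetaModel, TrainingConfig, grid_search_train,
                    predict_probabilities, prune_zero_importance)
from .types import ConsensusCall, FilterConfig, SequencingStats, SVCall, SVType
from .vcf_io import parse_caller_vcf, parse_sv_vcf, write_consensus_vcf

CALLERS_BY_SVTYPE = {SVType.DEL: DEL_CALLERS, SVType.INS: INS_CALLERS}


def load_calls(
    vcf_paths: dict[str, str],
    registry: Optional[DialectRegistry] = None,
    filter_config: FilterConfig = FilterConfig(),
) -> dict[str, list[SVCall]]:
    """Parse and filter one VCF per caller."""
    registry = registry or default_registry()
    out = {}
    for caller, path in vcf_paths.items():
        calls = parse_caller_vcf(path, registry.get(caller), registry)
        out[caller] = filter_sv_calls(calls, filter_config)
    return out


def _svtype_subset(
    calls_by_caller: dict[str, list[SVCall]], svtype: SVType
) -> dict[str, list[SVCall]]:
    callers = CALLERS_BY_SVTYPE[svtype]
    return {
        caller: [c for c in calls_by_caller.get(caller, []) if c.svtype is svtype]
        for caller in callers
        if caller in calls_by_caller
    }


@dataclass
class TrainingRun:
    """Everything produced while training one SV type's models."""

    svtype: SVType
    consensus: list[ConsensusCall]
    labels: list[bool]
    fm_matrix: FeatureMatrix
    bm_matrix: FeatureMatrix
    fm_model: TrainedMetaModel
    bm_model: TrainedMetaModel
    selected_features: list[str]

    def report(self) -> dict:
        return {
            "svtype": self.svtype.value,
            "n_consensus": len(self.consensus),
            "n_tp_labels": int(sum(self.labels)),
            "initial_features": len(self.fm_matrix.feature_names),
            "selected_features": len(self.selected_features),
            "final_features": len(self.fm_model.feature_names),
            "fm_hyperparameters": self.fm_model.hyperparameters,
            "fm_cv_auc": self.fm_model.cv_auc,
            "bm_cv_auc": self.bm_model.cv_auc,
            "fm_importances": self.fm_model.importances,
        }


def train_for_svtype(
    calls_by_caller: dict[str, list[SVCall]],
    truth: Sequence[SVCall],
    svtype: SVType,
    stats: SequencingStats,
    config: TrainingConfig,
    registry: Optional[DialectRegistry] = None,
    merge_params: MergeParams = MergeParams(),
    match_params: MatchParams = MatchParams(),
) -> TrainingRun:
    """Train the full model (FM) and the basic model (BM) for one SV type.

    FM: correlation pre-selection on the harmonized metric matrix, grid
    search, then iterative zero-importance pruning. BM: SV length plus
    per-caller presence flags only.
    """
    registry = registry or default_registry()
    sub_calls = _svtype_subset(calls_by_caller, svtype)
    consensus = merge_calls(sub_calls, merge_params)
    truth_t = [t for t in truth if t.svtype is svtype]
    match = match_to_truth(consensus, truth_t, match_params)
    matched = {cid for cid, _ in match.pairs}
    labels = [c.id in matched for c in consensus]

    feat_registry = default_feature_registry(svtype, registry)
    fm_matrix = build_feature_matrix(consensus, sub_calls, feat_registry, stats, labels)
    selected = correlation_select(fm_matrix, r_threshold=0.90)
    fm_model = grid_search_train(fm_matrix, config, feature_names=selected)
    fm_model = prune_zero_importance(fm_model, fm_matrix, config)
    fm_model.svtype = svtype

    bm_matrix = basic_feature_matrix(consensus, sub_calls, svtype, stats, labels)
    bm_model = grid_search_train(bm_matrix, config)
    bm_model.svtype = svtype

    return TrainingRun(
        svtype=svtype,
        consensus=consensus,
        labels=labels,
        fm_matrix=fm_matrix,
        bm_matrix=bm_matrix,
        fm_model=fm_model,
        bm_model=bm_model,
        selected_features=selected,
    )


def run_train(
    vcf_paths: dict[str, str],
    truth_vcf: str,
    stats: SequencingStats,
    out_dir: str,
    svtypes: Sequence[SVType] = (SVType.DEL, SVType.INS),
    config: Optional[TrainingConfig] = None,
    registry: Optional[DialectRegistry] = None,
    filter_config: FilterConfig = FilterConfig(),
    merge_params: MergeParams = MergeParams(),
    match_params: MatchParams = MatchParams(),
) -> dict[str, dict]:
    """File-level training entry point: produces BM and FM artifacts plus a
    training report per SV type under ``out_dir/<svtype>/{fm,bm}``."""
    config = config or TrainingConfig()
    registry = registry or default_registry()
    calls = load_calls(vcf_paths, registry, filter_config)
    truth_filter = FilterConfig(
        min_svlen=filter_config.min_svlen,
        autosomes_only=filter_config.autosomes_only,
        include_regions=filter_config.include_regions,
        require_nonref_genotype=True,
    )
    truth = filter_sv_calls(parse_sv_vcf(truth_vcf), truth_filter)

    reports = {}
    for svtype in svtypes:
        run = train_for_svtype(
            calls, truth, svtype, stats, config, registry, merge_params, match_params
        )
        base = os.path.join(out_dir, svtype.value)
        run.fm_model.save(os.path.join(base, "fm"))
        run.bm_model.save(os.path.join(base, "bm"))
        report = run.report()
        with open(os.path.join(base, "training_report.json"), "w") as fh:
            json.dump(report, fh, indent=1)
        reports[svtype.value] = report
    _write_provenance(out_dir, {"seed": config.seed, "command": "train"})
    return reports


def predict_for_svtype(
    calls_by_caller: dict[str, list[SVCall]],
    svtype: SVType,
    stats: SequencingStats,
    model: TrainedMetaModel,
    registry: Optional[DialectRegistry] = None,
    merge_params: MergeParams = MergeParams(),
) -> tuple[list[ConsensusCall], FeatureMatrix, np.ndarray]:
    """Merge one SV type's calls and attach TP probabilities."""
    if model.svtype is not svtype:
        raise ValueError(
            f"model is for {model.svtype.value}, cannot apply to {svtype.value} calls"
        )
    registry = registry or default_registry()
    sub_calls = _svtype_subset(calls_by_caller, svtype)
    consensus = merge_calls(sub_calls, merge_params)
    feat_registry = default_feature_registry(svtype, registry)
    matrix = build_feature_matrix(consensus, sub_calls, feat_registry, stats)
    probs = predict_probabilities(model, matrix) if consensus else np.array([])
    for call, p in zip(consensus, probs):
        call.probability = float(p)
    return consensus, matrix, probs


def run_predict(
    vcf_paths: dict[str, str],
    stats: SequencingStats,
    model_dir: str,
    out_vcf: str,
    svtypes: Sequence[SVType] = (SVType.DEL, SVType.INS),
    registry: Optional[DialectRegistry] = None,
    filter_config: FilterConfig = FilterConfig(),
    merge_params: MergeParams = MergeParams(),
) -> list[ConsensusCall]:
    """Score caller VCFs into a probability-ranked consensus VCF.

    Models are loaded from ``model_dir/<svtype>/fm``; DEL and INS are
    processed by their respective models and written sorted together.
    """
    registry = registry or default_registry()
    calls = load_calls(vcf_paths, registry, filter_config)
    all_consensus: list[ConsensusCall] = []
    for svtype in svtypes:
        model = TrainedMetaModel.load(os.path.join(model_dir, svtype.value, "fm"))
        consensus, _, _ = predict_for_svtype(
            calls, svtype, stats, model, registry, merge_params
        )
        all_consensus.extend(consensus)
    extra = [
        f"##svmeta_registry_hash={registry.content_hash()}",
        f"##svmeta_merge_params=max_dist={merge_params.max_dist},"
        f"min_support={merge_params.min_support},"
        f"type_match={merge_params.require_type_match}",
    ]
    write_consensus_vcf(all_consensus, out_vcf, extra_header=extra)
    _write_provenance(
        os.path.dirname(out_vcf) or ".",
        {"command": "predict", "model_dir": model_dir},
    )
    return all_consensus


def run_bench(
    calls: Sequence,
    truth: Sequence[SVCall],
    match_params: MatchParams = MatchParams(),
    probabilities: Optional[Sequence[float]] = None,
) -> dict:
    """Benchmark any call set against a truth set.

    Returns the JSON-ready report: counts, precision/recall/F1 (rounded
    half-up to 2 decimals at this reporting boundary), and — when
    probabilities are supplied — ROC AUC and the per-decile table.
    """
    result = match_to_truth(calls, truth, match_params)
    metrics = compute_metrics(result).rounded()
    report = {
        "tp": result.tp,
        "fp": result.fp,
        "fn": result.fn,
        "precision": metrics.precision,
        "recall": metrics.recall,
        "f1": metrics.f1,
    }
    if probabilities is not None and len(probabilities) == len(list(calls)):
        matched = {cid for cid, _ in result.pairs}
        labels = [c.id in matched for c in calls]
        if 0 < sum(labels) < len(labels):
            report["auc"] = roc_auc(probabilities, labels)
        deciles = decile_report(probabilities, labels)
        report["deciles"] = deciles.where(deciles.notna(), None).to_dict("records")
    return report


def _write_provenance(directory: str, payload: dict) -> None:
    os.makedirs(directory, exist_ok=True)
    payload = dict(payload, version=__version__)
    blob = json.dumps(payload, sort_keys=True)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    with open(os.path.join(directory, "provenance.json"), "w") as fh:
        json.dump(payload, fh, indent=1)
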