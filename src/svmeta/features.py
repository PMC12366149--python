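"""Per-consensus-call feature matrices for the type-specific classifiers.

Each consensus call becomes one row; each registered (caller, metric) pair
becomes one column named ``caller.metric``. A caller that did not support a
consensus call contributes NaN — the explicit missing sentinel consumed
natively by the gradient-boosted tree learner — never 0, so "caller silent"
stays distinguishable from "caller reports 0". Coverage-type metrics are
divided by the sample's mean coverage and edit-distance-type metrics by the
read length, making features transferable across sequencing depths and read
lengths.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dialects import DEL_CALLERS, INS_CALLERS, NORM_KINDS, DialectRegistry
from .types import ConsensusCall, SequencingStats, SVCall, SVType

SVLEN_COLUMN = "svlen"

_ALLOWED_CALLERS = {
    SVType.DEL: frozenset(DEL_CALLERS),
    SVType.INS: frozenset(INS_CALLERS),
}


@dataclass(frozen=True)
class FeatureRegistry:
    """Declares which (caller, metric, normalization) triples feed a model."""

    svtype: SVType
    entries: tuple[tuple[str, str, str], ...]
    include_svlen: bool = True
    include_presence: bool = False
    presence_callers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        allowed = _ALLOWED_CALLERS[self.svtype]
        for caller, metric, kind in self.entries:
            if caller not in allowed:
                raise ValueError(
                    f"caller {caller!r} not allowed in the {self.svtype.value} registry"
                )
            if kind not in NORM_KINDS:
                raise ValueError(f"unknown normalization kind {kind!r}")
        names = [f"{c}.{m}" for c, m, _ in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate feature entries")

    @property
    def callers(self) -> tuple[str, ...]:
        if self.entries:
            return tuple(sorted({c for c, _, _ in self.entries}))
        return tuple(sorted(self.presence_callers))

    def column_names(self) -> list[str]:
        cols = [SVLEN_COLUMN] if self.include_svlen else []
        cols += [f"{c}.{m}" for c, m, _ in self.entries]
        if self.include_presence:
            cols += [f"presence_{c}" for c in self.callers]
        return cols

    def content_hash(self) -> str:
        blob = json.dumps(
            {
                "svtype": self.svtype.value,
                "entries": [list(e) for e in self.entries],
                "svlen": self.include_svlen,
                "presence": self.include_presence,
                "presence_callers": list(self.callers) if self.include_presence else [],
            },
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_feature_registry(
    svtype: SVType, dialects: Optional[DialectRegistry] = None
) -> FeatureRegistry:
    """The full-model registry: every registered metric of the type-specific
    caller set plus SV length (35 columns for DEL, 36 for INS with the
    default dialects)."""
    if dialects is None:
        from .dialects import default_registry

        dialects = default_registry()
    callers = DEL_CALLERS if svtype is SVType.DEL else INS_CALLERS
    entries = tuple(
        (caller, spec.name, spec.normalization)
        for caller in callers
        for spec in dialects.metric_specs(caller, svtype)
    )
    return FeatureRegistry(svtype=svtype, entries=entries)


def basic_feature_registry(svtype: SVType) -> FeatureRegistry:
    """The basic-model registry: SV length plus one 0/1 presence flag per
    caller, nothing else."""
    callers = DEL_CALLERS if svtype is SVType.DEL else INS_CALLERS
    return FeatureRegistry(
        svtype=svtype, entries=(), include_presence=True, presence_callers=callers
    )


@dataclass
class FeatureMatrix:
    """Feature vectors (rows = consensus-call IDs) with optional TP labels."""

    df: pd.DataFrame
    stats: Optional[SequencingStats] = None
    registry_hash: str = ""
    labels: Optional[pd.Series] = None
    svtype: Optional[SVType] = None

    def __post_init__(self) -> None:
        if self.labels is not None:
            if not self.labels.index.equals(self.df.index):
                raise ValueError("label index must align 1:1 with feature rows")

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    def to_tsv(self, path: str | os.PathLike) -> None:
        out = self.df.copy()
        if self.labels is not None:
            out["__label__"] = self.labels.astype(int)
        out.to_csv(path, sep="\t", index_label="id", na_rep="NA")
        meta = {
            "registry_hash": self.registry_hash,
            "missing_sentinel": "NA",
            "stats": None
            if self.stats is None
            else {"mean_coverage": self.stats.mean_coverage,
                  "read_length": self.stats.read_length},
        }
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id", na_values=["NA"])
        labels = None
        if "__label__" in df.columns:
            labels = df.pop("__label__").astype(bool)
        stats = None
        registry_hash = ""
        meta_path = str(path) + ".meta.json"
        if os.path.exists(meta_path):
            with open(meta_path) as fh:
                meta = json.load(fh)
            registry_hash = meta.get("registry_hash", "")
            if meta.get("stats"):
                stats = SequencingStats(**meta["stats"])
        return cls(df=df, stats=stats, registry_hash=registry_hash, labels=labels)


def normalize_metric(value: float, kind: str, stats: SequencingStats) -> float:
    """Apply the registered normalization to one raw metric value."""
    if kind == "coverage":
        return value / stats.mean_coverage
    if kind == "read_length":
        return value / stats.read_length
    if kind == "none":
        return value
    raise ValueError(f"unknown normalization kind {kind!r}")


def build_feature_matrix(
    consensus: Sequence[ConsensusCall],
    calls_by_caller: dict[str, list[SVCall]],
    registry: FeatureRegistry,
    stats: SequencingStats,
    labels: Optional[Sequence[bool]] = None,
) -> FeatureMatrix:
    """Assemble the harmonized feature matrix for a consensus call set.

    For every registry entry the value comes from the caller's
    representative member of the cluster, normalized per the entry's kind;
    NaN when the caller did not support the call or did not report the
    metric.
    """
    for caller in registry.callers:
        if caller not in calls_by_caller:
            warnings.warn(
                f"registry caller {caller!r} absent from inputs; its feature "
                "columns will be all-missing",
                stacklevel=2,
            )

    columns = registry.column_names()
    ids = [c.id for c in consensus]
    data = np.full((len(ids), len(columns)), np.nan)
    col_index = {name: j for j, name in enumerate(columns)}

    for i, cons in enumerate(consensus):
        if registry.include_svlen:
            data[i, col_index[SVLEN_COLUMN]] = cons.svlen
        for caller, metric, kind in registry.entries:
            rep = cons.representatives.get(caller)
            if rep is None:
                continue
            raw = rep.metrics.get(metric)
            if raw is not None:
                data[i, col_index[f"{caller}.{metric}"]] = normalize_metric(
                    raw, kind, stats
                )
        if registry.include_presence:
            supporting = {c for c, _ in cons.members}
            for caller in registry.callers:
                data[i, col_index[f"presence_{caller}"]] = float(caller in supporting)

    df = pd.DataFrame(data, index=pd.Index(ids, name="id"), columns=columns)
    label_series = (
        None if labels is None else pd.Series(list(labels), index=df.index, dtype=bool)
    )
    return FeatureMatrix(
        df=df,
        stats=stats,
        registry_hash=registry.content_hash(),
        labels=label_series,
        svtype=registry.svtype,
    )


def basic_feature_matrix(
    consensus: Sequence[ConsensusCall],
    calls_by_caller: dict[str, list[SVCall]],
    svtype: SVType,
    stats: Optional[SequencingStats] = None,
    labels: Optional[Sequence[bool]] = None,
) -> FeatureMatrix:
    """SV length + per-caller presence flags only (the basic model input)."""
    registry = basic_feature_registry(svtype)
    return build_feature_matrix(
        consensus,
        calls_by_caller,
        registry,
        stats or SequencingStats(mean_coverage=1.0, read_length=1.0),
        labels=labels,
    )


def correlation_select(
    matrix: FeatureMatrix,
    labels: Optional[pd.Series] = None,
    r_threshold: float = 0.90,
) -> list[str]:
    """Redundancy-pruning feature pre-selection.

    Constant (or all-missing) columns are dropped. For every column pair
    with absolute pairwise Pearson correlation above ``r_threshold``
    (pairwise-complete rows), the member less correlated with the TP label
    is dropped; ties drop the lexicographically later name. Output order
    follows the input column order; the result is invariant to row order
    and to column order up to that tie rule.
    """
    if labels is None:
        labels = matrix.labels
    if labels is None:
        raise ValueError("correlation_select requires labels")
    df = matrix.df
    if len(df) < 2:
        raise ValueError("need at least 2 rows")

    keep = [c for c in df.columns if df[c].nunique(dropna=True) > 1]
    if not keep:
        warnings.warn("all feature columns are constant; empty selection", stacklevel=2)
        return []
    sub = df[keep]
    corr = sub.corr(method="pearson")
    label_corr = sub.corrwith(labels.astype(float)).abs().fillna(0.0)

    dropped: set[str] = set()
    names = sorted(keep)
    for i, a in enumerate(names):
        if a in dropped:
            continue
        for b in names[i + 1:]:
            if b in dropped:
                continue
            r = corr.loc[a, b]
            if pd.notna(r) and abs(r) > r_threshold:
                la, lb = label_corr[a], label_corr[b]
                # keep the better label correlate; on ties keep the
                # lexicographically earlier name (a)
                dropped.add(b if (la > lb or la == lb) else a)
                if a in dropped:
                    break
    return [c for c in keep if c not in dropped]
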