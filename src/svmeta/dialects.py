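"""Caller dialect registry: which VCF fields carry which quality metrics.

Each short-read SV caller writes a different VCF dialect — metrics live in
INFO, FORMAT or the QUAL column under caller-specific names, and several
callers report duplications (folded into the insertion class here) or
negative deletion lengths. A :class:`CallerDialect` declares, per caller,
how to map the dialect onto the harmonized :class:`~svmeta.types.SVCall`.

The default registry below covers the six deletion callers (BreakDancer,
Delly, LUMPY, Manta, Pindel, TARDIS) and the five insertion callers (Delly,
INSurVeyor, Manta, Pindel, TARDIS). The registry is data-driven
configuration: metric lists can be extended or replaced per deployment
without touching parser code.

Normalization kinds
-------------------
``coverage``     metric scales with local depth / supporting-read counts;
                 divided by sample mean coverage.
``read_length``  metric is an edit distance over read spans; divided by
                 read length.
``none``         dimensionless metric used as-is.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

from .types import SVType

#: metric sources understood by the parser
SOURCES = ("INFO", "FORMAT", "QUAL")

NORM_KINDS = ("coverage", "read_length", "none")


@dataclass(frozen=True)
class MetricSpec:
    """One quality metric: VCF field, where it lives, harmonized name, and
    which normalization applies. INFO flag fields (e.g. PRECISE) yield 1.0
    when set and 0.0 when unset."""

    vcf_field: str
    source: str
    name: str
    normalization: str = "none"

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown metric source {self.source!r}")
        if self.normalization not in NORM_KINDS:
            raise ValueError(f"unknown normalization kind {self.normalization!r}")


@dataclass(frozen=True)
class CallerDialect:
    caller: str
    svtype_map: dict[str, SVType] = field(
        default_factory=lambda: {"DEL": SVType.DEL, "INS": SVType.INS, "DUP": SVType.INS}
    )
    metric_specs: tuple[MetricSpec, ...] = ()
    #: restrict standalone evaluation to FILTER==PASS records
    high_confidence_only: bool = False

    def __post_init__(self) -> None:
        names = [m.name for m in self.metric_specs]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate metric names in dialect {self.caller}")

    def specs_for(self, svtype: SVType) -> tuple[MetricSpec, ...]:
        return self.metric_specs


def _specs(*triples: tuple[str, str, str, str]) -> tuple[MetricSpec, ...]:
    return tuple(MetricSpec(*t) for t in triples)


# Per-caller metric sets, grouped by the metric categories the callers
# actually expose (supporting read-pair/split-read counts, assigned
# qualities, microhomology lengths, local depth, genotype quality,
# variant fraction, consensus alignment quality / entropy, PRECISE flag).
# Count-type and depth-type metrics are coverage-normalized; INSurVeyor's
# stable-read edit distances are read-length-normalized.

_BREAKDANCER = CallerDialect(
    caller="breakdancer",
    metric_specs=_specs(
        ("QUAL", "QUAL", "score", "none"),
        ("RSUP", "INFO", "supporting_read_pairs", "coverage"),
        ("VAF", "INFO", "allele_fraction", "none"),
    ),
)

_DELLY_DEL = _specs(
    ("PE", "INFO", "paired_read_support", "coverage"),
    ("SR", "INFO", "split_read_support", "coverage"),
    ("MAPQ", "INFO", "pe_mapq", "none"),
    ("SRMAPQ", "INFO", "sr_mapq", "none"),
    ("HOMLEN", "INFO", "homology_len", "none"),
    ("CE", "INFO", "consensus_entropy", "none"),
    ("GQV", "FORMAT", "genotype_quality", "none"),
    ("RDRATIO", "INFO", "read_depth_ratio", "none"),
    ("VF", "INFO", "variant_fraction", "none"),
    ("PRECISE", "INFO", "precise", "none"),
)

_DELLY_INS = _specs(
    ("PE", "INFO", "paired_read_support", "coverage"),
    ("SR", "INFO", "split_read_support", "coverage"),
    ("MAPQ", "INFO", "pe_mapq", "none"),
    ("GQV", "FORMAT", "genotype_quality", "none"),
    ("HOMLEN", "INFO", "homology_len", "none"),
    ("PRECISE", "INFO", "precise", "none"),
)

_LUMPY = CallerDialect(
    caller="lumpy",
    metric_specs=_specs(
        ("PE", "INFO", "paired_read_support", "coverage"),
        ("SR", "INFO", "split_read_support", "coverage"),
        ("SU", "INFO", "total_support", "coverage"),
        ("ABAL", "FORMAT", "allele_balance", "none"),
        ("GQV", "FORMAT", "genotype_quality", "none"),
        ("QUAL", "QUAL", "qual", "none"),
        ("SBIAS", "INFO", "strand_bias", "none"),
    ),
)

_MANTA_DEL = _specs(
    ("PR", "FORMAT", "paired_read_support", "coverage"),
    ("SR", "FORMAT", "split_read_support", "coverage"),
    ("QUAL", "QUAL", "qual", "none"),
    ("GQV", "FORMAT", "genotype_quality", "none"),
    ("HOMLEN", "INFO", "homology_len", "none"),
    ("LDP", "FORMAT", "local_depth", "coverage"),
    ("PRECISE", "INFO", "precise", "none"),
)

_MANTA_INS = _specs(
    ("PR", "FORMAT", "paired_read_support", "coverage"),
    ("SR", "FORMAT", "split_read_support", "coverage"),
    ("QUAL", "QUAL", "qual", "none"),
    ("GQV", "FORMAT", "genotype_quality", "none"),
    ("HOMLEN", "INFO", "homology_len", "none"),
    ("PRECISE", "INFO", "precise", "none"),
)

_PINDEL_DEL = _specs(
    ("SVSUP", "INFO", "supporting_reads", "coverage"),
    ("VF", "INFO", "variant_fraction", "none"),
    ("HOMLEN", "INFO", "homology_len", "none"),
)

_PINDEL_INS = _specs(
    ("SVSUP", "INFO", "supporting_reads", "coverage"),
    ("HOMLEN", "INFO", "homology_len", "none"),
    ("LDP", "INFO", "local_depth", "coverage"),
)

_TARDIS_DEL = _specs(
    ("CNVL", "INFO", "cnv_likelihood", "none"),
    ("RPSUP", "INFO", "paired_read_support", "coverage"),
    ("SRSUP", "INFO", "split_read_support", "coverage"),
    ("LDP", "INFO", "local_depth", "coverage"),
)

_TARDIS_INS = _specs(
    ("CNVL", "INFO", "cnv_likelihood", "none"),
    ("SRSUP", "INFO", "split_read_support", "coverage"),
)

_INSURVEYOR = CallerDialect(
    caller="insurveyor",
    svtype_map={"INS": SVType.INS, "DUP": SVType.INS},
    high_confidence_only=True,
    metric_specs=_specs(
        ("SRSUP", "INFO", "split_read_support", "coverage"),
        ("PESUP", "INFO", "paired_read_support", "coverage"),
        ("SPANNING", "INFO", "spanning_reads", "coverage"),
        ("STABLE", "INFO", "stable_reads", "coverage"),
        ("AVGED", "INFO", "avg_stable_edit_dist", "read_length"),
        ("MAXED", "INFO", "max_stable_edit_dist", "read_length"),
        ("MAPQ", "INFO", "mapq", "none"),
        ("QUAL", "QUAL", "qual", "none"),
        ("HOMLEN", "INFO", "homology_len", "none"),
        ("LAMAPQ", "INFO", "left_anchor_mapq", "none"),
        ("RAMAPQ", "INFO", "right_anchor_mapq", "none"),
        ("LCLIP", "INFO", "left_clip_len", "none"),
        ("RCLIP", "INFO", "right_clip_len", "none"),
        ("DPLOC", "INFO", "local_depth", "coverage"),
        ("DPFLANK", "INFO", "flank_depth", "coverage"),
        ("GQV", "FORMAT", "genotype_quality", "none"),
        ("VAF", "INFO", "allele_fraction", "none"),
        ("PRECISE", "INFO", "precise", "none"),
    ),
)


class DialectRegistry:
    """Lookup of caller name -> dialect, with per-SV-type metric views."""

    def __init__(self, dialects: dict[str, CallerDialect] | None = None,
                 per_svtype_specs: dict[tuple[str, str], tuple[MetricSpec, ...]] | None = None):
        self._dialects = dict(dialects or {})
        # callers whose metric set differs between DEL and INS
        self._per_svtype = dict(per_svtype_specs or {})

    def register(self, dialect: CallerDialect) -> None:
        self._dialects[dialect.caller] = dialect

    def get(self, caller: str) -> CallerDialect:
        try:
            return self._dialects[caller]
        except KeyError:
            raise KeyError(
                f"caller {caller!r} is not registered; known callers: "
                f"{sorted(self._dialects)}"
            ) from None

    def callers(self) -> list[str]:
        return sorted(self._dialects)

    def metric_specs(self, caller: str, svtype: SVType) -> tuple[MetricSpec, ...]:
        key = (caller, svtype.value)
        if key in self._per_svtype:
            return self._per_svtype[key]
        return self.get(caller).metric_specs

    def content_hash(self) -> str:
        """Stable hash of the registry content, recorded in model artifacts
        so a model is only ever applied to features built the same way."""
        payload = {
            caller: {
                "svtype_map": {k: v.value for k, v in d.svtype_map.items()},
                "metrics": {
                    st: [list(m.__dict__.values()) for m in self.metric_specs(caller, SVType(st))]
                    for st in ("DEL", "INS")
                },
            }
            for caller, d in sorted(self._dialects.items())
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_registry() -> DialectRegistry:
    """Registry for the seven supported callers with the default metric sets
    (34 deletion metrics across six callers, 35 insertion metrics across
    five)."""
    reg = DialectRegistry(
        dialects={
            "breakdancer": _BREAKDANCER,
            "delly": CallerDialect(caller="delly", metric_specs=_DELLY_DEL,
                                   high_confidence_only=True),
            "lumpy": _LUMPY,
            "manta": CallerDialect(caller="manta", metric_specs=_MANTA_DEL),
            "pindel": CallerDialect(caller="pindel", metric_specs=_PINDEL_DEL),
            "tardis": CallerDialect(caller="tardis", metric_specs=_TARDIS_DEL),
            "insurveyor": _INSURVEYOR,
        },
        per_svtype_specs={
            ("delly", "DEL"): _DELLY_DEL,
            ("delly", "INS"): _DELLY_INS,
            ("manta", "DEL"): _MANTA_DEL,
            ("manta", "INS"): _MANTA_INS,
            ("pindel", "DEL"): _PINDEL_DEL,
            ("pindel", "INS"): _PINDEL_INS,
            ("tardis", "DEL"): _TARDIS_DEL,
            ("tardis", "INS"): _TARDIS_INS,
        },
    )
    return reg


#: callers contributing features to each type-specific model
DEL_CALLERS = ("breakdancer", "delly", "lumpy", "manta", "pindel", "tardis")
INS_CALLERS = ("delly", "insurveyor", "manta", "pindel", "tardis")
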