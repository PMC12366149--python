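"""Core domain types for multi-caller SV consensus calling.

Coordinates follow the VCF convention throughout: 1-based POS, inclusive END.
Contig names are normalized by stripping any ``chr`` prefix so GRCh37- and
GRCh38-style inputs compare equal; autosomes are the contigs ``1``..``22``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional


AUTOSOMES = frozenset(str(i) for i in range(1, 23))


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr``/``Chr``/``CHR`` prefix from a contig name."""
    if name[:3].lower() == "chr":
        return name[3:]
    return name


class SVType(str, Enum):
    DEL = "DEL"
    INS = "INS"


class Genotype(str, Enum):
    hom_ref = "hom_ref"
    het = "het"
    hom_alt = "hom_alt"
    missing = "missing"

    @property
    def is_nonref(self) -> bool:
        return self in (Genotype.het, Genotype.hom_alt)


@dataclass(frozen=True)
class SequencingStats:
    """Sample-level sequencing statistics used for metric normalization.

    Parameters
    ----------
    mean_coverage:
        Genome-wide mean sequencing depth in reads per base (e.g. ``35.0``).
        Divides every coverage-referring quality metric so models transfer
        across sequencing depths.
    read_length:
        Read length in bp (e.g. ``150``). Divides edit-distance-type metrics.
    """

    mean_coverage: float
    read_length: float

    def __post_init__(self) -> None:
        if self.mean_coverage <= 0 or self.read_length <= 0:
            raise ValueError(
                "mean_coverage and read_length must be strictly positive, got "
                f"{self.mean_coverage}, {self.read_length}"
            )


@dataclass
class SVCall:
    """One caller's SV record with normalized coordinates and raw metrics.

    ``metrics`` maps metric name -> raw (un-normalized) numeric value; a key
    may be absent or map to ``None`` when the caller did not report it.
    Missing is never conflated with 0.
    """

    id: str
    caller: str
    chrom: str
    pos: int
    end: int
    svtype: SVType
    svlen: int
    genotype: Genotype = Genotype.missing
    precise: bool = True
    metrics: dict[str, Optional[float]] = field(default_factory=dict)
    filter_pass: bool = True

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.svlen < 1:
            raise ValueError(f"svlen must be >= 1, got {self.svlen}")


@dataclass
class ConsensusCall:
    """A cluster of same-type SV calls merged by breakpoint proximity.

    ``members`` retains every (caller, caller-local id) pair in the cluster;
    ``representatives`` keeps, per caller, the single member call chosen as
    that caller's feature source (the one closest to the representative
    coordinates when a caller contributed more than one call).
    """

    id: str
    chrom: str
    pos: int
    end: int
    svtype: SVType
    svlen: int
    members: list[tuple[str, str]]
    representatives: dict[str, SVCall] = field(default_factory=dict)
    probability: Optional[float] = None

    @property
    def supp(self) -> int:
        """Number of distinct supporting callers."""
        return len({caller for caller, _ in self.members})

    @property
    def callers(self) -> list[str]:
        return sorted({caller for caller, _ in self.members})


@dataclass(frozen=True)
class FilterConfig:
    """Predicates applied to raw caller output before merging.

    Defaults mirror standard SV benchmarking practice: autosomal variants of
    length >= 50 bp (the conventional SV size threshold), both DEL and INS.
    """

    min_svlen: int = 50
    allowed_types: frozenset[SVType] = frozenset((SVType.DEL, SVType.INS))
    autosomes_only: bool = True
    include_regions: Optional["GenomeRegions"] = None
    require_nonref_genotype: bool = False
    require_filter_pass: bool = False

    def __post_init__(self) -> None:
        if self.min_svlen < 1:
            raise ValueError("min_svlen must be >= 1")


class GenomeRegions:
    """A set of genomic intervals loaded from a BED file (0-based half-open).

    A variant is considered inside the regions when both of its breakpoints
    fall within covered bases, matching the containment semantics used by
    high-confidence-region benchmarking.
    """

    def __init__(self, intervals: Mapping[str, list[tuple[int, int]]]):
        from intervaltree import IntervalTree

        self._trees = {}
        for chrom, ivs in intervals.items():
            tree = IntervalTree()
            for start, stop in ivs:
                if stop > start:
                    tree[start:stop] = True
            tree.merge_overlaps()
            self._trees[normalize_chrom(chrom)] = tree

    @classmethod
    def from_bed(cls, path: str) -> "GenomeRegions":
        intervals: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                intervals.setdefault(fields[0], []).append(
                    (int(fields[1]), int(fields[2]))
                )
        return cls(intervals)

    def contains_point(self, chrom: str, pos: int) -> bool:
        """True if the 1-based position lies in a covered interval."""
        tree = self._trees.get(normalize_chrom(chrom))
        return bool(tree is not None and tree[pos - 1])

    def contains_call(self, chrom: str, pos: int, end: int) -> bool:
        return self.contains_point(chrom, pos) and self.contains_point(chrom, end)
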