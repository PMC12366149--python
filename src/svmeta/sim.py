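"""Seeded synthetic multi-caller SV data for end-to-end testing.

The generator emulates the structure of real multi-caller call sets
without any sequence-level simulation: a truth set of autosomal DEL/INS
records, and per caller an imperfect detection of it — caller-specific
sensitivity, breakpoint jitter, false positives at a per-Mb rate, and
quality-metric values drawn from TP- or FP-conditional distributions.

Two features of real data drive the design:

* a fraction of truth SVs is invisible to short-read calling entirely
  (``hard_fraction``); every caller misses those, which is what makes
  false-negative accounting and the union recall realistic;
* coverage-type metrics scale linearly with the configured mean coverage,
  so coverage normalization (and its scale-invariance property) is
  exercised end-to-end.

Default caller profiles are ordered qualitatively like real short-read
callers: a high-precision/low-recall profile (tardis-like), a balanced
high-F1 profile (manta-like), and a noisy low-precision one
(breakdancer-like).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .bench import MatchParams, match_to_truth
from .dialects import DialectRegistry, default_registry
from .types import ConsensusCall, Genotype, SequencingStats, SVCall, SVType
from .vcf_io import write_caller_vcf


@dataclass(frozen=True)
class MetricGen:
    """TP/FP-conditional generator for one quality metric.

    Continuous metrics are Gaussian (clipped at physical bounds); the
    PRECISE flag is Bernoulli. ``coverage``-kind metrics are drawn as a
    depth *ratio* and multiplied by the sample mean coverage;
    ``read_length``-kind metrics are drawn as a fraction of the read
    length.
    """

    mu_tp: float
    mu_fp: float
    sigma: float
    kind: str = "none"
    lo: float = 0.0
    hi: float = np.inf
    bernoulli: bool = False

    def draw(self, is_tp: bool, rng: np.random.Generator, stats: SequencingStats,
             z: float = 0.0, rho: float = 0.0) -> float:
        """Draw one value; ``z`` is the variant's latent quality factor and
        ``rho`` the across-caller correlation it induces. The marginal
        distribution stays N(mu, sigma) for any rho."""
        mu = self.mu_tp if is_tp else self.mu_fp
        if self.bernoulli:
            return float(rng.random() < mu)
        center = mu + z * rho * self.sigma
        within = self.sigma * float(np.sqrt(max(0.0, 1.0 - rho * rho)))
        value = float(np.clip(rng.normal(center, within), self.lo, self.hi))
        if self.kind == "coverage":
            return value * stats.mean_coverage
        if self.kind == "read_length":
            return value * stats.read_length
        return value


@dataclass(frozen=True)
class CallerProfile:
    """Behavioral profile of one simulated caller."""

    caller: str
    #: marginal detection probability per SV type (recall against truth)
    sensitivity: dict[SVType, float]
    #: SD (bp) of the rounded zero-mean Gaussian breakpoint noise,
    #: truncated at 6 SD
    jitter_sd: float
    #: false positives per megabase per SV type
    fp_rate_per_mb: dict[SVType, float]
    #: (metric name -> generator) per SV type; built from the dialect
    #: registry when omitted
    metric_gens: dict[SVType, dict[str, MetricGen]] = field(default_factory=dict)
    #: probability of FILTER==PASS for (TP, FP) calls
    pass_p: tuple[float, float] = (1.0, 1.0)
    #: fraction of detected insertions emitted with the DUP type token
    dup_fraction: float = 0.0


#: strongly label-separated metrics get a 2-SD mean shift between the
#: TP- and FP-conditional distributions; the rest a 0.3-SD shift
_STRONG = dict(mu_tp=1.5, mu_fp=0.5, sigma=0.5)
_WEAK = dict(mu_tp=0.65, mu_fp=0.5, sigma=0.5)


def _auto_metric_gens(
    caller: str, registry: DialectRegistry
) -> dict[SVType, dict[str, MetricGen]]:
    """Generators for every registered metric: the first two non-flag
    metrics of each caller carry the strong TP/FP separation."""
    out: dict[SVType, dict[str, MetricGen]] = {}
    for svtype in (SVType.DEL, SVType.INS):
        gens: dict[str, MetricGen] = {}
        n_strong = 0
        for spec in registry.metric_specs(caller, svtype):
            if spec.name == "precise":
                gens[spec.name] = MetricGen(mu_tp=0.85, mu_fp=0.35, sigma=0.0,
                                            bernoulli=True)
                continue
            params = _STRONG if n_strong < 2 else _WEAK
            n_strong += 1
            gens[spec.name] = MetricGen(kind=spec.normalization, **params)
        out[svtype] = gens
    return out


def default_profiles(registry: Optional[DialectRegistry] = None) -> dict[str, CallerProfile]:
    """Seven caller profiles whose sensitivities and FP rates are ordered
    like the heterogeneity observed among real short-read SV callers."""
    registry = registry or default_registry()
    spec = {
        #            sens DEL, sens INS, jitter, fpMb DEL, fpMb INS, dup
        "breakdancer": (0.22, 0.00, 120.0, 10.0, 0.0, 0.0),
        "delly":       (0.56, 0.07, 20.0, 7.0, 0.8, 0.2),
        "lumpy":       (0.51, 0.00, 30.0, 2.3, 0.0, 0.0),
        "manta":       (0.65, 0.11, 15.0, 1.7, 1.0, 0.25),
        "pindel":      (0.65, 0.20, 10.0, 8.7, 11.6, 0.0),
        "tardis":      (0.32, 0.08, 40.0, 0.5, 8.2, 0.0),
        "insurveyor":  (0.00, 0.35, 15.0, 0.0, 2.3, 0.3),
    }
    profiles = {}
    for caller, (s_del, s_ins, jit, fp_del, fp_ins, dup) in spec.items():
        profiles[caller] = CallerProfile(
            caller=caller,
            sensitivity={SVType.DEL: s_del, SVType.INS: s_ins},
            jitter_sd=jit,
            fp_rate_per_mb={SVType.DEL: fp_del, SVType.INS: fp_ins},
            metric_gens=_auto_metric_gens(caller, registry),
            pass_p=(0.97, 0.85) if caller in ("delly", "insurveyor") else (1.0, 1.0),
            dup_fraction=dup,
        )
    return profiles


@dataclass
class SimulationConfig:
    seed: int = 0
    contigs: tuple[tuple[str, int], ...] = (("1", 10_000_000), ("2", 10_000_000))
    n_truth: dict[SVType, int] = field(
        default_factory=lambda: {SVType.DEL: 2000, SVType.INS: 2000}
    )
    svlen_max: int = 10_000
    #: fraction of truth SVs undetectable by every caller (drives the
    #: union's false negatives, mirroring short-read blind spots)
    hard_fraction: dict[SVType, float] = field(
        default_factory=lambda: {SVType.DEL: 0.21, SVType.INS: 0.52}
    )
    #: density of recurrent artifact loci per Mb: false-positive-prone sites
    #: that multiple callers co-report, as mapping artifacts do in real data
    artifact_rate_per_mb: dict[SVType, float] = field(
        default_factory=lambda: {SVType.DEL: 4.0, SVType.INS: 3.0}
    )
    #: fraction of each caller's false positives drawn from the shared
    #: artifact pool rather than placed independently
    fp_shared_fraction: float = 0.5
    #: probability that a caller omits any given metric on a call (real
    #: VCFs frequently lack individual fields)
    metric_missing_p: float = 0.15
    #: across-caller correlation of metric deviations at the same variant:
    #: a latent per-locus quality factor shared by every caller reporting
    #: the site (marginal metric distributions are unaffected)
    metric_corr: float = 0.7
    stats: SequencingStats = field(
        default_factory=lambda: SequencingStats(mean_coverage=35.0, read_length=250.0)
    )
    profiles: Optional[dict[str, CallerProfile]] = None
    registry: Optional[DialectRegistry] = None

    def __post_init__(self) -> None:
        if self.registry is None:
            self.registry = default_registry()
        if self.profiles is None:
            self.profiles = default_profiles(self.registry)
        for p in self.profiles.values():
            if not all(0.0 <= s <= 1.0 for s in p.sensitivity.values()):
                raise ValueError(f"sensitivities of {p.caller} must lie in [0, 1]")
            if p.jitter_sd < 0:
                raise ValueError("jitter SD must be >= 0")

    @property
    def genome_mb(self) -> float:
        return sum(length for _, length in self.contigs) / 1e6


@dataclass
class SimulationLedger:
    """Ground truth of one simulation run: the truth set, every emitted
    call, and each call's origin (a truth ID, or "FP")."""

    truth: list[SVCall]
    calls: dict[str, list[SVCall]]
    origins: dict[tuple[str, str], str]
    hard_ids: set[str]
    dup_ids: set[str]

    def origin_counts(self, caller: str) -> tuple[int, int]:
        """(n_tp, n_fp) emitted by one caller."""
        tagged = [self.origins[(caller, c.id)] for c in self.calls[caller]]
        n_fp = sum(1 for o in tagged if o == "FP")
        return len(tagged) - n_fp, n_fp

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("caller\tcall_id\torigin\tchrom\tpos\tend\tsvtype\tsvlen\n")
            for caller in sorted(self.calls):
                for c in self.calls[caller]:
                    fh.write(
                        f"{caller}\t{c.id}\t{self.origins[(caller, c.id)]}\t"
                        f"{c.chrom}\t{c.pos}\t{c.end}\t{c.svtype.value}\t{c.svlen}\n"
                    )


def _draw_svlen(rng: np.random.Generator, svlen_max: int) -> int:
    return int(np.exp(rng.uniform(np.log(50), np.log(svlen_max))))


def simulate_truth_set(config: SimulationConfig) -> list[SVCall]:
    """Generate the truth records: per type, ``n_truth`` SVs placed
    uniformly on the contigs, deletions non-overlapping (rejection
    sampling), lengths log-uniform on [50, svlen_max]."""
    rng = np.random.default_rng(config.seed)
    contigs = list(config.contigs)
    weights = np.array([length for _, length in contigs], dtype=float)
    weights /= weights.sum()

    truth: list[SVCall] = []
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name, _ in contigs}
    for svtype in (SVType.DEL, SVType.INS):
        for k in range(config.n_truth.get(svtype, 0)):
            for attempt in range(1000):
                ci = rng.choice(len(contigs), p=weights)
                name, length = contigs[ci]
                svlen = _draw_svlen(rng, config.svlen_max)
                pos = int(rng.integers(1, max(2, length - svlen)))
                end = pos + svlen - 1 if svtype is SVType.DEL else pos
                if svtype is SVType.DEL and any(
                    pos <= e and end >= s for s, e in occupied[name]
                ):
                    continue
                if svtype is SVType.DEL:
                    occupied[name].append((pos, end))
                truth.append(
                    SVCall(
                        id=f"truth_{svtype.value}_{k:05d}",
                        caller="truth",
                        chrom=name,
                        pos=pos,
                        end=end,
                        svtype=svtype,
                        svlen=svlen,
                        genotype=Genotype.het if rng.random() < 0.6 else Genotype.hom_alt,
                    )
                )
                break
            else:
                raise RuntimeError(
                    f"could not place truth SV {k} of type {svtype.value}: "
                    "contigs too small for the requested count"
                )
    return truth


def _jitter(rng: np.random.Generator, sd: float) -> int:
    if sd == 0:
        return 0
    raw = rng.normal(0.0, sd)
    return int(round(np.clip(raw, -6 * sd, 6 * sd)))


def simulate_caller_outputs(
    truth: list[SVCall],
    config: SimulationConfig,
) -> tuple[SimulationLedger, dict[str, list[SVCall]]]:
    """Emit each caller's imperfect view of the truth set.

    Detection is independent per caller given a truth record's
    hard/detectable status; detected calls get jittered breakpoints and
    TP-conditional metrics, false positives are placed uniformly at the
    profile's per-Mb rate with FP-conditional metrics.
    """
    rng = np.random.default_rng(config.seed + 1)
    registry = config.registry
    profiles = config.profiles
    for caller in profiles:
        registry.get(caller)  # unknown caller -> configuration error

    hard_ids = {
        t.id
        for t in truth
        if rng.random() < config.hard_fraction.get(t.svtype, 0.0)
    }
    # latent per-variant quality factors, shared across callers
    z_of: dict[str, float] = {t.id: float(rng.normal()) for t in truth}
    detectable_frac = {
        svtype: 1.0 - config.hard_fraction.get(svtype, 0.0)
        for svtype in (SVType.DEL, SVType.INS)
    }

    calls: dict[str, list[SVCall]] = {}
    origins: dict[tuple[str, str], str] = {}
    dup_ids: set[str] = set()
    contig_len = dict(config.contigs)

    # recurrent artifact loci shared across callers (drawn once per run)
    artifacts: dict[SVType, list[SVCall]] = {}
    for svtype in (SVType.DEL, SVType.INS):
        pool: list[SVCall] = []
        n_art = int(round(config.artifact_rate_per_mb.get(svtype, 0.0) * config.genome_mb))
        for a in range(n_art):
            ci = int(rng.integers(0, len(config.contigs)))
            name, length = config.contigs[ci]
            svlen = _draw_svlen(rng, config.svlen_max)
            pos = int(rng.integers(1, max(2, length - svlen)))
            site = SVCall(
                id=f"artifact_{svtype.value}_{a:05d}", caller="artifact",
                chrom=name, pos=pos,
                end=pos + svlen - 1 if svtype is SVType.DEL else pos,
                svtype=svtype, svlen=svlen, genotype=Genotype.het,
            )
            z_of[site.id] = float(rng.normal())
            pool.append(site)
        artifacts[svtype] = pool

    for caller in sorted(profiles):
        profile = profiles[caller]
        emitted: list[SVCall] = []
        counter = 0
        for t in truth:
            sens = profile.sensitivity.get(t.svtype, 0.0)
            if sens == 0.0 or t.id in hard_ids:
                continue
            # conditional detection probability given the record is callable
            p_detect = min(1.0, sens / detectable_frac[t.svtype])
            if rng.random() >= p_detect:
                continue
            call = _emit(rng, profile, registry, config.stats, t, True,
                         contig_len, f"{caller}_{counter:06d}",
                         metric_missing_p=config.metric_missing_p,
                         z=z_of[t.id], rho=config.metric_corr)
            counter += 1
            if t.svtype is SVType.INS and rng.random() < profile.dup_fraction:
                dup_ids.add(call.id)
            emitted.append(call)
            origins[(caller, call.id)] = t.id
        for svtype in (SVType.DEL, SVType.INS):
            rate = profile.fp_rate_per_mb.get(svtype, 0.0)
            n_fp = int(rng.poisson(rate * config.genome_mb)) if rate > 0 else 0
            pool = artifacts[svtype]
            for _ in range(n_fp):
                if pool and rng.random() < config.fp_shared_fraction:
                    site = pool[int(rng.integers(0, len(pool)))]
                    fake = SVCall(
                        id="x", caller=caller, chrom=site.chrom, pos=site.pos,
                        end=site.end, svtype=svtype, svlen=site.svlen,
                        genotype=Genotype.het,
                    )
                    z_site = z_of[site.id]
                    jitter_site = True
                else:
                    ci = int(rng.integers(0, len(config.contigs)))
                    name, length = config.contigs[ci]
                    svlen = _draw_svlen(rng, config.svlen_max)
                    pos = int(rng.integers(1, max(2, length - svlen)))
                    fake = SVCall(
                        id="x", caller=caller, chrom=name, pos=pos,
                        end=pos + svlen - 1 if svtype is SVType.DEL else pos,
                        svtype=svtype, svlen=svlen, genotype=Genotype.het,
                    )
                    z_site = float(rng.normal())
                    jitter_site = False
                call = _emit(rng, profile, registry, config.stats, fake, False,
                             contig_len, f"{caller}_{counter:06d}",
                             jitter=jitter_site,
                             metric_missing_p=config.metric_missing_p,
                             z=z_site, rho=config.metric_corr)
                counter += 1
                if svtype is SVType.INS and rng.random() < profile.dup_fraction:
                    dup_ids.add(call.id)
                emitted.append(call)
                origins[(caller, call.id)] = "FP"
        calls[caller] = emitted

    ledger = SimulationLedger(
        truth=truth, calls=calls, origins=origins, hard_ids=hard_ids, dup_ids=dup_ids
    )
    return ledger, calls


def _emit(
    rng: np.random.Generator,
    profile: CallerProfile,
    registry: DialectRegistry,
    stats: SequencingStats,
    source: SVCall,
    is_tp: bool,
    contig_len: dict[str, int],
    call_id: str,
    jitter: Optional[bool] = None,
    metric_missing_p: float = 0.0,
    z: float = 0.0,
    rho: float = 0.0,
) -> SVCall:
    do_jitter = is_tp if jitter is None else jitter
    pos = max(1, source.pos + (_jitter(rng, profile.jitter_sd) if do_jitter else 0))
    if source.svtype is SVType.DEL:
        end = source.end + (_jitter(rng, profile.jitter_sd) if do_jitter else 0)
        end = min(max(end, pos + 49), contig_len.get(source.chrom, end))
        svlen = end - pos + 1
    else:
        svlen = max(50, source.svlen + (_jitter(rng, profile.jitter_sd / 2) if do_jitter else 0))
        end = pos

    gens = profile.metric_gens.get(source.svtype, {})
    metrics: dict[str, Optional[float]] = {}
    precise = True
    for spec in registry.metric_specs(profile.caller, source.svtype):
        gen = gens.get(spec.name)
        if gen is None:
            metrics[spec.name] = None
            continue
        value = gen.draw(is_tp, rng, stats, z=z, rho=rho)
        if spec.name == "precise":
            precise = value >= 0.5
            metrics[spec.name] = value
        elif rng.random() < metric_missing_p:
            metrics[spec.name] = None  # caller omitted the field
        else:
            metrics[spec.name] = value

    genotype = source.genotype
    if is_tp and rng.random() < 0.1:
        genotype = Genotype.het if genotype is Genotype.hom_alt else Genotype.hom_alt
    tp_pass, fp_pass = profile.pass_p
    return SVCall(
        id=call_id,
        caller=profile.caller,
        chrom=source.chrom,
        pos=pos,
        end=end,
        svtype=source.svtype,
        svlen=svlen,
        genotype=genotype,
        precise=precise,
        metrics=metrics,
        filter_pass=rng.random() < (tp_pass if is_tp else fp_pass),
    )


def write_simulation(
    ledger: SimulationLedger,
    config: SimulationConfig,
    out_dir: str | os.PathLike,
) -> dict[str, str]:
    """Write truth.vcf, one VCF per caller (duplication-typed insertions
    use the DUP token to exercise DUP folding), ledger.tsv and stats.json.
    Returns caller -> VCF path."""
    os.makedirs(out_dir, exist_ok=True)
    contigs = [name for name, _ in config.contigs]
    paths: dict[str, str] = {}
    truth_path = os.path.join(out_dir, "truth.vcf")
    write_caller_vcf(truth_path, ledger.truth, config.registry, contigs)
    paths["truth"] = truth_path
    for caller, calls in ledger.calls.items():
        path = os.path.join(out_dir, f"{caller}.vcf")
        write_caller_vcf(path, calls, config.registry, contigs,
                         dup_ids=ledger.dup_ids)
        paths[caller] = path
    ledger.write_tsv(os.path.join(out_dir, "ledger.tsv"))
    with open(os.path.join(out_dir, "stats.json"), "w") as fh:
        json.dump(
            {
                "mean_coverage": config.stats.mean_coverage,
                "read_length": config.stats.read_length,
                "seed": config.seed,
            },
            fh,
            indent=1,
        )
    return paths


def label_consensus(
    consensus: list[ConsensusCall],
    ledger: SimulationLedger,
    params: MatchParams = MatchParams(),
) -> list[bool]:
    """TP/FP training labels for consensus calls, derived by matching the
    consensus against the simulated truth under the benchmark protocol."""
    result = match_to_truth(consensus, ledger.truth, params)
    matched = {cid for cid, _ in result.pairs}
    return [c.id in matched for c in consensus]
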