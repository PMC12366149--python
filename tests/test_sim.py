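"""Synthetic multi-caller data generator: determinism, rates, labeling."""

import numpy as np
import pytest

from svmeta.merge import merge_calls
from svmeta.sim import (
    CallerProfile,
    MetricGen,
    SimulationConfig,
    label_consensus,
    simulate_caller_outputs,
    simulate_truth_set,
)
from svmeta.types import SequencingStats, SVType


def _single_caller_config(sens, jitter, fp_rate, seed=0, n=200):
    profile = CallerProfile(
        caller="manta",
        sensitivity={SVType.DEL: sens, SVType.INS: sens},
        jitter_sd=jitter,
        fp_rate_per_mb={SVType.DEL: fp_rate, SVType.INS: 0.0},
        metric_gens={
            svt: {"qual": MetricGen(mu_tp=1.5, mu_fp=0.5, sigma=0.5)}
            for svt in SVType
        },
        dup_fraction=0.0,
    )
    return SimulationConfig(
        seed=seed,
        n_truth={SVType.DEL: n, SVType.INS: 0},
        contigs=(("1", 20_000_000),),
        hard_fraction={SVType.DEL: 0.0, SVType.INS: 0.0},
        profiles={"manta": profile},
    )


def test_empty_truth_request_yields_empty_set():
    config = SimulationConfig(seed=0, n_truth={SVType.DEL: 0, SVType.INS: 0})
    assert simulate_truth_set(config) == []


def test_truth_set_is_nonoverlapping_and_min_length():
    config = SimulationConfig(
        seed=5, n_truth={SVType.DEL: 500, SVType.INS: 0}, contigs=(("1", 10_000_000),)
    )
    truth = simulate_truth_set(config)
    assert len(truth) == 500
    assert min(t.svlen for t in truth) >= 50
    by_pos = sorted(truth, key=lambda t: t.pos)
    assert all(a.end < b.pos for a, b in zip(by_pos, by_pos[1:]))


def test_truth_generation_is_seed_deterministic():
    config = SimulationConfig(seed=9, n_truth={SVType.DEL: 100, SVType.INS: 100})
    t1 = simulate_truth_set(config)
    t2 = simulate_truth_set(config)
    assert [(a.chrom, a.pos, a.end, a.svlen) for a in t1] == [
        (a.chrom, a.pos, a.end, a.svlen) for a in t2
    ]


def test_capacity_error_when_contigs_too_small():
    config = SimulationConfig(
        seed=0, n_truth={SVType.DEL: 5000, SVType.INS: 0}, contigs=(("1", 100_000),)
    )
    with pytest.raises(RuntimeError, match="too small"):
        simulate_truth_set(config)


def test_noiseless_limit_reproduces_truth_exactly():
    config = _single_caller_config(sens=1.0, jitter=0.0, fp_rate=0.0)
    truth = simulate_truth_set(config)
    ledger, calls = simulate_caller_outputs(truth, config)
    emitted = calls["manta"]
    assert len(emitted) == len(truth)
    assert sorted((c.chrom, c.pos, c.end) for c in emitted) == sorted(
        (t.chrom, t.pos, t.end) for t in truth
    )
    assert all(origin != "FP" for origin in ledger.origins.values())


def test_detection_count_within_binomial_bounds():
    config = _single_caller_config(sens=0.6, jitter=10.0, fp_rate=0.0, n=2000)
    config = SimulationConfig(
        seed=1, n_truth={SVType.DEL: 2000, SVType.INS: 0},
        contigs=(("1", 50_000_000),),
        hard_fraction={SVType.DEL: 0.0, SVType.INS: 0.0},
        profiles=config.profiles,
    )
    truth = simulate_truth_set(config)
    ledger, _ = simulate_caller_outputs(truth, config)
    n_tp, _ = ledger.origin_counts("manta")
    sd = np.sqrt(2000 * 0.6 * 0.4)
    assert abs(n_tp - 1200) <= 3 * sd


def test_fp_count_within_poisson_bounds():
    config = _single_caller_config(sens=0.0, jitter=0.0, fp_rate=5.0, n=0)
    config = SimulationConfig(
        seed=2, n_truth={SVType.DEL: 0, SVType.INS: 0},
        contigs=(("1", 100_000_000),),
        profiles=config.profiles,
    )
    ledger, _ = simulate_caller_outputs([], config)
    _, n_fp = ledger.origin_counts("manta")
    assert abs(n_fp - 500) <= 3 * np.sqrt(500)


def test_jitter_stays_within_six_sd():
    config = _single_caller_config(sens=1.0, jitter=20.0, fp_rate=0.0, n=300)
    truth = simulate_truth_set(config)
    ledger, calls = simulate_caller_outputs(truth, config)
    truth_by_id = {t.id: t for t in truth}
    for call in calls["manta"]:
        origin = truth_by_id[ledger.origins[("manta", call.id)]]
        assert abs(call.pos - origin.pos) <= 6 * 20


def test_coverage_metrics_scale_linearly_with_mean_coverage(small_sim):
    config, truth, _, calls = small_sim
    doubled = SimulationConfig(
        seed=config.seed,
        n_truth=config.n_truth,
        contigs=config.contigs,
        stats=SequencingStats(
            mean_coverage=2 * config.stats.mean_coverage,
            read_length=config.stats.read_length,
        ),
    )
    _, calls2 = simulate_caller_outputs(truth, doubled)
    registry = config.registry
    for caller in calls:
        specs = {
            (svt, s.name): s.normalization
            for svt in SVType
            for s in registry.metric_specs(caller, svt)
        }
        for c1, c2 in zip(calls[caller], calls2[caller]):
            for name, v1 in c1.metrics.items():
                v2 = c2.metrics[name]
                kind = specs[(c1.svtype, name)]
                if v1 is None:
                    assert v2 is None
                elif kind == "coverage":
                    assert v2 == pytest.approx(2 * v1)
                else:
                    assert v2 == v1


class TestLabelConsensus:
    def test_noiseless_single_caller_all_tp(self):
        config = _single_caller_config(sens=1.0, jitter=0.0, fp_rate=0.0)
        truth = simulate_truth_set(config)
        ledger, calls = simulate_caller_outputs(truth, config)
        consensus = merge_calls(calls)
        labels = label_consensus(consensus, ledger)
        assert len(labels) == len(consensus) == len(truth)
        assert all(labels)

    def test_pure_fp_simulation_all_fp(self):
        config = _single_caller_config(sens=0.0, jitter=0.0, fp_rate=2.0)
        truth = simulate_truth_set(config)
        ledger, calls = simulate_caller_outputs(truth, config)
        consensus = merge_calls(calls)
        labels = label_consensus(consensus, ledger)
        assert len(consensus) > 0
        assert not any(labels)

    def test_mixed_run_label_counts_track_ledger(self, small_sim):
        config, truth, ledger, calls = small_sim
        consensus = merge_calls(calls)
        labels = label_consensus(consensus, ledger)
        # consensus clusters containing at least one truth-origin member
        tp_clusters = sum(
            any(ledger.origins[(caller, mid)] != "FP" for caller, mid in c.members)
            for c in consensus
        )
        n_tp = sum(labels)
        # matching tolerance: a small fraction may flip near the distance
        # and size-similarity bounds
        assert abs(n_tp - tp_clusters) <= 0.05 * len(consensus)


def test_full_run_is_seed_deterministic(small_sim):
    config, truth, ledger, calls = small_sim
    truth2 = simulate_truth_set(config)
    ledger2, calls2 = simulate_caller_outputs(truth2, config)
    for caller in calls:
        assert [(c.id, c.pos, c.end, c.metrics) for c in calls[caller]] == [
            (c.id, c.pos, c.end, c.metrics) for c in calls2[caller]
        ]
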