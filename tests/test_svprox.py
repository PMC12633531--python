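"""SV-proximity distances, pseudo-event null and bin classification."""

import math

import numpy as np
import pytest

from kataegis_storm.datamodel import (
    BEYOND,
    DetectionParams,
    GenomeRef,
    SnvRecord,
    SvBreakpoint,
)
from kataegis_storm.detect import KataegisEvent
from kataegis_storm.svprox import (
    adjust_proximity,
    bin_distances,
    breakpoint_index,
    classify_events_by_bin,
    event_sv_distance,
    interval_bp_distance,
    proximity_test,
    simulate_pseudo_events,
    sv_type_proximity,
)

EDGES = DetectionParams().distance_bin_edges


def bp_at(positions, chrom="chr1"):
    return breakpoint_index([SvBreakpoint("s", chrom, p, "DEL")
                             for p in positions])


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_breakpoint_inside_event_gives_zero():
    e = KataegisEvent("s", "chr1", 10000, 12000, 4, (), 1.0)
    assert event_sv_distance(e, bp_at([11000])) == 0.0


def test_distance_to_nearer_edge():
    e = KataegisEvent("s", "chr1", 10000, 12000, 4, (), 1.0)
    assert event_sv_distance(e, bp_at([15000])) == 3000.0
    assert event_sv_distance(e, bp_at([9000])) == 1000.0


def test_no_breakpoint_on_chromosome_is_beyond():
    e = KataegisEvent("s", "chr1", 10000, 12000, 4, (), 1.0)
    assert event_sv_distance(e, bp_at([5000], chrom="chr2")) == BEYOND


def test_distances_match_brute_force(rng):
    bps = np.sort(rng.integers(1, 10**7, size=40))
    idx = {"chr1": bps}
    for _ in range(100):
        start = int(rng.integers(1, 10**7 - 5000))
        end = start + int(rng.integers(0, 5000))
        e = KataegisEvent("s", "chr1", start, end, 4, (), 1.0)
        d = event_sv_distance(e, idx)
        brute = min(0.0 if start <= b <= end else min(abs(b - start), abs(b - end))
                    for b in bps)
        assert d == brute


# ---------------------------------------------------------------------------
# pseudo events
# ---------------------------------------------------------------------------

def test_degenerate_pool_centres_every_pseudo_event(lengths_only_genome):
    e = KataegisEvent("s", "chr1", 100000, 102000, 4, (), 1.0)
    pool = [SnvRecord("s", "chr2", 5_000_000, "C", "T")]
    chroms, starts, ends = simulate_pseudo_events(
        e, pool, 1000, lengths_only_genome, np.random.default_rng(0))
    assert set(chroms) == {"chr2"}
    assert np.all(starts == starts[0]) and np.all(ends == ends[0])
    assert (starts[0] + ends[0]) // 2 == pytest.approx(5_000_000, abs=1)


def test_pseudo_events_preserve_span(lengths_only_genome, rng):
    e = KataegisEvent("s", "chr1", 100000, 102000, 4, (), 1.0)
    pool = [SnvRecord("s", "chr1", int(p), "C", "T")
            for p in rng.integers(10_000, 49_000_000, size=200)]
    chroms, starts, ends = simulate_pseudo_events(
        e, pool, 1000, lengths_only_genome, rng)
    assert np.all(ends - starts == e.span)
    assert np.all(starts >= 1)
    assert np.all(ends <= 50_000_000)


def test_pseudo_events_reproducible_under_seed(lengths_only_genome):
    e = KataegisEvent("s", "chr1", 100000, 105000, 4, (), 1.0)
    pool = [SnvRecord("s", "chr1", 1000 + 17 * i, "C", "T") for i in range(50)]
    a = simulate_pseudo_events(e, pool, 500, lengths_only_genome,
                               np.random.default_rng(42))
    b = simulate_pseudo_events(e, pool, 500, lengths_only_genome,
                               np.random.default_rng(42))
    assert np.array_equal(a[1], b[1]) and np.array_equal(a[2], b[2])


def test_empty_pool_returns_none(lengths_only_genome):
    e = KataegisEvent("s", "chr1", 100000, 102000, 4, (), 1.0)
    assert simulate_pseudo_events(e, [], 100, lengths_only_genome,
                                  np.random.default_rng(0)) is None


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def test_half_open_bin_boundaries():
    counts = bin_distances([0, 999, 1000], EDGES)
    assert counts[0] == 2 and counts[1] == 1


def test_beyond_falls_in_last_bin():
    counts = bin_distances([BEYOND] * 5, EDGES)
    assert counts[-1] == 5 and counts.sum() == 5


def test_bin_counts_match_numpy_histogram(rng):
    d = rng.uniform(0, 2e8, size=10**4)
    counts = bin_distances(d, EDGES)
    finite_edges = list(EDGES[:-1]) + [np.inf]
    expected, _ = np.histogram(d, bins=finite_edges)
    assert counts.tolist() == expected.tolist()
    assert counts.sum() == 10**4


def test_negative_distance_is_an_error():
    with pytest.raises(ValueError):
        bin_distances([-1.0], EDGES)


# ---------------------------------------------------------------------------
# rank test
# ---------------------------------------------------------------------------

def test_rank_p_when_observed_exceeds_all_simulations():
    obs = [100.0] * 5  # 5 events in bin 0-1kb
    pseudo = np.full((5, 1000), 5e7)  # simulations all far away
    null = proximity_test(obs, pseudo, EDGES)
    assert null.p_enrich[0] == pytest.approx(1 / 1001)
    assert null.p_sparse[0] == 1.0


def test_rank_p_saturates_on_ties():
    obs = [5e6] * 3
    pseudo = np.full((3, 1000), 5e6)  # same bin every time
    null = proximity_test(obs, pseudo, EDGES)
    b = 4  # 1-10 Mb bin
    assert null.p_enrich[b] == 1.0 and null.p_sparse[b] == 1.0


def test_sim_rows_conserve_totals(rng):
    obs = rng.uniform(0, 2e8, size=20)
    pseudo = rng.uniform(0, 2e8, size=(20, 300))
    null = proximity_test(obs, pseudo, EDGES)
    assert null.observed_counts.sum() == 20
    assert np.all(null.sim_counts.sum(axis=1) == 20)
    assert np.all(null.p_enrich >= 1 / 301) and np.all(null.p_enrich <= 1.0)


def test_classification_lookup():
    obs = [500.0, BEYOND]
    pseudo = np.tile(np.linspace(1e3, 2e8, 1000), (2, 1))
    null = proximity_test(obs, pseudo, EDGES)
    null.bin_class = ["enriched", "neither", "neither", "neither",
                      "neither", "neither", "sparse"]
    events = [KataegisEvent("s", "chr1", 1, 2, 4, (), 1.0),
              KataegisEvent("s", "chr2", 1, 2, 4, (), 1.0)]
    classify_events_by_bin(events, obs, null)
    assert events[0].sv_class == "SV_associated"
    assert events[1].sv_class == "SV_independent"


def test_adjust_proximity_fills_fdr_and_classes(rng):
    obs = rng.uniform(0, 2e8, size=30)
    pseudo = rng.uniform(0, 2e8, size=(30, 200))
    null = proximity_test(obs, pseudo, EDGES)
    adjust_proximity([null])
    assert null.bin_class is not None and len(null.bin_class) == 7
    assert np.all(null.fdr_enrich >= null.p_enrich - 1e-12)


# ---------------------------------------------------------------------------
# SV-type enrichment
# ---------------------------------------------------------------------------

def test_sv_type_fisher_against_oracle():
    from tests.test_apobec import hypergeom_tail_ge  # noqa: F401

    events = {"s": [KataegisEvent("s", "chr1", 1_000_000, 1_002_000, 4, (), 1.0)]}
    bps = {"s": ([SvBreakpoint("s", "chr1", 1_001_000 + i, "DEL")
                  for i in range(8)]
                 + [SvBreakpoint("s", "chr1", 30_000_000 + 1000 * i, "TRA",
                                 mate=("chr2", 500)) for i in range(12)])}
    res = sv_type_proximity(events, bps, window=10_000)
    by_type = {r["sv_type"]: r for r in res}
    assert by_type["DEL"]["direction"] == "enriched"
    assert by_type["DEL"]["table"] == ((8, 0), (0, 12))
    from scipy.stats import fisher_exact
    _, p = fisher_exact(((8, 0), (0, 12)), alternative="two-sided")
    assert by_type["DEL"]["p"] == pytest.approx(p)


def test_proportional_types_give_odds_one():
    events = {"s": [KataegisEvent("s", "chr1", 1_000_000, 1_002_000, 4, (), 1.0)]}
    bps = {"s": []}
    for cls in ("DEL", "DUP"):
        bps["s"] += [SvBreakpoint("s", "chr1", 1_001_000 + i, cls)
                     for i in range(5)]
        bps["s"] += [SvBreakpoint("s", "chr1", 40_000_000 + 1000 * i, cls)
                     for i in range(10)]
    res = sv_type_proximity(events, bps, window=10_000)
    for r in res:
        assert r["odds_ratio"] == pytest.approx(1.0)
        assert r["p"] == 1.0


def test_shuffled_labels_calibrate_near_alpha(rng):
    """Permuting SV-type labels should flag ~5% of types at alpha=0.05."""
    hits = 0
    trials = 0
    events = {"s": [KataegisEvent("s", "chr1", 25_000_000, 25_002_000, 4, (), 1.0)]}
    for _ in range(120):
        positions = rng.integers(1, 50_000_000, size=60)
        labels = rng.permutation(["DEL"] * 30 + ["DUP"] * 30)
        bps = {"s": [SvBreakpoint("s", "chr1", int(p), str(l))
                     for p, l in zip(positions, labels)]}
        for r in sv_type_proximity(events, bps, window=5_000_000):
            trials += 1
            hits += r["p"] < 0.05
    assert trials > 0
    assert hits / trials <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / trials)
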