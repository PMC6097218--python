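import itertools
import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from finishkit import simulate as sim
from finishkit.fingerprint import (CloneFingerprint, Fragment, FingerprintSet,
                                   MinimumTilingPath, PhysicalContig,
                                   assemble_physical_contigs,
                                   build_overlap_network, decode_fragment,
                                   parse_fingerprints, select_mtp,
                                   shared_bands, sulston_score,
                                   write_fingerprints)
from finishkit.io import FormatError


def brute_force_sulston(k, n_low, n_high, tolerance, gel_bins):
    """Independent binomial-sum oracle: direct summation with math.comb."""
    p = 1.0 - (1.0 - 2.0 * tolerance / gel_bins) ** n_high
    return sum(math.comb(n_low, j) * p ** j * (1 - p) ** (n_low - j)
               for j in range(k, n_low + 1))


def make_fp(clone_id, sizes, channel="blue"):
    return CloneFingerprint(clone_id, [Fragment(channel, s) for s in sizes])


# ---------------------------------------------------------------------------
# parsing / encoding

@pytest.mark.parametrize("encoded,channel,size", [
    (10150, "green", 150),      # offset 10,000 is the green channel
    (42, "blue", 42),           # zero offset
    (20001, "yellow", 1),
    (39999, "red", 9999),
])
def test_decode_offset_dialect(encoded, channel, size):
    frag = decode_fragment(encoded)
    assert (frag.channel, frag.size) == (channel, size)
    assert frag.encoded == encoded


@pytest.mark.parametrize("bad", [0, -5, 40000, 41000, 30000])
def test_decode_rejects_out_of_range(bad):
    with pytest.raises(FormatError):
        decode_fragment(bad)


def test_parse_fingerprints_round_trip(tmp_path):
    path = tmp_path / "fp.tsv"
    path.write_text("cloneA\t42,10150,20007\ncloneB\t30001,95\n")
    fps = parse_fingerprints(path)
    assert len(fps) == 2
    assert [f.channel for f in fps["cloneA"].fragments] == \
           ["blue", "green", "yellow"]
    out = tmp_path / "out.tsv"
    write_fingerprints(fps, out)
    assert parse_fingerprints(out)["cloneA"].fragments[1].size == 150


def test_parse_rejects_duplicates_and_empty(tmp_path):
    dup = tmp_path / "dup.tsv"
    dup.write_text("c1\t42\nc1\t50\n")
    with pytest.raises(FormatError, match="c1"):
        parse_fingerprints(dup)
    empty = tmp_path / "empty.tsv"
    empty.write_text("c2\t\n")
    with pytest.raises(FormatError, match="c2"):
        parse_fingerprints(empty)


# ---------------------------------------------------------------------------
# Sulston score

def test_disjoint_fingerprints_score_one():
    a = make_fp("a", [100, 200, 300])
    b = make_fp("b", [500, 600, 700])
    assert sulston_score(a, b, tolerance=1, gel_bins=3000) == pytest.approx(1.0)


def test_sulston_matches_brute_force_oracle():
    """DERIVED oracle: grid n <= 12, k <= n, three tolerances, < 1e-12 rel."""
    rng = np.random.default_rng(5)
    for tolerance in (1.0, 3.0, 7.0):
        for n in range(1, 13):
            base = np.sort(rng.uniform(50, 2900, n))
            for k in range(0, n + 1):
                # construct two clones sharing exactly k bands
                a_sizes = list(base)
                b_sizes = list(base[:k]) + list(base[k:] + 3 * tolerance + 10)
                a = make_fp("a", a_sizes)
                b = make_fp("b", sorted(b_sizes))
                got = sulston_score(a, b, tolerance, 3000)
                kk = shared_bands(a, b, tolerance)
                expect = brute_force_sulston(kk, n, n, tolerance, 3000)
                assert got == pytest.approx(expect, rel=1e-12)


def test_sulston_symmetric_and_monotone():
    rng = np.random.default_rng(11)
    sizes = np.sort(rng.uniform(100, 2900, 10))
    a = make_fp("a", sizes)
    prev = None
    for k in range(0, 11):
        shared = list(sizes[:k]) + list(rng.uniform(3000, 6000, 10 - k) % 2900 + 4000)
        b = make_fp("b", sorted(s % 9000 + 100 for s in shared))
        s_ab = sulston_score(a, b, 1.0, 3000)
        s_ba = sulston_score(b, a, 1.0, 3000)
        assert s_ab == pytest.approx(s_ba)
    # monotone non-increasing in k at fixed n via the oracle formula
    scores = [brute_force_sulston(k, 10, 10, 1.0, 3000) for k in range(11)]
    assert all(x >= y for x, y in zip(scores, scores[1:]))


def test_empty_fingerprint_rejected():
    with pytest.raises(ValueError):
        CloneFingerprint("x", [])


# ---------------------------------------------------------------------------
# overlap network

def test_network_thresholding():
    rng = np.random.default_rng(3)
    base = np.sort(rng.uniform(100, 2400, 60))
    fps = FingerprintSet()
    fps.add(make_fp("A", base))
    fps.add(make_fp("B", base + 0.01))                     # near-identical
    fps.add(make_fp("C", np.sort(rng.uniform(100, 2400, 60))))
    g = build_overlap_network(fps, cutoff=1e-10, tolerance=1.0, gel_bins=2500)
    assert g.has_edge("A", "B")
    assert not g.has_edge("A", "C") or g.edges["A", "C"]["score"] <= 1e-10
    assert not any(u == v for u, v in g.edges)
    # identical duplicate: edge at any cutoff >= minimal achievable score
    s = sulston_score(fps["A"], fps["B"], 1.0, 2500)
    assert s <= 1e-10


def test_component_count_matches_simulated_regions():
    """Noise-free tiling clones from 3 disjoint regions -> 3 components."""
    cfg = sim.GenomeConfig(length=400_000)
    fps = FingerprintSet()
    region_of = {}
    for r in range(3):
        genome, _ = sim.simulate_genome(cfg, seed=200 + r)
        clones = sim.simulate_bac_library(
            genome, sim.BacConfig(n_clones=12, mean_length=100_000,
                                  sd_length=8000), seed=300 + r)
        sub = sim.simulate_fingerprints(
            clones, sim.FingerprintConfig(sizing_sd=0.0), seed=400 + r)
        for cid in sub:
            new_id = f"r{r}_{cid}"
            fps.add(CloneFingerprint(new_id, sub[cid].fragments))
            region_of[new_id] = r
    g = build_overlap_network(fps, cutoff=1e-10, tolerance=1.0, gel_bins=2500)
    import networkx as nx
    comps = [c for c in nx.connected_components(g) if len(c) > 1]
    regions_seen = {frozenset(region_of[c] for c in comp) for comp in comps}
    assert all(len(r) == 1 for r in regions_seen)


# ---------------------------------------------------------------------------
# contig assembly

def test_small_component_dropped_and_no_clone_lost(small_library):
    _, clones, fps = small_library
    g = build_overlap_network(fps, cutoff=1e-10, tolerance=2.0, gel_bins=2500)
    asm = assemble_physical_contigs(g, min_clones=5)
    placed = set().union(*[set(c.clones) for c in asm.contigs]) if asm.contigs else set()
    assert placed | asm.q_clones | asm.unplaced == set(fps)
    assert all(len(c) >= 5 for c in asm.contigs)
    for ctg in asm.contigs:
        starts = [ctg.coordinates[c][0] for c in ctg.clones]
        assert all(x <= y + 1e-9 for x, y in zip(starts, starts[1:]))


def test_noise_free_order_recovery():
    genome, _ = sim.simulate_genome(sim.GenomeConfig(length=800_000), seed=21)
    clones = sim.simulate_bac_library(
        genome, sim.BacConfig(n_clones=50, mean_length=140_000,
                              sd_length=12_000), seed=22)
    fps = sim.simulate_fingerprints(clones,
                                    sim.FingerprintConfig(sizing_sd=0.0),
                                    seed=23)
    g = build_overlap_network(fps, cutoff=1e-10, tolerance=1.0, gel_bins=2500)
    asm = assemble_physical_contigs(g)
    mid = {c.clone_id: (c.start + c.end) / 2 for c in clones}
    for ctg in asm.contigs:
        rho = abs(spearmanr([mid[c] for c in ctg.clones],
                            range(len(ctg))).statistic)
        assert rho >= 0.98


def test_chimeric_clone_flagged_as_q():
    genome, _ = sim.simulate_genome(sim.GenomeConfig(length=1_500_000), seed=31)
    clones = sim.simulate_bac_library(
        genome, sim.BacConfig(n_clones=90, chimera_rate=1 / 90), seed=32)
    chims = {c.clone_id for c in clones if c.chimera_of}
    fps = sim.simulate_fingerprints(clones, sim.FingerprintConfig(), seed=33)
    g = build_overlap_network(fps, cutoff=1e-10, tolerance=2.0, gel_bins=2500)
    asm = assemble_physical_contigs(g)
    assert chims <= asm.q_clones


# ---------------------------------------------------------------------------
# minimum tiling path

def exhaustive_mtp(intervals, edges):
    """Minimal clone subset covering the span, consecutive pairs linked."""
    ids = sorted(intervals)
    span = (min(s for s, _ in intervals.values()),
            max(e for _, e in intervals.values()))
    for size in range(1, len(ids) + 1):
        best = None
        for combo in itertools.combinations(ids, size):
            ivs = sorted(combo, key=lambda c: intervals[c][0])
            if intervals[ivs[0]][0] > span[0]:
                continue
            ok = True
            reach = intervals[ivs[0]][1]
            for prev, nxt in zip(ivs, ivs[1:]):
                if intervals[nxt][0] > reach or \
                        (prev, nxt) not in edges and (nxt, prev) not in edges:
                    ok = False
                    break
                reach = max(reach, intervals[nxt][1])
            if ok and reach >= span[1]:
                best = combo
                break
        if best:
            return size
    return len(ids)


def make_contig(intervals):
    order = sorted(intervals, key=lambda c: intervals[c][0])
    return PhysicalContig("ctg", order, dict(intervals))


def graph_from_overlaps(intervals):
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(intervals)
    for a, b in itertools.combinations(intervals, 2):
        (s1, e1), (s2, e2) = intervals[a], intervals[b]
        if min(e1, e2) > max(s1, s2):
            g.add_edge(a, b, score=1e-20, shared_bands=10)
    return g


def test_mtp_worked_example():
    intervals = {"c0": (0, 120), "c1": (50, 170), "c2": (100, 220),
                 "c3": (150, 270)}
    g = graph_from_overlaps(intervals)
    mtp = select_mtp(make_contig(intervals), g)
    assert mtp.clones == ["c0", "c2", "c3"]


def test_mtp_singleton():
    intervals = {"only": (0.0, 100.0)}
    g = graph_from_overlaps(intervals)
    assert select_mtp(make_contig(intervals), g).clones == ["only"]


def test_mtp_equals_exhaustive_on_random_instances():
    rng = np.random.default_rng(17)
    for _ in range(100):
        n = int(rng.integers(2, 11))
        starts = np.sort(rng.uniform(0, 500, n))
        lengths = rng.uniform(80, 200, n)
        intervals = {f"c{i}": (float(starts[i]), float(starts[i] + lengths[i]))
                     for i in range(n)}
        # ensure connectivity of the cover (chain reachability)
        g = graph_from_overlaps(intervals)
        import networkx as nx
        if nx.number_connected_components(g) != 1:
            continue
        mtp = select_mtp(make_contig(intervals), g)
        opt = exhaustive_mtp(intervals, set(g.edges))
        assert len(mtp.clones) == opt
        # MTP covers the span with linked consecutive clones
        reach = intervals[mtp.clones[0]][1]
        for prev, nxt in zip(mtp.clones, mtp.clones[1:]):
            assert intervals[nxt][0] <= reach
            assert g.has_edge(prev, nxt)
            reach = max(reach, intervals[nxt][1])
        assert reach >= max(e for _, e in intervals.values())


def test_mtp_requires_coordinates():
    ctg = PhysicalContig("ctg", ["a"], {})
    import networkx as nx
    with pytest.raises(ValueError):
        select_mtp(ctg, nx.Graph())
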