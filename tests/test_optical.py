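import re

import numpy as np
import pytest

from finishkit import simulate as sim
from finishkit.io import revcomp
from finishkit.optical import (AlignParams, OpticalMap, OpticalMolecule,
                               align_digest_to_map, assemble_optical_maps,
                               build_islands, digest_sequence, validate_maps,
                               _dp_align)

PARAMS = AlignParams(max_skip=None, threshold=1e-3, seed=1)


# ---------------------------------------------------------------------------
# digestion

def test_digest_simple_examples():
    d = digest_sequence("AAGCTCTTCAA", "GCTCTTC")
    assert list(d.sites) == [2]
    assert len(digest_sequence("ACGT" * 10, "GCTCTTC").sites) == 0


def test_digest_counts_reverse_strand_and_skips_n():
    seq = "AAGCTCTTC" + "T" * 20 + revcomp("GCTCTTC") + "A" * 10
    d = digest_sequence(seq, "GCTCTTC")
    assert len(d.sites) == 2
    withn = seq[:3] + "N" + seq[4:]
    assert len(digest_sequence(withn, "GCTCTTC").sites) == 1


def test_digest_matches_regex_oracle(small_genome):
    genome, _ = small_genome
    seq = genome[:100_000]
    d = digest_sequence(seq, "GCTCTTC")
    expect = sorted({m.start() for m in re.finditer("(?=GCTCTTC)", seq)} |
                    {m.start() for m in re.finditer(f"(?={revcomp('GCTCTTC')})", seq)})
    assert list(d.sites) == expect


def test_digest_strand_symmetry(small_genome):
    genome, _ = small_genome
    seq = genome[:50_000]
    fwd = digest_sequence(seq, "GCTCTTC").sites
    rev = digest_sequence(revcomp(seq), "GCTCTTC").sites
    mirrored = sorted(len(seq) - 7 - s for s in fwd)
    assert list(rev) == mirrored


def test_digest_empty_motif_rejected():
    with pytest.raises(ValueError):
        digest_sequence("ACGT", "")


# ---------------------------------------------------------------------------
# DP alignment

def brute_force_best(q, t, p):
    best = [-1e18]

    def score_chain(chain):
        s = p.match_bonus
        for (i1, j1), (i2, j2) in zip(chain, chain[1:]):
            gq, gt = q[i2] - q[i1], t[j2] - t[j1]
            pen = ((gq - gt) / (p.sigma * max(gq, gt, 1000.0))) ** 2
            s += p.match_bonus - pen - p.false_penalty * (i2 - i1 - 1) \
                - p.miss_penalty * (j2 - j1 - 1)
        return s

    def extend(chain):
        best[0] = max(best[0], score_chain(chain))
        i0, j0 = chain[-1]
        for i in range(i0 + 1, len(q)):
            for j in range(j0 + 1, len(t)):
                extend(chain + [(i, j)])

    for i in range(len(q)):
        for j in range(len(t)):
            extend([(i, j)])
    return best[0]


def test_dp_equals_exhaustive_enumeration():
    rng = np.random.default_rng(42)
    p = AlignParams()
    for _ in range(25):
        n, m = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        q = np.sort(rng.uniform(0, 120_000, n))
        t = np.sort(rng.uniform(0, 120_000, m))
        s_dp, _ = _dp_align(q, t, p.sigma, p.miss_penalty, p.false_penalty,
                            p.match_bonus, None)
        assert s_dp == pytest.approx(brute_force_best(q, t, p), abs=1e-9)


def test_self_alignment_plus_orientation(small_genome):
    genome, _ = small_genome
    seq = genome[:200_000]
    d = digest_sequence(seq, seq_id="S")
    omap = OpticalMap("m", float(len(seq)), d.sites.copy())
    a = align_digest_to_map(d, omap, PARAMS)
    assert a is not None and a.orientation == "+"
    assert len(a.site_pairs) == len(d.sites)
    assert a.unmatched_query == 0 and a.unmatched_target == 0


def test_revcomp_alignment_minus_orientation(small_genome):
    genome, _ = small_genome
    seq = genome[:200_000]
    omap = OpticalMap("m", float(len(seq)),
                      digest_sequence(seq).sites.copy())
    d_rc = digest_sequence(revcomp(seq), seq_id="S_rc")
    a = align_digest_to_map(d_rc, omap, PARAMS)
    assert a is not None and a.orientation == "-"
    assert len(a.site_pairs) == len(omap.sites)


def test_deleted_site_gives_one_unmatched_query_site(small_genome):
    genome, _ = small_genome
    seq = genome[:150_000]
    d = digest_sequence(seq, seq_id="S")
    assert len(d.sites) >= 6
    kept = np.delete(d.sites, len(d.sites) // 2)
    omap = OpticalMap("m", float(len(seq)), kept)
    a = align_digest_to_map(d, omap, PARAMS)
    assert a is not None and a.orientation == "+"
    assert a.unmatched_query == 1
    assert a.unmatched_target == 0


def test_alignment_requires_two_sites():
    omap = OpticalMap("m", 1000.0, np.array([100.0, 500.0]))
    bad = OpticalMolecule("x", 1000.0, np.array([100.0]))
    with pytest.raises(ValueError):
        align_digest_to_map(bad, omap, PARAMS)


# ---------------------------------------------------------------------------
# molecule assembly

def test_short_molecules_excluded():
    mols = [OpticalMolecule("short", 100_000.0, np.arange(5) * 9000.0 + 1000)]
    assert assemble_optical_maps(mols) == []


def test_error_free_molecules_recover_one_map():
    genome, _ = sim.simulate_genome(sim.GenomeConfig(length=500_000), seed=55)
    cfg = sim.OpticalConfig(coverage=25, sizing_sd=0.0, miss_rate=0.0,
                            false_per_kb=0.0)
    mols, truth = sim.simulate_optical_molecules(genome, cfg, seed=56)
    maps = assemble_optical_maps(mols, seed=57)
    big = max(maps, key=lambda m: len(m.sites))
    true_sites = truth["sites"]
    # the consensus frame may be mirrored: its interval sequence must match
    # a contiguous run of the true interval sequence in one orientation,
    # site for site within 500 bp
    cons_iv = np.diff(np.sort(big.sites))
    true_iv = np.diff(true_sites)
    assert len(cons_iv) >= 0.8 * len(true_iv)

    def matches(run, ref):
        n = len(run)
        for start in range(len(ref) - n + 1):
            if np.all(np.abs(ref[start:start + n] - run) <= 500):
                return True
        return False

    assert matches(cons_iv, true_iv) or matches(cons_iv[::-1], true_iv)


def test_two_unrelated_regions_give_two_maps():
    g1, _ = sim.simulate_genome(sim.GenomeConfig(length=450_000), seed=60)
    g2, _ = sim.simulate_genome(sim.GenomeConfig(length=450_000), seed=61)
    cfg = sim.OpticalConfig(coverage=20, sizing_sd=0.0, miss_rate=0.0,
                            false_per_kb=0.0)
    m1, _ = sim.simulate_optical_molecules(g1, cfg, seed=62)
    m2, _ = sim.simulate_optical_molecules(g2, cfg, seed=63)
    mols = m1 + [OpticalMolecule("b" + m.molecule_id, m.length, m.sites)
                 for m in m2]
    maps = assemble_optical_maps(mols, seed=64)
    big = sorted((m for m in maps if len(m.molecule_ids) > 3),
                 key=lambda m: -len(m.sites))
    assert len(big) >= 2
    groups = [{mid.lstrip("b")[:3] != mid[:3] for mid in m.molecule_ids}
              for m in big[:2]]
    for m in big[:2]:
        froms = {mid.startswith("b") for mid in m.molecule_ids}
        assert len(froms) == 1        # no cross-region mixing


# ---------------------------------------------------------------------------
# validation

def _irregular_map(n_sites=10, seed=9):
    # irregular spacings: uniformly spaced labels carry no alignment signal
    rng = np.random.default_rng(seed)
    gaps = rng.uniform(4000, 16000, n_sites)
    sites = 5000.0 + np.cumsum(gaps) - gaps[0]
    return OpticalMap("m", sites[-1] + 5000.0, sites)


def _molecule_from(omap, lo, hi, mid):
    sel = omap.sites[(omap.sites >= lo) & (omap.sites < hi)]
    return OpticalMolecule(mid, hi - lo, sel - lo)


def test_validate_uniform_coverage_high_confidence():
    omap = _irregular_map()
    mols = [_molecule_from(omap, 0, omap.length, f"m{i}") for i in range(5)]
    out = validate_maps([omap], mols, min_support=3, p_align=1e-3)
    assert out[0].high_confidence is True


def test_validate_weak_interval_low_confidence():
    omap = _irregular_map(12)
    # molecules only cover the left or the right half; the junction
    # interval is spanned by nothing (a chimeric-join signature)
    cut = float(omap.sites[6] - 2000.0)
    mols = ([_molecule_from(omap, 0, cut, f"l{i}") for i in range(5)]
            + [_molecule_from(omap, cut, omap.length, f"r{i}")
               for i in range(5)])
    out = validate_maps([omap], mols, min_support=3, p_align=1e-3)
    assert out[0].high_confidence is False
    assert out[0].interval_support[5] < 3


# ---------------------------------------------------------------------------
# islands

def test_islands_constructed_instance(small_genome):
    genome, _ = small_genome
    # one map over [0, 500k); two scaffolds at disjoint coordinates
    omap = OpticalMap("om0", 500_000.0,
                      digest_sequence(genome[:500_000]).sites.copy())
    s1 = digest_sequence(genome[20_000:160_000], seq_id="s1")
    s2 = digest_sequence(genome[200_000:370_000], seq_id="s2")
    lonely = digest_sequence(genome[520_000:600_000], seq_id="lonely")
    params = AlignParams(max_skip=6, threshold=1e-6, seed=3)
    alignments = [a for d in (s1, s2)
                  for a in [align_digest_to_map(d, omap, params)] if a]
    assert len(alignments) == 2
    islands = build_islands([s1, s2, lonely], [omap], alignments)
    assert len(islands) == 2
    main = islands[0]
    scaffs = [c for c in main.components if c[0] == "scaffold"]
    assert [c[1] for c in scaffs] == ["s1", "s2"]
    assert all(c[2] == "+" for c in scaffs)
    assert len(main.gaps) == 1
    assert main.gaps[0]["size"] == pytest.approx(40_000, abs=2000)
    assert islands[1].components[0][1] == "lonely"


def test_scaffold_spanning_two_maps_merges_them(small_genome):
    genome, _ = small_genome
    m1 = OpticalMap("om1", 300_000.0,
                    digest_sequence(genome[:300_000]).sites.copy())
    m2 = OpticalMap("om2", 300_000.0,
                    digest_sequence(genome[300_000:600_000]).sites.copy())
    spanner = digest_sequence(genome[200_000:420_000], seq_id="spanner")
    params = AlignParams(max_skip=6, threshold=1e-4, seed=4)
    alignments = [a for m in (m1, m2)
                  for a in [align_digest_to_map(spanner, m, params)] if a]
    assert len(alignments) == 2
    islands = build_islands([spanner], [m1, m2], alignments)
    assert len(islands) == 1
    kinds = [(k, i) for k, i, *_ in islands[0].components]
    assert ("map", "om1") in kinds and ("map", "om2") in kinds
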