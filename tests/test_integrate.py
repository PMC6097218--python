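import numpy as np
import pytest

from finishkit import simulate as sim
from finishkit.integrate import (Bridge, GapRecord, KmerIndex,
                                 audit_gene_gaps, bridge_interscaffold_gaps,
                                 classify_contig_mappings, find_gap_records,
                                 fill_intrascaffold_gaps, map_reads_stringent,
                                 patch_content_flags, reduce_superscaffolds)
from finishkit.io import AgpComponent, Gff3Feature, revcomp


def _mutate(s, positions):
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    s = list(s)
    for p in positions:
        s[p] = flip[s[p]]
    return "".join(s)


# ---------------------------------------------------------------------------
# stringent mapper

@pytest.fixture(scope="module")
def target(small_genome=None):
    genome, _ = sim.simulate_genome(sim.GenomeConfig(length=150_000), seed=500)
    return genome


def test_exact_read_maps_uniquely(target):
    read = target[40_000:40_100]
    res = map_reads_stringent({"r": read}, {"chr": target})
    assert res[0].mapped and res[0].unique
    assert res[0].hits[0].target_start == 40_000


def test_two_close_mismatches_rejected(target):
    # 60 bp read with 2 mismatches 10 bp apart: no valid 50 bp HSP remains
    read = _mutate(target[10_000:10_060], [25, 35])
    res = map_reads_stringent({"r": read}, {"chr": target})
    assert not res[0].mapped


def test_short_exact_read_rejected(target):
    res = map_reads_stringent({"r": target[5000:5040]}, {"chr": target})
    assert not res[0].mapped


def test_distant_mismatches_accepted(target):
    # 120 bp read, mismatches 70 bp apart: every 50 bp window has <= 1
    read = _mutate(target[60_000:60_120], [20, 90])
    res = map_reads_stringent({"r": read}, {"chr": target})
    assert res[0].mapped


def test_reverse_strand_read_maps(target):
    res = map_reads_stringent({"r": revcomp(target[70_000:70_080])},
                              {"chr": target})
    assert res[0].mapped and res[0].hits[0].strand == "-"


def test_k_larger_than_query_rejected(target):
    with pytest.raises(ValueError):
        map_reads_stringent({"r": "ACGTACGT"}, {"chr": target}, k=13)


def test_multimapping_read_reports_all_tied_locations(target):
    dup = target[:30_000] + target[12_000:12_100] + target[30_100:]
    res = map_reads_stringent({"r": target[12_000:12_100]}, {"chr": dup})
    assert res[0].mapped and not res[0].unique
    assert len(res[0].hits) == 2


# ---------------------------------------------------------------------------
# contig classification

def test_classification_three_classes(target):
    donor = {
        "exact": target[20_000:60_000],
        "partial": target[80_000:100_000] + _mutate(target[100_000:101_000],
                                                    list(range(0, 1000, 10))),
        "unmatched": sim.simulate_genome(sim.GenomeConfig(length=10_000),
                                         seed=501)[0],
    }
    mappings, summary = classify_contig_mappings(donor, {"chr": target})
    byid = {m.contig_id: m for m in mappings}
    assert byid["exact"].mapping_class == "exact"
    assert byid["exact"].interval == (20_000, 60_000)
    assert byid["partial"].mapping_class == "partial"
    assert byid["partial"].aligned_fraction > 0.90
    assert byid["unmatched"].mapping_class == "unmatched"
    assert summary["exact"]["count"] == 1
    total = sum(summary[c]["total_length"] for c in summary)
    assert total == sum(len(s) for s in donor.values())


# ---------------------------------------------------------------------------
# gap filling

def test_fill_worked_example_with_homopolymer_flag():
    left, right = "ACGTACGT" * 4, "TTGGCCAA" * 4
    patch = "G" * 12
    donor = {"d": left + patch + right}
    target = {"s": left + "N" * 20 + right}
    fills, patched = fill_intrascaffold_gaps(target, donor)
    assert fills[0].status == "filled"
    assert fills[0].patch == patch
    assert fills[0].homopolymer == "G10+"
    assert patched["s"] == donor["d"]


def test_gc_rich_flag_at_080_threshold():
    gc, homo = patch_content_flags("GCGCGCGCGCGCGCGCG" + "ATA")
    assert gc == pytest.approx(17 / 20)
    assert gc >= 0.80 and homo is None


def test_flanks_on_different_donor_contigs_unfilled(target):
    t = {"s": target[:2000] + "N" * 30 + target[50_000:52_000]}
    donor = {"d1": target[:10_000], "d2": target[45_000:60_000]}
    fills, patched = fill_intrascaffold_gaps(t, donor)
    assert fills[0].status == "unfilled"
    assert patched["s"] == t["s"]


def test_overlapping_flank_images_reported_as_bridged_overlap(target):
    seg = target[10_000:14_000]
    # the draft doubles a region around the gap; donor carries it once
    t = {"s": seg + "N" * 10 + seg[-2500:] + target[14_000:18_000]}
    donor = {"d": seg + target[14_000:18_000]}
    fills, _ = fill_intrascaffold_gaps(t, donor)
    assert fills[0].status == "bridged-overlap"


def test_patching_conservative_outside_n_runs(target):
    draft, truth = sim.simulate_draft_assembly(
        target, sim.DraftConfig(n_scaffolds=2, n_gaps=10), seed=502)
    fills, patched = fill_intrascaffold_gaps(draft, {"genome": target})
    for name in draft:
        runs = [(g.start, g.end, f.patch) for g, f in
                ((f.gap, f) for f in fills
                 if f.gap.scaffold_id == name and f.status == "filled")]
        expect = draft[name]
        for s, e, patch in sorted(runs, reverse=True):
            expect = expect[:s] + patch + expect[e:]
        assert patched[name] == expect


def test_find_gap_records_sized_tag():
    gaps = find_gap_records({"s": "AC" + "N" * 5 + "GT" + "N" * 150 + "AA"})
    assert [(g.start, g.end, g.sized_tag) for g in gaps] == \
           [(2, 7, False), (9, 159, True)]


# ---------------------------------------------------------------------------
# bridging

def test_clean_bridge_recovers_missing_sequence(target):
    left = target[:40_000]
    right = target[60_000:100_000]
    missing = target[40_000:60_000]
    agp = [
        AgpComponent("ss1", 0, 40_000, 1, "W", component_id="scafA",
                     component_beg=0, component_end=40_000, orientation="+"),
        AgpComponent("ss1", 40_000, 40_100, 2, "U", gap_length=100,
                     gap_type="scaffold", linkage="yes", evidence="na"),
        AgpComponent("ss1", 40_100, 80_100, 3, "W", component_id="scafB",
                     component_beg=0, component_end=40_000, orientation="+"),
    ]
    bridges = bridge_interscaffold_gaps(
        agp, {"scafA": left, "scafB": right}, {"donor": target})
    assert len(bridges) == 1
    assert bridges[0].clean
    assert bridges[0].inserted_sequence == missing


def test_bridge_with_mismatched_flank_not_clean(target):
    left = _mutate(target[:40_000], [39_500])    # one mismatch in the flank
    right = target[60_000:100_000]
    pairs = [("scafA", "scafB")]
    bridges = bridge_interscaffold_gaps(
        pairs, {"scafA": left, "scafB": right}, {"donor": target})
    assert len(bridges) == 1
    assert not bridges[0].clean


def test_no_spanning_donor_no_bridge(target):
    pairs = [("scafA", "scafB")]
    bridges = bridge_interscaffold_gaps(
        pairs, {"scafA": target[:30_000], "scafB": target[60_000:90_000]},
        {"donor": target[:35_000]})
    assert bridges == []


# ---------------------------------------------------------------------------
# super-scaffold reduction

class FakeIsland:
    def __init__(self, island_id, scaffolds):
        self.island_id = island_id
        self.components = [("scaffold", sid, orient, 0.0, 0.0)
                           for sid, orient in scaffolds]


def _ss_agp(ss_id, scaffolds, part0=1):
    comps = []
    pos = 0
    for i, (sid, orient) in enumerate(scaffolds):
        comps.append(AgpComponent(ss_id, pos, pos + 1000, part0 + i, "W",
                                  component_id=sid, component_beg=0,
                                  component_end=1000, orientation=orient))
        pos += 1000
    return comps


def test_island_merges_adjacent_superscaffolds():
    agp = (_ss_agp("ss1", [("a1", "+"), ("a2", "+")])
           + _ss_agp("ss2", [("b1", "+")])
           + _ss_agp("ss3", [("c1", "+")]))
    islands = [FakeIsland("isl1", [("a2", "+"), ("b1", "+")])]
    graph, merged = reduce_superscaffolds(agp, islands)
    assert graph.components == [["ss1", "ss2"], ["ss3"]]
    objs = {c.object_id for c in merged}
    assert objs == {"ss1+ss2", "ss3"}
    # internal order preserved
    first = [c.component_id for c in merged
             if c.object_id == "ss1+ss2" and not c.is_gap]
    assert first == ["a1", "a2", "b1"]


def test_unoriented_scaffold_receives_orientation():
    agp = (_ss_agp("ss1", [("a1", "+"), ("a2", "?")])
           + _ss_agp("ss2", [("b1", "+")]))
    islands = [FakeIsland("isl1", [("a1", "+"), ("a2", "-"), ("b1", "+")])]
    graph, merged = reduce_superscaffolds(agp, islands)
    assert graph.orientation_calls == {"a2": "-"}
    # a flipped island votes through the oriented scaffolds
    islands = [FakeIsland("isl2", [("a1", "-"), ("a2", "+"), ("b1", "-")])]
    graph, _ = reduce_superscaffolds(agp, islands)
    assert graph.orientation_calls == {"a2": "-"}


def test_contradicting_island_does_not_merge():
    agp = (_ss_agp("ss1", [("a1", "+"), ("a2", "+")])
           + _ss_agp("ss2", [("b1", "+"), ("b2", "+")]))
    islands = [FakeIsland("isl1", [("a2", "+"), ("b1", "+"), ("a1", "+")])]
    graph, _ = reduce_superscaffolds(agp, islands)
    assert graph.components == [["ss1"], ["ss2"]]
    assert graph.contradictions


def test_simulated_pseudomolecule_reduction(target):
    # 6 super-scaffolds; islands span 4 junctions -> 2 components
    agp = []
    for i in range(6):
        agp += _ss_agp(f"ss{i}", [(f"s{i}a", "+"), (f"s{i}b", "?")])
    islands = [FakeIsland(f"isl{i}", [(f"s{i}b", "+"), (f"s{i+1}a", "+")])
               for i in [0, 1, 3, 4]]
    graph, merged = reduce_superscaffolds(agp, islands)
    assert graph.components == [["ss0", "ss1", "ss2"], ["ss3", "ss4", "ss5"]]
    assert set(graph.orientation_calls) == {"s0b", "s1b", "s3b", "s4b"}


# ---------------------------------------------------------------------------
# gene gap audit

def _gene_features():
    return [
        Gff3Feature("s", ".", "gene", 10, 200, ".", "+", ".", {"ID": "g1"}),
        Gff3Feature("s", ".", "mRNA", 10, 200, ".", "+", ".",
                    {"ID": "m1", "Parent": "g1"}),
        Gff3Feature("s", ".", "CDS", 20, 80, ".", "+", "0",
                    {"ID": "c1", "Parent": "m1"}),
        Gff3Feature("s", ".", "CDS", 120, 180, ".", "+", "0",
                    {"ID": "c2", "Parent": "m1"}),
    ]


def test_cds_gap_flagged_and_completed_after_patch():
    seq = "A" * 40 + "N" * 10 + "A" * 250
    asm = {"s": seq}
    report = audit_gene_gaps(_gene_features(), asm)
    assert bool(report.loc[0, "span_gap"]) and bool(report.loc[0, "cds_gap"])
    patched = {"s": seq.replace("N" * 10, "G" * 10)}
    report = audit_gene_gaps(_gene_features(), asm, patched)
    assert report.loc[0, "status"] == "completed"


def test_intron_gap_sets_span_flag_only():
    seq = "A" * 90 + "N" * 10 + "A" * 200       # N inside the intron 80..120
    report = audit_gene_gaps(_gene_features(), {"s": seq})
    assert bool(report.loc[0, "span_gap"]) and not bool(report.loc[0, "cds_gap"])


def test_feature_beyond_bounds_raises():
    with pytest.raises(ValueError):
        audit_gene_gaps(_gene_features(), {"s": "A" * 100})
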