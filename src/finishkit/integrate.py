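"""Assembly reconciliation: classify, bridge, fill, super-scaffold, audit.

A draft "target" assembly (scaffolds with N-gaps, AGP super-scaffold layout)
is reconciled against a donor "finisher" assembly.  The read/contig mapping
primitive is a stringent ungapped seed-and-extend aligner: exact k-mer seeds
are extended to maximal HSPs in which every window of hsp_len bases carries
at most max_mismatch_per_hsp mismatches (defaults k=13, one mismatch per
50 bp, minimum HSP length 50, ~98% identity).

Gap filling is conservative: an intra-scaffold N-run is replaced only when
both gap-adjacent flanks match a single donor contig exactly, uniquely, in
consistent order and orientation; everything else is reported, not applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import AgpComponent, Gff3Feature, gc_fraction, log, n_runs, revcomp

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_ints(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(kmer integer, start position) for every ACGT-only k-window."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    kv = np.zeros(n, dtype=np.int64)
    for j in range(k):
        kv = kv * 4 + codes[j:j + n]
    bad = (codes >= 4).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    nbad = cs[k:] - cs[:-k]
    ok = nbad == 0
    return kv[ok], np.nonzero(ok)[0].astype(np.int64)


class KmerIndex:
    """Sorted k-mer index over a set of target sequences."""

    def __init__(self, sequences: Mapping[str, str], k: int = 13):
        self.k = k
        self.names: list[str] = []
        self.seqs: list[str] = []
        self.codes: list[np.ndarray] = []
        kmers, positions, seqidx = [], [], []
        for i, (name, seq) in enumerate(sequences.items()):
            self.names.append(name)
            self.seqs.append(seq)
            codes = _encode(seq)
            self.codes.append(codes)
            kv, pos = _kmer_ints(codes, k)
            kmers.append(kv)
            positions.append(pos)
            seqidx.append(np.full(len(kv), i, dtype=np.int32))
        kv = np.concatenate(kmers) if kmers else np.empty(0, dtype=np.int64)
        order = np.argsort(kv, kind="stable")
        self.kmers = kv[order]
        self.positions = (np.concatenate(positions)[order]
                          if kmers else np.empty(0, dtype=np.int64))
        self.seqidx = (np.concatenate(seqidx)[order]
                       if kmers else np.empty(0, dtype=np.int32))

    def lookup(self, kmer: int) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self.kmers, kmer, "left")
        hi = np.searchsorted(self.kmers, kmer, "right")
        return self.seqidx[lo:hi], self.positions[lo:hi]


@dataclass
class HspHit:
    query_id: str
    target_id: str
    strand: str            # + / -
    query_start: int       # on the original query
    query_end: int
    target_start: int
    target_end: int
    mismatches: int

    @property
    def length(self) -> int:
        return self.query_end - self.query_start

    @property
    def score(self) -> int:
        return self.length - self.mismatches


@dataclass
class ReadMapping:
    query_id: str
    hits: list[HspHit]     # all tied best locations
    unique: bool

    @property
    def mapped(self) -> bool:
        return bool(self.hits)


def _best_segment(mismatch_pos: Sequence[int], length: int, hsp_len: int,
                  max_mm: int) -> tuple[int, int, int] | None:
    """Longest read segment in which every hsp_len window has <= max_mm
    mismatches.  Returns (start, end, mismatches_inside) or None."""
    p = list(mismatch_pos)
    violations = [(p[t], p[t + max_mm]) for t in range(len(p) - max_mm)
                  if p[t + max_mm] - p[t] < hsp_len]
    starts = [0] + [a + 1 for a, _ in violations]
    best = None
    for s in starts:
        end = length
        for a, b in violations:
            if a >= s:
                end = min(end, b)
        if end <= s:
            continue
        mm = sum(1 for x in p if s <= x < end)
        cand = (end - s, -mm, s)
        if best is None or cand > best:
            best = cand
    if best is None:
        return None
    ln, negmm, s = best
    return s, s + ln, -negmm


def map_reads_stringent(queries: Mapping[str, str], target: Mapping[str, str] | KmerIndex,
                        k: int = 13, hsp_len: int = 50,
                        max_mismatch_per_hsp: int = 1, min_len: int = 50,
                        seed_stride: int = 1) -> list[ReadMapping]:
    """Ungapped stringent seed-and-extend mapping of short queries.

    A query maps at a location iff it has an HSP of length >= min_len whose
    every hsp_len window contains <= max_mismatch_per_hsp mismatches.  All
    tied best-scoring locations are reported with a uniqueness flag.
    """
    index = target if isinstance(target, KmerIndex) else KmerIndex(target, k)
    if index.k != k:
        raise ValueError("index built with a different k")
    out = []
    for qid in queries:
        seq = queries[qid]
        if k > len(seq):
            raise ValueError(f"k={k} exceeds query {qid!r} length {len(seq)}")
        if len(seq) < min_len:
            out.append(ReadMapping(qid, [], False))
            continue
        hits: dict[tuple[int, str, int], HspHit] = {}
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            codes = _encode(s)
            kv, qpos = _kmer_ints(codes, k)
            diagonals: set[tuple[int, int]] = set()
            for kk, qp in zip(kv[::seed_stride], qpos[::seed_stride]):
                sidx, tpos = index.lookup(int(kk))
                for si, tp in zip(sidx, tpos):
                    diagonals.add((int(si), int(tp) - int(qp)))
            for si, d in diagonals:
                tcodes = index.codes[si]
                q0 = max(0, -d)
                q1 = min(len(s), len(tcodes) - d)
                if q1 - q0 < min_len:
                    continue
                tslice = tcodes[q0 + d:q1 + d]
                qslice = codes[q0:q1]
                mm = np.nonzero((tslice != qslice) | (tslice >= 4) | (qslice >= 4))[0]
                seg = _best_segment(mm.tolist(), q1 - q0, hsp_len,
                                    max_mismatch_per_hsp)
                if seg is None:
                    continue
                ss, se, nmm = seg
                if se - ss < min_len:
                    continue
                hit = HspHit(qid, index.names[si], strand, q0 + ss, q0 + se,
                             q0 + ss + d, q0 + se + d, nmm)
                if strand == "-":
                    hit.query_start = len(s) - (q0 + se)
                    hit.query_end = len(s) - (q0 + ss)
                key = (si, strand, hit.target_start)
                if key not in hits or hit.score > hits[key].score:
                    hits[key] = hit
        if not hits:
            out.append(ReadMapping(qid, [], False))
            continue
        best_score = max(h.score for h in hits.values())
        best = sorted((h for h in hits.values() if h.score == best_score),
                      key=lambda h: (h.target_id, h.target_start, h.strand))
        out.append(ReadMapping(qid, best, len(best) == 1))
    return out


# ---------------------------------------------------------------------------
# contig classification

@dataclass
class ContigMapping:
    contig_id: str
    scaffold_id: str | None
    interval: tuple[int, int] | None     # 0-based half-open on the target
    orientation: str | None
    aligned_fraction: float
    identity: float
    mapping_class: str                   # exact | partial | unmatched


def _find_exact(contig: str, target: Mapping[str, str]
                ) -> tuple[str, int, str] | None:
    for orient, probe in (("+", contig), ("-", revcomp(contig))):
        for name, seq in target.items():
            pos = seq.find(probe)
            if pos != -1:
                return name, pos, orient
    return None


def classify_contig_mappings(donor: Mapping[str, str], target: Mapping[str, str],
                             partial_threshold: float = 0.90,
                             k: int = 13, hsp_len: int = 50,
                             max_mismatch_per_hsp: int = 1,
                             seed_stride: int = 200
                             ) -> tuple[list[ContigMapping], dict]:
    """Classify donor contigs against a target assembly.

    exact: the full contig matches a target substring with no mismatch;
    partial: chained stringent HSPs cover > partial_threshold of the contig;
    unmatched: everything else.  Classes are exhaustive and exclusive.
    """
    index = KmerIndex(target, k)
    results: list[ContigMapping] = []
    for cid in donor:
        seq = donor[cid]
        exact = _find_exact(seq, target)
        if exact is not None:
            name, pos, orient = exact
            results.append(ContigMapping(cid, name, (pos, pos + len(seq)),
                                         orient, 1.0, 1.0, "exact"))
            continue
        cover = np.zeros(len(seq), dtype=bool)
        mism = 0
        best_hit = None
        # accumulate coverage over all HSPs on the dominant scaffold/strand
        hits = _all_hsps(cid, seq, index, k, hsp_len, max_mismatch_per_hsp,
                         seed_stride)
        if hits:
            from collections import Counter
            keyof = lambda h: (h.target_id, h.strand)
            dominant = Counter(keyof(h) for h in hits).most_common(1)[0][0]
            span_lo, span_hi = None, None
            for h in hits:
                if keyof(h) != dominant:
                    continue
                cover[h.query_start:h.query_end] = True
                mism += h.mismatches
                span_lo = h.target_start if span_lo is None else min(span_lo, h.target_start)
                span_hi = h.target_end if span_hi is None else max(span_hi, h.target_end)
                best_hit = h
        frac = float(cover.sum()) / len(seq) if len(seq) else 0.0
        aligned_cols = int(cover.sum())
        ident = (aligned_cols - mism) / aligned_cols if aligned_cols else 0.0
        if frac > partial_threshold and best_hit is not None:
            results.append(ContigMapping(cid, best_hit.target_id,
                                         (int(span_lo), int(span_hi)),
                                         best_hit.strand, frac, ident, "partial"))
        else:
            results.append(ContigMapping(cid, None, None, None, frac, ident,
                                         "unmatched"))
    summary = {}
    for cls in ("exact", "partial", "unmatched"):
        sel = [r for r in results if r.mapping_class == cls]
        summary[cls] = {"count": len(sel),
                        "total_length": sum(len(donor[r.contig_id]) for r in sel)}
    return results, summary


def _all_hsps(qid: str, seq: str, index: KmerIndex, k: int, hsp_len: int,
              max_mm: int, seed_stride: int) -> list[HspHit]:
    """All acceptable maximal HSPs of a long query (not only tied best)."""
    hits: dict[tuple, HspHit] = {}
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        codes = _encode(s)
        kv, qpos = _kmer_ints(codes, k)
        diagonals: set[tuple[int, int]] = set()
        for kk, qp in zip(kv[::seed_stride], qpos[::seed_stride]):
            sidx, tpos = index.lookup(int(kk))
            if len(sidx) > 50:      # repetitive seed
                continue
            for si, tp in zip(sidx, tpos):
                diagonals.add((int(si), int(tp) - int(qp)))
        for si, d in diagonals:
            tcodes = index.codes[si]
            q0 = max(0, -d)
            q1 = min(len(s), len(tcodes) - d)
            if q1 - q0 < hsp_len:
                continue
            mmv = np.nonzero((tcodes[q0 + d:q1 + d] != codes[q0:q1])
                             | (tcodes[q0 + d:q1 + d] >= 4)
                             | (codes[q0:q1] >= 4))[0]
            seg = _best_segment(mmv.tolist(), q1 - q0, hsp_len, max_mm)
            if seg is None:
                continue
            ss, se, nmm = seg
            if se - ss < hsp_len:
                continue
            hit = HspHit(qid, index.names[si], strand, q0 + ss, q0 + se,
                         q0 + ss + d, q0 + se + d, nmm)
            if strand == "-":
                hit.query_start = len(s) - (q0 + se)
                hit.query_end = len(s) - (q0 + ss)
            key = (si, strand, d)
            if key not in hits or hit.score > hits[key].score:
                hits[key] = hit
    return list(hits.values())


# ---------------------------------------------------------------------------
# gap records and filling

@dataclass
class GapRecord:
    scaffold_id: str
    start: int               # 0-based half-open N-run interval
    end: int
    declared_size: int       # N count
    sized_tag: bool = False  # runs >= 100 N, AGP "sized gap" convention

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def find_gap_records(assembly: Mapping[str, str], sized_min: int = 100
                     ) -> list[GapRecord]:
    gaps = []
    for name in assembly:
        for s, e in n_runs(assembly[name]):
            gaps.append(GapRecord(name, s, e, e - s, (e - s) >= sized_min))
    return gaps


@dataclass
class GapFill:
    gap: GapRecord
    donor_contig: str | None
    patch: str | None
    filled_length: int
    gc: float
    homopolymer: str | None      # 'G10+', 'C10+', both as 'G10+,C10+', or None
    status: str                  # filled | bridged-overlap | unfilled
    reason: str = ""


_HOMOPOLYMER_RE = {"G10+": re.compile(r"G{10,}"), "C10+": re.compile(r"C{10,}")}


def patch_content_flags(patch: str) -> tuple[float, str | None]:
    gc = gc_fraction(patch)
    tags = [tag for tag, rx in _HOMOPOLYMER_RE.items() if rx.search(patch)]
    return gc, (",".join(tags) if tags else None)


def _occurrences(needle: str, haystack: str, limit: int = 2) -> list[int]:
    found = []
    pos = haystack.find(needle)
    while pos != -1 and len(found) < limit:
        found.append(pos)
        pos = haystack.find(needle, pos + 1)
    return found


def _locate_unique(flank: str, donor: Mapping[str, str]
                   ) -> tuple[str, str, int, int] | None:
    """Unique exact location of a flank in the donor: (contig, orient,
    start, end) in + frame of the oriented donor contig.

    A palindromic flank hits the same physical locus in both orientations;
    hits are deduplicated by physical interval ('+' preferred)."""
    by_locus: dict[tuple[str, int], tuple[str, str, int, int]] = {}
    for name, seq in donor.items():
        for orient, hay in (("+", seq), ("-", revcomp(seq))):
            for pos in _occurrences(flank, hay, limit=3):
                phys = pos if orient == "+" else len(seq) - pos - len(flank)
                key = (name, phys)
                if key not in by_locus or orient == "+":
                    if key in by_locus and by_locus[key][1] == "+":
                        continue
                    by_locus[key] = (name, orient, pos, pos + len(flank))
                if len(by_locus) > 1:
                    return None
    found = list(by_locus.values())
    return found[0] if len(found) == 1 else None


def fill_intrascaffold_gaps(target: Mapping[str, str], donor: Mapping[str, str],
                            gaps: Sequence[GapRecord] | None = None,
                            flank_len: int = 1000
                            ) -> tuple[list[GapFill], dict[str, str]]:
    """Fill N-runs whose flanks map exactly and uniquely to one donor contig.

    The patch is the donor sequence between the two flank images; the
    patched assembly substitutes it for the N-run and is otherwise
    byte-identical to the target.  Gaps whose flank images overlap are
    reported as bridged-overlap; everything else stays unfilled with a
    reason code.
    """
    if gaps is None:
        gaps = find_gap_records(target)
    fills: list[GapFill] = []
    edits: dict[str, list[tuple[int, int, str]]] = {}
    for gap in gaps:
        seq = target[gap.scaffold_id]
        # flank bounded by the adjacent N-runs
        ls = gap.start
        while ls > 0 and seq[ls - 1] != "N" and gap.start - ls < flank_len:
            ls -= 1
        left = seq[ls:gap.start]
        re_ = gap.end
        while re_ < len(seq) and seq[re_] != "N" and re_ - gap.end < flank_len:
            re_ += 1
        right = seq[gap.end:re_]
        if len(left) < 20 or len(right) < 20:
            fills.append(GapFill(gap, None, None, 0, 0.0, None, "unfilled",
                                 "flank too short"))
            continue
        lloc = _locate_unique(left, donor)
        rloc = _locate_unique(right, donor)
        if lloc is None or rloc is None:
            fills.append(GapFill(gap, None, None, 0, 0.0, None, "unfilled",
                                 "flank not unique/exact in donor"))
            continue
        lc, lo, lstart, lend = lloc
        rc, ro, rstart, rend = rloc
        if lc != rc or lo != ro:
            fills.append(GapFill(gap, None, None, 0, 0.0, None, "unfilled",
                                 "flanks on different donor contigs or strands"))
            continue
        if lend > rstart:
            fills.append(GapFill(gap, lc, None, 0, 0.0, None,
                                 "bridged-overlap", "flank images overlap"))
            continue
        hay = donor[lc] if lo == "+" else revcomp(donor[lc])
        patch = hay[lend:rstart]
        if "N" in patch:
            fills.append(GapFill(gap, lc, None, 0, 0.0, None, "unfilled",
                                 "donor span contains N"))
            continue
        gc, homo = patch_content_flags(patch)
        fills.append(GapFill(gap, lc, patch, len(patch), gc, homo, "filled"))
        edits.setdefault(gap.scaffold_id, []).append((gap.start, gap.end, patch))
    patched = dict(target)
    for name, muts in edits.items():
        seq = patched[name]
        for s, e, patch in sorted(muts, reverse=True):
            seq = seq[:s] + patch + seq[e:]
        patched[name] = seq
    return fills, patched


# ---------------------------------------------------------------------------
# inter-scaffold bridging

@dataclass
class Bridge:
    left_scaffold: str
    right_scaffold: str
    donor_contig: str
    clean: bool
    inserted_sequence: str
    left_junction: int       # donor coordinate of left flank image end (+ frame)
    right_junction: int


def _locate_flank_any(flank: str, donor: Mapping[str, str],
                      index: KmerIndex | None, k: int
                      ) -> list[tuple[str, str, int, int, bool]]:
    """All locations of a flank in donor contigs; exact matches first, else
    stringent HSPs covering >= 90% of the flank.  (contig, orient, start,
    end, exact) in the oriented + frame."""
    found = []
    for name, seq in donor.items():
        for orient, hay in (("+", seq), ("-", revcomp(seq))):
            for pos in _occurrences(flank, hay, limit=4):
                found.append((name, orient, pos, pos + len(flank), True))
    if found:
        return found
    if index is None:
        return []
    hits = _all_hsps("flank", flank, index, k, 50, 1, seed_stride=25)
    for h in sorted(hits, key=lambda h: -h.score):
        if h.length >= 0.9 * len(flank):
            if h.strand == "+":
                start = h.target_start - h.query_start
            else:
                tlen = len(donor[h.target_id])
                start = (tlen - h.target_end) - h.query_start
            found.append((h.target_id, h.strand, start, start + len(flank), False))
    return found


def bridge_interscaffold_gaps(scaffold_order: Sequence[tuple[str, str]] | Sequence[AgpComponent],
                              target: Mapping[str, str],
                              donor: Mapping[str, str],
                              flank_len: int = 1000,
                              k: int = 13) -> list[Bridge]:
    """Bridge adjacent scaffold pairs with a donor contig spanning both ends.

    scaffold_order: either AGP components (adjacency within each object) or
    explicit (left_scaffold, right_scaffold) pairs.  A Bridge is emitted when
    one donor contig carries the terminal flank of the left scaffold and the
    leading flank of the right scaffold in consistent order and orientation;
    clean iff both flanks match exactly.  Conflicting candidates are all
    reported, none applied.
    """
    pairs: list[tuple[str, str]] = []
    if scaffold_order and isinstance(scaffold_order[0], AgpComponent):
        by_obj: dict[str, list[AgpComponent]] = {}
        for c in scaffold_order:
            if not c.is_gap:
                by_obj.setdefault(c.object_id, []).append(c)
        for comps in by_obj.values():
            comps.sort(key=lambda c: c.part_number)
            for a, b in zip(comps, comps[1:]):
                pairs.append((a.component_id, b.component_id))
    else:
        pairs = [tuple(p) for p in scaffold_order]

    index = KmerIndex(donor, k)
    bridges: list[Bridge] = []
    for left_id, right_id in pairs:
        lseq = target[left_id].rstrip("N")
        rseq = target[right_id].lstrip("N")
        left = lseq[-flank_len:]
        right = rseq[:flank_len]
        if len(left) < 50 or len(right) < 50:
            continue
        lhits = _locate_flank_any(left, donor, index, k)
        rhits = _locate_flank_any(right, donor, index, k)
        cands = []
        for lc, lo, ls, le, lex in lhits:
            for rc, ro, rs, rend, rex in rhits:
                if lc == rc and lo == ro and le <= rs:
                    cands.append((lc, lo, le, rs, lex and rex))
        if len(cands) > 1:
            log(f"bridge: {len(cands)} conflicting donor candidates for "
                f"{left_id}|{right_id}; reporting all, applying none")
        for lc, lo, le, rs, clean in sorted(cands):
            hay = donor[lc] if lo == "+" else revcomp(donor[lc])
            bridges.append(Bridge(left_id, right_id, lc, clean, hay[le:rs],
                                  le, rs))
    return bridges


# ---------------------------------------------------------------------------
# super-scaffold reduction

@dataclass
class SuperScaffoldGraph:
    edges: list[tuple[str, str, str]]          # (ss_a, ss_b, evidence id)
    components: list[list[str]]                # merged super-scaffold groups
    orientation_calls: dict[str, str]          # scaffold -> +/- newly oriented
    contradictions: list[str] = field(default_factory=list)


def reduce_superscaffolds(superscaffolds: Sequence[AgpComponent],
                          islands: Sequence,
                          physical_placements: Mapping[str, Sequence[str]] | None = None
                          ) -> tuple[SuperScaffoldGraph, list[AgpComponent]]:
    """Merge adjacent super-scaffolds joined by island (or physical-contig)
    evidence and orient previously unoriented scaffolds.

    superscaffolds: AGP describing each super-scaffold's ordered scaffolds;
    super-scaffold order along the chromosome follows first appearance.
    islands: Island objects whose scaffold components sit on the target
    scaffolds.  physical_placements: optional {contig_id: [scaffold ids]}.
    """
    order: list[str] = []
    members: dict[str, list[AgpComponent]] = {}
    for c in superscaffolds:
        if c.object_id not in members:
            members[c.object_id] = []
            order.append(c.object_id)
        if not c.is_gap:
            members[c.object_id].append(c)
    for comps in members.values():
        comps.sort(key=lambda c: c.part_number)
    scaffold_to_ss = {c.component_id: obj for obj, comps in members.items()
                      for c in comps}

    evidence_groups: list[tuple[str, list[str], dict[str, str]]] = []
    for isl in islands:
        scafs = [(cid, orient) for kind, cid, orient, *_ in isl.components
                 if kind == "scaffold"]
        evidence_groups.append((isl.island_id, [c for c, _ in scafs],
                                dict(scafs)))
    if physical_placements:
        for pid, scafs in physical_placements.items():
            evidence_groups.append((pid, list(scafs), {}))

    edges: list[tuple[str, str, str]] = []
    contradictions: list[str] = []
    parent = {ss: ss for ss in order}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pos_of = {ss: i for i, ss in enumerate(order)}
    for ev_id, scafs, _orients in evidence_groups:
        touched = [scaffold_to_ss[s] for s in scafs if s in scaffold_to_ss]
        seen = sorted(set(touched), key=pos_of.get)
        for a, b in zip(seen, seen[1:]):
            if pos_of[b] - pos_of[a] != 1:
                continue       # evidence must span an adjacent junction
            # order consistency: all of a's scaffolds before b's (or all after)
            ia = [i for i, s in enumerate(scafs) if scaffold_to_ss.get(s) == a]
            ib = [i for i, s in enumerate(scafs) if scaffold_to_ss.get(s) == b]
            if max(ia) < min(ib) or max(ib) < min(ia):
                edges.append((a, b, ev_id))
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
            else:
                contradictions.append(
                    f"{ev_id}: interleaved scaffolds across {a}|{b}, no merge")
                log(f"reduce_superscaffolds: {contradictions[-1]}")

    groups: dict[str, list[str]] = {}
    for ss in order:
        groups.setdefault(find(ss), []).append(ss)
    components = [sorted(g, key=pos_of.get) for g in
                  sorted(groups.values(), key=lambda g: pos_of[g[0]])]

    # orientation calls for '?' scaffolds covered by island components
    orientation_calls: dict[str, str] = {}
    agp_orient = {c.component_id: c.orientation
                  for comps in members.values() for c in comps}
    for ev_id, scafs, orients in evidence_groups:
        if not orients:
            continue
        votes = []
        for s, o in orients.items():
            known = agp_orient.get(s)
            if known in ("+", "-"):
                votes.append(1 if known == o else -1)
        sign = 1 if sum(votes) >= 0 else -1
        for s, o in orients.items():
            if agp_orient.get(s) in ("?", "na", None) and s in scaffold_to_ss:
                call = o if sign == 1 else ("-" if o == "+" else "+")
                orientation_calls[s] = call

    merged: list[AgpComponent] = []
    for group in components:
        obj = "+".join(group)
        pos = 0
        part = 1
        for gi, ss in enumerate(group):
            for c in members[ss]:
                length = c.object_end - c.object_beg
                orient = orientation_calls.get(c.component_id, c.orientation)
                merged.append(AgpComponent(obj, pos, pos + length, part, "W",
                                           component_id=c.component_id,
                                           component_beg=c.component_beg,
                                           component_end=c.component_end,
                                           orientation=orient))
                pos += length
                part += 1
            if gi < len(group) - 1:
                merged.append(AgpComponent(obj, pos, pos + 100, part, "U",
                                           gap_length=100, gap_type="scaffold",
                                           linkage="yes", evidence="map"))
                pos += 100
                part += 1
    graph = SuperScaffoldGraph(edges, components, orientation_calls,
                               contradictions)
    return graph, merged


# ---------------------------------------------------------------------------
# gene gap audit

def audit_gene_gaps(features: Sequence[Gff3Feature], assembly: Mapping[str, str],
                    patched: Mapping[str, str] | None = None):
    """Per-gene N-gap audit: genomic-span and CDS flags, plus completion
    status against a patched assembly when supplied."""
    import pandas as pd
    genes = [f for f in features if f.ftype == "gene"]
    mrnas_by_gene: dict[str, list[str]] = {}
    cds_by_mrna: dict[str, list[tuple[str, int, int]]] = {}
    for f in features:
        if f.ftype == "mRNA" and f.parent:
            mrnas_by_gene.setdefault(f.parent, []).append(f.id)
        if f.ftype == "CDS" and f.parent:
            cds_by_mrna.setdefault(f.parent, []).append((f.seqid, f.start, f.end))
    rows = []
    for g in genes:
        if g.seqid not in assembly:
            raise ValueError(f"gene {g.id}: unknown sequence {g.seqid}")
        if g.end > len(assembly[g.seqid]):
            raise ValueError(f"gene {g.id}: span beyond {g.seqid} bounds")
        cds_ivs = [iv for m in mrnas_by_gene.get(g.id, [])
                   for iv in cds_by_mrna.get(m, [])]

        def has_n(asm, ivs):
            return any("N" in asm[s][a:b] for s, a, b in ivs)

        span_iv = [(g.seqid, g.start, g.end)]
        span_gap = has_n(assembly, span_iv)
        cds_gap = has_n(assembly, cds_ivs)
        status = ""
        if patched is not None and (span_gap or cds_gap):
            still = has_n(patched, cds_ivs) if cds_gap else has_n(patched, span_iv)
            status = "still-gapped" if still else "completed"
        rows.append({"gene_id": g.id, "seqid": g.seqid,
                     "start": g.start, "end": g.end,
                     "span_gap": span_gap, "cds_gap": cds_gap,
                     "confidence": g.attributes.get("confidence", ""),
                     "status": status})
    return pd.DataFrame(rows)
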