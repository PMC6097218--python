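"""BAC fingerprint physical mapping.

Clones are characterised by multi-channel restriction fragment size lists
("fingerprints").  Overlap between two clones is scored with the Sulston
probability of sharing at least the observed number of bands by chance; a
thresholded overlap network is assembled into ordered physical contigs, with
questionable (Q-) clones flagged, and a minimum tiling path (MTP) is selected
per contig by greedy furthest-reach interval covering.

Fragment encoding follows the four-dye convention in which an encoded value
v carries the dye channel in its ten-thousands digit: channel 0 (blue) has
offset 0, green 10,000, yellow 20,000 and red 30,000, so v = offset + size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import binom

from .io import FormatError, provenance_header

CHANNELS = ("blue", "green", "yellow", "red")
_CHANNEL_OFFSET = {c: 10000 * i for i, c in enumerate(CHANNELS)}


@dataclass(frozen=True)
class Fragment:
    """A single sized restriction fragment in one dye channel."""
    channel: str
    size: float

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.size <= 0:
            raise ValueError(f"fragment size must be positive, got {self.size}")

    @property
    def encoded(self) -> int:
        return _CHANNEL_OFFSET[self.channel] + int(round(self.size))


@dataclass
class CloneFingerprint:
    clone_id: str
    fragments: list[Fragment]

    def __post_init__(self):
        if not self.fragments:
            raise ValueError(f"clone {self.clone_id!r} has no fragments")

    def __len__(self) -> int:
        return len(self.fragments)

    def sizes_by_channel(self) -> dict[str, np.ndarray]:
        out: dict[str, list[float]] = {}
        for f in self.fragments:
            out.setdefault(f.channel, []).append(f.size)
        return {c: np.sort(np.asarray(v)) for c, v in out.items()}


class FingerprintSet(dict):
    """Mapping clone_id -> CloneFingerprint with uniqueness enforced."""

    def add(self, fp: CloneFingerprint) -> None:
        if fp.clone_id in self:
            raise FormatError(f"duplicate clone_id {fp.clone_id!r}")
        self[fp.clone_id] = fp


def decode_fragment(value: int | float) -> Fragment:
    """Decode an offset-encoded fragment number into (channel, size)."""
    v = float(value)
    if v <= 0 or v >= 40000:
        raise FormatError(f"encoded fragment value {value} out of range (0, 40000)")
    channel = CHANNELS[int(v // 10000)]
    size = v % 10000
    if size == 0:
        raise FormatError(f"encoded fragment value {value} has zero size")
    return Fragment(channel, size)


def parse_fingerprints(path: str | Path) -> FingerprintSet:
    """Parse the offset-encoded fingerprint TSV dialect.

    One clone per line: ``clone_id<TAB>v1,v2,...`` where each v is
    channel_offset + fragment_size.
    """
    fps = FingerprintSet()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[1].strip():
                raise FormatError(f"{path}:{ln}: clone {parts[0]!r} has no fragments")
            clone_id = parts[0].strip()
            try:
                frags = [decode_fragment(float(x)) for x in parts[1].split(",") if x.strip()]
            except FormatError as e:
                raise FormatError(f"{path}:{ln}: {e}") from None
            if not frags:
                raise FormatError(f"{path}:{ln}: clone {clone_id!r} has no fragments")
            if clone_id in fps:
                raise FormatError(f"{path}:{ln}: duplicate clone_id {clone_id!r}")
            fps.add(CloneFingerprint(clone_id, frags))
    return fps


def write_fingerprints(fps: FingerprintSet, path: str | Path,
                       seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed) + "\n")
        for clone_id in fps:
            encoded = ",".join(str(f.encoded) for f in fps[clone_id].fragments)
            fh.write(f"{clone_id}\t{encoded}\n")


# ---------------------------------------------------------------------------
# Sulston overlap scoring

def _greedy_match(a: np.ndarray, b: np.ndarray, tolerance: float) -> int:
    """One-to-one greedy matching of two sorted size arrays within tolerance."""
    i = j = k = 0
    while i < len(a) and j < len(b):
        d = a[i] - b[j]
        if abs(d) <= tolerance:
            k += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return k


def shared_bands(a: CloneFingerprint, b: CloneFingerprint, tolerance: float) -> int:
    """Number of bands shared between two fingerprints, matched per channel."""
    sa, sb = a.sizes_by_channel(), b.sizes_by_channel()
    return sum(_greedy_match(sa[c], sb[c], tolerance) for c in sa if c in sb)


def sulston_score(a: CloneFingerprint, b: CloneFingerprint,
                  tolerance: float = 1.0, gel_bins: int = 3000) -> float:
    """Probability of observing >= k shared bands by chance.

    Under the standard model each of the n_low bands of the smaller
    fingerprint independently matches some band of the larger one with
    probability p = 1 - (1 - 2*tolerance/gel_bins)**n_high; the score is the
    upper binomial tail at the observed shared-band count.  Low scores
    indicate genuine clone overlap.
    """
    if tolerance <= 0 or gel_bins <= 0:
        raise ValueError("tolerance and gel_bins must be positive")
    if not a.fragments or not b.fragments:
        raise ValueError("cannot score empty fingerprints")
    k = shared_bands(a, b, tolerance)
    n_low, n_high = min(len(a), len(b)), max(len(a), len(b))
    p_match = 1.0 - (1.0 - 2.0 * tolerance / gel_bins) ** n_high
    p_match = min(max(p_match, 0.0), 1.0)
    return float(binom.sf(k - 1, n_low, p_match))


# ---------------------------------------------------------------------------
# overlap network and contig assembly

def build_overlap_network(fps: FingerprintSet, cutoff: float = 1e-10,
                          tolerance: float = 1.0, gel_bins: int = 3000,
                          order_cutoff: float = 1e-2) -> nx.Graph:
    """Undirected clone graph with an edge wherever sulston_score <= cutoff.

    Pairs that miss the edge cutoff but score <= order_cutoff are kept in
    graph metadata ("order_pairs": excess shared bands over chance) -- they
    carry no topology but provide long-baseline evidence when ordering
    clones within a contig.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1)")
    g = nx.Graph(cutoff=cutoff, tolerance=tolerance, gel_bins=gel_bins)
    ids = list(fps)
    g.add_nodes_from(ids)
    by_channel = {cid: fps[cid].sizes_by_channel() for cid in ids}
    counts = {cid: len(fps[cid]) for cid in ids}
    g.graph["n_bands"] = counts
    order_pairs: dict[tuple[str, str], float] = {}
    for x in range(len(ids)):
        ca = ids[x]
        sa = by_channel[ca]
        for y in range(x + 1, len(ids)):
            cb = ids[y]
            sb = by_channel[cb]
            k = sum(_greedy_match(sa[c], sb[c], tolerance) for c in sa if c in sb)
            if k == 0:
                continue
            n_low = min(counts[ca], counts[cb])
            n_high = max(counts[ca], counts[cb])
            p_match = 1.0 - (1.0 - 2.0 * tolerance / gel_bins) ** n_high
            p_match = min(max(p_match, 0.0), 1.0)
            score = float(binom.sf(k - 1, n_low, p_match))
            if score <= max(order_cutoff, cutoff):
                key = (ca, cb) if ca < cb else (cb, ca)
                order_pairs[key] = k - p_match * n_low
            if score <= cutoff:
                # expected chance matches: used as a seriation baseline
                g.add_edge(ca, cb, score=score, shared_bands=k,
                           expected_bands=p_match * n_low)
    g.graph["order_pairs"] = order_pairs
    return g


@dataclass
class PhysicalContig:
    contig_id: str
    clones: list[str]                       # ordered
    coordinates: dict[str, tuple[float, float]]  # clone -> (start, end)
    q_clones: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.clones)

    @property
    def span(self) -> tuple[float, float]:
        starts = [self.coordinates[c][0] for c in self.clones]
        ends = [self.coordinates[c][1] for c in self.clones]
        return min(starts), max(ends)


@dataclass
class PhysicalAssembly:
    contigs: list[PhysicalContig]
    q_clones: set[str]
    unplaced: set[str]       # singletons and sub-threshold components


def _find_q_clones(g: nx.Graph, radius: int = 4) -> set[str]:
    """Clones joining two otherwise-unlinked clone groups.

    A clone is questionable when its neighbour set splits into >= 2 connected
    groups of >= 2 clones that cannot reach each other within `radius` hops
    once the clone is removed.  An articulation clone separating two parts of
    >= 2 clones is the unreachable-at-any-distance special case; the finite
    radius additionally catches chimeric clones that short-circuit two
    distant stretches of one connected tiling.
    """
    q: set[str] = set()
    for comp in nx.connected_components(g):
        if len(comp) < 4:
            continue
        sub = g.subgraph(comp)
        for v in sorted(comp):
            nbrs = set(sub.neighbors(v))
            if len(nbrs) < 3:
                continue
            # a second chimera among the neighbours can mask the split, so
            # the test is repeated with each single neighbour withheld
            for held in [None] + sorted(nbrs):
                probe = nbrs - {held} if held else nbrs
                if len(probe) < 3:
                    continue
                groups = sorted(nx.connected_components(sub.subgraph(probe)),
                                key=lambda p: (-len(p), sorted(p)[0]))
                if len(groups) < 2 or len(groups[0]) < 2:
                    continue
                without = sub.subgraph(comp - {v} - ({held} if held else set()))
                if not _groups_linked(without, groups, radius):
                    q.add(v)
                    break
    return q


def _groups_linked(g: nx.Graph, groups: list[set], radius: int) -> bool:
    """True iff every pair of groups is within `radius` hops in g."""
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            seen = set(groups[gi])
            frontier = set(groups[gi])
            found = bool(frontier & groups[gj])
            for _ in range(radius):
                if found:
                    break
                frontier = {w for u in frontier for w in g.neighbors(u)} - seen
                if not frontier:
                    break
                seen |= frontier
                if frontier & groups[gj]:
                    found = True
            if not found:
                return False
    return True


def _split_thin_junctions(g: nx.Graph, comp: set, cutoff: float,
                          max_junction_edges: int = 2,
                          min_part: int = 5) -> None:
    """Cut weak joins exposed by a stricter cutoff.

    Clone groups that stay connected under edges <= cutoff are contracted;
    two groups are separated only when (a) at most max_junction_edges weak
    edges bridge them -- a thin junction is evidence of a spurious or
    chimeric join, whereas many sub-threshold edges across a cut merely
    reflect stringency attrition inside a genuine contig -- and (b) both
    sides keep >= min_part clones, so stragglers are never shed.
    """
    sub = g.subgraph(comp)
    strong = nx.Graph()
    strong.add_nodes_from(sorted(comp))
    strong.add_edges_from((u, v) for u, v, d in sub.edges(data=True)
                          if d["score"] <= cutoff)
    parts = sorted(nx.connected_components(strong), key=lambda p: sorted(p)[0])
    if len(parts) < 2:
        return
    part_of = {}
    for i, p in enumerate(parts):
        for v in p:
            part_of[v] = i
    bundles: dict[tuple[int, int], list[tuple[str, str]]] = {}
    for u, v, d in sub.edges(data=True):
        pu, pv = part_of[u], part_of[v]
        if pu != pv:
            bundles.setdefault((min(pu, pv), max(pu, pv)), []).append((u, v))
    parent = list(range(len(parts)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # wide (trustworthy) bundles keep their parts together
    for (pu, pv), edges in sorted(bundles.items()):
        if len(edges) > max_junction_edges:
            parent[find(pu)] = find(pv)
    # grow groups until every group reaches min_part or nothing changes:
    # a sub-minimum group rejoins via its widest remaining bundle
    changed = True
    while changed:
        changed = False
        size: dict[int, int] = {}
        for i, p in enumerate(parts):
            size[find(i)] = size.get(find(i), 0) + len(p)
        for (pu, pv), edges in sorted(bundles.items(),
                                      key=lambda kv: (-len(kv[1]), kv[0])):
            ru, rv = find(pu), find(pv)
            if ru != rv and (size[ru] < min_part or size[rv] < min_part):
                parent[ru] = rv
                changed = True
                break
    for (pu, pv), edges in sorted(bundles.items()):
        if find(pu) != find(pv):
            g.remove_edges_from(edges)


def _spectral_order(sub: nx.Graph, weight: str = "shared_bands") -> list[str]:
    """Seriation by the Fiedler vector of the weighted graph Laplacian.

    Deterministic: nodes are indexed in sorted order, eigenvectors come from
    a symmetric dense solver, ties and the reflection ambiguity are broken by
    clone_id.
    """
    nodes = sorted(sub.nodes)
    if len(nodes) <= 2:
        return nodes
    idx = {n: i for i, n in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for u, v, d in sub.edges(data=True):
        # excess over chance sharpens the seriation signal
        val = float(d.get(weight, 1.0)) - float(d.get("expected_bands", 0.0))
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = max(val, 0.1)
    lap = np.diag(w.sum(axis=1)) - w
    vals, vecs = np.linalg.eigh(lap)
    fiedler = vecs[:, 1]
    order = sorted(range(len(nodes)), key=lambda i: (fiedler[i], nodes[i]))
    order = _refine_order(order, w)
    ordered = [nodes[i] for i in order]
    if ordered[0] > ordered[-1]:
        ordered.reverse()
    return ordered


def _refine_order(order: list[int], w: np.ndarray, max_rounds: int = 50
                  ) -> list[int]:
    """Adjacent-swap hill climbing on the seriation stress
    sum_ij w_ij (pos_i - pos_j)^2, polishing local inversions left by the
    spectral solution.  Deterministic."""
    n = len(order)
    pos = np.empty(n)
    pos[order] = np.arange(n)

    def stress_delta(a: int, b: int) -> float:
        # change in stress when a and b trade positions (a-b term invariant)
        pa, pb = pos[a], pos[b]
        v = (pb - pos) ** 2 - (pa - pos) ** 2
        delta = float((w[a] - w[b]) @ v)
        delta += 2.0 * w[a, b] * (pb - pa) ** 2    # undo the a/b cross terms
        return delta

    for _ in range(max_rounds):
        improved = False
        for i in range(n - 1):
            a, b = order[i], order[i + 1]
            if stress_delta(a, b) < -1e-12:
                order[i], order[i + 1] = b, a
                pos[a], pos[b] = pos[b], pos[a]
                improved = True
        if not improved:
            break
    return order


def _witness_refine(order: list[str], order_pairs: Mapping[tuple[str, str], float],
                    all_ids: Sequence[str], max_pass: int = 80) -> list[str]:
    """Polish a clone order with long-baseline overlap votes.

    For each adjacent pair, every other clone D votes on the orientation of
    the pair by the difference of its excess shared bands with the two
    clones, signed by which side of the pair D lies on.  Clones outside the
    contig ("witnesses") get their side from the sign of the correlation
    between their excess-band profile and the current positions.  Adjacent
    pairs are swapped while the net vote favours it; deterministic.
    """
    def kx(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        return order_pairs.get(key, 0.0)

    order = list(order)
    n = len(order)
    if n < 3:
        return order
    members = set(order)
    for _ in range(max_pass):
        swapped = False
        ext: list[tuple[str, float]] = []
        for d in all_ids:
            if d in members:
                continue
            ks = np.array([kx(d, m) for m in order])
            if (ks > 0).sum() < 2 or ks.std() == 0:
                continue
            r = np.corrcoef(np.arange(n), ks)[0, 1]
            if abs(r) > 0.4:
                ext.append((d, 1.0 if r > 0 else -1.0))
        for i in range(n - 1):
            a, b = order[i], order[i + 1]
            vote = 0.0
            for j, d in enumerate(order):
                if d in (a, b):
                    continue
                side = -1.0 if j < i else 1.0
                vote += side * (kx(b, d) - kx(a, d))
            for d, side in ext:
                vote += side * (kx(b, d) - kx(a, d))
            if vote < 0:
                order[i], order[i + 1] = b, a
                swapped = True
        if not swapped:
            break
    return order


_RETENTION = 0.75   # expected fraction of bands surviving matching at full overlap


def _stack_runs(order: Sequence[str], pairs: Mapping, nb: Mapping[str, int],
                thresh: float = 0.45) -> list[tuple[int, int]]:
    """Maximal runs of consecutive clones that all mutually overlap deeply."""
    def kx(a, b):
        key = (a, b) if a < b else (b, a)
        return pairs.get(key, 0.0)

    runs = []
    i, n = 0, len(order)
    while i < n:
        j = i + 1
        while j < n and all(
                kx(order[x], order[j]) >= thresh * _RETENTION
                * min(nb[order[x]], nb[order[j]]) for x in range(i, j)):
            j += 1
        if j - i >= 3:
            runs.append((i, j))
        i = max(j, i + 1)
    return runs


def _stack_reorder(order: list[str], lo: int, hi: int, pairs: Mapping,
                   nb: Mapping[str, int], all_ids: Sequence[str]) -> list[str]:
    """Re-order a deep stack of mutually overlapping clones by estimated
    midpoints.

    Within a stack, member-member overlaps are saturated (nested clones) and
    carry little order information; flanking witnesses do.  A right-side
    witness's excess shared bands grow with the member's end coordinate and
    a left-side witness's with the negated start, so midpoints follow from
    averaged witness profiles -- two-sided: (P_right - P_left)/2; one-sided:
    P/retention - clone_length/2, which cancels the clone-length confound.
    """
    def kx(a, b):
        key = (a, b) if a < b else (b, a)
        return pairs.get(key, 0.0)

    run = order[lo:hi]
    rset = set(run)
    wit: dict[str, np.ndarray] = {}
    for d in all_ids:
        if d in rset:
            continue
        prof = np.array([kx(d, m) for m in run])
        if (prof > 0).sum() >= 2:
            wit[d] = prof
    if not wit:
        return run
    sides: dict[str, float] = {}
    in_order = {c: i for i, c in enumerate(order)}
    for d in wit:
        if d in in_order:                      # same contig: side is known
            sides[d] = -1.0 if in_order[d] < lo else 1.0
    nvec = np.array([nb[m] for m in run], dtype=float)

    def estimate(smap: Mapping[str, float]) -> np.ndarray:
        """Midpoint estimates: a right witness's profile tracks member ends,
        a left witness's the negated starts; averaging both cancels the
        clone-length confound, one-sided profiles subtract half the length
        (band count) instead."""
        plus = [wit[d] for d, s in smap.items() if s > 0]
        minus = [wit[d] for d, s in smap.items() if s < 0]
        if plus and minus:
            return (np.mean(plus, axis=0) - np.mean(minus, axis=0)) / (2 * _RETENTION)
        if plus:
            return np.mean(plus, axis=0) / _RETENTION - nvec / 2
        if minus:
            return -np.mean(minus, axis=0) / _RETENTION + nvec / 2
        return np.arange(len(run), dtype=float)

    prelim = estimate(sides) if sides else np.arange(len(run), dtype=float)
    for d in sorted(wit):
        if d not in sides:
            prof = wit[d]
            if prof.std() > 0 and prelim.std() > 0:
                c = float(np.corrcoef(prelim, prof)[0, 1])
                sides[d] = 1.0 if c > 0 else -1.0
    m = estimate(sides)
    if not any(d in in_order for d in sides):
        # no anchored witness: orientation is relative; keep the incoming one
        if m.std() > 0 and float(np.corrcoef(m, np.arange(len(run)))[0, 1]) < 0:
            m = -m
    return [c for _, c in sorted(zip(m, run), key=lambda t: (t[0], t[1]))]


def _infer_coordinates(order: Sequence[str], fps_len: Mapping[str, int],
                       g: nx.Graph, band_unit: float = 1.0,
                       order_pairs: Mapping[tuple[str, str], float] | None = None,
                       retention: float = 0.75
                       ) -> dict[str, tuple[float, float]]:
    """Linear coordinates from estimated clone lengths and overlap fractions.

    Clone length is proportional to its band count; consecutive-clone offset
    comes from the excess-shared-band overlap fraction (retention is the
    expected fraction of bands surviving size matching at full overlap).
    Units are arbitrary band units.
    """
    coords: dict[str, tuple[float, float]] = {}
    pos = 0.0
    prev = None
    for cid in order:
        length = fps_len[cid] * band_unit
        if prev is not None:
            n_min = max(1, min(fps_len[prev], fps_len[cid]))
            if order_pairs is not None:
                key = (prev, cid) if prev < cid else (cid, prev)
                kex = order_pairs.get(key, 0.0)
            elif g.has_edge(prev, cid):
                d = g.edges[prev, cid]
                kex = d["shared_bands"] - d.get("expected_bands", 0.0)
            else:
                kex = 0.0
            frac = min(1.0, max(0.0, kex / (retention * n_min)))
            pos = coords[prev][0] + fps_len[prev] * band_unit * (1.0 - frac)
            pos = max(pos, coords[prev][0])   # non-decreasing starts
        coords[cid] = (pos, pos + length)
        prev = cid
    return coords


def assemble_physical_contigs(graph: nx.Graph, n_iterations: int = 5,
                              stringency_factor: float = 1e-5,
                              min_clones: int = 5,
                              band_outlier_factor: float = 1.5) -> PhysicalAssembly:
    """Iteratively refine the overlap network into ordered physical contigs.

    Clones with a band count above band_outlier_factor times the library
    median are flagged questionable up front (the signature of two
    co-ligated inserts).  Then, at iteration i, the effective cutoff is
    cutoff * stringency_factor**i: thin weak junctions exposed by the
    stricter cutoff are split, and Q-clones -- clones joining two otherwise
    unconnected groups -- are flagged at each step and excluded from
    ordering.  Components below min_clones are reported as unplaced.
    """
    base_cutoff = graph.graph.get("cutoff", 1e-10)
    g = graph.copy()
    all_clones = set(g.nodes)
    q_clones: set[str] = set()

    n_bands_all = graph.graph.get("n_bands")
    if n_bands_all:
        med = float(np.median(list(n_bands_all.values())))
        outliers = {c for c in g.nodes
                    if n_bands_all[c] > band_outlier_factor * med}
        q_clones |= outliers
        g.remove_nodes_from(outliers)

    for it in range(1, n_iterations + 1):
        newq = _find_q_clones(g)
        q_clones |= newq
        g.remove_nodes_from(newq)
        cutoff_i = base_cutoff * stringency_factor ** it
        for comp in sorted(nx.connected_components(g),
                           key=lambda c: sorted(c)[0]):
            if len(comp) < 2:
                continue
            _split_thin_junctions(g, comp, cutoff_i, min_part=min_clones)
    q_clones |= _find_q_clones(g)
    g.remove_nodes_from(q_clones & set(g.nodes))

    contigs: list[PhysicalContig] = []
    unplaced: set[str] = set()
    components = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    n_bands = graph.graph.get("n_bands")   # optional: clone_id -> band count
    order_pairs = graph.graph.get("order_pairs", {})
    all_ids = sorted(graph.nodes)
    for comp in components:
        if len(comp) < min_clones:
            unplaced |= comp
            continue
        sub = g.subgraph(comp)
        order = _spectral_order(sub)
        if order_pairs:
            order = _witness_refine(order, order_pairs, all_ids)
            nb = n_bands or {c: 100 for c in order}
            for lo, hi in _stack_runs(order, order_pairs, nb):
                order[lo:hi] = _stack_reorder(order, lo, hi, order_pairs,
                                              nb, all_ids)
        lens = {c: (n_bands[c] if n_bands else 100) for c in order}
        coords = _infer_coordinates(order, lens, sub, order_pairs=order_pairs)
        contigs.append(PhysicalContig(f"ctg{len(contigs):04d}", order, coords))

    # attach each Q-clone to the contig holding most of its former neighbours
    for q in sorted(q_clones):
        best, best_n = None, 0
        nbrs = set(graph.neighbors(q))
        for ctg in contigs:
            n = len(nbrs & set(ctg.clones))
            if n > best_n:
                best, best_n = ctg, n
        if best is not None:
            best.q_clones.add(q)

    placed = set().union(*[set(c.clones) for c in contigs]) if contigs else set()
    unplaced |= all_clones - placed - q_clones
    return PhysicalAssembly(contigs, q_clones, unplaced)


# ---------------------------------------------------------------------------
# minimum tiling path

@dataclass
class MinimumTilingPath:
    contig_id: str
    clones: list[str]


def select_mtp(contig: PhysicalContig, graph: nx.Graph) -> MinimumTilingPath:
    """Greedy furthest-reach interval cover over the contig's coordinates.

    Consecutive MTP clones must share a significant overlap edge in the
    graph; ties are broken by smaller clone_id.  Greedy furthest-reach is
    optimal for interval covering.
    """
    if not contig.coordinates:
        raise ValueError(f"contig {contig.contig_id} has no inferred coordinates")
    clones = [c for c in contig.clones if c not in contig.q_clones]
    if len(clones) == 1:
        return MinimumTilingPath(contig.contig_id, clones)
    span_start, span_end = contig.span
    # first clone: covers the leftmost start, reaches furthest right
    first = min(clones, key=lambda c: (contig.coordinates[c][0],
                                       -contig.coordinates[c][1], c))
    path = [first]
    covered = contig.coordinates[first][1]
    while covered < span_end:
        last = path[-1]
        cands = [c for c in clones if c not in path
                 and contig.coordinates[c][0] <= covered
                 and contig.coordinates[c][1] > covered
                 and graph.has_edge(last, c)]
        if not cands:
            # fall back to any overlapping clone (disconnected coordinate gap)
            cands = [c for c in clones if c not in path
                     and contig.coordinates[c][0] <= covered
                     and contig.coordinates[c][1] > covered]
        if not cands:
            break
        nxt = max(cands, key=lambda c: (contig.coordinates[c][1],))
        best_end = contig.coordinates[nxt][1]
        nxt = min(c for c in cands if contig.coordinates[c][1] == best_end)
        path.append(nxt)
        covered = best_end
    return MinimumTilingPath(contig.contig_id, path)


def write_contig_report(assembly: PhysicalAssembly, path: str | Path,
                        mtps: Mapping[str, MinimumTilingPath] | None = None,
                        seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed) + "\n")
        fh.write("contig_id\tclone_id\torder\tstart\tend\tq_clone\tmtp\n")
        for ctg in assembly.contigs:
            mtp = set(mtps[ctg.contig_id].clones) if mtps and ctg.contig_id in mtps else set()
            for i, cid in enumerate(ctg.clones):
                s, e = ctg.coordinates[cid]
                fh.write(f"{ctg.contig_id}\t{cid}\t{i}\t{s:.1f}\t{e:.1f}\t0\t"
                         f"{1 if cid in mtp else 0}\n")
            for q in sorted(ctg.q_clones):
                fh.write(f"{ctg.contig_id}\t{q}\t-1\tnan\tnan\t1\t0\n")
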