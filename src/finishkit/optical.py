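"""Optical (nick-label) mapping: digestion, assembly, alignment, islands.

An optical molecule or consensus map is an ordered list of label-site
coordinates in bp.  Sequences are digested in silico at a nickase
recognition motif (default GCTCTTC, Nt.BspQI) on both strands.  Alignment of
two site lists is a dynamic program over monotone site correspondences:
matching a pair of sites extends the chain with a bonus minus a squared
standardized interval-length difference, and every skipped (missed/false)
label costs a fixed penalty.  Significance uses a chance-chain model: the
expected number of spurious monotone chains of the observed length, with
the per-step chance-match probability estimated empirically from unrelated
interval pairs.  This statistic reaches the very small p-value magnitudes
optical assembly thresholds are conventionally quoted on.

Consensus maps are assembled from molecules by pairwise overlap alignment
(candidate pairs pre-filtered on shared quantized interval k-mers),
orientation/offset layout refined by joint least squares, an EM loop that
registers every molecule against well-supported site clusters, and a final
refinement pass that realigns molecules by DP and drops unsupported sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import log, revcomp

DEFAULT_MOTIF = "GCTCTTC"


# ---------------------------------------------------------------------------
# types

@dataclass
class SequenceDigest:
    seq_id: str
    length: int
    sites: np.ndarray          # strictly increasing, 0-based motif starts

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype=float)
        if len(self.sites) and (self.sites[0] < 0 or self.sites[-1] >= self.length):
            raise ValueError(f"{self.seq_id}: sites outside [0, length)")
        if np.any(np.diff(self.sites) <= 0):
            raise ValueError(f"{self.seq_id}: sites not strictly increasing")


@dataclass
class OpticalMolecule:
    molecule_id: str
    length: float
    sites: np.ndarray

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype=float)
        if len(self.sites) and self.length < self.sites[-1]:
            raise ValueError(f"{self.molecule_id}: length shorter than last site")


@dataclass
class OpticalMap:
    map_id: str
    length: float
    sites: np.ndarray
    support: np.ndarray | None = None      # per-site molecule support
    interval_support: np.ndarray | None = None
    high_confidence: bool | None = None
    molecule_ids: list[str] = field(default_factory=list)


@dataclass
class MapAlignment:
    query_id: str
    target_id: str
    orientation: str                     # '+' or '-'
    site_pairs: list[tuple[int, int]]    # (query index, target index), query
                                         # indices in original orientation
    unmatched_query: int
    unmatched_target: int
    score: float
    p_value: float
    query_positions: np.ndarray = None   # matched query sites, oriented frame
    target_positions: np.ndarray = None
    query_length: float = 0.0

    def project(self, x: float) -> float:
        """Project an original-orientation query coordinate onto the target.

        Piecewise-linear through matched site pairs, linear extrapolation
        beyond the outermost matched sites.
        """
        xo = self.query_length - x if self.orientation == "-" else x
        qp, tp = self.query_positions, self.target_positions
        if len(qp) == 1:
            return float(tp[0] + (xo - qp[0]))
        return float(np.interp(xo, qp, tp)) if qp[0] <= xo <= qp[-1] else (
            float(tp[0] + (xo - qp[0])) if xo < qp[0] else float(tp[-1] + (xo - qp[-1])))


@dataclass
class Island:
    island_id: str
    components: list[tuple[str, str, str, float, float]]  # kind, id, orient, start, end
    gaps: list[dict] = field(default_factory=list)

    @property
    def scaffold_ids(self) -> list[str]:
        return [cid for kind, cid, *_ in self.components if kind == "scaffold"]


@dataclass
class AlignParams:
    sigma: float = 0.03
    miss_penalty: float = 2.0      # skipped target label
    false_penalty: float = 2.0     # skipped query label
    match_bonus: float = 6.0
    max_skip: int | None = None    # None: unrestricted lookback
    threshold: float = 1e-5        # p-value acceptance threshold
    seed: int = 0


# ---------------------------------------------------------------------------
# digestion

def digest_sequence(sequence: str, motif: str = DEFAULT_MOTIF,
                    seq_id: str = "seq") -> SequenceDigest:
    """Label sites of a nicking motif on both strands of a sequence.

    Sites are 0-based start positions of motif occurrences on the forward
    strand plus occurrences of the reverse-complement motif, merged and
    deduplicated.  Windows containing N never match.
    """
    if not motif:
        raise ValueError("empty motif")
    seq = sequence.upper()
    sites: set[int] = set()
    for m in (motif.upper(), revcomp(motif.upper())):
        start = seq.find(m)
        while start != -1:
            sites.add(start)
            start = seq.find(m, start + 1)
    return SequenceDigest(seq_id, len(seq), np.array(sorted(sites), dtype=float))


# ---------------------------------------------------------------------------
# core dynamic-programming aligner

def _dp_align(q: np.ndarray, t: np.ndarray, sigma: float, miss_penalty: float,
              false_penalty: float, match_bonus: float,
              max_skip: int | None) -> tuple[float, list[tuple[int, int]]]:
    """Best monotone site correspondence between positions q and t.

    Free end gaps (overlap-style).  Returns (score, [(qi, ti), ...]).
    """
    n, m = len(q), len(t)
    if n == 0 or m == 0:
        return 0.0, []
    K = max(n, m) if max_skip is None else max_skip
    D = np.full((n, m), match_bonus)
    BTI = np.zeros((n, m), dtype=np.int32)   # di of best predecessor (0 = chain start)
    BTJ = np.zeros((n, m), dtype=np.int32)
    for i in range(1, n):
        best = D[i]
        for di in range(1, min(K, i) + 1):
            gq = q[i] - q[i - di]
            prev = D[i - di]
            for dj in range(1, min(K, m - 1) + 1):
                gt = t[dj:] - t[:-dj]
                denom = sigma * np.maximum(np.maximum(gq, gt), 1000.0)
                pen = ((gq - gt) / denom) ** 2
                cand = (prev[:-dj] + match_bonus - pen
                        - false_penalty * (di - 1) - miss_penalty * (dj - 1))
                sl = slice(dj, m)
                upd = cand > best[sl]
                if np.any(upd):
                    best[sl] = np.where(upd, cand, best[sl])
                    idx = np.nonzero(upd)[0] + dj
                    BTI[i, idx] = di
                    BTJ[i, idx] = dj
    i, j = np.unravel_index(int(np.argmax(D)), D.shape)
    score = float(D[i, j])
    pairs = []
    while True:
        pairs.append((int(i), int(j)))
        di, dj = int(BTI[i, j]), int(BTJ[i, j])
        if di == 0:
            break
        i, j = i - di, j - dj
    pairs.reverse()
    return score, pairs


def _chance_match_q(interval_pools: Sequence[np.ndarray], p: AlignParams,
                    seed: int, n_sample: int = 2000) -> float:
    """Empirical probability that an unrelated interval pair 'matches'.

    A random interval pair counts as a chance match when its squared
    standardized length difference stays below the match bonus, i.e. it
    would extend a chance chain with positive score.  Estimated from
    intervals drawn from unrelated molecules/maps; the seed fixes the draw.
    """
    gaps = [np.diff(pool) for pool in interval_pools if len(pool) >= 2]
    allg = np.concatenate(gaps) if gaps else np.array([9000.0])
    allg = allg[allg > 0]
    if len(allg) < 2:
        return 0.05
    rng = np.random.default_rng(seed)
    a = allg[rng.integers(len(allg), size=n_sample)]
    b = allg[rng.integers(len(allg), size=n_sample)]
    denom = p.sigma * np.maximum(np.maximum(a, b), 1000.0)
    pen = ((a - b) / denom) ** 2
    q = float(np.mean(pen < p.match_bonus))
    return min(max(q, 1e-4), 0.9)


def _chain_pvalue(k: int, n_q: int, n_t: int, q: float) -> float:
    """Chance probability of a monotone chain of k matched label pairs.

    Approximates the expected number of chance chains reaching length k:
    ~ n_q*n_t starting pairs, each extended (k-1) times with per-step
    probability q.  Small p-values on the scale optical-map assembly
    thresholds are quoted on.
    """
    if k <= 0:
        return 1.0
    logp = np.log(max(n_q, 1) * max(n_t, 1)) + (k - 1) * np.log(q)
    return float(min(1.0, np.exp(max(logp, -700.0))))


# ---------------------------------------------------------------------------
# digest / map alignment

def align_digest_to_map(digest: SequenceDigest | OpticalMolecule,
                        omap: OpticalMap,
                        params: AlignParams | None = None) -> MapAlignment | None:
    """Best-scoring alignment of a sequence digest (or molecule) to a map.

    Both orientations are tried; the alignment is reported only when its
    permutation-null p-value is at or below params.threshold.  Absence of a
    significant alignment returns None.
    """
    p = params or AlignParams()
    qid = getattr(digest, "seq_id", None) or getattr(digest, "molecule_id")
    q = np.asarray(digest.sites, dtype=float)
    if len(q) < 2:
        raise ValueError(f"{qid}: need >= 2 label sites to align")
    t = np.asarray(omap.sites, dtype=float)
    best = None
    for orient in ("+", "-"):
        qo = q if orient == "+" else np.sort(digest.length - q)
        score, pairs = _dp_align(qo, t, p.sigma, p.miss_penalty,
                                 p.false_penalty, p.match_bonus, p.max_skip)
        if best is None or score > best[0]:
            best = (score, pairs, orient, qo)
    score, pairs, orient, qo = best
    if not pairs:
        return None
    qprob = _chance_match_q([q, t], p, p.seed)
    pval = _chain_pvalue(len(pairs), len(q), len(t), qprob)
    if pval > p.threshold:
        return None
    qi_span = pairs[-1][0] - pairs[0][0] + 1
    ti_span = pairs[-1][1] - pairs[0][1] + 1
    n = len(q)
    if orient == "-":
        orig_pairs = [(n - 1 - qi, ti) for qi, ti in pairs]
    else:
        orig_pairs = list(pairs)
    return MapAlignment(
        query_id=qid, target_id=omap.map_id, orientation=orient,
        site_pairs=orig_pairs,
        unmatched_query=qi_span - len(pairs),
        unmatched_target=ti_span - len(pairs),
        score=score, p_value=pval,
        query_positions=np.array([qo[i] for i, _ in pairs]),
        target_positions=np.array([t[j] for _, j in pairs]),
        query_length=float(digest.length))


# ---------------------------------------------------------------------------
# molecule assembly into consensus maps

def _interval_kmers(sites: np.ndarray, k: int, quantum: float) -> set[tuple[int, ...]]:
    gaps = np.diff(sites)
    qg = np.rint(gaps / quantum).astype(int)
    return {tuple(qg[i:i + k]) for i in range(len(qg) - k + 1)}


def _neighbour_keys(key: tuple[int, ...]) -> Iterable[tuple[int, ...]]:
    """The 3^k quantization-neighbour keys of an interval k-mer."""
    def rec(prefix, rest):
        if not rest:
            yield tuple(prefix)
            return
        for d in (-1, 0, 1):
            yield from rec(prefix + [rest[0] + d], rest[1:])
    yield from rec([], list(key))


class _OffsetUnionFind:
    """Union-find tracking each molecule's (flip, offset) to its root frame."""

    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}
        self.flip = {x: 1 for x in items}      # +1 / -1
        self.offset = {x: 0.0 for x in items}

    def find(self, x: str) -> tuple[str, int, float]:
        if self.parent[x] == x:
            return x, self.flip[x], self.offset[x]
        root, f, c = self.find(self.parent[x])
        # compose: x -> parent (fx, cx), parent -> root (f, c)
        fx, cx = self.flip[x], self.offset[x]
        self.parent[x] = root
        self.flip[x] = f * fx
        self.offset[x] = c + f * cx
        return root, self.flip[x], self.offset[x]

    def union(self, a: str, b: str, f_ab: int, c_ab: float) -> bool:
        """Link frames so that pos_a = c_ab + f_ab * pos_b."""
        ra, fa, ca = self.find(a)
        rb, fb, cb = self.find(b)
        if ra == rb:
            return False
        # pos_root_a = ca + fa*pos_a = ca + fa*(c_ab + f_ab*pos_b)
        # pos_b = fb_inv*(pos_root_b - cb) with fb_inv = fb (fb in {+-1})
        # root_b -> root_a:  g = ca + fa*c_ab + fa*f_ab*fb*(x - cb*fb)... derive:
        # pos_b = fb*(pos_root_b - cb)   since pos_root_b = cb + fb*pos_b
        f = fa * f_ab * fb
        c = ca + fa * c_ab - f * cb
        self.parent[rb] = ra
        self.flip[rb] = f
        self.offset[rb] = c
        return True


def _fit_transform(alignment_pairs_q: np.ndarray, pairs_t: np.ndarray,
                   orient: str, q_len: float) -> tuple[int, float]:
    """(flip, offset) such that t_pos ~= offset + flip * x for original-frame
    query coordinates x; alignment_pairs_q holds oriented positions q'."""
    if orient == "+":
        return 1, float(np.mean(pairs_t - alignment_pairs_q))
    # oriented query position q' = q_len - x, and t = c + q'  =>  t = (c + q_len) - x
    return -1, q_len + float(np.mean(pairs_t - alignment_pairs_q))


def assemble_optical_maps(molecules: Sequence[OpticalMolecule],
                          min_molecule_len: float = 150000.0,
                          p_pairwise: float = 1e-10,
                          p_refine: float = 1e-10,
                          p_final: float = 1e-15,
                          params: AlignParams | None = None,
                          min_site_support: int = 2,
                          min_matched_sites: int = 5,
                          max_partners: int = 30,
                          kmer_k: int = 3,
                          kmer_quantum: float = 500.0,
                          seed: int = 0) -> list[OpticalMap]:
    """Assemble consensus optical maps de novo from molecules.

    Molecules shorter than min_molecule_len are excluded.  Candidate
    overlapping pairs are pre-filtered on shared quantized interval k-mers,
    aligned by DP in both orientations and accepted at p <= p_pairwise under
    the shared permutation null.  Accepted overlaps are merged greedily (by
    decreasing score) into consistent coordinate frames; a consensus is grown
    molecule-by-molecule along each frame and refined by realigning every
    molecule (p <= p_final), dropping sites below min_site_support.
    """
    p = params or AlignParams(max_skip=4)
    kept = sorted((m for m in molecules if m.length >= min_molecule_len),
                  key=lambda m: m.molecule_id)
    if not kept:
        log("assemble_optical_maps: all molecules below length filter")
        return []
    usable = [m for m in kept if len(m.sites) >= 2]
    by_id = {m.molecule_id: m for m in usable}

    # --- candidate pairs from shared interval k-mers
    index: dict[tuple[int, ...], list[str]] = {}
    mol_keys: dict[str, set[tuple[int, ...]]] = {}
    for m in usable:
        fwd = _interval_kmers(m.sites, kmer_k, kmer_quantum)
        rev = _interval_kmers(np.sort(m.length - m.sites), kmer_k, kmer_quantum)
        mol_keys[m.molecule_id] = fwd | rev
        for key in fwd:
            index.setdefault(key, []).append(m.molecule_id)
    pair_hits: dict[tuple[str, str], int] = {}
    for m in usable:
        probes = set()
        for key in mol_keys[m.molecule_id]:
            probes.update(_neighbour_keys(key))
        for key in probes:
            for other in index.get(key, ()):
                if other > m.molecule_id:
                    pair_hits[(m.molecule_id, other)] = \
                        pair_hits.get((m.molecule_id, other), 0) + 1
    # cap partners per molecule by hit count
    partner_count: dict[str, int] = {m.molecule_id: 0 for m in usable}
    candidates = []
    for (a, b), hits in sorted(pair_hits.items(), key=lambda kv: (-kv[1], kv[0])):
        if partner_count[a] >= max_partners and partner_count[b] >= max_partners:
            continue
        partner_count[a] += 1
        partner_count[b] += 1
        candidates.append((a, b))

    # --- chance-chain null: per-step match probability from the data
    site_arrays = [m.sites for m in usable]
    qprob = _chance_match_q(site_arrays, p, seed)

    # --- pairwise alignment of candidates
    accepted = []   # (score, a, b, flip, offset)
    for a, b in candidates:
        ma, mb = by_id[a], by_id[b]
        best = None
        for orient in ("+", "-"):
            qo = mb.sites if orient == "+" else np.sort(mb.length - mb.sites)
            score, pairs = _dp_align(qo, ma.sites, p.sigma, p.miss_penalty,
                                     p.false_penalty, p.match_bonus, 4)
            if best is None or score > best[0]:
                best = (score, pairs, orient, qo)
        score, pairs, orient, qo = best
        pval = _chain_pvalue(len(pairs), len(mb.sites), len(ma.sites), qprob)
        if pval > p_pairwise or len(pairs) < min_matched_sites or score <= 0:
            continue
        qpos = np.array([qo[i] for i, _ in pairs])
        tpos = np.array([ma.sites[j] for _, j in pairs])
        flip, off = _fit_transform(qpos, tpos, orient, mb.length)
        accepted.append((score, a, b, flip, off))

    # --- greedy frame merging
    uf = _OffsetUnionFind([m.molecule_id for m in usable])
    for score, a, b, flip, off in sorted(accepted, key=lambda r: (-r[0], r[1], r[2])):
        uf.union(a, b, flip, off)

    groups: dict[str, list[str]] = {}
    for m in usable:
        root, _, _ = uf.find(m.molecule_id)
        groups.setdefault(root, []).append(m.molecule_id)

    maps: list[OpticalMap] = []
    for root in sorted(groups):
        members = groups[root]
        frames = {}
        for mid in members:
            _, f, c = uf.find(mid)
            frames[mid] = (f, c)
        if len(members) > 2:
            # offsets composed along the merge tree drift; re-estimate them
            # jointly by least squares over all accepted overlap constraints
            frames = _ls_frames(members, frames, accepted)
        cons = _build_consensus(members, by_id, frames, p, qprob, p_refine)
        cons = _refine_consensus(cons, members, by_id, p, qprob,
                                 (p_refine, p_final), min_site_support)
        if cons is None or len(cons[0]) == 0:
            continue
        sites, support = cons
        origin = sites[0]
        sites = sites - origin
        length = float(sites[-1]) if len(sites) else 0.0
        maps.append(OpticalMap(
            map_id=f"map{len(maps):04d}", length=length, sites=sites,
            support=support, molecule_ids=sorted(members)))
    return maps


def _ls_frames(members: Sequence[str], frames: Mapping[str, tuple[int, float]],
               accepted: Sequence[tuple]) -> dict[str, tuple[int, float]]:
    """Weighted least-squares molecule offsets from pairwise overlaps.

    Flips come from the union-find frames; each accepted alignment of b
    onto a (pos_a = off + flip*pos_b) contributes c_b - c_a = f_a * off.
    """
    idx = {m: i for i, m in enumerate(sorted(members))}
    n = len(idx)
    rows, rhs, wts = [], [], []
    for score, a, b, flip, off in accepted:
        if a not in idx or b not in idx:
            continue
        fa = frames[a][0]
        if frames[b][0] != fa * flip:
            continue     # orientation-inconsistent edge; leave it out
        row = np.zeros(n)
        row[idx[b]] = 1.0
        row[idx[a]] = -1.0
        rows.append(row)
        rhs.append(fa * off)
        wts.append(max(score, 1.0))
    if not rows:
        return dict(frames)
    anchor = sorted(members)[0]
    row = np.zeros(n)
    row[idx[anchor]] = 1.0
    rows.append(row)
    rhs.append(frames[anchor][1])
    wts.append(1.0)
    a_mat = np.asarray(rows)
    b_vec = np.asarray(rhs)
    w = np.sqrt(np.asarray(wts))
    keep = np.ones(len(rows), dtype=bool)
    keep[-1] = True
    sol = None
    # robust refit: a single spurious long-range overlap otherwise folds
    # the whole layout; residual outliers are dropped and the fit repeated
    for _ in range(3):
        sol, *_ = np.linalg.lstsq(a_mat[keep] * w[keep, None],
                                  b_vec[keep] * w[keep], rcond=None)
        resid = a_mat @ sol - b_vec
        scale = max(20_000.0, 6.0 * float(np.median(np.abs(resid[:-1])))
                    if len(resid) > 1 else 20_000.0)
        new_keep = np.abs(resid) <= scale
        new_keep[-1] = True
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
    return {m: (frames[m][0], float(sol[idx[m]])) for m in members}


def _oriented_sites(mol: OpticalMolecule, frame: tuple[int, float]) -> np.ndarray:
    f, c = frame
    return np.sort(c + f * mol.sites)


def _nearest_signed_diffs(cp: np.ndarray, sites: np.ndarray) -> np.ndarray:
    """Signed distance from each site to its nearest consensus position."""
    j = np.searchsorted(cp, sites)
    jl = np.clip(j - 1, 0, len(cp) - 1)
    jr = np.clip(j, 0, len(cp) - 1)
    dl = cp[jl] - sites
    dr = cp[jr] - sites
    return np.where(np.abs(dl) <= np.abs(dr), dl, dr)


def _build_consensus(members, by_id, frames, p: AlignParams, qprob: float,
                     p_refine: float, match_radius: float = 400.0,
                     cluster_gap: float = 1000.0,
                     min_cluster_support: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Consensus site positions for one molecule frame group.

    Two phases.  First, molecules are walked left-to-right and each one's
    residual frame shift is estimated against a growing site list (mode of
    pairwise offsets in a +-30 kb window, polished by median passes) --
    frame offsets drift across a deep merge tree, site patterns do not.
    Second, all shift-corrected site observations are pooled and clustered:
    sorted observations split where consecutive ones are more than
    cluster_gap apart, and a cluster in which many molecules contribute two
    or more observations is split again at its widest internal gap (those
    molecules resolve two genuine close labels).  Support = number of
    distinct contributing molecules.
    """
    def robust_shift(cp: np.ndarray, sites: np.ndarray) -> float:
        """Residual registration of one molecule against anchor sites.

        Frames from the joint least squares are good to a few kb, so the
        correction is a contraction: median signed offset to the nearest
        anchor within shrinking capture windows.  No long-range search --
        that would let molecules jump to self-similar registrations.
        """
        shift = 0.0
        for capture in (2500.0, 1200.0, match_radius * 1.5):
            d = _nearest_signed_diffs(cp, sites + shift)
            close = d[np.abs(d) <= capture]
            if len(close) >= 3:
                shift += float(np.median(close))
        return shift

    def cluster_observations(observations: list[tuple[float, str]]
                             ) -> list[tuple[float, float]]:
        observations = sorted(observations)
        clusters: list[list[tuple[float, str]]] = [[observations[0]]]
        for obs in observations[1:]:
            if obs[0] - clusters[-1][-1][0] > cluster_gap:
                clusters.append([obs])
            else:
                clusters[-1].append(obs)

        def emit(cluster) -> list[list[tuple[float, str]]]:
            mols = [m for _, m in cluster]
            n_multi = len(mols) - len(set(mols))
            if n_multi >= 0.3 * len(set(mols)) and len(cluster) >= 4:
                gaps = [cluster[i + 1][0] - cluster[i][0]
                        for i in range(len(cluster) - 1)]
                cut = int(np.argmax(gaps)) + 1
                if 0 < cut < len(cluster):
                    return emit(cluster[:cut]) + emit(cluster[cut:])
            return [cluster]

        flat: list[list[tuple[float, str]]] = []
        for cluster in clusters:
            flat.extend(emit(cluster))
        # adjacent clusters with disjoint molecule sets are registration
        # islands of one label; a genuine close pair shares its molecules
        merged: list[list[tuple[float, str]]] = [flat[0]]
        for cl in flat[1:]:
            prev = merged[-1]
            gap = cl[0][0] - prev[-1][0]
            sp, sc = {m for _, m in prev}, {m for _, m in cl}
            shared = len(sp & sc)
            if gap <= 2 * cluster_gap and shared < 0.25 * min(len(sp), len(sc)):
                merged[-1] = prev + cl
            else:
                merged.append(cl)
        out = [(float(np.mean([x for x, _ in cl])),
                float(len({m for _, m in cl}))) for cl in merged]
        return sorted(out)

    # round 0: pool raw frame positions (joint LS frames are good to ~2 kb)
    order = sorted(members)
    shifts: dict[str, float] = {mid: 0.0 for mid in order}
    observations: list[tuple[float, str]] = []
    for mid in order:
        observations.extend((float(x), mid)
                            for x in _oriented_sites(by_id[mid], frames[mid]))
    sites_out = cluster_observations(observations)

    # EM rounds: re-register each molecule against the well-supported
    # clusters, re-pool and re-cluster; anchors sharpen every round
    for _ in range(6):
        strong = np.array([x for x, w in sites_out if w >= 5])
        cp = strong if len(strong) >= 10 else np.array([x for x, _ in sites_out])
        observations = []
        for mid in order:
            sites = _oriented_sites(by_id[mid], frames[mid])
            shift = shifts[mid] + robust_shift(cp, sites + shifts[mid])
            shifts[mid] = shift
            observations.extend((float(x), mid) for x in sites + shift)
        sites_out = cluster_observations(observations)

    if len(members) > 1:
        sites_out = [(x, w) for x, w in sites_out if w >= min_cluster_support]
    pos = np.array([x for x, _ in sites_out])
    w = np.array([w for _, w in sites_out])
    return pos, w


def _refine_consensus(cons, members, by_id, p: AlignParams, qprob: float,
                      p_gates: tuple[float, float], min_site_support: int
                      ) -> tuple[np.ndarray, np.ndarray] | None:
    """Realign all molecules to the consensus; reposition and filter sites.

    Singleton observations from the build (support 1) are dropped first --
    they are unconfirmed and would otherwise clutter the realignment.  The
    first realignment pass runs at the refinement threshold (repositioning
    irons out residual registration warp), the last at the final one."""
    pos, w = cons
    if len(pos) == 0:
        return None
    if len(members) > 1:
        # at decent coverage, realign against well-supported sites only
        thr = 5.0 if np.percentile(w, 75) >= 15 else float(min(min_site_support, 2))
        keep0 = w >= thr
        if not np.any(keep0):
            return None
        pos = pos[keep0]
    for p_gate in p_gates:
        sums = np.zeros(len(pos))
        counts = np.zeros(len(pos))
        for mid in members:
            mol = by_id[mid]
            best = None
            for orient in ("+", "-"):
                qo = mol.sites if orient == "+" else np.sort(mol.length - mol.sites)
                score, pairs = _dp_align(qo, pos, p.sigma, p.miss_penalty,
                                         p.false_penalty, p.match_bonus, 6)
                if best is None or score > best[0]:
                    best = (score, pairs, qo)
            score, pairs, qo = best
            pval = _chain_pvalue(len(pairs), len(mol.sites), len(pos), qprob)
            # a label-sparse molecule cannot reach a long chain; membership
            # is already established, so half its sites matching suffices
            confident = (pval <= p_gate
                         or len(pairs) >= 0.5 * len(mol.sites))
            if len(members) > 1 and (not confident or len(pairs) < 3):
                continue
            shift = np.mean([pos[j] - qo[i] for i, j in pairs])
            for i, j in pairs:
                sums[j] += qo[i] + shift
                counts[j] += 1.0
        keep = counts >= (min_site_support if len(members) > 1 else 1)
        if not np.any(keep):
            return None
        new_pos = np.where(counts > 0, sums / np.maximum(counts, 1.0), pos)[keep]
        new_pos = np.sort(new_pos)
        # collapse numerically coincident sites
        dedup_pos, dedup_cnt = [], []
        for x, c in zip(new_pos, counts[keep]):
            if dedup_pos and x - dedup_pos[-1] < 1.0:
                w = dedup_cnt[-1]
                dedup_pos[-1] = (dedup_pos[-1] * w + x * c) / (w + c)
                dedup_cnt[-1] = w + c
            else:
                dedup_pos.append(float(x))
                dedup_cnt.append(float(c))
        pos = np.asarray(dedup_pos)
        support = np.asarray(dedup_cnt)
    return pos, support


# ---------------------------------------------------------------------------
# map validation

def validate_maps(maps: Sequence[OpticalMap], molecules: Sequence[OpticalMolecule],
                  min_support: int = 3,
                  params: AlignParams | None = None,
                  p_align: float = 1e-6,
                  seed: int = 0) -> list[OpticalMap]:
    """Flag maps high-confidence iff every consensus interval is spanned by
    >= min_support realigned molecules."""
    p = params or AlignParams(max_skip=4)
    usable = [m for m in molecules if len(m.sites) >= 2]
    if not usable:
        for om in maps:
            om.high_confidence = False
        return list(maps)
    site_arrays = [m.sites for m in usable]
    qprob = _chance_match_q(site_arrays, p, seed)
    for om in maps:
        n_int = max(len(om.sites) - 1, 0)
        cover = np.zeros(n_int)
        for mol in usable:
            best = None
            for orient in ("+", "-"):
                qo = mol.sites if orient == "+" else np.sort(mol.length - mol.sites)
                score, pairs = _dp_align(qo, om.sites, p.sigma, p.miss_penalty,
                                         p.false_penalty, p.match_bonus, 4)
                if best is None or score > best[0]:
                    best = (score, pairs)
            score, pairs = best
            pval = _chain_pvalue(len(pairs), len(mol.sites), len(om.sites), qprob)
            if pval > p_align or len(pairs) < 3:
                continue
            t_lo = min(j for _, j in pairs)
            t_hi = max(j for _, j in pairs)
            cover[t_lo:t_hi] += 1
        om.interval_support = cover
        om.high_confidence = bool(n_int > 0 and np.all(cover >= min_support))
    return list(maps)


# ---------------------------------------------------------------------------
# islands

def build_islands(scaffolds: Sequence[SequenceDigest],
                  maps: Sequence[OpticalMap],
                  alignments: Sequence[MapAlignment],
                  conflict_tol: float = 20000.0,
                  unsized_dist: float = 50000.0) -> list[Island]:
    """Connected scaffold/map components ordered on a common optical frame.

    Each connected component of the bipartite scaffold-map alignment graph
    becomes one island; scaffolds are ordered and oriented by their projected
    map coordinates, with inter-scaffold gaps sized from the optical distance
    between aligned scaffold ends (negative gaps are overlaps).  A scaffold
    whose multiple placements disagree beyond conflict_tol is left unplaced
    (singleton island, conflict logged).  Unaligned scaffolds form singleton
    islands.
    """
    scaff_by_id = {s.seq_id: s for s in scaffolds}
    map_by_id = {m.map_id: m for m in maps}
    aligns_by_scaffold: dict[str, list[MapAlignment]] = {}
    for a in alignments:
        if a.query_id in scaff_by_id and a.target_id in map_by_id:
            aligns_by_scaffold.setdefault(a.query_id, []).append(a)

    # map frames per component: anchor the lexicographically first map at 0/+
    import networkx as nx
    g = nx.Graph()
    for sid in aligns_by_scaffold:
        for a in aligns_by_scaffold[sid]:
            g.add_edge(("scaffold", sid), ("map", a.target_id))
    islands: list[Island] = []
    conflicts: set[str] = set()

    def map_frame_components():
        for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]):
            yield comp

    for comp in map_frame_components():
        map_nodes = sorted(n for k, n in comp if k == "map")
        scaff_nodes = sorted(n for k, n in comp if k == "scaffold")
        # map frames (map-local coord -> global flip/offset), grown by the
        # strongest spanning evidence first so weak spurious cross-map
        # alignments never anchor a frame
        frames: dict[str, tuple[int, float]] = {map_nodes[0]: (1, 0.0)}
        while True:
            best = None
            for sid in scaff_nodes:
                placed = [a for a in aligns_by_scaffold[sid]
                          if a.target_id in frames]
                pending = [a for a in aligns_by_scaffold[sid]
                           if a.target_id not in frames]
                for a0 in placed:
                    for a in pending:
                        strength = min(len(a0.site_pairs), len(a.site_pairs))
                        key = (strength, sid, a0.target_id, a.target_id)
                        if best is None or key > best[0]:
                            best = (key, sid, a0, a)
            if best is None:
                break
            _, sid, a0, a = best
            f0, c0 = frames[a0.target_id]
            x0, x1 = 0.0, scaff_by_id[sid].length
            gA = sorted([c0 + f0 * a0.project(x0), c0 + f0 * a0.project(x1)])
            tB = sorted([a.project(x0), a.project(x1)])
            same = (a.orientation == a0.orientation)
            fB = f0 if same else -f0
            cB = gA[0] - tB[0] if fB == 1 else gA[0] + tB[1]
            frames[a.target_id] = (fB, cB)
        # place scaffolds: keep the strongest alignment and every alignment
        # consistent with it; a disagreeing alignment of comparable
        # strength is a genuine conflict, a weak one is discarded
        placements = []
        for sid in scaff_nodes:
            cands = []
            for a in aligns_by_scaffold[sid]:
                f, c = frames[a.target_id]
                g0 = c + f * a.project(0.0)
                g1 = c + f * a.project(scaff_by_id[sid].length)
                plus = (a.orientation == "+") == (f == 1)
                cands.append((len(a.site_pairs), tuple(sorted((g0, g1))),
                              "+" if plus else "-"))
            cands.sort(key=lambda t: -t[0])
            best_pairs, best_span, best_orient = cands[0]
            kept, clash = [cands[0]], False
            for pairs, span, orient in cands[1:]:
                agrees = (abs(span[0] - best_span[0]) <= conflict_tol
                          and orient == best_orient)
                if agrees:
                    kept.append((pairs, span, orient))
                elif pairs >= 0.67 * best_pairs:
                    clash = True
            if clash:
                conflicts.add(sid)
                log(f"build_islands: conflicting placements for scaffold {sid}")
                continue
            start = float(np.mean([s for _, (s, _), _ in kept]))
            end = float(np.mean([e for _, (_, e), _ in kept]))
            placements.append(("scaffold", sid, best_orient, start, end))
        for mid in map_nodes:
            f, c = frames[mid]
            g0, g1 = sorted((c, c + f * map_by_id[mid].length))
            placements.append(("map", mid, "+" if f == 1 else "-", g0, g1))
        placements.sort(key=lambda r: (r[3], r[0], r[1]))
        island = Island(f"island{len(islands):04d}", placements)
        # inter-scaffold gaps
        scafs = [pl for pl in placements if pl[0] == "scaffold"]
        for left, right in zip(scafs, scafs[1:]):
            sized = _ends_labelled(scaff_by_id[left[1]], left[2], "right", unsized_dist) and \
                    _ends_labelled(scaff_by_id[right[1]], right[2], "left", unsized_dist)
            island.gaps.append({
                "left": left[1], "right": right[1],
                "size": float(right[3] - left[4]),
                "sized": bool(sized)})
        islands.append(island)

    # singletons: unaligned or conflicting scaffolds
    for s in sorted(scaff_by_id.values(), key=lambda s: s.seq_id):
        if s.seq_id not in aligns_by_scaffold or s.seq_id in conflicts:
            islands.append(Island(
                f"island{len(islands):04d}",
                [("scaffold", s.seq_id, "+", 0.0, float(s.length))]))
    return islands


def _ends_labelled(digest: SequenceDigest, orient: str, side: str,
                   unsized_dist: float) -> bool:
    """True when the relevant scaffold end has a label within unsized_dist."""
    if len(digest.sites) == 0:
        return False
    # physical end of the scaffold facing the gap
    phys_side = side if orient == "+" else ("left" if side == "right" else "right")
    if phys_side == "right":
        return (digest.length - digest.sites[-1]) <= unsized_dist
    return digest.sites[0] <= unsized_dist


def islands_to_agp(islands: Sequence[Island],
                   scaffold_lengths: Mapping[str, int]) -> list:
    """AGP v2.1 components for islands (scaffold W lines, map-evidence gaps)."""
    from .io import AgpComponent
    comps: list[AgpComponent] = []
    for isl in islands:
        scafs = [pl for pl in isl.components if pl[0] == "scaffold"]
        pos = 0
        part = 1
        for i, (_, sid, orient, *_rest) in enumerate(scafs):
            length = scaffold_lengths[sid]
            comps.append(AgpComponent(isl.island_id, pos, pos + length, part,
                                      "W", component_id=sid, component_beg=0,
                                      component_end=length, orientation=orient))
            pos += length
            part += 1
            if i < len(scafs) - 1:
                gap = isl.gaps[i]
                if gap["sized"] and gap["size"] >= 1:
                    ctype, glen = "N", int(round(gap["size"]))
                else:
                    ctype, glen = "U", 100   # unsized or overlap: AGP convention
                evidence = "overlap" if gap["size"] < 0 else "map"
                comps.append(AgpComponent(isl.island_id, pos, pos + glen, part,
                                          ctype, gap_length=glen,
                                          gap_type="scaffold", linkage="yes",
                                          evidence=evidence))
                pos += glen
                part += 1
    return comps


# ---------------------------------------------------------------------------
# BNX-like / CMAP-like TSV

def write_molecules(molecules: Sequence[OpticalMolecule], path,
                    seed: int | None = None) -> None:
    """BNX-like TSV: molecule_id, length, comma-separated site positions."""
    from .io import provenance_header
    with open(path, "w") as fh:
        fh.write(provenance_header(seed) + "\n")
        fh.write("molecule_id\tlength\tsites\n")
        for m in molecules:
            fh.write(f"{m.molecule_id}\t{m.length:.1f}\t"
                     + ",".join(f"{x:.1f}" for x in m.sites) + "\n")


def read_molecules(path) -> list[OpticalMolecule]:
    from .io import FormatError
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("molecule_id"):
                continue
            f = line.split("\t")
            if len(f) != 3:
                raise FormatError(f"{path}:{ln}: need 3 fields")
            sites = np.array([float(x) for x in f[2].split(",") if x])
            out.append(OpticalMolecule(f[0], float(f[1]), sites))
    return out


def write_cmap(maps: Sequence[OpticalMap], path, seed: int | None = None) -> None:
    """CMAP-like TSV, one row per site; positions 1-based on disk."""
    from .io import provenance_header
    with open(path, "w") as fh:
        fh.write(provenance_header(seed) + "\n")
        fh.write("map_id\tlength\tsite_index\tposition\tsupport\n")
        for m in maps:
            sup = m.support if m.support is not None else [1] * len(m.sites)
            for i, (x, s) in enumerate(zip(m.sites, sup), 1):
                fh.write(f"{m.map_id}\t{m.length:.1f}\t{i}\t{x + 1:.1f}\t{s:.0f}\n")


def read_cmap(path) -> list[OpticalMap]:
    from .io import FormatError
    rows: dict[str, dict] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("map_id"):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(f"{path}:{ln}: need >= 4 fields")
            rec = rows.setdefault(f[0], {"length": float(f[1]), "sites": [],
                                         "support": []})
            rec["sites"].append(float(f[3]) - 1.0)
            rec["support"].append(float(f[4]) if len(f) > 4 else 1.0)
    return [OpticalMap(mid, rec["length"], np.array(rec["sites"]),
                       support=np.array(rec["support"]))
            for mid, rec in rows.items()]
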