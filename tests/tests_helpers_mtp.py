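"""Shared brute-force oracles used by the recovery test-suite."""

import itertools

import networkx as nx
import numpy as np

from finishkit.fingerprint import PhysicalContig


def graph_from_overlaps(intervals):
    g = nx.Graph()
    g.add_nodes_from(intervals)
    for a, b in itertools.combinations(intervals, 2):
        (s1, e1), (s2, e2) = intervals[a], intervals[b]
        if min(e1, e2) > max(s1, s2):
            g.add_edge(a, b, score=1e-20, shared_bands=10)
    return g


def contig_from_intervals(intervals):
    order = sorted(intervals, key=lambda c: intervals[c][0])
    return PhysicalContig("ctg", order, dict(intervals))


def exhaustive_cover_size(intervals, edges):
    """Size of the smallest linked clone subset covering the span."""
    ids = sorted(intervals)
    span = (min(s for s, _ in intervals.values()),
            max(e for _, e in intervals.values()))
    for size in range(1, len(ids) + 1):
        for combo in itertools.combinations(ids, size):
            ivs = sorted(combo, key=lambda c: intervals[c][0])
            if intervals[ivs[0]][0] > span[0]:
                continue
            reach = intervals[ivs[0]][1]
            ok = True
            for prev, nxt in zip(ivs, ivs[1:]):
                linked = (prev, nxt) in edges or (nxt, prev) in edges
                if intervals[nxt][0] > reach or not linked:
                    ok = False
                    break
                reach = max(reach, intervals[nxt][1])
            if ok and reach >= span[1]:
                return size
    return len(ids)


def brute_force_alignment(q, t, p):
    """Best monotone chain score by explicit enumeration."""
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
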