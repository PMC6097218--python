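"""Synthetic inputs with machine-readable truth for every pipeline stage.

The generators emulate the statistical structure of the real data the
toolkit targets: a genome with tandem repeat arrays and GC-rich/homopolymer
gap-prone motifs; a tiling BAC library with noisy multi-enzyme SNapShot-style
fingerprints; optical molecules with sizing/label noise; a fragmented draft
with sized N-gaps biased toward the gap-prone motifs; MAGIC-style founder
matrices with a recombination-suppressed interval; and genotype panels with
block LD structure.  Identical seeds give byte-identical outputs.

Background sequence is i.i.d. at a configurable GC content; no Markov
structure is modelled, which is sufficient for the algorithms under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .fingerprint import CloneFingerprint, Fragment, FingerprintSet
from .optical import DEFAULT_MOTIF, OpticalMolecule, digest_sequence
from .regions import MISSING, FounderMatrix, GenotypeMatrix
from .io import revcomp

# classic five-enzyme SNapShot panel: four dye-labelled sticky-end
# enzymes plus unlabelled HaeIII to shorten fragments into the sizing window
DEFAULT_ENZYMES: dict[str, tuple[str, str | None]] = {
    "BamHI": ("GGATCC", "blue"),
    "EcoRI": ("GAATTC", "green"),
    "XbaI": ("TCTAGA", "yellow"),
    "XhoI": ("CTCGAG", "red"),
    "HaeIII": ("GGCC", None),
}


@dataclass
class TandemArraySpec:
    unit_length: int = 10000
    copies: int = 4
    position: int | None = None       # None: placed by the generator


@dataclass
class GenomeConfig:
    length: int = 2_000_000
    gc: float = 0.45
    tandem_arrays: list[TandemArraySpec] = field(default_factory=list)
    n_gc_tracts: int = 0
    gc_tract_length: int = 200
    gc_tract_gc: float = 0.9
    n_homopolymers: int = 0
    homopolymer_length: int = 15


@dataclass
class BacConfig:
    n_clones: int = 150
    mean_length: int = 160_000
    sd_length: int = 15_000
    chimera_rate: float = 0.0
    chimera_min_separation: float = 4.0   # in units of mean_length


@dataclass
class FingerprintConfig:
    enzymes: dict = field(default_factory=lambda: dict(DEFAULT_ENZYMES))
    sizing_sd: float = 0.005
    size_window: tuple[int, int] = (100, 1200)


@dataclass
class OpticalConfig:
    coverage: float = 50.0
    mean_length: float = 200_000.0
    sd_length: float = 35_000.0
    min_length: float = 120_000.0
    sizing_sd: float = 0.03
    miss_rate: float = 0.10
    false_per_kb: float = 0.01          # 1 false label / 100 kb
    chimera_rate: float = 0.0
    motif: str = DEFAULT_MOTIF


@dataclass
class DraftConfig:
    n_scaffolds: int = 4
    n_gaps: int = 200
    gap_length_range: tuple[int, int] = (20, 400)
    min_gap_spacing: int = 4000
    size_distortion: float = 0.3        # declared N count off by up to +-30%
    motif_enrichment: float = 0.5       # fraction of gaps placed on planted tracts


@dataclass
class MagicConfig:
    n_founders: int = 8
    n_progeny: int = 500
    chrom_length: float = 100e6
    marker_spacing: float = 1e6
    crossovers_per_progeny: float = 2.0
    suppressed_interval: tuple[float, float] | None = (30e6, 60e6)
    missing_rate: float = 0.0


@dataclass
class LdBlockSpec:
    n_snps: int = 5
    freq: float = 0.4                   # haplotype-pattern frequency


@dataclass
class LdConfig:
    n_samples: int = 500
    blocks: list[LdBlockSpec] = field(default_factory=lambda: [LdBlockSpec(), LdBlockSpec()])
    snp_spacing: float = 1000.0
    missing_rate: float = 0.0


@dataclass
class SimConfig:
    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    bac: BacConfig = field(default_factory=BacConfig)
    fingerprint: FingerprintConfig = field(default_factory=FingerprintConfig)
    optical: OpticalConfig = field(default_factory=OpticalConfig)
    draft: DraftConfig = field(default_factory=DraftConfig)
    magic: MagicConfig = field(default_factory=MagicConfig)
    ld: LdConfig = field(default_factory=LdConfig)

    def as_dict(self) -> dict:
        return asdict(self)


class ConfigError(ValueError):
    pass


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


# ---------------------------------------------------------------------------
# genome

def simulate_genome(cfg: GenomeConfig, seed: int = 0) -> tuple[str, dict]:
    """Background i.i.d. sequence with planted arrays and gap-prone motifs.

    Truth tracks (BED-style lists of (start, end, label)) record every
    tandem-array unit, GC-rich tract and homopolymer, at exact coordinates.
    """
    rng = np.random.default_rng(seed)
    seq = list(_random_seq(rng, cfg.length, cfg.gc))
    truth = {"tandem_units": [], "gc_tracts": [], "homopolymers": []}
    occupied: list[tuple[int, int]] = []

    def place(length: int, position: int | None) -> int:
        if length > cfg.length:
            raise ConfigError(f"feature of length {length} exceeds genome "
                              f"length {cfg.length}")
        if position is not None:
            if position + length > cfg.length:
                raise ConfigError("feature exceeds genome length")
            return position
        for _ in range(1000):
            pos = int(rng.integers(0, cfg.length - length))
            if all(pos + length <= s or pos >= e for s, e in occupied):
                return pos
        raise ConfigError("could not place feature without overlap")

    for spec in cfg.tandem_arrays:
        total = spec.unit_length * spec.copies
        pos = place(total, spec.position)
        unit = _random_seq(rng, spec.unit_length, cfg.gc)
        seq[pos:pos + total] = list(unit * spec.copies)
        occupied.append((pos, pos + total))
        for c in range(spec.copies):
            s = pos + c * spec.unit_length
            truth["tandem_units"].append((s, s + spec.unit_length, f"unit{c}"))
    for i in range(cfg.n_gc_tracts):
        pos = place(cfg.gc_tract_length, None)
        tract = _random_seq(rng, cfg.gc_tract_length, cfg.gc_tract_gc)
        seq[pos:pos + cfg.gc_tract_length] = list(tract)
        occupied.append((pos, pos + cfg.gc_tract_length))
        truth["gc_tracts"].append((pos, pos + cfg.gc_tract_length, f"gc{i}"))
    for i in range(cfg.n_homopolymers):
        base = "G" if i % 2 == 0 else "C"
        pos = place(cfg.homopolymer_length, None)
        seq[pos:pos + cfg.homopolymer_length] = [base] * cfg.homopolymer_length
        occupied.append((pos, pos + cfg.homopolymer_length))
        truth["homopolymers"].append((pos, pos + cfg.homopolymer_length,
                                      f"{base}{cfg.homopolymer_length}"))
    return "".join(seq), truth


# ---------------------------------------------------------------------------
# BAC library and fingerprints

@dataclass
class SimClone:
    clone_id: str
    start: int
    end: int
    sequence: str
    chimera_of: tuple | None = None   # ((s1, e1), (s2, e2)) when chimeric


def simulate_bac_library(genome: str, cfg: BacConfig, seed: int = 0
                         ) -> list[SimClone]:
    """Uniform clone starts, Gaussian lengths, optional chimeric joins.

    A chimera models co-ligation of two inserts from the library's own
    fragment pool: it concatenates the intervals of two ordinary clones
    sampled from distant regions (separation > chimera_min_separation *
    mean_length), so each chimeric half coexists with a genuine clone.
    """
    rng = np.random.default_rng(seed)
    clones: list[SimClone] = []
    chimera_flags = [bool(rng.random() < cfg.chimera_rate)
                     for _ in range(cfg.n_clones)]
    for i in range(cfg.n_clones):
        length = int(max(10_000, rng.normal(cfg.mean_length, cfg.sd_length)))
        length = min(length, len(genome))
        s = int(rng.integers(0, len(genome) - length + 1))
        clones.append(SimClone(f"clone{i:04d}", s, s + length,
                               genome[s:s + length]))
    ordinary = [i for i in range(cfg.n_clones) if not chimera_flags[i]]
    min_sep = cfg.chimera_min_separation * cfg.mean_length
    for i in range(cfg.n_clones):
        if not chimera_flags[i] or len(ordinary) < 2:
            continue
        a = clones[int(ordinary[rng.integers(len(ordinary))])]
        for _ in range(200):
            b = clones[int(ordinary[rng.integers(len(ordinary))])]
            if abs(b.start - a.start) > min_sep:
                break
        clones[i] = SimClone(clones[i].clone_id, a.start, a.end,
                             a.sequence + b.sequence,
                             chimera_of=((a.start, a.end), (b.start, b.end)))
    return clones


def _digest_positions(seq: str, site: str) -> list[int]:
    pos = []
    start = seq.find(site)
    while start != -1:
        pos.append(start)
        start = seq.find(site, start + 1)
    # nick sites on the reverse strand cut too
    rc = revcomp(site)
    if rc != site:
        start = seq.find(rc)
        while start != -1:
            pos.append(start)
            start = seq.find(rc, start + 1)
    return sorted(set(pos))


def simulate_fingerprints(clones: Sequence[SimClone],
                          cfg: FingerprintConfig | None = None,
                          seed: int = 0) -> FingerprintSet:
    """SNapShot-style in silico fingerprints.

    All enzymes digest simultaneously (cut-site union); a fragment appears in
    a dye channel when one of its bounding cuts was made by a dye-labelled
    enzyme (a fragment cut by two different dye enzymes appears in both).
    Fragments outside the resolvable size window are dropped; sizes carry
    multiplicative Gaussian noise.
    """
    cfg = cfg or FingerprintConfig()
    rng = np.random.default_rng(seed)
    lo, hi = cfg.size_window
    fps = FingerprintSet()
    for clone in clones:
        cuts: list[tuple[int, str]] = []
        for enzyme, (site, _channel) in cfg.enzymes.items():
            for p in _digest_positions(clone.sequence, site):
                cuts.append((p, enzyme))
        cuts.sort()
        frags: list[Fragment] = []
        for (p1, e1), (p2, e2) in zip(cuts, cuts[1:]):
            size = p2 - p1
            if size <= 0:
                continue
            channels = {cfg.enzymes[e][1] for e in (e1, e2)
                        if cfg.enzymes[e][1] is not None}
            for channel in sorted(channels):
                noisy = size * (1.0 + rng.normal(0.0, cfg.sizing_sd))
                if lo <= noisy <= hi:
                    frags.append(Fragment(channel, float(round(noisy, 1))))
        if frags:
            fps.add(CloneFingerprint(clone.clone_id, frags))
    return fps


# ---------------------------------------------------------------------------
# optical molecules

def simulate_optical_molecules(genome: str, cfg: OpticalConfig, seed: int = 0,
                               region: tuple[int, int] | None = None
                               ) -> tuple[list[OpticalMolecule], dict]:
    """Molecules sampled at configured coverage with label noise.

    True nick sites come from in silico digestion; each molecule's
    inter-site intervals get multiplicative Gaussian noise, sites are
    dropped at miss_rate, false sites added at false_per_kb, and molecules
    are flipped with probability 1/2.  Truth records source interval,
    orientation and chimera status per molecule.
    """
    rng = np.random.default_rng(seed)
    lo, hi = region if region else (0, len(genome))
    region_len = hi - lo
    digest = digest_sequence(genome[lo:hi], cfg.motif)
    true_sites = digest.sites
    n_mol = int(np.ceil(cfg.coverage * region_len / cfg.mean_length))
    molecules = []
    truth = {"sites": true_sites + lo, "molecules": []}
    for i in range(n_mol):
        length = float(np.clip(rng.normal(cfg.mean_length, cfg.sd_length),
                               cfg.min_length, region_len))
        chimeric = rng.random() < cfg.chimera_rate
        if chimeric:
            l1 = length / 2
            s1 = float(rng.uniform(0, region_len - l1))
            s2 = float(rng.uniform(0, region_len - l1))
            parts = [(s1, s1 + l1), (s2, s2 + l1)]
        else:
            s = float(rng.uniform(0, region_len - length))
            parts = [(s, s + length)]
        sites = []
        offset = 0.0
        for ps, pe in parts:
            within = true_sites[(true_sites >= ps) & (true_sites < pe)] - ps
            sites.extend(offset + within)
            offset += pe - ps
        sites = np.sort(np.asarray(sites))
        # multiplicative interval noise (anchored at molecule start)
        bounds = np.concatenate([[0.0], sites])
        gaps = np.diff(bounds)
        gaps = gaps * (1.0 + rng.normal(0.0, cfg.sizing_sd, size=len(gaps)))
        noisy = np.cumsum(gaps)
        keep = rng.random(len(noisy)) >= cfg.miss_rate
        noisy = noisy[keep]
        n_false = rng.poisson(cfg.false_per_kb * length / 1000.0)
        false_pos = rng.uniform(0, length, size=n_false)
        allsites = np.sort(np.concatenate([noisy, false_pos]))
        allsites = allsites[(allsites >= 0) & (allsites <= length)]
        flipped = bool(rng.random() < 0.5)
        if flipped:
            allsites = np.sort(length - allsites)
        molecules.append(OpticalMolecule(f"mol{i:05d}", length, allsites))
        truth["molecules"].append({"molecule_id": f"mol{i:05d}",
                                   "parts": [(lo + a, lo + b) for a, b in parts],
                                   "flipped": flipped,
                                   "chimeric": chimeric})
    return molecules, truth


# ---------------------------------------------------------------------------
# draft assembly with N-gaps

def simulate_draft_assembly(genome: str, cfg: DraftConfig, seed: int = 0,
                            genome_truth: dict | None = None
                            ) -> tuple[dict[str, str], dict]:
    """Cut the genome into scaffolds and mask intervals as N-runs.

    A configurable fraction of gaps is placed on planted gap-prone motifs
    (GC tracts/homopolymers from the genome truth); declared N counts are
    distorted from the true masked lengths by up to +-size_distortion.
    Truth records, per gap, the draft N-run coordinates, the true genome
    interval and the true (masked) sequence, plus a draft-to-truth AGP-style
    correspondence per scaffold.
    """
    rng = np.random.default_rng(seed)
    glen = len(genome)
    # scaffold breakpoints
    if cfg.n_scaffolds > 1:
        bps = np.sort(rng.choice(np.arange(glen // 10, glen - glen // 10),
                                 size=cfg.n_scaffolds - 1, replace=False))
    else:
        bps = np.array([], dtype=int)
    bounds = [0] + [int(b) for b in bps] + [glen]
    planted: list[tuple[int, int]] = []
    if genome_truth:
        for key in ("gc_tracts", "homopolymers"):
            planted += [(s, e) for s, e, _ in genome_truth.get(key, [])]
    planted.sort()

    # choose gap intervals on the genome, spaced apart
    gaps: list[tuple[int, int]] = []

    def far_enough(s, e):
        return all(e + cfg.min_gap_spacing <= gs or s >= ge + cfg.min_gap_spacing
                   for gs, ge in gaps)

    n_planted = int(round(cfg.motif_enrichment * cfg.n_gaps))
    for s, e in planted[:n_planted]:
        pad = 5
        s2, e2 = max(0, s - pad), min(glen, e + pad)
        if far_enough(s2, e2):
            gaps.append((s2, e2))
    attempts = 0
    while len(gaps) < cfg.n_gaps and attempts < cfg.n_gaps * 200:
        attempts += 1
        length = int(rng.integers(cfg.gap_length_range[0],
                                  cfg.gap_length_range[1] + 1))
        s = int(rng.integers(1000, glen - length - 1000))
        e = s + length
        if far_enough(s, e) and all(not (s < b < e) for b in bounds):
            gaps.append((s, e))
    gaps.sort()

    draft: dict[str, str] = {}
    truth = {"gaps": [], "scaffolds": []}
    for si, (b0, b1) in enumerate(zip(bounds, bounds[1:])):
        name = f"scaffold{si:03d}"
        local_gaps = [(s, e) for s, e in gaps if b0 <= s and e <= b1]
        pieces = []
        cursor = b0
        draft_pos = 0
        for s, e in local_gaps:
            pieces.append(genome[cursor:s])
            draft_pos += s - cursor
            true_len = e - s
            declared = max(1, int(round(true_len * (1.0 + rng.uniform(
                -cfg.size_distortion, cfg.size_distortion)))))
            pieces.append("N" * declared)
            truth["gaps"].append({
                "scaffold": name,
                "draft_interval": (draft_pos, draft_pos + declared),
                "true_interval": (s, e),
                "true_sequence": genome[s:e],
                "declared_size": declared})
            draft_pos += declared
            cursor = e
        pieces.append(genome[cursor:b1])
        draft[name] = "".join(pieces)
        truth["scaffolds"].append({"scaffold": name, "genome_interval": (b0, b1)})
    return draft, truth


# ---------------------------------------------------------------------------
# MAGIC founders

def simulate_magic_founders(cfg: MagicConfig, seed: int = 0
                            ) -> tuple[FounderMatrix, dict]:
    """Founder-painted progeny with a recombination-suppressed interval.

    Crossover positions are drawn from a piecewise-constant intensity that is
    zero inside the suppressed interval; founder codes switch at each
    crossover.  Markers sit on a regular grid.
    """
    rng = np.random.default_rng(seed)
    L = cfg.chrom_length
    sup = cfg.suppressed_interval
    if sup is not None and (sup[0] < 0 or sup[1] > L or sup[0] >= sup[1]):
        raise ConfigError("suppressed interval outside chromosome")
    active_len = L - (0 if sup is None else (sup[1] - sup[0]))
    positions = np.arange(cfg.marker_spacing / 2, L, cfg.marker_spacing)
    codes = np.full((cfg.n_progeny, len(positions)), MISSING, dtype=np.int16)
    truth = {"crossovers": []}
    for p in range(cfg.n_progeny):
        n_co = rng.poisson(cfg.crossovers_per_progeny)
        xs = np.sort(rng.uniform(0, active_len, size=n_co))
        if sup is not None:
            xs = np.where(xs >= sup[0], xs + (sup[1] - sup[0]), xs)
        founders = [int(rng.integers(cfg.n_founders))]
        for _ in range(n_co):
            nxt = int(rng.integers(cfg.n_founders - 1))
            if nxt >= founders[-1]:
                nxt += 1
            founders.append(nxt)
        seg_idx = np.searchsorted(xs, positions, "right")
        codes[p] = np.asarray(founders, dtype=np.int16)[seg_idx]
        truth["crossovers"].append(list(map(float, xs)))
    if cfg.missing_rate > 0:
        mask = rng.random(codes.shape) < cfg.missing_rate
        codes[mask] = MISSING
    fm = FounderMatrix([f"progeny{i:04d}" for i in range(cfg.n_progeny)],
                       positions, codes,
                       founders=tuple(range(cfg.n_founders)))
    return fm, truth


# ---------------------------------------------------------------------------
# LD panel

def simulate_ld_panel(cfg: LdConfig, seed: int = 0
                      ) -> tuple[GenotypeMatrix, dict]:
    """Block-structured haplotype pools collapsed to diploid genotypes.

    Within a block every haplotype carries either the all-reference or the
    all-alternate pattern (D' = 1 by construction); blocks segregate
    independently.  Diploids are formed by random haplotype pairing.
    """
    rng = np.random.default_rng(seed)
    n_hap = 2 * cfg.n_samples
    hap_cols = []
    block_of = []
    for bi, block in enumerate(cfg.blocks):
        pattern = rng.random(n_hap) < block.freq
        for _ in range(block.n_snps):
            hap_cols.append(pattern.astype(np.int8))
            block_of.append(bi)
    haplotypes = np.column_stack(hap_cols)        # n_hap x n_snps
    genotypes = (haplotypes[0::2] + haplotypes[1::2]).astype(np.int8)
    if cfg.missing_rate > 0:
        mask = rng.random(genotypes.shape) < cfg.missing_rate
        genotypes[mask] = MISSING
    n_snps = haplotypes.shape[1]
    gm = GenotypeMatrix(
        [f"sample{i:04d}" for i in range(cfg.n_samples)],
        [f"snp{i:04d}" for i in range(n_snps)],
        np.arange(1, n_snps + 1, dtype=float) * cfg.snp_spacing,
        genotypes)
    return gm, {"haplotypes": haplotypes, "block_of": np.asarray(block_of)}
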