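"""Region-level analyses: crossover binning, alignment density, pairwise LD.

Crossovers are counted from a founder-assignment matrix of a multi-parent
(MAGIC-style) population: a crossover is recorded between consecutive
non-missing markers whose founder codes differ, placed at the interval
midpoint, and accumulated in fixed genomic bins (default 10 Mb).  The
recombination-suppressed ("centromeric") interval is the longest run of bins
whose count is at most a fraction f of the genome-wide mean.

Pairwise linkage disequilibrium follows the Haploview conventions: two-locus
haplotype frequencies by EM over unphased diploid genotypes (only the
double-heterozygote phase is ambiguous), D' = |D|/Dmax, a genotype
likelihood-ratio LOD against D = 0, and the three-way colour classification
(D' = 1 with LOD > 2 -> high; LOD < 2 -> none; otherwise low-medium).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import Gff3Feature, log, revcomp

MISSING = -1


# ---------------------------------------------------------------------------
# containers

@dataclass
class FounderMatrix:
    progeny_ids: list[str]
    positions: np.ndarray            # marker physical positions, bp
    codes: np.ndarray                # progeny x markers, int codes, MISSING=-1
    founders: tuple = ()

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.codes = np.asarray(self.codes)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        if self.codes.shape != (len(self.progeny_ids), len(self.positions)):
            raise ValueError("codes shape does not match progeny x markers")


@dataclass
class GenotypeMatrix:
    sample_ids: list[str]
    snp_ids: list[str]
    positions: np.ndarray
    genotypes: np.ndarray            # samples x snps in {0,1,2}, MISSING=-1

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    def maf(self) -> np.ndarray:
        g = np.ma.masked_equal(self.genotypes, MISSING)
        freq = g.mean(axis=0).filled(np.nan) / 2.0
        return np.minimum(freq, 1.0 - freq)


@dataclass
class CrossoverProfile:
    bin_size: float
    counts: np.ndarray
    zero_runs: list[tuple[float, float]]         # bp intervals of zero bins
    suppressed_interval: tuple[float, float] | None
    suppressed_fraction: float
    note: str = ("suppressed interval = longest run of bins with count <= "
                 "f * genome-wide mean; operational stand-in for a "
                 "recombination-suppressed centromeric region")


@dataclass
class BinnedDensity:
    bin_size: float
    unique: np.ndarray
    multi: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.unique + self.multi


@dataclass
class LDResult:
    snp_a: str
    snp_b: str
    hap_freqs: tuple[float, float, float, float]   # AB, Ab, aB, ab
    d: float
    d_prime: float
    lod: float
    ld_class: str                                  # high | low-medium | none


# ---------------------------------------------------------------------------
# crossovers

def count_crossovers(fm: FounderMatrix, bin_size: float = 10e6,
                     chrom_length: float | None = None,
                     suppressed_fraction: float = 0.1) -> CrossoverProfile:
    """Bin founder-switch midpoints across all progeny.

    A switch between consecutive non-missing markers counts one crossover at
    the interval midpoint.  zero_runs are maximal runs of empty bins;
    the suppressed interval is the longest run of bins at or below
    suppressed_fraction of the mean per-bin count.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    length = chrom_length if chrom_length is not None else float(self_len(fm))
    n_bins = int(np.ceil(length / bin_size))
    counts = np.zeros(n_bins)
    pos = fm.positions
    for row in fm.codes:
        obs = np.nonzero(row != MISSING)[0]
        if len(obs) < 2:
            continue
        codes = row[obs]
        where = np.nonzero(codes[1:] != codes[:-1])[0]
        for w in where:
            mid = 0.5 * (pos[obs[w]] + pos[obs[w + 1]])
            counts[min(int(mid // bin_size), n_bins - 1)] += 1
    zero_runs = [(s * bin_size, min(e * bin_size, length))
                 for s, e in _runs(counts == 0)]
    mean = counts.mean() if n_bins else 0.0
    low = counts <= suppressed_fraction * mean
    runs = _runs(low)
    suppressed = None
    if runs and mean > 0:
        s, e = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
        suppressed = (s * bin_size, min(e * bin_size, length))
    return CrossoverProfile(bin_size, counts, zero_runs, suppressed,
                            suppressed_fraction)


def self_len(fm: FounderMatrix) -> float:
    return float(fm.positions[-1]) + 1.0


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def total_switches(fm: FounderMatrix) -> int:
    """Independent conservation check: founder switches summed over progeny."""
    n = 0
    for row in fm.codes:
        obs = row[row != MISSING]
        n += int(np.sum(obs[1:] != obs[:-1]))
    return n


# ---------------------------------------------------------------------------
# binned alignment density

def binned_density(records: Sequence, bin_size: float, chrom_length: float,
                   seed: int = 0) -> BinnedDensity:
    """Count alignment records in bins, unique and multi-mapped separately.

    Each record carries all tied best locations: either a bare sequence of
    positions or an object with .hits (taking hit.target_start).  Unique
    records are counted at their location; multi-mapped records once, at a
    tied location chosen uniformly at random under the seed.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rng = np.random.default_rng(seed)
    n_bins = int(np.ceil(chrom_length / bin_size))
    unique = np.zeros(n_bins)
    multi = np.zeros(n_bins)
    for rec in records:
        if hasattr(rec, "hits"):
            locs = [h.target_start for h in rec.hits]
        else:
            locs = list(rec)
        if not locs:
            continue
        if len(locs) == 1:
            loc, arr = locs[0], unique
        else:
            loc, arr = locs[int(rng.integers(len(locs)))], multi
        arr[min(int(loc // bin_size), n_bins - 1)] += 1
    return BinnedDensity(bin_size, unique, multi)


def motif_density(sequence: str, motifs: str | Sequence[str], bin_size: float
                  ) -> BinnedDensity:
    """Exact occurrence counts of motifs (both strands) in bins.

    Used as a repeat-family proxy track; every occurrence counts at its
    forward-strand start position and is reported in the 'unique' channel.
    """
    if isinstance(motifs, str):
        motifs = [motifs]
    if not motifs or any(not m for m in motifs):
        raise ValueError("empty motif set")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    seq = sequence.upper()
    n_bins = int(np.ceil(len(seq) / bin_size)) or 1
    counts = np.zeros(n_bins)
    for motif in motifs:
        probes = {motif.upper(), revcomp(motif.upper())}
        for probe in probes:
            start = seq.find(probe)
            while start != -1:
                counts[min(int(start // bin_size), n_bins - 1)] += 1
                start = seq.find(probe, start + 1)
    return BinnedDensity(bin_size, counts, np.zeros(n_bins))


# ---------------------------------------------------------------------------
# two-locus EM and LD

def genotype_counts(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """3x3 pairwise genotype table over pairwise-complete samples."""
    ok = (ga != MISSING) & (gb != MISSING)
    table = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            table[i, j] = np.sum((ga[ok] == i) & (gb[ok] == j))
    return table


def estimate_haplotype_frequencies(table: np.ndarray, tol: float = 1e-9,
                                   max_iter: int = 1000
                                   ) -> tuple[float, float, float, float]:
    """Two-locus haplotype frequencies (AB, Ab, aB, ab) by EM.

    table[i, j] = number of samples carrying i copies of allele A and j of
    allele B.  Only the double heterozygote is phase-ambiguous; EM starts at
    linkage equilibrium and iterates to the ML solution.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (3, 3) or np.any(t < 0):
        raise ValueError("need a non-negative 3x3 genotype table")
    n = t.sum()
    if n == 0:
        raise ValueError("no double-typed samples")
    pa = (2 * t[2, :].sum() + t[1, :].sum()) / (2 * n)
    pb = (2 * t[:, 2].sum() + t[:, 1].sum()) / (2 * n)
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("monomorphic locus: D' undefined")
    # haplotype counts fixed by unambiguous cells
    fixed = np.zeros(4)  # AB, Ab, aB, ab
    contrib = {
        (2, 2): (2, 0, 0, 0), (2, 1): (1, 1, 0, 0), (2, 0): (0, 2, 0, 0),
        (1, 2): (1, 0, 1, 0), (1, 0): (0, 1, 0, 1),
        (0, 2): (0, 0, 2, 0), (0, 1): (0, 0, 1, 1), (0, 0): (0, 0, 0, 2)}
    for (i, j), c in contrib.items():
        fixed += t[i, j] * np.asarray(c, dtype=float)
    n_dh = t[1, 1]
    h = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    for _ in range(max_iter):
        cis = h[0] * h[3]
        trans = h[1] * h[2]
        q = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        counts = fixed.copy()
        counts[0] += n_dh * q
        counts[3] += n_dh * q
        counts[1] += n_dh * (1 - q)
        counts[2] += n_dh * (1 - q)
        new = counts / (2 * n)
        if np.max(np.abs(new - h)) < tol:
            h = new
            break
        h = new
    return tuple(float(x) for x in h)


def _genotype_loglik(table: np.ndarray, h: Sequence[float]) -> float:
    p11, p10, p01, p00 = h
    probs = np.array([
        [p00 ** 2, 2 * p00 * p01, p01 ** 2],
        [2 * p00 * p10, 2 * (p11 * p00 + p10 * p01), 2 * p01 * p11],
        [p10 ** 2, 2 * p10 * p11, p11 ** 2]])
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(table > 0, table * np.log(np.maximum(probs, 1e-300)), 0.0)
    return float(ll.sum())


def ld_statistics(table: np.ndarray) -> tuple[tuple, float, float, float]:
    """(hap_freqs, D, D', LOD) for a 3x3 pairwise genotype table."""
    h = estimate_haplotype_frequencies(table)
    p11, p10, p01, p00 = h
    pa, pb = p11 + p10, p11 + p01
    d = p11 - pa * pb
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    d_prime = abs(d) / dmax if dmax > 0 else 0.0
    h0 = (pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb))
    lod = (_genotype_loglik(table, h) - _genotype_loglik(table, h0)) / np.log(10)
    return h, float(d), float(min(d_prime, 1.0)), float(lod)


def classify_ld(d_prime: float, lod: float) -> str:
    if lod < 2.0:
        return "none"
    if d_prime >= 1.0 - 1e-9:
        return "high"
    return "low-medium"


def pairwise_ld(gm: GenotypeMatrix, maf_min: float = 0.3,
                gene_features: Sequence[Gff3Feature] | None = None,
                flank: float = 2000.0) -> list[LDResult]:
    """All-pairs D'/LOD over SNPs passing the MAF and gene-flank filters.

    SNPs are kept when MAF > maf_min and, if gene features are given, when
    positioned within a gene span extended by flank bp on each side.
    """
    maf = gm.maf()
    keep = maf > maf_min
    if gene_features is not None:
        spans = [(f.start - flank, f.end + flank) for f in gene_features
                 if f.ftype == "gene"]
        in_gene = np.array([any(s <= p < e for s, e in spans)
                            for p in gm.positions])
        keep &= in_gene
    idx = np.nonzero(keep)[0]
    if len(idx) < 2:
        log("pairwise_ld: fewer than 2 SNPs retained after filtering")
        return []
    results = []
    for x in range(len(idx)):
        for y in range(x + 1, len(idx)):
            i, j = idx[x], idx[y]
            table = genotype_counts(gm.genotypes[:, i], gm.genotypes[:, j])
            try:
                h, d, dp, lod = ld_statistics(table)
            except ValueError:
                continue
            results.append(LDResult(gm.snp_ids[i], gm.snp_ids[j], h, d, dp,
                                    lod, classify_ld(dp, lod)))
    return results


# ---------------------------------------------------------------------------
# founder / genotype tables on disk

def write_founder_matrix(fm: FounderMatrix, path, seed: int | None = None) -> None:
    """TSV: header row of marker positions; one progeny per line."""
    from .io import provenance_header
    with open(path, "w") as fh:
        fh.write(provenance_header(seed) + "\n")
        fh.write("progeny_id\t" + "\t".join(f"{p:.0f}" for p in fm.positions) + "\n")
        for pid, row in zip(fm.progeny_ids, fm.codes):
            fh.write(pid + "\t" + "\t".join("." if c == MISSING else str(int(c))
                                            for c in row) + "\n")


def read_founder_matrix(path) -> FounderMatrix:
    from .io import FormatError
    progeny, rows = [], []
    positions = None
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if positions is None:
                positions = np.array([float(x) for x in f[1:]])
                continue
            progeny.append(f[0])
            rows.append([MISSING if x == "." else int(x) for x in f[1:]])
    if positions is None:
        raise FormatError(f"{path}: empty founder matrix")
    return FounderMatrix(progeny, positions, np.array(rows, dtype=np.int16))


def write_genotype_matrix(gm: GenotypeMatrix, path, seed: int | None = None) -> None:
    from .io import provenance_header
    with open(path, "w") as fh:
        fh.write(provenance_header(seed) + "\n")
        fh.write("sample_id\t" + "\t".join(gm.snp_ids) + "\n")
        fh.write("#position\t" + "\t".join(f"{p:.0f}" for p in gm.positions) + "\n")
        for sid, row in zip(gm.sample_ids, gm.genotypes):
            fh.write(sid + "\t" + "\t".join("." if g == MISSING else str(int(g))
                                            for g in row) + "\n")


def read_genotype_matrix(path) -> GenotypeMatrix:
    from .io import FormatError
    samples, rows = [], []
    snp_ids = positions = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#position"):
                positions = np.array([float(x) for x in line.split("\t")[1:]])
                continue
            if line.startswith("#"):
                continue
            f = line.split("\t")
            if snp_ids is None:
                snp_ids = f[1:]
                continue
            samples.append(f[0])
            rows.append([MISSING if x == "." else int(x) for x in f[1:]])
    if snp_ids is None or positions is None:
        raise FormatError(f"{path}: missing header rows")
    return GenotypeMatrix(samples, snp_ids, positions,
                          np.array(rows, dtype=np.int8))


def read_vcf_genotypes(path) -> GenotypeMatrix:
    """Minimal biallelic VCF reader (GT field only, diploid)."""
    from .io import FormatError
    samples = None
    snp_ids, positions, rows = [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            f = line.split("\t")
            if samples is None or len(f) < 10:
                raise FormatError(f"{path}:{ln}: malformed VCF line")
            if "," in f[4]:
                continue                      # multi-allelic: skipped
            snp_ids.append(f[2] if f[2] != "." else f"{f[0]}:{f[1]}")
            positions.append(float(f[1]))
            gt_idx = f[8].split(":").index("GT")
            row = []
            for sample in f[9:]:
                gt = sample.split(":")[gt_idx].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles:
                    row.append(MISSING)
                else:
                    row.append(sum(int(a) for a in alleles))
            rows.append(row)
    order = np.argsort(positions, kind="stable")
    arr = np.array(rows, dtype=np.int8)[order].T
    return GenotypeMatrix(samples, [snp_ids[i] for i in order],
                          np.array(positions)[order], arr)
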