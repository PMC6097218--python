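"""Shared format readers and writers.

All coordinates are 0-based half-open internally.  AGP and GFF3 use their
native 1-based inclusive conventions on disk; the converters here are exact
inverses of each other.  Machine outputs carry a provenance comment header
(tool version, seed, config hash) and logs go to stderr, never stdout.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__version__ = "0.1.0"


class FormatError(ValueError):
    """Malformed input; message carries file and line context where known."""


# ---------------------------------------------------------------------------
# provenance

def provenance_header(seed: int | None = None, config: Mapping | None = None) -> str:
    """One-line comment header stamped on TSV/AGP outputs."""
    cfg_hash = "-"
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        cfg_hash = hashlib.sha1(blob).hexdigest()[:12]
    return f"# finishkit v{__version__} seed={seed if seed is not None else '-'} config={cfg_hash}"


def log(msg: str) -> None:
    print(f"[finishkit] {msg}", file=sys.stderr)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {seq_id: sequence} dict (upper-cased)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def n_runs(sequence: str) -> list[tuple[int, int]]:
    """Maximal runs of N as 0-based half-open intervals."""
    runs = []
    start = None
    for i, c in enumerate(sequence):
        if c == "N":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(sequence)))
    return runs


# ---------------------------------------------------------------------------
# AGP v2.1

@dataclass
class AgpComponent:
    object_id: str
    object_beg: int          # 0-based half-open on the object
    object_end: int
    part_number: int
    component_type: str      # W/F/O ... or N/U for gaps
    component_id: str | None = None
    component_beg: int | None = None   # 0-based half-open on the component
    component_end: int | None = None
    orientation: str | None = None     # +, -, ?, na
    gap_length: int | None = None
    gap_type: str | None = None
    linkage: str | None = None
    evidence: str | None = None

    @property
    def is_gap(self) -> bool:
        return self.component_type in ("N", "U")


def read_agp(path: str | Path) -> list[AgpComponent]:
    comps: list[AgpComponent] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise FormatError(f"{path}:{ln}: AGP line has {len(f)} fields (need >= 8)")
            try:
                obj, beg, end, part, ctype = f[0], int(f[1]), int(f[2]), int(f[3]), f[4]
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: {e}") from None
            if ctype in ("N", "U"):
                comps.append(AgpComponent(obj, beg - 1, end, part, ctype,
                                          gap_length=int(f[5]), gap_type=f[6],
                                          linkage=f[7],
                                          evidence=f[8] if len(f) > 8 else "na"))
            else:
                comps.append(AgpComponent(obj, beg - 1, end, part, ctype,
                                          component_id=f[5],
                                          component_beg=int(f[6]) - 1,
                                          component_end=int(f[7]),
                                          orientation=f[8] if len(f) > 8 else "?"))
    _validate_agp(comps, str(path))
    return comps


def _validate_agp(comps: Sequence[AgpComponent], source: str) -> None:
    by_obj: dict[str, list[AgpComponent]] = {}
    for c in comps:
        by_obj.setdefault(c.object_id, []).append(c)
    for obj, parts in by_obj.items():
        pos = 0
        for c in sorted(parts, key=lambda c: c.part_number):
            if c.object_beg != pos:
                raise FormatError(
                    f"{source}: AGP components for {obj} do not tile: "
                    f"part {c.part_number} starts at {c.object_beg}, expected {pos}")
            if c.object_end <= c.object_beg:
                raise FormatError(f"{source}: empty/negative span in {obj} part {c.part_number}")
            pos = c.object_end


def write_agp(comps: Iterable[AgpComponent], path: str | Path,
              seed: int | None = None, config: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, config) + "\n")
        fh.write("##agp-version\t2.1\n")
        for c in comps:
            base = [c.object_id, str(c.object_beg + 1), str(c.object_end),
                    str(c.part_number), c.component_type]
            if c.is_gap:
                rest = [str(c.gap_length), c.gap_type or "scaffold",
                        c.linkage or "yes", c.evidence or "na"]
            else:
                rest = [c.component_id or "", str((c.component_beg or 0) + 1),
                        str(c.component_end or 0), c.orientation or "?"]
            fh.write("\t".join(base + rest) + "\n")


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED: (chrom, start, end, name); name '' when absent."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{ln}: BED line needs >= 3 fields")
            out.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ""))
    return out


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


# ---------------------------------------------------------------------------
# GFF3 (gene/mRNA/CDS tables)

@dataclass
class Gff3Feature:
    seqid: str
    source: str
    ftype: str
    start: int           # 0-based half-open
    end: int
    score: str
    strand: str
    phase: str
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def id(self) -> str | None:
        return self.attributes.get("ID")

    @property
    def parent(self) -> str | None:
        return self.attributes.get("Parent")


def read_gff3(path: str | Path, seq_lengths: Mapping[str, int] | None = None
              ) -> list[Gff3Feature]:
    feats: list[Gff3Feature] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}:{ln}: GFF3 line has {len(f)} fields (need 9)")
            attrs = {}
            for kv in f[8].split(";"):
                if kv and "=" in kv:
                    k, v = kv.split("=", 1)
                    attrs[k.strip()] = v.strip()
            feat = Gff3Feature(f[0], f[1], f[2], int(f[3]) - 1, int(f[4]),
                               f[5], f[6], f[7], attrs)
            if feat.end <= feat.start:
                raise FormatError(f"{path}:{ln}: empty/negative feature span")
            if seq_lengths is not None and feat.seqid in seq_lengths:
                if feat.end > seq_lengths[feat.seqid]:
                    raise FormatError(
                        f"{path}:{ln}: feature {feat.id or f[2]} extends beyond "
                        f"{feat.seqid} length {seq_lengths[feat.seqid]}")
            feats.append(feat)
    _validate_gff3(feats, str(path))
    return feats


def _validate_gff3(feats: Sequence[Gff3Feature], source: str) -> None:
    spans = {f.id: (f.seqid, f.start, f.end) for f in feats if f.id}
    for f in feats:
        if f.parent and f.parent in spans:
            pseq, pstart, pend = spans[f.parent]
            if f.seqid != pseq or f.start < pstart or f.end > pend:
                raise FormatError(
                    f"{source}: {f.ftype} at {f.seqid}:{f.start}-{f.end} outside "
                    f"parent {f.parent} span {pseq}:{pstart}-{pend}")


# ---------------------------------------------------------------------------
# generic TSV tables

def read_tsv(path: str | Path, columns: Sequence[str] | None = None):
    """Read a TSV with optional '#' comment lines into a pandas DataFrame."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t", comment="#")
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
    return df


def write_tsv(df, path: str | Path, seed: int | None = None,
              config: Mapping | None = None) -> None:
    buf = _io.StringIO()
    buf.write(provenance_header(seed, config) + "\n")
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# sequence helpers

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)
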