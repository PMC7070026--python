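"""Readers/writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open.  VCF (1-based) is converted
on read and write; nothing else in the package ever sees a 1-based
coordinate.  Readers reject malformed records rather than silently repairing
them, and every reader that drops records reports how many and why.

Missing signal-track data is a distinct state (NaN), never imputed as 0:
operations that average tracks skip missing bases and report the coverage
fraction, because real methylation/recombination tracks have gaps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "GenomicInterval",
    "Variant",
    "SignalTrack",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
    "read_variants",
    "write_variants_tsv",
    "write_vcf",
    "merge_intervals",
    "subtract_intervals",
    "intersect_intervals",
    "total_length",
    "write_manifest",
]

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """A line could not be parsed; the message names the line number."""


class ValidationError(ValueError):
    """A record parsed but violates an invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom`` (0-based)."""

    chrom: str
    start: int
    end: int
    score: float | None = field(default=None, compare=False)
    label: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Variant:
    """A sequence variant in 0-based coordinates.

    ``vtype`` is derived: SNV iff both alleles are single differing bases,
    otherwise INS/DEL by allele-length comparison.
    """

    chrom: str
    pos0: int
    ref: str
    alt: str
    group: str = ""
    sample: str = ""

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise ValidationError(f"empty allele at {self.chrom}:{self.pos0}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt at {self.chrom}:{self.pos0}")
        bad = set(self.ref + self.alt) - set("ACGT")
        if bad:
            raise ValidationError(
                f"non-ACGT allele characters {sorted(bad)} at "
                f"{self.chrom}:{self.pos0}"
            )

    @property
    def vtype(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def indel_len(self) -> int:
        return abs(len(self.ref) - len(self.alt))


class SignalTrack:
    """A per-chromosome step function: sorted non-overlapping intervals.

    Bases not covered by any interval are *missing* (returned as NaN),
    deliberately distinct from a value of 0.
    """

    def __init__(self, data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                 name: str = "", units: str = ""):
        self.name = name
        self.units = units
        self.data = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if np.any(starts[1:] < ends[:-1]) or np.any(np.diff(starts) < 0):
                raise ValidationError(
                    f"overlapping or unsorted intervals on {chrom}")
            if np.any(starts >= ends):
                raise ValidationError(f"empty interval on {chrom}")
            self.data[chrom] = (starts, ends, values)

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval],
                       name: str = "", units: str = "") -> "SignalTrack":
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        data = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda iv: iv.start)
            data[chrom] = (
                np.array([iv.start for iv in ivs]),
                np.array([iv.end for iv in ivs]),
                np.array([iv.score if iv.score is not None else np.nan
                          for iv in ivs]),
            )
        return cls(data, name=name, units=units)

    def chroms(self) -> list[str]:
        return list(self.data)

    def value_at(self, chrom: str, pos: int) -> float:
        """Value covering ``pos``, or NaN when the base is uncovered."""
        if chrom not in self.data:
            return np.nan
        starts, ends, values = self.data[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return np.nan

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`value_at`."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.shape, np.nan)
        if chrom not in self.data:
            return out
        starts, ends, values = self.data[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        out[ok] = values[idx[ok]]
        return out

    def mean_over(self, chrom: str, start: int, end: int) -> tuple[float, float]:
        """Mean value over covered bases in [start, end).

        Returns ``(mean, coverage_fraction)``; mean is NaN when no base in
        the window is covered.
        """
        if end <= start:
            raise ValidationError("empty window")
        if chrom not in self.data:
            return np.nan, 0.0
        starts, ends, values = self.data[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return np.nan, 0.0
        s = np.clip(starts[lo:hi], start, end)
        e = np.clip(ends[lo:hi], start, end)
        w = (e - s).astype(float)
        covered = w.sum()
        if covered == 0:
            return np.nan, 0.0
        return float(np.sum(values[lo:hi] * w) / covered), float(covered / (end - start))

    def to_array(self, chrom: str, length: int) -> np.ndarray:
        """Rasterize to a per-base float array; uncovered bases are NaN."""
        arr = np.full(length, np.nan)
        if chrom in self.data:
            starts, ends, values = self.data[chrom]
            for s, e, v in zip(starts, ends, values):
                arr[max(s, 0):min(e, length)] = v
        return arr


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def read_bed(path, has_score: bool = False) -> list[GenomicInterval]:
    """Read BED3/BED6 into sorted :class:`GenomicInterval` records."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated "
                                 f"fields, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            label = fields[3] if len(fields) > 3 else None
            score = None
            if has_score and len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            try:
                intervals.append(GenomicInterval(fields[0], start, end,
                                                 score=score, label=label))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.label is not None or iv.score is not None:
                fields.append(iv.label if iv.label is not None else ".")
            if iv.score is not None:
                fields.append(format_float(iv.score))
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path, name: str = "", units: str = "") -> SignalTrack:
    """Read a 4-column bedGraph; overlapping intervals are an error."""
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns, "
                                 f"got {len(fields)}")
            try:
                rec = (int(fields[1]), int(fields[2]), float(fields[3]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad numeric field") from exc
            if rec[0] >= rec[1]:
                raise ValidationError(f"{path}:{lineno}: empty interval")
            by_chrom.setdefault(fields[0], []).append(rec)
    data = {}
    for chrom, recs in by_chrom.items():
        recs.sort()
        starts = np.array([r[0] for r in recs])
        ends = np.array([r[1] for r in recs])
        if np.any(starts[1:] < ends[:-1]):
            raise ValidationError(f"{path}: overlapping intervals on {chrom}")
        data[chrom] = (starts, ends, np.array([r[2] for r in recs]))
    return SignalTrack(data, name=name or str(path), units=units)


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            starts, ends, values = track.data[chrom]
            for s, e, v in zip(starts, ends, values):
                if np.isnan(v):
                    continue  # missing stays absent from the file
                fh.write(f"{chrom}\t{s}\t{e}\t{format_float(v)}\n")


def format_float(x: float) -> str:
    """Deterministic compact float formatting for all TSV/BED output."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Load a FASTA into an upper-cased dict chrom -> sequence."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

TSV_COLUMNS = ("chrom", "pos", "ref", "alt", "group", "sample")


def read_variants(path, fmt: str = "auto", max_indel_len: int | None = None,
                  genome: Mapping[str, str] | None = None,
                  ) -> tuple[list[Variant], dict]:
    """Read variants from VCF or the package TSV dialect.

    Positions are normalized to 0-based; multi-allelic VCF records are
    split; INDELs longer than ``max_indel_len`` are dropped and counted in
    the returned report.  When ``genome`` is given, REF alleles are checked
    against it and mismatches raise :class:`ValidationError`.

    TSV dialect: '#'-comment lines allowed; header required with columns
    ``chrom, pos0|pos1, ref, alt[, group, sample]`` — the position column
    name declares the coordinate base.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "vcf" if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz") else "tsv"
    if fmt == "vcf":
        variants = _read_vcf(path)
    elif fmt == "tsv":
        variants = _read_tsv_variants(path)
    else:
        raise ValueError(f"unknown variant format {fmt!r}")

    report = {"n_read": len(variants), "dropped_long_indels": 0}
    if max_indel_len is not None:
        kept = []
        for v in variants:
            if v.vtype != "SNV" and v.indel_len > max_indel_len:
                report["dropped_long_indels"] += 1
            else:
                kept.append(v)
        variants = kept
    report["n_kept"] = len(variants)

    if genome is not None:
        bad = [v for v in variants
               if genome.get(v.chrom, "")[v.pos0:v.pos0 + len(v.ref)] != v.ref]
        if bad:
            shown = ", ".join(f"{v.chrom}:{v.pos0}:{v.ref}" for v in bad[:5])
            raise ValidationError(
                f"{len(bad)} variant REF alleles disagree with the genome "
                f"(first offenders: {shown})")
    return variants, report


def _read_vcf(path) -> list[Variant]:
    import pysam

    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            for alt in rec.alts:  # split multi-allelics
                if alt is None or set(alt) - set("ACGT") or set(rec.ref) - set("ACGT"):
                    continue  # symbolic / non-ACGT alleles are not supported
                sample = rec.samples.keys()[0] if rec.samples else ""
                variants.append(Variant(rec.chrom, rec.start, rec.ref, alt,
                                        sample=sample))
    return variants


def _read_tsv_variants(path) -> list[Variant]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = list(df.columns)
    if not cols or cols[0] != "chrom" or cols[1] not in ("pos0", "pos1"):
        raise ParseError(
            f"{path}: TSV variant header must start with 'chrom' and "
            "'pos0' or 'pos1' (declaring the coordinate base)")
    offset = 0 if cols[1] == "pos0" else 1
    variants = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        variants.append(Variant(
            d["chrom"], int(d[cols[1]]) - offset, d["ref"], d["alt"],
            group=str(d.get("group", "") or ""),
            sample=str(d.get("sample", "") or "")))
    return variants


def write_variants_tsv(variants: Sequence[Variant], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos0\tref\talt\tgroup\tsample\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos0}\t{v.ref}\t{v.alt}\t{v.group}\t{v.sample}\n")


def write_vcf(variants: Sequence[Variant], path,
              contigs: Mapping[str, int] | None = None) -> None:
    """Write a minimal sorted VCF 4.2 (positions converted to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for chrom, length in contigs.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos0)):
            fh.write(f"{v.chrom}\t{v.pos0 + 1}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# interval set algebra (sorted, per-chromosome numpy boundaries)
# ---------------------------------------------------------------------------

def _bounds(intervals: Iterable[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, pairs in by.items():
        pairs.sort()
        out[chrom] = (np.array([p[0] for p in pairs], dtype=np.int64),
                      np.array([p[1] for p in pairs], dtype=np.int64))
    return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: sorted, non-overlapping, adjacent runs merged."""
    out = []
    for chrom, (starts, ends) in sorted(_bounds(intervals).items()):
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, int(cur_s), int(cur_e)))
    return out


def subtract_intervals(a: Iterable[GenomicInterval],
                       b: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Set difference a \\ b."""
    a = merge_intervals(a)
    b = list(b)
    bb = _bounds(merge_intervals(b)) if b else {}
    out = []
    for iv in a:
        if iv.chrom not in bb:
            out.append(iv)
            continue
        starts, ends = bb[iv.chrom]
        cur = iv.start
        lo = np.searchsorted(ends, iv.start, side="right")
        hi = np.searchsorted(starts, iv.end, side="left")
        for s, e in zip(starts[lo:hi], ends[lo:hi]):
            if s > cur:
                out.append(GenomicInterval(iv.chrom, int(cur), int(s)))
            cur = max(cur, e)
        if cur < iv.end:
            out.append(GenomicInterval(iv.chrom, int(cur), iv.end))
    return out


def intersect_intervals(a: Iterable[GenomicInterval],
                        b: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    a = merge_intervals(a)
    b = list(b)
    bb = _bounds(merge_intervals(b)) if b else {}
    out = []
    for iv in a:
        if iv.chrom not in bb:
            continue
        starts, ends = bb[iv.chrom]
        lo = np.searchsorted(ends, iv.start, side="right")
        hi = np.searchsorted(starts, iv.end, side="left")
        for s, e in zip(starts[lo:hi], ends[lo:hi]):
            s2, e2 = max(s, iv.start), min(e, iv.end)
            if s2 < e2:
                out.append(GenomicInterval(iv.chrom, int(s2), int(e2)))
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in merge_intervals(intervals))


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def write_manifest(path, command: str, inputs: Mapping, parameters: Mapping,
                   seed: int | None) -> None:
    """JSON run-manifest: inputs, parameters, seed, package versions.

    Content is fully determined by the arguments (no timestamps), so reruns
    with the same seed produce byte-identical manifests.
    """
    import numpy
    import scipy
    from . import __version__

    manifest = {
        "command": command,
        "inputs": dict(inputs),
        "parameters": dict(parameters),
        "seed": seed,
        "versions": {"nucmut": __version__, "numpy": numpy.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
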