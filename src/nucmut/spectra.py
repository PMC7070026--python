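"""96-type mutation spectra, trinucleotide background correction,
per-type Fisher tests, and mutational-signature refitting.

Single-base substitutions are classified on the pyrimidine strand into the
canonical 96 types (6 substitutions x 4 five-prime x 4 three-prime flanks).
Because a region set (e.g. strong-nucleosome territory) has a different
trinucleotide composition than the genome, raw per-type counts F_i are
rescaled to the genome background before signature refitting:

    F_corrected_i = F_i / N_tri(i) * N_tri_genome(i)

where N_tri(i) counts the occurrences of type i's trinucleotide context in
the region set and N_tri_genome(i) genome-wide.  Per-type enrichment is
tested with a two-sided Fisher exact test on the raw-count table
[[F_region, N_region - F_region], [F_genome - F_region,
(N_genome - N_region) - (F_genome - F_region)]], BH-corrected across the
96 types.  Signature refitting solves the non-negative least-squares
problem argmin_{w>=0} ||S w - spectrum||_2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

from .io import GenomicInterval, ValidationError, Variant, revcomp

__all__ = [
    "MUTATION_TYPES_96", "TRINUC_CONTEXTS_32",
    "SpectrumCounts", "SignatureFit",
    "classify_96", "spectrum_with_background", "background_correct",
    "fisher_per_type", "refit_signatures",
    "count_trinucleotides", "type_context_index",
]

_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
MUTATION_TYPES_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in _SUBS for five in "ACGT" for three in "ACGT"
)
_TYPE_INDEX = {t: i for i, t in enumerate(MUTATION_TYPES_96)}

# 32 pyrimidine-centered trinucleotide contexts, ordered to match the types
TRINUC_CONTEXTS_32 = tuple(
    f"{five}{center}{three}"
    for center in "CT" for five in "ACGT" for three in "ACGT"
)
_CONTEXT_INDEX = {c: i for i, c in enumerate(TRINUC_CONTEXTS_32)}


def type_context_index(type_idx: int) -> int:
    """Map a 96-type index to its 32-context index."""
    label = MUTATION_TYPES_96[type_idx]
    tri = label[0] + label[2] + label[6]
    return _CONTEXT_INDEX[tri]


def classify_96(variant: Variant, genome: Mapping[str, str]) -> int:
    """Canonical 96-type index of an SNV; purine refs are strand-collapsed.

    Raises :class:`ValidationError` for non-SNVs or when a flank contains N
    or falls outside the contig (the caller counts these as unclassifiable).
    """
    if variant.vtype != "SNV":
        raise ValidationError("classify_96 requires an SNV")
    seq = genome[variant.chrom]
    p = variant.pos0
    if p < 1 or p + 2 > len(seq):
        raise ValidationError("flank outside contig")
    five, ref, three = seq[p - 1], seq[p], seq[p + 1]
    if ref != variant.ref:
        raise ValidationError(f"REF mismatch at {variant.chrom}:{p}")
    alt = variant.alt
    if ref in "AG":  # purine: report on the pyrimidine strand
        five, ref, three = revcomp(three), revcomp(ref), revcomp(five)
        alt = revcomp(alt)
    label = f"{five}[{ref}>{alt}]{three}"
    if label not in _TYPE_INDEX:
        raise ValidationError(f"unclassifiable context {label}")
    return _TYPE_INDEX[label]


_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def count_trinucleotides(genome: Mapping[str, str],
                         regions: Sequence[GenomicInterval] | None = None,
                         ) -> np.ndarray:
    """Strand-collapsed trinucleotide counts (length-32 vector).

    A base contributes when it sits inside a region (or anywhere, when
    ``regions`` is None) and both flanking bases lie within the contig with
    no N anywhere in the triplet.  Purine-centered triplets are counted as
    their reverse complement.
    """
    counts = np.zeros(32, dtype=np.int64)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    if regions is not None:
        for iv in regions:
            by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, seq in genome.items():
        code = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        if len(code) < 3:
            continue
        left, center, right = code[:-2], code[1:-1], code[2:]
        valid = (left >= 0) & (center >= 0) & (right >= 0)
        # collapse purine-centered triplets onto the pyrimidine strand
        # (codes A=0 C=1 G=2 T=3; purines are A and G)
        pur = (center == 0) | (center == 2)
        l_c = np.where(pur, 3 - right, left)
        c_c = np.where(pur, 3 - center, center)
        r_c = np.where(pur, 3 - left, right)
        # context index: center C->0, T->1 block of 16; 4*five + three
        ctx = (c_c == 3).astype(np.int64) * 16 + l_c * 4 + r_c
        if regions is None:
            sel = valid
        else:
            sel = np.zeros(len(center), dtype=bool)
            for iv in by_chrom.get(chrom, []):
                lo = max(iv.start, 1)
                hi = min(iv.end, len(seq) - 1)
                if lo < hi:
                    sel[lo - 1:hi - 1] = True  # center index offset by 1
            sel &= valid
        counts += np.bincount(ctx[sel], minlength=32)
    return counts


@dataclass
class SpectrumCounts:
    """Raw and background counts for a region set and the whole workspace."""

    F: np.ndarray               # 96 region counts
    N_tri: np.ndarray           # 32 region trinucleotide counts
    F_genome: np.ndarray        # 96 workspace counts
    N_tri_genome: np.ndarray    # 32 workspace trinucleotide counts
    n_unclassifiable: int = 0

    def to_frame(self) -> pd.DataFrame:
        ctx = [type_context_index(i) for i in range(96)]
        return pd.DataFrame({
            "type": MUTATION_TYPES_96,
            "F": self.F, "F_genome": self.F_genome,
            "N_tri": self.N_tri[ctx], "N_tri_genome": self.N_tri_genome[ctx],
        })


def spectrum_with_background(variants: Sequence[Variant],
                             regions: Sequence[GenomicInterval],
                             genome: Mapping[str, str],
                             workspace: Sequence[GenomicInterval] | None = None,
                             ) -> SpectrumCounts:
    """Count the 96-type spectrum inside ``regions`` and over the workspace.

    ``workspace`` defaults to the whole genome.  Non-SNVs and N-context
    SNVs are skipped and counted in ``n_unclassifiable``.
    """
    starts_by: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for iv in regions:
        s, e = starts_by.setdefault(iv.chrom, ([], []))
        s.append(iv.start)
        e.append(iv.end)
    starts_by = {c: (np.sort(np.array(s)), np.array(sorted(e)))
                 for c, (s, e) in starts_by.items()}

    def in_regions(chrom, pos):
        if chrom not in starts_by:
            return False
        s, e = starts_by[chrom]
        i = np.searchsorted(s, pos, side="right") - 1
        return i >= 0 and pos < e[i]

    F = np.zeros(96, dtype=np.int64)
    F_genome = np.zeros(96, dtype=np.int64)
    n_bad = 0
    for v in variants:
        if v.vtype != "SNV":
            continue
        try:
            t = classify_96(v, genome)
        except ValidationError:
            n_bad += 1
            continue
        F_genome[t] += 1
        if in_regions(v.chrom, v.pos0):
            F[t] += 1
    N_tri = count_trinucleotides(genome, regions)
    N_tri_genome = count_trinucleotides(genome, workspace)
    return SpectrumCounts(F, N_tri, F_genome, N_tri_genome, n_bad)


def background_correct(counts: SpectrumCounts) -> np.ndarray:
    """Rescale region counts to the genome trinucleotide background.

    F_corrected_i = F_i / N_tri(i) * N_tri_genome(i); a type with zero
    context occurrence and zero observed count corrects to 0, but a count
    without any context occurrence is an impossible input and raises.
    """
    ctx = np.array([type_context_index(i) for i in range(96)])
    n_region = counts.N_tri[ctx].astype(float)
    n_genome = counts.N_tri_genome[ctx].astype(float)
    F = counts.F.astype(float)
    bad = (F > 0) & (n_region == 0)
    if np.any(bad):
        which = [MUTATION_TYPES_96[i] for i in np.nonzero(bad)[0]]
        raise ValidationError(f"counts without context occurrences: {which}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(n_region > 0, F / np.maximum(n_region, 1) * n_genome, 0.0)
    return out


def fisher_per_type(counts: SpectrumCounts) -> pd.DataFrame:
    """Two-sided Fisher exact test per mutation type, BH across 96 types.

    Contingency table per type i (raw integer counts):
    [[F_region, N_region - F_region],
     [F_genome - F_region, (N_genome - N_region) - (F_genome - F_region)]].
    Direction is the sign of (odds ratio - 1): +1 enriched in regions.
    """
    ctx = np.array([type_context_index(i) for i in range(96)])
    rows = []
    for i in range(96):
        a = int(counts.F[i])
        b = int(counts.N_tri[ctx[i]]) - a
        c = int(counts.F_genome[i]) - a
        d = (int(counts.N_tri_genome[ctx[i]]) - int(counts.N_tri[ctx[i]])) - c
        if min(a, b, c, d) < 0:
            raise ValidationError(
                f"negative contingency cell for {MUTATION_TYPES_96[i]}")
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        direction = int(np.sign(a * d - b * c))  # sign of (odds ratio - 1)
        rows.append((MUTATION_TYPES_96[i], a, b, c, d, p, direction))
    df = pd.DataFrame(rows, columns=["type", "a", "b", "c", "d", "p", "direction"])
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


@dataclass
class SignatureFit:
    weights: pd.Series          # non-negative, indexed by signature name
    residual: float             # L2 reconstruction residual
    percent: pd.Series          # 100 * w / sum(w); zeros when sum(w) == 0


def refit_signatures(spectrum: np.ndarray, signatures: pd.DataFrame) -> SignatureFit:
    """Express a 96-vector as a non-negative combination of signatures.

    ``signatures``: 96 x K frame, columns sum to 1, rows indexed by (or
    ordered as) the canonical 96 labels.  Corrected non-integer spectra are
    accepted as-is.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != (96,):
        raise ValidationError("spectrum must have 96 entries")
    if np.any(spectrum < 0):
        raise ValidationError("negative spectrum entries")
    S = signatures.to_numpy(dtype=float)
    if S.shape[0] != 96:
        raise ValidationError("signature matrix must have 96 rows")
    if not np.allclose(S.sum(axis=0), 1.0, atol=1e-6):
        raise ValidationError("signature columns must sum to 1")
    if list(signatures.index) == sorted(MUTATION_TYPES_96):
        # accept alphabetically-sorted input but fit in canonical order
        S = signatures.loc[list(MUTATION_TYPES_96)].to_numpy(dtype=float)
    w, rnorm = nnls(S, spectrum)
    weights = pd.Series(w, index=signatures.columns, name="weight")
    total = w.sum()
    percent = pd.Series(100.0 * w / total if total > 0 else np.zeros_like(w),
                        index=signatures.columns, name="percent")
    return SignatureFit(weights, float(rnorm), percent)
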