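"""Translational-positioning statistics from MNase-seq fragment midpoints.

For a focal genomic base, collect the absolute distances ``d_i`` to every
fragment midpoint within +/-95 bp (the half nucleosome-repeat-length bound,
closed at 95) and summarize them as

    d_mean = sum(d_i) / n                  (0 <= d <= 95)
    d_var  = sum((d_i - d_mean)^2) / (n-1)

Low ``d_var`` means the surrounding nucleosomes occupy nearly the same
translational position across cells ("strong" positioning); ``d_mean``
locates the base relative to the dyad (small = near dyad, ~95 = linker).
Sites with fewer than 10 midpoints in the window are unusable, as are sites
below the mappability threshold.

Occupancy is the ratio of observed midpoint coverage to a composition- or
uniformly-matched simulated control, in 10-bp bins anchored at coordinate 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (GenomicInterval, SignalTrack, ValidationError,
                 intersect_intervals, merge_intervals, subtract_intervals,
                 total_length)

__all__ = [
    "FragmentMidpointSet",
    "SiteNucleosomeStats",
    "ContextPartition",
    "fragment_midpoint",
    "site_positioning_stats",
    "batch_positioning_stats",
    "bin_dmean",
    "DMEAN_BIN_UPPER",
    "midpoint_coverage",
    "compute_occupancy",
    "simulate_control_fragments",
    "usable_sites_filter",
    "classify_stability_terciles",
    "partition_genome_context",
]

DMEAN_BIN_UPPER = np.array([18.0, 36.0, 54.0, 73.0, 95.0])
WINDOW_DEFAULT = 95
MIN_MIDPOINTS_DEFAULT = 10


def fragment_midpoint(start: int, end: int) -> int:
    """Midpoint of a half-open fragment; left-of-center for even lengths."""
    return start + (end - start - 1) // 2


class FragmentMidpointSet:
    """Genome-sorted MNase fragment midpoint positions per chromosome."""

    def __init__(self, positions: Mapping[str, np.ndarray]):
        self.positions = {}
        for chrom, pos in positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if np.any(np.diff(arr) < 0):
                arr = np.sort(arr)
            self.positions[chrom] = arr

    @classmethod
    def from_fragments(cls, intervals: Iterable[GenomicInterval]) -> "FragmentMidpointSet":
        by: dict[str, list[int]] = {}
        for iv in intervals:
            by.setdefault(iv.chrom, []).append(fragment_midpoint(iv.start, iv.end))
        return cls({c: np.sort(v) for c, v in by.items()})

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.positions.values())

    def chroms(self) -> list[str]:
        return list(self.positions)

    def in_window(self, chrom: str, lo: int, hi: int) -> np.ndarray:
        """Midpoints with position in the closed range [lo, hi]."""
        pos = self.positions.get(chrom)
        if pos is None:
            return np.empty(0, dtype=np.int64)
        i = np.searchsorted(pos, lo, side="left")
        j = np.searchsorted(pos, hi, side="right")
        return pos[i:j]

    def to_intervals(self) -> list[GenomicInterval]:
        return [GenomicInterval(c, int(p), int(p) + 1)
                for c, pos in sorted(self.positions.items()) for p in pos]


@dataclass(frozen=True)
class SiteNucleosomeStats:
    chrom: str
    pos0: int
    n: int
    d_mean: float      # NaN when n == 0
    d_var: float       # NaN when n < 2
    d_mean_bin: int    # 0 when undefined
    occupancy: float   # NaN when unavailable
    usable: bool


def site_positioning_stats(chrom: str, pos0: int, midpoints: FragmentMidpointSet,
                           window: int = WINDOW_DEFAULT,
                           min_midpoints: int = MIN_MIDPOINTS_DEFAULT,
                           occupancy: float = np.nan) -> SiteNucleosomeStats:
    """Positioning statistics for one focal site.

    Distances use the closed bound |midpoint - site| <= window.  With no
    midpoint in the window the statistics are missing (NaN), never 0; with a
    single midpoint d_var is missing (the n-1 denominator is undefined).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    mids = midpoints.in_window(chrom, pos0 - window, pos0 + window)
    n = len(mids)
    if n == 0:
        return SiteNucleosomeStats(chrom, pos0, 0, np.nan, np.nan, 0,
                                   occupancy, False)
    d = np.abs(mids - pos0).astype(float)
    d_mean = float(np.mean(d))
    d_var = float(np.var(d, ddof=1)) if n >= 2 else np.nan
    return SiteNucleosomeStats(chrom, pos0, n, d_mean, d_var,
                               bin_dmean(d_mean), occupancy,
                               n >= min_midpoints)


def batch_positioning_stats(positions: np.ndarray, midpoints: np.ndarray,
                            window: int = WINDOW_DEFAULT,
                            min_midpoints: int = MIN_MIDPOINTS_DEFAULT,
                            ) -> pd.DataFrame:
    """Vectorized positioning stats for many sites on one chromosome.

    Uses prefix sums over the sorted midpoint array, O((S+M) log M); agrees
    with :func:`site_positioning_stats` to floating-point rounding.
    Columns: pos0, n, d_mean, d_var, d_mean_bin, usable.
    """
    positions = np.asarray(positions, dtype=np.int64)
    m = np.sort(np.asarray(midpoints, dtype=np.int64)).astype(float)
    ps1 = np.concatenate([[0.0], np.cumsum(m)])
    ps2 = np.concatenate([[0.0], np.cumsum(m * m)])
    lo = np.searchsorted(m, positions - window, side="left")
    hi = np.searchsorted(m, positions + window, side="right")
    k = np.clip(np.searchsorted(m, positions, side="left"), lo, hi)
    n = (hi - lo).astype(float)
    s = positions.astype(float)
    sum_below = ps1[k] - ps1[lo]
    n_below = (k - lo).astype(float)
    sum_all = ps1[hi] - ps1[lo]
    sum_d = (n_below * s - sum_below) + ((sum_all - sum_below) - (n - n_below) * s)
    sum_d2 = (ps2[hi] - ps2[lo]) - 2.0 * s * sum_all + n * s * s
    with np.errstate(invalid="ignore", divide="ignore"):
        d_mean = np.where(n > 0, sum_d / np.maximum(n, 1), np.nan)
        d_var = np.where(n > 1,
                         np.maximum(sum_d2 - n * d_mean ** 2, 0.0) / np.maximum(n - 1, 1),
                         np.nan)
    d_mean = np.where(n > 0, d_mean, np.nan)
    bins = np.zeros(len(positions), dtype=int)
    ok = ~np.isnan(d_mean)
    bins[ok] = np.searchsorted(DMEAN_BIN_UPPER, d_mean[ok], side="left") + 1
    return pd.DataFrame({
        "pos0": positions, "n": (hi - lo).astype(int), "d_mean": d_mean,
        "d_var": d_var, "d_mean_bin": bins,
        "usable": (hi - lo) >= min_midpoints,
    })


def bin_dmean(d_mean: float) -> int:
    """Five d_mean categories: [0,18], [19,36], [37,54], [55,73], [74,95].

    The printed integer bins leave gaps for non-integer means; a real-valued
    d_mean maps to bin k iff d_mean in (upper(k-1), upper(k)] with upper =
    (18, 36, 54, 73, 95), which reproduces the integer behaviour exactly.
    """
    if not (0 <= d_mean <= 95):
        raise ValueError(f"d_mean {d_mean} outside [0, 95]")
    return int(np.searchsorted(DMEAN_BIN_UPPER, d_mean, side="left")) + 1


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

def midpoint_coverage(midpoints: FragmentMidpointSet, chrom: str,
                      length: int) -> np.ndarray:
    """Per-base midpoint count array for one chromosome."""
    cov = np.zeros(length, dtype=np.int64)
    pos = midpoints.positions.get(chrom)
    if pos is not None:
        valid = pos[(pos >= 0) & (pos < length)]
        np.add.at(cov, valid, 1)
    return cov


def compute_occupancy(observed: Mapping[str, np.ndarray],
                      control: Mapping[str, np.ndarray],
                      bin_size: int = 10) -> SignalTrack:
    """Per-bin occupancy = sum(observed coverage) / sum(control coverage).

    Bins tile each chromosome from position 0.  Bins whose control sum is 0
    are missing (absent from the track), not 0 or infinity.
    """
    data = {}
    for chrom, obs in observed.items():
        ctl = control.get(chrom)
        if ctl is None or len(ctl) != len(obs):
            raise ValidationError(f"control coverage missing/mismatched on {chrom}")
        if np.any(obs < 0) or np.any(ctl < 0):
            raise ValidationError("negative coverage")
        nbins = int(np.ceil(len(obs) / bin_size))
        pad = nbins * bin_size - len(obs)
        obs_b = np.pad(obs.astype(float), (0, pad)).reshape(nbins, bin_size).sum(1)
        ctl_b = np.pad(ctl.astype(float), (0, pad)).reshape(nbins, bin_size).sum(1)
        keep = ctl_b > 0
        idx = np.nonzero(keep)[0]
        data[chrom] = (idx * bin_size, np.minimum((idx + 1) * bin_size, len(obs)),
                       obs_b[keep] / ctl_b[keep])
    return SignalTrack(data, name="occupancy", units="ratio")


def simulate_control_fragments(workspace: Mapping[str, int] | Sequence[GenomicInterval],
                               n: int, length: int = 25,
                               mode: str = "uniform",
                               genome: Mapping[str, str] | None = None,
                               observed: FragmentMidpointSet | None = None,
                               seed: int | None = None,
                               rng: np.random.Generator | None = None,
                               ) -> FragmentMidpointSet:
    """Sample control fragment midpoints over the workspace.

    ``uniform`` draws fragment starts uniformly.  ``gc_weighted`` reweights
    candidate starts by the GC content of the 5-mer at the start so the
    control matches the base composition of the observed fragment ends
    (requires ``genome`` and ``observed``).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    if isinstance(workspace, Mapping):
        segs = [GenomicInterval(c, 0, L) for c, L in workspace.items()]
    else:
        segs = merge_intervals(workspace)
    if not segs and n > 0:
        raise ValidationError("empty workspace")
    if n == 0:
        return FragmentMidpointSet({})
    lens = np.array([max(len(s) - length + 1, 0) for s in segs], dtype=float)
    if lens.sum() == 0:
        raise ValidationError("workspace segments shorter than fragment length")

    if mode == "uniform":
        seg_idx = rng.choice(len(segs), size=n, p=lens / lens.sum())
        offs = rng.integers(0, lens[seg_idx].astype(np.int64))
        by: dict[str, list[int]] = {}
        for i, o in zip(seg_idx, offs):
            s = segs[i]
            by.setdefault(s.chrom, []).append(s.start + int(o) + (length - 1) // 2)
        return FragmentMidpointSet({c: np.sort(v) for c, v in by.items()})
    if mode == "gc_weighted":
        if genome is None or observed is None:
            raise ValueError("gc_weighted mode needs genome and observed midpoints")
        return _gc_weighted_control(segs, n, length, genome, observed, rng)
    raise ValueError(f"unknown mode {mode!r}")


def _gc_weighted_control(segs, n, length, genome, observed, rng):
    # empirical GC-class (0..5 G/C bases in the 5-mer at the fragment start)
    # frequencies among observed starts, relative to the workspace background
    def gc5(chrom, start):
        return sum(b in "GC" for b in genome[chrom][start:start + 5])

    obs_counts = np.zeros(6)
    half = (length - 1) // 2
    for chrom, mids in observed.positions.items():
        for mp in mids[:: max(1, len(mids) // 5000)]:  # subsample for speed
            start = int(mp) - half
            if 0 <= start and start + 5 <= len(genome.get(chrom, "")):
                obs_counts[gc5(chrom, start)] += 1
    obs_freq = obs_counts / max(obs_counts.sum(), 1)

    cand_chrom, cand_start, cand_gc = [], [], []
    for s in segs:
        seq = genome[s.chrom]
        for st in range(s.start, min(s.end - length + 1, len(seq) - 4)):
            cand_chrom.append(s.chrom)
            cand_start.append(st)
            cand_gc.append(gc5(s.chrom, st))
    cand_gc = np.array(cand_gc)
    bg_counts = np.bincount(cand_gc, minlength=6).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_class = np.where(bg_counts > 0, obs_freq / np.maximum(bg_counts, 1), 0.0)
    w = w_class[cand_gc]
    w = w / w.sum()
    pick = rng.choice(len(cand_start), size=n, p=w)
    by: dict[str, list[int]] = {}
    for i in pick:
        by.setdefault(cand_chrom[i], []).append(cand_start[i] + half)
    return FragmentMidpointSet({c: np.sort(v) for c, v in by.items()})


# ---------------------------------------------------------------------------
# filters and partitions
# ---------------------------------------------------------------------------

def usable_sites_filter(sites: Sequence[tuple[str, int]],
                        stats: pd.DataFrame | None,
                        mappability: SignalTrack | None,
                        min_mappability: float = 90.0,
                        min_midpoints: int = MIN_MIDPOINTS_DEFAULT) -> np.ndarray:
    """Boolean usable mask: enough midpoints AND mappable at the focal base.

    Missing mappability excludes a site (conservative).  ``stats`` rows must
    align with ``sites``; pass None to skip the midpoint-count criterion.
    """
    mask = np.ones(len(sites), dtype=bool)
    if stats is not None:
        mask &= np.asarray(stats["n"]) >= min_midpoints
    if mappability is not None:
        by: dict[str, list[int]] = {}
        for i, (chrom, pos) in enumerate(sites):
            by.setdefault(chrom, []).append(i)
        for chrom, idx in by.items():
            idx = np.array(idx)
            vals = mappability.values_at(chrom, np.array([sites[i][1] for i in idx]))
            mask[idx] &= ~np.isnan(vals) & (vals >= min_mappability)
    return mask


def classify_stability_terciles(dyads: pd.DataFrame) -> pd.Series:
    """Split dyads into high/middle/low stability terciles by score.

    Sizes differ by at most one; remainders go to the lower-score groups
    first.  Ties are broken by (chrom, pos0) order so the labelling is
    invariant to input row order.
    """
    if len(dyads) < 3:
        raise ValidationError("need at least 3 dyads")
    scores = dyads["stability_score"].to_numpy(dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValidationError("non-finite stability scores")
    if np.all(scores == scores[0]):
        raise ValidationError("all stability scores equal: no ordering")
    order = np.lexsort((dyads["pos0"].to_numpy(), dyads["chrom"].to_numpy(), scores))
    n = len(dyads)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]  # low gets extra first
    labels = np.empty(n, dtype=object)
    bounds = np.cumsum([0] + sizes)
    for name, lo, hi in zip(("low", "middle", "high"), bounds[:-1], bounds[1:]):
        labels[order[lo:hi]] = name
    return pd.Series(labels, index=dyads.index, name="stability_class")


@dataclass(frozen=True)
class ContextPartition:
    strong: tuple[GenomicInterval, ...]
    rotational_only: tuple[GenomicInterval, ...]
    other: tuple[GenomicInterval, ...]


def partition_genome_context(strong: Sequence[GenomicInterval],
                             rotational: Sequence[GenomicInterval],
                             workspace: Sequence[GenomicInterval]) -> ContextPartition:
    """Three-way disjoint genome partition with strong taking precedence.

    strong | rotational-but-not-strong | everything else; the three classes
    tile the workspace exactly.
    """
    ws = merge_intervals(workspace)
    for name, ivs in (("strong", strong), ("rotational", rotational)):
        if total_length(intersect_intervals(ivs, ws)) != total_length(ivs):
            raise ValidationError(f"{name} intervals extend outside the workspace")
    strong_m = intersect_intervals(strong, ws)
    rot_only = subtract_intervals(intersect_intervals(rotational, ws), strong_m)
    other = subtract_intervals(subtract_intervals(ws, strong_m), rot_only)
    return ContextPartition(tuple(strong_m), tuple(rot_only), tuple(other))
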