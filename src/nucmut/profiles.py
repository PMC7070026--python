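"""Randomization enrichment, dyad-anchored meta-profiles, and repair
escape-ratio profiles.

Enrichment of events in an annotation is measured against a randomization
null: every event is re-placed uniformly within the (chromosome-matched)
workspace 10,000 times, giving an expected overlap count, a fold
enrichment, sampling-percentile confidence bounds, and an empirical
two-sided p (+1 corrected so p is never 0).

The escape ratio compares per-bin mutation densities of a repair-proficient
cohort A and a repair-deficient cohort B around dyads, normalized by their
genome-wide background densities estimated from randomly placed 1600-bp
windows:

    R_i = (m_i^A / m_i^B) / (mbar^A / mbar^B)

R_i > 1 means replication errors disproportionately escape repair in bin i.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (GenomicInterval, SignalTrack, ValidationError, Variant,
                 merge_intervals)

__all__ = [
    "EnrichmentResult", "MetaProfile",
    "randomized_enrichment", "meta_profile",
    "escape_ratio", "escape_ratio_profile", "fisher_escape_region",
]


@dataclass
class EnrichmentResult:
    observed: int
    expected: float
    fold: float
    fold_ci: tuple[float, float]   # 2.5 / 97.5 sampling percentiles
    p: float                       # empirical two-sided, +1 corrected
    n_samples: int


def _workspace_arrays(workspace: Sequence[GenomicInterval]):
    by: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in sorted({iv.chrom for iv in workspace}):
        ivs = sorted((iv for iv in merge_intervals(workspace)
                      if iv.chrom == chrom), key=lambda iv: iv.start)
        starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        ends = np.array([iv.end for iv in ivs], dtype=np.int64)
        offsets = np.concatenate([[0], np.cumsum(ends - starts)])
        by[chrom] = (starts, ends, offsets)
    return by


def _annotation_bounds(annotation: Sequence[GenomicInterval]):
    by: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for iv in merge_intervals(annotation):
        s = by.setdefault(iv.chrom, ([], []))
        s[0].append(iv.start)
        s[1].append(iv.end)
    return {c: (np.array(s), np.array(e)) for c, (s, e) in by.items()}


def _points_in(bounds, chrom, positions):
    if chrom not in bounds:
        return np.zeros(len(positions), dtype=bool)
    starts, ends = bounds[chrom]
    i = np.searchsorted(starts, positions, side="right") - 1
    return (i >= 0) & (positions < ends[np.clip(i, 0, None)])


def randomized_enrichment(events: Sequence[tuple[str, int]] | Sequence[GenomicInterval],
                          annotation: Sequence[GenomicInterval],
                          workspace: Sequence[GenomicInterval],
                          n_samples: int = 10_000,
                          seed: int | None = None,
                          rng: np.random.Generator | None = None,
                          ) -> EnrichmentResult:
    """Observed vs expected event count in an annotation, by randomization.

    Each sample re-places every event uniformly within the workspace,
    preserving its chromosome (and, for interval events, its length, placed
    wholly inside a workspace segment).  p = 2 * min(tails) with the +1
    correction, capped at 1; the fold CI is observed / [97.5, 2.5]
    percentiles of the sampled counts.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    ws = _workspace_arrays(workspace)
    ann = _annotation_bounds(annotation)
    interval_mode = len(events) > 0 and isinstance(events[0], GenomicInterval)

    if interval_mode:
        ev_by = {}
        for iv in events:
            ev_by.setdefault(iv.chrom, []).append((iv.start, iv.end))
        observed = sum(
            int(np.any(_points_in(ann, chrom, np.arange(s, e))))
            for chrom, pairs in ev_by.items() for s, e in pairs)
        counts = _sample_interval_counts(ev_by, ws, ann, n_samples, rng)
    else:
        ev_by = {}
        for chrom, pos in events:
            ev_by.setdefault(chrom, []).append(pos)
        observed = 0
        for chrom, positions in ev_by.items():
            observed += int(_points_in(ann, chrom, np.asarray(positions)).sum())
        counts = np.zeros(n_samples, dtype=np.int64)
        for chrom, positions in sorted(ev_by.items()):
            if chrom not in ws:
                raise ValidationError(f"events on {chrom} outside workspace")
            starts, ends, offsets = ws[chrom]
            total = offsets[-1]
            draws = rng.integers(0, total, size=(n_samples, len(positions)))
            seg = np.searchsorted(offsets, draws, side="right") - 1
            pos = starts[seg] + (draws - offsets[seg])
            counts += _points_in(ann, chrom, pos).sum(axis=1)

    expected = float(counts.mean())
    fold = observed / expected if expected > 0 else np.inf
    hi_tail = int(np.sum(counts >= observed))
    lo_tail = int(np.sum(counts <= observed))
    p = min(1.0, 2.0 * (1 + min(hi_tail, lo_tail)) / (n_samples + 1))
    q_lo, q_hi = np.percentile(counts, [97.5, 2.5])
    ci = (observed / q_lo if q_lo > 0 else np.inf,
          observed / q_hi if q_hi > 0 else np.inf)
    return EnrichmentResult(observed, expected, fold, ci, p, n_samples)


def _sample_interval_counts(ev_by, ws, ann, n_samples, rng):
    counts = np.zeros(n_samples, dtype=np.int64)
    for chrom, pairs in sorted(ev_by.items()):
        if chrom not in ws:
            raise ValidationError(f"events on {chrom} outside workspace")
        starts, ends, _ = ws[chrom]
        seg_lens = ends - starts
        for s, e in pairs:
            length = e - s
            valid = seg_lens >= length
            if not np.any(valid):
                raise ValidationError(
                    f"interval of length {length} exceeds every workspace "
                    f"segment on {chrom}")
            slots = (seg_lens[valid] - length + 1).astype(float)
            segs = np.nonzero(valid)[0]
            pick = rng.choice(len(segs), size=n_samples, p=slots / slots.sum())
            offs = rng.integers(0, slots[pick].astype(np.int64))
            new_s = starts[segs[pick]] + offs
            # overlap if any annotation interval intersects [new_s, new_s+len)
            if chrom in ann:
                a_s, a_e = ann[chrom]
                i = np.searchsorted(a_s, new_s + length, side="left") - 1
                hit = (i >= 0) & (a_e[np.clip(i, 0, None)] > new_s)
                counts += hit
    return counts


@dataclass
class MetaProfile:
    bin_starts: np.ndarray     # bp offsets relative to anchor (negative = upstream)
    values: np.ndarray         # events per bp per anchor, or mean signal
    n_anchors: int
    n_dropped_anchors: int
    bin_size: int
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_start": self.bin_starts, "value": self.values})


def meta_profile(anchors: Sequence[tuple[str, int]],
                 events: Sequence[tuple[str, int]] | None = None,
                 signal: SignalTrack | None = None,
                 chrom_lengths: Mapping[str, int] | None = None,
                 window: int = 1000, bin_size: int = 10,
                 mode: str = "event_density") -> MetaProfile:
    """Binned profile of events or signal around anchor positions.

    Offsets are event - anchor in [-window, window); bin 0 starts at the
    anchor.  ``event_density`` reports count / (bin_size * n_anchors);
    ``signal_mean`` averages the track over anchors ignoring missing bases.
    Anchors whose window leaves the contig are dropped and counted
    (requires ``chrom_lengths``).
    """
    if window % bin_size:
        raise ValidationError("window must be a multiple of bin size")
    if not anchors:
        raise ValidationError("no anchors")
    kept, dropped = [], 0
    for chrom, pos in anchors:
        if chrom_lengths is not None:
            L = chrom_lengths.get(chrom, 0)
            if pos - window < 0 or pos + window > L:
                dropped += 1
                continue
        kept.append((chrom, pos))
    if not kept:
        raise ValidationError("all anchors dropped at contig edges")
    nbins = 2 * window // bin_size
    bin_starts = np.arange(-window, window, bin_size)

    if mode == "event_density":
        if events is None:
            raise ValidationError("event_density mode needs events")
        ev_by: dict[str, np.ndarray] = {}
        for chrom, pos in events:
            ev_by.setdefault(chrom, []).append(pos)
        ev_by = {c: np.sort(np.asarray(v, dtype=np.int64))
                 for c, v in ev_by.items()}
        hist = np.zeros(nbins, dtype=np.int64)
        for chrom, pos in kept:
            ev = ev_by.get(chrom)
            if ev is None:
                continue
            lo = np.searchsorted(ev, pos - window, side="left")
            hi = np.searchsorted(ev, pos + window, side="left")
            offs = ev[lo:hi] - pos
            hist += np.bincount((offs + window) // bin_size, minlength=nbins)
        values = hist / (bin_size * len(kept))
        return MetaProfile(bin_starts, values, len(kept), dropped, bin_size,
                           mode)
    if mode == "signal_mean":
        if signal is None or chrom_lengths is None:
            raise ValidationError("signal_mean mode needs signal and chrom_lengths")
        arrays = {c: signal.to_array(c, L) for c, L in chrom_lengths.items()}
        acc = np.zeros(nbins)
        cnt = np.zeros(nbins)
        for chrom, pos in kept:
            sl = arrays[chrom][pos - window:pos + window].reshape(nbins, bin_size)
            ok = ~np.isnan(sl)
            acc += np.where(ok, sl, 0.0).sum(axis=1)
            cnt += ok.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(cnt > 0, acc / cnt, np.nan)
        return MetaProfile(bin_starts, values, len(kept), dropped, bin_size,
                           mode)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# escape ratios
# ---------------------------------------------------------------------------

def escape_ratio(m_a, m_b, mbar_a: float, mbar_b: float):
    """Background-normalized density ratio R = (m_a/m_b) / (mbar_a/mbar_b).

    Accepts scalars or arrays; undefined entries (m_b == 0) come back NaN.
    The ratio is scale-invariant: multiplying both cohorts' densities by a
    common factor leaves R unchanged.
    """
    m_a = np.asarray(m_a, dtype=float)
    m_b = np.asarray(m_b, dtype=float)
    if mbar_a <= 0 or mbar_b <= 0:
        raise ValidationError("background densities must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (m_a / m_b) / (mbar_a / mbar_b)
    r = np.where(m_b > 0, r, np.nan)
    return float(r) if r.ndim == 0 else r


def _positions_by_chrom(variants: Sequence[Variant]) -> dict[str, np.ndarray]:
    by: dict[str, list[int]] = {}
    for v in variants:
        by.setdefault(v.chrom, []).append(v.pos0)
    return {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in by.items()}


def escape_ratio_profile(cohort_a: Sequence[Variant],
                         cohort_b: Sequence[Variant],
                         dyads: pd.DataFrame,
                         chrom_lengths: Mapping[str, int],
                         window: int = 800, bin_size: int = 10,
                         bg_width: int = 1600,
                         n_bg_windows: int | None = None,
                         mappability: SignalTrack | None = None,
                         min_mappability: float = 100.0,
                         pseudocount: float = 0.0,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None,
                         ) -> pd.DataFrame:
    """Background-normalized escape-ratio profile around dyads.

    Per 10-bp bin i: m_i = cohort count / (bin_size * n dyads); the
    background density mbar of each cohort comes from ``n_bg_windows``
    (default: one per dyad) random ``bg_width``-bp windows; R_i =
    (m_i^A / m_i^B) / (mbar^A / mbar^B).  When a mappability track is
    given, dyads must have mappability >= ``min_mappability`` over the full
    +/-window, and background windows are drawn under the same constraint.
    Bins with zero cohort-B counts give missing R_i unless a
    ``pseudocount`` (e.g. 0.5) is requested.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    if not len(cohort_a) or not len(cohort_b):
        raise ValidationError("both cohorts must be nonempty")
    pos_a = _positions_by_chrom(cohort_a)
    pos_b = _positions_by_chrom(cohort_b)

    def dyad_ok(chrom, pos):
        L = chrom_lengths.get(chrom, 0)
        if pos - window < 0 or pos + window > L:
            return False
        if mappability is not None:
            mean, cov = mappability.mean_over(chrom, pos - window, pos + window)
            return cov == 1.0 and mean >= min_mappability
        return True

    usable = [(r.chrom, int(r.pos0)) for r in dyads.itertuples(index=False)
              if dyad_ok(r.chrom, int(r.pos0))]
    if not usable:
        raise ValidationError("no usable dyads after the mappability filter")
    nbins = 2 * window // bin_size
    bin_starts = np.arange(-window, window, bin_size)

    def bin_counts(pos_by):
        hist = np.zeros(nbins, dtype=np.int64)
        for chrom, pos in usable:
            ev = pos_by.get(chrom)
            if ev is None:
                continue
            lo = np.searchsorted(ev, pos - window, side="left")
            hi = np.searchsorted(ev, pos + window, side="left")
            hist += np.bincount((ev[lo:hi] - pos + window) // bin_size,
                                minlength=nbins)
        return hist

    count_a, count_b = bin_counts(pos_a), bin_counts(pos_b)
    n_dyads = len(usable)
    m_a = count_a / (bin_size * n_dyads)
    m_b = count_b / (bin_size * n_dyads)

    n_bg = n_bg_windows if n_bg_windows is not None else n_dyads
    bg_a = bg_b = 0
    total_width = 0
    chroms = sorted(chrom_lengths)
    lens = np.array([max(chrom_lengths[c] - bg_width, 0) for c in chroms],
                    dtype=float)
    if lens.sum() <= 0:
        raise ValidationError("chromosomes shorter than the background width")
    drawn = 0
    attempts = 0
    while drawn < n_bg and attempts < 50 * n_bg:
        attempts += 1
        ci = int(rng.choice(len(chroms), p=lens / lens.sum()))
        start = int(rng.integers(0, int(lens[ci])))
        chrom = chroms[ci]
        if mappability is not None:
            mean, cov = mappability.mean_over(chrom, start, start + bg_width)
            if cov < 1.0 or mean < min_mappability:
                continue
        for pos_by, which in ((pos_a, "a"), (pos_b, "b")):
            ev = pos_by.get(chrom)
            if ev is None:
                continue
            cnt = int(np.searchsorted(ev, start + bg_width, side="left")
                      - np.searchsorted(ev, start, side="left"))
            if which == "a":
                bg_a += cnt
            else:
                bg_b += cnt
        total_width += bg_width
        drawn += 1
    if drawn < n_bg:
        raise ValidationError("could not place enough background windows "
                              "under the mappability constraint")
    if bg_a == 0 or bg_b == 0:
        raise ValidationError("zero background mutations in a cohort: "
                              "escape ratio undefined")
    mbar_a = bg_a / total_width
    mbar_b = bg_b / total_width

    ca = count_a.astype(float) + pseudocount
    cb = count_b.astype(float) + pseudocount
    ratio = escape_ratio(ca, cb, mbar_a, mbar_b)
    return pd.DataFrame({
        "bin_start": bin_starts, "m_a": m_a, "m_b": m_b,
        "count_a": count_a, "count_b": count_b,
        "mbar_a": mbar_a, "mbar_b": mbar_b, "R": ratio,
        "n_dyads": n_dyads,
    })


def fisher_escape_region(cohort_a: Sequence[Variant],
                         cohort_b: Sequence[Variant],
                         dyads: pd.DataFrame,
                         region_halfwidth: int = 95,
                         all_halfwidth: int = 800) -> tuple[float, float]:
    """Fisher test for differential repair performance in dyad +/- 95 bp.

    Counts each cohort's mutations inside the strong region (dyad +/-
    ``region_halfwidth``) and inside all considered regions (dyad +/-
    ``all_halfwidth``) and tests the 2x2 table
    [[N^p_strong, N^p_all - N^p_strong], [N^d_strong, N^d_all - N^d_strong]].
    Returns (odds_ratio, p).
    """
    pos_a = _positions_by_chrom(cohort_a)
    pos_b = _positions_by_chrom(cohort_b)
    dy = {c: np.sort(g["pos0"].to_numpy(dtype=np.int64))
          for c, g in dyads.groupby("chrom")}

    def count_near(pos_by, halfwidth):
        n = 0
        for chrom, d in dy.items():
            ev = pos_by.get(chrom)
            if ev is None:
                continue
            i = np.searchsorted(d, ev)
            near = np.zeros(len(ev), dtype=bool)
            right_ok = i < len(d)
            near[right_ok] |= (d[i[right_ok]] - ev[right_ok]) <= halfwidth
            left_ok = i > 0
            near[left_ok] |= (ev[left_ok] - d[i[left_ok] - 1]) <= halfwidth
            n += int(near.sum())
        return n

    n_strong_a = count_near(pos_a, region_halfwidth)
    n_all_a = count_near(pos_a, all_halfwidth)
    n_strong_b = count_near(pos_b, region_halfwidth)
    n_all_b = count_near(pos_b, all_halfwidth)
    cells = [[n_strong_a, n_all_a - n_strong_a],
             [n_strong_b, n_all_b - n_strong_b]]
    if min(min(r) for r in cells) < 0:
        raise ValidationError("negative derived contingency cell")
    odds, p = stats.fisher_exact(cells, alternative="two-sided")
    return float(odds), float(p)
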