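"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study conditions end to end: a first-order
Markov genome with tunable GC and CpG enrichment; a nucleosome landscape of
dyads spaced ~ one nucleosome repeat length (191.4 bp) whose MNase fragment
midpoints scatter around each dyad with a per-dyad Gaussian jitter SD
sigma_k (the stability ground truth — low sigma = strong translational
positioning); de novo mutations drawn from a known logistic model over
site features; paired repair-proficient/deficient cohorts with a known
escape-ratio step profile around dyads; signature-mixture SNV sets; and
smooth functional tracks.  Every generator records its ground truth
(beta*, sigma_k, R_i, w) so downstream stages have parameter-recovery tests
without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io import BASES, GenomicInterval, SignalTrack, ValidationError, Variant
from .nucstats import FragmentMidpointSet
from .spectra import (MUTATION_TYPES_96, TRINUC_CONTEXTS_32, _BASE_CODE,
                      type_context_index)

__all__ = [
    "SimConfig", "gen_genome", "gen_nucleosome_landscape",
    "gen_mutations_from_model", "gen_paired_cohorts",
    "gen_signature_mixture", "gen_tracks",
]

NRL_DEFAULT = 191.4
FRAGMENT_LENGTH_DEFAULT = 147


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generators.

    ``jitter_sd_range`` is the support of the per-dyad uniform jitter-SD
    draw (bp); the spread across dyads is what creates the stability
    gradient that d_var must recover.  The seed is mandatory: every
    generator draws from ``numpy.random.default_rng(seed)``.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrS1": 1_000_000})
    gc: float = 0.41
    cpg_enrichment: float = 0.25
    nrl: float = NRL_DEFAULT
    jitter_sd_range: tuple[float, float] = (3.0, 35.0)
    fragments_per_dyad: int = 50
    fragment_length: int = FRAGMENT_LENGTH_DEFAULT
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.gc < 1):
            raise ValidationError("GC fraction must be in (0, 1)")
        if self.cpg_enrichment < 0:
            raise ValidationError("CpG enrichment must be >= 0")
        if self.nrl <= self.jitter_sd_range[1]:
            raise ValidationError("NRL must exceed the jitter support")
        if self.seed is None:
            raise ValidationError("seed is mandatory")


def gen_genome(cfg: SimConfig,
               rng: np.random.Generator | None = None) -> dict[str, str]:
    """First-order Markov genome at the configured GC and CpG enrichment.

    Stationary base frequencies follow the GC fraction; the C->G transition
    probability is multiplied by the enrichment factor (0 removes CpG
    dinucleotides entirely, 1 gives independence).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    p = np.array([(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2])
    q = p.copy()  # transition row after a C
    q[2] *= cfg.cpg_enrichment
    q /= q.sum()
    cp = np.cumsum(p).tolist()
    cq = np.cumsum(q).tolist()
    genome = {}
    for chrom, length in cfg.chrom_lengths.items():
        out = []
        append = out.append
        prev_is_c = False
        for x in rng.random(length).tolist():
            c = cq if prev_is_c else cp
            if x < c[1]:
                b = "A" if x < c[0] else "C"
                prev_is_c = b == "C"
            else:
                b = "G" if x < c[2] else "T"
                prev_is_c = False
            append(b)
        genome[chrom] = "".join(out)
    return genome


def gen_nucleosome_landscape(genome: Mapping[str, str], cfg: SimConfig,
                             rng: np.random.Generator | None = None,
                             ) -> tuple[pd.DataFrame, FragmentMidpointSet,
                                        list[GenomicInterval], list[GenomicInterval]]:
    """Dyads, fragment midpoints, and strong/rotational region sets.

    Dyad spacing ~ Normal(NRL, NRL/10) truncated positive; each dyad gets
    ``fragments_per_dyad`` midpoints ~ round(Normal(dyad, sigma_k)) clipped
    to the contig.  Strong regions are dyad +/- 73 bp for the lowest-sigma
    tercile of dyads; rotational regions mirror the middle tercile (a
    purely structural stand-in so the three-way partition is exercisable).
    Returns (dyad table with ground-truth sigma_k, midpoints, strong,
    rotational).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    records = []
    mids_by: dict[str, list[np.ndarray]] = {}
    margin = 200
    for chrom, seq in genome.items():
        length = len(seq)
        pos = float(margin + rng.uniform(0, cfg.nrl))
        dyads = []
        while pos < length - margin:
            dyads.append(int(round(pos)))
            gap = rng.normal(cfg.nrl, cfg.nrl / 10.0)
            pos += max(gap, cfg.nrl / 4.0)  # truncate at a positive floor
        sigmas = rng.uniform(*cfg.jitter_sd_range, size=len(dyads))
        chrom_mids = []
        for dyad, sigma in zip(dyads, sigmas):
            m = np.round(rng.normal(dyad, sigma, size=cfg.fragments_per_dyad))
            chrom_mids.append(np.clip(m, 0, length - 1).astype(np.int64))
            records.append((chrom, dyad, sigma, -sigma))
        if chrom_mids:
            mids_by[chrom] = [np.sort(np.concatenate(chrom_mids))]
    dyad_df = pd.DataFrame(records,
                           columns=["chrom", "pos0", "sigma", "stability_score"])
    midpoints = FragmentMidpointSet(
        {c: v[0] for c, v in mids_by.items()})
    # stability terciles by sigma (low sigma = stable)
    strong, rotational = [], []
    if len(dyad_df) >= 3:
        q1, q2 = np.quantile(dyad_df["sigma"], [1 / 3, 2 / 3])
        for row in dyad_df.itertuples(index=False):
            lo = max(row.pos0 - 73, 0)
            hi = min(row.pos0 + 74, len(genome[row.chrom]))
            if row.sigma <= q1:
                strong.append(GenomicInterval(row.chrom, lo, hi))
            elif row.sigma <= q2:
                rotational.append(GenomicInterval(row.chrom, lo, hi))
    return dyad_df, midpoints, strong, rotational


def gen_mutations_from_model(genome: Mapping[str, str],
                             features: pd.DataFrame,
                             beta: Mapping[str, float],
                             n_target: int,
                             rng: np.random.Generator | None = None,
                             seed: int | None = None,
                             cpg_to_t_weight: float = 1.0,
                             ) -> tuple[list[Variant], dict]:
    """Mutate sites independently under a known logistic model.

    ``features`` needs ``chrom``, ``pos0`` and one numeric column per key
    of ``beta``.  The intercept is solved so the expected mutation count is
    ``n_target``.  SNV alternate alleles are uniform over the three
    non-reference bases, except that a C in CpG context mutates to T with
    relative weight ``cpg_to_t_weight``.  Returns the variants plus the
    ground truth (solved intercept and beta*).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    missing = set(beta) - set(features.columns)
    if missing:
        raise ValidationError(f"beta keys not in features: {sorted(missing)}")
    eta0 = np.zeros(len(features))
    for name, b in beta.items():
        eta0 += b * features[name].to_numpy(dtype=float)

    def expected(b0):
        return float(np.sum(expit(b0 + eta0))) - n_target

    b0 = brentq(expected, -50.0, 20.0)
    prob = expit(b0 + eta0)
    if prob.sum() < 50:
        import warnings
        warnings.warn("expected mutation count < 50: recovery tests will be "
                      "underpowered", RuntimeWarning)
    hit = rng.random(len(features)) < prob
    variants = []
    for chrom, pos0 in features.loc[hit, ["chrom", "pos0"]].itertuples(index=False):
        pos0 = int(pos0)
        seq = genome[chrom]
        ref = seq[pos0]
        if ref not in BASES:
            continue
        alts = [b for b in BASES if b != ref]
        w = np.ones(3)
        if cpg_to_t_weight != 1.0:
            if ref == "C" and pos0 + 1 < len(seq) and seq[pos0 + 1] == "G":
                w[alts.index("T")] = cpg_to_t_weight
            elif ref == "G" and pos0 >= 1 and seq[pos0 - 1] == "C":
                w[alts.index("A")] = cpg_to_t_weight
        alt = alts[rng.choice(3, p=w / w.sum())]
        variants.append(Variant(chrom, pos0, ref, alt, group="denovo"))
    truth = {"intercept": b0, "beta": dict(beta), "n_sites": len(features),
             "expected_count": float(prob.sum()), "n_generated": len(variants)}
    return variants, truth


def gen_paired_cohorts(genome: Mapping[str, str],
                       dyads: pd.DataFrame,
                       r_p: Callable[[np.ndarray], np.ndarray],
                       r_d: Callable[[np.ndarray], np.ndarray],
                       b_p: float, b_d: float,
                       window: int = 800,
                       rng: np.random.Generator | None = None,
                       seed: int | None = None,
                       bin_size: int = 10,
                       ) -> tuple[list[Variant], list[Variant], pd.DataFrame]:
    """Two mutation cohorts with a known escape-ratio profile around dyads.

    Cohort A ("proficient") mutates each base at offset o of a dyad with
    per-bp probability r_p(o), plus a uniform genome-wide background b_p;
    cohort B ("deficient") likewise with r_d and b_d.  The recorded truth
    per 10-bp offset bin is R_i = (r_p(i)/r_d(i)) / (b_p/b_d) evaluated at
    bin centers.  All rates are per-bp Bernoulli probabilities and must
    stay below 0.05.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    offsets = np.arange(-window, window)
    rp, rd = np.asarray(r_p(offsets), float), np.asarray(r_d(offsets), float)
    for name, rates in (("r_p", rp), ("r_d", rd), ("b_p", np.array([b_p])),
                        ("b_d", np.array([b_d]))):
        if np.any(rates < 0) or np.any(rates > 1):
            raise ValidationError(f"{name} rate outside [0, 1]")
        if np.any(rates >= 0.05):
            raise ValidationError(f"{name} rate too large (>= 0.05/bp)")

    def place(rate_profile, background, group):
        variants = []
        for chrom, seq in genome.items():
            length = len(seq)
            dy = dyads.loc[dyads["chrom"] == chrom, "pos0"].to_numpy()
            # profile component: Bernoulli per (dyad, offset) above background
            extra = np.clip(rate_profile - background, 0.0, 1.0)
            nz = np.nonzero(extra > 0)[0]
            for d in dy:
                hits = nz[rng.random(len(nz)) < extra[nz]]
                for o in hits:
                    pos = int(d + offsets[o])
                    if 0 <= pos < length:
                        variants.append(_snv_at(genome, chrom, pos, rng, group))
            # uniform background over the chromosome
            n_bg = rng.poisson(background * length)
            for pos in rng.integers(0, length, size=n_bg):
                variants.append(_snv_at(genome, chrom, int(pos), rng, group))
        variants.sort(key=lambda v: (v.chrom, v.pos0))
        return variants

    cohort_a = place(rp, b_p, "proficient")
    cohort_b = place(rd, b_d, "deficient")
    centers = np.arange(-window, window, bin_size) + bin_size / 2.0
    rp_c = np.asarray(r_p(centers), float)
    rd_c = np.asarray(r_d(centers), float)
    with np.errstate(divide="ignore", invalid="ignore"):
        truth_r = (rp_c / rd_c) / (b_p / b_d)
    truth = pd.DataFrame({"bin_start": np.arange(-window, window, bin_size),
                          "true_R": truth_r})
    return cohort_a, cohort_b, truth


def _snv_at(genome, chrom, pos, rng, group):
    ref = genome[chrom][pos]
    alts = [b for b in BASES if b != ref]
    return Variant(chrom, pos, ref, alts[int(rng.integers(3))], group=group)


def gen_signature_mixture(genome: Mapping[str, str],
                          signatures: pd.DataFrame,
                          weights: Sequence[float],
                          n: int,
                          rng: np.random.Generator | None = None,
                          seed: int | None = None,
                          ) -> tuple[list[Variant], dict]:
    """``n`` SNVs whose 96-type distribution is the signature mixture S.w.

    Each sampled type is placed at a uniformly chosen genome position with
    the matching (strand-collapsed) trinucleotide context, without position
    reuse.  A required context absent from the genome raises, naming it.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValidationError("weights must be non-negative and sum to 1")
    S = signatures.to_numpy(dtype=float)
    if S.shape != (96, len(w)):
        raise ValidationError("signature matrix must be 96 x K")
    probs = S @ w
    probs = probs / probs.sum()
    type_counts = rng.multinomial(n, probs)

    ctx_positions = _context_position_index(genome)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    # group types by shared trinucleotide context so positions are drawn
    # once per context without replacement (no position reuse across types)
    need_by_ctx: dict[int, list[tuple[int, int]]] = {}
    for t in np.nonzero(type_counts)[0]:
        need_by_ctx.setdefault(type_context_index(int(t)), []).append(
            (int(t), int(type_counts[t])))
    variants = []
    for tri_idx, items in sorted(need_by_ctx.items()):
        total = sum(cnt for _, cnt in items)
        pool = ctx_positions.get(tri_idx)
        if pool is None or len(pool[1]) < total:
            raise ValidationError(
                f"context {TRINUC_CONTEXTS_32[tri_idx]} has too few genome "
                f"positions for {total} mutations")
        chroms, positions, is_pyrimidine = pool
        pick = rng.choice(len(positions), size=total, replace=False)
        offset = 0
        for t, cnt in items:
            alt_pyr = MUTATION_TYPES_96[t][4]  # ">X" base, pyrimidine strand
            for i in pick[offset:offset + cnt]:
                chrom, pos = chroms[i], int(positions[i])
                ref = genome[chrom][pos]
                alt = alt_pyr if is_pyrimidine[i] else comp[alt_pyr]
                variants.append(Variant(chrom, pos, ref, alt, group="signature"))
            offset += cnt
    variants.sort(key=lambda v: (v.chrom, v.pos0))
    truth = {"weights": {str(c): float(x)
                         for c, x in zip(signatures.columns, w)},
             "n_requested": n, "n_generated": len(variants)}
    return variants, truth


def _context_position_index(genome):
    """Map 32-context index -> (chrom array, position array, pyrimidine mask)."""
    out: dict[int, list] = {}
    for chrom, seq in genome.items():
        code = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        if len(code) < 3:
            continue
        left, center, right = code[:-2], code[1:-1], code[2:]
        valid = (left >= 0) & (center >= 0) & (right >= 0)
        pur = (center == 0) | (center == 2)
        l_c = np.where(pur, 3 - right, left)
        c_c = np.where(pur, 3 - center, center)
        r_c = np.where(pur, 3 - left, right)
        ctx = (c_c == 3).astype(np.int64) * 16 + l_c * 4 + r_c
        pos_all = np.arange(1, len(seq) - 1)
        for tri in np.unique(ctx[valid]):
            sel = valid & (ctx == tri)
            entry = out.setdefault(int(tri), [[], [], []])
            entry[0].append(np.full(sel.sum(), chrom, dtype=object))
            entry[1].append(pos_all[sel])
            entry[2].append(~pur[sel])
    return {tri: (np.concatenate(e[0]), np.concatenate(e[1]),
                  np.concatenate(e[2]))
            for tri, e in out.items()}


def gen_tracks(chrom_lengths: Mapping[str, int],
               specs: Mapping[str, Mapping],
               rng: np.random.Generator | None = None,
               seed: int | None = None,
               step: int = 10) -> dict[str, SignalTrack]:
    """Smooth or constant per-feature signal tracks at ``step``-bp resolution.

    Spec per feature: ``{"kind": "constant", "value": c}`` or
    ``{"kind": "smooth", "bandwidth": bp, "mean": m, "sd": s}`` (a moving
    average of white noise, rescaled to the stated mean/sd); an optional
    ``"clip": (lo, hi)`` bounds the values (e.g. mappability in [0, 100]).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    tracks = {}
    for name, spec in specs.items():
        data = {}
        for chrom, length in chrom_lengths.items():
            nbin = int(np.ceil(length / step))
            starts = np.arange(nbin, dtype=np.int64) * step
            ends = np.minimum(starts + step, length)
            if spec["kind"] == "constant":
                values = np.full(nbin, float(spec["value"]))
            elif spec["kind"] == "smooth":
                halfw = max(int(spec["bandwidth"] / step) // 2, 1)
                noise = rng.normal(size=nbin + 2 * halfw)
                kernel = np.ones(2 * halfw + 1) / (2 * halfw + 1)
                smooth = np.convolve(noise, kernel, mode="valid")
                smooth = (smooth - smooth.mean()) / max(smooth.std(), 1e-12)
                values = spec.get("mean", 0.0) + spec.get("sd", 1.0) * smooth
            else:
                raise ValidationError(f"unknown track kind {spec['kind']!r}")
            if "clip" in spec:
                values = np.clip(values, *spec["clip"])
            data[chrom] = (starts, ends, values)
        tracks[name] = SignalTrack(data, name=name)
    return tracks
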