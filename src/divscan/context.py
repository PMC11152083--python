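"""Composition and proximity analysis of selected windows.

Two questions about the selected windows: do they fall inside genic regions
more or less often than chance (permutation enrichment), and which genes
lie within regulatory reach (the 250-kb start-codon proximity rule)?

The permutation null re-places every window, length preserved, uniformly at
random on the analyzed genome (optionally restricted to the window's own
scaffold).  Shuffled windows may overlap one another; the null statistic is
the summed per-window overlap with the merged genic regions.  Empirical
one-sided p-values use the +1 correction, p = (1 + #{null >= obs}) / (1 + n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, GenomeInterval

log = logging.getLogger("divscan")

DEFAULT_PROXIMITY = 250_000  # bp up/downstream of a window
DEFAULT_N_PERM = 10_000


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Sequence[GenomeInterval]) -> list[GenomeInterval]:
    """Union of intervals: sorted, overlapping/adjacent runs merged per scaffold."""
    out: list[GenomeInterval] = []
    for iv in sorted(intervals, key=lambda v: (v.chrom, v.start, v.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomeInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def overlap_length(a: Sequence[GenomeInterval], b: Sequence[GenomeInterval]) -> int:
    """Total bp of intersection between the unions of two interval sets."""
    bp = 0
    by_chrom: dict[str, list[GenomeInterval]] = {}
    for iv in merge_intervals(b):
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for iv in merge_intervals(a):
        for other in by_chrom.get(iv.chrom, ()):
            lo = max(iv.start, other.start)
            hi = min(iv.end, other.end)
            if hi > lo:
                bp += hi - lo
    return bp


class _CoverageProfile:
    """Per-scaffold cumulative coverage of a merged interval set, supporting
    vectorized 'covered bp in [s, e)' queries."""

    def __init__(self, merged: Sequence[GenomeInterval]):
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        self.cum: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[GenomeInterval]] = {}
        for iv in merged:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            s = np.array([iv.start for iv in ivs], dtype=np.int64)
            e = np.array([iv.end for iv in ivs], dtype=np.int64)
            self.starts[chrom] = s
            self.ends[chrom] = e
            self.cum[chrom] = np.concatenate([[0], np.cumsum(e - s)])

    def overlap_with(self, chrom: str, starts: np.ndarray, length: int) -> np.ndarray:
        """Covered bp inside [start, start+length) for each start."""
        return self._cov(chrom, starts + length) - self._cov(chrom, starts)

    def _cov(self, chrom: str, x: np.ndarray) -> np.ndarray:
        if chrom not in self.starts:
            return np.zeros(len(x), dtype=np.int64)
        s, e, cum = self.starts[chrom], self.ends[chrom], self.cum[chrom]
        i = np.searchsorted(s, x, side="right") - 1
        out = np.zeros(len(x), dtype=np.int64)
        has = i >= 0
        ii = i[has]
        out[has] = cum[ii] + np.clip(x[has] - s[ii], 0, (e - s)[ii])
        return out


# ---------------------------------------------------------------------------
# permutation enrichment
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed_overlap: int
    null_mean: float
    null_sd: float
    z: float
    p_greater: float
    p_less: float
    n_perm: int
    seed: int
    scope: str

    def to_dict(self) -> dict:
        return asdict(self)


def permutation_enrichment(
    windows: Sequence[GenomeInterval],
    genic: Sequence[GenomeInterval],
    chrom_sizes: Mapping[str, int],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    scope: str = "genome",
) -> PermutationResult:
    """Permutation test of window/genic-region overlap.

    Each permutation re-places every window uniformly at random (length
    preserved, integer starts, overlaps among shuffled windows permitted).
    ``scope='genome'`` places windows anywhere a window of that length fits,
    each placement equally likely; ``scope='chromosome'`` keeps each window
    on its own scaffold.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if scope not in ("genome", "chromosome"):
        raise ValueError(f"unknown scope {scope!r}")
    rng = np.random.default_rng(seed)
    merged_genic = merge_intervals(genic)
    profile = _CoverageProfile(merged_genic)
    observed = overlap_length(windows, genic)

    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    null = np.zeros(n_perm, dtype=np.int64)
    for win in windows:
        w = len(win)
        if scope == "chromosome":
            avail = np.array([chrom_sizes[win.chrom] - w + 1], dtype=np.int64)
            if avail[0] <= 0:
                raise ValueError(f"window {win} does not fit on its scaffold")
            target_chroms, weights = [win.chrom], avail
        else:
            avail = sizes - w + 1
            fits = avail > 0
            if not fits.any():
                raise ValueError(f"window {win} fits on no scaffold")
            target_chroms = [c for c, f in zip(chroms, fits) if f]
            weights = avail[fits]
        probs = weights / weights.sum()
        which = rng.choice(len(target_chroms), size=n_perm, p=probs)
        starts = (rng.random(n_perm) * weights[which]).astype(np.int64)
        for ci, chrom in enumerate(target_chroms):
            sel = which == ci
            if sel.any():
                null[sel] += profile.overlap_with(chrom, starts[sel], w)

    null_mean = float(null.mean()) if n_perm else float("nan")
    null_sd = float(null.std(ddof=1))
    z = (observed - null_mean) / null_sd if null_sd > 0 else float("nan")
    p_greater = (1 + int((null >= observed).sum())) / (1 + n_perm)
    p_less = (1 + int((null <= observed).sum())) / (1 + n_perm)
    return PermutationResult(
        observed_overlap=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p_greater=p_greater,
        p_less=p_less,
        n_perm=n_perm,
        seed=seed,
        scope=scope,
    )


def expected_overlap_exhaustive(
    window_len: int,
    genic: Sequence[GenomeInterval],
    chrom_sizes: Mapping[str, int],
) -> float:
    """Exact null mean for a single window by enumerating every placement.

    Small-genome oracle for the Monte-Carlo null; O(genome length)."""
    profile = _CoverageProfile(merge_intervals(genic))
    total = 0
    n = 0
    for chrom, size in chrom_sizes.items():
        k = size - window_len + 1
        if k <= 0:
            continue
        starts = np.arange(k, dtype=np.int64)
        total += int(profile.overlap_with(chrom, starts, window_len).sum())
        n += k
    if n == 0:
        raise ValueError("window fits nowhere")
    return total / n


# ---------------------------------------------------------------------------
# proximity
# ---------------------------------------------------------------------------

@dataclass
class ProximityResult:
    """Genes whose start codon lies within D bp of a selected window."""

    per_window: dict[str, list[str]]
    gene_distance: dict[str, int]
    distance_bp: int

    @property
    def genes(self) -> list[str]:
        return sorted(self.gene_distance)


def genes_near_windows(
    windows: Sequence[GenomeInterval],
    genes: Sequence[GeneModel],
    distance_bp: int = DEFAULT_PROXIMITY,
    window_ids: Sequence[str] | None = None,
) -> ProximityResult:
    """Report genes with start codons within ``distance_bp`` of each window.

    A gene is in range iff its strand-aware 5' end falls in
    [window.start − D, window.end + D) on the same scaffold.  Distance is 0
    when the start codon lies inside the window, otherwise the gap to the
    nearest window edge; genes are deduplicated across windows keeping the
    minimum distance.
    """
    if distance_bp < 0:
        raise ValueError("distance must be >= 0")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    pos: dict[str, np.ndarray] = {}
    order: dict[str, list[GeneModel]] = {}
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.start_codon_pos)
        order[chrom] = gs
        pos[chrom] = np.array([g.start_codon_pos for g in gs], dtype=np.int64)

    ids = list(window_ids) if window_ids is not None else [
        f"{w.chrom}:{w.start}-{w.end}" for w in windows
    ]
    per_window: dict[str, list[str]] = {}
    gene_distance: dict[str, int] = {}
    for win, wid in zip(windows, ids):
        hits: list[str] = []
        if win.chrom in pos:
            p = pos[win.chrom]
            lo = int(np.searchsorted(p, win.start - distance_bp, side="left"))
            hi = int(np.searchsorted(p, win.end + distance_bp, side="left"))
            for g in order[win.chrom][lo:hi]:
                scp = g.start_codon_pos
                dist = max(0, win.start - scp, scp - win.end + 1)
                hits.append(g.gene_id)
                if g.gene_id not in gene_distance or dist < gene_distance[g.gene_id]:
                    gene_distance[g.gene_id] = dist
        per_window[wid] = hits
    return ProximityResult(per_window, gene_distance, distance_bp)
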