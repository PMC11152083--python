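"""Chromosomal inversion calling from pairwise whole-genome alignment records.

The visual screen — inspect 20-Mb spans of a dot plot and flag reverse-
diagonal segments longer than 50 kb — is formalized as strand-run analysis:
within each (reference scaffold, query scaffold) pairing, alignment blocks
are filtered (length, mapping quality), ordered along the reference, and a
local "direct" orientation is defined per 20-Mb screening window as the
strand carrying the majority of aligned bp there.  Maximal runs of blocks
on the opposite strand, with inter-block reference gaps up to ``merge_gap``,
become inversion calls when their reference span exceeds ``min_len``.

Defining orientation by the local majority means a query scaffold that is
entirely reverse-complemented relative to the reference (an assembly
orientation choice, not a rearrangement) yields no calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, GenomeInterval, PafRecord

log = logging.getLogger("divscan")


@dataclass
class InversionParams:
    min_len: int = 50_000          # calls must span more than this on the reference
    screen_len: int = 20_000_000   # majority-strand screening window
    min_block: int = 5_000         # discard smaller alignment blocks
    merge_gap: int = 100_000       # max reference gap between merged blocks
    min_mapq: int = 30

    def __post_init__(self) -> None:
        for name in ("min_len", "screen_len", "min_block", "merge_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_block > self.min_len:
            raise ValueError("min_block must not exceed min_len")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class InversionCall:
    ref_interval: GenomeInterval
    query_chrom: str
    query_interval: GenomeInterval
    n_blocks: int
    screen_window_id: str

    @property
    def length(self) -> int:
        return len(self.ref_interval)


def _majority_strand_by_screen(
    blocks: Sequence[PafRecord], screen_len: int
) -> dict[int, str]:
    """Majority strand per screening window, weighted by aligned reference bp.
    A block votes in the window containing its reference midpoint."""
    weight: dict[int, dict[str, int]] = {}
    for b in blocks:
        sw = ((b.tstart + b.tend) // 2) // screen_len
        weight.setdefault(sw, {"+": 0, "-": 0})[b.strand] += b.tend - b.tstart
    return {
        sw: ("+" if w["+"] >= w["-"] else "-") for sw, w in weight.items()
    }


def detect_inversions(
    paf_records: Iterable[PafRecord],
    params: InversionParams | None = None,
) -> list[InversionCall]:
    """Call inversions per (reference scaffold, query scaffold) pairing.

    Returns calls sorted by reference coordinate.  Empty input yields an
    empty list.
    """
    params = params or InversionParams()
    groups: dict[tuple[str, str], list[PafRecord]] = {}
    for r in paf_records:
        if r.block_len < params.min_block or r.mapq < params.min_mapq:
            continue
        groups.setdefault((r.tname, r.qname), []).append(r)

    calls: list[InversionCall] = []
    for (tname, qname), blocks in groups.items():
        blocks.sort(key=lambda b: (b.tstart, b.tend))
        majority = _majority_strand_by_screen(blocks, params.screen_len)

        run: list[PafRecord] = []

        def flush() -> None:
            if not run:
                return
            ref_start = min(b.tstart for b in run)
            ref_end = max(b.tend for b in run)
            if ref_end - ref_start > params.min_len:
                q_start = min(b.qstart for b in run)
                q_end = max(b.qend for b in run)
                sw = ((ref_start + ref_end) // 2) // params.screen_len
                calls.append(
                    InversionCall(
                        ref_interval=GenomeInterval(tname, ref_start, ref_end),
                        query_chrom=qname,
                        query_interval=GenomeInterval(qname, q_start, q_end),
                        n_blocks=len(run),
                        screen_window_id=f"{tname}:{sw}",
                    )
                )
            run.clear()

        for b in blocks:
            sw = ((b.tstart + b.tend) // 2) // params.screen_len
            inverted = b.strand != majority[sw]
            if inverted:
                if run and b.tstart - max(x.tend for x in run) > params.merge_gap:
                    flush()
                run.append(b)
            else:
                flush()
        flush()

    calls.sort(key=lambda c: (c.ref_interval.chrom, c.ref_interval.start))
    return calls


def genes_in_inversions(
    calls: Sequence[InversionCall], genes: Sequence[GeneModel]
) -> tuple[dict[str, list[str]], list[str]]:
    """Genes overlapping each inversion call by at least 1 bp (half-open),
    plus the deduplicated union across calls."""
    per_call: dict[str, list[str]] = {}
    union: set[str] = set()
    for call in calls:
        iv = call.ref_interval
        key = f"{iv.chrom}:{iv.start}-{iv.end}"
        hits = [
            g.gene_id
            for g in genes
            if g.interval.chrom == iv.chrom
            and g.interval.start < iv.end
            and g.interval.end > iv.start
        ]
        per_call[key] = hits
        union.update(hits)
    return per_call, sorted(union)


def calls_frame(calls: Sequence[InversionCall]) -> pd.DataFrame:
    """Tabular view of inversion calls (TSV/BED-ready)."""
    rows = [
        (
            c.ref_interval.chrom, c.ref_interval.start, c.ref_interval.end,
            c.query_chrom, c.query_interval.start, c.query_interval.end,
            c.n_blocks, c.length, c.screen_window_id,
        )
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "ref_chrom", "ref_start", "ref_end",
            "query_chrom", "query_start", "query_end",
            "n_blocks", "length", "screen_window",
        ],
    )
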