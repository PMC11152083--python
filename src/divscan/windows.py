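"""Fixed-width genome windows and per-pair aligned-base / SNP accumulation.

The reference genome is tiled with nonoverlapping windows (default 10 kb,
trailing partial window kept).  For every species pair, each reference
position that carries an unambiguous base contributes one "aligned base"
when the partner row also carries an unambiguous base in that column, and
one SNP when the two bases differ.  Lowercase (soft-masked) bases count as
their base; IUPAC ambiguity codes other than A/C/G/T behave like N (not
aligned).  Reference positions covered by more than one block are counted
once: the first block encountered wins and the multiplicity is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ChromosomeClassMap, GenomeInterval, MafBlock

log = logging.getLogger("divscan")

DEFAULT_WINDOW_SIZE = 10_000   # bp
DEFAULT_MIN_ALIGNED = 3_000    # bp; the "least 1% of aligned bases" cut

# byte lookup: 1 for unambiguous A/C/G/T (either case), else 0
_UNAMBIG = np.zeros(256, dtype=bool)
for _b in b"ACGTacgt":
    _UNAMBIG[_b] = True
# uppercase base code for SNP comparison; non-ACGT collapse to 0 ('N'-like)
_UPPER = np.zeros(256, dtype=np.uint8)
for _lo, _up in zip(b"acgt", b"ACGT"):
    _UPPER[_lo] = _up
for _up in b"ACGT":
    _UPPER[_up] = _up


@dataclass
class WindowGrid:
    """Contiguous nonoverlapping windows of width ``window_size`` per scaffold."""

    chrom_sizes: dict[str, int]
    window_size: int
    chroms: list[str] = field(init=False)
    n_per_chrom: dict[str, int] = field(init=False)
    offsets: dict[str, int] = field(init=False)
    n_windows: int = field(init=False)

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window size must be >= 1 bp")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"scaffold {chrom} has nonpositive size {size}")
        self.chroms = list(self.chrom_sizes)
        self.n_per_chrom = {
            c: -(-s // self.window_size) for c, s in self.chrom_sizes.items()
        }
        self.offsets = {}
        off = 0
        for c in self.chroms:
            self.offsets[c] = off
            off += self.n_per_chrom[c]
        self.n_windows = off

    def window_index(self, chrom: str, pos: int) -> int:
        """Global index of the window containing reference position ``pos``."""
        return self.offsets[chrom] + pos // self.window_size

    def intervals(self) -> Iterator[GenomeInterval]:
        for c in self.chroms:
            size = self.chrom_sizes[c]
            for i in range(self.n_per_chrom[c]):
                start = i * self.window_size
                yield GenomeInterval(c, start, min(start + self.window_size, size))

    def frame(self) -> pd.DataFrame:
        rows = [
            (f"{iv.chrom}:{iv.start // self.window_size}", iv.chrom, iv.start, iv.end)
            for iv in self.intervals()
        ]
        return pd.DataFrame(rows, columns=["window_id", "chrom", "start", "end"])


def make_windows(chrom_sizes: Mapping[str, int], window_size: int = DEFAULT_WINDOW_SIZE) -> WindowGrid:
    """Tile each scaffold with nonoverlapping windows; the last window of a
    scaffold may be shorter than ``window_size``."""
    return WindowGrid(dict(chrom_sizes), window_size)


@dataclass
class PairCounts:
    """Per-window aligned-base and SNP counts for one species pair."""

    species_a: str
    species_b: str
    aligned: np.ndarray  # int64[n_windows]
    snp: np.ndarray      # int64[n_windows]

    @property
    def pair(self) -> str:
        return f"{self.species_a}|{self.species_b}"


class _CoverageMask:
    """Tracks which reference positions were already counted (first block wins)."""

    def __init__(self, chrom_sizes: Mapping[str, int]):
        self._sizes = chrom_sizes
        self._masks: dict[str, np.ndarray] = {}
        self.duplicates = 0

    def claim(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        mask = self._masks.get(chrom)
        if mask is None:
            mask = np.zeros(self._sizes[chrom], dtype=bool)
            self._masks[chrom] = mask
        fresh = ~mask[positions]
        self.duplicates += int(positions.size - fresh.sum())
        mask[positions[fresh]] = True
        return fresh


def accumulate_pair_counts(
    maf_blocks: Iterable[MafBlock],
    grid: WindowGrid,
    species_a: str,
    species_b: str,
    coord_species: str | None = None,
) -> PairCounts:
    """Accumulate aligned-base and SNP counts for one species pair.

    Counts are assigned to windows on ``coord_species`` coordinates (default:
    ``species_a``, the reference of the pair).  Passing the grid genome as
    ``coord_species`` lets control pairs (neither member being the reference)
    be counted on reference windows, the coordinate system the scan uses.

    A column contributes iff the coordinate row has a base (non-gap) giving
    it a reference position, and both pair members carry an unambiguous
    A/C/G/T in the column.  Overlapping reference coverage is resolved
    first-block-wins.
    """
    coord_species = coord_species or species_a
    aligned = np.zeros(grid.n_windows, dtype=np.int64)
    snp = np.zeros(grid.n_windows, dtype=np.int64)
    seen = _CoverageMask(grid.chrom_sizes)
    gap_only = 0

    for block in maf_blocks:
        crow = block.row_for(coord_species)
        if crow is None:
            continue
        arow = crow if species_a == coord_species else block.row_for(species_a)
        brow = crow if species_b == coord_species else block.row_for(species_b)
        if arow is None or brow is None:
            continue
        if crow.chrom not in grid.chrom_sizes:
            log.debug("MAF block on unknown scaffold %s skipped", crow.chrom)
            continue

        ctext = np.frombuffer(crow.text.encode(), dtype=np.uint8)
        nongap = ctext != ord("-")
        if not nongap.any():
            gap_only += 1
            continue
        # forward reference coordinate of every non-gap coordinate column
        if crow.strand == "+":
            positions = crow.start + np.cumsum(nongap) - 1
        else:
            # alignment text walks the reverse strand: coordinates descend
            positions = (crow.start + crow.size - 1) - (np.cumsum(nongap) - 1)
        atext = np.frombuffer(arow.text.encode(), dtype=np.uint8)
        btext = np.frombuffer(brow.text.encode(), dtype=np.uint8)
        ok = nongap & _UNAMBIG[atext] & _UNAMBIG[btext]
        if not ok.any():
            continue
        pos = positions[ok]
        fresh = seen.claim(crow.chrom, pos)
        pos = pos[fresh]
        if pos.size == 0:
            continue
        mism = (_UPPER[atext[ok]] != _UPPER[btext[ok]])[fresh]
        widx = grid.offsets[crow.chrom] + pos // grid.window_size
        aligned += np.bincount(widx, minlength=grid.n_windows)
        snp += np.bincount(widx[mism], minlength=grid.n_windows)

    if gap_only:
        log.info("%d MAF blocks had gap-only coordinate rows; skipped", gap_only)
    if seen.duplicates:
        log.info(
            "%d reference positions covered more than once; first block kept",
            seen.duplicates,
        )
    return PairCounts(species_a, species_b, aligned, snp)


def compute_proportions(
    counts: Sequence[PairCounts],
    grid: WindowGrid,
    class_map: ChromosomeClassMap,
    min_aligned: int = DEFAULT_MIN_ALIGNED,
) -> pd.DataFrame:
    """Build the per-window statistics table.

    One row per window with per-pair ``aligned:<pair>``, ``snp:<pair>`` and
    ``prop:<pair>`` columns (proportion = snp/aligned, NaN when no aligned
    bases).  ``pass_filter`` is true only when every pair reaches
    ``min_aligned`` aligned bases and the window's chromosome class is one
    that is analyzed (autosome or Z; W and "exclude" are flagged out).
    """
    if min_aligned < 0:
        raise ValueError("min_aligned must be >= 0")
    df = grid.frame()
    df["class"] = df["chrom"].map(lambda c: class_map.class_of(c))
    pass_filter = np.ones(grid.n_windows, dtype=bool)
    for pc in counts:
        with np.errstate(invalid="ignore", divide="ignore"):
            prop = np.where(pc.aligned > 0, pc.snp / np.maximum(pc.aligned, 1), np.nan)
        df[f"aligned:{pc.pair}"] = pc.aligned
        df[f"snp:{pc.pair}"] = pc.snp
        df[f"prop:{pc.pair}"] = prop
        pass_filter &= pc.aligned >= max(min_aligned, 1)
    pass_filter &= df["class"].isin(["autosome", "Z"]).to_numpy()
    df["pass_filter"] = pass_filter
    return df


def pair_columns(stats: pd.DataFrame) -> list[str]:
    """Species pairs present in a window-statistics table."""
    return [c.split(":", 1)[1] for c in stats.columns if c.startswith("prop:")]
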