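"""The ΔSNP outlier scan and guide-tree utilities.

Per-window SNP proportions are Z-transformed within each
(species pair × chromosome class) stratum, restricted to windows passing
the aligned-base filter.  For each focal comparison (a pair containing the
focal species) the contrast

    ΔSNP = z_focal − max(z over control comparisons)

is positive when divergence is elevated specifically on the focal lineage
and near zero when the elevation is shared among the other species (which
the control pairs absorb).  The top quantile of ΔSNP (default 1%) is taken
per focal comparison and chromosome class, and windows selected in *every*
focal comparison form the final "selected windows" set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

log = logging.getLogger("divscan")

DEFAULT_QUANTILE = 0.99
ANALYZED_CLASSES = ("autosome", "Z")


@dataclass
class ComparisonDesign:
    """Focal-vs-control comparison layout.

    ``focal_pairs`` are (focal, other) species pairs; ``control_pairs`` are
    pairs among the non-focal species and absorb divergence shared across
    the non-focal lineages.
    """

    focal_species: str
    focal_pairs: list[tuple[str, str]]
    control_pairs: list[tuple[str, str]]
    quantile: float = DEFAULT_QUANTILE
    classes: tuple[str, ...] = ANALYZED_CLASSES

    def __post_init__(self) -> None:
        errs = self.validate()
        if errs:
            raise ValueError("; ".join(errs))

    def validate(self) -> list[str]:
        errs = []
        for p in self.focal_pairs:
            if self.focal_species not in p:
                errs.append(f"focal pair {p} does not contain {self.focal_species}")
        for p in self.control_pairs:
            if self.focal_species in p:
                errs.append(f"control pair {p} contains focal species")
        if not self.control_pairs:
            errs.append("at least one control pair is required")
        if not self.focal_pairs:
            errs.append("at least one focal comparison is required")
        if not (0.0 < self.quantile < 1.0):
            errs.append(f"quantile must be in (0,1), got {self.quantile}")
        return errs

    @staticmethod
    def from_species(focal: str, others: Sequence[str], quantile: float = DEFAULT_QUANTILE) -> "ComparisonDesign":
        """All-focal-vs-each-other design: one focal pair per non-focal
        species, every pair among them as control."""
        others = list(others)
        focal_pairs = [(focal, o) for o in others]
        control_pairs = [
            (others[i], others[j])
            for i in range(len(others))
            for j in range(i + 1, len(others))
        ]
        return ComparisonDesign(focal, focal_pairs, control_pairs, quantile=quantile)


def pair_key(pair: tuple[str, str]) -> str:
    return f"{pair[0]}|{pair[1]}"


# ---------------------------------------------------------------------------
# Z-transformation and ΔSNP
# ---------------------------------------------------------------------------

def z_transform(values: np.ndarray, classes: np.ndarray | None = None) -> np.ndarray:
    """Standardize values to zero mean / unit sd within each class stratum.

    Sample standard deviation (n−1).  NaN inputs stay NaN and do not enter
    the moments.  A stratum with fewer than two finite values or zero sd is
    degenerate and raises.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    if classes is None:
        classes = np.zeros(values.shape, dtype=int)
    classes = np.asarray(classes)
    for cls in pd.unique(classes):
        sel = classes == cls
        x = values[sel]
        finite = np.isfinite(x)
        if finite.sum() < 2:
            raise ValueError(f"stratum {cls!r}: need >=2 finite values")
        mu = x[finite].mean()
        sd = x[finite].std(ddof=1)
        if sd == 0:
            raise ValueError(f"stratum {cls!r}: zero standard deviation (degenerate)")
        out[sel] = (x - mu) / sd
    return out


def delta_snp(z_focal: float | np.ndarray, z_controls: Sequence[float] | np.ndarray) -> float | np.ndarray:
    """ΔSNP contrast: focal z minus the maximum control z.

    Positive values mean divergence elevated specifically in the focal
    comparison.  (The statistic is sometimes written with the subtraction
    reversed; selecting high focal-specific divergence requires this
    orientation — see docs/methods.md.)
    """
    z_controls = np.asarray(z_controls, dtype=float)
    return np.asarray(z_focal, dtype=float) - z_controls.max(axis=0)


def compute_delta_table(stats: pd.DataFrame, design: ComparisonDesign) -> pd.DataFrame:
    """Z-transform proportions and compute ΔSNP per focal comparison.

    Strata are (species pair × chromosome class); only windows with
    ``pass_filter`` true (aligned-base filter met in every pair, analyzed
    class) get defined z and delta values.
    """
    df = stats[["window_id", "chrom", "start", "end", "class", "pass_filter"]].copy()
    passing = stats["pass_filter"].to_numpy()
    cls = stats["class"].to_numpy()
    all_pairs = design.focal_pairs + design.control_pairs
    zcols: dict[str, np.ndarray] = {}
    for pair in all_pairs:
        key = pair_key(pair)
        col = f"prop:{key}"
        if col not in stats.columns:
            raise KeyError(f"window table lacks proportions for pair {key}")
        z = np.full(len(stats), np.nan)
        z[passing] = z_transform(
            stats.loc[passing, col].to_numpy(), cls[passing]
        )
        zcols[key] = z
        df[f"z:{key}"] = z
    zc = np.vstack([zcols[pair_key(p)] for p in design.control_pairs])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        zc_max = np.nanmax(zc, axis=0)
    zc_defined = np.isfinite(zc).all(axis=0)
    for pair in design.focal_pairs:
        key = pair_key(pair)
        delta = zcols[key] - zc_max
        delta[~zc_defined] = np.nan
        df[f"delta:{key}"] = delta
    return df


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

@dataclass
class SelectedWindows:
    """Top-quantile windows per focal comparison and their intersection."""

    per_focal: dict[str, set[str]]
    thresholds: dict[tuple[str, str], float]
    intersection: set[str]
    by_class: dict[str, set[str]]

    @property
    def n_selected(self) -> int:
        return len(self.intersection)


def select_top_quantile(
    delta_table: pd.DataFrame,
    design: ComparisonDesign,
) -> SelectedWindows:
    """Select windows in the top ΔSNP quantile of every focal comparison.

    The threshold is the empirical quantile (linear interpolation) of the
    defined deltas within each (focal comparison × chromosome class);
    windows with delta >= threshold are selected, so ties at the threshold
    are included and the argmax window is always selected.
    """
    q = design.quantile
    per_focal: dict[str, set[str]] = {}
    thresholds: dict[tuple[str, str], float] = {}
    for pair in design.focal_pairs:
        key = pair_key(pair)
        chosen: set[str] = set()
        for cls in design.classes:
            sub = delta_table[
                (delta_table["class"] == cls) & np.isfinite(delta_table[f"delta:{key}"])
            ]
            if sub.empty:
                continue
            deltas = sub[f"delta:{key}"].to_numpy()
            if deltas.size < 1.0 / (1.0 - q):
                log.warning(
                    "focal %s class %s: only %d windows for quantile %.3f; "
                    "selecting at least the maximum", key, cls, deltas.size, q,
                )
            thr = float(np.quantile(deltas, q))
            thresholds[(key, cls)] = thr
            chosen |= set(sub.loc[deltas >= thr, "window_id"])
        per_focal[key] = chosen
    inter = intersect_selected(list(per_focal.values()))
    cls_of = dict(zip(delta_table["window_id"], delta_table["class"]))
    by_class = {
        cls: {w for w in inter if cls_of.get(w) == cls} for cls in design.classes
    }
    return SelectedWindows(per_focal, thresholds, inter, by_class)


def intersect_selected(per_focal_sets: Sequence[set[str]]) -> set[str]:
    """Windows present in every focal comparison's top-quantile set."""
    if not per_focal_sets:
        raise ValueError("need at least one selected-window set")
    out = set(per_focal_sets[0])
    for s in per_focal_sets[1:]:
        out &= s
    return out


def selected_intervals(delta_table: pd.DataFrame, window_ids: set[str]) -> pd.DataFrame:
    sub = delta_table[delta_table["window_id"].isin(window_ids)]
    return sub[["window_id", "chrom", "start", "end", "class"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# guide-tree utilities
# ---------------------------------------------------------------------------

def estimate_pairwise_distance(paf_records, min_mapq: int = 0) -> float:
    """Approximate per-base divergence from pairwise alignment records:
    1 − Σ matches / Σ alignment block length over records with
    mapq >= ``min_mapq``."""
    nm = bl = 0
    for r in paf_records:
        if r.mapq < min_mapq:
            continue
        nm += r.n_match
        bl += r.block_len
    if bl == 0:
        raise ValueError("no alignment records pass the mapq filter")
    return 1.0 - nm / bl


def build_nj_tree(dist: pd.DataFrame | Mapping[str, Mapping[str, float]]) -> str:
    """Neighbor-joining tree (Saitou–Nei) from a symmetric distance matrix,
    returned as a newick string.

    Taxa are processed in name order so equal-distance ties resolve
    deterministically; negative branch lengths are clamped to zero (logged).
    Two taxa yield a single edge of the given length, split evenly.
    """
    df = pd.DataFrame(dist)
    taxa = sorted(df.index)
    df = df.loc[taxa, taxa]
    arr = df.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix is not symmetric")
    if (arr < 0).any() or (np.diag(arr) != 0).any():
        raise ValueError("distances must be nonnegative with zero diagonal")
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    if len(taxa) == 2:
        d = float(arr[0, 1])
        return f"({taxa[0]}:{d / 2:g},{taxa[1]}:{d / 2:g});"
    dm = DistanceMatrix(arr, ids=taxa)
    tree = _skbio_nj(dm, neg_as_zero=True)
    return str(tree).strip()


def tree_patristic_distances(newick: str) -> pd.DataFrame:
    """Leaf-to-leaf path-length matrix of a newick tree (for checking that a
    reconstructed tree reproduces an additive distance matrix)."""
    from skbio import TreeNode
    from io import StringIO

    tree = TreeNode.read(StringIO(newick))
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
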