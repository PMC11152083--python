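"""Four-species alignment simulator with known planted truth.

Emulates the inputs of the comparative scan: four swallow-like genomes
related by a known tree at background pairwise divergences of roughly
0.03–0.04 substitutions/site, focal-branch windows with elevated
substitution rate, unaligned reference tracts (alignment gaps), gene
annotations, and reverse-complemented (inverted) segments in one query
assembly.

Sequences evolve by a Jukes–Cantor process: along a branch of length t the
per-site probability of observing a different base is (3/4)(1 − e^(−4t/3)),
each alternative base equally likely.  Inside planted windows the focal
terminal branch length is multiplied by the window's rate multiplier, so
elevated divergence appears in every focal comparison but in no control
comparison — the statistical structure the ΔSNP contrast assumes.  There
are no indels inside aligned tracts; alignment gaps are modelled as
unaligned reference tracts instead.

All randomness flows from ``SimConfig.seed``; identical configs give
byte-identical fixture files.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict
from io import StringIO
from typing import Mapping, Sequence

import numpy as np
from Bio import Phylo

from .io_formats import (
    Assembly,
    ChromosomeClassMap,
    GeneModel,
    GenomeInterval,
    MafBlock,
    MafRow,
    PafRecord,
    SequenceRecord,
    write_class_map,
    write_fasta,
    write_gff_genes,
    write_maf,
    write_paf,
)

log = logging.getLogger("divscan")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_SPECIES = ("house_martin", "barn_swallow", "bank_swallow", "tree_swallow")

# Branch lengths (substitutions/site) chosen so the *observed* pairwise
# divergence of the focal species against the three others is 0.030 / 0.038 /
# 0.039 after Jukes-Cantor multiple-hit correction, on the unrooted 4-taxon
# topology ((focal, sister), near, far): path lengths t = -(3/4)ln(1 - 4p/3).
DEFAULT_TREE = (
    "((house_martin:0.01523,barn_swallow:0.01523):0.004,"
    "bank_swallow:0.01951,tree_swallow:0.02055);"
)


@dataclass(frozen=True)
class PlantedWindow:
    chrom: str
    start: int
    end: int
    rate_multiplier: float = 5.0
    species: str | None = None  # None = focal terminal branch (the only model)


@dataclass(frozen=True)
class PlantedInversion:
    species: str
    chrom: str
    start: int
    end: int


def _default_planted_windows(window_size: int = 10_000) -> list[PlantedWindow]:
    # 20 windows at 5x rate: 15 autosomal + 5 on Z, aligned to the 10-kb grid
    layout = {
        "chrA1": (30, 80, 150, 270, 420),
        "chrA2": (55, 120, 200, 310, 450),
        "chrA3": (40, 100, 260, 380, 520),
        "chrZ": (60, 140, 230, 330, 480),
    }
    return [
        PlantedWindow(chrom, i * window_size, (i + 1) * window_size, 5.0)
        for chrom, idxs in layout.items()
        for i in idxs
    ]


def _default_planted_inversions() -> list[PlantedInversion]:
    # 40 kb (below the >50 kb call floor), 60 kb and 500 kb in the
    # chromosome-level comparator genome
    return [
        PlantedInversion("barn_swallow", "chrA1", 2_000_000, 2_040_000),
        PlantedInversion("barn_swallow", "chrA2", 1_500_000, 1_560_000),
        PlantedInversion("barn_swallow", "chrA3", 3_000_000, 3_500_000),
    ]


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 4                      # last one is "chrZ"
    chrom_len: int = 6_000_000
    tree: str = DEFAULT_TREE
    focal_species: str = "house_martin"
    planted_windows: list[PlantedWindow] = field(default_factory=_default_planted_windows)
    planted_inversions: list[PlantedInversion] = field(default_factory=_default_planted_inversions)
    n_genes: int = 200
    gap_fraction: float = 0.08
    base_composition: tuple[float, float, float, float] = (0.285, 0.215, 0.215, 0.285)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gap_fraction <= 0.5:
            raise ValueError("gap_fraction must be in [0, 0.5]")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        sizes = self.chrom_sizes()
        for pw in self.planted_windows:
            if pw.species is not None and pw.species != self.focal_species:
                raise ValueError(
                    f"planted window on non-focal branch {pw.species!r}: "
                    "only focal-branch rate elevation is modelled"
                )
            if pw.rate_multiplier < 1:
                raise ValueError("rate_multiplier must be >= 1")
            if pw.chrom not in sizes or not (0 <= pw.start < pw.end <= sizes[pw.chrom]):
                raise ValueError(f"planted window {pw} outside chromosome bounds")
        for group in (self.planted_windows, self.planted_inversions):
            seen: list[tuple[str, int, int]] = []
            keyed = [
                (getattr(x, "species", None), x.chrom, x.start, x.end) for x in group
            ]
            for i, a in enumerate(keyed):
                for b in keyed[i + 1:]:
                    if a[0] == b[0] and a[1] == b[1] and a[2] < b[3] and b[2] < a[3]:
                        raise ValueError(f"planted intervals overlap: {a} / {b}")
        for inv in self.planted_inversions:
            if inv.chrom not in sizes or not (0 <= inv.start < inv.end <= sizes[inv.chrom]):
                raise ValueError(f"planted inversion {inv} outside chromosome bounds")

    def chrom_names(self) -> list[str]:
        return [f"chrA{i + 1}" for i in range(self.n_chroms - 1)] + ["chrZ"]

    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_len for c in self.chrom_names()}

    def class_map(self) -> ChromosomeClassMap:
        cmap = ChromosomeClassMap()
        for c in self.chrom_names():
            cmap[c] = "Z" if c == "chrZ" else "autosome"
        return cmap

    def species(self) -> list[str]:
        tree = Phylo.read(StringIO(self.tree), "newick")
        return [leaf.name for leaf in tree.get_terminals()]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_windows"] = [asdict(w) for w in self.planted_windows]
        d["planted_inversions"] = [asdict(v) for v in self.planted_inversions]
        return d


@dataclass
class SimTruth:
    planted_windows: list[PlantedWindow]
    planted_inversions: list[PlantedInversion]
    realized_divergence: dict[str, float]
    gene_intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    def planted_window_ids(self, window_size: int) -> set[str]:
        ids: set[str] = set()
        for pw in self.planted_windows:
            for w in range(pw.start // window_size, -(-pw.end // window_size)):
                ids.add(f"{pw.chrom}:{w}")
        return ids

    def to_dict(self) -> dict:
        return {
            "planted_windows": [asdict(w) for w in self.planted_windows],
            "planted_inversions": [asdict(v) for v in self.planted_inversions],
            "realized_divergence": self.realized_divergence,
            "gene_intervals": [list(g) for g in self.gene_intervals],
        }


Sequences = dict[str, dict[str, np.ndarray]]  # species -> chrom -> uint8[0..3]


def _jc_evolve(
    parent: np.ndarray, p_change: np.ndarray | float, rng: np.random.Generator
) -> np.ndarray:
    """One Jukes–Cantor branch: each site flips to a uniformly chosen other
    base with probability p_change (scalar or per-site)."""
    hit = rng.random(parent.size) < p_change
    child = parent.copy()
    child[hit] = (child[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return child


def _jc_p(t: float | np.ndarray) -> float | np.ndarray:
    return 0.75 * (1.0 - np.exp(-4.0 * np.asarray(t, dtype=float) / 3.0))


def _gap_tracts(
    size: int, gap_fraction: float, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Non-overlapping unaligned tracts totalling ~gap_fraction of the scaffold."""
    budget = int(size * gap_fraction)
    tracts: list[tuple[int, int]] = []
    used = 0
    guard = 0
    while used < budget and guard < 10_000:
        guard += 1
        length = int(rng.integers(500, 5_001))
        start = int(rng.integers(0, max(size - length, 1)))
        end = start + length
        if any(start < e and s < end for s, e in tracts):
            continue
        tracts.append((start, end))
        used += length
    return sorted(tracts)


def simulate_alignment(config: SimConfig) -> tuple[Sequences, list[MafBlock], SimTruth]:
    """Simulate the four genomes and their multiple alignment.

    Returns per-species sequences (base-coded uint8 arrays), MAF blocks
    (one per aligned tract, focal species as reference, no indels) and the
    planted truth with realized pairwise divergences.
    """
    rng = np.random.default_rng(config.seed)
    tree = Phylo.read(StringIO(config.tree), "newick")
    species = [leaf.name for leaf in tree.get_terminals()]
    if config.focal_species not in species:
        raise ValueError(f"focal species {config.focal_species!r} not in tree")
    if len(species) < 2:
        raise ValueError("tree must have at least two leaves")

    windows_by_chrom: dict[str, list[PlantedWindow]] = {}
    for pw in config.planted_windows:
        windows_by_chrom.setdefault(pw.chrom, []).append(pw)

    sequences: Sequences = {sp: {} for sp in species}
    blocks: list[MafBlock] = []
    comp = np.asarray(config.base_composition)
    sizes = config.chrom_sizes()

    for chrom, size in sizes.items():
        anc = rng.choice(4, size=size, p=comp).astype(np.uint8)

        def descend(clade, seq: np.ndarray) -> None:
            for child in clade.clades:
                t = child.branch_length or 0.0
                is_focal_tip = child.is_terminal() and child.name == config.focal_species
                if is_focal_tip and chrom in windows_by_chrom and t > 0:
                    t_site = np.full(size, t)
                    for pw in windows_by_chrom[chrom]:
                        t_site[pw.start:pw.end] = t * pw.rate_multiplier
                    p = _jc_p(t_site)
                else:
                    p = _jc_p(t)
                child_seq = _jc_evolve(seq, p, rng) if t > 0 else seq.copy()
                if child.is_terminal():
                    sequences[child.name][chrom] = child_seq
                else:
                    descend(child, child_seq)

        descend(tree.root, anc)

        gaps = _gap_tracts(size, config.gap_fraction, rng)
        bounds = [0] + [x for tr in gaps for x in tr] + [size]
        aligned_tracts = [
            (bounds[i], bounds[i + 1])
            for i in range(0, len(bounds), 2)
            if bounds[i + 1] > bounds[i]
        ]
        ordered = [config.focal_species] + [s for s in species if s != config.focal_species]
        for start, end in aligned_tracts:
            rows = [
                MafRow(
                    species=sp,
                    chrom=chrom,
                    start=start,
                    size=end - start,
                    strand="+",
                    src_size=size,
                    text=_BASES[sequences[sp][chrom][start:end]].tobytes().decode(),
                )
                for sp in ordered
            ]
            blocks.append(MafBlock(rows))

    realized: dict[str, float] = {}
    aligned_mask = {chrom: np.zeros(sizes[chrom], dtype=bool) for chrom in sizes}
    for b in blocks:
        r = b.rows[0]
        aligned_mask[r.chrom][r.start:r.start + r.size] = True
    for i, a in enumerate(species):
        for b_sp in species[i + 1:]:
            diff = tot = 0
            for chrom in sizes:
                m = aligned_mask[chrom]
                diff += int((sequences[a][chrom][m] != sequences[b_sp][chrom][m]).sum())
                tot += int(m.sum())
            realized[f"{a}|{b_sp}"] = diff / tot if tot else float("nan")

    truth = SimTruth(
        planted_windows=list(config.planted_windows),
        planted_inversions=list(config.planted_inversions),
        realized_divergence=realized,
    )
    return sequences, blocks, truth


def _revcomp_inplace(seq: np.ndarray, start: int, end: int) -> None:
    # base coding A=0,C=1,G=2,T=3 makes complement = 3 - base
    seq[start:end] = (3 - seq[start:end])[::-1]


def plant_inversions(
    config: SimConfig, sequences: Sequences
) -> tuple[Sequences, dict[str, list[PafRecord]]]:
    """Reverse-complement the planted segments in the named assemblies and
    build a truth PAF per non-focal species against the focal reference.

    Alignment records are split into blocks of at most 500 kb; inverted
    segments appear as '-' records flanked by '+' records.  Match counts
    are exact base-identity counts, so distance estimates from these
    records recover the realized divergence.
    """
    focal = config.focal_species
    mutated: Sequences = {
        sp: {c: s.copy() for c, s in chroms.items()} for sp, chroms in sequences.items()
    }
    inv_by_sp: dict[str, list[PlantedInversion]] = {}
    for inv in config.planted_inversions:
        if inv.species == focal:
            raise ValueError("inversions are planted in query genomes, not the reference")
        if inv.species not in sequences:
            raise ValueError(f"unknown species {inv.species!r} in planted inversion")
        inv_by_sp.setdefault(inv.species, []).append(inv)
        _revcomp_inplace(mutated[inv.species][inv.chrom], inv.start, inv.end)

    chunk = 500_000
    pafs: dict[str, list[PafRecord]] = {}
    for sp in sequences:
        if sp == focal:
            continue
        records: list[PafRecord] = []
        for chrom, ref_seq in sequences[focal].items():
            size = len(ref_seq)
            invs = sorted(
                (i for i in inv_by_sp.get(sp, []) if i.chrom == chrom),
                key=lambda i: i.start,
            )
            bounds = [0] + [x for i in invs for x in (i.start, i.end)] + [size]
            inverted_flags = []
            segs = []
            for k in range(len(bounds) - 1):
                if bounds[k + 1] > bounds[k]:
                    segs.append((bounds[k], bounds[k + 1]))
                    inverted_flags.append(k % 2 == 1)
            qseq = sequences[sp][chrom]  # pre-inversion: orientation handled by strand
            for (s0, e0), inv_flag in zip(segs, inverted_flags):
                pieces = list(range(s0, e0, chunk)) + [e0]
                for p0, p1 in zip(pieces[:-1], pieces[1:]):
                    nm = int((ref_seq[p0:p1] == qseq[p0:p1]).sum())
                    records.append(
                        PafRecord(
                            qname=chrom, qlen=size, qstart=p0, qend=p1,
                            strand="-" if inv_flag else "+",
                            tname=chrom, tlen=size, tstart=p0, tend=p1,
                            n_match=nm, block_len=p1 - p0, mapq=60,
                        )
                    )
        pafs[sp] = records
    return mutated, pafs


def _place_genes(config: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Uniformly placed non-overlapping genes with random strands."""
    sizes = config.chrom_sizes()
    chroms = list(sizes)
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes: list[GeneModel] = []
    guard = 0
    while len(genes) < config.n_genes and guard < config.n_genes * 100:
        guard += 1
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        length = int(rng.integers(1_000, 20_001))
        if sizes[chrom] <= length:
            continue
        start = int(rng.integers(0, sizes[chrom] - length))
        end = start + length
        if any(start < e and s < end for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"gene{len(genes) + 1:05d}",
                interval=GenomeInterval(chrom, start, end),
                strand=strand,
            )
        )
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start))
    return genes


def _to_assembly(name: str, chroms: Mapping[str, np.ndarray]) -> Assembly:
    return Assembly(
        [SequenceRecord(c, _BASES[s].tobytes().decode()) for c, s in chroms.items()],
        name=name,
    )


def emit_fixture_set(config: SimConfig, outdir: str | os.PathLike) -> dict[str, str]:
    """Write the complete fixture set and return a name -> path map.

    Files: one FASTA per species (inversions applied), ``alignment.maf``,
    one ``<species>_vs_<focal>.paf`` per non-focal species, ``genes.gff3``,
    ``class_map.tsv``, ``truth.json`` and ``config.json``.  Identical seeds
    give byte-identical files.
    """
    os.makedirs(outdir, exist_ok=True)
    outdir = str(outdir)
    sequences, blocks, truth = simulate_alignment(config)
    mutated, pafs = plant_inversions(config, sequences)
    # gene placement draws from its own stream so it is independent of the
    # evolutionary randomness but still seed-determined
    genes = _place_genes(config, np.random.default_rng(config.seed + 1))
    truth.gene_intervals = [
        (g.interval.chrom, g.interval.start, g.interval.end, g.strand) for g in genes
    ]

    paths: dict[str, str] = {}
    for sp, chroms in mutated.items():
        p = os.path.join(outdir, f"{sp}.fa")
        write_fasta(_to_assembly(sp, chroms), p)
        paths[f"fasta:{sp}"] = p
    p = os.path.join(outdir, "alignment.maf")
    write_maf(blocks, p)
    paths["maf"] = p
    for sp, records in pafs.items():
        p = os.path.join(outdir, f"{sp}_vs_{config.focal_species}.paf")
        write_paf(records, p)
        paths[f"paf:{sp}"] = p
    p = os.path.join(outdir, "genes.gff3")
    write_gff_genes(genes, p)
    paths["gff"] = p
    p = os.path.join(outdir, "class_map.tsv")
    write_class_map(config.class_map(), p)
    paths["class_map"] = p
    p = os.path.join(outdir, "truth.json")
    with open(p, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
    paths["truth"] = p
    p = os.path.join(outdir, "config.json")
    with open(p, "w") as fh:
        json.dump(config.to_dict(), fh, indent=1, sort_keys=True)
    paths["config"] = p
    return paths
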