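"""End-to-end orchestration: windows -> counts -> ΔSNP scan -> enrichment ->
proximity -> inversions, with on-disk TSV/BED artifacts per stage so partial
reruns are possible."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .context import (
    DEFAULT_N_PERM,
    DEFAULT_PROXIMITY,
    PermutationResult,
    ProximityResult,
    genes_near_windows,
    permutation_enrichment,
)
from .inversions import InversionCall, InversionParams, calls_frame, detect_inversions, genes_in_inversions
from .io_formats import (
    GenomeInterval,
    read_class_map,
    read_gff_genes,
    read_maf,
    read_paf,
)
from .scan import (
    ComparisonDesign,
    SelectedWindows,
    compute_delta_table,
    pair_key,
    select_top_quantile,
    selected_intervals,
)
from .windows import (
    DEFAULT_MIN_ALIGNED,
    DEFAULT_WINDOW_SIZE,
    accumulate_pair_counts,
    compute_proportions,
    make_windows,
)

log = logging.getLogger("divscan")


@dataclass
class RunConfig:
    maf_path: str | None
    class_map_path: str
    focal_species: str
    other_species: list[str]
    gff_path: str | None = None
    paf_paths: dict[str, str] = field(default_factory=dict)  # query species -> PAF
    chrom_sizes: dict[str, int] | None = None  # inferred from MAF if omitted
    window_size: int = DEFAULT_WINDOW_SIZE
    min_aligned: int = DEFAULT_MIN_ALIGNED
    quantile: float = 0.99
    proximity_bp: int = DEFAULT_PROXIMITY
    n_perm: int = DEFAULT_N_PERM
    inversion: InversionParams = field(default_factory=InversionParams)
    seed: int = 0
    outdir: str = "divscan_out"

    def design(self) -> ComparisonDesign:
        return ComparisonDesign.from_species(
            self.focal_species, self.other_species, quantile=self.quantile
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["inversion"] = self.inversion.to_dict()
        return d


def load_run_config(path: str) -> RunConfig:
    """Read a RunConfig from a YAML or JSON file (YAML is a JSON superset,
    so one loader covers both)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"run config {path} must be a mapping")
    if "inversion" in data and isinstance(data["inversion"], dict):
        data["inversion"] = InversionParams(**data["inversion"])
    return RunConfig(**data)


def validate_config(config: RunConfig) -> list[str]:
    """Content validation; returns a list of problems (empty = ok) and logs
    warnings for legitimate but non-default parameter choices."""
    errs: list[str] = []
    for label, path in [("MAF", config.maf_path), ("class map", config.class_map_path),
                        ("GFF3", config.gff_path)]:
        if path is not None and not os.path.exists(path):
            errs.append(f"{label} file not found: {path}")
    for sp, path in config.paf_paths.items():
        if not os.path.exists(path):
            errs.append(f"PAF file for {sp} not found: {path}")
    if not (0.0 < config.quantile < 1.0):
        errs.append(f"quantile must be in (0,1), got {config.quantile}")
    if config.window_size < 1:
        errs.append("window size must be >= 1")
    if config.min_aligned < 0:
        errs.append("min_aligned must be >= 0")
    if config.proximity_bp < 0:
        errs.append("proximity distance must be >= 0")
    if not config.other_species:
        errs.append("need at least one non-focal species")
    if len(config.other_species) < 2:
        errs.append("need >=2 non-focal species to form a control pair")
    if config.focal_species in config.other_species:
        errs.append("focal species listed among other species")
    if not errs:
        if config.window_size != DEFAULT_WINDOW_SIZE:
            log.warning("non-default window size %d bp", config.window_size)
        if config.min_aligned != DEFAULT_MIN_ALIGNED:
            log.warning("non-default aligned-base filter %d bp", config.min_aligned)
        if config.proximity_bp != DEFAULT_PROXIMITY:
            log.warning("non-default proximity distance %d bp", config.proximity_bp)
    return errs


@dataclass
class RunReport:
    config: RunConfig
    window_stats: pd.DataFrame
    delta_table: pd.DataFrame
    selected: SelectedWindows
    enrichment: PermutationResult | None
    proximity: ProximityResult | None
    inversion_calls: list[InversionCall]
    inversion_genes: list[str]
    version: str = __version__

    def summary(self) -> dict:
        d = {
            "version": self.version,
            "seed": self.config.seed,
            "n_windows": int(len(self.window_stats)),
            "n_windows_pass_filter": int(self.window_stats["pass_filter"].sum()),
            "n_selected": self.selected.n_selected,
            "n_selected_by_class": {
                cls: len(ids) for cls, ids in self.selected.by_class.items()
            },
            "n_inversions": len(self.inversion_calls),
            "n_inversion_genes": len(self.inversion_genes),
            "parameters": {
                "window_size": self.config.window_size,
                "min_aligned": self.config.min_aligned,
                "quantile": self.config.quantile,
                "proximity_bp": self.config.proximity_bp,
                "n_perm": self.config.n_perm,
                "inversion": self.config.inversion.to_dict(),
            },
        }
        if self.enrichment is not None:
            d["enrichment"] = self.enrichment.to_dict()
        if self.proximity is not None:
            d["n_proximal_genes"] = len(self.proximity.gene_distance)
        return d


def run_scan(config: RunConfig, maf_blocks=None, write: bool = True) -> RunReport:
    """Execute the full scan.

    ``maf_blocks`` can supply an in-memory block list (e.g. straight from the
    simulator) instead of reading ``config.maf_path``.  With ``write`` true,
    each stage's table is written under ``config.outdir``.
    """
    errs = validate_config(config) if maf_blocks is None else [
        e for e in validate_config(config) if "MAF" not in e
    ]
    if errs:
        raise ValueError("invalid run configuration: " + "; ".join(errs))

    design = config.design()
    class_map = read_class_map(config.class_map_path)

    if maf_blocks is None:
        maf_blocks = list(read_maf(config.maf_path))
    species_in_maf = {r.species for b in maf_blocks for r in b.rows}
    for sp in [config.focal_species, *config.other_species]:
        if sp not in species_in_maf:
            raise ValueError(f"species {sp!r} absent from the alignment")

    chrom_sizes = config.chrom_sizes
    if chrom_sizes is None:
        chrom_sizes = {}
        for b in maf_blocks:
            r = b.row_for(config.focal_species)
            if r is not None:
                chrom_sizes.setdefault(r.chrom, r.src_size)
    grid = make_windows(chrom_sizes, config.window_size)
    log.info("windows: %d over %d scaffolds", grid.n_windows, len(chrom_sizes))

    counts = [
        accumulate_pair_counts(
            maf_blocks, grid, a, b, coord_species=config.focal_species
        )
        for a, b in design.focal_pairs + design.control_pairs
    ]
    stats = compute_proportions(counts, grid, class_map, config.min_aligned)
    log.info("windows passing filter: %d", int(stats["pass_filter"].sum()))

    delta = compute_delta_table(stats, design)
    selected = select_top_quantile(delta, design)
    log.info("selected windows: %d", selected.n_selected)
    sel_df = selected_intervals(delta, selected.intersection)
    sel_ivs = [
        GenomeInterval(r.chrom, int(r.start), int(r.end))
        for r in sel_df.itertuples(index=False)
    ]

    enrichment = None
    proximity = None
    inv_calls: list[InversionCall] = []
    inv_genes: list[str] = []

    genes = read_gff_genes(config.gff_path) if config.gff_path else None
    if genes is not None and sel_ivs:
        genic = [g.interval for g in genes]
        analyzed_sizes = {
            c: s for c, s in chrom_sizes.items()
            if class_map.get(c) in ("autosome", "Z")
        }
        enrichment = permutation_enrichment(
            sel_ivs, genic, analyzed_sizes,
            n_perm=config.n_perm, seed=config.seed,
        )
        proximity = genes_near_windows(
            sel_ivs, genes, config.proximity_bp,
            window_ids=list(sel_df["window_id"]),
        )

    for sp, paf_path in config.paf_paths.items():
        records = read_paf(paf_path)
        inv_calls.extend(detect_inversions(records, config.inversion))
    if genes is not None and inv_calls:
        _, inv_genes = genes_in_inversions(inv_calls, genes)

    report = RunReport(
        config=config,
        window_stats=stats,
        delta_table=delta,
        selected=selected,
        enrichment=enrichment,
        proximity=proximity,
        inversion_calls=inv_calls,
        inversion_genes=inv_genes,
    )
    if write:
        write_report(report)
    return report


def write_report(report: RunReport) -> None:
    outdir = report.config.outdir
    os.makedirs(outdir, exist_ok=True)
    report.window_stats.to_csv(
        os.path.join(outdir, "window_stats.tsv"), sep="\t", index=False
    )
    report.delta_table.to_csv(
        os.path.join(outdir, "delta_table.tsv"), sep="\t", index=False
    )
    sel = selected_intervals(report.delta_table, report.selected.intersection)
    sel.to_csv(os.path.join(outdir, "selected_windows.tsv"), sep="\t", index=False)
    sel[["chrom", "start", "end"]].to_csv(
        os.path.join(outdir, "selected_windows.bed"), sep="\t",
        header=False, index=False,
    )
    calls_frame(report.inversion_calls).to_csv(
        os.path.join(outdir, "inversions.tsv"), sep="\t", index=False
    )
    if report.proximity is not None:
        pd.DataFrame(
            sorted(report.proximity.gene_distance.items()),
            columns=["gene_id", "distance_bp"],
        ).to_csv(os.path.join(outdir, "proximal_genes.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report.summary(), fh, indent=1, sort_keys=True)
    log.info("report written to %s", outdir)
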