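import numpy as np
import pytest

import divscan as ds


def small_sim_config(seed: int = 3) -> ds.SimConfig:
    """Desk-size simulation: 4 x 200-kb scaffolds, 3 planted focal windows,
    one callable and one sub-threshold inversion."""
    return ds.SimConfig(
        seed=seed,
        chrom_len=200_000,
        planted_windows=[
            ds.PlantedWindow("chrA1", 50_000, 60_000, 5.0),
            ds.PlantedWindow("chrA2", 120_000, 130_000, 5.0),
            ds.PlantedWindow("chrZ", 80_000, 90_000, 5.0),
        ],
        planted_inversions=[
            ds.PlantedInversion("barn_swallow", "chrA1", 100_000, 140_000),  # 40 kb
            ds.PlantedInversion("barn_swallow", "chrA2", 20_000, 80_000),    # 60 kb
        ],
        n_genes=50,
    )


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """Emitted file set for the small config plus its in-memory objects."""
    cfg = small_sim_config()
    outdir = tmp_path_factory.mktemp("fixture")
    paths = ds.emit_fixture_set(cfg, outdir)
    return {"config": cfg, "paths": paths, "outdir": outdir}


@pytest.fixture(scope="session")
def default_run():
    """Full default-condition simulation and scan, shared across tests.

    The default config is the study condition the scan is validated under:
    four 6-Mb scaffolds (three autosomes + Z), 20 planted 5x-rate focal
    windows, three planted inversions, ~0.03-0.04 background divergence.
    """
    cfg = ds.SimConfig(seed=11)
    sequences, blocks, truth = ds.simulate_alignment(cfg)
    grid = ds.make_windows(cfg.chrom_sizes(), 10_000)
    others = [s for s in cfg.species() if s != cfg.focal_species]
    design = ds.ComparisonDesign.from_species(cfg.focal_species, others)
    counts = [
        ds.accumulate_pair_counts(blocks, grid, a, b, coord_species=cfg.focal_species)
        for a, b in design.focal_pairs + design.control_pairs
    ]
    stats = ds.compute_proportions(counts, grid, cfg.class_map())
    delta = ds.compute_delta_table(stats, design)
    selected = ds.select_top_quantile(delta, design)
    mutated, pafs = ds.plant_inversions(cfg, sequences)
    return {
        "config": cfg,
        "truth": truth,
        "grid": grid,
        "design": design,
        "counts": counts,
        "stats": stats,
        "delta": delta,
        "selected": selected,
        "pafs": pafs,
    }


def random_maf_blocks(rng: np.random.Generator, n_blocks: int, species, chrom="chr1",
                      src_size=50_000):
    """Random gappy MAF blocks over one reference scaffold (non-overlapping
    reference coverage), for count-oracle tests."""
    alphabet = np.frombuffer(b"ACGTN-acgt", dtype=np.uint8)
    blocks = []
    cursor = 0
    for _ in range(n_blocks):
        cursor += int(rng.integers(0, 200))
        width = int(rng.integers(5, 120))
        ref_text = alphabet[rng.integers(0, len(alphabet), size=width)]
        ref_size = int((ref_text != ord("-")).sum())
        if ref_size == 0 or cursor + ref_size > src_size:
            continue
        rows = [ds.MafRow(species[0], chrom, cursor, ref_size, "+", src_size,
                          ref_text.tobytes().decode())]
        for sp in species[1:]:
            q = alphabet[rng.integers(0, len(alphabet), size=width)]
            rows.append(ds.MafRow(sp, chrom, 0, int((q != ord("-")).sum()), "+",
                                  src_size, q.tobytes().decode()))
        blocks.append(ds.MafBlock(rows))
        cursor += ref_size
    return blocks


def naive_pair_counts(blocks, grid, species_a, species_b, coord_species=None):
    """Independent per-column scan oracle for aligned-base / SNP counting."""
    coord_species = coord_species or species_a
    aligned = np.zeros(grid.n_windows, dtype=int)
    snp = np.zeros(grid.n_windows, dtype=int)
    seen = set()
    unamb = set("ACGTacgt")
    for block in blocks:
        crow = block.row_for(coord_species)
        arow = block.row_for(species_a)
        brow = block.row_for(species_b)
        if crow is None or arow is None or brow is None:
            continue
        pos = crow.start - 1
        for col in range(len(crow.text)):
            c = crow.text[col]
            if c == "-":
                continue
            pos += 1
            a, b = arow.text[col], brow.text[col]
            if a not in unamb or b not in unamb:
                continue
            if (crow.chrom, pos) in seen:
                continue
            seen.add((crow.chrom, pos))
            w = grid.offsets[crow.chrom] + pos // grid.window_size
            aligned[w] += 1
            if a.upper() != b.upper():
                snp[w] += 1
    return aligned, snp
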