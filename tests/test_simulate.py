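"""The four-species alignment simulator and its planted truth."""

import filecmp
import json

import numpy as np
import pytest

import divscan as ds

from conftest import small_sim_config


def test_two_species_divergence_calibration():
    # one 1-Mb chromosome, total path 0.03046 subs/site -> observed ~0.03
    cfg = ds.SimConfig(
        seed=5, n_chroms=2, chrom_len=1_000_000,
        tree="(a:0.01523,b:0.01523);", focal_species="a",
        planted_windows=[], planted_inversions=[], n_genes=0,
    )
    _, _, truth = ds.simulate_alignment(cfg)
    assert truth.realized_divergence["a|b"] == pytest.approx(0.03, abs=0.004)


def test_zero_length_branches_give_identical_sequences():
    cfg = ds.SimConfig(
        seed=6, n_chroms=2, chrom_len=50_000, tree="(a:0.0,b:0.0);",
        focal_species="a", planted_windows=[], planted_inversions=[], n_genes=0,
    )
    seqs, blocks, truth = ds.simulate_alignment(cfg)
    for chrom in seqs["a"]:
        assert np.array_equal(seqs["a"][chrom], seqs["b"][chrom])
    assert all(v == 0.0 for v in truth.realized_divergence.values())


def test_gap_fraction_respected():
    cfg = small_sim_config()
    _, blocks, _ = ds.simulate_alignment(cfg)
    aligned = sum(b.rows[0].size for b in blocks)
    total = cfg.n_chroms * cfg.chrom_len
    frac = 1 - aligned / total
    assert 0.5 * cfg.gap_fraction <= frac <= 1.5 * cfg.gap_fraction


def test_planted_window_elevates_only_focal_comparisons(default_run):
    """Planted focal-branch windows must look divergent in every focal
    comparison and background-level in every control comparison — the
    structure the ΔSNP contrast assumes."""
    stats = default_run["stats"]
    truth = default_run["truth"]
    design = default_run["design"]
    planted = truth.planted_window_ids(10_000)
    is_planted = stats["window_id"].isin(planted)
    from divscan.scan import pair_key
    for pair in design.focal_pairs:
        col = f"prop:{pair_key(pair)}"
        assert stats.loc[is_planted, col].mean() > 2 * stats.loc[~is_planted, col].mean()
    for pair in design.control_pairs:
        col = f"prop:{pair_key(pair)}"
        ratio = stats.loc[is_planted, col].mean() / stats.loc[~is_planted, col].mean()
        assert 0.9 < ratio < 1.1


def test_config_validation_errors():
    with pytest.raises(ValueError, match="non-focal"):
        ds.SimConfig(planted_windows=[
            ds.PlantedWindow("chrA1", 0, 10_000, 5.0, species="barn_swallow")
        ])
    with pytest.raises(ValueError, match="overlap"):
        ds.SimConfig(planted_inversions=[
            ds.PlantedInversion("barn_swallow", "chrA1", 0, 100_000),
            ds.PlantedInversion("barn_swallow", "chrA1", 50_000, 150_000),
        ])
    with pytest.raises(ValueError, match="bounds"):
        ds.SimConfig(chrom_len=100_000)  # default planted windows out of range
    with pytest.raises(ValueError, match="rate_multiplier"):
        ds.SimConfig(planted_windows=[ds.PlantedWindow("chrA1", 0, 10_000, 0.5)])


def test_truth_paf_marks_each_inversion_with_minus_blocks():
    cfg = small_sim_config()
    seqs, _, _ = ds.simulate_alignment(cfg)
    mutated, pafs = ds.plant_inversions(cfg, seqs)
    recs = pafs["barn_swallow"]
    minus = [r for r in recs if r.strand == "-"]
    spans = {(r.tname, r.tstart, r.tend) for r in minus}
    assert spans == {("chrA1", 100_000, 140_000), ("chrA2", 20_000, 80_000)}
    # species without inversions align all-plus
    assert all(r.strand == "+" for r in pafs["tree_swallow"])
    # the mutated assembly is reverse-complemented exactly on the segment
    seg = slice(100_000, 140_000)
    assert np.array_equal(
        mutated["barn_swallow"]["chrA1"][seg],
        (3 - seqs["barn_swallow"]["chrA1"][seg])[::-1],
    )


def test_inversion_at_chromosome_start_has_no_left_flank():
    cfg = ds.SimConfig(
        seed=8, chrom_len=200_000,
        planted_windows=[],
        planted_inversions=[ds.PlantedInversion("barn_swallow", "chrA1", 0, 60_000)],
        n_genes=0,
    )
    seqs, _, _ = ds.simulate_alignment(cfg)
    _, pafs = ds.plant_inversions(cfg, seqs)
    minus = [r for r in pafs["barn_swallow"] if r.strand == "-"]
    assert {(r.tstart, r.tend) for r in minus} == {(0, 60_000)}


def test_empty_inversion_list_gives_all_plus_records():
    cfg = ds.SimConfig(seed=9, chrom_len=100_000, planted_windows=[],
                       planted_inversions=[], n_genes=0)
    seqs, _, _ = ds.simulate_alignment(cfg)
    _, pafs = ds.plant_inversions(cfg, seqs)
    assert all(r.strand == "+" for recs in pafs.values() for r in recs)


def test_paf_distance_recovers_nominal_divergence(default_run):
    truth = default_run["truth"]
    pafs = default_run["pafs"]
    for sp, target in [("barn_swallow", 0.030), ("bank_swallow", 0.038),
                       ("tree_swallow", 0.039)]:
        est = ds.estimate_pairwise_distance(pafs[sp])
        assert est == pytest.approx(target, abs=0.005)
        # the PAF estimate covers every position, the realized divergence
        # only aligned tracts; they agree up to that sampling difference
        assert est == pytest.approx(
            truth.realized_divergence[f"house_martin|{sp}"], abs=1e-3
        )


def test_fixture_set_deterministic_and_parseable(small_fixture, tmp_path):
    cfg = small_fixture["config"]
    paths = small_fixture["paths"]
    # every emitted file goes back through its reader
    for sp in cfg.species():
        asm = ds.read_fasta(paths[f"fasta:{sp}"])
        assert asm.chrom_sizes() == cfg.chrom_sizes()
    blocks = list(ds.read_maf(paths["maf"]))
    assert blocks and all(len(b.rows) == 4 for b in blocks)
    for sp in cfg.species():
        if sp != cfg.focal_species:
            assert ds.read_paf(paths[f"paf:{sp}"])
    genes = ds.read_gff_genes(paths["gff"])
    assert len(genes) == cfg.n_genes
    cmap = ds.read_class_map(paths["class_map"])
    assert cmap["chrZ"] == "Z"
    truth = json.load(open(paths["truth"]))
    assert len(truth["gene_intervals"]) == cfg.n_genes
    # identical seed -> byte-identical outputs
    again = ds.emit_fixture_set(cfg, tmp_path / "again")
    for key, p in paths.items():
        assert filecmp.cmp(p, again[key], shallow=False), key


def test_fixture_maf_round_trip_counts(small_fixture):
    """Counts from the written-and-reread MAF equal counts from the
    in-memory blocks (the writer loses nothing the counter needs)."""
    cfg = small_fixture["config"]
    _, blocks, _ = ds.simulate_alignment(cfg)
    reread = list(ds.read_maf(small_fixture["paths"]["maf"]))
    grid = ds.make_windows(cfg.chrom_sizes(), 10_000)
    a = ds.accumulate_pair_counts(blocks, grid, "house_martin", "barn_swallow")
    b = ds.accumulate_pair_counts(reread, grid, "house_martin", "barn_swallow")
    assert np.array_equal(a.aligned, b.aligned)
    assert np.array_equal(a.snp, b.snp)


def test_zero_genes_yields_valid_empty_gff(tmp_path):
    cfg = ds.SimConfig(seed=10, chrom_len=100_000, planted_windows=[],
                       planted_inversions=[], n_genes=0)
    paths = ds.emit_fixture_set(cfg, tmp_path)
    assert ds.read_gff_genes(paths["gff"]) == []


def test_null_simulation_has_chance_level_intersection():
    """Without planted windows the three focal top-1% sets share only what
    chance allows."""
    cfg = ds.SimConfig(seed=13, chrom_len=1_000_000, planted_windows=[],
                       planted_inversions=[], n_genes=0)
    _, blocks, _ = ds.simulate_alignment(cfg)
    grid = ds.make_windows(cfg.chrom_sizes(), 10_000)
    others = [s for s in cfg.species() if s != cfg.focal_species]
    design = ds.ComparisonDesign.from_species(cfg.focal_species, others)
    counts = [
        ds.accumulate_pair_counts(blocks, grid, a, b, coord_species=cfg.focal_species)
        for a, b in design.focal_pairs + design.control_pairs
    ]
    stats = ds.compute_proportions(counts, grid, cfg.class_map())
    delta = ds.compute_delta_table(stats, design)
    sel = ds.select_top_quantile(delta, design)
    # focal comparisons share the focal lineage, so their noise is correlated;
    # still, the intersection must stay a small fraction of the genome
    assert sel.n_selected <= 0.01 * grid.n_windows
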