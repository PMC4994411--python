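import numpy as np
import pandas as pd
import pytest

from asterion.classify import AntisenseClass, classify_annotation, summarize
from asterion.conservation import build_matrix
from asterion.evidence import EvidenceIndex, orientation_filter
from asterion.expression import pair_correlations
from asterion.simulate import (
    SimulationConfig,
    default_conservation_truth,
    simulate_annotation,
    simulate_conservation_hits,
    simulate_cne_hits,
    simulate_evidence_hits,
    simulate_expression,
)
from asterion.stats import largest_intron_per_gene, rank_sum_test


SMALL = dict(n_genes=30, planted={"intronic": 5, "nested": 3, "exonic": 2,
                                  "utr3": 2, "utr5": 1})


def test_classifier_recovers_planted_classes():
    """The classifier, used as an oracle on the generator's truth labels,
    finds exactly the planted configurations and nothing else."""
    cfg = SimulationConfig(seed=11, **SMALL)
    aset, truth = simulate_annotation(cfg)
    s = summarize(classify_annotation(aset))
    assert {c.value: n for c, n in s.counts.items()} == cfg.planted
    assert s.n_gene_level_pairs == cfg.planted["intronic"]


def test_zero_planting_means_zero_overlaps():
    cfg = SimulationConfig(
        seed=3, n_genes=40,
        planted={"intronic": 0, "nested": 0, "exonic": 0, "utr3": 0, "utr5": 0},
    )
    aset, _ = simulate_annotation(cfg)
    assert classify_annotation(aset) == []


def test_annotation_bytes_reproducible(tmp_path):
    from asterion.annotation_io import write_annotation

    paths = []
    for run in (1, 2):
        cfg = SimulationConfig(seed=5, **SMALL)
        aset, _ = simulate_annotation(cfg)
        p = tmp_path / f"run{run}.gff3"
        write_annotation(aset, str(p))
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_planted_intronic_ast_inside_one_intron():
    cfg = SimulationConfig(seed=7, **SMALL)
    aset, truth = simulate_annotation(cfg)
    for p in truth.planted_pairs:
        if p.cls != "intronic":
            continue
        host = aset[p.host_transcript]
        ast = aset[p.ast_transcript]
        assert any(i.contains(ast.span()) for i in host.introns())


class TestExpression:
    def test_target_rho_zero_within_sampling_noise(self):
        cfg = SimulationConfig(seed=2, n_samples=100, **SMALL)
        aset, truth = simulate_annotation(cfg)
        expr = simulate_expression(cfg, truth, aset)
        rhos, _ = pair_correlations(truth.gene_pairs("intronic"), expr)
        assert abs(np.mean(rhos)) < 3 / np.sqrt(cfg.n_samples)

    def test_target_rho_hits_within_tolerance(self):
        """Gaussian-copula pairs at rho 0.9, 500 samples: realized
        Spearman within +/- 0.05 of target."""
        cfg = SimulationConfig(seed=9, rho_target=0.9, n_samples=500, **SMALL)
        aset, truth = simulate_annotation(cfg)
        expr = simulate_expression(cfg, truth, aset)
        rhos, _ = pair_correlations(truth.gene_pairs("intronic"), expr)
        assert np.mean(rhos) == pytest.approx(0.9, abs=0.05)

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(seed=4, **SMALL)
        aset, truth = simulate_annotation(cfg)
        a = simulate_expression(cfg, truth, aset)
        b = simulate_expression(cfg, truth, aset)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestEvidenceHits:
    def test_ratio_one_equalizes_rates(self):
        """With enrichment ratio 1 the AST and non-AST hit rates are equal
        within binomial error at matched lengths (pooled over genes)."""
        cfg = SimulationConfig(
            seed=6, n_genes=1500, evidence_enrichment_ratio=1.0,
            evidence_length_slope=0.0,
            planted={"intronic": 200, "nested": 0, "exonic": 0, "utr3": 0,
                     "utr5": 0},
        )
        aset, truth = simulate_annotation(cfg)
        simulate_evidence_hits(cfg, truth, aset)
        flags = truth.evidence_flags
        ast_rate = np.mean([flags[t] for t in truth.ast_transcripts])
        other_rate = np.mean(
            [f for t, f in flags.items() if t not in truth.ast_transcripts]
        )
        assert ast_rate == pytest.approx(other_rate, abs=0.1)
        assert other_rate == pytest.approx(cfg.evidence_base_rate, abs=0.05)

    def test_decoy_fraction_filtered(self):
        cfg = SimulationConfig(seed=8, n_genes=800, decoy_fraction=0.5, **{
            k: v for k, v in SMALL.items() if k != "n_genes"})
        aset, truth = simulate_annotation(cfg)
        hits = simulate_evidence_hits(cfg, truth, aset)
        kept = orientation_filter(hits)
        n_decoys = len(hits) - len(kept)
        n_transcripts = len(aset)
        assert n_decoys / n_transcripts == pytest.approx(0.5, abs=0.07)

    def test_base_rate_zero_gives_empty_table(self):
        cfg = SimulationConfig(seed=1, evidence_base_rate=0.0,
                               decoy_fraction=0.0, **SMALL)
        aset, truth = simulate_annotation(cfg)
        assert simulate_evidence_hits(cfg, truth, aset) == []


class TestConservationHits:
    def test_zero_dropout_recovers_truth_exactly(self):
        cfg = SimulationConfig(seed=12, **SMALL)
        aset, truth = simulate_annotation(cfg)
        tables = simulate_conservation_hits(cfg, truth)
        m = build_matrix(
            list(truth.conservation.index),
            list(truth.conservation.columns),
            tables,
        )
        pd.testing.assert_frame_equal(
            m.to_frame().astype(bool), truth.conservation
        )

    def test_all_false_truth_gives_all_false_matrix(self):
        cfg = SimulationConfig(seed=13, **SMALL)
        aset, truth = simulate_annotation(cfg)
        pairs = [f"{h}|{a}" for h, a in truth.gene_pairs("intronic")]
        falsy = pd.DataFrame(
            False, index=pairs, columns=[f"genome{g:02d}" for g in range(6)]
        )
        tables = simulate_conservation_hits(cfg, truth, conservation=falsy)
        m = build_matrix(pairs, list(falsy.columns), tables)
        assert not m.to_frame().to_numpy().any()

    def test_dropout_recall(self):
        """Single-witness conserved cells with dropout d are recovered at
        rate 1 - d within binomial error."""
        d = 0.3
        cfg = SimulationConfig(seed=14, hit_dropout=d, **SMALL)
        aset, truth = simulate_annotation(cfg)
        pairs = [f"p{i}" for i in range(25)]
        genomes = [f"genome{g:02d}" for g in range(20)]
        all_true = pd.DataFrame(True, index=pairs, columns=genomes)
        tables = simulate_conservation_hits(cfg, truth, conservation=all_true)
        m = build_matrix(pairs, genomes, tables)
        recall = m.to_frame().to_numpy().sum() / (len(pairs) * len(genomes))
        n = len(pairs) * len(genomes)
        half_width = 1.96 * np.sqrt(d * (1 - d) / n)
        assert abs(recall - (1 - d)) < half_width + 0.01


def test_host_introns_dominate_background():
    """Host genes draw the long-intron model: the largest-intron rank-sum
    comparison is overwhelmingly significant."""
    cfg = SimulationConfig(
        seed=15, n_genes=500,
        planted={"intronic": 60, "nested": 0, "exonic": 0, "utr3": 0,
                 "utr5": 0},
    )
    aset, truth = simulate_annotation(cfg)
    table = largest_intron_per_gene(aset, host_genes=truth.host_genes)
    table = table[table["largest_intron"] > 0]
    res = rank_sum_test(
        table.loc[table.is_host, "largest_intron"].to_numpy(),
        table.loc[~table.is_host, "largest_intron"].to_numpy(),
        alternative="a_greater",
    )
    assert res.p_one_sided < 1e-6


def test_cne_hit_table_shape():
    hits = simulate_cne_hits(n_queries=28, n_subjects=27, seed=0)
    from asterion.conservation import count_cne

    assert count_cne(hits) == (28, 27)


def test_default_truth_has_one_universal_pair():
    cfg = SimulationConfig(seed=16, **SMALL)
    truth = default_conservation_truth(cfg, [f"p{i}" for i in range(8)])
    assert truth.iloc[0].all()
    assert truth.shape == (8, cfg.n_genomes)
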