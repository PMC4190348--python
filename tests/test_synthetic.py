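"""The study generator: determinism, planted structure, truth round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from rxnet.enrichment import fisher_enrichment
from rxnet.expression import InvalidInputError
from rxnet.synthetic import (
    SimTruth,
    make_annotation,
    make_counts,
    make_genesets,
    make_promoters,
    make_timecourse,
)


class TestDeterminism:
    def test_counts_identical_across_runs(self):
        a = make_counts(50, 2, 1e5, 0.2, 2.0, seed=42)
        b = make_counts(50, 2, 1e5, 0.2, 2.0, seed=42)
        pd.testing.assert_frame_equal(a.counts.values, b.counts.values)
        assert a.truth.de_labels == b.truth.de_labels

    def test_promoter_fasta_bytes_identical(self, tmp_path):
        from rxnet.motif import write_fasta

        for name in ("x", "y"):
            sim = make_promoters(5, length=300, sites_per_gene=1, seed=7)
            write_fasta(sim.promoters, tmp_path / f"{name}.fa")
        assert (tmp_path / "x.fa").read_bytes() == (tmp_path / "y.fa").read_bytes()

    def test_different_seeds_differ(self):
        a = make_counts(50, 2, 1e5, seed=1)
        b = make_counts(50, 2, 1e5, seed=2)
        assert not a.counts.values.equals(b.counts.values)


class TestMakeCounts:
    def test_label_counts_match_requested_fraction(self):
        sim = make_counts(100, de_fraction=0.1, fc=2.0, seed=0)
        labels = pd.Series(sim.truth.de_labels)
        assert (labels != "null").sum() == 10
        assert (labels == "down").sum() == 5
        assert (labels == "up").sum() == 5

    def test_unit_fold_change_labels_everything_null(self):
        sim = make_counts(100, de_fraction=0.5, fc=1.0, seed=0)
        assert set(sim.truth.de_labels.values()) == {"null"}

    def test_nonpositive_library_rejected(self):
        with pytest.raises(InvalidInputError):
            make_counts(10, lib_size=0)

    def test_null_gene_condition_ratios_centre_on_one(self):
        sim = make_counts(2000, n_reps=3, lib_size=1e6, de_fraction=0.0,
                          fc=3.0, seed=12)
        cond = sim.counts.sample_meta["condition"]
        sib = sim.counts.values[[s for s in sim.counts.sample_ids
                                 if cond[s] == "sibling"]].sum(axis=1)
        mut = sim.counts.values[[s for s in sim.counts.sample_ids
                                 if cond[s] == "mutant"]].sum(axis=1)
        keep = (sib + mut) > 50  # ratio is ill-behaved at tiny counts
        ratios = (sib[keep] / mut[keep]).to_numpy()
        se = ratios.std(ddof=1) / np.sqrt(keep.sum())
        assert abs(ratios.mean() - 1.0) < 3 * se + 0.01


class TestMakeTimecourse:
    def test_zero_noise_gives_exact_unit_correlation(self):
        sim = make_timecourse(30, module_sizes=(10, 10, 10), noise_sd=0.0,
                              within_module_corr=1.0, seed=0)
        X = sim.matrix.values
        labels = pd.Series(sim.truth.module_labels)
        for grp in ("group1", "group2", "group3"):
            sub = X.loc[labels[labels == grp].index].to_numpy()
            r = np.corrcoef(sub)
            assert np.allclose(r, 1.0)

    def test_realized_correlation_tracks_target(self):
        target = 0.9
        sim = make_timecourse(60, module_sizes=(25, 0, 0),
                              within_module_corr=target, seed=5)
        labels = pd.Series(sim.truth.module_labels)
        sub = sim.matrix.values.loc[labels[labels == "group1"].index].to_numpy()
        r = np.corrcoef(sub)
        iu, ju = np.triu_indices(sub.shape[0], 1)
        assert abs(r[iu, ju].mean() - target) <= 0.03

    def test_background_rarely_exceeds_edge_threshold(self):
        sim = make_timecourse(200, module_sizes=(0, 0, 0), seed=8)
        r = np.corrcoef(sim.matrix.values.to_numpy())
        iu, ju = np.triu_indices(200, 1)
        # P(|r| >= 0.95) over 12 stages is ~2e-6 per pair -> expect ~0.05
        assert (np.abs(r[iu, ju]) >= 0.95).sum() <= 3

    def test_invalid_correlation_rejected(self):
        with pytest.raises(InvalidInputError):
            make_timecourse(20, within_module_corr=0.0)
        with pytest.raises(InvalidInputError):
            make_timecourse(20, within_module_corr=1.2)

    def test_modules_cannot_exceed_gene_count(self):
        with pytest.raises(InvalidInputError):
            make_timecourse(10, module_sizes=(5, 5, 5))


class TestMakePromoters:
    def test_base_composition_must_sum_to_one(self):
        with pytest.raises(InvalidInputError):
            make_promoters(2, base_comp=(0.3, 0.3, 0.3, 0.3))

    def test_planted_sites_never_overlap(self):
        sim = make_promoters(8, length=500, sites_per_gene=5, seed=6)
        by_gene = {}
        for g, off, _ in sim.truth.planted_positions:
            by_gene.setdefault(g, []).append(off)
        for offs in by_gene.values():
            offs.sort()
            assert all(b - a >= 12 for a, b in zip(offs, offs[1:]))

    def test_too_many_sites_rejected(self):
        with pytest.raises(InvalidInputError):
            make_promoters(2, length=100, sites_per_gene=10)


class TestMakeAnnotation:
    def test_overlapping_cds_layout_is_one_gene(self):
        sim = make_annotation([
            ("a", "chr1", "+", [(0, 200)], [(0, 200)]),
            ("b", "chr1", "+", [(100, 400)], [(100, 300)]),
        ])
        assert sim.expected_clusters == [frozenset({"a", "b"})]

    def test_cdsless_transcript_joins_by_transcribed_overlap(self):
        sim = make_annotation([
            ("a", "chr1", "+", [(100, 300)], [(100, 300)]),
            ("c", "chr1", "+", [(250, 400)], None),
        ])
        assert sim.expected_clusters == [frozenset({"a", "c"})]

    def test_short_isolated_novel_transcript_is_discarded(self):
        sim = make_annotation([
            ("a", "chr1", "+", [(0, 500)], [(0, 500)]),
            ("nov", "chr2", "+", [(0, 250)], None, "novel"),
        ])
        assert sim.expected_clusters == [frozenset({"a"})]

    def test_cds_outside_exons_rejected(self):
        from rxnet.annotation import InvalidModelError

        with pytest.raises(InvalidModelError):
            make_annotation([("a", "chr1", "+", [(0, 100)], [(50, 200)])])


class TestMakeGenesets:
    def test_full_overlap_reaches_minimal_point_probability(self):
        sim = make_genesets(80, n_terms=3, term_size=10,
                            enriched_term_overlap=1.0, seed=2)
        terms = {t: set(g["gene"]) for t, g in sim.annotation.groupby("term_id")}
        uni = {f"g{i:05d}" for i in range(80)}
        query = set(sim.truth.query_genes)
        assert terms["t000"] == query
        out = fisher_enrichment(query, {"t000": terms["t000"]}, uni)
        assert out["p"].iloc[0] == pytest.approx(
            float(hypergeom.pmf(10, 80, 10, 10)), rel=1e-9
        )

    def test_single_universal_term_cannot_enrich(self):
        sim = make_genesets(40, n_terms=1, term_size=40,
                            enriched_term_overlap=1.0, seed=3)
        terms = {t: set(g["gene"]) for t, g in sim.annotation.groupby("term_id")}
        uni = {f"g{i:05d}" for i in range(40)}
        out = fisher_enrichment(set(sim.truth.query_genes), terms, uni)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_background_rate_overlap_rarely_enriches(self):
        # designed overlap at the chance rate: q should stay >= 0.05
        n_calm = 0
        for seed in range(20):
            sim = make_genesets(300, n_terms=10, term_size=15,
                                enriched_term_overlap=15 / 300, seed=seed)
            terms = {t: set(g["gene"])
                     for t, g in sim.annotation.groupby("term_id")}
            uni = {f"g{i:05d}" for i in range(300)}
            out = fisher_enrichment(set(sim.truth.query_genes), terms, uni)
            q0 = out.set_index("term").loc["t000", "q"]
            n_calm += q0 >= 0.05
        assert n_calm >= 18  # >= 90% of seeds

    def test_overlap_above_one_rejected(self):
        with pytest.raises(InvalidInputError):
            make_genesets(50, enriched_term_overlap=1.5)


def test_truth_round_trip(tmp_path):
    counts = make_counts(30, de_fraction=0.2, fc=2.0, seed=1)
    prom = make_promoters(5, length=300, sites_per_gene=2, seed=1)
    gs = make_genesets(30, n_terms=2, term_size=5, seed=1)
    tc = make_timecourse(30, module_sizes=(5, 5, 5), seed=1)
    merged = SimTruth(
        de_labels=counts.truth.de_labels,
        module_labels=tc.truth.module_labels,
        planted_sites=prom.truth.planted_sites,
        planted_positions=prom.truth.planted_positions,
        scan_hits=prom.truth.scan_hits,
        enriched_terms=gs.truth.enriched_terms,
        query_genes=gs.truth.query_genes,
    )
    merged.write(tmp_path)
    back = SimTruth.read(tmp_path)
    assert back.de_labels == merged.de_labels
    assert back.module_labels == merged.module_labels
    assert back.planted_sites == merged.planted_sites
    assert back.planted_positions == merged.planted_positions
    assert back.scan_hits == merged.scan_hits
    assert back.enriched_terms == merged.enriched_terms
    assert back.query_genes == merged.query_genes
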