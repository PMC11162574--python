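import numpy as np
import pandas as pd
import pytest

from dupevol import methylation, simulate
from dupevol.io import GeneModel


def calls_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "position", "context",
                                       "n_methylated", "n_total"])


class TestClassifyExpression:
    @pytest.mark.parametrize(
        "fpkm, expected",
        [
            (0.0005, "non"),
            (0.001, "low"),
            (5.0, "low"),  # closed right boundary
            (5.01, "medium"),
            (50.0, "medium"),
            (50.01, "high"),
        ],
    )
    def test_cutpoints(self, fpkm, expected):
        assert methylation.classify_expression(fpkm) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            methylation.classify_expression(-1.0)


class TestRegionMethylation:
    def test_fully_methylated_region(self):
        calls = calls_frame([("chr1", p, "CG", 10, 10) for p in (120, 150, 180)])
        gene = GeneModel("chr1", 100, 200, "+", "g")
        rm = methylation.region_methylation(calls, gene, "gene_body")
        assert rm.level == 1.0 and rm.n_sites == 3

    def test_coverage_weighted_pooling(self):
        # (3/10 and 7/10) pool to 10/20 = 0.5, not the site mean of levels
        calls = calls_frame(
            [("chr1", 120, "CG", 3, 10), ("chr1", 150, "CG", 7, 10)]
        )
        gene = GeneModel("chr1", 100, 200, "+", "g")
        rm = methylation.region_methylation(calls, gene, "gene_body", min_sites=2)
        assert rm.level == pytest.approx(0.5)

    def test_too_few_sites_gives_nan(self):
        calls = calls_frame([("chr1", 5000, "CG", 5, 10)])
        gene = GeneModel("chr1", 100, 200, "+", "g")
        rm = methylation.region_methylation(calls, gene, "gene_body", min_sites=1)
        assert np.isnan(rm.level) and rm.n_sites == 0

    def test_promoter_respects_strand(self):
        calls = calls_frame(
            [("chr1", 50, "CG", 10, 10), ("chr1", 250, "CG", 0, 10)]
        )
        plus = GeneModel("chr1", 100, 200, "+", "gp")
        minus = GeneModel("chr1", 100, 200, "-", "gm")
        up_plus = methylation.region_methylation(calls, plus, "promoter", min_sites=1)
        up_minus = methylation.region_methylation(calls, minus, "promoter", min_sites=1)
        assert up_plus.level == 1.0  # site at 50 is upstream of a + gene
        assert up_minus.level == 0.0  # site at 250 is upstream of a - gene

    def test_promoter_truncated_at_chromosome_start(self):
        calls = calls_frame([("chr1", 10, "CG", 5, 10)])
        gene = GeneModel("chr1", 100, 200, "+", "g")
        rm = methylation.region_methylation(calls, gene, "promoter", min_sites=1)
        assert rm.level == pytest.approx(0.5)

    def test_additive_over_split_call_files(self, rng):
        rows = [("chr1", int(p), "CG", int(m), 10)
                for p, m in zip(rng.integers(1, 5000, 200),
                                rng.integers(0, 11, 200))]
        calls = calls_frame(rows)
        gene = GeneModel("chr1", 1000, 3000, "+", "g")
        whole = methylation.region_methylation(calls, gene, "gene_body")
        half_a = calls.iloc[::2]
        half_b = calls.iloc[1::2]
        merged = pd.concat([half_a, half_b])
        again = methylation.region_methylation(merged, gene, "gene_body")
        assert whole.level == pytest.approx(again.level)


class TestMetageneProfile:
    def test_uniform_methylation_gives_flat_profile(self):
        calls = calls_frame(
            [("chr1", p, "CG", 5, 10) for p in range(1, 20000, 25)]
        )
        genes = [GeneModel("chr1", 5000, 7000, "+", "g1"),
                 GeneModel("chr1", 12000, 14000, "-", "g2")]
        prof = methylation.metagene_profile(
            calls, genes, {"g1": "high", "g2": "high"}
        )
        levels = prof.levels["high"]
        assert np.allclose(levels[~np.isnan(levels)], 0.5)

    def test_minus_strand_upstream_lies_past_tes_coordinate(self):
        # one cytosine 100 bp beyond the end of a minus-strand gene must land
        # in the upstream flank (5' of its TSS)
        calls = calls_frame([("chr1", 2100, "CG", 10, 10)])
        gene = GeneModel("chr1", 1000, 2000, "-", "g")
        prof = methylation.metagene_profile(calls, [gene], {"g": "low"})
        nf = prof.n_flank_bins
        upstream = prof.levels["low"][:nf]
        assert np.nansum(upstream) == 1.0  # the single site, fully methylated
        assert np.all(np.isnan(prof.levels["low"][nf:]))

    def test_strand_mirror_invariance(self, rng):
        """Reverse-complementing the genome (mirrored coordinates, flipped
        strands) leaves the transcription-oriented profile unchanged."""
        L = 60_000
        cfg = simulate.MethylomeSimConfig(
            seed=77, n_genes=10, genome_length=L, coverage=10
        )
        genes, calls, _expr, truth = simulate.simulate_methylome(cfg)
        classes = dict(truth["class"])
        prof = methylation.metagene_profile(calls, genes, classes, context=None)
        mirror_calls = calls.assign(position=L + 1 - calls["position"])
        mirror_genes = [
            GeneModel(g.chrom, L + 1 - g.end, L + 1 - g.start,
                      "-" if g.strand == "+" else "+", g.gene_id)
            for g in genes
        ]
        prof_m = methylation.metagene_profile(
            mirror_calls, mirror_genes, classes, context=None
        )
        for cls in methylation.EXPRESSION_CLASSES:
            np.testing.assert_allclose(
                prof.levels[cls], prof_m.levels[cls], equal_nan=True
            )

    def test_short_genes_excluded_and_counted(self):
        calls = calls_frame([("chr1", 100, "CG", 5, 10)])
        genes = [GeneModel("chr1", 90, 110, "+", "tiny")]  # 21 bp < 40 bins
        prof = methylation.metagene_profile(calls, genes, {"tiny": "low"})
        assert prof.n_excluded_short == 1
        assert prof.n_genes["low"] == 0

    def test_planted_landscape_recovered_per_bin(self):
        flat = {c: 0.2 for c in methylation.EXPRESSION_CLASSES}
        cfg = simulate.MethylomeSimConfig(seed=5, body_levels=flat)
        genes, calls, _expr, truth = simulate.simulate_methylome(cfg)
        prof = methylation.metagene_profile(
            calls, genes, dict(truth["class"]), context=None
        )
        nf, nb = prof.n_flank_bins, prof.n_body_bins
        for cls in methylation.EXPRESSION_CLASSES:
            v = prof.levels[cls]
            assert np.nanmax(np.abs(v[:nf] - 0.8)) < 0.02
            assert np.nanmax(np.abs(v[nf:nf + nb] - 0.2)) < 0.02
            assert np.nanmax(np.abs(v[nf + nb:] - 0.8)) < 0.02


class TestAssociation:
    def test_constant_level_reported_as_na(self):
        levels = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "region": "gene_body",
             "context": "CG", "level": [0.5, 0.5, 0.5], "n_sites": 5}
        )
        fpkm = pd.Series([1.0, 10.0, 100.0], index=["a", "b", "c"])
        out = methylation.methylation_expression_association(levels, fpkm)
        assert np.isnan(out["r"].iloc[0]) and out["reason"].iloc[0] != ""

    def test_planted_anticorrelation_recovered(self):
        cfg = simulate.MethylomeSimConfig(
            seed=9, n_genes=1000, genome_length=4_000_000, expression_corr=-0.5
        )
        genes, calls, expr, _truth = simulate.simulate_methylome(cfg)
        tbl = methylation.region_methylation_table(calls, genes, context=None)
        body = tbl[tbl.region == "gene_body"]
        fpkm = expr.values.mean(axis=1)
        out = methylation.methylation_expression_association(body, fpkm)
        r = out["r"].iloc[0]
        se = (1 - 0.5**2) / np.sqrt(1000)
        assert abs(r - (-0.5)) < 3 * se
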