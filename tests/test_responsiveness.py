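import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from tissueresp.errors import (
    FilterDomainError,
    IncompleteDesignError,
    InvalidTableError,
)
from tissueresp.io import round_half_away
from tissueresp.quantify import quantify_samples
from tissueresp.responsiveness import (
    FilterConfig,
    SRTable,
    build_sr_table,
    classify_twofold,
    filter_genes,
    fisher_tissue_comparison,
    multi_tissue_responders,
    rank_top_n,
    space_responsiveness,
    tissue_specific_responders,
    total_space_responsiveness,
)

from .conftest import make_model, make_sample
from .reference_values import (
    FOCAL_TISSUE_SR_ROWS,
    MULTI_TISSUE_SR_ROWS,
    OVARY_RPKM_ROWS,
)

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


def srtable_from(rows, tissues=("t1", "t2", "t3", "t4", "t5", "t6")):
    sr = pd.DataFrame(
        {g: list(v) for g, v in rows}, index=list(tissues[: len(rows[0][1])])
    ).T
    sr.index.name = "gene_id"
    return SRTable(sr=sr)


class TestSpaceResponsiveness:
    def test_reference_pair(self):
        assert round_half_away(space_responsiveness(2.61, 7.42)) == -1.51

    def test_identity(self):
        for x in (0.01, 1.0, 523.7):
            assert space_responsiveness(x, x) == 0.0

    def test_reference_pair_near_zero(self):
        assert round_half_away(space_responsiveness(710.87, 678.32)) == 0.07

    def test_nonpositive_raises(self):
        with pytest.raises(FilterDomainError):
            space_responsiveness(0.0, 1.0)
        with pytest.raises(FilterDomainError):
            space_responsiveness(1.0, -2.0)

    @given(a=positive, b=positive)
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry(self, a, b):
        assert space_responsiveness(a, b) == pytest.approx(
            -space_responsiveness(b, a), abs=1e-9
        )

    @pytest.mark.parametrize("label,gc,sf,expected", OVARY_RPKM_ROWS)
    def test_all_reference_rows(self, label, gc, sf, expected):
        assert round_half_away(space_responsiveness(sf, gc)) == expected


class TestTotalSpaceResponsiveness:
    def test_reference_vectors(self):
        assert round_half_away(
            total_space_responsiveness((2.69, 2.72, 0.59, 0.40, 4.48, 4.34))
        ) == 7.35
        assert round_half_away(
            total_space_responsiveness((2.06, 2.14, -0.16, -0.34, 2.57, 1.47))
        ) == 4.21

    def test_zero_vector(self):
        assert total_space_responsiveness([0.0] * 6) == 0.0

    def test_missing_values_raise(self):
        with pytest.raises(ValueError):
            total_space_responsiveness([1.0, float("nan")])

    @given(
        st.lists(st.floats(-20, 20, allow_nan=False), min_size=1, max_size=8)
    )
    @settings(max_examples=200, deadline=None)
    def test_norm_bounds(self, v):
        norm = total_space_responsiveness(v)
        biggest = max(abs(x) for x in v)
        assert norm >= biggest - 1e-9
        assert norm <= math.sqrt(len(v)) * biggest + 1e-9

    @pytest.mark.parametrize("gene,vec,printed", MULTI_TISSUE_SR_ROWS)
    def test_multi_tissue_reference_norms(self, gene, vec, printed):
        # printed SR inputs are rounded, so allow +-0.02 on the norm
        assert total_space_responsiveness(vec) == pytest.approx(
            printed, abs=0.02
        )

    @pytest.mark.parametrize("gene,vec,printed", FOCAL_TISSUE_SR_ROWS)
    def test_focal_reference_norms(self, gene, vec, printed):
        assert total_space_responsiveness(vec) == pytest.approx(
            printed, abs=0.02
        )


def _expr_two_tissues(rng, n_genes=200):
    models = {
        f"g{i:03d}": make_model(f"g{i:03d}", [(1, int(rng.integers(300, 4000)))])
        for i in range(n_genes)
    }
    samples = []
    for tissue in ("brain", "liver"):
        for cond in ("SF", "GC"):
            counts = {g: int(rng.integers(0, 400)) for g in models}
            samples.append(make_sample(tissue, cond, counts, total=2_000_000))
    return quantify_samples(models, samples)


class TestFilterGenes:
    def _mini_expr(self, rpkm_gc=5.0):
        # one gene, one tissue; choose counts so RPKM is exactly controllable
        models = {"g1": make_model("g1", [(1, 1000)])}  # 1 kb
        total = 1_000_000  # rpkm == count
        samples = [
            make_sample("liver", "SF", {"g1": 10}, total=total),
            make_sample("liver", "GC", {"g1": int(rpkm_gc * 1)}, total=total),
        ]
        return quantify_samples(models, samples)

    def test_gc_rpkm_below_threshold_excluded(self):
        models = {"g1": make_model("g1", [(1, 10000)])}  # 10 kb
        total = 1_000_000
        samples = [
            make_sample("liver", "SF", {"g1": 100}, total=total),  # rpkm 10
            make_sample("liver", "GC", {"g1": 9}, total=total),  # rpkm 0.9
        ]
        expr = quantify_samples(models, samples)
        cfg = FilterConfig(scope="per-tissue")
        assert filter_genes(expr, cfg, tissue="liver") == set()

    def test_inclusive_boundary(self):
        models = {"g1": make_model("g1", [(1, 5000)])}  # 5 kb
        total = 1_000_000
        # 5 reads on 5 kb at 1e6 depth -> rpkm exactly 1.0, reads exactly 5
        samples = [
            make_sample("liver", "SF", {"g1": 5}, total=total),
            make_sample("liver", "GC", {"g1": 5}, total=total),
        ]
        expr = quantify_samples(models, samples)
        cfg = FilterConfig(scope="per-tissue")
        assert filter_genes(expr, cfg, tissue="liver") == {"g1"}

    def test_brute_force_predicate_oracle(self, rng):
        expr = _expr_two_tissues(rng)
        cfg = FilterConfig(min_rpkm=1.0, min_reads=5, scope="all-tissues")
        got = filter_genes(expr, cfg)
        expected = set()
        for g in expr.genes:
            ok = True
            for tissue in ("brain", "liver"):
                for cond in ("SF", "GC"):
                    col = f"{tissue}_{cond}"
                    if not (
                        expr.rpkm.at[g, col] >= cfg.min_rpkm
                        and expr.counts.at[g, col] >= cfg.min_reads
                    ):
                        ok = False
            if ok:
                expected.add(g)
        assert got == expected

    def test_per_tissue_requires_tissue(self, rng):
        expr = _expr_two_tissues(rng, n_genes=5)
        with pytest.raises(IncompleteDesignError):
            filter_genes(expr, FilterConfig(scope="per-tissue"))

    def test_missing_sample_raises(self):
        models = {"g1": make_model("g1", [(1, 1000)])}
        expr = quantify_samples(
            models, [make_sample("liver", "SF", {"g1": 10})]
        )
        with pytest.raises(IncompleteDesignError):
            filter_genes(expr, FilterConfig(scope="per-tissue"),
                         tissue="liver")

    def test_monotone_in_thresholds(self, rng):
        expr = _expr_two_tissues(rng)
        base = filter_genes(expr, FilterConfig(1.0, 5))
        for min_rpkm, min_reads in [(2.0, 5), (1.0, 20), (4.0, 50)]:
            stricter = filter_genes(expr, FilterConfig(min_rpkm, min_reads))
            assert stricter <= base


class TestClassifyTwofold:
    @pytest.mark.parametrize(
        "sr,expected",
        [(1.0, "up"), (0.99, "none"), (-1.31, "down"), (-0.5, "none"),
         (3.2, "up"), (-1.0, "down"), (0.0, "none")],
    )
    def test_cases(self, sr, expected):
        assert classify_twofold(sr) == expected

    @given(sf=positive, gc=positive)
    @settings(max_examples=200, deadline=None)
    def test_consistent_with_rpkm_ratio(self, sf, gc):
        # twofold-up <=> RPKM_SF >= 2 * RPKM_GC, up to float round-off
        call = classify_twofold(space_responsiveness(sf, gc))
        ratio = sf / gc
        if call == "up":
            assert ratio >= 2 * (1 - 1e-9)
        elif ratio >= 2 * (1 + 1e-9):
            pytest.fail("ratio >= 2 but not classified up")
        if call == "down":
            assert ratio <= 0.5 * (1 + 1e-9)
        elif ratio <= 0.5 * (1 - 1e-9):
            pytest.fail("ratio <= 1/2 but not classified down")


class TestMultiTissueResponders:
    def test_reference_up_gene_qualifies(self):
        srt = srtable_from([("klf9", (2.69, 2.72, 0.59, 0.40, 4.48, 4.34))])
        calls = multi_tissue_responders(srt)
        assert len(calls) == 1
        assert calls[0].direction == "up"
        assert len(calls[0].tissues) == 4

    def test_zero_vector_not_called(self):
        srt = srtable_from([("flat", (0.0,) * 6)])
        assert multi_tissue_responders(srt) == []

    def test_reference_down_gene(self):
        srt = srtable_from(
            [("keap1a", (-0.13, -0.41, -1.51, -1.52, -1.00, -1.11))]
        )
        calls = multi_tissue_responders(srt)
        assert len(calls) == 1
        assert calls[0].direction == "down"

    def test_mixed_direction(self):
        srt = srtable_from([("mix", (2.0, 2.0, -2.0, -2.0, 0.0, 0.0))])
        (call,) = multi_tissue_responders(srt)
        assert call.direction == "mixed"


class TestTissueSpecificResponders:
    def test_dominant_gene_called(self):
        srt = srtable_from(
            [("prdx1", (4.66, -0.15, 0.07, -0.42, -0.36, 0.53))],
            tissues=("intestine", "brain", "eye", "ovary", "testis", "liver"),
        )
        (call,) = tissue_specific_responders(srt, "intestine")
        assert call.direction == "up"

    def test_tied_maxima_not_called(self):
        srt = srtable_from([("tie", (3.0, 3.0, 0.0, 0.0, 0.0, 0.0))])
        assert tissue_specific_responders(srt, "t1") == []

    def test_down_gene_with_secondary_signal(self):
        # dominant -5.83 vs second-largest -2.12: ratio 2.75 >= 2
        srt = srtable_from(
            [("cdo1", (-5.83, 0.14, 0.72, -2.12, -0.21, -0.67))],
            tissues=("intestine", "brain", "eye", "ovary", "testis", "liver"),
        )
        (call,) = tissue_specific_responders(srt, "intestine")
        assert call.direction == "down"

    def test_dominance_just_under_ratio_rejected(self):
        srt = srtable_from([("g", (3.9, 2.0, 0.0, 0.0, 0.0, 0.0))])
        assert tissue_specific_responders(srt, "t1") == []

    def test_unknown_tissue(self):
        srt = srtable_from([("g", (1.0,) * 6)])
        with pytest.raises(KeyError):
            tissue_specific_responders(srt, "kidney")


class TestRankTopN:
    def test_full_permutation(self):
        srt = srtable_from([("a", (1.0,) * 6), ("b", (2.0,) * 6)])
        assert set(rank_top_n(srt, n=2)) == {"a", "b"}

    def test_top_one(self):
        srt = srtable_from([("lo", (1.0,) * 6), ("hi", (5.0,) * 6)])
        assert rank_top_n(srt, n=1) == ["hi"]

    def test_n_too_large(self):
        srt = srtable_from([("a", (1.0,) * 6)])
        with pytest.raises(ValueError):
            rank_top_n(srt, n=2)

    def test_matches_sort_then_slice_oracle(self, rng):
        rows = [
            (f"g{i:04d}", tuple(rng.normal(0, 2, 6))) for i in range(1000)
        ]
        srt = srtable_from(rows)
        got = rank_top_n(srt, n=400)
        oracle = [
            g
            for g, _ in sorted(
                ((g, float(np.linalg.norm(v))) for g, v in rows),
                key=lambda t: (-t[1], t[0]),
            )
        ][:400]
        assert got == oracle


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            comb(col1, x, exact=True)
            * comb(n - col1, row1 - x, exact=True)
            / comb(n, row1, exact=True)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


class TestFisherTissueComparison:
    def test_reference_counts_below_bound(self):
        assert fisher_tissue_comparison(91, 13528, 2279, 9905) < 1e-4

    def test_equal_proportions(self):
        assert fisher_tissue_comparison(5, 50, 10, 100) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        a, ta, b, tb = 1, 10, 9, 10
        got = fisher_tissue_comparison(a, ta, b, tb)
        assert got == pytest.approx(
            fisher_enumeration_oracle(a, ta - a, b, tb - b), rel=1e-9
        )

    def test_random_tables_match_oracle(self, rng):
        for _ in range(30):
            ta, tb = int(rng.integers(1, 25)), int(rng.integers(1, 25))
            a, b = int(rng.integers(0, ta + 1)), int(rng.integers(0, tb + 1))
            got = fisher_tissue_comparison(a, ta, b, tb)
            want = fisher_enumeration_oracle(a, ta - a, b, tb - b)
            assert got == pytest.approx(want, rel=1e-8)

    def test_row_swap_symmetry(self, rng):
        for _ in range(20):
            ta, tb = int(rng.integers(1, 200)), int(rng.integers(1, 200))
            a, b = int(rng.integers(0, ta + 1)), int(rng.integers(0, tb + 1))
            assert fisher_tissue_comparison(a, ta, b, tb) == pytest.approx(
                fisher_tissue_comparison(b, tb, a, ta)
            )

    def test_invalid_counts(self):
        with pytest.raises(InvalidTableError):
            fisher_tissue_comparison(-1, 10, 0, 10)
        with pytest.raises(InvalidTableError):
            fisher_tissue_comparison(11, 10, 0, 10)


class TestBuildSrTable:
    def test_norm_invariant(self, rng):
        expr = _expr_two_tissues(rng)
        kept = filter_genes(expr, FilterConfig())
        srt = build_sr_table(expr, kept)
        norms = np.linalg.norm(srt.sr.to_numpy(), axis=1)
        assert np.allclose(srt.tsr.to_numpy(), norms)

    def test_unfiltered_zero_rpkm_raises(self):
        models = {"g1": make_model("g1", [(1, 1000)])}
        samples = [
            make_sample("liver", "SF", {"g1": 0}),
            make_sample("liver", "GC", {"g1": 10}),
        ]
        expr = quantify_samples(models, samples)
        with pytest.raises(FilterDomainError):
            build_sr_table(expr, {"g1"})
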