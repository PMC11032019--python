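from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from _oracles import binom_lower_exact, binom_upper_exact, hypergeom_upper_exact
from conftest import make_table
from omeconcord.enrichment import (
    TissueSdeContext,
    binom_lower,
    binom_upper,
    directionality,
    enrich_tissue,
    hypergeom_upper,
    joint_enrichment,
    run_enrichment,
    same_direction,
)
from omeconcord.io_model import EnrichmentConfig, FeatureUniverse


class TestHypergeomUpper:
    def test_whole_support(self):
        assert hypergeom_upper(0, 5, 4, 10) == 1.0

    def test_enumeration_4_of_5_in_4_of_10(self):
        # C(10,4)=210 draws of 4 from 10 with 5 marked; 5 draws have all 4 marked
        assert hypergeom_upper(4, 5, 4, 10) == pytest.approx(5 / 210, abs=1e-12)

    def test_enumeration_3_of_5_in_4_of_20(self):
        assert hypergeom_upper(3, 5, 4, 20) == pytest.approx(155 / 4845, abs=1e-12)

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            hypergeom_upper(5, 4, 10, 20)
        with pytest.raises(ValueError):
            hypergeom_upper(1, 25, 4, 20)

    def test_strictly_decreasing_in_k(self):
        N, K, n = 50, 12, 15
        tails = [hypergeom_upper(k, K, n, N) for k in range(0, min(K, n) + 1)]
        assert all(a > b for a, b in zip(tails, tails[1:]))

    @settings(deadline=None, max_examples=60)
    @given(st.data())
    def test_matches_exact_enumeration(self, data):
        N = data.draw(st.integers(1, 20))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, min(N, 12)))
        k = data.draw(st.integers(0, min(K, n)))
        exact = float(hypergeom_upper_exact(k, K, n, N))
        assert hypergeom_upper(k, K, n, N) == pytest.approx(exact, abs=1e-12)


class TestDirectionality:
    def test_all_down(self):
        p, call = directionality(0, 10, 0.5)
        assert p == pytest.approx(1 / 1024, abs=1e-12)
        assert call == "down"

    def test_mostly_up(self):
        p, call = directionality(8, 10, 0.5)
        assert p == pytest.approx(1013 / 1024, abs=1e-12)
        assert call == "up"

    def test_cutoffs_act_on_p_pos(self):
        cfg = EnrichmentConfig()
        # p_pos just above 0.95 -> up call
        p, call = directionality(9, 10, 0.5, cfg)
        assert p > 0.95 and call == "up"
        p, call = directionality(5, 10, 0.5, cfg)
        assert call == "none"

    def test_strictly_increasing_in_k_up(self):
        vals = [directionality(k, 12, 0.3)[0] for k in range(13)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            directionality(1, 0, 0.5)
        with pytest.raises(ValueError):
            directionality(5, 4, 0.5)

    @settings(deadline=None, max_examples=60)
    @given(st.data())
    def test_tails_match_exact_rational(self, data):
        n = data.draw(st.integers(1, 12))
        k = data.draw(st.integers(0, n))
        pi = data.draw(st.sampled_from([Fraction(1, 2), Fraction(1, 3),
                                        Fraction(3, 4), Fraction(1, 10)]))
        assert binom_lower(k, n, float(pi)) == pytest.approx(
            float(binom_lower_exact(k, n, pi)), abs=1e-12)
        assert binom_upper(k, n, float(pi)) == pytest.approx(
            float(binom_upper_exact(k, n, pi)), abs=1e-12)


class TestEnrichTissue:
    def ctx(self, sde, directions, universe, **kw):
        return TissueSdeContext.from_sets("leaf", sde, directions, universe, **kw)

    def test_enrichment_p_from_enumeration(self, small_universe, cfg):
        term = sorted(small_universe.term_members("T1"))
        others = sorted(small_universe.features - set(term))
        sde = set(term[:3]) | {others[0]}
        stats = enrich_tissue(self.ctx(sde, {f: "up" for f in sde},
                                       small_universe), small_universe, cfg)
        assert stats["T1"].k == 3 and stats["T1"].n == 4
        assert stats["T1"].p == pytest.approx(155 / 4845, abs=1e-12)

    def test_min_term_size_skips(self, small_universe, cfg):
        others = sorted(small_universe.features - small_universe.term_members("T1"))
        sde = set(others[:4])
        stats = enrich_tissue(self.ctx(sde, {}, small_universe),
                              small_universe, cfg)
        assert "T1" not in stats
        cfg0 = EnrichmentConfig(min_term_size=0)
        # k=0 is reported with p=1 when the size gate is disabled
        hits = enrich_tissue(self.ctx(sde, {}, small_universe),
                             small_universe, cfg0)
        assert hits["T1"].p == 1.0

    def test_saturation(self, small_universe, cfg):
        sde = set(small_universe.features)
        stats = enrich_tissue(self.ctx(sde, {}, small_universe),
                              small_universe, cfg)
        assert stats["T1"].k == stats["T1"].K
        assert stats["T1"].p == 1.0

    def test_empty_sde_errors(self, small_universe, cfg):
        with pytest.raises(ValueError, match="no SDE features"):
            enrich_tissue(self.ctx(set(), {}, small_universe),
                          small_universe, cfg)

    def test_pi_estimated_from_background(self, small_universe):
        feats = sorted(small_universe.features)
        sde = set(feats[:4])
        directions = {feats[0]: "up", feats[1]: "up", feats[2]: "up",
                      feats[3]: "down"}
        ctx = self.ctx(sde, directions, small_universe)
        assert ctx.pi == pytest.approx(0.75)
        fixed = self.ctx(sde, directions, small_universe, pi_fixed=0.5)
        assert fixed.pi == 0.5


class TestJointEnrichment:
    def test_identical_sde_sets_reduce_to_single_tissue(self, small_universe, cfg):
        term = sorted(small_universe.term_members("T1"))
        others = sorted(small_universe.features - set(term))
        sde = set(term[:3]) | {others[0]}
        ctx_r = TissueSdeContext.from_sets("root", sde, {}, small_universe)
        ctx_l = TissueSdeContext.from_sets("leaf", sde, {}, small_universe)
        joint = joint_enrichment(ctx_r, ctx_l, small_universe, cfg)
        k_both, n_both, p_both = joint["T1"]
        assert (k_both, n_both) == (3, 4)
        assert p_both == pytest.approx(155 / 4845, abs=1e-12)

    def test_disjoint_sets_give_p_one(self, small_universe, cfg):
        feats = sorted(small_universe.features)
        ctx_r = TissueSdeContext.from_sets("root", set(feats[:3]), {},
                                           small_universe)
        ctx_l = TissueSdeContext.from_sets("leaf", set(feats[10:13]), {},
                                           small_universe)
        joint = joint_enrichment(ctx_r, ctx_l, small_universe, cfg)
        assert all(p == 1.0 for _, _, p in joint.values())

    def test_fisher_alternative(self, small_universe):
        cfg = EnrichmentConfig(p_both_method="fisher")
        term = sorted(small_universe.term_members("T1"))
        sde = set(term[:3])
        ctx_r = TissueSdeContext.from_sets("root", sde, {}, small_universe)
        ctx_l = TissueSdeContext.from_sets("leaf", sde, {}, small_universe)
        joint = joint_enrichment(ctx_r, ctx_l, small_universe, cfg)
        assert 0.0 < joint["T1"][2] < 1.0


class TestSameDirection:
    def test_both_up_product(self):
        p, call = same_direction((10, 10, 0.5), (10, 10, 0.5))
        assert call == "both-up"
        assert p == pytest.approx((2.0**-10) ** 2, rel=1e-9)

    def test_discordant_is_one(self):
        p, call = same_direction((10, 10, 0.5), (0, 10, 0.5))
        assert p == 1.0 and call == "none"

    def test_flip_symmetry(self):
        p_up, c_up = same_direction((9, 10, 0.5), (10, 10, 0.5))
        p_dn, c_dn = same_direction((1, 10, 0.5), (0, 10, 0.5))
        assert c_up == "both-up" and c_dn == "both-down"
        assert p_up == pytest.approx(p_dn, rel=1e-9)

    def test_undirected_tissue_gives_one(self):
        p, call = same_direction((0, 0, 0.5), (10, 10, 0.5))
        assert p == 1.0 and call == "none"


def two_tissue_tables(universe, term_members, n_term_hits, direction=1.0):
    feats = sorted(universe.features)
    term = sorted(term_members)
    tables = {}
    for tissue in ("leaf", "root"):
        sde = {f: direction for f in term[:n_term_hits]}
        tables[tissue] = make_table(sde, tissue, universe_features=feats)
    return tables


class TestRunEnrichment:
    def test_single_tissue_has_no_cross_block(self, small_universe, cfg):
        tables = two_tissue_tables(small_universe,
                                   small_universe.term_members("T1"), 3)
        res = run_enrichment({"leaf": tables["leaf"]}, small_universe, cfg)
        assert all(r.cross is None for r in res)
        assert any(r.tissue_stats["leaf"].p is not None for r in res)

    def test_planted_both_up_term_classified(self, small_universe):
        # pi is pinned at 0.5: the fixture's background is too small to
        # estimate it, which is exactly what --pi 0.5 is for
        cfg = EnrichmentConfig(pi_fixed=0.5)
        tables = two_tissue_tables(small_universe,
                                   small_universe.term_members("T1"), 5)
        res = run_enrichment(tables, small_universe, cfg)
        r = {x.term: x for x in res}["T1"]
        assert r.cross.concordant_call == "both-up"
        assert r.cross.p_both_adj < 0.05 and r.cross.p_same < 0.05

    def test_label_swap_symmetry(self, small_universe):
        cfg = EnrichmentConfig(pi_fixed=0.5)
        up = two_tissue_tables(small_universe,
                               small_universe.term_members("T1"), 5, 1.0)
        down = two_tissue_tables(small_universe,
                                 small_universe.term_members("T1"), 5, -1.0)
        res_up = {r.term: r for r in run_enrichment(up, small_universe, cfg)}
        res_dn = {r.term: r for r in run_enrichment(down, small_universe, cfg)}
        for term in res_up:
            u, d = res_up[term], res_dn[term]
            assert u.cross.p_both == pytest.approx(d.cross.p_both, abs=1e-12)
            assert u.tissue_stats["leaf"].p == pytest.approx(
                d.tissue_stats["leaf"].p, abs=1e-12)
            swap = {"both-up": "both-down", "both-down": "both-up"}
            assert d.cross.concordant_call == swap.get(
                u.cross.concordant_call, u.cross.concordant_call)
            tswap = {"up": "down", "down": "up", "none": "none"}
            assert d.tissue_stats["leaf"].call == tswap[u.tissue_stats["leaf"].call]

    def test_leaf_only_down_term(self):
        # a term enriched and down-called in the leaf only
        cfg = EnrichmentConfig(pi_fixed=0.5)
        features = [f"g{i}" for i in range(40)]
        universe = FeatureUniverse(
            features=frozenset(features),
            terms={"T1": ("t", frozenset(features[:6])),
                   "T2": ("t2", frozenset(features[20:30]))},
        )
        leaf_sde = {f: -1.0 for f in features[:5]}
        leaf_sde[features[30]] = 1.0
        root_sde = {features[35]: 1.0, features[36]: -1.0,
                    features[20]: 1.0, features[21]: 1.0}
        tables = {
            "leaf": make_table(leaf_sde, "leaf", universe_features=features),
            "root": make_table(root_sde, "root", universe_features=features),
        }
        res = {r.term: r for r in run_enrichment(tables, universe, cfg)}
        t1 = res["T1"]
        assert t1.tissue_stats["leaf"].p_adj < 0.05
        assert t1.tissue_stats["leaf"].call == "down"
        assert t1.cross.concordant_call == "none"
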