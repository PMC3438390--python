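"""STR association maps, profile decomposition, offspring fast typing."""

import numpy as np
import pytest

from mhckit.model import Diplotype
from mhckit.phasing import check_mendelian
from mhckit.strtyping import (
    build_str_maps,
    decompose_str_profile,
    fast_type_offspring,
)


def _sig_pair(pool, a, b):
    return tuple(sorted(
        (pool.get(a).a_signature(), pool.get(b).a_signature()),
        key=lambda s: sorted(s),
    ))


class TestBuildMaps:
    def test_haplotype_1_signature_maps_to_its_patterns(self, pool, str_maps):
        a_map, _ = str_maps
        sig = pool.get("1").a_signature()
        assert a_map.forward[sig] == (frozenset({177, 196}), frozenset({201}))

    def test_recombinants_share_a_signature_with_their_a_donor(self, pool, str_maps):
        a_map, _ = str_maps
        assert pool.get("3").a_signature() == pool.get("4").a_signature()
        assert pool.get("21").a_signature() == pool.get("22").a_signature()
        # 30 distinct A-block signatures among 32 haplotypes
        assert len(a_map.forward) == 30

    def test_known_pattern_collision_is_reported_not_fatal(self, pool, str_maps):
        # two haplotypes carry different A1 alleles but identical printed
        # patterns; the map must surface this rather than hide or crash
        a_map, _ = str_maps
        assert len(a_map.collisions) == 1
        s1, s2 = a_map.collisions[0]
        assert {s1, s2} == {
            pool.get("10").a_signature(), pool.get("12").a_signature(),
        }

    def test_conflicting_drb_lengths_reported_and_strict_raises(self, pool, str_maps):
        _, drb_map = str_maps
        assert "Mafa-DRB1*10:02" in drb_map.conflicts
        assert drb_map.certain["Mafa-DRB1*10:02"] == frozenset({204, 208, 218})
        with pytest.raises(ValueError, match="conflicting D6S2878"):
            build_str_maps(pool, strict=True)

    def test_unconflicted_allele_has_a_unique_length(self, str_maps):
        _, drb_map = str_maps
        assert drb_map.length_of("Mafa-DRB*W25:02") == 185

    def test_empty_pool_gives_empty_maps(self):
        from mhckit.model import HaplotypePool

        a_map, drb_map = build_str_maps(HaplotypePool([]))
        assert not a_map.forward and not drb_map.certain


class TestDecomposeProfile:
    def test_union_profile_recovers_generating_pair(self, pool, str_maps):
        a_map, _ = str_maps
        h1, h2 = pool.get("1"), pool.get("2")
        prof = {
            "D6S2854": h1.d6s2854.lengths | h2.d6s2854.lengths,
            "D6S2859": h1.d6s2859.lengths | h2.d6s2859.lengths,
        }
        res = decompose_str_profile(prof, a_map)
        assert not res.flagged
        assert _sig_pair(pool, "1", "2") in [tuple(c) for c in res.candidates]

    def test_homozygote_profile_returns_self_pair(self, pool, str_maps):
        a_map, _ = str_maps
        h = pool.get("21")
        res = decompose_str_profile(
            {"D6S2854": h.d6s2854.lengths, "D6S2859": h.d6s2859.lengths}, a_map
        )
        assert _sig_pair(pool, "21", "21") in [tuple(c) for c in res.candidates]

    def test_unmatchable_profile_is_flagged(self, str_maps):
        a_map, _ = str_maps
        res = decompose_str_profile(
            {"D6S2854": frozenset({999}), "D6S2859": frozenset({998})}, a_map
        )
        assert res.flagged and res.candidates == []

    def test_parental_constraint_restricts_candidates(self, pool, str_maps):
        a_map, _ = str_maps
        h1, h5 = pool.get("1"), pool.get("5")
        prof = {
            "D6S2854": h1.d6s2854.lengths | h5.d6s2854.lengths,
            "D6S2859": h1.d6s2859.lengths | h5.d6s2859.lengths,
        }
        free = decompose_str_profile(prof, a_map)
        constrained = decompose_str_profile(
            prof, a_map,
            parental_constraint=(Diplotype(("1", "2")), Diplotype(("5", "9"))),
            pool=pool,
        )
        assert set(map(tuple, constrained.candidates)) <= set(
            map(tuple, free.candidates)
        )
        assert [tuple(c) for c in constrained.candidates] == [
            _sig_pair(pool, "1", "5")
        ]

    def test_generation_then_decomposition_recovers_pair_in_seeded_draws(
        self, pool, str_maps
    ):
        a_map, _ = str_maps
        rng = np.random.default_rng(23)
        ids = pool.ids
        for _ in range(200):
            a, b = rng.choice(ids, size=2)
            ha, hb = pool.get(a), pool.get(b)
            prof = {}
            if ha.d6s2854.lengths is not None and hb.d6s2854.lengths is not None:
                prof["D6S2854"] = ha.d6s2854.lengths | hb.d6s2854.lengths
            if ha.d6s2859.lengths is not None and hb.d6s2859.lengths is not None:
                prof["D6S2859"] = ha.d6s2859.lengths | hb.d6s2859.lengths
            if not prof:
                continue
            res = decompose_str_profile(prof, a_map)
            assert _sig_pair(pool, a, b) in [tuple(c) for c in res.candidates]


class TestFastTyping:
    def _profile_for(self, pool, a, b):
        ha, hb = pool.get(a), pool.get(b)
        prof = {
            "D6S2854": (ha.d6s2854.lengths or frozenset())
            | (hb.d6s2854.lengths or frozenset()),
            "D6S2859": (ha.d6s2859.lengths or frozenset())
            | (hb.d6s2859.lengths or frozenset()),
        }
        drb = ha.d6s2878_certain() | hb.d6s2878_certain()
        return prof, drb

    def test_child_profile_yields_the_generating_call(self, pool):
        prof, drb = self._profile_for(pool, "1", "5")
        res = fast_type_offspring(
            prof, drb, Diplotype(("1", "2")), Diplotype(("5", "9")), pool
        )
        assert res.status == "call"
        assert res.call == Diplotype(("1", "5"))

    def test_recombinant_child_raises_the_crossover_flag(self, pool):
        from mhckit.regions import Interval
        from mhckit.simulate import make_chimera

        chim = make_chimera(pool.get("21"), pool.get("26"), Interval.A_B, "rec")
        other = pool.get("3")
        prof = {
            "D6S2854": chim.d6s2854.lengths | other.d6s2854.lengths,
            "D6S2859": chim.d6s2859.lengths | other.d6s2859.lengths,
        }
        drb = chim.d6s2878_certain() | other.d6s2878_certain()
        res = fast_type_offspring(
            prof, drb, Diplotype(("21", "5")), Diplotype(("26", "3")), pool
        )
        assert res.status == "crossover-flag"
        assert res.candidates == ()

    def test_profile_without_any_markers_is_fully_ambiguous(self, pool):
        res = fast_type_offspring(
            {}, None, Diplotype(("21", "5")), Diplotype(("26", "3")), pool
        )
        assert res.status == "ambiguous"
        assert len(res.candidates) == 4

    def test_missing_a_markers_fall_back_to_d6s2878_alone(self, pool):
        drb = pool.get("21").d6s2878_certain() | pool.get("3").d6s2878_certain()
        res = fast_type_offspring(
            {}, drb, Diplotype(("21", "5")), Diplotype(("26", "3")), pool
        )
        surviving = set(res.candidates)
        # must equal the transmissible pairs consistent with D6S2878 alone
        expected = set()
        for s in ("21", "5"):
            for d in ("26", "3"):
                cand = Diplotype((s, d))
                pred = pool.get(s).d6s2878_certain() | pool.get(d).d6s2878_certain()
                if pred == drb:
                    expected.add(cand)
        assert surviving == expected

    def test_unphased_parent_is_a_hard_error_naming_the_parent(self, pool):
        with pytest.raises(ValueError, match="dam"):
            fast_type_offspring({}, None, Diplotype(("1", "2")), None, pool)

    def test_calls_are_always_mendelian_consistent(self, pool):
        rng = np.random.default_rng(31)
        ids = pool.ids
        for _ in range(50):
            sire = Diplotype(tuple(rng.choice(ids, size=2)))
            dam = Diplotype(tuple(rng.choice(ids, size=2)))
            a = sire.pair[int(rng.integers(2))]
            b = dam.pair[int(rng.integers(2))]
            prof, drb = self._profile_for(pool, a, b)
            res = fast_type_offspring(prof, drb, sire, dam, pool)
            assert res.status in ("call", "ambiguous")
            for cand in res.candidates:
                assert check_mendelian(cand, sire, dam, pool).consistent

    def test_tolerance_absorbs_one_bp_drift(self, pool):
        ha, hb = pool.get("1"), pool.get("5")
        prof = {
            "D6S2854": frozenset(
                x + 1 for x in ha.d6s2854.lengths | hb.d6s2854.lengths
            ),
            "D6S2859": ha.d6s2859.lengths | hb.d6s2859.lengths,
        }
        drb = ha.d6s2878_certain() | hb.d6s2878_certain()
        strict = fast_type_offspring(
            prof, drb, Diplotype(("1", "2")), Diplotype(("5", "9")), pool
        )
        loose = fast_type_offspring(
            prof, drb, Diplotype(("1", "2")), Diplotype(("5", "9")), pool,
            tolerance=1,
        )
        assert strict.status == "crossover-flag"
        assert loose.status == "call" and loose.call == Diplotype(("1", "5"))
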