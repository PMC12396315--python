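"""Screening tests: threshold arithmetic, brute-force equivalence,
permutation invariance, monotonicity, proxy assignment and pair building."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lingcontact.errors import InvalidInputError
from lingcontact.screen import (
    AncestryProfile,
    ScreenConfig,
    assign_source_proxies,
    build_contact_pairs,
    annotate_triplets,
    detect_admixed_candidates,
    passes_per_k,
    threshold_robustness,
)
from lingcontact.synthetic import AdmixtureEventSpec, simulate_q_profiles


def brute_force_passes(fractions, top2_min=0.70, minor_min=0.05):
    s = sorted(fractions, reverse=True)
    return (s[0] + s[1]) >= top2_min and s[1] >= minor_min


def random_q_tables(rng, n_pops, k_values, admix_frac=0.3):
    """Random simplex rows with a mix of concentrated and diffuse profiles."""
    tables = {}
    for k in k_values:
        conc = np.where(rng.random(n_pops) < admix_frac, 0.8, 12.0)
        raw = rng.gamma(np.repeat(conc[:, None], k, axis=1) / k, 1.0)
        raw /= raw.sum(axis=1, keepdims=True)
        tables[k] = pd.DataFrame(
            raw, index=[f"POP{i:03d}" for i in range(n_pops)],
            columns=[f"C{c}" for c in range(k)],
        )
    return tables


class TestPassesPerK:
    @pytest.mark.parametrize(
        "fractions,expected",
        [
            ((0.65, 0.30, 0.05), True),  # top2 = 0.95, minor 0.30
            ((0.50, 0.19, 0.17, 0.14), False),  # top2 = 0.69 < 0.70
            ((0.92, 0.04, 0.04), False),  # minor 0.04 < 0.05: noise
            ((0.65, 0.05, 0.30), True),  # order of columns is irrelevant
            ((0.35, 0.35, 0.30), True),
        ],
    )
    def test_threshold_arithmetic(self, fractions, expected):
        prof = AncestryProfile("X", len(fractions), fractions)
        ok, major, minor = passes_per_k(prof, ScreenConfig())
        assert ok is expected
        fr = np.asarray(fractions)
        assert fr[major] >= fr[minor]

    def test_tie_broken_by_lowest_index(self):
        prof = AncestryProfile("X", 3, (0.4, 0.4, 0.2))
        _, major, minor = passes_per_k(prof, ScreenConfig())
        assert (major, minor) == (0, 1)

    def test_invalid_simplex_rejected(self):
        with pytest.raises(InvalidInputError):
            AncestryProfile("X", 3, (0.5, 0.2, 0.2))


class TestDetect:
    def test_boundary_five_vs_four_k_levels(self):
        for n_support, expected in [(5, 1), (4, 0)]:
            ev = AdmixtureEventSpec(
                "POP000", "POP001", "POP002", alpha=0.3,
                k_support=frozenset(range(12, 12 + n_support)),
            )
            q_tables, _ = simulate_q_profiles(8, set(range(12, 31)), [ev], seed=1)
            cands = detect_admixed_candidates(q_tables, ScreenConfig())
            assert len(cands) == expected

    def test_brute_force_equivalence_random_tables(self):
        rng = np.random.default_rng(7)
        for rep in range(5):
            q_tables = random_q_tables(rng, 30, range(12, 31))
            cfg = ScreenConfig()
            got = {pop: ks for pop, ks in detect_admixed_candidates(q_tables, cfg)}
            want = {}
            for pop in q_tables[12].index:
                ks = {
                    k for k, q in q_tables.items()
                    if brute_force_passes(q.loc[pop].to_numpy())
                }
                if len(ks) >= 5:
                    want[pop] = frozenset(ks)
            assert got == want

    def test_component_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        q_tables = random_q_tables(rng, 25, range(12, 31))
        shuffled = {
            k: q.iloc[:, rng.permutation(q.shape[1])].set_axis(q.columns, axis=1)
            for k, q in q_tables.items()
        }
        a = detect_admixed_candidates(q_tables, ScreenConfig())
        b = detect_admixed_candidates(shuffled, ScreenConfig())
        assert {(p, ks) for p, ks in a} == {(p, ks) for p, ks in b}

    @settings(max_examples=20, deadline=None)
    @given(
        top2=st.floats(0.70, 0.95),
        minor=st.floats(0.05, 0.2),
        min_k=st.integers(5, 10),
    )
    def test_monotonicity_in_thresholds(self, top2, minor, min_k):
        if not minor < top2:
            return
        rng = np.random.default_rng(99)
        q_tables = random_q_tables(rng, 20, range(12, 25))
        loose = {p for p, _ in detect_admixed_candidates(q_tables, ScreenConfig())}
        strict_cfg = ScreenConfig(top2_min=top2, minor_min=minor, min_k_levels=min_k)
        strict = {p for p, _ in detect_admixed_candidates(q_tables, strict_cfg)}
        assert strict <= loose

    def test_too_few_k_levels_rejected(self):
        rng = np.random.default_rng(3)
        q_tables = random_q_tables(rng, 5, range(12, 14))
        with pytest.raises(InvalidInputError):
            detect_admixed_candidates(q_tables, ScreenConfig())


class TestProxies:
    def test_planted_sources_recovered_at_every_supporting_k(self, planted_event):
        q_tables, _ = simulate_q_profiles(10, set(range(12, 31)), [planted_event], purity=0.9, seed=2)
        cands = detect_admixed_candidates(q_tables, ScreenConfig())
        triplets = assign_source_proxies(cands[0], q_tables, ScreenConfig())
        assert len(triplets) == 1
        t = triplets[0]
        assert {t.source1_pop, t.source2_pop} == {"POP001", "POP002"}
        assert t.n_k_admixed == len(planted_event.k_support)
        assert t.n_k_source1 == t.n_k_admixed
        assert t.n_k_source2 == t.n_k_admixed

    def test_low_purity_proxy_excluded(self, planted_event):
        q_tables, _ = simulate_q_profiles(10, set(range(12, 31)), [planted_event], purity=0.9, seed=2)
        cands = detect_admixed_candidates(q_tables, ScreenConfig())
        cfg = ScreenConfig(source_purity_min=0.95)  # above the generator's 0.9 floor
        strict = assign_source_proxies(cands[0], q_tables, cfg)
        loose = assign_source_proxies(cands[0], q_tables, ScreenConfig(source_purity_min=0.80))
        assert len(strict) <= len(loose)

    def test_interchangeable_proxies_yield_multiple_triplets(self):
        # two populations share the minor source's home component (index distance
        # is a multiple of each K in support? instead: same index mod K for all
        # supported K cannot happen for two distinct pops; use purity overlap)
        ev = AdmixtureEventSpec(
            "POP000", "POP001", "POP002", alpha=0.3, k_support=frozenset(range(12, 17)),
        )
        q_tables, _ = simulate_q_profiles(14, set(range(12, 31)), [ev], purity=0.9, seed=4)
        # make POP013 a second proxy for source1's component at each supporting K
        for k in ev.k_support:
            q = q_tables[k]
            comp = 1 % k
            row = np.zeros(q.shape[1])
            row[comp] = 0.92
            rest = (1 - 0.92) / (q.shape[1] - 1)
            row[np.arange(q.shape[1]) != comp] = rest
            q.loc["POP013"] = row
        cands = detect_admixed_candidates(q_tables, ScreenConfig())
        triplets = assign_source_proxies(cands[0], q_tables, ScreenConfig())
        # alpha=0.3 puts the minor share on source1's component, so the planted
        # and injected proxies both appear as source-2 candidates
        s2s = {t.source2_pop for t in triplets}
        assert s2s == {"POP001", "POP013"}
        assert {t.source1_pop for t in triplets} == {"POP002"}
        assert all(t.target_pop == "POP000" for t in triplets)


class TestContactPairs:
    def meta(self):
        return pd.DataFrame(
            {
                "population_id": ["T", "S1", "S2", "S3", "S4"],
                "language_glottocode": ["lt", "ls1", "ls2", "ls3", "ls4"],
                "family": ["X", "X", "Y", "Z", "Y"],
                "area_autotyp": ["Africa"] * 5,
                "area_glottolog": ["Africa"] * 5,
            }
        )

    def make_triplet(self, s1, s2):
        from lingcontact.screen import TripletCandidate

        return TripletCandidate("T", s1, s2, 6, 6, 6)

    def test_exactly_one_related_source_required(self):
        pairs = build_contact_pairs([self.make_triplet("S1", "S2")], self.meta())
        assert len(pairs) == 1
        assert pairs[0].target_language == "lt"
        assert pairs[0].source_clade_languages == ("ls2", "ls4")  # family Y clade
        assert build_contact_pairs([self.make_triplet("S2", "S3")], self.meta()) == []

    def test_pairs_sharing_source_collapse_under_broad_id(self):
        meta = pd.DataFrame(
            {
                "population_id": [f"T{i}" for i in range(7)] + ["SRC", "REL"],
                "language_glottocode": [f"lt{i}" for i in range(7)] + ["lsrc", "lrel"],
                "family": [f"F{i}" for i in range(7)] + ["SPA", "F0"],
                "area_autotyp": ["Africa"] * 9,
                "area_glottolog": ["Africa"] * 9,
            }
        )
        from lingcontact.screen import TripletCandidate

        triplets = []
        for i in range(7):
            meta.loc[meta.population_id == "REL", "family"] = f"F{i}"
            # related source per target: reuse REL with matching family is awkward;
            # instead give each target its own related source
        meta = pd.concat(
            [
                meta[meta.population_id != "REL"],
                pd.DataFrame(
                    {
                        "population_id": [f"R{i}" for i in range(7)],
                        "language_glottocode": [f"lr{i}" for i in range(7)],
                        "family": [f"F{i}" for i in range(7)],
                        "area_autotyp": ["Africa"] * 7,
                        "area_glottolog": ["Africa"] * 7,
                    }
                ),
            ],
            ignore_index=True,
        )
        triplets = [TripletCandidate(f"T{i}", f"R{i}", "SRC", 6, 6, 6) for i in range(7)]
        pairs = build_contact_pairs(triplets, meta)
        assert len(pairs) == 7
        assert len({p.broad_pair_id for p in pairs}) == 1
        assert len({p.pair_id for p in pairs}) == 7

    def test_target_equal_source_flagged_f3_impossible(self):
        from lingcontact.screen import TripletCandidate

        meta = self.meta()
        trip = TripletCandidate("T", "T", "S2", 6, 6, 6)  # related source is T itself
        pairs = build_contact_pairs([trip], meta)
        assert len(pairs) == 1 and not pairs[0].f3_impossible
        trip2 = TripletCandidate("T", "S1", "T", 6, 6, 6)
        # unrelated source == target: family X == X so not cross-family; craft one
        meta2 = meta.copy()
        meta2.loc[meta2.population_id == "T", "family"] = "Q"
        # now T's family Q; S1 (X) and T (Q): T is "related" to itself
        pairs2 = build_contact_pairs([TripletCandidate("T", "T", "S1", 6, 6, 6)], meta2)
        assert len(pairs2) == 1
        assert pairs2[0].f3_impossible is False or pairs2[0].f3_impossible is True  # flag present

    def test_missing_metadata_raises_naming_population(self):
        from lingcontact.screen import TripletCandidate

        with pytest.raises(InvalidInputError, match="S9"):
            build_contact_pairs([TripletCandidate("T", "S1", "S9", 6, 6, 6)], self.meta())

    def test_annotate_skips_unmapped_populations(self, planted_event):
        from lingcontact.screen import TripletCandidate

        meta = self.meta()
        kept = annotate_triplets(
            [TripletCandidate("T", "S1", "S2", 6, 6, 6), TripletCandidate("T", "S1", "S9", 6, 6, 6)],
            meta,
        )
        assert len(kept) == 1
        assert kept[0].target_language == "lt"


class TestRobustness:
    def test_constructed_half_retention(self):
        # half the candidates have top2 exactly 0.75: survive 0.70, fail 0.80
        pops = [f"POP{i:03d}" for i in range(8)]
        tables = {}
        for k in range(12, 20):
            rows = []
            for i in range(8):
                row = np.full(k, 0.0)
                if i < 4:
                    row[0], row[1] = 0.60, 0.30  # top2 = 0.90
                else:
                    row[0], row[1] = 0.50, 0.25  # top2 = 0.75
                row[2:] = (1 - row.sum()) / (k - 2)
                rows.append(row)
            tables[k] = pd.DataFrame(rows, index=pops, columns=[f"C{c}" for c in range(k)])
        out = threshold_robustness(tables, ScreenConfig(), alt_top2=(0.80,))
        assert out.loc[out.top2_min == 0.70, "retained"].iloc[0] == 1.0
        assert out.loc[out.top2_min == 0.80, "retained"].iloc[0] == 0.5

    def test_random_tables_match_brute_force(self):
        rng = np.random.default_rng(11)
        q_tables = random_q_tables(rng, 20, range(12, 25))
        out = threshold_robustness(q_tables, ScreenConfig(), alt_top2=(0.80, 0.90))
        base = {p for p, _ in detect_admixed_candidates(q_tables, ScreenConfig())}
        for alt in (0.80, 0.90):
            kept = {
                p for p, _ in detect_admixed_candidates(q_tables, ScreenConfig(top2_min=alt))
            }
            want = len(kept & base) / len(base) if base else float("nan")
            got = out.loc[out.top2_min == alt, "retained"].iloc[0]
            assert got == want or (np.isnan(got) and np.isnan(want))

    def test_alt_threshold_must_exceed_baseline(self):
        rng = np.random.default_rng(12)
        q_tables = random_q_tables(rng, 10, range(12, 20))
        with pytest.raises(InvalidInputError):
            threshold_robustness(q_tables, ScreenConfig(), alt_top2=(0.70,))
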