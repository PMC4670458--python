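"""Observed statistic, length-matched resampling null and empirical p-values."""

import numpy as np
import pytest

from seedenrich import (
    GeneSet,
    MatureMiRNA,
    NullSpec,
    SiteCandidateIndex,
    TargetEnrichment,
    UTRPool,
    UTRRecord,
    empirical_p,
    find_sites,
    null_distribution,
    observed_median_density,
    run_enrichment,
)
from seedenrich.sites import seed_match_patterns

from conftest import random_utr
from oracles import oracle_scan, resimulate_null

LET7 = MatureMiRNA("let-7a", "UGAGGUAGUAGGUUGUAUAGUU")
PAT8 = seed_match_patterns(LET7)[0]  # CTACCTCA


def utr_with_density(gene_id, sites_per_kb, length=1000, spacer="G"):
    """A UTR of the given length with exactly the requested 8mer count."""
    k = int(round(sites_per_kb * length / 1000))
    gap = (length - 8 * k) // k if k else length
    parts = []
    for _ in range(k):
        parts.append(PAT8)
        parts.append(spacer * gap)
    seq = "".join(parts)[:length].ljust(length, spacer)
    return UTRRecord(gene_id, seq)


class TestObservedMedian:
    def test_no_sites_zero(self):
        pool = UTRPool([UTRRecord("g1", "T" * 200), UTRRecord("g2", "T" * 300)])
        gs = GeneSet("s", ("g1", "g2"))
        assert observed_median_density(gs, pool, LET7) == 0.0

    def test_median_of_three_forced(self):
        pool = UTRPool([utr_with_density(f"g{i}", d) for i, d in
                        enumerate([1.0, 2.0, 3.0])])
        gs = GeneSet("s", ("g0", "g1", "g2"))
        assert observed_median_density(gs, pool, LET7) == 2.0

    def test_even_set_median_is_mean_of_central(self):
        pool = UTRPool([utr_with_density(f"g{i}", d) for i, d in
                        enumerate([1.0, 2.0, 3.0, 10.0])])
        gs = GeneSet("s", ("g0", "g1", "g2", "g3"))
        assert observed_median_density(gs, pool, LET7) == 2.5

    def test_matches_per_utr_oracle_then_median(self, rng):
        recs = [UTRRecord(f"g{i}", random_utr(rng, int(rng.integers(200, 3000))))
                for i in range(50)]
        pool = UTRPool(recs)
        gs = GeneSet("s", tuple(r.gene_id for r in recs))
        expected = np.median(
            [1000.0 * len(oracle_scan(r.sequence, LET7.sequence)) / r.length
             for r in recs]
        )
        assert observed_median_density(gs, pool, LET7) == pytest.approx(expected)

    def test_unresolvable_id_names_the_gene(self):
        pool = UTRPool([UTRRecord("g1", "ACGTACGT")])
        with pytest.raises(KeyError, match="ghost"):
            observed_median_density(GeneSet("s", ("ghost",)), pool, LET7)

    def test_monotone_in_added_sites(self, rng):
        """Appending extra sites to the set's UTRs never decreases M_obs."""
        recs = [UTRRecord(f"g{i}", random_utr(rng, 800)) for i in range(9)]
        pool = UTRPool(recs)
        gs = GeneSet("s", tuple(r.gene_id for r in recs))
        base = observed_median_density(gs, pool, LET7)
        # replace a 8+gap stretch with a planted 8mer in every UTR
        boosted = UTRPool(
            UTRRecord(r.gene_id, PAT8 + "GG" + r.sequence[10:]) for r in recs
        )
        assert observed_median_density(gs, boosted, LET7) >= base


class TestEmpiricalP:
    def test_direct_counting(self):
        null = list(range(1, 11))
        assert empirical_p(7.5, null) == (0.7, 0.3)

    def test_all_ties_count_to_neither_side(self):
        assert empirical_p(2.0, [2.0] * 10) == (0.0, 0.0)

    def test_below_all_null_is_exact_zero(self):
        assert empirical_p(0.0, [0.5, 1.0, 2.0])[0] == 0.0

    def test_sides_and_ties_partition(self, rng):
        null = rng.choice([0.0, 1.0, 2.0, 3.0], size=1000)
        m = 1.0
        pl, pr = empirical_p(m, null)
        ties = np.mean(null == m)
        assert pl + pr + ties == pytest.approx(1.0)

    def test_mid_p_splits_ties(self):
        pl, pr = empirical_p(2.0, [1.0, 2.0, 2.0, 3.0], tie_mode="mid")
        assert (pl, pr) == (0.5, 0.5)

    def test_empty_null_errors(self):
        with pytest.raises(ValueError):
            empirical_p(1.0, [])


class TestNullDistribution:
    def test_degenerate_background_forces_equality(self):
        """Background identical to the observed set with full-length windows:
        every null median equals M_obs."""
        obs = [utr_with_density("g1", 3.0, 500), utr_with_density("g2", 3.0, 500)]
        bg = [UTRRecord("b1", obs[0].sequence), UTRRecord("b2", obs[1].sequence)]
        pool = UTRPool(obs + bg)
        gs = GeneSet("s", ("g1", "g2"))
        m_obs = observed_median_density(gs, pool, LET7)
        spec = NullSpec(B=50, background_ids=("b1", "b2"), rng_seed=1)
        null = null_distribution([500, 500], spec, pool, LET7)
        assert np.all(null == m_obs)

    def test_seed_reproducibility(self, rng):
        recs = [UTRRecord(f"b{i}", random_utr(rng, int(rng.integers(300, 2000))))
                for i in range(20)]
        pool = UTRPool(recs)
        spec = NullSpec(B=5, background_ids=tuple(r.gene_id for r in recs),
                        rng_seed=42)
        a = null_distribution([200, 500], spec, pool, LET7)
        b = null_distribution([200, 500], spec, pool, LET7)
        assert np.array_equal(a, b)

    def test_tiny_instance_matches_resimulation_oracle(self, rng):
        """Independent re-implementation sharing the RNG protocol but
        counting sites via find_sites on extracted substrings."""
        recs = [UTRRecord(f"b{i}",
                          random_utr(rng, 400) + PAT8 + random_utr(rng, 400))
                for i in range(4)]
        pool = UTRPool(recs)
        bg_ids = tuple(r.gene_id for r in recs)
        lengths = [150, 333]
        spec = NullSpec(B=100, background_ids=bg_ids, rng_seed=7)
        got = null_distribution(lengths, spec, pool, LET7)

        def count(sub):
            return len(find_sites(UTRRecord("w", sub), LET7)) if len(sub) >= 7 else 0

        expected = resimulate_null(
            lengths, [(r.gene_id, r.sequence) for r in recs], seed=7, B=100,
            count_sites=count,
        )
        assert np.array_equal(got, expected)

    def test_unmatchable_length_errors_by_default(self):
        pool = UTRPool([UTRRecord("b1", "ACGT" * 25)])
        spec = NullSpec(B=3, background_ids=("b1",), rng_seed=0)
        with pytest.raises(ValueError, match="background"):
            null_distribution([500], spec, pool, LET7)

    def test_longest_fallback_substitutes_whole_utr_density(self):
        bg = utr_with_density("b1", 2.0, 1000)
        pool = UTRPool([bg])
        spec = NullSpec(B=10, background_ids=("b1",), rng_seed=0,
                        fallback="longest")
        null = null_distribution([5000], spec, pool, LET7)
        assert np.all(null == 2.0)

    def test_whole_utr_mode_uses_full_densities(self, rng):
        recs = [utr_with_density(f"b{i}", float(i % 4), 1000) for i in range(12)]
        pool = UTRPool(recs)
        spec = NullSpec(B=200, background_ids=tuple(r.gene_id for r in recs),
                        rng_seed=3, mode="whole-utr", nearest_k=12)
        null = null_distribution([1000], spec, pool, LET7)
        assert set(np.unique(null)) <= {0.0, 1.0, 2.0, 3.0}


class TestRunEnrichment:
    def make_inputs(self, rng):
        recs = [UTRRecord(f"g{i}", random_utr(rng, int(rng.integers(300, 1500))))
                for i in range(40)]
        pool = UTRPool(recs)
        ids = pool.gene_ids
        sets = [GeneSet("upregulated", tuple(ids[:5])),
                GeneSet("downregulated", tuple(ids[5:10]))]
        bg = tuple(ids[10:])
        mirnas = [LET7, MatureMiRNA("miR-x", "UACGUACGUACGUACGUACGUA")]
        return pool, sets, bg, mirnas

    def test_cardinality(self, rng):
        pool, sets, bg, mirnas = self.make_inputs(rng)
        spec = NullSpec(B=10, background_ids=bg, rng_seed=0, fallback="longest")
        results = run_enrichment(sets, mirnas, pool, spec)
        assert len(results) == 4
        assert {(r.mirna_name, r.set_label) for r in results} == {
            (m.name, s.label) for m in mirnas for s in sets
        }

    def test_background_set_overlap_rejected(self, rng):
        pool, sets, bg, mirnas = self.make_inputs(rng)
        bad_bg = bg + (sets[0].gene_ids[0],)
        spec = NullSpec(B=5, background_ids=bad_bg, rng_seed=0)
        with pytest.raises(ValueError, match="overlap"):
            run_enrichment(sets, mirnas, pool, spec)

    def test_adding_a_mirna_leaves_other_cells_unchanged(self, rng):
        """Per-cell RNG streams are derived from (seed, miRNA, set)."""
        pool, sets, bg, mirnas = self.make_inputs(rng)
        spec = NullSpec(B=20, background_ids=bg, rng_seed=5, fallback="longest")
        solo = run_enrichment(sets, [mirnas[0]], pool, spec)
        both = run_enrichment(sets, mirnas, pool, spec)
        for r_solo in solo:
            r_both = next(r for r in both
                          if (r.mirna_name, r.set_label)
                          == (r_solo.mirna_name, r_solo.set_label))
            assert np.array_equal(r_solo.null_medians, r_both.null_medians)
            assert r_solo.m_obs == r_both.m_obs

    def test_invariant_p_sum(self, rng):
        pool, sets, bg, mirnas = self.make_inputs(rng)
        spec = NullSpec(B=50, background_ids=bg, rng_seed=9, fallback="longest")
        for r in run_enrichment(sets, mirnas, pool, spec):
            ties = np.mean(r.null_medians == r.m_obs)
            assert r.p_left + r.p_right + ties == pytest.approx(1.0)
            assert r.p_left + r.p_right <= 1.0 + 1e-12


class TestModelInterface:
    def test_fit_summary_and_lookup(self, rng):
        recs = [UTRRecord(f"g{i}", random_utr(rng, 600)) for i in range(30)]
        pool = UTRPool(recs)
        ids = pool.gene_ids
        model = TargetEnrichment(
            pool, [LET7],
            [GeneSet("upregulated", tuple(ids[:4]))],
            background_ids=tuple(ids[4:]),
            B=25, fallback="longest",
        )
        res = model.fit(seed=3)
        assert res.table.shape[0] == 1
        r = res.result_for("let-7a", "upregulated")
        assert r.B == 25
        text = res.summary()
        assert "M_obs" in text and "let-7a" in text

    def test_from_diffexp_builds_sets_and_background(self, rng):
        import pandas as pd

        recs = [UTRRecord(f"g{i}", random_utr(rng, 600)) for i in range(12)]
        pool = UTRPool(recs)
        calls = ["up"] * 3 + ["down"] * 3 + ["non_de"] * 6
        de = pd.DataFrame({"call": calls}, index=[f"g{i}" for i in range(12)])
        model = TargetEnrichment.from_diffexp(de, pool, [LET7], B=5)
        assert {s.label for s in model.gene_sets} == {"upregulated",
                                                      "downregulated"}
        assert len(model.background_ids) == 6
        set_ids = {g for s in model.gene_sets for g in s.gene_ids}
        assert set_ids.isdisjoint(model.background_ids)
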