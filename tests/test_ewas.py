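import numpy as np
import pytest
from scipy import stats

from mammclock.datamodel import EWASRow, ProbeAnnotation, ValidationError
from mammclock.ewas import (
    concordance,
    context_summary,
    correlation_screen,
    interaction_screen,
    meta_screen,
    select_top,
    sex_screen,
    stouffer_meta,
)

from conftest import make_beta, make_samples


def row(pid, p, z, r=None, n=50, t=0.0):
    return EWASRow(pid, r if r is not None else np.sign(z) * 0.5, n, t, p, z)


class TestCorrelationScreen:
    def test_probe_equal_to_trait_is_perfect_hit(self):
        trait = np.linspace(0.1, 0.9, 20)
        vals = np.vstack([trait, np.full(20, 0.5)])
        rows = correlation_screen(make_beta(vals), trait)
        assert rows[0].r == pytest.approx(1.0)
        assert rows[0].p < 1e-20
        assert rows[0].z > 0

    def test_statistics_match_scipy_pearsonr(self):
        rng = np.random.default_rng(0)
        n = 25
        trait = rng.uniform(0, 60, n)
        vals = rng.uniform(0.1, 0.9, size=(10, n))
        rows = correlation_screen(make_beta(vals), trait)
        for j, r in enumerate(rows):
            ref_r, ref_p = stats.pearsonr(vals[j], trait)
            assert r.r == pytest.approx(ref_r, abs=1e-12)
            assert r.p == pytest.approx(ref_p, rel=1e-9)
            assert r.n == n

    def test_t_and_p_formulas_at_known_r(self):
        # r = 0.5, n = 20 -> t = 0.5*sqrt(18)/sqrt(0.75) ~ 2.449,
        # two-sided p = 2*P(T_18 > t) ~ 0.0248
        t = 0.5 * np.sqrt(18) / np.sqrt(1 - 0.25)
        p = 2 * stats.t.sf(t, 18)
        assert t == pytest.approx(2.449, abs=1e-3)
        assert p == pytest.approx(0.02477, abs=1e-4)

    def test_zero_variance_probe_flagged(self):
        trait = np.linspace(1, 10, 10)
        vals = np.vstack([np.full(10, 0.4), np.linspace(0.1, 0.9, 10)])
        rows = correlation_screen(make_beta(vals), trait)
        assert np.isnan(rows[0].r) and rows[0].p == 1.0 and rows[0].z == 0.0
        assert rows[1].p < 0.05

    def test_sign_of_z_matches_sign_of_r(self):
        rng = np.random.default_rng(1)
        trait = rng.uniform(0, 50, 30)
        vals = rng.uniform(0.05, 0.95, size=(50, 30))
        for r in correlation_screen(make_beta(vals), trait):
            if r.r != 0 and not np.isnan(r.r):
                assert np.sign(r.z) == np.sign(r.r)

    def test_z_p_consistency(self):
        rng = np.random.default_rng(2)
        trait = rng.uniform(0, 50, 40)
        vals = rng.uniform(0.05, 0.95, size=(100, 40))
        for r in correlation_screen(make_beta(vals), trait):
            if abs(r.z) < 6:
                p_back = 2 * stats.norm.sf(abs(r.z))
                assert p_back == pytest.approx(r.p, abs=1e-6)

    def test_pairwise_complete_missing_values(self):
        trait = np.linspace(1, 12, 12)
        vals = np.vstack([np.linspace(0.1, 0.9, 12), np.linspace(0.1, 0.9, 12)])
        vals[0, :3] = np.nan
        rows = correlation_screen(make_beta(vals), trait)
        assert rows[0].n == 9 and rows[1].n == 12
        assert rows[0].r == pytest.approx(1.0)

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            correlation_screen(make_beta([[0.1, 0.2]]), np.array([1.0, 2.0]))

    def test_matches_small_permutation_oracle(self):
        rng = np.random.default_rng(3)
        n = 30
        trait = rng.uniform(0, 50, n)
        vals = rng.uniform(0.2, 0.8, size=(5, n))
        rows = correlation_screen(make_beta(vals), trait)
        n_perm = 20000
        for j, r in enumerate(rows):
            obs = abs(np.corrcoef(vals[j], trait)[0, 1])
            perm_r = np.empty(n_perm)
            for b in range(n_perm):
                perm_r[b] = np.corrcoef(vals[j], rng.permutation(trait))[0, 1]
            p_emp = (1 + np.sum(np.abs(perm_r) >= obs)) / (n_perm + 1)
            se = np.sqrt(max(r.p * (1 - r.p), 1e-6) / n_perm)
            assert abs(p_emp - r.p) < 4 * se + 2 / n_perm


class TestStouffer:
    def test_single_cohort_identity(self):
        m = stouffer_meta([("a", 2.5, 40)])
        assert m.z_meta == pytest.approx(2.5)

    def test_equal_cohorts_scale_by_sqrt2(self):
        m = stouffer_meta([("a", 2.0, 50), ("b", 2.0, 50)])
        assert m.z_meta == pytest.approx(2.0 * np.sqrt(2))

    def test_worked_example(self):
        # z = (2, -1), n = (100, 25): (10*2 - 5*1)/sqrt(125)
        m = stouffer_meta([("a", 2.0, 100), ("b", -1.0, 25)])
        assert m.z_meta == pytest.approx(15 / np.sqrt(125), abs=1e-10)
        assert m.z_meta == pytest.approx(1.3416, abs=1e-4)

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValidationError):
            stouffer_meta([("a", 1.0, 0)])

    def test_unweighted_option(self):
        m = stouffer_meta([("a", 3.0, 10), ("b", 0.0, 1000)], weighted=False)
        assert m.z_meta == pytest.approx(3.0 / np.sqrt(2))

    def test_meta_screen_intersects_probes(self):
        rows_a = [row("p1", 0.5, 1.0), row("p2", 0.5, 2.0)]
        rows_b = [row("p2", 0.5, 2.0), row("p3", 0.5, 1.0)]
        metas = meta_screen({"a": rows_a, "b": rows_b})
        assert [m.probe_id for m in metas] == ["p2"]
        assert metas[0].z_meta == pytest.approx(2 * np.sqrt(2))


class TestSelectTop:
    def brute_force(self, rows, thr, cap):
        pos = sorted(
            [r for r in rows if r.p < thr and r.z > 0],
            key=lambda r: (-abs(r.z), r.probe_id),
        )[:cap]
        neg = sorted(
            [r for r in rows if r.p < thr and r.z < 0],
            key=lambda r: (-abs(r.z), r.probe_id),
        )[:cap]
        return pos, neg

    def test_spec_example(self):
        rows = [
            row("a", 1e-6, 3.0),
            row("b", 1e-4, 2.0),
            row("c", 1e-7, -4.0),
        ]
        pos, neg = select_top(rows)
        assert [r.probe_id for r in pos] == ["a"]
        assert [r.probe_id for r in neg] == ["c"]

    def test_cap_is_exact(self):
        rows = [row(f"p{i:04d}", 1e-8, 1.0 + i * 0.01) for i in range(600)]
        pos, neg = select_top(rows, cap_per_direction=500)
        assert len(pos) == 500 and len(neg) == 0
        assert pos[0].probe_id == "p0599"  # largest |z| first

    def test_empty_input(self):
        assert select_top([]) == ([], [])

    def test_matches_brute_force_and_order_invariant(self):
        rng = np.random.default_rng(4)
        rows = [
            row(f"p{i:05d}", float(10 ** rng.uniform(-9, -3)),
                float(rng.normal(0, 3)))
            for i in range(2000)
        ]
        thr, cap = 1e-5, 50
        expected = self.brute_force(rows, thr, cap)
        got = select_top(rows, thr, cap)
        assert got == expected
        shuffled = list(rows)
        rng.shuffle(shuffled)
        assert select_top(shuffled, thr, cap) == expected


class TestConcordance:
    def test_shared_divergent_and_ns(self):
        a = [row("p1", 1e-7, 5.0), row("p2", 1e-7, 5.0), row("p3", 1e-7, 5.0)]
        b = [row("p1", 1e-7, 6.0), row("p2", 1e-7, -6.0), row("p3", 0.2, 1.0)]
        labels, n_excl = concordance(a, b)
        by = {l.probe_id: l.label for l in labels}
        assert by == {"p1": "shared", "p2": "divergent", "p3": "not_significant"}
        assert n_excl == 0

    def test_one_sided_probes_counted_not_labelled(self):
        a = [row("p1", 1e-7, 5.0), row("only_a", 1e-7, 5.0)]
        b = [row("p1", 1e-7, 5.0), row("only_b", 1e-7, 5.0)]
        labels, n_excl = concordance(a, b)
        assert [l.probe_id for l in labels] == ["p1"]
        assert n_excl == 2


class TestContextSummary:
    def ann(self, pid, region="promoter", cgi=True, tss=-200):
        return ProbeAnnotation(pid, "scaffold_1", 100, "GENE", tss, region, cgi)

    def test_all_hyper_promoters(self):
        rows = [row(f"p{i}", 1e-7, 4.0) for i in range(5)]
        annots = {f"p{i}": self.ann(f"p{i}") for i in range(5)}
        table = context_summary(rows, annots)
        prom = table[table.context == "cgi:True"]
        assert int(prom.n_hyper.iloc[0]) == 5
        assert int(prom.n_hypo.iloc[0]) == 0

    def test_unannotated_probes_counted(self):
        rows = [row("px", 1e-7, -2.0)]
        table = context_summary(rows, {})
        unk = table[table.context == "unannotated"]
        assert int(unk.n_hypo.iloc[0]) == 1

    def test_empty_selection(self):
        table = context_summary([], {})
        assert table.empty


class TestSexScreens:
    def _sex_dataset(self, seed=0, n=60, confound=False):
        rng = np.random.default_rng(seed)
        sexes = ["F"] * (n // 2) + ["M"] * (n // 2)
        if confound:
            ages = np.concatenate(
                [rng.uniform(30, 60, n // 2), rng.uniform(1, 30, n // 2)]
            )
        else:
            ages = rng.uniform(1, 60, n)
        samples = make_samples(ages, sexes=sexes)
        return rng, samples, np.array([s.sex == "F" for s in samples], float), ages

    def test_pure_sex_probe_is_significant(self):
        rng, samples, sex, ages = self._sex_dataset()
        vals = np.vstack([0.2 + 0.5 * sex + rng.normal(0, 0.01, len(sex))])
        vals = np.clip(vals, 0.001, 0.999)
        rows = sex_screen(make_beta(vals), samples)
        assert rows[0].p < 1e-20

    def test_age_adjustment_removes_confounding(self):
        rng, samples, sex, ages = self._sex_dataset(seed=1, confound=True)
        # probes purely driven by age, which is confounded with sex
        base = 0.3 + 0.008 * ages
        vals = np.clip(
            base[None, :] + rng.normal(0, 0.02, size=(300, len(ages))), 0.001, 0.999
        )
        beta = make_beta(vals)
        adj = sex_screen(beta, samples, adjust_for_age=True)
        unadj = sex_screen(beta, samples, adjust_for_age=False)
        frac_adj = np.mean([r.p < 0.05 for r in adj])
        frac_unadj = np.mean([r.p < 0.05 for r in unadj])
        assert frac_unadj > frac_adj  # adjustment removes the inflation
        assert frac_adj < 0.12

    def test_single_sex_is_error(self):
        samples = make_samples([1, 2, 3, 4], sexes=["F"] * 4)
        with pytest.raises(ValidationError, match="both sexes"):
            sex_screen(make_beta(np.full((2, 4), 0.5)), samples)

    def test_m_value_option_runs(self):
        rng, samples, sex, ages = self._sex_dataset(seed=2)
        vals = np.clip(rng.uniform(0.2, 0.8, (5, len(ages))), 0.001, 0.999)
        rows = sex_screen(make_beta(vals), samples, use_m_values=True)
        assert len(rows) == 5


class TestInteractionScreen:
    def test_female_only_age_slope_detected(self):
        rng = np.random.default_rng(5)
        n = 140
        sexes = ["F"] * 70 + ["M"] * 70
        ages = rng.uniform(1, 70, n)
        samples = make_samples(ages, sexes=sexes)
        f = np.array([s.sex == "F" for s in samples], float)
        signal = 0.2 + 0.008 * ages * f  # slope in females only
        vals = np.clip(signal[None, :] + rng.normal(0, 0.02, (1, n)), 0.001, 0.999)
        rows = interaction_screen(make_beta(vals), samples)
        assert rows[0].p < 1e-5

    def test_equal_slopes_not_flagged(self):
        rng = np.random.default_rng(6)
        n = 100
        sexes = ["F"] * 50 + ["M"] * 50
        ages = rng.uniform(1, 70, n)
        samples = make_samples(ages, sexes=sexes)
        vals = np.clip(
            0.3 + 0.005 * ages[None, :] + rng.normal(0, 0.02, (200, n)),
            0.001, 0.999,
        )
        rows = interaction_screen(make_beta(vals), samples)
        frac = np.mean([r.p < 0.05 for r in rows])
        assert 0.0 <= frac < 0.12

    def test_df_exhausted_is_error(self):
        samples = make_samples([1, 2, 3, 4], sexes=["F", "F", "M", "M"])
        with pytest.raises(ValidationError):
            interaction_screen(make_beta(np.full((2, 4), 0.5)), samples)
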