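import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from dyadscan.cohort_io import CohortTable, SubjectRecord, dyad_eligible
from dyadscan.dyad_stats import (
    DyadSpec,
    DyadTable,
    TABLE2_SPECS,
    apoe_by_birthplace,
    build_dyad_table,
    compare_dyads,
    describe_groups,
    dyad_matrix,
    odds_ratio,
    risk_ratio,
)
from dyadscan.errors import DegenerateEstimateError, DegenerateTableError

from conftest import PUBLISHED_COUNTS, PUBLISHED_RR

FS = DyadSpec("father", "male")


def _table(a, n_case, c, n_ctrl, spec=FS):
    return DyadTable(spec, a, n_case, c, n_ctrl)


def _random_tables(rng, n, max_n=400):
    out = []
    while len(out) < n:
        n_case = int(rng.integers(10, max_n))
        n_ctrl = int(rng.integers(10, max_n))
        a = int(rng.integers(1, n_case))
        c = int(rng.integers(1, n_ctrl))
        out.append(_table(a, n_case, c, n_ctrl))
    return out


class TestBuildDyadTable:
    def _toy_cohort(self):
        rows = [
            # (status, sex, pat, mat)
            ("case", "male", "yes", "no"),
            ("case", "male", "yes", "no"),
            ("case", "male", "yes", "yes"),  # both affected -> excluded
            ("case", "female", "no", "no"),
            ("control", "male", "yes", "no"),
            ("control", "male", "no", "no"),
        ]
        recs = [
            SubjectRecord(f"t{i}", st, sx, paternal_history=p, maternal_history=m)
            for i, (st, sx, p, m) in enumerate(rows)
        ]
        return CohortTable.from_records(recs)

    def test_hand_counted_toy(self):
        t = build_dyad_table(self._toy_cohort(), FS)
        assert (t.a, t.n_case, t.c, t.n_ctrl) == (2, 2, 1, 2)

    def test_matches_per_record_scan(self, paperlike_cohort):
        # independent naive counter over SubjectRecords
        for spec in TABLE2_SPECS:
            t = build_dyad_table(paperlike_cohort, spec)
            a = n_case = c = n_ctrl = 0
            for rec in paperlike_cohort.records:
                if spec.offspring_sex != "any" and rec.sex != spec.offspring_sex:
                    continue
                out = dyad_eligible(rec, spec.parent)
                if out == "excluded":
                    continue
                if rec.status == "case":
                    n_case += 1
                    a += out == "exposed"
                else:
                    n_ctrl += 1
                    c += out == "exposed"
            assert (t.a, t.n_case, t.c, t.n_ctrl) == (a, n_case, c, n_ctrl)

    @pytest.mark.parametrize(
        "parent,sex",
        [k for k in PUBLISHED_COUNTS if k != ("mother", "male")],
    )
    def test_margin_cohort_reproduces_published_counts(
        self, margin_cohort, parent, sex
    ):
        # mother->son is excluded: its printed margins are jointly
        # infeasible with the father->son / any->son margins
        t = build_dyad_table(margin_cohort, DyadSpec(parent, sex))
        assert (t.a, t.n_case, t.c, t.n_ctrl) == PUBLISHED_COUNTS[(parent, sex)]

    def test_mother_son_control_margin_still_matches(self, margin_cohort):
        t = build_dyad_table(margin_cohort, DyadSpec("mother", "male"))
        assert (t.c, t.n_ctrl) == PUBLISHED_COUNTS[("mother", "male")][2:]

    def test_degenerate_margin_raises(self):
        recs = [SubjectRecord("a", "case", "male", paternal_history="no")]
        with pytest.raises(DegenerateTableError):
            build_dyad_table(CohortTable.from_records(recs), FS)


class TestRiskRatio:
    def test_father_son_published_value(self):
        assert round(risk_ratio(_table(52, 325, 36, 761)).value, 2) == 3.38

    def test_equal_proportions_give_unity(self):
        assert risk_ratio(_table(5, 50, 10, 100)).value == pytest.approx(1.0)

    def test_random_tables_match_rational_oracle(self, rng):
        for t in _random_tables(rng, 50):
            expect = Fraction(t.a * t.n_ctrl, t.c * t.n_case)
            assert risk_ratio(t).value == pytest.approx(float(expect), rel=1e-12)

    def test_zero_control_exposure_raises_with_advice(self):
        with pytest.raises(DegenerateEstimateError, match="continuity"):
            risk_ratio(_table(5, 50, 0, 100))

    def test_zero_case_exposure_flags_one_sided(self):
        est = risk_ratio(_table(0, 50, 10, 100))
        assert est.value == 0.0 and est.one_sided
        assert est.ci95[0] == 0.0 and est.ci95[1] > 0

    def test_continuity_mode(self):
        est = risk_ratio(_table(5, 50, 0, 100), continuity=True)
        assert math.isfinite(est.value) and est.value > 0

    def test_ci_contains_value(self, rng):
        for t in _random_tables(rng, 20):
            est = risk_ratio(t)
            assert est.ci95[0] <= est.value <= est.ci95[1]


class TestOddsRatio:
    def test_published_cells_value(self):
        # a=52, b=273, c=36, d=725
        assert round(odds_ratio(_table(52, 325, 36, 761)).value, 3) == 3.836

    def test_proportional_rows_give_unity(self):
        assert odds_ratio(_table(10, 30, 20, 60)).value == pytest.approx(1.0)

    def test_zero_cell_raises_with_advice(self):
        with pytest.raises(DegenerateEstimateError, match="Haldane"):
            odds_ratio(_table(50, 50, 10, 100))

    def test_continuity_on_request(self):
        est = odds_ratio(_table(50, 50, 10, 100), continuity=True)
        assert math.isfinite(est.value)

    def test_woolf_identity(self, rng):
        # 1/(n p(1-p)) + 1/(n' p'(1-p')) == 1/a + 1/b + 1/c + 1/d
        for t in _random_tables(rng, 100):
            if t.a in (0, t.n_case) or t.c in (0, t.n_ctrl):
                continue
            lhs = 1 / (t.n_case * t.p * (1 - t.p)) + 1 / (
                t.n_ctrl * t.p_prime * (1 - t.p_prime)
            )
            rhs = 1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d
            assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_monotone_in_a(self):
        values_rr, values_or = [], []
        for a in range(1, 20):
            t = _table(a, 40, 10, 100)
            values_rr.append(risk_ratio(t).value)
            values_or.append(odds_ratio(t).value)
        assert all(x < y for x, y in zip(values_rr, values_rr[1:]))
        assert all(x < y for x, y in zip(values_or, values_or[1:]))


class TestCompareDyads:
    def test_father_daughter_vs_father_son_phi(self):
        t1 = _table(*PUBLISHED_COUNTS[("father", "female")], spec=DyadSpec("father", "female"))
        t2 = _table(*PUBLISHED_COUNTS[("father", "male")])
        cmp_ = compare_dyads(t1, t2, mode="risk_ratio")
        assert round(cmp_.phi, 2) == 0.76

    def test_identity(self):
        t = _table(52, 325, 36, 761)
        cmp_ = compare_dyads(t, t)
        assert cmp_.phi == pytest.approx(1.0)
        assert cmp_.z == pytest.approx(0.0)
        assert cmp_.p_two_sided == pytest.approx(1.0)

    @pytest.mark.parametrize("mode", ["risk_ratio", "odds_ratio"])
    @pytest.mark.parametrize("rule", ["paper_literal", "pooled_woolf"])
    def test_reciprocity_and_antisymmetry(self, rng, mode, rule):
        tables = _random_tables(rng, 20)
        for t1, t2 in zip(tables[:10], tables[10:]):
            ab = compare_dyads(t1, t2, mode=mode, variance_rule=rule)
            ba = compare_dyads(t2, t1, mode=mode, variance_rule=rule)
            assert ab.phi * ba.phi == pytest.approx(1.0, rel=1e-12)
            assert ab.z == pytest.approx(-ba.z, rel=1e-12)
            assert ab.p_two_sided == pytest.approx(ba.p_two_sided, rel=1e-12)

    def test_literal_variance_is_woolf_for_either_mode(self, rng):
        # paper_literal z must agree with pooled_woolf z in odds-ratio mode
        t1, t2 = _random_tables(rng, 2)
        lit = compare_dyads(t1, t2, mode="odds_ratio", variance_rule="paper_literal")
        woolf = compare_dyads(t1, t2, mode="odds_ratio", variance_rule="pooled_woolf")
        assert lit.z == pytest.approx(woolf.z, rel=1e-12)

    def test_two_sided_p_from_normal(self):
        t1 = _table(60, 300, 30, 700)
        t2 = _table(40, 300, 35, 700)
        cmp_ = compare_dyads(t1, t2)
        assert cmp_.p_two_sided == pytest.approx(2 * stats.norm.sf(abs(cmp_.z)))


class TestDyadMatrix:
    def test_published_matrix_cells(self, margin_cohort):
        m = dyad_matrix(margin_cohort, TABLE2_SPECS)
        assert len(m.cells) == 21
        # mother->daughter (row 3) vs father->son (col 0)
        assert round(m.comparison(3, 0).phi, 3) == 0.787

    def test_diagonal_effects_match_published(self, margin_cohort):
        m = dyad_matrix(margin_cohort, TABLE2_SPECS)
        for i, spec in enumerate(TABLE2_SPECS):
            key = (spec.parent, spec.offspring_sex)
            if key in PUBLISHED_RR:
                assert round(m.effects[i].value, 2) == PUBLISHED_RR[key]

    def test_cells_equal_pairwise_calls(self, margin_cohort):
        m = dyad_matrix(margin_cohort, TABLE2_SPECS)
        for (i, j), cell in m.cells.items():
            direct = compare_dyads(m.tables[i], m.tables[j])
            assert cell.phi == pytest.approx(direct.phi, rel=1e-12)
            assert cell.z == pytest.approx(direct.z, rel=1e-12)

    def test_two_identical_specs(self, margin_cohort):
        m = dyad_matrix(margin_cohort, [FS, FS])
        assert m.comparison(1, 0).phi == pytest.approx(1.0)

    def test_report_frame_layout(self, margin_cohort):
        frame = dyad_matrix(margin_cohort, TABLE2_SPECS).to_frame()
        assert list(frame["dyad"]) == [s.label for s in TABLE2_SPECS]
        assert frame.loc[0, "cases"] == "52/325 (0.160)"
        assert frame.loc[0, "controls"] == "36/761 (0.047)"


class TestDescribeGroups:
    def _history_cohort(self):
        # 414/2139 exposed controls vs 417/855 exposed cases (family history)
        recs = []
        i = 0
        for status, exposed, total in (("control", 414, 2139), ("case", 417, 855)):
            for k in range(total):
                pat = "yes" if k < exposed else "no"
                recs.append(
                    SubjectRecord(
                        f"d{i}", status, "female",
                        age_at_assessment=80.0,
                        paternal_history=pat, maternal_history="no",
                    )
                )
                i += 1
        return CohortTable.from_records(recs)

    def test_family_history_chi_square_p(self):
        comps = describe_groups(
            self._history_cohort(), "case_vs_control", ["paternal_history"]
        )
        (c,) = comps
        assert c.test == "chi_square"
        assert c.p < 0.001
        # oracle: scipy on the printed 2x2
        chi2, p, _, _ = stats.chi2_contingency(
            [[414, 2139 - 414], [417, 855 - 417]], correction=False
        )
        assert c.statistic == pytest.approx(chi2)

    def test_identical_groups_p_one(self):
        recs = []
        for g, status in enumerate(("control", "case")):
            for k in range(40):
                recs.append(
                    SubjectRecord(
                        f"i{g}_{k}", status, "female", age_at_assessment=80.0,
                        paternal_history="yes" if k < 20 else "no",
                        maternal_history="no",
                    )
                )
        (c,) = describe_groups(
            CohortTable.from_records(recs), "case_vs_control", ["paternal_history"]
        )
        assert c.p == pytest.approx(1.0)

    def test_continuous_uses_mann_whitney(self, rng):
        recs = [
            SubjectRecord(
                f"c{i}", "case" if i % 3 == 0 else "control", "female",
                age_at_assessment=80.0, education=float(rng.normal(5, 2)),
            )
            for i in range(90)
        ]
        (c,) = describe_groups(
            CohortTable.from_records(recs), "case_vs_control", ["education"]
        )
        assert c.test == "mann_whitney"
        assert "mean" in c.groups["case"] and "sd" in c.groups["case"]

    def test_mann_whitney_null_pvalues_uniform(self, rng):
        # simulation oracle: p-values under the null are U(0,1)
        pvals = []
        for _ in range(1000):
            x, y = rng.normal(size=30), rng.normal(size=30)
            pvals.append(
                stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
            )
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_eoad_vs_load_grouping(self, paperlike_cohort):
        comps = describe_groups(paperlike_cohort, "eoad_vs_load", ["education"])
        (c,) = comps
        assert set(c.groups) == {"EOAD", "LOAD"}

    def test_unknown_variable_raises(self, margin_cohort):
        with pytest.raises(ValueError, match="unknown variable"):
            describe_groups(margin_cohort, "case_vs_control", ["nope"])


class TestApoeByBirthplace:
    def _cohort(self, same_counts, diff_counts):
        recs, i = [], 0
        for town, counts in (("A", same_counts), (("A", "B"), diff_counts)):
            same = isinstance(town, str)
            for geno, k in counts.items():
                for _ in range(k):
                    recs.append(
                        SubjectRecord(
                            f"a{i}", "control", "female", age_at_assessment=80.0,
                            father_birthplace="A",
                            mother_birthplace="A" if same else "B",
                            apoe=geno,
                        )
                    )
                    i += 1
        return CohortTable.from_records(recs)

    def test_constructed_homozygote_ratio_two(self):
        same = {"e4/e4": 20, "e3/e3": 30, "e3/e4": 50}
        diff = {"e4/e4": 10, "e3/e3": 40, "e3/e4": 50}
        comp = apoe_by_birthplace(self._cohort(same, diff))
        hs = comp.groups["same"]["homozygote_fraction"]
        hd = comp.groups["different"]["homozygote_fraction"]
        assert hs / hd == pytest.approx(2.0)

    def test_chi_square_matches_textbook_formula(self):
        same = {"e4/e4": 15, "e3/e3": 35, "e3/e4": 50}
        diff = {"e4/e4": 5, "e3/e3": 45, "e3/e4": 50}
        comp = apoe_by_birthplace(self._cohort(same, diff))
        obs = np.array(
            [[same[g], diff[g]] for g in ("e3/e3", "e3/e4", "e4/e4")]
        )
        expected = obs.sum(1, keepdims=True) * obs.sum(0) / obs.sum()
        chi2 = ((obs - expected) ** 2 / expected).sum()
        assert comp.statistic == pytest.approx(chi2)

    def test_inbreeding_homozygote_excess(self):
        # closed-form: excess homozygosity = F * (1 - sum p_i^2)
        from dyadscan.synthetic_cohort import SimConfig, Locus, _apoe_genotypes

        cfg = SimConfig(
            n_cases=1, n_controls=1, loci=[], kinship_phi=0.25,
            apoe_freqs=(0.07, 0.77, 0.16),
        )
        rng = np.random.default_rng(0)
        n = 200_000
        same = np.ones(n, dtype=bool)
        genos = _apoe_genotypes(cfg, same, n, rng)
        hom = np.isin(genos, ["e2/e2", "e3/e3", "e4/e4"]).mean()
        p = np.array(cfg.apoe_freqs)
        expect = 0.25 + (1 - 0.25) * (p**2).sum()
        assert hom == pytest.approx(expect, abs=0.005)
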