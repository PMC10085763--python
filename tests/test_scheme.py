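import numpy as np
import pandas as pd
import pytest

from rcgs.models import ChainSettings
from rcgs.scheme import (
    PlanError,
    SchemeConfig,
    bulk_f1_genotype,
    make_cross_plan,
    make_cycle_cross_plan,
    run_scheme,
    select_c0_parents,
    select_families,
)
from rcgs.simpop import SimIndividual, TrainingPopConfig, cross, make_founders


def small_scheme_config(h2=0.5, preset="P+RKHS-KA", chain=None,
                        do_final_trial=False):
    """Scaled-down scheme preserving the study's structure: 14 families,
    6 selected, within+between crossing, 3 cycles, truncation selection."""
    return SchemeConfig(
        training=TrainingPopConfig(
            n_founders=16, n_markers=400, n_chromosomes=7,
            family_sizes=(14,) * 14, family_h2_targets=(h2,) * 14, n_qtl=100),
        n_families_select=6, n_top_lines_per_family=4,
        crosses_within_per_family=2, crosses_between_per_pair=2,
        n_between_pairs=9,
        n_f1_per_cycle=(60, 50, 60), n_select_per_cycle=(20, 20),
        cycle_crosses=((5, 18), (5, 18)),
        model_preset=preset,
        chain=chain or ChainSettings(1200, 300, 2, seed=0),
        family_criteria=("mean_gy", "h2"),
        do_final_trial=do_final_trial,
        n_advance_per_cycle=(10, 10, 10), advance_rank_band=30,
        n_c0_checks=10, trial_reps=2,
    )


class TestFamilySelection:
    def _summary(self, values):
        cols = ["mean_gy", "h2", "within_ability", "between_ability"]
        return pd.DataFrame(values, columns=["family"] + cols)

    def test_dominant_family_always_selected(self):
        rows = [[f"F{k}", 1.0, 0.2, 0.1, 0.1] for k in range(1, 6)]
        rows.append(["F9", 9.0, 0.9, 0.9, 0.9])
        assert "F9" in select_families(self._summary(rows), 2)

    def test_all_equal_ties_break_by_family_id(self):
        rows = [[f, 1.0, 0.5, 0.2, 0.2] for f in ("Fb", "Fa", "Fc")]
        assert select_families(self._summary(rows), 2) == ["Fa", "Fb"]

    def test_matches_brute_force_rank_sum(self):
        rng = np.random.default_rng(7)
        rows = [[f"F{k:02d}", *rng.random(4)] for k in range(14)]
        df = self._summary(rows)
        got = select_families(df, 6)
        cols = ["mean_gy", "h2", "within_ability", "between_ability"]
        scores = {}
        for _, row in df.iterrows():
            s = 0.0
            for c in cols:
                s += sum(1 for v in df[c] if v > row[c]) + 1
            scores[row["family"]] = s
        expected = sorted(df["family"], key=lambda f: (scores[f], f))[:6]
        assert got == expected

    def test_top_lines_per_family(self):
        blues = pd.DataFrame({
            "line": [f"L{i}" for i in range(6)],
            "family": ["A", "A", "A", "B", "B", "B"],
            "value": [1.0, 3.0, 2.0, 9.0, 7.0, 8.0],
        })
        assert select_c0_parents(blues, ["A", "B"], 2) == ["L1", "L2", "L3", "L5"]
        with pytest.raises(ValueError, match="fewer"):
            select_c0_parents(blues, ["A"], 4)


def _verify_plan(plan, parents_by_family, n_within, n_between, min_uses):
    """Brute-force constraint verifier for a C1-style crossing plan."""
    fam_of = {p: f for f, ps in parents_by_family.items() for p in ps}
    uses = {f: set() for f in parents_by_family}
    n_w = n_b = 0
    for a, b, kind in plan.crosses:
        assert a != b, "selfing cross"
        fa, fb = fam_of[a], fam_of[b]
        if kind == "within":
            assert fa == fb
            n_w += 1
        else:
            assert fa != fb
            uses[fa].add(tuple(sorted((fa, fb))))
            uses[fb].add(tuple(sorted((fa, fb))))
            n_b += 1
    assert n_w == n_within and n_b == n_between
    for f, pairset in uses.items():
        assert len(pairset) >= min_uses, f"family {f} in only {len(pairset)} pairs"


class TestCrossPlans:
    def _parents(self, n_fam=6, n_per=10):
        return {f"F{k}": [f"F{k}_P{i}" for i in range(n_per)]
                for k in range(n_fam)}

    def test_study_defaults_give_146_crosses(self):
        rng = np.random.default_rng(1)
        plan = make_cross_plan(self._parents(), rng)
        assert plan.n_within == 36 and plan.n_between == 110
        _verify_plan(plan, self._parents(), 36, 110, 3)

    def test_scored_pairs_respect_intercross_floor(self):
        rng = np.random.default_rng(2)
        parents = self._parents()
        fams = sorted(parents)
        # scores that would starve family F5 without the repair step
        scores = {(a, b): (0.0 if "F5" in (a, b) else 1.0)
                  for i, a in enumerate(fams) for b in fams[i + 1:]}
        plan = make_cross_plan(parents, rng, pair_scores=scores)
        _verify_plan(plan, parents, 36, 110, 3)

    def test_single_family_between_crossing_is_infeasible(self):
        with pytest.raises(PlanError):
            make_cross_plan({"F0": ["a", "b"]}, np.random.default_rng(0),
                            n_between_pairs=1)

    def test_impossible_intercross_floor_is_reported(self):
        with pytest.raises(PlanError, match="infeasible"):
            make_cross_plan(self._parents(), np.random.default_rng(0),
                            n_between_pairs=8, min_intercross_uses=3)

    def test_cycle_plan_shifts_infeasible_within_to_between(self):
        rng = np.random.default_rng(3)
        parents = {"cA": ["p1"], "cB": ["p2"], "cC": ["p3"]}  # all singletons
        plan = make_cycle_cross_plan(parents, n_within=5, n_between=10, rng=rng)
        assert plan.n_within == 0 and plan.n_between == 15
        multi = {"cA": ["p1", "p4"], "cB": ["p2"], "cC": ["p3"]}
        plan2 = make_cycle_cross_plan(multi, n_within=3, n_between=4, rng=rng)
        assert plan2.n_within == 3 and plan2.n_between == 4


class TestBulkGenotype:
    def _f1s(self, seed, n=20):
        fs = make_founders(2, 60, 2, seed=seed)
        rng = np.random.default_rng(seed)
        p1 = SimIndividual("a", fs.haplotypes[0])
        p2 = SimIndividual("b", fs.haplotypes[1])
        return cross(p1, p2, n, rng, fs, "f1"), p1, p2

    def test_inbred_parents_give_deterministic_bulk(self):
        f1s, p1, p2 = self._f1s(4)
        bulk = bulk_f1_genotype(f1s, 5)
        assert np.allclose(bulk, (p1.dosage + p2.dosage) / 2.0)

    def test_single_plant_is_ordinary_genotype(self):
        f1s, *_ = self._f1s(5)
        assert np.array_equal(bulk_f1_genotype(f1s, 1), f1s[0].dosage.astype(float))

    def test_f2_bulk_approaches_expectation(self):
        # bulk F2s of a heterozygous F1: expectation = F1 dosage
        fs = make_founders(2, 40, 2, seed=6)
        rng = np.random.default_rng(6)
        f1 = cross(SimIndividual("a", fs.haplotypes[0]),
                   SimIndividual("b", fs.haplotypes[1]), 1, rng, fs, "f1")[0]
        f2s = cross(f1, f1, 600, rng, fs, "f2")
        bulk = bulk_f1_genotype(f2s)
        assert np.abs(bulk - f1.dosage).mean() < 0.1


@pytest.fixture(scope="module")
def result():
    return run_scheme(small_scheme_config(do_final_trial=True), seed=4)


class TestSchemeEngine:
    def test_cycle_structure(self, result):
        labels = [p.label for p in result.cycles]
        assert labels == ["C0", "C1", "C2", "C3"]
        assert len(result.cycles[1].individuals) == 60
        assert len(result.cycles[1].selected_ids) == 20
        sel = set(result.cycles[1].selected_ids)
        assert sel <= {i.id for i in result.cycles[1].individuals}

    def test_selection_differential_positive_every_cycle(self, result):
        for pop in result.cycles[1:3]:
            table = pop.gebvs.table.set_index("id")["gebv"]
            assert table.loc[pop.selected_ids].mean() > table.mean()

    def test_candidates_are_unphenotyped_in_fit(self, result):
        assert not result.cycles[1].gebvs.table["phenotyped"].any()

    def test_gain_reports_and_trial(self, result):
        assert result.gain_true.basis == "true_breeding_value"
        assert len(result.gain_true.cycle_mean) == 4
        assert result.gain_phenotype is not None
        assert set(result.trial_table.index) == {"C0", "C1", "C2", "C3"}
        # heritable trait, truncation selection: truth improves overall
        assert result.gain_true.per_cycle_gain > 0

    def test_gebv_cycle_means_reported(self, result):
        df = result.gebv_cycle_means
        assert list(df["cycle"]) == ["C0", "C1", "C2", "C3"]
        assert np.isfinite(df["mean_gebv"]).all()

    def test_determinism(self):
        cfg = small_scheme_config(chain=ChainSettings(400, 100, 2, seed=0))
        a = run_scheme(cfg, seed=9)
        b = run_scheme(cfg, seed=9)
        assert a.gain_true.to_dict() == b.gain_true.to_dict()
        pd.testing.assert_frame_equal(a.cycles[1].gebvs.table,
                                      b.cycles[1].gebvs.table)

    def test_diversity_maintained_through_cycles(self, result):
        from rcgs.evaluation import diversity_summary
        from rcgs.genotypes import MarkerMatrix
        mms = {}
        for pop in result.cycles[1:]:
            dosages = np.stack([i.dosage for i in pop.individuals]).astype(float)
            mms[pop.label] = MarkerMatrix(
                [i.id for i in pop.individuals],
                [f"M{j}" for j in range(dosages.shape[1])], dosages)
        div = diversity_summary(mms)
        within_c3 = div[(div.cycle_a == "C3") & (div.cycle_b == "C3")]["mean"].iloc[0]
        within_c1 = div[(div.cycle_a == "C1") & (div.cycle_b == "C1")]["mean"].iloc[0]
        assert within_c3 > 0.25 * within_c1  # no collapse of diversity
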