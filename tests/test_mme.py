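"""Mixed-model equations: closed forms, solver agreement, standard errors,
EBV/GEBV equivalences and the GWAS screen."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from salmogs.containers import GenotypeMatrix, Pedigree, TraitModel
from salmogs.mme import (EvaluationData, build_mme, gwas_scan,
                         prediction_error_variance, run_evaluation, solve_mme)
from salmogs.relmat import (RelationshipMatrix, a_inverse, h_inverse,
                            numerator_relationship)


@pytest.fixture
def sire_model():
    """Balanced paternal half-sib design: 5 unrelated sires, 10 records each."""
    rng = np.random.default_rng(1)
    var_s, var_e = 0.2, 0.8
    n, n_sires = 10, 5
    rows = []
    for i in range(n_sires):
        s_eff = rng.normal(0, np.sqrt(var_s))
        for _ in range(n):
            rows.append((f"s{i}", "t", s_eff + rng.normal(0, np.sqrt(var_e)), "c"))
    phen = pd.DataFrame(rows, columns=["id", "trait", "value", "cohort"])
    tm = TraitModel(("t",), [[var_s]], [[0.05]], [[var_e]])
    ids = [f"s{i}" for i in range(n_sires)]
    return phen, tm, ids, n, var_s, var_e


class TestSolver:
    def test_blup_equals_shrunken_family_mean(self, sire_model):
        phen, tm, ids, n, var_s, var_e = sire_model
        system = build_mme(phen, tm, sp.eye(len(ids), format="csc"), ids,
                          family_effect=False)
        sol = solve_mme(system)
        blup = system.animal_solutions(sol)["t"]
        t_icc = var_s / (var_s + var_e)
        shrink = n * t_icc / (1 + (n - 1) * t_icc)
        ybar = phen.groupby("id")["value"].mean()
        expected = (ybar - phen["value"].mean()) * shrink
        assert np.abs(blup - expected.loc[blup.index]).max() < 1e-8

    def test_direct_and_cg_agree(self, sire_model):
        phen, tm, ids, *_ = sire_model
        system = build_mme(phen, tm, sp.eye(len(ids), format="csc"), ids,
                          family_effect=False)
        direct = solve_mme(system, method="direct")
        cg = solve_mme(system, method="conjugate_gradient")
        assert np.abs(direct - cg).max() < 1e-6

    def test_constant_phenotypes_zero_breeding_values(self, sire_model):
        phen, tm, ids, *_ = sire_model
        phen = phen.assign(value=3.14)
        system = build_mme(phen, tm, sp.eye(len(ids), format="csc"), ids,
                          family_effect=False)
        sol = solve_mme(system)
        assert np.abs(system.animal_solutions(sol)["t"]).max() < 1e-10
        assert sol[0] == pytest.approx(3.14)

    def test_no_random_effects_reduces_to_ols(self):
        # prior variance -> infinity is emulated by a huge additive variance
        # on an unphenotyped animal set; instead check the fixed block alone:
        rng = np.random.default_rng(0)
        y = rng.normal(size=12)
        phen = pd.DataFrame({"id": [f"i{k}" for k in range(12)], "trait": "t",
                             "value": y,
                             "cohort": ["a"] * 6 + ["b"] * 6})
        tm = TraitModel(("t",), [[1e6]], [[1.0]], [[1.0]])
        ids = [f"i{k}" for k in range(12)]
        system = build_mme(phen, tm, sp.eye(12, format="csc") * 1e-6, ids,
                          family_effect=False)
        # with a diffuse genetic prior the fixed solutions approach group
        # means (OLS normal equations)
        sol = solve_mme(system)
        fixed = dict(zip(system.fixed_labels, sol[: system.n_fixed]))
        assert fixed[("t", "a")] + np.mean(
            system.animal_solutions(sol)["t"][:6]) == pytest.approx(y[:6].mean(), abs=1e-6)

    def test_phenotyped_individual_missing_from_K_rejected(self, sire_model):
        phen, tm, ids, *_ = sire_model
        with pytest.raises(ValueError, match="absent"):
            build_mme(phen, tm, sp.eye(2, format="csc"), ids[:2],
                      family_effect=False)


class TestPredictionError:
    def test_unconnected_founder_se_is_prior_sd(self, sire_model):
        phen, tm, ids, *_ = sire_model
        all_ids = ids + ["lonely"]
        system = build_mme(phen, tm, sp.eye(len(all_ids), format="csc"),
                          all_ids, family_effect=False)
        se = prediction_error_variance(system)
        assert se.loc["lonely", "t"] == pytest.approx(np.sqrt(0.2))

    def test_progeny_records_lower_se(self):
        rng = np.random.default_rng(2)
        rows = [("sire", None, None)] + [(f"o{k}", "sire", None) for k in range(50)]
        ped = Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam"]))
        tm = TraitModel(("t",), [[0.4]], [[0.05]], [[0.6]])
        k_inv = a_inverse(ped)
        ids = ped.ids

        def run(n_prog):
            phen = pd.DataFrame({
                "id": [f"o{k}" for k in range(n_prog)], "trait": "t",
                "value": rng.normal(size=n_prog), "cohort": "c"})
            system = build_mme(phen, tm, k_inv, ids, family_effect=False)
            return prediction_error_variance(system, ids=["sire"]).iloc[0, 0]

        assert run(50) < run(5) < np.sqrt(0.4)

    def test_matches_full_inverse_on_toy(self, sire_model):
        phen, tm, ids, *_ = sire_model
        system = build_mme(phen, tm, sp.eye(len(ids), format="csc"), ids,
                          family_effect=False)
        full = prediction_error_variance(system)
        c_inv = np.linalg.inv(system.coeff.toarray())
        oracle = np.sqrt(np.diag(c_inv)[system.animal_slice])
        assert np.allclose(full["t"].to_numpy(), oracle, atol=1e-10)


@pytest.fixture(scope="module")
def eval_bundle(family_population, univariate_model):
    """Phenotyped founder-generation + genotyped unphenotyped offspring."""
    rng = np.random.default_rng(8)
    haps = family_population["all_haplotypes"]
    ped = family_population["pedigree"]
    mm = family_population["marker_map"]
    g = haps.to_genotypes(mm.marker_ids)
    keep = [mk for mk, p in zip(g.marker_ids, g.allele_freq())
            if 0.02 < p < 0.98]
    g = g.subset(marker_ids=keep)
    from salmogs.simulate import draw_qtl_effects, true_breeding_values
    founders = family_population["founders"]
    effects = draw_qtl_effects(mm, founders, univariate_model, rng)
    fr = founders.dosages()[:, mm.qtl_indices].mean(axis=0) / 2
    tbv = true_breeding_values(haps, mm, effects, np.clip(fr, 1e-6, 1 - 1e-6),
                               univariate_model)
    # phenotype 6 of 10 offspring per family; the rest are candidates
    off = ped.table[ped.table["sire"].notna()]
    fams = off.groupby(["sire", "dam"])["id"].apply(list)
    trained, candidates = [], []
    for ids in fams:
        trained.extend(ids[:6])
        candidates.extend(ids[6:])
    noise = rng.normal(0, np.sqrt(0.56), size=len(trained))
    fam_lab = (off.set_index("id")["sire"] + "|" + off.set_index("id")["dam"])
    fam_eff = {f: rng.normal(0, np.sqrt(0.10)) for f in fam_lab.unique()}
    phen = pd.DataFrame({
        "id": trained, "trait": "weight_marine",
        "value": [tbv.loc[i, "weight_marine"] + fam_eff[fam_lab[i]] for i in trained]
                 + noise,
        "cohort": "c0", "family": [fam_lab[i] for i in trained]})
    return {"phen": phen, "ped": ped, "g": g, "tbv": tbv,
            "candidates": candidates, "trained": trained}


class TestRunEvaluation:
    def test_h_without_genotypes_equals_a(self, eval_bundle, univariate_model):
        data = EvaluationData(eval_bundle["phen"], eval_bundle["ped"],
                              univariate_model, genotypes=None)
        ebv = run_evaluation(data, "weight_marine", K_kind="A")
        hbv = run_evaluation(data, "weight_marine", K_kind="H")
        assert hbv["tag"].iloc[0] == "EBV"
        assert np.allclose(ebv["bv"], hbv["bv"])

    def test_all_genotyped_gstar_equals_a_reduces_exactly(self, family_population,
                                                          univariate_model,
                                                          eval_bundle):
        """With G* := A22 the single-step equations collapse to pedigree BLUP."""
        ped = eval_bundle["ped"]
        A = numerator_relationship(ped)
        gen = eval_bundle["trained"][:30]
        A22 = A.submatrix(gen)
        gstar = RelationshipMatrix(gen, A22.values.copy(), "Gstar")
        pos = np.array([ped.index_of(i) for i in gen])
        k_h = h_inverse(a_inverse(ped), gstar, A22, pos)
        tm = univariate_model
        phen = eval_bundle["phen"]
        sys_a = build_mme(phen, tm, a_inverse(ped), ped.ids)
        sys_h = build_mme(phen, tm, k_h, ped.ids)
        sol_a, sol_h = solve_mme(sys_a), solve_mme(sys_h)
        assert np.abs(sol_a - sol_h).max() < 1e-8

    def test_gebv_beats_ebv_for_unphenotyped_sibs(self, eval_bundle,
                                                  univariate_model):
        data_a = EvaluationData(eval_bundle["phen"], eval_bundle["ped"],
                                univariate_model)
        data_h = EvaluationData(eval_bundle["phen"], eval_bundle["ped"],
                                univariate_model, genotypes=eval_bundle["g"])
        ebv = run_evaluation(data_a, "weight_marine", K_kind="A")
        gebv = run_evaluation(data_h, "weight_marine", K_kind="H")
        cand = eval_bundle["candidates"]
        truth = eval_bundle["tbv"].loc[cand, "weight_marine"]
        r_e = np.corrcoef(ebv.set_index("id").loc[cand, "bv"], truth)[0, 1]
        r_g = np.corrcoef(gebv.set_index("id").loc[cand, "bv"], truth)[0, 1]
        assert gebv["tag"].iloc[0] == "GEBV"
        assert r_g > r_e

    def test_within_family_discrimination(self, eval_bundle, univariate_model,
                                          family_population):
        """EBV of unphenotyped full sibs are identical; GEBV vary within
        family."""
        data_a = EvaluationData(eval_bundle["phen"], eval_bundle["ped"],
                                univariate_model)
        data_h = EvaluationData(eval_bundle["phen"], eval_bundle["ped"],
                                univariate_model, genotypes=eval_bundle["g"])
        ebv = run_evaluation(data_a, "weight_marine", K_kind="A").set_index("id")
        gebv = run_evaluation(data_h, "weight_marine", K_kind="H").set_index("id")
        ped = family_population["pedigree"].table
        cand = set(eval_bundle["candidates"])
        off = ped[ped["id"].isin(cand)]
        var_e, var_g = [], []
        for _, grp in off.groupby(["sire", "dam"]):
            ids = grp["id"].tolist()
            if len(ids) < 2:
                continue
            var_e.append(np.var(ebv.loc[ids, "bv"]))
            var_g.append(np.var(gebv.loc[ids, "bv"]))
        assert np.mean(var_e) < 1e-16
        assert np.mean(var_g) > 1e-4

    def test_unknown_model_rejected(self, eval_bundle, univariate_model):
        data = EvaluationData(eval_bundle["phen"], eval_bundle["ped"],
                              univariate_model)
        with pytest.raises(ValueError, match="unknown model"):
            run_evaluation(data, "nonexistent")


@pytest.fixture(scope="module")
def geno(tiny_map, tiny_founders):
    g = tiny_founders.to_genotypes(tiny_map.marker_ids)
    keep = [mk for mk, p in zip(g.marker_ids, g.maf()) if p > 0.05]
    return g.subset(marker_ids=keep)


class TestGWAS:
    def test_planted_marker_is_global_minimum(self, geno):
        rng = np.random.default_rng(0)
        x = geno.dosages[:, 7]
        y = 2.0 * x + rng.normal(0, 0.01, size=len(x))
        phen = pd.DataFrame({"id": geno.ids, "trait": "t", "value": y,
                             "cohort": "c"})
        res = gwas_scan(phen, geno, "t")
        best = res.loc[res["p"].idxmin(), "marker_id"]
        assert best == geno.marker_ids[7]

    def test_null_phenotype_type_I_calibrated(self):
        # independent loci so the per-marker tests are effectively
        # independent and the false-positive fraction concentrates at 0.05
        rng = np.random.default_rng(1)
        n, m = 120, 400
        dos = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        g = GenotypeMatrix([f"i{k}" for k in range(n)],
                           [f"m{k}" for k in range(m)], dos)
        fracs = []
        for rep in range(10):
            y = rng.normal(size=n)
            phen = pd.DataFrame({"id": g.ids, "trait": "t", "value": y,
                                 "cohort": "c"})
            res = gwas_scan(phen, g, "t")
            fracs.append((res["p"] < 0.05).mean())
        p_hat = np.mean(fracs)
        se = np.sqrt(0.05 * 0.95 / (10 * m))
        assert abs(p_hat - 0.05) < 4 * se

    def test_effect_recovery_on_planted_qtl(self, geno):
        rng = np.random.default_rng(2)
        beta = 0.7
        x = geno.dosages[:, 3]
        y = beta * x + rng.normal(0, 0.5, size=len(x))
        phen = pd.DataFrame({"id": geno.ids, "trait": "t", "value": y,
                             "cohort": "c"})
        res = gwas_scan(phen, geno, "t").set_index("marker_id")
        est = res.loc[geno.marker_ids[3], "effect"]
        se = 0.5 / (x.std() * np.sqrt(len(x)))
        assert abs(est - beta) < 3 * se
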