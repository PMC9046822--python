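"""Multi-year breeding-program simulation and scheme comparison.

Runs year classes in sequence: spawn a partial factorial (every parent
crossed exactly twice), sample candidates from the pooled progeny,
allocate them to the marine sib-test or the freshwater broodstock
population, phenotype, genotype, evaluate (pedigree EBV or single-step
GEBV), select the next parents on the index, and carry repeat spawners
across year classes.  True breeding values are tracked throughout so that
realised genetic trends and prediction accuracies can be measured exactly.

Phenotypes of a year class become available to evaluations at later
spawning years only (the sib-test completes before its cohort's
candidates are themselves used as parents, so a candidate's own marine
sibs are always in the training data, while the candidate itself carries
no marine phenotype — the within-family information must come from its
genotype).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (GenotypeMatrix, HaplotypeSet, MarkerMap, Pedigree,
                         TraitModel, weight_trait_model)
from .impute import frequency_impute
from .mme import EvaluationData, run_evaluation
from .qc_io import qc_filter
from .selection import (DEFAULT_INDEX_WEIGHTS, genetic_gain, select_parents,
                        selection_index, standardize_bv)
from .simulate import (SimulationConfig, draw_qtl_effects, founder_allele_freqs,
                       make_progeny, mate_partial_factorial, simulate_assay,
                       simulate_founders, simulate_genome, simulate_phenotypes,
                       true_breeding_values)

__all__ = ["SimulationState", "simulate_breeding_cycle", "evaluate_at_year",
           "final_evaluations", "compare_schemes", "true_index"]


@dataclass
class SimulationState:
    """Everything a breeding-cycle run produced."""

    config: SimulationConfig
    trait_model: TraitModel
    scheme: str
    marker_map: MarkerMap
    qtl_effects: np.ndarray
    founder_qtl_freqs: np.ndarray
    pedigree: pd.DataFrame  # id, sire, dam, sex, year_class, family
    haplotypes: HaplotypeSet
    true_bv: pd.DataFrame
    phenotypes: pd.DataFrame  # long, plus year_class column for availability
    genotypes: GenotypeMatrix | None
    selection_history: list = field(default_factory=list)
    genetic_mean: pd.DataFrame | None = None
    bv_tables: dict = field(default_factory=dict)  # (year, tag) -> table
    index_weights: dict = field(default_factory=dict)

    def pedigree_obj(self) -> Pedigree:
        return Pedigree(self.pedigree[["id", "sire", "dam", "sex", "year_class"]])

    def phenotypes_before(self, year: int) -> pd.DataFrame:
        return self.phenotypes[self.phenotypes["year_class"] < year].reset_index(drop=True)


def _default_index_weights(tm: TraitModel) -> dict[str, float]:
    w = {t: DEFAULT_INDEX_WEIGHTS[t] for t in tm.traits
         if DEFAULT_INDEX_WEIGHTS.get(t, 0) > 0}
    if not w:  # fall back to the first marine trait
        marine = [t for t in tm.traits if tm.environment[t] == "marine"]
        w = {(marine or list(tm.traits))[0]: 1.0}
    return w


def evaluate_at_year(state: SimulationState, year: int, K_kind: str,
                     compute_se: bool = False, se_ids=None) -> pd.DataFrame:
    """Breeding-value run with the data available at a spawning year."""
    phen = state.phenotypes_before(year)
    existing = set(state.pedigree.loc[state.pedigree["year_class"] < year, "id"])
    genotypes = state.genotypes if K_kind == "H" else None
    if genotypes is not None:
        genotypes = genotypes.subset(ids=[i for i in genotypes.ids if i in existing])
        if genotypes.n_individuals == 0:
            genotypes = None
    if genotypes is not None:
        # full QC before breeding-value production, then complete the matrix
        genotypes, _ = qc_filter(genotypes, maf_min=state.config.maf_min,
                                 mode="full")
        if np.isnan(genotypes.dosages).any():
            genotypes = frequency_impute(genotypes, genotypes)
    ped = Pedigree(state.pedigree.loc[state.pedigree["year_class"] < year,
                                      ["id", "sire", "dam", "sex", "year_class"]])
    data = EvaluationData(phen, ped, state.trait_model, genotypes=genotypes)
    phenotyped_traits = [t for t in state.trait_model.traits
                         if t in set(phen["trait"])]
    return run_evaluation(data, phenotyped_traits, K_kind=K_kind,
                          evaluation_year=year, compute_se=compute_se,
                          se_ids=se_ids)


def _select(state: SimulationState, year: int, rng: np.random.Generator,
            selection: str, evaluate_both: bool) -> tuple[list, list, str]:
    cfg = state.config
    n_sires = n_dams = cfg.families_per_year // 2
    ped = state.pedigree
    alive = ped[(ped["alive"]) & (ped["year_class"] < year)]
    have_data = not state.phenotypes_before(year).empty

    if selection == "index" and have_data:
        k_kind = "H" if state.scheme == "genomic" else "A"
        bv = evaluate_at_year(state, year, k_kind)
        state.bv_tables[(year, bv["tag"].iloc[0])] = bv
        if evaluate_both:
            other = "A" if k_kind == "H" else "H"
            if other == "A" or state.genotypes is not None:
                bv_other = evaluate_at_year(state, year, other)
                state.bv_tables[(year, bv_other["tag"].iloc[0])] = bv_other
        sds = dict(zip(state.trait_model.traits, state.trait_model.genetic_sd))
        idx = selection_index(standardize_bv(bv, sds), state.index_weights)
        method = f"index_{bv['tag'].iloc[0]}"
    else:
        idx = pd.Series(rng.random(len(alive)), index=alive["id"].to_numpy())
        method = "random"

    prev_parents = set()
    for h in state.selection_history:
        prev_parents.update(h["sires"])
        prev_parents.update(h["dams"])

    def choose(n: int, sex: str) -> list:
        pool = alive[alive["sex"] == sex]
        n_repeat = int(round(cfg.repeat_spawner_fraction * n)) if prev_parents else 0
        chosen: list = []
        if n_repeat:
            repeat_pool = pool[pool["id"].isin(prev_parents)]
            if len(repeat_pool):
                s, d = (select_parents(repeat_pool, idx, min(n_repeat, len(repeat_pool)), 0,
                                       current_year=year, male_min_age=cfg.male_min_age,
                                       female_min_age=cfg.female_min_age,
                                       max_age=cfg.max_parent_age)
                        if sex == "M" else
                        select_parents(repeat_pool, idx, 0, min(n_repeat, len(repeat_pool)),
                                       current_year=year, male_min_age=cfg.male_min_age,
                                       female_min_age=cfg.female_min_age,
                                       max_age=cfg.max_parent_age))
                chosen = s if sex == "M" else d
        rest_pool = pool[~pool["id"].isin(chosen)]
        need = n - len(chosen)
        s, d = (select_parents(rest_pool, idx, need, 0, current_year=year,
                               male_min_age=cfg.male_min_age,
                               female_min_age=cfg.female_min_age,
                               max_age=cfg.max_parent_age)
                if sex == "M" else
                select_parents(rest_pool, idx, 0, need, current_year=year,
                               male_min_age=cfg.male_min_age,
                               female_min_age=cfg.female_min_age,
                               max_age=cfg.max_parent_age))
        return chosen + (s if sex == "M" else d)

    return choose(n_sires, "M"), choose(n_dams, "F"), method


def simulate_breeding_cycle(config: SimulationConfig,
                            trait_model: TraitModel | None = None,
                            scheme: str = "genomic",
                            selection: str = "index",
                            index_weights: Mapping[str, float] | None = None,
                            evaluate_both_at_spawning: bool = False) -> SimulationState:
    """Run the year-class loop under a pedigree-only or genomic scheme.

    ``scheme`` decides the relationship matrix used for mid-cycle
    evaluations (A for ``pedigree_only``, H for ``genomic``) and whether
    candidates are genotyped.  ``selection='random'`` disables selection
    (null runs).  Deterministic given ``config.seed``.
    """
    if scheme not in ("pedigree_only", "genomic"):
        raise ValueError("scheme must be 'pedigree_only' or 'genomic'")
    tm = trait_model if trait_model is not None else weight_trait_model()
    marker_map = simulate_genome(config)
    freqs = founder_allele_freqs(marker_map, config)
    founders = simulate_founders(marker_map, config, freqs=freqs)
    effects = draw_qtl_effects(marker_map, founders, tm, config.rng("qtl"))
    qtl = marker_map.qtl_indices
    founder_qtl_freqs = founders.dosages()[:, qtl].mean(axis=0) / 2.0
    founder_qtl_freqs = np.clip(founder_qtl_freqs, 1e-6, 1 - 1e-6)

    sex_rng = config.rng("sex")
    n_f = config.n_founders
    # stagger founder year classes so both sexes are age-eligible from year 1
    span = max(config.female_min_age, 1)
    founder_yc = 1 - config.female_min_age - (np.arange(n_f) % span)
    # founders arrive sexed: balanced broodstock, randomly ordered
    sexes = sex_rng.permutation(np.array(["M", "F"]).repeat((n_f + 1) // 2)[:n_f])
    ped = pd.DataFrame({
        "id": founders.ids, "sire": None, "dam": None, "sex": sexes,
        "year_class": founder_yc, "family": [f"founder|{i}" for i in founders.ids],
        "alive": True,
    })
    tbv = true_breeding_values(founders, marker_map, effects, founder_qtl_freqs, tm)
    state = SimulationState(
        config=config, trait_model=tm, scheme=scheme, marker_map=marker_map,
        qtl_effects=effects, founder_qtl_freqs=founder_qtl_freqs, pedigree=ped,
        haplotypes=founders, true_bv=tbv,
        phenotypes=pd.DataFrame(columns=["id", "trait", "value", "cohort",
                                         "family", "environment", "year_class"]),
        genotypes=None,
        index_weights=dict(index_weights) if index_weights else _default_index_weights(tm),
    )

    n_per_family = max(1, config.pooled_progeny_per_year // config.families_per_year)
    marker_ids = list(marker_map.marker_ids)
    gmeans = []
    for year in range(1, config.n_year_classes + 1):
        sel_rng = config.rng(f"select_{year}")
        sires, dams, method = _select(state, year, sel_rng, selection,
                                      evaluate_both_at_spawning)
        matings = mate_partial_factorial(sires, dams, config.families_per_year,
                                         config.rng(f"mate_{year}"))
        # sample candidates from the pooled progeny: per-family counts are
        # multivariate hypergeometric (simple random sampling of the pool)
        n_sample = min(config.progeny_genotyped_per_year,
                       config.families_per_year * n_per_family)
        samp_rng = config.rng(f"sample_{year}")
        pool_fams = np.repeat(np.arange(config.families_per_year), n_per_family)
        take = samp_rng.permutation(pool_fams)[:n_sample]
        fam_counts = np.bincount(take, minlength=config.families_per_year)

        prog_rng = config.rng(f"meiosis_{year}")
        parent_haps = state.haplotypes.subset_ids(sorted(set(sires) | set(dams)))
        fam_haps, fam_rows = [], []
        for f_i in range(len(matings)):
            if fam_counts[f_i] == 0:
                continue
            sub = matings.iloc[[f_i]]
            hs, rows = make_progeny(
                sub, parent_haps, marker_map, int(fam_counts[f_i]), prog_rng,
                recombination_rate_cM_per_Mbp=config.recombination_rate_cM_per_Mbp,
                id_prefix=f"Y{year}F{f_i}_")
            fam_haps.append(hs)
            fam_rows.append(rows)
        cohort_haps = fam_haps[0]
        for hs in fam_haps[1:]:
            cohort_haps = cohort_haps.concat(hs)
        cohort_rows = pd.concat(fam_rows, ignore_index=True)

        alloc_rng = config.rng(f"alloc_{year}")
        n_c = len(cohort_haps.ids)
        marine = alloc_rng.random(n_c) < config.marine_fraction
        sexes_c = np.where(alloc_rng.random(n_c) < 0.5, "M", "F")
        cohort_ped = pd.DataFrame({
            "id": cohort_rows["id"], "sire": cohort_rows["sire"],
            "dam": cohort_rows["dam"], "sex": sexes_c, "year_class": year,
            "family": cohort_rows["sire"].astype(str) + "|" + cohort_rows["dam"].astype(str),
            "alive": ~marine,  # marine fish are harvested, not broodstock
        })
        state.pedigree = pd.concat([state.pedigree, cohort_ped], ignore_index=True)
        state.haplotypes = state.haplotypes.concat(cohort_haps)

        tbv_c = true_breeding_values(cohort_haps, marker_map, effects,
                                     founder_qtl_freqs, tm)
        state.true_bv = pd.concat([state.true_bv, tbv_c])
        allocation = pd.Series(np.where(marine, "marine", "fresh"),
                               index=cohort_haps.ids)
        cohort_lab = pd.Series([f"yc{year}_{e}" for e in allocation],
                               index=cohort_haps.ids)
        phen = simulate_phenotypes(
            tbv_c, cohort_ped.set_index("id")["family"], allocation, cohort_lab,
            tm, config.rng(f"phen_{year}"),
            cohort_effect_sd=config.cohort_effect_sd)
        phen["year_class"] = year
        state.phenotypes = (phen if state.phenotypes.empty else
                            pd.concat([state.phenotypes, phen], ignore_index=True))

        if scheme == "genomic":
            assay_rng = config.rng(f"assay_{year}")
            to_geno = list(cohort_haps.ids) + [
                p for p in set(sires) | set(dams)
                if state.genotypes is None or p not in set(state.genotypes.ids)]
            gtrue = state.haplotypes.subset_ids(
                list(dict.fromkeys(to_geno))).to_genotypes(marker_ids)
            observed = simulate_assay(gtrue, marker_ids, config.hd_missing_rate,
                                      config.hd_error_rate, assay_rng, assay="HD")
            if state.genotypes is None:
                state.genotypes = observed
            else:
                merged = np.vstack([state.genotypes.dosages, observed.dosages])
                state.genotypes = GenotypeMatrix(
                    state.genotypes.ids + observed.ids, marker_ids, merged, assay="HD")

        gmeans.append({"year_class": year,
                       **{t: float(tbv_c[t].mean()) for t in tm.traits}})
        state.selection_history.append({
            "year": year, "method": method, "sires": list(sires),
            "dams": list(dams), "n_candidates": n_c})

    state.genetic_mean = pd.DataFrame(gmeans)
    return state


def final_evaluations(state: SimulationState, compute_se: bool = True,
                      se_ids=None) -> pd.DataFrame:
    """Post-program evaluation with all phenotypes (the 'updated' run).

    Returns stacked EBV and GEBV tables (GEBV only when genotypes exist),
    with standard errors when requested — the substrate for choosing the
    best estimate of the true breeding value in validation.
    """
    year = state.config.n_year_classes + 1
    tables = [evaluate_at_year(state, year, "A", compute_se=compute_se, se_ids=se_ids)]
    if state.genotypes is not None:
        tables.append(evaluate_at_year(state, year, "H", compute_se=compute_se,
                                se_ids=se_ids))
    return pd.concat(tables, ignore_index=True)


def true_index(state: SimulationState) -> pd.Series:
    """Index computed from true breeding values in genetic-SD units."""
    sds = dict(zip(state.trait_model.traits, state.trait_model.genetic_sd))
    w = {t: v for t, v in state.index_weights.items() if v > 0}
    total = sum(w.values())
    idx = pd.Series(0.0, index=state.true_bv.index)
    for t, v in w.items():
        idx = idx + (v / total) * state.true_bv[t] / sds[t]
    return idx


def _index_gain(state: SimulationState) -> float:
    """Cumulative true-index gain from first to last year class."""
    idx = true_index(state)
    ped = state.pedigree.set_index("id")
    df = pd.DataFrame({"bv": idx, "year_class": ped.loc[idx.index, "year_class"],
                       "trait": "INDEX"}).reset_index(names="id")
    df = df[df["year_class"] >= 1]
    gains = genetic_gain(df, baseline_year=1)
    return float(gains.loc[gains["trait"] == "INDEX", "cumulative_gain"].iloc[0])


def compare_schemes(config: SimulationConfig,
                    trait_model: TraitModel | None = None,
                    index_weights: Mapping[str, float] | None = None,
                    n_replicates: int = 20, seed: int = 0,
                    selection: str = "index") -> dict:
    """Paired genomic vs pedigree-only comparison over replicate programs.

    Each replicate runs both schemes from the same founders and seeds and
    records the cumulative true-index gain.  Reports per-replicate gains,
    the paired one-sided test that genomic gain exceeds pedigree gain, the
    mean gain difference with a t-interval, and a bootstrap percentile CI
    for the ratio of mean gains.
    """
    rows = []
    for k in range(n_replicates):
        cfg_k = replace(config, seed=(seed * 100_003 + k) % (2**31 - 1))
        gains = {}
        for scheme in ("genomic", "pedigree_only"):
            st = simulate_breeding_cycle(cfg_k, trait_model, scheme=scheme,
                                         selection=selection,
                                         index_weights=index_weights)
            gains[scheme] = _index_gain(st)
        rows.append({"replicate": k, "gain_genomic": gains["genomic"],
                     "gain_pedigree": gains["pedigree_only"],
                     "difference": gains["genomic"] - gains["pedigree_only"]})
    reps = pd.DataFrame(rows)
    diff = reps["difference"].to_numpy()
    if np.std(diff, ddof=1) == 0:
        # degenerate paired design (e.g. selection off: runs are identical)
        p_value = 1.0 if diff.mean() <= 0 else 0.0
        diff_ci = (float(diff.mean()), float(diff.mean()))
    else:
        tstat = stats.ttest_rel(reps["gain_genomic"], reps["gain_pedigree"],
                                alternative="greater")
        p_value = float(tstat.pvalue)
        diff_ci = tuple(stats.t.interval(0.95, len(reps) - 1, loc=diff.mean(),
                                         scale=stats.sem(diff)))
    # bootstrap CI for the ratio of mean gains
    boot_rng = np.random.default_rng(seed + 7)
    ratios = []
    n = len(reps)
    for _ in range(2000):
        pick = boot_rng.integers(0, n, size=n)
        denom = reps["gain_pedigree"].to_numpy()[pick].mean()
        num = reps["gain_genomic"].to_numpy()[pick].mean()
        ratios.append(num / denom if denom != 0 else np.inf)
    ratios = np.array(ratios)
    finite = ratios[np.isfinite(ratios)]
    lo, hi = (np.percentile(finite, [2.5, 97.5]) if len(finite) else (np.nan, np.nan))
    mean_ped = reps["gain_pedigree"].mean()
    summary = {
        "mean_gain_genomic": float(reps["gain_genomic"].mean()),
        "mean_gain_pedigree": float(mean_ped),
        "mean_difference": float(diff.mean()),
        "difference_ci": diff_ci,
        "p_one_sided": p_value,
        "gain_ratio": float(reps["gain_genomic"].mean() / mean_ped) if mean_ped else np.nan,
        "ratio_ci": (float(lo), float(hi)),
    }
    return {"replicates": reps, "summary": summary}
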