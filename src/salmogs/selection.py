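"""Breeding-value standardisation, selection index, parent selection,
genetic-gain tracking and prediction-accuracy validation.

Breeding values are expressed in genetic standard deviations before
indexing.  The index combines standardised trait breeding values with the
program's selection pressures (acquired AGD resistance 38%, harvest weight
25%, innate AGD resistance 13%, maturation 13%, flesh colour 13%; monitor
traits carry zero weight), normalised to sum to one.  Validation compares
the at-spawning EBV and GEBV of parents with the updated breeding value
two program-years later — the run with the lowest standard errors serving
as the closest estimate of the true breeding value — using Spearman rank
correlations.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "DEFAULT_INDEX_WEIGHTS", "standardize_bv", "acquired_agd_bv",
    "selection_index", "select_parents", "genetic_gain", "validate_accuracy",
]

# Selection pressures of the breeding objective (monitor traits weight 0).
DEFAULT_INDEX_WEIGHTS: dict[str, float] = {
    "agd_acquired": 0.38,
    "weight_marine": 0.25,
    "agd_innate": 0.13,
    "maturation_marine": 0.13,
    "color": 0.13,
    "fat": 0.0,
}


def standardize_bv(bvs: pd.DataFrame, genetic_sds: Mapping[str, float]) -> pd.DataFrame:
    """Scale breeding values (and SEs) to genetic-standard-deviation units."""
    out = bvs.copy()
    for trait in out["trait"].unique():
        sd = genetic_sds.get(trait)
        if sd is None:
            raise KeyError(f"no genetic SD supplied for trait {trait!r}")
        if sd <= 0:
            raise ValueError(f"genetic SD for {trait!r} must be positive")
        rows = out["trait"] == trait
        out.loc[rows, "bv"] = out.loc[rows, "bv"] / sd
        if "se" in out.columns:
            out.loc[rows, "se"] = out.loc[rows, "se"] / sd
    return out


def acquired_agd_bv(score_bvs: pd.DataFrame, score_traits: Sequence[str],
                    weights: Sequence[float] | None = None,
                    derived_trait: str = "agd_acquired") -> pd.DataFrame:
    """Derived acquired-resistance breeding value from repeated-score BVs.

    Combines the (standardised) breeding values of the post-naive disease
    scores — resistance at repeat infections — as a weighted linear
    combination (equal weights by default).  Individuals missing every
    component are omitted with a note column in the result.
    """
    if len(score_traits) == 0:
        raise ValueError("need at least one component score trait")
    if weights is None:
        weights = np.full(len(score_traits), 1.0 / len(score_traits))
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(score_traits):
        raise ValueError("weights length must match component traits")
    weights = weights / weights.sum()
    wide = score_bvs[score_bvs["trait"].isin(score_traits)].pivot_table(
        index="id", columns="trait", values="bv")
    wide = wide.reindex(columns=list(score_traits))
    rows = []
    for ind, row in wide.iterrows():
        present = ~row.isna().to_numpy()
        if not present.any():
            rows.append((ind, np.nan, "omitted: no component BVs"))
            continue
        w = weights[present] / weights[present].sum()
        rows.append((ind, float(row.to_numpy()[present] @ w), ""))
    return pd.DataFrame(rows, columns=["id", "bv", "note"]).assign(trait=derived_trait)


def selection_index(standardized_bvs: pd.DataFrame,
                    weights: Mapping[str, float]) -> pd.Series:
    """Index = sum of normalised selection pressures times standardised BVs.

    Traits with zero weight are ignored; individuals missing any weighted
    trait BV are excluded (their index is NaN).
    """
    if any(w < 0 for w in weights.values()):
        raise ValueError("selection pressures must be non-negative")
    active = {t: w for t, w in weights.items() if w > 0}
    total = sum(active.values())
    if total == 0:
        raise ValueError("all index weights are zero")
    norm = {t: w / total for t, w in active.items()}
    wide = standardized_bvs[standardized_bvs["trait"].isin(norm)].pivot_table(
        index="id", columns="trait", values="bv")
    missing_traits = set(norm) - set(wide.columns)
    if missing_traits:
        raise ValueError(f"no breeding values for weighted traits: {sorted(missing_traits)}")
    idx = pd.Series(0.0, index=wide.index)
    for t, w in norm.items():
        idx = idx + w * wide[t]
    return idx.rename("index")


def select_parents(candidates: pd.DataFrame, index: pd.Series,
                   n_sires: int, n_dams: int,
                   max_per_family: int | None = None,
                   current_year: int | None = None,
                   male_min_age: int = 2, female_min_age: int = 3,
                   max_age: int = 6) -> tuple[list, list]:
    """Truncation selection on the index within sex, with a family cap.

    ``candidates`` needs columns id, sex ('M'/'F'), year_class and family.
    Age eligibility applies when ``current_year`` is given: males usable
    from ``male_min_age``, females from ``female_min_age``, both up to
    ``max_age``.  Ties break deterministically by id.
    """
    cand = candidates.copy()
    cand["index"] = cand["id"].map(index)
    cand = cand.dropna(subset=["index"])
    if current_year is not None:
        age = current_year - cand["year_class"].astype(int)
        keep = ((cand["sex"] == "M") & (age >= male_min_age) & (age <= max_age)) | \
               ((cand["sex"] == "F") & (age >= female_min_age) & (age <= max_age))
        cand = cand[keep]

    def pick(sex: str, n: int) -> list:
        if n <= 0:
            return []
        pool = cand[cand["sex"] == sex].sort_values(
            ["index", "id"], ascending=[False, True])
        chosen: list = []
        fam_counts: dict = {}
        for row in pool.itertuples():
            fam = row.family
            if max_per_family is not None and fam_counts.get(fam, 0) >= max_per_family:
                continue
            chosen.append(row.id)
            fam_counts[fam] = fam_counts.get(fam, 0) + 1
            if len(chosen) == n:
                return chosen
        raise ValueError(
            f"cannot select {n} {sex} parents: only {len(chosen)} eligible "
            f"under family cap {max_per_family}")

    return pick("M", n_sires), pick("F", n_dams)


def genetic_gain(bv_by_individual: pd.DataFrame, baseline_year: int,
                 unit_sds: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Cumulative and mean annual genetic gain per trait.

    ``bv_by_individual`` is long format (id, year_class, trait, bv —
    estimated or true breeding values).  Per trait: year-class means,
    cumulative gain = mean(last) - mean(baseline), annual gain = the
    least-squares slope of year-class means on year class.  Gains are
    divided by ``unit_sds`` (genetic SDs) when given.
    """
    years = sorted(bv_by_individual["year_class"].unique())
    if baseline_year not in years:
        raise ValueError(f"baseline year {baseline_year} has no breeding values")
    if len(years) < 2:
        raise ValueError("need at least two year classes")
    rows = []
    for trait, grp in bv_by_individual.groupby("trait"):
        means = grp.groupby("year_class")["bv"].mean()
        sd = unit_sds.get(trait, 1.0) if unit_sds else 1.0
        yrs = means.index.to_numpy(dtype=float)
        slope = float(np.polyfit(yrs, means.to_numpy() / sd, 1)[0])
        cumulative = float((means.loc[years[-1]] - means.loc[baseline_year]) / sd)
        rows.append((trait, cumulative, slope))
    return pd.DataFrame(rows, columns=["trait", "cumulative_gain", "annual_gain"])


def _pick_truth(updated: pd.DataFrame) -> pd.DataFrame:
    """Per id x trait, the updated BV from the run with the lowest SE.

    Ties between EBV and GEBV standard errors resolve in favour of GEBV.
    """
    pref = {"GEBV": 0, "EBV": 1}
    upd = updated.copy()
    upd["_pref"] = upd["tag"].map(pref).fillna(2)
    upd = upd.sort_values(["id", "trait", "se", "_pref"],
                          kind="stable").groupby(["id", "trait"], as_index=False).first()
    return upd[["id", "trait", "bv", "se", "tag"]]


def validate_accuracy(spawning_ebv: pd.DataFrame, spawning_gebv: pd.DataFrame,
                      updated: pd.DataFrame,
                      index_weights: Mapping[str, float] | None = None,
                      genetic_sds: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Prediction-accuracy validation against progeny-updated breeding values.

    For the shared parent set, computes per trait the Spearman correlations
    r(T_hat, GEBV) and r(T_hat, EBV) of at-spawning breeding values with
    the updated best estimate T_hat (lowest-SE run, GEBV preferred on
    ties), plus Delta = r(G) - r(E).  When ``index_weights`` is supplied an
    INDEX row is added, with both at-spawning and updated indices
    recomputed from (standardised) breeding values.
    """
    truth = _pick_truth(updated)
    shared = (set(spawning_ebv["id"]) & set(spawning_gebv["id"]) & set(truth["id"]))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared parents; correlation undefined")
    shared = sorted(shared)

    def wide(df: pd.DataFrame) -> pd.DataFrame:
        return df[df["id"].isin(shared)].pivot_table(index="id", columns="trait",
                                                     values="bv")

    w_truth, w_e, w_g = wide(truth), wide(spawning_ebv), wide(spawning_gebv)
    rows = []
    for trait in sorted(set(w_truth.columns) & set(w_e.columns) & set(w_g.columns)):
        joined = pd.concat([w_truth[trait].rename("t"), w_g[trait].rename("g"),
                            w_e[trait].rename("e")], axis=1).dropna()
        if len(joined) < 3:
            continue
        r_g = float(spearmanr(joined["t"], joined["g"]).statistic)
        r_e = float(spearmanr(joined["t"], joined["e"]).statistic)
        rows.append((trait, r_g, r_e, r_g - r_e, len(joined)))
    if index_weights is not None:
        sds = genetic_sds or {t: 1.0 for t in index_weights}
        idx_t = selection_index(standardize_bv(truth, sds), index_weights)
        idx_g = selection_index(standardize_bv(spawning_gebv, sds), index_weights)
        idx_e = selection_index(standardize_bv(spawning_ebv, sds), index_weights)
        joined = pd.concat([idx_t.rename("t"), idx_g.rename("g"),
                            idx_e.rename("e")], axis=1).dropna()
        if len(joined) >= 3:
            r_g = float(spearmanr(joined["t"], joined["g"]).statistic)
            r_e = float(spearmanr(joined["t"], joined["e"]).statistic)
            rows.append(("INDEX", r_g, r_e, r_g - r_e, len(joined)))
    report = pd.DataFrame(rows, columns=["trait", "r_truth_gebv", "r_truth_ebv",
                                         "delta", "n"])
    return report
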