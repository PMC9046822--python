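"""Henderson mixed-model equations for multi-trait animal models.

The general model is y = X tau + Z_n u_n + Z_g u_g + e with
u_n ~ N(0, I x G_n) (trait-by-family, common environment plus non-additive
effects), u_g ~ N(0, K x G_p) (trait-by-animal additive effects with K the
pedigree matrix A for EBV or the single-step matrix H for GEBV) and
e ~ N(0, R) across the traits recorded on the same individual.  Variance
components are inputs via the TraitModel; no REML is performed here.

Effects are ordered animal-major (all traits of animal 1, then animal 2,
...), so the additive prior precision is K^{-1} x G_p^{-1} as a Kronecker
product in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse import linalg as spla

from .containers import GenotypeMatrix, Pedigree, TraitModel
from .relmat import (a_inverse, genomic_relationship, h_inverse,
                     numerator_relationship, scale_blend_G)

__all__ = [
    "MMESystem", "build_mme", "solve_mme", "prediction_error_variance",
    "EvaluationData", "run_evaluation", "gwas_scan", "MODEL_TRAITS",
]


@dataclass
class MMESystem:
    """Assembled mixed-model equations C x = rhs with block bookkeeping."""

    coeff: sparse.csc_matrix
    rhs: np.ndarray
    fixed_labels: list
    family_ids: list
    animal_ids: list
    traits: tuple[str, ...]
    n_fixed: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_fixed = len(self.fixed_labels)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def family_slice(self) -> slice:
        return slice(self.n_fixed, self.n_fixed + len(self.family_ids) * self.n_traits)

    @property
    def animal_slice(self) -> slice:
        start = self.n_fixed + len(self.family_ids) * self.n_traits
        return slice(start, start + len(self.animal_ids) * self.n_traits)

    def animal_solutions(self, solution: np.ndarray) -> pd.DataFrame:
        block = solution[self.animal_slice].reshape(len(self.animal_ids), self.n_traits)
        return pd.DataFrame(block, index=self.animal_ids, columns=list(self.traits))


def _residual_precision_blocks(phenotypes: pd.DataFrame, traits: Sequence[str],
                               R: np.ndarray) -> sparse.csc_matrix:
    """Sparse R^{-1} over observations, block-diagonal by individual.

    Residuals of different traits on the same individual covary per R;
    repeated records of the same trait are residual-independent.
    """
    t_index = {t: i for i, t in enumerate(traits)}
    n_obs = len(phenotypes)
    rows, cols, vals = [], [], []
    obs_trait = phenotypes["trait"].map(t_index).to_numpy()
    for _, grp in phenotypes.groupby("id", sort=False).indices.items():
        obs = np.asarray(grp)
        tt = obs_trait[obs]
        k = len(obs)
        block = np.zeros((k, k))
        for a in range(k):
            block[a, a] = R[tt[a], tt[a]]
            for b in range(a + 1, k):
                if tt[a] != tt[b]:
                    block[a, b] = block[b, a] = R[tt[a], tt[b]]
        binv = np.linalg.inv(block)
        rows.extend(np.repeat(obs, k))
        cols.extend(np.tile(obs, k))
        vals.extend(binv.ravel())
    return sparse.csc_matrix(sparse.coo_matrix((vals, (rows, cols)),
                                               shape=(n_obs, n_obs)))


def build_mme(phenotypes: pd.DataFrame, trait_model: TraitModel,
              K_inv: sparse.spmatrix | np.ndarray, animal_ids: Sequence,
              fixed: str = "cohort", family_effect: bool = True) -> MMESystem:
    """Assemble Henderson's equations for the stacked multi-trait model.

    ``phenotypes`` is long-format with columns id, trait, value, and the
    ``fixed`` grouping column (trait-by-group fixed effects, e.g. cohort)
    plus ``family`` when ``family_effect`` is on.  ``K_inv`` is the inverse
    relationship matrix over ``animal_ids`` (A^{-1} or H^{-1}).  Every
    phenotyped individual must appear in ``animal_ids``.
    """
    traits = trait_model.traits
    known_traits = set(traits)
    bad = set(phenotypes["trait"]) - known_traits
    if bad:
        raise ValueError(f"phenotype traits not in model: {sorted(bad)}")
    animal_index = {v: i for i, v in enumerate(animal_ids)}
    missing = [i for i in phenotypes["id"].unique() if i not in animal_index]
    if missing:
        raise ValueError(f"phenotyped individuals absent from K: {missing[:5]}")
    t = len(traits)
    t_index = {tr: i for i, tr in enumerate(traits)}
    n_obs = len(phenotypes)
    y = phenotypes["value"].to_numpy(dtype=float)
    obs_trait = phenotypes["trait"].map(t_index).to_numpy()

    # fixed: one level per (trait, group) cell
    groups = phenotypes[fixed].astype(str).to_numpy()
    fixed_labels = sorted({(traits[tt], g) for tt, g in zip(obs_trait, groups)})
    f_index = {lab: i for i, lab in enumerate(fixed_labels)}
    x_cols = np.array([f_index[(traits[tt], g)] for tt, g in zip(obs_trait, groups)])
    X = sparse.csc_matrix((np.ones(n_obs), (np.arange(n_obs), x_cols)),
                          shape=(n_obs, len(fixed_labels)))

    blocks = [X]
    family_ids: list = []
    if family_effect:
        if "family" not in phenotypes.columns:
            raise ValueError("family_effect requested but no 'family' column")
        family_ids = sorted(map(str, set(phenotypes["family"].astype(str))))
        fam_index = {f: i for i, f in enumerate(family_ids)}
        zn_cols = np.array([fam_index[f] * t + tt for f, tt in
                            zip(phenotypes["family"].astype(str), obs_trait)])
        Zn = sparse.csc_matrix((np.ones(n_obs), (np.arange(n_obs), zn_cols)),
                               shape=(n_obs, len(family_ids) * t))
        blocks.append(Zn)
    zg_cols = np.array([animal_index[i] * t + tt for i, tt in
                        zip(phenotypes["id"], obs_trait)])
    Zg = sparse.csc_matrix((np.ones(n_obs), (np.arange(n_obs), zg_cols)),
                           shape=(n_obs, len(animal_ids) * t))
    blocks.append(Zg)
    W = sparse.hstack(blocks, format="csc")

    r_inv = _residual_precision_blocks(phenotypes, traits, trait_model.R)
    rhs = W.T @ (r_inv @ y)

    gp_inv = np.linalg.inv(trait_model.G_p)
    prior_blocks = [sparse.csc_matrix((len(fixed_labels), len(fixed_labels)))]
    if family_effect and family_ids:
        gn_inv = np.linalg.inv(trait_model.G_n)
        prior_blocks.append(sparse.kron(sparse.eye(len(family_ids)), gn_inv, format="csc"))
    prior_blocks.append(sparse.kron(sparse.csc_matrix(K_inv), gp_inv, format="csc"))
    prior = sparse.block_diag(prior_blocks, format="csc")
    C = sparse.csc_matrix(W.T @ r_inv @ W + prior)
    return MMESystem(C, rhs, list(fixed_labels), family_ids,
                     list(animal_ids), traits)


def solve_mme(system: MMESystem, method: str = "direct",
              tol: float = 1e-10) -> np.ndarray:
    """Solve the equations directly (sparse LU) or by conjugate gradients."""
    C, rhs = system.coeff, system.rhs
    if method == "direct":
        density = C.nnz / max(1, C.shape[0] ** 2)
        if density > 0.02:  # dense factorization beats sparse LU with fill-in
            sol = np.linalg.solve(C.toarray(), rhs)
        else:
            sol = spla.spsolve(C, rhs)
    elif method == "conjugate_gradient":
        diag = C.diagonal()
        M = sparse.diags(1.0 / np.where(diag > 0, diag, 1.0))
        sol, info = spla.cg(C, rhs, rtol=max(tol, 1e-12), atol=0.0, maxiter=20000, M=M)
        if info != 0:
            raise RuntimeError(f"conjugate gradient did not converge (info={info})")
    else:
        raise ValueError("method must be 'direct' or 'conjugate_gradient'")
    resid = np.linalg.norm(C @ sol - rhs)
    if resid > max(tol, 1e-8) * max(1.0, np.linalg.norm(rhs)):
        raise RuntimeError(f"MME solution residual too large: {resid:.3g}")
    return sol


def prediction_error_variance(system: MMESystem,
                              ids: Sequence | None = None) -> pd.DataFrame:
    """Standard errors of breeding values from the inverse coefficient matrix.

    SE(i, t) = sqrt([C^{-1}]_{(i,t),(i,t)}) on the animal block — the MME are
    assembled with the actual (co)variances, so the diagonal of the inverse
    is the prediction error variance directly.  Dense inversion; intended
    for desk-scale systems.
    """
    t = system.n_traits
    start = system.animal_slice.start
    if ids is not None and len(ids) * t < len(system.animal_ids):
        # targeted columns of C^{-1} via one factorization + unit-vector solves
        a_index = {v: i for i, v in enumerate(system.animal_ids)}
        cols = np.array([start + a_index[i] * t + k for i in ids for k in range(t)])
        n_eq = system.coeff.shape[0]
        density = system.coeff.nnz / max(1, n_eq ** 2)
        E = np.zeros((n_eq, len(cols)))
        E[cols, np.arange(len(cols))] = 1.0
        try:
            if density > 0.02:
                from scipy.linalg import cho_factor, cho_solve
                sols = cho_solve(cho_factor(system.coeff.toarray()), E)
            else:
                sols = spla.splu(system.coeff).solve(E)
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            raise ValueError("indefinite or singular MME system") from exc
        pev = sols[cols, np.arange(len(cols))]
        if np.any(pev < -1e-8):
            raise ValueError("indefinite system: negative prediction error variance")
        block = np.sqrt(np.maximum(pev, 0.0)).reshape(len(ids), t)
        return pd.DataFrame(block, index=list(ids), columns=list(system.traits))
    try:
        c_inv = np.linalg.inv(system.coeff.toarray())
    except np.linalg.LinAlgError as exc:
        raise ValueError("indefinite or singular MME system") from exc
    pev = np.diag(c_inv)[system.animal_slice]
    if np.any(pev < -1e-8):
        raise ValueError("indefinite system: negative prediction error variance")
    block = np.sqrt(np.maximum(pev, 0.0)).reshape(len(system.animal_ids), t)
    out = pd.DataFrame(block, index=system.animal_ids, columns=list(system.traits))
    if ids is not None:
        out = out.loc[list(ids)]
    return out


# ---------------------------------------------------------------------------
# evaluation driver

MODEL_TRAITS = {
    "AGD": ("agd_acquired", "agd_innate"),
    "Weight": ("weight_marine", "weight_fresh"),
    "Maturation": ("maturation_marine", "maturation_fresh",
                   "weight_marine", "weight_fresh"),
    "Quality": ("color", "fat"),
}


@dataclass
class EvaluationData:
    """Bundle of inputs for one breeding-value run."""

    phenotypes: pd.DataFrame
    pedigree: Pedigree
    trait_model: TraitModel
    genotypes: GenotypeMatrix | None = None
    tau: float = 0.05


def _k_inverse(data: EvaluationData, kind: str):
    ped = data.pedigree
    if kind == "A" or data.genotypes is None or data.genotypes.n_individuals == 0:
        return a_inverse(ped)
    if kind != "H":
        raise ValueError("K_kind must be 'A' or 'H'")
    g = data.genotypes
    genotyped = [i for i in ped.ids if i in set(g.ids)]
    if not genotyped:
        return a_inverse(ped)
    gmat = genomic_relationship(g.subset(ids=genotyped))
    A = numerator_relationship(ped)
    A22 = A.submatrix(genotyped)
    gstar = scale_blend_G(gmat, A22, tau=data.tau)
    positions = np.array([ped.index_of(i) for i in genotyped])
    return h_inverse(a_inverse(ped), gstar, A22, positions)


def run_evaluation(data: EvaluationData, model_name, K_kind: str = "A",
                   evaluation_year: int | None = None,
                   compute_se: bool = False, se_ids: Sequence | None = None,
                   method: str = "direct") -> pd.DataFrame:
    """One breeding-value production run.

    ``model_name`` selects a configured trait set (the named multi-trait
    models, or any single trait name present in the trait model).  The same
    model is solved with K = A (tag EBV) or K = H (tag GEBV), keeping pre-
    and post-genomic breeding values directly comparable.  Returns a
    BreedingValueTable: id, trait, bv, se, tag, year.
    """
    if isinstance(model_name, (list, tuple)):
        traits = [t for t in model_name if t in data.trait_model.traits]
    elif model_name in MODEL_TRAITS:
        traits = [t for t in MODEL_TRAITS[model_name] if t in data.trait_model.traits]
    elif model_name in data.trait_model.traits:
        traits = [model_name]
    else:
        raise ValueError(f"unknown model {model_name!r}")
    missing = [t for t in traits if t not in set(data.phenotypes["trait"])]
    if not traits or len(missing) == len(traits):
        raise ValueError(f"no phenotype records for model {model_name!r}")
    sub_model = data.trait_model.subset(traits)
    phen = data.phenotypes[data.phenotypes["trait"].isin(traits)].reset_index(drop=True)
    k_inv = _k_inverse(data, K_kind)
    system = build_mme(phen, sub_model, k_inv, data.pedigree.ids)
    sol = solve_mme(system, method=method)
    bv = system.animal_solutions(sol)
    tag = "GEBV" if (K_kind == "H" and data.genotypes is not None
                     and data.genotypes.n_individuals > 0) else "EBV"
    se = prediction_error_variance(system, ids=se_ids) if compute_se else None
    rows = []
    for i in system.animal_ids:
        for t in traits:
            has_se = se is not None and i in se.index
            rows.append((i, t, float(bv.loc[i, t]),
                         float(se.loc[i, t]) if has_se else np.nan,
                         tag, evaluation_year))
    return pd.DataFrame(rows, columns=["id", "trait", "bv", "se", "tag", "year"])


# ---------------------------------------------------------------------------
# GWAS screen


def gwas_scan(phenotypes: pd.DataFrame, genotypes: GenotypeMatrix,
              trait: str, fixed: str | None = "cohort") -> pd.DataFrame:
    """Single-marker regression screen for large-effect QTL.

    Phenotype and dosage are residualised on the fixed covariate groups,
    then each marker is tested by OLS of phenotype on dosage.  Intended as
    a screen (no kinship correction); a Bonferroni threshold over tested
    markers is included in the output attributes.
    """
    phen = phenotypes[phenotypes["trait"] == trait]
    ids = [i for i in phen["id"] if i in set(genotypes.ids)]
    phen = phen.set_index("id").loc[ids]
    g = genotypes.subset(ids=ids)
    y = phen["value"].to_numpy(dtype=float)
    if fixed is not None and fixed in phen.columns:
        for _, grp in phen.groupby(fixed).indices.items():
            y[np.asarray(grp)] -= y[np.asarray(grp)].mean()
    else:
        y = y - y.mean()
    n = len(y)
    results = []
    for k, marker in enumerate(g.marker_ids):
        x = g.dosages[:, k]
        ok = ~np.isnan(x)
        xx, yy = x[ok], y[ok]
        if len(xx) < 3 or xx.std() == 0:
            results.append((marker, np.nan, np.nan, np.nan, "monomorphic_or_sparse"))
            continue
        xc = xx - xx.mean()
        beta = float(xc @ yy / (xc @ xc))
        resid = yy - yy.mean() - beta * xc
        dof = len(xx) - 2
        se = np.sqrt((resid @ resid) / dof / (xc @ xc))
        tstat = beta / se if se > 0 else np.inf
        p = 2 * stats.t.sf(abs(tstat), dof)
        results.append((marker, beta, tstat, p, "ok"))
    out = pd.DataFrame(results, columns=["marker_id", "effect", "t", "p", "note"])
    n_tested = int((out["note"] == "ok").sum())
    out.attrs["bonferroni_threshold"] = 0.05 / max(n_tested, 1)
    return out
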