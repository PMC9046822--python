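"""Core in-memory containers shared across the pipeline.

All genotype dosages are stored as float arrays coded 0/1/2 with ``nan``
for missing calls, individuals in rows and markers in columns.  Pedigrees
are kept topologically ordered (parents before offspring) so that the
tabular relationship-matrix recursions can run in a single pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "HaplotypeSet",
    "GenotypeMatrix",
    "Pedigree",
    "TraitModel",
    "default_trait_model",
    "weight_trait_model",
]

MISSING = np.nan


def _check_unique(values: Sequence, what: str) -> None:
    if len(set(values)) != len(values):
        raise ValueError(f"{what} must be unique")


@dataclass(frozen=True)
class MarkerMap:
    """Genome coordinates and functional roles for a set of SNP loci.

    Parameters
    ----------
    table:
        One row per marker with columns ``marker_id``, ``chromosome``
        (integer, >= 1), ``position_bp`` (1-based, strictly increasing
        within a chromosome) and ``role`` (``neutral``, ``qtl`` or
        ``trait_associated``).
    """

    table: pd.DataFrame

    _ROLES = ("neutral", "qtl", "trait_associated")

    def __post_init__(self) -> None:
        required = {"marker_id", "chromosome", "position_bp", "role"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"marker map missing columns: {sorted(missing)}")
        _check_unique(list(self.table["marker_id"]), "marker ids")
        if (self.table["chromosome"] < 1).any() or (self.table["position_bp"] < 1).any():
            raise ValueError("chromosome and position_bp must be >= 1")
        bad_roles = set(self.table["role"]) - set(self._ROLES)
        if bad_roles:
            raise ValueError(f"unknown marker roles: {sorted(bad_roles)}")
        for _, grp in self.table.groupby("chromosome"):
            pos = grp["position_bp"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError("positions must be strictly increasing within chromosome")
        self.table.reset_index(drop=True, inplace=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["position_bp"].to_numpy()

    @property
    def qtl_indices(self) -> np.ndarray:
        return np.flatnonzero((self.table["role"] == "qtl").to_numpy())

    def indices_of(self, marker_ids: Iterable[str]) -> np.ndarray:
        lookup = {m: i for i, m in enumerate(self.marker_ids)}
        try:
            return np.array([lookup[m] for m in marker_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"marker {exc.args[0]!r} not in map") from exc

    def subset(self, indices: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.iloc[np.sort(indices)].reset_index(drop=True))


@dataclass
class HaplotypeSet:
    """Phased biallelic haplotypes, shape ``(n_individuals, 2, n_markers)``."""

    ids: list[str]
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, m)")
        if self.haplotypes.shape[0] != len(self.ids):
            raise ValueError("id count does not match haplotype count")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("haplotype alleles must be 0/1")
        _check_unique(self.ids, "individual ids")

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[2]

    def dosages(self) -> np.ndarray:
        """Genotype dosages (sum of the two phased alleles), ``(n, m)`` float."""
        return self.haplotypes.sum(axis=1).astype(float)

    def to_genotypes(self, marker_ids: Sequence[str], assay: str = "true") -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.ids), list(marker_ids), self.dosages(), assay=assay)

    def subset_ids(self, ids: Sequence[str]) -> "HaplotypeSet":
        index = {v: i for i, v in enumerate(self.ids)}
        rows = [index[i] for i in ids]
        return HaplotypeSet(list(ids), self.haplotypes[rows])

    def concat(self, other: "HaplotypeSet") -> "HaplotypeSet":
        return HaplotypeSet(self.ids + other.ids, np.concatenate([self.haplotypes, other.haplotypes]))


@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x markers) in {0, 1, 2, nan}."""

    ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    assay: str = "HD"

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.marker_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.ids)} ids x {len(self.marker_ids)} markers"
            )
        with np.errstate(invalid="ignore"):
            ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or nan")
        _check_unique(self.ids, "individual ids")
        _check_unique(self.marker_ids, "marker ids")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def marker_call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=0)

    def individual_call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Per-marker alt-allele frequency over non-missing calls (nan if none)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset(self, ids: Sequence[str] | None = None,
               marker_ids: Sequence[str] | None = None) -> "GenotypeMatrix":
        row_idx = np.arange(self.n_individuals)
        col_idx = np.arange(self.n_markers)
        out_ids, out_markers = list(self.ids), list(self.marker_ids)
        if ids is not None:
            index = {v: i for i, v in enumerate(self.ids)}
            row_idx = np.array([index[i] for i in ids], dtype=int)
            out_ids = list(ids)
        if marker_ids is not None:
            index = {v: i for i, v in enumerate(self.marker_ids)}
            col_idx = np.array([index[m] for m in marker_ids], dtype=int)
            out_markers = list(marker_ids)
        return GenotypeMatrix(out_ids, out_markers,
                              self.dosages[np.ix_(row_idx, col_idx)], assay=self.assay)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.ids), list(self.marker_ids),
                              self.dosages.copy(), assay=self.assay)


class Pedigree:
    """Pedigree with sire/dam links, sex and year class, topologically ordered.

    Unknown parents are ``None``.  Construction sorts individuals so that
    every parent precedes its offspring and raises on cycles.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"id", "sire", "dam"}
        if required - set(table.columns):
            raise ValueError("pedigree needs columns id, sire, dam")
        table = table.copy()
        for col in ("sex", "year_class"):
            if col not in table.columns:
                table[col] = None
        table["sire"] = table["sire"].where(pd.notna(table["sire"]), None)
        table["dam"] = table["dam"].where(pd.notna(table["dam"]), None)
        _check_unique(list(table["id"]), "pedigree ids")
        self.table = self._toposort(table)
        self._index = {v: i for i, v in enumerate(self.table["id"])}

    @staticmethod
    def _toposort(table: pd.DataFrame) -> pd.DataFrame:
        ids = list(table["id"])
        known = set(ids)
        parents = {row.id: [p for p in (row.sire, row.dam) if p is not None and p in known]
                   for row in table.itertuples()}
        order: list = []
        seen: dict = {}

        def visit(node, stack):
            state = seen.get(node)
            if state == 2:
                return
            if state == 1:
                raise ValueError(f"pedigree cycle involving {node!r}")
            seen[node] = 1
            for p in parents[node]:
                visit(p, stack)
            seen[node] = 2
            order.append(node)

        for node in ids:
            visit(node, [])
        pos = {v: i for i, v in enumerate(order)}
        return table.sort_values("id", key=lambda s: s.map(pos)).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list:
        return list(self.table["id"])

    def index_of(self, individual_id) -> int:
        return self._index[individual_id]

    def parent_indices(self) -> np.ndarray:
        """(n, 2) array of sire/dam row indices, -1 for unknown."""
        out = np.full((len(self), 2), -1, dtype=int)
        for i, row in enumerate(self.table.itertuples()):
            if row.sire is not None and row.sire in self._index:
                out[i, 0] = self._index[row.sire]
            if row.dam is not None and row.dam in self._index:
                out[i, 1] = self._index[row.dam]
        return out

    def families(self) -> pd.Series:
        """Full-sib family label per individual ('sire|dam'), indexed by id."""
        lab = [
            f"{row.sire}|{row.dam}" if (row.sire is not None or row.dam is not None) else f"founder|{row.id}"
            for row in self.table.itertuples()
        ]
        return pd.Series(lab, index=self.table["id"].to_numpy())

    def subset(self, ids: Sequence) -> "Pedigree":
        keep = set(ids)
        return Pedigree(self.table[self.table["id"].isin(keep)].reset_index(drop=True))


def _check_psd(mat: np.ndarray, name: str, tol: float = 1e-8) -> None:
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -tol * max(1.0, abs(w.max())):
        raise ValueError(f"{name} must be positive semi-definite (min eig {w.min():.3g})")


@dataclass(frozen=True)
class TraitModel:
    """Multi-trait variance structure driving simulation and evaluation.

    ``G_p`` is the additive genetic covariance across traits, ``G_n`` the
    non-genetic (full-sib family / common-environment) covariance and ``R``
    the residual covariance.  With phenotypic variances normalised to
    diag(G_p + G_n + R), heritabilities are diag(G_p) over that total.
    ``environment`` maps each trait to 'marine' or 'fresh'; marine traits
    are expressed only on sea-transferred animals, fresh traits only on
    broodstock candidates.
    """

    traits: tuple[str, ...]
    G_p: np.ndarray
    G_n: np.ndarray
    R: np.ndarray
    environment: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = len(self.traits)
        for name in ("G_p", "G_n", "R"):
            mat = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, mat)
            if mat.shape != (t, t):
                raise ValueError(f"{name} must be {t}x{t}")
            _check_psd(mat, name)
        h2 = self.h2
        if np.any(h2 <= 0) or np.any(h2 >= 1):
            raise ValueError("each heritability must lie in (0, 1)")
        env = dict(self.environment) or {t_: "marine" for t_ in self.traits}
        bad = set(env.values()) - {"marine", "fresh"}
        if bad:
            raise ValueError(f"unknown environments: {sorted(bad)}")
        object.__setattr__(self, "environment", env)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def phenotypic_variance(self) -> np.ndarray:
        return np.diag(self.G_p) + np.diag(self.G_n) + np.diag(self.R)

    @property
    def h2(self) -> np.ndarray:
        return np.diag(self.G_p) / self.phenotypic_variance

    @property
    def genetic_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.G_p))

    @property
    def genetic_correlations(self) -> np.ndarray:
        sd = self.genetic_sd
        return self.G_p / np.outer(sd, sd)

    def trait_index(self, trait: str) -> int:
        return self.traits.index(trait)

    def subset(self, traits: Sequence[str]) -> "TraitModel":
        idx = [self.trait_index(t) for t in traits]
        sub = np.ix_(idx, idx)
        return TraitModel(tuple(traits), self.G_p[sub], self.G_n[sub], self.R[sub],
                          {t: self.environment[t] for t in traits})


def _model_from_h2(traits: Sequence[str], h2: Sequence[float],
                   genetic_corr: Mapping[tuple[str, str], float],
                   c2: float, environment: Mapping[str, str]) -> TraitModel:
    """Build a TraitModel with unit phenotypic variances from h2 and r_g."""
    t = len(traits)
    h2 = np.asarray(h2, dtype=float)
    G_p = np.diag(h2.astype(float)).copy()
    sd = np.sqrt(h2)
    for (a, b), r in genetic_corr.items():
        i, j = traits.index(a), traits.index(b)
        G_p[i, j] = G_p[j, i] = r * sd[i] * sd[j]
    G_n = np.eye(t) * c2
    R = np.diag(1.0 - h2 - c2)
    return TraitModel(tuple(traits), G_p, G_n, R, environment)


def default_trait_model(c2: float = 0.10) -> TraitModel:
    """The breeding-objective trait set with its published heritabilities.

    Traits and h2: acquired AGD resistance 0.36, innate AGD resistance 0.16,
    harvest weight 0.44, marine maturation 0.20, flesh colour 0.65, flesh fat
    0.28, plus the freshwater expressions of weight and maturation linked to
    their marine counterparts by genetic correlations 0.63 and 0.76.  AGD
    resistance is genetically uncorrelated with the freshwater traits, and
    unreported correlations are set to zero.  Phenotypic variances are
    normalised to 1 with a common-environment fraction ``c2`` per trait.
    """
    traits = ("agd_acquired", "agd_innate", "weight_marine", "weight_fresh",
              "maturation_marine", "maturation_fresh", "color", "fat")
    h2 = (0.36, 0.16, 0.44, 0.44, 0.20, 0.20, 0.65, 0.28)
    rg = {("weight_marine", "weight_fresh"): 0.63,
          ("maturation_marine", "maturation_fresh"): 0.76}
    env = {"agd_acquired": "marine", "agd_innate": "marine",
           "weight_marine": "marine", "weight_fresh": "fresh",
           "maturation_marine": "marine", "maturation_fresh": "fresh",
           "color": "marine", "fat": "marine"}
    return _model_from_h2(traits, h2, rg, c2, env)


def weight_trait_model(h2: float = 0.44, r_g: float = 0.63, c2: float = 0.10) -> TraitModel:
    """Two-trait harvest-weight model (marine + freshwater expression).

    The workhorse for scaled simulation experiments: the marine trait is the
    phenotyped sib-test trait, the freshwater trait is measured on broodstock
    candidates, and the two are linked by genetic correlation ``r_g``.
    """
    traits = ("weight_marine", "weight_fresh")
    return _model_from_h2(traits, (h2, h2), {traits: r_g}, c2,
                          {"weight_marine": "marine", "weight_fresh": "fresh"})
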