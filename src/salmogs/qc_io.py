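"""File formats, two-level genotype QC, Mendelian checks and parentage.

Formats are deliberately simple and text-based: genotypes as TSV
(individuals x markers, NA for missing) or minimal biallelic-SNV VCF,
pedigree and phenotypes as CSV, marker maps as TSV.  QC follows the
two-level workflow used in production: *basic* QC removes failing markers
but keeps every individual so that parentage can be assigned for as many
animals as possible; *full* QC also removes low-call-rate individuals
before breeding-value production.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MarkerMap, Pedigree

__all__ = [
    "read_genotypes", "write_genotypes", "read_pedigree", "write_pedigree",
    "read_marker_map", "write_marker_map", "read_phenotypes", "write_phenotypes",
    "QCReport", "qc_filter", "mendelian_error_check", "assign_parentage",
]


# ---------------------------------------------------------------------------
# readers / writers


def write_genotypes(g: GenotypeMatrix, path: str, fmt: str = "tsv",
                    marker_map: MarkerMap | None = None) -> None:
    if fmt == "tsv":
        df = pd.DataFrame(g.dosages, index=g.ids, columns=g.marker_ids)
        df.index.name = "id"
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")
    elif fmt == "vcf":
        if marker_map is None:
            raise ValueError("VCF output requires a marker map")
        _write_vcf(g, marker_map, path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


def read_genotypes(path: str, fmt: str = "tsv", assay: str = "HD") -> GenotypeMatrix:
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty genotype file: {path}")
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return GenotypeMatrix(list(df.index.astype(str)), list(df.columns),
                              df.to_numpy(dtype=float), assay=assay)
    if fmt == "vcf":
        return _read_vcf(path, assay=assay)
    raise ValueError(f"unknown genotype format {fmt!r}")


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def _write_vcf(g: GenotypeMatrix, marker_map: MarkerMap, path: str) -> None:
    """Minimal biallelic-SNV VCF with GT-only genotypes, 1-based positions."""
    idx = marker_map.indices_of(g.marker_ids)
    chroms = marker_map.chromosomes[idx]
    pos = marker_map.positions[idx]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(set(int(c) for c in chroms)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(i) for i in g.ids) + "\n")
        for k, marker in enumerate(g.marker_ids):
            calls = "\t".join(
                "./." if np.isnan(d) else _GT_CODE[d] for d in g.dosages[:, k])
            fh.write(f"{chroms[k]}\t{pos[k]}\t{marker}\tA\tG\t.\t.\t.\tGT\t{calls}\n")


def _read_vcf(path: str, assay: str = "HD") -> GenotypeMatrix:
    """Read a VCF of biallelic SNVs; multiallelic sites are dropped with a warning."""
    import warnings

    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    ids = list(vcf.samples)
    marker_ids, rows = [], []
    for variant in vcf:
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            warnings.warn(f"skipping non-biallelic-SNV site {variant.ID or variant.POS}")
            continue
        gt = variant.gt_types.astype(float)  # 0/1/2, 3 = unknown under gts012
        gt[gt == 3] = np.nan
        marker_ids.append(variant.ID or f"{variant.CHROM}_{variant.POS}")
        rows.append(gt)
    if not rows:
        raise ValueError(f"no usable biallelic SNVs in {path}")
    return GenotypeMatrix(ids, marker_ids, np.array(rows).T, assay=assay)


def write_pedigree(ped: Pedigree, path: str) -> None:
    ped.table.to_csv(path, index=False)


def read_pedigree(path: str) -> Pedigree:
    df = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str})
    return Pedigree(df)


def write_marker_map(marker_map: MarkerMap, path: str) -> None:
    marker_map.table.to_csv(path, sep="\t", index=False)


def read_marker_map(path: str) -> MarkerMap:
    return MarkerMap(pd.read_csv(path, sep="\t"))


def write_phenotypes(phenotypes: pd.DataFrame, path: str) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"id": str})


# ---------------------------------------------------------------------------
# quality control


@dataclass
class QCReport:
    """What qc_filter removed and why."""

    mode: str
    markers_removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["marker_id", "reason", "value"]))
    individuals_removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "reason", "value"]))

    @property
    def n_markers_removed(self) -> int:
        return len(self.markers_removed)

    @property
    def n_individuals_removed(self) -> int:
        return len(self.individuals_removed)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# qc mode: {self.mode}\n")
            for df, kind in ((self.markers_removed, "marker"),
                             (self.individuals_removed, "individual")):
                for row in df.itertuples(index=False):
                    fh.write(f"{kind}\t{row[0]}\t{row[1]}\t{row[2]:.4f}\n")


def qc_filter(g: GenotypeMatrix, maf_min: float = 0.02,
              marker_call_min: float = 0.90, ind_call_min: float = 0.90,
              mode: str = "basic") -> tuple[GenotypeMatrix, QCReport]:
    """Two-level genotype QC.

    Markers failing ``MAF >= maf_min`` (strictly below is removed; the
    boundary is kept) or call rate below ``marker_call_min`` are removed in
    both modes.  Individuals below ``ind_call_min`` are removed only in
    ``full`` mode — ``basic`` mode keeps every individual so parentage can
    still be assigned.
    """
    if mode not in ("basic", "full"):
        raise ValueError("mode must be 'basic' or 'full'")
    for name, thr in (("maf_min", maf_min), ("marker_call_min", marker_call_min),
                      ("ind_call_min", ind_call_min)):
        if not (0 <= thr <= 1):
            raise ValueError(f"{name} must be in [0, 1]")
    report = QCReport(mode=mode)

    keep_ids = list(g.ids)
    if mode == "full":
        icr = g.individual_call_rate()
        bad = icr < ind_call_min
        report.individuals_removed = pd.DataFrame(
            {"id": np.array(g.ids, dtype=object)[bad], "reason": "call_rate",
             "value": icr[bad]})
        keep_ids = [i for i, b in zip(g.ids, bad) if not b]
        g = g.subset(ids=keep_ids)

    maf = g.maf()
    call = g.marker_call_rate()
    with np.errstate(invalid="ignore"):
        bad_maf = np.isnan(maf) | (maf < maf_min)
        bad_call = call < marker_call_min
    removed = []
    for k, marker in enumerate(g.marker_ids):
        if bad_maf[k]:
            removed.append((marker, "maf", 0.0 if np.isnan(maf[k]) else maf[k]))
        elif bad_call[k]:
            removed.append((marker, "call_rate", call[k]))
    if removed:
        report.markers_removed = pd.DataFrame(removed,
                                              columns=["marker_id", "reason", "value"])
    keep = [m for m, b1, b2 in zip(g.marker_ids, bad_maf, bad_call) if not (b1 or b2)]
    return g.subset(marker_ids=keep), report


# ---------------------------------------------------------------------------
# Mendelian checks


def _parent_offspring_conflicts(off: np.ndarray, par: np.ndarray) -> np.ndarray:
    """Boolean opposing-homozygote mask; nan-safe (missing never conflicts)."""
    with np.errstate(invalid="ignore"):
        return ((off == 0) & (par == 2)) | ((off == 2) & (par == 0))


def _trio_conflicts(off: np.ndarray, sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Trio-impossible dosage combinations (all three genotyped)."""
    with np.errstate(invalid="ignore"):
        c = _parent_offspring_conflicts(off, sire) | _parent_offspring_conflicts(off, dam)
        c |= (off == 1) & (((sire == 0) & (dam == 0)) | ((sire == 2) & (dam == 2)))
    return c


def mendelian_error_check(g: GenotypeMatrix, pedigree: Pedigree,
                          marker_removal_rate: float = 0.05) -> dict:
    """Opposing-homozygote / trio-impossible error rates per marker and trio.

    Only parent-offspring pairs with both members genotyped at a marker
    contribute.  Returns per-marker rates (with markers above
    ``marker_removal_rate`` flagged), per-trio rates, and the overall rate.
    An absence of genotyped trios yields an empty report, not an error.
    """
    gindex = {v: i for i, v in enumerate(g.ids)}
    err_counts = np.zeros(g.n_markers)
    cmp_counts = np.zeros(g.n_markers)
    trio_rows = []
    for row in pedigree.table.itertuples():
        if row.id not in gindex:
            continue
        off = g.dosages[gindex[row.id]]
        s = g.dosages[gindex[row.sire]] if row.sire in gindex else None
        d = g.dosages[gindex[row.dam]] if row.dam in gindex else None
        if s is None and d is None:
            continue
        if s is not None and d is not None:
            conflicts = _trio_conflicts(off, s, d)
            comparable = ~np.isnan(off) & ~np.isnan(s) & ~np.isnan(d)
        else:
            par = s if s is not None else d
            conflicts = _parent_offspring_conflicts(off, par)
            comparable = ~np.isnan(off) & ~np.isnan(par)
        err_counts += conflicts & comparable
        cmp_counts += comparable
        n_cmp = comparable.sum()
        trio_rows.append((row.id, row.sire, row.dam, int((conflicts & comparable).sum()),
                          int(n_cmp), (conflicts & comparable).sum() / n_cmp if n_cmp else np.nan))
    with np.errstate(invalid="ignore"):
        marker_rates = np.where(cmp_counts > 0, err_counts / np.maximum(cmp_counts, 1), np.nan)
    per_marker = pd.DataFrame({"marker_id": g.marker_ids, "errors": err_counts.astype(int),
                               "comparisons": cmp_counts.astype(int), "rate": marker_rates})
    per_marker["flagged"] = per_marker["rate"] > marker_removal_rate
    per_trio = pd.DataFrame(trio_rows, columns=["id", "sire", "dam", "errors",
                                                "comparisons", "rate"])
    total_cmp = cmp_counts.sum()
    return {"per_marker": per_marker, "per_trio": per_trio,
            "overall_rate": float(err_counts.sum() / total_cmp) if total_cmp else np.nan}


# ---------------------------------------------------------------------------
# parentage assignment


def assign_parentage(offspring: GenotypeMatrix, candidates: GenotypeMatrix,
                     candidate_meta: pd.DataFrame, max_mismatch_rate: float = 0.02,
                     min_shared_markers: int = 80, margin: float = 0.02,
                     shortlist: int = 20) -> pd.DataFrame:
    """Exclusion-based parentage: best sire x dam trio per offspring.

    For every offspring the (male, female) candidate pair minimising the
    trio-impossible mismatch rate is found.  The assignment is accepted only
    if that rate is <= ``max_mismatch_rate`` and the second-best pair is
    worse by more than ``margin`` (ambiguity guard against duplicated
    samples and close relatives).  Candidates are shortlisted per sex by
    parent-offspring conflict rate before the exact trio scan.

    ``candidate_meta`` needs columns ``id`` and ``sex`` ('M'/'F').
    Returns one row per offspring: id, sire, dam, mismatch_rate, status.
    """
    shared = [m for m in offspring.marker_ids if m in set(candidates.marker_ids)]
    if len(shared) < min_shared_markers:
        raise ValueError(f"only {len(shared)} shared markers (< {min_shared_markers})")
    off = offspring.subset(marker_ids=shared)
    cand = candidates.subset(marker_ids=shared)
    meta = candidate_meta.set_index("id")
    males = [i for i in cand.ids if meta.loc[i, "sex"] == "M"]
    females = [i for i in cand.ids if meta.loc[i, "sex"] == "F"]

    cand_index = {v: i for i, v in enumerate(cand.ids)}
    results = []
    for oi, oid in enumerate(off.ids):
        o = off.dosages[oi]
        if not males or not females:
            results.append((oid, None, None, np.nan, "no candidates of one sex"))
            continue

        def po_rates(group: list) -> np.ndarray:
            rates = np.empty(len(group))
            for k, cid in enumerate(group):
                p = cand.dosages[cand_index[cid]]
                comparable = ~np.isnan(o) & ~np.isnan(p)
                n = comparable.sum()
                rates[k] = (_parent_offspring_conflicts(o, p) & comparable).sum() / n if n else np.inf
            return rates

        m_rates, f_rates = po_rates(males), po_rates(females)
        top_m = [males[k] for k in np.argsort(m_rates, kind="stable")[:shortlist]]
        top_f = [females[k] for k in np.argsort(f_rates, kind="stable")[:shortlist]]
        scored = []
        for sid in top_m:
            s = cand.dosages[cand_index[sid]]
            for did in top_f:
                d = cand.dosages[cand_index[did]]
                comparable = ~np.isnan(o) & ~np.isnan(s) & ~np.isnan(d)
                n = comparable.sum()
                if n == 0:
                    continue
                rate = (_trio_conflicts(o, s, d) & comparable).sum() / n
                scored.append((rate, sid, did))
        scored.sort(key=lambda x: (x[0], str(x[1]), str(x[2])))
        if not scored or scored[0][0] > max_mismatch_rate:
            results.append((oid, None, None, scored[0][0] if scored else np.nan,
                            "no pair under threshold"))
            continue
        best = scored[0]
        runners = [s for s in scored[1:] if s[1] != best[1] or s[2] != best[2]]
        if runners and runners[0][0] - best[0] <= margin:
            results.append((oid, None, None, best[0], "ambiguous (margin)"))
            continue
        results.append((oid, best[1], best[2], best[0], "assigned"))
    return pd.DataFrame(results, columns=["id", "sire", "dam", "mismatch_rate", "status"])
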