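"""LD census and two-tier SNP panel design.

The high-density panel is designed to tag every segregating chromosome
segment: an LD-pruned scaffold (no retained pair with r^2 above the
threshold) plus trait-associated markers is force-included, remaining
markers are placed in 100 kbp bins, and filler slots are awarded by a
deterministic rank score favouring high MAF and low local LD, one marker
per uncovered bin before any bin receives a second.  The low-density
(1K/3K-class) panel is an evenly spaced subset of the high-density panel
with the same within-window preference, sized for imputation back up to
the full marker set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MarkerMap

__all__ = [
    "LDTable", "PanelSpec", "pairwise_ld", "ld_prune", "bin_markers",
    "design_hd_panel", "design_ld_panel", "panel_summary",
]


@dataclass
class PanelSpec:
    """An ordered marker subset with provenance per marker."""

    marker_ids: list[str]
    density_class: str  # HD | LD1K | LD3K
    provenance: dict[str, str] = field(default_factory=dict)  # segment-tag | trait-associated | filler

    def __post_init__(self) -> None:
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("panel contains duplicate markers")

    def __len__(self) -> int:
        return len(self.marker_ids)

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for m in self.marker_ids:
                fh.write(f"{m}\t{self.provenance.get(m, 'filler')}\n")

    @classmethod
    def from_file(cls, path: str, density_class: str) -> "PanelSpec":
        markers, prov = [], {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                markers.append(parts[0])
                prov[parts[0]] = parts[1] if len(parts) > 1 else "filler"
        return cls(markers, density_class, prov)


LDTable = pd.DataFrame  # columns: marker_a, marker_b, distance_bp, r2


def pairwise_ld(g: GenotypeMatrix, marker_map: MarkerMap,
                max_dist_bp: int = 1_000_000) -> LDTable:
    """Squared dosage correlation for same-chromosome pairs within a window.

    Pairwise-complete observations are used; pairs where either marker has
    zero variance are skipped.
    """
    idx = marker_map.indices_of(g.marker_ids)
    chroms = marker_map.chromosomes[idx]
    pos = marker_map.positions[idx]
    rows = []
    dos = g.dosages
    complete = not np.isnan(dos).any()
    if complete:  # fast path: standardized dot products
        sd = dos.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (dos - dos.mean(axis=0)) / sd
        n = dos.shape[0]
    for c in np.unique(chroms):
        members = np.flatnonzero(chroms == c)
        p = pos[members]
        for a_i in range(len(members)):
            b_hi = a_i + 1 + np.searchsorted(p[a_i + 1:], p[a_i] + max_dist_bp,
                                             side="right")
            if b_hi <= a_i + 1:
                continue
            a_col = members[a_i]
            b_cols = members[a_i + 1: b_hi]
            if complete:
                if sd[a_col] == 0:
                    continue
                ok = sd[b_cols] > 0
                r = z[:, a_col] @ z[:, b_cols[ok]] / n
                for b_col, d, r_ab in zip(b_cols[ok], p[a_i + 1: b_hi][ok] - p[a_i], r):
                    rows.append((g.marker_ids[a_col], g.marker_ids[b_col],
                                 int(d), r_ab * r_ab))
                continue
            for b_i in range(a_i + 1, b_hi):
                x, y = dos[:, a_col], dos[:, members[b_i]]
                ok = ~np.isnan(x) & ~np.isnan(y)
                if ok.sum() < 3:
                    continue
                xs, ys = x[ok], y[ok]
                if xs.std() == 0 or ys.std() == 0:
                    continue
                r = np.corrcoef(xs, ys)[0, 1]
                rows.append((g.marker_ids[a_col], g.marker_ids[members[b_i]],
                             int(p[b_i] - p[a_i]), r * r))
    return pd.DataFrame(rows, columns=["marker_a", "marker_b", "distance_bp", "r2"])


def ld_prune(ld: LDTable, marker_ids: Sequence[str], r2_max: float = 0.2) -> list[str]:
    """Greedy left-to-right LD pruning.

    Scanning markers in the supplied (map) order, a marker is kept iff its
    r^2 with every already-kept marker (among pairs present in the LD
    table) is below ``r2_max``.  Ties resolve in favour of the earlier
    marker.
    """
    r2 = {}
    for row in ld.itertuples(index=False):
        r2[(row.marker_a, row.marker_b)] = row.r2
        r2[(row.marker_b, row.marker_a)] = row.r2
    kept: list[str] = []
    kept_set: set[str] = set()
    for m in marker_ids:
        if all(r2.get((m, k), 0.0) < r2_max for k in kept_set):
            kept.append(m)
            kept_set.add(m)
    return kept


def bin_markers(marker_map: MarkerMap, bin_bp: int = 100_000) -> pd.Series:
    """Assign each marker to a half-open physical bin.

    Bin k on chromosome c covers 1-based positions [k*bin_bp + 1,
    (k+1)*bin_bp], i.e. bin index = (position - 1) // bin_bp; the label is
    (chromosome, bin index).
    """
    bins = (marker_map.positions - 1) // bin_bp
    labels = list(zip(marker_map.chromosomes.tolist(), bins.tolist()))
    return pd.Series(labels, index=marker_map.marker_ids)


def _local_mean_r2(ld: LDTable) -> dict[str, float]:
    acc: dict[str, list[float]] = {}
    for row in ld.itertuples(index=False):
        acc.setdefault(row.marker_a, []).append(row.r2)
        acc.setdefault(row.marker_b, []).append(row.r2)
    return {m: float(np.mean(v)) for m, v in acc.items()}


def design_hd_panel(g: GenotypeMatrix, marker_map: MarkerMap,
                    scaffold: Sequence[str], trait_markers: Sequence[str],
                    target_size: int, ld: LDTable | None = None,
                    bin_bp: int = 100_000) -> PanelSpec:
    """High-density panel: scaffold + trait markers + rank-scored fillers.

    All scaffold (LD-pruned) and trait-associated markers are included
    first.  Remaining slots are filled by score = MAF rank - local-mean-r^2
    rank (higher is better), giving every occupied bin one marker before
    any bin receives a second.  Deterministic given input order.
    """
    prov: dict[str, str] = {m: "segment-tag" for m in scaffold}
    for m in trait_markers:
        prov[m] = "trait-associated"
    forced = list(dict.fromkeys(list(scaffold) + list(trait_markers)))
    if target_size < len(forced):
        raise ValueError(
            f"target_size {target_size} below minimum feasible {len(forced)} "
            "(scaffold + trait markers)")
    bins = bin_markers(marker_map, bin_bp)
    maf = pd.Series(g.maf(), index=g.marker_ids)
    eligible = [m for m in g.marker_ids
                if m not in prov and not np.isnan(maf[m]) and maf[m] > 0]
    local_r2 = _local_mean_r2(ld) if ld is not None else {}
    maf_rank = pd.Series(np.argsort(np.argsort(maf[eligible].to_numpy())),
                         index=eligible, dtype=float)
    r2_vals = pd.Series([local_r2.get(m, 0.0) for m in eligible], index=eligible)
    r2_rank = pd.Series(np.argsort(np.argsort(r2_vals.to_numpy())),
                        index=eligible, dtype=float)
    score = maf_rank - r2_rank

    selected = list(forced)
    covered = {bins[m] for m in selected if m in bins.index}
    slots = target_size - len(selected)
    # pass 1: best-scoring eligible marker for each uncovered occupied bin
    by_bin: dict = {}
    for m in eligible:
        by_bin.setdefault(bins[m], []).append(m)
    uncovered = [b for b in by_bin if b not in covered]
    uncovered.sort()
    picked: list[str] = []
    for b in uncovered:
        if slots <= len(picked):
            break
        best = max(by_bin[b], key=lambda m: (score[m], m))
        picked.append(best)
    # pass 2: fill remaining slots globally by score
    chosen = set(selected) | set(picked)
    rest = sorted((m for m in eligible if m not in chosen),
                  key=lambda m: (-score[m], m))
    picked.extend(rest[: max(0, slots - len(picked))])
    for m in picked:
        prov[m] = "filler"
    selected.extend(picked)
    order = {m: i for i, m in enumerate(marker_map.marker_ids)}
    selected.sort(key=lambda m: order[m])
    return PanelSpec(selected, "HD", prov)


def design_ld_panel(g: GenotypeMatrix, marker_map: MarkerMap, hd_panel: PanelSpec,
                    target_size: int, trait_markers: Sequence[str] = (),
                    ld: LDTable | None = None) -> PanelSpec:
    """Low-density panel: even physical spacing over the HD panel.

    The genome is cut into ``target_size`` equal-length windows (allocated
    across chromosomes by length); within each window the HD marker with
    the best MAF / local-LD rank score is taken.  Trait-associated markers
    are force-included.
    """
    if target_size > len(hd_panel):
        raise ValueError("LD panel target exceeds HD panel size")
    hd_set = set(hd_panel.marker_ids)
    missing = set(trait_markers) - hd_set
    if missing:
        raise ValueError(f"trait markers not on HD panel: {sorted(missing)[:5]}")
    idx = marker_map.indices_of(hd_panel.marker_ids)
    chroms = marker_map.chromosomes[idx]
    pos = marker_map.positions[idx]
    maf = pd.Series(g.maf(), index=g.marker_ids).reindex(hd_panel.marker_ids).fillna(0.0)
    local_r2 = _local_mean_r2(ld) if ld is not None else {}

    chrom_lengths = {int(c): int(pos[chroms == c].max()) for c in np.unique(chroms)}
    total_len = sum(chrom_lengths.values())
    prov = {m: "trait-associated" for m in trait_markers}
    selected = list(trait_markers)
    selected_set = set(selected)
    n_free = target_size - len(selected)
    if n_free < 0:
        raise ValueError("target_size smaller than forced trait-marker set")
    for c, clen in sorted(chrom_lengths.items()):
        n_windows = max(1, round(n_free * clen / total_len))
        window = clen / n_windows
        members = np.flatnonzero(chroms == c)
        for w in range(n_windows):
            lo, hi = w * window, (w + 1) * window
            in_win = [hd_panel.marker_ids[k] for k in members
                      if lo < pos[k] <= hi + (window if w == n_windows - 1 else 0)]
            in_win = [m for m in in_win if m not in selected_set]
            if not in_win:
                continue
            ranks_maf = {m: r for r, m in enumerate(sorted(in_win, key=lambda m: maf[m]))}
            ranks_r2 = {m: r for r, m in enumerate(
                sorted(in_win, key=lambda m: -local_r2.get(m, 0.0)))}
            best = max(in_win, key=lambda m: (ranks_maf[m] + ranks_r2[m], m))
            selected.append(best)
            selected_set.add(best)
            prov[best] = "segment-tag"
    order = {m: i for i, m in enumerate(marker_map.marker_ids)}
    selected.sort(key=lambda m: order[m])
    density = "LD1K" if target_size <= 2000 else "LD3K"
    return PanelSpec(selected, density, prov)


def panel_summary(panel: PanelSpec, marker_map: MarkerMap,
                  g: GenotypeMatrix | None = None, bin_bp: int = 100_000) -> dict:
    """Spacing, largest gap, mean MAF and bin-coverage statistics."""
    if len(panel) == 0:
        raise ValueError("empty panel")
    idx = marker_map.indices_of(panel.marker_ids)
    chroms = marker_map.chromosomes[idx]
    pos = marker_map.positions[idx]
    gaps = []
    for c in np.unique(chroms):
        p = np.sort(pos[chroms == c])
        if len(p) > 1:
            gaps.extend(np.diff(p).tolist())
    bins_all = bin_markers(marker_map, bin_bp)
    occupied = set(bins_all)
    covered = set(bins_all[panel.marker_ids])
    out = {
        "n_markers": len(panel),
        "mean_spacing_bp": float(np.mean(gaps)) if gaps else np.nan,
        "largest_gap_bp": float(np.max(gaps)) if gaps else np.nan,
        "bin_coverage": len(covered) / len(occupied),
    }
    if g is not None:
        maf = pd.Series(g.maf(), index=g.marker_ids)
        out["mean_maf"] = float(maf.reindex(panel.marker_ids).mean())
    return out
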