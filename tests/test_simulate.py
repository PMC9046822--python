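"""Generator contracts: genome placement, founder LD, mating design,
meiosis, phenotype variance structure and assay observation."""

import numpy as np
import pandas as pd
import pytest

from salmogs import SimulationConfig, weight_trait_model
from salmogs.simulate import (draw_qtl_effects,
                              make_progeny, mate_partial_factorial,
                              simulate_assay, simulate_founders,
                              simulate_genome, simulate_phenotypes,
                              true_breeding_values)


def small_cfg(**kw) -> SimulationConfig:
    base = dict(n_chromosomes=1, chromosome_length_bp=1_000_000, n_markers=10,
                n_qtl=2, n_founders=20, seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenome:
    def test_counts_and_sorting(self):
        mm = simulate_genome(small_cfg())
        assert len(mm) == 10
        assert (mm.table["role"] == "qtl").sum() == 2
        assert len(set(mm.positions)) == 10
        assert np.all(np.diff(mm.positions) > 0)

    def test_deterministic_given_seed(self):
        a = simulate_genome(small_cfg())
        b = simulate_genome(small_cfg())
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_too_many_qtl_rejected(self):
        with pytest.raises(ValueError):
            small_cfg(n_qtl=11)

    def test_too_many_markers_rejected(self):
        with pytest.raises(ValueError):
            small_cfg(chromosome_length_bp=5, n_markers=10, n_qtl=1)


class TestFounderLD:
    def test_ld_calibrated_at_target_distance(self):
        cfg = SimulationConfig(n_chromosomes=1, chromosome_length_bp=20_000_000,
                               n_markers=1500, n_qtl=10, n_founders=300, seed=3)
        mm = simulate_genome(cfg)
        founders = simulate_founders(mm, cfg)
        dos = founders.dosages()
        pos = mm.positions
        rng = np.random.default_rng(0)
        r2 = []
        for _ in range(4000):
            i = rng.integers(len(pos))
            d = np.abs(pos - pos[i])
            cand = np.flatnonzero((d >= 450_000) & (d <= 550_000))
            if not len(cand):
                continue
            j = rng.choice(cand)
            x, y = dos[:, i], dos[:, j]
            if x.std() == 0 or y.std() == 0:
                continue
            r2.append(np.corrcoef(x, y)[0, 1] ** 2)
        assert 0.15 <= np.mean(r2) <= 0.25

    def test_no_ld_gives_sampling_floor(self):
        # with the Markov persistence switched off, loci are independent and
        # the observed mean r^2 is the finite-sample floor ~ 1/n
        cfg = SimulationConfig(n_chromosomes=1, chromosome_length_bp=5_000_000,
                               n_markers=400, n_qtl=10, n_founders=250,
                               ld_target=None, seed=4)
        mm = simulate_genome(cfg)
        dos = simulate_founders(mm, cfg).dosages()
        n = dos.shape[0]
        rng = np.random.default_rng(1)
        r2 = []
        for _ in range(2000):
            i, j = rng.choice(400, size=2, replace=False)
            x, y = dos[:, i], dos[:, j]
            if x.std() == 0 or y.std() == 0:
                continue
            r2.append(np.corrcoef(x, y)[0, 1] ** 2)
        expected_floor = 1.0 / n
        assert np.mean(r2) == pytest.approx(expected_floor, rel=0.5)

    def test_unattainable_target_rejected(self):
        with pytest.raises(ValueError):
            small_cfg(ld_target=(1.5, 500_000))
        with pytest.raises(ValueError):
            small_cfg(ld_target=(0.0, 500_000))

    def test_bit_identical_given_seed(self, tiny_config, tiny_map):
        a = simulate_founders(tiny_map, tiny_config)
        b = simulate_founders(tiny_map, tiny_config)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_maf_spectrum_truncated(self, tiny_founders):
        maf = np.minimum(tiny_founders.dosages().mean(axis=0) / 2,
                         1 - tiny_founders.dosages().mean(axis=0) / 2)
        # the generating spectrum is truncated at 0.02; sampling can push
        # a realized frequency slightly below but never to fixation
        assert maf.min() >= 0.0
        assert (maf > 0.3).mean() > 0.2  # U-shape still has a broad middle


class TestPartialFactorial:
    def test_each_parent_used_exactly_twice(self):
        sires = [f"s{i}" for i in range(100)]
        dams = [f"d{i}" for i in range(100)]
        fam = mate_partial_factorial(sires, dams, 200, np.random.default_rng(0))
        assert len(fam) == 200
        assert (fam["sire"].value_counts() == 2).all()
        assert (fam["dam"].value_counts() == 2).all()
        assert not fam.duplicated(subset=["sire", "dam"]).any()

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            mate_partial_factorial(["s"], ["d"], 2, np.random.default_rng(0))

    def test_incompatible_counts_rejected(self):
        with pytest.raises(ValueError):
            mate_partial_factorial(["s1", "s2"], ["d1", "d2", "d3"], 4,
                                   np.random.default_rng(0))


class TestMeiosis:
    def test_mendelian_forcing_opposite_homozygotes(self, tiny_map):
        m = len(tiny_map)
        haps = np.zeros((2, 2, m), dtype=np.uint8)
        haps[1] = 1  # parent B homozygous alt everywhere
        from salmogs.containers import HaplotypeSet
        parents = HaplotypeSet(["A", "B"], haps)
        matings = pd.DataFrame({"family": ["f0"], "sire": ["A"], "dam": ["B"]})
        off, _ = make_progeny(matings, parents, tiny_map, 20,
                              np.random.default_rng(0))
        assert np.all(off.dosages() == 1.0)

    def test_zero_recombination_transmits_intact_haplotypes(self, tiny_map,
                                                            tiny_founders):
        matings = pd.DataFrame({"family": ["f0"],
                                "sire": [tiny_founders.ids[0]],
                                "dam": [tiny_founders.ids[1]]})
        off, _ = make_progeny(matings, tiny_founders, tiny_map, 10,
                              np.random.default_rng(0),
                              recombination_rate_cM_per_Mbp=0.0)
        parents = tiny_founders.haplotypes[:2]
        for k in range(10):
            for g in range(2):
                gamete = off.haplotypes[k, g]
                assert any(np.array_equal(gamete, parents[g, h]) for h in range(2))

    def test_full_sib_genome_sharing_near_half(self, family_population):
        # realized IBS-based sharing proxy: correlation of centred dosages
        off = family_population["offspring"]
        rows = family_population["pedigree"].table
        fam = rows[rows["sire"].notna()].groupby(["sire", "dam"])["id"].apply(list)
        dos = off.dosages()
        index = {v: i for i, v in enumerate(off.ids)}
        z = dos - dos.mean(axis=0)
        rels = []
        for ids in fam:
            for a in range(len(ids) - 1):
                i, j = index[ids[a]], index[ids[a + 1]]
                rels.append((z[i] @ z[j]) / np.sqrt((z[i] @ z[i]) * (z[j] @ z[j])))
        assert np.mean(rels) == pytest.approx(0.5, abs=0.06)

    def test_missing_parent_haplotypes_error(self, tiny_map, tiny_founders):
        matings = pd.DataFrame({"family": ["f0"], "sire": ["nope"],
                                "dam": [tiny_founders.ids[0]]})
        with pytest.raises(ValueError, match="missing haplotypes"):
            make_progeny(matings, tiny_founders, tiny_map, 1,
                         np.random.default_rng(0))


@pytest.fixture(scope="module")
def cohort(tiny_config, tiny_map, tiny_founders):
    rng = np.random.default_rng(11)
    sires = tiny_founders.ids[:20]
    dams = tiny_founders.ids[40:60]
    matings = mate_partial_factorial(sires, dams, 40, rng)
    off, rows = make_progeny(matings, tiny_founders, tiny_map, 40, rng)
    return off, rows


class TestPhenotypes:
    def test_heritability_and_rg_realized(self, tiny_map, tiny_founders, cohort):
        tm = weight_trait_model()
        off, rows = cohort
        effects = draw_qtl_effects(tiny_map, tiny_founders, tm,
                                   np.random.default_rng(5))
        qtl = tiny_map.qtl_indices
        fr = tiny_founders.dosages()[:, qtl].mean(axis=0) / 2
        tbv = true_breeding_values(off, tiny_map, effects, fr, tm)
        fams = pd.Series((rows["sire"] + "|" + rows["dam"]).to_numpy(),
                         index=rows["id"].to_numpy())
        alloc = pd.Series("marine", index=off.ids)
        cohort_lab = pd.Series("c0", index=off.ids)
        phen = simulate_phenotypes(tbv, fams, alloc, cohort_lab, tm,
                                   np.random.default_rng(6))
        w = phen[phen["trait"] == "weight_marine"].set_index("id")
        tb = tbv.loc[w.index, "weight_marine"]
        # regression of phenotype on true BV ~ 1 and variance ratio ~ h2
        slope = np.polyfit(tb, w["value"], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)
        h2_real = tb.var() / w["value"].var()
        assert h2_real == pytest.approx(0.44, abs=0.10)
        rg = np.corrcoef(tbv["weight_marine"], tbv["weight_fresh"])[0, 1]
        assert rg == pytest.approx(0.63, abs=0.10)

    def test_zero_noise_phenotype_equals_true_bv(self, tiny_map, tiny_founders):
        tm_raw = weight_trait_model()
        from salmogs.containers import TraitModel
        eps = 1e-12
        tm = TraitModel(tm_raw.traits, tm_raw.G_p, np.eye(2) * eps,
                        np.eye(2) * eps, tm_raw.environment)
        effects = draw_qtl_effects(tiny_map, tiny_founders, tm,
                                   np.random.default_rng(5))
        qtl = tiny_map.qtl_indices
        fr = tiny_founders.dosages()[:, qtl].mean(axis=0) / 2
        tbv = true_breeding_values(tiny_founders, tiny_map, effects, fr, tm)
        ids = tiny_founders.ids
        fams = pd.Series([f"f{i}" for i in range(len(ids))], index=ids)
        phen = simulate_phenotypes(tbv, fams, pd.Series("marine", index=ids),
                                   pd.Series("c", index=ids), tm,
                                   np.random.default_rng(1), cohort_effect_sd=0.0)
        w = phen[phen["trait"] == "weight_marine"].set_index("id")["value"]
        assert np.allclose(w, tbv.loc[w.index, "weight_marine"], atol=1e-5)

    def test_unallocated_individual_rejected(self, tiny_map, tiny_founders):
        tm = weight_trait_model()
        effects = draw_qtl_effects(tiny_map, tiny_founders, tm,
                                   np.random.default_rng(5))
        qtl = tiny_map.qtl_indices
        fr = tiny_founders.dosages()[:, qtl].mean(axis=0) / 2
        tbv = true_breeding_values(tiny_founders, tiny_map, effects, fr, tm)
        ids = tiny_founders.ids
        alloc = pd.Series("marine", index=ids[:-1])  # one individual missing
        with pytest.raises(ValueError, match="allocation"):
            simulate_phenotypes(tbv, pd.Series("f", index=ids), alloc,
                                pd.Series("c", index=ids), tm,
                                np.random.default_rng(1))


class TestAssay:
    def test_noise_free_assay_is_panel_restriction(self, tiny_map, tiny_founders):
        g = tiny_founders.to_genotypes(tiny_map.marker_ids)
        panel = list(tiny_map.marker_ids[:50])
        obs = simulate_assay(g, panel, 0.0, 0.0, np.random.default_rng(0))
        assert np.array_equal(obs.dosages[:, :50], g.dosages[:, :50])
        assert np.isnan(obs.dosages[:, 50:]).all()

    def test_missingness_rate_realized(self, tiny_map, tiny_founders):
        g = tiny_founders.to_genotypes(tiny_map.marker_ids)
        obs = simulate_assay(g, list(tiny_map.marker_ids), 0.2, 0.0,
                             np.random.default_rng(1))
        n_calls = g.dosages.size
        realized = np.isnan(obs.dosages).mean()
        se = np.sqrt(0.2 * 0.8 / n_calls)
        assert abs(realized - 0.2) < 3 * se

    def test_empty_panel_all_missing(self, tiny_map, tiny_founders):
        g = tiny_founders.to_genotypes(tiny_map.marker_ids)
        obs = simulate_assay(g, [], 0.0, 0.0, np.random.default_rng(0))
        assert np.isnan(obs.dosages).all()

    def test_bad_rates_rejected(self, tiny_map, tiny_founders):
        g = tiny_founders.to_genotypes(tiny_map.marker_ids)
        with pytest.raises(ValueError):
            simulate_assay(g, [], 1.0, 0.0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            simulate_assay(g, [], 0.0, -0.1, np.random.default_rng(0))


def test_mendelian_consistency_exhaustive(family_population):
    """No offspring dosage is impossible given its parents, at any locus."""
    haps = family_population["all_haplotypes"]
    dos = haps.dosages()
    index = {v: i for i, v in enumerate(haps.ids)}
    ped = family_population["pedigree"].table
    for row in ped[ped["sire"].notna()].itertuples():
        o = dos[index[row.id]]
        s = dos[index[row.sire]]
        d = dos[index[row.dam]]
        assert not np.any((o == 0) & ((s == 2) | (d == 2)))
        assert not np.any((o == 2) & ((s == 0) | (d == 0)))
        assert not np.any((o == 1) & (((s == 0) & (d == 0)) | ((s == 2) & (d == 2))))
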