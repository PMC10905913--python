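"""Window enumeration, transmission expectations, the Poisson deficiency
test, clustering, carrier statuses and inter-region LD."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln, logsumexp
from scipy.stats import poisson

from dhhscan import dhh_scan as ds
from dhhscan import genotype_io as gio
from dhhscan import simdata

from conftest import make_genotypes, make_snp_map


def two_chrom_map(n1, n2):
    m1 = make_snp_map(n1, chrom="1")
    m2 = make_snp_map(n2, chrom="2")
    return gio.SnpMap(
        snp_id=np.concatenate([m1.snp_id, m2.snp_id]),
        chrom=np.concatenate([m1.chrom, m2.chrom]),
        pos=np.concatenate([m1.pos, m2.pos]),
        ref=np.concatenate([m1.ref, m2.ref]),
        alt=np.concatenate([m1.alt, m2.alt]),
    )


class TestWindows:
    def test_dense_window_count(self):
        assert len(ds.enumerate_windows(make_snp_map(25), 20)) == 6

    def test_short_chromosome_yields_none(self):
        assert ds.enumerate_windows(make_snp_map(19), 20) == []

    def test_windows_never_span_chromosomes(self):
        ws = ds.enumerate_windows(two_chrom_map(20, 20), 20)
        assert len(ws) == 2
        assert [w.chrom for w in ws] == ["1", "2"]
        assert [(w.start, w.end) for w in ws] == [(0, 19), (20, 39)]

    def test_step_offsets(self):
        ws = ds.enumerate_windows(make_snp_map(30), 10, step=5)
        assert [(w.start, w.end) for w in ws] == [(0, 9), (5, 14), (10, 19), (15, 24), (20, 29)]


class TestMaternalFrequencies:
    def test_two_haplotypes_split_evenly(self):
        pat = np.zeros((4, 3))
        mat = np.array([[0, 0, 0], [0, 0, 0], [1, 1, 1], [1, 1, 1]])
        geno = make_genotypes("abcd", pat, mat)
        freqs = ds.maternal_haplotype_frequencies(geno, ds.Window("1", 0, 2))
        assert freqs == {"000": 0.5, "111": 0.5}

    def test_monomorphic_window(self):
        geno = make_genotypes("ab", np.ones((2, 3)), np.ones((2, 3)))
        freqs = ds.maternal_haplotype_frequencies(geno, ds.Window("1", 0, 2))
        assert freqs == {"111": 1.0}

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, derandomize=True, deadline=None)
    def test_frequencies_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 40)
        m = rng.integers(1, 8)
        geno = make_genotypes(
            [f"a{i}" for i in range(n)],
            rng.integers(0, 2, (n, m)),
            rng.integers(0, 2, (n, m)),
        )
        freqs = ds.maternal_haplotype_frequencies(geno, ds.Window("1", 0, m - 1))
        assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)


class TestTransmissionProb:
    def test_genotyped_parent_copy_counting(self):
        k = "000"
        assert ds.transmission_prob(("000", "111"), k) == 0.5
        assert ds.transmission_prob(("000", "000"), k) == 1.0
        assert ds.transmission_prob(("111", "101"), k) == 0.0

    def test_mgs_modes(self):
        k = "000"
        het = ("000", "111")
        non = ("111", "101")
        assert ds.transmission_prob(het, k, kind="SIRE_MGS", mode="conservative") == 0.25
        assert ds.transmission_prob(
            non, k, kind="SIRE_MGS", f_k=0.04, mode="frequency-augmented"
        ) == pytest.approx(0.02)

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            ds.transmission_prob(("0", "0"), "0", kind="SIRE_MGS", f_k=1.5)


def _trio_population(parent_kinds, rng, window=3):
    """Build a toy genotyped population from per-trio parent haplotype
    specs; haplotype '1'*window is the tested carrier haplotype."""
    carrier = np.ones(window, dtype=np.int8)
    other = np.zeros(window, dtype=np.int8)
    animals, pat, mat, trios = [], [], [], []
    for i, (sire_copies, dam_copies, kind) in enumerate(parent_kinds):
        names = [f"o{i}", f"s{i}", f"d{i}"]
        animals += names
        off_p = other.copy()
        off_m = other.copy()
        s_p = carrier if sire_copies >= 1 else other
        s_m = carrier if sire_copies == 2 else other
        d_p = carrier if dam_copies >= 1 else other
        d_m = carrier if dam_copies == 2 else other
        pat += [off_p, s_p, d_p]
        mat += [off_m, s_m, d_m]
        trios.append(gio.Trio(f"o{i}", f"s{i}", f"d{i}", gio.TrioKind(kind)))
    geno = make_genotypes(animals, np.array(pat), np.array(mat))
    return geno, gio.TrioSet(trios)


def _mc_expected_homozygotes(parent_kinds, f_k, mode, n_rep, rng):
    """Monte-Carlo gene-drop oracle: simulate phase choices explicitly."""
    g = 1.0 if mode == "frequency-augmented" else 0.0
    total = np.zeros(n_rep)
    for sire_copies, dam_copies, kind in parent_kinds:
        s_isk = np.array([sire_copies >= 1, sire_copies == 2])
        d_isk = np.array([dam_copies >= 1, dam_copies == 2])
        s_tr = s_isk[rng.integers(0, 2, n_rep)]
        if kind == "SIRE_DAM":
            d_tr = d_isk[rng.integers(0, 2, n_rep)]
        else:  # dam's paternal allele from the MGS, maternal from granddam
            from_mgs = rng.random(n_rep) < 0.5
            mgs_allele = d_isk[rng.integers(0, 2, n_rep)]
            gd_allele = rng.random(n_rep) < g * f_k
            d_tr = np.where(from_mgs, mgs_allele, gd_allele).astype(bool)
        total += (s_tr & d_tr).astype(float)
    return total.mean(), total.std(ddof=1) / math.sqrt(n_rep)


class TestCountHomozygotes:
    def test_all_parents_heterozygous_sire_dam(self):
        kinds = [(1, 1, "SIRE_DAM")] * 100
        geno, trios = _trio_population(kinds, None)
        n_obs, n_exp = ds.count_homozygotes(
            trios, geno, ds.Window("1", 0, 2), "111", f_k=0.0
        )
        assert n_exp == pytest.approx(25.0)
        assert n_obs == 0

    def test_mgs_conservative(self):
        kinds = [(1, 1, "SIRE_MGS")] * 80
        geno, trios = _trio_population(kinds, None)
        _, n_exp = ds.count_homozygotes(
            trios, geno, ds.Window("1", 0, 2), "111", f_k=0.3, mode="conservative"
        )
        assert n_exp == pytest.approx(80 * 0.5 * 0.25)

    @pytest.mark.parametrize("mode", ["conservative", "frequency-augmented"])
    def test_matches_monte_carlo_gene_drop(self, mode):
        """n_exp equals the mean of explicit gene-drop simulations within 4 SE
        on randomized trio configurations."""
        rng = np.random.default_rng(2024)
        n_rep = 100_000
        for _ in range(10):
            n_trios = int(rng.integers(5, 30))
            kinds = [
                (
                    int(rng.integers(0, 3)),
                    int(rng.integers(0, 3)),
                    "SIRE_MGS" if rng.random() < 0.7 else "SIRE_DAM",
                )
                for _ in range(n_trios)
            ]
            f_k = float(rng.uniform(0.0, 0.3))
            geno, trios = _trio_population(kinds, rng)
            _, n_exp = ds.count_homozygotes(
                trios, geno, ds.Window("1", 0, 2), "111", f_k=f_k, mode=mode
            )
            mc_mean, mc_se = _mc_expected_homozygotes(kinds, f_k, mode, n_rep, rng)
            assert abs(n_exp - mc_mean) <= 4 * max(mc_se, 1e-12), (kinds, f_k, mode)


class TestPoissonTest:
    def test_degenerate_and_closed_forms(self):
        assert ds.poisson_deficit_test(0, 0) == 1.0
        assert ds.poisson_deficit_test(0, 13) == pytest.approx(math.exp(-13), rel=1e-12)
        assert ds.poisson_deficit_test(1, 11) == pytest.approx(12 * math.exp(-11), rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            ds.poisson_deficit_test(-1, 3)
        with pytest.raises(ValueError):
            ds.poisson_deficit_test(1, -3.0)

    def test_matches_scipy_cdf(self):
        for lam in (0.1, 1.0, 7.3, 13.0, 47.0, 100.0):
            for k in (0, 1, 5, 20, 100):
                assert ds.poisson_deficit_test(k, lam) == pytest.approx(
                    float(poisson.cdf(k, lam)), rel=1e-10
                )

    @given(st.integers(0, 60), st.floats(0.01, 80), st.floats(0.01, 20))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_monotonicity(self, k, lam, dlam):
        p = ds.poisson_deficit_test(k, lam)
        assert ds.poisson_deficit_test(k + 1, lam) >= p
        assert ds.poisson_deficit_test(k, lam + dlam) <= p + 1e-15


class TestDeficit:
    @pytest.mark.parametrize(
        "obs,exp,value", [(8, 49, 0.8367), (1, 11, 0.9091), (10, 10.0, 0.0)]
    )
    def test_values(self, obs, exp, value):
        assert ds.deficit(obs, exp) == pytest.approx(value, abs=5e-5)

    def test_zero_expectation_is_an_error(self):
        with pytest.raises(ValueError):
            ds.deficit(0, 0.0)


class TestScan:
    def test_rare_haplotypes_never_tested(self, demo_bundle, demo_trios):
        res = ds.scan(demo_bundle.geno, demo_trios, demo_bundle.snp_map,
                      freq_min=0.01)
        assert all(w.freq_maternal > 0.01 for w in res.results)

    def test_significant_results_obey_thresholds(self, demo_bundle, demo_trios):
        res = ds.scan(demo_bundle.geno, demo_trios, demo_bundle.snp_map)
        assert res.significant
        for w in res.significant:
            assert w.p_poisson < 1.9e-4
            assert 0.75 <= w.deficit <= 1.0


class TestClustering:
    def _wr(self, chrom, start, codes, p=1e-6, n_obs=0, n_exp=12.0):
        codes = np.asarray(codes, dtype=np.int8)
        return ds.WindowResult(
            chrom=chrom, start=start, end=start + len(codes) - 1,
            alleles="".join("G" if c else "A" for c in codes), codes=codes,
            freq_maternal=0.05, n_obs=n_obs, n_exp=n_exp, p_poisson=p,
        )

    def test_overlapping_consistent_windows_merge(self):
        smap = make_snp_map(30)
        w1 = self._wr("1", 0, [0, 1, 0, 1, 0])
        w2 = self._wr("1", 1, [1, 0, 1, 0, 1], p=1e-7)  # agrees on shared SNPs 1-4
        regions = ds.cluster_regions([w1, w2], smap)
        assert len(regions) == 1
        reg = regions[0]
        assert (reg.first, reg.last) == (0, 5)
        assert reg.carrier_codes.tolist() == [0, 1, 0, 1, 0, 1]
        assert reg.p_poisson == 1e-7  # statistics from the min-p member

    def test_different_chromosomes_never_merge(self):
        smap = two_chrom_map(20, 20)
        w1 = self._wr("1", 0, [1] * 5)
        w2 = self._wr("2", 20, [1] * 5)
        assert len(ds.cluster_regions([w1, w2], smap)) == 2

    def test_allele_conflict_keeps_windows_apart(self):
        smap = make_snp_map(30)
        w1 = self._wr("1", 0, [0, 0, 0, 0, 0])
        w2 = self._wr("1", 1, [0, 0, 0, 1, 1])  # disagrees at SNPs 1-3
        assert len(ds.cluster_regions([w1, w2], smap)) == 2

    def test_abutting_windows_merge(self):
        smap = make_snp_map(30)
        w1 = self._wr("1", 0, [1, 1, 1])
        w2 = self._wr("1", 3, [0, 0, 0])
        regions = ds.cluster_regions([w1, w2], smap)
        assert len(regions) == 1
        assert regions[0].carrier_codes.tolist() == [1, 1, 1, 0, 0, 0]

    def test_order_invariance(self, demo_bundle, demo_trios):
        res = ds.scan(demo_bundle.geno, demo_trios, demo_bundle.snp_map,
                      keep_all=False)
        smap = demo_bundle.snp_map
        fwd = ds.cluster_regions(res.significant, smap)
        rev = ds.cluster_regions(list(reversed(res.significant)), smap)
        key = lambda rs: [(r.chrom, r.first, r.last, r.carrier_haplotype) for r in rs]
        assert key(fwd) == key(rev)


class TestStatusAndLd:
    def _region(self, codes, first=0):
        codes = np.asarray(codes, dtype=np.int8)
        return ds.DHHRegion(
            region_id="R1", chrom="1", first=first, last=first + len(codes) - 1,
            carrier_codes=codes,
            carrier_haplotype="".join("G" if c else "A" for c in codes),
            member_windows=[], n_obs=0, n_exp=10.0, p_poisson=1e-6,
        )

    def test_status_counts_exact_phase_matches(self):
        carrier = [1, 0, 1]
        geno = make_genotypes(
            ["hom", "het", "recombinant"],
            np.array([[1, 0, 1], [1, 0, 1], [1, 1, 1]]),
            np.array([[1, 0, 1], [0, 0, 0], [1, 0, 1]]),
        )
        st_ = ds.assign_status(geno, self._region(carrier))
        assert st_["status"].tolist() == [2, 1, 1]
        # a phase differing at a single SNP never counts
        geno2 = make_genotypes(
            ["rec"], np.array([[1, 1, 1]]), np.array([[0, 0, 1]])
        )
        assert ds.assign_status(geno2, self._region(carrier))["status"].tolist() == [0]

    def test_ld_identity_and_complement(self):
        v = np.array([0, 1, 2, 1, 0, 2, 1])
        assert ds.region_ld_r2(v, v) == pytest.approx(1.0)
        assert ds.region_ld_r2(v, 2 - v) == pytest.approx(1.0)

    def test_ld_constant_vector_not_computable(self):
        assert math.isnan(ds.region_ld_r2([1, 1, 1], [0, 1, 2]))

    def test_independent_statuses_are_unlinked(self):
        rng = np.random.default_rng(5)
        a = rng.binomial(1, 0.1, 5000)
        b = rng.binomial(1, 0.1, 5000)
        assert ds.region_ld_r2(a, b) < 0.01


class TestPartialDeficit:
    def test_juvenile_mode_yields_partial_deficit(self):
        """Survival-to-genotyping of 0.15 leaves obs/exp near 0.15, the
        mechanism behind 84-91%-deficit haplotypes."""
        cfg = simdata.SimConfig(
            seed=77, n_snps_per_chrom=100,
            lethals=[simdata.LethalSpec(mode="juvenile", carrier_frequency=0.25,
                                        start_snp=40, juvenile_survival=0.15)],
        )
        b = simdata.simulate_population(cfg)
        df = b.pedigree
        ped = gio.Pedigree(df.assign(sire=df["sire"].where(df["sire"] != "0", None),
                                     dam=df["dam"].where(df["dam"] != "0", None)))
        trios = gio.build_trios(ped, b.geno)
        tl = b.truth["lethals"][0]
        w = ds.Window(tl["chrom"], tl["first_snp"], tl["last_snp"])
        k = "".join(map(str, tl["carrier_codes"]))
        n_obs, n_exp = ds.count_homozygotes(trios, b.geno, w, k)
        ratio = n_obs / n_exp
        se = math.sqrt(0.15 * 0.85 / n_exp)
        assert abs(ratio - 0.15) <= 3 * se
        assert 0.75 <= ds.deficit(n_obs, n_exp) <= 1.0
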