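"""Informative-marker filters, genotype-matrix coding, non-recombining
interval detection and pool state classification."""

import numpy as np
import pandas as pd
import pytest

import poolcross as pc
from poolcross.markers import HET, HOM_FAY, HOM_WT, MISSING


def _toy_counts():
    """Six variants with pool-A fractions .5,.5,.9,.45,.05,.55 and
    pool-B fractions .1,.3,.1,.15,.1,0.0, all at depth 40."""
    fa = [0.5, 0.5, 0.9, 0.45, 0.05, 0.55]
    fb = [0.1, 0.3, 0.1, 0.15, 0.1, 0.0]
    rows = []
    for i, (a, b) in enumerate(zip(fa, fb)):
        rows.append(("c2", 100_000 * (i + 1), "A", "C",
                     round(40 * (1 - a)), round(40 * a),
                     round(40 * (1 - b)), round(40 * b)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "A_ref", "A_alt", "B_ref", "B_alt"])


class TestMarkerSelection:
    FILT = pc.MarkerFilter(region=("c2", 1, 10_000_000))

    def test_toy_table_hard_filter_survivors(self):
        cand, attrition = pc.apply_hard_filters(_toy_counts(), "A", "B",
                                                self.FILT)
        assert list(cand["pos"]) == [100_000, 400_000, 600_000]
        assert attrition["frequency"] == 3

    def test_depth_filter_excludes_regardless_of_frequency(self):
        counts = _toy_counts()
        counts.loc[0, ["A_ref", "A_alt"]] = [10, 9]  # depth 19, fraction ~0.47
        cand, _ = pc.apply_hard_filters(counts, "A", "B", self.FILT)
        assert 100_000 not in list(cand["pos"])

    def test_boundary_frequencies_pass(self):
        counts = pd.DataFrame([("c2", 1000, "A", "C", 20, 20, 36, 4)],
                              columns=["chrom", "pos", "ref", "alt",
                                       "A_ref", "A_alt", "B_ref", "B_alt"])
        cand, _ = pc.apply_hard_filters(counts, "A", "B", self.FILT)
        assert len(cand) == 1  # 0.5 in pool A, 0.1 in pool B

    def test_fst_mode_filter(self):
        filt = pc.MarkerFilter(region=("c2", 1, 10_000_000), min_fst=0.35)
        cand, attrition = pc.apply_hard_filters(_toy_counts(), "A", "B", filt)
        fst = pc.variant_fst(_toy_counts(), "A", "B")["fst"]
        assert set(cand["pos"]) == \
            set(_toy_counts().loc[fst > 0.35, "pos"])
        assert "fst" in attrition

    def test_empty_candidate_set_reports_attrition(self):
        filt = pc.MarkerFilter(region=("c9", 1, 100))
        with pytest.raises(ValueError, match="attrition|region|depth|freq"):
            pc.select_markers(_toy_counts(), "A", "B", filt)

    def _spaced_counts(self, n=60, gap=80_000):
        pos = gap * np.arange(1, n + 1)
        return pd.DataFrame({
            "chrom": "c2", "pos": pos, "ref": "A", "alt": "C",
            "A_ref": 20, "A_alt": 20, "B_ref": 36, "B_alt": 4})

    def test_spacing_gaps_fall_in_range(self):
        filt = pc.MarkerFilter(region=("c2", 1, 10**9),
                               spacing_range=(150_000, 250_000))
        sel = pc.select_markers(self._spaced_counts(), "A", "B", filt, seed=4)
        gaps = np.diff(sel["pos"])
        assert ((gaps >= 150_000) & (gaps <= 250_000)).all()
        assert not sel["gap_exceeded"].any()

    def test_selection_is_deterministic_and_idempotent(self):
        filt = pc.MarkerFilter(region=("c2", 1, 10**9),
                               spacing_range=(150_000, 250_000))
        sel1 = pc.select_markers(self._spaced_counts(), "A", "B", filt, seed=4)
        sel2 = pc.select_markers(self._spaced_counts(), "A", "B", filt, seed=4)
        assert list(sel1["pos"]) == list(sel2["pos"])
        again = pc.select_markers(sel1.drop(columns="gap_exceeded"),
                                  "A", "B", filt, seed=99)
        assert list(again["pos"]) == list(sel1["pos"])

    def test_oversized_gaps_tolerated_and_logged(self):
        counts = self._spaced_counts(n=4, gap=1_000_000)
        filt = pc.MarkerFilter(region=("c2", 1, 10**9),
                               spacing_range=(150_000, 250_000))
        sel = pc.select_markers(counts, "A", "B", filt, seed=0)
        assert len(sel) == 4
        assert sel["gap_exceeded"].iloc[1:].all()


class TestGenotypeMatrix:
    def test_simulated_pedigree_matches_direct_recoding(self, small_pedigree):
        table = small_pedigree.genotype_table("BC")
        chrom = "chr11"
        positions = {f"{chrom}:{p}": int(p)
                     for p in small_pedigree.markers[chrom]}
        matrix = pc.build_genotype_matrix(table, chrom, positions)
        # oracle: recode straight from the phased haplotypes
        for j, ind in enumerate(small_pedigree.backcross()):
            mat, pat = ind.haplotypes[chrom]
            expected = (mat.astype(int) + pat).astype(np.int8)
            assert np.array_equal(matrix.codes[:, j], expected)
        assert set(np.unique(matrix.codes)) <= {HOM_WT, HET}

    def test_backcross_has_no_homozygous_fayoumi_cells(self, small_pedigree):
        table = small_pedigree.genotype_table("BC")
        positions = {f"chr1:{p}": int(p)
                     for p in small_pedigree.markers["chr1"]}
        matrix = pc.build_genotype_matrix(table, "chr1", positions)
        assert HOM_FAY not in matrix.codes

    def test_all_missing_column_retained(self):
        geno = pd.DataFrame({"id": ["i1", "i2"], "phenotype": ["AB", "WT"],
                             "m1": [1, 0], "m2": [np.nan, np.nan]})
        matrix = pc.build_genotype_matrix(geno, "c", {"m1": 100, "m2": 200})
        assert (matrix.codes[1] == MISSING).all()
        assert matrix.marker_names == ["m1", "m2"]

    def test_non_diagnostic_marker_excluded_with_warning(self):
        geno = pd.DataFrame({"id": ["i1"], "phenotype": ["AB"],
                             "m1": ["A/C"], "m2": ["G/G"]})
        with pytest.warns(UserWarning, match="not line-diagnostic"):
            matrix = pc.build_genotype_matrix(
                geno, "c", {"m1": 100, "m2": 200},
                founder_alleles={"m1": ("A", "C"), "m2": ("G", "G")})
        assert matrix.marker_names == ["m1"]
        assert matrix.codes[0, 0] == HET


def _matrix(codes, positions=None, phenotypes=()):
    codes = np.asarray(codes, dtype=np.int8)
    n_mark, n_ind = codes.shape
    if positions is None:
        positions = 100 * (1 + np.arange(n_mark))
    return pc.GenotypeMatrix(
        chrom="c", positions=np.asarray(positions, dtype=np.int64),
        marker_names=[f"m{i+1}" for i in range(n_mark)],
        individuals=[f"i{j+1}" for j in range(n_ind)],
        codes=codes, phenotypes=list(phenotypes))


class TestInterval:
    def test_toy_five_marker_example(self):
        # one event between m2/m3 (bird 1), one between m4/m5 (bird 2)
        codes = np.array([
            [1, 0, 1, 0],
            [1, 0, 1, 0],
            [0, 0, 1, 0],   # bird 1 switches between m2 and m3
            [0, 0, 1, 0],
            [0, 1, 1, 0],   # bird 2 switches between m4 and m5
        ])
        res = pc.find_nonrecombining_interval(_matrix(codes),
                                              carriers=[0, 0, 1, 0],
                                              anchor="m3")
        assert (res.first_marker, res.last_marker) == ("m3", "m4")
        assert res.n_recombinants_at_borders == (1, 1)
        assert res.flank_positions == (200, 500)

    def test_single_marker_chromosome(self):
        res = pc.find_nonrecombining_interval(
            _matrix([[1, 0]]), carriers=[1, 0])
        assert res.first_marker == res.last_marker == "m1"

    def test_everywhere_recombinant_interval_is_anchor_alone(self):
        codes = np.array([[0, 1], [1, 0], [0, 1], [1, 0]])
        res = pc.find_nonrecombining_interval(_matrix(codes),
                                              carriers=[0, 1], anchor="m2")
        assert res.first_marker == res.last_marker == "m2"

    def test_anchor_autodetected_as_perfectly_associated_marker(self):
        codes = np.array([
            [1, 0, 0],
            [1, 1, 0],   # perfectly associated with carriers (1,1,0)
            [1, 1, 1],
        ])
        res = pc.find_nonrecombining_interval(_matrix(codes),
                                              carriers=[1, 1, 0])
        assert res.first_marker == "m2" == res.last_marker

    def test_missing_codes_do_not_count_as_events(self):
        codes = np.array([[1, 0], [MISSING, 0], [1, 0]])
        res = pc.find_nonrecombining_interval(_matrix(codes),
                                              carriers=[1, 0], anchor="m1")
        assert (res.first_marker, res.last_marker) == ("m1", "m3")

    def test_no_perfect_marker_lists_candidates(self):
        codes = np.array([[1, 0], [0, 1]])
        with pytest.raises(ValueError, match="best candidates"):
            pc.find_nonrecombining_interval(_matrix(codes), carriers=[1, 1])

    def test_interval_consistent_with_simulated_crossover_log(
            self, small_pedigree):
        chrom = "chr11"
        table = small_pedigree.genotype_table("BC")
        positions = {f"{chrom}:{p}": int(p)
                     for p in small_pedigree.markers[chrom]}
        matrix = pc.build_genotype_matrix(table, chrom, positions)
        carriers = small_pedigree.fay_counts(
            *small_pedigree.config.causal_locus) >= 1
        res = pc.find_nonrecombining_interval(matrix, carriers)
        # oracle from the simulator's crossover log: no marker gap inside
        # the interval may flank an odd number of crossovers
        mpos = small_pedigree.markers[chrom]
        lo = np.searchsorted(mpos, res.start)
        hi = np.searchsorted(mpos, res.end)
        for ind in small_pedigree.backcross():
            co = small_pedigree.crossovers[ind.id][chrom]
            for k in range(lo, hi):
                n_co = np.sum((co > mpos[k]) & (co <= mpos[k + 1]))
                assert n_co % 2 == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_cold_region_recovered_as_nonrecombining_interval(self, seed):
        cold = ("c1", 1_000_000, 2_000_000, 0.001)
        cfg = pc.CrossConfig(
            chromosomes=[pc.Chromosome("c1", 3_000_000, rate_cm_per_mb=4.0)],
            causal_locus=("c1", 1_500_000), cold_region=cold,
            n_backcross=365, variant_spacing_bp=50_000, seed=seed)
        ped = pc.simulate_cross(cfg)
        table = ped.genotype_table("BC")
        positions = {f"c1:{p}": int(p) for p in ped.markers["c1"]}
        matrix = pc.build_genotype_matrix(table, "c1", positions)
        carriers = ped.fay_counts("c1", 1_500_000) >= 1
        res = pc.find_nonrecombining_interval(matrix, carriers)
        assert res.start <= 1_050_000 and res.end >= 1_950_000


class TestPoolState:
    @pytest.mark.parametrize("ref,alt,expected", [
        (40, 0, "FIXED_REF"),
        (0, 35, "FIXED_ALT"),
        (18, 22, "SEGREGATING"),   # fraction 0.55
        (0, 0, "MISSING"),
    ])
    def test_state_calls(self, ref, alt, expected):
        assert pc.classify_pool_state(ref, alt) == expected

    def test_threshold_is_exclusive(self):
        # a single heterozygote in a 5-bird pool gives expectation 0.1,
        # which at the default threshold is called segregating
        assert pc.classify_pool_state(90, 10) == "SEGREGATING"

    def test_state_matrix_flank_selection(self):
        counts = pd.DataFrame({
            "chrom": "c", "pos": [1_000, 6_000, 20_000],
            "ref": "A", "alt": "C",
            "P1_ref": [40, 0, 20], "P1_alt": [0, 40, 20]})
        states = pc.pool_state_matrix(counts, ["P1"],
                                      anchor=("c", 5_000, 6_000),
                                      flank_bp=5_000)
        assert list(states["pos"]) == [1_000, 6_000]
        assert list(states["P1"]) == ["FIXED_REF", "FIXED_ALT"]
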