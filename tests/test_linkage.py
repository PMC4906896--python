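import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptxmap import linkage, qc
from ptxmap.linkage import PhasedGameteMatrix
from ptxmap.simulate import SimConfig, simulate_cross


def _pgm(data, ids=None, parent="P1"):
    data = np.asarray(data, dtype=float)
    ids = pd.Index(ids or [f"m{i}" for i in range(data.shape[0])])
    return PhasedGameteMatrix(
        data=data, marker_ids=ids, parent=parent,
        phase_flags=pd.Series(False, index=ids),
        configurations=pd.Series("ABxAA", index=ids),
    )


class TestRecode:
    def test_split_one_marker_per_configuration(self):
        from ptxmap.formats_io import GenotypeMatrix

        ids = ["a", "b", "c", "d"]
        parents = pd.DataFrame(
            [("AG", "AA"), ("AA", "AG"), ("AG", "AG"), ("AG", "CT")],
            index=ids, columns=["P1", "P2"])
        calls = pd.DataFrame(
            [["AA", "AG"], ["AG", "AA"], ["AA", "GG"], ["AC", "GT"]],
            index=ids, columns=["S1", "S2"])
        markers = pd.DataFrame({"marker_id": ids, "alleles": "A/C/G/T",
                                "chrom": "NA", "pos": range(4)}, index=ids)
        gm = GenotypeMatrix(markers=markers, calls=calls, parents=parents)
        sets = linkage.split_by_configuration(gm)
        assert set(sets["P1"].marker_ids) == {"a", "d"}
        assert set(sets["P2"].marker_ids) == {"b", "d"}
        assert set(sets["ABxAB"].marker_ids) == {"c"}
        # ABxAA: progeny AA -> P1 transmitted A (code 0), AG -> G (code 1)
        assert sets["P1"].data[0].tolist() == [0.0, 1.0]
        # ABxCD split: AC -> P1 gave A / P2 gave C; GT -> G / T
        assert sets["P1"].data[1].tolist() == [0.0, 1.0]
        assert sets["P2"].data[1].tolist() == [0.0, 1.0]
        # ABxAB homozygotes reveal both transmissions; no het rows here
        assert sets["ABxAB"].data[0].tolist() == [0.0, 1.0]

    def test_set_sizes_track_proportions(self, small_cross):
        gm, truth = small_cross
        sets = linkage.split_by_configuration(gm)
        counts = truth.markers["configuration"].value_counts()
        assert sets["P1"].n_markers == counts["ABxAA"] + counts["ABxCD"]
        assert sets["P2"].n_markers == counts["AAxAB"] + counts["ABxCD"]


class TestPairwiseRF:
    def test_rf_simple_count(self):
        x = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], dtype=float)
        y = x.copy()
        y[0] = 1
        y[9] = 0
        rf = linkage.pairwise_rf_lod(np.vstack([x, y]))
        assert rf.r[0, 1] == pytest.approx(0.2)
        assert rf.n[0, 1] == 10

    def test_lod_closed_forms(self):
        assert linkage._lod(np.array(100.0), np.array(20.0)) == \
            pytest.approx(8.3708, abs=1e-3)
        assert linkage._lod(np.array(100.0), np.array(0.0)) == \
            pytest.approx(100 * np.log10(2), abs=1e-9)

    def test_uninformative_pair_is_nan(self):
        x = np.array([0.0, np.nan, 1.0])
        y = np.array([np.nan, 1.0, np.nan])
        rf = linkage.pairwise_rf_lod(np.vstack([x, y]))
        assert np.isnan(rf.r[0, 1]) and rf.n[0, 1] == 0


class TestPhasing:
    def test_flip_symmetry(self):
        x = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], dtype=float)
        y = x.copy()
        y[[1, 6]] = 1 - y[[1, 6]]  # 2 recombinants, r = 0.2
        for invert in (False, True):
            y2 = 1 - y if invert else y
            pgm = _pgm(np.vstack([x, y2]))
            rf = linkage.pairwise_rf_lod(pgm)
            ph = linkage.infer_phase(pgm, np.array([0, 1]), rf, lod_min=0.5)
            flags = ph.phase_flags.to_numpy()
            assert flags[0] == flags[1] if not invert else flags[0] != flags[1]
            r_after = linkage.pairwise_rf_lod(ph).r[0, 1]
            assert r_after == pytest.approx(0.2)

    def test_phase_recovery_up_to_global_flip(self, clean_cross):
        """On error-free data, recovered phases equal the simulated parental
        phases up to one global flip per linkage group."""
        gm, truth = clean_cross
        sets = linkage.split_by_configuration(gm)
        map_table, pgm, _ = linkage.build_parental_map(sets["P1"])
        for lg, grp in map_table.groupby("lg"):
            ids = [m for m in grp["marker_id"]]
            rec = pgm.phase_flags.loc[ids].astype(int)
            tru = truth.phase_flags.loc[ids, "P1"].astype(int)
            assert len(set((rec ^ tru).tolist())) == 1


class TestGrouping:
    def test_two_chromosomes_two_groups(self, clean_cross):
        gm, truth = clean_cross
        sets = linkage.split_by_configuration(gm)
        rf = linkage.pairwise_rf_lod(sets["P1"])
        groups = linkage.group_markers(rf)
        assert len(groups) == 2
        # each group maps to one true chromosome
        for g in groups:
            lgs = truth.markers.loc[sets["P1"].marker_ids[g], "lg"]
            assert lgs.nunique() == 1

    def test_all_missing_marker_is_singleton(self):
        data = np.array([[0, 0, 1, 1], [0, 0, 1, 1],
                         [np.nan] * 4], dtype=float)
        rf = linkage.pairwise_rf_lod(_pgm(data))
        groups = linkage.group_markers(rf, lod_min=0.5)
        assert sorted(len(g) for g in groups) == [1, 2]


class TestBins:
    def test_identical_markers_share_bin(self):
        v = np.array([0, 1, 0, 1, 1, 0], dtype=float)
        w = 1 - v  # opposite vector: 6 observed recombinations
        bins = linkage.collapse_bins(_pgm(np.vstack([v, v, v, w])))
        assert len(bins) == 2
        sizes = sorted(len(b.members) for b in bins)
        assert sizes == [1, 3]

    def test_representative_least_missing_ties_lexicographic(self):
        v = np.array([0, 1, 0, 1, 1, 0], dtype=float)
        v2 = v.copy()
        v2[0] = np.nan
        bins = linkage.collapse_bins(_pgm(np.vstack([v2, v, v]),
                                          ids=["a", "c", "b"]))
        assert bins[0].representative == "b"

    def test_all_distinct_markers_all_singletons(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 2, size=(1, 50)).astype(float)
        data = np.vstack([base, 1 - base,
                          np.roll(base, 7), 1 - np.roll(base, 7)])
        # force observable recombination between every pair
        bins = linkage.collapse_bins(_pgm(data))
        assert len(bins) == len(data)


def _chain_matrix(n, flips_per_gap, n_markers, rng):
    """Markers along a chromosome with exactly ``flips_per_gap`` recombinant
    gametes between neighbours (disjoint flip sets -> additive r)."""
    data = [rng.integers(0, 2, size=n).astype(float)]
    cursor = 0
    for _ in range(n_markers - 1):
        v = data[-1].copy()
        idx = np.arange(cursor, cursor + flips_per_gap) % n
        v[idx] = 1 - v[idx]
        cursor += flips_per_gap
        data.append(v)
    return np.vstack(data)


class TestOrdering:
    def test_five_bins_recover_truth_and_minimal_sarf(self):
        """Bins at 0,10,20,30,40 cM: MST ordering equals the truth (or its
        reverse) and attains the exhaustive-minimum SARF over all 5! orders."""
        import itertools

        rng = np.random.default_rng(4)
        data = _chain_matrix(500, 50, 5, rng)  # adjacent r = 0.1
        perm = rng.permutation(5)
        shuffled = data[perm]
        rf = linkage.pairwise_rf_lod(shuffled)
        d = rf.r
        order = linkage.order_markers_mst(d)
        recovered = [int(perm[i]) for i in order]
        assert recovered in ([0, 1, 2, 3, 4], [4, 3, 2, 1, 0])
        best = min(linkage.sarf(list(p), d)
                   for p in itertools.permutations(range(5)))
        assert linkage.sarf(order, d) <= best + 1e-9

    def test_two_bins_trivial(self):
        assert linkage.order_markers_mst(np.array([[0, 0.1], [0.1, 0]])) \
            == [0, 1]

    def test_sarf_never_beaten_by_truth_on_clean_data(self, clean_cross):
        """The returned order's SARF <= the true order's SARF (the estimator
        cannot lose to the truth on its own objective) on error-free data."""
        gm, truth = clean_cross
        sets = linkage.split_by_configuration(gm)
        map_table, pgm, _ = linkage.build_parental_map(sets["P1"])
        id_to_row = {m: i for i, m in enumerate(pgm.marker_ids)}
        for lg, grp in map_table.groupby("lg"):
            reps = grp.drop_duplicates("bin_id").sort_values("position")
            rows = [id_to_row[m] for m in reps["marker_id"]]
            rf = linkage.pairwise_rf_lod(pgm.data[rows])
            d = np.clip(rf.r, 0, None)
            map_order = list(range(len(rows)))
            true_cm = truth.markers.loc[reps["marker_id"], "cm"].to_numpy()
            true_order = list(np.argsort(true_cm))
            assert linkage.sarf(map_order, d) <= \
                linkage.sarf(true_order, d) + 1e-9


class TestKosambi:
    def test_closed_forms(self):
        assert linkage.kosambi(0.0) == 0.0
        assert linkage.kosambi(0.25) == pytest.approx(25 * np.log(3))
        assert linkage.kosambi_inverse(31.35) == pytest.approx(0.278, abs=5e-4)

    def test_domain(self):
        with pytest.raises(ValueError):
            linkage.kosambi(0.5)

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=0.49))
    def test_roundtrip_property(self, r):
        assert linkage.kosambi_inverse(linkage.kosambi(r)) == \
            pytest.approx(r, abs=1e-10)


class TestDoubleRecombinantScan:
    def test_isolated_flip_flagged(self):
        col = np.array([0, 0, 0, 1, 0, 0, 0], dtype=float)[:, None]
        flags, dropped = linkage.scan_double_recombinants(col)
        assert flags[:, 0].tolist() == [False, False, False, True,
                                        False, False, False]

    def test_true_crossover_not_flagged(self):
        col = np.array([0, 0, 0, 1, 1, 1], dtype=float)[:, None]
        flags, _ = linkage.scan_double_recombinants(col)
        assert not flags.any()

    @staticmethod
    def _truth_phased(seed, error_rate):
        """Raw-coded maternal set in true order, aligned to the simulated
        phase (the pipeline's phasing step normally provides this)."""
        cfg = SimConfig(n_progeny=250, lg_lengths=(100.0,), n_markers=150,
                        missing_rate=0.0, error_rate=error_rate, seed=seed)
        gm, truth = simulate_cross(cfg)
        pgm = linkage.split_by_configuration(gm)["P1"]
        order = np.argsort(truth.markers.loc[pgm.marker_ids, "cm"].to_numpy(),
                           kind="stable")
        ids = pgm.marker_ids[order]
        flags = truth.phase_flags.loc[ids, "P1"].to_numpy()[:, None]
        data = np.abs(pgm.data[order] - flags)   # flip to homolog coding
        true_h = np.abs(truth.true_gamete_codes("P1", ids) - flags[:, 0][:, None])
        return data, true_h.astype(float)

    def test_planted_error_recall(self):
        """>= 80% of planted genotyping errors are flagged on a dense map."""
        data, true_h = self._truth_phased(seed=31, error_rate=0.01)
        wrong = np.isfinite(data) & (data != true_h)
        flags, _ = linkage.scan_double_recombinants(data)
        wrong[[0, -1], :] = False  # terminal genotypes cannot be flagged
        recall = flags[wrong].mean()
        assert recall >= 0.8

    def test_clean_data_flag_rate_near_double_crossover_background(self):
        data, _ = self._truth_phased(seed=32, error_rate=0.0)
        flags, _ = linkage.scan_double_recombinants(data)
        assert flags.mean() < 0.001


class TestMapBuilding:
    def test_positions_from_adjacent_rf(self):
        rng = np.random.default_rng(5)
        data = _chain_matrix(1000, 100, 3, rng)  # adjacent r exactly 0.1
        pgm = _pgm(data)
        lg_map, _ = linkage.map_linkage_group(pgm, lg=1, drop_threshold=1.1)
        pos = np.sort(lg_map["position"].to_numpy())
        d = linkage.kosambi(0.1)
        assert pos == pytest.approx([0.0, d, 2 * d], abs=1e-9)
        assert d == pytest.approx(10.1366, abs=1e-3)

    def test_single_bin_lg_has_zero_length(self):
        v = np.array([0, 1, 0, 1], dtype=float)
        lg_map, _ = linkage.map_linkage_group(_pgm(np.vstack([v, v])), lg=1)
        assert (lg_map["position"] == 0).all()

    def test_total_length_tracks_mapping_function_expectation(self,
                                                              clean_cross):
        """Total map length within 10% of the derived expectation: summed
        Kosambi transforms of the interference-free (Haldane) recombination
        fractions between adjacent informative marker positions."""
        gm, truth = clean_cross
        sets = linkage.split_by_configuration(gm)
        map_table, _, summary = linkage.build_parental_map(sets["P1"])
        expected = 0.0
        for lg in (1, 2):
            ids = sets["P1"].marker_ids
            cms = np.sort(truth.markers.loc[
                truth.markers.index.isin(ids)
                & (truth.markers["lg"] == lg), "cm"].unique())
            gaps = np.diff(cms)
            r_h = (1 - np.exp(-2 * gaps / 100)) / 2
            expected += float(linkage.kosambi(r_h).sum())
        total = summary["length"].sum()
        assert total == pytest.approx(expected, rel=0.10)


class TestRecombinationCounting:
    def test_sign_changes(self):
        col = np.array([0, 0, 0, 1, 1, 1], dtype=float)[:, None]
        assert linkage.count_sign_changes(col)[0] == 1

    def test_missing_skipped(self):
        col = np.array([0, np.nan, 0, 1, 1, 1], dtype=float)[:, None]
        assert linkage.count_sign_changes(col)[0] == 1

    def test_per_lg_means_track_length(self, clean_cross):
        gm, truth = clean_cross
        sets = linkage.split_by_configuration(gm)
        map_table, pgm, _ = linkage.build_parental_map(sets["P1"])
        counts = linkage.count_recombination_events(pgm, map_table)
        # chromosomes are 90 and 70 cM; observed events near L/100
        assert counts["mean_events"].max() == pytest.approx(0.9, abs=0.12)
        assert counts["mean_events"].min() == pytest.approx(0.7, abs=0.12)


class TestIntegration:
    def _identical_parent_setup(self):
        rng = np.random.default_rng(6)
        data = _chain_matrix(240, 24, 6, rng)  # adjacent r = 0.1
        pgm1 = _pgm(data, ids=[f"a{i}" for i in range(6)])
        pgm2 = _pgm(data, ids=[f"b{i}" for i in range(6)], parent="P2")
        p1_map, pgm1c = linkage.map_linkage_group(pgm1, lg=1,
                                                  drop_threshold=1.1)
        p2_map, pgm2c = linkage.map_linkage_group(pgm2, lg=1,
                                                  drop_threshold=1.1)
        anchors = _pgm(data[[1, 4]], ids=["x1", "x2"])
        return p1_map, p2_map, pgm1c, pgm2c, anchors

    def test_identical_parents_integrate_to_parental_positions(self):
        """When both parental maps coincide and anchors sit exactly on
        mapped markers, integration reproduces the parental coordinates."""
        p1_map, p2_map, pgm1, pgm2, anchors = self._identical_parent_setup()
        integrated = linkage.integrate_maps(p1_map, p2_map, pgm1, pgm2,
                                            anchors, lod_attach=5.0)
        assert integrated["lg"].nunique() == 1
        merged = integrated.set_index("marker_id")
        ref = p1_map.set_index("marker_id")
        for mid in ref.index:
            assert merged.loc[mid, "position"] == \
                pytest.approx(ref.loc[mid, "position"], abs=1e-6)
        assert np.all(np.diff(integrated["position"]) >= -1e-9)

    def test_no_anchors_is_an_error(self):
        p1_map, p2_map, pgm1, pgm2, _ = self._identical_parent_setup()
        empty = _pgm(np.empty((0, 240)))
        with pytest.raises(linkage.LinkageError, match="anchor"):
            linkage.integrate_maps(p1_map, p2_map, pgm1, pgm2, empty)

    def test_simulated_cross_integrates_to_true_order(self, small_cross):
        from ptxmap.pipeline import order_recovery_tau, run_pipeline

        gm, truth = small_cross
        res = run_pipeline(gm=gm, compute_ld=False)
        assert res.integrated is not None
        tau = order_recovery_tau(res.integrated, truth)
        assert len(tau) == 3
        assert (tau["purity"] == 1.0).all()
        assert tau["abs_tau"].min() >= 0.9
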