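"""COI origin tracer: curation, encoding, clustering, DAPC, profiles."""

import numpy as np
import pytest
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import adjusted_rand_score

import dorsatrace as dt
from dorsatrace.coitrace import AlleleMatrix, _diffngroup


def make_aln(seqs, regions=None, ids=None):
    n = len(seqs)
    return dt.BarcodeAlignment(
        ids=ids or [f"s{i}" for i in range(n)],
        seqs=[s.upper() for s in seqs],
        region=regions or ["Unknown"] * n,
    )


class TestCurateAlignment:
    def test_internal_stop_codon_rejected(self):
        clean = "ATTGCAGGAATTGCA"  # no TAA/TAG codons in frame 1
        dirty = "ATTGCATAAATTGCA"  # TAA at codon 3
        aln = make_aln([clean, clean, dirty])
        kept, report = dt.curate_alignment(aln, frame=1)
        assert kept.ids == ["s0", "s1"]
        assert report == [("s2", "stop_codon")]

    def test_clean_alignment_untouched(self, barcode_reference):
        _, aln, _ = barcode_reference
        kept, report = dt.curate_alignment(aln, frame=1)
        assert report == []
        assert kept.ids == aln.ids

    def test_private_gap_rejected_at_threshold(self):
        base = "ATTGCAGGAATT"
        seqs = [base] * 99 + ["ATT-CAGGAATT"]
        kept, report = dt.curate_alignment(make_aln(seqs), frame=1, gap_consistency=0.05)
        # 1/100 gapped < 0.05 -> the gap is inconsistent
        assert ("s99", "inconsistent_gap") in report
        assert len(kept.ids) == 99

    def test_consistent_gap_column_kept(self):
        gapped = "ATT-CAGGAATT"
        seqs = [gapped] * 50 + ["ATTGCAGGAATT"] * 50
        kept, report = dt.curate_alignment(make_aln(seqs), frame=1, gap_consistency=0.05)
        assert report == []

    def test_excess_ambiguity_rejected(self):
        clean = "ATTGCAGGAATT"
        dirty = "ATTNNNNNNATT"
        kept, report = dt.curate_alignment(
            make_aln([clean, clean, dirty]), frame=1, max_ambiguous=2
        )
        assert report == [("s2", "too_ambiguous")]

    def test_missing_frame_and_reference_is_hard_error(self):
        with pytest.raises(ValueError, match="frame or ref_id"):
            dt.curate_alignment(make_aln(["ATTGCA", "ATTGCA"]))

    def test_frame_inference_from_reference_row(self):
        # TAA sits in frame 1; frames 2 and 3 are stop-free for the
        # reference, so inference must avoid frame 1
        seqs = ["ATTGCATAAATTGCAGGA"] * 3
        kept, report = dt.curate_alignment(make_aln(seqs), ref_id="s0")
        assert report == []


class TestExciseRegion:
    def test_gapless_reference_prefix(self):
        aln = make_aln(["ACGTACGTACGTACG", "TGCATGCATGCATGC"])
        out = dt.excise_region(aln, "s0", ref_start=1, ref_len=10)
        assert out.columns == 10
        assert out.seqs[0] == "ACGTACGTAC"

    def test_internal_reference_gaps_widen_window(self):
        ref = "AC--GTACGTACGT"  # 12 non-gap chars
        other = "ACGGGTACGTACGT"
        out = dt.excise_region(make_aln([ref, other]), "s0", ref_start=1, ref_len=10)
        # 10 reference bases span 12 alignment columns (2 internal gaps)
        assert out.columns == 12

    def test_window_exceeding_reference_is_hard_error(self):
        aln = make_aln(["ACGTACGT", "ACGTACGA"])
        with pytest.raises(ValueError, match="exceeds"):
            dt.excise_region(aln, "s0", ref_start=1, ref_len=10)


class TestEncodeAlignment:
    def test_hand_encoding_single_polymorphic_column(self):
        x = dt.encode_alignment(make_aln(["ACG", "AAG", "ACG"]))
        assert x.columns == ["2.C", "2.A"]  # major allele first
        assert x.x.tolist() == [[1, 0], [0, 1], [1, 0]]

    def test_n_at_polymorphic_position_is_missing(self):
        x = dt.encode_alignment(make_aln(["ACG", "AAG", "ANG"]))
        assert np.isnan(x.x[2]).all()

    def test_invariant_alignment_is_hard_error(self):
        with pytest.raises(ValueError, match="polymorphic"):
            dt.encode_alignment(make_aln(["ACG", "ACG"]))

    def test_exactly_one_indicator_set_per_observed_column(self, barcode_reference):
        _, aln, _ = barcode_reference
        x = dt.encode_alignment(aln)
        pos = [c.rsplit(".", 1)[0] for c in x.columns]
        for p in set(pos):
            block = x.x[:, [i for i, q in enumerate(pos) if q == p]]
            sums = np.nansum(block, axis=1)
            observed = ~np.isnan(block).all(axis=1)
            assert np.all(sums[observed] == 1)


class TestFindClusters:
    def test_two_separated_clouds_recovered_exactly(self):
        cfg = dt.disjoint_pool_config(
            {"Africa": 20, "Pacific": 20}, haps_per_region=1,
            hap_divergence=0.05, mutation_rate=0.005, seed=20,
        )
        aln, truth = dt.simulate_barcodes(cfg)
        x = dt.encode_alignment(aln)
        labels, bic, k = dt.find_clusters(x, k_max=8, seed=20)
        assert k == 2
        true = (np.asarray(aln.region) == "Pacific").astype(int)
        assert adjusted_rand_score(true, labels) == 1.0

    def test_homogeneous_cloud_selects_one_cluster(self):
        cfg = dt.disjoint_pool_config(
            {"Africa": 40}, haps_per_region=1, mutation_rate=0.01, seed=21
        )
        aln, _ = dt.simulate_barcodes(cfg)
        x = dt.encode_alignment(aln)
        labels, bic, k = dt.find_clusters(x, k_max=8, seed=21)
        assert k == 1
        assert len(set(labels)) == 1

    def test_seed_determinism(self, barcode_reference):
        _, aln, _ = barcode_reference
        x = dt.encode_alignment(aln)
        l1, b1, k1 = dt.find_clusters(x, k_max=10, seed=3)
        l2, b2, k2 = dt.find_clusters(x, k_max=10, seed=3)
        assert k1 == k2 and np.array_equal(l1, l2) and b1 == b2

    def test_wss_non_increasing_in_k(self, barcode_reference):
        _, aln, _ = barcode_reference
        x = dt.encode_alignment(aln)
        _, bic, _ = dt.find_clusters(x, k_max=10, seed=3, n_restarts=20)
        n = x.n
        wss = {k: np.exp((v - k * np.log(n)) / n) * n for k, v in bic.items()}
        ks = sorted(wss)
        for a, b in zip(ks, ks[1:]):
            assert wss[b] <= wss[a] * 1.001  # generous restarts: near-nested

    def test_k_max_at_least_n_is_hard_error(self):
        x = AlleleMatrix(ids=["a", "b"], columns=["1.A"], x=[[1.0], [0.0]])
        with pytest.raises(ValueError, match="k_max"):
            dt.find_clusters(x, k_max=2)

    def test_diffngroup_flat_curve_gives_one(self):
        bic = {k: 100.0 + 2 * k for k in range(1, 8)}  # strictly increasing
        assert _diffngroup(bic) == 1


def separable_matrix(seed=22, n_per=30, shift=6.0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n_per, 30))
    b = rng.normal(shift, 1, size=(n_per, 30))
    x = np.vstack([a, b])
    x = (x > x.mean(axis=0)).astype(float)  # binarize to indicator-like data
    labels = np.array([0] * n_per + [1] * n_per)
    return AlleleMatrix(
        ids=[f"i{i}" for i in range(2 * n_per)],
        columns=[f"{j+1}.A" for j in range(30)],
        x=x,
    ), labels


class TestXvalPcSelection:
    def test_separable_data_hits_perfect_accuracy_at_smallest_grid_value(self):
        x, labels = separable_matrix()
        table, best = dt.xval_pc_selection(x, labels, pc_grid=[1, 3, 5], reps=5, seed=1)
        assert all(v == 1.0 for v in table.values())
        assert best == 1

    def test_permuted_labels_accuracy_near_prevalence(self):
        cfg = dt.disjoint_pool_config(
            {"Africa": 40, "Pacific": 20}, haps_per_region=2, mutation_rate=0.002, seed=23
        )
        aln, _ = dt.simulate_barcodes(cfg)
        x = dt.encode_alignment(aln)
        rng = np.random.default_rng(23)
        labels = rng.permutation(np.array([0] * 40 + [1] * 20))
        table, _ = dt.xval_pc_selection(x, labels, pc_grid=[3], reps=20, seed=23)
        # null accuracy ≈ majority prevalence 2/3, within Monte-Carlo error
        assert abs(table[3] - 2 / 3) < 0.15

    def test_single_rep_reproducible(self):
        x, labels = separable_matrix()
        t1, b1 = dt.xval_pc_selection(x, labels, pc_grid=[2, 4], reps=1, seed=9)
        t2, b2 = dt.xval_pc_selection(x, labels, pc_grid=[2, 4], reps=1, seed=9)
        assert t1 == t2 and b1 == b2

    def test_singleton_cluster_excluded_with_warning(self):
        x, labels = separable_matrix()
        labels = labels.copy()
        labels[0] = 2  # singleton cluster
        with pytest.warns(RuntimeWarning, match="excluded"):
            table, _ = dt.xval_pc_selection(x, labels, pc_grid=[2], reps=2, seed=1)


class TestFitDapc:
    def test_two_clusters_give_one_axis(self):
        x, labels = separable_matrix()
        model = dt.fit_dapc(x, labels, n_pcs=5)
        assert model.n_da == 1
        assert model.da_axes.shape == (5, 1)

    def test_self_assignment_perfect_on_separable_data(self):
        x, labels = separable_matrix()
        model = dt.fit_dapc(x, labels, n_pcs=5)
        assert model.self_assignment_accuracy == 1.0

    def test_matches_lda_on_pcs_oracle(self):
        # 60 individuals × 30 indicator columns, 3 overlapping clusters
        rng = np.random.default_rng(24)
        centers = rng.normal(0, 1.2, size=(3, 30))
        raw = np.vstack([c + rng.normal(0, 1, size=(20, 30)) for c in centers])
        x_bin = (raw > 0).astype(float)
        labels = np.repeat([0, 1, 2], 20)
        x = AlleleMatrix(
            ids=[f"i{i}" for i in range(60)],
            columns=[f"{j+1}.A" for j in range(30)],
            x=x_bin,
        )
        n_pcs = 10
        model = dt.fit_dapc(x, labels, n_pcs=n_pcs)
        mine = [c.cluster for c in dt.assign_barcode(model, x)]

        # independent oracle: sklearn PCA then LDA with equal priors
        scores = PCA(n_components=n_pcs).fit_transform(x_bin)
        lda = LinearDiscriminantAnalysis(priors=np.full(3, 1 / 3)).fit(scores, labels)
        oracle = lda.predict(scores)
        assert np.array_equal(mine, oracle)

    def test_npcs_above_n_minus_one_is_hard_error(self):
        x, labels = separable_matrix(n_per=5)
        with pytest.raises(ValueError, match="n_pcs"):
            dt.fit_dapc(x, labels, n_pcs=30)


@pytest.fixture(scope="module")
def fitted():
    x, labels = separable_matrix(seed=25)
    with np.errstate(all="ignore"):
        return x, labels, dt.fit_dapc(x, labels, n_pcs=5)


class TestAssignBarcode:
    def test_posteriors_sum_to_one(self, fitted):
        x, labels, model = fitted
        rng = np.random.default_rng(26)
        q = AlleleMatrix(
            ids=[f"q{i}" for i in range(100)],
            columns=list(x.columns),
            x=rng.integers(0, 2, size=(100, len(x.columns))).astype(float),
        )
        post = dt.membership_posteriors(model, q)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_training_points_assigned_with_high_posterior(self, fitted):
        x, labels, model = fitted
        calls = dt.assign_barcode(model, x)
        assert all(c.posterior > 0.99 for c in calls)
        assert [c.cluster for c in calls] == list(labels)

    def test_equidistant_query_splits_posterior(self, fitted):
        x, labels, model = fitted
        # craft a query landing exactly midway between the two centroids
        mid = model.centroids.mean(axis=0)
        # invert: z = ((xi - center) @ P) @ A; pick xi = center + P A (AᵀPᵀP A)⁻¹ mid
        pa = model.pc_loadings @ model.da_axes
        xi = model.center + pa @ np.linalg.solve(pa.T @ pa, mid)
        q = AlleleMatrix(ids=["q"], columns=list(x.columns), x=xi[None, :])
        post = dt.membership_posteriors(model, q)
        assert np.allclose(post[0], [0.5, 0.5], atol=1e-6)

    def test_argmax_invariant_to_query_column_permutation(self, fitted):
        x, labels, model = fitted
        rng = np.random.default_rng(27)
        perm = rng.permutation(len(x.columns))
        q_perm = AlleleMatrix(
            ids=list(x.ids),
            columns=[x.columns[j] for j in perm],
            x=x.x[:, perm],
        )
        assert [c.cluster for c in dt.assign_barcode(model, q_perm)] == [
            c.cluster for c in dt.assign_barcode(model, x)
        ]

    def test_insufficient_overlap_returns_na(self, fitted):
        x, labels, model = fitted
        q = AlleleMatrix(
            ids=["q"],
            columns=list(x.columns),
            x=np.full((1, len(x.columns)), np.nan),
        )
        call = dt.assign_barcode(model, q)[0]
        assert call.origin == "NA"
        assert call.reason == "insufficient_overlap"


class TestRegionProfile:
    def test_hand_normalization(self):
        # cluster 0 holds 9/10 of region A and 1/100 of region B
        labels = [0] * 10 + [1] * 100
        labels[9] = 1  # region A sample #10 goes to cluster 1
        labels[10] = 0  # one region B sample goes to cluster 0
        regions = ["Africa"] * 10 + ["South Asia"] * 100
        prof = dt.region_profile(labels, regions)
        assert prof.normalized[0]["Africa"] == pytest.approx(0.9 / 0.91, abs=1e-9)
        assert prof.normalized[0]["South Asia"] == pytest.approx(0.01 / 0.91, abs=1e-9)

    def test_uniform_draws_give_uniform_profile(self):
        rng = np.random.default_rng(28)
        regions = ["Africa"] * 60 + ["East Asia"] * 60
        labels = rng.integers(0, 3, size=120)
        prof = dt.region_profile(labels, regions)
        for c in prof.normalized:
            vals = list(prof.normalized[c].values())
            assert abs(vals[0] - 0.5) < 0.2

    def test_unknown_and_excluded_regions_dropped(self):
        labels = [0, 0, 0, 0]
        regions = ["Africa", "Unknown", "Pacific", "Africa"]
        prof = dt.region_profile(labels, regions, exclusions={"Pacific"})
        assert prof.region_totals == {"Africa": 2}
        assert prof.n_with_known_origin[0] == 2

    def test_normalized_proportions_sum_to_one(self, barcode_reference):
        _, aln, _ = barcode_reference
        x = dt.encode_alignment(aln)
        labels, _, _ = dt.find_clusters(x, k_max=8, seed=7)
        prof = dt.region_profile(labels, aln.region)
        for c, props in prof.normalized.items():
            assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)


class TestClusterOrigin:
    def _profile(self, normalized):
        return dt.ClusterRegionProfile(
            counts={c: {} for c in normalized},
            normalized=normalized,
            n_with_known_origin={c: 100 for c in normalized},
            region_totals={},
        )

    def test_dominant_africa_called_africa(self):
        prof = self._profile({1: {"Africa": 0.948, "South Asia": 0.052}})
        assert dt.cluster_origin(prof, 1) == "Africa"

    def test_mixed_profile_is_ambiguous_descending(self):
        prof = self._profile({2: {"South Asia": 0.70, "Africa": 0.25, "Pacific": 0.05}})
        assert dt.cluster_origin(prof, 2) == "ambiguous:Asia,Africa,Pacific"

    def test_mascarenes_map_to_asia(self):
        prof = self._profile({5: {"Mascarenes": 1.0}})
        assert dt.cluster_origin(prof, 5) == "Asia"


class TestEndToEndRecovery:
    def test_holdout_queries_recover_true_origin(self):
        cfg = dt.disjoint_pool_config(
            {"Africa": 50, "Southeast Asia": 50}, mutation_rate=0.002, seed=30
        )
        aln, _ = dt.simulate_barcodes(cfg)
        model, profile, _ = dt.fit_coi_pipeline(aln, k_max=12, xval_reps=10, seed=30)
        qcfg = dt.HaplotypeSimConfig(
            regions={"Africa": 20, "Southeast Asia": 20},
            haplotypes=cfg.haplotypes,
            haplotype_pools=cfg.haplotype_pools,
            mutation_rate=0.002,
            barcode_length=cfg.barcode_length,
            seed=31,
        )
        qaln, _ = dt.simulate_barcodes(qcfg)
        q = dt.encode_against_model(qaln, model)
        calls = dt.calls_with_origin(dt.assign_barcode(model, q), profile)
        hits = sum(
            c.origin == dt.DEFAULT_ORIGIN_MAP[r] for c, r in zip(calls, qaln.region)
        )
        assert hits / len(calls) >= 0.95

    def test_planted_discordance_surfaces_in_coi_calls(self):
        rate = 0.1
        cfg = dt.disjoint_pool_config(
            {"Africa": 100, "Southeast Asia": 100},
            mutation_rate=0.001,
            discordance_rate=rate,
            seed=32,
        )
        aln, truth = dt.simulate_barcodes(cfg)
        # fit on concordant reference, call the discordant set
        ref_cfg = dt.HaplotypeSimConfig(
            regions=cfg.regions,
            haplotypes=cfg.haplotypes,
            haplotype_pools=cfg.haplotype_pools,
            mutation_rate=0.001,
            barcode_length=cfg.barcode_length,
            seed=33,
        )
        ref_aln, _ = dt.simulate_barcodes(ref_cfg)
        model, profile, _ = dt.fit_coi_pipeline(ref_aln, k_max=12, xval_reps=5, seed=33)
        q = dt.encode_against_model(aln, model)
        calls = dt.calls_with_origin(dt.assign_barcode(model, q), profile)
        mismatch = np.mean(
            [c.origin != dt.DEFAULT_ORIGIN_MAP[r] for c, r in zip(calls, aln.region)]
        )
        # COI calls disagree with nuclear truth for ≈ the planted fraction
        assert abs(mismatch - rate) < 0.05
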