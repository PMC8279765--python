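import numpy as np
import pytest

from oracles import random_profile

from pestiscan.align import sw_score, sw_score_naive
from pestiscan.cli_io import FixtureSpec, generate_family_fixture
from pestiscan.hmm_core import forward_score, write_model
from pestiscan.model_builder import (
    CalibrationReport,
    ClusterSet,
    MclConvergenceError,
    SeqRecord,
    ShortSequenceError,
    SimilarityGraph,
    build_models,
    build_pipeline,
    calibrate_cutoff,
    deduplicate,
    make_cterm_model,
    mcl_cluster,
    similarity_graph,
    validate_model,
)


def clique_edges(names, weight):
    return [
        (names[i], names[j], weight)
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]


class TestDeduplicate:
    def test_exact_duplicates_merge(self):
        clusters, reps = deduplicate([SeqRecord("A", "MKV"), SeqRecord("B", "MKV")])
        assert len(reps) == 1
        assert clusters.clusters == [["A", "B"]]

    def test_substring_merges_keeping_longest(self):
        clusters, reps = deduplicate([SeqRecord("A", "MKVLT"), SeqRecord("B", "KVL")])
        assert [r.id for r in reps] == ["A"]
        assert clusters.clusters == [["A", "B"]]

    def test_single_mismatch_not_merged(self):
        _, reps = deduplicate([SeqRecord("A", "MKVLT"), SeqRecord("B", "MKALT")])
        assert sorted(r.id for r in reps) == ["A", "B"]

    def test_tie_broken_lexicographically(self):
        _, reps = deduplicate([SeqRecord("B", "MKV"), SeqRecord("A", "MKV")])
        assert [r.id for r in reps] == ["A"]

    def test_idempotent_on_representatives(self):
        seqs = [
            SeqRecord("A", "MKVLTQSW"),
            SeqRecord("B", "KVLT"),
            SeqRecord("C", "MKVLTQSW"),
            SeqRecord("D", "HHHH"),
        ]
        _, reps = deduplicate(seqs)
        again_clusters, again = deduplicate(reps)
        assert [r.id for r in again] == [r.id for r in reps]
        assert all(len(c) == 1 for c in again_clusters.clusters)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            deduplicate([])


class TestSimilarityGraph:
    def test_identical_sequences_edge_is_self_score(self):
        seq = "MKVLTQSWHEAGAWGHEE"
        graph = similarity_graph(
            [SeqRecord("A", seq), SeqRecord("B", seq)], edge_floor=0.0
        )
        assert len(graph.edges) == 1
        a, b, w = graph.edges[0]
        assert w == sw_score(seq, seq)

    def test_symmetry(self):
        a, b = "MKVLTQSWHE", "KVLTMSWHEA"
        assert sw_score(a, b) == sw_score(b, a)

    def test_floor_drops_weak_pairs(self):
        graph = similarity_graph(
            [SeqRecord("A", "MKVLT"), SeqRecord("B", "WWWHH")], edge_floor=50.0
        )
        assert graph.edges == []

    def test_sw_against_naive_oracle_known_pair(self):
        # Smith-Waterman on the classic pair, BLOSUM62, open 10 / extend 1
        assert sw_score("HEAGAWGHEE", "PAWHEAE") == sw_score_naive("HEAGAWGHEE", "PAWHEAE")
        assert sw_score("HEAGAWGHEE", "PAWHEAE") == 18.0

    def test_sw_against_naive_oracle_random(self):
        rng = np.random.default_rng(11)
        from pestiscan.alphabet import AMINO_ACIDS

        for _ in range(15):
            a = "".join(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(5, 40))))
            b = "".join(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(5, 40))))
            assert sw_score(a, b) == pytest.approx(sw_score_naive(a, b))


class TestMcl:
    def test_two_disconnected_cliques(self):
        nodes = ["a1", "a2", "a3", "b1", "b2", "b3"]
        edges = clique_edges(nodes[:3], 5.0) + clique_edges(nodes[3:], 5.0)
        cs = mcl_cluster(SimilarityGraph(nodes=nodes, edges=edges))
        assert sorted(map(sorted, cs.clusters)) == [["a1", "a2", "a3"], ["b1", "b2", "b3"]]

    def test_single_node(self):
        cs = mcl_cluster(SimilarityGraph(nodes=["only"], edges=[]))
        assert cs.clusters == [["only"]]
        assert cs.singletons == ["only"]

    def test_barbell_splits_at_weak_bridge(self):
        left = [f"l{i}" for i in range(4)]
        right = [f"r{i}" for i in range(4)]
        edges = clique_edges(left, 10.0) + clique_edges(right, 10.0) + [("l3", "r0", 1.0)]
        cs = mcl_cluster(SimilarityGraph(nodes=left + right, edges=edges), inflation=2.0)
        assert sorted(map(sorted, cs.clusters)) == [sorted(left), sorted(right)]

    def test_partition_and_order_invariance(self):
        rng = np.random.default_rng(3)
        nodes = [f"n{i}" for i in range(12)]
        edges = []
        for i in range(12):
            for j in range(i + 1, 12):
                if rng.random() < 0.4:
                    edges.append((nodes[i], nodes[j], float(rng.integers(1, 20))))
        cs = mcl_cluster(SimilarityGraph(nodes=nodes, edges=edges))
        flat = sorted(n for c in cs.clusters for n in c)
        assert flat == sorted(nodes)
        shuffled_nodes = list(reversed(nodes))
        shuffled_edges = list(reversed(edges))
        cs2 = mcl_cluster(SimilarityGraph(nodes=shuffled_nodes, edges=shuffled_edges))
        assert sorted(map(sorted, cs.clusters)) == sorted(map(sorted, cs2.clusters))

    def test_intermediate_matrices_column_stochastic(self):
        left = [f"l{i}" for i in range(4)]
        right = [f"r{i}" for i in range(4)]
        edges = clique_edges(left, 10.0) + clique_edges(right, 10.0) + [("l3", "r0", 1.0)]
        trace = []
        mcl_cluster(SimilarityGraph(nodes=left + right, edges=edges), _trace=trace)
        assert trace
        for M in trace:
            assert np.allclose(M.sum(axis=0), 1.0, atol=1e-9)

    def test_non_convergence_reports_residual(self):
        # a long path mixes slowly; one iteration cannot reach the fixed point
        nodes = [f"p{i}" for i in range(8)]
        edges = [(nodes[i], nodes[i + 1], 1.0) for i in range(7)]
        with pytest.raises(MclConvergenceError, match="residual"):
            mcl_cluster(SimilarityGraph(nodes=nodes, edges=edges), max_iter=1)

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            mcl_cluster(SimilarityGraph(nodes=["a"], edges=[]), inflation=1.0)


def _sized_clusters_fixture():
    """Families of sizes 1..8 with low divergence, as explicit clusters."""
    spec = FixtureSpec(
        seed=9, n_families=8, family_size=8, family_length=60,
        divergence=0.05, n_decoys=0,
    )
    families, _, _ = generate_family_fixture(spec)
    seqs, clusters = [], []
    for size, (name, fam) in zip(range(1, 9), sorted(families.items())):
        # family_size is 8; take the first `size` members
        chosen = fam[:size]
        seqs.extend(chosen)
        clusters.append([r.id for r in chosen])
    return ClusterSet(clusters=clusters), seqs


class TestBuildModels:
    def test_min_size_five_filters_clusters(self):
        clusters, seqs = _sized_clusters_fixture()
        models = build_models(clusters, seqs, min_size=5)
        assert len(models) == 4  # sizes 5, 6, 7, 8
        assert sorted(m.source_size for m in models) == [5, 6, 7, 8]

    def test_min_size_one_models_every_cluster(self):
        clusters, seqs = _sized_clusters_fixture()
        models = build_models(clusters, seqs, min_size=1)
        assert len(models) == len(clusters.clusters)

    def test_min_size_monotone_subset(self):
        clusters, seqs = _sized_clusters_fixture()
        for m in range(1, 8):
            lo = {x.name for x in build_models(clusters, seqs, min_size=m)}
            hi = {x.name for x in build_models(clusters, seqs, min_size=m + 1)}
            assert hi <= lo

    def test_designated_singleton_model(self):
        rec = SeqRecord("xpp37", "MKVLTQSWHEAGAWGHEE")
        clusters = ClusterSet(clusters=[["xpp37"]])
        models = build_models(clusters, [rec], min_size=5, single_model_ids=["xpp37"])
        assert len(models) == 1
        assert models[0].source_size == 1
        assert models[0].consensus() == rec.sequence


class TestCtermModel:
    def _long_records(self, n, length, seed=21):
        rng = np.random.default_rng(seed)
        from pestiscan.alphabet import AMINO_ACIDS

        tail = "".join(rng.choice(list(AMINO_ACIDS), size=300))
        recs = []
        for i in range(n):
            core = "".join(rng.choice(list(AMINO_ACIDS), size=length - 300))
            mutated_tail = "".join(
                c if rng.random() > 0.05 else str(rng.choice(list(AMINO_ACIDS)))
                for c in tail
            )
            recs.append(SeqRecord(f"cry{i}", core + mutated_tail))
        return recs, tail

    def test_length_999_rejected(self):
        recs, _ = self._long_records(1, 999)
        with pytest.raises(ShortSequenceError, match="1000"):
            make_cterm_model(recs, core_boundary=700)

    def test_length_1001_boundary_700_bounds_consensus(self):
        recs, _ = self._long_records(5, 1001)
        model = make_cterm_model(recs, core_boundary=700)
        assert model.n_match <= 301
        assert model.group_label == "Cry_Cterm"

    def test_invalid_boundary_rejected(self):
        recs, _ = self._long_records(1, 1100)
        with pytest.raises(ValueError, match="boundary"):
            make_cterm_model(recs, core_boundary=2000)

    def test_cterm_model_beats_core_model_on_tail_fragment(self):
        # conserved 300-aa C-terminus behind divergent cores
        recs, tail = self._long_records(5, 1100)
        boundary = 800
        cterm = make_cterm_model(recs, core_boundary=boundary)
        # control: model of the divergent cores only
        from pestiscan.msa import progressive_align
        from pestiscan.hmm_core import build_profile

        core_msa = progressive_align([(r.id, r.sequence[:boundary]) for r in recs])
        core_model = build_profile(core_msa, name="core_only")
        rng = np.random.default_rng(77)
        held_out_tail = "".join(
            c if rng.random() > 0.05 else str(rng.choice(list("ACDEFGHIKLMNPQRSTVWY")))
            for c in tail
        )
        s_cterm = forward_score(cterm, held_out_tail).forward_bits
        s_core = forward_score(core_model, held_out_tail).forward_bits
        assert s_cterm > s_core


class TestCalibration:
    @pytest.fixture()
    def dummy_model(self):
        return random_profile(np.random.default_rng(1), 3)

    def test_degenerate_positives_only(self, dummy_model):
        report = calibrate_cutoff(dummy_model, [], precomputed=([100.0, 110.0, 120.0], []))
        assert report.proposed_cutoff == pytest.approx(99.5)

    def test_separable_sets_split_cleanly(self, dummy_model):
        report = calibrate_cutoff(
            dummy_model, [], precomputed=([100.0, 110.0], [10.0, 12.0])
        )
        c = report.proposed_cutoff
        assert all(s >= c for s in [100.0, 110.0])
        assert all(s < c for s in [10.0, 12.0])

    def test_bimodal_monte_carlo_kde(self, dummy_model):
        rng = np.random.default_rng(7)
        pos = list(rng.normal(100, 3, 50))
        bg = list(rng.normal(30, 3, 200))
        report = calibrate_cutoff(dummy_model, [], precomputed=(pos, bg))
        c = report.proposed_cutoff
        assert 45 < c < 85
        errors = sum(s < c for s in pos) + sum(s >= c for s in bg)
        assert errors == 0
        # oracle: direct argmin of an independently fitted KDE between means
        from scipy.stats import gaussian_kde

        kde = gaussian_kde(np.array(pos + bg), bw_method="silverman")
        grid = np.linspace(np.mean(bg), np.mean(pos), 2000)
        oracle_cut = float(grid[np.argmin(kde(grid))])
        assert c == pytest.approx(oracle_cut, abs=2.0)

    def test_inseparable_flagged_not_raised(self, dummy_model):
        report = calibrate_cutoff(
            dummy_model, [], precomputed=([50.0, 100.0], [60.0, 10.0])
        )
        assert report.criteria_passed[3] is False
        assert report.separable is False

    def test_shifting_background_never_creates_false_positives(self, dummy_model):
        pos = [100.0, 110.0]
        for shift in (0.0, 10.0, 30.0, 60.0):
            bg = [10.0 + shift, 12.0 + shift]
            if max(bg) >= min(pos):
                continue
            report = calibrate_cutoff(dummy_model, [], precomputed=(pos, bg))
            assert sum(s >= report.proposed_cutoff for s in bg) == 0

    def test_criteria_count_enforced(self):
        with pytest.raises(ValueError):
            CalibrationReport(
                model_name="m", positive_scores=[], background_scores=[],
                proposed_cutoff=0.0, criteria_passed=[True], density_curve=[],
            )


class TestValidateModel:
    def test_clean_separation_passes_1_and_3(self, built_collection):
        model = built_collection["models"][0]
        members = [
            r for r in built_collection["members"]
            if r.id in set(built_collection["clusters"][0])
        ]
        report = validate_model(model, members, built_collection["decoys"])
        assert report.criteria_passed[0] is True
        assert report.criteria_passed[2] is True

    def test_positive_below_cutoff_fails_criterion_1(self, built_collection):
        model = built_collection["models"][0].with_cutoff(1e6)
        members = [
            r for r in built_collection["members"]
            if r.id in set(built_collection["clusters"][0])
        ]
        report = validate_model(model, members, [])
        assert report.criteria_passed[0] is False

    def test_fixture_family_passes_all_four(self, built_collection):
        for model, cluster in zip(built_collection["models"], built_collection["clusters"]):
            members = [r for r in built_collection["members"] if r.id in set(cluster)]
            report = validate_model(model, members, built_collection["decoys"])
            assert report.criteria_passed == [True, True, True, True]

    def test_requires_cutoff(self, built_collection):
        import dataclasses

        model = dataclasses.replace(built_collection["models"][0], gathering_cutoff=None)
        with pytest.raises(ValueError, match="cutoff"):
            validate_model(model, built_collection["members"][:1], [])


class TestPipelineDeterminism:
    def test_model_files_byte_identical_across_runs(self, tmp_path):
        spec = FixtureSpec(
            seed=4, n_families=2, family_size=5, family_length=80,
            divergence=0.1, n_decoys=0,
        )
        outputs = []
        for run in range(2):
            families, _, _ = generate_family_fixture(spec)
            members = [r for fam in families.values() for r in fam]
            models, _, _ = build_pipeline(members, min_size=5)
            paths = []
            for m in models:
                p = tmp_path / f"run{run}_{m.name}.phmm"
                write_model(m, p)
                paths.append(p.read_bytes())
            outputs.append(paths)
        assert outputs[0] == outputs[1]
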