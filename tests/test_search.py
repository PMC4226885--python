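"""Windows, interaction admission, elimination, optimization, staged search."""

import numpy as np
import pytest

from epiqtl import (
    GeneticMap,
    Locus,
    MIMModel,
    SearchConfig,
    qtl_window,
    run_search,
    simulate_backcross,
)
from epiqtl.search import (
    _Searcher,
    admit_interactions_with,
    backward_eliminate,
    optimize_positions,
    scan_main_effect,
    stage1,
)

from conftest import two_qtl_architecture

FAST = SearchConfig(resamples=150, seed=0)


@pytest.fixture(scope="module")
def gmap():
    return GeneticMap.uniform(n_chrom=1, length_cm=110.0, spacing_cm=10.0)


class TestQtlWindow:
    def test_mid_interval_locus(self, gmap):
        assert qtl_window(gmap, Locus("1", 47.0)) == (40.0, 50.0)

    def test_locus_on_marker_bounded_by_neighbors(self, gmap):
        assert qtl_window(gmap, Locus("1", 70.0)) == (60.0, 80.0)

    def test_near_chromosome_start(self, gmap):
        assert qtl_window(gmap, Locus("1", 5.0)) == (0.0, 10.0)

    def test_terminal_marker(self, gmap):
        lo, hi = qtl_window(gmap, Locus("1", 110.0))
        assert hi == 110.0
        assert lo == 100.0

    def test_wide_spacing_capped_at_ten(self):
        gmap = GeneticMap.uniform(n_chrom=1, length_cm=100.0, spacing_cm=50.0)
        assert qtl_window(gmap, Locus("1", 25.0)) == (15.0, 35.0)


class TestScanMainEffect:
    def test_returns_locus_outside_windows(self, arch1, arch1_cross):
        searcher = _Searcher(arch1_cross.data, FAST)
        model = MIMModel(qtl=(Locus("7", 70.0),), a=np.array([1.4]),
                         interactions=(), gamma=np.zeros(0), mu=0.0, sigma2=2.0)
        fit = searcher.fit(model, init=model)
        locus, stat, thr, p, _ = scan_main_effect(fit, searcher, searcher.rng)
        lo, hi = qtl_window(arch1_cross.data.map, Locus("7", 70.0))
        assert not (locus.chromosome == "7" and lo <= locus.position <= hi)
        assert stat > 0 and thr > 0 and 0 < p <= 1

    def test_strong_qtl_found_near_truth(self, arch1, arch1_cross):
        searcher = _Searcher(arch1_cross.data, FAST)
        fit = searcher.fit(MIMModel.null(
            mu=float(np.mean(arch1_cross.data.phenotypes)),
            sigma2=float(np.var(arch1_cross.data.phenotypes))))
        locus, stat, thr, p, _ = scan_main_effect(fit, searcher, searcher.rng)
        assert stat > thr
        truth = [q for q in arch1.qtl
                 if q.chromosome == locus.chromosome
                 and abs(q.position - locus.position) <= 10.0]
        assert truth, f"first hit {locus} not near any simulated QTL"


class TestAdmitInteractions:
    def test_single_qtl_unchanged(self, arch1_cross):
        searcher = _Searcher(arch1_cross.data, FAST)
        model = MIMModel(qtl=(Locus("7", 70.0),), a=np.zeros(1),
                         interactions=(), gamma=np.zeros(0))
        fit = searcher.fit(model)
        out = admit_interactions_with(fit, 0, searcher, searcher.rng)
        assert out.model == fit.model

    def test_strong_interaction_admitted_with_correct_sign(self):
        arch = two_qtl_architecture(gamma=-2.5)
        cross = simulate_backcross(arch, 300, seed=13)
        searcher = _Searcher(cross.data, FAST)
        model = MIMModel(qtl=arch.qtl, a=np.zeros(2), interactions=(),
                         gamma=np.zeros(0))
        fit = searcher.fit(model)
        out = admit_interactions_with(fit, 1, searcher, searcher.rng)
        assert out.model.interactions == ((0, 1),)
        assert out.model.gamma[0] < 0


class TestBackwardEliminate:
    def test_all_significant_identity(self):
        arch = two_qtl_architecture(gamma=2.5, a1=1.5, a2=1.5)
        cross = simulate_backcross(arch, 300, seed=14)
        searcher = _Searcher(cross.data, FAST)
        model = MIMModel(qtl=arch.qtl, a=np.zeros(2), interactions=((0, 1),),
                         gamma=np.zeros(1))
        fit = searcher.fit(model)
        origins = ["main", "main"]
        out = backward_eliminate(fit, searcher, searcher.rng, "stage1", origins)
        assert out.model.qtl == model.qtl
        assert out.model.interactions == ((0, 1),)

    def test_noise_qtl_removed(self):
        arch = two_qtl_architecture(gamma=0.0, a1=1.5, a2=0.0)
        cross = simulate_backcross(arch, 300, seed=15)
        searcher = _Searcher(cross.data, FAST)
        # inject a pure-noise QTL (true a2 = 0) next to the real one
        model = MIMModel(qtl=arch.qtl, a=np.zeros(2), interactions=(),
                         gamma=np.zeros(0))
        fit = searcher.fit(model)
        origins = ["main", "main"]
        out = backward_eliminate(fit, searcher, searcher.rng, "stage1", origins)
        assert out.model.qtl == (arch.qtl[0],)
        assert origins == ["main"]

    def test_removing_main_removes_interactions(self):
        # pure-noise data: everything should be stripped, and dropping a QTL
        # must take its interactions with it
        arch = two_qtl_architecture(gamma=0.0, a1=0.0, a2=0.0)
        cross = simulate_backcross(arch, 300, seed=16)
        searcher = _Searcher(cross.data, FAST)
        model = MIMModel(qtl=arch.qtl, a=np.zeros(2), interactions=((0, 1),),
                         gamma=np.zeros(1))
        fit = searcher.fit(model)
        origins = ["main", "main"]
        out = backward_eliminate(fit, searcher, searcher.rng, "stage1", origins)
        for k in range(out.model.n_qtl):
            pass  # structural invariant checked below
        assert all(
            k < out.model.n_qtl for pair in out.model.interactions for k in pair
        )
        assert out.model.n_qtl <= 1  # noise model essentially emptied

    def test_invalid_phase(self, arch1_cross):
        searcher = _Searcher(arch1_cross.data, FAST)
        fit = searcher.fit(MIMModel.null())
        with pytest.raises(ValueError):
            backward_eliminate(fit, searcher, searcher.rng, "stage7", [])


class TestOptimizePositions:
    def test_moves_toward_truth(self):
        arch = two_qtl_architecture(gamma=0.0, a1=2.0, a2=0.0)
        cross = simulate_backcross(arch, 2000, seed=17)
        searcher = _Searcher(cross.data, FAST)
        # start the QTL 4 cM off the simulated position (truth at 1:25)
        model = MIMModel(qtl=(Locus("1", 21.0),), a=np.zeros(1),
                         interactions=(), gamma=np.zeros(0))
        fit = searcher.fit(model)
        out = optimize_positions(fit, searcher, use_interactions=False)
        assert abs(out.model.qtl[0].position - 25.0) <= 2.0

    def test_stays_within_window(self, arch1_cross):
        searcher = _Searcher(arch1_cross.data, FAST)
        start = Locus("7", 68.0)
        model = MIMModel(qtl=(start,), a=np.zeros(1), interactions=(),
                         gamma=np.zeros(0))
        fit = searcher.fit(model)
        lo, hi = qtl_window(arch1_cross.data.map, start)
        out = optimize_positions(fit, searcher, use_interactions=False)
        assert lo <= out.model.qtl[0].position <= hi


class TestStages:
    def test_stage1_null_rejection_rate(self, null_arch):
        # P(any QTL accepted on no-QTL data) should be near alpha
        hits = 0
        for s in range(20):
            data = simulate_backcross(null_arch, 300, seed=40_000 + s).data
            cfg = SearchConfig(resamples=150, seed=s)
            fit, trace, searcher = stage1(data, cfg)
            hits += fit.model.n_qtl > 0
        assert hits <= 4  # binomial(20, 0.05): P(X > 4) < 0.003

    def test_full_search_recovers_planted_model(self):
        arch = two_qtl_architecture(gamma=2.2, a1=1.2, a2=1.2)
        cross = simulate_backcross(arch, 300, seed=18)
        result = run_search(cross.data, SearchConfig(resamples=150, seed=1))
        assert result.model.n_qtl == 2
        assert result.model.interactions == ((0, 1),)
        found = sorted(result.model.qtl)
        for est, true in zip(found, sorted(arch.qtl)):
            assert est.chromosome == true.chromosome
            assert abs(est.position - true.position) <= 10.0
        assert len(result.trace.checkpoints) == 6

    def test_search_deterministic(self):
        arch = two_qtl_architecture(gamma=2.2, a1=1.2, a2=1.2)
        cross = simulate_backcross(arch, 200, seed=19)
        cfg = SearchConfig(resamples=150, seed=9)
        r1 = run_search(cross.data, cfg)
        r2 = run_search(cross.data, cfg)
        assert r1.model == r2.model

    def test_final_model_self_consistent(self, arch1, arch1_cross):
        # every interaction passes its pointwise test; interaction-free mains
        # pass the genome-wide test
        from epiqtl.search import _drop_test_interaction, _drop_test_main

        cfg = SearchConfig(resamples=150, seed=2)
        result = run_search(arch1_cross.data, cfg)
        searcher = _Searcher(arch1_cross.data, cfg)
        searcher.origins = list(result.origins)
        fit = searcher.fit(result.model, init=result.model)
        rng = np.random.default_rng(123)
        for pair in fit.model.interactions:
            stat, thr = _drop_test_interaction(fit, pair, searcher, rng)
            assert stat > thr
        for k in range(fit.model.n_qtl):
            if not fit.model.partners(k):
                stat, thr = _drop_test_main(fit, k, searcher, rng,
                                            genome_wide=True)
                assert stat > thr
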