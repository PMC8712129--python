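"""Shared fixtures.

The expensive multi-seed synthetic benchmark (filter + wrapper + DE
baselines + held-out evaluation) runs once per session and feeds both the
subset-recovery and the baseline-ordering acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import settings

import modeselect as ms

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture()
def exact_ds():
    return ms.make_exact_fixture()


@pytest.fixture()
def small_synth():
    """60 x 40 separable dataset: quick end-to-end runs."""
    spec = ms.SynthSpec(n_samples=60, n_informative=3, n_redundant=5,
                        n_noise=32, effect=2.5, rho=0.9, seed=42)
    return ms.make_dataset(spec)


@dataclass
class BenchmarkSeed:
    seed: int
    handoff_size: int
    handoff_recall_informative: float
    handoff_n_signal: int
    wrapper_zero_error_small: bool
    mode_mean_size: float
    de1_mean_size: float
    de2_mean_size: float
    mode_best_front_error: float
    all_features_error: float


def _run_benchmark_seed(seed: int) -> BenchmarkSeed:
    """One seed of the scaled recovery benchmark (60 x 500, delta=2, rho=0.9).

    Selection (filter, wrapper, baselines) runs on the 60-sample dataset.
    Test errors are measured on a fresh 400-sample draw from the same
    generative process — exact generalization errors that selection never
    sees, feasible because the data are synthetic.
    """
    spec = ms.SynthSpec(n_samples=60, n_informative=5, n_redundant=20,
                        n_noise=475, effect=2.0, rho=0.9, seed=seed)
    ds, truth = ms.make_dataset(spec)
    test_spec = ms.SynthSpec(n_samples=400, n_informative=5, n_redundant=20,
                             n_noise=475, effect=2.0, rho=0.9,
                             seed=seed + 50_000)
    test, _ = ms.make_dataset(test_spec)
    cfg = ms.RunConfig(seed=seed,
                       filter_NP=20, filter_Ite=200, filter_Na=60,
                       wrapper_NP=20, wrapper_Ite=100, wrapper_Na=60)
    train = ds

    seq = np.random.SeedSequence(seed)
    s_filt, s_wrap, s_de1, s_de2, s_folds = seq.spawn(5)
    inner = ms.stratified_kfold(train.labels, cfg.inner_folds,
                                int(s_folds.generate_state(1)[0] % 2**31))
    filt = ms.run_filter_stage(train, cfg, rng=np.random.default_rng(s_filt))
    chosen = ms.pick_wrapper_input(filt)
    reads_before_eval = test.n_reads

    wrap = ms.run_wrapper_stage(train, chosen, cfg,
                                rng=np.random.default_rng(s_wrap), folds=inner)
    de1 = ms.run_baseline(train, chosen, cfg, "de1",
                          rng=np.random.default_rng(s_de1), folds=inner)
    de2 = ms.run_baseline(train, chosen, cfg, "de2",
                          rng=np.random.default_rng(s_de2), folds=inner)
    assert reads_before_eval == 0 and test.n_reads == 0

    def test_errors(res):
        out = []
        for subset, _objs in res.subsets:
            idx = subset.array()
            model = ms.nb_fit(train.matrix[:, idx], train.labels)
            pred = ms.nb_predict(model, test.matrix[:, idx])
            out.append((len(subset), float(np.mean(pred != test.labels))))
        return out

    mode_sols = test_errors(wrap)
    pts = np.array(mode_sols, dtype=float)
    from modeselect.mode_engine import nondominated_mask

    best = pts[nondominated_mask(pts)]
    model_all = ms.nb_fit(train.matrix, train.labels)
    all_err = float(np.mean(ms.nb_predict(model_all, test.matrix) != test.labels))

    informative = set(truth.tolist())
    signal = set(range(spec.n_informative + spec.n_redundant))
    return BenchmarkSeed(
        seed=seed,
        handoff_size=len(chosen),
        handoff_recall_informative=len(set(chosen.indices) & informative) / len(informative),
        handoff_n_signal=len(set(chosen.indices) & signal),
        wrapper_zero_error_small=any(
            o[1] == 0.0 and o[0] <= 5 for _, o in wrap.subsets
        ),
        mode_mean_size=float(np.mean([len(s) for s, _ in wrap.subsets])),
        de1_mean_size=float(np.mean([len(s) for s, _ in de1.subsets])),
        de2_mean_size=float(np.mean([len(s) for s, _ in de2.subsets])),
        mode_best_front_error=float(best[:, 1].min()),
        all_features_error=all_err,
    )


@pytest.fixture(scope="session")
def benchmark_runs() -> list[BenchmarkSeed]:
    return [_run_benchmark_seed(s) for s in range(10)]
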