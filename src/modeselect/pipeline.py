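"""Two-stage orchestration and the outer cross-validation protocol.

Stage 1 (filter) runs MODE over the full gene space with the three
mutual-information objectives; its smallest subset becomes the input to
stage 2 (wrapper), which runs MODE over the reduced space with the
(size, NB cross-validated error) objectives.  The DE1/DE2 baselines search
the same reduced space with scalar fitnesses.

Evaluation follows an outer stratified 5-fold protocol: selection sees
only the training split; each resulting subset is then scored by a naive
Bayes classifier fit on the whole training split and tested on the
held-out fold.  Solutions pooled over folds form a union set, summarized
as an "average" front (mean test error per subset size) and a "best" front
(nondominated (size, test error) pairs).  Dataset read counters verify
that held-out rows are never touched during selection.

Randomness: one SeedSequence per run; children are spawned in a documented
order (outer folds, then per-fold filter / wrapper / baselines / inner
folds), so every stage is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_data import Dataset, FoldPlan, RunConfig, default_filter_lambda, stratified_kfold
from .info_theory import build_cache
from .mode_engine import (
    Archive,
    Individual,
    IterationLogger,
    nondominated_mask,
    run_de_single,
    run_mode,
)
from .objectives import (
    FeatureSubset,
    binarize,
    cv_error,
    de1_fitness,
    de2_fitness,
    filter_objectives,
    nb_fit,
    nb_predict,
    wrapper_objectives,
)

__all__ = [
    "StageResult",
    "Solution",
    "FrontSummary",
    "run_filter_stage",
    "pick_wrapper_input",
    "run_wrapper_stage",
    "run_baseline",
    "run_two_stage",
    "outer_cv_experiment",
    "average_front",
    "best_front",
    "training_front_select",
    "all_features_test_error",
]


@dataclass
class StageResult:
    """Final archive of one optimizer run plus decoded subsets."""

    archive: Archive
    subsets: list[tuple[FeatureSubset, np.ndarray]]  # (subset, objective vector)
    logger: IterationLogger
    stage_tag: str  # filter | wrapper | de1 | de2
    lam: float


@dataclass(frozen=True)
class Solution:
    """One pooled solution of the outer protocol."""

    size: int
    test_error: float
    train_error: float
    fold: int
    indices: tuple[int, ...]


@dataclass
class FrontSummary:
    """Union set over outer folds with derived reporting fronts."""

    union_solutions: list[Solution]
    average_front: dict[int, float]
    best_front: list[tuple[int, float]]
    test_reads_during_selection: int = 0

    def to_dir(self, outdir, tag: str) -> None:
        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([dataclasses.asdict(s) for s in self.union_solutions]).to_csv(
            outdir / f"{tag}_union_front.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            sorted(self.average_front.items()), columns=["size", "mean_test_error"]
        ).to_csv(outdir / f"{tag}_average_front.tsv", sep="\t", index=False)
        pd.DataFrame(self.best_front, columns=["size", "test_error"]).to_csv(
            outdir / f"{tag}_best_front.tsv", sep="\t", index=False
        )


def _engine_cfg(cfg: RunConfig, NP: int, Na: int, Ite: int) -> RunConfig:
    return dataclasses.replace(cfg, NP=NP, Na=Na, Ite=Ite)


def run_filter_stage(train: Dataset, cfg: RunConfig,
                     rng: np.random.Generator | None = None) -> StageResult:
    """MODE over the full gene space with the three MI objectives."""
    lam = cfg.filter_lam if cfg.filter_lam is not None else default_filter_lambda(train.n_features)
    cache = build_cache(train, k=cfg.knn_k, seed=cfg.seed)
    logger = IterationLogger(subset_size_fn=lambda pos: len(binarize(pos, lam)))

    def objective(pos: np.ndarray) -> np.ndarray:
        return filter_objectives(binarize(pos, lam), cache)

    ecfg = _engine_cfg(cfg, cfg.filter_NP, cfg.filter_Na, cfg.filter_Ite)
    arc = run_mode(objective, train.n_features, ecfg, logger=logger, rng=rng)
    subsets = [(binarize(m.position, lam), m.objectives.copy()) for m in arc.members]
    return StageResult(arc, subsets, logger, "filter", lam)


def pick_wrapper_input(result: StageResult) -> FeatureSubset:
    """Smallest-|S| archive member; ties by redundancy, relevance, insertion order."""
    if not result.subsets:
        raise ValueError("empty archive")
    def key(item):
        _, objs = item
        f1 = objs[0]
        f3 = objs[2] if len(objs) > 2 else 0.0
        f2 = objs[1] if len(objs) > 1 else 0.0
        return (f1, f3, f2)
    best = min(enumerate(result.subsets), key=lambda t: key(t[1]) + (t[0],))
    return best[1][0]


def _inner_folds(train: Dataset, cfg: RunConfig, seed: int) -> FoldPlan:
    return stratified_kfold(train.labels, cfg.inner_folds, seed)


def run_wrapper_stage(train: Dataset, subset: FeatureSubset, cfg: RunConfig,
                      rng: np.random.Generator | None = None,
                      folds: FoldPlan | None = None) -> StageResult:
    """MODE over the filter subset's columns with (size, inner-CV error)."""
    if len(subset) == 0:
        raise ValueError("wrapper input subset is empty")
    reduced = train.restrict_features(subset.indices)
    if folds is None:
        folds = _inner_folds(train, cfg, cfg.seed)
    lam = cfg.wrapper_lam
    logger = IterationLogger(subset_size_fn=lambda pos: len(binarize(pos, lam)))

    def objective(pos: np.ndarray) -> np.ndarray:
        return wrapper_objectives(pos, lam, reduced, folds)

    ecfg = _engine_cfg(cfg, cfg.wrapper_NP, cfg.wrapper_Na, cfg.wrapper_Ite)
    arc = run_mode(objective, len(subset), ecfg, logger=logger, rng=rng)
    subsets = [
        (_lift(binarize(m.position, lam), subset), m.objectives.copy())
        for m in arc.members
    ]
    return StageResult(arc, subsets, logger, "wrapper", lam)


def _lift(local: FeatureSubset, parent: FeatureSubset) -> FeatureSubset:
    """Map a subset of the reduced space back to original feature coordinates."""
    return FeatureSubset(
        tuple(sorted(parent.indices[j] for j in local.indices)), parent.source_dim
    )


def run_baseline(train: Dataset, subset: FeatureSubset, cfg: RunConfig,
                 which: str, rng: np.random.Generator | None = None,
                 folds: FoldPlan | None = None) -> StageResult:
    """Single-objective DE baseline (de1: error only; de2: alpha-weighted)."""
    if which not in ("de1", "de2"):
        raise ValueError("which must be 'de1' or 'de2'")
    reduced = train.restrict_features(subset.indices)
    if folds is None:
        folds = _inner_folds(train, cfg, cfg.seed)
    lam = cfg.wrapper_lam
    if which == "de1":
        fitness = lambda pos: de1_fitness(pos, lam, reduced, folds)
    else:
        fitness = lambda pos: de2_fitness(pos, lam, reduced, folds, cfg.alpha)
    logger = IterationLogger(subset_size_fn=lambda pos: len(binarize(pos, lam)))
    ecfg = _engine_cfg(cfg, cfg.wrapper_NP, cfg.wrapper_Na, cfg.wrapper_Ite)
    _best, elite = run_de_single(fitness, len(subset), ecfg, logger=logger, rng=rng)
    arc = Archive(capacity=cfg.wrapper_Na, members=list(elite))
    subsets = [
        (_lift(binarize(m.position, lam), subset), m.objectives.copy())
        for m in elite
    ]
    return StageResult(arc, subsets, logger, which, lam)


def run_two_stage(train: Dataset, cfg: RunConfig,
                  seed_seq: np.random.SeedSequence | None = None
                  ) -> tuple[StageResult, StageResult]:
    """Filter stage, smallest-subset handoff, wrapper stage."""
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(cfg.seed)
    s_filter, s_wrapper, s_folds = seed_seq.spawn(3)
    filt = run_filter_stage(train, cfg, rng=np.random.default_rng(s_filter))
    chosen = pick_wrapper_input(filt)
    folds = stratified_kfold(train.labels, cfg.inner_folds,
                             int(s_folds.generate_state(1)[0] % 2**31))
    wrap = run_wrapper_stage(train, chosen, cfg,
                             rng=np.random.default_rng(s_wrapper), folds=folds)
    return filt, wrap


def average_front(union: list[Solution]) -> dict[int, float]:
    """Mean test error per distinct subset size."""
    if not union:
        raise ValueError("empty union set")
    groups: dict[int, list[float]] = {}
    for s in union:
        groups.setdefault(s.size, []).append(s.test_error)
    return {k: float(np.mean(v)) for k, v in sorted(groups.items())}


def best_front(union: list[Solution]) -> list[tuple[int, float]]:
    """Nondominated (size, test error) pairs of the union set, deduplicated."""
    if not union:
        raise ValueError("empty union set")
    pts = np.array([[s.size, s.test_error] for s in union], dtype=float)
    mask = nondominated_mask(pts)
    kept = {(int(p[0]), float(p[1])) for p, m in zip(pts, mask) if m}
    return sorted(kept)


def training_front_select(union: list[Solution]) -> list[Solution]:
    """Solutions on the training Pareto front of (training error, size).

    Test statistics of the selected set are reported downstream; test
    values play no role in the selection itself.
    """
    if not union:
        raise ValueError("empty union set")
    pts = np.array([[s.train_error, s.size] for s in union], dtype=float)
    mask = nondominated_mask(pts)
    return [s for s, m in zip(union, mask) if m]


def all_features_test_error(ds: Dataset, folds: FoldPlan) -> float:
    """NB test error using every feature, under the outer fold plan."""
    return cv_error(ds, folds)


def outer_cv_experiment(ds: Dataset, cfg: RunConfig,
                        methods: tuple[str, ...] = ("mode",),
                        k: int = 5) -> dict[str, FrontSummary]:
    """Outer stratified k-fold evaluation of the requested methods.

    Per fold: the filter stage runs once on the training split; its
    smallest subset seeds the wrapper search of every requested method
    ("mode", "de1", "de2").  Each solution subset is then scored on the
    held-out fold by an NB classifier refit on the whole training split.
    """
    seed_seq = np.random.SeedSequence(cfg.seed)
    outer_seed = int(seed_seq.generate_state(1)[0] % 2**31)
    plan = stratified_kfold(ds.labels, k, outer_seed)
    fold_seqs = seed_seq.spawn(k)
    summaries: dict[str, list[Solution]] = {m: [] for m in methods}
    leaked = 0
    for fold in range(k):
        tr_rows = plan.train_rows(fold)
        te_rows = plan.test_rows(fold)
        train = ds.restrict_samples(tr_rows)
        test = ds.restrict_samples(te_rows)
        s_filter, s_wrap, s_de1, s_de2, s_folds = fold_seqs[fold].spawn(5)
        inner = stratified_kfold(train.labels, cfg.inner_folds,
                                 int(s_folds.generate_state(1)[0] % 2**31))
        filt = run_filter_stage(train, cfg, rng=np.random.default_rng(s_filter))
        chosen = pick_wrapper_input(filt)
        stage_results: dict[str, StageResult] = {}
        if "mode" in methods:
            stage_results["mode"] = run_wrapper_stage(
                train, chosen, cfg, rng=np.random.default_rng(s_wrap), folds=inner
            )
        if "de1" in methods:
            stage_results["de1"] = run_baseline(
                train, chosen, cfg, "de1", rng=np.random.default_rng(s_de1), folds=inner
            )
        if "de2" in methods:
            stage_results["de2"] = run_baseline(
                train, chosen, cfg, "de2", rng=np.random.default_rng(s_de2), folds=inner
            )
        leaked += test.n_reads  # selection must not have touched held-out rows
        # evaluation phase: refit NB on the whole training split per subset
        for name, res in stage_results.items():
            for subset, objs in res.subsets:
                idx = subset.array()
                model = nb_fit(train.matrix[:, idx], train.labels)
                pred = nb_predict(model, test.matrix[:, idx])
                test_err = float(np.mean(pred != test.labels))
                if res.stage_tag == "wrapper":
                    train_err = float(objs[1])
                elif res.stage_tag == "de1":
                    train_err = float(objs[0])
                else:  # de2 scalar mixes size and error; recompute the error part
                    train_err = cv_error(train.restrict_features(subset.indices), inner)
                summaries[name].append(
                    Solution(len(subset), test_err, train_err, fold, subset.indices)
                )
    out: dict[str, FrontSummary] = {}
    for name, union in summaries.items():
        out[name] = FrontSummary(
            union_solutions=union,
            average_front=average_front(union),
            best_front=best_front(union),
            test_reads_during_selection=leaked,
        )
    return out


def write_run_metadata(cfg: RunConfig, outdir) -> None:
    """Persist the run configuration for reproducibility."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run.json").write_text(cfg.to_json())
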