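"""End-to-end orchestration: data -> filter -> optimize -> classify -> report.

A single :class:`RunConfig` drives one filter x optimizer combination
over a list of subset sizes and classifiers; :func:`run_grid` sweeps the
full design (filters, then optimizers, then k, then classifiers — a
deterministic order for stable log diffs).  One global seed fans out to
per-stage seeds through ``numpy.random.SeedSequence([seed, stage])``
(stage 0 = synthesis, 1 = filter, 2 = wrapper, 3 = evaluation), so each
stage is independently replayable.

Two evaluation protocols are available.  ``nested`` (honest default)
re-runs the whole selection inside every outer training fold, so the
held-out samples never influence gene choice.  ``paper_faithful``
selects once on the full dataset and then cross-validates the chosen
genes — the protocol summary tables in this literature typically use,
kept for comparability; its accuracies are optimistically biased.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import classify
from .datasets import ExpressionDataset, load_expression_dataset
from .filters import FilterParams, shortlist
from .metrics import (
    _conventional,
    confusion_counts,
    metrics_from_counts,
    minority_class,
    stratified_kfold,
)
from .synthetic import SyntheticConfig, generate_dataset
from .wrapper import WrapperConfig, dual_level_select

logger = logging.getLogger("leukoswarm")

__all__ = ["RunConfig", "run_pipeline", "run_grid", "stage_seed"]

_STAGES = {"synth": 0, "filter": 1, "wrapper": 2, "eval": 3}


def stage_seed(global_seed: int, stage: str, extra: int = 0) -> int:
    """Derived seed for a named pipeline stage (documented counter scheme)."""
    ss = np.random.SeedSequence([int(global_seed), _STAGES[stage], int(extra)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """One pipeline run: a single filter x optimizer, several k and classifiers."""

    input: object  # path | SyntheticConfig | ExpressionDataset
    filter_method: str = "cfs"
    filter_params: FilterParams = field(default_factory=FilterParams)
    wrapper: WrapperConfig = field(default_factory=WrapperConfig)
    k_list: tuple = (50, 100, 200)
    classifiers: tuple = ("PNN",)
    eval_folds: int = 10
    seed: int = 0
    positive_class: int | None = None

    def resolve_dataset(self) -> ExpressionDataset:
        if isinstance(self.input, ExpressionDataset):
            return self.input
        if isinstance(self.input, SyntheticConfig):
            cfg = replace(self.input, seed=stage_seed(self.seed, "synth"))
            ds, _ = generate_dataset(cfg)
            return ds
        return load_expression_dataset(self.input)


def _log_stage(name: str, t0: float, detail: str) -> None:
    logger.info("%s: %.2fs %s", name, time.perf_counter() - t0, detail)


def _evaluate_cell(ds, genes, kind, plan, positive, seed):
    X = ds.samples_x_genes(genes)
    y = ds.labels
    per_fold, preds = [], np.empty(len(y), dtype=int)
    for tr, te in plan.folds():
        model = classify.train(kind, X[tr], y[tr], seed=seed)
        p = model.predict(X[te])
        preds[te] = p
        per_fold.append(confusion_counts(p, y[te], positive))
    pc, mc, fa = (sum(f[i] for f in per_fold) for i in range(3))
    report = metrics_from_counts(pc, mc, fa, folds=plan.k,
                                 positive_class=positive, per_fold=per_fold)
    report.conv_sensitivity, report.conv_specificity, report.conv_accuracy = \
        _conventional(preds, y, positive)
    return report


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute one configured run; deterministic given the config.

    Returns a JSON-serializable report with one cell per (k, classifier),
    echoing every parameter and derived seed.
    """
    t0 = time.perf_counter()
    ds = cfg.resolve_dataset()
    _log_stage("input", t0, f"p={ds.n_genes} n={ds.n_samples} classes={ds.class_counts}")
    positive = minority_class(ds.labels) if cfg.positive_class is None else cfg.positive_class
    fparams = replace(cfg.filter_params, seed=stage_seed(cfg.seed, "filter"))
    wcfg = replace(
        cfg.wrapper,
        seed=stage_seed(cfg.seed, "wrapper"),
        optimizer_cfg=replace(cfg.wrapper.optimizer_cfg,
                              seed=stage_seed(cfg.seed, "wrapper", 1)),
    )
    eval_seed = stage_seed(cfg.seed, "eval")
    cells = []

    if wcfg.leakage_mode == "paper_faithful":
        t1 = time.perf_counter()
        pool = shortlist(ds, cfg.filter_method, fparams)
        _log_stage("filter", t1, f"method={cfg.filter_method} pool={pool.pool_size}")
        plan = stratified_kfold(ds.labels, k=cfg.eval_folds, seed=eval_seed)
        for k in cfg.k_list:
            t2 = time.perf_counter()
            genes, opt = dual_level_select(
                ds, cfg.filter_method, fparams, wcfg, k, pool=pool
            )
            _log_stage("wrapper", t2, f"k={k} best_fitness={opt.best_fitness:.3f}")
            for kind in cfg.classifiers:
                report = _evaluate_cell(ds, genes, kind, plan, positive, eval_seed)
                cells.append(_cell(cfg, ds, k, kind, genes, opt, report))
    elif wcfg.leakage_mode == "nested":
        plan = stratified_kfold(ds.labels, k=cfg.eval_folds, seed=eval_seed)
        for k in cfg.k_list:
            t2 = time.perf_counter()
            fold_preds = {kind: np.empty(ds.n_samples, dtype=int) for kind in cfg.classifiers}
            fold_counts = {kind: [] for kind in cfg.classifiers}
            last_opt = None
            sel_union: set[int] = set()
            for tr, te in plan.folds():
                train_ds = ExpressionDataset(
                    matrix=ds.matrix[:, tr],
                    gene_ids=ds.gene_ids,
                    sample_ids=[ds.sample_ids[i] for i in tr],
                    labels=ds.labels[tr],
                    class_names=ds.class_names,
                )
                genes, last_opt = dual_level_select(
                    train_ds, cfg.filter_method, fparams, wcfg, k
                )
                sel_union.update(int(g) for g in genes)
                Xtr = ds.samples_x_genes(genes)[tr]
                Xte = ds.samples_x_genes(genes)[te]
                for kind in cfg.classifiers:
                    model = classify.train(kind, Xtr, ds.labels[tr], seed=eval_seed)
                    p = model.predict(Xte)
                    fold_preds[kind][te] = p
                    fold_counts[kind].append(confusion_counts(p, ds.labels[te], positive))
            _log_stage("wrapper+eval", t2, f"k={k} nested folds={plan.k}")
            for kind in cfg.classifiers:
                pc, mc, fa = (sum(f[i] for f in fold_counts[kind]) for i in range(3))
                report = metrics_from_counts(
                    pc, mc, fa, folds=plan.k, positive_class=positive,
                    per_fold=fold_counts[kind],
                )
                report.conv_sensitivity, report.conv_specificity, \
                    report.conv_accuracy = _conventional(
                        fold_preds[kind], ds.labels, positive)
                cells.append(_cell(cfg, ds, k, kind, sorted(sel_union), last_opt, report))
    else:
        raise ValueError(f"unknown leakage_mode {wcfg.leakage_mode!r}")

    return {
        "config": {
            "filter_method": cfg.filter_method,
            "optimizer": cfg.wrapper.optimizer_cfg.algorithm,
            "k_list": list(cfg.k_list),
            "classifiers": list(cfg.classifiers),
            "eval_folds": cfg.eval_folds,
            "leakage_mode": cfg.wrapper.leakage_mode,
            "seed": cfg.seed,
            "derived_seeds": {s: stage_seed(cfg.seed, s) for s in _STAGES},
        },
        "dataset": {
            "n_genes": ds.n_genes,
            "n_samples": ds.n_samples,
            "class_counts": list(ds.class_counts),
            "class_names": list(ds.class_names),
        },
        "cells": cells,
    }


def _cell(cfg, ds, k, kind, genes, opt, report) -> dict:
    return {
        "filter": cfg.filter_method,
        "optimizer": cfg.wrapper.optimizer_cfg.algorithm,
        "k": int(k),
        "classifier": kind,
        "selected_genes": [ds.gene_ids[int(g)] for g in genes],
        "optimizer_result": {
            "best_fitness": float(opt.best_fitness),
            "evaluations": int(opt.evaluations),
            "iterations": int(len(opt.history)),
            "seed": int(opt.seed),
        },
        "metrics": report.to_dict(),
    }


def run_grid(
    ds: ExpressionDataset,
    filters: tuple,
    optimizers: tuple,
    k_list: tuple,
    classifiers: tuple,
    base_wrapper: WrapperConfig | None = None,
    filter_params: FilterParams | None = None,
    eval_folds: int = 10,
    seed: int = 0,
    leakage_mode: str = "paper_faithful",
) -> list[dict]:
    """Sweep the full design on one dataset; returns one cell per combination.

    Shortlists are computed once per filter and shared across optimizers.
    """
    base_wrapper = base_wrapper or WrapperConfig()
    fparams = replace(filter_params or FilterParams(), seed=stage_seed(seed, "filter"))
    positive = minority_class(ds.labels)
    eval_seed = stage_seed(seed, "eval")
    plan = stratified_kfold(ds.labels, k=eval_folds, seed=eval_seed)
    cells = []
    for fi, fmethod in enumerate(filters):
        pool = shortlist(ds, fmethod, fparams)
        for oi, algo in enumerate(optimizers):
            wcfg = replace(
                base_wrapper,
                leakage_mode=leakage_mode,
                seed=stage_seed(seed, "wrapper", fi * 100 + oi),
                optimizer_cfg=replace(
                    base_wrapper.optimizer_cfg,
                    algorithm=algo,
                    seed=stage_seed(seed, "wrapper", fi * 100 + oi + 50),
                ),
            )
            for k in k_list:
                genes, opt = dual_level_select(ds, fmethod, fparams, wcfg, k, pool=pool)
                for kind in classifiers:
                    report = _evaluate_cell(ds, genes, kind, plan, positive, eval_seed)
                    cfg_stub = RunConfig(
                        input=ds, filter_method=fmethod, wrapper=wcfg,
                        k_list=(k,), classifiers=(kind,), seed=seed,
                    )
                    cells.append(_cell(cfg_stub, ds, k, kind, genes, opt, report))
    return cells


def write_report(report, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
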