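"""End-to-end orchestration: repertoires -> properties -> selection -> report.

These functions are the scripted entry points of the package (there is
deliberately no shell CLI; see examples/ for narrative usage).  Every
run writes a ``manifest.json`` stamping the resolved configuration and
seed so each artifact file is reproducible from its manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import MetricReport, composite_score, run_benchmark as _run_benchmark
from .features import FeatureMatrix, GroupSpec, build_feature_matrix, standardize
from .grouplasso import FitConfig, fit as glfit
from .network import read_repertoire, repertoire_properties, write_property_table
from .selection import as_singleton_groups, cv_select, permutation_select

logger = logging.getLogger(__name__)


def _write_manifest(outdir: Path, stage: str, params: dict) -> None:
    manifest = {"stage": stage, "params": params}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_network(
    inputs,
    outdir: str | Path,
    max_dist: int = 1,
    min_size: int = 2,
    column_map: dict | None = None,
) -> list[Path]:
    """Read repertoire tables, write one cluster-property CSV per patient.

    Unreadable inputs are reported and skipped; at least one must succeed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = [Path(p) for p in inputs]
    if not inputs:
        raise ValueError("no input repertoire files given")
    written: list[Path] = []
    failures: dict[str, str] = {}
    for path in inputs:
        try:
            rep = read_repertoire(path, column_map=column_map)
            table = repertoire_properties(rep, max_dist=max_dist, min_size=min_size)
            out = outdir / f"{rep.patient_id}.properties.csv"
            write_property_table(table, out)
            written.append(out)
        except Exception as exc:  # noqa: BLE001 - per-file failure, continue
            logger.error("failed on %s: %s", path, exc)
            failures[str(path)] = str(exc)
    if not written:
        raise RuntimeError(f"no repertoire could be processed: {failures}")
    _write_manifest(outdir, "network", {
        "inputs": [str(p) for p in inputs], "max_dist": max_dist,
        "min_size": min_size, "failures": failures,
    })
    return written


def run_select(
    features_csv: str | Path,
    groups_json: str | Path,
    outcome_csv: str | Path,
    outdir: str | Path,
    method: str = "p-group-lasso",
    K: int = 50,
    tau: float = 0.5,
    nfolds: int = 10,
    seed: int = 0,
    config: FitConfig = FitConfig(),
):
    """Standardize a saved feature matrix and run one selection method."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    feats = pd.read_csv(features_csv, index_col=0)
    spec = GroupSpec.from_json(groups_json)
    outcome = pd.read_csv(outcome_csv, index_col=0).iloc[:, 0]
    y = outcome.reindex(feats.index).to_numpy(dtype=float)
    if np.isnan(y).any() or set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1 and cover every patient")

    fm = FeatureMatrix(values=feats.to_numpy(dtype=float),
                       columns=list(feats.columns), patients=list(feats.index))
    fm = standardize(fm)

    rng = np.random.default_rng(seed)
    if method in ("p-group-lasso", "p-lasso"):
        mspec = spec if method == "p-group-lasso" else as_singleton_groups(spec)
        result = permutation_select(fm.values, y, mspec, K=K, tau=tau, rng=rng,
                                    config=config, method_name=method)
    elif method in ("cv-group-lasso", "cv-lasso"):
        mspec = spec if method == "cv-group-lasso" else as_singleton_groups(spec)
        result = cv_select(fm.values, y, mspec, nfolds=nfolds, rng=rng,
                           config=config, method_name=method)
    else:
        raise ValueError(
            f"unknown method {method!r}; valid: p-group-lasso, cv-group-lasso, "
            "p-lasso, cv-lasso"
        )
    result.to_json(outdir / "selection.json", spec=mspec)

    # composite score = coefficient x standardized feature over the selected
    # columns: CV methods use the penalized fit at lambda*, permutation
    # methods an unpenalized logistic refit on the selected columns
    cols = result.selected_columns(mspec)
    if result.extra.get("coefficients") is not None:
        coefs = np.asarray(result.extra["coefficients"])[cols]
    elif len(cols):
        refit_spec = GroupSpec(names=["selected"], sizes=[len(cols)])
        _, coefs, _ = glfit(fm.values[:, cols], y, refit_spec, 0.0, config=config)
    else:
        coefs = np.zeros(0)
    scores = [composite_score(row, coefs, cols) for row in fm.values]
    pd.DataFrame({"patient_id": fm.patients, "composite_score": scores}).to_csv(
        outdir / "composite_scores.csv", index=False
    )
    _write_manifest(outdir, "select", {
        "features": str(features_csv), "groups": str(groups_json),
        "outcome": str(outcome_csv), "method": method, "K": K, "tau": tau,
        "nfolds": nfolds, "seed": seed, "config": asdict(config),
    })
    return result


def run_benchmark(
    scenarios,
    methods,
    outdir: str | Path,
    N: int = 100,
    seed: int = 0,
    K: int = 50,
    tau: float = 0.5,
    nfolds: int = 10,
    config: FitConfig = FitConfig(),
    level: str = "feature",
) -> MetricReport:
    """Simulation sweep wrapper writing tidy CSV + aggregate JSON + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = _run_benchmark(
        scenarios, methods, N=N, seed=seed, K=K, tau=tau, nfolds=nfolds,
        config=config, level=level,
        progress=lambda s, r: logger.info("scenario %s replicate %d done", s, r),
    )
    report.to_files(outdir / "benchmark")
    _write_manifest(outdir, "benchmark", {
        "scenarios": list(scenarios) if not isinstance(scenarios, str) else [scenarios],
        "methods": list(methods) if not isinstance(methods, str) else [methods],
        "N": N, "seed": seed, "K": K, "tau": tau, "nfolds": nfolds,
        "level": level, "config": asdict(config),
    })
    return report
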