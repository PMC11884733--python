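"""Selection-performance metrics and the multi-method simulation benchmark.

Metrics follow the usual variable-selection conventions: sensitivity is
the fraction of truly causal variables recovered, FDR the fraction of
selected variables that are not causal, F1 the harmonic mean of
precision (1 - FDR) and sensitivity, and stability the mean pairwise
Jaccard index of the selected-variable lists across simulation
replicates.  Degenerate cases are fixed explicitly: an empty selection
has FDR 0 and F1 0, and two empty lists have Jaccard 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .features import GroupSpec
from .grouplasso import FitConfig
from .selection import SelectionResult, as_singleton_groups, cv_select, permutation_select
from .simulate import SCENARIOS, SimulatedDataset, make_scenario


def sensitivity(selected: set, truth: set) -> float:
    """|selected ∩ truth| / |truth|."""
    truth = set(truth)
    if not truth:
        raise ValueError("truth set must be nonempty")
    return len(set(selected) & truth) / len(truth)


def fdr(selected: set, truth: set) -> float:
    """|selected \\ truth| / |selected|; 0 for an empty selection."""
    selected = set(selected)
    if not selected:
        return 0.0
    return len(selected - set(truth)) / len(selected)


def f1(selected: set, truth: set) -> float:
    """Harmonic mean of precision (1 - FDR) and sensitivity; 0 when both 0."""
    sens = sensitivity(selected, truth)
    prec = 1.0 - fdr(selected, truth)
    if not set(selected):
        return 0.0
    if sens + prec == 0:
        return 0.0
    return 2 * prec * sens / (prec + sens)


def jaccard(a: set, b: set) -> float:
    """|A ∩ B| / |A ∪ B|; two empty lists count as identical (1)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def stability(lists) -> float:
    """Mean pairwise Jaccard over all C(N,2) selection lists."""
    lists = [set(s) for s in lists]
    if len(lists) < 2:
        raise ValueError("stability needs at least 2 lists")
    pairs = list(combinations(lists, 2))
    return float(np.mean([jaccard(a, b) for a, b in pairs]))


def composite_score(
    X_row: np.ndarray, coefficients: dict[int, float] | np.ndarray,
    selected_columns=None,
) -> float:
    """Per-patient linear score: sum of coefficient * standardized feature
    over the selected columns (intercept excluded)."""
    X_row = np.asarray(X_row, dtype=float)
    if isinstance(coefficients, dict):
        cols = np.array(sorted(coefficients), dtype=int)
        coefs = np.array([coefficients[c] for c in cols])
    else:
        coefs = np.asarray(coefficients, dtype=float)
        cols = np.arange(len(coefs)) if selected_columns is None else np.asarray(
            selected_columns, dtype=int
        )
        if len(cols) != len(coefs):
            raise ValueError("coefficients and selected columns disagree")
    if len(cols) and (cols.min() < 0 or cols.max() >= X_row.size):
        raise ValueError("selected column index out of range")
    if selected_columns is not None and isinstance(coefficients, dict):
        if not set(cols) <= set(np.asarray(selected_columns, dtype=int)):
            raise ValueError("coefficient indices must lie in the selected columns")
    return float(X_row[cols] @ coefs) if len(cols) else 0.0


# ----------------------------------------------------------------- benchmark

METHODS = ("p-group-lasso", "cv-group-lasso", "p-lasso", "cv-lasso")


def _run_method(
    method: str,
    data: SimulatedDataset,
    rng: np.random.Generator,
    K: int,
    tau: float,
    nfolds: int,
    config: FitConfig,
) -> tuple[SelectionResult, GroupSpec]:
    X, y, spec = data.X.values, data.y, data.spec
    if method == "p-group-lasso":
        return permutation_select(X, y, spec, K=K, tau=tau, rng=rng,
                                  config=config, method_name=method), spec
    if method == "cv-group-lasso":
        return cv_select(X, y, spec, nfolds=nfolds, rng=rng,
                         config=config, method_name=method), spec
    if method == "p-lasso":
        s1 = as_singleton_groups(spec)
        return permutation_select(X, y, s1, K=K, tau=tau, rng=rng,
                                  config=config, method_name=method), s1
    if method == "cv-lasso":
        s1 = as_singleton_groups(spec)
        return cv_select(X, y, s1, nfolds=nfolds, rng=rng,
                         config=config, method_name=method), s1
    if method == "oracle":
        # plug-in reference that returns the truth exactly
        res = SelectionResult(
            method="oracle", selected=sorted(data.truth_groups),
            frequencies=np.zeros(data.spec.G), K=1, tau=0.0,
        )
        return res, data.spec
    raise ValueError(f"unknown method {method!r}; valid: {METHODS + ('oracle',)}")


@dataclass
class MetricReport:
    replicates: pd.DataFrame   # tidy: scenario, method, replicate, metric, value
    aggregate: pd.DataFrame    # scenario, method, metric, mean value

    def to_files(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.replicates.to_csv(prefix.with_suffix(".replicates.csv"), index=False)
        agg = {
            f"{r.scenario}|{r.method}|{r.metric}": r.value
            for r in self.aggregate.itertuples()
        }
        prefix.with_suffix(".aggregate.json").write_text(json.dumps(agg, indent=2))


def replicate_metrics(
    result: SelectionResult,
    method_spec: GroupSpec,
    data: SimulatedDataset,
    level: str = "feature",
) -> dict[str, float]:
    """Per-replicate metrics at feature-column level (groups expanded to
    their columns) or at property-group level."""
    if level == "feature":
        selected = set(int(c) for c in result.selected_columns(method_spec))
        truth = set(int(c) for c in np.flatnonzero(data.truth_mask))
    elif level == "group":
        if method_spec.G == data.spec.G:           # grouped method
            selected = set(result.selected)
        else:                                      # singleton method: map back
            group_of = data.spec.group_of()
            cols = result.selected_columns(method_spec)
            selected = set(int(group_of[c]) for c in cols)
        truth = set(data.truth_groups)
    else:
        raise ValueError("level must be 'feature' or 'group'")
    return {
        "sensitivity": sensitivity(selected, truth),
        "fdr": fdr(selected, truth),
        "f1": f1(selected, truth),
        "_selected": selected,  # consumed by stability, stripped before report
    }


def run_benchmark(
    scenarios,
    methods,
    N: int = 100,
    seed: int = 0,
    K: int = 50,
    tau: float = 0.5,
    nfolds: int = 10,
    config: FitConfig = FitConfig(),
    level: str = "feature",
    progress=None,
) -> MetricReport:
    """Simulate N replicates per scenario, run each method, aggregate metrics.

    Child seeds are spawned deterministically from ``seed`` so serial and
    parallel execution agree; per-replicate failures are recorded as
    flagged rows rather than aborting the sweep.
    """
    if N < 2:
        raise ValueError("N must be >= 2 (stability needs pairs)")
    if isinstance(scenarios, str):
        scenarios = [scenarios]
    if isinstance(methods, str):
        methods = [methods]
    for s in scenarios:
        if s not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {s!r}; valid: {', '.join(sorted(SCENARIOS))}"
            )

    rows = []
    for s_idx, scen in enumerate(scenarios):
        data_seeds = np.random.SeedSequence((seed, s_idx, 0)).spawn(N)
        method_seeds = {
            m: np.random.SeedSequence((seed, s_idx, 1 + m_idx)).spawn(N)
            for m_idx, m in enumerate(methods)
        }
        selections: dict[str, list[set]] = {m: [] for m in methods}
        for rep in range(N):
            data = make_scenario(scen, rng=np.random.default_rng(data_seeds[rep]))
            for m in methods:
                rng = np.random.default_rng(method_seeds[m][rep])
                try:
                    result, mspec = _run_method(m, data, rng, K, tau, nfolds, config)
                    metrics = replicate_metrics(result, mspec, data, level=level)
                except Exception as exc:  # noqa: BLE001 - sweep must continue
                    rows.append(dict(scenario=scen, method=m, replicate=rep,
                                     metric="error", value=np.nan, note=str(exc)))
                    continue
                selections[m].append(metrics.pop("_selected"))
                for name, val in metrics.items():
                    rows.append(dict(scenario=scen, method=m, replicate=rep,
                                     metric=name, value=val, note=""))
            if progress is not None:
                progress(scen, rep)
        for m in methods:
            if len(selections[m]) >= 2:
                rows.append(dict(scenario=scen, method=m, replicate=-1,
                                 metric="stability",
                                 value=stability(selections[m]), note=""))

    replicates = pd.DataFrame(
        rows, columns=["scenario", "method", "replicate", "metric", "value", "note"]
    )
    per_rep = replicates[replicates.replicate >= 0]
    agg = (
        per_rep.groupby(["scenario", "method", "metric"], as_index=False)["value"]
        .mean()
    )
    stab = replicates[replicates.metric == "stability"][
        ["scenario", "method", "metric", "value"]
    ]
    aggregate = pd.concat([agg, stab], ignore_index=True)
    return MetricReport(replicates=replicates, aggregate=aggregate)
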