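"""Pseudo-variable-assisted group selection and cross-validated baselines.

The permutation-assisted procedure augments the standardized design X
(n x P, G groups) with a pseudo copy whose rows are shuffled by one
random permutation pi, giving 2G groups whose pseudo half is known to be
unrelated to the response while retaining the original inter-feature
correlation.  Fitting the group-Lasso path on the augmented design gives
each group an importance score

    W_g = sup { lambda : block g nonzero at lambda }

and the strongest pseudo score C_pi = max_{G<g<=2G} W_g benchmarks the
real groups: S_pi = { g <= G : W_g > C_pi }.  Repeating over K
permutations, groups selected in more than a fraction tau of the draws
are reported.  ``cv_select`` is the conventional alternative: lambda is
tuned by minimizing mean held-out binomial deviance over stratified
folds, and the selected groups are the nonzero blocks of the full-data
fit at that lambda.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .features import GroupSpec
from .grouplasso import (
    FitConfig,
    PathResult,
    _precompute,
    fit,
    fit_path,
    lambda_grid,
    lambda_max,
    penalty_weights,
)


@dataclass
class AugmentedDesign:
    X_A: np.ndarray
    spec_A: GroupSpec
    permutation: np.ndarray
    n_original_groups: int


@dataclass
class ImportanceScores:
    W: np.ndarray        # (2G,) supremum-lambda scores
    C_pi: float          # max over pseudo groups
    n_original_groups: int


@dataclass
class SelectionResult:
    method: str
    selected: list[int]                  # original group ids, sorted
    frequencies: np.ndarray              # (G,) selection frequency over K draws
    K: int
    tau: float
    per_permutation: list[list[int]] = field(default_factory=list)
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def selected_columns(self, spec: GroupSpec) -> np.ndarray:
        if not self.selected:
            return np.array([], dtype=int)
        return np.concatenate([spec.columns_of(g) for g in self.selected])

    def to_json(self, path: str | Path, spec: GroupSpec | None = None) -> None:
        payload = {
            "method": self.method,
            "seed": self.seed,
            "K": self.K,
            "tau": self.tau,
            "selected_groups": self.selected,
            "frequencies": self.frequencies.tolist(),
            "per_permutation": self.per_permutation,
        }
        if spec is not None:
            payload["group_names"] = [spec.names[g] for g in self.selected]
        Path(path).write_text(json.dumps(payload, indent=2))


def augment_with_pseudo(
    X: np.ndarray,
    spec: GroupSpec,
    rng: np.random.Generator,
    per_group_shuffle: bool = False,
) -> AugmentedDesign:
    """Append pseudo groups: a row-permuted copy of X.

    By default one permutation shuffles the whole matrix jointly so the
    pseudo block preserves the correlation structure among features;
    ``per_group_shuffle`` draws an independent permutation per group
    (breaks between-group pseudo correlation, off by default).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to permute")
    perm = rng.permutation(n)
    if per_group_shuffle:
        pseudo = np.empty_like(X)
        for g in range(spec.G):
            cols = spec.columns_of(g)
            pseudo[:, cols] = X[rng.permutation(n)][:, cols]
    else:
        pseudo = X[perm]
    X_A = np.hstack([X, pseudo])
    spec_A = GroupSpec(
        names=list(spec.names) + [f"{name}__pseudo" for name in spec.names],
        sizes=list(spec.sizes) * 2,
    )
    return AugmentedDesign(X_A=X_A, spec_A=spec_A, permutation=perm,
                           n_original_groups=spec.G)


def importance_scores(path: PathResult, n_original_groups: int) -> ImportanceScores:
    """W_g = largest grid lambda at which block g is nonzero (0 if never)."""
    support = path.group_support()          # (L, 2G); lambdas descending
    W = np.zeros(path.spec.G)
    for g in range(path.spec.G):
        hit = np.flatnonzero(support[:, g])
        if hit.size:
            W[g] = float(path.lambdas[hit].max())
    C_pi = float(W[n_original_groups:].max()) if path.spec.G > n_original_groups else 0.0
    return ImportanceScores(W=W, C_pi=C_pi, n_original_groups=n_original_groups)


def select_once(
    X: np.ndarray,
    y: np.ndarray,
    spec: GroupSpec,
    rng: np.random.Generator,
    config: FitConfig = FitConfig(),
    full_path: bool = False,
) -> set[int]:
    """One permutation round: augment, fit the path, threshold at C_pi.

    By default the path is truncated at the first grid point where any
    pseudo block becomes nonzero: every original group already in the
    model entered at a strictly larger lambda than C_pi, and no group
    entering later can beat C_pi, so the truncated and full paths give
    the identical S_pi (``full_path=True`` forces the literal full-grid
    computation).
    """
    aug = augment_with_pseudo(X, spec, rng)
    weights = penalty_weights(aug.spec_A, config.penalty_convention)
    G = spec.G
    pseudo_cols = np.arange(spec.P, 2 * spec.P)
    stop = None if full_path else (lambda b: bool(np.any(b[pseudo_cols])))
    path = fit_path(aug.X_A, y, aug.spec_A, weights=weights, config=config,
                    stop_when=stop)
    scores = importance_scores(path, n_original_groups=G)
    return {g for g in range(G) if scores.W[g] > scores.C_pi}


def permutation_select(
    X: np.ndarray,
    y: np.ndarray,
    spec: GroupSpec,
    K: int = 50,
    tau: float = 0.5,
    rng: np.random.Generator | int | None = None,
    config: FitConfig = FitConfig(),
    method_name: str = "p-group-lasso",
) -> SelectionResult:
    """K-permutation selection: keep groups with frequency > tau."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if not 0 <= tau < 1:
        raise ValueError("tau must lie in [0, 1)")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    hits = np.zeros(spec.G)
    per_perm: list[list[int]] = []
    for _ in range(K):
        s = select_once(X, y, spec, rng, config)
        per_perm.append(sorted(s))
        for g in s:
            hits[g] += 1
    freq = hits / K
    selected = sorted(int(g) for g in np.flatnonzero(freq > tau))
    return SelectionResult(
        method=method_name, selected=selected, frequencies=freq,
        K=K, tau=tau, per_permutation=per_perm, seed=seed,
    )


def _binomial_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    """-2 log-likelihood of Bernoulli observations given the linear predictor."""
    return 2.0 * float(np.logaddexp(0.0, eta).sum() - y @ eta)


def cv_select(
    X: np.ndarray,
    y: np.ndarray,
    spec: GroupSpec,
    nfolds: int = 10,
    rng: np.random.Generator | int | None = None,
    config: FitConfig = FitConfig(),
    method_name: str = "cv-group-lasso",
) -> SelectionResult:
    """Tune lambda by mean held-out binomial deviance over stratified folds."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    weights = penalty_weights(spec, config.penalty_convention)
    lmax = lambda_max(X, y, spec, weights)
    grid = lambda_grid(lmax, config)

    skf = StratifiedKFold(
        n_splits=nfolds, shuffle=True,
        random_state=int(rng.integers(2**31 - 1)),
    )
    dev = np.zeros(len(grid))
    for train, test in skf.split(X, y):
        if len(np.unique(y[train])) < 2:
            raise ValueError("a training fold contains a single class")
        warm = None
        pre = _precompute(X[train], spec)
        for k, lam in enumerate(grid):
            b0, b, _ = fit(X[train], y[train], spec, lam, weights, config,
                           warm_start=warm, _pre=pre)
            warm = (b0, b)
            dev[k] += _binomial_deviance(y[test], b0 + X[test] @ b)
    dev /= nfolds
    k_star = int(np.argmin(dev))
    lam_star = float(grid[k_star])

    path = fit_path(X, y, spec, weights=weights, config=config, grid=grid)
    support = path.group_support()[k_star]
    selected = sorted(int(g) for g in np.flatnonzero(support))
    freq = support.astype(float)
    res = SelectionResult(
        method=method_name, selected=selected, frequencies=freq,
        K=1, tau=0.0, per_permutation=[selected], seed=seed,
    )
    res.extra = {
        "lambda_star": lam_star,
        "mean_deviance": dev.tolist(),
        "coefficients": path.coefs[k_star].tolist(),
        "intercept": float(path.intercepts[k_star]),
    }
    return res


def as_singleton_groups(spec: GroupSpec) -> GroupSpec:
    """Dissolve the group structure: every column its own group (plain Lasso)."""
    names = [
        f"{name}[{k}]"
        for g, name in enumerate(spec.names)
        for k in range(spec.sizes[g])
    ]
    return GroupSpec(names=names, sizes=[1] * spec.P)
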