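"""Synthetic per-patient network-property data with a known causal structure.

The generator mimics what the real pipeline produces without needing
sequencing data: each patient gets a random number of clusters; each
cluster gets an 11-dimensional property vector drawn through a Gaussian
copula (correlation ``R``) with per-property marginals -- log-normal for
cluster size and the count/eigenvalue scales, scaled Beta for the
bounded graph statistics.  The four NA-prone properties are set to NA on
2-node clusters, exactly as the real property tables behave.

The binary response is driven by four latent causal variables
Z_1..Z_4, one per causal property (baseline count, diameter length,
eigenvector centrality value, central eigenvector), each a weighted
combination of per-patient percentiles of that property's cluster-level
values.  The response follows a logistic model in standardized Z, either
linear or with the pairwise interactions Z1*Z2 + Z3*Z4, with the
intercept solved numerically to hit a target prevalence (0.5 balanced,
0.3 imbalanced).  Twelve named scenarios vary n, the presence of 200
extra Uniform(0,1) nuisance columns, balance, and linearity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .features import (
    FeatureMatrix,
    GroupSpec,
    PropertySchema,
    build_feature_matrix,
    causal_column_mask,
    standardize,
)
from .network import (
    CAUSAL_PROPERTIES,
    NA_PROPERTIES,
    PROPERTY_ORDER,
    Clone,
    ClusterPropertyRecord,
    ClusterPropertyTable,
    Repertoire,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _default_marginals() -> dict[str, tuple]:
    """Marginal families per property: ("lognormal", mu, sigma),
    ("beta", a, b, lo, hi) or ("normal", mu, sigma)."""
    return {
        "node_count": ("lognormal", math.log(3.0), 0.8),
        "count_baseline": ("lognormal", math.log(30.0), 1.0),
        "count_post": ("lognormal", math.log(30.0), 1.0),
        "diameter_length": ("lognormal", math.log(2.0), 0.7),
        "assortativity": ("beta", 2.0, 2.0, -1.0, 1.0),
        "transitivity": ("beta", 2.0, 5.0, 0.0, 1.0),
        "density": ("beta", 5.0, 2.0, 0.0, 1.0),
        "degree_centralization": ("beta", 2.0, 4.0, 0.0, 1.0),
        "closeness_centralization": ("beta", 2.0, 4.0, 0.0, 1.0),
        "eigen_centrality_value": ("lognormal", math.log(2.0), 0.5),
        "central_eigen": ("beta", 2.0, 4.0, 0.0, 1.0),
    }


def _exchangeable_corr(k: int, rho: float) -> np.ndarray:
    return np.full((k, k), rho) + (1 - rho) * np.eye(k)


@dataclass
class PropertySimParams:
    """Copula correlation, marginals and the cluster-count distribution.

    Defaults emulate a mid-sized bulk-TCR cohort: a median of about 270
    clusters per patient (log-normal), cluster sizes log-normal with
    median 3 so roughly a third of clusters are 2-node, and moderate
    exchangeable inter-property correlation (rho = 0.3).
    """

    marginals: dict[str, tuple] = field(default_factory=_default_marginals)
    R: np.ndarray = field(
        default_factory=lambda: _exchangeable_corr(len(PROPERTY_ORDER), 0.3)
    )
    clusters_lognorm: tuple[float, float] = (math.log(271.0), 0.8)
    min_clusters: int = 2

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        k = len(PROPERTY_ORDER)
        if self.R.shape != (k, k):
            raise ValueError(f"R must be {k}x{k}")
        if not np.allclose(self.R, self.R.T):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0):
            raise ValueError("R must have unit diagonal")
        if np.linalg.eigvalsh(self.R).min() < -1e-10:
            raise ValueError("R must be positive semi-definite")


def _marginal_ppf(spec: tuple, u: np.ndarray) -> np.ndarray:
    family = spec[0]
    if family == "lognormal":
        _, mu, sigma = spec
        return stats.lognorm.ppf(u, s=sigma, scale=math.exp(mu))
    if family == "beta":
        _, a, b, lo, hi = spec
        return lo + (hi - lo) * stats.beta.ppf(u, a, b)
    if family == "normal":
        _, mu, sigma = spec
        return stats.norm.ppf(u, loc=mu, scale=sigma)
    raise ValueError(f"unknown marginal family {family!r}")


def simulate_property_draws(
    n_patients: int,
    params: PropertySimParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[ClusterPropertyTable]:
    """Draw per-patient collections of cluster-level property vectors.

    Cluster sizes are rounded up with a floor of 2; diameters rounded up
    with a floor of 1; the NA-prone properties are NA on 2-node clusters.
    """
    params = params or PropertySimParams()
    rng = np.random.default_rng(rng)
    chol = np.linalg.cholesky(
        params.R + 1e-12 * np.eye(len(PROPERTY_ORDER))
    )
    mu_c, sd_c = params.clusters_lognorm

    tables: list[ClusterPropertyTable] = []
    for i in range(n_patients):
        m = max(params.min_clusters, int(np.ceil(rng.lognormal(mu_c, sd_c))))
        z = rng.standard_normal((m, len(PROPERTY_ORDER))) @ chol.T
        u = stats.norm.cdf(z)
        cols = {}
        for j, prop in enumerate(PROPERTY_ORDER):
            vals = _marginal_ppf(params.marginals[prop], u[:, j])
            if prop == "node_count":
                vals = np.maximum(2, np.ceil(vals)).astype(float)
            elif prop == "diameter_length":
                vals = np.maximum(1, np.ceil(vals)).astype(float)
            elif prop in ("count_baseline", "count_post"):
                vals = np.maximum(1, np.round(vals)).astype(float)
            cols[prop] = vals
        two_node = cols["node_count"] == 2
        for prop in NA_PROPERTIES:
            cols[prop] = np.where(two_node, np.nan, cols[prop])
        records = [
            ClusterPropertyRecord(
                cluster_id=k, **{p: float(cols[p][k]) for p in PROPERTY_ORDER}
            )
            for k in range(m)
        ]
        tables.append(ClusterPropertyTable(patient_id=f"sim{i:04d}", records=records))
    return tables


@dataclass
class CausalModel:
    """Latent causal variables and the response model built on them."""

    causal_properties: tuple[str, ...] = CAUSAL_PROPERTIES
    percentiles: tuple[float, ...] = (10.0, 25.0, 50.0, 75.0, 90.0)
    weights: np.ndarray = field(
        default_factory=lambda: np.full((len(CAUSAL_PROPERTIES), 5), 0.2)
    )
    alpha: np.ndarray = field(
        default_factory=lambda: np.array([1.1, 1.0, -0.9, 0.9])
    )
    interaction_coef: float = 0.8
    linkage: str = "linear"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        k = len(self.causal_properties)
        if k != 4:
            raise ValueError("the causal model uses exactly four latent variables")
        if self.weights.shape != (k, len(self.percentiles)):
            raise ValueError("weights must be (4, n_percentiles)")
        if self.alpha.shape != (k,):
            raise ValueError("alpha must have one entry per latent variable")
        if self.linkage not in ("linear", "nonlinear"):
            raise ValueError("linkage must be 'linear' or 'nonlinear'")


def build_latent(
    draws: list[ClusterPropertyTable], model: CausalModel | None = None
) -> np.ndarray:
    """Z[i, j]: weighted combination of percentiles of causal property j
    over patient i's cluster values (NA entries ignored)."""
    model = model or CausalModel()
    n = len(draws)
    Z = np.empty((n, len(model.causal_properties)))
    for i, table in enumerate(draws):
        for j, prop in enumerate(model.causal_properties):
            vals = np.asarray(table.property_values(prop), dtype=float)
            finite = vals[~np.isnan(vals)]
            if finite.size == 0:
                Z[i, j] = 0.0
                continue
            pct = np.percentile(finite, model.percentiles)
            Z[i, j] = float(model.weights[j] @ pct)
    return Z


def _linear_predictor(Z_std: np.ndarray, model: CausalModel) -> np.ndarray:
    eta = Z_std @ model.alpha
    if model.linkage == "nonlinear":
        eta = eta + model.interaction_coef * (
            Z_std[:, 0] * Z_std[:, 1] + Z_std[:, 2] * Z_std[:, 3]
        )
    return eta


def simulate_response(
    Z: np.ndarray,
    model: CausalModel | None = None,
    balanced: bool = True,
    rng: np.random.Generator | int | None = None,
    imbalanced_prevalence: float = 0.3,
) -> np.ndarray:
    """Bernoulli response from the logistic model on standardized Z."""
    model = model or CausalModel()
    rng = np.random.default_rng(rng)
    Z = np.asarray(Z, dtype=float)
    if not np.isfinite(Z).all():
        raise ValueError("Z must be finite")
    sd = Z.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    Z_std = (Z - Z.mean(axis=0)) / sd
    eta = _linear_predictor(Z_std, model)
    target = 0.5 if balanced else imbalanced_prevalence

    def mean_prob(a0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(a0 + eta))))) - target

    alpha0 = optimize.brentq(mean_prob, -30.0, 30.0)
    p = 1.0 / (1.0 + np.exp(-(alpha0 + eta)))
    return (rng.random(len(p)) < p).astype(float)


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    n: int
    n_additional: int      # Uniform(0,1) nuisance columns (0 or 200)
    balanced: bool
    linear: bool


def _registry() -> dict[str, ScenarioConfig]:
    out = {}
    for n in (200, 300):
        for extra, ptag in ((200, "p270"), (0, "p70")):
            for bal, btag in ((True, "baln"), (False, "unbaln")):
                for lin, ltag in ((True, "lin"), (False, "nonlin")):
                    name = f"n{n}_{ptag}_{btag}_{ltag}"
                    out[name] = ScenarioConfig(name, n, extra, bal, lin)
    return out


_ALL = _registry()

#: The twelve named scenarios (n200 imbalanced rows are not part of the set).
SCENARIOS: dict[str, ScenarioConfig] = {
    k: v for k, v in _ALL.items() if not (v.n == 200 and not v.balanced)
}


@dataclass
class SimulatedDataset:
    X: FeatureMatrix                  # standardized design
    spec: GroupSpec
    y: np.ndarray
    truth_mask: np.ndarray            # boolean over columns, 25 True
    truth_groups: list[int]           # the 4 causal property groups
    Z: np.ndarray
    config: ScenarioConfig
    seed: int | None = None


def make_scenario(
    name_or_cfg: str | ScenarioConfig,
    params: PropertySimParams | None = None,
    model: CausalModel | None = None,
    rng: np.random.Generator | int | None = None,
) -> SimulatedDataset:
    """Simulate one full dataset for a named scenario."""
    if isinstance(name_or_cfg, str):
        if name_or_cfg not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {name_or_cfg!r}; valid names: "
                + ", ".join(sorted(SCENARIOS))
            )
        cfg = SCENARIOS[name_or_cfg]
    else:
        cfg = name_or_cfg
    params = params or PropertySimParams()
    model = model or CausalModel(linkage="linear" if cfg.linear else "nonlinear")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)

    draws = simulate_property_draws(cfg.n, params, rng)
    fm, spec = build_feature_matrix(draws)
    schema = PropertySchema()
    truth = causal_column_mask(schema)

    if cfg.n_additional:
        extra = rng.uniform(size=(cfg.n, cfg.n_additional))
        values = np.hstack([fm.values, extra])
        columns = list(fm.columns) + [
            f"uniform_{j:03d}" for j in range(cfg.n_additional)
        ]
        fm = FeatureMatrix(values=values, columns=columns, patients=fm.patients,
                           imputed=fm.imputed)
        spec = GroupSpec(
            names=list(spec.names) + [f"uniform_{j:03d}" for j in range(cfg.n_additional)],
            sizes=list(spec.sizes) + [1] * cfg.n_additional,
        )
        truth = np.concatenate([truth, np.zeros(cfg.n_additional, dtype=bool)])

    fm = standardize(fm)
    Z = build_latent(draws, model)
    y = simulate_response(Z, model, balanced=cfg.balanced, rng=rng)
    truth_groups = [
        g for g, name in enumerate(spec.names) if name in model.causal_properties
    ]
    return SimulatedDataset(
        X=fm, spec=spec, y=y, truth_mask=truth, truth_groups=truth_groups,
        Z=Z, config=cfg, seed=seed,
    )


def simulate_toy_repertoire(
    n_clones: int = 50,
    seq_length: int = 12,
    mutation_rate: float = 0.3,
    rng: np.random.Generator | int | None = None,
    patient_id: str = "toy",
) -> Repertoire:
    """Small random repertoire with controllable cluster structure.

    With probability ``mutation_rate`` a new clone is a single-substitution
    neighbor of an existing one (creating network edges); otherwise it is
    a fresh random sequence.  Counts are log-normal integers.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(rng)
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n_clones:
        if seqs and rng.random() < mutation_rate:
            base = seqs[rng.integers(len(seqs))]
            pos = int(rng.integers(len(base)))
            new = base[:pos] + AA[rng.integers(20)] + base[pos + 1 :]
        else:
            new = "".join(AA[k] for k in rng.integers(0, 20, size=seq_length))
        if new not in seen:
            seen.add(new)
            seqs.append(new)
    clones = [
        Clone(
            sequence=s,
            count_baseline=int(np.ceil(rng.lognormal(2.0, 1.0))),
            count_post=int(np.ceil(rng.lognormal(2.0, 1.0))),
        )
        for s in seqs
    ]
    return Repertoire(patient_id=patient_id, clones=clones)
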