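"""Approximate Bayesian computation: rejection, regression adjustment,
logistic model choice, posterior summaries and pod-based error rates.

The workflow mirrors the classical summary-statistics ABC pipeline for
demographic model choice on a single locus:

1. a *reference table* of prior-predictive simulations per scenario, each
   reduced to the per-layer feature vector (h, S, k, Tajima's D);
2. *normalized Euclidean distances* between the observed feature vector and
   every row (per-feature scale = pooled standard deviation, or MAD);
3. *rejection* of all but the closest fraction (1% at full scale);
4. *local-linear regression adjustment* of retained parameters
   (Epanechnikov kernel on distance, bandwidth = largest accepted distance;
   bounded parameters regressed on a logit scale so adjusted draws respect
   their prior bounds);
5. *logistic-regression model choice*: kernel-weighted multinomial logistic
   regression of scenario label on features over the accepted set,
   evaluated at the observed vector;
6. *pods*: prior-predictive pseudo-observed datasets run through the same
   pipeline to estimate type I / type II scenario-assignment errors.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalsim import SampleConfig, default_sample_config, simulate_variants, SiteExhaustionError
from .demography import PriorSet, build_scenario, default_priors, draw_params
from .sumstats import features_from_variants

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceTable",
    "Accepted",
    "PosteriorSummary",
    "ABCResult",
    "ConfusionSummary",
    "build_reference_table",
    "normalized_distance",
    "reject",
    "loclinear_adjust",
    "model_choice_logistic",
    "posterior_summary",
    "pods_confusion",
    "fit",
]


@dataclass
class ReferenceTable:
    """Prior-predictive simulations reduced to feature vectors."""

    scenario_ids: np.ndarray  # (rows,) str
    params: pd.DataFrame  # (rows, union of parameter names), NaN where unused
    features: np.ndarray  # (rows, d)
    scales: np.ndarray  # (d,)
    feature_names: list[str]
    priors: dict[str, PriorSet] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


@dataclass
class Accepted:
    """Rows retained by rejection, with their distances."""

    table: ReferenceTable
    indices: np.ndarray
    distances: np.ndarray

    @property
    def n(self) -> int:
        return self.indices.size

    def features(self) -> np.ndarray:
        return self.table.features[self.indices]

    def params(self) -> pd.DataFrame:
        return self.table.params.iloc[self.indices]

    def scenario_ids(self) -> np.ndarray:
        return self.table.scenario_ids[self.indices]

    def kernel_weights(self) -> np.ndarray:
        """Epanechnikov weights, bandwidth = largest accepted distance."""
        dmax = self.distances.max()
        if dmax == 0:
            return np.ones(self.n)
        w = 1.0 - (self.distances / dmax) ** 2
        # the boundary row would get weight 0; keep it infinitesimally in
        return np.maximum(w, 1e-12)


@dataclass
class PosteriorSummary:
    mode: float
    hpd_low: float
    hpd_high: float


@dataclass
class ABCResult:
    accepted: Accepted
    adjusted: pd.DataFrame  # adjusted parameter samples (focal scenario rows)
    weights: np.ndarray
    model_probabilities: dict[str, float]
    summaries: dict[str, PosteriorSummary]
    focal_scenario: str


@dataclass
class ConfusionSummary:
    """Pod assignment counts: rows = generating scenario, columns = chosen."""

    counts: pd.DataFrame
    n_pods_per_model: int

    def type_errors(self) -> pd.DataFrame:
        """Per focal scenario: type I = own pods assigned elsewhere;
        type II = share of other scenarios' pods assigned to it."""
        scen = list(self.counts.index)
        rows = []
        for s in scen:
            own = self.counts.loc[s]
            t1 = 1.0 - own[s] / own.sum()
            others = self.counts.drop(index=s)
            t2 = others[s].sum() / others.to_numpy().sum()
            rows.append({"scenario": s, "type_I": t1, "type_II": t2})
        return pd.DataFrame(rows).set_index("scenario")


def _feature_names(sample_config: SampleConfig) -> list[str]:
    layers = sorted((l.label for l in sample_config.layers), key=lambda lab: dict(
        (sl.label, sl.age) for sl in sample_config.layers)[lab])
    return [f"{stat}_{layer}" for layer in layers for stat in ("h", "S", "k", "D")]


def _scales(features: np.ndarray, method: str) -> np.ndarray:
    if method == "sd":
        s = features.std(axis=0, ddof=1)
    elif method == "mad":
        med = np.median(features, axis=0)
        s = 1.4826 * np.median(np.abs(features - med), axis=0)
    else:
        raise ValueError(f"unknown scale method {method!r}")
    zero = s <= 0
    if zero.any():
        logger.warning("feature(s) %s have zero spread; scale set to 1", np.flatnonzero(zero))
        s = np.where(zero, 1.0, s)
    return s


def simulate_feature_row(
    scenario_id: str,
    priors: PriorSet,
    sample_config: SampleConfig,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> tuple[dict[str, float], np.ndarray]:
    """One prior-predictive draw -> (parameters, feature vector).

    Infinite-sites site exhaustion (astronomical mutation counts under
    extreme prior corners) triggers a fresh parameter draw, with a logged
    warning; these corners are unobservable anyway at the data's diversity.
    """
    for _ in range(max_retries):
        params = draw_params(priors, rng)
        scenario = build_scenario(scenario_id, params)
        try:
            derived, layers = simulate_variants(scenario, sample_config, params["mu"], rng)
        except SiteExhaustionError:
            logger.warning("site exhaustion under %s; redrawing parameters", scenario_id)
            continue
        feats = features_from_variants(derived, layers, sample_config.ages_by_layer())
        return params, feats
    raise RuntimeError(f"site exhaustion persisted for {max_retries} draws under {scenario_id}")


def build_reference_table(
    scenarios: list[str],
    priors: dict[str, PriorSet] | None,
    n_sims_per_model: int,
    sample_config: SampleConfig | None = None,
    rng: np.random.Generator | None = None,
    scale_method: str = "sd",
) -> ReferenceTable:
    """Simulate ``n_sims_per_model`` datasets per scenario and reduce each to
    its feature vector; per-feature scales are pooled across scenarios."""
    if n_sims_per_model < 100:
        raise ValueError("n_sims_per_model must be >= 100")
    if rng is None:
        rng = np.random.default_rng()
    sample_config = sample_config or default_sample_config()
    priors = priors or {s: default_priors(s) for s in scenarios}

    rows_params: list[dict[str, float]] = []
    rows_feats: list[np.ndarray] = []
    labels: list[str] = []
    for scenario_id in scenarios:
        pr = priors[scenario_id]
        for _ in range(n_sims_per_model):
            params, feats = simulate_feature_row(scenario_id, pr, sample_config, rng)
            rows_params.append(params)
            rows_feats.append(feats)
            labels.append(scenario_id)

    features = np.vstack(rows_feats)
    table = ReferenceTable(
        scenario_ids=np.asarray(labels),
        params=pd.DataFrame(rows_params),
        features=features,
        scales=_scales(features, scale_method),
        feature_names=_feature_names(sample_config),
        priors=priors,
    )
    return table


def normalized_distance(observed: np.ndarray, table: ReferenceTable) -> np.ndarray:
    """Normalized Euclidean distance of every table row to ``observed``."""
    observed = np.asarray(observed, dtype=float)
    if observed.shape != (table.n_features,):
        raise ValueError(
            f"observed vector has shape {observed.shape}, table expects ({table.n_features},)"
        )
    z = (table.features - observed) / table.scales
    return np.sqrt((z**2).sum(axis=1))


def reject(table: ReferenceTable, distances: np.ndarray, accept_fraction: float) -> Accepted:
    """Keep the ``ceil(fraction * rows)`` rows of smallest distance.

    Ties at the acceptance threshold are broken by row order (stable sort).
    """
    if table.n_rows == 0:
        raise ValueError("empty reference table")
    if not 0 < accept_fraction <= 1:
        raise ValueError("accept_fraction must be in (0, 1]")
    m = math.ceil(accept_fraction * table.n_rows)
    order = np.argsort(distances, kind="stable")[:m]
    return Accepted(table=table, indices=order, distances=distances[order])


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def loclinear_adjust(
    accepted: Accepted,
    observed: np.ndarray,
    priors: PriorSet | None = None,
    param_names: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Local-linear regression adjustment of accepted parameter draws.

    Each parameter is regressed (weighted least squares, Epanechnikov
    weights) on the observed-centered normalized features; the adjusted
    sample is the fitted value at the observed vector plus the residuals.
    Parameters with known prior bounds are regressed on a logit-transformed
    scale and back-transformed, so adjusted draws always respect the prior.

    Returns (adjusted parameter DataFrame, weights).  A singular design
    falls back to the unadjusted rejection sample with a warning.
    """
    table = accepted.table
    observed = np.asarray(observed, dtype=float)
    X = (accepted.features() - observed) / table.scales
    w = accepted.kernel_weights()
    params = accepted.params()
    if param_names is None:
        param_names = [c for c in params.columns if params[c].notna().all()]
    if accepted.n <= X.shape[1] + 1:
        raise ValueError("need more accepted rows than features + 1 for regression")

    A = np.column_stack([np.ones(accepted.n), X])
    sw = np.sqrt(w)
    adjusted = {}
    for name in param_names:
        y = params[name].to_numpy(dtype=float)
        bounds = None
        if priors is not None and name in priors.priors:
            bounds = priors.bounds(name)
        if bounds is not None:
            a, b = bounds
            eps = 1e-9 * (b - a)
            z = _logit(np.clip((y - a) / (b - a), eps, 1 - eps))
        else:
            z = y
        beta, _, rank, _ = np.linalg.lstsq(A * sw[:, None], z * sw, rcond=None)
        if rank < A.shape[1]:
            warnings.warn(f"singular regression design for {name!r}; returning unadjusted sample")
            adjusted[name] = y
            continue
        resid = z - A @ beta
        z_adj = beta[0] + resid
        if bounds is not None:
            a, b = bounds
            adjusted[name] = a + (b - a) * _expit(z_adj)
        else:
            adjusted[name] = z_adj
    return pd.DataFrame(adjusted, index=params.index), w


def model_choice_logistic(
    table: ReferenceTable,
    distances: np.ndarray,
    observed: np.ndarray,
    accept_fraction: float,
) -> dict[str, float]:
    """Posterior scenario probabilities by kernel-weighted multinomial
    logistic regression over the accepted rows, evaluated at the observed
    feature vector.  Falls back to weighted acceptance frequencies if the
    regression cannot be fitted."""
    accepted = reject(table, distances, accept_fraction)
    labels = accepted.scenario_ids()
    present = sorted(set(labels))
    all_scenarios = sorted(set(table.scenario_ids))
    if len(present) == 1:
        return {s: (1.0 if s == present[0] else 0.0) for s in all_scenarios}

    observed = np.asarray(observed, dtype=float)
    X = (accepted.features() - observed) / table.scales
    w = accepted.kernel_weights()
    try:
        from sklearn.linear_model import LogisticRegression

        # effectively unpenalized multinomial logit (the classical estimator;
        # sklearn's default ridge penalty blunts near-separable scenarios)
        clf = LogisticRegression(max_iter=5000, C=1e6)
        clf.fit(X, labels, sample_weight=w)
        probs = clf.predict_proba(np.zeros((1, X.shape[1])))[0]
        out = {s: 0.0 for s in all_scenarios}
        out.update(dict(zip(clf.classes_, probs)))
    except Exception as exc:  # pragma: no cover - convergence fallback
        warnings.warn(f"logistic model choice failed ({exc}); using weighted frequencies")
        out = {s: 0.0 for s in all_scenarios}
        for s in present:
            out[s] = float(w[labels == s].sum())
    total = sum(out.values())
    return {s: v / total for s, v in out.items()}


def posterior_summary(
    samples: np.ndarray,
    weights: np.ndarray | None = None,
    bounds: tuple[float, float] | None = None,
    mass: float = 0.90,
    grid_size: int = 512,
) -> PosteriorSummary:
    """Weighted-KDE posterior mode and highest-density interval.

    Gaussian kernel with Silverman bandwidth on the (optionally
    prior-bounded) support; the HPD is the envelope of the highest-density
    region holding ``mass`` (default 90%, i.e. 5%/95% bounds).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 50:
        raise ValueError("posterior summary needs >= 50 samples")
    if weights is None:
        weights = np.ones_like(samples)
    weights = np.asarray(weights, dtype=float)
    if np.ptp(samples) == 0:
        c = float(samples[0])
        return PosteriorSummary(mode=c, hpd_low=c, hpd_high=c)

    from scipy.stats import gaussian_kde

    kde = gaussian_kde(samples, bw_method="silverman", weights=weights)
    lo = samples.min() if bounds is None else max(bounds[0], samples.min())
    hi = samples.max() if bounds is None else min(bounds[1], samples.max())
    pad = 0.05 * (hi - lo)
    glo, ghi = lo - pad, hi + pad
    if bounds is not None:
        glo, ghi = max(bounds[0], glo), min(bounds[1], ghi)
    grid = np.linspace(glo, ghi, grid_size)
    dens = kde(grid)
    mode = float(grid[np.argmax(dens)])

    order = np.argsort(dens)[::-1]
    csum = np.cumsum(dens[order])
    csum /= csum[-1]
    n_in = int(np.searchsorted(csum, mass)) + 1
    region = np.sort(order[:n_in])
    return PosteriorSummary(mode=mode, hpd_low=float(grid[region[0]]), hpd_high=float(grid[region[-1]]))


def fit(
    table: ReferenceTable,
    observed: np.ndarray,
    accept_fraction: float = 0.01,
    focal_scenario: str | None = None,
) -> ABCResult:
    """Full single-observation analysis: model choice over the whole table,
    then rejection + regression adjustment within the focal scenario's rows
    (highest-probability scenario unless given)."""
    distances = normalized_distance(observed, table)
    probs = model_choice_logistic(table, distances, observed, accept_fraction)
    if focal_scenario is None:
        focal_scenario = max(probs, key=probs.get)

    mask = table.scenario_ids == focal_scenario
    sub = ReferenceTable(
        scenario_ids=table.scenario_ids[mask],
        params=table.params.loc[mask].reset_index(drop=True),
        features=table.features[mask],
        scales=table.scales,
        feature_names=table.feature_names,
        priors=table.priors,
    )
    sub_d = normalized_distance(observed, sub)
    accepted = reject(sub, sub_d, accept_fraction)
    priors = table.priors.get(focal_scenario)
    adjusted, weights = loclinear_adjust(accepted, observed, priors=priors)
    summaries = {}
    for name in adjusted.columns:
        b = priors.bounds(name) if priors is not None and name in priors.priors else None
        summaries[name] = posterior_summary(adjusted[name].to_numpy(), weights, bounds=b)
    return ABCResult(
        accepted=accepted,
        adjusted=adjusted,
        weights=weights,
        model_probabilities=probs,
        summaries=summaries,
        focal_scenario=focal_scenario,
    )


def pods_confusion(
    scenarios: list[str],
    n_pods_per_model: int,
    priors: dict[str, PriorSet] | None,
    rng: np.random.Generator,
    table: ReferenceTable | None = None,
    n_sims_per_model: int = 10_000,
    accept_fraction: float = 0.01,
    sample_config: SampleConfig | None = None,
) -> ConfusionSummary:
    """Scenario-choice confidence from pseudo-observed datasets.

    Each pod (prior-predictive draw from its scenario) is pushed through the
    full pipeline — feature vector, distances to a shared reference table,
    logistic model choice — and assigned to the highest-probability
    scenario.  Type I error for a focal scenario is the fraction of its own
    pods assigned elsewhere; type II the fraction of other scenarios' pods
    assigned to it.
    """
    if n_pods_per_model < 10:
        raise ValueError("n_pods_per_model must be >= 10")
    sample_config = sample_config or default_sample_config()
    priors = priors or {s: default_priors(s) for s in scenarios}
    if table is None:
        table = build_reference_table(
            scenarios, priors, n_sims_per_model, sample_config=sample_config, rng=rng
        )
    counts = pd.DataFrame(0, index=scenarios, columns=scenarios, dtype=int)
    for scenario_id in scenarios:
        for _ in range(n_pods_per_model):
            _, feats = simulate_feature_row(scenario_id, priors[scenario_id], sample_config, rng)
            distances = normalized_distance(feats, table)
            probs = model_choice_logistic(table, distances, feats, accept_fraction)
            chosen = max(probs, key=probs.get)
            counts.loc[scenario_id, chosen] += 1
    return ConfusionSummary(counts=counts, n_pods_per_model=n_pods_per_model)
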