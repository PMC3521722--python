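"""Rejection ABC with logistic-regression model choice and local-linear
parameter adjustment.

The reference table holds, for each simulated dataset, the simulating
scenario, its parameter draw and its summary vector.  Inference against an
observed summary vector proceeds in three steps:

1. *Rejection*: summaries are normalized per statistic (median absolute
   deviation over the whole table) and the closest fraction of simulations
   by Euclidean distance is retained.
2. *Model choice*: a weighted multinomial logistic regression of the
   scenario indicator on the normalized summary deviations over the
   retained rows, evaluated at deviation zero, estimates per-scenario
   posterior probabilities (the raw retained proportions are always
   reported alongside).
3. *Parameter adjustment*: within the chosen scenario's simulations, the
   retained parameter values are regressed on the summary deviations
   (local-linear, Epanechnikov kernel weights, parameters logit-transformed
   over their prior bounds) and residual-corrected to deviation zero, which
   shrinks the retained cloud toward the observed data while guaranteeing
   the adjusted values stay inside the prior bounds.

The two regression steps are exposed as scikit-learn estimators
(:class:`ABCScenarioClassifier`, :class:`ABCParameterAdjuster`); the
module-level functions are thin wrappers over them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .coalescent import SampleConfig, dataset_summaries, summary_names
from .scenarios import DemographicScenario, sample_prior
from .stats import SummaryVector

__all__ = [
    "ReferenceTable",
    "RejectionResult",
    "ScenarioPosteriors",
    "AdjustedPosterior",
    "PosteriorSummary",
    "AbcResult",
    "ABCScenarioClassifier",
    "ABCParameterAdjuster",
    "build_reference_table",
    "rejection",
    "scenario_posteriors",
    "adjust_parameters",
    "posterior_summary",
    "weighted_quantile",
    "percent_change",
    "infer",
]

_LOGIT_EPS = 1e-9


def _mad_scale(X: np.ndarray) -> np.ndarray:
    """Per-column scale: MAD, falling back to SD, falling back to 1."""
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    sd = X.std(axis=0)
    scale = mad.copy()
    use_sd = scale == 0
    scale[use_sd] = sd[use_sd]
    degenerate = scale == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} summary statistic(s) constant across the "
            "reference table; scale set to 1",
            stacklevel=3,
        )
        scale[degenerate] = 1.0
    return scale


@dataclass
class ReferenceTable:
    """Simulated (scenario, parameters, summaries) rows plus normalization."""

    scenario: np.ndarray  # row scenario names
    params: pd.DataFrame  # one column per parameter, NaN where absent
    summaries: np.ndarray  # (n_rows, n_stats)
    stat_names: tuple[str, ...]
    scale: np.ndarray
    scenarios: dict[str, DemographicScenario]
    sample_config: SampleConfig

    @property
    def n_rows(self) -> int:
        return len(self.scenario)

    def rows_for(self, scenario: str) -> np.ndarray:
        return np.flatnonzero(self.scenario == scenario)

    def save(self, path: str) -> None:
        """Persist as TSV plus a JSON sidecar of scale factors and design."""
        df = pd.DataFrame({"scenario": self.scenario})
        df = pd.concat([df, self.params.reset_index(drop=True)], axis=1)
        for i, name in enumerate(self.stat_names):
            df[name] = self.summaries[:, i]
        df.to_csv(path, sep="\t", index=False)
        meta = {
            "stat_names": list(self.stat_names),
            "scale": self.scale.tolist(),
            "param_names": list(self.params.columns),
            "scenarios": {
                name: {
                    "param_bounds": {
                        p: list(scn.prior.bounds_for(p)) for p in scn.param_names
                    },
                    "mu_mean_bounds": list(scn.prior.mu_mean_bounds),
                    "gsm_p_bounds": list(scn.prior.gsm_p_bounds),
                    "gamma_shape": scn.prior.gamma_shape,
                    "rate_mode": scn.prior.rate_mode,
                }
                for name, scn in self.scenarios.items()
            },
            "sample_config": {
                "samples": [list(x) for x in self.sample_config.samples],
                "n_loci": self.sample_config.n_loci,
                "founder": self.sample_config.founder,
            },
        }
        with open(path + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "ReferenceTable":
        from .scenarios import PriorSpec, make_scenario

        df = pd.read_csv(path, sep="\t")
        with open(path + ".meta.json") as fh:
            meta = json.load(fh)
        stat_names = tuple(meta["stat_names"])
        scenarios = {}
        for name, sm in meta["scenarios"].items():
            prior = PriorSpec(
                param_bounds={p: tuple(b) for p, b in sm["param_bounds"].items()},
                mu_mean_bounds=tuple(sm["mu_mean_bounds"]),
                gsm_p_bounds=tuple(sm["gsm_p_bounds"]),
                gamma_shape=sm["gamma_shape"],
                rate_mode=sm["rate_mode"],
            )
            scenarios[name] = make_scenario(name, prior)
        sc = meta["sample_config"]
        sample_config = SampleConfig(
            samples=tuple((int(a), int(b)) for a, b in sc["samples"]),
            n_loci=int(sc["n_loci"]),
            founder=int(sc["founder"]),
        )
        return cls(
            scenario=df["scenario"].to_numpy(),
            params=df[meta["param_names"]],
            summaries=df[list(stat_names)].to_numpy(),
            stat_names=stat_names,
            scale=np.asarray(meta["scale"], dtype=float),
            scenarios=scenarios,
            sample_config=sample_config,
        )


def build_reference_table(
    scenarios: list[DemographicScenario],
    n_per_scenario: int,
    sample_config: SampleConfig,
    rng: np.random.Generator,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` datasets per scenario and tabulate their
    parameter draws and summary vectors."""
    if n_per_scenario < 100:
        raise ValueError("need at least 100 simulations per scenario")
    names = summary_names(sample_config)
    labels: list[str] = []
    records: list[dict] = []
    summaries = np.empty((n_per_scenario * len(scenarios), len(names)))
    row = 0
    for scn in scenarios:
        for _ in range(n_per_scenario):
            draw = sample_prior(scn, rng, n_loci=sample_config.n_loci)
            summaries[row] = dataset_summaries(draw, sample_config, rng)
            labels.append(scn.name)
            rec = dict(draw.params)
            rec["mu_mean"] = draw.mu_mean
            rec["gsm_p"] = draw.gsm_p
            records.append(rec)
            row += 1
    params = pd.DataFrame.from_records(records)
    return ReferenceTable(
        scenario=np.asarray(labels, dtype=object),
        params=params,
        summaries=summaries,
        stat_names=names,
        scale=_mad_scale(summaries),
        scenarios={s.name: s for s in scenarios},
        sample_config=sample_config,
    )


@dataclass(frozen=True)
class RejectionResult:
    """Indices (in table order) and distances of the retained simulations."""

    indices: np.ndarray
    distances: np.ndarray  # distances of the retained rows, same order

    @property
    def n_retained(self) -> int:
        return len(self.indices)

    def weights(self) -> np.ndarray:
        """Epanechnikov kernel weights in distance, uniform if degenerate."""
        dmax = self.distances.max()
        if dmax == 0:
            return np.ones_like(self.distances)
        w = 1.0 - (self.distances / dmax) ** 2
        if w.sum() == 0:  # all retained rows share the maximal distance
            return np.ones_like(self.distances)
        return w


def _as_observed(table: ReferenceTable, observed) -> np.ndarray:
    if isinstance(observed, SummaryVector):
        if observed.names != table.stat_names:
            raise ValueError(
                "observed summary names do not match the reference table: "
                f"{observed.names} vs {table.stat_names}"
            )
        return np.asarray(observed.values, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if observed.shape != (len(table.stat_names),):
        raise ValueError("observed vector length does not match the table")
    return observed


def _rejection_core(
    X: np.ndarray, scale: np.ndarray, observed: np.ndarray, tolerance: float
) -> RejectionResult:
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be a fraction in (0, 1]")
    dev = (X - observed) / scale
    d = np.sqrt(np.sum(dev * dev, axis=1))
    m = int(np.ceil(tolerance * len(d)))
    order = np.argsort(d, kind="stable")[:m]  # ties broken by row index
    return RejectionResult(indices=order, distances=d[order])


def rejection(table: ReferenceTable, observed, tolerance: float = 0.01) -> RejectionResult:
    """Retain the closest ``tolerance`` fraction of simulations by
    normalized Euclidean distance to the observed summaries."""
    obs = _as_observed(table, observed)
    return _rejection_core(table.summaries, table.scale, obs, tolerance)


class ABCScenarioClassifier(BaseEstimator, ClassifierMixin):
    """Rejection + weighted multinomial-logistic ABC model choice.

    A scikit-learn classifier over summary vectors: ``fit`` stores the
    reference simulations (X = summary vectors, y = scenario labels) and
    their robust per-statistic scale; ``predict_proba`` runs rejection
    around each query point and evaluates the local logistic regression at
    deviation zero.

    Parameters
    ----------
    tolerance : float
        Fraction of simulations retained by the rejection step.
    ridge : float
        L2 penalty of the logistic regression (kept tiny, for numerical
        stability only).
    """

    def __init__(self, tolerance: float = 0.01, ridge: float = 1e-6):
        self.tolerance = tolerance
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        self.X_ = X
        self.y_ = y
        self.scale_ = _mad_scale(X)
        return self

    def _posteriors_one(self, x: np.ndarray):
        rej = _rejection_core(self.X_, self.scale_, x, self.tolerance)
        labels = self.y_[rej.indices]
        direct = np.array(
            [np.mean(labels == c) for c in self.classes_], dtype=float
        )
        flags: list[str] = []
        present = np.unique(labels)
        if len(present) < 2:
            flags.append("degenerate_single_scenario")
            return direct, direct, flags
        devs = (self.X_[rej.indices] - x) / self.scale_
        w = rej.weights()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                clf = LogisticRegression(
                    C=1.0 / self.ridge, max_iter=1000, solver="lbfgs"
                )
                clf.fit(devs, labels, sample_weight=w)
                p_at_zero = clf.predict_proba(np.zeros((1, devs.shape[1])))[0]
        except Exception:
            flags.append("logistic_fallback")
            return direct, direct, flags
        logistic = np.zeros(len(self.classes_))
        for p, c in zip(p_at_zero, clf.classes_):
            logistic[np.flatnonzero(self.classes_ == c)[0]] = p
        logistic /= logistic.sum()
        return direct, logistic, flags

    def predict_proba(self, X):
        check_is_fitted(self, "X_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((len(X), len(self.classes_)))
        for i, x in enumerate(X):
            _, logistic, _ = self._posteriors_one(x)
            out[i] = logistic
        return out

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


@dataclass(frozen=True)
class ScenarioPosteriors:
    """Per-scenario posterior probabilities (direct and logistic)."""

    direct: dict[str, float]
    logistic: dict[str, float]
    flags: tuple[str, ...]

    def best(
        self,
        scenarios: dict[str, DemographicScenario] | None = None,
        use: str = "logistic",
    ) -> str:
        """Highest-posterior scenario; exact ties break toward the scenario
        with fewer parameters (then alphabetically)."""
        probs = self.logistic if use == "logistic" else self.direct

        def key(name):
            n_par = scenarios[name].n_params if scenarios else 0
            return (-probs[name], n_par, name)

        return min(probs, key=key)


def scenario_posteriors(
    table: ReferenceTable, observed, tolerance: float = 0.01
) -> ScenarioPosteriors:
    """Estimate per-scenario posterior probabilities for the observed data."""
    obs = _as_observed(table, observed)
    clf = ABCScenarioClassifier(tolerance=tolerance)
    clf.fit(table.summaries, table.scenario)
    clf.scale_ = table.scale  # share the table's normalization
    direct, logistic, flags = clf._posteriors_one(obs)
    classes = [str(c) for c in clf.classes_]
    return ScenarioPosteriors(
        direct=dict(zip(classes, map(float, direct))),
        logistic=dict(zip(classes, map(float, logistic))),
        flags=tuple(flags),
    )


class ABCParameterAdjuster(BaseEstimator):
    """Beaumont-style local-linear regression adjustment of ABC posteriors.

    ``fit`` stores retained summary vectors and parameter values together
    with the per-parameter prior bounds; :meth:`adjust` regresses the
    logit-transformed parameters on the normalized summary deviations with
    Epanechnikov weights and residual-corrects to deviation zero.  The
    back-transform keeps every adjusted value inside its prior bounds.
    """

    def __init__(self, bounds=None):
        self.bounds = bounds

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if y.shape[0] != X.shape[0]:
            y = y.T
        self.X_ = X
        self.y_ = y
        self.n_features_in_ = X.shape[1]
        bounds = self.bounds
        if bounds is None:
            bounds = [(col.min(), col.max()) for col in y.T]
        self.bounds_ = list(bounds)
        return self

    def _to_logit(self, y):
        z = np.empty_like(y)
        for j, (lo, hi) in enumerate(self.bounds_):
            u = np.clip((y[:, j] - lo) / (hi - lo), _LOGIT_EPS, 1 - _LOGIT_EPS)
            z[:, j] = np.log(u / (1 - u))
        return z

    def _from_logit(self, z):
        y = np.empty_like(z)
        for j, (lo, hi) in enumerate(self.bounds_):
            y[:, j] = lo + (hi - lo) * expit(z[:, j])
        return y

    def adjust(self, x_obs: np.ndarray, weights: np.ndarray) -> np.ndarray:
        """Adjusted parameter samples for one observed summary vector."""
        check_is_fitted(self, "X_")
        devs = self.X_ - np.asarray(x_obs, dtype=float)
        z = self._to_logit(self.y_)
        z_adj = np.empty_like(z)
        for j in range(z.shape[1]):
            reg = LinearRegression()
            reg.fit(devs, z[:, j], sample_weight=weights)
            fitted = reg.predict(devs)
            # evaluate at deviation zero, keep the residuals
            z_adj[:, j] = reg.intercept_ + (z[:, j] - fitted)
        return self._from_logit(z_adj)


@dataclass
class AdjustedPosterior:
    """Weighted posterior samples for one scenario's parameters."""

    scenario: str
    param_names: tuple[str, ...]
    samples: pd.DataFrame  # adjusted (or raw, if flagged unadjusted)
    raw: pd.DataFrame
    weights: np.ndarray
    flags: tuple[str, ...] = ()


def adjust_parameters(
    table: ReferenceTable, observed, scenario: str, tolerance: float = 0.01
) -> AdjustedPosterior:
    """Local-linear-adjusted posterior for the chosen scenario's parameters.

    Rejection is run within the chosen scenario's simulations (so the
    retained count does not depend on how the other scenarios fit).  When
    fewer retained rows than summaries + 1 are available the adjustment is
    skipped and the unadjusted retained draws are returned, flagged.
    """
    if scenario not in table.scenarios:
        raise ValueError(f"scenario {scenario!r} not present in the table")
    obs = _as_observed(table, observed)
    rows = table.rows_for(scenario)
    rej = _rejection_core(table.summaries[rows], table.scale, obs, tolerance)
    keep = rows[rej.indices]
    if len(keep) < 30:
        raise ValueError(
            f"only {len(keep)} retained rows for scenario {scenario!r}; "
            "need at least 30 (increase tolerance or the table size)"
        )
    scn = table.scenarios[scenario]
    names = scn.param_names
    raw = table.params.loc[keep, list(names)].reset_index(drop=True)
    w = rej.weights()
    flags: tuple[str, ...] = ()
    if len(keep) < len(table.stat_names) + 1:
        flags = ("unadjusted",)
        samples = raw.copy()
    else:
        adjuster = ABCParameterAdjuster(
            bounds=[scn.prior.bounds_for(p) for p in names]
        )
        adjuster.fit(table.summaries[keep], raw.to_numpy())
        samples = pd.DataFrame(
            adjuster.adjust(obs, w), columns=list(names)
        )
    return AdjustedPosterior(
        scenario=scenario, param_names=names, samples=samples,
        raw=raw, weights=w, flags=flags,
    )


def weighted_quantile(values, q, weights=None) -> np.ndarray:
    """Quantiles of a weighted sample, reducing to linear (type-7)
    interpolation for uniform weights."""
    values = np.asarray(values, dtype=float)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if values.size == 0:
        raise ValueError("need at least one sample")
    if values.size == 1:
        return np.full(q.shape, values[0])
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    x = values[order]
    w = weights[order]
    total = w.sum()
    cum_prev = np.cumsum(w) - w
    with np.errstate(invalid="ignore", divide="ignore"):
        p = cum_prev / (total - w)
    p = np.nan_to_num(p, nan=0.5)
    p = np.maximum.accumulate(np.clip(p, 0.0, 1.0))
    return np.interp(q, p, x)


@dataclass(frozen=True)
class PosteriorSummary:
    """Median and 0.025/0.975 quantiles of one parameter's posterior."""

    median: float
    q025: float
    q975: float
    not_estimable: bool = False


def posterior_summary(
    samples, weights=None, prior_bounds: tuple[float, float] | None = None
) -> PosteriorSummary:
    """Weighted median and 95% interval; when prior bounds are given and
    the interval covers more than 90% of the prior range, the parameter is
    flagged as not estimable (a posterior flat across its prior)."""
    q025, med, q975 = weighted_quantile(samples, [0.025, 0.5, 0.975], weights)
    not_est = False
    if prior_bounds is not None:
        lo, hi = prior_bounds
        not_est = (q975 - q025) > 0.9 * (hi - lo)
    return PosteriorSummary(
        median=float(med), q025=float(q025), q975=float(q975),
        not_estimable=bool(not_est),
    )


def percent_change(n_before: float, n_after: float) -> int:
    """Percent change in Ne as printed in the study tables.

    Declines report the percentage lost, ``trunc(100 (1 - after/before))``;
    increases report the new size as a percentage of the old,
    ``trunc(100 after/before)``.  Truncation is toward zero.
    """
    if n_before <= 0:
        raise ValueError("n_before must be positive")
    if n_after <= n_before:
        return int(100.0 * (1.0 - n_after / n_before))
    return int(100.0 * n_after / n_before)


@dataclass
class AbcResult:
    """Complete inference output for one observed dataset."""

    posteriors: ScenarioPosteriors
    best_scenario: str
    retained: RejectionResult
    adjusted: AdjustedPosterior
    param_summaries: dict[str, PosteriorSummary]
    tolerance: float

    def to_frame(self) -> pd.DataFrame:
        """Result-table layout: per parameter median and 95% quantiles."""
        rows = []
        for name, s in self.param_summaries.items():
            rows.append(
                {
                    "scenario": self.best_scenario,
                    "posterior_prob": self.posteriors.logistic[self.best_scenario],
                    "parameter": name,
                    "median": s.median,
                    "q025": s.q025,
                    "q975": s.q975,
                    "not_estimable": s.not_estimable,
                }
            )
        return pd.DataFrame(rows)

    def ne_change(self) -> dict[str, int]:
        """Percent Ne change(s) implied by the posterior medians."""
        med = {k: s.median for k, s in self.param_summaries.items()}
        name = self.best_scenario
        if name == "bottleneck":
            return {"change": percent_change(med["N_pre"], med["N_post"])}
        if name == "increasing":
            return {"change": percent_change(med["N_anc"], med["N_cur"])}
        if name == "fluctuating":
            return {
                "change_expansion": percent_change(med["N_anc"], med["N_hist"]),
                "change_decline": percent_change(med["N_hist"], med["N_pres"]),
            }
        return {}


def infer(table: ReferenceTable, observed, tolerance: float = 0.01) -> AbcResult:
    """Full ABC inference: model choice, then adjusted posteriors for the
    winning scenario's parameters."""
    obs = _as_observed(table, observed)
    post = scenario_posteriors(table, obs, tolerance)
    best = post.best(table.scenarios)
    rej = rejection(table, obs, tolerance)
    adj = adjust_parameters(table, obs, best, tolerance)
    scn = table.scenarios[best]
    summaries = {}
    for p in scn.param_names:
        summaries[p] = posterior_summary(
            adj.samples[p].to_numpy(), adj.weights,
            prior_bounds=scn.prior.bounds_for(p),
        )
    return AbcResult(
        posteriors=post, best_scenario=best, retained=rej,
        adjusted=adj, param_summaries=summaries, tolerance=tolerance,
    )
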