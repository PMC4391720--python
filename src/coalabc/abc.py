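"""Approximate Bayesian Computation: reference tables, model choice and
posterior parameter estimation.

The engine follows standard rejection ABC practice: summary statistics are
standardized by their pooled median absolute deviation, candidate
simulations are ranked by Euclidean distance to the observed vector, and
the closest ``tolerance`` fraction is retained.  Model choice on the
accepted set is available by three methods — simple rejection (accepted
fraction per model), multinomial logistic regression with Epanechnikov
distance weights, and a small neural-network classifier — exposed as a
single sklearn-compatible classifier, :class:`ABCModelChoice`.

Parameter estimation uses nonlinear (single-hidden-layer) regression
adjustment of the accepted parameter draws on the summary statistics:
bounded parameters are logit-transformed to their prior support, a
multi-layer perceptron ``m(s)`` is fitted on the accepted set, and the
adjusted draws are ``θ_i − m(s_i) + m(s_obs)`` back-transformed.  Point
estimates are posterior medians with 95% highest-posterior-density
intervals.

Model choice between the four scenarios is hierarchical: the most probable
model is first selected within each scenario, then the four winners are
compared against each other on their pooled simulations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.utils.validation import check_is_fitted

from .io import Alignment, PopulationMap
from .models import DemographicModel, Priors, draw_parameters
from .sim import SampleConfig, matrix_summaries, simulate_two_locus_dataset
from .stats import pairwise_differences, tajimas_d_from_counts

__all__ = [
    "STAT_NAMES",
    "LOCI",
    "stat_columns",
    "ModelChoiceResult",
    "HierarchicalResult",
    "PosteriorResult",
    "ABCModelChoice",
    "ABCParameterEstimator",
    "build_reference_table",
    "observed_summaries",
    "rejection_choice",
    "mnlogistic_choice",
    "neuralnet_choice",
    "select_summary_vector",
    "hierarchical_choice",
    "estimate_parameters",
    "hpd_interval",
]

STAT_NAMES = ("pi", "ss", "d", "pi_w", "pi_b")
LOCI = ("coi", "its2")
PARAM_COLUMNS = ("theta_coi", "theta_its2", "tau1", "tau2", "tau3", "m", "alpha")


def stat_columns(names: tuple[str, ...] | list[str]) -> list[str]:
    """Expand per-locus statistic names into reference-table column names.

    Vectors concatenate both loci, so a 3-name vector has 6 columns.
    """
    return [f"{name}_{locus}" for name in names for locus in LOCI]


@dataclass
class ModelChoiceResult:
    method: str
    tolerance: float
    probabilities: pd.Series  # indexed by model_id, sums to 1

    @property
    def best_model(self) -> int:
        return int(self.probabilities.idxmax())


@dataclass
class HierarchicalResult:
    within: dict[int, ModelChoiceResult]  # scenario -> within-scenario result
    winners: dict[int, int]  # scenario -> winning model_id
    among: ModelChoiceResult  # comparison of the 4 winners

    def to_frame(self) -> pd.DataFrame:
        """Two-column layout: within-scenario and among-scenario probabilities."""
        rows = []
        for scen in sorted(self.within):
            for mid, p in self.within[scen].probabilities.items():
                rows.append(
                    {
                        "scenario": scen,
                        "model_id": int(mid),
                        "within_scenarios": p,
                        "among_scenarios": (
                            float(self.among.probabilities.get(mid, np.nan))
                            if mid == self.winners[scen]
                            else np.nan
                        ),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class PosteriorResult:
    model_id: int
    samples: pd.DataFrame  # adjusted posterior draws per parameter
    point: dict[str, float] = field(default_factory=dict)
    hpd95: dict[str, tuple[float, float]] = field(default_factory=dict)


def build_reference_table(
    models: list[DemographicModel],
    priors: Priors,
    sample_config: SampleConfig,
    n_sims_per_model: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate the ABC reference table: per model, prior draws → two-locus
    coalescent simulation → full candidate summary set.

    Columns: model_id, scenario, parameter draws (NaN where a model does not
    use a parameter), the ten per-locus statistics and the Tajima's-D
    defined flags (undefined D at S = 0 is imputed as 0 and flagged).
    """
    if n_sims_per_model < 1:
        raise ValueError("n_sims_per_model must be >= 1")
    records = []
    for model in models:
        for _ in range(n_sims_per_model):
            params = draw_parameters(model, priors, rng)
            res_coi, res_its2 = simulate_two_locus_dataset(
                model, params, sample_config, rng
            )
            row: dict[str, float] = {
                "model_id": model.model_id,
                "scenario": model.scenario,
            }
            for col in PARAM_COLUMNS:
                row[col] = params.get(col, np.nan)
            for locus, res in (("coi", res_coi), ("its2", res_its2)):
                summ = matrix_summaries(res)
                for name in STAT_NAMES:
                    row[f"{name}_{locus}"] = summ[name]
                row[f"d_defined_{locus}"] = summ["d_defined"]
            records.append(row)
    return pd.DataFrame.from_records(records)


def observed_summaries(
    aln_coi: Alignment,
    aln_its2: Alignment,
    popmap: PopulationMap,
) -> pd.Series:
    """The candidate summary vector computed on observed alignments.

    Statistics use the region level of the population map so that observed
    and simulated vectors share a definition (simulated demes = regions):
    total π and S per locus, Tajima's D, mean within-region π and mean raw
    between-region π over region pairs.
    """
    out: dict[str, float] = {}
    for locus, aln in (("coi", aln_coi), ("its2", aln_its2)):
        popmap.check_covers(aln)
        D = pairwise_differences(aln)
        n = aln.n
        iu = np.triu_indices(n, k=1)
        pi = float(D[iu].mean())
        X = np.array(
            [list(seq) for _, seq in aln.sequences], dtype="U1"
        )
        S = 0
        for j in range(X.shape[1]):
            col = X[:, j]
            states = set(col[(col != "N") & (col != "-")].tolist())
            if len(states) > 1:
                S += 1
        d = tajimas_d_from_counts(n, S, pi) if S > 0 else 0.0
        groups = popmap.grouped(aln, "region")
        id_index = {sid: i for i, sid in enumerate(aln.sample_ids)}
        idx = [
            np.array([id_index[s] for s in groups[r]])
            for r in popmap.regions
            if groups[r]
        ]
        pi_w_vals = [
            float(D[np.ix_(ix, ix)][np.triu_indices(len(ix), k=1)].mean())
            for ix in idx
            if len(ix) >= 2
        ]
        pi_b_vals = [
            float(D[np.ix_(idx[a], idx[b])].mean())
            for a in range(len(idx) - 1)
            for b in range(a + 1, len(idx))
        ]
        out[f"pi_{locus}"] = pi
        out[f"ss_{locus}"] = float(S)
        out[f"d_{locus}"] = float(d) if math.isfinite(d) else 0.0
        out[f"pi_w_{locus}"] = float(np.mean(pi_w_vals)) if pi_w_vals else 0.0
        out[f"pi_b_{locus}"] = float(np.mean(pi_b_vals)) if pi_b_vals else 0.0
    return pd.Series(out)


def _mad_scale(X: np.ndarray) -> np.ndarray:
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    return np.where(mad > 0, mad, 1.0)


class ABCModelChoice(BaseEstimator, ClassifierMixin):
    """ABC model choice as an sklearn classifier.

    ``fit`` takes the reference table's summary matrix ``X`` and model
    labels ``y``; ``predict_proba`` returns posterior model probabilities
    for observed summary vectors by the configured method on the
    ``tolerance``-closest simulations (MAD-standardized Euclidean
    distance).

    Parameters
    ----------
    method : {"rejection", "mnlogistic", "neuralnet"}
    tolerance : float
        Fraction of simulations retained (e.g. 0.001 or 0.01).
    hidden_units, n_restarts, reg_c, max_iter, random_state
        Classifier hyperparameters for the regression-based methods;
        ``reg_c`` is the inverse regularization strength guarding against
        perfect separation in the logistic method.
    """

    def __init__(
        self,
        method: str = "rejection",
        tolerance: float = 0.01,
        hidden_units: int = 5,
        n_restarts: int = 10,
        reg_c: float = 1.0,
        max_iter: int = 500,
        random_state: int | None = None,
    ):
        self.method = method
        self.tolerance = tolerance
        self.hidden_units = hidden_units
        self.n_restarts = n_restarts
        self.reg_c = reg_c
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if self.method not in ("rejection", "mnlogistic", "neuralnet"):
            raise ValueError(f"unknown method {self.method!r}")
        self.classes_ = np.unique(y)
        self.X_ = X
        self.y_ = y
        self.scale_ = _mad_scale(X)
        self.n_accept_ = max(1, math.ceil(self.tolerance * X.shape[0]))
        if self.tolerance * X.shape[0] < 1:
            raise ValueError(
                f"tolerance {self.tolerance} keeps no rows of {X.shape[0]}"
            )
        return self

    def _accepted(self, obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Z = (self.X_ - obs) / self.scale_
        dist = np.sqrt((Z**2).sum(axis=1))
        order = np.argsort(dist, kind="stable")[: self.n_accept_]
        return order, dist[order]

    def _proba_one(self, obs: np.ndarray) -> np.ndarray:
        idx, dist = self._accepted(obs)
        y_acc = self.y_[idx]
        if self.method == "rejection":
            probs = np.array(
                [np.mean(y_acc == c) for c in self.classes_], dtype=float
            )
            return probs
        present = np.unique(y_acc)
        if len(present) < 2:
            return np.array(
                [1.0 if c in present else 0.0 for c in self.classes_]
            )
        Xc = (self.X_[idx] - obs) / self.scale_
        d_max = dist.max()
        weights = (
            1.0 - (dist / d_max) ** 2 if d_max > 0 else np.ones_like(dist)
        )
        weights = np.maximum(weights, 1e-6)
        if self.method == "mnlogistic":
            clf = LogisticRegression(
                C=self.reg_c, max_iter=self.max_iter * 4
            )
            clf.fit(Xc, y_acc, sample_weight=weights)
            p = clf.predict_proba(np.zeros((1, Xc.shape[1])))[0]
            out = np.zeros(len(self.classes_))
            for cls, pi in zip(clf.classes_, p):
                out[np.where(self.classes_ == cls)[0][0]] = pi
            return out
        # neuralnet: small MLP ensemble averaged over restarts
        seed0 = self.random_state if self.random_state is not None else 0
        acc = np.zeros(len(self.classes_))
        for r in range(self.n_restarts):
            clf = MLPClassifier(
                hidden_layer_sizes=(self.hidden_units,),
                solver="lbfgs",
                max_iter=self.max_iter,
                alpha=1e-3,
                random_state=seed0 + r,
            )
            with warnings.catch_warnings():
                # individual restarts may stop at max_iter; the ensemble
                # average is what matters
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(Xc, y_acc)
            p = clf.predict_proba(np.zeros((1, Xc.shape[1])))[0]
            for cls, pi in zip(clf.classes_, p):
                acc[np.where(self.classes_ == cls)[0][0]] += pi
        return acc / self.n_restarts

    def predict_proba(self, X):
        check_is_fitted(self, "X_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.vstack([self._proba_one(row) for row in X])
        return out / out.sum(axis=1, keepdims=True)

    def predict(self, X):
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]


def _logit(u: np.ndarray) -> np.ndarray:
    return np.log(u / (1.0 - u))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class ABCParameterEstimator(BaseEstimator, RegressorMixin):
    """Neural-network regression adjustment of accepted parameter draws.

    ``fit`` takes the reference-table summary matrix ``X`` and the matrix of
    parameter draws ``theta`` (one column per parameter);
    ``sample_posterior(obs)`` returns the adjusted accepted draws.
    Parameters with finite prior bounds are logit-transformed onto the real
    line before the regression so adjusted draws respect the prior support.

    Parameters
    ----------
    tolerance : float
        Fraction of simulations retained.
    bounds : dict mapping parameter name to (lo, hi), optional
    hidden_units, n_restarts, max_iter, random_state
        MLP hyperparameters; predictions are averaged over restarts.
    min_accept : int
        Minimum accepted rows required (error below this).
    """

    def __init__(
        self,
        tolerance: float = 0.01,
        bounds: dict[str, tuple[float, float]] | None = None,
        hidden_units: int = 5,
        n_restarts: int = 10,
        max_iter: int = 500,
        min_accept: int = 20,
        random_state: int | None = None,
    ):
        self.tolerance = tolerance
        self.bounds = bounds
        self.hidden_units = hidden_units
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.min_accept = min_accept
        self.random_state = random_state

    def fit(self, X, theta):
        X = np.asarray(X, dtype=float)
        if isinstance(theta, pd.DataFrame):
            self.param_names_ = list(theta.columns)
            theta = theta.to_numpy(dtype=float)
        else:
            theta = np.asarray(theta, dtype=float)
            if theta.ndim == 1:
                theta = theta[:, None]
            self.param_names_ = [f"p{i}" for i in range(theta.shape[1])]
        if X.shape[0] != theta.shape[0]:
            raise ValueError("X and theta must have matching rows")
        self.X_ = X
        self.theta_ = theta
        self.scale_ = _mad_scale(X)
        self.n_accept_ = max(1, math.ceil(self.tolerance * X.shape[0]))
        if self.n_accept_ < self.min_accept:
            raise ValueError(
                f"tolerance {self.tolerance} accepts only {self.n_accept_} rows "
                f"(< min_accept={self.min_accept})"
            )
        return self

    def _transform(self, theta: np.ndarray) -> np.ndarray:
        out = theta.copy()
        eps = 1e-9
        for j, name in enumerate(self.param_names_):
            b = (self.bounds or {}).get(name)
            if b is not None:
                lo, hi = b
                u = np.clip((out[:, j] - lo) / (hi - lo), eps, 1 - eps)
                out[:, j] = _logit(u)
        return out

    def _back_transform(self, t: np.ndarray) -> np.ndarray:
        out = t.copy()
        for j, name in enumerate(self.param_names_):
            b = (self.bounds or {}).get(name)
            if b is not None:
                lo, hi = b
                out[:, j] = lo + (hi - lo) * _expit(out[:, j])
        return out

    def sample_posterior(self, obs) -> pd.DataFrame:
        check_is_fitted(self, "X_")
        obs = np.asarray(obs, dtype=float).ravel()
        Z = (self.X_ - obs) / self.scale_
        dist = np.sqrt((Z**2).sum(axis=1))
        idx = np.argsort(dist, kind="stable")[: self.n_accept_]
        Xc = Z[idx]
        t_acc = self._transform(self.theta_[idx])
        # no regression signal when the accepted statistics are constant
        if np.allclose(Xc.std(axis=0), 0.0):
            adjusted = t_acc
        else:
            seed0 = self.random_state if self.random_state is not None else 0
            pred_acc = np.zeros_like(t_acc)
            pred_obs = np.zeros(t_acc.shape[1])
            for r in range(self.n_restarts):
                reg = MLPRegressor(
                    hidden_layer_sizes=(self.hidden_units,),
                    solver="lbfgs",
                    max_iter=self.max_iter,
                    alpha=1e-2,
                    random_state=seed0 + r,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    reg.fit(Xc, t_acc if t_acc.shape[1] > 1 else t_acc.ravel())
                pa = reg.predict(Xc)
                po = reg.predict(np.zeros((1, Xc.shape[1])))
                if pa.ndim == 1:
                    pa = pa[:, None]
                    po = po[:, None]
                pred_acc += pa
                pred_obs += po[0]
            pred_acc /= self.n_restarts
            pred_obs /= self.n_restarts
            adjusted = t_acc - pred_acc + pred_obs
        back = self._back_transform(adjusted)
        return pd.DataFrame(back, columns=self.param_names_)


# ---------------------------------------------------------------------------
# Thin functional wrappers over the estimators
# ---------------------------------------------------------------------------


def _choice(
    obs: pd.Series,
    table: pd.DataFrame,
    tolerance: float,
    method: str,
    vector: tuple[str, ...] | list[str] | None = None,
    random_state: int | None = None,
) -> ModelChoiceResult:
    cols = stat_columns(vector if vector is not None else STAT_NAMES)
    clf = ABCModelChoice(
        method=method, tolerance=tolerance, random_state=random_state
    )
    clf.fit(table[cols].to_numpy(), table["model_id"].to_numpy())
    probs = clf.predict_proba(obs[cols].to_numpy())[0]
    return ModelChoiceResult(
        method=method,
        tolerance=tolerance,
        probabilities=pd.Series(probs, index=clf.classes_.astype(int)),
    )


def rejection_choice(obs, table, tolerance, vector=None) -> ModelChoiceResult:
    """Simple-rejection model probabilities (accepted fraction per model)."""
    return _choice(obs, table, tolerance, "rejection", vector)


def mnlogistic_choice(
    obs, table, tolerance, vector=None, random_state=None
) -> ModelChoiceResult:
    """Weighted multinomial-logistic model probabilities at the observed point."""
    return _choice(obs, table, tolerance, "mnlogistic", vector, random_state)


def neuralnet_choice(
    obs, table, tolerance, vector=None, random_state=None
) -> ModelChoiceResult:
    """Neural-network classifier model probabilities (restart ensemble)."""
    return _choice(obs, table, tolerance, "neuralnet", vector, random_state)


def select_summary_vector(
    candidate_vectors: list[tuple[str, ...]],
    table: pd.DataFrame,
    pods: pd.DataFrame,
    tolerance: float = 0.01,
) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Choose the summary vector maximizing Pr(true)/mean Pr(false) on PODs.

    ``pods`` holds pseudo-observed datasets (rows with ``model_id`` and the
    full candidate statistic columns, simulated from the prior).  For each
    candidate vector, rejection model choice is run on every POD against the
    reference table restricted to that vector; the score is the mean over
    PODs of the probability of the true model divided by the mean
    probability of the false models (floored at half an accepted draw to
    keep perfect classifications finite).
    """
    if not candidate_vectors:
        raise ValueError("need at least one candidate vector")
    n_models = table["model_id"].nunique()
    rows = []
    for vec in candidate_vectors:
        cols = stat_columns(vec)
        clf = ABCModelChoice(method="rejection", tolerance=tolerance)
        clf.fit(table[cols].to_numpy(), table["model_id"].to_numpy())
        probs = clf.predict_proba(pods[cols].to_numpy())
        floor = 0.5 / (clf.n_accept_ * max(n_models - 1, 1))
        ratios = []
        for i, (_, pod) in enumerate(pods.iterrows()):
            true_ix = np.where(clf.classes_ == pod["model_id"])[0][0]
            p_true = probs[i, true_ix]
            p_false = np.delete(probs[i], true_ix).mean()
            ratios.append(p_true / max(p_false, floor))
        rows.append({"vector": vec, "score": float(np.mean(ratios))})
    scores = pd.DataFrame(rows)
    best = scores.loc[scores["score"].idxmax(), "vector"]
    return tuple(best), scores


def hierarchical_choice(
    obs: pd.Series,
    table: pd.DataFrame,
    tolerance: float = 0.001,
    method: str = "rejection",
    vector: tuple[str, ...] | None = None,
) -> HierarchicalResult:
    """Within-then-among scenario model choice.

    Stage 1 selects the most probable model inside each scenario's model
    set; stage 2 compares the four winners on their pooled simulations.
    """
    within: dict[int, ModelChoiceResult] = {}
    winners: dict[int, int] = {}
    for scen, sub in table.groupby("scenario"):
        if sub["model_id"].nunique() == 1:
            mid = int(sub["model_id"].iloc[0])
            within[int(scen)] = ModelChoiceResult(
                method, tolerance, pd.Series([1.0], index=[mid])
            )
            winners[int(scen)] = mid
            continue
        res = _choice(obs, sub, tolerance, method, vector)
        within[int(scen)] = res
        winners[int(scen)] = res.best_model
    pooled = table[table["model_id"].isin(winners.values())]
    among = _choice(obs, pooled, tolerance, method, vector)
    return HierarchicalResult(within=within, winners=winners, among=among)


def estimate_parameters(
    obs: pd.Series,
    table: pd.DataFrame,
    model: DemographicModel,
    priors: Priors,
    tolerance: float = 0.01,
    vector: tuple[str, ...] | None = None,
    random_state: int | None = None,
    min_accept: int = 20,
) -> PosteriorResult:
    """Posterior parameters for one model by neural-net regression adjustment.

    The table must be restricted to the model's simulations.  The nuclear θ
    is tied to the mitochondrial θ by the exact 1:4 constraint, so it is
    derived from the adjusted mitochondrial draws rather than regressed
    independently.
    """
    sub = table[table["model_id"] == model.model_id]
    if sub.empty:
        raise ValueError(f"no rows for model {model.model_id}")
    cols = stat_columns(vector) if vector is not None else stat_columns(STAT_NAMES)
    free = ["theta_coi"] + [s for s in model.tau_symbols]
    if model.has_migration:
        free.append("m")
    if model.has_growth:
        free.append("alpha")
    bounds: dict[str, tuple[float, float]] = {"theta_coi": priors.theta_coi}
    if "tau1" in free:
        bounds["tau1"] = priors.tau1
    if "tau2" in free:
        bounds["tau2"] = (priors.tau23_low, priors.tau1[1])
    if "tau3" in free:
        bounds["tau3"] = (priors.tau23_low, priors.tau1[1])
    if "m" in free:
        bounds["m"] = priors.m
    if "alpha" in free:
        bounds["alpha"] = priors.alpha
    est = ABCParameterEstimator(
        tolerance=tolerance,
        bounds=bounds,
        random_state=random_state,
        min_accept=min_accept,
    )
    est.fit(sub[cols].to_numpy(), sub[free])
    samples = est.sample_posterior(obs[cols].to_numpy())
    samples["theta_its2"] = 4.0 * samples["theta_coi"]
    point = {c: float(samples[c].median()) for c in samples.columns}
    hpd = {c: hpd_interval(samples[c].to_numpy()) for c in samples.columns}
    return PosteriorResult(
        model_id=model.model_id, samples=samples, point=point, hpd95=hpd
    )


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the sorted samples."""
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    k = math.ceil(mass * n)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])
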