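"""Bayesian Gaussian random-intercept mixed models via blocked Gibbs sampling.

Model (all columns z-scored before fitting):

    y_ij = x_ij' beta + u_i + eps_ij,   eps_ij ~ N(0, sigma^2),
    u_i ~ N(0, tau^2),                  i = participant, j = trial,

with effectively-flat conjugate priors beta ~ N(0, 1e6 I) and
sigma^2, tau^2 ~ InverseGamma(1e-3, 1e-3). The sampler draws (beta, u) as
one joint Gaussian block given the variances, then sigma^2 and tau^2 from
their inverse-gamma full conditionals. The joint fixed/random block is
essential here: pain-quality predictors are constant within participant, so
beta and u are strongly correlated a posteriori and one-at-a-time updates
mix far too slowly for the potential-scale-reduction criterion.

Convergence is checked with split-Rhat (each chain halved; between- vs
within-half variance), required < 1.1 for all parameters. Posteriors are
summarized by the mean of pooled post-burn-in draws and equal-tailed 95%
credible intervals (linear-interpolation quantiles); an association is
flagged "credibly nonzero" when its 95% CI excludes 0.

Ten models are fitted: {SF-MPQ-2 subclass scores; the items of each of the
four subclasses} x {extension-phase muscle activity; DISTANCE between the
activity centroid and the pain site}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from . import sfmpq2

BETA_PRIOR_VARIANCE = 1.0e6
IG_PRIOR_SHAPE = 1.0e-3
IG_PRIOR_RATE = 1.0e-3
RHAT_THRESHOLD = 1.1

DEPENDENTS = ("extension_activity", "distance_cm")

MODEL_PREDICTORS: dict[str, tuple[str, ...]] = {
    "subclass": sfmpq2.SUBCLASS_NAMES,
    "continuous": sfmpq2.CONTINUOUS_ITEMS,
    "intermittent": sfmpq2.INTERMITTENT_ITEMS,
    "neuropathic": sfmpq2.NEUROPATHIC_ITEMS,
    "affective": sfmpq2.AFFECTIVE_ITEMS,
}

MODEL_DISPLAY = {
    "subclass": "SFMPQ-2 subclass",
    "continuous": "Continuous pain",
    "intermittent": "Intermittent pain",
    "neuropathic": "Neuropathic pain",
    "affective": "Affective",
}


@dataclass(frozen=True)
class ModelSpec:
    """One regression: a named predictor set against one dependent variable."""

    model_name: str
    dependent: str
    predictors: tuple[str, ...]
    include_nrs_covariate: bool = False

    def __post_init__(self) -> None:
        if self.model_name not in MODEL_PREDICTORS:
            raise ValueError(f"unknown model {self.model_name!r}")
        if self.dependent not in DEPENDENTS:
            raise ValueError(f"unknown dependent {self.dependent!r}")
        if tuple(self.predictors) != MODEL_PREDICTORS[self.model_name]:
            raise ValueError(
                f"predictors for {self.model_name!r} must be "
                f"{MODEL_PREDICTORS[self.model_name]}"
            )


def build_model_specs(include_nrs_covariate: bool = False) -> list[ModelSpec]:
    """The ten study models: 5 predictor sets x 2 dependent variables."""
    return [
        ModelSpec(
            model_name=name,
            dependent=dep,
            predictors=MODEL_PREDICTORS[name],
            include_nrs_covariate=include_nrs_covariate,
        )
        for dep in DEPENDENTS
        for name in MODEL_PREDICTORS
    ]


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler settings; defaults are the study's full settings."""

    n_iterations: int = 16_000
    n_burn_in: int = 13_000
    n_chains: int = 4
    seed: int = 0
    thinning: int = 1

    def __post_init__(self) -> None:
        if self.n_burn_in >= self.n_iterations:
            raise ValueError("n_burn_in must be < n_iterations")
        if self.n_chains < 2:
            raise ValueError("Rhat needs at least 2 chains")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.n_burn_in) // self.thinning


@dataclass
class HierarchicalModel:
    """Design for one fit: standardized y, X (intercept first), grouping.

    ``groups`` maps each observation to a participant index (0..G-1);
    ``groups=None`` requests a fixed-effects-only fit (no random intercepts,
    tau^2 dropped from the model).
    """

    y: np.ndarray
    X: np.ndarray
    coef_names: Sequence[str]
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.y.ndim != 1 or self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("y must be 1-D and X (n_obs x p) with matching n_obs")
        if not np.all(np.isfinite(self.y)) or not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite values in response or design")
        if len(self.coef_names) != self.X.shape[1]:
            raise ValueError("coef_names length must match design columns")
        if self.groups is not None:
            self.groups = np.asarray(self.groups, dtype=int)
            if self.groups.shape != self.y.shape:
                raise ValueError("groups must align with observations")
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            r = np.linalg.qr(self.X, mode="r")
            bad = [
                self.coef_names[j]
                for j in range(self.X.shape[1])
                if abs(r[j, j]) < 1e-8 * abs(r[0, 0])
            ]
            raise ValueError(f"design is rank deficient; collinear columns: {bad}")

    @property
    def n_groups(self) -> int:
        return 0 if self.groups is None else int(self.groups.max()) + 1


def standardize(column: np.ndarray) -> tuple[np.ndarray, float, float]:
    """z-score a column; returns (z, mean, sd) with sd computed with n-1.

    A constant column is a degenerate predictor and raises ``ValueError``.
    """
    x = np.asarray(column, dtype=float)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    # ptp guard: round-off in the mean can leave a spurious sd ~1e-16 on
    # columns whose entries are all identical
    if x.size < 2 or np.ptp(x) == 0 or not sd > 0:
        raise ValueError("cannot standardize a constant column (sd = 0)")
    return (x - mean) / sd, mean, sd


def _invgamma_draw(rng: np.random.Generator, shape: float, rate: float) -> float:
    return float(rate / rng.gamma(shape))


def _run_chain(
    model: HierarchicalModel, settings: MCMCSettings, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    y, X = model.y, model.X
    n, p = X.shape
    mixed = model.groups is not None
    G = model.n_groups

    XtX = X.T @ X
    Xty = X.T @ y
    if mixed:
        g = model.groups
        counts = np.bincount(g, minlength=G).astype(float)
        if np.any(counts == 0):
            raise ValueError("every group index up to max(groups) must occur")
        XtZ = np.stack([np.bincount(g, weights=X[:, j], minlength=G) for j in range(p)])
        Zty = np.bincount(g, weights=y, minlength=G)

    # over-dispersed starting values for the variances; (beta, u) are drawn
    # jointly in the first sweep so they need no explicit initialization
    ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid0 = y - X @ ols
    s2_base = max(float(np.var(resid0, ddof=min(p, n - 1))), 1e-8)
    sigma2 = s2_base * float(np.exp(rng.normal(0.0, 1.0)))
    tau2 = 0.0
    if mixed:
        gm = np.bincount(g, weights=resid0, minlength=G) / counts
        tau2 = max(float(np.var(gm)), 0.05 * s2_base) * float(np.exp(rng.normal(0.0, 1.0)))

    keep = settings.n_retained
    beta_draws = np.empty((keep, p))
    sigma2_draws = np.empty(keep)
    tau2_draws = np.empty(keep) if mixed else None
    u_draws = np.empty((keep, G)) if mixed else None

    prior_prec = 1.0 / BETA_PRIOR_VARIANCE
    k = 0
    for it in range(settings.n_iterations):
        if mixed:
            dim = p + G
            prec = np.zeros((dim, dim))
            prec[:p, :p] = XtX / sigma2
            prec[:p, :p].flat[:: p + 1] += prior_prec
            prec[:p, p:] = XtZ / sigma2
            prec[p:, :p] = prec[:p, p:].T
            idx = np.arange(p, dim)
            prec[idx, idx] = counts / sigma2 + 1.0 / tau2
            b = np.concatenate([Xty, Zty]) / sigma2
            L = linalg.cholesky(prec, lower=True)
            mean = linalg.cho_solve((L, True), b)
            z = rng.standard_normal(dim)
            draw = mean + linalg.solve_triangular(L, z, lower=True, trans="T")
            beta, u = draw[:p], draw[p:]
            resid = y - X @ beta - u[g]
            tau2 = _invgamma_draw(
                rng, IG_PRIOR_SHAPE + G / 2.0, IG_PRIOR_RATE + 0.5 * float(u @ u)
            )
        else:
            prec = XtX / sigma2 + prior_prec * np.eye(p)
            b = Xty / sigma2
            L = linalg.cholesky(prec, lower=True)
            mean = linalg.cho_solve((L, True), b)
            z = rng.standard_normal(p)
            beta = mean + linalg.solve_triangular(L, z, lower=True, trans="T")
            resid = y - X @ beta
        sigma2 = _invgamma_draw(
            rng, IG_PRIOR_SHAPE + n / 2.0, IG_PRIOR_RATE + 0.5 * float(resid @ resid)
        )
        if it >= settings.n_burn_in and (it - settings.n_burn_in) % settings.thinning == 0:
            beta_draws[k] = beta
            sigma2_draws[k] = sigma2
            if mixed:
                tau2_draws[k] = tau2
                u_draws[k] = u
            k += 1

    out: dict[str, np.ndarray] = {
        name: beta_draws[:k, j] for j, name in enumerate(model.coef_names)
    }
    out["sigma2"] = sigma2_draws[:k]
    if mixed:
        out["tau2"] = tau2_draws[:k]
        for i in range(G):
            out[f"u[{i}]"] = u_draws[:k, i]
    return out


def gibbs_sample(
    model: HierarchicalModel, settings: MCMCSettings
) -> dict[str, np.ndarray]:
    """Run ``n_chains`` Gibbs chains; returns parameter -> (chains x draws).

    Chain seeds are derived deterministically from ``settings.seed`` via a
    seed sequence, so identical settings reproduce identical draws.
    """
    children = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    chains = [
        _run_chain(model, settings, np.random.default_rng(child)) for child in children
    ]
    return {
        name: np.stack([c[name] for c in chains]) for name in chains[0]
    }


def compute_rhat(chains: np.ndarray) -> float:
    """Split-Rhat (potential scale reduction factor) for one parameter.

    Each chain is halved; with W the mean within-half variance and B the
    between-half variance of the half means (times draws per half),
    Rhat = sqrt(((n-1)/n * W + B/n) / W).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a (n_chains x n_draws) array with >= 2 chains")
    n = chains.shape[1]
    if n < 4:
        raise ValueError("need at least 4 retained draws per chain for split-Rhat")
    half = n // 2
    halves = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    within = halves.var(axis=1, ddof=1)
    W = float(within.mean())
    if W == 0.0:
        raise ValueError("degenerate chains: zero within-chain variance in all halves")
    B = half * float(halves.mean(axis=1).var(ddof=1))
    var_plus = (half - 1) / half * W + B / half
    return float(np.sqrt(var_plus / W))


def summarize_posterior(chains: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Per-parameter posterior summary of the retained draws.

    Columns: estimate (pooled posterior mean), ci_low/ci_high (equal-tailed
    95% interval, linear-interpolation quantiles), rhat (NaN for degenerate
    constant chains), and the credibly_nonzero flag (95% CI excludes 0).
    """
    rows = []
    for name, draws in chains.items():
        pooled = np.asarray(draws, dtype=float).ravel()
        lo, hi = np.quantile(pooled, [0.025, 0.975])
        try:
            rhat = compute_rhat(draws)
        except ValueError:
            rhat = float("nan")
        rows.append(
            {
                "parameter": name,
                "estimate": float(pooled.mean()),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "rhat": rhat,
                "credibly_nonzero": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class FitResult:
    """One fitted model: spec, posterior summary, diagnostics."""

    spec: ModelSpec
    summary: pd.DataFrame
    max_rhat: float
    converged: bool
    dropped_predictors: tuple[str, ...] = ()
    chains: dict[str, np.ndarray] | None = None


def _design_for_spec(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[HierarchicalModel, tuple[str, ...]]:
    predictors = list(spec.predictors)
    if spec.include_nrs_covariate:
        predictors.append("nrs")
    dropped = []
    cols = []
    names = ["intercept"]
    for name in predictors:
        col = data[name].to_numpy(dtype=float)
        if np.ptp(col) > 0:
            cols.append(standardize(col)[0])
            names.append(name)
        else:
            dropped.append(name)
    y = standardize(data[spec.dependent].to_numpy(dtype=float))[0]
    X = np.column_stack([np.ones(len(data))] + cols)
    groups = pd.Categorical(data["patient_id"]).codes.astype(int)
    model = HierarchicalModel(y=y, X=X, coef_names=names, groups=groups)
    return model, tuple(dropped)


def fit_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    settings: MCMCSettings,
    keep_chains: bool = False,
) -> FitResult:
    """Standardize, fit, and summarize one model on trial-level data.

    ``data`` must carry patient_id, the dependent column, and the predictor
    columns (patient-level scores repeated across trials). Predictors that
    are constant across the cohort cannot be standardized; they are dropped
    from the design and reported as NaN rows flagged non-convergent-free.
    """
    model, dropped = _design_for_spec(data, spec)
    if dropped:
        warnings.warn(
            f"model {spec.model_name}/{spec.dependent}: dropped constant "
            f"predictor(s) {dropped}",
            RuntimeWarning,
            stacklevel=2,
        )
    chains = gibbs_sample(model, settings)
    summary = summarize_posterior(chains)
    for name in dropped:
        summary = pd.concat(
            [
                summary,
                pd.DataFrame(
                    [
                        {
                            "parameter": name,
                            "estimate": np.nan,
                            "ci_low": np.nan,
                            "ci_high": np.nan,
                            "rhat": np.nan,
                            "credibly_nonzero": False,
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )
    max_rhat = float(np.nanmax(summary["rhat"].to_numpy()))
    return FitResult(
        spec=spec,
        summary=summary,
        max_rhat=max_rhat,
        converged=bool(max_rhat < RHAT_THRESHOLD),
        dropped_predictors=dropped,
        chains=chains if keep_chains else None,
    )


@dataclass
class FitReport:
    """All ten model fits: per-dependent report tables + long-form summary."""

    tables: dict[str, pd.DataFrame]
    summary: pd.DataFrame
    results: list[FitResult] = field(default_factory=list)


def fit_all_models(
    trial_outcomes: pd.DataFrame,
    patients: pd.DataFrame,
    settings: MCMCSettings,
    include_nrs_covariate: bool = False,
) -> FitReport:
    """Fit the ten study models and assemble the two report tables.

    ``trial_outcomes`` holds one row per (patient, experimental trial) with
    the extension-phase activity and DISTANCE outcomes; ``patients`` holds
    the pain scores. Each model gets its own deterministic seed derived from
    ``settings.seed``. Models with any Rhat >= 1.1 are reported with a
    convergence warning flag, never dropped.
    """
    if "patient_id" not in trial_outcomes or "patient_id" not in patients:
        raise ValueError("both tables need a patient_id join key")
    missing = set(trial_outcomes["patient_id"]) - set(patients["patient_id"])
    if missing:
        raise ValueError(f"outcomes reference unknown patients: {sorted(missing)}")
    data = trial_outcomes.merge(patients, on="patient_id", how="left", validate="m:1")
    specs = build_model_specs(include_nrs_covariate)
    seeds = [
        int(child.generate_state(1)[0] % (2**31))
        for child in np.random.SeedSequence(settings.seed).spawn(len(specs))
    ]
    results: list[FitResult] = []
    long_rows = []
    for spec, seed in zip(specs, seeds):
        res = fit_model(data, spec, replace(settings, seed=seed))
        results.append(res)
        keep = res.summary[res.summary["parameter"].isin(spec.predictors)]
        for _, r in keep.iterrows():
            long_rows.append(
                {
                    "model_name": spec.model_name,
                    "dependent": spec.dependent,
                    "parameter": r["parameter"],
                    "estimate": r["estimate"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "rhat": r["rhat"],
                    "credibly_nonzero": r["credibly_nonzero"],
                    "model_converged": res.converged,
                }
            )
    long = pd.DataFrame(long_rows)
    tables = {}
    for dep in DEPENDENTS:
        sub = long[long["dependent"] == dep]
        rows = []
        for m in MODEL_PREDICTORS:
            for v in MODEL_PREDICTORS[m]:
                r = sub[(sub["model_name"] == m) & (sub["parameter"] == v)].iloc[0]
                rows.append(
                    {
                        "Model": MODEL_DISPLAY[m],
                        "Variables": sfmpq2.DISPLAY_NAMES[v],
                        "Estimate": r["estimate"],
                        "Lower CI": r["ci_low"],
                        "Upper CI": r["ci_high"],
                        "Rhat": r["rhat"],
                    }
                )
        tables[dep] = pd.DataFrame(rows)
    return FitReport(tables=tables, summary=long, results=results)
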