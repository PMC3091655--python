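"""Poisson log-link count model over chromatin classes, with BIC selection.

The observation is a genomic window *i* with chromatin class xi_i, length
L_i and feature coverage K_i; the per-window feature count follows

    C_i ~ Poisson(lambda_i),
    log(lambda_i) = mu_{g(xi_i)} + beta_{g(xi_i)} log(L_i)
                    + zeta_{g(xi_i)} log(K_i + 1),

where g maps the window's chromatin class to its parameter group under a
candidate tying configuration (:class:`~hetchrom.partition.ModelConfig`).
The intercept mu captures the overall count density of a group, beta the
window-length effect, zeta the coverage effect. Coverage enters as
log(K + 1) so that uncovered windows (K = 0) keep a finite predictor.

Each configuration is scored by bic_score = 2*loglik - p*ln(N) (higher is
better); the configuration with the best score is the MAX model, and the
Bayes factor between two configurations is approximated by
exp(|score difference| / 2). Within a configuration the maximum-likelihood
estimate is found by Newton iteration with step halving (the grouped Poisson
regression is a concave problem); the discrete search over configurations is
either exhaustive (the 52 set partitions of five classes in joint mode) or a
seeded simulated-annealing walk.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import gammaln

from .features import WindowFeatureRecord, records_to_frame
from .partition import (
    ModelConfig,
    ModelComparison,
    enumerate_model_space,
    support_label,
)
from .regions import CHROMATIN_CLASSES

__all__ = [
    "ParameterSet",
    "ChromatinCountModel",
    "PartitionPoissonResults",
    "ModelSelectionResults",
    "ConvergenceError",
    "poisson_loglik",
    "compare_fits",
]


class ConvergenceError(RuntimeError):
    """The Newton iteration failed to reach the gradient tolerance."""


@dataclass(frozen=True)
class ParameterSet:
    """Per-class regression parameters (tied classes share values)."""

    mu: dict[str, float]
    beta: dict[str, float]
    zeta: dict[str, float]

    def linear_predictor(
        self, classes: Sequence[str], log_length: np.ndarray, log_coverage: np.ndarray
    ) -> np.ndarray:
        mu = np.array([self.mu[c] for c in classes])
        beta = np.array([self.beta[c] for c in classes])
        zeta = np.array([self.zeta[c] for c in classes])
        return mu + beta * log_length + zeta * log_coverage


def poisson_loglik(
    params: ParameterSet,
    data: pd.DataFrame,
    config: ModelConfig | None = None,
    coverage_offset: float = 1.0,
) -> float:
    """Poisson log-likelihood of a window feature table under ``params``.

    ``data`` needs columns ``class``, ``C``, ``K``, ``L``. If ``config`` is
    given, parameter values are checked to be constant within its groups.
    """
    if config is not None:
        for pname in ("mu", "beta", "zeta"):
            table = getattr(params, pname)
            for group in getattr(config, f"{pname}_partition"):
                vals = {table[c] for c in group}
                if len(vals) > 1:
                    raise ValueError(
                        f"{pname} not constant within tied group {group}: {vals}"
                    )
    L = np.asarray(data["L"], dtype=float)
    K = np.asarray(data["K"], dtype=float)
    C = np.asarray(data["C"], dtype=float)
    if np.any(L <= 0):
        raise ValueError("all window lengths must be positive")
    eta = params.linear_predictor(
        list(data["class"]), np.log(L), np.log(K + coverage_offset)
    )
    if not np.all(np.isfinite(eta)):
        bad = int(np.flatnonzero(~np.isfinite(eta))[0])
        raise ValueError(f"non-finite linear predictor at window index {bad}")
    lam = np.exp(eta)
    return float(np.sum(C * eta - lam - gammaln(C + 1)))


class ChromatinCountModel:
    """Grouped Poisson regression of per-window feature counts.

    Parameters
    ----------
    counts, lengths, coverages : array-like
        Per-window feature count C, window length L (bp, > 0) and feature
        coverage K (bp, >= 0).
    chromatin_classes : sequence of str
        Per-window chromatin class label.
    feature : str, optional
        Name of the molecular feature being modelled (for reports).
    coverage_offset : float
        Offset a in log(K + a); default 1.0.

    Examples
    --------
    >>> model = ChromatinCountModel.from_frame(window_table, feature="rna_te")
    >>> res = model.fit(ModelConfig.from_merges([["EU", "PEU"]], model.classes))
    >>> sel = model.select_max_model()
    >>> sel.best.config.label()
    """

    def __init__(
        self,
        counts,
        lengths,
        coverages,
        chromatin_classes,
        feature: str = "feature",
        coverage_offset: float = 1.0,
    ) -> None:
        self.endog = np.asarray(counts, dtype=float)
        L = np.asarray(lengths, dtype=float)
        K = np.asarray(coverages, dtype=float)
        if np.any(L <= 0):
            raise ValueError("window lengths must be positive")
        if np.any(K < 0):
            raise ValueError("coverages must be nonnegative")
        if np.any(self.endog < 0) or np.any(self.endog != np.round(self.endog)):
            raise ValueError("counts must be nonnegative integers")
        self.log_length = np.log(L)
        self.log_coverage = np.log(K + coverage_offset)
        self.class_labels = np.asarray(list(chromatin_classes), dtype=object)
        if not (
            len(self.endog)
            == len(self.log_length)
            == len(self.log_coverage)
            == len(self.class_labels)
        ):
            raise ValueError("all inputs must have equal length")
        self.feature = feature
        self.coverage_offset = coverage_offset
        order = {c: i for i, c in enumerate(CHROMATIN_CLASSES)}
        present = sorted(
            set(self.class_labels), key=lambda c: (order.get(c, len(order)), c)
        )
        self.classes: tuple[str, ...] = tuple(present)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        feature: str | None = None,
        coverage_offset: float = 1.0,
    ) -> "ChromatinCountModel":
        """Build from a window feature table (columns class, feature, C, K, L).

        If the table holds several features, ``feature`` selects one.
        """
        if feature is not None and "feature" in df.columns:
            df = df[df["feature"] == feature]
            if df.empty:
                raise ValueError(f"no rows for feature {feature!r}")
        return cls(
            df["C"], df["L"], df["K"], df["class"],
            feature=feature or "feature", coverage_offset=coverage_offset,
        )

    @classmethod
    def from_records(
        cls,
        records: Sequence[WindowFeatureRecord],
        feature: str,
        coverage_offset: float = 1.0,
    ) -> "ChromatinCountModel":
        return cls.from_frame(
            records_to_frame(records), feature=feature, coverage_offset=coverage_offset
        )

    @property
    def nobs(self) -> int:
        return len(self.endog)

    # -- design and likelihood ---------------------------------------------

    def design_matrix(self, config: ModelConfig) -> tuple[np.ndarray, list[str]]:
        """Stack group indicator, indicator*logL and indicator*logK columns."""
        cols: list[np.ndarray] = []
        names: list[str] = []
        covariates = {
            "mu": np.ones(self.nobs),
            "beta": self.log_length,
            "zeta": self.log_coverage,
        }
        for pname, cov in covariates.items():
            for group in getattr(config, f"{pname}_partition"):
                mask = np.isin(self.class_labels, group).astype(float)
                if pname == "mu" and mask.sum() == 0:
                    raise ValueError(
                        f"empty parameter group {group}: no windows of these classes"
                    )
                cols.append(mask * cov)
                names.append(f"{pname}[{'='.join(group)}]")
        return np.column_stack(cols), names

    def loglike(self, flat_params: np.ndarray, X: np.ndarray) -> float:
        eta = X @ flat_params
        lam = np.exp(np.minimum(eta, 700.0))
        return float(np.sum(self.endog * eta - lam - gammaln(self.endog + 1)))

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        config: ModelConfig | None = None,
        tol: float = 1e-9,
        max_iter: int = 200,
    ) -> "PartitionPoissonResults":
        """Maximum-likelihood fit of one tying configuration by Newton
        iteration with step halving.

        Collinear design columns (e.g. a group whose windows share a single
        length, making its beta column a multiple of its intercept column)
        are detected by pivoted QR and dropped; the fit is then of the
        reduced model, flagged via ``reduced``, and the parameter count p
        reflects only the identified columns.
        """
        for cls_label in set(self.class_labels):
            if config is not None and cls_label not in config.classes:
                raise ValueError(f"class {cls_label!r} missing from configuration")
        if config is None:
            config = ModelConfig.all_distinct(self.classes)
        X_full, names_full = self.design_matrix(config)

        # identifiability: pivoted QR rank detection
        q, r, piv = linalg.qr(X_full, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        rank = int(np.sum(diag > diag[0] * max(X_full.shape) * np.finfo(float).eps))
        keep = np.sort(piv[:rank])
        reduced = rank < X_full.shape[1]
        X = X_full[:, keep]
        names = [names_full[i] for i in keep]

        beta_hat = np.zeros(X.shape[1])
        # start intercept-like columns at the log mean count
        mean_c = max(self.endog.mean(), 1e-3)
        for j, name in enumerate(names):
            if name.startswith("mu["):
                beta_hat[j] = math.log(mean_c)

        ll = self.loglike(beta_hat, X)
        converged = False
        for _ in range(max_iter):
            eta = X @ beta_hat
            lam = np.exp(np.minimum(eta, 700.0))
            grad = X.T @ (self.endog - lam)
            if np.max(np.abs(grad)) < tol * max(1.0, abs(ll)):
                converged = True
                break
            H = (X * lam[:, None]).T @ X
            try:
                with warnings.catch_warnings():
                    # near-collinear groups are expected and handled; the QR
                    # reduction above removed the exactly dependent columns
                    warnings.simplefilter("ignore", linalg.LinAlgWarning)
                    step = linalg.solve(H, grad, assume_a="pos")
            except linalg.LinAlgError:
                step = linalg.lstsq(H, grad)[0]
            # step halving keeps the ascent monotone
            scale = 1.0
            for _ in range(60):
                candidate = beta_hat + scale * step
                ll_new = self.loglike(candidate, X)
                if ll_new >= ll - 1e-13:
                    break
                scale *= 0.5
            else:
                break
            if abs(ll_new - ll) < 1e-13 * max(1.0, abs(ll)) and np.max(
                np.abs(grad)
            ) < 1e-5 * max(1.0, abs(ll)):
                beta_hat, ll = candidate, ll_new
                converged = True
                break
            beta_hat, ll = candidate, ll_new
        if not converged:
            eta = X @ beta_hat
            lam = np.exp(np.minimum(eta, 700.0))
            grad = X.T @ (self.endog - lam)
            if np.max(np.abs(grad)) < 1e-6 * max(1.0, abs(ll)):
                converged = True  # gradient small enough in absolute terms
        if not converged:
            raise ConvergenceError(
                f"Newton iteration did not converge for {config.label()}: "
                f"|grad|_inf = {np.max(np.abs(grad)):.3g}, loglik = {ll:.6g}"
            )

        eta = X @ beta_hat
        lam = np.exp(np.minimum(eta, 700.0))
        H = (X * lam[:, None]).T @ X
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", linalg.LinAlgWarning)
                cov = linalg.inv(H)
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except linalg.LinAlgError:
            cov = np.full((X.shape[1], X.shape[1]), np.nan)
            bse = np.full(X.shape[1], np.nan)

        return PartitionPoissonResults(
            model=self,
            config=config,
            param_names=names,
            params=beta_hat,
            bse=bse,
            cov_params=cov,
            llf=ll,
            nobs=self.nobs,
            df_model=rank,
            reduced=reduced,
            dropped=[names_full[i] for i in piv[rank:]],
        )

    # -- model selection ----------------------------------------------------

    def fit_all(self, mode: str = "joint") -> "ModelSelectionResults":
        """Exhaustively fit every configuration of the model space."""
        fits = [self.fit(cfg) for cfg in enumerate_model_space(self.classes, mode)]
        return ModelSelectionResults(self, _rank(fits), strategy="exhaustive")

    def select_max_model(
        self,
        mode: str = "joint",
        strategy: str = "exhaustive",
        seed: int | None = None,
        iterations: int = 1_000_000,
        t0: float = 5.0,
        cooling: float = 0.999,
    ) -> "ModelSelectionResults":
        """Find the MAX model (best bic_score) for this feature.

        ``exhaustive`` fits every configuration (the default in joint mode,
        where five classes give 52 fits). ``anneal`` runs a seeded simulated
        annealing walk over configurations: each proposal moves one class to
        another (or a new) group, parameters are refit exactly at every
        visited configuration, and acceptance follows a Metropolis rule under
        a geometric temperature schedule T_{t+1} = cooling * T_t.
        """
        if strategy == "exhaustive":
            return self.fit_all(mode)
        if strategy != "anneal":
            raise ValueError(f"unknown strategy {strategy!r}")
        if seed is None:
            raise ValueError("annealing requires an explicit seed (reproducibility)")
        rng = np.random.default_rng(seed)
        cache: dict[str, PartitionPoissonResults] = {}

        def fitted(cfg: ModelConfig) -> PartitionPoissonResults:
            key = cfg.label()
            if key not in cache:
                cache[key] = self.fit(cfg)
            return cache[key]

        current = ModelConfig.all_distinct(self.classes)
        cur_fit = fitted(current)
        best_fit = cur_fit
        temp = t0
        trace: list[tuple[int, str, float]] = [(0, current.label(), cur_fit.bic_score)]
        for it in range(1, iterations + 1):
            proposal = _propose(current, mode, rng)
            prop_fit = fitted(proposal)
            delta = prop_fit.bic_score - cur_fit.bic_score
            if delta >= 0 or rng.random() < math.exp(delta / max(temp, 1e-12)):
                current, cur_fit = proposal, prop_fit
                trace.append((it, current.label(), cur_fit.bic_score))
                if (cur_fit.bic_score, -cur_fit.df_model) > (
                    best_fit.bic_score,
                    -best_fit.df_model,
                ):
                    best_fit = cur_fit
            temp *= cooling
        return ModelSelectionResults(
            self, _rank(list(cache.values())), strategy="anneal", trace=trace
        )


def _propose(config: ModelConfig, mode: str, rng: np.random.Generator) -> ModelConfig:
    """Move one random class to another existing or a new group."""
    classes = config.classes
    pname = "mu" if mode == "joint" else ("mu", "beta", "zeta")[rng.integers(3)]
    partition = [list(g) for g in getattr(config, f"{pname}_partition")]
    ci = int(rng.integers(len(classes)))
    cls_label = classes[ci]
    src = next(i for i, g in enumerate(partition) if cls_label in g)
    targets = [i for i in range(len(partition)) if i != src]
    if len(partition[src]) > 1:
        targets.append(len(partition))  # split off into a new group
    if not targets:
        return config
    dst = targets[int(rng.integers(len(targets)))]
    partition[src].remove(cls_label)
    if dst == len(partition):
        partition.append([cls_label])
    else:
        partition[dst].append(cls_label)
    partition = [g for g in partition if g]
    if mode == "joint":
        return ModelConfig.joint(partition, classes)
    parts = {
        p: [list(g) for g in getattr(config, f"{p}_partition")]
        for p in ("mu", "beta", "zeta")
    }
    parts[pname] = partition
    return ModelConfig.independent(parts["mu"], parts["beta"], parts["zeta"], classes)


def _rank(fits: list["PartitionPoissonResults"]) -> list["PartitionPoissonResults"]:
    return sorted(fits, key=lambda f: (-f.bic_score, f.df_model, f.config.label()))


@dataclass
class PartitionPoissonResults:
    """MLE fit of one tying configuration.

    ``bic_score`` is 2*llf - p*ln(N); larger is better. ``reduced`` flags a
    fit where collinear design columns were dropped (``dropped`` lists them);
    p (``df_model``) counts only the identified parameters.
    """

    model: ChromatinCountModel
    config: ModelConfig
    param_names: list[str]
    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    llf: float
    nobs: int
    df_model: int
    reduced: bool = False
    dropped: list[str] = field(default_factory=list)

    @property
    def bic_score(self) -> float:
        return 2.0 * self.llf - self.df_model * math.log(self.nobs)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return np.column_stack(
            [self.params - z * self.bse, self.params + z * self.bse]
        )

    def parameter_set(self) -> ParameterSet:
        """Broadcast fitted group values to per-class parameters.

        Dropped (unidentified) columns broadcast as 0, matching the reduced
        model actually fitted.
        """
        values = dict(zip(self.param_names, self.params))
        out: dict[str, dict[str, float]] = {"mu": {}, "beta": {}, "zeta": {}}
        for pname in out:
            for group in getattr(self.config, f"{pname}_partition"):
                v = values.get(f"{pname}[{'='.join(group)}]", 0.0)
                for c in group:
                    out[pname][c] = float(v)
        return ParameterSet(**out)

    def compare(self, other: "PartitionPoissonResults") -> ModelComparison:
        return compare_fits(self, other)

    def summary(self) -> str:
        lines = [
            f"Poisson partition model — feature: {self.model.feature}",
            f"configuration: {self.config.label()}",
            f"N = {self.nobs}   p = {self.df_model}   "
            f"loglik = {self.llf:.4f}   BIC score = {self.bic_score:.4f}",
        ]
        if self.reduced:
            lines.append(f"note: reduced fit; dropped columns: {self.dropped}")
        lines.append(f"{'parameter':<22}{'coef':>12}{'std err':>12}{'[0.025':>12}{'0.975]':>12}")
        ci = self.conf_int()
        for i, name in enumerate(self.param_names):
            lines.append(
                f"{name:<22}{self.params[i]:>12.4f}{self.bse[i]:>12.4f}"
                f"{ci[i, 0]:>12.4f}{ci[i, 1]:>12.4f}"
            )
        return "\n".join(lines)


def compare_fits(
    a: PartitionPoissonResults, b: PartitionPoissonResults
) -> ModelComparison:
    """BIC-score comparison of two fits of the same data."""
    if a.nobs != b.nobs:
        raise ValueError(f"fits are on different data (N = {a.nobs} vs {b.nobs})")
    return ModelComparison(
        a.config.label(), b.config.label(), a.bic_score, b.bic_score
    )


@dataclass
class ModelSelectionResults:
    """Ranked fits of a model-space search; ``best`` is the MAX model."""

    model: ChromatinCountModel
    fits: list[PartitionPoissonResults]
    strategy: str
    trace: list[tuple[int, str, float]] | None = None

    @property
    def best(self) -> PartitionPoissonResults:
        return self.fits[0]

    def to_frame(self) -> pd.DataFrame:
        best = self.best
        rows = []
        for f in self.fits:
            delta = best.bic_score - f.bic_score
            rows.append(
                {
                    "model": f.config.label(),
                    "loglik": f.llf,
                    "p": f.df_model,
                    "N": f.nobs,
                    "bic_score": f.bic_score,
                    "delta_bic": delta,
                    "bayes_factor_vs_best": math.exp(min(0.5 * delta, 700.0)),
                    "support": support_label(delta),
                    "reduced": f.reduced,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "feature": self.model.feature,
            "strategy": self.strategy,
            "n_models": len(self.fits),
            "max_model": self.best.config.label(),
            "models": self.to_frame().to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def summary(self, top: int = 10) -> str:
        df = self.to_frame().head(top)
        lines = [
            f"Model selection — feature: {self.model.feature} "
            f"({self.strategy}, {len(self.fits)} models, N = {self.best.nobs})",
            f"MAX model: {self.best.config.label()} "
            f"(BIC score {self.best.bic_score:.2f})",
            df.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)
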