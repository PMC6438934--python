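"""Gibbs sampler for the normal hierarchical growth model on sqrt-EFW.

Model
-----
For fetus-visit j of pregnancy i at gestational week w_ij, with outcome
y_ij = sqrt(EFW_ij) in sqrt-grams:

    y_ij = (beta0 + u_{0i}) + (beta1 + u_{1i}) w_ij + eps_ij
    (u_{0i}, u_{1i}) ~ N(0, Sigma_u),      eps_ij ~ N(0, sigma2_e)

with conjugate priors

    beta     ~ N(m0, V0)                    (default m0 = 0, V0 = diag(1000, 1000))
    Sigma_u  ~ InvWishart(nu0, S0)          (default nu0 = 2, S0 = diag(0.02, 20))
    sigma2_e ~ InvGamma(a0, b0)             (default a0 = b0 = 0.01)

Both co-twins share the pregnancy-level random effect ("patient" is the
grouping unit).  The sampler cycles the full conditionals in the fixed
order beta -> {u_i} -> Sigma_u -> sigma2_e, discards ``burn_in``
iterations, then keeps every ``thin``-th draw until ``n_keep`` draws are
retained.  All randomness flows from one counter-based Philox stream, so
a seed fixes the retained draws bit-for-bit.

Inverse-Wishart convention: Sigma ~ IW(nu, S) means Sigma^{-1} ~
Wishart(nu, S^{-1}) with E[Sigma] = S / (nu - p - 1) for nu > p + 1
(p = 2 here).  This is the convention scipy.stats.invwishart uses and is
verified against it in the test suite.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .cohort import ExamRecord, Pregnancy

DEFAULT_WEEK_GRID: tuple[int, ...] = tuple(range(16, 38))

PARAM_NAMES = ("beta0", "beta1", "Sigma_u_00", "Sigma_u_01", "Sigma_u_11", "sigma2_e")


@dataclass
class ModelConfig:
    """Priors and chain schedule for :func:`fit_gibbs`."""

    prior_beta_mean: tuple[float, float] = (0.0, 0.0)
    prior_beta_var: tuple[float, float] = (1000.0, 1000.0)
    iw_df: float = 2.0
    iw_scale: tuple[float, float] = (0.02, 20.0)
    ig_shape: float = 0.01
    ig_scale: float = 0.01
    n_keep: int = 5000
    thin: int = 5
    burn_in: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_keep", "thin", "burn_in"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if min(self.prior_beta_var) <= 0 or min(self.iw_scale) <= 0:
            raise ValueError("prior scale parameters must be positive definite")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws of the population-level parameters."""

    beta: np.ndarray  # (k, 2)
    Sigma_u: np.ndarray  # (k, 2, 2)
    sigma2_e: np.ndarray  # (k,)
    meta: dict = field(default_factory=dict)
    group_effects: np.ndarray | None = None  # (k, G, 2) if retained

    def __post_init__(self) -> None:
        k = len(self.sigma2_e)
        if self.beta.shape != (k, 2) or self.Sigma_u.shape != (k, 2, 2):
            raise ValueError("inconsistent draw shapes")
        if np.any(self.sigma2_e < 0):
            raise ValueError("sigma2_e draws must be non-negative")

    @property
    def n_draws(self) -> int:
        return len(self.sigma2_e)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta0": self.beta[:, 0],
                "beta1": self.beta[:, 1],
                "Sigma_u_00": self.Sigma_u[:, 0, 0],
                "Sigma_u_01": self.Sigma_u[:, 0, 1],
                "Sigma_u_11": self.Sigma_u[:, 1, 1],
                "sigma2_e": self.sigma2_e,
            }
        )

    def save(self, csv_path: str | Path, meta_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if meta_path is not None:
            Path(meta_path).write_text(json.dumps(self.meta, indent=2, default=str))

    @classmethod
    def load(cls, csv_path: str | Path, meta_path: str | Path | None = None) -> "PosteriorDraws":
        df = pd.read_csv(csv_path)
        k = len(df)
        Sigma = np.empty((k, 2, 2))
        Sigma[:, 0, 0] = df["Sigma_u_00"]
        Sigma[:, 0, 1] = Sigma[:, 1, 0] = df["Sigma_u_01"]
        Sigma[:, 1, 1] = df["Sigma_u_11"]
        meta = {}
        if meta_path is not None and Path(meta_path).exists():
            meta = json.loads(Path(meta_path).read_text())
        return cls(
            beta=df[["beta0", "beta1"]].to_numpy(),
            Sigma_u=Sigma,
            sigma2_e=df["sigma2_e"].to_numpy(),
            meta=meta,
        )


# ---------------------------------------------------------------------------
# small linear-algebra helpers (batched 2x2)


def _inv2(M: np.ndarray) -> np.ndarray:
    det = M[..., 0, 0] * M[..., 1, 1] - M[..., 0, 1] * M[..., 1, 0]
    out = np.empty_like(M)
    out[..., 0, 0] = M[..., 1, 1]
    out[..., 1, 1] = M[..., 0, 0]
    out[..., 0, 1] = -M[..., 0, 1]
    out[..., 1, 0] = -M[..., 1, 0]
    return out / det[..., None, None]


def _chol2(M: np.ndarray) -> np.ndarray:
    l11 = np.sqrt(M[..., 0, 0])
    l21 = M[..., 1, 0] / l11
    l22 = np.sqrt(np.maximum(M[..., 1, 1] - l21**2, 0.0))
    L = np.zeros_like(M)
    L[..., 0, 0] = l11
    L[..., 1, 0] = l21
    L[..., 1, 1] = l22
    return L


def sample_invwishart(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """Draw Sigma ~ InvWishart(df, scale), p = 2, via a Bartlett factor.

    Convention: E[Sigma] = scale / (df - p - 1) for df > p + 1.
    """
    p = scale.shape[0]
    if df < p:
        raise ValueError(f"inverse-Wishart df must be >= dimension {p}")
    L = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((p, p))
    for i in range(p):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    W = L @ A @ A.T @ L.T  # Wishart(df, scale^{-1})
    return np.linalg.inv(W)


# ---------------------------------------------------------------------------
# estimator


class RandomSlopeGibbs(RegressorMixin, BaseEstimator):
    """Bayesian random-intercept/random-slope regression fit by Gibbs sampling.

    scikit-learn-style estimator: ``X`` is the gestational week (a single
    feature column), ``y`` the sqrt-scale outcome, and ``groups`` (passed
    to :meth:`fit`) the pregnancy identifier shared by co-twins.

    Parameters mirror :class:`ModelConfig`; ``random_effects=False`` pins
    every u_i at zero (the conjugate fixed-effects special case) and
    ``fixed_sigma2_e`` freezes the residual variance, which together make
    the posterior of beta available in closed form — used as the analytic
    oracle in tests.

    Attributes (after fit)
    ----------------------
    draws_ : PosteriorDraws
    beta_draws_, Sigma_u_draws_, sigma2_e_draws_ : views into ``draws_``
    n_obs_, n_groups_ : data dimensions
    """

    def __init__(
        self,
        prior_beta_mean: tuple[float, float] = (0.0, 0.0),
        prior_beta_var: tuple[float, float] = (1000.0, 1000.0),
        iw_df: float = 2.0,
        iw_scale: tuple[float, float] = (0.02, 20.0),
        ig_shape: float = 0.01,
        ig_scale: float = 0.01,
        n_keep: int = 5000,
        thin: int = 5,
        burn_in: int = 1000,
        random_effects: bool = True,
        fixed_sigma2_e: float | None = None,
        keep_group_effects: bool = False,
        seed: int = 0,
    ):
        self.prior_beta_mean = prior_beta_mean
        self.prior_beta_var = prior_beta_var
        self.iw_df = iw_df
        self.iw_scale = iw_scale
        self.ig_shape = ig_shape
        self.ig_scale = ig_scale
        self.n_keep = n_keep
        self.thin = thin
        self.burn_in = burn_in
        self.random_effects = random_effects
        self.fixed_sigma2_e = fixed_sigma2_e
        self.keep_group_effects = keep_group_effects
        self.seed = seed

    # -- data preparation ---------------------------------------------------

    @staticmethod
    def _factorize(groups: Sequence) -> tuple[np.ndarray, list]:
        """Group index by order of first appearance (relabel-invariant)."""
        index: dict = {}
        g = np.empty(len(groups), dtype=np.int64)
        labels: list = []
        for i, lab in enumerate(groups):
            if lab not in index:
                index[lab] = len(labels)
                labels.append(lab)
            g[i] = index[lab]
        return g, labels

    def fit(self, X, y, groups=None) -> "RandomSlopeGibbs":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("X must be a single column of gestational weeks")
        y = np.asarray(y, dtype=float)
        n = len(y)
        if n == 0:
            raise ValueError("empty data")
        if X.shape[0] != n:
            raise ValueError("X and y length mismatch")
        if groups is None:
            raise ValueError("groups (pregnancy ids) are required")
        g, labels = self._factorize(list(groups))
        G = len(labels)
        if self.random_effects and G < 2:
            raise ValueError("need at least 2 pregnancies to fit random effects")
        counts = np.bincount(g, minlength=G)
        n_weeks_per_group = [
            len(np.unique(X[g == i, 0])) for i in range(G)
        ]
        if self.random_effects and max(n_weeks_per_group) < 2:
            warnings.warn(
                "no within-pregnancy replication across weeks: random slopes weakly identified",
                stacklevel=2,
            )

        cfg = ModelConfig(
            prior_beta_mean=tuple(self.prior_beta_mean),
            prior_beta_var=tuple(self.prior_beta_var),
            iw_df=self.iw_df,
            iw_scale=tuple(self.iw_scale),
            ig_shape=self.ig_shape,
            ig_scale=self.ig_scale,
            n_keep=self.n_keep,
            thin=self.thin,
            burn_in=self.burn_in,
            seed=self.seed,
        )
        draws = self._run_chain(X[:, 0], y, g, G, cfg)
        draws.meta.update(
            {
                "n_obs": int(n),
                "n_groups": int(G),
                "seed": int(self.seed),
                "config": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in vars(cfg).items()
                },
                "data_hash": hashlib.sha256(
                    np.ascontiguousarray(np.column_stack([X[:, 0], y, g])).tobytes()
                ).hexdigest(),
            }
        )
        self.draws_ = draws
        self.beta_draws_ = draws.beta
        self.Sigma_u_draws_ = draws.Sigma_u
        self.sigma2_e_draws_ = draws.sigma2_e
        self.n_obs_ = n
        self.n_groups_ = G
        self.group_labels_ = labels
        return self

    def _run_chain(
        self, w: np.ndarray, y: np.ndarray, g: np.ndarray, G: int, cfg: ModelConfig
    ) -> PosteriorDraws:
        rng = np.random.Generator(np.random.Philox(cfg.seed))
        n = len(y)
        X = np.column_stack([np.ones(n), w])
        XtX_g = np.zeros((G, 2, 2))
        Xty_g = np.zeros((G, 2))
        np.add.at(XtX_g, g, np.einsum("ni,nj->nij", X, X))
        np.add.at(Xty_g, g, X * y[:, None])
        XtX = XtX_g.sum(axis=0)
        Xty = Xty_g.sum(axis=0)

        m0 = np.asarray(cfg.prior_beta_mean, dtype=float)
        V0inv = np.diag(1.0 / np.asarray(cfg.prior_beta_var, dtype=float))
        S0 = np.diag(cfg.iw_scale)
        a0, b0 = cfg.ig_shape, cfg.ig_scale

        beta = np.zeros(2)
        u = np.zeros((G, 2))
        Sigma = np.eye(2)
        s2 = self.fixed_sigma2_e if self.fixed_sigma2_e is not None else 1.0

        k = 0
        total = cfg.burn_in + cfg.thin * cfg.n_keep
        beta_d = np.empty((cfg.n_keep, 2))
        Sigma_d = np.zeros((cfg.n_keep, 2, 2))
        s2_d = np.empty(cfg.n_keep)
        u_d = (
            np.empty((cfg.n_keep, G, 2)) if self.keep_group_effects else None
        )

        for it in range(total):
            # beta | rest
            ystar = y - u[g, 0] - u[g, 1] * w
            prec = V0inv + XtX / s2
            cov = _inv2(prec)
            mean = cov @ (V0inv @ m0 + X.T @ ystar / s2)
            beta = mean + _chol2(cov) @ rng.standard_normal(2)

            if self.random_effects:
                # u_i | rest
                Sinv = np.linalg.inv(Sigma)
                Ai = Sinv[None, :, :] + XtX_g / s2
                bi = (Xty_g - XtX_g @ beta) / s2
                Ci = _inv2(Ai)
                mi = np.einsum("gij,gj->gi", Ci, bi)
                u = mi + np.einsum("gij,gj->gi", _chol2(Ci), rng.standard_normal((G, 2)))
                # Sigma_u | u
                Sigma = sample_invwishart(rng, cfg.iw_df + G, S0 + u.T @ u)

            if self.fixed_sigma2_e is None:
                r = y - (beta[0] + u[g, 0]) - (beta[1] + u[g, 1]) * w
                s2 = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + 0.5 * np.dot(r, r)))

            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and k < cfg.n_keep:
                beta_d[k] = beta
                Sigma_d[k] = Sigma if self.random_effects else 0.0
                s2_d[k] = s2
                if u_d is not None:
                    u_d[k] = u
                k += 1

        return PosteriorDraws(
            beta=beta_d, Sigma_u=Sigma_d, sigma2_e=s2_d, group_effects=u_d
        )

    # -- prediction ---------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Posterior-mean population sqrt-EFW at the given weeks."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        bbar = self.beta_draws_.mean(axis=0)
        return bbar[0] + bbar[1] * X[:, 0]

    def sample_predictive(self, week: float, rng: np.random.Generator | None = None,
                          seed: int | None = None) -> np.ndarray:
        """One sqrt-scale predictive draw per retained posterior draw."""
        self._check_fitted()
        return posterior_predictive(
            self.draws_, week, rng=rng, seed=seed, grid=None
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "draws_"):
            raise AttributeError("estimator is not fitted; call fit() first")


# ---------------------------------------------------------------------------
# functional wrappers


def exam_design(
    exams: Iterable[ExamRecord],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(weeks, sqrt-EFW outcome, pregnancy ids) from exam records."""
    exams = list(exams)
    w = np.array([e.ga_weeks for e in exams], dtype=float)
    y = np.sqrt(np.array([e.efw_g for e in exams], dtype=float))
    ids = [e.pregnancy_id for e in exams]
    return w, y, ids


def fit_gibbs(
    exams: Iterable[ExamRecord],
    pregnancies: Iterable[Pregnancy] | None = None,
    config: ModelConfig | None = None,
    **estimator_kwargs,
) -> PosteriorDraws:
    """Fit the hierarchical model to exam records; outcome is sqrt(EFW).

    ``pregnancies``, when given, restricts the exams to those pregnancy
    ids (the post-eligibility analysis set).
    """
    config = config or ModelConfig()
    exams = list(exams)
    if pregnancies is not None:
        keep = {p.pregnancy_id for p in pregnancies}
        exams = [e for e in exams if e.pregnancy_id in keep]
    if not exams:
        raise ValueError("no exam records to fit")
    w, y, ids = exam_design(exams)
    est = RandomSlopeGibbs(
        prior_beta_mean=config.prior_beta_mean,
        prior_beta_var=config.prior_beta_var,
        iw_df=config.iw_df,
        iw_scale=config.iw_scale,
        ig_shape=config.ig_shape,
        ig_scale=config.ig_scale,
        n_keep=config.n_keep,
        thin=config.thin,
        burn_in=config.burn_in,
        seed=config.seed,
        **estimator_kwargs,
    )
    est.fit(w[:, None], y, groups=ids)
    return est.draws_


def posterior_predictive(
    draws: PosteriorDraws,
    week: float,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    grid: Sequence[float] | None = DEFAULT_WEEK_GRID,
    extrapolate: bool = False,
) -> np.ndarray:
    """Sqrt-scale predictive sample for a *new* pregnancy at ``week``.

    Per retained draw: sample (u0*, u1*) ~ N(0, Sigma_u draw) and
    eps ~ N(0, sigma2_e draw), return (beta0+u0*) + (beta1+u1*)*week + eps.
    The sample size equals the number of retained draws.
    """
    if grid is not None and week not in grid and not extrapolate:
        raise ValueError(
            f"week {week} outside the reference grid; pass extrapolate=True to override"
        )
    if rng is None:
        rng = np.random.Generator(np.random.Philox(seed if seed is not None else 0))
    k = draws.n_draws
    L = _chol2(draws.Sigma_u + 1e-300)
    u = np.einsum("kij,kj->ki", L, rng.standard_normal((k, 2)))
    eps = rng.standard_normal(k) * np.sqrt(draws.sigma2_e)
    return (draws.beta[:, 0] + u[:, 0]) + (draws.beta[:, 1] + u[:, 1]) * week + eps


def predictive_table_samples(
    draws: PosteriorDraws,
    weeks: Sequence[int] = DEFAULT_WEEK_GRID,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Predictive samples for each grid week from one root seed."""
    rng = np.random.Generator(np.random.Philox(seed))
    return {int(w): posterior_predictive(draws, w, rng=rng, grid=None) for w in weeks}


# ---------------------------------------------------------------------------
# diagnostics


def _ess(x: np.ndarray) -> float:
    import arviz as az

    return float(az.ess(np.asarray(x)[None, :]))


def diagnostics(draws: PosteriorDraws, flag_threshold: float = 3.0) -> pd.DataFrame:
    """Per-parameter effective sample size and Geweke z statistic.

    Geweke compares the first 10% of the retained chain with the last 50%;
    segment means are contrasted with a standard error built from the
    segment variances scaled by their effective sample sizes.  Constant
    (degenerate) chains are reported as such, with ESS undefined.
    """
    if draws.n_draws < 100:
        raise ValueError("need at least 100 retained draws for diagnostics")
    frame = draws.to_frame()
    rows = []
    for name in PARAM_NAMES:
        x = frame[name].to_numpy()
        if np.ptp(x) == 0.0:
            rows.append(
                {"parameter": name, "ess": np.nan, "geweke_z": np.nan,
                 "degenerate": True, "flagged": False}
            )
            continue
        k = len(x)
        a, b = x[: max(k // 10, 2)], x[k // 2:]
        ess_a, ess_b = max(_ess(a), 1.0), max(_ess(b), 1.0)
        se = np.sqrt(a.var(ddof=1) / ess_a + b.var(ddof=1) / ess_b)
        z = (a.mean() - b.mean()) / se if se > 0 else np.nan
        rows.append(
            {
                "parameter": name,
                "ess": _ess(x),
                "geweke_z": z,
                "degenerate": False,
                "flagged": bool(abs(z) > flag_threshold),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def conjugate_beta_posterior(
    w: np.ndarray,
    y: np.ndarray,
    sigma2_e: float,
    prior_mean: Sequence[float] = (0.0, 0.0),
    prior_var: Sequence[float] = (1000.0, 1000.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form N(mean, cov) posterior of beta with known sigma2_e and
    no random effects — the analytic oracle for the sampler's special case."""
    X = np.column_stack([np.ones_like(w), w])
    V0inv = np.diag(1.0 / np.asarray(prior_var, dtype=float))
    prec = V0inv + X.T @ X / sigma2_e
    cov = np.linalg.inv(prec)
    mean = cov @ (V0inv @ np.asarray(prior_mean, dtype=float) + X.T @ y / sigma2_e)
    return mean, cov
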