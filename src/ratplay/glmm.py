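"""Binary mixed-effects logistic models of partner preference.

Two models ask what distinguishes strongly preferred partners (preference
index >= 2, outcome 1) from avoided partners (index <= 0.25, outcome 0)
across classified dyad-days:

* model 1 — play style and quality: the partner's play output toward the
  focal animal and the percentages of its responses (no response, evasion,
  pin) and role reversals;
* model 2 — dyadic asymmetries: play symmetry, time in proximity, and
  weight and dominance-rank differences, with crossed random intercepts for
  initiator and recipient identity.

Estimation maximises the Laplace-approximated marginal likelihood of a
logistic model with Gaussian random intercepts (one or more crossed
grouping factors).  The inner mode-finding is a damped Newton iteration on
the penalised log-likelihood; the outer optimisation runs L-BFGS-B over the
fixed effects and log standard deviations.  Wald standard errors come from
the numerically differentiated Hessian of the marginal log-likelihood, and
confidence intervals are ``estimate +/- 1.96 * SE`` on the log-odds scale
with odds ratios ``exp(estimate)``.  When every random-effect variance
estimates at the boundary (0) the model collapses to an ordinary logistic
regression, which is then reported with a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .events import AttackEvent, ValidationError

logger = logging.getLogger(__name__)

WALD_Z = 1.96
#: below this standard deviation a random effect counts as at the boundary
BOUNDARY_SD = 1e-2

MODEL1_PREDICTORS = ("partner_play_frequency", "pct_no_response",
                     "pct_evasion", "pct_pin", "pct_role_reversal")
MODEL2_PREDICTORS = ("symmetry", "proximity_s", "weight_diff",
                     "dominance_diff")


class SeparationError(RuntimeError):
    """Raised on (quasi-)complete separation: the maximum-likelihood
    estimates diverge, so Wald inference is meaningless.  Consider a
    penalized (e.g. Firth) fit outside this package."""


@dataclass
class GLMMFit:
    """Fitted model: one table row per fixed effect plus random-intercept
    variances per grouping factor."""

    table: pd.DataFrame
    random_variance: dict[str, float]
    n_rows: int
    converged: bool
    used_plain_logistic: bool
    log_likelihood: float
    predictors: tuple[str, ...]
    random: tuple[str, ...]

    def coef(self, term: str) -> pd.Series:
        return self.table.set_index("term").loc[term]


class _LaplaceLogit:
    """Laplace-approximated logistic regression with crossed Gaussian
    random intercepts."""

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 group_codes: Sequence[np.ndarray]):
        self.X = np.asarray(X, float)
        self.y = np.asarray(y, float)
        self.codes = [np.asarray(c) for c in group_codes]
        self.sizes = [int(c.max()) + 1 for c in self.codes]
        self.offsets = np.concatenate([[0], np.cumsum(self.sizes)])[:-1]
        self.m = int(sum(self.sizes))
        self._u = np.zeros(self.m)

    # -- random-effect linear algebra ------------------------------------
    def _zu(self, u: np.ndarray) -> np.ndarray:
        eta = np.zeros(len(self.y))
        for off, c in zip(self.offsets, self.codes):
            eta += u[off + c]
        return eta

    def _zt(self, v: np.ndarray) -> np.ndarray:
        out = np.empty(self.m)
        for off, size, c in zip(self.offsets, self.sizes, self.codes):
            out[off:off + size] = np.bincount(c, weights=v, minlength=size)
        return out

    def _ztwz(self, w: np.ndarray) -> np.ndarray:
        M = np.zeros((self.m, self.m))
        for oi, ci in zip(self.offsets, self.codes):
            for oj, cj in zip(self.offsets, self.codes):
                np.add.at(M, (oi + ci, oj + cj), w)
        return M

    def _dinv_diag(self, sigma2: np.ndarray) -> np.ndarray:
        return np.concatenate([np.full(s, 1.0 / v)
                               for s, v in zip(self.sizes, sigma2)])

    # -- likelihood ------------------------------------------------------
    def _inner_mode(self, beta: np.ndarray, sigma2: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
        """Newton iteration for the conditional mode of u."""
        dinv = self._dinv_diag(sigma2)
        xb = self.X @ beta
        u = self._u.copy()
        for _ in range(100):
            eta = xb + self._zu(u)
            mu = expit(eta)
            grad = self._zt(self.y - mu) - dinv * u
            if np.max(np.abs(grad)) < 1e-9:
                break
            w = np.clip(mu * (1 - mu), 1e-10, None)
            H = self._ztwz(w)
            H[np.diag_indices_from(H)] += dinv
            step = np.linalg.solve(H, grad)
            # damped update against overshoot
            f0 = self._penalized(u, xb, dinv)
            scale = 1.0
            for _ in range(20):
                u_new = u + scale * step
                if self._penalized(u_new, xb, dinv) >= f0 - 1e-12:
                    break
                scale *= 0.5
            u = u_new
        self._u = u
        eta = xb + self._zu(u)
        return u, eta

    def _penalized(self, u: np.ndarray, xb: np.ndarray,
                   dinv: np.ndarray) -> float:
        eta = xb + self._zu(u)
        return float(self.y @ eta - np.logaddexp(0.0, eta).sum()
                     - 0.5 * (dinv * u * u).sum())

    def nll(self, theta: np.ndarray) -> float:
        """Negative Laplace marginal log-likelihood at
        theta = (beta, log sigma per factor)."""
        p = self.X.shape[1]
        beta, log_sigma = theta[:p], theta[p:]
        sigma2 = np.exp(2.0 * log_sigma)
        u, eta = self._inner_mode(beta, sigma2)
        dinv = self._dinv_diag(sigma2)
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        H = self._ztwz(w)
        H[np.diag_indices_from(H)] += dinv
        sign, logdet_h = np.linalg.slogdet(H)
        if sign <= 0:
            return np.inf
        logdet_d = float(np.sum(
            [s * np.log(v) for s, v in zip(self.sizes, sigma2)]))
        ll = (self.y @ eta - np.logaddexp(0.0, eta).sum()
              - 0.5 * (dinv * u * u).sum()
              - 0.5 * logdet_d - 0.5 * logdet_h)
        return -float(ll)


def _plain_logit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Ordinary logistic fit via Newton-Raphson; returns (beta, ll)."""
    beta = np.zeros(X.shape[1])
    for _ in range(100):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < 1e-10:
            break
        w = np.clip(mu * (1 - mu), 1e-10, None)
        H = (X * w[:, None]).T @ X
        try:
            beta = beta + np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix in logistic fit") from exc
        if np.max(np.abs(beta)) > 1e3:
            raise SeparationError("diverging logistic estimates")
    eta = X @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    return beta, ll


def _numeric_hessian(fun, x: np.ndarray) -> np.ndarray:
    """Central-difference Hessian."""
    d = len(x)
    h = 1e-4 * (1.0 + np.abs(x))
    H = np.zeros((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h[i]
            ej = np.zeros(d); ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def fit_binary_glmm(rows: pd.DataFrame,
                    predictors: Sequence[str] = MODEL1_PREDICTORS,
                    outcome: str = "outcome",
                    random: str | Sequence[str] = "initiator_id",
                    force_zero_variance: bool = False) -> GLMMFit:
    """Fit a binary logistic mixed model with random intercepts.

    ``rows`` is a long table with one line per classified dyad-day;
    ``random`` names one or more grouping columns (crossed random
    intercepts).  Predictors enter untransformed, so odds ratios are
    per unit of each predictor.

    Raises :class:`SeparationError` on complete separation and
    :class:`ValidationError` when fewer than two outcome classes are
    present.
    """
    if isinstance(random, str):
        random = (random,)
    random = tuple(random)
    predictors = tuple(predictors)
    missing = [c for c in (*predictors, outcome, *random)
               if c not in rows.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    data = rows[[outcome, *predictors, *random]].dropna()
    y = data[outcome].to_numpy(dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValidationError(
            "outcome must contain both classes coded 0/1")
    X = np.column_stack([np.ones(len(data))]
                        + [data[c].to_numpy(dtype=float)
                           for c in predictors])
    terms = ("intercept", *predictors)

    # ordinary logistic start values; also the separation sentinel
    beta0, ll_plain = _plain_logit(X, y)
    if np.max(np.abs(beta0)) > 30:
        raise SeparationError(
            f"fitted log-odds exceed 30 (max |beta| = "
            f"{np.max(np.abs(beta0)):.1f}): complete separation likely")

    if force_zero_variance:
        return _finish_plain(X, y, terms, random, ll_plain, len(data),
                             predictors)

    p = X.shape[1]
    active = list(random)
    boundary: list[str] = []
    while active:
        codes = [pd.Categorical(data[r]).codes.astype(np.int64)
                 for r in active]
        model = _LaplaceLogit(X, y, codes)
        theta0 = np.concatenate([beta0, np.full(len(active), np.log(0.5))])
        bounds = ([(None, None)] * p
                  + [(np.log(1e-4), np.log(50.0))] * len(active))
        res = optimize.minimize(model.nll, theta0, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-10})
        theta = res.x
        sigma = np.exp(theta[p:])
        at_bound = sigma < BOUNDARY_SD
        if not at_bound.any():
            break
        # drop boundary factors (their likelihood direction is flat) and
        # refit with the remainder
        boundary.extend(r for r, b in zip(active, at_bound) if b)
        active = [r for r, b in zip(active, at_bound) if not b]
        logger.info("random-effect variance at boundary for %s; refitting",
                    boundary)

    if not active:
        logger.info("all random-effect variances at boundary; falling back "
                    "to plain logistic with cluster flag")
        return _finish_plain(X, y, terms, random, ll_plain, len(data),
                             predictors)

    hess = _numeric_hessian(model.nll, theta)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    se = np.sqrt(np.clip(np.diag(cov)[:p], 0.0, None))
    beta = theta[:p]
    if np.max(np.abs(beta)) > 30:
        raise SeparationError("diverging mixed-model estimates")
    table = _wald_table(terms, beta, se)
    variances = {r: 0.0 for r in boundary}
    variances.update({r: float(s ** 2) for r, s in zip(active, sigma)})
    return GLMMFit(table=table,
                   random_variance={r: variances[r] for r in random},
                   n_rows=len(data), converged=bool(res.success),
                   used_plain_logistic=False,
                   log_likelihood=-float(res.fun),
                   predictors=predictors, random=random)


def _finish_plain(X, y, terms, random, ll, n, predictors) -> GLMMFit:
    beta, _ = _plain_logit(X, y)
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    se = np.sqrt(np.diag(cov))
    return GLMMFit(table=_wald_table(terms, beta, se),
                   random_variance={r: 0.0 for r in random},
                   n_rows=n, converged=True, used_plain_logistic=True,
                   log_likelihood=ll, predictors=tuple(predictors),
                   random=tuple(random))


def _wald_table(terms, beta, se) -> pd.DataFrame:
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "term": list(terms),
        "estimate": beta,
        "se": se,
        "z": z,
        "p": p,
        "odds_ratio": np.exp(beta),
        "ci_low": beta - WALD_Z * se,
        "ci_high": beta + WALD_Z * se,
    })


def simulate_glmm_rows(n_rows: int = 200, n_groups: int = 20,
                       effect: float = 0.08, intercept: float = -2.4,
                       sigma: float = 1.0, seed: int | None = None,
                       predictor: str = "pct_role_reversal",
                       x_low: float = 0.0, x_high: float = 60.0
                       ) -> pd.DataFrame:
    """Rows from a known random-intercept logistic model, for calibration.

    Each of ``n_groups`` initiators contributes ``n_rows / n_groups`` rows;
    the predictor is uniform on ``[x_low, x_high]`` (a percentage scale by
    default) and the outcome follows
    ``logit P(y=1) = intercept + effect * x + u_initiator`` with
    ``u ~ N(0, sigma^2)``.  Used to verify that the fitter recovers planted
    effect signs and achieves nominal Wald coverage.
    """
    rng = np.random.default_rng(seed)
    per = n_rows // n_groups
    groups = np.repeat(np.arange(n_groups), per)
    if len(groups) < n_rows:
        groups = np.concatenate([groups,
                                 np.arange(n_rows - len(groups))])
    u = rng.normal(0.0, sigma, size=n_groups)
    x = rng.uniform(x_low, x_high, size=n_rows)
    eta = intercept + effect * x + u[groups]
    y = (rng.random(n_rows) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return pd.DataFrame({"outcome": y, predictor: x,
                         "initiator_id": [f"I{g}" for g in groups]})


# ---------------------------------------------------------------------------
# feature-table construction


def build_feature_table(events: Iterable[AttackEvent],
                        index_table: pd.DataFrame,
                        symmetry_df: pd.DataFrame,
                        proximity_df: pd.DataFrame,
                        weights: dict[tuple[int, str], float],
                        dominance: dict[tuple[int, str], int]
                        ) -> pd.DataFrame:
    """One row per classified (strong_preferred / avoided) dyad-day.

    ``index_table`` must already be restricted to non-excluded group-days.
    ``weights`` maps (group_id, animal_id) -> body weight in grams and
    ``dominance`` maps (group_id, animal_id) -> tube-test rank.  Dyads whose
    focal animal never attacked the partner that day have undefined tactic
    percentages; such rows are dropped with a log entry.
    """
    events = list(events)
    ev_df = pd.DataFrame([{
        "group_id": e.group_id, "day": e.day, "initiator": e.initiator,
        "recipient": e.recipient, "response": e.response,
        "role_reversal": e.role_reversal} for e in events])

    sym_lookup = {}
    for r in symmetry_df.to_dict("records"):
        key = (r["group_id"], r["day"],
               *sorted((r["animal_a"], r["animal_b"])))
        sym_lookup[key] = r["symmetry"]
    prox_lookup = {}
    for r in proximity_df.to_dict("records"):
        key = (r["group_id"], r["day"],
               *sorted((r["animal_a"], r["animal_b"])))
        prox_lookup[key] = r["proximity_s"]

    focal = index_table[index_table["classification"].isin(
        ["strong_preferred", "avoided"])]
    rows = []
    n_dropped = 0
    for rec in focal.to_dict("records"):
        g, d = rec["group_id"], rec["day"]
        i, j = rec["initiator"], rec["recipient"]
        received = ev_df[(ev_df["group_id"] == g) & (ev_df["day"] == d)
                         & (ev_df["initiator"] == i)
                         & (ev_df["recipient"] == j)]
        n_ij = len(received)
        if n_ij == 0:
            n_dropped += 1
            logger.info("dropping dyad %s->%s (group %s day %s): zero "
                        "attacks, tactic percentages undefined", i, j, g, d)
            continue
        back = ev_df[(ev_df["group_id"] == g) & (ev_df["day"] == d)
                     & (ev_df["initiator"] == j) & (ev_df["recipient"] == i)]
        dyad_key = (g, d, *sorted((i, j)))
        resp = received["response"]
        rows.append({
            "group_id": g, "day": d, "initiator": i, "partner": j,
            "initiator_id": f"G{g}_{i}", "partner_id": f"G{g}_{j}",
            "outcome": 1 if rec["classification"] == "strong_preferred"
                       else 0,
            "classification": rec["classification"],
            "partner_play_frequency": len(back),
            "pct_no_response": 100.0 * (resp == "no_response").mean(),
            "pct_evasion": 100.0 * (resp == "evasion").mean(),
            "pct_pin": 100.0 * (resp == "pin").mean(),
            "pct_role_reversal":
                100.0 * received["role_reversal"].mean(),
            "symmetry": sym_lookup.get(dyad_key, float("nan")),
            "proximity_s": prox_lookup.get(dyad_key, float("nan")),
            "weight_diff": weights[(g, i)] - weights[(g, j)],
            "dominance_diff": dominance[(g, i)] - dominance[(g, j)],
        })
    if n_dropped:
        logger.info("dropped %d dyad-day rows with zero received attacks",
                    n_dropped)
    return pd.DataFrame(rows)
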