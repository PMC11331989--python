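"""Longitudinal actor-partner interdependence and mediation models.

The APIM is a two-intercept, role-stratified linear model on the
alternating-winner compressed series: for each interval i >= 2 the
winner-role and loser-role outcomes (negativity at interval i) are
regressed on the same player's negativity at i-1 (actor effect) and the
partner's negativity at i-1 (partner effect), with a couple-level
random intercept, estimated by maximum likelihood.

The mediation model decomposes the effect of the forced-break indicator
on blast level into a direct path and an indirect path through winner
negativity, with a couple-clustered nonparametric bootstrap for the
indirect effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "ApimEstimate",
    "ApimResult",
    "MediationResult",
    "build_apim_table",
    "fit_apim",
    "fit_mediation",
]

ROLES = ("winner", "loser")


def build_apim_table(compressed: pd.DataFrame) -> pd.DataFrame:
    """Lagged actor/partner rows from a compressed alternating series.

    For every interval i >= 2 two rows are produced: the winner-role
    outcome is the interval's mean winner negativity with the acting
    player's own i-1 negativity as the actor term (they lost i-1, since
    winners alternate) and the partner's i-1 negativity as the partner
    term; symmetrically for the loser role.  A session of k intervals
    yields 2*(k-1) rows.  Input order is irrelevant (internal sort).
    """
    comp = compressed.sort_values(["couple_id", "interval_index"]).reset_index(drop=True)
    rows = []
    for couple_id, grp in comp.groupby("couple_id", sort=True):
        if len(grp) < 2:
            raise ValueError(f"couple {couple_id}: need >= 2 compressed intervals")
        w = grp["mean_winner_neg"].to_numpy(dtype=float)
        l = grp["mean_loser_neg"].to_numpy(dtype=float)
        idx = grp["interval_index"].to_numpy()
        for i in range(1, len(grp)):
            # winner at i was loser at i-1 (alternating winners)
            rows.append(
                {
                    "couple_id": couple_id,
                    "interval_index": int(idx[i]),
                    "role": "winner",
                    "outcome": w[i],
                    "actor_lag": l[i - 1],
                    "partner_lag": w[i - 1],
                }
            )
            rows.append(
                {
                    "couple_id": couple_id,
                    "interval_index": int(idx[i]),
                    "role": "loser",
                    "outcome": l[i],
                    "actor_lag": w[i - 1],
                    "partner_lag": l[i - 1],
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ApimEstimate:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    stat: float
    df: float


@dataclass(frozen=True)
class ApimResult:
    """Role-stratified APIM estimates.

    ``effects[role][term]`` holds the estimate for ``term`` in
    ``{"intercept", "actor", "partner"}``; ``couple_var`` is the
    couple-level random-intercept variance; ``method`` records the
    estimator actually used ("mixed_ml" or the OLS fallback used for
    degenerate, noise-free designs).
    """

    effects: Mapping[str, Mapping[str, ApimEstimate]]
    couple_var: float
    n_couples: int
    n_rows: int
    converged: bool
    method: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for role, terms in self.effects.items():
            for term, est in terms.items():
                rows.append(
                    {
                        "role": role,
                        "term": term,
                        "estimate": est.estimate,
                        "se": est.se,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "stat": est.stat,
                        "df": est.df,
                    }
                )
        return pd.DataFrame(rows)


def _design(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    names = []
    cols = []
    for role in ROLES:
        mask = (table["role"] == role).to_numpy(dtype=float)
        cols.append(mask)
        names.append(f"{role}:intercept")
    for term in ("actor_lag", "partner_lag"):
        for role in ROLES:
            mask = (table["role"] == role).to_numpy(dtype=float)
            cols.append(mask * table[term].to_numpy(dtype=float))
            names.append(f"{role}:{term.removesuffix('_lag')}")
    X = np.column_stack(cols)
    y = table["outcome"].to_numpy(dtype=float)
    return X, y, names


def fit_apim(table: pd.DataFrame) -> ApimResult:
    """Fit the role-stratified APIM by maximum likelihood.

    Requires >= 2 couples and >= 10 rows.  The primary estimator is a
    linear mixed model with a couple-level random intercept (ML); for
    noise-free degenerate data where the mixed likelihood is undefined
    the fit falls back to OLS with a zero couple variance, reported via
    ``method``.  Rank-deficient designs raise.
    """
    required = {"couple_id", "role", "outcome", "actor_lag", "partner_lag"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"APIM table missing columns: {sorted(missing)}")
    n_couples = table["couple_id"].nunique()
    if n_couples < 2:
        raise ValueError("need >= 2 couples")
    if len(table) < 10:
        raise ValueError("need >= 10 rows")

    X, y, names = _design(table)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient APIM design (constant or collinear predictors)")

    df_resid = float(len(y) - X.shape[1])
    ols = sm.OLS(y, X).fit()
    noise_free = ols.ssr / max(len(y), 1) < 1e-12

    if not noise_free:
        groups = table["couple_id"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=groups)
            fit = model.fit(reml=False)
        params = np.asarray(fit.fe_params, dtype=float)
        ses = np.asarray(fit.bse_fe, dtype=float)
        couple_var = float(np.asarray(fit.cov_re)[0, 0]) if np.asarray(fit.cov_re).size else 0.0
        converged = bool(fit.converged)
        method = "mixed_ml"
    else:
        params = np.asarray(ols.params, dtype=float)
        ses = np.asarray(ols.bse, dtype=float)
        couple_var = 0.0
        converged = True
        method = "ols_degenerate"

    z = sps.norm.ppf(0.975)
    effects: dict[str, dict[str, ApimEstimate]] = {r: {} for r in ROLES}
    for name, est, se in zip(names, params, ses):
        role, term = name.split(":")
        stat = est / se if se > 0 else 0.0
        effects[role][term] = ApimEstimate(
            estimate=float(est),
            se=float(se),
            ci_low=float(est - z * se),
            ci_high=float(est + z * se),
            stat=float(stat),
            df=df_resid,
        )
    return ApimResult(
        effects=effects,
        couple_var=couple_var,
        n_couples=int(n_couples),
        n_rows=int(len(table)),
        converged=converged,
        method=method,
    )


@dataclass(frozen=True)
class MediationResult:
    """Path decomposition of the forced-break effect on blast level.

    ``c`` is the total effect (blast units per unit exposure), ``a``
    the exposure->negativity path, ``b`` the negativity->blast path
    adjusted for exposure, ``c_prime`` the direct effect and
    ``indirect = a*b`` with a couple-clustered percentile bootstrap CI.
    For unclustered OLS on one sample, ``c = c_prime + a*b`` exactly.
    """

    c: float
    a: float
    b: float
    c_prime: float
    indirect: float
    indirect_ci: tuple[float, float]
    direct_ci: tuple[float, float]
    p_values: Mapping[str, float] = field(default_factory=dict)
    n_boot: int = 0
    n_couples: int = 0
    n_trials: int = 0


def _ols_paths(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    one = np.ones_like(x)
    Xc = np.column_stack([one, x])
    c = np.linalg.lstsq(Xc, y, rcond=None)[0][1]
    a = np.linalg.lstsq(Xc, m, rcond=None)[0][1]
    Xb = np.column_stack([one, x, m])
    coef = np.linalg.lstsq(Xb, y, rcond=None)[0]
    c_prime, b = coef[1], coef[2]
    return float(c), float(a), float(b), float(c_prime)


def fit_mediation(
    data: pd.DataFrame,
    n_boot: int = 5000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> MediationResult:
    """Simple mediation of exposure on outcome through a mediator.

    ``data`` needs columns ``couple_id``, ``exposure`` (0/1 forced
    break), ``mediator`` (winner negativity at selection) and
    ``outcome`` (blast).  Paths are OLS; the indirect effect is a*b
    with a nonparametric bootstrap resampling couples with replacement
    (clustered), percentile CI.  ``n_boot`` below 100 is rejected.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    required = {"couple_id", "exposure", "mediator", "outcome"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"mediation data missing columns: {sorted(missing)}")
    d = data.dropna(subset=["exposure", "mediator", "outcome"]).reset_index(drop=True)
    levels = d["exposure"].nunique()
    if levels < 2:
        raise ValueError("both exposure levels must be present")

    x = d["exposure"].to_numpy(dtype=float)
    m = d["mediator"].to_numpy(dtype=float)
    y = d["outcome"].to_numpy(dtype=float)
    c, a, b, c_prime = _ols_paths(x, m, y)

    # Wald p-values from the full-sample OLS fits (for comparability)
    one = np.ones_like(x)
    p_c = sm.OLS(y, np.column_stack([one, x])).fit().pvalues[1]
    p_a = sm.OLS(m, np.column_stack([one, x])).fit().pvalues[1]
    fit_b = sm.OLS(y, np.column_stack([one, x, m])).fit()
    p_cp, p_b = fit_b.pvalues[1], fit_b.pvalues[2]

    rng = np.random.default_rng(seed)
    couples = d["couple_id"].unique()
    index_by_couple = {cid: np.flatnonzero(d["couple_id"].to_numpy() == cid)
                       for cid in couples}
    boot_ind = np.empty(n_boot)
    boot_dir = np.empty(n_boot)
    for i in range(n_boot):
        chosen = rng.choice(couples, size=len(couples), replace=True)
        idx = np.concatenate([index_by_couple[cid] for cid in chosen])
        xb, mb, yb = x[idx], m[idx], y[idx]
        if np.unique(xb).size < 2 or np.std(mb) == 0:
            boot_ind[i] = np.nan
            boot_dir[i] = np.nan
            continue
        _, ab, bb, cpb = _ols_paths(xb, mb, yb)
        boot_ind[i] = ab * bb
        boot_dir[i] = cpb
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = 100 * alpha, 100 * (1 - alpha)
    indirect_ci = tuple(np.nanpercentile(boot_ind, [lo, hi]))
    direct_ci = tuple(np.nanpercentile(boot_dir, [lo, hi]))

    return MediationResult(
        c=c,
        a=a,
        b=b,
        c_prime=c_prime,
        indirect=a * b,
        indirect_ci=(float(indirect_ci[0]), float(indirect_ci[1])),
        direct_ci=(float(direct_ci[0]), float(direct_ci[1])),
        p_values={"c": float(p_c), "a": float(p_a), "b": float(p_b),
                  "c_prime": float(p_cp)},
        n_boot=n_boot,
        n_couples=int(len(couples)),
        n_trials=int(len(d)),
    )
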