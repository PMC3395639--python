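"""Longitudinal group x time evaluation of derived measures.

Each measure (gamma, lambda, inter/intrahemispheric FC, ROI diffusion
metrics) is modelled with a repeated-measures linear mixed model:

    y_st = X_st beta + b_s + e_st

with fixed effects for group, time and their interaction, a subject-level
random intercept ``b_s ~ N(0, sigma_b^2)``, and a continuous-time AR1
residual correlation ``corr(e_st, e_su) = phi^{|t - u|}`` (t in days).
Variance parameters are estimated by restricted maximum likelihood with
the residual variance profiled out; fixed effects follow by GLS.

The interface is statsmodels-like: build a :class:`LongitudinalModel`
(e.g. via :meth:`LongitudinalModel.from_dataframe`), call :meth:`fit`, and
read estimates, standard errors, p-values and :meth:`summary` off the
returned :class:`LongitudinalResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import solve_triangular
from scipy.stats import studentized_range, t as t_dist

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "group", "day", "value")


class ConvergenceError(RuntimeError):
    """REML optimization failed; carries the optimizer diagnostics."""


def validate_table(df: pd.DataFrame, measure: str | None = None) -> pd.DataFrame:
    """Check the tidy longitudinal table contract and return the relevant rows.

    Expected columns: subject_id, group, day, value (+ optional 'measure'
    when several measures share one table).  At most one value per
    (subject, day, measure); exactly two nonempty groups.
    """
    if measure is not None and "measure" in df.columns:
        df = df[df["measure"] == measure]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"table lacks required columns: {missing}")
    df = df.dropna(subset=["value"])
    if df.empty:
        raise ValueError("no observations for this measure")
    dup = df.duplicated(subset=["subject_id", "day"])
    if dup.any():
        raise ValueError("more than one value per (subject, day, measure)")
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    return df


class LongitudinalModel:
    """Mixed model for one measure of a longitudinal two-group design.

    Parameters
    ----------
    table : DataFrame
        Tidy rows (subject_id, group, day, value); pass `measure` to
        :meth:`from_dataframe` to slice a multi-measure table.
    time_as : {'continuous', 'categorical'}
        Continuous time (days) gives single-df group/time/interaction
        tests; categorical time supports per-day contrasts.
    ar1 : bool
        Continuous-time AR1 residual correlation (phi per day).
    random_intercept, random_slope : bool
        Subject-level random effects.  The random slope (on days) is an
        optional extension; the default model is random intercept + AR1.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        time_as: str = "continuous",
        ar1: bool = True,
        random_intercept: bool = True,
        random_slope: bool = False,
    ) -> None:
        if time_as not in ("continuous", "categorical"):
            raise ValueError("time_as must be 'continuous' or 'categorical'")
        df = validate_table(table)
        df = df.sort_values(["subject_id", "day"]).reset_index(drop=True)
        self.table = df
        self.time_as = time_as
        self.ar1 = ar1
        self.random_intercept = random_intercept
        self.random_slope = random_slope

        self.groups = sorted(df["group"].unique())
        self.days = np.array(sorted(df["day"].unique()), dtype=float)
        if len(self.days) < 2:
            raise ValueError("need at least two time points to estimate a time effect")
        per_group = df.groupby("group")["subject_id"].nunique()
        if (per_group < 2).any():
            raise ValueError("need at least two subjects per group")

        self.subjects = list(df["subject_id"].unique())
        self._y = df["value"].to_numpy(dtype=float)
        self._day = df["day"].to_numpy(dtype=float)
        self._grp = (df["group"] == self.groups[1]).to_numpy(dtype=float)
        self._X, self.exog_names = self._build_design()
        self._blocks = self._subject_blocks()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, measure: str | None = None, **kwargs) -> "LongitudinalModel":
        return cls(validate_table(df, measure), **kwargs)

    # ------------------------------------------------------------- design
    def _build_design(self) -> tuple[np.ndarray, list[str]]:
        g = self._grp
        if self.time_as == "continuous":
            day_c = self._day - self._day.mean()
            x = np.column_stack([np.ones_like(g), g, day_c, g * day_c])
            names = ["Intercept", f"group[{self.groups[1]}]", "day", f"group[{self.groups[1]}]:day"]
            return x, names
        cols = [np.ones_like(g), g]
        names = ["Intercept", f"group[{self.groups[1]}]"]
        for d in self.days[1:]:
            ind = (self._day == d).astype(float)
            cols.append(ind)
            names.append(f"day[{d:g}]")
        for d in self.days[1:]:
            ind = (self._day == d).astype(float)
            cols.append(g * ind)
            names.append(f"group[{self.groups[1]}]:day[{d:g}]")
        return np.column_stack(cols), names

    def _subject_blocks(self):
        """Subjects grouped by identical day patterns, for batched solves."""
        df = self.table
        patterns: dict[tuple, list[np.ndarray]] = {}
        for _, idx in df.groupby("subject_id").indices.items():
            idx = np.asarray(idx)
            patterns.setdefault(tuple(self._day[idx]), []).append(idx)
        return [
            (np.asarray(days, dtype=float), np.stack(idx_list))
            for days, idx_list in patterns.items()
        ]

    # --------------------------------------------------------------- REML
    def _theta_names(self) -> list[str]:
        names = []
        if self.random_intercept:
            names.append("log_tau_intercept")
        if self.random_slope:
            names.append("log_tau_slope")
        if self.ar1:
            names.append("logit_phi")
        return names

    def _corr_matrix(self, days: np.ndarray, theta: dict) -> np.ndarray:
        n = len(days)
        r = np.eye(n)
        if self.ar1:
            phi = theta["phi"]
            if phi > 0:
                r = phi ** np.abs(days[:, None] - days[None, :])
        if self.random_intercept:
            r = r + theta["tau_b"]
        if self.random_slope:
            z = (days - self.days.mean()) / max(1.0, float(np.ptp(self.days)))
            r = r + theta["tau_s"] * np.outer(z, z)
        return r

    @staticmethod
    def _unpack(theta_vec: np.ndarray, names: list[str]) -> dict:
        out = {"tau_b": 0.0, "tau_s": 0.0, "phi": 0.0}
        for v, name in zip(theta_vec, names):
            if name == "log_tau_intercept":
                out["tau_b"] = float(np.exp(np.clip(v, -30, 30)))
            elif name == "log_tau_slope":
                out["tau_s"] = float(np.exp(np.clip(v, -30, 30)))
            elif name == "logit_phi":
                out["phi"] = float(1.0 / (1.0 + np.exp(-np.clip(v, -30, 30))))
        return out

    def _gls_pieces(self, theta: dict):
        """Accumulate GLS quantities; correlation factorizations are shared
        across subjects with identical day patterns."""
        p = self._X.shape[1]
        xtvx = np.zeros((p, p))
        xtvy = np.zeros(p)
        ytvy = 0.0
        logdet_r = 0.0
        for days, ids in self._blocks:  # ids: (n_subjects_in_pattern, n_i)
            r = self._corr_matrix(days, theta)
            try:
                chol = np.linalg.cholesky(r)
            except np.linalg.LinAlgError:
                return None
            s, n_i = ids.shape
            xb = self._X[ids]  # (s, n_i, p)
            xw = solve_triangular(
                chol, xb.transpose(1, 0, 2).reshape(n_i, s * p), lower=True
            ).reshape(n_i, s, p)
            yw = solve_triangular(chol, self._y[ids].T, lower=True)  # (n_i, s)
            xtvx += np.einsum("nsp,nsq->pq", xw, xw)
            xtvy += np.einsum("nsp,ns->p", xw, yw)
            ytvy += float((yw**2).sum())
            logdet_r += s * 2.0 * float(np.sum(np.log(np.diag(chol))))
        return xtvx, xtvy, ytvy, logdet_r

    def _neg_reml(self, theta_vec: np.ndarray, names: list[str]) -> float:
        theta = self._unpack(theta_vec, names)
        pieces = self._gls_pieces(theta)
        if pieces is None:
            return 1e12
        xtvx, xtvy, ytvy, logdet_r = pieces
        n, p = self._X.shape
        try:
            beta = np.linalg.solve(xtvx, xtvy)
            sign, logdet_x = np.linalg.slogdet(xtvx)
        except np.linalg.LinAlgError:
            return 1e12
        if sign <= 0:
            return 1e12
        rss = ytvy - beta @ xtvy
        if rss <= 0:
            return 1e12
        sigma2 = rss / (n - p)
        return 0.5 * ((n - p) * np.log(sigma2) + logdet_r + logdet_x + (n - p))

    def fit(self, start: np.ndarray | None = None) -> "LongitudinalResults":
        """Estimate variance parameters by REML and fixed effects by GLS."""
        names = self._theta_names()
        if names:
            starts = [np.zeros(len(names))] if start is None else [np.asarray(start)]
            if start is None:
                starts.append(np.full(len(names), -2.0))
                starts.append(np.full(len(names), 1.0))
            best = None
            for s0 in starts:
                res = optimize.minimize(
                    self._neg_reml,
                    s0,
                    args=(names,),
                    method="Nelder-Mead",
                    options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
                )
                if best is None or res.fun < best.fun:
                    best = res
            if not np.isfinite(best.fun) or best.fun >= 1e12:
                raise ConvergenceError(
                    f"REML optimization failed: {best.message} (fun={best.fun})"
                )
            if not best.success:
                logger.warning("REML optimizer reports non-success: %s", best.message)
            theta = self._unpack(best.x, names)
            converged = bool(best.success)
            neg_reml = float(best.fun)
        else:
            theta = {"tau_b": 0.0, "tau_s": 0.0, "phi": 0.0}
            converged = True
            neg_reml = float(self._neg_reml(np.zeros(0), names))

        xtvx, xtvy, ytvy, _ = self._gls_pieces(theta)
        n, p = self._X.shape
        beta = np.linalg.solve(xtvx, xtvy)
        sigma2 = float((ytvy - beta @ xtvy) / (n - p))
        cov = sigma2 * np.linalg.inv(xtvx)
        return LongitudinalResults(model=self, params=beta, cov_params=cov,
                                   sigma2=sigma2, theta=theta, converged=converged,
                                   reml_criterion=neg_reml)


@dataclass
class LongitudinalResults:
    """Fitted mixed model: estimates, uncertainties and tests.

    Degrees of freedom follow the inner/outer (containment) convention:
    effects that vary within subject (time, group x time) are tested
    against ``n_obs - n_subjects - p_within`` df; between-subject effects
    (intercept, group) against ``n_subjects - 2``.
    """

    model: LongitudinalModel
    params: np.ndarray
    cov_params: np.ndarray
    sigma2: float
    theta: dict
    converged: bool
    reml_criterion: float
    _effect_dfs: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        m = self.model
        n_sub = len(m.subjects)
        n_obs = len(m._y)
        p = len(self.params)
        # nlme convention: the intercept is tested at the innermost level but
        # does not count against the within-subject parameter budget
        varies_within = np.array([("day" in name) for name in m.exog_names])
        within = varies_within | np.array([n == "Intercept" for n in m.exog_names])
        p_within = int(varies_within.sum())
        df_within = max(1, n_obs - n_sub - p_within)
        df_between = max(1, n_sub - 2)
        self._effect_dfs = np.where(within, df_within, df_between).astype(float)

    # ------------------------------------------------------------- access
    @property
    def exog_names(self) -> list[str]:
        return self.model.exog_names

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def dfs(self) -> np.ndarray:
        return self._effect_dfs

    @property
    def pvalues(self) -> pd.Series:
        p = 2 * t_dist.sf(np.abs(self.tvalues), self._effect_dfs)
        return pd.Series(p, index=self.exog_names)

    @property
    def sigma_subject(self) -> float:
        """SD of the subject random intercept."""
        return float(np.sqrt(self.theta["tau_b"] * self.sigma2))

    @property
    def ar1_phi(self) -> float:
        """Residual correlation at lag one day."""
        return self.theta["phi"]

    def effect_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "df": self._effect_dfs,
                "p": self.pvalues.to_numpy(),
            },
            index=self.exog_names,
        )

    def contrast(self, c: np.ndarray, df: float | None = None) -> dict:
        """Estimate, SE, t and p for a linear combination of fixed effects."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.params)
        se = float(np.sqrt(c @ self.cov_params @ c))
        df = float(df if df is not None else max(1, len(self.model.subjects) - 2))
        tval = est / se if se > 0 else np.inf
        return {
            "estimate": est,
            "se": se,
            "t": tval,
            "df": df,
            "p": float(2 * t_dist.sf(abs(tval), df)),
        }

    def summary(self) -> str:
        m = self.model
        lines = [
            "Longitudinal mixed model (REML)",
            "=" * 64,
            f"groups: {m.groups[0]} (ref) vs {m.groups[1]}   "
            f"subjects: {len(m.subjects)}   observations: {len(m._y)}",
            f"time: {m.time_as} over days {list(m.days.astype(int))}",
            f"residual SD: {np.sqrt(self.sigma2):.4g}   subject SD: {self.sigma_subject:.4g}"
            + (f"   AR1 phi/day: {self.ar1_phi:.4g}" if m.ar1 else ""),
            f"converged: {self.converged}   -REML/2 criterion: {self.reml_criterion:.4f}",
            "-" * 64,
            f"{'effect':<28}{'est':>9}{'se':>9}{'t':>8}{'df':>6}{'p':>8}",
        ]
        tab = self.effect_table()
        for name, row in tab.iterrows():
            lines.append(
                f"{name:<28}{row.estimate:>9.4f}{row.se:>9.4f}"
                f"{row.t:>8.2f}{row.df:>6.0f}{row.p:>8.4f}"
            )
        return "\n".join(lines)


def fit_longitudinal(
    table: pd.DataFrame, measure: str | None = None, **kwargs
) -> LongitudinalResults:
    """Convenience wrapper: build the model for `measure` and fit it."""
    return LongitudinalModel.from_dataframe(table, measure=measure, **kwargs).fit()


def per_timepoint_contrast(
    table: pd.DataFrame,
    measure: str | None = None,
    day: float | None = None,
    **model_kwargs,
) -> pd.DataFrame:
    """Model-based group difference at each day, Tukey-adjusted across days.

    Fits the categorical-time mixed model and computes the
    (group 2 - group 1) contrast of cell means per day.  The unadjusted
    p-value uses a t reference with between-subject df; the adjusted one
    applies Tukey's studentized-range correction with the number of days
    as family size.  Returns one row per day (or only `day` if given).
    """
    model_kwargs.setdefault("time_as", "categorical")
    model = LongitudinalModel.from_dataframe(table, measure=measure, **model_kwargs)
    if day is not None and float(day) not in set(model.days):
        raise ValueError(f"day {day} not present in the table")
    res = model.fit()
    names = model.exog_names
    k_days = len(model.days)
    df_bet = max(1, len(model.subjects) - 2)
    rows = []
    for d in model.days:
        c = np.zeros(len(names))
        c[names.index(f"group[{model.groups[1]}]")] = 1.0
        inter = f"group[{model.groups[1]}]:day[{d:g}]"
        if inter in names:
            c[names.index(inter)] = 1.0
        base = res.contrast(c, df=df_bet)
        q = abs(base["t"]) * np.sqrt(2.0)
        p_adj = float(studentized_range.sf(q, k_days, df_bet))
        rows.append(
            {
                "day": d,
                "estimate": base["estimate"],
                "se": base["se"],
                "t": base["t"],
                "df": df_bet,
                "p_unadjusted": base["p"],
                "p_tukey": min(1.0, p_adj),
            }
        )
    out = pd.DataFrame(rows).set_index("day")
    if day is not None:
        return out.loc[[float(day)]]
    return out
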