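"""Covariate-adjusted mediation with percentile-bootstrap inference,
plus the surrounding descriptive statistics (partial correlation, ANCOVA
group comparison, standardization).

The mediation model is the classic three-regression ("Model 4") scheme,
following the four-step logic: with predictor X, mediator M, outcome Y and
a common covariate set C,

    step 1:  Y = c·X + C          (total effect c)
    step 2:  M = a·X + C          (a path)
    steps 3/4:  Y = c'·X + b·M + C  (direct effect c', b path)

The indirect effect is the product of coefficients a·b; with ordinary
least squares and identical covariate sets the decomposition
c = c' + a·b holds exactly.  All variables are standardized once before
fitting; inference on the indirect effect is by percentile bootstrap over
resampled (standardized) rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "standardize",
    "partial_correlation",
    "PartialCorrelationResult",
    "ancova_group_difference",
    "AncovaResult",
    "BootstrapConfig",
    "PathEstimate",
    "MediationModel",
    "MediationResults",
    "fit_mediation",
    "effect_decomposition",
]

logger = logging.getLogger(__name__)


def standardize(values: Sequence[float]) -> np.ndarray:
    """z-scores with the sample (n-1) standard deviation."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot standardize a zero-variance variable")
    return (x - x.mean()) / sd


# -- partial correlation --------------------------------------------------


@dataclass(frozen=True)
class PartialCorrelationResult:
    r: float
    p: float
    df: int
    n: int


def partial_correlation(
    x: Sequence[float], y: Sequence[float], covariates
) -> PartialCorrelationResult:
    """Partial correlation of x and y given covariates.

    Computed as the Pearson correlation of the least-squares residuals of
    x and y on the covariates (plus intercept); the p-value is two-sided
    from a t distribution with n - k - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != x.size:
        C = C.T
    n, k = x.size, C.shape[1]
    if y.size != n or C.shape[0] != n:
        raise ValueError("x, y and covariates must have the same length")
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates")
    resid = []
    for v in (x, y):
        coef, *_ = np.linalg.lstsq(design, v, rcond=None)
        r_v = v - design @ coef
        if r_v.std() == 0:
            raise ValueError("zero residual variance; cannot compute partial correlation")
        resid.append(r_v)
    r = float(np.corrcoef(resid[0], resid[1])[0, 1])
    df = n - k - 2
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrelationResult(r=r, p=p, df=df, n=n)


# -- ANCOVA group comparison ---------------------------------------------


@dataclass(frozen=True)
class AncovaResult:
    F: float
    df_num: int
    df_den: int
    p: float
    descriptives: pd.DataFrame  # raw per-group mean/sd/n of the outcome


def ancova_group_difference(
    data: pd.DataFrame, outcome: str, group: str = "group", covariate: str = "sdq_conduct"
) -> AncovaResult:
    """One-way ANCOVA: outcome ~ group + covariate, F for the group term
    with (1, n - 3) degrees of freedom; raw group descriptives returned
    alongside."""
    counts = data[group].value_counts()
    if len(counts) != 2 or (counts < 3).any():
        raise ValueError("ANCOVA needs two groups with at least 3 participants each")
    model = sm.OLS.from_formula(f"{outcome} ~ C({group}) + {covariate}", data=data).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("singular ANCOVA design")
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc[f"C({group})"]
    F, p = float(row["F"]), float(row["PR(>F)"])
    # Degenerate perfect fit (e.g. outcome identical to the covariate):
    # the group SS is analytically zero and F is 0/0; report 0.
    y = np.asarray(data[outcome], dtype=float)
    ss_total = float(((y - y.mean()) ** 2).sum())
    if row["sum_sq"] <= 1e-10 * max(ss_total, np.finfo(float).tiny):
        F, p = 0.0, 1.0
    desc = (
        data.groupby(group)[outcome]
        .agg(["mean", "std", "count"])
        .rename(columns={"count": "n", "std": "sd"})
    )
    return AncovaResult(
        F=F,
        df_num=int(row["df"]),
        df_den=int(table.loc["Residual", "df"]),
        p=p,
        descriptives=desc,
    )


# -- mediation ------------------------------------------------------------


@dataclass(frozen=True)
class BootstrapConfig:
    """Percentile-bootstrap settings for the indirect effect."""

    n_resamples: int = 5000
    ci_level: float = 0.95
    method: str = "percentile"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_resamples < 1000:
            raise ValueError("n_resamples must be >= 1000")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.method != "percentile":
            raise ValueError("only the percentile method is implemented")


@dataclass(frozen=True)
class PathEstimate:
    """One regression path: analytic OLS inference plus bootstrap spread."""

    name: str
    coef: float
    se: float
    t: float
    p: float
    ci: tuple[float, float]
    boot_se: float = np.nan
    boot_ci: tuple[float, float] = (np.nan, np.nan)


def effect_decomposition(direct: float, indirect: float) -> dict[str, float]:
    """Total/direct/indirect decomposition with relative percentages.

    total = direct + indirect; percentages are of the total (the total row
    is 100%), undefined (NaN) when the total is zero.
    """
    total = direct + indirect
    if total == 0:
        return {
            "total": 0.0, "direct": direct, "indirect": indirect,
            "total_pct": np.nan, "direct_pct": np.nan, "indirect_pct": np.nan,
        }
    return {
        "total": total,
        "direct": direct,
        "indirect": indirect,
        "total_pct": 100.0,
        "direct_pct": 100.0 * direct / total,
        "indirect_pct": 100.0 * indirect / total,
    }


def _batched_ols(D: np.ndarray, r: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """OLS coefficients for each bootstrap resample (rows of ``idx``)."""
    Db = D[idx]  # (B, n, p)
    rb = r[idx]  # (B, n)
    XtX = np.einsum("bnp,bnq->bpq", Db, Db)
    Xty = np.einsum("bnp,bn->bp", Db, rb)
    return np.linalg.solve(XtX, Xty[..., None])[..., 0]


class MediationModel:
    """Simple mediation (X -> M -> Y) with optional covariates.

    Parameters
    ----------
    x, m, y : array-like
        Predictor, mediator and outcome (one value per participant).
    covariates : 2d array-like or None
        Covariate columns entered in every regression stage.
    standardize_vars : bool
        Standardize all variables before fitting (default).  When False
        the inputs must already be standardized; anything else raises.
    names : tuple of str
        Labels used in summaries, ``(x, m, y)``.
    """

    def __init__(
        self,
        x,
        m,
        y,
        covariates=None,
        standardize_vars: bool = True,
        names: tuple[str, str, str] = ("X", "M", "Y"),
        covariate_names: Optional[Sequence[str]] = None,
    ):
        x = np.asarray(x, dtype=float)
        m = np.asarray(m, dtype=float)
        y = np.asarray(y, dtype=float)
        n = x.size
        if m.size != n or y.size != n:
            raise ValueError("x, m, y must have the same length")
        if n < 10:
            raise ValueError(f"mediation needs n >= 10, got n={n}")
        if covariates is None:
            C = np.empty((n, 0))
        else:
            C = np.atleast_2d(np.asarray(covariates, dtype=float))
            if C.shape[0] != n:
                C = C.T
            if C.shape[0] != n:
                raise ValueError("covariates must align with x/m/y")
        cols = [x, m, y] + [C[:, j] for j in range(C.shape[1])]
        if standardize_vars:
            cols = [standardize(c) for c in cols]
        else:
            for c in cols:
                if abs(c.mean()) > 1e-8 or abs(c.std(ddof=1) - 1.0) > 1e-6:
                    raise ValueError(
                        "inputs must be standardized when standardize_vars=False"
                    )
        self.x, self.m, self.y = cols[0], cols[1], cols[2]
        self.C = np.column_stack(cols[3:]) if C.shape[1] else np.empty((n, 0))
        self.n = n
        self.names = names
        self.covariate_names = list(
            covariate_names
            if covariate_names is not None
            else [f"cov{j + 1}" for j in range(self.C.shape[1])]
        )

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        x: str,
        m: str,
        y: str,
        covariates: Sequence[str] = (),
        standardize_vars: bool = True,
    ) -> "MediationModel":
        covs = data[list(covariates)].to_numpy() if covariates else None
        return cls(
            data[x].to_numpy(),
            data[m].to_numpy(),
            data[y].to_numpy(),
            covariates=covs,
            standardize_vars=standardize_vars,
            names=(x, m, y),
            covariate_names=list(covariates),
        )

    # ------------------------------------------------------------------
    def fit(self, boot: Optional[BootstrapConfig] = None) -> "MediationResults":
        """Fit the three regression stages and bootstrap the effects."""
        if boot is None:
            boot = BootstrapConfig()
        n = self.n
        ones = np.ones(n)
        D_xc = np.column_stack([ones, self.x, self.C])           # stages 1 & 2
        D_xmc = np.column_stack([ones, self.x, self.m, self.C])  # stages 3/4

        total_fit = sm.OLS(self.y, D_xc).fit()
        m_fit = sm.OLS(self.m, D_xc).fit()
        full_fit = sm.OLS(self.y, D_xmc).fit()

        # Bootstrap: resample standardized rows, re-estimate every stage.
        rng = np.random.default_rng(boot.seed)
        B = boot.n_resamples
        a_b = np.empty(B)
        b_b = np.empty(B)
        cprime_b = np.empty(B)
        total_b = np.empty(B)
        chunk = max(1, int(2_000_000 // max(n, 1)))
        done = 0
        redraws = 0
        while done < B:
            nb = min(chunk, B - done)
            idx = rng.integers(0, n, size=(nb, n))
            for attempt in range(100):
                try:
                    coef_m = _batched_ols(D_xc, self.m, idx)
                    coef_t = _batched_ols(D_xc, self.y, idx)
                    coef_f = _batched_ols(D_xmc, self.y, idx)
                    break
                except np.linalg.LinAlgError:
                    # Degenerate resample (collinear/constant draw): redraw.
                    redraws += 1
                    idx = rng.integers(0, n, size=(nb, n))
            else:  # pragma: no cover - astronomically unlikely
                raise np.linalg.LinAlgError("could not draw a non-singular resample")
            a_b[done : done + nb] = coef_m[:, 1]
            total_b[done : done + nb] = coef_t[:, 1]
            cprime_b[done : done + nb] = coef_f[:, 1]
            b_b[done : done + nb] = coef_f[:, 2]
            done += nb
        if redraws:
            logger.warning("redrew %d degenerate bootstrap chunk(s)", redraws)
        indirect_b = a_b * b_b

        lo_q = 100.0 * (1.0 - boot.ci_level) / 2.0
        hi_q = 100.0 - lo_q

        def pct_ci(v: np.ndarray) -> tuple[float, float]:
            lo, hi = np.percentile(v, [lo_q, hi_q])
            return float(lo), float(hi)

        def path(name, fit_, col, boot_vals) -> PathEstimate:
            ci = fit_.conf_int(alpha=1.0 - boot.ci_level)[col]
            return PathEstimate(
                name=name,
                coef=float(fit_.params[col]),
                se=float(fit_.bse[col]),
                t=float(fit_.tvalues[col]),
                p=float(fit_.pvalues[col]),
                ci=(float(ci[0]), float(ci[1])),
                boot_se=float(boot_vals.std(ddof=1)),
                boot_ci=pct_ci(boot_vals),
            )

        paths = {
            "a": path("a (X -> M)", m_fit, 1, a_b),
            "b": path("b (M -> Y | X)", full_fit, 2, b_b),
            "total": path("c (X -> Y, total)", total_fit, 1, total_b),
            "direct": path("c' (X -> Y, direct)", full_fit, 1, cprime_b),
        }
        indirect = float(paths["a"].coef * paths["b"].coef)
        stages = {
            "total (Y ~ X + C)": _stage_info(total_fit),
            "mediator (M ~ X + C)": _stage_info(m_fit),
            "full (Y ~ X + M + C)": _stage_info(full_fit),
        }
        return MediationResults(
            model=self,
            paths=paths,
            indirect=indirect,
            indirect_boot_se=float(indirect_b.std(ddof=1)),
            indirect_boot_ci=pct_ci(indirect_b),
            stages=stages,
            boot=boot,
        )


def _stage_info(fit_) -> dict[str, float]:
    return {
        "r_squared": float(fit_.rsquared),
        "F": float(fit_.fvalue),
        "df_model": int(fit_.df_model),
        "df_resid": int(fit_.df_resid),
        "p": float(fit_.f_pvalue),
    }


@dataclass
class MediationResults:
    """Estimates, bootstrap uncertainty and diagnostics of a fitted
    mediation model."""

    model: MediationModel
    paths: dict[str, PathEstimate]
    indirect: float
    indirect_boot_se: float
    indirect_boot_ci: tuple[float, float]
    stages: dict[str, dict[str, float]]
    boot: BootstrapConfig

    @property
    def total(self) -> float:
        return self.paths["total"].coef

    @property
    def direct(self) -> float:
        return self.paths["direct"].coef

    @property
    def significant_indirect(self) -> bool:
        lo, hi = self.indirect_boot_ci
        return not (lo <= 0.0 <= hi)

    def effect_table(self) -> pd.DataFrame:
        """Total/direct/indirect table with bootstrap SE, percentile CI
        and relative effect percentages."""
        dec = effect_decomposition(self.direct, self.indirect)
        rows = [
            {
                "effect": "Total",
                "estimate": self.total,
                "boot_se": self.paths["total"].boot_se,
                "ci_low": self.paths["total"].boot_ci[0],
                "ci_high": self.paths["total"].boot_ci[1],
                "relative_pct": dec["total_pct"],
            },
            {
                "effect": "Direct",
                "estimate": self.direct,
                "boot_se": self.paths["direct"].boot_se,
                "ci_low": self.paths["direct"].boot_ci[0],
                "ci_high": self.paths["direct"].boot_ci[1],
                "relative_pct": dec["direct_pct"],
            },
            {
                "effect": "Indirect",
                "estimate": self.indirect,
                "boot_se": self.indirect_boot_se,
                "ci_low": self.indirect_boot_ci[0],
                "ci_high": self.indirect_boot_ci[1],
                "relative_pct": dec["indirect_pct"],
            },
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        x, m, y = self.model.names
        lines = [
            f"Mediation: {x} -> {m} -> {y}"
            + (f"  (covariates: {', '.join(self.model.covariate_names)})"
               if self.model.covariate_names else ""),
            f"n = {self.model.n}, bootstrap resamples = {self.boot.n_resamples}, "
            f"CI level = {self.boot.ci_level:.2f}",
            "-" * 78,
            f"{'path':<24}{'beta':>8}{'SE':>8}{'t':>8}{'p':>8}{'boot SE':>9}{'boot CI':>20}",
        ]
        for key in ("a", "b", "total", "direct"):
            e = self.paths[key]
            lines.append(
                f"{e.name:<24}{e.coef:>8.3f}{e.se:>8.3f}{e.t:>8.3f}{e.p:>8.4f}"
                f"{e.boot_se:>9.3f}  [{e.boot_ci[0]:>7.3f}, {e.boot_ci[1]:>7.3f}]"
            )
        lines.append(
            f"{'indirect (a*b)':<24}{self.indirect:>8.3f}{'':>8}{'':>8}{'':>8}"
            f"{self.indirect_boot_se:>9.3f}  [{self.indirect_boot_ci[0]:>7.3f}, "
            f"{self.indirect_boot_ci[1]:>7.3f}]"
        )
        lines.append("-" * 78)
        for name, info in self.stages.items():
            lines.append(
                f"{name}: R^2 = {info['r_squared']:.3f}, "
                f"F({info['df_model']},{info['df_resid']}) = {info['F']:.3f}, p = {info['p']:.4f}"
            )
        dec = effect_decomposition(self.direct, self.indirect)
        lines.append(
            f"total = {dec['total']:.3f}; direct {dec['direct_pct']:.2f}% / "
            f"indirect {dec['indirect_pct']:.2f}% of total"
        )
        return "\n".join(lines)


def fit_mediation(
    x, m, y, covariates=None, boot: Optional[BootstrapConfig] = None, **kwargs
) -> MediationResults:
    """Functional wrapper: build a :class:`MediationModel` and fit it."""
    return MediationModel(x, m, y, covariates=covariates, **kwargs).fit(boot=boot)
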