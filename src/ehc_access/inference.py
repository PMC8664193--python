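"""Statistical stages of the accessibility analysis.

Three stages mirror a standard health-geography equity workflow:

1. a Pearson screen flags covariate pairs with |r| >= 0.6 and drops the
   lower-priority member, and the RT-TT correlation quantifies whether the
   two accessibility measures agree;
2. one-way ANOVA with a Tukey HSD post-hoc compares each measure between
   urban, densely populated and rural areas;
3. negative binomial (NB2) regressions model disparities in RT/TT/TPT over
   demographic and socioeconomic covariates, optionally with a
   rural x older-adults interaction, on the full study area or restricted
   to a measure's 5th (most underserviced) quintile.

Access times are continuous minutes but heavily right-skewed and
overdispersed; they are rounded to integer minutes so the NB count
likelihood is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .accessibility import DENSELY_POPULATED, RURAL, URBAN

PEARSON_THRESHOLD = 0.6
MIN_ALPHA = 1e-8
MAX_ALPHA = 50.0


class ConvergenceError(RuntimeError):
    """Raised when a model fit fails to converge."""


# ----------------------------------------------------------------------
# correlation
# ----------------------------------------------------------------------

def pearson_screen(
    table: pd.DataFrame,
    threshold: float = PEARSON_THRESHOLD,
    priority: Sequence[str] | None = None,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Flag highly correlated covariate pairs and drop the later-priority one.

    ``priority`` orders columns by preference (earlier = kept); it defaults
    to the table's column order. Constant columns have undefined r; they are
    flagged against themselves (r = nan) and dropped. Returns
    (retained columns, flagged (kept, dropped, r) triples).
    """
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise ValueError("need at least 2 covariates and 3 observations")
    cols = list(priority) if priority is not None else list(table.columns)
    if set(cols) != set(table.columns):
        raise ValueError("priority must be a permutation of the table columns")
    flagged: list[tuple[str, str, float]] = []
    retained: list[str] = []
    for col in cols:
        x = table[col].to_numpy(dtype=float)
        if np.std(x) == 0:
            flagged.append((col, col, float("nan")))
            continue
        clash = None
        for kept in retained:
            r = float(np.corrcoef(table[kept].to_numpy(dtype=float), x)[0, 1])
            if abs(r) >= threshold:
                clash = (kept, col, r)
                break
        if clash is None:
            retained.append(col)
        else:
            flagged.append(clash)
    return retained, flagged


def correlation_rt_tt(records: pd.DataFrame) -> tuple[float, float]:
    """Pearson r (with two-sided p) between per-area RT and TT minutes."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    rt = records["rt_min"].to_numpy(dtype=float)
    tt = records["tt_min"].to_numpy(dtype=float)
    if np.std(rt) == 0 or np.std(tt) == 0:
        raise ValueError("correlation undefined: a measure has zero variance")
    res = stats.pearsonr(rt, tt)
    return float(res.statistic), float(res.pvalue)


# ----------------------------------------------------------------------
# ANOVA / Tukey
# ----------------------------------------------------------------------

@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_stats: pd.DataFrame              # group, n, mean, sd
    tukey: dict[tuple[str, str], tuple[float, float]]  # (g1,g2) -> (mean diff, adj p)


def anova_by_area_type(values: Sequence[float], types: Sequence[str]) -> AnovaResult:
    """One-way ANOVA of a measure across area types, with Tukey HSD post-hoc.

    Groups are taken in sorted label order; the Tukey adjusted p-values use
    the studentized range distribution.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(types)})
    labels = sorted(df["group"].unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = []
    for g in labels:
        x = df.loc[df["group"] == g, "value"].to_numpy()
        if len(x) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        samples.append(x)

    F, p = stats.f_oneway(*samples)
    res = stats.tukey_hsd(*samples)
    tukey: dict[tuple[str, str], tuple[float, float]] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            diff = float(np.mean(samples[i]) - np.mean(samples[j]))
            tukey[(labels[i], labels[j])] = (diff, float(res.pvalue[i, j]))

    group_stats = pd.DataFrame({
        "group": labels,
        "n": [len(s) for s in samples],
        "mean": [float(np.mean(s)) for s in samples],
        "sd": [float(np.std(s, ddof=1)) for s in samples],
    })
    n = len(df)
    return AnovaResult(
        F=float(F),
        df_between=len(labels) - 1,
        df_within=n - len(labels),
        p=float(p),
        group_stats=group_stats,
        tukey=tukey,
    )


# ----------------------------------------------------------------------
# negative binomial regression
# ----------------------------------------------------------------------

@dataclass
class NBModelResult:
    """Fitted NB2 regression: term -> (estimate, se, p), dispersion and fit
    statistics. ``aic = 2k - 2 llf`` and ``bic = k ln n - 2 llf`` with k
    counting the coefficients plus the dispersion parameter."""

    coefficients: dict[str, tuple[float, float, float]]
    alpha: float
    log_likelihood: float
    aic: float
    bic: float
    n: int
    label: str = ""

    def estimate(self, term: str) -> float:
        return self.coefficients[term][0]

    def pvalue(self, term: str) -> float:
        return self.coefficients[term][2]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t, e, s, p) for t, (e, s, p) in self.coefficients.items()],
            columns=["term", "estimate", "se", "p"],
        )


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    scale = np.linalg.norm(arr, axis=0)
    scale[scale == 0] = 1.0
    rank = np.linalg.matrix_rank(arr / scale)
    if rank < X.shape[1]:
        # name the offending terms via tiny R diagonal of a pivoted QR
        _, r = np.linalg.qr(arr / scale)
        diag = np.abs(np.diag(r))
        bad = [c for c, d in zip(X.columns, diag) if d < 1e-8 * diag.max()]
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad or list(X.columns)}")


def fit_nb(
    X: pd.DataFrame,
    y: Sequence[float],
    alpha: float | None = None,
    label: str = "",
) -> NBModelResult:
    """Maximum-likelihood NB2 regression with log link.

    The response is rounded to integer minutes. The dispersion ``alpha``
    (variance = mu + alpha mu^2) is estimated by profile maximum
    likelihood over a GLM fit unless fixed via the ``alpha`` argument; at
    the lower boundary (~0) the model coincides with Poisson regression.
    Coefficient p-values are two-sided Wald tests.
    """
    y_arr = np.rint(np.asarray(y, dtype=float))
    if np.any(y_arr < 0):
        raise ValueError("response must be nonnegative")
    if len(y_arr) != len(X):
        raise ValueError("response and design length mismatch")
    _check_full_rank(X)

    def fit_at(a: float):
        fam = sm.families.NegativeBinomial(alpha=a)
        model = sm.GLM(y_arr, X, family=fam)
        return model.fit(maxiter=200, tol=1e-10)

    if alpha is None:
        def nll(log_a: float) -> float:
            try:
                return -fit_at(float(np.exp(log_a))).llf
            except (np.linalg.LinAlgError, ValueError) as exc:
                raise ConvergenceError(f"GLM fit failed at alpha=e^{log_a:.3f}: {exc}")

        opt = optimize.minimize_scalar(
            nll, bounds=(np.log(MIN_ALPHA), np.log(MAX_ALPHA)),
            method="bounded", options={"xatol": 1e-7},
        )
        if not opt.success:
            raise ConvergenceError(f"dispersion profile failed: {opt.message}")
        alpha_hat = float(np.exp(opt.x))
    else:
        if alpha <= 0:
            raise ValueError("fixed alpha must be positive")
        alpha_hat = float(alpha)

    res = fit_at(alpha_hat)
    if not np.all(np.isfinite(res.params)):
        raise ConvergenceError("non-finite coefficients in NB fit")

    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    pvals = 2.0 * stats.norm.sf(np.abs(params / bse))
    coeffs = {
        term: (float(params[i]), float(bse[i]), float(pvals[i]))
        for i, term in enumerate(X.columns)
    }
    llf = float(res.llf)
    k = X.shape[1] + 1  # coefficients + dispersion
    n = len(y_arr)
    return NBModelResult(
        coefficients=coeffs,
        alpha=alpha_hat,
        log_likelihood=llf,
        aic=2 * k - 2 * llf,
        bic=k * np.log(n) - 2 * llf,
        n=n,
        label=label,
    )


# ----------------------------------------------------------------------
# disparity models
# ----------------------------------------------------------------------

BASE_COVARIATES = ("older_share", "high_edu_share", "median_income", "has_station")


def build_design(
    areas: pd.DataFrame,
    with_interaction: bool = False,
    income_scale: float = 1.0,
) -> pd.DataFrame:
    """Design matrix for a disparity model.

    Urban is the reference area type and the alphabetically first region is
    the reference region, so neither carries a column. ``income_scale``
    rescales median income (1.0 keeps raw currency units; 1e-3 puts the
    coefficient per 1,000 of income).
    """
    X = pd.DataFrame(index=areas.index)
    X["const"] = 1.0
    X["older_share"] = areas["older_share"].astype(float)
    X["high_edu_share"] = areas["high_edu_share"].astype(float)
    X["median_income"] = areas["median_income"].astype(float) * income_scale
    X["has_station"] = areas["has_station"].astype(float)
    # area-type dummies with urban as reference; when a (sub)sample lacks
    # the reference type (e.g. a quintile-5 subset with no urban areas)
    # the first present type takes its place so the design stays full rank
    names = {DENSELY_POPULATED: "dense", RURAL: "rural"}
    present = [t for t in (URBAN, DENSELY_POPULATED, RURAL)
               if (areas["area_type"] == t).any()]
    for t in present[1:]:
        X[names[t]] = (areas["area_type"] == t).astype(float)
    regions = sorted(areas["region"].unique())
    for r in regions[1:]:
        X[f"region[{r}]"] = (areas["region"] == r).astype(float)
    if with_interaction:
        if "rural" in X.columns:
            X["rural_x_older"] = X["rural"] * X["older_share"]
        # with rural constant the interaction would duplicate older_share
        # (all rural) or vanish (no rural): skip it either way
    # any remaining zero-variance column (e.g. has_station within a small
    # subset) would alias the intercept
    constant = [c for c in X.columns if c != "const" and X[c].nunique() == 1]
    X = X.drop(columns=constant)
    return _prune_aliased_dummies(X)


#: columns never pruned from a design; aliasing among these is an error
_PROTECTED_TERMS = ("const", "older_share", "high_edu_share", "median_income",
                    "rural_x_older")


def _prune_aliased_dummies(X: pd.DataFrame) -> pd.DataFrame:
    """Drop indicator columns made redundant by a (sub)sample's composition.

    Small quintile subsets can alias dummies (e.g. every region-b area in
    the subset is rural): rank-revealing QR identifies the redundant
    columns, and only indicator terms may be sacrificed — dependence
    involving the substantive covariates still raises downstream."""
    from scipy.linalg import qr as _qr

    arr = X.to_numpy(dtype=float)
    scale = np.linalg.norm(arr, axis=0)
    scale[scale == 0] = 1.0
    _, r, piv = _qr(arr / scale, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > 1e-10 * diag.max()))
    if rank == X.shape[1]:
        return X
    redundant = [X.columns[i] for i in piv[rank:]]
    droppable = [c for c in redundant if c not in _PROTECTED_TERMS]
    return X.drop(columns=droppable)


@dataclass(frozen=True)
class ModelSpec:
    measure: str                      # "rt" | "tt" | "tpt"
    with_interaction: bool = False
    subset: str = "all"               # "all" | "quintile5"

    @property
    def label(self) -> str:
        parts = [self.measure]
        if self.with_interaction:
            parts.append("interaction")
        if self.subset != "all":
            parts.append(self.subset)
        return "_".join(parts)


def fit_disparity_models(
    areas: pd.DataFrame,
    access: pd.DataFrame,
    spec: ModelSpec,
    income_scale: float = 1.0,
) -> NBModelResult:
    """Fit one disparity regression for a measure per a :class:`ModelSpec`.

    Merges the covariate and access tables on area_id, optionally restricts
    to the measure's 5th quintile, builds the design (with the rural x
    older-adults interaction when requested) and fits the NB2 model.
    """
    if spec.measure not in ("rt", "tt", "tpt"):
        raise ValueError(f"unknown measure {spec.measure!r}")
    data = areas.merge(access, on="area_id", validate="one_to_one")
    if spec.subset == "quintile5":
        data = data[data[f"quintile_{spec.measure}"] == 5]
    elif spec.subset != "all":
        raise ValueError(f"unknown subset {spec.subset!r}")
    if data.empty:
        raise ValueError(f"subset {spec.subset!r} is empty")
    data = data.reset_index(drop=True)
    X = build_design(data, with_interaction=spec.with_interaction,
                     income_scale=income_scale)
    if len(data) <= X.shape[1] + 1:
        raise ValueError(
            f"subset too small ({len(data)} rows) for design rank {X.shape[1]}"
        )
    y = data[f"{spec.measure}_min"]
    return fit_nb(X, y, label=spec.label)
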