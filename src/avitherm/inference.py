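"""Candidate-model construction, AICc ranking, model averaging and the
supporting diagnostics (VIF, t-tests).

The scientific question — do relative bill or leg surface areas predict
thermoregulatory traits? — is answered with a small-sample
information-theoretic workflow: every marginality-respecting subset of
{sex, bill index, tarsi index, bill x sex, tarsi x sex} (plus body mass
where relevant) is fitted as a Gaussian linear model, ranked by AICc,
and coefficients are averaged over the top model set (delta AICc < 2)
with unconditional standard errors.  Relative importance weights (RIW)
sum the Akaike weights of every candidate model containing a term.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelSpec",
    "LinearFit",
    "ModelTable",
    "AveragedCoefficients",
    "fit_lm",
    "aicc",
    "enumerate_models",
    "rank_models",
    "model_average",
    "riw",
    "vif",
    "two_sample_t",
    "paired_t",
    "DEFAULT_TERMS",
]

#: The candidate term pool used for most responses.  Interactions imply
#: their main effects (marginality).
DEFAULT_TERMS = ("sex", "bill_index", "tarsi_index",
                 "bill_index:sex", "tarsi_index:sex")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: a response name plus a term set."""

    response: str
    terms: frozenset[str]

    def __post_init__(self) -> None:
        for term in self.terms:
            if ":" in term:
                for main in term.split(":"):
                    if main not in self.terms:
                        raise ValueError(
                            f"interaction {term!r} requires main effect "
                            f"{main!r} (marginality)")

    @property
    def label(self) -> str:
        if not self.terms:
            return "Null"
        mains = sorted(t for t in self.terms if ":" not in t)
        inters = sorted(t for t in self.terms if ":" in t)
        return " + ".join(mains + inters)


@dataclass
class LinearFit:
    """OLS fit summary.  ``k`` counts coefficients plus the residual
    variance, so the intercept-only (null) model has k = 2."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    rss: float
    loglik: float
    k: int
    n: int
    r2: float
    flags: list[str] = field(default_factory=list)


@dataclass
class ModelTable:
    """Ranked candidate set: AICc, delta AICc and Akaike weights.

    Weights are computed over the *full* candidate set (they sum to 1
    there); the delta < 2 cut is only applied when reporting or
    averaging.
    """

    table: pd.DataFrame  # ranked ascending by AICc
    fits: list[LinearFit]  # same order as table rows

    def top_set(self, delta_cut: float = 2.0) -> "ModelTable":
        keep = self.table["dAICc"] < delta_cut
        return ModelTable(self.table[keep].reset_index(drop=True),
                          [f for f, k in zip(self.fits, keep) if k])


@dataclass
class AveragedCoefficients:
    """Model-averaged estimates with unconditional SEs, CIs and RIW."""

    table: pd.DataFrame  # index: term; columns: estimate, se, ci_lo, ci_hi, riw, significant
    averaged: bool  # False when a single dominant model was returned


def design_matrix(data: pd.DataFrame, terms: frozenset[str] | set[str],
                  ) -> pd.DataFrame:
    """Build the design for a term set from an individuals frame.

    ``sex`` is coded 0/1 with female as the reference level;
    interactions are products of their main-effect columns.
    """
    X = pd.DataFrame(index=data.index)
    X["Intercept"] = 1.0
    for term in sorted(terms, key=lambda t: (":" in t, t)):
        if ":" in term:
            a, b = term.split(":")
            X[term] = _numeric_column(data, a) * _numeric_column(data, b)
        else:
            X[term] = _numeric_column(data, term)
    return X


def _numeric_column(data: pd.DataFrame, name: str) -> pd.Series:
    col = data[name]
    if name == "sex":
        return (col == "M").astype(float) if col.dtype == object else \
            col.astype(float)
    return col.astype(float)


def fit_lm(X: pd.DataFrame, y: pd.Series | np.ndarray,
           spec: ModelSpec | None = None) -> LinearFit:
    """Gaussian OLS fit with the ML log-likelihood used by AICc.

    logLik = -n/2 (ln(2 pi RSS / n) + 1).  A perfect fit (RSS ~ 0) has
    an unbounded likelihood and is flagged ``degenerate`` rather than
    ranked.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than coefficients")
    if np.linalg.matrix_rank(X.to_numpy()) < p:
        raise ValueError("design matrix is rank deficient")
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    flags = []
    if rss < 1e-12 * max(float(np.var(y)) * n, 1.0):
        loglik = np.inf
        flags.append("degenerate_perfect_fit")
    else:
        loglik = -n / 2.0 * (np.log(2.0 * np.pi * rss / n) + 1.0)
    if spec is None:
        spec = ModelSpec("y", frozenset(c for c in X.columns
                                        if c != "Intercept"))
    return LinearFit(spec=spec, params=res.params, bse=res.bse, rss=rss,
                     loglik=float(loglik), k=p + 1, n=n,
                     r2=float(res.rsquared), flags=flags)


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with the small-sample correction.

    AICc = -2 logLik + 2k + 2k(k+1)/(n - k - 1).  ``k`` counts all
    estimated parameters including the residual variance.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def enumerate_models(terms: tuple[str, ...] = DEFAULT_TERMS,
                     response: str = "y") -> list[ModelSpec]:
    """All marginality-respecting subsets of the term pool (incl. null).

    For the standard five-term pool this yields 13 candidate models.
    """
    mains = [t for t in terms if ":" not in t]
    inters = [t for t in terms if ":" in t]
    specs = []
    for r in range(len(mains) + 1):
        for main_set in itertools.combinations(mains, r):
            allowed = [i for i in inters
                       if all(m in main_set for m in i.split(":"))]
            for s in range(len(allowed) + 1):
                for inter_set in itertools.combinations(allowed, s):
                    specs.append(ModelSpec(
                        response, frozenset(main_set) | frozenset(inter_set)))
    return specs


def rank_models(data: pd.DataFrame, response: str,
                specs: list[ModelSpec] | None = None,
                terms: tuple[str, ...] = DEFAULT_TERMS) -> ModelTable:
    """Fit and rank every candidate model for one response.

    Rows with missing response values are dropped before fitting, so
    ``n`` always reflects the rows actually used.
    """
    if specs is None:
        specs = enumerate_models(terms, response=response)
    mask = data[response].notna()
    sub = data[mask]
    fits = []
    for spec in specs:
        X = design_matrix(sub, spec.terms)
        fits.append(fit_lm(X, sub[response], spec=spec))
    usable = [f for f in fits if np.isfinite(f.loglik)]
    if not usable:
        raise ValueError("no finite-likelihood candidate model")
    rows = pd.DataFrame({
        "model": [f.spec.label for f in usable],
        "k": [f.k for f in usable],
        "logLik": [f.loglik for f in usable],
        "AICc": [aicc(f.loglik, f.k, f.n) for f in usable],
        "R2": [f.r2 for f in usable],
    })
    rows["dAICc"] = rows["AICc"] - rows["AICc"].min()
    rel = np.exp(-0.5 * rows["dAICc"].to_numpy())
    rows["weight"] = rel / rel.sum()
    order = np.argsort(rows["AICc"].to_numpy(), kind="stable")
    rows = rows.iloc[order].reset_index(drop=True)
    rows = rows[["model", "k", "logLik", "AICc", "dAICc", "weight", "R2"]]
    return ModelTable(rows, [usable[i] for i in order])


def model_average(table: ModelTable, delta_cut: float = 2.0,
                  dominant_weight: float = 0.9,
                  ci_z: float = 1.96) -> AveragedCoefficients:
    """Natural (conditional) model averaging over the top model set.

    Each coefficient is averaged over only those delta AICc < 2 models
    that contain it, with weights renormalized over that subset.  The
    unconditional SE follows Burnham & Anderson:
    sqrt(sum_i w_i (SE_i^2 + (b_i - b_bar)^2)).  If the top model alone
    carries weight >= ``dominant_weight``, its coefficients are returned
    unaveraged.  A term is "significant" when its CI excludes zero.
    """
    if len(table.fits) == 0:
        raise ValueError("empty model table")
    top = table.top_set(delta_cut)
    if table.table["weight"].iloc[0] >= dominant_weight or len(top.fits) == 1:
        fit = table.fits[0]
        rows = _coefficient_rows(
            [(fit, 1.0)], table, ci_z)
        return AveragedCoefficients(rows, averaged=False)
    weights = top.table["weight"].to_numpy()
    pairs = list(zip(top.fits, weights))
    rows = _coefficient_rows(pairs, table, ci_z)
    return AveragedCoefficients(rows, averaged=True)


def _coefficient_rows(pairs, full_table: ModelTable, ci_z: float,
                      ) -> pd.DataFrame:
    coef_names: list[str] = []
    for fit, _ in pairs:
        for name in fit.params.index:
            if name not in coef_names:
                coef_names.append(name)
    records = {}
    for name in coef_names:
        present = [(f, w) for f, w in pairs if name in f.params.index]
        w = np.array([w for _, w in present])
        w = w / w.sum()
        est = np.array([f.params[name] for f, _ in present])
        se = np.array([f.bse[name] for f, _ in present])
        mean = float(np.sum(w * est))
        unc_se = float(np.sqrt(np.sum(w * (se ** 2 + (est - mean) ** 2))))
        lo, hi = mean - ci_z * unc_se, mean + ci_z * unc_se
        records[name] = {
            "estimate": mean, "se": unc_se, "ci_lo": lo, "ci_hi": hi,
            "riw": np.nan if name == "Intercept" else riw(name, full_table),
            "significant": bool(lo > 0 or hi < 0),
        }
    return pd.DataFrame(records).T


def riw(term: str, table: ModelTable) -> float:
    """Relative importance weight: summed Akaike weights of all candidate
    models containing ``term``."""
    known = set()
    for fit in table.fits:
        known |= fit.spec.terms
    if term not in known and term != "Intercept":
        raise ValueError(f"term {term!r} appears in no candidate model")
    total = 0.0
    for fit, w in zip(table.fits, table.table["weight"]):
        if term in fit.spec.terms:
            total += float(w)
    return total


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors of the main-effects design.

    ``VIF_j = 1 / (1 - R2_j)`` from regressing predictor j on the other
    predictors (plus an intercept).  Perfectly collinear predictors are
    reported as ``inf``.  Pass main effects only; interactions inflate
    VIF trivially.
    """
    cols = [c for c in X.columns if c != "Intercept"]
    if len(cols) < 2:
        raise ValueError("VIF needs at least two predictors")
    out = {}
    for col in cols:
        others = sm.add_constant(X[[c for c in cols if c != col]].astype(float))
        r2 = sm.OLS(X[col].astype(float), others).fit().rsquared
        out[col] = np.inf if r2 > 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def two_sample_t(a, b) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test; returns (t, df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    df = a.size + b.size - 2
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, df, 1.0
        return np.inf, df, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), df, float(p)


def paired_t(a, b) -> tuple[float, int, float]:
    """Paired t-test on matched observations; returns (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    df = a.size - 1
    if np.var(d, ddof=1) == 0:
        if np.mean(d) == 0:
            return 0.0, df, 1.0
        return np.inf if np.mean(d) > 0 else -np.inf, df, 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), df, float(p)
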