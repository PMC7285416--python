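"""Multiple linear regression of study-level effect sizes on study covariates.

For one gene, each study contributes its LFC as the response; covariates come
from the study metadata.  Numeric factors enter as-is; categorical factors are
one-hot coded against a first-level reference.  Each factor gets one p-value:
the coefficient t-test for single-column factors and a partial F-test for
multi-level categorical factors.  With ~10 studies and a many-level factor
such as country the design is close to saturated, so the fit warns when the
residual degrees of freedom drop below 3 and refuses when none remain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .effect_size import StudyEffect
from .errors import MulticollinearityError, ValidationError
from .io import StudyMetadata

#: factor name → metadata attribute (or derived quantity)
_NUMERIC_FACTORS = {
    "n_total": lambda s: s.n_total,
    "n_control": lambda s: s.n_control,
    "n_case": lambda s: s.n_case,
    "sample_size": lambda s: s.n_total,
    "study_age": lambda s: s.study_age_years,
    "study_age_years": lambda s: s.study_age_years,
}
_CATEGORICAL_FACTORS = {"country": lambda s: s.country, "organism": lambda s: s.organism}


@dataclass(frozen=True)
class MLRResult:
    """OLS results for one gene: per-factor p-values (joint for multi-level
    categoricals), term coefficients, R² and the study count."""

    gene: str
    factor_p: Mapping[str, float]
    coefficients: Mapping[str, float]
    n_studies: int
    r2: float
    residual_df: int

    def summary(self) -> str:
        lines = [
            f"MLR of {self.gene} study-level LFC on covariates "
            f"(k={self.n_studies}, R2={self.r2:.3f}, resid df={self.residual_df})",
            f"  {'factor':<18}{'p':>12}",
        ]
        for f, p in self.factor_p.items():
            lines.append(f"  {f:<18}{p:>12.4g}")
        return "\n".join(lines)


def _design(
    effects: Sequence[StudyEffect],
    studies: Sequence[StudyMetadata],
    factors: Sequence[str],
) -> tuple[pd.Series, pd.DataFrame, dict[str, list[str]]]:
    by_id = {s.study_id: s for s in studies}
    missing = [e.study_id for e in effects if e.study_id not in by_id]
    if missing:
        raise ValidationError(f"effects reference unknown study(ies): {', '.join(missing)}")
    # canonical row order: sort by study_id so permuting input order is a no-op
    ordered = sorted(effects, key=lambda e: e.study_id)
    y = pd.Series([e.lfc for e in ordered], index=[e.study_id for e in ordered], name="lfc")
    cols: dict[str, list[float]] = {}
    factor_cols: dict[str, list[str]] = {}
    for f in factors:
        metas = [by_id[e.study_id] for e in ordered]
        if f in _NUMERIC_FACTORS:
            cols[f] = [float(_NUMERIC_FACTORS[f](m)) for m in metas]
            factor_cols[f] = [f]
        elif f in _CATEGORICAL_FACTORS:
            levels = pd.Series([_CATEGORICAL_FACTORS[f](m) for m in metas])
            dummies = pd.get_dummies(levels, prefix=f, drop_first=True, dtype=float)
            factor_cols[f] = list(dummies.columns)
            for c in dummies.columns:
                cols[c] = list(dummies[c])
        else:
            raise ValidationError(
                f"unknown factor {f!r}; known: "
                + ", ".join(sorted((*_NUMERIC_FACTORS, *_CATEGORICAL_FACTORS)))
            )
    X = pd.DataFrame(cols, index=y.index)
    X.insert(0, "const", 1.0)
    return y, X, factor_cols


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    _, R = np.linalg.qr(X.to_numpy())
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [c for c, d in zip(X.columns, diag) if d <= tol]


def fit_mlr(
    effects: Sequence[StudyEffect],
    studies: Sequence[StudyMetadata],
    factors: Sequence[str],
    weighted: bool = False,
) -> MLRResult:
    """Regress one gene's per-study LFCs on study-level factors.

    Parameters
    ----------
    factors
        Names among ``n_total``/``n_control``/``n_case``/``sample_size``
        (numeric), ``study_age`` (numeric), ``country``/``organism``
        (categorical).
    weighted
        If true, weight studies by 1/se² (WLS); default is plain OLS.
    """
    if not factors:
        raise ValidationError("at least one factor is required")
    genes = {e.gene for e in effects}
    if len(genes) != 1:
        raise ValidationError(f"effects must be for a single gene, got {sorted(genes)}")
    y, X, factor_cols = _design(effects, studies, factors)
    k, p = X.shape
    if k < p + 1:
        raise ValidationError(
            f"need at least {p + 1} studies to fit {p} parameters, got {k}"
        )
    if np.linalg.matrix_rank(X.to_numpy()) < p:
        raise MulticollinearityError(_aliased_columns(X))
    resid_df = k - p
    if resid_df <= 0:
        raise ValidationError(f"no residual degrees of freedom (k={k}, params={p})")
    if resid_df < 3:
        warnings.warn(
            f"only {resid_df} residual df; factor p-values will be unstable",
            stacklevel=2,
        )
    if weighted:
        w = np.array([1.0 / sorted(effects, key=lambda e: e.study_id)[i].se ** 2 for i in range(k)])
        res = sm.WLS(y, X, weights=w).fit()
    else:
        res = sm.OLS(y, X).fit()
    factor_p: dict[str, float] = {}
    for f, colnames in factor_cols.items():
        if len(colnames) == 1:
            factor_p[f] = float(res.pvalues[colnames[0]])
        else:
            contrast = np.zeros((len(colnames), p))
            for i, c in enumerate(colnames):
                contrast[i, list(X.columns).index(c)] = 1.0
            factor_p[f] = float(res.f_test(contrast).pvalue)
    return MLRResult(
        gene=next(iter(genes)),
        factor_p=factor_p,
        coefficients={c: float(res.params[c]) for c in X.columns},
        n_studies=k,
        r2=float(res.rsquared),
        residual_df=resid_df,
    )
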