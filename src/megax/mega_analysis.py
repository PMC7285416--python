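"""Fixed/random-effects pooling of per-study log fold changes ("mega-analysis").

Model
-----
Each study *i* contributes an effect ``y_i`` (log2 fold change) with
within-study variance ``se_i²``.  Cochran's heterogeneity statistic is

    Q = Σ w_i (y_i − ŷ_F)²,   w_i = 1/se_i²,   df = k − 1

with ``I² = 100·max(0, (Q − df)/Q)`` and the DerSimonian–Laird moment
estimate ``τ² = max(0, (Q − df) / (Σw − Σw²/Σw))``.  The pooled estimate is
the inverse-variance weighted mean, with random-effects weights
``1/(se_i² + τ²)``.  Model selection follows the heterogeneity rule: the
fixed-effects model is chosen iff ``Q ≤ df`` (equivalently the truncated I²
is zero), otherwise the random-effects model.

The *partial* mega-analysis re-pools only the top fraction of studies ranked
by absolute effect size (default the top half, minimum two studies) — a
deliberate screen for genes that move strongly in a subset of datasets.  By
construction this selection inflates the pooled effect magnitude under the
null; see the package methods note.

:class:`MegaAnalysis` is the model object (statsmodels-style); its
:meth:`~MegaAnalysis.fit` returns a :class:`MegaResult` carrying estimates,
CI, p-value, heterogeneity diagnostics and normalized study weights.  The
module-level functions (:func:`heterogeneity`, :func:`pool`,
:func:`mega_analyze`, :func:`select_top_datasets`,
:func:`partial_mega_analyze`) are thin functional entry points over the same
code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effect_size import StudyEffect
from .errors import InsufficientStudiesError, ValidationError

Z975 = float(stats.norm.ppf(0.975))  # 1.959964...


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q with df = k−1, the I² percentage, the chi-square upper-tail
    p of Q, and the DerSimonian–Laird between-study variance τ²."""

    Q: float
    df: int
    ISq_pct: float
    p_Q: float
    tau2: float


@dataclass(frozen=True)
class MegaResult:
    """Pooled-effect results object.

    Carries the selected model, pooled LFC with SE / 95% CI / two-sided normal
    p-value, the heterogeneity diagnostics, per-study weights normalized so
    the largest is 1 (forest-plot convention), and the studies pooled.
    """

    gene: str
    model: Literal["fixed", "random"]
    k_studies: int
    pooled_lfc: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    het: HeterogeneityStats
    weights: dict[str, float] = field(default_factory=dict)
    studies_used: tuple[str, ...] = ()
    effects: tuple[StudyEffect, ...] = ()

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        h = self.het
        lines = [
            f"Mega-analysis of {self.gene} ({self.k_studies} studies, {self.model}-effects model)",
            "=" * 72,
            f"  pooled LFC {self.pooled_lfc: .4f}   SE {self.se:.4f}   "
            f"95% CI [{self.ci95[0]: .4f}, {self.ci95[1]: .4f}]   p {self.p_value:.3g}",
            f"  Q {h.Q:.4f} (df {h.df}, p {h.p_Q:.3g})   ISq {h.ISq_pct:.2f}%   tau2 {h.tau2:.4f}",
            "-" * 72,
            f"  {'study':<12}{'LFC':>9}{'SE':>9}{'weight':>9}",
        ]
        for e in self.effects:
            lines.append(
                f"  {e.study_id:<12}{e.lfc:>9.3f}{e.se:>9.3f}{self.weights[e.study_id]:>9.3f}"
            )
        return "\n".join(lines)

    def forest_frame(self) -> pd.DataFrame:
        """Per-study forest-plot coordinates: LFC, 95% CI, normalized weight."""
        return pd.DataFrame(
            {
                "study_id": [e.study_id for e in self.effects],
                "lfc": [e.lfc for e in self.effects],
                "ci_low": [e.lfc - Z975 * e.se for e in self.effects],
                "ci_high": [e.lfc + Z975 * e.se for e in self.effects],
                "weight": [self.weights[e.study_id] for e in self.effects],
            }
        )

    def plot_forest(self, ax=None):
        """Forest plot: per-study effects with CIs, weight bars, pooled diamond."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.5 * self.k_studies + 1.5))
        frame = self.forest_frame()
        y = np.arange(len(frame))[::-1]
        ax.hlines(y, frame["ci_low"], frame["ci_high"], color="steelblue")
        ax.scatter(frame["lfc"], y, marker="*", color="crimson", zorder=3)
        ax.barh(y, frame["weight"], height=0.25, left=ax.get_xlim()[1], color="yellowgreen")
        ax.axvline(0.0, color="grey", lw=0.8, ls=":")
        ax.axvline(self.pooled_lfc, color="black", lw=1.0, ls="--")
        ax.set_yticks(y, frame["study_id"])
        ax.set_xlabel("log2 fold change")
        ax.set_title(f"{self.gene} ({self.model}-effects pooled LFC {self.pooled_lfc:.2f})")
        return ax

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "model": self.model,
            "k_studies": self.k_studies,
            "pooled_lfc": self.pooled_lfc,
            "se": self.se,
            "ci95": list(self.ci95),
            "p_value": self.p_value,
            "het": {
                "Q": self.het.Q,
                "df": self.het.df,
                "ISq_pct": self.het.ISq_pct,
                "p_Q": self.het.p_Q,
                "tau2": self.het.tau2,
            },
            "weights": dict(self.weights),
            "studies_used": list(self.studies_used),
            "forest": self.forest_frame().to_dict(orient="records"),
        }


def _validate(effects: Sequence[StudyEffect]) -> tuple[np.ndarray, np.ndarray]:
    if len(effects) < 2:
        raise InsufficientStudiesError(f"pooling needs k >= 2 studies, got {len(effects)}")
    genes = {e.gene for e in effects}
    if len(genes) > 1:
        raise ValidationError(f"effects mix genes: {sorted(genes)}")
    se = np.array([e.se for e in effects], dtype=float)
    if np.any(se <= 0):
        bad = [e.study_id for e in effects if e.se <= 0]
        raise ValidationError(f"non-positive SE for study(ies): {', '.join(bad)}")
    lfc = np.array([e.lfc for e in effects], dtype=float)
    return lfc, se


def heterogeneity(effects: Sequence[StudyEffect]) -> HeterogeneityStats:
    """Cochran's Q, I², p(Q) and DerSimonian–Laird τ² for one gene's effects."""
    lfc, se = _validate(effects)
    w = 1.0 / se**2
    fixed = float(np.sum(w * lfc) / np.sum(w))
    Q = float(np.sum(w * (lfc - fixed) ** 2))
    df = len(effects) - 1
    isq = 100.0 * max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (Q - df) / c) if c > 0 else 0.0
    if Q <= df:
        tau2 = 0.0
    p_q = float(stats.chi2.sf(Q, df))
    return HeterogeneityStats(Q=Q, df=df, ISq_pct=isq, p_Q=p_q, tau2=tau2)


def pool(effects: Sequence[StudyEffect], model: Literal["fixed", "random"]) -> MegaResult:
    """Inverse-variance pooling under the given model.

    Fixed-effects weights are ``1/se²``; random-effects weights are
    ``1/(se² + τ²)`` with τ² estimated by DerSimonian–Laird from the same
    effects.
    """
    if model not in ("fixed", "random"):
        raise ValidationError(f"model must be 'fixed' or 'random', got {model!r}")
    lfc, se = _validate(effects)
    het = heterogeneity(effects)
    tau2 = het.tau2 if model == "random" else 0.0
    w = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w * lfc) / np.sum(w))
    pooled_se = float(1.0 / math.sqrt(np.sum(w)))
    z = pooled / pooled_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    norm_w = w / w.max()
    return MegaResult(
        gene=effects[0].gene,
        model=model,
        k_studies=len(effects),
        pooled_lfc=pooled,
        se=pooled_se,
        ci95=(pooled - Z975 * pooled_se, pooled + Z975 * pooled_se),
        p_value=p,
        het=het,
        weights={e.study_id: float(nw) for e, nw in zip(effects, norm_w)},
        studies_used=tuple(e.study_id for e in effects),
        effects=tuple(effects),
    )


def mega_analyze(effects: Sequence[StudyEffect]) -> MegaResult:
    """Pool with automatic model selection: fixed iff Q ≤ df, else random."""
    het = heterogeneity(effects)
    model: Literal["fixed", "random"] = "fixed" if het.Q <= het.df else "random"
    return pool(effects, model)


def select_top_datasets(effects: Sequence[StudyEffect], fraction: float = 0.5) -> list[StudyEffect]:
    """The ``floor(k·fraction)`` effects with largest \\|LFC\\| (minimum 2).

    Ties are broken by input order (stable sort), and the returned subset
    preserves input order.
    """
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    k = len(effects)
    m = math.floor(k * fraction)
    if m < 2:
        raise InsufficientStudiesError(
            f"top-{fraction:g} of {k} studies keeps {m}; need at least 2"
        )
    ranked = sorted(range(k), key=lambda i: -abs(effects[i].lfc))  # stable
    keep = sorted(ranked[:m])
    return [effects[i] for i in keep]


def partial_mega_analyze(effects: Sequence[StudyEffect], fraction: float = 0.5) -> MegaResult:
    """Mega-analysis restricted to the top-|LFC| fraction of studies."""
    return mega_analyze(select_top_datasets(effects, fraction))


class MegaAnalysis:
    """Model object for pooling one gene's per-study effects.

    Parameters
    ----------
    effects
        Per-study :class:`~megax.effect_size.StudyEffect` records, all for
        the same gene, each with a positive SE.

    Examples
    --------
    >>> model = MegaAnalysis(effects)
    >>> res = model.fit()                 # heterogeneity-driven model choice
    >>> res_fixed = model.fit(model="fixed")
    >>> res_top = model.fit_partial(0.5)  # top half by |LFC|
    """

    def __init__(self, effects: Sequence[StudyEffect]):
        _validate(effects)
        self.effects = list(effects)
        self.gene = effects[0].gene

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, gene: str | None = None) -> "MegaAnalysis":
        """Build from a tidy effect table with columns ``study_id``, ``gene``,
        ``lfc``, ``se``, ``n_control``, ``n_case``."""
        if gene is not None:
            df = df[df["gene"] == gene]
        effects = [
            StudyEffect(
                study_id=str(r.study_id),
                gene=str(r.gene),
                lfc=float(r.lfc),
                se=float(r.se),
                n_control=int(r.n_control),
                n_case=int(r.n_case),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(effects)

    def heterogeneity(self) -> HeterogeneityStats:
        return heterogeneity(self.effects)

    def fit(self, model: Literal["fixed", "random"] | None = None) -> MegaResult:
        if model is None:
            return mega_analyze(self.effects)
        return pool(self.effects, model)

    def fit_partial(self, fraction: float = 0.5) -> MegaResult:
        return partial_mega_analyze(self.effects, fraction)
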