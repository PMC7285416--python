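"""Multi-study case/control expression simulator with known ground truth.

Generative model (log2 scale throughout):

* each gene *g* has a true log2 fold change δ_g and a per-gene baseline
  μ_g ~ U(baseline_range);
* each study *s* perturbs the effect: δ_gs = δ_g + covariate shifts for the
  study's metadata + N(0, τ²);
* control samples ~ N(μ_g, σ²), case samples ~ N(μ_g + δ_gs, σ²) with
  σ = ``base_noise_sd``.

:func:`simulate_effect_table` is the effect-level shortcut that skips the
matrices and emits (LFC, SE) pairs directly from the implied marginal,
``LFC ~ N(δ_g + shifts, τ² + SE²)`` with ``SE = σ·sqrt(1/n_control +
1/n_case)``; the two simulators agree in distribution.

Randomness is drawn from streams keyed by ``(seed, purpose, study_id, gene)``
so any study/gene block can be regenerated independently and results are
invariant to generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

from .effect_size import StudyEffect
from .errors import ValidationError
from .io import ExpressionStudy, StudyMetadata

#: covariate effect spec: either {level: shift} for categorical covariates or
#: a per-unit slope for numeric ones
CovariateEffect = Union[Mapping[str, float], float]


def _stream(seed: int, *keys: object) -> np.random.Generator:
    """Deterministic RNG keyed by (seed, *keys); order-independent by design."""
    words = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(words)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of a simulated collection.

    ``gene_truth`` maps gene → true δ (log2 fold change); ``tau2`` is the
    between-study variance of the study-level effect; ``covariate_effects``
    maps a :class:`~megax.io.StudyMetadata` field to either a {level: shift}
    table (categorical) or a per-unit slope (numeric); ``base_noise_sd`` is
    the per-sample residual SD on the log2 scale.
    """

    gene_truth: Mapping[str, float]
    tau2: float = 0.0
    covariate_effects: Mapping[str, CovariateEffect] = field(default_factory=dict)
    base_noise_sd: float = 1.0
    baseline_range: tuple[float, float] = (6.0, 10.0)
    seed: int = 0

    def __post_init__(self):
        if self.tau2 < 0:
            raise ValidationError(f"tau2 must be >= 0, got {self.tau2}")
        if self.base_noise_sd <= 0:
            raise ValidationError(f"base_noise_sd must be > 0, got {self.base_noise_sd}")
        if not self.gene_truth:
            raise ValidationError("gene_truth must name at least one gene")

    def covariate_shift(self, study: StudyMetadata) -> float:
        """Total additive shift on δ implied by the study's covariates."""
        total = 0.0
        for cov, eff in self.covariate_effects.items():
            value = getattr(study, cov)
            if isinstance(eff, Mapping):
                total += float(eff.get(value, 0.0))
            else:
                total += float(eff) * float(value)
        return total

    def study_effect_mean(self, study: StudyMetadata, gene: str) -> float:
        return float(self.gene_truth[gene]) + self.covariate_shift(study)


def study_level_effect(truth: SimulationTruth, study: StudyMetadata, gene: str) -> float:
    """Realized δ_gs: mean effect plus the N(0, τ²) between-study deviation."""
    mean = truth.study_effect_mean(study, gene)
    if truth.tau2 == 0:
        return mean
    rng = _stream(truth.seed, "study-effect", study.study_id, gene)
    return mean + rng.normal(0.0, np.sqrt(truth.tau2))


def simulate_collection(
    truth: SimulationTruth, studies: Sequence[StudyMetadata]
) -> list[ExpressionStudy]:
    """Simulate full expression matrices for every study in *studies*."""
    if not studies:
        raise ValidationError("studies must be nonempty")
    genes = list(truth.gene_truth)
    out: list[ExpressionStudy] = []
    for s in studies:
        values = np.empty((len(genes), s.n_total))
        for i, g in enumerate(genes):
            mu = float(_stream(truth.seed, "baseline", g).uniform(*truth.baseline_range))
            delta_gs = study_level_effect(truth, s, g)
            rng = _stream(truth.seed, "samples", s.study_id, g)
            values[i, : s.n_control] = rng.normal(mu, truth.base_noise_sd, s.n_control)
            values[i, s.n_control :] = rng.normal(mu + delta_gs, truth.base_noise_sd, s.n_case)
        group = ["control"] * s.n_control + ["case"] * s.n_case
        sample_ids = [f"{s.study_id}.{j + 1}" for j in range(s.n_total)]
        out.append(
            ExpressionStudy(
                metadata=s, genes=genes, values=values, group=group,
                sample_ids=sample_ids, scale="log2",
            )
        )
    return out


def simulate_effect_table(
    truth: SimulationTruth, studies: Sequence[StudyMetadata]
) -> list[StudyEffect]:
    """Simulate per-study (LFC, SE) pairs directly, skipping the matrices.

    The SE is reported at its true value ``σ·sqrt(1/n_control + 1/n_case)``
    and the LFC is drawn from the marginal N(δ + shifts, τ² + SE²).
    """
    if not studies:
        raise ValidationError("studies must be nonempty")
    effects: list[StudyEffect] = []
    for s in studies:
        se = truth.base_noise_sd * np.sqrt(1.0 / s.n_control + 1.0 / s.n_case)
        for g in genes_of(truth):
            mean = truth.study_effect_mean(s, g)
            rng = _stream(truth.seed, "effect", s.study_id, g)
            lfc = rng.normal(mean, np.sqrt(truth.tau2 + se**2))
            effects.append(
                StudyEffect(
                    study_id=s.study_id, gene=g, lfc=float(lfc), se=float(se),
                    n_control=s.n_control, n_case=s.n_case,
                )
            )
    return effects


def genes_of(truth: SimulationTruth) -> list[str]:
    return list(truth.gene_truth)


def default_study_grid(
    k: int = 11, n_control: int = 30, n_case: int = 30, country: str | Sequence[str] = "A"
) -> list[StudyMetadata]:
    """Convenience grid of k equally sized synthetic studies (SIM001..)."""
    if isinstance(country, str):
        countries = [country] * k
    else:
        countries = list(country)
        if len(countries) != k:
            raise ValidationError("country list length must equal k")
    return [
        StudyMetadata(
            study_id=f"SIM{i + 1:03d}", n_control=n_control, n_case=n_case,
            country=countries[i], study_age_years=float(i + 1),
        )
        for i in range(k)
    ]
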