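"""Signed regulatory network assembly from literature relations.

Two networks connect a *driver* gene (e.g. PPARG) to a *disease* entity:

* the **diagnostic network** collects genes regulated contra-directionally
  by driver and disease — disease-up & driver-inhibited genes are *positive
  markers*, disease-down & driver-activated genes are *negative markers*.
  Each marker can additionally be checked for consistency against the pooled
  expression direction from the mega-analysis; inconsistent genes stay in
  the network but are excluded from the default marker report.
* the **prognostic network** collects driver→gene→disease chains: genes the
  driver inhibits that promote the disease (*promoters*) and genes the
  driver activates that inhibit it (*inhibitors*).  Pooled directions are
  attached for annotation only — no filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ValidationError
from .io import SignedRelation
from .mega_analysis import MegaResult

#: pooled effects smaller than this are treated as directionless
_DIRECTION_EPS = 1e-9


@dataclass
class MarkerNetwork:
    """Contra-directional (diagnostic) marker network around a driver gene."""

    driver: str
    disease: str
    positive_markers: list[str]
    negative_markers: list[str]
    edges: list[SignedRelation]
    consistency: dict[str, str] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return self.positive_markers + self.negative_markers

    def report(self, include_inconsistent: bool = False) -> dict[str, list[str]]:
        """Marker lists for reporting; by default drops genes whose pooled
        expression direction contradicts the literature direction."""
        def keep(g: str) -> bool:
            return include_inconsistent or self.consistency.get(g) != "inconsistent"

        return {
            "positive_markers": [g for g in self.positive_markers if keep(g)],
            "negative_markers": [g for g in self.negative_markers if keep(g)],
        }

    def to_dict(self) -> dict:
        return {
            "driver": self.driver,
            "disease": self.disease,
            "positive_markers": list(self.positive_markers),
            "negative_markers": list(self.negative_markers),
            "consistency": dict(self.consistency),
            "report": self.report(),
        }


@dataclass
class RegulatorChain:
    """Driver→gene→disease (prognostic) chains around a driver gene."""

    driver: str
    disease: str
    promoters: list[str]
    inhibitors: list[str]
    edges: list[SignedRelation]
    pooled_direction: dict[str, int] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return self.promoters + self.inhibitors

    def to_dict(self) -> dict:
        return {
            "driver": self.driver,
            "disease": self.disease,
            "promoters": list(self.promoters),
            "inhibitors": list(self.inhibitors),
            "pooled_direction": dict(self.pooled_direction),
        }


def _polarity_map(
    relations: Sequence[SignedRelation], role: str
) -> dict[tuple[str, str], int]:
    """Collapse relations to {(source,target): polarity}, rejecting conflicts."""
    out: dict[tuple[str, str], int] = {}
    for r in relations:
        key = (r.source, r.target)
        if key in out and out[key] != r.polarity:
            raise ValidationError(
                f"conflicting polarities for {role} relation {r.source}->{r.target}"
            )
        out[key] = r.polarity
    return out


def _sign(x: float) -> int:
    if abs(x) < _DIRECTION_EPS:
        return 0
    return 1 if x > 0 else -1


def build_diagnostic_network(
    relations: Sequence[SignedRelation],
    driver: str,
    disease: str,
    mega: Mapping[str, MegaResult] | None = None,
) -> MarkerNetwork:
    """Assemble the contra-directional marker network.

    A gene is a positive marker iff the disease edge is +1 and the driver
    edge is −1, a negative marker iff both are reversed.  With *mega*
    supplied, each marker's pooled LFC sign is compared to the disease
    polarity; pooled effects within 1e-9 of zero are 'untested'.
    Marker lists preserve relation-table order (first appearance of the
    disease edge), so row order only affects presentation, not membership.
    Two edges between the same pair with opposing polarity (under any
    relation kind) are rejected as conflicting.
    """
    driver_pol = _polarity_map(
        [r for r in relations if r.source == driver], "driver"
    )
    disease_pol = _polarity_map(
        [r for r in relations if r.source == disease], "disease"
    )
    positive: list[str] = []
    negative: list[str] = []
    edges: list[SignedRelation] = []
    consistency: dict[str, str] = {}
    for (src, gene), dpol in disease_pol.items():
        gpol = driver_pol.get((driver, gene))
        if gpol is None or gpol != -dpol:
            continue  # not contra-directional (or no driver edge)
        (positive if dpol == 1 else negative).append(gene)
        edges.extend(r for r in relations if r.target == gene and r.source in (driver, disease))
        if mega is None or gene not in mega:
            consistency[gene] = "untested"
        else:
            s = _sign(mega[gene].pooled_lfc)
            consistency[gene] = "untested" if s == 0 else ("consistent" if s == dpol else "inconsistent")
    return MarkerNetwork(
        driver=driver,
        disease=disease,
        positive_markers=positive,
        negative_markers=negative,
        edges=edges,
        consistency=consistency,
    )


def build_prognostic_network(
    relations: Sequence[SignedRelation],
    driver: str,
    disease: str,
    mega: Mapping[str, MegaResult] | None = None,
) -> RegulatorChain:
    """Assemble driver→gene→disease chains.

    Promoters: driver ┤ gene and gene ⊕ disease.  Inhibitors: driver ⊕ gene
    and gene ┤ disease.  Pooled LFC directions are attached for annotation
    only; no gene is dropped for moving with rather than against the
    literature direction.
    """
    driver_pol = _polarity_map(
        [r for r in relations if r.source == driver], "driver"
    )
    to_disease = _polarity_map(
        [r for r in relations if r.target == disease], "disease"
    )
    promoters: list[str] = []
    inhibitors: list[str] = []
    edges: list[SignedRelation] = []
    for (gene, _), gdpol in to_disease.items():
        dpol = driver_pol.get((driver, gene))
        if dpol is None:
            continue
        if dpol == -1 and gdpol == 1:
            promoters.append(gene)
        elif dpol == 1 and gdpol == -1:
            inhibitors.append(gene)
        else:
            continue
        edges.extend(
            r for r in relations
            if (r.source == driver and r.target == gene) or (r.source == gene and r.target == disease)
        )
    direction = {}
    if mega:
        direction = {g: _sign(mega[g].pooled_lfc) for g in promoters + inhibitors if g in mega}
    return RegulatorChain(
        driver=driver,
        disease=disease,
        promoters=promoters,
        inhibitors=inhibitors,
        edges=edges,
        pooled_direction=direction,
    )
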