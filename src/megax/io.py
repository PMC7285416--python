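"""Readers and writers for every external table the pipeline touches.

Formats
-------
* **Expression study TSV** (canonical dialect): row 1 is ``gene`` followed by
  sample identifiers, row 2 is ``group`` followed by per-sample labels
  (``control`` / ``case``), each further row is a gene symbol followed by its
  expression values.  Missing values are encoded as ``NA``.
* **Study-metadata TSV**: columns ``study_id``, ``n_control``, ``n_case``,
  ``country``, ``study_age_years`` and optionally ``organism``.
* **Signed-relation TSV**: columns ``source``, ``target``, ``polarity``
  (``+``/``-``/``+1``/``-1``), ``kind`` (``regulation`` or
  ``disease_association``) and ``provenance``.
* **GMT** gene-set collections (name, external id, members).

The printed study table and the two literature-relation networks from the
source study are packaged as fixtures and exposed through
:func:`load_table1_studies`, :func:`load_diagnostic_relations` and
:func:`load_prognostic_relations`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

GROUP_CONTROL = "control"
GROUP_CASE = "case"
_VALID_GROUPS = {GROUP_CONTROL, GROUP_CASE}
_VALID_KINDS = {"regulation", "disease_association"}

#: Optional alias map for symbols printed non-standardly in the source
#: figures.  Off by default; pass to readers explicitly to apply.
SYMBOL_ALIASES = {"MI21": "MIR21"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyMetadata:
    """Study-level record: accession, group sizes and the covariates used by
    the influential-factor regression (country, study age, sample size)."""

    study_id: str
    n_control: int
    n_case: int
    country: str = ""
    study_age_years: float = 0.0
    organism: str = "Homo sapiens"

    def __post_init__(self):
        if self.n_control < 1 or self.n_case < 1:
            raise ValidationError(
                f"{self.study_id}: n_control and n_case must be >= 1 "
                f"(got {self.n_control}/{self.n_case})"
            )
        if self.study_age_years < 0:
            raise ValidationError(f"{self.study_id}: study_age_years must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_control + self.n_case


@dataclass
class ExpressionStudy:
    """One case/control expression matrix (genes x samples) with group labels.

    ``values[i, j]`` is the expression of ``genes[i]`` in sample
    ``sample_ids[j]``; ``group[j]`` labels that sample ``control`` or ``case``.
    ``scale`` records whether values are raw intensities or log2.
    """

    metadata: StudyMetadata
    genes: list[str]
    values: np.ndarray
    group: list[str]
    sample_ids: list[str] = field(default_factory=list)
    scale: Literal["linear", "log2"] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape[0] != len(self.genes):
            raise ValidationError("row count does not match number of genes")
        if self.values.shape[1] != len(self.group):
            raise ValidationError("column count does not match number of group labels")
        if not self.sample_ids:
            self.sample_ids = [f"S{j + 1}" for j in range(self.values.shape[1])]
        if len(self.sample_ids) != len(self.group):
            raise ValidationError("sample_ids length does not match group labels")
        bad = sorted(set(self.group) - _VALID_GROUPS)
        if bad:
            raise ValidationError(f"unknown group label(s): {', '.join(bad)}")
        n_ctrl = sum(g == GROUP_CONTROL for g in self.group)
        n_case = sum(g == GROUP_CASE for g in self.group)
        if (n_ctrl, n_case) != (self.metadata.n_control, self.metadata.n_case):
            raise ValidationError(
                f"{self.metadata.study_id}: group counts {n_ctrl}/{n_case} do not "
                f"match metadata {self.metadata.n_control}/{self.metadata.n_case}"
            )

    @property
    def control_mask(self) -> np.ndarray:
        return np.array([g == GROUP_CONTROL for g in self.group])

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([g == GROUP_CASE for g in self.group])

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.genes.index(gene)]
        except ValueError:
            raise KeyError(f"gene {gene!r} not present in {self.metadata.study_id}") from None


@dataclass(frozen=True)
class SignedRelation:
    """A signed literature edge: ``source`` regulates / is associated with
    ``target`` with polarity +1 (activation / up) or -1 (inhibition / down)."""

    source: str
    target: str
    polarity: int
    relation_kind: str = "regulation"
    provenance: str = ""

    def __post_init__(self):
        if self.polarity not in (1, -1):
            raise ValidationError(f"polarity must be +1 or -1, got {self.polarity!r}")
        if self.relation_kind not in _VALID_KINDS:
            raise ValidationError(f"unknown relation kind {self.relation_kind!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.relation_kind)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (e.g. one GO term) with an external identifier."""

    name: str
    external_id: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")


# ---------------------------------------------------------------------------
# expression studies
# ---------------------------------------------------------------------------

def read_expression_study(path: str | Path, metadata: StudyMetadata) -> "ExpressionStudy":
    """Parse a canonical-dialect expression TSV into an :class:`ExpressionStudy`.

    The group counts are validated against *metadata* and the intensity scale
    is detected heuristically (see :func:`megax.effect_size.detect_scale`).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise FormatError(f"{path}: expected at least a sample row and a group row")
    header = lines[0].split("\t")
    group_row = lines[1].split("\t")
    if len(group_row) != len(header):
        raise FormatError(f"{path}: group row has {len(group_row)} fields, header has {len(header)}")
    sample_ids = header[1:]
    group = group_row[1:]
    bad = sorted(set(group) - _VALID_GROUPS)
    if bad:
        raise ValidationError(f"{path}: unknown group label(s): {', '.join(bad)}")
    genes: list[str] = []
    rows: list[list[float]] = []
    for ln, line in enumerate(lines[2:], start=3):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(f"{path}:{ln}: expected {len(header)} fields, got {len(fields)}")
        genes.append(fields[0])
        try:
            rows.append([np.nan if v == "NA" else float(v) for v in fields[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: non-numeric expression value") from exc
    study = ExpressionStudy(
        metadata=metadata,
        genes=genes,
        values=np.array(rows, dtype=float).reshape(len(genes), len(sample_ids)),
        group=group,
        sample_ids=sample_ids,
    )
    from .effect_size import detect_scale  # local import: avoids a cycle

    study.scale = detect_scale(study)
    return study


def _fmt(v: float) -> str:
    if np.isnan(v):
        return "NA"
    return repr(float(v))


def write_expression_study(study: ExpressionStudy, path: str | Path) -> None:
    """Write *study* in the canonical dialect; floats use shortest round-trip
    representation so read -> write is byte-identical for canonical files."""
    path = Path(path)
    out = ["\t".join(["gene", *study.sample_ids]), "\t".join(["group", *study.group])]
    for g, row in zip(study.genes, study.values):
        out.append("\t".join([g, *(_fmt(v) for v in row)]))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# study-metadata table
# ---------------------------------------------------------------------------

_STUDY_COLUMNS = ["study_id", "n_control", "n_case", "country", "study_age_years"]


def read_study_table(path: str | Path) -> list[StudyMetadata]:
    """Read a study-metadata TSV (one row per expression dataset)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    records: list[StudyMetadata] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        for col in ("n_control", "n_case"):
            try:
                int(row[col])
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer {col}={row[col]!r} for {row['study_id']}"
                ) from None
        if row["study_id"] in seen:
            raise ValidationError(f"{path}: duplicate study_id {row['study_id']!r}")
        seen.add(row["study_id"])
        records.append(
            StudyMetadata(
                study_id=row["study_id"],
                n_control=int(row["n_control"]),
                n_case=int(row["n_case"]),
                country=row["country"],
                study_age_years=float(row["study_age_years"]),
                organism=row.get("organism", "Homo sapiens"),
            )
        )
    return records


def write_study_table(studies: Sequence[StudyMetadata], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "study_id": s.study_id,
                "n_control": s.n_control,
                "n_case": s.n_case,
                "country": s.country,
                "study_age_years": s.study_age_years,
                "organism": s.organism,
            }
            for s in studies
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# signed relations
# ---------------------------------------------------------------------------

_POLARITY = {"+": 1, "-": -1, "+1": 1, "-1": -1, "1": 1}


def read_relation_table(path: str | Path, aliases: dict[str, str] | None = None) -> list[SignedRelation]:
    """Read a signed-relation TSV into a list of :class:`SignedRelation`.

    *aliases* optionally rewrites entity names (e.g. ``{"MI21": "MIR21"}``);
    it is off by default so packaged fixtures keep their printed symbols.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["source", "target", "polarity", "kind"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    aliases = aliases or {}
    relations: list[SignedRelation] = []
    seen: set[tuple[str, str, str]] = set()
    for _, row in df.iterrows():
        pol = _POLARITY.get(str(row["polarity"]).strip())
        if pol is None:
            raise FormatError(f"{path}: polarity must be one of +, -, +1, -1; got {row['polarity']!r}")
        rel = SignedRelation(
            source=aliases.get(row["source"], row["source"]),
            target=aliases.get(row["target"], row["target"]),
            polarity=pol,
            relation_kind=row["kind"],
            provenance=row.get("provenance", "") or "",
        )
        if rel.key in seen:
            raise ValidationError(f"{path}: duplicate relation {rel.key}")
        seen.add(rel.key)
        relations.append(rel)
    return relations


def write_relation_table(relations: Iterable[SignedRelation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "source": r.source,
                "target": r.target,
                "polarity": "+" if r.polarity > 0 else "-",
                "kind": r.relation_kind,
                "provenance": r.provenance,
            }
            for r in relations
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: ``name<TAB>id<TAB>member...`` per line.

    Duplicate members within a set are dropped with a logged warning.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{ln}: GMT line needs name, id and at least one member")
        name, external_id, *members = fields
        members = [m for m in members if m]
        if len(set(members)) < len(members):
            dupes = sorted({m for m in members if members.count(m) > 1})
            logger.warning("%s:%d: duplicate member(s) %s in set %r dropped", path, ln, dupes, name)
        if not members:
            raise FormatError(f"{path}:{ln}: gene set {name!r} has an empty member list")
        sets.append(GeneSet(name=name, external_id=external_id, members=frozenset(members)))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    lines = ["\t".join([s.name, s.external_id, *sorted(s.members)]) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _fixture_path(name: str) -> Path:
    return Path(resources.files("megax") / "data" / name)


def load_table1_studies() -> list[StudyMetadata]:
    """The 12 qualified case/control expression datasets (printed study table)."""
    return read_study_table(_fixture_path("table1_studies.tsv"))


def load_diagnostic_relations(aliases: dict[str, str] | None = None) -> list[SignedRelation]:
    """Signed driver->gene and disease->gene edges of the diagnostic network."""
    return read_relation_table(_fixture_path("diagnostic_relations.tsv"), aliases=aliases)


def load_prognostic_relations(aliases: dict[str, str] | None = None) -> list[SignedRelation]:
    """Signed driver->gene and gene->disease edges of the prognostic network."""
    return read_relation_table(_fixture_path("prognostic_relations.tsv"), aliases=aliases)


def relabel_groups(study: ExpressionStudy, swap: bool = True) -> ExpressionStudy:
    """Return a copy of *study* with control/case labels swapped (test helper)."""
    if not swap:
        return study
    flipped = [GROUP_CASE if g == GROUP_CONTROL else GROUP_CONTROL for g in study.group]
    meta = replace(study.metadata, n_control=study.metadata.n_case, n_case=study.metadata.n_control)
    return ExpressionStudy(
        metadata=meta,
        genes=list(study.genes),
        values=study.values.copy(),
        group=flipped,
        sample_ids=list(study.sample_ids),
        scale=study.scale,
    )
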