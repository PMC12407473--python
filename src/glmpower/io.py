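"""Design-document schema, readers/writers, and the packaged example designs.

A design document is a JSON file that fully describes a power or sample-size
problem: between-ISU factors with allocation ratios, within-ISU dimensions
(outcomes, repeated measures, nested clusters), a cell-means table, the
variability model, the hypothesis, and the type I error rate.  Validation is
by pydantic models — a schema violation reports the offending field path —
and documents round-trip losslessly through ``load_design`` /
``save_design``.

Five worked example designs ship with the package (``example_names`` /
``load_example``): a cluster-randomized trial, a longitudinal trial, a
multilevel multivariate trial, a multilevel longitudinal trial, and a
subgroup (interaction) analysis.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    model_validator,
)

from .covariance import (
    AR1,
    ClusterHierarchy,
    ClusterLevel,
    CompoundSymmetric,
    LEAR,
    RepeatedStructure,
    Unstructured,
)
from .design import (
    BetweenStructure,
    CellMeans,
    HypothesisSpec,
    StudyDesign,
    WithinStructure,
)

__all__ = [
    "DesignDocument",
    "DesignValidationError",
    "load_design",
    "save_design",
    "design_to_document",
    "design_from_document",
    "design_schema",
    "example_names",
    "load_example",
    "write_fixtures",
]

SCHEMA_VERSION = "1.0"


class DesignValidationError(ValueError):
    """A design document failed schema or domain validation."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FactorDoc(_Model):
    name: str
    levels: list[str] = Field(min_length=1)


class BetweenDoc(_Model):
    factors: list[FactorDoc] = Field(min_length=1)
    allocation_ratios: list[int] = Field(min_length=1)
    total_isus: int | None = None


class OutcomeDoc(_Model):
    name: str
    sd: float = Field(gt=0)


class RepeatedDoc(_Model):
    timings: list[float] = Field(min_length=2)
    structure: Literal["unstructured", "compound_symmetric", "lear", "ar1"]
    correlation: list[list[float]] | None = None
    rho: float | None = None
    rho_base: float | None = None
    delta_decay: float | None = None

    @model_validator(mode="after")
    def _check_parameters(self) -> "RepeatedDoc":
        need = {
            "unstructured": ("correlation",),
            "compound_symmetric": ("rho",),
            "lear": ("rho_base", "delta_decay"),
            "ar1": ("rho",),
        }[self.structure]
        for f in need:
            if getattr(self, f) is None:
                raise ValueError(f"repeated structure {self.structure!r} requires {f!r}")
        return self


class ClusterLevelDoc(_Model):
    name: str
    size: int = Field(ge=2, le=10_000)
    icc: float = Field(gt=-1.0, lt=1.0)


class WithinDoc(_Model):
    outcomes: list[OutcomeDoc] = Field(min_length=1)
    outcome_correlation: list[list[float]] | None = None
    repeated: RepeatedDoc | None = None
    #: innermost level first (members within the smallest cluster)
    clusters: list[ClusterLevelDoc] | None = None


class MeansDoc(_Model):
    values: list[list[float]] = Field(min_length=1)
    row_labels: list[str] | None = None
    column_labels: list[str] | None = None


Selection = Literal["average", "identity", "successive-difference"]


class HypothesisDoc(_Model):
    between: str | list[str]
    outcomes: Selection = "identity"
    repeated: Selection = "average"
    clusters: Selection = "average"
    theta_null: list[list[float]] | None = None


class DesignDocument(_Model):
    """Top-level schema for a .json design file."""

    schema_version: str = SCHEMA_VERSION
    title: str = ""
    solve_for: Literal["power", "samplesize"] = "power"
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    target_power: float | None = Field(default=None, gt=0.0, lt=1.0)
    between: BetweenDoc
    within: WithinDoc
    means: MeansDoc
    hypothesis: HypothesisDoc
    notes: str | None = None

    @model_validator(mode="after")
    def _check_solve_for(self) -> "DesignDocument":
        if self.solve_for == "samplesize" and self.target_power is None:
            raise ValueError("solve_for='samplesize' requires target_power")
        if self.solve_for == "power" and self.between.total_isus is None:
            raise ValueError("solve_for='power' requires between.total_isus")
        return self


def _repeated_from_doc(doc: RepeatedDoc) -> RepeatedStructure:
    if doc.structure == "unstructured":
        return Unstructured(np.asarray(doc.correlation, dtype=float))
    if doc.structure == "compound_symmetric":
        return CompoundSymmetric(doc.rho)
    if doc.structure == "lear":
        return LEAR(doc.rho_base, doc.delta_decay)
    return AR1(doc.rho)


def design_from_document(doc: DesignDocument) -> StudyDesign:
    """Turn a validated document into a StudyDesign (enforcing all domain
    invariants: divisibility, conformance, positive definiteness)."""
    try:
        between = BetweenStructure(
            factors=tuple((f.name, tuple(f.levels)) for f in doc.between.factors),
            allocation_ratios=tuple(doc.between.allocation_ratios),
            total_isus=doc.between.total_isus,
        )
        within = WithinStructure(
            outcomes=tuple(o.name for o in doc.within.outcomes),
            outcome_sds=tuple(o.sd for o in doc.within.outcomes),
            outcome_correlation=(
                None
                if doc.within.outcome_correlation is None
                else np.asarray(doc.within.outcome_correlation, dtype=float)
            ),
            timings=(
                None if doc.within.repeated is None
                else tuple(doc.within.repeated.timings)
            ),
            repeated=(
                None if doc.within.repeated is None
                else _repeated_from_doc(doc.within.repeated)
            ),
            clusters=(
                None
                if doc.within.clusters is None
                else ClusterHierarchy(
                    tuple(
                        ClusterLevel(lv.name, lv.size, lv.icc)
                        for lv in doc.within.clusters
                    )
                )
            ),
        )
        hyp = HypothesisSpec(
            between=(
                doc.hypothesis.between
                if isinstance(doc.hypothesis.between, str)
                else tuple(doc.hypothesis.between)
            ),
            outcomes=doc.hypothesis.outcomes,
            repeated=doc.hypothesis.repeated,
            clusters=doc.hypothesis.clusters,
            theta_null=(
                None
                if doc.hypothesis.theta_null is None
                else np.asarray(doc.hypothesis.theta_null, dtype=float)
            ),
        )
        return StudyDesign(
            between=between,
            within=within,
            means=CellMeans(np.asarray(doc.means.values, dtype=float)),
            hypothesis=hyp,
            alpha=doc.alpha,
            title=doc.title,
        )
    except ValueError as exc:
        raise DesignValidationError(str(exc)) from exc


def _cell_labels(between: BetweenStructure) -> list[str]:
    labels = [""]
    for name, levels in between.factors:
        labels = [
            (lab + ":" if lab else "") + f"{name}={lv}"
            for lab in labels
            for lv in levels
        ]
    return labels


def _column_labels(within: WithinStructure) -> list[str]:
    cols = []
    for o in within.outcomes:
        if within.timings is None:
            cols.append(o)
        else:
            cols.extend(f"{o}@t={t:g}" for t in within.timings)
    return cols


def design_to_document(
    design: StudyDesign,
    solve_for: Literal["power", "samplesize"] = "power",
    target_power: float | None = None,
    notes: str | None = None,
) -> DesignDocument:
    """Serialize a StudyDesign back into its document form."""
    w = design.within
    repeated_doc = None
    if w.repeated is not None:
        r = w.repeated
        if isinstance(r, Unstructured):
            repeated_doc = RepeatedDoc(
                timings=list(w.timings),
                structure="unstructured",
                correlation=np.asarray(r.correlation, dtype=float).tolist(),
            )
        elif isinstance(r, CompoundSymmetric):
            repeated_doc = RepeatedDoc(
                timings=list(w.timings), structure="compound_symmetric", rho=r.rho
            )
        elif isinstance(r, LEAR):
            repeated_doc = RepeatedDoc(
                timings=list(w.timings),
                structure="lear",
                rho_base=r.rho_base,
                delta_decay=r.delta_decay,
            )
        elif isinstance(r, AR1):
            repeated_doc = RepeatedDoc(
                timings=list(w.timings), structure="ar1", rho=r.rho
            )
        else:  # pragma: no cover
            raise TypeError(f"unknown repeated structure {type(r).__name__}")
    hyp = design.hypothesis
    return DesignDocument(
        schema_version=SCHEMA_VERSION,
        title=design.title,
        solve_for=solve_for,
        alpha=design.alpha,
        target_power=target_power,
        between=BetweenDoc(
            factors=[
                FactorDoc(name=n, levels=list(levels))
                for n, levels in design.between.factors
            ],
            allocation_ratios=list(design.between.allocation_ratios),
            total_isus=design.between.total_isus,
        ),
        within=WithinDoc(
            outcomes=[
                OutcomeDoc(name=n, sd=s)
                for n, s in zip(w.outcomes, w.outcome_sds)
            ],
            outcome_correlation=(
                None
                if w.outcome_correlation is None
                else np.asarray(w.outcome_correlation, dtype=float).tolist()
            ),
            repeated=repeated_doc,
            clusters=(
                None
                if w.clusters is None
                else [
                    ClusterLevelDoc(name=lv.name, size=lv.size, icc=lv.icc)
                    for lv in w.clusters.levels
                ]
            ),
        ),
        means=MeansDoc(
            values=design.means.values.tolist(),
            row_labels=_cell_labels(design.between),
            column_labels=_column_labels(w),
        ),
        hypothesis=HypothesisDoc(
            between=(
                hyp.between if isinstance(hyp.between, str) else list(hyp.between)
            ),
            outcomes=hyp.outcomes,
            repeated=hyp.repeated,
            clusters=hyp.clusters,
            theta_null=(
                None
                if hyp.theta_null is None
                else np.asarray(hyp.theta_null, dtype=float).tolist()
            ),
        ),
        notes=notes,
    )


def design_schema() -> dict:
    """JSON Schema for design documents, generated from the validator models
    (single source of truth: the pydantic classes above)."""
    return DesignDocument.model_json_schema()


def _parse_document(text: str, source: str) -> DesignDocument:
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DesignValidationError(f"{source}: not valid JSON: {exc}") from exc
    try:
        return DesignDocument.model_validate(raw)
    except ValidationError as exc:
        msgs = "; ".join(
            f"{'.'.join(str(loc) for loc in e['loc'])}: {e['msg']}"
            for e in exc.errors()
        )
        raise DesignValidationError(f"{source}: {msgs}") from exc


def load_design(path: str | Path) -> StudyDesign:
    """Read, validate, and construct a StudyDesign from a .json design file."""
    path = Path(path)
    design = design_from_document(_parse_document(path.read_text(), str(path)))
    return design


def load_document(path: str | Path) -> DesignDocument:
    path = Path(path)
    return _parse_document(path.read_text(), str(path))


def save_design(
    design: StudyDesign,
    path: str | Path,
    solve_for: Literal["power", "samplesize"] = "power",
    target_power: float | None = None,
    notes: str | None = None,
) -> None:
    """Write a design document (full double precision, stable key order)."""
    doc = design_to_document(
        design, solve_for=solve_for, target_power=target_power, notes=notes
    )
    Path(path).write_text(
        json.dumps(doc.model_dump(exclude_none=False), indent=2) + "\n"
    )


# ---------------------------------------------------------------------------
# Packaged example designs
# ---------------------------------------------------------------------------

_EXAMPLES = {
    "example1": "example1.json",
    "example2": "example2.json",
    "example3": "example3.json",
    "example4": "example4.json",
    "example5": "example5.json",
}


def example_names() -> list[str]:
    return sorted(_EXAMPLES)


def _example_text(name: str) -> str:
    try:
        fname = _EXAMPLES[name]
    except KeyError:
        raise KeyError(f"unknown example {name!r}; have {example_names()}") from None
    return (resources.files("glmpower") / "fixtures" / fname).read_text()


def load_example(name: str) -> StudyDesign:
    """Load one of the packaged example designs by name ('example1'..'example5')."""
    return design_from_document(_parse_document(_example_text(name), name))


def load_example_document(name: str) -> DesignDocument:
    return _parse_document(_example_text(name), name)


def write_fixtures(out_dir: str | Path) -> list[Path]:
    """Copy the packaged example design files into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, fname in sorted(_EXAMPLES.items()):
        dest = out / fname
        dest.write_text(_example_text(name))
        written.append(dest)
    return written
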