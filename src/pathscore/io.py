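"""Readers and writers for the standard data carriers.

Carriers: tab-separated expression matrices (probesets x samples), GEO
series-matrix text files, JSON pathway-model specifications and TSV result
tables.  Intensities are kept on the linear scale at parse time; the
log2(x + 1) transform is applied downstream at a single site (evidence
construction and calibration), never here.  Missing cells are preserved as
missing and become "no observation" evidence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model import (
    DOWN_REGULATED,
    UP_REGULATED,
    PathwayModel,
    ProbesetNode,
    TargetGeneNode,
)

__all__ = [
    "Sample",
    "ExpressionMatrix",
    "FormatError",
    "SCHEMA_VERSION",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_series_matrix",
    "read_model_spec",
    "write_model_spec",
    "read_labels_tsv",
    "write_labels_tsv",
]

SCHEMA_VERSION = 1


class FormatError(ValueError):
    """A carrier file violates its documented format."""


@dataclass
class Sample:
    """One array sample: linear-scale hybridisation value per probeset.

    Non-finite or negative intensities are QC findings, not parse errors, so
    they are representable here; missing probesets simply carry no entry.
    """

    sample_id: str
    intensities: dict[str, float]
    annotation: dict[str, str] = field(default_factory=dict)


@dataclass
class ExpressionMatrix:
    """Rectangular probesets x samples intensity matrix with annotations."""

    probeset_ids: list[str]
    samples: list[Sample]

    def __post_init__(self) -> None:
        if len(set(self.probeset_ids)) != len(self.probeset_ids):
            raise FormatError("duplicate probeset IDs in matrix")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate sample IDs in matrix")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def to_dataframe(self) -> pd.DataFrame:
        """Probesets x samples DataFrame; missing values become NaN."""
        data = {
            s.sample_id: [s.intensities.get(ps, np.nan) for ps in self.probeset_ids]
            for s in self.samples
        }
        return pd.DataFrame(data, index=list(self.probeset_ids))

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        annotations: Mapping[str, Mapping[str, str]] | None = None,
    ) -> "ExpressionMatrix":
        """Build from a probesets x samples DataFrame (NaN = missing)."""
        annotations = annotations or {}
        samples = []
        for sid in frame.columns:
            col = frame[sid]
            intens = {
                str(ps): float(v) for ps, v in col.items() if not pd.isna(v)
            }
            samples.append(
                Sample(str(sid), intens, dict(annotations.get(str(sid), {})))
            )
        return cls([str(ps) for ps in frame.index], samples)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        keep = set(sample_ids)
        return ExpressionMatrix(
            list(self.probeset_ids),
            [s for s in self.samples if s.sample_id in keep],
        )


# ---------------------------------------------------------------------------
# TSV expression matrices
# ---------------------------------------------------------------------------

def _format_float(value: float) -> str:
    # repr round-trips doubles exactly
    return repr(float(value))


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a probesets x samples TSV.

    The first header cell names the ID column; the remaining header cells are
    sample IDs.  Empty cells are missing values.  Ragged rows are rejected
    with their line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].rstrip("\r").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: header must name an ID column and >=1 sample")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}: duplicate sample IDs in header")
    probeset_ids: list[str] = []
    columns: list[list[float]] = [[] for _ in sample_ids]
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.rstrip("\r").split("\t")
        if len(cells) != len(header):
            raise FormatError(
                f"{path}: line {lineno} has {len(cells)} columns, expected {len(header)}"
            )
        ps = cells[0]
        if ps in seen:
            raise FormatError(f"{path}: line {lineno}: duplicate probeset ID {ps!r}")
        seen.add(ps)
        probeset_ids.append(ps)
        for j, cell in enumerate(cells[1:]):
            if cell == "":
                columns[j].append(math.nan)
            else:
                try:
                    columns[j].append(float(cell))
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: cannot parse {cell!r} as a number"
                    ) from exc
    samples = [
        Sample(
            sid,
            {
                ps: v
                for ps, v in zip(probeset_ids, col)
                if not math.isnan(v)
            },
        )
        for sid, col in zip(sample_ids, columns)
    ]
    return ExpressionMatrix(probeset_ids, samples)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV at full double precision (empty cell = missing)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["probeset_id", *matrix.sample_ids]) + "\n")
        for ps in matrix.probeset_ids:
            row = [ps]
            for s in matrix.samples:
                v = s.intensities.get(ps)
                row.append("" if v is None else _format_float(v))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# GEO series-matrix files
# ---------------------------------------------------------------------------

_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"


def _unquote(cell: str) -> str:
    cell = cell.strip()
    if len(cell) >= 2 and cell[0] == '"' and cell[-1] == '"':
        return cell[1:-1]
    return cell


def read_series_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a GEO series-matrix text file.

    The expression table sits between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end``; ``!Sample_*`` metadata lines preceding it
    populate per-sample annotations.  Quoted and unquoted identifiers and
    Windows line endings are both tolerated.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    meta: dict[str, list[str]] = {}
    begin = end = None
    for i, line in enumerate(lines):
        line = line.rstrip("\r")
        if line == _TABLE_BEGIN:
            begin = i
            break
        if line.startswith("!Sample_"):
            cells = line.split("\t")
            key = cells[0][len("!Sample_"):]
            meta[key] = [_unquote(c) for c in cells[1:]]
    if begin is None:
        raise FormatError(f"{path}: missing {_TABLE_BEGIN} marker")
    for i in range(begin + 1, len(lines)):
        if lines[i].rstrip("\r") == _TABLE_END:
            end = i
            break
    if end is None:
        raise FormatError(f"{path}: missing {_TABLE_END} marker (truncated file?)")
    table = [lines[i].rstrip("\r") for i in range(begin + 1, end) if lines[i].strip()]
    if not table:
        raise FormatError(f"{path}: empty expression table")
    header = [_unquote(c) for c in table[0].split("\t")]
    sample_ids = header[1:]
    probeset_ids: list[str] = []
    columns: list[list[float]] = [[] for _ in sample_ids]
    seen: set[str] = set()
    for offset, line in enumerate(table[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise FormatError(
                f"{path}: table row {offset} has {len(cells)} columns, "
                f"expected {len(header)}"
            )
        ps = _unquote(cells[0])
        if ps in seen:
            raise FormatError(f"{path}: duplicate probeset ID {ps!r}")
        seen.add(ps)
        probeset_ids.append(ps)
        for j, cell in enumerate(cells[1:]):
            cell = _unquote(cell)
            if cell in ("", "null", "NA"):
                columns[j].append(math.nan)
            else:
                try:
                    columns[j].append(float(cell))
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: table row {offset}: cannot parse {cell!r}"
                    ) from exc
    samples = []
    for j, sid in enumerate(sample_ids):
        annotation = {
            key: values[j] for key, values in meta.items() if j < len(values)
        }
        intens = {
            ps: columns[j][k]
            for k, ps in enumerate(probeset_ids)
            if not math.isnan(columns[j][k])
        }
        samples.append(Sample(sid, intens, annotation))
    return ExpressionMatrix(probeset_ids, samples)


# ---------------------------------------------------------------------------
# JSON model specifications
# ---------------------------------------------------------------------------

def _require(obj: Mapping, key: str, where: str):
    if key not in obj:
        raise FormatError(f"model spec: missing field {key!r} in {where}")
    return obj[key]


def read_model_spec(path: str | Path) -> PathwayModel:
    """Read a pathway-model JSON specification.

    Validates the schema field-by-field; probability invariants (open-interval
    bounds, direction ordering, unique probeset IDs) are enforced by the
    model dataclasses and reported as rejections.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: top level must be an object")
    version = _require(doc, "schema_version", "document")
    if version != SCHEMA_VERSION:
        raise FormatError(
            f"{path}: unsupported schema_version {version!r} (expected {SCHEMA_VERSION})"
        )
    pathway = _require(doc, "pathway", "document")
    prior = _require(doc, "prior_active", "document")
    genes_spec = _require(doc, "target_genes", "document")
    if not isinstance(genes_spec, list):
        raise FormatError(f"{path}: target_genes must be an array")
    thresholds = doc.get("thresholds", {"default": 0.0})
    if not isinstance(thresholds, dict):
        raise FormatError(f"{path}: thresholds must be an object")
    genes = []
    for g in genes_spec:
        gene_symbol = _require(g, "gene", "target gene entry")
        direction = _require(g, "direction", f"gene {gene_symbol!r}")
        if direction not in (UP_REGULATED, DOWN_REGULATED):
            raise FormatError(
                f"{path}: gene {gene_symbol!r}: direction must be "
                f"{UP_REGULATED!r} or {DOWN_REGULATED!r}"
            )
        probesets = []
        ps_spec = _require(g, "probesets", f"gene {gene_symbol!r}")
        for p in ps_spec:
            probesets.append(
                ProbesetNode(
                    probeset_id=str(_require(p, "id", f"probeset of {gene_symbol!r}")),
                    p_high_given_up=float(_require(p, "p_high_given_up", f"probeset of {gene_symbol!r}")),
                    p_high_given_down=float(_require(p, "p_high_given_down", f"probeset of {gene_symbol!r}")),
                    log2_threshold=float(_require(p, "log2_threshold", f"probeset of {gene_symbol!r}")),
                    soft_scale=float(_require(p, "soft_scale", f"probeset of {gene_symbol!r}")),
                )
            )
        genes.append(
            TargetGeneNode(
                gene_symbol=str(gene_symbol),
                direction=direction,
                p_up_given_active=float(_require(g, "p_up_given_active", f"gene {gene_symbol!r}")),
                p_up_given_inactive=float(_require(g, "p_up_given_inactive", f"gene {gene_symbol!r}")),
                probesets=probesets,
            )
        )
    return PathwayModel(
        pathway_name=str(pathway),
        prior_active=float(prior),
        target_genes=genes,
        frozen=bool(doc.get("frozen", False)),
        thresholds={str(k): float(v) for k, v in thresholds.items()},
    )


def write_model_spec(model: PathwayModel, path: str | Path) -> None:
    """Write a model as JSON; floats serialise via repr, so read/write is exact."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "pathway": model.pathway_name,
        "prior_active": model.prior_active,
        "frozen": model.frozen,
        "thresholds": dict(model.thresholds),
        "target_genes": [
            {
                "gene": g.gene_symbol,
                "direction": g.direction,
                "p_up_given_active": g.p_up_given_active,
                "p_up_given_inactive": g.p_up_given_inactive,
                "probesets": [
                    {
                        "id": ps.probeset_id,
                        "p_high_given_up": ps.p_high_given_up,
                        "p_high_given_down": ps.p_high_given_down,
                        "log2_threshold": ps.log2_threshold,
                        "soft_scale": ps.soft_scale,
                    }
                    for ps in g.probesets
                ],
            }
            for g in model.target_genes
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Calibration label files
# ---------------------------------------------------------------------------

def read_labels_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sample_id <tab> label in {active, inactive}."""
    labels: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.rstrip("\r").split("\t")
        if len(cells) != 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 columns")
        sid, label = cells
        if lineno == 1 and label == "label":
            continue  # optional header
        if label not in ("active", "inactive"):
            raise FormatError(
                f"{path}: line {lineno}: label must be 'active' or 'inactive', got {label!r}"
            )
        if sid in labels:
            raise FormatError(f"{path}: line {lineno}: duplicate sample {sid!r}")
        labels[sid] = label
    return labels


def write_labels_tsv(labels: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, label in labels.items():
            fh.write(f"{sid}\t{label}\n")
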