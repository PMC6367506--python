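"""Model calibration on ground-truth labelled samples.

Probeset conditional probabilities (relation: probeset high/low given gene
up/down) are estimated from samples whose pathway activity state is known.
During calibration the latent gene state is hard-assigned from the sample
label and the gene's regulation direction: an active-pathway sample implies
*up* for an up-regulated gene and *down* for a down-regulated one; an
inactive sample implies the reverse.  Counts are Laplace-smoothed so fitted
probabilities stay strictly inside (0, 1).  After calibration a model is
frozen: probabilities become immutable and only per-context decision
thresholds may still be added, which keeps exactly the same model when it is
re-thresholded for another tissue.

Also here: the evidence-score ranking used to shortlist candidate target
genes from accumulated experimental evidence categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import Sample
from .model import (
    ACTIVE,
    INACTIVE,
    UP_REGULATED,
    FrozenModelError,
    PathwayModel,
)

__all__ = [
    "CalibrationError",
    "CalibrationSet",
    "GeneEvidenceRecord",
    "EVIDENCE_CATEGORIES",
    "fit_probeset_cpts",
    "set_discretization_thresholds",
    "freeze",
    "recalibrate_threshold",
    "rank_candidate_genes",
]

EVIDENCE_CATEGORIES = (
    "response_element_motif",
    "promoter_functionality",
    "tf_binding_in_vivo",
    "tf_binding_in_vitro",
    "differential_expression",
)


class CalibrationError(ValueError):
    """Calibration input cannot support the requested fit."""


@dataclass
class CalibrationSet:
    """Labelled samples with known ('ground truth') pathway activity state."""

    samples: list[Sample]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        ids = {s.sample_id for s in self.samples}
        if len(ids) != len(self.samples):
            raise CalibrationError("duplicate sample IDs in calibration set")
        for sid, label in self.labels.items():
            if sid not in ids:
                raise CalibrationError(f"labelled sample {sid!r} is not present")
            if label not in (ACTIVE, INACTIVE):
                raise CalibrationError(
                    f"label for {sid!r} must be {ACTIVE!r} or {INACTIVE!r}, got {label!r}"
                )
        values = set(self.labels.values())
        if ACTIVE not in values or INACTIVE not in values:
            raise CalibrationError("need at least one sample per class")

    def labelled_samples(self) -> list[tuple[Sample, str]]:
        """(sample, label) pairs in sample order, labelled samples only."""
        return [
            (s, self.labels[s.sample_id])
            for s in self.samples
            if s.sample_id in self.labels
        ]


def _log2_value(intensity: float) -> float:
    return math.log2(max(intensity, 0.0) + 1.0)


def fit_probeset_cpts(
    skeleton: PathwayModel,
    calib: CalibrationSet,
    pseudocount: float = 1.0,
) -> PathwayModel:
    """Estimate probeset high/low CPTs from labelled samples.

    For each probeset, a sample counts as *high* when log2(intensity + 1)
    exceeds the probeset's discretisation threshold (set the thresholds
    first, e.g. with :func:`set_discretization_thresholds`).  With
    pseudocount ``a``,

        p_high|up = (n_high_in_up_assigned + a) / (n_up_assigned + 2a)

    and analogously for the down state.  Returns a new, still-unfrozen model;
    the skeleton is untouched.
    """
    if skeleton.frozen:
        raise FrozenModelError("cannot calibrate a frozen model")
    if not (pseudocount > 0 and math.isfinite(pseudocount)):
        raise ValueError(f"pseudocount must be positive, got {pseudocount!r}")
    model = skeleton.copy()
    pairs = calib.labelled_samples()
    for gene in model.target_genes:
        for ps in gene.probesets:
            n = {True: 0, False: 0}       # gene state up?: count
            n_high = {True: 0, False: 0}
            for sample, label in pairs:
                value = sample.intensities.get(ps.probeset_id)
                if value is None or math.isnan(value):
                    continue
                gene_up = (label == ACTIVE) == (gene.direction == UP_REGULATED)
                high = _log2_value(value) > ps.log2_threshold
                n[gene_up] += 1
                if high:
                    n_high[gene_up] += 1
            if n[True] + n[False] == 0:
                raise CalibrationError(
                    f"probeset {ps.probeset_id!r} is absent from every calibration sample"
                )
            model.set_probeset_cpt(
                ps.probeset_id,
                p_high_given_up=(n_high[True] + pseudocount) / (n[True] + 2 * pseudocount),
                p_high_given_down=(n_high[False] + pseudocount) / (n[False] + 2 * pseudocount),
            )
    return model


def set_discretization_thresholds(
    skeleton: PathwayModel, calib: CalibrationSet
) -> PathwayModel:
    """Set each probeset's high/low cut from the calibration data.

    The threshold is the midpoint of the two per-class medians of
    log2(intensity + 1).  Identical class medians leave the probeset at the
    common median (it then becomes uninformative after CPT fitting, which is
    the intended behaviour for a non-separating probeset).
    """
    if skeleton.frozen:
        raise FrozenModelError("cannot re-threshold probesets of a frozen model")
    model = skeleton.copy()
    pairs = calib.labelled_samples()
    for gene in model.target_genes:
        for ps in gene.probesets:
            per_class: dict[str, list[float]] = {ACTIVE: [], INACTIVE: []}
            for sample, label in pairs:
                value = sample.intensities.get(ps.probeset_id)
                if value is None or math.isnan(value):
                    continue
                per_class[label].append(_log2_value(value))
            if not per_class[ACTIVE] and not per_class[INACTIVE]:
                raise CalibrationError(
                    f"probeset {ps.probeset_id!r} is absent from every calibration sample"
                )
            if not per_class[ACTIVE] or not per_class[INACTIVE]:
                raise CalibrationError(
                    f"probeset {ps.probeset_id!r} has no values in one class"
                )
            m_active = float(np.median(per_class[ACTIVE]))
            m_inactive = float(np.median(per_class[INACTIVE]))
            model.set_probeset_cpt(
                ps.probeset_id, log2_threshold=(m_active + m_inactive) / 2.0
            )
    return model


def freeze(model: PathwayModel) -> PathwayModel:
    """Return a frozen copy: probabilities locked, thresholds still extensible.

    Idempotent: freezing a frozen model returns an equal frozen copy.
    """
    frozen = model.copy()
    frozen.frozen = True
    return frozen


def recalibrate_threshold(
    scores: Sequence[float],
    labels: Sequence[str],
    objective: str = "accuracy",
) -> float:
    """Choose a log2odds decision threshold from labelled scores.

    Candidate thresholds are the midpoints between adjacent distinct sorted
    scores, plus one candidate below all scores and one above.  A sample is
    called active when its score strictly exceeds the threshold.  The
    returned threshold maximises the objective (``"accuracy"`` or
    ``"youden"`` = sensitivity + specificity - 1); ties are broken toward the
    threshold nearest 0, then toward the smaller value.
    """
    if objective not in ("accuracy", "youden"):
        raise ValueError(f"objective must be 'accuracy' or 'youden', got {objective!r}")
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    scores = [float(s) for s in scores]
    for label in labels:
        if label not in (ACTIVE, INACTIVE):
            raise ValueError(f"labels must be {ACTIVE!r}/{INACTIVE!r}, got {label!r}")
    n_pos = sum(1 for l in labels if l == ACTIVE)
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise CalibrationError("need at least one score per class")
    distinct = sorted(set(scores))
    candidates = [distinct[0] - 1.0]
    candidates += [(a + b) / 2.0 for a, b in zip(distinct, distinct[1:])]
    candidates += [distinct[-1] + 1.0]

    def score_threshold(t: float) -> float:
        tp = sum(1 for s, l in zip(scores, labels) if l == ACTIVE and s > t)
        tn = sum(1 for s, l in zip(scores, labels) if l == INACTIVE and s <= t)
        if objective == "accuracy":
            return (tp + tn) / len(scores)
        return tp / n_pos + tn / n_neg - 1.0

    best = max(
        candidates,
        key=lambda t: (score_threshold(t), -abs(t), -t),
    )
    return float(best)


@dataclass
class GeneEvidenceRecord:
    """Accumulated experimental evidence that a gene is a direct TC target.

    Component categories: response-element motif in the promoter, promoter
    functionality (e.g. promoter-luciferase), in-vivo TF binding (ChIP-seq),
    in-vitro TF binding (EMSA), and differential expression upon pathway
    activation.  ``n_cell_types`` and ``n_groups`` count corroboration across
    cell types and independent research groups.
    """

    gene_symbol: str
    component_scores: dict[str, float] = field(default_factory=dict)
    n_cell_types: int = 0
    n_groups: int = 0

    def __post_init__(self) -> None:
        for cat, value in self.component_scores.items():
            if cat not in EVIDENCE_CATEGORIES:
                raise ValueError(f"unknown evidence category {cat!r}")
            if value < 0:
                raise ValueError(f"component score for {cat!r} must be >= 0")
        if self.n_cell_types < 0 or self.n_groups < 0:
            raise ValueError("corroboration counts must be >= 0")


def rank_candidate_genes(
    records: Iterable[GeneEvidenceRecord],
    weights: Mapping[str, float] | None = None,
    corroboration_bonus: float = 0.5,
) -> list[tuple[str, float]]:
    """Rank candidate target genes by weighted total evidence score.

    total = sum(weight[cat] * component[cat]) +
            corroboration_bonus * (n_cell_types + n_groups)

    Descending by total; ties broken alphabetically by gene symbol.
    """
    records = list(records)
    present = {cat for r in records for cat in r.component_scores}
    if weights is None:
        weights = {cat: 1.0 for cat in EVIDENCE_CATEGORIES}
    for cat, w in weights.items():
        if w < 0:
            raise ValueError(f"weight for {cat!r} must be >= 0")
    missing = present - set(weights)
    if missing:
        raise ValueError(f"weights missing for categories: {sorted(missing)}")
    if corroboration_bonus < 0:
        raise ValueError("corroboration_bonus must be >= 0")
    totals = []
    for r in records:
        total = sum(weights[cat] * v for cat, v in r.component_scores.items())
        total += corroboration_bonus * (r.n_cell_types + r.n_groups)
        totals.append((r.gene_symbol, float(total)))
    return sorted(totals, key=lambda item: (-item[1], item[0]))
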