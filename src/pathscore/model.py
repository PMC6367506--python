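"""Tree-structured Bayesian network for pathway activity inference.

A pathway model is a three-layer tree.  At the root sits the latent
transcription complex (TC) of the pathway — the transcription factor that is
either actively transcribing its target genes or not.  Each direct target
gene (TG) is a latent binary node (transcriptionally *up* or *down*) whose
state depends probabilistically on the TC state.  Each target gene carries
one or more observed probeset (PS) nodes — microarray probesets measuring
that transcript — each binary (*high* or *low* hybridisation) conditional on
the gene state.

Because the graph is a tree, the posterior probability that the TC is active
given probeset evidence factorises over genes and is computed exactly.
Continuous intensities enter as *soft evidence*: a weight in [0, 1] for the
"high" state obtained from a logistic squash of the log2 intensity around a
per-probeset discretisation threshold (``soft_scale -> inf`` recovers a hard
high/low cut, also available as a mode).

The activity read-out is the probability ``P(TC = active | evidence)`` and
its log2-odds transform ``log2(P / (1 - P))`` — the pathway activity score.
Probabilities are clamped to ``[EPSILON, 1 - EPSILON]`` with
``EPSILON = 1e-12`` before the odds transform, so the score is capped at
``±LOG2ODDS_CAP ≈ ±39.86``.
"""

from __future__ import annotations

import copy
import itertools
import math
from dataclasses import dataclass, field
from functools import reduce
from typing import Mapping

import numpy as np

__all__ = [
    "EPSILON",
    "LOG2ODDS_CAP",
    "UP_REGULATED",
    "DOWN_REGULATED",
    "ACTIVE",
    "INACTIVE",
    "INDETERMINATE",
    "ModelError",
    "FrozenModelError",
    "EvidenceError",
    "ProbesetNode",
    "TargetGeneNode",
    "PathwayModel",
    "EvidenceVector",
    "ActivityResult",
    "evidence_from_intensities",
    "infer_activity",
    "joint_enumeration_oracle",
    "to_log2odds",
    "to_scaled_score",
    "call_activity",
]

EPSILON = 1e-12
LOG2ODDS_CAP = math.log2((1.0 - EPSILON) / EPSILON)

UP_REGULATED = "up_regulated"
DOWN_REGULATED = "down_regulated"

ACTIVE = "active"
INACTIVE = "inactive"
INDETERMINATE = "indeterminate"

_LN2 = math.log(2.0)


class ModelError(ValueError):
    """A pathway model violates a structural or probabilistic invariant."""


class FrozenModelError(ModelError):
    """Attempted probability mutation of a frozen (calibrated) model."""


class EvidenceError(ValueError):
    """Evidence refers to unknown probesets or carries invalid weights."""


def _check_open_prob(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and 0.0 < float(value) < 1.0):
        raise ModelError(f"{name} must lie strictly inside (0, 1), got {value!r}")


@dataclass
class ProbesetNode:
    """Observed microarray probeset: binary high/low given the gene state.

    ``log2_threshold`` is the discretisation cut in log2(intensity + 1) units;
    ``soft_scale`` is the steepness of the logistic soft-evidence mapping.
    """

    probeset_id: str
    p_high_given_up: float = 0.85
    p_high_given_down: float = 0.15
    log2_threshold: float = 8.0
    soft_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.probeset_id:
            raise ModelError("probeset_id must be a non-empty string")
        _check_open_prob(f"{self.probeset_id}: p_high_given_up", self.p_high_given_up)
        _check_open_prob(f"{self.probeset_id}: p_high_given_down", self.p_high_given_down)
        if not math.isfinite(self.log2_threshold):
            raise ModelError(f"{self.probeset_id}: log2_threshold must be finite")
        if not (self.soft_scale > 0 and math.isfinite(self.soft_scale)):
            raise ModelError(f"{self.probeset_id}: soft_scale must be positive and finite")


@dataclass
class TargetGeneNode:
    """Latent target gene: up or down depending on the TC state.

    ``direction`` states the expected change upon pathway activation; the CPT
    must respect it (an up-regulated gene is more likely up under an active
    TC than under an inactive one, and vice versa).
    """

    gene_symbol: str
    probesets: list[ProbesetNode]
    direction: str = UP_REGULATED
    p_up_given_active: float = 0.90
    p_up_given_inactive: float = 0.10

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ModelError("gene_symbol must be a non-empty string")
        if self.direction not in (UP_REGULATED, DOWN_REGULATED):
            raise ModelError(
                f"{self.gene_symbol}: direction must be "
                f"{UP_REGULATED!r} or {DOWN_REGULATED!r}, got {self.direction!r}"
            )
        _check_open_prob(f"{self.gene_symbol}: p_up_given_active", self.p_up_given_active)
        _check_open_prob(f"{self.gene_symbol}: p_up_given_inactive", self.p_up_given_inactive)
        if self.direction == UP_REGULATED:
            if not self.p_up_given_active > self.p_up_given_inactive:
                raise ModelError(
                    f"{self.gene_symbol}: up-regulated gene requires "
                    "p_up_given_active > p_up_given_inactive"
                )
        else:
            if not self.p_up_given_active < self.p_up_given_inactive:
                raise ModelError(
                    f"{self.gene_symbol}: down-regulated gene requires "
                    "p_up_given_active < p_up_given_inactive"
                )
        if not self.probesets:
            raise ModelError(f"{self.gene_symbol}: at least one probeset is required")


@dataclass
class PathwayModel:
    """The full three-layer network for one signalling pathway.

    ``thresholds`` maps a context label (tissue/cell type, e.g. ``"default"``
    or ``"brain"``) to the log2odds decision threshold used for qualitative
    calls in that context.  Once ``frozen`` is set (after calibration), any
    mutation of probabilities is rejected, but threshold entries may still be
    added — re-thresholding keeps exactly the same model.
    """

    pathway_name: str
    target_genes: list[TargetGeneNode]
    prior_active: float = 0.5
    frozen: bool = False
    thresholds: dict[str, float] = field(default_factory=lambda: {"default": 0.0})

    def __post_init__(self) -> None:
        if not self.pathway_name:
            raise ModelError("pathway_name must be a non-empty string")
        _check_open_prob("prior_active", self.prior_active)
        if not self.target_genes:
            raise ModelError("a pathway model needs at least one target gene")
        seen: set[str] = set()
        for gene in self.target_genes:
            for ps in gene.probesets:
                if ps.probeset_id in seen:
                    raise ModelError(f"duplicate probeset ID {ps.probeset_id!r}")
                seen.add(ps.probeset_id)
        for context, value in self.thresholds.items():
            if not math.isfinite(value):
                raise ModelError(f"threshold {context!r} must be finite")

    # -- lookup -----------------------------------------------------------

    @property
    def probeset_ids(self) -> list[str]:
        return [ps.probeset_id for g in self.target_genes for ps in g.probesets]

    def gene(self, gene_symbol: str) -> TargetGeneNode:
        for g in self.target_genes:
            if g.gene_symbol == gene_symbol:
                return g
        raise KeyError(gene_symbol)

    def probeset(self, probeset_id: str) -> ProbesetNode:
        for g in self.target_genes:
            for ps in g.probesets:
                if ps.probeset_id == probeset_id:
                    return ps
        raise KeyError(probeset_id)

    def copy(self) -> "PathwayModel":
        return copy.deepcopy(self)

    # -- guarded mutation -------------------------------------------------

    def _require_unfrozen(self) -> None:
        if self.frozen:
            raise FrozenModelError(
                f"model {self.pathway_name!r} is frozen; probabilities are immutable "
                "(only decision thresholds may be added)"
            )

    def set_prior(self, prior_active: float) -> None:
        self._require_unfrozen()
        _check_open_prob("prior_active", prior_active)
        self.prior_active = float(prior_active)

    def set_gene_cpt(
        self,
        gene_symbol: str,
        *,
        p_up_given_active: float | None = None,
        p_up_given_inactive: float | None = None,
    ) -> None:
        self._require_unfrozen()
        gene = self.gene(gene_symbol)
        new = copy.copy(gene)
        if p_up_given_active is not None:
            new.p_up_given_active = float(p_up_given_active)
        if p_up_given_inactive is not None:
            new.p_up_given_inactive = float(p_up_given_inactive)
        new.__post_init__()  # re-validate ordering constraint
        gene.p_up_given_active = new.p_up_given_active
        gene.p_up_given_inactive = new.p_up_given_inactive

    def set_probeset_cpt(
        self,
        probeset_id: str,
        *,
        p_high_given_up: float | None = None,
        p_high_given_down: float | None = None,
        log2_threshold: float | None = None,
        soft_scale: float | None = None,
    ) -> None:
        self._require_unfrozen()
        ps = self.probeset(probeset_id)
        new = copy.copy(ps)
        if p_high_given_up is not None:
            new.p_high_given_up = float(p_high_given_up)
        if p_high_given_down is not None:
            new.p_high_given_down = float(p_high_given_down)
        if log2_threshold is not None:
            new.log2_threshold = float(log2_threshold)
        if soft_scale is not None:
            new.soft_scale = float(soft_scale)
        new.__post_init__()
        ps.p_high_given_up = new.p_high_given_up
        ps.p_high_given_down = new.p_high_given_down
        ps.log2_threshold = new.log2_threshold
        ps.soft_scale = new.soft_scale

    def set_threshold(self, context: str, log2odds_threshold: float) -> None:
        """Add or replace a per-context decision threshold (allowed when frozen)."""
        if not math.isfinite(log2odds_threshold):
            raise ModelError("threshold must be finite")
        self.thresholds[context] = float(log2odds_threshold)


@dataclass
class EvidenceVector:
    """Per-probeset weight of the 'high' state: 1 = certainly high, 0 = low.

    Probesets absent from ``weights`` carry no observation and marginalise
    out of the inference.
    """

    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ps_id, w in self.weights.items():
            if not (isinstance(w, (int, float)) and math.isfinite(w) and 0.0 <= w <= 1.0):
                raise EvidenceError(
                    f"evidence weight for {ps_id!r} must lie in [0, 1], got {w!r}"
                )

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class ActivityResult:
    """Inference read-out for one sample and one pathway.

    ``log2odds`` is the pathway activity score; ``gene_contributions`` are the
    additive per-gene log2 likelihood-ratio terms, so the prior log2odds plus
    their sum reproduces the score (before the ±LOG2ODDS_CAP clip).
    """

    probability_active: float
    log2odds: float
    call: str
    gene_contributions: dict[str, float]
    scaled_score: float | None = None


def _validate_evidence(model: PathwayModel, evidence: EvidenceVector) -> None:
    known = set(model.probeset_ids)
    for ps_id in evidence.weights:
        if ps_id not in known:
            raise EvidenceError(
                f"probeset {ps_id!r} in evidence is not part of model "
                f"{model.pathway_name!r}"
            )


def evidence_from_intensities(
    model: PathwayModel,
    intensities: Mapping[str, float],
    mode: str = "soft",
) -> EvidenceVector:
    """Convert linear-scale probeset intensities into evidence weights.

    For each model probeset with a finite intensity value, the log2(I + 1)
    value is compared with the probeset's discretisation threshold.  In
    ``"soft"`` mode the weight is ``logistic((x - t) * soft_scale)``; in
    ``"hard"`` mode it is 1 if ``x > t`` and 0 otherwise.  Intensities for
    probesets not in the model are ignored; missing/NaN values yield no
    observation.  Negative intensities are rejected — they are QC findings
    and must be handled before scoring.
    """
    if mode not in ("soft", "hard"):
        raise ValueError(f"mode must be 'soft' or 'hard', got {mode!r}")
    weights: dict[str, float] = {}
    for gene in model.target_genes:
        for ps in gene.probesets:
            value = intensities.get(ps.probeset_id)
            if value is None:
                continue
            value = float(value)
            if math.isnan(value):
                continue
            if value < 0 or not math.isfinite(value):
                raise EvidenceError(
                    f"intensity for {ps.probeset_id!r} must be a finite non-negative "
                    f"value, got {value!r} (run QC before scoring)"
                )
            x = math.log2(value + 1.0)
            if mode == "hard":
                weights[ps.probeset_id] = 1.0 if x > ps.log2_threshold else 0.0
            else:
                z = (x - ps.log2_threshold) * ps.soft_scale
                weights[ps.probeset_id] = 1.0 / (1.0 + math.exp(-z))
    return EvidenceVector(weights)


def _log_gene_likelihood(gene: TargetGeneNode, weights: Mapping[str, float], tc_active: bool) -> float:
    """log P(observed probeset evidence of ``gene`` | TC state).

    Sum over the latent gene state of P(TG | TC) times the product over the
    observed probesets of the soft-evidence factor
    ``w * P(high | TG) + (1 - w) * P(low | TG)``.  Returns 0.0 (likelihood 1)
    when no probeset of the gene is observed.
    """
    p_up = gene.p_up_given_active if tc_active else gene.p_up_given_inactive
    log_up = 0.0
    log_down = 0.0
    observed = False
    for ps in gene.probesets:
        w = weights.get(ps.probeset_id)
        if w is None:
            continue
        observed = True
        log_up += math.log(w * ps.p_high_given_up + (1.0 - w) * (1.0 - ps.p_high_given_up))
        log_down += math.log(w * ps.p_high_given_down + (1.0 - w) * (1.0 - ps.p_high_given_down))
    if not observed:
        return 0.0
    return float(np.logaddexp(math.log(p_up) + log_up, math.log(1.0 - p_up) + log_down))


def infer_activity(
    model: PathwayModel,
    evidence: EvidenceVector,
    threshold_context: str = "default",
) -> ActivityResult:
    """Exact posterior probability that the pathway's TC is active.

    The tree structure makes the evidence likelihood factorise over target
    genes; computation is in log space.  The qualitative call uses the
    model's threshold for ``threshold_context`` (0.0 if absent).
    """
    _validate_evidence(model, evidence)
    prior_log2odds = math.log2(model.prior_active / (1.0 - model.prior_active))
    contributions: dict[str, float] = {}
    total = prior_log2odds
    for gene in model.target_genes:
        la = _log_gene_likelihood(gene, evidence.weights, tc_active=True)
        li = _log_gene_likelihood(gene, evidence.weights, tc_active=False)
        contrib = (la - li) / _LN2
        contributions[gene.gene_symbol] = contrib
        total += contrib
    log2odds = min(max(total, -LOG2ODDS_CAP), LOG2ODDS_CAP)
    probability = 1.0 / (1.0 + 2.0 ** (-log2odds))
    threshold = model.thresholds.get(threshold_context, 0.0)
    return ActivityResult(
        probability_active=probability,
        log2odds=log2odds,
        call=call_activity(log2odds, threshold),
        gene_contributions=contributions,
    )


def joint_enumeration_oracle(
    model: PathwayModel,
    evidence: EvidenceVector,
    max_probeset_states: int = 2**20,
) -> float:
    """P(TC active | evidence) by explicit summation over every joint state.

    Test oracle only: enumerates all 2 x 2^#genes x 2^#probesets joint
    configurations of the network.  The 2^#probesets probeset-configuration
    block is materialised as an explicit joint vector (Kronecker product of
    per-probeset factors) for each (TC, gene-states) assignment, so models
    with up to ~20 probesets remain tractable; larger models are rejected.
    """
    _validate_evidence(model, evidence)
    genes = model.target_genes
    flat_ps = [(gi, ps) for gi, g in enumerate(genes) for ps in g.probesets]
    if 2 ** len(flat_ps) > max_probeset_states:
        raise ModelError(
            f"model has {len(flat_ps)} probesets; joint enumeration capped at "
            f"{max_probeset_states} probeset configurations"
        )
    numerator = 0.0
    denominator = 0.0
    for tc_active in (True, False):
        p_tc = model.prior_active if tc_active else 1.0 - model.prior_active
        for gene_states in itertools.product((True, False), repeat=len(genes)):
            p_genes = p_tc
            for g, up in zip(genes, gene_states):
                p_up = g.p_up_given_active if tc_active else g.p_up_given_inactive
                p_genes *= p_up if up else 1.0 - p_up
            # factor per probeset over its (high, low) states, folding in the
            # evidence weight; unobserved probesets get evidence factor 1
            factors = []
            for gi, ps in flat_ps:
                p_high = ps.p_high_given_up if gene_states[gi] else ps.p_high_given_down
                w = evidence.weights.get(ps.probeset_id)
                if w is None:
                    factors.append(np.array([p_high, 1.0 - p_high]))
                else:
                    factors.append(np.array([p_high * w, (1.0 - p_high) * (1.0 - w)]))
            joint = reduce(np.kron, factors, np.array([1.0]))
            block = p_genes * float(joint.sum())
            denominator += block
            if tc_active:
                numerator += block
    return numerator / denominator


def to_log2odds(p: float) -> float:
    """log2 odds of a probability, clamped to [EPSILON, 1 - EPSILON] first.

    The complement is formed before clamping so the transform is exactly
    antisymmetric (including at the caps) despite floating-point rounding.
    """
    if not (isinstance(p, (int, float)) and 0.0 <= p <= 1.0):
        raise ValueError(f"probability must lie in [0, 1], got {p!r}")
    q = max(1.0 - float(p), EPSILON)
    p = max(float(p), EPSILON)
    return math.log2(p) - math.log2(q)


def to_scaled_score(log2odds: float, lo: float, hi: float) -> float:
    """Affine map of a log2odds score onto a 0-100 scale, clipped at the ends."""
    if not lo < hi:
        raise ValueError(f"require lo < hi, got lo={lo!r}, hi={hi!r}")
    return float(np.clip(100.0 * (log2odds - lo) / (hi - lo), 0.0, 100.0))


def call_activity(log2odds: float, threshold: float) -> str:
    """Qualitative call: active iff the score strictly exceeds the threshold.

    Equality at the threshold is deliberately called inactive (conservative,
    deterministic tie rule).
    """
    if not (math.isfinite(log2odds) and math.isfinite(threshold)):
        raise ValueError("log2odds and threshold must be finite")
    return ACTIVE if log2odds > threshold else INACTIVE
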