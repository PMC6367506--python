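"""PI3K read-out via FOXO activity, the SOD2 stress rule, and reporting.

The PI3K growth-factor pathway removes the FOXO transcription factor from
the nucleus, so measured FOXO transcriptional activity is *inversely*
related to PI3K pathway activity — but only in the absence of cellular
oxidative stress.  Under oxidative stress FOXO is alternatively
phosphorylated and transcribes protective targets such as SOD2, so an
elevated SOD2 level (above a reference mean + 2 SD threshold) means FOXO
activity no longer reads out PI3K and no conclusion can be drawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Sample
from .model import INDETERMINATE, ActivityResult, call_activity

__all__ = [
    "StressAssessment",
    "Pi3kReadout",
    "assess_oxidative_stress",
    "sod2_level_from_sample",
    "interpret_pi3k",
    "multi_pathway_report",
]


@dataclass
class StressAssessment:
    """SOD2-based oxidative-stress flag against a normal-tissue reference.

    ``stressed`` is true iff the sample SOD2 level *strictly* exceeds the
    reference mean + 2 SD; a level exactly at the threshold counts as
    non-stressed.
    """

    sod2_level: float
    reference_mean: float
    reference_sd: float
    threshold: float
    stressed: bool


@dataclass
class Pi3kReadout:
    """PI3K activity inferred from a FOXO score under the stress rule.

    When the sample is oxidative-stressed the PI3K score is absent and the
    call is indeterminate; otherwise the PI3K score is minus the FOXO score.
    """

    foxo_log2odds: float
    stress: StressAssessment
    pi3k_log2odds: float | None
    call: str


def assess_oxidative_stress(
    sod2_level: float, reference: Sequence[float]
) -> StressAssessment:
    """Flag oxidative stress from a SOD2 level and normal-tissue reference values.

    The threshold is the reference sample mean plus two sample standard
    deviations (n - 1 denominator).  At least two reference values are
    required.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.size < 2:
        raise ValueError("need at least 2 reference SOD2 values")
    mean = float(reference.mean())
    sd = float(reference.std(ddof=1))
    threshold = mean + 2.0 * sd
    return StressAssessment(
        sod2_level=float(sod2_level),
        reference_mean=mean,
        reference_sd=sd,
        threshold=threshold,
        stressed=bool(sod2_level > threshold),
    )


def sod2_level_from_sample(sample: Sample, probeset_ids: Sequence[str]) -> float:
    """Sample SOD2 expression: mean of the designated probeset intensities.

    Probesets missing from the sample are skipped; all missing is an error.
    """
    values = [
        sample.intensities[ps]
        for ps in probeset_ids
        if ps in sample.intensities and not math.isnan(sample.intensities[ps])
    ]
    if not values:
        raise ValueError(
            f"sample {sample.sample_id!r} has none of the SOD2 probesets {list(probeset_ids)}"
        )
    return float(np.mean(values))


def interpret_pi3k(
    foxo_result: ActivityResult,
    stress: StressAssessment,
    threshold: float = 0.0,
) -> Pi3kReadout:
    """Turn a FOXO activity result into a PI3K pathway read-out."""
    if stress.stressed:
        return Pi3kReadout(
            foxo_log2odds=foxo_result.log2odds,
            stress=stress,
            pi3k_log2odds=None,
            call=INDETERMINATE,
        )
    pi3k = -foxo_result.log2odds
    return Pi3kReadout(
        foxo_log2odds=foxo_result.log2odds,
        stress=stress,
        pi3k_log2odds=pi3k,
        call=call_activity(pi3k, threshold),
    )


def multi_pathway_report(
    results: Sequence[tuple[str, Mapping[str, ActivityResult]]] | Mapping[str, Mapping[str, ActivityResult]],
    qc_pass: Mapping[str, bool] | None = None,
    annotation: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One row per sample, one log2odds column per pathway.

    ``results`` maps sample_id -> {pathway_name -> ActivityResult} (a mapping
    or an ordered sequence of pairs; duplicate sample IDs are rejected).
    Columns are ``sample_id``, ``qc_pass``, ``annotation`` and then the
    pathway names in sorted order; a pathway missing for a sample yields an
    empty (NaN) cell.
    """
    if isinstance(results, Mapping):
        items = list(results.items())
    else:
        items = list(results)
    ids = [sid for sid, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated sample IDs in report input")
    if not items or any(not per_sample for _, per_sample in items):
        raise ValueError("each sample needs at least one pathway result")
    pathways = sorted({p for _, per_sample in items for p in per_sample})
    qc_pass = qc_pass or {}
    annotation = annotation or {}
    rows = []
    for sid, per_sample in items:
        row: dict[str, object] = {
            "sample_id": sid,
            "qc_pass": qc_pass.get(sid, True),
            "annotation": annotation.get(sid, ""),
        }
        for p in pathways:
            result = per_sample.get(p)
            row[p] = np.nan if result is None else result.log2odds
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", "qc_pass", "annotation", *pathways])
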