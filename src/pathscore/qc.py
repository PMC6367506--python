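"""Matrix-level sample quality control.

Array QC conventionally covers a dozen parameters; only five are computable
from an expression matrix (negative intensities, >16-bit intensities, mean
intensity band, GAPDH and ACTB 3'/5' ratios).  The remaining checks
(spike-in controls, border controls, centre of intensity, RNA degradation
slope) need raw probe-level data and are reported here as *not evaluable*
placeholder slots; they never fail a sample unless strict mode is on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io import ExpressionMatrix, Sample

__all__ = [
    "QCConfig",
    "QCCheck",
    "QCReport",
    "run_qc",
    "three_prime_ratio",
    "filter_by_qc",
    "MAX_16BIT",
]

MAX_16BIT = 65535.0

# checks needing probe-level (CEL) data; reported as not-evaluable slots
_CEL_LEVEL_CHECKS = (
    "poly_a_spike_in_controls",
    "labelled_crna_spike_in_controls",
    "centre_of_intensity",
    "positive_border_controls",
    "negative_border_controls",
    "rna_degradation_slope",
)


@dataclass
class QCConfig:
    """Thresholds and control probesets for matrix-level QC.

    Defaults follow HG-U133 Plus 2.0 convention: AFFX control probesets for
    the GAPDH/ACTB 3'/5' degradation checks, a ratio cap of 3.0, and a broad
    mean-intensity band.  All values are configuration, to be adapted to the
    normalisation in use.
    """

    mean_intensity_band: tuple[float, float] = (50.0, 5000.0)
    ratio_cap: float = 3.0
    gapdh_3: str = "AFFX-HUMGAPDH/M33197_3_at"
    gapdh_5: str = "AFFX-HUMGAPDH/M33197_5_at"
    actb_3: str = "AFFX-HSAC07/X00351_3_at"
    actb_5: str = "AFFX-HSAC07/X00351_5_at"
    strict: bool = False  # not-evaluable checks fail the sample when True


@dataclass
class QCCheck:
    """One QC parameter: metric value, human-readable rule, tri-state outcome.

    ``passed`` is None when the check could not be evaluated from the matrix.
    """

    name: str
    metric_value: float
    threshold_description: str
    passed: bool | None


@dataclass
class QCReport:
    sample_id: str
    checks: list[QCCheck] = field(default_factory=list)
    overall_pass: bool = True


def three_prime_ratio(sample: Sample, probeset_3: str, probeset_5: str) -> float | None:
    """3'/5' intensity ratio of a control gene; None when not evaluable."""
    v3 = sample.intensities.get(probeset_3)
    v5 = sample.intensities.get(probeset_5)
    if v3 is None or v5 is None or math.isnan(v3) or math.isnan(v5):
        return None
    if v5 <= 0 or v3 <= 0:
        return None
    return float(v3) / float(v5)


def run_qc(sample: Sample, config: QCConfig | None = None) -> QCReport:
    """Run all matrix-level checks on one sample, in a fixed order."""
    config = config or QCConfig()
    values = [v for v in sample.intensities.values() if not math.isnan(v)]
    if not values:
        raise ValueError(f"sample {sample.sample_id!r} has no intensity values")
    checks: list[QCCheck] = []

    n_negative = sum(1 for v in values if v < 0)
    checks.append(
        QCCheck("negative_intensities", float(n_negative), "count == 0", n_negative == 0)
    )
    n_over = sum(1 for v in values if v > MAX_16BIT)
    checks.append(
        QCCheck("over_16bit_intensities", float(n_over), f"count == 0 (cap {MAX_16BIT:g})", n_over == 0)
    )
    lo, hi = config.mean_intensity_band
    mean = sum(values) / len(values)
    checks.append(
        QCCheck("mean_intensity", float(mean), f"within [{lo:g}, {hi:g}]", lo <= mean <= hi)
    )
    for name, ps3, ps5 in (
        ("gapdh_3prime_5prime_ratio", config.gapdh_3, config.gapdh_5),
        ("actb_3prime_5prime_ratio", config.actb_3, config.actb_5),
    ):
        ratio = three_prime_ratio(sample, ps3, ps5)
        checks.append(
            QCCheck(
                name,
                math.nan if ratio is None else ratio,
                f"ratio <= {config.ratio_cap:g}",
                None if ratio is None else ratio <= config.ratio_cap,
            )
        )
    for name in _CEL_LEVEL_CHECKS:
        checks.append(QCCheck(name, math.nan, "requires probe-level data", None))

    evaluated = [c.passed for c in checks if c.passed is not None]
    overall = all(evaluated)
    if config.strict and any(c.passed is None for c in checks):
        overall = False
    return QCReport(sample_id=sample.sample_id, checks=checks, overall_pass=overall)


def filter_by_qc(
    matrix: ExpressionMatrix, reports: Sequence[QCReport] | Mapping[str, QCReport]
) -> ExpressionMatrix:
    """Drop samples that failed QC, preserving sample order.

    Exactly one report per matrix sample is required; an empty result matrix
    is valid (downstream operations reject it themselves).
    """
    if isinstance(reports, Mapping):
        by_id = dict(reports)
    else:
        by_id = {r.sample_id: r for r in reports}
    ids = set(matrix.sample_ids)
    if set(by_id) != ids:
        missing = sorted(ids - set(by_id)) + sorted(set(by_id) - ids)
        raise ValueError(f"QC reports do not match matrix samples: {missing}")
    keep = [sid for sid in matrix.sample_ids if by_id[sid].overall_pass]
    return matrix.subset_samples(keep)
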