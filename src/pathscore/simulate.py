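"""Synthetic two-class expression datasets drawn from a pathway model.

The generator follows the network's causal direction: the sample label fixes
the TC state; each target gene's up/down state is drawn from its
P(up | TC); each probeset's high/low state from P(high | gene state); and
the observed linear intensity is ``2**x - 1`` with ``x`` Gaussian around a
state-dependent log2 mean.  This emulates the two-class latent structure of
calibration data — it does not attempt probe-level artefacts, batch effects
or cross-hybridisation.

All randomness flows from a single seeded generator, so a configuration is
fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationSet
from .io import ExpressionMatrix, Sample
from .model import ACTIVE, INACTIVE, PathwayModel, ProbesetNode, TargetGeneNode

__all__ = ["SimulationConfig", "simulate_dataset", "make_example_model"]


@dataclass
class SimulationConfig:
    """Study-condition parameters for the generator.

    ``mu_low``/``mu_high`` are log2-intensity means of the low/high probeset
    states (defaults 6 and 10, a typical 16-fold separation on microarray
    log scale); ``sigma`` is the within-state log2 SD (default 0.5, i.e. the
    two states sit 8 sigma apart so the binary state is well resolved, which
    the calibration round-trip requires by design); ``dropout_rate`` is the
    probability that a probeset value is missing in a sample.
    """

    n_active: int
    n_inactive: int
    seed: int
    mu_low: float = 6.0
    mu_high: float = 10.0
    sigma: float = 0.5
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_active < 0 or self.n_inactive < 0:
            raise ValueError("sample counts must be non-negative")
        if not self.mu_high > self.mu_low:
            raise ValueError("mu_high must exceed mu_low")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


def simulate_dataset(
    model: PathwayModel, config: SimulationConfig
) -> tuple[ExpressionMatrix, CalibrationSet]:
    """Draw a labelled probeset-intensity dataset from the model.

    Active-labelled samples come first, then inactive; sample IDs encode the
    class.  Returns the matrix together with a calibration set carrying the
    generating labels.
    """
    rng = np.random.default_rng(config.seed)
    probeset_ids = model.probeset_ids
    samples: list[Sample] = []
    labels: dict[str, str] = {}
    plan = [(ACTIVE, i) for i in range(config.n_active)]
    plan += [(INACTIVE, i) for i in range(config.n_inactive)]
    for label, i in plan:
        sid = f"sim_{label}_{i + 1:04d}"
        tc_active = label == ACTIVE
        intensities: dict[str, float] = {}
        for gene in model.target_genes:
            p_up = gene.p_up_given_active if tc_active else gene.p_up_given_inactive
            gene_up = rng.random() < p_up
            for ps in gene.probesets:
                p_high = ps.p_high_given_up if gene_up else ps.p_high_given_down
                high = rng.random() < p_high
                mu = config.mu_high if high else config.mu_low
                x = rng.normal(mu, config.sigma)
                value = float(2.0**x - 1.0)
                if config.dropout_rate > 0 and rng.random() < config.dropout_rate:
                    continue
                intensities[ps.probeset_id] = value
        samples.append(Sample(sid, intensities, {"simulated_label": label}))
        labels[sid] = label
    matrix = ExpressionMatrix(list(probeset_ids), samples)
    return matrix, CalibrationSet(samples=samples, labels=labels)


def make_example_model(
    pathway_name: str = "EXAMPLE",
    n_genes: int = 28,
    n_probesets_per_gene: int = 2,
    p_up_given_active: float = 0.90,
    p_up_given_inactive: float = 0.10,
    p_high_given_up: float = 0.85,
    p_high_given_down: float = 0.15,
    log2_threshold: float = 8.0,
    soft_scale: float = 1.0,
    prior_active: float = 0.5,
    n_down_regulated: int = 0,
) -> PathwayModel:
    """A generic pathway model for simulation, examples and tests.

    Defaults mirror a typical signature of this kind: 28 direct target genes
    (real models select roughly 25-35) with two probesets each.  Gene
    symbols are ``TG01..``; probesets ``TG01_ps1..``.  The first
    ``n_down_regulated`` genes are encoded as down-regulated targets (their
    relation-(i) probabilities mirrored).
    """
    if n_genes < 1 or n_probesets_per_gene < 1:
        raise ValueError("need at least one gene and one probeset per gene")
    genes = []
    for g in range(1, n_genes + 1):
        down = g <= n_down_regulated
        probesets = [
            ProbesetNode(
                probeset_id=f"TG{g:02d}_ps{k}",
                p_high_given_up=p_high_given_up,
                p_high_given_down=p_high_given_down,
                log2_threshold=log2_threshold,
                soft_scale=soft_scale,
            )
            for k in range(1, n_probesets_per_gene + 1)
        ]
        genes.append(
            TargetGeneNode(
                gene_symbol=f"TG{g:02d}",
                direction="down_regulated" if down else "up_regulated",
                p_up_given_active=(
                    p_up_given_inactive if down else p_up_given_active
                ),
                p_up_given_inactive=(
                    p_up_given_active if down else p_up_given_inactive
                ),
                probesets=probesets,
            )
        )
    return PathwayModel(
        pathway_name=pathway_name, target_genes=genes, prior_active=prior_active
    )
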