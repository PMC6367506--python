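import numpy as np
import pytest

from pathscore import (
    EvidenceVector,
    PathwayModel,
    ProbesetNode,
    TargetGeneNode,
)


def random_model(rng: np.random.Generator, max_genes: int = 6, max_probesets: int = 3) -> PathwayModel:
    """A random tree model with non-degenerate CPTs and a mix of directions."""
    n_genes = int(rng.integers(1, max_genes + 1))
    genes = []
    ps_counter = 0
    for g in range(n_genes):
        direction = "up_regulated" if rng.random() < 0.7 else "down_regulated"
        lo, hi = sorted(rng.uniform(0.05, 0.95, size=2))
        if hi - lo < 0.05:
            lo, hi = 0.2, 0.8
        p_active, p_inactive = (hi, lo) if direction == "up_regulated" else (lo, hi)
        probesets = []
        for _ in range(int(rng.integers(1, max_probesets + 1))):
            ps_counter += 1
            probesets.append(
                ProbesetNode(
                    probeset_id=f"ps{ps_counter}",
                    p_high_given_up=float(rng.uniform(0.05, 0.95)),
                    p_high_given_down=float(rng.uniform(0.05, 0.95)),
                    log2_threshold=float(rng.uniform(5, 11)),
                    soft_scale=float(rng.uniform(0.5, 3.0)),
                )
            )
        genes.append(
            TargetGeneNode(
                gene_symbol=f"G{g + 1}",
                direction=direction,
                p_up_given_active=float(p_active),
                p_up_given_inactive=float(p_inactive),
                probesets=probesets,
            )
        )
    return PathwayModel(
        pathway_name="RANDOM",
        target_genes=genes,
        prior_active=float(rng.uniform(0.1, 0.9)),
    )


def random_evidence(rng: np.random.Generator, model: PathwayModel, p_observe: float = 0.8) -> EvidenceVector:
    weights = {
        ps_id: float(rng.random())
        for ps_id in model.probeset_ids
        if rng.random() < p_observe
    }
    return EvidenceVector(weights)


@pytest.fixture
def tiny_model() -> PathwayModel:
    """One up-regulated gene, one probeset, symmetric strong CPTs."""
    return PathwayModel(
        pathway_name="TINY",
        target_genes=[
            TargetGeneNode(
                gene_symbol="G1",
                probesets=[ProbesetNode("PS1", p_high_given_up=0.9, p_high_given_down=0.1)],
                p_up_given_active=0.9,
                p_up_given_inactive=0.1,
            )
        ],
        prior_active=0.5,
    )
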