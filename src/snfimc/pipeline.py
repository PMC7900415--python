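"""End-to-end composition: similarities -> fusion -> completion -> scores.

The full pipeline takes the association matrix plus the two static
similarity inputs (disease semantic similarity from the term DAG, miRNA
functional similarity) and
  1. computes GIP kernel similarity for diseases and miRNAs from A,
  2. fuses (semantic, GIP) and (functional, GIP) per entity class with SNF,
  3. fits the nonnegative inductive completion on A with the fused
     similarities as feature matrices,
  4. scores every disease-miRNA pair.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any

from .containers import AssociationMatrix, ScoreMatrix, SimilarityMatrix
from .gip import gip_similarity
from .imc import IMCConfig, IMCFactors, fit_imc, predict_scores
from .semantic import DEFAULT_DELTA
from .snf import SNFConfig, snf_fuse


@dataclass
class PipelineConfig:
    """Every knob of the end-to-end run, with defaults.

    ``delta`` is consumed upstream when the semantic similarity is built
    from a DAG; it is carried here so a run's effective configuration is
    complete and reproducible from its own echo.
    """

    delta: float = DEFAULT_DELTA
    gamma_prime_disease: float = 1.0
    gamma_prime_mirna: float = 1.0
    snf: SNFConfig = field(default_factory=SNFConfig)
    imc: IMCConfig = field(default_factory=IMCConfig)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        snf = SNFConfig(**d.pop("snf", {}))
        imc = IMCConfig(**d.pop("imc", {}))
        return cls(snf=snf, imc=imc, **d)


def build_similarities(
    assoc: AssociationMatrix,
    disease_sim: SimilarityMatrix,
    mirna_sim: SimilarityMatrix,
    config: PipelineConfig | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Fused disease and miRNA similarities (Sd, Sm) for the given A.

    ``disease_sim`` / ``mirna_sim`` are the static views (semantic,
    functional); the GIP views are recomputed here from ``assoc``, so
    passing a masked association matrix yields leak-free fold
    similarities.
    """
    config = config or PipelineConfig()
    if disease_sim.ids != assoc.disease_ids:
        raise ValueError("disease similarity ids do not match association rows")
    if mirna_sim.ids != assoc.mirna_ids:
        raise ValueError("miRNA similarity ids do not match association columns")
    gkd = gip_similarity(assoc, "disease", config.gamma_prime_disease)
    gkm = gip_similarity(assoc, "mirna", config.gamma_prime_mirna)
    sd = snf_fuse(disease_sim, gkd, config.snf)
    sm = snf_fuse(mirna_sim, gkm, config.snf)
    return sd, sm


def predict(
    assoc: AssociationMatrix,
    disease_sim: SimilarityMatrix,
    mirna_sim: SimilarityMatrix,
    config: PipelineConfig | None = None,
) -> tuple[ScoreMatrix, IMCFactors]:
    """Run the full pipeline and score every disease-miRNA pair."""
    config = config or PipelineConfig()
    sd, sm = build_similarities(assoc, disease_sim, mirna_sim, config)
    factors = fit_imc(assoc, sd, sm, config.imc)
    scores = predict_scores(sd, sm, factors, assoc.disease_ids, assoc.mirna_ids)
    return scores, factors
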