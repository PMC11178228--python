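"""Genotype-specific splicing-defect models and ground-truth tables.

Two mechanistic regimes are modelled on top of a shared per-intron
wild-type baseline efficiency:

* ``transcription_coupled`` — a gene is "affected" with probability
  ``sigmoid(alpha + beta * log(rate))``, so highly transcribed genes are
  more likely to suffer a splicing defect; an affected gene multiplies
  the baseline efficiency of *every* one of its introns by a single
  shared draw ``delta_g ~ Beta(delta_shape_a, delta_shape_b)``.  This
  produces the within-gene co-splicing signature: when one intron of a
  pre-mRNA is affected, its siblings tend to be affected too.

* ``motif_dependent`` — each intron is penalized independently in
  proportion to the Hamming distance of its donor hexamer from the
  consensus: ``se = baseline * (1 - gamma * m / 6)``.

The baseline draw depends only on ``(seed, intron)``, never on the
model kind, so wild-type (``kind="none"``) and mutant tables generated
from the same seed share their baselines and are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .._seeds import child_rng
from ..annotation import GeneModel, donor_hexamer

__all__ = ["DefectModel", "TruthTable", "assign_rates", "apply_defect_model"]

_KINDS = ("none", "transcription_coupled", "motif_dependent")


@dataclass
class DefectModel:
    kind: str = "none"
    # transcription_coupled parameters (logistic link on log rate)
    alpha: float = -4.0
    beta: float = 1.5
    delta_shape_a: float = 2.0
    delta_shape_b: float = 6.0
    # motif_dependent parameter: penalty per 5'SS consensus mismatch
    gamma: float = 0.8
    # wild-type per-intron baseline efficiency ~ Beta(a, b)
    baseline_se_a: float = 30.0
    baseline_se_b: float = 1.5
    consensus_5ss: str = "GTAAGT"

    def validate(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        for name in ("delta_shape_a", "delta_shape_b", "baseline_se_a", "baseline_se_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class TruthTable:
    """Ground truth for recovery testing.

    ``introns`` holds one row per (genotype, gene, intron_index) with the
    true splicing efficiency; ``genes`` holds the transcription rate and
    the affected flag per gene.
    """

    introns: pd.DataFrame  # genotype, gene_id, intron_index, intron_id, true_se
    genes: pd.DataFrame  # genotype, gene_id, true_rate, gene_affected


def assign_rates(
    genes: list[GeneModel], mu: float, sigma: float, seed: int
) -> pd.DataFrame:
    """Draw per-gene transcription rates from LogNormal(mu, sigma).

    Rates play the role of an FPKM-like transcription proxy and are
    strictly positive.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = child_rng(seed, "rates")
    rates = rng.lognormal(mu, sigma, size=len(genes))
    return pd.DataFrame({"gene_id": [g.gene_id for g in genes], "rate": rates})


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def apply_defect_model(
    genes: list[GeneModel],
    rates: pd.DataFrame,
    model: DefectModel,
    seed: int,
    genome: Mapping[str, str] | None = None,
    genotype: str = "mut",
) -> TruthTable:
    """Compute true per-intron splicing efficiencies under ``model``.

    ``genome`` is required for ``motif_dependent`` (the donor hexamer is
    read off the sequence).  Baselines are drawn from the seed-derived
    ``baseline`` stream independently of ``model.kind``.
    """
    model.validate()
    rate_map = dict(zip(rates["gene_id"], rates["rate"]))

    intron_rows = []
    base_rng = child_rng(seed, "baseline")
    defect_rng = child_rng(seed, "defect", genotype)

    gene_rows = []
    for g in genes:
        rate = float(rate_map[g.gene_id])
        baselines = base_rng.beta(model.baseline_se_a, model.baseline_se_b, size=g.n_introns)
        affected = False
        if model.kind == "transcription_coupled":
            p_aff = float(expit(model.alpha + model.beta * np.log(rate)))
            affected = bool(defect_rng.random() < p_aff)
            delta_g = float(defect_rng.beta(model.delta_shape_a, model.delta_shape_b))
            se = baselines * (delta_g if affected else 1.0)
        elif model.kind == "motif_dependent":
            if genome is None:
                raise ValueError("motif_dependent model requires the genome sequences")
            mism = np.array(
                [_hamming(donor_hexamer(i, genome), model.consensus_5ss) for i in g.introns]
            )
            se = baselines * (1.0 - model.gamma * mism / 6.0)
            affected = bool(np.any(mism > 0)) and model.gamma > 0
        else:  # none
            se = baselines
        gene_rows.append((genotype, g.gene_id, rate, affected))
        for intr, s in zip(g.introns, se):
            intron_rows.append((genotype, g.gene_id, intr.intron_index, intr.id, float(s)))

    introns = pd.DataFrame(
        intron_rows, columns=["genotype", "gene_id", "intron_index", "intron_id", "true_se"]
    )
    genes_df = pd.DataFrame(
        gene_rows, columns=["genotype", "gene_id", "true_rate", "gene_affected"]
    )
    return TruthTable(introns=introns, genes=genes_df)
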