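"""Canonical simulation scenarios and their end-to-end readouts.

These presets define the study conditions the package's recovery checks
run under; they are fixed scenario definitions, not tuning knobs.

* ``transcription_coupled`` — default fission-yeast-like genome
  (degeneracy 0.15, protected GT/AG); gene-level defects whose odds
  grow with transcription rate (``alpha=-4, beta=1.5`` on log rate,
  shared per-gene severity ``delta_g ~ Beta(2, 6)``).
* ``motif_dependent`` — a more degenerate genome (per-position
  degeneracy 0.3, terminal dinucleotides mutable) with full per-mismatch
  penalty ``gamma=1``, so a donor site far from consensus can abolish
  splicing of its own intron while leaving siblings untouched.

Both use log-normal transcription rates (``mu=3, sigma=1`` on the log
scale, an FPKM-like scale with median ~20) and junction-read depth 3
reads per boundary per rate unit, giving median boundary coverage of
roughly 120 reads.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cosplicing, seqfeatures, splicing
from ._seeds import child_rng, child_seed
from .cytometry import GateConfig, call_hits, correct_autofluorescence, gate_events, summarize_well
from .simulate import (
    CytometrySimParams,
    DefectModel,
    GenomeSpec,
    apply_defect_model,
    assign_rates,
    default_plate_layout,
    simulate_genome,
    simulate_junction_counts,
    simulate_plate,
)

__all__ = [
    "mechanism_scenario",
    "mechanism_readout",
    "screen_scenario_recovery",
    "null_screen_false_positive_rate",
]

RATE_MU, RATE_SIGMA = 3.0, 1.0
DEPTH = 3.0


def mechanism_scenario(kind: str) -> tuple[GenomeSpec, DefectModel]:
    if kind == "transcription_coupled":
        spec = GenomeSpec(n_genes=1000)
        model = DefectModel(kind=kind, alpha=-4.0, beta=1.5)
    elif kind == "motif_dependent":
        spec = GenomeSpec(
            n_genes=1000, degeneracy=0.3, protect_terminal_dinucleotides=False
        )
        model = DefectModel(kind=kind, gamma=1.0)
    else:
        raise ValueError(f"unknown mechanism scenario {kind!r}")
    return spec, model


def mechanism_readout(kind: str, seed: int, k: int = 50) -> dict:
    """Run one full mechanism-discrimination analysis on one seed.

    Returns the three discriminating readouts: the worst-vs-best
    host-gene FPKM comparison, whether the worst-5% donor composition
    differs from background, and the anchor-conditioned co-splicing
    drop at non-anchor introns relative to the unaffected-anchor
    control.
    """
    spec, model = mechanism_scenario(kind)
    genome, genes = simulate_genome(spec, seed)
    rates = assign_rates(genes, RATE_MU, RATE_SIGMA, seed)
    wt_model = DefectModel(kind="none")
    truth_wt = apply_defect_model(genes, rates, wt_model, seed, genome, genotype="WT")
    truth_mut = apply_defect_model(genes, rates, model, seed, genome, genotype="mut")

    from .simulate.defects import TruthTable

    both = TruthTable(
        introns=pd.concat([truth_wt.introns, truth_mut.introns], ignore_index=True),
        genes=pd.concat([truth_wt.genes, truth_mut.genes], ignore_index=True),
    )
    counts = simulate_junction_counts(both, rates, DEPTH, seed)
    se_tab = splicing.splicing_efficiency(counts)
    se_wt = se_tab[se_tab["genotype"] == "WT"].set_index("intron_id")["se"]
    se_mut = se_tab[se_tab["genotype"] == "mut"].set_index("intron_id")["se"]
    ranked = splicing.rank_affected(se_wt, se_mut)

    # (a) expression association of the k worst vs k best spliced introns
    fpkm = rates.rename(columns={"rate": "fpkm"})
    assoc = cosplicing.expression_association(ranked, fpkm, k=k)

    # (b) donor-site composition of the worst 5% vs all quantified introns
    worst = splicing.select_extremes(ranked, 0.05, "worst")
    introns_by_id = {i.id: i for g in genes for i in g.introns}
    bg_windows = seqfeatures.extract_junction_windows(
        [introns_by_id[i] for i in ranked["intron_id"]], genome, (3, 8), "5p"
    )
    worst_windows = seqfeatures.extract_junction_windows(
        [introns_by_id[i] for i in worst], genome, (3, 8), "5p"
    )
    comp = seqfeatures.compare_to_background(
        seqfeatures.splice_site_matrix(worst_windows),
        seqfeatures.splice_site_matrix(bg_windows),
    )

    # (c) co-splicing drop at non-anchor introns, affected vs control anchor
    profiles = cosplicing.build_gene_profiles(
        se_tab[["gene_id", "intron_index", "genotype", "se"]], fpkm
    )

    def non_anchor_drop(comparator: str, threshold: float) -> float:
        drops = []
        for anchor in (1, 2, 3):
            prof = cosplicing.cosplicing_profile(
                profiles, n_introns=3, anchor=anchor, threshold=threshold, comparator=comparator
            )
            if prof.n_genes == 0:
                continue
            other = [p for p in range(3) if p != anchor - 1]
            drops.append(float(np.mean(prof.mean_se_wt[other] - prof.mean_se_mut[other])))
        return float(np.mean(drops)) if drops else float("nan")

    drop_affected = non_anchor_drop("lt", 0.5)
    drop_control = non_anchor_drop("gt", 0.9)
    excess = (
        drop_affected - drop_control
        if not (np.isnan(drop_affected) or np.isnan(drop_control))
        else float("nan")
    )
    return {
        "assoc_p": assoc["p_value"],
        "assoc_worst_higher": assoc["worst_mean"] > assoc["best_mean"],
        "motif_significant": bool(comp["significant"].any()),
        "cosplice_excess": excess,
        "n_quantified": int(len(ranked)),
    }


SCREEN_PLANTED = {"hitA": 0.45, "hitB": 0.55, "hitC": 0.65}


def screen_scenario_recovery(
    seed: int,
    n_null_strains: int = 26,
    n_events_per_well: int = 2500,
) -> dict:
    """Simulate one 96-well screen with three planted low-efficiency
    strains and report whether they are the top three by |log2fc|."""
    strains = ["WT_reporter"] + list(SCREEN_PLANTED) + [
        f"strain{k:03d}" for k in range(1, n_null_strains + 1)
    ]
    se_map = {
        (s, "dmut"): SCREEN_PLANTED.get(s, 0.9) for s in strains
    }
    params = CytometrySimParams(
        n_events_per_well=n_events_per_well, reporter_se_map=se_map
    )
    layout = default_plate_layout(strains, n_replicate_wells=3)
    tables = simulate_plate(layout, params, seed)

    summaries = []
    for row in layout.itertuples(index=False):
        gated = gate_events(tables[row.well], GateConfig())
        meta = {"well": row.well, "strain": row.strain, "reporter": row.reporter}
        summaries.append((row.role, summarize_well(gated, meta)))
    ctrl = next(w for role, w in summaries if role == "autofluor_control" and w.qc_pass)
    wells = correct_autofluorescence([w for role, w in summaries if role == "sample"], ctrl)
    ratios = pd.DataFrame(
        [(w.strain_id, w.ratio) for w in wells], columns=["strain", "ratio"]
    )
    results = call_hits(ratios, "WT_reporter")
    results = results[results["strain"] != "WT_reporter"]
    top3 = set(results.reindex(results["log2fc"].abs().sort_values(ascending=False).index)[
        "strain"
    ].head(3))
    return {"top3": top3, "recovered": top3 == set(SCREEN_PLANTED), "results": results}


def null_screen_false_positive_rate(
    seed: int,
    n_screens: int = 1000,
    n_strains: int = 8,
    n_reps: int = 3,
    ratio_cv: float = 0.03,
) -> float:
    """Fraction of null strains called at p < 0.05 over reduced screens.

    Every strain's replicate ratios are drawn from the reference
    distribution (the reduced stand-in for a plate with no planted
    effects), so the expected fraction is the nominal 5%.
    """
    rng = child_rng(seed, "null_screens")
    n_sig = 0
    n_tests = 0
    for _ in range(n_screens):
        rows = [("ref", r) for r in rng.normal(1.0, ratio_cv, n_reps)]
        for s in range(n_strains):
            rows += [(f"s{s}", r) for r in rng.normal(1.0, ratio_cv, n_reps)]
        results = call_hits(pd.DataFrame(rows, columns=["strain", "ratio"]), "ref")
        results = results[results["strain"] != "ref"]
        n_sig += int((results["p_value"] < 0.05).sum())
        n_tests += n_strains
    return n_sig / n_tests
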