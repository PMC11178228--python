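"""End-to-end workflows: reporter-screen and RNA-seq style analyses.

Both workflows run from a single :class:`RunConfig` (loadable from
YAML), derive all randomness from one master seed via the documented
sub-seed scheme, write every intermediate as a commented TSV, and
record a manifest (inputs, parameters, output hashes, warnings) so a
re-run with the same configuration is byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import cosplicing, cytometry, de, seqfeatures, splicing
from .annotation import write_fasta, write_gff3
from .io import file_sha256, read_events_csv, read_layout, write_tsv
from .simulate import (
    CytometrySimParams,
    DefectModel,
    GenomeSpec,
    apply_defect_model,
    assign_rates,
    default_plate_layout,
    simulate_gene_counts,
    simulate_genome,
    simulate_junction_counts,
    simulate_plate,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_screen_workflow", "run_rnaseq_workflow"]

VERSION = "0.1.0"


@dataclass
class RunConfig:
    scenario: str = "default"
    seed: int = 0
    params: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            scenario=raw.get("scenario", "default"),
            seed=int(raw.get("seed", 0)),
            params=raw.get("params", {}),
        )

    def block(self, name: str) -> dict[str, Any]:
        return dict(self.params.get(name, {}))


@dataclass
class RunManifest:
    workflow: str
    scenario: str
    seed: int
    version: str = VERSION
    stages: list[dict[str, Any]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, params: dict[str, Any], outputs: list[Path]) -> None:
        self.stages.append(
            {
                "stage": name,
                "params": {k: repr(v) for k, v in params.items()},
                "outputs": {str(p): file_sha256(p) for p in outputs},
            }
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


# ---------------------------------------------------------------------------
# screen workflow
# ---------------------------------------------------------------------------


def run_screen_workflow(config: RunConfig, out_dir: str | Path) -> RunManifest:
    """Plate simulation/ingestion -> gating -> correction -> hit calling.

    Writes ``wells.tsv``, ``screen_results.tsv``, ``volcano.tsv`` and
    ``manifest.json`` under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest("screen", config.scenario, config.seed)

    plate_cfg = config.block("plate")
    if "events_dir" in plate_cfg:
        layout = read_layout(plate_cfg["layout"])
        events_dir = Path(plate_cfg["events_dir"])
        tables = {
            row.well: read_events_csv(events_dir / f"{row.well}.csv")
            for row in layout.itertuples(index=False)
        }
    else:
        strains = plate_cfg.get("strains")
        planted = plate_cfg.get("planted", {})
        if strains is None:
            n_null = int(plate_cfg.get("n_null_strains", 20))
            strains = [plate_cfg.get("reference_strain", "WT_reporter")] + [
                f"strain{k:03d}" for k in range(1, n_null + 1)
            ]
        reporter = plate_cfg.get("reporter", "dmut")
        default_se = float(plate_cfg.get("default_se", 0.9))
        se_map = {(s, reporter): float(planted.get(s, default_se)) for s in strains}
        params = CytometrySimParams(
            n_events_per_well=int(plate_cfg.get("n_events_per_well", 10_000)),
            reporter_se_map=se_map,
        )
        layout = default_plate_layout(
            strains, reporter=reporter, n_replicate_wells=int(plate_cfg.get("n_replicate_wells", 3))
        )
        tables = simulate_plate(layout, params, config.seed)

    gate_cfg = cytometry.GateConfig(**config.block("gates"))
    min_events = int(config.block("qc").get("min_events", 1000))

    control_wells = layout[layout["role"] == "autofluor_control"]
    if control_wells.empty:
        raise ValueError("pre-flight: layout has no autofluorescence control well")

    summaries = []
    for row in layout.itertuples(index=False):
        gated = cytometry.gate_events(tables[row.well], gate_cfg)
        meta = {"well": row.well, "strain": row.strain, "reporter": row.reporter}
        summaries.append((row.role, cytometry.summarize_well(gated, meta, min_events)))

    controls = [w for role, w in summaries if role == "autofluor_control" and w.qc_pass]
    if not controls:
        raise ValueError("pre-flight: no autofluorescence control passed QC")
    # pool control medians into one synthetic control summary
    ctrl = controls[0]
    if len(controls) > 1:
        ctrl = cytometry.WellSummary(
            well_id="+".join(c.well_id for c in controls),
            strain_id=controls[0].strain_id,
            reporter_id=controls[0].reporter_id,
            n_gated=sum(c.n_gated for c in controls),
            median_yfp=float(np.mean([c.median_yfp for c in controls])),
            median_red=float(np.mean([c.median_red for c in controls])),
            corrected_red=float(np.mean([c.median_red for c in controls])),
            ratio=float("nan"),
            qc_pass=True,
        )

    sample_wells = [w for role, w in summaries if role == "sample"]
    corrected = cytometry.correct_autofluorescence(
        sample_wells, ctrl, channels=config.block("correction").get("channels", "red_only")
    )

    wells_df = pd.DataFrame([w.__dict__ for w in corrected])
    wells_path = out / "wells.tsv"
    write_tsv(wells_df, wells_path, {"stage": "wells", "min_events": str(min_events)})

    hits_cfg = config.block("hits")
    reference = hits_cfg.get("reference_strain", plate_cfg.get("reference_strain", "WT_reporter"))
    ratios = wells_df.rename(columns={"strain_id": "strain"})[["strain", "ratio"]]
    results = cytometry.call_hits(
        ratios,
        reference_strain=reference,
        p_threshold=float(hits_cfg.get("p_threshold", 0.05)),
        lfc_threshold=float(hits_cfg.get("lfc_threshold", 0.0)),
        bh_correct=bool(hits_cfg.get("bh_correct", False)),
    )
    results_path = out / "screen_results.tsv"
    write_tsv(results, results_path, {"stage": "hits", "reference": reference})

    volcano = results[["strain", "log2fc", "p_value"]].copy()
    volcano["neg_log10_p"] = -np.log10(volcano["p_value"])
    volcano_path = out / "volcano.tsv"
    write_tsv(volcano, volcano_path, {"stage": "volcano"})

    manifest.add_stage(
        "screen", {"reference": reference, "min_events": min_events},
        [wells_path, results_path, volcano_path],
    )
    manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# RNA-seq workflow
# ---------------------------------------------------------------------------


def run_rnaseq_workflow(config: RunConfig, out_dir: str | Path) -> RunManifest:
    """Simulation -> splicing efficiency -> deciles/extremes -> features
    -> co-splicing/expression -> DE surrogate.

    Writes the full analysis table set plus genome FASTA/GFF3 and a
    manifest under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest("rnaseq", config.scenario, config.seed)
    seed = config.seed

    sim_cfg = config.block("simulation")
    spec = GenomeSpec(**sim_cfg.get("genome", {"n_genes": 600}))
    genome, genes = simulate_genome(spec, seed)
    fasta_path, gff_path = out / "genome.fa", out / "genes.gff3"
    write_fasta(genome, fasta_path)
    write_gff3(genes, gff_path)

    rates = assign_rates(
        genes, float(sim_cfg.get("rate_mu", 3.0)), float(sim_cfg.get("rate_sigma", 1.0)), seed
    )
    model = DefectModel(**sim_cfg.get("defect_model", {"kind": "transcription_coupled"}))
    wt_model = DefectModel(
        kind="none", baseline_se_a=model.baseline_se_a, baseline_se_b=model.baseline_se_b
    )
    truth_wt = apply_defect_model(genes, rates, wt_model, seed, genome, genotype="WT")
    truth_mut = apply_defect_model(genes, rates, model, seed, genome, genotype="mut")
    truth = pd.concat([truth_wt.introns, truth_mut.introns], ignore_index=True)
    truth_path = out / "truth.tsv"
    write_tsv(truth, truth_path, {"stage": "truth", "kind": model.kind})

    depth = float(sim_cfg.get("depth", 2.0))
    from .simulate.defects import TruthTable

    both = TruthTable(
        introns=truth, genes=pd.concat([truth_wt.genes, truth_mut.genes], ignore_index=True)
    )
    counts = simulate_junction_counts(both, rates, depth, seed)
    se_tab = splicing.splicing_efficiency(
        counts, min_coverage=int(config.block("splice").get("min_coverage", 10))
    )
    se_path = out / "se_table.tsv"
    write_tsv(se_tab, se_path, {"stage": "splicing_efficiency"})

    se_wt = se_tab[se_tab["genotype"] == "WT"].set_index("intron_id")["se"]
    se_mut = se_tab[se_tab["genotype"] == "mut"].set_index("intron_id")["se"]

    deciles = splicing.decile_report(se_wt, {"mut": se_mut})
    deciles_path = out / "decile_report.tsv"
    write_tsv(deciles, deciles_path, {"stage": "deciles"})

    ranked = splicing.rank_affected(se_wt, se_mut, metric="difference")
    fraction = float(config.block("splice").get("extreme_fraction", 0.05))
    worst = splicing.select_extremes(ranked, fraction, "worst")
    best = splicing.select_extremes(ranked, fraction, "best")
    (out / "extremes_worst.txt").write_text("\n".join(worst) + "\n")
    (out / "extremes_best.txt").write_text("\n".join(best) + "\n")

    # splice-site composition of the worst set vs all quantified introns
    introns_by_id = {i.id: i for g in genes for i in g.introns}
    all_ids = [i for i in ranked["intron_id"] if i in introns_by_id]
    win = tuple(config.block("features").get("window_5p", (3, 8)))
    bg_windows = seqfeatures.extract_junction_windows(
        [introns_by_id[i] for i in all_ids], genome, win, "5p"
    )
    worst_windows = seqfeatures.extract_junction_windows(
        [introns_by_id[i] for i in worst if i in introns_by_id], genome, win, "5p"
    )
    bg_mat = seqfeatures.splice_site_matrix(bg_windows)
    worst_mat = seqfeatures.splice_site_matrix(worst_windows)
    comp = seqfeatures.compare_to_background(worst_mat, bg_mat)
    comp_path = out / "motif_comparison.tsv"
    write_tsv(comp, comp_path, {"stage": "motif_comparison", "method": "chi2-vs-background"})

    per_intron, pairwise = seqfeatures.composition_stats(
        {
            "all": [introns_by_id[i] for i in all_ids],
            "worst": [introns_by_id[i] for i in worst if i in introns_by_id],
            "best": [introns_by_id[i] for i in best if i in introns_by_id],
        },
        genome,
    )
    write_tsv(per_intron, out / "composition.tsv", {"stage": "composition"})
    write_tsv(pairwise, out / "composition_tests.tsv", {"stage": "composition"})

    # co-splicing and expression association
    fpkm = rates.rename(columns={"rate": "fpkm"})
    profiles = cosplicing.build_gene_profiles(
        se_tab.rename(columns={"se": "se"})[["gene_id", "intron_index", "genotype", "se"]], fpkm
    )
    cos_rows = []
    for anchor in (1, 2, 3):
        for comparator, threshold in (("lt", 0.5), ("gt", 0.9)):
            prof = cosplicing.cosplicing_profile(
                profiles, n_introns=3, anchor=anchor, threshold=threshold, comparator=comparator
            )
            for pos in range(3):
                cos_rows.append(
                    (
                        anchor,
                        f"{comparator}{threshold}",
                        pos + 1,
                        prof.n_genes,
                        prof.mean_se_wt[pos] if prof.n_genes else float("nan"),
                        prof.mean_se_mut[pos] if prof.n_genes else float("nan"),
                    )
                )
    cos_df = pd.DataFrame(
        cos_rows, columns=["anchor", "filter", "position", "n_genes", "mean_se_wt", "mean_se_mut"]
    )
    cos_path = out / "cosplicing_profile.tsv"
    write_tsv(cos_df, cos_path, {"stage": "cosplicing"})

    assoc = cosplicing.expression_association(
        ranked, fpkm, k=int(config.block("cosplice").get("k", 50))
    )
    assoc_df = pd.DataFrame(
        [
            (
                assoc["k"],
                assoc["worst_mean"],
                assoc["best_mean"],
                assoc["worst_median"],
                assoc["best_median"],
                assoc["t_stat"],
                assoc["p_value"],
            )
        ],
        columns=[
            "k", "worst_mean_fpkm", "best_mean_fpkm",
            "worst_median_fpkm", "best_median_fpkm", "t_stat", "p_value",
        ],
    )
    assoc_path = out / "expression_association.tsv"
    write_tsv(assoc_df, assoc_path, {"stage": "expression_association"})

    # DE surrogate on simulated gene counts
    de_cfg = config.block("de")
    gene_counts = simulate_gene_counts(
        rates,
        de_cfg.get("fold_changes", {}),
        float(de_cfg.get("dispersion", 10.0)),
        int(de_cfg.get("n_reps", 2)),
        seed,
    )
    factors = de.size_factors(gene_counts, pseudocount=1.0)
    groups = pd.Series(
        {c: ("WT" if c.startswith("WT") else "mut") for c in gene_counts.columns}
    )
    de_res = de.differential_expression(gene_counts, factors, groups, reference="WT")
    de_out = de_res.reset_index()
    de_path = out / "de_results.tsv"
    write_tsv(de_out, de_path, {"stage": "de", "method": "simplified-surrogate"})
    volcano = de_out[[de_out.columns[0], "log2fc", "p_value", "significant"]].copy()
    volcano["neg_log10_p"] = -np.log10(volcano["p_value"])
    write_tsv(volcano, out / "volcano.tsv", {"stage": "de_volcano", "method": "simplified-surrogate"})

    manifest.add_stage(
        "rnaseq",
        {"kind": model.kind, "depth": depth, "n_genes": spec.n_genes},
        [se_path, deciles_path, comp_path, cos_path, assoc_path, de_path],
    )
    manifest.write(out / "manifest.json")
    return manifest
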