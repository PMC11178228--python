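"""Plate-reader cytometry processing: gating, well summaries, hit calling.

The processing chain mirrors a standard reporter-screen workflow:

1. hierarchical gating — scatter (FSC-A/SSC-A), then singlets
   (FSC-H vs FSC-A), then an optional fluorescence gate;
2. per-well summaries — median FITC (YFP) and PE-Texas Red (RFP) of the
   gated population, with a minimum-event QC threshold (default 1000);
3. autofluorescence correction — the untransformed wild-type control
   well's red median is subtracted from every well's red median before
   the YFP/RFP ratio is formed;
4. hit calling — per-strain log2 fold change of the mean ratio against
   a reference strain, with a two-sided Welch t-test across replicate
   wells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GateConfig",
    "WellSummary",
    "gate_events",
    "summarize_well",
    "correct_autofluorescence",
    "call_hits",
]

REQUIRED_CHANNELS = ("FSC-A", "FSC-H", "SSC-A", "FITC-A", "PETexasRed-A")


@dataclass(frozen=True)
class GateConfig:
    """Hierarchical gate definition (scatter -> singlet -> fluorescence).

    Quantile-based bounds (``scatter_quantile``) and the singlet band
    slope are *resolved* against a population once, after which every
    gate is a pure interval filter — applying a resolved gate twice is
    the same as applying it once.
    """

    scatter_bounds: tuple[tuple[float, float], tuple[float, float]] | None = None
    scatter_quantile: float = 0.90  # central density mass kept when bounds unset
    singlet_slope: float | None = None
    singlet_tol: float = 0.25  # FSC-H within +/-25% of slope * FSC-A
    fluor_bounds: tuple[tuple[float, float], tuple[float, float]] | None = None

    @property
    def resolved(self) -> bool:
        return self.scatter_bounds is not None and self.singlet_slope is not None

    def resolve(self, events: pd.DataFrame) -> "GateConfig":
        """Fix data-dependent bounds against ``events``."""
        cfg = self
        if cfg.scatter_bounds is None:
            tail = (1.0 - cfg.scatter_quantile) / 2.0
            fsc = events["FSC-A"].quantile([tail, 1.0 - tail]).to_numpy()
            ssc = events["SSC-A"].quantile([tail, 1.0 - tail]).to_numpy()
            cfg = replace(cfg, scatter_bounds=((fsc[0], fsc[1]), (ssc[0], ssc[1])))
        if cfg.singlet_slope is None:
            x = events["FSC-A"].to_numpy(float)
            y = events["FSC-H"].to_numpy(float)
            denom = float(np.dot(x, x))
            slope = float(np.dot(x, y) / denom) if denom > 0 else 1.0
            cfg = replace(cfg, singlet_slope=slope)
        return cfg


def _check_channels(events: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_CHANNELS if c not in events.columns]
    if missing:
        raise ValueError(f"event table is missing channel column(s): {missing}")


def gate_events(events: pd.DataFrame, gates: GateConfig) -> pd.DataFrame:
    """Apply the three gate stages in order and return surviving events.

    Unresolved quantile gates are resolved against ``events`` first;
    resolved gates are pure filters and idempotent.
    """
    _check_channels(events)
    if events.empty:
        return events
    cfg = gates if gates.resolved else gates.resolve(events)
    n0 = len(events)

    (f_lo, f_hi), (s_lo, s_hi) = cfg.scatter_bounds
    out = events[
        events["FSC-A"].between(f_lo, f_hi) & events["SSC-A"].between(s_lo, s_hi)
    ]
    n1 = len(out)

    expected = cfg.singlet_slope * out["FSC-A"]
    out = out[(out["FSC-H"] - expected).abs() <= cfg.singlet_tol * expected.abs()]
    n2 = len(out)

    if cfg.fluor_bounds is not None:
        (y_lo, y_hi), (r_lo, r_hi) = cfg.fluor_bounds
        out = out[
            out["FITC-A"].between(y_lo, y_hi) & out["PETexasRed-A"].between(r_lo, r_hi)
        ]
    n3 = len(out)
    logger.info("gating retained %d -> %d (scatter) -> %d (singlet) -> %d (fluor)", n0, n1, n2, n3)
    return out


@dataclass
class WellSummary:
    well_id: str
    strain_id: str
    reporter_id: str
    n_gated: int
    median_yfp: float
    median_red: float
    corrected_red: float
    ratio: float  # NaN when QC fails or corrected red <= 0
    qc_pass: bool


def summarize_well(
    gated: pd.DataFrame,
    meta: dict[str, str],
    min_events: int = 1000,
) -> WellSummary:
    """Summarize a gated well: channel medians, event count, QC flag.

    A well is trustable only when at least ``min_events`` events survive
    gating (default 1000); below that the ratio is reported NA.
    Before autofluorescence correction ``corrected_red`` equals the raw
    red median.
    """
    n = len(gated)
    qc = n >= min_events
    if n == 0:
        med_y = med_r = float("nan")
    else:
        med_y = float(gated["FITC-A"].median())
        med_r = float(gated["PETexasRed-A"].median())
    ratio = med_y / med_r if qc and n > 0 and med_r > 0 else float("nan")
    return WellSummary(
        well_id=meta.get("well", ""),
        strain_id=meta.get("strain", ""),
        reporter_id=meta.get("reporter", ""),
        n_gated=n,
        median_yfp=med_y,
        median_red=med_r,
        corrected_red=med_r,
        ratio=ratio,
        qc_pass=qc,
    )


def correct_autofluorescence(
    wells: Sequence[WellSummary],
    wt_control: WellSummary,
    channels: str = "red_only",
) -> list[WellSummary]:
    """Subtract the untransformed-control medians and recompute ratios.

    By default only the PE-Texas Red channel is corrected; ``both`` also
    subtracts the control's FITC median from each well's YFP median.
    The ratio becomes NA whenever the corrected red signal is <= 0 or
    the well failed QC.
    """
    if channels not in ("red_only", "both"):
        raise ValueError("channels must be 'red_only' or 'both'")
    if not wt_control.qc_pass:
        raise ValueError(
            f"autofluorescence control well {wt_control.well_id!r} failed QC "
            f"({wt_control.n_gated} gated events)"
        )
    out = []
    for w in wells:
        corr_red = w.median_red - wt_control.median_red
        med_y = w.median_yfp - wt_control.median_yfp if channels == "both" else w.median_yfp
        ratio = med_y / corr_red if (w.qc_pass and corr_red > 0) else float("nan")
        out.append(
            WellSummary(
                well_id=w.well_id,
                strain_id=w.strain_id,
                reporter_id=w.reporter_id,
                n_gated=w.n_gated,
                median_yfp=med_y,
                median_red=w.median_red,
                corrected_red=corr_red,
                ratio=ratio,
                qc_pass=w.qc_pass,
            )
        )
    return out


def call_hits(
    ratios: pd.DataFrame,
    reference_strain: str,
    p_threshold: float = 0.05,
    lfc_threshold: float = 0.0,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Call screen hits from replicate well ratios.

    ``ratios`` holds one row per replicate well with columns
    ``strain, ratio`` (NA ratios are dropped).  Per strain the log2 fold
    change of the mean ratio against the reference strain's mean is
    reported, with a two-sided Welch t-test of the replicate ratios
    against the reference replicates.  Strains with fewer than two
    replicates get an NA p-value and are never significant.  Output is
    sorted by p-value (NA last).
    """
    df = ratios.dropna(subset=["ratio"])
    ref = df.loc[df["strain"] == reference_strain, "ratio"].to_numpy(float)
    if len(ref) < 2:
        raise ValueError(
            f"reference strain {reference_strain!r} needs >= 2 replicate ratios, got {len(ref)}"
        )
    ref_mean = float(ref.mean())

    rows = []
    for strain, sub in df.groupby("strain", sort=True):
        vals = sub["ratio"].to_numpy(float)
        mean_ratio = float(vals.mean())
        log2fc = float(np.log2(mean_ratio / ref_mean)) if mean_ratio > 0 else float("nan")
        if len(vals) >= 2:
            p = float(stats.ttest_ind(vals, ref, equal_var=False).pvalue)
        else:
            p = float("nan")
        rows.append((strain, len(vals), mean_ratio, ref_mean, log2fc, p))
    out = pd.DataFrame(
        rows, columns=["strain", "n_reps", "mean_ratio", "reference_ratio", "log2fc", "p_value"]
    )
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        mask = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(
                out.loc[mask, "p_value"], method="fdr_bh"
            )[1]
        out["p_adj"] = adj
        pcol = "p_adj"
    else:
        pcol = "p_value"
    out["significant"] = (out[pcol] < p_threshold) & (out["log2fc"].abs() >= lfc_threshold)
    out["significant"] = out["significant"].fillna(False)
    return out.sort_values("p_value", na_position="last").reset_index(drop=True)
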