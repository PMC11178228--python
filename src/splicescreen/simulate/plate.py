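"""Simulated dual-fluorophore reporter plates.

Each cell expresses the reporter at a log-normal level X.  The red
channel reads expression (``red = coupling_red * X``) while the yellow
channel additionally requires splicing (``yfp = coupling_yfp * se * X``),
so the YFP/RFP ratio estimates the reporter's splicing efficiency.
Both channels carry multiplicative measurement noise and additive
channel autofluorescence; untransformed wild-type control wells have
zero coupling and therefore report autofluorescence only.

Scatter channels are drawn so that configurable fractions of events
fail the scatter and singlet gates, mimicking debris and doublets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._seeds import child_rng

__all__ = ["CytometrySimParams", "simulate_plate", "default_plate_layout"]

EVENT_COLUMNS = ["FSC-A", "FSC-H", "SSC-A", "FITC-A", "PETexasRed-A"]


@dataclass
class CytometrySimParams:
    n_events_per_well: int = 10_000
    expr_mu: float = 7.0
    expr_sigma: float = 0.5
    coupling_red: float = 1.0
    coupling_yfp: float = 1.2
    autofluor_red_mu: float = 120.0
    autofluor_red_sigma: float = 25.0
    autofluor_yfp_mu: float = 60.0
    autofluor_yfp_sigma: float = 15.0
    noise_cv: float = 0.08
    # (strain, reporter) -> true splicing efficiency of that well's reporter
    reporter_se_map: dict[tuple[str, str], float] = field(default_factory=dict)
    debris_frac: float = 0.05
    doublet_frac: float = 0.04
    fsc_mu: float = 100_000.0
    fsc_sigma: float = 12_000.0
    ssc_mu: float = 50_000.0
    ssc_sigma: float = 9_000.0

    def validate(self) -> None:
        if self.n_events_per_well < 1:
            raise ValueError("n_events_per_well must be >= 1")
        if self.coupling_red <= 0 or self.coupling_yfp <= 0:
            raise ValueError("channel gains must be > 0")
        for se in self.reporter_se_map.values():
            if not 0.0 <= se <= 1.0:
                raise ValueError("reporter_se_map values must be in [0, 1]")
        for frac in (self.debris_frac, self.doublet_frac):
            if not 0.0 <= frac < 1.0:
                raise ValueError("gate-failure fractions must be in [0, 1)")


def default_plate_layout(
    strains: list[str],
    reporter: str = "dmut",
    n_replicate_wells: int = 2,
    control_wells: tuple[str, ...] = ("H2", "H3", "H12"),
) -> pd.DataFrame:
    """A simple 96-well layout: sample strains in row-major order with
    untransformed wild-type autofluorescence controls at fixed wells."""
    rows = "ABCDEFGH"
    wells = [f"{r}{c}" for r in rows for c in range(1, 13)]
    layout = []
    free = [w for w in wells if w not in control_wells]
    i = 0
    for strain in strains:
        for _ in range(n_replicate_wells):
            if i >= len(free):
                raise ValueError("layout overflow: too many strains for one plate")
            layout.append((free[i], strain, reporter, "sample"))
            i += 1
    for w in control_wells:
        layout.append((w, "WT_untransformed", "none", "autofluor_control"))
    return pd.DataFrame(layout, columns=["well", "strain", "reporter", "role"])


def _simulate_well(
    params: CytometrySimParams, se: float, coupled: bool, rng: np.random.Generator
) -> pd.DataFrame:
    n = params.n_events_per_well
    x = rng.lognormal(params.expr_mu, params.expr_sigma, size=n)

    noise_r = 1.0 + params.noise_cv * rng.standard_normal(n)
    noise_y = 1.0 + params.noise_cv * rng.standard_normal(n)
    auto_r = np.clip(
        rng.normal(params.autofluor_red_mu, params.autofluor_red_sigma, size=n), 0, None
    )
    auto_y = np.clip(
        rng.normal(params.autofluor_yfp_mu, params.autofluor_yfp_sigma, size=n), 0, None
    )
    if coupled:
        red = params.coupling_red * x * noise_r + auto_r
        yfp = params.coupling_yfp * se * x * noise_y + auto_y
    else:  # untransformed control: autofluorescence only
        red = auto_r
        yfp = auto_y

    fsc = rng.normal(params.fsc_mu, params.fsc_sigma, size=n)
    ssc = rng.normal(params.ssc_mu, params.ssc_sigma, size=n)
    debris = rng.random(n) < params.debris_frac
    fsc[debris] *= 0.25  # small particles fall outside the scatter gate
    ssc[debris] *= 3.0
    hratio = rng.normal(1.0, 0.02, size=n)
    doublet = rng.random(n) < params.doublet_frac
    hratio[doublet] = 0.55  # doublets have low height/area ratio
    fsc_h = fsc * hratio

    return pd.DataFrame(
        {
            "FSC-A": fsc,
            "FSC-H": fsc_h,
            "SSC-A": ssc,
            "FITC-A": yfp,
            "PETexasRed-A": red,
        }
    )


def simulate_plate(
    layout: pd.DataFrame, params: CytometrySimParams, seed: int
) -> dict[str, pd.DataFrame]:
    """Simulate event tables for every well of ``layout``.

    ``layout`` needs columns ``well, strain, reporter, role``; sample
    wells must have a ``(strain, reporter)`` entry in
    ``params.reporter_se_map``.  Each well draws from its own sub-seed
    stream, so the table of one well never depends on the others.
    """
    params.validate()
    required = {"well", "strain", "reporter", "role"}
    if not required.issubset(layout.columns):
        raise ValueError(f"layout must have columns {sorted(required)}")
    tables: dict[str, pd.DataFrame] = {}
    for row in layout.itertuples(index=False):
        rng = child_rng(seed, "plate", row.well)
        if row.role == "autofluor_control":
            tables[row.well] = _simulate_well(params, 0.0, coupled=False, rng=rng)
            continue
        key = (row.strain, row.reporter)
        if key not in params.reporter_se_map:
            raise KeyError(f"well {row.well}: no reporter_se_map entry for {key}")
        tables[row.well] = _simulate_well(
            params, params.reporter_se_map[key], coupled=True, rng=rng
        )
    return tables
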