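"""Study-shaped synthetic data: turnover curves and 10-min group tables.

The generator mirrors the infusion design behind the shipped presets:
[1,6-¹³C₂]glucose for 10, 30, 60 and 90 min with three animals per time
point for the kinetic arm, and single-time-point (10-min) group tables
with treatment effects (AlCl₃ lowers labelled concentrations by roughly
15–35%, a subsequent restorative intervention brings them back toward
control).  Replicate scatter is multiplicative Gaussian with a small
additive enrichment floor, the same noise family the fitting module's
Monte-Carlo analysis assumes, so simulation and inference stay
coherent.  Every draw is reproducible from the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fluxes import FluxSet
from .model import (FITTED_CURVES, PlasmaInput, PoolSpec, TIMECOURSE_COLUMNS,
                    simulate_labeling)

__all__ = ["StudyDesign", "generate_timecourse_dataset", "generate_group_table"]

#: Default per-group multipliers applied to control labelled means.
DEFAULT_GROUP_EFFECTS = {
    "control_cmc": 1.00,
    "control_rs": 0.97,
    "alcl3_cmc": 0.75,
    "alcl3_rs": 0.93,
}


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout, noise level and treatment effects."""

    time_points: tuple[float, ...] = (10.0, 30.0, 60.0, 90.0)
    n_per_timepoint: int = 3
    n_per_group: int = 6
    noise_cv: float = 0.05
    noise_floor: float = 0.005
    group_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_timepoint < 1 or self.n_per_group < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.noise_cv < 0 or self.noise_floor < 0:
            raise ValueError("noise parameters must be >= 0")
        bad = {g: m for g, m in self.group_effects.items() if m <= 0}
        if bad:
            raise ValueError(f"group effect multipliers must be > 0: {bad}")


def generate_timecourse_dataset(
    truth: FluxSet,
    pools: PoolSpec,
    plasma: PlasmaInput,
    design: StudyDesign,
    *,
    curves: tuple[tuple[str, int], ...] = FITTED_CURVES,
    method: str = "ivp",
) -> pd.DataFrame:
    """Noisy enrichment time courses from a known ground truth.

    Simulates the noiseless curves, then draws ``n_per_timepoint``
    replicates per (curve, time) with Gaussian noise of
    SD = max(noise_cv · value, noise_floor) on the enrichment fraction.
    Negative draws are clipped at zero; the number of clipped points is
    recorded in ``df.attrs["n_clipped"]``.
    """
    clean = simulate_labeling(truth, pools, plasma, design.time_points,
                              curves=curves, method=method)
    rng = np.random.default_rng(design.seed)
    totals = {"Glu": pools.conc_glu, "GABA": pools.conc_gaba,
              "Gln": pools.conc_gln, "Asp": pools.conc_asp}
    records = []
    n_clipped = 0
    for row in clean.itertuples(index=False):
        total = totals[row.metabolite]
        # noise_cv = 0 means a noiseless dataset; the floor only pads
        # the CV noise on low-enrichment curves
        sd = (max(design.noise_cv * row.enrichment_fraction,
                  design.noise_floor) if design.noise_cv > 0 else 0.0)
        for rep in range(design.n_per_timepoint):
            e = row.enrichment_fraction + rng.normal(0.0, sd) \
                if sd > 0 else row.enrichment_fraction
            if e < 0:
                e = 0.0
                n_clipped += 1
            records.append((row.region, row.metabolite, row.carbon_position,
                            row.time_min, rep, e, e * total))
    out = pd.DataFrame.from_records(records, columns=TIMECOURSE_COLUMNS)
    out.attrs["n_clipped"] = n_clipped
    out.attrs["seed"] = design.seed
    return out


def generate_group_table(
    base: pd.DataFrame,
    design: StudyDesign,
    *,
    groups: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Synthetic 10-min labelled-concentration table with group effects.

    ``base`` holds the control means in tidy group-table form (columns
    region, group, position, labeled_conc_umol_g; only the control rows
    are read).  Each group's mean is the control mean times its effect
    multiplier; per-animal values are Gaussian with CV ``noise_cv``,
    and the returned table records the group mean, SEM and n.
    """
    if groups is None:
        groups = tuple(design.group_effects)
    control = base[base["group"].str.startswith("control")]
    if control.empty:
        control = base
    control = (control.groupby(["region", "position"], sort=False)
               ["labeled_conc_umol_g"].mean())
    if (control <= 0).any():
        raise ValueError("control means must be positive")
    rng = np.random.default_rng(design.seed)
    rows = []
    for (region, position), mean in control.items():
        for group in groups:
            m = design.group_effects[group] * mean
            if design.noise_cv > 0:
                draws = rng.normal(m, design.noise_cv * m, size=design.n_per_group)
                draws = np.clip(draws, 0.0, None)
                g_mean = float(draws.mean())
                g_sem = float(draws.std(ddof=1) / np.sqrt(design.n_per_group))
            else:
                g_mean, g_sem = float(m), 0.0
            rows.append((region, group, position, g_mean, g_sem,
                         design.n_per_group))
    return pd.DataFrame(rows, columns=["region", "group", "position",
                                       "labeled_conc_umol_g", "sem", "n"])
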