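"""Shipped region configurations and reference group tables.

One YAML file per brain region (cortex, hippocampus, striatum) holds the
metabolite pool sizes and compartmental partition, the two cycling/TCA
ratio constraints, the initial-rate coefficients, the plasma input and
ground-truth flux presets for the control and AlCl₃-exposed groups.
The flux presets are keyed to published regional rates for this study
design; remaining parameters are package defaults documented in
docs/methods.md.

Also shipped: the 10-min labelled amino-acid concentration table
(μmol/g, mean ± SEM per region × treatment group) used by the
initial-rate estimators, and the group-average plasma glucose-C1
fractional enrichment (0.50) adopted for those estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .fluxes import FluxSet
from .model import PlasmaInput, PoolSpec

__all__ = [
    "RegionConfig",
    "load_region_config",
    "REGIONS",
    "GROUPS",
    "GLC1_DEFAULT",
    "labeled_group_table",
]

REGIONS = ("cortex", "hippocampus", "striatum")
GROUPS = ("control_cmc", "control_rs", "alcl3_cmc", "alcl3_rs")

#: Group-average plasma [1-13C]glucose fractional enrichment used with
#: the shipped group table (configurable everywhere it is consumed).
GLC1_DEFAULT = 0.50


@dataclass(frozen=True)
class RegionConfig:
    """Everything needed to simulate or fit one brain region."""

    region: str
    pools: PoolSpec
    ratio_glu: float
    ratio_gaba: float
    plasma: PlasmaInput
    flux_presets: dict[str, FluxSet]
    initial_rate_coefficients: dict[str, float]

    def fluxes(self, group: str = "control") -> FluxSet:
        try:
            return self.flux_presets[group]
        except KeyError:
            raise KeyError(
                f"no flux preset {group!r} for region {self.region!r}; "
                f"available: {sorted(self.flux_presets)}") from None


def load_region_config(source: str | Path) -> RegionConfig:
    """Load a region configuration.

    ``source`` is a shipped region name (``cortex``, ``hippocampus``,
    ``striatum``) or a path to a YAML file with the same schema.
    """
    if isinstance(source, str) and source in REGIONS:
        text = (resources.files("neuroflux") / "configs" / f"{source}.yaml").read_text()
    else:
        text = Path(source).read_text()
    raw = yaml.safe_load(text)

    pools = PoolSpec(region=raw["region"], **raw["pools"])
    constraints = raw["constraints"]
    presets = {
        name: FluxSet.from_primary(
            ratio_glu=constraints["ratio_glu"],
            ratio_gaba=constraints["ratio_gaba"],
            **params,
        )
        for name, params in raw["fluxes"].items()
    }
    return RegionConfig(
        region=raw["region"],
        pools=pools,
        ratio_glu=constraints["ratio_glu"],
        ratio_gaba=constraints["ratio_gaba"],
        plasma=PlasmaInput(**raw.get("plasma", {})),
        flux_presets=presets,
        initial_rate_coefficients=dict(raw["initial_rate_coefficients"]),
    )


# 10-min labelled amino-acid concentrations (μmol/g): mean, SEM, n per
# (region, treatment group).  Positions: Glu_C4, GABA_C2, Gln_C4,
# Asp_C3, Glu_C3, GABA_C4.
_GROUP_TABLE = {
    ("cortex", "control_cmc"): ((1.97, 0.21, 0.29, 0.20, 0.42, 0.08),
                                (0.09, 0.02, 0.02, 0.02, 0.07, 0.02), 7),
    ("cortex", "control_rs"): ((1.99, 0.20, 0.25, 0.17, 0.32, 0.05),
                               (0.13, 0.01, 0.01, 0.01, 0.02, 0.01), 5),
    ("cortex", "alcl3_cmc"): ((1.61, 0.16, 0.19, 0.12, 0.23, 0.04),
                              (0.06, 0.01, 0.01, 0.01, 0.02, 0.01), 5),
    ("cortex", "alcl3_rs"): ((1.91, 0.21, 0.25, 0.17, 0.29, 0.05),
                             (0.05, 0.01, 0.02, 0.01, 0.01, 0.01), 7),
    ("hippocampus", "control_cmc"): ((1.67, 0.31, 0.25, 0.17, 0.34, 0.09),
                                     (0.07, 0.02, 0.02, 0.01, 0.05, 0.01), 7),
    ("hippocampus", "control_rs"): ((1.64, 0.29, 0.23, 0.14, 0.27, 0.08),
                                    (0.08, 0.02, 0.01, 0.01, 0.02, 0.01), 5),
    ("hippocampus", "alcl3_cmc"): ((1.24, 0.19, 0.16, 0.10, 0.17, 0.04),
                                   (0.06, 0.01, 0.01, 0.01, 0.02, 0.01), 5),
    ("hippocampus", "alcl3_rs"): ((1.61, 0.27, 0.24, 0.16, 0.28, 0.08),
                                  (0.09, 0.01, 0.02, 0.02, 0.04, 0.01), 7),
    ("striatum", "control_cmc"): ((1.34, 0.22, 0.18, 0.12, 0.30, 0.07),
                                  (0.11, 0.02, 0.02, 0.01, 0.03, 0.02), 7),
    ("striatum", "control_rs"): ((1.29, 0.19, 0.17, 0.12, 0.22, 0.05),
                                 (0.06, 0.01, 0.01, 0.01, 0.02, 0.01), 5),
    ("striatum", "alcl3_cmc"): ((0.86, 0.14, 0.11, 0.06, 0.11, 0.04),
                                (0.06, 0.01, 0.01, 0.01, 0.02, 0.01), 5),
    ("striatum", "alcl3_rs"): ((1.20, 0.18, 0.15, 0.11, 0.21, 0.05),
                               (0.07, 0.01, 0.01, 0.02, 0.02, 0.01), 7),
}

_POSITIONS = ("Glu_C4", "GABA_C2", "Gln_C4", "Asp_C3", "Glu_C3", "GABA_C4")


def labeled_group_table() -> pd.DataFrame:
    """Shipped 10-min labelled-concentration group table (tidy form).

    Columns: region, group, position, labeled_conc_umol_g, sem, n.
    """
    rows = []
    for (region, group), (means, sems, n) in _GROUP_TABLE.items():
        for pos, m, s in zip(_POSITIONS, means, sems):
            rows.append((region, group, pos, m, s, n))
    return pd.DataFrame(
        rows,
        columns=["region", "group", "position", "labeled_conc_umol_g",
                 "sem", "n"],
    )
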