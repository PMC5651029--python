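"""Initial-rate estimators of cerebral glucose oxidation (CMR_Glc(ox)).

During a short (10-min) [1,6-¹³C₂]glucose infusion essentially all ¹³C
trapped in glutamate, GABA, aspartate and glutamine has passed once
through pyruvate dehydrogenase, so the labelled amount accumulated per
unit time, scaled by the plasma glucose-C1 enrichment, approximates the
glucose-oxidation rate of the cells holding those pools:

    CMR_Glc(Glu)   = ½ · (1/T) · (1/Glc₁) · {0.82·(L_Glu4 + 2·L_Glu3)
                                             + 0.42·2·L_Asp3}
    CMR_Glc(GABA)  = ½ · (1/T) · (1/Glc₁) · {0.02·(L_Glu4 + 2·L_Glu3)
                                             + (L_GABA2 + 2·L_GABA4)
                                             + 0.42·2·L_Asp3}
    CMR_Glc(Total) = ½ · (1/T) · (1/Glc₁) · {(L_Glu4 + 2·L_Glu3)
                                             + (L_GABA2 + 2·L_GABA4)
                                             + 2·L_Asp3 + L_Gln4}

where L_Xi is the labelled concentration (μmol/g) of metabolite X at
carbon i, T the infusion time in minutes, Glc₁ the fractional plasma
[1-¹³C]glucose enrichment, ½ converts labelled three-carbon units to
glucose, the factor 2 on second-turn positions (C3 of Glu/Asp, C4 of
GABA) accounts for the label split by the symmetric succinate pool, and
0.82 / 0.02 / 0.42 are the glutamatergic and GABAergic shares of the
glutamate and aspartate pools (region-configurable).

These estimators neglect label lost to CO₂, lactate/alanine and
glutamine cycling, and therefore run low relative to dynamic-model
fits; comparisons between groups remain valid because the bias is
shared.  No correction is applied.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "DEFAULT_COEFFICIENTS",
    "cmr_glutamatergic",
    "cmr_gabaergic",
    "cmr_total",
    "cmr_table",
]

#: Pool-partition coefficients of the estimator equations.
DEFAULT_COEFFICIENTS = {
    "glutamatergic_glu": 0.82,
    "gabaergic_glu": 0.02,
    "asp": 0.42,
}

_REQUIRED = ("Glu_C4", "Glu_C3", "GABA_C2", "GABA_C4", "Asp_C3", "Gln_C4")


def _labeled(table: pd.DataFrame, region: str, group: str) -> dict[str, float]:
    sel = table[(table["region"] == region) & (table["group"] == group)]
    if sel.empty:
        raise KeyError(f"no rows for region={region!r}, group={group!r}")
    values = dict(zip(sel["position"], sel["labeled_conc_umol_g"]))
    missing = [p for p in _REQUIRED if p not in values]
    if missing:
        raise KeyError(
            f"missing labelled positions for ({region}, {group}): {missing}")
    bad = {p: v for p, v in values.items() if v < 0}
    if bad:
        raise ValueError(f"negative labelled concentrations: {bad}")
    return values


def _prefactor(glc1: float, infusion_min: float) -> float:
    if not 0 < glc1 <= 1:
        raise ValueError(f"plasma Glc1 enrichment must be in (0, 1], got {glc1}")
    if infusion_min <= 0:
        raise ValueError("infusion time must be positive")
    return 0.5 / (infusion_min * glc1)


def cmr_glutamatergic(
    table: pd.DataFrame,
    region: str,
    group: str,
    *,
    glc1: float,
    infusion_min: float = 10.0,
    coefficients: dict[str, float] | None = None,
) -> float:
    """Glucose-oxidation rate of glutamatergic neurons, μmol/g/min."""
    c = {**DEFAULT_COEFFICIENTS, **(coefficients or {})}
    L = _labeled(table, region, group)
    pool_sum = (c["glutamatergic_glu"] * (L["Glu_C4"] + 2 * L["Glu_C3"])
                + c["asp"] * 2 * L["Asp_C3"])
    return _prefactor(glc1, infusion_min) * pool_sum


def cmr_gabaergic(
    table: pd.DataFrame,
    region: str,
    group: str,
    *,
    glc1: float,
    infusion_min: float = 10.0,
    coefficients: dict[str, float] | None = None,
) -> float:
    """Glucose-oxidation rate of GABAergic neurons, μmol/g/min."""
    c = {**DEFAULT_COEFFICIENTS, **(coefficients or {})}
    L = _labeled(table, region, group)
    pool_sum = (c["gabaergic_glu"] * (L["Glu_C4"] + 2 * L["Glu_C3"])
                + (L["GABA_C2"] + 2 * L["GABA_C4"])
                + c["asp"] * 2 * L["Asp_C3"])
    return _prefactor(glc1, infusion_min) * pool_sum


def cmr_total(
    table: pd.DataFrame,
    region: str,
    group: str,
    *,
    glc1: float,
    infusion_min: float = 10.0,
) -> float:
    """Total neuronal glucose-oxidation rate, μmol/g/min."""
    L = _labeled(table, region, group)
    pool_sum = ((L["Glu_C4"] + 2 * L["Glu_C3"])
                + (L["GABA_C2"] + 2 * L["GABA_C4"])
                + 2 * L["Asp_C3"]
                + L["Gln_C4"])
    return _prefactor(glc1, infusion_min) * pool_sum


def cmr_table(
    table: pd.DataFrame,
    *,
    glc1: float,
    infusion_min: float = 10.0,
    coefficients: dict[str, float] | None = None,
) -> pd.DataFrame:
    """All three estimators for every (region, group) in ``table``.

    Returns a tidy frame with columns region, group, cmr_glu, cmr_gaba,
    cmr_total (μmol/g/min).
    """
    rows = []
    for (region, group), _ in table.groupby(["region", "group"], sort=False):
        kwargs = dict(glc1=glc1, infusion_min=infusion_min)
        rows.append((
            region, group,
            cmr_glutamatergic(table, region, group,
                              coefficients=coefficients, **kwargs),
            cmr_gabaergic(table, region, group,
                          coefficients=coefficients, **kwargs),
            cmr_total(table, region, group, **kwargs),
        ))
    return pd.DataFrame(rows, columns=["region", "group", "cmr_glu",
                                       "cmr_gaba", "cmr_total"])
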