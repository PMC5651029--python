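"""Metabolic flux sets for the three-compartment brain model.

The model distinguishes glutamatergic neurons, GABAergic neurons and
astroglia.  A :class:`FluxSet` holds every steady-state flux (all in
μmol/g/min) of the network: compartmental TCA cycle rates, the
glutamate–glutamine and GABA–glutamine neurotransmitter cycles, the GABA
shunt, pyruvate carboxylase anaplerosis, the α-ketoglutarate↔glutamate
exchange and the dilution fluxes of the four amino-acid pools.

Steady state imposes linear mass-balance relations between fluxes
(e.g. glutamate decarboxylase must supply both the GABA shunt and the
GABA–glutamine cycle).  :func:`mass_balance_residuals` reports the
imbalance at every constrained node; :meth:`FluxSet.from_primary`
constructs a balanced set from the independent (fitted) fluxes plus the
two cycling/TCA ratio constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

__all__ = [
    "FluxSet",
    "FluxValidationError",
    "mass_balance_residuals",
    "derived_outputs",
    "PRIMARY_FLUXES",
]

#: Independent fluxes varied during fitting; everything else in a
#: :class:`FluxSet` follows from these plus the two ratio constraints.
PRIMARY_FLUXES = (
    "v_tca_glu",
    "v_tca_gaba_net",
    "v_shunt",
    "v_tca_a_net",
    "v_pc",
    "v_x",
    "v_dil_glu",
    "v_dil_gaba",
    "v_dil_a",
    "v_dil_gln",
)


class FluxValidationError(ValueError):
    """Raised when a flux set violates positivity or balance requirements."""


@dataclass(frozen=True)
class FluxSet:
    """All fluxes of the three-compartment model, μmol/g/min.

    Attributes
    ----------
    v_tca_glu
        Glutamatergic-neuron TCA cycle rate.
    v_tca_gaba
        Total GABAergic TCA rate (net oxidative flux plus GABA-shunt
        return), ``v_tca_gaba_net + v_shunt``.
    v_tca_gaba_net
        Net GABAergic TCA rate (α-ketoglutarate → succinate).
    v_tca_a_net
        Net astroglial TCA rate.
    v_tca_a
        Total astroglial citrate-synthesis flux,
        ``v_tca_a_net + v_pc + v_cyc_gaba_gln``.
    v_cyc_glu_gln, v_cyc_gaba_gln
        Glutamate–glutamine and GABA–glutamine neurotransmitter cycles.
    v_gad
        Glutamate decarboxylase flux, ``v_shunt + v_cyc_gaba_gln``.
    v_shunt
        GABA shunt (GABA → succinate within GABAergic neurons).
    v_pc
        Pyruvate carboxylase (astroglial anaplerosis); balanced by an
        equal glutamine efflux.
    v_gln
        Glutamine synthetase flux,
        ``v_cyc_glu_gln + v_cyc_gaba_gln + v_pc``.
    v_x
        α-Ketoglutarate ↔ glutamate (and oxaloacetate ↔ aspartate)
        exchange rate.
    v_dil_gln, v_dil_a, v_dil_gaba, v_dil_glu
        Isotopic dilution (unlabelled inflow/outflow) of the glutamine,
        astroglial-glutamate, GABA and neuronal-glutamate pools.
    """

    v_tca_glu: float
    v_tca_gaba: float
    v_tca_gaba_net: float
    v_tca_a_net: float
    v_tca_a: float
    v_cyc_glu_gln: float
    v_cyc_gaba_gln: float
    v_gad: float
    v_shunt: float
    v_pc: float
    v_gln: float
    v_x: float
    v_dil_gln: float
    v_dil_a: float
    v_dil_gaba: float
    v_dil_glu: float

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not (value == value) or value in (float("inf"), float("-inf")):
                raise FluxValidationError(f"flux {f.name} is not finite: {value!r}")
            if value < 0:
                raise FluxValidationError(f"flux {f.name} is negative: {value:g}")

    @classmethod
    def from_primary(
        cls,
        *,
        ratio_glu: float,
        ratio_gaba: float,
        v_tca_glu: float,
        v_tca_gaba_net: float,
        v_shunt: float,
        v_tca_a_net: float,
        v_pc: float,
        v_x: float,
        v_dil_glu: float = 0.0,
        v_dil_gaba: float = 0.0,
        v_dil_a: float = 0.0,
        v_dil_gln: float = 0.0,
    ) -> "FluxSet":
        """Build a mass-balanced flux set from the independent fluxes.

        ``ratio_glu`` and ``ratio_gaba`` are the fixed
        V_cyc(Glu-Gln)/V_tca(Glu) and V_cyc(GABA-Gln)/V_tca(GABA)
        constraints; the dependent fluxes are completed so that every
        node balance holds exactly.
        """
        if ratio_glu <= 0 or ratio_gaba <= 0:
            raise FluxValidationError("ratio constraints must be positive")
        v_tca_gaba = v_tca_gaba_net + v_shunt
        v_cyc_glu_gln = ratio_glu * v_tca_glu
        v_cyc_gaba_gln = ratio_gaba * v_tca_gaba
        return cls(
            v_tca_glu=v_tca_glu,
            v_tca_gaba=v_tca_gaba,
            v_tca_gaba_net=v_tca_gaba_net,
            v_tca_a_net=v_tca_a_net,
            v_tca_a=v_tca_a_net + v_pc + v_cyc_gaba_gln,
            v_cyc_glu_gln=v_cyc_glu_gln,
            v_cyc_gaba_gln=v_cyc_gaba_gln,
            v_gad=v_shunt + v_cyc_gaba_gln,
            v_shunt=v_shunt,
            v_pc=v_pc,
            v_gln=v_cyc_glu_gln + v_cyc_gaba_gln + v_pc,
            v_x=v_x,
            v_dil_gln=v_dil_gln,
            v_dil_a=v_dil_a,
            v_dil_gaba=v_dil_gaba,
            v_dil_glu=v_dil_glu,
        )

    def primary(self) -> dict[str, float]:
        """Return the independent fluxes as a name → value mapping."""
        return {name: getattr(self, name) for name in PRIMARY_FLUXES}

    def with_values(self, **updates: float) -> "FluxSet":
        """Return a copy with the given fields replaced (no re-balancing)."""
        return replace(self, **updates)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def mass_balance_residuals(fluxes: FluxSet) -> dict[str, float]:
    """Steady-state imbalance (inflow − outflow, μmol/g/min) per node.

    Nodes checked: the GABA pool, the glutamine pool, GABAergic-neuron
    glutamate, astroglial glutamate (via the total astroglial TCA
    relation) and the GABAergic TCA decomposition.  A balanced
    :class:`FluxSet` — e.g. anything built by
    :meth:`FluxSet.from_primary` — gives an all-zero vector.
    """
    return {
        "gaba": fluxes.v_gad - fluxes.v_shunt - fluxes.v_cyc_gaba_gln,
        "glutamine": fluxes.v_gln
        - fluxes.v_cyc_glu_gln
        - fluxes.v_cyc_gaba_gln
        - fluxes.v_pc,
        "gabaergic_glutamate": fluxes.v_shunt
        + fluxes.v_cyc_gaba_gln
        - fluxes.v_gad,
        "astroglial_glutamate": fluxes.v_tca_a
        - fluxes.v_tca_a_net
        - fluxes.v_pc
        - fluxes.v_cyc_gaba_gln,
        "gabaergic_tca": fluxes.v_tca_gaba - fluxes.v_tca_gaba_net - fluxes.v_shunt,
    }


def derived_outputs(fluxes: FluxSet) -> dict[str, float]:
    """Composite rates reported per region.

    ``neurotransmitter_cycling`` is the summed glutamate–glutamine and
    GABA–glutamine cycle flux.  ``neuronal_glucose_oxidation`` is
    ``(v_tca_glu + v_tca_gaba_net) / 2``: two pyruvates oxidised per
    glucose, with the GABA-shunt return excluded so shunt carbon is not
    counted twice.
    """
    return {
        "neurotransmitter_cycling": fluxes.v_cyc_glu_gln + fluxes.v_cyc_gaba_gln,
        "neuronal_glucose_oxidation": (fluxes.v_tca_glu + fluxes.v_tca_gaba_net) / 2.0,
    }
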