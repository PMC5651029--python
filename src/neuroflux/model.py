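"""Positional ¹³C label routing and enrichment simulation.

[1,6-¹³C₂]glucose labels both pyruvate molecules at C3.  Pyruvate
dehydrogenase places that label on α-ketoglutarate C4 (hence glutamate
C4 and, after decarboxylation, GABA C2); passage through the symmetric
succinate/fumarate pool scrambles it 50/50 onto oxaloacetate C2/C3, so
second-turn label appears at glutamate C3/C2, GABA C3/C4 and aspartate
C3.  Pyruvate carboxylase deposits pyruvate-C3 label directly on
oxaloacetate C3 (astroglia only), routing label to glutamine C2/C3.

The tracked state is the fractional enrichment of every (pool, carbon
position) node: per compartment a lumped α-ketoglutarate pool (C2–C4)
and oxaloacetate pool (C2, C3), the compartmental glutamate pools
(C2–C4), GABA (C2–C4), glutamine (C2–C4) and aspartate (C2, C3).  With
fluxes held at steady state the enrichment dynamics are linear,

    C_P · df(P,s)/dt = Σ_in V · f(src) − (Σ_out V) · f(P,s),

driven by the plasma glucose enrichment.  Two integrators are provided:
an adaptive ODE solver (default) and a brute-force matrix-exponential
solution of the same linear system, used as an independent numerical
oracle and as the fast path inside fitting loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .fluxes import FluxSet, FluxValidationError, mass_balance_residuals

__all__ = [
    "PoolSpec",
    "PlasmaInput",
    "LabelTransition",
    "LabelNetwork",
    "build_label_network",
    "simulate_labeling",
    "simulate_states",
    "measured_curves",
    "FITTED_CURVES",
    "TIMECOURSE_COLUMNS",
]

#: The six turnover curves used for model fitting.
FITTED_CURVES = (
    ("Glu", 4),
    ("Glu", 3),
    ("GABA", 2),
    ("GABA", 3),
    ("Asp", 3),
    ("Gln", 4),
)

#: Tidy schema of an enrichment time course table.
TIMECOURSE_COLUMNS = (
    "region",
    "metabolite",
    "carbon_position",
    "time_min",
    "replicate_id",
    "enrichment_fraction",
    "labeled_conc_umol_g",
)

PYRUVATE = ("pyruvate", 3)  # source node: glycolytic [3-13C]pyruvate


@dataclass(frozen=True)
class PoolSpec:
    """Tissue metabolite pools and their compartmental partition.

    Concentrations in μmol/g wet weight.  Glutamine and GABA are
    assigned wholly to astroglia and GABAergic neurons respectively;
    the tissue glutamate pool is split between the three compartments
    by the ``glu_fraction_*`` weights (summing to 1).  Aspartate is
    taken to exchange with the glutamatergic-neuron oxaloacetate pool.
    ``intermediate_pool`` is the lumped αKG/OAA pool per compartment
    and is small relative to the amino-acid pools.
    """

    region: str
    conc_glu: float = 11.0
    conc_gln: float = 4.0
    conc_gaba: float = 2.2
    conc_asp: float = 2.5
    glu_fraction_glutamatergic: float = 0.82
    glu_fraction_gabaergic: float = 0.02
    glu_fraction_astroglial: float = 0.16
    intermediate_pool: float = 0.1

    def __post_init__(self) -> None:
        for name in ("conc_glu", "conc_gln", "conc_gaba", "conc_asp",
                     "intermediate_pool"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        total = (self.glu_fraction_glutamatergic
                 + self.glu_fraction_gabaergic
                 + self.glu_fraction_astroglial)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"glutamate compartment fractions sum to {total!r}, expected 1")

    @property
    def glu_fractions(self) -> tuple[float, float, float]:
        return (self.glu_fraction_glutamatergic,
                self.glu_fraction_gabaergic,
                self.glu_fraction_astroglial)


@dataclass(frozen=True)
class PlasmaInput:
    """Plasma [1-¹³C]/[6-¹³C]glucose enrichment forcing function.

    The bolus + exponentially tapered infusion protocol raises plasma
    enrichment quickly to a plateau; this is modelled as
    ``steady_enrichment * (1 - exp(-t / rise_tau))`` with ``rise_tau``
    in minutes (0 gives a step input).
    """

    steady_enrichment: float = 0.45
    rise_tau: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.steady_enrichment <= 1.0:
            raise ValueError("steady_enrichment must lie in [0, 1]")
        if self.rise_tau < 0:
            raise ValueError("rise_tau must be >= 0")

    def enrichment(self, t: np.ndarray | float) -> np.ndarray | float:
        if self.rise_tau == 0:
            return self.steady_enrichment * np.ones_like(np.asarray(t, dtype=float))
        return self.steady_enrichment * (1.0 - np.exp(-np.asarray(t, float) / self.rise_tau))


@dataclass(frozen=True)
class LabelTransition:
    """One carbon-skeleton transfer: src position → dst position.

    ``weight`` is the scrambling weight (weights out of a symmetric
    intermediate sum to 1 per source position); ``flux`` names the
    carrying flux for diagnostics.
    """

    src: tuple[str, int]
    dst: tuple[str, int]
    rate: float
    flux: str
    weight: float = 1.0


@dataclass
class LabelNetwork:
    """Assembled linear labelling system  dx/dt = A x + b p(t)."""

    states: list[tuple[str, int]]
    concs: dict[str, float]
    transitions: list[LabelTransition]
    outflow: dict[str, float]
    index: dict[tuple[str, int], int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {s: i for i, s in enumerate(self.states)}

    def system_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        n = len(self.states)
        A = np.zeros((n, n))
        b = np.zeros(n)
        for pool, pos in self.states:
            i = self.index[(pool, pos)]
            A[i, i] -= self.outflow[pool] / self.concs[pool]
        for tr in self.transitions:
            if tr.dst not in self.index:
                continue  # label leaving the tracked set (CO2-bound carboxyls)
            i = self.index[tr.dst]
            c = self.concs[tr.dst[0]]
            if tr.src == PYRUVATE:
                b[i] += tr.weight * tr.rate / c
            elif tr.src in self.index:
                A[i, self.index[tr.src]] += tr.weight * tr.rate / c
            # untracked sources (unlabelled dilution inflow) contribute 0
        return A, b

    def label_flows(self, x: np.ndarray, p: float) -> tuple[float, float]:
        """Total ¹³C inflow and outflow (μmol/g/min) at state ``x``.

        Inflow counts label entering from pyruvate; outflow counts label
        leaving each pool at its molecular turnover rate minus label
        transferred onward into tracked positions (i.e. only genuine
        losses: decarboxylated carbons, glutamine efflux, dilution).
        Conservation requires  d/dt Σ C·x = inflow − outflow.
        """
        inflow = 0.0
        transferred = 0.0
        for tr in self.transitions:
            if tr.dst not in self.index:
                continue
            if tr.src == PYRUVATE:
                inflow += tr.weight * tr.rate * p
            elif tr.src in self.index:
                transferred += tr.weight * tr.rate * x[self.index[tr.src]]
        gross_out = sum(self.outflow[pool] * x[self.index[(pool, pos)]]
                        for pool, pos in self.states)
        return inflow, gross_out - transferred


def build_label_network(fluxes: FluxSet, pools: PoolSpec) -> LabelNetwork:
    """Wire the carbon map of the three-compartment model.

    Compartment prefixes: ``G`` glutamatergic neuron, ``B`` GABAergic
    neuron, ``A`` astroglia.  Pools per compartment: ``kg`` lumped
    α-ketoglutarate (C2–C4) and ``oaa`` oxaloacetate (C2, C3), plus the
    amino-acid pools glu (per compartment), gaba, gln and asp.
    """
    v = fluxes
    wg, wb, wa = pools.glu_fractions
    ck = pools.intermediate_pool
    concs = {
        "kgG": ck, "oaaG": ck, "gluG": wg * pools.conc_glu,
        "kgB": ck, "oaaB": ck, "gluB": wb * pools.conc_glu,
        "kgA": ck, "oaaA": ck, "gluA": wa * pools.conc_glu,
        "gaba": pools.conc_gaba,
        "gln": pools.conc_gln,
        "asp": pools.conc_asp,
    }
    states: list[tuple[str, int]] = []
    for pool in concs:
        positions = (2, 3) if pool.startswith("oaa") or pool == "asp" else (2, 3, 4)
        states.extend((pool, p) for p in positions)

    tr: list[LabelTransition] = []

    def condensation(kg: str, oaa: str, rate: float, flux: str) -> None:
        # OAA + acetyl-CoA -> citrate -> aKG: acetyl C2 (from pyr C3) -> aKG C4,
        # OAA C2 -> aKG C3, OAA C3 -> aKG C2.
        tr.append(LabelTransition(PYRUVATE, (kg, 4), rate, flux))
        tr.append(LabelTransition((oaa, 2), (kg, 3), rate, flux))
        tr.append(LabelTransition((oaa, 3), (kg, 2), rate, flux))

    def scrambled(src_pool: str, src_positions: Iterable[int], oaa: str,
                  rate: float, flux: str) -> None:
        # through symmetric succinate/fumarate: 50/50 onto OAA C2/C3
        for sp in src_positions:
            for dp in (2, 3):
                tr.append(LabelTransition((src_pool, sp), (oaa, dp), rate, flux, 0.5))

    def exchange(a: str, b: str, positions: Sequence[tuple[int, int]],
                 rate: float, flux: str) -> None:
        for pa, pb in positions:
            tr.append(LabelTransition((a, pa), (b, pb), rate, flux))
            tr.append(LabelTransition((b, pb), (a, pa), rate, flux))

    glu_kg = [(2, 2), (3, 3), (4, 4)]

    # --- glutamatergic neuron -------------------------------------------
    condensation("kgG", "oaaG", v.v_tca_glu, "v_tca_glu")
    scrambled("kgG", (3, 4), "oaaG", v.v_tca_glu, "v_tca_glu")
    exchange("kgG", "gluG", glu_kg, v.v_x, "v_x")
    exchange("oaaG", "asp", [(2, 2), (3, 3)], v.v_x, "v_x")
    # glutamine returned by the Glu-Gln cycle
    for p in (2, 3, 4):
        tr.append(LabelTransition(("gln", p), ("gluG", p), v.v_cyc_glu_gln,
                                  "v_cyc_glu_gln"))
        # released transmitter glutamate taken up by astroglia
        tr.append(LabelTransition(("gluG", p), ("gluA", p), v.v_cyc_glu_gln,
                                  "v_cyc_glu_gln"))

    # --- GABAergic neuron -----------------------------------------------
    condensation("kgB", "oaaB", v.v_tca_gaba, "v_tca_gaba")
    scrambled("kgB", (3, 4), "oaaB", v.v_tca_gaba_net, "v_tca_gaba_net")
    exchange("kgB", "gluB", glu_kg, v.v_x, "v_x")
    # net aKG -> glutamate flux replacing carbon decarboxylated by GAD
    for p in (2, 3, 4):
        tr.append(LabelTransition(("kgB", p), ("gluB", p), v.v_shunt, "v_shunt"))
        tr.append(LabelTransition(("gln", p), ("gluB", p), v.v_cyc_gaba_gln,
                                  "v_cyc_gaba_gln"))
    # GAD: glutamate C4->GABA C2, C3->C3, C2->C4 (carboxyl C1 lost as CO2)
    for gp, bp in ((4, 2), (3, 3), (2, 4)):
        tr.append(LabelTransition(("gluB", gp), ("gaba", bp), v.v_gad, "v_gad"))
    # GABA shunt: GABA C2/C3 -> succinate C2/C3 -> OAA C2/C3 (scrambled);
    # GABA C4 reaches a carboxyl carbon and is lost on the next turn
    scrambled("gaba", (2, 3), "oaaB", v.v_shunt, "v_shunt")

    # --- astroglia --------------------------------------------------------
    condensation("kgA", "oaaA", v.v_tca_a, "v_tca_a")
    scrambled("kgA", (3, 4), "oaaA", v.v_tca_a_net, "v_tca_a_net")
    exchange("kgA", "gluA", glu_kg, v.v_x, "v_x")
    # pyruvate carboxylase: pyruvate C3 -> OAA C3, no back-scrambling
    tr.append(LabelTransition(PYRUVATE, ("oaaA", 3), v.v_pc, "v_pc"))
    # GABA taken up by astroglia is oxidised through the astroglial TCA
    scrambled("gaba", (2, 3), "oaaA", v.v_cyc_gaba_gln, "v_cyc_gaba_gln")
    # net aKG -> glutamate flux supporting glutamine synthesis
    for p in (2, 3, 4):
        tr.append(LabelTransition(("kgA", p), ("gluA", p),
                                  v.v_pc + v.v_cyc_gaba_gln, "v_gln_anaplerotic"))
        tr.append(LabelTransition(("gluA", p), ("gln", p), v.v_gln, "v_gln"))

    outflow = {
        "kgG": v.v_tca_glu + v.v_x,
        "oaaG": v.v_tca_glu + v.v_x,
        "gluG": v.v_x + v.v_cyc_glu_gln + v.v_dil_glu,
        "kgB": v.v_tca_gaba_net + v.v_shunt + v.v_x,
        "oaaB": v.v_tca_gaba,
        "gluB": v.v_x + v.v_gad,
        "gaba": v.v_gad + v.v_dil_gaba,
        "kgA": v.v_tca_a_net + v.v_pc + v.v_cyc_gaba_gln + v.v_x,
        "oaaA": v.v_tca_a,
        "gluA": v.v_x + v.v_gln + v.v_dil_a,
        "gln": v.v_gln + v.v_dil_gln,
        "asp": v.v_x,
    }
    return LabelNetwork(states=states, concs=concs, transitions=tr,
                        outflow=outflow)


def _validate(fluxes: FluxSet, pools: PoolSpec, times: Sequence[float]) -> None:
    residuals = mass_balance_residuals(fluxes)
    bad = {k: r for k, r in residuals.items() if abs(r) > 1e-8}
    if bad:
        raise FluxValidationError(f"flux set violates steady-state balance: {bad}")
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")


def measured_curves(network: LabelNetwork, pools: PoolSpec,
                    x: np.ndarray) -> dict[tuple[str, int], np.ndarray]:
    """Map state trajectories to measurable tissue enrichments.

    Tissue glutamate is the pool-fraction-weighted mix of the three
    compartmental glutamate pools; GABA, glutamine and aspartate map
    directly to their single compartment.
    """
    wg, wb, wa = pools.glu_fractions
    ix = network.index
    out: dict[tuple[str, int], np.ndarray] = {}
    for p in (2, 3, 4):
        out[("Glu", p)] = (wg * x[ix[("gluG", p)]]
                           + wb * x[ix[("gluB", p)]]
                           + wa * x[ix[("gluA", p)]])
        out[("GABA", p)] = x[ix[("gaba", p)]]
        out[("Gln", p)] = x[ix[("gln", p)]]
    out[("Asp", 3)] = x[ix[("asp", 3)]]
    out[("Asp", 2)] = x[ix[("asp", 2)]]
    return out


def _total_conc(pools: PoolSpec, metabolite: str) -> float:
    return {"Glu": pools.conc_glu, "GABA": pools.conc_gaba,
            "Gln": pools.conc_gln, "Asp": pools.conc_asp}[metabolite]


def simulate_labeling(
    fluxes: FluxSet,
    pools: PoolSpec,
    plasma: PlasmaInput,
    times: Sequence[float],
    *,
    method: str = "ivp",
    curves: Sequence[tuple[str, int]] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Simulate fractional ¹³C enrichment time courses.

    Parameters
    ----------
    fluxes, pools, plasma
        Balanced flux set, regional pool sizes and plasma forcing.
    times
        Sampling times in minutes (t = 0 is infusion start, all pools
        unlabelled).
    method
        ``"ivp"`` — adaptive LSODA integration (default);
        ``"expm"`` — exact matrix-exponential solution of the linear
        system (handles arbitrarily stiff exchange rates).
    curves
        Which (metabolite, position) curves to report; defaults to the
        six fitted curves plus Glu-C2, GABA-C4 and Gln-C3/C2.

    Returns
    -------
    pandas.DataFrame
        Tidy table with :data:`TIMECOURSE_COLUMNS` (``replicate_id`` 0,
        noiseless).
    """
    network, t, X = simulate_states(fluxes, pools, plasma, times,
                                    method=method, rtol=rtol, atol=atol)
    if curves is None:
        curves = list(FITTED_CURVES) + [("Glu", 2), ("GABA", 4), ("Gln", 3),
                                        ("Gln", 2)]
    meas = measured_curves(network, pools, X)
    records = []
    for met, pos in curves:
        conc = _total_conc(pools, met)
        for j, tj in enumerate(t):
            e = float(meas[(met, pos)][j])
            records.append((pools.region, met, pos, float(tj), 0, e, e * conc))
    return pd.DataFrame.from_records(records, columns=TIMECOURSE_COLUMNS)


def simulate_states(
    fluxes: FluxSet,
    pools: PoolSpec,
    plasma: PlasmaInput,
    times: Sequence[float],
    *,
    method: str = "ivp",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[LabelNetwork, np.ndarray, np.ndarray]:
    """Integrate the full positional state; returns (network, t, X).

    ``X[i, j]`` is the enrichment of state ``network.states[i]`` at
    ``t[j]``.  Lower-level companion of :func:`simulate_labeling`.
    """
    _validate(fluxes, pools, times)
    network = build_label_network(fluxes, pools)
    A, b = network.system_matrices()
    t = np.asarray(times, dtype=float)
    if method == "expm":
        X = _solve_expm(A, b, plasma, t)
    elif method == "ivp":
        X = _solve_ivp(A, b, plasma, t, network, rtol=rtol, atol=atol)
    else:
        raise ValueError(f"unknown method {method!r}")
    return network, t, X


def _solve_ivp(A: np.ndarray, b: np.ndarray, plasma: PlasmaInput,
               t: np.ndarray, network: LabelNetwork, *,
               rtol: float, atol: float) -> np.ndarray:
    t_span = (0.0, float(max(t.max(), 1e-9)))

    def rhs(ti: float, x: np.ndarray) -> np.ndarray:
        return A @ x + b * plasma.enrichment(ti)

    sol = solve_ivp(rhs, t_span, np.zeros(A.shape[0]), method="LSODA",
                    t_eval=np.sort(np.unique(t)), rtol=rtol, atol=atol)
    if not sol.success:
        # name the stiffest pool (largest outflow / concentration)
        rates = {p: network.outflow[p] / network.concs[p] for p in network.concs}
        worst = max(rates, key=rates.get)
        raise RuntimeError(
            f"integration failed: {sol.message}; fastest pool {worst!r} turns "
            f"over at {rates[worst]:.3g}/min — consider method='expm'")
    tu = np.sort(np.unique(t))
    pos = {tj: j for j, tj in enumerate(tu)}
    cols = [pos[tj] for tj in t]
    return sol.y[:, cols]


def _solve_expm(A: np.ndarray, b: np.ndarray, plasma: PlasmaInput,
                t: np.ndarray) -> np.ndarray:
    """Exact solution via the augmented autonomous system [x; p; 1]."""
    n = A.shape[0]
    M = np.zeros((n + 2, n + 2))
    M[:n, :n] = A
    M[:n, n] = b
    E, tau = plasma.steady_enrichment, plasma.rise_tau
    if tau > 0:
        M[n, n] = -1.0 / tau
        M[n, n + 1] = E / tau
        p0 = 0.0
    else:
        p0 = E
    z0 = np.zeros(n + 2)
    z0[n] = p0
    z0[n + 1] = 1.0
    X = np.empty((n, t.size))
    cache: dict[float, np.ndarray] = {}
    for j, tj in enumerate(t):
        if tj not in cache:
            cache[tj] = expm(M * tj) @ z0
        X[:, j] = cache[tj][:n]
    return X
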