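"""Label-routing simulation: oracles, invariants and failure modes."""

import numpy as np
import pytest

import neuroflux as nf

TIMES = [5.0, 10.0, 30.0, 60.0, 90.0]


def closed_system(cfg, **overrides):
    """Control fluxes with all label sinks removed (no dilution, no PC)."""
    params = cfg.fluxes("control").primary()
    params.update(v_pc=0.0, v_dil_glu=0.0, v_dil_gaba=0.0, v_dil_a=0.0,
                  v_dil_gln=0.0)
    params.update(overrides)
    return nf.FluxSet.from_primary(ratio_glu=cfg.ratio_glu,
                                   ratio_gaba=cfg.ratio_gaba, **params)


class TestSimulation:
    def test_unlabelled_plasma_gives_zero_enrichment(self, cortex):
        plasma = nf.PlasmaInput(steady_enrichment=0.0)
        df = nf.simulate_labeling(cortex.fluxes("control"), cortex.pools,
                                  plasma, TIMES)
        assert (df["enrichment_fraction"] == 0).all()

    def test_closed_system_reaches_precursor_enrichment(self, cortex):
        fx = closed_system(cortex)
        df = nf.simulate_labeling(fx, cortex.pools, cortex.plasma, [5000.0],
                                  method="expm")
        glu4 = df.query("metabolite == 'Glu' and carbon_position == 4")
        assert glu4["enrichment_fraction"].iloc[0] == pytest.approx(
            cortex.plasma.steady_enrichment, abs=1e-5)

    def test_labeled_concentration_consistent_with_enrichment(self, cortex):
        df = nf.simulate_labeling(cortex.fluxes("control"), cortex.pools,
                                  cortex.plasma, TIMES)
        conc = {"Glu": cortex.pools.conc_glu, "GABA": cortex.pools.conc_gaba,
                "Gln": cortex.pools.conc_gln, "Asp": cortex.pools.conc_asp}
        expected = df["metabolite"].map(conc) * df["enrichment_fraction"]
        np.testing.assert_allclose(df["labeled_conc_umol_g"], expected,
                                   rtol=1e-12)

    def test_rejects_unbalanced_fluxes(self, cortex):
        fx = cortex.fluxes("control").with_values(v_gad=0.5)
        with pytest.raises(nf.FluxValidationError):
            nf.simulate_labeling(fx, cortex.pools, cortex.plasma, TIMES)

    def test_rejects_empty_or_negative_times(self, cortex):
        fx = cortex.fluxes("control")
        with pytest.raises(ValueError):
            nf.simulate_labeling(fx, cortex.pools, cortex.plasma, [])
        with pytest.raises(ValueError):
            nf.simulate_labeling(fx, cortex.pools, cortex.plasma, [-1.0])

    def test_rejects_nonpositive_pool(self):
        with pytest.raises(ValueError, match="conc_glu"):
            nf.PoolSpec(region="cortex", conc_glu=0.0)


class TestOracles:
    def test_one_pool_analytic_limit(self, cortex):
        """With one active compartment and fast exchange, Glu-C4 follows
        the closed-form single-pool solution E·(1 − exp(−V t / C))."""
        v, vx = 0.5, 1.0e6
        eps = 1e-9
        fx = nf.FluxSet.from_primary(
            ratio_glu=eps, ratio_gaba=eps, v_tca_glu=v, v_tca_gaba_net=0.0,
            v_shunt=0.0, v_tca_a_net=0.0, v_pc=0.0, v_x=vx,
            v_dil_glu=0.0, v_dil_gaba=0.0, v_dil_a=0.0, v_dil_gln=0.0)
        plasma = nf.PlasmaInput(steady_enrichment=0.45, rise_tau=0.0)
        net, t, X = nf.simulate_states(fx, cortex.pools, plasma, TIMES,
                                       method="expm")
        g4 = X[net.index[("gluG", 4)]]
        c_eff = net.concs["gluG"] + net.concs["kgG"]
        analytic = 0.45 * (1.0 - np.exp(-v * t / c_eff))
        np.testing.assert_allclose(g4, analytic, atol=1e-6)

    def test_matrix_exponential_matches_time_stepping(self, cortex):
        fx = cortex.fluxes("control")
        a = nf.simulate_labeling(fx, cortex.pools, cortex.plasma, TIMES,
                                 method="ivp")
        b = nf.simulate_labeling(fx, cortex.pools, cortex.plasma, TIMES,
                                 method="expm")
        assert np.max(np.abs(a["enrichment_fraction"]
                             - b["enrichment_fraction"])) < 1e-6

    def test_label_conservation(self, cortex):
        """d/dt of total labelled carbon equals inflow − losses, computed
        independently from the transition bookkeeping."""
        fx = cortex.fluxes("control")
        net, t, X = nf.simulate_states(fx, cortex.pools, cortex.plasma,
                                       TIMES, method="expm")
        A, b = net.system_matrices()
        concs = np.array([net.concs[p] for p, _ in net.states])
        vmax = max(fx.to_dict().values())
        for j, tj in enumerate(t):
            p = cortex.plasma.enrichment(tj)
            dxdt = A @ X[:, j] + b * p
            lhs = float(concs @ dxdt)
            inflow, outflow = net.label_flows(X[:, j], p)
            assert abs(lhs - (inflow - outflow)) < 1e-8 * vmax


class TestInvariants:
    def test_enrichment_bounded_by_plasma(self, cortex):
        fx = cortex.fluxes("control")
        times = np.linspace(0.5, 300, 120)
        df = nf.simulate_labeling(fx, cortex.pools, cortex.plasma, times,
                                  method="expm")
        e = df["enrichment_fraction"]
        assert (e >= -1e-12).all()
        assert (e <= cortex.plasma.steady_enrichment + 1e-9).all()

    def test_first_turn_curves_monotone_under_step_input(self, cortex):
        fx = cortex.fluxes("control")
        plasma = nf.PlasmaInput(steady_enrichment=0.45, rise_tau=0.0)
        times = np.linspace(1, 200, 80)
        df = nf.simulate_labeling(fx, cortex.pools, plasma, times,
                                  method="expm")
        for met, pos in [("Glu", 4), ("GABA", 2), ("Gln", 4)]:
            curve = df.query("metabolite == @met and carbon_position == @pos")
            assert (np.diff(curve["enrichment_fraction"]) > -1e-10).all(), \
                f"{met}-C{pos} not monotone"

    def test_second_turn_lags_first_turn(self, cortex):
        """Glu-C3 labelling requires a full extra TCA turn, so without
        pyruvate carboxylase it trails Glu-C4 at all pre-steady times."""
        fx = closed_system(cortex)
        times = np.linspace(1, 120, 60)
        df = nf.simulate_labeling(fx, cortex.pools, cortex.plasma, times,
                                  method="expm")
        g4 = df.query("metabolite == 'Glu' and carbon_position == 4")
        g3 = df.query("metabolite == 'Glu' and carbon_position == 3")
        assert (g3["enrichment_fraction"].to_numpy()
                < g4["enrichment_fraction"].to_numpy()).all()

    def test_scrambling_weights_sum_to_one(self, cortex):
        net = nf.build_label_network(cortex.fluxes("control"), cortex.pools)
        half = [tr for tr in net.transitions if tr.weight != 1.0]
        assert half, "expected scrambled transitions"
        by_source = {}
        for tr in half:
            by_source.setdefault((tr.src, tr.flux), 0.0)
            by_source[(tr.src, tr.flux)] += tr.weight
        assert all(abs(w - 1.0) < 1e-12 for w in by_source.values())

    def test_all_measured_positions_reachable_from_pyruvate(self, cortex):
        import networkx as nxg
        net = nf.build_label_network(cortex.fluxes("control"), cortex.pools)
        g = nxg.DiGraph()
        for tr in net.transitions:
            if tr.rate > 0:
                g.add_edge(tr.src, tr.dst)
        targets = [("gluG", 4), ("gluG", 3), ("gluG", 2), ("gaba", 2),
                   ("gaba", 3), ("gaba", 4), ("asp", 3), ("gln", 4),
                   ("gln", 3), ("gln", 2)]
        reachable = nxg.descendants(g, ("pyruvate", 3))
        for t in targets:
            assert t in reachable, f"{t} unreachable from pyruvate C3"
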