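"""Mass-action network construction, integration, and endpoint analyses."""

import numpy as np
import pytest

from hairpinjoint.kinetics import (
    FLUORESCENCE_CONDITION,
    GEL_SHIFT_CONDITION,
    GEL_SHIFT_DCAS9,
    GEL_SHIFT_DNA,
    NM,
    UM,
    Condition,
    RateModel,
    Reaction,
    ReactionNetwork,
    dcas9_endpoint,
    dcas9_gate_series,
    dose_response,
    enumerate_network,
    mismatch_discrimination,
    simulate,
    toehold_rate,
    truth_table,
)


class TestToeholdRate:
    def test_zero_toehold_is_leak(self):
        assert toehold_rate(0, 0, RateModel(k_leak=0.0)) == 0.0
        assert toehold_rate(0, 0, RateModel(k_leak=5.0)) == 5.0

    def test_one_nt_rate_is_k_base(self):
        m = RateModel()
        assert toehold_rate(1, 0, m) == pytest.approx(m.k_base)

    def test_monotone_in_length(self):
        m = RateModel()
        rates = [toehold_rate(n, 0, m) for n in range(0, 13)]
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert max(rates) <= m.k_max

    def test_saturation_value(self):
        m = RateModel()
        expected = min(m.k_max, m.k_base * m.per_nt_factor ** (m.n_sat - 1))
        assert toehold_rate(7, 0, m) == pytest.approx(expected)
        assert toehold_rate(12, 0, m) == pytest.approx(expected)

    def test_mismatch_penalty(self):
        m = RateModel()
        assert toehold_rate(8, 2, m) == pytest.approx(
            toehold_rate(8, 0, m) * m.mismatch_factor ** 2)

    def test_negative_inputs(self):
        with pytest.raises(ValueError):
            toehold_rate(-1)
        with pytest.raises(ValueError):
            toehold_rate(3, -2)


class TestEnumerateNetwork:
    def test_reporter_only_prunes_si_branch(self, circuit):
        net = enumerate_network(circuit, FLUORESCENCE_CONDITION)
        assert [r.name for r in net.reactions] == ["R1", "R2", "R3"]

    def test_full_system(self, circuit):
        cond = Condition({"T": 60 * NM, "H1": 60 * NM, "H2": 60 * NM,
                          "RepFQ": 30 * NM, "SIgRNA": 30 * NM}, t_end=1200)
        net = enumerate_network(circuit, cond)
        assert [r.name for r in net.reactions] == ["R1", "R2", "R3", "R4"]
        assert len(net.species) <= 12

    def test_leak_reaction_only_when_enabled(self, circuit):
        net = enumerate_network(circuit, FLUORESCENCE_CONDITION,
                                RateModel(k_leak=1.0))
        assert any(r.name == "R5" for r in net.reactions)

    def test_stoichiometry_conserves_strands(self, circuit):
        net = enumerate_network(circuit, FLUORESCENCE_CONDITION)
        net.validate()  # raises on any non-conserving reaction

    def test_bad_reaction_rejected(self):
        net = ReactionNetwork(
            species={"A": 1.0, "B": 0.0},
            composition={"A": {"A": 1}, "B": {"B": 1}},
            reactions=[Reaction("bad", ("A",), ("B",), 1.0)],
        )
        with pytest.raises(ValueError, match="conserve"):
            net.validate()


class TestSimulate:
    def test_all_zero_initials_stay_zero(self, circuit):
        cond = Condition({"T": 0.0, "H1": 0.0, "H2": 0.0, "RepFQ": 0.0},
                         t_end=600.0)
        tc = simulate(enumerate_network(circuit, cond), cond)
        assert np.allclose(tc.concentrations.to_numpy(), 0.0)

    def test_bimolecular_closed_form(self):
        # A + B -> C with equal initials c: [C](t) = c^2 k t / (1 + c k t)
        c0, k, t_end = 50 * NM, 1e6, 3600.0
        net = ReactionNetwork(
            species={"A": c0, "B": c0, "C": 0.0},
            composition={"A": {"A": 1}, "B": {"B": 1},
                         "C": {"A": 1, "B": 1}},
            reactions=[Reaction("bind", ("A", "B"), ("C",), k)],
        )
        tc = simulate(net, t_end=t_end, n_samples=51)
        analytic = c0 ** 2 * k * tc.times / (1 + c0 * k * tc.times)
        sim = tc.concentrations["C"].to_numpy()
        assert np.allclose(sim[1:], analytic[1:], rtol=1e-4)

    def test_strand_conservation(self, circuit):
        tc = simulate(enumerate_network(circuit, FLUORESCENCE_CONDITION),
                      FLUORESCENCE_CONDITION)
        assert tc.conservation_residual() < 1e-6

    def test_reporter_limited_completion(self, circuit):
        # T=H1=H2=60 nM, reporter 30 nM: displaced reporter -> 30 nM
        cond = Condition(dict(FLUORESCENCE_CONDITION.concentrations),
                         t_end=4 * 3600.0)
        tc = simulate(enumerate_network(circuit, cond), cond)
        assert tc.endpoint_fluorescence() == pytest.approx(30 * NM, rel=1e-3)


class TestTruthTable:
    def test_and_gate(self, circuit):
        table = truth_table(circuit)
        assert len(table) == 8
        on = table[table["T"] & table["H1"] & table["H2"]]["endpoint_M"].iloc[0]
        off = table[~(table["T"] & table["H1"] & table["H2"])]["endpoint_M"]
        assert on > 0
        assert (off <= 1e-3 * on).all()


class TestDoseResponse:
    def test_pattern(self, circuit):
        concs = [x * NM for x in (0, 30, 45, 60, 75, 90)]
        table = dose_response(circuit, concs)
        end = table["endpoint_M"].to_numpy()
        assert end[0] == 0.0
        assert np.all(np.diff(end) >= -1e-6 * 30 * NM)
        assert np.all(end <= 30 * NM * (1 + 1e-6))

    def test_negative_concentration_rejected(self, circuit):
        with pytest.raises(ValueError):
            dose_response(circuit, [-1 * NM])


class TestMismatchDiscrimination:
    def test_identical_trigger_ratio_one(self, circuit):
        ratio = mismatch_discrimination(circuit, circuit.trigger.sequence,
                                        horizon_s=1200.0)
        assert ratio == pytest.approx(1.0)

    def test_penalty_softens_as_factor_approaches_one(self, circuit):
        # short horizon so the soft-penalty run is not already saturated
        wrong = _mutate_toehold(circuit, 4)
        strict = mismatch_discrimination(circuit, wrong, horizon_s=600.0,
                                         model=RateModel(mismatch_factor=1e-2))
        soft = mismatch_discrimination(circuit, wrong, horizon_s=600.0,
                                       model=RateModel(mismatch_factor=0.5))
        none = mismatch_discrimination(circuit, wrong, horizon_s=600.0,
                                       model=RateModel(mismatch_factor=1.0))
        assert strict > soft > none
        assert none == pytest.approx(1.0, rel=1e-6)

    def test_length_mismatch_is_an_error(self, circuit):
        with pytest.raises(ValueError, match="length"):
            mismatch_discrimination(circuit, circuit.trigger.sequence[:-1])


class TestDcas9Endpoint:
    def test_no_active_grna_no_binding(self):
        assert dcas9_endpoint(0.0, GEL_SHIFT_DCAS9, GEL_SHIFT_DNA) == 0.0

    def test_monotone(self):
        xs = np.linspace(0, 2 * UM, 9)
        fr = [dcas9_endpoint(x, GEL_SHIFT_DCAS9, GEL_SHIFT_DNA) for x in xs]
        assert all(b >= a for a, b in zip(fr, fr[1:]))
        assert all(0.0 <= f <= 1.0 for f in fr)

    def test_gate_series_strictly_increasing(self, circuit):
        series = dcas9_gate_series(circuit,
                                   [x * UM for x in (0, 0.25, 0.5, 1, 2)])
        fr = series["bound_dna_fraction"].to_numpy()
        assert fr[0] == 0.0
        assert np.all(np.diff(fr) > 0)

    def test_rnp_limited_by_dcas9(self):
        f_excess = dcas9_endpoint(5 * UM, 1 * UM, GEL_SHIFT_DNA)
        f_matched = dcas9_endpoint(1 * UM, 1 * UM, GEL_SHIFT_DNA)
        assert f_excess == pytest.approx(f_matched)


def _mutate_toehold(circuit, n_mut):
    """Transversion-substitute the first n_mut toehold bases of the trigger."""
    swap = {"A": "C", "C": "A", "G": "U", "U": "G", "T": "G"}
    seq = list(circuit.trigger.sequence)
    for i in range(n_mut):
        seq[i] = swap[seq[i]]
    return "".join(seq)


def test_time_to_90_percent_regime(circuit):
    """Under default rates at the assay concentrations the signal saturates
    on the tens-of-minutes scale."""
    table = dose_response(circuit, [60 * NM])
    t90_min = table["t90_s"].iloc[0] / 60.0
    assert 1.0 <= t90_min <= 60.0
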