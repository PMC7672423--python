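"""Circuit designer: trigger partition, hairpin/SI-gRNA/reporter construction,
independence certification, and the seeded design search."""

import dataclasses
import json

import pytest

import hairpinjoint as hj
from hairpinjoint.design import (
    DEFAULT_SCAFFOLD,
    DesignInfeasibleError,
    DesignParams,
    build_hairpins,
    build_reporter,
    build_si_grna,
    derive_activator,
    design_circuit,
    independence_check,
    partition_trigger,
)
from hairpinjoint.sequences import Domain, revcomp


class TestPartitionTrigger:
    def test_equal_split(self):
        d1, d2 = partition_trigger("ACGUACGUACGUACGU", 8)
        assert d1.sequence == "ACGUACGU" and d2.sequence == "ACGUACGU"
        assert d1.role == "toehold" and d2.role == "migration"

    def test_length_arithmetic(self):
        d1, d2 = partition_trigger("A" * 8 + "C" * 14, 8)
        assert len(d2) == 14
        assert d1.sequence + d2.sequence == "A" * 8 + "C" * 14

    def test_too_short_trigger(self):
        with pytest.raises(DesignInfeasibleError, match="14"):
            partition_trigger("ACGUA", 8)


class TestDeriveActivator:
    def test_construction_by_definition(self):
        d3 = Domain("d3", "GGGGGG")
        act = derive_activator("AAAAAAAAAACCCCCCCCCC", 10, d3)
        assert act == "GGGGGGCCCCCCCCCC"

    def test_activator_length(self):
        d3 = Domain("d3", "ACGUACGUACGU")
        act = derive_activator("ACGU" * 5, 12, d3)
        assert len(act) == len(d3) + 12

    @pytest.mark.parametrize("n_seed", [10, 12, 15])
    def test_all_inhibitor_lengths_construct(self, n_seed):
        d3 = Domain("d3", "ACGUACGUACGU")
        spacer = "GCAUGGACUCAGGCAUUCCA"
        act = derive_activator(spacer, n_seed, d3)
        assert act.endswith(spacer[-n_seed:])

    def test_seed_longer_than_spacer(self):
        with pytest.raises(DesignInfeasibleError):
            derive_activator("ACGU", 10, Domain("d3", "GG"))


class TestBuildHairpins:
    def test_hand_assembly(self):
        doms = dict(d1="AA", d2="CG", d3="UU", d4="GG")
        h1, h2 = build_hairpins(*(Domain(k, v) for k, v in doms.items()))
        assert h1.sequence == "CGUUCGUU"
        assert h2.sequence == "UUGGAACG"

    def test_domain_multiplicity(self):
        doms = [Domain(n, s) for n, s in
                [("d1", "ACGU"), ("d2", "GGAU"), ("d3", "CCAU"), ("d4", "AUGG")]]
        h1, h2 = build_hairpins(*doms)
        assert h1.domain_refs == ("d2", "d3", "d2*", "d1*")
        assert h2.domain_refs == ("d3", "d4", "d3*", "d2*")

    def test_opened_exposed_regions(self):
        # trigger opens H1 exposing d2.d3; that opens H2 exposing d3.d4
        doms = {n: Domain(n, s) for n, s in
                [("d1", "ACGU"), ("d2", "GGAU"), ("d3", "CCAU"), ("d4", "AUGG")]}
        h1, h2 = build_hairpins(*doms.values())
        assert h1.sequence.startswith(doms["d2"].sequence + doms["d3"].sequence)
        assert h2.sequence.startswith(doms["d3"].sequence + doms["d4"].sequence)

    def test_stems_are_complementary(self, circuit):
        for name in ("H1", "H2"):
            strand = getattr(circuit, name.lower())
            seq = strand.sequence
            for i, j in circuit.intra_strand_pairs(name):
                assert revcomp(seq[i], circuit.material) == seq[j]


class TestSiGrnaAndReporter:
    def test_inhibitor_is_revcomp_of_activator(self, circuit):
        inh = revcomp(circuit.activator.sequence, circuit.material)
        assert circuit.si_grna.sequence.endswith(inh)

    def test_cis_fold_seed_pairing(self, circuit):
        seq = circuit.si_grna.sequence
        for i, j in circuit.intra_strand_pairs("SIgRNA"):
            assert revcomp(seq[i], circuit.material) == seq[j]

    def test_three_prime_extension_is_default(self):
        assert DesignParams().extension_end == "3prime"

    def test_five_prime_variant_constructible(self):
        params = DesignParams(extension_end="5prime")
        d3 = Domain("d3", "ACGUACGUACGU")
        d4 = Domain("d4", "GGCAUUCCAGCA")
        si = build_si_grna("GCAUGGACUCAGGCAUUCCA"[:8] + "GGCAUUCCAGCA",
                           DEFAULT_SCAFFOLD, d3, d4, params)
        assert si.domain_refs[0] == "d4*"
        inh = revcomp(d3.sequence + d4.sequence)
        assert si.sequence.startswith(inh)

    def test_reporter_duality(self, circuit):
        d3 = circuit.domain("d3")
        d4 = circuit.domain("d4")
        rep_f, rep_q = build_reporter(d3, d4)
        # quencher strand is the complement of RepF's d4* segment
        a, b = rep_f.segment("d4*")
        assert rep_q.sequence == revcomp(rep_f.sequence[a:b], circuit.material)
        # the activator is fully complementary to RepF
        assert revcomp(circuit.activator.sequence, circuit.material) == rep_f.sequence


class TestIndependenceCheck:
    def test_shared_long_word_fails(self):
        trigger = "AAAACGGAUCCAUGAAAA"
        activator = "UUUCGGAUCUUU"  # shares the 6-mer CGGAUC
        rep, ok = independence_check(activator, trigger, lcs_max=5)
        assert rep.lcs_len == 6 and not ok

    def test_disjoint_alphabet_passes(self):
        rep, ok = independence_check("GGUGGU", "AACCAACC", lcs_max=5)
        assert rep.lcs_len == 0 and ok

    def test_reverse_complement_similarity_also_screened(self):
        trigger = "AAAAGGAUCCGAAAA"
        activator = revcomp(trigger[3:11])  # complementary 8-mer
        rep, ok = independence_check(activator, trigger, lcs_max=5)
        assert rep.lcs_rc_len >= 8 and not ok


class TestDesignCircuit:
    def test_determinism_same_seed(self, fixture_set):
        from hairpinjoint.io import circuit_to_document

        trig = fixture_set.triggers[0][1]
        sp = fixture_set.spacers[0][1]
        a = design_circuit(trig, sp, DesignParams(rng_seed=7))
        b = design_circuit(trig, sp, DesignParams(rng_seed=7))
        assert json.dumps(circuit_to_document(a)) == json.dumps(circuit_to_document(b))

    def test_distinct_seeds_may_differ(self, fixture_set):
        trig = fixture_set.triggers[0][1]
        sp = fixture_set.spacers[0][1]
        a = design_circuit(trig, sp, DesignParams(rng_seed=0))
        b = design_circuit(trig, sp, DesignParams(rng_seed=1))
        # both valid; d3 choice is seed-dependent (not required to differ,
        # but the trigger partition and d4 must agree)
        assert a.domain("d1") == b.domain("d1")
        assert a.domain("d4") == b.domain("d4")

    def test_accepted_design_invariants(self, circuit):
        params = circuit.params
        trig = circuit.trigger.sequence
        spacer = circuit.si_grna._domain("spacer").sequence
        # d4 equals the PAM-proximal spacer seed
        assert circuit.domain("d4").sequence == spacer[-params.n_seed:]
        # activator/inhibitor duality
        inh = revcomp(circuit.activator.sequence, circuit.material)
        assert circuit.si_grna.sequence.endswith(inh)
        # independence at the accepted threshold
        rep, ok = independence_check(circuit.activator.sequence, trig,
                                     params.lcs_max)
        assert ok and rep.lcs_len <= params.lcs_max

    def test_changing_trigger_preserves_si_grna_and_reporter(self, circuit):
        # architecture-level invariant: SI-gRNA and reporter depend only on
        # (spacer, d3), so rebuilding with a new trigger leaves them unchanged
        d3 = circuit.domain("d3")
        d4 = circuit.domain("d4")
        spacer = circuit.si_grna._domain("spacer").sequence
        si2 = build_si_grna(spacer, circuit.scaffold, d3, d4, circuit.params)
        rep_f2, rep_q2 = build_reporter(d3, d4)
        assert si2.sequence == circuit.si_grna.sequence
        assert rep_f2.sequence == circuit.rep_f.sequence
        assert rep_q2.sequence == circuit.rep_q.sequence
        new_trigger = "AGCAGAUUGCAGUAAGCUGAAU"
        c2 = design_circuit(new_trigger, spacer,
                            dataclasses.replace(circuit.params))
        assert c2.si_grna.sequence[-len(d3):] == \
            revcomp(c2.domain("d3").sequence, c2.material)

    def test_infeasible_pair_reports_histogram(self):
        # trigger contains the spacer seed verbatim: no d3 can fix that
        spacer = "GCAUGGACUCAGGCAUUCCA"
        trigger = "AAAA" + spacer[-12:] + "AAAAAA"
        with pytest.raises(DesignInfeasibleError, match="independence"):
            design_circuit(trigger, spacer, DesignParams(rng_seed=0))

    def test_self_complementary_d3_candidate_rejected(self):
        # the crosstalk screen rejects a d3 whose toehold d3* self-dimerizes
        from hairpinjoint.design import _crosstalk

        fatal, _ = _crosstalk(
            {"d1": "ACGUACGU", "d2": "AAGGAAGGAAGGAA",
             "d3": "GGGGGGCCCCCC"},
            "ACGUACGUAAGGAAGGAAGGAA", "RNA", 5)
        assert any("d3* toehold vs d3* toehold" in f for f in fatal)

    def test_wrong_spacer_length(self):
        with pytest.raises(DesignInfeasibleError, match="20"):
            design_circuit("ACGUACGUACGUACGUACGUAC", "ACGUACGU",
                           DesignParams(rng_seed=0))


def test_params_validation():
    with pytest.raises(ValueError):
        DesignParams(n1=3).validate()
    with pytest.raises(ValueError):
        DesignParams(n3=4).validate()
    with pytest.raises(ValueError):
        DesignParams(n_seed=11).validate()  # not in the allowed set
    with pytest.raises(ValueError):
        DesignParams(extension_end="sideways").validate()
    DesignParams().validate()
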