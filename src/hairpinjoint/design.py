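"""Constraint-based design of the two-hairpin conditional-gRNA circuit.

Given an arbitrary trigger RNA and a 20-nt Cas9 spacer, the designer
emits a complete circuit in which the trigger and the gRNA never share
sequence:

* the trigger (domains d1.d2) opens hairpin H1 by toehold-mediated
  strand displacement, exposing d2.d3;
* the exposed segment opens hairpin H2, exposing the *activator* d3.d4;
* d4 is the PAM-proximal seed of the spacer and d3 is a free domain
  chosen by the designer, so the activator is sequence-related to the
  guide and unrelated to the trigger;
* the activator strips the cis inhibitor off the self-inhibitory gRNA
  (SI-gRNA) and, in the reporter configuration, displaces the quencher
  strand of the RepF:RepQ duplex.

Committed strand architecture (5'->3'):

    H1      = [d2][d3][d2*][d1*]        stem d2:d2*, loop d3, 3' toehold d1*
    H2      = [d3][d4][d3*][d2*]        stem d3:d3*, loop d4, 3' toehold d2*
    SI-gRNA = [spacer][scaffold][linker][d4*][d3*]   (3' extension, default)
    RepF    = [d4*][d3*]  (fluorophore) ; RepQ = [d4]  (quencher)

The loop of each hairpin is exactly the domain to be exposed next, the
toeholds sit at free 3' termini, and H2's d2* toehold cannot invade
H1's paired stem without a nucleation toehold, which is the metastability
that keeps the unreacted mixture dark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import folding
from .sequences import (
    RNA,
    DNA,
    Domain,
    SimilarityReport,
    Strand,
    gc_content,
    revcomp,
    similarity,
    validate_sequence,
)

logger = logging.getLogger(__name__)

#: Standard S. pyogenes single-guide scaffold (constant Cas9-binding segment).
DEFAULT_SCAFFOLD = (
    "GUUUUAGAGCUAGAAAUAGCAAGUUAAAAUAAGGCUAGUCCGUUAUCAACUUGAAAAAGUGGCACCGAGUCGGUGC"
)


class DesignInfeasibleError(ValueError):
    """Raised when no circuit satisfying the constraints can be produced."""


@dataclass(frozen=True)
class DesignParams:
    """Tunable design parameters.

    n1: trigger toehold length (nt); n3: length of the free domain d3;
    n_seed: inhibitor length = how many PAM-proximal spacer nt the cis
    inhibitor pairs (the gel-shift variants use 10/12/15); extension_end:
    which gRNA end carries the inhibitor (3' tolerated best by dCas9);
    linker_seq: unstructured spacer between scaffold and inhibitor;
    gc_bounds: GC fraction window for sampled d3; lcs_max: longest common
    substring tolerated between activator and trigger; max_attempts:
    rejection-sampling budget; rng_seed: seeds the d3 search.
    """

    n1: int = 8
    n3: int = 12
    n_seed: int = 12
    n_seed_choices: tuple[int, ...] = (10, 12, 15)
    extension_end: str = "3prime"
    linker_seq: str = "AACAA"
    gc_bounds: tuple[float, float] = (0.4, 0.6)
    lcs_max: int = 5
    max_attempts: int = 500
    rng_seed: int = 0
    spacer_len: int = 20
    max_homopolymer: int = 4

    def validate(self) -> None:
        if self.n1 < 4:
            raise ValueError("n1 (trigger toehold) must be >= 4 nt")
        if self.n3 < 6:
            raise ValueError("n3 (free domain) must be >= 6 nt")
        if self.n_seed > self.spacer_len:
            raise DesignInfeasibleError(
                f"n_seed={self.n_seed} exceeds spacer length {self.spacer_len}"
            )
        if self.n_seed_choices and self.n_seed not in self.n_seed_choices:
            raise ValueError(
                f"n_seed={self.n_seed} not in allowed set {self.n_seed_choices}"
            )
        if self.extension_end not in {"3prime", "5prime"}:
            raise ValueError("extension_end must be '3prime' or '5prime'")
        if self.lcs_max < 3:
            raise ValueError("lcs_max must be >= 3")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")
        lo, hi = self.gc_bounds
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("gc_bounds must satisfy 0 <= lo <= hi <= 1")


@dataclass(frozen=True)
class IntendedPair:
    """A declared duplex: ascending range on strand_a pairs the descending
    range on strand_b (antiparallel); ranges are 0-based half-open."""

    strand_a: str
    range_a: tuple[int, int]
    strand_b: str
    range_b: tuple[int, int]

    def expand(self) -> list[tuple[int, int]]:
        a0, a1 = self.range_a
        b0, b1 = self.range_b
        if a1 - a0 != b1 - b0:
            raise ValueError("intended-pair ranges differ in length")
        return [(a0 + k, b1 - 1 - k) for k in range(a1 - a0)]


@dataclass(frozen=True)
class CircuitSpec:
    """A complete designed system plus its intended base pairing."""

    trigger: Strand
    h1: Strand
    h2: Strand
    si_grna: Strand
    rep_f: Strand
    rep_q: Strand
    activator: Strand
    params: DesignParams
    intended_pairs: tuple[IntendedPair, ...]
    scaffold: str
    provenance: dict = field(default_factory=dict)
    warnings: tuple[str, ...] = ()

    @property
    def material(self) -> str:
        return self.trigger.material

    def domain(self, name: str) -> Domain:
        for strand in (self.trigger, self.h1, self.h2, self.si_grna):
            for d in strand.domains:
                if d.name == name:
                    return d
        raise KeyError(name)

    def strands(self) -> tuple[Strand, ...]:
        return (self.trigger, self.h1, self.h2, self.si_grna,
                self.rep_f, self.rep_q)

    def intra_strand_pairs(self, strand_name: str) -> set[tuple[int, int]]:
        """Intended (i, j) pairs internal to one strand."""
        out: set[tuple[int, int]] = set()
        for ip in self.intended_pairs:
            if ip.strand_a == strand_name and ip.strand_b == strand_name:
                out.update(ip.expand())
        return {(min(i, j), max(i, j)) for i, j in out}


def partition_trigger(trigger_seq: str, n1: int, material: str = RNA
                      ) -> tuple[Domain, Domain]:
    """Split the trigger into a 5' toehold d1 (n1 nt) and migration domain d2."""
    seq = validate_sequence(trigger_seq, material)
    if len(seq) < n1 + 6:
        raise DesignInfeasibleError(
            f"trigger of {len(seq)} nt too short: need at least n1+6 = {n1 + 6} nt"
        )
    return (
        Domain("d1", seq[:n1], role="toehold", material=material),
        Domain("d2", seq[n1:], role="migration", material=material),
    )


def derive_activator(spacer: str, n_seed: int, d3: Domain,
                     material: str = RNA) -> str:
    """Activator sequence d3.d4, with d4 = the 3'-terminal n_seed nt of the spacer.

    The 3' end of the spacer is PAM-proximal (the seed) and abuts the
    scaffold, which is what lets the cis inhibitor reach it.
    """
    sp = validate_sequence(spacer, material)
    if n_seed > len(sp):
        raise DesignInfeasibleError(
            f"n_seed={n_seed} exceeds spacer length {len(sp)}"
        )
    return d3.sequence + sp[len(sp) - n_seed:]


def build_hairpins(d1: Domain, d2: Domain, d3: Domain, d4: Domain
                   ) -> tuple[Strand, Strand]:
    """H1 = [d2][d3][d2*][d1*], H2 = [d3][d4][d3*][d2*] (stems + 3' toeholds)."""
    mats = {d.material for d in (d1, d2, d3, d4)}
    if len(mats) != 1:
        raise ValueError("hairpin domains must share one material")
    material = mats.pop()
    doms = (d1, d2, d3, d4)
    h1 = Strand("H1", material, ("d2", "d3", "d2*", "d1*"), doms)
    h2 = Strand("H2", material, ("d3", "d4", "d3*", "d2*"), doms)
    return h1, h2


def hairpin_intended_pairs(circuit_h1: Strand, circuit_h2: Strand
                           ) -> list[IntendedPair]:
    """Stem declarations for the two hairpins (d2:d2* and d3:d3*)."""
    out = []
    for strand, stem, star in ((circuit_h1, "d2", "d2*"), (circuit_h2, "d3", "d3*")):
        a = strand.segment(stem)
        b = strand.segment(star)
        out.append(IntendedPair(strand.name, a, strand.name, b))
    return out


def build_si_grna(spacer: str, scaffold: str, d3: Domain, d4: Domain,
                  params: DesignParams, material: str = RNA) -> Strand:
    """Self-inhibitory gRNA: guide + scaffold + linker + cis inhibitor.

    The inhibitor is revcomp(activator) = [d4*][d3*]: d4* pairs the spacer
    seed in cis and d3* stays single-stranded as the displacement toehold.
    For the default 3' extension the toehold is the 3' terminus; the 5'
    variant places the inhibitor upstream of the spacer, with the toehold
    adjacent to the linker.
    """
    sp = validate_sequence(spacer, material)
    doms = (
        Domain("spacer", sp, role="migration", material=material),
        Domain("scaffold", validate_sequence(scaffold, material),
               role="structural", material=material),
        Domain("linker", validate_sequence(params.linker_seq, material),
               role="structural", material=material),
        d3,
        d4,
    )
    if params.extension_end == "3prime":
        refs = ("spacer", "scaffold", "linker", "d4*", "d3*")
    else:
        refs = ("d4*", "d3*", "linker", "spacer", "scaffold")
    return Strand("SIgRNA", material, refs, doms, notes="self-inhibitory gRNA")


def si_grna_intended_pairs(si: Strand, n_seed: int) -> IntendedPair:
    """The cis seed:inhibitor duplex declaration on the SI-gRNA."""
    sp0, sp1 = si.segment("spacer")
    inh0, inh1 = si.segment("d4*")
    seed = (sp1 - n_seed, sp1)
    if inh0 < sp0:  # 5' extension: inhibitor upstream of the spacer
        return IntendedPair(si.name, (inh0, inh1), si.name, seed)
    return IntendedPair(si.name, seed, si.name, (inh0, inh1))


def build_reporter(d3: Domain, d4: Domain) -> tuple[Strand, Strand]:
    """Fluorophore strand RepF = [d4*][d3*], quencher strand RepQ = [d4].

    The annealed RepF:RepQ duplex pairs d4:d4* and leaves d3* single
    stranded, so the same activator that opens the SI-gRNA displaces RepQ.
    The assay anneals RepF:RepQ at a 1:1.5 ratio so every fluorophore
    strand starts quenched.
    """
    material = d3.material
    doms = (d3, d4)
    rep_f = Strand("RepF", material, ("d4*", "d3*"), doms, notes="fluorophore")
    rep_q = Strand("RepQ", material, ("d4",), doms, notes="quencher")
    return rep_f, rep_q


def independence_check(activator_seq: str, trigger_seq: str, lcs_max: int,
                       material: str = RNA) -> tuple[SimilarityReport, bool]:
    """Certify the activator shares no usable sequence with the trigger.

    Passes iff both the plain and the reverse-complement longest common
    substrings are <= lcs_max (no shared nucleation-length word).
    """
    rep = similarity(activator_seq, trigger_seq, material)
    return rep, rep.lcs_len <= lcs_max and rep.lcs_rc_len <= lcs_max


def _sample_d3(rng: np.random.Generator, params: DesignParams,
               material: str) -> str:
    alphabet = "ACGU" if material == RNA else "ACGT"
    lo, hi = params.gc_bounds
    while True:
        seq = "".join(rng.choice(list(alphabet), size=params.n3))
        if not (lo <= gc_content(seq) <= hi):
            continue
        if _max_homopolymer(seq) > params.max_homopolymer:
            continue
        return seq


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _masked_si_sequence(circuit_si: Strand) -> str:
    """SI-gRNA sequence with the scaffold masked out of the pairing check.

    The scaffold has its own essential Cas9-binding fold; whether it folds
    is Cas9's problem, not the circuit's, so it is excluded here.
    """
    seq = list(circuit_si.sequence)
    a, b = circuit_si.segment("scaffold")
    seq[a:b] = "N" * (b - a)
    return "".join(seq)


def verify_circuit_folding(circuit: CircuitSpec,
                           thresholds: folding.FoldThresholds = folding.FoldThresholds(),
                           ) -> dict[str, folding.FoldReport]:
    """Fold H1, H2 and the SI-gRNA and score stems/toeholds per strand."""
    reports: dict[str, folding.FoldReport] = {}
    for strand, toehold_ref in ((circuit.h1, "d1*"), (circuit.h2, "d2*")):
        a, b = strand.segment(toehold_ref)
        reports[strand.name] = folding.fold_report(
            strand.name,
            strand.sequence,
            circuit.intra_strand_pairs(strand.name),
            {toehold_ref: list(range(a, b))},
            thresholds,
        )
    si = circuit.si_grna
    a, b = si.segment("d3*")
    reports[si.name] = folding.fold_report(
        si.name,
        _masked_si_sequence(si),
        circuit.intra_strand_pairs(si.name),
        {"d3*": list(range(a, b))},
        thresholds,
    )
    return reports


def _crosstalk(circuit_domains: dict[str, str], trigger_seq: str,
               material: str, lcs_max: int) -> tuple[list[str], list[str]]:
    """Screen unintended duplex runs between co-existing accessible regions.

    Regions: the free trigger, the H1 toehold (d1*), the H2 toehold (d2*)
    and the shared SI-gRNA/reporter toehold (d3*).  Pairs involving the
    designer-chosen d3 are fatal (the search can resample d3); contacts
    fixed entirely by the user's trigger (d1* vs d2*) are reported as
    warnings only, since a toehold:toehold association has no adjacent
    stem to invade and is reversible.
    """
    d1s = revcomp(circuit_domains["d1"], material)
    d2s = revcomp(circuit_domains["d2"], material)
    d3s = revcomp(circuit_domains["d3"], material)
    fatal: list[str] = []
    warn: list[str] = []
    for name_a, seq_a, name_b, seq_b in (
        ("trigger", trigger_seq, "d3* toehold", d3s),
        ("d1* toehold", d1s, "d3* toehold", d3s),
        ("d2* toehold", d2s, "d3* toehold", d3s),
        ("d3* toehold", d3s, "d3* toehold", d3s),
    ):
        run = similarity(seq_a, seq_b, material).max_duplex_run
        if run >= lcs_max:
            fatal.append(f"{name_a} vs {name_b}: complementary run {run}")
    run = similarity(d1s, d2s, material).max_duplex_run
    if run >= lcs_max:
        warn.append(
            f"d1* toehold vs d2* toehold: complementary run {run} "
            "(trigger-intrinsic, unproductive association)"
        )
    return fatal, warn


def design_circuit(trigger_seq: str, spacer_seq: str,
                   params: DesignParams | None = None,
                   scaffold: str | None = None,
                   material: str | None = None) -> CircuitSpec:
    """Seeded rejection-sampling search for a complete valid circuit.

    Samples candidate free domains d3 until one passes (i) independence of
    activator and trigger, (ii) folding verification of both hairpins and
    the SI-gRNA cis-fold, (iii) the crosstalk screen.  Deterministic for a
    fixed (trigger, spacer, params, seed).
    """
    params = params or DesignParams()
    params.validate()
    if material is None:
        joint = (trigger_seq + spacer_seq).upper()
        material = DNA if "T" in joint and "U" not in joint else RNA
    if scaffold is None:
        scaffold = DEFAULT_SCAFFOLD if material == RNA else (
            DEFAULT_SCAFFOLD.replace("U", "T"))
        logger.info("using packaged standard Cas9 scaffold (%d nt)", len(scaffold))
    trigger_seq = validate_sequence(trigger_seq, material)
    spacer_seq = validate_sequence(spacer_seq, material)
    if len(spacer_seq) != params.spacer_len:
        raise DesignInfeasibleError(
            f"spacer must be {params.spacer_len} nt, got {len(spacer_seq)}"
        )

    d1, d2 = partition_trigger(trigger_seq, params.n1, material)
    d4 = Domain("d4", spacer_seq[len(spacer_seq) - params.n_seed:],
                role="output", material=material)
    rng = np.random.default_rng(params.rng_seed)
    histogram = {"independence": 0, "folding": 0, "crosstalk": 0}

    for attempt in range(1, params.max_attempts + 1):
        d3 = Domain("d3", _sample_d3(rng, params, material),
                    role="output", material=material)
        activator_seq = derive_activator(spacer_seq, params.n_seed, d3, material)
        _, indep_ok = independence_check(activator_seq, trigger_seq,
                                         params.lcs_max, material)
        if not indep_ok:
            histogram["independence"] += 1
            continue
        fatal, warn = _crosstalk(
            {"d1": d1.sequence, "d2": d2.sequence, "d3": d3.sequence},
            trigger_seq, material, params.lcs_max)
        if fatal:
            histogram["crosstalk"] += 1
            continue
        circuit = _assemble_circuit(trigger_seq, spacer_seq, scaffold,
                                    d1, d2, d3, d4, params, material,
                                    attempt, warn)
        reports = verify_circuit_folding(circuit)
        if not all(r.passed for r in reports.values()):
            histogram["folding"] += 1
            continue
        return circuit

    raise DesignInfeasibleError(
        f"no valid d3 found within {params.max_attempts} attempts; "
        f"rejections: {histogram}"
    )


def _assemble_circuit(trigger_seq: str, spacer_seq: str, scaffold: str,
                      d1: Domain, d2: Domain, d3: Domain, d4: Domain,
                      params: DesignParams, material: str,
                      attempts: int, warnings: list[str]) -> CircuitSpec:
    doms = (d1, d2, d3, d4)
    trigger = Strand("T", material, ("d1", "d2"), doms, notes="trigger")
    h1, h2 = build_hairpins(d1, d2, d3, d4)
    si = build_si_grna(spacer_seq, scaffold, d3, d4, params, material)
    rep_f, rep_q = build_reporter(d3, d4)
    activator = Strand("activator", material, ("d3", "d4"), doms,
                       notes="exposed output of opened H2 (tethered)")

    pairs: list[IntendedPair] = hairpin_intended_pairs(h1, h2)
    pairs.append(si_grna_intended_pairs(si, params.n_seed))
    # reporter duplex RepF:RepQ — d4 on RepQ pairs d4* on RepF
    pairs.append(IntendedPair("RepQ", rep_q.segment("d4"),
                              "RepF", rep_f.segment("d4*")))
    # trigger toehold on H1
    pairs.append(IntendedPair("T", (0, params.n1), "H1", h1.segment("d1*")))

    assert activator.sequence == d3.sequence + d4.sequence
    inh = revcomp(activator.sequence, material)
    si_seq = si.sequence
    assert inh in si_seq, "inhibitor must be revcomp(activator) and contiguous"

    return CircuitSpec(
        trigger=trigger, h1=h1, h2=h2, si_grna=si,
        rep_f=rep_f, rep_q=rep_q, activator=activator,
        params=params, intended_pairs=tuple(pairs), scaffold=scaffold,
        provenance={"rng_seed": params.rng_seed, "attempts": attempts},
        warnings=tuple(warnings),
    )
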