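# Methods

## Circuit grammar and committed architecture

The toolkit operates on named domains concatenated 5′→3′ into strands; a
starred reference means reverse complement within the same material
(stars never nest). RNA and DNA are both supported, and the only T↔U
bridge is an explicit transcription operation — sequences of different
materials never mix silently.

The two-hairpin joint is committed to one concrete layout:

| strand | 5′→3′ layout | structure |
|---|---|---|
| trigger T | `[1][2]` | single-stranded input |
| H1 | `[2][3][2*][1*]` | stem 2:2\*, loop 3, 3′ toehold 1\* |
| H2 | `[3][4][3*][2*]` | stem 3:3\*, loop 4, 3′ toehold 2\* |
| SI-gRNA | `[spacer][scaffold][linker][4*][3*]` | seed:4\* cis duplex, free 3′ toehold 3\* |
| RepF / RepQ | `[4*][3*]` / `[4]` | duplex 4:4\*, free toehold 3\* |

This layout was chosen because (a) opening H1 with the trigger exposes
exactly 2·3 and opening H2 exposes exactly 3·4; (b) H2's 2\* toehold faces
H1's *paired* stem, so the unreacted H1+H2 mixture is metastable — no
nucleation site exists until the trigger arrives; and (c) the activator
presents domain 3 at a free terminus, able to nucleate on the 3\*
toeholds of the SI-gRNA and the reporter. Domain 4 is defined as the
3′-terminal `n_seed` nucleotides of the 20-nt spacer: the PAM-proximal
seed, adjacent to the scaffold, which is what the cis inhibitor must
reach across the scaffold loop. The 3′ gRNA extension is the default
(dCas9 tolerates 3′ appendages better than 5′ ones); the 5′ variant is
constructible but places the displacement toehold internally, next to
the linker.

Default design parameters: trigger toehold `n1 = 8` nt, free domain
`n3 = 12` nt, inhibitor length `n_seed ∈ {10, 12, 15}` (default 12),
linker `AACAA`, candidate-d3 GC fraction in [0.4, 0.6] with homopolymer
runs ≤ 4, similarity ceiling `lcs_max = 5` nt, search budget 500
attempts. `lcs_max = 5` operationalizes "no sequence similarity" as "no
shared word of nucleation length or longer", the same length scale below
which a toehold cannot stably initiate displacement.

## Design search and acceptance rules

`design_circuit` rejection-samples d3 (seeded, deterministic) until a
candidate passes three gates:

1. **Independence** — longest common substring between activator (3·4)
   and trigger, both plain and against the reverse complement, ≤
   `lcs_max`. Because domain 4 is fixed by the user's spacer, a
   trigger/spacer pair whose seed shares a ≥6-mer with the trigger is
   genuinely infeasible and is reported as such with a rejection
   histogram rather than papered over.
2. **Crosstalk screen** — no complementary run ≥ `lcs_max` between
   co-existing accessible single-stranded regions for any pair the
   search can influence (the d3-derived toeholds against the trigger,
   the other toeholds, and themselves). Contacts fixed entirely by the
   user's trigger (the 1\* vs 2\* toeholds of H1 and H2) are logged as
   warnings instead: the designer cannot change them, and a
   toehold:toehold association has no adjacent stem to invade, so it is
   reversible sequestration rather than a displacement leak.
3. **Folding verification** — see below.

## Folding model

Structure checking uses base-pair maximization (Nussinov dynamic
programming) over Watson–Crick pairs, minimum loop 3, G·U off by default;
the traceback is deterministic (the leftmost base of each interval pairs
whenever pairing is optimal, most distal optimal partner first). An
exhaustive recursion over all nested pairings serves as the independent
oracle for sequences ≤ 20 nt. The scaffold is masked out of the SI-gRNA
check: its fold is Cas9's concern, not the circuit's.

Pair maximization has no stacking or loop-entropy terms, so its optima
are routinely decorated with isolated pairs and 2–4-bp helices that are
not thermodynamically stable at 37 °C, and a shifted-register helix can
outscore the intended stem by a single pair. Verification therefore
judges designs at the helix level: a competing helix "counts" only when
it reaches nucleation length (`sequester_helix_min = 5` stacked pairs,
matching `lcs_max`). A toehold base is accessible unless held in such a
helix, and an intended stem pair is recovered when predicted outright or
displaced only by sub-threshold competitors. Pass thresholds: intended
stem recovery ≥ 0.9 and toehold accessibility ≥ 0.8 per strand. These
thresholds and the helix-length rule are this package's choices; a full
nearest-neighbour energy backend could replace the pair-count model
behind the same `fold_report` contract.

## Kinetic model

The cascade is five irreversible mass-action reactions (R1–R4 plus an
optional H1+H2 leak, default rate 0); every displacement step consumes a
long toehold and leaves no reverse toehold, so reverse rates are
neglected. The activator stays tethered to the opened T:H1:H2 assembly,
so reporter displacement and SI-gRNA activation compete for assemblies
when both are present (the bench assays run them separately, as do the
default conditions). Rate constants follow the standard toehold-length
law: `k(n) = min(k_max, k_base·f^(min(n, n_sat)−1))` with
`k_max = 3×10⁶ M⁻¹s⁻¹`, `k_base = 10² M⁻¹s⁻¹` (the 1-nt rate),
`f = 10^0.7` per nucleotide, saturation at `n_sat = 7` nt; each
trigger–design mismatch multiplies the T+H1 rate by
`mismatch_factor = 10⁻²`. No rate constants were fitted to data — the
model's predictions are used only for qualitative patterns (gating,
ordering, saturation regime, conservation), never for absolute rates.

Integration uses LSODA (`scipy.integrate.solve_ivp`) at rtol 10⁻⁹ /
atol 10⁻¹³ M, tight enough that the per-strand mass-balance residual
stays below 10⁻⁶ relative at every sample. Each species carries a
per-strand composition vector, and every reaction is audited for strand
conservation before integration.

dCas9 binding is an equilibrium endpoint, not kinetics: the gel shift it
mirrors is a 10-min endpoint assay. With dCas9 in excess of DNA,
RNP ≈ min(activated gRNA, dCas9) and
`bound fraction = RNP/(K_d + RNP)` with `K_d = 10 nM`, clipped so bound
DNA never exceeds total DNA. Gel features such as multiple bound bands
are aggregated into this single fraction. Temperature (37 °C) is an
annotation only; there is no Arrhenius scaling.

Standard conditions shipped with the package: the fluorescence regime
(trigger/H1/H2 60 nM, RepF:RepQ 30 nM, 20-min endpoint, kinetic-mode
sampling) and the gel-shift regime (trigger and hairpins 2 µM, SI-gRNA
1 µM, 1-h activation, then dCas9 1 µM + DNA 100 nM).

## Synthetic fixtures: what they emulate and what they do not

`generate_fixtures` draws uniform-random trigger RNAs (14–30 nt by
default; the regression set uses fixed 22-mers) and 20-nt spacers with
GC in [0.3, 0.7], seeded and byte-reproducible. This emulates the
*length and composition* of miRNA/sRNA-class triggers, not their
biology: real cellular RNAs carry secondary structure, protein occupancy
and expression dynamics that uniform random sequences do not. Passing
the designer-soundness checks on these fixtures shows the search and its
certificates behave as specified on typical inputs; it does not
guarantee any particular natural RNA is a workable trigger (a strongly
self-structured trigger, or one sharing a ≥6-mer with the spacer seed,
is correctly reported infeasible).

## Numerical and reproducibility choices

All randomness flows through explicit integer seeds
(`numpy.random.Generator`); identical seeds give byte-identical circuit
documents and fixture files, which is why the circuit JSON omits
timestamps by default. Coordinates are 0-based half-open, sequences
5′→3′, concentrations molar internally (nM/µM accepted in configs with
unit suffixes), times in seconds. The Nussinov inner loop is compiled
with numba (a pure-Python fallback keeps the package importable without
it). Problem sizes used by the shipped checks — 100 design pairs, 500
oracle sequences per dynamic program, 201-point time grids — keep the
full suite and the acceptance script in the seconds-to-minutes range on
one CPU.

## Known limitations

* Pair-count folding cannot rank near-isoenergetic structures; the
  helix-length rule is a proxy for missing loop/stacking energetics.
* No partition function: "accessible" is a structural statement, not a
  probability.
* The rate law is literature-standard but uncalibrated; absolute times
  (e.g. the minutes-scale t₉₀) shift with `k_base` and `f`, though the
  qualitative patterns do not.
* In-cell behaviour (transcription, degradation, RNA chaperones,
  chromosomal context) is out of scope; the model describes the
  in-vitro assays only.
* No pseudoknots, no G·U pairs in the core algebra, no chemically
  modified nucleotides.
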