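"""Seeded generator of synthetic trigger/spacer fixtures.

Emulates the short trigger RNAs the circuit is meant to sense
(miRNA/sRNA-like, 14-30 nt) and 20-nt Cas9 spacers, with controllable GC
content.  Regeneration with the same seed is byte-identical, which is what
makes the whole toolkit testable without any download.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequences import RNA, DNA, gc_content


@dataclass(frozen=True)
class FixtureSet:
    """Synthetic triggers and spacers plus the manifest that regenerates them."""

    triggers: list[tuple[str, str]]
    spacers: list[tuple[str, str]]
    manifest: dict


def _draw(rng: np.random.Generator, length: int, gc_bounds: tuple[float, float],
          alphabet: str, max_tries: int = 10_000) -> str:
    lo, hi = gc_bounds
    for _ in range(max_tries):
        seq = "".join(rng.choice(list(alphabet), size=length))
        if lo <= gc_content(seq) <= hi:
            return seq
    raise ValueError(
        f"infeasible bounds: no {length}-mer with GC in [{lo}, {hi}] "
        f"after {max_tries} draws"
    )


def generate_fixtures(seed: int, n_triggers: int = 100, n_spacers: int = 100,
                      length_bounds: tuple[int, int] = (14, 30),
                      gc_bounds: tuple[float, float] = (0.3, 0.7),
                      spacer_len: int = 20,
                      material: str = RNA) -> FixtureSet:
    """Deterministic synthetic trigger RNAs and spacers.

    Trigger lengths are drawn uniformly from ``length_bounds`` (inclusive);
    all sequences satisfy ``gc_bounds``.
    """
    lo, hi = length_bounds
    if lo < 1 or hi < lo:
        raise ValueError(f"bad length bounds {length_bounds}")
    glo, ghi = gc_bounds
    if not (0.0 <= glo <= ghi <= 1.0):
        raise ValueError(f"bad GC bounds {gc_bounds}")
    alphabet = "ACGU" if material == RNA else "ACGT"
    rng = np.random.default_rng(seed)
    triggers = [
        (f"trigger_{k:03d}", _draw(rng, int(rng.integers(lo, hi + 1)),
                                   gc_bounds, alphabet))
        for k in range(n_triggers)
    ]
    spacers = [
        (f"spacer_{k:03d}", _draw(rng, spacer_len, gc_bounds, alphabet))
        for k in range(n_spacers)
    ]
    manifest = {
        "seed": seed, "n_triggers": n_triggers, "n_spacers": n_spacers,
        "length_bounds": list(length_bounds), "gc_bounds": list(gc_bounds),
        "spacer_len": spacer_len, "material": material,
    }
    return FixtureSet(triggers=triggers, spacers=spacers, manifest=manifest)


def write_fixture_set(fixtures: FixtureSet, outdir: str | Path) -> dict[str, Path]:
    """Write triggers.fa, spacers.fa and manifest.json under *outdir*."""
    import json

    from .io import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "triggers": outdir / "triggers.fa",
        "spacers": outdir / "spacers.fa",
        "manifest": outdir / "manifest.json",
    }
    write_fasta(fixtures.triggers, paths["triggers"])
    write_fasta(fixtures.spacers, paths["spacers"])
    paths["manifest"].write_text(
        json.dumps(fixtures.manifest, indent=2, sort_keys=True) + "\n")
    return paths
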