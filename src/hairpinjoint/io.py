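"""File formats: FASTA, circuit JSON documents, condition configs, tables.

Coordinates are 0-based half-open everywhere; sequences are stored 5'->3';
all computation is in molar (configs accept nM/uM and min/h with explicit
unit suffixes).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .design import CircuitSpec, DesignParams, IntendedPair
from .kinetics import Condition, NM, UM
from .sequences import Domain, Strand

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"


class FastaParseError(ValueError):
    """Malformed FASTA; message names the offending line."""


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Order-preserving FASTA parse to (id, uppercase sequence) pairs.

    Duplicate identifiers are rejected; mixed-case input is uppercased
    with a logged note; an empty file yields an empty list with a warning.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        logger.warning("empty FASTA file: %s", path)
        return []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected '>' header, got {line[:30]!r}"
                )
            break
    records = list(SeqIO.parse(str(path), "fasta"))
    seen: set[str] = set()
    out: list[tuple[str, str]] = []
    for rec in records:
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate identifier {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if seq != seq.upper():
            logger.info("uppercasing mixed-case record %s", rec.id)
        out.append((rec.id, seq.upper()))
    return out


def write_fasta(records: list[tuple[str, str]] | list[tuple[str, str, str]],
                path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns.

    Each record is (id, seq) or (id, seq, description).
    """
    seqrecords = []
    for rec in records:
        name, seq = rec[0], rec[1]
        desc = rec[2] if len(rec) > 2 else ""
        seqrecords.append(SeqRecord(Seq(seq), id=name, description=desc))
    SeqIO.write(seqrecords, str(path), "fasta")


def _strand_to_dict(strand: Strand) -> dict:
    return {
        "name": strand.name,
        "material": strand.material,
        "domain_refs": list(strand.domain_refs),
        "sequence": strand.sequence,
        "notes": strand.notes,
    }


def circuit_to_document(circuit: CircuitSpec, qc: dict | None = None,
                        timestamp: str | None = None) -> dict:
    """Serialize a circuit (plus optional QC block) to the JSON document schema.

    The timestamp is optional and omitted by default so that identical
    seeds yield byte-identical documents.
    """
    domains = {d.name: {"sequence": d.sequence, "role": d.role,
                        "material": d.material}
               for d in (circuit.trigger.domains + circuit.si_grna.domains)}
    doc = {
        "schema_version": SCHEMA_VERSION,
        "circuit": {
            "material": circuit.material,
            "domains": domains,
            "strands": [_strand_to_dict(s) for s in circuit.strands()],
            "activator": _strand_to_dict(circuit.activator),
            "scaffold": circuit.scaffold,
            "intended_pairs": [
                {"strand_a": p.strand_a, "range_a": list(p.range_a),
                 "strand_b": p.strand_b, "range_b": list(p.range_b)}
                for p in circuit.intended_pairs
            ],
            "warnings": list(circuit.warnings),
        },
        "params": asdict(circuit.params),
        "provenance": {
            "rng_seed": circuit.params.rng_seed,
            "attempts": circuit.provenance.get("attempts"),
            "tool_version": __version__,
        },
    }
    if qc is not None:
        doc["qc"] = qc
    if timestamp is not None:
        doc["provenance"]["timestamp"] = timestamp
    return doc


def document_to_circuit(doc: dict) -> CircuitSpec:
    """Rebuild a CircuitSpec from its JSON document (round-trip inverse)."""
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported circuit document schema {version!r}; this tool "
            f"reads schema {SCHEMA_VERSION} — regenerate or migrate the file"
        )
    c = doc["circuit"]
    raw_params = dict(doc["params"])
    for key in ("n_seed_choices", "gc_bounds"):
        if key in raw_params and isinstance(raw_params[key], list):
            raw_params[key] = tuple(raw_params[key])
    params = DesignParams(**raw_params)
    domains = {
        name: Domain(name, d["sequence"], role=d["role"], material=d["material"])
        for name, d in c["domains"].items()
    }

    def strand(payload: dict) -> Strand:
        refs = tuple(payload["domain_refs"])
        doms = tuple(domains[r.rstrip("*")] for r in refs)
        s = Strand(payload["name"], payload["material"], refs, doms,
                   notes=payload.get("notes", ""))
        if s.sequence != payload["sequence"]:
            raise ValueError(
                f"strand {s.name!r}: stored sequence disagrees with domains"
            )
        return s

    by_name = {p["name"]: strand(p) for p in c["strands"]}
    pairs = tuple(
        IntendedPair(p["strand_a"], tuple(p["range_a"]),
                     p["strand_b"], tuple(p["range_b"]))
        for p in c["intended_pairs"]
    )
    return CircuitSpec(
        trigger=by_name["T"], h1=by_name["H1"], h2=by_name["H2"],
        si_grna=by_name["SIgRNA"], rep_f=by_name["RepF"], rep_q=by_name["RepQ"],
        activator=strand(c["activator"]),
        params=params, intended_pairs=pairs, scaffold=c["scaffold"],
        provenance={"rng_seed": doc["provenance"].get("rng_seed"),
                    "attempts": doc["provenance"].get("attempts")},
        warnings=tuple(c.get("warnings", ())),
    )


def write_circuit(circuit: CircuitSpec, path: str | Path,
                  qc: dict | None = None) -> None:
    Path(path).write_text(
        json.dumps(circuit_to_document(circuit, qc), indent=2, sort_keys=True)
        + "\n")


def read_circuit(path: str | Path) -> CircuitSpec:
    return document_to_circuit(json.loads(Path(path).read_text()))


_UNIT_SCALE = {
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "nm": 1e-9, "pm": 1e-12,
    "s": 1.0, "sec": 1.0, "min": 60.0, "h": 3600.0, "hr": 3600.0,
}


def parse_quantity(value) -> float:
    """Parse '60 nM' / '20 min' / plain numbers into SI (molar / seconds)."""
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    parts = text.split()
    if len(parts) == 1:
        # allow '60nM'
        for unit in sorted(_UNIT_SCALE, key=len, reverse=True):
            low = text.lower()
            if low.endswith(unit) and low[: -len(unit)].strip():
                try:
                    return float(low[: -len(unit)]) * _UNIT_SCALE[unit]
                except ValueError:
                    continue
        return float(text)
    if len(parts) == 2:
        unit = parts[1].lower()
        if unit not in _UNIT_SCALE:
            raise ValueError(f"unknown unit {parts[1]!r} in {text!r}")
        return float(parts[0]) * _UNIT_SCALE[unit]
    raise ValueError(f"cannot parse quantity {text!r}")


def read_condition(path: str | Path) -> Condition:
    """Load a condition config (YAML mapping: strand -> concentration,
    plus t_end, optional n_samples and temperature_c)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    t_end = parse_quantity(raw.pop("t_end", "20 min"))
    n_samples = int(raw.pop("n_samples", 201))
    temp = float(raw.pop("temperature_c", 37.0))
    conc = {name: parse_quantity(v) for name, v in raw.items()}
    return Condition(concentrations=conc, t_end=t_end, n_samples=n_samples,
                     temperature_c=temp)


def circuit_fasta_records(circuit: CircuitSpec) -> list[tuple[str, str, str]]:
    """All designed strands as FASTA records with role annotations."""
    out = []
    for s in circuit.strands() + (circuit.activator,):
        role = s.notes or "designed strand"
        out.append((s.name, s.sequence,
                    f"{role} | domains={'.'.join(s.domain_refs)}"))
    return out
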