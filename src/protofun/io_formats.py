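"""File formats and run configuration.

Reads FASTA cohorts (Bio.SeqIO), protein-to-GO annotation tables (TSV,
one ``protein_id<TAB>go_id`` pair per row) and writes prediction tables
(``protein_id<TAB>go_id<TAB>score``).  Holds the run configuration with
every documented default.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO

from ._aadata import ALPHABET, NONCANONICAL_MAP

logger = logging.getLogger("protofun")

SCORE_DECIMALS = 3  # prediction TSV precision; diff-stable CAFA-style output


class FormatError(ValueError):
    """Raised for malformed or invariant-violating input files."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus its sanitized amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise FormatError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise FormatError(
                f"protein {self.id!r}: non-canonical residues {sorted(bad)}"
            )


def sanitize_sequence(seq: str, policy: str = "map") -> str:
    """Map or drop non-canonical residues.

    policy="map": B->D, Z->E, J->L, U->C, O->K, X dropped (the descriptor
    property tables cover only the 20 canonical letters).
    policy="drop": every non-canonical residue dropped.
    """
    if policy not in ("map", "drop"):
        raise ValueError(f"unknown residue policy {policy!r}")
    out = []
    for ch in seq.upper():
        if ch in ALPHABET:
            out.append(ch)
        elif ch in ("*", "-", ".", " "):
            continue
        elif policy == "map" and ch in NONCANONICAL_MAP:
            out.append(NONCANONICAL_MAP[ch])
        elif ch == "X" or policy == "drop":
            continue
        else:
            raise FormatError(f"unrecognized residue {ch!r}")
    return "".join(out)


def read_fasta(path: str | Path, residue_policy: str = "map") -> list[ProteinRecord]:
    """Read a FASTA cohort; ids are headers up to the first whitespace."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        seq = sanitize_sequence(str(rec.seq), residue_policy)
        records.append(ProteinRecord(rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[ProteinRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


@dataclass
class AnnotationTable:
    """A set of (protein id, GO term id) pairs; the ground-truth label sets."""

    pairs: set[tuple[str, str]]
    propagated: bool = False

    def terms_of(self, protein_id: str) -> set[str]:
        return {t for p, t in self.pairs if p == protein_id}

    def by_protein(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for p, t in self.pairs:
            out.setdefault(p, set()).add(t)
        return out


def read_annotations(path: str | Path, ontology=None) -> AnnotationTable:
    """Read a protein->GO TSV; rejects terms absent from *ontology*."""
    pairs: set[tuple[str, str]] = set()
    unknown: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise FormatError(f"{path}:{lineno}: malformed row {line!r}")
            pid, term = fields
            if ontology is not None and term not in ontology.terms:
                unknown.append((lineno, term))
                continue
            pairs.add((pid, term))
    if unknown:
        listed = ", ".join(f"{t} (line {ln})" for ln, t in unknown[:10])
        raise FormatError(f"{path}: unknown GO terms: {listed}")
    if not pairs:
        warnings.warn(f"{path}: empty annotation table")
    return AnnotationTable(pairs=pairs, propagated=False)


def write_annotations(path: str | Path, table: AnnotationTable) -> None:
    with open(path, "w") as fh:
        for pid, term in sorted(table.pairs):
            fh.write(f"{pid}\t{term}\n")


def write_predictions(path: str | Path, scores: dict[str, dict[str, float]]) -> None:
    """Write per-protein term scores, sorted by protein then descending score.

    Scores are rounded to 3 decimals; rows round-trip bit-identically
    through :func:`read_predictions` at that precision.
    """
    with open(path, "w") as fh:
        fh.write("protein_id\tgo_id\tscore\n")
        for pid in sorted(scores):
            terms = scores[pid]
            for term, s in sorted(terms.items(), key=lambda kv: (-kv[1], kv[0])):
                if not (0.0 <= s <= 1.0):
                    raise FormatError(
                        f"score {s} for ({pid}, {term}) outside [0, 1]"
                    )
                fh.write(f"{pid}\t{term}\t{s:.{SCORE_DECIMALS}f}\n")


def read_predictions(path: str | Path) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein_id"):
            raise FormatError(f"{path}: missing prediction header")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: malformed row {line!r}")
            pid, term, s = fields
            out.setdefault(pid, {})[term] = float(s)
    return out


@dataclass
class RunConfig:
    """Run-level configuration with documented defaults.

    Defaults equal the study's stated values wherever one exists: square
    grid side derived from the feature count (39 for the default 1,484
    descriptors), 80/20 train/validation split, family selection strictly
    above 50 proteins, head/tail average-count cutoff 2,000 inclusive.
    """

    reduction_method: str = "pca"  # {"pca", "umap"}
    grid_side: int | None = None  # None -> ceil(sqrt(n_features))
    seed: int = 0
    residue_policy: str = "map"
    family_min_count: int = 50  # strict > (terms need more than this)
    head_tail_anp_cutoff: float = 2000.0  # inclusive (>= is head)
    train_fraction: float = 0.8
    validation_fraction: float = 0.2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise FormatError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
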