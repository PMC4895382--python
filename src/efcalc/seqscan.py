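"""Canonical EF-hand calcium-binding loop detection from protein sequence.

An EF hand coordinates a single Ca2+ ion in a pentagonal bipyramid through
a 12-residue loop. Six loop positions contribute ligands and are labelled by
the coordination axis they occupy: X (position 1), Y (3), Z (5), -Y (7),
-X (9) and -Z (12). Position 7 coordinates through its backbone carbonyl
(any residue can do this), position 9 usually through a hydrogen-bonded
water, and position 12 supplies the invariant bidentate Glu/Asp. The
scanner classifies 12-residue windows against per-position allowed-residue
rules and reports which coordination positions fail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from Bio import SeqIO

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: coordination-position label -> 1-based loop position
POSITION_LABELS = {"X": 1, "Y": 3, "Z": 5, "-Y": 7, "-X": 9, "-Z": 12}
LOOP_LENGTH = 12


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with author residue numbering.

    ``numbering_offset`` is the author residue number of string index 0
    (e.g. 743 for the alpha-actinin-1 calmodulin-like-domain construct),
    so author number = index + offset.
    """

    id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        bad = set(self.residues) - AMINO_ACIDS - {"X"}
        if bad:
            raise ValueError(f"non-standard residue codes in {self.id!r}: {sorted(bad)}")

    def author_number(self, index: int) -> int:
        return index + self.numbering_offset

    def index_of(self, author_number: int) -> int:
        return author_number - self.numbering_offset


@dataclass(frozen=True)
class CoordinationRuleSet:
    """Allowed residues per coordination position of the 12-residue EF loop.

    ``allowed`` maps position label (X, Y, Z, -Y, -X, -Z) to the set of
    one-letter codes accepted there; ``None`` means the position is
    sequence-permissive (it coordinates through backbone or water, so any
    residue passes), while an empty set admits nothing. The bidentate -Z
    position is restricted to Glu/Asp.
    """

    allowed: dict[str, frozenset[str] | None] = field(
        default_factory=lambda: {
            "X": frozenset("D"),
            "Y": frozenset("DNS"),
            "Z": frozenset("DNST"),
            "-Y": None,  # backbone carbonyl coordinates: permissive
            "-X": frozenset("STDNEGQ"),  # water-mediated: permissive set
            "-Z": frozenset("ED"),
        }
    )

    def __post_init__(self) -> None:
        unknown = set(self.allowed) - set(POSITION_LABELS)
        if unknown:
            raise ValueError(f"unknown coordination positions: {sorted(unknown)}")
        minus_z = self.allowed.get("-Z")
        if minus_z is None or not minus_z <= frozenset("ED"):
            raise ValueError("-Z (position 12) must be a subset of {E, D}")

    def passes(self, label: str, residue: str) -> bool:
        allowed = self.allowed[label]
        if allowed is None:  # sequence-permissive position
            return residue != "X"
        return residue in allowed

    @classmethod
    def strict_position7(cls) -> "CoordinationRuleSet":
        """Profile requiring small residues at the backbone-coordinating -Y."""
        base = cls()
        allowed = dict(base.allowed)
        allowed["-Y"] = frozenset("GASTKRQ")
        return cls(allowed=allowed)

    @classmethod
    def from_config(cls, path) -> "CoordinationRuleSet":
        """Read per-position rules from a plain-text config.

        Format: one line per position, ``label: residues`` (e.g. ``X: D``);
        ``*`` or an empty residue list marks a permissive position. Lines
        starting with ``#`` are ignored; omitted positions keep defaults.
        """
        allowed = dict(cls().allowed)
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                label, _, residues = line.partition(":")
                label = label.strip()
                residues = residues.strip().replace(",", "").replace(" ", "")
                if label not in POSITION_LABELS:
                    raise ValueError(f"unknown position label {label!r} in {path}")
                allowed[label] = None if residues in ("", "*") else frozenset(residues)
        return cls(allowed=allowed)


@dataclass(frozen=True)
class EFHandHit:
    """A candidate 12-residue EF loop with per-position canonical calls."""

    record_id: str
    loop_start: int  # author residue number of loop position 1
    loop_sequence: str
    position_calls: dict[str, tuple[bool, str]]  # label -> (passes, residue)
    canonical: bool
    failed_positions: tuple[str, ...]

    def __post_init__(self) -> None:
        assert len(self.loop_sequence) == LOOP_LENGTH
        assert self.canonical == (len(self.failed_positions) == 0)


def _evaluate_window(record: SequenceRecord, start_index: int,
                     rules: CoordinationRuleSet) -> EFHandHit:
    loop = record.residues[start_index:start_index + LOOP_LENGTH]
    calls: dict[str, tuple[bool, str]] = {}
    failed: list[str] = []
    for label, pos in POSITION_LABELS.items():
        residue = loop[pos - 1]
        ok = rules.passes(label, residue)
        calls[label] = (ok, residue)
        if not ok:
            failed.append(label)
    return EFHandHit(
        record_id=record.id,
        loop_start=record.author_number(start_index),
        loop_sequence=loop,
        position_calls=calls,
        canonical=not failed,
        failed_positions=tuple(failed),
    )


def scan_sequence(record: SequenceRecord,
                  rules: CoordinationRuleSet | None = None,
                  mode: str = "window",
                  annotations: list[int] | None = None) -> list[EFHandHit]:
    """Scan a sequence for EF-hand loops.

    Parameters
    ----------
    record
        Sequence with author numbering.
    rules
        Coordination rules; default canonical profile if omitted.
    mode
        ``"window"`` evaluates every 12-residue window whose first residue
        passes the X rule (overlaps all reported, ordered by start).
        ``"annotated"`` evaluates exactly the provided loop starts.
    annotations
        Author residue numbers of loop position 1 (annotated mode only).
    """
    rules = rules or CoordinationRuleSet()
    if not record.residues:
        raise ValueError("empty sequence")
    if len(record.residues) < LOOP_LENGTH:
        raise ValueError(f"sequence shorter than the {LOOP_LENGTH}-residue EF loop")

    if mode == "annotated":
        if not annotations:
            raise ValueError("annotated mode requires loop start positions")
        hits = []
        for start in sorted(annotations):
            idx = record.index_of(start)
            if idx < 0 or idx + LOOP_LENGTH > len(record.residues):
                raise IndexError(
                    f"annotated loop start {start} out of range for {record.id!r}")
            hits.append(_evaluate_window(record, idx, rules))
        return hits
    if mode != "window":
        raise ValueError(f"unknown scan mode {mode!r}")

    if len(record.residues) == LOOP_LENGTH:
        # degenerate input: exactly one window, evaluated unconditionally
        return [_evaluate_window(record, 0, rules)]
    hits = []
    for idx in range(len(record.residues) - LOOP_LENGTH + 1):
        if rules.passes("X", record.residues[idx]):
            hits.append(_evaluate_window(record, idx, rules))
    return hits


def classify_ef_hands(hits: list[EFHandHit]) -> dict:
    """Summarise canonical vs degenerate calls over a hit list."""
    canonical = [h for h in hits if h.canonical]
    degenerate = [h for h in hits if not h.canonical]
    return {
        "count_canonical": len(canonical),
        "count_degenerate": len(degenerate),
        "canonical_loops": [(h.record_id, h.loop_start) for h in canonical],
        "degenerate_loops": [
            {
                "record_id": h.record_id,
                "loop_start": h.loop_start,
                "failed_positions": list(h.failed_positions),
            }
            for h in degenerate
        ],
    }


def read_fasta(path, numbering_offsets: dict[str, int] | None = None) -> list[SequenceRecord]:
    offsets = numbering_offsets or {}
    return [
        SequenceRecord(id=rec.id, residues=str(rec.seq).upper(),
                       numbering_offset=offsets.get(rec.id, 1))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_annotations(path) -> dict[str, list[int]]:
    """TSV of (record_id, loop_start) pairs -> starts per record."""
    ann: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            record_id, start = line.split("\t")[:2]
            ann.setdefault(record_id, []).append(int(start))
    return ann


def report_tsv(hits: list[EFHandHit]) -> str:
    lines = ["record_id\tloop_start\tloop_sequence\tcanonical\tfailed_positions"]
    for h in hits:
        lines.append("\t".join([
            h.record_id, str(h.loop_start), h.loop_sequence,
            str(h.canonical).lower(), ",".join(h.failed_positions),
        ]))
    return "\n".join(lines) + "\n"


def report_json(hits: list[EFHandHit]) -> str:
    payload = [
        {
            "record_id": h.record_id,
            "loop_start": h.loop_start,
            "loop_sequence": h.loop_sequence,
            "canonical": h.canonical,
            "failed_positions": list(h.failed_positions),
            "position_calls": {k: {"pass": v[0], "residue": v[1]}
                               for k, v in h.position_calls.items()},
        }
        for h in hits
    ]
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"
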