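"""Prohormone precursor sequences and their annotated bioactive-peptide features.

A precursor is the full translation product (signal peptide included) from
which bioactive peptides are excised by proteolysis.  Coordinates follow the
UniProt convention throughout: 1-based, inclusive on both ends.  Cleavage
boundaries, by contrast, are between-residue indices ``0..L`` (boundary ``b``
sits between residues ``b`` and ``b+1``), which keeps window arithmetic
around cleavage sites unambiguous.

The bundled fixture registry contains the human proglucagon precursor
(P01275) plus seven constructed stand-in prohormones (see
``data/synthetic_prohormones.fasta``); the stand-ins are synthetic sequences
with realistic processing topology, not database entries.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical 20-letter amino-acid alphabet.
ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Symbol used for window positions that fall outside the precursor.
GAP = "-"

FEATURE_KINDS = frozenset({"signal", "propeptide", "chain", "peptide"})


class PrecursorError(ValueError):
    """Malformed precursor input (FASTA or feature table)."""


@dataclass(frozen=True)
class PeptideFeature:
    """An annotated region of a precursor (UniProt chain/peptide style).

    ``start``/``end`` are 1-based inclusive.  ``amidated`` marks features
    whose mature form carries a C-terminal amide (derived from a precursor
    glycine at ``end + 1``).
    """

    name: str
    start: int
    end: int
    kind: str = "peptide"
    amidated: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise PrecursorError(
                f"feature {self.name!r}: require 1 <= start <= end, "
                f"got start={self.start}, end={self.end}"
            )
        if self.kind not in FEATURE_KINDS:
            raise PrecursorError(f"feature {self.name!r}: unknown kind {self.kind!r}")


@dataclass
class PrecursorRecord:
    """A prohormone sequence with its peptide features."""

    accession: str
    gene_symbol: str
    sequence: str
    features: list[PeptideFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise PrecursorError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise PrecursorError(
                f"{self.accession}: non-amino-acid characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def subsequence(self, start: int, end: int) -> str:
        """Residues ``start..end`` (1-based inclusive)."""
        if not (1 <= start <= end <= len(self)):
            raise PrecursorError(
                f"{self.accession}: coordinates {start}..{end} outside 1..{len(self)}"
            )
        return self.sequence[start - 1 : end]

    def add_feature(self, feature: PeptideFeature) -> None:
        if feature.end > len(self):
            raise PrecursorError(
                f"{self.accession}: feature {feature.name!r} end {feature.end} "
                f"exceeds sequence length {len(self)}"
            )
        self.features.append(feature)

    def signal_end(self) -> int:
        """End position of the annotated signal peptide, or 0 if none."""
        for f in self.features:
            if f.kind == "signal":
                return f.end
        return 0


class PrecursorRegistry:
    """Accession-indexed collection of :class:`PrecursorRecord`."""

    def __init__(self) -> None:
        self._records: dict[str, PrecursorRecord] = {}

    def add(self, record: PrecursorRecord) -> None:
        if record.accession in self._records:
            raise PrecursorError(f"duplicate accession {record.accession!r}")
        self._records[record.accession] = record

    def __getitem__(self, accession: str) -> PrecursorRecord:
        return self._records[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self._records

    def __iter__(self):
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    @property
    def accessions(self) -> list[str]:
        return list(self._records)

    def locate(self, peptide: str) -> list[tuple[str, int, int]]:
        """All exact occurrences of ``peptide`` across the registry.

        Returns ``(accession, start, end)`` triples (1-based inclusive),
        including overlapping occurrences within one precursor.
        """
        hits: list[tuple[str, int, int]] = []
        for rec in self:
            pos = rec.sequence.find(peptide)
            while pos != -1:
                hits.append((rec.accession, pos + 1, pos + len(peptide)))
                pos = rec.sequence.find(peptide, pos + 1)
        return hits


def load_precursor_fasta(path: str | Path, registry: PrecursorRegistry | None = None) -> PrecursorRegistry:
    """Load precursors from FASTA into a registry.

    Header dialect: ``>ACCESSION|GENE optional description``.  Sequences are
    uppercased and validated against the 20-letter alphabet; duplicate
    accessions are rejected.
    """
    registry = registry if registry is not None else PrecursorRegistry()
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        ident = rec.id
        if "|" in ident:
            accession, gene = ident.split("|", 1)
        else:
            accession, gene = ident, ident
        if not accession:
            raise PrecursorError(f"FASTA record with empty accession: {rec.description!r}")
        try:
            registry.add(PrecursorRecord(accession, gene, str(rec.seq)))
        except PrecursorError:
            raise
        n += 1
    if n == 0:
        logger.warning("no FASTA records found in %s", path)
    return registry


def load_feature_table(path: str | Path, registry: PrecursorRegistry) -> dict[str, int]:
    """Attach features from a TSV (accession, name, start, end, kind, amidated).

    Rows referencing accessions absent from the registry are skipped and
    counted.  Returns a small report dict with ``attached`` and ``skipped``
    counts.
    """
    required = ["accession", "name", "start", "end", "kind", "amidated"]
    attached = skipped = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or any(c not in reader.fieldnames for c in required):
            raise PrecursorError(
                f"feature table {path}: required columns {required}, "
                f"found {reader.fieldnames}"
            )
        for row in reader:
            acc = row["accession"]
            if acc not in registry:
                skipped += 1
                logger.warning("feature row for unknown accession %r skipped", acc)
                continue
            feature = PeptideFeature(
                name=row["name"],
                start=int(row["start"]),
                end=int(row["end"]),
                kind=row["kind"],
                amidated=row["amidated"].strip().lower() in {"true", "1", "yes"},
            )
            registry[acc].add_feature(feature)
            attached += 1
    return {"attached": attached, "skipped": skipped}


def amidation_valid(precursor: PrecursorRecord, last_residue_pos: int) -> bool:
    """Whether an amidated C terminus at ``last_residue_pos`` is chemically possible.

    A C-terminal amide is donated by a precursor glycine: the residue
    immediately after the amidated terminus must exist and be ``G``.  At the
    precursor C terminus there is no successor, so the answer is False.
    """
    if not (1 <= last_residue_pos <= len(precursor)):
        raise PrecursorError(
            f"{precursor.accession}: position {last_residue_pos} outside 1..{len(precursor)}"
        )
    if last_residue_pos == len(precursor):
        return False
    return precursor.sequence[last_residue_pos] == "G"


@dataclass(frozen=True)
class TerminusContext:
    """The residues flanking one cleavage boundary.

    ``residues`` holds ``2 * flank`` characters for positions
    ``-flank..-1, +1..+flank`` left to right; out-of-range positions carry
    :data:`GAP`.  Position -1/-2 correspond to Schechter–Berger P1/P2 and
    +1/+2 to P1'/P2'.
    """

    accession: str
    boundary: int
    residues: str
    terminus: str = ""  # "N" or "C" when derived from a peptide terminus

    @property
    def flank(self) -> int:
        return len(self.residues) // 2

    def at(self, position: int) -> str:
        """Residue at a signed position (-flank..-1, +1..+flank)."""
        f = self.flank
        if not (-f <= position <= f) or position == 0:
            raise ValueError(f"position {position} outside -{f}..-1,+1..+{f}")
        idx = position + f if position < 0 else position + f - 1
        return self.residues[idx]

    @property
    def key(self) -> str:
        return self.residues


def window(precursor: PrecursorRecord, boundary: int, flank: int = 4,
           terminus: str = "") -> TerminusContext:
    """Extract the ``2*flank`` residue context around a cleavage boundary.

    ``boundary`` is a between-residue index in ``0..L``.  Positions beyond
    the sequence ends are filled with :data:`GAP`.
    """
    if flank < 1:
        raise PrecursorError(f"flank must be >= 1, got {flank}")
    L = len(precursor)
    if not (0 <= boundary <= L):
        raise PrecursorError(
            f"{precursor.accession}: boundary {boundary} outside 0..{L}"
        )
    seq = precursor.sequence
    left = seq[max(0, boundary - flank) : boundary].rjust(flank, GAP)
    right = seq[boundary : boundary + flank].ljust(flank, GAP)
    return TerminusContext(precursor.accession, boundary, left + right, terminus)


def bundled_registry(include_synthetic: bool = True) -> PrecursorRegistry:
    """The fixture registry shipped with the package.

    Always contains the P01275 proglucagon precursor; with
    ``include_synthetic`` (default) also the seven synthetic stand-in
    prohormones.
    """
    data = resources.files("enteropep") / "data"
    registry = load_precursor_fasta(str(data / "proglucagon.fasta"))
    load_feature_table(str(data / "proglucagon_features.tsv"), registry)
    if include_synthetic:
        load_precursor_fasta(str(data / "synthetic_prohormones.fasta"), registry)
        load_feature_table(str(data / "synthetic_prohormone_features.tsv"), registry)
    return registry
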