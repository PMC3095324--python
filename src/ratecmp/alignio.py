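"""Codon alignment I/O and column filtering.

A :class:`CodonAlignment` is the unit of per-locus computation: an aligned
set of coding sequences (gap character ``-``, ambiguity ``N``) with one
species label per record.  Species labels come either from a
``record_id|species`` FASTA header convention or from a sidecar mapping
(TSV: ``record_id<TAB>species``).

The column filter :func:`complete_deletion` implements the classic
"complete deletion" rule: every alignment column (or codon column) that
contains a gap or missing datum in *any* record is removed before distances
are computed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlignmentError",
    "CodonAlignment",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_species_map",
    "complete_deletion",
    "concatenate",
]

VALID_CHARS = frozenset("ACGTN-")


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignments."""


@dataclass
class CodonAlignment:
    """An aligned set of coding sequences with species labels.

    Parameters
    ----------
    locus_id : str
        Identifier of the locus (gene or clade).
    records : list of (record_id, species, sequence)
        Sequences over the alphabet ``{A, C, G, T, N, -}``, all of equal
        length.  A species may contribute several records (paralogs).
    boundaries : list of (locus_id, start, end), optional
        Per-locus column blocks, populated by :func:`concatenate`.
    """

    locus_id: str
    records: list[tuple[str, str, str]]
    boundaries: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError(f"{self.locus_id}: alignment has no records")
        lengths = {len(seq) for _, _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.locus_id}: unequal sequence lengths {sorted(lengths)}"
            )
        for rid, _, seq in self.records:
            bad = set(seq.upper()) - VALID_CHARS
            if bad:
                raise AlignmentError(f"{self.locus_id}/{rid}: invalid characters {bad}")

    def __len__(self) -> int:
        return len(self.records[0][2])

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def species(self) -> list[str]:
        """Distinct species labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for _, sp, _ in self.records:
            seen.setdefault(sp)
        return list(seen)

    @property
    def n_codons(self) -> int:
        if len(self) % 3:
            raise AlignmentError(f"{self.locus_id}: length {len(self)} not codon-framed")
        return len(self) // 3

    def sequences_for(self, species: str) -> list[str]:
        """All sequences (paralogs included) labelled with *species*."""
        return [seq for _, sp, seq in self.records if sp == species]

    def subset(self, species: Iterable[str]) -> "CodonAlignment":
        """Restrict to records whose species label is in *species*."""
        keep = set(species)
        recs = [r for r in self.records if r[1] in keep]
        missing = keep - {r[1] for r in recs}
        if missing:
            raise AlignmentError(f"{self.locus_id}: species missing {sorted(missing)}")
        return CodonAlignment(self.locus_id, recs)


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read a sidecar TSV mapping ``record_id -> species``."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rid, _, sp = line.partition("\t")
        if not sp:
            raise AlignmentError(f"species map line without tab: {line!r}")
        mapping[rid] = sp.strip()
    return mapping


def _label(record_id: str, species_map: Mapping[str, str] | None) -> tuple[str, str]:
    if species_map is not None:
        if record_id not in species_map:
            raise AlignmentError(f"record {record_id!r} missing from species map")
        return record_id, species_map[record_id]
    if "|" in record_id:
        rid, _, sp = record_id.rpartition("|")
        return rid, sp
    raise AlignmentError(
        f"record {record_id!r} has no '|species' suffix and no species map given"
    )


def read_fasta_alignment(
    path: str | Path | io.TextIOBase,
    species_map: Mapping[str, str] | None = None,
    locus_id: str | None = None,
) -> CodonAlignment:
    """Read an aligned FASTA file into a :class:`CodonAlignment`.

    Species labels are taken from *species_map* when given, otherwise parsed
    from a ``record_id|species`` header convention.
    """
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        rid, sp = _label(rec.id, species_map)
        records.append((rid, sp, str(rec.seq).upper()))
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    if locus_id is None:
        locus_id = Path(path).stem if isinstance(path, (str, Path)) else "locus"
    return CodonAlignment(locus_id, records)


def write_fasta_alignment(aln: CodonAlignment, path: str | Path) -> None:
    """Write records as FASTA with ``record_id|species`` headers."""
    recs = [
        SeqRecord(Seq(seq), id=f"{rid}|{sp}", description="")
        for rid, sp, seq in aln.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def complete_deletion(
    aln: CodonAlignment, unit: Literal["nucleotide", "codon"] = "nucleotide"
) -> CodonAlignment:
    """Remove every column containing a gap or missing datum in any record.

    With ``unit="codon"`` a whole codon column is dropped if any of its three
    positions carries ``-`` or ``N`` in any record; the alignment must be
    codon-framed in that case.  Idempotent; may return a zero-length
    alignment (a single empty column set), in which case the result has
    length 0.
    """
    seqs = [seq for _, _, seq in aln.records]
    length = len(aln)
    if unit == "codon":
        n_codons = aln.n_codons
        keep_codons = [
            c
            for c in range(n_codons)
            if not any(
                seq[3 * c + k] in "N-" for seq in seqs for k in range(3)
            )
        ]
        cols = [3 * c + k for c in keep_codons for k in range(3)]
    elif unit == "nucleotide":
        cols = [
            j for j in range(length) if not any(seq[j] in "N-" for seq in seqs)
        ]
    else:
        raise ValueError(f"unknown deletion unit {unit!r}")
    records = [
        (rid, sp, "".join(seq[j] for j in cols)) for rid, sp, seq in aln.records
    ]
    return CodonAlignment(aln.locus_id, records)


def concatenate(
    loci: Sequence[CodonAlignment], species_order: Sequence[str]
) -> CodonAlignment:
    """Concatenate per-locus alignments into one matrix, one row per species.

    Every locus must carry exactly one record per species in *species_order*
    (resolve paralogs upstream).  Per-locus column blocks are recorded in
    ``boundaries``.
    """
    if not loci:
        raise AlignmentError("nothing to concatenate")
    parts: dict[str, list[str]] = {sp: [] for sp in species_order}
    boundaries = []
    offset = 0
    for aln in loci:
        by_species: dict[str, list[str]] = {}
        for _, sp, seq in aln.records:
            by_species.setdefault(sp, []).append(seq)
        for sp in species_order:
            if sp not in by_species:
                raise AlignmentError(f"{aln.locus_id}: missing species {sp!r}")
            if len(by_species[sp]) > 1:
                raise AlignmentError(
                    f"{aln.locus_id}: species {sp!r} has "
                    f"{len(by_species[sp])} paralogous records; resolve first"
                )
            parts[sp].append(by_species[sp][0])
        boundaries.append((aln.locus_id, offset, offset + len(aln)))
        offset += len(aln)
    records = [(sp, sp, "".join(parts[sp])) for sp in species_order]
    out = CodonAlignment("concatenated", records, boundaries=boundaries)
    return out
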