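"""Core data model for circular mitochondrial genomes and gapped alignments.

Provides the sequence/annotation containers used by every downstream analysis:
:class:`CircularGenome`, :class:`GeneAnnotation`, :class:`Msa`, FASTA and
annotation I/O, circular-coordinate arithmetic, and anchor-based rotation of
circular genomes to a common start point.

All user-facing coordinates are 1-based inclusive.  Wrap-around intervals on a
circular genome are written ``start > end`` and are never represented by
duplicating sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
GAP = "-"
ALIGNED_ALPHABET = DNA_ALPHABET | {GAP}
GENE_GROUPS = ("ND", "COX", "ATP", "tRNA", "rRNA", "CR", "intergenic")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Malformed or empty input file."""


class AlignmentShapeError(ValueError):
    """Ragged alignment: gapped sequences differ in length."""


class AnchorNotFoundError(ValueError):
    """Rotation anchor absent from the genome and its reverse complement."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularGenome:
    """An (optionally circular) DNA sequence over {A,C,G,T,N}."""

    id: str
    sequence: str
    is_circular: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if len(self.sequence) == 0:
            raise ValueError(f"genome {self.id!r} is empty")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(f"genome {self.id!r} has non-DNA characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "CircularGenome":
        return CircularGenome(self.id, reverse_complement(self.sequence), self.is_circular)


def interval_length(start: int, end: int, L: int | None = None) -> int:
    """Length of a 1-based inclusive interval; ``start > end`` wraps the origin."""
    if start <= end:
        return end - start + 1
    if L is None:
        raise ValueError("wrap-around interval requires the genome length L")
    return (L - start + 1) + end


@dataclass(frozen=True)
class GeneAnnotation:
    """A named gene as one or more 1-based inclusive intervals on the genome.

    ``gene_group`` follows the mitochondrial convention (ND / COX / ATP / tRNA
    / rRNA / CR); an interval with ``start > end`` wraps the replication
    origin.
    """

    gene_name: str
    gene_group: str
    intervals: tuple[tuple[int, int], ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"annotation {self.gene_name!r} has no intervals")
        if self.gene_group not in GENE_GROUPS:
            raise ValueError(
                f"annotation {self.gene_name!r}: unknown gene group {self.gene_group!r}"
            )
        if self.strand not in "+-":
            raise ValueError(f"annotation {self.gene_name!r}: strand must be + or -")
        object.__setattr__(self, "intervals", tuple((int(s), int(e)) for s, e in self.intervals))

    @property
    def wraps(self) -> bool:
        return any(s > e for s, e in self.intervals)

    def length(self, L: int | None = None) -> int:
        return sum(interval_length(s, e, L) for s, e in self.intervals)

    def contains(self, position: int, L: int | None = None) -> bool:
        for s, e in self.intervals:
            if s <= e:
                if s <= position <= e:
                    return True
            else:
                if L is None:
                    raise ValueError("wrap-around interval requires L")
                if position >= s or position <= e:
                    return True
        return False


def gene_length(annotation: GeneAnnotation, L: int | None = None) -> int:
    """Total gene length in bp (sum over intervals; wrap handled)."""
    return annotation.length(L)


def infer_gene_group(name: str) -> str:
    """Guess the gene group from a conventional mitochondrial gene name."""
    u = name.upper()
    if u.startswith("ND"):
        return "ND"
    if u.startswith(("COX", "CYTB", "COB")):
        return "COX"
    if u.startswith("ATP"):
        return "ATP"
    if "TRNA" in u:
        return "tRNA"
    if "RRNA" in u:
        return "rRNA"
    if u.startswith(("VS", "CS", "HVS", "CR", "D-LOOP")):
        return "CR"
    return "intergenic"


class Msa:
    """A gapped multiple sequence alignment with a column coordinate system.

    The coordinate-reference record (``reference_id``, default: the first
    record) defines the mapping from alignment columns to ungapped reference
    positions; ``reference_start`` shifts those positions onto genome
    coordinates (e.g. the control region start within a full mitogenome).
    """

    def __init__(
        self,
        records: Sequence[tuple[str, str]],
        reference_id: str | None = None,
        reference_start: int = 1,
    ) -> None:
        records = [(str(i), str(s).upper()) for i, s in records]
        if len(records) < 2:
            raise AlignmentShapeError("an alignment needs at least 2 sequences")
        n_cols = len(records[0][1])
        for rid, seq in records:
            if len(seq) != n_cols:
                raise AlignmentShapeError(
                    f"ragged alignment: {rid!r} has length {len(seq)}, expected {n_cols}"
                )
            bad = set(seq) - ALIGNED_ALPHABET
            if bad:
                raise FormatError(f"record {rid!r} has non-DNA characters: {sorted(bad)}")
        if n_cols == 0:
            raise AlignmentShapeError("alignment has zero columns")
        ids = [rid for rid, _ in records]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate record ids in alignment")
        if reference_id is None:
            reference_id = ids[0]
        if reference_id not in ids:
            raise ValueError(f"reference_id {reference_id!r} not among record ids")
        self.records: list[tuple[str, str]] = records
        self.reference_id = reference_id
        self.reference_start = int(reference_start)
        self._array: np.ndarray | None = None
        self._coord: np.ndarray | None = None

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def n_seqs(self) -> int:
        return len(self.records)

    @property
    def n_cols(self) -> int:
        return len(self.records[0][1])

    def sequence(self, rid: str) -> str:
        for i, s in self.records:
            if i == rid:
                return s
        raise KeyError(rid)

    def as_array(self) -> np.ndarray:
        """(n_seqs, n_cols) array of single characters."""
        if self._array is None:
            self._array = np.array([list(s) for _, s in self.records], dtype="<U1")
        return self._array

    def coordinate_map(self) -> np.ndarray:
        """1-based ungapped reference position per column (length n_cols).

        Columns where the reference carries a gap map to the preceding
        reference position (0 before the first reference base).
        """
        if self._coord is None:
            ref = self.sequence(self.reference_id)
            out = np.empty(len(ref), dtype=np.int64)
            pos = 0
            for j, c in enumerate(ref):
                if c != GAP:
                    pos += 1
                out[j] = pos
            self._coord = out
        return self._coord

    def ref_position(self, column: int) -> int:
        """Genome coordinate of a 1-based alignment column."""
        return int(self.coordinate_map()[column - 1]) + self.reference_start - 1

    def resample_columns(self, column_indices: Iterable[int]) -> "Msa":
        """New alignment from 0-based column indices (bootstrap resampling)."""
        idx = np.asarray(list(column_indices), dtype=int)
        arr = self.as_array()[:, idx]
        recs = [(rid, "".join(row)) for rid, row in zip(self.ids, arr)]
        return Msa(recs, reference_id=self.reference_id, reference_start=self.reference_start)


# ---------------------------------------------------------------------------
# I/O


def read_alignment(path: str | Path, reference_id: str | None = None,
                   reference_start: int = 1) -> Msa:
    """Read a gapped FASTA alignment; rejects ragged or empty files."""
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return Msa(records, reference_id=reference_id, reference_start=reference_start)


def write_alignment(msa: Msa, path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=rid, description="") for rid, s in msa.records]
    SeqIO.write(recs, str(path), "fasta-2line")


def read_genome(path: str | Path, is_circular: bool = True) -> CircularGenome:
    """Read the first (or only) FASTA record as an ungapped circular genome."""
    for r in SeqIO.parse(str(path), "fasta"):
        return CircularGenome(r.id, str(r.seq).replace(GAP, ""), is_circular)
    raise FormatError(f"{path}: no FASTA records found")


def read_genomes(path: str | Path, is_circular: bool = True) -> list[CircularGenome]:
    out = [CircularGenome(r.id, str(r.seq).replace(GAP, ""), is_circular)
           for r in SeqIO.parse(str(path), "fasta")]
    if not out:
        raise FormatError(f"{path}: no FASTA records found")
    return out


def write_genome(genome: CircularGenome, path: str | Path) -> None:
    SeqIO.write([SeqRecord(Seq(genome.sequence), id=genome.id, description="")],
                str(path), "fasta-2line")


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotations from a 5-column TSV or a GFF3 file.

    TSV columns: gene, group, start, end, strand (header optional).  GFF3 is
    recognised by the ``##gff`` pragma or a ``.gff``/``.gff3`` suffix; the
    gene name is taken from ``Name=`` or ``ID=`` attributes and the group from
    a ``gene_group=`` attribute when present, else inferred from the name.
    Multi-interval genes repeat the name; intervals are merged per name.
    """
    path = Path(path)
    text = path.read_text()
    is_gff = text.startswith("##gff") or path.suffix.lower() in (".gff", ".gff3")
    rows: list[tuple[str, str | None, int, int, str]] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        try:
            if is_gff:
                if len(fields) < 9:
                    raise ValueError("expected 9 GFF3 columns")
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                name = attrs.get("Name") or attrs.get("ID") or f"feature{lineno}"
                group = attrs.get("gene_group")
                rows.append((name, group, int(fields[3]), int(fields[4]), fields[6]))
            else:
                if fields[0].lower() in ("gene", "gene_name", "name"):
                    continue  # header
                name, group, start, end = fields[0], fields[1], int(fields[2]), int(fields[3])
                strand = fields[4] if len(fields) > 4 else "+"
                rows.append((name, group or None, start, end, strand))
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}:{lineno}: bad annotation line ({exc})") from exc
    merged: dict[str, dict] = {}
    for name, group, start, end, strand in rows:
        entry = merged.setdefault(
            name, {"group": group or infer_gene_group(name), "intervals": [], "strand": strand}
        )
        entry["intervals"].append((start, end))
    return [
        GeneAnnotation(name, e["group"], tuple(e["intervals"]), e["strand"])
        for name, e in merged.items()
    ]


def write_annotations(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    lines = ["gene\tgroup\tstart\tend\tstrand"]
    for a in annotations:
        for s, e in a.intervals:
            lines.append(f"{a.gene_name}\t{a.gene_group}\t{s}\t{e}\t{a.strand}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Circular arithmetic


def rotate_to_anchor(genome: CircularGenome, anchor: str) -> CircularGenome:
    """Rotate a circular genome so its sequence starts at ``anchor``.

    The first occurrence of the anchor motif (searching the forward strand,
    then the reverse complement) becomes position 1.  Multiple occurrences use
    the first and log a warning; an absent anchor raises
    :class:`AnchorNotFoundError`.
    """
    anchor = anchor.upper()
    if not anchor:
        raise ValueError("empty anchor")
    if not genome.is_circular:
        raise ValueError(f"genome {genome.id!r} is not circular; cannot rotate")
    for g in (genome, genome.reverse_complement()):
        doubled = g.sequence + g.sequence[: len(anchor) - 1]
        idx = doubled.find(anchor)
        if idx >= 0:
            if doubled.find(anchor, idx + 1) >= 0:
                logger.warning(
                    "anchor occurs more than once in %s; using first occurrence", genome.id
                )
            rotated = g.sequence[idx:] + g.sequence[:idx]
            logger.info("rotated %s by %d bp to anchor", genome.id, idx)
            return CircularGenome(g.id, rotated, True)
    raise AnchorNotFoundError(
        f"anchor {anchor!r} not found in {genome.id!r} or its reverse complement"
    )


def circular_spacing_stats(
    positions: Sequence[int], L: int, circular: bool = True
) -> tuple[float, float]:
    """Mean and population SD of gaps between consecutive 1-based positions.

    With ``circular=True`` the wrap-around gap is included, so the mean is
    exactly ``L / n``.  Positions must be distinct and within [1, L].
    """
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    if pos.size < 2:
        raise ValueError("need at least 2 positions")
    if np.any(np.diff(pos) == 0):
        raise ValueError("duplicate positions")
    if pos[0] < 1 or pos[-1] > L:
        raise ValueError(f"positions must lie in [1, {L}]")
    gaps = np.diff(pos).astype(float)
    if circular:
        gaps = np.append(gaps, L - pos[-1] + pos[0])
    return float(np.mean(gaps)), float(np.std(gaps))
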