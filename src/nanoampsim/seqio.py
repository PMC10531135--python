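"""Readers and writers for the formats the simulator consumes and emits.

FASTA/FASTQ parsing is delegated to Biopython and SAM consumption to pysam;
this module owns the two conventions the simulator itself defines:

* the FASTQ title-line annotation ``nbIns=<i> nbDel=<d> nbSub=<s> cat=<c>``
  carrying the per-read error counts and length category (with an optional
  ``src=<taxon>`` token recording the read's taxon of origin), and
* the per-read profile file: one comma-separated line per read with the
  insertion, deletion and substitution percentages to inject, printed with
  four decimal places.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "ReadAnnotation",
    "AlignmentSummary",
    "ProfileEntry",
    "CATEGORIES",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "read_annotated_fastq",
    "write_fastq",
    "parse_sam",
    "read_profile",
    "write_profile",
    "read_truth_table",
    "write_truth_table",
]

#: Closed set of length-category labels, in the order of the length-parameter
#: vector, plus the label for fully random reads added via the -r option.
CATEGORIES = (
    "gauss",
    "longDel",
    "longRead",
    "short",
    "veryShort",
    "secondGauss",
    "random",
)

_VALID_SEQ = re.compile(r"^[ACGTN]+$")


@dataclass
class SeqRecord:
    """A named nucleotide sequence.

    ``quality`` holds the FASTQ quality string when the record came from a
    FASTQ file; it is not part of the record's identity.
    """

    id: str
    sequence: str
    description: str = ""
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if not self.sequence:
            raise ValueError(f"SeqRecord {self.id!r}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadAnnotation:
    """Simulation annotations carried on the FASTQ title line."""

    n_ins: int = 0
    n_del: int = 0
    n_sub: int = 0
    category: str = "gauss"
    source_taxon: str = ""

    def __post_init__(self) -> None:
        for name in ("n_ins", "n_del", "n_sub"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category {self.category!r} not one of {CATEGORIES}"
            )

    def to_tokens(self) -> str:
        tokens = []
        if self.source_taxon:
            tokens.append(f"src={self.source_taxon}")
        tokens.append(
            f"nbIns={self.n_ins} nbDel={self.n_del} nbSub={self.n_sub} cat={self.category}"
        )
        return " ".join(tokens)

    @classmethod
    def from_description(cls, description: str) -> tuple["ReadAnnotation | None", str]:
        """Split a title-line remainder into (annotation, leftover text).

        Returns ``(None, description)`` when no annotation tokens are present.
        """
        tokens = description.split()
        fields: dict[str, str] = {}
        rest: list[str] = []
        for tok in tokens:
            key, eq, val = tok.partition("=")
            if eq and key in ("nbIns", "nbDel", "nbSub", "cat", "src"):
                fields[key] = val
            else:
                rest.append(tok)
        if not {"nbIns", "nbDel", "nbSub", "cat"} <= fields.keys():
            return None, description
        ann = cls(
            n_ins=int(fields["nbIns"]),
            n_del=int(fields["nbDel"]),
            n_sub=int(fields["nbSub"]),
            category=fields["cat"],
            source_taxon=fields.get("src", ""),
        )
        return ann, " ".join(rest)


@dataclass
class AlignmentSummary:
    """Per-read error accounting extracted from one primary SAM record."""

    read_id: str
    mapped: bool
    target_id: str = ""
    read_length: int = 0
    n_match: int = 0
    n_mismatch: int = 0
    n_ins: int = 0
    n_del: int = 0

    def __post_init__(self) -> None:
        if self.mapped:
            if self.n_match + self.n_mismatch <= 0:
                raise ValueError(
                    f"mapped read {self.read_id!r} has no aligned columns"
                )
        else:
            if self.target_id or any(
                (self.n_match, self.n_mismatch, self.n_ins, self.n_del)
            ):
                raise ValueError(
                    f"unmapped read {self.read_id!r} must have empty target and zero counts"
                )

    @property
    def identity(self) -> float:
        """Percent identity: 100 * matches / aligned columns."""
        cols = self.n_match + self.n_mismatch + self.n_ins + self.n_del
        return 100.0 * self.n_match / cols

    @property
    def error_rate(self) -> float:
        return 100.0 - self.identity


@dataclass(frozen=True)
class ProfileEntry:
    """One profile-file line: error percentages relative to read length."""

    ins_pct: float
    del_pct: float
    sub_pct: float

    def __post_init__(self) -> None:
        for name in ("ins_pct", "del_pct", "sub_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ins_pct + self.del_pct + self.sub_pct > 100.0 + 1e-9:
            raise ValueError("profile percentages exceed 100% of read length")

    @property
    def total(self) -> float:
        return self.ins_pct + self.del_pct + self.sub_pct


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> list[SeqRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip()
        records.append(SeqRecord(id=rec.id, sequence=str(rec.seq).upper(), description=desc))
    _check_unique_ids(records, path)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Read a 4-line-record FASTQ file (phred+33).

    The quality string is retained on each record; the title-line remainder
    (everything after the id, including any annotation tokens) is kept in
    ``description``.
    """
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            desc = rec.description[len(rec.id):].strip()
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            records.append(
                SeqRecord(id=rec.id, sequence=str(rec.seq).upper(), description=desc, quality=qual)
            )
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc
    _check_unique_ids(records, path)
    return records


def read_annotated_fastq(
    path: str | Path,
) -> list[tuple[SeqRecord, "ReadAnnotation | None"]]:
    """Read a FASTQ file, splitting simulator annotations off the title line."""
    out = []
    for rec in read_fastq(path):
        ann, rest = ReadAnnotation.from_description(rec.description)
        out.append((replace(rec, description=rest), ann))
    return out


def write_fastq(
    records: Iterable[tuple[SeqRecord, "ReadAnnotation | None"] | SeqRecord],
    path: str | Path,
    quality: int = 8,
) -> None:
    """Write FASTQ with a single fixed phred quality for every base.

    Each item may be a bare record or a ``(record, annotation)`` pair; the
    annotation is appended to the end of the title line in the canonical
    ``nbIns=… nbDel=… nbSub=… cat=…`` form.
    """
    if not 0 <= quality <= 93:
        raise ValueError(f"quality must be in [0, 93], got {quality}")
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for item in records:
            if isinstance(item, SeqRecord):
                rec, ann = item, None
            else:
                rec, ann = item
            title = rec.id
            if rec.description:
                title += f" {rec.description}"
            if ann is not None:
                title += f" {ann.to_tokens()}"
            fh.write(f"@{title}\n{rec.sequence}\n+\n{qchar * len(rec.sequence)}\n")


def _check_unique_ids(records: Sequence[SeqRecord], path: str | Path) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)


# ---------------------------------------------------------------------------
# SAM

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


def _mismatches_from_md(md: str) -> int:
    """Count substituted positions encoded in an MD tag."""
    n = 0
    for m in _MD_TOKEN.finditer(md):
        if m.group(3):
            n += 1
    return n


def parse_sam(path: str | Path) -> list[AlignmentSummary]:
    """Summarize every primary record of a SAM/BAM file.

    Secondary (0x100) and supplementary (0x800) records are skipped.  For
    mapped records, insertions and deletions come from CIGAR I/D operations,
    mismatches from ``NM - I - D`` (cross-checked against the MD tag when
    present; MD wins on conflict), and matches are the remaining aligned
    M/=/X columns.  Hard- and soft-clipped bases are excluded.
    """
    summaries: list[AlignmentSummary] = []
    md_conflicts = 0
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as sam:
            for aln in sam:
                if aln.is_secondary or aln.is_supplementary:
                    continue
                if aln.is_unmapped:
                    summaries.append(
                        AlignmentSummary(read_id=aln.query_name, mapped=False)
                    )
                    continue
                stats = aln.get_cigar_stats()[0]
                # cigar op order: MIDNSHP=X
                aligned_cols = stats[0] + stats[7] + stats[8]
                n_ins, n_del = stats[1], stats[2]
                if not aln.has_tag("NM"):
                    raise ValueError(
                        f"mapped read {aln.query_name!r} is missing the NM tag"
                    )
                nm = aln.get_tag("NM")
                n_mismatch = nm - n_ins - n_del
                if aln.has_tag("MD"):
                    md_mm = _mismatches_from_md(str(aln.get_tag("MD")))
                    if md_mm != n_mismatch:
                        md_conflicts += 1
                        n_mismatch = md_mm
                if n_mismatch < 0:
                    raise ValueError(
                        f"read {aln.query_name!r}: NM={nm} inconsistent with "
                        f"CIGAR (I={n_ins}, D={n_del})"
                    )
                summaries.append(
                    AlignmentSummary(
                        read_id=aln.query_name,
                        mapped=True,
                        target_id=aln.reference_name or "",
                        read_length=aln.query_length
                        or (aligned_cols - 0) + n_ins,
                        n_match=aligned_cols - n_mismatch,
                        n_mismatch=n_mismatch,
                        n_ins=n_ins,
                        n_del=n_del,
                    )
                )
    finally:
        pysam.set_verbosity(save)
    if md_conflicts:
        warnings.warn(
            f"{md_conflicts} record(s) had NM/MD mismatch counts in conflict; "
            "MD was trusted",
            stacklevel=2,
        )
    return summaries


# ---------------------------------------------------------------------------
# Profile file


def write_profile(entries: Iterable[ProfileEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f"{e.ins_pct:.4f},{e.del_pct:.4f},{e.sub_pct:.4f}\n")


def read_profile(path: str | Path) -> list[ProfileEntry]:
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 comma-separated fields, got {len(parts)}"
                )
            try:
                ins, dele, sub = (float(p) for p in parts)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            entries.append(ProfileEntry(ins, dele, sub))
    return entries


# ---------------------------------------------------------------------------
# Truth table (read id -> taxon/species)


def write_truth_table(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttaxon\n")
        for read_id, taxon in pairs:
            fh.write(f"{read_id}\t{taxon}\n")


def read_truth_table(path: str | Path) -> dict[str, str]:
    truth: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if header.strip() and not header.startswith("read_id"):
            _store_truth_line(truth, header, path, 1)
        for lineno, line in enumerate(fh, start=2):
            if line.strip():
                _store_truth_line(truth, line, path, lineno)
    return truth


def _store_truth_line(truth: dict, line: str, path: str | Path, lineno: int) -> None:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != 2:
        raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
    truth[parts[0]] = parts[1]
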