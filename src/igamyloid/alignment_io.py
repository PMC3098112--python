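"""Reading, validating and masking germline-derivative alignment sets.

The unit of analysis is a :class:`GermlineAlignment`: one germline reference
sequence plus a set of gapless-or-gapped, equal-length, pre-aligned derivative
sequences, each labelled amyloidogenic (``AM``) or non-amyloidogenic (``NAM``),
together with a per-column annotation table giving the structural region
(CDR or FR) and solvent exposure (exposed or buried) of every alignment
column.  Sequences are assumed to be pre-aligned to their germline; no
aligner is embedded.

Coordinates are 1-based alignment-column indices throughout.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
VALID_CHARS = frozenset(AMINO_ACIDS + GAP)

REGIONS = ("CDR", "FR")
EXPOSURES = ("exposed", "buried")
LABELS = ("AM", "NAM", "UNKNOWN")


class AlignmentError(ValueError):
    """Raised when an alignment set violates a structural invariant."""


@dataclass(frozen=True)
class ResidueAnnotation:
    """Region/exposure annotation for one alignment column (1-based)."""

    position: int
    region: str
    exposure: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise AlignmentError(f"position must be >= 1, got {self.position}")
        if self.region not in REGIONS:
            raise AlignmentError(
                f"region must be one of {REGIONS}, got {self.region!r}"
            )
        if self.exposure not in EXPOSURES:
            raise AlignmentError(
                f"exposure must be one of {EXPOSURES}, got {self.exposure!r}"
            )


@dataclass(frozen=True)
class SequenceRecord:
    """An aligned derivative sequence with its class label and germline."""

    id: str
    sequence: str
    label: str = "UNKNOWN"
    germline_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - VALID_CHARS
        if bad:
            raise AlignmentError(
                f"record {self.id!r}: illegal characters {sorted(bad)} "
                f"(expected the 20 amino acids or '{GAP}')"
            )
        if self.label not in LABELS:
            raise AlignmentError(
                f"record {self.id!r}: unknown label {self.label!r} "
                f"(expected one of {LABELS})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GermlineAlignment:
    """A germline plus labelled, annotated, aligned derivatives.

    ``mask_prefix`` leading columns are logically excluded from all
    downstream mutation calling and probability products (the variable
    domain's first residues may be primer-derived); sequence storage is
    unchanged.
    """

    germline_id: str
    germline_seq: str
    derivatives: tuple[SequenceRecord, ...]
    annotations: tuple[ResidueAnnotation, ...]
    mask_prefix: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "germline_seq", self.germline_seq.upper())
        object.__setattr__(self, "derivatives", tuple(self.derivatives))
        object.__setattr__(self, "annotations", tuple(self.annotations))
        length = len(self.germline_seq)
        bad = set(self.germline_seq) - VALID_CHARS
        if bad:
            raise AlignmentError(
                f"germline {self.germline_id!r}: illegal characters {sorted(bad)}"
            )
        for rec in self.derivatives:
            if len(rec) != length:
                raise AlignmentError(
                    f"record {rec.id!r} has length {len(rec)}, expected "
                    f"germline length {length}"
                )
        if not 0 <= self.mask_prefix < length:
            raise AlignmentError(
                f"mask_prefix must be in [0, {length}), got {self.mask_prefix}"
            )
        seen: dict[int, ResidueAnnotation] = {}
        for ann in self.annotations:
            if ann.position in seen:
                raise AlignmentError(
                    f"duplicate annotation for column {ann.position}"
                )
            if ann.position > length:
                raise AlignmentError(
                    f"annotation column {ann.position} beyond alignment "
                    f"length {length}"
                )
            seen[ann.position] = ann
        missing = [
            x for x in self.analysis_range if x not in seen
        ]
        if missing:
            raise AlignmentError(
                f"columns lacking annotation in analysis range: {missing[:10]}"
            )
        object.__setattr__(self, "_by_position", seen)

    _by_position: Mapping[int, ResidueAnnotation] = field(
        default_factory=dict, repr=False, compare=False
    )

    @property
    def length(self) -> int:
        return len(self.germline_seq)

    @property
    def analysis_range(self) -> range:
        """1-based columns included in the analysis (after masking)."""
        return range(self.mask_prefix + 1, self.length + 1)

    def annotation_at(self, position: int) -> ResidueAnnotation:
        try:
            return self._by_position[position]
        except KeyError:
            raise AlignmentError(
                f"column {position} lacks a region/exposure annotation"
            ) from None

    def members(self, label: str) -> tuple[SequenceRecord, ...]:
        return tuple(r for r in self.derivatives if r.label == label)

    def get(self, record_id: str) -> SequenceRecord:
        for rec in self.derivatives:
            if rec.id == record_id:
                return rec
        raise KeyError(record_id)


def _parse_label_suffix(header_id: str) -> tuple[str, str | None]:
    """Split a FASTA id of the form ``acc|AM`` into (id, label)."""
    if "|" in header_id:
        base, _, tail = header_id.rpartition("|")
        if tail in ("AM", "NAM"):
            return base, tail
    return header_id, None


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column tab-separated id -> label table."""
    labels: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise AlignmentError(f"label table row too short: {row!r}")
            rec_id, label = row[0].strip(), row[1].strip()
            if label not in LABELS:
                raise AlignmentError(
                    f"unknown label {label!r} for record {rec_id!r}"
                )
            labels[rec_id] = label
    return labels


def read_annotations(path: str | Path) -> list[ResidueAnnotation]:
    """Read tab-separated columns: position, region, exposure.

    A header line is permitted and detected by a non-numeric first field.
    """
    out: list[ResidueAnnotation] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            first = row[0].strip()
            if not first.lstrip("-").isdigit():
                continue  # header
            if len(row) < 3:
                raise AlignmentError(f"annotation row too short: {row!r}")
            out.append(
                ResidueAnnotation(int(first), row[1].strip(), row[2].strip())
            )
    return out


def read_alignment(
    fasta_path: str | Path,
    annotation_path: str | Path,
    labels: Mapping[str, str] | str | Path | None = None,
    *,
    germline_id: str | None = None,
    mask_prefix: int = 5,
) -> GermlineAlignment:
    """Read and validate a germline-derivative alignment set.

    The germline is the first FASTA record unless ``germline_id`` names
    another record.  Labels come from (in order of precedence) the
    ``labels`` mapping or sidecar table path, then a ``|AM`` / ``|NAM``
    FASTA-header suffix; otherwise a derivative is ``UNKNOWN``.
    """
    if isinstance(labels, (str, Path)):
        labels = read_labels(labels)
    labels = dict(labels or {})

    try:
        records = list(SeqIO.parse(str(fasta_path), "fasta"))
    except Exception as exc:  # pragma: no cover - biopython raises rarely
        raise AlignmentError(f"cannot parse FASTA {fasta_path}: {exc}") from exc
    if not records:
        raise AlignmentError(f"no FASTA records in {fasta_path}")

    parsed: list[tuple[str, str, str | None]] = []
    for rec in records:
        base, suffix = _parse_label_suffix(rec.id)
        parsed.append((base, str(rec.seq), suffix))

    if germline_id is None:
        g_index = 0
    else:
        ids = [p[0] for p in parsed]
        if germline_id not in ids:
            raise AlignmentError(
                f"germline record {germline_id!r} not found in {fasta_path}"
            )
        g_index = ids.index(germline_id)
    g_id, g_seq, _ = parsed[g_index]

    derivatives = []
    for i, (rec_id, seq, suffix) in enumerate(parsed):
        if i == g_index:
            continue
        label = labels.get(rec_id, suffix or "UNKNOWN")
        derivatives.append(
            SequenceRecord(id=rec_id, sequence=seq, label=label, germline_id=g_id)
        )

    annotations = read_annotations(annotation_path)
    return GermlineAlignment(
        germline_id=g_id,
        germline_seq=g_seq,
        derivatives=tuple(derivatives),
        annotations=tuple(annotations),
        mask_prefix=mask_prefix,
    )


def write_alignment(
    aln: GermlineAlignment,
    fasta_path: str | Path,
    annotation_path: str | Path,
    label_path: str | Path | None = None,
) -> None:
    """Write a GermlineAlignment back to FASTA + annotation (+ labels)."""
    bio_records = [
        _BioSeqRecord(Seq(aln.germline_seq), id=aln.germline_id, description="")
    ]
    bio_records += [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="")
        for r in aln.derivatives
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(bio_records, fh, "fasta")

    with open(annotation_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["position", "region", "exposure"])
        for ann in sorted(aln.annotations, key=lambda a: a.position):
            writer.writerow([ann.position, ann.region, ann.exposure])

    if label_path is not None:
        with open(label_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for rec in aln.derivatives:
                writer.writerow([rec.id, rec.label])


def mask_leading_residues(aln: GermlineAlignment, k: int) -> GermlineAlignment:
    """Return a copy whose analysis range starts at column ``k + 1``.

    Masking is logical and idempotent: the stored sequences are unchanged
    and re-masking with the same ``k`` is a no-op.
    """
    if not 0 <= k < aln.length:
        raise AlignmentError(
            f"mask length {k} out of range for alignment of length {aln.length}"
        )
    if k == aln.mask_prefix:
        return aln
    return replace(aln, mask_prefix=k)


def records_to_fasta_str(records: Iterable[SequenceRecord]) -> str:
    """Render labelled records as FASTA with ``|label`` header suffixes."""
    buf = io.StringIO()
    bio = [
        _BioSeqRecord(
            Seq(r.sequence),
            id=f"{r.id}|{r.label}" if r.label != "UNKNOWN" else r.id,
            description="",
        )
        for r in records
    ]
    SeqIO.write(bio, buf, "fasta")
    return buf.getvalue()
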