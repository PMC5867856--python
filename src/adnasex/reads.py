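"""Aligned-read container and I/O for SAM and tab-separated alignment tables.

The package works on already-aligned shotgun reads.  Internally every record
is an :class:`AlignedRead` with 0-based half-open reference coordinates
(SAM's 1-based POS is converted on read).  A read stores its bases in the
orientation of the alignment (reference-forward); molecule-oriented views —
with the original fragment's own 5' end at offset 0, which is what terminal
deamination counting needs — are exposed as properties that
reverse-complement minus-strand records.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

TSV_COLUMNS = ("read_id", "chrom", "start", "length", "strand", "mapq", "seq", "ref_bases")


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (A/C/G/T/N, case-preserving)."""
    return seq.translate(_COMP)[::-1]


class AlignmentParseError(ValueError):
    """A malformed alignment record or table row."""


@dataclasses.dataclass(slots=True)
class AlignedRead:
    """One mapped sequencing read.

    Attributes
    ----------
    read_id : str
        Query name.
    chrom : str
        Reference sequence name.
    start : int
        0-based leftmost reference coordinate of the alignment.
    length : int
        Aligned fragment length in bp (equals ``len(seq)``).
    strand : str
        ``'+'`` or ``'-'``.
    mapq : int
        Mapping quality as reported by the aligner; taken as-is.
    seq : str
        Read bases as stored in the alignment (reference-forward).
    ref_bases : str
        Reference bases over the aligned span (reference-forward).
    has_indels : bool
        True when the original record contained insertions or deletions; such
        reads keep only their matched columns in ``seq``/``ref_bases`` and are
        excluded from damage profiling (but still counted per chromosome).
    """

    read_id: str
    chrom: str
    start: int
    length: int
    strand: str
    mapq: int
    seq: str
    ref_bases: str
    has_indels: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if not (self.length == len(self.seq) == len(self.ref_bases)):
            raise ValueError(
                f"read {self.read_id}: length {self.length} != "
                f"len(seq) {len(self.seq)} or len(ref_bases) {len(self.ref_bases)}"
            )

    @property
    def end(self) -> int:
        """Half-open end coordinate (may exceed a circular reference's length)."""
        return self.start + self.length

    @property
    def molecule_seq(self) -> str:
        """Read bases oriented 5'→3' of the original molecule."""
        return self.seq if self.strand == "+" else revcomp(self.seq)

    @property
    def molecule_ref(self) -> str:
        """Reference bases in the molecule's own 5'→3' orientation."""
        return self.ref_bases if self.strand == "+" else revcomp(self.ref_bases)

    @property
    def five_prime_position(self) -> int:
        """Reference coordinate of the molecule's 5'-most base.

        Alignment start for plus-strand molecules, alignment end for minus
        strand — the coordinate conventional duplicate marking keys on.
        """
        return self.start if self.strand == "+" else self.end

    @property
    def mismatches(self) -> list[tuple[int, str, str]]:
        """(offset from the molecule's 5' end, ref base, read base) triples."""
        ref = self.molecule_ref
        obs = self.molecule_seq
        return [(i, r, o) for i, (r, o) in enumerate(zip(ref, obs)) if r != o]

    def duplicate_key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.five_prime_position, self.length)


def _ref_bases_from_mapping(
    chrom: str, start: int, end: int, reference: Mapping[str, str]
) -> str:
    if chrom not in reference:
        raise AlignmentParseError(
            f"unknown reference name {chrom!r}; known: {sorted(reference)}"
        )
    return reference[chrom][start:end].upper()


def parse_sam(
    path: str | Path, reference: Mapping[str, str] | None = None
) -> list[AlignedRead]:
    """Parse a SAM/BAM file into :class:`AlignedRead` records.

    Unmapped records are skipped (counted in the log).  Reference bases are
    reconstructed from the MD tag when present, otherwise sliced from
    ``reference`` (name → sequence); one of the two must be available.
    Records with indels keep only their matched columns and are flagged.
    """
    reads: list[AlignedRead] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.reference_name is None:
                skipped += 1
                continue
            try:
                reads.append(_read_from_record(rec, reference))
            except AlignmentParseError:
                raise
            except Exception as exc:  # malformed record
                raise AlignmentParseError(
                    f"malformed SAM record {rec.query_name!r}: {exc}"
                ) from exc
    if skipped:
        log.info("parse_sam: skipped %d unmapped record(s)", skipped)
    return reads


def _read_from_record(
    rec: pysam.AlignedSegment, reference: Mapping[str, str] | None
) -> AlignedRead:
    chrom = rec.reference_name
    strand = "-" if rec.is_reverse else "+"
    cigar_ops = {op for op, _ in (rec.cigartuples or [])}
    simple = cigar_ops <= {0, 7, 8}  # M, =, X only
    if simple:
        seq = (rec.query_sequence or "").upper()
        start = rec.reference_start
        if rec.has_tag("MD"):
            ref = rec.get_reference_sequence().upper()
        elif reference is not None:
            ref = _ref_bases_from_mapping(chrom, start, start + len(seq), reference)
        else:
            raise AlignmentParseError(
                f"record {rec.query_name!r} has no MD tag and no reference was supplied"
            )
        return AlignedRead(rec.query_name, chrom, start, len(seq), strand,
                           rec.mapping_quality, seq, ref, has_indels=False)
    # indel/clipped record: keep matched columns only
    if rec.has_tag("MD"):
        pairs = rec.get_aligned_pairs(matches_only=True, with_seq=True)
        qseq = rec.query_sequence or ""
        seq = "".join(qseq[q] for q, _, _ in pairs).upper()
        ref = "".join(s for _, _, s in pairs).upper()
    elif reference is not None:
        pairs = rec.get_aligned_pairs(matches_only=True)
        qseq = rec.query_sequence or ""
        seq = "".join(qseq[q] for q, _ in pairs).upper()
        ref = "".join(
            _ref_bases_from_mapping(chrom, r, r + 1, reference) for _, r in pairs
        )
    else:
        raise AlignmentParseError(
            f"record {rec.query_name!r} has no MD tag and no reference was supplied"
        )
    return AlignedRead(rec.query_name, chrom, rec.reference_start, len(seq), strand,
                       rec.mapping_quality, seq, ref, has_indels=True)


def parse_tsv(path: str | Path) -> list[AlignedRead]:
    """Parse the plain alignment table (columns ``read_id chrom start length
    strand mapq seq ref_bases``, tab-separated, with header)."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "chrom": str,
                                            "strand": str, "seq": str,
                                            "ref_bases": str})
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise AlignmentParseError(f"alignment TSV missing column(s): {sorted(missing)}")
    reads = []
    for row in df.itertuples(index=False):
        try:
            reads.append(AlignedRead(row.read_id, row.chrom, int(row.start),
                                     int(row.length), row.strand, int(row.mapq),
                                     row.seq, row.ref_bases))
        except (ValueError, TypeError) as exc:
            raise AlignmentParseError(f"bad TSV row for read {row.read_id!r}: {exc}") from exc
    return reads


def parse_alignments(
    source: str | Path, reference: Mapping[str, str] | None = None
) -> list[AlignedRead]:
    """Parse alignments from SAM/BAM or from the alignment TSV, by extension."""
    path = Path(source)
    if path.suffix.lower() in (".sam", ".bam", ".cram"):
        return parse_sam(path, reference)
    return parse_tsv(path)


def write_tsv(reads: Iterable[AlignedRead], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.read_id, r.chrom, r.start, r.length, r.strand, r.mapq, r.seq, r.ref_bases)
         for r in reads],
        columns=list(TSV_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def _md_tag(seq: str, ref: str) -> tuple[str, int]:
    """Build an MD tag (reference orientation) and NM count for a gapless alignment."""
    parts: list[str] = []
    run = 0
    nm = 0
    for r, o in zip(ref, seq):
        if r == o:
            run += 1
        else:
            parts.append(str(run))
            parts.append(r)
            run = 0
            nm += 1
    parts.append(str(run))
    return "".join(parts), nm


def write_sam(
    reads: Sequence[AlignedRead],
    path: str | Path,
    lengths: Mapping[str, int],
) -> int:
    """Write reads as SAM with MD/NM tags so parsing needs no reference.

    Reads whose span exceeds the declared reference length (circular,
    origin-wrapping mito fragments) cannot be expressed as one gapless SAM
    record; they are skipped with a warning and the number written is
    returned.  Use the alignment TSV to persist wrapping reads losslessly.
    """
    names = list(lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": int(lengths[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    written = 0
    skipped = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as af:
        for r in reads:
            if r.chrom not in tid:
                raise KeyError(f"no header length for chromosome {r.chrom!r}")
            if r.end > lengths[r.chrom]:
                skipped += 1
                continue
            seg = pysam.AlignedSegment(af.header)
            seg.query_name = r.read_id
            seg.flag = 16 if r.strand == "-" else 0
            seg.reference_id = tid[r.chrom]
            seg.reference_start = r.start
            seg.mapping_quality = r.mapq
            seg.cigartuples = [(0, r.length)]
            seg.query_sequence = r.seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * r.length)
            md, nm = _md_tag(r.seq, r.ref_bases)
            seg.set_tag("MD", md)
            seg.set_tag("NM", nm)
            af.write(seg)
            written += 1
    if skipped:
        log.warning("write_sam: skipped %d origin-wrapping read(s); "
                    "use the alignment TSV for lossless round-trips", skipped)
    return written
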