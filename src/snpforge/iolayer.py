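"""Readers and writers for the on-disk formats the pipeline touches.

The pipeline consumes a reference transcriptome (FASTA of "unigenes":
assembled contigs plus unassembled singletons), read alignments against
those unigenes (SAM/BAM with read groups identifying the source genotype
and sequencing platform), a dataset manifest describing each sequencing
dataset, and BED intervals of putative introns.  All coordinates are
0-based half-open internally; emitted variant tables are 1-based.

Paired singletons -- 5' and 3' reads of one cDNA clone that failed to
assemble into a contig -- are recognised by a configurable name pattern
and share a ``locus_key`` so that downstream selection treats them as a
single locus.
"""

from __future__ import annotations

import re
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, IntegrityError

__all__ = [
    "Platform",
    "ManifestRecord",
    "DatasetManifest",
    "UnigeneRecord",
    "AlignedRead",
    "AlignmentStore",
    "DEFAULT_PAIR_PATTERN",
    "read_manifest",
    "write_manifest",
    "summarize_manifest",
    "bundled_sunflower_manifest",
    "read_reference",
    "write_reference",
    "read_alignments",
    "write_alignments",
    "read_bed",
]


class Platform(str, Enum):
    """Sequencing platform of a dataset (Sanger capillary, Roche 454
    GS FLX, or Illumina single/paired-end short reads)."""

    SANGER = "sanger"
    FLX454 = "flx454"
    ILLUMINA_SE = "illumina_se"
    ILLUMINA_PE = "illumina_pe"


#: SAM @RG PL value emitted for each platform.
PLATFORM_TO_PL: dict[Platform, str] = {
    Platform.SANGER: "CAPILLARY",
    Platform.FLX454: "LS454",
    Platform.ILLUMINA_SE: "ILLUMINA",
    Platform.ILLUMINA_PE: "ILLUMINA",
}

#: Default pattern recognising paired singletons: a shared stem followed
#: by a ``_p1``/``_p2`` member suffix.  One capture group yields the stem.
DEFAULT_PAIR_PATTERN = r"^(.+)_p[12]$"

_MANIFEST_COLUMNS = [
    "genotype_id",
    "accession_id",
    "platform",
    "read_length_min_bp",
    "read_length_max_bp",
    "read_length_avg_bp",
    "n_reads",
    "total_bases_mb",
]


@dataclass(frozen=True)
class ManifestRecord:
    """One sequencing dataset: a (genotype, platform) batch of reads."""

    genotype_id: str
    platform: Platform
    read_length_min_bp: int
    read_length_max_bp: int
    read_length_avg_bp: float
    n_reads: int
    total_bases_mb: float
    accession_id: str | None = None

    def __post_init__(self) -> None:
        if not (
            self.read_length_min_bp
            <= self.read_length_avg_bp
            <= self.read_length_max_bp
        ):
            raise FormatError(
                f"{self.genotype_id}: read lengths must satisfy "
                f"min <= avg <= max, got {self.read_length_min_bp} / "
                f"{self.read_length_avg_bp} / {self.read_length_max_bp}"
            )
        if self.read_length_min_bp <= 0:
            raise FormatError(f"{self.genotype_id}: non-positive read length")
        if self.n_reads < 0 or self.total_bases_mb < 0:
            raise FormatError(f"{self.genotype_id}: negative read/base count")


@dataclass(frozen=True)
class DatasetManifest:
    """The full set of sequencing datasets feeding the reference assembly
    and SNP discovery (structure of the study's dataset summary table)."""

    records: tuple[ManifestRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))

    @property
    def genotypes(self) -> frozenset[str]:
        return frozenset(r.genotype_id for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __add__(self, other: "DatasetManifest") -> "DatasetManifest":
        return DatasetManifest(self.records + other.records)


def summarize_manifest(manifest: DatasetManifest) -> dict[str, float]:
    """Total read and megabase accounting over all datasets.

    Returns ``{"total_reads": int, "total_mb": float}`` as plain sums of
    the per-dataset read counts and megabase totals.
    """
    return {
        "total_reads": int(sum(r.n_reads for r in manifest.records)),
        "total_mb": float(sum(r.total_bases_mb for r in manifest.records)),
    }


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a dataset manifest TSV (one row per sequencing dataset)."""
    df = pd.read_csv(path, sep="\t", dtype={"accession_id": "string"})
    missing = set(_MANIFEST_COLUMNS) - {"accession_id"} - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        accession = getattr(row, "accession_id", None)
        if accession is not None and pd.isna(accession):
            accession = None
        try:
            platform = Platform(row.platform)
        except ValueError as exc:
            raise FormatError(f"unknown platform {row.platform!r}") from exc
        records.append(
            ManifestRecord(
                genotype_id=str(row.genotype_id),
                platform=platform,
                read_length_min_bp=int(row.read_length_min_bp),
                read_length_max_bp=int(row.read_length_max_bp),
                read_length_avg_bp=float(row.read_length_avg_bp),
                n_reads=int(row.n_reads),
                total_bases_mb=float(row.total_bases_mb),
                accession_id=accession,
            )
        )
    return DatasetManifest(tuple(records))


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    rows = [
        {
            "genotype_id": r.genotype_id,
            "accession_id": r.accession_id if r.accession_id is not None else "",
            "platform": r.platform.value,
            "read_length_min_bp": r.read_length_min_bp,
            "read_length_max_bp": r.read_length_max_bp,
            "read_length_avg_bp": r.read_length_avg_bp,
            "n_reads": r.n_reads,
            "total_bases_mb": r.total_bases_mb,
        }
        for r in manifest.records
    ]
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def bundled_sunflower_manifest() -> DatasetManifest:
    """The sunflower study's published per-dataset sequencing summary
    (7 Sanger datasets, one 454 run, 4 Illumina single-end and 4
    paired-end runs), shipped with the package as reference input."""
    return read_manifest(Path(__file__).parent / "data" / "sunflower_manifest.tsv")


# ---------------------------------------------------------------------------
# Reference transcriptome


@dataclass(frozen=True)
class UnigeneRecord:
    """A reference unigene: an assembled contig or an unassembled singleton.

    ``locus_key`` equals ``unigene_id`` except for paired singletons,
    whose two members share the captured name stem.
    """

    unigene_id: str
    sequence: str
    kind: str  # "contig" | "singleton"
    locus_key: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise FormatError(f"{self.unigene_id}: empty sequence")
        if self.kind not in ("contig", "singleton"):
            raise FormatError(f"{self.unigene_id}: bad kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def read_reference(
    fasta_path: str | Path, pair_pattern: str = DEFAULT_PAIR_PATTERN
) -> "OrderedDict[str, UnigeneRecord]":
    """Read the unigene reference FASTA.

    Entries whose name matches ``pair_pattern`` (one capture group = the
    shared clone stem) are singletons sharing a locus_key; entries whose
    description contains the word ``singleton`` are singletons with
    locus_key equal to their own id; everything else is a contig.
    """
    try:
        pattern = re.compile(pair_pattern)
    except re.error as exc:
        raise FormatError(f"invalid pair pattern {pair_pattern!r}: {exc}") from exc
    if pattern.groups != 1:
        raise FormatError("pair_pattern must have exactly one capture group")

    records: OrderedDict[str, UnigeneRecord] = OrderedDict()
    with open(fasta_path) as handle:
        entries = list(SeqIO.parse(handle, "fasta"))
    for entry in entries:
        if entry.id in records:
            raise IntegrityError(f"duplicate unigene id {entry.id!r}")
        m = pattern.match(entry.id)
        flagged_singleton = "singleton" in entry.description.lower()
        if m:
            kind, locus_key = "singleton", m.group(1)
        elif flagged_singleton:
            kind, locus_key = "singleton", entry.id
        else:
            kind, locus_key = "contig", entry.id
        records[entry.id] = UnigeneRecord(
            unigene_id=entry.id,
            sequence=str(entry.seq).upper(),
            kind=kind,
            locus_key=locus_key,
        )
    if not records:
        raise FormatError(f"no FASTA entries in {fasta_path}")
    return records


def write_reference(
    records: Mapping[str, UnigeneRecord] | Iterable[UnigeneRecord],
    path: str | Path,
) -> None:
    if isinstance(records, Mapping):
        records = records.values()
    seqs = [
        SeqRecord(
            Seq(r.sequence),
            id=r.unigene_id,
            description=r.kind if r.kind == "singleton" else "",
        )
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seqs, handle, "fasta")


# ---------------------------------------------------------------------------
# Alignments


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read in reference orientation.

    ``matches`` holds (reference position, read base) for every aligned
    base; ``insertions`` holds (anchor position, inserted sequence) with
    the insertion falling immediately right of the anchor column;
    ``deletions`` holds (first deleted position, length).  Soft-clipped
    bases are excluded entirely.
    """

    read_id: str
    unigene_id: str
    genotype_id: str
    platform: Platform
    matches: tuple[tuple[int, str], ...]
    insertions: tuple[tuple[int, str], ...] = ()
    deletions: tuple[tuple[int, int], ...] = ()
    is_paired: bool = False

    @property
    def start(self) -> int:
        positions = [p for p, _ in self.matches] + [p for p, _ in self.deletions]
        return min(positions)

    @property
    def end(self) -> int:
        """Half-open end of the aligned span on the reference."""
        positions = [p for p, _ in self.matches] + [
            p + n - 1 for p, n in self.deletions
        ]
        return max(positions) + 1


class AlignmentStore:
    """Per-unigene collections of aligned reads keyed by genotype."""

    def __init__(self) -> None:
        self._reads: OrderedDict[str, list[AlignedRead]] = OrderedDict()

    def add(self, read: AlignedRead) -> None:
        self._reads.setdefault(read.unigene_id, []).append(read)

    def unigenes(self) -> list[str]:
        return list(self._reads)

    def reads(self, unigene_id: str) -> list[AlignedRead]:
        return self._reads.get(unigene_id, [])

    def __iter__(self):
        for reads in self._reads.values():
            yield from reads

    def read_counts(self) -> dict[str, int]:
        """Total reads aligned per unigene (the contig-depth statistic
        gating variant mining)."""
        return {u: len(rs) for u, rs in self._reads.items()}

    @property
    def n_reads(self) -> int:
        return sum(len(rs) for rs in self._reads.values())


def _platform_from_rg(pl: str | None, is_paired: bool) -> Platform:
    pl = (pl or "").upper()
    if pl == "CAPILLARY":
        return Platform.SANGER
    if pl in ("LS454", "454"):
        return Platform.FLX454
    # Default short-read platform; paired flag separates SE from PE.
    return Platform.ILLUMINA_PE if is_paired else Platform.ILLUMINA_SE


def read_alignments(
    sam_path: str | Path, manifest: DatasetManifest
) -> AlignmentStore:
    """Load mapped reads from SAM or BAM (format sniffed by pysam).

    Every read must carry an RG tag whose read group's SM field is a
    genotype present in the manifest; unmapped reads are skipped and
    soft-clipped bases are excluded from the aligned span.
    """
    genotypes = manifest.genotypes
    store = AlignmentStore()
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as af:
        rg_info: dict[str, tuple[str | None, str | None]] = {}
        for rg in af.header.to_dict().get("RG", []):
            rg_info[rg["ID"]] = (rg.get("SM"), rg.get("PL"))
        lengths = dict(zip(af.references, af.lengths))
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            if not aln.has_tag("RG"):
                raise IntegrityError(f"read {aln.query_name!r} lacks an RG tag")
            rg_id = aln.get_tag("RG")
            if rg_id not in rg_info:
                raise IntegrityError(f"read group {rg_id!r} not in SAM header")
            sample, pl = rg_info[rg_id]
            if sample not in genotypes:
                raise IntegrityError(
                    f"read {aln.query_name!r}: genotype {sample!r} absent "
                    f"from manifest"
                )
            read = _read_from_pysam(aln, sample, pl)
            ref_len = lengths.get(read.unigene_id)
            if ref_len is not None and read.end > ref_len:
                raise FormatError(
                    f"read {read.read_id!r} extends past end of "
                    f"{read.unigene_id} ({read.end} > {ref_len})"
                )
            store.add(read)
    return store


def _read_from_pysam(
    aln: pysam.AlignedSegment, sample: str, pl: str | None
) -> AlignedRead:
    seq = aln.query_sequence or ""
    matches: list[tuple[int, str]] = []
    insertions: list[tuple[int, str]] = []
    deletions: list[tuple[int, int]] = []
    rpos = aln.reference_start
    qpos = 0
    for op, length in aln.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            for i in range(length):
                matches.append((rpos + i, seq[qpos + i].upper()))
            rpos += length
            qpos += length
        elif op == 1:  # I — anchored to the left flanking column
            insertions.append((rpos - 1, seq[qpos : qpos + length].upper()))
            qpos += length
        elif op == 2:  # D
            deletions.append((rpos, length))
            rpos += length
        elif op == 3:  # N (skip)
            rpos += length
        elif op == 4:  # S — soft clip excluded
            qpos += length
        # H/P consume nothing we track
    return AlignedRead(
        read_id=aln.query_name,
        unigene_id=aln.reference_name,
        genotype_id=sample,
        platform=_platform_from_rg(pl, aln.is_paired),
        matches=tuple(matches),
        insertions=tuple(insertions),
        deletions=tuple(deletions),
        is_paired=bool(aln.is_paired),
    )


def write_alignments(
    store: AlignmentStore,
    reference: Mapping[str, UnigeneRecord],
    path: str | Path,
) -> None:
    """Emit the store as SAM against the given reference.

    Each (genotype, platform) pair becomes one read group with SM set to
    the genotype and PL to the SAM platform tag. Reads must be contiguous
    over their aligned span (true of everything this package produces).
    """
    unigenes = [u for u in reference if store.reads(u)] or list(reference)
    rgs = sorted(
        {(r.genotype_id, r.platform) for r in store},
        key=lambda gp: (gp[0], gp[1].value),
    )
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": u, "LN": len(reference[u].sequence)} for u in unigenes
        ],
        "RG": [
            {"ID": f"{g}.{p.value}", "SM": g, "PL": PLATFORM_TO_PL[p]}
            for g, p in rgs
        ],
    }
    tid = {u: i for i, u in enumerate(unigenes)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for unigene in unigenes:
            for read in store.reads(unigene):
                out.write(_read_to_pysam(read, tid[unigene], out.header))


def _read_to_pysam(
    read: AlignedRead, tid: int, header: pysam.AlignmentHeader
) -> pysam.AlignedSegment:
    match_at = dict(read.matches)
    deleted: set[int] = set()
    for start, length in read.deletions:
        deleted.update(range(start, start + length))
    ins_at = dict(read.insertions)

    cigar: list[tuple[int, int]] = []
    query: list[str] = []

    def push(op: int, n: int = 1) -> None:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    start = read.start
    for pos in range(start, read.end):
        if pos in match_at:
            push(0)
            query.append(match_at[pos])
        elif pos in deleted:
            push(2)
        else:
            raise FormatError(
                f"read {read.read_id!r} is not contiguous at {pos}"
            )
        if pos in ins_at:
            push(1, len(ins_at[pos]))
            query.append(ins_at[pos])

    seg = pysam.AlignedSegment(header)
    seg.query_name = read.read_id
    seg.query_sequence = "".join(query)
    seg.reference_id = tid
    seg.reference_start = start
    seg.mapping_quality = 60
    seg.cigartuples = cigar
    seg.flag = 0x1 | 0x8 | 0x40 if read.is_paired else 0
    seg.query_qualities = pysam.qualitystring_to_array("I" * len(seg.query_sequence))
    seg.set_tag("RG", f"{read.genotype_id}.{read.platform.value}")
    return seg


# ---------------------------------------------------------------------------
# Intervals


def read_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read putative-intron intervals (BED, 0-based half-open)."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise FormatError(
                    f"{path}:{lineno}: interval end {end} <= start {start}"
                )
            intervals.setdefault(chrom, []).append((start, end))
    return intervals
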