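"""Six-frame longest-ORF computation and 4-way unigene classification.

Each unigene is translated in all six reading frames and the length of
its longest open reading frame is recorded.  Combined with whether the
unigene has a protein hit in at least one sequenced plant genome, the
ORF length classifies the unigene:

    hit and ORF > 50 aa      -> gene
    hit and ORF <= 50 aa     -> pseudogene_or_fragment
    no hit and ORF > 75 aa   -> possible_novel_gene
    no hit and ORF <= 75 aa  -> not_gene (presumably UTR sequence)

Only unigenes classified gene / possible_novel_gene remain eligible to
contribute SNPs to the genotyping array.

EST-derived transcripts are frequently 5'/3'-truncated, so an ORF may
run off the end of the sequence without reaching a stop codon.  Because
the length thresholds were calibrated empirically on this same statistic
in the original analysis, the exact ORF definition matters; both a
start-codon-anchored mode (default) and a stop-free mode are provided
and the mode used is recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import DomainError, FormatError
from .iolayer import UnigeneRecord

__all__ = [
    "FRAMES",
    "OrfResult",
    "UNIGENE_CLASSES",
    "ARRAY_ELIGIBLE_CLASSES",
    "longest_orf",
    "classify_unigene",
    "classify_reference",
    "read_hits_tsv",
    "write_classes_tsv",
]

#: Frame labels in tie-break priority order.
FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")

UNIGENE_CLASSES = (
    "gene",
    "pseudogene_or_fragment",
    "possible_novel_gene",
    "not_gene",
)

#: Classes whose SNPs may enter array selection.
ARRAY_ELIGIBLE_CLASSES = frozenset({"gene", "possible_novel_gene"})

_STOPS = frozenset({"TAA", "TAG", "TGA"})
_START = "ATG"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class OrfResult:
    """Longest ORF over all six frames.

    ``start_nt``/``end_nt`` are 0-based half-open nucleotide coordinates
    on the scanned strand (the reverse complement for minus frames);
    ``end_nt`` includes the stop codon when one terminates the ORF, and
    ``length_aa`` excludes it.
    """

    frame: str
    start_nt: int
    end_nt: int
    length_aa: int


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _codon_kind(codon: str) -> str:
    """'start' | 'stop' | 'aa'. Codons containing N (or any non-ACGT
    symbol) are neither start nor stop and count as one residue."""
    if any(b not in "ACGT" for b in codon):
        return "aa"
    if codon == _START:
        return "start"
    if codon in _STOPS:
        return "stop"
    return "aa"


def _scan_frame(strand_seq: str, offset: int, mode: str):
    """Yield (start_nt, end_nt, length_aa) of every maximal ORF in one
    frame of the given strand sequence."""
    codons = [
        strand_seq[i : i + 3]
        for i in range(offset, len(strand_seq) - 2, 3)
    ]
    kinds = [_codon_kind(c) for c in codons]
    n = len(codons)
    if mode == "start_to_stop":
        i = 0
        while i < n:
            if kinds[i] != "start":
                i += 1
                continue
            j = i
            while j < n and kinds[j] != "stop":
                j += 1
            if j < n:  # stop codon included in the span
                yield offset + 3 * i, offset + 3 * (j + 1), j - i
            else:  # ran off the sequence end within frame
                yield offset + 3 * i, offset + 3 * n, n - i
            # later ATGs inside this ORF give strictly shorter ORFs,
            # so resume after the stop
            i = j + 1
    elif mode == "stop_free":
        i = 0
        while i < n:
            if kinds[i] == "stop":
                i += 1
                continue
            j = i
            while j < n and kinds[j] != "stop":
                j += 1
            yield offset + 3 * i, offset + 3 * j, j - i
            i = j + 1
    else:
        raise DomainError(f"unknown ORF mode {mode!r}")


def longest_orf(sequence: str, mode: str = "start_to_stop") -> OrfResult:
    """Longest open reading frame across all six reading frames.

    In ``start_to_stop`` mode an ORF runs from ATG to the next in-frame
    stop codon or the sequence end; in ``stop_free`` mode any maximal
    stop-free codon run counts.  Ties break towards the lower frame
    index (+1,+2,+3,-1,-2,-3), then the smaller start coordinate.
    """
    seq = sequence.upper()
    best = OrfResult(frame="+1", start_nt=0, end_nt=0, length_aa=0)
    best_key = (0, -0, -0)  # (length, -frame_idx, -start)
    for frame_idx, frame in enumerate(FRAMES):
        strand = seq if frame.startswith("+") else _revcomp(seq)
        offset = int(frame[1]) - 1
        for start, end, length in _scan_frame(strand, offset, mode):
            key = (length, -frame_idx, -start)
            if key > best_key:
                best_key = key
                best = OrfResult(frame, start, end, length)
    return best


def classify_unigene(orf_len_aa: int, has_hit: bool) -> str:
    """Assign the 4-way class from ORF length and homology evidence.

    Thresholds are strict ("longer than"): 50 aa with a hit, 75 aa
    without.
    """
    if orf_len_aa < 0:
        raise DomainError("negative ORF length")
    if has_hit:
        return "gene" if orf_len_aa > 50 else "pseudogene_or_fragment"
    return "possible_novel_gene" if orf_len_aa > 75 else "not_gene"


def read_hits_tsv(path: str | Path) -> dict[str, int]:
    """Homology-hit table: unigene_id -> number of sequenced genomes
    (0-9) with a protein hit at the screening E-value threshold."""
    df = pd.read_csv(path, sep="\t")
    required = {"unigene_id", "n_genomes_with_hit"}
    if not required <= set(df.columns):
        raise FormatError(f"hit table needs columns {sorted(required)}")
    return dict(
        zip(df["unigene_id"].astype(str), df["n_genomes_with_hit"].astype(int))
    )


def classify_reference(
    reference: Mapping[str, UnigeneRecord],
    hits: Mapping[str, int],
    mode: str = "start_to_stop",
) -> pd.DataFrame:
    """Classify every unigene; returns a table with the ORF statistic,
    frame, hit status and class.  Unigenes absent from the hit table are
    treated as having no hit."""
    rows = []
    for unigene_id, rec in reference.items():
        orf = longest_orf(rec.sequence, mode=mode)
        has_hit = hits.get(unigene_id, 0) >= 1
        rows.append(
            {
                "unigene_id": unigene_id,
                "orf_len_aa": orf.length_aa,
                "frame": orf.frame,
                "has_hit": has_hit,
                "unigene_class": classify_unigene(orf.length_aa, has_hit),
                "orf_mode": mode,
            }
        )
    return pd.DataFrame(rows)


def write_classes_tsv(classes: pd.DataFrame, path: str | Path) -> None:
    classes.to_csv(path, sep="\t", index=False)
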