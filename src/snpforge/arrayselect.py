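"""Candidate gating and selection for the genotyping array.

An Infinium/GoldenGate array slot is expensive, so mined variants are
funnelled through: (1) a flanking-error score flagging misassembled or
error-rich contigs, (2) hard gates on probe design scores, SNP type
([A/T] and [C/G] substitutions need two bead types and are discarded),
and host-unigene class, (3) one SNP per locus, biased towards SNPs
supported by many genotypes, and (4) a final ranking by Infinium design
score capped at the array size (10,640 in the original design).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DomainError, FormatError
from .iolayer import AlignmentStore, UnigeneRecord
from .orfclass import ARRAY_ELIGIBLE_CLASSES
from .snpmine import VariantCall

__all__ = [
    "DesignScoreRecord",
    "SelectionParams",
    "CandidateSNP",
    "flanking_error_score",
    "assemble_candidates",
    "gate_candidates",
    "select_per_locus",
    "rank_and_cap",
    "build_panel",
    "read_scores_tsv",
    "write_panel_tsv",
    "write_audit_tsv",
]

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class DesignScoreRecord:
    """Vendor probe-convertibility scores for one SNP, both in [0, 1]."""

    snp_id: str
    infinium_score: float
    goldengate_score: float

    def __post_init__(self) -> None:
        for name in ("infinium_score", "goldengate_score"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FormatError(f"{self.snp_id}: {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class SelectionParams:
    min_infinium: float = 0.70
    min_goldengate: float = 0.55
    max_flanking: float = 10.0
    target_count: int = 10640

    def __post_init__(self) -> None:
        if not (0 <= self.min_infinium <= 1 and 0 <= self.min_goldengate <= 1):
            raise DomainError("score thresholds must lie in [0, 1]")
        if self.max_flanking < 0:
            raise DomainError("max_flanking must be nonnegative")
        if self.target_count <= 0:
            raise DomainError("target_count must be positive")


@dataclass(frozen=True)
class CandidateSNP:
    """A mined variant joined with everything selection needs."""

    variant: VariantCall
    unigene_class: str
    flanking_score: float
    scores: DesignScoreRecord

    @property
    def snp_id(self) -> str:
        return self.variant.snp_id

    @property
    def locus_key(self) -> str:
        return self.variant.locus_key


def flanking_error_score(
    store: AlignmentStore,
    ref: UnigeneRecord,
    snp_position: int,
) -> float:
    """Read-vs-reference mismatch load around a SNP.

    For each genotype, count mismatches between its reads and the
    reference across the entire unigene alignment excluding the SNP
    column itself (each indel event counts one mismatch); sum the
    per-genotype counts and divide by the number of reads covering the
    SNP position.  Values above ~10 indicate misalignment or excess
    sequencing error.
    """
    seq = ref.sequence
    mismatches = 0
    depth = 0
    for read in store.reads(ref.unigene_id):
        covers = False
        ins_anchors = {a for a, _ in read.insertions}
        for pos, base in read.matches:
            if pos == snp_position:
                covers = True
                continue
            if pos in ins_anchors:
                continue  # counted as one insertion event below
            if base in _BASES and seq[pos] in _BASES and base != seq[pos]:
                mismatches += 1
        for anchor, _ins in read.insertions:
            if anchor != snp_position:
                mismatches += 1
        for start, length in read.deletions:
            if start <= snp_position < start + length:
                covers = True
            if start != snp_position:
                mismatches += 1
        if covers:
            depth += 1
    if depth == 0:
        raise DomainError(
            f"no reads cover {ref.unigene_id}:{snp_position + 1}"
        )
    return mismatches / depth


def assemble_candidates(
    calls: Sequence[VariantCall],
    classes: Mapping[str, str] | pd.DataFrame,
    scores: Mapping[str, DesignScoreRecord],
    store: AlignmentStore | None = None,
    reference: Mapping[str, UnigeneRecord] | None = None,
    flanking: Mapping[str, float] | None = None,
) -> list[CandidateSNP]:
    """Join variant calls with unigene classes, design scores, and the
    flanking-error score (computed from alignments unless supplied).
    Calls lacking a design-score record are dropped: without vendor
    scores a SNP cannot be considered for the array."""
    if isinstance(classes, pd.DataFrame):
        classes = dict(
            zip(classes["unigene_id"].astype(str), classes["unigene_class"])
        )
    out = []
    for call in calls:
        rec = scores.get(call.snp_id)
        if rec is None:
            continue
        if flanking is not None and call.snp_id in flanking:
            fscore = flanking[call.snp_id]
        elif store is not None and reference is not None:
            fscore = flanking_error_score(
                store, reference[call.unigene_id], call.position
            )
        else:
            raise DomainError(
                "need either precomputed flanking scores or store+reference"
            )
        out.append(
            CandidateSNP(
                variant=call,
                unigene_class=classes.get(call.unigene_id, "not_gene"),
                flanking_score=fscore,
                scores=rec,
            )
        )
    return out


def gate_candidates(
    candidates: Sequence[CandidateSNP],
    params: SelectionParams = SelectionParams(),
    audit: list | None = None,
) -> list[CandidateSNP]:
    """Apply the hard gates; order is preserved.

    Retained iff Infinium score >= min_infinium, GoldenGate score >=
    min_goldengate (both inclusive), the SNP is array-compatible (a
    base substitution other than [A/T]/[C/G]), the host unigene is
    classified gene or possible_novel_gene, and the flanking-error score
    is <= max_flanking.  If ``audit`` is given, one (snp_id, reason)
    tuple is appended per discarded candidate (first failing gate).
    """
    kept = []
    for cand in candidates:
        reason = None
        if cand.scores.infinium_score < params.min_infinium:
            reason = "infinium_score_below_threshold"
        elif cand.scores.goldengate_score < params.min_goldengate:
            reason = "goldengate_score_below_threshold"
        elif not cand.variant.array_compatible:
            reason = "incompatible_snp_type"
        elif cand.unigene_class not in ARRAY_ELIGIBLE_CLASSES:
            reason = f"unigene_class_{cand.unigene_class}"
        elif cand.flanking_score > params.max_flanking:
            reason = "flanking_score_above_threshold"
        if reason is None:
            kept.append(cand)
        elif audit is not None:
            audit.append((cand.snp_id, reason))
    return kept


def _per_locus_key(cand: CandidateSNP):
    # more supporting genotypes first, then higher Infinium score,
    # then leftmost position, then snp_id for full determinism
    return (
        -cand.variant.n_supporting_genotypes,
        -cand.scores.infinium_score,
        cand.variant.position,
        cand.snp_id,
    )


def select_per_locus(gated: Sequence[CandidateSNP]) -> list[CandidateSNP]:
    """Keep one SNP per locus_key, biased towards multi-genotype support.

    Within a locus the winner sorts first by (supporting genotypes descending,
    Infinium score descending, position ascending).  Paired singletons
    share a locus_key, so exactly one member of a pair can donate a SNP.
    Output follows first appearance order of each locus.
    """
    best: dict[str, CandidateSNP] = {}
    order: list[str] = []
    for cand in gated:
        key = cand.locus_key
        if key not in best:
            best[key] = cand
            order.append(key)
        elif _per_locus_key(cand) < _per_locus_key(best[key]):
            best[key] = cand
    return [best[k] for k in order]


def rank_and_cap(
    selected: Sequence[CandidateSNP], target_count: int
) -> list[CandidateSNP]:
    """Final panel: sort by Infinium score descending (ties: GoldenGate
    score descending, then snp_id ascending) and keep the top
    ``target_count``; all survive if fewer exist."""
    if target_count <= 0:
        raise DomainError("target_count must be positive")
    ranked = sorted(
        selected,
        key=lambda c: (
            -c.scores.infinium_score,
            -c.scores.goldengate_score,
            c.snp_id,
        ),
    )
    return ranked[:target_count]


def build_panel(
    candidates: Sequence[CandidateSNP],
    params: SelectionParams = SelectionParams(),
    audit: list | None = None,
) -> list[CandidateSNP]:
    """gate -> one per locus -> rank and cap."""
    gated = gate_candidates(candidates, params, audit=audit)
    per_locus = select_per_locus(gated)
    return rank_and_cap(per_locus, params.target_count)


# ---------------------------------------------------------------------------
# I/O


def read_scores_tsv(path: str | Path) -> dict[str, DesignScoreRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"snp_id", "infinium_score", "goldengate_score"}
    if not required <= set(df.columns):
        raise FormatError(f"score table needs columns {sorted(required)}")
    return {
        str(r.snp_id): DesignScoreRecord(
            str(r.snp_id), float(r.infinium_score), float(r.goldengate_score)
        )
        for r in df.itertuples(index=False)
    }


def write_panel_tsv(panel: Sequence[CandidateSNP], path: str | Path) -> None:
    rows = [
        {
            "snp_id": c.snp_id,
            "unigene_id": c.variant.unigene_id,
            "position": c.variant.position + 1,
            "locus_key": c.locus_key,
            "ref_allele": c.variant.ref_allele,
            "alt_allele": c.variant.alt_allele,
            "pair_label": (
                "/".join(sorted(c.variant.pair_label))
                if c.variant.pair_label
                else ""
            ),
            "is_transition": c.variant.is_transition,
            "n_supporting_genotypes": c.variant.n_supporting_genotypes,
            "unigene_class": c.unigene_class,
            "flanking_score": c.flanking_score,
            "infinium_score": c.scores.infinium_score,
            "goldengate_score": c.scores.goldengate_score,
        }
        for c in panel
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_audit_tsv(audit: Sequence[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(audit, columns=["snp_id", "discard_reason"]).to_csv(
        path, sep="\t", index=False
    )
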