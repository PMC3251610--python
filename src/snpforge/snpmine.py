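"""Pileup construction, reference-ambiguity correction, and SNP/INDEL mining.

Variants are mined from per-genotype pileups over multi-genotype EST
alignments under three criteria: (i) at least ``min_reads_per_genotype``
reads per genotype at the position, (ii) at least ``min_genotypes``
genotypes satisfying (i), and (iii) a within-genotype major-allele
frequency of at least ``min_within_genotype_freq`` (0.9 by default --
the source lines are inbred, so a genotype's reads should be effectively
fixed for one allele).  A call additionally requires that at least two
qualifying genotypes disagree on their major allele, since otherwise no
polymorphism exists.  Unigenes with fewer than ``min_contig_reads`` or
more than ``max_contig_reads`` total aligned reads yield no calls; the
upper bound guards against collapsed paralogs.

Ambiguous reference bases (N or IUPAC codes) left by the assembler are
corrected beforehand from the pooled read stack wherever depth and
majority support suffice.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import DomainError, FormatError
from .iolayer import AlignmentStore, UnigeneRecord

__all__ = [
    "DELETION",
    "INSERTION",
    "MiningParams",
    "PileupColumn",
    "GenotypeSupport",
    "VariantCall",
    "build_pileups",
    "correct_reference",
    "call_variants",
    "classify_variant_type",
    "filter_intronic",
    "mine",
    "write_variants_tsv",
    "write_variants_vcf",
    "write_change_log",
]

#: Allele symbol for a read deleted at a column (one event per anchor).
DELETION = "-"
#: Allele symbol for a read carrying an insertion right of the column.
INSERTION = "+"

_BASES = frozenset("ACGT")
_FREQ_SLACK = 1e-9  # guards exact fractions like 9/10 against float rounding


@dataclass(frozen=True)
class MiningParams:
    """Thresholds of the mining criteria.

    min_contig_reads/max_contig_reads bound the total reads aligned to a
    unigene (6..5000 by default); min_reads_per_genotype, min_genotypes
    and min_within_genotype_freq are criteria (i)-(iii); the
    ref_correct_* pair governs ambiguity correction.
    """

    min_contig_reads: int = 6
    max_contig_reads: int = 5000
    min_reads_per_genotype: int = 2
    min_genotypes: int = 2
    min_within_genotype_freq: float = 0.9
    ref_correct_min_depth: int = 6
    ref_correct_min_freq: float = 0.5

    def __post_init__(self) -> None:
        if self.min_contig_reads > self.max_contig_reads:
            raise DomainError("min_contig_reads > max_contig_reads")
        if min(self.min_contig_reads, self.min_reads_per_genotype,
               self.min_genotypes, self.ref_correct_min_depth) < 1:
            raise DomainError("count thresholds must be positive")
        if not 0.5 < self.min_within_genotype_freq <= 1.0:
            raise DomainError("min_within_genotype_freq must lie in (0.5, 1]")


@dataclass
class PileupColumn:
    """Per-genotype allele tallies at one reference position."""

    unigene_id: str
    position: int  # 0-based
    ref_base: str
    counts: dict[str, Counter]  # genotype -> allele -> count

    def pooled(self) -> Counter:
        pooled: Counter = Counter()
        for c in self.counts.values():
            pooled.update(c)
        return pooled

    @property
    def depth(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())


@dataclass(frozen=True)
class GenotypeSupport:
    """One genotype's evidence at a variant column."""

    depth: int
    major_allele: str
    major_freq: float


@dataclass(frozen=True)
class VariantCall:
    """A mined variant with its per-genotype support."""

    unigene_id: str
    position: int  # 0-based
    locus_key: str
    ref_allele: str
    alt_allele: str
    var_class: str  # "SNP" | "INDEL"
    genotypes: Mapping[str, GenotypeSupport]
    supporting: tuple[str, ...]
    pair_label: frozenset | None
    is_transition: bool
    array_compatible: bool
    multiallelic: bool = False

    @property
    def n_supporting_genotypes(self) -> int:
        return len(self.supporting)

    @property
    def snp_id(self) -> str:
        """Stable identifier; position reported 1-based."""
        return f"{self.unigene_id}:{self.position + 1}"


# ---------------------------------------------------------------------------
# Pileups


def build_pileups(
    store: AlignmentStore, reference: Mapping[str, UnigeneRecord]
) -> dict[str, list[PileupColumn]]:
    """Tally per-genotype alleles at every covered reference position.

    A read contributes its base at each aligned column; a deletion
    contributes one DELETION symbol at its leftmost deleted column; a
    read with an insertion immediately right of column p contributes one
    INSERTION symbol at p in place of its matched base, so column totals
    never exceed the number of covering reads.
    """
    pileups: dict[str, list[PileupColumn]] = {}
    for unigene in store.unigenes():
        if unigene not in reference:
            raise FormatError(f"alignments reference unknown unigene {unigene!r}")
        seq = reference[unigene].sequence
        columns: dict[int, dict[str, Counter]] = {}

        def tally(pos: int, genotype: str, allele: str) -> None:
            columns.setdefault(pos, {}).setdefault(genotype, Counter())[allele] += 1

        for read in store.reads(unigene):
            ins_anchors = {anchor for anchor, _ in read.insertions}
            for pos, base in read.matches:
                if pos in ins_anchors:
                    tally(pos, read.genotype_id, INSERTION)
                else:
                    tally(pos, read.genotype_id, base)
            for start, _length in read.deletions:
                tally(start, read.genotype_id, DELETION)
        pileups[unigene] = [
            PileupColumn(unigene, pos, seq[pos], columns[pos])
            for pos in sorted(columns)
        ]
    return pileups


# ---------------------------------------------------------------------------
# Reference ambiguity correction


@dataclass(frozen=True)
class ReferenceCorrection:
    unigene_id: str
    position: int
    old_base: str
    new_base: str


def correct_reference(
    pileups: Mapping[str, Sequence[PileupColumn]],
    reference: Mapping[str, UnigeneRecord],
    params: MiningParams = MiningParams(),
) -> tuple[dict[str, UnigeneRecord], list[ReferenceCorrection]]:
    """Replace ambiguous reference bases supported by the read stack.

    A position whose reference base is not A/C/G/T is replaced by the
    pooled strict-majority base when total depth >= ref_correct_min_depth
    and that base's pooled frequency >= ref_correct_min_freq.  Ties (no
    unique most-common base) and non-ambiguous positions are never
    touched, which also makes the operation idempotent.
    """
    corrected: dict[str, UnigeneRecord] = dict(reference)
    log: list[ReferenceCorrection] = []
    for unigene, columns in pileups.items():
        seq = list(reference[unigene].sequence)
        changed = False
        for col in columns:
            if seq[col.position] in _BASES:
                continue
            pooled = Counter(
                {a: n for a, n in col.pooled().items() if a in _BASES}
            )
            depth = col.depth
            if depth < params.ref_correct_min_depth or not pooled:
                continue
            (top, n_top), *rest = pooled.most_common()
            if rest and rest[0][1] == n_top:
                continue  # no strict majority
            if n_top / depth < params.ref_correct_min_freq - _FREQ_SLACK:
                continue
            log.append(
                ReferenceCorrection(unigene, col.position, seq[col.position], top)
            )
            seq[col.position] = top
            changed = True
        if changed:
            corrected[unigene] = replace(
                reference[unigene], sequence="".join(seq)
            )
    return corrected, log


# ---------------------------------------------------------------------------
# Variant calling


def classify_variant_type(ref_allele: str, alt_allele: str) -> dict:
    """Label a base substitution for array design.

    Transitions are A<->G and C<->T.  [A/T] and [C/G] substitutions are
    flagged array-incompatible: their two alleles are complementary, so
    an Infinium assay would need two bead types.
    """
    if ref_allele not in _BASES or alt_allele not in _BASES:
        raise DomainError(f"alleles must be bases, got {ref_allele}/{alt_allele}")
    if ref_allele == alt_allele:
        raise DomainError("identical alleles do not form a substitution")
    pair = frozenset((ref_allele, alt_allele))
    return {
        "pair_label": pair,
        "is_transition": pair in (frozenset("AG"), frozenset("CT")),
        "array_compatible": pair not in (frozenset("AT"), frozenset("CG")),
    }


def _genotype_support(counts: Counter) -> GenotypeSupport:
    depth = sum(counts.values())
    # deterministic major allele: highest count, then lexicographic
    major = min(counts, key=lambda a: (-counts[a], a))
    return GenotypeSupport(depth, major, counts[major] / depth)


def call_variants(
    pileups: Mapping[str, Sequence[PileupColumn]],
    params: MiningParams,
    contig_read_counts: Mapping[str, int],
    locus_keys: Mapping[str, str] | None = None,
) -> list[VariantCall]:
    """Mine variants from pileup columns under criteria (i)-(iii).

    A genotype *supports* a column iff its depth >= min_reads_per_genotype
    and its major-allele frequency >= min_within_genotype_freq.  A call is
    emitted iff >= min_genotypes genotypes support the column and at least
    two supporting genotypes carry different major alleles.  The alternate
    allele is the non-reference major allele backed by the most supporting
    genotypes (ties: more pooled reads, then lexicographic).  Columns whose
    conflicting alleles involve the indel symbols are INDEL calls.
    """
    calls: list[VariantCall] = []
    for unigene, columns in pileups.items():
        total_reads = contig_read_counts.get(unigene, 0)
        if not params.min_contig_reads <= total_reads <= params.max_contig_reads:
            continue
        locus = locus_keys.get(unigene, unigene) if locus_keys else unigene
        for col in columns:
            call = _call_column(col, params, locus)
            if call is not None:
                calls.append(call)
    return calls


def _call_column(
    col: PileupColumn, params: MiningParams, locus_key: str
) -> VariantCall | None:
    support = {g: _genotype_support(c) for g, c in col.counts.items()}
    supporting = sorted(
        g
        for g, s in support.items()
        if s.depth >= params.min_reads_per_genotype
        and s.major_freq >= params.min_within_genotype_freq - _FREQ_SLACK
    )
    if len(supporting) < params.min_genotypes:
        return None
    majors = {support[g].major_allele for g in supporting}
    if len(majors) < 2:
        return None

    ref = col.ref_base
    non_ref = [a for a in majors if a != ref]
    if not non_ref:
        return None  # cannot happen with >=2 distinct majors, defensive
    pooled = col.pooled()

    def alt_rank(allele: str):
        n_geno = sum(
            1 for g in supporting if support[g].major_allele == allele
        )
        return (-n_geno, -pooled[allele], allele)

    alt = min(non_ref, key=alt_rank)

    is_indel = any(a in (DELETION, INSERTION) for a in majors | {ref, alt})
    if not is_indel and ref in _BASES and alt in _BASES:
        typing = classify_variant_type(ref, alt)
        var_class = "SNP"
    else:
        typing = {"pair_label": None, "is_transition": False,
                  "array_compatible": False}
        var_class = "INDEL" if is_indel else "SNP"
        if var_class == "SNP" and ref not in _BASES:
            # uncorrected ambiguous reference: keep the call but it cannot
            # be typed for the array
            pass
    return VariantCall(
        unigene_id=col.unigene_id,
        position=col.position,
        locus_key=locus_key,
        ref_allele=ref,
        alt_allele=alt,
        var_class=var_class,
        genotypes=dict(support),
        supporting=tuple(supporting),
        pair_label=typing["pair_label"],
        is_transition=typing["is_transition"],
        array_compatible=typing["array_compatible"],
        multiallelic=len(majors) > 2,
    )


def filter_intronic(
    calls: Sequence[VariantCall],
    introns: Mapping[str, Sequence[tuple[int, int]]],
) -> list[VariantCall]:
    """Drop calls falling inside putative-intron intervals.

    Intervals are 0-based half-open per unigene; order of surviving
    calls is preserved.
    """
    for unigene, ivals in introns.items():
        for start, end in ivals:
            if end <= start:
                raise FormatError(
                    f"{unigene}: interval end {end} <= start {start}"
                )
    kept = []
    for call in calls:
        ivals = introns.get(call.unigene_id, ())
        if any(start <= call.position < end for start, end in ivals):
            continue
        kept.append(call)
    return kept


def mine(
    store: AlignmentStore,
    reference: Mapping[str, UnigeneRecord],
    params: MiningParams = MiningParams(),
    introns: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> tuple[list[VariantCall], dict[str, UnigeneRecord], list[ReferenceCorrection]]:
    """Full mining pipeline: pileups -> ambiguity correction -> calls
    (-> intron filter).  Returns (calls, corrected reference, change log)."""
    pileups = build_pileups(store, reference)
    corrected, change_log = correct_reference(pileups, reference, params)
    for unigene, columns in pileups.items():
        seq = corrected[unigene].sequence
        for col in columns:
            col.ref_base = seq[col.position]
    locus_keys = {u: r.locus_key for u, r in corrected.items()}
    calls = call_variants(pileups, params, store.read_counts(), locus_keys)
    if introns:
        calls = filter_intronic(calls, introns)
    return calls, corrected, change_log


# ---------------------------------------------------------------------------
# Writers (1-based positions on output)


def write_variants_tsv(calls: Sequence[VariantCall], path: str | Path) -> None:
    import pandas as pd

    rows = []
    for c in calls:
        rows.append(
            {
                "snp_id": c.snp_id,
                "unigene_id": c.unigene_id,
                "position": c.position + 1,
                "locus_key": c.locus_key,
                "ref_allele": c.ref_allele,
                "alt_allele": c.alt_allele,
                "var_class": c.var_class,
                "n_supporting_genotypes": c.n_supporting_genotypes,
                "supporting_genotypes": ",".join(c.supporting),
                "pair_label": (
                    "/".join(sorted(c.pair_label)) if c.pair_label else ""
                ),
                "is_transition": c.is_transition,
                "array_compatible": c.array_compatible,
                "multiallelic": c.multiallelic,
                "genotype_detail": ";".join(
                    f"{g}:{s.depth}:{s.major_allele}:{s.major_freq:.4f}"
                    for g, s in sorted(c.genotypes.items())
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_variants_vcf(
    calls: Sequence[VariantCall],
    reference: Mapping[str, UnigeneRecord],
    path: str | Path,
) -> None:
    """Minimal VCF: CHROM=unigene, 1-based POS, INFO carries support."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for u, rec in reference.items():
            fh.write(f"##contig=<ID={u},length={len(rec.sequence)}>\n")
        fh.write(
            '##INFO=<ID=NSG,Number=1,Type=Integer,'
            'Description="Supporting genotypes">\n'
        )
        fh.write(
            '##INFO=<ID=GF,Number=.,Type=String,'
            'Description="genotype:depth:major:freq">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            gf = ",".join(
                f"{g}:{s.depth}:{s.major_allele}:{s.major_freq:.4f}"
                for g, s in sorted(c.genotypes.items())
            )
            ref, alt = c.ref_allele, c.alt_allele
            if c.var_class == "INDEL":
                # symbolic representation of anchored indel events
                ref, alt = c.ref_allele, "<DEL>" if alt == DELETION else "<INS>"
            fh.write(
                f"{c.unigene_id}\t{c.position + 1}\t{c.snp_id}\t{ref}\t{alt}"
                f"\t.\tPASS\tNSG={c.n_supporting_genotypes};GF={gf}\n"
            )


def write_change_log(
    log: Sequence[ReferenceCorrection], path: str | Path
) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "unigene_id": r.unigene_id,
                "position": r.position + 1,
                "old_base": r.old_base,
                "new_base": r.new_base,
            }
            for r in log
        ],
        columns=["unigene_id", "position", "old_base", "new_base"],
    ).to_csv(path, sep="\t", index=False)
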