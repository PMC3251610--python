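"""Seeded synthetic-data generator for every input the pipeline consumes.

The generator emulates a multi-genotype transcriptome re-sequencing
study against a unigene reference: reference sequences with the length
structure of an EST assembly (contigs around 830 bp, singletons around
440 bp, some singletons paired), fixed between-genotype variants planted
at roughly 1 SNP per 164 bp, platform-specific reads with substitution
errors, ambiguity codes injected into the emitted reference, and a
samples x loci genotype-call matrix with group-specific inbreeding and
missing data.  Every draw descends from a single integer seed, and the
complete ground truth (planted variants, per-read emission log, true
allele frequencies) is returned alongside the data.

Inbred genotypes are simulated as fully homozygous haplotypes; each
planted variant splits the genotype panel into two balanced allele
pools, emulating fixed differences between the two breeding pools a
genotyping array is designed to separate.  Read placement is uniform
along each unigene -- no expression-level variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .iolayer import (
    AlignedRead,
    AlignmentStore,
    DatasetManifest,
    ManifestRecord,
    Platform,
    UnigeneRecord,
)

__all__ = [
    "PlatformProfile",
    "GroupSpec",
    "MatrixSpec",
    "SimulationConfig",
    "PlantedVariant",
    "ReadEmission",
    "TruthTable",
    "simulate_reference",
    "plant_variants",
    "simulate_alignments",
    "simulate_genotype_matrix",
]

_BASES = np.array(list("ACGT"))
#: Two-base IUPAC codes by the unordered base pair they contain.
_IUPAC2 = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


@dataclass(frozen=True)
class PlatformProfile:
    """Read length, per-base substitution error rate, and mean aligned
    depth per genotype for one sequencing platform."""

    platform: Platform
    read_length: int
    error_rate: float
    mean_depth: float

    def __post_init__(self) -> None:
        if self.read_length <= 0 or self.mean_depth <= 0:
            raise DomainError("read_length and mean_depth must be positive")
        if not 0 <= self.error_rate < 1:
            raise DomainError("error_rate must lie in [0, 1)")


@dataclass(frozen=True)
class GroupSpec:
    """One breeding/population group of the genotyped panel."""

    group: str
    species: str
    n_samples: int
    inbreeding: float  # Wright's F: P(het) = 2p(1-p)(1-F)

    def __post_init__(self) -> None:
        if not 0 <= self.inbreeding <= 1:
            raise DomainError("inbreeding coefficient must lie in [0, 1]")


@dataclass(frozen=True)
class MatrixSpec:
    """Genotype-call matrix dimensions and noise model.

    Allele frequencies are drawn uniformly on [maf_low, 1 - maf_low];
    calls go missing independently at ``missing_rate``; the first
    ``n_replicate_pairs`` samples are re-emitted as technical replicates
    (same calls, fresh missingness).
    """

    n_loci: int = 300
    groups: tuple[GroupSpec, ...] = (
        GroupSpec("OPV_landrace", "H. annuus", 9, 0.0),
        GroupSpec("HA_oil", "H. annuus", 9, 0.65),
        GroupSpec("HA_nonoil", "H. annuus", 1, 0.65),
        GroupSpec("RHA_oil", "H. annuus", 10, 0.65),
        GroupSpec("RHA_nonoil", "H. annuus", 1, 0.65),
        GroupSpec("wild", "H. annuus", 2, 0.0),
        GroupSpec("wild", "H. argophyllus", 2, 0.0),
        GroupSpec("wild", "H. niveus", 2, 0.0),
    )
    missing_rate: float = 0.02
    n_replicate_pairs: int = 3
    maf_low: float = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulated experiment.

    Defaults mirror the emulated study: 4 inbred genotypes re-sequenced
    to mean per-genotype depth 6 with 36 bp reads at 0.5% base error,
    variants fixed between genotype pools at 1 per 163.6 bp, contig and
    singleton lengths around 830 and 440 bp.
    """

    seed: int = 0
    n_unigenes: int = 20
    contig_length_mean: float = 828.5
    contig_length_sd: float = 150.0
    singleton_length_mean: float = 444.2
    singleton_length_sd: float = 80.0
    min_length: int = 150
    singleton_fraction: float = 0.61
    singleton_pair_fraction: float = 0.15
    n_genotypes: int = 4
    snp_rate: float = 1.0 / 163.6
    indel_rate: float = 0.0005
    ambiguity_rate: float = 0.002
    platform_profiles: tuple[PlatformProfile, ...] = (
        PlatformProfile(Platform.ILLUMINA_SE, 36, 0.005, 6.0),
    )
    matrix: MatrixSpec = MatrixSpec()

    def __post_init__(self) -> None:
        for name in ("snp_rate", "indel_rate", "ambiguity_rate",
                     "singleton_fraction", "singleton_pair_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DomainError(f"{name} must lie in [0, 1]")
        if self.n_unigenes < 1 or self.n_genotypes < 1:
            raise DomainError("need at least one unigene and one genotype")

    @property
    def genotype_ids(self) -> tuple[str, ...]:
        return tuple(f"G{i + 1:02d}" for i in range(self.n_genotypes))


def _rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stage,)))


# ---------------------------------------------------------------------------
# Truth containers


@dataclass(frozen=True)
class PlantedVariant:
    unigene_id: str
    position: int  # 0-based on the reference
    ref_allele: str
    alt_allele: str  # base for SNPs, "-" deletion, "+" insertion
    var_class: str  # "SNP" | "INDEL"
    genotype_alleles: Mapping[str, str]  # genotype -> allele carried


@dataclass(frozen=True)
class ReadEmission:
    read_id: str
    unigene_id: str
    genotype_id: str
    platform: Platform
    start: int
    error_positions: tuple[int, ...]  # reference positions of injected errors


@dataclass
class TruthTable:
    variants: list[PlantedVariant] = field(default_factory=list)
    emissions: list[ReadEmission] = field(default_factory=list)

    def variants_by_position(self) -> dict[tuple[str, int], PlantedVariant]:
        return {(v.unigene_id, v.position): v for v in self.variants}


# ---------------------------------------------------------------------------
# Reference


def simulate_reference(
    cfg: SimulationConfig,
) -> tuple[dict[str, UnigeneRecord], dict[str, UnigeneRecord]]:
    """Draw the unigene reference.

    Returns (emitted, clean): the emitted reference has ambiguity codes
    injected at ``ambiguity_rate`` (N half the time, else the two-base
    IUPAC code covering the true base), while the clean truth keeps the
    true bases.  Paired singletons share a ``<stem>_p1``/``_p2`` name.
    """
    rng = _rng(cfg, stage=0)
    n_singletons = int(round(cfg.n_unigenes * cfg.singleton_fraction))
    n_pairs = int(round(n_singletons * cfg.singleton_pair_fraction / 2))
    clean: dict[str, UnigeneRecord] = {}
    emitted: dict[str, UnigeneRecord] = {}

    def draw_length(mean: float, sd: float) -> int:
        return max(cfg.min_length, int(round(rng.normal(mean, sd))))

    def add(unigene_id: str, kind: str, locus_key: str, length: int) -> None:
        seq = "".join(rng.choice(_BASES, size=length))
        clean[unigene_id] = UnigeneRecord(unigene_id, seq, kind, locus_key)
        out = list(seq)
        n_amb = rng.binomial(length, cfg.ambiguity_rate)
        for pos in rng.choice(length, size=min(n_amb, length), replace=False):
            true = out[pos]
            if rng.random() < 0.5:
                out[pos] = "N"
            else:
                other = rng.choice([b for b in "ACGT" if b != true])
                out[pos] = _IUPAC2[frozenset((true, other))]
        emitted[unigene_id] = UnigeneRecord(
            unigene_id, "".join(out), kind, locus_key
        )

    idx = 0
    for _ in range(n_pairs):
        idx += 1
        stem = f"SNG{idx:04d}"
        for member in ("p1", "p2"):
            add(
                f"{stem}_{member}",
                "singleton",
                stem,
                draw_length(cfg.singleton_length_mean, cfg.singleton_length_sd),
            )
    for _ in range(n_singletons - 2 * n_pairs):
        idx += 1
        uid = f"SNG{idx:04d}"
        add(uid, "singleton", uid,
            draw_length(cfg.singleton_length_mean, cfg.singleton_length_sd))
    for i in range(cfg.n_unigenes - n_singletons):
        uid = f"CTG{i + 1:04d}"
        add(uid, "contig", uid,
            draw_length(cfg.contig_length_mean, cfg.contig_length_sd))
    return emitted, clean


# ---------------------------------------------------------------------------
# Haplotypes


@dataclass(frozen=True)
class Haplotype:
    """One genotype's sequence for one unigene, expressed against
    reference coordinates: per-position allele (base or "-" when the
    position is deleted) plus insertions keyed by anchor position."""

    alleles: tuple[str, ...]
    insertions: Mapping[int, str]


def plant_variants(
    clean_ref: Mapping[str, UnigeneRecord],
    cfg: SimulationConfig,
) -> tuple[dict[str, dict[str, Haplotype]], TruthTable]:
    """Plant fixed between-genotype variants on the clean reference.

    Variant positions are drawn per-bp at ``snp_rate`` (indels at
    ``indel_rate``); at each variant the genotype panel is split into
    two balanced allele pools.  Returns per-genotype haplotypes keyed
    ``{genotype: {unigene: Haplotype}}`` and the truth table.
    """
    if cfg.n_genotypes < 2:
        raise DomainError("planting variants needs >= 2 genotypes")
    rng = _rng(cfg, stage=1)
    genotypes = cfg.genotype_ids
    haplotypes: dict[str, dict[str, Haplotype]] = {g: {} for g in genotypes}
    truth = TruthTable()
    for unigene_id, rec in clean_ref.items():
        L = len(rec.sequence)
        is_variant = rng.random(L) < cfg.snp_rate
        is_indel = rng.random(L) < cfg.indel_rate
        alleles = {g: list(rec.sequence) for g in genotypes}
        insertions: dict[str, dict[int, str]] = {g: {} for g in genotypes}
        for pos in range(L):
            if not (is_variant[pos] or is_indel[pos]):
                continue
            pool = list(rng.permutation(genotypes))
            alt_pool = pool[: len(pool) // 2]
            ref_base = rec.sequence[pos]
            if is_indel[pos] and 0 < pos < L - 1:
                if rng.random() < 0.5:  # 1-bp deletion
                    alt = "-"
                    for g in alt_pool:
                        alleles[g][pos] = "-"
                else:  # 1-bp insertion right of pos
                    alt = "+"
                    ins_base = str(rng.choice(_BASES))
                    for g in alt_pool:
                        insertions[g][pos] = ins_base
            else:
                alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
                for g in alt_pool:
                    alleles[g][pos] = alt
            truth.variants.append(
                PlantedVariant(
                    unigene_id=unigene_id,
                    position=pos,
                    ref_allele=ref_base,
                    alt_allele=alt,
                    var_class="SNP" if alt in "ACGT" else "INDEL",
                    genotype_alleles={
                        g: (alt if g in alt_pool else ref_base)
                        for g in genotypes
                    },
                )
            )
        for g in genotypes:
            haplotypes[g][unigene_id] = Haplotype(
                tuple(alleles[g]), dict(insertions[g])
            )
    return haplotypes, truth


# ---------------------------------------------------------------------------
# Reads


def simulate_alignments(
    haplotypes: Mapping[str, Mapping[str, Haplotype]],
    cfg: SimulationConfig,
    truth: TruthTable | None = None,
) -> tuple[AlignmentStore, DatasetManifest]:
    """Emit reads from the haplotypes directly as alignments.

    Per unigene, genotype and platform profile, the read count is
    ``round(mean_depth * L / read_length)`` with uniform start
    positions; each aligned base substitutes to a random different base
    with probability ``error_rate``.  Positions known by construction --
    no aligner involved.  The emission log is appended to ``truth`` when
    given.  Also returns the matching dataset manifest.
    """
    rng = _rng(cfg, stage=2)
    store = AlignmentStore()
    per_dataset: dict[tuple[str, Platform], list[int]] = {}
    read_serial = 0
    for genotype in sorted(haplotypes):
        for unigene in sorted(haplotypes[genotype]):
            hap = haplotypes[genotype][unigene]
            L = len(hap.alleles)
            for profile in cfg.platform_profiles:
                span = min(profile.read_length, L)
                n_reads = int(round(profile.mean_depth * L / span))
                starts = rng.integers(0, L - span + 1, size=n_reads)
                for start in sorted(starts.tolist()):
                    read_serial += 1
                    read = _emit_read(
                        f"r{read_serial:07d}", unigene, genotype, profile,
                        hap, int(start), span, rng, truth,
                    )
                    if read is None:
                        continue
                    store.add(read)
                    key = (genotype, profile.platform)
                    per_dataset.setdefault(key, []).append(
                        len(read.matches)
                        + sum(len(s) for _, s in read.insertions)
                    )
    records = []
    for (genotype, platform), lengths in sorted(
        per_dataset.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        arr = np.array(lengths)
        records.append(
            ManifestRecord(
                genotype_id=genotype,
                platform=platform,
                read_length_min_bp=int(arr.min()),
                read_length_max_bp=int(arr.max()),
                read_length_avg_bp=float(arr.mean()),
                n_reads=int(arr.size),
                total_bases_mb=float(arr.sum() / 1e6),
            )
        )
    return store, DatasetManifest(tuple(records))


def _emit_read(
    read_id: str,
    unigene: str,
    genotype: str,
    profile: PlatformProfile,
    hap: Haplotype,
    start: int,
    span: int,
    rng: np.random.Generator,
    truth: TruthTable | None,
) -> AlignedRead | None:
    matches: list[tuple[int, str]] = []
    insertions: list[tuple[int, str]] = []
    deletions: list[tuple[int, int]] = []
    errors: list[int] = []
    for pos in range(start, start + span):
        allele = hap.alleles[pos]
        if allele == "-":
            if deletions and deletions[-1][0] + deletions[-1][1] == pos:
                last_start, last_len = deletions[-1]
                deletions[-1] = (last_start, last_len + 1)
            else:
                deletions.append((pos, 1))
            continue
        base = allele
        if rng.random() < profile.error_rate:
            base = str(rng.choice([b for b in "ACGT" if b != allele]))
            errors.append(pos)
        matches.append((pos, base))
        ins = hap.insertions.get(pos)
        if ins is not None and pos < start + span - 1:
            insertions.append((pos, ins))
    if not matches:
        return None  # span fell entirely inside a deletion
    # an aligned span may not begin or end with a deletion event
    first, last = matches[0][0], matches[-1][0]
    deletions = [
        (s, n) for s, n in deletions if s > first and s + n - 1 < last
    ]
    read = AlignedRead(
        read_id=read_id,
        unigene_id=unigene,
        genotype_id=genotype,
        platform=profile.platform,
        matches=tuple(matches),
        insertions=tuple(insertions),
        deletions=tuple(deletions),
        is_paired=profile.platform is Platform.ILLUMINA_PE,
    )
    if truth is not None:
        truth.emissions.append(
            ReadEmission(
                read_id, unigene, genotype, profile.platform,
                start, tuple(errors),
            )
        )
    return read


# ---------------------------------------------------------------------------
# Genotype matrix


def simulate_genotype_matrix(cfg: SimulationConfig):
    """Draw a samples x loci call matrix with known allele frequencies.

    Per locus the A-allele frequency p is uniform on
    [maf_low, 1 - maf_low]; per sample in a group with inbreeding F the
    call is AA/AB/BB with probabilities (p^2 + Fpq, 2pq(1-F), q^2 + Fpq);
    calls then go missing independently.  Replicate samples duplicate
    their source's calls with independently redrawn missingness.

    Returns (GenotypeMatrix, true-frequency DataFrame).
    """
    from .genodiv import GenotypeMatrix  # local import avoids cycle

    rng = _rng(cfg, stage=3)
    spec = cfg.matrix
    loci = [f"SNP{i + 1:05d}" for i in range(spec.n_loci)]
    p = rng.uniform(spec.maf_low, 1 - spec.maf_low, size=spec.n_loci)
    q = 1 - p

    sample_rows = []
    call_rows = []
    serial = 0
    for group in spec.groups:
        f = group.inbreeding
        probs = np.stack(
            [p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q],
            axis=1,
        )
        cum = np.cumsum(probs, axis=1)
        for _ in range(group.n_samples):
            serial += 1
            sid = f"S{serial:03d}"
            u = rng.random(spec.n_loci)
            codes = (u[:, None] > cum).sum(axis=1)  # 0=AA 1=AB 2=BB
            calls = np.array(_CALL_CODES)[codes]
            sample_rows.append(
                {
                    "sample_id": sid,
                    "species": group.species,
                    "group": group.group,
                    "replicate_of": None,
                }
            )
            call_rows.append(calls)

    calls = pd.DataFrame(
        np.array(call_rows, dtype=object),
        index=[r["sample_id"] for r in sample_rows],
        columns=loci,
    )
    # replicates: duplicated calls, missingness drawn independently below
    rep_sources = list(calls.index[: spec.n_replicate_pairs])
    for src in rep_sources:
        rep_id = f"{src}rep"
        calls.loc[rep_id] = calls.loc[src]
        meta = next(r for r in sample_rows if r["sample_id"] == src)
        sample_rows.append(
            {
                "sample_id": rep_id,
                "species": meta["species"],
                "group": meta["group"],
                "replicate_of": src,
            }
        )
    miss = rng.random(calls.shape) < spec.missing_rate
    calls = calls.mask(miss, other=np.nan)

    samples = (
        pd.DataFrame(sample_rows).set_index("sample_id").loc[calls.index]
    )
    truth_freqs = pd.DataFrame({"snp_id": loci, "p_allele_a": p})
    return GenotypeMatrix(calls, samples), truth_freqs


_CALL_CODES = ["AA", "AB", "BB"]
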