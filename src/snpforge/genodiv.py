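"""Genotype-matrix QC and marker-panel diversity statistics.

Operates on a samples x loci matrix of biallelic calls (AA/AB/BB, or
missing) with per-sample species and breeding-group metadata.  Provides
the panel-evaluation statistics used to judge a genotyping array:
call-rate usability, replicate concordance, cross-species
transferability, minor-allele-frequency filtering, gene diversity
(expected heterozygosity), per-sample observed heterozygosity, Nei's
standard genetic distance among individuals, principal coordinates
analysis, and the Evanno delta-K statistic over supplied per-K model
log-likelihoods (the Bayesian clustering itself is consumed, not run).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, IntegrityError

__all__ = [
    "GROUPS",
    "MISSING",
    "GenotypeMatrix",
    "PcoResult",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "filter_call_rate",
    "replicate_concordance",
    "transferability_counts",
    "minor_allele_freq",
    "filter_maf",
    "gene_diversity",
    "locus_stats",
    "sample_heterozygosity",
    "nei_distance",
    "pco",
    "evanno_delta_k",
    "read_loglik_tsv",
]

GROUPS = (
    "OPV_landrace",
    "HA_oil",
    "HA_nonoil",
    "RHA_oil",
    "RHA_nonoil",
    "wild",
    "other",
)

#: On-disk token for a missing (no-call) genotype.
MISSING = "NC"

_CALLS = ("AA", "AB", "BB")
#: Frequency of the A allele implied by each call.
_DOSAGE = {"AA": 1.0, "AB": 0.5, "BB": 0.0}


@dataclass(frozen=True)
class GenotypeMatrix:
    """Samples x loci call matrix with sample metadata.

    ``calls``: DataFrame indexed by sample_id, one column per snp_id,
    values in {"AA","AB","BB"} or NaN for missing.
    ``samples``: DataFrame indexed by sample_id with columns
    ``species``, ``group`` and ``replicate_of`` (NaN when the sample is
    not a replicate).
    """

    calls: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.calls.index.equals(self.samples.index):
            raise IntegrityError("calls and samples must share the sample index")
        for col in ("species", "group"):
            if col not in self.samples.columns:
                raise IntegrityError(f"samples metadata lacks {col!r}")
        bad_groups = set(self.samples["group"]) - set(GROUPS)
        if bad_groups:
            raise IntegrityError(f"unknown groups: {sorted(bad_groups)}")
        if "replicate_of" in self.samples.columns:
            refs = self.samples["replicate_of"].dropna()
            missing = set(refs) - set(self.samples.index)
            if missing:
                raise IntegrityError(
                    f"replicate_of references unknown samples: {sorted(missing)}"
                )
        values = set(pd.unique(self.calls.values.ravel()))
        bad = {v for v in values if not (pd.isna(v) or v in _CALLS)}
        if bad:
            raise FormatError(f"invalid call values: {sorted(map(str, bad))}")

    @property
    def loci(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.index)

    def dosage(self) -> pd.DataFrame:
        """Per-sample A-allele frequency (1, 0.5, 0; NaN when missing)."""
        return self.calls.apply(lambda s: s.map(_DOSAGE))

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls.loc[list(sample_ids)], self.samples.loc[list(sample_ids)]
        )

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls[list(loci)], self.samples)


def read_matrix_tsv(path: str | Path) -> GenotypeMatrix:
    """Genotype matrix TSV: columns sample_id, species, group,
    replicate_of, then one column per snp_id with calls in
    {AA, AB, BB, NC}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta_cols = ["sample_id", "species", "group", "replicate_of"]
    if df.columns[: len(meta_cols)].tolist() != meta_cols:
        raise FormatError(f"matrix TSV must start with columns {meta_cols}")
    df = df.set_index("sample_id")
    samples = df[meta_cols[1:]]
    calls = df.drop(columns=meta_cols[1:]).replace(MISSING, np.nan)
    return GenotypeMatrix(calls, samples)


def write_matrix_tsv(m: GenotypeMatrix, path: str | Path) -> None:
    out = pd.concat([m.samples, m.calls.fillna(MISSING)], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# QC


def filter_call_rate(
    m: GenotypeMatrix,
    threshold: float = 0.8,
    sample_subset: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Keep loci whose non-missing fraction over the (sub)sample set is
    at least ``threshold`` (the 80% "usable data" rule by default)."""
    if not 0 < threshold <= 1:
        raise DomainError("threshold must lie in (0, 1]")
    subset = list(sample_subset) if sample_subset is not None else m.sample_ids
    if not subset:
        raise DomainError("empty sample subset")
    rates = m.calls.loc[subset].notna().mean(axis=0)
    kept = rates.index[rates >= threshold - 1e-12]
    return m.subset_loci(list(kept))


@dataclass(frozen=True)
class ConcordanceResult:
    discordant_calls: int
    both_called: int
    missing_mismatch: int


def replicate_concordance(
    m: GenotypeMatrix,
) -> dict[tuple[str, str], ConcordanceResult]:
    """Compare each declared replicate with its source sample.

    ``discordant_calls`` counts loci where both are called but differ;
    ``missing_mismatch`` counts loci where exactly one is missing (the
    benign failure mode: replicate differences should come from missing
    data, not from conflicting allele calls).
    """
    if "replicate_of" not in m.samples.columns:
        return {}
    out: dict[tuple[str, str], ConcordanceResult] = {}
    for rep_id, source in m.samples["replicate_of"].dropna().items():
        a = m.calls.loc[rep_id]
        b = m.calls.loc[source]
        both = a.notna() & b.notna()
        out[(rep_id, source)] = ConcordanceResult(
            discordant_calls=int((both & (a != b)).sum()),
            both_called=int(both.sum()),
            missing_mismatch=int((a.notna() ^ b.notna()).sum()),
        )
    return out


def transferability_counts(
    m: GenotypeMatrix,
    species_sets: Iterable[frozenset] | None = None,
    threshold: float = 0.8,
) -> dict[frozenset, int]:
    """Count loci usable in every species of each requested species set.

    A locus is usable within a species iff its call rate over that
    species' samples meets ``threshold`` (for a 2-sample species this
    degenerates to "called in both").  By default every non-empty subset
    of the species present is evaluated.
    """
    species_present = sorted(set(m.samples["species"]))
    if len(species_present) < 2:
        raise DomainError("need at least two species for transferability")
    if species_sets is None:
        species_sets = [
            frozenset(c)
            for r in range(1, len(species_present) + 1)
            for c in itertools.combinations(species_present, r)
        ]
    usable: dict[str, pd.Series] = {}
    for sp in species_present:
        ids = m.samples.index[m.samples["species"] == sp]
        rates = m.calls.loc[ids].notna().mean(axis=0)
        usable[sp] = rates >= threshold - 1e-12
    out: dict[frozenset, int] = {}
    for sset in species_sets:
        unknown = set(sset) - set(species_present)
        if unknown:
            raise DomainError(f"unknown species: {sorted(unknown)}")
        mask = np.logical_and.reduce([usable[sp].values for sp in sset])
        out[frozenset(sset)] = int(mask.sum())
    return out


# ---------------------------------------------------------------------------
# Allele-frequency statistics


def _allele_freq(calls: pd.Series) -> float:
    """Frequency of the A allele among non-missing calls."""
    dosage = calls.map(_DOSAGE)
    if dosage.notna().sum() == 0:
        raise DomainError("all calls missing at locus")
    return float(dosage.mean())


def minor_allele_freq(calls: pd.Series) -> float:
    p = _allele_freq(calls)
    return min(p, 1.0 - p)


def filter_maf(m: GenotypeMatrix, min_maf: float = 0.10) -> GenotypeMatrix:
    """Keep loci with minor allele frequency >= ``min_maf``; loci with
    no calls at all are dropped with a warning."""
    kept = []
    dropped_empty = 0
    for locus in m.loci:
        calls = m.calls[locus]
        if calls.notna().sum() == 0:
            dropped_empty += 1
            continue
        if minor_allele_freq(calls) >= min_maf - 1e-12:
            kept.append(locus)
    if dropped_empty:
        warnings.warn(
            f"dropped {dropped_empty} all-missing loci", stacklevel=2
        )
    return m.subset_loci(kept)


def gene_diversity(calls: pd.Series) -> float:
    """Expected heterozygosity He = 1 - p^2 - q^2 = 2p(1-p) from the
    allele frequencies of the non-missing calls."""
    p = _allele_freq(calls)
    return 1.0 - p * p - (1.0 - p) * (1.0 - p)


def locus_stats(m: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus call rate, MAF and gene diversity (NaN when no calls)."""
    rows = []
    n = len(m.sample_ids)
    for locus in m.loci:
        calls = m.calls[locus]
        called = int(calls.notna().sum())
        if called:
            maf = minor_allele_freq(calls)
            he = gene_diversity(calls)
        else:
            maf = he = float("nan")
        rows.append(
            {
                "snp_id": locus,
                "call_rate": called / n,
                "maf": maf,
                "gene_diversity": he,
            }
        )
    return pd.DataFrame(rows)


def sample_heterozygosity(
    m: GenotypeMatrix,
) -> tuple[pd.Series, pd.DataFrame]:
    """Observed heterozygosity per sample and per-group mean +/- SE.

    Per sample: fraction of AB among its non-missing calls.  Group SE is
    sd/sqrt(n) over the group's samples (NaN for groups of size < 2).
    Inbred breeding lines should sit far below open-pollinated and wild
    material on this statistic.
    """
    het = (m.calls == "AB").sum(axis=1) / m.calls.notna().sum(axis=1)
    het.name = "observed_het"
    rows = []
    for group, ids in m.samples.groupby("group", sort=True).groups.items():
        vals = het.loc[ids]
        n = len(vals)
        rows.append(
            {
                "group": group,
                "n": n,
                "mean": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan"),
            }
        )
    return het, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Distances and ordination


def nei_distance(
    m: GenotypeMatrix, unbiased: bool = False
) -> pd.DataFrame:
    """Nei's standard genetic distance among individual samples.

    Each sample is treated as a two-allele population: its per-locus
    A-allele frequency is 1, 0.5 or 0.  Over the loci non-missing in
    both samples, with Jx = mean(p^2 + q^2), Jy likewise and
    Jxy = mean(px*py + qx*qy):

        D = -ln( Jxy / sqrt(Jx * Jy) )

    ``unbiased=True`` substitutes the small-sample estimator of
    within-sample homozygosity (2*J - 1 for a single diploid).  A pair
    sharing no alleles anywhere (Jxy = 0) has infinite D; such entries
    are replaced by (max finite D + 1) with a warning so ordination
    stays computable.  Pairs with no shared non-missing loci are NaN.
    """
    dosage = m.dosage().to_numpy(dtype=float)
    ids = m.sample_ids
    n = len(ids)
    if n < 2:
        raise DomainError("need at least two samples")
    D = np.zeros((n, n))
    any_inf = False
    for i in range(n):
        for j in range(i + 1, n):
            px, py = dosage[i], dosage[j]
            shared = ~np.isnan(px) & ~np.isnan(py)
            if not shared.any():
                D[i, j] = D[j, i] = np.nan
                continue
            x, y = px[shared], py[shared]
            jx = np.mean(x * x + (1 - x) * (1 - x))
            jy = np.mean(y * y + (1 - y) * (1 - y))
            jxy = np.mean(x * y + (1 - x) * (1 - y))
            if unbiased:
                jx = 2 * jx - 1
                jy = 2 * jy - 1
            if jxy <= 0 or jx <= 0 or jy <= 0:
                D[i, j] = D[j, i] = np.inf
                any_inf = True
                continue
            identity = jxy / np.sqrt(jx * jy)
            # identical frequency vectors give identity >= 1 only through
            # rounding; clamp so D(x,x)=0 holds exactly
            D[i, j] = D[j, i] = max(0.0, -np.log(min(identity, 1.0)))
    if any_inf:
        finite = D[np.isfinite(D)]
        sentinel = (finite.max() if finite.size else 0.0) + 1.0
        warnings.warn(
            f"pairs with no shared alleles: infinite Nei D replaced by "
            f"sentinel {sentinel:.3f}",
            stacklevel=2,
        )
        D[np.isinf(D)] = sentinel
    return pd.DataFrame(D, index=ids, columns=ids)


@dataclass(frozen=True)
class PcoResult:
    """Principal coordinates: samples x axes coordinates, the positive
    eigenvalues, and percent variance per axis (over positive
    eigenvalues only; negative eigenvalues of non-Euclidean distances
    are dropped and reported)."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    n_negative_eigenvalues: int


def pco(d: pd.DataFrame, atol: float = 1e-8) -> PcoResult:
    """Classical metric scaling (Gower) of a distance matrix.

    Double-centres -D^2/2, eigendecomposes, and scales eigenvectors by
    the square root of their (positive) eigenvalues.
    """
    D = d.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1]:
        raise DomainError("distance matrix must be square")
    if np.isnan(D).any():
        raise DomainError("distance matrix contains missing entries")
    if not np.allclose(D, D.T, atol=atol):
        raise DomainError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=atol):
        raise DomainError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D * D) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(atol, abs(eigval[0]) * 1e-12) if n else atol
    positive = eigval > tol
    n_negative = int((eigval < -tol).sum())
    lam = eigval[positive]
    coords = eigvec[:, positive] * np.sqrt(lam)
    pct = 100.0 * lam / lam.sum() if lam.size else np.array([])
    return PcoResult(
        coordinates=pd.DataFrame(
            coords,
            index=d.index,
            columns=[f"PCO{i + 1}" for i in range(coords.shape[1])],
        ),
        eigenvalues=lam,
        percent_variance=pct,
        n_negative_eigenvalues=n_negative,
    )


# ---------------------------------------------------------------------------
# Evanno delta-K


def evanno_delta_k(
    loglik: Mapping[int, Sequence[float]],
) -> dict[int, float]:
    """Evanno's delta-K from per-K clustering log-likelihood runs.

        deltaK(K) = | mean L(K+1) - 2 mean L(K) + mean L(K-1) | / sd(L(K))

    Defined only at interior K with both neighbours present; K values
    whose run standard deviation is zero are omitted.  Requires at least
    three consecutive K values with >= 2 runs each.
    """
    ks = sorted(loglik)
    if len(ks) < 3:
        raise DomainError("need >= 3 K values")
    for k in ks:
        if len(loglik[k]) < 2:
            raise DomainError(f"K={k}: need >= 2 runs")
    means = {k: float(np.mean(loglik[k])) for k in ks}
    sds = {k: float(np.std(loglik[k], ddof=1)) for k in ks}
    out: dict[int, float] = {}
    for k in ks:
        if k - 1 not in means or k + 1 not in means:
            continue
        if sds[k] == 0.0:
            continue
        out[k] = abs(means[k + 1] - 2 * means[k] + means[k - 1]) / sds[k]
    if not out and not any(k - 1 in means and k + 1 in means for k in ks):
        raise DomainError("K values are not consecutive")
    return out


def read_loglik_tsv(path: str | Path) -> dict[int, list[float]]:
    """Likelihood table TSV with columns K, run, log_likelihood."""
    df = pd.read_csv(path, sep="\t")
    required = {"K", "run", "log_likelihood"}
    if not required <= set(df.columns):
        raise FormatError(f"likelihood table needs columns {sorted(required)}")
    return {
        int(k): grp["log_likelihood"].astype(float).tolist()
        for k, grp in df.groupby("K")
    }
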