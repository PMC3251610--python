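"""Independent brute-force oracles used by the tests.

These deliberately re-derive expected results by the most literal route
available (direct tallies, exhaustive enumeration, Biopython translate)
and stay independent of the implementation paths they check.
"""

import re

from Bio.Seq import Seq

_FREQ_SLACK = 1e-9


def oracle_call_column(counts, ref_base, params):
    """Literal evaluation of the mining criteria on one column.

    ``counts``: genotype -> {allele: count}.  Returns None when no call,
    else (supporting genotypes sorted, alt allele, var_class).
    """
    support = {}
    for g, cnt in counts.items():
        depth = sum(cnt.values())
        if depth < params.min_reads_per_genotype:
            continue  # criterion (i)
        top = max(cnt.values())
        major = sorted(a for a, n in cnt.items() if n == top)[0]
        if top / depth < params.min_within_genotype_freq - _FREQ_SLACK:
            continue  # criterion (iii)
        support[g] = major
    if len(support) < params.min_genotypes:
        return None  # criterion (ii)
    majors = set(support.values())
    if len(majors) < 2:
        return None  # no polymorphism among qualifying genotypes
    non_ref = [a for a in majors if a != ref_base]
    if not non_ref:
        return None
    pooled = {}
    for cnt in counts.values():
        for a, n in cnt.items():
            pooled[a] = pooled.get(a, 0) + n
    alt = min(
        non_ref,
        key=lambda a: (
            -sum(1 for m in support.values() if m == a),
            -pooled.get(a, 0),
            a,
        ),
    )
    is_indel = any(a in "-+" for a in majors | {ref_base, alt})
    return sorted(support), alt, ("INDEL" if is_indel else "SNP")


def oracle_longest_orf(seq, mode):
    """Six-frame longest ORF via Biopython translation plus regex.

    Returns (frame, start_nt, end_nt, length_aa) with coordinates on the
    scanned strand; the stop codon is part of the span only in
    start_to_stop mode (a stop-free run by definition excludes it).
    """
    frames = ("+1", "+2", "+3", "-1", "-2", "-3")
    best_key = (0, 0, 0)
    best = ("+1", 0, 0, 0)
    for fi, frame in enumerate(frames):
        strand = seq if frame[0] == "+" else str(Seq(seq).reverse_complement())
        off = int(frame[1]) - 1
        trimmed = strand[off : off + 3 * ((len(strand) - off) // 3)]
        protein = str(Seq(trimmed).translate())
        pattern = r"M[^*]*" if mode == "start_to_stop" else r"[^*]+"
        for m in re.finditer(pattern, protein):
            length = len(m.group())
            start = off + 3 * m.start()
            end = start + 3 * length
            if mode == "start_to_stop":
                stopped = m.end() < len(protein) and protein[m.end()] == "*"
                if stopped:
                    end += 3
            key = (length, -fi, -start)
            if key > best_key:
                best_key = key
                best = (frame, start, end, length)
    return best


def oracle_select_per_locus(candidates):
    """Exhaustive per-locus argmax under the documented sort key."""
    by_locus = {}
    for c in candidates:
        by_locus.setdefault(c.locus_key, []).append(c)
    out = {}
    for locus, group in by_locus.items():
        out[locus] = min(
            group,
            key=lambda c: (
                -c.variant.n_supporting_genotypes,
                -c.scores.infinium_score,
                c.variant.position,
                c.snp_id,
            ),
        )
    return out
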