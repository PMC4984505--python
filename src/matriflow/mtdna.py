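"""Sequence-level diversity and differentiation for the mtDNA fragment.

Haplotypes are collapsed from the alignment; haplotype diversity uses
Nei's unbiased estimator Hd = n/(n-1) (1 - sum p_i^2), nucleotide
diversity is the mean pairwise difference per site, and population
differentiation is a one-level AMOVA F_ST on haplotype identity
(equivalent to comparing haplotype frequencies) with a permutation test.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .core import Alignment, HaplotypeTable


class UndefinedStatisticError(ValueError):
    """Raised when a statistic needs more samples than supplied."""


def collapse_haplotypes(aln: Alignment, subset=None) -> HaplotypeTable:
    """Collapse identical sequences into a haplotype table.

    ``subset`` optionally restricts to one cohort (or several) first.
    Haplotypes are sorted by decreasing total count, then by sequence.
    """
    if subset is not None:
        aln = aln.subset(subset)
    per_hap: dict[str, Counter] = {}
    for c, s in zip(aln.cohorts, aln.seqs):
        per_hap.setdefault(s, Counter())[c] += 1
    order = sorted(per_hap, key=lambda s: (-sum(per_hap[s].values()), s))
    return HaplotypeTable(
        seqs=tuple(order),
        counts=tuple(dict(per_hap[s]) for s in order),
        site_count=aln.site_count,
    )


def haplotype_diversity(tbl: HaplotypeTable) -> float:
    """Nei's unbiased haplotype (gene) diversity."""
    n = tbl.n
    if n < 2:
        raise UndefinedStatisticError("haplotype diversity needs n >= 2")
    p = tbl.totals / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def _pairwise_diffs(s1: str, s2: str) -> int:
    return sum(a != b for a, b in zip(s1, s2))


def nucleotide_diversity(tbl: HaplotypeTable, site_count: int | None = None) -> float:
    """Mean pairwise nucleotide differences per site (pi).

    Uses the unbiased pairwise form: sum over haplotype pairs of
    count_i * count_j * d_ij, divided by C(n,2) * L.
    """
    n = tbl.n
    if n < 2:
        raise UndefinedStatisticError("nucleotide diversity needs n >= 2")
    L = site_count or tbl.site_count
    tot = tbl.totals
    acc = 0.0
    for i in range(tbl.n_hap):
        for j in range(i + 1, tbl.n_hap):
            acc += tot[i] * tot[j] * _pairwise_diffs(tbl.seqs[i], tbl.seqs[j])
    return float(acc / (n * (n - 1) / 2) / L)


def _amova_fst_identity(hap_idx: np.ndarray, group_idx: np.ndarray, k: int) -> float:
    """One-level AMOVA F_ST with 0/1 haplotype-identity distances.

    With identity distances the sums of squared deviations reduce to
    counts of non-identical pairs, so everything is frequency algebra.
    """
    n = hap_idx.size
    groups = np.unique(group_idx)
    # total SSD = (1/n) * number of unordered non-identical pairs
    cnt_tot = np.bincount(hap_idx)
    pairs_tot = n * (n - 1) / 2 - np.sum(cnt_tot * (cnt_tot - 1) / 2)
    ssd_total = pairs_tot / n
    ssd_within = 0.0
    sizes = []
    for g in groups:
        sel = hap_idx[group_idx == g]
        ng = sel.size
        sizes.append(ng)
        cnt = np.bincount(sel)
        pairs = ng * (ng - 1) / 2 - np.sum(cnt * (cnt - 1) / 2)
        ssd_within += pairs / ng
    sizes = np.asarray(sizes, dtype=float)
    kk = sizes.size
    ssd_among = ssd_total - ssd_within
    df_among, df_within = kk - 1, n - kk
    if df_within <= 0:
        return 0.0
    sigma_w = ssd_within / df_within
    n_prime = (n - np.sum(sizes**2) / n) / df_among
    sigma_a = (ssd_among / df_among - sigma_w) / n_prime
    denom = sigma_a + sigma_w
    return float(sigma_a / denom) if denom > 0 else 0.0


def mtdna_fst(
    aln: Alignment,
    groups: dict[str, str] | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Haplotype-frequency F_ST between labelled groups, permutation p.

    ``groups`` maps individual id -> group label; by default the cohort
    labels are used.  p = (#permuted >= observed + 1)/(n_perm + 1).
    """
    labels = (
        np.array([groups[i] for i in aln.ids])
        if groups is not None
        else np.array(aln.cohorts)
    )
    uniq, group_idx = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise UndefinedStatisticError("F_ST needs at least two groups")
    for g in range(uniq.size):
        if (group_idx == g).sum() < 2:
            raise UndefinedStatisticError(
                f"group {uniq[g]!r} has fewer than 2 sequences"
            )
    hap_of = {s: i for i, s in enumerate(dict.fromkeys(aln.seqs))}
    hap_idx = np.array([hap_of[s] for s in aln.seqs])

    obs = _amova_fst_identity(hap_idx, group_idx, uniq.size)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = group_idx.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if _amova_fst_identity(hap_idx, perm, uniq.size) >= obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return obs, float(p)


def diversity_report(aln: Alignment) -> dict:
    """Per-cohort n, nHap, S, Hd, pi plus the pooled values."""
    out = {}
    for cohort in aln.cohort_labels() + ["all"]:
        tbl = collapse_haplotypes(aln, None if cohort == "all" else cohort)
        out[cohort] = {
            "n": tbl.n,
            "nHap": tbl.n_hap,
            "S": tbl.segregating_sites,
            "Hd": round(haplotype_diversity(tbl), 4) if tbl.n >= 2 else None,
            "pi": round(nucleotide_diversity(tbl), 5) if tbl.n >= 2 else None,
        }
    return out
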