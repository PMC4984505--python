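"""Genotype-level statistics for the 22-locus microsatellite panel.

Covers marker validation (null-allele EM, island-model neutrality scan,
genotypic linkage screen), diversity (Nei unbiased He, rarefied allelic
richness, Weir & Cockerham F_IS), differentiation (multilocus W&C theta
with permutation tests, two-level AMOVA, Mantel test), individual
homozygosity indices (internal relatedness IR and homozygosity-by-loci
HL, with deme-specific allele frequencies), the bottleneck
heterozygosity-excess test under a two-phase mutation model, Evanno's
delta-K, and Narum's FDR-corrected alpha.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .core import MISSING, GenotypeMatrix

# ------------------------------------------------------------ frequencies


def allele_frequencies(
    g: GenotypeMatrix, locus: int, individuals=None
) -> dict[int, float]:
    counts = g.allele_counts(locus, individuals)
    tot = sum(counts.values())
    return {a: c / tot for a, c in counts.items()} if tot else {}


# ------------------------------------------------------------- diversity


def expected_het(g: GenotypeMatrix, deme: str | None = None) -> pd.Series:
    """Nei's unbiased expected heterozygosity per locus (one deme)."""
    idx = g.deme_indices(deme) if deme else np.arange(g.n)
    out = {}
    for l, name in enumerate(g.loci):
        counts = g.allele_counts(l, idx)
        n_genes = sum(counts.values())
        if n_genes < 2:
            out[name] = np.nan
            continue
        p = np.array(list(counts.values())) / n_genes
        out[name] = n_genes / (n_genes - 1) * (1.0 - np.sum(p**2))
    return pd.Series(out, name="He")


def observed_het(g: GenotypeMatrix, deme: str | None = None) -> pd.Series:
    idx = g.deme_indices(deme) if deme else np.arange(g.n)
    gt = g.genotypes[idx]
    out = {}
    for l, name in enumerate(g.loci):
        typed = gt[:, l, 0] != MISSING
        if typed.sum() == 0:
            out[name] = np.nan
        else:
            out[name] = float(
                (gt[typed, l, 0] != gt[typed, l, 1]).mean()
            )
    return pd.Series(out, name="Ho")


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_ar(
    g: GenotypeMatrix, deme: str | None, g_genes: int
) -> pd.Series:
    """Allelic richness rarefied to ``g_genes`` gene copies per locus.

    Hypergeometric rarefaction: sum over alleles of the probability that
    the allele appears in a random subsample of g_genes copies.
    """
    idx = g.deme_indices(deme) if deme else np.arange(g.n)
    out = {}
    for l, name in enumerate(g.loci):
        counts = g.allele_counts(l, idx)
        N = sum(counts.values())
        if N == 0:
            out[name] = np.nan
            continue
        if g_genes > N:
            raise ValueError(
                f"g_genes={g_genes} exceeds {N} available copies at {name}"
            )
        ar = 0.0
        for Ni in counts.values():
            if N - Ni < g_genes:
                ar += 1.0
            else:
                ar += 1.0 - math.exp(
                    _log_comb(N - Ni, g_genes) - _log_comb(N, g_genes)
                )
        out[name] = ar
    return pd.Series(out, name="Ar")


# ------------------------------------------ Weir & Cockerham components


def _wc_components(g: GenotypeMatrix, deme_idx_sets: list[np.ndarray]):
    """Per-locus sums of W&C (1984) a, b, c over alleles.

    Returns arrays (sum_a, sum_b, sum_c) of length n_loci.  Loci where
    fewer than two demes are typed contribute zeros.
    """
    r = len(deme_idx_sets)
    sum_a = np.zeros(g.n_loci)
    sum_b = np.zeros(g.n_loci)
    sum_c = np.zeros(g.n_loci)
    for l in range(g.n_loci):
        ns, freqs, hets = [], [], []
        alleles: set[int] = set()
        for idx in deme_idx_sets:
            gt = g.genotypes[idx, l, :]
            typed = gt[:, 0] != MISSING
            n_i = int(typed.sum())
            if n_i == 0:
                continue
            gt = gt[typed]
            cnt: dict[int, int] = {}
            het: dict[int, int] = {}
            for a, b in gt:
                cnt[a] = cnt.get(a, 0) + 1
                cnt[b] = cnt.get(b, 0) + 1
                if a != b:
                    het[a] = het.get(a, 0) + 1
                    het[b] = het.get(b, 0) + 1
            ns.append(n_i)
            freqs.append({a: c / (2 * n_i) for a, c in cnt.items()})
            hets.append({a: h / n_i for a, h in het.items()})
            alleles.update(cnt)
        ri = len(ns)
        if ri < 2 or len(alleles) < 2:
            continue
        ns = np.array(ns, dtype=float)
        nbar = ns.mean()
        nc = (ri * nbar - np.sum(ns**2) / (ri * nbar)) / (ri - 1)
        for al in sorted(alleles):
            p_i = np.array([f.get(al, 0.0) for f in freqs])
            h_i = np.array([h.get(al, 0.0) for h in hets])
            pbar = np.sum(ns * p_i) / (ri * nbar)
            s2 = np.sum(ns * (p_i - pbar) ** 2) / ((ri - 1) * nbar)
            hbar = np.sum(ns * h_i) / (ri * nbar)
            if nbar <= 1:
                continue
            a = (nbar / nc) * (
                s2
                - (pbar * (1 - pbar) - (ri - 1) / ri * s2 - hbar / 4)
                / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (ri - 1) / ri * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            sum_a[l] += a
            sum_b[l] += b
            sum_c[l] += c
    return sum_a, sum_b, sum_c


def wc_theta(g: GenotypeMatrix, demes: list[str] | None = None) -> float:
    """Multilocus Weir & Cockerham theta (F_ST) across the given demes."""
    demes = demes or g.deme_labels()
    sets = [g.deme_indices(d) for d in demes]
    a, b, c = _wc_components(g, sets)
    denom = np.sum(a + b + c)
    return float(np.sum(a) / denom) if denom != 0 else 0.0


def fis(g: GenotypeMatrix, deme: str | None = None) -> float:
    """Weir & Cockerham's multilocus f (F_IS) within one deme."""
    idx = g.deme_indices(deme) if deme else np.arange(g.n)
    # with a single deme the b and c components carry all information
    sub = GenotypeMatrix(
        ids=[g.ids[i] for i in idx],
        demes=["one"] * len(idx),
        loci=list(g.loci),
        genotypes=g.genotypes[idx],
    )
    sum_b = 0.0
    sum_c = 0.0
    for l in range(sub.n_loci):
        gt = sub.genotypes[:, l, :]
        typed = gt[:, 0] != MISSING
        n_i = int(typed.sum())
        if n_i < 2:
            continue
        gt = gt[typed]
        cnt: dict[int, int] = {}
        het: dict[int, int] = {}
        for x, y in gt:
            cnt[x] = cnt.get(x, 0) + 1
            cnt[y] = cnt.get(y, 0) + 1
            if x != y:
                het[x] = het.get(x, 0) + 1
                het[y] = het.get(y, 0) + 1
        for al, c_al in cnt.items():
            p = c_al / (2 * n_i)
            h = het.get(al, 0) / n_i
            b = (n_i / (n_i - 1)) * (
                p * (1 - p) - (2 * n_i - 1) / (4 * n_i) * h
            )
            sum_b += b
            sum_c += h / 2
    denom = sum_b + sum_c
    return float(sum_b / denom) if denom != 0 else 0.0


def pairwise_fst(
    g: GenotypeMatrix,
    deme_a: str,
    deme_b: str,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """W&C theta between two demes with a permutation p-value."""
    ia, ib = g.deme_indices(deme_a), g.deme_indices(deme_b)
    if ia.size < 5 or ib.size < 5:
        raise ValueError("each deme needs at least 5 individuals")
    obs = float(
        np.sum((comp := _wc_components(g, [ia, ib]))[0])
        / max(np.sum(comp[0] + comp[1] + comp[2]), 1e-300)
    )
    pool = np.concatenate([ia, ib])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        pa, pb = perm[: ia.size], perm[ia.size:]
        a, b, c = _wc_components(g, [pa, pb])
        denom = np.sum(a + b + c)
        theta = np.sum(a) / denom if denom != 0 else 0.0
        if theta >= obs:
            hits += 1
    return obs, (hits + 1) / (n_perm + 1)


# ----------------------------------------------------------------- AMOVA


@dataclass
class AmovaResult:
    f_ct: float
    f_sc: float
    f_st: float
    p_ct: float
    p_sc: float
    variance_components: tuple[float, float, float]  # (among-group, among-deme, within)


def _amova_ss(g: GenotypeMatrix, deme_of: np.ndarray, group_of_deme: dict):
    """Sums of squares from allele-identity distances, summed over loci."""
    demes = np.unique(deme_of)
    groups = sorted({group_of_deme[d] for d in demes})
    ssd_t = ssd_wg = ssd_wd = 0.0
    N_genes = 0.0
    n_d: dict = {}
    for l in range(g.n_loci):
        gt = g.genotypes[:, l, :]
        typed = gt[:, 0] != MISSING

        def pairs_not_identical(mask):
            alleles = gt[mask].ravel()
            n = alleles.size
            if n < 2:
                return 0.0, n
            _, cnt = np.unique(alleles, return_counts=True)
            return n * (n - 1) / 2 - np.sum(cnt * (cnt - 1) / 2), n

        tot_pairs, n_tot = pairs_not_identical(typed)
        ssd_t += tot_pairs / max(n_tot, 1)
        for grp in groups:
            m = typed & np.isin(
                deme_of, [d for d in demes if group_of_deme[d] == grp]
            )
            p, n = pairs_not_identical(m)
            if n:
                ssd_wg += p / n
        for d in demes:
            m = typed & (deme_of == d)
            p, n = pairs_not_identical(m)
            if n:
                ssd_wd += p / n
            n_d[d] = n_d.get(d, 0) + n
        N_genes += n_tot
    return ssd_t, ssd_wg, ssd_wd, N_genes, n_d


def amova(
    g: GenotypeMatrix,
    group_of_deme: dict[str, str],
    n_perm: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level AMOVA (groups / demes / within) on allele identity.

    F_CT is tested by permuting whole demes among groups; F_SC by
    permuting individuals among demes within groups.
    """
    deme_of = np.array(g.demes)
    demes = sorted(set(g.demes))
    groups = sorted(set(group_of_deme[d] for d in demes))
    if len(groups) < 2 or len(demes) <= len(groups):
        raise ValueError("need >=2 groups and more demes than groups")

    def components(deme_arr, g_of_d):
        ssd_t, ssd_wg, ssd_wd, N, n_d = _amova_ss(g, deme_arr, g_of_d)
        ds = sorted(n_d)
        G = len(set(g_of_d[d] for d in ds))
        D = len(ds)
        df_ag, df_ap, df_wd = G - 1, D - G, N - D
        ms_ag = (ssd_t - ssd_wg) / df_ag
        ms_ap = (ssd_wg - ssd_wd) / df_ap
        ms_wd = ssd_wd / df_wd
        n_g = {grp: sum(n_d[d] for d in ds if g_of_d[d] == grp) for grp in set(g_of_d.values())}
        s_dg = {
            grp: sum(n_d[d] ** 2 for d in ds if g_of_d[d] == grp)
            for grp in n_g
        }
        n1 = (N - sum(s_dg[grp] / n_g[grp] for grp in n_g)) / df_ap
        n2 = (
            sum(s_dg[grp] / n_g[grp] for grp in n_g)
            - sum(n_d[d] ** 2 for d in ds) / N
        ) / df_ag
        n3 = (N - sum(v**2 for v in n_g.values()) / N) / df_ag
        sig_c = ms_wd
        sig_b = (ms_ap - sig_c) / n1
        sig_a = (ms_ag - sig_c - n2 * sig_b) / n3
        tot = sig_a + sig_b + sig_c
        f_ct = sig_a / tot if tot > 0 else 0.0
        f_sc = sig_b / (sig_b + sig_c) if (sig_b + sig_c) > 0 else 0.0
        f_st = (sig_a + sig_b) / tot if tot > 0 else 0.0
        return f_ct, f_sc, f_st, (sig_a, sig_b, sig_c)

    f_ct, f_sc, f_st, sig = components(deme_of, group_of_deme)
    rng = np.random.default_rng(seed)

    hits_ct = 0
    grp_list = [group_of_deme[d] for d in demes]
    for _ in range(n_perm):
        perm = rng.permutation(grp_list)
        g_of_d = dict(zip(demes, perm))
        if len(set(g_of_d.values())) < 2:
            continue
        try:
            c, _, _, _ = components(deme_of, g_of_d)
        except (ZeroDivisionError, ValueError):
            continue
        if c >= f_ct:
            hits_ct += 1
    p_ct = (hits_ct + 1) / (n_perm + 1)

    hits_sc = 0
    for _ in range(n_perm):
        perm = deme_of.copy()
        for grp in groups:
            members = np.where(
                np.isin(deme_of, [d for d in demes if group_of_deme[d] == grp])
            )[0]
            perm[members] = rng.permutation(deme_of[members])
        s = components(perm, group_of_deme)[1]
        if s >= f_sc:
            hits_sc += 1
    p_sc = (hits_sc + 1) / (n_perm + 1)
    return AmovaResult(f_ct, f_sc, f_st, p_ct, p_sc, sig)


# --------------------------------------------- individual-level indices


def internal_relatedness(
    genotype: np.ndarray,
    freqs: list[dict[int, float]],
    homozygous_only: bool = False,
) -> float:
    """Amos' internal relatedness for one individual.

    IR = (2H - sum f) / (2N - sum f) with H homozygous loci, N typed
    loci, and sum f the summed frequencies of the individual's alleles
    (all carried alleles by default; ``homozygous_only`` restricts the
    sum to the allele of each homozygous locus, counted once).
    """
    H = 0
    N = 0
    sf = 0.0
    for l, (a, b) in enumerate(genotype):
        if a == MISSING:
            continue
        N += 1
        if a == b:
            H += 1
            if homozygous_only:
                sf += freqs[l].get(int(a), 0.0)
            else:
                sf += 2 * freqs[l].get(int(a), 0.0)
        elif not homozygous_only:
            sf += freqs[l].get(int(a), 0.0) + freqs[l].get(int(b), 0.0)
    if N == 0 or (2 * N - sf) == 0:
        return np.nan
    return (2 * H - sf) / (2 * N - sf)


def homozygosity_by_loci(
    genotype: np.ndarray, exp_het: np.ndarray
) -> float:
    """Aparicio's HL: sum E over homozygous loci / sum E over typed loci."""
    eh = ej = 0.0
    for l, (a, b) in enumerate(genotype):
        if a == MISSING or np.isnan(exp_het[l]):
            continue
        if a == b:
            eh += exp_het[l]
        else:
            ej += exp_het[l]
    denom = eh + ej
    return eh / denom if denom > 0 else np.nan


def individual_indices(
    g: GenotypeMatrix,
    include_self: bool = True,
    homozygous_only: bool = False,
    min_typed: float = 0.5,
) -> pd.DataFrame:
    """IR and HL per individual, with deme-specific allele frequencies.

    Individuals typed at fewer than ``min_typed`` of the loci get NaN.
    ``include_self=False`` recomputes each locus frequency without the
    focal individual's two copies.
    """
    rows = []
    for deme in g.deme_labels():
        idx = g.deme_indices(deme)
        freqs = [allele_frequencies(g, l, idx) for l in range(g.n_loci)]
        counts = [g.allele_counts(l, idx) for l in range(g.n_loci)]
        ngenes = [sum(c.values()) for c in counts]
        eh = np.array(
            [
                (
                    n / (n - 1) * (1 - sum((c / n) ** 2 for c in cnt.values()))
                    if n >= 2
                    else np.nan
                )
                for cnt, n in zip(counts, ngenes)
            ]
        )
        for i in idx:
            gt = g.genotypes[i]
            typed = (gt[:, 0] != MISSING).mean()
            if typed < min_typed:
                rows.append(
                    {"id": g.ids[i], "deme": deme, "IR": np.nan, "HL": np.nan}
                )
                continue
            if include_self:
                f_use = freqs
            else:
                f_use = []
                for l in range(g.n_loci):
                    cnt = dict(counts[l])
                    n = ngenes[l]
                    a, b = gt[l]
                    if a != MISSING:
                        cnt[int(a)] = cnt.get(int(a), 0) - 1
                        cnt[int(b)] = cnt.get(int(b), 0) - 1
                        n -= 2
                    f_use.append(
                        {al: c / n for al, c in cnt.items() if c > 0}
                        if n > 0
                        else {}
                    )
            rows.append(
                {
                    "id": g.ids[i],
                    "deme": deme,
                    "IR": internal_relatedness(gt, f_use, homozygous_only),
                    "HL": homozygosity_by_loci(gt, eh),
                }
            )
    return pd.DataFrame(rows)


def deme_diversity(g: GenotypeMatrix, rarefy_to: int | None = None) -> pd.DataFrame:
    """Per-deme He, Ar, F_IS, mean IR, mean HL summary table."""
    ind = individual_indices(g)
    if rarefy_to is None:
        rarefy_to = min(
            int(
                min(
                    sum(g.allele_counts(l, g.deme_indices(d)).values())
                    for l in range(g.n_loci)
                )
            )
            for d in g.deme_labels()
        )
    rows = []
    for d in g.deme_labels():
        sub = ind[ind["deme"] == d]
        rows.append(
            {
                "deme": d,
                "n": int(len(sub)),
                "He": float(expected_het(g, d).mean()),
                "Ar": float(rarefied_ar(g, d, rarefy_to).mean()),
                "F_IS": fis(g, d),
                "mean_IR": float(sub["IR"].mean()),
                "mean_HL": float(sub["HL"].mean()),
            }
        )
    return pd.DataFrame(rows)


def rir_rhl_diagnostic(deme_stats: pd.DataFrame) -> dict:
    """Correlations of deme-mean IR and HL with deme F_IS.

    Under asymmetric migration immigrant rare alleles weaken the IR-F_IS
    correlation more than the HL-F_IS one, so R_HL > R_IR is the expected
    signature.  Returns both coefficients, their p-values and the
    contrast R_HL - R_IR.
    """
    d = deme_stats.dropna(subset=["mean_IR", "mean_HL", "F_IS"])
    if (
        len(d) < 3
        or np.isclose(d["F_IS"].var(), 0)
        or np.isclose(d["mean_IR"].var(), 0)
        or np.isclose(d["mean_HL"].var(), 0)
    ):
        warnings.warn("degenerate deme table: correlations undefined")
        return {
            "R_IR": np.nan,
            "R_HL": np.nan,
            "p_IR": np.nan,
            "p_HL": np.nan,
            "contrast": np.nan,
        }
    r_ir, p_ir = stats.pearsonr(d["mean_IR"], d["F_IS"])
    r_hl, p_hl = stats.pearsonr(d["mean_HL"], d["F_IS"])
    return {
        "R_IR": float(r_ir),
        "R_HL": float(r_hl),
        "p_IR": float(p_ir),
        "p_HL": float(p_hl),
        "contrast": float(r_hl - r_ir),
    }


# ------------------------------------------------------ null-allele EM


def null_allele_em(
    g: GenotypeMatrix,
    locus: int,
    include_missing: bool = False,
    tol: float = 1e-6,
    max_iter: int = 5000,
) -> float:
    """Dempster EM estimate of the null-allele frequency at one locus.

    Observed homozygotes are mixtures of true homozygotes and
    visible/null heterozygotes; with ``include_missing`` blank genotypes
    are treated as null homozygotes.  Returns the converged null
    frequency (0 for a monomorphic locus).
    """
    gt = g.genotypes[:, locus, :]
    typed = gt[:, 0] != MISSING
    n_typed = int(typed.sum())
    if n_typed < 10:
        raise ValueError("need at least 10 typed individuals")
    obs = gt[typed]
    alleles = sorted(set(obs.ravel().tolist()))
    if len(alleles) < 2:
        return 0.0
    ai = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    n_het = np.zeros((k, k))
    n_hom = np.zeros(k)
    for a, b in obs:
        if a == b:
            n_hom[ai[a]] += 1
        else:
            n_het[ai[a], ai[b]] += 1
    n_blank = int((~typed).sum()) if include_missing else 0
    n_eff = n_typed + n_blank

    p = np.full(k, 1.0 / (k + 1))
    pn = 1.0 / (k + 1)
    for _ in range(max_iter):
        counts = np.zeros(k)
        cn = 0.0
        counts += n_het.sum(axis=1) + n_het.sum(axis=0)
        # split observed homozygotes between (i,i) and (i,null)
        denom = p + 2 * pn
        w_true = np.where(denom > 0, p / denom, 1.0)
        counts += n_hom * (2 * w_true + (1 - w_true))
        cn += np.sum(n_hom * (1 - w_true))
        cn += 2 * n_blank
        total = counts.sum() + cn
        new_p = counts / total
        new_pn = cn / total
        if max(np.abs(new_p - p).max(), abs(new_pn - pn)) < tol:
            p, pn = new_p, new_pn
            break
        p, pn = new_p, new_pn
    return float(pn)


# ------------------------------------------------------ bottleneck test


def _coalescent_tpm_locus(
    n: int, theta: float, p_smm: float, var_tpm: float, rng
) -> np.ndarray:
    """One neutral locus: n gene copies under the coalescent with TPM.

    Mutations are single-step with probability ``p_smm``; otherwise the
    step is 1 + Geometric with variance ``var_tpm``; direction is
    symmetric.  Returns allele states of the sample.
    """
    import random as _pyrandom

    # geometric parameter giving the requested extra-step variance
    if var_tpm > 0:
        pg = (-1 + math.sqrt(1 + 4 * var_tpm)) / (2 * var_tpm)
        pg = min(max(pg, 1e-6), 1.0)
    else:
        pg = 1.0
    pyr = _pyrandom.Random(int(rng.integers(1, 2**31 - 1)))
    parent = np.full(2 * n - 1, -1, dtype=int)
    node_time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += pyr.expovariate(k * (k - 1) / 2.0)
        a = active.pop(pyr.randrange(len(active)))
        b = active.pop(pyr.randrange(len(active)))
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        active.append(nxt)
        nxt += 1
    # branch lengths and mutation counts, vectorised
    has_parent = parent >= 0
    blen = np.where(has_parent, node_time[parent] - node_time, 0.0)
    nmut = rng.poisson(theta / 2.0 * blen)
    total = int(nmut.sum())
    if total:
        steps = np.ones(total, dtype=int)
        multi = rng.random(total) >= p_smm
        if multi.any():
            steps[multi] = 1 + rng.geometric(pg, size=int(multi.sum()))
        steps *= np.where(rng.random(total) < 0.5, 1, -1)
    # accumulate states root-down (nodes are created in time order, so
    # descending ids visit parents before children)
    state = np.zeros(2 * n - 1, dtype=int)
    offsets = np.concatenate([[0], np.cumsum(nmut)]).astype(int)
    for v in range(2 * n - 3, -1, -1):
        s = state[parent[v]]
        if nmut[v]:
            s += int(steps[offsets[v]:offsets[v + 1]].sum())
        state[v] = s
    return state[:n]


def _heq_conditional(
    n: int, k_obs: int, p_smm: float, var_tpm: float, n_sim: int, rng
) -> np.ndarray:
    """Equilibrium He distribution conditional on the observed allele count.

    Theta is tuned so simulated allele counts bracket ``k_obs``; only
    simulations with exactly k_obs alleles are retained.
    """
    # coarse search for a theta producing k_obs alleles on average
    grid = np.exp(np.linspace(np.log(0.05), np.log(200), 16))
    mean_k = []
    for th in grid:
        ks = [
            len(np.unique(_coalescent_tpm_locus(n, th, p_smm, var_tpm, rng)))
            for _ in range(20)
        ]
        mean_k.append(np.mean(ks))
    theta0 = grid[int(np.argmin(np.abs(np.array(mean_k) - k_obs)))]

    hes = []
    attempts = 0
    while len(hes) < n_sim and attempts < 50 * n_sim:
        attempts += 1
        sam = _coalescent_tpm_locus(n, theta0, p_smm, var_tpm, rng)
        vals, cnt = np.unique(sam, return_counts=True)
        if len(vals) != k_obs:
            continue
        p = cnt / n
        hes.append(n / (n - 1) * (1 - np.sum(p**2)))
    return np.array(hes)


@dataclass
class BottleneckResult:
    per_locus: pd.DataFrame      # He_obs, Heq_mean, Heq_sd, excess flag
    wilcoxon_p_excess: float     # one-tailed, H1: heterozygosity excess
    mode_shift: bool             # True if allele-frequency mode shifted


def bottleneck_test(
    g: GenotypeMatrix,
    deme: str | None = None,
    p_smm: float = 0.10,
    var_tpm: float = 0.10,
    n_coalsim: int = 1000,
    seed: int | None = None,
) -> BottleneckResult:
    """Heterozygosity-excess bottleneck test under a two-phase model.

    For each polymorphic locus the mutation-drift-equilibrium He is
    simulated conditional on the observed allele count; a one-tailed
    Wilcoxon signed-rank over loci tests for systematic excess, and the
    pooled allele-frequency spectrum is checked for a mode shift away
    from the rare-allele class.  ``p_smm`` is the fraction of mutations
    forced to be strictly single-step.
    """
    rng = np.random.default_rng(seed)
    idx = g.deme_indices(deme) if deme else np.arange(g.n)
    rows = []
    freqs_all = []
    for l, name in enumerate(g.loci):
        counts = g.allele_counts(l, idx)
        n_genes = sum(counts.values())
        k = len(counts)
        freqs_all.extend([c / n_genes for c in counts.values()])
        if k < 2 or n_genes < 4:
            continue  # fixed or undersampled loci excluded
        p = np.array(list(counts.values())) / n_genes
        he_obs = n_genes / (n_genes - 1) * (1 - np.sum(p**2))
        heq = _heq_conditional(n_genes, k, p_smm, var_tpm, n_coalsim, rng)
        if heq.size < 20:
            continue
        rows.append(
            {
                "locus": name,
                "k": k,
                "He_obs": he_obs,
                "Heq_mean": float(heq.mean()),
                "Heq_sd": float(heq.std(ddof=1)),
                "p_excess": float((heq < he_obs).mean()),
                "excess": he_obs > heq.mean(),
            }
        )
    per_locus = pd.DataFrame(rows)
    if len(per_locus) >= 5:
        delta = per_locus["He_obs"] - per_locus["Heq_mean"]
        w = stats.wilcoxon(delta, alternative="greater")
        p_wil = float(w.pvalue)
    else:
        p_wil = np.nan
    bins = np.histogram(freqs_all, bins=np.linspace(0, 1, 11))[0]
    mode_shift = bool(np.argmax(bins) != 0)
    return BottleneckResult(per_locus, p_wil, mode_shift)


# ------------------------------------------------------------ FDIST scan


def fdist_scan(
    g: GenotypeMatrix,
    n_sims: int = 5000,
    n_demes_sim: int = 12,
    mutation: str = "smm",
    envelope: float = 0.95,
    seed: int | None = None,
    layers_per_tree: int = 5,
) -> pd.DataFrame:
    """Island-model neutrality scan of per-locus F_ST against He.

    Neutral loci are simulated with msprime under a ``n_demes_sim``-island
    model whose migration rate is set so the expected F_ST matches the
    trimmed mean of the observed per-locus values; per-simulated-locus
    (He, F_ST) pairs form the null cloud, and each observed locus gets
    the empirical quantile of its F_ST among simulated loci of similar He.
    Loci outside the central ``envelope`` band are flagged.  To keep the
    null cloud affordable each simulated ancestry carries
    ``layers_per_tree`` independent mutation layers (mildly correlated
    pseudo-loci; the envelope quantiles are insensitive to this).
    """
    import msprime

    demes = g.deme_labels()
    if len(demes) < 2:
        raise ValueError("need at least two demes")
    sets = [g.deme_indices(d) for d in demes]
    sizes = [s.size for s in sets]

    a, b, c = _wc_components(g, sets)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus_fst = np.where((a + b + c) != 0, a / (a + b + c), 0.0)
    he_obs = np.array(
        [float(np.nanmean([expected_het(g, d)[n] for d in demes])) for n in g.loci]
    )
    trim = stats.trim_mean(per_locus_fst[~np.isnan(per_locus_fst)], 0.1)
    # numerical floor: below F_ST ~ 0.01 the implied island migration
    # rate explodes (simulation cost ~ 4Nm) while the envelope is
    # indistinguishable from the near-panmictic band
    target = float(np.clip(trim, 0.01, 0.5))

    d = n_demes_sim
    # island model: F_ST ~ 1 / (1 + 4Nm (d/(d-1))^2)
    Ne = 2500.0
    four_nm = (1.0 / target - 1.0) / (d / (d - 1)) ** 2
    m = four_nm / (4 * Ne)
    demog = msprime.Demography.island_model([Ne] * d, migration_rate=m)
    samples = {i: sizes[i] for i in range(len(sizes))}
    rng = np.random.default_rng(seed)
    sim_he, sim_fst = [], []
    n_trees = max(1, int(np.ceil(n_sims / layers_per_tree)))
    anc = msprime.sim_ancestry(
        samples=samples,
        demography=demog,
        sequence_length=1,
        num_replicates=n_trees,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    # the mutation model is rate-independent: build it once
    model = (
        msprime.SMM(lo=1, hi=200)
        if mutation == "smm"
        else msprime.InfiniteAlleles()
    )
    mut_seed = int(rng.integers(1, 2**31 - 1))
    pops = np.repeat(np.arange(len(sizes)), [2 * s for s in sizes])
    layer_i = 0
    for ts in anc:
        for _ in range(layers_per_tree):
            layer_i += 1
            # metapopulation-scaled locus diversity varied across
            # simulated loci so the null cloud spans the He axis
            theta_locus = float(rng.uniform(0.2, 8.0))
            mu = theta_locus / (4 * Ne * d)
            mts = msprime.sim_mutations(
                ts, rate=mu, model=model,
                random_seed=mut_seed + layer_i,
            )
            var = next(mts.variants(), None)
            if var is None:
                continue
            geno = var.genotypes
            # haploid-level W&C on gene copies in the sampled demes
            he_i, fst_i = _haploid_he_fst(geno, pops)
            if not np.isnan(fst_i):
                sim_he.append(he_i)
                sim_fst.append(fst_i)
    sim_he = np.array(sim_he)
    sim_fst = np.array(sim_fst)

    lo_q, hi_q = (1 - envelope) / 2, 1 - (1 - envelope) / 2
    rows = []
    for name, he, f in zip(g.loci, he_obs, per_locus_fst):
        if sim_he.size < 50:
            rows.append({"locus": name, "He": he, "F_ST": f, "quantile": np.nan,
                         "outlier_high": False, "outlier_low": False})
            continue
        w = np.argsort(np.abs(sim_he - he))[: max(200, sim_he.size // 20)]
        q = float((sim_fst[w] < f).mean())
        rows.append(
            {
                "locus": name,
                "He": he,
                "F_ST": f,
                "quantile": q,
                "outlier_high": q > hi_q,
                "outlier_low": q < lo_q,
            }
        )
    return pd.DataFrame(rows)


def _haploid_he_fst(geno: np.ndarray, pops: np.ndarray):
    """Mean within-deme He and haploid W&C theta for one simulated locus."""
    labels = np.unique(pops)
    r = labels.size
    ns = np.array([(pops == l).sum() for l in labels], dtype=float)
    nbar = ns.mean()
    nc = (r * nbar - np.sum(ns**2) / (r * nbar)) / (r - 1)
    alleles = np.unique(geno)
    if alleles.size < 2:
        return np.nan, np.nan
    sum_a = sum_b = 0.0
    hes = []
    for l, n_i in zip(labels, ns):
        gl = geno[pops == l]
        _, cnt = np.unique(gl, return_counts=True)
        p = cnt / n_i
        hes.append(n_i / (n_i - 1) * (1 - np.sum(p**2)))
    for al in alleles:
        p_i = np.array([(geno[pops == l] == al).mean() for l in labels])
        pbar = np.sum(ns * p_i) / (r * nbar)
        s2 = np.sum(ns * (p_i - pbar) ** 2) / ((r - 1) * nbar)
        # haploid variant (no heterozygotes): a and b components only
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2)
        sum_a += a
        sum_b += b
    denom = sum_a + sum_b
    fst = sum_a / denom if denom != 0 else np.nan
    return float(np.mean(hes)), fst


# ------------------------------------------------- Evanno, FDR, Mantel


def evanno_delta_k(L: pd.DataFrame) -> pd.Series:
    """Evanno's delta-K from a (K x replicate) ln-likelihood table.

    delta-K(K) = mean over replicates |L(K+1) - 2 L(K) + L(K-1)| divided
    by the SD of L(K) across replicates; defined for interior K only.
    A zero SD at some K makes delta-K undefined there (raises).
    """
    Ks = np.asarray(sorted(L.index))
    if np.any(np.diff(Ks) != 1):
        raise ValueError("K values must be consecutive integers")
    out = {}
    for K in Ks[1:-1]:
        second = L.loc[K + 1] - 2 * L.loc[K] + L.loc[K - 1]
        sd = float(L.loc[K].std(ddof=1))
        if np.isclose(sd, 0):
            raise ZeroDivisionError(
                f"replicate likelihoods at K={K} are constant; delta-K undefined"
            )
        out[int(K)] = float(np.mean(np.abs(second))) / sd
    return pd.Series(out, name="deltaK")


def fdr_correct(pvalues, alpha: float = 0.05):
    """Narum's FDR-adjusted alpha: alpha / sum_{i=1..k} 1/i.

    Returns (boolean reject decisions, adjusted alpha).
    """
    p = np.asarray(pvalues, dtype=float)
    k = p.size
    alpha_adj = alpha / np.sum(1.0 / np.arange(1, k + 1))
    return p <= alpha_adj, float(alpha_adj)


def mantel(
    m1: np.ndarray,
    m2: np.ndarray,
    n_perm: int = 9999,
    seed: int | None = None,
    statistic: str = "r",
) -> tuple[float, float]:
    """Mantel matrix correlation with a row/column permutation null.

    ``statistic`` 'r' = Pearson correlation of off-diagonal entries,
    'z' = raw cross-product sum.  For matrices small enough that every
    permutation fits in ``n_perm`` the p-value is exact (all n!
    relabellings enumerated), else (hits+1)/(n_perm+1) over random
    permutations.  One-tailed (greater).
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    n = m1.shape[0]
    if m1.shape != (n, n) or m2.shape != (n, n):
        raise ValueError("matrices must be square and equal-sized")
    iu = np.triu_indices(n, 1)

    def stat(perm):
        m2p = m2[np.ix_(perm, perm)]
        x, y = m1[iu], m2p[iu]
        if statistic == "z":
            return float(np.sum(x * y))
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    ident = np.arange(n)
    obs = stat(ident)
    if math.factorial(n) <= n_perm:
        vals = [stat(np.array(p)) for p in itertools.permutations(range(n))]
        p = float(np.mean([v >= obs - 1e-12 for v in vals]))
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            if stat(rng.permutation(n)) >= obs - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    return obs, p


# ----------------------------------------------- genotypic LD screening


def linkage_screen(
    g: GenotypeMatrix,
    n_perm: int = 200,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genotypic linkage disequilibrium screen over locus pairs.

    For each pair the G statistic (log-likelihood ratio of the genotype
    contingency table) is compared with its permutation null obtained by
    shuffling one locus' genotypes across individuals.  Returns a
    per-pair table with p-values; intended as a summary-level QC step.
    """
    rng = np.random.default_rng(seed)

    def g_stat(x, y):
        tab = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy().astype(float)
        tot = tab.sum()
        e = np.outer(tab.sum(1), tab.sum(0)) / tot
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(tab > 0, tab * np.log(tab / e), 0.0)
        return 2 * terms.sum()

    codes = []
    for l in range(g.n_loci):
        gt = np.sort(g.genotypes[:, l, :], axis=1)
        codes.append(
            np.array([f"{a}/{b}" if a != MISSING else "" for a, b in gt])
        )
    rows = []
    for i, j in itertools.combinations(range(g.n_loci), 2):
        mask = (codes[i] != "") & (codes[j] != "")
        x, y = codes[i][mask], codes[j][mask]
        if x.size < 10:
            continue
        obs = g_stat(x, y)
        hits = 0
        for _ in range(n_perm):
            if g_stat(x, rng.permutation(y)) >= obs - 1e-12:
                hits += 1
        rows.append(
            {
                "locus_a": g.loci[i],
                "locus_b": g.loci[j],
                "G": obs,
                "p": (hits + 1) / (n_perm + 1),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df.attrs["n_significant"] = int((df["p"] < alpha).sum())
    return df
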