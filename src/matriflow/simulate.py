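"""Synthetic datasets with the structure the analysis assumes.

The generator emulates three maternally-founded demes sampled over three
annual cohorts: mtDNA descends within each matriline from one of three
founding haplotypes 1-2 substitutions apart (satellites arise on a
neutral coalescent genealogy with a transition-biased mutation model);
nuclear microsatellites evolve on structured-coalescent genealogies with
asymmetric gene flow among the demes under a stepwise/two-phase ladder
model (msprime backend); phenotypes follow allometric weight-length
growth with cohort-specific condition shifts and log-normal noise.
Every generating parameter is carried in a truth record so estimators
can be validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Alignment, GenotypeMatrix
from . import io as mio

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass
class SimConfig:
    """Generating parameters; defaults mirror the study conditions."""

    seed: int = 1
    matrilines: tuple = ("A", "B", "C")
    cohorts: tuple = ("2010", "2011", "2012")
    # per-cohort, per-matriline diploid sample sizes
    sample_sizes: dict = field(
        default_factory=lambda: {
            "2010": (82, 35, 33),
            "2011": (58, 35, 32),
            "2012": (62, 32, 27),
        }
    )
    # nuclear side: mutation-scaled sizes and immigration rates M[j][i]
    theta: tuple = (2.6, 2.067, 4.2)
    # effective migrants per generation Nem[j -> i]; None = panmixia
    nem: dict | None = field(
        default_factory=lambda: {
            ("B", "A"): 0.3,
            ("C", "A"): 0.3,
            ("A", "B"): 10.0,
            ("C", "B"): 8.0,
            ("A", "C"): 20.0,
            ("B", "C"): 10.0,
        }
    )
    n_loci: int = 22
    msat_mu: float = 5e-4
    msat_model: str = "smm"          # 'smm' or 'tpm'
    tpm_p: float = 0.10              # fraction of strictly single-step mutations
    tpm_m: float = 0.5               # geometric parameter of multi-step tail
    ladder: tuple = (1, 120)
    # mitochondrial side
    mt_length: int = 355
    mt_theta: float = 2.0            # haploid 2*N*mu (used when sat_rate is None)
    mt_pop_size: float = 1000.0
    mt_growth: float = 0.5           # per-generation growth; 0 = constant N
    # expected mutations on a root-to-tip path; scales the locus rate to
    # the realised genealogy so satellite load stays stable under growth
    mt_sat_rate: float | None = 0.5
    mt_kappa: float = 8.0
    founder_steps: tuple = (0, 1, 2)  # substitutions separating founders
    # phenotypes: log10(W_mg) = b*log10(L_mm) + log10(a) + noise
    allometry_b: float = 3.397
    allometry_log10a: float = -3.813
    length_means: tuple = (66.59, 69.0, 71.60)
    length_sd: float = 3.5
    weight_sigma: float = 0.05
    cohort_kn_factor: tuple = (0.95, 1.00, 1.06)

    def migration_matrix(self) -> np.ndarray:
        """Mutation-scaled immigration rates M[j, i] (into i from j)."""
        k = len(self.matrilines)
        M = np.zeros((k, k))
        if self.nem:
            idx = {m: i for i, m in enumerate(self.matrilines)}
            for (src, dst), nem in self.nem.items():
                M[idx[src], idx[dst]] = 4.0 * nem / self.theta[idx[dst]]
        return M


@dataclass
class SimResult:
    alignment: Alignment
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: dict


# -------------------------------------------------------------- nuclear


def simulate_genotypes(
    theta,
    M: np.ndarray | None,
    sizes,
    n_loci: int,
    mu: float = 5e-4,
    model: str = "smm",
    tpm_p: float = 0.10,
    tpm_m: float = 0.5,
    ladder=(1, 120),
    seed: int = 1,
    deme_names=None,
    id_prefix: str = "ind",
) -> GenotypeMatrix:
    """Microsatellite genotypes under an island (or panmictic) model.

    ``theta`` per-deme mutation-scaled sizes; ``M[j, i]`` mutation-scaled
    immigration into deme i from j (None or all-zero with one deme =
    panmixia).  Sizes are diploid counts per deme.
    """
    import msprime

    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    sizes = list(np.atleast_1d(sizes).astype(int))
    k = theta.size
    if len(sizes) != k:
        raise ValueError("need one sample size per deme")
    if any(s <= 0 for s in sizes):
        raise ValueError("sample sizes must be positive")
    deme_names = list(deme_names or [f"deme{i}" for i in range(k)])

    Ne = theta / (4.0 * mu)
    demog = msprime.Demography()
    for i in range(k):
        demog.add_population(name=f"p{i}", initial_size=Ne[i])
    has_migration = M is not None and k > 1 and np.any(np.asarray(M) > 0)
    if has_migration:
        for j in range(k):
            for i in range(k):
                if i != j and M[j, i] > 0:
                    # backwards-time rate of lineages in i tracing to j
                    demog.set_migration_rate(
                        source=f"p{i}", dest=f"p{j}", rate=M[j, i] * mu
                    )
    elif k > 1:
        # fully isolated demes: give them a distant common ancestor so
        # the coalescent terminates; differentiation stays near-maximal
        anc_size = float(Ne.max())
        demog.add_population(name="anc", initial_size=anc_size)
        demog.add_population_split(
            time=20.0 * anc_size, derived=[f"p{i}" for i in range(k)],
            ancestral="anc",
        )

    lo, hi = ladder
    root = (lo + hi) // 2
    root_dist = np.zeros(hi - lo + 1)
    root_dist[root - lo] = 1.0
    if model == "smm":
        mut_model = msprime.SMM(lo=lo, hi=hi, root_distribution=root_dist)
    elif model == "tpm":
        # p here is the probability of a multi-step mutation in msprime's
        # parameterisation; the study convention passes the single-step
        # fraction, so complement it
        mut_model = msprime.TPM(
            p=1.0 - tpm_p, m=tpm_m, lo=lo, hi=hi, root_distribution=root_dist
        )
    else:
        raise ValueError(f"unknown msat model {model!r}")

    rng = np.random.default_rng(seed)
    n_tot = sum(sizes)
    gt = np.zeros((n_tot, n_loci, 2), dtype=int)
    reps = msprime.sim_ancestry(
        samples={f"p{i}": sizes[i] for i in range(k)},
        demography=demog,
        sequence_length=1,
        num_replicates=n_loci,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    for l, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts, rate=mu, model=mut_model,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        var = next(mts.variants(), None)
        if var is None:
            gt[:, l, :] = root
        else:
            alleles = np.array(
                [int(a) if a is not None else root for a in var.alleles]
            )
            sizes_per_genome = alleles[var.genotypes]
            gt[:, l, :] = sizes_per_genome.reshape(-1, 2)
    demes = [deme_names[i] for i in range(k) for _ in range(sizes[i])]
    ids = [f"{id_prefix}{i:04d}" for i in range(n_tot)]
    return GenotypeMatrix(ids=ids, demes=demes, loci=[f"L{j + 1:02d}" for j in range(n_loci)], genotypes=gt)


# --------------------------------------------------------------- mtDNA


def _random_seq(length: int, rng) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _mutate_seq(seq: list, site: int, kappa: float, rng) -> None:
    base = seq[site]
    if rng.random() < kappa / (kappa + 2.0):
        seq[site] = _TRANSITION[base]
    else:
        seq[site] = rng.choice(list(_TRANSVERSIONS[base]))


def _matriline_sequences(
    n: int,
    founder: str,
    theta: float,
    kappa: float,
    rng,
    pop_size: float = 1000.0,
    growth: float = 0.5,
    sat_rate: float | None = 0.5,
) -> list[str]:
    """Coalescent genealogy of one matriline, mutations sprinkled on it.

    With ``growth > 0`` the matriline expanded towards the present, so
    the genealogy is star-like and satellites are mostly recent private
    mutations off the founding haplotype -- the structure the haplotype
    network analysis assumes.  With ``growth = 0`` this is the standard
    constant-size coalescent with haploid theta = 2*N*mu.
    """
    import msprime

    if n == 1:
        return [founder]
    N = float(pop_size)
    demog = msprime.Demography()
    demog.add_population(initial_size=N, growth_rate=growth)
    ts = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        demography=demog,
        sequence_length=1,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    tree = ts.first()
    if sat_rate is not None:
        # expected mutations on a root-to-tip path = sat_rate
        depth = float(tree.time(tree.root))
        mu_locus = sat_rate / max(depth, 1e-9)
    else:
        mu_locus = theta / (2.0 * N)  # haploid theta = 2 N mu
    L = len(founder)
    seqs: dict[int, list] = {}
    order = [tree.root]
    seqs[tree.root] = list(founder)
    # preorder walk applying Poisson(branch * mu) substitutions
    stack = list(tree.children(tree.root))
    while stack:
        u = stack.pop()
        s = list(seqs[tree.parent(u)])
        nmut = rng.poisson(tree.branch_length(u) * mu_locus)
        for _ in range(nmut):
            _mutate_seq(s, int(rng.integers(0, L)), kappa, rng)
        seqs[u] = s
        stack.extend(tree.children(u))
    return ["".join(seqs[i]) for i in ts.samples()]


def _founder_haplotypes(cfg: SimConfig, rng) -> list[str]:
    base = _random_seq(cfg.mt_length, rng)
    founders = []
    used_sites: set[int] = set()
    for steps in cfg.founder_steps:
        s = list(base)
        for _ in range(steps):
            site = int(rng.integers(0, cfg.mt_length))
            while site in used_sites:
                site = int(rng.integers(0, cfg.mt_length))
            used_sites.add(site)
            s[site] = _TRANSITION[s[site]]  # founders differ by transitions
        founders.append("".join(s))
    return founders


# ------------------------------------------------------------ phenotypes


def _phenotypes(ids, cohorts, cfg: SimConfig, rng) -> pd.DataFrame:
    c_idx = {c: i for i, c in enumerate(cfg.cohorts)}
    rows = []
    for i, c in zip(ids, cohorts):
        ci = c_idx[c]
        L = max(rng.normal(cfg.length_means[ci], cfg.length_sd), 30.0)
        log_w_mg = (
            cfg.allometry_b * np.log10(L)
            + cfg.allometry_log10a
            + np.log10(cfg.cohort_kn_factor[ci])
            + rng.normal(0.0, cfg.weight_sigma)
        )
        rows.append(
            {
                "id": i,
                "weight_g": 10.0**log_w_mg / 1000.0,
                "length_mm": L,
                "cohort": c,
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------- pipeline


def simulate_structured(cfg: SimConfig) -> SimResult:
    """Full synthetic dataset: alignment + genotypes + phenotypes + truth."""
    if not cfg.sample_sizes or all(
        sum(v) == 0 for v in cfg.sample_sizes.values()
    ):
        raise ValueError("configuration yields zero samples")
    rng = np.random.default_rng(cfg.seed)
    k = len(cfg.matrilines)
    M = cfg.migration_matrix()

    # ids, organised cohort-major then matriline
    ids: list[str] = []
    id_cohort: list[str] = []
    id_matriline: list[str] = []
    for c in cfg.cohorts:
        for mi, m in enumerate(cfg.matrilines):
            for j in range(cfg.sample_sizes[c][mi]):
                ids.append(f"{c}_{m}{j + 1:03d}")
                id_cohort.append(c)
                id_matriline.append(m)

    # --- mtDNA: one genealogy per matriline spanning all cohorts
    founders = _founder_haplotypes(cfg, rng)
    seq_of: dict[str, str] = {}
    for mi, m in enumerate(cfg.matrilines):
        members = [i for i, mm in zip(ids, id_matriline) if mm == m]
        seqs = _matriline_sequences(
            len(members),
            founders[mi],
            cfg.mt_theta,
            cfg.mt_kappa,
            rng,
            pop_size=cfg.mt_pop_size,
            growth=cfg.mt_growth,
            sat_rate=cfg.mt_sat_rate,
        )
        for ind, s in zip(members, seqs):
            seq_of[ind] = s
    aln = Alignment(
        ids=tuple(ids),
        cohorts=tuple(id_cohort),
        seqs=tuple(seq_of[i] for i in ids),
    )

    # --- microsatellites: one structured draw shared by all cohorts
    # (cohorts are temporal samples of the same demes, so their allele
    # pools must come from a common genealogy; simulating cohorts
    # independently would fabricate between-cohort differentiation)
    totals_per_deme = [
        sum(cfg.sample_sizes[c][mi] for c in cfg.cohorts)
        for mi in range(k)
    ]
    gm = simulate_genotypes(
        cfg.theta,
        M if cfg.nem else None,
        totals_per_deme,
        cfg.n_loci,
        mu=cfg.msat_mu,
        model=cfg.msat_model,
        tpm_p=cfg.tpm_p,
        tpm_m=cfg.tpm_m,
        ladder=cfg.ladder,
        seed=int(rng.integers(1, 2**31 - 1)),
        deme_names=list(cfg.matrilines),
    )
    # msprime rows are deme-major; our ids are cohort-major -- map each
    # deme's rows onto that deme's individuals across cohorts in order
    geno = np.zeros((len(ids), cfg.n_loci, 2), dtype=int)
    row = 0
    for mi, m in enumerate(cfg.matrilines):
        members = [
            x for x, mm in zip(range(len(ids)), id_matriline) if mm == m
        ]
        for pos in members:
            geno[pos] = gm.genotypes[row]
            row += 1
    genotypes = GenotypeMatrix(
        ids=ids,
        demes=[f"{c}{m}" for c, m in zip(id_cohort, id_matriline)],
        loci=[f"L{j + 1:02d}" for j in range(cfg.n_loci)],
        genotypes=geno,
    )

    phenos = _phenotypes(ids, id_cohort, cfg, rng)

    truth = {
        "config": {
            k_: (v if not isinstance(v, dict) else {str(kk): vv for kk, vv in v.items()})
            for k_, v in asdict(cfg).items()
        },
        "matriline_of": dict(zip(ids, id_matriline)),
        "founders": founders,
        "migration_matrix": M.tolist(),
    }
    return SimResult(aln, genotypes, phenos, truth)


def make_fixtures(outdir, seed: int = 12345) -> dict[str, Path]:
    """Deterministic miniature dataset for tests: 3 demes, 8 loci, 40 seqs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(
        seed=seed,
        cohorts=("2010",),
        sample_sizes={"2010": (16, 12, 12)},
        n_loci=8,
        length_means=(66.59,),
        cohort_kn_factor=(1.0,),
        mt_theta=2.0,
    )
    sim = simulate_structured(cfg)
    paths = {
        "fasta": outdir / "fixture_nd5.fasta",
        "genepop": outdir / "fixture_genotypes.gen",
        "phenotypes": outdir / "fixture_phenotypes.tsv",
        "cohorts": outdir / "fixture_cohorts.tsv",
    }
    mio.write_fasta(sim.alignment, paths["fasta"])
    mio.write_genepop(sim.genotypes, paths["genepop"])
    sim.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    pd.DataFrame(
        {"id": sim.alignment.ids, "cohort": sim.alignment.cohorts}
    ).to_csv(paths["cohorts"], sep="\t", index=False)
    return paths
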