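"""End-to-end orchestration: sequences -> matrilines -> demes -> statistics.

A :class:`RunConfig` names the inputs, toggles stages, and carries every
seed and permutation/chain budget, so a run is reproducible from its
config alone.  Stage outputs are cached on disk keyed by a content hash
of the stage inputs and the relevant config subsection; reruns with an
unchanged config reuse cached intermediates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import condition, haplonet, io as mio, migration, msat, mtdna, skyline

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    fasta: str | None = None
    cohort_map: str | None = None
    genepop: str | None = None
    phenotypes: str | None = None
    outdir: str = "matriflow_out"
    seed: int = 1
    stages: tuple = ("mtdna", "network", "msat", "condition")
    n_perm: int = 1000
    epsilon: float = 35.0
    tv_weight: int = 8
    kappa: float = 8.0
    mutation_rate_per_site_per_my: float = 0.946e-5
    chain: dict = field(default_factory=dict)
    cache: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _hash_inputs(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, (str, Path)) and Path(str(p)).is_file():
            h.update(Path(str(p)).read_bytes())
        else:
            h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


class _Cache:
    def __init__(self, root: Path, enabled: bool):
        self.root = root
        self.enabled = enabled
        root.mkdir(parents=True, exist_ok=True)

    def get(self, stage: str, key: str):
        f = self.root / f"{stage}-{key}.json"
        if self.enabled and f.is_file():
            logger.info("stage %s: cache hit (%s)", stage, key)
            return json.loads(f.read_text())
        return None

    def put(self, stage: str, key: str, value) -> None:
        if self.enabled:
            (self.root / f"{stage}-{key}.json").write_text(
                json.dumps(value, indent=1, default=_json_default)
            )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    raise TypeError(f"not serialisable: {type(o)}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the enabled stages and return the machine-readable report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cache = _Cache(outdir / "cache", cfg.cache)

    needed = {
        "mtdna": ["fasta"],
        "network": ["fasta"],
        "skyline": ["fasta"],
        "msat": ["genepop"],
        "migration": ["genepop"],
        "condition": ["phenotypes"],
    }
    for stage in cfg.stages:
        for inp in needed.get(stage, []):
            if getattr(cfg, inp) is None:
                raise ValueError(f"stage {stage!r} requires input {inp!r}")

    report: dict = {"config": asdict(cfg), "seed": cfg.seed}
    aln = None
    assignment_rows = None

    if any(s in cfg.stages for s in ("mtdna", "network", "skyline")):
        aln = mio.read_alignment(cfg.fasta, cfg.cohort_map)

    if "mtdna" in cfg.stages:
        key = _hash_inputs(cfg.fasta, cfg.cohort_map, cfg.n_perm, cfg.seed)
        cached = cache.get("mtdna", key)
        if cached is None:
            div = mtdna.diversity_report(aln)
            cohorts = aln.cohort_labels()
            fsts = {}
            for i, a in enumerate(cohorts):
                for b in cohorts[i + 1:]:
                    sub = aln.subset([a, b])
                    f, p = mtdna.mtdna_fst(
                        sub, n_perm=cfg.n_perm, seed=cfg.seed
                    )
                    fsts[f"{a}~{b}"] = {"fst": round(f, 6), "p": round(p, 5)}
            cached = {"diversity": div, "pairwise_fst": fsts}
            cache.put("mtdna", key, cached)
        report["mtdna"] = cached

    if "network" in cfg.stages:
        tbl = mtdna.collapse_haplotypes(aln)
        net = haplonet.median_joining(
            tbl, epsilon=cfg.epsilon, tv_weight=cfg.tv_weight
        )
        pruned = haplonet.mp_prune(net)
        assign = haplonet.assign_matrilines(pruned)
        assignment_rows = haplonet.label_individuals(aln, tbl, assign)
        mains_bp = [
            haplonet.hamming(
                pruned.nodes[a]["seq"], pruned.nodes[b]["seq"]
            )
            for i, a in enumerate(assign.main_haplotypes)
            for b in assign.main_haplotypes[i + 1:]
        ]
        report["network"] = {
            "n_haplotypes": tbl.n_hap,
            "n_satellites": tbl.n_hap - len(assign.main_haplotypes),
            "n_shortest_trees": len(pruned.graph["shortest_trees"]),
            "main_haplotypes": assign.main_haplotypes,
            "main_divergence_bp": mains_bp,
            "matriline_sizes": pd.DataFrame(assignment_rows)
            .groupby("matriline")["id"]
            .count()
            .to_dict(),
        }
        pd.DataFrame(assignment_rows).to_csv(
            outdir / "matriline_assignment.tsv", sep="\t", index=False
        )
        edges = pd.DataFrame(
            [
                {"u": u, "v": v, "weight": d["weight"], "bp": d["bp"]}
                for u, v, d in pruned.edges(data=True)
            ]
        )
        edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)

    if "skyline" in cfg.stages:
        sky = {}
        if assignment_rows is None:
            tbl = mtdna.collapse_haplotypes(aln)
            net = haplonet.median_joining(
                tbl, epsilon=cfg.epsilon, tv_weight=cfg.tv_weight
            )
            assign = haplonet.assign_matrilines(haplonet.mp_prune(net))
            assignment_rows = haplonet.label_individuals(aln, tbl, assign)
        rows = pd.DataFrame(assignment_rows)
        for mat, sub in rows.dropna(subset=["matriline"]).groupby("matriline"):
            ids = set(sub["id"])
            keep = [i for i, x in enumerate(aln.ids) if x in ids]
            if len(keep) < 3:
                continue
            sub_aln = type(aln)(
                ids=tuple(aln.ids[i] for i in keep),
                cohorts=tuple(aln.cohorts[i] for i in keep),
                seqs=tuple(aln.seqs[i] for i in keep),
            )
            tree, profile = skyline.matriline_skyline(sub_aln, kappa=cfg.kappa)
            (outdir / f"skyline_{mat}.nwk").write_text(tree.newick())
            sky[mat] = {
                "boundaries_subs_per_site": profile.boundaries.tolist(),
                "ne_tau": profile.estimates.tolist(),
                "epsilon": profile.epsilon,
            }
        report["skyline"] = sky

    g = None
    if any(s in cfg.stages for s in ("msat", "migration")):
        g = mio.read_genepop(cfg.genepop)

    if "msat" in cfg.stages:
        key = _hash_inputs(cfg.genepop, cfg.n_perm, cfg.seed)
        cached = cache.get("msat", key)
        if cached is None:
            div = msat.deme_diversity(g)
            diag = msat.rir_rhl_diagnostic(div)
            nulls = {
                loc: round(msat.null_allele_em(g, l), 4)
                for l, loc in enumerate(g.loci)
            }
            demes = g.deme_labels()
            fst = {}
            for i, a in enumerate(demes):
                for b in demes[i + 1:]:
                    f, p = msat.pairwise_fst(
                        g, a, b, n_perm=cfg.n_perm, seed=cfg.seed
                    )
                    fst[f"{a}~{b}"] = {"fst": round(f, 5), "p": round(p, 5)}
            decisions, alpha_adj = msat.fdr_correct(
                [v["p"] for v in fst.values()]
            )
            cached = {
                "deme_diversity": div.to_dict(orient="records"),
                "rir_rhl": diag,
                "null_alleles": nulls,
                "pairwise_fst": fst,
                "fdr_alpha": alpha_adj,
                "n_significant_after_fdr": int(np.sum(decisions)),
            }
            cache.put("msat", key, cached)
        report["msat"] = cached

    if "migration" in cfg.stages:
        chain = migration.ChainConfig(**cfg.chain) if cfg.chain else migration.ChainConfig()
        run_i = migration.sample_posterior(
            g, "panmixia", chain, seed=cfg.seed
        )
        run_ii = migration.sample_posterior(
            g, "island", chain, seed=cfg.seed + 1
        )
        nem = migration.effective_migrants(run_ii.theta_mode, run_ii.m_mode)
        report["migration"] = {
            "model_comparison": migration.compare_models(run_i, run_ii),
            "theta_mode": run_ii.theta_mode.tolist(),
            "nem": nem.tolist(),
            "demes": g.deme_labels(),
        }
        pd.DataFrame(
            nem, index=g.deme_labels(), columns=g.deme_labels()
        ).to_csv(outdir / "nem_matrix.tsv", sep="\t")

    if "condition" in cfg.stages:
        pheno = mio.read_phenotypes(cfg.phenotypes)
        fit = condition.allometry_fit(pheno)
        pheno = condition.add_condition_index(pheno, fit)
        cond = {
            "a": fit.a,
            "b": fit.b,
            "R": fit.r,
            "mean_Kn": float(pheno["Kn"].mean()),
            "Kn_by_cohort": pheno.groupby("cohort")["Kn"]
            .agg(["mean", "std"])
            .round(4)
            .to_dict(orient="index"),
        }
        if assignment_rows is not None:
            rows = pd.DataFrame(assignment_rows)
            joined = pheno.merge(rows[["id", "matriline"]], on="id", how="inner")
            if (
                "msat" in report
                and joined["matriline"].notna().sum() > 30
            ):
                ind = msat.individual_indices(g)
                joined = joined.merge(ind[["id", "IR", "HL"]], on="id", how="inner")
                if len(joined.dropna(subset=["IR", "HL"])) > 30:
                    table = condition.hfc_model(joined)
                    cond["hfc_anova"] = {
                        str(k): {
                            "df": float(v["df"]),
                            "F": (None if np.isnan(v["F"]) else float(v["F"])),
                            "p": (
                                None
                                if np.isnan(v["PR(>F)"])
                                else float(v["PR(>F)"])
                            ),
                        }
                        for k, v in table.iterrows()
                    }
        report["condition"] = cond

    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, default=_json_default, sort_keys=True)
    )
    return report
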