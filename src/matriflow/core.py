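"""Shared in-memory containers for the pipeline.

The pipeline moves three kinds of data between stages: an aligned set of
mitochondrial sequences with cohort labels, a diploid microsatellite
genotype matrix with deme labels, and a phenotype table (weight, length,
cohort).  These are deliberately thin wrappers over numpy/pandas objects so
that every statistics module can operate on plain arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")

#: missing genotype sentinel (GenePop "000")
MISSING = -1


class AlignmentError(ValueError):
    """Raised when sequences cannot form a valid alignment."""


class LabelError(KeyError):
    """Raised when an individual id has no cohort/deme label."""


@dataclass(frozen=True)
class Alignment:
    """Equal-length DNA sequences with individual ids and cohort labels.

    Invariants: all sequences share ``site_count`` length, ids are unique,
    and sequences contain only A/C/G/T (ambiguity handling happens at read
    time, see :func:`matriflow.io.read_alignment`).
    """

    ids: tuple[str, ...]
    cohorts: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self):
        if not self.seqs:
            raise AlignmentError("empty alignment")
        n = len(self.seqs[0])
        if n == 0:
            raise AlignmentError("zero-length sequences")
        for s in self.seqs:
            if len(s) != n:
                raise AlignmentError(
                    f"unequal sequence lengths: {len(s)} != {n}"
                )
            bad = set(s) - VALID_BASES
            if bad:
                raise AlignmentError(f"non-ACGT characters {sorted(bad)}")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids")
        if not (len(self.ids) == len(self.cohorts) == len(self.seqs)):
            raise AlignmentError("ids/cohorts/seqs length mismatch")

    @property
    def n(self) -> int:
        return len(self.seqs)

    @property
    def site_count(self) -> int:
        return len(self.seqs[0])

    def subset(self, cohort) -> "Alignment":
        """Restrict to one cohort (or an iterable of cohorts)."""
        wanted = {cohort} if isinstance(cohort, str) else set(cohort)
        keep = [i for i, c in enumerate(self.cohorts) if c in wanted]
        if not keep:
            raise AlignmentError(f"no records for cohort(s) {sorted(wanted)}")
        return Alignment(
            ids=tuple(self.ids[i] for i in keep),
            cohorts=tuple(self.cohorts[i] for i in keep),
            seqs=tuple(self.seqs[i] for i in keep),
        )

    def cohort_labels(self) -> list[str]:
        seen: list[str] = []
        for c in self.cohorts:
            if c not in seen:
                seen.append(c)
        return seen


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct haplotypes of an alignment with per-cohort counts.

    ``counts[h][cohort]`` holds the number of copies of haplotype ``h``;
    haplotypes are ordered by decreasing total count, ties broken by
    sequence, so the table is deterministic for a given input.
    """

    seqs: tuple[str, ...]
    counts: tuple[dict, ...]          # per-haplotype {cohort: count}
    site_count: int

    @property
    def n(self) -> int:
        return sum(sum(c.values()) for c in self.counts)

    @property
    def n_hap(self) -> int:
        return len(self.seqs)

    @property
    def totals(self) -> np.ndarray:
        return np.array([sum(c.values()) for c in self.counts], dtype=int)

    @property
    def segregating_sites(self) -> int:
        cols = zip(*self.seqs)
        return sum(1 for col in cols if len(set(col)) > 1)

    def to_frame(self) -> pd.DataFrame:
        cohorts = sorted({k for c in self.counts for k in c})
        rows = []
        for i, (s, c) in enumerate(zip(self.seqs, self.counts)):
            row = {"haplotype": f"H{i + 1:02d}", "total": sum(c.values())}
            row.update({k: c.get(k, 0) for k in cohorts})
            row["seq"] = s
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class GenotypeMatrix:
    """Diploid genotypes at integer-sized microsatellite loci.

    ``genotypes`` has shape (n_individuals, n_loci, 2); allele sizes are
    positive integers, missing alleles are ``MISSING``.  A genotype is
    either fully typed or fully missing at a locus.
    """

    ids: list[str]
    demes: list[str]
    loci: list[str]
    genotypes: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.genotypes, dtype=int)
        if g.shape != (len(self.ids), len(self.loci), 2):
            raise ValueError(f"genotype array has shape {g.shape}")
        half = (g == MISSING).sum(axis=2)
        if np.any(half == 1):
            raise ValueError("half-missing genotypes are not supported")
        if np.any((g != MISSING) & (g <= 0)):
            raise ValueError("allele sizes must be positive integers")
        self.genotypes = g

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def deme_labels(self) -> list[str]:
        seen: list[str] = []
        for d in self.demes:
            if d not in seen:
                seen.append(d)
        return seen

    def deme_indices(self, deme: str) -> np.ndarray:
        idx = np.array([i for i, d in enumerate(self.demes) if d == deme])
        if idx.size == 0:
            raise LabelError(f"unknown deme {deme!r}")
        return idx

    def subset(self, demes) -> "GenotypeMatrix":
        wanted = {demes} if isinstance(demes, str) else set(demes)
        keep = [i for i, d in enumerate(self.demes) if d in wanted]
        return GenotypeMatrix(
            ids=[self.ids[i] for i in keep],
            demes=[self.demes[i] for i in keep],
            loci=list(self.loci),
            genotypes=self.genotypes[keep],
        )

    def missing_rate(self) -> float:
        return float((self.genotypes[:, :, 0] == MISSING).mean())

    def allele_counts(self, locus: int, individuals=None) -> dict[int, int]:
        """Counts of each allele at one locus (missing excluded)."""
        g = self.genotypes[:, locus, :]
        if individuals is not None:
            g = g[np.asarray(individuals)]
        alleles = g[g != MISSING]
        vals, cnt = np.unique(alleles, return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))


def phenotype_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype table: id, weight_g > 0, length_mm > 0, cohort."""
    required = {"id", "weight_g", "length_mm", "cohort"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns {sorted(missing)}")
    if (df["weight_g"] <= 0).any() or (df["length_mm"] <= 0).any():
        raise ValueError("weights and lengths must be positive")
    if df["id"].duplicated().any():
        raise ValueError("duplicate individual ids in phenotype table")
    out = df.copy()
    out["cohort"] = out["cohort"].astype(str)
    return out
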