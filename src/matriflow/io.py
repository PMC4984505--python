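"""Readers and writers for the standard field formats.

FASTA goes through Biopython; GenePop and the sidecar TSVs are small
line-oriented formats handled here directly.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import MISSING, Alignment, AlignmentError, GenotypeMatrix, LabelError


def read_cohort_map(path) -> dict[str, str]:
    """Two-column TSV (id, cohort) -> mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("cohort map needs two columns: id, cohort")
    id_col, cohort_col = df.columns[:2]
    return dict(zip(df[id_col], df[cohort_col]))


_COHORT_IN_ID = re.compile(r"(?:^|[_|.-])(\d{4})(?:[_|.-]|$)")


def cohort_from_id(seq_id: str) -> str | None:
    """Extract a 4-digit year token embedded in a sequence id, if any."""
    m = _COHORT_IN_ID.search(seq_id)
    return m.group(1) if m else None


def read_alignment(path, cohort_map=None, on_ambiguity: str = "reject") -> Alignment:
    """Read an aligned FASTA into an :class:`Alignment`.

    Cohort labels come from ``cohort_map`` (dict or TSV path) when given,
    otherwise from a 4-digit year token in each id.  ``on_ambiguity``
    controls non-ACGT characters: ``"reject"`` raises, ``"mask"`` drops
    every alignment column containing one.
    """
    if cohort_map is not None and not isinstance(cohort_map, dict):
        cohort_map = read_cohort_map(cohort_map)

    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper().replace("U", "T")
        if not s:
            raise AlignmentError(f"empty sequence for {rec.id}")
        ids.append(rec.id)
        seqs.append(s)
    if not ids:
        raise AlignmentError(f"no FASTA records in {path}")

    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")

    bad_cols = set()
    for s in seqs:
        for j, ch in enumerate(s):
            if ch not in "ACGT":
                bad_cols.add(j)
    if bad_cols:
        if on_ambiguity == "reject":
            raise AlignmentError(
                f"{len(bad_cols)} column(s) contain gaps/ambiguity codes; "
                "pass on_ambiguity='mask' to drop them"
            )
        if on_ambiguity == "mask":
            keep = [j for j in range(len(seqs[0])) if j not in bad_cols]
            if not keep:
                raise AlignmentError("all columns masked")
            seqs = ["".join(s[j] for j in keep) for s in seqs]
        else:
            raise ValueError(f"unknown on_ambiguity={on_ambiguity!r}")

    cohorts = []
    for i in ids:
        if cohort_map is not None:
            if i not in cohort_map:
                raise LabelError(f"id {i!r} missing from cohort map")
            cohorts.append(str(cohort_map[i]))
        else:
            c = cohort_from_id(i)
            if c is None:
                raise LabelError(
                    f"id {i!r} encodes no cohort; provide a cohort map"
                )
            cohorts.append(c)

    return Alignment(ids=tuple(ids), cohorts=tuple(cohorts), seqs=tuple(seqs))


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for i, s in zip(aln.ids, aln.seqs):
            fh.write(f">{i}\n{s}\n")


# ---------------------------------------------------------------- GenePop

def read_genepop(path) -> GenotypeMatrix:
    """Parse a GenePop file (2- or 3-digit alleles, 000/00 = missing).

    Population names are taken from the id of each population's last
    individual when it looks like a label, else ``pop1``, ``pop2``...
    The individual id before the comma is kept verbatim.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError("empty GenePop file")
    # line 0 = title
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        part = lines[i].strip()
        if part:
            loci.extend(x.strip() for x in part.split(",") if x.strip())
        i += 1
    if not loci:
        raise ValueError("no locus names before first POP")

    ids: list[str] = []
    demes: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_idx = 0
    while i < len(lines):
        if lines[i].strip().upper() == "POP":
            pop_idx += 1
            i += 1
            continue
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if "," not in line:
            raise ValueError(f"malformed GenePop line: {line!r}")
        ind_id, geno = line.split(",", 1)
        alleles = geno.split()
        if len(alleles) != len(loci):
            raise ValueError(
                f"{ind_id.strip()!r}: {len(alleles)} genotypes for "
                f"{len(loci)} loci"
            )
        row = []
        for tok in alleles:
            if len(tok) % 2 != 0:
                raise ValueError(f"odd-width genotype token {tok!r}")
            w = len(tok) // 2
            a, b = int(tok[:w]), int(tok[w:])
            row.append(
                (MISSING, MISSING) if a == 0 or b == 0 else (a, b)
            )
        ids.append(ind_id.strip())
        demes.append(f"pop{pop_idx}")
        rows.append(row)

    if not rows:
        raise ValueError("GenePop file contains no individuals")
    return GenotypeMatrix(
        ids=ids, demes=demes, loci=loci,
        genotypes=np.array(rows, dtype=int),
    )


def write_genepop(g: GenotypeMatrix, path, title: str = "matriflow export") -> None:
    width = 3 if int(g.genotypes.max()) > 99 else 2
    fmt = f"{{:0{width}d}}"
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in g.loci:
            fh.write(locus + "\n")
        for deme in g.deme_labels():
            fh.write("POP\n")
            for i in g.deme_indices(deme):
                toks = []
                for a, b in g.genotypes[i]:
                    if a == MISSING:
                        toks.append(fmt.format(0) * 2)
                    else:
                        toks.append(fmt.format(a) + fmt.format(b))
                fh.write(f"{g.ids[i]} , " + " ".join(toks) + "\n")


def read_genotype_tsv(path) -> GenotypeMatrix:
    """Long-form TSV: id, deme, locus, allele1, allele2 (0 = missing)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "deme": str, "locus": str})
    loci = list(dict.fromkeys(df["locus"]))
    ids = list(dict.fromkeys(df["id"]))
    deme_of = dict(zip(df["id"], df["deme"].astype(str)))
    gt = np.full((len(ids), len(loci), 2), MISSING, dtype=int)
    li = {l: j for j, l in enumerate(loci)}
    ii = {x: i for i, x in enumerate(ids)}
    for _, r in df.iterrows():
        a, b = int(r["allele1"]), int(r["allele2"])
        if a > 0 and b > 0:
            gt[ii[r["id"]], li[r["locus"]]] = (a, b)
    return GenotypeMatrix(
        ids=ids, demes=[deme_of[x] for x in ids], loci=loci, genotypes=gt
    )


def read_phenotypes(path) -> pd.DataFrame:
    from .core import phenotype_table

    return phenotype_table(pd.read_csv(path, sep="\t", dtype={"id": str, "cohort": str}))
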