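"""Relative condition factor (Kn) and heterozygosity-fitness models.

The length-weight relationship W = a * L^b is fitted by ordinary least
squares on log10-transformed data; Kn = W / (a * L^b) so that a fish on
the fitted allometric curve scores exactly 1.  An ANCOVA checks whether
one common slope can serve all cohorts before pooling.  The
heterozygosity-fitness model regresses Kn on the individual
homozygosity indices with matriline nested inside cohort, using
sequential (type-I) F tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass
class AllometryFit:
    a: float                 # intercept back-transformed, weight units per L^b
    b: float                 # allometric slope
    r: float                 # correlation of log W with log L
    per_group: pd.DataFrame  # slope/intercept/R per grouping level
    ancova: pd.DataFrame     # slope-homogeneity test table
    log_base: float = 10.0


def allometry_fit(tbl: pd.DataFrame, grouping: str = "cohort") -> AllometryFit:
    """OLS fit of log10(W) on log10(L), with per-group slopes and ANCOVA.

    The ANCOVA model is log10(W) ~ log10(L) * group; the interaction rows
    test slope homogeneity among groups.  ``a`` is 10**intercept, so
    Kn = W / (a * L**b) is unit-consistent with the data supplied.
    """
    if len(tbl) < 3:
        raise ValueError("allometry fit needs at least 3 individuals")
    d = tbl.copy()
    d["logW"] = np.log10(d["weight_g"])
    d["logL"] = np.log10(d["length_mm"])

    pooled = smf.ols("logW ~ logL", data=d).fit()
    b = float(pooled.params["logL"])
    a = float(10.0 ** pooled.params["Intercept"])
    r = float(np.corrcoef(d["logL"], d["logW"])[0, 1])

    rows = []
    for g, sub in d.groupby(grouping):
        if len(sub) >= 3:
            f = smf.ols("logW ~ logL", data=sub).fit()
            rows.append(
                {
                    grouping: g,
                    "slope": float(f.params["logL"]),
                    "intercept": float(f.params["Intercept"]),
                    "R": float(np.corrcoef(sub["logL"], sub["logW"])[0, 1]),
                    "n": len(sub),
                }
            )
    per_group = pd.DataFrame(rows)

    if d[grouping].nunique() > 1:
        anc = smf.ols(f"logW ~ logL * C({grouping})", data=d).fit()
        ancova = pd.DataFrame(
            {"t": anc.tvalues, "P": anc.pvalues, "coef": anc.params}
        )
    else:
        ancova = pd.DataFrame(columns=["t", "P", "coef"])
    return AllometryFit(a=a, b=b, r=r, per_group=per_group, ancova=ancova)


def condition_index(W, L, a: float, b: float):
    """Relative condition factor Kn = W / (a * L^b)."""
    W = np.asarray(W, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(W <= 0) or np.any(L <= 0):
        raise ValueError("weights and lengths must be positive")
    return W / (a * L**b)


def add_condition_index(tbl: pd.DataFrame, fit: AllometryFit | None = None) -> pd.DataFrame:
    if fit is None:
        fit = allometry_fit(tbl)
    out = tbl.copy()
    out["Kn"] = condition_index(out["weight_g"], out["length_mm"], fit.a, fit.b)
    return out


def hfc_residuals(hl, ir) -> np.ndarray:
    """Residuals of the HL ~ IR regression (decorrelates the two indices)."""
    ir = np.asarray(ir, dtype=float)
    hl = np.asarray(hl, dtype=float)
    X = sm.add_constant(ir)
    return np.asarray(sm.OLS(hl, X).fit().resid)


#: sequential model terms, in reporting order
_HFC_TERMS = [
    ("Rds", "Rds"),
    ("IR", "IR"),
    ("cohort", "C(cohort)"),
    ("Rds:IR", "Rds:IR"),
    ("cohort:matriline", "C(cohort):C(matriline)"),
    ("Rds:cohort", "Rds:C(cohort)"),
    ("IR:cohort", "IR:C(cohort)"),
    ("Rds:cohort:matriline", "Rds:C(cohort):C(matriline)"),
    ("IR:cohort:matriline", "IR:C(cohort):C(matriline)"),
    ("Rds:IR:cohort", "Rds:IR:C(cohort)"),
    ("Rds:IR:cohort:matriline", "Rds:IR:C(cohort):C(matriline)"),
]


def hfc_model(df: pd.DataFrame) -> pd.DataFrame:
    """Heterozygosity-fitness ANOVA of Kn with matriline nested in cohort.

    ``df`` needs columns Kn, HL, IR, cohort, matriline.  HL enters only
    through Rds, the residual of its regression on IR, so the two indices
    are orthogonal predictors.  Sequential (type-I) sums of squares are
    computed in the fixed row order Rds, IR, cohort, Rds:IR,
    cohort:matriline, Rds:cohort, IR:cohort, Rds:cohort:matriline,
    IR:cohort:matriline, Rds:IR:cohort, Rds:IR:cohort:matriline; each F
    uses the full-model residual mean square.
    """
    import patsy
    from scipy import stats as sps

    d = df.dropna(subset=["Kn", "HL", "IR", "cohort", "matriline"]).copy()
    n_dropped = len(df) - len(d)
    d["Rds"] = hfc_residuals(d["HL"], d["IR"])
    y = d["Kn"].to_numpy(dtype=float)
    n = y.size

    def rss_rank(X):
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), int(rank)

    X = np.ones((n, 1))
    prev_rss, prev_rank = rss_rank(X)
    rows = []
    for name, term in _HFC_TERMS:
        cols = np.asarray(patsy.dmatrix("0 + " + term, d))
        X = np.column_stack([X, cols])
        cur_rss, cur_rank = rss_rank(X)
        rows.append(
            {
                "term": name,
                "df": cur_rank - prev_rank,
                "sum_sq": prev_rss - cur_rss,
            }
        )
        prev_rss, prev_rank = cur_rss, cur_rank
    df_resid = n - prev_rank
    ms_resid = prev_rss / df_resid if df_resid > 0 else np.nan
    for r in rows:
        if r["df"] > 0 and ms_resid > 0:
            r["F"] = (r["sum_sq"] / r["df"]) / ms_resid
            r["PR(>F)"] = float(sps.f.sf(r["F"], r["df"], df_resid))
        else:
            r["F"] = np.nan
            r["PR(>F)"] = np.nan
    rows.append(
        {
            "term": "Residual",
            "df": df_resid,
            "sum_sq": prev_rss,
            "F": np.nan,
            "PR(>F)": np.nan,
        }
    )
    table = pd.DataFrame(rows).set_index("term")
    table.index.name = None
    table.attrs["n_dropped"] = n_dropped
    return table
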