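"""Covariate-adjusted group comparison, effect sizes, FDR, and demographics.

The group contrast on each network indicator's AUC is an ordinary
least-squares fit of the AUC on an intercept, a patient indicator, and the
clinical nuisance covariates (years of education, MMSE, grey/white-matter
volume, mean framewise displacement, and medication category as dummy
columns); the reported statistic is the group coefficient's t with residual
degrees of freedom.  Nodal comparisons are corrected with Benjamini-Hochberg
FDR at q < 0.05.  Effect sizes are Cohen's d on the raw (unadjusted) group
values by default; a covariate-adjusted variant (d computed on nuisance-model
residuals) is available since reporting conventions differ between tools.

Demographic comparisons mirror the usual clinical Table 1: pooled two-sample
t for approximately normal variables, tie-corrected Mann-Whitney z for skewed
ones, and Pearson chi-square (no continuity correction) for sex composition.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .cohort import CONTROL, PATIENT

__all__ = [
    "DEFAULT_COVARIATES",
    "MEDICATION_DUMMIES",
    "build_design",
    "glm_group_test",
    "cohens_d",
    "fdr_bh",
    "spearman_corr",
    "two_sample_t_from_summary",
    "chi_square_2x2",
    "mann_whitney",
    "normality_screen",
    "compare_global_aucs",
    "compare_nodal_aucs",
    "demographics_table",
    "MetricComparison",
]

DEFAULT_COVARIATES = ("education_years", "mmse", "gmv", "wmv", "mean_fd")
#: medication dummy levels; reference category = {drug_naive, none}
MEDICATION_DUMMIES = ("gcs_alone", "gcs_hcq", "gcs_isa")


@dataclass(frozen=True)
class MetricComparison:
    metric_name: str
    t_statistic: float
    p_value: float
    cohens_d: float
    direction: str  # "patient_lower" / "patient_higher" / "none"


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < X.shape[1]:
        culprits = []
        for col in X.columns:
            sub = X.drop(columns=[col]).to_numpy(dtype=float)
            if np.linalg.matrix_rank(sub) == rank:
                culprits.append(col)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {culprits}")


def build_design(
    phenotype: pd.DataFrame,
    covariates: tuple[str, ...] | list[str] = DEFAULT_COVARIATES,
    include_medication: bool = True,
) -> pd.DataFrame:
    """Design matrix: intercept, group (patient = 1), covariates, medication
    dummies (reference: drug-naive patients and untreated controls).

    Raises on missing values in any used column and on rank deficiency.
    """
    cols = {"intercept": np.ones(len(phenotype))}
    cols["group"] = (phenotype["group"] == PATIENT).astype(float).to_numpy()
    for c in covariates:
        if c not in phenotype.columns:
            raise ValueError(f"phenotype table lacks covariate column {c!r}")
        vals = pd.to_numeric(phenotype[c], errors="coerce").to_numpy(dtype=float)
        if np.isnan(vals).any():
            bad = phenotype.loc[np.isnan(vals), "subject_id"].tolist()
            raise ValueError(f"covariate {c!r} has missing values for subjects {bad}")
        cols[c] = vals
    if include_medication and "medication" in phenotype.columns:
        for level in MEDICATION_DUMMIES:
            dummy = (phenotype["medication"] == level).astype(float).to_numpy()
            cols[f"medication_{level}"] = dummy
    X = pd.DataFrame(cols, index=phenotype.index)
    # In small samples the medication dummies can alias the group column
    # (e.g. no drug-naive patient drawn); drop aliased/constant dummies rather
    # than failing, since the reference category is arbitrary.
    med_cols = [c for c in X.columns if c.startswith("medication_")]
    while med_cols and np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        dropped = med_cols.pop()
        warnings.warn(
            f"dropping aliased medication dummy column {dropped!r} from the design",
            stacklevel=2,
        )
        X = X.drop(columns=[dropped])
    _check_full_rank(X)
    return X


def glm_group_test(values: np.ndarray, design: pd.DataFrame) -> tuple[float, float]:
    """OLS of per-subject values on the design; returns the group
    coefficient's t statistic and two-sided p (residual dof)."""
    y = np.asarray(values, dtype=float)
    if y.size <= design.shape[1] + 1:
        raise ValueError(
            f"need more subjects ({y.size}) than design columns + 1 ({design.shape[1] + 1})"
        )
    _check_full_rank(design)
    fit = sm.OLS(y, design.to_numpy(dtype=float)).fit()
    gi = list(design.columns).index("group")
    return float(fit.tvalues[gi]), float(fit.pvalues[gi])


def cohens_d(values: np.ndarray, groups: np.ndarray) -> float:
    """(mean_1 - mean_2) / pooled SD with (n1-1, n2-1) weighting; group 1 is
    the patient group when labels are group names, else the first unique."""
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = [PATIENT, CONTROL] if set(np.unique(g)) == {PATIENT, CONTROL} else list(pd.unique(g))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    y1, y2 = y[g == labels[0]], y[g == labels[1]]
    if len(y1) < 2 or len(y2) < 2:
        raise ValueError("both groups need at least 2 observations")
    n1, n2 = len(y1), len(y2)
    sp2 = ((n1 - 1) * y1.var(ddof=1) + (n2 - 1) * y2.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled standard deviation; Cohen's d undefined")
    return float((y1.mean() - y2.mean()) / np.sqrt(sp2))


def fdr_bh(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def spearman_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; rank correlation undefined")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def two_sample_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance Student t from printed group summaries (mean, SD, n)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    t, p = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return float(t), float(p)


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero marginal total; chi-square undefined")
    res = sps.chi2_contingency(obs, correction=False)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Mann-Whitney U with tie-corrected normal z; (U, z, p).

    p is exact (full enumeration) when both samples have n <= 8 and no ties
    occur, otherwise the two-sided normal approximation on z.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    u = float(sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic)
    combined = np.concatenate([x, y])
    _, counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = 0.0 if var_u == 0 else float((u - n1 * n2 / 2.0) / np.sqrt(var_u))
    no_ties = counts.size == n
    if n1 <= 8 and n2 <= 8 and no_ties:
        p = float(sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
    else:
        p = float(2 * sps.norm.sf(abs(z)))
    return u, z, min(p, 1.0)


def normality_screen(values: np.ndarray) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality check (reporting aid only; the choice of
    t vs Mann-Whitney per variable is a caller decision, not automated).

    Lilliefors variant: mean/SD estimated from the data."""
    v = np.asarray(values, dtype=float)
    if v.size < 4 or np.ptp(v) == 0:
        return np.nan, np.nan
    stat, p = sps.kstest(v, "norm", args=(v.mean(), v.std(ddof=1)))
    return float(stat), float(p)


def compare_global_aucs(
    auc: pd.DataFrame,
    phenotype: pd.DataFrame,
    design: pd.DataFrame,
    metrics: tuple[str, ...] | None = None,
    adjusted_d: bool = False,
) -> pd.DataFrame:
    """Covariate-adjusted group comparison of each global indicator's AUC.

    ``auc``: wide table (one row per subject, one column per metric),
    subject order matching ``phenotype`` and ``design`` rows.
    """
    merged = auc.merge(phenotype[["subject_id", "group"]], on="subject_id")
    if len(merged) != len(phenotype):
        raise ValueError("AUC table and phenotype table have mismatched subjects")
    merged = merged.set_index("subject_id").loc[phenotype["subject_id"]].reset_index()
    names = [m for m in (metrics or merged.columns) if m not in ("subject_id", "group")]
    rows = []
    for m in names:
        vals = merged[m].to_numpy(dtype=float)
        t, p = glm_group_test(vals, design)
        if adjusted_d:
            nuis = design.drop(columns=["group"]).to_numpy(dtype=float)
            resid = vals - nuis @ np.linalg.lstsq(nuis, vals, rcond=None)[0]
            d = cohens_d(resid, merged["group"].to_numpy())
        else:
            d = cohens_d(vals, merged["group"].to_numpy())
        direction = "patient_lower" if t < 0 else ("patient_higher" if t > 0 else "none")
        rows.append(MetricComparison(m, t, p, d, direction))
    return pd.DataFrame(
        {
            "metric": [r.metric_name for r in rows],
            "t": [r.t_statistic for r in rows],
            "p": [r.p_value for r in rows],
            "cohens_d": [r.cohens_d for r in rows],
            "direction": [r.direction for r in rows],
        }
    )


def compare_nodal_aucs(
    nodal_auc: pd.DataFrame,
    phenotype: pd.DataFrame,
    design: pd.DataFrame,
    q: float = 0.05,
) -> pd.DataFrame:
    """Region x metric group comparison with BH-FDR across regions per metric.

    ``nodal_auc``: wide table with columns (subject_id, region, <metrics>).
    """
    metrics = [c for c in nodal_auc.columns if c not in ("subject_id", "region")]
    order = {sid: k for k, sid in enumerate(phenotype["subject_id"])}
    rows = []
    for metric in metrics:
        wide = nodal_auc.pivot(index="subject_id", columns="region", values=metric)
        wide = wide.loc[sorted(wide.index, key=order.get)]
        tps = [glm_group_test(wide[reg].to_numpy(dtype=float), design) for reg in wide.columns]
        pvals = np.array([p for _, p in tps])
        rej, p_adj = fdr_bh(pvals, q=q)
        for k, reg in enumerate(wide.columns):
            rows.append((metric, reg, tps[k][0], pvals[k], p_adj[k], bool(rej[k])))
    return pd.DataFrame(rows, columns=["metric", "region", "t", "p", "q_fdr", "significant"])


_NORMAL_VARS = ("age", "tiv", "gmv", "wmv")
_SKEWED_VARS = ("education_years", "mmse", "hama", "hamd")


def demographics_table(phenotype: pd.DataFrame) -> pd.DataFrame:
    """Group-wise demographic/clinical summary in the usual Table-1 layout.

    Sex uses Pearson chi-square; approximately normal variables are shown as
    mean +/- SD with the pooled t; skewed scores as median (IQR) with the
    Mann-Whitney z.  Patient-only variables (disease activity, medication
    counts) are summarized without a test.
    """
    pat = phenotype[phenotype["group"] == PATIENT]
    con = phenotype[phenotype["group"] == CONTROL]

    def msd(v):
        return f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"

    def miqr(v):
        return f"{v.median():.2f} ({v.quantile(0.25):.2f}, {v.quantile(0.75):.2f})"

    rows = []
    if "sex" in phenotype.columns:
        tab = np.array(
            [
                [(pat["sex"] == "female").sum(), (pat["sex"] == "male").sum()],
                [(con["sex"] == "female").sum(), (con["sex"] == "male").sum()],
            ]
        )
        chi2, p = chi_square_2x2(tab)
        rows.append(
            (
                "sex (female/male)",
                f"{tab[0, 0]}/{tab[0, 1]}",
                f"{tab[1, 0]}/{tab[1, 1]}",
                "chi2",
                chi2,
                p,
            )
        )
    for var in _NORMAL_VARS:
        if var not in phenotype.columns:
            continue
        t, p = sps.ttest_ind(pat[var], con[var], equal_var=True)
        rows.append((var, msd(pat[var]), msd(con[var]), "t", float(t), float(p)))
    for var in _SKEWED_VARS:
        if var not in phenotype.columns:
            continue
        _, z, p = mann_whitney(pat[var].to_numpy(), con[var].to_numpy())
        rows.append((var, miqr(pat[var]), miqr(con[var]), "z", z, p))
    if "sledai" in phenotype.columns and pat["sledai"].notna().any():
        rows.append(("sledai", miqr(pat["sledai"].dropna()), "", "", np.nan, np.nan))
    if "medication" in phenotype.columns:
        counts = pat["medication"].value_counts()
        for level in ("drug_naive",) + MEDICATION_DUMMIES:
            rows.append((f"medication: {level}", str(int(counts.get(level, 0))), "0", "", np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["variable", "patients", "controls", "statistic", "value", "p"]
    )
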