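"""Group-comparison and symptom-association statistics.

Descriptives use Kruskal-Wallis (chi-square approximation) and Pearson
chi-square for sex; normalized global measures are compared with Welch
t-tests; hub and co-module probabilities with Fisher exact tests;
symptom-measure associations with Spearman correlations in patients only;
and the psychological-distress analysis with an ANCOVA including the
group-by-covariate interaction, after Box-Cox normalization where the
residuals call for it.  Multiple testing is controlled per family with
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "descriptive_group_compare",
    "welch_t",
    "fisher_exact_2x2",
    "spearman_assoc",
    "box_cox",
    "BoxCoxResult",
    "needs_transform",
    "ancova_interaction",
    "AncovaResult",
    "bh_fdr",
    "compare_global_measures",
    "hub_group_tests",
    "comodule_group_tests",
    "spearman_table",
]


@dataclass
class StatResult:
    statistic: float
    kind: str  # "t" | "F" | "chi2" | "H" | "rho" | "odds-ratio"
    p_raw: float
    df: Optional[float] = None
    p_fdr: Optional[float] = None
    effect: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_raw) or 0 <= self.p_raw <= 1):
            raise ValueError("p-value outside [0, 1]")


def welch_t(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Two-tailed independent-samples t-test assuming unequal variances
    (Welch statistic with Satterthwaite degrees of freedom)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return StatResult(0.0, "t", 1.0, df=float(a.size + b.size - 2))
        return StatResult(np.inf, "t", 0.0, df=float(a.size + b.size - 2))
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (va**2 / (a.size**2 * (a.size - 1)) + vb**2 / (b.size**2 * (b.size - 1)))
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(float(t), "t", float(p), df=float(df),
                      effect={"mean_diff": float(a.mean() - b.mean())})


def descriptive_group_compare(manifest: pd.DataFrame) -> pd.DataFrame:
    """Kruskal-Wallis per continuous variable, Pearson chi-square for sex.

    ``manifest`` needs a ``group`` column (HC/IBS); every numeric column
    except ``sex_m`` is compared with Kruskal-Wallis (chi-square
    approximation); ``sex_m`` (0/1) with a chi-square test on the 2x2
    contingency table.  Constant variables get p = 1 with a warning.
    """
    groups = manifest["group"]
    if groups.nunique() < 2:
        raise ValueError("descriptive comparison needs both groups present")
    rows = []
    for col in manifest.columns:
        if col in ("group", "cohort") or not pd.api.types.is_numeric_dtype(manifest[col]):
            continue
        a = manifest.loc[groups == "HC", col].dropna().to_numpy()
        b = manifest.loc[groups == "IBS", col].dropna().to_numpy()
        if col == "sex_m":
            table = np.array(
                [[np.sum(a == 1), np.sum(a == 0)], [np.sum(b == 1), np.sum(b == 0)]]
            )
            chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
            rows.append({"variable": col, "kind": "chi2", "statistic": chi2, "df": dof, "p_raw": p})
            continue
        if np.concatenate([a, b]).std() == 0:
            warnings.warn(f"variable {col!r} is constant; p set to 1", stacklevel=2)
            rows.append({"variable": col, "kind": "H", "statistic": 0.0, "df": 1, "p_raw": 1.0})
            continue
        h, p = sps.kruskal(a, b)
        rows.append({"variable": col, "kind": "H", "statistic": h, "df": 1, "p_raw": p})
    return pd.DataFrame(rows).set_index("variable")


def fisher_exact_2x2(table: np.ndarray) -> StatResult:
    """Two-sided Fisher exact test: sum of hypergeometric probabilities not
    exceeding the observed table's."""
    table = np.asarray(table)
    if table.shape != (2, 2) or (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("table must be a 2x2 array of nonnegative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return StatResult(np.nan, "odds-ratio", 1.0)
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return StatResult(float(odds), "odds-ratio", float(p))


def spearman_assoc(scores: Sequence[float], measures: Sequence[float]) -> StatResult:
    """Spearman rank correlation with tie-corrected ranks."""
    scores = np.asarray(scores, dtype=float)
    measures = np.asarray(measures, dtype=float)
    if scores.size != measures.size or scores.size < 4:
        raise ValueError("need at least 4 paired observations")
    if scores.std() == 0 or measures.std() == 0:
        return StatResult(np.nan, "rho", np.nan, effect={"note": np.nan})
    rho, p = sps.spearmanr(scores, measures)
    return StatResult(float(rho), "rho", float(p), df=float(scores.size - 2))


@dataclass
class BoxCoxResult:
    transformed: np.ndarray
    lam: float
    shift: float


def box_cox(
    values: Sequence[float],
    lam: Optional[float] = None,
    shift: float | str = 0.0,
    grid: tuple[float, float, int] = (-3.0, 3.0, 601),
) -> BoxCoxResult:
    """Box-Cox power transform y = (x^lam - 1)/lam (ln x at lam = 0).

    ``lam=None`` selects lambda by profile log-likelihood on a grid over
    [-3, 3].  ``shift`` is added to the data first; ``"auto"`` shifts
    nonpositive data to a minimum of 1.  Nonpositive values with no shift
    are an error.
    """
    x = np.asarray(values, dtype=float)
    if shift == "auto":
        shift = float(1.0 - x.min()) if x.min() <= 0 else 0.0
    x = x + float(shift)
    if (x <= 0).any():
        raise ValueError("Box-Cox requires positive values; configure a shift")
    if lam is None:
        lo, hi, num = grid
        lams = np.linspace(lo, hi, int(num))
        lls = [sps.boxcox_llf(l, x) for l in lams]
        lam = float(lams[int(np.argmax(lls))])
    if lam == 0:
        y = np.log(x)
    else:
        y = (x**lam - 1.0) / lam
    return BoxCoxResult(y, float(lam), float(shift))


def needs_transform(values: Sequence[float]) -> bool:
    """Normality gate: absolute skewness > 1 or Shapiro-Wilk p < 0.05."""
    x = np.asarray(values, dtype=float)
    if x.std() == 0:
        return False
    if abs(sps.skew(x)) > 1:
        return True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = sps.shapiro(x)
    return bool(p < 0.05)


@dataclass
class AncovaResult:
    """Type-III F tests of group, covariate and their interaction, plus
    per-group Pearson correlations/slopes of measure on covariate."""

    terms: pd.DataFrame  # index: term, columns: F, df_num, df_den, p_raw
    slopes: pd.DataFrame  # index: group, columns: slope, r, p
    lam: Optional[float] = None  # Box-Cox lambda applied to the measure, if any

    @property
    def interaction(self) -> StatResult:
        row = self.terms.loc["group:covariate"]
        return StatResult(float(row["F"]), "F", float(row["p_raw"]),
                          df=float(row["df_den"]))


def _drop_term_f(y: np.ndarray, x_full: np.ndarray, drop: int) -> tuple[float, float, float]:
    n, p = x_full.shape
    rss_full = _rss(y, x_full)
    rss_red = _rss(y, np.delete(x_full, drop, axis=1))
    df_den = n - p
    gain = max(rss_red - rss_full, 0.0)
    scale = max(rss_red, rss_full, 1.0)
    if rss_full <= 1e-12 * scale:
        # noiseless fit: the term either explains nothing (F = 0) or
        # everything that remains (F unbounded)
        if gain <= 1e-12 * scale:
            return 0.0, float(df_den), 1.0
        return float(np.inf), float(df_den), 0.0
    f = gain / (rss_full / df_den)
    return float(f), float(df_den), float(sps.f.sf(f, 1, df_den))


def _rss(y: np.ndarray, x: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r)


def ancova_interaction(
    measure: Sequence[float],
    group: Sequence[str],
    covariate: Sequence[float],
    transform: str = "auto",  # "auto" | "none"
) -> AncovaResult:
    """ANCOVA of measure on group, covariate, and group x covariate.

    The covariate is standardized to mean 0 / SD 1; when ``transform`` is
    ``"auto"`` the dependent variable (and a covariate failing the
    normality gate) is Box-Cox transformed first.  Group is sum-coded, so
    the drop-one F tests are type III.  Per-group Pearson correlations of
    the (transformed) measure with the covariate are reported alongside.
    """
    y = np.asarray(measure, dtype=float)
    g = np.asarray(group)
    z = np.asarray(covariate, dtype=float)
    levels = sorted(set(g.tolist()))
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    if y.size != g.size or y.size != z.size:
        raise ValueError("measure, group and covariate must align")

    lam = None
    if transform == "auto":
        if needs_transform(y):
            res = box_cox(y, shift="auto")
            y, lam = res.transformed, res.lam
        if needs_transform(z):
            z = box_cox(z, shift="auto").transformed
    if z.std() == 0:
        raise ValueError("covariate is constant")
    z = (z - z.mean()) / z.std()

    gsum = np.where(g == levels[0], 1.0, -1.0)  # sum coding
    x_full = np.column_stack([np.ones_like(y), gsum, z, gsum * z])
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError("singular ANCOVA design")

    rows = {}
    for name, col in (("group", 1), ("covariate", 2), ("group:covariate", 3)):
        f, df_den, p = _drop_term_f(y, x_full, col)
        rows[name] = {"F": f, "df_num": 1.0, "df_den": df_den, "p_raw": p}
    terms = pd.DataFrame(rows).T

    slope_rows = {}
    for level in levels:
        sel = g == level
        zz, yy = z[sel], y[sel]
        slope = float(np.polyfit(zz, yy, 1)[0]) if zz.std() > 0 else np.nan
        if zz.std() > 0 and yy.std() > 0:
            r, p = sps.pearsonr(zz, yy)
        else:
            r, p = np.nan, np.nan
        slope_rows[level] = {"slope": slope, "r": float(r), "p": float(p)}
    slopes = pd.DataFrame(slope_rows).T
    return AncovaResult(terms, slopes, lam)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


# ---------------------------------------------------------------------------
# Analysis-battery helpers operating on pipeline outputs


def compare_global_measures(
    normalized: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Welch t-test per normalized global measure (HC vs IBS)."""
    rows = {}
    for col in normalized.columns:
        a = normalized.loc[groups == "HC", col].dropna()
        b = normalized.loc[groups == "IBS", col].dropna()
        res = welch_t(a, b)
        rows[col] = {
            "mean_HC": a.mean(), "sem_HC": a.sem(), "mean_IBS": b.mean(),
            "sem_IBS": b.sem(), "t": res.statistic, "df": res.df, "p_raw": res.p_raw,
        }
    return pd.DataFrame(rows).T


def hub_group_tests(hub_flags: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Fisher exact test per node on hub counts (HC vs IBS), BH-corrected
    across the node family."""
    hc_ids = groups.index[groups == "HC"]
    ibs_ids = groups.index[groups == "IBS"]
    rows = {}
    for node in hub_flags.columns:
        a_hub = int(hub_flags.loc[hc_ids, node].sum())
        b_hub = int(hub_flags.loc[ibs_ids, node].sum())
        table = np.array(
            [[a_hub, len(hc_ids) - a_hub], [b_hub, len(ibs_ids) - b_hub]], dtype=int
        )
        res = fisher_exact_2x2(table)
        rows[node] = {
            "pct_hub_HC": 100.0 * a_hub / len(hc_ids),
            "pct_hub_IBS": 100.0 * b_hub / len(ibs_ids),
            "odds_ratio": res.statistic,
            "p_raw": res.p_raw,
        }
    out = pd.DataFrame(rows).T
    out["p_fdr"] = bh_fdr(out["p_raw"].to_numpy())
    return out


def comodule_group_tests(
    comembership: dict[str, np.ndarray],
    n_subjects: dict[str, int],
    node_labels: Sequence[str],
) -> pd.DataFrame:
    """Fisher exact test per node pair on same-module counts, BH-corrected
    across the pair family."""
    freq_hc, freq_ibs = comembership["HC"], comembership["IBS"]
    n_hc, n_ibs = n_subjects["HC"], n_subjects["IBS"]
    rows = []
    n = freq_hc.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            a = int(round(freq_hc[i, j] * n_hc))
            b = int(round(freq_ibs[i, j] * n_ibs))
            table = np.array([[a, n_hc - a], [b, n_ibs - b]], dtype=int)
            res = fisher_exact_2x2(table)
            rows.append({
                "node_i": node_labels[i], "node_j": node_labels[j],
                "freq_HC": freq_hc[i, j], "freq_IBS": freq_ibs[i, j],
                "p_raw": res.p_raw,
            })
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p_raw"].to_numpy())
    return out


def spearman_table(
    manifest: pd.DataFrame,
    normalized: pd.DataFrame,
    instruments: Sequence[str],
    measures: Sequence[str] = (
        "clustering_coefficient",
        "betweenness_centrality",
        "characteristic_path_length",
    ),
) -> pd.DataFrame:
    """Spearman correlations between symptom scores and normalized global
    measures, in IBS patients only, BH-corrected across the table."""
    ibs = manifest.index[manifest["group"] == "IBS"]
    rows = []
    for instrument in instruments:
        for measure in measures:
            if len(ibs) < 4:
                rows.append({"instrument": instrument, "measure": measure,
                             "rho": np.nan, "p_raw": np.nan})
                continue
            res = spearman_assoc(
                manifest.loc[ibs, instrument].to_numpy(),
                normalized.loc[ibs, measure].to_numpy(),
            )
            rows.append({
                "instrument": instrument, "measure": measure,
                "rho": res.statistic, "p_raw": res.p_raw,
            })
    out = pd.DataFrame(rows)
    valid = out["p_raw"].notna()
    out["p_fdr"] = np.nan
    out.loc[valid, "p_fdr"] = bh_fdr(out.loc[valid, "p_raw"].to_numpy())
    return out
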