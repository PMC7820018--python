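"""ICC(3,1) stability scoring and stable-feature selection.

The reproducibility metric throughout is the intraclass correlation for a
two-way mixed-effects, consistency, single-measurement design:

    ICC(3,1) = (MS_R - MS_E) / (MS_R + (k - 1) MS_E)

where MS_R is the mean square for rows (subjects), MS_E the residual mean
square of the two-way ANOVA decomposition, and k the number of measurement
columns (timepoints, protocols or scanners, depending on the experiment).
Being a consistency coefficient, it is invariant to per-column offsets and
to a common affine rescaling of the whole matrix.

Classification bands: good (ICC >= 0.90), moderate (0.75 < ICC < 0.90),
poor (ICC <= 0.75).  The 0.90 boundary is counted as good; both thresholds
are configurable.

Experiment orchestration mirrors a phantom + cohort stability study:

* repeatability — test vs retest columns, rows are subject x protocol
  instances, per scanner and pooled; also the 32-subject two-scan cohort;
* intra-scanner reproducibility — k = 6 protocol columns per scanner,
  median over the three scanners;
* inter-scanner reproducibility — k = 3 scanner columns per protocol,
  median over the six protocols;
* clinical reproducibility — k = 3 protocol columns over the cohort, plus
  two pairwise contrasts (IV-contrast effect, slice-thickness effect);
* volume collinearity — per-protocol Spearman rho of each feature against
  tumor volume, median of the three protocols;
* selection — features whose pooled median ICC exceeds the threshold in
  both the repeatability and the reproducibility experiment groups, minus
  features strongly rank-correlated with tumor volume.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaDecomposition",
    "IccEstimate",
    "anova_two_way",
    "icc3",
    "classify_icc",
    "fdr_correct",
    "repeatability",
    "intra_scanner",
    "inter_scanner",
    "clinical_reproducibility",
    "volume_collinearity",
    "commonality",
    "select_stable",
    "category_summary",
    "feature_correlation_matrix",
    "feature_category",
]

GOOD_THRESHOLD = 0.90
MODERATE_THRESHOLD = 0.75


# ---------------------------------------------------------------------------
# core statistic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaDecomposition:
    """Mean squares and degrees of freedom of a subjects x raters matrix."""

    ms_rows: float
    ms_cols: float
    ms_error: float
    df_rows: int
    df_cols: int
    df_error: int


@dataclass(frozen=True)
class IccEstimate:
    """One ICC(3,1) value with its row-effect F-test.

    ``icc`` is NaN for a degenerate (zero-denominator, i.e. constant)
    matrix; callers treat NaN as 'poor' in summaries.
    """

    icc: float
    p_value: float
    n: int
    k: int
    anova: AnovaDecomposition


def _as_matrix(matrix) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError(f"measurement matrix must be 2D, got ndim={m.ndim}")
    # complete-case: drop rows with any missing cell
    keep = ~np.isnan(m).any(axis=1)
    if not keep.all():
        logger.warning("dropping %d incomplete rows of %d", (~keep).sum(), len(keep))
        m = m[keep]
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError(f"need n >= 2 subjects and k >= 2 columns, got {n} x {k}")
    return m


def anova_two_way(matrix) -> AnovaDecomposition:
    """Two-way ANOVA decomposition (rows = subjects, columns = raters).

    SS_rows = k sum_i (rowmean_i - grand)^2, SS_cols = n sum_j
    (colmean_j - grand)^2, SS_error = SS_total - SS_rows - SS_cols, with
    degrees of freedom (n-1), (k-1) and (n-1)(k-1).
    """
    m = _as_matrix(matrix)
    n, k = m.shape
    grand = m.mean()
    ss_rows = k * float(np.sum((m.mean(axis=1) - grand) ** 2))
    ss_cols = n * float(np.sum((m.mean(axis=0) - grand) ** 2))
    ss_total = float(np.sum((m - grand) ** 2))
    ss_error = max(ss_total - ss_rows - ss_cols, 0.0)
    return AnovaDecomposition(
        ms_rows=ss_rows / (n - 1),
        ms_cols=ss_cols / (k - 1),
        ms_error=ss_error / ((n - 1) * (k - 1)),
        df_rows=n - 1,
        df_cols=k - 1,
        df_error=(n - 1) * (k - 1),
    )


def icc3(matrix) -> IccEstimate:
    """ICC(3,1) of an n x k measurement matrix, with the row-effect F test.

    Returns NaN (never raises) for a constant matrix, where the coefficient
    is undefined; the event is logged.
    """
    m = _as_matrix(matrix)
    n, k = m.shape
    dec = anova_two_way(m)
    denom = dec.ms_rows + (k - 1) * dec.ms_error
    if denom <= 0:
        logger.warning("degenerate (constant) matrix: ICC undefined, returning NaN")
        return IccEstimate(float("nan"), float("nan"), n, k, dec)
    value = (dec.ms_rows - dec.ms_error) / denom
    if dec.ms_error == 0:
        p = 0.0  # perfect consistency: F is infinite
    else:
        f = dec.ms_rows / dec.ms_error
        p = float(stats.f.sf(f, dec.df_rows, dec.df_error))
    return IccEstimate(float(value), p, n, k, dec)


def _icc_array(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ICC(3,1) + p-value over a (features, n, k) stack."""
    m = np.asarray(values, dtype=float)
    _, n, k = m.shape
    grand = m.mean(axis=(1, 2), keepdims=True)
    row = m.mean(axis=2, keepdims=True) - grand
    col = m.mean(axis=1, keepdims=True) - grand
    ss_rows = k * np.sum(row[:, :, 0] ** 2, axis=1)
    ss_cols = n * np.sum(col[:, 0, :] ** 2, axis=1)
    ss_total = np.sum((m - grand) ** 2, axis=(1, 2))
    ss_err = np.maximum(ss_total - ss_rows - ss_cols, 0.0)
    ms_r = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(denom > 0, (ms_r - ms_e) / np.where(denom > 0, denom, 1.0), np.nan)
        f = np.where(ms_e > 0, ms_r / np.where(ms_e > 0, ms_e, 1.0), np.inf)
    p = np.where(
        np.isfinite(f), stats.f.sf(np.where(np.isfinite(f), f, 1.0), n - 1, (n - 1) * (k - 1)), 0.0
    )
    p = np.where(denom > 0, p, np.nan)
    return icc, p


def classify_icc(
    value: float,
    good: float = GOOD_THRESHOLD,
    moderate: float = MODERATE_THRESHOLD,
) -> str:
    """Map an ICC (or Spearman rho) to {good, moderate, poor}.

    ``good`` iff value >= 0.90; ``moderate`` iff 0.75 < value < 0.90;
    ``poor`` iff value <= 0.75.  NaN (undefined) counts as poor, logged.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        logger.warning("undefined stability value classified as poor")
        return "poor"
    if value >= good:
        return "good"
    if value > moderate:
        return "moderate"
    return "poor"


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-safe)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# experiment orchestration on long-format feature tables
# ---------------------------------------------------------------------------


def _pivot(table: pd.DataFrame, row_keys: list[str], col_key: str) -> tuple[np.ndarray, list[str], list]:
    """Pivot a long table to a (features, rows, cols) stack.

    Rows with any missing cell for a feature are excluded feature-wise by
    the downstream complete-case handling; the pivot itself requires the
    table to be complete (the synthetic generators guarantee it).
    """
    wide = table.pivot_table(
        index=["feature"] + row_keys, columns=col_key, values="value", aggfunc="first"
    )
    features = wide.index.get_level_values("feature").unique().tolist()
    cols = wide.columns.tolist()
    stacks = []
    for f in features:
        sub = wide.xs(f, level="feature")
        stacks.append(sub.to_numpy())
    arr = np.stack(stacks)
    if np.isnan(arr).any():
        raise ValueError("feature table has missing cells for some slots")
    return arr, features, cols


def _stability_frame(table, row_keys, col_key, experiment: str) -> pd.DataFrame:
    arr, features, cols = _pivot(table, row_keys, col_key)
    if arr.shape[2] < 2:
        raise ValueError(
            f"experiment {experiment!r}: need >= 2 columns of {col_key!r}, "
            f"found {cols}"
        )
    icc, p = _icc_array(arr)
    df = pd.DataFrame(
        {
            "feature": features,
            "experiment": experiment,
            "icc": icc,
            "p_value": p,
        }
    ).set_index("feature")
    df["p_adj"] = fdr_correct(df["p_value"].to_numpy())
    df["classification"] = [classify_icc(v) for v in df["icc"]]
    return df


def _median_frame(frames: dict[str, pd.DataFrame], experiment: str) -> pd.DataFrame:
    """Median ICC over sub-experiments, with Fisher-style p aggregation
    replaced by the median p (reported for reference only)."""
    iccs = pd.DataFrame({k: v["icc"] for k, v in frames.items()})
    ps = pd.DataFrame({k: v["p_value"] for k, v in frames.items()})
    out = pd.DataFrame(
        {
            "experiment": experiment,
            "icc": iccs.median(axis=1),
            "p_value": ps.median(axis=1),
        }
    )
    out["p_adj"] = fdr_correct(out["p_value"].to_numpy())
    out["classification"] = [classify_icc(v) for v in out["icc"]]
    return out


def repeatability(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Test-retest ICC per feature: per scanner and pooled over scanners.

    Rows are subject x protocol instances (so a one-subject phantom
    contributes one row per protocol), columns the two timepoints.
    """
    tps = sorted(table["timepoint"].unique())
    if len(tps) < 2:
        raise ValueError(f"repeatability needs 2 timepoints, found {tps}")
    out: dict[str, pd.DataFrame] = {}
    scanners = sorted(table["scanner"].unique())
    for sc in scanners:
        sub = table[table["scanner"] == sc]
        out[f"repeatability[{sc}]"] = _stability_frame(
            sub, ["subject", "protocol"], "timepoint", f"repeatability[{sc}]"
        )
    label = "repeatability[pooled]"
    out[label] = _stability_frame(
        table, ["subject", "scanner", "protocol"], "timepoint", label
    )
    return out


def intra_scanner(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Reproducibility across protocols within each scanner.

    ICC with k = #protocol columns per scanner (rows = subject x timepoint
    instances); the reported value is the median over the scanners.
    """
    per: dict[str, pd.DataFrame] = {}
    for sc in sorted(table["scanner"].unique()):
        sub = table[table["scanner"] == sc]
        per[sc] = _stability_frame(
            sub, ["subject", "timepoint"], "protocol", f"intra_scanner[{sc}]"
        )
    return _median_frame(per, "intra_scanner[median]"), per


def inter_scanner(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Reproducibility across scanners within each protocol.

    ICC with k = #scanner columns per protocol; reported value is the
    median over the protocols.
    """
    per: dict[str, pd.DataFrame] = {}
    for pr in sorted(table["protocol"].unique()):
        sub = table[table["protocol"] == pr]
        per[pr] = _stability_frame(
            sub, ["subject", "timepoint"], "scanner", f"inter_scanner[{pr}]"
        )
    return _median_frame(per, "inter_scanner[median]"), per


def clinical_reproducibility(
    table: pd.DataFrame, pair: tuple[str, str] | None = None
) -> pd.DataFrame:
    """Cohort reproducibility across clinical protocols.

    Default: k = 3 protocol columns over all subjects.  With ``pair``, a
    k = 2 contrast (e.g. IV-contrast effect WBCECT2 vs NCCTT2, or
    slice-thickness effect BLDCT5 vs WBCECT2).
    """
    protocols = sorted(table["protocol"].unique())
    if pair is not None:
        unknown = [p for p in pair if p not in protocols]
        if unknown:
            raise ValueError(
                f"unknown protocol label(s) {unknown}; available: {protocols}"
            )
        table = table[table["protocol"].isin(pair)]
        label = f"clinical[{pair[0]} vs {pair[1]}]"
    else:
        label = "clinical[all protocols]"
    return _stability_frame(table, ["subject", "timepoint"], "protocol", label)


def volume_collinearity(
    table: pd.DataFrame,
    volumes: pd.Series,
    good: float = GOOD_THRESHOLD,
    moderate: float = MODERATE_THRESHOLD,
) -> pd.DataFrame:
    """Spearman rho of each feature against tumor volume, per protocol.

    The reported rho per feature is the median over the protocols
    (average-rank tie handling, as in :func:`scipy.stats.spearmanr`).
    Classification mirrors the ICC bands on rho.
    """
    missing = set(table["subject"].unique()) - set(volumes.index)
    if missing:
        raise ValueError(f"volumes missing for subjects: {sorted(missing)[:5]} ...")
    rows = []
    protocols = sorted(table["protocol"].unique())
    for feat, sub in table.groupby("feature", sort=True):
        rhos = {}
        for pr in protocols:
            s = sub[sub["protocol"] == pr].set_index("subject")["value"]
            v = volumes.loc[s.index]
            rho = stats.spearmanr(s.to_numpy(), v.to_numpy()).statistic
            rhos[pr] = float(rho)
        med = float(np.median(list(rhos.values())))
        rows.append({"feature": feat, "rho": med, **{f"rho[{p}]": r for p, r in rhos.items()}})
    out = pd.DataFrame(rows).set_index("feature")
    out["classification"] = [classify_icc(abs(r), good, moderate) for r in out["rho"]]
    return out


def commonality(
    results_by_experiment: dict[str, pd.DataFrame | set],
    level: str = "good",
) -> dict[frozenset, dict]:
    """Venn-region membership of 'good' feature sets across experiments.

    Accepts either stability frames (classification column) or plain sets.
    Returns, for every non-empty combination of experiment labels, the
    features belonging to exactly those experiments' good sets.
    """
    sets = {}
    for label, res in results_by_experiment.items():
        if isinstance(res, pd.DataFrame):
            sets[label] = set(res.index[res["classification"] == level])
        else:
            sets[label] = set(res)
    labels = list(sets)
    regions: dict[frozenset, dict] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(set(), *(sets[l] for l in labels if l not in combo))
            members = inside - outside
            regions[frozenset(combo)] = {
                "count": len(members),
                "members": sorted(members),
            }
    return regions


def feature_category(feature_id: str) -> str:
    """Category tag: TA (original image), LOG (any LoG scale), WF (wavelet)."""
    if feature_id.startswith("log-sigma"):
        return "LOG"
    if feature_id.startswith("wavelet"):
        return "WF"
    return "TA"


def select_stable(
    repeatability_results: dict[str, pd.DataFrame],
    reproducibility_results: dict[str, pd.DataFrame],
    collinearity: pd.DataFrame | None = None,
    icc_threshold: float = GOOD_THRESHOLD,
    rho_threshold: float = GOOD_THRESHOLD,
) -> pd.DataFrame:
    """Two-step stable-feature selection.

    Step 1 keeps features whose *median* ICC over the repeatability
    experiment group and over the reproducibility experiment group both
    exceed ``icc_threshold``.  Step 2 removes features with
    ``|rho| > rho_threshold`` against tumor volume.  The result is sorted
    by decreasing overall median ICC (median over all experiments of both
    groups) and tagged TA / LOG / WF.
    """
    rep = pd.DataFrame({k: v["icc"] for k, v in repeatability_results.items()})
    rpr = pd.DataFrame({k: v["icc"] for k, v in reproducibility_results.items()})
    rep_median = rep.median(axis=1)
    rpr_median = rpr.median(axis=1)
    overall = pd.concat([rep, rpr], axis=1).median(axis=1)
    keep = (rep_median > icc_threshold) & (rpr_median > icc_threshold)
    selected = pd.DataFrame(
        {
            "median_icc": overall[keep],
            "repeatability_median_icc": rep_median[keep],
            "reproducibility_median_icc": rpr_median[keep],
        }
    )
    if collinearity is not None:
        rho = collinearity["rho"].reindex(selected.index)
        selected["rho_volume"] = rho
        selected = selected[~(rho.abs() > rho_threshold)]
    selected["category"] = [feature_category(f) for f in selected.index]
    return selected.sort_values("median_icc", ascending=False)


def category_summary(stable: pd.DataFrame, icc_column: str = "median_icc") -> pd.DataFrame:
    """Per-category (TA/LOG/WF) median ICC, sample std and count.

    Sample standard deviation uses the n-1 denominator; a single-member
    category reports std 0 (logged).  Values rounded to 3 decimals for
    reporting.
    """
    rows = []
    for cat, grp in stable.groupby("category"):
        vals = grp[icc_column].to_numpy(dtype=float)
        if len(vals) == 1:
            logger.info("category %s has a single member; std reported as 0", cat)
            std = 0.0
        else:
            std = float(np.std(vals, ddof=1))
        rows.append(
            {
                "category": cat,
                "median_icc": round(float(np.median(vals)), 3),
                "std": round(std, 3),
                "count": len(vals),
            }
        )
    return pd.DataFrame(rows).set_index("category")


def feature_correlation_matrix(
    table: pd.DataFrame,
    features: list[str] | None = None,
    ranking: pd.Series | None = None,
    top: int = 50,
) -> pd.DataFrame:
    """Spearman correlation matrix between features (default: top 50).

    Observations are all (subject, scanner, protocol, timepoint) slots;
    by default the feature subset is the ``top`` features by the supplied
    repeatability ranking (median ICC), else all features.
    """
    if features is None:
        if ranking is not None:
            features = ranking.sort_values(ascending=False).index[:top].tolist()
        else:
            features = sorted(table["feature"].unique())[:top]
    wide = table[table["feature"].isin(features)].pivot_table(
        index=["subject", "scanner", "protocol", "timepoint"],
        columns="feature",
        values="value",
        aggfunc="first",
    )[features]
    return wide.corr(method="spearman")
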