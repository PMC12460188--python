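"""Per-ROI group inference on baseline-corrected coherence.

Order of operations: Fisher z-transform of the corrected values, outlier
removal (1.5 IQR fence, then iterative trimming of extrema until skewness
and excess kurtosis fall below critical values), one-way within-dyad
repeated-measures ANOVA over the four conditions with Mauchly's sphericity
test and Greenhouse-Geisser correction, Benjamini-Hochberg FDR over ROIs,
and post hoc paired t-tests restricted to contrasts containing the
cooperation condition, FDR-corrected jointly across all post hoc tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as _linalg
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .extraction import ANALYSIS_CONDITIONS

__all__ = [
    "AnovaResult",
    "fisher_z",
    "remove_outliers",
    "rm_anova",
    "fdr_bh",
    "posthoc_cooperation_tests",
    "run_group_stats",
]

POSTHOC_CONTRASTS = (
    ("cooperation", "solo"),
    ("cooperation", "communication"),
    ("cooperation", "competition"),
)


def fisher_z(values: np.ndarray, clip: float = 1.0 - 1e-7) -> np.ndarray:
    """Fisher z-transform (atanh), with |v| clipped just inside 1."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v) | np.isnan(v)):
        raise ValueError("values contain non-finite entries")
    return np.arctanh(np.clip(v, -clip, clip))


def remove_outliers(
    values: np.ndarray,
    skew_limit: float = 1.0,
    kurtosis_limit: float = 2.0,
    floor: float = 0.7,
    min_survivors: int = 5,
) -> tuple[np.ndarray, list[dict]]:
    """Two-stage outlier removal; returns a keep-mask and a removal log.

    Stage 1 fences values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].  Stage 2
    iteratively drops the single most extreme remaining value (largest
    absolute deviation from the current median) until |skewness| and
    |excess kurtosis| fall below the critical values, or until fewer than
    ``floor`` of the original values would remain.  With fewer than
    ``min_survivors`` survivors the caller should exclude the cell.
    """
    v = np.asarray(values, dtype=float)
    n0 = v.size
    if n0 < min_survivors:
        raise ValueError(f"need at least {min_survivors} values, got {n0}")
    keep = np.isfinite(v)
    log: list[dict] = []
    q1, q3 = np.percentile(v[keep], [25, 75])
    iqr = q3 - q1
    fence = (q1 - 1.5 * iqr, q3 + 1.5 * iqr)
    for i in np.flatnonzero(keep):
        if not fence[0] <= v[i] <= fence[1]:
            keep[i] = False
            log.append({"index": int(i), "value": float(v[i]), "reason": "iqr"})
    floor_n = int(np.ceil(floor * n0))
    while keep.sum() > max(floor_n, 3):
        sample = v[keep]
        if np.ptp(sample) == 0:  # moments undefined, nothing to trim
            break
        sk = _stats.skew(sample)
        ku = _stats.kurtosis(sample)  # excess kurtosis, normal = 0
        if abs(sk) < skew_limit and abs(ku) < kurtosis_limit:
            break
        if keep.sum() - 1 < floor_n:
            break
        med = np.median(sample)
        cand = np.flatnonzero(keep)
        worst = cand[np.argmax(np.abs(v[cand] - med))]
        keep[worst] = False
        log.append(
            {
                "index": int(worst),
                "value": float(v[worst]),
                "reason": "moments",
            }
        )
    return keep, log


@dataclass(frozen=True)
class AnovaResult:
    """Omnibus within-subject ANOVA summary for one ROI."""

    f_value: float
    df_effect: float
    df_error: float
    ss_condition: float
    ss_subject: float
    ss_error: float
    epsilon: float
    mauchly_w: float
    mauchly_chi2: float
    mauchly_p: float
    gg_applied: bool
    p_value: float
    p_uncorrected_df: float
    n_subjects: int
    degenerate: bool = False


def rm_anova(values: np.ndarray, mauchly_alpha: float = 0.05) -> AnovaResult:
    """One-way repeated-measures ANOVA on an (n_subjects, k) value matrix.

    Partitions the total sum of squares into condition, subject and error
    terms; F = MS_condition / MS_error.  Mauchly's W tests sphericity on the
    orthonormal-contrast covariance; when its p-value falls below
    ``mauchly_alpha`` both degrees of freedom are multiplied by the
    Greenhouse-Geisser epsilon.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2:
        raise ValueError("values must be (n_subjects, k)")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = y.mean()
    ss_subject = k * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_condition = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_error = ss_total - ss_subject - ss_condition
    df1 = k - 1.0
    df2 = (k - 1.0) * (n - 1.0)
    ms_cond = ss_condition / df1
    ms_err = ss_error / df2
    degenerate = ms_err <= np.finfo(float).eps * max(1.0, abs(ss_total))
    f_value = np.inf if degenerate and ms_cond > 0 else ms_cond / max(ms_err, 1e-300)

    # sphericity on the orthonormal contrast space
    c = _linalg.helmert(k, full=False)  # (k-1, k), orthonormal rows
    s = np.cov(y, rowvar=False)
    t = c @ s @ c.T
    eig_mean = np.trace(t) / (k - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = float(np.linalg.det(t) / eig_mean ** (k - 1.0))
    w = float(np.clip(w, 1e-300, 1.0)) if np.isfinite(w) else 1e-300
    chi_df = k * (k - 1.0) / 2.0 - 1.0
    correction = 1.0 - (2.0 * (k - 1.0) ** 2 + (k - 1.0) + 2.0) / (
        6.0 * (k - 1.0) * (n - 1.0)
    )
    chi2 = -(n - 1.0) * correction * np.log(w)
    mauchly_p = float(_stats.chi2.sf(chi2, chi_df)) if chi_df > 0 else 1.0

    eps = float(np.trace(t) ** 2 / ((k - 1.0) * np.trace(t @ t)))
    eps = float(np.clip(eps, 1.0 / (k - 1.0), 1.0))

    gg = mauchly_p < mauchly_alpha
    p_plain = float(_stats.f.sf(f_value, df1, df2))
    p_gg = float(_stats.f.sf(f_value, eps * df1, eps * df2))
    return AnovaResult(
        f_value=float(f_value),
        df_effect=df1 * (eps if gg else 1.0),
        df_error=df2 * (eps if gg else 1.0),
        ss_condition=float(ss_condition),
        ss_subject=float(ss_subject),
        ss_error=float(ss_error),
        epsilon=eps,
        mauchly_w=w,
        mauchly_chi2=float(chi2),
        mauchly_p=mauchly_p,
        gg_applied=bool(gg),
        p_value=p_gg if gg else p_plain,
        p_uncorrected_df=p_plain,
        n_subjects=n,
        degenerate=bool(degenerate),
    )


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted q-values, reject mask)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def posthoc_cooperation_tests(
    cell_values: dict[tuple, np.ndarray] | pd.DataFrame,
    significant_rois: list,
    q: float = 0.05,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Paired two-tailed t-tests of cooperation against the other conditions.

    ``cell_values`` maps (roi, condition) to per-dyad value vectors (aligned
    by dyad, NaN where removed), or is a long DataFrame with columns roi,
    condition, dyad, value.  Tests run only for omnibus-significant ROIs;
    the BH correction is applied jointly across all contrasts x ROIs.
    """
    if isinstance(cell_values, pd.DataFrame):
        store: dict[tuple, np.ndarray] = {}
        dyads = sorted(cell_values["dyad"].unique())
        piv = cell_values.pivot_table(
            index="dyad", columns=["roi", "condition"], values="value",
            dropna=False,
        ).reindex(dyads)
        for key in piv.columns:
            store[key] = piv[key].to_numpy()
        cell_values = store
    rows = []
    for roi in significant_rois:
        coop = cell_values.get((roi, "cooperation"))
        if coop is None:
            continue
        for cond in ("solo", "communication", "competition"):
            other = cell_values.get((roi, cond))
            if other is None:
                continue
            ok = np.isfinite(coop) & np.isfinite(other)
            n = int(ok.sum())
            if n < min_pairs:
                rows.append(
                    {
                        "roi": roi,
                        "contrast": f"cooperation-{cond}",
                        "t": np.nan,
                        "df": n - 1,
                        "p": np.nan,
                        "n_pairs": n,
                        "skipped": True,
                    }
                )
                continue
            d = coop[ok] - other[ok]
            if np.allclose(d.std(ddof=1), 0.0):
                if np.allclose(d.mean(), 0.0):
                    t, p = 0.0, 1.0
                else:  # constant nonzero difference: the t -> inf limit
                    t, p = np.inf * np.sign(d.mean()), 0.0
            else:
                t, p = _stats.ttest_rel(coop[ok], other[ok])
            rows.append(
                {
                    "roi": roi,
                    "contrast": f"cooperation-{cond}",
                    "t": float(t),
                    "df": n - 1,
                    "p": float(p),
                    "n_pairs": n,
                    "skipped": False,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["roi", "contrast", "t", "df", "p", "n_pairs", "skipped"],
    )
    if out.empty:
        out["q"] = []
        out["significant"] = []
        return out
    tested = out["p"].notna()
    qvals = np.full(len(out), np.nan)
    rej = np.zeros(len(out), dtype=bool)
    if tested.any():
        qvals[tested.to_numpy()], rej[tested.to_numpy()] = fdr_bh(
            out.loc[tested, "p"].to_numpy(), q
        )
    out["q"] = qvals
    out["significant"] = rej
    out["direction"] = np.sign(out["t"]).fillna(0).astype(int)
    return out


def run_group_stats(
    corrected: pd.DataFrame,
    fdr_q: float = 0.05,
    min_complete: int = 5,
    sqrt_before_z: bool = False,
) -> dict:
    """Full inference on the corrected table (long format).

    Pipeline per ROI: Fisher z (optionally on the signed square root of the
    corrected values), per-condition outlier removal, listwise complete
    cases, repeated-measures ANOVA, BH FDR over ROIs, post hoc cooperation
    contrasts for significant ROIs.  Returns omnibus and post hoc tables
    plus the outlier log.
    """
    df = corrected[~corrected["missing"]].copy() if "missing" in corrected else corrected.copy()
    vals = df["value"].to_numpy(dtype=float)
    if sqrt_before_z:
        vals = np.sign(vals) * np.sqrt(np.abs(vals))
    df["z"] = fisher_z(vals)

    dyads = sorted(df["dyad"].unique())
    rois = sorted(df["roi"].unique())
    cell: dict[tuple, np.ndarray] = {}
    outlier_rows = []
    for roi in rois:
        for cond in ANALYSIS_CONDITIONS:
            sub = df[(df["roi"] == roi) & (df["condition"] == cond)]
            v = (
                sub.set_index("dyad")["z"].reindex(dyads).to_numpy(dtype=float)
            )
            present = np.isfinite(v)
            if present.sum() >= min_complete:
                keep, log = remove_outliers(
                    v[present], min_survivors=min_complete
                )
                idx = np.flatnonzero(present)
                removed = idx[~keep]
                v[removed] = np.nan
                for entry in log:
                    outlier_rows.append(
                        {
                            "roi": roi,
                            "condition": cond,
                            "dyad": dyads[idx[entry["index"]]],
                            "value": entry["value"],
                            "reason": entry["reason"],
                        }
                    )
            cell[(roi, cond)] = v

    omnibus_rows = []
    for roi in rois:
        mat = np.column_stack([cell[(roi, c)] for c in ANALYSIS_CONDITIONS])
        complete = np.isfinite(mat).all(axis=1)
        row: dict = {"roi": roi, "n_complete": int(complete.sum())}
        if complete.sum() < min_complete:
            row.update(
                {k: np.nan for k in ("F", "df1", "df2", "epsilon", "mauchly_w",
                                     "mauchly_p", "p")},
                gg_applied=False,
                excluded=True,
            )
        else:
            res = rm_anova(mat[complete])
            row.update(
                F=res.f_value,
                df1=res.df_effect,
                df2=res.df_error,
                epsilon=res.epsilon,
                mauchly_w=res.mauchly_w,
                mauchly_p=res.mauchly_p,
                gg_applied=res.gg_applied,
                p=res.p_value,
                excluded=bool(res.degenerate),
            )
        omnibus_rows.append(row)
    omnibus = pd.DataFrame(omnibus_rows)
    tested = omnibus["p"].notna() & ~omnibus["excluded"]
    omnibus["q"] = np.nan
    omnibus["significant"] = False
    if tested.any():
        qv, rej = fdr_bh(omnibus.loc[tested, "p"].to_numpy(), fdr_q)
        omnibus.loc[tested, "q"] = qv
        omnibus.loc[tested, "significant"] = rej
    significant_rois = omnibus.loc[omnibus["significant"], "roi"].tolist()
    posthoc = posthoc_cooperation_tests(cell, significant_rois, fdr_q)
    return {
        "omnibus": omnibus,
        "posthoc": posthoc,
        "outlier_log": pd.DataFrame(
            outlier_rows, columns=["roi", "condition", "dyad", "value", "reason"]
        ),
        "cell_values": cell,
    }
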