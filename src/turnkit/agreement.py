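"""Agreement statistics for validating detected turn boundaries.

Compares two time-event series (rater vs rater, or rater vs algorithm):
ICC(2,1) for absolute agreement, Spearman's rho for relative agreement,
RMSE, and Bland-Altman limits of agreement (bias +- 1.96 SD of the paired
differences) expressed both in seconds and as a percentage of the grand
mean. Also provides the per-feature two-group comparison (Shapiro-Wilk
normality gate choosing t-test vs Mann-Whitney U).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport",
    "icc_2_1",
    "limits_of_agreement",
    "compare_event_series",
    "compare_groups",
]


@dataclass
class AgreementReport:
    icc21: float
    rho: float
    rmse: float
    loa_abs: float
    loa_pct: float
    bias: float
    bland_altman: List[Tuple[float, float]]  # (pair mean, difference)
    n: int
    n_unmatched_ref: int = 0
    n_unmatched_test: int = 0

    def as_dict(self) -> dict:
        return {
            "icc21": self.icc21, "rho": self.rho, "rmse": self.rmse,
            "loa_abs": self.loa_abs, "loa_pct": self.loa_pct,
            "bias": self.bias, "n": self.n,
            "n_unmatched_ref": self.n_unmatched_ref,
            "n_unmatched_test": self.n_unmatched_test,
        }


def icc_2_1(pairs: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``pairs`` is an (n, k) table of n targets rated by k raters (k=2 for
    boundary comparisons). From the two-way ANOVA mean squares:

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    Returns NaN (with a warning) for a zero-variance table.
    """
    x = np.asarray(pairs, float)
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC(2,1) needs at least 3 paired measurements")
    if not np.all(np.isfinite(x)):
        raise ValueError("ICC input must be finite")
    grand = x.mean()
    ss_total = np.sum((x - grand) ** 2)
    if ss_total == 0:
        warnings.warn("zero total variance; ICC undefined")
        return float("nan")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        warnings.warn("degenerate ANOVA decomposition; ICC undefined")
        return float("nan")
    return float((ms_r - ms_e) / denom)


def limits_of_agreement(a: Sequence[float], b: Sequence[float]
                        ) -> Tuple[float, float, float]:
    """Bland-Altman limits: returns (loa_abs, loa_pct, bias).

    d = a - b; bias = mean(d); loa_abs = 1.96 * SD(d); loa_pct expresses
    loa_abs as a percentage of the mean of the pairwise averages (NaN with
    a warning when that grand mean is zero).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    d = a - b
    bias = float(np.mean(d))
    loa_abs = float(1.96 * np.std(d, ddof=1)) if d.size >= 2 else 0.0
    grand = float(np.mean((a + b) / 2.0))
    if grand == 0:
        warnings.warn("grand mean is zero; LOA%% undefined")
        loa_pct = float("nan")
    else:
        loa_pct = 100.0 * loa_abs / grand
    return loa_abs, loa_pct, bias


def _match_events(ref_starts: np.ndarray, test_starts: np.ndarray,
                  tol: float) -> List[Tuple[int, int]]:
    """Greedy nearest-start 1:1 matching within ``tol`` seconds."""
    cand = [
        (abs(ts - rs), i, j)
        for i, rs in enumerate(ref_starts)
        for j, ts in enumerate(test_starts)
        if abs(ts - rs) <= tol
    ]
    cand.sort()
    used_r, used_t, matches = set(), set(), []
    for _, i, j in cand:
        if i in used_r or j in used_t:
            continue
        used_r.add(i)
        used_t.add(j)
        matches.append((i, j))
    return sorted(matches)


def compare_event_series(ref, test, match_tol_s: float = 2.0
                         ) -> Dict[str, AgreementReport]:
    """Agreement between two turn-event series, per boundary.

    ``ref`` and ``test`` are sequences of objects with ``start_s``/``end_s``
    (TurnEvent or EventAnnotation). Events are matched 1:1 by nearest start
    within ``match_tol_s``; unmatched events are excluded and counted.
    Returns ``{"start": AgreementReport, "end": AgreementReport}``.
    """
    ref_starts = np.array([e.start_s for e in ref])
    test_starts = np.array([e.start_s for e in test])
    matches = _match_events(ref_starts, test_starts, match_tol_s)
    if len(matches) < 3:
        raise ValueError(f"only {len(matches)} matched pairs; need at least 3")
    n_un_ref = len(ref) - len(matches)
    n_un_test = len(test) - len(matches)

    out = {}
    for boundary in ("start", "end"):
        attr = f"{boundary}_s"
        a = np.array([getattr(ref[i], attr) for i, _ in matches])
        b = np.array([getattr(test[j], attr) for _, j in matches])
        icc = icc_2_1(np.column_stack([a, b]))
        rho = float(stats.spearmanr(a, b).statistic)
        rmse = float(np.sqrt(np.mean((a - b) ** 2)))
        loa_abs, loa_pct, bias = limits_of_agreement(a, b)
        out[boundary] = AgreementReport(
            icc21=icc, rho=rho, rmse=rmse, loa_abs=loa_abs, loa_pct=loa_pct,
            bias=bias,
            bland_altman=list(zip(((a + b) / 2).tolist(), (a - b).tolist())),
            n=len(matches),
            n_unmatched_ref=n_un_ref, n_unmatched_test=n_un_test,
        )
    return out


def pooled_event_agreement(series_pairs, match_tol_s: float = 2.0
                           ) -> Dict[str, AgreementReport]:
    """Agreement over several sessions: match events within each session,
    pool the matched boundary pairs, then compute one report per boundary.

    ``series_pairs`` is an iterable of (ref_events, test_events) tuples, one
    per session, each in that session's own time base.
    """
    starts_a, starts_b, ends_a, ends_b = [], [], [], []
    n_un_ref = n_un_test = 0
    for ref, test in series_pairs:
        m = _match_events(np.array([e.start_s for e in ref]),
                          np.array([e.start_s for e in test]), match_tol_s)
        n_un_ref += len(ref) - len(m)
        n_un_test += len(test) - len(m)
        for i, j in m:
            starts_a.append(ref[i].start_s)
            starts_b.append(test[j].start_s)
            ends_a.append(ref[i].end_s)
            ends_b.append(test[j].end_s)
    if len(starts_a) < 3:
        raise ValueError(f"only {len(starts_a)} matched pairs; need at least 3")
    out = {}
    for boundary, (a, b) in (("start", (starts_a, starts_b)),
                             ("end", (ends_a, ends_b))):
        a, b = np.asarray(a), np.asarray(b)
        loa_abs, loa_pct, bias = limits_of_agreement(a, b)
        out[boundary] = AgreementReport(
            icc21=icc_2_1(np.column_stack([a, b])),
            rho=float(stats.spearmanr(a, b).statistic),
            rmse=float(np.sqrt(np.mean((a - b) ** 2))),
            loa_abs=loa_abs, loa_pct=loa_pct, bias=bias,
            bland_altman=list(zip(((a + b) / 2).tolist(), (a - b).tolist())),
            n=a.size, n_unmatched_ref=n_un_ref, n_unmatched_test=n_un_test,
        )
    return out


def compare_groups(features_pd: pd.DataFrame, features_cl: pd.DataFrame,
                   alpha: float = 0.05, fdr: bool = False) -> pd.DataFrame:
    """Per-feature two-group comparison with a normality gate.

    For each shared feature column: Shapiro-Wilk on each group; if both are
    compatible with normality (p > 0.05) a two-sample t-test, otherwise a
    Mann-Whitney U-test. Group z-scores are computed against the pooled
    mean/SD. Constant features are skipped (test = 'skipped'). With
    ``fdr=True`` a Benjamini-Hochberg corrected significance column is
    added (off by default).
    """
    rows = []
    for col in features_pd.columns:
        if col not in features_cl.columns:
            continue
        a = features_pd[col].to_numpy(float)
        b = features_cl[col].to_numpy(float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size < 3 or b.size < 3:
            rows.append((col, "skipped", np.nan, np.nan, np.nan, False))
            continue
        pooled = np.concatenate([a, b])
        psd = pooled.std(ddof=1)
        if psd == 0 or a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
            rows.append((col, "skipped", np.nan, np.nan, np.nan, False))
            continue
        z_pd = (a.mean() - pooled.mean()) / psd
        z_cl = (b.mean() - pooled.mean()) / psd
        normal = (stats.shapiro(a).pvalue > 0.05) and (stats.shapiro(b).pvalue > 0.05)
        if normal:
            p = float(stats.ttest_ind(a, b).pvalue)
            test = "t-test"
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            test = "mann-whitney"
        rows.append((col, test, p, z_pd, z_cl, p < alpha))
    df = pd.DataFrame(rows, columns=["feature_id", "test", "p_value",
                                     "z_pd", "z_cl", "significant"])
    if fdr:
        from statsmodels.stats.multitest import multipletests
        mask = df["p_value"].notna()
        rej = np.zeros(len(df), bool)
        if mask.any():
            rej[mask.to_numpy()] = multipletests(
                df.loc[mask, "p_value"], alpha=alpha, method="fdr_bh")[0]
        df["significant_fdr"] = rej
    return df
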