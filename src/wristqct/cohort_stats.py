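"""Cohort-level statistics: correlation, regression, agreement, group tests.

The layer reproduces the statistical toolkit of a paired-modality bone study:
Pearson correlation with Fisher-z 95 % confidence intervals, simple linear
regression with R^2, Bland-Altman limits of agreement, the Mann-Whitney
U-test (exact by enumeration for small samples), the Shapiro-Wilk normality
test, and normality-gated descriptive summaries (mean +/- SD when normal at
alpha = 0.05, otherwise median [Q1 ; Q3]).

Shapiro-Wilk follows Royston's 1995 polynomial approximation (weights from
normal order-statistic means, log-normal null transformation of 1 - W);
Mann-Whitney enumerates every rank assignment when min(n, m) <= 8 and there
are no ties, switching to the tie-corrected normal approximation otherwise.
All tests are two-sided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from math import asin, comb, sqrt
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps


# --------------------------------------------------------------------------
# correlation / regression / agreement

def pearson_with_ci(x, y, alpha: float = 0.05):
    """Pearson r with Fisher-z CI and two-sided t-test p-value.

    Returns ``(r, (ci_low, ci_high), p)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need paired samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("undefined correlation: zero variance")
    r = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) < 1.0:
        t = r * sqrt((n - 2) / (1 - r * r))
        p = float(2 * sps.t.sf(abs(t), n - 2))
    else:
        p = 0.0
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        zc = sps.norm.ppf(1 - alpha / 2)
        lo, hi = np.tanh(z - zc / sqrt(n - 3)), np.tanh(z + zc / sqrt(n - 3))
    else:
        lo, hi = (r, r) if abs(r) == 1.0 else (-1.0, 1.0)
    return r, (float(lo), float(hi)), p


def simple_regression(x, y):
    """OLS y = a x + b; returns (slope, intercept, R^2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0:
        raise ValueError("constant predictor")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
    return float(slope), float(intercept), float(r2)


def bland_altman(x, y):
    """Mean difference (x - y) and 1.96 SD limits of agreement.

    Returns ``(mean_diff, (loa_low, loa_high))``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need paired samples with n >= 2")
    d = x - y
    m = float(d.mean())
    s = float(d.std(ddof=1))
    return m, (m - 1.96 * s, m + 1.96 * s)


# --------------------------------------------------------------------------
# Mann-Whitney U

def mann_whitney_u(x, y, exact_max: int = 8):
    """Two-sided Mann-Whitney U-test.

    ``U`` counts pairs where x exceeds y (ties count one half).  With
    ``min(n, m) <= exact_max`` and no ties the p-value is exact by full
    enumeration of the C(n+m, n) rank assignments; otherwise the
    tie-corrected normal approximation is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be nonempty")
    u = float(sum((xi > y).sum() + 0.5 * (xi == y).sum() for xi in x))
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < n + m
    if min(n, m) <= exact_max and not has_ties:
        ranks = sps.rankdata(pooled)
        total = comb(n + m, n)
        count_le = count_ge = 0
        for picks in combinations(range(n + m), n):
            u_s = sum(ranks[list(picks)]) - n * (n + 1) / 2
            count_le += u_s <= u
            count_ge += u_s >= u
        p = min(1.0, 2 * min(count_le, count_ge) / total)
    else:
        ranks = sps.rankdata(pooled)
        _, cnt = np.unique(pooled, return_counts=True)
        tie_term = (cnt**3 - cnt).sum() / ((n + m) * (n + m - 1))
        mu = n * m / 2
        sd = sqrt(n * m / 12 * ((n + m + 1) - tie_term))
        if sd == 0:
            return u, 1.0
        z = (u - mu - 0.5 * np.sign(u - mu)) / sd  # continuity corrected
        p = float(min(1.0, 2 * sps.norm.sf(abs(z))))
    return u, float(p)


# --------------------------------------------------------------------------
# Shapiro-Wilk (Royston 1995 approximation)

def _sw_weights(n: int) -> np.ndarray:
    m = sps.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    mm = m @ m
    c = m / sqrt(mm)
    if n == 3:
        a = np.array([-sqrt(0.5), 0.0, sqrt(0.5)])
        return a
    u = 1.0 / sqrt(n)
    an = (-2.706056 * u**5 + 4.434685 * u**4 - 2.071190 * u**3
          - 0.147981 * u**2 + 0.221157 * u + c[-1])
    an1 = (-3.582633 * u**5 + 5.682633 * u**4 - 1.752461 * u**3
           - 0.293762 * u**2 + 0.042981 * u + c[-2])
    a = np.empty(n)
    if n <= 5:
        phi = (mm - 2 * m[-1] ** 2) / (1 - 2 * an**2)
        a[1:-1] = m[1:-1] / sqrt(phi)
        a[0], a[-1] = -an, an
    else:
        phi = (mm - 2 * m[-1] ** 2 - 2 * m[-2] ** 2) / (1 - 2 * an**2 - 2 * an1**2)
        a[2:-2] = m[2:-2] / sqrt(phi)
        a[0], a[-1] = -an, an
        a[1], a[-2] = -an1, an1
    return a


def shapiro_wilk(x):
    """Shapiro-Wilk W statistic and upper-tail p-value, 3 <= n <= 5000."""
    x = np.sort(np.asarray(x, float))
    n = x.size
    if not 3 <= n <= 5000:
        raise ValueError("Shapiro-Wilk supports 3 <= n <= 5000")
    if x[0] == x[-1]:
        raise ValueError("zero variance: normality test undefined")
    a = _sw_weights(n)
    w = float((a @ x) ** 2 / ((x - x.mean()) @ (x - x.mean())))
    w = min(w, 1.0)
    if n == 3:
        p = 6.0 / np.pi * (asin(sqrt(w)) - asin(sqrt(0.75)))
        return w, float(np.clip(p, 0.0, 1.0))
    if n <= 11:
        g = -2.273 + 0.459 * n
        mu = 0.5440 - 0.39978 * n + 0.025054 * n**2 - 0.0006714 * n**3
        sig = np.exp(1.3822 - 0.77857 * n + 0.062767 * n**2 - 0.0020322 * n**3)
        if g - np.log(1 - w) <= 0:
            return w, 0.0
        z = (-np.log(g - np.log(1 - w)) - mu) / sig
    else:
        ln = np.log(n)
        mu = 0.0038915 * ln**3 - 0.083751 * ln**2 - 0.31082 * ln - 1.5861
        sig = np.exp(0.0030302 * ln**2 - 0.082676 * ln - 0.4803)
        z = (np.log(1 - w) - mu) / sig
    return w, float(sps.norm.sf(z))


# --------------------------------------------------------------------------
# summaries and report

def summarize_column(values, alpha: float = 0.05) -> dict:
    """Normality-gated summary of one column: mean +/- SD when the
    Shapiro-Wilk test does not reject at ``alpha``, else median [Q1 ; Q3]."""
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise ValueError("need at least 3 values to summarize")
    w, p = shapiro_wilk(v)
    if p >= alpha:
        return {"style": "mean_sd", "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)), "shapiro_w": w, "shapiro_p": p,
                "text": f"{v.mean():.3g} ± {v.std(ddof=1):.3g}"}
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"style": "median_iqr", "median": float(med), "q1": float(q1),
            "q3": float(q3), "shapiro_w": w, "shapiro_p": p,
            "text": f"{med:.3g} [{q1:.3g} ; {q3:.3g}]"}


def summarize(table: pd.DataFrame, group_col: str | None = "sex",
              alpha: float = 0.05) -> dict:
    """Per-column summaries for each group and the whole cohort."""
    num = table.select_dtypes("number")
    groups = {"Total": table}
    if group_col and group_col in table:
        for g, sub in table.groupby(group_col):
            groups[str(g)] = sub
    out: dict = {}
    for col in num.columns:
        out[col] = {}
        for gname, sub in groups.items():
            vals = sub[col].dropna()
            try:
                out[col][gname] = summarize_column(vals, alpha)
            except ValueError as err:
                out[col][gname] = {"style": "skipped", "reason": str(err)}
    return out


def _fmt_p(p: float) -> str:
    return "p < 0.001" if p < 0.001 else f"p = {p:.3g}"


#: default pairwise comparison plan: (table name, row columns, col columns)
DEFAULT_COMPARISON_PLAN = [
    ("bmd_bmc_vs_reference",
     ["BMD_DXA", "BMC_DXA"],
     ["BMD_CBCT_whole", "BMD_CBCT_cort", "BMC_CBCT_whole", "BMC_CBCT_cort"]),
    ("fe_vs_mineral",
     ["BMD_CBCT_whole", "BMC_CBCT_whole", "BMD_DXA", "BMC_DXA"],
     ["Stiffness", "Strength", "Fmax"]),
    ("fe_vs_microstructure",
     ["BVTV_trab", "Tb_Th", "Tb_Sc", "Tb_Nd", "C_Th", "TBV"],
     ["BMD_CBCT_whole", "BMC_CBCT_whole", "Stiffness", "Strength", "Fmax"]),
]


@dataclass
class StatsReport:
    pearson: dict = field(default_factory=dict)
    regression: dict = field(default_factory=dict)
    bland_altman: dict = field(default_factory=dict)
    mann_whitney: dict = field(default_factory=dict)
    summaries: dict = field(default_factory=dict)
    missing_columns: list = field(default_factory=list)

    def cell(self, table: str, row: str, col: str):
        return self.pearson.get(table, {}).get((row, col))

    def n_cells(self) -> int:
        return sum(len(v) for v in self.pearson.values())

    def to_json(self, path: str | Path) -> None:
        def enc(d):
            return {f"{k[0]}|{k[1]}" if isinstance(k, tuple) else k:
                    (enc(v) if isinstance(v, dict) else v)
                    for k, v in d.items()}
        payload = {"pearson": enc(self.pearson),
                   "regression": enc(self.regression),
                   "bland_altman": enc(self.bland_altman),
                   "mann_whitney": enc(self.mann_whitney),
                   "summaries": self.summaries,
                   "missing_columns": self.missing_columns}
        Path(path).write_text(json.dumps(payload, indent=2, default=str))

    def to_markdown(self) -> str:
        lines = []
        for tname, cells in self.pearson.items():
            rows = sorted({k[0] for k in cells})
            cols = sorted({k[1] for k in cells})
            lines.append(f"### {tname}\n")
            lines.append("| | " + " | ".join(cols) + " |")
            lines.append("|" + "---|" * (len(cols) + 1))
            for rlab in rows:
                entries = []
                for clab in cols:
                    c = cells.get((rlab, clab))
                    entries.append(c["text"] if c and "text" in c else "NA")
                lines.append(f"| {rlab} | " + " | ".join(entries) + " |")
            lines.append("")
        return "\n".join(lines)


def build_report(table: pd.DataFrame, comparison_plan=None,
                 group_col: str | None = "sex") -> StatsReport:
    """Compute every pairwise cell of the comparison plan on a cohort table.

    Each cell holds Pearson r with CI and p (formatted like
    ``r = 0.84 (0.63 : 0.93) p < 0.001``) plus the matching regression and
    Bland-Altman outputs; missing columns are listed and their cells marked
    NA; zero-variance columns surface as NA cells as well.
    """
    plan = comparison_plan or DEFAULT_COMPARISON_PLAN
    rep = StatsReport()
    rep.summaries = summarize(table, group_col=group_col)
    for tname, row_cols, col_cols in plan:
        cells, regs, bas = {}, {}, {}
        for rc in row_cols:
            for cc in col_cols:
                key = (rc, cc)
                if rc not in table or cc not in table:
                    for missing in (c for c in (rc, cc) if c not in table):
                        if missing not in rep.missing_columns:
                            rep.missing_columns.append(missing)
                    cells[key] = {"na": True, "text": "NA"}
                    continue
                x = table[rc].to_numpy(float)
                y = table[cc].to_numpy(float)
                ok = np.isfinite(x) & np.isfinite(y)
                try:
                    r, (lo, hi), p = pearson_with_ci(x[ok], y[ok])
                except ValueError as err:
                    cells[key] = {"na": True, "text": "NA", "reason": str(err)}
                    continue
                cells[key] = {"r": r, "ci_low": lo, "ci_high": hi, "p": p,
                              "text": f"r = {r:.2g} ({lo:.2g} : {hi:.2g}) "
                                      f"{_fmt_p(p)}"}
                slope, inter, r2 = simple_regression(x[ok], y[ok])
                regs[key] = {"slope": slope, "intercept": inter, "r2": r2}
                md, (lo_a, hi_a) = bland_altman(x[ok], y[ok])
                bas[key] = {"mean_diff": md, "loa_low": lo_a, "loa_high": hi_a}
        rep.pearson[tname] = cells
        rep.regression[tname] = regs
        rep.bland_altman[tname] = bas
    if group_col and group_col in table:
        grps = [g for _, g in table.groupby(group_col)]
        if len(grps) == 2:
            for col in table.select_dtypes("number").columns:
                a = grps[0][col].dropna().to_numpy()
                b = grps[1][col].dropna().to_numpy()
                if a.size and b.size:
                    u, p = mann_whitney_u(a, b)
                    rep.mann_whitney[col] = {"U": u, "p": p}
    return rep
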