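"""Normality-gated within-subject statistics for sectioned features.

The decision tree mirrors standard practice for 2 (driving mode) x 6
(time section) repeated-measures designs: Shapiro-Wilk normality checks
per design cell gate between (a) a within-subject ANOVA with
Greenhouse-Geisser correction, partial eta squared, and Holm-corrected
paired t post-hocs, and (b) per-mode Friedman tests with Conover
post-hocs plus paired Wilcoxon tests between modes, Holm-corrected.
All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import json
import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FeatureMatrix",
    "StatReport",
    "holm_adjust",
    "shapiro_gate",
    "gg_epsilon",
    "rm_anova",
    "friedman_test",
    "conover_posthoc",
    "paired_tests",
    "feature_correlations",
    "analyze_feature",
]

ALPHA = 0.05


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """subjects x (mode x section) values of one feature, complete cases.

    ``data`` has shape (n_subjects, n_modes, n_sections); listwise
    deletion is applied on construction and recorded.
    """

    data: np.ndarray
    modes: list[str]
    subjects: list
    feature: str = ""
    n_dropped: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim == 2:       # one-factor design
            self.data = self.data[:, None, :]
            if not self.modes:
                self.modes = ["all"]
        keep = ~np.isnan(self.data).any(axis=(1, 2))
        self.n_dropped = int((~keep).sum())
        self.data = self.data[keep]
        self.subjects = [s for s, k in zip(self.subjects, keep) if k]
        if self.data.shape[0] < 3:
            raise ValueError("need at least 3 complete-case subjects")

    @classmethod
    def from_tidy(cls, table: pd.DataFrame, feature: str = "",
                  value_col: str = "value") -> "FeatureMatrix":
        """Build from a tidy table with subject, condition, section columns."""
        modes = sorted(table["condition"].unique().tolist())
        # canonical study order: PAD first when present
        if set(modes) == {"Manual", "PAD"}:
            modes = ["PAD", "Manual"]
        subjects = sorted(table["subject"].unique().tolist())
        sections = sorted(table["section"].unique().tolist())
        arr = np.full((len(subjects), len(modes), len(sections)), np.nan)
        for _, row in table.iterrows():
            i = subjects.index(row["subject"])
            j = modes.index(row["condition"])
            k = sections.index(row["section"])
            arr[i, j, k] = row[value_col]
        return cls(arr, modes, subjects, feature)

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]


@dataclass
class StatReport:
    """Structured result of one feature's analysis tree."""

    feature: str
    design: dict
    gate: dict                       # per-cell Shapiro-Wilk p + decision
    path: str                        # "parametric" | "nonparametric"
    omnibus: list[dict] = field(default_factory=list)
    posthoc: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    def effect(self, name: str) -> dict:
        for o in self.omnibus:
            if o["effect"] == name:
                return o
        raise KeyError(name)

    def to_json(self, path=None) -> str:
        doc = {
            "feature": self.feature,
            "design": self.design,
            "gate": self.gate,
            "path": self.path,
            "omnibus": self.omnibus,
            "posthoc": (self.posthoc.to_dict("records")
                        if self.posthoc is not None else []),
            "notes": self.notes,
        }
        s = json.dumps(doc, indent=1, default=float)
        if path is not None:
            from pathlib import Path
            Path(path).write_text(s)
        return s

    def summary(self) -> str:
        lines = [f"{self.feature}: {self.path} path "
                 f"(gate min p = {self.gate['min_p']:.3g})"]
        for o in self.omnibus:
            stat_desc = f"{o['stat_name']}({o['df_str']}) = {o['stat']:.2f}"
            line = f"  {o['effect']}: {stat_desc}, p = {o['p']:.4g}"
            if o.get("partial_eta_sq") is not None:
                line += f", pes = {o['partial_eta_sq']:.3f}"
            lines.append(line)
        if self.posthoc is not None and len(self.posthoc):
            sig = self.posthoc[self.posthoc["p_holm"] < ALPHA]
            lines.append(f"  post-hoc: {len(sig)}/{len(self.posthoc)} "
                         "pairs significant after Holm")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def holm_adjust(pvals) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment.

    Sort raw p ascending; adjusted_i = max_{j<=i} min(1, (m-j+1) * p_j),
    mapped back to the input order.
    """
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adj[idx] = running
    return adj


def shapiro_gate(matrix: FeatureMatrix, alpha: float = ALPHA) -> dict:
    """Shapiro-Wilk per design cell; any failing cell flips the whole
    feature to the nonparametric path.  A constant cell is undefined for
    the test and counts as non-normal."""
    cells = {}
    for j, mode in enumerate(matrix.modes):
        for k in range(matrix.data.shape[2]):
            x = matrix.data[:, j, k]
            if np.ptp(x) == 0:
                p = 0.0
            else:
                p = float(sps.shapiro(x).pvalue)
            cells[f"{mode}/T{k + 1}"] = p
    min_p = min(cells.values())
    return {
        "cells": cells,
        "min_p": min_p,
        "alpha": alpha,
        "path": "nonparametric" if min_p < alpha else "parametric",
    }


def _effect_epsilon(scores: np.ndarray, transformed: bool = False) -> float:
    """Greenhouse-Geisser epsilon from per-subject scores.

    For raw level means (``transformed=False``, subjects x k) epsilon is
    (tr S~)^2 / ((k-1) tr S~^2) with S~ the double-centered covariance.
    For scores already projected onto d orthonormal effect contrasts
    (``transformed=True``) it is (tr S)^2 / (d tr S^2) directly.  Both are
    bounded to [1/d, 1].
    """
    if transformed:
        d = scores.shape[1]
        if d <= 1:
            return 1.0
        S = np.cov(scores, rowvar=False, ddof=1)
        eps = np.trace(S) ** 2 / (d * np.trace(S @ S))
        return float(np.clip(eps, 1.0 / d, 1.0))
    k = scores.shape[1]
    if k <= 2:
        return 1.0
    S = np.cov(scores, rowvar=False, ddof=1)
    H = np.eye(k) - np.ones((k, k)) / k
    St = H @ S @ H
    eps = np.trace(St) ** 2 / ((k - 1) * np.trace(St @ St))
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def gg_epsilon(scores: np.ndarray) -> float:
    """Public wrapper: GG epsilon of a subjects x levels score matrix."""
    return _effect_epsilon(np.asarray(scores, float))


def _helmert(k: int) -> np.ndarray:
    H = np.zeros((k - 1, k))
    for i in range(k - 1):
        H[i, : i + 1] = 1.0
        H[i, i + 1] = -(i + 1)
        H[i] /= np.linalg.norm(H[i])
    return H


def mauchly_sphericity(scores: np.ndarray, transformed: bool = False
                       ) -> tuple[float, float]:
    """Mauchly's W test of sphericity with the chi-square approximation.

    ``scores`` is subjects x k level means (or subjects x d orthonormal
    contrast scores with ``transformed=True``).  Returns (W, p); for
    d <= 1 sphericity holds trivially and (1, 1) is returned.
    """
    x = np.asarray(scores, float)
    n = x.shape[0]
    if not transformed:
        x = x @ _helmert(x.shape[1]).T
    d = x.shape[1]
    if d <= 1 or n - 1 <= d:
        return 1.0, 1.0
    S = np.cov(x, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(S)
    if np.any(eig <= 0):
        return 0.0, 0.0
    W = float(np.exp(np.sum(np.log(eig)) - d * np.log(eig.mean())))
    f = 1.0 - (2 * d ** 2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f * np.log(max(W, 1e-300))
    df = d * (d + 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, df))
    return W, p


def _interaction_scores(data: np.ndarray) -> np.ndarray:
    """Project subject cell matrices onto orthonormal interaction contrasts."""
    n, a, b = data.shape
    M = np.kron(_helmert(a), _helmert(b))      # (a-1)(b-1) x ab
    return data.reshape(n, a * b) @ M.T


def rm_anova(matrix: FeatureMatrix) -> list[dict]:
    """Two-way (or one-way) within-subject ANOVA with GG correction.

    Returns one dict per effect with F, uncorrected and GG-corrected df,
    p (GG-corrected whenever epsilon < 1 and k > 2) and partial eta
    squared.  For a 2-level factor epsilon is exactly 1.
    """
    y = matrix.data
    if np.isnan(y).any():
        raise ValueError("missing cells: apply listwise deletion first")
    n, a, b = y.shape
    gm = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)

    effects = []

    def add(name, ss_eff, df_eff, ss_err, df_err, scores,
            transformed=False):
        eps = _effect_epsilon(scores, transformed=transformed)
        _, p_sphericity = mauchly_sphericity(scores, transformed=transformed)
        F = (ss_eff / df_eff) / (ss_err / df_err)
        df1, df2 = df_eff * eps, df_err * eps
        p_gg = float(sps.f.sf(F, df1, df2))
        p_unc = float(sps.f.sf(F, df_eff, df_err))
        # GG correction applied when applicable: Mauchly rejects sphericity
        corrected = p_sphericity < ALPHA and df_eff > 1
        effects.append({
            "effect": name,
            "stat_name": "F",
            "stat": float(F),
            "df": (df_eff, df_err),
            "df_gg": (float(df1), float(df2)),
            "df_str": (f"{df1:.2f}, {df2:.2f}" if corrected
                       else f"{df_eff}, {df_err}"),
            "epsilon": eps,
            "sphericity_p": p_sphericity,
            "gg_applied": bool(corrected),
            "p": p_gg if corrected else p_unc,
            "p_gg": p_gg,
            "p_uncorrected": p_unc,
            "partial_eta_sq": float(ss_eff / (ss_eff + ss_err)),
        })

    if a > 1:
        ss_a = n * b * np.sum((m_a - gm) ** 2)
        ss_ea = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2)
        add("mode", ss_a, a - 1, ss_ea, (a - 1) * (n - 1), m_sa)
    ss_b = n * a * np.sum((m_b - gm) ** 2)
    ss_eb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2)
    add("time", ss_b, b - 1, ss_eb, (b - 1) * (n - 1), m_sb)
    if a > 1:
        resid = (y - m_sa[:, :, None] - m_sb[:, None, :] -
                 m_ab[None, :, :] + m_a[None, :, None] + m_b[None, None, :]
                 + m_s[:, None, None] - gm)
        ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
        ss_eab = np.sum(resid ** 2)
        add("mode x time", ss_ab, (a - 1) * (b - 1), ss_eab,
            (a - 1) * (b - 1) * (n - 1), _interaction_scores(y),
            transformed=True)
    return effects


def friedman_test(block_data: np.ndarray) -> dict:
    """Friedman chi-square over one within factor (subjects x k levels)."""
    n, k = block_data.shape
    if k < 3:
        raise ValueError("Friedman needs k >= 3 levels; use Wilcoxon for 2")
    if np.all(np.ptp(block_data, axis=1) == 0):
        # every block fully tied: no evidence against the null
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.friedmanchisquare(*[block_data[:, j] for j in range(k)])
    return {"effect": "time", "stat_name": "chi2", "stat": float(stat),
            "df": k - 1, "df_str": str(k - 1), "p": float(p)}


def conover_posthoc(block_data: np.ndarray,
                    level_names: list[str] | None = None) -> pd.DataFrame:
    """Conover's pairwise rank comparisons after a Friedman test.

    Within-subject ranks give column rank sums R_j; each pair's statistic
    is t = (R_i - R_j) / sqrt(2 n (A - C)(1 - T1 / (n (k-1))) / ((n-1)(k-1)))
    with df = (n-1)(k-1), where A is the sum of squared ranks, C the rank
    correction n k (k+1)^2 / 4, and T1 the Friedman statistic.  Raw p
    values are Holm-adjusted.
    """
    x = np.asarray(block_data, float)
    n, k = x.shape
    names = level_names or [f"T{j + 1}" for j in range(k)]
    ranks = np.apply_along_axis(sps.rankdata, 1, x)
    R = ranks.sum(axis=0)
    A = float(np.sum(ranks ** 2))
    C = n * k * (k + 1) ** 2 / 4.0
    if A == C:   # all columns identical: no rank variation at all
        T1 = 0.0
    else:
        T1 = (k - 1) * float(np.sum((R - n * (k + 1) / 2.0) ** 2)) / (A - C)
    df = (n - 1) * (k - 1)
    denom_sq = 2.0 * n * (A - C) * (1.0 - T1 / (n * (k - 1))) / df
    denom = np.sqrt(max(denom_sq, 0.0))
    rows = []
    for i, j in combinations(range(k), 2):
        if denom == 0:
            t, p = 0.0, 1.0
        else:
            t = (R[i] - R[j]) / denom
            p = 2.0 * float(sps.t.sf(abs(t), df))
        rows.append({"pair": f"{names[i]} vs {names[j]}",
                     "stat_name": "t", "stat": float(t), "df": df,
                     "p_raw": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out


def paired_tests(pairs: list[tuple[str, np.ndarray, np.ndarray]],
                 method: str = "t") -> pd.DataFrame:
    """Holm-corrected paired comparisons (paired t or Wilcoxon)."""
    rows = []
    for name, x, y in pairs:
        d = np.asarray(x, float) - np.asarray(y, float)
        n = len(d)
        if method == "t":
            if np.allclose(d.std(ddof=1), 0.0):
                raise ValueError(
                    f"zero-variance differences in pair {name!r}")
            t, p = sps.ttest_rel(x, y)
            rows.append({"pair": name, "stat_name": "t", "stat": float(t),
                         "df": n - 1, "p_raw": float(p),
                         "mean_diff": float(d.mean())})
        elif method == "wilcoxon":
            if np.all(d == 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.wilcoxon(x, y)
            rows.append({"pair": name, "stat_name": "W", "stat": float(stat),
                         "df": n - 1, "p_raw": float(p),
                         "mean_diff": float(d.mean())})
        else:
            raise ValueError("method must be 't' or 'wilcoxon'")
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out


def feature_correlations(eeg_table: pd.DataFrame,
                         behavior_table: pd.DataFrame,
                         value_a: str = "value",
                         value_b: str = "value") -> pd.DataFrame:
    """Pearson correlations between two sectioned features across subjects.

    One row per section (matched subjects only) plus one for the
    T1-T6 subject averages; p two-sided from t with df = n - 2, reported
    as r(df).
    """
    a = eeg_table.pivot_table(index="subject", columns="section",
                              values=value_a)
    b = behavior_table.pivot_table(index="subject", columns="section",
                                   values=value_b)
    subjects = a.index.intersection(b.index)
    a, b = a.loc[subjects], b.loc[subjects]
    rows = []

    def corr(x, y, label):
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        if n < 3:
            rows.append({"pair": label, "r": np.nan, "df": max(n - 2, 0),
                         "p": np.nan, "n": n})
            return
        r, p = sps.pearsonr(x[ok], y[ok])
        rows.append({"pair": label, "r": float(r), "df": n - 2,
                     "p": float(p), "n": n})

    for s in a.columns.intersection(b.columns):
        corr(a[s].to_numpy(), b[s].to_numpy(), f"T{s}")
    corr(a.mean(axis=1).to_numpy(), b.mean(axis=1).to_numpy(), "avgT1T6")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the decision tree
# ---------------------------------------------------------------------------

def _parametric_branch(matrix: FeatureMatrix, report: StatReport) -> None:
    report.omnibus = rm_anova(matrix)
    post_frames = []
    sig = {o["effect"] for o in report.omnibus if o["p"] < ALPHA}
    y = matrix.data
    if "mode" in sig and len(matrix.modes) == 2:
        ph = paired_tests([(f"{matrix.modes[0]} vs {matrix.modes[1]}",
                            y[:, 0, :].mean(axis=1),
                            y[:, 1, :].mean(axis=1))], method="t")
        ph.insert(0, "family", "mode")
        post_frames.append(ph)
    if "time" in sig:
        k = y.shape[2]
        coll = y.mean(axis=1)
        pairs = [(f"T{i + 1} vs T{j + 1}", coll[:, i], coll[:, j])
                 for i, j in combinations(range(k), 2)]
        ph = paired_tests(pairs, method="t")
        ph.insert(0, "family", "time")
        post_frames.append(ph)
    if "mode x time" in sig and len(matrix.modes) == 2:
        k = y.shape[2]
        pairs = [(f"{matrix.modes[0]} vs {matrix.modes[1]} at T{j + 1}",
                  y[:, 0, j], y[:, 1, j]) for j in range(k)]
        ph = paired_tests(pairs, method="t")
        ph.insert(0, "family", "mode x time")
        post_frames.append(ph)
    if post_frames:
        report.posthoc = pd.concat(post_frames, ignore_index=True)


def _nonparametric_branch(matrix: FeatureMatrix, report: StatReport) -> None:
    y = matrix.data
    k = y.shape[2]
    post_frames = []
    # time: one Friedman per mode; the family decision Holm-combines them
    fried = []
    for j, mode in enumerate(matrix.modes):
        f = friedman_test(y[:, j, :])
        f["effect"] = f"time ({mode})"
        fried.append(f)
    p_fam = holm_adjust([f["p"] for f in fried])
    for f, pf in zip(fried, p_fam):
        f["p_family"] = float(pf)
        report.omnibus.append(f)
    report.omnibus.append({
        "effect": "time", "stat_name": "chi2(family)",
        "stat": max(f["stat"] for f in fried),
        "df": k - 1, "df_str": str(k - 1),
        "p": float(min(p_fam)),
    })
    for j, mode in enumerate(matrix.modes):
        if fried[j]["p"] < ALPHA:
            ph = conover_posthoc(y[:, j, :])
            ph.insert(0, "family", f"time ({mode})")
            post_frames.append(ph)
    # mode: paired Wilcoxon at each section, Holm over the six sections
    if len(matrix.modes) == 2:
        pairs = [(f"{matrix.modes[0]} vs {matrix.modes[1]} at T{j + 1}",
                  y[:, 0, j], y[:, 1, j]) for j in range(k)]
        wil = paired_tests(pairs, method="wilcoxon")
        wil.insert(0, "family", "mode")
        post_frames.append(wil)
        report.omnibus.append({
            "effect": "mode", "stat_name": "wilcoxon(family)",
            "stat": float(wil["stat"].iloc[int(np.argmin(wil["p_raw"]))]),
            "df": y.shape[0] - 1, "df_str": str(y.shape[0] - 1),
            "p": float(wil["p_holm"].min()),
        })
    if post_frames:
        report.posthoc = pd.concat(post_frames, ignore_index=True)


def analyze_feature(table: pd.DataFrame, feature: str = "",
                    value_col: str = "value") -> StatReport:
    """Run the full normality-gated analysis on a tidy feature table.

    The table needs subject, condition, section and value columns; the
    Shapiro-Wilk gate picks the parametric (RM-ANOVA + paired t) or
    nonparametric (Friedman/Conover + Wilcoxon) branch for the whole
    feature.
    """
    matrix = FeatureMatrix.from_tidy(table, feature, value_col)
    gate = shapiro_gate(matrix)
    report = StatReport(
        feature=feature or matrix.feature,
        design={"modes": matrix.modes, "n_sections": matrix.data.shape[2],
                "n_subjects": matrix.n_subjects,
                "n_dropped": matrix.n_dropped},
        gate=gate,
        path=gate["path"],
    )
    if gate["path"] == "parametric":
        _parametric_branch(matrix, report)
    else:
        _nonparametric_branch(matrix, report)
    return report
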