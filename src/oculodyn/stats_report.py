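"""Session-level statistics: normality gate, paired Wilcoxon tests, and the
summary tables of the cohort analysis.

The analysis design pairs the 29 fixation-level estimates within each
session and runs one two-sided Wilcoxon signed-rank test per session for a
given comparison (BNR vs ANR at fixed series length or window; length vs
length; window vs window).  Significance is reported as the percentage of
sessions with p below alpha, alongside a histogram of p-values in bins of
width 0.05.  No multiple-testing correction is applied by default,
mirroring raw p < 0.05 reporting; a Benjamini-Hochberg option exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .exceptions import DegenerateInputError, InvalidParameterError, TooShortError
from .invariants import sample_size_bound

__all__ = [
    "Comparison",
    "ComparisonResult",
    "WilcoxonResult",
    "shapiro_wilk",
    "wilcoxon_signed_rank",
    "session_significance",
    "build_summary_tables",
]

#: SessionTable column contract: one row per (session_id, fixation_id,
#: condition, measure, scope) estimate.
SESSION_TABLE_COLUMNS = (
    "session_id",
    "fixation_id",
    "condition",  # "BNR" | "ANR"
    "measure",  # "D2" | "K2"
    "scope",  # series length (D2) or window label (K2)
    "value",
)


def shapiro_wilk(values) -> float:
    """Shapiro-Wilk normality p-value (3 <= n <= 5000).

    Used to *report* the normality gate that motivates the non-parametric
    Wilcoxon choice, never to branch the analysis.
    """
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise InvalidParameterError(f"Shapiro-Wilk supports 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant sample: normality undefined")
    return float(scipy.stats.shapiro(x).pvalue)


@dataclass
class WilcoxonResult:
    statistic: float  # W+ (sum of positive-difference ranks)
    p_value: float
    n_used: int  # pairs remaining after zero-difference removal
    method: str  # "exact" | "approx" | "degenerate"
    degenerate: bool = False


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by dynamic programming over all sign assignments.

    Average ranks can be half-integers, so everything is doubled to stay on
    an integer lattice; the distribution of 2*W+ is built by convolution
    over the 2^n equally likely sign vectors.
    """
    doubled = np.round(2.0 * ranks).astype(np.int64)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2.0 * w_plus))
    p_low = float(dist[: w2 + 1].sum())
    p_high = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(p_low, p_high))


def wilcoxon_signed_rank(a, b, alternative: str = "two-sided") -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped; ties share average ranks.  The null
    distribution is enumerated exactly for n <= 25 (ties included) and
    approximated by the tie-corrected, continuity-corrected normal above.
    All-zero differences yield p = 1 with a degenerate flag.
    """
    if alternative != "two-sided":
        raise InvalidParameterError("only the two-sided alternative is implemented")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidParameterError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, "degenerate", degenerate=True)
    if n < 5:
        raise TooShortError(f"need >= 5 non-zero differences, got {n}")
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        p = _exact_signed_rank_p(ranks, w_plus)
        return WilcoxonResult(w_plus, p, n, "exact")
    res = scipy.stats.wilcoxon(
        d, zero_method="wilcox", correction=True, alternative="two-sided", method="approx"
    )
    return WilcoxonResult(w_plus, float(res.pvalue), n, "approx")


@dataclass(frozen=True)
class Comparison:
    """A paired comparison over a session table.

    ``factor`` names the varied column (``condition`` or ``scope``);
    ``level_a``/``level_b`` its two levels; ``fixed`` pins the remaining
    design columns (e.g. measure="D2", scope=2999).
    """

    factor: str
    level_a: object
    level_b: object
    fixed: tuple = ()

    def label(self) -> str:
        fixed = ", ".join(f"{k}={v}" for k, v in self.fixed)
        return f"{self.level_a} vs {self.level_b}" + (f" [{fixed}]" if fixed else "")


@dataclass
class ComparisonResult:
    label: str
    p_values: dict
    percent_significant: float
    alpha: float
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray
    excluded_sessions: list = field(default_factory=list)
    degenerate_sessions: list = field(default_factory=list)


def session_significance(
    table: pd.DataFrame, comparison: Comparison, alpha: float = 0.05
) -> ComparisonResult:
    """One Wilcoxon test per session, pairing values across its fixations.

    Sessions with fewer than 5 complete pairs are excluded and listed.
    Returns the percentage of sessions significant at ``alpha`` and the
    p-value histogram (bin width 0.05).
    """
    df = table
    for key, val in comparison.fixed:
        df = df[df[key] == val]
    pivot = df.pivot_table(
        index=["session_id", "fixation_id"],
        columns=comparison.factor,
        values="value",
        aggfunc="first",
    )
    missing = [lv for lv in (comparison.level_a, comparison.level_b) if lv not in pivot.columns]
    if missing:
        raise InvalidParameterError(f"levels {missing} absent for comparison {comparison.label()}")
    pivot = pivot[[comparison.level_a, comparison.level_b]].dropna()
    p_values: dict = {}
    excluded: list = []
    degenerate: list = []
    for session, grp in pivot.groupby(level="session_id"):
        if len(grp) < 5:
            excluded.append(session)
            continue
        try:
            res = wilcoxon_signed_rank(
                grp[comparison.level_a].to_numpy(), grp[comparison.level_b].to_numpy()
            )
        except TooShortError:
            excluded.append(session)
            continue
        if res.degenerate:
            degenerate.append(session)
        p_values[session] = res.p_value
    if p_values:
        p_arr = np.array(list(p_values.values()))
        percent = float(100.0 * np.mean(p_arr < alpha))
    else:
        p_arr = np.array([])
        percent = float("nan")
    edges = np.arange(0.0, 1.0001, 0.05)
    counts, _ = np.histogram(p_arr, bins=edges)
    return ComparisonResult(
        label=comparison.label(),
        p_values=p_values,
        percent_significant=percent,
        alpha=alpha,
        histogram_counts=counts,
        histogram_edges=edges,
        excluded_sessions=excluded,
        degenerate_sessions=degenerate,
    )


def benjamini_hochberg(p_values, alpha: float = 0.05) -> np.ndarray:
    """BH-adjusted q-values (optional, off by default in the report)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _mean_sd_cell(values: pd.Series) -> str:
    vals = values.dropna()
    if vals.empty:
        return "NA(0)"
    return f"{vals.mean():.4f}({vals.std(ddof=1) if len(vals) > 1 else 0.0:.4f})"


def _pairwise_scope_table(
    table: pd.DataFrame, measure: str, scopes, alpha: float
) -> pd.DataFrame:
    """Percent-significant rows (BNR/ANR) over all scope pairs."""
    pairs = [(a, b) for i, a in enumerate(scopes) for b in scopes[i + 1 :]]
    data = {}
    for a, b in pairs:
        col = f"{a} vs {b}"
        cells = []
        for condition in ("BNR", "ANR"):
            comp = Comparison(
                "scope", a, b, fixed=(("measure", measure), ("condition", condition))
            )
            try:
                res = session_significance(table, comp, alpha)
                cells.append(f"{res.percent_significant:.0f}%")
            except InvalidParameterError:
                cells.append("NA")
        data[col] = cells
    return pd.DataFrame(data, index=["BNR", "ANR"])


def build_summary_tables(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Build the four cohort summary tables from a session table.

    Returns a dict of DataFrames:

    * ``d2_means`` - mean(stdev) of D2 per condition x series length, with a
      last row giving the percent of sessions where BNR vs ANR differs
      significantly at that length;
    * ``d2_length_significance`` - percent significant per condition for
      each pair of lengths;
    * ``k2_means`` / ``k2_window_significance`` - the same pair for the
      entropy per fixation window;
    * ``flags`` - data-quality flags (e.g. D2 at length 1000 exceeding the
      2 log10 N bound).
    """
    out: dict = {}
    flags: list[str] = []
    for measure, means_key, sig_key in (
        ("D2", "d2_means", "d2_length_significance"),
        ("K2", "k2_means", "k2_window_significance"),
    ):
        sub = table[table["measure"] == measure]
        if sub.empty:
            out[means_key] = pd.DataFrame()
            out[sig_key] = pd.DataFrame()
            continue
        if measure == "D2":
            scopes = sorted(sub["scope"].unique(), key=lambda s: int(s))
        else:  # windows like "<700...1500>": order by start sample
            scopes = sorted(
                sub["scope"].unique(),
                key=lambda s: int(str(s).strip("<>").split("...")[0]),
            )
        means = pd.DataFrame(index=["BNR mean (stdev)", "ANR mean (stdev)"], columns=scopes)
        sig_row = {}
        for scope in scopes:
            cell = sub[sub["scope"] == scope]
            means.loc["BNR mean (stdev)", scope] = _mean_sd_cell(
                cell[cell["condition"] == "BNR"]["value"]
            )
            means.loc["ANR mean (stdev)", scope] = _mean_sd_cell(
                cell[cell["condition"] == "ANR"]["value"]
            )
            comp = Comparison(
                "condition", "BNR", "ANR", fixed=(("measure", measure), ("scope", scope))
            )
            try:
                res = session_significance(table, comp, alpha)
                sig_row[scope] = f"{res.percent_significant:.0f}%"
            except InvalidParameterError:
                sig_row[scope] = "NA"
        means.loc[f"BNR vs ANR (p < {alpha})"] = pd.Series(sig_row)
        out[means_key] = means
        out[sig_key] = _pairwise_scope_table(table, measure, scopes, alpha)
        n_missing = int(sub["value"].isna().sum())
        if n_missing:
            flags.append(f"{measure}: {n_missing} missing estimates")
    d2_1000 = table[(table["measure"] == "D2") & (table["scope"].astype(str) == "1000")]
    if not d2_1000.empty:
        bound = sample_size_bound(1000)
        n_over = int((d2_1000["value"] > bound).sum())
        if n_over:
            flags.append(
                f"D2 at length 1000: {n_over} estimates exceed the 2 log10 N bound {bound:g}"
            )
    out["flags"] = pd.DataFrame({"flag": flags})
    return out
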