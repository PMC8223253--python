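"""Aligned-rank-transform factorial statistics and companion utilities.

The factorial analysis is nonparametric: for each effect in the model the
responses are *aligned* (every estimated marginal effect except the one of
interest is subtracted, via the cell-means decomposition), assigned
mid-ranks, and then a mixed factorial ANOVA is run on that effect's ranks
with subject as the blocking unit — the classic split-plot error terms:
subjects-within-groups for between effects, effect-by-subject interaction
for within effects. Per-effect p values are Holm-corrected, as are post hoc
pairwise cell contrasts.

Also here: Holm's step-down adjustment, median/IQR description, and the
normality-gated paired comparison (Shapiro-Wilk, then paired t or Wilcoxon).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "ARTResult",
    "align",
    "align_and_rank",
    "art_anova",
    "art_diagnostic",
    "describe",
    "holm",
    "paired_compare",
    "posthoc_pairwise",
]


# ---------------------------------------------------------------------------
# p-value adjustment and simple descriptives


def holm(pvals) -> np.ndarray:
    """Holm step-down adjusted p values, returned in input order.

    adjusted_(i) = max_{j<=i} min(1, (m - j + 1) * p_(j)) over the ascending
    order statistics.
    """
    p = np.asarray(pvals, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adjusted[idx] = running
    return adjusted


def describe(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear-interpolation quartiles."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("no values to describe")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


@dataclass(frozen=True)
class PairedComparison:
    normality_p: float
    test: str  # "paired_t" or "wilcoxon"
    statistic: float
    p: float


def paired_compare(before, after, alpha: float = 0.05) -> PairedComparison:
    """Shapiro-Wilk on the paired differences, then paired t (if normal,
    p > alpha) else Wilcoxon signed-rank."""
    b = np.asarray(before, dtype=np.float64)
    a = np.asarray(after, dtype=np.float64)
    if b.shape != a.shape:
        raise ValueError(f"length mismatch: {b.shape} vs {a.shape}")
    if b.size < 3:
        raise ValueError("need at least 3 paired observations")
    diff = a - b
    if np.allclose(diff, diff[0]):
        # constant differences: Shapiro is undefined; the t test is degenerate
        if diff[0] == 0:
            return PairedComparison(1.0, "paired_t", 0.0, 1.0)
        return PairedComparison(1.0, "paired_t", np.inf * np.sign(diff[0]), 0.0)
    norm_p = float(sstats.shapiro(diff).pvalue)
    if norm_p > alpha:
        res = sstats.ttest_rel(after, before)
        return PairedComparison(norm_p, "paired_t", float(res.statistic), float(res.pvalue))
    res = sstats.wilcoxon(after, before)
    return PairedComparison(norm_p, "wilcoxon", float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# Aligned rank transform


def _check_cells(table: pd.DataFrame, factors: tuple[str, ...]) -> None:
    levels = [table[f].unique() for f in factors]
    counts = table.groupby(list(factors), observed=True).size()
    for cell in itertools.product(*levels):
        key = cell if len(cell) > 1 else cell[0]
        if key not in counts.index:
            raise ValueError(f"empty design cell {dict(zip(factors, cell))}")


def align(
    table: pd.DataFrame,
    effect: tuple[str, ...],
    factors: tuple[str, ...],
    response: str = "avg_energy",
) -> np.ndarray:
    """Aligned responses for one effect.

    y_aligned = y - full-factorial cell mean + inclusion-exclusion estimate
    of the effect of interest, so every marginal effect other than ``effect``
    is stripped before ranking.
    """
    effect = tuple(effect)
    factors = tuple(factors)
    if not set(effect) <= set(factors):
        raise ValueError(f"effect {effect} not within model factors {factors}")
    _check_cells(table, factors)
    y = table[response].to_numpy(dtype=np.float64)
    if not np.isfinite(y).all():
        raise ValueError("responses must be finite")
    grand = y.mean()
    cell_mean = table.groupby(list(factors), observed=True)[response].transform("mean").to_numpy()

    estimate = np.zeros(len(y))
    for r in range(len(effect) + 1):
        for subset in itertools.combinations(effect, r):
            sign = (-1) ** (len(effect) - len(subset))
            if subset:
                marg = (
                    table.groupby(list(subset), observed=True)[response]
                    .transform("mean")
                    .to_numpy()
                )
            else:
                marg = np.full(len(y), grand)
            estimate += sign * marg
    return y - cell_mean + estimate


def align_and_rank(
    table: pd.DataFrame,
    effect: tuple[str, ...],
    factors: tuple[str, ...],
    response: str = "avg_energy",
) -> tuple[np.ndarray, np.ndarray]:
    """(aligned, mid-ranked aligned) responses for one effect."""
    aligned = align(table, effect, factors, response)
    return aligned, sstats.rankdata(aligned, method="average")


def _mean_by(frame: pd.DataFrame, cols: tuple[str, ...], col: str = "_y") -> np.ndarray:
    if not cols:
        return np.full(len(frame), frame[col].mean())
    return frame.groupby(list(cols), observed=True)[col].transform("mean").to_numpy()


def _split_plot_f(
    table: pd.DataFrame,
    response_col: np.ndarray,
    effect: tuple[str, ...],
    between: tuple[str, ...],
    within: tuple[str, ...],
    subject: str,
) -> tuple[float, int, int]:
    """F, df1, df2 for one effect of a split-plot design on the given column.

    Supports at most one between-subject factor. A pure between effect is
    tested against subjects-within-groups on the subject means. An effect
    with within part W (other within factors collapsed out first) gets the
    classic univariate error term W x subject(group):

      F = [SS_effect / prod(levels-1)] / [SS_{W x S(group)} / ((m-a) prod(levels_W - 1))]

    with both sums of squares built by inclusion-exclusion over marginal
    means (unweighted means, i.e. type-III-style, when mildly unbalanced).
    """
    if len(between) > 1:
        raise NotImplementedError("at most one between-subject factor is supported")
    df = table[[subject, *between, *within]].copy()
    df["_y"] = np.asarray(response_col, dtype=np.float64)
    eff_within = tuple(f for f in effect if f in within)

    subj_group = df.groupby([subject], observed=True)
    m = subj_group.ngroups
    if between:
        group_of = subj_group[between[0]].first()
        n_groups = group_of.nunique()
        if group_of.value_counts().nunique() > 1:
            warnings.warn("unbalanced between-subject groups; using unweighted (type-III) means")
    else:
        group_of = None
        n_groups = 1

    if not eff_within:
        # between main effect: one-way ANOVA on subject means
        subj_means = subj_group["_y"].mean()
        groups = [subj_means[group_of == g].to_numpy() for g in group_of.unique()]
        grand = subj_means.mean()
        ss_a = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_e = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df1, df2 = n_groups - 1, m - n_groups
        if df1 < 1 or df2 < 1 or ss_e <= 0:
            raise ValueError("degenerate between-subject design")
        return float((ss_a / df1) / (ss_e / df2)), df1, df2

    # collapse over within factors not in the effect
    keys = [subject, *between, *eff_within]
    cell = df.groupby(keys, observed=True)["_y"].mean().reset_index()

    # effect SS: inclusion-exclusion estimate over subsets of the effect
    est = np.zeros(len(cell))
    for r in range(len(effect) + 1):
        for sub in itertools.combinations(effect, r):
            est += (-1) ** (len(effect) - len(sub)) * _mean_by(cell, sub)
    ss_eff = float((est**2).sum())
    df1 = 1
    for f in effect:
        df1 *= cell[f].nunique() - 1

    # error SS: W x subject(group) interaction, by inclusion-exclusion
    resid = np.zeros(len(cell))
    for r in range(len(eff_within) + 1):
        for sub in itertools.combinations(eff_within, r):
            sign = (-1) ** (len(eff_within) - len(sub))
            resid += sign * (
                _mean_by(cell, (subject, *sub)) - _mean_by(cell, (*between, *sub))
            )
    ss_err = float((resid**2).sum())
    df_err = m - n_groups
    for f in eff_within:
        df_err *= cell[f].nunique() - 1

    if df1 < 1 or df_err < 1 or ss_err <= 0:
        raise ValueError("degenerate within-subject design")
    return float((ss_eff / df1) / (ss_err / df_err)), df1, df_err


@dataclass
class ARTResult:
    """Per-effect aligned-rank ANOVA table plus the design it came from."""

    effects: pd.DataFrame  # effect, F, df1, df2, p, p_holm
    table: pd.DataFrame = field(repr=False)
    between: tuple[str, ...] = ()
    within: tuple[str, ...] = ()
    subject: str = "subject"
    response: str = "avg_energy"
    diagnostics: dict = field(default_factory=dict)

    def effect_row(self, effect: tuple[str, ...] | str) -> pd.Series:
        name = effect if isinstance(effect, str) else "*".join(effect)
        match = self.effects[self.effects["effect"] == name]
        if match.empty:
            raise KeyError(f"effect {name!r} not in result")
        return match.iloc[0]


def _all_effects(factors: tuple[str, ...]) -> list[tuple[str, ...]]:
    out = []
    for r in range(1, len(factors) + 1):
        out.extend(itertools.combinations(factors, r))
    return out


def art_anova(
    table: pd.DataFrame,
    between: tuple[str, ...] | list[str] = (),
    within: tuple[str, ...] | list[str] = (),
    subject: str = "subject",
    response: str = "avg_energy",
    run_diagnostic: bool = False,
) -> ARTResult:
    """Aligned-rank-transform factorial ANOVA for a mixed design.

    Every main effect and interaction of ``between`` + ``within`` gets its
    own aligned-rank column and F test; p values are Holm-corrected across
    the effect family. With ``run_diagnostic`` the ART correctness check is
    stored: F of every *other* effect computed on each effect's aligned
    (unranked) column, all of which should be ~0.
    """
    between = tuple(between)
    within = tuple(within)
    factors = between + within
    if not factors:
        raise ValueError("no factors given")
    for col in (subject, response, *factors):
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from table")
    # each subject must sit in exactly one level of every between factor
    for bf in between:
        if (table.groupby(subject, observed=True)[bf].nunique() > 1).any():
            raise ValueError(f"between factor {bf!r} varies within a subject")

    effects = _all_effects(factors)
    rows = []
    aligned_cols = {}
    for eff in effects:
        aligned, ranked = align_and_rank(table, eff, factors, response)
        aligned_cols[eff] = aligned
        f, df1, df2 = _split_plot_f(table, ranked, eff, between, within, subject)
        p = float(sstats.f.sf(f, df1, df2))
        rows.append({"effect": "*".join(eff), "F": f, "df1": df1, "df2": df2, "p": p})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm(out["p"].to_numpy())

    diagnostics = {}
    if run_diagnostic:
        for eff in effects:
            others = [e for e in effects if e != eff]
            fmax = 0.0
            for other in others:
                f, _, _ = _split_plot_f(
                    table, aligned_cols[eff], other, between, within, subject
                )
                fmax = max(fmax, f)
            diagnostics["*".join(eff)] = fmax

    return ARTResult(
        effects=out,
        table=table.reset_index(drop=True),
        between=between,
        within=within,
        subject=subject,
        response=response,
        diagnostics=diagnostics,
    )


def art_diagnostic(result: ARTResult) -> dict:
    """Max other-effect F on each effect's aligned column (should be ~0)."""
    if result.diagnostics:
        return result.diagnostics
    factors = result.between + result.within
    effects = _all_effects(factors)
    diagnostics = {}
    for eff in effects:
        aligned = align(result.table, eff, factors, result.response)
        fmax = 0.0
        for other in effects:
            if other == eff:
                continue
            f, _, _ = _split_plot_f(
                result.table, aligned, other, result.between, result.within, result.subject
            )
            fmax = max(fmax, f)
        diagnostics["*".join(eff)] = fmax
    return diagnostics


def posthoc_pairwise(
    result: ARTResult,
    effect: tuple[str, ...] | list[str],
    cells: list[tuple] | None = None,
) -> pd.DataFrame:
    """Pairwise cell contrasts on ranks aligned for the combined cell factor.

    The factors in ``effect`` are fused into one cell factor; responses are
    aligned for that fused factor (all other marginal effects stripped),
    mid-ranked, and each requested pair of cells compared — paired t on
    per-subject means when every factor in ``effect`` is within-subject,
    Welch two-sample otherwise. Holm correction is applied within the
    returned family. ``estimate`` is mean_rank(a) - mean_rank(b).
    """
    effect = tuple(effect)
    table = result.table.copy()
    factors = result.between + result.within
    if not set(effect) <= set(factors):
        raise ValueError(f"effect {effect} not within model factors {factors}")

    fused = "_cell"
    other = "_other"
    table[fused] = list(zip(*(table[f] for f in effect))) if len(effect) > 1 else table[effect[0]]
    rest = [f for f in factors if f not in effect]
    if rest:
        table[other] = (
            list(zip(*(table[f] for f in rest))) if len(rest) > 1 else table[rest[0]]
        )
        model = (other, fused)
    else:
        model = (fused,)
    _, ranked = align_and_rank(table, (fused,), model, result.response)
    table["_rank"] = ranked

    all_cells = sorted(table[fused].unique())
    if cells is None:
        cells = all_cells
    unknown = [c for c in cells if c not in all_cells]
    if unknown:
        raise ValueError(f"unknown cell(s) {unknown}; available: {all_cells}")

    is_within = set(effect) <= set(result.within)
    rows = []
    for a, b in itertools.combinations(cells, 2):
        sa = table[table[fused] == a].groupby(result.subject, observed=True)["_rank"].mean()
        sb = table[table[fused] == b].groupby(result.subject, observed=True)["_rank"].mean()
        if is_within:
            common = sa.index.intersection(sb.index)
            if len(common) < 3:
                raise ValueError(f"fewer than 3 paired subjects for cells {a} vs {b}")
            res = sstats.ttest_rel(sa[common], sb[common])
            test = "paired_t"
            estimate = float((sa[common] - sb[common]).mean())
        else:
            res = sstats.ttest_ind(sa, sb, equal_var=False)
            test = "welch_t"
            estimate = float(sa.mean() - sb.mean())
        rows.append(
            {
                "cell_a": a,
                "cell_b": b,
                "estimate": estimate,
                "statistic": float(res.statistic),
                "p": float(res.pvalue),
                "test": test,
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm(out["p"].to_numpy())
    return out
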