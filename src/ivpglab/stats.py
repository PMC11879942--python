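"""Statistical stage: two-way ANOVA, Tukey post-hoc compact letters, and
Pearson correlations against heart rate and the coded inflow pattern.

The factorial layout is group (Sham vs. HTN-CM) x inflow pattern
(EA-separation / half-separation / fusion); the design is unbalanced, so
Type-II sums of squares are the default (Type I/III available via
``ss_type``).  The Tukey HSD post-hoc is run on the six group x pattern
cells — matching tables that annotate each of the six cells with a
superscript letter — and summarised with a compact letter display
(insert-and-absorb): cells sharing a letter are not significantly
different at the chosen alpha.

For correlations the ordinal pattern is used through its numeric coding
(1 = EA-separation, 2 = EA-half-separation, 3 = EA-fusion), so an r
against the pattern is a relative, not absolute, measure.  No multiplicity
correction is applied across outcomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import validate_cohort

logger = logging.getLogger(__name__)

DEFAULT_OUTCOMES = (
    "lvm_g",
    "e_m_s",
    "hr_bpm",
    "eprime_avg_cm_s",
    "e_over_eprime",
    "lvedp_mmhg",
    "pre_a_lvdp_mmhg",
    "sap_mmhg",
    "total_ivpg_mmhg_cm",
    "basal_ivpg_mmhg_cm",
    "mid_apical_ivpg_mmhg_cm",
)

DEFAULT_CORR_VARIABLES = (
    "total_ivpg_mmhg_cm",
    "basal_ivpg_mmhg_cm",
    "mid_apical_ivpg_mmhg_cm",
    "e_over_eprime",
    "e_m_s",
    "eprime_avg_cm_s",
)


@dataclass
class StatsReport:
    """Assembled ANOVA / Tukey / correlation results."""

    anova: dict[str, pd.DataFrame]
    tukey_letters: dict[str, dict[str, str]]
    pearson: pd.DataFrame
    cell_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def _prepare(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    if "eprime_avg_cm_s" not in df.columns and "eprime_ivs_cm_s" in df.columns:
        df["eprime_avg_cm_s"] = 0.5 * (
            df["eprime_ivs_cm_s"] + df["eprime_lvfw_cm_s"]
        )
    df["cell"] = df["group"].astype(str) + ":" + df["pattern"].astype(str)
    return df


def pearson_with_coded_pattern(table: pd.DataFrame, variable: str) -> tuple[float, float, int]:
    """Pearson r of a variable against the 1/2/3 pattern code."""
    return pearson(table, variable, "pattern_code")


def pearson(table: pd.DataFrame, variable: str, against: str) -> tuple[float, float, int]:
    """Pearson r, two-sided p (t transform, n − 2 df) and n for two columns."""
    df = _prepare(table)
    sub = pd.DataFrame({"x": df[variable], "y": df[against]}).dropna()
    x = sub["x"].to_numpy(dtype=float)
    y = sub["y"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 complete rows for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError(f"degenerate variable: zero variance in {variable!r} or {against!r}")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), len(x)


def two_way_anova(
    table: pd.DataFrame, outcome: str, ss_type: int = 2
) -> pd.DataFrame:
    """Two-way factorial ANOVA (group x pattern) for one outcome.

    Returns the statsmodels ANOVA table with rows for the group effect,
    the pattern effect, their interaction and the residual; Type-II sums
    of squares by default for the unbalanced layout.
    """
    df = _prepare(table).dropna(subset=[outcome])
    if df["group"].nunique() < 2:
        logger.warning("single-group table: group factor dropped from ANOVA")
        model = smf.ols(f"Q('{outcome}') ~ C(pattern)", data=df).fit()
        return sm.stats.anova_lm(model, typ=ss_type)
    if df["pattern"].nunique() < 2:
        logger.warning("single-pattern table: pattern factor dropped from ANOVA")
        model = smf.ols(f"Q('{outcome}') ~ C(group)", data=df).fit()
        return sm.stats.anova_lm(model, typ=ss_type)
    model = smf.ols(f"Q('{outcome}') ~ C(group) * C(pattern)", data=df).fit()
    return sm.stats.anova_lm(model, typ=ss_type)


def tukey_pairwise(
    table: pd.DataFrame, outcome: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Tukey HSD over the 6 group x pattern cells (Tukey–Kramer for
    unequal cell sizes).  Returns one row per cell pair."""
    df = _prepare(table).dropna(subset=[outcome])
    counts = df.groupby("cell")[outcome].count()
    usable = counts[counts >= 2].index
    dropped = sorted(set(counts.index) - set(usable))
    if dropped:
        logger.warning("cells with < 2 observations dropped from Tukey: %s", dropped)
    df = df[df["cell"].isin(usable)]
    res = pairwise_tukeyhsd(df[outcome].to_numpy(dtype=float),
                            df["cell"].to_numpy(), alpha=alpha)
    out = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    out["p-adj"] = res.pvalues
    out["reject"] = res.reject
    return out


def compact_letter_display(
    cells: list[str], pairs: pd.DataFrame
) -> dict[str, str]:
    """Insert-and-absorb compact letter display from pairwise decisions.

    ``pairs`` needs columns ``group1``, ``group2``, ``reject``.  Cells
    sharing a letter are not significantly different.
    """
    cells = list(cells)
    significant = {
        frozenset((r.group1, r.group2))
        for r in pairs.itertuples()
        if bool(r.reject)
    }
    # start with one letter-set holding everything, then split on each
    # significant pair and absorb redundant sets
    letters: list[set[str]] = [set(cells)]
    for pair in significant:
        a, b = tuple(pair)
        for s in list(letters):
            if a in s and b in s:
                letters.remove(s)
                sa, sb = s - {b}, s - {a}
                for cand in (sa, sb):
                    if not any(cand <= other for other in letters):
                        letters.append(cand)
        letters = [s for s in letters if not any(
            s < other for other in letters)]
    # deterministic letter order: by best (earliest) member cell
    letters.sort(key=lambda s: min(cells.index(c) for c in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {c: "" for c in cells}
    for letter, s in zip(alphabet, letters):
        for c in cells:
            if c in s:
                out[c] += letter
    return out


def tukey_letters(
    table: pd.DataFrame, outcome: str, alpha: float = 0.05
) -> dict[str, str]:
    """Compact letters per group x pattern cell for one outcome."""
    df = _prepare(table).dropna(subset=[outcome])
    pairs = tukey_pairwise(table, outcome, alpha=alpha)
    order = (
        df.groupby("cell")[outcome].mean().sort_values(ascending=False).index
    )
    present = set(pairs["group1"]) | set(pairs["group2"])
    return compact_letter_display([c for c in order if c in present], pairs)


def cell_summary(
    table: pd.DataFrame, outcomes=DEFAULT_OUTCOMES, alpha: float = 0.05
) -> pd.DataFrame:
    """Cell mean ± SD table with Tukey letters, one row per outcome."""
    df = _prepare(table)
    cells = sorted(df["cell"].unique())
    rows = []
    for outcome in outcomes:
        if outcome not in df.columns:
            continue
        letters = tukey_letters(df, outcome, alpha=alpha)
        row: dict[str, str] = {"outcome": outcome}
        for cell in cells:
            vals = df.loc[df["cell"] == cell, outcome].dropna()
            if len(vals) == 0:
                row[cell] = "/"
            else:
                row[cell] = (
                    f"{vals.mean():.2f} ± {vals.std(ddof=1):.2f}"
                    f" {letters.get(cell, '')}".rstrip()
                )
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_table(
    table: pd.DataFrame, variables=DEFAULT_CORR_VARIABLES
) -> pd.DataFrame:
    """Pearson r/p/n of each variable against HR and the pattern code."""
    df = _prepare(table)
    rows = []
    for var in variables:
        if var not in df.columns:
            continue
        for against in ("hr_bpm", "pattern_code"):
            r, p, n = pearson(df, var, against)
            rows.append({"variable": var, "against": against, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)


def run_full_analysis(
    cohort: pd.DataFrame,
    outcomes=DEFAULT_OUTCOMES,
    variables=DEFAULT_CORR_VARIABLES,
    alpha: float = 0.05,
    ss_type: int = 2,
) -> StatsReport:
    """ANOVA + Tukey letters + correlations for a validated cohort table.

    Deterministic given the cohort (row order does not matter).
    """
    validate_cohort(cohort)
    df = _prepare(cohort).sort_values("animal_id").reset_index(drop=True)
    anova = {}
    letters = {}
    for outcome in outcomes:
        if outcome not in df.columns:
            continue
        anova[outcome] = two_way_anova(df, outcome, ss_type=ss_type)
        letters[outcome] = tukey_letters(df, outcome, alpha=alpha)
    return StatsReport(
        anova=anova,
        tukey_letters=letters,
        pearson=correlation_table(df, variables=variables),
        cell_table=cell_summary(df, outcomes=outcomes, alpha=alpha),
    )
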