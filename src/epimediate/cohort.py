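"""Participant-characteristics table and its tests.

Case/control comparisons use Pearson's chi-squared test without continuity
correction for categorical variables and one-way (linear model) ANOVA for
continuous ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import SampleMeta


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 counts: (case-yes, case-no, control-yes, control-no)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 or x != int(x) for x in counts):
            raise ValueError("counts must be non-negative integers")
        margins = (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)
        if any(m == 0 for m in margins):
            raise ValueError("chi-squared test undefined: zero margin")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def pearson_chi2(table: TwoByTwo) -> tuple[float, float]:
    """Pearson chi-squared statistic and p on a 2x2 table, 1 df.

    No Yates continuity correction: statistic = N(ad-bc)^2 /
    ((a+b)(c+d)(a+c)(b+d)).
    """
    stat, p, dof, _ = stats.chi2_contingency(table.as_array(), correction=False)
    assert dof == 1
    return float(stat), float(p)


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Standard one-way ANOVA F statistic and p-value."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def _categorical_rows(meta: SampleMeta, column: str, label: str, yes_level) -> list[dict]:
    tab = meta.table
    case = tab[tab["case"] == 1]
    ctrl = tab[tab["case"] == 0]
    rows = []
    levels = sorted(tab[column].unique(), key=lambda v: v != yes_level)
    # p-value from the yes/no 2x2 (binary characteristics only)
    try:
        t22 = TwoByTwo(
            a=int((case[column] == yes_level).sum()),
            b=int((case[column] != yes_level).sum()),
            c=int((ctrl[column] == yes_level).sum()),
            d=int((ctrl[column] != yes_level).sum()),
        )
        _, p = pearson_chi2(t22)
        p_txt = f"{p:.3f}"
    except ValueError:
        p_txt = "NA"
    rows.append({"characteristic": label, "level": "", "case": "", "control": "", "p_value": p_txt, "test": "chi2"})
    for level in levels[::-1]:
        n_case = int((case[column] == level).sum())
        n_ctrl = int((ctrl[column] == level).sum())
        pct_case = 100.0 * n_case / len(case) if len(case) else 0.0
        pct_ctrl = 100.0 * n_ctrl / len(ctrl) if len(ctrl) else 0.0
        rows.append(
            {
                "characteristic": label,
                "level": str(level),
                "case": f"{n_case} ({pct_case:.1f}%)",
                "control": f"{n_ctrl} ({pct_ctrl:.1f}%)",
                "p_value": "",
                "test": "",
            }
        )
    return rows


def _continuous_rows(meta: SampleMeta, column: str, label: str) -> list[dict]:
    tab = meta.table
    case = tab.loc[tab["case"] == 1, column].to_numpy(dtype=float)
    ctrl = tab.loc[tab["case"] == 0, column].to_numpy(dtype=float)
    try:
        _, p = one_way_anova([case, ctrl])
        p_txt = f"{p:.3f}"
    except ValueError:
        p_txt = "NA"
    rows = [
        {"characteristic": label, "level": "", "case": "", "control": "", "p_value": p_txt, "test": "anova"},
        {
            "characteristic": label,
            "level": "Mean (SD)",
            "case": f"{case.mean():.1f} ({case.std(ddof=1):.1f})" if len(case) > 1 else "NA",
            "control": f"{ctrl.mean():.1f} ({ctrl.std(ddof=1):.1f})" if len(ctrl) > 1 else "NA",
            "p_value": "",
            "test": "",
        },
        {
            "characteristic": label,
            "level": "Range",
            "case": f"{case.min():.1f}-{case.max():.1f}" if len(case) else "NA",
            "control": f"{ctrl.min():.1f}-{ctrl.max():.1f}" if len(ctrl) else "NA",
            "p_value": "",
            "test": "",
        },
    ]
    return rows


def summarize_cohort(meta: SampleMeta) -> pd.DataFrame:
    """Participant-characteristics table: one block per characteristic.

    Percentages are 100 x count / group size; continuous variables are
    compared by ANOVA, binary ones by Pearson chi-squared.
    """
    rows: list[dict] = []
    rows += _continuous_rows(meta, "age_psv", "Age at PSV (years)")
    rows += _continuous_rows(meta, "time_psv_sv", "Time PSV to SV (years)")
    rows += _categorical_rows(meta, "sex", "Sex", yes_level="F")
    rows += _categorical_rows(meta, "dr34", "DR3/4", yes_level=1)
    rows += _categorical_rows(meta, "platform", "Platform", yes_level="EPIC")
    return pd.DataFrame(rows)


def render_cohort_table(table: pd.DataFrame) -> str:
    """Human-readable text rendering of the characteristics table."""
    lines = []
    for char, block in table.groupby("characteristic", sort=False):
        head = block.iloc[0]
        lines.append(f"{char}  (p = {head['p_value']}, {head['test']})")
        for _, row in block.iloc[1:].iterrows():
            lines.append(f"  {row['level']:<12} case {row['case']:<16} control {row['control']}")
    return "\n".join(lines) + "\n"
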