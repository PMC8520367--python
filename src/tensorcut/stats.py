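"""Two-group inference from published summary statistics.

The clinical comparison that motivated this package reports each measured
variable as mean ± SD per arm (n = 36 in both arms) with an unsigned t
statistic per row. With equal group sizes the two-sample t statistic

    t = |m1 - m2| / sqrt(s1^2/n + s2^2/n)

coincides for the pooled-variance and Welch forms, so the usual pooled/Welch
ambiguity is moot here. Count data are compared with the Pearson chi-squared
test (no continuity correction; the source prints no chi-squared values, so
that operation is property-tested only).

The printed comparison tables ship as a tab-separated fixture
(``data/clinical_tables.tsv``: cardiac function; inflammatory factors and
vascular endothelial function; serum NO/NOS/iNOS) and every row's t can be
re-derived and checked against the printed value. Unit oddities in the source
(ET-1 in umol/L, NOS/iNOS on a 0.03 U/L scale) are preserved verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "GroupSummary",
    "ComparisonRow",
    "RowCheck",
    "t_from_summaries",
    "chi_square_2x2",
    "verify_table_fixture",
    "load_clinical_tables",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, SD and size of one study arm at one timepoint."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if not (self.sd > 0):
            raise InvalidInputError(f"SD must be positive, got {self.sd}")
        if self.n < 2:
            raise InvalidInputError(f"group size must be >= 2, got {self.n}")


@dataclass(frozen=True)
class ComparisonRow:
    """One printed table row: a variable at one timepoint, both arms."""

    variable: str
    timepoint: str
    observation: GroupSummary
    control: GroupSummary
    printed_t: float
    printed_p_bound: str = ""
    unit: str = ""
    table: str = ""

    def __post_init__(self):
        if self.observation.n != self.control.n:
            raise InvalidInputError("both arms must have the same n in a table row")
        if self.printed_t < 0:
            raise InvalidInputError("printed t statistics are unsigned")


def t_from_summaries(a: GroupSummary, b: GroupSummary) -> float:
    """Unsigned two-sample t statistic from summary data.

    t = |mean_a - mean_b| / sqrt(sd_a^2/n_a + sd_b^2/n_b); symmetric in its
    arguments and invariant under a common rescaling of means and SDs.
    """
    se = np.sqrt(a.sd**2 / a.n + b.sd**2 / b.n)
    return float(abs(a.mean - b.mean) / se)


def chi_square_2x2(counts) -> float:
    """Pearson chi-squared statistic for a 2x2 count table, no Yates correction.

    Equals n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) in closed form; computed here
    from observed-vs-expected cells.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (2, 2):
        raise InvalidInputError(f"expected a 2x2 table, got shape {obs.shape}")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise InvalidInputError("counts must be nonnegative integers")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise InvalidInputError("chi-squared undefined with a zero marginal")
    expected = np.outer(rows, cols) / obs.sum()
    return float(((obs - expected) ** 2 / expected).sum())


@dataclass(frozen=True)
class RowCheck:
    """Result of re-deriving one table row's t statistic."""

    row: ComparisonRow
    computed_t: float
    passed: bool


def verify_table_fixture(rows, tol: float = 1e-3):
    """Recompute t for every row and compare with the printed value.

    Returns a list of :class:`RowCheck`; mismatches are reported, not raised.
    """
    report = []
    for row in rows:
        t = t_from_summaries(row.observation, row.control)
        report.append(RowCheck(row, t, abs(t - row.printed_t) <= tol))
    return report


def load_clinical_tables(path=None):
    """Load the packaged comparison tables (or a user TSV in the same dialect).

    Columns: table, variable, unit, timepoint, obs_mean, obs_sd, ctrl_mean,
    ctrl_sd, n, t, p.
    """
    if path is None:
        src = resources.files("tensorcut.data").joinpath("clinical_tables.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"variable", "timepoint", "obs_mean", "obs_sd", "ctrl_mean", "ctrl_sd", "n", "t"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"fixture is missing columns: {sorted(missing)}")
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(
            ComparisonRow(
                variable=str(rec.variable),
                timepoint=str(rec.timepoint),
                observation=GroupSummary(float(rec.obs_mean), float(rec.obs_sd), int(rec.n)),
                control=GroupSummary(float(rec.ctrl_mean), float(rec.ctrl_sd), int(rec.n)),
                printed_t=float(rec.t),
                printed_p_bound=str(getattr(rec, "p", "")),
                unit=str(getattr(rec, "unit", "")),
                table=str(getattr(rec, "table", "")),
            )
        )
    return rows
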