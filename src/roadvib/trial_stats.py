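"""Road-trial study statistics: category summaries, ANOVA, Tukey HSD.

The standardized design is incomplete (no cobblestone above 60 km/h, no
dirt road above 30 km/h, no rough asphalt at 150 km/h), so the two-way
analysis fits a cell-means model on the observed cells only and decomposes
the model sum of squares sequentially (speed, then road surface, then their
interaction), with degrees of freedom taken from design-matrix ranks. For
the 12-cell x 10-replicate design this yields interaction df 4 and residual
df 108. Pairwise comparisons use Tukey's HSD with the pooled residual mean
square over all 66 cell pairs as the family.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from roadvib.displacement import TrialResult


@dataclass(frozen=True)
class CategorySummary:
    """Descriptive statistics of one surface x speed category."""

    surface: str
    speed: float
    mean_dbar: float
    sd_dbar: float
    cv_pct: float
    min_di: float
    max_di: float
    n_trials: int
    single_trial: bool = False  # SD reported as 0 from a single trial

    @property
    def label(self) -> str:
        return f"{self.surface}-{int(self.speed)}"


@dataclass(frozen=True)
class AnovaRow:
    term: str
    df: int
    sum_sq: float
    mean_sq: float | None
    f_value: float | None
    p_value: float | None


@dataclass
class AnovaTable:
    """Sequential two-way decomposition: speed, surface, interaction, residual."""

    rows: list[AnovaRow]
    n_observations: int

    def __getitem__(self, term: str) -> AnovaRow:
        for row in self.rows:
            if row.term == term:
                return row
        raise KeyError(term)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": r.term,
                    "df": r.df,
                    "sum_sq": r.sum_sq,
                    "mean_sq": r.mean_sq,
                    "F": r.f_value,
                    "p": r.p_value,
                }
                for r in self.rows
            ]
        )


@dataclass(frozen=True)
class TukeyComparison:
    """One family-wise adjusted pairwise comparison of category means.

    ``mean_diff`` is mean(group_i) - mean(group_ii); the confidence limits
    are reported on the same orientation with ``ci_lower <= ci_upper``.
    """

    group_i: str
    group_ii: str
    mean_diff: float
    p_adj: float
    ci_lower: float
    ci_upper: float

    @property
    def varying_factor(self) -> str | None:
        si, vi = self.group_i.split("-")
        sj, vj = self.group_ii.split("-")
        if si == sj and vi != vj:
            return "speed"
        if si != sj and vi == vj:
            return "road_surface"
        return None


def _group(trials: list[TrialResult]) -> dict[tuple[str, float], list[TrialResult]]:
    groups: dict[tuple[str, float], list[TrialResult]] = {}
    for t in trials:
        groups.setdefault((t.surface, t.speed), []).append(t)
    return groups


def category_summary(trials: list[TrialResult]) -> list[CategorySummary]:
    """Per-category mean/SD/CV of D̄x plus pooled D_i extremes.

    SD uses the n-1 denominator; a single-trial category reports SD 0 and
    is flagged. CV is SD/mean x 100.
    """
    if not trials:
        raise ValueError("no trials given")
    out = []
    for (surface, speed), ts in sorted(_group(trials).items()):
        dbars = np.array([t.dbar for t in ts])
        single = len(ts) < 2
        sd = 0.0 if single else float(dbars.std(ddof=1))
        mean = float(dbars.mean())
        out.append(
            CategorySummary(
                surface=surface,
                speed=speed,
                mean_dbar=mean,
                sd_dbar=sd,
                cv_pct=0.0 if mean == 0 else 100.0 * sd / mean,
                min_di=float(min(t.min_di for t in ts)),
                max_di=float(max(t.max_di for t in ts)),
                n_trials=len(ts),
                single_trial=single,
            )
        )
    return out


def _rss(y: np.ndarray, x: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of a least-squares fit."""
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


def _dummies(labels: list, levels: list) -> np.ndarray:
    # labels may be tuples; avoid numpy's 2-D coercion of tuple lists
    return np.column_stack(
        [np.fromiter((1.0 if lab == lv else 0.0 for lab in labels), float, len(labels)) for lv in levels]
    )


def two_way_anova(trials: list[TrialResult]) -> AnovaTable:
    """Sequential (Type I) two-way ANOVA of D̄x on speed and road surface.

    Fits nested least-squares models — intercept, + speed, + surface,
    + observed-cell means — and attributes each sum-of-squares increment to
    the added term; degrees of freedom are rank increments, so empty design
    cells are handled without imputation. F tests use the cell-means
    residual mean square.
    """
    groups = _group(trials)
    if len(groups) < 2:
        raise ValueError("need at least 2 categories for a two-way analysis")
    if any(len(ts) < 2 for ts in groups.values()):
        raise ValueError("need at least 2 trials per category")
    y = np.array([t.dbar for t in trials], dtype=float)
    n = y.size
    speeds = sorted({t.speed for t in trials})
    surfaces = sorted({t.surface for t in trials})
    cells = sorted(groups)

    intercept = np.ones((n, 1))
    x_speed = np.hstack([intercept, _dummies([t.speed for t in trials], speeds)])
    x_surface = np.hstack([x_speed, _dummies([t.surface for t in trials], surfaces)])
    x_cells = _dummies([(t.surface, t.speed) for t in trials], cells)

    rss0, rank0 = _rss(y, intercept)
    rss1, rank1 = _rss(y, x_speed)
    rss2, rank2 = _rss(y, x_surface)
    rss3, rank3 = _rss(y, x_cells)

    terms = [
        ("speed", rss0 - rss1, rank1 - rank0),
        ("road_surface", rss1 - rss2, rank2 - rank1),
        ("speed:road_surface", rss2 - rss3, rank3 - rank2),
    ]
    df_resid = n - rank3
    # round-off floor: SS below this is numerically zero (constant data)
    tol = 1e-12 * float(y @ y + 1.0)
    if rss3 < tol:
        rss3 = 0.0
    ms_resid = rss3 / df_resid if df_resid > 0 else float("nan")

    rows = []
    for term, ss, df in terms:
        ss = 0.0 if ss < tol else ss
        ms = ss / df if df > 0 else None
        if ms is None or df_resid <= 0 or ms_resid == 0:
            f_val = p_val = None
        else:
            f_val = ms / ms_resid
            p_val = float(stats.f.sf(f_val, df, df_resid))
        rows.append(AnovaRow(term, df, ss, ms, f_val, p_val))
    rows.append(AnovaRow("residual", df_resid, rss3, ms_resid, None, None))
    return AnovaTable(rows=rows, n_observations=n)


def tukey_hsd(trials: list[TrialResult], alpha: float = 0.05) -> list[TukeyComparison]:
    """All pairwise Tukey-HSD comparisons among category means.

    The family is every pair of observed cells, adjusted with the
    studentized range over the pooled residual mean square (the within-cell
    variance, identical to the cell-means ANOVA residual). ``mean_diff``
    follows the group-I-minus-group-II orientation.
    """
    groups = _group(trials)
    labels = [f"{t.surface}-{int(t.speed)}" for t in trials]
    y = np.array([t.dbar for t in trials], dtype=float)
    n = y.size
    k = len(groups)
    if n - k < 1:
        raise ValueError("Tukey HSD needs at least 1 residual degree of freedom")

    # degenerate zero-variance guard: studentized range is undefined there
    means = {lab: float(np.mean(y[np.array(labels) == lab])) for lab in sorted(set(labels))}
    pooled_var = sum(
        float(((y[np.array(labels) == lab] - means[lab]) ** 2).sum()) for lab in means
    ) / (n - k)
    if pooled_var == 0:
        out = []
        for gi, gj in itertools.combinations(sorted(means), 2):
            diff = means[gi] - means[gj]
            out.append(
                TukeyComparison(gi, gj, diff, 0.0 if diff != 0 else 1.0, diff, diff)
            )
        return out

    res = pairwise_tukeyhsd(endog=y, groups=np.array(labels), alpha=alpha)
    out = []
    uniq = list(res.groupsunique)
    pairs = list(itertools.combinations(range(len(uniq)), 2))
    for (i, j), meandiff, p, (lo, hi) in zip(pairs, res.meandiffs, res.pvalues, res.confint):
        # statsmodels reports mean(group_j) - mean(group_i); flip to I - II
        out.append(
            TukeyComparison(
                group_i=str(uniq[i]),
                group_ii=str(uniq[j]),
                mean_diff=float(-meandiff),
                p_adj=float(p),
                ci_lower=float(-hi),
                ci_upper=float(-lo),
            )
        )
    return out


def single_factor_view(comparisons: list[TukeyComparison]) -> dict[str, list[TukeyComparison]]:
    """Comparisons differing in exactly one factor, grouped by that factor."""
    view: dict[str, list[TukeyComparison]] = {"speed": [], "road_surface": []}
    for c in comparisons:
        factor = c.varying_factor
        if factor is not None:
            view[factor].append(c)
    return view


def significance_stars(p: float) -> str:
    """Display convention: ``*`` for p < 0.05, ``***`` for p < 0.001."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""


def study_report(trials: list[TrialResult]) -> dict:
    """JSON-able study report: summaries, ANOVA table, one-factor Tukey view.

    The Tukey family is all pairwise cell comparisons; the single-factor
    view shown is a display subset of that family.
    """
    summaries = category_summary(trials)
    table = two_way_anova(trials)
    comparisons = tukey_hsd(trials)
    view = single_factor_view(comparisons)
    return {
        "n_trials": len(trials),
        "categories": [
            {
                "surface": s.surface,
                "speed": s.speed,
                "mean_dbar": s.mean_dbar,
                "sd_dbar": s.sd_dbar,
                "cv_pct": s.cv_pct,
                "min_di": s.min_di,
                "max_di": s.max_di,
                "n_trials": s.n_trials,
            }
            for s in summaries
        ],
        "anova": [
            {
                "source": r.term,
                "df": r.df,
                "sum_sq": r.sum_sq,
                "mean_sq": r.mean_sq,
                "F": r.f_value,
                "p": r.p_value,
            }
            for r in table.rows
        ],
        "tukey_family": "all pairwise category comparisons (pooled residual MS)",
        "tukey": {
            factor: [
                {
                    "group_i": c.group_i,
                    "group_ii": c.group_ii,
                    "mean_diff": c.mean_diff,
                    "p_adj": c.p_adj,
                    "ci_lower": c.ci_lower,
                    "ci_upper": c.ci_upper,
                    "stars": significance_stars(c.p_adj),
                }
                for c in comps
            ]
            for factor, comps in view.items()
        },
    }


def summaries_to_frame(summaries: list[CategorySummary]) -> pd.DataFrame:
    """Category summaries as a table (one row per surface x speed cell)."""
    return pd.DataFrame(
        [
            {
                "surface": s.surface,
                "speed": s.speed,
                "mean_dbar": s.mean_dbar,
                "sd_dbar": s.sd_dbar,
                "cv_pct": s.cv_pct,
                "min_di": s.min_di,
                "max_di": s.max_di,
                "n_trials": s.n_trials,
            }
            for s in summaries
        ]
    )
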