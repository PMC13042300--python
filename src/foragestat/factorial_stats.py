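"""Factorial ANOVA and post hoc machinery for the plate assays.

Two tracks mirror the assay's analysis workflow:

* **Raw track** — fixed-effects factorial ANOVA on per-plate percent-exiting
  values (1-, 2-, or 3-way with all interactions), Type III sums of squares
  under sum-to-zero contrasts for unbalanced designs, followed by Šidák- or
  Dunnett-corrected post hoc comparisons.

* **Summary track** — the same ANOVA reconstructed from (mean, SD, n)
  summaries, used downstream of the bootstrap where each strain contributes
  one summarized difference sample with pseudo-N = N_fed + N_fd - 1.

The ANOVA fits go through statsmodels; the summary bridge works because a
fixed-effects ANOVA depends on the data only through cell means and
within-cell sums of squares, so a moment-matched reconstruction is exact.
Dunnett's many-to-one probabilities are computed from the equicorrelated
multivariate-t box probability.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.optimize import brentq

from .assay_data import GroupSample
from .bootstrap_effect import BootstrapResult

__all__ = [
    "SummaryCell",
    "FactorialDesign",
    "AnovaTable",
    "ComparisonResult",
    "AdjustMethod",
    "anova_raw",
    "anova_from_summary",
    "sidak_adjust",
    "posthoc_sidak",
    "posthoc_dunnett",
    "dunnett_pvalues",
    "dunnett_critical_value",
    "two_sample_t",
    "bootstrap_effect_anova",
    "report_hierarchy",
]


class AdjustMethod(str, enum.Enum):
    SIDAK = "sidak"
    DUNNETT = "dunnett"
    NONE = "none"


@dataclass(frozen=True)
class SummaryCell:
    """(mean, sd, n) sufficient statistics for one design cell."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.n < 2:
            raise ValueError(f"summary cell needs n >= 2, got {self.n}")


@dataclass
class FactorialDesign:
    """Cells of a full factorial design, keyed by level combinations.

    ``factors`` maps factor name -> ordered level labels; every cell key is a
    tuple of levels, one per factor in order.  Cells hold either raw score
    vectors or :class:`SummaryCell` statistics.
    """

    factors: dict[str, list[str]]
    cells: dict[tuple, object]
    response: str = "score"

    def __post_init__(self) -> None:
        names = list(self.factors)
        if not names:
            raise ValueError("design needs at least one factor")
        for name, levels in self.factors.items():
            if len(levels) < 2:
                raise ValueError(f"factor {name!r} needs >= 2 levels")
        expected = 1
        for levels in self.factors.values():
            expected *= len(levels)
        if len(self.cells) != expected:
            raise ValueError(
                f"full factorial needs {expected} cells, got {len(self.cells)}"
            )
        for key in self.cells:
            if len(key) != len(names):
                raise ValueError(f"cell key {key} does not match factor count")
            for lev, name in zip(key, names):
                if lev not in self.factors[name]:
                    raise ValueError(f"level {lev!r} not declared for factor {name!r}")

    @property
    def factor_names(self) -> list[str]:
        return list(self.factors)

    def is_summary(self) -> bool:
        return any(isinstance(c, SummaryCell) for c in self.cells.values())

    @classmethod
    def from_samples(
        cls, factors: dict[str, list[str]], cells: Mapping[tuple, object], **kw
    ) -> "FactorialDesign":
        norm = {}
        for key, val in cells.items():
            if isinstance(val, GroupSample):
                val = val.values
            if not isinstance(val, SummaryCell):
                val = np.asarray(val, dtype=float)
                if val.size == 0:
                    raise ValueError(f"empty cell {key}")
            norm[tuple(key)] = val
        return cls(factors={k: list(v) for k, v in factors.items()}, cells=norm, **kw)


@dataclass
class AnovaTable:
    """Per-term SS / df / MS / F / p, with the residual row last.

    ``degenerate`` flags a zero residual mean square (no within-cell
    variance), in which case F and p are NaN rather than infinite.
    """

    table: pd.DataFrame  # index: term names + "Residual"; cols: sum_sq df mean_sq F p
    degenerate: bool = False

    @property
    def residual_df(self) -> float:
        return float(self.table.loc["Residual", "df"])

    @property
    def residual_ms(self) -> float:
        return float(self.table.loc["Residual", "mean_sq"])

    def term_p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def terms(self) -> list[str]:
        return [t for t in self.table.index if t != "Residual"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="term")

    def to_dict(self) -> dict:
        return {
            "degenerate": self.degenerate,
            "terms": {
                t: {c: _jsonable(self.table.loc[t, c]) for c in self.table.columns}
                for t in self.table.index
            },
        }

    def to_text(self) -> str:
        """Plain-text rendering, highest-order interactions first."""
        order = sorted(self.terms(), key=lambda t: -t.count(":"))
        lines = ["term                                     df        F         P"]
        for t in order:
            row = self.table.loc[t]
            lines.append(
                f"{t:<40} {row['df']:>3.0f} {row['F']:>9.4g} {row['p']:>9.4g}"
            )
        res = self.table.loc["Residual"]
        lines.append(f"{'Residual':<40} {res['df']:>3.0f}")
        return "\n".join(lines)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        x = x.item()
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


@dataclass(frozen=True)
class ComparisonResult:
    """One post hoc comparison with its multiplicity-adjusted p-value."""

    label: str
    estimate: float
    raw_p: float
    adjusted_p: float
    method: AdjustMethod
    family_size: int
    statistic: float = float("nan")
    df: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "estimate": self.estimate,
            "raw_p": self.raw_p,
            "adjusted_p": self.adjusted_p,
            "method": self.method.value,
            "family_size": self.family_size,
            "statistic": _jsonable(self.statistic),
            "df": _jsonable(self.df),
        }


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def _long_frame(design: FactorialDesign) -> pd.DataFrame:
    """Expand raw cells into a long-form frame with sanitized factor columns."""
    rows = []
    names = design.factor_names
    for key, values in design.cells.items():
        if isinstance(values, SummaryCell):
            raise TypeError("anova_raw requires raw cells; use anova_from_summary")
        for v in np.asarray(values, dtype=float):
            rows.append(dict(zip(names, key), y=v))
    return pd.DataFrame(rows)


def anova_raw(design: FactorialDesign) -> AnovaTable:
    """Full-factorial fixed-effects ANOVA with all interactions.

    Unbalanced designs use Type III (marginal) sums of squares under
    sum-to-zero contrasts; balanced designs are SS-type invariant.
    """
    data = _long_frame(design)
    names = design.factor_names
    safe = {name: f"F{i}" for i, name in enumerate(names)}
    data = data.rename(columns=safe)
    terms = " * ".join(f"C({safe[n]}, Sum)" for n in names)
    model = smf.ols(f"y ~ {terms}", data=data).fit()
    if model.df_resid < 1:
        raise ValueError("zero residual degrees of freedom")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns on 0/0 F under degeneracy
        aov = sm.stats.anova_lm(model, typ=3)
    aov = aov.drop(index="Intercept")

    unsafe = {f"C({v}, Sum)": k for k, v in safe.items()}

    def _pretty(term: str) -> str:
        if term == "Residual":
            return term
        return ":".join(unsafe[p] for p in term.split(":"))

    aov.index = [_pretty(t) for t in aov.index]
    out = pd.DataFrame(
        {
            "sum_sq": aov["sum_sq"],
            "df": aov["df"],
            "mean_sq": aov["sum_sq"] / aov["df"],
            "F": aov["F"],
            "p": aov["PR(>F)"],
        }
    )
    # rounding can leave ~1e-28 where the residual SS is really zero
    total_ss = float(out["sum_sq"].sum())
    degenerate = bool(out.loc["Residual", "sum_sq"] <= 1e-10 * (total_ss + 1.0))
    if degenerate:
        out.loc[out.index != "Residual", ["F", "p"]] = np.nan
        warnings.warn(
            "zero within-cell variance: F ratios undefined", RuntimeWarning,
            stacklevel=2,
        )
    return AnovaTable(table=out, degenerate=degenerate)


def _reconstruct_cell(cell: SummaryCell) -> np.ndarray:
    """Raw vector of length n with exactly the cell's mean and sample SD."""
    z = np.zeros(cell.n)
    z[0], z[1] = 1.0, -1.0
    scale = np.sqrt((cell.n - 1) / 2.0)  # sample SD of z is sqrt(2/(n-1))
    return cell.mean + cell.sd * z * scale


def anova_from_summary(design: FactorialDesign) -> AnovaTable:
    """ANOVA from per-cell (mean, sd, n) summaries.

    Reconstructs a moment-matched raw dataset per cell and dispatches to
    :func:`anova_raw`; the result is identical to the ANOVA of any raw data
    with the same cell means, SDs, and sizes.
    """
    cells = {}
    for key, cell in design.cells.items():
        if not isinstance(cell, SummaryCell):
            raise TypeError("anova_from_summary requires SummaryCell cells")
        cells[key] = _reconstruct_cell(cell)
    raw_design = FactorialDesign(
        factors=design.factors, cells=cells, response=design.response
    )
    return anova_raw(raw_design)


# ---------------------------------------------------------------------------
# Post hoc comparisons
# ---------------------------------------------------------------------------

def sidak_adjust(raw_p: float, m: int) -> float:
    """Šidák familywise adjustment ``1 - (1 - p)^m`` for m comparisons."""
    if m < 1:
        raise ValueError(f"family size must be >= 1, got {m}")
    if not 0.0 <= raw_p <= 1.0:
        raise ValueError(f"p-value {raw_p} outside [0, 1]")
    if m == 1:
        return float(raw_p)  # exact identity, avoids 1-(1-p) round-trip
    return float(1.0 - (1.0 - raw_p) ** m)


def _cell_stats(cell) -> tuple[float, float, int]:
    if isinstance(cell, SummaryCell):
        return cell.mean, cell.sd, cell.n
    v = np.asarray(cell, dtype=float)
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    return float(v.mean()), float(sd), int(v.size)


def _pooled_residual(cells: Sequence) -> tuple[float, float]:
    """Pooled residual mean square and df across cells (raw or summary)."""
    ss, df = 0.0, 0.0
    for cell in cells:
        mean, sd, n = _cell_stats(cell)
        ss += (n - 1) * sd**2
        df += n - 1
    if df < 1:
        raise ValueError("pooled residual degrees of freedom < 1")
    return ss / df, df


def posthoc_sidak(
    design: FactorialDesign,
    plan: Sequence[tuple[str, tuple, tuple]],
    family_size: int | None = None,
) -> list[ComparisonResult]:
    """Šidák-corrected pairwise cell comparisons (e.g. mutant vs matched WT,
    separately for fed and food-deprived).

    Each comparison is a two-sided t on the difference of cell means using
    the design-wide pooled residual mean square; the family size defaults to
    the number of planned comparisons.
    """
    mse, df = _pooled_residual(list(design.cells.values()))
    m = family_size if family_size is not None else len(plan)
    results = []
    for label, key_a, key_b in plan:
        if key_a not in design.cells or key_b not in design.cells:
            raise KeyError(f"comparison {label!r} references an absent cell")
        mean_a, _, n_a = _cell_stats(design.cells[key_a])
        mean_b, _, n_b = _cell_stats(design.cells[key_b])
        est = mean_a - mean_b
        se = np.sqrt(mse * (1.0 / n_a + 1.0 / n_b))
        if se == 0:
            t, raw_p = (0.0, 1.0) if est == 0 else (np.inf, 0.0)
        else:
            t = est / se
            raw_p = 2.0 * sps.t.sf(abs(t), df)
        results.append(
            ComparisonResult(
                label=label,
                estimate=est,
                raw_p=float(raw_p),
                adjusted_p=sidak_adjust(float(raw_p), m),
                method=AdjustMethod.SIDAK,
                family_size=m,
                statistic=float(t),
                df=df,
            )
        )
    return results


def _dunnett_corr(ns: np.ndarray, n0: int) -> np.ndarray:
    lam = np.sqrt(ns / (ns + n0))
    rho = np.outer(lam, lam)
    np.fill_diagonal(rho, 1.0)
    return rho


def _dunnett_box_prob(c: float, rho: np.ndarray, df: float, seed: int = 0) -> float:
    """P(|T_i| <= c for all i) under the central equicorrelated multivariate t."""
    k = rho.shape[0]
    mvt = sps.multivariate_t(loc=np.zeros(k), shape=rho, df=df)
    return float(
        mvt.cdf(
            np.full(k, c),
            lower_limit=np.full(k, -c),
            maxpts=50_000 * k,
            random_state=np.random.default_rng(seed),
        )
    )


def dunnett_pvalues(
    t_stats: Sequence[float], ns: Sequence[int], n_control: int, df: float
) -> np.ndarray:
    """Two-sided Dunnett p-values for many-to-one t statistics.

    ``ns`` are the treatment group sizes; the correlation between statistics
    sharing the control is sqrt(n_i n_j / ((n_i+n0)(n_j+n0))).  k=1 reduces
    exactly to the ordinary two-sided t.  QMC integration of the multivariate
    t is seeded, with absolute tolerance ~1e-4 (recorded as 1e-3 in results).
    """
    t_stats = np.asarray(t_stats, dtype=float)
    ns = np.asarray(ns, dtype=float)
    k = t_stats.size
    if k == 1:
        return np.atleast_1d(2.0 * sps.t.sf(np.abs(t_stats), df))
    rho = _dunnett_corr(ns, n_control)
    out = np.empty(k)
    for i, t in enumerate(np.abs(t_stats)):
        out[i] = min(1.0, max(0.0, 1.0 - _dunnett_box_prob(t, rho, df)))
    return out


def dunnett_critical_value(
    ns: Sequence[int], n_control: int, df: float, alpha: float = 0.05
) -> float:
    """Two-sided critical value c with P(max |T_i| > c) = alpha under the null."""
    ns = np.asarray(ns, dtype=float)
    if ns.size == 1:
        return float(sps.t.isf(alpha / 2.0, df))
    rho = _dunnett_corr(ns, n_control)
    return float(
        brentq(lambda c: _dunnett_box_prob(c, rho, df) - (1.0 - alpha), 0.5, 15.0,
               xtol=1e-5)
    )


def _dunnett_results(
    labels, means, sds, ns, mean0, sd0, n0
) -> list[ComparisonResult]:
    means, sds, ns = (np.asarray(a, dtype=float) for a in (means, sds, ns))
    k = means.size
    ss = float(np.sum((ns - 1) * sds**2) + (n0 - 1) * sd0**2)
    df = float(np.sum(ns) + n0 - (k + 1))
    if df < 1:
        raise ValueError("pooled residual degrees of freedom < 1")
    s2 = ss / df
    se = np.sqrt(s2 * (1.0 / ns + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (means - mean0) / se, 0.0)
    pvals = dunnett_pvalues(t, ns.astype(int), int(n0), df)
    return [
        ComparisonResult(
            label=lab,
            estimate=float(means[i] - mean0),
            raw_p=float(2.0 * sps.t.sf(abs(t[i]), df)),
            adjusted_p=float(pvals[i]),
            method=AdjustMethod.DUNNETT,
            family_size=k,
            statistic=float(t[i]),
            df=df,
        )
        for i, lab in enumerate(labels)
    ]


def posthoc_dunnett(
    groups: Mapping[str, object] | Sequence, control
) -> list[ComparisonResult]:
    """Dunnett many-to-one comparisons of each treatment group to one control.

    ``groups`` maps labels to raw vectors / GroupSamples / SummaryCells (a
    bare sequence gets numeric labels).  Used for single-control designs, e.g.
    several deprivation durations all compared with the fed condition.
    """
    if not isinstance(groups, Mapping):
        groups = {str(i): g for i, g in enumerate(groups)}
    if not groups:
        raise ValueError("need at least one treatment group")
    mean0, sd0, n0 = _cell_stats(
        control.values if isinstance(control, GroupSample) else control
    )
    if n0 == 0:
        raise ValueError("empty control group")
    labels = list(groups)
    stats = [_cell_stats(g.values if isinstance(g, GroupSample) else g)
             for g in groups.values()]
    means, sds, ns = zip(*stats)
    return _dunnett_results(labels, means, sds, ns, mean0, sd0, n0)


def two_sample_t(a, b, label: str = "a vs b") -> ComparisonResult:
    """Two-sided pooled-variance (Student) t-test.

    Accepts raw vectors / GroupSamples or SummaryCells; moment-matched raw and
    summary inputs give identical results because only (mean, sd, n) enter.
    """
    mean_a, sd_a, n_a = _cell_stats(a.values if isinstance(a, GroupSample) else a)
    mean_b, sd_b, n_b = _cell_stats(b.values if isinstance(b, GroupSample) else b)
    if n_a < 2 or n_b < 2:
        raise ValueError("two_sample_t needs n >= 2 in both groups")
    t, p = sps.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=True
    )
    if np.isnan(t):  # both variances zero and means equal
        t, p = 0.0, 1.0
    return ComparisonResult(
        label=label,
        estimate=mean_a - mean_b,
        raw_p=float(p),
        adjusted_p=float(p),
        method=AdjustMethod.NONE,
        family_size=1,
        statistic=float(t),
        df=float(n_a + n_b - 2),
    )


# ---------------------------------------------------------------------------
# Bootstrap-summary dispatch and the reporting policy
# ---------------------------------------------------------------------------

def bootstrap_effect_anova(
    results: Mapping[tuple, BootstrapResult],
    factors: dict[str, list[str]],
    posthoc: AdjustMethod | str = AdjustMethod.SIDAK,
    plan: Sequence[tuple[str, tuple, tuple]] | None = None,
    control_key: tuple | None = None,
) -> tuple[AnovaTable, list[ComparisonResult]]:
    """ANOVA + post hoc on bootstrapped-difference summaries.

    Each strain's bootstrapped effect of food deprivation enters as one
    summary cell (mean_of_means, mean_of_sds, pseudo_n).  Multi-control
    designs use Šidák comparisons from ``plan``; single-control designs
    (``posthoc='dunnett'``) compare every cell to ``control_key``.
    """
    posthoc = AdjustMethod(posthoc)
    cells = {}
    for key, res in results.items():
        if res.pseudo_n < 2:
            raise ValueError(f"cell {key}: pseudo_n < 2")
        cells[tuple(key)] = SummaryCell(
            mean=res.mean_of_means, sd=res.mean_of_sds, n=res.pseudo_n
        )
    design = FactorialDesign(factors=factors, cells=cells)
    table = anova_from_summary(design)
    comparisons: list[ComparisonResult] = []
    if posthoc is AdjustMethod.SIDAK:
        if plan:
            comparisons = posthoc_sidak(design, plan)
    elif posthoc is AdjustMethod.DUNNETT:
        if control_key is None:
            raise ValueError("dunnett post hoc needs a control_key")
        control = cells[tuple(control_key)]
        treatments = {
            "/".join(map(str, k)): c for k, c in cells.items()
            if k != tuple(control_key)
        }
        comparisons = posthoc_dunnett(treatments, control)
    return table, comparisons


def report_hierarchy(
    table: AnovaTable, alpha: float = 0.05
) -> list[tuple[str, float]]:
    """The standard factorial reporting policy as an executable rule.

    Report the significant term(s) of the highest interaction order that has
    any; only if no interaction of any order is significant fall through to
    the significant main effects.  Returns (term, p) pairs, highest order
    first; empty when nothing is significant.
    """
    by_order: dict[int, list[tuple[str, float]]] = {}
    for term in table.terms():
        order = term.count(":") + 1
        p = table.term_p(term)
        by_order.setdefault(order, []).append((term, p))
    for order in sorted((o for o in by_order if o >= 2), reverse=True):
        hits = [(t, p) for t, p in by_order[order] if p < alpha]
        if hits:
            return hits
    return [(t, p) for t, p in by_order.get(1, []) if p < alpha]
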