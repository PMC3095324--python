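"""Annual-vs-perennial comparison statistics.

Given per-locus rate pairs (annual rate, perennial rate) for each
comparison cell — one annual species x one perennial species x one
estimator — this module runs the battery used to test rate heterogeneity
against the molecular-clock null:

* an exact one-sided **sign test** on the count of loci where the annual
  rate exceeds the perennial rate (ties removed),
* a **paired t-test** on the per-locus rate differences,
* a **through-origin regression** of perennial rate on annual rate
  (both species diverged from a common ancestor, so the regression line is
  constrained through (0, 0)); a slope below 1 means the annual lineage
  evolves faster.

The `statsmodels`-style entry point is :class:`AnnualPerennialComparison`,
a model built from a paired rate table (or directly from loci) whose
``fit()`` returns :class:`AnnualPerennialResults` with the per-cell
summaries, a ``summary()`` table and scatter/plot accessors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rates import OK, NEGATIVE, UNDEFINED, build_rate_table

__all__ = [
    "sign_test",
    "paired_t",
    "PairedTResult",
    "regression_through_origin",
    "ComparisonSummary",
    "cross_comparison",
    "AnnualPerennialComparison",
    "AnnualPerennialResults",
]


def sign_test(k: int, n: int) -> float:
    """One-sided exact binomial tail ``P(X >= k | n, 1/2)``.

    Exact integer arithmetic (no floating summation); *n* must already
    exclude ties.
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n < 1:
        raise ValueError("n must be >= 1")
    tail = sum(comb(n, i) for i in range(k, n + 1))
    return float(Fraction(tail, 1 << n))


@dataclass(frozen=True)
class PairedTResult:
    statistic: float
    df: int
    pvalue: float
    note: str = ""


def paired_t(
    diffs: Sequence[float], alternative: str = "greater"
) -> PairedTResult:
    """Paired t-test on per-locus rate differences (annual - perennial).

    ``t = mean / (sd / sqrt(n))`` with ``df = n - 1``; one-sided p for the
    annual-faster alternative by default (``alternative="two-sided"`` for
    the symmetric test).  Zero variance gives a degenerate result with an
    explanatory note.
    """
    x = np.asarray(list(diffs), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 differences")
    if not np.all(np.isfinite(x)):
        raise ValueError("differences must be finite")
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(float("nan"), n - 1, 1.0, "all differences zero")
        t = math.inf if mean > 0 else -math.inf
        p = 0.0 if mean > 0 else 1.0
        if alternative == "two-sided":
            p = 0.0
        return PairedTResult(t, n - 1, p, "zero variance")
    t = mean / (sd / math.sqrt(n))
    if alternative == "greater":
        p = float(stats.t.sf(t, n - 1))
    elif alternative == "two-sided":
        p = float(2.0 * stats.t.sf(abs(t), n - 1))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return PairedTResult(t, n - 1, p)


def regression_through_origin(
    annual: Sequence[float], perennial: Sequence[float]
) -> tuple[float, float, float]:
    """Through-origin regression of perennial rate on annual rate.

    Returns ``(slope, r2_pearson, r2_origin)`` where
    ``slope = sum(x*y) / sum(x**2)`` with x = annual, y = perennial,
    ``r2_origin = 1 - sum((y - b*x)**2) / sum(y**2)`` (the no-intercept
    coefficient of determination) and ``r2_pearson`` the squared Pearson
    correlation.  A slope below 1 corresponds to faster evolution in the
    annual lineage.
    """
    x = np.asarray(list(annual), dtype=float)
    y = np.asarray(list(perennial), dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("all annual rates are zero; slope undefined")
    slope = float(np.dot(x, y)) / sxx
    syy = float(np.dot(y, y))
    resid = y - slope * x
    r2_origin = 1.0 - float(np.dot(resid, resid)) / syy if syy > 0 else float("nan")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        r2_pearson = float("nan")
    else:
        r2_pearson = float(np.corrcoef(x, y)[0, 1] ** 2)
    return slope, r2_pearson, r2_origin


@dataclass
class ComparisonSummary:
    """One annual x perennial x estimator cell of the comparison battery."""

    annual: str
    perennial: str
    estimator: str
    n_used: int
    n_excluded: int
    n_ties: int
    k_annual_higher: int
    proportion: float
    sign_p: float
    t_stat: float
    t_p: float
    slope: float
    r2_pearson: float
    r2_origin: float

    def as_dict(self) -> dict:
        return {
            "annual": self.annual,
            "perennial": self.perennial,
            "estimator": self.estimator,
            "n": self.n_used,
            "n_excluded": self.n_excluded,
            "n_ties": self.n_ties,
            "k_annual_higher": self.k_annual_higher,
            "proportion": self.proportion,
            "sign_p": self.sign_p,
            "t_stat": self.t_stat,
            "t_p": self.t_p,
            "slope": self.slope,
            "r2_pearson": self.r2_pearson,
            "r2_origin": self.r2_origin,
        }


def cross_comparison(
    rate_table: pd.DataFrame,
    annuals: Sequence[str],
    perennials: Sequence[str],
    estimators: Sequence[str],
    exclude_negative: bool = False,
) -> tuple[list[ComparisonSummary], pd.DataFrame]:
    """Run the full battery over every annual x perennial x estimator cell.

    Loci with an undefined member are excluded (logged); ties contribute to
    the t-test and regression but not to the sign test's *n*.  Negative
    decomposed rates are kept by default (legitimate "perennial higher"
    evidence) unless *exclude_negative*.

    Returns the list of :class:`ComparisonSummary` (one per cell; an empty
    cell raises) and an exclusion log DataFrame.
    """
    summaries: list[ComparisonSummary] = []
    log_rows = []
    for a in annuals:
        for p in perennials:
            for est in estimators:
                cell = rate_table[
                    (rate_table["annual"] == a)
                    & (rate_table["perennial"] == p)
                    & (rate_table["estimator"] == est)
                ]
                bad_flag = {UNDEFINED}
                if exclude_negative:
                    bad_flag.add(NEGATIVE)
                defined = (
                    ~cell["annual_flag"].isin(bad_flag)
                    & ~cell["perennial_flag"].isin(bad_flag)
                    & np.isfinite(cell["annual_rate"])
                    & np.isfinite(cell["perennial_rate"])
                )
                used = cell[defined]
                for _, row in cell[~defined].iterrows():
                    log_rows.append(
                        {
                            "locus_id": row["locus_id"],
                            "annual": a,
                            "perennial": p,
                            "estimator": est,
                            "reason": (
                                row["annual_flag"]
                                if row["annual_flag"] != OK
                                else row["perennial_flag"]
                            ),
                        }
                    )
                if used.empty:
                    raise ValueError(
                        f"no usable loci for {a} vs {p} ({est}) after exclusions"
                    )
                x = used["annual_rate"].to_numpy()
                y = used["perennial_rate"].to_numpy()
                diffs = x - y
                nonties = diffs[diffs != 0.0]
                k = int((nonties > 0).sum())
                n_sign = int(nonties.size)
                sp = sign_test(k, n_sign) if n_sign >= 1 else float("nan")
                tres = paired_t(diffs) if diffs.size >= 2 else PairedTResult(
                    float("nan"), 0, float("nan"), "too few loci"
                )
                slope, r2p, r2o = regression_through_origin(x, y)
                summaries.append(
                    ComparisonSummary(
                        annual=a,
                        perennial=p,
                        estimator=est,
                        n_used=int(used.shape[0]),
                        n_excluded=int((~defined).sum()),
                        n_ties=int(diffs.size - n_sign),
                        k_annual_higher=k,
                        proportion=k / n_sign if n_sign else float("nan"),
                        sign_p=sp,
                        t_stat=tres.statistic,
                        t_p=tres.pvalue,
                        slope=slope,
                        r2_pearson=r2p,
                        r2_origin=r2o,
                    )
                )
    log = pd.DataFrame(
        log_rows, columns=["locus_id", "annual", "perennial", "estimator", "reason"]
    )
    return summaries, log


class AnnualPerennialComparison:
    """Model for the genome-wide annual-vs-perennial rate comparison.

    Built from a paired per-locus rate table (columns ``locus_id``,
    ``annual``, ``perennial``, ``estimator``, ``annual_rate``,
    ``perennial_rate``, ``annual_flag``, ``perennial_flag``), or directly
    from codon alignments via :meth:`from_loci`.  ``fit()`` runs the sign
    test, paired t-test and through-origin regression for every cell and
    returns an :class:`AnnualPerennialResults`.
    """

    def __init__(
        self,
        rate_table: pd.DataFrame,
        annuals: Sequence[str] | None = None,
        perennials: Sequence[str] | None = None,
        estimators: Sequence[str] | None = None,
        exclude_negative: bool = False,
    ):
        required = {
            "locus_id",
            "annual",
            "perennial",
            "estimator",
            "annual_rate",
            "perennial_rate",
        }
        missing = required - set(rate_table.columns)
        if missing:
            raise ValueError(f"rate table missing columns {sorted(missing)}")
        table = rate_table.copy()
        for col in ("annual_flag", "perennial_flag"):
            if col not in table.columns:
                table[col] = OK
        self.rate_table = table
        self.annuals = list(annuals) if annuals else sorted(table["annual"].unique())
        self.perennials = (
            list(perennials) if perennials else sorted(table["perennial"].unique())
        )
        self.estimators = (
            list(estimators) if estimators else sorted(table["estimator"].unique())
        )
        self.exclude_negative = exclude_negative

    @classmethod
    def from_loci(
        cls,
        loci,
        annuals: Sequence[str],
        perennials: Sequence[str],
        outgroup: str,
        estimators: Sequence[str] = ("d", "pN", "pS"),
        method: str = "outgroup",
        exclude_negative: bool = False,
        **kwargs,
    ) -> "AnnualPerennialComparison":
        """Estimate per-locus rates from codon alignments, then build the model."""
        table = build_rate_table(
            loci, annuals, perennials, outgroup, estimators, method, **kwargs
        )
        return cls(
            table,
            annuals=annuals,
            perennials=perennials,
            estimators=estimators,
            exclude_negative=exclude_negative,
        )

    def fit(self) -> "AnnualPerennialResults":
        cells, log = cross_comparison(
            self.rate_table,
            self.annuals,
            self.perennials,
            self.estimators,
            exclude_negative=self.exclude_negative,
        )
        return AnnualPerennialResults(self, cells, log)


class AnnualPerennialResults:
    """Fitted comparison battery: one summary row per comparison cell."""

    def __init__(
        self,
        model: AnnualPerennialComparison,
        cells: list[ComparisonSummary],
        exclusion_log: pd.DataFrame,
    ):
        self.model = model
        self.cells = cells
        self.exclusion_log = exclusion_log
        self.summaries = pd.DataFrame([c.as_dict() for c in cells])

    # -- aggregate statistics -------------------------------------------------

    def pooled_sign_test(self) -> tuple[int, int, float]:
        """Exact sign test on counts pooled over all cells.

        Cells share species and loci, so under the clock null the pooled
        test is anti-conservative; it summarizes overall directionality.
        Returns ``(k, n, p)``.
        """
        k = int(sum(c.k_annual_higher for c in self.cells))
        n = int(sum(c.n_used - c.n_ties for c in self.cells))
        return k, n, sign_test(k, n)

    def scatter_data(self, annual: str, perennial: str, estimator: str) -> pd.DataFrame:
        """Per-locus (annual_rate, perennial_rate) pairs for one cell."""
        t = self.model.rate_table
        cell = t[
            (t["annual"] == annual)
            & (t["perennial"] == perennial)
            & (t["estimator"] == estimator)
        ]
        ok = np.isfinite(cell["annual_rate"]) & np.isfinite(cell["perennial_rate"])
        return cell.loc[ok, ["locus_id", "annual_rate", "perennial_rate"]].reset_index(
            drop=True
        )

    def plot(self, annual: str, perennial: str, estimator: str, ax=None):
        """Scatter of perennial vs annual rates with diagonal and fit line."""
        import matplotlib.pyplot as plt

        data = self.scatter_data(annual, perennial, estimator)
        cell = next(
            c
            for c in self.cells
            if (c.annual, c.perennial, c.estimator) == (annual, perennial, estimator)
        )
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(data["annual_rate"], data["perennial_rate"], s=12, alpha=0.7)
        lim = max(
            float(data["annual_rate"].max()), float(data["perennial_rate"].max())
        )
        xs = np.linspace(0, lim * 1.05, 10)
        ax.plot(xs, xs, ls=":", color="gray", label="slope 1 (clock)")
        ax.plot(xs, cell.slope * xs, color="red", label=f"slope {cell.slope:.2f}")
        ax.set_xlabel(f"{annual} rate ({estimator})")
        ax.set_ylabel(f"{perennial} rate ({estimator})")
        ax.legend(frameon=False)
        return ax

    def write_tsv(self, path) -> None:
        self.summaries.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        """Plain-text report shaped like the sign-test/regression tables."""
        lines = [
            "Annual vs perennial evolutionary-rate comparison",
            f"  cells: {len(self.cells)}  "
            f"(annuals: {', '.join(self.model.annuals)}; "
            f"perennials: {', '.join(self.model.perennials)}; "
            f"estimators: {', '.join(self.model.estimators)})",
            "",
            f"{'comparison':<14}{'est':<5}{'n':>5}{'higher%':>9}{'sign_p':>11}"
            f"{'t_p':>11}{'slope':>8}{'R2(P)':>8}{'R2(0)':>8}",
        ]
        for c in self.cells:
            lines.append(
                f"{c.annual + ' vs ' + c.perennial:<14}{c.estimator:<5}"
                f"{c.n_used:>5}{100 * c.proportion:>8.1f}%{c.sign_p:>11.3g}"
                f"{c.t_p:>11.3g}{c.slope:>8.3f}{c.r2_pearson:>8.3f}{c.r2_origin:>8.3f}"
            )
        k, n, p = self.pooled_sign_test()
        lines.append("")
        lines.append(f"pooled sign test: {k}/{n} annual-higher, one-sided p = {p:.3g}")
        if len(self.exclusion_log):
            lines.append(f"excluded locus-cells: {len(self.exclusion_log)}")
        return "\n".join(lines)
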