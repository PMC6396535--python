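"""Structure–function agreement and pattern-frequency statistics.

Validation of standardized densitometry against gas transfer: subjects are
dichotomized (structure abnormal iff SMS < −2; function abnormal iff D_LCO
below 80% predicted), agreement is summarized by Cohen's kappa on the 2×2
confusion matrix with a large-sample test of κ = 0, association by Spearman
rank correlation and the OLS R², and the distribution of regional
involvement by frequencies over the eight apical/central/basal patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError
from .sms import CANONICAL_PATTERNS, PATTERN_ORDER, SMSResult, classify_pattern


@dataclass
class ConfusionMatrix2x2:
    """Structure (rows: normal/abnormal) × function (cols: normal/abnormal)."""

    both_normal: int            # structure normal,  function normal
    struct_normal_func_abn: int
    struct_abn_func_normal: int
    both_abnormal: int

    def __post_init__(self) -> None:
        for v in self.cells:
            if v < 0:
                raise DegenerateInputError("confusion-matrix cells must be ≥ 0")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.both_normal, self.struct_normal_func_abn,
                self.struct_abn_func_normal, self.both_abnormal)

    @property
    def total(self) -> int:
        return sum(self.cells)

    @property
    def row_marginals(self) -> tuple[int, int]:
        a, b, c, d = self.cells
        return (a + b, c + d)

    @property
    def col_marginals(self) -> tuple[int, int]:
        a, b, c, d = self.cells
        return (a + c, b + d)

    def __str__(self) -> str:
        a, b, c, d = self.cells
        r1, r2 = self.row_marginals
        c1, c2 = self.col_marginals
        w = max(5, len(str(self.total)))
        return "\n".join([
            f"{'':>24}{'function':^{3 * w + 6}}",
            f"{'':>24}{'normal':>{w}}  {'abnormal':>{w + 3}}  {'Total':>{w}}",
            f"{'structure':<14}{'normal':>10}{a:>{w}}  {b:>{w + 3}}  {r1:>{w}}",
            f"{'':<14}{'abnormal':>10}{c:>{w}}  {d:>{w + 3}}  {r2:>{w}}",
            f"{'':<14}{'Total':>10}{c1:>{w}}  {c2:>{w + 3}}  {self.total:>{w}}",
        ])


def dichotomize(sms: float, dlco_pct: float, sms_threshold: float = -2.0,
                dlco_threshold: float = 80.0) -> tuple[str, str]:
    """(structure, function) labels; both comparisons are strict."""
    if sms is None or dlco_pct is None or \
            (isinstance(sms, float) and math.isnan(sms)) or \
            (isinstance(dlco_pct, float) and math.isnan(dlco_pct)):
        raise DegenerateInputError("dichotomize needs both SMS and D_LCO %pred")
    structure = "abnormal" if sms < sms_threshold else "normal"
    function = "abnormal" if dlco_pct < dlco_threshold else "normal"
    return structure, function


def confusion_from_pairs(sms: Sequence[float], dlco_pct: Sequence[float],
                         sms_threshold: float = -2.0,
                         dlco_threshold: float = 80.0,
                         ) -> tuple[ConfusionMatrix2x2, int]:
    """Build the confusion matrix, excluding (and counting) missing pairs."""
    cells = {"nn": 0, "na": 0, "an": 0, "aa": 0}
    excluded = 0
    for s, d in zip(sms, dlco_pct):
        try:
            structure, function = dichotomize(s, d, sms_threshold, dlco_threshold)
        except DegenerateInputError:
            excluded += 1
            continue
        cells[structure[0] + function[0]] += 1
    return ConfusionMatrix2x2(cells["nn"], cells["na"], cells["an"],
                              cells["aa"]), excluded


@dataclass
class KappaResult:
    kappa: float
    p_value: float
    se0: float
    n: int


def cohens_kappa(matrix: ConfusionMatrix2x2) -> KappaResult:
    """Cohen's kappa for a 2×2 table with a large-sample test of κ = 0.

    κ = (p_o − p_e)/(1 − p_e) with the usual marginal-product expected
    agreement; the null standard error is the Fleiss large-sample form and
    the p-value the two-sided normal tail of κ / SE₀.
    """
    n = matrix.total
    if n == 0:
        raise DegenerateInputError("empty confusion matrix")
    a, b, c, d = (v / n for v in matrix.cells)
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    p_o = a + d
    p_e = rows[0] * cols[0] + rows[1] * cols[1]
    if p_e == 1.0:
        raise DegenerateInputError(
            "all probability mass in one marginal cell; kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)
    se0 = math.sqrt(max(p_e + p_e ** 2
                        - sum(r * cc * (r + cc) for r, cc in zip(rows, cols)),
                        0.0)) / ((1.0 - p_e) * math.sqrt(n))
    if se0 == 0.0:
        p_value = float("nan")
    else:
        # two-sided normal tail, 2·Φ(−|z|) = erfc(|z|/√2)
        p_value = math.erfc(abs(kappa) / se0 / math.sqrt(2.0))
    return KappaResult(kappa=float(kappa), p_value=float(p_value),
                       se0=float(se0), n=n)


def spearman_and_r2(x: Sequence[float], y: Sequence[float],
                    ) -> tuple[float, float, float]:
    """Spearman rho (tie-corrected) with p-value, plus OLS R² of y on x."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise DegenerateInputError("need ≥ 3 paired observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateInputError("correlation undefined for constant input")
    rho, p = stats.spearmanr(xa, ya)
    r = stats.pearsonr(xa, ya).statistic
    return float(rho), float(p), float(r * r)


def pattern_frequencies(results: Iterable) -> pd.DataFrame:
    """Counts and proportions over the eight regional involvement patterns.

    Accepts SMSResults, regional-score mappings/triples or pattern names.
    Rows follow the fixed canonical order; proportions sum to 1.
    """
    counts = {name: 0 for name in PATTERN_ORDER}
    n = 0
    for item in results:
        if isinstance(item, str):
            name = item
        else:
            name = classify_pattern(item).name
        if name not in counts:
            raise DegenerateInputError(f"unknown pattern name {name!r}")
        counts[name] += 1
        n += 1
    if n == 0:
        raise DegenerateInputError("no results to tabulate")
    df = pd.DataFrame({
        "pattern": list(PATTERN_ORDER),
        "count": [counts[p] for p in PATTERN_ORDER],
    })
    df["proportion"] = df["count"] / n
    df["canonical"] = df["pattern"].isin(CANONICAL_PATTERNS)
    return df


@dataclass
class ValidationReport:
    """Aggregate validation of scored subjects against gas transfer."""

    confusion: ConfusionMatrix2x2
    kappa: KappaResult
    spearman_rho: float
    spearman_p: float
    r_squared: float
    pattern_table: Optional[pd.DataFrame] = None
    regional_kappa: dict = field(default_factory=dict)
    n_excluded_missing: int = 0
    thresholds: dict = field(default_factory=lambda: {"sms": -2.0, "dlco_pct": 80.0})

    def to_dict(self) -> dict:
        out = {
            "confusion": dict(zip(("both_normal", "struct_normal_func_abn",
                                   "struct_abn_func_normal", "both_abnormal"),
                                  self.confusion.cells)),
            "kappa": self.kappa.kappa, "kappa_p": self.kappa.p_value,
            "spearman_rho": self.spearman_rho, "spearman_p": self.spearman_p,
            "r_squared": self.r_squared,
            "regional_kappa": {r: k.kappa for r, k in self.regional_kappa.items()},
            "n_excluded_missing": self.n_excluded_missing,
            "thresholds": self.thresholds,
        }
        if self.pattern_table is not None:
            out["pattern_frequencies"] = dict(
                zip(self.pattern_table["pattern"], self.pattern_table["count"]))
        return out

    def __str__(self) -> str:
        parts = [str(self.confusion),
                 f"kappa = {self.kappa.kappa:.3f}, p = {self.kappa.p_value:.3g}",
                 f"Spearman rho = {self.spearman_rho:.3f} "
                 f"(p = {self.spearman_p:.3g}), R^2 = {self.r_squared:.3f}",
                 f"excluded for missing values: {self.n_excluded_missing}"]
        if self.regional_kappa:
            parts.append("regional kappa: " + ", ".join(
                f"{r} {k.kappa:.3f}" for r, k in self.regional_kappa.items()))
        return "\n".join(parts)


def plot_pattern_frequencies(table: pd.DataFrame, ax=None):
    """Bar plot of the eight regional patterns; canonical bars highlighted."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    colors = ["C2" if c else "C7" for c in table["canonical"]]
    ax.bar(table["pattern"], table["proportion"], color=colors)
    ax.set_ylabel("proportion of subjects")
    ax.tick_params(axis="x", rotation=45)
    for label in ax.get_xticklabels():
        label.set_horizontalalignment("right")
    return ax


def build_validation_report(results: Sequence[SMSResult],
                            dlco_pct: Sequence[float],
                            sms_threshold: float = -2.0,
                            dlco_threshold: float = 80.0) -> ValidationReport:
    """Validate a scored cohort against D_LCO %pred."""
    sms = [r.sms_global for r in results]
    confusion, excluded = confusion_from_pairs(
        sms, dlco_pct, sms_threshold, dlco_threshold)
    kappa = cohens_kappa(confusion)
    pairs = [(s, d) for s, d in zip(sms, dlco_pct)
             if d is not None and not math.isnan(d)]
    rho, p, r2 = spearman_and_r2([s for s, _ in pairs], [d for _, d in pairs])
    regional_kappa = {}
    regions_present = {r for res in results for r in res.sms_regional}
    for region in sorted(regions_present):
        reg_sms = [res.sms_regional[region] for res in results]
        m, _ = confusion_from_pairs(reg_sms, dlco_pct, sms_threshold,
                                    dlco_threshold)
        regional_kappa[region] = cohens_kappa(m)
    table = None
    if all(len(res.sms_regional) == 3 for res in results) and results:
        table = pattern_frequencies(results)
    return ValidationReport(
        confusion=confusion, kappa=kappa, spearman_rho=rho, spearman_p=p,
        r_squared=r2, pattern_table=table, regional_kappa=regional_kappa,
        n_excluded_missing=excluded,
        thresholds={"sms": sms_threshold, "dlco_pct": dlco_threshold},
    )
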