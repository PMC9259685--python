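"""Cohort-level statistics over per-sample carrier calls.

Implements the association arithmetic used to compare carrier frequencies
between case and control cohorts: carrier-exclusion (removing carriers of
one variant class from both cohorts before testing another), 2x2 odds
ratios with Wald confidence intervals (the cross-product ratio equals the
single-covariate logistic-regression MLE), prevalences, and two-sample
proportion tests (Fisher exact by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortTable",
    "OddsRatioResult",
    "exclude_carriers",
    "odds_ratio",
    "odds_ratio_from_counts",
    "prevalence",
    "format_prevalence",
    "proportion_test",
]

_REQUIRED = ("sample_id", "cohort")


class UndefinedOddsRatioError(ValueError):
    """A margin of the 2x2 table is structurally zero."""


@dataclass
class CohortTable:
    """One row per sample: cohort membership plus boolean carrier flags.

    ``data`` columns: sample_id, cohort in {case, control}, optional
    ancestry (verbatim), and any number of boolean flag columns
    (any_variant, severe, p.N409S, CNG, CNL, gbap1_like, ...).
    """

    data: pd.DataFrame
    exclusion_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in _REQUIRED:
            if col not in self.data.columns:
                raise ValueError(f"missing required column {col}")
        bad = set(self.data["cohort"]) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown cohort labels {sorted(bad)}")
        if self.data["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_ids")

    @property
    def flag_columns(self) -> list[str]:
        skip = set(_REQUIRED) | {"ancestry"}
        return [c for c in self.data.columns if c not in skip]

    def counts(self, flag: str) -> tuple[int, int, int, int]:
        """(a, b, c, d): case carriers, case non-carriers, control
        carriers, control non-carriers."""
        self._check_flag(flag)
        case = self.data[self.data["cohort"] == "case"]
        ctrl = self.data[self.data["cohort"] == "control"]
        a = int(case[flag].sum())
        c = int(ctrl[flag].sum())
        return a, len(case) - a, c, len(ctrl) - c

    def _check_flag(self, flag: str) -> None:
        if flag not in self.data.columns:
            raise KeyError(f"no flag column {flag}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortTable":
        df = pd.read_csv(path, sep="\t")
        for col in df.columns:
            if col not in _REQUIRED and col != "ancestry":
                df[col] = df[col].astype(bool)
        return cls(df)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_counts(
        cls,
        flag: str,
        case_carriers: int,
        case_total: int,
        control_carriers: int,
        control_total: int,
        extra_flags: dict[str, tuple[int, int]] | None = None,
    ) -> "CohortTable":
        """Build a synthetic per-sample table realizing the given counts.

        ``extra_flags`` may mark the FIRST k case / control samples with an
        additional flag, allowing published marginal counts (e.g. severe
        within non-p.N409S) to be reconstructed.
        """
        rows = []
        for cohort, carr, tot in (
            ("case", case_carriers, case_total),
            ("control", control_carriers, control_total),
        ):
            for i in range(tot):
                rows.append(
                    {
                        "sample_id": f"{cohort}_{i + 1}",
                        "cohort": cohort,
                        flag: i < carr,
                    }
                )
        df = pd.DataFrame(rows)
        if extra_flags:
            for name, (k_case, k_ctrl) in extra_flags.items():
                df[name] = False
                df.loc[df.index[df["cohort"] == "case"][:k_case], name] = True
                df.loc[df.index[df["cohort"] == "control"][:k_ctrl], name] = True
        return cls(df)


def exclude_carriers(table: CohortTable, variant_class: str) -> CohortTable:
    """Remove carriers of ``variant_class`` from both cohorts."""
    table._check_flag(variant_class)
    mask = table.data[variant_class].astype(bool)
    removed_case = int((mask & (table.data["cohort"] == "case")).sum())
    removed_ctrl = int((mask & (table.data["cohort"] == "control")).sum())
    out = CohortTable(
        table.data[~mask].reset_index(drop=True).copy(),
        exclusion_log=list(table.exclusion_log),
    )
    out.exclusion_log.append(
        f"excluded {variant_class}: {removed_case} case, {removed_ctrl} control"
    )
    if out.data.empty:
        out.exclusion_log.append("warning: all samples excluded")
    return out


@dataclass(frozen=True)
class OddsRatioResult:
    or_value: float
    ci_low: float
    ci_high: float
    counts: tuple[int, int, int, int]  # a, b, c, d
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        if self.or_value <= 0:
            raise ValueError("odds ratio must be positive")
        if not self.ci_low <= self.or_value <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")


def odds_ratio_from_counts(
    a: int, b: int, c: int, d: int
) -> OddsRatioResult:
    """Cross-product odds ratio (a*d)/(b*c) with a 95% Wald interval.

    Equals the single-covariate logistic-regression MLE.  Zero cells get
    the Haldane-Anscombe 0.5 correction (flagged); a structurally zero
    margin (an empty row or column) leaves the OR undefined.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be >= 0")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise UndefinedOddsRatioError("a margin of the 2x2 table is zero")
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if corrected else (a, b, c, d)
    )
    or_value = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    return OddsRatioResult(
        or_value=or_value,
        ci_low=or_value * math.exp(-1.959963984540054 * se),
        ci_high=or_value * math.exp(1.959963984540054 * se),
        counts=(a, b, c, d),
        continuity_corrected=corrected,
    )


def odds_ratio(table: CohortTable, exposure_flag: str) -> OddsRatioResult:
    return odds_ratio_from_counts(*table.counts(exposure_flag))


def prevalence(table: CohortTable, flag: str, cohort: str) -> float:
    """Percent carriers of ``flag`` within one cohort stratum."""
    table._check_flag(flag)
    sub = table.data[table.data["cohort"] == cohort]
    if sub.empty:
        raise ValueError(f"empty stratum {cohort}")
    return 100.0 * float(sub[flag].sum()) / len(sub)


def format_prevalence(pct: float) -> str:
    """1 d.p., or 2 d.p. below 1%."""
    return f"{pct:.2f}" if pct < 1.0 else f"{pct:.1f}"


def proportion_test(
    a: int, n1: int, b: int, n2: int, method: str = "fisher"
) -> float:
    """Two-sided p-value comparing a/n1 vs b/n2 carriers.

    ``method``: "fisher" (exact, default) or "chi2".
    """
    if not (0 <= a <= n1 and 0 <= b <= n2) or n1 == 0 or n2 == 0:
        raise ValueError("invalid counts")
    table = np.array([[a, n1 - a], [b, n2 - b]])
    if method == "fisher":
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if method == "chi2":
        return float(stats.chi2_contingency(table, correction=True)[1])
    raise ValueError(f"unknown method {method}")
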