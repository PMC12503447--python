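"""Descriptive layer: frequency/mortality, co-occurrence, phi, collinearity.

These are the cohort-level summaries a registry analysis reports before any
network modelling: how common each complication is and how lethal, how often
complications cluster in the same patient, the phi coefficient (Pearson
correlation of two binary indicators, computed from the 2x2 contingency
table) between every pair, and an eigenvalue-based multicollinearity
diagnostic of the full correlation matrix.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._util import round_half_up
from .cohort import CohortMatrix
from .errors import ValidationError

__all__ = [
    "MarginalSummary",
    "CooccurrenceSummary",
    "PhiMatrix",
    "CollinearityReport",
    "marginal_summary",
    "cooccurrence_summary",
    "phi_matrix",
    "collinearity_report",
]

#: Condition number above which multicollinearity is conventionally "severe".
SEVERE_CONDITION_NUMBER = 30.0


@dataclass(frozen=True)
class MarginalSummary:
    """Per-complication carrier counts and mortality.

    ``pct_with`` and ``pct_death`` are kept at full precision; display
    rounding (half-up, one decimal) happens in :meth:`to_frame`.
    ``pct_death`` is ``nan`` (an explicit "undefined" sentinel) for
    complications with zero carriers — never a division by zero.
    """

    variables: tuple[str, ...]
    count_with: tuple[int, ...]
    pct_with: tuple[float, ...]
    deaths_after: tuple[int, ...]
    pct_death: tuple[float, ...]
    denominator: int
    denominator_mode: str

    def row(self, variable: str) -> dict[str, float]:
        i = self.variables.index(variable)
        return {
            "count_with": self.count_with[i],
            "pct_with": self.pct_with[i],
            "deaths_after": self.deaths_after[i],
            "pct_death": self.pct_death[i],
        }

    def to_frame(self, display: bool = False) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "variable": self.variables,
                "count_with": self.count_with,
                "pct_with": self.pct_with,
                "deaths_after": self.deaths_after,
                "pct_death": self.pct_death,
            }
        )
        if display:
            for col in ("pct_with", "pct_death"):
                frame[col] = frame[col].map(lambda x: round_half_up(x, 1))
        return frame

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame(display=True).to_csv(path, sep="\t", index=False)
        return path


@dataclass(frozen=True)
class CooccurrenceSummary:
    """Complication-multiplicity histogram and per-variable co-occurrence.

    ``multiplicity_counts[k]`` is the number of patients with exactly k
    complications (k >= 1; outcome excluded); their sum equals the number
    of patients with at least one complication. ``cooccur_rate[v]`` is the
    fraction of carriers of v who have at least one other complication
    (``nan`` when v has no carriers). ``pattern_counts`` counts each exact
    complication set, including the empty set, and sums to N.
    """

    multiplicity_counts: Mapping[int, int]
    cooccur_rate: Mapping[str, float]
    pattern_counts: Mapping[tuple[str, ...], int]
    n_patients: int

    @property
    def n_with_any(self) -> int:
        return sum(self.multiplicity_counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.multiplicity_counts.items()),
            columns=["n_complications", "n_patients"],
        )

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write("# multiplicity histogram\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)
            fh.write("# co-occurrence rate per complication\n")
            for name, rate in self.cooccur_rate.items():
                fh.write(f"{name}\t{'' if np.isnan(rate) else rate}\n")
        return path


@dataclass(frozen=True)
class PhiMatrix:
    """Symmetric V x V matrix of phi coefficients with unit diagonal.

    Pairs involving a zero-variance column are undefined: the cell holds
    ``nan`` and ``defined`` is False there. ``n_undefined_pairs`` counts
    such off-diagonal pairs (each counted once).
    """

    names: tuple[str, ...]
    values: np.ndarray
    defined: np.ndarray
    n_used: int

    @property
    def n_undefined_pairs(self) -> int:
        off = ~self.defined
        return int(np.triu(off, k=1).sum())

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.names.index(a), self.names.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.names), columns=list(self.names))

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index_label="variable")
        return path


@dataclass(frozen=True)
class CollinearityReport:
    """Eigenvalue diagnostic of the Pearson correlation matrix.

    ``condition_number`` is sqrt(lambda_max / lambda_min) by default (the
    convention under which > 30 signals severe multicollinearity); the
    plain eigenvalue ratio is available via ``mode='ratio'``. A singular
    correlation matrix yields an infinite condition number with
    ``flag_severe`` set. Zero-variance columns are excluded and listed.
    """

    names: tuple[str, ...]
    correlation_matrix: np.ndarray
    eigenvalues: tuple[float, ...]
    condition_number: float
    flag_severe: bool
    mode: str
    excluded: tuple[str, ...] = ()

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"condition_number\t{self.condition_number}\n")
            fh.write(f"mode\t{self.mode}\n")
            fh.write(f"flag_severe\t{self.flag_severe}\n")
            fh.write("eigenvalues\t" + "\t".join(f"{e:.10g}" for e in self.eigenvalues) + "\n")
            if self.excluded:
                fh.write("excluded_zero_variance\t" + "\t".join(self.excluded) + "\n")
            pd.DataFrame(
                self.correlation_matrix, index=list(self.names), columns=list(self.names)
            ).to_csv(fh, sep="\t", index_label="variable")
        return path


def marginal_summary(
    cohort: CohortMatrix, denominator: str = "with_complication"
) -> MarginalSummary:
    """Carrier count, frequency and mortality for each complication.

    ``denominator`` chooses the base for ``pct_with``: the number of
    patients with at least one complication (the default, matching
    frequency tables reported on the complication cohort) or all patients.
    Mortality percentages are always among carriers.
    """
    if denominator not in ("with_complication", "all"):
        raise ValidationError(
            f"denominator must be 'with_complication' or 'all', got {denominator!r}"
        )
    comp = cohort.complication_columns()
    death = cohort.column(cohort.catalog.outcome)
    if denominator == "with_complication":
        denom = int((comp.sum(axis=1) >= 1).sum())
        if denom == 0:
            raise ValidationError("no patients with complications in cohort")
    else:
        denom = cohort.n_patients

    names = cohort.catalog.complications
    counts, pct_with, deaths, pct_death = [], [], [], []
    for j, name in enumerate(names):
        col = comp[:, j]
        c = int(col.sum())
        d = int((col & death).sum())
        counts.append(c)
        deaths.append(d)
        pct_with.append(100.0 * c / denom)
        pct_death.append(100.0 * d / c if c > 0 else float("nan"))
    return MarginalSummary(
        variables=names,
        count_with=tuple(counts),
        pct_with=tuple(pct_with),
        deaths_after=tuple(deaths),
        pct_death=tuple(pct_death),
        denominator=denom,
        denominator_mode=denominator,
    )


def cooccurrence_summary(cohort: CohortMatrix) -> CooccurrenceSummary:
    """Multiplicity histogram, co-occurrence rates and pattern counts."""
    comp = cohort.complication_columns()
    names = cohort.catalog.complications
    row_sums = comp.sum(axis=1)
    multiplicity = {
        int(k): int((row_sums == k).sum())
        for k in np.unique(row_sums)
        if k >= 1
    }
    rates: dict[str, float] = {}
    for j, name in enumerate(names):
        carriers = comp[:, j] == 1
        n_c = int(carriers.sum())
        rates[name] = float((row_sums[carriers] >= 2).mean()) if n_c else float("nan")
    patterns = Counter(
        tuple(n for n, v in zip(names, row) if v) for row in comp
    )
    return CooccurrenceSummary(
        multiplicity_counts=multiplicity,
        cooccur_rate=rates,
        pattern_counts=dict(patterns),
        n_patients=cohort.n_patients,
    )


def phi_matrix(cohort: CohortMatrix) -> PhiMatrix:
    """Phi coefficient between every pair of catalog variables.

    phi(X, Y) = (n11 n00 - n10 n01) / sqrt(n1. n0. n.1 n.0) from the 2x2
    table — algebraically the Pearson correlation of the two 0/1 columns.
    Computed from contingency counts, not a correlation routine, so the
    equivalence can serve as an independent check.
    """
    x = cohort.values.astype(np.int64)
    n = x.shape[0]
    s = x.sum(axis=0)                      # per-column count of ones
    n11 = x.T @ x                          # pairwise co-occurrence counts
    num = n * n11 - np.outer(s, s)
    var_term = s * (n - s)
    denom = np.sqrt(np.outer(var_term, var_term).astype(float))
    degenerate = var_term == 0
    defined = ~(degenerate[:, None] | degenerate[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(defined, num / np.where(denom == 0, np.nan, denom), np.nan)
    np.fill_diagonal(values, 1.0)
    np.fill_diagonal(defined, True)
    return PhiMatrix(
        names=cohort.catalog.names,
        values=values,
        defined=defined,
        n_used=n,
    )


def collinearity_report(
    cohort: CohortMatrix, mode: str = "sqrt_ratio"
) -> CollinearityReport:
    """Eigenvalue analysis of the Pearson correlation matrix.

    ``mode='sqrt_ratio'`` (default) reports sqrt(lambda_max / lambda_min);
    ``mode='ratio'`` reports the raw eigenvalue ratio. Values above 30 are
    flagged severe.
    """
    if mode not in ("sqrt_ratio", "ratio"):
        raise ValidationError(f"mode must be 'sqrt_ratio' or 'ratio', got {mode!r}")
    x = cohort.values.astype(float)
    variances = x.var(axis=0)
    keep = variances > 0
    if int(keep.sum()) < 2:
        raise ValidationError("need at least 2 columns with nonzero variance")
    names = tuple(n for n, k in zip(cohort.catalog.names, keep) if k)
    excluded = tuple(n for n, k in zip(cohort.catalog.names, keep) if not k)
    corr = np.corrcoef(x[:, keep], rowvar=False)
    eig = np.linalg.eigvalsh(corr)
    eig = np.clip(eig, 0.0, None)[::-1]  # descending, PSD up to rounding
    lam_max, lam_min = float(eig[0]), float(eig[-1])
    if lam_min <= 1e-12:
        cond = float("inf")
    else:
        ratio = lam_max / lam_min
        cond = float(np.sqrt(ratio)) if mode == "sqrt_ratio" else float(ratio)
    return CollinearityReport(
        names=names,
        correlation_matrix=corr,
        eigenvalues=tuple(float(e) for e in eig),
        condition_number=cond,
        flag_severe=bool(cond > SEVERE_CONDITION_NUMBER),
        mode=mode,
        excluded=excluded,
    )
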