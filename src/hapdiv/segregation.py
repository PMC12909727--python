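"""Chi-square goodness-of-fit tests for Mendelian segregation in F2 populations.

A cross between a functional and a loss-of-function line yields an F2
expected to segregate 1:2:1 in genotype and — with a dominant functional
allele — 3:1 in phenotype.  The test is the classical uncorrected Pearson
chi-square; Yates' continuity correction is available behind a flag but off
by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy.special import gammaincc


@dataclass(frozen=True)
class SegregationResult:
    observed: tuple[int, ...]
    expected_ratio: tuple[float, ...]
    expected: tuple[float, ...]
    chi2: float
    df: int
    p_value: float

    def summary(self) -> str:
        obs = ":".join(str(o) for o in self.observed)
        ratio = ":".join(f"{r:g}" for r in self.expected_ratio)
        return (
            f"observed {obs} vs expected {ratio} — "
            f"chi2 = {self.chi2:.4g}, df = {self.df}, p = {self.p_value:.3f}"
        )

    def to_row(self) -> dict:
        return {
            "observed": ",".join(map(str, self.observed)),
            "ratio": ",".join(f"{r:g}" for r in self.expected_ratio),
            "expected": ",".join(f"{e:.4g}" for e in self.expected),
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p_value,
        }


def chi_square_pvalue(chi2: float, df: int) -> float:
    """Upper-tail chi-square probability via the regularized incomplete gamma.

    P(X >= chi2) = Q(df/2, chi2/2); accurate well beyond 6 significant digits.
    """
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(gammaincc(df / 2.0, chi2 / 2.0))


def chi_square_gof(
    observed: Sequence[int],
    expected_ratio: Sequence[float],
    yates: bool = False,
) -> SegregationResult:
    """Goodness of fit of observed class counts to an expected ratio.

    expected_i = N * w_i / sum(w); chi2 = sum (obs - exp)^2 / exp; df = k - 1.
    With ``yates`` the |obs - exp| terms are reduced by 0.5 (continuity
    correction) — off by default, matching the plain Pearson statistic.
    """
    obs = tuple(int(o) for o in observed)
    ratio = tuple(float(w) for w in expected_ratio)
    if len(obs) != len(ratio):
        raise ValueError("observed and expected_ratio length mismatch")
    if len(obs) < 2:
        raise ValueError("need >= 2 classes")
    if any(o < 0 for o in obs):
        raise ValueError("counts must be non-negative")
    total = sum(obs)
    if total <= 0:
        raise ValueError("total observed count must be positive")
    if any(w <= 0 for w in ratio):
        raise ValueError("expected ratio weights must be positive")
    wsum = sum(ratio)
    expected = tuple(total * w / wsum for w in ratio)
    chi2 = 0.0
    for o, e in zip(obs, expected):
        dev = abs(o - e)
        if yates:
            dev = max(dev - 0.5, 0.0)
        chi2 += dev * dev / e
    df = len(obs) - 1
    return SegregationResult(
        observed=obs,
        expected_ratio=ratio,
        expected=expected,
        chi2=chi2,
        df=df,
        p_value=chi_square_pvalue(chi2, df),
    )


def phenotype_from_genotype(genotype: str, dominant: bool = True) -> str:
    """Phenol phenotype under complete dominance of the functional allele.

    Carriers of at least one functional (non-deletion) allele — 'AA' or
    'Aa' — are positive; only the deletion homozygote 'aa' is negative.
    """
    if genotype not in {"AA", "Aa", "aa"}:
        raise ValueError(f"unknown genotype {genotype!r}")
    if not dominant:
        return "positive" if genotype == "AA" else "negative"
    return "negative" if genotype == "aa" else "positive"
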