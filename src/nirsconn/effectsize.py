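"""Closed-form effect-size conversions for behavioural statistics.

Utilities relating Cohen's f, partial eta squared and Kendall's W to
the test statistics they are reported with:

* eta_p^2 = f^2 / (1 + f^2)            (Cohen's f <-> partial eta squared)
* eta_p^2 = F df1 / (F df1 + df2)      (from an ANOVA F statistic)
* W = chi^2 / (n (k - 1))              (from a Friedman chi-square)
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError


@dataclass
class EffectSizeResult:
    value: float
    kind: str
    inputs: dict


def f_to_eta2p(f: float) -> float:
    """Partial eta squared from Cohen's f: f^2 / (1 + f^2)."""
    if f < 0:
        raise ParameterError("Cohen's f must be non-negative")
    return f * f / (1.0 + f * f)


def eta2p_to_f(eta2p: float) -> float:
    """Cohen's f from partial eta squared: sqrt(eta / (1 - eta))."""
    if not 0.0 <= eta2p < 1.0:
        raise ParameterError("partial eta squared must lie in [0, 1)")
    return (eta2p / (1.0 - eta2p)) ** 0.5


def eta2p_from_F(F: float, df1: int, df2: int) -> float:
    """Partial eta squared from an F statistic: F df1 / (F df1 + df2)."""
    if F < 0:
        raise ParameterError("F must be non-negative")
    if df1 < 1 or df2 < 1:
        raise ParameterError("degrees of freedom must be >= 1")
    return F * df1 / (F * df1 + df2)


def kendalls_w(chi2: float, n: int, k: int) -> float:
    """Kendall's W from a Friedman chi-square: chi^2 / (n (k - 1)), capped at 1."""
    if n < 2 or k < 2:
        raise ParameterError("need n >= 2 subjects and k >= 2 conditions")
    if chi2 < 0:
        raise ParameterError("chi-square must be non-negative")
    return min(chi2 / (n * (k - 1)), 1.0)


def as_result(kind: str, value: float, **inputs) -> EffectSizeResult:
    """Wrap a computed effect size with its inputs for reporting."""
    if kind not in {"cohens_f", "partial_eta_squared", "kendalls_w"}:
        raise ParameterError(f"unknown effect-size kind {kind!r}")
    return EffectSizeResult(value=value, kind=kind, inputs=inputs)
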