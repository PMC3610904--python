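"""Single-hit Poisson limiting-dilution analysis (LDA).

In a limiting-dilution transplant, graded doses of ``d`` bone-marrow cells are
injected into cohorts of recipients and each animal is scored engrafted when
its multilineage blood chimerism exceeds a threshold (0.1% by convention,
strict inequality). Under the single-hit Poisson model the number of
repopulating units an animal receives is Poisson(f*d), where ``f`` is the
frequency of repopulating units per transplanted cell, so

    P(no engraftment at dose d) = exp(-f * d).

The log-likelihood over dose groups is maximized in one dimension to estimate
``f``; its reciprocal 1/f is the familiar "one repopulating unit per X cells".
The non-responder curve plots ln(fraction negative) against dose, which the
model predicts to be the line -f*d through the origin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2, norm

log = logging.getLogger(__name__)

__all__ = [
    "DoseGroup", "LDAFit", "CurvePoint",
    "binarize_engraftment", "single_hit_loglik", "fit_frequency",
    "nonresponder_points", "read_dose_table",
]

DEFAULT_THRESHOLD = 0.1  # percent multilineage chimerism; positivity is strict ">"


@dataclass(frozen=True)
class DoseGroup:
    """One dilution group: dose per recipient, recipients tested / engrafted."""

    dose: float
    n_tested: int
    n_engrafted: int

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("dose must be > 0")
        if self.n_tested < 0 or not (0 <= self.n_engrafted <= self.n_tested):
            raise ValueError("need 0 <= n_engrafted <= n_tested")

    @property
    def n_negative(self) -> int:
        return self.n_tested - self.n_engrafted


@dataclass(frozen=True)
class LDAFit:
    """Fitted repopulating-unit frequency with CI and boundary diagnostics."""

    frequency: float            # repopulating units per transplanted cell
    ci_low: float
    ci_high: float
    loglik: float
    boundary_flag: str = "none"  # none | zero | infinite
    ci_method: str = "wald"

    @property
    def reciprocal(self) -> float:
        """Cells per repopulating unit (1/f)."""
        if self.frequency == 0.0:
            return math.inf
        return 1.0 / self.frequency

    def to_dict(self) -> dict:
        return {
            "frequency": self.frequency,
            "reciprocal": self.reciprocal,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "reciprocal_ci_low": (math.inf if self.ci_high == 0
                                  else 1.0 / self.ci_high),
            "reciprocal_ci_high": (math.inf if self.ci_low == 0
                                   else 1.0 / self.ci_low),
            "loglik": self.loglik,
            "boundary_flag": self.boundary_flag,
            "ci_method": self.ci_method,
        }


@dataclass(frozen=True)
class CurvePoint:
    """One non-responder curve point: (dose, ln fraction negative)."""

    dose: float
    log_fraction_negative: float | None
    excluded: bool = False   # all animals engrafted: ln(0) undefined


def binarize_engraftment(chimerism_rows: Iterable[tuple[float, float]],
                         threshold: float = DEFAULT_THRESHOLD) -> list[DoseGroup]:
    """Score per-animal chimerism into dose groups.

    An animal is positive iff its percent multilineage chimerism is strictly
    greater than ``threshold`` (default 0.1%); a reading exactly at the
    threshold is negative. Rows are aggregated by dose, ascending.
    """
    per_dose: dict[float, list[int]] = {}
    for dose, chimerism in chimerism_rows:
        if chimerism < 0:
            raise ValueError(f"negative chimerism {chimerism!r} at dose {dose}")
        tested_engrafted = per_dose.setdefault(float(dose), [0, 0])
        tested_engrafted[0] += 1
        if chimerism > threshold:
            tested_engrafted[1] += 1
    return [DoseGroup(dose=d, n_tested=t, n_engrafted=e)
            for d, (t, e) in sorted(per_dose.items())]


def single_hit_loglik(f: float, groups: Sequence[DoseGroup]) -> float:
    """Log-likelihood of frequency ``f`` under the single-hit Poisson model.

    Sum over groups of ``neg * (-f d) + pos * log(1 - exp(-f d))``; -inf when
    a positive animal is asserted at f = 0 (or any term hits log 0).
    """
    if f < 0:
        raise ValueError("frequency must be >= 0")
    total = 0.0
    for g in groups:
        fd = f * g.dose
        total += g.n_negative * (-fd)
        if g.n_engrafted:
            p_pos = -math.expm1(-fd)  # 1 - exp(-f d), stable near 0
            if p_pos <= 0.0:
                return -math.inf
            total += g.n_engrafted * math.log(p_pos)
    return total


def _score(f: float, groups: Sequence[DoseGroup]) -> float:
    """d loglik / d f."""
    total = 0.0
    for g in groups:
        fd = f * g.dose
        total -= g.n_negative * g.dose
        if g.n_engrafted:
            e = math.exp(-fd)
            total += g.n_engrafted * g.dose * e / (1.0 - e)
    return total


def _d2loglik(f: float, groups: Sequence[DoseGroup]) -> float:
    total = 0.0
    for g in groups:
        if g.n_engrafted:
            e = math.exp(-f * g.dose)
            total -= g.n_engrafted * g.dose ** 2 * e / (1.0 - e) ** 2
    return total


def fit_frequency(groups: Sequence[DoseGroup], alpha: float = 0.05,
                  ci_method: str = "wald") -> LDAFit:
    """Maximum-likelihood fit of the repopulating-unit frequency.

    The score equation is solved by bracketed root finding (the likelihood is
    strictly concave whenever the data contain both a positive and a negative
    animal, so the root is unique). The default 95% CI is Wald on log f via
    the observed information; ``ci_method='profile'`` inverts the likelihood
    ratio instead, which behaves better near the boundary.
    """
    groups = list(groups)
    if not groups or sum(g.n_tested for g in groups) == 0:
        raise ValueError("need at least one tested animal")
    pos = sum(g.n_engrafted for g in groups)
    neg = sum(g.n_negative for g in groups)
    if pos == 0:
        return LDAFit(frequency=0.0, ci_low=0.0, ci_high=math.nan,
                      loglik=0.0, boundary_flag="zero", ci_method=ci_method)
    if neg == 0:
        return LDAFit(frequency=math.inf, ci_low=math.nan, ci_high=math.inf,
                      loglik=0.0, boundary_flag="infinite", ci_method=ci_method)

    # bracket the score root around a method-of-moments start
    f0 = pos / sum(g.dose * g.n_tested for g in groups)
    lo, hi = f0, f0
    while _score(lo, groups) <= 0:
        lo /= 8.0
    while _score(hi, groups) >= 0:
        hi *= 8.0
    f_hat = brentq(_score, lo, hi, args=(groups,), xtol=1e-300, rtol=1e-14)
    ll = single_hit_loglik(f_hat, groups)

    zq = norm.ppf(1 - alpha / 2)
    if ci_method == "wald":
        # observed information on the log-f scale; score term vanishes at MLE
        info = -(f_hat ** 2) * _d2loglik(f_hat, groups)
        se = 1.0 / math.sqrt(info)
        ci_low = f_hat * math.exp(-zq * se)
        ci_high = f_hat * math.exp(zq * se)
    elif ci_method == "profile":
        target = ll - chi2.ppf(1 - alpha, df=1) / 2.0
        drop = lambda f: single_hit_loglik(f, groups) - target
        lo_b = f_hat
        while drop(lo_b) > 0 and lo_b > 1e-300:
            lo_b /= 8.0
        ci_low = brentq(drop, lo_b, f_hat, rtol=1e-12) if drop(lo_b) <= 0 else 0.0
        hi_b = f_hat
        while drop(hi_b) > 0:
            hi_b *= 8.0
        ci_high = brentq(drop, f_hat, hi_b, rtol=1e-12)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return LDAFit(frequency=f_hat, ci_low=ci_low, ci_high=ci_high,
                  loglik=ll, boundary_flag="none", ci_method=ci_method)


def nonresponder_points(groups: Sequence[DoseGroup]) -> list[CurvePoint]:
    """Non-responder curve: (dose, ln(fraction negative)) per group.

    A group with every animal engrafted has ln(0) and is returned flagged
    ``excluded``; under the fitted model the finite points lie on -f*d.
    """
    points = []
    for g in groups:
        if g.n_tested < 1:
            raise ValueError("each dose group needs n_tested >= 1")
        if g.n_negative == 0:
            points.append(CurvePoint(dose=g.dose, log_fraction_negative=None,
                                     excluded=True))
        else:
            points.append(CurvePoint(
                dose=g.dose,
                log_fraction_negative=math.log(g.n_negative / g.n_tested)))
    return points


def read_dose_table(path, threshold: float = DEFAULT_THRESHOLD) -> list[DoseGroup]:
    """Read a dose table TSV, auto-detecting its flavor by header.

    Either aggregated counts (``dose``, ``n_tested``, ``n_engrafted``) or
    per-animal chimerism (``dose``, ``chimerism_percent`` or ``chimerism``),
    which is binarized at ``threshold``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = set(df.columns)
    if {"dose", "n_tested", "n_engrafted"} <= cols:
        return [DoseGroup(dose=float(r.dose), n_tested=int(r.n_tested),
                          n_engrafted=int(r.n_engrafted))
                for r in df.sort_values("dose").itertuples()]
    chim_col = next((c for c in ("chimerism_percent", "chimerism") if c in cols),
                    None)
    if "dose" in cols and chim_col:
        rows = list(zip(df["dose"].astype(float), df[chim_col].astype(float)))
        return binarize_engraftment(rows, threshold=threshold)
    raise ValueError("dose table must have columns (dose, n_tested, n_engrafted)"
                     " or (dose, chimerism_percent)")
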