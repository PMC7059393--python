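"""Single-hit Poisson statistics for limiting-dilution assays.

A well seeded at nominal dose ``d`` cells receives a Poisson-distributed
number of clonogenic cells with mean ``f*d``, where ``f`` is the frequency
of colony-forming cells (CFU-f).  Under the single-hit model a well is
negative iff it received none: ``P(neg) = exp(-f*d)``.  The frequency is
estimated by maximum likelihood over all dilution steps, with a profile
likelihood 95% confidence interval.  The monoclonality probability of a
positive well is the zero-truncated Poisson mass at one,
``P(k=1 | k>=1) = f*d*exp(-f*d) / (1 - exp(-f*d))``, which motivates the
"probably single-cell derived" filter (p > 0.5) applied before scoring
differentiation of individual colonies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

CHI2_1_95 = 3.841458820694124  # chi-square(1) 0.95 quantile


@dataclass(frozen=True)
class DilutionGroup:
    dose: float
    wells_tested: int
    wells_positive: int

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if not 0 <= self.wells_positive <= self.wells_tested:
            raise ValueError("wells_positive must be in [0, wells_tested]")


@dataclass
class DilutionDesign:
    groups: list[DilutionGroup]

    def __post_init__(self) -> None:
        doses = [g.dose for g in self.groups]
        if len(set(doses)) != len(doses):
            raise ValueError("doses must be distinct")
        if not self.groups:
            raise ValueError("design needs at least one group")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DilutionDesign":
        return cls([DilutionGroup(float(r.dose), int(r.wells_tested),
                                  int(r.wells_positive))
                    for r in df.itertuples()])

    @classmethod
    def from_counts(cls, doses: Sequence[float], tested: Sequence[int],
                    positive: Sequence[int]) -> "DilutionDesign":
        return cls([DilutionGroup(d, t, p)
                    for d, t, p in zip(doses, tested, positive)])


@dataclass
class FrequencyEstimate:
    f_hat: float
    ci_low: float
    ci_high: float
    log_likelihood: float
    converged: bool = True

    def to_json(self) -> str:
        return json.dumps({
            "f_hat": self.f_hat, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "log_likelihood": self.log_likelihood, "converged": self.converged,
        }, indent=2)


@dataclass
class MonoclonalityResult:
    dose: float
    p_single: float
    passes_filter: bool


def log_likelihood(f: float, design: DilutionDesign) -> float:
    """Binomial log likelihood of the design at frequency ``f`` (constants
    dropped)."""
    ll = 0.0
    for g in design.groups:
        neg = g.wells_tested - g.wells_positive
        lam = f * g.dose
        ll += -neg * lam
        if g.wells_positive:
            if lam <= 0:
                return -math.inf
            ll += g.wells_positive * math.log(-math.expm1(-lam))
    return ll


def _score(f: float, design: DilutionDesign) -> float:
    """d/df of the log likelihood; strictly decreasing (concave likelihood)."""
    s = 0.0
    for g in design.groups:
        neg = g.wells_tested - g.wells_positive
        lam = f * g.dose
        s += -neg * g.dose
        if g.wells_positive:
            s += g.wells_positive * g.dose * math.exp(-lam) / (-math.expm1(-lam))
    return s


def fit_frequency(design: DilutionDesign, f_max: float = 1.0,
                  conf_chi2: float = CHI2_1_95) -> FrequencyEstimate:
    """Maximum-likelihood CFU-f frequency with profile-likelihood 95% CI.

    The single-hit log likelihood is concave in ``f``, so the MLE is the
    root of the score function (found to near machine precision, matching
    the single-group closed form ``-ln(neg/tested)/d``).  The CI is
    ``{f : 2*(l(f_hat) - l(f)) <= 3.841}``.

    Degenerate designs: all wells negative gives ``f_hat = 0`` with a
    one-sided upper bound; all wells positive gives a boundary estimate at
    ``f_max`` flagged ``converged=False``.
    """
    total_pos = sum(g.wells_positive for g in design.groups)
    total_neg = sum(g.wells_tested - g.wells_positive for g in design.groups)

    if total_pos == 0:
        # l(f) = -f * sum(neg_g * d_g); one-sided upper bound from the profile
        slope = sum(g.wells_tested * g.dose for g in design.groups)
        upper = min(conf_chi2 / 2.0 / slope, f_max)
        return FrequencyEstimate(0.0, 0.0, upper, 0.0, True)

    lo, hi = 1e-12, f_max
    if total_neg == 0 or _score(hi, design) >= 0:
        # likelihood still increasing at the boundary
        ll = log_likelihood(f_max, design)
        ci_low = _profile_bound(design, f_max, ll, conf_chi2, side="low", lo=lo)
        return FrequencyEstimate(f_max, ci_low, f_max, ll, False)

    f_hat = brentq(_score, lo, hi, args=(design,), xtol=1e-14, rtol=1e-15)
    ll_hat = log_likelihood(f_hat, design)
    ci_low = _profile_bound(design, f_hat, ll_hat, conf_chi2, side="low", lo=0.0)
    ci_high = _profile_bound(design, f_hat, ll_hat, conf_chi2, side="high", hi=f_max)
    return FrequencyEstimate(f_hat, ci_low, ci_high, ll_hat, True)


def _profile_bound(design: DilutionDesign, f_hat: float, ll_hat: float,
                   conf_chi2: float, side: str, lo: float = 0.0,
                   hi: float = 1.0) -> float:
    def g(f: float) -> float:
        return 2.0 * (ll_hat - log_likelihood(f, design)) - conf_chi2

    if side == "low":
        a = max(lo, 1e-300)
        if g(a) <= 0:  # the whole lower range is inside the interval
            return lo
        return brentq(g, a, f_hat, xtol=1e-12)
    else:
        if g(hi) <= 0:
            return hi
        return brentq(g, f_hat, hi, xtol=1e-12)


def single_dose_mle(tested: int, positive: int, dose: float) -> float:
    """Closed-form single-group MLE ``-ln(neg/tested)/dose``."""
    neg = tested - positive
    if neg == 0:
        raise ValueError("no negative wells: MLE at boundary")
    return -math.log(neg / tested) / dose


def monoclonality_probability(f: float, dose: float) -> float:
    """P(exactly one clonogenic cell | well positive) = zero-truncated
    Poisson mass at k=1, ``lam*exp(-lam)/(1-exp(-lam))`` with ``lam=f*dose``.

    Returns the limit value 1.0 at ``lam = 0``.
    """
    lam = f * dose
    if lam < 0:
        raise ValueError("f*dose must be non-negative")
    if lam == 0.0:
        return 1.0
    return lam * math.exp(-lam) / (-math.expm1(-lam))


def select_monoclonal_doses(estimate: FrequencyEstimate, doses: Sequence[float],
                            threshold: float = 0.5) -> list[MonoclonalityResult]:
    """Per-dose monoclonality probability at the fitted frequency; a dose
    passes the filter iff p_single strictly exceeds the threshold."""
    out = []
    for d in doses:
        p = monoclonality_probability(estimate.f_hat, d)
        out.append(MonoclonalityResult(d, p, p > threshold))
    return out


ADIPO_THRESHOLD = 0.10   # fraction of cells with fat droplets, strict >
OSTEO_THRESHOLD = 0.4    # background-normalized Alizarin Red absorbance, strict >


@dataclass
class WellPhenotype:
    well_id: str
    dose: Optional[float] = None
    adipo_fraction: Optional[float] = None
    osteo_absorbance: Optional[float] = None
    adipo_positive: Optional[bool] = None
    osteo_positive: Optional[bool] = None


def score_well(well_id: str, adipo_fraction: Optional[float] = None,
               osteo_absorbance: Optional[float] = None,
               dose: Optional[float] = None) -> WellPhenotype:
    """Apply the differentiation positivity thresholds to one well.

    Adipogenic: > 10% of cells with fat droplets.  Osteogenic: background-
    normalized absorbance > 0.4.  Both thresholds are strict, so boundary
    values score negative.  An absent measurement leaves its flag unset;
    at least one measurement is required.
    """
    if adipo_fraction is None and osteo_absorbance is None:
        raise ValueError(f"well {well_id}: no measurement to score")
    w = WellPhenotype(well_id, dose, adipo_fraction, osteo_absorbance)
    if adipo_fraction is not None:
        if not 0 <= adipo_fraction <= 1:
            raise ValueError("adipo_fraction must be in [0, 1]")
        w.adipo_positive = adipo_fraction > ADIPO_THRESHOLD
    if osteo_absorbance is not None:
        w.osteo_positive = osteo_absorbance > OSTEO_THRESHOLD
    return w


def summarize_clonal_potential(wells: Sequence[WellPhenotype],
                               monoclonal_doses: Optional[Sequence[float]] = None
                               ) -> pd.DataFrame:
    """Percent of wells positive per lineage, with explicit denominators.

    When ``monoclonal_doses`` is given, only wells at those doses (the ones
    that are probably single-cell derived) are counted.  Zero-denominator
    lineages report percent NaN with ``empty=True`` rather than silently.
    """
    if monoclonal_doses is not None:
        allowed = set(monoclonal_doses)
        wells = [w for w in wells if w.dose in allowed]
    rows = []
    for lineage, flag in (("adipogenic", "adipo_positive"),
                          ("osteogenic", "osteo_positive")):
        scored = [w for w in wells if getattr(w, flag) is not None]
        n_pos = sum(bool(getattr(w, flag)) for w in scored)
        n = len(scored)
        pct = 100.0 * n_pos / n if n else float("nan")
        rows.append((lineage, n, n_pos, pct, n == 0))
    return pd.DataFrame(rows, columns=["lineage", "wells_scored",
                                       "wells_positive", "percent_positive",
                                       "empty"])
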