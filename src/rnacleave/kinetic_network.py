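"""First-order reaction network of the RNA model compound.

The 3',5' dimer (species ``N4``) interconverts with its 2',5' isomer
(``N5``) by phosphate migration while both isomers undergo
transesterification cleavage to 2',3'-O-methyleneadenosine (``N6``) plus
2',3'-cAMP; the cyclic phosphate is hydrolyzed to 2'/3'-AMP and finally to
adenosine:

    N4 <-> N5            (k_iso_45, k_iso_54)
    N4 -> N6 + cAMP      (k_cl_4)
    N5 -> N6 + cAMP      (k_cl_5)
    cAMP -> AMP          (k_h_cAMP)
    AMP -> Ado           (k_h_AMP)

All steps are first order, so the composition vector obeys a linear ODE
solved exactly by the matrix exponential.  Compositions are expressed as
mole fractions on a dimer-equivalent basis: every cleaved dimer yields one
unit of ``N6`` and one unit of the cAMP lineage, so two conservation sums
hold at every time point,

    N4 + N5 + N6 = 1    and    N4 + N5 + cAMP + AMP + Ado = 1,

mirroring RP-HPLC peak-area shares with equal response factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field
from scipy.linalg import expm

__all__ = [
    "SPECIES",
    "KineticNetwork",
    "TimeCourse",
    "propagate",
    "observed_cleavage_rate",
    "observed_isomerization_rate",
    "RateEstimate",
]

#: Species order used in every composition vector and CSV column set.
SPECIES = ("N4", "N5", "N6", "cAMP", "AMP", "Ado")

_CSV_COLUMNS = ("time_s", "frac_4", "frac_5", "frac_6",
                "frac_cAMP", "frac_AMP", "frac_Ado")


class KineticNetwork(BaseModel):
    """Rate constants (s^-1) of the isomerization/cleavage/hydrolysis net."""

    model_config = {"frozen": True}

    k_iso_45: float = Field(0.0, ge=0.0, description="N4 -> N5 isomerization")
    k_iso_54: float = Field(0.0, ge=0.0, description="N5 -> N4 isomerization")
    k_cl_4: float = Field(0.0, ge=0.0, description="N4 cleavage")
    k_cl_5: float = Field(0.0, ge=0.0, description="N5 cleavage")
    k_h_cAMP: float = Field(0.0, ge=0.0, description="cAMP -> AMP hydrolysis")
    k_h_AMP: float = Field(0.0, ge=0.0, description="AMP -> Ado hydrolysis")

    def rate_matrix(self) -> np.ndarray:
        """Generator matrix A such that dx/dt = A x in the SPECIES order."""
        A = np.zeros((6, 6))
        A[0, 0] = -(self.k_iso_45 + self.k_cl_4)
        A[0, 1] = self.k_iso_54
        A[1, 0] = self.k_iso_45
        A[1, 1] = -(self.k_iso_54 + self.k_cl_5)
        # one N6 and one cAMP unit per cleaved dimer
        A[2, 0] = self.k_cl_4
        A[2, 1] = self.k_cl_5
        A[3, 0] = self.k_cl_4
        A[3, 1] = self.k_cl_5
        A[3, 3] = -self.k_h_cAMP
        A[4, 3] = self.k_h_cAMP
        A[4, 4] = -self.k_h_AMP
        A[5, 4] = self.k_h_AMP
        return A


@dataclass
class TimeCourse:
    """Sampled mole fractions of all species versus time.

    ``fractions`` has one row per time point and one column per species in
    :data:`SPECIES` order.  ``noisy`` marks data carrying observation
    noise, for which the conservation sums hold only after renormalization.
    """

    times: np.ndarray
    fractions: np.ndarray
    noisy: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.times.ndim != 1 or self.fractions.shape != (self.times.size, 6):
            raise ValueError("times must be 1-D and fractions (n_times, 6)")
        if self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0.0):
            raise ValueError("times must start at 0 and strictly increase")

    @property
    def pool(self) -> np.ndarray:
        """Uncleaved isomer-pool fraction N4 + N5 at each time point."""
        return self.fractions[:, 0] + self.fractions[:, 1]

    def conservation_error(self) -> float:
        """Largest deviation of either conservation sum from unity."""
        s_3p = self.fractions[:, [0, 1, 2]].sum(axis=1)
        s_5p = self.fractions[:, [0, 1, 3, 4, 5]].sum(axis=1)
        return float(max(np.abs(s_3p - 1.0).max(), np.abs(s_5p - 1.0).max()))


def propagate(
    network: KineticNetwork, initial: np.ndarray, times: np.ndarray
) -> TimeCourse:
    """Exact time courses of the first-order network.

    Solves x(t) = expm(A t) x0 at each requested time — no step-wise
    numerical integration, so conservation holds to machine precision.

    Parameters
    ----------
    network : KineticNetwork
        Rate constants; nonnegativity is enforced by the model.
    initial : array-like, shape (6,)
        Initial mole fractions in :data:`SPECIES` order; the two
        conservation sums must each equal 1 (a pure-dimer start
        ``[1, 0, 0, 0, 0, 0]`` is typical).
    times : array-like
        Sampling times (s), strictly increasing from 0.
    """
    x0 = np.asarray(initial, dtype=float)
    if x0.shape != (6,) or np.any(x0 < 0.0):
        raise ValueError("initial must be 6 nonnegative fractions")
    for idx in ([0, 1, 2], [0, 1, 3, 4, 5]):
        if abs(x0[idx].sum() - 1.0) > 1e-9:
            raise ValueError("initial fractions must satisfy conservation sums")
    times = np.asarray(times, dtype=float)
    A = network.rate_matrix()
    # eigenvalue spread is modest for realistic rate sets; expm per time
    # point keeps the code simple and exact
    frac = np.vstack([expm(A * t) @ x0 for t in times])
    return TimeCourse(times=times, fractions=frac)


@dataclass(frozen=True)
class RateEstimate:
    """Rate-constant estimate with its regression standard error."""

    value: float
    stderr: float
    flag: str | None = None


def observed_cleavage_rate(tc: TimeCourse) -> RateEstimate:
    """Observed cleavage rate constant of the isomer pool (s^-1).

    The two isomers are treated as a single pool — the experimental
    observable is the disappearance of N4 + N5 — and k_cl is the negated
    slope of an ordinary least-squares line through ln(N4 + N5) versus
    time.  With multiplicative observation noise of constant relative
    magnitude, log-scale errors are homoscedastic, so the unweighted
    log-linear fit is the correctly weighted estimator.  The pool decay is
    exactly single-exponential whenever both isomers cleave at the same
    rate; otherwise the estimate is the best log-linear approximation and
    carries a small bias.

    Raises
    ------
    ValueError
        Fewer than 4 time points, or non-positive pool fractions.
    """
    if tc.times.size < 4:
        raise ValueError("need at least 4 time points")
    pool = tc.pool
    if np.any(pool <= 0.0):
        raise ValueError("pool fractions must be positive for log fit")
    slope, se, _ = _ols_line(tc.times, np.log(pool))
    flag = "increasing_pool" if slope > 0.0 else None
    return RateEstimate(value=-slope, stderr=se, flag=flag)


def observed_isomerization_rate(tc: TimeCourse) -> RateEstimate:
    """Total isomerization rate k_iso_45 + k_iso_54 (s^-1).

    The within-pool isomer share r(t) = N5/(N4+N5) relaxes toward its
    equilibrium value as a single exponential with rate constant
    k_iso_45 + k_iso_54 (exactly so when the two isomers cleave at equal
    rates).  Fitted as r(t) = r_eq + (r_0 - r_eq) exp(-k t) by nonlinear
    least squares.  A flat ratio (already at equilibrium) leaves the rate
    unidentifiable; the estimate is then flagged ``no_signal``.
    """
    if tc.times.size < 4:
        raise ValueError("need at least 4 time points")
    pool = tc.pool
    if np.any(pool <= 0.0):
        raise ValueError("pool fractions must be positive")
    ratio = tc.fractions[:, 1] / pool
    if np.ptp(ratio) < 1e-12:
        return RateEstimate(value=0.0, stderr=np.inf, flag="no_signal")

    from scipy.optimize import curve_fit

    def model(t, r_eq, r0, k):
        return r_eq + (r0 - r_eq) * np.exp(-k * t)

    # crude rate scale from the ratio's initial slope
    k0 = max(abs(ratio[1] - ratio[0]) / (tc.times[1] * max(np.ptp(ratio), 1e-12)), 1e-12)
    popt, pcov = curve_fit(
        model, tc.times, ratio,
        p0=[ratio[-1], ratio[0], k0],
        bounds=([0.0, 0.0, 0.0], [1.0, 1.0, np.inf]),
        maxfev=10000,
    )
    se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.inf
    return RateEstimate(value=float(popt[2]), stderr=se)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, slope standard error, and intercept of an OLS line."""
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    dof = max(n - 2, 1)
    se = math.sqrt(float((resid**2).sum()) / dof / sxx)
    return slope, se, intercept
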