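"""Hill titration fits and multiexponential stopped-flow kinetics fits.

pH-dependence data (tryptophan fluorescence λmax shifts, CD amplitudes)
are min-max normalised to (0, 1) with the acidic plateau at 1 and fitted
with the Hill equation

    y(pH) = 1 / (1 + 10^{n (pH − pK)})

to obtain the transition midpoint pK and cooperativity n.  Stopped-flow
fluorescence traces are fitted with an offset plus a sum of exponentials

    I(t) = I∞ + Σᵢ aᵢ exp(−t/τᵢ),

growing the number of terms N until the reduced chi-square falls below
3×10⁻⁵ (on the normalised intensity scale) or an extra term would improve
chi-square by less than a factor of 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._utils import hill_protonation

__all__ = [
    "HillFitResult",
    "ExpFitResult",
    "KineticTrace",
    "normalize_ph_response",
    "fit_hill_transition",
    "fit_multiexponential",
    "reduced_chi_square",
]

#: Reduced chi-square convergence threshold of the N-selection loop.
CHI2_THRESHOLD = 3e-5
#: Minimum chi-square improvement factor that justifies one more term.
CHI2_IMPROVEMENT_FACTOR = 10.0


@dataclass(frozen=True)
class HillFitResult:
    """Hill-equation fit of a normalised pH transition."""

    pk: float
    n: float
    covariance: np.ndarray
    residual_ss: float
    extrapolated: bool = False

    @property
    def pk_se(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))


@dataclass(frozen=True)
class ExpFitResult:
    """Selected multiexponential model: N terms, amplitudes, times, offset.

    ``selection_trace`` records the reduced chi-square of every candidate N
    tried, so the stopping rule can be audited after the fact.
    """

    n_terms: int
    amplitudes: np.ndarray
    taus: np.ndarray
    offset: float
    reduced_chi_square: float
    selection_trace: dict
    converged: bool = True

    def __post_init__(self):
        if self.n_terms < 1:
            raise ValueError("at least one exponential term required")
        if np.any(np.asarray(self.taus) <= 0):
            raise ValueError("characteristic times must be positive")


@dataclass(frozen=True)
class KineticTrace:
    """Stopped-flow trace with an optional excluded leading window.

    Early mixing artefacts (and, for some exit traces, an initial rise) are
    excluded from fitting by dropping all points with t < ``exclude_prefix``.
    Intensities are expected on the scale of the membrane-adsorbed-state
    fluorescence (normalisation reference > 0).
    """

    times: np.ndarray
    intensities: np.ndarray
    exclude_prefix: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or t.shape != y.shape or t.size < 2:
            raise ValueError("times and intensities must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)

    def fitting_window(self) -> tuple[np.ndarray, np.ndarray]:
        mask = self.times >= self.exclude_prefix
        return self.times[mask], self.intensities[mask]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, exclude_prefix: float = 0.0) -> "KineticTrace":
        cols = list(df.columns[:2])
        return cls(df[cols[0]].to_numpy(), df[cols[1]].to_numpy(), exclude_prefix)


def normalize_ph_response(
    table: pd.DataFrame, ph_col: str = "ph", response_col: str = "response"
) -> pd.DataFrame:
    """Min-max normalise a pH-response table so the acidic plateau maps to 1.

    Protonation-driven transitions read high at low pH after normalisation,
    matching the Hill model's orientation; the raw orientation is detected
    from the mean response of the acidic vs basic half of the pH range.
    """
    df = table.sort_values(ph_col).reset_index(drop=True)
    if len(df) < 4:
        raise ValueError("need at least 4 pH points")
    y = df[response_col].to_numpy(dtype=float)
    span = y.max() - y.min()
    if span <= 0 or span < 1e-12 * max(1.0, abs(y).max()):
        raise ValueError("flat response: no transition to normalise")
    norm = (y - y.min()) / span
    half = len(df) // 2
    if norm[:half].mean() < norm[half:].mean():  # acidic side must map high
        norm = 1.0 - norm
    return pd.DataFrame({ph_col: df[ph_col].to_numpy(), response_col: norm})


def _hill_model(ph, pk, n):
    return hill_protonation(ph, pk, n)


def fit_hill_transition(
    table: pd.DataFrame, ph_col: str = "ph", response_col: str = "response"
) -> HillFitResult:
    """Levenberg–Marquardt Hill fit of a normalised pH transition.

    Initialised at n = 1 and pK = the linearly interpolated pH of
    half-response.
    """
    df = table.sort_values(ph_col)
    ph = df[ph_col].to_numpy(dtype=float)
    y = df[response_col].to_numpy(dtype=float)
    if ph.size < 3:
        raise ValueError("need at least 3 pH points to fit pK and n")
    # linear interpolation of the 0.5 crossing; y decreases with pH
    pk0 = float(np.interp(0.5, y[::-1], ph[::-1]))
    try:
        popt, pcov = curve_fit(_hill_model, ph, y, p0=(pk0, 1.0), method="lm", maxfev=10000)
    except RuntimeError as err:
        raise RuntimeError(f"Hill fit did not converge: {err}") from err
    pk, n = float(popt[0]), float(popt[1])
    if n < 0:  # sign ambiguity of (pk, n) — refit orientation is fixed by data
        raise RuntimeError("Hill fit converged to a negative cooperativity")
    resid = y - _hill_model(ph, pk, n)
    extrapolated = not (ph.min() - 1.0 <= pk <= ph.max() + 1.0)
    return HillFitResult(
        pk=pk,
        n=n,
        covariance=np.asarray(pcov),
        residual_ss=float(np.sum(resid**2)),
        extrapolated=extrapolated,
    )


def reduced_chi_square(observed, fitted, n_params: int) -> float:
    """Residual sum of squares over degrees of freedom (unit variance scale)."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    dof = obs.size - int(n_params)
    if dof <= 0:
        raise ValueError("degrees of freedom must be positive")
    return float(np.sum((obs - fit) ** 2) / dof)


def _multiexp(t, offset, *params):
    """offset + sum of a_i * exp(-t / 10**logtau_i); params alternate (a, logtau)."""
    out = np.full_like(np.asarray(t, dtype=float), offset)
    for i in range(0, len(params), 2):
        a, logtau = params[i], params[i + 1]
        out = out + a * np.exp(-np.asarray(t, dtype=float) / 10.0**logtau)
    return out


def _fit_n_terms(t, y, n_terms: int):
    """Fit offset + n_terms exponentials; taus parametrised as log10 to stay positive."""
    t_lo = max(t[t > 0].min() if np.any(t > 0) else (t[1] - t[0]), 1e-12)
    logtaus = np.linspace(np.log10(t_lo), np.log10(t.max()), n_terms + 2)[1:-1]
    # linear solve for amplitudes + offset at the initial taus
    design = np.column_stack(
        [np.exp(-t[:, None] / 10.0**logtaus[None, :]), np.ones_like(t)]
    )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    p0 = [coef[-1]]
    for a, lt in zip(coef[:-1], logtaus):
        p0 += [a, lt]
    popt, _ = curve_fit(_multiexp, t, y, p0=p0, method="lm", maxfev=40000)
    fitted = _multiexp(t, *popt)
    chi2 = reduced_chi_square(y, fitted, len(popt))
    offset = float(popt[0])
    amps = np.array(popt[1::2], dtype=float)
    taus = 10.0 ** np.array(popt[2::2], dtype=float)
    order = np.argsort(taus)
    return offset, amps[order], taus[order], chi2


def fit_multiexponential(
    trace: KineticTrace,
    max_n: int = 4,
    chi2_threshold: float = CHI2_THRESHOLD,
    improvement_factor: float = CHI2_IMPROVEMENT_FACTOR,
) -> ExpFitResult:
    """Fit N = 1, 2, … exponentials, stopping by the chi-square rule.

    The first N whose reduced chi-square is below ``chi2_threshold`` is
    selected; otherwise, if going from N to N+1 improves the reduced
    chi-square by less than ``improvement_factor``, N is kept.  Reaching
    ``max_n`` without either condition returns a result flagged
    unconverged.
    """
    t, y = trace.fitting_window()
    if t.size < 4:
        raise ValueError("too few points inside the fitting window")
    trace_chi2: dict[int, float] = {}
    fits: dict[int, tuple] = {}
    for n in range(1, max_n + 1):
        try:
            fits[n] = _fit_n_terms(t, y, n)
        except (RuntimeError, np.linalg.LinAlgError):
            # a non-converging candidate cannot be selected; record and move on
            trace_chi2[n] = float("inf")
            continue
        trace_chi2[n] = fits[n][3]
        if trace_chi2[n] < chi2_threshold:
            return _result(fits[n], n, trace_chi2, converged=True)
        if n >= 2 and np.isfinite(trace_chi2[n - 1]):
            if trace_chi2[n - 1] / trace_chi2[n] < improvement_factor:
                return _result(fits[n - 1], n - 1, trace_chi2, converged=True)
    # fell through: return the best candidate, flagged
    best = min((n for n in fits), key=lambda n: trace_chi2[n])
    return _result(fits[best], best, trace_chi2, converged=False)


def _result(fit, n, trace_chi2, converged):
    offset, amps, taus, chi2 = fit
    return ExpFitResult(
        n_terms=n,
        amplitudes=amps,
        taus=taus,
        offset=offset,
        reduced_chi_square=chi2,
        selection_trace=dict(trace_chi2),
        converged=converged,
    )
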