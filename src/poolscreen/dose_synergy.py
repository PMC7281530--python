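"""Dose-response fitting, EC_x estimation, and ZIP synergy scoring.

Monotherapy viability curves are described by the four-parameter Hill
(log-logistic) model

    y(d) = emin + (emax - emin) * d^h / (ec50^h + d^h)

with ``y`` the inhibition fraction in [0, 1]. The screen dose for each drug
is the EC10 — the concentration producing 10% growth inhibition — obtained
by closed-form inversion of the fitted curve.

Drug combinations measured on a dose matrix are scored with the
zero-interaction-potency (ZIP) model: the null expectation for two
non-interacting drugs is probabilistic independence of their inhibition
fractions, y_AB = y_A + y_B - y_A*y_B. The observed combination response at
each dose pair is smoothed by fitting potency-shifted conditional Hill
curves along its row and column (drug A's curve at fixed drug B dose starts
from drug B's monotherapy effect and saturates at 1, and vice versa); the
ZIP delta is the averaged fitted response minus the independence
expectation, in percentage points. The overall synergy score is the mean
delta over all combination cells, and the most-synergistic-area (MSA) score
the maximum mean delta over any contiguous dose window of at least 3x3
cells (the full surface included, so MSA is never below the overall score).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponseCurve",
    "DoseMatrix",
    "SynergyResult",
    "HillFitError",
    "fit_hill",
    "estimate_ecx",
    "zip_expected",
    "zip_delta",
    "most_synergistic_area",
    "inhibition_from_fluorescence",
]

FLAT_RESPONSE_SPAN = 0.02  # emax - emin below this flags an uninformative fit


class HillFitError(RuntimeError):
    """Raised when a dose-response fit fails to converge."""


@dataclass
class DoseResponseCurve:
    """Four-parameter Hill description of a monotherapy inhibition curve.

    ``emin``/``emax`` are the lower/upper inhibition asymptotes (fractions),
    ``ec50`` the half-effect concentration in the units of the input doses,
    and ``hill`` the (positive) slope.
    """

    emin: float
    emax: float
    ec50: float
    hill: float
    residual_norm: float | None = None
    flat: bool = field(default=False)

    def __post_init__(self) -> None:
        if not (self.emin <= self.emax):
            raise ValueError("emin must not exceed emax")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.hill <= 0:
            raise ValueError("hill slope must be positive")

    def predict(self, doses) -> np.ndarray:
        """Predicted inhibition fraction at each dose (0 allowed)."""
        d = np.asarray(doses, dtype=float)
        t = np.zeros_like(d)
        pos = d > 0
        t[pos] = (d[pos] / self.ec50) ** self.hill
        return self.emin + (self.emax - self.emin) * t / (1.0 + t)


def _hill(d, emin, emax, log_ec50, h):
    t = np.where(d > 0, (d / np.exp(log_ec50)) ** h, 0.0)
    return emin + (emax - emin) * t / (1.0 + t)


def fit_hill(doses, inhibition, weights=None) -> DoseResponseCurve:
    """Least-squares four-parameter Hill fit of inhibition fractions vs dose.

    Parameters
    ----------
    doses
        Concentrations, >= 0 (0 is the vehicle margin); at least 4 distinct.
    inhibition
        Observed inhibition fractions in [0, 1], same length.
    weights
        Optional relative weights (per-point precision); larger = trusted more.

    Returns a :class:`DoseResponseCurve` with the residual norm attached;
    a response span below ``FLAT_RESPONSE_SPAN`` sets the ``flat`` flag.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(inhibition, dtype=float)
    if d.shape != y.shape:
        raise ValueError("doses and inhibition must align")
    if len(np.unique(d)) < 4:
        raise ValueError("need >= 4 distinct doses for a 4-parameter fit")
    if ((y < -1e-9) | (y > 1 + 1e-9)).any():
        raise ValueError("inhibition values must lie in [0, 1]")

    pos = d[d > 0]
    mid = np.median(pos)
    p0 = (float(np.min(y)), float(np.max(y)), float(np.log(mid)), 1.0)
    span = np.ptp(y)
    if span < FLAT_RESPONSE_SPAN:
        # Degenerate flat response: parameters other than the level are
        # unidentifiable; return the level with the flag set.
        level = float(np.clip(np.mean(y), 0.0, 1.0))
        return DoseResponseCurve(
            emin=level, emax=min(level + 1e-9, 1.0) if level < 1 else level,
            ec50=mid, hill=1.0,
            residual_norm=float(np.linalg.norm(y - np.mean(y))), flat=True,
        )
    sigma = None if weights is None else 1.0 / np.sqrt(np.asarray(weights, dtype=float))
    lo, hi = np.min(pos), np.max(pos)
    bounds = (
        [0.0, 0.0, np.log(lo) - 7.0, 0.05],
        [1.0, 1.0, np.log(hi) + 7.0, 20.0],
    )
    try:
        popt, _ = curve_fit(
            _hill, d, y, p0=p0, sigma=sigma, bounds=bounds, maxfev=20000,
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
    except (RuntimeError, ValueError) as exc:
        raise HillFitError(
            f"Hill fit failed for {len(d)} points (dose range {lo:g}-{hi:g}): {exc}"
        ) from exc
    emin, emax, log_ec50, h = popt
    if emax < emin:  # bounds allow the degenerate ordering; normalise
        emin, emax = emax, emin
    resid = float(np.linalg.norm(_hill(d, *popt) - y))
    return DoseResponseCurve(
        emin=float(emin), emax=float(emax), ec50=float(np.exp(log_ec50)),
        hill=float(h), residual_norm=resid, flat=bool(emax - emin < FLAT_RESPONSE_SPAN),
    )


def estimate_ecx(curve: DoseResponseCurve, x: float) -> float:
    """Concentration producing ``x``% inhibition, by closed-form inversion.

    ``ec_x = ec50 * (f / (1 - f))^(1/h)`` with
    ``f = (x/100 - emin) / (emax - emin)``; requires emin < x/100 < emax.
    """
    target = x / 100.0
    if not (curve.emin < target < curve.emax):
        raise ValueError(
            f"{x}% inhibition is outside the achievable range "
            f"({curve.emin:.3f}, {curve.emax:.3f})"
        )
    f = (target - curve.emin) / (curve.emax - curve.emin)
    return float(curve.ec50 * (f / (1.0 - f)) ** (1.0 / curve.hill))


def zip_expected(ya, yb):
    """ZIP null expectation: probabilistic independence ya + yb - ya*yb."""
    ya = np.asarray(ya, dtype=float)
    yb = np.asarray(yb, dtype=float)
    if ((ya < 0) | (ya > 1)).any() or ((yb < 0) | (yb > 1)).any():
        raise ValueError("inhibition fractions must lie in [0, 1]")
    out = ya + yb - ya * yb
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# dose matrices


@dataclass
class DoseMatrix:
    """Mean inhibition fractions on a (drug A dose) x (drug B dose) grid.

    Dose vectors are ascending and must start at 0: the zero row/column are
    the monotherapy margins of the other drug. Values outside [0, 1] are
    clipped at construction (count kept in ``n_clipped``).
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    inhibition: np.ndarray
    n_replicates: int = 1
    drug_a: str = "drug_A"
    drug_b: str = "drug_B"
    n_clipped: int = field(default=0)

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        for name, dv in (("doses_a", self.doses_a), ("doses_b", self.doses_b)):
            if dv.ndim != 1 or len(dv) < 2:
                raise ValueError(f"{name} must be a 1-D grid of >= 2 doses")
            if (np.diff(dv) <= 0).any():
                raise ValueError(f"{name} must be strictly ascending")
            if dv[0] != 0:
                raise ValueError(f"{name} must start at 0 (monotherapy margin)")
        if self.inhibition.shape != (len(self.doses_a), len(self.doses_b)):
            raise ValueError("inhibition grid does not match dose vectors")
        out_of_range = int(((self.inhibition < 0) | (self.inhibition > 1)).sum())
        if out_of_range:
            logger.info("clipped %d inhibition values to [0, 1]", out_of_range)
            self.inhibition = np.clip(self.inhibition, 0.0, 1.0)
        self.n_clipped = out_of_range

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.inhibition, index=self.doses_a, columns=self.doses_b)

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis(f"{self.drug_a}\\{self.drug_b}").to_csv(path)

    @classmethod
    def from_csv(cls, path, readout: str = "inhibition", blank: float = 0.0,
                 **kwargs) -> "DoseMatrix":
        """Load a matrix CSV whose first row/column are the dose grids.

        ``readout='inhibition'`` takes cells as inhibition fractions;
        ``readout='fluorescence'`` converts raw readings via the vehicle
        (0, 0) well: ``1 - (v - blank) / (vehicle - blank)``.
        """
        df = pd.read_csv(path, index_col=0)
        doses_a = df.index.to_numpy(dtype=float)
        doses_b = df.columns.to_numpy(dtype=float)
        values = df.to_numpy(dtype=float)
        if readout == "fluorescence":
            vehicle = values[0, 0]
            values = inhibition_from_fluorescence(values, vehicle=vehicle, blank=blank)
        elif readout != "inhibition":
            raise ValueError(f"unknown readout {readout!r}")
        return cls(doses_a=doses_a, doses_b=doses_b, inhibition=values, **kwargs)


def inhibition_from_fluorescence(values, vehicle: float, blank: float = 0.0):
    """Convert raw viability fluorescence to inhibition fractions.

    ``inhibition = 1 - (value - blank) / (vehicle - blank)``, clipped to
    [0, 1] (values brighter than vehicle read as 0 inhibition).
    """
    if vehicle <= blank:
        raise ValueError("vehicle signal must exceed blank")
    frac = (np.asarray(values, dtype=float) - blank) / (vehicle - blank)
    return np.clip(1.0 - frac, 0.0, 1.0)


# ---------------------------------------------------------------------------
# ZIP scoring


@dataclass
class SynergyResult:
    """ZIP delta surface (percentage points) with summary scores."""

    delta: pd.DataFrame  # index: interior doses of drug A; columns: of drug B
    overall: float       # mean delta over all combination cells
    msa: float           # max mean delta over any >=3x3 contiguous window
    curve_a: DoseResponseCurve
    curve_b: DoseResponseCurve

    def summary(self) -> dict:
        return {
            "overall": self.overall,
            "msa": self.msa,
            "drug_a_hill": vars(self.curve_a),
            "drug_b_hill": vars(self.curve_b),
        }


def _conditional_hill(d, baseline, emax, log_m, h):
    # Potency-shifted conditional curve: response to one drug at a fixed
    # dose of the other, running from ``baseline`` at dose 0 towards
    # ``emax`` at saturating dose.
    t = np.where(d > 0, (d / np.exp(log_m)) ** h, 0.0)
    return (baseline + emax * t) / (1.0 + t)


def _fit_conditional(doses: np.ndarray, y: np.ndarray, baseline: float) -> np.ndarray:
    """Fitted values of the conditional response curve at ``doses``.

    The fit is initialised at the ZIP potency shift — baseline at the fixed
    drug's monotherapy effect, maximal effect 1 — but both ends are fitted,
    so the smoother can represent any uniform departure from independence
    (a constant synergy offset must survive smoothing, not be absorbed by
    it). Falls back to the raw observations when the fit fails.
    """
    mid = np.median(doses)
    span = max(float(np.ptp(y)), 0.0)
    if span < 1e-9:  # flat row: the fit is the constant itself
        return np.full_like(y, float(np.mean(y)))
    try:
        popt, _ = curve_fit(
            _conditional_hill, doses, y,
            p0=(min(max(baseline, 0.0), 1.0), 1.0, np.log(mid), 1.0),
            bounds=(
                [0.0, 0.0, np.log(doses.min()) - 7.0, 0.05],
                [1.0, 2.0, np.log(doses.max()) + 7.0, 20.0],
            ),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        logger.warning("conditional fit failed at baseline %.3f; using raw values", baseline)
        return y.copy()
    return _conditional_hill(doses, *popt)


def zip_delta(matrix: DoseMatrix, msa_min_window: int = 3) -> SynergyResult:
    """Score a dose-combination matrix with the ZIP model.

    Fits the two monotherapy Hill curves from the zero-dose margins, then
    for every combination cell averages the row-wise and column-wise
    conditional (potency-shifted) fitted responses and subtracts the
    independence expectation of the fitted monotherapy effects. Deltas are
    reported in percentage points (x100).
    """
    da, db = matrix.doses_a, matrix.doses_b
    curve_a = fit_hill(da, matrix.inhibition[:, 0])
    curve_b = fit_hill(db, matrix.inhibition[0, :])

    ia, ib = da[1:], db[1:]          # interior (combination) dose grids
    obs = matrix.inhibition[1:, 1:]  # combination cells
    ya = curve_a.predict(ia)         # fitted monotherapy effects
    yb = curve_b.predict(ib)

    fit_by_col = np.empty_like(obs)
    for j, b in enumerate(yb):
        fit_by_col[:, j] = _fit_conditional(ia, obs[:, j], baseline=float(b))
    fit_by_row = np.empty_like(obs)
    for i, a in enumerate(ya):
        fit_by_row[i, :] = _fit_conditional(ib, obs[i, :], baseline=float(a))

    fitted = 0.5 * (fit_by_col + fit_by_row)
    expected = zip_expected(ya[:, None], yb[None, :])
    delta = 100.0 * (fitted - expected)

    overall = float(delta.mean())
    if min(delta.shape) >= msa_min_window:
        msa = most_synergistic_area(delta, min_window=msa_min_window)
    else:
        msa = overall
    frame = pd.DataFrame(delta, index=ia, columns=ib)
    return SynergyResult(delta=frame, overall=overall, msa=msa,
                         curve_a=curve_a, curve_b=curve_b)


def most_synergistic_area(surface, min_window: int = 3) -> float:
    """Maximum mean over all contiguous windows with both dims >= ``min_window``.

    The candidate set includes the full surface, so the MSA score can never
    fall below the overall mean; on typical smooth delta surfaces the
    maximiser is a small (3x3) hot window.
    """
    s = np.asarray(surface, dtype=float)
    if min(s.shape) < min_window:
        raise ValueError(f"surface smaller than the {min_window}x{min_window} minimum window")
    c = np.cumsum(np.cumsum(np.pad(s, ((1, 0), (1, 0))), axis=0), axis=1)
    best = -np.inf
    for a in range(min_window, s.shape[0] + 1):
        for b in range(min_window, s.shape[1] + 1):
            sums = c[a:, b:] - c[:-a, b:] - c[a:, :-b] + c[:-a, :-b]
            best = max(best, float(sums.max() / (a * b)))
    return best
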