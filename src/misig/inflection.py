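"""Genus inflection point from the AF-ANI scatter.

The scatter of ANI against AF (every genome vs the primary reference,
anchored at the self-comparison (AF=1, ANI=100)) follows a sigmoid trend.  A
quartic polynomial is fit by ordinary least squares; its second derivative is
a quadratic whose smaller real root inside the observed AF range is the genus
inflection point -- the AF at which the rate of genomic change starts to
slow, a soft counterpart of the hard demarcation boundary.  Gompertz and
logistic fits provide independent estimates through their closed-form
inflection points; an estimate is accepted only when the quartic fit is good
(R^2 >= 0.90 by default) and both sigmoid estimates agree with it within
tolerance.  Confidence intervals come from a nonparametric bootstrap that
always retains the anchor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import MisigError

__all__ = [
    "QuarticFit",
    "InflectionPair",
    "SigmoidFit",
    "InflectionConfig",
    "InflectionEstimate",
    "ANCHOR",
    "fit_quartic",
    "second_derivative_roots",
    "fit_sigmoid",
    "estimate_genus_inflection",
]

#: The self-comparison of the primary reference, included in every regression.
ANCHOR: tuple[float, float] = (1.0, 100.0)


@dataclass(frozen=True, slots=True)
class QuarticFit:
    """OLS quartic ANI = c0 + c1*AF + ... + c4*AF^4."""

    coefficients: tuple[float, float, float, float, float]
    r2: float
    n_points: int
    anchor_included: bool

    def __call__(self, af: float | np.ndarray) -> float | np.ndarray:
        return np.polynomial.polynomial.polyval(af, self.coefficients)


@dataclass(frozen=True, slots=True)
class InflectionPair:
    """Real roots of the quartic's second derivative inside the AF range."""

    first: tuple[float, float]          # (af, ani)
    second: tuple[float, float] | None


@dataclass(frozen=True, slots=True)
class SigmoidFit:
    """Converged Gompertz or logistic fit with its analytic inflection.

    Gompertz: ANI = y0 + A*exp(-B*exp(-C*AF)), inflection at
    (ln(B)/C, y0 + A/e).  Logistic: ANI = y0 + A/(1+exp(-K*(AF-x0))),
    inflection at (x0, y0 + A/2).
    """

    family: Literal["gompertz", "logistic"]
    parameters: tuple[float, ...]
    r2: float

    @property
    def analytic_inflection(self) -> tuple[float, float]:
        if self.family == "gompertz":
            y0, a, b, c = self.parameters
            return (np.log(b) / c, y0 + a / np.e)
        y0, a, k, x0 = self.parameters
        return (x0, y0 + a / 2.0)

    def __call__(self, af: float | np.ndarray) -> float | np.ndarray:
        if self.family == "gompertz":
            y0, a, b, c = self.parameters
            return y0 + a * np.exp(-b * np.exp(-c * np.asarray(af, dtype=float)))
        y0, a, k, x0 = self.parameters
        return y0 + a / (1.0 + np.exp(-k * (np.asarray(af, dtype=float) - x0)))


@dataclass(frozen=True, slots=True)
class InflectionConfig:
    """Acceptance gate and bootstrap settings for the genus inflection point."""

    r2_min: float = 0.90
    agreement_tol_af: float = 0.05
    agreement_tol_ani: float = 1.0
    n_boot: int = 1000
    seed: int = 0


@dataclass(frozen=True, slots=True)
class InflectionEstimate:
    af_star: float
    ani_star: float
    method: str
    ci95_af: tuple[float, float] | None
    ci95_ani: tuple[float, float] | None
    ci99_af: tuple[float, float] | None
    ci99_ani: tuple[float, float] | None
    r2_quartic: float
    accepted: bool
    sigmoid_inflections: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Quartic fit and its inflection roots
# ---------------------------------------------------------------------------

def _with_anchor(points: Sequence[tuple[float, float]], include: bool) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise MisigError("invalid points: expected (af, ani) pairs")
    if include and not np.any((pts[:, 0] == ANCHOR[0]) & (pts[:, 1] == ANCHOR[1])):
        pts = np.vstack([pts, np.asarray(ANCHOR)])
    return pts


def fit_quartic(
    points: Sequence[tuple[float, float]], include_anchor: bool = True
) -> QuarticFit:
    """Ordinary least-squares quartic regression of ANI on AF.

    R^2 is computed on the fitted point set (anchor included when used) and
    clamped at 0 for pathological fits.
    """
    pts = _with_anchor(points, include_anchor)
    if pts.shape[0] < 6:
        raise MisigError(f"underdetermined: quartic fit needs >=6 points, got {pts.shape[0]}")
    af, ani = pts[:, 0], pts[:, 1]
    if np.unique(af).size < 5:
        raise MisigError("degenerate AF values: fewer than 5 distinct AF values")
    # Fit in a scaled domain for conditioning, then convert back to the
    # plain power basis.
    series = np.polynomial.Polynomial.fit(af, ani, deg=4)
    coef = series.convert().coef
    coef = np.pad(coef, (0, 5 - coef.size))
    pred = np.polynomial.polynomial.polyval(af, coef)
    ss_res = float(np.sum((ani - pred) ** 2))
    ss_tot = float(np.sum((ani - ani.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return QuarticFit(
        coefficients=tuple(float(c) for c in coef),
        r2=r2,
        n_points=int(pts.shape[0]),
        anchor_included=bool(include_anchor),
    )


def second_derivative_roots(
    fit: QuarticFit, af_range: tuple[float, float]
) -> InflectionPair:
    """Solve 12*c4*x^2 + 6*c3*x + 2*c2 = 0 and keep real roots in range.

    The smaller-AF root is the genus inflection point candidate.
    """
    c0, c1, c2, c3, c4 = fit.coefficients
    lo, hi = af_range
    if c4 != 0.0:
        disc = 36.0 * c3 * c3 - 96.0 * c4 * c2
        if disc < 0:
            raise MisigError("no inflection detected: complex second-derivative roots")
        sq = np.sqrt(disc)
        roots = sorted(((-6.0 * c3 - sq) / (24.0 * c4), (-6.0 * c3 + sq) / (24.0 * c4)))
    elif c3 != 0.0:
        roots = [-c2 / (3.0 * c3)]
    else:
        raise MisigError("no inflection detected: second derivative has no root")
    in_range = sorted({r for r in roots if lo <= r <= hi})
    if not in_range:
        raise MisigError(f"no inflection detected: no real root in AF range [{lo}, {hi}]")
    first = (in_range[0], float(fit(in_range[0])))
    second = (in_range[1], float(fit(in_range[1]))) if len(in_range) > 1 else None
    return InflectionPair(first=first, second=second)


# ---------------------------------------------------------------------------
# Sigmoid fits
# ---------------------------------------------------------------------------

def _gompertz(x, y0, a, b, c):
    return y0 + a * np.exp(-b * np.exp(-c * x))


def _logistic(x, y0, a, k, x0):
    return y0 + a / (1.0 + np.exp(-k * (x - x0)))


def _sigmoid_starts(af: np.ndarray, ani: np.ndarray, family: str) -> list[list[float]]:
    """Three deterministic multi-starts from data quantiles."""
    y_lo, y_hi = float(np.min(ani)), float(np.max(ani))
    amp = max(y_hi - y_lo, 1e-6)
    x_mids = np.quantile(af, [0.25, 0.5, 0.75])
    starts = []
    for xm in x_mids:
        xm = float(min(max(xm, 1e-3), 1.0))
        if family == "gompertz":
            for c in (5.0, 12.0):
                starts.append([y_lo, amp, float(np.exp(c * xm)), c])
        else:
            for k in (5.0, 12.0):
                starts.append([y_lo, amp, k, xm])
    return starts[:6]


def fit_sigmoid(
    points: Sequence[tuple[float, float]],
    family: Literal["gompertz", "logistic"] = "gompertz",
    include_anchor: bool = True,
) -> SigmoidFit:
    """Nonlinear least squares sigmoid fit with deterministic multi-starts.

    Raises "fit failed" when no start converges (e.g. zero ANI variance).
    """
    if family not in ("gompertz", "logistic"):
        raise MisigError(f"invalid family: {family!r}")
    pts = _with_anchor(points, include_anchor)
    if pts.shape[0] < 5:
        raise MisigError(f"underdetermined: sigmoid fit needs >=5 points, got {pts.shape[0]}")
    af, ani = pts[:, 0], pts[:, 1]
    if float(np.var(ani)) == 0.0:
        raise MisigError("fit failed: zero variance in ANI values")
    model = _gompertz if family == "gompertz" else _logistic
    best: tuple[float, np.ndarray] | None = None
    for p0 in _sigmoid_starts(af, ani, family):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(model, af, ani, p0=p0, maxfev=20000)
        except (RuntimeError, TypeError, ValueError):
            continue
        if family == "gompertz" and (popt[2] <= 0 or popt[3] <= 0):
            continue  # inflection ln(B)/C undefined
        resid = ani - model(af, *popt)
        ss = float(np.sum(resid**2))
        if np.isfinite(ss) and (best is None or ss < best[0]):
            best = (ss, popt)
    if best is None:
        raise MisigError(f"fit failed: no converged {family} fit")
    ss_res, popt = best
    ss_tot = float(np.sum((ani - ani.mean()) ** 2))
    r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return SigmoidFit(family=family, parameters=tuple(float(p) for p in popt), r2=r2)


# ---------------------------------------------------------------------------
# Combined estimator with bootstrap CIs
# ---------------------------------------------------------------------------

def _quartic_first_inflection(
    pts: np.ndarray, af_range: tuple[float, float]
) -> tuple[float, float, float]:
    fit = fit_quartic(pts, include_anchor=False)  # pts already anchored
    pair = second_derivative_roots(fit, af_range)
    return pair.first[0], pair.first[1], fit.r2


def estimate_genus_inflection(
    points: Sequence[tuple[float, float]],
    config: InflectionConfig | None = None,
) -> InflectionEstimate:
    """Point estimate, acceptance gate and bootstrap CIs for the genus inflection.

    The quartic first inflection is the point estimate.  It is accepted only
    when the quartic R^2 reaches ``r2_min`` *and* both the Gompertz and
    logistic analytic inflections lie within the agreement tolerances of the
    quartic estimate.  Percentile CIs (95% and 99%) per axis come from
    resampling the non-anchor points with replacement (the anchor is always
    retained), re-fitting the quartic and re-extracting the first inflection;
    resamples without a real in-range root are dropped.
    """
    config = config or InflectionConfig()
    pts = _with_anchor(points, include=True)
    af_range = (float(pts[:, 0].min()), float(pts[:, 0].max()))
    af_star, ani_star, r2_q = _quartic_first_inflection(pts, af_range)

    sigmoid_inflections: dict[str, tuple[float, float] | None] = {}
    agree = True
    for family in ("gompertz", "logistic"):
        try:
            sfit = fit_sigmoid(pts, family=family, include_anchor=False)
            s_af, s_ani = sfit.analytic_inflection
            sigmoid_inflections[family] = (float(s_af), float(s_ani))
            if (
                abs(s_af - af_star) > config.agreement_tol_af
                or abs(s_ani - ani_star) > config.agreement_tol_ani
            ):
                agree = False
        except MisigError:
            sigmoid_inflections[family] = None
            agree = False
    accepted = bool(r2_q >= config.r2_min and agree)

    # Bootstrap (anchor pinned).
    anchor_mask = (pts[:, 0] == ANCHOR[0]) & (pts[:, 1] == ANCHOR[1])
    anchor_rows = pts[anchor_mask][:1]
    free = pts[~anchor_mask]
    rng = np.random.default_rng(config.seed)
    boot_af: list[float] = []
    boot_ani: list[float] = []
    for _ in range(config.n_boot):
        idx = rng.integers(0, free.shape[0], free.shape[0])
        sample = np.vstack([free[idx], anchor_rows])
        try:
            b_af, b_ani, _ = _quartic_first_inflection(
                sample, (float(sample[:, 0].min()), float(sample[:, 0].max()))
            )
        except MisigError:
            continue
        boot_af.append(b_af)
        boot_ani.append(b_ani)

    def _ci(vals: list[float], level: float) -> tuple[float, float] | None:
        if len(vals) < max(10, config.n_boot // 2):
            return None
        alpha = (100.0 - level) / 2.0
        lo, hi = np.percentile(vals, [alpha, 100.0 - alpha])
        return (float(lo), float(hi))

    return InflectionEstimate(
        af_star=float(af_star),
        ani_star=float(ani_star),
        method="quartic",
        ci95_af=_ci(boot_af, 95.0),
        ci95_ani=_ci(boot_ani, 95.0),
        ci99_af=_ci(boot_af, 99.0),
        ci99_ani=_ci(boot_ani, 99.0),
        r2_quartic=float(r2_q),
        accepted=accepted,
        sigmoid_inflections=sigmoid_inflections,
    )
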