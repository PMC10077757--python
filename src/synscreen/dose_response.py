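"""Four-parameter logistic dose-response fitting and derived metrics.

The model, with dose ``c`` in nM, is

    V(c) = einf + (e0 - einf) / (1 + (c / ec50)^h)

with baseline viability ``e0`` at zero dose, plateau ``einf`` at
infinite dose, inflection concentration ``ec50`` and Hill slope ``h``
(h > 0 for curves that decrease with dose in this parameterization).

Two derived metrics follow the screening conventions of large
cell-line panels:

* **absolute IC50** — the smallest tested concentration at which the
  fitted curve crosses 50% of untreated control.  This is distinct from
  the EC50 inflection point and is censored (">cmax" / "<cmin") when
  the curve does not cross 0.5 inside the tested range.
* **AUC** — the mean of the fitted viability, clipped to [0, 1], over
  the tested log10-dose window.  AUC is 1 for a fully resistant flat
  curve and tends to 0 as the curve approaches complete kill
  everywhere; lower AUC = more sensitive.

Fitting is deterministic: a fixed 5x3 multi-start grid over
(log10 ec50, h) feeds a bounded trust-region least-squares solver and
the best SSE wins, ties broken by smaller h then smaller ec50.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from synscreen.errors import InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)

#: Parameter bounds keeping 6-point fits identifiable.
E0_BOUNDS = (0.5, 1.5)
EINF_BOUNDS = (-0.1, 1.2)
HILL_BOUNDS = (0.1, 10.0)
LOG_EC50_MARGIN = 2.0  # decades beyond the tested range

_HILL_STARTS = (0.5, 1.0, 2.0)
_N_EC50_STARTS = 5

#: Censoring markers for the absolute IC50.
CENSOR_HIGH = ">cmax"
CENSOR_LOW = "<cmin"


@dataclass(frozen=True)
class FourPLParams:
    """Parameters of the four-parameter logistic viability model."""

    e0: float
    einf: float
    ec50: float
    hill: float

    def __post_init__(self) -> None:
        if not (self.ec50 > 0):
            raise ValidationError(f"ec50 must be > 0, got {self.ec50}")

    def viability(self, dose) -> np.ndarray | float:
        """Fitted viability at dose (nM); vectorized over arrays."""
        dose = np.asarray(dose, dtype=float)
        with np.errstate(over="ignore"):
            v = self.einf + (self.e0 - self.einf) / (
                1.0 + (dose / self.ec50) ** self.hill
            )
        return v if v.ndim else float(v)


@dataclass(frozen=True)
class DoseResponseFit:
    """A fitted curve with its derived screening metrics.

    ``ic50`` is the absolute IC50 in nM with ``ic50_censor`` one of
    None, ">cmax" or "<cmin"; a censored IC50 stores the corresponding
    range bound so that downstream fold changes stay defined
    (conservative substitution).
    """

    params: FourPLParams
    converged: bool
    ic50: float
    ic50_censor: str | None
    auc: float
    dose_range: tuple[float, float]
    residual_sse: float

    @property
    def ic50_value(self) -> float:
        """IC50 with censoring bound substituted (always finite)."""
        return self.ic50


_LN10 = np.log(10.0)


def _model(theta: np.ndarray, log_dose: np.ndarray) -> np.ndarray:
    log_ec50, h, e0, einf = theta
    with np.errstate(over="ignore"):
        return einf + (e0 - einf) / (1.0 + 10.0 ** (h * (log_dose - log_ec50)))


def _model_batch(theta: np.ndarray, log_dose: np.ndarray) -> np.ndarray:
    """Model for a (B, 4) parameter batch -> (B, n) viabilities."""
    lec, h, e0, einf = (theta[:, k][:, None] for k in range(4))
    with np.errstate(over="ignore"):
        u = 10.0 ** (h * (log_dose[None, :] - lec))
    return einf + (e0 - einf) / (1.0 + u)


def _jacobian_batch(theta: np.ndarray, log_dose: np.ndarray) -> np.ndarray:
    """Analytic Jacobian, (B, n, 4)."""
    lec, h, e0, einf = (theta[:, k][:, None] for k in range(4))
    x = log_dose[None, :]
    with np.errstate(over="ignore"):
        u = 10.0 ** (h * (x - lec))
    s = 1.0 / (1.0 + u)
    us2 = np.where(np.isfinite(u), u * s * s, 0.0)
    J = np.empty(theta.shape[:1] + log_dose.shape + (4,))
    J[..., 0] = (e0 - einf) * _LN10 * h * us2
    J[..., 1] = -(e0 - einf) * _LN10 * (x - lec) * us2
    J[..., 2] = s
    J[..., 3] = 1.0 - s
    return J


def _lm_multistart(
    starts: np.ndarray,
    log_dose: np.ndarray,
    y: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    max_iter: int = 120,
) -> tuple[np.ndarray, np.ndarray]:
    """Bounds-projected Levenberg-Marquardt over a batch of starts.

    All starts iterate in lockstep (vectorized over the batch); steps
    that do not reduce the SSE are rejected with an increased damping
    factor.  Parameters are clipped to the box after every accepted
    step.  Returns (theta, sse) per start; fully deterministic.
    """
    theta = np.clip(starts, lo, hi)
    resid = _model_batch(theta, log_dose) - y
    sse = np.sum(resid ** 2, axis=1)
    lam = np.full(theta.shape[0], 1e-3)
    for _ in range(max_iter):
        J = _jacobian_batch(theta, log_dose)
        g = np.einsum("bnk,bn->bk", J, resid)
        H = np.einsum("bnk,bnl->bkl", J, J)
        diag = np.einsum("bkk->bk", H).copy()
        diag[diag <= 0] = 1e-12
        H_damped = H + lam[:, None, None] * diag[:, None, :] * np.eye(4)
        try:
            step = np.linalg.solve(H_damped, -g[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - heavy damping fallback
            step = -g / (diag + 1.0)
        trial = np.clip(theta + step, lo, hi)
        trial_resid = _model_batch(trial, log_dose) - y
        trial_sse = np.sum(trial_resid ** 2, axis=1)
        accept = trial_sse < sse
        moved = np.max(np.abs(trial - theta), axis=1)
        improved = sse - trial_sse
        theta[accept] = trial[accept]
        resid[accept] = trial_resid[accept]
        sse = np.where(accept, trial_sse, sse)
        lam = np.where(accept, np.maximum(lam * 0.33, 1e-12), lam * 4.0)
        done = (accept & (improved < 1e-14) & (moved < 1e-10)) | (lam > 1e10)
        if np.all(done | (sse < 1e-22)):
            break
    return theta, sse


def _polish(theta, sse, log_dose, y, lo, hi):
    """Trust-region refinement of the selected multi-start candidate."""
    eps = 1e-12
    x0 = np.clip(theta, lo + eps, hi - eps)
    try:
        res = least_squares(
            lambda th: _model_batch(th[None], log_dose)[0] - y,
            x0, jac=lambda th: _jacobian_batch(th[None], log_dose)[0],
            bounds=(lo, hi), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=200,
        )
    except Exception:  # pragma: no cover - keep the LM solution
        return theta, sse
    refined_sse = float(np.sum(res.fun ** 2))
    if res.status > 0 and np.all(np.isfinite(res.x)) and refined_sse <= sse:
        return res.x, refined_sse
    return theta, sse


def fit_4pl(
    doses: Sequence[float],
    viability: Sequence[float],
    quadrature_points: int = 257,
) -> DoseResponseFit:
    """Fit the 4PL model to replicate-averaged viability points.

    Parameters
    ----------
    doses
        Concentrations in nM; at least 4 distinct positive doses.
    viability
        Fractional viability aligned to ``doses`` (unclipped).

    Notes
    -----
    If the optimizer fails on every start, or the response is flat
    (slope unidentifiable), the fit is flagged ``converged=False`` and
    the metrics fall back to model-free estimates: IC50 by log-linear
    interpolation between the observed points bracketing 0.5 and AUC by
    trapezoid on the observed (clipped) points.
    """
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    keep = doses > 0
    doses, viability = doses[keep], viability[keep]
    order = np.argsort(doses)
    doses, viability = doses[order], viability[order]
    if np.unique(doses).size < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct positive doses, got {np.unique(doses).size}"
        )
    cmin, cmax = float(doses[0]), float(doses[-1])
    log_dose = np.log10(doses)

    if np.ptp(viability) < 1e-12:
        # Flat response: slope unidentifiable, fall back directly.
        flat = float(viability[0])
        params = FourPLParams(e0=flat, einf=flat,
                              ec50=float(np.sqrt(cmin * cmax)), hill=1.0)
        ic50, censor = _fallback_ic50(doses, viability, cmin, cmax)
        auc = _observed_auc(doses, viability)
        return DoseResponseFit(params, False, ic50, censor, auc,
                               (cmin, cmax), 0.0)

    lo = np.array([np.log10(cmin) - LOG_EC50_MARGIN, HILL_BOUNDS[0],
                   E0_BOUNDS[0], EINF_BOUNDS[0]])
    hi = np.array([np.log10(cmax) + LOG_EC50_MARGIN, HILL_BOUNDS[1],
                   E0_BOUNDS[1], EINF_BOUNDS[1]])
    e0_init = float(np.clip(viability[0], *E0_BOUNDS))
    einf_init = float(np.clip(viability.min(), *EINF_BOUNDS))

    starts = np.array([
        [lec, h0, e0_init, einf_init]
        for lec in np.linspace(np.log10(cmin), np.log10(cmax), _N_EC50_STARTS)
        for h0 in _HILL_STARTS
    ])
    thetas, sses = _lm_multistart(starts, log_dose, viability, lo, hi)
    candidates = [
        (float(s), float(th[1]), float(10.0 ** th[0]), th)
        for th, s in zip(thetas, sses)
        if np.isfinite(s) and np.all(np.isfinite(th))
    ]

    if not candidates:
        ic50, censor = _fallback_ic50(doses, viability, cmin, cmax)
        auc = _observed_auc(doses, viability)
        params = FourPLParams(e0=float(viability[0]), einf=float(viability[-1]),
                              ec50=float(np.sqrt(cmin * cmax)), hill=1.0)
        return DoseResponseFit(params, False, ic50, censor, auc,
                               (cmin, cmax), float("nan"))

    # Best SSE wins; candidates within a relative hair of the best are
    # treated as ties and broken by smaller hill, then smaller ec50,
    # for determinism across equivalent optima.
    best_sse = min(c[0] for c in candidates)
    tol = best_sse * 1e-9 + 1e-15
    tied = [c for c in candidates if c[0] <= best_sse + tol]
    tied.sort(key=lambda c: (c[1], c[2]))
    sse, _, _, theta = tied[0]
    theta, sse = _polish(theta, sse, log_dose, viability, lo, hi)
    params = FourPLParams(e0=float(theta[2]), einf=float(theta[3]),
                          ec50=float(10.0 ** theta[0]), hill=float(theta[1]))
    ic50, censor = absolute_ic50(params, cmin, cmax)
    auc = curve_auc(params, cmin, cmax, n_points=quadrature_points)
    return DoseResponseFit(params, True, ic50, censor, auc, (cmin, cmax), sse)


def _fallback_ic50(doses, viability, cmin, cmax) -> tuple[float, str | None]:
    """Log-linear interpolation between observed points bracketing 0.5."""
    if viability[0] < 0.5:
        return cmin, CENSOR_LOW
    below = np.flatnonzero(viability < 0.5)
    if below.size == 0:
        return cmax, CENSOR_HIGH
    j = below[0]
    x0, x1 = np.log10(doses[j - 1]), np.log10(doses[j])
    y0, y1 = viability[j - 1], viability[j]
    x = x0 + (0.5 - y0) * (x1 - x0) / (y1 - y0)
    return float(10.0 ** x), None


def _observed_auc(doses, viability) -> float:
    v = np.clip(viability, 0.0, 1.0)
    x = np.log10(doses)
    return float(np.trapezoid(v, x) / (x[-1] - x[0]))


def absolute_ic50(
    params: FourPLParams, cmin: float, cmax: float
) -> tuple[float, str | None]:
    """Smallest c in [cmin, cmax] with fitted viability 0.5, or censored.

    Returns ``(value, censor)``; a censored result stores the bound
    itself so fold changes downstream stay defined.  Censoring is
    ">cmax" when the fitted viability stays above 0.5 over the whole
    range, "<cmin" when the curve is already below 0.5 at cmin.
    """
    if cmin >= cmax:
        raise ValidationError("cmin must be < cmax")
    grid = np.logspace(np.log10(cmin), np.log10(cmax), 513)
    v = params.viability(grid)
    reached = np.flatnonzero(v <= 0.5)
    if reached.size == 0:
        return float(cmax), CENSOR_HIGH
    if v[0] < 0.5:
        return float(cmin), CENSOR_LOW
    # Monotone-decreasing closed-form inversion when well-defined.
    e0, einf, h = params.e0, params.einf, params.hill
    if e0 > 0.5 > einf:
        ratio = (e0 - einf) / (0.5 - einf) - 1.0
        if ratio > 0:
            c = params.ec50 * ratio ** (1.0 / h)
            if cmin <= c <= cmax:
                return float(c), None
    # Boundary/corner cases (curve touching 0.5, einf at 0.5): first
    # grid point at or below 0.5, log-linear interpolated.
    j = int(reached[0])
    if v[j] == 0.5 or j == 0:
        return float(grid[j]), None
    x = np.interp(0.5, [v[j], v[j - 1]],
                  [np.log10(grid[j]), np.log10(grid[j - 1])])
    return float(10.0 ** x), None


def curve_auc(
    params: FourPLParams, cmin: float, cmax: float, n_points: int = 257
) -> float:
    """Mean of clip(V(c), 0, 1) over log10-dose on [cmin, cmax].

    Trapezoid quadrature on >= 256 intervals; 1.0 for a flat resistant
    curve, approaching 0 for complete kill over the whole range.
    """
    if cmin >= cmax:
        raise ValidationError("cmin must be < cmax")
    if n_points < 257:
        n_points = 257
    x = np.linspace(np.log10(cmin), np.log10(cmax), n_points)
    v = np.clip(params.viability(10.0 ** x), 0.0, 1.0)
    return float(np.trapezoid(v, x) / (x[-1] - x[0]))


def auc_zscore_matrix(
    auc: pd.DataFrame, compounds: Sequence[str] | None = None
) -> pd.DataFrame:
    """Column-wise Z-scores of an AUC matrix (cell lines x compounds).

    z = (auc - mean) / sd with sample sd (ddof=1), computed across all
    cell lines per compound; missing entries stay missing.  A constant
    column yields all zeros with a warning.
    """
    if compounds is not None:
        auc = auc[list(compounds)]
    out = {}
    for compound in auc.columns:
        col = auc[compound].astype(float)
        n = col.notna().sum()
        if n < 3:
            raise InsufficientDataError(
                f"compound {compound!r} has {n} AUC values; need >= 3"
            )
        sd = col.std(ddof=1)
        if sd == 0:
            warnings.warn(f"compound {compound!r} has zero AUC variance; "
                          f"Z-scores set to 0", stacklevel=2)
            z = col - col.mean()
        else:
            z = (col - col.mean()) / sd
        out[compound] = z
    return pd.DataFrame(out, index=auc.index)


def classify_sensitivity(
    viability_at_top: float, top_dose_ok: bool = True
) -> str:
    """Classify a line as sensitive/insensitive from top-dose viability.

    Insensitive lines are those whose measured viability remains
    strictly above 50% at the configured top dose (10 uM by default in
    the pipeline); exactly 0.5 counts as sensitive.
    """
    if not top_dose_ok:
        raise ValidationError(
            "sensitivity classification is defined only at the configured top dose"
        )
    return "insensitive" if viability_at_top > 0.5 else "sensitive"


# ---------------------------------------------------------------------------
# Batch fitting
# ---------------------------------------------------------------------------

FIT_COLUMNS = [
    "cell_line", "compound", "anchor_compound", "anchor_dose",
    "e0", "einf", "ec50_nM", "hill", "ic50_nM", "ic50_censored",
    "auc", "converged", "sse",
]


def fit_screen(points: pd.DataFrame) -> pd.DataFrame:
    """Fit one 4PL curve per (cell_line, compound[, anchor]) group.

    ``points`` is a replicate-averaged viability frame from
    :func:`synscreen.screen_io.normalize_viability`.  Returns a tidy
    table with one row per fitted curve (stable column order).
    """
    keys = ["cell_line", "compound", "anchor_compound", "anchor_dose"]
    rows = []
    for key, grp in points.groupby(keys, dropna=False, sort=False):
        grp = grp[grp["dose"] > 0]
        fit = fit_4pl(grp["dose"].to_numpy(), grp["viability"].to_numpy())
        rows.append({
            "cell_line": key[0], "compound": key[1],
            "anchor_compound": key[2], "anchor_dose": key[3],
            "e0": fit.params.e0, "einf": fit.params.einf,
            "ec50_nM": fit.params.ec50, "hill": fit.params.hill,
            "ic50_nM": fit.ic50, "ic50_censored": fit.ic50_censor or "",
            "auc": fit.auc, "converged": fit.converged,
            "sse": fit.residual_sse,
        })
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def fit_from_row(row: pd.Series) -> DoseResponseFit:
    """Rehydrate a :class:`DoseResponseFit` from a ``fit_screen`` row.

    The dose range is not stored in the table; metrics are carried over
    as-is, so this is sufficient for fold-change computations.
    """
    params = FourPLParams(e0=row["e0"], einf=row["einf"],
                          ec50=row["ec50_nM"], hill=row["hill"])
    return DoseResponseFit(
        params=params, converged=bool(row["converged"]),
        ic50=float(row["ic50_nM"]),
        ic50_censor=row["ic50_censored"] or None,
        auc=float(row["auc"]), dose_range=(float("nan"), float("nan")),
        residual_sse=float(row["sse"]),
    )
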