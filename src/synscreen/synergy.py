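"""Anchored drug-combination synergy scoring.

A combination is scored against the Bliss independence null: with
inhibition fractions ``fa`` and ``fb`` of the two single agents, the
expected combined inhibition is ``fa + fb - fa*fb``, and the *excess*
(observed minus expected) is positive for synergy.  Inhibition is
``clip(1 - viability, 0, 1)`` — Bliss requires probabilities.

Three outcome metrics summarise each (cell line, anchor, library
compound) combination, each averaged over the anchor concentrations
(IC15/IC25/IC50 of the anchor drug per cell line):

* ``delta_emax``  — fold change in maximal effect at the top library
  dose (combination / monotherapy);
* ``delta_ic50``  — fold change in IC50 (monotherapy / combination, so
  > 1 means the combination improves potency);
* ``bliss_avg``   — mean Bliss excess over all cells with both doses
  positive.

A combination is a *hit* when the averaged ΔEmax or ΔIC50 exceeds 5 or
the averaged Bliss score exceeds 0 (strict inequalities).  The
*maximum effective synergy* is the largest Bliss excess among cells
whose observed combination viability is below 50%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from synscreen.dose_response import (
    DoseResponseFit,
    fit_4pl,
)
from synscreen.errors import InsufficientDataError, ValidationError

#: Hit-selection defaults.
FOLD_CHANGE_THRESHOLD = 5.0
BLISS_THRESHOLD = 0.0
EFFECTIVE_VIABILITY_CUTOFF = 0.5


def inhibition(viability) -> np.ndarray | float:
    """Inhibition fraction clip(1 - viability, 0, 1)."""
    return np.clip(1.0 - np.asarray(viability, dtype=float), 0.0, 1.0)


def bliss_expected(fa, fb):
    """Expected combined inhibition under Bliss independence.

    Symmetric in its arguments; inputs must be inhibition fractions in
    [0, 1] (use :func:`inhibition` to convert viabilities).
    """
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    for name, f in (("fa", fa), ("fb", fb)):
        with np.errstate(invalid="ignore"):
            if np.any((f < 0) | (f > 1) | ~np.isfinite(f)):
                raise ValidationError(f"{name} must lie in [0, 1]")
    out = fa + fb - fa * fb
    return out if out.ndim else float(out)


@dataclass
class CombinationMatrix:
    """An anchored viability grid with its monotherapy margins.

    ``viability`` has shape (len(doses_a), len(doses_b)); ``mono_a`` and
    ``mono_b`` are the single-agent viabilities at the corresponding
    doses (NaN where a margin was not measured).  Anchored 1xK series
    are represented as a single-row grid.
    """

    cell_line: str
    compound_a: str
    compound_b: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    viability: np.ndarray
    mono_a: np.ndarray
    mono_b: np.ndarray

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        self.mono_a = np.asarray(self.mono_a, dtype=float)
        self.mono_b = np.asarray(self.mono_b, dtype=float)
        if self.viability.shape != (self.doses_a.size, self.doses_b.size):
            raise ValidationError("viability grid does not match dose vectors")
        if self.mono_a.shape != self.doses_a.shape or self.mono_b.shape != self.doses_b.shape:
            raise ValidationError("monotherapy margins do not match dose vectors")
        for d in (self.doses_a, self.doses_b):
            if d.size > 1 and np.any(np.diff(d) <= 0):
                raise ValidationError("dose vectors must be strictly increasing")
            if np.any(d <= 0):
                raise ValidationError("grid doses must be > 0 (margins live separately)")

    def transpose(self) -> "CombinationMatrix":
        """Swap the two compounds' roles (grid transposed)."""
        return CombinationMatrix(
            cell_line=self.cell_line,
            compound_a=self.compound_b, compound_b=self.compound_a,
            doses_a=self.doses_b, doses_b=self.doses_a,
            viability=self.viability.T,
            mono_a=self.mono_b, mono_b=self.mono_a,
        )


def bliss_excess_matrix(m: CombinationMatrix) -> np.ndarray:
    """Observed minus Bliss-expected inhibition per grid cell.

    Cells whose monotherapy margin is missing (NaN) are returned as NaN
    and excluded from downstream averages.
    """
    fa = inhibition(m.mono_a)[:, None]
    fb = inhibition(m.mono_b)[None, :]
    defined = np.isfinite(m.mono_a)[:, None] & np.isfinite(m.mono_b)[None, :]
    expected = np.where(defined, fa + fb - fa * fb, np.nan)
    observed = inhibition(m.viability)
    excess = np.where(defined & np.isfinite(m.viability),
                      observed - expected, np.nan)
    return excess


def average_bliss(excess: np.ndarray) -> float:
    """Arithmetic mean of the Bliss excess over defined cells.

    NaN (undefined marker) when no cell is defined.
    """
    excess = np.asarray(excess, dtype=float)
    if not np.isfinite(excess).any():
        return float("nan")
    return float(np.nanmean(excess))


def delta_emax(mono_top_viability: float, combo_top_viability: float) -> float:
    """Fold change in maximal effect at the highest library dose.

    Emax = clip(1 - viability, 0, 1) at the top dose; returns
    Emax_combo / Emax_mono.  0/0 -> 1.0; a finite combination effect on
    a null monotherapy baseline -> +inf (maximal evidence, satisfies
    any finite threshold).
    """
    for name, v in (("mono", mono_top_viability), ("combo", combo_top_viability)):
        if v is None or not np.isfinite(v):
            raise ValidationError(f"missing top-dose {name} viability")
    emax_mono = float(inhibition(mono_top_viability))
    emax_combo = float(inhibition(combo_top_viability))
    if emax_mono == 0.0:
        return 1.0 if emax_combo == 0.0 else math.inf
    return emax_combo / emax_mono


def delta_ic50(mono_fit: DoseResponseFit, combo_fit: DoseResponseFit) -> float:
    """Fold change in IC50: monotherapy / combination (> 1 = improvement).

    Censored IC50s enter as their censoring bound (conservative).  When
    both are censored at the same bound the fold change is 1.0.
    """
    if (mono_fit.ic50_censor is not None
            and mono_fit.ic50_censor == combo_fit.ic50_censor
            and mono_fit.ic50 == combo_fit.ic50):
        return 1.0
    combo = combo_fit.ic50_value
    if combo == 0:
        return math.inf
    return mono_fit.ic50_value / combo


@dataclass
class SynergyMetrics:
    """Per-combination outcome metrics, averaged over anchors.

    ``per_anchor`` maps an anchor label (e.g. "IC25") to the
    (delta_emax, delta_ic50, bliss_avg) triple at that anchor.  NaN
    marks an undefined metric; +inf marks a fold change from a null
    baseline and propagates through the anchor average.
    """

    delta_emax: float
    delta_ic50: float
    bliss_avg: float
    per_anchor: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    max_effective_synergy: float = float("nan")
    is_hit: bool = False


def _mean_defined(values: Sequence[float]) -> float:
    vals = [v for v in values if v is not None and not math.isnan(v)]
    if not vals:
        return float("nan")
    if any(math.isinf(v) for v in vals):
        return math.inf
    return float(np.mean(vals))


def anchored_metrics(
    per_anchor: Mapping[str, tuple[float, float, float]],
) -> SynergyMetrics:
    """Average the three outcome metrics over anchor concentrations.

    Each averaged metric is the arithmetic mean over the anchors where
    it is defined; +inf propagates (mean with inf = inf).
    """
    if not per_anchor:
        raise InsufficientDataError("no anchors with defined metrics")
    de = _mean_defined([v[0] for v in per_anchor.values()])
    di = _mean_defined([v[1] for v in per_anchor.values()])
    bl = _mean_defined([v[2] for v in per_anchor.values()])
    return SynergyMetrics(delta_emax=de, delta_ic50=di, bliss_avg=bl,
                          per_anchor=dict(per_anchor))


def select_hits(
    m: SynergyMetrics,
    fold_change_threshold: float = FOLD_CHANGE_THRESHOLD,
    bliss_threshold: float = BLISS_THRESHOLD,
) -> bool:
    """Hit iff ΔEmax > 5 or ΔIC50 > 5 or average Bliss > 0 (strict).

    NaN metrics never satisfy a criterion; +inf always does.
    """
    def gt(value: float, threshold: float) -> bool:
        return (not math.isnan(value)) and value > threshold

    return (gt(m.delta_emax, fold_change_threshold)
            or gt(m.delta_ic50, fold_change_threshold)
            or gt(m.bliss_avg, bliss_threshold))


def max_effective_synergy(
    viability: np.ndarray,
    excess: np.ndarray,
    viability_cutoff: float = EFFECTIVE_VIABILITY_CUTOFF,
) -> float:
    """Highest Bliss excess among cells with observed viability < 50%.

    NaN (undefined marker) when no cell qualifies.
    """
    viability = np.asarray(viability, dtype=float)
    excess = np.asarray(excess, dtype=float)
    if viability.shape != excess.shape:
        raise ValidationError("viability and excess grids must align")
    mask = np.isfinite(excess) & np.isfinite(viability) & (viability < viability_cutoff)
    if not mask.any():
        return float("nan")
    return float(np.max(excess[mask]))


def cross_entity_overlap(
    hits: Mapping[str, Mapping[str, bool]],
) -> set[str]:
    """Library compounds flagged as hits in every provided cell line.

    ``hits`` maps cell line -> {compound: is_hit}.  Compounds absent
    from a line's table were not screened there and are excluded from
    that line's domain rather than counted as misses.
    """
    if len(hits) < 2:
        raise ValidationError("need hit tables for >= 2 cell lines")
    union: set[str] = set()
    for table in hits.values():
        union |= set(table)
    if not union:
        raise ValidationError("empty compound library across hit tables")
    overlap = set()
    for compound in union:
        flags = [table[compound] for table in hits.values() if compound in table]
        if flags and all(flags):
            overlap.add(compound)
    return overlap


# ---------------------------------------------------------------------------
# Anchored-screen orchestration
# ---------------------------------------------------------------------------

SYNERGY_COLUMNS = [
    "cell_line", "anchor_compound", "library_compound",
    "delta_emax", "delta_ic50", "bliss_avg",
    "max_effective_synergy", "is_hit", "n_anchors",
]


def score_combination_matrix(m: CombinationMatrix) -> dict:
    """Average Bliss and maximum effective synergy for a full dose grid."""
    excess = bliss_excess_matrix(m)
    return {
        "bliss_avg": average_bliss(excess),
        "max_effective_synergy": max_effective_synergy(m.viability, excess),
        "n_defined": int(np.isfinite(excess).sum()),
    }


def score_anchored_screen(
    points: pd.DataFrame,
    fold_change_threshold: float = FOLD_CHANGE_THRESHOLD,
    bliss_threshold: float = BLISS_THRESHOLD,
    normalize_to_anchor: bool = False,
) -> pd.DataFrame:
    """Score every (cell line, library compound) of an anchored screen.

    ``points`` is a replicate-averaged viability frame (combination
    schema) containing, per cell line and anchor dose: combination rows
    (dose > 0 and anchor_dose > 0), library monotherapy margins
    (anchor_dose == 0) and anchor monotherapy margins (rows whose
    ``compound`` is the anchor itself with dose == 0).

    With ``normalize_to_anchor`` the combination series is divided by
    the anchor-alone viability before curve fitting and ΔEmax, so both
    fold changes measure the effect beyond the anchor's own; Bliss
    excess always uses the untreated-control scale.
    """
    rows = []
    for cell_line, cdf in points.groupby("cell_line", sort=False):
        anchor_names = cdf.loc[cdf["anchor_dose"] > 0, "anchor_compound"].dropna().unique()
        for anchor_name in anchor_names:
            adf = cdf[(cdf["anchor_compound"] == anchor_name) | (cdf["anchor_dose"] == 0)]
            anchor_doses = np.sort(
                adf.loc[adf["anchor_dose"] > 0, "anchor_dose"].unique()
            )
            # anchor-alone margins, one per anchor dose
            anchor_mono = {
                float(r["anchor_dose"]): float(r["viability"])
                for _, r in adf[(adf["compound"] == anchor_name)
                                & (adf["dose"] == 0)].iterrows()
            }
            lib_compounds = [
                c for c in adf.loc[adf["dose"] > 0, "compound"].unique()
                if c != anchor_name
            ]
            for lib in lib_compounds:
                rows.append(_score_one_combination(
                    cell_line, anchor_name, lib, adf, anchor_doses, anchor_mono,
                    fold_change_threshold, bliss_threshold, normalize_to_anchor,
                ))
    return pd.DataFrame(rows, columns=SYNERGY_COLUMNS)


def _score_one_combination(
    cell_line, anchor_name, lib, adf, anchor_doses, anchor_mono,
    fc_thr, bliss_thr, normalize_to_anchor,
) -> dict:
    mono = (adf[(adf["compound"] == lib) & (adf["anchor_dose"] == 0)
                & (adf["dose"] > 0)]
            .sort_values("dose"))
    mono_doses = mono["dose"].to_numpy()
    mono_viab = mono["viability"].to_numpy()
    mono_fit = fit_4pl(mono_doses, mono_viab)

    per_anchor: dict[str, tuple[float, float, float]] = {}
    viab_cells, excess_cells = [], []
    for a_dose in anchor_doses:
        combo = (adf[(adf["compound"] == lib) & (adf["anchor_dose"] == a_dose)
                     & (adf["dose"] > 0)]
                 .sort_values("dose"))
        if combo.empty:
            continue
        c_doses = combo["dose"].to_numpy()
        c_viab = combo["viability"].to_numpy()
        v_anchor = anchor_mono.get(float(a_dose), float("nan"))

        # Bliss excess on the untreated-control scale (1 x K grid).
        mono_at = pd.Series(mono_viab, index=mono_doses).reindex(c_doses)
        grid = CombinationMatrix(
            cell_line=cell_line, compound_a=anchor_name, compound_b=lib,
            doses_a=np.array([a_dose]), doses_b=c_doses,
            viability=c_viab[None, :],
            mono_a=np.array([v_anchor]), mono_b=mono_at.to_numpy(),
        )
        excess = bliss_excess_matrix(grid)
        viab_cells.append(c_viab)
        excess_cells.append(excess.ravel())

        fit_viab = c_viab / v_anchor if (normalize_to_anchor
                                         and np.isfinite(v_anchor)
                                         and v_anchor > 0) else c_viab
        combo_fit = fit_4pl(c_doses, fit_viab)
        de = delta_emax(mono_viab[-1], fit_viab[-1])
        di = delta_ic50(mono_fit, combo_fit)
        per_anchor[f"{a_dose:g}"] = (de, di, average_bliss(excess))

    metrics = anchored_metrics(per_anchor)
    all_viab = np.concatenate(viab_cells)
    all_excess = np.concatenate(excess_cells)
    metrics.max_effective_synergy = max_effective_synergy(all_viab, all_excess)
    metrics.is_hit = select_hits(metrics, fc_thr, bliss_thr)
    return {
        "cell_line": cell_line, "anchor_compound": anchor_name,
        "library_compound": lib,
        "delta_emax": metrics.delta_emax, "delta_ic50": metrics.delta_ic50,
        "bliss_avg": metrics.bliss_avg,
        "max_effective_synergy": metrics.max_effective_synergy,
        "is_hit": metrics.is_hit, "n_anchors": len(per_anchor),
    }
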