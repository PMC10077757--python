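"""Differential drug-sensitivity testing and set enrichment.

Two building blocks are combined into the analysis pipelines:

1. **Moderated t-statistics.**  Each feature (a compound's AUC profile,
   or a gene's expression profile, across cell lines) is fit by
   ordinary least squares against a shared design matrix.  Residual
   variances are then shrunk toward a pooled prior by empirical Bayes:
   assuming s^2 ~ s0^2 * F(d, d0), the prior degrees of freedom d0 and
   prior variance s0^2 are estimated by method of moments on log s^2,
   and the posterior variance s~^2 = (d0*s0^2 + d*s^2) / (d0 + d)
   replaces s^2 in the t-statistic, which then has d + d0 degrees of
   freedom.  With a single feature (or d0 = 0) this reduces exactly to
   the ordinary t-test.

2. **Weighted-KS set enrichment.**  Features are ranked by the
   moderated t (descending, ties broken lexicographically).  For a set,
   a running sum increments by |t|^p / sum_set |t|^p at member
   positions and decrements by 1/(N - |set|) elsewhere; the enrichment
   score (ES) is the signed extremum.  Significance comes from
   member-label permutations: random same-size sets drawn from the
   ranked universe give the null ES distribution, NES = ES divided by
   the mean |null ES| of matching sign, and
   p = (1 + #{null same sign, as-or-more extreme}) / (1 + #{null same sign}).
   Benjamini-Hochberg adjusts across sets.

Sign convention for the pediatric-vs-adult contrast: the tested
coefficient is the pediatric indicator on AUC, so compound sets whose
members have *lower* AUC (more sensitivity) in pediatric lines receive
negative NES.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from synscreen.errors import InsufficientDataError, ValidationError
from synscreen.screen_io import SensitivityDataset, SetCollection

logger = logging.getLogger(__name__)

DEFAULT_MIN_SET_SIZE = 5


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def build_group_design(flags: pd.Series, name: str = "group") -> pd.DataFrame:
    """Intercept + 0/1 indicator design from a boolean series."""
    design = pd.DataFrame(
        {"intercept": 1.0, name: flags.astype(float)}, index=flags.index
    )
    _check_full_rank(design)
    return design


def build_continuous_design(
    covariate: pd.Series,
    categorical: pd.Series | None = None,
    name: str = "covariate",
) -> pd.DataFrame:
    """Intercept + continuous covariate (+ dummy-coded categorical)."""
    design = pd.DataFrame(
        {"intercept": 1.0, name: covariate.astype(float)}, index=covariate.index
    )
    if categorical is not None and categorical.nunique() > 1:
        dummies = pd.get_dummies(categorical, prefix=categorical.name or "cat",
                                 drop_first=True, dtype=float)
        design = pd.concat([design, dummies.loc[design.index]], axis=1)
    _check_full_rank(design)
    return design


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores rank
        collinear = [
            col for col in design.columns
            if np.linalg.matrix_rank(design.drop(columns=[col]).to_numpy(float)) == rank
        ]
        raise ValidationError(f"design matrix is rank-deficient; "
                              f"collinear columns: {collinear}")


# ---------------------------------------------------------------------------
# Moderated t-statistics
# ---------------------------------------------------------------------------

@dataclass
class ModeratedTStats:
    """Per-feature moderated statistics plus the global prior.

    ``table`` columns: coef, se, s2, df, s2_post, t, df_total, pval.
    ``d0`` may be inf (complete shrinkage: all s~^2 = s0^2).
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float

    @property
    def t(self) -> pd.Series:
        return self.table["t"]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of s^2 ~ s0^2 F(df, d0) on log variances.

    Returns (d0, s0_sq); d0 = inf when the log-variances are less
    dispersed than expected under equal true variances.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return 0.0, float(np.median(s2[ok])) if ok.any() else float("nan")
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    emean = float(np.mean(e))
    n = e.size
    evar = float(np.sum((e - emean) ** 2) / (n - 1)) - float(
        np.mean(special.polygamma(1, df[ok] / 2.0))
    )
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def squeeze_var(s2: np.ndarray, df: np.ndarray,
                d0: float, s0_sq: float) -> np.ndarray:
    """Posterior variances (d0*s0^2 + df*s^2) / (d0 + df)."""
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s0_sq)
    if d0 == 0:
        return s2.copy()
    return (d0 * s0_sq + df * s2) / (d0 + df)


def moderated_t(
    responses: pd.DataFrame,
    design: pd.DataFrame,
    coef: str,
    group: str | None = None,
    min_per_group: int = 3,
    d0_override: float | None = None,
) -> ModeratedTStats:
    """Empirical-Bayes moderated t for one design coefficient.

    Parameters
    ----------
    responses
        Feature x sample matrix (NaN = missing observation).
    design
        Sample x covariate matrix; rows must align with ``responses``
        columns.  Must be full rank.
    coef
        Name of the coefficient of interest.
    group
        Optional name of a 0/1 design column; features with fewer than
        ``min_per_group`` observations in either group are dropped
        (logged).  Without ``group``, features need at least
        p + ``min_per_group`` observations overall.
    d0_override
        Inject prior degrees of freedom directly (0 disables
        moderation; inf shrinks fully); mainly for verification.
    """
    if not responses.columns.equals(design.index):
        design = design.loc[responses.columns]
    _check_full_rank(design)
    if coef not in design.columns:
        raise ValidationError(f"coefficient {coef!r} not in design columns")
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise InsufficientDataError(
            f"{n} samples cannot identify {p} design columns with residual df"
        )
    j = design.columns.get_loc(coef)
    Y = responses.to_numpy(dtype=float)

    complete = ~np.isnan(Y).any()
    feats, coefs, ses, s2s, dfs = [], [], [], [], []
    if complete:
        XtX_inv = np.linalg.inv(X.T @ X)
        pinv = XtX_inv @ X.T
        B = Y @ pinv.T                       # features x p
        resid = Y - B @ X.T
        df = n - p
        s2 = np.sum(resid ** 2, axis=1) / df
        cjj = XtX_inv[j, j]
        feats = list(responses.index)
        coefs = B[:, j]
        s2s = s2
        ses = np.sqrt(np.maximum(s2, 0) * cjj)
        dfs = np.full(len(feats), float(df))
    else:
        dropped = 0
        for fid, y in zip(responses.index, Y):
            mask = np.isfinite(y)
            if group is not None:
                g = X[mask, design.columns.get_loc(group)]
                if (g == 1).sum() < min_per_group or (g == 0).sum() < min_per_group:
                    dropped += 1
                    continue
            elif mask.sum() < p + min_per_group:
                dropped += 1
                continue
            Xm = X[mask]
            if np.linalg.matrix_rank(Xm) < p or mask.sum() <= p:
                dropped += 1
                continue
            XtX_inv = np.linalg.inv(Xm.T @ Xm)
            b = XtX_inv @ Xm.T @ y[mask]
            resid = y[mask] - Xm @ b
            df = mask.sum() - p
            s2 = float(resid @ resid) / df
            feats.append(fid)
            coefs.append(b[j])
            s2s.append(s2)
            ses.append(np.sqrt(max(s2, 0) * XtX_inv[j, j]))
            dfs.append(float(df))
        if dropped:
            logger.warning("moderated_t: dropped %d feature(s) below the "
                           "observation minimum", dropped)
        coefs, ses = np.asarray(coefs), np.asarray(ses)
        s2s, dfs = np.asarray(s2s), np.asarray(dfs)
    if len(feats) == 0:
        raise InsufficientDataError("no features with enough observations")

    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_sq = fit_f_dist(s2s, dfs)
    elif len(feats) < 2:
        d0, s0_sq = 0.0, float(s2s[0])  # single feature: ordinary t
    else:
        d0, s0_sq = fit_f_dist(s2s, dfs)
    s2_post = squeeze_var(s2s, dfs, d0, s0_sq)

    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.sqrt(np.where(s2s > 0, s2_post / s2s, np.nan))
        t = np.where(ses > 0, coefs / (ses * scale), np.nan)
    df_total = dfs + (0.0 if np.isinf(d0) else d0)
    df_eff = np.where(np.isinf(df_total), 1e6, df_total)
    pvals = 2.0 * stats.t.sf(np.abs(t), df_eff)

    table = pd.DataFrame({
        "coef": coefs, "se": ses, "s2": s2s, "df": dfs,
        "s2_post": s2_post, "t": t, "df_total": df_total, "pval": pvals,
    }, index=pd.Index(feats, name=responses.index.name or "feature"))
    return ModeratedTStats(table=table, d0=float(d0), s0_sq=float(s0_sq))


def rank_features(stats_or_t: ModeratedTStats | pd.Series) -> pd.Series:
    """Order features by t, descending; ties broken lexicographically.

    Features with non-finite t are dropped with a logged warning.
    Returns a Series (index = feature, values = t) in ranked order.
    """
    t = stats_or_t.t if isinstance(stats_or_t, ModeratedTStats) else stats_or_t
    finite = t[np.isfinite(t.to_numpy(dtype=float))]
    if len(finite) < len(t):
        logger.warning("rank_features: dropped %d feature(s) with non-finite t",
                       len(t) - len(finite))
    if len(finite) < 2:
        raise InsufficientDataError("need >= 2 features with finite t to rank")
    order = sorted(finite.index, key=lambda f: (-finite[f], str(f)))
    return finite.loc[order]


# ---------------------------------------------------------------------------
# Weighted-KS enrichment
# ---------------------------------------------------------------------------

def enrichment_score(
    ranking: pd.Series,
    members,
    weight: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted Kolmogorov-Smirnov enrichment score for one set.

    ``ranking`` is an ordered Series (feature -> t, descending).
    Returns (es, running_sum, leading_edge); es is the signed extremum
    of the running sum and lies in [-1, 1].  The leading edge is the
    member prefix up to the extremum (suffix from it for negative ES).
    """
    ids = ranking.index.to_numpy()
    t = ranking.to_numpy(dtype=float)
    n = ids.size
    member_set = set(members)
    is_hit = np.fromiter((f in member_set for f in ids), bool, count=n)
    k = int(is_hit.sum())
    if k == 0:
        return float("nan"), np.zeros(n), []
    if k >= n:
        # degenerate: every ranked feature is a member
        return 1.0, np.cumsum(np.abs(t) ** weight / np.sum(np.abs(t) ** weight)), list(ids)
    w = np.abs(t) ** weight
    hit_w = np.where(is_hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = is_hit.astype(float)
        denom = float(k)
    steps = hit_w / denom - (~is_hit) / float(n - k)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        es = float(running[i_max])
        leading = [f for f in ids[: i_max + 1] if f in member_set]
    else:
        es = float(running[i_min])
        leading = [f for f in ids[i_min:] if f in member_set]
    return es, running, leading


def _null_es(
    abs_w: np.ndarray, size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES for random member sets of a given size (vectorized).

    ``abs_w`` are the |t|^p weights in ranked order.  For each
    permutation a size-``size`` subset of positions is drawn without
    replacement; the running-sum extremum only needs the sorted hit
    positions and their cumulative weights.
    """
    n = abs_w.size
    positions = np.empty((n_perm, size), dtype=np.int64)
    for i in range(n_perm):
        positions[i] = rng.choice(n, size=size, replace=False)
    positions.sort(axis=1)
    w = abs_w[positions]
    denom = w.sum(axis=1, keepdims=True)
    zero = denom[:, 0] == 0
    if zero.any():
        w[zero] = 1.0
        denom[zero] = float(size)
    cum_w = np.cumsum(w, axis=1) / denom
    miss = 1.0 / (n - size)
    ks = np.arange(1, size + 1)
    # running sum just after hit k and just before hit k
    after = cum_w - (positions + 1 - ks[None, :] + 1) * miss + miss
    before = np.concatenate(
        [np.zeros((n_perm, 1)), cum_w[:, :-1]], axis=1
    ) - (positions - ks[None, :] + 1) * miss
    hi = after.max(axis=1)
    lo = np.minimum(before.min(axis=1), 0.0)
    return np.where(hi >= -lo, hi, lo)


ENRICHMENT_COLUMNS = ["set", "es", "nes", "pval", "padj", "size", "leading_edge"]


def permutation_test(
    ranking: pd.Series,
    sets: SetCollection,
    n_perm: int = 1000,
    seed: int | None = None,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Permutation-based enrichment over a collection of sets.

    Null scores come from random member-label sets of equal size drawn
    from the ranked universe.  NES divides ES by the mean |null ES| of
    matching sign; the p-value counts same-sign null scores at least as
    extreme, with the +1 guard making the minimum attainable p
    1/(1 + #same-sign nulls).  Reproducible given ``seed``.
    """
    if n_perm < 100:
        raise ValidationError(f"n_perm must be >= 100, got {n_perm}")
    rng = np.random.default_rng(seed)
    universe = set(ranking.index)
    abs_w = np.abs(ranking.to_numpy(dtype=float)) ** weight

    sized: dict[int, list[str]] = {}
    skipped = 0
    results = []
    for name, members in sets.items():
        present = [m for m in members if m in universe]
        if len(present) < min_size or len(present) >= len(ranking):
            skipped += 1
            continue
        sized.setdefault(len(present), []).append(name)
        es, _, leading = enrichment_score(ranking, present, weight)
        results.append({"set": name, "es": es, "size": len(present),
                        "leading_edge": leading})
    if skipped:
        logger.info("permutation_test: %d set(s) below min_size %d or "
                    "spanning the whole ranking", skipped, min_size)
    if not results:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)

    null_by_size = {
        size: _null_es(abs_w, size, n_perm, rng) for size in sorted(sized)
    }
    for rec in results:
        null = null_by_size[rec["size"]]
        es = rec["es"]
        same_sign = null > 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            logger.warning("permutation_test: no same-sign null scores for "
                           "set %s; p set to 1", rec["set"])
            rec["nes"] = float("nan")
            rec["pval"] = 1.0
            continue
        mean_abs = float(np.mean(np.abs(null[same_sign])))
        rec["nes"] = es / mean_abs if mean_abs > 0 else float("nan")
        n_extreme = int((same_sign & (np.abs(null) >= abs(es))).sum())
        rec["pval"] = (1 + n_extreme) / (1 + n_same)

    out = pd.DataFrame(results)
    out["padj"] = bh_adjust(out["pval"].to_numpy())
    out["leading_edge"] = out["leading_edge"].map(";".join)
    return out[ENRICHMENT_COLUMNS].sort_values("pval", kind="stable").reset_index(drop=True)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise ValidationError("p-values must lie in [0, 1]")
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Analysis pipelines
# ---------------------------------------------------------------------------

def compound_set_enrichment(
    dataset: SensitivityDataset,
    grouping: str = "target_pathway",
    n_perm: int = 1000,
    seed: int | None = None,
    min_size: int = DEFAULT_MIN_SET_SIZE,
) -> tuple[pd.DataFrame, ModeratedTStats]:
    """Pediatric-vs-adult differential sensitivity, enriched over compound sets.

    Features are compounds (AUC across cell lines); the design is an
    intercept plus the pediatric indicator.  Negative NES = the set's
    compounds are more potent (lower AUC) in pediatric lines.
    """
    flags = dataset.cell_meta.loc[dataset.cell_lines, "pediatric"].astype(bool)
    if flags.sum() < 3 or (~flags).sum() < 3:
        raise InsufficientDataError("need >= 3 pediatric and >= 3 adult lines")
    design = build_group_design(flags, name="pediatric")
    responses = dataset.auc.T  # compounds x cell lines
    mstats = moderated_t(responses, design, coef="pediatric",
                         group="pediatric", min_per_group=3)
    ranking = rank_features(mstats)
    sets = dataset.compound_sets(grouping)
    res = permutation_test(ranking, sets, n_perm=n_perm, seed=seed,
                           min_size=min_size)
    return res, mstats


def biomarker_gsea(
    expression: pd.DataFrame,
    dataset: SensitivityDataset,
    compound: str,
    genesets: SetCollection,
    n_perm: int = 1000,
    seed: int | None = None,
    min_size: int = DEFAULT_MIN_SET_SIZE,
) -> tuple[pd.DataFrame, ModeratedTStats]:
    """Gene-set enrichment against a compound's AUC as continuous covariate.

    Genes are ranked by the moderated t of the AUC coefficient in a
    per-gene model expression ~ AUC + tumor_type.  Negative t means
    higher expression goes with lower AUC, i.e. greater sensitivity.
    """
    if compound not in dataset.compounds:
        raise ValidationError(f"compound {compound!r} absent from dataset")
    auc = dataset.auc[compound].dropna()
    lines = expression.columns.intersection(auc.index)
    if len(lines) < 4:
        raise InsufficientDataError("too few cell lines with both expression and AUC")
    tumor = dataset.cell_meta.loc[lines, "tumor_type"]
    design = build_continuous_design(auc.loc[lines], tumor, name="auc")
    mstats = moderated_t(expression[lines], design, coef="auc")
    ranking = rank_features(mstats)
    res = permutation_test(ranking, genesets, n_perm=n_perm, seed=seed,
                           min_size=min_size)
    return res, mstats


def mutation_association(
    dataset: SensitivityDataset,
    compound: str,
    mutation_flag: str,
) -> dict:
    """AUC summaries by mutation status + two-sided rank-sum p-value.

    A convenience view of the same differential machinery with a binary
    covariate; uses the exact Wilcoxon rank-sum distribution where
    feasible.
    """
    if compound not in dataset.compounds:
        raise ValidationError(f"compound {compound!r} absent from dataset")
    if mutation_flag not in dataset.cell_meta.columns:
        raise ValidationError(f"mutation flag {mutation_flag!r} not in cell_meta")
    flags = dataset.cell_meta.loc[dataset.cell_lines, mutation_flag].astype(bool)
    auc = dataset.auc[compound]
    mut = auc[flags].dropna().to_numpy()
    wt = auc[~flags].dropna().to_numpy()
    if mut.size == 0 or wt.size == 0:
        raise InsufficientDataError("both mutation groups must be non-empty")
    res = stats.mannwhitneyu(mut, wt, alternative="two-sided", method="auto")
    return {
        "compound": compound, "mutation": mutation_flag,
        "n_mutant": int(mut.size), "n_wildtype": int(wt.size),
        "median_mutant": float(np.median(mut)),
        "median_wildtype": float(np.median(wt)),
        "mean_mutant": float(np.mean(mut)),
        "mean_wildtype": float(np.mean(wt)),
        "pval": float(res.pvalue),
    }


def target_level_summary(mstats: ModeratedTStats,
                         compound_meta: pd.DataFrame,
                         padj: pd.Series | None = None) -> pd.DataFrame:
    """Per-target aggregation of compound-level statistics.

    Averages the moderated t within each annotated target and carries
    the minimum adjusted p — a presentation convenience for volcano-style
    overviews, not an inferential procedure.
    """
    df = mstats.table.join(compound_meta["target"], how="inner")
    if padj is None:
        padj = pd.Series(bh_adjust(df["pval"].to_numpy()), index=df.index)
    df = df.assign(padj=padj)
    out = df.groupby("target").agg(
        mean_t=("t", "mean"), n_compounds=("t", "size"), min_padj=("padj", "min")
    )
    return out.sort_values("mean_t")
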