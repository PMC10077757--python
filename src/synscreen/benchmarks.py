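"""Property benchmarks: recovery, null behavior and oracle agreement.

Each function simulates the relevant study design with the package's
own generators, runs the analysis end to end, and measures how well
known ground truth (or an independent brute-force oracle) is recovered.
The oracles here are deliberately naive re-implementations — log-space
bisection for the IC50 inversion, a pure-Python running sum for the
enrichment score, a double loop for the maximum effective synergy — so
they share no code path with the implementations they check.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from synscreen import enrichment, screen_io, simulate, synergy
from synscreen.dose_response import FourPLParams, fit_4pl
from synscreen.simulate import DOSE_GRID_6, NoiseModel


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def bisect_ic50(params: FourPLParams, cmin: float, cmax: float) -> float | None:
    """Log-space bisection of V(c) = 0.5; None when there is no crossing."""
    lo, hi = np.log10(cmin), np.log10(cmax)
    f = lambda x: params.viability(10.0 ** x) - 0.5
    grid = np.linspace(lo, hi, 2049)
    vals = f(grid)
    if vals[0] < 0:
        return 10.0 ** lo
    crossings = np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))
    if crossings.size == 0:
        return None
    a, b = grid[crossings[0]], grid[crossings[0] + 1]
    for _ in range(200):
        m = 0.5 * (a + b)
        if f(a) * f(m) <= 0:
            b = m
        else:
            a = m
    return 10.0 ** (0.5 * (a + b))


def brute_force_es(ranking: pd.Series, members, weight: float = 1.0) -> float:
    """Running-sum enrichment score by direct iteration."""
    member_set = set(members)
    t = ranking.to_numpy(dtype=float)
    ids = list(ranking.index)
    in_set = [f in member_set for f in ids]
    denom = sum(abs(ti) ** weight for ti, m in zip(t, in_set) if m)
    n_miss = len(ids) - sum(in_set)
    best = worst = total = 0.0
    first = True
    for ti, m in zip(t, in_set):
        total += abs(ti) ** weight / denom if m else -1.0 / n_miss
        if first:
            best = worst = total
            first = False
        best = max(best, total)
        worst = min(worst, total)
    return best if best >= -worst else worst


def brute_force_max_effective(viability: np.ndarray, excess: np.ndarray,
                              cutoff: float = 0.5) -> float:
    best = np.nan
    rows, cols = viability.shape
    for i in range(rows):
        for j in range(cols):
            if viability[i, j] < cutoff and np.isfinite(excess[i, j]):
                if np.isnan(best) or excess[i, j] > best:
                    best = excess[i, j]
    return best


# ---------------------------------------------------------------------------
# Benchmarks
# ---------------------------------------------------------------------------

def fourpl_recovery(n_curves: int = 200, sigma: float = 0.05,
                    replicates: int = 2, seed: int = 0) -> dict:
    """Median relative IC50/AUC error over simulated decade-grid screens."""
    rng = np.random.default_rng(seed)
    ic50_err, auc_err = [], []
    grid = DOSE_GRID_6
    for _ in range(n_curves):
        truth = FourPLParams(e0=1.0, einf=float(rng.uniform(0, 0.3)),
                             ec50=float(10 ** rng.uniform(0.5, 3.5)),
                             hill=float(rng.uniform(0.8, 2.5)))
        v = truth.viability(grid)
        y = np.mean([v + rng.normal(0, sigma, grid.size)
                     for _ in range(replicates)], axis=0)
        fit = fit_4pl(grid, y)
        true_ic50 = bisect_ic50(truth, grid[0], grid[-1])
        fine = np.linspace(np.log10(grid[0]), np.log10(grid[-1]), 20001)
        true_auc = float(np.trapezoid(
            np.clip(truth.viability(10 ** fine), 0, 1), fine)
            / (fine[-1] - fine[0]))
        if fit.ic50_censor is None and true_ic50 is not None:
            ic50_err.append(abs(fit.ic50 - true_ic50) / true_ic50)
        auc_err.append(abs(fit.auc - true_auc) / true_auc)
    return {
        "median_ic50_rel_err": float(np.median(ic50_err)),
        "median_auc_rel_err": float(np.median(auc_err)),
        "n_curves": n_curves,
        "n_ic50_evaluable": len(ic50_err),
    }


def ic50_oracle_agreement(n_draws: int = 1000, seed: int = 0) -> dict:
    """Max relative deviation of the closed-form absolute IC50 from bisection."""
    from synscreen.dose_response import absolute_ic50
    rng = np.random.default_rng(seed)
    worst = 0.0
    checked = 0
    cmin, cmax = 0.1, 1e4
    for _ in range(n_draws):
        params = FourPLParams(
            e0=float(rng.uniform(0.8, 1.2)),
            einf=float(rng.uniform(-0.1, 0.45)),
            ec50=float(10 ** rng.uniform(-1, 4)),
            hill=float(rng.uniform(0.3, 5.0)))
        ic50, censor = absolute_ic50(params, cmin, cmax)
        oracle = bisect_ic50(params, cmin, cmax)
        if censor is None and oracle is not None:
            worst = max(worst, abs(ic50 - oracle) / oracle)
            checked += 1
    return {"max_rel_deviation": float(worst), "n_checked": checked,
            "n_draws": n_draws}


def _grid_from_points(points: pd.DataFrame) -> synergy.CombinationMatrix:
    points = points.copy()
    points["anchor_compound"] = points["anchor_compound"].fillna("")
    combo = points[(points["anchor_dose"] > 0) & (points["dose"] > 0)]
    doses_a = np.sort(combo["anchor_dose"].unique())
    doses_b = np.sort(combo["dose"].unique())
    grid = (combo.pivot(index="anchor_dose", columns="dose",
                        values="viability").loc[doses_a, doses_b].to_numpy())
    mono_a = (points[(points["dose"] == 0) & (points["anchor_dose"] > 0)]
              .set_index("anchor_dose")["viability"].loc[doses_a].to_numpy())
    mono_b = (points[(points["dose"] > 0) & (points["anchor_dose"] == 0)]
              .set_index("dose")["viability"].loc[doses_b].to_numpy())
    return synergy.CombinationMatrix(
        cell_line="L", compound_a="A", compound_b="B",
        doses_a=doses_a, doses_b=doses_b, viability=grid,
        mono_a=mono_a, mono_b=mono_b)


def bliss_null_and_recovery(n_grids: int = 50, delta: float = 0.2,
                            sigma: float = 0.05, seed: int = 0) -> dict:
    """Exact zero under noise-free independence; planted-delta recovery."""
    df, _ = simulate.gen_combination_matrix(
        delta=0.0, noise=NoiseModel(sigma=0.0, replicates=1), seed=seed)
    null_avg = synergy.average_bliss(synergy.bliss_excess_matrix(
        _grid_from_points(screen_io.normalize_viability(df))))

    recovered = []
    for i in range(n_grids):
        df, _ = simulate.gen_combination_matrix(
            delta=delta, noise=NoiseModel(sigma=sigma, replicates=2),
            seed=seed + 1 + i)
        excess = synergy.bliss_excess_matrix(
            _grid_from_points(screen_io.normalize_viability(df)))
        recovered.append(synergy.average_bliss(excess))
    return {
        "null_average_bliss": float(null_avg),
        "recovered_mean": float(np.mean(recovered)),
        "bias": float(np.mean(recovered) - delta),
        "n_grids": n_grids, "delta": delta,
    }


def hit_selection(n_compounds: int = 198, n_planted: int = 8,
                  delta: float = 0.2, sigma: float = 0.05,
                  seed: int = 0) -> dict:
    """Planted-compound recall and the null Bliss-rule false-positive rate."""
    noise = NoiseModel(sigma=sigma, replicates=2)
    df, truth = simulate.gen_anchored_library_screen(
        n_compounds=n_compounds, n_synergistic=n_planted, delta=delta,
        noise=noise, seed=seed)
    scores = synergy.score_anchored_screen(
        screen_io.normalize_viability(df))
    planted = set(truth["synergistic_compounds"])
    flagged = set(scores.loc[scores["is_hit"], "library_compound"])
    recall = len(planted & flagged)

    df0, _ = simulate.gen_anchored_library_screen(
        n_compounds=n_compounds, n_synergistic=0, delta=delta,
        noise=noise, seed=seed + 1)
    scores0 = synergy.score_anchored_screen(
        screen_io.normalize_viability(df0))
    bliss_fpr = float((scores0["bliss_avg"] > 0).mean())
    return {
        "recall": recall, "n_planted": n_planted,
        "bliss_false_positive_rate": bliss_fpr,
        "null_mean_bliss": float(scores0["bliss_avg"].mean()),
        "n_compounds": n_compounds,
    }


def max_synergy_oracle(n_grids: int = 500, seed: int = 0) -> dict:
    """Vectorized maximum effective synergy vs a brute-force double loop."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_grids):
        viability = rng.uniform(0, 1, (10, 10))
        excess = rng.normal(0, 0.2, (10, 10))
        got = synergy.max_effective_synergy(viability, excess)
        ref = brute_force_max_effective(viability, excess)
        same = (np.isnan(got) and np.isnan(ref)) or got == ref
        mismatches += 0 if same else 1
    return {"n_mismatch": mismatches, "n_grids": n_grids}


def es_oracle(n_instances: int = 1000, seed: int = 0) -> dict:
    """Weighted-KS score vs the pure-Python running-sum oracle."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(20, 201))
        ids = [f"g{i:03d}" for i in range(n)]
        ranking = enrichment.rank_features(
            pd.Series(rng.normal(0, 1, n), index=ids))
        size = int(rng.integers(1, max(2, n // 3)))
        members = set(rng.choice(ids, size=size, replace=False).tolist())
        es, _, _ = enrichment.enrichment_score(ranking, members)
        worst = max(worst, abs(es - brute_force_es(ranking, members)))
    return {"max_abs_diff": float(worst), "n_instances": n_instances}


def type1_control(n_sets: int = 200, n_perm: int = 1000,
                  n_features: int = 1000, seed: int = 0) -> dict:
    """Fraction of sets with p < 0.05 under a fully null ranking."""
    rng = np.random.default_rng(seed)
    ids = [f"f{i:04d}" for i in range(n_features)]
    ranking = enrichment.rank_features(
        pd.Series(rng.normal(0, 1, n_features), index=ids))
    sets = simulate.gen_gene_sets(ids, n_sets=n_sets, size_range=(10, 50),
                                  seed=seed + 1, prefix="NULL")
    res = enrichment.permutation_test(ranking, sets, n_perm=n_perm,
                                      seed=seed + 2)
    return {"frac_p_below_005": float((res["pval"] < 0.05).mean()),
            "n_sets": int(len(res)), "n_perm": n_perm}


def planted_pathway_recovery(n_ped: int = 40, n_adult: int = 200,
                             shift: float = -0.15,
                             pathway: str = "DNA replication",
                             n_perm: int = 1000, seed: int = 0) -> dict:
    """Compound-set enrichment must put the shifted pathway first."""
    ds, _ = simulate.gen_sensitivity_dataset(
        n_ped=n_ped, n_adult=n_adult, shifted_pathways={pathway: shift},
        seed=seed)
    res, _ = enrichment.compound_set_enrichment(ds, n_perm=n_perm, seed=seed)
    res = res.assign(abs_nes=res["nes"].abs()).sort_values(
        "abs_nes", ascending=False).reset_index(drop=True)
    rank = int(res.index[res["set"] == pathway][0]) + 1
    row = res[res["set"] == pathway].iloc[0]
    return {"rank_by_abs_nes": rank, "nes": float(row["nes"]),
            "padj": float(row["padj"]), "n_sets": int(len(res))}


def biomarker_recovery(n_lines: int = 60, n_genes: int = 2000,
                       beta: float = 1.0, n_perm: int = 5000,
                       n_null_reps: int = 50, null_n_perm: int = 500,
                       seed: int = 0) -> dict:
    """Planted gene set vs a compound's AUC; uniform p under beta = 0.

    The planted set's expression follows -beta * AUC + N(0, 1), beta
    equal to the noise sd.  The null check repeats the analysis with
    beta = 0 and KS-tests the planted set's p-values against U(0, 1).
    """
    ds, _ = simulate.gen_sensitivity_dataset(n_ped=n_lines, n_adult=0,
                                             seed=seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    sets = simulate.gen_gene_sets(genes, n_sets=50, size_range=(20, 80),
                                  seed=seed + 1)
    expr, _ = simulate.gen_expression_dataset(
        n_genes=n_genes, planted_sets=sets, betas={"SET001": beta},
        dataset=ds, compound="CPD001", noise_sd=1.0, seed=seed + 2)
    res, _ = enrichment.biomarker_gsea(expr, ds, "CPD001", sets,
                                       n_perm=n_perm, seed=seed + 3)
    planted = res[res["set"] == "SET001"].iloc[0]

    single = screen_io.SetCollection.from_dict({"SET001": sets["SET001"]})
    null_ps = []
    for rep in range(n_null_reps):
        expr0, _ = simulate.gen_expression_dataset(
            n_genes=n_genes, planted_sets=sets, betas={"SET001": 0.0},
            dataset=ds, compound="CPD001", noise_sd=1.0,
            seed=seed + 10 + rep)
        res0, _ = enrichment.biomarker_gsea(
            expr0, ds, "CPD001", single, n_perm=null_n_perm,
            seed=seed + 10 + rep, min_size=5)
        null_ps.append(float(res0["pval"].iloc[0]))
    ks_p = float(sps.kstest(null_ps, "uniform").pvalue)
    return {"planted_padj": float(planted["padj"]),
            "planted_nes": float(planted["nes"]),
            "null_ks_p": ks_p, "n_null_reps": n_null_reps}


def pipeline_smoke(out_root: str | Path, seed: int = 0) -> dict:
    """Default-design end-to-end run, twice, comparing output hashes."""
    from synscreen.pipeline import run_pipeline, validate_config
    out_root = Path(out_root)
    manifests = []
    for name in ("first", "second"):
        cfg = validate_config({"seed": seed, "out_dir": str(out_root / name)})
        manifests.append(run_pipeline(cfg))
    log = (out_root / "first" / "run.log").read_text()
    required_counts = ["averaged points", "fallback", "combinations scored",
                       "set(s) tested"]
    return {
        "completed": all(m["completed"] for m in manifests),
        "n_outputs": sum(len(v) for v in manifests[0]["stages"].values()),
        "hashes_identical": manifests[0]["stages"] == manifests[1]["stages"],
        "log_counts_present": all(k in log for k in required_counts),
    }
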