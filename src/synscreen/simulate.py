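"""Synthetic screen generators with serialized ground truth.

Every generator emulates one of the study designs the analysis modules
consume and returns its inputs alongside a truth record, so each stage
of the pipeline can be tested against a known answer:

* 6-point log-spaced monotherapy dose grids (0.1 nM - 10 uM),
* 10x10 five-fold combination matrices starting at 0.03 nM,
* 3-anchor x 198-compound anchored library screens,
* an AUC matrix over pediatric + adult cell-line panels with
  group-level pathway sensitivity shifts,
* expression matrices with a gene set planted to track one compound's
  AUC.

Noise is additive Gaussian on the viability fraction (default
sigma = 0.05, a typical MTT-assay coefficient of variation) applied
independently per replicate well (default 2 replicates, matching
replicate-averaged reporting).  Raw signals are produced on an
arbitrary 10,000-unit scale with a constant background offset of
0.2 x scale so that empty wells stay non-negative under the noise
model; plate normalization is affine-invariant, so the offset never
reaches the analysis.  All generators are deterministic given their
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from synscreen.dose_response import FourPLParams
from synscreen.errors import ValidationError
from synscreen.screen_io import SensitivityDataset, SetCollection
from synscreen.synergy import bliss_expected, inhibition

SIGNAL_SCALE = 10_000.0
BACKGROUND = 0.2  # fraction of scale added to every well

#: The 6-point monotherapy grid, nM (0.1 nM ... 10 uM, decade spacing).
DOSE_GRID_6 = np.array([0.1, 1.0, 10.0, 100.0, 1_000.0, 10_000.0])

#: 10 five-fold steps starting at 0.03 nM for combination matrices.
COMBO_GRID_10 = 0.03 * 5.0 ** np.arange(10)

N_CONTROL_WELLS = 16
N_ANCHOR_WELLS = 8


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise on viability, per replicate well."""

    sigma: float = 0.05
    replicates: int = 2

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")


def _signal(viability: np.ndarray) -> np.ndarray:
    return np.maximum(SIGNAL_SCALE * (BACKGROUND + viability), 0.0)


def _control_rows(cell_line: str, rng: np.random.Generator,
                  sigma: float, combination: bool) -> list[dict]:
    rows = []
    for i in range(N_CONTROL_WELLS):
        for role, level in (("pos_control", 1.0), ("neg_control", 0.0)):
            rec = {
                "cell_line": cell_line, "compound": "DMSO" if role == "pos_control" else "EMPTY",
                "dose": 0.0, "replicate": i + 1,
                "signal": float(_signal(np.array(level + rng.normal(0, sigma)))),
                "role": role,
            }
            if combination:
                rec["anchor_compound"] = ""
                rec["anchor_dose"] = 0.0
            rows.append(rec)
    return rows


def _draw_mono_params(rng: np.random.Generator) -> FourPLParams:
    """Monotherapy truth: full-baseline curves with IC50 inside the grid."""
    return FourPLParams(
        e0=1.0,
        einf=float(rng.uniform(0.0, 0.3)),
        ec50=float(10.0 ** rng.uniform(0.5, 3.5)),
        hill=float(rng.uniform(0.8, 2.5)),
    )


def _draw_library_params(rng: np.random.Generator) -> FourPLParams:
    """Library truth: mixed potency, some compounds inactive in range."""
    return FourPLParams(
        e0=1.0,
        einf=float(rng.uniform(0.1, 0.7)),
        ec50=float(10.0 ** rng.uniform(0.5, 5.5)),
        hill=float(rng.uniform(0.8, 2.5)),
    )


def _params_dict(p: FourPLParams) -> dict:
    return {"e0": p.e0, "einf": p.einf, "ec50": p.ec50, "hill": p.hill}


def invert_4pl(params: FourPLParams, viability: float) -> float:
    """Dose at which the true curve crosses a viability level (nM)."""
    e0, einf, h = params.e0, params.einf, params.hill
    if not (einf < viability < e0):
        raise ValidationError(
            f"viability {viability} outside the curve's range ({einf}, {e0})"
        )
    ratio = (e0 - einf) / (viability - einf) - 1.0
    return float(params.ec50 * ratio ** (1.0 / h))


# ---------------------------------------------------------------------------
# Monotherapy screens
# ---------------------------------------------------------------------------

def gen_monotherapy_screen(
    n_lines: int = 5,
    compounds: Sequence[str] | None = None,
    dose_grid: np.ndarray = DOSE_GRID_6,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a monotherapy screen on the 6-point decade grid.

    Returns (well table in the monotherapy schema, truth dict with the
    4PL parameters per cell line x compound).
    """
    dose_grid = np.asarray(dose_grid, dtype=float)
    if np.any(np.diff(dose_grid) <= 0):
        raise ValidationError("dose grid must be strictly increasing")
    if compounds is None:
        compounds = [f"CPD{i + 1:03d}" for i in range(10)]
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    truth: dict = {"kind": "monotherapy", "seed": seed,
                   "sigma": noise.sigma, "replicates": noise.replicates,
                   "dose_grid_nM": dose_grid.tolist(), "curves": {}}
    for li in range(n_lines):
        cell_line = f"LINE{li + 1:03d}"
        rows.extend(_control_rows(cell_line, rng, noise.sigma, combination=False))
        for compound in compounds:
            params = _draw_mono_params(rng)
            truth["curves"][f"{cell_line}|{compound}"] = _params_dict(params)
            v_true = params.viability(dose_grid)
            for rep in range(1, noise.replicates + 1):
                v = v_true + rng.normal(0, noise.sigma, size=dose_grid.size)
                for d, vi in zip(dose_grid, v):
                    rows.append({
                        "cell_line": cell_line, "compound": compound,
                        "dose": float(d), "replicate": rep,
                        "signal": float(_signal(np.array(vi))), "role": "sample",
                    })
    df = pd.DataFrame(rows)
    df["anchor_compound"] = None
    df["anchor_dose"] = 0.0
    return df, truth


# ---------------------------------------------------------------------------
# Combination matrices
# ---------------------------------------------------------------------------

def gen_combination_matrix(
    truth_a: FourPLParams | None = None,
    truth_b: FourPLParams | None = None,
    delta: float = 0.0,
    doses_a: np.ndarray = COMBO_GRID_10,
    doses_b: np.ndarray = COMBO_GRID_10,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    cell_line: str = "LINE001",
    compound_a: str = "ANCHOR",
    compound_b: str = "LIBRARY",
) -> tuple[pd.DataFrame, dict]:
    """Simulate a full combination dose matrix with planted Bliss excess.

    Observed combination inhibition is clip(E_bliss + delta + eps, 0, 1)
    per replicate; monotherapy margins come from the same truth curves
    with unclipped viability noise.  Default truth curves are
    partial-efficacy compounds (einf = 0.4): planted excess is only
    observable where the independence expectation has headroom below
    full inhibition, so saturating curves would leave nothing to
    recover (see methods note).
    """
    if abs(delta) > 0.5:
        raise ValidationError("|delta| must be <= 0.5")
    rng = np.random.default_rng(seed)
    if truth_a is None:
        truth_a = FourPLParams(e0=1.0, einf=0.4, ec50=float(np.sqrt(
            doses_a[0] * doses_a[-1])), hill=1.0)
    if truth_b is None:
        truth_b = FourPLParams(e0=1.0, einf=0.4, ec50=float(np.sqrt(
            doses_b[0] * doses_b[-1])), hill=1.0)
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)

    fa = inhibition(truth_a.viability(doses_a))
    fb = inhibition(truth_b.viability(doses_b))
    expected = bliss_expected(fa[:, None], fb[None, :])

    rows = _control_rows(cell_line, rng, noise.sigma, combination=True)
    for rep in range(1, noise.replicates + 1):
        # margins: compound A alone (as anchor rows) and B alone
        va = truth_a.viability(doses_a) + rng.normal(0, noise.sigma, doses_a.size)
        for d, v in zip(doses_a, va):
            rows.append({"cell_line": cell_line, "compound": compound_a,
                         "dose": 0.0, "replicate": rep,
                         "signal": float(_signal(np.array(v))), "role": "sample",
                         "anchor_compound": compound_a, "anchor_dose": float(d)})
        vb = truth_b.viability(doses_b) + rng.normal(0, noise.sigma, doses_b.size)
        for d, v in zip(doses_b, vb):
            rows.append({"cell_line": cell_line, "compound": compound_b,
                         "dose": float(d), "replicate": rep,
                         "signal": float(_signal(np.array(v))), "role": "sample",
                         "anchor_compound": "", "anchor_dose": 0.0})
        inh_obs = np.clip(
            expected + delta + rng.normal(0, noise.sigma, expected.shape), 0.0, 1.0
        )
        viab = 1.0 - inh_obs
        for i, da in enumerate(doses_a):
            for j, db in enumerate(doses_b):
                rows.append({"cell_line": cell_line, "compound": compound_b,
                             "dose": float(db), "replicate": rep,
                             "signal": float(_signal(np.array(viab[i, j]))),
                             "role": "sample",
                             "anchor_compound": compound_a,
                             "anchor_dose": float(da)})
    truth = {
        "kind": "combination_matrix", "seed": seed, "delta": delta,
        "sigma": noise.sigma, "replicates": noise.replicates,
        "cell_line": cell_line,
        "compound_a": compound_a, "compound_b": compound_b,
        "params_a": _params_dict(truth_a), "params_b": _params_dict(truth_b),
        "doses_a_nM": doses_a.tolist(), "doses_b_nM": doses_b.tolist(),
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Anchored library screens
# ---------------------------------------------------------------------------

ANCHOR_LEVELS = {"IC15": 0.85, "IC25": 0.75, "IC50": 0.50}

#: Fixed anchor-drug truth: a potent inhibitor with near-complete kill,
#: so IC15/IC25/IC50 anchor doses are all well inside the tested range.
ANCHOR_TRUTH = FourPLParams(e0=1.0, einf=0.02, ec50=50.0, hill=1.3)


def gen_anchored_library_screen(
    n_compounds: int = 198,
    frac_synergistic: float = 0.0,
    n_synergistic: int | None = None,
    delta: float = 0.2,
    dose_grid: np.ndarray = DOSE_GRID_6,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    cell_line: str = "LINE001",
    anchor_compound: str = "ANCHOR",
    anchor_truth: FourPLParams = ANCHOR_TRUTH,
) -> tuple[pd.DataFrame, dict]:
    """Simulate an anchored combination screen for one cell line.

    Each library compound gets a 6-dose series at each of the three
    anchor concentrations (the anchor drug's IC15/IC25/IC50, derived
    from its truth curve), plus monotherapy margins for the library
    compound and for the anchor alone.  A planted fraction of
    compounds receives uniform Bliss excess ``delta`` on every
    combination cell; the rest combine independently.
    """
    if not 0.0 <= frac_synergistic <= 1.0:
        raise ValidationError("frac_synergistic must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dose_grid = np.asarray(dose_grid, dtype=float)
    compounds = [f"CPD{i + 1:03d}" for i in range(n_compounds)]
    if n_synergistic is None:
        n_synergistic = int(round(frac_synergistic * n_compounds))
    synergistic = sorted(
        rng.choice(n_compounds, size=n_synergistic, replace=False).tolist()
    )
    planted = {compounds[i] for i in synergistic}

    anchor_doses = {
        level: invert_4pl(anchor_truth, v) for level, v in ANCHOR_LEVELS.items()
    }
    fa_anchor = {
        level: float(inhibition(anchor_truth.viability(d)))
        for level, d in anchor_doses.items()
    }

    rows = _control_rows(cell_line, rng, noise.sigma, combination=True)
    # Anchor-alone margins at each anchor dose.  The anchor margin is
    # reused by every library compound on the screen, so it is laid out
    # like a plate control: N_ANCHOR_WELLS wells per replicate.
    for rep in range(1, noise.replicates + 1):
        for level, d in anchor_doses.items():
            for _ in range(N_ANCHOR_WELLS):
                v = float(anchor_truth.viability(d)) + rng.normal(0, noise.sigma)
                rows.append({"cell_line": cell_line, "compound": anchor_compound,
                             "dose": 0.0, "replicate": rep,
                             "signal": float(_signal(np.array(v))), "role": "sample",
                             "anchor_compound": anchor_compound,
                             "anchor_dose": float(d)})

    truth_curves = {}
    for compound in compounds:
        params = _draw_library_params(rng)
        truth_curves[compound] = _params_dict(params)
        fb = inhibition(params.viability(dose_grid))
        for rep in range(1, noise.replicates + 1):
            v_mono = params.viability(dose_grid) + rng.normal(
                0, noise.sigma, dose_grid.size)
            for d, v in zip(dose_grid, v_mono):
                rows.append({"cell_line": cell_line, "compound": compound,
                             "dose": float(d), "replicate": rep,
                             "signal": float(_signal(np.array(v))),
                             "role": "sample",
                             "anchor_compound": "", "anchor_dose": 0.0})
            for level, a_dose in anchor_doses.items():
                expected = bliss_expected(fa_anchor[level], fb)
                if compound in planted:
                    expected = expected + delta
                inh_obs = np.clip(
                    expected + rng.normal(0, noise.sigma, dose_grid.size), 0, 1)
                for d, io in zip(dose_grid, inh_obs):
                    rows.append({"cell_line": cell_line, "compound": compound,
                                 "dose": float(d), "replicate": rep,
                                 "signal": float(_signal(np.array(1.0 - io))),
                                 "role": "sample",
                                 "anchor_compound": anchor_compound,
                                 "anchor_dose": float(a_dose)})
    truth = {
        "kind": "anchored_library_screen", "seed": seed, "delta": delta,
        "sigma": noise.sigma, "replicates": noise.replicates,
        "cell_line": cell_line, "anchor_compound": anchor_compound,
        "anchor_params": _params_dict(anchor_truth),
        "anchor_doses_nM": {k: float(v) for k, v in anchor_doses.items()},
        "dose_grid_nM": dose_grid.tolist(),
        "synergistic_compounds": sorted(planted),
        "library_params": truth_curves,
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Sensitivity datasets and expression
# ---------------------------------------------------------------------------

PEDIATRIC_TYPES = ["ES", "MB", "NB", "OS", "RMS"]
ADULT_TYPES = ["breast", "lung", "colon", "skin", "ovary", "pancreas"]

DEFAULT_PATHWAYS = [
    "DNA replication", "Genome integrity", "IGF1R signaling",
    "ERK MAPK signaling", "EGFR signaling", "WNT signaling",
    "PI3K/MTOR signaling", "Cell cycle", "Apoptosis regulation",
    "Chromatin histone acetylation", "Chromatin other", "Mitosis",
    "RTK signaling", "Metabolism", "Protein stability and degradation",
    "JNK and p38 signaling", "Hormone-related", "Cytoskeleton",
]


def default_compound_annotations(
    n_compounds: int = 198, seed: int = 0
) -> pd.DataFrame:
    """Compound -> (target, target_pathway) table emulating a 198-drug library.

    Pathways are assigned round-robin with mild random imbalance so most
    pathways clear the min-size-5 enrichment filter; targets group 2-3
    compounds each.
    """
    rng = np.random.default_rng(seed)
    compounds = [f"CPD{i + 1:03d}" for i in range(n_compounds)]
    weights = rng.uniform(0.5, 2.0, size=len(DEFAULT_PATHWAYS))
    pathway_idx = rng.choice(len(DEFAULT_PATHWAYS), size=n_compounds,
                             p=weights / weights.sum())
    pathways = [DEFAULT_PATHWAYS[i] for i in pathway_idx]
    targets = []
    counter: dict[str, int] = {}
    for pw in pathways:
        k = counter.get(pw, 0)
        counter[pw] = k + 1
        targets.append(f"{pw.split()[0].upper()}_T{k // 2 + 1}")
    return pd.DataFrame({"target": targets, "target_pathway": pathways},
                        index=pd.Index(compounds, name="compound"))


def gen_sensitivity_dataset(
    n_ped: int = 40,
    n_adult: int = 200,
    compound_meta: pd.DataFrame | None = None,
    shifted_pathways: Mapping[str, float] | None = None,
    mutation_effects: Mapping[str, Mapping[str, float]] | None = None,
    biological_sd: float = 0.12,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> tuple[SensitivityDataset, dict]:
    """Simulate an AUC matrix over a pediatric + adult cell-line panel.

    AUC = compound base + cell-line offset + per-(line, compound)
    biological response heterogeneity (sd ``biological_sd``) +
    pediatric x pathway shift (+ mutation effects) + assay noise,
    truncated to [0, 1].  Negative shifts make pediatric lines *more*
    sensitive to that pathway's compounds.  The biological term gives
    each compound a realistic across-line AUC spread (~0.1-0.2 in
    large panels), which is what biomarker analyses correlate against.
    """
    shifted_pathways = dict(shifted_pathways or {})
    mutation_effects = {k: dict(v) for k, v in (mutation_effects or {}).items()}
    for shift in shifted_pathways.values():
        if abs(shift) > 0.5:
            raise ValidationError("|pathway shift| must be <= 0.5")
    rng = np.random.default_rng(seed)
    if compound_meta is None:
        compound_meta = default_compound_annotations(seed=seed)
    compounds = compound_meta.index

    lines = [f"PED{i + 1:03d}" for i in range(n_ped)] + \
            [f"ADT{i + 1:03d}" for i in range(n_adult)]
    pediatric = np.array([True] * n_ped + [False] * n_adult)
    tumor_type = np.concatenate([
        rng.choice(PEDIATRIC_TYPES, size=n_ped),
        rng.choice(ADULT_TYPES, size=n_adult),
    ])
    mutation_flags = {"STAG2_mut": rng.random(len(lines)) < 0.10}
    cell_meta = pd.DataFrame(
        {"pediatric": pediatric, "tumor_type": tumor_type, **mutation_flags},
        index=pd.Index(lines, name="cell_line"),
    )

    base = rng.uniform(0.4, 0.9, size=len(compounds))
    line_offset = rng.normal(0, 0.05, size=len(lines))
    biological = rng.normal(0, biological_sd, size=(len(lines), len(compounds)))
    shift_vec = compound_meta["target_pathway"].map(
        lambda pw: shifted_pathways.get(pw, 0.0)).to_numpy()
    auc = (base[None, :] + line_offset[:, None] + biological
           + pediatric[:, None] * shift_vec[None, :])
    for flag, effects in mutation_effects.items():
        carrier = cell_meta[flag].to_numpy(dtype=float)
        for compound, eff in effects.items():
            ci = compounds.get_loc(compound)
            auc[:, ci] += carrier * eff
    auc = np.clip(auc + rng.normal(0, noise.sigma, auc.shape), 0.0, 1.0)

    dataset = SensitivityDataset(
        auc=pd.DataFrame(auc, index=cell_meta.index, columns=compounds),
        cell_meta=cell_meta, compound_meta=compound_meta,
    )
    truth = {
        "kind": "sensitivity_dataset", "seed": seed, "sigma": noise.sigma,
        "biological_sd": biological_sd,
        "n_ped": n_ped, "n_adult": n_adult,
        "shifted_pathways": shifted_pathways,
        "mutation_effects": mutation_effects,
    }
    return dataset, truth


def gen_gene_sets(
    genes: Sequence[str],
    n_sets: int = 50,
    size_range: tuple[int, int] = (20, 80),
    seed: int = 0,
    prefix: str = "SET",
) -> SetCollection:
    """Random gene sets drawn from a gene universe (for null backgrounds)."""
    rng = np.random.default_rng(seed)
    coll = SetCollection()
    genes = list(genes)
    for i in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        coll.add(f"{prefix}{i + 1:03d}", [genes[g] for g in members])
    return coll


def gen_expression_dataset(
    n_genes: int = 2000,
    planted_sets: SetCollection | None = None,
    betas: Mapping[str, float] | None = None,
    dataset: SensitivityDataset | None = None,
    compound: str | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate expression with gene sets planted against a compound's AUC.

    Genes in a planted set follow expr = -beta * AUC(compound) + eps
    (higher expression in sensitive lines for beta > 0); background
    genes are pure noise eps ~ N(0, noise_sd).  Planted sets must be
    disjoint.  Returns (genes x cell lines matrix, truth).
    """
    if dataset is None or compound is None:
        raise ValidationError("an AUC dataset and compound are required")
    betas = dict(betas or {})
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    auc = dataset.auc[compound].to_numpy(dtype=float)
    expr = rng.normal(0, noise_sd, size=(n_genes, auc.size))

    planted_genes: dict[str, str] = {}
    if planted_sets is not None:
        gene_pos = {g: i for i, g in enumerate(genes)}
        for name, beta in betas.items():
            if name not in planted_sets:
                raise ValidationError(f"beta given for unknown set {name!r}")
            for g in planted_sets[name]:
                if g in planted_genes:
                    raise ValidationError("planted sets must be disjoint")
                planted_genes[g] = name
                if beta != 0.0 and g in gene_pos:
                    expr[gene_pos[g]] += -beta * auc
    matrix = pd.DataFrame(expr, index=pd.Index(genes, name="gene"),
                          columns=dataset.cell_lines)
    truth = {
        "kind": "expression_dataset", "seed": seed, "noise_sd": noise_sd,
        "compound": compound, "betas": betas,
        "planted_sets": {name: list(planted_sets[name])
                         for name in planted_sets} if planted_sets else {},
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# Truth serialization
# ---------------------------------------------------------------------------

def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
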