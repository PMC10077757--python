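"""End-to-end orchestration: simulate -> normalize -> fit -> synergy -> enrich.

A run is driven by a declarative :class:`RunConfig` (YAML file or
dict); CLI flags override file values.  Every stage writes its TSV
output plus a JSON metadata sidecar carrying the config hash, seed and
software version, and the run manifest lists all outputs with content
hashes so that re-running an identical config reproduces identical
hashes.  Filtering counts (dropped compounds, undefined cells, sets
below the minimum size) are logged at each stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import synscreen
from synscreen import dose_response, enrichment, screen_io, simulate, synergy
from synscreen.errors import ConfigError
from synscreen.simulate import NoiseModel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated run configuration with study-derived defaults.

    Thresholds default to the hit-selection rules (fold change 5,
    Bliss 0), the insensitivity cutoff (viability 0.5 at the 10 uM top
    dose) and the minimum enrichment set size of 5.  Design sizes
    default to a compact simulated study that exercises every stage.
    """

    seed: int = 0
    out_dir: str = "runs/default"
    n_perm: int = 1000

    # thresholds
    fold_change_threshold: float = 5.0
    bliss_threshold: float = 0.0
    sensitivity_cutoff: float = 0.5
    top_dose_nM: float = 10_000.0
    min_set_size: int = 5
    normalize_to_anchor: bool = False

    # noise model
    sigma: float = 0.05
    replicates: int = 2

    # simulated design sizes
    mono_lines: int = 3
    mono_compounds: int = 8
    anchored_compounds: int = 60
    anchored_synergistic: int = 6
    anchored_delta: float = 0.2
    n_ped: int = 40
    n_adult: int = 200
    shifted_pathway: str = "DNA replication"
    pathway_shift: float = -0.15
    n_genes: int = 1000
    planted_beta: float = 1.0
    biomarker_compound: str = "CPD001"

    def noise(self) -> NoiseModel:
        return NoiseModel(sigma=self.sigma, replicates=self.replicates)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def validate_config(raw: str | Path | dict | None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file or dict plus overrides.

    Unknown keys are rejected by name; thresholds must be finite and
    ``n_perm`` at least 100.
    """
    data: dict = {}
    if isinstance(raw, (str, Path)):
        with open(raw) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {raw} must contain a mapping")
        data.update(loaded)
    elif isinstance(raw, dict):
        data.update(raw)
    elif raw is not None:
        raise ConfigError(f"unsupported config source {type(raw).__name__}")
    data.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(data) - set(_FIELDS)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(**data)

    if cfg.n_perm < 100:
        raise ConfigError(f"n_perm must be >= 100, got {cfg.n_perm}")
    for key in ("fold_change_threshold", "bliss_threshold",
                "sensitivity_cutoff", "top_dose_nM"):
        value = getattr(cfg, key)
        if not pd.notna(value) or abs(float(value)) == float("inf"):
            raise ConfigError(f"threshold {key} must be finite, got {value}")
    if cfg.min_set_size < 1:
        raise ConfigError(f"min_set_size must be >= 1, got {cfg.min_set_size}")
    if not 0 <= cfg.anchored_synergistic <= cfg.anchored_compounds:
        raise ConfigError("anchored_synergistic must be within the library size")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _sidecar(path: Path, cfg: RunConfig) -> None:
    meta = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
            "version": synscreen.__version__}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, sort_keys=True) + "\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order and return the run manifest.

    The manifest maps stage -> {filename: sha256}; it is also written
    to ``manifest.json`` in the output directory.  A stage failure
    leaves the manifest recording the stages completed so far and
    re-raises.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("synscreen")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                      "version": synscreen.__version__, "stages": {}}
    try:
        for stage, func in (("simulate", _stage_simulate),
                            ("normalize", _stage_normalize),
                            ("fit", _stage_fit),
                            ("synergy", _stage_synergy),
                            ("enrich", _stage_enrich)):
            logger.info("stage %s: start", stage)
            outputs = func(cfg, out)
            for p in outputs:
                _sidecar(p, cfg)
            manifest["stages"][stage] = {p.name: _sha256(p) for p in outputs}
            logger.info("stage %s: wrote %d output(s)", stage, len(outputs))
    except Exception:
        manifest["completed"] = False
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True) + "\n")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    manifest["completed"] = True
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path) -> list[Path]:
    noise = cfg.noise()
    seed = cfg.seed
    mono, mono_truth = simulate.gen_monotherapy_screen(
        n_lines=cfg.mono_lines,
        compounds=[f"CPD{i + 1:03d}" for i in range(cfg.mono_compounds)],
        noise=noise, seed=seed)
    screen_io.write_screen_table(mono, out / "monotherapy.csv")
    simulate.write_truth(mono_truth, out / "monotherapy_truth.json")

    combo_frames = []
    combo_truths = {}
    for li in range(cfg.mono_lines):
        cell_line = f"LINE{li + 1:03d}"
        df, truth = simulate.gen_anchored_library_screen(
            n_compounds=cfg.anchored_compounds,
            n_synergistic=cfg.anchored_synergistic,
            delta=cfg.anchored_delta, noise=noise,
            seed=seed + 100 + li, cell_line=cell_line)
        combo_frames.append(df)
        combo_truths[cell_line] = truth
    screen_io.write_screen_table(pd.concat(combo_frames, ignore_index=True),
                                 out / "anchored_screen.csv")
    simulate.write_truth(combo_truths, out / "anchored_screen_truth.json")

    dataset, sens_truth = simulate.gen_sensitivity_dataset(
        n_ped=cfg.n_ped, n_adult=cfg.n_adult,
        shifted_pathways={cfg.shifted_pathway: cfg.pathway_shift},
        noise=noise, seed=seed + 500)
    dataset.write(out)
    simulate.write_truth(sens_truth, out / "sensitivity_truth.json")

    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    genesets = simulate.gen_gene_sets(gene_ids, n_sets=30,
                                      size_range=(20, 60), seed=seed + 600)
    expr, expr_truth = simulate.gen_expression_dataset(
        n_genes=cfg.n_genes, planted_sets=genesets,
        betas={"SET001": cfg.planted_beta}, dataset=dataset,
        compound=cfg.biomarker_compound, seed=seed + 700)
    expr.to_csv(out / "expression.tsv", sep="\t")
    screen_io.write_gmt(genesets, out / "genesets.gmt")
    simulate.write_truth(expr_truth, out / "expression_truth.json")

    return [out / n for n in (
        "monotherapy.csv", "monotherapy_truth.json",
        "anchored_screen.csv", "anchored_screen_truth.json",
        "sensitivity_auc.tsv", "sensitivity_cell_meta.tsv",
        "sensitivity_compound_meta.tsv", "sensitivity_truth.json",
        "expression.tsv", "genesets.gmt", "expression_truth.json",
    )]


def _stage_normalize(cfg: RunConfig, out: Path) -> list[Path]:
    outputs = []
    for name, schema in (("monotherapy", "monotherapy"),
                         ("anchored_screen", "combination")):
        df = screen_io.read_screen_table(out / f"{name}.csv", schema=schema)
        points = screen_io.normalize_viability(df)
        logger.info("normalize %s: %d wells -> %d averaged points",
                    name, len(df), len(points))
        path = out / f"{name}_viability.tsv"
        points.to_csv(path, sep="\t", index=False)
        outputs.append(path)
    return outputs


def _stage_fit(cfg: RunConfig, out: Path) -> list[Path]:
    points = pd.read_csv(out / "monotherapy_viability.tsv", sep="\t")
    fits = dose_response.fit_screen(points)
    n_fallback = int((~fits["converged"]).sum())
    logger.info("fit: %d curves, %d fallback (non-converged)",
                len(fits), n_fallback)
    top = points[points["dose"] == cfg.top_dose_nM]
    cls = top.assign(sensitivity=[
        dose_response.classify_sensitivity(v) for v in top["viability"]])
    logger.info("fit: %d insensitive curve(s) at top dose",
                int((cls["sensitivity"] == "insensitive").sum()))
    fits_path = out / "monotherapy_fits.tsv"
    fits.to_csv(fits_path, sep="\t", index=False)
    cls_path = out / "sensitivity_classification.tsv"
    cls[["cell_line", "compound", "viability", "sensitivity"]].to_csv(
        cls_path, sep="\t", index=False)
    return [fits_path, cls_path]


def _stage_synergy(cfg: RunConfig, out: Path) -> list[Path]:
    points = pd.read_csv(out / "anchored_screen_viability.tsv", sep="\t")
    points["anchor_compound"] = points["anchor_compound"].fillna("")
    scores = synergy.score_anchored_screen(
        points,
        fold_change_threshold=cfg.fold_change_threshold,
        bliss_threshold=cfg.bliss_threshold,
        normalize_to_anchor=cfg.normalize_to_anchor)
    n_undefined = int(scores["bliss_avg"].isna().sum())
    logger.info("synergy: %d combinations scored, %d hits, "
                "%d with undefined average Bliss",
                len(scores), int(scores["is_hit"].sum()), n_undefined)
    scores_path = out / "synergy_metrics.tsv"
    scores.to_csv(scores_path, sep="\t", index=False)

    hits = {
        line: dict(zip(sub["library_compound"], sub["is_hit"]))
        for line, sub in scores.groupby("cell_line")
    }
    overlap_path = out / "cross_entity_overlap.tsv"
    if len(hits) >= 2:
        overlap = sorted(synergy.cross_entity_overlap(hits))
        logger.info("synergy: %d compound(s) synergistic across all %d lines",
                    len(overlap), len(hits))
    else:
        overlap = []
        logger.info("synergy: overlap skipped (single cell line)")
    pd.DataFrame({"library_compound": overlap}).to_csv(
        overlap_path, sep="\t", index=False)
    return [scores_path, overlap_path]


def _stage_enrich(cfg: RunConfig, out: Path) -> list[Path]:
    dataset = screen_io.SensitivityDataset.read(out)
    res, mstats = enrichment.compound_set_enrichment(
        dataset, grouping="target_pathway", n_perm=cfg.n_perm,
        seed=cfg.seed, min_size=cfg.min_set_size)
    logger.info("enrich: %d pathway set(s) tested, %d at padj < 0.05",
                len(res), int((res["padj"] < 0.05).sum()))
    pathway_path = out / "pathway_enrichment.tsv"
    res.to_csv(pathway_path, sep="\t", index=False)

    stats_path = out / "compound_stats.tsv"
    mstats.table.to_csv(stats_path, sep="\t", index_label="compound")

    zscores = dose_response.auc_zscore_matrix(dataset.auc)
    z_path = out / "auc_zscores.tsv"
    zscores.to_csv(z_path, sep="\t", index_label="cell_line")

    expr = pd.read_csv(out / "expression.tsv", sep="\t", index_col="gene")
    genesets = screen_io.read_gmt(out / "genesets.gmt")
    bio, _ = enrichment.biomarker_gsea(
        expr, dataset, cfg.biomarker_compound, genesets,
        n_perm=cfg.n_perm, seed=cfg.seed, min_size=cfg.min_set_size)
    logger.info("enrich: %d gene set(s) tested against %s AUC, %d at padj < 0.05",
                len(bio), cfg.biomarker_compound,
                int((bio["padj"] < 0.05).sum()))
    bio_path = out / "biomarker_enrichment.tsv"
    bio.to_csv(bio_path, sep="\t", index=False)

    mut = enrichment.mutation_association(dataset, cfg.biomarker_compound,
                                          "STAG2_mut")
    mut_path = out / "mutation_association.json"
    mut_path.write_text(json.dumps(mut, indent=2, sort_keys=True) + "\n")
    return [pathway_path, stats_path, z_path, bio_path, mut_path]
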