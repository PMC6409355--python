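"""Pipeline stages behind the command line: extract, fit, classify.

Each stage reads/writes plain TSV and leaves a JSON manifest (config, seed,
package version) next to its outputs so any run can be reproduced
bit-identically from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import __version__
from .classification import (bp_baseline, kfold_cv, min_max_normalize,
                             split_high_low)
from .genomic_io import (GeneAnnotation, PeakFeatures, TimeCourseRecord,
                         extract_features_for_genes, extract_peak_features,
                         join_expression, promoter_window, read_bedgraph,
                         read_expression_table, read_gene_annotation,
                         read_narrowpeak, records_to_frame, select_strongest,
                         write_features_tsv, NoPeakInPromoter)
from .inference_stats import inference_report
from .model_core import (MODEL_D_FUNCTIONS, ModelSpec, design_matrix,
                         fit_model, stepwise_select)
from .synthetic_data import (GenerativeConfig, generate_timecourse,
                             write_genomic_artifacts)

logger = logging.getLogger(__name__)

DEFAULTS: dict[str, Any] = {
    "promoter": {"upstream": 1500, "downstream": 500},
    "min_height": 1.0,
    "annotation_format": "bed6",
    "models": [1, 2, 3, 4],
    "stepwise": None,          # None | "aic" | "pvalue"
    "classification": {"fraction": 0.3, "cv_k": 10, "model": 4},
    "seed": 0,
}

CONFIG_TEMPLATE = """\
# oct4expr pipeline configuration.
# Provide exactly one of `simulate` or `inputs`.

simulate:                 # synthetic dataset with known truth
  n_genes: 20
  noise_sd: 0.05
  feature_law: constant   # constant | decay_height | log_width

# inputs:                 # real data
#   annotation: genes.bed
#   annotation_format: bed6        # bed6 | gtf
#   expression: expression.tsv     # columns gene_id/day/expression
#   tracks:                        # bedGraph per day, OR `peaks:` narrowPeak per day
#     0: day0.bedgraph
#     1: day1.bedgraph

promoter:
  upstream: 1500          # bp upstream of the TSS
  downstream: 500         # bp downstream
min_height: 1.0           # signal threshold for peak derivation from tracks

models: [1, 2, 3, 4]      # which distance time-functions to fit
stepwise: null            # null | aic | pvalue

classification:
  fraction: 0.3           # extreme-quantile fraction for high/low groups
  cv_k: 10
  model: 4

seed: 0
"""


def load_config(path: str | Path | None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULTS))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, {k: v for k, v in overrides.items() if v is not None})
    if bool(cfg.get("simulate")) == bool(cfg.get("inputs")):
        raise ValueError("config must contain exactly one of 'simulate' or 'inputs'")
    return cfg


def _deep_update(base: dict, extra: dict) -> None:
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value


def write_manifest(out_dir: Path, stage: str, cfg: dict, extra: dict | None = None) -> Path:
    payload = {"stage": stage, "config": cfg, "version": __version__}
    if extra:
        payload.update(extra)
    path = out_dir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)
    return path


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(cfg: dict, out_dir: str | Path) -> dict[str, Any]:
    """Generate a synthetic dataset and its on-disk artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = dict(cfg.get("simulate") or {})
    sim_cfg.setdefault("seed", cfg["seed"])
    gen = GenerativeConfig(**sim_cfg)
    dataset = write_genomic_artifacts(generate_timecourse(gen), out)
    write_manifest(out, "simulate", cfg,
                   {"n_records": len(dataset.records),
                    "clamped_genes": dataset.clamped})
    return {
        "annotation": dataset.annotation_path,
        "tracks": dataset.track_paths,
        "expression": dataset.expression_path,
        "dataset": dataset,
    }


def run_extract(cfg: dict, out_dir: str | Path) -> Path:
    """Extraction stage: strongest promoter peak per gene per day, joined
    with expression.  Writes features.tsv and records.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.get("simulate"):
        sim = run_simulate(cfg, out / "sim")
        annotation_path = sim["annotation"]
        track_paths = sim["tracks"]
        expression_path = sim["expression"]
        annotation_format = "bed6"
        peak_paths = None
    else:
        inputs = cfg["inputs"]
        annotation_path = inputs["annotation"]
        expression_path = inputs["expression"]
        annotation_format = inputs.get("annotation_format",
                                       cfg["annotation_format"])
        track_paths = {int(d): p for d, p in (inputs.get("tracks") or {}).items()}
        peak_paths = ({int(d): p for d, p in inputs["peaks"].items()}
                      if inputs.get("peaks") else None)

    genes = read_gene_annotation(annotation_path, format=annotation_format)
    up = cfg["promoter"]["upstream"]
    down = cfg["promoter"]["downstream"]

    if peak_paths is not None:
        features = _features_from_called_peaks(peak_paths, genes, up, down)
    else:
        tracks = {day: read_bedgraph(path) for day, path in track_paths.items()}
        features = extract_features_for_genes(
            tracks, genes, upstream=up, downstream=down,
            min_height=cfg["min_height"])

    write_features_tsv(features, out / "features.tsv")
    expression = read_expression_table(expression_path)
    records = join_expression(features, expression)
    records_to_frame(records).to_csv(out / "records.tsv", sep="\t", index=False)
    write_manifest(out, "extract", cfg, {"n_features": len(features),
                                         "n_records": len(records)})
    return out / "records.tsv"


def _features_from_called_peaks(
    peak_paths: dict[int, Any],
    genes: Sequence[GeneAnnotation],
    upstream: int,
    downstream: int,
) -> list[PeakFeatures]:
    out: list[PeakFeatures] = []
    for day, path in sorted(peak_paths.items()):
        peaks = read_narrowpeak(path)
        for gene in genes:
            window = promoter_window(gene, upstream, downstream)
            inside = [p for p in peaks
                      if p.chrom == window.chrom
                      and p.start < window.end and p.end > window.start]
            try:
                best = select_strongest(inside, tss=gene.tss)
            except NoPeakInPromoter:
                logger.warning("gene %s day %d: no called peak in promoter",
                               gene.gene_id, day)
                continue
            H, D, W = extract_peak_features(best, gene)
            out.append(PeakFeatures(gene_id=gene.gene_id, day=day,
                                    height=H, distance=D, width=W))
    return out


def read_records_tsv(path: str | Path) -> list[TimeCourseRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        TimeCourseRecord(gene_id=str(r.gene_id), day=int(r.day),
                         height=float(r.height), distance=float(r.distance),
                         width=float(r.width), expression=float(r.expression))
        for r in df.itertuples()
    ]


def run_fit(cfg: dict, records_path: str | Path, out_dir: str | Path) -> dict[str, Path]:
    """Fit every requested model per gene and pooled; write coefficient,
    inference and model-comparison tables, plus stepwise selection when
    configured."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = read_records_tsv(records_path)
    by_gene: dict[str, list[TimeCourseRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)

    fit_rows, inf_rows, cmp_rows = [], [], []
    for model_id in cfg["models"]:
        spec = ModelSpec(model_id=model_id)
        units: list[tuple[str, list[TimeCourseRecord]]] = [
            (gid, recs) for gid, recs in sorted(by_gene.items())
        ]
        units.append(("pooled", records))
        for unit, recs in units:
            try:
                fit = fit_model(recs, spec)
            except Exception as exc:  # rank deficiency or too few records
                logger.warning("model %s on %s not fit: %s", model_id, unit, exc)
                continue
            fit_rows.append({
                "unit": unit, "model": model_id,
                "beta1": fit.beta[0], "beta2": fit.beta[1], "beta3": fit.beta[2],
                "intercept": fit.intercept,
                "se1": fit.se_beta[0], "se2": fit.se_beta[1], "se3": fit.se_beta[2],
                "residual_sd": fit.residual_sd, "n": fit.n,
                "term2": spec.terms[1],
            })
            if fit.dof >= 1:
                rep = inference_report(fit)
                inf_rows.append({
                    "unit": unit, "model": model_id,
                    "adj_r_squared": rep.adj_r_squared,
                    "f_stat": rep.f_stat, "f_pvalue": rep.f_pvalue,
                    "p1": rep.t_pvalues[0], "p2": rep.t_pvalues[1],
                    "p3": rep.t_pvalues[2],
                })
                if unit == "pooled":
                    cmp_rows.append({"model": model_id,
                                     "f_t": MODEL_D_FUNCTIONS[model_id],
                                     "adj_r_squared": rep.adj_r_squared})

    paths = {
        "fits": out / "fits.tsv",
        "inference": out / "inference.tsv",
        "model_comparison": out / "model_comparison.tsv",
    }
    pd.DataFrame(fit_rows).to_csv(paths["fits"], sep="\t", index=False)
    pd.DataFrame(inf_rows).to_csv(paths["inference"], sep="\t", index=False)
    pd.DataFrame(cmp_rows).to_csv(paths["model_comparison"], sep="\t", index=False)

    if cfg.get("stepwise"):
        selected = stepwise_select(records, criterion=cfg["stepwise"])
        paths["stepwise"] = out / "stepwise_terms.txt"
        paths["stepwise"].write_text("\n".join(selected) + "\n")

    write_manifest(out, "fit", cfg, {"n_records": len(records)})
    return paths


def run_classify(cfg: dict, records_path: str | Path, out_dir: str | Path) -> dict[str, Path]:
    """Cross-validated high/low classification: regression model vs the
    feedforward baseline under identical folds.  Writes the per-fold
    coefficient table and a pooled metrics table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = read_records_tsv(records_path)
    cls = cfg["classification"]
    seed = int(cfg["seed"])
    spec = ModelSpec(model_id=cls.get("model", 4))

    report = kfold_cv(records, spec=spec, k=int(cls["cv_k"]), seed=seed,
                      fraction=float(cls["fraction"]))

    fold_rows = []
    for f, fit in enumerate(report.fold_fits):
        if fit is None:
            continue
        fold_rows.append({"fold": f + 1, "beta1": fit.beta[0],
                          "beta2": fit.beta[1], "beta3": fit.beta[2],
                          "epsilon": fit.intercept})
    cv_path = out / "cv_folds.tsv"
    pd.DataFrame(fold_rows).to_csv(cv_path, sep="\t", index=False)

    # Baseline on the same folds: labels from the global threshold rule.
    normalized, _ = min_max_normalize(records)
    X, y = design_matrix(normalized, spec)
    _, labels, _ = split_high_low(y, fraction=float(cls["fraction"]))
    bp_metrics, _ = bp_baseline(X, labels, seed=seed,
                                folds=report.fold_of_sample)

    metrics_path = out / "metrics.tsv"
    pd.DataFrame([
        {"method": f"Model {spec.model_id}", "acc": report.metrics.acc,
         "sn": report.metrics.sn, "sp": report.metrics.sp,
         "mcc": report.metrics.mcc},
        {"method": "BP neural network", "acc": bp_metrics.acc,
         "sn": bp_metrics.sn, "sp": bp_metrics.sp, "mcc": bp_metrics.mcc},
    ]).to_csv(metrics_path, sep="\t", index=False)

    write_manifest(out, "classify", cfg, {"n_records": len(records)})
    return {"cv_folds": cv_path, "metrics": metrics_path}


def run_all(cfg: dict, out_dir: str | Path) -> dict[str, Any]:
    out = Path(out_dir)
    records_path = run_extract(cfg, out / "extract")
    fit_paths = run_fit(cfg, records_path, out / "fit")
    cls_paths = run_classify(cfg, records_path, out / "classify")
    return {"records": records_path, **fit_paths, **cls_paths}
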