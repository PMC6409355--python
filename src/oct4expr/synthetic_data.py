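"""Synthetic time-course datasets with known generative truth.

Expression follows the general temporal-interaction model

    Exp = b1 * H * e^t + b2 * D * f(t) + b3 * W * log10(t+1) + c + N(0, sigma)

over the eight developmental days {0, 1, 3, 5, 7, 11, 15, 18}.  The default
``f(t) = 0.5^t`` is the distance law with the best observed fit among the
four candidates; feature trajectories default to constant per gene, with an
exponential-decay height law and a logarithmic-growth width law available to
mimic the temporal trends seen in binding data.

Besides the tabular records the generator writes matching on-disk artifacts
(a bedGraph track per day, a BED6 annotation, an expression TSV and a JSON
manifest) on a single synthetic chromosome, so the whole extraction pipeline
can be exercised end-to-end and must reproduce the generated (H, D, W)
exactly.  Feature marginals (H ~ U[1,10], W ~ U[50,500] bp, D uniform over
the distances that keep the peak inside the 2-kb promoter window) are
generator conventions, not measured quantities.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genomic_io import DEFAULT_TIMEPOINTS, TimeCourseRecord
from .model_core import TIME_FUNCTIONS

_GENE_SPACING = 10_000
_CHROM = "chrSyn"
_UPSTREAM = 1500
_DOWNSTREAM = 500


@dataclass(frozen=True)
class GenerativeConfig:
    """Ground truth of a synthetic dataset.

    ``noise_sd`` is the standard deviation of the normal disturbance;
    ``feature_law`` selects how (H, D, W) evolve over time.
    """

    n_genes: int = 30
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS
    true_beta: tuple[float, float, float] = (0.5, -0.3, 1.2)
    true_intercept: float = 0.1
    noise_sd: float = 0.0
    f_t: str = "0.5^t"
    feature_law: str = "constant"
    decay_rate: float = 0.1
    growth_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        tp = tuple(self.timepoints)
        if tp[0] != 0 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing from 0")
        if self.f_t not in ("t", "t^2", "t^3", "0.5^t"):
            raise ValueError(f"unsupported f_t {self.f_t!r}")
        if self.feature_law not in ("constant", "decay_height", "log_width"):
            raise ValueError(f"unsupported feature_law {self.feature_law!r}")


@dataclass
class SyntheticDataset:
    records: list[TimeCourseRecord]
    truth: GenerativeConfig
    clamped: list[str] = field(default_factory=list)
    track_paths: dict[int, Path] = field(default_factory=dict)
    annotation_path: Path | None = None
    expression_path: Path | None = None
    manifest_path: Path | None = None


def expression_value(
    h: float, d: float, w: float, t: float,
    beta: Sequence[float], intercept: float, f_t: str = "0.5^t",
) -> float:
    """Deterministic part of the generative expression model."""
    b1, b2, b3 = beta
    return (b1 * h * math.exp(t)
            + b2 * d * TIME_FUNCTIONS[f_t](t)
            + b3 * w * math.log10(t + 1.0)
            + intercept)


def _max_distance(width: int) -> int:
    # Keep the whole peak inside the promoter window on either strand.
    return _UPSTREAM - math.ceil(width / 2) - 1


def generate_timecourse(config: GenerativeConfig) -> SyntheticDataset:
    """Draw per-gene features, evolve them over the time course and emit
    noisy model expression.  Byte-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    records: list[TimeCourseRecord] = []
    clamped: list[str] = []
    width_pad = len(str(max(config.n_genes - 1, 0)))
    for g in range(config.n_genes):
        gene_id = f"gene{g:0{width_pad}d}"
        h0 = float(rng.uniform(1.0, 10.0))
        w0 = int(rng.integers(50, 501))
        d_raw = int(rng.integers(0, 1501))
        d0 = min(d_raw, _max_distance(w0))
        if d0 != d_raw:
            clamped.append(gene_id)
        for t in config.timepoints:
            if config.feature_law == "decay_height":
                h = h0 * math.exp(-config.decay_rate * t)
            else:
                h = h0
            if config.feature_law == "log_width":
                w = int(round(w0 * (1.0 + config.growth_rate * math.log10(t + 1.0))))
            else:
                w = w0
            d = min(d0, _max_distance(w))
            exp = expression_value(h, d, w, float(t), config.true_beta,
                                   config.true_intercept, config.f_t)
            if config.noise_sd > 0:
                exp += float(rng.normal(0.0, config.noise_sd))
            records.append(TimeCourseRecord(
                gene_id=gene_id, day=int(t), height=h, distance=float(d),
                width=float(w), expression=exp))
    return SyntheticDataset(records=records, truth=config, clamped=clamped)


def write_genomic_artifacts(dataset: SyntheticDataset, out_dir: str | Path) -> SyntheticDataset:
    """Write bedGraph tracks, BED6 annotation, expression TSV and manifest.

    Gene ``g`` sits at TSS ``10000 * (g + 1)`` on alternating strands; each
    (gene, day) peak is a rectangular block of height H and width W whose
    midpoint lies D bp upstream of the TSS, inside the promoter window.
    Floats are printed with ``repr`` so they round-trip exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = sorted({r.gene_id for r in dataset.records})
    tss = {gid: _GENE_SPACING * (i + 1) for i, gid in enumerate(genes)}
    strand = {gid: ("+" if i % 2 == 0 else "-") for i, gid in enumerate(genes)}

    ann_path = out / "genes.bed"
    with open(ann_path, "w") as fh:
        for gid in genes:
            if strand[gid] == "+":
                start, end = tss[gid], tss[gid] + 1000
            else:
                start, end = tss[gid] - 999, tss[gid] + 1
            fh.write(f"{_CHROM}\t{start}\t{end}\t{gid}\t0\t{strand[gid]}\n")

    days = sorted({r.day for r in dataset.records})
    track_paths: dict[int, Path] = {}
    for day in days:
        rows = []
        for r in dataset.records:
            if r.day != day:
                continue
            w, d = int(r.width), int(r.distance)
            mid = tss[r.gene_id] + (-d if strand[r.gene_id] == "+" else d)
            start = mid - w // 2
            end = start + w
            rows.append((start, end, r.height))
        rows.sort()
        path = out / f"signal_day{day}.bedgraph"
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="synthetic day {day}"\n')
            for start, end, h in rows:
                fh.write(f"{_CHROM}\t{start}\t{end}\t{h!r}\n")
        track_paths[day] = path

    expr_path = out / "expression.tsv"
    with open(expr_path, "w") as fh:
        fh.write("gene_id\tday\texpression\n")
        for r in dataset.records:
            fh.write(f"{r.gene_id}\t{r.day}\t{r.expression!r}\n")

    manifest_path = out / "manifest.json"
    manifest = {
        "config": asdict(dataset.truth),
        "clamped_genes": dataset.clamped,
        "chrom": _CHROM,
        "annotation": ann_path.name,
        "tracks": {str(d): p.name for d, p in track_paths.items()},
        "expression": expr_path.name,
        "records": [asdict(r) for r in dataset.records],
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    dataset.track_paths = track_paths
    dataset.annotation_path = ann_path
    dataset.expression_path = expr_path
    dataset.manifest_path = manifest_path
    return dataset


def generate_classification_set(
    config: GenerativeConfig,
    separation: float,
    fraction: float = 0.3,
    jitter_frac: float = 0.05,
) -> tuple[list[TimeCourseRecord], np.ndarray, dict]:
    """Two gene populations whose model expressions differ by
    ``separation * noise_sd``, labelled by the extreme-quantile rule.

    The high population holds a ``fraction`` share of the genes, so at
    strong separation the quantile labels coincide with population
    membership and the threshold falls inside the gap.  Feature trajectories are
    solved so the deterministic expression is flat across days within each
    population (height carries the separation; a small height jitter of
    ``jitter_frac * noise_sd`` keeps the design full rank), which makes the
    null case (separation 0) genuinely unpredictable.  Returned labels are
    1/0 for the top/bottom ``fraction`` of samples and NaN for the middle
    band, which a strict-extremes evaluation excludes.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    sigma = config.noise_sd if config.noise_sd > 0 else 1.0
    rng = np.random.default_rng(config.seed)
    b1, b2, b3 = config.true_beta
    if b1 == 0:
        raise ValueError("height coefficient must be nonzero to place the separation")
    d0, w0, spread = 500.0, 200.0, 100.0

    # Baseline level keeping solved heights strictly positive at every day,
    # with headroom for the per-gene D/W spread.
    worst = max(
        abs(b2) * (d0 + spread) * TIME_FUNCTIONS[config.f_t](float(t))
        + abs(b3) * (w0 + spread) * math.log10(t + 1.0) + abs(config.true_intercept)
        for t in config.timepoints
    )
    base = worst + 50.0 * sigma + 1.0

    n_high = max(1, math.floor(fraction * config.n_genes))
    records: list[TimeCourseRecord] = []
    population: list[int] = []
    width_pad = len(str(max(config.n_genes - 1, 0)))
    for g in range(config.n_genes):
        gene_id = f"gene{g:0{width_pad}d}"
        is_high = g < n_high
        level = base + (separation * sigma if is_high else 0.0)
        # D and W vary per gene; the solved height absorbs their
        # contribution, so the deterministic expression stays flat in time.
        d_g = float(rng.uniform(d0 - spread, d0 + spread))
        w_g = float(rng.uniform(w0 - spread, w0 + spread))
        for t in config.timepoints:
            target = level + float(rng.normal(0.0, jitter_frac * sigma))
            other = (b2 * d_g * TIME_FUNCTIONS[config.f_t](float(t))
                     + b3 * w_g * math.log10(t + 1.0) + config.true_intercept)
            h = (target - other) / (b1 * math.exp(t))
            exp = target + float(rng.normal(0.0, config.noise_sd))
            records.append(TimeCourseRecord(
                gene_id=gene_id, day=int(t), height=h, distance=d_g,
                width=w_g, expression=exp))
            population.append(1 if is_high else 0)

    from .classification import split_high_low

    expressions = np.array([r.expression for r in records])
    _, _, group = split_high_low(expressions, fraction=fraction)
    labels = np.full(len(records), np.nan)
    labels[group == 1] = 1.0
    labels[group == -1] = 0.0
    info = {
        "population": np.array(population),
        "base_level": base,
        "separation_units": separation,
        "sigma": sigma,
    }
    return records, labels, info
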