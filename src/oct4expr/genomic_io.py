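"""Genomic input handling: tracks, annotations, promoter windows, peak features.

All coordinates are 0-based, half-open — the native convention of bedGraph
and BED.  The promoter window of a gene spans 1.5 kb upstream to 0.5 kb
downstream of its transcription start site (TSS), strand-aware.  From the
strongest Oct4 binding peak inside that window three characteristics are
extracted per gene per timepoint:

* ``H`` (height)   — maximum signal value of the peak,
* ``D`` (distance) — absolute bp separation between peak midpoint and TSS,
* ``W`` (width)    — length of the peak interval in bp.

These, joined with an expression table over the developmental time course,
form the :class:`TimeCourseRecord` observations the regression models
consume.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Developmental days observed in the reprogramming time course.
DEFAULT_TIMEPOINTS: tuple[int, ...] = (0, 1, 3, 5, 7, 11, 15, 18)

DEFAULT_UPSTREAM = 1500
DEFAULT_DOWNSTREAM = 500


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to what promoter analysis needs: TSS and strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")


@dataclass(frozen=True)
class PromoterWindow:
    """Half-open promoter interval attached to a gene."""

    chrom: str
    start: int
    end: int
    gene_id: str
    clipped: bool = False


@dataclass(frozen=True)
class Peak:
    """A binding peak; ``summit`` is diagnostic only and may be absent."""

    chrom: str
    start: int
    end: int
    height: float
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"peak end {self.end} must exceed start {self.start}")
        if self.height < 0:
            raise ValueError(f"peak height must be >= 0, got {self.height}")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError("peak summit must lie inside [start, end)")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PeakFeatures:
    gene_id: str
    day: int
    height: float
    distance: int
    width: int


@dataclass(frozen=True)
class TimeCourseRecord:
    """One (gene, day) observation: peak features plus expression."""

    gene_id: str
    day: int
    height: float
    distance: float
    width: float
    expression: float

    def __post_init__(self) -> None:
        for name in ("height", "distance", "width", "expression"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{self.gene_id} day {self.day}: non-finite {name}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("track", "browser", "#")


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    """Read a 4-column bedGraph into (chrom, start, end, value) tuples.

    Track/browser/comment lines are skipped; malformed lines raise with
    their line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"bedGraph not found: {path}")
    intervals: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom, start_s, end_s, value_s = fields[:4]
            try:
                start, end, value = int(start_s), int(end_s), float(value_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: could not parse record: {exc}") from None
            intervals.append((chrom, start, end, value))
    return intervals


def read_gene_annotation(path: str | Path, format: str = "bed6") -> list[GeneAnnotation]:
    """Read gene annotations from BED6 or a minimal GTF.

    The TSS is the interval start on ``+`` and ``end - 1`` on ``-``
    (0-based).  Duplicate gene ids are fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation not found: {path}")
    genes: list[GeneAnnotation] = []
    if format == "bed6":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(_SKIP_PREFIXES):
                    continue
                fields = line.split()
                if len(fields) < 6:
                    raise ValueError(f"{path}:{lineno}: BED6 needs 6 columns")
                chrom, start, end, name, _score, strand = fields[:6]
                genes.append(_make_gene(name, chrom, int(start), int(end), strand))
    elif format == "gtf":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 9:
                    raise ValueError(f"{path}:{lineno}: GTF needs 9 columns")
                if fields[2] != "gene":
                    continue
                chrom, start, end, strand, attrs = (
                    fields[0], int(fields[3]) - 1, int(fields[4]), fields[6], fields[8],
                )
                gene_id = _gtf_attribute(attrs, "gene_id")
                if gene_id is None:
                    raise ValueError(f"{path}:{lineno}: gene feature without gene_id")
                genes.append(_make_gene(gene_id, chrom, start, end, strand))
    else:
        raise ValueError(f"unknown annotation format {format!r}")

    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    return genes


def _make_gene(name: str, chrom: str, start: int, end: int, strand: str) -> GeneAnnotation:
    tss = start if strand == "+" else end - 1
    return GeneAnnotation(gene_id=name, chrom=chrom, tss=tss, strand=strand)


def _gtf_attribute(attrs: str, key: str) -> str | None:
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key):
            return chunk[len(key):].strip().strip('"')
    return None


def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Read ENCODE narrowPeak: signalValue (col 7) becomes height, col 10
    the summit offset (-1 means absent)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"narrowPeak not found: {path}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 10:
                raise ValueError(f"{path}:{lineno}: narrowPeak needs 10 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            height = float(fields[6])
            offset = int(fields[9])
            summit = start + offset if offset >= 0 else None
            peaks.append(Peak(chrom=chrom, start=start, end=end, height=height, summit=summit))
    return peaks


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns gene_id/day/expression."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"gene_id", "day", "expression"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression table {path} lacks columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# promoter windows and peak features
# ---------------------------------------------------------------------------

def promoter_window(
    gene: GeneAnnotation,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> PromoterWindow:
    """Strand-aware promoter window [TSS - upstream, TSS + downstream).

    On ``-`` the window is reflected about the TSS.  Starts below zero are
    clipped (flagged and logged).
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    clipped = start < 0
    if clipped:
        logger.warning("promoter window of %s clipped at chromosome start", gene.gene_id)
        start = 0
    return PromoterWindow(chrom=gene.chrom, start=start, end=end,
                          gene_id=gene.gene_id, clipped=clipped)


def peaks_from_signal(
    track: Iterable[tuple[str, int, int, float]],
    window: PromoterWindow,
    min_height: float = 1.0,
) -> list[Peak]:
    """Derive peaks inside a promoter window from a bedGraph-style track.

    A peak is a maximal run of contiguous intervals with value >= min_height,
    intersected with the window; its height is the run maximum and its summit
    the midpoint of the first maximal-value interval.
    """
    if min_height <= 0:
        raise ValueError("min_height must be > 0")
    runs: list[list[tuple[int, int, float]]] = []
    current: list[tuple[int, int, float]] = []
    for chrom, start, end, value in track:
        if chrom != window.chrom:
            continue
        if value >= min_height:
            if current and start != current[-1][1]:
                runs.append(current)
                current = []
            current.append((start, end, value))
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)

    peaks: list[Peak] = []
    for run in runs:
        r_start, r_end = run[0][0], run[-1][1]
        start = max(r_start, window.start)
        end = min(r_end, window.end)
        if end <= start:
            continue
        height = max(v for _, _, v in run)
        first_max = next(iv for iv in run if iv[2] == height)
        summit = (first_max[0] + first_max[1]) // 2
        summit = min(max(summit, start), end - 1)
        peaks.append(Peak(chrom=window.chrom, start=start, end=end,
                          height=height, summit=summit))
    return peaks


def extract_peak_features(peak: Peak, gene: GeneAnnotation) -> tuple[float, int, int]:
    """Return (H, D, W): peak height, |midpoint - TSS| in bp, and width."""
    H = peak.height
    W = peak.width
    D = abs(peak.midpoint - gene.tss)
    return H, D, W


class NoPeakInPromoter(ValueError):
    """Raised when a promoter holds no qualifying peak at a timepoint."""


def select_strongest(peaks: Sequence[Peak], tss: int | None = None) -> Peak:
    """Pick the peak of maximal height; ties broken by smallest distance to
    ``tss`` (when given), then leftmost start.  Deterministic in input order."""
    if not peaks:
        raise NoPeakInPromoter("no peak in promoter")

    def key(p: Peak) -> tuple[float, int, int]:
        dist = abs(p.midpoint - tss) if tss is not None else 0
        return (-p.height, dist, p.start)

    return min(peaks, key=key)


# ---------------------------------------------------------------------------
# feature tables and joins
# ---------------------------------------------------------------------------

def features_to_frame(features: Sequence[PeakFeatures]) -> pd.DataFrame:
    return pd.DataFrame(
        [(f.gene_id, f.day, f.height, f.distance, f.width) for f in features],
        columns=["gene_id", "day", "height", "distance", "width"],
    )


def write_features_tsv(features: Sequence[PeakFeatures], path: str | Path) -> None:
    features_to_frame(features).to_csv(path, sep="\t", index=False)


def read_features_tsv(path: str | Path) -> list[PeakFeatures]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        PeakFeatures(gene_id=str(r.gene_id), day=int(r.day), height=float(r.height),
                     distance=int(r.distance), width=int(r.width))
        for r in df.itertuples()
    ]


def join_expression(
    features: Sequence[PeakFeatures],
    expression: pd.DataFrame,
) -> list[TimeCourseRecord]:
    """Inner-join peak features with an expression table on (gene_id, day).

    Keys must be unique on both sides; unmatched records are logged and
    dropped.  Output is sorted by (gene_id, day).
    """
    feat = features_to_frame(list(features))
    expr = expression[["gene_id", "day", "expression"]].copy()
    for name, df in (("features", feat), ("expression", expr)):
        dup = df.duplicated(subset=["gene_id", "day"])
        if dup.any():
            bad = df.loc[dup, ["gene_id", "day"]].iloc[0]
            raise ValueError(
                f"duplicate (gene_id, day) key in {name}: ({bad.gene_id}, {bad.day})")
    merged = feat.merge(expr, on=["gene_id", "day"], how="inner")
    n_drop_f = len(feat) - len(merged)
    n_drop_e = len(expr) - len(merged)
    if n_drop_f or n_drop_e:
        logger.warning(
            "join_expression dropped %d feature and %d expression records "
            "without a partner", n_drop_f, n_drop_e)
    merged = merged.sort_values(["gene_id", "day"], kind="mergesort").reset_index(drop=True)
    return [
        TimeCourseRecord(gene_id=str(r.gene_id), day=int(r.day), height=float(r.height),
                         distance=float(r.distance), width=float(r.width),
                         expression=float(r.expression))
        for r in merged.itertuples()
    ]


def records_to_frame(records: Sequence[TimeCourseRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.day, r.height, r.distance, r.width, r.expression) for r in records],
        columns=["gene_id", "day", "height", "distance", "width", "expression"],
    )


def extract_features_for_genes(
    tracks_by_day: dict[int, list[tuple[str, int, int, float]]],
    genes: Sequence[GeneAnnotation],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    min_height: float = 1.0,
) -> list[PeakFeatures]:
    """Full extraction stage: for every gene and day, find the strongest
    promoter peak and summarise it as (H, D, W).  Genes without a qualifying
    peak at a timepoint are dropped with a warning."""
    out: list[PeakFeatures] = []
    for day, track in sorted(tracks_by_day.items()):
        for gene in genes:
            window = promoter_window(gene, upstream, downstream)
            peaks = peaks_from_signal(track, window, min_height=min_height)
            try:
                best = select_strongest(peaks, tss=gene.tss)
            except NoPeakInPromoter:
                logger.warning("gene %s day %d: no peak in promoter, dropped",
                               gene.gene_id, day)
                continue
            H, D, W = extract_peak_features(best, gene)
            out.append(PeakFeatures(gene_id=gene.gene_id, day=day,
                                    height=H, distance=D, width=W))
    return out
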