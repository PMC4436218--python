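"""PWM site prediction, functional classification, and per-site occupancy.

Sites are predicted by scanning both strands with a log-odds matrix built
from PFM counts (+0.01 pseudocount per cell). A window is reported when its
relative score, (score - min) / (max - min), reaches the threshold. A
predicted site is functional when the mean of its two ChIP occupancy scores
reaches the cutoff (default 20).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fragment_io import BASE_ORDER, MotifMatrix
from .occupancy import OccupancyTrack

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 0.01
DEFAULT_THRESHOLD = 0.80
DEFAULT_FUNCTIONAL_CUTOFF = 20.0

GENE_CLASSES = ("class1_active", "class2_poised", "class3_bivalent_unregulated")


@dataclass(frozen=True)
class PredictedSite:
    """A motif hit spanning `width` bp of a named region (0-based start)."""

    region: str
    start: int
    strand: str  # '+' or '-'
    width: int
    pwm_score: float  # log2 odds
    relative_score: float  # (score - min) / (max - min), in [0, 1]
    chip_oct4: float | None = None
    chip_sox2: float | None = None
    functional: bool | None = None
    gene_class: str | None = None

    @property
    def site_id(self) -> str:
        return f"{self.region}:{self.start}:{self.strand}"

    @property
    def end(self) -> int:
        return self.start + self.width

    @property
    def chip_mean(self) -> float | None:
        if self.chip_oct4 is None or self.chip_sox2 is None:
            return None
        return (self.chip_oct4 + self.chip_sox2) / 2.0


@dataclass(frozen=True)
class SiteOccupancySummary:
    """Per-site in vivo / in vitro averages and their log2 fold change."""

    site: PredictedSite
    invivo_avg: float
    invitro_avg: float
    log2_fold: float


def log_odds_matrix(motif: MotifMatrix,
                    pseudocount: float = PSEUDOCOUNT) -> np.ndarray:
    """log2 odds matrix (4 x width) from PFM counts and background."""
    counts = motif.counts + pseudocount
    probs = counts / counts.sum(axis=0, keepdims=True)
    return np.log2(probs / motif.background[:, None])


def _encode(sequence: str) -> np.ndarray:
    """Map bases to 0..3; anything not ACGT becomes 4."""
    table = np.full(256, 4, dtype=np.int64)
    for i, base in enumerate(BASE_ORDER):
        table[ord(base)] = i
        table[ord(base.lower())] = i
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def scan_pwm(sequence: str, motif: MotifMatrix,
             threshold: float = DEFAULT_THRESHOLD,
             region_name: str = "region") -> list[PredictedSite]:
    """Scan both strands; report windows whose relative score >= threshold.

    Windows containing ambiguous bases are not scored. If both strands pass
    at one position, the higher-scoring strand is reported (tie: forward).
    Overlapping hits are all reported.
    """
    width = motif.width
    if len(sequence) < width:
        return []
    lo = log_odds_matrix(motif)
    lo_rc = lo[::-1, ::-1]  # reverse complement: rows A<->T, C<->G and columns flipped
    smin, smax = lo.min(axis=0).sum(), lo.max(axis=0).sum()
    span = smax - smin

    codes = _encode(sequence)
    windows = np.lib.stride_tricks.sliding_window_view(codes, width)
    valid = (windows < 4).all(axis=1)
    cols = np.arange(width)
    # pad log-odds with a row for ambiguous codes so indexing stays vectorized
    lo_p = np.vstack([lo, np.full((1, width), -np.inf)])
    lo_rc_p = np.vstack([lo_rc, np.full((1, width), -np.inf)])
    fwd = lo_p[windows, cols].sum(axis=1)
    rev = lo_rc_p[windows, cols].sum(axis=1)

    sites = []
    for pos in np.flatnonzero(valid):
        f, r = fwd[pos], rev[pos]
        score, strand = (f, "+") if f >= r else (r, "-")
        rel = (score - smin) / span
        if rel >= threshold:
            sites.append(PredictedSite(
                region=region_name, start=int(pos), strand=strand, width=width,
                pwm_score=float(score), relative_score=float(rel),
            ))
    return sites


def scan_regions(sequences: dict[str, str], motif: MotifMatrix,
                 threshold: float = DEFAULT_THRESHOLD) -> list[PredictedSite]:
    """scan_pwm over every named sequence, concatenating the hit lists."""
    sites = []
    for name in sequences:
        sites.extend(scan_pwm(sequences[name], motif, threshold, region_name=name))
    return sites


def classify_sites(sites: list[PredictedSite],
                   chip_scores: dict[str, tuple[float, float]],
                   cutoff: float = DEFAULT_FUNCTIONAL_CUTOFF,
                   class_map: dict[str, str] | None = None) -> list[PredictedSite]:
    """Attach ChIP occupancy and the functional flag (chip_mean >= cutoff).

    `chip_scores` maps site_id -> (oct4, sox2); missing sites are scored 0
    with a warning. `class_map` maps region name -> gene class label.
    """
    classified = []
    for site in sites:
        if site.site_id in chip_scores:
            oct4, sox2 = chip_scores[site.site_id]
        else:
            logger.warning("no ChIP entry for site %s; scoring it 0", site.site_id)
            oct4, sox2 = 0.0, 0.0
        if oct4 < 0 or sox2 < 0:
            raise ValidationError(f"negative ChIP score for site {site.site_id}")
        mean = (oct4 + sox2) / 2.0
        gene_class = class_map.get(site.region) if class_map else site.gene_class
        classified.append(replace(
            site, chip_oct4=float(oct4), chip_sox2=float(sox2),
            functional=bool(mean >= cutoff), gene_class=gene_class,
        ))
    return classified


def site_occupancy(track: OccupancyTrack, site: PredictedSite) -> float:
    """Arithmetic mean of the track over the site's span."""
    values = track.values.get(site.region)
    if values is None:
        raise ValidationError(f"track has no region {site.region}")
    if site.start < 0 or site.end > values.size:
        raise ValidationError(
            f"site {site.site_id} extends past region edge "
            f"({site.start}..{site.end} of {values.size} bp)"
        )
    return float(values[site.start:site.end].mean())


def fold_change(invivo_avg: float, invitro_avg: float) -> float:
    """log2(in vivo / in vitro); negative means in vivo depletion."""
    if invivo_avg <= 0 or invitro_avg <= 0:
        raise ValidationError(
            f"fold_change requires positive averages, got ({invivo_avg}, {invitro_avg})"
        )
    # log2(a) - log2(b) rather than log2(a/b): keeps antisymmetry exact
    return math.log2(invivo_avg) - math.log2(invitro_avg)


def summarize_sites(sites: list[PredictedSite], invivo: OccupancyTrack,
                    invitro: OccupancyTrack) -> list[SiteOccupancySummary]:
    """Per-site occupancy averages on both tracks plus log2 fold change."""
    out = []
    for site in sites:
        a = site_occupancy(invivo, site)
        b = site_occupancy(invitro, site)
        out.append(SiteOccupancySummary(site=site, invivo_avg=a, invitro_avg=b,
                                        log2_fold=fold_change(a, b)))
    return out


# ---------------------------------------------------------------------------
# tabular I/O


def sites_to_frame(sites: list[PredictedSite]) -> pd.DataFrame:
    return pd.DataFrame([{
        "site_id": s.site_id, "region": s.region, "start": s.start,
        "strand": s.strand, "width": s.width, "pwm_score": s.pwm_score,
        "relative_score": s.relative_score, "chip_oct4": s.chip_oct4,
        "chip_sox2": s.chip_sox2, "functional": s.functional,
        "gene_class": s.gene_class,
    } for s in sites])


def write_sites(sites: list[PredictedSite], path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_sites(path) -> list[PredictedSite]:
    df = pd.read_csv(path, sep="\t")
    sites = []
    for row in df.itertuples(index=False):
        functional = None if pd.isna(row.functional) else bool(row.functional)
        sites.append(PredictedSite(
            region=str(row.region), start=int(row.start), strand=str(row.strand),
            width=int(row.width), pwm_score=float(row.pwm_score),
            relative_score=float(row.relative_score),
            chip_oct4=None if pd.isna(row.chip_oct4) else float(row.chip_oct4),
            chip_sox2=None if pd.isna(row.chip_sox2) else float(row.chip_sox2),
            functional=functional,
            gene_class=None if pd.isna(row.gene_class) else str(row.gene_class),
        ))
    return sites


def read_chip_table(path) -> dict[str, tuple[float, float]]:
    """TSV with columns site_id, oct4, sox2."""
    df = pd.read_csv(path, sep="\t")
    return {str(r.site_id): (float(r.oct4), float(r.sox2))
            for r in df.itertuples(index=False)}


def read_class_map(path) -> dict[str, str]:
    """TSV with columns region, gene_class."""
    df = pd.read_csv(path, sep="\t")
    return {str(r.region): str(r.gene_class) for r in df.itertuples(index=False)}


def summaries_to_frame(summaries: list[SiteOccupancySummary]) -> pd.DataFrame:
    frame = sites_to_frame([s.site for s in summaries])
    frame["invivo_avg"] = [s.invivo_avg for s in summaries]
    frame["invitro_avg"] = [s.invitro_avg for s in summaries]
    frame["log2_fold"] = [s.log2_fold for s in summaries]
    return frame


def write_summaries(summaries: list[SiteOccupancySummary], path) -> None:
    summaries_to_frame(summaries).to_csv(path, sep="\t", index=False)
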