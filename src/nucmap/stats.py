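"""Group summaries, two-group z-tests, track correlation, and enrichment QC."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .fragment_io import GenomicRegion
from .occupancy import OccupancyTrack
from .tfbs import SiteOccupancySummary


@dataclass(frozen=True)
class GroupSummary:
    """Mean/SEM occupancy and median fold change for one (class, flag) cell.

    SEM uses the n-1 sample standard deviation over sqrt(n); with n = 1 it
    is reported as 0 and `sem_defined` is False.
    """

    gene_class: str | None
    functional: bool
    n: int
    mean_invivo: float
    sem_invivo: float
    mean_invitro: float
    sem_invitro: float
    median_log2_fold: float
    sem_defined: bool = True

    @property
    def group_key(self) -> tuple[str | None, bool]:
        return (self.gene_class, self.functional)


@dataclass(frozen=True)
class GroupComparison:
    group_a: tuple
    group_b: tuple
    z: float
    p: float


@dataclass(frozen=True)
class EnrichmentEstimate:
    p_unenriched: float
    p_enriched: float

    def __post_init__(self):
        if not 0 < self.p_unenriched <= 1:
            raise ValidationError(f"p_unenriched must be in (0, 1], got {self.p_unenriched}")
        if not 0 <= self.p_enriched <= 1:
            raise ValidationError(f"p_enriched must be in [0, 1], got {self.p_enriched}")

    @property
    def fold(self) -> float:
        return self.p_enriched / self.p_unenriched


@dataclass(frozen=True)
class OnTargetReport:
    table: pd.DataFrame  # columns: region, length, actual, expected, ratio
    total_reads: int
    on_target_fraction: float


def sem(values: np.ndarray) -> float:
    """Standard error of the mean (n-1 denominator); 0 when n < 2."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / math.sqrt(values.size))


def summarize_groups(summaries: list[SiteOccupancySummary]) -> list[GroupSummary]:
    """One GroupSummary per nonempty (gene_class, functional) cell."""
    cells: dict[tuple, list[SiteOccupancySummary]] = {}
    for s in summaries:
        if s.site.functional is None:
            raise ValidationError(f"site {s.site.site_id} is unclassified")
        cells.setdefault((s.site.gene_class, s.site.functional), []).append(s)
    out = []
    for (gene_class, functional), members in sorted(
            cells.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])):
        vivo = np.array([m.invivo_avg for m in members])
        vitro = np.array([m.invitro_avg for m in members])
        folds = np.array([m.log2_fold for m in members])
        out.append(GroupSummary(
            gene_class=gene_class, functional=functional, n=len(members),
            mean_invivo=float(vivo.mean()), sem_invivo=sem(vivo),
            mean_invitro=float(vitro.mean()), sem_invitro=sem(vitro),
            median_log2_fold=float(np.median(folds)),
            sem_defined=len(members) >= 2,
        ))
    return out


def two_group_z(values_a, values_b, label_a="a", label_b="b") -> GroupComparison:
    """Two-sample z-test on group means using each group's SEM.

    z = (mean_a - mean_b) / sqrt(sem_a^2 + sem_b^2); two-sided p from the
    standard normal. Both groups need n >= 2.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("two_group_z requires n >= 2 in both groups")
    diff = a.mean() - b.mean()
    denom = math.sqrt(sem(a) ** 2 + sem(b) ** 2)
    if diff == 0:
        z = 0.0
    elif denom == 0:
        raise ValidationError("two_group_z: zero variance in both groups with unequal means")
    else:
        z = diff / denom
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return GroupComparison(group_a=(label_a,), group_b=(label_b,), z=float(z), p=p)


def spearman_tracks(track_a: OccupancyTrack, track_b: OccupancyTrack) -> tuple[float, float]:
    """Spearman rank correlation over all bp of two tracks on identical regions.

    Returns (rho, p); p uses the large-sample approximation and is
    informational only. Ties get average ranks.
    """
    names_a = [r.name for r in track_a.regions]
    names_b = [r.name for r in track_b.regions]
    if names_a != names_b:
        raise ValidationError("tracks cover different region sets")
    for r in track_a.regions:
        if track_a.values[r.name].size != track_b.values[r.name].size:
            raise ValidationError(f"region {r.name} length mismatch between tracks")
    rho, p = sps.spearmanr(track_a.all_values(), track_b.all_values())
    return float(rho), float(p)


def enrichment_fold(on_target_clones: int, total_clones: int,
                    region_bp: int, genome_bp: int) -> EnrichmentEstimate:
    """Enrichment fold from clone counts and region/genome sizes."""
    if total_clones <= 0 or genome_bp <= 0 or region_bp <= 0:
        raise ValidationError("counts and sizes must be positive")
    if on_target_clones > total_clones:
        raise ValidationError("on-target clones exceed total clones")
    return EnrichmentEstimate(p_unenriched=region_bp / genome_bp,
                              p_enriched=on_target_clones / total_clones)


def enrichment_fold_from_probs(p_enriched: float, p_unenriched: float) -> EnrichmentEstimate:
    """Enrichment fold directly from the two sequencing probabilities."""
    return EnrichmentEstimate(p_unenriched=p_unenriched, p_enriched=p_enriched)


def paired_percentage(paired_reads: float, total_ends: float) -> float:
    """Percent of read ends that formed aligned pairs: 100 * paired / total."""
    if total_ends <= 0:
        raise ValidationError("total_ends must be positive")
    return 100.0 * paired_reads / total_ends


def on_target_report(read_counts: dict[str, int], regions: list[GenomicRegion],
                     total_reads: int) -> OnTargetReport:
    """Per-region actual/expected read ratios plus the overall on-target fraction.

    Expected reads for a region = total_reads * region length / total target
    length (reads distributed proportionally to length).
    """
    total_len = sum(r.length for r in regions)
    if total_len == 0:
        raise ValidationError("region lengths sum to zero")
    if total_reads <= 0:
        raise ValidationError("total_reads must be positive")
    on_target = sum(read_counts.get(r.name, 0) for r in regions)
    if on_target > total_reads:
        raise ValidationError("on-target reads exceed total reads")
    rows = []
    for r in regions:
        actual = read_counts.get(r.name, 0)
        expected = total_reads * r.length / total_len
        rows.append((r.name, r.length, actual, expected, actual / expected))
    table = pd.DataFrame(rows, columns=["region", "length", "actual", "expected", "ratio"])
    return OnTargetReport(table=table, total_reads=total_reads,
                          on_target_fraction=on_target / total_reads)


def groups_to_frame(groups: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_class": g.gene_class, "functional": g.functional, "n": g.n,
        "mean_invivo": g.mean_invivo, "sem_invivo": g.sem_invivo,
        "mean_invitro": g.mean_invitro, "sem_invitro": g.sem_invitro,
        "median_log2_fold": g.median_log2_fold, "sem_defined": g.sem_defined,
    } for g in groups])
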