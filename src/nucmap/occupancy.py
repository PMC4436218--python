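"""Center-weighted nucleosome occupancy tracks.

Each fragment contributes a truncated Gaussian weight profile anchored at
its midpoint: w(d) = exp(-0.5 * (d / sigma)^2) for integer offsets
|d| <= truncation, zero beyond. Odd-length fragments have a single center;
for even-length fragments the two central positions each act as center and
the two profiles are averaged, so per-fragment mass is independent of
length parity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import ValidationError
from .fragment_io import FragmentRecord, GenomicRegion

logger = logging.getLogger(__name__)

STAGE_RAW = "raw"
STAGE_NORMALIZED = "normalized"
STAGE_GC_ADJUSTED = "gc_adjusted"

GC_FLOOR = 0.01


@dataclass(frozen=True)
class CenterKernel:
    """Truncated Gaussian weight applied around a fragment midpoint."""

    sigma: float = 20.0
    truncation: int = 73

    def weight(self, d) -> np.ndarray | float:
        """w(d) for integer offset(s) d from the center."""
        d = np.asarray(d, dtype=float)
        w = np.exp(-0.5 * (d / self.sigma) ** 2)
        return np.where(np.abs(d) <= self.truncation, w, 0.0)[()]

    def weights(self) -> np.ndarray:
        """The full profile over d = -truncation .. +truncation."""
        d = np.arange(-self.truncation, self.truncation + 1)
        return np.exp(-0.5 * (d / self.sigma) ** 2)

    @property
    def mass(self) -> float:
        """Total weight a fully interior fragment deposits."""
        return float(self.weights().sum())

    @property
    def support(self) -> int:
        return 2 * self.truncation + 1


DEFAULT_KERNEL = CenterKernel()


@dataclass
class OccupancyTrack:
    """Per-bp occupancy scores over a set of named regions."""

    regions: list[GenomicRegion]
    values: dict[str, np.ndarray]
    stage: str = STAGE_RAW
    dataset_label: str = ""

    def __post_init__(self):
        for region in self.regions:
            vals = np.asarray(self.values[region.name], dtype=float)
            self.values[region.name] = vals
            if vals.shape != (region.length,):
                raise ValidationError(
                    f"track {self.dataset_label!r}: region {region.name} has "
                    f"{vals.size} values for {region.length} bp"
                )
            if (vals < 0).any():
                raise ValidationError(
                    f"track {self.dataset_label!r}: negative values in {region.name}"
                )

    @property
    def total_bp(self) -> int:
        return sum(r.length for r in self.regions)

    def all_values(self) -> np.ndarray:
        """Concatenated per-bp values over all regions, in region order."""
        return np.concatenate([self.values[r.name] for r in self.regions]) \
            if self.regions else np.empty(0)

    def grand_mean(self) -> float:
        return float(self.all_values().mean())

    def copy(self) -> "OccupancyTrack":
        return OccupancyTrack(
            regions=list(self.regions),
            values={k: v.copy() for k, v in self.values.items()},
            stage=self.stage,
            dataset_label=self.dataset_label,
        )


def fragment_centers(fragment: FragmentRecord) -> list[tuple[int, float]]:
    """Weighted midpoint position(s) of a fragment.

    Odd length: the single central bp with weight 1. Even length: the two
    central bp, each with weight 1/2.
    """
    length = fragment.length
    if length < 1:
        raise ValidationError(f"fragment {fragment} has nonpositive length")
    if length % 2 == 1:
        return [(fragment.start + (length - 1) // 2, 1.0)]
    mid = fragment.start + length // 2
    return [(mid - 1, 0.5), (mid, 0.5)]


def fragment_weights(fragment: FragmentRecord,
                     kernel: CenterKernel = DEFAULT_KERNEL) -> tuple[int, np.ndarray]:
    """Per-bp weight profile for one fragment.

    Returns (genomic position of the first profile entry, profile array).
    The profile sums to kernel.mass for both parities.
    """
    centers = fragment_centers(fragment)
    first = min(c for c, _ in centers) - kernel.truncation
    last = max(c for c, _ in centers) + kernel.truncation
    profile = np.zeros(last - first + 1)
    base = kernel.weights()
    for center, wt in centers:
        off = center - kernel.truncation - first
        profile[off:off + base.size] += wt * base
    return first, profile


def build_occupancy(fragments: Iterable[FragmentRecord],
                    regions: list[GenomicRegion],
                    kernel: CenterKernel = DEFAULT_KERNEL,
                    dataset_label: str = "") -> OccupancyTrack:
    """Sum fragment center-weight profiles into a raw per-bp track.

    Fragments whose midpoint falls outside a region still contribute the part
    of their weight support that overlaps it; contributions falling outside
    all regions are discarded (no edge renormalization).
    """
    pad = kernel.truncation
    hists = {r.name: np.zeros(r.length + 2 * pad) for r in regions}
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)

    n = 0
    for frag in fragments:
        n += 1
        targets = by_chrom.get(frag.chrom)
        if not targets:
            continue
        for center, wt in fragment_centers(frag):
            for region in targets:
                idx = center - region.start + pad
                if 0 <= idx < hists[region.name].size:
                    hists[region.name][idx] += wt
    if n == 0:
        logger.warning("build_occupancy: empty fragment stream, track is all zero")

    base = kernel.weights()
    values = {}
    for region in regions:
        smoothed = np.convolve(hists[region.name], base, mode="same")
        values[region.name] = smoothed[pad:pad + region.length] if pad else smoothed
    return OccupancyTrack(regions=list(regions), values=values,
                          stage=STAGE_RAW, dataset_label=dataset_label)


def normalize_track(track: OccupancyTrack) -> OccupancyTrack:
    """Divide every value by the grand mean over all covered bp (mean -> 1)."""
    if track.stage != STAGE_RAW:
        raise ValidationError(f"normalize_track expects a raw track, got {track.stage!r}")
    mean = track.grand_mean()
    if mean <= 0:
        raise ValidationError("normalize_track: all-zero track, normalization undefined")
    out = track.copy()
    for name in out.values:
        out.values[name] /= mean
    out.stage = STAGE_NORMALIZED
    return out
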