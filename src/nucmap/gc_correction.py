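"""GC-bias model: quadratic fit of log bin score on GC, and per-bp correction.

A naked-DNA MNase control is binned (20 bp), log mean score is regressed on
bin GC fraction with an ordinary least-squares quadratic F(GC), and tracks
are corrected by dividing each bp by exp(F(GC_i)) where GC_i is the GC
fraction of a +/-10 bp window around position i. Corrected values are
floored at 0.01.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FitError, ValidationError
from .occupancy import (GC_FLOOR, STAGE_GC_ADJUSTED, STAGE_NORMALIZED,
                        OccupancyTrack)

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 20
DEFAULT_WINDOW_HALFWIDTH = 10

_GC_BASES = frozenset("GCgc")
_VALID_BASES = frozenset("ACGTacgt")


@dataclass
class GCModel:
    """Quadratic F(GC) = a*GC^2 + b*GC + c fitted on log-scale bin scores."""

    coefficients: tuple[float, float, float]  # (a, b, c)
    bin_size: int = DEFAULT_BIN_SIZE
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH
    n_bins_fit: int = 0
    n_bins_excluded: int = 0

    def __post_init__(self):
        if self.bin_size <= 0 or self.window_halfwidth <= 0:
            raise ValidationError("bin_size and window_halfwidth must be positive")

    def predict(self, gc) -> np.ndarray:
        a, b, c = self.coefficients
        gc = np.asarray(gc, dtype=float)
        return a * gc ** 2 + b * gc + c

    def to_json(self, path) -> None:
        doc = {
            "coefficients": list(self.coefficients),
            "bin_size": self.bin_size,
            "window_halfwidth": self.window_halfwidth,
            "n_bins_fit": self.n_bins_fit,
            "n_bins_excluded": self.n_bins_excluded,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GCModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            coefficients=tuple(doc["coefficients"]),
            bin_size=doc.get("bin_size", DEFAULT_BIN_SIZE),
            window_halfwidth=doc.get("window_halfwidth", DEFAULT_WINDOW_HALFWIDTH),
            n_bins_fit=doc.get("n_bins_fit", 0),
            n_bins_excluded=doc.get("n_bins_excluded", 0),
        )


@dataclass
class GCBinTable:
    """(bin GC fraction, mean bin score) pairs used to fit the GC model."""

    table: pd.DataFrame  # columns: region, bin_start, gc, score
    bin_size: int = DEFAULT_BIN_SIZE
    n_partial_dropped: int = 0


def gc_fraction_window(sequence: str, i: int,
                       halfwidth: int = DEFAULT_WINDOW_HALFWIDTH) -> float:
    """GC fraction of the +/-halfwidth window around position i.

    The window is shrunk to available bases at region edges. Ambiguous
    bases are excluded from numerator and denominator; an all-ambiguous
    window yields 0.5 with a warning.
    """
    if not 0 <= i < len(sequence):
        raise ValidationError(f"position {i} outside sequence of length {len(sequence)}")
    window = sequence[max(0, i - halfwidth):i + halfwidth + 1]
    counted = sum(1 for b in window if b in _VALID_BASES)
    if counted == 0:
        logger.warning("gc_fraction_window: all-ambiguous window at position %d", i)
        return 0.5
    gc = sum(1 for b in window if b in _GC_BASES)
    return gc / counted


def gc_profile(sequence: str, halfwidth: int = DEFAULT_WINDOW_HALFWIDTH) -> np.ndarray:
    """Vectorized gc_fraction_window over every position of a sequence."""
    codes = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    is_gc = ((codes == ord("G")) | (codes == ord("C"))).astype(float)
    is_valid = np.isin(codes, np.frombuffer(b"ACGT", dtype=np.uint8)).astype(float)
    n = codes.size
    cum_gc = np.concatenate(([0.0], np.cumsum(is_gc)))
    cum_valid = np.concatenate(([0.0], np.cumsum(is_valid)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - halfwidth)
    hi = np.minimum(n, idx + halfwidth + 1)
    gc = cum_gc[hi] - cum_gc[lo]
    valid = cum_valid[hi] - cum_valid[lo]
    if (valid == 0).any():
        logger.warning("gc_profile: %d all-ambiguous windows set to 0.5",
                       int((valid == 0).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(valid > 0, gc / np.maximum(valid, 1), 0.5)
    return frac


def build_bin_table(control_track: OccupancyTrack, sequences: dict[str, str],
                    bin_size: int = DEFAULT_BIN_SIZE) -> GCBinTable:
    """Tile track regions into complete bins of `bin_size` bp.

    Per bin: score = mean of the per-bp track values, gc = GC fraction of
    the bin's bases (ambiguous bases excluded). Trailing partial bins are
    dropped and counted.
    """
    if control_track.stage != STAGE_NORMALIZED:
        raise ValidationError("build_bin_table expects a normalized control track")
    rows = []
    n_partial = 0
    for region in control_track.regions:
        if region.name not in sequences:
            raise ValidationError(f"no sequence for region {region.name}")
        seq = sequences[region.name].upper()
        if len(seq) != region.length:
            raise ValidationError(
                f"sequence for {region.name} has {len(seq)} bp, region has {region.length}"
            )
        vals = control_track.values[region.name]
        n_bins = region.length // bin_size
        if region.length % bin_size:
            n_partial += 1
        for b in range(n_bins):
            s = b * bin_size
            chunk = seq[s:s + bin_size]
            counted = sum(1 for x in chunk if x in _VALID_BASES)
            gc = (sum(1 for x in chunk if x in _GC_BASES) / counted) if counted else 0.5
            rows.append((region.name, s, gc, float(vals[s:s + bin_size].mean())))
    table = pd.DataFrame(rows, columns=["region", "bin_start", "gc", "score"])
    return GCBinTable(table=table, bin_size=bin_size, n_partial_dropped=n_partial)


def fit_gc_model(bin_table: GCBinTable,
                 window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH) -> GCModel:
    """OLS quadratic of log(score) on GC over bins with score > 0."""
    table = bin_table.table
    usable = table[table["score"] > 0]
    n_excluded = len(table) - len(usable)
    if len(usable) < 3:
        raise FitError(f"need >= 3 bins with positive score, got {len(usable)}")
    a, b, c = np.polyfit(usable["gc"].to_numpy(), np.log(usable["score"].to_numpy()), 2)
    return GCModel(coefficients=(float(a), float(b), float(c)),
                   bin_size=bin_table.bin_size,
                   window_halfwidth=window_halfwidth,
                   n_bins_fit=len(usable), n_bins_excluded=n_excluded)


def apply_gc_correction(track: OccupancyTrack, sequences: dict[str, str],
                        model: GCModel, floor: float = GC_FLOOR) -> OccupancyTrack:
    """Divide each bp by exp(F(GC_i)) and floor the result at `floor`."""
    if track.stage != STAGE_NORMALIZED:
        raise ValidationError("apply_gc_correction expects a normalized track")
    for region in track.regions:  # validate everything before writing anything
        if region.name not in sequences:
            raise ValidationError(f"no sequence for region {region.name}")
        if len(sequences[region.name]) != region.length:
            raise ValidationError(
                f"sequence for {region.name} has {len(sequences[region.name])} bp, "
                f"region has {region.length}"
            )
    out = track.copy()
    for region in out.regions:
        gc = gc_profile(sequences[region.name], model.window_halfwidth)
        corrected = out.values[region.name] / np.exp(model.predict(gc))
        out.values[region.name] = np.maximum(corrected, floor)
    out.stage = STAGE_GC_ADJUSTED
    return out
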