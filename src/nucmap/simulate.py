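"""Synthetic worlds and mononucleosome libraries with known ground truth.

A world realizes region sequences with a controllable GC landscape, plants
motif instances (exact consensus strings), and defines a positive per-bp
nucleosome preference landscape lambda. Libraries are drawn multinomially
over fragment-midpoint positions:

* ``invitro``  - midpoints proportional to lambda (sequence preference only)
* ``invivo``   - lambda multiplied by a displacement factor delta over a
  nucleosome-sized window centered on each functional motif
* ``naked``    - proportional to exp(a*GC^2 + b*GC + c) of the +/-10 bp GC
  fraction (uniform when the bias coefficients are zero)

Fragment lengths are 147 +/- uniform jitter, so both the odd- and
even-length midpoint rules are always exercised downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .fragment_io import (FragmentRecord, GenomicRegion, MotifMatrix,
                          write_fasta, write_fragments, write_motif,
                          write_regions)
from .gc_correction import gc_profile

# Invented joint-binding motif with an unambiguous 15 bp consensus.
DEFAULT_MOTIF_COUNTS = np.array([
    # consensus: C T T T G T T A T G C A A A T
    [1, 1, 1, 1, 1, 1, 1, 97, 1, 1, 1, 97, 97, 97, 1],   # A
    [97, 1, 1, 1, 1, 1, 1, 1, 1, 1, 97, 1, 1, 1, 1],     # C
    [1, 1, 1, 1, 97, 1, 1, 1, 1, 97, 1, 1, 1, 1, 1],     # G
    [1, 97, 97, 97, 1, 97, 97, 1, 97, 1, 1, 1, 1, 1, 97], # T
], dtype=float)

DEFAULT_MOTIF = MotifMatrix(counts=DEFAULT_MOTIF_COUNTS)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

LIBRARY_KINDS = ("invitro", "invivo", "naked")
_KIND_CODE = {"invitro": 11, "invivo": 22, "naked": 33}

MIN_REGION_LENGTH = 1000
DISPLACEMENT_WINDOW = 147  # a bound TF excludes the whole nucleosome footprint


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RegionSpec:
    name: str
    length: int
    chrom: str = ""  # empty -> auto "chr_<name>", keeping regions disjoint
    start: int = 1_000_000  # genomic offset of the region
    gene_class: str = "class1_active"

    def resolved_chrom(self) -> str:
        return self.chrom or f"chr_{self.name}"


@dataclass(frozen=True)
class MotifPlacement:
    region: str
    pos: int  # region-relative 0-based start of the motif
    strand: str = "+"
    functional: bool = False


@dataclass(frozen=True)
class PlantedMotif:
    region: str
    pos: int
    strand: str
    functional: bool
    gene_class: str
    chip_oct4: float
    chip_sox2: float

    @property
    def site_id(self) -> str:
        return f"{self.region}:{self.pos}:{self.strand}"


@dataclass
class SimConfig:
    seed: int = 0
    regions: list[RegionSpec] = field(default_factory=lambda: [RegionSpec("regA", 10_000)])
    placements: list[MotifPlacement] = field(default_factory=list)
    motif: MotifMatrix = field(default_factory=lambda: DEFAULT_MOTIF)
    # GC landscape: gc(i) = base + amplitude * sin(2*pi*i / period)
    gc_base: float = 0.5
    gc_amplitude: float = 0.0
    gc_period: float = 2000.0
    # preference landscape
    preference_amplitude: float = 0.4  # log-scale sd of the smooth background
    smoothness_sigma: float = 50.0
    n_positioning_elements: int = 0
    delta: float = 1.0  # displacement factor at functional sites, in (0, 1]
    displacement_window: int = DISPLACEMENT_WINDOW
    # naked-library multiplicative GC bias exp(a*GC^2 + b*GC + c)
    gc_bias: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # library sampling
    depth: int = 100_000
    fragment_length: int = 147
    length_jitter: int = 20
    chip_functional_range: tuple[float, float] = (25.0, 60.0)
    chip_nonfunctional_range: tuple[float, float] = (0.0, 15.0)

    @classmethod
    def from_dict(cls, doc: dict) -> "SimConfig":
        doc = dict(doc)
        regions = [RegionSpec(**r) for r in doc.pop("regions", [])]
        placements = [MotifPlacement(**p) for p in doc.pop("placements", [])]
        for key in ("gc_bias", "chip_functional_range", "chip_nonfunctional_range"):
            if key in doc:
                doc[key] = tuple(doc[key])
        cfg = cls(**doc)
        if regions:
            cfg.regions = regions
        cfg.placements = placements
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SyntheticWorld:
    config: SimConfig
    regions: list[GenomicRegion]
    sequences: dict[str, str]
    preference: dict[str, np.ndarray]         # lambda, in vitro landscape
    preference_invivo: dict[str, np.ndarray]  # lambda with displacement applied
    planted: list[PlantedMotif]
    gene_classes: dict[str, str]

    @property
    def seed(self) -> int:
        return self.config.seed

    @property
    def motif(self) -> MotifMatrix:
        return self.config.motif

    def chip_scores(self) -> dict[str, tuple[float, float]]:
        return {m.site_id: (m.chip_oct4, m.chip_sox2) for m in self.planted}


def _validate(config: SimConfig) -> None:
    if config.depth < 0:
        raise ConfigError("depth must be >= 0")
    if not 0 < config.delta <= 1:
        raise ConfigError(f"delta must be in (0, 1], got {config.delta}")
    names = [r.name for r in config.regions]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate region names")
    by_name = {r.name: r for r in config.regions}
    for r in config.regions:
        if r.length < MIN_REGION_LENGTH:
            raise ConfigError(f"region {r.name}: length {r.length} < {MIN_REGION_LENGTH}")
    for i, r in enumerate(config.regions):
        for other in config.regions[i + 1:]:
            if (r.resolved_chrom() == other.resolved_chrom()
                    and r.start < other.start + other.length
                    and other.start < r.start + r.length):
                raise ConfigError(f"regions {r.name} and {other.name} overlap")
    width = config.motif.width
    spans: dict[str, list[tuple[int, int]]] = {}
    for p in config.placements:
        if p.region not in by_name:
            raise ConfigError(f"placement references unknown region {p.region}")
        if p.strand not in "+-":
            raise ConfigError(f"bad strand {p.strand!r}")
        if p.pos < 0 or p.pos + width > by_name[p.region].length:
            raise ConfigError(f"motif at {p.region}:{p.pos} does not fit inside the region")
        for s, e in spans.get(p.region, ()):
            if p.pos < e and s < p.pos + width:
                raise ConfigError(f"overlapping planted motifs in {p.region} at {p.pos}")
        spans.setdefault(p.region, []).append((p.pos, p.pos + width))


def _smooth_field(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth standard-normal-ish field: Gaussian-filtered white noise, unit sd."""
    half = int(3 * sigma)
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    kernel /= kernel.sum()
    noise = rng.standard_normal(n + 2 * half)
    smooth = np.convolve(noise, kernel, mode="same")[half:half + n]
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def make_world(config: SimConfig) -> SyntheticWorld:
    """Realize sequences, plant motifs, and build preference landscapes."""
    _validate(config)
    rng = np.random.default_rng(config.seed)
    consensus = config.motif.consensus()
    width = config.motif.width

    regions, sequences, preference, pref_invivo = [], {}, {}, {}
    gene_classes = {}
    for spec in config.regions:
        region = GenomicRegion(name=spec.name, chrom=spec.resolved_chrom(),
                               start=spec.start, end=spec.start + spec.length)
        regions.append(region)
        gene_classes[spec.name] = spec.gene_class

        i = np.arange(spec.length)
        gc_prob = np.clip(
            config.gc_base
            + config.gc_amplitude * np.sin(2 * np.pi * i / config.gc_period),
            0.02, 0.98,
        )
        u = rng.random(spec.length)
        v = rng.random(spec.length)
        # G/C with prob gc (split evenly), A/T otherwise
        bases = np.where(u < gc_prob,
                         np.where(v < 0.5, "G", "C"),
                         np.where(v < 0.5, "A", "T"))
        seq = list("".join(bases))

        lam = np.exp(config.preference_amplitude
                     * _smooth_field(spec.length, config.smoothness_sigma, rng))
        for _ in range(config.n_positioning_elements):
            center = rng.integers(100, spec.length - 100)
            lam *= 1.0 + 2.0 * np.exp(-0.5 * ((i - center) / 30.0) ** 2)
        lam /= lam.mean()

        sequences[spec.name] = seq  # finalized below after planting
        preference[spec.name] = lam

    planted = []
    for p in config.placements:
        word = consensus if p.strand == "+" else reverse_complement(consensus)
        seq = sequences[p.region]
        seq[p.pos:p.pos + width] = list(word)
        if p.functional:
            lo, hi = config.chip_functional_range
        else:
            lo, hi = config.chip_nonfunctional_range
        planted.append(PlantedMotif(
            region=p.region, pos=p.pos, strand=p.strand, functional=p.functional,
            gene_class=gene_classes[p.region],
            chip_oct4=float(rng.uniform(lo, hi)), chip_sox2=float(rng.uniform(lo, hi)),
        ))

    for name in sequences:
        sequences[name] = "".join(sequences[name])

    half = config.displacement_window // 2
    for name in preference:
        pref_invivo[name] = preference[name].copy()
    for m in planted:
        if not m.functional:
            continue
        center = m.pos + width // 2
        lam = pref_invivo[m.region]
        lo = max(0, center - half)
        hi = min(lam.size, center + half + 1)
        lam[lo:hi] *= config.delta

    return SyntheticWorld(config=config, regions=regions, sequences=sequences,
                          preference=preference, preference_invivo=pref_invivo,
                          planted=planted, gene_classes=gene_classes)


def _midpoint_weights(world: SyntheticWorld, kind: str) -> dict[str, np.ndarray]:
    cfg = world.config
    if kind == "invitro":
        return world.preference
    if kind == "invivo":
        return world.preference_invivo
    if kind == "naked":
        a, b, c = cfg.gc_bias
        out = {}
        for region in world.regions:
            gc = gc_profile(world.sequences[region.name])
            out[region.name] = np.exp(a * gc ** 2 + b * gc + c)
        return out
    raise ConfigError(f"unknown library kind {kind!r}; expected one of {LIBRARY_KINDS}")


def sample_library(world: SyntheticWorld, kind: str, depth: int | None = None,
                   replicate: int = 0) -> list[FragmentRecord]:
    """Draw a seeded fragment library of the given kind.

    The RNG stream is derived from (world seed, kind, replicate), so repeated
    calls with identical arguments return identical libraries and different
    replicates are independent.
    """
    cfg = world.config
    depth = cfg.depth if depth is None else depth
    weights = _midpoint_weights(world, kind)
    if depth == 0:
        return []
    rng = np.random.default_rng([cfg.seed, _KIND_CODE[kind], replicate])

    concat = np.concatenate([weights[r.name] for r in world.regions])
    p = concat / concat.sum()
    counts = rng.multinomial(depth, p)
    flat_mid = np.repeat(np.arange(concat.size), counts)

    lengths = cfg.fragment_length + rng.integers(
        -cfg.length_jitter, cfg.length_jitter + 1, size=depth)
    lengths = np.maximum(lengths, 1)

    # map flat index -> (region, genomic midpoint)
    offsets, gstarts, chroms = [], [], []
    acc = 0
    for r in world.regions:
        offsets.append(acc)
        gstarts.append(r.start)
        chroms.append(r.chrom)
        acc += r.length
    offsets = np.array(offsets + [acc])
    region_idx = np.searchsorted(offsets, flat_mid, side="right") - 1
    gmid = flat_mid - offsets[region_idx] + np.array(gstarts)[region_idx]

    # start so that the occupancy midpoint rule recovers gmid (odd) or the
    # left of the two central bp (even)
    starts = np.where(lengths % 2 == 1,
                      gmid - (lengths - 1) // 2,
                      gmid - lengths // 2 + 1)
    fragments = [
        FragmentRecord(chrom=chroms[ri], start=int(s), end=int(s + L))
        for ri, s, L in zip(region_idx, starts, lengths)
    ]
    return fragments


def write_truth(world: SyntheticWorld, outdir) -> Path:
    """Write ground-truth tables: regions, sequences, motif, chip, classes, lambda."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = outdir / "truth"
    truth.mkdir(exist_ok=True)

    write_regions(world.regions, outdir / "regions.tsv")
    write_fasta(world.sequences, outdir / "regions.fa")
    write_motif(world.motif, outdir / "motif.pfm", name="sim_joint_motif")

    with open(outdir / "chip.tsv", "w") as fh:
        fh.write("site_id\toct4\tsox2\n")
        for m in world.planted:
            fh.write(f"{m.site_id}\t{m.chip_oct4:.4f}\t{m.chip_sox2:.4f}\n")

    with open(outdir / "classes.tsv", "w") as fh:
        fh.write("region\tgene_class\n")
        for name, klass in world.gene_classes.items():
            fh.write(f"{name}\t{klass}\n")

    with open(truth / "motifs.tsv", "w") as fh:
        fh.write("site_id\tregion\tpos\tstrand\tfunctional\tgene_class"
                 "\tchip_oct4\tchip_sox2\n")
        for m in world.planted:
            fh.write(f"{m.site_id}\t{m.region}\t{m.pos}\t{m.strand}"
                     f"\t{m.functional}\t{m.gene_class}"
                     f"\t{m.chip_oct4:.4f}\t{m.chip_sox2:.4f}\n")

    for region in world.regions:
        lam = world.preference[region.name]
        lam_vivo = world.preference_invivo[region.name]
        with open(truth / f"lambda_{region.name}.tsv", "w") as fh:
            fh.write("pos\tlambda\tlambda_invivo\n")
            for pos in range(lam.size):
                fh.write(f"{pos}\t{lam[pos]:.8g}\t{lam_vivo[pos]:.8g}\n")

    params = {
        "seed": world.config.seed,
        "delta": world.config.delta,
        "displacement_window": world.config.displacement_window,
        "gc_bias": list(world.config.gc_bias),
        "depth": world.config.depth,
        "fragment_length": world.config.fragment_length,
        "length_jitter": world.config.length_jitter,
    }
    with open(truth / "params.json", "w") as fh:
        json.dump(params, fh, indent=2)
        fh.write("\n")
    return outdir


def write_libraries(world: SyntheticWorld, outdir, kinds=LIBRARY_KINDS) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind in kinds:
        path = outdir / f"{kind}.bed"
        write_fragments(sample_library(world, kind), path)
        paths[kind] = path
    return paths
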