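"""Forward simulator of founder-haplotype decay at STR markers.

Model
-----
``k`` carrier chromosomes descend independently from one founder through
``g`` meioses (a star genealogy). In each meiosis, crossovers fall on the
chromosome as a Poisson process with rate 1 per Morgan (Haldane model, no
interference). A marker at genetic distance ``d`` Morgans from the focal
variant stays on the founder-descended background through one meiosis iff
an even number of crossovers falls between it and the variant — probability
``(1 + e^(-2d))/2 = 1 - theta_Haldane(d)`` — so the per-marker retention
probability after ``g`` meioses is ``(1 - theta)^g``. The contiguous
founder segment around the variant is bounded by the nearest crossover over
all meioses on each side, making its one-sided genetic length Exponential
with mean ``1/g`` Morgans (censored at the map ends).

Markers that have lost founder descent, and the entire non-transmitted
homolog, draw alleles i.i.d. from per-marker population frequencies (no
background LD). Genotypes are emitted unphased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import GeneticMap, GenotypeRecord, write_genotypes, write_map

__all__ = [
    "AlleleFreqs",
    "SimulationConfig",
    "LineageTruth",
    "SimulatedCohort",
    "allele_freqs_for_heterozygosity",
    "default_allele_freqs",
    "family_labels",
    "simulate_cohort",
    "simulate_minimal_spans",
    "write_fixture",
]

# per-marker allele ladder and frequencies: {marker: (labels, probs)}
AlleleFreqs = Mapping[str, tuple[tuple[int, ...], tuple[float, ...]]]


def allele_freqs_for_heterozygosity(H: float, k_alleles: int) -> tuple[float, ...]:
    """Frequency vector with expected heterozygosity ``1 - sum(p^2) = H``.

    Uses one major allele and ``k_alleles - 1`` equifrequent minors; the
    major frequency solves the resulting quadratic exactly. Raises when
    ``H`` exceeds the equifrequent bound ``1 - 1/k_alleles``.
    """
    if not 0 < H < 1:
        raise ValueError(f"H must lie in (0,1), got {H}")
    if k_alleles < 2:
        raise ValueError("need at least 2 alleles")
    bound = 1.0 - 1.0 / k_alleles
    if H > bound + 1e-12:
        raise ValueError(
            f"H={H} infeasible with {k_alleles} alleles (max 1 - 1/k = {bound:.6f})"
        )
    m = k_alleles - 1
    disc = 1.0 + (m + 1) * (m - 1 - m * H)
    p_major = (1.0 + math.sqrt(max(disc, 0.0))) / (m + 1)
    q = (1.0 - p_major) / m
    return (p_major,) + (q,) * m


def default_allele_freqs(
    gmap: GeneticMap, k_alleles: int = 8, base_size: int = 120, het_default: float = 0.75
) -> dict[str, tuple[tuple[int, ...], tuple[float, ...]]]:
    """Dinucleotide-style allele ladders (2-bp spacing) for every map marker.

    Each marker's frequency vector reproduces its map heterozygosity (or
    ``het_default`` when the map carries none).
    """
    out = {}
    for j, m in enumerate(gmap.markers):
        labels = tuple(base_size + 10 * j + 2 * i for i in range(k_alleles))
        probs = allele_freqs_for_heterozygosity(m.het if m.het is not None else het_default, k_alleles)
        out[m.name] = (labels, probs)
    return out


def family_labels(k: int, n_families: int | None = None, prefix: str = "FAM") -> list[str]:
    """Assign k lineages to family labels round-robin over n_families."""
    n = k if n_families is None else n_families
    if not 1 <= n <= k:
        raise ValueError("n_families must lie in [1, lineages]")
    return [f"{prefix}{(i % n) + 1}" for i in range(k)]


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one simulated founder cohort.

    ``allele_freqs`` maps marker name to (allele ladder, frequencies);
    ``founder_haplotype`` maps marker name to the founder allele (drawn from
    the ladder when omitted). ``mutation_rate`` is the per-meiosis stepwise
    (+/-1 ladder unit) probability applied to founder-descended alleles.
    """

    map: GeneticMap
    generations: int
    lineages: int
    allele_freqs: AlleleFreqs
    founder_haplotype: Mapping[str, int] | None = None
    mutation_rate: float = 0.0
    map_function: str = "haldane"
    n_families: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.lineages < 1:
            raise ValueError("lineages must be >= 1")
        if self.map_function != "haldane":
            raise ValueError("only the haldane map function is supported")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must lie in [0,1)")
        for m in self.map.markers:
            if m.name not in self.allele_freqs:
                raise ValueError(f"no allele frequencies for marker {m.name}")
            labels, probs = self.allele_freqs[m.name]
            if len(labels) != len(probs):
                raise ValueError(f"{m.name}: ladder/frequency length mismatch")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{m.name}: frequencies must sum to 1 (got {sum(probs)})")
            if self.founder_haplotype is not None:
                fa = self.founder_haplotype.get(m.name)
                if fa is not None and fa not in labels:
                    raise ValueError(f"{m.name}: founder allele {fa} outside ladder")


@dataclass(frozen=True)
class LineageTruth:
    """Retained founder segment of one lineage (cM extents around the variant)."""

    lineage: int
    family_id: str
    individual_id: str
    left_cM: float
    right_cM: float
    founder_markers: tuple[bool, ...]  # founder-descent indicator, map order


@dataclass(frozen=True)
class SimulatedCohort:
    config: SimulationConfig
    founder_haplotype: dict[str, int]
    genotypes: tuple[GenotypeRecord, ...]
    truth: tuple[LineageTruth, ...]


def _marker_geometry(gmap: GeneticMap) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Distances (Morgans) of markers from the variant, split by side.

    Returns (left_idx, d_left, right_idx, d_right); left indices run from
    the variant outward (nearest first), distances ascending.
    """
    pos = np.array([m.pos_cM for m in gmap.markers])
    v = gmap.variant_cM
    left = np.nonzero(pos < v)[0][::-1]
    right = np.nonzero(pos >= v)[0]
    return left, (v - pos[left]) / 100.0, right, (pos[right] - v) / 100.0


def _draw_idx(rng: np.random.Generator, probs: np.ndarray, shape) -> np.ndarray:
    """Categorical draws via inverse CDF (vectorised)."""
    return np.searchsorted(np.cumsum(probs), rng.random(shape), side="right").clip(0, len(probs) - 1)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Simulate ``k`` unphased carrier genotypes descending from one founder.

    RNG streams are split per (seed, lineage index) so varying ``lineages``
    never perturbs the other lineages' draws; identical config and seed give
    bit-identical output.
    """
    gmap = config.map
    g, k = config.generations, config.lineages
    nmark = len(gmap.markers)
    left_idx, dL, right_idx, dR = _marker_geometry(gmap)
    DL = float(dL[-1]) if dL.size else 0.0
    DR = float(dR[-1]) if dR.size else 0.0

    ladders = {m.name: (np.asarray(config.allele_freqs[m.name][0]),
                        np.asarray(config.allele_freqs[m.name][1], dtype=float))
               for m in gmap.markers}

    founder_rng = np.random.default_rng([config.seed, 0x0F0F])
    founder: dict[str, int] = {}
    for m in gmap.markers:
        labels, probs = ladders[m.name]
        given = None if config.founder_haplotype is None else config.founder_haplotype.get(m.name)
        founder[m.name] = int(given if given is not None else labels[_draw_idx(founder_rng, probs, ())])

    families = family_labels(k, config.n_families)
    genotypes: list[GenotypeRecord] = []
    truth: list[LineageTruth] = []

    for j in range(k):
        rng = np.random.default_rng([config.seed, 1 + j])
        retained = np.ones(nmark, dtype=bool)
        ext = {"L": DL, "R": DR}
        for side, idx, d, D in (("L", left_idx, dL, DL), ("R", right_idx, dR, DR)):
            if idx.size == 0 or g == 0:
                continue
            counts = rng.poisson(D, size=g)
            total = int(counts.sum())
            points = rng.uniform(0.0, D, size=total)
            meiosis = np.repeat(np.arange(g), counts)
            # parity of crossover count between variant and marker, per meiosis
            for i, dist in zip(idx, d):
                below = points < dist
                per_meiosis = np.bincount(meiosis[below], minlength=g)
                retained[i] = bool(((per_meiosis % 2) == 0).all())
            ext[side] = float(points.min()) if total else D
        if g == 0:
            ext = {"L": DL, "R": DR}

        pairs = []
        for i, m in enumerate(gmap.markers):
            labels, probs = ladders[m.name]
            b = int(labels[_draw_idx(rng, probs, ())])
            if retained[i]:
                a_idx = int(np.nonzero(labels == founder[m.name])[0][0])
                if config.mutation_rate > 0.0 and g > 0:
                    steps = rng.binomial(g, config.mutation_rate)
                    if steps:
                        a_idx += int(rng.choice([-1, 1], size=steps).sum())
                        a_idx = int(np.clip(a_idx, 0, len(labels) - 1))
                a = int(labels[a_idx])
            else:
                a = int(labels[_draw_idx(rng, probs, ())])
            pairs.append((min(a, b), max(a, b)))

        iid = f"L{j + 1}"
        genotypes.append(GenotypeRecord(iid, families[j], True, tuple(pairs)))
        truth.append(LineageTruth(j, families[j], iid, 100.0 * ext["L"], 100.0 * ext["R"],
                                  tuple(bool(x) for x in retained)))

    return SimulatedCohort(config, founder, tuple(genotypes), tuple(truth))


def simulate_minimal_spans(
    gmap: GeneticMap,
    generations: int,
    lineages: int,
    reps: int,
    rng: np.random.Generator,
    allele_freqs: AlleleFreqs | None = None,
) -> np.ndarray:
    """Minimal shared cM spans of ``reps`` simulated cohorts (vectorised).

    Implements the same generative model as :func:`simulate_cohort`
    (crossover-parity founder retention plus population-allele chance
    sharing) and applies the same delineation rule (allele-set intersection,
    consecutive shared run around the variant), without materialising
    genotype records. Used by the Monte-Carlo founder-age estimator.
    """
    if allele_freqs is None:
        allele_freqs = default_allele_freqs(gmap)
    g, k = generations, lineages
    left_idx, dL, right_idx, dR = _marker_geometry(gmap)
    pos = np.array([m.pos_cM for m in gmap.markers])

    def side_retained(d: np.ndarray) -> np.ndarray:
        """(reps, lineages, nside) founder-retention indicators."""
        n = d.size
        if n == 0:
            return np.ones((reps, k, 0), dtype=bool)
        if g == 0:
            return np.ones((reps, k, n), dtype=bool)
        inc = np.diff(d, prepend=0.0)
        draws = rng.poisson(inc, size=(reps, k, g, n))
        counts = np.cumsum(draws, axis=3)
        return ((counts % 2) == 0).all(axis=2)

    retL, retR = side_retained(dL), side_retained(dR)

    def shared_flags(idx: np.ndarray, ret: np.ndarray) -> np.ndarray:
        """(reps, nside) all-carrier allele-sharing indicator per marker."""
        n = idx.size
        out = np.empty((reps, n), dtype=bool)
        for s, i in enumerate(idx):
            labels, probs = allele_freqs[gmap.markers[i].name]
            probs = np.asarray(probs, dtype=float)
            K = len(labels)
            founder = _draw_idx(rng, probs, (reps, 1))
            popA = _draw_idx(rng, probs, (reps, k))
            popB = _draw_idx(rng, probs, (reps, k))
            a = np.where(ret[:, :, s], founder, popA)
            masks = (np.uint64(1) << a.astype(np.uint64)) | (np.uint64(1) << popB.astype(np.uint64))
            out[:, s] = np.bitwise_and.reduce(masks, axis=1) != 0
        return out

    shL, shR = shared_flags(left_idx, retL), shared_flags(right_idx, retR)

    def run_length(sh: np.ndarray) -> np.ndarray:
        """Consecutive shared markers from the variant outward, per rep."""
        if sh.shape[1] == 0:
            return np.zeros(sh.shape[0], dtype=int)
        return np.where(sh.all(axis=1), sh.shape[1], np.argmin(sh, axis=1))

    rlL, rlR = run_length(shL), run_length(shR)
    spans = np.zeros(reps)
    both = (rlL > 0) & (rlR > 0)
    if both.any():
        posL = pos[left_idx]   # nearest-first
        posR = pos[right_idx]
        spans[both] = posR[rlR[both] - 1] - posL[rlL[both] - 1]
    return spans


def write_fixture(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write MAP, PED and truth-TSV files; all re-readable by founderhap.io."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "map": outdir / "markers.map",
        "genotypes": outdir / "genotypes.ped",
        "truth": outdir / "truth.tsv",
    }
    write_map(cohort.config.map, paths["map"])
    write_genotypes(cohort.genotypes, paths["genotypes"])
    names = cohort.config.map.marker_names
    with open(paths["truth"], "w") as fh:
        fh.write("lineage\tfamily_id\tindividual_id\tleft_cM\tright_cM\t"
                 + "\t".join(names) + "\n")
        for t in cohort.truth:
            fh.write(
                f"{t.lineage}\t{t.family_id}\t{t.individual_id}\t"
                f"{t.left_cM:.6f}\t{t.right_cM:.6f}\t"
                + "\t".join("1" if b else "0" for b in t.founder_markers) + "\n"
            )
    return paths
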