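"""Mapping-population simulator.

Generates multi-population single-chromosome genotype data with a known true
marker order, so the whole consensus pipeline can be exercised and scored
against ground truth.  The default study design follows the simulated
examples the method was developed on: 8-16 F2 populations, 50 codominant
markers, inter-marker intervals drawn 75% from U[1, 4] cM and 25% from
U[4, 20] cM, configurable per-cell missing rates (0-40%), and a genotype
misclassification model in which, at affected loci, 5% of heterozygotes are
scored as each homozygote and 10% of each homozygote class is scored as
heterozygous.

Meiosis is simulated with no crossover interference: the recombination
fraction of an interval of d cM is Haldane's r = (1 - exp(-2d/100)) / 2.
RIL genotypes are drawn directly from the fixed-line two-locus distribution
with the standard inflation r_RIL = 2r/(1+2r) rather than by iterating
selfing generations (marginally equivalent, far cheaper).

Marker naming follows the shared/unique convention used throughout:
the marker at true position k is named ``mar{k}`` when shared and
``mar{k}_{i}`` when unique to dataset i, so shared markers are recognised
across datasets by identical names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, ConsensusProblem, CrossType, Dataset
from .exceptions import ValidationError
from .twopoint import build_rf_matrix

__all__ = [
    "TrueMap",
    "NoiseSpec",
    "GroundTruth",
    "haldane",
    "haldane_inverse_cM",
    "draw_true_map",
    "simulate_population",
    "apply_noise",
    "make_problem",
    "example_noise_strata",
]


def haldane(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Haldane mapping function: cM distance -> recombination fraction."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_cM) / 100.0)) / 2.0


def haldane_inverse_cM(r: float | np.ndarray) -> float | np.ndarray:
    """Inverse Haldane: recombination fraction -> cM distance."""
    return -50.0 * np.log(1.0 - 2.0 * np.asarray(r))


@dataclass
class TrueMap:
    """A true marker order with inter-marker interval lengths in cM.

    ``shared_mask`` (markers x datasets), when set, records which datasets
    carry each marker; it is filled by :func:`make_problem`.
    """

    names: list[str]
    interval_lengths_cM: list[float]
    shared_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.interval_lengths_cM = [float(x) for x in self.interval_lengths_cM]
        if len(self.interval_lengths_cM) != max(len(self.names) - 1, 0):
            raise ValidationError("need exactly n_markers - 1 intervals")
        if any(x < 0 for x in self.interval_lengths_cM):
            raise ValidationError("interval lengths must be non-negative")

    @property
    def n_markers(self) -> int:
        return len(self.names)

    @property
    def length_cM(self) -> float:
        return float(sum(self.interval_lengths_cM))


@dataclass
class NoiseSpec:
    """Missing-data and misclassification parameters for one noise stratum.

    Misclassification is applied only to the stratum of
    ``error_locus_fraction`` of loci crossed with ``error_individual_fraction``
    of individuals.  Within the stratum, a heterozygote is scored as the A
    homozygote with probability ``h_to_a`` and as the B homozygote with
    ``h_to_b``; each homozygote class is scored as heterozygous with
    probability ``a_to_h`` / ``b_to_h``.  The defaults reproduce the
    canonical model (5%/5% and 10%/10%), i.e. a 10% error rate at affected
    loci regardless of genotype class.
    """

    missing_rate: float = 0.0
    error_locus_fraction: float = 0.0
    error_individual_fraction: float = 0.0
    h_to_a: float = 0.05
    h_to_b: float = 0.05
    a_to_h: float = 0.10
    b_to_h: float = 0.10

    def __post_init__(self) -> None:
        for name in (
            "missing_rate",
            "error_locus_fraction",
            "error_individual_fraction",
            "h_to_a",
            "h_to_b",
            "a_to_h",
            "b_to_h",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.h_to_a + self.h_to_b > 1.0:
            raise ValidationError("h_to_a + h_to_b must not exceed 1")


def example_noise_strata(kind: str) -> list[NoiseSpec]:
    """Noise configurations of the canonical simulated designs.

    ``"high_missing"``: 40% missing; in 10% of individuals, misclassification
    at 20% of loci (first stratum) and 80% of loci (second stratum).
    ``"low_missing"``: same but 20% missing.
    ``"errors_wide"``: 20% missing, 10% errors at 75% of loci in all
    individuals.
    ``"clean"``: no noise.
    """
    if kind == "clean":
        return []
    if kind == "high_missing":
        return [
            NoiseSpec(missing_rate=0.4, error_locus_fraction=0.2,
                      error_individual_fraction=0.1),
            NoiseSpec(missing_rate=0.0, error_locus_fraction=0.8,
                      error_individual_fraction=0.1),
        ]
    if kind == "low_missing":
        return [
            NoiseSpec(missing_rate=0.2, error_locus_fraction=0.2,
                      error_individual_fraction=0.1),
            NoiseSpec(missing_rate=0.0, error_locus_fraction=0.8,
                      error_individual_fraction=0.1),
        ]
    if kind == "errors_wide":
        return [
            NoiseSpec(missing_rate=0.2, error_locus_fraction=0.75,
                      error_individual_fraction=1.0),
        ]
    raise ValidationError(f"unknown noise kind {kind!r}")


def draw_true_map(
    n_markers: int,
    frac_short: float = 0.75,
    short_range: tuple[float, float] = (1.0, 4.0),
    long_range: tuple[float, float] = (4.0, 20.0),
    rng: np.random.Generator | int | None = None,
) -> TrueMap:
    """Draw a true map whose intervals come from a two-component uniform
    mixture (default: 75% from U[1,4] cM, 25% from U[4,20] cM)."""
    if n_markers < 2:
        raise ValidationError("need at least 2 markers")
    if not 0.0 <= frac_short <= 1.0:
        raise ValidationError("frac_short outside [0, 1]")
    for lo, hi in (short_range, long_range):
        if not (0 < lo <= hi):
            raise ValidationError("invalid interval range")
    rng = np.random.default_rng(rng)
    n_int = n_markers - 1
    short = rng.random(n_int) < frac_short
    lengths = np.where(
        short,
        rng.uniform(short_range[0], short_range[1], n_int),
        rng.uniform(long_range[0], long_range[1], n_int),
    )
    names = [f"mar{k}" for k in range(1, n_markers + 1)]
    return TrueMap(names, lengths.tolist())


def _simulate_gametes(
    intervals_cM: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate n gamete haplotypes (0/1 alleles) marker by marker with
    per-interval crossover probability haldane(d), no interference."""
    m = len(intervals_cM) + 1
    out = np.empty((m, n), dtype=np.int8)
    out[0] = rng.integers(0, 2, n)
    r = haldane(intervals_cM)
    flips = rng.random((m - 1, n)) < r[:, None]
    out[1:] = flips
    return np.bitwise_xor.accumulate(out, axis=0)


def simulate_population(
    true_map: TrueMap,
    cross_type: CrossType | str,
    n_individuals: int,
    rng: np.random.Generator | int | None = None,
    dataset_id: int = 0,
) -> Dataset:
    """Simulate one mapping population scored at every true-map marker.

    F2 individuals are the sum of two independent gametes; BC individuals a
    single gamete against an all-A tester; RIL genotypes are drawn as fixed
    lines with effective per-interval fraction 2r/(1+2r).
    """
    cross_type = CrossType(cross_type)
    if n_individuals < 1:
        raise ValidationError("need at least one individual")
    rng = np.random.default_rng(rng)
    intervals = np.asarray(true_map.interval_lengths_cM)

    if cross_type is CrossType.F2:
        g1 = _simulate_gametes(intervals, n_individuals, rng)
        g2 = _simulate_gametes(intervals, n_individuals, rng)
        geno = (g1 + g2).astype(np.int8)  # 0=A, 1=H, 2=B
    elif cross_type is CrossType.BC:
        geno = _simulate_gametes(intervals, n_individuals, rng)  # 0=A, 1=H
    else:  # RIL: chain with inflated recombination, fixed lines
        r = haldane(intervals)
        r_ril = 2.0 * r / (1.0 + 2.0 * r)
        m = len(intervals) + 1
        geno = np.empty((m, n_individuals), dtype=np.int8)
        geno[0] = rng.integers(0, 2, n_individuals)
        flips = rng.random((m - 1, n_individuals)) < r_ril[:, None]
        geno[1:] = flips
        geno = np.bitwise_xor.accumulate(geno, axis=0) * 2  # 0=A, 2=B
    return Dataset(dataset_id, cross_type, list(true_map.names), geno)


def apply_noise(
    dataset: Dataset,
    spec: NoiseSpec | list[NoiseSpec],
    rng: np.random.Generator | int | None = None,
) -> tuple[Dataset, dict]:
    """Apply missing data and stratified misclassification; returns a
    modified copy and a change log with counts per stratum.

    For BC data the heterozygote is misclassified to the A homozygote with
    probability ``h_to_a + h_to_b`` (the only homozygote present) and A to H
    with ``a_to_h``; for RIL the homozygotes flip into each other with
    ``a_to_h`` / ``b_to_h``.
    """
    specs = [spec] if isinstance(spec, NoiseSpec) else list(spec)
    rng = np.random.default_rng(rng)
    G = dataset.genotypes.copy()
    m, n = G.shape
    log: dict = {"strata": [], "n_missing": 0, "n_misclassified": 0}

    for s in specs:
        n_err = 0
        if s.error_locus_fraction > 0 and s.error_individual_fraction > 0:
            n_loci = int(round(s.error_locus_fraction * m))
            n_ind = int(round(s.error_individual_fraction * n))
            loci = rng.choice(m, size=n_loci, replace=False)
            inds = rng.choice(n, size=n_ind, replace=False)
            sub = G[np.ix_(loci, inds)]
            u = rng.random(sub.shape)
            new = sub.copy()
            if dataset.cross_type is CrossType.F2:
                het = sub == 1
                new[het & (u < s.h_to_a)] = 0
                new[het & (u >= s.h_to_a) & (u < s.h_to_a + s.h_to_b)] = 2
                new[(sub == 0) & (u < s.a_to_h)] = 1
                new[(sub == 2) & (u < s.b_to_h)] = 1
            elif dataset.cross_type is CrossType.BC:
                new[(sub == 1) & (u < s.h_to_a + s.h_to_b)] = 0
                new[(sub == 0) & (u < s.a_to_h)] = 1
            else:  # RIL
                new[(sub == 0) & (u < s.a_to_h)] = 2
                new[(sub == 2) & (u < s.b_to_h)] = 0
            n_err = int(np.sum((new != sub) & (sub != MISSING)))
            G[np.ix_(loci, inds)] = new
        n_miss = 0
        if s.missing_rate > 0:
            miss = (rng.random(G.shape) < s.missing_rate) & (G != MISSING)
            n_miss = int(miss.sum())
            G[miss] = MISSING
        log["strata"].append({"n_misclassified": n_err, "n_missing": n_miss})
        log["n_missing"] += n_miss
        log["n_misclassified"] += n_err

    out = Dataset(dataset.id, dataset.cross_type, list(dataset.markers), G)
    return out, log


@dataclass
class GroundTruth:
    """True structure of a simulated consensus problem, for scoring."""

    true_map: TrueMap
    #: full (possibly suffixed) marker names, in true order
    names: list[str]
    #: markers x datasets presence indicator
    shared_mask: np.ndarray
    #: true order of the shared markers only
    true_shared_order: tuple[str, ...] = field(init=False)
    #: true order per dataset (its markers only)
    dataset_orders: list[tuple[str, ...]] = field(init=False)

    def __post_init__(self) -> None:
        n_ds = self.shared_mask.shape[1]
        shared = self.shared_mask.sum(axis=1) >= 2
        self.true_shared_order = tuple(
            nm for nm, s in zip(self.names, shared) if s
        )
        self.dataset_orders = [
            tuple(nm for nm, p in zip(self.names, self.shared_mask[:, i]) if p)
            for i in range(n_ds)
        ]


def make_problem(
    true_map: TrueMap,
    n_datasets: int,
    sample_sizes: int | list[int],
    noise: NoiseSpec | list[NoiseSpec] | list[list[NoiseSpec]] | None = None,
    cross_type: CrossType | str = CrossType.F2,
    shared_fraction: float | None = None,
    shared_mask: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    min_informative: int = 10,
) -> tuple[ConsensusProblem, GroundTruth]:
    """Simulate a full consensus problem with ground truth.

    ``shared_mask`` (markers x datasets booleans) fixes marker presence
    explicitly; otherwise each marker is shared by all datasets with
    probability ``shared_fraction`` (default 1.0) and assigned to a single
    random dataset otherwise.  Shared markers keep the plain name
    ``mar{k}``; unique markers are renamed ``mar{k}_{i}`` for dataset i.
    ``noise`` may be one spec/strata list for all datasets or one per
    dataset.  Genotypes are simulated, noise applied, and RF matrices built,
    yielding a ready :class:`~consmap.core.ConsensusProblem`.
    """
    if n_datasets < 2:
        raise ValidationError("need at least 2 datasets")
    rng = np.random.default_rng(rng)
    m = true_map.n_markers

    if shared_mask is None:
        frac = 1.0 if shared_fraction is None else float(shared_fraction)
        if not 0.0 <= frac <= 1.0:
            raise ValidationError("shared_fraction outside [0, 1]")
        shared_mask = np.zeros((m, n_datasets), dtype=bool)
        is_shared = rng.random(m) < frac
        shared_mask[is_shared, :] = True
        for k in np.where(~is_shared)[0]:
            shared_mask[k, rng.integers(0, n_datasets)] = True
    else:
        shared_mask = np.asarray(shared_mask, dtype=bool)
        if shared_mask.shape != (m, n_datasets):
            raise ValidationError("shared_mask shape must be (markers, datasets)")
        counts = shared_mask.sum(axis=1)
        if np.any(counts == 0):
            raise ValidationError("every marker must be present in >= 1 dataset")

    counts = shared_mask.sum(axis=1)
    names = [
        f"mar{k + 1}" if counts[k] >= 2 else f"mar{k + 1}_{int(np.argmax(shared_mask[k])) + 1}"
        for k in range(m)
    ]

    if isinstance(sample_sizes, int):
        sample_sizes = [sample_sizes] * n_datasets
    if len(sample_sizes) != n_datasets:
        raise ValidationError("one sample size per dataset required")

    # normalise noise to one strata-list per dataset
    if noise is None:
        per_ds_noise: list[list[NoiseSpec]] = [[] for _ in range(n_datasets)]
    elif isinstance(noise, NoiseSpec):
        per_ds_noise = [[noise] for _ in range(n_datasets)]
    elif all(isinstance(x, NoiseSpec) for x in noise):
        per_ds_noise = [list(noise) for _ in range(n_datasets)]  # type: ignore[arg-type]
    else:
        per_ds_noise = [list(x) for x in noise]  # type: ignore[union-attr]
        if len(per_ds_noise) != n_datasets:
            raise ValidationError("one noise spec per dataset required")

    datasets, rf_matrices = [], []
    for i in range(n_datasets):
        full = simulate_population(
            true_map, cross_type, sample_sizes[i], rng, dataset_id=i
        )
        keep = np.where(shared_mask[:, i])[0]
        ds = Dataset(
            i,
            full.cross_type,
            [names[k] for k in keep],
            full.genotypes[keep],
        )
        if per_ds_noise[i]:
            ds, _ = apply_noise(ds, per_ds_noise[i], rng)
        datasets.append(ds)
        rf_matrices.append(build_rf_matrix(ds, min_informative=min_informative))

    problem = ConsensusProblem(datasets, rf_matrices)
    truth = GroundTruth(
        TrueMap(true_map.names, true_map.interval_lengths_cM, shared_mask),
        names,
        shared_mask,
    )
    return problem, truth
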