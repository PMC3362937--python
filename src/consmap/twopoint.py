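"""Two-point recombination-fraction estimation.

Builds the per-dataset matrix of pairwise recombination fractions that all
ordering criteria consume.  Estimators by cross type:

* BC: direct count of recombinant individuals among non-missing pairs.
* F2 (codominant): single-parameter maximum likelihood on the 3x3 joint
  genotype table.  The double-heterozygote class mixes the two phases, so
  its probability is ((1-r)^2 + r^2)/2; the likelihood is maximised
  numerically on [0, 0.5].
* RIL (selfed to fixation): observed strain discordance R relates to the
  meiotic recombination fraction via R = 2r/(1+2r), inverted as
  r = R / (2(1-R)).

Pairs with fewer informative individuals than ``min_informative`` are
flagged unreliable and their rf is imputed as the minimum two-hop sum
rf(a,x) + rf(x,b) over reliably estimated hops, so downstream criteria see
a complete matrix.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import MISSING, CrossType, Dataset, RFMatrix
from .exceptions import ValidationError

__all__ = ["rf_bc", "rf_f2_codominant", "rf_ril", "build_rf_matrix"]

#: grid used for the F2 likelihood scan (step 5e-4 after refinement)
_R_GRID = np.linspace(1e-6, 0.5, 501)


def _pair_valid(row_a: np.ndarray, row_b: np.ndarray) -> np.ndarray:
    return (row_a != MISSING) & (row_b != MISSING)


def rf_bc(row_a: np.ndarray, row_b: np.ndarray) -> tuple[float, int]:
    """Backcross estimate: fraction of recombinant individuals.

    Returns ``(rf, n_informative)``; ``rf`` is NaN when no individual is
    informative for the pair.
    """
    valid = _pair_valid(row_a, row_b)
    n = int(valid.sum())
    if n == 0:
        return float("nan"), 0
    rec = int(np.sum(row_a[valid] != row_b[valid]))
    return min(rec / n, 0.5), n


def _f2_class_counts(row_a: np.ndarray, row_b: np.ndarray) -> tuple[int, int, int, int]:
    """Collapse the 3x3 F2 table to its four probability classes.

    Classes: same homozygote (prob (1-r)^2/4 each cell), opposite homozygote
    (r^2/4), homozygote x heterozygote (r(1-r)/2), double heterozygote
    ((1-r)^2/2 + r^2/2).
    """
    valid = _pair_valid(row_a, row_b)
    a, b = row_a[valid], row_b[valid]
    het_a, het_b = a == 1, b == 1
    both_hom = ~het_a & ~het_b
    n_same = int(np.sum(both_hom & (a == b)))
    n_opp = int(np.sum(both_hom & (a != b)))
    n_mix = int(np.sum(het_a ^ het_b))
    n_hh = int(np.sum(het_a & het_b))
    return n_same, n_opp, n_mix, n_hh


def _f2_loglik(r: np.ndarray, counts: tuple[int, int, int, int]) -> np.ndarray:
    n_same, n_opp, n_mix, n_hh = counts
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            n_same * np.log((1 - r) ** 2 / 4)
            + n_opp * np.log(r**2 / 4)
            + n_mix * np.log(r * (1 - r) / 2)
            + n_hh * np.log(((1 - r) ** 2 + r**2) / 2)
        )
    return ll


def rf_f2_codominant(row_a: np.ndarray, row_b: np.ndarray) -> tuple[float, int]:
    """F2 codominant ML estimate on [0, 0.5] via grid scan plus refinement."""
    counts = _f2_class_counts(row_a, row_b)
    n = sum(counts)
    if n == 0:
        return float("nan"), 0
    n_same, n_opp, n_mix, n_hh = counts
    if n_opp == 0 and n_mix == 0:
        return 0.0, n  # perfectly cosegregating
    ll = _f2_loglik(_R_GRID, counts)
    k = int(np.argmax(ll))
    lo = _R_GRID[max(k - 1, 0)]
    hi = _R_GRID[min(k + 1, len(_R_GRID) - 1)]
    fine = np.linspace(lo, hi, 81)
    r_hat = float(fine[np.argmax(_f2_loglik(fine, counts))])
    return min(max(r_hat, 0.0), 0.5), n


def rf_ril(row_a: np.ndarray, row_b: np.ndarray) -> tuple[float, int]:
    """RIL estimate: discordance R mapped to meiotic r = R/(2(1-R))."""
    valid = _pair_valid(row_a, row_b)
    n = int(valid.sum())
    if n == 0:
        return float("nan"), 0
    R = float(np.sum(row_a[valid] != row_b[valid])) / n
    if R >= 2.0 / 3.0:
        warnings.warn(
            f"RIL discordance {R:.3f} >= 2/3 implies r > 0.5; clamped to 0.5",
            stacklevel=2,
        )
        return 0.5, n
    return min(R / (2.0 * (1.0 - R)), 0.5), n


_ESTIMATORS = {
    CrossType.BC: rf_bc,
    CrossType.F2: rf_f2_codominant,
    CrossType.RIL: rf_ril,
}


def _f2_matrix_vectorized(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs F2 ML estimates via class-count matrix products."""
    m = G.shape[0]
    valid = (G != MISSING).astype(np.float64)
    het = ((G == 1) & (G != MISSING)).astype(np.float64)
    a_hom = (G == 0).astype(np.float64)
    b_hom = (G == 2).astype(np.float64)
    n_same = a_hom @ a_hom.T + b_hom @ b_hom.T
    n_opp = a_hom @ b_hom.T + b_hom @ a_hom.T
    hom = a_hom + b_hom
    n_mix = het @ hom.T + hom @ het.T
    n_hh = het @ het.T
    n_tot = (n_same + n_opp + n_mix + n_hh).astype(int)

    iu = np.triu_indices(m, k=1)
    C = np.stack([x[iu] for x in (n_same, n_opp, n_mix, n_hh)], axis=1)
    r = _R_GRID
    with np.errstate(divide="ignore"):
        logp = np.stack(
            [
                np.log((1 - r) ** 2 / 4),
                np.log(r**2 / 4),
                np.log(r * (1 - r) / 2),
                np.log(((1 - r) ** 2 + r**2) / 2),
            ]
        )
    ll = C @ logp  # (n_pairs, n_grid)
    k = np.argmax(ll, axis=1)
    # one parabolic refinement step on the log-likelihood grid
    k_in = np.clip(k, 1, len(r) - 2)
    y0 = ll[np.arange(len(k)), k_in - 1]
    y1 = ll[np.arange(len(k)), k_in]
    y2 = ll[np.arange(len(k)), k_in + 1]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    h = r[1] - r[0]
    r_hat = np.where(k == k_in, r[k_in] + shift * h, r[k])
    # perfectly cosegregating pairs sit at exactly 0
    r_hat = np.where((C[:, 1] == 0) & (C[:, 2] == 0), 0.0, r_hat)
    r_hat = np.clip(r_hat, 0.0, 0.5)

    rf = np.zeros((m, m))
    rf[iu] = r_hat
    rf = rf + rf.T
    return rf, n_tot


def _discordance_matrix(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs mismatch fraction among non-missing pairs (BC/RIL)."""
    valid = (G != MISSING).astype(np.float64)
    n = valid @ valid.T
    # mismatches among valid pairs: count equal-and-valid, subtract
    eq = np.zeros_like(n)
    for code in np.unique(G[G != MISSING]):
        ind = (G == code).astype(np.float64)
        eq += ind @ ind.T
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (n - eq) / n
    return R, n.astype(int)


def build_rf_matrix(
    dataset: Dataset,
    min_informative: int = 10,
) -> RFMatrix:
    """Estimate the complete pairwise RF matrix for one dataset.

    Markers with no informative pair at all are excluded with a warning.
    Pairs below ``min_informative`` are imputed by the minimum two-hop sum
    over reliable entries and flagged in ``unreliable``.
    """
    if dataset.n_markers < 2:
        raise ValidationError("need at least 2 markers")
    G = dataset.genotypes
    m = dataset.n_markers

    if dataset.cross_type is CrossType.F2:
        rf, n_inf = _f2_matrix_vectorized(G)
    else:
        R, n_inf = _discordance_matrix(G)
        with np.errstate(invalid="ignore"):
            if dataset.cross_type is CrossType.RIL:
                rf = np.where(R >= 2.0 / 3.0, 0.5, R / (2.0 * np.maximum(1.0 - R, 1e-12)))
            else:
                rf = R
        rf = np.clip(rf, 0.0, 0.5)
    np.fill_diagonal(rf, 0.0)
    np.fill_diagonal(n_inf, 0)

    # drop markers that are entirely missing (no informative pair anywhere)
    off_diag_n = n_inf + np.eye(m, dtype=int) * 0
    informative_any = (off_diag_n.sum(axis=1) - np.diag(off_diag_n)) > 0
    if not informative_any.all():
        dropped = [dataset.markers[i] for i in np.where(~informative_any)[0]]
        warnings.warn(
            f"dataset {dataset.id}: excluding all-missing markers {dropped}",
            stacklevel=2,
        )
        keep = np.where(informative_any)[0]
        markers = [dataset.markers[i] for i in keep]
        rf = rf[np.ix_(keep, keep)]
        n_inf = n_inf[np.ix_(keep, keep)]
        m = len(markers)
    else:
        markers = list(dataset.markers)

    unreliable = (n_inf < min_informative) & ~np.eye(m, dtype=bool)
    if unreliable.any():
        rf = _impute_unreliable(rf, unreliable)
    rf = np.nan_to_num(rf, nan=0.5)
    rf = np.clip((rf + rf.T) / 2.0, 0.0, 0.5)
    np.fill_diagonal(rf, 0.0)
    return RFMatrix(markers, rf, n_inf, unreliable)


def _impute_unreliable(rf: np.ndarray, unreliable: np.ndarray) -> np.ndarray:
    """Replace unreliable entries with min two-hop sums over reliable hops."""
    work = rf.copy()
    work[unreliable] = np.inf
    work[np.isnan(work)] = np.inf
    # one min-plus pass suffices for the criterion's purposes; repeat twice
    # to propagate through chains of unreliable pairs
    for _ in range(2):
        two_hop = np.min(work[:, :, None] + work[None, :, :], axis=1)
        work = np.minimum(work, two_hop)
    out = rf.copy()
    fill = np.minimum(work, 0.5)
    fill[np.isinf(fill)] = 0.5
    out[unreliable] = fill[unreliable]
    return out
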