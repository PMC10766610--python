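"""Gene-level RSA statistic: min hypergeometric upper tail over ranked wells.

Every QC-passing library well is ranked by rescue activity (robust z of
rel_change, rank 1 = strongest). For a gene whose N wells sit at ranks
r_1 < ... < r_N among M ranked wells, the RSA score is

    P = min_j  P( X >= j ),   X ~ Hypergeometric(M, N, r_j)

i.e. the most surprising prefix of the gene's wells, reported as log10 P.
Probabilities are computed in log space with log-gamma binomials (M ~ 2800
wells overflows direct factorials). Ties are handled conservatively: tied
wells all receive the largest rank of the tied block, so a constant activity
vector scores P = 1 for every gene. No multiplicity correction is applied —
calibration comes from the randomized-activity permutation null
(:mod:`tpdscreen.hit_calling`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata

from .exceptions import ValidationError
from .qc_normalize import NormalizedWell
from .screen_io import GeneScore, ScreenLibrary

LOG10E = np.log10(np.e)


@dataclass
class RankedActivity:
    """All QC-passing library wells in activity rank order."""

    well_keys: list[tuple[str, str, str]]  # sorted by rank, ties by well key
    ranks: np.ndarray  # per well (same order as well_keys), max-tie ranks
    gene_ids: list[str]  # per well
    M: int

    def gene_ranks(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for g, r in zip(self.gene_ids, self.ranks):
            out.setdefault(g, []).append(int(r))
        return {g: np.sort(np.array(r)) for g, r in out.items()}


def _log_binom(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def log10_hypergeom_sf(j: int, M: int, N: int, r: int) -> float:
    """log10 P(X >= j) for X ~ Hypergeometric(M population, N special,
    r draws), exact in log space."""
    _check_args(j, M, N, r)
    ks = np.arange(j, min(N, r) + 1)
    ks = ks[(r - ks) <= (M - N)]
    if ks.size == 0:
        return float("-inf")
    log_terms = _log_binom(N, ks) + _log_binom(M - N, r - ks) - _log_binom(M, r)
    return float(min(logsumexp(log_terms) * LOG10E, 0.0))


def hypergeom_sf(j: int, M: int, N: int, r: int) -> float:
    """P(X >= j); see :func:`log10_hypergeom_sf`."""
    return float(10.0 ** log10_hypergeom_sf(j, M, N, r))


def _check_args(j: int, M: int, N: int, r: int) -> None:
    if not (1 <= j <= N <= M):
        raise ValidationError(f"need 1 <= j <= N <= M, got j={j}, N={N}, M={M}")
    if not (j <= r <= M):
        raise ValidationError(f"need j <= r <= M, got j={j}, r={r}, M={M}")


def rsa_log10p(ranks, M: int) -> float:
    """log10 of the min hypergeometric tail over a gene's rank prefix.

    ``ranks`` are the gene's well ranks (1-based, non-decreasing; tied wells
    of one gene share their block's largest rank).
    """
    r = np.asarray(sorted(int(x) for x in ranks))
    if r.size == 0:
        raise ValidationError("a gene needs at least one ranked well")
    if np.any(np.diff(r) < 0):
        raise ValidationError("ranks must be non-decreasing")
    N = r.size
    best = 0.0
    for j, rj in enumerate(r, start=1):
        best = min(best, log10_hypergeom_sf(j, M, N, int(rj)))
    return best


def _batched_log10_sf(J: np.ndarray, R: np.ndarray, N: np.ndarray,
                      M: int) -> np.ndarray:
    """Vectorized log10 P(X >= j) for many (j, r, N) triples sharing M.

    N is small (pooled wells per gene, <= ~6), so the tail sum is expanded
    over a fixed offset axis and masked.
    """
    J = np.asarray(J, float)
    R = np.asarray(R, float)
    N = np.asarray(N, float)
    max_terms = int(N.max() - J.min()) + 1
    offs = np.arange(max_terms)[:, None]
    K = J[None, :] + offs
    valid = (K <= np.minimum(N, R)[None, :]) & ((R[None, :] - K) <= (M - N[None, :]))
    Kc = np.where(valid, K, 1.0)
    log_terms = (
        _log_binom(N[None, :], Kc)
        + _log_binom(M - N[None, :], R[None, :] - Kc)
        - _log_binom(M, R[None, :])
    )
    log_terms = np.where(valid, log_terms, -np.inf)
    return np.minimum(logsumexp(log_terms, axis=0) * LOG10E, 0.0)


def score_from_z(
    z: np.ndarray,
    gene_of_well: np.ndarray,
    gene_ids: list[str],
    direction: str = "up",
) -> np.ndarray:
    """RSA log10 P for every gene given well activities; the fast path shared
    by the observed run and the permutation null.

    ``gene_of_well[i]`` indexes ``gene_ids`` for well i.
    """
    if direction not in ("up", "down"):
        raise ValidationError("direction must be 'up' or 'down'")
    z = np.asarray(z, dtype=float)
    M = z.size
    ranks = rankdata(-z if direction == "up" else z, method="max")
    order = np.argsort(gene_of_well, kind="stable")
    g_sorted = gene_of_well[order]
    r_sorted = ranks[order]
    # per-gene sorted rank lists, flattened with prefix positions j = 1..N
    boundaries = np.flatnonzero(np.r_[True, np.diff(g_sorted) != 0])
    counts = np.diff(np.r_[boundaries, g_sorted.size])
    J = np.concatenate([np.arange(1, c + 1) for c in counts])
    R = np.concatenate(
        [np.sort(r_sorted[b : b + c]) for b, c in zip(boundaries, counts)]
    )
    Nrep = np.repeat(counts, counts)
    log10sf = _batched_log10_sf(J, R, Nrep, M)
    out = np.zeros(len(gene_ids))
    gene_index_sorted = g_sorted[boundaries]
    mins = np.minimum.reduceat(log10sf, np.r_[0, np.cumsum(counts)[:-1]])
    out[:] = np.nan
    out[gene_index_sorted] = mins
    return out


def rank_wells(
    normalized: list[NormalizedWell], direction: str = "up"
) -> RankedActivity:
    """Rank QC-passing library wells by robust z (descending for rescue
    screens). Tied wells receive the largest rank of their tied block —
    the conservative choice for the tail statistic — and the listing order
    breaks ties by well key for determinism."""
    if direction not in ("up", "down"):
        raise ValidationError("direction must be 'up' or 'down'")
    wells = [
        w for w in normalized
        if w.well_class == "library" and w.qc_pass and np.isfinite(w.robust_z)
    ]
    if not wells:
        raise ValidationError("no QC-passing library wells with finite robust_z")
    sign = -1.0 if direction == "up" else 1.0
    z = np.array([w.robust_z for w in wells])
    ranks = rankdata(sign * z, method="max")
    order = sorted(
        range(len(wells)), key=lambda i: (sign * z[i], wells[i].well_key)
    )
    return RankedActivity(
        well_keys=[wells[i].well_key for i in order],
        ranks=ranks[order].astype(int),
        gene_ids=[wells[i].gene_id for i in order],
        M=len(wells),
    )


def score_genes(
    normalized: list[NormalizedWell],
    library: ScreenLibrary,
    direction: str = "up",
    min_wells: int = 2,
) -> list[GeneScore]:
    """Per-gene RSA log10 P and max rel_change over QC-passing wells.

    Genes with fewer than ``min_wells`` passing wells are reported with
    ``qc_pass=False`` and no score — the screen's "did not pass the Firefly
    threshold" set — never as P = 1.
    """
    lib_wells = [w for w in normalized if w.well_class == "library"]
    unknown = sorted({w.gene_id for w in lib_wells} - set(library.genes))
    if unknown:
        raise ValidationError(
            f"wells reference genes absent from the library: {unknown[:10]}"
            + ("..." if len(unknown) > 10 else "")
        )
    passing = [
        w for w in lib_wells if w.qc_pass and np.isfinite(w.robust_z)
    ]
    gene_ids = sorted(library.genes)
    n_pass: dict[str, int] = {g: 0 for g in gene_ids}
    max_rc: dict[str, float] = {}
    for w in passing:
        n_pass[w.gene_id] += 1
        if np.isfinite(w.rel_change):
            max_rc[w.gene_id] = max(max_rc.get(w.gene_id, -np.inf), w.rel_change)

    # every QC-passing library well enters the ranking (M), even if its gene
    # ends up below min_wells and is not scored
    log10p_by_gene: dict[str, float] = {}
    if passing:
        ranked_ids = sorted({w.gene_id for w in passing})
        ranked_idx = {g: i for i, g in enumerate(ranked_ids)}
        z = np.array([w.robust_z for w in passing])
        gene_of_well = np.array([ranked_idx[w.gene_id] for w in passing])
        log10p = score_from_z(z, gene_of_well, ranked_ids, direction=direction)
        log10p_by_gene = {g: float(log10p[i]) for g, i in ranked_idx.items()}

    scores: list[GeneScore] = []
    for g in gene_ids:
        if n_pass[g] >= min_wells:
            scores.append(
                GeneScore(
                    gene_id=g,
                    rsa_log10p=log10p_by_gene[g],
                    max_rel_change=float(max_rc[g]),
                    n_wells_used=n_pass[g],
                    qc_pass=True,
                )
            )
        else:
            scores.append(
                GeneScore(
                    gene_id=g,
                    rsa_log10p=None,
                    max_rel_change=max_rc.get(g),
                    n_wells_used=n_pass[g],
                    qc_pass=False,
                )
            )
    return scores
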