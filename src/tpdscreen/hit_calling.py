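"""Randomized-activity permutation null, hit calling, and empirical FDR.

The null is built exactly the way the observed run is scored: robust-z
activities are shuffled among the QC-passing library wells (within each assay
plate by default, which preserves plate structure the normalization may not
fully remove) and genes are re-scored with the RSA statistic. The plug-in
empirical FDR at a log10 P threshold is the mean number of null genes below
the threshold divided by the observed number of hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .qc_normalize import NormalizedWell
from .rsa_stats import score_from_z
from .screen_io import GeneScore, ScreenLibrary

DEFAULT_THRESHOLD = -3.0
STRONG_THRESHOLD = -4.0


@dataclass
class PermutationNull:
    """Gene-level RSA log10 P under shuffled activities."""

    gene_ids: list[str]
    log10p: np.ndarray  # shape (n_perm, n_genes)
    threshold_log10p: float
    seed: int
    scope: str

    @property
    def n_perm(self) -> int:
        return int(self.log10p.shape[0])

    def mean_exceedance(self, threshold_log10p: float | None = None) -> float:
        thr = self.threshold_log10p if threshold_log10p is None else threshold_log10p
        return float(np.mean(np.sum(self.log10p < thr, axis=1)))


@dataclass
class HitCallResult:
    """Hits below threshold plus the plug-in FDR of the list."""

    hits: list[GeneScore]
    n_hits: int
    fdr_estimate: float | None  # fraction; None when no null was supplied
    n_qc_excluded_genes: int
    threshold_log10p: float
    strength: dict[str, str] = field(default_factory=dict)


def randomized_runs(
    normalized: list[NormalizedWell],
    library: ScreenLibrary,
    n_perm: int = 100,
    seed: int = 0,
    scope: str = "per_plate",
    direction: str = "up",
    threshold_log10p: float = DEFAULT_THRESHOLD,
) -> PermutationNull:
    """Score ``n_perm`` randomized activity runs; deterministic under seed."""
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if scope not in ("per_plate", "global"):
        raise ValidationError("scope must be 'per_plate' or 'global'")
    wells = [
        w for w in normalized
        if w.well_class == "library" and w.qc_pass and np.isfinite(w.robust_z)
    ]
    if not wells:
        raise ValidationError("no QC-passing library wells to permute")
    gene_ids = sorted({w.gene_id for w in wells})
    gene_idx = {g: i for i, g in enumerate(gene_ids)}
    z = np.array([w.robust_z for w in wells])
    gene_of_well = np.array([gene_idx[w.gene_id] for w in wells])
    if scope == "per_plate":
        plate_keys = sorted({w.plate_key for w in wells})
        groups = [
            np.array([i for i, w in enumerate(wells) if w.plate_key == key])
            for key in plate_keys
        ]
    else:
        groups = [np.arange(len(wells))]

    rng = np.random.default_rng(seed)
    out = np.empty((n_perm, len(gene_ids)))
    zp = z.copy()
    for p in range(n_perm):
        for idx in groups:
            zp[idx] = z[idx][rng.permutation(idx.size)]
        out[p] = score_from_z(zp, gene_of_well, gene_ids, direction=direction)
    return PermutationNull(
        gene_ids=gene_ids,
        log10p=out,
        threshold_log10p=threshold_log10p,
        seed=seed,
        scope=scope,
    )


def _sorted_hits(observed: list[GeneScore], threshold: float) -> list[GeneScore]:
    hits = [
        s for s in observed
        if s.qc_pass and s.rsa_log10p is not None and s.rsa_log10p < threshold
    ]
    # deterministic ordering: strongest P first, larger rescue breaks ties
    hits.sort(
        key=lambda s: (s.rsa_log10p, -(s.max_rel_change or 0.0), s.gene_id)
    )
    return hits


def estimate_fdr(
    observed: list[GeneScore],
    null: PermutationNull,
    threshold_log10p: float = DEFAULT_THRESHOLD,
) -> HitCallResult:
    """Plug-in empirical FDR: mean null exceedance / observed exceedance."""
    if threshold_log10p >= 0:
        raise ValidationError("threshold_log10p must be < 0 (log10 of a P value)")
    observed_scored = {s.gene_id for s in observed if s.qc_pass}
    null_set = set(null.gene_ids)
    if not observed_scored <= null_set:
        raise ValidationError(
            "permutation null does not cover the observed gene set: "
            f"missing {sorted(observed_scored - null_set)[:5]}"
        )
    hits = _sorted_hits(observed, threshold_log10p)
    mean_null = null.mean_exceedance(threshold_log10p)
    n_hits = len(hits)
    fdr = mean_null / max(1, n_hits) if n_hits > 0 else 0.0
    return HitCallResult(
        hits=hits,
        n_hits=n_hits,
        fdr_estimate=float(fdr),
        n_qc_excluded_genes=sum(1 for s in observed if not s.qc_pass),
        threshold_log10p=threshold_log10p,
        strength=_strength(hits, threshold_log10p, STRONG_THRESHOLD),
    )


def _strength(hits: list[GeneScore], threshold: float,
              strong_threshold: float) -> dict[str, str]:
    return {
        s.gene_id: ("strong" if s.rsa_log10p < strong_threshold else "weaker")
        for s in hits
    }


def call_hits(
    observed: list[GeneScore],
    threshold_log10p: float = DEFAULT_THRESHOLD,
    strong_threshold: float = STRONG_THRESHOLD,
) -> HitCallResult:
    """Threshold the observed scores; hits below ``strong_threshold`` are
    annotated "strong", the rest "weaker". QC-excluded genes are counted
    separately and never appear as hits."""
    if threshold_log10p >= 0 or strong_threshold >= 0:
        raise ValidationError("log10 P thresholds must be < 0")
    hits = _sorted_hits(observed, threshold_log10p)
    return HitCallResult(
        hits=hits,
        n_hits=len(hits),
        fdr_estimate=None,
        n_qc_excluded_genes=sum(1 for s in observed if not s.qc_pass),
        threshold_log10p=threshold_log10p,
        strength=_strength(hits, threshold_log10p, strong_threshold),
    )
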