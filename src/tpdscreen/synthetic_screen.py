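"""Synthetic data with known ground truth for every downstream stage.

The screen generator emulates an arrayed CRISPR rescue screen against a
degrader compound: a 943-gene library with 3–4 pooled guides per gene, one
gene per well, stamped from source plates into triplicate 384-well assay
plates. Firefly luminescence is proportional to per-well cell number (with
plate effects and log-normal well-to-well variation); HiBiT luminescence is
coupled to Firefly through a smooth strictly increasing cubic. A global
degradation factor ``d`` removes a fraction of HiBiT in non-rescued wells;
knockout of a rescuing gene restores a fraction ``rho`` of the degraded span,
so the treated/baseline HiBiT ratio is ``1-d`` for non-hits and
``1-d+rho*d`` for hits (``rho = 1`` is full rescue). Infection failures are
drawn per library source well — a bad virus well fails in all stamped
replicates — with Firefly left at the background level of the non-infected,
puromycin-killed controls, which is what the Firefly QC gate catches.

Separate small generators emit 4PL dose-response tables, flow-cytometry style
ratiometric (GFP/mCherry) degradation + viability summaries, and bell-shaped
(hook-effect) ternary-binding isotherms, each with exact known parameters for
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .screen_io import PlateWell, ScreenLibrary

ROWS = "ABCDEFGHIJKLMNOP"
N_PLATE_WELLS = 384

DEFAULT_CONTROLS = {
    "media_ctrl": 4,
    "uninfected_ctrl": 4,
    "plate_pos_ctrl": 4,
    "nontargeting_ctrl": 4,
}


@dataclass
class ScreenSimConfig:
    """Generative conditions of the simulated rescue screen.

    Defaults mirror the screen being emulated: 943 genes, 3–4 pooled guides
    per gene (mean ≈ 3.95, i.e. ~3722 guides), triplicate plates, a strong
    degrader (90% of the reporter removed), and an infection-failure rate of
    117/943 so the expected number of QC-failing genes matches the screen's
    own QC-excluded set.
    """

    n_genes: int = 943
    guides_per_gene: tuple[int, int] = (3, 4)
    n_replicate_plates: int = 3
    hit_genes: dict[str, float] = field(default_factory=dict)
    degradation_factor: float = 0.9
    cellnum_lognormal_sigma: float = 0.2
    plate_effect_sigma: float = 0.1
    firefly_gain: float = 20.0
    hibit_firefly_curve: tuple[float, float, float, float] = (
        100.0,
        0.5,
        1.0e-5,
        1.0e-10,
    )
    measurement_cv: float = 0.05
    infection_failure_rate: float = 117.0 / 943.0
    rho_jitter_kappa: float = 50.0
    mean_cells: float = 500.0
    background_firefly: float = 200.0
    background_hibit: float = 20.0
    controls_per_plate: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CONTROLS)
    )
    control_layout: str = "scattered"  # or "edge"
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        lo, hi = self.guides_per_gene
        if not 1 <= lo <= hi:
            raise ConfigError("guides_per_gene must be an increasing range >= 1")
        if not 0.0 <= self.degradation_factor < 1.0:
            raise ConfigError("degradation_factor must be in [0, 1)")
        for g, rho in self.hit_genes.items():
            if not 0.0 < rho <= 1.0:
                raise ConfigError(f"rescue fraction for {g} must be in (0, 1]")
        if not 0.0 <= self.infection_failure_rate <= 1.0:
            raise ConfigError("infection_failure_rate must be a probability")
        if min(self.cellnum_lognormal_sigma, self.plate_effect_sigma,
               self.measurement_cv) < 0:
            raise ConfigError("sigmas and CVs must be >= 0")
        if self.control_layout not in ("scattered", "edge"):
            raise ConfigError("control_layout must be 'scattered' or 'edge'")
        # the Firefly->HiBiT coupling must be strictly increasing over the
        # simulated Firefly range (derivative positive for x >= 0 suffices
        # when all coefficients beyond the constant are non-negative and at
        # least one is positive)
        _, a1, a2, a3 = self.hibit_firefly_curve
        if a1 <= 0 or a2 < 0 or a3 < 0:
            raise ConfigError(
                "hibit_firefly_curve must be strictly increasing over the "
                "simulated Firefly range"
            )


@dataclass
class GroundTruth:
    """Per-well and per-gene truth recorded by :func:`simulate_screen`.

    ``true_rel_change`` is the noiseless rescue ratio relative to the non-hit
    baseline, ``(1-d+rho*d)/(1-d)`` (1.0 for non-hits); it is the quantity the
    normalizer's ``rel_change`` estimates.
    """

    true_rel_change: dict[tuple[str, str, str], float]
    hit_rho: dict[str, float]
    qc_fail_wells: dict[tuple[str, str, str], bool]
    qc_fail_genes: set[str]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def _cubic(coefs: tuple[float, float, float, float], x: np.ndarray) -> np.ndarray:
    a0, a1, a2, a3 = coefs
    return a0 + a1 * x + a2 * x**2 + a3 * x**3


def make_library(config: ScreenSimConfig, rng: np.random.Generator) -> ScreenLibrary:
    """Draw the gene -> pooled-guide library for a configuration.

    Guide counts are drawn from ``guides_per_gene`` so that the mean pool size
    is ~3.95 when the range is the default (3, 4) — i.e. ~3722 guides for 943
    genes — and uniformly otherwise.
    """
    lo, hi = config.guides_per_gene
    genes: dict[str, list[str]] = {}
    for gid in _gene_ids(config.n_genes):
        if (lo, hi) == (3, 4):
            n_guides = 4 if rng.random() < (3722.0 / 943.0 - 3.0) else 3
        else:
            n_guides = int(rng.integers(lo, hi + 1))
        genes[gid] = [f"{gid}_sg{j}" for j in range(1, n_guides + 1)]
    return ScreenLibrary(genes=genes)


def _plate_layout(
    config: ScreenSimConfig, n_plates: int, rng: np.random.Generator
) -> list[dict[str, list[str]]]:
    """Per source plate: well IDs reserved for each control class + library."""
    all_wells = [f"{r}{c:02d}" for r in ROWS for c in range(1, 25)]
    n_ctrl = sum(config.controls_per_plate.values())
    layouts = []
    for _ in range(n_plates):
        if config.control_layout == "scattered":
            ctrl_idx = rng.choice(N_PLATE_WELLS, size=n_ctrl, replace=False)
            ctrl_wells = [all_wells[i] for i in sorted(ctrl_idx)]
        else:  # edge: fill along the first column(s)
            ctrl_wells = all_wells[:n_ctrl]
        layout: dict[str, list[str]] = {}
        k = 0
        for cls, cnt in config.controls_per_plate.items():
            layout[cls] = ctrl_wells[k : k + cnt]
            k += cnt
        layout["library"] = [w for w in all_wells if w not in set(ctrl_wells)]
        layouts.append(layout)
    return layouts


def simulate_screen(
    config: ScreenSimConfig,
) -> tuple[list[PlateWell], GroundTruth, ScreenLibrary]:
    """Generate the full arrayed screen: wells, ground truth, and library.

    Deterministic under a fixed config + seed; the global seed fans out into
    independent substreams (library, layout, per-assay-plate noise) so a
    single plate can be regenerated without replaying the whole screen.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    lib_ss, layout_ss, fail_ss, plates_ss = ss.spawn(4)
    library = make_library(config, np.random.default_rng(lib_ss))

    gene_ids = list(library.genes)
    for g in config.hit_genes:
        if g not in library.genes:
            raise ConfigError(f"hit gene {g!r} not in the simulated library")

    lib_wells_per_plate = N_PLATE_WELLS - sum(config.controls_per_plate.values())
    n_src_plates = -(-config.n_genes // lib_wells_per_plate)  # ceil
    layouts = _plate_layout(config, n_src_plates, np.random.default_rng(layout_ss))

    # infection failure is a property of the library source well: one failed
    # virus well fails in every stamped replicate
    fail_rng = np.random.default_rng(fail_ss)
    failed = {
        g: bool(fail_rng.random() < config.infection_failure_rate)
        for g in gene_ids
    }

    # assign genes to source plate wells in order
    assignment: list[tuple[int, str, str]] = []  # (plate index, well, gene)
    gi = 0
    for p, layout in enumerate(layouts):
        for w in layout["library"]:
            if gi >= len(gene_ids):
                break
            assignment.append((p, w, gene_ids[gi]))
            gi += 1

    d = config.degradation_factor
    kappa = config.rho_jitter_kappa
    wells: list[PlateWell] = []
    truth_rel: dict[tuple[str, str, str], float] = {}
    truth_fail: dict[tuple[str, str, str], bool] = {}

    plate_streams = plates_ss.spawn(n_src_plates * config.n_replicate_plates)
    for rep in range(1, config.n_replicate_plates + 1):
        rep_id = f"R{rep}"
        for p, layout in enumerate(layouts):
            plate_id = f"P{p + 1}"
            rng = np.random.default_rng(
                plate_streams[(rep - 1) * n_src_plates + p]
            )
            plate_effect = (
                np.exp(rng.normal(0.0, config.plate_effect_sigma))
                if config.plate_effect_sigma > 0
                else 1.0
            )

            def noise() -> float:
                if config.measurement_cv == 0:
                    return 1.0
                return 1.0 + rng.normal(0.0, config.measurement_cv)

            def background_pair() -> tuple[float, float]:
                ff = config.background_firefly * noise()
                hb = config.background_hibit * noise()
                return max(hb, 0.0), max(ff, 0.0)

            # controls
            for cls, ctrl_wells in layout.items():
                if cls == "library":
                    continue
                for w in ctrl_wells:
                    if cls in ("media_ctrl", "uninfected_ctrl"):
                        hb, ff = background_pair()
                    else:
                        n_cells = config.mean_cells * plate_effect * (
                            np.exp(rng.normal(0.0, config.cellnum_lognormal_sigma))
                            if config.cellnum_lognormal_sigma > 0
                            else 1.0
                        )
                        ff = config.firefly_gain * n_cells * noise()
                        baseline = _cubic(config.hibit_firefly_curve, np.asarray(ff))
                        rescue = 1.0 if cls == "plate_pos_ctrl" else (1.0 - d)
                        hb = float(baseline) * rescue * noise()
                    wells.append(
                        PlateWell(plate_id, rep_id, w, "", [], cls,
                                  max(hb, 0.0), max(ff, 0.0))
                    )

            # library wells
            for pp, w, gene in assignment:
                if pp != p:
                    continue
                key = (plate_id, rep_id, w)
                if failed[gene]:
                    # puromycin-killed: Firefly stays at background level,
                    # safely below the QC threshold of 1.25x control
                    ff = config.background_firefly * rng.uniform(0.7, 1.1)
                    hb = config.background_hibit * noise()
                    truth_rel[key] = float("nan")
                    truth_fail[key] = True
                    wells.append(
                        PlateWell(plate_id, rep_id, w, gene,
                                  library.genes[gene], "library",
                                  max(hb, 0.0), max(ff, 0.0))
                    )
                    continue
                n_cells = config.mean_cells * plate_effect * (
                    np.exp(rng.normal(0.0, config.cellnum_lognormal_sigma))
                    if config.cellnum_lognormal_sigma > 0
                    else 1.0
                )
                ff = config.firefly_gain * n_cells * noise()
                baseline = float(_cubic(config.hibit_firefly_curve, np.asarray(ff)))
                rho_gene = config.hit_genes.get(gene, 0.0)
                if rho_gene > 0.0:
                    # per-well guide-potency jitter around the gene's rescue
                    # fraction; rho = 1 is exactly full rescue
                    if rho_gene >= 1.0 or kappa <= 0:
                        rho = rho_gene
                    else:
                        rho = float(
                            rng.beta(rho_gene * kappa, (1.0 - rho_gene) * kappa)
                        )
                else:
                    rho = 0.0
                factor = 1.0 - d + rho * d
                hb = baseline * factor * noise()
                truth_rel[key] = factor / (1.0 - d)
                truth_fail[key] = False
                wells.append(
                    PlateWell(plate_id, rep_id, w, gene, library.genes[gene],
                              "library", max(hb, 0.0), max(ff, 0.0))
                )

    library.wells_per_gene = {}
    for w in wells:
        if w.well_class == "library":
            library.wells_per_gene.setdefault(w.gene_id, []).append(
                (w.plate_id, w.well_id)
            )
    truth = GroundTruth(
        true_rel_change=truth_rel,
        hit_rho=dict(config.hit_genes),
        qc_fail_wells=truth_fail,
        qc_fail_genes={g for g, f in failed.items() if f},
    )
    return wells, truth, library


def four_pl(dose: np.ndarray, bottom: float, top: float, ec50: float,
            hill: float) -> np.ndarray:
    """Four-parameter logistic: top at dose -> 0, bottom at dose -> inf
    (for hill > 0)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ec50) ** hill)


def simulate_dose_response(
    bottom: float,
    top: float,
    ec50: float,
    hill: float,
    doses: np.ndarray,
    cv: float = 0.0,
    n_rep: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy 4PL responses, one row per (dose, replicate)."""
    doses = np.asarray(doses, dtype=float)
    if hill == 0:
        raise ConfigError("hill = 0 gives a degenerate (flat) curve")
    if np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
        raise ConfigError("doses must be positive and strictly increasing")
    if cv < 0:
        raise ConfigError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_rep + 1):
        y = four_pl(doses, bottom, top, ec50, hill)
        if cv > 0:
            y = y * (1.0 + rng.normal(0.0, cv, size=doses.size))
        rows.append(pd.DataFrame({"dose": doses, "response": y, "replicate": rep}))
    return pd.concat(rows, ignore_index=True)


def simulate_flow_ratiometric(
    dc50: float,
    gi50: float,
    doses: np.ndarray,
    hills: tuple[float, float] = (1.0, 1.0),
    dmax: float = 0.95,
    bg_gfp: float = 100.0,
    bg_mch: float = 150.0,
    signal: float = 5000.0,
    viable_top: float = 0.9,
    viable_bottom: float = 0.05,
    cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-dose flow summaries: median GFP/mCherry and viable-gate fraction.

    The background-subtracted GFP/mCherry ratio follows a descending 4PL with
    midpoint ``dc50`` (lower plateau ``1 - dmax`` of the DMSO ratio); the
    viable fraction follows a descending 4PL with midpoint ``gi50``.
    """
    doses = np.asarray(doses, dtype=float)
    if gi50 <= 0 or dc50 <= 0:
        raise ConfigError("dc50 and gi50 must be > 0")
    if np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
        raise ConfigError("doses must be positive and strictly increasing")
    rng = np.random.default_rng(seed)
    ratio = four_pl(doses, 1.0 - dmax, 1.0, dc50, hills[0])
    viable = four_pl(doses, viable_bottom, viable_top, gi50, hills[1])

    def jitter(x: np.ndarray) -> np.ndarray:
        if cv == 0:
            return x
        return x * (1.0 + rng.normal(0.0, cv, size=x.shape))

    mch = jitter(np.full(doses.size, signal)) + bg_mch
    gfp = jitter(signal * ratio) + bg_gfp
    return pd.DataFrame(
        {
            "dose": doses,
            "median_gfp": gfp,
            "median_mch": mch,
            "viable_fraction": np.clip(jitter(viable), 0.0, 1.0),
        }
    )


def bell_isotherm(conc: np.ndarray, kd1: float, kd2: float,
                  rmax: float) -> np.ndarray:
    """Hook-effect steady-state response: product of an ascending and a
    descending hyperbola, peaking at sqrt(kd1*kd2)."""
    conc = np.asarray(conc, dtype=float)
    return rmax * (conc / (kd1 + conc)) * (kd2 / (kd2 + conc))


def simulate_ternary_isotherm(
    kd1: float,
    kd2: float,
    rmax: float,
    concentrations: np.ndarray,
    cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    if min(kd1, kd2, rmax) <= 0:
        raise ConfigError("kd1, kd2, rmax must all be > 0")
    conc = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    resp = bell_isotherm(conc, kd1, kd2, rmax)
    if cv > 0:
        resp = resp * (1.0 + rng.normal(0.0, cv, size=conc.size))
    return pd.DataFrame({"conc": conc, "response": resp})


def simulate_dissociation(
    koff: float,
    amplitude: float,
    baseline: float,
    times: np.ndarray,
    cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-exponential dissociation trace (SPR-style)."""
    if koff <= 0:
        raise ConfigError("koff must be > 0")
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    resp = baseline + amplitude * np.exp(-koff * t)
    if cv > 0:
        resp = resp + amplitude * rng.normal(0.0, cv, size=t.size)
    return pd.DataFrame({"time": t, "response": resp})
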