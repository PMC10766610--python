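"""Generate the arrayed rescue screen used throughout the analysis.

Default study conditions: 943 genes, 3-4 pooled guides per gene, triplicate
384-well plates, 90% degradation of the reporter, per-library-well infection
failures at 117/943, and 30 planted rescuer genes with rescue fractions drawn
in [0.5, 1]. Writes the plate table, the library annotation, and the ground
truth under results/screen/.
"""

import pathlib

import numpy as np
import pandas as pd

from tpdscreen.screen_io import write_library, write_plate_table
from tpdscreen.synthetic_screen import ScreenSimConfig, simulate_screen

SEED = 20240
ROOT = pathlib.Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "screen"
SCRATCH = ROOT / "scratch" / "screen"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    planted = rng.choice(np.arange(1, 944), size=30, replace=False)
    hit_genes = {
        f"G{i:04d}": float(r)
        for i, r in zip(planted, rng.uniform(0.5, 1.0, size=30))
    }
    cfg = ScreenSimConfig(seed=SEED, hit_genes=hit_genes)
    wells, truth, library = simulate_screen(cfg)

    write_plate_table(str(SCRATCH / "plates.csv"), wells, header=f"seed={SEED}")
    write_library(str(SCRATCH / "library.csv"), library, header=f"seed={SEED}")
    pd.DataFrame(
        [{"gene_id": g, "rescue_fraction": r} for g, r in sorted(hit_genes.items())]
    ).to_csv(OUT / "true_hits.csv", index=False)
    pd.DataFrame(
        [{"gene_id": g} for g in sorted(truth.qc_fail_genes)]
    ).to_csv(OUT / "true_qc_failures.csv", index=False)

    print(f"simulated {len(wells)} wells across "
          f"{len({w.plate_key for w in wells})} assay plates")
    print(f"library: {library.n_genes} genes, {library.n_guides} pooled guides")
    print(f"planted rescuers: {len(hit_genes)}; "
          f"infection-failed genes: {len(truth.qc_fail_genes)}")
    print(f"tables in {OUT} (plates/library in {SCRATCH})")


if __name__ == "__main__":
    main()
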