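"""QC gate, plate normalization, and gene-level RSA scoring of the screen.

Reads scratch/screen/plates.csv, applies the Firefly QC threshold
(log10 ratio > log10(1.25) over the media/non-infected control median), fits
the per-plate cubic HiBiT ~ Firefly baseline, converts wells to rel_change
and per-plate robust z, and scores genes with the min-hypergeometric RSA
statistic. Gene scores and plate polynomials go under results/screen/; the
large normalized-well table goes under scratch/screen/.
"""

import pathlib

import pandas as pd

from tpdscreen.cli import _normalized_frame
from tpdscreen.qc_normalize import normalize_screen
from tpdscreen.rsa_stats import score_genes
from tpdscreen.screen_io import read_library, read_plate_table, write_gene_scores

ROOT = pathlib.Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "screen"
SCRATCH = ROOT / "scratch" / "screen"


def main() -> None:
    wells = read_plate_table(str(SCRATCH / "plates.csv"))
    library = read_library(str(SCRATCH / "library.csv"))
    normed, polys = normalize_screen(wells)

    n_lib = sum(1 for w in normed if w.well_class == "library")
    n_fail = sum(
        1 for w in normed if w.well_class == "library" and not w.qc_pass)
    scores = score_genes(normed, library)
    n_excluded = sum(1 for s in scores if not s.qc_pass)

    _normalized_frame(normed).to_csv(SCRATCH / "normalized_wells.csv", index=False)
    pd.DataFrame(
        [
            {"plate_id": p.plate_id, "replicate_id": p.replicate_id,
             "c0": p.coefficients[0], "c1": p.coefficients[1],
             "c2": p.coefficients[2], "c3": p.coefficients[3],
             "n_points_used": p.n_points_used}
            for p in polys.values()
        ]
    ).to_csv(OUT / "plate_polynomials.csv", index=False)
    write_gene_scores(str(OUT / "gene_scores.csv"), scores)

    print(f"{n_lib} library wells; {n_fail} failed the Firefly QC gate")
    print(f"{len(polys)} plate polynomials fit")
    print(f"{len(scores) - n_excluded} genes scored; "
          f"{n_excluded} genes QC-excluded (too few passing wells)")


if __name__ == "__main__":
    main()
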