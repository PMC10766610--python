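"""Data model and CSV I/O for the arrayed rescue screen.

The screen's atomic observation is one 384-well plate well carrying a pair of
luminescence readings: HiBiT (tagged-protein abundance) and Firefly (cell
number control). Wells are either library wells — one gene, a pool of sgRNAs —
or controls (media-only, non-infected/puromycin-killed, per-plate positive
guides, non-targeting guides).

All tables are comma-separated UTF-8 with a mandatory header row. Lines
starting with ``#`` are treated as comments (pipeline artifacts carry their
provenance in such headers). ``guide_ids`` are serialized semicolon-joined so
a well stays one row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .exceptions import FormatError, ValidationError

WELL_CLASSES = (
    "library",
    "media_ctrl",
    "uninfected_ctrl",
    "plate_pos_ctrl",
    "nontargeting_ctrl",
)
CONTROL_CLASSES = tuple(c for c in WELL_CLASSES if c != "library")

_WELL_RE = re.compile(r"^([A-Pa-p])(\d{1,2})$")

PLATE_COLUMNS = [
    "plate_id",
    "replicate_id",
    "well_id",
    "gene_id",
    "guide_ids",
    "well_class",
    "hibit_rlu",
    "firefly_rlu",
]

GENE_SCORE_COLUMNS = [
    "gene_id",
    "rsa_log10p",
    "max_rel_change",
    "n_wells_used",
    "qc_pass",
]


def parse_well_id(well_id: str) -> tuple[str, int]:
    """Parse a 384-well ID into (row letter, column number).

    Accepts case-insensitive, optionally non-zero-padded IDs ("a1", "A01").
    Rows run A–P and columns 1–24.
    """
    m = _WELL_RE.match(str(well_id).strip())
    if not m:
        raise ValidationError(f"well_id {well_id!r} is not a valid 384-well ID")
    row = m.group(1).upper()
    col = int(m.group(2))
    if not 1 <= col <= 24:
        raise ValidationError(f"well_id {well_id!r}: column {col} outside 1-24")
    return row, col


def canonical_well_id(well_id: str) -> str:
    """Upper-case, zero-padded well ID, e.g. 'a1' -> 'A01'."""
    row, col = parse_well_id(well_id)
    return f"{row}{col:02d}"


@dataclass
class PlateWell:
    """One well's raw luminescence pair plus identity and class metadata."""

    plate_id: str
    replicate_id: str
    well_id: str
    gene_id: str
    guide_ids: list[str]
    well_class: str
    hibit_rlu: float
    firefly_rlu: float

    def __post_init__(self) -> None:
        self.well_id = canonical_well_id(self.well_id)
        if self.well_class not in WELL_CLASSES:
            raise ValidationError(
                f"well_class {self.well_class!r} not one of {WELL_CLASSES}"
            )
        if self.hibit_rlu < 0 or self.firefly_rlu < 0:
            raise ValidationError(
                f"negative RLU in well {self.plate_id}/{self.replicate_id}/"
                f"{self.well_id}"
            )
        if self.well_class == "library":
            if not self.gene_id:
                raise ValidationError(
                    f"library well {self.well_id} has empty gene_id"
                )
            if not 1 <= len(self.guide_ids) <= 6:
                raise ValidationError(
                    f"library well {self.well_id}: {len(self.guide_ids)} guides "
                    "(expected 1-6)"
                )
        else:
            if self.gene_id:
                raise ValidationError(
                    f"control well {self.well_id} has non-empty gene_id "
                    f"{self.gene_id!r}"
                )

    @property
    def plate_key(self) -> tuple[str, str]:
        """Identity of the physical assay plate (library plate x replicate)."""
        return (self.plate_id, self.replicate_id)


@dataclass
class ScreenLibrary:
    """gene -> pooled sgRNAs, plus (optionally) the wells each gene occupies."""

    genes: dict[str, list[str]]
    wells_per_gene: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_guides(self) -> int:
        return sum(len(g) for g in self.genes.values())


@dataclass
class GeneScore:
    """Per-gene screen result: RSA log10 P and the largest relative change.

    ``rsa_log10p`` / ``max_rel_change`` are ``None`` for genes that failed the
    per-gene QC rule (too few Firefly-passing wells); a failed gene is flagged,
    never silently scored 0.
    """

    gene_id: str
    rsa_log10p: float | None
    max_rel_change: float | None
    n_wells_used: int
    qc_pass: bool


def _require_columns(df: pd.DataFrame, columns: Iterable[str], path: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_plate_table(path: str) -> list[PlateWell]:
    """Read a plate-well CSV into validated :class:`PlateWell` records.

    Malformed rows raise with the offending row number; they are never
    silently dropped.
    """
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    if df.empty and df.columns.size == 0:
        raise FormatError(f"{path}: empty file")
    _require_columns(df, PLATE_COLUMNS, path)
    wells = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            hibit = float(row.hibit_rlu)
            firefly = float(row.firefly_rlu)
        except ValueError as exc:
            raise FormatError(f"{path} row {i}: non-numeric RLU ({exc})") from exc
        guides = [g for g in str(row.guide_ids).split(";") if g]
        try:
            wells.append(
                PlateWell(
                    plate_id=row.plate_id,
                    replicate_id=row.replicate_id,
                    well_id=row.well_id,
                    gene_id=row.gene_id,
                    guide_ids=guides,
                    well_class=row.well_class,
                    hibit_rlu=hibit,
                    firefly_rlu=firefly,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
    return wells


def write_plate_table(path: str, wells: list[PlateWell], header: str | None = None) -> None:
    if not wells:
        raise ValidationError("refusing to write an empty plate table")
    df = pd.DataFrame(
        {
            "plate_id": [w.plate_id for w in wells],
            "replicate_id": [w.replicate_id for w in wells],
            "well_id": [w.well_id for w in wells],
            "gene_id": [w.gene_id for w in wells],
            "guide_ids": [";".join(w.guide_ids) for w in wells],
            "well_class": [w.well_class for w in wells],
            "hibit_rlu": [repr(float(w.hibit_rlu)) for w in wells],
            "firefly_rlu": [repr(float(w.firefly_rlu)) for w in wells],
        }
    )
    _write_csv(path, df, header)


def read_library(path: str) -> ScreenLibrary:
    """Read a (gene_id, guide_id) CSV, one guide per row."""
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    if df.empty:
        raise FormatError(f"{path}: empty library file")
    _require_columns(df, ["gene_id", "guide_id"], path)
    genes: dict[str, list[str]] = {}
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pair = (row.gene_id, row.guide_id)
        if not row.gene_id or not row.guide_id:
            raise ValidationError(f"{path} row {i}: empty gene_id or guide_id")
        if pair in seen:
            raise ValidationError(
                f"{path} row {i}: duplicate (gene, guide) pair {pair}"
            )
        seen.add(pair)
        genes.setdefault(row.gene_id, []).append(row.guide_id)
    return ScreenLibrary(genes=genes)


def write_library(path: str, library: ScreenLibrary, header: str | None = None) -> None:
    rows = [
        {"gene_id": g, "guide_id": guide}
        for g, guides in library.genes.items()
        for guide in guides
    ]
    if not rows:
        raise ValidationError("refusing to write an empty library")
    _write_csv(path, pd.DataFrame(rows), header)


def write_gene_scores(path: str, scores: list[GeneScore], header: str | None = None) -> None:
    """Write gene scores; floats round-trip at full precision (repr)."""
    if not scores:
        raise ValidationError("refusing to write an empty gene-score table")
    df = pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in scores],
            "rsa_log10p": [
                "" if s.rsa_log10p is None else repr(float(s.rsa_log10p))
                for s in scores
            ],
            "max_rel_change": [
                "" if s.max_rel_change is None else repr(float(s.max_rel_change))
                for s in scores
            ],
            "n_wells_used": [s.n_wells_used for s in scores],
            "qc_pass": [s.qc_pass for s in scores],
        }
    )
    _write_csv(path, df, header)


def read_gene_scores(path: str) -> list[GeneScore]:
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    if df.empty:
        raise FormatError(f"{path}: empty gene-score file")
    _require_columns(df, GENE_SCORE_COLUMNS, path)
    scores = []
    for row in df.itertuples(index=False):
        scores.append(
            GeneScore(
                gene_id=row.gene_id,
                rsa_log10p=float(row.rsa_log10p) if row.rsa_log10p else None,
                max_rel_change=(
                    float(row.max_rel_change) if row.max_rel_change else None
                ),
                n_wells_used=int(row.n_wells_used),
                qc_pass=str(row.qc_pass).strip().lower() == "true",
            )
        )
    return scores


def _write_csv(path: str, df: pd.DataFrame, header: str | None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
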