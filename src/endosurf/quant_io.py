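"""Data model and TSV I/O for fraction-wise peak-area tables and annotation tables.

The experimental unit is one *cell line* measured in four fractions:

* ``control`` — no biotinylation; streptavidin-bead background.
* ``surface`` — biotinylated at 4 °C, no internalization; the cell-surface pool.
* ``stripping`` — biotinylated then MESNA-stripped without warming; strip-failure
  background.
* ``internalization`` — biotinylated, warmed to allow endocytosis, then stripped;
  only internalized protein is protected from MESNA.

Peak areas are the summed extracted fragment-ion chromatographic areas of a
protein's unique peptides in one biological replicate — non-negative, in
arbitrary intensity units.  A missing (protein, fraction) combination means the
protein produced no extractable peak and is treated as not detected (area 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

FRACTIONS = ("control", "surface", "stripping", "internalization")

#: accepted spellings, compared after lower-casing and whitespace stripping
_FRACTION_ALIASES = {
    "control": "control",
    "surface": "surface",
    "cell-surface": "surface",
    "cell surface": "surface",
    "stripping": "stripping",
    "strip": "stripping",
    "internalization": "internalization",
    "internalisation": "internalization",
    "internalized": "internalization",
}

#: controlled GO-style location terms used downstream (canonical spelling)
TERMS_OF_INTEREST = ("Plasma membrane", "Cell surface", "Cytoplasm")


class QuantFormatError(ValueError):
    """Malformed quant/annotation table (missing column, bad label, bad value)."""


def normalize_fraction(label: str) -> str:
    key = " ".join(str(label).split()).lower()
    if key not in _FRACTION_ALIASES:
        raise QuantFormatError(
            f"unknown fraction label {label!r}; expected one of {sorted(set(_FRACTION_ALIASES))}"
        )
    return _FRACTION_ALIASES[key]


def normalize_term(term: str) -> str:
    """Whitespace-normalize and case-fold a location term for matching."""
    return " ".join(str(term).split()).lower()


@dataclass
class QuantTable:
    """Per-replicate protein-level peak areas for one cell line.

    ``data`` has columns ``protein_id, fraction, replicate, peak_area`` with
    fractions already normalized; one row per observed replicate measurement.
    """

    cell_line: str
    data: pd.DataFrame
    max_replicates: int = 3

    def __post_init__(self) -> None:
        required = ["protein_id", "fraction", "replicate", "peak_area"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise QuantFormatError(f"quant table missing column(s): {', '.join(missing)}")
        df = self.data
        bad = ~df["fraction"].isin(FRACTIONS)
        if bad.any():
            raise QuantFormatError(f"unknown fraction label(s): {sorted(df.loc[bad, 'fraction'].unique())}")
        areas = pd.to_numeric(df["peak_area"], errors="coerce")
        if areas.isna().any() or not all(math.isfinite(a) for a in areas):
            row = int(df.index[areas.isna() | ~areas.map(math.isfinite)][0])
            raise QuantFormatError(f"non-numeric or non-finite peak_area at row {row}")
        if (areas < 0).any():
            row = int(df.index[areas < 0][0])
            raise QuantFormatError(f"negative peak_area at row {row}")
        dup = df.duplicated(subset=["protein_id", "fraction", "replicate"])
        if dup.any():
            key = df.loc[dup, ["protein_id", "fraction", "replicate"]].iloc[0].tolist()
            raise QuantFormatError(f"duplicate (protein, fraction, replicate) row: {key}")
        counts = df.groupby(["protein_id", "fraction"], sort=False).size()
        if (counts > self.max_replicates).any():
            key = counts[counts > self.max_replicates].index[0]
            raise QuantFormatError(
                f"{key} has more than the design maximum of {self.max_replicates} replicates"
            )

    @property
    def proteins(self) -> list[str]:
        return sorted(self.data["protein_id"].unique())


def read_quant_table(path, cell_line: str, max_replicates: int = 3) -> QuantTable:
    """Read a quant TSV (columns protein_id, fraction, replicate, peak_area).

    Fraction labels are normalized ("Cell-surface " → "surface"); unknown
    labels, duplicate replicate rows and negative areas are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = ["protein_id", "fraction", "replicate", "peak_area"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise QuantFormatError(f"{path}: missing column(s): {', '.join(missing)}")
    df = df[required].copy()
    df["fraction"] = df["fraction"].map(normalize_fraction)
    df["replicate"] = df["replicate"].astype(int)
    df["peak_area"] = pd.to_numeric(df["peak_area"], errors="coerce")
    bad = df["peak_area"].isna() | (df["peak_area"] < 0)
    if bad.any():
        # +2: header line plus 1-based numbering
        raise QuantFormatError(f"{path}: invalid peak_area at line {int(df.index[bad][0]) + 2}")
    return QuantTable(cell_line=cell_line, data=df.reset_index(drop=True), max_replicates=max_replicates)


def write_quant_table(table: QuantTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def aggregate_replicates(table: QuantTable) -> pd.DataFrame:
    """Collapse replicates to per-(protein, fraction) means and SDs.

    Returns a DataFrame indexed by protein_id with one ``mean_<fraction>`` and
    one ``sd_<fraction>`` column per fraction.  A fraction with no replicate
    rows for a protein yields mean 0 (not detected) and SD 0; SD over a single
    replicate is 0.
    """
    g = table.data.groupby(["protein_id", "fraction"], sort=True)["peak_area"]
    means = g.mean().unstack("fraction").reindex(columns=list(FRACTIONS)).fillna(0.0)
    sds = g.std(ddof=1).unstack("fraction").reindex(columns=list(FRACTIONS)).fillna(0.0)
    out = pd.concat(
        {f"mean_{f}": means[f] for f in FRACTIONS} | {f"sd_{f}": sds[f] for f in FRACTIONS},
        axis=1,
    )
    out.index.name = "protein_id"
    return out.sort_index()


@dataclass
class AnnotationSet:
    """protein_id → set of location terms, matched case-insensitively."""

    terms: dict[str, set[str]] = field(default_factory=dict)

    def has_term(self, protein_id: str, term: str) -> bool:
        return normalize_term(term) in self.terms.get(protein_id, set())

    def proteins_with(self, term: str) -> set[str]:
        t = normalize_term(term)
        return {p for p, ts in self.terms.items() if t in ts}


def read_annotation_table(path) -> AnnotationSet:
    """Read an annotation TSV with columns protein_id, term (one term per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_id", "term"):
        if col not in df.columns:
            raise QuantFormatError(f"{path}: missing column(s): {col}")
    terms: dict[str, set[str]] = {}
    for pid, term in zip(df["protein_id"], df["term"]):
        terms.setdefault(str(pid), set()).add(normalize_term(term))
    return AnnotationSet(terms=terms)


def write_annotation_table(annotations: AnnotationSet, path) -> None:
    rows = [
        {"protein_id": p, "term": t}
        for p in sorted(annotations.terms)
        for t in sorted(annotations.terms[p])
    ]
    pd.DataFrame(rows, columns=["protein_id", "term"]).to_csv(path, sep="\t", index=False)


@dataclass
class ReferenceList:
    """A named plain list of protein IDs (e.g. the BBB plasma-membrane catalogue)."""

    name: str
    members: set[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("reference list name must be non-empty")
        self.members = set(self.members)


def read_reference_list(path, name: str | None = None) -> ReferenceList:
    """One protein_id per line; blank lines and '#' comments ignored."""
    members = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                members.add(line)
    return ReferenceList(name=name or str(path), members=members)


def read_fpkm_table(path) -> pd.Series:
    """Read a transcript-abundance TSV (protein_id, fpkm) into a Series."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    for col in ("protein_id", "fpkm"):
        if col not in df.columns:
            raise QuantFormatError(f"{path}: missing column(s): {col}")
    if df.empty:
        raise QuantFormatError(f"{path}: empty fpkm table")
    if df["protein_id"].duplicated().any():
        dup = df.loc[df["protein_id"].duplicated(), "protein_id"].iloc[0]
        raise QuantFormatError(f"{path}: duplicated protein_id {dup!r}")
    return df.set_index("protein_id")["fpkm"].astype(float)


def read_atlas_table(path) -> pd.DataFrame:
    """Read an atlas-style localization TSV (protein_id, tissue, detection_level)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_id", "tissue", "detection_level"):
        if col not in df.columns:
            raise QuantFormatError(f"{path}: missing column(s): {col}")
    levels = {"not_detected", "low", "medium", "high"}
    bad = ~df["detection_level"].isin(levels)
    if bad.any():
        raise QuantFormatError(
            f"{path}: unknown detection_level {df.loc[bad, 'detection_level'].iloc[0]!r}"
        )
    if df.duplicated(subset=["protein_id", "tissue"]).any():
        raise QuantFormatError(f"{path}: duplicated (protein_id, tissue) row")
    return df.reset_index(drop=True)
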