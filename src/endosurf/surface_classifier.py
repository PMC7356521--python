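"""Cell-surface calling from Cell-surface/Control peak-area ratios.

The streptavidin pulldown carries background: proteins that bind the beads
without being biotinylated appear in every fraction, including the no-biotin
control.  Genuinely biotinylated cell-surface proteins are enriched in the
surface fraction relative to control, so the surface/control ratio R separates
them from background.  Ratios are binned on a binary-log scale, the per-bin
percentage of proteins carrying each GO location term is profiled, and the
surface threshold T* is derived as the smallest power of two above which no
"Cytoplasm"-annotated protein remains — cytosolic contamination defines how
high background enrichment can reach.

Classes:

* ``non_specific`` — R ≤ 2: consistent with bead background.
* ``cytosol_like`` — 2 < R ≤ T*: enriched, but within the range occupied by
  cytosolic contaminants.
* ``cell_surface`` — R > T*: called a biotinylated cell-surface protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant_io import AnnotationSet, TERMS_OF_INTEREST, normalize_term

NON_SPECIFIC_CUTOFF = 2.0  # surface/control ratio at or below which binding is non-specific


def compute_ratio(surface_mean: float, control_mean: float) -> float:
    """Surface-to-control mean peak-area ratio.

    control 0 with surface > 0 gives +inf (detected only with biotin); both 0
    gives NaN — the protein was not seen in either fraction and is excluded
    from binning and threshold derivation.
    """
    if surface_mean < 0 or control_mean < 0:
        raise ValueError("peak-area means must be >= 0")
    if control_mean == 0:
        return math.inf if surface_mean > 0 else math.nan
    return surface_mean / control_mean


def ratio_bin(ratio: float) -> float:
    """Binary-log bin index k such that ratio lies in (2^(k-1), 2^k].

    Upper-inclusive so that the printed thresholds (4, 8) are bin edges.
    Infinite and undefined ratios have no bin (NaN).
    """
    if math.isnan(ratio) or math.isinf(ratio):
        return math.nan
    if ratio <= 0:
        raise ValueError("ratio must be positive to bin")
    return float(math.ceil(math.log2(ratio) - 1e-12))


@dataclass
class SurfaceCallResult:
    """Per-protein ratios, bins and three-way surface class for one cell line.

    ``table`` columns: protein_id (index), R_sc, bin, surface_class; proteins
    with undefined R (absent from both fractions) carry class ``undefined``.
    """

    cell_line: str
    table: pd.DataFrame
    threshold: float

    @property
    def surface_proteins(self) -> set[str]:
        return set(self.table.index[self.table["surface_class"] == "cell_surface"])

    def class_counts(self) -> dict[str, int]:
        return self.table["surface_class"].value_counts().to_dict()

    @classmethod
    def from_ratios(
        cls, cell_line: str, threshold: float, ratios: dict[str, float]
    ) -> "SurfaceCallResult":
        """Build a result from externally known per-protein ratios.

        Useful for running the downstream set algebra on published protein
        lists where only ratios (or just list membership) are available.
        """
        frame = pd.DataFrame({"R_sc": pd.Series(ratios, dtype=float)})
        frame.index.name = "protein_id"
        frame["bin"] = [ratio_bin(v) if v > 0 else math.nan for v in frame["R_sc"]]
        return call_surface(frame, threshold, cell_line=cell_line)


def compute_ratios(means: pd.DataFrame) -> pd.DataFrame:
    """Vectorized surface/control ratios + bins for an aggregated means table."""
    surf = means["mean_surface"].to_numpy(dtype=float)
    ctrl = means["mean_control"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(ctrl > 0, surf / np.where(ctrl > 0, ctrl, 1.0),
                     np.where(surf > 0, np.inf, np.nan))
    out = pd.DataFrame({"R_sc": r}, index=means.index)
    out["bin"] = [ratio_bin(v) if v > 0 else math.nan for v in r]
    return out


def annotation_profile(
    ratios: pd.DataFrame, annotations: AnnotationSet, term: str
) -> dict[int, float]:
    """Percentage of binned proteins in each binary-log bin carrying *term*.

    Only proteins with a finite ratio (hence a bin) contribute.  Bins with no
    proteins are simply absent from the mapping, never reported as 0 %.
    """
    if normalize_term(term) not in {normalize_term(t) for t in TERMS_OF_INTEREST}:
        raise ValueError(f"unknown term {term!r}; known terms: {list(TERMS_OF_INTEREST)}")
    binned = ratios.dropna(subset=["bin"])
    profile: dict[int, float] = {}
    for k, group in binned.groupby("bin"):
        n = len(group)
        hits = sum(annotations.has_term(p, term) for p in group.index)
        profile[int(k)] = 100.0 * hits / n
    return profile


def derive_threshold(
    ratios: pd.DataFrame,
    annotations: AnnotationSet,
    tolerance: float = 0.0,
    override: float | None = None,
) -> float:
    """Smallest power of two b ≥ 2 with (almost) no Cytoplasm protein above it.

    ``tolerance`` is the fraction of Cytoplasm-annotated proteins allowed to
    remain above the threshold (default 0, the strict exclusion rule).
    ``override`` short-circuits derivation with a fixed manual threshold.
    Infinite ratios are excluded — a protein invisible in the control says
    nothing about how far contamination reaches.
    """
    if override is not None:
        if override < NON_SPECIFIC_CUTOFF:
            raise ValueError("threshold override must be >= 2")
        return float(override)
    cyto = [p for p in ratios.index if annotations.has_term(p, "Cytoplasm")]
    vals = ratios.loc[cyto, "R_sc"].to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if len(cyto) == 0 or (len(finite) == 0 and not np.isinf(vals).any()):
        raise ValueError(
            "no Cytoplasm-annotated protein with a ratio; supply a manual threshold override"
        )
    if len(finite) == 0:
        raise ValueError(
            "all Cytoplasm-annotated proteins have infinite ratios; supply a manual override"
        )
    b = NON_SPECIFIC_CUTOFF
    n = len(finite)
    while np.sum(finite > b) > tolerance * n:
        b *= 2
    return float(b)


def call_surface(
    ratios: pd.DataFrame, threshold: float, cell_line: str = ""
) -> SurfaceCallResult:
    """Three-way classification of every protein given the derived threshold."""
    if threshold < NON_SPECIFIC_CUTOFF:
        raise ValueError("threshold must be >= 2")
    r = ratios["R_sc"]

    def classify(v: float) -> str:
        if math.isnan(v):
            return "undefined"
        if v <= NON_SPECIFIC_CUTOFF:
            return "non_specific"
        if v <= threshold:
            return "cytosol_like"
        return "cell_surface"

    table = ratios.copy()
    table["surface_class"] = [classify(v) for v in r]
    return SurfaceCallResult(cell_line=cell_line, table=table, threshold=threshold)
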