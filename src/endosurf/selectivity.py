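"""Cross-cell-line selectivity: which endocytic surface proteins belong to the
target endothelium and not to the peripheral comparator.

Given surface and endocytosis calls for a target line A (brain microvascular
model) and a comparator line B (peripheral model), plus a reference catalogue
of plasma-membrane proteins from the target barrier, candidates are selected
through three mutually exclusive routes and their union:

* Criterion I   — endocytic only in A AND cell-surface only in A, ∩ reference.
* Criterion II  — endocytic only in A, cell-surface in both lines, ∩ reference.
* Criterion III — endocytic in both lines but with an internalization-fraction
  peak-area fold change A/B above a threshold (default 4), ∩ reference.

Every intermediate set size is kept (the Venn accounting), including the
conservation identity |selective endocytic| = |I pre-reference| + |II
pre-reference|, which holds because endocytic calls are a subset of surface
calls and the surface set partitions into A-only and shared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .endocytosis_classifier import EndocytosisCallResult
from .quant_io import ReferenceList
from .surface_classifier import SurfaceCallResult

FOLD_THRESHOLD = 4.0


def fold_change(internal_mean_a: float, internal_mean_b: float) -> float:
    """Cross-line peak-area fold change A/B; +inf when B is 0, NaN when both are."""
    if internal_mean_a < 0 or internal_mean_b < 0:
        raise ValueError("peak-area means must be >= 0")
    if internal_mean_b == 0:
        return math.inf if internal_mean_a > 0 else math.nan
    return internal_mean_a / internal_mean_b


@dataclass
class SelectivityReport:
    """Per-protein selectivity flags and the full Venn accounting."""

    table: pd.DataFrame  # flags + fold change + criterion_selected per protein
    venn: dict[str, float] = field(default_factory=dict)

    @property
    def final_candidates(self) -> set[str]:
        return set(self.table.index[self.table["criterion_selected"] != "none"])


def select_candidates(
    surface_a: SurfaceCallResult,
    endo_a: EndocytosisCallResult,
    surface_b: SurfaceCallResult,
    endo_b: EndocytosisCallResult,
    reference: ReferenceList,
    means_a: pd.DataFrame | None = None,
    means_b: pd.DataFrame | None = None,
    fold_threshold: float = FOLD_THRESHOLD,
    fold_fraction: str = "internalization",
) -> SelectivityReport:
    """Apply Criteria I–III and assemble the Venn accounting.

    ``means_a``/``means_b`` (aggregated fraction means) supply the peak areas
    for the Criterion-III fold change; they may be omitted only when the two
    endocytic sets do not intersect.  ``fold_fraction`` chooses which
    fraction's means the fold change uses (internalization by default; surface
    as the alternative).
    """
    if not reference.members:
        raise ValueError("reference list is empty")
    if fold_fraction not in ("internalization", "surface"):
        raise ValueError("fold_fraction must be 'internalization' or 'surface'")

    surf_A = surface_a.surface_proteins
    surf_B = surface_b.surface_proteins
    endo_A = endo_a.endocytic_proteins
    endo_B = endo_b.endocytic_proteins
    for name, endo, surf in (("A", endo_A, surf_A), ("B", endo_B, surf_B)):
        stray = endo - surf
        if stray:
            raise ValueError(
                f"line {name}: endocytic protein(s) missing from the surface set "
                f"(upstream contract breach): {sorted(stray)[:5]}"
            )

    selective_surface = surf_A - surf_B
    common_surface = surf_A & surf_B
    selective_endocytic = endo_A - endo_B
    common_endocytic = endo_A & endo_B

    crit1_pre = selective_endocytic & selective_surface
    crit2_pre = selective_endocytic & common_surface

    col = f"mean_{'internalization' if fold_fraction == 'internalization' else 'surface'}"
    fold: dict[str, float] = {}
    for pid in sorted(common_endocytic):
        if means_a is None or means_b is None:
            raise ValueError("fraction means required to evaluate Criterion III fold changes")
        fold[pid] = fold_change(float(means_a.loc[pid, col]), float(means_b.loc[pid, col]))
    crit3_pre = {p for p, f in fold.items() if not math.isnan(f) and f > fold_threshold}

    crit1 = crit1_pre & reference.members
    crit2 = crit2_pre & reference.members
    crit3 = crit3_pre & reference.members
    final = crit1 | crit2 | crit3

    universe = sorted(surf_A | surf_B | endo_A | endo_B)
    rows = []
    for pid in universe:
        if pid in crit1:
            chosen = "I"
        elif pid in crit2:
            chosen = "II"
        elif pid in crit3:
            chosen = "III"
        else:
            chosen = "none"
        rows.append(
            {
                "protein_id": pid,
                "surface_in_A": pid in surf_A,
                "surface_in_B": pid in surf_B,
                "endocytic_in_A": pid in endo_A,
                "endocytic_in_B": pid in endo_B,
                "in_reference": pid in reference.members,
                "fold_change": fold.get(pid, math.nan),
                "criterion_selected": chosen,
            }
        )
    table = pd.DataFrame(rows).set_index("protein_id")

    finite_folds = [f for f in fold.values() if math.isfinite(f)]
    venn = {
        "surface_A": len(surf_A),
        "surface_B": len(surf_B),
        "common_surface": len(common_surface),
        "selective_surface": len(selective_surface),
        "endocytic_A": len(endo_A),
        "endocytic_B": len(endo_B),
        "common_endocytic": len(common_endocytic),
        "selective_endocytic": len(selective_endocytic),
        "criterion_I_pre_reference": len(crit1_pre),
        "criterion_II_pre_reference": len(crit2_pre),
        "criterion_III_pre_reference": len(crit3_pre),
        "criterion_I": len(crit1),
        "criterion_II": len(crit2),
        "criterion_III": len(crit3),
        "final_candidates": len(final),
        "mean_fold_change_arithmetic": float(np.mean(finite_folds)) if finite_folds else math.nan,
        "mean_fold_change_geometric": (
            float(np.exp(np.mean(np.log(finite_folds)))) if finite_folds and min(finite_folds) > 0 else math.nan
        ),
    }
    return SelectivityReport(table=table, venn=venn)
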