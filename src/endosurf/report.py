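"""Pipeline orchestration, counts accounting and report generation.

Runs surface → endocytosis per cell line, then cross-line selectivity and
database prioritization, and assembles a counts dictionary holding every
intermediate set size (identified totals, ratio > 2 counts and percentages,
derived thresholds, per-criterion endocytic counts, the full selectivity Venn,
and the prioritization funnel).  All outputs are plain TSV/JSON so repeated
runs with the same inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import endosurf

from . import quant_io
from .endocytosis_classifier import EndocytosisCallResult, call_endocytic
from .prioritization import PrioritizationResult, prioritize
from .quant_io import AnnotationSet, QuantTable, ReferenceList, aggregate_replicates
from .selectivity import SelectivityReport, select_candidates
from .surface_classifier import (
    SurfaceCallResult,
    annotation_profile,
    call_surface,
    compute_ratios,
    derive_threshold,
)

logger = logging.getLogger("endosurf")


@dataclass
class LineResult:
    """Everything computed for one cell line."""

    cell_line: str
    means: pd.DataFrame
    surface: SurfaceCallResult
    endocytosis: EndocytosisCallResult
    profiles: dict[str, dict[int, float]] = field(default_factory=dict)

    def counts(self) -> dict:
        tab = self.surface.table
        defined = tab["R_sc"].notna()
        finite_or_inf = tab.loc[defined, "R_sc"]
        gt2 = int((finite_or_inf > 2.0).sum())
        identified = int(len(self.means))
        surface_n = int((tab["surface_class"] == "cell_surface").sum())
        crit = self.endocytosis.criterion_counts()
        return {
            "identified": identified,
            "ratio_gt2": gt2,
            "ratio_gt2_percent": round(100.0 * gt2 / identified, 1) if identified else 0.0,
            "undefined_ratio": int((~defined).sum()),
            "threshold": self.surface.threshold,
            "surface": surface_n,
            "surface_percent": round(100.0 * surface_n / identified, 1) if identified else 0.0,
            "cytosol_like": int((tab["surface_class"] == "cytosol_like").sum()),
            "non_specific": int((tab["surface_class"] == "non_specific").sum()),
            "endocytic": int(self.endocytosis.table["endocytic"].sum()),
            "criterion_A": crit["A"],
            "criterion_B": crit["B"],
        }


def process_line(
    quant: QuantTable,
    annotations: AnnotationSet,
    threshold_override: float | None = None,
    threshold_tolerance: float = 0.0,
) -> LineResult:
    """Aggregate replicates, derive the surface threshold and call both stages."""
    means = aggregate_replicates(quant)
    ratios = compute_ratios(means)
    t_star = derive_threshold(
        ratios, annotations, tolerance=threshold_tolerance, override=threshold_override
    )
    surface = call_surface(ratios, t_star, cell_line=quant.cell_line)
    endo = call_endocytic(means, surface)
    profiles = {
        term: annotation_profile(ratios, annotations, term)
        for term in quant_io.TERMS_OF_INTEREST
    }
    n_inf = int((surface.table["R_sc"] == float("inf")).sum())
    if n_inf:
        logger.warning("%s: %d protein(s) with infinite surface/control ratio", quant.cell_line, n_inf)
    return LineResult(
        cell_line=quant.cell_line, means=means, surface=surface,
        endocytosis=endo, profiles=profiles,
    )


@dataclass
class PipelineResult:
    target: LineResult
    comparator: LineResult
    selectivity: SelectivityReport
    prioritization: PrioritizationResult | None
    counts: dict


def run_two_line_analysis(
    quant_target: QuantTable,
    quant_comparator: QuantTable,
    annotations: AnnotationSet,
    reference: ReferenceList,
    fpkm: pd.Series | None = None,
    atlas: pd.DataFrame | None = None,
    fold_threshold: float = 4.0,
    fold_fraction: str = "internalization",
    expression_threshold: float = 5.0,
    threshold_override_target: float | None = None,
    threshold_override_comparator: float | None = None,
) -> PipelineResult:
    """Full analysis for one target/comparator pair; inputs already in memory."""
    target = process_line(quant_target, annotations, threshold_override_target)
    comparator = process_line(quant_comparator, annotations, threshold_override_comparator)
    sel = select_candidates(
        target.surface, target.endocytosis,
        comparator.surface, comparator.endocytosis,
        reference,
        means_a=target.means, means_b=comparator.means,
        fold_threshold=fold_threshold, fold_fraction=fold_fraction,
    )
    prior = None
    if fpkm is not None and atlas is not None and sel.final_candidates:
        prior = prioritize(sel.final_candidates, fpkm, atlas, expression_threshold)
    counts = {
        "lines": {
            target.cell_line: target.counts(),
            comparator.cell_line: comparator.counts(),
        },
        "selectivity": sel.venn,
    }
    if prior is not None:
        tab = prior.table
        counts["prioritization"] = {
            "candidates": int(len(tab)),
            "expression_pass": int((tab["expression_status"] == "pass").sum()),
            "localization_pass": int((tab["localization_status"] == "pass").sum()),
            "ranked": list(prior.ranked.index),
        }
    return PipelineResult(
        target=target, comparator=comparator, selectivity=sel,
        prioritization=prior, counts=counts,
    )


def top_k(means: pd.DataFrame, fraction: str, proteins: set[str] | None = None, k: int = 10) -> list[str]:
    """Top-k protein IDs by mean peak area in one fraction, ties lexicographic."""
    if k < 1:
        raise ValueError("k must be >= 1")
    col = f"mean_{quant_io.normalize_fraction(fraction)}"
    sub = means if proteins is None else means.loc[means.index.intersection(sorted(proteins))]
    if k > len(sub):
        warnings.warn(f"k={k} exceeds table size {len(sub)}; returning the full table")
    order = sub.reset_index().sort_values(
        by=[col, "protein_id"], ascending=[False, True]
    )["protein_id"]
    return list(order.head(k))


def union_count(list_a, list_b) -> int:
    return len(set(list_a) | set(list_b))


def write_outputs(result: PipelineResult, out_dir) -> None:
    """Write every stage table plus the counts JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for line in (result.target, result.comparator):
        surface_tab = line.surface.table.copy()
        surface_tab["threshold"] = line.surface.threshold
        surface_tab.to_csv(out / f"surface_{line.cell_line}.tsv", sep="\t")
        line.endocytosis.table.to_csv(out / f"endocytic_{line.cell_line}.tsv", sep="\t")
        line.means.to_csv(out / f"means_{line.cell_line}.tsv", sep="\t")
    result.selectivity.table.to_csv(out / "selectivity.tsv", sep="\t")
    if result.prioritization is not None:
        result.prioritization.table.to_csv(out / "prioritization.tsv", sep="\t")
        (out / "prioritization_audit.json").write_text(
            json.dumps(result.prioritization.audit, indent=2, sort_keys=True) + "\n"
        )
    (out / "counts.json").write_text(
        json.dumps(result.counts, indent=2, sort_keys=True) + "\n"
    )
    (out / "run_log.txt").write_text(
        f"endosurf {endosurf.__version__}\n"
        + json.dumps({"counts": result.counts}, indent=2, sort_keys=True)
        + "\n"
    )
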