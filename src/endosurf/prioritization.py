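"""Database-driven prioritization of selective endocytic candidates.

The selectivity stage yields candidates from one pair of cell lines; whether a
candidate is worth pursuing as a brain-delivery target also depends on (i)
whether its transcript is actually expressed in brain endothelial cells
(RNA-seq FPKM), (ii) whether the protein is detected in brain microvessel
endothelium in an immunohistochemistry atlas, and (iii) how broadly it is
expressed in peripheral tissues — a narrowly distributed protein gives less
off-target uptake.  The filter is staged: expression first (FPKM strictly
above the threshold, default 5), then atlas localization; survivors are ranked
by peripheral tissue breadth ascending, FPKM descending, protein_id as the
final tie-break.  Candidates missing from a database are kept in the audit
with an ``unknown`` status rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

EXPRESSION_THRESHOLD = 5.0
BRAIN_TISSUE = "brain_microvessel"


@dataclass
class PrioritizationResult:
    """Ranked records plus the per-stage audit of removals."""

    table: pd.DataFrame  # one row per candidate, ranked rows first
    audit: dict[str, list[str]]

    @property
    def ranked(self) -> pd.DataFrame:
        return self.table[self.table["final_rank"] > 0].sort_values("final_rank")


def prioritize(
    candidates: set[str] | list[str],
    fpkm: pd.Series,
    atlas: pd.DataFrame,
    expression_threshold: float = EXPRESSION_THRESHOLD,
) -> PrioritizationResult:
    """Staged expression → localization filter and tissue-breadth ranking.

    ``fpkm`` is a protein_id-indexed Series; ``atlas`` has columns protein_id,
    tissue, detection_level with brain rows under tissue ``brain_microvessel``.
    """
    if len(fpkm) == 0:
        raise ValueError("empty fpkm table")
    if fpkm.index.duplicated().any():
        raise ValueError("duplicated protein_id in fpkm table")
    if atlas.duplicated(subset=["protein_id", "tissue"]).any():
        raise ValueError("duplicated (protein_id, tissue) in atlas table")
    candidates = sorted(set(candidates))
    if not candidates:
        raise ValueError("candidate set is empty")

    detected = atlas[atlas["detection_level"] != "not_detected"]
    brain_detected = set(detected.loc[detected["tissue"] == BRAIN_TISSUE, "protein_id"])
    atlas_proteins = set(atlas["protein_id"])
    breadth = (
        detected[detected["tissue"] != BRAIN_TISSUE]
        .groupby("protein_id")["tissue"]
        .nunique()
    )

    rows = []
    audit: dict[str, list[str]] = {
        "input": list(candidates),
        "expression_unknown": [],
        "expression_failed": [],
        "localization_unknown": [],
        "localization_failed": [],
        "ranked": [],
    }
    for pid in candidates:
        rec = {
            "protein_id": pid,
            "fpkm": float(fpkm[pid]) if pid in fpkm.index else float("nan"),
            "expression_status": "unknown",
            "localization_status": "unknown",
            "atlas_detected_in_brain_microvessel": pid in brain_detected,
            "tissue_breadth": int(breadth.get(pid, 0)),
            "final_rank": 0,
        }
        if pid not in fpkm.index:
            audit["expression_unknown"].append(pid)
        elif rec["fpkm"] > expression_threshold:
            rec["expression_status"] = "pass"
        else:
            rec["expression_status"] = "fail"
            audit["expression_failed"].append(pid)
        if rec["expression_status"] == "pass":
            if pid not in atlas_proteins:
                audit["localization_unknown"].append(pid)
            elif pid in brain_detected:
                rec["localization_status"] = "pass"
            else:
                rec["localization_status"] = "fail"
                audit["localization_failed"].append(pid)
        rows.append(rec)

    table = pd.DataFrame(rows).set_index("protein_id")
    survivors = table[
        (table["expression_status"] == "pass") & (table["localization_status"] == "pass")
    ]
    order = survivors.reset_index().sort_values(
        by=["tissue_breadth", "fpkm", "protein_id"],
        ascending=[True, False, True],
    )["protein_id"]
    for rank, pid in enumerate(order, start=1):
        table.loc[pid, "final_rank"] = rank
        audit["ranked"].append(pid)
    return PrioritizationResult(table=table, audit=audit)
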