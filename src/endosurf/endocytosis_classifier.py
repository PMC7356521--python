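"""Endocytosis calling from stripping efficacy and internalization ratios.

MESNA reduces the biotinylation reagent's disulfide and removes biotin from
protein still exposed at the cell surface; protein endocytosed during the warm
incubation is protected.  Three statistics per protein:

* stripping efficacy ``E = 100·(1 − strip/surface)`` — how completely MESNA
  removes the surface signal (%); not clamped, so poorly stripped proteins can
  show E < 0.
* internalization efficiency ``eta = internalization/surface`` — the fraction
  of the surface pool recovered after warming + stripping.  eta > 1 means the
  internalized signal exceeds the labeled surface pool (recycling or ongoing
  delivery) and the efficiency is flagged as overestimated.
* ``R_is = internalization/stripping`` — internalized signal over the
  strip-failure background; the internalized pool must rise clearly above what
  stripping leaves behind.

Two acceptance routes (mutually exclusive by the eta split):

* criterion A: eta ≤ 2.0, E > 85 %, R_is > 2.0 — efficiently stripped proteins
  with a moderate internalized pool.
* criterion B: eta > 2.0, E > 50 %, R_is > 2.0 — strongly accumulating
  proteins, tolerated at lower stripping efficacy.

A protein is called endocytic when it meets either criterion, has a nonzero
internalization signal, and was already called ``cell_surface``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .surface_classifier import SurfaceCallResult

ETA_SPLIT = 2.0
E_MIN_A = 85.0
E_MIN_B = 50.0
RIS_MIN = 2.0


def stripping_efficacy(surface_mean: float, stripping_mean: float) -> float:
    """E (%) = 100·(1 − strip/surface); NaN when the surface pool is empty."""
    if surface_mean < 0 or stripping_mean < 0:
        raise ValueError("peak-area means must be >= 0")
    if surface_mean == 0:
        return math.nan
    return (1.0 - stripping_mean / surface_mean) * 100.0


def _ratio(num: float, den: float) -> float:
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def evaluate_criteria(E: float, eta: float, R_is: float) -> str:
    """Apply the A/B acceptance routes to one protein's statistics.

    Inequalities are strict exactly as specified (>85, >50, >2.0, with the
    eta tie at 2.0 going to the A branch); NaN statistics fail everything.
    """
    if any(math.isnan(v) for v in (E, eta, R_is)):
        return "none"
    if eta <= ETA_SPLIT and E > E_MIN_A and R_is > RIS_MIN:
        return "A"
    if eta > ETA_SPLIT and E > E_MIN_B and R_is > RIS_MIN:
        return "B"
    return "none"


@dataclass
class EndocytosisCallResult:
    """Per-protein E, eta, R_is, criterion and endocytic flag for one cell line.

    ``table`` columns: E, R_is, eta, criterion, endocytic, overestimated.
    """

    cell_line: str
    table: pd.DataFrame

    @property
    def endocytic_proteins(self) -> set[str]:
        return set(self.table.index[self.table["endocytic"]])

    def criterion_counts(self) -> dict[str, int]:
        endo = self.table[self.table["endocytic"]]
        return {
            "A": int((endo["criterion"] == "A").sum()),
            "B": int((endo["criterion"] == "B").sum()),
        }

    @classmethod
    def from_sets(
        cls,
        cell_line: str,
        universe,
        endocytic_ids,
        criterion_b_ids=(),
    ) -> "EndocytosisCallResult":
        """Build a result from externally known endocytic membership.

        For set-algebra use with published lists, where the underlying peak
        areas are unavailable: statistics are NaN, only membership and the
        A/B split are carried.
        """
        endocytic_ids, b_ids = set(endocytic_ids), set(criterion_b_ids)
        if not b_ids <= endocytic_ids:
            raise ValueError("criterion_b_ids must be a subset of endocytic_ids")
        rows = []
        for pid in universe:
            endo = pid in endocytic_ids
            crit = "none" if not endo else ("B" if pid in b_ids else "A")
            rows.append({
                "protein_id": pid, "E": math.nan, "R_is": math.nan, "eta": math.nan,
                "criterion": crit, "endocytic": endo, "overestimated": False,
            })
        table = pd.DataFrame(rows).set_index("protein_id")
        return cls(cell_line=cell_line, table=table)


def call_endocytic(means: pd.DataFrame, surface_calls: SurfaceCallResult) -> EndocytosisCallResult:
    """Call endocytic cell-surface proteins from aggregated fraction means.

    Statistics are computed for every protein; the criteria only decide the
    call for proteins in the ``cell_surface`` class (candidates are drawn from
    the biotinylated cell-surface proteins), and a zero internalization mean
    can never be endocytic.
    """
    rows = []
    cls = surface_calls.table["surface_class"]
    for pid, row in means.iterrows():
        surf, strip, internal = row["mean_surface"], row["mean_stripping"], row["mean_internalization"]
        E = stripping_efficacy(surf, strip)
        eta = _ratio(internal, surf)
        r_is = _ratio(internal, strip)
        is_surface = cls.get(pid, "undefined") == "cell_surface"
        crit = evaluate_criteria(E, eta, r_is) if is_surface else "none"
        endocytic = crit != "none" and internal > 0 and is_surface
        rows.append(
            {
                "protein_id": pid,
                "E": E,
                "R_is": r_is,
                "eta": eta,
                "criterion": crit,
                "endocytic": endocytic,
                "overestimated": bool(endocytic and eta > 1.0),
            }
        )
    table = pd.DataFrame(rows).set_index("protein_id")
    return EndocytosisCallResult(cell_line=surface_calls.cell_line, table=table)
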