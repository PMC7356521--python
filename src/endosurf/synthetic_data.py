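"""Generative model of the surface-biotinylation internalization experiment.

Produces per-replicate peak-area tables for a target (brain-microvascular-like)
and a comparator (peripheral-like) endothelial cell line, together with matched
GO-style annotations, a transcript-abundance (FPKM) table, an atlas-style
tissue-localization table, a plasma-membrane reference list and the ground
truth — everything the downstream pipeline consumes, with known labels.

Four ground-truth classes:

* ``surface_endocytic`` — biotinylated surface proteins that internalize;
  a subset accumulates internalized signal beyond the labeled pool
  (``internal_ratio`` > 1, the overestimation route).
* ``surface_static``   — biotinylated surface proteins that stay put.
* ``cytosolic``        — cytosolic contaminants of the pulldown; modest
  surface/control enrichment (drawn in (2, 4]) that the threshold-derivation
  step must learn to exclude.
* ``nonspecific_binder`` — bead background, surface/control ratio ≤ 2.

Expected (noise-free) fraction means for a surface-class protein with
abundance a, line multiplier m, stripping efficiency s and internalized ratio
i:  control = eps·a·m, surface = a·m, stripping = a·m·(1−s),
internalization = a·m·i.  Contaminant classes put r·control in the surface
fraction, are untouched by MESNA (stripping = surface, the reagent only
removes biotin) and carry internalization ≈ surface, so they fail the
internalization-over-stripping requirement whatever the surface call says.
Each expected mean is multiplied by i.i.d. multiplicative log-normal noise per
replicate (unit mean, CV as configured).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quant_io import AnnotationSet, QuantTable, ReferenceList

PERIPHERAL_TISSUES = (
    "lung", "liver", "kidney", "heart", "spleen", "pancreas",
    "intestine", "skin", "muscle", "testis", "placenta", "adipose",
)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated two-line experiment.

    Counts give the class mix per protein universe (default 500 proteins);
    ``noise_cv`` is the multiplicative log-normal coefficient of variation per
    replicate; ``background_level`` (eps) is the bead background relative to
    abundance; ``annotation_noise`` is the fraction of proteins whose GO label
    set is class-discordant.
    """

    seed: int
    n_surface_endocytic: int = 120
    n_surface_static: int = 180
    n_cytosolic: int = 120
    n_nonspecific: int = 80
    noise_cv: float = 0.20
    background_level: float = 0.02
    n_replicates: int = 3
    annotation_noise: float = 0.05
    frac_accumulating: float = 0.10       # endocytic proteins on the eta>2 route
    p_target_only: float = 0.25           # surface proteins absent from the comparator
    p_comparator_only: float = 0.10       # surface proteins absent from the target
    p_high_fold: float = 0.15             # shared endocytic proteins with fold change > 4
    p_comparator_static: float = 0.15     # shared endocytic proteins inert in the comparator
    p_control_missing: float = 0.25       # surface proteins invisible in the control
    reference_coverage: float = 0.70      # chance a true surface protein is in the PM list
    cell_line_target: str = "hCMEC_D3"
    cell_line_comparator: str = "HUVEC"
    n_funnel_expressed: int = 7           # planted FPKM>5 among selective candidates
    n_funnel_brain: int = 5               # ... of which atlas brain-detected
    n_funnel_narrow: int = 2              # ... of which narrowly distributed

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        for name in ("n_surface_endocytic", "n_surface_static", "n_cytosolic",
                     "n_nonspecific", "n_replicates"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 <= self.annotation_noise <= 1:
            raise ValueError("annotation_noise must be in [0, 1]")
        if self.background_level <= 0:
            raise ValueError("background_level must be > 0")


@dataclass
class ProteinTruth:
    protein_id: str
    truth_class: str
    abundance: float
    strip_eff: float          # s in [0, 1]
    internal_ratio: float     # i >= 0; > 1 models apparent overestimation
    internal_ratio_comparator: float  # comparator-line i (near 0: internalizes only in target)
    mult_target: float        # per-line expression multipliers (0 = absent)
    mult_comparator: float
    control_ratio: float      # surface/control enrichment for contaminant classes
    in_reference: bool
    fpkm: float
    atlas_brain_detected: bool
    tissue_breadth: int


@dataclass
class SimulationResult:
    quant_target: QuantTable
    quant_comparator: QuantTable
    annotations: AnnotationSet
    fpkm: pd.Series
    atlas: pd.DataFrame
    reference: ReferenceList
    truth: list[ProteinTruth] = field(default_factory=list)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.truth]).set_index("protein_id")


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


def _draw_truths(cfg: SimulationConfig, rng: np.random.Generator) -> list[ProteinTruth]:
    truths: list[ProteinTruth] = []
    classes = (
        ["surface_endocytic"] * cfg.n_surface_endocytic
        + ["surface_static"] * cfg.n_surface_static
        + ["cytosolic"] * cfg.n_cytosolic
        + ["nonspecific_binder"] * cfg.n_nonspecific
    )
    width = len(str(max(len(classes), 1)))
    for idx, cls in enumerate(classes):
        pid = f"P{idx + 1:0{width}d}"
        abundance = float(rng.lognormal(mean=np.log(1e5), sigma=1.0))
        control_ratio = 0.0
        if cls == "surface_endocytic":
            if rng.random() < cfg.frac_accumulating:
                # accumulating route: internalized signal outruns the labeled pool
                s = float(rng.uniform(0.75, 0.95))
                i = float(rng.uniform(3.0, 6.0))
            else:
                s = float(rng.uniform(0.93, 0.99))
                i = float(rng.uniform(0.30, 0.80))
        elif cls == "surface_static":
            s = float(rng.uniform(0.88, 0.99))
            i = float(rng.uniform(0.0, 0.01))
        elif cls == "cytosolic":
            s, i = 0.0, float(rng.uniform(0.3, 1.2))
            control_ratio = float(rng.uniform(2.2, 4.0))
        else:  # nonspecific_binder
            s, i = 0.0, float(rng.uniform(0.3, 1.2))
            control_ratio = float(rng.uniform(0.5, 2.0))

        i_comp = i
        if cls in ("surface_endocytic", "surface_static"):
            u = rng.random()
            if u < cfg.p_target_only:
                m_t, m_c = 1.0, 0.0
            elif u < cfg.p_target_only + cfg.p_comparator_only:
                m_t, m_c = 0.0, 1.0
            else:
                m_t = 1.0
                if cls == "surface_endocytic" and rng.random() < cfg.p_high_fold:
                    m_c = 1.0 / float(rng.uniform(6.0, 12.0))
                else:
                    m_c = float(np.exp(rng.normal(0.0, 0.3)))
                # some shared surface proteins internalize only in the target
                # line (surface-expressed everywhere, endocytosed at the barrier)
                if cls == "surface_endocytic" and rng.random() < cfg.p_comparator_static:
                    i_comp = float(rng.uniform(0.0, 0.01))
            in_ref = bool(rng.random() < cfg.reference_coverage)
        else:
            # contamination is universal: present in both lines
            m_t = float(np.exp(rng.normal(0.0, 0.3)))
            m_c = float(np.exp(rng.normal(0.0, 0.3)))
            in_ref = bool(rng.random() < 0.02)

        truths.append(ProteinTruth(
            protein_id=pid, truth_class=cls, abundance=abundance,
            strip_eff=s, internal_ratio=i, internal_ratio_comparator=i_comp,
            mult_target=m_t, mult_comparator=m_c,
            control_ratio=control_ratio, in_reference=in_ref,
            fpkm=0.0, atlas_brain_detected=False, tissue_breadth=0,
        ))
    return truths


def _expected_means(t: ProteinTruth, line_key: str, eps_p: float, control_seen: bool) -> dict[str, float]:
    """Noise-free expected mean per fraction for one protein in one line."""
    mult = t.mult_target if line_key == "target" else t.mult_comparator
    i = t.internal_ratio if line_key == "target" else t.internal_ratio_comparator
    if mult == 0:
        return {}
    if t.truth_class in ("surface_endocytic", "surface_static"):
        surface = t.abundance * mult
        return {
            "control": eps_p * t.abundance * mult if control_seen else 0.0,
            "surface": surface,
            "stripping": surface * (1.0 - t.strip_eff),
            "internalization": surface * i,
        }
    control = eps_p * t.abundance * mult
    surface = control * t.control_ratio
    return {
        "control": control,
        "surface": surface,
        "stripping": surface,                   # MESNA leaves non-biotinylated binders alone
        "internalization": surface * i,
    }


def _assign_databases(cfg: SimulationConfig, rng: np.random.Generator,
                      truths: list[ProteinTruth]) -> None:
    """Plant the FPKM / atlas funnel among the target-selective endocytic proteins."""
    selective = [
        t for t in truths
        if t.truth_class == "surface_endocytic" and t.in_reference and t.mult_target > 0
        and (
            t.mult_comparator == 0                                      # absent from comparator
            or t.internal_ratio_comparator < 0.02 <= t.internal_ratio   # inert in comparator
            or t.mult_target / max(t.mult_comparator, 1e-12) > 4        # high cross-line fold
        )
    ]
    funnel = selective[: cfg.n_funnel_expressed]
    brain = funnel[: cfg.n_funnel_brain]
    narrow = brain[: cfg.n_funnel_narrow]
    funnel_ids = {t.protein_id for t in funnel}
    brain_ids = {t.protein_id for t in brain}
    narrow_ids = {t.protein_id for t in narrow}
    for t in truths:
        if t.protein_id in funnel_ids:
            t.fpkm = float(rng.uniform(8.0, 40.0))
            t.atlas_brain_detected = t.protein_id in brain_ids
            if t.protein_id in narrow_ids:
                t.tissue_breadth = int(rng.integers(1, 3))
            elif t.atlas_brain_detected:
                t.tissue_breadth = int(rng.integers(6, 11))
            else:
                t.tissue_breadth = int(rng.integers(3, 9))
        else:
            # background: median FPKM around 1, mostly below the expression cut
            t.fpkm = float(rng.lognormal(mean=0.0, sigma=0.8))
            t.atlas_brain_detected = bool(rng.random() < 0.3)
            t.tissue_breadth = int(rng.integers(0, len(PERIPHERAL_TISSUES) + 1))


def _annotation_terms(cfg: SimulationConfig, rng: np.random.Generator,
                      t: ProteinTruth) -> set[str]:
    """Class-concordant GO labels with directed discordance.

    Discordant surface proteins lose their annotation (incomplete databases);
    discordant contaminants swap to a surface label.  Spurious "Cytoplasm"
    labels land only on low-enrichment proteins, matching the observed pattern
    the cytosol-exclusion threshold exploits.
    """
    discordant = rng.random() < cfg.annotation_noise
    if t.truth_class in ("surface_endocytic", "surface_static"):
        return set() if discordant else {"Plasma membrane", "Cell surface"}
    if t.truth_class == "cytosolic":
        return {"Plasma membrane"} if discordant else {"Cytoplasm"}
    # nonspecific binders: a mixed bag, half of them cytosol-annotated
    if discordant:
        return {"Cell surface"}
    return {"Cytoplasm"} if rng.random() < 0.5 else set()


def simulate_experiment(config: SimulationConfig) -> SimulationResult:
    """Run the generative model; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    truths = _draw_truths(config, rng)
    _assign_databases(config, rng, truths)

    annotations = AnnotationSet()
    for t in truths:
        terms = _annotation_terms(config, rng, t)
        if terms:
            annotations.terms[t.protein_id] = {s.lower() for s in terms}

    # per-protein bead-background level; per-line control visibility for
    # surface proteins (a protein can fall below detection in the no-biotin lane)
    eps = {t.protein_id: config.background_level * float(np.exp(rng.normal(0.0, 0.5)))
           for t in truths}
    control_seen = {
        t.protein_id: {
            "target": not (t.truth_class.startswith("surface")
                           and rng.random() < config.p_control_missing),
            "comparator": not (t.truth_class.startswith("surface")
                               and rng.random() < config.p_control_missing),
        }
        for t in truths
    }

    def build_line(line_key: str, cell_line: str) -> QuantTable:
        rows = []
        for t in truths:
            means = _expected_means(t, line_key, eps[t.protein_id], control_seen[t.protein_id][line_key])
            for fraction, mu in means.items():
                if mu <= 0:
                    continue
                noise = _lognormal_noise(rng, config.noise_cv, config.n_replicates)
                for rep in range(1, config.n_replicates + 1):
                    rows.append({
                        "protein_id": t.protein_id,
                        "fraction": fraction,
                        "replicate": rep,
                        "peak_area": mu * noise[rep - 1],
                    })
        df = pd.DataFrame(rows, columns=["protein_id", "fraction", "replicate", "peak_area"])
        return QuantTable(cell_line=cell_line, data=df, max_replicates=config.n_replicates)

    quant_target = build_line("target", config.cell_line_target)
    quant_comparator = build_line("comparator", config.cell_line_comparator)

    fpkm = pd.Series({t.protein_id: t.fpkm for t in truths}, name="fpkm")
    fpkm.index.name = "protein_id"

    atlas_rows = []
    for t in truths:
        tissues = list(rng.permutation(len(PERIPHERAL_TISSUES))[: t.tissue_breadth])
        detected = {PERIPHERAL_TISSUES[i] for i in tissues}
        atlas_rows.append({
            "protein_id": t.protein_id, "tissue": "brain_microvessel",
            "detection_level": "medium" if t.atlas_brain_detected else "not_detected",
        })
        for tissue in PERIPHERAL_TISSUES:
            atlas_rows.append({
                "protein_id": t.protein_id, "tissue": tissue,
                "detection_level": str(rng.choice(["low", "medium", "high"])) if tissue in detected
                else "not_detected",
            })
    atlas = pd.DataFrame(atlas_rows, columns=["protein_id", "tissue", "detection_level"])

    reference = ReferenceList(
        name="BBB_PM", members={t.protein_id for t in truths if t.in_reference}
    )
    return SimulationResult(
        quant_target=quant_target, quant_comparator=quant_comparator,
        annotations=annotations, fpkm=fpkm, atlas=atlas,
        reference=reference, truth=truths,
    )
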