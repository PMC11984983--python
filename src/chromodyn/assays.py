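"""Bench-assay calculators and image-derived classifiers.

Small, exactly specified quantifications used around the imaging pipeline:
beta-galactosidase Miller units for the centromeric transcriptional
read-through assay, centromeric-plasmid mitotic stability, chromosome-loss
frequency and fold change, spindle-pole-body (SPB) inheritance and Kar9
asymmetry classification, spindle geometry (length, alignment angle,
budding index) and study-count filtering of BioGRID interaction networks.

Confidence intervals are additions of this package (the original
quantifications report dispersion from replicates) and are labelled as
such in every output that carries one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.proportion import confint_proportions_2indep, proportion_confint

__all__ = [
    "MillerInput",
    "StabilityCounts",
    "InteractionEdge",
    "SpindleGeometry",
    "miller_units",
    "mitotic_stability",
    "chromosome_loss_frequency",
    "fold_change",
    "loss_fold_change",
    "classify_spb_inheritance",
    "classify_kar9_distribution",
    "spindle_geometry",
    "filter_interaction_network",
    "read_biogrid",
]


@dataclass(frozen=True)
class MillerInput:
    """Inputs to the beta-galactosidase activity calculation.

    Absorbances are dimensionless; ``t_min`` is the reaction time in
    minutes and ``v_ml`` the culture volume assayed in millilitres.
    """

    od420: float
    od550: float
    od610: float
    t_min: float
    v_ml: float

    def __post_init__(self) -> None:
        if self.t_min <= 0:
            raise ValueError("reaction time must be positive")
        if self.v_ml <= 0:
            raise ValueError("culture volume must be positive")
        if self.od610 <= 0:
            raise ValueError("OD610 (cell density) must be positive")


def miller_units(inp: MillerInput) -> float:
    """Miller units = 1000 * (OD420 - 1.75 * OD550) / (t * v * OD610).

    The 1.75*OD550 term subtracts light scattering by cell debris from the
    o-nitrophenol absorbance. A negative result (blank-dominated reaction)
    is allowed but flagged with a warning.
    """
    units = 1000.0 * (inp.od420 - 1.75 * inp.od550) / (inp.t_min * inp.v_ml * inp.od610)
    if units < 0:
        warnings.warn("negative Miller units: scattering term exceeds OD420 (blank-dominated)")
    return units


@dataclass(frozen=True)
class StabilityCounts:
    """Colony counts for the centromeric-plasmid stability assay."""

    n_selective: int
    n_nonselective: int

    def __post_init__(self) -> None:
        if self.n_selective < 0 or self.n_nonselective < 0:
            raise ValueError("counts must be non-negative")
        if self.n_selective > self.n_nonselective:
            warnings.warn("more colonies on selective than non-selective medium")


@dataclass(frozen=True)
class StabilityResult:
    per_100: float
    ci_low: float  # Clopper-Pearson 95% interval, per-100 scale
    ci_high: float
    ci_note: str = "95% Clopper-Pearson interval (addition of this package)"


def mitotic_stability(counts: StabilityCounts) -> StabilityResult:
    """Colonies on selective medium per 100 on non-selective medium."""
    if counts.n_nonselective == 0:
        raise ValueError("zero colonies on non-selective medium")
    per100 = 100.0 * counts.n_selective / counts.n_nonselective
    lo, hi = proportion_confint(counts.n_selective, counts.n_nonselective, alpha=0.05, method="beta")
    return StabilityResult(per_100=per100, ci_low=100.0 * lo, ci_high=100.0 * hi)


def chromosome_loss_frequency(n_loss_first_division: int, n_total: int) -> float:
    """Fraction of colonies showing chromosome loss at the first division."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_loss_first_division < 0 or n_loss_first_division > n_total:
        raise ValueError("n_loss_first_division must be in [0, n_total]")
    return n_loss_first_division / n_total


def fold_change(freq_mutant: float, freq_wt: float) -> float:
    """Ratio of loss frequencies. Undefined (nan, with warning) when the
    reference frequency is zero."""
    if freq_wt == 0:
        warnings.warn("reference frequency is zero; fold change undefined")
        return float("nan")
    return freq_mutant / freq_wt


@dataclass(frozen=True)
class FoldChangeResult:
    fold: float
    ci_low: float
    ci_high: float
    ci_note: str = "95% score (Koopman) interval for the frequency ratio (addition of this package)"


def loss_fold_change(
    n_loss_mutant: int, n_total_mutant: int, n_loss_wt: int, n_total_wt: int
) -> FoldChangeResult:
    """Fold change in loss frequency with a score-method confidence interval."""
    f_mut = chromosome_loss_frequency(n_loss_mutant, n_total_mutant)
    f_wt = chromosome_loss_frequency(n_loss_wt, n_total_wt)
    fold = fold_change(f_mut, f_wt)
    lo, hi = confint_proportions_2indep(
        n_loss_mutant, n_total_mutant, n_loss_wt, n_total_wt, compare="ratio", method="score"
    )
    return FoldChangeResult(fold=fold, ci_low=float(lo), ci_high=float(hi))


def classify_spb_inheritance(
    intensity_daughter_cell_spb: float,
    intensity_mother_cell_spb: float,
    asymmetry_threshold: float = 1.5,
) -> str:
    """Classify SPB inheritance as proper / reversed / symmetric.

    The old SPB carries the brighter (slow-maturing) fluorophore signal; if
    the brighter SPB sits in the daughter cell the inheritance is proper,
    in the mother cell reversed. If the two intensities differ by less than
    ``asymmetry_threshold``-fold the SPBs are indistinguishable: symmetric.
    """
    d, m = intensity_daughter_cell_spb, intensity_mother_cell_spb
    if d < 0 or m < 0:
        raise ValueError("intensities must be non-negative")
    if d == 0 and m == 0:
        warnings.warn("both SPB intensities are zero; classifying symmetric")
        return "symmetric"
    lo, hi = min(d, m), max(d, m)
    ratio = float("inf") if lo == 0 else hi / lo
    if ratio < asymmetry_threshold:
        return "symmetric"
    return "proper" if d > m else "reversed"


def classify_kar9_distribution(
    i_spb1: float,
    i_spb2: float,
    strong_threshold: float = 5.0,
    weak_threshold: float = 1.5,
    detection_limit: float = 1e-9,
) -> str:
    """Classify Kar9 signal over the two SPBs.

    Signal essentially on one SPB only -> strong asymmetry; unequal on both
    -> weak asymmetry; equal -> symmetry. The dimmer intensity is floored
    at ``detection_limit`` so a zero signal maps to strong asymmetry.
    """
    if i_spb1 < 0 or i_spb2 < 0:
        raise ValueError("intensities must be non-negative")
    lo, hi = min(i_spb1, i_spb2), max(i_spb1, i_spb2)
    if hi == 0:
        return "symmetry"
    ratio = hi / max(lo, detection_limit)
    if ratio >= strong_threshold:
        return "strong_asymmetry"
    if ratio >= weak_threshold:
        return "weak_asymmetry"
    return "symmetry"


@dataclass(frozen=True)
class SpindleGeometry:
    spindle_length_um: float
    alignment_angle_deg: float  # in [0, 90]
    budding_index: float
    is_metaphase_length: bool  # spindle length in the 1.5-2.0 um band
    is_large_budded: bool  # budding index > 0.6


def spindle_geometry(
    spb1: tuple[float, float],
    spb2: tuple[float, float],
    mother_center: tuple[float, float],
    bud_center: tuple[float, float],
    mother_diameter_um: float,
    daughter_diameter_um: float,
) -> SpindleGeometry:
    """Spindle length, spindle-to-polarity-axis angle and budding index.

    The alignment angle is the smaller of the two angles between the
    spindle vector and the mother-bud axis, i.e., in [0, 90] degrees.
    """
    v = np.subtract(spb2, spb1, dtype=float)
    a = np.subtract(bud_center, mother_center, dtype=float)
    nv, na = np.linalg.norm(v), np.linalg.norm(a)
    if nv == 0:
        raise ValueError("coincident SPB positions")
    if na == 0:
        raise ValueError("coincident mother and bud centers")
    if mother_diameter_um <= 0:
        raise ValueError("mother diameter must be positive")
    cosang = abs(float(np.dot(v, a)) / (nv * na))
    angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
    length = float(nv)
    bi = daughter_diameter_um / mother_diameter_um
    return SpindleGeometry(
        spindle_length_um=length,
        alignment_angle_deg=angle,
        budding_index=bi,
        is_metaphase_length=1.5 <= length <= 2.0,
        is_large_budded=bi > 0.6,
    )


@dataclass(frozen=True)
class InteractionEdge:
    """One deduplicated, undirected protein-protein interaction.

    ``n_studies`` is the number of distinct publications supporting the
    pair (physical and genetic evidence pooled unless filtered upstream).
    """

    protein_a: str
    protein_b: str
    n_studies: int
    interaction_type: str = "physical"

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be at least 1")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.protein_a, self.protein_b))


def read_biogrid(path, physical_only: bool = False) -> list[InteractionEdge]:
    """Read a BioGRID TAB export into deduplicated undirected edges.

    Distinct publication identifiers are pooled per unordered gene pair;
    physical and genetic evidence are pooled unless ``physical_only``.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    a = cols.get("official symbol interactor a")
    b = cols.get("official symbol interactor b")
    pub = cols.get("publication source") or cols.get("pubmed id")
    etype = cols.get("experimental system type")
    if a is None or b is None or pub is None:
        raise ValueError("not a recognizable BioGRID TAB export")
    if physical_only and etype is not None:
        df = df[df[etype].str.lower() == "physical"]
    pooled: dict[frozenset, tuple[set, set]] = {}
    for _, row in df.iterrows():
        key = frozenset((str(row[a]).upper(), str(row[b]).upper()))
        if len(key) < 2:
            continue  # self-interaction
        pubs, types = pooled.setdefault(key, (set(), set()))
        pubs.add(str(row[pub]))
        if etype is not None:
            types.add(str(row[etype]).lower())
    edges = []
    for key, (pubs, types) in pooled.items():
        pa, pb = sorted(key)
        edges.append(
            InteractionEdge(
                protein_a=pa,
                protein_b=pb,
                n_studies=len(pubs),
                interaction_type="physical" if types == {"physical"} else ("genetic" if types == {"genetic"} else "mixed"),
            )
        )
    return edges


def filter_interaction_network(
    edges: list[InteractionEdge],
    seeds: list[str],
    min_studies: int = 3,
    hops: int = 2,
) -> nx.Graph:
    """Retain well-corroborated interactions around seed proteins.

    Edges supported by fewer than ``min_studies`` distinct publications are
    dropped; the returned graph is the subgraph of the retained network
    induced on the seeds plus everything reachable within ``hops`` steps.
    With ``hops = 0`` the result contains the seed nodes and no edges.
    Seeds absent from the retained network stay as isolated nodes.
    """
    seeds = [s.upper() for s in seeds]
    g = nx.Graph()
    for e in edges:
        if e.n_studies >= min_studies:
            g.add_edge(
                e.protein_a.upper(), e.protein_b.upper(), n_studies=e.n_studies, interaction_type=e.interaction_type
            )
    keep: set[str] = set(seeds)
    frontier = [s for s in seeds if s in g]
    for s in seeds:
        if s not in g:
            warnings.warn(f"seed {s} absent from the retained network")
    for _ in range(hops):
        nxt = []
        for node in frontier:
            for nb in g.neighbors(node):
                if nb not in keep:
                    keep.add(nb)
                    nxt.append(nb)
        frontier = nxt
    if hops == 0:
        out = nx.Graph()
        out.add_nodes_from(seeds)
        return out
    out = g.subgraph(keep & set(g.nodes)).copy()
    out.add_nodes_from(seeds)  # keep absent seeds visible as isolates
    return out
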