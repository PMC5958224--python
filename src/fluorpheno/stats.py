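"""Treatment comparison, trait correlation network, and the MDA assay.

Treatment comparison is a per-parameter two-group Welch test with the
conventional star coding (* P<0.05, ** P<0.01, *** P<0.001); the trait
network keeps Pearson correlations passing both |r| > 0.40 and P < 0.01
(strict inequalities); MDA content is computed from the TBA-assay
absorbance difference with an extinction coefficient of 155 mM^-1 cm^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SignificanceResult",
    "CorrelationNetwork",
    "MdaAssay",
    "stars",
    "compare_treatments",
    "correlation_network",
    "mda_content",
    "network_to_edgelist",
    "save_network",
]


@dataclass
class SignificanceResult:
    parameter: str
    p_value: float
    stars: str
    statistic: float = float("nan")
    day: int | None = None
    genotype: str | None = None
    group_means: tuple[float, float] | None = None


@dataclass
class CorrelationNetwork:
    graph: nx.Graph
    r_min: float = 0.40
    p_max: float = 0.01

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def edges(self):
        return [
            (u, v, d["r"], d["p_value"]) for u, v, d in self.graph.edges(data=True)
        ]


@dataclass
class MdaAssay:
    """Inputs of the thiobarbituric-acid MDA determination."""

    A532: float
    A600: float
    epsilon: float = 155.0      # mM^-1 cm^-1
    path_cm: float = 1.0
    assay_volume_mL: float = 2.0
    extract_volume_mL: float = 5.0
    aliquot_mL: float = 1.0
    fresh_weight_g: float = 0.1

    def __post_init__(self):
        for name in ("epsilon", "path_cm", "assay_volume_mL", "extract_volume_mL",
                     "aliquot_mL", "fresh_weight_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def stars(p: float) -> str:
    """Star coding with strict thresholds: *** p<0.001, ** p<0.01, * p<0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_treatments(
    table: pd.DataFrame,
    parameter: str,
    group_col: str = "label",
    day: int | None = None,
    genotype: str | None = None,
) -> SignificanceResult:
    """Two-group comparison of one parameter between treatments.

    Welch's unequal-variance t test (for two groups this plays the role of
    the one-way ANOVA screen). ``day``/``genotype``, when given, filter the
    table on columns of the same name.
    """
    sub = table
    if day is not None and "day" in sub.columns:
        sub = sub[sub["day"] == day]
    if genotype is not None and "genotype" in sub.columns:
        sub = sub[sub["genotype"] == genotype]
    groups = [g[parameter].to_numpy(dtype=float) for _, g in sub.groupby(group_col)]
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {len(groups)}")
    a, b = groups
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if np.var(a) == 0 and np.var(b) == 0:
        # degenerate: no within-group variability
        p = 1.0 if np.mean(a) == np.mean(b) else 0.0
        t = 0.0 if p == 1.0 else float("inf")
    else:
        t, p = sps.ttest_ind(a, b, equal_var=False)
    return SignificanceResult(
        parameter=parameter,
        p_value=float(p),
        stars=stars(float(p)),
        statistic=float(t),
        day=day,
        genotype=genotype,
        group_means=(float(np.mean(a)), float(np.mean(b))),
    )


def correlation_network(
    table: pd.DataFrame,
    trait_subset: list[str] | None = None,
    r_min: float = 0.40,
    p_max: float = 0.01,
    categories: dict[str, str] | None = None,
) -> CorrelationNetwork:
    """Thresholded Pearson correlation network over trait columns.

    Every pair of traits is correlated; an edge is kept iff |r| > r_min
    and p < p_max (both strict). Constant traits are excluded with a
    warning. ``categories`` maps trait name to a category stored as a node
    attribute (kinetic_chl, multicolor, morphological, physiological).
    """
    traits = trait_subset if trait_subset is not None else list(table.columns)
    data = table[traits].apply(pd.to_numeric)
    keep = []
    for name in traits:
        col = data[name].dropna()
        if len(col) >= 3 and np.ptp(col.to_numpy()) > 0:
            keep.append(name)
        else:
            warnings.warn(f"trait {name!r} is constant or too short; excluded", stacklevel=2)
    g = nx.Graph()
    for name in keep:
        g.add_node(name, category=(categories or {}).get(name, "unknown"))
    for i, a in enumerate(keep):
        for b in keep[i + 1:]:
            pair = data[[a, b]].dropna()
            if len(pair) < 3:
                continue
            r, p = sps.pearsonr(pair[a], pair[b])
            if abs(r) > r_min and p < p_max:
                g.add_edge(a, b, r=float(r), p_value=float(p), weight=abs(float(r)))
    return CorrelationNetwork(graph=g, r_min=r_min, p_max=p_max)


def network_to_edgelist(net: CorrelationNetwork) -> pd.DataFrame:
    rows = [
        {"source": u, "target": v, "r": d["r"], "p_value": d["p_value"]}
        for u, v, d in net.graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "r", "p_value"])


def save_network(net: CorrelationNetwork, graphml_path=None, csv_path=None) -> None:
    if graphml_path is not None:
        nx.write_graphml(net.graph, graphml_path)
    if csv_path is not None:
        network_to_edgelist(net).to_csv(csv_path, index=False)


def mda_content(a: MdaAssay) -> float:
    """MDA content in nmol per gram fresh weight.

    Beer-Lambert on the 532-600 nm absorbance difference gives the
    chromophore concentration in mM; scaled by the assay volume, the
    extract/aliquot dilution, and fresh weight.
    """
    delta = a.A532 - a.A600
    if delta < 0:
        raise ValueError("negative chromophore signal (A532 < A600)")
    conc_mM = delta / (a.epsilon * a.path_cm)          # mM = nmol/uL = umol/mL
    nmol_in_assay = conc_mM * a.assay_volume_mL * 1000.0
    nmol_in_extract = nmol_in_assay * (a.extract_volume_mL / a.aliquot_mL)
    return nmol_in_extract / a.fresh_weight_g
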