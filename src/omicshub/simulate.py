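"""Synthetic inputs with planted structure.

Generates the four pipeline inputs — a normalized log2 expression study, an
undirected protein interaction network, MaxQuant-style TAP-MS intensity
tables, and a gene-family annotation — each together with the ground truth
that was planted into it (differentially expressed genes, high-degree hub
nodes, bait-specific interactors), so every downstream stage can be scored
against a known answer.

All randomness in a generator flows from one ``numpy.random.Generator``
seeded by the caller; identical parameters and seed give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .deg import ExpressionStudy, contrast_label
from .enrichment import FamilyAnnotation
from .tap import TapTable

__all__ = [
    "SyntheticDesign",
    "PlantedTruth",
    "generate_expression_study",
    "generate_interaction_network",
    "generate_tap_intensities",
    "generate_family_annotation",
]

# Baseline log2 expression level: Normal(8, 2) per gene, typical of a
# normalized expression array after log transformation.
BASELINE_MEAN = 8.0
BASELINE_SD = 2.0

#: Power-law exponent for background node degrees (PPI-like topology).
DEGREE_EXPONENT = 2.5


class InvalidDesignError(ValueError):
    """Raised when a synthetic design violates its invariants."""


@dataclass(frozen=True)
class SyntheticDesign:
    """Factorial design of a synthetic expression study.

    Defaults emulate a two-genotype (wild type vs overexpressor) by
    two-sulfur-condition (sufficient ``nS`` vs deficient ``-S``) by
    two-tissue design with three biological replicates per cell.
    """

    n_genes: int = 1000
    genotypes: tuple[str, ...] = ("WT", "OX")
    conditions: tuple[str, ...] = ("nS", "-S")  # reference level first
    tissues: tuple[str, ...] = ("shoot", "root")
    n_replicates: int = 3
    planted_deg_fraction: float = 0.1
    planted_log2fc: float = 2.0
    noise_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise InvalidDesignError("n_genes must be positive")
        for name in ("genotypes", "conditions", "tissues"):
            if len(getattr(self, name)) == 0:
                raise InvalidDesignError(f"factor {name!r} has no levels")
        if len(self.conditions) != 2:
            raise InvalidDesignError(
                "conditions must have exactly two levels (reference, stressed)"
            )
        if self.n_replicates < 2:
            raise InvalidDesignError("n_replicates must be >= 2 for ANOVA")
        if not 0.0 <= self.planted_deg_fraction <= 1.0:
            raise InvalidDesignError("planted_deg_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise InvalidDesignError("noise_sd must be > 0")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators.

    ``deg_ids_by_contrast`` maps a contrast label (``"<genotype>:<tissue>"``)
    to ``{gene_id: +1 | -1}`` — the sign of the planted log2 shift in the
    stressed condition. ``hub_ids`` are nodes given elevated degree;
    ``specific_interactor_ids`` are proteins present only in bait runs.
    """

    deg_ids_by_contrast: dict[str, dict[str, int]] = field(default_factory=dict)
    hub_ids: set[str] = field(default_factory=set)
    specific_interactor_ids: set[str] = field(default_factory=set)

    def deg_ids(self, contrast: str, direction: str | None = None) -> set[str]:
        signs = self.deg_ids_by_contrast.get(contrast, {})
        if direction is None:
            return set(signs)
        want = 1 if direction == "up" else -1
        return {g for g, s in signs.items() if s == want}

    def to_dict(self) -> dict:
        return {
            "deg_ids_by_contrast": {
                c: dict(sorted(m.items())) for c, m in sorted(self.deg_ids_by_contrast.items())
            },
            "hub_ids": sorted(self.hub_ids),
            "specific_interactor_ids": sorted(self.specific_interactor_ids),
        }


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_expression_study(
    design: SyntheticDesign,
) -> tuple[ExpressionStudy, PlantedTruth]:
    """Simulate a genes x samples log2 expression matrix with planted DEGs.

    Per-gene baselines are drawn from Normal(8, 2); within each contrast
    (genotype x tissue) a fraction ``planted_deg_fraction`` of genes gets a
    ±``planted_log2fc`` shift in the stressed (second) condition; i.i.d.
    Gaussian noise with sd ``noise_sd`` is added to every observation.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    genes = _gene_ids(design.n_genes)
    cells = list(
        itertools.product(design.genotypes, design.conditions, design.tissues)
    )
    sample_rows = []
    for geno, cond, tis in cells:
        for rep in range(1, design.n_replicates + 1):
            sample_rows.append(
                {
                    "sample_id": f"{geno}_{cond}_{tis}_r{rep}",
                    "genotype": geno,
                    "condition": cond,
                    "tissue": tis,
                    "replicate": rep,
                }
            )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")

    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=design.n_genes)
    matrix = np.tile(baseline[:, None], (1, len(samples)))

    stressed = design.conditions[1]
    n_planted = round(design.planted_deg_fraction * design.n_genes)
    truth = PlantedTruth()
    gene_index = {g: i for i, g in enumerate(genes)}
    for geno in design.genotypes:
        for tis in design.tissues:
            label = contrast_label(geno, tis)
            chosen = rng.choice(design.n_genes, size=n_planted, replace=False)
            signs = rng.choice([-1, 1], size=n_planted)
            planted = {genes[i]: int(s) for i, s in zip(chosen, signs)}
            truth.deg_ids_by_contrast[label] = planted
            cols = np.flatnonzero(
                (samples["genotype"] == geno)
                & (samples["tissue"] == tis)
                & (samples["condition"] == stressed)
            )
            for g, s in planted.items():
                matrix[gene_index[g], cols] += s * design.planted_log2fc

    matrix += rng.normal(0.0, design.noise_sd, size=matrix.shape)
    frame = pd.DataFrame(matrix, index=pd.Index(genes, name="gene_id"),
                         columns=samples.index)
    study = ExpressionStudy(
        matrix=frame,
        samples=samples,
        condition_levels=tuple(design.conditions),
    )
    return study, truth


def _background_degrees(rng: np.random.Generator, n: int, mean: float,
                        d_max: int) -> np.ndarray:
    """Power-law degree draws (exponent 2.5) rescaled to the requested mean.

    The raw truncated power law on [1, d_max] has mean <= ~1.95, so draws are
    scaled to hit ``mean`` while preserving the heavy-tailed shape.
    """
    support = np.arange(1, d_max + 1, dtype=float)
    pmf = support ** (-DEGREE_EXPONENT)
    pmf /= pmf.sum()
    raw = rng.choice(support, size=n, p=pmf)
    scaled = np.maximum(1, np.rint(raw * mean / (pmf @ support)).astype(int))
    return np.minimum(scaled, d_max)


class InfeasibleDegreeError(ValueError):
    """Raised when a requested hub degree cannot fit in the node count."""


def generate_interaction_network(
    n_nodes: int,
    n_hubs: int,
    hub_degree: int,
    background_degree_mean: float = 3.0,
    seed: int = 0,
    node_ids: list[str] | None = None,
) -> tuple[nx.Graph, PlantedTruth]:
    """Simple undirected network with ``n_hubs`` planted high-degree nodes.

    Non-hub degrees follow a rescaled power law (exponent 2.5); each planted
    hub is then wired to uniformly sampled partners until its degree reaches
    ``hub_degree``. The result has no self-loops and no duplicate edges.
    """
    if n_hubs >= n_nodes:
        raise InvalidDesignError("n_hubs must be < n_nodes")
    if hub_degree >= n_nodes:
        raise InfeasibleDegreeError(
            f"hub_degree={hub_degree} impossible with n_nodes={n_nodes}"
        )
    if n_hubs > 0 and hub_degree <= background_degree_mean:
        raise InvalidDesignError("hub_degree must exceed background_degree_mean")
    rng = np.random.default_rng(seed)

    if node_ids is None:
        width = max(4, len(str(n_nodes)))
        node_ids = [f"P{i:0{width}d}" for i in range(1, n_nodes + 1)]
    elif len(node_ids) != n_nodes:
        raise InvalidDesignError("node_ids length must equal n_nodes")

    g = nx.Graph()
    g.add_nodes_from(node_ids)

    hub_idx = rng.choice(n_nodes, size=n_hubs, replace=False) if n_hubs else []
    hubs = {node_ids[i] for i in hub_idx}

    # Background: configuration-style pairing of power-law degree stubs,
    # simplified to a plain graph.
    degrees = _background_degrees(
        rng, n_nodes, background_degree_mean, d_max=max(2, n_nodes // 10)
    )
    stubs = np.repeat(np.arange(n_nodes), degrees)
    rng.shuffle(stubs)
    for u, v in zip(stubs[0::2], stubs[1::2]):
        if u != v:
            g.add_edge(node_ids[u], node_ids[v])

    non_hub_pool = [n for n in node_ids if n not in hubs]
    for h in sorted(hubs):
        need = hub_degree - g.degree(h)
        candidates = [n for n in non_hub_pool if n != h and not g.has_edge(h, n)]
        if need > 0:
            if need > len(candidates):
                raise InfeasibleDegreeError(
                    f"cannot raise node {h} to degree {hub_degree}"
                )
            partners = rng.choice(len(candidates), size=need, replace=False)
            g.add_edges_from((h, candidates[i]) for i in partners)

    truth = PlantedTruth(hub_ids=hubs)
    return g, truth


def generate_tap_intensities(
    n_background: int,
    n_specific: int,
    bait_intensity_scale: float = 5e6,
    n_replicates: int = 2,
    seed: int = 0,
    specific_prefix: str = "SP",
    mw_mean_kda: float = 45.0,
) -> tuple[TapTable, PlantedTruth]:
    """MaxQuant-style intensity table with planted bait-specific proteins.

    Background proteins are detected in both bait and control purifications
    with log-normal intensities; planted specific interactors are detected
    only in the bait runs (control cells are "not detected", encoded NaN,
    never numeric zero). ``n_replicates`` is 1 or 2, mirroring purifications
    analyzed as biological duplicates or singletons.
    """
    if n_background < 0 or n_specific < 0:
        raise InvalidDesignError("protein counts must be non-negative")
    if n_replicates not in (1, 2):
        raise InvalidDesignError("n_replicates must be 1 or 2")
    if bait_intensity_scale <= 0:
        raise InvalidDesignError("bait_intensity_scale must be positive")
    rng = np.random.default_rng(seed)

    n = n_background + n_specific
    ids = [f"BG{i:04d}" for i in range(1, n_background + 1)] + [
        f"{specific_prefix}{i:04d}" for i in range(1, n_specific + 1)
    ]
    specific = set(ids[n_background:])
    mw = rng.lognormal(mean=np.log(mw_mean_kda), sigma=0.5, size=n)

    def draws(scale: float, rows: int) -> np.ndarray:
        return rng.lognormal(mean=np.log(scale), sigma=0.4,
                             size=(rows, n_replicates))

    bait = np.vstack([
        draws(bait_intensity_scale / 5.0, n_background),
        draws(bait_intensity_scale, n_specific),
    ]) if n else np.empty((0, n_replicates))
    ctrl = np.vstack([
        draws(bait_intensity_scale / 5.0, n_background),
        np.full((n_specific, n_replicates), np.nan),
    ]) if n else np.empty((0, n_replicates))

    data = {"protein_id": ids, "mw_kda": np.round(mw, 2)}
    bait_cols = [f"bait_rep{r}" for r in range(1, n_replicates + 1)]
    ctrl_cols = [f"ctrl_rep{r}" for r in range(1, n_replicates + 1)]
    for j, c in enumerate(bait_cols):
        data[c] = bait[:, j]
    for j, c in enumerate(ctrl_cols):
        data[c] = ctrl[:, j]
    table = TapTable(
        data=pd.DataFrame(data),
        bait_cols=bait_cols,
        control_cols=ctrl_cols,
    )
    return table, PlantedTruth(specific_interactor_ids=specific)


def generate_family_annotation(
    universe: list[str],
    n_families: int = 20,
    family_size_mean: int = 25,
    enriched_from: set[str] | None = None,
    enriched_family_size: int = 30,
    enriched_overlap: int = 25,
    seed: int = 0,
) -> FamilyAnnotation:
    """Random gene families over ``universe``, optionally one planted family.

    The planted family (``FAM_PLANTED``) draws ``enriched_overlap`` members
    from ``enriched_from`` and the rest at random, so an overrepresentation
    test over a query set containing ``enriched_from`` should flag it.
    """
    rng = np.random.default_rng(seed)
    universe = list(universe)
    families: dict[str, set[str]] = {}
    for i in range(1, n_families + 1):
        size = max(2, int(rng.poisson(family_size_mean)))
        size = min(size, len(universe))
        members = rng.choice(len(universe), size=size, replace=False)
        families[f"FAM{i:03d}"] = {universe[j] for j in members}
    if enriched_from:
        pool = sorted(enriched_from)
        k = min(enriched_overlap, len(pool), enriched_family_size)
        members = set(
            pool[i] for i in rng.choice(len(pool), size=k, replace=False)
        )
        rest = [g for g in universe if g not in members]
        extra = enriched_family_size - len(members)
        if extra > 0 and rest:
            members |= {
                rest[i]
                for i in rng.choice(len(rest), size=min(extra, len(rest)),
                                    replace=False)
            }
        families["FAM_PLANTED"] = members
    return FamilyAnnotation(families=families, universe=set(universe))


def truth_to_json(truth: PlantedTruth) -> dict:
    return truth.to_dict()
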