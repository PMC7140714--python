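"""End-to-end orchestration: simulate -> DEGs -> Venn -> enrichment -> hubs
-> TAP scores -> summary.

``run_pipeline`` executes every stage on a synthetic study with planted
structure, writes all stage outputs under an output directory, and returns a
machine-readable summary (set sizes, overlap percentages, hub lists,
differential calls, enrichment hits, planted-structure recovery rates).
Re-running with the same config and seed reproduces byte-identical stage
outputs and summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .deg import FactorialAnova, contrast_label, get_deg_set
from .enrichment import enrich_families
from .hubs import (
    conditioned_degrees,
    differential_hubs,
    expand_first_neighbors,
    records_to_frame,
    select_hubs,
    write_edge_list,
)
from .sets import common_fraction, partition_three, partition_two, round_half_up
from .simulate import (
    SyntheticDesign,
    generate_expression_study,
    generate_family_annotation,
    generate_interaction_network,
    generate_tap_intensities,
)
from .tap import call_interactome, score_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

TAP_CONDITIONS = ("nS", "4d-S", "10d-S")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics."""


@dataclass
class RunConfig:
    """All thresholds and simulation sizes for one pipeline run."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    # expression simulation
    n_genes: int = 1000
    n_replicates: int = 3
    planted_deg_fraction: float = 0.1
    planted_log2fc: float = 2.0
    noise_sd: float = 0.25
    # DEG filter
    fc_threshold: float = 1.5
    alpha: float = 0.05
    # enrichment
    enrichment_alpha: float = 0.01
    # network simulation + hub thresholds
    n_hubs: int = 5
    hub_degree: int = 20
    background_degree_mean: float = 3.0
    hub_min_degree: int = 10
    diff_abs_min: int = 9
    diff_rel_min: float = 0.20
    # TAP simulation + scoring
    tap_n_background: int = 60
    tap_n_specific: int = 15
    tap_bait_scale: float = 5e6
    min_specificity: float = 2.0

    def validate(self) -> None:
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        for name in ("alpha", "enrichment_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.hub_min_degree < 1 or self.diff_abs_min < 0:
            raise ValueError("hub thresholds out of range")
        if not 0 <= self.diff_rel_min <= 1:
            raise ValueError("diff_rel_min must lie in [0, 1]")
        if self.min_specificity < 1:
            raise ValueError("min_specificity must be >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage on synthetic inputs; write outputs; return summary."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"counts": {}}

    # --- simulate expression + call DEGs -------------------------------
    design = SyntheticDesign(
        n_genes=cfg.n_genes,
        n_replicates=cfg.n_replicates,
        planted_deg_fraction=cfg.planted_deg_fraction,
        planted_log2fc=cfg.planted_log2fc,
        noise_sd=cfg.noise_sd,
        seed=cfg.seed,
    )
    study, truth = generate_expression_study(design)
    io.write_expression_study(study, out / "expression.tsv", out / "samples.tsv")
    io.write_truth(truth, out / "expression_truth.json")

    results = FactorialAnova(study).fit()
    deg_sets = results.call_degs(cfg.fc_threshold, cfg.alpha)
    records = results.deg_records(cfg.fc_threshold, cfg.alpha)
    records.to_csv(out / "deg_records.tsv", sep="\t", index=False)
    deg_dir = out / "deg_sets"
    deg_dir.mkdir(exist_ok=True)
    for s in deg_sets:
        safe = s.contrast.replace(":", "_")
        io.write_id_set(s.gene_ids, deg_dir / f"{safe}.{s.direction}.txt")
    summary["deg_set_sizes"] = {
        f"{s.contrast}|{s.direction}": len(s) for s in deg_sets
    }

    # planted-DEG recovery, pooled over contrasts and directions
    n_planted = n_recovered = n_called = 0
    for s in deg_sets:
        planted = truth.deg_ids(s.contrast, s.direction)
        n_planted += len(planted)
        n_recovered += len(planted & s.gene_ids)
        n_called += len(s.gene_ids)
    summary["deg_recovery"] = {
        "planted": n_planted,
        "recovered": n_recovered,
        "called": n_called,
        "recovery_pct": 100.0 * n_recovered / n_planted if n_planted else None,
        "false_positive_pct": (
            100.0 * (n_called - n_recovered) / n_called if n_called else None
        ),
    }

    # --- Venn partitions: WT vs OX per tissue and direction ------------
    genotypes = study.factor_levels("genotype")
    venn: dict[str, dict] = {}
    for tissue in study.factor_levels("tissue"):
        for direction in ("up", "down"):
            a = get_deg_set(deg_sets, contrast_label(genotypes[0], tissue), direction)
            b = get_deg_set(deg_sets, contrast_label(genotypes[1], tissue), direction)
            part = partition_two(a.gene_ids, b.gene_ids,
                                 labels=(genotypes[0], genotypes[1]))
            entry = dict(part.sizes())
            if part.union_size:
                frac = common_fraction(part)
                entry["common_pct"] = frac
                entry["common_pct_rounded"] = round_half_up(frac)
            venn[f"{tissue}|{direction}"] = entry
    summary["deg_venn"] = venn
    (out / "deg_venn.json").write_text(
        json.dumps(venn, indent=2, sort_keys=True) + "\n"
    )

    # --- family enrichment on the first contrast's up-set --------------
    first_up = get_deg_set(
        deg_sets, contrast_label(genotypes[0], study.factor_levels("tissue")[0]), "up"
    )
    ann = generate_family_annotation(
        list(study.genes),
        enriched_from=first_up.gene_ids,
        seed=cfg.seed + 1,
    )
    ann.to_gmt(out / "families.gmt")
    enr = enrich_families(first_up.gene_ids, ann, alpha=cfg.enrichment_alpha)
    enr_rows = [
        {
            "family": r.family_name, "k": r.k, "m": r.m, "n": r.n, "N": r.N,
            "p_value": r.p_value, "enriched": r.enriched,
        }
        for r in enr
    ]
    (out / "enrichment.tsv").write_text(
        "family\tk\tm\tn\tN\tp_value\tenriched\n"
        + "".join(
            f"{r['family']}\t{r['k']}\t{r['m']}\t{r['n']}\t{r['N']}\t"
            f"{r['p_value']:.6g}\t{r['enriched']}\n"
            for r in enr_rows
        )
    )
    summary["enriched_families"] = [r["family"] for r in enr_rows if r["enriched"]]

    # --- interaction network + hub analysis ----------------------------
    net, net_truth = generate_interaction_network(
        n_nodes=cfg.n_genes,
        n_hubs=cfg.n_hubs,
        hub_degree=cfg.hub_degree,
        background_degree_mean=cfg.background_degree_mean,
        seed=cfg.seed + 2,
        node_ids=list(study.genes),
    )
    write_edge_list(net, out / "network_edges.tsv")
    io.write_truth(net_truth, out / "network_truth.json")

    tissue0 = study.factor_levels("tissue")[0]
    set_wt = get_deg_set(deg_sets, contrast_label(genotypes[0], tissue0), "up").gene_ids | get_deg_set(
        deg_sets, contrast_label(genotypes[0], tissue0), "down"
    ).gene_ids
    set_ox = get_deg_set(deg_sets, contrast_label(genotypes[1], tissue0), "up").gene_ids | get_deg_set(
        deg_sets, contrast_label(genotypes[1], tissue0), "down"
    ).gene_ids
    labels = {f"-S in {genotypes[0]}": set_wt, f"-S in {genotypes[1]}": set_ox}
    hub_neighborhood = expand_first_neighbors(net, net_truth.hub_ids) - net_truth.hub_ids
    labels["planted-neighborhood"] = hub_neighborhood
    recs = conditioned_degrees(net, labels)
    records_to_frame(recs).to_csv(out / "hub_degrees.tsv", sep="\t", index=False)

    selected = select_hubs(recs, "planted-neighborhood", cfg.hub_min_degree)
    summary["hubs"] = {
        "selected": selected,
        "planted": sorted(net_truth.hub_ids),
        "planted_recovered_pct": (
            100.0 * len(net_truth.hub_ids & set(selected)) / len(net_truth.hub_ids)
            if net_truth.hub_ids else None
        ),
    }
    r1 = conditioned_degrees(net, {"-S": set_wt})
    r2 = conditioned_degrees(net, {"-S": set_ox})
    calls = differential_hubs(r1, r2, "-S", cfg.diff_abs_min, cfg.diff_rel_min)
    flagged = [c for c in calls if c.flagged]
    (out / "differential_hubs.tsv").write_text(
        "node_id\td1\td2\tabs_diff\trel_diff\tdirection\tflagged\n"
        + "".join(
            f"{c.node_id}\t{c.d1}\t{c.d2}\t{c.abs_diff}\t{c.rel_diff:.4f}\t"
            f"{c.direction}\t{c.flagged}\n"
            for c in calls
            if c.d1 or c.d2
        )
    )
    summary["differential_hubs"] = [c.node_id for c in flagged]

    # --- TAP-MS scoring across tissues x conditions --------------------
    tap_summary: dict[str, dict] = {}
    interactomes: dict[str, set[str]] = {}
    n_spec_planted = n_spec_called = 0
    for t_i, tissue in enumerate(study.factor_levels("tissue")):
        # constitutive interactors co-purifying in every growth condition
        core_table, core_truth = generate_tap_intensities(
            n_background=0,
            n_specific=cfg.tap_n_specific,
            bait_intensity_scale=cfg.tap_bait_scale,
            seed=cfg.seed + 8 + t_i,
            specific_prefix="SPcore_",
        )
        for c_i, condition in enumerate(TAP_CONDITIONS):
            table, tap_truth = generate_tap_intensities(
                n_background=cfg.tap_n_background,
                n_specific=max(1, cfg.tap_n_specific // 3),
                bait_intensity_scale=cfg.tap_bait_scale,
                seed=cfg.seed + 10 + 3 * t_i + c_i,
                specific_prefix=f"SP{condition.replace('-', '')}_",
            )
            table.data = pd.concat(
                [table.data, core_table.data], ignore_index=True
            )
            tap_truth.specific_interactor_ids |= core_truth.specific_interactor_ids
            table.condition, table.tissue = condition, tissue
            tag = f"{tissue}_{condition.replace('-', '')}"
            table.to_tsv(out / f"tap_{tag}.tsv")
            scores = score_table(table)
            scores.to_csv(out / f"tap_scores_{tag}.tsv", sep="\t", index=False)
            called = call_interactome(scores, cfg.min_specificity)
            ids = called[(tissue, condition)] if isinstance(called, dict) else called
            interactomes[f"{tissue}|{condition}"] = ids
            io.write_id_set(ids, out / f"interactome_{tag}.txt")
            n_spec_planted += len(tap_truth.specific_interactor_ids)
            n_spec_called += len(tap_truth.specific_interactor_ids & ids)
            tap_summary[f"{tissue}|{condition}"] = {
                "n_scored": len(scores),
                "n_called": len(ids),
            }
    summary["tap"] = tap_summary
    summary["tap_specific_recovery_pct"] = (
        100.0 * n_spec_called / n_spec_planted if n_spec_planted else None
    )

    # three-condition interactome Venn per tissue
    tap_venn: dict[str, dict] = {}
    for tissue in study.factor_levels("tissue"):
        three = [interactomes[f"{tissue}|{c}"] for c in TAP_CONDITIONS]
        part = partition_three(*three, labels=TAP_CONDITIONS)
        entry = dict(part.sizes())
        entry["union"] = part.union_size
        if part.union_size:
            frac = part.triple_fraction()
            entry["triple_pct"] = frac
            entry["triple_pct_rounded"] = round_half_up(frac)
        tap_venn[tissue] = entry
    summary["tap_venn"] = tap_venn

    # --- summary + manifest --------------------------------------------
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=sorted) + "\n"
    )
    manifest = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return summary
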