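"""End-to-end orchestration: QC -> counts -> D/D_FOIL battery -> CF -> conflicts.

A single structured configuration (flat YAML keys) drives the whole
analysis; every stage writes a plain-text artifact (TSV or JSON) and the
final stage consolidates the evidence into introgression calls.  Re-running
with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import yaml

from . import dstats, seqio_qc, site_patterns, trees_concordance as tc
from .dstats import TestBattery, apply_battery, bonferroni, dfoil, ghost_direction, patterson_d
from .seqio_qc import QcConfig, qc_locus, read_fasta_locus, write_qc_report
from .site_patterns import TaxonSet, count_patterns, write_counts_tsv
from .trees_concordance import (Clade, ConcordanceEstimate, asymmetry_test,
                                bipartition_conflicts, concordance_factor,
                                excess_cf, parse_tree, write_cf_tsv,
                                write_conflict_json)

log = logging.getLogger("introkit.pipeline")


class PipelineError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything one analysis run needs; see ``RunConfig.from_yaml``."""

    out_dir: str
    loci_dir: str | None = None
    gene_trees_dir: str | None = None
    species_tree_a: str | None = None
    species_tree_b: str | None = None
    reference_taxon: str | None = None
    qc: QcConfig = field(default_factory=QcConfig)
    taxon_sets: list[TaxonSet] = field(default_factory=list)
    dfoil_mode: str = "alt"
    ghost_contrasts: list[dict] = field(default_factory=list)
    clade_contrasts: list[dict] = field(default_factory=list)
    family_alpha: float = 0.05
    n_boot: int = 1000
    min_support_conflict: float = 0.0
    count_subsets: tuple[str, ...] = ("primary",)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        qc = QcConfig(**raw.pop("qc", {}))
        tsets = [_taxon_set_from_dict(d) for d in raw.pop("taxon_sets", [])]
        return cls(qc=qc, taxon_sets=tsets, **raw)


def _taxon_set_from_dict(d: dict) -> TaxonSet:
    label = d.get("label", "")
    if "p4" in d:
        return TaxonSet.quintet(d["p1"], d["p2"], d["p3"], d["p4"], d["o"],
                                label=label)
    return TaxonSet.quartet(d["p1"], d["p2"], d["p3"], d["o"], label=label)


# ---------------------------------------------------------------------------
# stages


def stage_qc(cfg: RunConfig) -> dict[str, list[seqio_qc.LocusAlignment]]:
    if cfg.loci_dir is None:
        raise PipelineError("no loci_dir configured")
    if not os.path.isdir(cfg.loci_dir):
        raise PipelineError(f"missing input path: {cfg.loci_dir}")
    subsets: dict[str, list] = {"primary": [], "MS": [], "NL": [], "discard": []}
    records = []
    for name in sorted(os.listdir(cfg.loci_dir)):
        if not name.endswith((".fa", ".fasta", ".fna")):
            continue
        aln = read_fasta_locus(os.path.join(cfg.loci_dir, name),
                               reference_taxon=cfg.reference_taxon)
        cleaned, rec = qc_locus(aln, cfg.qc)
        subsets[rec.subset].append(cleaned)
        records.append(rec)
    os.makedirs(cfg.out_dir, exist_ok=True)
    write_qc_report(records, os.path.join(cfg.out_dir, "qc_report.tsv"))
    log.info("qc: %s", {k: len(v) for k, v in subsets.items()})
    if not records:
        raise PipelineError(f"no FASTA loci found in {cfg.loci_dir}")
    if not any(subsets[s] for s in cfg.count_subsets):
        raise PipelineError("empty locus set after QC")
    return subsets


def stage_counts(cfg: RunConfig, loci) -> dict[str, site_patterns.PatternCounts]:
    out = {}
    for ts in cfg.taxon_sets:
        out[ts.label] = count_patterns(loci, ts)
    write_counts_tsv(out, os.path.join(cfg.out_dir, "pattern_counts.tsv"))
    with open(os.path.join(cfg.out_dir, "pattern_exclusions.json"), "w") as fh:
        json.dump({label: dict(pc.excluded_by_reason)
                   for label, pc in out.items()}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def battery_size(taxon_sets: list[TaxonSet]) -> int:
    """One chi-square comparison per D test, four per D_FOIL test."""
    return sum(1 if ts.arity == 4 else 4 for ts in taxon_sets)


def stage_dstats(cfg: RunConfig, counts: dict) -> list:
    if not counts:
        return []
    battery = TestBattery(n_comparisons=battery_size(cfg.taxon_sets),
                          family_alpha=cfg.family_alpha)
    results = []
    for ts in cfg.taxon_sets:
        pc = counts[ts.label]
        if ts.arity == 4:
            results.append(patterson_d(pc, taxa=ts))
        else:
            results.append(dfoil(pc, mode=cfg.dfoil_mode, battery=battery,
                                 taxa=ts))
    apply_battery(results, battery)
    dstats.write_battery_tsv(results,
                             os.path.join(cfg.out_dir, "battery_report.tsv"))
    return results


def stage_cf(cfg: RunConfig) -> list[dict]:
    if cfg.gene_trees_dir is None or not cfg.clade_contrasts:
        return []
    if not os.path.isdir(cfg.gene_trees_dir):
        raise PipelineError(f"missing input path: {cfg.gene_trees_dir}")
    trees = []
    for name in sorted(os.listdir(cfg.gene_trees_dir)):
        if name.endswith((".nwk", ".tre", ".newick")):
            trees.append(parse_tree(os.path.join(cfg.gene_trees_dir, name)))
    if not trees:
        raise PipelineError(f"no newick trees in {cfg.gene_trees_dir}")
    universe = frozenset().union(*(tc.tree_taxa(t) for t in trees))
    estimates, contrasts = [], []
    for con in cfg.clade_contrasts:
        focal = concordance_factor(
            trees, Clade.of(con["focal"], universe, label=con.get("label", "")),
            n_boot=cfg.n_boot, seed=cfg.seed)
        alts = [concordance_factor(trees, Clade.of(a, universe),
                                   n_boot=cfg.n_boot, seed=cfg.seed)
                for a in con["alternatives"]]
        adm = excess_cf(focal, alts)
        estimates.extend([focal, *alts])
        contrasts.append({"label": con.get("label", ""), "admixture": adm})
    write_cf_tsv(estimates, os.path.join(cfg.out_dir, "cf_table.tsv"))
    return contrasts


def stage_conflicts(cfg: RunConfig) -> list:
    if cfg.species_tree_a is None or cfg.species_tree_b is None:
        return []
    for p in (cfg.species_tree_a, cfg.species_tree_b):
        if not os.path.exists(p):
            raise PipelineError(f"missing input path: {p}")
    conflicts = bipartition_conflicts(parse_tree(cfg.species_tree_a),
                                      parse_tree(cfg.species_tree_b),
                                      min_support=cfg.min_support_conflict)
    write_conflict_json(conflicts, os.path.join(cfg.out_dir, "tree_conflicts.json"))
    return conflicts


# ---------------------------------------------------------------------------
# consolidation


def consolidate_calls(cfg: RunConfig, dresults: list, cf_contrasts: list,
                      conflicts: list) -> list[dict]:
    """Merge the evidence streams into per-pair introgression calls.

    Every significant battery entry lands in exactly one call (keyed by the
    participant pair it implicates) or in the ``unexplained`` list.
    """
    calls: dict[frozenset, dict] = {}
    unexplained = []

    def call_for(pair: frozenset) -> dict:
        if pair not in calls:
            calls[pair] = {"participants": sorted(pair), "evidence": [],
                           "magnitude": {}, "direction": "uncertain"}
        return calls[pair]

    by_label = {r.taxa.label: r for r in dresults if r.taxa is not None}
    ghost_called = set()
    for gc in cfg.ghost_contrasts:
        excl, incl = by_label.get(gc["excl"]), by_label.get(gc["incl"])
        if excl is None or incl is None:
            continue
        verdict = ghost_direction(excl, incl,
                                  {k: gc[k] for k in ("focal", "candidate",
                                                      "relative")})
        if verdict.endswith("(directional)"):
            pair = frozenset((gc["focal"], gc["candidate"]))
            c = call_for(pair)
            c["evidence"].append("ghost-direction")
            c["direction"] = f"{gc['candidate']} into {gc['focal']}"
            ghost_called.add(gc["excl"])

    for r in dresults:
        if isinstance(r, dstats.DTestResult):
            pair = r.implicated_pair()
            if pair is None:
                if r.significant:
                    unexplained.append(r.taxa.label)
                continue
            if not r.significant:
                continue
            c = call_for(frozenset(pair))
            c["evidence"].append("D")
            c["magnitude"]["D"] = round(r.D, 4)
            if r.taxa.label in ghost_called:
                c["evidence"].append("ghost-excluded-test")
        else:
            role_pair = dstats.hypothesis_pair(r.interpretation)
            if role_pair is None:
                if any(s != "0" for s in r.signature):
                    unexplained.append(r.taxa.label if r.taxa else "?")
                continue
            taxa_pair = frozenset(
                "+".join(r.taxa.taxon(x) for x in ("P1", "P2")) if role == "P12"
                else r.taxa.taxon(role) for role in role_pair)
            c = call_for(taxa_pair)
            c["evidence"].append("D_FOIL")
            c["magnitude"]["signature"] = "".join(r.signature)
            if c["direction"] == "uncertain":  # ghost calls take precedence
                c["direction"] = r.interpretation_label

    for con in cf_contrasts:
        adm = con["admixture"]
        if adm.significant:
            pair = frozenset((",".join(sorted(adm.focal.clade.side)),))
            c = call_for(pair)
            c["evidence"].append("cf-asymmetry")
            c["magnitude"]["excess_cf"] = round(adm.excess, 4)

    if conflicts:
        pair = frozenset(("nuclear-tree", "other-tree"))
        c = call_for(pair)
        c["evidence"].append("mito-nuclear conflict")
        c["magnitude"]["n_conflicts"] = len(conflicts)

    out = [calls[k] for k in sorted(calls, key=lambda p: sorted(p))]
    return [c for c in out if c["evidence"]] + (
        [{"participants": [], "evidence": [], "unexplained": sorted(unexplained)}]
        if unexplained else [])


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages in order; returns the report bundle."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    report: dict = {"seed": cfg.seed}
    subsets = stage_qc(cfg) if cfg.loci_dir else {}
    report["qc"] = {k: len(v) for k, v in subsets.items()}
    loci = [a for s in cfg.count_subsets for a in subsets.get(s, [])]
    counts = stage_counts(cfg, loci) if cfg.taxon_sets and loci else {}
    dresults = stage_dstats(cfg, counts) if counts else []
    cf_contrasts = stage_cf(cfg)
    conflicts = stage_conflicts(cfg)
    calls = consolidate_calls(cfg, dresults, cf_contrasts, conflicts)
    report["n_tests"] = len(dresults)
    report["n_calls"] = len([c for c in calls if c["participants"]])
    with open(os.path.join(cfg.out_dir, "introgression_calls.json"), "w") as fh:
        json.dump(calls, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(cfg.out_dir, "run_summary.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"report": report, "calls": calls, "dresults": dresults,
            "cf_contrasts": cf_contrasts, "conflicts": conflicts}


# ---------------------------------------------------------------------------
# worked examples


def _load_worked_examples() -> dict:
    src = resources.files("introkit.data").joinpath("worked_examples.json")
    with src.open() as fh:
        return json.load(fh)


def verify_paper() -> list[dict]:
    """Recompute the worked examples from their packaged inputs.

    Each row compares a quantity computed by the package from printed inputs
    (site-pattern counts, CF point estimates, battery size) with the printed
    value, at the printed precision.
    """
    ex = _load_worked_examples()
    rows = []

    def add(name, computed, printed, ndigits):
        rows.append({"name": name, "computed": round(computed, ndigits),
                     "printed": printed,
                     "pass": round(computed, ndigits) == round(printed, ndigits)})

    for key in ("abba_baba_nuclear", "abba_baba_mitochondrial"):
        e = ex[key]
        pc = site_patterns.PatternCounts(
            arity=4, counts=Counter({"ABBA": e["n_abba"], "BABA": e["n_baba"]}))
        add(key + ":D", patterson_d(pc).D, e["printed_D"], 3)

    e = ex["bonferroni_battery"]
    thr, _ = bonferroni([1.0] * e["n_comparisons"], e["family_alpha"])
    # printed to one significant figure
    add("bonferroni:threshold", float(f"{thr:.1g}"), e["printed_threshold"], 4)

    for key in ("excess_cf_americanus", "excess_cf_roberti", "excess_cf_aestus"):
        e = ex[key]
        universe = frozenset(e["universe"])

        def est(d):
            return ConcordanceEstimate(
                clade=Clade.of(d["taxa"], universe), cf=d["cf"],
                ci_low=d["ci"][0], ci_high=d["ci"][1], n_genes=d["n_genes"],
                method="posterior-mean")

        adm = excess_cf(est(e["focal"]), [est(a) for a in e["alternatives"]])
        add(key + ":pct", round(adm.excess * 100), e["printed_excess_pct"], 0)
    return rows
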