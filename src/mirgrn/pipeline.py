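"""Pipeline configuration and stage orchestration.

``run_pipeline`` executes the stages in study order — family assignment,
TMM normalization, conservation classification, target prediction, network
assembly, network analysis, cross-group comparison — on a run directory,
writing each stage's tables before the next starts and recording every
kept/dropped decision in a machine-readable summary.  Stage outputs are
deterministic functions of the input files and the configuration, so a
rerun with the same seed produces byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import yaml

from . import conservation, families, grn, io, netstats, normalization, targets
from .simulate import SimulationParams, write_inputs

logger = logging.getLogger(__name__)

STAGES = ("simulate", "families", "normalize", "classify", "targets", "grn",
          "analyze", "compare")


@dataclass
class PipelineConfig:
    """Paths, thresholds and the root seed for one pipeline run.

    Default thresholds are the study's quoted rules where they exist
    (coverage 0.80, TPM 1.0, 2,500-nt UTR cap, strict score rule on
    interaction edges, alpha 0.005) and documented package defaults
    elsewhere.
    """

    run_dir: str = "run"
    input_dir: str | None = None          # defaults to <run_dir>/inputs
    seed: int = 0
    simulate: dict | None = field(default_factory=dict)  # SimulationParams overrides; None = use existing inputs
    min_coverage: float = families.MIN_COVERAGE
    min_identity: float = families.MIN_IDENTITY
    min_count: int = 5
    tpm_min: float = targets.TPM_MIN
    utr_max: int = targets.UTR_MAX
    max_scan: int = targets.MAX_SCAN
    score_min: float = targets.SCORE_MIN
    energy_max: float = targets.ENERGY_MAX
    consensus_mode: str = "positional"
    alpha: float = conservation.ALPHA_INTERSECTION
    walktrap_t: int = 4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not (0 < self.min_coverage <= 1) or not (0 <= self.min_identity <= 1):
            raise ValueError("coverage/identity thresholds must be fractions")
        if self.min_count < 1 or self.tpm_min < 0 or self.walktrap_t < 1:
            raise ValueError("min_count, tpm_min and walktrap_t out of range")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.simulate is None:
            indir = Path(self.input_dir or Path(self.run_dir) / "inputs")
            for needed in ("counts.tsv", "groups.tsv", "reference_primary.fasta"):
                if not (indir / needed).exists():
                    raise FileNotFoundError(f"missing input file: {indir / needed}")

    def sim_params(self) -> SimulationParams:
        overrides = dict(self.simulate or {})
        overrides.setdefault("seed", self.seed)
        for key in ("groups", "precursor_len", "mature_len", "utr_signal_offset_range",
                    "kernel_genes"):
            if key in overrides and isinstance(overrides[key], list):
                overrides[key] = tuple(
                    tuple(x) if isinstance(x, list) else x for x in overrides[key]
                )
        return SimulationParams(**overrides)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, through: str = "compare") -> dict:
    """Execute stages in order up to ``through``; returns the summary dict.

    Each stage writes its outputs under ``<run_dir>/<stage>/`` before the
    next stage starts; on failure, partial outputs are retained and a
    StageFailure naming the stage is raised.
    """
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}")
    config.validate()
    run_dir = Path(config.run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    indir = Path(config.input_dir or run_dir / "inputs")

    summary: dict = {"seed": config.seed, "stages": {}}
    state: dict = {}
    last = STAGES.index(through)
    for stage in STAGES[: last + 1]:
        try:
            _STAGE_FUNCS[stage](config, indir, run_dir, state, summary)
        except Exception as exc:
            io.write_json(summary, run_dir / "summary.json")
            raise StageFailure(stage, exc) from exc
    io.write_json(summary, run_dir / "summary.json")
    return summary


# ---------------------------------------------------------------------------
# Stage implementations


def _stage_simulate(config, indir, run_dir, state, summary):
    if config.simulate is None:
        summary["stages"]["simulate"] = {"skipped": True}
        return
    params = config.sim_params()
    ledger = write_inputs(params, indir)
    summary["stages"]["simulate"] = {
        "species": len(params.all_species),
        "families_planted": len(ledger.labels),
        "genes": params.n_genes,
        "ppi_edges": len(ledger.ppi_strata),
    }


def _load_inputs(config, indir, state):
    if "loci" in state:
        return
    groups_tbl = io.read_tsv(indir / "groups.tsv")
    dup = groups_tbl["species"].duplicated()
    if dup.any():
        raise ValueError(f"species mapped to two groups: {groups_tbl['species'][dup].iloc[0]}")
    state["groups"] = dict(zip(groups_tbl["species"], groups_tbl["group"]))
    state["group_species"] = {
        g: sorted(groups_tbl[groups_tbl["group"] == g]["species"]) for g in
        dict.fromkeys(groups_tbl["group"])
    }
    loci = []
    for sp in state["groups"]:
        prec = {r.id: r for r in io.read_fasta(indir / f"precursors_{sp}.fasta")}
        mat = {r.id: r for r in io.read_fasta(indir / f"matures_{sp}.fasta")}
        for lid, rec in prec.items():
            loci.append(families.MiRNALocus(
                species=sp, locus_id=lid, precursor=rec.seq, mature=mat[lid].seq,
                arm=rec.attrs.get("arm", "5p"),
            ))
    state["loci"] = loci

    ref = [
        families.ReferenceEntry(r.attrs["family"], r.seq, r.attrs.get("tier", "primary"))
        for r in io.read_fasta(indir / "reference_primary.fasta")
    ]
    secondary = indir / "reference_secondary.fasta"
    if secondary.exists():
        ref += [
            families.ReferenceEntry(r.attrs["family"], r.seq, "secondary")
            for r in io.read_fasta(secondary)
        ]
    state["reference"] = ref
    state["counts"] = io.read_matrix_tsv(indir / "counts.tsv").astype(np.int64)
    state["ages"] = families.load_age_table(io.read_tsv(indir / "ages.tsv"))


def _stage_families(config, indir, run_dir, state, summary):
    _load_inputs(config, indir, state)
    outdir = run_dir / "families"
    outdir.mkdir(exist_ok=True)
    report = families.assign_catalog(
        state["loci"], state["reference"],
        min_coverage=config.min_coverage, min_identity=config.min_identity,
    )
    io.write_tsv(report, outdir / "assignments.tsv")
    state["assignments"] = report
    state["locus_family"] = dict(zip(report["locus_id"], report["family"]))

    mature_groups = families.group_by_mature(state["loci"])
    io.write_tsv(
        pd.DataFrame(
            [{"mature": grp[0].mature, "n_loci": len(grp),
              "loci": ",".join(sorted(l.locus_id for l in grp))}
             for grp in mature_groups]
        ),
        outdir / "mature_groups.tsv",
    )
    summary["stages"]["families"] = {
        "loci": len(report),
        "assigned_known": int((report["status"] == "known").sum()),
        "novel_unassigned": int((report["status"] == "novel").sum()),
        "mature_groups": len(mature_groups),
        "rule": "local-alignment hit with coverage>=0.80 and identity>=0.70",
    }


def _stage_normalize(config, indir, run_dir, state, summary):
    outdir = run_dir / "normalize"
    outdir.mkdir(exist_ok=True)
    counts = state["counts"]
    fam_of = state["locus_family"]
    assigned = [l for l in counts.index if fam_of.get(l)]
    agg = counts.loc[assigned].groupby([fam_of[l] for l in assigned]).sum()
    factors = normalization.tmm_factors(agg)
    cpm = normalization.normalize(counts, factors)
    flags = normalization.detection_flags(counts, config.min_count)
    io.write_tsv(factors.report(), outdir / "tmm_factors.tsv")
    io.write_matrix_tsv(cpm.round(4), outdir / "cpm.tsv")
    io.write_matrix_tsv(flags.astype(int), outdir / "detection_flags.tsv")
    state["cpm"], state["flags"] = cpm, flags
    summary["stages"]["normalize"] = {
        "reference_sample": factors.reference,
        "loci_in_family_aggregate": len(assigned),
        "detected_locus_species": int(flags.to_numpy().sum()),
        "rule": f"detected iff count >= {config.min_count}; TMM factors on family aggregate",
    }


def _stage_classify(config, indir, run_dir, state, summary):
    outdir = run_dir / "classify"
    outdir.mkdir(exist_ok=True)
    loci_df = pd.DataFrame(
        [{"locus_id": l.locus_id, "species": l.species,
          "family": state["locus_family"].get(l.locus_id, "")}
         for l in state["loci"]]
    )
    presence, provenance = conservation.presence_matrix(
        loci_df[loci_df["family"] != ""], state["flags"], state["groups"]
    )
    labels = conservation.classify_conservation(presence)
    venn = conservation.venn_counts(presence)
    tests = conservation.intersection_tests(presence, alpha=config.alpha)

    io.write_matrix_tsv(presence.astype(int), outdir / "presence.tsv")
    io.write_tsv(
        pd.DataFrame([{"family": f, "label": lab} for f, lab in sorted(labels.items())]),
        outdir / "labels.tsv",
    )
    io.write_tsv(
        pd.DataFrame([{"region": "&".join(combo), "count": c}
                      for combo, c in sorted(venn.items())]),
        outdir / "venn_regions.tsv",
    )
    io.write_tsv(tests, outdir / "intersection_tests.tsv")
    state["presence"], state["labels"] = presence, labels
    label_counts: dict[str, int] = {}
    for lab in labels.values():
        label_counts[lab] = label_counts.get(lab, 0) + 1
    summary["stages"]["classify"] = {
        "families_detected": int(presence.any(axis=1).sum()),
        "families_never_detected_excluded": int((~presence.any(axis=1)).sum()),
        "labels": dict(sorted(label_counts.items())),
        "venn_regions_nonzero": sum(1 for c in venn.values() if c > 0),
        "intersection_tests_significant": int(tests["significant"].sum()),
        "alpha": config.alpha,
    }


def _stage_targets(config, indir, run_dir, state, summary):
    outdir = run_dir / "targets"
    outdir.mkdir(exist_ok=True)
    flags = state["flags"]
    fam_of = state["locus_family"]

    rows = []
    per_species_counts = {}
    for sp in state["groups"]:
        matures: dict[str, str] = {}
        fam_of_mid: dict[str, str] = {}
        seen: dict[str, set] = {}
        for l in state["loci"]:
            fam = fam_of.get(l.locus_id, "")
            if l.species != sp or not fam:
                continue
            if l.locus_id in flags.index and bool(flags.loc[l.locus_id, sp]):
                if l.mature in seen.setdefault(fam, set()):
                    continue
                seen[fam].add(l.mature)
                mid = f"{fam}#{len(seen[fam])}"
                matures[mid] = l.mature
                fam_of_mid[mid] = fam

        transcripts = {}
        tfile = indir / f"transcripts_{sp}.fasta"
        if tfile.exists():
            for r in io.read_fasta(tfile):
                transcripts[r.id] = (r.seq, r.attr_int("stop_offset"))
        tpm_tbl = io.read_tsv(indir / f"tpm_{sp}.tsv") if (indir / f"tpm_{sp}.tsv").exists() \
            else pd.DataFrame(columns=["species_gene", "tpm"])
        tpm = dict(zip(tpm_tbl["species_gene"], tpm_tbl["tpm"]))

        res = targets.predict_targets_for_species(
            matures, transcripts, tpm,
            max_scan=config.max_scan, utr_max=config.utr_max,
            score_min=config.score_min, energy_max=config.energy_max,
            tpm_min=config.tpm_min, max_gap=targets.CONSENSUS_MAX_GAP,
            consensus_mode=config.consensus_mode,
        )
        per_species_counts[sp] = res["counts"]
        for _, r in res["filtered"].iterrows():
            rows.append({"species": sp, "family": fam_of_mid[r["mirna"]],
                         "gene": r["gene"], "site_type": r["site_type"],
                         "core_start": int(r["core_start"])})

    interactions = pd.DataFrame(
        rows, columns=["species", "family", "gene", "site_type", "core_start"]
    ).drop_duplicates(["species", "family", "gene"]).sort_values(
        ["species", "family", "gene"]).reset_index(drop=True)
    io.write_tsv(interactions, outdir / "interactions.tsv")
    state["target_interactions"] = interactions
    summary["stages"]["targets"] = {
        "species": {sp: c for sp, c in sorted(per_species_counts.items())},
        "filtered_interactions": len(interactions),
        "rules": "AAUAAA/AUUAAA UTR; seed+hybrid consensus; TPM>=%g filter" % config.tpm_min,
    }


def _stage_grn(config, indir, run_dir, state, summary):
    outdir = run_dir / "grn"
    outdir.mkdir(exist_ok=True)
    omap = io.read_ortholog_map(indir / "orthologs.tsv")
    mapped = grn.map_orthologs(state["target_interactions"], omap)
    state["mapped_interactions"] = mapped
    ppi_raw = io.read_tsv(indir / "ppi.tsv")
    ppi = grn.filter_ppi(ppi_raw)
    kernel = set(io.read_tsv(indir / "kernel.tsv")["gene"])
    vfile = indir / "validated.tsv"
    validated = io.read_tsv(vfile) if vfile.exists() else None

    # per-species TPM in the reference namespace, for the conserved-expression rule
    ref_of = {
        (r.species, r.species_gene): r.ref_gene for r in omap.itertuples(index=False)
    }
    tpm_ref: dict[str, dict[str, float]] = {}
    for sp in state["groups"]:
        f = indir / f"tpm_{sp}.tsv"
        if not f.exists():
            continue
        tbl = io.read_tsv(f)
        d: dict[str, float] = {}
        for r in tbl.itertuples(index=False):
            ref = ref_of.get((sp, r.species_gene))
            if ref is not None:
                d[ref] = max(d.get(ref, 0.0), float(r.tpm))
        tpm_ref[sp] = d

    state["grns"] = {}
    grn_summary = {}
    for group, sp_list in state["group_species"].items():
        conserved = grn.conservation_filter(mapped, sp_list)
        threshold = grn.conservation_threshold(len(sp_list))
        expressed = {
            g for g in set().union(*(set(tpm_ref.get(sp, {})) for sp in sp_list))
            if sum(tpm_ref.get(sp, {}).get(g, 0.0) >= config.tpm_min for sp in sp_list)
            >= threshold
        } if sp_list else set()
        network = grn.assemble_grn(group, conserved, expressed, ppi, kernel, validated)
        state["grns"][group] = network
        io.write_tsv(grn.grn_edge_table(network), outdir / f"grn_{group}.tsv")
        nx.write_graphml(network.graph, outdir / f"grn_{group}.graphml")
        grn_summary[group] = {
            "species": len(sp_list),
            "conservation_threshold": threshold,
            "conserved_interactions": len(conserved),
            "nodes": network.graph.number_of_nodes(),
            "ppi_edges": len(network.ppi_edges),
            "mir_target_edges": len(network.mir_target_edges),
        }
    summary["stages"]["grn"] = {
        "ppi_edges_input": len(ppi_raw),
        "ppi_edges_pass_score_rule": len(ppi),
        "ppi_edges_dropped_by_score_rule": len(ppi_raw) - len(ppi),
        "interactions_mapped_to_reference": len(mapped),
        "interactions_unmapped_dropped": len(state["target_interactions"]) - len(mapped),
        "groups": grn_summary,
        "rules": "experimental>0 & combined>experimental; kernel adjacency; ceil(n/2) support",
    }


def _stage_analyze(config, indir, run_dir, state, summary):
    outdir = run_dir / "analyze"
    outdir.mkdir(exist_ok=True)
    stage = {}
    for group, network in state["grns"].items():
        g = network.graph
        deg = netstats.degree_centrality(g)
        clo = netstats.closeness_centrality(g)
        rows = [
            {"node": n, "kind": g.nodes[n]["kind"], "degree": deg[n],
             "closeness": round(clo[n], 6)}
            for n in sorted(g.nodes)
        ]
        io.write_tsv(pd.DataFrame(rows, columns=["node", "kind", "degree", "closeness"]),
                     outdir / f"centrality_{group}.tsv")
        if g.number_of_edges() > 0:
            part = netstats.walktrap_communities(g, t=config.walktrap_t)
            io.write_tsv(
                pd.DataFrame(
                    [{"node": n, "community": part.membership[n]} for n in sorted(g.nodes)]
                ),
                outdir / f"communities_{group}.tsv",
            )
            q = netstats.modularity(g, part.membership)
            stage[group] = {"communities": part.n_communities, "modularity": round(q, 6)}
        else:
            stage[group] = {"communities": g.number_of_nodes(), "modularity": None}
    summary["stages"]["analyze"] = stage


def _stage_compare(config, indir, run_dir, state, summary):
    outdir = run_dir / "compare"
    outdir.mkdir(exist_ok=True)
    groups = list(state["grns"])
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            cmpres = netstats.jaccard_similarity(
                state["grns"][ga].mir_target_edges, state["grns"][gb].mir_target_edges,
                group_a=ga, group_b=gb,
            )
            rows.append({"group_a": ga, "group_b": gb,
                         "jaccard": round(cmpres.jaccard, 6),
                         "conserved_count": cmpres.conserved_count})
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "jaccard", "conserved_count"])
    io.write_tsv(pairwise, outdir / "pairwise_jaccard.tsv")

    # conserved vs group-specific families: expression and target-count tests
    labels = state["labels"]
    cpm, flags = state["cpm"], state["flags"]
    fam_of = state["locus_family"]
    expr: dict[str, list[float]] = {}
    for l in state["loci"]:
        fam = fam_of.get(l.locus_id, "")
        if fam and l.locus_id in flags.index and bool(flags.loc[l.locus_id, l.species]):
            expr.setdefault(fam, []).append(float(cpm.loc[l.locus_id, l.species]))
    fam_expr = {f: float(np.median(v)) for f, v in expr.items()}
    tgt = state["mapped_interactions"]
    fam_targets = {
        f: int(tgt[tgt["family"] == f]["ref_gene"].nunique()) for f in labels
    }
    compare_summary: dict = {"pairwise": len(rows)}
    try:
        expr_test, tgt_test = conservation.compare_conserved_vs_specific(
            labels, fam_expr, fam_targets
        )
        report = pd.DataFrame([
            {"comparison": "expression", "U": expr_test.statistic, "n1": expr_test.n1,
             "n2": expr_test.n2, "p_value": expr_test.p_value,
             "alternative": expr_test.alternative},
            {"comparison": "target_count", "U": tgt_test.statistic, "n1": tgt_test.n1,
             "n2": tgt_test.n2, "p_value": tgt_test.p_value,
             "alternative": tgt_test.alternative},
        ])
        io.write_tsv(report, outdir / "rank_tests.tsv")
        compare_summary["expression_test"] = {
            "U": expr_test.statistic, "p_value": expr_test.p_value,
        }
        compare_summary["target_count_test"] = {
            "U": tgt_test.statistic, "p_value": tgt_test.p_value,
        }
    except ValueError:
        compare_summary["rank_tests"] = "skipped: a label class is empty"
    summary["stages"]["compare"] = compare_summary


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "families": _stage_families,
    "normalize": _stage_normalize,
    "classify": _stage_classify,
    "targets": _stage_targets,
    "grn": _stage_grn,
    "analyze": _stage_analyze,
    "compare": _stage_compare,
}
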