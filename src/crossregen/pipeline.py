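"""End-to-end orchestration of the synthetic comparative analysis with
a reproducibility manifest.

``run_all`` executes: simulate -> normalize -> paired DE + time-course
DE against the modeled control -> soft clustering -> enrichment (ORA
for clusters, paired set statistic for the cohort) -> term network ->
ortholog-mapped concordance -> miRNA screen -> report.  Every stage
writes deterministic TSV/JSON outputs; the manifest records the config
hash, seed and a SHA-256 checksum per output file, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, counts, diffexp, dynamic, enrichment, io, mirna, network, ortho
from .sim import SimConfig, emit_genesets, emit_orthomap, emit_targets, \
    simulate_paired_cohort, simulate_timecourse

STAGES = ("simulate", "normalize", "de", "timecourse", "cluster", "enrich",
          "network", "compare", "mirna", "report")


@dataclass
class RunConfig:
    """Single document of every stage parameter, defaulting to the
    study's printed thresholds."""

    seed: int = 0
    outdir: str = "crossregen_run"
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    tau: float = 7.0
    fdr_cut: float = 0.01
    lfc_cut: float = 1.0
    relax_fdr: float = 0.05
    relax_min: int = 50
    n_clusters: int = 5
    fuzzifier: float = 1.25
    membership: float = 0.7
    share_cut: float = 0.98
    edge_cut: float = 0.4
    ora_fdr: float = 0.1
    gage_fdr: float = 0.01
    context_cut: float = -0.2
    rho_cut: float = -0.4
    interaction_fdr: float = 0.05
    overlap_fdr: float = 0.01
    top_k: int = 15
    target_p: float = 0.01
    skip: tuple = ()

    _RANGES = {
        "fdr_cut": (0, 1), "relax_fdr": (0, 1), "membership": (0, 1),
        "share_cut": (0, 1), "edge_cut": (0, 1), "ora_fdr": (0, 1),
        "gage_fdr": (0, 1), "interaction_fdr": (0, 1), "overlap_fdr": (0, 1),
        "target_p": (0, 1),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.tau <= 0 or self.fuzzifier <= 1:
            raise ValueError("tau must be > 0 and fuzzifier > 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def canonical(self) -> str:
        """Canonical JSON of the analysis parameters (the output
        location does not affect results and is excluded)."""
        doc = asdict(self)
        doc.pop("outdir", None)
        return json.dumps(doc, sort_keys=True, default=list)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the full synthetic pipeline; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        written.append(path)

    state: dict = {}
    for stage in STAGES:
        if stage in config.skip:
            continue
        try:
            _STAGE_FUNCS[stage](config, state, emit)
        except Exception as exc:  # noqa: BLE001 - rethrown with stage context
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = "ok"
    for path in written:
        manifest["outputs"][path.name] = _sha256(path)
    io.write_json(manifest, out / "manifest.json")
    return manifest


def _stage_simulate(config, state, emit):
    sim_cfg = SimConfig(seed=config.seed, **config.sim)
    tc, tc_truth = simulate_timecourse(sim_cfg)
    co, co_mi, co_truth = simulate_paired_cohort(sim_cfg)
    state.update(sim_cfg=sim_cfg, tc=tc, tc_truth=tc_truth, co=co, co_mi=co_mi,
                 co_truth=co_truth)
    state["sets_hs"] = emit_genesets(sim_cfg, co_truth, genes=list(co.genes))
    state["omap"] = emit_orthomap(sim_cfg)
    state["sets_dr"] = enrichment.GeneSetCollection(
        {n: ortho.map_term_genes(s, state["omap"], mode="expand")
         for n, s in state["sets_hs"].items()},
        provenance="synthetic",
    )
    state["targets"] = emit_targets(sim_cfg, co_truth, genes=list(co.genes))
    emit("timecourse_counts.tsv", lambda p: io.write_counts(tc, p, p.parent / "timecourse_meta.tsv"))
    emit("cohort_counts.tsv", lambda p: io.write_counts(co, p, p.parent / "cohort_meta.tsv"))
    emit("cohort_mirna_counts.tsv",
         lambda p: io.write_counts(co_mi, p, p.parent / "cohort_mirna_meta.tsv"))
    emit("genesets.gmt", lambda p: enrichment.write_gmt(state["sets_hs"], p))
    emit("orthomap.tsv", lambda p: io.write_orthomap(state["omap"], p))
    emit("targets.tsv", lambda p: io.write_targets(state["targets"], p))
    emit("truth.json", lambda p: co_truth.to_json(p))


def _stage_normalize(config, state, emit):
    for key, name in (("tc", "timecourse"), ("co", "cohort"), ("co_mi", "cohort_mirna")):
        cm = counts.filter_low_expression(state[key])
        fac = counts.tmm_factors(cm)
        state[key + "_f"] = cm
        state[key + "_fac"] = fac
        state[key + "_expr"] = counts.log_cpm(cm, fac)
        emit(f"{name}_factors.tsv", lambda p, f=fac: io.write_factors(f, p))


def _stage_de(config, state, emit):
    de = diffexp.paired_de(state["co_f"], state["co_fac"])
    de = diffexp.call_degs(de, config.fdr_cut, config.lfc_cut,
                           config.relax_fdr, config.relax_min)
    state["de"] = de
    de_mi = diffexp.paired_de(state["co_mi_f"], state["co_mi_fac"])
    state["de_mi"] = diffexp.call_degs(de_mi, config.relax_fdr, 0.5, None, 0)
    emit("cohort_de.tsv", lambda p: io.write_table(de.table, p, index_label="gene_id"))
    emit("cohort_mirna_de.tsv",
         lambda p: io.write_table(state["de_mi"].table, p, index_label="mirna_id"))


def _stage_timecourse(config, state, emit):
    model = dynamic.control_weights(
        sorted(state["tc_f"].meta["timepoint"].dropna().unique()), config.tau
    )
    traj = dynamic.timecourse_de(state["tc_f"], state["tc_fac"], model)
    state["traj"] = traj
    state["union"] = dynamic.union_degs(traj, config.fdr_cut, config.lfc_cut)
    emit("trajectory_lfc.tsv", lambda p: io.write_table(traj.lfc, p, "gene_id"))
    emit("trajectory_fdr.tsv", lambda p: io.write_table(traj.fdr, p, "gene_id"))


def _stage_cluster(config, state, emit):
    z = clustering.zscore_rows(state["traj"].lfc.loc[state["union"]])
    assign = clustering.fuzzy_cmeans(
        z, c=config.n_clusters, m=config.fuzzifier, seed=config.seed
    )
    state["assign"] = assign
    state["cores"] = clustering.core_genes(assign, config.membership)
    emit("membership.tsv", lambda p: io.write_table(assign.membership, p, "gene_id"))
    emit("centers.tsv", lambda p: io.write_table(assign.centers, p, "cluster"))
    emit("core_sets.gmt", lambda p: enrichment.write_gmt(
        enrichment.GeneSetCollection(
            {c: set(g) for c, g in state["cores"].items() if g}), p))


def _stage_enrich(config, state, emit):
    universe_dr = set(state["tc_f"].genes)
    centers = state["assign"].centers
    cluster_res = {}
    for cl, genes in state["cores"].items():
        if not genes:
            continue
        # direction = sign of the cluster's (z-scored) center at its
        # strongest excursion; tags the ORA rows for the heatmaps
        center = centers.loc[cl]
        direction = "up" if center.iloc[int(np.argmax(np.abs(center)))] > 0 else "down"
        cluster_res[cl] = enrichment.ora_fisher(
            set(genes), state["sets_dr"], universe_dr, direction=direction)
    state["cluster_enrich"] = cluster_res
    gage = enrichment.gage_paired(state["co_expr"], state["co_f"].meta,
                                  state["sets_hs"].restrict(set(state["co_f"].genes), 2))
    state["gage"] = gage
    rows = [df.assign(condition=cl) for cl, df in cluster_res.items()]
    emit("cluster_enrichment.tsv", lambda p: io.write_table(
        pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(), p))
    emit("cohort_gage.tsv", lambda p: io.write_table(gage, p))


def _stage_network(config, state, emit):
    cluster_terms = {}
    for cl, df in state["cluster_enrich"].items():
        sig = df[df["fdr"] < config.ora_fdr]
        cluster_terms[cl] = [
            (r["term"], state["sets_dr"].sets[r["term"]], r["p"])
            for _, r in sig.iterrows()
        ]
    g = network.build_network(cluster_terms, config.edge_cut, config.share_cut)
    state["network"] = g
    emit("term_network.graphml", lambda p: network.export_network(g, graphml_path=p))
    emit("term_network.gexf", lambda p: network.export_network(g, gexf_path=p))


def _stage_compare(config, state, emit):
    results = {"cohort": state["gage"]}
    cutoffs = {"cohort": ("fdr", config.gage_fdr)}
    for cl, df in state["cluster_enrich"].items():
        results[cl] = df
        cutoffs[cl] = ("fdr", config.ora_fdr)
    sig = enrichment.significance_matrix(results, cutoffs)
    state["sig"] = sig
    cluster_cols = [c for c in sig.columns if c != "cohort"]
    state["concordance"] = ortho.concordance(sig[["cohort"]], sig[cluster_cols])
    hc = ortho.hclust_binary(sig)
    emit("significance_matrix.tsv", lambda p: io.write_table(sig, p, "term"))
    emit("concordance.tsv", lambda p: io.write_table(state["concordance"], p, "cluster"))
    emit("dendrogram_orders.json", lambda p: io.write_json(
        {axis: [str(x) for x in hc[axis]["order"]] for axis in hc}, p))


def _stage_mirna(config, state, emit):
    cand = mirna.filter_targets(state["targets"], config.context_cut)
    inter = mirna.correlate_pairs(
        state["co_expr"], state["co_mi_expr"], cand,
        mrna_calls=state["de"].table["call"],
        mirna_calls=state["de_mi"].table["call"],
        rho_cut=config.rho_cut, fdr_cut=config.interaction_fdr,
    )
    groups = mirna.top_k(mirna.merge_mirnas(inter, overlap_fdr=config.overlap_fdr),
                         config.top_k)
    target_enrich = mirna.enrich_targets(
        groups, state["sets_hs"], set(state["co_f"].genes), config.target_p)
    state["interactions"] = inter
    state["groups"] = groups
    state["target_enrich"] = target_enrich
    emit("interactions.tsv", lambda p: io.write_table(inter, p))
    emit("mirna_groups.json", lambda p: io.write_json(
        [{"rank": g.rank, "members": g.members, "n_targets": g.n_targets,
          "targets": sorted(g.targets)} for g in groups], p))
    rows = [df.assign(group=lead) for lead, df in target_enrich.items()]
    emit("target_enrichment.tsv", lambda p: io.write_table(
        pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(), p))


def _stage_report(config, state, emit):
    summary = {
        "n_union_degs": int(len(state["union"])),
        "cluster_sizes": {c: len(g) for c, g in state["cores"].items()},
        "n_de_up": state["de"].n_up,
        "n_de_down": state["de"].n_down,
        "de_relaxation_applied": bool(state["de"].relaxation_applied),
        "n_valid_interactions": int(state["interactions"]["valid"].sum())
        if len(state["interactions"]) else 0,
        "n_mirna_groups": len(state["groups"]),
    }
    emit("summary.json", lambda p: io.write_json(summary, p))
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        enc = ortho.encode_significance(state["sig"])
        fig, ax = plt.subplots(figsize=(6, max(3, 0.2 * len(enc))))
        ax.imshow(enc.to_numpy(), aspect="auto", cmap="coolwarm", vmin=-1, vmax=1)
        ax.set_xticks(range(len(enc.columns)))
        ax.set_xticklabels(enc.columns, rotation=90, fontsize=6)
        ax.set_yticks([])
        fig.tight_layout()
        emit("significance_heatmap.png", lambda p: fig.savefig(p, dpi=100))
        plt.close(fig)
    except Exception:  # pragma: no cover - plotting is best-effort
        pass


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "de": _stage_de,
    "timecourse": _stage_timecourse,
    "cluster": _stage_cluster,
    "enrich": _stage_enrich,
    "network": _stage_network,
    "compare": _stage_compare,
    "mirna": _stage_mirna,
    "report": _stage_report,
}
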