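"""End-to-end orchestration: synthetic or user data through filtering,
cross-site differential expression, seasonal-bias classification,
enrichment, the four co-expression networks, interface scoring, mediation
screening, ordination and (optionally) qPCR normalisation.

Stages run in a fixed order; a failing stage marks the bundle partial and
its downstream dependents are skipped with a recorded reason.  A single
seed, recorded in the manifest together with a config hash, determines
every stochastic step.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .study import ExpressionStudy
from . import de, enrich, minet, ordination, qnorm, syndata

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ResultsBundle", "run_pipeline", "reduce_orthologues"]

#: per-network candidate-edge p cut and marker correction for the four
#: network designs (1: core hubs only; 2: all biased genes, core hubs;
#: 3: all immune genes, core hubs; 4: core + organismal genes, all hubs).
#: The per-resample threshold only generates candidate edges; the final
#: control on reported edges is the bootstrap-consensus cut (edge_p_cut).
#: At n ~ 36 samples a marker-corrected per-resample cut leaves the
#: candidate set empty, so the defaults use an uncorrected 1e-4; stricter
#: marker-corrected cuts remain available through the config.
DEFAULT_NETWORK_PARAMS = {
    "network1": {"p_cut": 1e-4, "marker_correction": False},
    "network2": {"p_cut": 1e-4, "marker_correction": False},
    "network3": {"p_cut": 1e-4, "marker_correction": False},
    "network4": {"p_cut": 1e-4, "marker_correction": False},
}


@dataclass
class PipelineConfig:
    # input: either a synthetic config or three TSV paths
    syn: syndata.SynConfig | None = None
    matrix_path: str | None = None
    samples_path: str | None = None
    genes_path: str | None = None
    gmt_path: str | None = None      # gene sets (orthologue symbol space)
    ct_path: str | None = None       # optional long-format Ct table

    alpha: float = 0.05
    pseudocount: float = 1.0
    filter_mean_min: float = 0.5
    filter_max_undetected: float = 0.5

    gsea_n_perm: int = 200
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    gsea_weight: float = 1.0

    network_params: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_NETWORK_PARAMS.items()}
    )
    dpi_tolerance: float = 0.0
    n_boot: int = 200
    edge_p_cut: float = 1e-6
    n_null_pairs: int = 2000
    cross_min: int = 1
    within_quantile: float = 0.5
    organismal_cap: int = 80         # max organismal genes added to network 4

    seed: int = 0
    outdir: str | None = None
    paper_scale: bool = False        # n_boot=2000, gsea_n_perm=1000

    def __post_init__(self) -> None:
        if self.paper_scale:
            self.n_boot = 2000
            self.gsea_n_perm = 1000
        if self.syn is None and self.matrix_path is None:
            self.syn = syndata.SynConfig(seed=self.seed)
        for p in (self.matrix_path, self.samples_path, self.genes_path,
                  self.gmt_path, self.ct_path):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(p)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.syn is not None:
            d["syn"] = asdict(self.syn)
            d["syn"]["sites"] = list(self.syn.sites)
            d["syn"]["length_range_mm"] = list(self.syn.length_range_mm)
        return d

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    config: PipelineConfig
    stages: dict[str, dict] = field(default_factory=dict)
    study: ExpressionStudy | None = None
    filter_report: Any = None
    de_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    bias_table: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    networks: dict[str, nx.Graph] = field(default_factory=dict)
    topology: dict[str, pd.DataFrame] = field(default_factory=dict)
    modules: dict[str, dict] = field(default_factory=dict)
    module_overlap: dict[str, tuple] = field(default_factory=dict)
    interface: pd.DataFrame | None = None
    edge_partition: Any = None
    mediation: pd.DataFrame | None = None
    pco: Any = None
    qnorm_audit: pd.DataFrame | None = None
    qnorm_stability: Any = None
    relative_expression: pd.DataFrame | None = None

    @property
    def partial(self) -> bool:
        return any(s["status"] == "failed" for s in self.stages.values())

    def manifest(self) -> dict:
        import scipy
        return {
            "package": "seasonet",
            "version": __version__,
            "lib_versions": {
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "networkx": nx.__version__,
            },
            "seed": self.config.seed,
            "config_hash": self.config.config_hash(),
            "config": self.config.to_dict(),
            "stages": self.stages,
            "partial": self.partial,
        }

    # -- disk output -------------------------------------------------------
    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        if self.study is not None:
            self.study.write_tsv(outdir, prefix="filtered")
        for site, tbl in self.de_tables.items():
            tbl.to_csv(os.path.join(outdir, f"de_{site}.tsv"), sep="\t",
                       index_label="gene")
        if self.bias_table is not None:
            self.bias_table.to_csv(
                os.path.join(outdir, "seasonal_bias.tsv"), sep="\t",
                index_label="gene")
        if self.enrichment is not None:
            self.enrichment.to_csv(
                os.path.join(outdir, "enrichment.tsv"), sep="\t",
                index_label="set")
        for name, G in self.networks.items():
            nx.write_graphml(G, os.path.join(outdir, f"{name}.graphml"))
            minet.write_sif(G, os.path.join(outdir, f"{name}.sif"))
        for name, tbl in self.topology.items():
            tbl.to_csv(os.path.join(outdir, f"{name}_topology.tsv"),
                       sep="\t", index_label="gene")
        for name, mods in self.modules.items():
            rows = [(h, len(m), ";".join(sorted(m))) for h, m in mods.items()]
            pd.DataFrame(rows, columns=["hub", "size", "members"]).to_csv(
                os.path.join(outdir, f"{name}_modules.tsv"), sep="\t",
                index=False)
        if self.interface is not None:
            self.interface.to_csv(os.path.join(outdir, "interface.tsv"),
                                  sep="\t", index=False)
        if self.mediation is not None:
            self.mediation.to_csv(os.path.join(outdir, "mediation.tsv"),
                                  sep="\t", index=False)
        if self.pco is not None:
            self.pco.scores.to_csv(os.path.join(outdir, "pco_scores.tsv"),
                                   sep="\t", index_label="sample")
            self.pco.axis_tests.to_csv(
                os.path.join(outdir, "pco_axis_tests.tsv"), sep="\t")
        if self.qnorm_audit is not None:
            self.qnorm_audit.to_csv(os.path.join(outdir, "qnorm_screen.tsv"),
                                    sep="\t", index_label="gene")
        if self.qnorm_stability is not None:
            self.qnorm_stability.table.to_csv(
                os.path.join(outdir, "qnorm_stability.tsv"), sep="\t",
                index_label="gene")
        if self.relative_expression is not None:
            self.relative_expression.to_csv(
                os.path.join(outdir, "relative_expression.tsv"), sep="\t",
                index_label="sample")
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)


def reduce_orthologues(
    genes: pd.DataFrame, seed: int = 0
) -> pd.Series:
    """One-to-one orthologue reduction of the annotation.

    Genes without an orthologue symbol are dropped; where several genes
    share a symbol a single gene is randomly retained (seeded).  Returns a
    gene -> symbol mapping over the retained genes.
    """
    rng = np.random.default_rng(seed)
    orth = genes["orthologue"].dropna()
    orth = orth[orth.astype(str).str.len() > 0]
    keep = []
    for _, grp in orth.groupby(orth.values):
        idx = list(grp.index)
        keep.append(idx[rng.integers(len(idx))])
    return orth.loc[sorted(keep)]


def _stage(bundle: ResultsBundle, name: str, depends: list[str] | None = None):
    """Decorator-style stage runner with dependency-aware skipping."""
    def run(fn):
        for dep in depends or []:
            if bundle.stages.get(dep, {}).get("status") != "ok":
                bundle.stages[name] = {
                    "status": "skipped",
                    "reason": f"dependency {dep} not satisfied",
                }
                log.info("stage %-12s skipped (needs %s)", name, dep)
                return None
        try:
            info = fn() or {}
            bundle.stages[name] = {"status": "ok", **info}
            log.info("stage %-12s ok %s", name, info)
            return True
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            bundle.stages[name] = {"status": "failed", "reason": str(exc)}
            log.warning("stage %-12s failed: %s", name, exc)
            return None
    return run


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Execute the full analysis; returns a :class:`ResultsBundle`.

    Stage order: input -> filter -> per-site DE -> bias classification ->
    orthologue reduction + enrichment -> networks 1-4 (with bootstrap
    consensus, topology, modules and overlap graphs) -> interface scoring
    -> mediation screen over key genes -> ordination -> qPCR screening.
    """
    bundle = ResultsBundle(config=config)
    state: dict[str, Any] = {}

    @_stage(bundle, "input")
    def _input():
        if config.matrix_path is not None:
            state["study"] = ExpressionStudy.read_tsv(
                config.matrix_path, config.samples_path, config.genes_path
            )
        else:
            state["study"], state["truth"] = syndata.generate_study(config.syn)
        s = state["study"]
        return {"n_genes": s.n_genes, "n_samples": s.n_samples}

    @_stage(bundle, "filter", depends=["input"])
    def _filter():
        filtered, report = de.filter_low_expression(
            state["study"], config.filter_mean_min, config.filter_max_undetected
        )
        state["study"] = filtered
        bundle.study = filtered
        bundle.filter_report = report
        return {"n_kept": report.n_kept, "n_removed": report.n_input - report.n_kept}

    @_stage(bundle, "de", depends=["filter"])
    def _de():
        study = state["study"]
        sites = study.sites
        if len(sites) != 2:
            raise ValueError(f"expected 2 sites, found {len(sites)}")
        for site in sites:
            bundle.de_tables[site] = de.per_site_de(
                study, site, config.pseudocount
            )
        return {"sites": sites}

    @_stage(bundle, "classify", depends=["de"])
    def _classify():
        a, b = (bundle.de_tables[s] for s in state["study"].sites)
        bundle.bias_table = de.classify_seasonal_bias(a, b, config.alpha)
        return {
            "n_winter": bundle.bias_table.attrs["n_winter"],
            "n_summer": bundle.bias_table.attrs["n_summer"],
        }

    @_stage(bundle, "enrich", depends=["classify"])
    def _enrich():
        study = state["study"]
        orth = reduce_orthologues(study.genes, config.seed)
        if config.gmt_path is not None:
            sets = enrich.read_gmt(config.gmt_path)
        elif "truth" in state:
            sets = syndata.planted_gene_sets(state["truth"], use_orthologues=True)
        else:
            raise ValueError("no gene sets: provide a GMT file")
        state["gene_sets"] = sets
        per_site = {}
        for site in study.sites:
            ranked = de.ranking_metric(bundle.de_tables[site], "fold")
            ranked = ranked[ranked.index.isin(orth.index)]
            ranked.index = orth.loc[ranked.index]
            per_site[site] = enrich.gsea_preranked(
                ranked, sets,
                n_perm=config.gsea_n_perm, weight=config.gsea_weight,
                min_size=config.gsea_min_size, max_size=config.gsea_max_size,
                seed=config.seed,
            )
        a, b = (per_site[s] for s in study.sites)
        bundle.enrichment = enrich.combine_sites(a, b)
        return {"n_sets": len(bundle.enrichment)}

    # ------------------------------------------------------------------ nets
    @_stage(bundle, "networks", depends=["classify"])
    def _networks():
        study = state["study"]
        genes = study.genes
        bias = bundle.bias_table["class"]
        biased = bias.index[bias != "none"]
        core = genes.index[genes["core_flag"]].intersection(biased)
        immune = genes.index[genes["immune_flag"]]
        if len(core) < 3:
            raise ValueError("fewer than 3 seasonally-biased core genes")
        state["core"] = core

        org_genes = pd.Index([])
        if "gene_sets" in state or "truth" in state:
            sets = state.get("gene_sets") or syndata.planted_gene_sets(
                state["truth"], use_orthologues=True
            )
            symbols = {
                g
                for name, members in sets.items()
                if name.startswith("organismal")
                for g in members
            }
            orth_all = genes["orthologue"]
            org_genes = genes.index[orth_all.isin(symbols)][: config.organismal_cap]
        designs = {
            "network1": (core, core),
            "network2": (biased, core),
            "network3": (immune, core),
            "network4": (core.union(org_genes), core.union(org_genes)),
        }
        info = {}
        rng = np.random.default_rng(config.seed)
        for name, (nodes, hubs) in designs.items():
            if len(nodes) < 3 or len(hubs) == 0:
                bundle.stages[f"{name}"] = {
                    "status": "skipped", "reason": "too few genes"}
                continue
            sub = study.subset_genes(nodes)
            pars = config.network_params[name]
            thr = minet.calibrate_mi_threshold(
                sub,
                p_cut=pars["p_cut"],
                marker_correction=pars["marker_correction"],
                n_null_pairs=config.n_null_pairs,
                seed=int(rng.integers(2**31 - 1)),
                pseudocount=config.pseudocount,
            )
            G = minet.bootstrap_consensus(
                sub, list(hubs), thr,
                dpi_tolerance=config.dpi_tolerance,
                n_boot=config.n_boot,
                edge_p_cut=config.edge_p_cut,
                seed=int(rng.integers(2**31 - 1)),
                pseudocount=config.pseudocount,
                bias_labels=bias.reindex(nodes),
            )
            bundle.networks[name] = G
            bundle.topology[name] = minet.node_topology(G)
            mods = minet.extract_modules(G, list(hubs))
            bundle.modules[name] = mods
            if name in ("network2", "network3") and len(mods) >= 2:
                bias_sets = {
                    "winter_biased": set(bias.index[bias == "winter"]),
                    "summer_biased": set(bias.index[bias == "summer"]),
                }
                bundle.module_overlap[name] = minet.module_overlap_graph(
                    mods, 0.1, bias_sets, universe=set(nodes)
                )
            info[name] = {
                "nodes": G.number_of_nodes(),
                "edges": G.number_of_edges(),
                "mi_threshold": round(thr.threshold, 4),
            }
        if not bundle.networks:
            raise ValueError("no networks could be built")
        return info

    @_stage(bundle, "interface", depends=["networks"])
    def _interface():
        if "network1" not in bundle.networks:
            raise ValueError("network1 unavailable")
        bias = bundle.bias_table["class"]
        bundle.interface = minet.interface_scores(
            bundle.networks["network1"],
            bias.loc[state["core"]],
            cross_min=config.cross_min,
            within_quantile=config.within_quantile,
            core_nodes=list(state["core"]),
        )
        keys = bundle.interface.loc[bundle.interface["key"], "gene"]
        state["key_genes"] = list(keys)
        if "network4" in bundle.networks:
            genes = state["study"].genes
            G4 = bundle.networks["network4"]
            immune_flags = genes["immune_flag"].reindex(G4.nodes).fillna(False)
            key_flags = {
                g: g in set(state["key_genes"])
                for g in state["core"] if g in G4
            }
            bundle.edge_partition = minet.edge_partition_stats(
                G4, immune_flags, key_flags
            )
        return {"n_key": len(state["key_genes"])}

    @_stage(bundle, "mediate", depends=["interface"])
    def _mediate():
        study = state["study"]
        bias = bundle.bias_table["class"]
        keys = set(state["key_genes"])
        winter_core = [g for g in state["core"]
                       if bias[g] == "winter" and g not in keys]
        summer_core = [g for g in state["core"]
                       if bias[g] == "summer" and g not in keys]
        if len(winter_core) < 2 or len(summer_core) < 2:
            raise ValueError("not enough non-key core genes for PC1 scores")
        W, _ = ordination.pc1_scores(study, winter_core, config.pseudocount)
        S, _ = ordination.pc1_scores(study, summer_core, config.pseudocount)
        L = study.log2(config.pseudocount)
        rows = []
        for gene in sorted(keys):
            fit = ordination.path_mediation(
                W.to_numpy(), S.to_numpy(), L.loc[gene].to_numpy(),
                alpha=config.alpha,
            )
            d = dataclasses.asdict(fit)
            d["gene"] = gene
            rows.append(d)
        bundle.mediation = pd.DataFrame(rows)
        if rows:
            cols = ["gene"] + [c for c in bundle.mediation.columns if c != "gene"]
            bundle.mediation = bundle.mediation[cols]
        return {"n_key_genes": len(rows),
                "n_negation": int(bundle.mediation["negation"].sum()) if rows else 0}

    @_stage(bundle, "ordination", depends=["filter"])
    def _ordination():
        study = state["study"]
        immune = study.genes.index[study.genes["immune_flag"]]
        subset = immune if len(immune) >= 3 else None
        bundle.pco = ordination.pco_ordination(
            study, subset, k=3, pseudocount=config.pseudocount
        )
        return {"axes": bundle.pco.scores.shape[1]}

    @_stage(bundle, "qnorm", depends=["classify"])
    def _qnorm():
        study = state["study"]
        candidates, audit = qnorm.screen_control_candidates(
            study, bundle.bias_table
        )
        bundle.qnorm_audit = audit
        info = {"n_candidates": len(candidates)}
        if len(candidates) >= 3:
            top = candidates[:20]
            bundle.qnorm_stability = qnorm.stability_rank(
                study.matrix.loc[top], study.samples["season"]
            )
            info["best_pair"] = list(bundle.qnorm_stability.best_pair)
        if config.ct_path is not None:
            ct = qnorm.read_ct_csv(config.ct_path)
            targets = sorted(ct.loc[ct["role"] == "target", "gene"].unique())
            controls = sorted(ct.loc[ct["role"] == "control", "gene"].unique())
            bundle.relative_expression = qnorm.relative_expression(
                ct, targets, controls, mode="ddct"
            )
            info["n_qpcr_targets"] = len(targets)
        return info

    if config.outdir:
        bundle.write(config.outdir)
    return bundle
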