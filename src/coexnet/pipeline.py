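"""End-to-end orchestration: simulate (or load) expression matrices, infer
one MI network per phenotype, detect and filter communities, run ORA,
compare communities across networks into similarity clusters, and call
moderated differential expression against the reference phenotype.

Every stage writes plain TSV/GMT/GraphML so it can be rerun or inspected
independently; a JSON manifest records parameters, derived seeds and
stage wall times, and the whole run is deterministic given the seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community_comparison as cc
from . import community_detection as cd
from . import differential_expression as de
from . import enrichment as en
from . import mi_network as mi
from . import synthetic_data as sd


@dataclass
class RunConfig:
    """Single source of parameters for a full run."""

    synthetic: str | None = "benchmark"  # 'benchmark', 'small', or None
    expression_dir: str | None = None  # TSVs named <phenotype>.tsv
    reference: str | None = None  # required when loading from TSVs
    gmt: str | None = None  # annotation GMT; synthetic runs generate one
    top_k: int = 1200  # 0.06% of the benchmark's 1,999,000 pairs
    n_bins: int | None = None  # None -> max(2, floor(sqrt(n)/2))
    block_size: int = 256
    min_community_size: int = 10
    n_trials: int = 10
    alpha: float = 0.05
    keywords: list = field(default_factory=lambda: ["immun", "inflamm"])
    compare_all: bool = False  # compare all communities, not just selected
    tau: float = 0.2
    lfc_thresh: float = 1.0
    b_thresh: float = 6.0
    p_prior: float = 0.01
    n_decoy_terms: int = 50
    decoy_size: int = 20
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def validate_config(config: RunConfig) -> list:
    """Range and consistency checks; returns a list of problems (empty
    when the config is valid)."""
    problems = []
    if config.synthetic is None and config.expression_dir is None:
        problems.append("either synthetic or expression_dir must be set")
    if config.synthetic not in (None, "benchmark", "small"):
        problems.append(f"unknown synthetic design {config.synthetic!r}")
    if config.expression_dir is not None:
        p = Path(config.expression_dir)
        if not p.is_dir():
            problems.append(f"expression_dir {p} does not exist")
        elif not list(p.glob("*.tsv")):
            problems.append(f"expression_dir {p} contains no .tsv matrices")
        if config.reference is None and config.synthetic is None:
            problems.append("reference phenotype required with expression_dir")
    if config.gmt is not None and not Path(config.gmt).is_file():
        problems.append(f"gmt {config.gmt} does not exist")
    if config.top_k < 1:
        problems.append("top_k must be >= 1")
    if not 0 <= config.tau <= 1:
        problems.append("tau must lie in [0, 1]")
    if not 0 < config.alpha < 1:
        problems.append("alpha must lie in (0, 1)")
    if config.min_community_size < 1:
        problems.append("min_community_size must be >= 1")
    if not config.keywords and not config.compare_all:
        problems.append("keywords must be non-empty unless compare_all is set")
    return problems


@dataclass
class RunReport:
    """In-memory results of a full run plus the manifest."""

    config: RunConfig
    design: sd.SyntheticDesign | None
    expression: dict
    annotations: en.AnnotationDB
    networks: dict
    partitions: dict
    community_sets: dict
    ora: pd.DataFrame
    summaries: pd.DataFrame
    selected: set
    records: pd.DataFrame
    meta_network: object
    clusters: list
    de_tables: dict
    de_profile: pd.DataFrame
    exclusive: dict
    manifest: dict


def _load_expression(config: RunConfig) -> tuple:
    if config.synthetic is not None:
        design = (
            sd.benchmark_design(config.seed)
            if config.synthetic == "benchmark"
            else sd.small_design(config.seed)
        )
        expr = sd.generate_expression(design)
        reference = design.reference
        return design, expr, reference
    expr = {}
    for path in sorted(Path(config.expression_dir).glob("*.tsv")):
        phen = path.stem
        expr[phen] = mi.ExpressionMatrix.from_tsv(path, phenotype=phen)
    universes = {p: frozenset(m.genes) for p, m in expr.items()}
    first = next(iter(universes.values()))
    bad = {p for p, u in universes.items() if u != first}
    if bad:
        raise ValueError(
            f"gene universes differ across phenotype matrices: {sorted(bad)}"
        )
    if config.reference not in expr:
        raise ValueError(f"reference {config.reference!r} has no matrix")
    return None, expr, config.reference


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage in order for every phenotype.

    Stage failures raise with a stage-tagged message; outputs written so
    far are left in place next to a STAGE_FAILED marker.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "stages": {},
        "versions": _versions(),
    }
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        design, expr, reference = _load_expression(config)
        phens = list(expr)
        if design is not None and config.gmt is None:
            annotations = sd.generate_annotations(
                design, config.n_decoy_terms, config.decoy_size
            )
        elif config.gmt is not None:
            annotations = en.AnnotationDB.from_gmt(config.gmt)
        else:
            raise ValueError("a GMT annotation file is required for real data")
        if out:
            for p, m in expr.items():
                m.to_tsv(out / f"expression_{p}.tsv")
            annotations.to_gmt(out / "annotations.gmt")
            if design is not None:
                truth = sd.planted_truth(design)
                for name, df in truth.items():
                    df.to_csv(out / f"truth_{name}.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "phenotypes": phens,
            "reference": reference,
        }

        # derived per-stage seeds, all below 2**31
        seed_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31]))
        detect_seeds = {p: int(seed_rng.integers(2**31)) for p in phens}

        stage = "network"
        t0 = time.perf_counter()
        networks = {}
        for p in phens:
            pairs = mi.all_pairs_mi(expr[p], config.n_bins, config.block_size)
            networks[p] = mi.top_k_threshold(pairs, config.top_k, phenotype=p)
            if out:
                networks[p].to_tsv(out / f"edges_{p}.tsv")
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "top_k": config.top_k,
            "edges": {p: networks[p].n_edges for p in phens},
        }

        stage = "communities"
        t0 = time.perf_counter()
        partitions = {}
        community_sets = {}
        for p in phens:
            partitions[p] = cd.detect_communities(
                networks[p], seed=detect_seeds[p], n_trials=config.n_trials
            )
            community_sets[p] = cd.filter_communities(
                partitions[p], networks[p], config.min_community_size, p
            )
            if out:
                partitions[p].to_tsv(out / f"partition_{p}.tsv")
                community_sets[p].to_tsv(out / f"communities_{p}.tsv")
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "seeds": detect_seeds,
        }

        stage = "enrichment"
        t0 = time.perf_counter()
        ora_frames = []
        sig_by_net = {}
        selected: set = set()
        summaries = []
        for p in phens:
            universe = frozenset(networks[p].nodes) & annotations.universe
            res = en.ora_all_communities(
                community_sets[p], annotations, universe
            )
            ora_frames.append(res)
            sig = en.significant_terms(res, config.alpha)
            sig_by_net[p] = set().union(*sig.values()) if sig else set()
            sel = (
                {c.label for c in community_sets[p]}
                if config.compare_all
                else en.select_communities_by_terms(
                    res, config.keywords, config.alpha
                )
                if len(res)
                else set()
            )
            selected |= sel
            summaries.append(
                cd.network_summary(
                    networks[p],
                    partitions[p],
                    community_sets[p],
                    res,
                    config.alpha,
                    sel,
                )
            )
        ora = (
            pd.concat(ora_frames, ignore_index=True)
            if ora_frames
            else pd.DataFrame(columns=en.RESULT_COLUMNS)
        )
        exclusive = en.exclusive_terms(sig_by_net) if len(sig_by_net) > 1 else {}
        summary_df = pd.DataFrame(summaries)
        if out:
            ora.to_csv(out / "ora_results.tsv", sep="\t", index=False)
            summary_df.to_csv(out / "network_summary.tsv", sep="\t", index=False)
            mat = en.significance_matrix(ora, config.alpha)
            mat.to_csv(out / "significance_matrix.tsv", sep="\t")
            pd.DataFrame(
                [(n, t) for n, ts in exclusive.items() for t in sorted(ts)],
                columns=["network", "term"],
            ).to_csv(out / "exclusive_terms.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "selected_communities": len(selected),
        }

        stage = "comparison"
        t0 = time.perf_counter()
        compared = {
            p: [c for c in community_sets[p] if c.label in selected]
            for p in phens
        }
        records = cc.all_pairs_similarity(compared)
        meta = cc.build_meta_network(records, compared)
        clusters = cc.extract_similarity_clusters(
            meta, records, config.tau, compared
        )
        if out:
            records.to_csv(out / "similarity_records.tsv", sep="\t", index=False)
            import networkx as nx

            nx.write_graphml(meta, out / "meta_network.graphml")
            rows = [
                (c.cluster_id, net, label)
                for c in clusters
                for net, label in c.members
            ]
            pd.DataFrame(
                rows, columns=["cluster", "network", "community"]
            ).to_csv(out / "clusters.tsv", sep="\t", index=False)
            for c in clusters:
                c.gene_matrix.to_csv(
                    out / f"cluster_{c.cluster_id}_gene_jaccard.tsv", sep="\t"
                )
                c.edge_matrix.to_csv(
                    out / f"cluster_{c.cluster_id}_edge_jaccard.tsv", sep="\t"
                )
            if clusters:
                cc.cluster_overlap_matrix(clusters).to_csv(
                    out / "cluster_overlap.tsv", sep="\t"
                )
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "n_clusters": len(clusters),
        }

        stage = "differential_expression"
        t0 = time.perf_counter()
        de_tables = {}
        for p in phens:
            if p == reference:
                continue
            de_tables[p] = de.run_de(
                expr[p],
                expr[reference],
                config.lfc_thresh,
                config.b_thresh,
                config.p_prior,
            )
            if out:
                de_tables[p].to_csv(out / f"de_{p}.tsv", sep="\t", index=False)
        profile = de.community_de_profile(compared, de_tables)
        if out:
            profile.to_csv(out / "community_de_profile.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "contrasts": sorted(de_tables),
        }
    except Exception as err:
        if out:
            (out / "STAGE_FAILED").write_text(f"{stage}: {err}\n")
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    if out:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return RunReport(
        config=config,
        design=design,
        expression=expr,
        annotations=annotations,
        networks=networks,
        partitions=partitions,
        community_sets=community_sets,
        ora=ora,
        summaries=summary_df,
        selected=selected,
        records=records,
        meta_network=meta,
        clusters=clusters,
        de_tables=de_tables,
        de_profile=profile,
        exclusive=exclusive,
        manifest=manifest,
    )


def _versions() -> dict:
    import networkx
    import scipy
    import sklearn
    import statsmodels

    from . import __version__

    return {
        "coexnet": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }
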