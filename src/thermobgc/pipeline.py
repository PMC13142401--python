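"""Stage orchestration: simulate -> dereplicate -> features -> ordination -> stats.

Each stage reads its upstream artifacts from a run directory, never mutates
its inputs, and is idempotent given identical inputs and seeds.  A missing
upstream artifact raises an error naming the subcommand that produces it.
`run_all` executes the full chain and writes a reproducibility manifest
listing the seed, config digest, input digests and every threshold in
effect.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from thermobgc import __version__, features as feat, io, network as net, ordination as ordn, stats as uni
from thermobgc.sim import SimConfig, contigs_from_profile, simulate_study

logger = logging.getLogger("thermobgc.pipeline")

#: Analysis thresholds in effect unless overridden in the config file.
DEFAULT_THRESHOLDS = {
    "cutoff": net.DEFAULT_CUTOFF,
    "sentinel": net.DEFAULT_SENTINEL,
    "gcf_prevalence_fraction": feat.GCF_PREVALENCE_FRACTION,
    "taxon_prevalence_fraction": feat.TAXON_PREVALENCE_FRACTION,
    "support_threshold": feat.TAXON_SUPPORT_THRESHOLD,
    "n_taxonomy_pcs": feat.N_TAXONOMY_PCS,
    "n_permutations": ordn.DEFAULT_N_PERMUTATIONS,
    "k_range": list(ordn.DEFAULT_K_RANGE),
}

#: RDA constraints: the measured environmental gradients (tectonic setting
#: is *not* a constraint — sample clusters are discovered from site scores).
ENV_CONSTRAINTS = ["temperature", "pH", "conductivity", "crustal_thickness"]
#: Marginal PERMANOVA model: the key covariates plus the tectonic setting.
MARGINAL_TERMS = ["temperature", "pH", "crustal_thickness", "tectonic_setting"]


def load_config(path: str | Path | None) -> dict:
    """Load a key: value config file (YAML), merged over the defaults."""
    cfg = {"simulation": {}, "thresholds": dict(DEFAULT_THRESHOLDS)}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg["simulation"].update(user.get("simulation", {}))
        cfg["thresholds"].update(user.get("thresholds", {}))
    return cfg


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path}; run the `{producer}` subcommand first"
        )
    return path


def _write_manifest(rundir: Path, config: dict, seed: int) -> None:
    inputs = sorted((rundir / "inputs").glob("*")) if (rundir / "inputs").exists() else []
    manifest = {
        "version": __version__,
        "seed": int(seed),
        "config_sha256": io.config_digest(config),
        "thresholds": config.get("thresholds", dict(DEFAULT_THRESHOLDS)),
        "input_digests": {p.name: io.file_digest(p) for p in inputs if p.is_file()},
    }
    (rundir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_simulate(config: dict, rundir: str | Path, seed: int | None = None) -> SimConfig:
    """Generate a synthetic study and write all four input formats."""
    rundir = Path(rundir)
    simcfg = SimConfig(**config.get("simulation", {}))
    if seed is not None:
        simcfg.seed = int(seed)
    logger.info("simulate: config %s", simcfg)
    env, inventory, networks, taxonomy, truth = simulate_study(simcfg)
    contigs = contigs_from_profile(taxonomy, seed=simcfg.seed + 1)

    inputs = rundir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    io.write_metadata(inputs / "metadata.csv", env)
    io.write_inventory(inputs / "inventory.tsv", inventory)
    for cls, edges in networks.items():
        io.write_network(inputs / f"network_{cls}.tsv", edges)
    io.write_contigs(inputs / "contigs.tsv", contigs)
    truth_payload = {
        "family_of": truth.family_of,
        "reference_of_family": truth.reference_of_family,
        "family_class": truth.family_class,
        "composition": truth.composition.to_dict(),
        "cluster_labels": truth.cluster_labels.to_dict(),
        "depth_coefficient": truth.depth_coefficient,
        "novelty_ct_slope": truth.novelty_ct_slope,
    }
    (inputs / "ground_truth.json").write_text(json.dumps(truth_payload, indent=2, sort_keys=True) + "\n")
    (inputs / "config.yaml").write_text(yaml.safe_dump({"simulation": simcfg.to_dict()}))
    _write_manifest(rundir, {**config, "simulation": simcfg.to_dict()}, simcfg.seed)
    return simcfg


def run_dereplicate(rundir: str | Path, config: dict | None = None) -> None:
    """Build per-class networks, derive GCFs, and score novelty."""
    rundir = Path(rundir)
    config = config or load_config(None)
    thr = config["thresholds"]
    inventory = io.read_inventory(_require(rundir / "inputs" / "inventory.tsv", "simulate"))
    outdir = rundir / "derep"
    outdir.mkdir(parents=True, exist_ok=True)

    all_fams: list[net.GCF] = []
    novelty_frames = []
    sample_novelty_rows = []
    communities = {}
    for path in sorted((rundir / "inputs").glob("network_*.tsv")):
        cls = path.stem.replace("network_", "")
        edges = io.read_network(path)
        class_nodes = set(inventory.loc[inventory["bgc_class"] == cls, "bgc_id"])
        nodes = class_nodes | set(edges["bgc_a"]) | set(edges["bgc_b"])
        network = net.build_network(edges, nodes=nodes, cutoff=thr["cutoff"], bgc_class=cls)
        refs = {n for n in nodes if io.is_reference_id(n)}
        fams = net.classify_novelty(net.connected_components(network), refs)
        all_fams.extend(fams)
        scores = net.min_reference_distance(network, refs, sentinel=thr["sentinel"])
        scores.insert(1, "bgc_class", cls)
        novelty_frames.append(scores)
        if cls in net.MAJOR_CLASSES:
            per_sample = net.sample_min_novelty(scores, inventory, cls)
            for s, v in per_sample.items():
                sample_novelty_rows.append((s, cls, v))
        comms, q = net.modularity_communities(network)
        communities[cls] = {"n_communities": len(comms), "modularity_Q": q}

    net.family_table(all_fams).to_csv(outdir / "families.tsv", sep="\t", index=False)
    membership = pd.DataFrame(
        sorted(net.family_membership(all_fams).items()), columns=["bgc_id", "family_id"]
    )
    membership.to_csv(outdir / "membership.tsv", sep="\t", index=False)
    pd.concat(novelty_frames, ignore_index=True).to_csv(
        outdir / "bgc_novelty.tsv", sep="\t", index=False, float_format="%.6g"
    )
    pd.DataFrame(sample_novelty_rows, columns=["sample_id", "bgc_class", "min_novelty"]).to_csv(
        outdir / "sample_novelty.tsv", sep="\t", index=False, float_format="%.6g"
    )
    (outdir / "communities.json").write_text(json.dumps(communities, indent=2, sort_keys=True) + "\n")


def run_features(rundir: str | Path, config: dict | None = None) -> None:
    """Build presence/Hellinger matrices, class proportions, taxonomy PCs."""
    rundir = Path(rundir)
    config = config or load_config(None)
    thr = config["thresholds"]
    inventory = io.read_inventory(_require(rundir / "inputs" / "inventory.tsv", "simulate"))
    env = io.read_metadata(_require(rundir / "inputs" / "metadata.csv", "simulate"))
    membership = pd.read_csv(_require(rundir / "derep" / "membership.tsv", "dereplicate"), sep="\t")
    family_of = dict(zip(membership["bgc_id"], membership["family_id"]))
    outdir = rundir / "features"
    outdir.mkdir(parents=True, exist_ok=True)

    presence, fam_class = feat.presence_matrix(inventory, family_of, samples=list(env.index))
    io.write_matrix(outdir / "presence.tsv", presence)
    fam_class.rename("bgc_class").to_csv(outdir / "family_class.tsv", sep="\t")
    filtered = feat.prevalence_filter(presence, thr["gcf_prevalence_fraction"])
    io.write_matrix(outdir / "presence_filtered.tsv", filtered)
    io.write_matrix(outdir / "hellinger.tsv", feat.hellinger(filtered))
    io.write_matrix(outdir / "class_proportions.tsv", feat.class_proportions(presence, fam_class))

    contigs = io.read_contigs(_require(rundir / "inputs" / "contigs.tsv", "simulate"))
    profile = feat.taxonomy_features(
        contigs,
        support_threshold=thr["support_threshold"],
        prevalence_fraction=thr["taxon_prevalence_fraction"],
    )
    profile = profile.reindex(sorted(env.index)).fillna(0.0)
    io.write_matrix(outdir / "taxon_profile.tsv", profile)
    n_pcs = min(thr["n_taxonomy_pcs"], len(profile) - 1, profile.shape[1])
    scores, _, var_frac = feat.pca(feat.hellinger(profile), n_pcs)
    io.write_matrix(outdir / "taxon_pcs.tsv", scores)
    (outdir / "taxon_pca.json").write_text(
        json.dumps({"n_components": int(n_pcs),
                    "variance_fractions": [float(v) for v in var_frac],
                    "cumulative_variance": float(np.sum(var_frac))}, indent=2) + "\n"
    )


def run_ordination(rundir: str | Path, config: dict | None = None, seed: int = 0) -> dict:
    """Constrained ordination, clustering, and the multivariate test suite."""
    rundir = Path(rundir)
    config = config or load_config(None)
    thr = config["thresholds"]
    nperm = int(thr["n_permutations"])
    env = io.read_metadata(_require(rundir / "inputs" / "metadata.csv", "simulate"))
    families = pd.read_csv(_require(rundir / "derep" / "families.tsv", "dereplicate"), sep="\t")
    Y = io.read_matrix(_require(rundir / "features" / "hellinger.tsv", "features"))
    taxon_pcs = io.read_matrix(_require(rundir / "features" / "taxon_pcs.tsv", "features"))
    env = env.loc[Y.index]
    outdir = rundir / "ordination"
    outdir.mkdir(parents=True, exist_ok=True)

    depth = pd.Series(np.log1p(env["sequencing_depth"]), name="log1p_depth")
    X = env[ENV_CONSTRAINTS]

    conditioned = ordn.partial_rda(Y, X, Z=depth, n_permutations=nperm, seed=seed)
    unconditioned = ordn.partial_rda(Y, X, Z=None, n_permutations=0, seed=seed)
    io.write_matrix(outdir / "site_scores.tsv", conditioned.site_scores)
    io.write_matrix(outdir / "site_scores_unconditioned.tsv", unconditioned.site_scores)

    rho_before = ordn.axis_depth_check(unconditioned.site_scores, depth)
    rho_after = ordn.axis_depth_check(conditioned.site_scores, depth)

    clusters = ordn.cluster_sites(conditioned.site_scores, k_range=tuple(thr["k_range"]), seed=seed)
    clusters.labels.to_frame().to_csv(outdir / "clusters.tsv", sep="\t")

    overall, terms = ordn.permanova(
        Y, env[MARGINAL_TERMS], condition=depth, by_margin=True,
        n_permutations=nperm, seed=seed,
    )
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(Y.to_numpy(float)))
    cluster_perm, _ = ordn.permanova(
        D, clusters.labels.astype(str), is_distance=True, by_margin=False,
        n_permutations=nperm, seed=seed,
    )
    anosim_res = ordn.anosim(D, clusters.labels, n_permutations=nperm, seed=seed)
    disp_res, _ = ordn.betadisper(D, clusters.labels, n_permutations=nperm, seed=seed)
    part = ordn.varpart(
        Y,
        env[["temperature", "pH", "conductivity", "crustal_thickness"]],
        taxon_pcs,
        condition=depth,
        n_permutations=nperm,
        seed=seed,
    )

    def _test(t: ordn.TestResult) -> dict:
        return {"statistic": t.statistic, "p_value": t.p_value, "effect_size": t.effect_size,
                "n_permutations": t.n_permutations, "name": t.name}

    results = {
        "n_gcfs": int(len(families)),
        "rda": {
            "overall": _test(conditioned.overall),
            "r_squared": conditioned.r_squared,
            "condition": list(conditioned.condition_names),
        },
        "axis_depth_rho": {
            "before_conditioning": rho_before["rho"].to_dict(),
            "after_conditioning": rho_after["rho"].to_dict(),
        },
        "clusters": {
            "chosen_k": clusters.chosen_k,
            "silhouette_best_k": clusters.silhouette_best_k,
            "wss": {str(k): v for k, v in clusters.wss.items()},
            "silhouette": {str(k): v for k, v in clusters.silhouette.items()},
            "rule": clusters.rule,
        },
        "permanova_marginal": {name: _test(t) for name, t in terms.items()},
        "permanova_overall": _test(overall),
        "permanova_clusters": _test(cluster_perm),
        "anosim_clusters": _test(anosim_res),
        "betadisper_clusters": _test(disp_res),
        "varpart": {
            "unique_env": part.unique_x1,
            "unique_taxonomy": part.unique_x2,
            "shared": part.shared,
            "residual": part.residual,
            "p_unique_env": part.p_unique_x1,
            "p_unique_taxonomy": part.p_unique_x2,
        },
    }
    io.write_results_json(outdir / "results.json", results, seed=seed, config=config)
    return results


def run_stats(rundir: str | Path, config: dict | None = None, seed: int = 0) -> dict:
    """Diversity, group contrasts, and novelty regressions."""
    rundir = Path(rundir)
    config = config or load_config(None)
    env = io.read_metadata(_require(rundir / "inputs" / "metadata.csv", "simulate"))
    presence = io.read_matrix(_require(rundir / "features" / "presence.tsv", "features"))
    props = io.read_matrix(_require(rundir / "features" / "class_proportions.tsv", "features"))
    fam_class = pd.read_csv(
        _require(rundir / "features" / "family_class.tsv", "features"), sep="\t", index_col=0
    )["bgc_class"]
    sample_novelty = pd.read_csv(
        _require(rundir / "derep" / "sample_novelty.tsv", "dereplicate"), sep="\t"
    )
    outdir = rundir / "stats"
    outdir.mkdir(parents=True, exist_ok=True)

    # Shannon H on per-sample class count vectors of detected GCFs
    detected = presence > 0
    class_counts = detected.T.groupby(fam_class.reindex(presence.columns)).sum().T
    diversity = uni.diversity_table(presence, class_counts)
    diversity.to_csv(outdir / "diversity.tsv", sep="\t", float_format="%.6g")

    setting = env["tectonic_setting"].reindex(diversity.index)
    tests = []
    kw = uni.kruskal_wallis(diversity["shannon_H"], setting)
    tests.append(("shannon_by_setting", kw.name, kw.statistic, kw.p_value))
    for cls in ("NRPS", "terpene"):
        if cls in props.columns:
            kw_c = uni.kruskal_wallis(props[cls], setting.reindex(props.index))
            tests.append((f"{cls}_proportion_by_setting", kw_c.name, kw_c.statistic, kw_c.p_value))
    test_tab = pd.DataFrame(tests, columns=["test", "statistic_name", "statistic", "p_value"])
    test_tab["p_adjusted"] = uni.adjust_pvalues(test_tab["p_value"].to_numpy(), method="BH")
    test_tab["stars"] = [uni.significance_stars(p) for p in test_tab["p_adjusted"]]
    logger.info("BH family size for omnibus tests: %d", len(test_tab))

    # volcanic arc vs others contrast on NRPS proportions (binary contrast)
    arc = (env["tectonic_setting"] == "volcanic_arc").reindex(props.index)
    extra_rows = []
    if "NRPS" in props.columns and arc.nunique() == 2:
        w = uni.wilcoxon_rank_sum(props.loc[arc, "NRPS"], props.loc[~arc, "NRPS"])
        extra_rows.append(("NRPS_arc_vs_others", w.name, w.statistic, w.p_value, w.p_value,
                           uni.significance_stars(w.p_value)))
    if "terpene" in props.columns:
        dunn = uni.dunn_posthoc(props["terpene"], setting.reindex(props.index), adjust="holm")
        dunn.to_csv(outdir / "dunn_terpene_by_setting.tsv", sep="\t", index=False, float_format="%.6g")
    if extra_rows:
        test_tab = pd.concat(
            [test_tab, pd.DataFrame(extra_rows, columns=list(test_tab.columns))], ignore_index=True
        )
    test_tab.to_csv(outdir / "group_tests.tsv", sep="\t", index=False, float_format="%.6g")

    reg_rows = []
    fits = {}
    for cls in net.MAJOR_CLASSES:
        series = sample_novelty.loc[sample_novelty["bgc_class"] == cls].set_index("sample_id")["min_novelty"]
        if len(series) < 3:
            continue
        for covariate in ("crustal_thickness", "temperature", "pH"):
            fit = uni.novelty_regression(series, env[covariate], name=covariate)
            reg_rows.append((cls, covariate, fit.slope, fit.intercept, fit.r_squared, fit.p_value, fit.n))
            fits[(cls, covariate)] = fit
    regs = pd.DataFrame(
        reg_rows, columns=["bgc_class", "covariate", "slope", "intercept", "r_squared", "p_value", "n"]
    )
    regs.to_csv(outdir / "novelty_regressions.tsv", sep="\t", index=False, float_format="%.6g")

    results = {
        "shannon_mean": float(diversity["shannon_H"].mean()),
        "shannon_sd": float(diversity["shannon_H"].std()),
        "group_tests": test_tab.to_dict(orient="records"),
        "novelty_regressions": regs.to_dict(orient="records"),
    }
    io.write_results_json(outdir / "results.json", results, seed=seed, config=config)
    return results


def run_all(config: dict, rundir: str | Path, seed: int | None = None) -> dict:
    """Run every stage in order on one run directory."""
    rundir = Path(rundir)
    simcfg = run_simulate(config, rundir, seed=seed)
    run_dereplicate(rundir, config)
    run_features(rundir, config)
    ord_results = run_ordination(rundir, config, seed=simcfg.seed)
    stat_results = run_stats(rundir, config, seed=simcfg.seed)
    return {"ordination": ord_results, "stats": stat_results}
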