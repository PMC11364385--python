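"""End-to-end orchestration of the synthetic analysis.

``run_all`` executes the full chain — simulate panel -> EMP scoring ->
tissue DE -> per-model sharing -> cross-platform consensus -> GSEA ->
CNV profiles -> EMP-state markers -> association statistics -> survival
stratification — into one output directory with a machine-readable run
report (config, per-stage seeds, the stage DAG, and a checksum per output
file).  One master seed deterministically derives every per-stage seed,
so a rerun with the same config reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import association, cnv, consensus, enrichment, scoring, survival as surv
from .datamodel import GeneSignature
from .errors import ConfigError
from .hurdle import run_de
from .synthetic import PanelConfig, simulate_panel, simulate_survival

logger = logging.getLogger(__name__)

STAGES = [
    ("simulate", []),
    ("scoring", ["simulate"]),
    ("tissue_de", ["simulate"]),
    ("per_model", ["tissue_de"]),
    ("gsea", ["tissue_de"]),
    ("cnv", ["simulate"]),
    ("state_markers", ["scoring"]),
    ("associations", ["scoring"]),
    ("survival", ["simulate"]),
]


def _stage_seeds(master_seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for (name, _), child in zip(STAGES, children)
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.8g")


def load_config(source) -> dict[str, Any]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    if not isinstance(cfg, Mapping):
        raise ConfigError("config must be a mapping")
    if "seed" not in cfg or cfg["seed"] is None:
        raise ConfigError("config must declare an integer 'seed'")
    return dict(cfg)


def run_all(config, out_dir) -> dict[str, Any]:
    """Run every stage; returns the report (also written as report.json)."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(int(cfg["seed"]))
    report: dict[str, Any] = {
        "config": cfg,
        "stage_seeds": seeds,
        "dag": {name: deps for name, deps in STAGES},
        "outputs": {},
    }
    files: dict[str, Path] = {}

    def emit(stage: str, name: str, df: pd.DataFrame) -> None:
        path = out / name
        _write_tsv(df, path)
        report["outputs"].setdefault(stage, {})[name] = None  # checksum filled later
        files[name] = path

    # --- simulate ------------------------------------------------------
    panel_overrides = dict(cfg.get("panel", {}))
    panel = PanelConfig(**panel_overrides, seed=seeds["simulate"])
    dataset, truth = simulate_panel(panel)
    truth_json = {
        "de_genes": truth.de_genes,
        "intermediate_markers": truth.intermediate_markers,
        "epithelial_genes": truth.epithelial_genes,
        "mesenchymal_genes": truth.mesenchymal_genes,
        "cnv_segments": truth.cnv_segments,
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    files["truth.json"] = out / "truth.json"
    report["outputs"].setdefault("simulate", {})["truth.json"] = None

    platforms = sorted(dataset.cell_meta["platform"].unique())
    by_platform = {
        p: dataset.subset_cells((dataset.cell_meta["platform"] == p).to_numpy())
        for p in platforms
    }

    # --- scoring -------------------------------------------------------
    epi_sig = GeneSignature("epithelial_program", tuple(truth.epithelial_genes))
    mes_sig = GeneSignature("mesenchymal_program", tuple(truth.mesenchymal_genes))
    score_tables = {}
    for p, ds in by_platform.items():
        st = scoring.compute_emp(ds, epi_sig, mes_sig, seed=seeds["scoring"])
        score_tables[p] = st
        emit("scoring", f"emp_scores_{p}.tsv", st)
    all_scores = pd.concat(score_tables.values())

    # --- tissue DE (deep platform, tumor model as covariate) -----------
    deep = by_platform[platforms[0]] if "plate" not in by_platform else by_platform["plate"]
    de_tissue = run_de(
        deep, "tissue", "metastasis", "primary", covariate_keys=["tumor_model"]
    )
    emit("tissue_de", "de_tissue.tsv", de_tissue.table)

    # --- per-model DE + sharing ---------------------------------------
    de_models, excluded = consensus.per_model_de(deep)
    potential_of = deep.cell_meta.groupby("tumor_model")["metastatic_potential"].first().to_dict()
    shared, histogram = consensus.shared_upregulated(
        de_models, direction="up", min_models=2,
        within_groups={m: potential_of[m] for m in de_models},
    )
    sharing = {
        "excluded_models": excluded,
        "sharing_histogram": {str(k): v for k, v in sorted(histogram.items())},
        "signatures": {
            label: {"genes": sorted(sig.genes), "support": sig.support}
            for label, sig in shared.items()
        },
    }
    (out / "per_model_sharing.json").write_text(json.dumps(sharing, indent=1, sort_keys=True))
    files["per_model_sharing.json"] = out / "per_model_sharing.json"
    report["outputs"].setdefault("per_model", {})["per_model_sharing.json"] = None

    # --- GSEA on the tissue ranking ------------------------------------
    ranking = enrichment.rank_from_de(de_tissue)
    rng = np.random.default_rng(seeds["gsea"])
    gene_pool = list(dataset.genes)
    sets = [
        GeneSignature("EPITHELIAL_PROGRAM", tuple(truth.epithelial_genes)),
        GeneSignature("MESENCHYMAL_PROGRAM", tuple(truth.mesenchymal_genes)),
        GeneSignature("INTERMEDIATE_PROGRAM", tuple(truth.intermediate_markers)),
        GeneSignature("METASTASIS_UP", tuple(g for g, e in truth.de_genes.items() if e > 0) or ("none",)),
    ]
    for i in range(4):
        members = rng.choice(gene_pool, size=30, replace=False)
        sets.append(GeneSignature(f"RANDOM_{i}", tuple(members)))
    n_perm = int(cfg.get("gsea_permutations", 200))
    gsea_res = enrichment.preranked_gsea(ranking, sets, n_perm=max(n_perm, 100), seed=seeds["gsea"])
    emit("gsea", "gsea.tsv", gsea_res.table)

    # --- CNV ------------------------------------------------------------
    window = int(cfg.get("cnv_window", 101))
    profile = cnv.infer_profiles(deep, window=window)
    compare, skipped_models = cnv.compare_compartments(profile, deep.cell_meta)
    emit("cnv", "cnv_compare.tsv", compare)

    # --- EMP-state markers ---------------------------------------------
    state_sets = {}
    for p, ds in by_platform.items():
        de_states, _ = consensus.state_marker_de(ds, score_tables[p])
        state_sets[p] = {
            s: consensus.ConsensusSignature(
                label=s,
                genes=set(res.significant(direction="up").index),
                support={g: [p] for g in res.significant(direction="up").index},
                platforms={g: {p} for g in res.significant(direction="up").index},
            )
            for s, res in de_states.items()
        }
    if len(platforms) == 2:
        common_labels = set(state_sets[platforms[0]]) & set(state_sets[platforms[1]])
        inter = consensus.cross_platform_intersect(
            {s: state_sets[platforms[0]][s] for s in common_labels},
            {s: state_sets[platforms[1]][s] for s in common_labels},
        )
    else:
        inter = state_sets[platforms[0]]
    deep_name = deep.cell_meta["platform"].iloc[0]
    peak_flags = []
    for g in truth.intermediate_markers:
        prof = consensus.peak_profile(deep, g, score_tables[deep_name])
        peak_flags.append({"gene": g, "peaks_in_intermediate": prof.peaks_in_intermediate})
    markers = {
        "per_platform": {
            p: {s: sorted(sig.genes) for s, sig in sets_.items()} for p, sets_ in state_sets.items()
        },
        "cross_platform": {s: sorted(sig.genes) for s, sig in inter.items()},
        "peak_flags": peak_flags,
    }
    (out / "state_markers.json").write_text(json.dumps(markers, indent=1, sort_keys=True))
    files["state_markers.json"] = out / "state_markers.json"
    report["outputs"].setdefault("state_markers", {})["state_markers.json"] = None

    # --- associations ---------------------------------------------------
    assoc: dict[str, Any] = {}
    for p, ds in by_platform.items():
        assoc[f"potential_correlation_{p}"] = association.potential_correlation(
            score_tables[p], ds.cell_meta
        )
    paired_tissue = association.paired_emp_correlation(
        score_tables[deep_name], deep.cell_meta, pair_key="tissue"
    )
    assoc["paired_tissue_r2"] = paired_tissue.r2
    if len(platforms) == 2:
        paired_platform = association.paired_emp_correlation(
            all_scores, dataset.cell_meta, pair_key="platform"
        )
        assoc["cross_platform_r2"] = paired_platform.r2
    global_pca = association.pca(deep, n_components=5)
    sep = association.pc_separation(global_pca.coords, deep.cell_meta, axis=2, group_key="tissue")
    assoc["pc2_tissue_wilcoxon_p"] = sep.p
    (out / "associations.json").write_text(json.dumps(assoc, indent=1, sort_keys=True))
    files["associations.json"] = out / "associations.json"
    report["outputs"].setdefault("associations", {})["associations.json"] = None

    # --- survival -------------------------------------------------------
    surv_cfg = dict(cfg.get("survival", {}))
    n_patients = int(surv_cfg.get("n_patients", 400))
    hazard_beta = float(surv_cfg.get("hazard_beta", 1.5))
    sig_genes = [f"SIG{j:03d}" for j in range(10)]
    cohort, _ = simulate_survival(
        n_patients, hazard_beta, sig_genes, seed=seeds["survival"]
    )
    strat = surv.stratify_by_signature(cohort, sig_genes)
    by_subtype, skipped_subtypes = surv.subtype_stratified(cohort, sig_genes)
    surv_out = {
        "overall": {"chi2": strat.logrank.chi2, "p": strat.logrank.p,
                    "n_low": strat.n_low, "n_high": strat.n_high},
        "by_subtype": {
            s: {"chi2": r.logrank.chi2, "p": r.logrank.p, "n": r.n_low + r.n_high}
            for s, r in by_subtype.items()
        },
        "skipped_subtypes": skipped_subtypes,
    }
    (out / "survival.json").write_text(json.dumps(surv_out, indent=1, sort_keys=True))
    files["survival.json"] = out / "survival.json"
    report["outputs"].setdefault("survival", {})["survival.json"] = None

    # --- checksums + report ---------------------------------------------
    for stage, outputs in report["outputs"].items():
        for name in outputs:
            outputs[name] = _sha256(files[name])
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
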