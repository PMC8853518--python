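"""End-to-end study orchestration.

Per sex: differential expression per tissue -> signed coexpression network
per tissue -> CIE-related module selection -> cross-tissue overlap
meta-network with blood-brain calling -> blood-brain correlation tables ->
blood classifiers.  Every output is a deterministic function of (inputs,
config, seed); a manifest with content hashes makes reruns checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from bloodbrain import classify as clf
from bloodbrain import coexpr, diffexpr, modlink, xtissue
from bloodbrain.ingest import SampleMetadata, read_counts, read_metadata, logcpm, voom

log = logging.getLogger("bloodbrain")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

DEFAULT_CONFIG = {
    "blood_tissue": "BLD",
    "sexes": None,  # None -> all sexes present in the metadata
    "de_alpha": 0.05,
    "edge_alpha": 0.05,
    "network": {
        "beta": None,  # per-tissue map or single int; None -> scale-free pick
        "candidate_betas": list(range(1, 21)),
        "scale_free_r2_target": 0.8,
        "min_module_size": 100,
        "detect_cut_height": 0.99,
        "deep_split": True,
        "merge_cut_height": 0.25,
    },
    "classify": {
        "models": ["elastic_net_lr", "random_forest", "plsda"],
        "k_folds": 5,
        "repeats": 10,
        "grids": {},
    },
    "seed": 0,
}


class PipelineConfig:
    """Validated pipeline configuration (see DEFAULT_CONFIG for the schema)."""

    def __init__(self, raw: dict):
        cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
        for key, value in raw.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
        if "counts" not in cfg or "metadata" not in cfg:
            raise ValueError("config must provide 'counts' (per tissue) and 'metadata'")
        for tissue, path in cfg["counts"].items():
            if not Path(path).exists():
                raise FileNotFoundError(f"counts file for tissue {tissue!r}: {path}")
        if not Path(cfg["metadata"]).exists():
            raise FileNotFoundError(f"metadata file: {cfg['metadata']}")
        self.raw = cfg

    def __getitem__(self, key):
        return self.raw[key]

    def network_params(self, tissue: str) -> coexpr.NetworkParams:
        net = self.raw["network"]
        beta = net["beta"]
        if isinstance(beta, dict):
            beta = beta.get(tissue)
        return coexpr.NetworkParams(
            beta=beta,
            candidate_betas=tuple(net["candidate_betas"]),
            scale_free_r2_target=net["scale_free_r2_target"],
            min_module_size=net["min_module_size"],
            detect_cut_height=net["detect_cut_height"],
            deep_split=net["deep_split"],
            merge_cut_height=net["merge_cut_height"],
        )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(frame: pd.DataFrame, path: Path, index: bool = True):
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full analysis; returns the manifest dict (also written)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])

    counts = {t: read_counts(p) for t, p in config["counts"].items()}
    metadata = read_metadata(config["metadata"])
    blood = config["blood_tissue"]
    tissues = sorted(counts)
    if blood not in counts:
        raise ValueError(f"blood tissue {blood!r} not among counts inputs")
    sexes = config["sexes"] or sorted(metadata.table["sex"].unique())

    written: list[Path] = []

    for sex in sexes:
        stage = f"sex={sex}"
        log.info("[%s] differential expression", stage)
        deg_sets = {}
        universes = {}
        for tissue in tissues:
            meta_t = metadata.for_tissue(tissue)
            meta_t = meta_t[meta_t["sex"] == sex]
            cm = counts[tissue].subset_samples(meta_t["sample_id"])
            design = diffexpr.group_design(meta_t["group"], reference="Air")
            expr_w = voom(cm, design)
            table = diffexpr.fit_moderated(expr_w, design, np.array([0.0, 1.0]))
            path = out / f"de_{sex}_{tissue}.tsv"
            _write(table, path)
            written.append(path)
            deg_sets[tissue] = {
                d: diffexpr.deg_set(table, config["de_alpha"], d) for d in ("up", "down", "both")
            }
            universes[tissue] = frozenset(cm.genes)

        log.info("[%s] coexpression networks", stage)
        assignments = {}
        cie = {}
        for tissue in tissues:
            meta_t = metadata.for_tissue(tissue)
            meta_t = meta_t[meta_t["sex"] == sex]
            cm = counts[tissue].subset_samples(meta_t["sample_id"])
            expr = logcpm(cm)
            net = coexpr.build_network(expr, config.network_params(tissue))
            assignment = net["assignment"]
            assignments[tissue] = assignment
            labels = assignment.labels.rename("module").to_frame()
            path = out / f"modules_{sex}_{tissue}.tsv"
            _write(labels, path)
            written.append(path)
            if assignment.eigengenes is not None:
                path = out / f"eigengenes_{sex}_{tissue}.tsv"
                _write(assignment.eigengenes, path)
                written.append(path)

            enrich = modlink.module_deg_enrichment(
                assignment, deg_sets[tissue]["up"], deg_sets[tissue]["down"],
                universes[tissue], alpha=config["de_alpha"],
            )
            if assignment.eigengenes is not None and len(assignment.module_labels()):
                assoc = modlink.eigengene_trait_association(
                    assignment.eigengenes, meta_t.assign(
                        group=(meta_t["group"] == "CIE").astype(float)
                    ),
                )
            else:
                assoc = pd.DataFrame(columns=["module", "trait", "r", "p", "n"])
            selected = modlink.select_cie_modules(enrich, assoc, alpha=config["de_alpha"])
            cie[tissue] = set(selected["module"])
            path = out / f"cie_modules_{sex}_{tissue}.tsv"
            _write(selected, path, index=False)
            written.append(path)

        log.info("[%s] cross-tissue meta-network", stage)
        overlaps = {}
        for i, ta in enumerate(tissues):
            for tb in tissues[i + 1:]:
                if assignments[ta].module_labels() and assignments[tb].module_labels():
                    overlaps[(ta, tb)] = modlink.cross_tissue_overlap(
                        assignments[ta], assignments[tb]
                    )
        meta_net = modlink.build_meta_network(
            overlaps, cie, blood_tissue=blood, edge_alpha=config["edge_alpha"]
        )
        sif = out / f"meta_network_{sex}.sif"
        graphml = out / f"meta_network_{sex}.graphml"
        meta_net.write_sif(sif)
        meta_net.write_graphml(graphml)
        written += [sif, graphml]

        log.info("[%s] blood-brain correlations", stage)
        meta_sex = SampleMetadata(metadata.table[metadata.table["sex"] == sex])
        between_rows = []
        for tissue in tissues:
            if tissue == blood:
                continue
            meta_b = meta_sex.for_tissue(blood)
            meta_t = meta_sex.for_tissue(tissue)
            expr_b = logcpm(counts[blood].subset_samples(meta_b["sample_id"]))
            expr_t = logcpm(counts[tissue].subset_samples(meta_t["sample_id"]))
            rho, p, _ = xtissue.between_subject_correlation(expr_b, expr_t)
            between_rows.append({"tissue": tissue, "rho": rho, "p": p})
            within = xtissue.within_subject_correlation(
                expr_b, expr_t, meta_sex, blood, tissue
            )
            path = out / f"within_corr_{sex}_{blood}_{tissue}.tsv"
            _write(within, path)
            written.append(path)
        path = out / f"between_corr_{sex}.tsv"
        _write(pd.DataFrame(between_rows), path, index=False)
        written.append(path)

        log.info("[%s] blood classifiers", stage)
        meta_blood = meta_sex.for_tissue(blood)
        cm = counts[blood].subset_samples(meta_blood["sample_id"])
        ccfg = config["classify"]
        configs = [
            clf.ClassifierConfig(
                model=m,
                k_folds=ccfg["k_folds"],
                repeats=ccfg["repeats"],
                seed=seed,
                grid=ccfg["grids"].get(m),
            )
            for m in ccfg["models"]
        ]
        reports = clf.run_classification(cm, meta_blood, configs)
        metric_rows = []
        for model, report in reports.items():
            metric_rows.append({"model": model, **report.metrics,
                                "n_features_used": report.n_features_used})
            path = out / f"importance_{sex}_{model}.tsv"
            _write(report.importance.head(200), path, index=False)
            written.append(path)
            path = out / f"roc_{sex}_{model}.tsv"
            _write(report.roc_points, path, index=False)
            written.append(path)
        path = out / f"classifier_metrics_{sex}.tsv"
        _write(pd.DataFrame(metric_rows), path, index=False)
        written.append(path)
        params_path = out / f"classifier_params_{sex}.json"
        params_path.write_text(json.dumps(
            {m: r.selected_params for m, r in reports.items()}, indent=1, sort_keys=True
        ))
        written.append(params_path)

    manifest = {
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(config.raw, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
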