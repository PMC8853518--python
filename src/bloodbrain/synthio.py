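"""Seeded synthetic multi-tissue studies with planted ground truth.

Emulates the design of a chronic-intermittent-ethanol (CIE) mouse study at
the data level: two balanced groups (CIE vs Air), both sexes, the same
subjects measured in blood and several brain regions.  Counts are
negative-binomial (gamma-Poisson); genes in a planted module share a
per-subject latent factor — the future module eigengene — plus independent
noise scaled so the average within-module correlation matches the requested
strength.  A module configured for several tissues reuses the same subject
factor in each (optionally sign-flipped per tissue, mimicking conserved
modules with opposite regulation directions); planted DEGs shift the group
mean by a log2 fold-change; drinking traits are linear combinations of
selected latent factors plus Gaussian noise, so eigengene-trait
correlations are recoverable downstream.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from bloodbrain.ingest import CountMatrix, SampleMetadata, METADATA_COLUMNS
from bloodbrain.modlink import write_gmt

__all__ = [
    "ModuleSpec",
    "DegSpec",
    "SyntheticConfig",
    "GroundTruth",
    "generate_study",
    "write_fixtures",
    "read_fixtures",
]


@dataclasses.dataclass(frozen=True)
class ModuleSpec:
    """A planted coexpression module.

    strength is the target mean pairwise within-module correlation (in
    [0, 1]); trait_r the target eigengene-consumption correlation; tissues
    lists where the module appears (the same subject factor is reused, with
    the sign flips in ``tissue_signs`` if given).
    """

    module_id: int
    size: int
    tissues: tuple[str, ...]
    strength: float
    trait_r: float = 0.0
    group_shift: float = 0.0  # shift of the latent factor mean in the CIE group (sd units)
    tissue_signs: dict[str, int] | None = None

    def __post_init__(self):
        if self.size < 3:
            raise ValueError("module size must be >= 3 (eigengene undefined below)")
        if not np.isfinite(self.strength) or not 0 <= self.strength <= 1:
            raise ValueError("module strength must be finite, in [0, 1]")
        if not np.isfinite(self.trait_r) or not -1 <= self.trait_r <= 1:
            raise ValueError("trait_r must be finite, in [-1, 1]")
        if not self.tissues:
            raise ValueError("module must appear in at least one tissue")


@dataclasses.dataclass(frozen=True)
class DegSpec:
    """Planted differential expression: n_genes in one tissue at a log2 FC."""

    tissue: str
    n_genes: int
    log2fc: float
    direction: str = "up"

    def __post_init__(self):
        if not np.isfinite(self.log2fc):
            raise ValueError("log2fc must be finite")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.n_genes < 1:
            raise ValueError("need at least one DEG")


@dataclasses.dataclass
class SyntheticConfig:
    """Full specification of a synthetic multi-tissue study."""

    n_subjects_per_group: int = 10
    tissues: tuple[str, ...] = ("BLD", "PFC", "AMY", "HYP")
    n_genes: int = 1000
    module_specs: tuple[ModuleSpec, ...] = ()
    deg_specs: tuple[DegSpec, ...] = ()
    nb_dispersion: float = 0.1
    baseline_logmean_range: tuple[float, float] = (3.0, 9.0)  # log2 scale
    baseline_tissue_sd: float = 1.0  # tissue deviation from the shared baseline
    library_size_range: tuple[int, int] = (500_000, 2_000_000)
    sexes: tuple[str, ...] = ("M",)
    seed: int = 0

    def __post_init__(self):
        if not self.tissues:
            raise ValueError("tissue list must be nonempty")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("duplicate tissue names")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_subjects_per_group < 2:
            raise ValueError("need >= 2 subjects per group")
        for tissue in self.tissues:
            total = sum(m.size for m in self.module_specs if tissue in m.tissues)
            if total > self.n_genes:
                raise ValueError(f"module sizes exceed n_genes in tissue {tissue}")
        for spec in self.deg_specs:
            if spec.tissue not in self.tissues:
                raise ValueError(f"DEG spec names unknown tissue {spec.tissue!r}")
        for spec in self.module_specs:
            for tissue in spec.tissues:
                if tissue not in self.tissues:
                    raise ValueError(f"module names unknown tissue {tissue!r}")


@dataclasses.dataclass
class GroundTruth:
    """What was planted: module memberships, DEGs, traits, latent factors."""

    modules: dict[str, dict[str, int]]  # tissue -> gene -> module id
    degs: dict[str, dict[str, float]]  # tissue -> gene -> signed log2 FC
    traits: pd.DataFrame  # per subject: group, consumption, preference
    factors: pd.DataFrame  # per subject: latent factor per module id

    def to_json_dict(self) -> dict:
        return {
            "modules": self.modules,
            "degs": self.degs,
            "traits": self.traits.to_dict(orient="list"),
            "factors": {str(k): v for k, v in self.factors.to_dict(orient="list").items()},
            "subjects": self.traits.index.tolist(),
        }


def _gene_ids(n: int) -> list[str]:
    return [f"g{idx:05d}" for idx in range(n)]


def generate_study(config: SyntheticConfig):
    """Generate one synthetic study.

    Returns (counts per tissue, SampleMetadata, GroundTruth).  Identical
    config and seed reproduce the output bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    n_per = config.n_subjects_per_group
    subjects, groups, sexes = [], [], []
    for sex in config.sexes:
        for grp in ("CIE", "Air"):
            for i in range(n_per):
                subjects.append(f"{sex}_{grp}_{i:02d}")
                groups.append(grp)
                sexes.append(sex)
    n_subj = len(subjects)
    group_ind = np.array([1.0 if g == "CIE" else 0.0 for g in groups])

    genes = _gene_ids(config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    module_ids = [m.module_id for m in config.module_specs]
    if len(set(module_ids)) != len(module_ids):
        raise ValueError("module ids must be unique")

    # latent per-subject factor per module, standard normal + group shift
    factors = {}
    for spec in config.module_specs:
        f = rng.standard_normal(n_subj)
        if spec.group_shift:
            f = f + spec.group_shift * group_ind
        factors[spec.module_id] = f
    factor_frame = pd.DataFrame(factors, index=subjects)

    # traits: consumption loads on trait-linked factors, group shifts the mean
    consumption = 8.0 + 4.0 * group_ind + rng.standard_normal(n_subj) * 1.0
    preference_raw = 0.5 + 0.15 * group_ind + rng.standard_normal(n_subj) * 0.08
    for spec in config.module_specs:
        if spec.trait_r != 0.0:
            f = factor_frame[spec.module_id].to_numpy()
            fz = (f - f.mean()) / (f.std() + 1e-12)
            # mix the factor into consumption at the requested correlation
            r = spec.trait_r
            resid = consumption - consumption.mean()
            resid_z = resid / (resid.std() + 1e-12)
            consumption = consumption.mean() + consumption.std() * (
                r * fz + np.sqrt(max(1.0 - r**2, 0.0)) * resid_z
            )
    preference = np.clip(preference_raw, 0.0, 1.0)

    # per-tissue module membership: deterministic contiguous gene blocks
    module_genes: dict[str, dict[str, int]] = {t: {} for t in config.tissues}
    blocks: dict[int, list[str]] = {}
    cursor = 0
    for spec in config.module_specs:
        block = genes[cursor: cursor + spec.size]
        cursor += spec.size
        blocks[spec.module_id] = block
        for tissue in spec.tissues:
            for g in block:
                module_genes[tissue][g] = spec.module_id

    # planted DEGs drawn from genes free of module structure in that tissue
    deg_truth: dict[str, dict[str, float]] = {t: {} for t in config.tissues}
    free_start = cursor
    deg_cursor: dict[str, int] = {t: free_start for t in config.tissues}
    for spec in config.deg_specs:
        start = deg_cursor[spec.tissue]
        stop = start + spec.n_genes
        if stop > config.n_genes:
            raise ValueError("not enough background genes to plant DEGs")
        sign = 1.0 if spec.direction == "up" else -1.0
        for g in genes[start:stop]:
            deg_truth[spec.tissue][g] = sign * spec.log2fc
        deg_cursor[spec.tissue] = stop

    baseline_lo, baseline_hi = config.baseline_logmean_range
    lib_lo, lib_hi = config.library_size_range

    # one shared baseline across tissues (genes keep their characteristic
    # abundance everywhere, which is what makes mean-expression profiles of
    # two tissues rank-correlate), plus a per-tissue deviation.  Genes that
    # carry planted signal (module members, DEGs) sit in the lower abundance
    # range so their shifts do not dominate per-sample totals and leak into
    # every other gene through CPM normalization.
    shared_base = rng.uniform(baseline_lo, baseline_hi, size=config.n_genes)
    signal_rows = sorted(
        {gene_index[g] for block in blocks.values() for g in block}
        | {gene_index[g] for t in config.tissues for g in deg_truth[t]}
    )
    if signal_rows:
        span = baseline_hi - baseline_lo
        shared_base[signal_rows] = rng.uniform(
            baseline_lo, baseline_lo + span / 3.0, size=len(signal_rows)
        )

    counts_by_tissue: dict[str, CountMatrix] = {}
    meta_rows = []
    for tissue in config.tissues:
        base_log2 = shared_base + rng.normal(0.0, config.baseline_tissue_sd,
                                             size=config.n_genes)
        log2_expr = np.tile(base_log2[:, None], (1, n_subj)).astype(float)

        for spec in config.module_specs:
            if tissue not in spec.tissues:
                continue
            sign = (spec.tissue_signs or {}).get(tissue, 1)
            f = sign * factor_frame[spec.module_id].to_numpy()
            idx = [gene_index[g] for g in blocks[spec.module_id]]
            # shared-factor loading tuned so mean pairwise correlation ~= strength:
            # two genes sharing a factor with loading a over total per-gene noise
            # variance v correlate at a^2 / (a^2 + v); v includes the log-scale
            # gamma-Poisson variance (~dispersion / ln(2)^2) on top of the
            # per-gene Gaussian noise
            s = min(spec.strength, 0.999)
            tau = 0.35  # per-gene biological noise sd, log2 scale
            v_nb = config.nb_dispersion / np.log(2.0) ** 2
            v = tau**2 + v_nb
            a = np.sqrt(s / (1.0 - s) * v) if s > 0 else 0.0
            noise = rng.standard_normal((len(idx), n_subj))
            log2_expr[idx, :] += a * f[None, :] + tau * noise

        for g, lfc in deg_truth[tissue].items():
            gi = gene_index[g]
            log2_expr[gi, :] += lfc * group_ind

        lib = np.exp(rng.uniform(np.log(lib_lo), np.log(lib_hi), size=n_subj))
        rel = 2.0 ** log2_expr
        prop = rel / rel.sum(axis=0, keepdims=True)
        mu = prop * lib[None, :]
        # gamma-Poisson: variance mu + dispersion * mu^2
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam).astype(np.int64)

        sample_ids = [f"{subj}_{tissue}" for subj in subjects]
        counts_by_tissue[tissue] = CountMatrix(pd.Index(genes), pd.Index(sample_ids), counts)
        for j, subj in enumerate(subjects):
            meta_rows.append(
                {
                    "sample_id": sample_ids[j],
                    "subject_id": subj,
                    "tissue": tissue,
                    "sex": sexes[j],
                    "group": groups[j],
                    "consumption": consumption[j],
                    "preference": preference[j],
                }
            )

    metadata = SampleMetadata(pd.DataFrame(meta_rows, columns=METADATA_COLUMNS))
    traits = pd.DataFrame(
        {"group": groups, "sex": sexes, "consumption": consumption, "preference": preference},
        index=subjects,
    )
    truth = GroundTruth(module_genes, deg_truth, traits, factor_frame)
    return counts_by_tissue, metadata, truth


def write_fixtures(study, directory: str | Path, overwrite: bool = False) -> dict[str, Path]:
    """Write a study to disk: counts TSV per tissue, metadata TSV, GMT, JSON.

    Returns the mapping of logical names to paths.  Existing files raise
    unless ``overwrite`` is set.
    """
    counts_by_tissue, metadata, truth = study
    if not counts_by_tissue:
        raise ValueError("study has no tissues")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    paths: dict[str, Path] = {}
    for tissue, cm in counts_by_tissue.items():
        paths[f"counts_{tissue}"] = directory / f"counts_{tissue}.tsv"
    paths["metadata"] = directory / "metadata.tsv"
    paths["modules_gmt"] = directory / "planted_modules.gmt"
    paths["ground_truth"] = directory / "ground_truth.json"

    if not overwrite:
        clashes = [p for p in paths.values() if p.exists()]
        if clashes:
            raise FileExistsError(f"refusing to overwrite: {clashes[0]}")

    for tissue, cm in counts_by_tissue.items():
        frame = cm.to_frame()
        frame.index.name = "gene"
        frame.to_csv(paths[f"counts_{tissue}"], sep="\t")
    metadata.table.to_csv(paths["metadata"], sep="\t", index=False)

    gmt_sets: dict[str, set] = {}
    for tissue, mapping in truth.modules.items():
        by_module: dict[int, set] = {}
        for g, m in mapping.items():
            by_module.setdefault(m, set()).add(g)
        for m, gs in by_module.items():
            gmt_sets[f"{tissue}_module{m}"] = gs
    if not gmt_sets:
        gmt_sets["empty"] = set()
    write_gmt(gmt_sets, paths["modules_gmt"])

    paths["ground_truth"].write_text(json.dumps(truth.to_json_dict(), indent=1))
    return paths


def read_fixtures(directory: str | Path):
    """Re-read a study written by :func:`write_fixtures`."""
    from bloodbrain.ingest import read_counts, read_metadata

    directory = Path(directory)
    counts = {}
    for path in sorted(directory.glob("counts_*.tsv")):
        tissue = path.stem.removeprefix("counts_")
        counts[tissue] = read_counts(path)
    metadata = read_metadata(directory / "metadata.tsv")
    truth_raw = json.loads((directory / "ground_truth.json").read_text())
    return counts, metadata, truth_raw
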