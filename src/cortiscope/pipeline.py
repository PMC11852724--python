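"""End-to-end orchestration of the tumor-vs-normal transcriptome analysis.

A run is a pure function of (inputs, config, seed): simulate or load a
cohort, screen out tumor samples indistinguishable from normals in PCA
space, call DEGs per contrast, test the significance of the k-way DEG
intersections by permutation, score pathway activation per contrast and
report pathways with a common regulation trend, screen fusion
candidates, and score therapies. Every stage writes TSV artifacts into
the report directory plus a deterministic JSON manifest; per-stage
timing goes to the logger only so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexp import DEResults, NBDifferentialExpression
from .enrichment import ora
from .fusions import candidates_to_frame, recurrence_table, screen_fusions
from .io import (
    CountMatrix,
    DrugModel,
    GeneSet,
    read_annotation,
    read_count_matrix,
    read_drug_models,
    read_fusion_table,
    read_gene_sets_gmt,
    read_pathways,
    write_annotation,
    write_count_matrix,
    write_sample_sheet,
)
from .overlap import expected_overlap, permutation_overlap_test
from .pal import cnr, group_pal, normalized_expression
from .simulate import (
    default_cohort_spec,
    simulate_annotation,
    simulate_cohort,
    simulate_fusion_tables,
    simulate_pathways,
)
from .structure import exclude_normal_like, pca, vst_transform
from .therapy import bes_matrix, cluster_bes, gd2_signature, target_upregulation_proportion

logger = logging.getLogger("cortiscope")

__all__ = ["Contrast", "RunConfig", "run_pipeline", "lung_specific_genes"]


@dataclass(frozen=True)
class Contrast:
    name: str
    case_group: str
    control_group: str


@dataclass
class RunConfig:
    """All knobs of one pipeline run; loadable from a YAML file."""

    seed: int = 0
    simulate: bool = True
    # input paths (load mode)
    counts_path: str | None = None
    samples_path: str | None = None
    pathways_path: str | None = None
    annotation_path: str | None = None
    gmt_path: str | None = None
    drugs_path: str | None = None
    fusion_tables: dict[str, str] = field(default_factory=dict)  # sample -> path
    # contrasts
    contrasts: list[Contrast] = field(default_factory=list)
    # structure stage
    run_exclusion: bool = True
    n_top_genes: int = 500
    k_components: int = 2
    # diffexp stage
    lfc_threshold: float = 2.0
    alpha: float = 0.05
    strict: bool = True
    min_total: int = 10
    # overlap stage
    n_permutations: int = 10_000
    # fusion stage
    run_fusions: bool = True
    rt_max_gap: int = 100_000
    support_mode: str = "and"
    # therapy stage
    run_drugs: bool = True
    gd2_genes: tuple[str, str] | None = None
    # enrichment stage
    run_enrichment: bool = True
    # simulate-mode knobs
    normal_like_pituitary: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        contrasts = [Contrast(**c) for c in raw.pop("contrasts", [])]
        if "gd2_genes" in raw and raw["gd2_genes"] is not None:
            raw["gd2_genes"] = tuple(raw["gd2_genes"])
        cfg = cls(contrasts=contrasts, **raw)
        return cfg

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["contrasts"] = [c.__dict__ for c in self.contrasts]
        if self.gd2_genes is not None:
            d["gd2_genes"] = list(self.gd2_genes)
        return d

    @classmethod
    def default_synthetic(cls, seed: int = 0) -> "RunConfig":
        return cls(
            seed=seed,
            simulate=True,
            contrasts=[
                Contrast("pituitary", "pituitary_tumor", "pituitary_normal"),
                Contrast("lung", "lung_tumor", "lung_normal"),
                Contrast("pancreas", "pancreas_tumor", "pancreas_normal"),
            ],
        )


def lung_specific_genes(
    deg_results: Mapping[str, DEResults] | Sequence[DEResults],
) -> tuple[list[str], list[str]]:
    """Genes consistently up (resp. down) in every supplied contrast.

    For the tissue-specific signature the contrasts share the same case
    group (e.g. lung tumors vs pituitary tumors, vs normal lungs, vs
    normal pituitaries); a gene qualifies only when it passes the gates
    in the same direction in all of them simultaneously.
    """
    results = list(deg_results.values()) if isinstance(deg_results, Mapping) else list(deg_results)
    if not results:
        raise ValueError("no contrasts supplied")
    up = set(results[0].up)
    down = set(results[0].down)
    for res in results[1:]:
        up &= set(res.up)
        down &= set(res.down)
    return sorted(up), sorted(down)


def _derive_seed(master: int, stage: int) -> int:
    return (master * 1_000_003 + stage * 7919) % (2**31 - 1)


class _Manifest:
    def __init__(self, config: RunConfig) -> None:
        self.data = {
            "tool": "cortiscope",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "stages": [],
        }

    def stage(self, name: str, **info) -> None:
        self.data["stages"].append({"name": name, **info})

    def write(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _timed(manifest: _Manifest, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is not None:
                logger.error("stage %s: failed after %.2fs", name, dt)
                raise RuntimeError(f"pipeline stage {name!r} failed") from exc
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Ctx()


def _load_inputs(config: RunConfig, out: Path, manifest: _Manifest):
    """Simulate or load the cohort and every auxiliary input."""
    if config.simulate:
        spec = default_cohort_spec(
            seed=config.seed, normal_like_pituitary=config.normal_like_pituitary
        )
        cm, truth = simulate_cohort(spec)
        pathways, _ = simulate_pathways(truth, seed=_derive_seed(config.seed, 1))
        annotation = simulate_annotation(seed=_derive_seed(config.seed, 2))
        tumor_samples = [
            s for s in cm.sample_ids if cm.sample_meta.loc[s, "condition"] == "case"
        ]
        fusion_tables, fusion_truth = simulate_fusion_tables(
            annotation,
            tumor_samples,
            plant={
                "read_through": 5,
                "transcript_variant": 2,
                "rearrangement": 5,
                "mitochondrial": 3,
                "low_support": 5,
            },
            seed=_derive_seed(config.seed, 3),
            recurrent=[("rearrangement", 3)],
        )
        rng = np.random.default_rng(_derive_seed(config.seed, 4))
        gene_universe = truth.gene_ids
        collection = {}
        for i in range(20):
            genes = rng.choice(gene_universe, size=20, replace=False)
            collection[f"T{i + 1:03d}"] = GeneSet(name=f"random set {i + 1}", genes=frozenset(map(str, genes)))
        shared_up = sorted(
            set.intersection(*(set(truth.up_genes(g)) for g in truth.degs))
        )
        if shared_up:
            collection["T_SHARED_UP"] = GeneSet(
                name="planted shared upregulated genes", genes=frozenset(shared_up)
            )
        drugs = _simulated_drugs(truth, pathways, rng)
        gd2_genes = config.gd2_genes or tuple(shared_up[:2])
        write_count_matrix(cm, out / "counts.tsv")
        write_sample_sheet(cm, out / "samples.tsv")
        write_annotation(annotation, out / "annotation.tsv")
        manifest.stage(
            "simulate",
            n_genes=cm.n_genes,
            n_samples=cm.n_samples,
            n_pathways=len(pathways),
            n_planted_fusions=len(fusion_truth),
        )
        return cm, pathways, annotation, fusion_tables, collection, drugs, gd2_genes
    # load mode
    if not (config.counts_path and config.samples_path):
        raise ValueError("load mode needs counts_path and samples_path")
    cm = read_count_matrix(config.counts_path, config.samples_path)
    pathways = read_pathways(config.pathways_path) if config.pathways_path else {}
    annotation = read_annotation(config.annotation_path) if config.annotation_path else None
    fusion_tables = {
        sample: read_fusion_table(path, sample)
        for sample, path in sorted(config.fusion_tables.items())
    }
    collection = read_gene_sets_gmt(config.gmt_path) if config.gmt_path else {}
    drugs = read_drug_models(config.drugs_path, pathways or None) if config.drugs_path else []
    manifest.stage("load", n_genes=cm.n_genes, n_samples=cm.n_samples)
    return cm, pathways, annotation, fusion_tables, collection, drugs, config.gd2_genes


def _simulated_drugs(truth, pathways, rng) -> list[DrugModel]:
    """Drugs with planted-up targets (responsive) and neutral targets."""
    shared_up = sorted(set.intersection(*(set(truth.up_genes(g)) for g in truth.degs)))
    planted = {g for d in truth.degs.values() for g in d}
    neutral = sorted(set(truth.gene_ids) - planted)
    drugs = []
    pw_ids = sorted(pathways)
    for i in range(3):
        targets = rng.choice(shared_up, size=min(3, len(shared_up)), replace=False)
        drugs.append(
            DrugModel(
                drug_id=f"drug_up_{i + 1}",
                target_gene_ids=frozenset(map(str, targets)),
                pathway_ids=frozenset(pw_ids[:2]) if i == 0 and pw_ids else frozenset(),
            )
        )
    for i in range(2):
        targets = rng.choice(neutral, size=3, replace=False)
        drugs.append(
            DrugModel(drug_id=f"drug_neutral_{i + 1}", target_gene_ids=frozenset(map(str, targets)))
        )
    return drugs


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute every configured stage; returns the report directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)

    with _timed(manifest, "inputs"):
        (cm, pathways, annotation, fusion_tables, collection, drugs, gd2_genes) = _load_inputs(
            config, out, manifest
        )

    # --- structure: PCA and normal-like exclusion per contrast ------------
    excluded: dict[str, list[str]] = {}
    with _timed(manifest, "structure"):
        vst = vst_transform(cm)
        full_pca = pca(vst, n_top_genes=config.n_top_genes)
        full_pca.scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample_id")
        if config.run_exclusion:
            for contrast in config.contrasts:
                tumor_ids = cm.samples_in_group(contrast.case_group)
                normal_ids = cm.samples_in_group(contrast.control_group)
                sub = pca(vst.loc[:, tumor_ids + normal_ids], n_top_genes=config.n_top_genes)
                excluded[contrast.name] = exclude_normal_like(
                    sub, tumor_ids, normal_ids, config.k_components
                )
        rows = [
            {"contrast": name, "sample_id": s, "rule": "pc_centroid_distance"}
            for name, samples in sorted(excluded.items())
            for s in samples
        ]
        pd.DataFrame(rows, columns=["contrast", "sample_id", "rule"]).to_csv(
            out / "excluded_samples.tsv", sep="\t", index=False
        )
        manifest.stage(
            "structure",
            n_components=full_pca.n_components,
            excluded={k: sorted(v) for k, v in excluded.items()},
        )

    # --- differential expression per contrast -----------------------------
    results: dict[str, DEResults] = {}
    case_samples_by_contrast: dict[str, list[str]] = {}
    with _timed(manifest, "diffexp"):
        for contrast in config.contrasts:
            dropped = set(excluded.get(contrast.name, []))
            case_samples = [
                s for s in cm.samples_in_group(contrast.case_group) if s not in dropped
            ]
            case_samples_by_contrast[contrast.name] = case_samples
            model = NBDifferentialExpression(
                cm,
                case=contrast.case_group,
                control=contrast.control_group,
                case_samples=case_samples,
                min_total=config.min_total,
            )
            res = model.fit(config.lfc_threshold, config.alpha, config.strict)
            res.write(out / f"deg_{contrast.name}.tsv")
            results[contrast.name] = res
            manifest.stage(
                f"diffexp:{contrast.name}",
                n_up=len(res.up),
                n_down=len(res.down),
                n_tested=len(res.tested_genes),
            )

    # --- enrichment -------------------------------------------------------
    if config.run_enrichment and collection:
        with _timed(manifest, "enrichment"):
            for name, res in results.items():
                background = res.tested_genes
                degs = [g for g in res.up + res.down if g in set(background)]
                table = ora(degs, collection, background)
                table.to_csv(out / f"enrichment_{name}.tsv", sep="\t")
                manifest.stage(f"enrichment:{name}", n_terms_tested=len(table))

    # --- overlap significance --------------------------------------------
    with _timed(manifest, "overlap"):
        universe = set.intersection(*(set(r.tested_genes) for r in results.values()))
        rows = []
        for direction in ("up", "down"):
            sets = [
                set(getattr(results[c.name], direction)) & universe
                for c in config.contrasts
            ]
            observed = len(set.intersection(*sets)) if sets else 0
            sizes = [len(s) for s in sets]
            test = permutation_overlap_test(
                sizes if all(sizes) else [max(s, 1) for s in sizes],
                observed,
                len(universe),
                n_permutations=config.n_permutations,
                seed=_derive_seed(config.seed, 10 if direction == "up" else 11),
            )
            rows.append(
                {
                    "direction": direction,
                    "set_sizes": ",".join(map(str, sizes)),
                    "universe": len(universe),
                    "observed_overlap": observed,
                    "expected_overlap": expected_overlap(
                        [max(s, 1) for s in sizes], len(universe)
                    ),
                    "p_value": test.p_value,
                    "p_is_upper_bound": test.p_is_upper_bound,
                    "n_permutations": test.n_permutations,
                }
            )
        pd.DataFrame(rows).to_csv(out / "overlap.tsv", sep="\t", index=False)
        manifest.stage("overlap", universe=len(universe))

    # --- pathway activation ----------------------------------------------
    with _timed(manifest, "pal"):
        pal_tables = {}
        if pathways:
            for contrast in config.contrasts:
                table = group_pal(
                    cm,
                    case_samples_by_contrast[contrast.name],
                    cm.samples_in_group(contrast.control_group),
                    pathways,
                )
                table.to_csv(out / f"pal_{contrast.name}.tsv", sep="\t")
                pal_tables[contrast.name] = table
            common = _common_pathways(pal_tables)
            common.to_csv(out / "common_pathways.tsv", sep="\t")
            manifest.stage("pal", n_pathways=len(pathways), n_common=len(common))
        else:
            manifest.stage("pal", n_pathways=0, n_common=0)

    # --- fusion screen ----------------------------------------------------
    if config.run_fusions and fusion_tables and annotation is not None:
        with _timed(manifest, "fusions"):
            all_records = [r for sample in sorted(fusion_tables) for r in fusion_tables[sample]]
            candidates = screen_fusions(
                all_records,
                annotation,
                rt_max_gap=config.rt_max_gap,
                support_mode=config.support_mode,
            )
            candidates_to_frame(candidates).to_csv(
                out / "fusion_candidates.tsv", sep="\t", index=False
            )
            recurrence_table(candidates).to_csv(
                out / "fusion_recurrence.tsv", sep="\t", index=False
            )
            n_retained = sum(1 for c in candidates if c.fate == "retained")
            manifest.stage("fusions", n_candidates=len(candidates), n_retained=n_retained)

    # --- therapy scoring --------------------------------------------------
    if config.run_drugs and drugs:
        with _timed(manifest, "drugs"):
            norm = normalized_expression(cm)
            for contrast in config.contrasts:
                case_samples = case_samples_by_contrast[contrast.name]
                control_samples = cm.samples_in_group(contrast.control_group)
                matrix = bes_matrix(
                    cm, case_samples, control_samples, drugs, pathways or None
                )
                matrix.to_csv(out / f"bes_{contrast.name}.tsv", sep="\t", index_label="drug_id")
                if matrix.shape[1] >= 2:
                    clusters = cluster_bes(matrix, n_clusters=min(2, matrix.shape[1]))
                    clusters.to_csv(
                        out / f"bes_clusters_{contrast.name}.tsv",
                        sep="\t",
                        index_label="sample_id",
                    )
                controls = norm.loc[:, control_samples]
                cnr_by_sample = pd.DataFrame(
                    {s: cnr(norm[s], controls) for s in case_samples}
                )
                props = []
                for drug in drugs:
                    t = target_upregulation_proportion(drug, cnr_by_sample)
                    t.insert(0, "drug_id", drug.drug_id)
                    props.append(t.reset_index())
                pd.concat(props, ignore_index=True).to_csv(
                    out / f"target_proportions_{contrast.name}.tsv", sep="\t", index=False
                )
            manifest.stage("drugs", n_drugs=len(drugs))
        if gd2_genes and all(g in cm.gene_ids for g in gd2_genes):
            with _timed(manifest, "gd2"):
                rows = []
                for contrast in config.contrasts:
                    scores = gd2_signature(
                        cm,
                        case_samples_by_contrast[contrast.name],
                        cm.samples_in_group(contrast.control_group),
                        signature_genes=tuple(gd2_genes),
                    )
                    rows += [
                        {
                            "contrast": contrast.name,
                            "sample_id": s.sample_id,
                            "score": s.score,
                            "call": s.call,
                        }
                        for s in scores
                    ]
                pd.DataFrame(rows).to_csv(out / "gd2.tsv", sep="\t", index=False)
                manifest.stage("gd2", signature=list(gd2_genes))

    manifest.write(out / "manifest.json")
    return out


def _common_pathways(pal_tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Pathways with the same PAL sign in every contrast."""
    names = sorted(pal_tables)
    merged = pd.concat(
        {name: pal_tables[name]["pal"] for name in names}, axis=1, join="inner"
    )
    signs = np.sign(merged)
    consistent = (signs.nunique(axis=1) == 1) & (signs.iloc[:, 0] != 0)
    out = merged[consistent].copy()
    out["trend"] = np.where(signs[consistent].iloc[:, 0] > 0, "up", "down")
    return out
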