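"""Seed-reproducible synthetic cohorts with planted ground truth.

The generator emulates the statistical structure of a multi-tissue
tumor/normal bulk RNA-seq study so that every downstream stage is
testable without real data:

* gene baseline means are log-normal (meanlog 4, sdlog 1.5 by default),
  giving a realistic bulk dynamic range and sparsity;
* counts are negative binomial with Var = mu + dispersion * mu^2, per
  sample scaled by a library size factor;
* per-tissue multiplicative effects separate tissues in PCA space while
  cancelling inside tumor-vs-matched-normal contrasts;
* differential expression is planted as per-(gene, group) log2
  fold-changes applied to the group mean;
* optionally, k "normal-like" tumor samples per group are drawn from
  the matched control distribution to exercise the PCA exclusion rule;
* pathways with activator/repressor structure are built on top of the
  planted fold-changes so their expected activation sign is known;
* fusion tables plant candidates of every filter fate and class
  (low-support, mitochondrial partner, read-through, rearrangement,
  transcript variant) with the intended outcome recorded.

Everything is driven by one integer seed through a single
``numpy.random.Generator``; identical seeds give identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, FusionRecord, PathwayModel

__all__ = [
    "GroupSpec",
    "PlantedDeg",
    "CohortSpec",
    "PlantedFusion",
    "PlantedTruth",
    "default_cohort_spec",
    "simulate_cohort",
    "simulate_pathways",
    "simulate_annotation",
    "simulate_fusion_tables",
    "nb_counts",
]


@dataclass(frozen=True)
class GroupSpec:
    label: str
    condition: str  # "case" | "control"
    tissue: str
    n_samples: int


@dataclass(frozen=True)
class PlantedDeg:
    gene_id: str
    group: str
    log2fc: float


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort draw."""

    n_genes: int
    groups: list[GroupSpec]
    baseline_mean_log_mu: float = 4.0
    baseline_mean_log_sigma: float = 1.5
    dispersion: float = 0.1
    dispersion_log_sd: float = 0.0  # > 0 draws gene-wise dispersions
    planted_degs: list[PlantedDeg] = field(default_factory=list)
    library_size_log_sd: float = 0.15
    library_size_factors: dict[str, float] | None = None
    tissue_effect_log_sd: float = 0.7
    normal_like: dict[str, int] = field(default_factory=dict)  # group -> k samples
    seed: int = 0

    def validate(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.library_size_factors is not None and any(
            f <= 0 for f in self.library_size_factors.values()
        ):
            raise ValueError("size factors must be > 0")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels")
        genes = set(gene_ids(self.n_genes))
        for deg in self.planted_degs:
            if deg.gene_id not in genes:
                raise ValueError(f"planted gene id out of range: {deg.gene_id!r}")
            if deg.group not in labels:
                raise ValueError(f"planted DEG references unknown group {deg.group!r}")


@dataclass
class PlantedFusion:
    record: FusionRecord
    intended_fate: str  # retained | removed_low_support | removed_mitochondrial
    intended_class: str | None  # read_through | chromosomal_rearrangement | transcript_variant


@dataclass
class PlantedTruth:
    """The realized ground truth of one synthetic cohort."""

    gene_ids: list[str]
    degs: dict[str, dict[str, float]]  # group -> gene -> log2fc
    normal_like: dict[str, list[str]] = field(default_factory=dict)
    expected_pal_signs: dict[str, int] = field(default_factory=dict)
    fusion_truth: list[PlantedFusion] = field(default_factory=list)

    def up_genes(self, group: str) -> list[str]:
        return sorted(g for g, fc in self.degs.get(group, {}).items() if fc > 0)

    def down_genes(self, group: str) -> list[str]:
        return sorted(g for g, fc in self.degs.get(group, {}).items() if fc < 0)


def gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]


def nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray
) -> np.ndarray:
    """NB draws with Var = mean + dispersion * mean^2 (dispersion > 0)."""
    mean = np.asarray(mean, dtype=float)
    dispersion = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def default_cohort_spec(
    seed: int = 0,
    n_genes: int = 2000,
    degs_per_group: int = 40,
    shared_degs: int = 10,
    planted_log2fc: float = 4.0,
    dispersion: float = 0.1,
    normal_like_pituitary: int = 0,
) -> CohortSpec:
    """A study-shaped default: three tumor groups with matched normals.

    Group sizes mirror the analyzed cohort (16 pituitary tumors after
    exclusion vs 7 normals, 6 lung tumors vs 8 normals) except that the
    pancreatic group gets 2 samples, the minimum the two-group NB test
    supports. Each tumor group receives ``degs_per_group`` up- and
    down-regulated genes at +/- ``planted_log2fc``, of which
    ``shared_degs`` up and down are common to all three tumor groups.
    """
    groups = [
        GroupSpec("pituitary_tumor", "case", "pituitary", 16),
        GroupSpec("pituitary_normal", "control", "pituitary", 7),
        GroupSpec("lung_tumor", "case", "lung", 6),
        GroupSpec("lung_normal", "control", "lung", 8),
        GroupSpec("pancreas_tumor", "case", "pancreas", 2),
        GroupSpec("pancreas_normal", "control", "pancreas", 8),
    ]
    tumor_groups = [g.label for g in groups if g.condition == "case"]
    ids = gene_ids(n_genes)
    rng = np.random.default_rng(seed)
    n_specific = degs_per_group - shared_degs
    needed = 2 * shared_degs + 2 * n_specific * len(tumor_groups)
    chosen = rng.choice(n_genes, size=needed, replace=False)
    pool = [ids[i] for i in chosen]
    shared_up, pool = pool[:shared_degs], pool[shared_degs:]
    shared_down, pool = pool[:shared_degs], pool[shared_degs:]
    planted: list[PlantedDeg] = []
    for group in tumor_groups:
        up, pool = pool[:n_specific], pool[n_specific:]
        down, pool = pool[:n_specific], pool[n_specific:]
        for g in shared_up + up:
            planted.append(PlantedDeg(g, group, planted_log2fc))
        for g in shared_down + down:
            planted.append(PlantedDeg(g, group, -planted_log2fc))
    normal_like = (
        {"pituitary_tumor": normal_like_pituitary} if normal_like_pituitary else {}
    )
    return CohortSpec(
        n_genes=n_genes,
        groups=groups,
        dispersion=dispersion,
        planted_degs=planted,
        normal_like=normal_like,
        seed=seed,
    )


def simulate_cohort(spec: CohortSpec) -> tuple[CountMatrix, PlantedTruth]:
    """Draw one cohort: counts plus the realized planted truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ids = gene_ids(spec.n_genes)
    gene_index = {g: i for i, g in enumerate(ids)}

    baseline = rng.lognormal(
        mean=spec.baseline_mean_log_mu, sigma=spec.baseline_mean_log_sigma, size=spec.n_genes
    )
    tissues = sorted({g.tissue for g in spec.groups})
    tissue_mult = {
        t: np.exp(rng.normal(0.0, spec.tissue_effect_log_sd, size=spec.n_genes))
        if spec.tissue_effect_log_sd > 0
        else np.ones(spec.n_genes)
        for t in tissues
    }
    if spec.dispersion_log_sd > 0:
        dispersion = spec.dispersion * np.exp(
            rng.normal(0.0, spec.dispersion_log_sd, size=spec.n_genes)
        )
    else:
        dispersion = np.full(spec.n_genes, spec.dispersion)

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    for g in spec.groups:
        for i in range(g.n_samples):
            sid = f"{g.label}_{i + 1}"
            sample_ids.append(sid)
            meta_rows.append(
                {"sample_id": sid, "tissue": g.tissue, "condition": g.condition, "group": g.label}
            )
    if spec.library_size_factors is not None:
        missing = [s for s in sample_ids if s not in spec.library_size_factors]
        if missing:
            raise ValueError(f"size factors missing for sample(s) {missing[:3]}")
        size_factors = np.array([spec.library_size_factors[s] for s in sample_ids])
    else:
        size_factors = np.exp(rng.normal(0.0, spec.library_size_log_sd, size=len(sample_ids)))

    degs: dict[str, dict[str, float]] = {}
    lfc_by_group: dict[str, np.ndarray] = {g.label: np.zeros(spec.n_genes) for g in spec.groups}
    for deg in spec.planted_degs:
        lfc_by_group[deg.group][gene_index[deg.gene_id]] = deg.log2fc
        degs.setdefault(deg.group, {})[deg.gene_id] = deg.log2fc

    control_mean: dict[str, np.ndarray] = {}  # tissue -> control group mean
    for g in spec.groups:
        if g.condition == "control":
            control_mean[g.tissue] = (
                baseline * tissue_mult[g.tissue] * 2.0 ** lfc_by_group[g.label]
            )

    normal_like: dict[str, list[str]] = {}
    counts = np.empty((spec.n_genes, len(sample_ids)), dtype=np.int64)
    col = 0
    for g in spec.groups:
        group_mean = baseline * tissue_mult[g.tissue] * 2.0 ** lfc_by_group[g.label]
        k_normal_like = spec.normal_like.get(g.label, 0)
        if k_normal_like:
            if g.condition != "case":
                raise ValueError(f"normal_like only applies to case groups ({g.label})")
            if g.tissue not in control_mean:
                raise ValueError(f"no matched control group for tissue {g.tissue!r}")
            if k_normal_like > g.n_samples:
                raise ValueError(f"normal_like exceeds group size for {g.label}")
        for i in range(g.n_samples):
            plant_normal = i < k_normal_like
            mean_vec = control_mean[g.tissue] if plant_normal else group_mean
            sid = f"{g.label}_{i + 1}"
            if plant_normal:
                normal_like.setdefault(g.label, []).append(sid)
            counts[:, col] = nb_counts(rng, size_factors[col] * mean_vec, dispersion)
            col += 1

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=ids, columns=sample_ids),
        sample_meta=pd.DataFrame(meta_rows).set_index("sample_id"),
    )
    truth = PlantedTruth(gene_ids=ids, degs=degs, normal_like=normal_like)
    return cm, truth


# ---------------------------------------------------------------------------
# Pathways with planted activation signs
# ---------------------------------------------------------------------------


def simulate_pathways(
    truth: PlantedTruth,
    n_pathways: int = 10,
    genes_per_pathway: int = 10,
    frac_ambiguous: float = 0.2,
    seed: int = 0,
    group: str | None = None,
) -> tuple[dict[str, PathwayModel], dict[str, int]]:
    """Build pathways whose expected activation sign is known.

    "Activated" pathways draw their activators from planted-up genes and
    their repressors from planted-down genes; "suppressed" pathways do
    the converse; ``frac_ambiguous`` of the members get ARR = 0 and are
    drawn from unplanted genes. With ``group=None`` the planted genes
    consistent in sign across every group that has plants are used, so
    the expected sign holds for all contrasts simultaneously.
    """
    if group is not None:
        up_pool = truth.up_genes(group)
        down_pool = truth.down_genes(group)
    else:
        groups = [g for g, d in truth.degs.items() if d]
        if not groups:
            raise ValueError("no planted DEGs to build pathways from")
        up_pool = sorted(set.intersection(*(set(truth.up_genes(g)) for g in groups)))
        down_pool = sorted(set.intersection(*(set(truth.down_genes(g)) for g in groups)))
    planted_all = {g for d in truth.degs.values() for g in d}
    neutral_pool = sorted(set(truth.gene_ids) - planted_all)

    n_ambiguous = int(round(frac_ambiguous * genes_per_pathway))
    n_informative = genes_per_pathway - n_ambiguous
    if n_informative < 1:
        raise ValueError("every member would be ambiguous; nothing scoreable")
    n_act = (n_informative + 1) // 2
    n_rep = n_informative - n_act
    if n_act > len(up_pool) or n_act > len(down_pool) or n_rep > max(
        len(up_pool), len(down_pool)
    ):
        raise ValueError(
            f"not enough planted genes: need {n_act}+{n_rep}, "
            f"pools have {len(up_pool)} up / {len(down_pool)} down"
        )

    rng = np.random.default_rng(seed)
    pathways: dict[str, PathwayModel] = {}
    expected: dict[str, int] = {}
    for i in range(n_pathways):
        sign = 1 if i % 2 == 0 else -1
        act_pool = up_pool if sign > 0 else down_pool
        rep_pool = down_pool if sign > 0 else up_pool
        if n_rep > len(rep_pool):
            raise ValueError("not enough planted genes for repressor members")
        members: dict[str, int] = {}
        for g in rng.choice(act_pool, size=n_act, replace=False):
            members[str(g)] = 1
        for g in rng.choice(rep_pool, size=n_rep, replace=False):
            members[str(g)] = -1
        if n_ambiguous:
            for g in rng.choice(neutral_pool, size=n_ambiguous, replace=False):
                members[str(g)] = 0
        pid = f"P{i + 1:03d}"
        pathways[pid] = PathwayModel(pathway_id=pid, members=members)
        expected[pid] = sign
    truth.expected_pal_signs.update(expected)
    return pathways, expected


# ---------------------------------------------------------------------------
# Gene annotation and fusion tables
# ---------------------------------------------------------------------------


def simulate_annotation(
    n_genes: int = 60,
    n_chromosomes: int = 3,
    seed: int = 0,
    n_mitochondrial: int = 2,
    n_overlapping_pairs: int = 2,
) -> pd.DataFrame:
    """A compact synthetic gene annotation for fusion-screen tests.

    Genes are laid out sequentially per chromosome with gaps below the
    default read-through window; ``n_overlapping_pairs`` extra genes
    overlap an existing locus on the same strand (transcript-variant
    material) and ``n_mitochondrial`` genes sit on chrM with MT-
    symbols.
    """
    rng = np.random.default_rng(seed)
    rows = []
    per_chrom = int(np.ceil(n_genes / n_chromosomes))
    idx = 1
    for c in range(1, n_chromosomes + 1):
        pos = 10_000
        for _ in range(per_chrom):
            if idx > n_genes:
                break
            length = int(rng.integers(2_000, 50_000))
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"FG{idx:04d}"
            rows.append(
                {
                    "gene_id": gid,
                    "symbol": gid,
                    "chromosome": f"chr{c}",
                    "start": pos,
                    "end": pos + length - 1,
                    "strand": strand,
                }
            )
            pos += length + int(rng.integers(1_000, 30_000))
            idx += 1
    for j in range(n_overlapping_pairs):
        host = rows[int(rng.integers(0, len(rows)))]
        gid = f"FGOV{j + 1:02d}"
        start = host["start"] + (host["end"] - host["start"]) // 2
        rows.append(
            {
                "gene_id": gid,
                "symbol": gid,
                "chromosome": host["chromosome"],
                "start": start,
                "end": start + int(rng.integers(2_000, 20_000)),
                "strand": host["strand"],
            }
        )
    for j in range(n_mitochondrial):
        start = 1_000 + 2_000 * j
        rows.append(
            {
                "gene_id": f"FGMT{j + 1:02d}",
                "symbol": f"MT-G{j + 1}",
                "chromosome": "chrM",
                "start": start,
                "end": start + 1_500,
                "strand": "+",
            }
        )
    df = pd.DataFrame(rows).set_index("gene_id")
    df["is_mitochondrial"] = df["chromosome"] == "chrM"
    return df


def _read_through_pairs(annotation: pd.DataFrame, max_gap: int) -> list[tuple[str, str]]:
    """(left, right) = (5', 3') adjacent same-strand pairs within the gap."""
    pairs = []
    nuclear = annotation[~annotation["is_mitochondrial"]]
    for _, sub in nuclear.groupby("chromosome", sort=True):
        sub = sub.sort_values("start")
        genes = list(sub.itertuples())
        for a, b in zip(genes, genes[1:]):
            if a.strand != b.strand:
                continue
            if b.start <= a.end:  # overlapping, transcript-variant material
                continue
            gap = b.start - a.end - 1
            if gap > max_gap:
                continue
            if a.strand == "+":
                pairs.append((a.Index, b.Index))
            else:
                pairs.append((b.Index, a.Index))
    return pairs


def _overlapping_pairs(annotation: pd.DataFrame) -> list[tuple[str, str]]:
    pairs = []
    nuclear = annotation[~annotation["is_mitochondrial"]]
    for _, sub in nuclear.groupby("chromosome", sort=True):
        genes = list(sub.sort_values("start").itertuples())
        for i, a in enumerate(genes):
            for b in genes[i + 1 :]:
                if b.start > a.end:
                    break
                if a.strand == b.strand:
                    pairs.append((a.Index, b.Index))
    return pairs


def _cross_chromosome_pairs(
    annotation: pd.DataFrame, rng: np.random.Generator, n: int
) -> list[tuple[str, str]]:
    nuclear = annotation[~annotation["is_mitochondrial"]]
    by_chrom = {c: list(sub.index) for c, sub in nuclear.groupby("chromosome", sort=True)}
    chroms = sorted(by_chrom)
    if len(chroms) < 2:
        raise ValueError("need >= 2 chromosomes for rearrangement candidates")
    pairs = []
    seen = set()
    attempts = 0
    while len(pairs) < n and attempts < 100 * n + 100:
        c1, c2 = rng.choice(len(chroms), size=2, replace=False)
        g1 = by_chrom[chroms[c1]][int(rng.integers(len(by_chrom[chroms[c1]])))]
        g2 = by_chrom[chroms[c2]][int(rng.integers(len(by_chrom[chroms[c2]])))]
        if (g1, g2) not in seen:
            seen.add((g1, g2))
            pairs.append((g1, g2))
        attempts += 1
    if len(pairs) < n:
        raise ValueError("request exceeds available gene pairs")
    return pairs


def _breakpoint(annotation: pd.DataFrame, gene: str, side: str) -> tuple[str, int, str]:
    row = annotation.loc[gene]
    if side == "donor":  # 3' end of the 5' partner
        pos = int(row["end"] if row["strand"] == "+" else row["start"])
    else:  # 5' end of the 3' partner
        pos = int(row["start"] if row["strand"] == "+" else row["end"])
    return (str(row["chromosome"]), pos, str(row["strand"]))


def _make_record(
    annotation: pd.DataFrame,
    pair: tuple[str, str],
    sample_id: str,
    junction: int,
    spanning: int,
) -> FusionRecord:
    left, right = pair
    return FusionRecord(
        fusion_name=f"{left}--{right}",
        left_gene=left,
        right_gene=right,
        left_breakpoint=_breakpoint(annotation, left, "donor"),
        right_breakpoint=_breakpoint(annotation, right, "acceptor"),
        junction_read_count=junction,
        spanning_frag_count=spanning,
        sample_id=sample_id,
    )


def simulate_fusion_tables(
    annotation: pd.DataFrame,
    sample_ids: Sequence[str],
    plant: Mapping[str, int],
    seed: int = 0,
    rt_max_gap: int = 100_000,
    recurrent: Sequence[tuple[str, int]] = (),
) -> tuple[dict[str, list[FusionRecord]], list[PlantedFusion]]:
    """Plant fusion candidates with known filter fates and classes.

    ``plant`` maps class to count over the whole cohort; classes are
    ``low_support``, ``mitochondrial``, ``read_through``,
    ``rearrangement`` and ``transcript_variant``. Each candidate lands
    in one random sample. ``recurrent`` lists (class, n_samples) pairs:
    one extra gene pair of that class is planted into that many distinct
    samples. Retained-class candidates get support counts > 2 on both
    evidence types so their fate is decided by the locus geometry alone.
    """
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)

    rt_pool = _read_through_pairs(annotation, rt_max_gap)
    tv_pool = _overlapping_pairs(annotation)
    mito_genes = sorted(annotation.index[annotation["is_mitochondrial"]])
    nuclear_genes = sorted(annotation.index[~annotation["is_mitochondrial"]])

    def take(pool: list[tuple[str, str]], n: int, what: str) -> list[tuple[str, str]]:
        if n > len(pool):
            raise ValueError(f"request exceeds available gene pairs for {what}")
        chosen = rng.choice(len(pool), size=n, replace=False)
        return [pool[int(i)] for i in chosen]

    def strong_support() -> tuple[int, int]:
        return int(rng.integers(3, 30)), int(rng.integers(3, 20))

    tables: dict[str, list[FusionRecord]] = {s: [] for s in sample_ids}
    truth: list[PlantedFusion] = []

    def plant_one(pair, sample, junction, spanning, fate, cls):
        rec = _make_record(annotation, pair, sample, junction, spanning)
        tables[sample].append(rec)
        truth.append(PlantedFusion(record=rec, intended_fate=fate, intended_class=cls))

    def random_sample() -> str:
        return sample_ids[int(rng.integers(len(sample_ids)))]

    n_rt = plant.get("read_through", 0)
    for pair in take(rt_pool, n_rt, "read_through"):
        j, s = strong_support()
        plant_one(pair, random_sample(), j, s, "retained", "read_through")

    n_tv = plant.get("transcript_variant", 0)
    for pair in take(tv_pool, n_tv, "transcript_variant"):
        j, s = strong_support()
        plant_one(pair, random_sample(), j, s, "retained", "transcript_variant")

    n_cr = plant.get("rearrangement", 0)
    for pair in _cross_chromosome_pairs(annotation, rng, n_cr):
        j, s = strong_support()
        plant_one(pair, random_sample(), j, s, "retained", "chromosomal_rearrangement")

    n_mito = plant.get("mitochondrial", 0)
    if n_mito and not mito_genes:
        raise ValueError("annotation has no mitochondrial genes")
    for _ in range(n_mito):
        mt = mito_genes[int(rng.integers(len(mito_genes)))]
        other = nuclear_genes[int(rng.integers(len(nuclear_genes)))]
        pair = (mt, other) if rng.random() < 0.5 else (other, mt)
        j, s = strong_support()
        plant_one(pair, random_sample(), j, s, "removed_mitochondrial", None)

    n_low = plant.get("low_support", 0)
    for pair in _cross_chromosome_pairs(annotation, rng, n_low):
        j = int(rng.integers(0, 3))
        s = int(rng.integers(0, 3))
        plant_one(pair, random_sample(), j, s, "removed_low_support", None)

    for cls, k in recurrent:
        if k > len(sample_ids):
            raise ValueError("recurrent plant exceeds sample count")
        if cls == "read_through":
            pair = take(rt_pool, 1, "recurrent read_through")[0]
            cls_name = "read_through"
        elif cls == "transcript_variant":
            pair = take(tv_pool, 1, "recurrent transcript_variant")[0]
            cls_name = "transcript_variant"
        elif cls == "rearrangement":
            pair = _cross_chromosome_pairs(annotation, rng, 1)[0]
            cls_name = "chromosomal_rearrangement"
        else:
            raise ValueError(f"recurrent plants must be retained classes, got {cls!r}")
        chosen = rng.choice(len(sample_ids), size=k, replace=False)
        for si in chosen:
            j, s = strong_support()
            plant_one(pair, sample_ids[int(si)], j, s, "retained", cls_name)

    return tables, truth
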