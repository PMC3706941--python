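"""Named analyses of the berry plasticity study, orchestrated end to end.

Gene classes produced from a multi-vineyard, multi-stage expression matrix:

* plastic genes — modulated across vineyards (11-group Kruskal-Wallis);
* factor-associated genes — modulated across levels of an environmental or
  viticulture factor (trellis system, rootstock, area, ...);
* harvest analysis — vineyard-modulated genes at the ripe stage (SAM +
  2-fold screen) and the two-group vineyard partition they induce;
* developmental markers — monotone up/down stage profiles shared by all
  vineyards (SAM + ANOVA/Bonferroni + k-means + fold-change percentile);
* constitutive reference genes — no vineyard or stage modulation and
  minimal variance (candidate normalisation references).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import Dendrogram, hierarchical_dendrogram, kmeans_profiles, pearson_distance_matrix
from .core_data import ExpressionMatrix, GeneSet, average_replicates
from .stats_tests import (
    SamResult,
    anova_many,
    benjamini_hochberg,
    kruskal_wallis_many,
    sam,
    t_test_many,
)

logger = logging.getLogger("berryplast.pipeline")

__all__ = [
    "PlasticGenesResult",
    "FactorAssociationResult",
    "HarvestResult",
    "MarkerResult",
    "ConstitutiveResult",
    "GeneClassification",
    "call_plastic_genes",
    "factor_association",
    "harvest_analysis",
    "select_developmental_markers",
    "select_constitutive_genes",
    "classify_genes",
    "intersect_sets",
    "plastic_percentages",
    "PipelineConfig",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# plastic genes


@dataclass
class PlasticGenesResult:
    plastic: GeneSet
    p_values: pd.Series                  # per unimodal gene
    per_vineyard_modulated: dict[str, int]
    summary: dict[str, float]


def call_plastic_genes(m: ExpressionMatrix, unimodal: GeneSet,
                       alpha: float = 0.01) -> PlasticGenesResult:
    """Kruskal-Wallis across vineyards on the unimodal set: plastic genes.

    The summary also reports, per vineyard, how many unimodal genes are
    modulated across stages (same test, stage groups), their average, and
    the plastic set as a percentage of that average and of the whole array.
    The per-vineyard test uses the exact permutation p when the vineyard has
    few samples (the chi-square approximation cannot reach p < 0.01 with
    three replicates per stage), and the chi-square p otherwise.
    """
    vineyards = m.vineyards()
    if len(vineyards) < 2:
        raise ValueError("need >= 2 vineyards")
    mu = m.subset_genes(unimodal.members)
    groups = [s.vineyard for s in mu.samples]
    H, p = kruskal_wallis_many(mu.values, groups)
    pvals = pd.Series(p, index=mu.gene_ids)
    plastic = GeneSet("plastic", frozenset(pvals.index[pvals < alpha]))
    per_vin: dict[str, int] = {}
    for v in vineyards:
        mv = mu.select(vineyard=v)
        if len(set(s.stage for s in mv.samples)) < 2:
            raise ValueError(f"vineyard {v} lacks multiple stages for the ripening test")
        method = "exact" if mv.n_samples <= 10 else "chi2"
        _, pv = kruskal_wallis_many(mv.values, [s.stage for s in mv.samples], method=method)
        per_vin[v] = int((pv < alpha).sum())
    avg_mod = float(np.mean(list(per_vin.values())))
    pct_mod, pct_array = plastic_percentages(len(plastic), avg_mod, m.n_genes)
    summary = {
        "n_plastic": len(plastic),
        "n_unimodal": mu.n_genes,
        "avg_modulated": avg_mod,
        "pct_of_modulated": pct_mod,
        "pct_of_array": pct_array,
        "alpha": alpha,
        "n_vineyard_groups": len(vineyards),
    }
    return PlasticGenesResult(plastic, pvals, per_vin, summary)


def plastic_percentages(n_plastic: float, avg_modulated: float,
                        n_array: float) -> tuple[float, float]:
    """Plastic genes as %% of the average ripening-modulated count and of
    the array content."""
    pct_mod = 100.0 * n_plastic / avg_modulated if avg_modulated else float("nan")
    return (pct_mod, 100.0 * n_plastic / n_array)


# ---------------------------------------------------------------------------
# factor association


@dataclass
class FactorAssociationResult:
    significant: GeneSet
    p_values: pd.Series
    q_values: pd.Series
    permutation_fdr: float
    n_permutations: int
    levels: list


def factor_association(
    m: ExpressionMatrix,
    unimodal: GeneSet,
    factor: Mapping[str, object] | Callable[[object], object],
    alpha: float = 0.01,
    n_perms: int = 100,
    seed: int = 0,
    permutation: str = "samples",
) -> FactorAssociationResult:
    """Kruskal-Wallis across the levels of a sample factor.

    ``factor`` maps sample name -> level (or is a callable on the
    descriptor).  Besides BH q-values, a permutation FDR is estimated
    (mean permutation significant count / observed count).  Two null
    schemes are available: ``permutation="samples"`` (default) shuffles the
    factor labels freely across samples — the global no-association null —
    while ``permutation="vineyard"`` shuffles the vineyard -> level
    assignment with whole vineyards moving together, a stricter null that
    asks whether the factor explains more than an arbitrary vineyard
    grouping would (factor effects that are really generic vineyard
    effects stay "significant" under it).
    """
    mu = m.subset_genes(unimodal.members)
    if callable(factor):
        levels = [factor(s) for s in mu.samples]
    else:
        levels = [factor[name] for name in mu.sample_names]
    uniq = sorted(set(levels), key=str)
    if len(uniq) < 2:
        raise ValueError("factor needs >= 2 levels")
    for lv in uniq:
        if levels.count(lv) == 0:  # pragma: no cover - cannot happen by construction
            raise ValueError(f"level {lv} has no samples")
    H, p = kruskal_wallis_many(mu.values, levels)
    pvals = pd.Series(p, index=mu.gene_ids)
    q = pd.Series(benjamini_hochberg(p), index=mu.gene_ids)
    sig = GeneSet("factor_associated", frozenset(pvals.index[pvals < alpha]))

    vins = [s.vineyard for s in mu.samples]
    by_vin: dict[str, set] = {}
    for v, lv in zip(vins, levels):
        by_vin.setdefault(v, set()).add(lv)
    vineyard_constant = all(len(s) == 1 for s in by_vin.values())
    if permutation not in ("samples", "vineyard"):
        raise ValueError("permutation must be 'samples' or 'vineyard'")
    if permutation == "vineyard" and not vineyard_constant:
        raise ValueError("vineyard-block permutation requires a vineyard-level factor")
    rng = np.random.default_rng(seed)
    vals = mu.values
    perm_counts = []
    vin_list = list(by_vin)
    vin_level = {v: next(iter(s)) for v, s in by_vin.items()} if vineyard_constant else None
    for _ in range(n_perms):
        if permutation == "vineyard":
            shuffled = rng.permutation(len(vin_list))
            new_level = {v: vin_level[vin_list[j]] for v, j in zip(vin_list, shuffled)}
            perm_levels = [new_level[v] for v in vins]
        else:
            idx = rng.permutation(len(levels))
            perm_levels = [levels[j] for j in idx]
        _, pp = kruskal_wallis_many(vals, perm_levels)
        perm_counts.append(int((pp < alpha).sum()))
    n_sig = max(len(sig), 1)
    perm_fdr = float(np.mean(perm_counts)) / n_sig
    return FactorAssociationResult(sig, pvals, q, perm_fdr, n_perms, uniq)


# ---------------------------------------------------------------------------
# harvest analysis


@dataclass
class HarvestResult:
    sam_result: SamResult
    modulated: GeneSet                   # SAM-significant
    retained: GeneSet                    # >= fold_threshold in some vineyard pair
    dendrogram: Dendrogram
    vineyard_groups: dict[str, int]      # vineyard -> 1 | 2
    t_p_values: pd.Series
    t_significant: GeneSet


def harvest_analysis(
    m_stage3: ExpressionMatrix,
    fdr_target: float = 0.001,
    fold_threshold: float = 2.0,
    alpha_t: float = 0.05,
    linkage: str = "average",
    n_perms: int = 100,
    seed: int = 0,
) -> HarvestResult:
    """Vineyard-modulated genes at one stage and the 2-group sample split.

    SAM multiclass across vineyards at ``fdr_target``; genes kept if their
    largest vineyard-mean log2 difference reaches log2(fold_threshold); the
    retained genes' sample correlation dendrogram is cut into two vineyard
    groups which are then contrasted gene-wise by t-test at ``alpha_t``.
    """
    vineyards = m_stage3.vineyards()
    if len(vineyards) < 3:
        raise ValueError("need >= 3 vineyards for a two-group partition")
    labels = [s.vineyard for s in m_stage3.samples]
    samres = sam(m_stage3, labels, mode="multiclass", fdr_target=fdr_target,
                 n_perms=n_perms, seed=seed)
    modulated = GeneSet("harvest_modulated", samres.significant.members)
    avg = average_replicates(m_stage3)
    sub = avg.subset_genes(modulated.members) if modulated.members else None
    if sub is None or sub.n_genes == 0:
        retained = GeneSet("harvest_retained", frozenset())
    else:
        vals = sub.values
        span = vals.max(axis=1) - vals.min(axis=1)   # max pairwise |delta|
        keep = span >= np.log2(fold_threshold)
        retained = GeneSet("harvest_retained",
                           frozenset(g for g, k in zip(sub.gene_ids, keep) if k))
    dm_source = avg.subset_genes(retained.members) if retained.members else avg
    d = pearson_distance_matrix(dm_source, axis="samples")
    dend = hierarchical_dendrogram(d, linkage=linkage, labels=dm_source.sample_names)
    cut = dend.cut(2)
    vin_groups = {s.vineyard: int(c) for s, c in zip(dm_source.samples, cut)}
    group_labels = [vin_groups[s.vineyard] for s in m_stage3.samples]
    if len(set(group_labels)) < 2:
        raise ValueError("two-cluster cut produced a single vineyard group")
    tvals, tp, _ = t_test_many(m_stage3.values, group_labels)
    t_p = pd.Series(tp, index=m_stage3.gene_ids)
    t_sig = GeneSet("harvest_t_significant", frozenset(t_p.index[t_p < alpha_t]))
    return HarvestResult(samres, modulated, retained, dend, vin_groups, t_p, t_sig)


# ---------------------------------------------------------------------------
# developmental markers


@dataclass
class MarkerResult:
    up: GeneSet
    down: GeneSet
    stage_modulated: GeneSet             # SAM ∩ ANOVA/Bonferroni
    clusters: object                     # ProfileClusters
    stage_delta: pd.Series               # per stage-modulated gene: stage3 - stage1
    warning: str | None = None


def select_developmental_markers(
    m: ExpressionMatrix,
    fdr_target: float = 0.001,
    alpha: float = 0.01,
    k: int = 8,
    percentile: float = 95.0,
    n_perms: int = 100,
    seed: int = 0,
) -> MarkerResult:
    """Monotone stage markers shared by all vineyards.

    Stage-modulated genes are SAM multiclass (stage groups, vineyards as
    replication) intersected with ANOVA at ``alpha`` Bonferroni-corrected
    over the SAM-significant count; their replicate-averaged profiles are
    k-means clustered (correlation distance) and only monotone up/down
    clusters survive, screened for the largest first-to-last-stage log2
    change (``percentile``-th percentile, per direction).
    """
    stages = m.stages()
    if len(stages) < 3:
        raise ValueError("marker selection requires all three stages")
    stage_labels = [s.stage for s in m.samples]
    samres = sam(m, stage_labels, mode="multiclass", fdr_target=fdr_target,
                 n_perms=n_perms, seed=seed)
    sam_set = samres.significant.members
    empty = GeneSet("marker", frozenset())
    if not sam_set:
        return MarkerResult(empty, empty, GeneSet("stage_modulated", frozenset()),
                            None, pd.Series(dtype=float), "no SAM-significant genes")
    msam = m.subset_genes(sam_set)
    F, p_anova = anova_many(msam.values, [s.stage for s in msam.samples])
    keep = p_anova < alpha / len(sam_set)
    modulated = GeneSet("stage_modulated",
                        frozenset(g for g, kk in zip(msam.gene_ids, keep) if kk))
    if not modulated.members:
        return MarkerResult(empty, empty, modulated, None, pd.Series(dtype=float),
                            "no gene survived ANOVA/Bonferroni")
    avg = average_replicates(m).subset_genes(modulated.members)
    clusters = kmeans_profiles(avg, k=min(k, avg.n_genes), metric="pearson", seed=seed)
    i1 = [i for i, s in enumerate(avg.samples) if s.stage == stages[0]]
    i3 = [i for i, s in enumerate(avg.samples) if s.stage == stages[-1]]
    delta = pd.Series(avg.values[:, i3].mean(axis=1) - avg.values[:, i1].mean(axis=1),
                      index=avg.gene_ids)
    out: dict[str, frozenset[str]] = {}
    for direction in ("up", "down"):
        cluster_ids = clusters.monotone_clusters(direction)
        genes = frozenset().union(*[clusters.genes_in(c) for c in cluster_ids]) if cluster_ids else frozenset()
        if genes:
            vals = delta.loc[list(genes)]
            mag = vals if direction == "up" else -vals
            cut = np.percentile(mag.to_numpy(), percentile)
            genes = frozenset(mag.index[mag >= cut])
        out[direction] = genes
    warning = None
    if not out["up"] and not out["down"]:
        warning = "no monotone cluster found"
    return MarkerResult(GeneSet("marker_up", out["up"]),
                        GeneSet("marker_down", out["down"]),
                        modulated, clusters, delta, warning)


# ---------------------------------------------------------------------------
# constitutive genes


@dataclass
class ConstitutiveResult:
    constitutive: GeneSet
    shared: GeneSet                      # stable in all three stages
    per_stage_stable: dict[int, int]
    sd_table: pd.Series                  # ascending SD over the full design
    warning: str | None = None


def select_constitutive_genes(
    m: ExpressionMatrix,
    fdr_target: float = 0.001,
    alpha: float = 0.01,
    sd_percentile: float = 99.0,
    n_perms: int = 100,
    seed: int = 0,
) -> ConstitutiveResult:
    """Reference genes: no vineyard modulation at any stage, minimal SD.

    Per stage, genes non-significant under both SAM multiclass (vineyard
    groups, ``fdr_target``) and one-way ANOVA (``alpha``) are retained; the
    three per-stage sets are intersected and ranked by standard deviation
    across all samples of the full design, keeping the lowest
    (100 - sd_percentile)%% — by default the SD values below the 1st
    percentile of the shared set.
    """
    stages = m.stages()
    per_stage_sets: list[frozenset[str]] = []
    per_stage_counts: dict[int, int] = {}
    for t in stages:
        mt = m.select(stage=t)
        labels = [s.vineyard for s in mt.samples]
        samres = sam(mt, labels, mode="multiclass", fdr_target=fdr_target,
                     n_perms=n_perms, seed=seed)
        F, p = anova_many(mt.values, labels)
        anova_sig = {g for g, pp in zip(mt.gene_ids, p) if pp < alpha}
        stable = frozenset(m.gene_ids) - samres.significant.members - anova_sig
        per_stage_sets.append(stable)
        per_stage_counts[t] = len(stable)
    shared = frozenset.intersection(*per_stage_sets) if per_stage_sets else frozenset()
    if not shared:
        return ConstitutiveResult(GeneSet("constitutive", frozenset()),
                                  GeneSet("shared_stable", frozenset()),
                                  per_stage_counts, pd.Series(dtype=float),
                                  "no gene stable in all stages")
    sub = m.subset_genes(shared)
    sd = pd.Series(sub.values.std(axis=1, ddof=1), index=sub.gene_ids).sort_values(kind="mergesort")
    cut = np.percentile(sd.to_numpy(), 100.0 - sd_percentile)
    kept = frozenset(sd.index[sd.to_numpy() <= cut])
    return ConstitutiveResult(GeneSet("constitutive", kept),
                              GeneSet("shared_stable", shared),
                              per_stage_counts, sd)


# ---------------------------------------------------------------------------
# classification and set algebra


@dataclass
class GeneClassification:
    labels: dict[str, str]
    provenance: dict[str, dict]
    conflicts: list[tuple[str, str, str]]   # gene, winning label, losing label

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gene_id": g, "class": c, **self.provenance.get(g, {})}
                for g, c in self.labels.items()]
        return pd.DataFrame(rows)

    def genes_of(self, label: str) -> frozenset[str]:
        return frozenset(g for g, c in self.labels.items() if c == label)


#: priority order for conflicting labels, highest first
_PRIORITY = ["plastic", "marker_up", "marker_down", "constitutive", "modulated_nonplastic"]


def classify_genes(
    universe: Sequence[str],
    plastic: GeneSet,
    marker_up: GeneSet,
    marker_down: GeneSet,
    constitutive: GeneSet,
    modulated: GeneSet | None = None,
) -> GeneClassification:
    """Merge the per-analysis sets into one exclusive label per gene.

    Priority: plastic > marker_up/down > constitutive >
    modulated_nonplastic > unclassified; conflicts are resolved by priority
    and recorded.  All sets must be drawn from ``universe``.
    """
    uni = set(universe)
    sets = {
        "plastic": plastic.members,
        "marker_up": marker_up.members,
        "marker_down": marker_down.members,
        "constitutive": constitutive.members,
        "modulated_nonplastic": (modulated.members if modulated else frozenset()),
    }
    for name, members in sets.items():
        if not members <= uni:
            extra = sorted(members - uni)[:5]
            raise ValueError(f"{name} set contains genes outside the universe (e.g. {extra})")
    labels: dict[str, str] = {}
    provenance: dict[str, dict] = {}
    conflicts: list[tuple[str, str, str]] = []
    for g in universe:
        hits = [lab for lab in _PRIORITY if g in sets[lab]]
        if not hits:
            labels[g] = "unclassified"
            continue
        labels[g] = hits[0]
        provenance[g] = {"source_sets": "|".join(hits)}
        for losing in hits[1:]:
            conflicts.append((g, hits[0], losing))
            logger.info("gene %s: label %s wins over %s", g, hits[0], losing)
    return GeneClassification(labels, provenance, conflicts)


def intersect_sets(sets: Sequence[GeneSet]) -> tuple[dict[tuple[bool, ...], int], GeneSet]:
    """Venn-style membership-pattern counts plus the full intersection."""
    if len(sets) < 2:
        raise ValueError("need >= 2 sets")
    universe = frozenset().union(*[s.members for s in sets])
    patterns: dict[tuple[bool, ...], int] = {}
    for g in universe:
        key = tuple(g in s for s in sets)
        patterns[key] = patterns.get(key, 0) + 1
    inter = frozenset.intersection(*[s.members for s in sets])
    return patterns, GeneSet("&".join(s.label for s in sets), inter)


# ---------------------------------------------------------------------------
# full run


@dataclass
class PipelineConfig:
    """Every threshold and seed of a full classification run."""

    alpha: float = 0.01
    sam_fdr: float = 0.001
    fold_threshold: float = 2.0
    alpha_t: float = 0.05
    k_clusters: int = 8
    marker_percentile: float = 95.0
    sd_percentile: float = 99.0
    k_max: int = 15
    n_perms: int = 100
    linkage: str = "average"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def run_pipeline(m: ExpressionMatrix, config: PipelineConfig,
                 outdir: str | Path | None = None) -> dict:
    """Unimodal filter -> plastic / markers / constitutive -> classification.

    Returns a result dict; when ``outdir`` is given, writes deterministic
    TSV gene lists, the classification table and a JSON run manifest.
    """
    from .preprocessing import unimodal_filter

    logger.info("unimodal filter: %d genes, k_max=%d", m.n_genes, config.k_max)
    part = unimodal_filter(m, k_max=config.k_max, seed=config.seed)
    logger.info("unimodal set: %d genes (k=%d, converged=%s)",
                len(part.unimodal_set), part.k, part.converged)
    plastic = call_plastic_genes(m, part.unimodal_set, alpha=config.alpha)
    logger.info("plastic: %d genes", len(plastic.plastic))
    markers = select_developmental_markers(
        m, fdr_target=config.sam_fdr, alpha=config.alpha, k=config.k_clusters,
        percentile=config.marker_percentile, n_perms=config.n_perms, seed=config.seed)
    logger.info("markers: %d up / %d down", len(markers.up), len(markers.down))
    constitutive = select_constitutive_genes(
        m, fdr_target=config.sam_fdr, alpha=config.alpha,
        sd_percentile=config.sd_percentile, n_perms=config.n_perms, seed=config.seed)
    logger.info("constitutive: %d genes", len(constitutive.constitutive))
    classification = classify_genes(
        m.gene_ids, plastic.plastic, markers.up, markers.down,
        constitutive.constitutive, markers.stage_modulated)
    results = {
        "partition": part,
        "plastic": plastic,
        "markers": markers,
        "constitutive": constitutive,
        "classification": classification,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, gs in [
            ("unimodal", part.unimodal_set), ("plastic", plastic.plastic),
            ("marker_up", markers.up), ("marker_down", markers.down),
            ("constitutive", constitutive.constitutive),
        ]:
            (outdir / f"{name}_genes.txt").write_text(
                "\n".join(sorted(gs.members)) + ("\n" if gs.members else ""))
        df = classification.to_frame().sort_values("gene_id", kind="mergesort")
        df.to_csv(outdir / "classification.tsv", sep="\t", index=False)
        manifest = {
            "config": asdict(config),
            "n_genes": m.n_genes,
            "n_samples": m.n_samples,
            "unimodal_k": part.k,
            "unimodal_converged": part.converged,
            "counts": {
                "unimodal": len(part.unimodal_set),
                "plastic": len(plastic.plastic),
                "marker_up": len(markers.up),
                "marker_down": len(markers.down),
                "constitutive": len(constitutive.constitutive),
            },
            "summary": plastic.summary,
        }
        (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return results
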