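"""Seeded, config-driven validation experiments and the classifier.

Each experiment replays one of the checks that established the reliability
of the alignment-free distance pipeline, end-to-end on a synthetic scenario
with a known truth:

* coverage titration — how far can read coverage drop before pairwise
  distances inflate and the tree topology degrades;
* duplicate recovery — are repeated sequencing runs of the same accession
  placed as siblings, and do the defined groups stay monophyletic;
* cross validation — do sketch-based Mash distances and SNP-array-based
  Rogers' distances agree (Mantel test) and yield the same tree;
* organelle robustness — does removing high-copy organelle DNA change the
  inferred tree;
* classification — propose a group for unlabeled accessions from their
  nearest labeled neighbours plus their placement in the tree.

Every experiment is a pure function of its config (including the seed), so
re-running reproduces reports byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import readqc, simdata, sketch as sketchmod
from .distance import (
    DistanceMatrix,
    MantelResult,
    mantel_test,
    pairwise_mash,
    rogers_matrix,
)
from .simdata import ReadSet, SyntheticTruth
from .tree import (
    SearchConfig,
    fitch_margoliash,
    is_monophyletic,
    quartet_distance,
    root_with_outgroup,
    sibling_fraction,
)

__all__ = [
    "ExperimentConfig",
    "TitrationReport",
    "DuplicateReport",
    "CrossValidationReport",
    "OrganelleReport",
    "ClassificationReport",
    "run_coverage_titration",
    "run_pair_coverage_curve",
    "run_duplicate_recovery",
    "run_cross_validation",
    "run_organelle_robustness",
    "run_classification_holdout",
    "mantel_null_calibration",
    "classify_unknowns",
    "annotate_tree",
]

OUTGROUP = "outgroup"


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared settings for the validation experiments."""

    scenario: str = "beet-mini"
    coverages: tuple[float, ...] = (5.0, 1.0, 0.5, 0.2)
    replicates: int = 10
    seed: int = 0
    sketch_k: int = sketchmod.DEFAULT_K
    sketch_s: int = sketchmod.DEFAULT_S
    sketch_m: int = sketchmod.DEFAULT_M_READS
    search: SearchConfig = field(default_factory=lambda: SearchConfig(jumbles=3))
    scenario_overrides: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        cov = self.coverages
        if any(c <= 0 for c in cov) or any(a <= b for a, b in zip(cov, cov[1:])):
            raise ValueError("coverages must be positive and strictly decreasing")


def _subseed(seed: int, *path: int) -> int:
    """Deterministic child seed below 2**31."""
    return int(np.random.SeedSequence([seed, *path]).generate_state(1)[0] % (2**31))


def _make_truth(config: ExperimentConfig, **extra) -> SyntheticTruth:
    overrides = dict(config.scenario_overrides)
    overrides.update(extra)
    return simdata.make_scenario(config.scenario, seed=config.seed, **overrides)


def _reads_for(
    truth: SyntheticTruth, individual: str, coverage: float, seed: int
) -> ReadSet:
    p = truth.params
    return simdata.simulate_reads(
        truth.haplotypes[individual],
        coverage=coverage,
        read_length=p.read_length,
        insert_mean=p.insert_mean,
        insert_sd=p.insert_sd,
        error_rate=p.error_rate,
        seed=seed,
    )


def _sketch_reads(reads: ReadSet, name: str, config: ExperimentConfig):
    trimmed = readqc.trim_reads(reads)
    return sketchmod.build_sketch(
        trimmed, name=name, k=config.sketch_k, s=config.sketch_s, m=config.sketch_m
    )


# ---------------------------------------------------------------------------
# Coverage titration
# ---------------------------------------------------------------------------


@dataclass
class TitrationReport:
    table: pd.DataFrame          # coverage, replicate, qdist_to_full, mean_mash, failed
    full_coverage: float
    n_taxa: int

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def qdist_zero_fraction(self, coverage: float) -> float:
        sub = self.table[(self.table.coverage == coverage) & (~self.table.failed)]
        return float((sub.qdist_to_full == 0).mean()) if len(sub) else float("nan")

    def mean_mash(self, coverage: float) -> float:
        sub = self.table[(self.table.coverage == coverage) & (~self.table.failed)]
        return float(sub.mean_mash.mean())


def run_coverage_titration(config: ExperimentConfig) -> TitrationReport:
    """Downsample, re-sketch and re-build the tree at each coverage.

    Per replicate, reads are simulated once at the scenario's full coverage;
    each titration level is obtained by fragment downsampling of those same
    reads (mirroring subsampling of a fixed sequencing run). Reported per
    cell: quartet distance of the tree at that coverage to the same
    replicate's full-coverage tree, and the mean off-diagonal Mash distance.
    """
    truth = _make_truth(config)
    if len(truth.taxa) < 5:
        raise ValueError("titration scenario needs at least 4 taxa plus outgroup")
    p = truth.params
    G = p.genome_length
    rows = []
    for rep in range(config.replicates):
        all_reads = {
            ind: _reads_for(truth, ind, p.coverage, _subseed(config.seed, 1, rep, i))
            for i, ind in enumerate(truth.taxa)
        }
        full_sketches = [
            _sketch_reads(all_reads[ind], ind, config) for ind in truth.taxa
        ]
        full_tree = fitch_margoliash(
            pairwise_mash(full_sketches),
            dataclasses.replace(config.search, seed=_subseed(config.seed, 2, rep)),
        )
        for cov in config.coverages:
            if cov > p.coverage:
                continue
            try:
                sketches = []
                for i, ind in enumerate(truth.taxa):
                    ds = readqc.downsample(
                        all_reads[ind], cov, G,
                        seed=_subseed(config.seed, 3, rep, i, int(cov * 1000)),
                    )
                    sketches.append(_sketch_reads(ds, ind, config))
                dm = pairwise_mash(sketches)
                t = fitch_margoliash(
                    dm,
                    dataclasses.replace(
                        config.search,
                        seed=_subseed(config.seed, 4, rep, int(cov * 1000)),
                    ),
                )
                rows.append(
                    {
                        "coverage": cov,
                        "replicate": rep,
                        "qdist_to_full": quartet_distance(t, full_tree),
                        "mean_mash": dm.mean_offdiagonal(),
                        "failed": False,
                    }
                )
            except ValueError as exc:  # e.g. copy filter emptied the sketch
                rows.append(
                    {
                        "coverage": cov,
                        "replicate": rep,
                        "qdist_to_full": -1,
                        "mean_mash": float("nan"),
                        "failed": True,
                    }
                )
    return TitrationReport(
        table=pd.DataFrame(rows), full_coverage=p.coverage, n_taxa=len(truth.taxa)
    )


def run_pair_coverage_curve(
    config: ExperimentConfig,
    n_seeds: int = 20,
    pair: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Mean Mash distance of one fixed accession pair across coverages.

    Replicates the coverage-dependence observation — estimated distances
    inflate as coverage drops — on a single synthetic pair over ``n_seeds``
    independent read simulations (paired across coverage levels).
    """
    truth = _make_truth(config)
    p = truth.params
    if pair is None:
        ingroup = [t for t in truth.taxa if truth.group_of[t] != OUTGROUP]
        pair = (ingroup[0], ingroup[-1])
    rows = []
    for rep in range(n_seeds):
        reads = {
            ind: _reads_for(truth, ind, p.coverage, _subseed(config.seed, 5, rep, i))
            for i, ind in enumerate(pair)
        }
        for cov in config.coverages:
            sks = []
            for i, ind in enumerate(pair):
                ds = readqc.downsample(
                    reads[ind], cov, p.genome_length,
                    seed=_subseed(config.seed, 6, rep, i, int(cov * 1000)),
                )
                sks.append(_sketch_reads(ds, ind, config))
            j, _, _ = sketchmod.jaccard(sks[0], sks[1])
            rows.append(
                {
                    "coverage": cov,
                    "seed_index": rep,
                    "mash": sketchmod.mash_distance(j, config.sketch_k),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Duplicate recovery
# ---------------------------------------------------------------------------


@dataclass
class DuplicateReport:
    sibling_fraction: float
    non_sibling_pairs: pd.DataFrame   # pair members, within-pair distance, NN dist
    group_monophyly: dict[str, bool]
    tree: object
    matrix: DistanceMatrix


def run_duplicate_recovery(config: ExperimentConfig) -> DuplicateReport:
    """Tree over all individuals; duplicates should sit as cherries."""
    truth = _make_truth(config)
    if not truth.duplicate_pairs:
        raise ValueError(
            f"scenario {config.scenario!r} contains no duplicate individuals"
        )
    p = truth.params
    sketches = [
        _sketch_reads(
            _reads_for(truth, ind, p.coverage, _subseed(config.seed, 7, i)), ind, config
        )
        for i, ind in enumerate(truth.taxa)
    ]
    dm = pairwise_mash(sketches)
    t = fitch_margoliash(
        dm, dataclasses.replace(config.search, seed=_subseed(config.seed, 8))
    )
    frac = sibling_fraction(t, truth.duplicate_pairs)
    rows = []
    t_unrooted = t
    for a, b in truth.duplicate_pairs:
        if sibling_fraction(t_unrooted, [(a, b)]) == 1.0:
            continue
        within = dm.get(a, b)
        others = [l for l in dm.labels if l not in (a, b)]
        nn = min(others, key=lambda o: dm.get(a, o))
        rows.append(
            {
                "member_a": a,
                "member_b": b,
                "within_pair_distance": within,
                "nearest_neighbor": nn,
                "nearest_neighbor_distance": dm.get(a, nn),
            }
        )
    groups = sorted({g for g in truth.group_of.values() if g != OUTGROUP})
    monophyly = {
        g: is_monophyletic(
            t, [i for i in truth.taxa if truth.group_of[i] == g], {OUTGROUP}
        )
        for g in groups
    }
    return DuplicateReport(
        sibling_fraction=frac,
        non_sibling_pairs=pd.DataFrame(
            rows,
            columns=[
                "member_a", "member_b", "within_pair_distance",
                "nearest_neighbor", "nearest_neighbor_distance",
            ],
        ),
        group_monophyly=monophyly,
        tree=t,
        matrix=dm,
    )


# ---------------------------------------------------------------------------
# Cross validation against SNP-array genotypes
# ---------------------------------------------------------------------------


@dataclass
class CrossValidationReport:
    mantel: MantelResult
    quartet_distance: int
    n_taxa: int
    mash: DistanceMatrix
    rogers: DistanceMatrix


def run_cross_validation(
    config: ExperimentConfig,
    n_markers: int = 2000,
    missing_rate: float = 0.05,
    permutations: int = 999,
) -> CrossValidationReport:
    """Mash vs Rogers' distances on the same accessions.

    Sketches come from simulated reads, genotypes from the same haplotypes;
    the two matrices are aligned by label, compared with a one-sided Mantel
    test, and the trees built from each are compared by quartet distance.
    """
    truth = _make_truth(config)
    p = truth.params
    sketches = [
        _sketch_reads(
            _reads_for(truth, ind, p.coverage, _subseed(config.seed, 9, i)), ind, config
        )
        for i, ind in enumerate(truth.taxa)
    ]
    mash_dm = pairwise_mash(sketches)
    genos = simdata.simulate_genotypes(
        truth.haplotypes, n_markers=n_markers, missing_rate=missing_rate,
        seed=_subseed(config.seed, 10),
    )
    rogers_dm = rogers_matrix(genos)
    result = mantel_test(
        mash_dm, rogers_dm, permutations=permutations,
        seed=_subseed(config.seed, 11),
    )
    t_mash = fitch_margoliash(
        mash_dm, dataclasses.replace(config.search, seed=_subseed(config.seed, 12))
    )
    t_rogers = fitch_margoliash(
        rogers_dm, dataclasses.replace(config.search, seed=_subseed(config.seed, 13))
    )
    qd = quartet_distance(t_mash, t_rogers)
    return CrossValidationReport(
        mantel=result, quartet_distance=qd, n_taxa=len(truth.taxa),
        mash=mash_dm, rogers=rogers_dm,
    )


def mantel_null_calibration(
    n: int = 20,
    replicates: int = 200,
    permutations: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error rate of the Mantel test on independent random matrices."""
    rng = np.random.default_rng(seed)
    rejections = 0
    labels = [f"t{i}" for i in range(n)]
    for rep in range(replicates):
        m1 = _random_distance_matrix(n, rng)
        m2 = _random_distance_matrix(n, rng)
        res = mantel_test(
            DistanceMatrix(labels, m1), DistanceMatrix(labels, m2),
            permutations=permutations, seed=_subseed(seed, 14, rep),
        )
        if res.p <= alpha:
            rejections += 1
    return rejections / replicates


def _random_distance_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    vals = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    vals[iu] = rng.random(iu[0].size)
    return vals + vals.T


# ---------------------------------------------------------------------------
# Organelle robustness
# ---------------------------------------------------------------------------


@dataclass
class OrganelleReport:
    quartet_distance: int
    discarded_fraction_mean: float
    spiked_fraction_mean: float
    n_taxa: int


def run_organelle_robustness(
    config: ExperimentConfig,
    organelle_length: int = 30_000,
    organelle_coverage: float = 100.0,
) -> OrganelleReport:
    """Spike shared high-copy organelle reads; compare filtered/unfiltered trees.

    Every accession receives reads from the same organelle sequence at
    ``organelle_coverage`` (emulating the high copy number of plastid and
    mitochondrial DNA); trees are then built with and without the k-mer
    organelle filter and compared by quartet distance.
    """
    truth = _make_truth(
        config,
        organelle_length=organelle_length,
        organelle_coverage=organelle_coverage,
    )
    p = truth.params
    sketches_raw = []
    sketches_filtered = []
    discarded = []
    spiked = []
    for i, ind in enumerate(truth.taxa):
        reads = _reads_for(truth, ind, p.coverage, _subseed(config.seed, 15, i))
        n_nuclear = reads.n_fragments
        reads = simdata.spike_organelle(
            reads, truth.organelle, organelle_coverage,
            seed=_subseed(config.seed, 16, i),
            read_length=p.read_length, insert_mean=p.insert_mean,
            error_rate=p.error_rate,
        )
        spiked.append(1.0 - n_nuclear / reads.n_fragments)
        sketches_raw.append(_sketch_reads(reads, ind, config))
        filtered, rep = readqc.filter_organelle(
            reads, truth.organelle, k=config.sketch_k, min_shared=1
        )
        discarded.append(rep.discarded_fraction)
        sketches_filtered.append(_sketch_reads(filtered, ind, config))
    t_raw = fitch_margoliash(
        pairwise_mash(sketches_raw),
        dataclasses.replace(config.search, seed=_subseed(config.seed, 17)),
    )
    t_filtered = fitch_margoliash(
        pairwise_mash(sketches_filtered),
        dataclasses.replace(config.search, seed=_subseed(config.seed, 18)),
    )
    return OrganelleReport(
        quartet_distance=quartet_distance(t_raw, t_filtered),
        discarded_fraction_mean=float(np.mean(discarded)),
        spiked_fraction_mean=float(np.mean(spiked)),
        n_taxa=len(truth.taxa),
    )


# ---------------------------------------------------------------------------
# Classification of unlabeled accessions
# ---------------------------------------------------------------------------


@dataclass
class ClassificationReport:
    table: pd.DataFrame

    def proposed(self, accession: str) -> str:
        row = self.table[self.table.accession == accession]
        return str(row.proposed_group.iloc[0])


def classify_unknowns(
    matrix: DistanceMatrix,
    labels: Mapping[str, str | None],
    tree,
    n_neighbors: int = 5,
    clade_coverage: float = 0.9,
) -> ClassificationReport:
    """Propose a group for each unlabeled accession.

    Two independent signals are reported: (1) the majority group among the
    ``n_neighbors`` nearest labeled accessions by distance (ties broken by
    the smallest mean distance to the tied groups), and (2) whether the
    accession falls inside the smallest clade of the given (rooted) tree
    containing at least ``clade_coverage`` of the proposed group's labeled
    members. Disagreement between the signals is reported, not hidden.
    """
    labeled = {a: g for a, g in labels.items() if g}
    unknowns = [a for a in matrix.labels if not labels.get(a)]
    groups = sorted(set(labeled.values()))
    if len(groups) < 2:
        raise ValueError("need at least 2 labeled groups")
    if not unknowns:
        raise ValueError("no unlabeled accessions to classify")
    k = n_neighbors
    if k > len(labeled):
        import warnings

        warnings.warn(
            f"n_neighbors={n_neighbors} exceeds {len(labeled)} labeled "
            "accessions; reducing",
            stacklevel=2,
        )
        k = len(labeled)

    clades: list[set[str]] = []
    for node in tree.preorder_node_iter():
        clades.append({lf.taxon.label for lf in node.leaf_iter()})

    rows = []
    for u in unknowns:
        dists = sorted(
            ((matrix.get(u, a), a) for a in labeled), key=lambda t: (t[0], t[1])
        )
        nearest = dists[:k]
        votes: dict[str, int] = {}
        for _, a in nearest:
            votes[labeled[a]] = votes.get(labeled[a], 0) + 1
        group_mean = {
            g: float(
                np.mean([matrix.get(u, a) for a in labeled if labeled[a] == g])
            )
            for g in groups
        }
        top = max(votes.values())
        tied = sorted([g for g, v in votes.items() if v == top])
        proposed = min(tied, key=lambda g: (group_mean[g], g))
        members = {a for a, g in labeled.items() if g == proposed}
        need = int(np.ceil(clade_coverage * len(members)))
        candidates = [
            c for c in clades if len(c & members) >= need
        ]
        smallest = min(candidates, key=len) if candidates else set()
        in_clade = u in smallest
        row = {
            "accession": u,
            "proposed_group": proposed,
            "tree_placement_ok": bool(in_clade),
            "signals_agree": bool(in_clade),
            "nearest_neighbors": ";".join(a for _, a in nearest),
            "nearest_distances": ";".join(f"{d:.6f}" for d, _ in nearest),
        }
        for g in groups:
            row[f"mean_dist_{g}"] = group_mean[g]
        rows.append(row)
    return ClassificationReport(table=pd.DataFrame(rows))


def run_classification_holdout(
    config: ExperimentConfig, n_holdout_per_group: int = 3
) -> pd.DataFrame:
    """Relabel accessions as unknown and score their reassignment.

    Holds out ``n_holdout_per_group`` accessions from each ingroup, builds
    the Mash matrix and rooted tree over everything, classifies the held-out
    accessions from the remaining labels, and reports correctness.
    """
    truth = _make_truth(config)
    p = truth.params
    sketches = [
        _sketch_reads(
            _reads_for(truth, ind, p.coverage, _subseed(config.seed, 19, i)), ind, config
        )
        for i, ind in enumerate(truth.taxa)
    ]
    dm = pairwise_mash(sketches)
    t = fitch_margoliash(
        dm, dataclasses.replace(config.search, seed=_subseed(config.seed, 20))
    )
    rooted = root_with_outgroup(t, [OUTGROUP])
    groups = sorted({g for g in truth.group_of.values() if g != OUTGROUP})
    held = [
        ind
        for g in groups
        for ind in [t_ for t_ in truth.taxa if truth.group_of[t_] == g][
            :n_holdout_per_group
        ]
    ]
    labels: dict[str, str | None] = {
        ind: (None if ind in held else truth.group_of[ind]) for ind in truth.taxa
    }
    labels[OUTGROUP] = OUTGROUP
    report = classify_unknowns(dm, labels, rooted)
    out = report.table.copy()
    out["true_group"] = [truth.group_of[a] for a in out.accession]
    out["correct"] = out.proposed_group == out.true_group
    return out


def annotate_tree(tree, metadata: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Join tree leaves to a metadata table keyed by its first column.

    Returns the annotation table (one row per leaf, metadata columns merged,
    empty where absent) and the count of unmatched leaves.
    """
    key = metadata.columns[0]
    leaves = sorted({lf.taxon.label for lf in tree.leaf_node_iter()})
    base = pd.DataFrame({key: leaves})
    joined = base.merge(metadata, on=key, how="left")
    other_cols = [c for c in metadata.columns if c != key]
    unmatched = int(joined[other_cols].isna().all(axis=1).sum()) if other_cols else 0
    return joined, unmatched
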