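"""Evaluation protocols: link-removal cross-validation (AUC_N), Top-k
recall curves over clinical cases, and the K/θ grid search.

AUC_N is the area under the ROC curve with false positives truncated at
``N``: sweeping the ranked candidate list, every non-target ahead of a
target is a false positive, and

    AUC_N = Σ_targets max(N − fp_before_target, 0) / (N · #targets).

The full AUC is the ``N = #negatives`` case.  Cross-validation removes a
seeded random fraction of the phenotype–gene links per fold, re-runs the
convolution on the remaining network, and averages AUC_N over the test
phenotypes within each fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .engine import GcasParams, normalize_network, propagate
from .errors import DataError, UsageError
from .network import HeteroNetwork, copy_network

log = logging.getLogger(__name__)

#: False-positive truncation grid used throughout the cross-validation.
N_GRID = (50, 100, 300, 500, 1000)


@dataclass
class FoldResult:
    """One cross-validation fold: removed links and its AUC summaries."""

    fold: int
    removed: Tuple[Tuple[str, str], ...]
    auc_by_n: Dict[int, float]
    full_auc: float
    n_test_phenotypes: int
    no_candidates: bool = False
    #: analytic expectation of auc_by_n under uniformly random rankings of
    #: the same candidate sets — the null the fold is compared against
    null_auc_by_n: Dict[int, float] = field(default_factory=dict)


@dataclass
class RecallCurve:
    """Percentage of cases (or pairs) captured within each Top-k cutoff."""

    ks: Tuple[int, ...]
    captured: Dict[int, float]
    n_total: int

    def __getitem__(self, k: int) -> float:
        return self.captured[k]


def auc_n(
    target_ranks: Iterable[int],
    n_candidates: int,
    n_limit: int,
    n_targets: Optional[int] = None,
) -> float:
    """Truncated ROC area for targets at given 1-based ranks.

    ``n_targets`` defaults to the number of ranks given; passing a larger
    value accounts for targets missing from the candidate list entirely
    (they contribute zero area but stay in the denominator).
    """
    given = [int(r) for r in target_ranks]
    ranks = sorted(set(given))
    if len(ranks) != len(given):
        raise DataError("target ranks must be distinct")
    total = n_targets if n_targets is not None else len(ranks)
    if total < 1:
        raise DataError("at least one target is required")
    if len(ranks) > total:
        raise DataError("more ranks than targets")
    if n_limit < 1:
        raise UsageError("N must be >= 1")
    if ranks and (ranks[0] < 1 or ranks[-1] > n_candidates):
        raise DataError(f"ranks must lie in [1, {n_candidates}]")
    area = 0.0
    for i, r in enumerate(ranks):
        fp_before = r - 1 - i  # non-targets ahead of this target
        area += max(n_limit - fp_before, 0)
    return area / (n_limit * total)


def full_auc(
    target_ranks: Iterable[int], n_candidates: int, n_targets: Optional[int] = None
) -> float:
    """Untruncated ROC area: the N = #negatives limit of :func:`auc_n`."""
    ranks = list(target_ranks)
    total = n_targets if n_targets is not None else len(ranks)
    negatives = n_candidates - len(ranks)
    if negatives < 1:
        return 1.0 if ranks else 0.0
    return auc_n(ranks, n_candidates, negatives, n_targets=total)


def expected_random_auc_n(
    n_candidates: int, n_targets: int, n_limit: int
) -> float:
    """Exact expected AUC_N under a uniformly random ranking.

    Each target's false-positive count is uniform on {0, …, #negatives}
    by symmetry, so by linearity the expectation is the single-target
    value.  This is the analytic null the cross-validation is compared
    against.
    """
    negatives = n_candidates - n_targets
    if negatives <= 0:
        return 1.0
    acc = sum(max(n_limit - j, 0) for j in range(negatives + 1))
    return acc / (n_limit * (negatives + 1))


def phenotype_gene_edges(net: HeteroNetwork) -> List[Tuple[str, str]]:
    """Sorted (phenotype, gene) pairs joined by any stored edge."""
    out: Set[Tuple[str, str]] = set()
    for assoc in net.edges():
        ta, tb = net.etype(assoc.a), net.etype(assoc.b)
        if ta == "phenotype" and tb == "gene":
            out.add((assoc.a, assoc.b))
        elif ta == "gene" and tb == "phenotype":
            out.add((assoc.b, assoc.a))
    return sorted(out)


def _remove_pg_edges(
    net: HeteroNetwork, pairs: Iterable[Tuple[str, str]]
) -> HeteroNetwork:
    drop = {tuple(sorted(p)) for p in pairs}
    out = HeteroNetwork()
    for nid in net.nodes():
        e = net.entity(nid)
        out.add_entity(type(e)(e.id, e.etype, e.label, set(e.synonyms)))
    for assoc in net.edges():
        if (assoc.a, assoc.b) in drop:
            continue
        out.add_assoc(assoc.a, assoc.b, assoc.weight, assoc.provenance, assoc.source)
    return out


def cross_validate(
    net_trunc: HeteroNetwork,
    params: GcasParams = GcasParams(),
    fraction: float = 0.10,
    folds: int = 10,
    seed: int = 0,
    n_grid: Sequence[int] = N_GRID,
) -> List[FoldResult]:
    """Link-removal cross-validation on the phenotype–gene projection.

    Each fold removes ``⌊fraction · E_pg⌋`` phenotype–gene links chosen
    by the seeded generator, re-runs the convolution from every test
    phenotype on the remaining network, ranks that phenotype's candidate
    genes (all genes with nonzero propagated score, retained direct
    neighbours included), and averages AUC_N over test phenotypes.
    Bit-reproducible for a fixed seed.
    """
    if not 0 < fraction < 1:
        raise UsageError("fraction must lie in (0, 1)")
    pg = phenotype_gene_edges(net_trunc)
    if not pg:
        raise DataError("no phenotype–gene links to cross-validate")
    n_remove = int(fraction * len(pg))
    if n_remove < 1:
        raise DataError(
            f"fraction {fraction} removes zero of {len(pg)} phenotype–gene links"
        )
    rng = np.random.default_rng(seed)
    results: List[FoldResult] = []
    for fold in range(folds):
        chosen_idx = rng.choice(len(pg), size=n_remove, replace=False)
        removed = tuple(sorted(pg[i] for i in chosen_idx))
        fold_net = _remove_pg_edges(net_trunc, removed)
        norm = normalize_network(fold_net)
        order = norm.node_order
        index = {nid: i for i, nid in enumerate(order)}
        gene_idx = np.array(
            [i for i, nid in enumerate(order) if fold_net.etype(nid) == "gene"]
        )
        gene_ids = [order[i] for i in gene_idx]
        targets_by_p: Dict[str, Set[str]] = {}
        for p, g in removed:
            targets_by_p.setdefault(p, set()).add(g)
        per_pheno: Dict[int, List[float]] = {n: [] for n in n_grid}
        per_null: Dict[int, List[float]] = {n: [] for n in n_grid}
        per_pheno_full: List[float] = []
        any_candidates = False
        for p in sorted(targets_by_p):
            vec = propagate(norm, index[p], params)
            scores = vec[gene_idx]
            mask = scores > 0
            if not mask.any():
                ranks: List[int] = []
                n_cand = 0
            else:
                cand_scores = scores[mask]
                cand_ids = [gene_ids[i] for i in np.flatnonzero(mask)]
                # sort by score descending, gene id ascending
                ordering = sorted(
                    range(len(cand_ids)), key=lambda i: (-cand_scores[i], cand_ids[i])
                )
                pos = {cand_ids[i]: r for r, i in enumerate(ordering, 1)}
                ranks = sorted(
                    pos[g] for g in targets_by_p[p] if g in pos
                )
                n_cand = len(cand_ids)
                any_candidates = True
            total_targets = len(targets_by_p[p])
            present = len(ranks)
            for n_limit in n_grid:
                per_pheno[n_limit].append(
                    auc_n(ranks, n_cand, n_limit, n_targets=total_targets)
                    if n_cand
                    else 0.0
                )
                # absent targets contribute zero under any ranking, so the
                # null scales the single-target expectation by present/total
                per_null[n_limit].append(
                    (present / total_targets)
                    * expected_random_auc_n(n_cand, present, n_limit)
                    if present
                    else 0.0
                )
            per_pheno_full.append(
                full_auc(ranks, n_cand, n_targets=total_targets) if n_cand else 0.0
            )
        results.append(
            FoldResult(
                fold=fold,
                removed=removed,
                auc_by_n={n: float(np.mean(per_pheno[n])) for n in n_grid},
                full_auc=float(np.mean(per_pheno_full)),
                n_test_phenotypes=len(targets_by_p),
                no_candidates=not any_candidates,
                null_auc_by_n={n: float(np.mean(per_null[n])) for n in n_grid},
            )
        )
    return results


def topk_recall(
    case_ranks: Mapping[str, Optional[int]], ks: Sequence[int]
) -> RecallCurve:
    """Percentage of cases whose best causal-gene rank is within each k."""
    if not case_ranks:
        raise DataError("no cases to evaluate")
    ks_sorted = tuple(sorted(set(int(k) for k in ks)))
    n = len(case_ranks)
    captured = {
        k: 100.0 * sum(1 for r in case_ranks.values() if r is not None and r <= k) / n
        for k in ks_sorted
    }
    return RecallCurve(ks=ks_sorted, captured=captured, n_total=n)


def pairwise_topk(
    pairs: Sequence[Tuple[str, str]],
    ranked_lists: Mapping[str, Sequence[str]],
    ks: Sequence[int],
    exclude_known: bool = False,
    known_pairs: Iterable[Tuple[str, str]] = (),
) -> RecallCurve:
    """Per-(phenotype, gene)-pair Top-k capture.

    With ``exclude_known``, pairs already linked in the pre-augmentation
    network (``known_pairs``) are dropped from both numerator and
    denominator, removing the overlap bias between input pairs and
    inferred associations.  A pair whose phenotype has no ranked list
    counts as never captured.
    """
    known = {tuple(p) for p in known_pairs}
    kept = [p for p in pairs if not (exclude_known and tuple(p) in known)]
    if not kept:
        raise DataError("no pairs left to evaluate")
    ks_sorted = tuple(sorted(set(int(k) for k in ks)))
    ranks: List[Optional[int]] = []
    for pheno, gene in kept:
        lst = ranked_lists.get(pheno)
        if lst is None:
            ranks.append(None)
            continue
        try:
            ranks.append(list(lst).index(gene) + 1)
        except ValueError:
            ranks.append(None)
    n = len(kept)
    captured = {
        k: 100.0 * sum(1 for r in ranks if r is not None and r <= k) / n
        for k in ks_sorted
    }
    return RecallCurve(ks=ks_sorted, captured=captured, n_total=n)


def grid_search(
    net_trunc: HeteroNetwork,
    k_range: Sequence[int] = tuple(range(2, 13)),
    theta_range: Sequence[float] = (0.05, 0.1, 0.25, 0.5, 0.75, 0.9),
    fraction: float = 0.10,
    folds: int = 3,
    seed: int = 0,
    objective_n: int = 50,
) -> Tuple[GcasParams, List[Dict[str, float]]]:
    """Select (K, θ) maximizing mean AUC over seeded link-removal folds.

    Each fold is a random sub-network (a fraction of phenotype–gene
    links withheld); the objective is the mean AUC_N at
    ``objective_n`` across folds.  Ties prefer smaller K, then smaller θ.
    Returns the winning parameters and the full objective table.
    """
    if not k_range or not theta_range:
        raise UsageError("parameter ranges must be non-empty")
    table: List[Dict[str, float]] = []
    best: Optional[Tuple[float, int, float]] = None
    for k in sorted(set(k_range)):
        for theta in sorted(set(theta_range)):
            params = GcasParams(K=int(k), theta=float(theta))
            res = cross_validate(
                net_trunc, params, fraction=fraction, folds=folds,
                seed=seed, n_grid=(objective_n,),
            )
            score = float(np.mean([r.auc_by_n[objective_n] for r in res]))
            table.append({"K": float(k), "theta": float(theta), "objective": score})
            key = (-score, int(k), float(theta))
            if best is None or key < (-best[0], best[1], best[2]):
                best = (score, int(k), float(theta))
    assert best is not None
    return GcasParams(K=best[1], theta=best[2]), table


@dataclass
class RecoveryResult:
    """Planted-case ranking versus a degree-matched random baseline."""

    planted_ranks: List[int]
    baseline_ranks: List[int]

    @property
    def planted_median(self) -> float:
        return float(np.median(self.planted_ranks))

    @property
    def baseline_median(self) -> float:
        return float(np.median(self.baseline_ranks))


def planted_case_recovery(
    hanrd: HeteroNetwork, cases, seed: int = 0
) -> RecoveryResult:
    """Rank each planted case's causal gene and a degree-matched decoy.

    For every case the ranked list for its phenotype query is computed
    once; the planted rank is the case's best causal-gene rank, and the
    baseline rank is that of a random non-causal gene whose network
    degree is closest to the causal gene's (ties resolved by the seeded
    generator).  Genes absent from a list are assigned rank
    ``len(list) + 1`` so medians stay defined.
    """
    from .prioritize import rank_for_case  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    genes = hanrd.nodes("gene")
    degree = {g: hanrd.degree(g) for g in genes}
    planted: List[int] = []
    baseline: List[int] = []
    for case in cases:
        ranked, causal_ranks, case_rank = rank_for_case(hanrd, case)
        worst = len(ranked) + 1
        planted.append(case_rank if case_rank is not None else worst)
        target = min(
            case.causal_genes,
            key=lambda g: (causal_ranks.get(g) or worst, g),
        )
        pool = [g for g in genes if g not in case.causal_genes]
        gap = min(abs(degree[g] - degree.get(target, 0)) for g in pool)
        closest = [g for g in pool if abs(degree[g] - degree.get(target, 0)) == gap]
        decoy = closest[int(rng.integers(0, len(closest)))]
        decoy_rank = ranked.rank_of(decoy)
        baseline.append(decoy_rank if decoy_rank is not None else worst)
    return RecoveryResult(planted_ranks=planted, baseline_ranks=baseline)
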