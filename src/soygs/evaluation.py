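"""Experimental designs for evaluating genomic-selection accuracy.

Four designs, each emitting an :class:`AccuracyTable`:

* :func:`training_size_sweep` -- random training sets of increasing size,
  predicting all remaining samples, repeated many times per size.
* :func:`cross_group_matrix` -- every ordered pair of subpopulations as
  training -> prediction; within-group cells use k-fold cross-validation.
  Used with phenotype-quartile ("Ppop") and genetic ("Gpop") partitions.
* :func:`leave_one_group_out` -- all other groups combined predict each
  group in turn.
* :func:`marker_subset_eval` -- marker sets chosen by association score
  thresholds (plus size-matched random controls) compared under fivefold
  80/20 cross-validation.

All designs are bit-reproducible from their seed: every repeat/fold draws
from its own seed substream, so reducing a repeat count never changes the
repeats that remain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    GenotypeMatrix,
    PhenotypeVector,
    PopulationPartition,
    check_aligned,
)
from .errors import ConfigurationError, DataError
from .gwas import (
    GWASResult,
    fit_null_mlm,
    sample_random_markers,
    scan_markers,
    select_markers_by_threshold,
)
from .relatedness import KinshipMatrix, genotype_pca, vanraden_kinship
from .rrblup import fit_rrblup, predict_gebv, prediction_accuracy

logger = logging.getLogger("soygs")

ROW_COLUMNS = [
    "design",
    "training_spec",
    "prediction_spec",
    "n_train",
    "n_test",
    "n_markers",
    "repeat_index",
    "fold_index",
    "accuracy",
]


@dataclass
class AccuracyTable:
    """Per-repeat/fold accuracies plus their per-cell summary."""

    design: str
    rows: pd.DataFrame
    group_keys: list[str]
    audit: list = field(default_factory=list, repr=False)

    @property
    def summary(self) -> pd.DataFrame:
        """Mean, SD and count of accuracy per design cell."""
        return (
            self.rows.groupby(self.group_keys, dropna=False)["accuracy"]
            .agg(mean="mean", sd="std", n_rows="count")
            .reset_index()
        )

    def cell_mean(self, **keys) -> float:
        sub = self.rows
        for k, v in keys.items():
            sub = sub[sub[k] == v]
        return float(sub["accuracy"].mean())


def _rng(*entropy) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(e) for e in entropy]))


def _derived_seed(*entropy) -> int:
    return int(np.random.SeedSequence([int(e) for e in entropy]).generate_state(1)[0] % (2**31))


def _fit_accuracy(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    train: np.ndarray,
    test: np.ndarray,
    gram: np.ndarray | None = None,
    audit: list | None = None,
) -> float:
    """Train on `train` rows, predict `test` rows, return Pearson accuracy.

    Undersized or degenerate splits come back as NaN (flagged missing),
    matching how unusable design cells are reported rather than dropped.
    """
    if len(train) < 10 or len(test) < 3:
        return float("nan")
    try:
        sub_gram = None if gram is None else gram[np.ix_(train, train)]
        fit = fit_rrblup(G.subset_samples(train), y.subset(train), gram=sub_gram)
        pred = predict_gebv(fit, G.subset_samples(test))
        acc = prediction_accuracy(pred, y.values[test])
    except DataError as exc:
        logger.warning("design cell flagged missing: %s", exc)
        return float("nan")
    if audit is not None:
        audit.append((train.copy(), test.copy(), pred, y.values[test], acc))
    return acc


def _kfold(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random folds of as-equal-as-possible size (pure random, unstratified)."""
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]


# ------------------------------------------------------------- size sweep


def training_size_sweep(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    sizes=tuple(range(100, 1000, 100)),
    n_repeats: int = 150,
    seed: int = 0,
    keep_predictions: bool = False,
) -> AccuracyTable:
    """Random training populations of each size predict all remaining samples."""
    check_aligned(G, y)
    n = G.n_samples
    if max(sizes) >= n:
        raise ConfigurationError("every training size must be smaller than the panel")
    gram = G.dosages @ G.dosages.T
    audit: list = []
    rows = []
    for size in sizes:
        for rep in range(n_repeats):
            rng = _rng(seed, size, rep)
            perm = rng.permutation(n)
            train, test = perm[:size], perm[size:]
            acc = _fit_accuracy(
                G, y, np.sort(train), np.sort(test), gram,
                audit if keep_predictions else None,
            )
            rows.append(
                {
                    "design": "size_sweep",
                    "training_spec": f"random-{size}",
                    "prediction_spec": "remainder",
                    "n_train": size,
                    "n_test": n - size,
                    "n_markers": G.n_markers,
                    "repeat_index": rep,
                    "fold_index": np.nan,
                    "accuracy": acc,
                }
            )
    return AccuracyTable("size_sweep", pd.DataFrame(rows, columns=ROW_COLUMNS),
                         ["n_train"], audit)


# ------------------------------------------------------- phenotype strata


def quartile_partition(y: PhenotypeVector, n_groups: int = 4) -> PopulationPartition:
    """Contiguous rank blocks of the trait: Ppop1 = lowest values.

    Block sizes are floor(n / n_groups), with the remainder distributed one
    sample at a time to the lowest-value groups; ties in the trait are
    broken by sample ID order, so the split is deterministic.
    """
    n = len(y)
    if n < 2 * n_groups:
        raise DataError("too few samples for the requested number of groups")
    order = np.lexsort((y.sample_ids, y.values))
    base, rem = divmod(n, n_groups)
    labels = np.empty(n, dtype=object)
    start = 0
    for i in range(n_groups):
        size = base + (1 if i < rem else 0)
        labels[order[start : start + size]] = f"Ppop{i + 1}"
        start += size
    return PopulationPartition(y.sample_ids, labels, scheme="phenotypic")


# -------------------------------------------------------- group matrices


def cross_group_matrix(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    partition: PopulationPartition,
    n_folds: int = 5,
    seed: int = 0,
) -> AccuracyTable:
    """g x g accuracy matrix over a partition.

    Off-diagonal (i, j): train on all of group i, predict all of group j
    (one deterministic accuracy).  Diagonal (i, i): k-fold CV within the
    group, accuracy = per-fold values (summarized as their mean).
    Undersized groups yield NaN cells, not errors.
    """
    check_aligned(G, y)
    labels = sorted(np.unique(partition.labels))
    if len(labels) < 2:
        raise DataError("cross_group_matrix needs at least 2 groups")
    gram = G.dosages @ G.dosages.T
    rows = []
    for gi, li in enumerate(labels):
        members_i = partition.members(li)
        for lj in labels:
            members_j = partition.members(lj)
            if li != lj:
                acc = _fit_accuracy(G, y, members_i, members_j, gram)
                rows.append(
                    {
                        "design": "cross_group",
                        "training_spec": li,
                        "prediction_spec": lj,
                        "n_train": len(members_i),
                        "n_test": len(members_j),
                        "n_markers": G.n_markers,
                        "repeat_index": np.nan,
                        "fold_index": np.nan,
                        "accuracy": acc,
                    }
                )
            else:
                if len(members_i) < 2 * n_folds:
                    folds = []
                    rows.append(
                        {
                            "design": "cross_group",
                            "training_spec": li,
                            "prediction_spec": li,
                            "n_train": np.nan,
                            "n_test": np.nan,
                            "n_markers": G.n_markers,
                            "repeat_index": np.nan,
                            "fold_index": np.nan,
                            "accuracy": np.nan,
                        }
                    )
                else:
                    folds = _kfold(len(members_i), n_folds, _rng(seed, gi))
                for f, fold in enumerate(folds):
                    test = members_i[fold]
                    train = np.setdiff1d(members_i, test)
                    acc = _fit_accuracy(G, y, train, test, gram)
                    rows.append(
                        {
                            "design": "cross_group",
                            "training_spec": li,
                            "prediction_spec": li,
                            "n_train": len(train),
                            "n_test": len(test),
                            "n_markers": G.n_markers,
                            "repeat_index": np.nan,
                            "fold_index": f,
                            "accuracy": acc,
                        }
                    )
    return AccuracyTable(
        "cross_group",
        pd.DataFrame(rows, columns=ROW_COLUMNS),
        ["training_spec", "prediction_spec"],
    )


def leave_one_group_out(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    partition: PopulationPartition,
    seed: int = 0,
) -> AccuracyTable:
    """Train on the union of all other groups, predict each group in turn."""
    check_aligned(G, y)
    labels = sorted(np.unique(partition.labels))
    if len(labels) < 2:
        raise DataError("leave_one_group_out needs at least 2 groups")
    gram = G.dosages @ G.dosages.T
    rows = []
    for lg in labels:
        test = partition.members(lg)
        train = np.flatnonzero(partition.labels != lg)
        acc = _fit_accuracy(G, y, train, test, gram)
        rows.append(
            {
                "design": "leave_one_group_out",
                "training_spec": f"all-but-{lg}",
                "prediction_spec": lg,
                "n_train": len(train),
                "n_test": len(test),
                "n_markers": G.n_markers,
                "repeat_index": np.nan,
                "fold_index": np.nan,
                "accuracy": acc,
            }
        )
    return AccuracyTable(
        "leave_one_group_out",
        pd.DataFrame(rows, columns=ROW_COLUMNS),
        ["prediction_spec"],
    )


# --------------------------------------------------------- marker subsets


def marker_subset_eval(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    gwas_result: GWASResult | None = None,
    thresholds=(0, 1, 2, 3, 4),
    n_folds: int = 5,
    n_random_repeats: int = 1,
    seed: int = 0,
    paper_mode: bool = False,
    n_pcs: int = 3,
) -> AccuracyTable:
    """Prediction accuracy of association-thresholded marker subsets.

    For each threshold t, markers with score > t form the "associated" set
    (t = 0 means every testable marker) and ``n_random_repeats``
    size-matched random sets form the control; both run through the same
    fivefold 80/20 cross-validation folds, so comparisons are paired.

    Selection modes
    ---------------
    ``paper_mode=False`` (default): association scores are recomputed
    inside each training fold, so marker selection never sees test-fold
    phenotypes.  ``paper_mode=True`` reproduces the original design of
    scanning once on the full panel before cross-validation -- simpler,
    but the selection step then leaks test phenotypes, which inflates CV
    accuracy at aggressive thresholds.  Both are provided deliberately so
    the two can be compared.
    """
    check_aligned(G, y)
    if G.has_missing():
        raise DataError("marker_subset_eval requires an imputed genotype matrix")
    n = G.n_samples
    folds = _kfold(n, n_folds, _rng(seed, 101))
    all_idx = np.arange(n)

    K = vanraden_kinship(G)
    pca = genotype_pca(G, n_pcs)

    if paper_mode and gwas_result is None:
        null = fit_null_mlm(y, pca, K)
        gwas_result = scan_markers(G, null, y, pca)

    rows = []

    def record(threshold, selection, rep, f, n_train, n_test, n_markers, acc):
        rows.append(
            {
                "design": "marker_subset",
                "training_spec": f"{selection}@thr{threshold}",
                "prediction_spec": f"fold{f}",
                "n_train": n_train,
                "n_test": n_test,
                "n_markers": n_markers,
                "repeat_index": rep,
                "fold_index": f,
                "accuracy": acc,
                "threshold": threshold,
                "selection": selection,
            }
        )

    if paper_mode:
        testable_ids = gwas_result.marker_ids[~np.isnan(gwas_result.score)]
        for t in thresholds:
            sel = select_markers_by_threshold(gwas_result, t)
            assoc_accs = _cv_marker_set(G, y, sel, folds, all_idx)
            for f, acc in enumerate(assoc_accs):
                test = folds[f]
                record(t, "associated", 0, f, n - len(test), len(test),
                       len(sel), acc)
            for rep in range(n_random_repeats):
                if len(sel) == 0:
                    rand_accs = [float("nan")] * n_folds
                    n_rand = 0
                elif len(sel) == len(testable_ids):
                    rand_accs = assoc_accs  # full set: random draw is the same set
                    n_rand = len(sel)
                else:
                    rand_ids = sample_random_markers(
                        testable_ids, len(sel), _derived_seed(seed, 13, int(t * 100), rep)
                    )
                    rand_accs = _cv_marker_set(G, y, rand_ids, folds, all_idx)
                    n_rand = len(rand_ids)
                for f, acc in enumerate(rand_accs):
                    test = folds[f]
                    record(t, "random", rep, f, n - len(test), len(test),
                           n_rand, acc)
    else:
        for f, test in enumerate(folds):
            train = np.setdiff1d(all_idx, test)
            K_tr = KinshipMatrix(K.sample_ids[train], K.values[np.ix_(train, train)])
            pcs_tr = pca.scores[train]
            y_tr = y.subset(train)
            null_tr = fit_null_mlm(y_tr, pcs_tr, K_tr)
            res_tr = scan_markers(G.subset_samples(train), null_tr, y_tr, pcs_tr)
            testable_ids = res_tr.marker_ids[~np.isnan(res_tr.score)]
            for t in thresholds:
                sel = select_markers_by_threshold(res_tr, t)
                acc = _single_marker_set_split(G, y, sel, train, test)
                record(t, "associated", 0, f, len(train), len(test), len(sel), acc)
                for rep in range(n_random_repeats):
                    if len(sel) == 0:
                        record(t, "random", rep, f, len(train), len(test), 0,
                               float("nan"))
                        continue
                    if len(sel) == len(testable_ids):
                        record(t, "random", rep, f, len(train), len(test),
                               len(sel), acc)
                        continue
                    rand_ids = sample_random_markers(
                        testable_ids,
                        len(sel),
                        _derived_seed(seed, 13, int(t * 100), f, rep),
                    )
                    r_acc = _single_marker_set_split(G, y, rand_ids, train, test)
                    record(t, "random", rep, f, len(train), len(test),
                           len(rand_ids), r_acc)

    df = pd.DataFrame(rows, columns=ROW_COLUMNS + ["threshold", "selection"])
    return AccuracyTable("marker_subset", df, ["threshold", "selection"])


def _cv_marker_set(G, y, marker_ids, folds, all_idx) -> list[float]:
    """Per-fold accuracies for one marker subset (gram cached per subset)."""
    if len(marker_ids) == 0:
        return [float("nan")] * len(folds)
    Gsub = G.subset_markers_by_id(marker_ids)
    gram = Gsub.dosages @ Gsub.dosages.T
    accs = []
    for test in folds:
        train = np.setdiff1d(all_idx, test)
        accs.append(_fit_accuracy(Gsub, y, train, test, gram))
    return accs


def _single_marker_set_split(G, y, marker_ids, train, test) -> float:
    if len(marker_ids) == 0:
        return float("nan")
    Gsub = G.subset_markers_by_id(marker_ids)
    return _fit_accuracy(Gsub, y, train, test)


__all__ = [
    "AccuracyTable",
    "cross_group_matrix",
    "leave_one_group_out",
    "marker_subset_eval",
    "quartile_partition",
    "training_size_sweep",
]
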