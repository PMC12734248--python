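"""Diagnostic nuclear-SNP panel discovery and application.

The nuclear evidence stream distilled for routine diagnostics: filter a
reference genotype table on missingness, minor allele frequency and
mean depth; impute the few remaining gaps; rank sites by recursive
feature elimination under a random-forest learner across a grid of
panel sizes; validate the chosen panel by repeated stratified holdout;
distill the panel into a CART decision tree on allele dosages; and
classify query specimens, conservatively refusing a call whenever any
tree site is missing or sequenced below the minimum depth (allelic
dropout at heterozygous sites cannot be excluded there).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .formats import GenotypeTable, OriginCall

logger = logging.getLogger("dorsatrace")


@dataclass
class TreeNode:
    """One node of the distilled decision tree (JSON-serializable).

    Internal nodes split on ``site`` at ``threshold`` (dosage < t goes
    left); leaves carry the majority ``leaf_class`` and per-class
    training counts.
    """

    site: str | None = None
    threshold: float | None = None
    left: int | None = None
    right: int | None = None
    leaf_class: str | None = None
    class_counts: dict[str, int] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.site is None


@dataclass
class SNPPanel:
    """A ranked diagnostic SNP panel with its distilled decision tree."""

    selected_sites: list[str]
    panel_size_grid: list[int]
    cv_accuracy: dict[int, tuple[float, float]]  # size -> (mean, sd)
    holdout_accuracy: float | None = None
    best_size: int | None = None
    tree: list[TreeNode] = field(default_factory=list)
    validation: dict[str, tuple[float, float]] = field(default_factory=dict)
    min_depth: int = 6
    ref_alt: dict[str, tuple[str, str]] = field(default_factory=dict)

    def tree_sites(self) -> list[str]:
        """All sites used by any split in the tree."""
        return sorted({n.site for n in self.tree if not n.is_leaf})

    def to_payload(self) -> dict:
        return {
            "model_type": "snp-panel",
            "selected_sites": self.selected_sites,
            "panel_size_grid": self.panel_size_grid,
            "cv_accuracy": {str(k): list(v) for k, v in self.cv_accuracy.items()},
            "holdout_accuracy": self.holdout_accuracy,
            "best_size": self.best_size,
            "tree": [
                {
                    "site": n.site,
                    "threshold": n.threshold,
                    "left": n.left,
                    "right": n.right,
                    "leaf_class": n.leaf_class,
                    "class_counts": n.class_counts,
                }
                for n in self.tree
            ],
            "validation": {k: list(v) for k, v in self.validation.items()},
            "min_depth": self.min_depth,
            "ref_alt": {k: list(v) for k, v in self.ref_alt.items()},
        }

    @classmethod
    def from_payload(cls, doc: dict) -> "SNPPanel":
        return cls(
            selected_sites=list(doc["selected_sites"]),
            panel_size_grid=[int(x) for x in doc["panel_size_grid"]],
            cv_accuracy={int(k): tuple(v) for k, v in doc["cv_accuracy"].items()},
            holdout_accuracy=doc.get("holdout_accuracy"),
            best_size=doc.get("best_size"),
            tree=[
                TreeNode(
                    site=n["site"],
                    threshold=n["threshold"],
                    left=n["left"],
                    right=n["right"],
                    leaf_class=n["leaf_class"],
                    class_counts={k: int(v) for k, v in n["class_counts"].items()},
                )
                for n in doc["tree"]
            ],
            validation={k: tuple(v) for k, v in doc.get("validation", {}).items()},
            min_depth=int(doc.get("min_depth", 6)),
            ref_alt={k: tuple(v) for k, v in doc.get("ref_alt", {}).items()},
        )


# ---------------------------------------------------------------------------
# Site filtering and imputation
# ---------------------------------------------------------------------------

def filter_sites(
    gt: GenotypeTable,
    max_missing: float = 0.01,
    min_maf: float = 0.05,
    depth_range: tuple[float, float] = (8.0, 12.0),
) -> GenotypeTable:
    """Keep sites passing missingness, MAF and mean-depth thresholds.

    A site survives when its missing fraction is ≤ ``max_missing``, its
    minor allele frequency (from non-missing genotypes) is strictly
    above ``min_maf``, and its mean depth lies inside the closed
    ``depth_range``.  Site order is preserved; per-criterion removal
    counts are logged.  Removing every site is a hard error.
    """
    miss_frac = np.mean(np.isnan(gt.geno), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(gt.geno, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)
    mean_depth = gt.depth.mean(axis=0)

    pass_miss = miss_frac <= max_missing
    pass_maf = maf > min_maf
    pass_depth = (mean_depth >= depth_range[0]) & (mean_depth <= depth_range[1])
    keep = pass_miss & pass_maf & pass_depth
    logger.info(
        "filter_sites: removed %d (missingness), %d (MAF), %d (depth); kept %d/%d",
        int((~pass_miss).sum()),
        int((~pass_maf).sum()),
        int((~pass_depth).sum()),
        int(keep.sum()),
        gt.n_sites,
    )
    if not keep.any():
        raise ValueError("all sites removed by filters")
    return gt.subset_sites(list(np.where(keep)[0]))


def impute_genotypes(gt: GenotypeTable) -> GenotypeTable:
    """Replace missing genotypes by the within-class modal dosage.

    Ties break toward the lower dosage; sites where a class is entirely
    missing fall back to the global mode.  Individuals without a class
    label are imputed from the global mode with a warning.  Deterministic.
    """
    geno = gt.geno.copy()
    labels = np.asarray(gt.class_label) if gt.class_label else np.array([None] * gt.n_ind)

    def _mode(values: np.ndarray) -> float:
        obs = values[~np.isnan(values)]
        if obs.size == 0:
            return np.nan
        counts = [(np.sum(obs == d), -d) for d in (0.0, 1.0, 2.0)]
        best = max(counts)
        return -best[1]

    global_modes = np.array([_mode(geno[:, j]) for j in range(gt.n_sites)])
    unlabeled_warned = False
    for j in range(gt.n_sites):
        col = geno[:, j]
        miss = np.where(np.isnan(col))[0]
        if miss.size == 0:
            continue
        for i in miss:
            lab = labels[i]
            if lab is None:
                if not unlabeled_warned:
                    warnings.warn(
                        "individual(s) without class label imputed from global mode",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    unlabeled_warned = True
                fill = global_modes[j]
            else:
                fill = _mode(col[labels == lab])
                if np.isnan(fill):
                    fill = global_modes[j]
            col[i] = fill
    # depth-0 genotypes were forced missing on construction; keep the
    # imputed dosages by raising those depths to a nominal 1
    depth = gt.depth.copy()
    depth[(depth == 0) & ~np.isnan(geno)] = np.maximum(
        depth[(depth == 0) & ~np.isnan(geno)], 1
    )
    return GenotypeTable(
        individuals=list(gt.individuals),
        sites=list(gt.sites),
        geno=geno,
        depth=depth,
        class_label=list(gt.class_label) if gt.class_label else None,
        ref=list(gt.ref) if gt.ref else None,
        alt=list(gt.alt) if gt.alt else None,
    )


# ---------------------------------------------------------------------------
# Recursive feature elimination
# ---------------------------------------------------------------------------

def _rf(seed: int, n_estimators: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_estimators, max_features="sqrt", random_state=seed, n_jobs=1
    )


def rfe_select(
    gt: GenotypeTable,
    grid=(1, 2, 5, 10, 15, 20, 50, 80, 100, 150, 200),
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    holdout_frac: float = 0.30,
    n_estimators: int = 100,
) -> SNPPanel:
    """Rank sites by recursive feature elimination over a panel-size grid.

    A stratified 30% set is held out first.  On the remainder, each
    repeated-CV fold fits a random forest on all sites, ranks them by
    Gini importance, and re-evaluates the top-s subset for every grid
    size s on the held fold; accuracies are aggregated as mean ± SD per
    size.  The final ranking comes from a forest fitted on the full
    training portion, and the best panel size (highest mean CV
    accuracy, ties toward smaller) is scored once on the 30% holdout.
    """
    if gt.class_label is None:
        raise ValueError("class labels required")
    if np.isnan(gt.geno).any():
        raise ValueError("genotype table must be complete (impute first)")
    y = np.asarray(gt.class_label)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < folds:
        raise ValueError("every class needs at least `folds` members")

    x = gt.geno
    rng = np.random.default_rng(seed)
    # stratified 30% holdout
    hold_idx, train_idx = [], []
    for c in classes:
        idx = np.where(y == c)[0]
        rng.shuffle(idx)
        n_hold = max(1, int(round(holdout_frac * len(idx))))
        hold_idx.extend(idx[:n_hold])
        train_idx.extend(idx[n_hold:])
    hold_idx, train_idx = np.array(sorted(hold_idx)), np.array(sorted(train_idx))
    x_tr, y_tr = x[train_idx], y[train_idx]
    x_ho, y_ho = x[hold_idx], y[hold_idx]

    usable_grid = sorted({int(s) for s in grid if s <= gt.n_sites})
    skipped = sorted({int(s) for s in grid} - set(usable_grid))
    if skipped:
        warnings.warn(f"grid sizes beyond available sites skipped: {skipped}",
                      RuntimeWarning, stacklevel=2)
    if not usable_grid:
        raise ValueError("no usable panel sizes in grid")

    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    acc: dict[int, list[float]] = {s: [] for s in usable_grid}
    for fold_i, (tr, te) in enumerate(cv.split(x_tr, y_tr)):
        rf_full = _rf(seed + fold_i, n_estimators).fit(x_tr[tr], y_tr[tr])
        ranking = np.argsort(-rf_full.feature_importances_, kind="stable")
        for s in usable_grid:
            top = ranking[:s]
            rf_s = _rf(seed + fold_i, n_estimators).fit(x_tr[tr][:, top], y_tr[tr])
            acc[s].append(float(np.mean(rf_s.predict(x_tr[te][:, top]) == y_tr[te])))

    cv_accuracy = {s: (float(np.mean(v)), float(np.std(v))) for s, v in acc.items()}
    best_size = min(
        (s for s in usable_grid),
        key=lambda s: (-round(cv_accuracy[s][0], 12), s),
    )

    rf_final = _rf(seed, n_estimators).fit(x_tr, y_tr)
    ranking = np.argsort(-rf_final.feature_importances_, kind="stable")
    selected = [gt.sites[j] for j in ranking]

    top = ranking[:best_size]
    rf_best = _rf(seed, n_estimators).fit(x_tr[:, top], y_tr)
    holdout_acc = float(np.mean(rf_best.predict(x_ho[:, top]) == y_ho))

    ref_alt = {}
    if gt.ref and gt.alt:
        ref_alt = {s: (gt.ref[j], gt.alt[j]) for j, s in enumerate(gt.sites)}
    return SNPPanel(
        selected_sites=selected,
        panel_size_grid=usable_grid,
        cv_accuracy=cv_accuracy,
        holdout_accuracy=holdout_acc,
        best_size=best_size,
        ref_alt=ref_alt,
    )


def validate_panel(
    gt: GenotypeTable,
    panel_sites: list[str],
    repeats: int = 100,
    holdout: float = 0.25,
    seed: int = 0,
    n_estimators: int = 100,
) -> dict[str, tuple[float, float]]:
    """Repeated stratified holdout validation of a fixed panel.

    Per repeat: a stratified (1−holdout)/holdout split, a random forest
    retrained on the panel sites only, and per-class holdout accuracy
    recorded.  Returns mean ± SD per class plus ``overall``.
    """
    if gt.class_label is None:
        raise ValueError("class labels required")
    y = np.asarray(gt.class_label)
    cols = [gt.site_index(s) for s in panel_sites]
    x = gt.geno[:, cols]
    if np.isnan(x).any():
        raise ValueError("panel sites must be complete (impute first)")
    classes = np.unique(y)
    rng = np.random.default_rng(seed)
    per_class: dict[str, list[float]] = {str(c): [] for c in classes}
    overall: list[float] = []
    for rep in range(repeats):
        hold_idx, train_idx = [], []
        for c in classes:
            idx = np.where(y == c)[0]
            rng.shuffle(idx)
            n_hold = min(max(1, int(round(holdout * len(idx)))), len(idx) - 1)
            hold_idx.extend(idx[:n_hold])
            train_idx.extend(idx[n_hold:])
        tr, ho = np.array(train_idx), np.array(hold_idx)
        rf = _rf(seed + rep, n_estimators).fit(x[tr], y[tr])
        pred = rf.predict(x[ho])
        overall.append(float(np.mean(pred == y[ho])))
        for c in classes:
            mask = y[ho] == c
            if mask.any():
                per_class[str(c)].append(float(np.mean(pred[mask] == c)))
    out = {c: (float(np.mean(v)), float(np.std(v))) for c, v in per_class.items()}
    out["overall"] = (float(np.mean(overall)), float(np.std(overall)))
    return out


# ---------------------------------------------------------------------------
# Decision tree distillation
# ---------------------------------------------------------------------------

def build_decision_tree(
    gt: GenotypeTable, panel_sites: list[str], min_leaf: int = 1, seed: int = 0
) -> list[TreeNode]:
    """Distill the panel into a CART tree on allele dosages.

    Gini-impurity splits on integer dosages land on thresholds in
    {0.5, 1.5}; growth stops at pure leaves or fewer than ``min_leaf``
    samples.  Leaves store the majority class with training counts.
    """
    if gt.class_label is None:
        raise ValueError("class labels required")
    cols = [gt.site_index(s) for s in panel_sites]
    x = gt.geno[:, cols]
    if np.isnan(x).any():
        raise ValueError("panel sites must be complete (impute first)")
    y = np.asarray(gt.class_label)

    clf = DecisionTreeClassifier(
        criterion="gini", min_samples_leaf=min_leaf, random_state=seed
    ).fit(x, y)
    t = clf.tree_
    classes = [str(c) for c in clf.classes_]
    # count training samples per node directly (robust to sklearn's
    # changing tree_.value semantics)
    path = clf.decision_path(x)
    count_mat = np.zeros((t.node_count, len(classes)), dtype=int)
    for ci, c in enumerate(clf.classes_):
        count_mat[:, ci] = np.asarray(path[y == c].sum(axis=0)).ravel()
    nodes: list[TreeNode] = []
    for nid in range(t.node_count):
        counts = {classes[ci]: int(count_mat[nid, ci]) for ci in range(len(classes))}
        if t.children_left[nid] == -1:
            leaf_class = classes[int(np.argmax(count_mat[nid]))]
            nodes.append(TreeNode(leaf_class=leaf_class, class_counts=counts))
        else:
            # snap split points onto the canonical dosage thresholds:
            # any cut below 1 separates {0}|{1,2}, any above separates
            # {0,1}|{2} — identical partitions of integer dosages
            thr = 0.5 if t.threshold[nid] <= 1.0 else 1.5
            nodes.append(
                TreeNode(
                    site=panel_sites[int(t.feature[nid])],
                    threshold=thr,
                    left=int(t.children_left[nid]),
                    right=int(t.children_right[nid]),
                    class_counts=counts,
                )
            )
    depth = clf.get_depth()
    logger.info("decision tree: %d nodes, depth %d over %d panel sites",
                len(nodes), depth, len(panel_sites))
    return nodes


def classify_specimen(
    tree: list[TreeNode],
    genotypes: dict[str, float],
    depths: dict[str, int],
    min_depth: int = 6,
) -> OriginCall:
    """Classify one specimen with the distilled tree, depth-masked.

    If any site used anywhere in the tree is absent from the query the
    call is NA (``site_absent``); if any such site has depth below
    ``min_depth`` or a missing genotype the call is NA
    (``incomplete_panel``) — a conservative rule because loci under the
    depth floor risk allelic dropout at heterozygous sites.  Otherwise
    the tree is traversed and the leaf's majority class returned with
    the leaf class fraction as probability.
    """
    used = sorted({n.site for n in tree if not n.is_leaf})
    specimen = str(genotypes.get("_id", ""))
    for s in used:
        if s not in genotypes or s not in depths:
            return OriginCall(specimen=specimen, method="SNPs", origin="NA",
                              reason="site_absent")
    for s in used:
        g = genotypes[s]
        if depths[s] < min_depth or g is None or (isinstance(g, float) and np.isnan(g)):
            return OriginCall(specimen=specimen, method="SNPs", origin="NA",
                              reason="incomplete_panel")
    nid = 0
    while not tree[nid].is_leaf:
        node = tree[nid]
        nid = node.left if genotypes[node.site] < node.threshold else node.right
    leaf = tree[nid]
    total = sum(leaf.class_counts.values())
    frac = leaf.class_counts.get(leaf.leaf_class, 0) / total if total else None
    return OriginCall(
        specimen=specimen,
        method="SNPs",
        origin=leaf.leaf_class,
        posterior=round(frac, 4) if frac is not None else None,
    )


def classify_table(
    panel: SNPPanel, gt: GenotypeTable, min_depth: int | None = None
) -> list[OriginCall]:
    """Classify every individual of a genotype table with a fitted panel."""
    md = panel.min_depth if min_depth is None else min_depth
    calls = []
    site_idx = {s: j for j, s in enumerate(gt.sites)}
    for i, ind in enumerate(gt.individuals):
        genotypes = {"_id": ind}
        depths = {}
        for s in panel.tree_sites():
            if s in site_idx:
                j = site_idx[s]
                genotypes[s] = gt.geno[i, j]
                depths[s] = int(gt.depth[i, j])
        call = classify_specimen(panel.tree, genotypes, depths, min_depth=md)
        calls.append(call)
    return calls
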