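"""COI-barcode origin tracing via DAPC of haplotype clusters.

The mitochondrial evidence stream: curate an aligned barcode reference
set, one-hot encode its variable positions, find haplotype clusters by
successive k-means on principal components (choosing k from the shape
of the BIC curve), pick the number of PCs by stratified cross-
validation, fit a discriminant analysis of principal components (DAPC),
and assign query barcodes to clusters with membership posteriors.
Cluster-level geographic profiles — region proportions normalized for
unequal sampling effort — turn a cluster assignment into a continental
origin call.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.linalg
from Bio.Seq import Seq
from sklearn.cluster import KMeans

from .formats import (
    DEFAULT_ORIGIN_MAP,
    BarcodeAlignment,
    OriginCall,
)

logger = logging.getLogger("dorsatrace")

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AlleleMatrix:
    """One-hot encoding of variable alignment columns (haploid).

    ``x[i, c]`` is 1 if individual ``i`` carries the base of indicator
    column ``c`` (label ``"<alignment_column>.<base>"``, 1-based
    column), 0 if it carries another observed base, and ``nan`` when
    the position is a gap/N/ambiguity for that individual.
    """

    ids: list[str]
    columns: list[str]
    x: np.ndarray
    column_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape != (len(self.ids), len(self.columns)):
            raise ValueError("x shape must be n_ind × n_columns")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset_rows(self, keep) -> "AlleleMatrix":
        keep = list(keep)
        return AlleleMatrix(
            ids=[self.ids[i] for i in keep],
            columns=list(self.columns),
            x=self.x[keep].copy(),
            column_means=None if self.column_means is None else self.column_means.copy(),
        )


@dataclass
class DAPCModel:
    """A fitted discriminant analysis of principal components.

    Queries are centered (``center``), projected on ``pc_loadings``,
    then on ``da_axes`` (k−1 discriminant axes whose within-cluster
    covariance is the identity), and scored by squared distance to the
    cluster ``centroids``.
    """

    columns: list[str]
    center: np.ndarray
    column_means: np.ndarray
    pc_loadings: np.ndarray
    n_pcs: int
    da_axes: np.ndarray
    k: int
    centroids: np.ndarray
    training_labels: list[int]
    training_ids: list[str]
    self_assignment_accuracy: float
    bic_curve: dict[int, float] = field(default_factory=dict)
    xval_table: dict[int, float] = field(default_factory=dict)

    @property
    def n_da(self) -> int:
        return self.k - 1

    def to_payload(self) -> dict:
        return {
            "model_type": "coi-dapc",
            "columns": self.columns,
            "center": self.center,
            "column_means": self.column_means,
            "pc_loadings": self.pc_loadings,
            "n_pcs": self.n_pcs,
            "da_axes": self.da_axes,
            "k": self.k,
            "centroids": self.centroids,
            "training_labels": self.training_labels,
            "training_ids": self.training_ids,
            "self_assignment_accuracy": self.self_assignment_accuracy,
            "bic_curve": {str(k): v for k, v in self.bic_curve.items()},
            "xval_table": {str(k): v for k, v in self.xval_table.items()},
        }

    @classmethod
    def from_payload(cls, doc: dict) -> "DAPCModel":
        return cls(
            columns=list(doc["columns"]),
            center=np.asarray(doc["center"], dtype=float),
            column_means=np.asarray(doc["column_means"], dtype=float),
            pc_loadings=np.asarray(doc["pc_loadings"], dtype=float),
            n_pcs=int(doc["n_pcs"]),
            da_axes=np.asarray(doc["da_axes"], dtype=float),
            k=int(doc["k"]),
            centroids=np.asarray(doc["centroids"], dtype=float),
            training_labels=[int(x) for x in doc["training_labels"]],
            training_ids=list(doc["training_ids"]),
            self_assignment_accuracy=float(doc["self_assignment_accuracy"]),
            bic_curve={int(k): float(v) for k, v in doc.get("bic_curve", {}).items()},
            xval_table={int(k): float(v) for k, v in doc.get("xval_table", {}).items()},
        )


@dataclass
class ClusterRegionProfile:
    """Per-cluster regional composition, normalized for sampling effort.

    For cluster c and region r the raw fraction is
    ``count_cr / region_total_r``; normalized proportions rescale these
    to sum to one within the cluster, so a region's overall sample size
    does not dominate the profile.
    """

    counts: dict[int, dict[str, int]]
    normalized: dict[int, dict[str, float]]
    n_with_known_origin: dict[int, int]
    region_totals: dict[str, int]
    origin_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ORIGIN_MAP))
    dominance_threshold: float = 0.90
    minor_floor: float = 0.05

    def to_payload(self) -> dict:
        return {
            "counts": {str(c): v for c, v in self.counts.items()},
            "normalized": {str(c): v for c, v in self.normalized.items()},
            "n_with_known_origin": {str(c): v for c, v in self.n_with_known_origin.items()},
            "region_totals": self.region_totals,
            "origin_map": self.origin_map,
            "dominance_threshold": self.dominance_threshold,
            "minor_floor": self.minor_floor,
        }

    @classmethod
    def from_payload(cls, doc: dict) -> "ClusterRegionProfile":
        return cls(
            counts={int(c): {r: int(x) for r, x in v.items()} for c, v in doc["counts"].items()},
            normalized={
                int(c): {r: float(x) for r, x in v.items()} for c, v in doc["normalized"].items()
            },
            n_with_known_origin={int(c): int(v) for c, v in doc["n_with_known_origin"].items()},
            region_totals={r: int(v) for r, v in doc["region_totals"].items()},
            origin_map=dict(doc["origin_map"]),
            dominance_threshold=float(doc["dominance_threshold"]),
            minor_floor=float(doc["minor_floor"]),
        )


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def _infer_frame(seq: str) -> int:
    """Pick the frame offset (0..2) minimizing internal stop codons."""
    best, best_stops = 0, np.inf
    for off in range(3):
        stops = _count_internal_stops(seq, off)
        if stops < best_stops:
            best, best_stops = off, stops
    return best

def _count_internal_stops(seq: str, offset: int) -> int:
    codons = [seq[i : i + 3] for i in range(offset, len(seq) - 2, 3)]
    if not codons:
        return 0
    stops = 0
    for codon in codons[:-1]:  # final codon is not "internal"
        if "-" in codon or any(b not in _BASES for b in codon):
            continue
        # invertebrate mitochondrial code (translation table 5)
        if str(Seq(codon).translate(table=5)) == "*":
            stops += 1
    return stops


def curate_alignment(
    aln: BarcodeAlignment,
    max_ambiguous: int = 5,
    gap_consistency: float = 0.05,
    frame: int | None = None,
    ref_id: str | None = None,
) -> tuple[BarcodeAlignment, list[tuple[str, str]]]:
    """Drop sequences with stop codons, excess ambiguity or private gaps.

    Automated proxies for manual alignment curation: sequences with an
    internal stop codon under the invertebrate mitochondrial code (in
    the stated frame, or the frame inferred from ``ref_id``), sequences
    with more than ``max_ambiguous`` N/IUPAC-ambiguity characters, and
    sequences gapped at columns where fewer than ``gap_consistency`` of
    all sequences are gapped, are removed.  Returns the retained
    alignment and a rejection report of (id, reason) pairs.
    """
    if aln.columns < 3:
        raise ValueError("alignment too short for codon framing")
    if frame is not None:
        if frame not in (1, 2, 3):
            raise ValueError("frame must be 1, 2 or 3")
        offset = frame - 1
    elif ref_id is not None:
        if ref_id not in aln.ids:
            raise ValueError(f"reference row {ref_id!r} not in alignment")
        offset = _infer_frame(aln.seqs[aln.ids.index(ref_id)])
    else:
        raise ValueError("either frame or ref_id must be given")

    gap_frac = np.array(
        [sum(s[j] == "-" for s in aln.seqs) / aln.n for j in range(aln.columns)]
    )
    rare_gap_cols = np.where(gap_frac < gap_consistency)[0]

    keep: list[int] = []
    report: list[tuple[str, str]] = []
    for i, (sid, seq) in enumerate(zip(aln.ids, aln.seqs)):
        if _count_internal_stops(seq, offset) > 0:
            report.append((sid, "stop_codon"))
            continue
        n_amb = sum(b not in _BASES and b != "-" for b in seq)
        if n_amb > max_ambiguous:
            report.append((sid, "too_ambiguous"))
            continue
        if any(seq[j] == "-" for j in rare_gap_cols):
            report.append((sid, "inconsistent_gap"))
            continue
        keep.append(i)
    return aln.subset(keep), report


def excise_region(
    aln: BarcodeAlignment, ref_id: str, ref_start: int, ref_len: int = 658
) -> BarcodeAlignment:
    """Excise the alignment columns spanning a reference subsequence.

    Columns are selected so that the reference row contributes its
    non-gap positions ``ref_start .. ref_start+ref_len−1`` (1-based);
    gap columns inside the window are retained, so the output width is
    at least ``ref_len``.
    """
    if ref_id not in aln.ids:
        raise ValueError(f"reference row {ref_id!r} not in alignment")
    ref = aln.seqs[aln.ids.index(ref_id)]
    nongap_cols = [j for j, b in enumerate(ref) if b != "-"]
    end = ref_start + ref_len - 1
    if ref_start < 1 or end > len(nongap_cols):
        raise ValueError(
            f"window [{ref_start}, {end}] exceeds reference length {len(nongap_cols)}"
        )
    first = nongap_cols[ref_start - 1]
    last = nongap_cols[end - 1]
    cols = slice(first, last + 1)
    return BarcodeAlignment(
        ids=list(aln.ids),
        seqs=[s[cols] for s in aln.seqs],
        region=list(aln.region),
    )


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def encode_alignment(aln: BarcodeAlignment, min_mac: int = 1) -> AlleleMatrix:
    """One-hot encode polymorphic alignment columns (haploid presence).

    Only columns with ≥2 observed A/C/G/T bases produce indicator
    groups; within a group indicators are ordered major allele first.
    Gaps, N and IUPAC ambiguities are missing (``nan`` across the whole
    indicator group for that individual).  Indicator columns with
    fewer than ``min_mac`` carriers are dropped.
    """
    seq_arr = np.array([list(s) for s in aln.seqs])
    labels: list[str] = []
    cols: list[np.ndarray] = []
    for j in range(aln.columns):
        col = seq_arr[:, j]
        observed = col[np.isin(col, list(_BASES))]
        bases, counts = np.unique(observed, return_counts=True)
        if len(bases) < 2:
            continue
        order = np.argsort(-counts, kind="stable")
        missing = ~np.isin(col, list(_BASES))
        for b in bases[order]:
            ind = (col == b).astype(float)
            ind[missing] = np.nan
            if np.nansum(ind) < min_mac:
                continue
            labels.append(f"{j + 1}.{b}")
            cols.append(ind)
    if not labels:
        raise ValueError("no polymorphic columns in alignment")
    x = np.column_stack(cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(x, axis=0)
    return AlleleMatrix(ids=list(aln.ids), columns=labels, x=x, column_means=means)


def encode_against_model(aln: BarcodeAlignment, model: "DAPCModel") -> AlleleMatrix:
    """Encode query sequences on a fitted model's indicator columns.

    Positions outside the model's column set are ignored (novel query
    alleles at modeled positions score 0 on every indicator of that
    position); gaps/N are missing.
    """
    seq_arr = np.array([list(s) for s in aln.seqs])
    cols = []
    for label in model.columns:
        pos_s, base = label.rsplit(".", 1)
        pos = int(pos_s) - 1
        if pos >= aln.columns:
            cols.append(np.full(aln.n, np.nan))
            continue
        col = seq_arr[:, pos]
        ind = (col == base).astype(float)
        ind[~np.isin(col, list(_BASES))] = np.nan
        cols.append(ind)
    return AlleleMatrix(ids=list(aln.ids), columns=list(model.columns), x=np.column_stack(cols))


# ---------------------------------------------------------------------------
# PCA helpers
# ---------------------------------------------------------------------------

def _impute(x: np.ndarray, means: np.ndarray) -> np.ndarray:
    out = x.copy()
    idx = np.where(np.isnan(out))
    out[idx] = means[idx[1]]
    return out


def _pca(x: np.ndarray, means: np.ndarray | None = None):
    """Mean-impute, center and decompose; returns (scores, loadings,
    explained-variance fractions, center)."""
    if means is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(x, axis=0)
        means = np.where(np.isnan(means), 0.0, means)
    xi = _impute(x, means)
    center = xi.mean(axis=0)
    xc = xi - center
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    return u * s, vt.T, explained, center, means


def _n_pcs_for(explained: np.ndarray, pca_keep, n_cap: int) -> int:
    if isinstance(pca_keep, (int, np.integer)):
        return max(1, min(int(pca_keep), n_cap))
    frac = float(pca_keep)
    cum = np.cumsum(explained)
    n = int(np.searchsorted(cum, frac - 1e-12) + 1)
    return max(1, min(n, n_cap))


# ---------------------------------------------------------------------------
# Cluster discovery
# ---------------------------------------------------------------------------

def find_clusters(
    x: AlleleMatrix,
    k_max: int = 40,
    pca_keep: float | int = 0.90,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[np.ndarray, dict[int, float], int]:
    """Successive k-means on PCA scores with BIC-based choice of k.

    For k = 1..k_max, k-means (``n_restarts`` seeded restarts, best
    within-cluster sum of squares kept) is run on the retained PC
    scores and scored by BIC(k) = n·ln(WSS_k/n) + k·ln(n).  The number
    of clusters follows the successive-decrease heuristic: the drops
    Δ_k = BIC(k) − BIC(k+1) are split into two groups by 1-D Ward
    clustering and the chosen k is one past the largest k whose drop
    falls in the high-decrease group (k = 1 when the curve never
    decreases).

    Returns (labels for chosen k, BIC curve, chosen k).
    """
    n = x.n
    if k_max >= n:
        raise ValueError(f"k_max ({k_max}) must be below the number of individuals ({n})")
    scores, loadings, explained, center, means = _pca(x.x)
    n_pcs = _n_pcs_for(explained, pca_keep, min(n - 1, scores.shape[1]))
    z = scores[:, :n_pcs]

    bic: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    tiny = 1e-12
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        lab = km.fit_predict(z)
        wss = max(float(km.inertia_), tiny)
        bic[k] = n * np.log(wss / n) + k * np.log(n)
        labels_by_k[k] = lab

    chosen = _diffngroup(bic)
    return labels_by_k[chosen], bic, chosen


def _diffngroup(bic: dict[int, float]) -> int:
    """Choose k from the BIC curve's successive decreases."""
    ks = sorted(bic)
    if len(ks) == 1:
        return ks[0]
    deltas = np.array([bic[k] - bic[k + 1] for k in ks[:-1]])
    if deltas.max() <= 0:
        return ks[0]
    if len(deltas) == 1:
        return ks[1]
    link = sch.linkage(deltas.reshape(-1, 1), method="ward")
    groups = sch.fcluster(link, t=2, criterion="maxclust")
    means = {g: deltas[groups == g].mean() for g in np.unique(groups)}
    high = max(means, key=means.get)
    in_high = np.where((groups == high) & (deltas > 0))[0]
    if in_high.size == 0:
        return ks[0]
    return ks[in_high.max()] + 1


# ---------------------------------------------------------------------------
# DAPC fit / cross-validation / assignment
# ---------------------------------------------------------------------------

def fit_dapc(x: AlleleMatrix, labels, n_pcs: int) -> DAPCModel:
    """Fit a DAPC: PCA retention followed by Fisher discriminant axes.

    The k−1 discriminant axes diagonalize between-cluster scatter
    against pooled within-cluster covariance (axes are scaled so the
    within-cluster covariance in DA space is the identity, making
    Euclidean distance to centroids a Mahalanobis distance).  A ridge
    is added when the within-class scatter is singular.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    k = len(classes)
    if k < 2:
        raise ValueError("need at least 2 clusters")
    n = x.n
    if n_pcs > n - 1:
        raise ValueError(f"n_pcs ({n_pcs}) must be at most n−1 ({n - 1})")

    scores, loadings, explained, center, means = _pca(x.x)
    n_pcs = min(n_pcs, scores.shape[1])
    z = scores[:, :n_pcs]

    grand = z.mean(axis=0)
    sw = np.zeros((n_pcs, n_pcs))
    sb = np.zeros((n_pcs, n_pcs))
    for c in classes:
        zc = z[labels == c]
        mu = zc.mean(axis=0)
        dev = zc - mu
        sw += dev.T @ dev
        dm = (mu - grand)[:, None]
        sb += len(zc) * (dm @ dm.T)
    dof = max(n - k, 1)
    sw_cov = sw / dof
    ridge = 0.0
    if np.linalg.matrix_rank(sw_cov) < n_pcs:
        ridge = 1e-8 * max(np.trace(sw_cov) / n_pcs, 1.0)
        warnings.warn("singular within-class scatter; ridge added", RuntimeWarning, stacklevel=2)
    evals, evecs = scipy.linalg.eigh(sb / dof, sw_cov + ridge * np.eye(n_pcs))
    order = np.argsort(evals)[::-1][: k - 1]
    da_axes = evecs[:, order]  # eigh normalizes vᵀ (Sw/dof) v = I

    zda = z @ da_axes
    centroids = np.vstack([zda[labels == c].mean(axis=0) for c in classes])

    d2 = ((zda[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    pred = classes[np.argmin(d2, axis=1)]
    acc = float(np.mean(pred == labels))

    return DAPCModel(
        columns=list(x.columns),
        center=center,
        column_means=means if x.column_means is None else np.asarray(x.column_means),
        pc_loadings=loadings[:, :n_pcs],
        n_pcs=n_pcs,
        da_axes=da_axes,
        k=k,
        centroids=centroids,
        training_labels=[int(c) for c in labels],
        training_ids=list(x.ids),
        self_assignment_accuracy=acc,
    )


def _stratified_split(labels: np.ndarray, test_frac: float, rng) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        idx = np.where(labels == c)[0]
        rng.shuffle(idx)
        n_test = min(max(1, int(round(test_frac * len(idx)))), len(idx) - 1)
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return np.array(sorted(train_idx)), np.array(sorted(test_idx))


def xval_pc_selection(
    x: AlleleMatrix,
    labels,
    pc_grid,
    reps: int = 30,
    test_frac: float = 0.10,
    seed: int = 0,
) -> tuple[dict[int, float], int]:
    """Choose the PC count by repeated stratified train/test assignment.

    For each candidate PC count, a DAPC is fitted on a stratified
    train split (default 90%) and assignment accuracy is measured on
    the held-out fraction, repeated ``reps`` times.  Clusters with
    fewer than 2 members are excluded from splitting with a warning.
    Returns (mean accuracy per PC count, best count — ties broken
    toward fewer PCs).
    """
    labels = np.asarray(labels)
    sizes = {c: int((labels == c).sum()) for c in np.unique(labels)}
    small = [c for c, s in sizes.items() if s < 2]
    if small:
        warnings.warn(
            f"cluster(s) {small} with <2 members excluded from cross-validation",
            RuntimeWarning,
            stacklevel=2,
        )
    usable = np.isin(labels, [c for c in sizes if sizes[c] >= 2])
    xs = x.subset_rows(np.where(usable)[0])
    ls = labels[usable]

    rng = np.random.default_rng(seed)
    pc_grid = [int(p) for p in pc_grid]
    acc = {p: [] for p in pc_grid}
    for _ in range(reps):
        tr, te = _stratified_split(ls, test_frac, rng)
        x_tr, x_te = xs.subset_rows(tr), xs.subset_rows(te)
        for p in pc_grid:
            if p > len(tr) - 1:
                continue
            model = fit_dapc(x_tr, ls[tr], p)
            calls = assign_barcode(model, x_te)
            pred = np.array([c.cluster if c.cluster is not None else -1 for c in calls])
            acc[p].append(float(np.mean(pred == ls[te])))
    table = {p: float(np.mean(v)) for p, v in acc.items() if v}
    if not table:
        raise ValueError("no PC count could be evaluated")
    best_acc = max(table.values())
    best = min(p for p, a in table.items() if a >= best_acc - 1e-12)
    return table, best


def reconcile_columns(query: AlleleMatrix, model: DAPCModel) -> AlleleMatrix:
    """Reorder/extend a query matrix onto a model's column set.

    Model columns absent from the query become all-missing (imputed
    from training means at projection time); novel query columns are
    ignored with a warning.
    """
    if list(query.columns) == list(model.columns):
        return query
    pos = {c: j for j, c in enumerate(query.columns)}
    novel = [c for c in query.columns if c not in set(model.columns)]
    if novel:
        warnings.warn(
            f"{len(novel)} query column(s) not in model ignored", RuntimeWarning, stacklevel=2
        )
    cols = [
        query.x[:, pos[c]] if c in pos else np.full(query.n, np.nan)
        for c in model.columns
    ]
    return AlleleMatrix(ids=list(query.ids), columns=list(model.columns),
                        x=np.column_stack(cols))


def assign_barcode(model: DAPCModel, query: AlleleMatrix) -> list[OriginCall]:
    """Assign query barcodes to DAPC clusters with membership posteriors.

    Query columns are reconciled to the model's column set first;
    missing model columns are imputed from the stored training column
    means.  A query row observing fewer than half of the model columns
    is returned as NA (``insufficient_overlap``).  Posteriors are a
    distance softmax under equal priors:
    P(g) ∝ exp(−½‖z − centroid_g‖²), normalized over clusters.
    """
    query = reconcile_columns(query, model)
    classes = sorted(set(model.training_labels))
    calls: list[OriginCall] = []
    overlap = np.mean(~np.isnan(query.x), axis=1)
    xi = _impute(query.x, model.column_means)
    z = (xi - model.center) @ model.pc_loadings @ model.da_axes
    d2 = ((z[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    # stable softmax of −d²/2
    log_w = -0.5 * d2
    log_w -= log_w.max(axis=1, keepdims=True)
    w = np.exp(log_w)
    post = w / w.sum(axis=1, keepdims=True)
    for i, sid in enumerate(query.ids):
        if overlap[i] < 0.5:
            calls.append(
                OriginCall(specimen=sid, method="COI-DAPC", origin="NA",
                           reason="insufficient_overlap")
            )
            continue
        g = int(np.argmax(post[i]))
        calls.append(
            OriginCall(
                specimen=sid,
                method="COI-DAPC",
                origin="unassigned",  # filled in by cluster_origin when a profile exists
                posterior=round(float(post[i, g]), 4),
                cluster=int(classes[g]),
            )
        )
    return calls


def membership_posteriors(model: DAPCModel, query: AlleleMatrix) -> np.ndarray:
    """Full posterior matrix (rows sum to 1) for query individuals."""
    query = reconcile_columns(query, model)
    xi = _impute(query.x, model.column_means)
    z = (xi - model.center) @ model.pc_loadings @ model.da_axes
    d2 = ((z[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    log_w = -0.5 * d2
    log_w -= log_w.max(axis=1, keepdims=True)
    w = np.exp(log_w)
    return w / w.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Regional profiles and origin calls
# ---------------------------------------------------------------------------

def region_profile(
    labels,
    regions,
    exclusions: set[str] = frozenset(),
    origin_map: dict[str, str] | None = None,
    dominance_threshold: float = 0.90,
    minor_floor: float = 0.05,
) -> ClusterRegionProfile:
    """Normalized per-cluster region proportions.

    Individuals with region ``Unknown`` or in ``exclusions`` are
    dropped.  Raw fractions ``count_cr / region_total_r`` correct for
    unequal sampling effort across regions before normalization within
    each cluster.  Regions left with zero total are dropped from the
    normalization with a warning.
    """
    labels = np.asarray(labels)
    regions = np.asarray(regions, dtype=object)
    keep = np.array([r != "Unknown" and r not in exclusions for r in regions])
    labels, regions = labels[keep], regions[keep]

    region_totals: dict[str, int] = {}
    for r in regions:
        region_totals[r] = region_totals.get(r, 0) + 1
    zero = [r for r, t in region_totals.items() if t == 0]
    if zero:
        warnings.warn(f"regions with zero total dropped: {zero}", RuntimeWarning, stacklevel=2)
        region_totals = {r: t for r, t in region_totals.items() if t > 0}

    counts: dict[int, dict[str, int]] = {}
    normalized: dict[int, dict[str, float]] = {}
    n_known: dict[int, int] = {}
    for c in sorted(set(int(v) for v in labels)):
        mask = labels == c
        cr = {r: int(np.sum(regions[mask] == r)) for r in region_totals}
        raw = {r: cr[r] / region_totals[r] for r in region_totals}
        total = sum(raw.values())
        counts[c] = cr
        normalized[c] = {r: (raw[r] / total if total > 0 else 0.0) for r in region_totals}
        n_known[c] = int(mask.sum())
    return ClusterRegionProfile(
        counts=counts,
        normalized=normalized,
        n_with_known_origin=n_known,
        region_totals=region_totals,
        origin_map=dict(origin_map or DEFAULT_ORIGIN_MAP),
        dominance_threshold=dominance_threshold,
        minor_floor=minor_floor,
    )


def cluster_origin(profile: ClusterRegionProfile, cluster: int) -> str:
    """Map a cluster's normalized regional profile to a continental origin.

    Region proportions are pooled per origin through the profile's
    origin map; the top origin is returned when it reaches the
    dominance threshold, otherwise an ambiguous call listing every
    origin above the minor floor (descending).
    """
    if cluster not in profile.normalized:
        raise KeyError(f"cluster {cluster} not in profile")
    by_origin: dict[str, float] = {}
    for r, p in profile.normalized[cluster].items():
        o = profile.origin_map.get(r)
        if o is None:
            continue
        by_origin[o] = by_origin.get(o, 0.0) + p
    if not by_origin:
        return "NA"
    top = max(by_origin, key=by_origin.get)
    if by_origin[top] >= profile.dominance_threshold:
        return top
    cands = sorted(
        (o for o, p in by_origin.items() if p >= profile.minor_floor),
        key=lambda o: -by_origin[o],
    )
    if len(cands) < 2:
        cands = sorted(by_origin, key=lambda o: -by_origin[o])[:2]
    return "ambiguous:" + ",".join(cands)


def calls_with_origin(
    calls: list[OriginCall], profile: ClusterRegionProfile
) -> list[OriginCall]:
    """Fill cluster-level origins into per-specimen DAPC calls."""
    out = []
    for c in calls:
        if c.cluster is None:
            out.append(c)
            continue
        origin = cluster_origin(profile, c.cluster)
        out.append(
            OriginCall(
                specimen=c.specimen,
                method=c.method,
                origin=origin,
                posterior=c.posterior,
                cluster=c.cluster,
                candidates=origin.split(":", 1)[1].split(",") if origin.startswith("ambiguous") else [],
                reason=c.reason,
            )
        )
    return out


# ---------------------------------------------------------------------------
# End-to-end fit pipeline
# ---------------------------------------------------------------------------

def fit_coi_pipeline(
    aln: BarcodeAlignment,
    k_max: int = 40,
    pca_keep: float | int = 0.90,
    pc_grid=None,
    xval_reps: int = 30,
    seed: int = 0,
    curate: bool = True,
    frame: int = 1,
    min_mac: int = 1,
    exclusions: set[str] = frozenset(),
) -> tuple[DAPCModel, ClusterRegionProfile, dict]:
    """Curate → encode → find clusters → cross-validate → fit → profile.

    Returns the fitted model, the cluster-region profile and a report
    dict (rejections, BIC curve, chosen k, xval table).
    """
    report: dict = {}
    if curate:
        aln, rejections = curate_alignment(aln, frame=frame)
        report["rejections"] = rejections
    x = encode_alignment(aln, min_mac=min_mac)
    labels, bic, chosen_k = find_clusters(x, k_max=k_max, pca_keep=pca_keep, seed=seed)
    report["bic_curve"] = bic
    report["chosen_k"] = chosen_k
    if chosen_k < 2:
        raise ValueError("cluster discovery found a single cluster; cannot fit a DAPC")
    if pc_grid is None:
        cap = max(2, min(x.n - 10, 60))
        pc_grid = sorted({p for p in (2, 5, 10, 15, 20, 25, 40, 60) if p <= cap})
    table, best = xval_pc_selection(
        x, labels, pc_grid, reps=xval_reps, seed=seed
    )
    report["xval_table"] = table
    model = fit_dapc(x, labels, best)
    model.bic_curve = bic
    model.xval_table = table
    profile = region_profile(labels, aln.region, exclusions=exclusions)
    return model, profile, report
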