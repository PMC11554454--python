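"""Polarity-invariant microstate segmentation.

The segmentation pipeline follows the classical topographic-analysis
recipe: global field power (GFP) is computed per sample; maps at GFP
peaks (high signal-to-noise moments) are clustered with the
atomize-and-agglomerate hierarchical clustering (AAHC) algorithm,
ignoring map polarity; clustering runs first per subject and the
subject templates are then pooled and clustered again to give group
templates; finally every sample of every recording is labeled with the
template of highest absolute spatial correlation (backfitting).

Polarity-invariant centroids are the first principal eigenvector of a
cluster's map outer-product sum: the sign-blind mean is ill-defined,
while the principal axis maximizes exactly the GFP-weighted squared
correlation that global explained variance (GEV) measures.  A cluster's
GEV contribution is therefore the top eigenvalue of its scatter matrix
divided by the total squared GFP, and AAHC repeatedly dissolves the
cluster with the smallest contribution, reassigning each freed map to
the surviving cluster with the highest absolute spatial correlation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import EEGRecording

CLASS_NAMES = ["A", "B", "C", "D"]


# --------------------------------------------------------------------------
# GFP and peak selection

def compute_gfp(rec: EEGRecording) -> np.ndarray:
    """Global field power: per-sample RMS of the average-referenced potentials.

    For an average-referenced sample this equals the population standard
    deviation of the potential values across electrodes.
    """
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    return np.sqrt(np.mean(rec.potentials ** 2, axis=0))


def find_gfp_peaks(gfp: np.ndarray, sampling_rate: float,
                   min_distance_ms: float = 10.0) -> np.ndarray:
    """Local GFP maxima, greedily thinned to a minimum spacing.

    A peak is a sample strictly greater than its left neighbour and at
    least its right neighbour; for a flat plateau the leftmost sample is
    kept.  Candidates are then retained in descending GFP order subject
    to the ``min_distance_ms`` spacing constraint, and returned sorted.
    """
    gfp = np.asarray(gfp, dtype=float)
    if gfp.size < 3:
        raise ValueError("GFP series too short for peak detection")
    if min_distance_ms <= 0:
        raise ValueError("min_distance_ms must be positive")

    left = gfp[1:-1] > gfp[:-2]
    right = gfp[1:-1] >= gfp[2:]
    candidates = np.flatnonzero(left & right) + 1
    # plateau: gfp[i] == gfp[i+1] ... keep only the leftmost sample, which is
    # the first candidate of the flat run; drop candidates whose value equals
    # their left neighbour's (they sit inside a plateau)
    candidates = candidates[gfp[candidates] > gfp[candidates - 1]]
    # drop plateau peaks that are not true local maxima on the right side:
    # walk right across the flat run and require a strict drop before a rise
    keep = []
    n = gfp.size
    for i in candidates:
        j = i
        while j + 1 < n and gfp[j + 1] == gfp[i]:
            j += 1
        if j + 1 < n and gfp[j + 1] < gfp[i]:
            keep.append(i)
        elif j + 1 == n:
            # plateau runs to the end: not an interior maximum
            continue
    candidates = np.asarray(keep, dtype=int)
    if candidates.size == 0:
        return candidates

    min_gap = int(np.ceil(min_distance_ms * sampling_rate / 1000.0))
    order = candidates[np.argsort(-gfp[candidates], kind="stable")]
    taken = np.zeros(n, dtype=bool)
    selected = []
    for idx in order:
        if not taken[idx]:
            selected.append(idx)
            lo, hi = max(0, idx - min_gap + 1), min(n, idx + min_gap)
            taken[lo:hi] = True
    return np.sort(np.asarray(selected, dtype=int))


def sample_peaks(peaks: np.ndarray, n: int = 1000,
                 rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Uniformly sample ``min(n, len(peaks))`` peak indices without replacement."""
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size == 0:
        raise ValueError("empty peak set")
    if n <= 0:
        raise ValueError("n must be positive")
    if peaks.size <= n:
        return peaks.copy()
    rng = np.random.default_rng(rng)
    chosen = rng.choice(peaks.size, size=n, replace=False)
    return np.sort(peaks[chosen])


# --------------------------------------------------------------------------
# Topographic similarity and explained variance

def spatial_correlation(map1: np.ndarray, map2: np.ndarray,
                        ignore_polarity: bool = True) -> float:
    """Pearson correlation between two topographies across electrodes.

    With ``ignore_polarity`` the absolute value is returned, matching the
    sign-blind similarity used throughout microstate clustering.
    """
    a = np.asarray(map1, dtype=float)
    b = np.asarray(map2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must have equal channel counts")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-300 or nb < 1e-300:
        raise ValueError("zero-variance map has no spatial correlation")
    r = float(a @ b / (na * nb))
    r = float(np.clip(r, -1.0, 1.0))
    return abs(r) if ignore_polarity else r


def _correlation_matrix(samples: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """|corr| between each column of ``samples`` (c, n) and each template (k, c).

    Zero-variance samples get correlation 0 to every template.
    """
    x = samples - samples.mean(axis=0, keepdims=True)
    t = templates - templates.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(x, axis=0)
    tn = np.linalg.norm(t, axis=1)
    safe = np.where(xn < 1e-300, 1.0, xn)
    corr = (t @ x) / (tn[:, None] * safe[None, :])
    corr[:, xn < 1e-300] = 0.0
    return np.clip(np.abs(corr), 0.0, 1.0)


def compute_gev(samples: np.ndarray, labels: np.ndarray, templates: np.ndarray,
                gfp: np.ndarray) -> tuple[float, np.ndarray]:
    """Global explained variance of a labeled set of maps.

    GEV = sum_t (GFP_t * |corr(x_t, a_L(t))|)^2 / sum_t GFP_t^2, with the
    per-class decomposition returned alongside the total.
    """
    samples = np.asarray(samples, dtype=float)
    labels = np.asarray(labels, dtype=int)
    templates = np.atleast_2d(np.asarray(templates, dtype=float))
    gfp = np.asarray(gfp, dtype=float)
    denom = float(np.sum(gfp ** 2))
    if denom <= 0:
        raise ValueError("all-zero GFP: GEV undefined")
    corr = _correlation_matrix(samples, templates)
    picked = corr[labels, np.arange(samples.shape[1])]
    contrib = (gfp * picked) ** 2
    per_class = np.array([
        contrib[labels == c].sum() for c in range(templates.shape[0])
    ]) / denom
    return float(per_class.sum()), per_class


# --------------------------------------------------------------------------
# AAHC clustering

@dataclass
class ClusterState:
    """Final AAHC assignment: map index -> cluster, centroids, per-cluster GEV."""

    assignment: np.ndarray
    centroids: np.ndarray
    gev_per_cluster: np.ndarray

    @property
    def gev(self) -> float:
        return float(self.gev_per_cluster.sum())


@dataclass
class TemplateSet:
    """k unit-norm, average-referenced template topographies."""

    maps: np.ndarray                     # (k, n_channels)
    ch_names: list[str] | None = None
    labels: list[str] | None = None      # A..D once canonicalized
    provenance: str = "group-level"
    gev: float | None = None

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))

    @property
    def k(self) -> int:
        return self.maps.shape[0]


def _top_eig(scatter: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = np.linalg.eigh(scatter)
    return float(vals[-1]), vecs[:, -1]


def aahc_cluster(maps: np.ndarray, k: int = 4) -> tuple[TemplateSet, ClusterState]:
    """Atomize-and-agglomerate hierarchical clustering of topographies.

    Every map starts as its own cluster.  Until ``k`` clusters remain,
    the cluster whose removal costs least — the one with the smallest
    GEV contribution — is atomized: its members are freed and reassigned
    one at a time to the surviving cluster whose centroid they correlate
    with most strongly in absolute value, the receiving centroid being
    updated after each insertion.  Map polarity is ignored throughout.

    ``maps`` rows are average-referenced topographies; their norms act
    as GFP weights (for GFP-peak maps the row norm is GFP * sqrt(n_ch)).
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    n, c = maps.shape
    if n < k:
        raise ValueError(f"need at least k={k} maps, got {n}")
    norms = np.linalg.norm(maps, axis=1)
    if np.any(norms < 1e-300):
        raise ValueError("zero-variance map cannot be clustered")
    total_sq = float(np.sum(norms ** 2))

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    scatters = {i: np.outer(maps[i], maps[i]) for i in range(n)}
    centroids = {i: maps[i] / norms[i] for i in range(n)}
    # singleton contribution = |m|^2 (eigenvalue of rank-1 scatter)
    costs = {i: float(norms[i] ** 2) for i in range(n)}

    if k > 1 and len({tuple(np.round(m / np.linalg.norm(m), 12)) for m in maps}) == 1:
        raise ValueError("all maps identical: cannot form k > 1 clusters")

    while len(members) > k:
        worst = min(costs, key=lambda i: (costs[i], i))
        freed = members.pop(worst)
        scatters.pop(worst)
        centroids.pop(worst)
        costs.pop(worst)
        live = sorted(members)
        cent_matrix = np.stack([centroids[i] for i in live])
        for m_idx in freed:
            m = maps[m_idx]
            corr = np.abs(cent_matrix @ m) / norms[m_idx]
            best_pos = int(np.argmax(corr))
            best = live[best_pos]
            members[best].append(m_idx)
            scatters[best] += np.outer(m, m)
            lam, vec = _top_eig(scatters[best])
            centroids[best] = vec
            costs[best] = lam
            cent_matrix[best_pos] = vec

    live = sorted(members)
    assignment = np.empty(n, dtype=int)
    for new_idx, ci in enumerate(live):
        assignment[members[ci]] = new_idx
    centroid_arr = np.stack([centroids[i] for i in live])
    # unit-norm, average-referenced (maps span the average-referenced
    # subspace, so eigenvectors already have ~zero mean; enforce exactly)
    centroid_arr -= centroid_arr.mean(axis=1, keepdims=True)
    centroid_arr /= np.linalg.norm(centroid_arr, axis=1, keepdims=True)
    gev_per = np.array([costs[i] for i in live]) / total_sq
    templates = TemplateSet(centroid_arr, provenance="aahc", gev=float(gev_per.sum()))
    return templates, ClusterState(assignment, centroid_arr, gev_per)


def best_partition_gev(maps: np.ndarray, k: int = 2) -> float:
    """Exhaustive-search oracle: best achievable GEV over all k-partitions.

    For each partition the optimal polarity-invariant centroid of a
    cluster is its scatter matrix's principal eigenvector, whose
    eigenvalue is the cluster's (unnormalized) GEV contribution.  Only
    practical for small map sets; used for validating AAHC.
    """
    from itertools import product

    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    n = maps.shape[0]
    if n > 12:
        raise ValueError("exhaustive partition search limited to 12 maps")
    total_sq = float(np.sum(np.linalg.norm(maps, axis=1) ** 2))
    best = 0.0
    for assign in product(range(k), repeat=n):
        if len(set(assign)) != k:
            continue
        total = 0.0
        for cluster in range(k):
            idx = [i for i, a in enumerate(assign) if a == cluster]
            sub = maps[idx]
            lam, _ = _top_eig(sub.T @ sub)
            total += lam
        best = max(best, total / total_sq)
    return best


# --------------------------------------------------------------------------
# Two-level clustering and canonical labeling

def _subject_seed(subject_id: str, seed: int) -> np.random.Generator:
    import zlib

    return np.random.default_rng([seed, zlib.crc32(str(subject_id).encode())])


def subject_templates(rec: EEGRecording, k: int = 4, n_peaks: int = 1000,
                      min_peak_distance_ms: float = 10.0,
                      rng: np.random.Generator | int | None = None) -> TemplateSet:
    """Single-subject template extraction: GFP peaks -> sample -> AAHC."""
    gfp = compute_gfp(rec)
    peaks = find_gfp_peaks(gfp, rec.sampling_rate, min_peak_distance_ms)
    if peaks.size < k:
        raise ValueError("too few GFP peaks for clustering")
    picked = sample_peaks(peaks, n_peaks, rng)
    templates, _ = aahc_cluster(rec.potentials[:, picked].T, k=k)
    templates.provenance = "subject-level"
    templates.ch_names = rec.ch_names
    return templates


def two_level_cluster(recordings, k: int = 4, n_peaks: int = 1000,
                      min_peak_distance_ms: float = 10.0, seed: int = 0
                      ) -> tuple[TemplateSet, dict[str, TemplateSet]]:
    """Subject-level AAHC followed by group-level AAHC on pooled templates.

    ``recordings`` iterates over ``(subject_id, EEGRecording)`` pairs.
    Each subject contributes k unit-norm maps with unit weight to the
    group stage; pooled maps are sorted deterministically so the result
    does not depend on subject order.  Per-subject sampling seeds derive
    from the subject id, for the same reason.
    """
    per_subject: dict[str, TemplateSet] = {}
    ch_names = None
    for subject_id, rec in recordings:
        rng = _subject_seed(subject_id, seed)
        per_subject[str(subject_id)] = subject_templates(
            rec, k=k, n_peaks=n_peaks,
            min_peak_distance_ms=min_peak_distance_ms, rng=rng)
        ch_names = rec.ch_names
    if not per_subject:
        raise ValueError("no recordings supplied")

    pooled = np.concatenate([ts.maps for ts in per_subject.values()])
    order = np.lexsort(np.round(pooled, 9).T[::-1])
    group, _ = aahc_cluster(pooled[order], k=k)
    group.provenance = "group-level"
    group.ch_names = ch_names
    return group, per_subject


def canonicalize_labels(templates: TemplateSet, positions: np.ndarray) -> TemplateSet:
    """Assign canonical A-D labels by optimal matching to reference maps.

    The four templates are matched one-to-one to the canonical reference
    topographies (A: left-posterior to right-anterior gradient, B: its
    mirror image, C: posterior-anterior, D: fronto-central maximum) by
    maximizing total absolute spatial correlation over all 24
    permutations.  Rows are reordered to A, B, C, D and each map's sign
    is oriented positively with its reference.
    """
    from itertools import permutations

    from .simulate import make_canonical_templates

    if templates.k != 4:
        raise ValueError("canonical A-D labeling requires exactly 4 templates")
    refs = make_canonical_templates(positions=positions)
    corr_signed = np.array([
        [spatial_correlation(t, r, ignore_polarity=False)
         for r in refs] for t in templates.maps
    ])
    corr = np.abs(corr_signed)
    best_perm = max(permutations(range(4)),
                    key=lambda p: sum(corr[t, c] for t, c in enumerate(p)))
    # row i of the output is the template assigned to class i (A..D)
    ordered = np.empty_like(templates.maps)
    for t_idx, class_idx in enumerate(best_perm):
        sign = 1.0 if corr_signed[t_idx, class_idx] >= 0 else -1.0
        ordered[class_idx] = sign * templates.maps[t_idx]
    return TemplateSet(ordered, ch_names=templates.ch_names,
                       labels=list(CLASS_NAMES), provenance=templates.provenance,
                       gev=templates.gev)


# --------------------------------------------------------------------------
# Backfitting

@dataclass
class Segmentation:
    """Per-sample microstate labels with fit quality."""

    labels: np.ndarray                  # (n_samples,) template indices
    correlation: np.ndarray             # |corr| to the winning template
    gev: float
    gev_per_class: np.ndarray
    sampling_rate: float
    class_names: list[str] = field(default_factory=lambda: list(CLASS_NAMES))


def _majority_smooth(labels: np.ndarray, k: int, half_window: int) -> np.ndarray:
    """Sliding majority vote over a +/- half_window sample neighbourhood.

    Ties resolve to the lowest class index, matching the package-wide
    tie-break convention.
    """
    n = labels.size
    onehot = np.zeros((k, n))
    onehot[labels, np.arange(n)] = 1.0
    kernel = np.ones(2 * half_window + 1)
    votes = np.stack([np.convolve(onehot[c], kernel, mode="same")
                      for c in range(k)])
    return np.argmax(votes, axis=0)


def backfit(rec: EEGRecording, templates: TemplateSet,
            smooth_window_ms: float = 0.0) -> Segmentation:
    """Label every sample with the template of highest |spatial correlation|.

    Ties break to the lowest class index.  Zero-variance samples carry
    no topographic information and inherit the nearest preceding label
    (leading zero-variance samples take the first labeled sample's
    class); they contribute zero to GEV either way.

    ``smooth_window_ms`` > 0 applies a sliding majority vote over a
    window of that total width to suppress spurious label flickers at
    low-field moments; it is off by default.
    """
    if rec.n_channels != templates.maps.shape[1]:
        raise ValueError("recording and templates have different channel counts")
    x = rec.potentials
    corr = _correlation_matrix(x, templates.maps)
    labels = np.argmax(corr, axis=0)          # argmax takes the lowest index on ties
    winning = corr[labels, np.arange(x.shape[1])]

    flat = np.linalg.norm(x - x.mean(axis=0, keepdims=True), axis=0) < 1e-300
    if flat.any():
        if flat.all():
            raise ValueError("recording has no sample with spatial variance")
        idx = np.arange(flat.size)
        prev = np.maximum.accumulate(np.where(~flat, idx, -1))
        first_good = int(np.flatnonzero(~flat)[0])
        prev[prev < 0] = first_good
        labels = labels[prev]
        winning = np.where(flat, 0.0, winning)

    if smooth_window_ms > 0:
        half = max(1, int(round(smooth_window_ms * rec.sampling_rate / 2000.0)))
        labels = _majority_smooth(labels, templates.k, half)
        winning = corr[labels, np.arange(x.shape[1])]

    gfp = compute_gfp(rec)
    denom = float(np.sum(gfp ** 2))
    contrib = (gfp * winning) ** 2
    per_class = np.array([
        contrib[labels == c].sum() for c in range(templates.k)
    ]) / denom
    names = templates.labels or [str(i) for i in range(templates.k)]
    return Segmentation(labels, winning, float(per_class.sum()), per_class,
                        rec.sampling_rate, list(names))
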