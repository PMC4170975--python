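"""Dataset curation, cross-validation schemes, and regression metrics.

Curation follows the redundancy-reduction protocol standard in ΔΔG
benchmarking: sequences (or chain pairs, for complexes) are clustered greedily
at 90 % identity in the style of CD-HIT — items sorted by length descending,
each joining the first representative it matches — and one representative per
cluster is retained, chosen as the member with the most available mutations.
This prevents leakage of near-identical proteins across the train/test
boundary.

Two cross-validation schemes are provided: repeated k-fold (default 20 folds
× 50 repetitions, giving a mean Pearson r and its dispersion σ across
repetitions) and leave-one-family-out, in which all mutations of one protein
family form the test set — the appropriate scheme when homology modelling
introduces family-level redundancy.

A quality filter for homology-model inputs rejects models whose wild-type
folding/binding energy exceeds 30 kcal/mol or whose normalized DOPE score
exceeds 1; boundary values are kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Cluster",
    "CrossValScheme",
    "CrossValResult",
    "ModelQuality",
    "pairwise_identity",
    "greedy_cluster",
    "select_representatives",
    "make_repeated_kfold",
    "make_leave_one_family_out",
    "pearson_r",
    "rmse",
    "quality_filter",
    "run_cross_validation",
    "IDENTITY_THRESHOLD",
    "DG_WT_CUTOFF",
    "DOPE_CUTOFF",
]

IDENTITY_THRESHOLD = 0.90
DG_WT_CUTOFF = 30.0   # kcal/mol, wild-type model energy above this is rejected
DOPE_CUTOFF = 1.0     # normalized DOPE above this is rejected


# ---------------------------------------------------------------------------
# Sequence identity and greedy clustering
# ---------------------------------------------------------------------------

_ALIGNER = None


def _aligner():
    global _ALIGNER
    if _ALIGNER is None:
        from Bio import Align
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1.0
        a.mismatch_score = 0.0
        a.open_gap_score = -10.0
        a.extend_gap_score = -0.5
        a.open_end_gap_score = 0.0
        a.extend_end_gap_score = 0.0
        _ALIGNER = a
    return _ALIGNER


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment sequence identity, normalized by the shorter sequence.

    Scoring: match +1, mismatch 0, gap open −10, gap extend −0.5, end gaps
    free (the convention of greedy identity-clustering tools).
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aln = _aligner().align(seq_a, seq_b)[0]
    counts = aln.counts()
    return counts.identities / min(len(seq_a), len(seq_b))


@dataclass
class Cluster:
    representative: str
    members: list[str]
    sequences: dict[str, tuple[str, ...]] = field(default_factory=dict)


def _as_seqs(value) -> tuple[str, ...]:
    if isinstance(value, str):
        return (value,)
    return tuple(value)


def _item_identity(seqs_a: tuple[str, ...], seqs_b: tuple[str, ...],
                   pair_mode: str) -> float:
    if pair_mode == "single":
        return pairwise_identity(seqs_a[0], seqs_b[0])
    if len(seqs_a) != len(seqs_b):
        raise ValueError("chain-count mismatch in average_of_chains mode")
    vals = [pairwise_identity(a, b) for a, b in zip(seqs_a, seqs_b)]
    return float(np.mean(vals))


def greedy_cluster(items: dict, threshold: float = IDENTITY_THRESHOLD,
                   pair_mode: str = "single") -> list[Cluster]:
    """CD-HIT-style greedy clustering at a sequence-identity threshold.

    Items (id → sequence, or id → tuple of chain sequences) are sorted by
    total length descending (ties lexicographic by id); each joins the first
    existing representative with identity ≥ threshold (averaged over chains
    in ``average_of_chains`` mode), otherwise it founds a new cluster.
    """
    if not items:
        raise ValueError("no items to cluster")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if pair_mode not in ("single", "average_of_chains"):
        raise ValueError(f"unknown pair_mode {pair_mode!r}")
    norm = {k: _as_seqs(v) for k, v in items.items()}
    order = sorted(norm, key=lambda k: (-sum(len(s) for s in norm[k]), k))
    clusters: list[Cluster] = []
    for item in order:
        placed = False
        for cl in clusters:
            ident = _item_identity(norm[item], norm[cl.representative], pair_mode)
            if ident >= threshold:
                cl.members.append(item)
                cl.sequences[item] = norm[item]
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=item, members=[item],
                                    sequences={item: norm[item]}))
    return clusters


def select_representatives(clusters: list[Cluster], mutation_counts: dict) -> list[str]:
    """One id per cluster: the member with the most available mutations
    (ties broken lexicographically)."""
    out = []
    for cl in clusters:
        for m in cl.members:
            if m not in mutation_counts:
                raise KeyError(f"no mutation count for {m!r}")
        out.append(min(cl.members, key=lambda m: (-mutation_counts[m], m)))
    return out


# ---------------------------------------------------------------------------
# Cross-validation schemes
# ---------------------------------------------------------------------------

@dataclass
class CrossValScheme:
    kind: str                       # repeated_kfold | leave_one_family_out
    k: int = 20
    repetitions: int = 50
    seed: int = 0
    families: list | None = None    # per-sample labels for the family scheme


def make_repeated_kfold(n: int, k: int = 20, repetitions: int = 50,
                        seed: int = 0) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Seeded repeated k-fold splits.

    Returns one list of (train_idx, test_idx) pairs per repetition; within a
    repetition the test folds exactly partition ``range(n)``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    reps = []
    for r in range(repetitions):
        rng = np.random.default_rng(seed + r)
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        reps.append([
            (np.sort(np.concatenate(folds[:i] + folds[i + 1:])),
             np.sort(folds[i]))
            for i in range(k)
        ])
    return reps


def make_leave_one_family_out(families) -> list[tuple[np.ndarray, np.ndarray]]:
    """One split per family; a family never appears in train and test at once."""
    labels = list(families)
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("leave-one-family-out needs at least 2 families")
    arr = np.array(labels, dtype=object)
    splits = []
    for fam in uniq:
        test = np.where(arr == fam)[0]
        train = np.where(arr != fam)[0]
        splits.append((train, test))
    return splits


def scheme_splits(scheme: CrossValScheme, n: int):
    """Materialize a scheme into repetition-grouped splits."""
    if scheme.kind == "repeated_kfold":
        return make_repeated_kfold(n, scheme.k, scheme.repetitions, scheme.seed)
    if scheme.kind == "leave_one_family_out":
        if scheme.families is None or len(scheme.families) != n:
            raise ValueError("family scheme needs one label per sample")
        return [make_leave_one_family_out(scheme.families)]
    raise ValueError(f"unknown scheme kind {scheme.kind!r}")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    xd = x - x.mean()
    yd = y - y.mean()
    vx = float((xd ** 2).sum())
    vy = float((yd ** 2).sum())
    if vx == 0.0 or vy == 0.0:
        raise ValueError("zero variance input")
    return float((xd * yd).sum() / math.sqrt(vx * vy))


def rmse(pred, obs) -> float:
    """Root-mean-square error, kcal/mol for ΔΔG vectors."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or len(pred) == 0:
        raise ValueError("pred and obs must be equal-length, non-empty")
    return float(np.sqrt(((pred - obs) ** 2).mean()))


# ---------------------------------------------------------------------------
# Quality filter for homology-model inputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelQuality:
    dg_wt: float            # kcal/mol, wild-type model folding/binding energy
    normalized_dope: float  # length-normalized model-quality score


def quality_filter(records):
    """Keep records whose model quality passes ΔG_wt ≤ 30 and DOPE ≤ 1.

    ``records`` is a list of (record, ModelQuality).  Returns (accepted
    records, rejection log); each log entry states which rule fired.
    Boundary values (exactly 30 / exactly 1) are accepted.
    """
    accepted = []
    log = []
    for rec, q in records:
        reasons = []
        if q.dg_wt > DG_WT_CUTOFF:
            reasons.append(f"dg_wt {q.dg_wt:g} > {DG_WT_CUTOFF:g} kcal/mol")
        if q.normalized_dope > DOPE_CUTOFF:
            reasons.append(f"normalized_dope {q.normalized_dope:g} > {DOPE_CUTOFF:g}")
        if reasons:
            log.append((rec, "; ".join(reasons)))
        else:
            accepted.append(rec)
    return accepted, log


# ---------------------------------------------------------------------------
# Cross-validated training
# ---------------------------------------------------------------------------

@dataclass
class CrossValResult:
    fold_r: list[float]
    fold_rmse: list[float]
    mean_r: float
    sigma_r: float
    pooled_rmse: float
    n_undefined_folds: int = 0


def run_cross_validation(X, y, params, scheme: CrossValScheme) -> CrossValResult:
    """Train/evaluate under a CV scheme; aggregate Pearson r and RMSE.

    σ is the standard deviation of the repetition-level mean r for repeated
    k-fold, or of the per-fold r for the family scheme.  Folds whose test set
    is too small or degenerate for a correlation are recorded as undefined
    and excluded from the mean.
    """
    from .sgbdt import fit_sgbdt, predict

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    reps = scheme_splits(scheme, len(y))
    fold_r: list[float] = []
    fold_rmse: list[float] = []
    rep_means: list[float] = []
    n_undef = 0
    sq_sum, n_total = 0.0, 0
    for rep in reps:
        rep_rs = []
        for train, test in rep:
            model = fit_sgbdt(X[train], y[train], params)
            pred = predict(model, X[test])
            sq_sum += float(((pred - y[test]) ** 2).sum())
            n_total += len(test)
            fold_rmse.append(rmse(pred, y[test]))
            try:
                r = pearson_r(pred, y[test])
            except ValueError:
                n_undef += 1
                continue
            rep_rs.append(r)
            fold_r.append(r)
        if rep_rs:
            rep_means.append(float(np.mean(rep_rs)))
    if scheme.kind == "repeated_kfold":
        mean_r = float(np.mean(rep_means)) if rep_means else float("nan")
        sigma = float(np.std(rep_means)) if len(rep_means) > 1 else 0.0
    else:
        mean_r = float(np.mean(fold_r)) if fold_r else float("nan")
        sigma = float(np.std(fold_r)) if len(fold_r) > 1 else 0.0
    pooled = math.sqrt(sq_sum / n_total) if n_total else float("nan")
    return CrossValResult(fold_r=fold_r, fold_rmse=fold_rmse, mean_r=mean_r,
                          sigma_r=sigma, pooled_rmse=pooled,
                          n_undefined_folds=n_undef)
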