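"""Segmentation metrics, volume agreement, and the cross-validation harness.

Conventions (both structures empty is a *correct* empty prediction):
DSC, recall and precision are reported as percentages in [0, 100];
DSC = 100 when prediction and truth are both empty, recall/precision
= 100 when the counterpart set is also empty, else 0.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SegScores",
    "FoldPlan",
    "dsc",
    "recall",
    "precision",
    "volume_agreement",
    "ag_metric_agreement",
    "make_folds",
    "evaluate_cohort",
]

AG_METRICS = ("total", "count", "average", "max", "min")


@dataclass
class SegScores:
    dsc: float
    recall: float
    precision: float
    rms: float = np.nan
    pearson_r: float = np.nan
    pearson_p: float = np.nan


@dataclass
class FoldPlan:
    folds: list          # dicts with train/val/test id lists
    n_folds: int
    split: tuple
    seed: int

    def to_json(self) -> dict:
        return {"n_folds": self.n_folds, "split": list(self.split),
                "seed": self.seed, "folds": self.folds}


def _binary(a) -> np.ndarray:
    return np.asarray(a) > 0


def _check_grids(a, b):
    a, b = _binary(a), _binary(b)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    return a, b


def dsc(a, b) -> float:
    """Dice-Sorensen coefficient as a percentage: 200|A∩B|/(|A|+|B|)."""
    a, b = _check_grids(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 100.0
    return 200.0 * int((a & b).sum()) / (na + nb)


def recall(pred, truth) -> float:
    """Sensitivity: 100*TP/(TP+FN); empty truth scores 100 iff the
    prediction is empty too."""
    pred, truth = _check_grids(pred, truth)
    tp = int((pred & truth).sum())
    denom = int(truth.sum())
    if denom == 0:
        return 100.0 if int(pred.sum()) == 0 else 0.0
    return 100.0 * tp / denom


def precision(pred, truth) -> float:
    """Positive predictive value: 100*TP/(TP+FP); empty prediction scores
    100 iff the truth is empty too."""
    pred, truth = _check_grids(pred, truth)
    tp = int((pred & truth).sum())
    denom = int(pred.sum())
    if denom == 0:
        return 100.0 if int(truth.sum()) == 0 else 0.0
    return 100.0 * tp / denom


def volume_agreement(est, ref):
    """Root-mean-squared difference and Pearson correlation of paired
    volume series; returns ``(rms, r, p)``.  Constant series have an
    undefined correlation and yield NaN with a warning."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("est and ref must have equal length")
    rms = float(np.sqrt(np.mean((est - ref) ** 2)))
    if est.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(est) == 0 or np.std(ref) == 0:
        warnings.warn("constant volume series: correlation undefined", stacklevel=2)
        return rms, float("nan"), float("nan")
    r, p = stats.pearsonr(est, ref)
    return rms, float(r), float(p)


def ag_metric_agreement(est, ref) -> pd.DataFrame:
    """Per-metric RMS and Pearson r for paired AG instance statistics.

    ``est``/``ref`` are equal-length lists of :class:`AGInstanceStats`
    (paired by subject).  Volumes are in mm^3; the count row is in
    occurrences.
    """
    if len(est) != len(ref):
        raise ValueError("est and ref must pair the same subjects")
    getters = {
        "total": lambda s: s.total_volume,
        "count": lambda s: float(s.count),
        "average": lambda s: s.average_volume,
        "max": lambda s: s.max_volume,
        "min": lambda s: s.min_volume,
    }
    rows = []
    for metric in AG_METRICS:
        e = [getters[metric](s) for s in est]
        r_ = [getters[metric](s) for s in ref]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rms, r, p = volume_agreement(e, r_)
        rows.append({"metric": metric, "rms": rms, "pearson_r": r,
                     "pearson_p": p,
                     "unit": "occurrences" if metric == "count" else "mm3"})
    return pd.DataFrame(rows).set_index("metric")


def make_folds(ids, split=(60, 10, 10), n_folds: int = 8, seed: int = 0,
               max_attempts: int = 10_000) -> FoldPlan:
    """Pseudo-random train/validation/test folds with full test coverage.

    Within each fold the three sets are disjoint with the configured
    sizes.  Across folds every id appears in at least one test set: when
    ``n_folds * n_test == len(ids)`` the test sets are a random
    partition of one permutation (coverage by construction); otherwise
    plans are redrawn until covered, up to ``max_attempts``.
    """
    ids = list(ids)
    n_train, n_val, n_test = split
    if len(ids) != sum(split):
        raise ValueError(f"need {sum(split)} ids for split {split}, got {len(ids)}")
    rng = np.random.default_rng(seed)

    def _fold_from_test(test_ids):
        rest = [i for i in ids if i not in set(test_ids)]
        rest = [rest[j] for j in rng.permutation(len(rest))]
        return {"train": sorted(rest[:n_train]),
                "val": sorted(rest[n_train:n_train + n_val]),
                "test": sorted(test_ids)}

    if n_folds * n_test == len(ids):
        perm = [ids[j] for j in rng.permutation(len(ids))]
        folds = [_fold_from_test(perm[f * n_test:(f + 1) * n_test])
                 for f in range(n_folds)]
        return FoldPlan(folds, n_folds, tuple(split), seed)

    for _ in range(max_attempts):
        folds = []
        for _f in range(n_folds):
            perm = [ids[j] for j in rng.permutation(len(ids))]
            folds.append({"train": sorted(perm[:n_train]),
                          "val": sorted(perm[n_train:n_train + n_val]),
                          "test": sorted(perm[n_train + n_val:])})
        covered = set().union(*(f["test"] for f in folds))
        if covered == set(ids):
            return FoldPlan(folds, n_folds, tuple(split), seed)
    raise RuntimeError("could not cover all ids in test sets within the "
                       "attempt budget")


def _region_masks(labels, boundaries, voxel_y):
    yield "total", np.ones_like(voxel_y, dtype=bool)
    yield "frontal", voxel_y >= boundaries.central_plane
    yield "parietal", ((voxel_y < boundaries.central_plane)
                       & (voxel_y >= boundaries.parieto_occipital_plane))
    yield "occipital", voxel_y < boundaries.parieto_occipital_plane


def evaluate_cohort(preds: dict, truths: dict, boundaries=None,
                    sources: dict | None = None,
                    structures: dict | None = None) -> pd.DataFrame:
    """Cohort-level segmentation scores per structure x region (x source).

    ``preds``/``truths`` map subject id -> LabelMap on a common grid per
    subject; ``structures`` maps structure name -> label code (defaults
    to lumen/PSD/AG plus the peri-sinus union).  Regions with neither
    truth nor predicted voxels in any subject are dropped from the table
    (they carry no information), mirroring how an all-empty region is
    excluded from reporting rather than scored.

    Returns a tidy frame with mean/sd DSC, recall, precision, plus
    volume RMS and Pearson r across subjects.
    """
    if set(preds) != set(truths):
        raise ValueError("preds and truths must cover the same subjects")
    if structures is None:
        structures = {"peri_sinus": None, "lumen": 1, "psd": 2, "ag": 3}
    subject_groups = {"all": sorted(preds)}
    if sources is not None:
        for sid, src in sources.items():
            subject_groups.setdefault(src, []).append(sid)

    rows = []
    for group, sids in subject_groups.items():
        for sname, code in structures.items():
            region_names = (["total"] if boundaries is None
                            else ["total", "frontal", "parietal", "occipital"])
            for region in region_names:
                per_subj = []
                vols_p, vols_t = [], []
                vv0 = None
                for sid in sids:
                    p_lab, t_lab = preds[sid], truths[sid]
                    p = np.asarray(p_lab.data)
                    t = np.asarray(t_lab.data)
                    pm = (p > 0) if code is None else (p == code)
                    tm = (t > 0) if code is None else (t == code)
                    if region != "total":
                        _, wy, _ = t_lab.world_coords()
                        rm = dict(_region_masks(t_lab, boundaries, wy))[region]
                        pm, tm = pm & rm, tm & rm
                    vv0 = float(np.prod(t_lab.spacing))
                    per_subj.append((dsc(pm, tm), recall(pm, tm), precision(pm, tm)))
                    vols_p.append(pm.sum() * vv0)
                    vols_t.append(tm.sum() * vv0)
                if not per_subj:
                    continue
                if sum(vols_p) == 0 and sum(vols_t) == 0:
                    continue   # empty region: excluded, not scored
                arr = np.asarray(per_subj)
                if len(vols_p) >= 3 and np.std(vols_p) > 0 and np.std(vols_t) > 0:
                    rms, r, pv = volume_agreement(vols_p, vols_t)
                else:
                    rms = float(np.sqrt(np.mean((np.array(vols_p)
                                                 - np.array(vols_t)) ** 2)))
                    r, pv = np.nan, np.nan
                rows.append({
                    "group": group, "structure": sname, "region": region,
                    "n": len(per_subj),
                    "dsc_mean": arr[:, 0].mean(), "dsc_sd": arr[:, 0].std(),
                    "recall_mean": arr[:, 1].mean(), "recall_sd": arr[:, 1].std(),
                    "precision_mean": arr[:, 2].mean(),
                    "precision_sd": arr[:, 2].std(),
                    "volume_rms_mm3": rms, "pearson_r": r, "pearson_p": pv,
                })
    return pd.DataFrame(rows)
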