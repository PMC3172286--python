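"""Short time-series clustering by predefined model temporal profiles.

The clustering follows the model-profile approach for short expression
time courses: enumerate all integer "unit-change" trajectories (start at
0, move by at most c units between consecutive timepoints), select a
small, maximally distinct subset of m model profiles, assign every gene
to its closest profile under d = 1 - Pearson r, and score each profile
by how many genes it attracts beyond the count expected under random
timepoint orderings (binomial upper tail, Bonferroni over profiles).

With T=5 timepoints the null is exact: the 4 post-baseline timepoints
admit 4! = 24 orderings, all enumerated; no Monte-Carlo noise enters.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

__all__ = [
    "ModelProfile",
    "ModelProfileSet",
    "ClusterResult",
    "enumerate_candidate_profiles",
    "select_model_profiles",
    "to_logratio_trajectory",
    "trajectories",
    "assign_genes",
    "profile_significance",
    "UNASSIGNED",
]

log = logging.getLogger(__name__)

UNASSIGNED = -1  # reserved bucket for zero-variance trajectories


@dataclass(frozen=True)
class ModelProfile:
    """An integer unit-change trajectory; steps[0] == 0."""

    profile_id: int
    steps: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.steps[0] != 0:
            raise ValueError("model profile must start at 0")


@dataclass
class ModelProfileSet:
    profiles: list[ModelProfile]
    max_unit_change: int

    def __len__(self) -> int:
        return len(self.profiles)

    def steps_matrix(self) -> np.ndarray:
        return np.array([p.steps for p in self.profiles], dtype=float)

    def ids(self) -> list[int]:
        return [p.profile_id for p in self.profiles]

    def by_id(self, profile_id: int) -> ModelProfile:
        for p in self.profiles:
            if p.profile_id == profile_id:
                return p
        raise KeyError(profile_id)


def enumerate_candidate_profiles(n_timepoints: int, max_unit_change: int) -> list[ModelProfile]:
    """All step sequences of length T starting at 0 with per-step change
    in {-c, ..., +c}, excluding the all-zero profile.

    Count is (2c+1)^(T-1) - 1; enumeration order (and the assigned ids)
    is lexicographic in the step vector.
    """
    if n_timepoints < 2:
        raise ValueError("need >= 2 timepoints")
    if max_unit_change < 1:
        raise ValueError("max unit change must be >= 1")
    c = max_unit_change
    out: list[ModelProfile] = []
    idx = 0
    for diffs in itertools.product(range(-c, c + 1), repeat=n_timepoints - 1):
        if all(d == 0 for d in diffs):
            continue
        steps = (0, *itertools.accumulate(diffs))
        out.append(ModelProfile(idx, tuple(steps)))
        idx += 1
    return out


def _row_zscores(x: np.ndarray) -> np.ndarray:
    """Rows standardized so that Z @ Z.T gives Pearson r; zero-variance
    rows come back as all-NaN."""
    x = np.asarray(x, dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return centered / norms


def select_model_profiles(
    candidates: list[ModelProfile], m: int, seed: int = 0
) -> ModelProfileSet:
    """Greedy max-min selection of m mutually distinct profiles.

    Distance is d = 1 - Pearson r between step vectors. Selection starts
    from the lexicographically smallest candidate and repeatedly adds the
    candidate whose minimum distance to the chosen set is largest, ties
    broken lexicographically. The result is deterministic; ``seed`` is
    accepted for interface uniformity. Returned ids are 0..m-1 in
    lexicographic step order.
    """
    if m > len(candidates):
        raise ValueError(f"asked for {m} profiles but only {len(candidates)} candidates")
    order = sorted(range(len(candidates)), key=lambda i: candidates[i].steps)
    steps = np.array([candidates[i].steps for i in order], dtype=float)
    z = _row_zscores(steps)
    # candidates exclude the all-zero profile, so no row is constant
    dist = 1.0 - np.round(z @ z.T, 12)

    chosen = [0]  # lexicographically smallest
    min_dist = dist[0].copy()
    while len(chosen) < m:
        min_dist[chosen] = -np.inf
        best = int(np.argmax(min_dist))  # argmax takes the first (lex smallest) tie
        chosen.append(best)
        min_dist = np.minimum(min_dist, dist[best])
    chosen.sort()
    c = max(int(np.abs(np.diff(steps[chosen], axis=1)).max()), 1)
    profiles = [
        ModelProfile(new_id, tuple(int(s) for s in steps[i]))
        for new_id, i in enumerate(chosen)
    ]
    return ModelProfileSet(profiles, max_unit_change=c)


def trajectories(matrix: ExpressionMatrix, genes: list[str] | None = None) -> pd.DataFrame:
    """Per-timepoint mean log2 intensity minus the baseline mean, for each
    gene: a genes x timepoints frame whose first (baseline) column is 0."""
    genes = matrix.genes if genes is None else [g for g in genes if g in matrix.values.index]
    log2 = matrix.log2().loc[genes]
    tps = matrix.timepoints
    if 0 not in tps:
        raise ValueError("matrix has no baseline (timepoint 0) samples")
    means = pd.DataFrame(
        {tp: log2[matrix.samples_at(tp)].mean(axis=1) for tp in tps}
    )
    traj = means.sub(means[0], axis=0)
    traj.columns = tps
    return traj


def to_logratio_trajectory(matrix: ExpressionMatrix, gene: str) -> np.ndarray:
    return trajectories(matrix, [gene]).loc[gene].to_numpy()


def assign_genes(traj: pd.DataFrame, profile_set: ModelProfileSet) -> pd.Series:
    """Assign each gene to the profile minimizing d = 1 - r.

    Ties go to the lowest profile id; zero-variance trajectories land in
    the reserved UNASSIGNED (-1) bucket.
    """
    z_genes = _row_zscores(traj.to_numpy())
    z_prof = _row_zscores(profile_set.steps_matrix())
    constant = np.isnan(z_genes).all(axis=1)
    r = np.round(np.nan_to_num(z_genes) @ z_prof.T, 12)
    ids = np.asarray(profile_set.ids())
    best = ids[np.argmax(r, axis=1)]  # profiles ordered by id: first max = lowest id
    best[constant] = UNASSIGNED
    if constant.any():
        log.info("%d constant trajectory(ies) left unassigned", int(constant.sum()))
    return pd.Series(best, index=traj.index, name="profile_id")


@dataclass
class ClusterResult:
    """Per-profile gene counts, expected counts and binomial p-values."""

    table: pd.DataFrame  # profile_id, steps, n_observed, n_expected, p_value, significant
    assignment: pd.Series
    alpha: float
    n_permutations: int

    def assigned_genes(self, profile_id: int) -> list[str]:
        return list(self.assignment.index[self.assignment == profile_id])

    def significant_profiles(self) -> list[int]:
        return list(self.table.loc[self.table["significant"], "profile_id"])

    def clustered_genes(self) -> list[str]:
        keep = set(self.significant_profiles())
        return [g for g, pid in self.assignment.items() if pid in keep]

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def profile_significance(
    assignment: pd.Series,
    traj: pd.DataFrame,
    profile_set: ModelProfileSet,
    alpha: float = 0.001,
    max_permutations: int = 240,
    seed: int = 0,
) -> ClusterResult:
    """Score each profile by its observed gene count against the count
    expected under permuted timepoint orderings.

    The baseline column stays fixed; the post-baseline columns are
    permuted (exhaustively when (T-1)! <= max_permutations, otherwise
    a seeded random sample that always includes the identity). The
    expected per-profile fraction over permutations feeds an upper-tail
    binomial p at the observed count; profiles never hit by observation
    (count 0) get p = 1. Significance is Bonferroni-corrected over the
    m profiles.
    """
    n_genes = len(assignment)
    n_tp = traj.shape[1]
    post = list(range(1, n_tp))
    n_total_perm = int(np.prod(range(1, len(post) + 1)))
    if n_total_perm <= max_permutations:
        perms = [list(p) for p in itertools.permutations(post)]
    else:
        rng = np.random.default_rng(seed)
        perms = [post] + [list(rng.permutation(post)) for _ in range(max_permutations - 1)]

    ids = profile_set.ids()
    counts = np.zeros((len(perms), len(ids)), dtype=float)
    values = traj.to_numpy()
    id_to_col = {pid: j for j, pid in enumerate(ids)}
    for i, perm in enumerate(perms):
        permuted = values[:, [0] + perm]
        perm_assign = assign_genes(
            pd.DataFrame(permuted, index=traj.index, columns=traj.columns), profile_set
        )
        vc = perm_assign.value_counts()
        for pid, n in vc.items():
            if pid != UNASSIGNED:
                counts[i, id_to_col[pid]] = n

    expected_frac = counts.mean(axis=0) / max(n_genes, 1)
    observed = np.zeros(len(ids), dtype=int)
    for pid, n in assignment.value_counts().items():
        if pid != UNASSIGNED:
            observed[id_to_col[pid]] = n

    p = np.ones(len(ids), dtype=float)
    nonzero = observed > 0
    p[nonzero] = stats.binom.sf(observed[nonzero] - 1, n_genes, expected_frac[nonzero])
    significant = p < alpha / len(ids)

    table = pd.DataFrame(
        {
            "profile_id": ids,
            "steps": [",".join(map(str, profile_set.by_id(pid).steps)) for pid in ids],
            "n_observed": observed,
            "n_expected": n_genes * expected_frac,
            "p_value": p,
            "significant": significant,
        }
    )
    return ClusterResult(
        table=table, assignment=assignment, alpha=alpha, n_permutations=len(perms)
    )
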