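"""Association, centrality, dominance and kinship metrics for the troop.

The social structure of the study group enters the downstream count model
through three per-individual covariates:

* eigenvector centrality on the dyadic association index (DAI) network
  built from 1 m-proximity durations during focal sessions,
* dominance rank from David's Score on the aggression-submission record,
* the number of matrilineal relatives present in the group.

All three are computed here from plain observation records.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProximityRecord",
    "AgonisticBout",
    "DAIMatrix",
    "CentralityVector",
    "DominanceResult",
    "SocialMetricsError",
    "UnknownIndividualError",
    "dai_value",
    "compute_dai",
    "eigenvector_centrality",
    "davids_score",
    "count_relatives",
]


class SocialMetricsError(ValueError):
    """Invalid input to a social-metric computation."""


class UnknownIndividualError(SocialMetricsError):
    """A record references an id missing from the roster."""


@dataclass(frozen=True)
class ProximityRecord:
    """Time (s) a partner spent within 1 m of the focal during one session."""

    focal_id: str
    partner_id: str
    overlap_duration: float
    session_id: str
    session_duration: float

    def __post_init__(self) -> None:
        if self.focal_id == self.partner_id:
            raise SocialMetricsError("focal and partner must differ")
        if self.overlap_duration < 0:
            raise SocialMetricsError(
                f"negative overlap_duration for {self.focal_id}/{self.partner_id}"
            )
        if self.overlap_duration > self.session_duration:
            raise SocialMetricsError("overlap_duration exceeds session_duration")


@dataclass(frozen=True)
class AgonisticBout:
    """One decided aggression-submission bout; the actor is the winner."""

    actor_id: str
    receiver_id: str

    def __post_init__(self) -> None:
        if self.actor_id == self.receiver_id:
            raise SocialMetricsError("actor and receiver must differ")


@dataclass(frozen=True)
class DAIMatrix:
    """Symmetric association matrix in [0, 1] with a zero diagonal."""

    individuals: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        n = len(self.individuals)
        if v.shape != (n, n):
            raise SocialMetricsError("matrix shape must match the id list")
        if not np.allclose(v, v.T):
            raise SocialMetricsError("DAI matrix must be symmetric")
        if np.any(v < 0) or np.any(v > 1):
            raise SocialMetricsError("DAI values must lie in [0, 1]")
        if np.any(np.diag(v) != 0):
            raise SocialMetricsError("DAI diagonal must be zero")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "individuals", tuple(self.individuals))

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.individuals)
        return pd.DataFrame(self.values, index=ids, columns=ids)


@dataclass(frozen=True)
class CentralityVector:
    """Unit-norm leading-eigenvector scores, one per individual."""

    individuals: tuple[str, ...]
    scores: np.ndarray
    eigenvalue: float
    n_iterations: int

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=list(self.individuals), name="centrality")


@dataclass(frozen=True)
class DominanceResult:
    """David's Scores and the implied descending ranks (1 = highest)."""

    individuals: tuple[str, ...]
    ds: np.ndarray
    rank: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": list(self.individuals), "ds": self.ds, "rank": self.rank}
        )


def _roster_ids(roster: Iterable) -> list[str]:
    ids = []
    for entry in roster:
        ids.append(entry if isinstance(entry, str) else entry.id)
    if len(set(ids)) != len(ids):
        raise SocialMetricsError("roster ids must be unique")
    return ids


# -- dyadic association index ------------------------------------------------

def dai_value(d_ab: float, d_a: float, d_b: float) -> float:
    """DAI = D_ab / (D_a + D_b - D_ab), 0 when the denominator vanishes."""
    denom = d_a + d_b - d_ab
    if denom <= 0:
        return 0.0
    return min(1.0, max(0.0, d_ab / denom))


def compute_dai(records: Sequence[ProximityRecord], roster: Iterable) -> DAIMatrix:
    """Build the dyadic association matrix from focal proximity records.

    ``D_a``/``D_b`` are each individual's total focal sampling time.  A
    dyad's joint term ``D_ab`` sums the 1 m-overlap logged from either
    member's focal sessions; because a balanced focal rotation observes
    each dyad from both sides, the two directed sums estimate the same
    quantity and are averaged (halved), which keeps the index within
    [0, 1] and makes a constantly proximate pair score exactly 1.
    """
    ids = _roster_ids(roster)
    index = {ind: k for k, ind in enumerate(ids)}
    n = len(ids)
    overlap = np.zeros((n, n))
    focal_time: dict[tuple[str, str], float] = {}
    for rec in records:
        for ind in (rec.focal_id, rec.partner_id):
            if ind not in index:
                raise UnknownIndividualError(f"unknown individual id: {ind}")
        key = (rec.focal_id, rec.session_id)
        focal_time[key] = max(focal_time.get(key, 0.0), rec.session_duration)
        i, j = index[rec.focal_id], index[rec.partner_id]
        overlap[i, j] += rec.overlap_duration
        overlap[j, i] += rec.overlap_duration

    total_focal = np.zeros(n)
    for (focal, _), dur in focal_time.items():
        total_focal[index[focal]] += dur

    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d_ab = overlap[i, j] / 2.0
            values[i, j] = values[j, i] = dai_value(d_ab, total_focal[i], total_focal[j])
    return DAIMatrix(tuple(ids), values)


# -- eigenvector centrality --------------------------------------------------

def _components(adj: np.ndarray) -> list[list[int]]:
    n = adj.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            node = stack.pop()
            comp.append(node)
            for nbr in np.flatnonzero(adj[node]):
                if not seen[nbr]:
                    seen[nbr] = True
                    stack.append(int(nbr))
        comps.append(sorted(comp))
    return comps


def eigenvector_centrality(
    m: DAIMatrix,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> CentralityVector:
    """Leading-eigenvector scores of the association matrix.

    Power iteration from the uniform vector, run on the largest connected
    component of the weighted graph; individuals outside that component
    (including isolates) score 0.  The returned vector has unit Euclidean
    norm and satisfies the eigen-residual contract ``|A x - lambda x| <
    10 * tol`` in max-norm.
    """
    a = m.values
    if not np.any(a):
        raise SocialMetricsError("all-zero association matrix has no centrality")
    comps = _components(a > 0)
    # isolates form singleton components with zero weight; drop them before
    # choosing the largest component
    comps = [c for c in comps if len(c) > 1 or np.any(a[c[0]])]
    comp = max(comps, key=len)
    sub = a[np.ix_(comp, comp)]

    # a positive diagonal shift leaves the eigenvectors untouched but breaks
    # the +/- eigenvalue symmetry of bipartite graphs (e.g. stars), which
    # would otherwise make plain power iteration oscillate
    shift = 0.1 * float(np.max(sub.sum(axis=1)))
    shifted = sub + shift * np.eye(sub.shape[0])

    x = np.full(len(comp), 1.0 / np.sqrt(len(comp)))
    lam = 0.0
    last_step = np.inf
    for iteration in range(1, max_iter + 1):
        y = shifted @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            raise SocialMetricsError("power iteration collapsed to zero")
        y /= norm
        last_step = float(np.max(np.abs(y - x)))
        x = y
        if last_step < tol:
            lam = float(x @ sub @ x)
            break
    else:
        raise SocialMetricsError(
            f"power iteration did not converge in {max_iter} iterations "
            f"(last max-norm step {last_step:.3e})"
        )

    scores = np.zeros(len(m.individuals))
    scores[np.asarray(comp)] = x
    return CentralityVector(m.individuals, scores, lam, iteration)


# -- David's Score -----------------------------------------------------------

def davids_score(
    bouts: Sequence[AgonisticBout],
    roster: Iterable,
    correction: str = "pij",
) -> DominanceResult:
    """David's Score dominance index from decided dyadic bouts.

    With ``s_ij`` wins of i over j in ``n_ij`` bouts, the ``pij`` variant
    uses the raw win proportion ``P_ij = s_ij / n_ij`` (0 for unobserved
    dyads); the ``dij`` variant applies the chance correction
    ``P_ij - (P_ij - 0.5) / (n_ij + 1)``.  Then

        DS_i = w_i + w2_i - l_i - l2_i,

    with w the row sums of P, l the column sums, and w2/l2 the
    interaction-weighted second-order terms.  Ranks are descending in DS
    with ties broken by roster order.
    """
    if correction not in ("pij", "dij"):
        raise SocialMetricsError(f"unknown correction: {correction!r}")
    ids = _roster_ids(roster)
    if not ids:
        raise SocialMetricsError("roster must be nonempty")
    index = {ind: k for k, ind in enumerate(ids)}
    n = len(ids)
    wins = np.zeros((n, n))
    for bout in bouts:
        for ind in (bout.actor_id, bout.receiver_id):
            if ind not in index:
                raise UnknownIndividualError(f"unknown individual id: {ind}")
        wins[index[bout.actor_id], index[bout.receiver_id]] += 1

    n_ij = wins + wins.T
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_ij > 0, wins / np.where(n_ij > 0, n_ij, 1), 0.0)
    if correction == "dij":
        p = np.where(n_ij > 0, p - (p - 0.5) / (n_ij + 1), 0.0)
    np.fill_diagonal(p, 0.0)

    w = p.sum(axis=1)
    w2 = p @ w
    loss = p.sum(axis=0)
    l2 = p.T @ loss
    ds = w + w2 - loss - l2

    order = np.lexsort((np.arange(n), -ds))  # descending DS, roster-order ties
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    return DominanceResult(tuple(ids), ds, rank)


# -- kinship -----------------------------------------------------------------

def count_relatives(roster: Iterable) -> dict[str, int]:
    """Number of group members sharing each individual's matriline.

    Members of a matriline of size k each count k - 1 relatives;
    individuals without a matriline (immigrant males) count 0.
    """
    sizes: dict[str, int] = {}
    entries = list(roster)
    for ind in entries:
        if ind.matriline is not None:
            sizes[ind.matriline] = sizes.get(ind.matriline, 0) + 1
    return {
        ind.id: (sizes[ind.matriline] - 1 if ind.matriline is not None else 0)
        for ind in entries
    }


# -- CSV I/O -----------------------------------------------------------------

def read_proximity_csv(path: str | Path) -> list[ProximityRecord]:
    df = pd.read_csv(path)
    return [
        ProximityRecord(
            focal_id=str(row.focal_id),
            partner_id=str(row.partner_id),
            overlap_duration=float(row.overlap_duration_s),
            session_id=str(row.session_id),
            session_duration=float(row.session_duration_s),
        )
        for row in df.itertuples()
    ]


def read_agonistic_csv(path: str | Path) -> list[AgonisticBout]:
    df = pd.read_csv(path)
    return [
        AgonisticBout(actor_id=str(row.actor_id), receiver_id=str(row.receiver_id))
        for row in df.itertuples()
    ]


def write_social_outputs(
    out_dir: str | Path,
    dai: DAIMatrix,
    centrality: CentralityVector,
    dominance: DominanceResult,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dai.to_frame().to_csv(out / "dai_matrix.csv", index_label="id")
    centrality.to_series().rename_axis("id").reset_index().to_csv(
        out / "centrality.csv", index=False
    )
    dominance.to_frame().to_csv(out / "dominance.csv", index=False)
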