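"""Additive genetic relationship matrices from pedigrees or clutch assumptions.

The pedigree route is the tabular method: processing individuals with
parents before offspring,

    a_xy = (a_{x,sire(y)} + a_{x,dam(y)}) / 2        (x before y)
    a_xx = 1 + a_{sire(x),dam(x)} / 2

so self-fertilization (dam == sire) automatically produces inbreeding
(diagonal 1 + F). Because the field-collected clutches have unknown
paternity, assumption-based matrices treat each maternal family as a block
of maternal half-sibs (a = 0.25), outcrossed full sibs (a = 0.5), progeny
of one selfing parent (a = 1.0 off-diagonal, diagonal 1.5), or a
per-clutch random mixture of the three.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import Pedigree

__all__ = ["ASSUMPTIONS", "RelationshipMatrix", "build_relationship_matrix"]

ASSUMPTIONS = (
    "pedigree",
    "half_sib",
    "full_sib_outcrossed",
    "full_sib_selfed",
    "heterogeneous",
)

#: within-clutch additive relationship (off-diagonal, diagonal) per assumption
_CLUTCH_BLOCKS = {
    "half_sib": (0.25, 1.0),
    "full_sib_outcrossed": (0.5, 1.0),
    "full_sib_selfed": (1.0, 1.5),
}


@dataclass
class RelationshipMatrix:
    ids: list[str]
    A: np.ndarray = field(repr=False)
    assumption: str = "pedigree"

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.ids)
        if self.A.shape != (n, n):
            raise ValueError("A must be square and conformable with ids")
        if not np.allclose(self.A, self.A.T, atol=1e-10):
            raise ValueError("A must be symmetric")
        if np.any(np.diag(self.A) < 1.0 - 1e-10):
            raise ValueError("A diagonal must be >= 1 (1 + inbreeding coefficient)")
        if n and np.linalg.eigvalsh(self.A)[0] < -1e-8:
            raise ValueError("A must be positive semidefinite")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def inbreeding(self) -> np.ndarray:
        """Per-individual inbreeding coefficient F (diagonal minus one)."""
        return np.diag(self.A) - 1.0

    def subset(self, ids: Sequence[str]) -> "RelationshipMatrix":
        idx = [self.ids.index(i) for i in ids]
        return RelationshipMatrix(list(ids), self.A[np.ix_(idx, idx)], self.assumption)


def _tabular_from_frame(ped: pd.DataFrame) -> np.ndarray:
    ids = list(ped["id"])
    pos = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    dam_idx = np.full(n, -1, dtype=int)
    sire_idx = np.full(n, -1, dtype=int)
    for i, (_, row) in enumerate(ped.iterrows()):
        for col, arr in (("dam", dam_idx), ("sire", sire_idx)):
            parent = row[col]
            if parent is None or parent == "" or (isinstance(parent, float) and np.isnan(parent)):
                continue
            j = pos.get(parent)
            if j is None or j >= i:
                raise ValueError(
                    f"pedigree is cyclic or unordered: parent {parent!r} of "
                    f"{row['id']!r} does not precede it"
                )
            arr[i] = j
    A = np.zeros((n, n))
    for i in range(n):
        d, s = dam_idx[i], sire_idx[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if d >= 0 and s >= 0 else 0.0)
        for j in range(i):
            a = 0.0
            if d >= 0:
                a += 0.5 * A[j, d]
            if s >= 0:
                a += 0.5 * A[j, s]
            A[i, j] = A[j, i] = a
    return A


def build_relationship_matrix(
    pedigree: Pedigree | pd.DataFrame,
    assumption: str = "pedigree",
    families: Mapping[str, str] | None = None,
    heterogeneous_proportions: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
) -> RelationshipMatrix:
    """Build the additive relationship matrix A.

    With ``assumption="pedigree"`` the tabular method is applied to the
    dam/sire links. The clutch-relatedness assumptions ignore the links and
    instead fill within-family blocks: ``half_sib`` (0.25),
    ``full_sib_outcrossed`` (0.5), ``full_sib_selfed`` (progeny of one
    selfing non-inbred parent: off-diagonal 1.0, diagonal 1.5), or
    ``heterogeneous`` (each clutch assigned one of the three at random with
    the given proportions, seeded). Family membership comes from the
    :class:`Pedigree` individuals or an explicit ``families`` mapping.
    """
    if assumption not in ASSUMPTIONS:
        raise ValueError(f"assumption must be one of {ASSUMPTIONS}, got {assumption!r}")

    if isinstance(pedigree, Pedigree):
        ids = pedigree.ids
        fam_map = families or {ind.id: ind.family for ind in pedigree.individuals}
        frame = pedigree.to_frame()
    else:
        frame = pedigree
        ids = list(frame["id"])
        if assumption != "pedigree" and families is None:
            if "family" not in frame.columns:
                raise ValueError("assumption-based A needs family membership")
            fam_map = dict(zip(frame["id"], frame["family"]))
        else:
            fam_map = dict(families or {})

    if assumption == "pedigree":
        return RelationshipMatrix(ids, _tabular_from_frame(frame), assumption)

    n = len(ids)
    A = np.eye(n)
    fams = pd.Series([fam_map[i] for i in ids], dtype=object)
    rng = np.random.default_rng(seed)
    props = np.asarray(heterogeneous_proportions, float)
    if assumption == "heterogeneous":
        if props.shape != (3,) or not np.isclose(props.sum(), 1.0):
            raise ValueError("heterogeneous_proportions must be 3 values summing to 1")
    kinds = list(_CLUTCH_BLOCKS)
    for fam in fams.unique():
        idx = np.flatnonzero(fams.to_numpy() == fam)
        kind = assumption
        if assumption == "heterogeneous":
            kind = kinds[rng.choice(3, p=props)]
        off, diag = _CLUTCH_BLOCKS[kind]
        block = np.full((idx.size, idx.size), off)
        np.fill_diagonal(block, diag)
        A[np.ix_(idx, idx)] = block
    return RelationshipMatrix(ids, A, assumption)
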