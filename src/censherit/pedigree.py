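"""Pedigree handling and the additive (numerator) relationship matrix.

The additive relationship matrix ``A`` holds expected additive-genetic
relationships between all pedigree members; its diagonal is ``1 + F`` where
``F`` is the inbreeding coefficient.  ``A`` is built by the tabular method,
and its sparse inverse directly from Henderson's rules with the
Meuwissen–Luo inbreeding correction, so the inverse never requires a dense
factorization.

Identifiers are opaque strings; unknown parents are coded by the empty
string or ``"0"``.  Internally animals are mapped to dense 0-based indices
in topological (parents-before-offspring) order, and that mapping is carried
on every output object.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import PedigreeError

#: Sentinels accepted for an unknown parent.
UNKNOWN = ""
_UNKNOWN_TOKENS = {"", "0", "na", "nan", "none"}

#: Guard for dense materialization of A.
MAX_DENSE_ANIMALS = 5000


def _norm_id(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return UNKNOWN
    s = str(x).strip()
    return UNKNOWN if s.lower() in _UNKNOWN_TOKENS else s


@dataclass
class Pedigree:
    """An ordered pedigree of (animal, sire, dam) string triples."""

    animal: list[str]
    sire: list[str]
    dam: list[str]
    is_sorted: bool = False

    def __post_init__(self) -> None:
        self.animal = [_norm_id(a) for a in self.animal]
        self.sire = [_norm_id(s) for s in self.sire]
        self.dam = [_norm_id(d) for d in self.dam]
        if len(self.animal) != len(set(self.animal)):
            seen, dups = set(), set()
            for a in self.animal:
                (dups if a in seen else seen).add(a)
            raise PedigreeError(f"duplicate animal ids: {sorted(dups)[:5]}")
        if UNKNOWN in self.animal:
            raise PedigreeError("an animal id may not be the unknown-parent sentinel")
        known = set(self.animal)
        for parents in (self.sire, self.dam):
            for p in parents:
                if p != UNKNOWN and p not in known:
                    raise PedigreeError(f"parent id {p!r} never appears as an animal (missing ancestor)")

    def __len__(self) -> int:
        return len(self.animal)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        cols = {c.lower(): c for c in df.columns}
        missing = [c for c in ("animal", "sire", "dam") if c not in cols]
        if missing:
            raise PedigreeError(f"pedigree table lacks required columns {missing}")
        return cls(
            list(df[cols["animal"]]), list(df[cols["sire"]]), list(df[cols["dam"]])
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"animal": self.animal, "sire": self.sire, "dam": self.dam})

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire/dam indices into the current order (-1 = unknown). Requires sorted."""
        if not self.is_sorted:
            raise PedigreeError("pedigree must be sorted (parents before offspring); call sort_pedigree")
        pos = {a: i for i, a in enumerate(self.animal)}
        n = len(self)
        si = np.full(n, -1, dtype=np.int64)
        di = np.full(n, -1, dtype=np.int64)
        for i in range(n):
            if self.sire[i] != UNKNOWN:
                si[i] = pos[self.sire[i]]
            if self.dam[i] != UNKNOWN:
                di[i] = pos[self.dam[i]]
        return si, di


@dataclass
class RelationshipMatrix:
    """Dense numerator relationship matrix with inbreeding coefficients."""

    A: np.ndarray
    inbreeding: np.ndarray
    ids: list[str] = field(default_factory=list)

    def to_coordinate_frame(self) -> pd.DataFrame:
        """Upper-triangle coordinate format (i, j, value), 0-based indices."""
        iu, ju = np.triu_indices_from(self.A)
        vals = self.A[iu, ju]
        keep = vals != 0.0
        return pd.DataFrame({"i": iu[keep], "j": ju[keep], "value": vals[keep]})


def sort_pedigree(ped: Pedigree) -> Pedigree:
    """Topologically sort a pedigree so every parent precedes its offspring.

    Idempotent; raises :class:`PedigreeError` on cycles, naming an involved id.
    """
    graph = {}
    for a, s, d in zip(ped.animal, ped.sire, ped.dam):
        graph[a] = [p for p in (s, d) if p != UNKNOWN]
    ts = graphlib.TopologicalSorter(graph)
    try:
        order = list(ts.static_order())
    except graphlib.CycleError as exc:
        cycle = exc.args[1]
        raise PedigreeError(f"pedigree contains a cycle involving {cycle[0]!r}: {cycle}") from exc
    # static_order is parents-first but not stable; keep input order among ties
    rank = {a: i for i, a in enumerate(order)}
    idx = sorted(range(len(ped)), key=lambda i: rank[ped.animal[i]])
    return Pedigree(
        [ped.animal[i] for i in idx],
        [ped.sire[i] for i in idx],
        [ped.dam[i] for i in idx],
        is_sorted=True,
    )


def build_relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Dense A by the tabular method: a_ij = (a_{j,s_i} + a_{j,d_i})/2 for j<i,
    a_ii = 1 + a_{s_i,d_i}/2, with unknown parents contributing zero."""
    if not ped.is_sorted:
        raise PedigreeError("build_relationship_matrix requires a sorted pedigree")
    n = len(ped)
    if n > MAX_DENSE_ANIMALS:
        raise PedigreeError(
            f"refusing to materialize a dense A for {n} > {MAX_DENSE_ANIMALS} animals; "
            "use build_relationship_inverse instead"
        )
    si, di = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = si[i], di[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += A[s, :i]
            if d >= 0:
                row += A[d, :i]
            row *= 0.5
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(A=A, inbreeding=np.diag(A) - 1.0, ids=list(ped.animal))


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo algorithm (no dense A)."""
    if not ped.is_sorted:
        raise PedigreeError("inbreeding_coefficients requires a sorted pedigree")
    si, di = ped.parent_indices()
    n = len(ped)
    F = np.zeros(n)
    D = np.zeros(n)  # Mendelian sampling variance scale d_i
    for i in range(n):
        s, d = si[i], di[i]
        D[i] = 0.5 - 0.25 * ((F[s] if s >= 0 else -1.0) + (F[d] if d >= 0 else -1.0))
        if s < 0 or d < 0:
            continue  # founder-parented animal: F = 0
        # a_ii = sum over ancestors j of L_j^2 d_j, traced highest-index first
        contrib = {i: 1.0}
        aii = 0.0
        while contrib:
            j = max(contrib)
            r = contrib.pop(j)
            if si[j] >= 0:
                contrib[si[j]] = contrib.get(si[j], 0.0) + 0.5 * r
            if di[j] >= 0:
                contrib[di[j]] = contrib.get(di[j], 0.0) + 0.5 * r
            aii += r * r * D[j]
        F[i] = aii - 1.0
    return F


def build_relationship_inverse(ped: Pedigree) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding-corrected Mendelian
    sampling variances d_i (Meuwissen–Luo)."""
    if not ped.is_sorted:
        raise PedigreeError("build_relationship_inverse requires a sorted pedigree")
    si, di = ped.parent_indices()
    F = inbreeding_coefficients(ped)
    n = len(ped)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = si[i], di[i]
        fs = F[s] if s >= 0 else -1.0
        fd = F[d] if d >= 0 else -1.0
        dd = 0.5 - 0.25 * (fs + fd)  # founders: 0.5-0.25*(-2)=1
        alpha = 1.0 / dd
        add(i, i, alpha)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * alpha)
                add(p, i, -0.5 * alpha)
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    add(p, q, 0.25 * alpha)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
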