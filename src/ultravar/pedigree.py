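"""Pedigree handling for the animal model.

Reads animal/sire/dam (or animal/sire/maternal-grandsire) pedigrees,
assigns a topological order, computes inbreeding coefficients, and builds
the additive numerator relationship matrix ``A`` together with its sparse
inverse via Henderson's rules.  ``A`` is the covariance kernel of the
additive-genetic random effect in every model fitted by this package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Sentinel used in pedigree files for an unknown parent.
UNKNOWN = "0"


class PedigreeMode(str, enum.Enum):
    """How the second parent column is interpreted."""

    SIRE_DAM = "sire_dam"
    #: Sire / maternal grandsire coding: relationship weights 0.5 and 0.25,
    #: non-inbred convention on the diagonal (the maternal line is untracked).
    SIRE_MGS = "sire_mgs"


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate id, ...)."""


@dataclass
class Pedigree:
    """A topologically ordered pedigree.

    Attributes
    ----------
    animals : list of str
        Animal ids in topological order (every parent precedes its offspring).
    parent1, parent2 : list of str or None
        Sire and dam (or maternal grandsire) per animal; ``None`` = unknown.
    mode : PedigreeMode
    index : dict mapping animal id -> position in ``animals``
    """

    animals: list[str]
    parent1: list[str | None]
    parent2: list[str | None]
    mode: PedigreeMode = PedigreeMode.SIRE_DAM
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {a: i for i, a in enumerate(self.animals)}
        if len(self.index) != len(self.animals):
            dup = pd.Series(self.animals)
            dup = dup[dup.duplicated()].iloc[0]
            raise PedigreeError(f"duplicate animal id {dup!r}")
        # verify topological order
        for i, (s, d) in enumerate(zip(self.parent1, self.parent2)):
            for p in (s, d):
                if p is not None and self.index[p] >= i:
                    raise PedigreeError(
                        f"pedigree not topologically ordered: parent {p!r} "
                        f"does not precede offspring {self.animals[i]!r}"
                    )

    def __len__(self) -> int:
        return len(self.animals)

    @property
    def n(self) -> int:
        return len(self.animals)

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Parent positions as int arrays, -1 for unknown."""
        p1 = np.array(
            [self.index[p] if p is not None else -1 for p in self.parent1], dtype=int
        )
        p2 = np.array(
            [self.index[p] if p is not None else -1 for p in self.parent2], dtype=int
        )
        return p1, p2

    @classmethod
    def from_entries(
        cls,
        entries: list[tuple[str, str | None, str | None]],
        mode: PedigreeMode = PedigreeMode.SIRE_DAM,
    ) -> "Pedigree":
        """Build a pedigree from (animal, parent1, parent2) triples.

        Animals appearing only as parents are auto-inserted as founders.
        The order of the input is preserved where it is already topological
        (Kahn's algorithm with first-appearance tie-break), so writing and
        re-reading an ordered pedigree is stable.
        """
        seen: dict[str, int] = {}
        parents: dict[str, tuple[str | None, str | None]] = {}
        order_hint: dict[str, int] = {}
        k = 0
        for animal, s, d in entries:
            s = None if s in (None, "", UNKNOWN) else str(s)
            d = None if d in (None, "", UNKNOWN) else str(d)
            animal = str(animal)
            if animal in parents:
                raise PedigreeError(f"duplicate animal id {animal!r}")
            parents[animal] = (s, d)
            for a in (s, d, animal):
                if a is not None and a not in order_hint:
                    order_hint[a] = k
                    k += 1
        for a in list(order_hint):
            parents.setdefault(a, (None, None))  # parent-only ids become founders

        # Kahn topological sort, stable on first appearance
        children: dict[str, list[str]] = {a: [] for a in parents}
        indeg = {a: 0 for a in parents}
        for a, (s, d) in parents.items():
            for p in {p for p in (s, d) if p is not None}:
                children[p].append(a)
            indeg[a] = len({p for p in (s, d) if p is not None})
        ready = sorted((a for a in parents if indeg[a] == 0), key=order_hint.get)
        out: list[str] = []
        import heapq

        heap = [(order_hint[a], a) for a in ready]
        heapq.heapify(heap)
        while heap:
            _, a = heapq.heappop(heap)
            out.append(a)
            for c in children[a]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    heapq.heappush(heap, (order_hint[c], c))
        if len(out) != len(parents):
            cyclic = sorted(a for a in parents if a not in set(out))
            raise PedigreeError(f"pedigree contains a cycle involving {cyclic[0]!r}")
        return cls(
            animals=out,
            parent1=[parents[a][0] for a in out],
            parent2=[parents[a][1] for a in out],
            mode=mode,
        )

    def to_frame(self) -> pd.DataFrame:
        col2 = "dam" if self.mode is PedigreeMode.SIRE_DAM else "mgs"
        return pd.DataFrame(
            {
                "animal": self.animals,
                "sire": [p or UNKNOWN for p in self.parent1],
                col2: [p or UNKNOWN for p in self.parent2],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_pedigree(path, mode: PedigreeMode = PedigreeMode.SIRE_DAM) -> Pedigree:
    """Read a pedigree CSV (header ``animal,sire,dam`` or ``animal,sire,mgs``).

    "0" or an empty field denotes an unknown parent.  Raises
    :class:`PedigreeError` on duplicate ids or cycles.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    second = "dam" if mode is PedigreeMode.SIRE_DAM else "mgs"
    if second not in cols and ("dam" in cols or "mgs" in cols):
        second = "dam" if "dam" in cols else "mgs"
    entries = list(zip(df["animal"], df["sire"], df[second]))
    return Pedigree.from_entries(entries, mode=mode)


def inbreeding_coefficients(ped: Pedigree) -> dict[str, float]:
    """Inbreeding coefficients F_i = 0.5 * a(sire_i, dam_i).

    In sire–maternal-grandsire mode the maternal line is untracked, so all
    coefficients are zero by convention.
    """
    if ped.mode is PedigreeMode.SIRE_MGS:
        return {a: 0.0 for a in ped.animals}
    A = build_A(ped)
    p1, p2 = ped.parent_indices()
    F = np.zeros(ped.n)
    known = (p1 >= 0) & (p2 >= 0)
    F[known] = 0.5 * A[p1[known], p2[known]]
    return dict(zip(ped.animals, F))


def build_A(ped: Pedigree, include_inbreeding: bool = True) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular recurrence.

    Off-diagonals: SIRE_DAM a_ij = 0.5 (a_j,s + a_j,d); SIRE_MGS
    a_ij = 0.5 a_j,s + 0.25 a_j,mgs (j earlier than i).

    Diagonal: with inbreeding (SIRE_DAM), a_ii = 1 + 0.5 a_s,d.  Without
    inbreeding -- and always in SIRE_MGS mode, whose Mendelian-sampling
    variances use the non-inbred 11/16, 3/4, 15/16, 1 table -- the diagonal
    follows a_ii = d_i + k' A_pp k over the known-parent weights k, which is
    exactly the matrix Henderson's no-inbreeding rules invert (a_ii = 1 for
    animals whose parents are unrelated non-inbred).
    """
    n = ped.n
    p1, p2 = ped.parent_indices()
    A = np.zeros((n, n))
    mgs = ped.mode is PedigreeMode.SIRE_MGS
    w1, w2 = 0.5, (0.25 if mgs else 0.5)
    for i in range(n):
        s, d = p1[i], p2[i]
        row = np.zeros(i)
        if s >= 0:
            row += w1 * A[s, :i]
        if d >= 0:
            row += w2 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        if include_inbreeding and not mgs:
            A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
        else:
            di = _mendelian_variance(s >= 0, d >= 0, mgs)
            quad = 0.0
            if s >= 0:
                quad += w1 * w1 * A[s, s]
            if d >= 0:
                quad += w2 * w2 * A[d, d]
            if s >= 0 and d >= 0:
                quad += 2.0 * w1 * w2 * A[s, d]
            A[i, i] = di + quad
    return A


def _mendelian_variance(s_known: bool, d_known: bool, mgs: bool) -> float:
    """Non-inbred Mendelian-sampling variance d_i (units of sigma2_a)."""
    if mgs:
        if s_known and d_known:
            return 11.0 / 16.0
        if s_known:
            return 3.0 / 4.0
        if d_known:
            return 15.0 / 16.0
        return 1.0
    return 1.0 - 0.25 * s_known - 0.25 * d_known


def build_A_inverse(ped: Pedigree, include_inbreeding: bool = False) -> sp.csr_matrix:
    """Sparse inverse of A by Henderson's rules.

    Per animal i with Mendelian-sampling variance d_i and parent weights k
    (0.5/0.5 for sire/dam; 0.5/0.25 for sire/MGS), add the outer product of
    (1, -k_p, -k_q)/d_i over positions (i, p, q).  With
    ``include_inbreeding`` the d_i incorporate parental F (SIRE_DAM only);
    the default matches analyses that ignore inbreeding.
    """
    n = ped.n
    p1, p2 = ped.parent_indices()
    mgs = ped.mode is PedigreeMode.SIRE_MGS
    if include_inbreeding and not mgs:
        Fmap = inbreeding_coefficients(ped)
        F = np.array([Fmap[a] for a in ped.animals])
    else:
        F = np.zeros(n)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        s, d = p1[i], p2[i]
        if mgs:
            k1, k2 = 0.5, 0.25
            if s >= 0 and d >= 0:
                di = 11.0 / 16.0
            elif s >= 0:
                di = 3.0 / 4.0
            elif d >= 0:
                di = 15.0 / 16.0
            else:
                di = 1.0
        else:
            k1 = k2 = 0.5
            di = 1.0
            if s >= 0:
                di -= 0.25 * (1.0 + F[s])
            if d >= 0:
                di -= 0.25 * (1.0 + F[d])
        coeff = [(i, 1.0)]
        if s >= 0:
            coeff.append((s, -k1))
        if d >= 0:
            coeff.append((d, -k2))
        alpha = 1.0 / di
        for a, ka in coeff:
            for b, kb in coeff:
                rows.append(a)
                cols.append(b)
                vals.append(alpha * ka * kb)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def write_ainv_triplets(Ainv: sp.spmatrix, path) -> None:
    """Export a sparse A-inverse as 0-based (i, j, value) triplets, lower triangle."""
    coo = sp.tril(Ainv).tocoo()
    df = pd.DataFrame({"i": coo.row, "j": coo.col, "value": coo.data})
    df.sort_values(["i", "j"]).to_csv(path, index=False)
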