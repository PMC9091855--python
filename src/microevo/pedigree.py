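"""Pedigree container, validation, and numerator-relationship-matrix machinery.

A pedigree here is the backbone of every pedigree-based computation in the
package: the animal model's additive relationship structure, gene-dropping of
haplotypes, and midparent breeding-value dropping.  Validation enforces the
structural invariants those computations rely on (acyclicity, sex-consistent
parents, parents born strictly before offspring, unique ids).
"""
from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

UNKNOWN = "0"
REQUIRED_COLUMNS = ("id", "sire", "dam", "sex", "birth_year")


class PedigreeError(ValueError):
    """Structural or validation error in a pedigree."""


def _normalise_parent(col: pd.Series) -> pd.Series:
    col = col.astype("string").str.strip()
    col = col.fillna(UNKNOWN)
    col = col.replace({"": UNKNOWN, "NA": UNKNOWN, "nan": UNKNOWN, "None": UNKNOWN})
    return col.astype(str)


class Pedigree:
    """Validated pedigree over string ids.

    Parameters
    ----------
    df : DataFrame with columns id, sire, dam, sex ('M'/'F'), birth_year
        (integer).  Unknown parents are encoded as "0", empty or NA.  An
        optional ``death_year`` column (last calendar year alive) is carried
        through if present.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise PedigreeError(f"pedigree table missing columns: {missing}")
        df = df.copy()
        df["id"] = df["id"].astype(str).str.strip()
        df["sire"] = _normalise_parent(df["sire"])
        df["dam"] = _normalise_parent(df["dam"])
        df["sex"] = df["sex"].astype(str).str.strip().str.upper().str[:1]
        df["birth_year"] = df["birth_year"].astype(int)
        if "death_year" in df.columns:
            df["death_year"] = df["death_year"].astype(int)

        if (df["id"] == UNKNOWN).any() or (df["id"] == "").any():
            raise PedigreeError("individual id may not be '0' or empty")
        dup = df["id"][df["id"].duplicated()]
        if len(dup):
            raise PedigreeError(f"duplicate ids in pedigree: {sorted(set(dup))[:5]}")
        bad_sex = df.loc[~df["sex"].isin(("M", "F")), "id"]
        if len(bad_sex):
            raise PedigreeError(f"sex must be M or F; offending ids: {list(bad_sex[:5])}")

        index = {i: k for k, i in enumerate(df["id"])}
        for col in ("sire", "dam"):
            known = df[col] != UNKNOWN
            orphan = known & ~df[col].isin(index)
            if orphan.any():
                n = int(orphan.sum())
                logger.warning(
                    "%d %s ids not present in the pedigree table; treated as unknown", n, col
                )
                df.loc[orphan, col] = UNKNOWN

        self.df = df.reset_index(drop=True)
        self._index = index
        self.ids = self.df["id"].to_numpy()
        self.sex = self.df["sex"].to_numpy()
        self.birth_year = self.df["birth_year"].to_numpy()
        self.sire_idx = np.array(
            [index.get(s, -1) if s != UNKNOWN else -1 for s in self.df["sire"]], dtype=np.int64
        )
        self.dam_idx = np.array(
            [index.get(d, -1) if d != UNKNOWN else -1 for d in self.df["dam"]], dtype=np.int64
        )
        self._check_cycles()
        self._check_parent_sex()
        self._check_birth_order()

    # -- validation -----------------------------------------------------
    def _check_cycles(self) -> None:
        """Kahn's algorithm on parent->offspring edges; leftovers lie on a cycle."""
        n = len(self.ids)
        indeg = np.zeros(n, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            for p in (self.sire_idx[i], self.dam_idx[i]):
                if p >= 0:
                    children[p].append(i)
                    indeg[i] += 1
        queue = [i for i in range(n) if indeg[i] == 0]
        seen = 0
        while queue:
            i = queue.pop()
            seen += 1
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if seen != n:
            on_cycle = self.ids[indeg > 0]
            raise PedigreeError(
                f"pedigree contains a cycle; individual '{on_cycle[0]}' is its own ancestor"
            )

    def _check_parent_sex(self) -> None:
        sires = self.sire_idx[self.sire_idx >= 0]
        dams = self.dam_idx[self.dam_idx >= 0]
        bad_sire = sires[self.sex[sires] != "M"]
        if len(bad_sire):
            raise PedigreeError(f"sire '{self.ids[bad_sire[0]]}' is not male")
        bad_dam = dams[self.sex[dams] != "F"]
        if len(bad_dam):
            raise PedigreeError(f"dam '{self.ids[bad_dam[0]]}' is not female")

    def _check_birth_order(self) -> None:
        for name, pidx in (("sire", self.sire_idx), ("dam", self.dam_idx)):
            known = pidx >= 0
            bad = known & (self.birth_year[pidx] >= self.birth_year)
            if bad.any():
                i = int(np.nonzero(bad)[0][0])
                raise PedigreeError(
                    f"{name} of '{self.ids[i]}' born {self.birth_year[pidx[i]]}, "
                    f"not strictly before offspring ({self.birth_year[i]})"
                )

    # -- basic API ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        try:
            return np.array([self._index[i] for i in np.asarray(ids, dtype=str)], dtype=np.int64)
        except KeyError as e:
            raise PedigreeError(f"id not in pedigree: {e.args[0]}") from None

    @property
    def topological_order(self) -> np.ndarray:
        """Indices sorted so parents always precede offspring (by birth year)."""
        return np.argsort(self.birth_year, kind="stable")

    @property
    def is_founder(self) -> np.ndarray:
        """Both parents unknown."""
        return (self.sire_idx < 0) & (self.dam_idx < 0)

    @property
    def death_year(self) -> np.ndarray | None:
        if "death_year" in self.df.columns:
            return self.df["death_year"].to_numpy()
        return None

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    """Read a headered CSV/TSV pedigree table and validate it."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.empty:
        raise PedigreeError(f"empty pedigree file: {path}")
    df.columns = [c.strip().lower() for c in df.columns]
    return Pedigree(df)


# ---------------------------------------------------------------------------
# Relationship matrices
# ---------------------------------------------------------------------------

@dataclass
class AInverse:
    """Sparse inverse of the numerator relationship matrix A.

    ``matrix`` is ordered like ``ids`` (pedigree order); ``inbreeding`` holds
    the inbreeding coefficient F of every individual.
    """

    ids: np.ndarray
    matrix: sparse.csr_matrix
    inbreeding: np.ndarray


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients without forming dense A.

    Uses the L·D·L' decomposition of A: the diagonal a_ii = sum_j L_ij^2 D_j
    is accumulated by tracing gametic contributions of i back through its
    ancestry, where D_j is the Mendelian-sampling variance of j.  F_i is then
    a_ii - 1.  Cost is O(n * ancestry size), no dense matrix.
    """
    order = ped.topological_order
    n = ped.n
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    F = np.zeros(n)
    D = np.ones(n)
    L = np.zeros(n)
    for i in order:
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s >= 0 and d >= 0:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            D[i] = 0.75 - 0.25 * F[max(s, d)]
        else:
            D[i] = 1.0
            F[i] = 0.0
            continue
        # trace L_i. back through the ancestry, highest rank first so every
        # node is finalised before its own contribution is propagated
        touched = [i]
        L[i] = 1.0
        heap = [(-rank[i], i)]
        queued = {i}
        while heap:
            _, j = heapq.heappop(heap)
            queued.discard(j)
            for p in (ped.sire_idx[j], ped.dam_idx[j]):
                if p >= 0:
                    if L[p] == 0.0:
                        touched.append(p)
                    if p not in queued:
                        heapq.heappush(heap, (-rank[p], p))
                        queued.add(p)
                    L[p] += 0.5 * L[j]
        a_ii = 0.0
        for j in touched:
            a_ii += L[j] * L[j] * D[j]
            L[j] = 0.0
        F[i] = a_ii - 1.0
    return F


def a_matrix(ped: Pedigree) -> np.ndarray:
    """Dense A by the tabular method, in pedigree order.

    Quadratic in pedigree size; intended for small pedigrees and as the
    independent oracle for :func:`a_inverse`.
    """
    n = ped.n
    order = ped.topological_order
    A = np.zeros((n, n))
    for i in order:
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        row = np.zeros(n)
        if s >= 0:
            row += 0.5 * A[s]
        if d >= 0:
            row += 0.5 * A[d]
        row[i] = 0.0
        A[i, :] = np.where(np.arange(n) == i, A[i, i], row)
        A[:, i] = A[i, :]
    return A


def a_inverse(ped: Pedigree) -> AInverse:
    """Sparse A^-1 by Henderson's rules with inbreeding (Quaas adjustment)."""
    F = inbreeding_coefficients(ped)
    n = ped.n
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s >= 0 and d >= 0:
            mend = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            mend = 0.75 - 0.25 * F[max(s, d)]
        else:
            mend = 1.0
        alpha = 1.0 / mend
        add(i, i, alpha)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * alpha)
                add(p, i, -0.5 * alpha)
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    add(p, q, 0.25 * alpha)
    M = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return AInverse(ids=ped.ids.copy(), matrix=M, inbreeding=F)
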