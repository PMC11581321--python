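"""Pedigree container.

A pedigree is an ordered list of animal records (animal, sire, dam, sex,
generation) kept in topological order: every named parent occurs earlier in
the list than its offspring. Unknown parents are ``None`` internally and
coded ``0`` (or ``UNKNOWN``) on disk.
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import IntegrityError

UNKNOWN = None
_UNKNOWN_CODES = {"", "0", "UNKNOWN", "NA", ".", "none", "None"}


@dataclass(frozen=True)
class PedigreeRecord:
    animal_id: str
    sire_id: Optional[str]
    dam_id: Optional[str]
    sex: str  # 'M' or 'F'
    generation: int


@dataclass
class Pedigree:
    """Acyclic parent map over animal identifiers, topologically ordered."""

    records: list[PedigreeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {r.animal_id: i for i, r in enumerate(self.records)}
        if len(self._index) != len(self.records):
            raise IntegrityError("duplicate animal identifiers in pedigree")
        sexes = {r.animal_id: r.sex for r in self.records}
        for i, r in enumerate(self.records):
            for pid, want in ((r.sire_id, "M"), (r.dam_id, "F")):
                if pid is None:
                    continue
                j = self._index.get(pid)
                if j is None:
                    raise IntegrityError(
                        f"animal {r.animal_id!r} references unknown parent {pid!r}"
                    )
                if j >= i:
                    raise IntegrityError(
                        f"parent {pid!r} listed after offspring {r.animal_id!r};"
                        " pedigree is not topologically ordered"
                    )
                if sexes[pid] != want:
                    role = "sire" if want == "M" else "dam"
                    raise IntegrityError(
                        f"{role} {pid!r} of {r.animal_id!r} has sex {sexes[pid]!r}"
                    )

    # -- construction -----------------------------------------------------

    @classmethod
    def from_tuples(
        cls,
        rows: Iterable[tuple],
        *,
        sort: bool = True,
    ) -> "Pedigree":
        """Build from (animal, sire, dam, sex[, generation]) tuples.

        Parent codes in ``_UNKNOWN_CODES`` become unknown. With ``sort=True``
        rows may arrive in any order; a topological sort is applied and a
        cycle raises :class:`IntegrityError`.
        """
        raw = []
        for row in rows:
            animal, sire, dam, sex = (str(x) if x is not None else None for x in row[:4])
            gen = int(row[4]) if len(row) > 4 and row[4] is not None else None
            sire = None if sire in _UNKNOWN_CODES or sire is None else sire
            dam = None if dam in _UNKNOWN_CODES or dam is None else dam
            raw.append((animal, sire, dam, sex, gen))
        order = {a: i for i, (a, *_rest) in enumerate(raw)}
        if len(order) != len(raw):
            raise IntegrityError("duplicate animal identifiers in pedigree input")
        if sort:
            for a, s, d, _, _ in raw:
                for p in (s, d):
                    if p is not None and p not in order:
                        raise IntegrityError(f"parent {p!r} has no animal record")
            # stable Kahn sort: among ready animals, keep input order, so an
            # already-ordered pedigree round-trips unchanged
            children: dict[str, list[str]] = {a: [] for a in order}
            indegree = {}
            for a, s, d, _, _ in raw:
                parents = {p for p in (s, d) if p is not None}
                indegree[a] = len(parents)
                for p in parents:
                    children[p].append(a)
            ready = [i for i, (a, *_r) in enumerate(raw) if indegree[a] == 0]
            heapq.heapify(ready)
            placed: list[tuple] = []
            while ready:
                i = heapq.heappop(ready)
                placed.append(raw[i])
                for c in children[raw[i][0]]:
                    indegree[c] -= 1
                    if indegree[c] == 0:
                        heapq.heappush(ready, order[c])
            if len(placed) != len(raw):
                cyclic = sorted(a for a, deg in indegree.items() if deg > 0)
                raise IntegrityError(f"pedigree contains a cycle involving {cyclic}")
            raw = placed
        gens: dict[str, int] = {}
        records = []
        for animal, sire, dam, sex, gen in raw:
            if gen is None:
                pg = [gens[p] for p in (sire, dam) if p is not None]
                gen = 1 + max(pg) if pg else 0
            gens[animal] = gen
            records.append(PedigreeRecord(animal, sire, dam, sex, gen))
        return cls(records)

    # -- accessors --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.animal_id for r in self.records]

    def index_of(self, animal_id: str) -> int:
        return self._index[animal_id]

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire/dam positional indices in topological order; -1 = unknown."""
        sire = np.full(len(self.records), -1, dtype=np.int64)
        dam = np.full(len(self.records), -1, dtype=np.int64)
        for i, r in enumerate(self.records):
            if r.sire_id is not None:
                sire[i] = self._index[r.sire_id]
            if r.dam_id is not None:
                dam[i] = self._index[r.dam_id]
        return sire, dam

    def founders(self) -> list[str]:
        return [r.animal_id for r in self.records if r.sire_id is None and r.dam_id is None]

    def subset_generations(self, max_generation: int) -> "Pedigree":
        return Pedigree([r for r in self.records if r.generation <= max_generation])


def mendelian_sampling_variances(pedigree: Pedigree, F: Sequence[float]) -> np.ndarray:
    """Within-family (Mendelian-sampling) variance coefficients d_i.

    d_i = 1 for both parents unknown, 0.75 - F_p/4 for one known parent,
    0.5 - (F_s + F_d)/4 for both known; these scale the additive variance of
    the deviation from the parent average and are the diagonal of D in the
    A = TDT' decomposition.
    """
    sire, dam = pedigree.parent_indices()
    F = np.asarray(F, dtype=float)
    d = np.ones(len(pedigree))
    both = (sire >= 0) & (dam >= 0)
    d[both] = 0.5 - 0.25 * (F[sire[both]] + F[dam[both]])
    one_s = (sire >= 0) & (dam < 0)
    d[one_s] = 0.75 - 0.25 * F[sire[one_s]]
    one_d = (sire < 0) & (dam >= 0)
    d[one_d] = 0.75 - 0.25 * F[dam[one_d]]
    return d


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen-Luo traversal.

    For each animal the diagonal of A is accumulated as sum(L_j^2 d_j) over
    its ancestor paths, where d_j are the Mendelian-sampling variances;
    F_i = a_ii - 1. Exact and O(n * pedigree depth) in practice.
    """
    sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    F = np.zeros(n)
    d = np.ones(n)
    for i in range(n):
        s, dm = sire[i], dam[i]
        if s >= 0 and dm >= 0:
            d[i] = 0.5 - 0.25 * (F[s] + F[dm])
        elif s >= 0:
            d[i] = 0.75 - 0.25 * F[s]
        elif dm >= 0:
            d[i] = 0.75 - 0.25 * F[dm]
        if s < 0 and dm < 0:
            continue  # founder: F = 0
        L = np.zeros(i + 1)
        L[i] = 1.0
        aii = 0.0
        for j in range(i, -1, -1):
            lj = L[j]
            if lj == 0.0:
                continue
            aii += lj * lj * d[j]
            if sire[j] >= 0:
                L[sire[j]] += 0.5 * lj
            if dam[j] >= 0:
                L[dam[j]] += 0.5 * lj
        F[i] = aii - 1.0
    return F
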