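"""Array-backed population state of a germinal center.

The living population is stored as parallel numpy arrays (one slot per
subclone) so the ODE right-hand side and the SHM update can operate on whole
vectors.  :class:`Subclone` is a lightweight per-subclone view used at API
boundaries and in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Subclone", "GCState", "EmptyPopulationError"]


class EmptyPopulationError(RuntimeError):
    """Raised when an operation requires at least one living subclone."""


@dataclass(frozen=True)
class Subclone:
    """One B-cell variant: immutable identity plus compartment counts."""

    id: int
    parent_id: int | None
    sigma: float          # absolute affinity (uM-scaled score; higher = stronger)
    n_mutations: int
    birth_step: int
    cb: float
    cc: float
    mem: float
    plasma: float


@dataclass
class GCState:
    """The living subclone population at one time point.

    All arrays share the same length and ordering.  ``removed_mem`` and
    ``removed_plasma`` accumulate the memory/plasma output carried by pruned
    subclones so GC export is never silently discarded.
    """

    time: float = 0.0
    step: int = 0
    ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    parent_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    sigma: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_mutations: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    birth_step: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    cb: np.ndarray = field(default_factory=lambda: np.empty(0))
    cc: np.ndarray = field(default_factory=lambda: np.empty(0))
    mem: np.ndarray = field(default_factory=lambda: np.empty(0))
    plasma: np.ndarray = field(default_factory=lambda: np.empty(0))
    next_id: int = 0
    removed_mem: float = 0.0
    removed_plasma: float = 0.0

    NO_PARENT: int = -1

    def __len__(self) -> int:
        return self.ids.size

    @property
    def n_subclones(self) -> int:
        return self.ids.size

    @property
    def cb_total(self) -> float:
        return float(self.cb.sum())

    @property
    def cc_total(self) -> float:
        return float(self.cc.sum())

    def add_subclones(
        self,
        sigma,
        n_mutations,
        parent_ids,
        cb,
        cc=None,
        mem=None,
        plasma=None,
    ) -> np.ndarray:
        """Append subclones; returns the newly assigned ids."""
        sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
        k = sigma.size
        new_ids = np.arange(self.next_id, self.next_id + k, dtype=np.int64)
        self.next_id += k

        def _arr(x, default=0.0, dtype=float):
            if x is None:
                return np.full(k, default, dtype=dtype)
            return np.broadcast_to(np.asarray(x, dtype=dtype), (k,)).copy()

        self.ids = np.concatenate([self.ids, new_ids])
        self.parent_ids = np.concatenate([self.parent_ids, _arr(parent_ids, dtype=np.int64)])
        self.sigma = np.concatenate([self.sigma, sigma])
        self.n_mutations = np.concatenate([self.n_mutations, _arr(n_mutations, dtype=np.int64)])
        self.birth_step = np.concatenate([self.birth_step, np.full(k, self.step, dtype=np.int64)])
        self.cb = np.concatenate([self.cb, _arr(cb)])
        self.cc = np.concatenate([self.cc, _arr(cc)])
        self.mem = np.concatenate([self.mem, _arr(mem)])
        self.plasma = np.concatenate([self.plasma, _arr(plasma)])
        return new_ids

    def keep(self, mask: np.ndarray) -> None:
        """Retain only subclones where ``mask`` is True (in place)."""
        for name in ("ids", "parent_ids", "sigma", "n_mutations",
                     "birth_step", "cb", "cc", "mem", "plasma"):
            setattr(self, name, getattr(self, name)[mask])

    def index_of(self, subclone_id: int) -> int:
        idx = np.flatnonzero(self.ids == subclone_id)
        if idx.size == 0:
            raise KeyError(f"no living subclone with id {subclone_id}")
        return int(idx[0])

    def subclone(self, subclone_id: int) -> Subclone:
        i = self.index_of(subclone_id)
        pid = int(self.parent_ids[i])
        return Subclone(
            id=int(self.ids[i]),
            parent_id=None if pid == self.NO_PARENT else pid,
            sigma=float(self.sigma[i]),
            n_mutations=int(self.n_mutations[i]),
            birth_step=int(self.birth_step[i]),
            cb=float(self.cb[i]),
            cc=float(self.cc[i]),
            mem=float(self.mem[i]),
            plasma=float(self.plasma[i]),
        )

    def subclones(self) -> list[Subclone]:
        return [self.subclone(int(i)) for i in self.ids]
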