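"""Somatic hypermutation engine.

After every 6-h centroblast division, each daughter cell acquires a Poisson
number of mutations.  Each mutation is routed through a fate tree: it hits
the framework region (FWR) or a complementarity-determining region (CDR),
may be a replacement or silent, an FWR replacement may be lethal, and a CDR
replacement may be neutral or affinity-changing.  A daughter with at least
one lethal mutation dies; a surviving mutated daughter founds a new subclone
(at the nucleotide tracking level for any mutation, at the peptide level only
for CDR replacements).  Affinity-changing daughters draw a single increment

    delta = X - mu - shift * sigma_parent,   X ~ InvGamma(shape, scale),

regardless of how many affinity-changing mutations they carry; mu = E[X]
centers the increment, and the parent-affinity shift makes improvements
increasingly unlikely for already-strong binders while the inverse-gamma
right tail keeps a small chance of large "key mutation" jumps.

Two interchangeable code paths exist: scalar per-cell functions
(:func:`draw_mutation_count`, :func:`classify_mutation`,
:func:`decide_cell_fate`) defining the unit semantics, and the vectorized
:func:`apply_shm_step` used by the simulator, which draws per-cell mutation
counts and per-cell multinomial leaf counts -- distributionally identical to
classifying each mutation one at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import (
    LEAF_NAMES,
    AffinityChangeParams,
    ModelParams,
    MutationTreeParams,
    ParameterError,
)
from .state import GCState

__all__ = [
    "MutationOutcome",
    "CellFate",
    "ShmStepRecord",
    "draw_mutation_count",
    "classify_mutation",
    "draw_affinity_delta",
    "decide_cell_fate",
    "apply_shm_step",
]

_LETHAL = "fwr_replacement_lethal"
_CDR_NEUTRAL = "cdr_replacement_neutral"
_CDR_AFFINITY = "cdr_replacement_affinity"


@dataclass(frozen=True)
class MutationOutcome:
    """One mutation's leaf in the fate tree; delta is zero unless the leaf
    is an affinity-changing CDR replacement."""

    category: str
    delta_affinity: float = 0.0

    def __post_init__(self) -> None:
        if self.category not in LEAF_NAMES:
            raise ParameterError(f"unknown mutation category {self.category!r}")


@dataclass(frozen=True)
class CellFate:
    """Aggregate fate of one daughter cell after m mutations."""

    n_mutations: int
    outcomes: tuple[MutationOutcome, ...]
    disposition: str  # unchanged | dies | spawns_new_subclone
    total_delta_affinity: float


def draw_mutation_count(rng: np.random.Generator, lam: float) -> int:
    """Number of mutations a daughter acquires in one division, ~Poisson(lam)."""
    if lam < 0:
        raise ParameterError("mutation rate lambda must be >= 0")
    return int(rng.poisson(lam))


def classify_mutation(rng: np.random.Generator, tree: MutationTreeParams) -> MutationOutcome:
    """Route one mutation through the fate tree by sequential branch draws."""
    if rng.random() < tree.p_fwr:
        if rng.random() < tree.p_repl_fwr:
            if rng.random() < tree.p_lethal_fwr:
                return MutationOutcome(_LETHAL)
            return MutationOutcome("fwr_replacement_viable")
        return MutationOutcome("silent")
    if rng.random() < tree.p_repl_cdr:
        if rng.random() < tree.p_affinity_cdr:
            return MutationOutcome(_CDR_AFFINITY)
        return MutationOutcome(_CDR_NEUTRAL)
    return MutationOutcome("silent")


def _draw_invgamma(rng: np.random.Generator, shape: float, scale: float, size=None):
    """InvGamma(shape, scale) via the reciprocal of a gamma variate."""
    return 1.0 / rng.gamma(shape, 1.0 / scale, size=size)


def draw_affinity_delta(
    rng: np.random.Generator,
    sigma_parent: float,
    params: AffinityChangeParams,
) -> float:
    """Affinity increment X - mu - shift*sigma_parent for one affinity event."""
    if sigma_parent < 0:
        raise ParameterError("sigma_parent must be >= 0")
    x = _draw_invgamma(rng, params.shape, params.scale)
    return float(x - params.mean - params.shift_coeff * sigma_parent)


def _spawns(level: str, peptide_rule: str, outcomes) -> bool:
    categories = [o.category for o in outcomes]
    if level == "nucleotide":
        return len(categories) > 0
    if peptide_rule == "affinity_only":
        return _CDR_AFFINITY in categories
    return _CDR_AFFINITY in categories or _CDR_NEUTRAL in categories


def decide_cell_fate(
    rng: np.random.Generator,
    n_mutations: int,
    tree: MutationTreeParams,
    affinity_params: AffinityChangeParams,
    sigma_parent: float,
    level: str = "nucleotide",
    peptide_spawn_rule: str = "any_cdr_replacement",
) -> CellFate:
    """Classify each of a daughter's mutations and aggregate its fate.

    Any lethal outcome kills the cell.  Otherwise the cell spawns a new
    subclone according to the tracking-level rule.  If one or more
    affinity-changing CDR replacements occurred, exactly one increment is
    drawn (multiple affinity-changing hits in the same division are not
    distinguished).
    """
    if n_mutations < 0:
        raise ParameterError("n_mutations must be >= 0")
    outcomes = tuple(classify_mutation(rng, tree) for _ in range(n_mutations))
    if any(o.category == _LETHAL for o in outcomes):
        return CellFate(n_mutations, outcomes, "dies", 0.0)
    delta = 0.0
    if any(o.category == _CDR_AFFINITY for o in outcomes):
        delta = draw_affinity_delta(rng, sigma_parent, affinity_params)
        outcomes = tuple(
            MutationOutcome(o.category, delta if o.category == _CDR_AFFINITY and not done else 0.0)
            for done, o in _mark_first_affinity(outcomes)
        )
    disposition = ("spawns_new_subclone"
                   if _spawns(level, peptide_spawn_rule, outcomes) else "unchanged")
    return CellFate(n_mutations, outcomes, disposition, delta)


def _mark_first_affinity(outcomes):
    seen = False
    for o in outcomes:
        yield seen, o
        if o.category == _CDR_AFFINITY:
            seen = True


def daughter_leave_probability(params: ModelParams) -> float:
    """Probability that a daughter cell leaves its parent subclone in one
    division (dies of a lethal hit or founds a new subclone).

    At the nucleotide level any mutated daughter leaves, so this is
    1 - exp(-lambda); at the peptide level only lethal hits and (depending on
    the spawn rule) CDR replacements remove a daughter, and Poisson thinning
    gives 1 - exp(-lambda * q) with q the per-mutation removal probability.
    """
    lam = params.mutations_per_division
    if params.subclone_level == "nucleotide":
        return float(1.0 - np.exp(-lam))
    lp = params.mutation_tree.leaf_probabilities()
    q = lp[1] + lp[4] if params.peptide_spawn_rule == "affinity_only" else lp[1] + lp[3] + lp[4]
    return float(1.0 - np.exp(-lam * q))


@dataclass
class ShmStepRecord:
    """Bookkeeping of one SHM sweep, for the events table and for audits.

    ``child_ids``/``parent_of_child`` etc. describe spawned subclones (one
    entry per spawn, in creation order); ``lethal_parent_ids`` lists the
    parent of every daughter killed by a lethal FWR replacement.
    """

    child_ids: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    parent_of_child: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    child_m: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    child_delta: np.ndarray = field(default_factory=lambda: np.empty(0))
    child_sigma: np.ndarray = field(default_factory=lambda: np.empty(0))
    child_leaf_counts: np.ndarray = field(default_factory=lambda: np.empty((0, 5), np.int64))
    lethal_parent_ids: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    @property
    def n_spawned(self) -> int:
        return self.child_ids.size

    @property
    def n_lethal(self) -> int:
        return self.lethal_parent_ids.size


def apply_shm_step(state: GCState, rng: np.random.Generator, params: ModelParams) -> ShmStepRecord:
    """Impose SHM on every eligible centroblast and rewrite the population.

    Subclones with CB below the eligibility floor (default 1 cell) are left
    untouched; for the rest, floor(CB_i) daughter cells each receive a fate.
    Dying or spawning daughters decrement the parent's CB by one each; every
    spawned subclone starts with CB=1, CC=M=P=0, the parent's mutation count
    plus its own m, and affinity clamped at the configured floor.  Total CB
    is conserved up to lethal deaths.
    """
    sched = params.schedule
    eligible = np.flatnonzero(state.cb >= sched.shm_eligibility_floor)
    rec = ShmStepRecord()
    if params.subunit_mutation_loss:
        # optional: sub-unit clones pay the same expected mutation outflow
        # (as deterministic decay; they still never spawn)
        p_leave = daughter_leave_probability(params)
        sub = state.cb < sched.shm_eligibility_floor
        state.cb = np.where(sub, state.cb * (1.0 - p_leave), state.cb)
    if eligible.size == 0:
        return rec

    n_cells = np.floor(state.cb[eligible]).astype(np.int64)
    if params.shm_sampling == "per_subclone":
        # one dividing daughter per eligible subclone per 6-h step
        parent_idx = eligible.copy()
        m = rng.poisson(params.mutations_per_division, size=eligible.size)
    elif params.shm_sampling == "poisson_events":
        # event-count mode: ~Poisson(lambda*floor(CB)) single-mutation
        # daughters per subclone, capped at the available cells
        events = np.minimum(rng.poisson(params.mutations_per_division * n_cells),
                            n_cells)
        parent_idx = np.repeat(eligible, events)
        m = np.ones(parent_idx.size, dtype=np.int64)
    else:  # per_cell: every one of floor(CB) daughters draws its own count
        parent_idx = np.repeat(eligible, n_cells)
        m = rng.poisson(params.mutations_per_division, size=parent_idx.size)

    mutated = m > 0
    parent_idx, m = parent_idx[mutated], m[mutated]
    if parent_idx.size == 0:
        return rec

    leaf_counts = rng.multinomial(m, params.mutation_tree.leaf_probabilities())
    lethal = leaf_counts[:, 1] > 0
    has_affinity = leaf_counts[:, 4] > 0
    cdr_repl = leaf_counts[:, 3] + leaf_counts[:, 4] > 0

    if params.subclone_level == "nucleotide":
        spawn = ~lethal
    elif params.peptide_spawn_rule == "affinity_only":
        spawn = ~lethal & has_affinity
    else:
        spawn = ~lethal & cdr_repl

    # one delta per spawning daughter with >= 1 affinity-changing mutation
    aff = spawn & has_affinity
    deltas = np.zeros(parent_idx.size)
    if aff.any():
        ap = params.affinity
        x = _draw_invgamma(rng, ap.shape, ap.scale, size=int(aff.sum()))
        deltas[aff] = x - ap.mean - ap.shift_coeff * state.sigma[parent_idx[aff]]

    # parent CB decrements: one per dying and one per spawning daughter
    removed = lethal | spawn
    if removed.any():
        dec = np.bincount(parent_idx[removed], minlength=state.n_subclones)
        state.cb = state.cb - dec

    rec.lethal_parent_ids = state.ids[parent_idx[lethal]]

    if spawn.any():
        sp = np.flatnonzero(spawn)
        p_idx = parent_idx[sp]
        sigma_child = np.maximum(state.sigma[p_idx] + deltas[sp],
                                 params.affinity.min_affinity)
        nmut_child = state.n_mutations[p_idx] + m[sp]
        parent_ids = state.ids[p_idx]
        child_ids = state.add_subclones(
            sigma=sigma_child, n_mutations=nmut_child,
            parent_ids=parent_ids, cb=1.0)
        rec.child_ids = child_ids
        rec.parent_of_child = parent_ids
        rec.child_m = m[sp]
        rec.child_delta = deltas[sp]
        rec.child_sigma = sigma_child
        rec.child_leaf_counts = leaf_counts[sp]
    return rec
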