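"""Model parameters for the germinal-center reaction simulator.

All quantities are grouped by the part of the model they feed:

* :class:`RateParams` -- proliferation/differentiation/death rates of the four
  B-cell compartments (centroblast CB, centrocyte CC, memory M, plasma P) plus
  the carrying-capacity term of the dark zone.
* :class:`SignalParams` -- the two sigmoidal survival signals derived from a
  subclone's relative affinity (one gating CB->CC differentiation, one gating
  CC apoptosis) and the monoclonal-expansion clamp.
* :class:`MutationTreeParams` -- branch probabilities of the somatic-
  hypermutation fate tree (framework vs CDR, replacement vs silent, lethal,
  affinity-changing).
* :class:`AffinityChangeParams` -- the inverse-gamma affinity-increment
  distribution for affinity-changing CDR replacements.
* :class:`ScheduleParams` -- timeline of the reaction (21 days, 6-h division
  steps, day-4 switches, founder cells, pruning thresholds).

Defaults are the literature-derived values of the published model; the fate
tree probabilities are not pinned by a single source and should be treated as
tunable (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "RateParams",
    "SignalParams",
    "MutationTreeParams",
    "AffinityChangeParams",
    "ScheduleParams",
    "ModelParams",
    "LEAF_NAMES",
    "ParameterError",
]


class ParameterError(ValueError):
    """Raised when a model parameter is out of its admissible range."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class RateParams:
    """Compartment rates (per day) and the dark-zone capacity term.

    ``capacity`` (A) and ``hill_h`` (h) shape the density-dependent
    proliferation factor A^h / (CB_total^h + A^h) that throttles CB division
    as the population approaches A cells.
    """

    rho_cb: float = 4.0        # CB proliferation
    eta_cb_cc: float = 6.0     # CB -> CC differentiation (max rate; gated by 1-S_d)
    eta_cc_cb: float = 1.0     # CC -> CB recycling
    eta_cc_m: float = 1.0      # CC -> memory
    eta_cc_p: float = 0.1      # CC -> plasma, per unit absolute affinity (day^-1 uM^-1)
    mu_cc: float = 4.0         # CC apoptosis (max rate; gated by 1-S_a)
    mu_p: float = 0.25         # plasma-cell death
    mu_m: float = 0.01         # memory-cell death
    capacity: float = 8000.0   # carrying capacity A (cells)
    hill_h: float = 20.0       # capacity Hill exponent h

    def __post_init__(self) -> None:
        for name in ("rho_cb", "eta_cb_cc", "eta_cc_cb", "eta_cc_m",
                     "eta_cc_p", "mu_cc", "mu_p", "mu_m"):
            _require(getattr(self, name) >= 0, f"rates.{name} must be >= 0")
        _require(self.capacity > 0, "rates.capacity must be > 0")
        _require(self.hill_h >= 1, "rates.hill_h must be >= 1")


@dataclass(frozen=True)
class SignalParams:
    """Sigmoidal survival-signal parameters S(x) = x^n / (k^n + x^n).

    ``k_d``/``n_d`` parameterize the differentiation signal S_d, ``k_a``/``n_a``
    the apoptosis signal S_a.  During the monoclonal-expansion phase (the
    first ``clamp_days`` of the reaction) both signals are pinned to
    ``clamp_value`` for every subclone so the founders can grow the GC.
    """

    k_d: float = 0.06
    n_d: float = 1.0
    k_a: float = 0.1
    n_a: float = 4.0
    clamp_value: float = 0.9
    clamp_days: float = 4.0

    def __post_init__(self) -> None:
        for k in ("k_d", "k_a"):
            _require(0 < getattr(self, k) <= 1, f"signals.{k} must be in (0, 1]")
        for n in ("n_d", "n_a"):
            _require(getattr(self, n) >= 1, f"signals.{n} must be >= 1")
        _require(0 <= self.clamp_value <= 1, "signals.clamp_value must be in [0, 1]")
        _require(self.clamp_days >= 0, "signals.clamp_days must be >= 0")


#: Canonical order of the five leaves of the mutation fate tree.
LEAF_NAMES = (
    "silent",
    "fwr_replacement_lethal",
    "fwr_replacement_viable",
    "cdr_replacement_neutral",
    "cdr_replacement_affinity",
)


@dataclass(frozen=True)
class MutationTreeParams:
    """Branch probabilities of the per-mutation fate tree.

    A mutation hits the framework region (FWR) with probability ``p_fwr``
    (otherwise a CDR); an FWR hit is a replacement with probability
    ``p_repl_fwr`` (else silent) and a replacement is lethal with probability
    ``p_lethal_fwr``; a CDR hit is a replacement with probability
    ``p_repl_cdr`` and a CDR replacement changes affinity with probability
    ``p_affinity_cdr`` (else neutral).

    These probabilities are not tightly constrained by data; the defaults are
    plausible literature-style values (FWR length fraction ~0.75, replacement
    fraction ~0.75, half of FWR replacements lethal, half of CDR replacements
    affinity-changing) and are first-class configuration.
    """

    p_fwr: float = 0.75
    p_repl_fwr: float = 0.75
    p_repl_cdr: float = 0.75
    p_lethal_fwr: float = 0.5
    p_affinity_cdr: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p_fwr", "p_repl_fwr", "p_repl_cdr",
                     "p_lethal_fwr", "p_affinity_cdr"):
            v = getattr(self, name)
            _require(0 <= v <= 1, f"mutation_tree.{name} must be in [0, 1]")

    def leaf_probabilities(self) -> np.ndarray:
        """Probabilities of the five tree leaves, in :data:`LEAF_NAMES` order.

        Products of branch probabilities; sums to 1 for any valid tree.
        """
        a, bf, bc = self.p_fwr, self.p_repl_fwr, self.p_repl_cdr
        d, e = self.p_lethal_fwr, self.p_affinity_cdr
        return np.array([
            a * (1 - bf) + (1 - a) * (1 - bc),   # silent (either region)
            a * bf * d,                           # FWR replacement, lethal
            a * bf * (1 - d),                     # FWR replacement, viable
            (1 - a) * bc * (1 - e),               # CDR replacement, neutral
            (1 - a) * bc * e,                     # CDR replacement, affinity
        ])


@dataclass(frozen=True)
class AffinityChangeParams:
    """Inverse-gamma affinity-increment distribution.

    An affinity-changing mutation updates sigma_child = sigma_parent + d with

        d = X - mu - shift_coeff * sigma_parent,
        X ~ InvGamma(shape, scale),  mu = E[X] = scale / (shape - 1).

    Centering by mu makes the increment zero-mean for a zero-affinity parent;
    the right skew of the inverse gamma leaves a small chance of large
    improvements ("key mutations"); the parent-affinity shift makes further
    gains progressively less likely for already-strong binders.

    ``rate`` follows the reciprocal-gamma convention: with
    ``rate_is_scale=True`` (default) it is the scale of the inverse gamma
    (equivalently the rate of the underlying gamma); set it False to read the
    value as 1/scale instead.
    """

    shape: float = 3.0
    rate: float = 0.3
    shift_coeff: float = 0.1      # affinity shift per unit parent affinity
    min_affinity: float = 1e-3    # floor for clamped affinities (uM)
    rate_is_scale: bool = True

    def __post_init__(self) -> None:
        _require(self.shape > 2,
                 "affinity.shape must be > 2 (finite mean and variance)")
        _require(self.rate > 0, "affinity.rate must be > 0")
        _require(self.shift_coeff >= 0, "affinity.shift_coeff must be >= 0")
        _require(self.min_affinity > 0, "affinity.min_affinity must be > 0")

    @property
    def scale(self) -> float:
        """Scale of the inverse gamma under the configured parameterization."""
        return self.rate if self.rate_is_scale else 1.0 / self.rate

    @property
    def mean(self) -> float:
        """Analytic mean mu of the inverse gamma (exists since shape > 2)."""
        return self.scale / (self.shape - 1.0)


@dataclass(frozen=True)
class ScheduleParams:
    """Timeline and bookkeeping thresholds of the reaction."""

    t_end: float = 21.0                 # days
    dt: float = 0.25                    # one CB division = 6 h
    shm_start_day: float = 4.0          # SHM (and clamp release) switch on
    n_founders: int = 3
    founder_affinities: tuple[float, ...] = (0.1, 0.3, 0.5)  # uM
    removal_threshold: float = 0.1      # prune when CB+CC falls below this
    shm_eligibility_floor: float = 1.0  # CB count required to mutate

    def __post_init__(self) -> None:
        _require(self.t_end > self.shm_start_day > 0,
                 "schedule requires t_end > shm_start_day > 0")
        _require(self.dt > 0, "schedule.dt must be > 0")
        n_steps = self.t_end / self.dt
        _require(abs(n_steps - round(n_steps)) < 1e-9,
                 "schedule.dt must divide t_end evenly")
        _require(len(self.founder_affinities) == self.n_founders,
                 "schedule.founder_affinities length must equal n_founders")
        _require(all(s > 0 for s in self.founder_affinities),
                 "schedule.founder_affinities must be positive")
        _require(self.removal_threshold >= 0,
                 "schedule.removal_threshold must be >= 0")
        _require(self.shm_eligibility_floor >= 0,
                 "schedule.shm_eligibility_floor must be >= 0")

    @property
    def n_steps(self) -> int:
        return round(self.t_end / self.dt)


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set of the model.

    ``subclone_level`` selects how SHM spawns new subclones: at the
    ``nucleotide`` level every non-lethal mutated daughter founds a new
    subclone; at the ``peptide`` level only daughters carrying at least one
    CDR replacement do (``peptide_spawn_rule='affinity_only'`` tightens this
    to affinity-changing replacements).

    ``mutations_per_division`` is the Poisson mean m per daughter cell,
    0.6 = 600 nt receptor x 1e-3 mutations/bp/division.

    ``shm_sampling`` chooses the granularity of the stochastic SHM overlay on
    the continuous cell counts: ``per_cell`` (default) mutates every one of
    floor(CB_i) daughters, so large clones mutate in proportion to their
    size; ``per_subclone`` mutates a single dividing daughter per eligible
    subclone per 6-h step; ``poisson_events`` draws
    ~Poisson(lambda*floor(CB_i)) single-mutation daughters per subclone.

    ``subunit_mutation_loss`` (off by default) additionally applies the
    expected mutation outflow to subclones below the SHM eligibility floor
    as a deterministic decay, so that sub-unit clones do not enjoy a
    mutation-free refuge relative to clones large enough to mutate; they
    still never spawn.  See docs/methods.md for why this matters.
    """

    rates: RateParams = field(default_factory=RateParams)
    signals: SignalParams = field(default_factory=SignalParams)
    mutation_tree: MutationTreeParams = field(default_factory=MutationTreeParams)
    affinity: AffinityChangeParams = field(default_factory=AffinityChangeParams)
    schedule: ScheduleParams = field(default_factory=ScheduleParams)
    mutations_per_division: float = 0.6
    subclone_level: str = "nucleotide"
    peptide_spawn_rule: str = "any_cdr_replacement"
    shm_sampling: str = "per_cell"
    subunit_mutation_loss: bool = False
    rtol: float = 1e-6
    atol: float = 1e-8

    def __post_init__(self) -> None:
        _require(self.mutations_per_division >= 0,
                 "mutations_per_division must be >= 0")
        _require(self.subclone_level in ("nucleotide", "peptide"),
                 "subclone_level must be 'nucleotide' or 'peptide'")
        _require(self.peptide_spawn_rule in ("any_cdr_replacement", "affinity_only"),
                 "peptide_spawn_rule must be 'any_cdr_replacement' or 'affinity_only'")
        _require(self.shm_sampling in ("per_subclone", "per_cell", "poisson_events"),
                 "shm_sampling must be 'per_subclone', 'per_cell' or 'poisson_events'")

    def replace(self, **kwargs: Any) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    def with_path(self, path: str, value: Any) -> "ModelParams":
        """Return a copy with the dotted parameter ``path`` set to ``value``.

        ``path`` is e.g. ``"rates.mu_cc"`` or ``"subclone_level"``.  Raises
        :class:`ParameterError` for unknown paths.
        """
        parts = path.split(".")
        if len(parts) == 1:
            name = parts[0]
            if name not in {f.name for f in dataclasses.fields(self)}:
                raise ParameterError(f"unknown parameter path: {path!r}")
            return dataclasses.replace(self, **{name: value})
        if len(parts) != 2:
            raise ParameterError(f"unknown parameter path: {path!r}")
        group, name = parts
        groups = {f.name for f in dataclasses.fields(self)}
        if group not in groups:
            raise ParameterError(f"unknown parameter group: {group!r}")
        sub = getattr(self, group)
        if not dataclasses.is_dataclass(sub) or name not in {f.name for f in dataclasses.fields(sub)}:
            raise ParameterError(f"unknown parameter path: {path!r}")
        return dataclasses.replace(self, **{group: dataclasses.replace(sub, **{name: value})})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
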