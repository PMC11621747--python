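"""Age-structured agent-based model of cultural transmission.

A metapopulation of ``n_groups`` groups of fixed size ``group_size`` evolves
in discrete years. Each year, in order:

1. **Survival** — each agent survives with probability ``exp(-r_S * age)``.
2. **Reproduction** — every vacant slot is refilled with an age-0 naive
   newborn, keeping group sizes exactly constant. Newborns inherit nothing
   culturally (they learn socially the same year), so parentage is not
   tracked.
3. **Migration** — each agent is flagged with probability ``m`` (or an
   age-class rate ``m_a``); flagged agents are exchanged by pairwise swaps
   between distinct groups so group sizes never change. An odd migrant out,
   or a pair that cannot be matched across groups, stays put that year.
4. **Learning** — newborns always learn; an agent of age ``a`` learns with
   probability ``exp(-r_L * a)``. A learner innovates with probability
   ``mu`` (receiving a globally novel variant); otherwise it samples
   ``n_partners`` distinct groupmates (self excluded) and adopts variant
   ``i`` with probability proportional to ``n_i**theta``, where ``n_i``
   counts variant ``i`` among the partners plus the learner's own current
   variant (if any). ``theta = 1`` is unbiased copying, ``theta > 1``
   conformist, ``theta < 1`` anticonformist. Naive agents are invisible to
   the tally. Updates are synchronous within the year.
5. **Aging** — survivors' ages increase by one.

A full run burns in the demography (no learning), seeds maximal
between-group diversity by fixing each group on its own unique variant, and
then records the cultural fixation index CFST each year.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diversity import cfst_from_matrix

__all__ = [
    "NAIVE",
    "AgeSchedule",
    "ABMParams",
    "Population",
    "YearEvents",
    "SimRecord",
    "survival_prob",
    "adoption_probs",
    "step_year",
    "run_simulation",
    "sweep_grid",
    "migration_contrast",
]

NAIVE = -1  # variant code for agents that have not yet acquired a trait


@dataclass(frozen=True)
class AgeSchedule:
    """Piecewise-constant annual migration probabilities by age class.

    ``boundaries`` are left edges of the classes (first must be 0); class k
    spans [boundaries[k], boundaries[k+1]). Defaults peak in young
    adulthood on the model's compressed age scale.
    """

    boundaries: tuple[int, ...] = (0, 3, 6, 12)
    rates: tuple[float, ...] = (0.05, 0.20, 0.10, 0.02)

    def __post_init__(self) -> None:
        if len(self.boundaries) != len(self.rates):
            raise ValueError("need one rate per age class")
        if self.boundaries[0] != 0 or list(self.boundaries) != sorted(set(self.boundaries)):
            raise ValueError("boundaries must start at 0 and strictly increase")
        if any(not 0.0 <= r <= 1.0 for r in self.rates):
            raise ValueError("migration probabilities must be in [0, 1]")

    @property
    def n_classes(self) -> int:
        return len(self.rates)

    def class_of(self, ages: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.boundaries, ages, side="right") - 1

    def rate_for(self, ages: np.ndarray) -> np.ndarray:
        return np.asarray(self.rates, dtype=float)[self.class_of(ages)]

    def scaled(self, factor: float) -> "AgeSchedule":
        """Rates multiplied by ``factor``, clipped into [0, 1]."""
        return replace(
            self, rates=tuple(float(np.clip(r * factor, 0.0, 1.0)) for r in self.rates)
        )


@dataclass(frozen=True)
class ABMParams:
    """Generative rates and structural constants of the simulator."""

    n_groups: int = 30
    group_size: int = 100
    n_partners: int = 30
    theta: float = 1.0
    mu: float = 0.01
    migration: float | AgeSchedule = 0.1
    r_S: float = 0.02
    r_L: float = 0.3
    burn_in_years: int = 500
    record_years: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_partners >= self.group_size:
            raise ValueError("n_partners must be smaller than group_size")
        if self.n_groups < 1 or self.group_size < 1:
            raise ValueError("n_groups and group_size must be positive")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")
        if isinstance(self.migration, (int, float)) and not 0.0 <= self.migration <= 1.0:
            raise ValueError("migration rate must be in [0, 1]")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.r_S < 0 or self.r_L < 0:
            raise ValueError("decline rates must be nonnegative")

    @property
    def n_agents(self) -> int:
        return self.n_groups * self.group_size

    def migration_rates(self, ages: np.ndarray) -> np.ndarray:
        if isinstance(self.migration, AgeSchedule):
            return self.migration.rate_for(ages)
        return np.full(len(ages), float(self.migration))


def survival_prob(age, r_S: float):
    """Annual survival probability exp(-r_S * age); nonincreasing in age."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 0) or r_S < 0:
        raise ValueError("age and r_S must be nonnegative")
    out = np.exp(-r_S * age)
    return float(out) if out.ndim == 0 else out


def adoption_probs(variant_counts: Mapping[object, float], theta: float) -> dict:
    """Frequency-dependent adoption probabilities p_i = n_i**theta / sum n**theta."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    counts = {v: c for v, c in variant_counts.items() if c > 0}
    if any(c < 0 for c in variant_counts.values()):
        raise ValueError("counts must be nonnegative")
    if not counts:
        raise ValueError("no variant with positive count to adopt")
    weights = {v: float(c) ** theta for v, c in counts.items()}
    total = sum(weights.values())
    return {v: w / total for v, w in weights.items()}


@dataclass
class YearEvents:
    """Per-year event detail, collected on demand for the observation layer."""

    learner_ids: np.ndarray  # ids of all agents that learned this year
    innovated_ids: np.ndarray  # subset that innovated
    social_ids: np.ndarray  # subset that sampled partners
    partner_ids: np.ndarray  # (len(social_ids), n_partners) partner agent ids
    partner_variants: np.ndarray  # same shape, partners' variants before updates
    migrated_ids: np.ndarray  # ids whose group actually changed
    died_ids: np.ndarray  # ids removed at the survival stage


@dataclass
class Population:
    """Metapopulation state. Slot ``s`` belongs to group ``s // group_size``."""

    n_groups: int
    group_size: int
    ids: np.ndarray
    ages: np.ndarray
    variants: np.ndarray
    year: int = 0
    next_variant: int = 0
    next_id: int = 0

    @classmethod
    def initial(cls, params: ABMParams) -> "Population":
        n = params.n_agents
        return cls(
            n_groups=params.n_groups,
            group_size=params.group_size,
            ids=np.arange(n, dtype=np.int64),
            ages=np.zeros(n, dtype=np.int64),
            variants=np.full(n, NAIVE, dtype=np.int64),
            next_id=n,
        )

    @property
    def groups(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_groups), self.group_size)

    def check(self) -> None:
        n = self.n_groups * self.group_size
        if not (len(self.ids) == len(self.ages) == len(self.variants) == n):
            raise RuntimeError("population invariant violated: wrong agent count")
        if np.any(self.ages < 0):
            raise RuntimeError("population invariant violated: negative age")

    def assign_unique_variants(self) -> None:
        """Fix every group on its own variant (maximal between-group diversity)."""
        self.variants = self.groups.astype(np.int64).copy()
        self.next_variant = max(self.next_variant, self.n_groups)

    def variant_count_matrix(self) -> np.ndarray:
        """(n_groups, n_distinct_variants) counts, naive agents excluded."""
        held = self.variants != NAIVE
        if not held.any():
            return np.zeros((self.n_groups, 1))
        codes = np.unique(self.variants[held], return_inverse=True)[1]
        n_var = codes.max() + 1
        flat = self.groups[held] * n_var + codes
        return np.bincount(flat, minlength=self.n_groups * n_var).reshape(
            self.n_groups, n_var
        ).astype(float)

    def cfst(self) -> float:
        return cfst_from_matrix(self.variant_count_matrix())

    def snapshot(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids.copy(),
                "age": self.ages.copy(),
                "group": self.groups,
                "variant": self.variants.copy(),
            }
        )

    # -- one simulated year -------------------------------------------------

    def step(
        self,
        params: ABMParams,
        rng: np.random.Generator,
        learning: bool = True,
        collect: bool = False,
    ) -> tuple[dict, YearEvents | None]:
        g_size = self.group_size
        n = self.n_groups * g_size

        # 1. survival
        died = rng.random(n) >= np.exp(-params.r_S * self.ages)
        died_ids = self.ids[died].copy()
        n_dead = int(died.sum())

        # 2. reproduction: vacant slots refilled with naive newborns
        self.ages[died] = 0
        self.variants[died] = NAIVE
        self.ids[died] = self.next_id + np.arange(n_dead)
        self.next_id += n_dead

        # 3. migration: pairwise swaps between distinct groups. Flagged
        # agents are paired at random; same-group pairs are repaired by one
        # rotation pass, and any still-unmatched pair (plus an odd migrant
        # out) stays put this year.
        rates = params.migration_rates(self.ages)
        flagged = np.flatnonzero(rng.random(n) < rates)
        migrated = np.zeros(n, dtype=bool)
        half = len(flagged) // 2
        if half:
            flagged = rng.permutation(flagged)
            a = flagged[:half]
            b = flagged[half : 2 * half]
            same = np.flatnonzero((a // g_size) == (b // g_size))
            if len(same):
                b[same] = b[np.roll(same, 1)]
                ok = (a // g_size) != (b // g_size)
                a, b = a[ok], b[ok]
            for arr in (self.ids, self.ages, self.variants):
                arr[a], arr[b] = arr[b], arr[a].copy()
            migrated[a] = True
            migrated[b] = True
        migrated_ids = self.ids[migrated].copy()

        # 4. learning (synchronous: tallies use start-of-phase variants)
        n_innov = 0
        events = None
        if learning:
            learner = rng.random(n) < np.exp(-params.r_L * self.ages)
            l_slots = np.flatnonzero(learner)
            innov = rng.random(len(l_slots)) < params.mu
            innov_slots = l_slots[innov]
            soc_slots = l_slots[~innov]
            n_innov = len(innov_slots)

            adopted, partner_slots, partner_variants = self._social_learning(
                soc_slots, params, rng
            )
            if collect:
                events = YearEvents(
                    learner_ids=self.ids[l_slots].copy(),
                    innovated_ids=self.ids[innov_slots].copy(),
                    social_ids=self.ids[soc_slots].copy(),
                    partner_ids=self.ids[partner_slots].copy(),
                    partner_variants=partner_variants,
                    migrated_ids=migrated_ids,
                    died_ids=died_ids,
                )
            held = adopted != NAIVE  # learners facing an all-naive tally stay naive
            self.variants[soc_slots[held]] = adopted[held]
            self.variants[innov_slots] = self.next_variant + np.arange(n_innov)
            self.next_variant += n_innov

        # 5. aging
        self.ages += 1
        self.year += 1
        self.check()

        tallies = {
            "year": self.year,
            "births": n_dead,
            "deaths": n_dead,
            "migrations": int(migrated.sum()),
            "innovations": n_innov,
        }
        return tallies, events

    def _social_learning(
        self, soc_slots: np.ndarray, params: ABMParams, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized partner sampling and n**theta adoption draw.

        Each learner's tally is the multiset of its partners' variants plus
        its own (one extra count). Picking an *entry* of that multiset with
        weight count(entry)**(theta-1) selects variant i with probability
        proportional to n_i**theta, which avoids building per-learner
        variant tables.
        """
        g_size = self.group_size
        k = len(soc_slots)
        L = params.n_partners
        if k == 0:
            empty = np.empty((0, L), dtype=np.int64)
            return np.empty(0, dtype=np.int64), empty, empty

        # distinct partners: the L smallest of G random keys, self masked out
        keys = rng.random((k, g_size))
        keys[np.arange(k), soc_slots % g_size] = np.inf
        local = np.argpartition(keys, L - 1, axis=1)[:, :L]
        partner_slots = (soc_slots // g_size)[:, None] * g_size + local
        partner_variants = self.variants[partner_slots].copy()

        entries = np.concatenate(
            [partner_variants, self.variants[soc_slots][:, None]], axis=1
        )
        order = np.argsort(entries, axis=1, kind="stable")
        svals = np.take_along_axis(entries, order, axis=1)
        new_seg = np.ones_like(svals, dtype=bool)
        new_seg[:, 1:] = svals[:, 1:] != svals[:, :-1]
        seg = np.cumsum(new_seg, axis=1) - 1
        rows = np.arange(k)[:, None]
        width = L + 1
        seg_len = np.bincount(
            (rows * width + seg).ravel(), minlength=k * width
        ).reshape(k, width)
        counts = seg_len[rows, seg]  # count of each entry's variant within its row
        with np.errstate(over="raise"):
            weights = counts.astype(float) ** (params.theta - 1.0)
        weights[svals == NAIVE] = 0.0
        totals = weights.sum(axis=1)
        draw = rng.random(k) * totals
        pick = (np.cumsum(weights, axis=1) > draw[:, None]).argmax(axis=1)
        adopted = svals[np.arange(k), pick]
        adopted[totals == 0.0] = NAIVE
        return adopted, partner_slots, partner_variants


@dataclass
class SimRecord:
    """Output of one simulation run."""

    cfst: np.ndarray  # index 0 = value at unique-variant assignment
    tallies: pd.DataFrame
    snapshot: pd.DataFrame
    params: ABMParams
    seed: int | None

    def mean_cfst(self, tail: int = 200) -> float:
        """Mean CFST over the last ``tail`` recorded years (excluding the
        assignment entry)."""
        recorded = self.cfst[1:]
        if len(recorded) == 0:
            return float(self.cfst[0])
        return float(recorded[-tail:].mean())


def step_year(
    pop: Population,
    params: ABMParams,
    rng: np.random.Generator,
    learning: bool = True,
    collect: bool = False,
) -> tuple[dict, YearEvents | None]:
    """Advance ``pop`` by one year in place; returns (tallies, events)."""
    return pop.step(params, rng, learning=learning, collect=collect)


def run_simulation(params: ABMParams, seed: int | None = None) -> SimRecord:
    """Burn in the demography, seed unique variants per group, record CFST."""
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    pop = Population.initial(params)
    for _ in range(params.burn_in_years):
        pop.step(params, rng, learning=False)
    pop.assign_unique_variants()
    cfst_series = [pop.cfst()]
    rows = []
    for _ in range(params.record_years):
        tallies, _ = pop.step(params, rng, learning=True)
        rows.append(tallies)
        cfst_series.append(pop.cfst())
    tallies_df = pd.DataFrame(
        rows, columns=["year", "births", "deaths", "migrations", "innovations"]
    )
    return SimRecord(
        cfst=np.asarray(cfst_series),
        tallies=tallies_df,
        snapshot=pop.snapshot(),
        params=params,
        seed=seed,
    )


def _replicate_seeds(seed: int | None, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def sweep_grid(
    theta_values: Sequence[float],
    m_values: Sequence[float],
    n_replicates: int,
    params: ABMParams,
    seed: int | None = None,
    tail: int = 200,
) -> pd.DataFrame:
    """Long-format table of mean terminal CFST per (theta, m, replicate).

    Each cell runs ``n_replicates`` independently seeded simulations and
    averages CFST over the final ``tail`` recorded years of each.
    """
    if not len(theta_values) or not len(m_values):
        raise ValueError("parameter grids must be nonempty")
    rows = []
    children = iter(
        np.random.SeedSequence(seed).spawn(len(theta_values) * len(m_values) * n_replicates)
    )
    for theta in theta_values:
        for m in m_values:
            p = replace(params, theta=theta, migration=m)
            for rep in range(n_replicates):
                child_seed = int(next(children).generate_state(1)[0] % (2**31))
                rec = run_simulation(p, seed=child_seed)
                rows.append(
                    {
                        "theta": theta,
                        "m": m,
                        "replicate": rep,
                        "mean_cfst": rec.mean_cfst(tail),
                    }
                )
    return pd.DataFrame(rows)


def migration_contrast(
    theta: float,
    m_low: float,
    m_high: float,
    params: ABMParams,
    n_replicates: int,
    seed: int | None = None,
    tail: int = 200,
) -> np.ndarray:
    """Distribution of Delta(CFST) between matched runs at m_high vs m_low.

    Replicate i uses common random numbers for both migration levels, so the
    returned differences isolate the migration effect.
    """
    diffs = []
    for child in np.random.SeedSequence(seed).spawn(n_replicates):
        state = child.generate_state(1)[0] % (2**31)
        low = run_simulation(replace(params, migration=m_low), seed=int(state))
        high = run_simulation(replace(params, migration=m_high), seed=int(state))
        diffs.append(high.mean_cfst(tail) - low.mean_cfst(tail))
    return np.asarray(diffs)
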