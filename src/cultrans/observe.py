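"""Synthetic observation layer: longitudinal panels and cross-sectional snapshots.

Emulates two styles of field data collected on the simulated metapopulation:

* a **longitudinal panel** — a wave-1 cohort of individuals followed yearly
  until death, recording each person's variant, group, true migration /
  innovation event indicators, and the variants of their social contacts
  (the actual interaction partners in years when they learned socially);
* a **cross-section** — a single-year summary (the CFST scalar, optionally
  per-group variant counts), the kind of data a typical comparative study
  would have.

Named presets mirror two canonical generating regimes: ``d_unbiased``
(theta = 1, m = 0.3) and ``d_conformist`` (theta = 2, m = 0.1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abm import NAIVE, ABMParams, Population, run_simulation

__all__ = [
    "LongitudinalPanel",
    "CrossSection",
    "sample_longitudinal",
    "make_reference",
    "preset_params",
    "validate_panel",
    "PRESETS",
]

#: generating regimes used for the reference cross-sections
PRESETS = {
    "d_unbiased": {"theta": 1.0, "migration": 0.3},
    "d_conformist": {"theta": 2.0, "migration": 0.1},
}

_RECORD_COLUMNS = [
    "year",
    "id",
    "age",
    "group",
    "variant",
    "prev_variant",
    "learned",
    "innovated",
    "migrated",
]


@dataclass
class LongitudinalPanel:
    """Person-year records plus an aligned (n_rows, L) contact-variant array.

    ``records`` columns: year, id, age, group, variant, prev_variant,
    learned, innovated, migrated. ``contacts[i]`` holds the variants of the
    L recorded contacts for row i (NAIVE for contacts holding no variant).
    ``prev_variant`` is the individual's variant at the end of the previous
    year (their own contribution to the adoption tally).
    """

    records: pd.DataFrame
    contacts: np.ndarray
    n_contacts: int

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, records_path, contacts_path) -> None:
        self.records.to_csv(records_path, index=False)
        n, L = self.contacts.shape
        long = pd.DataFrame(
            {
                "year": np.repeat(self.records["year"].to_numpy(), L),
                "id": np.repeat(self.records["id"].to_numpy(), L),
                "contact_rank": np.tile(np.arange(L), n),
                "contact_variant": self.contacts.ravel(),
            }
        )
        long.to_csv(contacts_path, index=False)

    @classmethod
    def from_csv(cls, records_path, contacts_path) -> "LongitudinalPanel":
        records = pd.read_csv(records_path)
        long = pd.read_csv(contacts_path)
        L = int(long["contact_rank"].max()) + 1 if len(long) else 0
        contacts = long["contact_variant"].to_numpy().reshape(len(records), L)
        return cls(records=records, contacts=contacts, n_contacts=L)


@dataclass
class CrossSection:
    """Single-year summary of the metapopulation."""

    year: int
    cfst: float
    group_counts: pd.DataFrame | None = None  # columns group, variant, count

    def __post_init__(self) -> None:
        if not 0.0 <= self.cfst <= 1.0:
            raise ValueError("CFST must lie in [0, 1]")

    def to_csv(self, path) -> None:
        pd.DataFrame({"year": [self.year], "cfst": [self.cfst]}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CrossSection":
        row = pd.read_csv(path).iloc[0]
        return cls(year=int(row["year"]), cfst=float(row["cfst"]))


def sample_longitudinal(
    params: ABMParams,
    n_individuals: int,
    n_years: int,
    seed: int | None = None,
    settle_years: int = 100,
) -> LongitudinalPanel:
    """Enroll a wave-1 cohort and follow it for ``n_years`` yearly waves.

    The simulation burns in the demography, seeds unique variants, runs
    ``settle_years`` with learning enabled to move off the artificial
    all-fixed start, then enrolls ``n_individuals`` uniformly at random from
    the whole metapopulation (no replacement enrollment afterwards). Each
    subsequent year produces one row per enrolled survivor with true event
    indicators and contact variants; contacts in years when the individual
    learned socially are the actual interaction partners, otherwise an
    observation-layer sample of groupmates.
    """
    if n_years <= 0:
        raise ValueError("n_years must be positive")
    if n_individuals > params.n_agents:
        raise ValueError("cannot enroll more individuals than the population holds")
    sim_ss, obs_ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(sim_ss)
    obs_rng = np.random.default_rng(obs_ss)

    pop = Population.initial(params)
    for _ in range(params.burn_in_years):
        pop.step(params, rng, learning=False)
    pop.assign_unique_variants()
    for _ in range(settle_years):
        pop.step(params, rng, learning=True)

    enrolled = obs_rng.choice(pop.ids, size=n_individuals, replace=False)
    enrolled = set(int(i) for i in enrolled)
    prev_variant = {int(i): int(v) for i, v in zip(pop.ids, pop.variants) if int(i) in enrolled}

    L = params.n_partners
    groups_template = pop.groups
    rows: list[tuple] = []
    contact_rows: list[np.ndarray] = []
    for wave in range(1, n_years + 1):
        _, ev = pop.step(params, rng, learning=True, collect=True)
        enrolled -= {int(i) for i in ev.died_ids}
        if not enrolled:
            break
        learner_ids = set(int(i) for i in ev.learner_ids)
        innovated_ids = set(int(i) for i in ev.innovated_ids)
        migrated_ids = set(int(i) for i in ev.migrated_ids)
        social_row = {int(i): r for r, i in enumerate(ev.social_ids)}

        # locate enrolled survivors in the post-step state
        id_to_slot = {int(i): s for s, i in enumerate(pop.ids) if int(i) in enrolled}
        for pid in sorted(enrolled):
            slot = id_to_slot[pid]
            group = int(groups_template[slot])
            learned = pid in learner_ids
            if learned and pid in social_row:
                cvars = ev.partner_variants[social_row[pid]]
            else:
                # observational sample of L groupmates (self excluded)
                base = group * params.group_size
                local = obs_rng.choice(params.group_size - 1, size=L, replace=False)
                local = local + (local >= slot - base)
                cvars = pop.variants[base + local]
            rows.append(
                (
                    wave,
                    pid,
                    int(pop.ages[slot]) - 1,  # age during the year (pre-aging)
                    group,
                    int(pop.variants[slot]),
                    prev_variant[pid],
                    int(learned),
                    int(pid in innovated_ids),
                    int(pid in migrated_ids),
                )
            )
            contact_rows.append(np.asarray(cvars, dtype=np.int64))
            prev_variant[pid] = int(pop.variants[slot])

    records = pd.DataFrame(rows, columns=_RECORD_COLUMNS)
    contacts = (
        np.vstack(contact_rows) if contact_rows else np.empty((0, L), dtype=np.int64)
    )
    return LongitudinalPanel(records=records, contacts=contacts, n_contacts=L)


def make_reference(params: ABMParams, seed: int | None = None) -> CrossSection:
    """Run the ABM to its recording horizon; return the final-year CFST."""
    rec = run_simulation(params, seed=seed)
    counts = (
        rec.snapshot[rec.snapshot["variant"] != NAIVE]
        .groupby(["group", "variant"])
        .size()
        .rename("count")
        .reset_index()
    )
    return CrossSection(
        year=params.burn_in_years + params.record_years,
        cfst=float(rec.cfst[-1]),
        group_counts=counts,
    )


def preset_params(name: str, base: ABMParams | None = None) -> ABMParams:
    """ABM parameters for a named generating regime (see ``PRESETS``)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    base = base if base is not None else ABMParams()
    return dataclasses.replace(base, **PRESETS[name])


def validate_panel(panel: LongitudinalPanel) -> list[str]:
    """Consistency (closure) checks; returns a list of violation messages.

    Checks, per individual: waves form a contiguous year range; non-learning
    years carry the previous variant forward; the realized group changes
    match the migration indicator; an innovated variant is novel (absent
    from self + contacts); a socially adopted variant lies in the support of
    self + contacts.
    """
    problems: list[str] = []
    rec = panel.records
    for pid, sub in rec.groupby("id"):
        years = sub["year"].to_numpy()
        if not np.array_equal(years, np.arange(years[0], years[0] + len(years))):
            problems.append(f"id {pid}: non-contiguous waves")
        prev_group = None
        for idx, row in sub.iterrows():
            support = set(panel.contacts[rec.index.get_loc(idx)]) - {NAIVE}
            if row["prev_variant"] != NAIVE:
                support.add(row["prev_variant"])
            if not row["learned"]:
                if row["variant"] != row["prev_variant"]:
                    problems.append(f"id {pid} year {row['year']}: variant changed without learning")
            elif row["innovated"]:
                if row["variant"] in support:
                    problems.append(f"id {pid} year {row['year']}: innovated variant not novel")
            elif row["variant"] != NAIVE and row["variant"] not in support:
                problems.append(
                    f"id {pid} year {row['year']}: adopted variant outside self+contacts"
                )
            if prev_group is not None and bool(row["migrated"]) != (row["group"] != prev_group):
                problems.append(f"id {pid} year {row['year']}: migration flag inconsistent")
            prev_group = row["group"]
    return problems
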