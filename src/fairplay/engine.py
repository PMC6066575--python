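"""Per-step life cycle and whole-run simulation driver.

Each simulation step executes seven phases in a fixed order:

1. juvenile play (pairing, bout counting, per-bout mortality ``c``)
2. maturation under the adult cap ``K``
3. adult foraging (reward ``R`` with success probability ``p``)
4. pooling & equal division of the step's gains among fair adults, per group
5. reproduction (threshold ``T``, delay ``d``, investment ``P``)
6. aging and lifespan deaths (dependent juveniles die with their parent)
7. group fission and cleanup

Pooling uses only the current step's foraging gains, never accumulated
holdings: pooling a step's gains and dividing by pool size leaves the
expected intake of fair and selfish adults identical (pR) while driving
the within-pool variance of that step's intake to zero — the variance
reduction that the whole model turns on.  Newborns (phase 5) are aged in
phase 6 of their birth step, so an offspring born at step t reaches age j
and matures at step t + j.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .params import ModelParams
from .population import (
    DeathCause,
    Population,
    init_population,
    remove_agents,
    spawn_offspring,
)

__all__ = [
    "StepReport",
    "SimResult",
    "step",
    "run_simulation",
    "play_phase",
    "mature_phase",
    "forage_phase",
    "pool_phase",
    "reproduce_phase",
    "age_phase",
    "fission_phase",
]


class StepReport(NamedTuple):
    step: int
    births: int
    play_bouts: int
    play_deaths: int
    matured: int
    cap_deaths: int
    lifespan_deaths: int
    fissions: int
    adult_count: int
    living_gene_frequency: float


_TRAJ_COLS = StepReport._fields


@dataclass
class SimResult:
    """Outcome of one run.

    ``gene_birth_frequency`` is the dependent variable of the model: the
    fraction of agents born during the measurement window
    [burn_in, tau) that carry the play gene at birth.  It is nan (with
    ``frequency_defined`` False) when the run produced no births in the
    window, e.g. extinction before burn-in.
    """

    params: ModelParams
    seed: int
    gene_birth_frequency: float
    frequency_defined: bool
    births_in_window: int
    play_mortality_percent: float
    extinct: bool
    extinction_step: int | None
    trajectory: pd.DataFrame | None

    def summary_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "gene_birth_frequency": (float(self.gene_birth_frequency)
                                     if self.frequency_defined else None),
            "births_in_window": int(self.births_in_window),
            "play_mortality_percent": float(self.play_mortality_percent),
            "extinct": bool(self.extinct),
            "extinction_step": (int(self.extinction_step)
                                if self.extinction_step is not None else None),
        }


# ---------------------------------------------------------------------
# phases


def play_phase(pop: Population, rng: np.random.Generator) -> tuple[int, int]:
    """Pair gene-carrying juveniles within groups for one play bout each.

    Juveniles without the play gene never play (and never pay the cost).
    Within each group, gene-carrying juveniles seek partners in random
    order, each pairing with a uniformly chosen group-mate that still
    lacks a partner; a juvenile left without any willing partner does not
    play.  The induced distribution is a uniform random within-group
    matching, realized here by randomly permuting the eligible juveniles
    and pairing adjacent members of the same group.  Both participants of
    a bout gain one bout count, and each independently dies with
    probability ``c``.  Returns (bouts, play deaths).
    """
    params = pop.params
    elig = np.flatnonzero(~pop.adult & pop.gene & (pop.age < params.j))
    if elig.size < 2:
        return 0, 0
    perm = rng.permutation(elig)
    order = np.argsort(pop.group[perm], kind="stable")
    s = perm[order]
    gs = pop.group[s]
    n = s.size
    # position within each contiguous group block
    block_start = np.maximum.accumulate(
        np.where(np.r_[True, gs[1:] != gs[:-1]], np.arange(n), 0))
    pos = np.arange(n) - block_start
    first = (pos % 2 == 0) & np.r_[gs[1:] == gs[:-1], False]
    firsts = s[first]
    seconds = s[np.flatnonzero(first) + 1]
    bouts = int(firsts.size)
    if bouts == 0:
        return 0, 0
    participants = np.concatenate([firsts, seconds])
    pop.bouts[participants] += 1
    newly = ~pop.ever_played[participants]
    pop.played_juveniles_total += int(np.count_nonzero(newly))
    pop.ever_played[participants] = True
    deaths = 0
    if params.c > 0:
        dead = participants[rng.random(participants.size) < params.c]
        deaths = int(dead.size)
        if deaths:
            pop.play_deaths_total += deaths
            remove_agents(pop, dead, DeathCause.PLAY)
    return bouts, deaths


def mature_phase(pop: Population, rng: np.random.Generator) -> tuple[int, int]:
    """Promote juveniles that completed the juvenile stage; enforce cap K.

    Candidates (age >= j) are processed in random order across the whole
    population, so the cap introduces no group bias: each matures while
    the adult count is below K, otherwise it dies (cause ``cap``).  On
    maturation an agent becomes fair iff fairness learning is enabled, it
    carries the play gene, and it played at least ``alpha`` bouts.
    Returns (matured, cap deaths).
    """
    params = pop.params
    cand = np.flatnonzero(~pop.adult & (pop.age >= params.j))
    if cand.size == 0:
        return 0, 0
    perm = rng.permutation(cand)
    room = max(0, params.K - pop.n_adults)
    promote, die = perm[:room], perm[room:]
    pop.adult[promote] = True
    if params.learn_fairness:
        pop.is_fair[promote] = (pop.gene[promote]
                                & (pop.bouts[promote] >= params.alpha))
    n_cap = int(die.size)
    if n_cap:
        remove_agents(pop, die, DeathCause.CAP)
    return int(promote.size), n_cap


def forage_phase(pop: Population, rng: np.random.Generator) -> np.ndarray:
    """Per-agent foraging gains for this step (zero for juveniles).

    Each adult succeeds with probability p; a success yields
    max(0, R + Normal(0, 0.1 R)) resource units.  The clamp at zero is a
    guard only (a negative draw needs a -10 sigma deviate).  Gains are
    returned, not yet credited: crediting happens in the pooling phase.
    """
    params = pop.params
    gains = np.zeros(pop.size)
    ad = np.flatnonzero(pop.adult)
    if ad.size == 0:
        return gains
    success = rng.random(ad.size) < params.p
    amounts = np.maximum(0.0, rng.normal(params.R, params.sd_R, ad.size))
    gains[ad] = np.where(success, amounts, 0.0)
    return gains


def pool_phase(pop: Population, gains: np.ndarray) -> np.ndarray:
    """Pool and evenly divide the step's gains among fair adults per group.

    Selfish adults keep their own gains.  Within each group, the gains of
    the m fair adults are summed and every fair adult is credited pool/m
    (a pool of one is the identity).  The returned per-agent credit is
    added to ``resources``; its total equals the total foraged gains
    exactly, so pooling conserves resources.
    """
    credits = gains.copy()
    fair = pop.adult & pop.is_fair
    if np.any(fair):
        nbins = pop.next_group_id
        grp = pop.group[fair]
        pool = np.bincount(grp, weights=gains[fair], minlength=nbins)
        m = np.bincount(grp, minlength=nbins)
        share = np.divide(pool, m, out=np.zeros_like(pool), where=m > 0)
        credits[fair] = share[grp]
    pop.resources += credits
    return credits


def reproduce_phase(pop: Population,
                    rng: np.random.Generator) -> tuple[int, int]:
    """One offspring per adult that meets threshold and delay this step.

    An adult reproduces iff resources >= T and at least d steps have
    passed since its last reproduction; it produces exactly one offspring
    per event regardless of surplus.  Returns (births, gene-on births).
    """
    params = pop.params
    step_idx = pop.step_index
    eligible = np.flatnonzero(
        pop.adult & (pop.resources >= params.T)
        & (step_idx - pop.last_repro >= params.d))
    if eligible.size == 0:
        return 0, 0
    return spawn_offspring(pop, eligible, step_idx, rng)


def age_phase(pop: Population) -> tuple[int, int]:
    """Increment every agent's age; remove those at the end of lifespan.

    Adults dying of lifespan take their living juvenile offspring along
    (dependent-offspring rule).  Returns the lifespan death count (the
    dependents are logged under cause ``parent_death``).
    """
    pop.age += 1
    dead = np.flatnonzero(pop.age >= pop.lifespan)
    if dead.size == 0:
        return 0, 0
    counts = remove_agents(pop, dead, DeathCause.LIFESPAN)
    return counts[DeathCause.LIFESPAN], counts.get(DeathCause.PARENT_DEATH, 0)


def fission_phase(pop: Population, rng: np.random.Generator) -> int:
    """Split groups that reached fission size f while below the group cap G.

    A fissioning group sends g adults, sampled uniformly without
    replacement, to a fresh group; moved adults take their dependent
    juveniles with them.  Returns the number of fissions this step.
    """
    params = pop.params
    if pop.size == 0:
        return 0
    adult_counts = np.bincount(pop.group[pop.adult], minlength=pop.next_group_id)
    big = np.flatnonzero(adult_counts >= params.f)
    if big.size == 0:
        return 0
    fissions = 0
    n_groups = pop.n_groups
    for gid in rng.permutation(big):
        if n_groups >= params.G:
            break
        adults_here = np.flatnonzero(pop.adult & (pop.group == gid))
        if adults_here.size < params.f:
            continue
        movers = rng.choice(adults_here, size=params.g, replace=False)
        new_gid = pop.next_group_id
        pop.next_group_id += 1
        pop.group[movers] = new_gid
        deps = np.flatnonzero((~pop.adult) & (pop.group == gid)
                              & np.isin(pop.parent_uid, pop.uid[movers]))
        pop.group[deps] = new_gid
        fissions += 1
        n_groups += 1
    return fissions


# ---------------------------------------------------------------------
# step & run


def step(pop: Population, rng: np.random.Generator) -> StepReport:
    """Execute one full simulation step; returns the phase counters."""
    if pop.extinct:
        raise RuntimeError("cannot step an extinct population")
    bouts, play_deaths = play_phase(pop, rng)
    matured, cap_deaths = mature_phase(pop, rng)
    gains = forage_phase(pop, rng)
    pool_phase(pop, gains)
    births, births_on = reproduce_phase(pop, rng)
    lifespan_deaths, parent_deaths = age_phase(pop)
    fissions = fission_phase(pop, rng)
    pop.log_births(births_on, births - births_on)
    pop.log_deaths(play=play_deaths, cap=cap_deaths,
                   lifespan=lifespan_deaths, parent_death=parent_deaths)
    report = StepReport(
        step=pop.step_index,
        births=births,
        play_bouts=bouts,
        play_deaths=play_deaths,
        matured=matured,
        cap_deaths=cap_deaths,
        lifespan_deaths=lifespan_deaths,
        fissions=fissions,
        adult_count=pop.n_adults,
        living_gene_frequency=pop.living_gene_frequency(),
    )
    pop.step_index += 1
    return report


def run_simulation(params: ModelParams, seed: int,
                   record_trajectory: bool = False) -> SimResult:
    """Run one complete simulation from a seed.

    Initializes the founder population, executes ``tau`` steps (halting
    early if the adult population goes extinct), and summarizes:

    * ``gene_birth_frequency`` — gene-on births / all births over steps
      [burn_in, tau);
    * ``play_mortality_percent`` — 100 x play deaths / juveniles that
      entered at least one bout, over the whole run.

    Identical (params, seed) always produce an identical result.
    """
    rng = np.random.default_rng(seed)
    pop = init_population(params, rng)
    traj = [] if record_trajectory else None
    extinct = False
    extinction_step = None
    for t in range(params.tau):
        report = step(pop, rng)
        if traj is not None:
            traj.append(report)
        if pop.extinct:
            extinct = True
            extinction_step = t
            break
    on = sum(pop.births_on[params.burn_in:])
    off = sum(pop.births_off[params.burn_in:])
    births_in_window = on + off
    defined = births_in_window > 0
    freq = on / births_in_window if defined else float("nan")
    if pop.played_juveniles_total > 0:
        mortality = 100.0 * pop.play_deaths_total / pop.played_juveniles_total
    else:
        mortality = 0.0
    trajectory = (pd.DataFrame(traj, columns=_TRAJ_COLS)
                  if record_trajectory else None)
    return SimResult(
        params=params,
        seed=int(seed),
        gene_birth_frequency=freq,
        frequency_defined=defined,
        births_in_window=births_in_window,
        play_mortality_percent=mortality,
        extinct=extinct,
        extinction_step=extinction_step,
        trajectory=trajectory,
    )
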