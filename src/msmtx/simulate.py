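"""Synthetic illness-death cohorts with known truth and registry sampling.

The generator emulates the data situation of a transplant-vs-no-transplant
registry comparison: a complete cohort moves through Diagnosis -> Transplant
-> Death with configurable piecewise-constant hazards, and two *partial*
views of it are then taken:

* the transplant registry sees only patients with an observed transplant
  (right-truncating the waiting time at the administrative cutoff and
  left-truncating post-transplant follow-up), and
* the non-transplant registry sees only patients who were never candidates
  for transplant.

Patients on the transplant pathway who die while waiting are visible in
neither registry -- they are the structural blind spot the multi-state
reconstruction has to compensate for.

Mechanism, per subject:

1. covariates and a shared lognormal frailty ``Z`` (``E[Z] = 1``) are drawn;
2. with probability ``pathway_prob`` the subject is routed to the transplant
   pathway; otherwise the transplant hazard is zero for them;
3. on the pathway, latent waiting time ``T12`` (hazard ``hazard_12`` scaled
   by ``Z**selection_gamma``) races latent pre-transplant death ``T13``
   (hazard ``hazard_13`` scaled by ``Z``);
4. if transplant wins, post-transplant death follows ``hazard_23 * Z`` on
   the chosen clock (time since diagnosis, or since transplant);
5. administrative censoring is drawn uniformly over a calendar window.

With ``frailty_sd = 0`` the pre-transplant death hazard is identical for
pathway and non-pathway subjects (the Markov / equal-mortality assumption
holds by construction); ``frailty_sd > 0`` with ``selection_gamma != 0``
routes high-risk patients preferentially to (or away from) transplant and
violates it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .stepfun import DAYS_PER_YEAR
from .events import REGISTRY_COLUMNS

__all__ = [
    "PiecewiseHazard",
    "ScenarioParams",
    "CompleteCohort",
    "simulate_cohort",
    "apply_registry_sampling",
    "make_scenario_presets",
]


@dataclass(frozen=True)
class PiecewiseHazard:
    """Piecewise-constant hazard: ``rates[j]`` applies on the j-th interval.

    ``breakpoints`` are in days (strictly increasing, all > 0); the first
    rate applies on ``[0, breakpoints[0])`` and the last beyond the final
    breakpoint.  Rates are per day.
    """

    breakpoints: tuple = ()
    rates: tuple = (0.0,)

    def __post_init__(self):
        object.__setattr__(self, "breakpoints", tuple(float(b) for b in self.breakpoints))
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))
        if len(self.rates) != len(self.breakpoints) + 1:
            raise ValueError("need len(rates) == len(breakpoints) + 1")
        if any(r < 0 for r in self.rates):
            raise ValueError("hazard rates must be >= 0")
        if any(b <= 0 for b in self.breakpoints) or any(
            b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])
        ):
            raise ValueError("breakpoints must be strictly increasing and > 0")

    @classmethod
    def constant(cls, rate_per_year: float) -> "PiecewiseHazard":
        return cls((), (rate_per_year / DAYS_PER_YEAR,))

    @classmethod
    def from_yearly(cls, rates_per_year, breakpoints_days=()) -> "PiecewiseHazard":
        return cls(tuple(breakpoints_days),
                   tuple(r / DAYS_PER_YEAR for r in rates_per_year))

    @property
    def is_zero(self) -> bool:
        return all(r == 0.0 for r in self.rates)

    @property
    def is_constant(self) -> bool:
        return len(set(self.rates)) == 1

    def _cum_at_breaks(self):
        out = [0.0]
        prev = 0.0
        for b, r in zip(self.breakpoints, self.rates):
            out.append(out[-1] + r * (b - prev))
            prev = b
        return out

    def cumulative(self, t):
        """Cumulative hazard H(t)."""
        t = np.asarray(t, dtype=float)
        edges = np.array((0.0,) + self.breakpoints)
        cum = np.array(self._cum_at_breaks())
        rates = np.array(self.rates)
        idx = np.searchsorted(edges, t, side="right") - 1
        idx = np.clip(idx, 0, len(rates) - 1)
        out = cum[idx] + rates[idx] * (t - edges[idx])
        return out if out.ndim else float(out)

    def rate_at(self, t: float) -> float:
        edges = (0.0,) + self.breakpoints
        for i in range(len(edges) - 1, -1, -1):
            if t >= edges[i]:
                return self.rates[i]
        return self.rates[0]

    def inverse(self, h: float) -> float:
        """Smallest t with H(t) = h; inf when the total mass is exhausted."""
        if h <= 0.0:
            return 0.0
        edges = (0.0,) + self.breakpoints
        cum = self._cum_at_breaks()  # H at each edge
        for i, r in enumerate(self.rates):
            top = cum[i + 1] if i < len(self.breakpoints) else math.inf
            if h <= top:
                if r == 0.0:
                    continue  # flat piece: jump to the next edge
                return edges[i] + (h - cum[i]) / r
        return math.inf

    def sample(self, exp_draw: float, factor: float = 1.0, t0: float = 0.0) -> float:
        """Inversion sampling, optionally conditional on survival to ``t0``.

        ``exp_draw`` is a unit-exponential variate; the subject's hazard is
        ``factor`` times this baseline.
        """
        if factor <= 0.0:
            return math.inf
        return self.inverse(float(self.cumulative(t0)) + exp_draw / factor)

    def constant_ratio_to(self, other: "PiecewiseHazard"):
        """r such that self = r * other everywhere, or None."""
        edges = sorted(set(self.breakpoints) | set(other.breakpoints) | {0.0})
        ratios = set()
        for e in edges:
            a, b = self.rate_at(e), other.rate_at(e)
            if a == 0.0 and b == 0.0:
                continue
            if b == 0.0:
                return None
            ratios.add(round(a / b, 12))
        if len(ratios) == 1:
            return ratios.pop()
        return None if ratios else 1.0

    def to_dict(self) -> dict:
        return {"breakpoints_days": list(self.breakpoints),
                "rates_per_day": list(self.rates)}

    @classmethod
    def from_dict(cls, d: dict) -> "PiecewiseHazard":
        return cls(tuple(d["breakpoints_days"]), tuple(d["rates_per_day"]))


def _default_prevalences():
    return {"age_gt60": 0.5, "raebt": 0.3, "cyto_abnormal": 0.5}


def _default_effects():
    return {"12": {}, "13": {}, "23": {}}


@dataclass
class ScenarioParams:
    """Full generative specification of the simulator and registry sampling.

    Notes
    -----
    ``pathway_prob`` is the baseline probability of being routed to the
    transplant pathway at diagnosis; non-pathway subjects have transplant
    hazard zero and form the non-transplant registry population.  With the
    default 1.0 every subject races transplant against death, and the
    fraction transplanted approaches the competing-risk fraction
    ``h12 / (h12 + h13)`` for constant hazards.
    """

    hazard_12: PiecewiseHazard
    hazard_13: PiecewiseHazard
    hazard_23: PiecewiseHazard
    clock_23: str = "forward"
    covariate_effects: dict = field(default_factory=_default_effects)
    covariate_prevalences: dict = field(default_factory=_default_prevalences)
    cyto_missing_frac: float = 0.0
    year_range: tuple = (1998, 2005)
    pathway_prob: float = 1.0
    frailty_sd: float = 0.0
    selection_gamma: float = 0.0
    admin_censor: tuple | None = None  # (lo_days, hi_days), uniform
    n: int = 1000
    seed: int = 0

    def __post_init__(self):
        for name in ("hazard_12", "hazard_13", "hazard_23"):
            h = getattr(self, name)
            if isinstance(h, dict):
                setattr(self, name, PiecewiseHazard.from_dict(h))
        if self.clock_23 not in ("forward", "reset"):
            raise ValueError("clock_23 must be 'forward' or 'reset'")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.frailty_sd < 0:
            raise ValueError("frailty_sd must be >= 0")
        if not 0.0 <= self.pathway_prob <= 1.0:
            raise ValueError("pathway_prob must be in [0, 1]")
        if self.admin_censor is not None:
            lo, hi = self.admin_censor
            if not (0 < lo <= hi):
                raise ValueError("admin_censor window must satisfy 0 < lo <= hi")
            self.admin_censor = (float(lo), float(hi))
        eff = {"12": {}, "13": {}, "23": {}}
        eff.update({k: dict(v) for k, v in self.covariate_effects.items()})
        self.covariate_effects = eff

    def to_dict(self) -> dict:
        d = asdict(self)
        for name in ("hazard_12", "hazard_13", "hazard_23"):
            d[name] = getattr(self, name).to_dict()
        d["year_range"] = list(self.year_range)
        d["admin_censor"] = list(self.admin_censor) if self.admin_censor else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioParams":
        d = dict(d)
        for name in ("hazard_12", "hazard_13", "hazard_23"):
            d[name] = PiecewiseHazard.from_dict(d[name])
        d["year_range"] = tuple(d["year_range"])
        if d.get("admin_censor") is not None:
            d["admin_censor"] = tuple(d["admin_censor"])
        return cls(**d)


@dataclass
class CompleteCohort:
    """A simulated cohort plus its latent truth.

    ``records`` uses the registry CSV schema with ``cohort='complete'``;
    ``truth`` carries what no registry observes: latent event times before
    censoring, the frailty, and the pathway flag.
    """

    records: pd.DataFrame
    truth: pd.DataFrame
    params: ScenarioParams

    def __len__(self):
        return len(self.records)

    def pathway_truth_death_times(self) -> np.ndarray:
        """Latent from-diagnosis death times of the transplant-pathway group.

        This is the bias-study's truth estimand: survival of the cohort that
        follows the transplant strategy, uncensored, valid under frailty.
        """
        m = self.truth["pathway"].values.astype(bool)
        return self.truth.loc[m, "t_death_latent"].values


def simulate_cohort(params: ScenarioParams) -> CompleteCohort:
    """Draw a complete illness-death cohort; reproducible given the seed.

    One master seed spawns an independent substream per subject, so growing
    ``n`` leaves earlier subjects' trajectories unchanged.
    """
    if params.hazard_12.is_zero and params.hazard_13.is_zero:
        raise ValueError("degenerate scenario: all transition hazards out of "
                         "Diagnosis are zero")

    prev = params.covariate_prevalences
    eff = params.covariate_effects
    y_lo, y_hi = params.year_range
    children = np.random.SeedSequence(params.seed).spawn(params.n)

    rows = []
    lat = []
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        u = rng.random(7)
        znorm = rng.standard_normal()
        e12, e13, e23 = rng.standard_exponential(3)

        age = float(u[0] < prev.get("age_gt60", 0.5))
        raebt = float(u[1] < prev.get("raebt", 0.3))
        cyto = float(u[2] < prev.get("cyto_abnormal", 0.5))
        cyto_obs = np.nan if u[3] < params.cyto_missing_frac else cyto
        year = int(y_lo + math.floor(u[4] * (y_hi - y_lo + 1)))
        year = min(year, y_hi)

        if params.frailty_sd > 0:
            logz = params.frailty_sd * znorm - 0.5 * params.frailty_sd ** 2
        else:
            logz = 0.0
        z = math.exp(logz)
        pathway = u[5] < params.pathway_prob

        x = {"age_gt60": age, "raebt": raebt, "cyto_abnormal": cyto}

        def lp(trans):
            # missing cytogenetics contributes at the reference level
            return sum(b * (0.0 if np.isnan(x[c]) else x[c])
                       for c, b in eff.get(trans, {}).items())

        f12 = math.exp(lp("12") + params.selection_gamma * logz)
        f13 = math.exp(lp("13")) * z
        f23 = math.exp(lp("23")) * z

        t12 = params.hazard_12.sample(e12, f12) if pathway else math.inf
        t13 = params.hazard_13.sample(e13, f13)
        if t12 < t13:
            if params.clock_23 == "forward":
                t_death = params.hazard_23.sample(e23, f23, t0=t12)
            else:
                t_death = t12 + params.hazard_23.sample(e23, f23)
        else:
            t_death = t13

        c = rng.uniform(*params.admin_censor) if params.admin_censor else math.inf
        if not (t_death < math.inf or c < math.inf):
            raise ValueError(
                "subject with infinite follow-up: bounded hazards require "
                "administrative censoring")

        tx_observed = t12 < t13 and t12 <= c
        t_end = min(t_death, c)
        dead = int(t_death <= c)

        rows.append({
            "id": f"s{i:06d}", "cohort": "complete",
            "t_tx_days": t12 if tx_observed else np.nan,
            "t_end_days": t_end, "dead": dead,
            "r_trunc_days": c if c < math.inf else np.nan,
            "age_gt60": age, "raebt": raebt, "cyto_abnormal": cyto_obs,
            "year_dx": year,
        })
        lat.append({
            "id": f"s{i:06d}", "frailty": z, "pathway": pathway,
            "t12_latent": t12, "t13_latent": t13, "t_death_latent": t_death,
            "censor_days": c, "transplanted_first": t12 < t13,
            "observed_tx": tx_observed,
        })

    records = pd.DataFrame(rows, columns=REGISTRY_COLUMNS)
    truth = pd.DataFrame(lat)
    return CompleteCohort(records=records, truth=truth, params=params)


def apply_registry_sampling(
    cohort: CompleteCohort,
    *,
    unobserved_pathway: str = "drop",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Take the two registry views of a complete cohort.

    The transplant registry keeps subjects with an *observed* transplant
    (transplant before death and before the administrative cutoff), so it
    never contains a death while waiting; their right-truncation limit is
    the censoring offset.  The non-transplant registry keeps subjects who
    could never transplant (latent transplant time infinite, i.e. not on
    the pathway).  Pathway subjects without an observed transplant -- deaths
    while waiting, or transplants beyond the registry window -- appear in
    neither registry by default (``unobserved_pathway='drop'``), mirroring a
    transplant registry that never registered them and a regional registry
    that covers a different population; ``'non_tx'`` reassigns them instead.
    """
    if unobserved_pathway not in ("drop", "non_tx"):
        raise ValueError("unobserved_pathway must be 'drop' or 'non_tx'")
    rec = cohort.records.set_index("id", drop=False)
    tru = cohort.truth.set_index("id")

    tx_mask = tru["observed_tx"].values.astype(bool)
    never_tx = ~np.isfinite(tru["t12_latent"].values)
    if unobserved_pathway == "non_tx":
        non_tx_mask = ~tx_mask
    else:
        non_tx_mask = never_tx

    tx = rec.loc[tru.index[tx_mask]].copy()
    non_tx = rec.loc[tru.index[non_tx_mask]].copy()

    tx["cohort"] = "tx_registry"
    non_tx["cohort"] = "non_tx_registry"
    non_tx["t_tx_days"] = np.nan
    non_tx["r_trunc_days"] = np.nan
    return (tx.reset_index(drop=True)[REGISTRY_COLUMNS],
            non_tx.reset_index(drop=True)[REGISTRY_COLUMNS])


def make_scenario_presets(n: int = 2000, seed: int = 0) -> dict:
    """Named study scenarios.

    * ``s1-markov``   -- constant hazards, no frailty: the equal-mortality
      (Markov) assumption holds and transplant neither helps nor harms
      (post-transplant death rate equals the pre-transplant rate).
    * ``s1-trm``      -- early post-transplant spike (treatment-related
      mortality) during the first quarter year.
    * ``frailty-selection`` -- shared frailty with risk-proportional routing
      to transplant: the crucial assumption fails.
    * ``tv-effect``   -- post-transplant hazard calibrated so the true
      transplant-vs-none hazard ratio on the diagnosis time scale is 5.8 in
      the first 3 months, ~2.4 until one year, and exactly 1 afterwards.

    Magnitudes follow the registry setting: waiting-time hazard 1.0/y
    (median observed wait around half a year), pre-transplant death hazard
    0.5/y (median untreated survival around 1.4 years), administrative
    censoring uniform over 1.5-8 years of follow-up.
    """
    base = dict(
        clock_23="forward",
        pathway_prob=0.5,
        admin_censor=(1.5 * DAYS_PER_YEAR, 8.0 * DAYS_PER_YEAR),
        n=n,
        seed=seed,
    )
    h12 = PiecewiseHazard.constant(1.0)
    h13 = PiecewiseHazard.constant(0.5)
    q = 0.25 * DAYS_PER_YEAR

    presets = {
        "s1-markov": ScenarioParams(
            hazard_12=h12, hazard_13=h13,
            hazard_23=PiecewiseHazard.constant(0.5), **base),
        "s1-trm": ScenarioParams(
            hazard_12=h12, hazard_13=h13,
            hazard_23=PiecewiseHazard.from_yearly((2.5, 0.4), (q,)), **base),
        "frailty-selection": ScenarioParams(
            hazard_12=h12, hazard_13=h13,
            hazard_23=PiecewiseHazard.constant(0.5),
            frailty_sd=0.8, selection_gamma=1.5, **base),
        "tv-effect": ScenarioParams(
            hazard_12=h12, hazard_13=h13,
            # clock-forward ratio to hazard_13: 5.8 -> sqrt(5.8) -> 1.0
            hazard_23=PiecewiseHazard.from_yearly(
                (5.8 * 0.5, math.sqrt(5.8) * 0.5, 0.5),
                (q, DAYS_PER_YEAR)), **base),
    }
    return presets
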